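{
 "genome_sizes.tsv": "3feeb691301760d917fc19cbab5393462a1fd848b918087dd66e8bf6ebdeda25",
 "table1_chromosomes.tsv": "67a2e098aa2d725355644bb744b0f1f852fa8cb252801203112a673fdf75a2a2",
 "table1_summary.tsv": "1fdeffdb3e49f9eafc9406fb8806d38d6f7bdad217fadfc63710724c5c18ad67",
 "table2_correlations.tsv": "e336a9389b98525d8c6d912827726d3dfca1ec725dc892e33e83bbef27e755b7",
 "table3_h2_excluding.tsv": "6d3e9e12743f3ecbb496bc41a2d35ea1473b48ea3f307babdfc91b00c195719e",
 "table3_summary.tsv": "791d00adc750deba96c3b1468f60ac6e3578397d5c238ba8cec89f7c620c4f31",
 "table3_unique.tsv": "1c0bae70098ca57c1f6167fbbf4200203cfc886aefe35204f87083718bb58073"
}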