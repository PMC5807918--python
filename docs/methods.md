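# Methods

## Model

For one quantitative trait measured on n inbred lines,

```
y = Xβ + Σᵢ gᵢ + ε,   gᵢ ~ N(0, Aᵢ σ²gᵢ),   ε ~ N(0, I σ²e),
```

with one random effect per chromosome (i = 1..21). Aᵢ is the genomic
relatedness matrix (GRM) built from the SNPs mapped to chromosome i,
and X holds an intercept plus, optionally, the leading principal
components of the all-SNP GRM. The phenotypic covariance is
V = Σᵢ Aᵢ σ²gᵢ + I σ²e.

### GRM estimator

The default is the GCTA-style estimator: off-diagonals average
(xⱼ−2p)(xₖ−2p)/(2p(1−p)) over markers; the diagonal uses the distinct
finite-sample form 1 + (x² − (1+2p)x + 2p²)/(2p(1−p)), which estimates
1 + F for individual-level inbreeding F. Allele frequencies come from
the analysed sample and are recomputed after any marker thinning.
Missing genotypes are mean-imputed to 2p, which zeroes their centred
contribution while keeping the marker count fixed. A
`yang_diagonal=False` switch restores the plain cross-product diagonal
for sensitivity checks.

Two consequences of the distinct diagonal matter downstream:

* **GRMs need not be positive semi-definite.** The REML layer therefore
  never assumes PSD component matrices; it only requires the total V to
  be positive definite.
* **Inbred panels have mean diagonal ≈ 2**, so one unit of σ²gᵢ carries
  A̅ᵢᵢ units of phenotypic variance. Heritability and percentage shares
  are computed from σ²gᵢ·mean(diag Aᵢ); with outbred data
  (diagonal ≈ 1) this reduces to the familiar Σσ²g/(Σσ²g+σ²e). Ignoring
  the scale on a fully inbred panel under-reports h² by roughly a
  factor (1+F)/… — in simulations at h² = 0.5 the unscaled form
  returned ≈ 0.33, the scaled form 0.5.

### AI-REML

`fit_greml` maximises the restricted likelihood
−½[(n−p)log 2π + log|V| + log|X'V⁻¹X| + y'Py] by average-information
(Newton-type) iterations:

* start at σ²gᵢ = Var(y)/(2k), σ²e = Var(y)/2; one EM-REML step first;
* AI steps with deep step-halving (up to 2⁻³⁹) whenever a proposal makes
  V non-positive-definite or lowers the likelihood; an EM step is the
  final fallback;
* active-set handling: a parameter pinned at its lower bound whose
  gradient points outward is excluded from the AI solve, so the
  remaining parameters take full Newton steps along the boundary;
* V proposals whose Cholesky-based reciprocal condition falls below
  1e−10 are treated as infeasible. With indefinite GRMs the
  unconstrained likelihood can otherwise climb indefinitely toward a
  singular V;
* convergence requires a full (or once-halved) step whose likelihood
  and relative parameter changes fall below `tol` (default 1e−6,
  `max_iter` 200). A point where no feasible uphill step remains is
  reported as the constrained optimum with an explanatory warning;
  `converged=False` is reserved for iteration-budget exhaustion.

Two constraint modes exist. `unconstrained` (default) allows negative
σ²gᵢ as long as V stays positive definite; zero-truncation is applied
only when percentages are formed, mirroring how partition tables are
conventionally reported. `constrained-nonnegative` keeps all components
at or above a small positive floor. With many weakly identified
components at small n the unconstrained likelihood rewards spreading
variance across components, so truncated shares from unconstrained fits
are noticeably flatter than constrained ones; single-chromosome
architectures are recovered much more sharply in constrained mode
(see the recovery tests). Both modes are exposed; reporting-stage
truncation is identical for both.

Standard errors come from the inverse AI matrix at the final
parameters; an ill-conditioned AI matrix (mutually near-collinear GRMs,
or A = I) triggers a pseudo-inverse and a warning rather than a hard
failure. The per-iteration restricted log-likelihood is recorded in
`loglik_trace`.

### Reporting rules

* h² = Σᵢ max(sᵢ,0) / (Σᵢ max(sᵢ,0) + σ²e) with sᵢ = σ²gᵢ·mean(diag Aᵢ).
* Percentage shares: negative components recorded as zero, the rest
  rescaled to sum to 100. Groups and subgenomes are exact sums of their
  member chromosomes before any rounding; display rounding is one
  decimal, half away from zero.
* Conditional effects: h²(full) − h²(one GRM excluded), stored
  unrounded; per-subgenome conditional contributions are
  zero-truncated sums of the per-chromosome unique contributions,
  normalised to 100 (one of several defensible conventions; the choice
  is recorded here because no canonical one exists).

## Statistics layer

* Size-vs-variance correlations are plain Pearson coefficients with
  two-sided t-based p-values; scopes are per-trait (21 chromosomes, 7
  chromosomes of one subgenome, or 7 group roll-ups) and pooled
  trait×unit cells across traits. No multiple-testing correction is
  applied anywhere.
* The attenuation adjustment is r_att = r·√reliability with the p-value
  recomputed at the same n. Note the direction: this *shrinks* the
  observed correlation for the noisiness of the underlying variance
  estimates — the opposite of the classical disattenuation correction —
  so only correlations that survive the acknowledged estimation noise
  stay significant. The reliability input is the squared mean jackknife
  correlation (below).
* The subgenome departure test is Σ(obs−exp)²/exp on the percentage
  scale with df = 2. Percentages are not counts, so the statistic is a
  calibrated departure index rather than a textbook Pearson test; the
  statistic is always reported alongside the p-value.
* ANCOVA models (effect ~ subgenome + size, with or without
  interaction) are ordinary least squares with type-II sums of squares
  via statsmodels. With the subgenome-size covariate the design is rank
  deficient (the covariate is constant within each factor level); the
  pinv-based fit reports both terms rather than silently dropping one.
* Medians of even-length sets are the mean of the central pair.

## Resampling

* **Null phenotypes**: y ~ N(0,1) i.i.d. per replicate, full multi-GRM
  refit, summarised by mean h² and a 2.5–97.5 percentile interval.
  This measures the small-sample upward bias floor of h² — on unrelated
  panels it shrinks toward 0 as n grows — and the null spread of
  subgenome contributions.
* **Jackknife reliability**: each replicate removes one uniformly drawn
  individual (with replacement across replicates), refits, and
  correlates the reduced-model per-component variance vector with the
  full-model one; reliability = (mean r)². The multi-trait variant
  pools all traits' components into a single vector per replicate.
* **SNP thinning**: schemes `all-20` (omit 20% of all markers), `AB-20`
  (20% of A/B markers) and `D-50` (50% of D markers); the thinned panel
  is re-filtered, GRMs rebuilt and the model refitted; chromosomes left
  without markers are dropped from the thinned run with a warning and
  zero-filled in the padded partition so roll-ups stay comparable.

All procedures are reproducible bit-for-bit given (inputs, seed,
n_reps); replicate seeds are spawned from the master seed with
`numpy.random.default_rng`.

## Synthetic populations

The generator emulates a primary-synthetic wheat panel:

* Founder haplotypes per chromosome are drawn by a copy-the-previous-
  allele Markov chain: marker j copies marker j−1 with probability
  1 − 1/L, else draws fresh at its own frequency (uniform on
  0.5 ± spread, default spread 0.4). L is the mean LD-block length in
  markers — defaults 3 for A and B, 15 for D, reflecting the much
  longer LD blocks wild *Ae. tauschii* accessions contribute.
* Each line takes its A and B chromosomes from one durum parent
  (default pool 30) and its D chromosomes from one tauschii accession
  (default pool 60), then is fully homozygous (`inbreeding=1`; a
  partial-inbreeding knob leaves a fraction of line×chromosome pairs
  heterozygous). Marker counts are apportioned to chromosomes by
  physical size (default total ≈ 6,176); the default population has
  173 lines.
* Markers that would fail the quality filters (missing < 20%,
  MAF > 5%, strict inequalities) are redrawn, so generated panels
  always pass `filter_markers` unchanged.

Because every line inherits whole parental chromosomes, parent identity
is a latent factor shared by all chromosomes of a pool: A/B GRMs
correlate strongly with each other (durum parent), D GRMs with each
other (tauschii parent), and the two clusters are nearly uncorrelated —
the clustered-GRM structure expected for this germplasm. The same
coupling means per-chromosome variance attribution on such a panel is
genuinely ambiguous (shared variance has no unique owner), so
**estimator-calibration experiments use `independent_chromosomes=True`**,
which redraws the founder per chromosome and makes chromosomes
unlinked. Recovery tests additionally use equal founder pools and a
uniform block length so no subgenome is informationally disadvantaged;
n = 400 lines identifies 21 components with usable precision, which the
default 173 does not (mirrored by the low jackknife reliability a
173-line panel produces).

Traits: `n_causal_per_chromosome` markers per chromosome with positive
budget receive N(0,1) effects; each chromosome's genetic value is
rescaled so its realized variance equals its budget exactly, and
Gaussian noise is scaled so realized h² equals `total_h2` (default 0.5)
exactly. Ground truth records realized per-chromosome variances, total
genetic and error variance and the causal marker ids.

What the generator does **not** emulate: recombination within
chromosomes (LD comes from founder blocks only), selection, genotyping
error beyond random missingness, the specific phenotype distributions
of real stress traits, or marker ascertainment. Passing tests therefore
demonstrate the correctness and calibration of the estimator machinery
under a known truth, not field performance on any real panel.

## Problem sizes used in tests

The shipped suite runs a down-scaled SHW panel (100 lines × 315
markers) for pipeline and resampling tests, 2-component toys (n = 40)
for the brute-force grid-search comparisons, and the n = 400
calibration population (30 replicates) for parameter recovery; the
whole suite completes in about two minutes on one CPU and
`scripts/acceptance.py` in about one.

## Known limitations

* Exact replication of the published real-data fits is impossible here
  (the genotype/phenotype data are external); the printed tables are
  packaged as fixtures and every statistic derivable from them is
  recomputed, but the fits behind them are not re-estimated.
* The printed group-level correlation column cannot be reconstructed
  exactly from the rounded partition table (deviations up to ~0.03);
  it was evidently computed on unrounded internal estimates.
* Unconstrained multi-GRM REML on small related panels is
  intrinsically fragile: the likelihood may prefer the
  positive-definiteness boundary, estimates carry large standard
  errors, and truncated shares flatten. The package surfaces this
  through warnings, the jackknife reliability and the null-phenotype
  calibration rather than hiding it.
* One phenotype at a time (no multi-trait REML), additive effects only,
  no dominance/epistasis/GxE, no LD-weighted or MAF-stratified GRMs.
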