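"""Synthetic allohexaploid wheat populations with known ground truth.

The generator emulates a panel of synthetic hexaploid wheat (SHW) lines:
each line derives its A and B subgenomes from one inbred durum parent
(AABB) and its D subgenome from one *Aegilops tauschii* accession (DD),
followed by chromosome doubling, so lines are fully homozygous by
default. Founder haplotypes are drawn block-wise along each chromosome
(a copy-the-previous-allele Markov chain), with much longer blocks on
the D subgenome — the wild accessions contribute long shared segments —
so linkage disequilibrium decays more slowly on D than on A/B, as in the
real germplasm.

Additive traits are simulated on top of a panel with a configurable
per-chromosome variance budget and total heritability (default 0.5),
with the realized per-chromosome variances recorded as ground truth.

The module also packages the printed partition, correlation and
conditional-effect tables as validated fixtures for the downstream
statistics.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core_io import (CHROMOSOMES, HOMOEO_GROUPS, SUBGENOMES, GenomeSizes,
                      GenotypePanel, MarkerMap, PhenotypeTable)
from .partition import ConditionalTable, PartitionTable

_DATA_DIR = Path(__file__).parent / "data"

#: total marker count the default plan aims at
_DEFAULT_TOTAL_MARKERS = 6176


def _default_marker_counts(total: int = _DEFAULT_TOTAL_MARKERS) -> dict[str, int]:
    """Apportion the marker total across chromosomes by physical size."""
    sizes = GenomeSizes.default().as_series()
    raw = sizes / sizes.sum() * total
    counts = raw.round().astype(int)
    return {c: int(counts[c]) for c in CHROMOSOMES}


@dataclass
class PopulationPlan:
    """Design of the synthetic SHW population.

    ``ld_block_length`` is the mean number of consecutive markers sharing a
    founder haplotype segment, per subgenome; the default makes D blocks
    five times longer than A/B blocks. ``founder_allele_freq_spread`` s
    sets founder allele frequencies to U(0.5-s, 0.5+s). ``inbreeding`` is
    the probability that a line is fully homozygous on a given chromosome
    (1 = classic doubled synthetic lines).
    """

    n_durum_parents: int = 30
    n_tauschii_parents: int = 60
    n_lines: int = 173
    markers_per_chromosome: dict[str, int] = field(
        default_factory=_default_marker_counts)
    ld_block_length: dict[str, float] = field(
        default_factory=lambda: {"A": 3.0, "B": 3.0, "D": 15.0})
    founder_allele_freq_spread: float = 0.4
    inbreeding: float = 1.0
    missing_rate: float = 0.0
    max_missing: float = 0.20
    min_maf: float = 0.05
    #: draw the founder independently per chromosome instead of one durum +
    #: one tauschii parent per line; removes the parent-identity factor that
    #: correlates chromosomes, giving genuinely unlinked chromosomes (used
    #: for estimator-calibration experiments rather than SHW realism)
    independent_chromosomes: bool = False

    def __post_init__(self) -> None:
        for name in ("n_durum_parents", "n_tauschii_parents", "n_lines"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if set(self.markers_per_chromosome) != set(CHROMOSOMES):
            raise ValueError("markers_per_chromosome must cover all 21 chromosomes")
        if not 0.0 <= self.inbreeding <= 1.0:
            raise ValueError("inbreeding must lie in [0, 1]")
        if not 0.0 < self.founder_allele_freq_spread < 0.5:
            raise ValueError("founder_allele_freq_spread must lie in (0, 0.5)")
        if not 0.0 <= self.missing_rate < self.max_missing:
            raise ValueError("missing_rate must lie in [0, max_missing)")


@dataclass
class TraitPlan:
    """Design of one simulated additive trait.

    ``chromosome_budget`` gives each chromosome's share of the additive
    variance (sums to 1); the default apportions by physical size. The
    realized per-chromosome genetic variances are rescaled to match the
    budget exactly on the realized-genotype scale, then Gaussian error is
    added so that the realized h2 equals ``total_h2``.
    """

    total_h2: float = 0.5
    chromosome_budget: dict[str, float] | None = None
    n_causal_per_chromosome: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.total_h2 < 1.0:
            raise ValueError("total_h2 must lie in [0, 1)")
        if self.chromosome_budget is None:
            sizes = GenomeSizes.default().as_series()
            self.chromosome_budget = dict(sizes / sizes.sum())
        b = np.array([self.chromosome_budget.get(c, 0.0) for c in CHROMOSOMES])
        if (b < 0).any():
            raise ValueError("chromosome budgets must be nonnegative")
        total = b.sum()
        if total > 0 and not np.isclose(total, 1.0, atol=1e-6):
            raise ValueError(f"chromosome budget sums to {total:.4f}, not 1")
        self.chromosome_budget = dict(zip(CHROMOSOMES, b))

    def budget_array(self) -> np.ndarray:
        return np.array([self.chromosome_budget[c] for c in CHROMOSOMES])


def _founder_haplotypes(n_founders: int, m: int, block_len: float, spread: float,
                        rng: np.random.Generator) -> np.ndarray:
    """Founder haplotypes with block-wise LD along the chromosome.

    Marker j copies marker j-1's allele with probability 1 - 1/block_len
    (per founder), otherwise draws fresh from Bernoulli(p_j); runs of
    copied alleles give LD blocks of mean length ``block_len`` markers.
    """
    p = rng.uniform(0.5 - spread, 0.5 + spread, size=m)
    hap = np.empty((n_founders, m), dtype=np.int8)
    hap[:, 0] = rng.random(n_founders) < p[0]
    copy_prob = 1.0 - 1.0 / max(block_len, 1.0)
    for j in range(1, m):
        copy = rng.random(n_founders) < copy_prob
        fresh = rng.random(n_founders) < p[j]
        hap[:, j] = np.where(copy, hap[:, j - 1], fresh)
    return hap


def simulate_genotypes(plan: PopulationPlan | None = None,
                       seed: int = 0,
                       max_retries: int = 30) -> GenotypePanel:
    """Generate an SHW-like genotype panel that passes the quality filters.

    Markers whose realized minor allele frequency or missing fraction would
    fail the filters are redrawn (breaking their local LD) up to
    ``max_retries`` times; a panel that still fails raises after a warning.
    """
    plan = plan or PopulationPlan()
    rng = np.random.default_rng(seed)
    n = plan.n_lines

    durum_of = rng.integers(0, plan.n_durum_parents, size=n)
    tauschii_of = rng.integers(0, plan.n_tauschii_parents, size=n)

    blocks, ids = [], []
    chrom_col = []
    for c in CHROMOSOMES:
        m_c = plan.markers_per_chromosome[c]
        sub = c[1]
        n_f = plan.n_durum_parents if sub in ("A", "B") else plan.n_tauschii_parents
        if plan.independent_chromosomes:
            parent_of = rng.integers(0, n_f, size=n)
        else:
            parent_of = durum_of if sub in ("A", "B") else tauschii_of
        hap = _founder_haplotypes(
            n_f, m_c, plan.ld_block_length[sub],
            plan.founder_allele_freq_spread, rng,
        )
        hap2 = hap  # second haplotype source for non-inbred line-chromosomes
        homozygous = rng.random(n) < plan.inbreeding
        other = rng.integers(0, n_f, size=n)
        f2 = np.where(homozygous, parent_of, other)
        geno = (hap[parent_of] + hap2[f2]).astype(float)

        if plan.missing_rate > 0.0:
            mask = rng.random((n, m_c)) < plan.missing_rate
            geno[mask] = np.nan

        geno = _enforce_filters(geno, plan, rng, max_retries, c)
        blocks.append(geno)
        ids.extend(f"{c}_m{j}" for j in range(m_c))
        chrom_col.extend([c] * m_c)

    genotypes = np.concatenate(blocks, axis=1)
    mmap = MarkerMap(pd.DataFrame({"marker_id": ids, "chromosome": chrom_col}))
    line_ids = [f"SHW{i + 1:03d}" for i in range(n)]
    return GenotypePanel(line_ids, genotypes, mmap)


def _enforce_filters(geno: np.ndarray, plan: PopulationPlan,
                     rng: np.random.Generator, max_retries: int,
                     chromosome: str) -> np.ndarray:
    """Redraw marker columns until MAF/missingness constraints hold."""
    n, m = geno.shape
    for attempt in range(max_retries):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            freq = np.nanmean(geno, axis=0) / 2.0
        maf = np.where(np.isnan(freq), 0.0, np.minimum(freq, 1.0 - freq))
        miss = np.isnan(geno).mean(axis=0)
        bad = (maf <= plan.min_maf) | (miss >= plan.max_missing)
        if not bad.any():
            return geno
        for j in np.flatnonzero(bad):
            # fresh biallelic column near balanced frequency, no block LD
            p = rng.uniform(0.25, 0.75)
            col = 2.0 * (rng.random(n) < p)
            if plan.inbreeding < 1.0:
                het = rng.random(n) < (1.0 - plan.inbreeding) / 2.0
                col[het] = 1.0
            if plan.missing_rate > 0.0:
                col[rng.random(n) < plan.missing_rate] = np.nan
            geno[:, j] = col
    warnings.warn(
        f"{chromosome}: markers still failing filters after {max_retries} redraws",
        stacklevel=2,
    )
    raise RuntimeError(f"could not satisfy MAF/missingness on {chromosome}")


@dataclass
class TraitGroundTruth:
    """Realized (not just planned) variance decomposition of one trait."""

    per_chromosome_variance: pd.Series   # realized var of each g_c
    genetic_variance: float              # realized var of sum_c g_c
    error_variance: float
    realized_h2: float
    causal_markers: dict[str, list[str]]

    def chromosome_pct(self) -> pd.Series:
        v = self.per_chromosome_variance
        return 100.0 * v / v.sum()


def simulate_trait(
    panel: GenotypePanel, trait_plan: TraitPlan | None = None,
    trait_name: str = "trait",
) -> tuple[PhenotypeTable, TraitGroundTruth]:
    """Simulate one additive trait on a panel.

    Per chromosome with positive budget, ``n_causal_per_chromosome``
    markers get N(0,1) additive effects; the chromosome's genetic value is
    rescaled so its realized variance equals budget_c (total genetic
    variance 1 before noise), and i.i.d. Gaussian error is added to make
    the realized h2 equal ``total_h2`` exactly.
    """
    trait_plan = trait_plan or TraitPlan()
    rng = np.random.default_rng(trait_plan.seed)
    budget = trait_plan.budget_array()
    n = panel.n_individuals
    chrom = panel.map.chromosomes
    g_total = np.zeros(n)
    per_chrom = {}
    causal: dict[str, list[str]] = {}

    pure_noise = budget.sum() == 0.0
    if pure_noise:
        warnings.warn("zero genetic variance requested; trait is pure noise",
                      stacklevel=2)

    for c, b in zip(CHROMOSOMES, budget):
        per_chrom[c] = 0.0
        if b <= 0.0:
            continue
        idx = np.flatnonzero(chrom == c)
        if idx.size == 0:
            raise ValueError(f"budget on chromosome {c} but no markers there")
        k = min(trait_plan.n_causal_per_chromosome, idx.size)
        pick = rng.choice(idx, size=k, replace=False)
        causal[c] = list(panel.map.marker_ids[pick])
        x = panel.genotypes[:, pick]
        col_mean = np.nanmean(x, axis=0)
        x = np.where(np.isnan(x), col_mean, x) - col_mean
        beta = rng.standard_normal(k)
        g = x @ beta
        sd = g.std(ddof=1)
        if sd <= 0.0:
            raise ValueError(f"no genetic variance realizable on {c}")
        g = g / sd * np.sqrt(b)
        per_chrom[c] = float(np.var(g, ddof=1))
        g_total += g

    h2 = trait_plan.total_h2
    if pure_noise or h2 == 0.0:
        e = rng.standard_normal(n)
        y = g_total * 0.0 + e
        gv, ev = 0.0, float(np.var(e, ddof=1))
    else:
        gv = float(np.var(g_total, ddof=1))
        e = rng.standard_normal(n)
        e = (e - e.mean()) / e.std(ddof=1)
        ev = gv * (1.0 - h2) / h2
        y = g_total + e * np.sqrt(ev)

    values = pd.DataFrame({trait_name: y}, index=panel.individual_ids)
    truth = TraitGroundTruth(
        per_chromosome_variance=pd.Series(per_chrom),
        genetic_variance=gv,
        error_variance=ev,
        realized_h2=gv / (gv + ev) if gv + ev > 0 else 0.0,
        causal_markers=causal,
    )
    return PhenotypeTable(values), truth


# ---------------------------------------------------------------------------
# Packaged printed-table fixtures
# ---------------------------------------------------------------------------

class FixtureError(RuntimeError):
    """Packaged fixture tables are corrupt or inconsistent."""


@dataclass
class PublishedTables:
    """The printed analysis tables as typed, validated objects.

    ``partition`` holds the per-chromosome percentage shares with roll-ups
    recomputed from the chromosome rows; ``partition_printed`` keeps the
    published (display-rounded) group/subgenome rows and chi-square
    p-values for regression checks. ``correlations`` is the per-trait
    size-vs-variance correlation table; ``conditional`` the
    leave-one-chromosome-out heritabilities.
    """

    partition: PartitionTable
    partition_printed: pd.DataFrame
    correlations: pd.DataFrame
    conditional: ConditionalTable
    conditional_printed: pd.DataFrame
    sizes: GenomeSizes


def _checksums() -> dict[str, str]:
    with open(_DATA_DIR / "checksums.json") as fh:
        return json.load(fh)


def load_published_tables() -> PublishedTables:
    """Load and validate the packaged printed tables."""
    sums = _checksums()
    for name, expect in sums.items():
        digest = hashlib.sha256((_DATA_DIR / name).read_bytes()).hexdigest()
        if digest != expect:
            raise FixtureError(f"checksum mismatch for packaged fixture {name}")

    chrom = pd.read_csv(_DATA_DIR / "table1_chromosomes.tsv", sep="\t",
                        index_col=0)
    summary = pd.read_csv(_DATA_DIR / "table1_summary.tsv", sep="\t",
                          index_col=0, na_values=["NA"])
    corr = pd.read_csv(_DATA_DIR / "table2_correlations.tsv", sep="\t",
                       index_col=0)
    h2ex = pd.read_csv(_DATA_DIR / "table3_h2_excluding.tsv", sep="\t",
                       index_col=0)
    uniq = pd.read_csv(_DATA_DIR / "table3_unique.tsv", sep="\t", index_col=0)
    t3sum = pd.read_csv(_DATA_DIR / "table3_summary.tsv", sep="\t",
                        index_col=0, na_values=["NA"])
    sizes = GenomeSizes.from_tsv(_DATA_DIR / "genome_sizes.tsv")

    traits = [c for c in chrom.columns if c != "size_mb"]
    pct = chrom[traits]
    sums_ok = pct.sum()
    if not np.allclose(sums_ok, 100.0, atol=0.5):
        raise FixtureError(
            f"partition columns do not sum to ~100: {sums_ok.to_dict()}")
    he = summary.loc["He", traits].astype(float) / 100.0
    partition = PartitionTable(pct, he)

    # printed roll-ups agree with recomputed sums to display rounding
    for g in HOMOEO_GROUPS:
        printed = summary.loc[f"Group{g}", traits].astype(float)
        if not np.allclose(printed, partition.group_pct.loc[f"Group{g}"],
                           atol=0.15):
            raise FixtureError(f"printed Group{g} row disagrees with members")
    for s in SUBGENOMES:
        printed = summary.loc[s, traits].astype(float)
        if not np.allclose(printed, partition.subgenome_pct.loc[s], atol=0.35):
            raise FixtureError(f"printed subgenome {s} row disagrees with members")

    # conditional: parenthesized value equals the He - h2_excluding subtraction
    he3 = t3sum.loc["He", traits].astype(float)
    resid = (he3 - h2ex[traits]) - uniq[traits]
    if np.abs(resid.to_numpy()).max() > 0.002:
        raise FixtureError("conditional unique contributions do not match "
                           "the printed subtraction")
    conditional = ConditionalTable(he3, h2ex[traits], uniq[traits])

    if abs(sizes.total() - float(summary.at["He", "size_mb"])) > 1.0:
        raise FixtureError("genome sizes do not sum to the printed total")

    return PublishedTables(partition, summary, corr, conditional, t3sum, sizes)
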