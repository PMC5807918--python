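"""Partition products: per-chromosome variance shares with group and
subgenome roll-ups, conditional (leave-one-chromosome-out) effects,
expected size-based contributions and the chi-square departure test,
plus the within-group homoeolog dominance share.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import CHROMOSOMES, HOMOEO_GROUPS, SUBGENOMES, GenomeSizes
from .greml import GremlFit, MixedModelSpec, fit_greml, heritability, proportion_table

logger = logging.getLogger(__name__)


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round half away from zero, as in the display tables (2.25 -> 2.3)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class PartitionTable:
    """Zero-truncated percentage shares per chromosome with roll-ups.

    ``chromosome_pct`` rows follow the canonical 1A..7D order; columns are
    traits. Each column sums to 100 (up to rounding if the table was built
    from rounded display values). Roll-ups are exact sums of member
    chromosomes, computed before any rounding.
    """

    chromosome_pct: pd.DataFrame   # 21 x t
    total_h2: pd.Series            # per trait, on the 0-1 scale
    group_pct: pd.DataFrame = field(init=False)
    subgenome_pct: pd.DataFrame = field(init=False)

    def __post_init__(self) -> None:
        cp = self.chromosome_pct
        missing = set(CHROMOSOMES) - set(cp.index)
        if missing:
            raise ValueError(f"partition table missing chromosomes: {sorted(missing)}")
        cp = cp.loc[list(CHROMOSOMES)].astype(float)
        if (cp.to_numpy() < -1e-9).any():
            raise ValueError("partition percentages must be zero-truncated")
        self.chromosome_pct = cp
        self.group_pct = pd.DataFrame(
            {g: cp.loc[[f"{g}{s}" for s in SUBGENOMES]].sum() for g in HOMOEO_GROUPS}
        ).T
        self.group_pct.index = [f"Group{g}" for g in HOMOEO_GROUPS]
        self.subgenome_pct = pd.DataFrame(
            {s: cp.loc[[f"{g}{s}" for g in HOMOEO_GROUPS]].sum() for s in SUBGENOMES}
        ).T

    @property
    def traits(self) -> list[str]:
        return list(self.chromosome_pct.columns)

    def display(self, ndigits: int = 1) -> pd.DataFrame:
        """Full stacked table (chromosomes, groups, subgenomes) rounded for display."""
        stacked = pd.concat([self.chromosome_pct, self.group_pct, self.subgenome_pct])
        return stacked.map(lambda v: round_half_up(v, ndigits))

    def to_tsv(self, path: str | Path, ndigits: int = 1) -> None:
        out = self.display(ndigits)
        out.index.name = "unit"
        out.to_csv(path, sep="\t")


def partition_from_fits(fits: dict[str, GremlFit]) -> PartitionTable:
    """Assemble a :class:`PartitionTable` from per-trait 21-component fits.

    Component labels of every fit must be the 21 chromosome names.
    """
    cols, h2 = {}, {}
    for trait, fit in fits.items():
        if fit.component_labels != list(CHROMOSOMES):
            raise ValueError(
                f"fit for {trait!r} does not carry the 21 chromosome components"
            )
        cols[trait] = pd.Series(proportion_table(fit), index=list(CHROMOSOMES))
        h2[trait] = heritability(fit)
    return PartitionTable(pd.DataFrame(cols), pd.Series(h2))


def aggregate_partition(
    chromosome_pct: pd.DataFrame, total_h2: pd.Series | None = None
) -> PartitionTable:
    """Roll chromosome percentages up to groups and subgenomes."""
    if total_h2 is None:
        total_h2 = pd.Series(np.nan, index=chromosome_pct.columns)
    return PartitionTable(chromosome_pct, total_h2)


# ---------------------------------------------------------------------------
# Conditional (leave-one-GRM-out) analysis
# ---------------------------------------------------------------------------

@dataclass
class ConditionalTable:
    """Heritability with one chromosome's GRM excluded, per trait.

    ``unique_contribution = h2_full - h2_excluding`` estimates the share of
    a chromosome's additive variance not tagged by markers on the other 20
    chromosomes; it may be negative through estimation noise and is stored
    unrounded.
    """

    h2_full: pd.Series                 # per trait
    h2_excluding: pd.DataFrame         # 21 x t
    unique_contribution: pd.DataFrame  # 21 x t
    non_converged: list[tuple[str, str]] = field(default_factory=list)

    def subgenome_contributions(self) -> pd.DataFrame:
        """Per-subgenome share of summed unique contributions, normalised to 100.

        Negative per-chromosome uniques are truncated to zero before
        summing, mirroring the zero-truncation used for the main partition.
        """
        u = self.unique_contribution.clip(lower=0.0)
        sums = pd.DataFrame(
            {s: u.loc[[f"{g}{s}" for g in HOMOEO_GROUPS]].sum() for s in SUBGENOMES}
        ).T
        return 100.0 * sums / sums.sum(axis=0)

    def to_tsv(self, path: str | Path) -> None:
        """Table-3-style layout: ``h2_excluding (unique)`` strings per cell."""
        out = pd.DataFrame(
            {
                t: [
                    f"{self.h2_excluding.at[c, t]:.3f} "
                    f"({self.unique_contribution.at[c, t]:.3f})"
                    for c in CHROMOSOMES
                ]
                for t in self.h2_excluding.columns
            },
            index=list(CHROMOSOMES),
        )
        out.index.name = "chromosome"
        out.to_csv(path, sep="\t")


def conditional_analysis(
    specs: dict[str, MixedModelSpec],
    full_fits: dict[str, GremlFit] | None = None,
    tol: float = 1e-6,
    max_iter: int = 200,
) -> ConditionalTable:
    """Refit each trait 21 times, excluding one chromosome's GRM per fit.

    ``specs`` maps trait name to the full 21-component model spec. Full-model
    fits are reused when given, otherwise fitted here. Non-convergent
    sub-fits are recorded per (trait, chromosome) cell, not fatal.
    """
    full_fits = dict(full_fits or {})
    h2_full, h2_ex, uniq = {}, {}, {}
    non_converged: list[tuple[str, str]] = []
    for trait, spec in specs.items():
        labels = [g.source_chromosome for g in spec.components]
        if labels != list(CHROMOSOMES):
            raise ValueError(f"spec for {trait!r} must carry all 21 chromosome GRMs")
        if trait not in full_fits:
            full_fits[trait] = fit_greml(spec, tol=tol, max_iter=max_iter)
        h2_full[trait] = heritability(full_fits[trait])
        col_ex, col_u = {}, {}
        for drop in CHROMOSOMES:
            comps = [g for g in spec.components if g.source_chromosome != drop]
            sub = MixedModelSpec(
                spec.phenotype, comps, spec.fixed_design, spec.constraint_mode
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = fit_greml(sub, tol=tol, max_iter=max_iter)
            if not fit.converged:
                non_converged.append((trait, drop))
                logger.warning("conditional fit %s without %s did not converge",
                               trait, drop)
            col_ex[drop] = heritability(fit)
            col_u[drop] = h2_full[trait] - col_ex[drop]
        h2_ex[trait] = pd.Series(col_ex)
        uniq[trait] = pd.Series(col_u)
    return ConditionalTable(
        pd.Series(h2_full), pd.DataFrame(h2_ex), pd.DataFrame(uniq), non_converged
    )


# ---------------------------------------------------------------------------
# Size-based expectation and departure test
# ---------------------------------------------------------------------------

def expected_contribution(sizes: GenomeSizes) -> pd.Series:
    """Expected percentage contribution of each subgenome: its share of
    the physical genome, 100 * size_s / total."""
    total = sizes.total()
    return pd.Series(
        {s: 100.0 * sizes.subgenome_size(s) / total for s in SUBGENOMES}
    )


def chi_square_contribution_test(
    observed_pct: pd.Series | np.ndarray, expected_pct: pd.Series | np.ndarray
) -> tuple[float, float]:
    """Pearson chi-square of observed vs expected subgenome percentages.

    Computed on the percentage scale with df = 2: X2 = sum (obs-exp)^2/exp.
    The percentage scale has no count interpretation, so the statistic is
    reported alongside the p-value and should be read as a calibrated
    departure index rather than a textbook count test.
    """
    obs = np.asarray(observed_pct, dtype=float)
    exp = np.asarray(expected_pct, dtype=float)
    if obs.shape != (3,) or exp.shape != (3,):
        raise ValueError("observed and expected must each have 3 subgenome entries")
    if not np.isclose(exp.sum(), 100.0, atol=0.5):
        raise ValueError(f"expected percentages sum to {exp.sum():.3f}, not 100")
    if (exp <= 0).any():
        raise ValueError("expected percentages must be positive")
    stat = float(((obs - exp) ** 2 / exp).sum())
    p = float(stats.chi2.sf(stat, df=2))
    return stat, p


def max_homoeolog_share(partition: PartitionTable) -> tuple[float, pd.DataFrame]:
    """Within-group dominance: the largest homoeolog share of each group total.

    For every trait x group cell with a nonzero group total, the share is
    max(three homoeolog percentages) / group total. Returns the overall
    average share (percent) and the per-cell table (NaN where the group
    contributed nothing; such cells are excluded from the average and
    counted in the log).
    """
    cp = partition.chromosome_pct
    shares = {}
    for trait in partition.traits:
        col = {}
        for g in HOMOEO_GROUPS:
            vals = cp.loc[[f"{g}{s}" for s in SUBGENOMES], trait]
            total = vals.sum()
            col[f"Group{g}"] = vals.max() / total if total > 0 else np.nan
        shares[trait] = pd.Series(col)
    table = pd.DataFrame(shares)
    n_zero = int(table.isna().sum().sum())
    if n_zero:
        logger.info("max_homoeolog_share: excluded %d zero-total group cells", n_zero)
    return float(100.0 * np.nanmean(table.to_numpy())), table
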