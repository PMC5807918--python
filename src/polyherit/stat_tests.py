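"""Correlation and regression layer: size-vs-variance Pearson
correlations at several scopes, outlier handling, attenuation adjustment
of correlations for estimation unreliability, medians across traits, and
the ANCOVA comparing subgenomes with a size covariate.

Attenuation convention: the adjusted coefficient is
``r_att = r * sqrt(reliability)``, where the reliability is the squared
mean jackknife correlation of the variance estimates (see
:mod:`polyherit.resampling`). This deliberately *shrinks* the observed
correlation — the opposite direction to classical disattenuation — so a
correlation must survive the acknowledged noise in the variance
estimates to remain significant. The p-value is recomputed for the
adjusted coefficient at the same sample size.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

from .core_io import HOMOEO_GROUPS, SUBGENOMES, GenomeSizes
from .partition import PartitionTable

SCOPES = ("all-21", "within-subgenome", "groups", "combined")


@dataclass
class CorrelationResult:
    r: float
    p_value: float
    n: int
    scope: str = ""
    label: str = ""
    r_attenuated: float | None = None
    p_attenuated: float | None = None
    outliers_removed: list[str] = field(default_factory=list)
    pairs: pd.DataFrame | None = None   # columns: label, size, value

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValueError("a correlation needs at least 3 pairs")
        if not -1.0 - 1e-12 <= self.r <= 1.0 + 1e-12:
            raise ValueError(f"|r| > 1: {self.r}")


def _pearson(pairs: pd.DataFrame, scope: str, label: str,
             outliers: list[str] | None = None) -> CorrelationResult:
    if len(pairs) < 3:
        raise ValueError(f"only {len(pairs)} pairs in scope {scope!r}; need >= 3")
    r, p = stats.pearsonr(pairs["size"], pairs["value"])
    return CorrelationResult(float(r), float(p), len(pairs), scope, label,
                             outliers_removed=list(outliers or []),
                             pairs=pairs.reset_index(drop=True))


def size_variance_correlation(
    partition: PartitionTable,
    sizes: GenomeSizes,
    scope: str = "all-21",
    trait: str | None = None,
    subgenome: str | None = None,
) -> CorrelationResult:
    """Pearson correlation between physical size (Mb) and percentage
    additive variance.

    Scopes:

    * ``all-21`` — one trait, its 21 chromosome shares vs chromosome sizes;
    * ``within-subgenome`` — one trait, the 7 chromosomes of ``subgenome``;
    * ``groups`` — one trait, the 7 group roll-ups vs cumulative group sizes;
    * ``combined`` — pools trait x unit cells over *all* traits; the unit is
      chromosomes (optionally restricted to one subgenome) or, with
      ``subgenome='groups'``, the homoeologous groups (7 x t pairs).
    """
    if scope not in SCOPES:
        raise ValueError(f"unknown scope {scope!r}; choose from {SCOPES}")
    chrom_sizes = sizes.as_series()
    group_sizes = pd.Series({f"Group{g}": sizes.group_size(g) for g in HOMOEO_GROUPS})

    def chrom_pairs(traits, chroms):
        rows = [
            {"label": f"{t}:{c}", "size": chrom_sizes[c],
             "value": partition.chromosome_pct.at[c, t]}
            for t in traits for c in chroms
        ]
        return pd.DataFrame(rows)

    def group_pairs(traits):
        rows = [
            {"label": f"{t}:{g}", "size": group_sizes[g],
             "value": partition.group_pct.at[g, t]}
            for t in traits for g in group_sizes.index
        ]
        return pd.DataFrame(rows)

    if scope == "combined":
        traits = partition.traits
        if subgenome == "groups":
            pairs = group_pairs(traits)
        elif subgenome is not None:
            if subgenome not in SUBGENOMES:
                raise ValueError(f"unknown subgenome {subgenome!r}")
            chroms = [f"{g}{subgenome}" for g in HOMOEO_GROUPS]
            pairs = chrom_pairs(traits, chroms)
        else:
            pairs = chrom_pairs(traits, list(chrom_sizes.index))
        return _pearson(pairs, scope, subgenome or "all")

    if trait is None:
        raise ValueError(f"scope {scope!r} requires a trait")
    if scope == "all-21":
        pairs = chrom_pairs([trait], list(chrom_sizes.index))
    elif scope == "groups":
        pairs = group_pairs([trait])
    else:
        if subgenome not in SUBGENOMES:
            raise ValueError(f"scope 'within-subgenome' requires subgenome A/B/D")
        pairs = chrom_pairs([trait], [f"{g}{subgenome}" for g in HOMOEO_GROUPS])
    return _pearson(pairs, scope, trait)


def remove_outliers(result: CorrelationResult, labels: list[str]) -> CorrelationResult:
    """Drop named trait:unit cells and recompute the correlation."""
    if result.pairs is None:
        raise ValueError("result carries no pair-level data")
    known = set(result.pairs["label"])
    unknown = [l for l in labels if l not in known]
    if unknown:
        raise KeyError(f"labels not present in the correlation: {unknown}")
    if not labels:
        return result
    reduced = result.pairs[~result.pairs["label"].isin(labels)]
    return _pearson(reduced, result.scope, result.label,
                    outliers=result.outliers_removed + list(labels))


def _pearson_pvalue(r: float, n: int) -> float:
    """Two-sided p for a correlation of r at sample size n (t distribution)."""
    if abs(r) >= 1.0:
        return 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def attenuation_adjust(result: CorrelationResult,
                       reliability: float) -> CorrelationResult:
    """Shrink r for estimation unreliability: r_att = r * sqrt(reliability).

    ``reliability`` must lie in (0, 1]; the p-value is recomputed for the
    adjusted coefficient at the same n.
    """
    if not 0.0 < reliability <= 1.0:
        raise ValueError(f"reliability must lie in (0, 1]; got {reliability}")
    r_att = result.r * float(np.sqrt(reliability))
    return replace(result, r_attenuated=r_att,
                   p_attenuated=_pearson_pvalue(r_att, result.n))


def median_r_across_traits(per_trait_results: list[CorrelationResult]) -> float:
    """Median of per-trait correlation coefficients (even length: mean of
    the central pair)."""
    if not per_trait_results:
        raise ValueError("no correlation results supplied")
    return float(np.median([res.r for res in per_trait_results]))


def correlation_table(partition: PartitionTable,
                      sizes: GenomeSizes) -> pd.DataFrame:
    """Per-trait size-vs-variance correlations in the published layout.

    One row per trait with columns A/B/D (chromosomes within a subgenome),
    Groups (7 homoeologous-group roll-ups) and All (all 21 chromosomes),
    plus a Combined row pooling trait x unit cells across traits.
    """
    rows = {}
    for t in partition.traits:
        rows[t] = {
            **{s: size_variance_correlation(
                partition, sizes, "within-subgenome", trait=t, subgenome=s).r
               for s in SUBGENOMES},
            "Groups": size_variance_correlation(partition, sizes, "groups",
                                                trait=t).r,
            "All": size_variance_correlation(partition, sizes, "all-21",
                                             trait=t).r,
        }
    rows["Combined"] = {
        **{s: size_variance_correlation(
            partition, sizes, "combined", subgenome=s).r for s in SUBGENOMES},
        "Groups": size_variance_correlation(partition, sizes, "combined",
                                            subgenome="groups").r,
        "All": size_variance_correlation(partition, sizes, "combined").r,
    }
    out = pd.DataFrame(rows).T[["A", "B", "D", "Groups", "All"]]
    out.index.name = "stress"
    return out


# ---------------------------------------------------------------------------
# ANCOVA
# ---------------------------------------------------------------------------

def ancova(
    effects: pd.Series,
    sizes: GenomeSizes,
    covariate: str = "subgenome-size",
    interaction: bool = False,
) -> pd.DataFrame:
    """OLS ANCOVA of additive effects on subgenome with a size covariate.

    ``effects`` is indexed by chromosome (one row per chromosome, typically
    stacked over traits with a MultiIndex (trait, chromosome) or repeated
    chromosome labels). Models:

    * ``covariate='subgenome-size'`` — effect ~ subgenome + subgenome_size;
    * ``covariate='chromosome-size'`` — effect ~ subgenome + chrom_size,
      or effect ~ subgenome * chrom_size with ``interaction=True``.

    Returns the type-II ANOVA table. With the subgenome-size covariate the
    covariate is constant within each subgenome level and therefore aliased
    with the factor once both are in the model; the covariate is entered
    first and the aliased row is reported with NaN F/p rather than dropped
    silently.
    """
    if covariate not in ("subgenome-size", "chromosome-size"):
        raise ValueError(f"unknown covariate {covariate!r}")
    chroms = (effects.index.get_level_values(-1)
              if isinstance(effects.index, pd.MultiIndex) else effects.index)
    df = pd.DataFrame({
        "effect": effects.to_numpy(float),
        "subgenome": [str(c)[1] for c in chroms],
        "chrom_size": [sizes[str(c)] for c in chroms],
        "subgenome_size": [sizes.subgenome_size(str(c)[1]) for c in chroms],
    })
    if covariate == "subgenome-size":
        model = smf.ols("effect ~ subgenome_size + C(subgenome)", data=df).fit()
    elif interaction:
        model = smf.ols("effect ~ C(subgenome) * chrom_size", data=df).fit()
    else:
        model = smf.ols("effect ~ C(subgenome) + chrom_size", data=df).fit()
    with np.errstate(divide="ignore", invalid="ignore"):
        table = sm.stats.anova_lm(model, typ=2)
    return table
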