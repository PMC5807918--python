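"""Calibration and robustness procedures around the REML engine:

* **null-phenotype replicates** — refit the full multi-GRM model on pure
  N(0,1) phenotypes to measure the small-sample upward bias floor of h2
  and the null spread of subgenome contributions;
* **leave-one-individual jackknife** — reliability of the variance
  estimates, the square of the mean correlation between full-model and
  reduced-model per-chromosome variance vectors;
* **SNP thinning** — rebuild GRMs and refit after randomly omitting
  markers (all chromosomes, A+B only, or D only) to probe sensitivity to
  marker density and LD-block coverage.

Every procedure is exactly reproducible given (seed, n_reps, inputs);
replicate seeds are spawned from the master seed with
``numpy.random.default_rng``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import (CHROMOSOMES, SUBGENOMES, GenotypePanel, chromosome_partition,
                      filter_markers)
from .grm import Grm, compute_grm
from .greml import GremlFit, MixedModelSpec, fit_greml, heritability
from .partition import PartitionTable, partition_from_fits

logger = logging.getLogger(__name__)

THINNING_SCHEMES = ("all-20", "AB-20", "D-50")


@dataclass
class ReplicateEnsemble:
    """Fits and summaries from a set of resampling replicates."""

    seeds: list[int]
    fits: list[GremlFit]
    h2: np.ndarray                     # per converged replicate
    subgenome_variance: pd.DataFrame | None  # replicates x (A, B, D), cumulative sigma2
    n_non_converged: int
    summary: dict = field(default_factory=dict)


def _subgenome_cumulative(fit: GremlFit) -> dict[str, float]:
    labels = fit.component_labels
    out = {}
    for s in SUBGENOMES:
        idx = [i for i, l in enumerate(labels) if l and l.endswith(s)]
        out[s] = float(np.maximum(fit.sigma2[idx], 0.0).sum())
    return out


def null_phenotype_run(
    grms: list[Grm],
    n_reps: int = 100,
    seed: int = 0,
    fixed_design: np.ndarray | None = None,
    tol: float = 1e-6,
    max_iter: int = 200,
) -> ReplicateEnsemble:
    """Fit the full multi-GRM model to i.i.d. N(0,1) phenotypes.

    Measures what the estimator reports when the phenotype carries no
    genetic signal: the mean null h2 (the bias floor) and a 95% percentile
    interval, plus per-subgenome cumulative variances when the GRMs carry
    chromosome labels.
    """
    ids = grms[0].individual_ids
    for g in grms[1:]:
        if g.individual_ids != ids:
            raise ValueError("GRMs do not share individuals")
    n = len(ids)
    rng = np.random.default_rng(seed)
    rep_seeds = [int(s) for s in rng.integers(0, 2**31 - 1, size=n_reps)]
    fits, h2s, sub_rows = [], [], []
    n_bad = 0
    labelled = all(g.source_chromosome for g in grms)
    for rs in rep_seeds:
        y = np.random.default_rng(rs).standard_normal(n)
        spec = MixedModelSpec(y, grms, fixed_design)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_greml(spec, tol=tol, max_iter=max_iter)
        fits.append(fit)
        if not fit.converged:
            n_bad += 1
            continue
        h2s.append(heritability(fit))
        if labelled:
            sub_rows.append(_subgenome_cumulative(fit))
    if n_bad:
        logger.warning("null run: %d/%d replicates did not converge", n_bad, n_reps)
    h2 = np.asarray(h2s)
    sub = pd.DataFrame(sub_rows) if labelled else None
    summary = {
        "h2_mean": float(h2.mean()) if h2.size else np.nan,
        "h2_ci95": [float(np.percentile(h2, 2.5)), float(np.percentile(h2, 97.5))]
        if h2.size else [np.nan, np.nan],
    }
    if sub is not None and len(sub):
        summary["subgenome_mean"] = sub.mean().to_dict()
        summary["subgenome_sd"] = sub.std(ddof=1).to_dict()
    return ReplicateEnsemble(rep_seeds, fits, h2, sub, n_bad, summary)


def jackknife_reliability(
    spec: MixedModelSpec,
    full_fit: GremlFit | None = None,
    n_reps: int = 100,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 200,
) -> tuple[float, np.ndarray]:
    """Reliability of the variance estimates by leave-one-out refitting.

    Each replicate removes one uniformly drawn individual (with
    replacement across replicates), refits the full model, and correlates
    the reduced-model per-component variance vector with the full-model
    one. Reliability = (mean Pearson r)^2. Returns it with the
    per-replicate correlations.
    """
    n = spec.phenotype.size
    if n < 10:
        raise ValueError("jackknife needs at least 10 individuals")
    if full_fit is None:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            full_fit = fit_greml(spec, tol=tol, max_iter=max_iter)
    full_vec = full_fit.sigma2
    rng = np.random.default_rng(seed)
    drop = rng.integers(0, n, size=n_reps)
    rs = []
    for d in drop:
        keep = np.delete(np.arange(n), d)
        comps = [
            Grm(
                [g.individual_ids[i] for i in keep],
                g.values[np.ix_(keep, keep)],
                g.n_markers,
                g.source_chromosome,
            )
            for g in spec.components
        ]
        sub = MixedModelSpec(
            spec.phenotype[keep], comps,
            spec.fixed_design[keep] if spec.fixed_design is not None else None,
            spec.constraint_mode,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_greml(sub, tol=tol, max_iter=max_iter)
        if not fit.converged:
            logger.warning("jackknife replicate (drop %d) did not converge", d)
            continue
        with np.errstate(invalid="ignore"):
            r = np.corrcoef(full_vec, fit.sigma2)[0, 1]
        if np.isfinite(r):
            rs.append(float(r))
    rs = np.asarray(rs)
    if rs.size == 0:
        raise RuntimeError("no usable jackknife replicate")
    reliability = float(np.mean(rs) ** 2)
    return reliability, rs


def pooled_jackknife_reliability(
    specs: dict[str, MixedModelSpec],
    full_fits: dict[str, GremlFit] | None = None,
    n_reps: int = 100,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 200,
) -> tuple[float, np.ndarray]:
    """Multi-trait reliability: per replicate, one pooled correlation over
    the concatenated (chromosome x trait) variance vector of all traits.
    """
    traits = list(specs)
    n = specs[traits[0]].phenotype.size
    full_fits = dict(full_fits or {})
    for t in traits:
        if t not in full_fits:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                full_fits[t] = fit_greml(specs[t], tol=tol, max_iter=max_iter)
    full_vec = np.concatenate([full_fits[t].sigma2 for t in traits])
    rng = np.random.default_rng(seed)
    drop = rng.integers(0, n, size=n_reps)
    rs = []
    for d in drop:
        keep = np.delete(np.arange(n), d)
        reduced = []
        ok = True
        for t in traits:
            spec = specs[t]
            comps = [
                Grm([g.individual_ids[i] for i in keep],
                    g.values[np.ix_(keep, keep)], g.n_markers,
                    g.source_chromosome)
                for g in spec.components
            ]
            sub = MixedModelSpec(
                spec.phenotype[keep], comps,
                spec.fixed_design[keep] if spec.fixed_design is not None else None,
                spec.constraint_mode,
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = fit_greml(sub, tol=tol, max_iter=max_iter)
            if not fit.converged:
                ok = False
                break
            reduced.append(fit.sigma2)
        if not ok:
            continue
        r = np.corrcoef(full_vec, np.concatenate(reduced))[0, 1]
        if np.isfinite(r):
            rs.append(float(r))
    rs = np.asarray(rs)
    if rs.size == 0:
        raise RuntimeError("no usable jackknife replicate")
    return float(np.mean(rs) ** 2), rs


# ---------------------------------------------------------------------------
# SNP thinning
# ---------------------------------------------------------------------------

@dataclass
class ThinningResult:
    scheme: str
    full_partition: PartitionTable
    thinned_partition: PartitionTable
    subgenome_delta: pd.DataFrame      # thinned - full, per subgenome x trait
    dropped_chromosomes: list[str]
    n_markers_full: int
    n_markers_thinned: int


def _thin_mask(panel: GenotypePanel, scheme: str, rng: np.random.Generator
               ) -> np.ndarray:
    sub = panel.map.table["subgenome"].to_numpy()
    keep = np.ones(panel.n_markers, bool)
    if scheme == "all-20":
        drop = rng.random(panel.n_markers) < 0.20
    elif scheme == "AB-20":
        drop = (rng.random(panel.n_markers) < 0.20) & np.isin(sub, ["A", "B"])
    elif scheme == "D-50":
        drop = (rng.random(panel.n_markers) < 0.50) & (sub == "D")
    else:
        raise ValueError(f"unknown scheme {scheme!r}; choose from {THINNING_SCHEMES}")
    keep[drop] = False
    return keep


def snp_thinning_run(
    panel: GenotypePanel,
    phenotypes: pd.DataFrame,
    scheme: str,
    seed: int = 0,
    fixed_design: np.ndarray | None = None,
    max_missing: float = 0.20,
    min_maf: float = 0.05,
    tol: float = 1e-6,
    max_iter: int = 200,
) -> ThinningResult:
    """Compare partitions before and after random marker omission.

    ``phenotypes`` holds one column per trait, aligned with the panel rows.
    The thinned panel is re-filtered, GRMs rebuilt (allele frequencies
    recomputed) and the full model refitted. Chromosomes left with no
    markers are dropped from the thinned run with a warning.
    """
    rng = np.random.default_rng(seed)
    keep = _thin_mask(panel, scheme, rng)
    thinned = panel.subset_markers(np.flatnonzero(keep))
    thinned, _ = filter_markers(thinned, max_missing, min_maf)

    def run(p: GenotypePanel) -> tuple[PartitionTable, list[str]]:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            parts = chromosome_partition(p.map)
        grms, dropped = {}, []
        for c, idx in parts.items():
            if idx.size == 0:
                dropped.append(c)
                continue
            grms[c] = compute_grm(p, idx, source_chromosome=c)
        if dropped:
            warnings.warn(
                f"chromosomes dropped from thinned run (no markers): {dropped}",
                stacklevel=3,
            )
        fits = {}
        for trait in phenotypes.columns:
            spec = MixedModelSpec(
                phenotypes[trait].to_numpy(float), list(grms.values()), fixed_design
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fits[trait] = fit_greml(spec, tol=tol, max_iter=max_iter)
        if dropped:
            # pad the partition with zero rows so roll-ups stay comparable
            from .greml import proportion_table as _pt
            cols = {}
            for trait, fit in fits.items():
                s = pd.Series(0.0, index=list(CHROMOSOMES))
                s[list(grms)] = _pt(fit)
                cols[trait] = s
            table = PartitionTable(
                pd.DataFrame(cols),
                pd.Series({t: heritability(f) for t, f in fits.items()}),
            )
        else:
            table = partition_from_fits(fits)
        return table, dropped

    full_table, _ = run(panel)
    thin_table, dropped = run(thinned)
    delta = thin_table.subgenome_pct - full_table.subgenome_pct
    return ThinningResult(
        scheme, full_table, thin_table, delta, dropped,
        panel.n_markers, thinned.n_markers,
    )
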