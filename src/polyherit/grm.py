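"""Genomic relatedness matrices from SNP subsets.

The default estimator is the GCTA/Yang et al. (2010) form: off-diagonal
entries average the cross-products of genotypes standardised by their
binomial variance 2p(1-p); diagonal entries use the distinct
finite-sample estimator 1 + (x^2 - (1+2p)x + 2p^2)/(2p(1-p)) averaged
over markers. Missing genotypes are mean-imputed to 2p, which makes
their centered contribution exactly zero while keeping the marker count
fixed.

With the Yang diagonal the matrix is not guaranteed positive
semi-definite; the REML layer never assumes it is.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core_io import GenotypePanel, StructuralError


class MonomorphicMarkerError(ValueError):
    """A marker in the subset has allele frequency 0 or 1."""


@dataclass
class Grm:
    """Symmetric n x n relatedness matrix for one SNP subset."""

    individual_ids: list[str]
    values: np.ndarray
    n_markers: int
    source_chromosome: str | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise StructuralError("GRM must be square")
        if v.shape[0] != len(self.individual_ids):
            raise StructuralError("GRM size does not match individual ids")
        if not np.allclose(v, v.T, atol=1e-10):
            raise StructuralError("GRM must be symmetric")
        if self.n_markers < 1:
            raise StructuralError("n_markers must be >= 1")
        self.values = (v + v.T) / 2.0

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def offdiag(self) -> np.ndarray:
        """Strictly-lower-triangle entries as a flat vector."""
        i, j = np.tril_indices(self.n, k=-1)
        return self.values[i, j]


def compute_grm(
    panel: GenotypePanel,
    marker_subset: np.ndarray | None = None,
    *,
    yang_diagonal: bool = True,
    source_chromosome: str | None = None,
) -> Grm:
    """Relatedness matrix from the markers in ``marker_subset``.

    Allele frequencies are computed within the analysed sample on
    non-missing calls. ``yang_diagonal=False`` switches the diagonal to the
    plain cross-product estimator for sensitivity checks.
    """
    if marker_subset is None:
        marker_subset = np.arange(panel.n_markers)
    marker_subset = np.asarray(marker_subset)
    if marker_subset.size == 0:
        raise ValueError("marker_subset is empty")
    g = panel.genotypes[:, marker_subset]
    with np.errstate(invalid="ignore"):
        p = np.nanmean(g, axis=0) / 2.0
    if np.isnan(p).any():
        raise MonomorphicMarkerError("a marker in the subset has no observed calls")
    mono = (p <= 0.0) | (p >= 1.0)
    if mono.any():
        bad = panel.map.marker_ids[marker_subset][mono][:5]
        raise MonomorphicMarkerError(
            f"monomorphic markers in subset (e.g. {list(bad)}); "
            "apply the MAF filter before building GRMs"
        )
    m = marker_subset.size
    denom = 2.0 * p * (1.0 - p)
    x = np.where(np.isnan(g), 2.0 * p, g)  # mean-imputation
    z = (x - 2.0 * p) / np.sqrt(denom)
    a = (z @ z.T) / m
    if yang_diagonal:
        # diagonal from observed calls only; imputed entries contribute 0
        obs = ~np.isnan(g)
        num = np.where(obs, x * x - (1.0 + 2.0 * p) * x + 2.0 * p * p, 0.0)
        diag = 1.0 + (num / denom).sum(axis=1) / m
        np.fill_diagonal(a, diag)
    return Grm(list(panel.individual_ids), a, int(m), source_chromosome)


def grm_correlations(grms: list[Grm]) -> pd.DataFrame:
    """Pearson correlations between GRMs over their off-diagonal entries.

    All GRMs must share the same individuals in the same order. Returns a
    symmetric k x k DataFrame with unit diagonal, labelled by source
    chromosome where available — the input for a clustered-heatmap display.
    """
    if not grms:
        raise ValueError("no GRMs supplied")
    ids = grms[0].individual_ids
    for g in grms[1:]:
        if g.individual_ids != ids:
            raise StructuralError("GRMs do not share individual ids/ordering")
    vecs = np.stack([g.offdiag() for g in grms])
    corr = np.corrcoef(vecs)
    labels = [
        g.source_chromosome if g.source_chromosome is not None else f"grm{i}"
        for i, g in enumerate(grms)
    ]
    return pd.DataFrame(corr, index=labels, columns=labels)


# ---------------------------------------------------------------------------
# GCTA-compatible serialization
# ---------------------------------------------------------------------------

def write_grm_gcta(grm: Grm, prefix: str | Path) -> None:
    """Write ``<prefix>.grm.gz`` (i, j, n_markers, value) and ``<prefix>.grm.id``."""
    prefix = Path(prefix)
    with gzip.open(str(prefix) + ".grm.gz", "wt") as fh:
        for i in range(grm.n):
            for j in range(i + 1):
                fh.write(f"{i + 1}\t{j + 1}\t{grm.n_markers}\t"
                         f"{grm.values[i, j]:.8g}\n")
    with open(str(prefix) + ".grm.id", "w") as fh:
        for ind in grm.individual_ids:
            fh.write(f"{ind}\t{ind}\n")


def read_grm_gcta(prefix: str | Path) -> Grm:
    prefix = Path(prefix)
    ids = [line.split()[1] for line in open(str(prefix) + ".grm.id")]
    n = len(ids)
    values = np.zeros((n, n))
    n_markers = 1
    with gzip.open(str(prefix) + ".grm.gz", "rt") as fh:
        for line in fh:
            i, j, m, v = line.split()
            i, j = int(i) - 1, int(j) - 1
            values[i, j] = values[j, i] = float(v)
            n_markers = int(float(m))
    return Grm(ids, values, n_markers)


def write_grm_tsv(grm: Grm, path: str | Path) -> None:
    df = pd.DataFrame(grm.values, index=grm.individual_ids,
                      columns=grm.individual_ids)
    df.index.name = "individual_id"
    df.to_csv(path, sep="\t")


def read_grm_tsv(path: str | Path, n_markers: int = 1) -> Grm:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return Grm(list(df.index.astype(str)), df.to_numpy(float), n_markers)
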