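"""Shared fixtures: small deterministic panels and the packaged tables.

Everything is generated programmatically; session scope keeps the slower
synthetic populations to one build per run.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import polyherit as ph
from polyherit.core_io import GenotypePanel, MarkerMap, chromosome_partition


@pytest.fixture(scope="session")
def published_tables():
    return ph.load_published_tables()


@pytest.fixture()
def tiny_panel():
    """3 individuals x 4 markers, one missing call, two chromosomes."""
    mmap = MarkerMap(pd.DataFrame({
        "marker_id": ["m1", "m2", "m3", "m4"],
        "chromosome": ["1A", "1A", "3D", "3D"],
    }))
    geno = np.array([
        [0.0, 1.0, 2.0, 1.0],
        [2.0, np.nan, 0.0, 1.0],
        [1.0, 1.0, 1.0, 0.0],
    ])
    return GenotypePanel(["ind1", "ind2", "ind3"], geno, mmap)


def hwe_panel(n: int, m_per: int, chromosomes: list[str],
              seed: int) -> GenotypePanel:
    """Unrelated individuals, Hardy-Weinberg genotypes, no LD."""
    rng = np.random.default_rng(seed)
    blocks, ids, chrom = [], [], []
    for c in chromosomes:
        p = rng.uniform(0.15, 0.85, m_per)
        blocks.append(rng.binomial(2, p, size=(n, m_per)).astype(float))
        ids += [f"{c}m{j}" for j in range(m_per)]
        chrom += [c] * m_per
    mmap = MarkerMap(pd.DataFrame({"marker_id": ids, "chromosome": chrom}))
    return GenotypePanel([f"i{j}" for j in range(n)],
                         np.concatenate(blocks, axis=1), mmap)


@pytest.fixture(scope="session")
def shw_panel():
    """Down-scaled SHW population: 100 lines, 15 markers per chromosome."""
    plan = ph.PopulationPlan(
        n_lines=100, n_durum_parents=20, n_tauschii_parents=25,
        markers_per_chromosome={c: 15 for c in ph.CHROMOSOMES},
        ld_block_length={"A": 3.0, "B": 3.0, "D": 8.0},
    )
    return ph.simulate_genotypes(plan, seed=11)


@pytest.fixture(scope="session")
def shw_grms(shw_panel):
    parts = chromosome_partition(shw_panel.map)
    return {c: ph.compute_grm(shw_panel, idx, source_chromosome=c)
            for c, idx in parts.items() if idx.size}


def two_component_toy(seed: int = 42, n: int = 40, m: int = 60):
    """Two independent HWE GRMs plus a phenotype with known variances."""
    rng = np.random.default_rng(seed)

    def grm_matrix():
        g = rng.binomial(2, rng.uniform(0.2, 0.8, m), size=(n, m)).astype(float)
        p = g.mean(0) / 2.0
        z = (g - 2 * p) / np.sqrt(2 * p * (1 - p))
        return z @ z.T / m

    A1, A2 = grm_matrix(), grm_matrix()
    L1 = np.linalg.cholesky(A1 + 1e-8 * np.eye(n))
    L2 = np.linalg.cholesky(A2 + 1e-8 * np.eye(n))
    y = (L1 @ rng.standard_normal(n) * np.sqrt(0.5)
         + L2 @ rng.standard_normal(n) * np.sqrt(0.3)
         + rng.standard_normal(n) * np.sqrt(0.4))
    ids = [str(i) for i in range(n)]
    g1 = ph.Grm(ids, A1, m, "1A")
    g2 = ph.Grm(ids, A2, m, "1B")
    return y, g1, g2
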