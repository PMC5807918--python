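"""The REML engine: correctness against a brute-force likelihood oracle,
monotonicity, degeneracy handling, reporting rules and principal components."""

import itertools
import warnings

import numpy as np
import pytest
from scipy.stats import multivariate_normal

import polyherit as ph
from polyherit.greml import (GremlFit, MixedModelSpec, compute_pcs, fit_greml,
                             heritability, proportion_table, restricted_loglik)
from conftest import hwe_panel, two_component_toy


def contrast_loglik(y, X, mats, theta):
    """Restricted likelihood via error contrasts K'y with K'X = 0 — an
    independent route that never touches the implementation's algebra."""
    n = y.size
    Q, _ = np.linalg.qr(np.eye(n) - X @ np.linalg.pinv(X), mode="reduced")
    K = Q[:, : n - X.shape[1]].T
    V = sum(t * a for t, a in zip(theta, mats))
    try:
        return multivariate_normal(
            mean=np.zeros(K.shape[0]), cov=K @ V @ K.T
        ).logpdf(K @ y)
    except (np.linalg.LinAlgError, ValueError):
        return -np.inf


class TestAgainstGridOracle:
    def test_two_component_toy_matches_grid_search(self):
        y, g1, g2 = two_component_toy()
        spec = MixedModelSpec(y, [g1, g2])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_greml(spec, tol=1e-8)

        n = y.size
        mats = [g1.values, g2.values, np.eye(n)]
        X = spec.fixed_design
        # components may be negative in unconstrained mode; only the
        # error variance is kept positive
        cgrid = np.linspace(-0.6, 1.2, 25)
        egrid = np.linspace(0.01, 1.8, 25)
        best = max(
            ((contrast_loglik(y, X, mats, t), t)
             for t in itertools.product(cgrid, cgrid, egrid)),
            key=lambda v: v[0],
        )
        grid = cgrid
        # refine around the coarse winner
        for _ in range(2):
            width = (grid[1] - grid[0])
            axes = [np.linspace(c - width, c + width, 11)
                    for c in best[1][:2]]
            axes.append(np.linspace(max(best[1][2] - width, 1e-4),
                                    best[1][2] + width, 11))
            best = max(
                ((contrast_loglik(y, X, mats, t), t)
                 for t in itertools.product(*axes)),
                key=lambda v: v[0],
            )
            grid = axes[0]

        est = np.append(fit.sigma2, fit.sigma2_e)
        np.testing.assert_allclose(est, best[1], atol=0.02)
        # and the oracle's likelihood at the AI solution is no worse
        assert contrast_loglik(y, X, mats, est) >= best[0] - 1e-3

    def test_restricted_loglik_matches_contrast_route(self):
        # the two parameterizations differ by the constant 0.5*log|X'X|,
        # so likelihood *differences* between parameter points must agree
        y, g1, g2 = two_component_toy(seed=7)
        spec = MixedModelSpec(y, [g1, g2])
        mats = [g1.values, g2.values, np.eye(y.size)]
        t1, t2 = (0.4, 0.3, 0.5), (0.7, 0.1, 0.8)
        mine = (restricted_loglik(spec, np.array(t1[:2]), t1[2])
                - restricted_loglik(spec, np.array(t2[:2]), t2[2]))
        oracle = (contrast_loglik(y, spec.fixed_design, mats, t1)
                  - contrast_loglik(y, spec.fixed_design, mats, t2))
        assert mine == pytest.approx(oracle, abs=1e-8)


class TestIterationBehavior:
    def test_loglik_trace_nondecreasing(self):
        y, g1, g2 = two_component_toy(seed=3)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_greml(MixedModelSpec(
                y, [g1, g2], constraint_mode="constrained-nonnegative"))
        tr = fit.loglik_trace
        assert len(tr) >= 2
        assert all(b >= a - 1e-8 * max(1, abs(a)) for a, b in zip(tr, tr[1:]))

    def test_permutation_invariance(self):
        y, g1, g2 = two_component_toy(seed=5)
        rng = np.random.default_rng(0)
        perm = rng.permutation(y.size)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_greml(MixedModelSpec(y, [g1, g2]), tol=1e-8)
            pg1 = ph.Grm([g1.individual_ids[i] for i in perm],
                         g1.values[np.ix_(perm, perm)], g1.n_markers, "1A")
            pg2 = ph.Grm([g2.individual_ids[i] for i in perm],
                         g2.values[np.ix_(perm, perm)], g2.n_markers, "1B")
            pfit = fit_greml(MixedModelSpec(y[perm], [pg1, pg2]), tol=1e-8)
        np.testing.assert_allclose(pfit.sigma2, fit.sigma2, atol=1e-4)
        assert pfit.sigma2_e == pytest.approx(fit.sigma2_e, abs=1e-4)


class TestDegenerateInputs:
    def test_constant_phenotype_flagged(self):
        n = 30
        g = ph.Grm([str(i) for i in range(n)], np.eye(n), 5)
        with pytest.warns(UserWarning, match="zero variance"):
            fit = fit_greml(MixedModelSpec(np.ones(n), [g]))
        assert fit.degenerate
        assert np.all(fit.sigma2 == 0) and fit.sigma2_e == 0

    def test_identity_grm_unidentifiable_warns(self):
        rng = np.random.default_rng(8)
        n = 50
        g = ph.Grm([str(i) for i in range(n)], np.eye(n), 5)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_greml(MixedModelSpec(rng.standard_normal(n), [g]))
        assert any("singular" in w or "ill-conditioned" in w
                   for w in fit.warnings)

    def test_rank_deficient_design_rejected(self):
        n = 20
        g = ph.Grm([str(i) for i in range(n)], np.eye(n), 5)
        X = np.ones((n, 2))
        with pytest.raises(ValueError, match="rank"):
            MixedModelSpec(np.arange(n, dtype=float), [g], X)


class TestReportingRules:
    def grm_eye(self, n, label="1A"):
        return ph.Grm([str(i) for i in range(n)], np.eye(n), 5, label)

    def fit_with(self, sigma2, sigma2_e, scale=None):
        k = len(sigma2)
        return GremlFit(np.array(sigma2, float), sigma2_e, np.zeros(1),
                        np.zeros(k + 1), 0.0, 1, True,
                        [f"c{i}" for i in range(k)],
                        component_scale=scale)

    def test_h2_arithmetic(self):
        assert heritability(self.fit_with([0.2, 0.3], 0.5)) == pytest.approx(0.5)

    def test_h2_truncates_negative_components(self):
        fit = self.fit_with([-0.1, 0.6], 0.5)
        assert heritability(fit) == pytest.approx(0.6 / 1.1)

    def test_h2_uses_component_scale(self):
        # inbred-style GRMs (mean diagonal 2): each unit of sigma2 carries
        # two units of phenotypic variance
        fit = self.fit_with([0.25], 0.5, scale=np.array([2.0]))
        assert heritability(fit) == pytest.approx(0.5)

    def test_h2_all_zero_flagged(self):
        with pytest.warns(UserWarning, match="undefined"):
            assert np.isnan(heritability(self.fit_with([0.0, 0.0], 0.0)))

    def test_proportions_simple(self):
        np.testing.assert_allclose(
            proportion_table(self.fit_with([1.0, 1.0, 2.0], 0.5)),
            [25.0, 25.0, 50.0])

    def test_proportions_zero_truncated(self):
        np.testing.assert_allclose(
            proportion_table(self.fit_with([-0.5, 1.0, 1.0], 0.1)),
            [0.0, 50.0, 50.0])

    def test_proportions_all_nonpositive_flagged(self):
        with pytest.warns(UserWarning, match="empty partition"):
            out = proportion_table(self.fit_with([-1.0, -0.2], 0.5))
        assert np.isnan(out).all()


class TestParameterRecovery:
    def test_h2_recovered_on_simulated_traits(self):
        # single all-marker GRM, traits simulated at h2 = 0.5
        h2s = []
        for rep in range(8):
            plan = ph.PopulationPlan(
                n_lines=250, n_durum_parents=60, n_tauschii_parents=60,
                markers_per_chromosome={c: 40 for c in ph.CHROMOSOMES},
                ld_block_length={"A": 3.0, "B": 3.0, "D": 3.0},
                independent_chromosomes=True)
            panel = ph.simulate_genotypes(plan, seed=300 + rep)
            grm = ph.compute_grm(panel)
            tab, _ = ph.simulate_trait(
                panel, ph.TraitPlan(seed=400 + rep, n_causal_per_chromosome=10))
            y = tab.values["trait"].to_numpy()
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = fit_greml(MixedModelSpec(y, [grm]))
            h2s.append(heritability(fit))
        assert np.mean(h2s) == pytest.approx(0.5, abs=0.08)


class TestPrincipalComponents:
    def test_pc1_separates_divergent_subpopulations(self):
        rng = np.random.default_rng(2)
        n, m = 80, 300
        p1 = rng.uniform(0.1, 0.5, m)
        p2 = np.clip(p1 + rng.uniform(0.2, 0.4, m), 0, 0.95)
        g = np.vstack([rng.binomial(2, p1, size=(n // 2, m)),
                       rng.binomial(2, p2, size=(n // 2, m))]).astype(float)
        import pandas as pd
        from polyherit.core_io import GenotypePanel, MarkerMap
        panel = GenotypePanel(
            [f"i{j}" for j in range(n)], g,
            MarkerMap(pd.DataFrame({"marker_id": [f"m{j}" for j in range(m)],
                                    "chromosome": ["1A"] * m})))
        pcs = compute_pcs(panel, k=2)
        group = np.array([0] * (n // 2) + [1] * (n // 2))
        signs = np.sign(pcs[:, 0] - np.median(pcs[:, 0]))
        # PC1 splits the two subpopulations
        assert abs(np.corrcoef(signs, group)[0, 1]) > 0.9

    def test_deterministic_sign_convention(self, shw_panel):
        a = compute_pcs(shw_panel, k=3)
        b = compute_pcs(shw_panel, k=3)
        np.testing.assert_array_equal(a, b)
        for j in range(3):
            lead = np.argmax(np.abs(a[:, j]))
            assert a[lead, j] > 0

    def test_k_zero_empty_block(self, shw_panel):
        assert compute_pcs(shw_panel, k=0).shape == (shw_panel.n_individuals, 0)

    def test_k_too_large_rejected(self, tiny_panel):
        with pytest.raises(ValueError):
            compute_pcs(tiny_panel, k=3)
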