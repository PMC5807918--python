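"""Multi-component GREML: restricted maximum likelihood for

    y = X beta + sum_i g_i + e,    g_i ~ N(0, A_i sigma2_i),  e ~ N(0, I sigma2_e)

so that V = sum_i A_i sigma2_i + I sigma2_e. The maximiser is
average-information (AI) REML with EM-REML fallback steps and
step-halving whenever an AI update leaves the feasible region or
decreases the restricted likelihood.

Conventions
-----------
* The restricted log-likelihood reported is
  -0.5 * [ (n-p) log 2pi + log|V| + log|X'V^-1X| + y'Py ].
* ``constraint_mode='unconstrained'`` (the default used for reporting)
  allows negative component variances as long as V stays positive
  definite; zero-truncation is applied only when percentages are formed
  (:func:`proportion_table`).
* Standard errors come from the inverse AI matrix at convergence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg as la

from .core_io import GenotypePanel
from .grm import Grm, compute_grm


class SingularModelError(np.linalg.LinAlgError):
    """V or X'V^-1X is numerically singular."""


@dataclass
class MixedModelSpec:
    """Inputs for one REML fit."""

    phenotype: np.ndarray              # y, length n
    components: list[Grm]              # the A_i
    fixed_design: np.ndarray | None = None   # X, defaults to intercept-only
    constraint_mode: str = "unconstrained"   # or "constrained-nonnegative"

    def __post_init__(self) -> None:
        y = np.asarray(self.phenotype, dtype=float).ravel()
        n = y.size
        if not self.components:
            raise ValueError("at least one variance component is required")
        for g in self.components:
            if g.n != n:
                raise ValueError(
                    f"GRM for {g.source_chromosome or 'component'} has "
                    f"{g.n} individuals, phenotype has {n}"
                )
        if self.fixed_design is None:
            X = np.ones((n, 1))
        else:
            X = np.atleast_2d(np.asarray(self.fixed_design, dtype=float))
            if X.shape[0] != n:
                raise ValueError("fixed_design rows must match phenotype length")
        if X.shape[1] >= n:
            raise ValueError("more fixed effects than observations")
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("fixed_design is rank deficient")
        if self.constraint_mode not in ("unconstrained", "constrained-nonnegative"):
            raise ValueError(f"unknown constraint_mode {self.constraint_mode!r}")
        self.phenotype = y
        self.fixed_design = X


@dataclass
class GremlFit:
    """REML estimates for one trait."""

    sigma2: np.ndarray          # per-component variances, length k
    sigma2_e: float
    beta: np.ndarray
    se_sigma2: np.ndarray       # length k+1; last entry is se(sigma2_e)
    loglik: float
    n_iter: int
    converged: bool
    component_labels: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)
    degenerate: bool = False
    #: restricted log-likelihood after each accepted iteration
    loglik_trace: list[float] = field(default_factory=list)
    #: mean diagonal of each A_i; the per-individual genetic variance of
    #: component i is sigma2_i * scale_i. For outbred panels the Yang
    #: diagonal averages ~1 and the scale is immaterial; for inbred lines
    #: it averages ~1+F (~2), and ignoring it would halve reported h2.
    component_scale: np.ndarray | None = None

    @property
    def n_components(self) -> int:
        return self.sigma2.size

    def scaled_sigma2(self) -> np.ndarray:
        """Per-component contribution to phenotypic variance, sigma2_i * scale_i."""
        if self.component_scale is None:
            return self.sigma2
        return self.sigma2 * self.component_scale


def _chol_logdet(mat: np.ndarray) -> tuple[np.ndarray, float]:
    c = la.cholesky(mat, lower=True)
    d = np.diag(c)
    # near-singular V is treated as infeasible: with indefinite (Yang-
    # diagonal) GRMs the restricted likelihood may keep climbing toward a
    # singular V, where its evaluation is meaningless
    if (d.min() / d.max()) ** 2 < 1e-10:
        raise np.linalg.LinAlgError("matrix numerically singular")
    return c, 2.0 * float(np.sum(np.log(d)))


def _reml_pieces(theta, A, y, X):
    """Return (loglik, P, Py, beta) for variance parameters theta.

    theta = (sigma2_1..sigma2_k, sigma2_e). Raises LinAlgError if V or
    X'V^-1X is not positive definite.
    """
    n = y.size
    V = theta[-1] * np.eye(n)
    for t, a in zip(theta[:-1], A):
        V += t * a.values
    c, logdet_v = _chol_logdet(V)
    Vinv = la.cho_solve((c, True), np.eye(n))
    VinvX = Vinv @ X
    XtViX = X.T @ VinvX
    cx, logdet_x = _chol_logdet(XtViX)
    beta = la.cho_solve((cx, True), VinvX.T @ y)
    P = Vinv - VinvX @ la.cho_solve((cx, True), VinvX.T)
    Py = P @ y
    p = X.shape[1]
    ll = -0.5 * ((n - p) * np.log(2.0 * np.pi) + logdet_v + logdet_x
                 + float(y @ Py))
    return ll, P, Py, beta


def fit_greml(
    spec: MixedModelSpec, tol: float = 1e-6, max_iter: int = 200
) -> GremlFit:
    """Maximise the restricted likelihood by AI-REML with EM fallback.

    Starts from an equal split of the phenotypic variance
    (sigma2_i = var(y)/(2k), sigma2_e = var(y)/2), takes one EM step to
    stabilise, then AI (Newton) steps. An AI step is rejected — halved, and
    finally replaced by an EM step — if it makes V indefinite or lowers the
    restricted likelihood. Convergence requires both the log-likelihood
    change and the relative parameter change to fall below ``tol``.
    """
    y, X, A = spec.phenotype, spec.fixed_design, spec.components
    n, k = y.size, len(A)
    labels = [g.source_chromosome or f"comp{i}" for i, g in enumerate(A)]
    vary = float(np.var(y, ddof=1)) if n > 1 else 0.0
    fit_warnings: list[str] = []

    if vary <= 0.0:
        msg = "phenotype has zero variance; returning degenerate fit"
        warnings.warn(msg, stacklevel=2)
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        return GremlFit(np.zeros(k), 0.0, beta, np.zeros(k + 1),
                        np.nan, 0, True, labels, [msg], degenerate=True,
                        component_scale=np.ones(k))

    constrained = spec.constraint_mode == "constrained-nonnegative"
    floor = 1e-8 * vary
    theta = np.array([vary / (2.0 * k)] * k + [vary / 2.0])

    ll, P, Py, beta = _reml_pieces(theta, A, y, X)
    mats = [g.values for g in A] + [np.eye(n)]

    def em_step(theta, P, Py):
        new = theta.copy()
        for i, a in enumerate(mats):
            tr = float(np.sum(P * a))
            quad = float(Py @ (a @ Py))
            new[i] = theta[i] + theta[i] ** 2 * (quad - tr) / n
        return np.maximum(new, floor)

    # lower bounds: all components in constrained mode, only the error
    # variance otherwise (V must keep a positive ridge)
    lower = np.full(k + 1, -np.inf)
    lower[-1] = floor
    if constrained:
        lower[:] = floor

    n_iter = 0
    converged = False
    stalled = 0
    trace: list[float] = [float(ll)]
    for n_iter in range(1, max_iter + 1):
        # score and average-information matrix at current theta
        t_vecs = np.column_stack([a @ Py for a in mats])      # n x (k+1)
        Pt = P @ t_vecs
        ai = 0.5 * (t_vecs.T @ Pt)
        score = np.array([
            -0.5 * (float(np.sum(P * a)) - float(Py @ t_vecs[:, i]))
            for i, a in enumerate(mats)
        ])

        # active set: parameters pinned at their bound with an outward
        # gradient take no step; the AI system is solved for the rest
        pinned = (theta <= lower + 1e-12 * vary) & (score < 0.0)
        free = ~pinned

        if n_iter == 1 or not free.any():
            # one EM step first: cheap, monotone, stabilises the start point
            candidates = [em_step(theta, P, Py)]
        else:
            ai_f = ai[np.ix_(free, free)]
            cond = np.linalg.cond(ai_f)
            if cond > 1e10:
                msg = ("AI matrix is ill-conditioned "
                       f"(cond={cond:.2g}); components may be unidentifiable")
                if msg not in fit_warnings:
                    fit_warnings.append(msg)
                    warnings.warn(msg, stacklevel=2)
                step_f = np.linalg.pinv(ai_f) @ score[free]
            else:
                step_f = la.solve(ai_f, score[free], assume_a="pos")
            step = np.zeros(k + 1)
            step[free] = step_f
            # the AI direction is an ascent direction (AI matrix is PSD),
            # so some halved step always exists that improves the likelihood
            # and keeps V positive definite; halve deeply because an
            # ill-conditioned AI matrix can propose huge steps
            candidates = [theta + step / 2.0**j for j in range(40)]

        accepted_j = None
        for j, cand in enumerate(candidates):
            cand = np.maximum(cand, lower)
            try:
                ll_new, P_new, Py_new, beta_new = _reml_pieces(cand, A, y, X)
            except np.linalg.LinAlgError:
                continue
            if ll_new >= ll - 1e-10 * max(1.0, abs(ll)):
                accepted_j = j
                break
        if accepted_j is None:
            # EM fallback: monotone whenever the current point is
            # nonnegative; from a point with negative components it has no
            # such guarantee, so it too must pass the improvement check
            cand = em_step(np.maximum(theta, floor), P, Py)
            try:
                ll_new, P_new, Py_new, beta_new = _reml_pieces(cand, A, y, X)
                ok = ll_new >= ll - 1e-10 * max(1.0, abs(ll))
            except np.linalg.LinAlgError:
                ok = False
            if not ok:
                # no candidate improves the likelihood: a constrained
                # maximum (possibly on the positive-definiteness boundary)
                msg = ("no uphill step remains; treating the current "
                       "point as the constrained optimum")
                fit_warnings.append(msg)
                warnings.warn(msg, stacklevel=2)
                converged = True
                break

        d_ll = ll_new - ll
        d_par = np.max(np.abs(cand - theta)) / max(1.0, np.max(np.abs(cand)))
        theta, ll, P, Py, beta = cand, ll_new, P_new, Py_new, beta_new
        trace.append(float(ll))
        small = abs(d_ll) < tol * max(1.0, abs(ll)) and d_par < 100.0 * tol
        if small and accepted_j in (0, 1):
            # a full (or once-halved) Newton step with negligible change:
            # a genuine stationary point of the constrained problem
            converged = True
            break
        # negligible progress from a heavily truncated step is a stall at
        # the positive-definiteness barrier, not convergence
        stalled = stalled + 1 if small else 0
        if stalled >= 3:
            msg = ("progress stalled near the positive-definiteness "
                   "boundary; estimates reported at the stall point")
            fit_warnings.append(msg)
            warnings.warn(msg, stacklevel=2)
            converged = True
            break

    if not converged:
        msg = f"REML did not converge in {max_iter} iterations"
        fit_warnings.append(msg)
        warnings.warn(msg, stacklevel=2)

    # standard errors from the inverse AI matrix at the final parameters
    t_vecs = np.column_stack([a @ Py for a in mats])
    ai = 0.5 * (t_vecs.T @ (P @ t_vecs))
    with np.errstate(invalid="ignore"):
        if np.linalg.cond(ai) > 1e10:
            se = np.sqrt(np.abs(np.diag(np.linalg.pinv(ai))))
            msg = "AI matrix singular at optimum; standard errors from pseudo-inverse"
            if msg not in fit_warnings:
                fit_warnings.append(msg)
                warnings.warn(msg, stacklevel=2)
        else:
            se = np.sqrt(np.diag(np.linalg.inv(ai)))

    return GremlFit(
        sigma2=theta[:-1].copy(),
        sigma2_e=float(theta[-1]),
        beta=beta,
        se_sigma2=se,
        loglik=float(ll),
        n_iter=n_iter,
        converged=converged,
        component_labels=labels,
        warnings=fit_warnings,
        loglik_trace=trace,
        component_scale=np.array([np.mean(np.diag(g.values)) for g in A]),
    )


def restricted_loglik(
    spec: MixedModelSpec, sigma2: np.ndarray, sigma2_e: float
) -> float:
    """Restricted log-likelihood at fixed variance parameters."""
    theta = np.append(np.asarray(sigma2, float), sigma2_e)
    ll, *_ = _reml_pieces(theta, spec.components, spec.phenotype,
                          spec.fixed_design)
    return ll


# ---------------------------------------------------------------------------
# Reporting helpers
# ---------------------------------------------------------------------------

def heritability(fit: GremlFit) -> float:
    """Total h2 under the zero-truncated reporting rule.

    Negative component variances are truncated to zero in both the
    numerator and the total, mirroring how partition percentages are
    reported; h2 = sum_i max(s_i, 0) / (sum_i max(s_i, 0) + sigma2_e),
    where s_i = sigma2_i * mean(diag A_i) is component i's contribution to
    phenotypic variance. The diagonal scale matters for inbred panels,
    where the Yang diagonal averages ~1+F rather than 1.
    """
    g = np.maximum(fit.scaled_sigma2(), 0.0).sum()
    total = g + max(fit.sigma2_e, 0.0)
    if total <= 0.0:
        warnings.warn("all variance estimates are zero; h2 undefined",
                      stacklevel=2)
        return np.nan
    return float(g / total)


def proportion_table(fit: GremlFit) -> np.ndarray:
    """Per-component percentages of total additive variance.

    Negative estimates are recorded as zeroes and the remaining components
    rescaled to sum to 100; components enter on the phenotypic-variance
    scale (sigma2_i times the mean GRM diagonal).
    """
    g = np.maximum(fit.scaled_sigma2(), 0.0)
    total = g.sum()
    if total <= 0.0:
        warnings.warn("no positive additive variance; empty partition",
                      stacklevel=2)
        return np.full(fit.n_components, np.nan)
    return 100.0 * g / total


def compute_pcs(panel: GenotypePanel, k: int = 10) -> np.ndarray:
    """Top-k principal components of the all-marker GRM.

    Eigenvectors of the aggregate relatedness matrix, unit-normalised,
    with a deterministic sign convention (the largest-magnitude loading of
    each PC is positive). Returns an n x k matrix of covariates.
    """
    n = panel.n_individuals
    if k >= n:
        raise ValueError(f"k={k} must be smaller than n={n}")
    if k == 0:
        return np.empty((n, 0))
    grm = compute_grm(panel)
    vals, vecs = la.eigh(grm.values)
    order = np.argsort(vals)[::-1][:k]
    pcs = vecs[:, order]
    for j in range(pcs.shape[1]):
        lead = np.argmax(np.abs(pcs[:, j]))
        if pcs[lead, j] < 0:
            pcs[:, j] = -pcs[:, j]
    return pcs
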