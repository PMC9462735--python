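"""Finite mixtures of univariate linear regressions fitted by EM.

The model underlying per-CpG population discovery: observed beta values
``y`` are explained by up to three latent sample populations, each with its
own linear relationship to the covariate ``x`` (here ``1 - purity``),

    y_i | z_i = k  ~  Normal(intercept_k + slope_k * x_i, residual_sd_k^2),

with mixing weights ``w_k``. EM alternates posterior membership
(responsibility) computation with weighted least-squares updates; the
number of components is chosen by BIC over K = 1..3 with several random
restarts per K.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RegressionComponent",
    "MixtureFit",
    "fit_em",
    "bic",
    "select_model",
]

#: Lower bound on component residual standard deviations.  Without a floor a
#: component collapsing onto a zero-variance subset of samples sends the
#: likelihood to infinity and stalls the fit.
RESIDUAL_SD_FLOOR = 1e-4

#: Components whose mixing weight drops below this are removed and EM
#: continues with fewer components (spurious tiny populations vanish).
DEFAULT_MIN_WEIGHT = 0.05

DEFAULT_MAX_ITER = 200
DEFAULT_TOL = 1e-6

_LOG_2PI = math.log(2.0 * math.pi)


def _logsumexp_rows(a: np.ndarray) -> np.ndarray:
    """Row-wise log-sum-exp; minimal and allocation-light (hot path)."""
    if a.shape[1] == 1:
        return a[:, 0]
    m = a.max(axis=1)
    return m + np.log(np.exp(a - m[:, None]).sum(axis=1))


@dataclass(frozen=True)
class RegressionComponent:
    """One population's fitted line and its share of the cohort.

    Attributes
    ----------
    intercept : float
        Value of the line at ``x = 0`` (beta units).  When ``x = 1 - purity``
        this is the pure-tumor methylation state of the population.
    slope : float
        Change in beta per unit covariate.
    residual_sd : float
        Residual standard deviation around the line, floored at
        :data:`RESIDUAL_SD_FLOOR`.
    weight : float
        Mixing proportion in (0, 1]; weights of a fit sum to one.
    """

    intercept: float
    slope: float
    residual_sd: float
    weight: float


@dataclass
class MixtureFit:
    """Result of fitting a K-component mixture of regressions to one CpG.

    ``labels`` are hard assignments in ``{1..K}`` (``labels[i]`` is the
    argmax of row ``i`` of ``responsibilities``).  ``ll_trace`` records the
    log-likelihood at every E-step; it is non-decreasing except immediately
    after a component drop, whose iteration indices are in ``drop_iters``.
    """

    components: list[RegressionComponent]
    responsibilities: np.ndarray
    labels: np.ndarray
    log_likelihood: float
    bic: float
    n_params: int
    converged: bool
    seed: int
    n_iter: int
    ll_trace: np.ndarray = field(default_factory=lambda: np.empty(0))
    drop_iters: list[int] = field(default_factory=list)

    @property
    def k(self) -> int:
        return len(self.components)

    @property
    def intercepts(self) -> np.ndarray:
        return np.array([c.intercept for c in self.components])

    @property
    def slopes(self) -> np.ndarray:
        return np.array([c.slope for c in self.components])

    @property
    def weights(self) -> np.ndarray:
        return np.array([c.weight for c in self.components])


def bic(log_likelihood: float, n_params: int, n: int) -> float:
    """Bayesian Information Criterion, ``-2*logL + p*ln(n)``.

    For a K-component mixture of regressions the free-parameter count is
    ``3K + (K - 1)``: intercept, slope and residual SD per component plus
    K - 1 free mixing weights.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if n_params < 1:
        raise ValueError("n_params must be >= 1")
    return -2.0 * log_likelihood + n_params * math.log(n)


def mixture_n_params(k: int) -> int:
    """Free parameters of a K-component mixture of regressions."""
    return 3 * k + (k - 1)


def _weighted_ols(y: np.ndarray, x: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    """Weighted least squares of y on x; slope is 0 if x has no weighted
    variance (constant covariate within the component)."""
    sw = w.sum()
    if sw <= 0.0:
        return float(np.mean(y)), 0.0
    xm = (w @ x) / sw
    ym = (w @ y) / sw
    dx = x - xm
    sxx = w @ (dx * dx)
    if sxx <= 1e-12 * sw * max(1.0, xm * xm):
        return float(ym), 0.0
    slope = (w @ (dx * (y - ym))) / sxx
    return float(ym - slope * xm), float(slope)


def _m_step(
    y: np.ndarray, x: np.ndarray, resp: np.ndarray, sd_floor: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Weighted-least-squares update of every component from responsibilities."""
    n, k = resp.shape
    intercepts = np.empty(k)
    slopes = np.empty(k)
    sds = np.empty(k)
    col_sums = resp.sum(axis=0)
    weights = col_sums / n
    for j in range(k):
        w = resp[:, j]
        a, b = _weighted_ols(y, x, w)
        intercepts[j] = a
        slopes[j] = b
        res = y - (a + b * x)
        denom = col_sums[j]
        var = (w @ (res * res)) / denom if denom > 0 else 0.0
        sds[j] = max(math.sqrt(max(var, 0.0)), sd_floor)
    return intercepts, slopes, sds, weights


def _log_component_densities(
    y: np.ndarray,
    x: np.ndarray,
    intercepts: np.ndarray,
    slopes: np.ndarray,
    sds: np.ndarray,
    weights: np.ndarray,
) -> np.ndarray:
    """n x k matrix of log(w_k * Normal(y | a_k + b_k x, sd_k^2))."""
    mu = intercepts[None, :] + slopes[None, :] * x[:, None]
    z = (y[:, None] - mu) / sds[None, :]
    return (
        np.log(weights)[None, :]
        - np.log(sds)[None, :]
        - 0.5 * _LOG_2PI
        - 0.5 * z * z
    )


def _validate_xy(y: np.ndarray, x: np.ndarray, k: int) -> None:
    if k < 1 or k > 3:
        raise ValueError(f"k must be in 1..3, got {k}")
    if y.shape != x.shape or y.ndim != 1:
        raise ValueError("y and x must be 1-d arrays of equal length")
    if len(y) < 3 * k:
        raise ValueError(f"need at least {3 * k} samples for k={k}, got {len(y)}")
    if not (np.isfinite(y).all() and np.isfinite(x).all()):
        raise ValueError("y and x must be finite")
    if k > 1 and np.ptp(x) == 0.0:
        raise ValueError("covariate has zero variance; only k=1 is identifiable")


def fit_em(
    y,
    x,
    k: int,
    seed: int,
    max_iter: int = DEFAULT_MAX_ITER,
    tol: float = DEFAULT_TOL,
    min_weight: float = DEFAULT_MIN_WEIGHT,
    sd_floor: float = RESIDUAL_SD_FLOOR,
) -> MixtureFit:
    """Fit a k-component Gaussian mixture of linear regressions by EM.

    Initialization is a random hard partition of the samples into ``k``
    groups drawn from the seeded generator, followed by one M-step.  EM
    iterates E and M steps until the relative log-likelihood change falls
    below ``tol`` or ``max_iter`` is reached.  Components whose weight falls
    below ``min_weight`` are dropped (weights renormalized) and EM continues,
    so the returned K may be smaller than requested.

    Parameters
    ----------
    y, x : array-like
        Response (beta values) and covariate (``1 - purity``), equal length.
    k : int
        Requested component count, 1-3.  Requires ``len(y) >= 3*k``.
    seed : int
        Seed for the initial partition; fits are bit-reproducible.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    _validate_xy(y, x, k)
    n = len(y)

    rng = np.random.default_rng(seed)
    # Random hard partition: a permuted round-robin keeps every group
    # non-empty and roughly balanced.
    init_labels = rng.permutation(np.arange(n) % k)
    resp = np.zeros((n, k))
    resp[np.arange(n), init_labels] = 1.0

    intercepts, slopes, sds, weights = _m_step(y, x, resp, sd_floor)

    ll_trace: list[float] = []
    drop_iters: list[int] = []
    prev_ll = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        log_dens = _log_component_densities(y, x, intercepts, slopes, sds, weights)
        log_norm = _logsumexp_rows(log_dens)
        ll = float(log_norm.sum())
        ll_trace.append(ll)
        resp = np.exp(log_dens - log_norm[:, None])

        if np.isfinite(prev_ll) and abs(ll - prev_ll) <= tol * (abs(prev_ll) + 1e-12):
            converged = True
            break
        prev_ll = ll

        intercepts, slopes, sds, weights = _m_step(y, x, resp, sd_floor)

        if len(weights) > 1 and weights.min() < min_weight:
            keep = weights >= min_weight
            if not keep.any():  # pathological: keep the heaviest component
                keep = weights == weights.max()
            intercepts, slopes, sds = intercepts[keep], slopes[keep], sds[keep]
            weights = weights[keep] / weights[keep].sum()
            drop_iters.append(it)
            prev_ll = -np.inf  # likelihood may jump; restart convergence check

    # Final E-step so responsibilities/labels match the returned parameters.
    log_dens = _log_component_densities(y, x, intercepts, slopes, sds, weights)
    log_norm = _logsumexp_rows(log_dens)
    ll = float(log_norm.sum())
    resp = np.exp(log_dens - log_norm[:, None])

    k_final = len(weights)
    p = mixture_n_params(k_final)
    components = [
        RegressionComponent(float(a), float(b), float(s), float(w))
        for a, b, s, w in zip(intercepts, slopes, sds, weights)
    ]
    return MixtureFit(
        components=components,
        responsibilities=resp,
        labels=np.argmax(resp, axis=1) + 1,
        log_likelihood=ll,
        bic=bic(ll, p, n),
        n_params=p,
        converged=converged,
        seed=int(seed),
        n_iter=it,
        ll_trace=np.asarray(ll_trace),
        drop_iters=drop_iters,
    )


def derive_restart_seed(seed: int, k: int, rep: int) -> int:
    """Deterministic, collision-resistant sub-seed for restart ``rep`` of the
    K=``k`` fit, via numpy's splittable SeedSequence hashing."""
    ss = np.random.SeedSequence([int(seed), int(k), int(rep)])
    return int(ss.generate_state(1)[0] % (2**31))


def select_model(
    y,
    x,
    k_max: int = 3,
    nrep: int = 3,
    seed: int = 0,
    max_iter: int = DEFAULT_MAX_ITER,
    tol: float = DEFAULT_TOL,
    min_weight: float = DEFAULT_MIN_WEIGHT,
    bic_tie_tol: float = 1e-9,
) -> MixtureFit:
    """Fit mixtures for K = 1..k_max with ``nrep`` restarts each and return
    the best fit by BIC.

    For each K the restart with the highest log-likelihood is kept; across K
    the fit minimizing BIC wins, with ties (within ``bic_tie_tol``) broken
    toward smaller K.  K values that are infeasible for the data (too few
    samples, zero-variance covariate) are skipped rather than fatal; K=1 is
    always feasible given >= 3 samples.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if k_max < 1 or k_max > 3:
        raise ValueError("k_max must be in 1..3")
    _validate_xy(y, x, 1)

    best_per_k: list[MixtureFit] = []
    for k in range(1, k_max + 1):
        best_k: MixtureFit | None = None
        for rep in range(nrep):
            sub = derive_restart_seed(seed, k, rep)
            try:
                fit = fit_em(
                    y, x, k, sub,
                    max_iter=max_iter, tol=tol,
                    min_weight=min_weight,
                )
            except ValueError:
                break  # k infeasible for this data; larger k will be too
            if best_k is None or fit.log_likelihood > best_k.log_likelihood:
                best_k = fit
            if k == 1:
                break  # K=1 is deterministic OLS; restarts are identical
        if best_k is not None:
            best_per_k.append(best_k)

    if not best_per_k:
        raise ValueError("no feasible mixture fit for the given data")

    best = best_per_k[0]
    for fit in best_per_k[1:]:
        if fit.bic < best.bic - bic_tie_tol:
            best = fit
    return best
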