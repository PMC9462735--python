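"""Purity-aware detrending of beta values, per CpG and per matrix.

For each CpG, sample populations are discovered with a mixture of linear
regressions of beta on ``1 - purity`` (a small amount of Gaussian noise is
added to the betas for discovery only, to keep zero-variance populations
from destabilizing the mixture fit).  Each discovered population is then
detrended twice with ordinary least squares on the ORIGINAL betas:

* beta ~ 1 - purity: the intercept is the pure-tumor methylation state;
  adding each sample's residual to it gives the purified tumor beta.
* beta ~ purity: the intercept is the inferred normal (microenvironment)
  state; residuals re-added give the per-sample inferred normal beta.

Both regressions describe the same fitted line (a + b*(1-p) = (a+b) - b*p),
so the residuals are identical and, before clamping, normal - tumor equals
the slope of the tumor fit within each population.  Final values are
clamped to [0, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .mixture_model import MixtureFit, select_model

__all__ = [
    "CpGAdjustment",
    "derive_cpg_seed",
    "adjust_cpg",
    "adjust_matrix",
    "single_population_adjust",
    "population_state_matrix",
]

logger = logging.getLogger(__name__)

DEFAULT_NOISE_SD = 0.005
MIN_SAMPLES = 10
#: Populations smaller than this cannot support a line fit and are merged
#: into the population with the nearest intercept.
MIN_POP_SIZE = 3


@dataclass
class CpGAdjustment:
    """Per-CpG adjustment bundle.

    ``labels`` holds 1-based population indices (0 marks samples with a
    missing beta).  ``tumor_raw`` / ``normal_raw`` are the pre-clamp values;
    ``tumor_beta`` / ``normal_beta`` are clamped to [0, 1].  ``tumor_fits``
    are (intercept, slope) of beta on ``1 - purity`` per population;
    ``normal_fits`` the same line reparametrized against purity.
    """

    cpg_id: str | None
    k_selected: int
    labels: np.ndarray
    tumor_fits: list[tuple[float, float]]
    normal_fits: list[tuple[float, float]]
    tumor_beta: np.ndarray
    normal_beta: np.ndarray
    tumor_raw: np.ndarray
    normal_raw: np.ndarray
    seed: int
    fit: MixtureFit | None = None


def derive_cpg_seed(global_seed: int, cpg_index: int, cpg_id: str | None = None) -> int:
    """Deterministic per-CpG seed, independent of worker scheduling.

    Depends only on ``(global_seed, cpg_index)`` through numpy's splittable
    SeedSequence hashing; ``cpg_id`` is accepted for interface symmetry but
    does not enter the derivation, so renaming probes never changes results.
    """
    if global_seed < 0:
        raise ValueError("global_seed must be >= 0")
    ss = np.random.SeedSequence([int(global_seed), int(cpg_index)])
    return int(ss.generate_state(1)[0] % (2**31))


def _validate_purity(purity: np.ndarray) -> None:
    if not np.isfinite(purity).all():
        raise ValueError("purity values must be finite")
    if (purity <= 0).any() or (purity > 1).any():
        raise ValueError("purity values must lie in (0, 1]")


def _ols_line(y: np.ndarray, x: np.ndarray) -> tuple[float, float]:
    """Closed-form OLS of y on x; slope 0 if x is constant."""
    xm = x.mean()
    ym = y.mean()
    dx = x - xm
    sxx = dx @ dx
    if sxx <= 1e-12 * len(x) * max(1.0, xm * xm):
        return float(ym), 0.0
    slope = (dx @ (y - ym)) / sxx
    return float(ym - slope * xm), float(slope)


def _merge_tiny_populations(labels: np.ndarray, intercepts: np.ndarray) -> np.ndarray:
    """Merge populations with fewer than MIN_POP_SIZE members into the
    population with the nearest intercept; relabel to contiguous 1..K."""
    labels = labels.copy()
    while True:
        uniq, counts = np.unique(labels, return_counts=True)
        if len(uniq) <= 1 or counts.min() >= MIN_POP_SIZE:
            break
        tiny = uniq[np.argmin(counts)]
        others = uniq[uniq != tiny]
        target = others[np.argmin(np.abs(intercepts[others - 1] - intercepts[tiny - 1]))]
        labels[labels == tiny] = target
    # relabel contiguously, preserving order of first appearance of the
    # surviving original indices
    uniq = np.unique(labels)
    remap = {old: new for new, old in enumerate(uniq, start=1)}
    return np.array([remap[v] for v in labels], dtype=int)


def _detrend_populations(
    beta: np.ndarray, purity: np.ndarray, labels: np.ndarray
) -> tuple[list[tuple[float, float]], list[tuple[float, float]], np.ndarray, np.ndarray]:
    """Per-population dual OLS detrending on the original betas."""
    tumor_fits: list[tuple[float, float]] = []
    normal_fits: list[tuple[float, float]] = []
    tumor_raw = np.empty_like(beta)
    normal_raw = np.empty_like(beta)
    for pop in np.unique(labels):
        m = labels == pop
        yb, p = beta[m], purity[m]
        a_t, b_t = _ols_line(yb, 1.0 - p)
        a_n, b_n = _ols_line(yb, p)
        tumor_fits.append((a_t, b_t))
        normal_fits.append((a_n, b_n))
        tumor_raw[m] = a_t + (yb - (a_t + b_t * (1.0 - p)))
        normal_raw[m] = a_n + (yb - (a_n + b_n * p))
    return tumor_fits, normal_fits, tumor_raw, normal_raw


def adjust_cpg(
    beta,
    purity,
    seed: int,
    noise_sd: float = DEFAULT_NOISE_SD,
    k_max: int = 3,
    nrep: int = 3,
    cpg_id: str | None = None,
    **select_kwargs,
) -> CpGAdjustment:
    """Adjust one CpG's beta values for tumor purity.

    Population discovery runs on a noisy working copy of the betas (seeded
    N(0, noise_sd^2) perturbation); all regressions use the original betas.
    Samples with a missing beta are excluded from the fit and emitted as
    missing.  Populations with fewer than three members are merged into the
    nearest population by intercept before detrending.

    Parameters
    ----------
    beta : array-like
        Per-sample beta values in [0, 1] (NaN = missing).
    purity : array-like
        Per-sample tumor purity in (0, 1], aligned with ``beta``.
    seed : int
        Drives both the discovery noise and the EM restarts.
    """
    beta = np.asarray(beta, dtype=float)
    purity = np.asarray(purity, dtype=float)
    if beta.shape != purity.shape or beta.ndim != 1:
        raise ValueError("beta and purity must be 1-d arrays of equal length")
    _validate_purity(purity)
    obs = np.isfinite(beta)
    n_obs = int(obs.sum())
    if n_obs < MIN_SAMPLES:
        raise ValueError(f"need at least {MIN_SAMPLES} observed samples, got {n_obs}")
    b = beta[obs]
    if (b < 0).any() or (b > 1).any():
        raise ValueError("beta values must lie in [0, 1]")
    p = purity[obs]
    x = 1.0 - p

    rng = np.random.default_rng(seed)
    noisy = b + rng.normal(0.0, noise_sd, size=n_obs)

    fit = select_model(noisy, x, k_max=k_max, nrep=nrep, seed=seed, **select_kwargs)
    labels_obs = _merge_tiny_populations(fit.labels, fit.intercepts)

    tumor_fits, normal_fits, tumor_raw_o, normal_raw_o = _detrend_populations(
        b, p, labels_obs
    )

    labels = np.zeros(len(beta), dtype=int)
    labels[obs] = labels_obs
    tumor_raw = np.full(len(beta), np.nan)
    normal_raw = np.full(len(beta), np.nan)
    tumor_raw[obs] = tumor_raw_o
    normal_raw[obs] = normal_raw_o

    return CpGAdjustment(
        cpg_id=cpg_id,
        k_selected=len(tumor_fits),
        labels=labels,
        tumor_fits=tumor_fits,
        normal_fits=normal_fits,
        tumor_beta=np.clip(tumor_raw, 0.0, 1.0),
        normal_beta=np.clip(normal_raw, 0.0, 1.0),
        tumor_raw=tumor_raw,
        normal_raw=normal_raw,
        seed=int(seed),
        fit=fit,
    )


def single_population_adjust(beta, purity) -> tuple[np.ndarray, np.ndarray]:
    """Detrend all samples as one population (no mixture discovery).

    This is the single-population baseline: OLS of beta on ``1 - purity``
    (tumor) and on purity (normal), residuals re-added to the intercepts,
    clamped to [0, 1].  Equivalent to :func:`adjust_cpg` whenever model
    selection returns K = 1.  Returns ``(tumor, normal)`` vectors.
    """
    beta = np.asarray(beta, dtype=float)
    purity = np.asarray(purity, dtype=float)
    if beta.shape != purity.shape or beta.ndim != 1:
        raise ValueError("beta and purity must be 1-d arrays of equal length")
    _validate_purity(purity)
    obs = np.isfinite(beta)
    if int(obs.sum()) < MIN_SAMPLES:
        raise ValueError(f"need at least {MIN_SAMPLES} observed samples")
    b, p = beta[obs], purity[obs]
    if (b < 0).any() or (b > 1).any():
        raise ValueError("beta values must lie in [0, 1]")
    _, _, tumor_raw_o, normal_raw_o = _detrend_populations(
        b, p, np.ones(len(b), dtype=int)
    )
    tumor = np.full(len(beta), np.nan)
    normal = np.full(len(beta), np.nan)
    tumor[obs] = np.clip(tumor_raw_o, 0.0, 1.0)
    normal[obs] = np.clip(normal_raw_o, 0.0, 1.0)
    return tumor, normal


def _fits_to_str(fits: list[tuple[float, float]], idx: int) -> str:
    return ",".join(f"{f[idx]:.6g}" for f in fits)


def _adjust_row(
    row: np.ndarray,
    purity: np.ndarray,
    seed: int,
    cpg_id: str,
    noise_sd: float,
    k_max: int,
    nrep: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, dict]:
    try:
        adj = adjust_cpg(
            row, purity, seed=seed, noise_sd=noise_sd,
            k_max=k_max, nrep=nrep, cpg_id=cpg_id,
        )
    except Exception as exc:  # row-level failures never abort the matrix
        summary = {
            "cpg_id": cpg_id, "k_selected": 0, "converged": False,
            "bic": np.nan, "log_likelihood": np.nan,
            "tumor_intercepts": "", "tumor_slopes": "", "normal_intercepts": "",
            "pop_sizes": "", "seed": seed, "failed": True, "error": str(exc),
        }
        return row, row, np.zeros(len(row), dtype=int), summary
    sizes = [int((adj.labels == k).sum()) for k in range(1, adj.k_selected + 1)]
    summary = {
        "cpg_id": cpg_id,
        "k_selected": adj.k_selected,
        "converged": bool(adj.fit.converged),
        "bic": adj.fit.bic,
        "log_likelihood": adj.fit.log_likelihood,
        "tumor_intercepts": _fits_to_str(adj.tumor_fits, 0),
        "tumor_slopes": _fits_to_str(adj.tumor_fits, 1),
        "normal_intercepts": _fits_to_str(adj.normal_fits, 0),
        "pop_sizes": ",".join(str(s) for s in sizes),
        "seed": seed,
        "failed": False,
        "error": "",
    }
    return adj.tumor_beta, adj.normal_beta, adj.labels, summary


def adjust_matrix(
    betas: pd.DataFrame,
    purity: pd.Series,
    global_seed: int,
    n_workers: int = 1,
    noise_sd: float = DEFAULT_NOISE_SD,
    k_max: int = 3,
    nrep: int = 3,
    log_every: int = 1000,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Adjust every CpG (row) of a beta matrix for tumor purity.

    Each row gets a deterministic seed from :func:`derive_cpg_seed`, so the
    result is bit-identical for any ``n_workers``.  Rows that fail to fit
    are emitted unadjusted and flagged in the fit summary.

    Parameters
    ----------
    betas : DataFrame
        CpGs x samples beta matrix, values in [0, 1], NaN allowed.
    purity : Series
        Purity in (0, 1] indexed by sample id; must cover every sample.

    Returns
    -------
    (tumor, normal, populations, fit_summary)
        Two beta matrices with the input's index/columns, an integer
        population-label matrix (0 = missing), and a per-CpG summary table.
    """
    if betas.index.has_duplicates:
        raise ValueError("duplicate CpG ids in beta matrix")
    if betas.columns.has_duplicates:
        raise ValueError("duplicate sample ids in beta matrix")
    missing = [s for s in betas.columns if s not in purity.index]
    if missing:
        raise ValueError(f"samples missing from purity table: {missing}")
    pvec = purity.loc[betas.columns].to_numpy(dtype=float)
    _validate_purity(pvec)

    values = betas.to_numpy(dtype=float)
    n_cpgs = values.shape[0]
    seeds = [derive_cpg_seed(global_seed, i) for i in range(n_cpgs)]
    cpg_ids = [str(c) for c in betas.index]

    if n_workers <= 1:
        results = []
        for i in range(n_cpgs):
            results.append(
                _adjust_row(values[i], pvec, seeds[i], cpg_ids[i], noise_sd, k_max, nrep)
            )
            if log_every and (i + 1) % log_every == 0:
                logger.info("adjusted %d / %d CpGs", i + 1, n_cpgs)
    else:
        results = Parallel(n_jobs=n_workers, batch_size="auto")(
            delayed(_adjust_row)(
                values[i], pvec, seeds[i], cpg_ids[i], noise_sd, k_max, nrep
            )
            for i in range(n_cpgs)
        )

    tumor = np.vstack([r[0] for r in results])
    normal = np.vstack([r[1] for r in results])
    pops = np.vstack([r[2] for r in results])
    summary = pd.DataFrame([r[3] for r in results])

    k_counts = summary.loc[~summary["failed"], "k_selected"].value_counts().to_dict()
    n_failed = int(summary["failed"].sum())
    logger.info(
        "adjusted %d CpGs: K counts %s, %d failed", n_cpgs, k_counts, n_failed
    )

    tumor_df = pd.DataFrame(tumor, index=betas.index, columns=betas.columns)
    normal_df = pd.DataFrame(normal, index=betas.index, columns=betas.columns)
    pops_df = pd.DataFrame(pops, index=betas.index, columns=betas.columns)
    return tumor_df, normal_df, pops_df, summary


def population_state_matrix(
    populations: pd.DataFrame, fit_summary: pd.DataFrame, which: str = "tumor"
) -> pd.DataFrame:
    """Expand per-population intercepts into a per-sample state matrix.

    For every CpG and sample, returns the fitted pure-tumor
    (``which="tumor"``) or inferred-normal (``which="normal"``) intercept of
    the population the sample belongs to; NaN where the population label is
    0 (missing) or the CpG failed.  Useful for comparing recovered states
    with simulation ground truth.
    """
    col = {"tumor": "tumor_intercepts", "normal": "normal_intercepts"}[which]
    out = np.full(populations.shape, np.nan)
    labels = populations.to_numpy(dtype=int)
    for i, (_, row) in enumerate(fit_summary.iterrows()):
        if row["failed"] or not row[col]:
            continue
        intercepts = np.array([float(v) for v in str(row[col]).split(",")])
        lab = labels[i]
        ok = lab > 0
        out[i, ok] = intercepts[lab[ok] - 1]
    return pd.DataFrame(out, index=populations.index, columns=populations.columns)
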