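"""Synthetic cohorts with the mixing structure the correction assumes.

Each CpG carries K latent tumor methylation states (K in {1, 2, 3}) and one
shared normal (microenvironment) state.  A sample assigned to population k
with tumor purity p is observed as

    beta = p * tumor_state_k + (1 - p) * normal_state + noise,

with Gaussian measurement noise, clamped to [0, 1].  This is exactly the
two-compartment dilution geometry the per-CpG regression model inverts, so
generated cohorts serve as ground truth for parameter-recovery tests.  The
module also provides the purity-perturbation utilities used by the
robustness experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SyntheticCohort",
    "simulate_cohort",
    "perturb_purity",
    "noise_grid",
]

DEFAULT_STATE_LEVELS = (0.0, 0.5, 1.0)
DEFAULT_PURITY_RANGE = (0.2, 0.95)
#: Minimum separation between distinct tumor states of one CpG when K > 1;
#: closer states are not resolvable as separate regression lines.
MIN_STATE_SEPARATION = 0.2


@dataclass
class SyntheticCohort:
    """A generated cohort with full ground truth.

    ``true_tumor_states[i]`` is the array of per-population tumor states of
    CpG ``i``; ``true_labels[i, j]`` the 1-based population of sample ``j``
    at CpG ``i``.  ``subtype`` (optional) is a per-sample binary label that
    drives population assignment at subtype-linked CpGs.
    """

    observed: pd.DataFrame
    purity: pd.Series
    true_tumor_states: list[np.ndarray]
    true_normal_states: np.ndarray
    true_labels: np.ndarray
    generator_params: dict
    subtype: pd.Series | None = None
    subtype_linked: np.ndarray | None = None

    @property
    def n_samples(self) -> int:
        return self.observed.shape[1]

    @property
    def n_cpgs(self) -> int:
        return self.observed.shape[0]

    def true_tumor_matrix(self) -> np.ndarray:
        """Per-sample true tumor state (n_cpgs x n_samples)."""
        out = np.empty_like(self.true_labels, dtype=float)
        for i, states in enumerate(self.true_tumor_states):
            out[i] = states[self.true_labels[i] - 1]
        return out


def _draw_states(
    rng: np.random.Generator, k: int, levels: np.ndarray
) -> np.ndarray:
    """Draw k tumor states from the allowed levels, pairwise separated by at
    least MIN_STATE_SEPARATION when k > 1."""
    if k == 1:
        return rng.choice(levels, size=1)
    if len(levels) < k:
        raise ValueError(
            f"state_levels {levels.tolist()} cannot supply {k} states separated "
            f"by {MIN_STATE_SEPARATION}"
        )
    for _ in range(100):
        states = rng.choice(levels, size=k, replace=False)
        d = np.abs(states[:, None] - states[None, :])
        if d[np.triu_indices(k, 1)].min() >= MIN_STATE_SEPARATION:
            return states
    raise ValueError(
        f"state_levels {levels.tolist()} cannot supply {k} states separated "
        f"by {MIN_STATE_SEPARATION}"
    )


def simulate_cohort(
    n_samples: int,
    n_cpgs: int,
    k_probs: dict[int, float] | None = None,
    purity_range: tuple[float, float] = DEFAULT_PURITY_RANGE,
    noise_sd: float = 0.03,
    state_levels=DEFAULT_STATE_LEVELS,
    normal_levels=None,
    seed: int = 0,
    subtype_frac: float = 0.0,
    subtype_linked_frac: float = 0.0,
    subtype_flip_prob: float = 0.05,
) -> SyntheticCohort:
    """Generate a cohort of purity-diluted methylation profiles.

    Parameters
    ----------
    n_samples, n_cpgs : int
        Cohort dimensions (``n_samples >= 20``).
    k_probs : dict, optional
        Distribution over the per-CpG population count, e.g.
        ``{1: 0.5, 2: 0.5}``.  Default ``{1: 0.4, 2: 0.4, 3: 0.2}``.
    purity_range : (low, high)
        Per-sample purity drawn Uniform(low, high), within (0, 1].
    noise_sd : float
        SD of the Gaussian measurement noise on observed betas.
    state_levels, normal_levels : sequence of floats in [0, 1]
        Allowed tumor and normal methylation states; ``normal_levels``
        defaults to ``state_levels``.
    subtype_frac : float
        If > 0, assign this fraction of samples to a binary "subtype" and,
        at a ``subtype_linked_frac`` share of the multi-population CpGs, let
        population membership follow the subtype (flipped with probability
        ``subtype_flip_prob``).  Used for clustering benchmarks.
    """
    if n_samples < 20:
        raise ValueError("n_samples must be >= 20")
    if n_cpgs < 1:
        raise ValueError("n_cpgs must be >= 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if k_probs is None:
        k_probs = {1: 0.4, 2: 0.4, 3: 0.2}
    ks = np.array(sorted(k_probs), dtype=int)
    probs = np.array([k_probs[k] for k in ks], dtype=float)
    if (probs < 0).any() or abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError("k_probs must be non-negative and sum to 1")
    if not set(ks) <= {1, 2, 3}:
        raise ValueError("population counts must be in {1, 2, 3}")
    lo, hi = purity_range
    if not (0.0 < lo <= hi <= 1.0):
        raise ValueError("purity_range must satisfy 0 < low <= high <= 1")
    state_levels = np.asarray(state_levels, dtype=float)
    normal_levels = (
        state_levels if normal_levels is None
        else np.asarray(normal_levels, dtype=float)
    )

    rng = np.random.default_rng(seed)
    purity = rng.uniform(lo, hi, size=n_samples)

    subtype = None
    if subtype_frac > 0.0:
        subtype = (rng.random(n_samples) < subtype_frac).astype(int)

    cpg_ks = rng.choice(ks, size=n_cpgs, p=probs)
    subtype_linked = np.zeros(n_cpgs, dtype=bool)

    tumor_states: list[np.ndarray] = []
    normal_states = np.empty(n_cpgs)
    labels = np.empty((n_cpgs, n_samples), dtype=int)
    observed = np.empty((n_cpgs, n_samples))

    for i in range(n_cpgs):
        k = int(cpg_ks[i])
        states = _draw_states(rng, k, state_levels)
        normal = float(rng.choice(normal_levels))
        if k == 1:
            lab = np.ones(n_samples, dtype=int)
        elif (
            subtype is not None
            and k == 2
            and rng.random() < subtype_linked_frac
        ):
            subtype_linked[i] = True
            lab = subtype + 1
            flip = rng.random(n_samples) < subtype_flip_prob
            lab[flip] = 3 - lab[flip]
        else:
            lab = rng.integers(1, k + 1, size=n_samples)
        tumor = states[lab - 1]
        eps = rng.normal(0.0, noise_sd, size=n_samples) if noise_sd > 0 else 0.0
        row = purity * tumor + (1.0 - purity) * normal + eps
        observed[i] = np.clip(row, 0.0, 1.0)
        tumor_states.append(states)
        normal_states[i] = normal
        labels[i] = lab

    sample_ids = [f"S{j:04d}" for j in range(n_samples)]
    cpg_ids = [f"cg{i:08d}" for i in range(n_cpgs)]
    params = dict(
        n_samples=n_samples, n_cpgs=n_cpgs,
        k_probs={int(k): float(v) for k, v in k_probs.items()},
        purity_range=[float(lo), float(hi)], noise_sd=float(noise_sd),
        state_levels=state_levels.tolist(),
        normal_levels=normal_levels.tolist(), seed=int(seed),
        subtype_frac=float(subtype_frac),
        subtype_linked_frac=float(subtype_linked_frac),
        subtype_flip_prob=float(subtype_flip_prob),
    )
    return SyntheticCohort(
        observed=pd.DataFrame(observed, index=cpg_ids, columns=sample_ids),
        purity=pd.Series(purity, index=sample_ids, name="purity"),
        true_tumor_states=tumor_states,
        true_normal_states=normal_states,
        true_labels=labels,
        generator_params=params,
        subtype=(
            pd.Series(subtype, index=sample_ids, name="subtype")
            if subtype is not None else None
        ),
        subtype_linked=subtype_linked,
    )


def perturb_purity(purity: pd.Series, s: float, seed: int = 0) -> pd.Series:
    """Add seeded N(0, s^2) noise to each purity, clipped to [0.01, 1.0].

    With ``s = 0`` the input is returned unchanged.  The expected absolute
    shift before clipping is ``s * sqrt(2/pi)``.
    """
    if s < 0:
        raise ValueError("s must be >= 0")
    if s == 0:
        return purity.copy()
    rng = np.random.default_rng(seed)
    shifted = purity.to_numpy(dtype=float) + rng.normal(0.0, s, size=len(purity))
    return pd.Series(np.clip(shifted, 0.01, 1.0), index=purity.index,
                     name=purity.name)


def noise_grid(s_min: float, s_max: float, step: float) -> np.ndarray:
    """Inclusive arithmetic grid of perturbation SDs.

    ``noise_grid(0.01, 0.19, 0.02)`` gives the ten values 0.01, 0.03, ...,
    0.19 used by the cohort-level robustness sweep.
    """
    if step <= 0:
        raise ValueError("step must be > 0")
    if s_min > s_max:
        raise ValueError("s_min must be <= s_max")
    n = int(round((s_max - s_min) / step)) + 1
    grid = s_min + step * np.arange(n)
    return grid[grid <= s_max + 1e-12]
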