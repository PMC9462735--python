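"""Evaluation machinery for purity-corrected methylation matrices.

Covers the analyses used to judge a correction: agglomerative clustering of
samples (Pearson distance, Ward linkage) and how well its top-level split
captures a binary subtype; a beta-dichotomization baseline; per-sample
correlation of inferred normal profiles with a reference normal methylome;
trimodal (hypo / intermediate / hyper) binning of X-chromosome-style beta
distributions; and the purity-perturbation decay sweep that measures how
population calls, adjusted betas and inferred normals deteriorate as noise
is added to the purity estimates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import squareform

from .beta_adjust import adjust_matrix
from .synthetic_data import perturb_purity

__all__ = [
    "SplitMetrics",
    "hierarchical_split",
    "split_metrics",
    "dichotomize",
    "correlation_to_reference",
    "trimodal_bins",
    "bin_concordance",
    "matched_label_concordance",
    "perturbation_decay",
]

BIN_NAMES = ("hypo", "intermediate", "hyper")


@dataclass
class SplitMetrics:
    """Agreement between a two-way cluster split and a binary truth.

    The cluster-to-class mapping is the accuracy-maximizing one of the two
    possibilities, so ``accuracy >= 0.5`` by construction.  Sensitivity and
    specificity treat the designated positive class as "positive".
    """

    accuracy: float
    sensitivity: float
    specificity: float
    confusion: np.ndarray  # [[TP, FN], [FP, TN]]
    mapping: dict


def hierarchical_split(matrix: pd.DataFrame, n_clusters: int = 2) -> pd.Series:
    """Cluster samples (columns) by Pearson distance and Ward linkage.

    Distance between two samples is ``1 - r`` over their beta profiles; the
    Ward tree is cut into ``n_clusters`` groups.  Constant sample columns,
    for which Pearson correlation is undefined, are jittered by 1e-9 with a
    warning.  Returns per-sample integer labels in ``1..n_clusters``.
    """
    n_samples = matrix.shape[1]
    if n_clusters > n_samples:
        raise ValueError("n_clusters exceeds the number of samples")
    values = matrix.to_numpy(dtype=float).copy()
    const = np.nanstd(values, axis=0) == 0.0
    if const.any():
        warnings.warn(
            f"{int(const.sum())} constant sample column(s); "
            "jittering by 1e-9 for Pearson distance"
        )
        ramp = np.linspace(0.0, 1e-9, values.shape[0])
        values[:, const] += ramp[:, None]
    corr = np.corrcoef(values, rowvar=False)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    z = linkage(squareform(dist, checks=False), method="ward")
    labels = fcluster(z, t=n_clusters, criterion="maxclust")
    return pd.Series(labels, index=matrix.columns, name="cluster")


def split_metrics(
    cluster_labels: pd.Series,
    truth_labels: pd.Series,
    positive_class=None,
) -> SplitMetrics:
    """Score a two-cluster split against binary truth labels.

    Both cluster-to-class mappings are evaluated and the one maximizing
    accuracy is reported.  ``positive_class`` names the truth value treated
    as positive for sensitivity/specificity (default: the lexically larger
    of the two truth values).
    """
    cl = cluster_labels.loc[truth_labels.index].to_numpy()
    tr = truth_labels.to_numpy()
    clusters = np.unique(cl)
    classes = np.unique(tr)
    if len(clusters) != 2 or len(classes) != 2:
        raise ValueError("split_metrics requires exactly two clusters and two classes")
    if positive_class is None:
        positive_class = classes[-1]
    elif positive_class not in classes:
        raise ValueError(f"positive_class {positive_class!r} not among {classes}")
    negative_class = classes[classes != positive_class][0]

    best = None
    for pos_cluster, neg_cluster in (clusters, clusters[::-1]):
        pred_pos = cl == pos_cluster
        is_pos = tr == positive_class
        tp = int(np.sum(pred_pos & is_pos))
        fn = int(np.sum(~pred_pos & is_pos))
        fp = int(np.sum(pred_pos & ~is_pos))
        tn = int(np.sum(~pred_pos & ~is_pos))
        acc = (tp + tn) / len(cl)
        if best is None or acc > best.accuracy:
            best = SplitMetrics(
                accuracy=acc,
                sensitivity=tp / (tp + fn) if tp + fn else np.nan,
                specificity=tn / (tn + fp) if tn + fp else np.nan,
                confusion=np.array([[tp, fn], [fp, tn]]),
                mapping={
                    int(pos_cluster): positive_class,
                    int(neg_cluster): negative_class,
                },
            )
    return best


def dichotomize(matrix: pd.DataFrame, threshold: float = 0.3) -> pd.DataFrame:
    """Binary methylation calls: 1 where beta is strictly above the
    threshold, 0 otherwise; NaN propagates."""
    values = matrix.to_numpy(dtype=float)
    out = np.where(values > threshold, 1.0, 0.0)
    out[np.isnan(values)] = np.nan
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def correlation_to_reference(
    inferred_normal: pd.DataFrame, reference_mean: pd.Series
) -> tuple[pd.Series, dict]:
    """Per-sample Pearson correlation with a reference normal methylome.

    ``reference_mean`` is the per-CpG average methylation of reference
    normal samples, aligned with the inferred matrix's CpGs.  Returns the
    per-sample r values plus a summary with the cohort median and the
    mean-profile-vs-reference r.
    """
    if len(reference_mean) < 3:
        raise ValueError("need at least 3 CpGs")
    if not inferred_normal.index.equals(reference_mean.index):
        if set(inferred_normal.index) != set(reference_mean.index):
            raise ValueError("CpG sets of inferred matrix and reference differ")
        reference_mean = reference_mean.loc[inferred_normal.index]
    ref = reference_mean.to_numpy(dtype=float)
    vals = inferred_normal.to_numpy(dtype=float)
    rs = np.array([_pearson(vals[:, j], ref) for j in range(vals.shape[1])])
    per_sample = pd.Series(rs, index=inferred_normal.columns, name="r")
    summary = {
        "median_r": float(np.nanmedian(rs)),
        "mean_vs_mean_r": _pearson(np.nanmean(vals, axis=1), ref),
    }
    return per_sample, summary


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    m = np.isfinite(a) & np.isfinite(b)
    a, b = a[m], b[m]
    if len(a) < 3 or a.std() == 0.0 or b.std() == 0.0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def trimodal_bins(
    values, cut_low: float = 0.25, cut_high: float = 0.75
) -> tuple[np.ndarray, dict]:
    """Bin beta values into hypo / intermediate / hyper categories.

    Models the trimodal methylation pattern expected at X-chromosome
    promoters in females (peaks near 0, 0.5 and 1 from X-inactivation).
    Returns the per-value labels and the fraction in each bin.
    """
    if not (0.0 < cut_low < cut_high < 1.0):
        raise ValueError("cuts must satisfy 0 < cut_low < cut_high < 1")
    v = np.asarray(values, dtype=float)
    labels = np.where(v <= cut_low, BIN_NAMES[0],
                      np.where(v < cut_high, BIN_NAMES[1], BIN_NAMES[2]))
    fractions = {name: float(np.mean(labels == name)) for name in BIN_NAMES}
    return labels, fractions


def bin_concordance(labels_a, labels_b) -> float:
    """Fraction of positions assigned the same bin in two labelings."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape:
        raise ValueError("labelings must have equal length")
    return float(np.mean(a == b))


def matched_label_concordance(labels_a: np.ndarray, labels_b: np.ndarray) -> float:
    """Agreement of two partition labelings after optimal label matching.

    Population indices are arbitrary, so labels are matched with the
    Hungarian algorithm on the contingency table before computing the
    fraction of samples assigned concordantly.  Entries labeled 0 (missing)
    in either input are ignored.
    """
    a = np.asarray(labels_a, dtype=int)
    b = np.asarray(labels_b, dtype=int)
    keep = (a > 0) & (b > 0)
    a, b = a[keep], b[keep]
    if len(a) == 0:
        return np.nan
    ua = np.unique(a)
    ub = np.unique(b)
    cont = np.zeros((len(ua), len(ub)))
    for i, va in enumerate(ua):
        for j, vb in enumerate(ub):
            cont[i, j] = np.sum((a == va) & (b == vb))
    ri, ci = linear_sum_assignment(-cont)
    return float(cont[ri, ci].sum() / len(a))


def perturbation_decay(
    betas: pd.DataFrame,
    purity: pd.Series,
    grid,
    n_reps: int,
    global_seed: int,
    reference_mean: pd.Series | None = None,
    **adjust_kwargs,
) -> pd.DataFrame:
    """Measure how adjustment outputs decay as purity noise grows.

    For each noise level ``s`` in ``grid`` and each replicate: the purity
    vector is perturbed with N(0, s^2), the matrix is re-adjusted with the
    same global seed, and the run is summarized by

    * ``pop_concordance`` — mean per-CpG population-call agreement with the
      unperturbed run, after Hungarian label matching;
    * ``sample_correlation`` — median per-sample Pearson r between the
      perturbed and unperturbed purified-tumor matrices;
    * ``normal_correlation`` — median per-sample r of the perturbed
      inferred normals against ``reference_mean`` (a reference normal
      methylome) when one is supplied, otherwise against the unperturbed
      run's inferred normal for the same sample;
    * ``mean_beta_shift`` — mean |purified tumor - input beta|.

    Returns a tidy table with the median and empirical 95% interval of each
    metric across replicates at each ``s``.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("grid must be non-empty")
    base_tumor, base_normal, base_pops, _ = adjust_matrix(
        betas, purity, global_seed, **adjust_kwargs
    )

    input_vals = betas.to_numpy(dtype=float)
    base_tv = base_tumor.to_numpy(dtype=float)
    base_nv = base_normal.to_numpy(dtype=float)
    base_pv = base_pops.to_numpy(dtype=int)

    records = []
    for si, s in enumerate(grid):
        per_rep = {m: [] for m in (
            "pop_concordance", "sample_correlation",
            "normal_correlation", "mean_beta_shift",
        )}
        for rep in range(n_reps):
            pseed = int(
                np.random.SeedSequence([int(global_seed), si, rep]).generate_state(1)[0]
                % (2**31)
            )
            pp = perturb_purity(purity, float(s), seed=pseed)
            tumor, normal, pops, _ = adjust_matrix(
                betas, pp, global_seed, **adjust_kwargs
            )
            tv = tumor.to_numpy(dtype=float)
            pv = pops.to_numpy(dtype=int)
            conc = np.array([
                matched_label_concordance(base_pv[i], pv[i])
                for i in range(pv.shape[0])
            ])
            per_rep["pop_concordance"].append(float(np.nanmean(conc)))
            rs = np.array([
                _pearson(tv[:, j], base_tv[:, j]) for j in range(tv.shape[1])
            ])
            per_rep["sample_correlation"].append(float(np.nanmedian(rs)))
            nv = normal.to_numpy(dtype=float)
            if reference_mean is not None:
                nr, _ = correlation_to_reference(normal, reference_mean)
                per_rep["normal_correlation"].append(float(nr.median()))
            else:
                nrs = np.array([
                    _pearson(nv[:, j], base_nv[:, j]) for j in range(nv.shape[1])
                ])
                per_rep["normal_correlation"].append(float(np.nanmedian(nrs)))
            per_rep["mean_beta_shift"].append(
                float(np.nanmean(np.abs(tv - input_vals)))
            )
        for metric, vals in per_rep.items():
            v = np.asarray(vals, dtype=float)
            records.append({
                "s": float(s),
                "metric": metric,
                "median": float(np.nanmedian(v)),
                "lo95": float(np.nanpercentile(v, 2.5)),
                "hi95": float(np.nanpercentile(v, 97.5)),
                "n_reps": n_reps,
            })
    return pd.DataFrame(records)
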