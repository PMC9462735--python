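"""Reading and writing the tab-separated formats used by the pipeline.

Beta matrices are TSV with a header row of sample ids and CpG ids in the
first column; values are decimals in [0, 1] with ``NA`` for missing.  The
purity table is two columns (sample id, purity).  All readers are
gzip-transparent (pandas infers compression from the ``.gz`` suffix).
Outputs are written at 6 decimal places so write-read round-trips are
well defined.
"""

from __future__ import annotations

import json
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "read_beta_matrix",
    "write_beta_matrix",
    "read_purity",
    "write_purity",
    "read_labels",
    "write_outputs",
]

OUTPUT_FLOAT_FORMAT = "%.6f"


def _package_version() -> str:
    try:
        return version("purebeta")
    except PackageNotFoundError:
        return "unknown"


def read_beta_matrix(path) -> pd.DataFrame:
    """Read a CpGs x samples beta matrix from TSV (optionally gzipped).

    Validates that CpG and sample identifiers are unique and that all
    non-missing values lie in [0, 1]; errors name the offending row or
    column.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate CpG ids in {path}: {dups[:5]}")
    if df.columns.has_duplicates:
        dups = df.columns[df.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample ids in {path}: {dups[:5]}")
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ValueError(f"non-numeric beta value in {path}: {exc}") from exc
    values = df.to_numpy()
    bad = (values < 0) | (values > 1)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"beta value out of [0, 1] at CpG {df.index[i]!r}, "
            f"sample {df.columns[j]!r}: {values[i, j]}"
        )
    return df


def write_beta_matrix(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", float_format=OUTPUT_FLOAT_FORMAT, na_rep="NA")


def read_purity(path) -> pd.Series:
    """Read a two-column (sample id, purity) TSV into a Series.

    Purities must lie in (0, 1]: a purity of zero means no tumor signal to
    recover and is rejected.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    if df.shape[1] < 1:
        raise ValueError(f"purity table {path} needs a value column")
    s = df.iloc[:, 0].astype(float)
    if s.index.has_duplicates:
        dups = s.index[s.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample ids in {path}: {dups[:5]}")
    bad = s[(~np.isfinite(s)) | (s <= 0) | (s > 1)]
    if len(bad):
        raise ValueError(
            f"purity values outside (0, 1] in {path} for samples: "
            f"{bad.index.tolist()[:5]}"
        )
    s.name = "purity"
    return s


def write_purity(purity: pd.Series, path) -> None:
    purity.rename("purity").to_csv(path, sep="\t", float_format=OUTPUT_FLOAT_FORMAT,
                                   index_label="sample_id")


def read_labels(path) -> pd.Series:
    """Read a two-column (sample id, label) TSV of binary sample labels."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] < 1:
        raise ValueError(f"label table {path} needs a value column")
    s = df.iloc[:, 0]
    s.name = "label"
    return s


def check_sample_coverage(betas: pd.DataFrame, purity: pd.Series) -> None:
    """Every sample in the beta matrix must have a purity; fatal otherwise."""
    missing = [s for s in betas.columns if s not in purity.index]
    if missing:
        raise ValueError(
            f"{len(missing)} sample(s) in the beta matrix lack a purity "
            f"estimate: {missing}"
        )


def write_outputs(
    out_dir,
    tumor: pd.DataFrame,
    normal: pd.DataFrame,
    populations: pd.DataFrame,
    fit_summary: pd.DataFrame,
    config: dict,
) -> dict:
    """Write adjustment outputs plus a provenance manifest to a directory.

    Files: ``tumor_beta.tsv``, ``normal_beta.tsv``, ``populations.tsv``,
    ``fit_summary.tsv`` and ``manifest.json`` (config, seeds and package
    version — enough to re-run byte-identically).  Returns the path map.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "tumor": out_dir / "tumor_beta.tsv",
        "normal": out_dir / "normal_beta.tsv",
        "populations": out_dir / "populations.tsv",
        "fit_summary": out_dir / "fit_summary.tsv",
        "manifest": out_dir / "manifest.json",
    }
    write_beta_matrix(tumor, paths["tumor"])
    write_beta_matrix(normal, paths["normal"])
    populations.to_csv(paths["populations"], sep="\t")
    fit_summary.to_csv(paths["fit_summary"], sep="\t", index=False)
    manifest = {
        "purebeta_version": _package_version(),
        "config": config,
        "n_cpgs": int(tumor.shape[0]),
        "n_samples": int(tumor.shape[1]),
    }
    with open(paths["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return {k: str(v) for k, v in paths.items()}
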