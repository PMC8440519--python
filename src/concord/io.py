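"""Plain-text I/O: TSV measure tables, NIfTI volumes, JSON summaries."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .containers import COVARIATE_COLUMNS, MeasureMatrix, validate_covariates
from .contrast import ChangeCategory, ChangeSummary

__all__ = [
    "read_measures_tsv",
    "write_measures_tsv",
    "read_timeseries_tsv",
    "write_timeseries_tsv",
    "load_volume",
    "save_volume",
    "summary_to_json",
]


def write_measures_tsv(
    path: str | Path, measures: MeasureMatrix, covariates: pd.DataFrame
) -> None:
    """One TSV: subject_id, covariate columns, then feature columns."""
    combined = covariates[list(COVARIATE_COLUMNS)].join(measures.values)
    combined.index.name = "subject_id"
    combined.to_csv(path, sep="\t")


def read_measures_tsv(
    path: str | Path, feature_kind: str = "fnc_edge"
) -> tuple[MeasureMatrix, pd.DataFrame]:
    """Split a combined TSV back into measures and covariates."""
    df = pd.read_csv(path, sep="\t", index_col="subject_id")
    cov = validate_covariates(df[list(COVARIATE_COLUMNS)])
    features = [c for c in df.columns if c not in COVARIATE_COLUMNS]
    return MeasureMatrix(values=df[features], feature_kind=feature_kind), cov


def write_timeseries_tsv(path: str | Path, series: np.ndarray) -> None:
    pd.DataFrame(series).to_csv(path, sep="\t", header=False, index=False)


def read_timeseries_tsv(path: str | Path) -> np.ndarray:
    return pd.read_csv(path, sep="\t", header=None).to_numpy(float)


def load_volume(path: str | Path) -> np.ndarray:
    return np.asanyarray(nib.load(str(path)).dataobj, dtype=float)


def save_volume(path: str | Path, volume: np.ndarray, zooms=(3.0, 3.0, 3.0)) -> None:
    affine = np.diag([*zooms, 1.0])
    nib.save(nib.Nifti1Image(np.asarray(volume, np.float32), affine), str(path))


def summary_to_json(summary: ChangeSummary) -> str:
    payload = {
        "total_passing": summary.total_passing,
        "counts": {c.value: n for c, n in summary.counts.items() if c is not ChangeCategory.NONE},
        "percentages": {c.value: p for c, p in summary.percentages.items()},
        "asd_weaker_counts": {c.value: n for c, n in summary.weaker_counts.items()},
        "asd_weaker_percentages": {c.value: p for c, p in summary.weaker_percentages.items()},
    }
    return json.dumps(payload, indent=2)
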