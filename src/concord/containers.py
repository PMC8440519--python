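"""Shared in-memory containers for the pipeline.

Measures travel as a :class:`MeasureMatrix` (subjects x features wrapped
around a DataFrame) and subject annotations as a plain covariate DataFrame
with the columns listed in :data:`COVARIATE_COLUMNS`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MEASURE_KINDS = ("network_voxel_z", "fnc_edge", "fc_edge", "gm_voxel")

#: required covariate columns; site is nested within dataset
COVARIATE_COLUMNS = (
    "group",
    "dataset",
    "site",
    "age",
    "gender",
    "motion_trans_mm",
    "motion_rot_deg",
)


@dataclass
class MeasureMatrix:
    """Subjects x features matrix of one neuroimaging measure family.

    ``values`` is indexed by subject id with unique feature columns;
    ``feature_kind`` is one of :data:`MEASURE_KINDS`.
    """

    values: pd.DataFrame
    feature_kind: str = "fnc_edge"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.feature_kind not in MEASURE_KINDS:
            raise ValueError(f"unknown feature_kind {self.feature_kind!r}")
        if self.values.columns.has_duplicates:
            raise ValueError("feature ids must be unique")
        arr = self.values.to_numpy(float)
        if arr.size and not np.all(np.isfinite(arr)):
            raise ValueError("measure values must be finite")

    @property
    def subjects(self) -> pd.Index:
        return self.values.index

    @property
    def features(self) -> pd.Index:
        return self.values.columns

    def aligned(self, covariates: pd.DataFrame) -> pd.DataFrame:
        """Covariate rows reindexed to this matrix's subjects (strict)."""
        missing = self.subjects.difference(covariates.index)
        if len(missing):
            raise KeyError(f"covariates missing for subjects: {list(missing)[:5]}")
        return covariates.loc[self.subjects]


def validate_covariates(cov: pd.DataFrame) -> pd.DataFrame:
    """Check the covariate table schema; returns the table unchanged."""
    for col in COVARIATE_COLUMNS:
        if col not in cov.columns:
            raise ValueError(f"covariate table missing column {col!r}")
    if cov.index.has_duplicates:
        raise ValueError("duplicate subject ids in covariate table")
    # site nested within dataset: one dataset per site id
    nested = cov.groupby("site")["dataset"].nunique()
    if (nested > 1).any():
        raise ValueError("site ids must be nested within datasets")
    return cov
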