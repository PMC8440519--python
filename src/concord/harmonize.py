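"""Three-step covariate and dataset-effect removal for multi-site measures.

Step 1 regresses, within each dataset, every feature on age, gender, site,
age x site and gender x site (OLS; residuals keep the dataset mean so that
between-dataset structure survives to step 2).  Step 2 estimates a
per-dataset "data effect" from healthy controls only: the dataset's HC mean
of the step-1 output minus the grand HC mean.  Step 3 subtracts that offset
from every subject of the dataset, patients included, so patient-vs-control
contrasts are corrected by an estimate that cannot absorb diagnosis effects.

Numerical notes: age is z-scored within dataset before forming interaction
terms (collinearity), gender is coded {0,1}, site enters as treatment-coded
dummies, and rank-deficient designs drop aliased columns greedily in
declaration order (singleton sites therefore contribute no dummies).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .containers import MeasureMatrix

__all__ = [
    "regress_within_dataset",
    "estimate_dataset_effects",
    "remove_dataset_effects",
    "harmonize",
]


def _design_matrix(cov: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Per-dataset design: intercept, age_z, gender, site dummies, interactions."""
    age = cov["age"].to_numpy(float)
    sd = age.std()
    age_z = (age - age.mean()) / sd if sd > 0 else np.zeros_like(age)
    gender = cov["gender"].to_numpy(float)
    cols: list[np.ndarray] = [np.ones(len(cov)), age_z, gender]
    names = ["intercept", "age", "gender"]
    sites = sorted(cov["site"].unique())
    for s in sites[1:]:  # first site is the reference level
        dummy = (cov["site"] == s).to_numpy(float)
        cols.append(dummy)
        names.append(f"site[{s}]")
        cols.append(age_z * dummy)
        names.append(f"age:site[{s}]")
        cols.append(gender * dummy)
        names.append(f"gender:site[{s}]")
    X = np.column_stack(cols)
    # greedy rank filter in declaration order
    keep: list[int] = []
    dropped: list[str] = []
    rank = 0
    for j in range(X.shape[1]):
        cand = X[:, keep + [j]]
        r = np.linalg.matrix_rank(cand)
        if r > rank:
            keep.append(j)
            rank = r
        else:
            dropped.append(names[j])
    if dropped:
        warnings.warn(f"dropping aliased design columns: {dropped}", stacklevel=3)
    return X[:, keep], [names[j] for j in keep]


def regress_within_dataset(
    measures: MeasureMatrix, covariates: pd.DataFrame
) -> MeasureMatrix:
    """Step 1: within-dataset OLS residualization of nuisance covariates.

    Residuals are returned with the dataset mean added back, so dataset-level
    offsets remain estimable in step 2.
    """
    cov = measures.aligned(covariates)
    values = measures.values.to_numpy(float).copy()
    for _, idx in cov.groupby("dataset").groups.items():
        rows = measures.values.index.get_indexer(idx)
        sub_cov = cov.loc[idx]
        if len(sub_cov) < 2:
            raise ValueError("need at least 2 subjects per dataset")
        X, _names = _design_matrix(sub_cov)
        Y = values[rows]
        beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
        resid = Y - X @ beta
        values[rows] = resid + Y.mean(axis=0)
    return MeasureMatrix(
        values=pd.DataFrame(values, index=measures.subjects, columns=measures.features),
        feature_kind=measures.feature_kind,
        meta={**measures.meta, "harmonized": "step1"},
    )


def estimate_dataset_effects(
    measures: MeasureMatrix, covariates: pd.DataFrame
) -> pd.DataFrame:
    """Step 2: per-dataset offsets from healthy controls.

    offset(dataset, feature) = mean over the dataset's HC subjects of the
    step-1 values, minus the grand HC mean (unweighted mean of the
    per-dataset HC means, so offsets sum to zero across datasets).
    """
    cov = measures.aligned(covariates)
    hc = cov["group"] == "HC"
    if not hc.any():
        raise ValueError("no healthy controls in cohort")
    ds_means = {}
    for ds, idx in cov.groupby("dataset").groups.items():
        sel = idx[cov.loc[idx, "group"] == "HC"]
        if len(sel) == 0:
            raise ValueError(f"dataset {ds} has no healthy controls")
        ds_means[ds] = measures.values.loc[sel].mean(axis=0)
    means = pd.DataFrame(ds_means).T  # datasets x features
    grand = means.mean(axis=0)
    return means - grand


def remove_dataset_effects(
    measures: MeasureMatrix, covariates: pd.DataFrame, offsets: pd.DataFrame
) -> MeasureMatrix:
    """Step 3: subtract each subject's dataset offset from every feature.

    Patients and controls alike are corrected by the HC-derived offset of
    their dataset, so within-dataset group differences are untouched.
    """
    cov = measures.aligned(covariates)
    unknown = set(cov["dataset"]) - set(offsets.index)
    if unknown:
        raise KeyError(f"no offsets for datasets: {sorted(unknown)}")
    shift = offsets.loc[cov["dataset"]].to_numpy(float)
    values = measures.values.to_numpy(float) - shift
    return MeasureMatrix(
        values=pd.DataFrame(values, index=measures.subjects, columns=measures.features),
        feature_kind=measures.feature_kind,
        meta={**measures.meta, "harmonized": "full"},
    )


def harmonize(measures: MeasureMatrix, covariates: pd.DataFrame) -> MeasureMatrix:
    """Run the full three-step procedure."""
    step1 = regress_within_dataset(measures, covariates)
    offsets = estimate_dataset_effects(step1, covariates)
    return remove_dataset_effects(step1, covariates, offsets)
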