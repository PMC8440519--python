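"""Clinical association: symptom correlations and medication tests.

Symptom severity (PANSS positive/negative for SZ; ADOS total and SRS for
ASD) is related to each neuroimaging measure by both Pearson and Spearman
correlation within the patient group, pairwise-complete over missing
entries; a finding is reported only when *both* correlations reach p < 0.01.
Antipsychotic exposure in SZ is tested by regressing each measure on the
chlorpromazine-equivalent dose (Bonferroni at 0.05/m); medication status in
ASD is tested by two-sample t-tests between medicated and unmedicated
patients (same correction).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .containers import MeasureMatrix
from .contrast import pooled_ttest

__all__ = ["symptom_correlations", "cpz_regression", "medication_group_test"]

DUAL_ALPHA = 0.01


def symptom_correlations(
    measures: MeasureMatrix,
    symptoms: pd.DataFrame,
    covariates: pd.DataFrame,
    group: str,
    alpha: float = DUAL_ALPHA,
) -> pd.DataFrame:
    """Pearson and Spearman correlations of each measure with each score.

    ``symptoms`` holds one column per score, indexed by subject id; rows are
    matched to the ``group`` patients.  Missing entries are dropped pairwise
    per (measure, score) pair.  ``significant`` requires p < ``alpha`` in
    both correlation types.
    """
    cov = measures.aligned(covariates)
    patients = cov.index[cov["group"] == group]
    patients = patients.intersection(symptoms.index)
    rows = []
    for score in symptoms.columns:
        if symptoms[score].dtype == object:
            continue
        s_all = symptoms.loc[patients, score]
        for feat in measures.features:
            m_all = measures.values.loc[patients, feat]
            ok = s_all.notna() & m_all.notna()
            if ok.sum() < 3:
                raise ValueError(f"fewer than 3 complete pairs for {feat}/{score}")
            s, m = s_all[ok], m_all[ok]
            if s.nunique() == 1 or m.nunique() == 1:
                raise ValueError(f"constant vector for {feat}/{score}")
            r, p_r = stats.pearsonr(m, s)
            rho, p_rho = stats.spearmanr(m, s)
            rows.append(
                {
                    "feature": feat,
                    "score": score,
                    "n": int(ok.sum()),
                    "pearson_r": r,
                    "pearson_p": p_r,
                    "spearman_rho": rho,
                    "spearman_p": p_rho,
                    "significant": (p_r < alpha) and (p_rho < alpha),
                }
            )
    return pd.DataFrame(rows)


def cpz_regression(
    measures: MeasureMatrix,
    cpz: pd.Series,
    covariates: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-measure linear regression on chlorpromazine-equivalent dose.

    One OLS fit per measure with CPZ as the sole predictor (nuisance
    covariates are removed upstream by harmonization); Bonferroni threshold
    ``alpha / n_measures``.
    """
    cov = measures.aligned(covariates)
    sz = cov.index[cov["group"] == "SZ"].intersection(cpz.dropna().index)
    if len(sz) < 3:
        raise ValueError("need at least 3 SZ patients with CPZ data")
    x = cpz.loc[sz].to_numpy(float)
    if np.all(x == x[0]):
        raise ValueError("CPZ doses are all identical")
    m = len(measures.features)
    rows = []
    for feat in measures.features:
        y = measures.values.loc[sz, feat].to_numpy(float)
        fit = stats.linregress(x, y)
        rows.append(
            {
                "feature": feat,
                "slope": fit.slope,
                "p": fit.pvalue,
                "flag": fit.pvalue < alpha / m,
            }
        )
    return pd.DataFrame(rows)


def medication_group_test(
    measures: MeasureMatrix,
    medicated: pd.Series,
    covariates: pd.DataFrame,
    group: str = "ASD",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Two-sample t-tests between medicated and unmedicated patients.

    ``medicated`` is a boolean series over patient subject ids; Bonferroni
    correction at ``alpha / n_measures``.
    """
    cov = measures.aligned(covariates)
    patients = cov.index[cov["group"] == group].intersection(medicated.dropna().index)
    flags = medicated.loc[patients].astype(bool)
    on, off = patients[flags], patients[~flags]
    if len(on) < 2 or len(off) < 2:
        raise ValueError("both medication groups must have >=2 subjects")
    t, p, _ = pooled_ttest(
        measures.values.loc[on].to_numpy(float),
        measures.values.loc[off].to_numpy(float),
    )
    m = len(measures.features)
    return pd.DataFrame(
        {
            "feature": list(measures.features),
            "t": t,
            "p": p,
            "flag": p < alpha / m,
        }
    )
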