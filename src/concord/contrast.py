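"""Three-group contrast engine: gates, ANOVA, pairwise t-tests, change categorization.

The scientific core of the package.  Every neuroimaging measure family
(network-voxel Z-scores, FNC edges, ROI-FC edges, gray-matter voxels) is run
through the same procedure:

1. an optional positivity gate (right-tailed one-sample t-test, Bonferroni)
   restricting network-voxel analyses to voxels with reliably positive
   intra-network connectivity;
2. a one-way fixed-effects ANOVA across the HC, SZ and ASD groups, with a
   per-family alpha and multiple-comparison correction;
3. two-tailed pooled-variance two-sample t-tests for each group pair, with
   the sign convention that a positive T means the *first* group is larger
   (so T(HC-SZ) > 0 reads "controls higher than schizophrenia patients");
4. a four-way categorization of each ANOVA-passing feature from the signs of
   T(HC-SZ) and T(HC-ASD):

   =============  =============  =====================
   T(HC-SZ)       T(HC-ASD)      category
   =============  =============  =====================
   > 0            > 0            common decrease
   < 0            < 0            common increase
   > 0            < 0            SZ-unique decrease
   < 0            > 0            ASD-unique decrease
   any exact 0    --             none
   =============  =============  =====================

5. within the two common categories, an "ASD-weaker" flag from the sign of
   T(SZ-ASD): a common decrease is weaker in ASD when T(SZ-ASD) < 0 (SZ sits
   further below ASD), a common increase when T(SZ-ASD) > 0.

Counts and percentages of the categories among ANOVA-passing features are
summarized per family, percentages reported to one decimal.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ChangeCategory",
    "WeakerFlag",
    "ContrastResult",
    "ChangeSummary",
    "GROUP_PAIRS",
    "positivity_gate",
    "omnibus_anova",
    "pooled_ttest",
    "pairwise_ttests",
    "correct_multiple",
    "categorize_changes",
    "asd_weaker_flags",
    "summarize_table1",
    "run_group_contrast",
]

GROUPS = ("HC", "SZ", "ASD")
GROUP_PAIRS = (("HC", "SZ"), ("HC", "ASD"), ("SZ", "ASD"))


class ChangeCategory(enum.Enum):
    """Four-way typing of a group difference, plus NONE for untyped features."""

    COMMON_DECREASE = "common_decrease"
    COMMON_INCREASE = "common_increase"
    SZ_UNIQUE_DECREASE = "sz_unique_decrease"
    ASD_UNIQUE_DECREASE = "asd_unique_decrease"
    NONE = "none"

    @property
    def is_common(self) -> bool:
        return self in (ChangeCategory.COMMON_DECREASE, ChangeCategory.COMMON_INCREASE)

    @property
    def is_unique(self) -> bool:
        return self in (
            ChangeCategory.SZ_UNIQUE_DECREASE,
            ChangeCategory.ASD_UNIQUE_DECREASE,
        )


class WeakerFlag(enum.Enum):
    """Whether ASD deviates less from HC than SZ does, within a common change."""

    ASD_WEAKER = "asd_weaker"
    NOT_WEAKER = "not_weaker"
    NOT_APPLICABLE = "n/a"


@dataclass
class ContrastResult:
    """Per-feature statistics from the three-group contrast.

    ``table`` columns: feature, anova_F, anova_p, anova_pass,
    t_hc_sz, p_hc_sz, t_hc_asd, p_hc_asd, t_sz_asd, p_sz_asd,
    sig_hc_sz, sig_hc_asd, sig_sz_asd (corrected pairwise flags),
    category, weaker.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        for pcol in ("anova_p", "p_hc_sz", "p_hc_asd", "p_sz_asd"):
            if pcol in self.table and len(self.table):
                p = self.table[pcol].to_numpy(float)
                if np.nanmin(p) < 0 or np.nanmax(p) > 1:
                    raise ValueError(f"{pcol} outside [0, 1]")

    @property
    def features(self) -> pd.Index:
        return pd.Index(self.table["feature"])

    def passing(self) -> pd.DataFrame:
        return self.table[self.table["anova_pass"]]


@dataclass
class ChangeSummary:
    """Category counts and one-decimal percentages among ANOVA-passing features."""

    total_passing: int
    counts: dict[ChangeCategory, int]
    weaker_counts: dict[ChangeCategory, int]
    percentages: dict[ChangeCategory, float] = field(default_factory=dict)
    weaker_percentages: dict[ChangeCategory, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cat in ChangeCategory:
            if cat is ChangeCategory.NONE:
                continue
            row = {
                "category": cat.value,
                "count": self.counts.get(cat, 0),
                "percent": self.percentages.get(cat, 0.0),
            }
            if cat.is_common:
                row["asd_weaker_count"] = self.weaker_counts.get(cat, 0)
                row["asd_weaker_percent"] = self.weaker_percentages.get(cat, 0.0)
            rows.append(row)
        frame = pd.DataFrame(rows)
        frame.attrs["total_passing"] = self.total_passing
        return frame


def _round1(x: float) -> float:
    # round-half-up at one decimal, matching how percentages are printed
    return math.floor(x * 10 + 0.5) / 10


def positivity_gate(
    zmaps: np.ndarray, alpha: float = 0.01, n_tests: int | None = None
) -> np.ndarray:
    """Select voxels with reliably positive Z-scores across subjects.

    Right-tailed one-sample t-test per voxel with Bonferroni correction:
    a voxel is retained iff ``p * n_tests < alpha``.  Zero-variance voxels
    are retained iff their common value is positive.

    Parameters
    ----------
    zmaps : (n_subjects, n_voxels) array
    alpha : corrected significance level (default 0.01)
    n_tests : Bonferroni multiplicity; defaults to the number of voxels

    Returns
    -------
    boolean array of length n_voxels
    """
    zmaps = np.asarray(zmaps, float)
    if zmaps.ndim != 2 or zmaps.shape[0] < 2:
        raise ValueError("need a (subjects, voxels) matrix with >=2 subjects")
    m = n_tests if n_tests is not None else zmaps.shape[1]
    mean = zmaps.mean(axis=0)
    sd = zmaps.std(axis=0, ddof=1)
    degenerate = sd == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(zmaps.shape[0]))
    p = stats.t.sf(t, df=zmaps.shape[0] - 1)
    p[degenerate] = np.where(mean[degenerate] > 0, 0.0, 1.0)
    return p * m < alpha


def omnibus_anova(
    values: np.ndarray | pd.DataFrame,
    groups: np.ndarray | pd.Series,
    alpha: float = 0.05,
    correction: str | None = None,
) -> pd.DataFrame:
    """One-way fixed-effects ANOVA per feature on three groups.

    Parameters
    ----------
    values : (n_subjects, n_features)
    groups : length n_subjects labels drawn from {HC, SZ, ASD}
    alpha : significance level for the pass flag
    correction : None (uncorrected), "BFN" or "FDR"

    Returns
    -------
    DataFrame with columns F, p, passed (one row per feature).
    """
    X = np.asarray(values, float)
    g = np.asarray(groups)
    known = [lab for lab in GROUPS if np.any(g == lab)]
    present = known if len(known) >= 2 else list(pd.unique(g))
    if len(present) < 2:
        raise ValueError("ANOVA needs at least two nonempty groups")
    samples = []
    for lab in present:
        sub = X[g == lab]
        if sub.shape[0] < 2:
            raise ValueError(f"group {lab} has fewer than 2 subjects")
        samples.append(sub)
    F, p = stats.f_oneway(*samples, axis=0)
    F = np.atleast_1d(F)
    p = np.atleast_1d(np.nan_to_num(p, nan=1.0))
    passed = correct_multiple(p, method=correction, alpha=alpha)
    cols = {"F": F, "p": p, "passed": passed}
    index = values.columns if isinstance(values, pd.DataFrame) else None
    return pd.DataFrame(cols, index=index)


def pooled_ttest(
    a: np.ndarray, b: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized two-tailed pooled-variance (Student) two-sample t-test.

    Operates column-wise on (n, m) matrices; returns (t, p, degenerate) where
    degenerate marks zero-pooled-variance features reported as t=0, p=1.
    """
    a = np.atleast_2d(np.asarray(a, float))
    b = np.atleast_2d(np.asarray(b, float))
    na, nb = a.shape[0], b.shape[0]
    if na < 2 or nb < 2:
        raise ValueError("both samples need >=2 observations")
    va = a.var(axis=0, ddof=1)
    vb = b.var(axis=0, ddof=1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    degenerate = sp2 == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (a.mean(axis=0) - b.mean(axis=0)) / np.sqrt(sp2 * (1 / na + 1 / nb))
    df = na + nb - 2
    p = 2 * stats.t.sf(np.abs(t), df=df)
    t = np.where(degenerate, 0.0, t)
    p = np.where(degenerate, 1.0, p)
    return t, p, degenerate


def pairwise_ttests(
    values: np.ndarray | pd.DataFrame, groups: np.ndarray | pd.Series
) -> pd.DataFrame:
    """Two-sample t-tests for HC-SZ, HC-ASD and SZ-ASD, per feature.

    Positive T means the first group of the pair has the larger mean.
    Pairs with a missing group yield NaN columns.
    """
    X = np.asarray(values, float)
    g = np.asarray(groups)
    n_feat = X.shape[1]
    out: dict[str, np.ndarray] = {}
    for first, second in GROUP_PAIRS:
        key = f"{first.lower()}_{second.lower()}"
        a, b = X[g == first], X[g == second]
        if a.shape[0] < 2 or b.shape[0] < 2:
            out[f"t_{key}"] = np.full(n_feat, np.nan)
            out[f"p_{key}"] = np.full(n_feat, np.nan)
            continue
        t, p, _ = pooled_ttest(a, b)
        out[f"t_{key}"] = t
        out[f"p_{key}"] = p
    index = values.columns if isinstance(values, pd.DataFrame) else None
    return pd.DataFrame(out, index=index)


def correct_multiple(
    pvals: np.ndarray, method: str | None, alpha: float
) -> np.ndarray:
    """Multiple-comparison flags: Bonferroni (``p*m < alpha``), BH-FDR, or raw.

    ``method`` is "BFN", "FDR" or None (plain ``p < alpha``).
    """
    p = np.asarray(pvals, float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values outside [0, 1]")
    if method is None:
        return p < alpha
    method = method.upper()
    if method in ("BFN", "BONFERRONI"):
        return p * p.size < alpha
    if method in ("FDR", "FDR_BH", "BH"):
        return multipletests(p, alpha=alpha, method="fdr_bh")[0]
    raise ValueError(f"unknown correction {method!r}")


def categorize_changes(
    t_hc_sz: np.ndarray, t_hc_asd: np.ndarray, anova_pass: np.ndarray
) -> list[ChangeCategory]:
    """Assign each feature a change category from the two patient-vs-HC T signs.

    Only ANOVA-passing features are typed; any exact zero T maps to NONE
    (the category definitions use strict inequalities).
    """
    t1 = np.asarray(t_hc_sz, float)
    t2 = np.asarray(t_hc_asd, float)
    ok = np.asarray(anova_pass, bool)
    cats: list[ChangeCategory] = []
    for passing, a, b in zip(ok, t1, t2):
        if not passing or np.isnan(a) or np.isnan(b) or a == 0 or b == 0:
            cats.append(ChangeCategory.NONE)
        elif a > 0 and b > 0:
            cats.append(ChangeCategory.COMMON_DECREASE)
        elif a < 0 and b < 0:
            cats.append(ChangeCategory.COMMON_INCREASE)
        elif a > 0 and b < 0:
            cats.append(ChangeCategory.SZ_UNIQUE_DECREASE)
        else:  # a < 0 and b > 0
            cats.append(ChangeCategory.ASD_UNIQUE_DECREASE)
    return cats


def asd_weaker_flags(
    t_sz_asd: np.ndarray, categories: list[ChangeCategory]
) -> list[WeakerFlag]:
    """Flag common changes where ASD deviates less from controls than SZ.

    Common decrease: ASD weaker iff T(SZ-ASD) < 0 (SZ fell further).
    Common increase: ASD weaker iff T(SZ-ASD) > 0 (SZ rose further).
    Strict inequalities; T = 0 is NOT_WEAKER.  Non-common categories get N/A.
    """
    t3 = np.asarray(t_sz_asd, float)
    flags: list[WeakerFlag] = []
    for t, cat in zip(t3, categories):
        if cat is ChangeCategory.COMMON_DECREASE:
            flags.append(WeakerFlag.ASD_WEAKER if t < 0 else WeakerFlag.NOT_WEAKER)
        elif cat is ChangeCategory.COMMON_INCREASE:
            flags.append(WeakerFlag.ASD_WEAKER if t > 0 else WeakerFlag.NOT_WEAKER)
        else:
            flags.append(WeakerFlag.NOT_APPLICABLE)
    return flags


def summarize_table1(
    categories: list[ChangeCategory] | dict[ChangeCategory, int],
    weaker: list[WeakerFlag] | dict[ChangeCategory, int] | None = None,
    total_passing: int | None = None,
    anova_pass: np.ndarray | None = None,
) -> ChangeSummary:
    """Summarize category counts into percentages of ANOVA-passing features.

    Accepts either per-feature category/weaker lists, or pre-tabulated counts
    (``{category: count}`` plus ``{common category: weaker count}``) with an
    explicit ``total_passing``.  With list input, ``anova_pass`` restricts the
    tally to gate-passing features; without it every listed feature is assumed
    to have passed.  Each category percentage is ``100 * count / total_passing``;
    each weaker percentage is relative to its common-category count.
    Percentages are rounded half-up to one decimal.
    """
    if isinstance(categories, dict):
        if total_passing is None:
            raise ValueError("total_passing required with pre-tabulated counts")
        counts = {c: int(categories.get(c, 0)) for c in ChangeCategory}
        weaker = weaker or {}
        weaker_counts = {
            ChangeCategory.COMMON_DECREASE: int(
                weaker.get(ChangeCategory.COMMON_DECREASE, 0)
            ),
            ChangeCategory.COMMON_INCREASE: int(
                weaker.get(ChangeCategory.COMMON_INCREASE, 0)
            ),
        }
    else:
        if weaker is None:
            weaker = [WeakerFlag.NOT_APPLICABLE] * len(categories)
        if anova_pass is not None:
            mask = np.asarray(anova_pass, bool)
            categories = [c for c, ok in zip(categories, mask) if ok]
            weaker = [w for w, ok in zip(weaker, mask) if ok]
        counts = {c: 0 for c in ChangeCategory}
        weaker_counts = {
            ChangeCategory.COMMON_DECREASE: 0,
            ChangeCategory.COMMON_INCREASE: 0,
        }
        for cat, wk in zip(categories, weaker):
            counts[cat] += 1
            if cat.is_common and wk is WeakerFlag.ASD_WEAKER:
                weaker_counts[cat] += 1
        if total_passing is None:
            total_passing = len(categories)
    if total_passing <= 0:
        raise ValueError("no ANOVA-passing features to summarize")
    percentages = {
        c: _round1(100.0 * counts[c] / total_passing)
        for c in ChangeCategory
        if c is not ChangeCategory.NONE
    }
    weaker_percentages = {}
    for c in (ChangeCategory.COMMON_DECREASE, ChangeCategory.COMMON_INCREASE):
        denom = counts[c]
        weaker_percentages[c] = _round1(100.0 * weaker_counts[c] / denom) if denom else 0.0
    return ChangeSummary(
        total_passing=int(total_passing),
        counts=counts,
        weaker_counts=weaker_counts,
        percentages=percentages,
        weaker_percentages=weaker_percentages,
    )


# Per-family gate settings: (anova alpha, anova correction, pairwise alpha,
# pairwise correction).  Gray matter defaults to FDR at 0.05.
FAMILY_ALPHAS = {
    "network_voxel_z": (0.05, None, 0.05, "FDR"),
    "fnc_edge": (0.01, "BFN", 0.01, "BFN"),
    "fc_edge": (0.01, "BFN", 0.01, "BFN"),
    "gm_voxel": (0.05, None, 0.05, "FDR"),
}


def run_group_contrast(
    values: pd.DataFrame,
    groups: pd.Series | np.ndarray,
    family: str = "fnc_edge",
    anova_alpha: float | None = None,
    anova_correction: str | None = "unset",
    pairwise_alpha: float | None = None,
    pairwise_correction: str | None = "unset",
) -> ContrastResult:
    """Run the full contrast procedure for one measure family.

    ``family`` selects the default alpha/correction per measure kind
    (see ``FAMILY_ALPHAS``); individual settings can be overridden.
    """
    if family not in FAMILY_ALPHAS:
        raise ValueError(f"unknown measure family {family!r}")
    a_alpha, a_corr, p_alpha, p_corr = FAMILY_ALPHAS[family]
    if anova_alpha is not None:
        a_alpha = anova_alpha
    if anova_correction != "unset":
        a_corr = anova_correction
    if pairwise_alpha is not None:
        p_alpha = pairwise_alpha
    if pairwise_correction != "unset":
        p_corr = pairwise_correction

    anova = omnibus_anova(values, groups, alpha=a_alpha, correction=a_corr)
    pw = pairwise_ttests(values, groups)
    cats = categorize_changes(
        pw["t_hc_sz"].to_numpy(),
        pw["t_hc_asd"].to_numpy(),
        anova["passed"].to_numpy(),
    )
    weaker = asd_weaker_flags(pw["t_sz_asd"].to_numpy(), cats)
    table = pd.DataFrame(
        {
            "feature": list(values.columns),
            "anova_F": anova["F"].to_numpy(),
            "anova_p": anova["p"].to_numpy(),
            "anova_pass": anova["passed"].to_numpy(),
        }
    )
    for key in ("hc_sz", "hc_asd", "sz_asd"):
        table[f"t_{key}"] = pw[f"t_{key}"].to_numpy()
        table[f"p_{key}"] = pw[f"p_{key}"].to_numpy()
        pv = pw[f"p_{key}"].to_numpy()
        if np.all(np.isnan(pv)):
            table[f"sig_{key}"] = False
        else:
            table[f"sig_{key}"] = correct_multiple(
                np.nan_to_num(pv, nan=1.0), method=p_corr, alpha=p_alpha
            )
    table["category"] = [c.value for c in cats]
    table["weaker"] = [w.value for w in weaker]
    return ContrastResult(table=table)
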