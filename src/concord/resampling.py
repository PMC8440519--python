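"""Permutation-null validation and Fisher's-method meta-analysis.

The permutation test follows the label-rearrangement scheme exactly: in
each permutation all subjects of the two groups are redistributed into two
dummy groups of the original sizes, the two-sample t-test is recomputed, and
the empirical p-value of a feature is the frequency with which the permuted
p falls strictly below the observed p.  No +1 smoothing is applied to the
numerator or denominator, so an empirical p of exactly 0 is possible at
finite permutation counts.  An exhaustive mode enumerates every distinct
split for small groups.

Fisher's method combines per-dataset p-values for one contrast into
X^2 = -2 * sum(ln p), referred to a chi-square distribution with 2k degrees
of freedom; the mean per-dataset T is reported alongside for features
passing Bonferroni correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from .contrast import correct_multiple, pooled_ttest

__all__ = ["PermutationResult", "MetaResult", "permutation_test", "fisher_combine"]


@dataclass
class PermutationResult:
    """Empirical p-values per feature and the corrected flags."""

    p_empirical: np.ndarray
    n_permutations: int
    flags: np.ndarray
    t_observed: np.ndarray
    p_observed: np.ndarray
    seed: int | None = None
    exhaustive: bool = False

    def to_frame(self, features=None) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t_obs": self.t_observed,
                "p_obs": self.p_observed,
                "p_empirical": self.p_empirical,
                "flag": self.flags,
            },
            index=features,
        )


@dataclass
class MetaResult:
    """Fisher-combined statistics per feature across datasets."""

    chi2: np.ndarray
    p_combined: np.ndarray
    flags: np.ndarray
    mean_t: np.ndarray
    df: int

    def to_frame(self, features=None) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chi2": self.chi2,
                "p_combined": self.p_combined,
                "flag": self.flags,
                "mean_t": np.where(self.flags, self.mean_t, np.nan),
            },
            index=features,
        )


def permutation_test(
    values: np.ndarray,
    labels: np.ndarray,
    group_a: str,
    group_b: str,
    n_perm: int = 1000,
    seed: int | None = None,
    exhaustive: bool = False,
    alpha: float = 0.01,
    correction: str | None = "BFN",
) -> PermutationResult:
    """Label-permutation test of a two-group difference, per feature.

    Parameters
    ----------
    values : (n_subjects, n_features)
    labels : group label per subject; only ``group_a``/``group_b`` rows used
    n_perm : number of random rearrangements (ignored in exhaustive mode)
    exhaustive : enumerate every distinct split (small groups only)
    alpha, correction : flagging of the empirical p-values (Bonferroni at
        the FNC alpha by default)
    """
    X = np.atleast_2d(np.asarray(values, float))
    g = np.asarray(labels)
    sel = (g == group_a) | (g == group_b)
    X = X[sel]
    g = g[sel]
    na = int((g == group_a).sum())
    nb = int((g == group_b).sum())
    if na == 0 or nb == 0:
        raise ValueError("both groups must be nonempty")
    if min(na, nb) < 2:
        raise ValueError("groups too small for a t-test")
    order = np.concatenate([np.where(g == group_a)[0], np.where(g == group_b)[0]])
    X = X[order]  # first na rows = group A
    t_obs, p_obs, _ = pooled_ttest(X[:na], X[na:])

    n_total = na + nb
    if exhaustive:
        splits = combinations(range(n_total), na)
        n_used = comb(n_total, na)
        counts = np.zeros(X.shape[1])
        for split in splits:
            idx_a = np.array(split)
            mask = np.zeros(n_total, bool)
            mask[idx_a] = True
            _, p_perm, _ = pooled_ttest(X[mask], X[~mask])
            counts += p_perm < p_obs
    else:
        if n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        rng = np.random.default_rng(seed)
        n_used = n_perm
        counts = np.zeros(X.shape[1])
        for _ in range(n_perm):
            perm = rng.permutation(n_total)
            _, p_perm, _ = pooled_ttest(X[perm[:na]], X[perm[na:]])
            counts += p_perm < p_obs
    p_emp = counts / n_used
    flags = correct_multiple(p_emp, method=correction, alpha=alpha)
    return PermutationResult(
        p_empirical=p_emp,
        n_permutations=n_used,
        flags=flags,
        t_observed=t_obs,
        p_observed=p_obs,
        seed=seed,
        exhaustive=exhaustive,
    )


def fisher_combine(
    pvals: np.ndarray,
    tvals: np.ndarray | None = None,
    alpha: float = 0.01,
    correction: str | None = "BFN",
) -> MetaResult:
    """Combine per-dataset p-values with Fisher's method, per feature.

    Parameters
    ----------
    pvals : (k_datasets, n_features) array of two-sided p-values in (0, 1];
        zeros are clipped to the smallest positive float with a warning
    tvals : optional matching T-values; their per-feature mean is reported
    """
    P = np.atleast_2d(np.asarray(pvals, float))
    if np.any((P < 0) | (P > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if np.any(P == 0):
        import warnings

        warnings.warn("p=0 input clipped to the smallest positive float", stacklevel=2)
        P = np.clip(P, np.finfo(float).tiny, 1.0)
    k = P.shape[0]
    chi2 = -2.0 * np.log(P).sum(axis=0)
    df = 2 * k
    p_comb = stats.chi2.sf(chi2, df=df)
    flags = correct_multiple(p_comb, method=correction, alpha=alpha)
    if tvals is None:
        mean_t = np.full(P.shape[1], np.nan)
    else:
        T = np.atleast_2d(np.asarray(tvals, float))
        if T.shape != P.shape:
            raise ValueError("tvals must match pvals in shape")
        mean_t = T.mean(axis=0)
    return MetaResult(chi2=chi2, p_combined=p_comb, flags=flags, mean_t=mean_t, df=df)
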