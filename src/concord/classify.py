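"""Cross-dataset SZ-vs-ASD classification from categorization-selected features.

The feature-selection rule is the point: the full group-contrast engine is
run on the *training* datasets only (their HC subjects are used solely for
categorization), and the classifier receives the union of the FNC edges with
disorder-unique changes and the ASD-weaker edges within the disorder-common
changes.  A linear support vector machine is trained on the SZ and ASD
patients of the training datasets, with its regularization parameter C tuned
by Bayesian optimization (Gaussian-process surrogate, expected-improvement
acquisition) over a log-spaced range via internal cross-validation.

With four SZ-recruiting and two ASD-recruiting datasets, every assignment of
two SZ datasets plus one ASD dataset to training (the rest to testing)
yields 6 x 2 = 12 experiments.  Metrics use ASD as the positive class, so
sensitivity is the fraction of ASD patients recognized and specificity the
fraction of SZ patients recognized.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import Matern
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.svm import SVC

from .containers import MeasureMatrix
from .contrast import ChangeCategory, WeakerFlag, run_group_contrast

__all__ = [
    "SplitPlan",
    "SplitResult",
    "enumerate_split_plans",
    "select_features",
    "tune_svm_c",
    "train_and_evaluate",
    "confusion_metrics",
    "summarize_splits",
]


@dataclass(frozen=True)
class SplitPlan:
    """One train/test assignment of whole datasets."""

    train_sz: tuple[str, ...]
    train_asd: tuple[str, ...]
    test_sz: tuple[str, ...]
    test_asd: tuple[str, ...]

    @property
    def train_datasets(self) -> tuple[str, ...]:
        return self.train_sz + self.train_asd

    @property
    def test_datasets(self) -> tuple[str, ...]:
        return self.test_sz + self.test_asd


@dataclass
class SplitResult:
    """Metrics (percent) and selected features for one split."""

    plan: SplitPlan
    accuracy: float
    sensitivity: float
    specificity: float
    features: list[str] = field(default_factory=list)
    best_c: float = np.nan


def enumerate_split_plans(
    sz_datasets: list[str], asd_datasets: list[str], n_train_sz: int = 2, n_train_asd: int = 1
) -> list[SplitPlan]:
    """All train/test dataset assignments; 12 plans for 4 SZ x 2 ASD datasets."""
    plans = []
    for train_sz in combinations(sz_datasets, n_train_sz):
        test_sz = tuple(d for d in sz_datasets if d not in train_sz)
        for train_asd in combinations(asd_datasets, n_train_asd):
            test_asd = tuple(d for d in asd_datasets if d not in train_asd)
            plans.append(SplitPlan(train_sz, train_asd, test_sz, test_asd))
    return plans


def select_features(
    measures: MeasureMatrix,
    covariates: pd.DataFrame,
    train_datasets: tuple[str, ...],
    family: str = "fnc_edge",
    **contrast_kwargs,
) -> list[str]:
    """Categorization-driven feature selection on training datasets only.

    Runs the three-group contrast engine on the training subjects (HC
    included, for categorization only) and returns the union of features
    with disorder-unique changes and ASD-weaker disorder-common changes.
    """
    cov = measures.aligned(covariates)
    in_train = cov["dataset"].isin(train_datasets).to_numpy()
    values = measures.values.loc[in_train]
    groups = cov.loc[in_train, "group"]
    result = run_group_contrast(values, groups, family=family, **contrast_kwargs)
    tab = result.table
    unique = tab["category"].isin(
        [ChangeCategory.SZ_UNIQUE_DECREASE.value, ChangeCategory.ASD_UNIQUE_DECREASE.value]
    )
    weaker_common = tab["weaker"] == WeakerFlag.ASD_WEAKER.value
    selected = tab.loc[unique | weaker_common, "feature"].tolist()
    if not selected:
        raise ValueError(
            "no features selected; consider lowering the ANOVA gate for this cohort"
        )
    return selected


def _expected_improvement(
    gp: GaussianProcessRegressor, candidates: np.ndarray, best: float, xi: float = 0.01
) -> np.ndarray:
    mu, sd = gp.predict(candidates, return_std=True)
    sd = np.maximum(sd, 1e-9)
    z = (mu - best - xi) / sd
    return (mu - best - xi) * stats.norm.cdf(z) + sd * stats.norm.pdf(z)


def tune_svm_c(
    X: np.ndarray,
    y: np.ndarray,
    log10_range: tuple[float, float] = (-3.0, 3.0),
    n_iter: int = 20,
    n_init: int = 5,
    cv: int = 5,
    seed: int = 0,
) -> float:
    """Bayesian optimization of the linear-SVM C over a log-spaced range.

    A Gaussian-process surrogate over log10(C) is fitted to cross-validated
    accuracies; candidates are proposed by expected improvement.  Returns
    the best C found.
    """
    rng = np.random.default_rng(seed)
    lo, hi = log10_range
    cv_splitter = StratifiedKFold(n_splits=cv, shuffle=True, random_state=seed)

    def objective(log_c: float) -> float:
        model = SVC(kernel="linear", C=10.0**log_c)
        return float(cross_val_score(model, X, y, cv=cv_splitter).mean())

    xs = list(rng.uniform(lo, hi, n_init))
    ys = [objective(x) for x in xs]
    gp = GaussianProcessRegressor(
        kernel=Matern(nu=2.5, length_scale=1.0, length_scale_bounds=(0.1, 100.0)),
        alpha=1e-4,
        normalize_y=True,
        random_state=seed,
    )
    candidates = np.linspace(lo, hi, 200).reshape(-1, 1)
    for _ in range(n_iter - n_init):
        with warnings.catch_warnings():
            # a flat CV-accuracy surface drives the length scale to its bound
            warnings.simplefilter("ignore")
            gp.fit(np.array(xs).reshape(-1, 1), np.array(ys))
        ei = _expected_improvement(gp, candidates, max(ys))
        xs.append(float(candidates[int(np.argmax(ei)), 0]))
        ys.append(objective(xs[-1]))
    return float(10.0 ** xs[int(np.argmax(ys))])


def confusion_metrics(
    y_true: np.ndarray, y_pred: np.ndarray, positive: str = "ASD", negative: str = "SZ"
) -> tuple[float, float, float]:
    """(accuracy, sensitivity, specificity) in percent, one decimal.

    Sensitivity is the recall of the positive (ASD) class, specificity the
    recall of the negative (SZ) class.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    tp = int(np.sum((y_true == positive) & (y_pred == positive)))
    fn = int(np.sum((y_true == positive) & (y_pred != positive)))
    tn = int(np.sum((y_true == negative) & (y_pred == negative)))
    fp = int(np.sum((y_true == negative) & (y_pred != negative)))
    acc = 100.0 * (tp + tn) / max(tp + tn + fp + fn, 1)
    sens = 100.0 * tp / max(tp + fn, 1)
    spec = 100.0 * tn / max(tn + fp, 1)
    return round(acc, 1), round(sens, 1), round(spec, 1)


def train_and_evaluate(
    measures: MeasureMatrix,
    covariates: pd.DataFrame,
    plan: SplitPlan,
    features: list[str] | None = None,
    tune: bool = True,
    seed: int = 0,
    positive: str = "ASD",
    **contrast_kwargs,
) -> SplitResult:
    """Run one split: select features, tune, train, evaluate on held-out datasets.

    Feature selection (when ``features`` is None) and C-tuning see only the
    training datasets.  Train-set means/SDs standardize both sets.
    """
    if features is None:
        features = select_features(
            measures, covariates, plan.train_datasets, **contrast_kwargs
        )
    cov = measures.aligned(covariates)
    patient = cov["group"].isin(["SZ", "ASD"])
    in_train = cov["dataset"].isin(plan.train_datasets) & patient
    in_test = cov["dataset"].isin(plan.test_datasets) & patient
    X_train = measures.values.loc[in_train.to_numpy(), features].to_numpy(float)
    y_train = cov.loc[in_train, "group"].to_numpy()
    X_test = measures.values.loc[in_test.to_numpy(), features].to_numpy(float)
    y_test = cov.loc[in_test, "group"].to_numpy()
    if len(set(y_train)) < 2 or len(set(y_test)) < 2:
        raise ValueError("train and test sets must both contain SZ and ASD")
    mu, sd = X_train.mean(axis=0), X_train.std(axis=0)
    sd[sd == 0] = 1.0
    X_train = (X_train - mu) / sd
    X_test = (X_test - mu) / sd
    c = tune_svm_c(X_train, y_train, seed=seed) if tune else 1.0
    model = SVC(kernel="linear", C=c)
    model.fit(X_train, y_train)
    acc, sens, spec = confusion_metrics(
        y_test, model.predict(X_test), positive=positive
    )
    return SplitResult(
        plan=plan,
        accuracy=acc,
        sensitivity=sens,
        specificity=spec,
        features=list(features),
        best_c=c,
    )


def summarize_splits(
    results: list[SplitResult] | pd.DataFrame,
) -> dict[str, float]:
    """Cross-split means (rounded to integer percent) and the best accuracy."""
    if isinstance(results, pd.DataFrame):
        acc = results["accuracy"].to_numpy(float)
        sens = results["sensitivity"].to_numpy(float)
        spec = results["specificity"].to_numpy(float)
    else:
        if not results:
            raise ValueError("no split results")
        acc = np.array([r.accuracy for r in results])
        sens = np.array([r.sensitivity for r in results])
        spec = np.array([r.specificity for r in results])
    return {
        "mean_accuracy": round(float(acc.mean())),
        "mean_sensitivity": round(float(sens.mean())),
        "mean_specificity": round(float(spec.mean())),
        "max_accuracy": round(float(acc.max()), 1),
    }


def results_frame(results: list[SplitResult]) -> pd.DataFrame:
    """Per-split metrics shaped like a train/test assignment table."""
    return pd.DataFrame(
        {
            "train_sz": ["+".join(r.plan.train_sz) for r in results],
            "train_asd": ["+".join(r.plan.train_asd) for r in results],
            "test_sz": ["+".join(r.plan.test_sz) for r in results],
            "test_asd": ["+".join(r.plan.test_asd) for r in results],
            "accuracy": [r.accuracy for r in results],
            "sensitivity": [r.sensitivity for r in results],
            "specificity": [r.specificity for r in results],
            "n_features": [len(r.features) for r in results],
        }
    )
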