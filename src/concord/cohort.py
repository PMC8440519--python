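"""Synthetic multi-dataset cohort generator with planted group effects.

Every downstream stage of the pipeline is exercised against cohorts produced
here, so the generator is the source of ground truth.  It emulates the
statistical structure the analysis assumes in a multi-site case-control
study of schizophrenia (SZ) and autism (ASD) against healthy controls (HC):

* subject-level measures (FNC edges, network-voxel Z-scores, ...) drawn from
  a baseline Gaussian with additive planted group shifts.  For a planted
  effect of standardized magnitude ``m`` the SZ group mean moves by ``-m``
  (decrease) or ``+m`` (increase); the ASD mean moves by ``lambda * m`` in
  the same direction for common categories and the opposite direction for
  disorder-unique categories, where ``lambda`` (``asd_scale``) encodes the
  globally weaker ASD effect;
* nuisance structure: per-dataset and per-site offsets, linear age slopes,
  a binary gender shift, i.i.d. Gaussian noise (sd 1, so magnitudes read as
  Cohen's d);
* network time series drawn from per-group latent covariance matrices whose
  off-diagonal entries realize the planted connectivity effects, with motion
  regressors (and optional >3 mm motion outliers) attached;
* volumes with a shared ellipsoidal brain support, plus deliberately
  misaligned ones, for exercising the normalization-quality screen;
* symptom scores linearly coupled to chosen features within patient groups.

The generator does not attempt realistic hemodynamics, spatial
autocorrelation, or scanner-specific artifacts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import COVARIATE_COLUMNS, MeasureMatrix
from .contrast import ChangeCategory

__all__ = [
    "PlantedEffect",
    "CohortSpec",
    "GroundTruth",
    "generate_cohort",
    "generate_network_timeseries",
    "generate_qc_volumes",
    "generate_symptoms",
    "write_cohort",
]

# (SZ sign, ASD sign) per category; ASD magnitude additionally scaled by lambda
_CATEGORY_SIGNS = {
    ChangeCategory.COMMON_DECREASE: (-1.0, -1.0),
    ChangeCategory.COMMON_INCREASE: (+1.0, +1.0),
    ChangeCategory.SZ_UNIQUE_DECREASE: (-1.0, +1.0),
    ChangeCategory.ASD_UNIQUE_DECREASE: (+1.0, -1.0),
}


@dataclass(frozen=True)
class PlantedEffect:
    """A single planted group difference at one feature."""

    feature_id: int
    category: ChangeCategory
    magnitude: float

    def __post_init__(self) -> None:
        if self.category not in _CATEGORY_SIGNS:
            raise ValueError(f"{self.category} is not a plantable category")
        if self.magnitude <= 0:
            raise ValueError("magnitude must be positive")

    def shifts(self, asd_scale: float) -> tuple[float, float]:
        s_sz, s_asd = _CATEGORY_SIGNS[self.category]
        return s_sz * self.magnitude, s_asd * asd_scale * self.magnitude


@dataclass
class CohortSpec:
    """Full parameterization of a synthetic cohort.

    ``dataset_kinds`` mirrors the multi-site design in which some datasets
    recruit HC+SZ ("SZ") and others HC+ASD ("ASD"); "ALL" datasets contain
    all three groups (the default when the field is None).
    """

    n_per_group_per_dataset: int
    n_datasets: int
    n_features: int = 200
    n_networks: int = 53
    n_timepoints: int = 150
    effect_plan: tuple[PlantedEffect, ...] = ()
    asd_scale: float = 1.0
    site_shift_sd: float = 0.0
    age_slope_sd: float = 0.0
    gender_shift_sd: float = 0.0
    noise_sd: float = 1.0
    symptom_coupling: tuple[tuple[int, float], ...] = ()
    motion_outlier_fraction: float = 0.0
    n_sites_per_dataset: int = 2
    dataset_kinds: tuple[str, ...] | None = None
    feature_kind: str = "fnc_edge"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group_per_dataset <= 0:
            raise ValueError("n_per_group_per_dataset must be positive")
        if self.n_datasets < 2:
            raise ValueError("need at least 2 datasets")
        if not (0 < self.asd_scale <= 1):
            raise ValueError("asd_scale must lie in (0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        for sd in (self.site_shift_sd, self.age_slope_sd, self.gender_shift_sd):
            if sd < 0:
                raise ValueError("standard deviations must be nonnegative")
        if not (0 <= self.motion_outlier_fraction < 1):
            raise ValueError("motion_outlier_fraction must lie in [0, 1)")
        ids = [e.feature_id for e in self.effect_plan]
        if len(ids) != len(set(ids)):
            raise ValueError("planted effect features must be distinct")
        if any(i < 0 or i >= self.n_features for i in ids):
            raise ValueError("planted effect feature id out of range")
        for fid, _coef in self.symptom_coupling:
            if fid < 0 or fid >= self.n_features:
                raise ValueError(f"symptom coupling references missing feature {fid}")
        if self.dataset_kinds is not None:
            if len(self.dataset_kinds) != self.n_datasets:
                raise ValueError("dataset_kinds must list one kind per dataset")
            if any(k not in ("SZ", "ASD", "ALL") for k in self.dataset_kinds):
                raise ValueError("dataset kinds must be SZ, ASD or ALL")

    def groups_for_dataset(self, d: int) -> tuple[str, ...]:
        kind = "ALL" if self.dataset_kinds is None else self.dataset_kinds[d]
        return {
            "ALL": ("HC", "SZ", "ASD"),
            "SZ": ("HC", "SZ"),
            "ASD": ("HC", "ASD"),
        }[kind]


@dataclass
class GroundTruth:
    """Planted truth the recovery tests score against."""

    categories: dict[int, ChangeCategory]
    asd_weaker: dict[int, bool]
    shifts: dict[int, tuple[float, float]]
    spec: CohortSpec

    def to_json(self) -> str:
        payload = {
            "categories": {str(k): v.value for k, v in self.categories.items()},
            "asd_weaker": {str(k): v for k, v in self.asd_weaker.items()},
            "shifts": {str(k): list(v) for k, v in self.shifts.items()},
            "spec": _spec_dict(self.spec),
        }
        return json.dumps(payload, indent=2)


def _spec_dict(spec: CohortSpec) -> dict:
    d = asdict(spec)
    d["effect_plan"] = [
        {"feature_id": e.feature_id, "category": e.category.value, "magnitude": e.magnitude}
        for e in spec.effect_plan
    ]
    return d


def _age_stats() -> tuple[float, float]:
    # uniform(16, 60): mean 38, sd 44/sqrt(12)
    return 38.0, 44.0 / np.sqrt(12.0)


def _roster(spec: CohortSpec, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for d in range(spec.n_datasets):
        for g in spec.groups_for_dataset(d):
            for i in range(spec.n_per_group_per_dataset):
                rows.append(
                    {
                        "subject_id": f"d{d:02d}_{g}_{i:04d}",
                        "group": g,
                        "dataset": f"ds{d:02d}",
                        "site": f"ds{d:02d}_s{i % spec.n_sites_per_dataset}",
                        "age": rng.uniform(16.0, 60.0),
                        "gender": int(rng.integers(0, 2)),
                    }
                )
    cov = pd.DataFrame(rows).set_index("subject_id")
    n = len(cov)
    trans = np.abs(rng.normal(0.4, 0.3, n)).clip(0.01, 2.5)
    rot = np.abs(rng.normal(0.3, 0.25, n)).clip(0.01, 2.5)
    if spec.motion_outlier_fraction > 0:
        n_out = int(round(spec.motion_outlier_fraction * n))
        out_idx = rng.choice(n, size=n_out, replace=False)
        trans[out_idx] = rng.uniform(3.5, 6.0, n_out)
    cov["motion_trans_mm"] = trans
    cov["motion_rot_deg"] = rot
    return cov[list(COVARIATE_COLUMNS)]


def generate_cohort(
    spec: CohortSpec,
) -> tuple[MeasureMatrix, pd.DataFrame, GroundTruth]:
    """Draw a full synthetic cohort.

    Returns the measure matrix, the covariate table (indexed by subject id)
    and the planted :class:`GroundTruth`.  The same spec (including seed)
    always yields bit-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    cov = _roster(spec, rng)
    n, m = len(cov), spec.n_features

    age_mu, age_sd = _age_stats()
    age_z = (cov["age"].to_numpy() - age_mu) / age_sd
    gender = cov["gender"].to_numpy(float)

    age_slopes = rng.normal(0.0, spec.age_slope_sd, m) if spec.age_slope_sd else np.zeros(m)
    gender_shifts = (
        rng.normal(0.0, spec.gender_shift_sd, m) if spec.gender_shift_sd else np.zeros(m)
    )
    ds_labels = sorted(cov["dataset"].unique())
    site_labels = sorted(cov["site"].unique())
    ds_offsets = {
        d: (rng.normal(0.0, spec.site_shift_sd, m) if spec.site_shift_sd else np.zeros(m))
        for d in ds_labels
    }
    site_offsets = {
        s: (rng.normal(0.0, spec.site_shift_sd, m) if spec.site_shift_sd else np.zeros(m))
        for s in site_labels
    }

    values = rng.normal(0.0, spec.noise_sd, (n, m))
    values += np.outer(age_z, age_slopes)
    values += np.outer(gender, gender_shifts)
    for d in ds_labels:
        values[cov["dataset"].to_numpy() == d] += ds_offsets[d]
    for s in site_labels:
        values[cov["site"].to_numpy() == s] += site_offsets[s]

    truth_cat: dict[int, ChangeCategory] = {}
    truth_weaker: dict[int, bool] = {}
    truth_shift: dict[int, tuple[float, float]] = {}
    is_sz = cov["group"].to_numpy() == "SZ"
    is_asd = cov["group"].to_numpy() == "ASD"
    for eff in spec.effect_plan:
        sz_shift, asd_shift = eff.shifts(spec.asd_scale)
        values[is_sz, eff.feature_id] += sz_shift
        values[is_asd, eff.feature_id] += asd_shift
        truth_cat[eff.feature_id] = eff.category
        truth_shift[eff.feature_id] = (sz_shift, asd_shift)
        if eff.category.is_common:
            truth_weaker[eff.feature_id] = abs(asd_shift) < abs(sz_shift)

    features = [f"f{j:04d}" for j in range(m)]
    mm = MeasureMatrix(
        values=pd.DataFrame(values, index=cov.index, columns=features),
        feature_kind=spec.feature_kind,
    )
    return mm, cov, GroundTruth(truth_cat, truth_weaker, truth_shift, spec)


# ---------------------------------------------------------------------------
# network time series


def edge_index_map(n_networks: int) -> list[tuple[int, int]]:
    """Upper-triangle (i, j) pairs in the feature enumeration order."""
    iu = np.triu_indices(n_networks, k=1)
    return list(zip(iu[0].tolist(), iu[1].tolist()))


def _group_covariance(
    spec: CohortSpec, group: str, base_edge_r: float, edge_scale: float
) -> np.ndarray:
    K = spec.n_networks
    sigma = np.eye(K)
    edges = edge_index_map(K)
    z0 = np.arctanh(base_edge_r)
    for eff in spec.effect_plan:
        if eff.feature_id >= len(edges):
            continue
        i, j = edges[eff.feature_id]
        sz_shift, asd_shift = eff.shifts(spec.asd_scale)
        # a patient *decrease* relative to HC lowers the patient correlation
        shift = {"HC": 0.0, "SZ": sz_shift, "ASD": asd_shift}[group]
        r = np.tanh(z0 + edge_scale * shift) if group != "HC" else base_edge_r
        sigma[i, j] = sigma[j, i] = r
    # repair indefiniteness from overlapping edges
    w, v = np.linalg.eigh(sigma)
    if w.min() < 1e-8:
        w = np.clip(w, 1e-8, None)
        sigma = v @ np.diag(w) @ v.T
        d = np.sqrt(np.diag(sigma))
        sigma = sigma / np.outer(d, d)
    return sigma


def generate_network_timeseries(
    spec: CohortSpec,
    covariates: pd.DataFrame | None = None,
    base_edge_r: float = 0.35,
    edge_scale: float = 0.3,
    tr: float = 2.0,
):
    """Per-subject K x T network time series realizing the planted FNC effects.

    Series are drawn i.i.d. in time from N(0, Sigma_group) where Sigma_group
    plants each effect on the upper-triangle edge addressed by its feature
    id: the HC correlation is ``base_edge_r`` and patient correlations move
    by ``edge_scale`` times the planted shift on the Fisher-z scale, in the
    direction of the planted change.  Six motion regressors (three
    translations in mm, three rotations in degrees) ride along; subjects
    flagged as motion outliers carry a >3 mm transition.

    Returns ``(series, covariates)`` where ``series`` maps subject id to a
    :class:`~concord.connectivity.NetworkTimeseries`.
    """
    from .connectivity import NetworkTimeseries

    if spec.n_timepoints <= 2:
        raise ValueError("need more than 2 timepoints")
    rng = np.random.default_rng(spec.seed + 1)
    if covariates is None:
        covariates = _roster(spec, rng)
    chol = {
        g: np.linalg.cholesky(_group_covariance(spec, g, base_edge_r, edge_scale))
        for g in ("HC", "SZ", "ASD")
    }
    out: dict[str, NetworkTimeseries] = {}
    T = spec.n_timepoints
    for sid, row in covariates.iterrows():
        series = chol[row["group"]] @ rng.standard_normal((spec.n_networks, T))
        motion = np.cumsum(rng.normal(0.0, 0.02, (6, T)), axis=1)
        if row["motion_trans_mm"] > 3.0:
            jump = rng.integers(T // 4, 3 * T // 4)
            motion[0, jump:] += row["motion_trans_mm"]
        out[sid] = NetworkTimeseries(series=series, motion=motion, tr=tr)
    return out, covariates


# ---------------------------------------------------------------------------
# QC volumes


def _ellipsoid_volume(
    shape: tuple[int, int, int],
    center: np.ndarray,
    radii: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    grid = np.indices(shape).astype(float)
    d2 = sum(
        ((grid[a] - center[a]) / radii[a]) ** 2 for a in range(3)
    )
    vol = np.where(d2 <= 1.0, 100.0 * np.exp(-0.5 * d2), 0.0)
    vol += np.abs(rng.normal(0.0, 0.5, shape)) * (d2 <= 1.0)
    return vol


def generate_qc_volumes(
    n_good: int,
    n_bad: int,
    seed: int = 0,
    shape: tuple[int, int, int] = (40, 44, 30),
):
    """Volumes sharing an ellipsoidal brain support, plus misaligned ones.

    "Good" volumes jitter the ellipsoid center and radii by under half a
    voxel; "bad" volumes are translated along the slice axis by roughly half
    the grid (or truncated), which drives the slab/whole mask correlations
    against the group mask below the screening thresholds.

    Returns ``(volumes, labels)``: a list of 3-D arrays and a boolean list
    marking the planted good volumes.
    """
    if n_good + n_bad == 0:
        raise ValueError("need at least one volume")
    if shape[2] < 20:
        raise ValueError("need at least 20 slices along the slice axis")
    rng = np.random.default_rng(seed)
    center0 = np.array([s / 2.0 for s in shape])
    radii0 = np.array([shape[0] * 0.36, shape[1] * 0.38, shape[2] * 0.36])
    volumes: list[np.ndarray] = []
    labels: list[bool] = []
    for _ in range(n_good):
        center = center0 + rng.uniform(-0.4, 0.4, 3)
        radii = radii0 + rng.uniform(-0.4, 0.4, 3)
        volumes.append(_ellipsoid_volume(shape, center, radii, rng))
        labels.append(True)
    for k in range(n_bad):
        center = center0.copy()
        if k % 2 == 0:
            center[2] += shape[2] / 2.0  # gross translation along slices
            radii = radii0
        else:
            radii = radii0 * np.array([1.0, 1.0, 0.45])  # truncated coverage
            center[2] -= shape[2] * 0.25
        volumes.append(_ellipsoid_volume(shape, center + rng.uniform(-0.5, 0.5, 3), radii, rng))
        labels.append(False)
    return volumes, labels


# ---------------------------------------------------------------------------
# symptoms


def generate_symptoms(
    measures: MeasureMatrix,
    covariates: pd.DataFrame,
    coupling: list[tuple[int, float]] | tuple[tuple[int, float], ...],
    noise_sd: float,
    seed: int = 0,
    group: str = "SZ",
    score_name: str = "score",
) -> pd.DataFrame:
    """Symptom scores linearly coupled to chosen features, patients only.

    score = sum_k coef_k * feature_k + N(0, noise_sd^2), computed for the
    subjects of ``group`` (a patient group).
    """
    if group not in ("SZ", "ASD"):
        raise ValueError("symptoms are generated for patient groups only")
    if not len(coupling):
        raise ValueError("empty coupling")
    cols = list(measures.features)
    for fid, _ in coupling:
        if fid < 0 or fid >= len(cols):
            raise ValueError(f"coupling references missing feature {fid}")
    rng = np.random.default_rng(seed)
    cov = measures.aligned(covariates)
    mask = cov["group"] == group
    if not mask.any():
        raise ValueError(f"no subjects in group {group}")
    sub = measures.values.loc[mask.to_numpy()]
    score = np.zeros(len(sub))
    for fid, coef in coupling:
        score += coef * sub[cols[fid]].to_numpy()
    score += rng.normal(0.0, noise_sd, len(sub))
    return pd.DataFrame({score_name: score, "group": group}, index=sub.index)


# ---------------------------------------------------------------------------
# on-disk formats


def write_cohort(
    out_dir: str | Path,
    measures: MeasureMatrix,
    covariates: pd.DataFrame,
    truth: GroundTruth | None = None,
) -> None:
    """Write measures+covariates as one TSV and the ground truth as JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    combined = covariates.join(measures.values)
    combined.index.name = "subject_id"
    combined.to_csv(out / "measures.tsv", sep="\t")
    if truth is not None:
        (out / "ground_truth.json").write_text(truth.to_json())
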