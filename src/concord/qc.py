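"""Normalization-quality screening and subject selection for fMRI/sMRI.

Poorly normalized scans are caught by comparing each subject's brain mask
against the group's.  For fMRI, an individual binary mask is computed from
the first volume (voxels above 90% of the whole-volume mean), a group mask
keeps voxels present in more than 90% of individual masks, and three Pearson
correlations between the individual and group mask are evaluated: over the
top ten slices, the bottom ten slices, and the whole grid.  A subject passes
when the correlations exceed 0.75 / 0.55 / 0.8 respectively, head motion
stays under 3 mm translation and 3 degrees rotation, and the scan has more
than 120 time points.  After screening, the group mask is recomputed once
from the passing subjects.

For sMRI the group mask keeps voxels of the group-mean image above 0.2 and
the correlations are computed on the continuous image values within that
mask (thresholds 0.6 / 0.6 / 0.8).

Slab orientation: "top"/"bottom" slices are taken along the third array axis
by default (highest indices = top); configurable because acquisition
orientation varies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "BinaryMask",
    "QCThresholds",
    "SubjectQC",
    "FMRI_THRESHOLDS",
    "SMRI_THRESHOLDS",
    "individual_mask_fmri",
    "group_mask",
    "slab_correlations",
    "screen_fmri_subject",
    "screen_smri_subject",
    "iterate_group_mask",
    "report_frame",
]

MAX_ROTATION_DEG = 3.0
MAX_TRANSLATION_MM = 3.0
MIN_TIMEPOINTS = 120  # strictly more than this many required


@dataclass
class BinaryMask:
    """A 3-D {0,1} brain mask with a designated slice axis."""

    grid: np.ndarray
    slice_axis: int = 2

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid).astype(bool)
        if self.grid.ndim != 3:
            raise ValueError("mask grid must be 3-D")
        if not 0 <= self.slice_axis < 3:
            raise ValueError("slice_axis must be 0, 1 or 2")

    @property
    def n_slices(self) -> int:
        return self.grid.shape[self.slice_axis]


@dataclass(frozen=True)
class QCThresholds:
    top_r: float
    bottom_r: float
    whole_r: float
    slab_size: int = 10

    def __post_init__(self) -> None:
        if self.slab_size < 1:
            raise ValueError("slab_size must be >= 1")


FMRI_THRESHOLDS = QCThresholds(top_r=0.75, bottom_r=0.55, whole_r=0.8)
SMRI_THRESHOLDS = QCThresholds(top_r=0.6, bottom_r=0.6, whole_r=0.8)


@dataclass
class SubjectQC:
    """Per-subject screening outcome."""

    r_top: float
    r_bottom: float
    r_whole: float
    passed: bool
    reasons: list[str] = field(default_factory=list)


def individual_mask_fmri(first_volume: np.ndarray, slice_axis: int = 2) -> BinaryMask:
    """Binary brain mask from the first fMRI volume.

    A voxel enters the mask iff its intensity exceeds 0.9 times the mean
    over all voxels of the volume.
    """
    vol = np.asarray(first_volume, float)
    if vol.ndim != 3:
        raise ValueError("expected a 3-D volume")
    mean = vol.mean()
    if mean <= 0 or not np.any(vol > 0):
        raise ValueError("volume has no positive signal; cannot form a mask")
    return BinaryMask(grid=vol > 0.9 * mean, slice_axis=slice_axis)


def group_mask(masks: list[BinaryMask]) -> BinaryMask:
    """Voxels included in strictly more than 90% of the individual masks."""
    if not masks:
        raise ValueError("need at least one mask")
    shape = masks[0].grid.shape
    axis = masks[0].slice_axis
    for m in masks:
        if m.grid.shape != shape:
            raise ValueError("all masks must share one grid")
    frac = np.mean([m.grid for m in masks], axis=0)
    return BinaryMask(grid=frac > 0.9, slice_axis=axis)


def _slab_slices(mask: BinaryMask, slab_size: int):
    n = mask.n_slices
    if slab_size > n:
        raise ValueError("slab_size exceeds number of slices")
    top = [slice(None)] * 3
    bottom = [slice(None)] * 3
    top[mask.slice_axis] = slice(n - slab_size, n)
    bottom[mask.slice_axis] = slice(0, slab_size)
    return tuple(top), tuple(bottom)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a.ravel().astype(float)
    b = b.ravel().astype(float)
    if a.std() == 0 or b.std() == 0:
        return np.nan  # degenerate slab: correlation undefined
    return float(np.corrcoef(a, b)[0, 1])


def slab_correlations(
    ind: BinaryMask, grp: BinaryMask, slab_size: int = 10
) -> tuple[float, float, float]:
    """Pearson correlations of two binary masks over top slab, bottom slab, whole grid.

    A constant slab in either mask yields NaN for that correlation (reported
    downstream as a "degenerate slab" failure).
    """
    if ind.grid.shape != grp.grid.shape:
        raise ValueError("masks must share one grid")
    top, bottom = _slab_slices(ind, slab_size)
    return (
        _pearson(ind.grid[top], grp.grid[top]),
        _pearson(ind.grid[bottom], grp.grid[bottom]),
        _pearson(ind.grid, grp.grid),
    )


def _correlation_checks(
    r_top: float, r_bottom: float, r_whole: float, thresholds: QCThresholds
) -> list[str]:
    reasons = []
    for name, r, thr in (
        ("top", r_top, thresholds.top_r),
        ("bottom", r_bottom, thresholds.bottom_r),
        ("whole", r_whole, thresholds.whole_r),
    ):
        if np.isnan(r):
            reasons.append(f"degenerate slab ({name})")
        elif not r > thr:
            reasons.append(f"{name}-mask correlation {r:.3f} <= {thr}")
    return reasons


def screen_fmri_subject(
    ind: BinaryMask,
    grp: BinaryMask,
    motion: tuple[float, float] | None,
    n_timepoints: int,
    thresholds: QCThresholds = FMRI_THRESHOLDS,
) -> SubjectQC:
    """Full fMRI inclusion screen for one subject.

    ``motion`` is (max translation mm, max rotation degrees) over the scan;
    a missing record fails the subject.  Pass requires translation < 3 mm,
    rotation < 3 degrees, strictly more than 120 time points, and all three
    mask correlations above the fMRI thresholds.
    """
    r_top, r_bottom, r_whole = slab_correlations(ind, grp, thresholds.slab_size)
    reasons = _correlation_checks(r_top, r_bottom, r_whole, thresholds)
    if motion is None:
        reasons.append("missing motion record")
    else:
        trans, rot = motion
        if not trans < MAX_TRANSLATION_MM:
            reasons.append(f"translation {trans:.2f} mm >= {MAX_TRANSLATION_MM}")
        if not rot < MAX_ROTATION_DEG:
            reasons.append(f"rotation {rot:.2f} deg >= {MAX_ROTATION_DEG}")
    if not n_timepoints > MIN_TIMEPOINTS:
        reasons.append(f"need >{MIN_TIMEPOINTS} time points, got {n_timepoints}")
    return SubjectQC(r_top, r_bottom, r_whole, passed=not reasons, reasons=reasons)


def screen_smri_subject(
    ind_image: np.ndarray,
    group_mean_image: np.ndarray,
    thresholds: QCThresholds = SMRI_THRESHOLDS,
    slice_axis: int = 2,
    mask_threshold: float = 0.2,
) -> SubjectQC:
    """Structural-image screen against the group-mean image.

    The group mask keeps voxels of the group-mean image above
    ``mask_threshold``; correlations are computed on the continuous image
    values, restricted to the mask, within the top slab, bottom slab and the
    whole mask.
    """
    ind = np.asarray(ind_image, float)
    ref = np.asarray(group_mean_image, float)
    if ind.shape != ref.shape:
        raise ValueError("images must share one grid")
    gmask = BinaryMask(grid=ref > mask_threshold, slice_axis=slice_axis)
    if not gmask.grid.any():
        raise ValueError("empty group mask at threshold")
    top, bottom = _slab_slices(gmask, thresholds.slab_size)

    def masked_r(region) -> float:
        sel = gmask.grid[region]
        if not sel.any():
            return np.nan
        return _pearson(ind[region][sel], ref[region][sel])

    r_top = masked_r(top)
    r_bottom = masked_r(bottom)
    r_whole = _pearson(ind[gmask.grid], ref[gmask.grid])
    reasons = _correlation_checks(r_top, r_bottom, r_whole, thresholds)
    return SubjectQC(r_top, r_bottom, r_whole, passed=not reasons, reasons=reasons)


def iterate_group_mask(
    subjects: dict[str, BinaryMask],
    motion: dict[str, tuple[float, float]] | None = None,
    n_timepoints: dict[str, int] | None = None,
    thresholds: QCThresholds = FMRI_THRESHOLDS,
) -> tuple[BinaryMask, list[str], dict[str, SubjectQC]]:
    """Screen against the initial group mask, then recompute it once.

    Each subject is screened against the group mask formed from *all*
    subjects; the final group mask is rebuilt from the passers' masks (one
    recomputation pass, no further iteration).  Motion/time-point records
    are optional; when omitted those criteria are treated as satisfied.

    Returns (final group mask, passing subject ids, per-subject reports).
    """
    if not subjects:
        raise ValueError("no subjects")
    initial = group_mask(list(subjects.values()))
    reports: dict[str, SubjectQC] = {}
    passers: list[str] = []
    for sid, mask in subjects.items():
        if motion is not None or n_timepoints is not None:
            mot = None if motion is None else motion.get(sid)
            T = MIN_TIMEPOINTS + 1 if n_timepoints is None else n_timepoints.get(sid, 0)
            rep = screen_fmri_subject(mask, initial, mot, T, thresholds)
        else:
            r_top, r_bottom, r_whole = slab_correlations(mask, initial, thresholds.slab_size)
            reasons = _correlation_checks(r_top, r_bottom, r_whole, thresholds)
            rep = SubjectQC(r_top, r_bottom, r_whole, passed=not reasons, reasons=reasons)
        reports[sid] = rep
        if rep.passed:
            passers.append(sid)
    if not passers:
        raise ValueError("all subjects failed the screen")
    final = group_mask([subjects[sid] for sid in passers])
    return final, passers, reports


def report_frame(reports: dict[str, SubjectQC]) -> pd.DataFrame:
    """Tidy per-subject QC report."""
    return pd.DataFrame(
        {
            "subject_id": list(reports),
            "r_top": [r.r_top for r in reports.values()],
            "r_bottom": [r.r_bottom for r in reports.values()],
            "r_whole": [r.r_whole for r in reports.values()],
            "passed": [r.passed for r in reports.values()],
            "reasons": ["; ".join(r.reasons) for r in reports.values()],
        }
    ).set_index("subject_id")
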