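"""ROI summaries, tumor size metrics and RECIST 1.1 response labels.

Parameter statistics are taken over the intersection of the drawn ROI
with the fitted-voxel mask.  Tumor volume follows the slice-stack
formula: per-slice lesion area times (slice thickness + inter-slice
gap), summed over slices.  Change metrics are plain differences and
percent changes relative to the pre-treatment value.  Response labels
follow RECIST 1.1 on a single target lesion: PR at >= 30% diameter
decrease, PD at >= 20% increase (with the 5 mm absolute guard), CR
when the lesion disappears, SD otherwise; responders (RG) are CR/PR.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .map_fitting import ParameterMap

__all__ = [
    "RoiStats",
    "DeltaMetrics",
    "PatientRecord",
    "roi_summary",
    "change_metrics",
    "tumor_volume",
    "volume_from_mask",
    "recist_classify",
]

RECIST_CATEGORIES = ("CR", "PR", "SD", "PD")


@dataclass(frozen=True)
class RoiStats:
    """Summary statistics of one parameter over an ROI (reporting scale).

    Quartiles use linear interpolation between order statistics, so the
    IQR matches the common statistical-software default.
    """

    parameter: str
    n_voxels: int
    mean: float
    median: float
    iqr: float

    def __post_init__(self) -> None:
        if self.n_voxels < 1:
            raise ValueError("an ROI summary needs at least one voxel")


@dataclass(frozen=True)
class DeltaMetrics:
    """Pre/post change: delta = post - pre, delta_pct = 100 * delta / pre."""

    pre: float
    post: float

    @property
    def delta(self) -> float:
        return self.post - self.pre

    @property
    def delta_pct(self) -> float:
        return 100.0 * self.delta / self.pre


@dataclass
class PatientRecord:
    """One synthetic or real patient: sizes, labels, marker values.

    ``markers_pre``/``markers_post`` map marker names (ADC, MD, MK,
    Dslow, Dfast, PF, Ktrans, Kep, Ve) to values on the reporting
    scale; for a synthetic cohort these are the ground truth, after the
    imaging pipeline they are ROI means.
    """

    patient_id: str
    group: str  # "RG" or "NRG"
    recist: str  # CR / PR / SD / PD
    pre_diameter_cm: float
    post_diameter_cm: float
    pre_volume_cm3: float
    post_volume_cm3: float
    markers_pre: dict = field(default_factory=dict)
    markers_post: dict = field(default_factory=dict)
    demographics: dict = field(default_factory=dict)
    geometry: dict = field(default_factory=dict)  # lesion axes etc. for rendering

    def __post_init__(self) -> None:
        if self.group not in ("RG", "NRG"):
            raise ValueError("group must be RG or NRG")
        if self.recist not in RECIST_CATEGORIES:
            raise ValueError(f"unknown RECIST category {self.recist!r}")
        if (self.group == "RG") != (self.recist in ("CR", "PR")):
            raise ValueError("group label inconsistent with RECIST category")
        if self.pre_diameter_cm <= 0 or self.pre_volume_cm3 <= 0:
            raise ValueError("pre-treatment sizes must be positive")

    @property
    def delta_diameter(self) -> DeltaMetrics:
        return DeltaMetrics(self.pre_diameter_cm, self.post_diameter_cm)

    @property
    def delta_volume(self) -> DeltaMetrics:
        return DeltaMetrics(self.pre_volume_cm3, self.post_volume_cm3)


def roi_summary(pmap: ParameterMap, roi: np.ndarray) -> RoiStats:
    """Summarise a parameter map over an ROI (reporting scale).

    Only voxels that are both inside the ROI and flagged as validly
    fitted contribute; an empty intersection is an error.
    """
    roi = np.asarray(roi, dtype=bool)
    if roi.shape != pmap.values.shape:
        raise ValueError("ROI shape does not match the parameter map")
    sel = roi & pmap.mask
    if not sel.any():
        raise ValueError("ROI does not intersect any fitted voxel")
    vals = pmap.values[sel] / pmap.scale
    q1, med, q3 = np.percentile(vals, [25, 50, 75])
    return RoiStats(pmap.name, int(sel.sum()), float(vals.mean()), float(med),
                    float(q3 - q1))


def change_metrics(pre, post) -> DeltaMetrics:
    """Pre/post change metrics; RoiStats arguments are compared by mean."""
    pre_v = pre.mean if isinstance(pre, RoiStats) else float(pre)
    post_v = post.mean if isinstance(post, RoiStats) else float(post)
    if pre_v == 0:
        raise ValueError("pre-treatment value must be nonzero")
    return DeltaMetrics(pre_v, post_v)


def tumor_volume(area_cm2, slice_thickness_cm: float, gap_cm: float = 0.0) -> float:
    """Slice-stack tumor volume: sum of area * (thickness + gap).

    ``area_cm2`` may be a scalar (single slice) or a sequence of
    per-slice lesion areas.
    """
    areas = np.atleast_1d(np.asarray(area_cm2, dtype=float))
    if np.any(areas < 0) or slice_thickness_cm <= 0 or gap_cm < 0:
        raise ValueError("areas must be >= 0, thickness > 0, gap >= 0")
    return float(areas.sum() * (slice_thickness_cm + gap_cm))


def volume_from_mask(mask: np.ndarray, spacing_mm, gap_mm: float = 0.0) -> float:
    """Tumor volume (cm^3) of a binary mask via the slice-stack formula.

    Per-slice area is the voxel count times the in-plane voxel area;
    the z spacing is treated as the slice thickness.
    """
    mask = np.asarray(mask, dtype=bool)
    dx, dy, dz = spacing_mm
    areas_cm2 = mask.sum(axis=(0, 1)) * (dx / 10.0) * (dy / 10.0)
    return tumor_volume(areas_cm2, dz / 10.0, gap_mm / 10.0)


def recist_classify(
    delta_diameter_pct: float,
    pre_diameter_cm: float | None = None,
) -> tuple[str, str]:
    """RECIST 1.1 category and responder group for one target lesion.

    Returns ``(category, group)`` with group RG iff CR or PR.  PR at a
    decrease >= 30%, CR at complete disappearance, PD at an increase
    >= 20% which — when the pre-treatment diameter is supplied — must
    also be >= 5 mm absolute; everything else is SD.
    """
    d = float(delta_diameter_pct)
    if d < -100.0:
        raise ValueError("diameter cannot shrink by more than 100%")
    if d == -100.0:
        cat = "CR"
    elif d <= -30.0:
        cat = "PR"
    elif d >= 20.0:
        if pre_diameter_cm is not None and pre_diameter_cm * d / 100.0 < 0.5:
            cat = "SD"
        else:
            cat = "PD"
    else:
        cat = "SD"
    return cat, ("RG" if cat in ("CR", "PR") else "NRG")
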