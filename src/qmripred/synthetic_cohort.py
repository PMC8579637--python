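"""Seeded synthetic pre/post-chemotherapy imaging cohort.

Generates a full stand-in for a nasopharyngeal-carcinoma induction-
chemotherapy study: per-patient ground-truth tissue parameters drawn
from responder (RG) and non-responder (NRG) group distributions, tumor
diameters and volumes with group-specific shrinkage, RECIST labels
consistent with the simulated diameter change, demographics matched to
typical cohort margins, and — on demand — rendered 4-D signal volumes
for every modality so the whole fitting and statistics pipeline can be
exercised without any real data.

Design notes
------------
* Markers reported as mean +/- SD are drawn truncated-normal; markers
  reported as median (IQR) are drawn log-normal matched to median and
  IQR (positivity and skew).
* A single latent "aggressiveness" factor (loading 0.5) induces
  cross-marker correlation within a patient: aggressive, chemo-
  sensitive tumors have low ADC/MD/Dslow and high MK.
* Post-treatment marker values are pre * (1 + d%/100) with
  group-specific normal d% distributions.
* Lesions are ellipsoids on a coarse voxel grid; recorded volumes use
  the same slice-stack formula as :func:`qmripred.roi_metrics.
  volume_from_mask` applied to the discretised mask, so the geometry
  round-trips exactly.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import optimize as _optimize
from scipy import stats as _stats

from .map_fitting import SignalVolume
from .roi_metrics import PatientRecord, recist_classify, volume_from_mask
from .signal_models import (
    DceAcquisition,
    DiffusionAcquisition,
    ParkerAif,
    TissueParams,
    add_noise,
    dki_signal,
    dwi_signal,
    ivim_signal,
    tofts_concentration,
)

__all__ = [
    "CohortConfig",
    "generate_cohort",
    "render_patient_images",
    "cohort_to_frame",
    "lesion_mask",
    "largest_slice_mask",
]

# median/IQR -> log-normal: median = exp(mu); IQR/median = exp(z75*s) - exp(-z75*s)
_Z75 = 0.6744897501960817

#: marker -> group -> distribution of the pre-treatment value, reporting scale.
#: ("norm", mean, sd) or ("lognorm", median, iqr).
DEFAULT_PRE_DISTRIBUTIONS: dict[str, dict[str, tuple]] = {
    "ADC": {"RG": ("norm", 1119.58, 144.06), "NRG": ("norm", 1386.25, 198.23)},
    "MD": {"RG": ("lognorm", 902.00, 150.0), "NRG": ("lognorm", 1121.00, 331.0)},
    "MK": {"RG": ("norm", 1052.25, 122.02), "NRG": ("norm", 935.10, 185.34)},
    "Dslow": {"RG": ("norm", 724.50, 235.92), "NRG": ("norm", 933.85, 219.95)},
    # no group difference reported for the perfusion / permeability markers:
    # both groups share the overall pre-treatment distribution
    "Dfast": {"RG": ("norm", 410.59, 181.513), "NRG": ("norm", 410.59, 181.513)},
    "PF": {"RG": ("lognorm", 198.50, 103.0), "NRG": ("lognorm", 198.50, 103.0)},
    "Ktrans": {"RG": ("norm", 920.43, 549.753), "NRG": ("norm", 920.43, 549.753)},
    "Kep": {"RG": ("lognorm", 1239.50, 945.0), "NRG": ("lognorm", 1239.50, 945.0)},
}

#: marker -> group -> (mean, sd) of the percent change after treatment.
#: Group-specific where group differences in change were observed; the
#: remaining markers use the overall pre-to-post shift with a nominal
#: 15-point spread.
DEFAULT_DELTA_PCT: dict[str, dict[str, tuple[float, float]]] = {
    "ADC": {"RG": (33.81, 22.2), "NRG": (18.14, 22.2)},
    "MD": {"RG": (58.56, 20.49), "NRG": (28.61, 21.77)},
    "MK": {"RG": (-60.92, 14.8), "NRG": (-28.17, 10.4)},
    "Dslow": {"RG": (20.4, 15.0), "NRG": (20.4, 15.0)},
    "Dfast": {"RG": (-11.6, 15.0), "NRG": (-11.6, 15.0)},
    "PF": {"RG": (22.4, 15.0), "NRG": (22.4, 15.0)},
    "Ktrans": {"RG": (-14.1, 15.0), "NRG": (-14.1, 15.0)},
    "Kep": {"RG": (-35.1, 15.0), "NRG": (-35.1, 15.0)},
}

#: physical plausibility bounds on the reporting scale (truncation of draws)
_MARKER_BOUNDS = {
    "ADC": (200.0, 3500.0),
    "MD": (200.0, 3500.0),
    "MK": (50.0, 2900.0),
    "Dslow": (100.0, 3500.0),
    "Dfast": (60.0, 4500.0),
    "PF": (10.0, 8000.0),
    "Ktrans": (10.0, 4500.0),
    "Kep": (50.0, 9000.0),
}

#: latent-factor sign: aggressiveness lowers diffusivities, raises kurtosis
_LATENT_SIGN = {"ADC": -1.0, "MD": -1.0, "Dslow": -1.0, "MK": 1.0}

#: quiescent background tissue (reporting scale)
BACKGROUND_MARKERS = {
    "ADC": 1600.0, "MD": 1350.0, "MK": 650.0, "Dslow": 1250.0,
    "Dfast": 280.0, "PF": 90.0, "Ktrans": 180.0, "Kep": 700.0,
}

#: demographic margins per group: category -> per-group count vectors
DEFAULT_DEMOGRAPHICS = {
    "sex": {"levels": ("M", "F"), "RG": (29, 7), "NRG": (17, 3)},
    "t_stage": {"levels": ("T1", "T2", "T3", "T4"), "RG": (2, 18, 10, 6), "NRG": (0, 7, 7, 6)},
    "n_stage": {"levels": ("N0", "N1", "N2", "N3"), "RG": (1, 5, 16, 14), "NRG": (1, 6, 6, 7)},
    "pathology": {"levels": ("undifferentiated", "low", "moderate"),
                  "RG": (19, 15, 2), "NRG": (7, 9, 4)},
    "regimen": {"levels": ("TP", "AP"), "RG": (27, 9), "NRG": (12, 8)},
}
DEFAULT_AGE = {"RG": (43.75, 13.14), "NRG": (48.75, 11.92)}


@dataclass
class CohortConfig:
    """Everything needed to generate a reproducible synthetic cohort."""

    n_responders: int = 36
    n_nonresponders: int = 20
    seed: int = 0
    pre_distributions: dict = field(default_factory=lambda: copy.deepcopy(DEFAULT_PRE_DISTRIBUTIONS))
    delta_pct: dict = field(default_factory=lambda: copy.deepcopy(DEFAULT_DELTA_PCT))
    diameter_delta_pct: dict = field(
        default_factory=lambda: {"RG": (-49.24, 15.0), "NRG": (-18.62, 10.0)})
    volume_delta_pct: dict = field(
        default_factory=lambda: {"RG": (-64.98, 17.77), "NRG": (-30.35, 14.94)})
    pre_diameter_cm: tuple = ("lognorm", 2.4, 1.0)  # median, IQR
    diameter_range_cm: tuple = (1.2, 3.6)
    latent_loading: float = 0.5
    # acquisitions
    dwi_b: tuple = (0.0, 600.0)
    dki_b: tuple = (0.0, 500.0, 1000.0, 1500.0, 2000.0)
    ivim_b: tuple = (0.0, 10.0, 20.0, 30.0, 50.0, 80.0, 100.0, 150.0, 200.0, 400.0, 600.0, 800.0)
    dce_n_frames: int = 35
    dce_dt_s: float = 8.1
    dce_n_baseline: int = 4
    # imaging
    grid_shape: tuple = (15, 15, 7)
    spacing_mm: tuple = (3.0, 3.0, 4.0)
    s0: float = 1000.0
    snr: float = 50.0  # S0 / Rician sigma for the diffusion series
    conc_noise_mM: float = 0.02  # Gaussian sigma on concentration curves
    within_tumor_cv: float = 0.05
    slice_gap_mm: float = 0.0

    def __post_init__(self) -> None:
        if self.n_responders < 2 or self.n_nonresponders < 2:
            raise ValueError("each group needs at least 2 patients")
        if not 0.0 <= self.latent_loading < 1.0:
            raise ValueError("latent loading must lie in [0, 1)")
        if self.snr <= 0:
            raise ValueError("SNR must be positive")

    @property
    def dwi_acq(self) -> DiffusionAcquisition:
        return DiffusionAcquisition(np.array(self.dwi_b))

    @property
    def dki_acq(self) -> DiffusionAcquisition:
        return DiffusionAcquisition(np.array(self.dki_b))

    @property
    def ivim_acq(self) -> DiffusionAcquisition:
        return DiffusionAcquisition(np.array(self.ivim_b))

    @property
    def dce_acq(self) -> DceAcquisition:
        return DceAcquisition.uniform(self.dce_n_frames, self.dce_dt_s, self.dce_n_baseline)

    def aif(self) -> ParkerAif:
        return ParkerAif(onset_s=self.dce_acq.onset_s)


def _lognorm_from_median_iqr(median: float, iqr: float):
    """(mu, sigma) of a log-normal with the given median and IQR."""
    mu = np.log(median)
    # IQR = median * (exp(z*s) - exp(-z*s)); solve for s
    r = iqr / median
    s = np.arcsinh(r / 2.0) / _Z75
    return mu, s


def _draw_marker(rng, dist: tuple, z: float, loading: float, sign: float,
                 bounds: tuple[float, float]) -> float:
    """One marker draw with a latent-factor contribution, truncated."""
    lam = loading * sign
    resid = np.sqrt(1.0 - loading**2)
    for _ in range(1000):
        u = lam * z + resid * rng.standard_normal()
        if dist[0] == "norm":
            v = dist[1] + dist[2] * u
        elif dist[0] == "lognorm":
            mu, s = _lognorm_from_median_iqr(dist[1], dist[2])
            v = float(np.exp(mu + s * u))
        else:
            raise ValueError(f"unknown distribution {dist[0]!r}")
        if bounds[0] <= v <= bounds[1]:
            return float(v)
        z = rng.standard_normal()  # fall back to an independent redraw
    raise RuntimeError("marker truncation failed")  # pragma: no cover


def _draw_categorical(rng, levels, counts, n: int):
    """n draws matching the given margins (exact when n == sum(counts))."""
    counts = np.asarray(counts, dtype=float)
    if n == int(counts.sum()):
        pool = np.repeat(np.arange(len(levels)), counts.astype(int))
        rng.shuffle(pool)
        return [levels[i] for i in pool]
    p = counts / counts.sum()
    return [levels[i] for i in rng.choice(len(levels), size=n, p=p)]


def tissue_params_from_markers(markers: dict, s0: float = 1000.0) -> TissueParams:
    """Reporting-scale marker dict -> physical TissueParams."""
    kt = markers["Ktrans"] * 1e-3
    kep = markers["Kep"] * 1e-3
    return TissueParams(
        S0=s0,
        ADC=markers["ADC"] * 1e-6,
        D=markers["MD"] * 1e-6,
        K=markers["MK"] * 1e-3,
        f=markers["PF"] * 1e-4,
        Dslow=markers["Dslow"] * 1e-6,
        Dfast=markers["Dfast"] * 1e-4,
        Ktrans=kt,
        Kep=kep,
    )


def _draw_patient_markers(rng, config: CohortConfig, group: str) -> dict:
    z = rng.standard_normal()  # latent aggressiveness
    markers = {}
    for name, per_group in config.pre_distributions.items():
        sign = _LATENT_SIGN.get(name, 0.0)
        loading = config.latent_loading if sign else 0.0
        markers[name] = _draw_marker(rng, per_group[group], z, loading,
                                     sign if sign else 1.0, _MARKER_BOUNDS[name])
    # keep the two-compartment model physical: Ve = Ktrans/Kep <= 1
    for _ in range(1000):
        if markers["Ktrans"] < 0.98 * markers["Kep"]:
            break
        markers["Ktrans"] = _draw_marker(rng, config.pre_distributions["Ktrans"][group],
                                         rng.standard_normal(), 0.0, 1.0,
                                         _MARKER_BOUNDS["Ktrans"])
        markers["Kep"] = _draw_marker(rng, config.pre_distributions["Kep"][group],
                                      rng.standard_normal(), 0.0, 1.0,
                                      _MARKER_BOUNDS["Kep"])
    markers["Ve"] = 1e3 * (markers["Ktrans"] * 1e-3) / (markers["Kep"] * 1e-3)
    return markers


def _apply_delta(rng, config: CohortConfig, group: str, markers: dict) -> dict:
    post = {}
    for name, pre_v in markers.items():
        if name == "Ve":
            continue
        mean, sd = config.delta_pct[name][group]
        for _ in range(1000):
            d = rng.normal(mean, sd)
            v = pre_v * (1.0 + d / 100.0)
            lo, hi = _MARKER_BOUNDS[name]
            if lo <= v <= hi:
                post[name] = float(v)
                break
        else:  # pragma: no cover
            post[name] = float(np.clip(pre_v, lo, hi))
    for _ in range(1000):
        if post["Ktrans"] < 0.98 * post["Kep"]:
            break
        post["Ktrans"] *= 0.9
    post["Ve"] = 1e3 * (post["Ktrans"] * 1e-3) / (post["Kep"] * 1e-3)
    return post


def lesion_mask(axes_mm, grid_shape, spacing_mm) -> np.ndarray:
    """Boolean ellipsoid mask centred on the grid (voxel-centre test)."""
    centre = (np.array(grid_shape) - 1) / 2.0
    coords = np.indices(grid_shape).astype(float)
    r = np.zeros(grid_shape)
    for axis in range(3):
        semi = max(axes_mm[axis], 1e-9)
        r += ((coords[axis] - centre[axis]) * spacing_mm[axis] / semi) ** 2
    return r <= 1.0


def largest_slice_mask(mask: np.ndarray) -> np.ndarray:
    """Restrict a 3-D mask to its largest axial (z) slice."""
    mask = np.asarray(mask, dtype=bool)
    counts = mask.sum(axis=(0, 1))
    z = int(np.argmax(counts))
    out = np.zeros_like(mask)
    out[:, :, z] = mask[:, :, z]
    return out


@lru_cache(maxsize=128)
def _matched_truncnorm_loc(target: float, sd: float, lo: float, hi: float) -> float:
    """Location of a truncated normal whose truncated mean equals target."""

    def mean_gap(m):
        a, b = (lo - m) / sd, (hi - m) / sd
        return _stats.truncnorm.mean(a, b, loc=m, scale=sd) - target

    return float(_optimize.brentq(mean_gap, target - 6 * sd, target + 6 * sd))


def _draw_truncnorm_matched(rng, target: float, sd: float, lo: float, hi: float) -> float:
    """Truncated-normal draw whose population mean is exactly ``target``."""
    m = _matched_truncnorm_loc(target, sd, lo, hi)
    for _ in range(100000):
        v = rng.normal(m, sd)
        if lo < v <= hi:
            return float(v)
    raise RuntimeError("truncated draw failed")  # pragma: no cover


def _lesion_geometry(rng, config: CohortConfig, group: str):
    """Draw pre/post ellipsoid axes and realised sizes for one patient.

    The diameter percent change is drawn from a truncated normal over
    the RECIST region of the intended group (responders shrink by at
    least 30%; non-responders are simulated as stable disease), with
    the location solved so the truncated mean matches the configured
    group mean.  The post-treatment cross-axes are sized so the
    discretised lesion voxel count matches the drawn volume change;
    recorded volumes come from the discretised masks, keeping the
    slice-stack volume formula an exact round trip.
    """
    kind, med, iqr = config.pre_diameter_cm
    mu, s = _lognorm_from_median_iqr(med, iqr)
    lo, hi = config.diameter_range_cm
    for _ in range(1000):
        d_pre = float(np.exp(rng.normal(mu, s)))
        if lo <= d_pre <= hi:
            break
    rb = rng.uniform(0.65, 0.85)
    rc = rng.uniform(0.6, 0.8)
    dd_mean, dd_sd = config.diameter_delta_pct[group]
    dd_lo, dd_hi = (-85.0, -30.0) if group == "RG" else (-29.999, 19.999)
    dd = _draw_truncnorm_matched(rng, dd_mean, dd_sd, dd_lo, dd_hi)
    cat, grp = recist_classify(dd, pre_diameter_cm=d_pre)
    assert grp == group
    dv_mean, dv_sd = config.volume_delta_pct[group]
    dv = _draw_truncnorm_matched(rng, dv_mean, dv_sd, -97.0, 150.0)
    d_post = d_pre * (1.0 + dd / 100.0)
    # pre axes (mm): a along x from the diameter, cross-axes by shape ratios
    a_pre = d_pre * 10.0 / 2.0
    axes_pre = (a_pre, rb * a_pre, rc * a_pre)
    mask_pre = lesion_mask(axes_pre, config.grid_shape, config.spacing_mm)
    n_pre = int(mask_pre.sum())
    # post cross-axes: start from the analytic volume-matching solution,
    # then rescale so the *discretised* voxel count hits the target, since
    # recorded volumes use the voxelised mask
    a_post = d_post * 10.0 / 2.0
    vol_scale = 1.0 + dv / 100.0
    cross = max(vol_scale * a_pre**3 * rb * rc / max(a_post, 1e-9), 1e-9)
    b0 = np.sqrt(cross * rb / rc)
    c0 = np.sqrt(cross * rc / rb)
    # choosing the cross-axis multiplier m so that exactly k voxels fall
    # inside reduces to an order statistic: a voxel is inside iff
    # (qy/b0^2 + qz/c0^2) <= (1 - qx/a^2) * m^2
    target_n = max(1, int(round(vol_scale * n_pre)))
    centre = (np.array(config.grid_shape) - 1) / 2.0
    coords = np.indices(config.grid_shape).astype(float)
    sq = [((coords[ax] - centre[ax]) * config.spacing_mm[ax]) ** 2 for ax in range(3)]
    along = sq[0] / max(a_post, 1e-9) ** 2
    cross_r = sq[1] / b0**2 + sq[2] / c0**2
    headroom = 1.0 - along
    valid = headroom > 0
    t = np.sort(cross_r[valid] / headroom[valid])
    # grid symmetry makes t values tie in groups; candidate counts are the
    # tie-group boundaries, so pick the boundary nearest the target
    uniq, first = np.unique(np.round(t, 12), return_index=True)
    cum = np.append(first[1:], t.size)  # count attained at each unique radius
    k = int(cum[np.argmin(np.abs(cum - min(target_n, t.size)))])
    mult = float(np.sqrt(max(t[k - 1], 1e-12)))
    mult = float(np.clip(mult, 0.3, 3.0))
    axes_post = (a_post, b0 * mult, c0 * mult)
    mask_post = lesion_mask(axes_post, config.grid_shape, config.spacing_mm)
    v_pre = volume_from_mask(mask_pre, config.spacing_mm, config.slice_gap_mm)
    v_post = volume_from_mask(mask_post, config.spacing_mm, config.slice_gap_mm)
    return {
        "axes_pre_mm": axes_pre, "axes_post_mm": axes_post,
        "d_pre_cm": d_pre, "d_post_cm": d_post, "cat": cat,
        "v_pre_cm3": v_pre, "v_post_cm3": v_post,
    }


def generate_cohort(config: CohortConfig | None = None) -> list[PatientRecord]:
    """Generate the full synthetic cohort (reproducible given the seed)."""
    config = config or CohortConfig()
    rng = np.random.default_rng(config.seed)
    groups = ["RG"] * config.n_responders + ["NRG"] * config.n_nonresponders
    sizes = {"RG": config.n_responders, "NRG": config.n_nonresponders}
    demo_by_group = {}
    for grp, n in sizes.items():
        cols = {"age": np.clip(rng.normal(*DEFAULT_AGE[grp], size=n), 18, 70).round(0)}
        for key, spec_ in DEFAULT_DEMOGRAPHICS.items():
            cols[key] = _draw_categorical(rng, spec_["levels"], spec_[grp], n)
        demo_by_group[grp] = cols
    counters = {"RG": 0, "NRG": 0}
    records = []
    for i, grp in enumerate(groups):
        markers_pre = _draw_patient_markers(rng, config, grp)
        markers_post = _apply_delta(rng, config, grp, markers_pre)
        geo = _lesion_geometry(rng, config, grp)
        k = counters[grp]
        counters[grp] += 1
        demo = {key: (vals[k] if not isinstance(vals, np.ndarray) else float(vals[k]))
                for key, vals in demo_by_group[grp].items()}
        records.append(PatientRecord(
            patient_id=f"P{i + 1:03d}",
            group=grp,
            recist=geo["cat"],
            pre_diameter_cm=geo["d_pre_cm"],
            post_diameter_cm=geo["d_post_cm"],
            pre_volume_cm3=geo["v_pre_cm3"],
            post_volume_cm3=geo["v_post_cm3"],
            markers_pre=markers_pre,
            markers_post=markers_post,
            demographics=demo,
            geometry={"axes_pre_mm": geo["axes_pre_mm"],
                      "axes_post_mm": geo["axes_post_mm"],
                      "render_seed": int(rng.integers(0, 2**31 - 1))},
        ))
    return records


def render_patient_images(record: PatientRecord, config: CohortConfig,
                          timepoint: str = "pre") -> dict:
    """Forward-model one patient's image set at one timepoint.

    Returns a dict with SignalVolumes ``dwi``/``dki``/``ivim`` (Rician
    noise), the DCE concentration volume ``dce`` (Gaussian noise), the
    lesion ``mask`` and its largest-axial-slice ``roi``.  Lesion voxels
    carry the patient's ground-truth parameters with mild within-tumor
    variability (log-normal, CV ``config.within_tumor_cv``); the
    background is homogeneous quiescent tissue.  Noise is seeded per
    patient and timepoint, so different patients get independent
    realisations while reruns are identical.
    """
    if timepoint not in ("pre", "post"):
        raise ValueError("timepoint must be 'pre' or 'post'")
    markers = record.markers_pre if timepoint == "pre" else record.markers_post
    axes = record.geometry[f"axes_{timepoint}_mm"]
    seed_base = record.geometry.get("render_seed", 0) + (0 if timepoint == "pre" else 1)
    rng = np.random.default_rng(np.random.SeedSequence([seed_base, 7]))
    mask = lesion_mask(axes, config.grid_shape, config.spacing_mm)
    n_vox = int(np.prod(config.grid_shape))
    cv = config.within_tumor_cv
    log_sd = np.sqrt(np.log(1.0 + cv**2)) if cv > 0 else 0.0

    vox = {}
    for name in BACKGROUND_MARKERS:
        base = np.full(config.grid_shape, BACKGROUND_MARKERS[name])
        jitter = np.exp(rng.normal(-0.5 * log_sd**2, log_sd, config.grid_shape)) if cv > 0 else 1.0
        base = np.where(mask, markers[name] * jitter, base)
        lo, hi = _MARKER_BOUNDS[name]
        vox[name] = np.clip(base, lo, hi)
    # physical units
    adc = vox["ADC"] * 1e-6
    d = vox["MD"] * 1e-6
    k = vox["MK"] * 1e-3
    f = np.clip(vox["PF"] * 1e-4, 0.0, 0.95)
    dslow = vox["Dslow"] * 1e-6
    dfast = np.maximum(vox["Dfast"] * 1e-4, dslow)
    ktrans = vox["Ktrans"] * 1e-3
    kep = vox["Kep"] * 1e-3
    ktrans = np.minimum(ktrans, 0.999 * kep)
    s0 = config.s0
    sigma = s0 / config.snr

    out = {"mask": mask, "roi": largest_slice_mask(mask)}
    for key, acq, model_args in (
        ("dwi", config.dwi_acq, ("adc",)),
        ("dki", config.dki_acq, ("dki",)),
        ("ivim", config.ivim_acq, ("ivim",)),
    ):
        b = acq.b_values
        if key == "dwi":
            sig = s0 * np.exp(-adc[..., None] * b)
        elif key == "dki":
            bd = b * d[..., None]
            sig = s0 * np.exp(-bd + bd**2 * k[..., None] / 6.0)
        else:
            tissue = (1.0 - f[..., None]) * np.exp(-b * dslow[..., None])
            blood = f[..., None] * np.exp(-b * (dslow + dfast)[..., None])
            sig = s0 * (tissue + blood)
        noisy = add_noise(sig, sigma, "rician", seed=rng)
        out[key] = SignalVolume(noisy, acq, config.spacing_mm)

    # DCE: per-voxel convolution only where Kep varies (lesion); the
    # homogeneous background shares one curve
    acq = config.dce_acq
    aif = config.aif()
    ct = np.zeros(config.grid_shape + (len(acq),))
    bg = tissue_params_from_markers(BACKGROUND_MARKERS, s0)
    ct[~mask] = tofts_concentration(bg, aif, acq)
    for i, j, z in np.argwhere(mask):
        p = TissueParams(S0=s0, Ktrans=ktrans[i, j, z], Kep=kep[i, j, z])
        ct[i, j, z] = tofts_concentration(p, aif, acq)
    ct = add_noise(ct, config.conc_noise_mM, "gaussian", seed=rng)
    out["dce"] = SignalVolume(np.maximum(ct, 0.0), acq, config.spacing_mm)
    return out


def cohort_to_frame(records: list[PatientRecord]) -> pd.DataFrame:
    """Long-format cohort table: one row per patient/timepoint/parameter."""
    rows = []
    for rec in records:
        for tp, markers, d_cm, v_cm3 in (
            ("pre", rec.markers_pre, rec.pre_diameter_cm, rec.pre_volume_cm3),
            ("post", rec.markers_post, rec.post_diameter_cm, rec.post_volume_cm3),
        ):
            for name, value in markers.items():
                rows.append({
                    "patient_id": rec.patient_id, "timepoint": tp,
                    "parameter": name, "mean": value,
                    "median": np.nan, "iqr": np.nan,
                    "diameter_cm": d_cm, "volume_cm3": v_cm3,
                    "group": rec.group, "recist": rec.recist,
                })
    return pd.DataFrame(rows)
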