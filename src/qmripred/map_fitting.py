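"""Voxel-wise inverse problems: parameter maps from 4-D signal volumes.

Each fitter consumes a :class:`SignalVolume` (voxel grid x measurement
axis) and returns :class:`ParameterMap` objects in the conventional
reporting scales (e.g. ADC reported as x1e-6 mm^2/s).  Fitting follows
the common quantitative-MRI practice:

* ADC — ordinary least squares of log-signal on b (two-variable linear
  fit of S0 and ADC);
* DKI — bounded nonlinear least squares on the kurtosis model, seeded
  by an exact log-quadratic estimate;
* IVIM — segmented fit: mono-exponential on b >= b_threshold for Dslow,
  perfusion fraction from the intercept deficit at b = 0, then a
  bounded one-parameter fit of Dfast on the full curve (a joint
  four-parameter fit is provided as an independent cross-check);
* Tofts — bounded nonlinear least squares of (Ktrans, Kep) on the
  concentration curve, with Ve = Ktrans/Kep.

Voxels that cannot be fitted (non-positive signals, too few samples,
non-convergence) are flagged out of the fitted mask rather than
imputed; masked-out voxels never influence their neighbours.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import optimize

from .signal_models import (
    AifModel,
    DceAcquisition,
    DiffusionAcquisition,
    aif_exp_convolution,
)

__all__ = [
    "SignalVolume",
    "ParameterMap",
    "REPORTING_SCALE",
    "fit_adc",
    "fit_dki",
    "fit_ivim_segmented",
    "fit_ivim_joint",
    "fit_tofts",
]

#: Conventional reporting scales: reported value = physical value / scale.
#: ADC/MD/Dslow in x1e-6 mm^2/s, Dfast and PF in x1e-4, MK and the DCE
#: parameters in x1e-3 (Ktrans/Kep per minute, Ve a fraction).
REPORTING_SCALE: dict[str, float] = {
    "S0": 1.0,
    "ADC": 1e-6,
    "MD": 1e-6,
    "MK": 1e-3,
    "Dslow": 1e-6,
    "Dfast": 1e-4,
    "PF": 1e-4,
    "Ktrans": 1e-3,
    "Kep": 1e-3,
    "Ve": 1e-3,
}


@dataclass
class SignalVolume:
    """A 4-D signal array: 3-D voxel grid x measurement axis.

    ``spacing_mm`` is the voxel size; the last axis must match the
    acquisition length (b-values or DCE frames).
    """

    data: np.ndarray
    acquisition: DiffusionAcquisition | DceAcquisition
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("signal volume must be 4-D (x, y, z, measurement)")
        if self.data.shape[-1] != len(self.acquisition):
            raise ValueError("measurement axis does not match acquisition length")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("voxel spacing must be positive")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    def to_nifti(self, path: str | Path) -> None:
        affine = np.diag(list(self.spacing_mm) + [1.0])
        nib.save(nib.Nifti1Image(self.data.astype(np.float32), affine), str(path))

    @classmethod
    def from_nifti(cls, path: str | Path, acquisition) -> "SignalVolume":
        img = nib.load(str(path))
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        return cls(np.asarray(img.dataobj, dtype=float), acquisition, spacing)


@dataclass
class ParameterMap:
    """A named voxel grid of one fitted parameter.

    ``values`` are stored in physical units; :meth:`reported` applies
    the reporting scale.  ``mask`` marks voxels with a valid fit and
    ``residual`` holds the per-voxel residual norm of that fit.
    """

    name: str
    values: np.ndarray
    mask: np.ndarray
    scale: float = 1.0
    residual: np.ndarray | None = None
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask shapes differ")
        if self.scale <= 0:
            raise ValueError("reporting scale must be positive")
        if not np.all(np.isfinite(self.values[self.mask])):
            raise ValueError("non-finite values inside the fitted mask")

    def reported(self) -> np.ndarray:
        """Values on the reporting scale (NaN outside the fitted mask)."""
        out = np.where(self.mask, self.values / self.scale, np.nan)
        return out

    def to_nifti(self, path: str | Path) -> None:
        path = Path(path)
        affine = np.diag(list(self.spacing_mm) + [1.0])
        img = nib.Nifti1Image(self.reported().astype(np.float32), affine)
        img.header["descrip"] = f"{self.name} x{self.scale:g}".encode()[:79]
        nib.save(img, str(path))
        sidecar = {"parameter": self.name, "scale": self.scale,
                   "convention": "stored = physical / scale"}
        path.with_suffix("").with_suffix(".json").write_text(json.dumps(sidecar))

    @classmethod
    def from_nifti(cls, path: str | Path) -> "ParameterMap":
        path = Path(path)
        img = nib.load(str(path))
        meta = json.loads(path.with_suffix("").with_suffix(".json").read_text())
        reported = np.asarray(img.dataobj, dtype=float)
        mask = np.isfinite(reported)
        values = np.where(mask, reported * meta["scale"], 0.0)
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        return cls(meta["parameter"], values, mask, meta["scale"], spacing_mm=spacing)


def _prepare_mask(vol: SignalVolume, mask, min_points: int) -> np.ndarray:
    """Voxels eligible for fitting: inside mask with all-positive signals."""
    base = np.ones(vol.grid_shape, dtype=bool) if mask is None else np.asarray(mask, dtype=bool)
    if base.shape != vol.grid_shape:
        raise ValueError("mask shape does not match the voxel grid")
    positive = np.all(vol.data > 0, axis=-1)
    enough = vol.data.shape[-1] >= min_points
    return base & positive & enough


def _loglinear(signals: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised OLS of log-signal on b: returns (ln S0, decay rate)."""
    logs = np.log(signals)
    X = np.column_stack([np.ones_like(b), -b])
    coef, *_ = np.linalg.lstsq(X, logs.T, rcond=None)
    return coef[0], coef[1]


def fit_adc(
    signals: SignalVolume,
    acq: DiffusionAcquisition | None = None,
    mask: np.ndarray | None = None,
) -> tuple[ParameterMap, ParameterMap]:
    """Mono-exponential (ADC) fit by linear least squares on log-signal.

    With exactly two b-values this reduces to
    ADC = ln(S(b1)/S(b2)) / (b2 - b1).  Returns the ADC map (x1e-6
    mm^2/s reporting scale) and the fitted S0 map.
    """
    acq = acq or signals.acquisition
    b = acq.b_values
    fit_mask = _prepare_mask(signals, mask, 2)
    adc = np.zeros(signals.grid_shape)
    s0 = np.zeros(signals.grid_shape)
    res = np.zeros(signals.grid_shape)
    if fit_mask.any():
        series = signals.data[fit_mask]
        ln_s0, rate = _loglinear(series, b)
        pred = np.exp(ln_s0)[:, None] * np.exp(-np.outer(rate, b))
        adc[fit_mask] = rate
        s0[fit_mask] = np.exp(ln_s0)
        res[fit_mask] = np.linalg.norm(series - pred, axis=1)
    common = dict(mask=fit_mask, residual=res, spacing_mm=signals.spacing_mm)
    return (
        ParameterMap("ADC", adc, scale=REPORTING_SCALE["ADC"], **common),
        ParameterMap("S0", s0, scale=1.0, **common),
    )


_DKI_BOUNDS = ((1e-12, 1e-5, 0.0), (np.inf, 4e-3, 3.0))  # S0, D, K


def _dki_residual(theta, b, y):
    s0, d, k = theta
    return s0 * np.exp(-b * d + (b * d) ** 2 * k / 6.0) - y


def _dki_jac(theta, b, y):
    s0, d, k = theta
    e = np.exp(-b * d + (b * d) ** 2 * k / 6.0)
    return np.column_stack([
        e,
        s0 * e * (-b + b**2 * d * k / 3.0),
        s0 * e * (b * d) ** 2 / 6.0,
    ])


def fit_dki(
    signals: SignalVolume,
    acq: DiffusionAcquisition | None = None,
    mask: np.ndarray | None = None,
) -> tuple[ParameterMap, ParameterMap, ParameterMap]:
    """Kurtosis-model fit: bounded NLS of (S0, D, K) per voxel.

    Requires >= 4 b-values.  Seeds from the exact log-quadratic
    estimate (ln S is quadratic in b under the model), then refines
    with trust-region least squares under D in [1e-5, 4e-3] mm^2/s and
    K in [0, 3] — the upper kurtosis bound keeps the fitted decay
    monotone over clinical b ranges.  Returns (MD, MK, S0) maps.
    """
    acq = acq or signals.acquisition
    b = acq.b_values
    if b.size < 4:
        raise ValueError("DKI fitting needs at least 4 b-values")
    fit_mask = _prepare_mask(signals, mask, 4)
    md = np.zeros(signals.grid_shape)
    mk = np.zeros(signals.grid_shape)
    s0 = np.zeros(signals.grid_shape)
    res = np.zeros(signals.grid_shape)
    lo, hi = np.array(_DKI_BOUNDS[0]), np.array(_DKI_BOUNDS[1])
    quad = np.column_stack([np.ones_like(b), -b, b**2 / 6.0])
    for idx in np.argwhere(fit_mask):
        i, j, k_ = idx
        y = signals.data[i, j, k_]
        coef, *_ = np.linalg.lstsq(quad, np.log(y), rcond=None)
        d0 = float(np.clip(coef[1], lo[1], hi[1]))
        k0 = float(np.clip(coef[2] / d0**2 if d0 > 0 else 0.0, lo[2], hi[2]))
        x0 = np.clip([np.exp(coef[0]), d0, k0], lo, hi * 0.999 + lo * 0.001)
        try:
            sol = optimize.least_squares(
                _dki_residual, x0, jac=_dki_jac, bounds=(lo, hi), args=(b, y),
                xtol=1e-12, ftol=1e-12, gtol=1e-12,
            )
        except Exception:
            fit_mask[i, j, k_] = False
            continue
        if not sol.success:
            fit_mask[i, j, k_] = False
            continue
        s0[i, j, k_], md[i, j, k_], mk[i, j, k_] = sol.x
        res[i, j, k_] = np.linalg.norm(sol.fun)
    common = dict(mask=fit_mask, residual=res, spacing_mm=signals.spacing_mm)
    return (
        ParameterMap("MD", md, scale=REPORTING_SCALE["MD"], **common),
        ParameterMap("MK", mk, scale=REPORTING_SCALE["MK"], **common),
        ParameterMap("S0", s0, scale=1.0, **common),
    )


def fit_ivim_segmented(
    signals: SignalVolume,
    acq: DiffusionAcquisition | None = None,
    b_threshold: float = 200.0,
    mask: np.ndarray | None = None,
) -> tuple[ParameterMap, ParameterMap, ParameterMap, ParameterMap]:
    """Segmented IVIM fit (Dslow, Dfast, PF, S0).

    Step 1: mono-exponential OLS on b >= b_threshold, where the
    perfusion pool has decayed away, gives Dslow and an intercept
    A = S0 * (1 - f).  Step 2: f = 1 - A / S(0).  Step 3: bounded
    one-parameter least squares of Dfast over [max(Dslow, 1e-3), 0.5]
    mm^2/s on the full curve with the other parameters held.  f is
    clipped into [0, 1]; voxels where it was clipped, or with f ~ 0
    (no perfusion signal to constrain Dfast), keep Dslow but have the
    perfusion parameters flagged unfit in the Dfast map mask.
    """
    acq = acq or signals.acquisition
    b = acq.b_values
    high = b >= b_threshold
    if high.sum() < 3 or (~high).sum() < 2:
        raise ValueError("need >= 3 b-values at/above threshold and >= 2 below")
    fit_mask = _prepare_mask(signals, mask, 6)
    shape = signals.grid_shape
    dslow = np.zeros(shape)
    dfast = np.zeros(shape)
    pf = np.zeros(shape)
    s0 = np.zeros(shape)
    res = np.zeros(shape)
    perf_mask = fit_mask.copy()
    if fit_mask.any():
        series = signals.data[fit_mask]
        ln_a, rate = _loglinear(series[:, high], b[high])
        rate = np.maximum(rate, 0.0)
        a = np.exp(ln_a)
        f = 1.0 - a / series[:, 0]
        clipped = (f < 0.0) | (f > 1.0)
        f = np.clip(f, 0.0, 1.0)
        s0_vox = np.where(f < 1.0, a / (1.0 - np.minimum(f, 1.0 - 1e-12)), series[:, 0])
        dslow[fit_mask] = rate
        pf[fit_mask] = f
        s0[fit_mask] = s0_vox
        degenerate = clipped | (f < 1e-6)
        idxs = np.argwhere(fit_mask)
        for row, (i, j, k_) in enumerate(idxs):
            if degenerate[row]:
                perf_mask[i, j, k_] = False
                continue
            y = series[row]
            fv, dv, s0v = f[row], rate[row], s0_vox[row]
            lo = max(dv, 1e-3)

            def sse(dfast_v):
                pred = s0v * ((1 - fv) * np.exp(-b * dv) + fv * np.exp(-b * (dv + dfast_v)))
                return float(np.sum((pred - y) ** 2))

            sol = optimize.minimize_scalar(sse, bounds=(lo, 0.5), method="bounded",
                                           options={"xatol": 1e-9})
            dfast[i, j, k_] = sol.x
            res[i, j, k_] = np.sqrt(sol.fun)
    common = dict(spacing_mm=signals.spacing_mm)
    return (
        ParameterMap("Dslow", dslow, mask=fit_mask, residual=res,
                     scale=REPORTING_SCALE["Dslow"], **common),
        ParameterMap("Dfast", dfast, mask=perf_mask, residual=res,
                     scale=REPORTING_SCALE["Dfast"], **common),
        ParameterMap("PF", pf, mask=fit_mask, residual=res,
                     scale=REPORTING_SCALE["PF"], **common),
        ParameterMap("S0", s0, mask=fit_mask, residual=res, scale=1.0, **common),
    )


def fit_ivim_joint(
    signals: SignalVolume,
    acq: DiffusionAcquisition | None = None,
    mask: np.ndarray | None = None,
) -> tuple[ParameterMap, ParameterMap, ParameterMap, ParameterMap]:
    """Joint four-parameter IVIM fit (independent cross-check).

    Bounded NLS over (S0, f, Dslow, Dfast) seeded from the segmented
    estimates.  Slower but free of the segmented approximation; used to
    validate the segmented route.
    """
    seg = fit_ivim_segmented(signals, acq, mask=mask)
    acq = acq or signals.acquisition
    b = acq.b_values
    dslow_m, dfast_m, pf_m, s0_m = seg
    fit_mask = dslow_m.mask.copy()
    shape = signals.grid_shape
    out = {n: np.zeros(shape) for n in ("Dslow", "Dfast", "PF", "S0")}
    res = np.zeros(shape)
    lo = np.array([1e-12, 0.0, 1e-6, 1e-3])
    hi = np.array([np.inf, 1.0, 4e-3, 0.5])

    def residual(theta, y):
        s0v, fv, dv, dfv = theta
        return s0v * ((1 - fv) * np.exp(-b * dv) + fv * np.exp(-b * (dv + dfv))) - y

    for i, j, k_ in np.argwhere(fit_mask):
        y = signals.data[i, j, k_]
        x0 = np.clip(
            [s0_m.values[i, j, k_], pf_m.values[i, j, k_],
             dslow_m.values[i, j, k_], max(dfast_m.values[i, j, k_], 5e-3)],
            lo, hi,
        )
        sol = optimize.least_squares(residual, x0, bounds=(lo, hi), args=(y,),
                                     xtol=1e-12, ftol=1e-12)
        if not sol.success:
            fit_mask[i, j, k_] = False
            continue
        out["S0"][i, j, k_], out["PF"][i, j, k_], out["Dslow"][i, j, k_], out["Dfast"][i, j, k_] = sol.x
        res[i, j, k_] = np.linalg.norm(sol.fun)
    common = dict(mask=fit_mask, residual=res, spacing_mm=signals.spacing_mm)
    return (
        ParameterMap("Dslow", out["Dslow"], scale=REPORTING_SCALE["Dslow"], **common),
        ParameterMap("Dfast", out["Dfast"], scale=REPORTING_SCALE["Dfast"], **common),
        ParameterMap("PF", out["PF"], scale=REPORTING_SCALE["PF"], **common),
        ParameterMap("S0", out["S0"], scale=1.0, **common),
    )


def fit_tofts(
    conc: SignalVolume,
    aif: AifModel,
    acq: DceAcquisition | None = None,
    mask: np.ndarray | None = None,
) -> tuple[ParameterMap, ParameterMap, ParameterMap]:
    """Two-compartment (Tofts) fit of concentration curves.

    Bounded NLS over Ktrans in [0, 5] /min and Kep in [1e-3, 10] /min;
    Ve = Ktrans/Kep (flagged out of the Ve mask when > 1).  The model
    curve is Ktrans times a unit-Ktrans convolution of the AIF, so
    Ktrans is re-estimated in closed form at each Kep evaluation.
    All-zero voxels get Ktrans = 0 without a nonlinear fit.
    """
    acq = acq or conc.acquisition
    t = acq.frame_times
    base = np.ones(conc.grid_shape, dtype=bool) if mask is None else np.asarray(mask, dtype=bool)
    fit_mask = base & np.all(np.isfinite(conc.data), axis=-1)
    shape = conc.grid_shape
    ktrans = np.zeros(shape)
    kep = np.full(shape, 1.0)
    res = np.zeros(shape)
    if not np.any(aif(t) > 0):
        raise ValueError("AIF is identically zero over the acquisition")

    def unit_curve(kep_v: float) -> np.ndarray:
        return aif_exp_convolution(aif, acq, kep_v)

    def residual(theta, y):
        kt, ke = theta
        return kt * unit_curve(ke) - y

    for i, j, k_ in np.argwhere(fit_mask):
        y = conc.data[i, j, k_]
        if np.max(np.abs(y)) <= 0:
            ktrans[i, j, k_] = 0.0
            continue
        # linear init of Ktrans at a nominal Kep, then bounded refinement
        best = None
        for ke0 in (0.3, 1.0, 3.0):
            u = unit_curve(ke0)
            kt0 = float(np.clip(np.dot(u, y) / max(np.dot(u, u), 1e-30), 1e-6, 5.0))
            sse = float(np.sum((kt0 * u - y) ** 2))
            if best is None or sse < best[0]:
                best = (sse, kt0, ke0)
        sol = optimize.least_squares(
            residual, x0=[best[1], best[2]], bounds=([0.0, 1e-3], [5.0, 10.0]),
            args=(y,), xtol=1e-12, ftol=1e-12,
        )
        if not sol.success:
            fit_mask[i, j, k_] = False
            continue
        ktrans[i, j, k_], kep[i, j, k_] = sol.x
        res[i, j, k_] = np.linalg.norm(sol.fun)
    ve = np.where(kep > 0, ktrans / kep, 0.0)
    ve_mask = fit_mask & (ve <= 1.0)
    common = dict(residual=res, spacing_mm=conc.spacing_mm)
    return (
        ParameterMap("Ktrans", ktrans, mask=fit_mask, scale=REPORTING_SCALE["Ktrans"], **common),
        ParameterMap("Kep", kep, mask=fit_mask, scale=REPORTING_SCALE["Kep"], **common),
        ParameterMap("Ve", ve, mask=ve_mask, scale=REPORTING_SCALE["Ve"], **common),
    )
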