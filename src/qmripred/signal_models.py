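"""Forward signal models for quantitative MRI.

Four voxel-level models are implemented:

* mono-exponential diffusion decay (the ADC model),
* the diffusion-kurtosis expansion (DKI; parameters D and K),
* the bi-exponential intravoxel-incoherent-motion model (IVIM;
  perfusion fraction f, tissue diffusivity Dslow, pseudo-diffusion Dfast),
* the standard two-compartment (Tofts) pharmacokinetic model for
  DCE-MRI concentration curves, driven by an arterial input function.

These are the ground-truth generators for every fitting routine in
:mod:`qmripred.map_fitting`; all take parameters in physical units
(diffusivities in mm^2/s, rate constants in 1/min) and are vectorised
over the measurement axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "DiffusionAcquisition",
    "DceAcquisition",
    "TissueParams",
    "AifModel",
    "StepAif",
    "ParkerAif",
    "dwi_signal",
    "dki_signal",
    "ivim_signal",
    "tofts_concentration",
    "aif_exp_convolution",
    "add_noise",
]


@dataclass(frozen=True)
class DiffusionAcquisition:
    """A set of diffusion weightings (b-values, s/mm^2).

    Must contain b = 0, be strictly increasing and non-negative.  Model
    fitting imposes further minima (>= 2 b-values for ADC, >= 4 for DKI,
    >= 6 for segmented IVIM).
    """

    b_values: np.ndarray

    def __post_init__(self) -> None:
        b = np.asarray(self.b_values, dtype=float)
        if b.ndim != 1 or b.size < 2:
            raise ValueError("need a 1-D array of at least two b-values")
        if np.any(b < 0):
            raise ValueError("b-values must be non-negative")
        if b[0] != 0.0:
            raise ValueError("acquisition must include b = 0 as the first entry")
        if np.any(np.diff(b) <= 0):
            raise ValueError("b-values must be strictly increasing")
        object.__setattr__(self, "b_values", b)

    def __len__(self) -> int:
        return self.b_values.size


@dataclass(frozen=True)
class DceAcquisition:
    """Frame times (s) of a dynamic contrast-enhanced series.

    ``n_baseline`` frames are acquired before contrast arrival; the
    injection onset is taken at the first post-baseline frame.
    """

    frame_times: np.ndarray
    n_baseline: int = 1

    def __post_init__(self) -> None:
        t = np.asarray(self.frame_times, dtype=float)
        if t.ndim != 1 or t.size < 2:
            raise ValueError("need a 1-D array of at least two frame times")
        if np.any(np.diff(t) <= 0):
            raise ValueError("frame times must be strictly increasing")
        if not (1 <= self.n_baseline < t.size):
            raise ValueError("n_baseline must be >= 1 and < number of frames")
        object.__setattr__(self, "frame_times", t)

    def __len__(self) -> int:
        return self.frame_times.size

    @property
    def onset_s(self) -> float:
        """Contrast arrival time: the first enhanced frame."""
        return float(self.frame_times[self.n_baseline])

    @classmethod
    def uniform(cls, n_frames: int = 35, dt_s: float = 8.1, n_baseline: int = 4) -> "DceAcquisition":
        return cls(np.arange(n_frames) * dt_s, n_baseline=n_baseline)


@dataclass(frozen=True)
class TissueParams:
    """Per-voxel tissue parameters for all four signal models.

    Units: S0 arbitrary; ADC, D, Dslow, Dfast in mm^2/s; K and f
    dimensionless; Ktrans and Kep in 1/min; Ve dimensionless
    (Ve = Ktrans/Kep by definition).
    """

    S0: float = 1.0
    ADC: float = 0.0
    D: float = 0.0
    K: float = 0.0
    f: float = 0.0
    Dslow: float = 0.0
    Dfast: float = 0.0
    Ktrans: float = 0.0
    Kep: float = 0.0
    Ve: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.S0 <= 0:
            raise ValueError("S0 must be positive")
        for name in ("ADC", "D", "Dslow", "Dfast", "K", "Ktrans", "Kep"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 <= self.f <= 1.0:
            raise ValueError("perfusion fraction f must lie in [0, 1]")
        if self.Dfast and self.Dfast < self.Dslow:
            raise ValueError("Dfast must be >= Dslow")
        ve = self.Ve
        if ve is None:
            ve = self.Ktrans / self.Kep if self.Kep > 0 else 0.0
            object.__setattr__(self, "Ve", ve)
        elif self.Kep > 0 and not np.isclose(ve, self.Ktrans / self.Kep, rtol=1e-6, atol=1e-12):
            raise ValueError("Ve must equal Ktrans/Kep when Kep > 0")
        if not 0.0 <= self.Ve <= 1.0 + 1e-12:
            raise ValueError("Ve must lie in [0, 1]")


class AifModel:
    """Arterial input function: plasma concentration Cp(t) in mM.

    Subclasses implement :meth:`concentration` on a time axis in
    seconds.  Concentration is zero before ``onset_s`` and non-negative
    everywhere.
    """

    name: str = "aif"

    def __init__(self, onset_s: float = 0.0):
        self.onset_s = float(onset_s)

    def concentration(self, t_s: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def __call__(self, t_s) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t_s, dtype=float))
        c = np.where(t >= self.onset_s, self.concentration(t), 0.0)
        return np.maximum(c, 0.0)

    @property
    def parameters(self) -> dict:
        return {"onset_s": self.onset_s}


class StepAif(AifModel):
    """Constant plasma concentration from onset onward.

    Exists for closed-form testing: with a step input the Tofts
    convolution integrates to Ve * amplitude * (1 - exp(-Kep * t)).
    """

    name = "step"

    def __init__(self, amplitude_mM: float = 1.0, onset_s: float = 0.0):
        super().__init__(onset_s)
        self.amplitude_mM = float(amplitude_mM)

    def concentration(self, t_s: np.ndarray) -> np.ndarray:
        return np.full_like(t_s, self.amplitude_mM, dtype=float)

    @property
    def parameters(self) -> dict:
        return {"amplitude_mM": self.amplitude_mM, "onset_s": self.onset_s}


class ParkerAif(AifModel):
    """Population-average arterial input function (Parker 2006 form).

    Sum of two Gaussian boluses plus an exponential washout modulated by
    a sigmoid; coefficients are the published population values, time
    measured in minutes from onset.
    """

    name = "parker"

    _A = (0.809, 0.330)       # mM * min
    _T = (0.17046, 0.365)     # min
    _SIGMA = (0.0563, 0.132)  # min
    _ALPHA = 1.050            # mM
    _BETA = 0.1685            # 1/min
    _S = 38.078               # 1/min
    _TAU = 0.483              # min

    def concentration(self, t_s: np.ndarray) -> np.ndarray:
        t = (t_s - self.onset_s) / 60.0  # min since onset
        c = np.zeros_like(t)
        for a, mu, sig in zip(self._A, self._T, self._SIGMA):
            c += a / (sig * np.sqrt(2 * np.pi)) * np.exp(-((t - mu) ** 2) / (2 * sig**2))
        c += self._ALPHA * np.exp(-self._BETA * t) / (1.0 + np.exp(-self._S * (t - self._TAU)))
        return c


def _check_b(b) -> np.ndarray:
    b = np.asarray(b, dtype=float)
    if np.any(b < 0):
        raise ValueError("b-values must be non-negative")
    return b


def dwi_signal(params: TissueParams, b) -> np.ndarray:
    """Mono-exponential diffusion signal S = S0 * exp(-b * ADC)."""
    b = _check_b(b)
    return params.S0 * np.exp(-b * params.ADC)


def dki_signal(params: TissueParams, b) -> np.ndarray:
    """Kurtosis signal S = S0 * exp(-b*D + (1/6) * b^2 * D^2 * K).

    At K = 0 this reduces to the mono-exponential model with ADC = D.
    The quadratic exponent is a truncated cumulant expansion; it is only
    a decreasing function of b for b < 3 / (D*K), which the fitting
    bounds respect.
    """
    b = _check_b(b)
    return params.S0 * np.exp(-b * params.D + (b**2) * (params.D**2) * params.K / 6.0)


def ivim_signal(params: TissueParams, b) -> np.ndarray:
    """Bi-exponential IVIM signal.

    S/S0 = (1 - f) * exp(-b * Dslow) + f * exp(-b * (Dslow + Dfast)),
    i.e. a tissue water pool decaying at Dslow and a perfusing blood
    pool whose apparent decay rate adds the pseudo-diffusion Dfast.
    """
    b = _check_b(b)
    if not 0.0 <= params.f <= 1.0:
        raise ValueError("perfusion fraction f must lie in [0, 1]")
    tissue = (1.0 - params.f) * np.exp(-b * params.Dslow)
    blood = params.f * np.exp(-b * (params.Dslow + params.Dfast))
    return params.S0 * (tissue + blood)


def aif_exp_convolution(
    aif: AifModel,
    acq: DceAcquisition,
    kep_per_min: float,
    refine: int = 20,
) -> np.ndarray:
    """Unit-Ktrans Tofts convolution of the AIF at the frame times.

    Evaluates integral_0^t Cp(tau) * exp(-Kep * (t - tau)) dtau (times
    in minutes inside the integral), exactly for a piecewise-linear Cp
    on a grid refined ``refine``-fold relative to the frame spacing.
    """
    t = acq.frame_times
    dt = np.min(np.diff(t)) / refine
    fine = np.arange(0.0, t[-1] + dt / 2, dt)
    # ensure onset and frame times are grid points so Cp kinks are exact
    fine = np.union1d(fine, np.append(t, aif.onset_s))
    cp = aif(fine)
    k = kep_per_min / 60.0
    h = np.diff(fine)
    c0, c1 = cp[:-1], cp[1:]
    slope = (c1 - c0) / h
    # int_0^h (c0 + slope*s) * exp(-k*(h-s)) ds, exact for linear Cp; the
    # trapezoid limit avoids catastrophic cancellation on tiny intervals
    # (duplicate-like grid points from merging frame times into the grid)
    e = np.exp(-k * h)
    small = k * h < 1e-6
    with np.errstate(divide="ignore", invalid="ignore"):
        exact = c0 * (1.0 - e) / k + slope * (h - (1.0 - e) / k) / k
    integrals = np.where(small, 0.5 * (c0 + c1) * h, exact)
    # linear recurrence ct[i] = ct[i-1]*exp(-k*h[i]) + I[i], solved with
    # cumulative exponentials; safe for k * total duration < ~700
    kt_nodes = k * np.cumsum(np.concatenate([[0.0], h]))
    if kt_nodes[-1] < 600.0:
        weighted = np.concatenate([[0.0], integrals * np.exp(kt_nodes[1:])])
        ct = np.exp(-kt_nodes) * np.cumsum(weighted)
    else:  # pragma: no cover - extreme decay, loop to avoid overflow
        ct = np.zeros_like(fine)
        for i in range(1, fine.size):
            ct[i] = ct[i - 1] * np.exp(-k * h[i - 1]) + integrals[i - 1]
    ct /= 60.0  # integral taken on the seconds axis; rates are per minute
    return np.interp(t, fine, ct)


def tofts_concentration(
    params: TissueParams,
    aif: AifModel,
    acq: DceAcquisition,
    refine: int = 20,
) -> np.ndarray:
    """Tissue concentration under the two-compartment (Tofts) model.

    Ct(t) = Ktrans * integral_0^t Cp(tau) * exp(-Kep * (t - tau)) dtau,
    with rate constants in 1/min and times in seconds.  With the
    default grid refinement the step-AIF closed form is reproduced to
    better than 1e-6 relative.
    """
    if params.Ktrans > 0 and params.Kep <= 0:
        raise ValueError("Kep must be positive when Ktrans > 0")
    if params.Ktrans == 0.0:
        return np.zeros_like(acq.frame_times)
    return params.Ktrans * aif_exp_convolution(aif, acq, params.Kep, refine=refine)


def add_noise(
    series,
    sigma: float,
    model: str = "rician",
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Add measurement noise to a signal series.

    ``rician`` emulates magnitude MRI reconstruction: the noiseless
    signal plus complex Gaussian noise, magnitude taken, so the output
    is non-negative and positively biased at low SNR (pure-noise mean
    sigma * sqrt(pi/2)).  ``gaussian`` is plain additive noise, used for
    derived concentration curves.  Reproducible given a seed; sigma = 0
    returns the input unchanged.
    """
    x = np.asarray(series, dtype=float)
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if sigma == 0:
        return x.copy()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if model == "gaussian":
        return x + rng.normal(0.0, sigma, x.shape)
    if model == "rician":
        re = x + rng.normal(0.0, sigma, x.shape)
        im = rng.normal(0.0, sigma, x.shape)
        return np.hypot(re, im)
    raise ValueError(f"unknown noise model {model!r}")
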