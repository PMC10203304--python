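"""Time-series and normalization rate estimators.

Covers: gross photosynthesis from light–dark shifts, denitrification and
nitrification from closed-vial ¹⁵N tracer series, microsensor
calibration, scalar-irradiance attenuation metrics, volumetric
normalization of ¹⁴C microradiograph counts, and per-reactor scaling.

All linear fits are ordinary least squares *with* intercept (blanks at
timepoint 0 may be nonzero) and report the standard error of the slope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import stats

from .core import PhotogranuleError, RateEstimate, ValidationError

__all__ = [
    "DarkShiftSeries",
    "IsotopeTimeSeries",
    "SpectralIrradianceProfile",
    "RadiographSummary",
    "AttenuationResult",
    "Calibration",
    "CalibrationError",
    "gross_photosynthesis",
    "excess_15n_total",
    "denitrification_rate",
    "nitrification_rate",
    "calibrate_sensor",
    "light_attenuation",
    "radiograph_volumetric_rate",
    "reactor_scale_rate",
    "nox_amount_nmol",
]


class CalibrationError(PhotogranuleError):
    """Calibration standards are unusable (non-monotone, too few, ...)."""


# -- domain types -----------------------------------------------------------


@dataclass(frozen=True)
class DarkShiftSeries:
    """Oxygen concentration versus time after darkening, at one depth."""

    depth_um: float
    times_s: np.ndarray
    conc_umol_per_l: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times_s, dtype=float)
        c = np.asarray(self.conc_umol_per_l, dtype=float)
        object.__setattr__(self, "times_s", t)
        object.__setattr__(self, "conc_umol_per_l", c)
        if t.shape != c.shape or t.ndim != 1:
            raise ValidationError("times and concentrations must be 1-D and equal length")
        if np.any(np.diff(t) <= 0):
            raise ValidationError("dark-shift times must be strictly increasing")


@dataclass(frozen=True)
class IsotopeTimeSeries:
    """Closed-vial ²⁹/³⁰N₂ excess and NOₓ amounts over time (nmol, h).

    The first timepoint serves as the blank.  ``label`` records which
    substrate carried the ¹⁵N label (ammonium or nitrate).
    """

    times_h: np.ndarray
    excess29_nmol: np.ndarray
    excess30_nmol: np.ndarray
    nox_nmol: np.ndarray
    label: str = "ammonium"
    light: bool = False
    acetate: bool = False

    def __post_init__(self) -> None:
        arrays = {}
        for name in ("times_h", "excess29_nmol", "excess30_nmol", "nox_nmol"):
            arrays[name] = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, arrays[name])
        n = arrays["times_h"].size
        if any(a.ndim != 1 or a.size != n for a in arrays.values()):
            raise ValidationError("isotope series columns must be 1-D and equal length")
        if np.any(arrays["times_h"] < 0) or np.any(np.diff(arrays["times_h"]) <= 0):
            raise ValidationError("times must be non-negative and strictly increasing")
        for name in ("excess29_nmol", "excess30_nmol", "nox_nmol"):
            if np.any(arrays[name] < 0):
                raise ValidationError(f"{name} contains negative amounts")

    @property
    def n_points(self) -> int:
        return int(self.times_h.size)

    @property
    def total_excess_15n_nmol(self) -> np.ndarray:
        """Total excess ¹⁵N per timepoint: excess ²⁹N₂ + 2 × excess ³⁰N₂."""
        return excess_15n_total(self.excess29_nmol, self.excess30_nmol)


@dataclass(frozen=True)
class SpectralIrradianceProfile:
    """Scalar irradiance relative to the granule surface, depth × wavelength."""

    depths_um: np.ndarray
    wavelengths_nm: np.ndarray
    relative_irradiance: np.ndarray  # shape (n_depths, n_wavelengths)

    def __post_init__(self) -> None:
        z = np.asarray(self.depths_um, dtype=float)
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        rel = np.asarray(self.relative_irradiance, dtype=float)
        object.__setattr__(self, "depths_um", z)
        object.__setattr__(self, "wavelengths_nm", wl)
        object.__setattr__(self, "relative_irradiance", rel)
        if rel.shape != (z.size, wl.size):
            raise ValidationError("relative_irradiance must have shape (n_depths, n_wavelengths)")
        if np.any(np.diff(z) <= 0):
            raise ValidationError("depths must be strictly increasing")
        if np.any(rel < 0):
            raise ValidationError("relative irradiance cannot be negative")
        surface = np.argmin(np.abs(z))
        if z[surface] == 0 and not np.allclose(rel[surface], 1.0):
            raise ValidationError("the surface row (z = 0) must be normalized to 1")


@dataclass(frozen=True)
class RadiographSummary:
    """Detector-count summary for one region of a granule cryosection."""

    counts: float
    area_mm2: float
    slice_thickness_um: float
    conversion_nmol_per_count: float | None = None
    region: str = "whole"

    def __post_init__(self) -> None:
        if self.counts < 0:
            raise ValidationError("counts cannot be negative")
        if self.area_mm2 <= 0 or self.slice_thickness_um <= 0:
            raise ValidationError("area and slice thickness must be positive")


@dataclass(frozen=True)
class AttenuationResult:
    """Band-averaged exponential attenuation fit I(z) = exp(−k z)."""

    k_per_um: float
    k_stderr_per_um: float
    z_p_um: float
    p: float
    n_depths: int
    excess_wavelengths_nm: np.ndarray
    flag: str | None = None


@dataclass(frozen=True)
class Calibration:
    """Monotone signal → concentration map from calibration standards."""

    mode: str
    params: tuple[float, ...]
    n_standards: int
    _map: Callable[[np.ndarray], np.ndarray] = field(repr=False, default=None)

    def __call__(self, signal):
        return self._map(np.asarray(signal, dtype=float))


# -- fitting helpers --------------------------------------------------------


def _ols(x: np.ndarray, y: np.ndarray, units: str) -> RateEstimate:
    """Least-squares line with intercept; stderr is that of the slope."""
    res = stats.linregress(x, y)
    stderr = float(res.stderr)
    if not np.isfinite(stderr):
        stderr = 0.0
    return RateEstimate(
        slope=float(res.slope),
        stderr=stderr,
        n_points=int(x.size),
        units=units,
        intercept=float(res.intercept),
    )


# -- operations -------------------------------------------------------------


def gross_photosynthesis(
    series: DarkShiftSeries, window_s: tuple[float, float] = (0.0, 5.0)
) -> RateEstimate:
    """Gross photosynthesis from the initial O₂ decline after darkening.

    The rate of the decrease in oxygen concentration immediately after
    covering the light equals the local gross photosynthesis rate
    (respiration continues unchanged, so it cancels).  Fits an OLS line
    to concentration vs time over ``window_s`` (default the first 5 s of
    a 5–10 s dark shift) and sign-flips the slope, in µmol L⁻¹ s⁻¹.

    An increasing concentration yields a negative rate with a warning
    flag rather than an error.
    """
    lo, hi = window_s
    if hi <= lo:
        raise ValidationError("dark-shift window must have positive length")
    mask = (series.times_s >= lo) & (series.times_s <= hi)
    if mask.sum() < 3:
        raise ValidationError(
            f"need ≥ 3 points in the {lo}-{hi} s window, found {int(mask.sum())}"
        )
    est = _ols(series.times_s[mask], series.conc_umol_per_l[mask], "umol_per_L_per_s")
    rate = -est.slope
    warning = None
    if rate < 0:
        warning = "oxygen increased during the dark shift; negative photosynthesis rate"
    return RateEstimate(
        slope=rate,
        stderr=est.stderr,
        n_points=est.n_points,
        units=est.units,
        intercept=est.intercept,
        warning=warning,
    )


def excess_15n_total(excess29_nmol, excess30_nmol):
    """Total excess ¹⁵N: excess ²⁹N₂ + 2 × excess ³⁰N₂ (nmol ¹⁵N).

    ³⁰N₂ carries two labelled atoms, ²⁹N₂ one.
    """
    e29 = np.asarray(excess29_nmol, dtype=float)
    e30 = np.asarray(excess30_nmol, dtype=float)
    if np.any(e29 < 0) or np.any(e30 < 0):
        raise ValidationError("excess N₂ amounts cannot be negative")
    out = e29 + 2.0 * e30
    return float(out) if out.ndim == 0 else out


def denitrification_rate(series: IsotopeTimeSeries) -> RateEstimate:
    """Denitrification as the OLS slope of total excess ¹⁵N vs time (nmol ¹⁵N h⁻¹)."""
    if series.n_points < 3:
        raise ValidationError("denitrification fit needs ≥ 3 timepoints")
    return _ols(series.times_h, series.total_excess_15n_nmol, "nmol_15N_per_h")


def nitrification_rate(series: IsotopeTimeSeries) -> RateEstimate:
    """Nitrification as the OLS slope of (total excess ¹⁵N + NOₓ) vs time.

    Tracks the production of extracellular nitrate and nitrite plus the
    ¹⁵N–N₂ subsequently produced from it, in nmol N h⁻¹, so that
    nitrified N already passed on to denitrification is not lost from
    the accounting.
    """
    if series.n_points < 3:
        raise ValidationError("nitrification fit needs ≥ 3 timepoints")
    y = series.total_excess_15n_nmol + series.nox_nmol
    return _ols(series.times_h, y, "nmol_N_per_h")


def nox_amount_nmol(
    conc_umol_per_l, vial_volume_ml: float, headspace_ml: float = 0.0
):
    """Convert a NOₓ concentration to a vial amount (nmol).

    The liquid volume is the vial volume minus the headspace; both must
    be supplied (typical incubations: 6 mL vials, 2 mL helium headspace).
    """
    liquid_ml = vial_volume_ml - headspace_ml
    if liquid_ml <= 0:
        raise ValidationError("vial volume minus headspace must be positive")
    conc = np.asarray(conc_umol_per_l, dtype=float)
    out = conc * liquid_ml  # µmol/L × mL = nmol
    return float(out) if out.ndim == 0 else out


def calibrate_sensor(
    signals: Sequence[float],
    standards_umol_per_l: Sequence[float],
    mode: str = "linear",
) -> Calibration:
    """Fit a monotone signal → concentration map from standards.

    ``linear`` suits amperometric sensors (two-point O₂ calibration in
    saturated water and ascorbate baseline passes exactly through both
    standards); ``log_linear`` suits potentiometric LIX sensors whose
    signal is Nernstian in log₁₀ concentration (nitrate dilution
    series, ≥ 3 standards, strictly positive concentrations).
    """
    sig = np.asarray(signals, dtype=float)
    conc = np.asarray(standards_umol_per_l, dtype=float)
    if sig.shape != conc.shape or sig.ndim != 1:
        raise CalibrationError("signals and standards must be 1-D and equal length")
    order = np.argsort(conc)
    sig, conc = sig[order], conc[order]
    if np.any(np.diff(conc) <= 0):
        raise CalibrationError("standards must be distinct concentrations")
    dsig = np.diff(sig)
    if not (np.all(dsig > 0) or np.all(dsig < 0)):
        raise CalibrationError("calibration standards are not monotone in signal")

    if mode == "linear":
        if sig.size < 2:
            raise CalibrationError("linear calibration needs ≥ 2 standards")
        slope, intercept = np.polyfit(sig, conc, 1)
        params = (float(slope), float(intercept))

        def _map(s, a=slope, b=intercept):
            return a * s + b

    elif mode == "log_linear":
        if sig.size < 3:
            raise CalibrationError("log-linear calibration needs ≥ 3 standards")
        if np.any(conc <= 0):
            raise CalibrationError("log-linear calibration needs positive concentrations")
        # Nernstian: signal = a·log10(conc) + b; invert for concentration.
        a, b = np.polyfit(np.log10(conc), sig, 1)
        params = (float(a), float(b))

        def _map(s, a=a, b=b):
            return 10.0 ** ((s - b) / a)

    else:
        raise ValidationError(f"unknown calibration mode {mode!r}")

    return Calibration(mode=mode, params=params, n_standards=int(sig.size), _map=_map)


def light_attenuation(
    profile: SpectralIrradianceProfile,
    band_nm: tuple[float, float],
    p: float = 0.1,
    excess_tolerance: float = 1e-9,
) -> AttenuationResult:
    """Band-averaged attenuation coefficient k and penetration depth z_p.

    Averages relative scalar irradiance over the wavelengths in
    ``band_nm``, fits log-linear OLS to I(z) = exp(−k z), and reports
    z_p = −ln(p)/k (default p = 0.1: the depth where 90 % of surface
    light has been absorbed).

    Wavelengths whose sub-surface irradiance exceeds the surface value
    (scattering / pigment-fluorescence excess, typically 700–800 nm) are
    excluded from the fit and reported separately.
    """
    lo, hi = band_nm
    in_band = (profile.wavelengths_nm >= lo) & (profile.wavelengths_nm <= hi)
    if not np.any(in_band):
        raise ValidationError(f"no wavelengths in band {lo}-{hi} nm")
    rel = profile.relative_irradiance[:, in_band]
    wl = profile.wavelengths_nm[in_band]
    subsurface = profile.depths_um > 0
    excess = np.any(rel[subsurface] > 1.0 + excess_tolerance, axis=0)
    excess_wl = wl[excess]
    rel = rel[:, ~excess]
    if rel.shape[1] == 0:
        raise ValidationError("all wavelengths in the band show excess irradiance")

    intensity = rel.mean(axis=1)
    keep = intensity > 0
    z = profile.depths_um[keep]
    logi = np.log(intensity[keep])
    if z.size < 3:
        raise ValidationError("attenuation fit needs ≥ 3 depths with positive irradiance")
    est = _ols(z, logi, "per_um")
    k = -est.slope
    flag = None
    if k <= 0:
        z_p = np.inf
        flag = "no attenuation detected; z_p undefined"
        k = max(k, 0.0)
    else:
        z_p = -np.log(p) / k
    return AttenuationResult(
        k_per_um=float(k),
        k_stderr_per_um=est.stderr,
        z_p_um=float(z_p),
        p=p,
        n_depths=int(z.size),
        excess_wavelengths_nm=excess_wl,
        flag=flag,
    )


def radiograph_volumetric_rate(
    summary: RadiographSummary,
    duration_h: float,
    blank: RadiographSummary | None = None,
    blank_duration_h: float | None = None,
) -> float:
    """Volumetric carbon-fixation rate from a microradiograph region.

    counts × conversion / (area × thickness × duration), in
    nmol C mm⁻³ h⁻¹ (thickness converted from µm to mm).  When a
    killed-control blank is supplied its rate is subtracted.
    """
    if duration_h <= 0:
        raise ValidationError("incubation duration must be positive")
    if summary.conversion_nmol_per_count is None:
        raise ValidationError(
            "no count-to-nmol conversion factor supplied; detector counts "
            "cannot be made absolute without the tracer specific activity"
        )
    thickness_mm = summary.slice_thickness_um / 1000.0
    rate = (
        summary.counts
        * summary.conversion_nmol_per_count
        / (summary.area_mm2 * thickness_mm * duration_h)
    )
    if blank is not None:
        blank_d = duration_h if blank_duration_h is None else blank_duration_h
        rate -= radiograph_volumetric_rate(blank, blank_d)
    return float(rate)


def reactor_scale_rate(
    per_granule_rate_nmol_per_h: float, granules_per_litre: float
) -> float:
    """Scale a per-granule rate to a reactor volumetric rate (mmol L⁻¹ d⁻¹).

    Parameterized helper: the granule number density is an input, not a
    measured constant.
    """
    if granules_per_litre < 0:
        raise ValidationError("granule density cannot be negative")
    return per_granule_rate_nmol_per_h * granules_per_litre * 24.0 / 1e6
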