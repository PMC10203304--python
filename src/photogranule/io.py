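"""Plain-text file I/O for profiles, time series and rate tables.

Microsensor exports are vendor-heterogeneous delimited text, so every
reader accepts both comma- and tab-separated files (decimal point only)
and enforces a minimal mandatory-column contract.  Writers use 15
significant digits so that write → read round-trips values to 12
significant digits.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import DepthProfile, PhotogranuleError
from .estimators import DarkShiftSeries, IsotopeTimeSeries, SpectralIrradianceProfile
from .inversion import RateProfile

__all__ = [
    "InputFileError",
    "read_profile_csv",
    "write_profile_csv",
    "read_dark_shift_csv",
    "read_isotope_csv",
    "read_spectral_csv",
    "write_rate_table",
    "write_manifest",
]

_FLOAT_FORMAT = "%.15g"


class InputFileError(PhotogranuleError):
    """A file failed the column/number contract; message names file and line."""


def _sniff_delimiter(path: Path) -> str:
    sample = path.read_text().splitlines()[0] if path.stat().st_size else ""
    return "\t" if "\t" in sample else ","


def _read_table(path: str | Path, required: tuple[str, ...]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise InputFileError(f"{path}: file not found")
    try:
        frame = pd.read_csv(path, sep=_sniff_delimiter(path), dtype=str)
    except Exception as exc:  # pandas parse failure
        raise InputFileError(f"{path}: could not parse delimited text ({exc})") from exc
    frame.columns = [c.strip() for c in frame.columns]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise InputFileError(
            f"{path}: missing required column(s) {', '.join(missing)} "
            f"(found: {', '.join(frame.columns)})"
        )
    return frame


def _numeric(frame: pd.DataFrame, path: Path, columns: tuple[str, ...]) -> pd.DataFrame:
    out = frame.copy()
    for col in columns:
        values = pd.to_numeric(frame[col], errors="coerce")
        bad = values.isna() & frame[col].notna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # +1 header, +1 one-based
            raise InputFileError(
                f"{path}: non-numeric value {frame[col][bad.idxmax()]!r} "
                f"in column {col!r} at line {line}"
            )
        if values.isna().any():
            line = int(values.isna().idxmax()) + 2
            raise InputFileError(f"{path}: empty cell in column {col!r} at line {line}")
        out[col] = values.astype(float)
    return out


def read_profile_csv(path: str | Path, analyte: str | None = None) -> DepthProfile:
    """Read a microsensor depth profile.

    Required columns: ``depth_um``, ``conc_umol_per_L``; optional
    ``analyte``, ``replicate``, ``condition``.  Rows with z < 0 are
    parsed and flagged as boundary layer (see
    :attr:`DepthProfile.boundary_layer_mask`), not dropped.
    """
    path = Path(path)
    frame = _numeric(
        _read_table(path, ("depth_um", "conc_umol_per_L")),
        path,
        ("depth_um", "conc_umol_per_L"),
    )
    depths = frame["depth_um"].to_numpy()
    dup = pd.Series(depths).duplicated()
    if dup.any():
        line = int(dup.idxmax()) + 2
        raise InputFileError(f"{path}: duplicate depth {depths[dup.idxmax()]} at line {line}")
    order = np.argsort(depths, kind="stable")
    if analyte is None:
        analyte = str(frame["analyte"].iloc[0]) if "analyte" in frame.columns else "oxygen"
    return DepthProfile(
        analyte=analyte,
        depths_um=depths[order],
        conc_umol_per_l=frame["conc_umol_per_L"].to_numpy()[order],
        condition=str(frame["condition"].iloc[0]) if "condition" in frame.columns else None,
        replicate_id=str(frame["replicate"].iloc[0]) if "replicate" in frame.columns else None,
    )


def write_profile_csv(profile: DepthProfile, path: str | Path) -> None:
    frame = pd.DataFrame(
        {
            "depth_um": profile.depths_um,
            "conc_umol_per_L": profile.conc_umol_per_l,
            "analyte": profile.analyte,
        }
    )
    frame.to_csv(path, index=False, float_format=_FLOAT_FORMAT)


def read_dark_shift_csv(path: str | Path, depth_um: float = 0.0) -> DarkShiftSeries:
    """Read a dark-shift series: columns ``time_s``, ``conc_umol_per_L``."""
    path = Path(path)
    frame = _numeric(
        _read_table(path, ("time_s", "conc_umol_per_L")), path, ("time_s", "conc_umol_per_L")
    )
    if "depth_um" in frame.columns:
        frame = _numeric(frame, path, ("depth_um",))
        depth_um = float(frame["depth_um"].iloc[0])
    return DarkShiftSeries(
        depth_um=depth_um,
        times_s=frame["time_s"].to_numpy(),
        conc_umol_per_l=frame["conc_umol_per_L"].to_numpy(),
    )


def read_isotope_csv(path: str | Path, **labels) -> IsotopeTimeSeries:
    """Read a closed-vial isotope series.

    Columns: ``time_h``, ``excess29_nmol``, ``excess30_nmol``, ``nox_nmol``.
    """
    path = Path(path)
    cols = ("time_h", "excess29_nmol", "excess30_nmol", "nox_nmol")
    frame = _numeric(_read_table(path, cols), path, cols)
    return IsotopeTimeSeries(
        times_h=frame["time_h"].to_numpy(),
        excess29_nmol=frame["excess29_nmol"].to_numpy(),
        excess30_nmol=frame["excess30_nmol"].to_numpy(),
        nox_nmol=frame["nox_nmol"].to_numpy(),
        **labels,
    )


def read_spectral_csv(path: str | Path) -> SpectralIrradianceProfile:
    """Read a long-format spectral profile: depth_um, wavelength_nm, rel_irradiance."""
    path = Path(path)
    cols = ("depth_um", "wavelength_nm", "rel_irradiance")
    frame = _numeric(_read_table(path, cols), path, cols)
    pivot = frame.pivot_table(
        index="depth_um", columns="wavelength_nm", values="rel_irradiance", sort=True
    )
    if pivot.isna().any().any():
        raise InputFileError(f"{path}: depth × wavelength grid is incomplete")
    return SpectralIrradianceProfile(
        depths_um=pivot.index.to_numpy(dtype=float),
        wavelengths_nm=pivot.columns.to_numpy(dtype=float),
        relative_irradiance=pivot.to_numpy(dtype=float),
    )


def write_spectral_csv(profile: SpectralIrradianceProfile, path: str | Path) -> None:
    z, wl = np.meshgrid(profile.depths_um, profile.wavelengths_nm, indexing="ij")
    frame = pd.DataFrame(
        {
            "depth_um": z.ravel(),
            "wavelength_nm": wl.ravel(),
            "rel_irradiance": profile.relative_irradiance.ravel(),
        }
    )
    frame.to_csv(path, index=False, float_format=_FLOAT_FORMAT)


def write_isotope_csv(series: IsotopeTimeSeries, path: str | Path) -> None:
    pd.DataFrame(
        {
            "time_h": series.times_h,
            "excess29_nmol": series.excess29_nmol,
            "excess30_nmol": series.excess30_nmol,
            "nox_nmol": series.nox_nmol,
        }
    ).to_csv(path, index=False, float_format=_FLOAT_FORMAT)


def write_dark_shift_csv(series: DarkShiftSeries, path: str | Path) -> None:
    pd.DataFrame(
        {
            "time_s": series.times_s,
            "conc_umol_per_L": series.conc_umol_per_l,
            "depth_um": series.depth_um,
        }
    ).to_csv(path, index=False, float_format=_FLOAT_FORMAT)


def write_rate_table(rates: RateProfile, path: str | Path) -> None:
    """Write the shell rate table plus a one-row summary CSV alongside.

    ``<stem>.csv`` holds the per-shell table; ``<stem>_summary.csv`` the
    totals (total rate, surface flux, analyte, D, R).
    """
    path = Path(path)
    rates.to_frame().to_csv(path, index=False, float_format=_FLOAT_FORMAT)
    summary_path = path.with_name(path.stem + "_summary" + path.suffix)
    rates.summary().to_csv(summary_path, index=False, float_format=_FLOAT_FORMAT)


def read_rate_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    cols = (
        "shell_index",
        "r_inner_um",
        "r_outer_um",
        "net_rate_nmol_per_h",
        "volumetric_rate_nmol_per_mm3_per_h",
    )
    return _numeric(_read_table(path, cols), path, cols)


def write_manifest(path: str | Path, **entries) -> None:
    """Machine-readable run manifest (inputs, parameters, seed, version).

    Deliberately excludes wall-clock timestamps so that identical runs
    produce identical artifacts.
    """
    from . import __version__

    payload = {"package": "photogranule", "version": __version__}
    payload.update(entries)
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True, default=str) + "\n")
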