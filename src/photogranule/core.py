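"""Shared domain types, unit conversions, and the concentric-shell geometry.

Coordinate convention
---------------------
Microsensor profiles are recorded as depth ``z`` (µm) from the granule
surface along a radius; the internal radial coordinate is ``r = R − z``.
Depth 0 is the surface, negative depths lie in the diffusive boundary
layer above the granule and are excluded from inversion by default.

Canonical internal units are µm, s and nmol.  Reported rates are
nmol h⁻¹ (per shell / per granule) and nmol mm⁻³ h⁻¹ (volumetric).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "PhotogranuleError",
    "ValidationError",
    "DepthProfile",
    "GranuleGeometry",
    "ShellGrid",
    "DiffusionModel",
    "RateEstimate",
    "build_shell_grid",
    "convert_conc_gradient",
    "UMOL_PER_L_TO_NMOL_PER_UM3",
    "SECONDS_PER_HOUR",
    "UM3_PER_MM3",
    "VOLUMETRIC_UMOL_L_S_TO_NMOL_MM3_H",
]

# -- unit bridges -----------------------------------------------------------

#: 1 µmol L⁻¹ expressed in nmol µm⁻³ (1 L = 10¹⁵ µm³, 1 µmol = 10³ nmol).
UMOL_PER_L_TO_NMOL_PER_UM3 = 1e-12

SECONDS_PER_HOUR = 3600.0

UM3_PER_MM3 = 1e9

#: 1 µmol L⁻¹ s⁻¹ expressed in nmol mm⁻³ h⁻¹.
VOLUMETRIC_UMOL_L_S_TO_NMOL_MM3_H = (
    UMOL_PER_L_TO_NMOL_PER_UM3 * SECONDS_PER_HOUR * UM3_PER_MM3
)  # = 3.6


class PhotogranuleError(Exception):
    """Base class for all errors raised by this package."""


class ValidationError(PhotogranuleError):
    """An input violated a documented precondition."""


def convert_conc_gradient(grad_umol_per_l_per_um: float) -> float:
    """Convert a concentration gradient from µmol L⁻¹ µm⁻¹ to nmol µm⁻⁴.

    This is the unit bridge that makes ``D · dC/dx · 4πr²`` come out in
    nmol s⁻¹ when D is in µm² s⁻¹ and r in µm.
    """
    g = float(grad_umol_per_l_per_um)
    if not np.isfinite(g):
        raise ValidationError("concentration gradient must be finite")
    return g * UMOL_PER_L_TO_NMOL_PER_UM3


# -- domain types -----------------------------------------------------------


@dataclass(frozen=True)
class GranuleGeometry:
    """Spherical granule of radius ``radius_um`` (µm)."""

    radius_um: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.radius_um) and self.radius_um > 0):
            raise ValidationError(f"granule radius must be positive, got {self.radius_um}")

    @property
    def volume_um3(self) -> float:
        return 4.0 / 3.0 * np.pi * self.radius_um**3


@dataclass(frozen=True)
class DiffusionModel:
    """Molecular diffusion coefficients per analyte, in µm² s⁻¹.

    Defaults are the literature values for oxygen (2000 µm² s⁻¹) and
    nitrate (1700 µm² s⁻¹) in water at the relevant temperature.
    """

    coefficients_um2_per_s: Mapping[str, float] = field(
        default_factory=lambda: {"oxygen": 2000.0, "nitrate": 1700.0}
    )

    def __post_init__(self) -> None:
        for analyte, d in self.coefficients_um2_per_s.items():
            if not (np.isfinite(d) and d > 0):
                raise ValidationError(f"diffusion coefficient for {analyte!r} must be > 0")

    def for_analyte(self, analyte: str) -> float:
        try:
            return float(self.coefficients_um2_per_s[analyte])
        except KeyError:
            known = ", ".join(sorted(self.coefficients_um2_per_s))
            raise ValidationError(
                f"no diffusion coefficient for analyte {analyte!r} (known: {known})"
            ) from None


@dataclass(frozen=True)
class DepthProfile:
    """One analyte's concentration versus depth along a radial transect.

    ``depths_um`` must be strictly increasing.  Negative depths (diffusive
    boundary layer, above the surface) are retained for plotting but are
    excluded from inversion; use :meth:`in_granule`.
    """

    analyte: str
    depths_um: np.ndarray
    conc_umol_per_l: np.ndarray
    condition: str | None = None
    replicate_id: str | None = None

    def __post_init__(self) -> None:
        depths = np.asarray(self.depths_um, dtype=float)
        conc = np.asarray(self.conc_umol_per_l, dtype=float)
        object.__setattr__(self, "depths_um", depths)
        object.__setattr__(self, "conc_umol_per_l", conc)
        if depths.ndim != 1 or conc.shape != depths.shape:
            raise ValidationError("depths and concentrations must be 1-D and equal length")
        if depths.size == 0:
            raise ValidationError("profile is empty")
        if not np.all(np.isfinite(depths)):
            raise ValidationError("profile depths must be finite")
        if not np.all(np.isfinite(conc)):
            raise ValidationError("profile concentrations must be finite")
        if np.any(np.diff(depths) <= 0):
            bad = depths[1:][np.diff(depths) <= 0][0]
            raise ValidationError(
                f"profile depths must be strictly increasing (violation near z={bad} µm)"
            )
        if np.any(conc < 0):
            raise ValidationError("profile concentrations must be non-negative")

    @property
    def n_points(self) -> int:
        return int(self.depths_um.size)

    @property
    def boundary_layer_mask(self) -> np.ndarray:
        """True for points recorded above the surface (z < 0)."""
        return self.depths_um < 0

    def in_granule(self) -> "DepthProfile":
        """The sub-profile at depths z ≥ 0 (inside the aggregate)."""
        keep = ~self.boundary_layer_mask
        if not np.any(keep):
            raise ValidationError("profile has no points inside the granule (z ≥ 0)")
        return DepthProfile(
            analyte=self.analyte,
            depths_um=self.depths_um[keep],
            conc_umol_per_l=self.conc_umol_per_l[keep],
            condition=self.condition,
            replicate_id=self.replicate_id,
        )


@dataclass(frozen=True)
class ShellGrid:
    """Concentric-shell discretization of a granule of radius R.

    ``interface_radii_um`` decreases strictly from R to 0; shell ``i``
    spans ``[interface_radii_um[i+1], interface_radii_um[i]]`` and is
    centred on measurement point ``i`` (outermost first).

    ``truncation_radius_um`` is the radius half a spacing below the
    deepest measurement.  When it is > 0 the profile stopped short of the
    centre and the innermost shell includes an unmeasured core; the
    inversion flags this.
    """

    geometry: GranuleGeometry
    interface_radii_um: np.ndarray
    truncation_radius_um: float = 0.0

    def __post_init__(self) -> None:
        radii = np.asarray(self.interface_radii_um, dtype=float)
        object.__setattr__(self, "interface_radii_um", radii)
        if radii.ndim != 1 or radii.size < 2:
            raise ValidationError("a shell grid needs at least two interfaces")
        if np.any(np.diff(radii) >= 0):
            raise ValidationError("interface radii must be strictly decreasing")
        if not np.isclose(radii[0], self.geometry.radius_um):
            raise ValidationError("outermost interface must sit at the granule surface")
        if radii[-1] < 0:
            raise ValidationError("interfaces cannot lie below the centre")

    @property
    def n_shells(self) -> int:
        return int(self.interface_radii_um.size - 1)

    @property
    def outer_radii_um(self) -> np.ndarray:
        return self.interface_radii_um[:-1]

    @property
    def inner_radii_um(self) -> np.ndarray:
        return self.interface_radii_um[1:]

    @property
    def shell_volumes_um3(self) -> np.ndarray:
        r = self.interface_radii_um
        return 4.0 / 3.0 * np.pi * (r[:-1] ** 3 - r[1:] ** 3)

    @property
    def interface_areas_um2(self) -> np.ndarray:
        return 4.0 * np.pi * self.interface_radii_um**2

    @property
    def is_truncated(self) -> bool:
        return self.truncation_radius_um > 0

    @property
    def total_volume_um3(self) -> float:
        r = self.interface_radii_um
        return float(4.0 / 3.0 * np.pi * (r[0] ** 3 - r[-1] ** 3))


@dataclass(frozen=True)
class RateEstimate:
    """A fitted rate (slope) with its standard error.

    ``warning`` carries soft diagnostics (e.g. oxygen increasing during a
    dark shift) that are not errors.
    """

    slope: float
    stderr: float
    n_points: int
    units: str
    intercept: float | None = None
    warning: str | None = None

    def __post_init__(self) -> None:
        if self.stderr < 0:
            raise ValidationError("standard error cannot be negative")
        if self.n_points < 2:
            raise ValidationError("a rate estimate needs at least two points")

    def confidence_interval(self, level: float = 0.95) -> tuple[float, float]:
        """Two-sided t-based confidence interval for the slope."""
        from scipy import stats

        dof = self.n_points - 2
        if dof < 1:
            raise ValidationError("confidence interval needs n_points ≥ 3")
        half = stats.t.ppf(0.5 + level / 2.0, dof) * self.stderr
        return (self.slope - half, self.slope + half)


# -- shell construction -----------------------------------------------------


def build_shell_grid(geometry: GranuleGeometry, depths_um: Sequence[float]) -> ShellGrid:
    """Build the staggered shell grid for a set of measurement depths.

    One shell per measurement point, with interfaces at the midpoints
    between adjacent measurement radii (``r = R − z``), the outermost
    interface at R and the innermost at the centre.  The two-point finite
    difference between adjacent measurements is then exactly the
    derivative at each interface for locally quadratic profiles.

    Raises on depths outside ``[0, R]`` (boundary-layer points must be
    stripped explicitly first — never silently) and on fewer than 3
    depths, the minimum for inversion.
    """
    depths = np.asarray(depths_um, dtype=float)
    if depths.ndim != 1:
        raise ValidationError("depths must be a 1-D sequence")
    R = geometry.radius_um
    if np.any(depths < 0):
        bad = depths[depths < 0][0]
        raise ValidationError(
            f"depth {bad} µm lies above the surface; strip boundary-layer points first"
        )
    over = depths[depths > R]
    if over.size:
        raise ValidationError(
            f"depth {over[0]} µm exceeds the granule radius R = {R} µm"
        )
    if np.any(np.diff(depths) <= 0):
        raise ValidationError("depths must be strictly increasing")

    radii = R - depths  # strictly decreasing
    if depths.size == 1:
        interfaces = np.array([R, 0.0])
        truncation = 0.0
    else:
        mid = 0.5 * (radii[:-1] + radii[1:])
        interfaces = np.concatenate(([R], mid, [0.0]))
        last_spacing = radii[-2] - radii[-1]
        truncation = max(0.0, radii[-1] - 0.5 * last_spacing)
        # Degenerate case: deepest midpoint already at the centre.
        if interfaces[-2] <= 0.0:
            interfaces = interfaces[:-1]
            interfaces[-1] = 0.0
    return ShellGrid(
        geometry=geometry,
        interface_radii_um=interfaces,
        truncation_radius_um=truncation,
    )
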