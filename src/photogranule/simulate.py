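"""Spherical reaction–diffusion forward simulator and fixture generator.

Solves steady-state and transient diffusion in a sphere with zero-order
(concentration-independent) layered sources and sinks,

    (1/r²) d/dr ( r² D dC/dr ) = −Q(r),      dC/dr|₀ = 0,  C(R) = C_bulk,

with a hard non-negativity constraint: zero-order consumption switches
off wherever the concentration would fall below zero, producing an
anoxic core with C = 0 and zero gradient at the oxic–anoxic front.
Zero-order kinetics are used deliberately — the shell inversion is
kinetics-free, and zero-order admits closed-form cross-checks (the
uniform-consumption parabola and the zero-order anoxic-shell solution).

The simulator is the package's independent oracle: it generates noisy
depth profiles, dark-shift transients, isotope time series and spectral
light fields with known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import integrate, sparse
from scipy.sparse.linalg import spsolve

from .core import (
    SECONDS_PER_HOUR,
    UM3_PER_MM3,
    UMOL_PER_L_TO_NMOL_PER_UM3,
    DepthProfile,
    GranuleGeometry,
    PhotogranuleError,
    ShellGrid,
    ValidationError,
    build_shell_grid,
)
from .estimators import DarkShiftSeries, IsotopeTimeSeries, SpectralIrradianceProfile
from .inversion import RateProfile

__all__ = [
    "Layer",
    "Optics",
    "GranuleScenario",
    "SteadyStateField",
    "DarkShiftResult",
    "SimulatedProfile",
    "SteadyStateError",
    "solve_steady_state",
    "solve_dark_shift",
    "sample_profile",
    "generate_isotope_series",
    "generate_light_profile",
]


class SteadyStateError(PhotogranuleError):
    """The oxic/anoxic front iteration failed to converge."""


@dataclass(frozen=True)
class Layer:
    """One concentric reactive layer, [r_inner, r_outer] µm.

    ``rate_umol_per_l_per_s`` is the unsigned zero-order volumetric rate;
    ``kind`` is "production" or "consumption".  ``light_dependent``
    layers (photosynthesis) are active only while the light is on.
    """

    r_inner_um: float
    r_outer_um: float
    rate_umol_per_l_per_s: float
    kind: str = "production"
    light_dependent: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("production", "consumption"):
            raise ValidationError(f"layer kind must be production|consumption, got {self.kind!r}")
        if not 0 <= self.r_inner_um < self.r_outer_um:
            raise ValidationError("layer must satisfy 0 ≤ r_inner < r_outer")
        if self.rate_umol_per_l_per_s < 0:
            raise ValidationError("layer rate is unsigned; use kind='consumption'")

    @property
    def signed_rate(self) -> float:
        return self.rate_umol_per_l_per_s * (1.0 if self.kind == "production" else -1.0)


@dataclass(frozen=True)
class Optics:
    """Surface scalar irradiance and exponential attenuation coefficient."""

    surface_irradiance_umol_m2_s: float = 250.0
    k_per_um: float = np.log(10.0) / 600.0  # 90 % absorbed within 600 µm


@dataclass(frozen=True)
class GranuleScenario:
    """Ground-truth specification for one simulated granule.

    Layers superpose linearly (a photic production layer may overlap a
    respiration layer) and may leave gaps, which are inert.  A single
    seed governs every stochastic draw derived from the scenario.
    """

    geometry: GranuleGeometry
    layers: tuple[Layer, ...] = ()
    bulk_umol_per_l: float = 250.0
    analyte: str = "oxygen"
    d_um2_per_s: float = 2000.0
    boundary_layer_um_per_s: float | None = None
    optics: Optics = field(default_factory=Optics)
    noise_sigma_umol_per_l: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.bulk_umol_per_l < 0:
            raise ValidationError("bulk concentration cannot be negative")
        if self.noise_sigma_umol_per_l < 0:
            raise ValidationError("noise σ cannot be negative")
        if self.d_um2_per_s <= 0:
            raise ValidationError("diffusion coefficient must be positive")
        R = self.geometry.radius_um
        for lay in self.layers:
            if lay.r_outer_um > R + 1e-9:
                raise ValidationError("layer extends beyond the granule radius")

    def volumetric_rate_at(self, r, light: bool = True):
        """Signed nominal zero-order rate (µmol L⁻¹ s⁻¹) at radius r."""
        r = np.asarray(r, dtype=float)
        q = np.zeros_like(r)
        for lay in self.layers:
            if lay.light_dependent and not light:
                continue
            inside = (r >= lay.r_inner_um) & (r <= lay.r_outer_um)
            q = np.where(inside, q + lay.signed_rate, q)
        return q

    def gross_photosynthesis_at(self, r):
        """True gross photosynthesis (µmol L⁻¹ s⁻¹) at radius r."""
        r = np.asarray(r, dtype=float)
        p = np.zeros_like(r)
        for lay in self.layers:
            if lay.light_dependent and lay.kind == "production":
                inside = (r >= lay.r_inner_um) & (r <= lay.r_outer_um)
                p = np.where(inside, p + lay.rate_umol_per_l_per_s, p)
        return p


# -- finite-volume machinery ------------------------------------------------


def _cell_layer_integrals(
    faces: np.ndarray, layers: Sequence[Layer], light: bool
) -> tuple[np.ndarray, np.ndarray]:
    """∫ q r² dr per cell, split into production (≥0) and consumption (≤0).

    Exact for the piecewise-constant layer rates (no quadrature error),
    which is what makes the discrete flux balance exact.
    """
    n = faces.size - 1
    prod = np.zeros(n)
    cons = np.zeros(n)
    for lay in layers:
        if lay.light_dependent and not light:
            continue
        lo = np.clip(faces[:-1], lay.r_inner_um, lay.r_outer_um)
        hi = np.clip(faces[1:], lay.r_inner_um, lay.r_outer_um)
        seg = np.maximum(hi**3 - lo**3, 0.0) / 3.0
        if lay.kind == "production":
            prod += lay.rate_umol_per_l_per_s * seg
        else:
            cons -= lay.rate_umol_per_l_per_s * seg
    return prod, cons


def _assemble(
    scenario: GranuleScenario, n_cells: int, h: float, active: np.ndarray, light: bool
):
    """Sparse operator and source for nodes 0..N (node N at r = R).

    Returns (A, b, prod, cons, faces) with A C + b = residual form
    A C = −(prod + active·cons) for interior rows, plus the boundary row.
    """
    R = scenario.geometry.radius_um
    d = scenario.d_um2_per_s
    nodes = n_cells + 1
    r_nodes = np.linspace(0.0, R, nodes)
    faces = np.concatenate(([0.0], 0.5 * (r_nodes[:-1] + r_nodes[1:]), [R]))
    a_face = faces**2  # interface area / 4π

    prod, cons = _cell_layer_integrals(faces, scenario.layers, light)

    # Conductances between node i and i+1 across face i+1.
    g = d * a_face[1:-1] / h  # length nodes-1
    main = np.zeros(nodes)
    lower = np.zeros(nodes - 1)
    upper = np.zeros(nodes - 1)
    main[:-1] -= np.concatenate((g, [0.0]))[: nodes - 1]
    main[1:] -= g
    upper[:] = g
    lower[:] = g
    b = np.zeros(nodes)

    if scenario.boundary_layer_um_per_s is None:
        # Dirichlet at the surface node.
        main[-1] = 1.0
        lower[-1] = 0.0
        b[-1] = scenario.bulk_umol_per_l
        dirichlet = True
    else:
        # Robin: mass-transfer flux k·R²·(C_bulk − C_N) balances the half-cell.
        k = scenario.boundary_layer_um_per_s
        main[-1] -= k * R**2
        b[-1] = -k * R**2 * scenario.bulk_umol_per_l
        dirichlet = False

    A = sparse.diags([lower, main, upper], [-1, 0, 1], format="csc")
    return A, b, prod, cons, faces, dirichlet


@dataclass(frozen=True)
class SteadyStateField:
    """Steady concentration field C(r) on a uniform fine grid."""

    scenario: GranuleScenario
    r_um: np.ndarray
    conc_umol_per_l: np.ndarray
    grid_spacing_um: float
    active_consumption: np.ndarray  # per cell, cells = faces[:-1]..faces[1:]
    faces_um: np.ndarray
    light: bool = True

    def concentration_at_radius(self, r):
        return np.interp(np.asarray(r, dtype=float), self.r_um, self.conc_umol_per_l)

    def concentration_at_depth(self, z):
        R = self.scenario.geometry.radius_um
        return self.concentration_at_radius(R - np.asarray(z, dtype=float))

    @property
    def anoxic_front_radius_um(self) -> float:
        """Outermost radius of the contiguous central region with C = 0."""
        zero = self.conc_umol_per_l <= 0.0
        if not zero[0]:
            return 0.0
        idx = np.argmin(zero) if not zero.all() else zero.size
        return float(self.r_um[idx - 1])

    def effective_cell_sources(self) -> tuple[np.ndarray, np.ndarray]:
        """(∫ q_eff r² dr per cell, faces): consumption masked by the front."""
        prod, cons = _cell_layer_integrals(self.faces_um, self.scenario.layers, self.light)
        return prod + self.active_consumption * cons, self.faces_um

    def surface_flux_nmol_per_h(self) -> float:
        """Outward diffusive transport through the granule surface (r = R).

        Discrete flux through the outermost interior face (positive =
        outward, i.e. −D dC/dr · 4πr²) plus the exact source content of
        the surface half-cell, so that the discrete steady balance
        surface flux = ∫ Q dV over the oxic region holds to solver
        precision.
        """
        d = self.scenario.d_um2_per_s
        h = self.grid_spacing_um
        grad = (self.conc_umol_per_l[-1] - self.conc_umol_per_l[-2]) / h  # dC/dr
        face_term = -d * grad * self.faces_um[-2] ** 2
        prod, cons = _cell_layer_integrals(self.faces_um, self.scenario.layers, self.light)
        half_cell = prod[-1] + self.active_consumption[-1] * cons[-1]
        return (
            (face_term + half_cell)
            * 4.0
            * np.pi
            * UMOL_PER_L_TO_NMOL_PER_UM3
            * SECONDS_PER_HOUR
        )

    def total_amount_nmol(self) -> float:
        """Total dissolved amount inside the granule (nmol)."""
        cell_c = self.conc_umol_per_l  # node-centred; cells match nodes
        vol = 4.0 / 3.0 * np.pi * (self.faces_um[1:] ** 3 - self.faces_um[:-1] ** 3)
        return float(np.sum(cell_c * vol) * UMOL_PER_L_TO_NMOL_PER_UM3)


def solve_steady_state(
    scenario: GranuleScenario,
    grid_spacing_um: float = 5.0,
    light: bool = True,
    max_front_iterations: int = 100,
) -> SteadyStateField:
    """Solve the steady spherical reaction–diffusion problem.

    Zero-order consumption is deactivated cell-by-cell wherever the
    concentration would drop below zero (active-set iteration), locating
    the oxic–anoxic front to within one grid cell.
    """
    R = scenario.geometry.radius_um
    if grid_spacing_um <= 0 or grid_spacing_um > R:
        raise ValidationError("grid spacing must be positive and smaller than R")
    n_cells = max(int(round(R / grid_spacing_um)), 2)
    h = R / n_cells
    nodes = n_cells + 1
    A, b, prod, cons, faces, dirichlet = _assemble(
        scenario, n_cells, h, np.ones(nodes), light
    )
    source = prod + cons
    rhs_full = -source
    if dirichlet:
        rhs_full[-1] = b[-1]
    else:
        rhs_full[-1] += b[-1]

    # Obstacle problem: C ≥ 0 with the equation holding where C > 0 and the
    # residual (net would-be source) non-positive where C is pinned at 0.
    tol = 1e-9 * max(scenario.bulk_umol_per_l, 1.0)
    fixed = np.zeros(nodes, dtype=bool)
    seen: set[bytes] = set()
    c = np.zeros(nodes)
    for _ in range(max_front_iterations):
        A2 = A.tolil()
        rhs = rhs_full.copy()
        for i in np.nonzero(fixed)[0]:
            A2.rows[i] = [i]
            A2.data[i] = [1.0]
            rhs[i] = 0.0
        c = spsolve(A2.tocsc(), rhs)
        residual = A @ c - rhs_full  # = A C + S on interior rows
        new_fixed = fixed | (c < -tol)
        release = fixed & (residual > tol)
        new_fixed[release] = False
        new_fixed[-1] = False  # the surface boundary row is never pinned
        if np.array_equal(new_fixed, fixed):
            break
        key = new_fixed.tobytes()
        if key in seen:
            fixed = new_fixed | fixed
            continue
        seen.add(key)
        fixed = new_fixed
    else:
        pinned = np.nonzero(fixed)[0]
        lo = pinned.min() * h if pinned.size else 0.0
        hi = pinned.max() * h if pinned.size else R
        raise SteadyStateError(
            "anoxic front iteration did not converge; "
            f"last pinned bracket r ∈ [{lo:.1f}, {hi:.1f}] µm"
        )
    c = np.maximum(c, 0.0)
    return SteadyStateField(
        scenario=scenario,
        r_um=np.linspace(0.0, R, nodes),
        conc_umol_per_l=c,
        grid_spacing_um=h,
        active_consumption=(~fixed).astype(float),
        faces_um=faces,
        light=light,
    )


# -- transient (dark shift) -------------------------------------------------


@dataclass(frozen=True)
class DarkShiftResult:
    """Concentration time series at chosen depths after light-off (t = 0)."""

    scenario: GranuleScenario
    times_s: np.ndarray
    depths_um: np.ndarray
    conc_umol_per_l: np.ndarray  # shape (n_times, n_depths)
    p_gross_true_umol_per_l_per_s: np.ndarray
    field0: SteadyStateField

    def series(self, depth_um: float) -> DarkShiftSeries:
        j = int(np.argmin(np.abs(self.depths_um - depth_um)))
        if abs(self.depths_um[j] - depth_um) > 1e-6:
            raise ValidationError(f"depth {depth_um} µm was not sampled")
        return DarkShiftSeries(
            depth_um=float(self.depths_um[j]),
            times_s=self.times_s,
            conc_umol_per_l=self.conc_umol_per_l[:, j],
        )


def solve_dark_shift(
    scenario: GranuleScenario,
    depths_um: Sequence[float],
    duration_s: float = 10.0,
    sample_dt_s: float = 1.0,
    grid_spacing_um: float = 5.0,
    rtol: float = 1e-8,
    atol: float = 1e-8,
) -> DarkShiftResult:
    """Method-of-lines transient after switching the light off.

    Starts from the illuminated steady state; at t = 0 light-dependent
    layers switch off and the field relaxes.  At each depth the initial
    dC/dt equals −P_gross there (dark respiration is unchanged and was
    balanced at steady state) before diffusion relaxes the gradients.
    Sampled at ≥ 1 Hz.
    """
    if sample_dt_s > 1.0 + 1e-12:
        raise ValidationError("dark-shift sampling must be at least 1 Hz")
    field0 = solve_steady_state(scenario, grid_spacing_um, light=True)
    R = scenario.geometry.radius_um
    depths = np.asarray(depths_um, dtype=float)
    if np.any((depths < 0) | (depths > R)):
        raise ValidationError("dark-shift depths must lie within [0, R]")

    n_cells = field0.r_um.size - 1
    h = field0.grid_spacing_um
    A, b, prod, cons, faces, dirichlet = _assemble(
        scenario, n_cells, h, np.ones(n_cells + 1), light=False
    )
    cell_vol = (faces[1:] ** 3 - faces[:-1] ** 3) / 3.0  # ∫ r² dr per cell
    src = prod + cons
    inv_vol = 1.0 / cell_vol

    bulk = scenario.bulk_umol_per_l

    def rhs(_t, c):
        dc = (A @ c + src) * inv_vol
        if dirichlet:
            dc[-1] = 0.0  # surface node pinned at bulk
        return dc

    jac = sparse.diags(
        [
            A.diagonal(-1) * inv_vol[1:],
            A.diagonal(0) * inv_vol,
            A.diagonal(1) * inv_vol[:-1],
        ],
        [-1, 0, 1],
        format="csc",
    ).tolil()
    if dirichlet:
        jac[-1, :] = 0.0
    jac = jac.tocsc()

    c0 = field0.conc_umol_per_l.copy()
    if dirichlet:
        c0[-1] = bulk
    t_eval = np.arange(0.0, duration_s + 1e-9, sample_dt_s)
    sol = integrate.solve_ivp(
        rhs,
        (0.0, duration_s),
        c0,
        method="BDF",
        t_eval=t_eval,
        jac=jac,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:  # pragma: no cover - defensive
        raise PhotogranuleError(f"transient solve failed: {sol.message}")
    radii = R - depths
    conc = np.empty((t_eval.size, depths.size))
    for i in range(t_eval.size):
        conc[i] = np.interp(radii, field0.r_um, sol.y[:, i])
    return DarkShiftResult(
        scenario=scenario,
        times_s=t_eval,
        depths_um=depths,
        conc_umol_per_l=conc,
        p_gross_true_umol_per_l_per_s=scenario.gross_photosynthesis_at(radii),
        field0=field0,
    )


# -- sampling and ground truth ----------------------------------------------


@dataclass(frozen=True)
class SimulatedProfile:
    """A sampled depth profile with its ground-truth shell rates."""

    profile: DepthProfile
    truth: RateProfile
    grid: ShellGrid


def _truth_rate_profile(field: SteadyStateField, grid: ShellGrid) -> RateProfile:
    """Exact per-shell rates implied by the (front-masked) imposed sources."""
    src, faces = field.effective_cell_sources()  # ∫ q_eff r² dr per cell
    cell_r3 = (faces[1:] ** 3 - faces[:-1] ** 3) / 3.0
    q_cell = np.divide(src, cell_r3, out=np.zeros_like(src), where=cell_r3 > 0)
    cum = np.concatenate(([0.0], np.cumsum(src)))  # ∫₀^face q_eff r² dr

    def integral_to(x: np.ndarray) -> np.ndarray:
        idx = np.clip(np.searchsorted(faces, x, side="right") - 1, 0, src.size - 1)
        partial = q_cell[idx] * (x**3 - faces[idx] ** 3) / 3.0
        return cum[idx] + partial

    bounds = grid.interface_radii_um
    net = integral_to(bounds[:-1]) - integral_to(bounds[1:])
    net *= 4.0 * np.pi * UMOL_PER_L_TO_NMOL_PER_UM3 * SECONDS_PER_HOUR
    volumes_mm3 = grid.shell_volumes_um3 / UM3_PER_MM3
    return RateProfile(
        grid=grid,
        net_rate_nmol_per_h=net,
        volumetric_rate_nmol_per_mm3_per_h=net / volumes_mm3,
        total_rate_nmol_per_h=float(net.sum()),
        surface_flux_nmol_per_h=float(net.sum()),
        analyte=field.scenario.analyte,
        diffusion_um2_per_s=field.scenario.d_um2_per_s,
    )


def sample_profile(
    field: SteadyStateField,
    depths_um: Sequence[float],
    noise_sigma_umol_per_l: float | None = None,
    seed: int | None = None,
) -> SimulatedProfile:
    """Sample the fine-grid field at measurement depths, with seeded noise.

    Interpolates the field, adds additive Gaussian noise (σ defaults to
    the scenario's), clips at zero, and attaches the ground-truth shell
    rates integrated on the sampling grid.
    """
    scenario = field.scenario
    R = scenario.geometry.radius_um
    depths = np.asarray(depths_um, dtype=float)
    if np.any((depths < 0) | (depths > R)):
        raise ValidationError("sampling depths must lie within [0, R]")
    sigma = (
        scenario.noise_sigma_umol_per_l
        if noise_sigma_umol_per_l is None
        else float(noise_sigma_umol_per_l)
    )
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    conc = field.concentration_at_depth(depths)
    if sigma > 0:
        conc = conc + rng.normal(0.0, sigma, size=conc.shape)
    conc = np.maximum(conc, 0.0)
    profile = DepthProfile(
        analyte=scenario.analyte,
        depths_um=depths,
        conc_umol_per_l=conc,
        condition="synthetic",
    )
    grid = build_shell_grid(scenario.geometry, depths)
    truth = _truth_rate_profile(field, grid)
    return SimulatedProfile(profile=profile, truth=truth, grid=grid)


# -- stochastic fixture generators ------------------------------------------


def generate_isotope_series(
    nitrification_nmol_per_h: float,
    denitrification_nmol_per_h: float,
    labelled_fraction: float = 1.0,
    times_h: Sequence[float] = (0.0, 2.0, 4.5, 5.5),
    sigma_nmol: float = 0.0,
    seed: int = 0,
    nox0_nmol: float = 0.0,
    label: str = "ammonium",
    light: bool = False,
    acetate: bool = False,
) -> IsotopeTimeSeries:
    """Closed-vial tracer series with linear-in-time accumulation.

    Total ¹⁵N–N₂ accumulates at denitrification × F (F = labelled
    fraction of the NOₓ pool) and is split into ²⁹N₂ : ³⁰N₂ as
    2F(1−F) : F² by random isotope pairing; NOₓ accumulates at
    (nitrification − denitrification).  Additive Gaussian noise σ is
    applied per observable and amounts are floored at 0.
    """
    F = labelled_fraction
    if not 0 < F <= 1:
        raise ValidationError("labelled fraction must lie in (0, 1]")
    if nitrification_nmol_per_h < 0 or denitrification_nmol_per_h < 0:
        raise ValidationError("rates must be non-negative")
    if sigma_nmol < 0:
        raise ValidationError("noise σ cannot be negative")
    t = np.asarray(times_h, dtype=float)
    n2_total = denitrification_nmol_per_h * t / 2.0  # nmol N₂ molecules
    e30 = n2_total * F**2
    e29 = n2_total * 2.0 * F * (1.0 - F)
    nox = nox0_nmol + (nitrification_nmol_per_h - denitrification_nmol_per_h) * t
    if np.any(nox < 0):
        raise ValidationError("scenario drives NOₓ below zero; raise nox0_nmol")
    rng = np.random.default_rng(seed)
    if sigma_nmol > 0:
        e29 = e29 + rng.normal(0.0, sigma_nmol, t.size)
        e30 = e30 + rng.normal(0.0, sigma_nmol, t.size)
        nox = nox + rng.normal(0.0, sigma_nmol, t.size)
    return IsotopeTimeSeries(
        times_h=t,
        excess29_nmol=np.maximum(e29, 0.0),
        excess30_nmol=np.maximum(e30, 0.0),
        nox_nmol=np.maximum(nox, 0.0),
        label=label,
        light=light,
        acetate=acetate,
    )


def generate_light_profile(
    wavelengths_nm: Sequence[float],
    depths_um: Sequence[float],
    k_per_um,
    excess_band_nm: tuple[float, float] | None = None,
    excess_amplitude: float = 0.3,
    excess_length_um: float = 300.0,
) -> SpectralIrradianceProfile:
    """Exponential spectral light field, optionally with a >1 excess band.

    ``k_per_um`` may be a scalar or one value per wavelength.  Within
    ``excess_band_nm`` the relative irradiance exceeds the surface value
    at shallow depths (decaying over ``excess_length_um``), emulating
    pigment fluorescence / scattering in the 700–800 nm range.
    """
    wl = np.asarray(wavelengths_nm, dtype=float)
    z = np.asarray(depths_um, dtype=float)
    k = np.broadcast_to(np.asarray(k_per_um, dtype=float), wl.shape).copy()
    if np.any(k < 0):
        raise ValidationError("attenuation coefficients must be ≥ 0")
    rel = np.exp(-np.outer(z, k))
    if excess_band_nm is not None:
        lo, hi = excess_band_nm
        in_band = (wl >= lo) & (wl <= hi)
        bump = 1.0 + excess_amplitude * np.exp(-z / excess_length_um)
        bump[z == 0] = 1.0  # surface stays normalized
        rel[:, in_band] = bump[:, None]
    return SpectralIrradianceProfile(depths_um=z, wavelengths_nm=wl, relative_irradiance=rel)
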