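"""2D mixture model of tumor growth with fibroblast barriers and chemotaxis.

The tissue is an incompressible mixture of four active components —
cancer cells (``C``), T-cells (``T``), non-activated fibroblasts
(``NA``) and activated fibroblasts / CAFs (``A``) — plus a passive
phase ``phi0 = 1 - sum(phi_i)`` (interstitial fluid, healthy and dead
cells) that also supplies the material consumed by proliferation.  Each
species obeys a conservation law

    d(phi_i)/dt + div(phi_i v_i) = Gamma_i

with velocities from the Onsager principle of least dissipation: the
per-cell 4x4 friction matrix ``A`` couples species velocities through
``sum_j A_ij v_j = -grad(mu_i)``, where ``mu_i`` are chemical potentials
of a Flory-Huggins free energy with a square-gradient penalty.  CAFs
produce matrix fibers, modeled as an extra friction ``xi1 * phi_A`` on
every pair involving the CAF component: a dense CAF ring is a
mechanical barrier for every motile species, including T-cells.

A single chemoattractant ``c`` produced by cancer cells and degraded at
a rate setting the penetration length ``lambda_c`` obeys a quasi-static
screened-Poisson equation; it drives the boundary influx of T-cells and
NAFs (chemotaxis from vasculature) and the NAF -> CAF conversion.

Discretization: conservative flux-form finite differences on a uniform
cell-centered grid, upwinded advection, 5-point Laplacians, no-flux
outer boundaries.  Time stepping is first-order IMEX: transport and
sources are explicit while a constant-coefficient hyper-diffusive
stabilizer (classic linearly-stabilized splitting for Cahn-Hilliard
type equations) is treated implicitly through a DCT diagonalization of
the Neumann Laplacian, lifting the severe dt ~ dx^4 restriction of the
gradient-penalty term.  A fully explicit mode remains available.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
from scipy.fft import dctn, idctn

from tmemix.grid import Grid2D
from tmemix import _kernels

__all__ = [
    "SpatialParams",
    "FieldState",
    "SourceGeometry",
    "SourceToggles",
    "free_energy_density",
    "total_free_energy",
    "chemical_potentials",
    "friction_matrix",
    "solve_velocities",
    "chemical_field",
    "source_terms",
    "make_initial_condition",
    "step",
    "Simulation",
    "ScenarioConfig",
    "ScenarioResult",
    "run_scenario",
    "scenario_names",
    "SCENARIOS",
]

PHI_FLOOR = 1e-8  # floor inside logarithms
PHI0_FLOOR = 1e-6  # floor on the passive fraction before forming phi_i/phi0

_IDX = {"c": 0, "t": 1, "na": 2, "a": 3}


@dataclass(frozen=True)
class SpatialParams:
    """Coefficients of the spatial mixture model (units of µm, kg and T0).

    Defaults are the reference parameter set of the model: entropic
    coefficients ``d0 .. d_caf`` and attractions ``lambda_*`` in
    kg µm⁻¹ T0⁻², gradient penalty ``kappa`` in kg µm T0⁻², rates in
    T0⁻¹, frictions ``xi0``/``xi1`` in kg µm⁻³ T0⁻¹, and the
    chemoattractant penetration length ``lambda_c`` in µm with
    production/degradation ratio ``alpha_cc``.

    The boundary-influx coefficients ``tau_t``/``tau_na`` default to
    25 µm T0⁻¹, calibrated by a stationary mass balance: the boundary
    influx ``tau * c * (1-S)`` integrated over the perimeter must match
    the pressure-death sink ``delta * phi * S`` integrated over the
    domain at the reported stromal occupancy (~20-25% of the tissue),
    with the chemoattractant profile of a central nest.  The reference
    table's 2.5e-3 undershoots that balance by four orders of magnitude
    and produces a tissue with essentially no stroma; any literal value
    can still be passed explicitly.
    """

    d0: float = 1.0e6
    d_c: float = 1.0e5
    d_t: float = 2.5e5
    d_naf: float = 2.5e5
    d_caf: float = 2.5e5
    lambda_cc: float = 2.5e5
    lambda_ct: float = 7.5e5
    lambda_cf: float = 0.0
    kappa: float = 3.6e7
    delta: float = 1.18
    tau_t: float = 25.0
    tau_na: float = 25.0
    delta_ct: float = 5.0
    xi0: float = 3.0e2
    xi1: float = 3.0e5
    k_plast: float = 10.0
    lambda_c: float = 30.0
    alpha_cc: float = 3.0
    growth_rate: float = 1.0  # cancer proliferation prefactor, T0^-1
    # Proliferation is degenerate below this mass fraction: a fraction
    # smaller than ~one cell per representative volume is not an
    # established population, and without this cut any numerically
    # leaked mass would be amplified by e^t over a 35 T0 run.
    growth_threshold: float = 1e-4
    # Whether mu_i carries the passive-phase osmotic term -d0(1+log phi0)
    # from phi0 = 1 - sum(phi).  Off by default: with it, the mixture is
    # strictly convex (no interface can exist) and every species gains a
    # dilute diffusivity ~d0/xi0 that disperses the nest; without it the
    # printed coefficients give a spinodal at C > d_c/(2 lambda_cc) = 0.2
    # and an interface width sqrt(kappa/(2 lambda_cc)) ~ 8.5 µm.
    d0_osmotic: bool = False

    def __post_init__(self) -> None:
        vec = np.array(
            [
                getattr(self, f.name)
                for f in self.__dataclass_fields__.values()
                if f.type != "bool"
            ],
            dtype=float,
        )
        if not np.all(np.isfinite(vec)) or np.any(vec < 0):
            raise ValueError("spatial parameters must be finite and >= 0")

    @classmethod
    def low_ct_attraction(cls, **kwargs) -> "SpatialParams":
        """Alternative profile with weak cancer/T-cell attraction.

        The reference table lists ``lambda_ct > lambda_cc`` although the
        accompanying text calls the cross-attractions low; this profile
        follows the text (``lambda_ct = 0.3 * lambda_cc``).
        """
        base = cls(**kwargs)
        return replace(base, lambda_ct=0.3 * base.lambda_cc)

    def diff_coeffs(self) -> np.ndarray:
        return np.array([self.d_c, self.d_t, self.d_naf, self.d_caf])


@dataclass(frozen=True)
class SourceToggles:
    """Scenario switches for the source terms.

    ``efficiency``: T-cells kill cancer cells (delta_ct active);
    ``activation``: NAF -> CAF conversion (k_plast active);
    ``t_source`` / ``naf_source``: chemotactic influx at the source
    geometry; ``growth``: cancer proliferation term; ``pressure``: the
    delta-weighted crowding death terms (off only for transport-only
    conservation studies).
    """

    efficiency: bool = True
    activation: bool = True
    t_source: bool = True
    naf_source: bool = True
    growth: bool = True
    pressure: bool = True

    @classmethod
    def all_off(cls) -> "SourceToggles":
        return cls(
            efficiency=False, activation=False, t_source=False,
            naf_source=False, growth=False, pressure=False,
        )


@dataclass(frozen=True)
class SourceGeometry:
    """Where T-cells and NAFs enter the tissue (vasculature proxy)."""

    mode: str = "whole-boundary"  # whole-boundary | vessel-disks | boundary-segment
    disks: tuple[tuple[tuple[float, float], float], ...] = ()
    segment: str = "right"

    def resolve(self, grid: Grid2D) -> np.ndarray:
        """Boolean mask of source cells."""
        if self.mode == "whole-boundary":
            return grid.boundary_mask()
        if self.mode == "boundary-segment":
            return grid.boundary_mask(self.segment)
        if self.mode == "vessel-disks":
            if not self.disks:
                raise ValueError("vessel-disks mode needs at least one disk")
            mask = np.zeros(grid.shape, dtype=bool)
            for center, radius in self.disks:
                mask |= grid.disk_mask(center, radius)
            return mask
        raise ValueError(f"unknown source mode {self.mode!r}")


@dataclass
class FieldState:
    """Gridded mass fractions of the four species plus the chemoattractant."""

    grid: Grid2D
    phi: np.ndarray  # (4, ny, nx): C, T, NA, A
    c: np.ndarray
    time: float = 0.0

    def __post_init__(self) -> None:
        self.phi = np.asarray(self.phi, dtype=float)
        self.c = np.asarray(self.c, dtype=float)
        if self.phi.shape != (4, *self.grid.shape):
            raise ValueError("phi must have shape (4, ny, nx)")
        if self.c.shape != self.grid.shape:
            raise ValueError("c must have shape (ny, nx)")

    @classmethod
    def zeros(cls, grid: Grid2D) -> "FieldState":
        return cls(grid, np.zeros((4, *grid.shape)), np.zeros(grid.shape))

    @property
    def phi_c(self) -> np.ndarray:
        return self.phi[0]

    @property
    def phi_t(self) -> np.ndarray:
        return self.phi[1]

    @property
    def phi_na(self) -> np.ndarray:
        return self.phi[2]

    @property
    def phi_a(self) -> np.ndarray:
        return self.phi[3]

    @property
    def active_sum(self) -> np.ndarray:
        return self.phi.sum(axis=0)

    @property
    def phi0(self) -> np.ndarray:
        return 1.0 - self.active_sum

    def validate(self, tol: float = 1e-6) -> None:
        if self.phi.min() < -tol or self.phi.max() > 1.0 + tol:
            raise ValueError("mass fractions must lie in [0, 1]")
        if self.phi0.min() < -tol:
            raise ValueError("passive fraction phi0 must be >= 0 cell-wise")
        if self.c.min() < -tol:
            raise ValueError("chemoattractant concentration must be >= 0")

    def copy(self) -> "FieldState":
        return FieldState(self.grid, self.phi.copy(), self.c.copy(), self.time)

    def species_means(self) -> dict[str, float]:
        return {
            name: float(self.phi[i].mean())
            for name, i in (("C", 0), ("T", 1), ("NA", 2), ("A", 3))
        }


# ---------------------------------------------------------------------------
# DCT helpers: the 5-point Neumann Laplacian (mirror ghosts) is diagonal in
# the type-II cosine basis, which gives O(N log N) screened-Poisson and
# stabilizer solves with exactly the same stencil as Grid2D.laplacian.
# ---------------------------------------------------------------------------


def _neumann_eigs(grid: Grid2D) -> np.ndarray:
    """-eigenvalues (>= 0) of the 5-point Neumann Laplacian, shape (ny, nx)."""
    kx = (2.0 / grid.dx * np.sin(np.pi * np.arange(grid.nx) / (2 * grid.nx))) ** 2
    ky = (2.0 / grid.dx * np.sin(np.pi * np.arange(grid.ny) / (2 * grid.ny))) ** 2
    return ky[:, None] + kx[None, :]


def _dct2(a: np.ndarray) -> np.ndarray:
    return dctn(a, type=2, norm="ortho")


def _idct2(a: np.ndarray) -> np.ndarray:
    return idctn(a, type=2, norm="ortho")


def chemical_field(
    phi_c: np.ndarray,
    params: SpatialParams,
    grid: Grid2D,
    eigs: np.ndarray | None = None,
) -> np.ndarray:
    """Quasi-static chemoattractant: lambda_c^2 lap(c) - c + alpha_cc*phi_c = 0.

    Solved spectrally with no-flux boundaries; uniform production yields
    ``c = alpha_cc * phi_c`` exactly and a localized source decays with
    penetration length ``lambda_c``.
    """
    if np.min(phi_c) < -1e-9 or np.max(phi_c) > 1.0 + 1e-9:
        raise ValueError("phi_c must lie in [0, 1]")
    if eigs is None:
        eigs = _neumann_eigs(grid)
    rhs = params.alpha_cc * phi_c
    c = _idct2(_dct2(rhs) / (1.0 + params.lambda_c**2 * eigs))
    return np.maximum(c, 0.0)


# ---------------------------------------------------------------------------
# Energetics
# ---------------------------------------------------------------------------


def _xlogx(x: np.ndarray) -> np.ndarray:
    """x*log(x) continuously extended to 0 at x = 0."""
    out = np.zeros_like(x)
    pos = x > 0
    out[pos] = x[pos] * np.log(x[pos])
    return out


def free_energy_density(
    fields: FieldState, params: SpatialParams, include_passive: bool = True
) -> np.ndarray:
    """Flory-Huggins interaction potential f (kg µm⁻¹ T0⁻²), cell-wise.

    ``include_passive=False`` omits the passive-phase entropy
    ``d0 * phi0 log(phi0)``, matching the dynamical potentials when
    ``params.d0_osmotic`` is off.
    """
    fields.validate()
    phi = np.clip(fields.phi, 0.0, 1.0)
    phi0 = np.clip(fields.phi0, 0.0, 1.0)
    d = params.diff_coeffs()
    f = params.d0 * _xlogx(phi0) if include_passive else np.zeros(phi0.shape)
    for i in range(4):
        f += d[i] * _xlogx(phi[i])
    c, t, na, a = phi
    f -= params.lambda_cc * c**2
    f -= params.lambda_ct * c * t
    f -= params.lambda_cf * c * (na + a)
    return f


def total_free_energy(fields: FieldState, params: SpatialParams) -> float:
    """Discrete free energy F = sum over cells (f + kappa/2 sum |grad phi|^2) dx^2.

    Uses the interaction potential consistent with the dynamical
    chemical potentials (passive-phase entropy included only when
    ``params.d0_osmotic`` is set), so that F is a Lyapunov functional
    of the source-free dynamics.
    """
    g = fields.grid
    f = free_energy_density(fields, params, include_passive=params.d0_osmotic)
    grad = sum(g.grad_sq(fields.phi[i]) for i in range(4))
    return float(((f + 0.5 * params.kappa * grad) * g.cell_area).sum())


def chemical_potentials(
    fields: FieldState,
    params: SpatialParams,
    floor_counter: dict | None = None,
) -> np.ndarray:
    """Chemical potentials mu_i = df/dphi_i - kappa lap(phi_i), shape (4, ny, nx).

    The chain-rule term ``-d0*(1 + log phi0)`` from the passive fraction
    enters only when ``params.d0_osmotic`` is set (see SpatialParams).
    Logarithm arguments are floored at ``PHI_FLOOR`` (and ``PHI0_FLOOR``
    for phi0); floored cells are counted when a counter dict is
    supplied.
    """
    g = fields.grid
    phi = fields.phi
    phi0 = fields.phi0
    if floor_counter is not None:
        floor_counter["phi"] = floor_counter.get("phi", 0) + int(
            (phi < PHI_FLOOR).sum()
        )
        floor_counter["phi0"] = floor_counter.get("phi0", 0) + int(
            (phi0 < PHI0_FLOOR).sum()
        )
    if params.d0_osmotic:
        log0 = np.log(np.maximum(phi0, PHI0_FLOOR))
        common = -params.d0 * (1.0 + log0)
    else:
        common = np.zeros(phi0.shape)
    d = params.diff_coeffs()
    c, t, na, a = phi
    mu = np.empty_like(phi)
    for i in range(4):
        mu[i] = d[i] * (1.0 + np.log(np.maximum(phi[i], PHI_FLOOR))) + common
        mu[i] -= params.kappa * g.laplacian(phi[i])
    mu[0] -= 2.0 * params.lambda_cc * c + params.lambda_ct * t + params.lambda_cf * (
        na + a
    )
    mu[1] -= params.lambda_ct * c
    mu[2] -= params.lambda_cf * c
    mu[3] -= params.lambda_cf * c
    return mu


# ---------------------------------------------------------------------------
# Onsager friction matrix and velocity solve
# ---------------------------------------------------------------------------


def friction_matrix(fields: FieldState, params: SpatialParams) -> np.ndarray:
    """Per-cell 4x4 friction matrix A (kg µm⁻³ T0⁻¹), shape (ny, nx, 4, 4).

    Pairwise frictions are ``xi0`` for every pair except those involving
    the CAF component, which carry ``xi0 + xi1*phi_A`` (fiber drag).
    With ``phi_tilde_i = phi_i / phi0`` (phi0 floored at ``PHI0_FLOOR``):

        A_ii = sum_{j != i} (xi_ij + xi_j0*phi_tilde_i) phi_j
               + xi_i0 (1 + phi_tilde_i)^2
        A_ij = phi_j (-xi_ij + xi_i0 + xi_j0 + sum_k xi_k0 phi_tilde_k)

    where the off-diagonal form is the published expression with the
    telescoping ``xi_i0(1+phi_tilde_i) - xi_i0 phi_tilde_i`` collapsed.
    Species order: (C, T, NA, A).
    """
    ny, nx = fields.grid.shape
    phi = np.moveaxis(fields.phi, 0, -1)  # (ny, nx, 4)
    phi0 = np.maximum(fields.phi0, PHI0_FLOOR)[..., None]
    phit = phi / phi0  # phi_tilde
    phi_a = phi[..., 3]

    xi_caf = params.xi0 + params.xi1 * phi_a  # friction of any pair with CAFs
    # xi0_i: friction of species i with the passive phase (a pair with CAFs
    # only when i is the CAF component itself)
    xi_i0 = np.empty((ny, nx, 4))
    xi_i0[..., :3] = params.xi0
    xi_i0[..., 3] = xi_caf
    # pairwise xi_ij, i != j
    xi = np.full((ny, nx, 4, 4), params.xi0)
    xi[..., 3, :] = xi_caf[..., None]
    xi[..., :, 3] = xi_caf[..., None]

    cross = (xi_i0 * phit).sum(axis=-1)  # sum_k xi_k0 phi_tilde_k

    a = (
        phi[..., None, :]
        * (-xi + xi_i0[..., :, None] + xi_i0[..., None, :] + cross[..., None, None])
    )
    diag = (xi[..., :, :] + xi_i0[..., None, :] * phit[..., :, None]) * phi[
        ..., None, :
    ]
    diag = diag.sum(axis=-1) - (
        (xi[..., np.arange(4), np.arange(4)] + xi_i0 * phit) * phi
    )  # drop j == i from the sum
    diag += xi_i0 * (1.0 + phit) ** 2
    a[..., np.arange(4), np.arange(4)] = diag
    return a


def solve_velocities(
    a: np.ndarray,
    mu: np.ndarray,
    grid: Grid2D,
    cond_threshold: float = 1e10,
    xi0: float = 3.0e2,
    reg_counter: dict | None = None,
    weights: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Solve sum_j A_ij v_j = -grad(mu_i) cell-wise.

    With ``weights`` (shape (4, ny, nx), typically the mass fractions)
    the right-hand side becomes the force density ``-phi_i grad(mu_i)``.
    Returns ``(vx, vy)`` each of shape (4, ny, nx).  Cells whose 1-norm
    condition estimate exceeds ``cond_threshold`` get a Tikhonov shift
    ``1e-8 * xi0`` on the diagonal (counted when a dict is supplied).
    Also returns, through the counter dict, the inverse matrices under
    key ``"ainv"`` for reuse by the stabilizer estimate.
    """
    ny, nx = grid.shape
    rhs = np.empty((ny, nx, 4, 2))
    for i in range(4):
        gx, gy = grid.gradient(mu[i])
        w = 1.0 if weights is None else weights[i]
        rhs[..., i, 0] = -gx * w
        rhs[..., i, 1] = -gy * w
    try:
        ainv = np.linalg.inv(a)
    except np.linalg.LinAlgError:
        a = a + (1e-8 * xi0) * np.eye(4)
        ainv = np.linalg.inv(a)
        if reg_counter is not None:
            reg_counter["cells"] = reg_counter.get("cells", 0) + a.shape[0] * a.shape[1]
    cond = np.abs(a).sum(axis=-2).max(axis=-1) * np.abs(ainv).sum(axis=-2).max(axis=-1)
    bad = cond > cond_threshold
    if bad.any():
        if reg_counter is not None:
            reg_counter["cells"] = reg_counter.get("cells", 0) + int(bad.sum())
        a = a.copy()
        a[bad] += (1e-8 * xi0) * np.eye(4)
        ainv = np.linalg.inv(a)
    v = ainv @ rhs  # (ny, nx, 4, 2)
    if reg_counter is not None:
        reg_counter["ainv"] = ainv
    vx = np.moveaxis(v[..., 0], -1, 0)
    vy = np.moveaxis(v[..., 1], -1, 0)
    return vx, vy


# ---------------------------------------------------------------------------
# Sources
# ---------------------------------------------------------------------------


def source_terms(
    fields: FieldState,
    c: np.ndarray,
    geometry: SourceGeometry,
    params: SpatialParams,
    toggles: SourceToggles = SourceToggles(),
    source_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Proliferation/death/influx rates Gamma_i, shape (4, ny, nx).

    Cancer cells proliferate in place (logistic through the pressure
    term) and are killed by T-cells when ``efficiency`` is on; CAF
    inhibition of killing is not present here — the fiber barrier acts
    through friction instead.  T-cells and NAFs enter on the source
    cells at rate ``c*(1-S)*tau/dx`` (a surface flux spread over one
    cell layer) and die under pressure; NAFs convert to CAFs at rate
    ``k_plast * c`` when ``activation`` is on.
    """
    g = fields.grid
    phi = fields.phi
    s = fields.active_sum
    if source_mask is None:
        source_mask = geometry.resolve(g)
    gam = np.zeros_like(phi)
    pc, pt, pna, pa = phi
    press = params.delta if toggles.pressure else 0.0
    # cancer: growth - killing - pressure
    gam[0] = -press * pc * s
    if toggles.growth:
        gam[0] += params.growth_rate * pc * (pc > params.growth_threshold)
    if toggles.efficiency:
        gam[0] -= params.delta_ct * pc * pt
    # T-cells: boundary influx + pressure death
    gam[1] = -press * pt * s
    if toggles.t_source:
        gam[1][source_mask] += (
            c[source_mask] * (1.0 - s[source_mask]) * params.tau_t / g.dx
        )
    # NAFs: boundary influx - activation - pressure
    gam[2] = -press * pna * s
    if toggles.naf_source:
        gam[2][source_mask] += (
            c[source_mask] * (1.0 - s[source_mask]) * params.tau_na / g.dx
        )
    gam[3] = -press * pa * s
    if toggles.activation:
        conv = params.k_plast * pna * c
        gam[2] -= conv
        gam[3] += conv
    return gam


# ---------------------------------------------------------------------------
# Initial conditions
# ---------------------------------------------------------------------------


def _tanh_disk(
    grid: Grid2D,
    center: tuple[float, float],
    radius: float,
    width: float,
    amplitude: float,
) -> np.ndarray:
    x, y = grid.coords()
    r = np.hypot(x - center[0], y - center[1])
    return amplitude * 0.5 * (1.0 - np.tanh((r - radius) / width))


def make_initial_condition(
    kind: str,
    grid: Grid2D,
    params: SpatialParams | None = None,
    nest_radius: float = 40.0,
    interface_width: float = 10.0,
    nest_amplitude: float = 0.8,
    nest_offset: float = 30.0,
) -> FieldState:
    """Initial field state: ``empty``, ``single-nest`` or ``two-nests``.

    A nest is a dense cancer phase (mass fraction 0.8) separated from
    the dilute phase by a tanh interface of width ~10 µm.  Two nests sit
    mirror-symmetric at ``nest_offset`` µm from the domain center.  The
    chemoattractant starts at its quasi-static profile.
    """
    if params is None:
        params = SpatialParams()
    state = FieldState.zeros(grid)
    cx, cy = grid.lx / 2.0, grid.ly / 2.0
    if kind == "empty":
        pass
    elif kind == "single-nest":
        if nest_radius + interface_width > min(cx, cy):
            raise ValueError("nest does not fit in the domain")
        state.phi[0] = _tanh_disk(
            grid, (cx, cy), nest_radius, interface_width, nest_amplitude
        )
    elif kind == "two-nests":
        if nest_offset + nest_radius + interface_width > min(cx, cy):
            raise ValueError("nests do not fit in the domain")
        total = _tanh_disk(
            grid, (cx - nest_offset, cy), nest_radius, interface_width, nest_amplitude
        ) + _tanh_disk(
            grid, (cx + nest_offset, cy), nest_radius, interface_width, nest_amplitude
        )
        if total.max() > nest_amplitude + 1e-9:
            import warnings

            warnings.warn("overlapping nests capped at the nest amplitude")
        state.phi[0] = np.minimum(total, nest_amplitude)
    else:
        raise ValueError(f"unknown initial-condition kind {kind!r}")
    # truncate the sub-threshold tanh tail: tissue outside the nest is
    # genuinely empty of cancer cells, not populated at 1e-10
    state.phi[0][state.phi[0] < params.growth_threshold] = 0.0
    state.c = chemical_field(state.phi[0], params, grid)
    return state


# ---------------------------------------------------------------------------
# Time stepping
# ---------------------------------------------------------------------------


def _upwind_divergence(
    grid: Grid2D, phi: np.ndarray, vx: np.ndarray, vy: np.ndarray
) -> np.ndarray:
    """div(phi v) in conservative flux form with upwinded face values.

    Face velocities are the average of adjacent cell centers; boundary
    faces carry zero flux, so grid totals are conserved to round-off.
    """
    dx = grid.dx
    div = np.zeros_like(phi)
    # x-faces
    vf = 0.5 * (vx[:, 1:] + vx[:, :-1])
    phif = np.where(vf > 0, phi[:, :-1], phi[:, 1:])
    flux = phif * vf
    div[:, :-1] += flux / dx
    div[:, 1:] -= flux / dx
    # y-faces
    vf = 0.5 * (vy[1:, :] + vy[:-1, :])
    phif = np.where(vf > 0, phi[:-1, :], phi[1:, :])
    flux = phif * vf
    div[:-1, :] += flux / dx
    div[1:, :] -= flux / dx
    return div


class Simulation:
    """Driver holding parameters, geometry, caches and run counters."""

    def __init__(
        self,
        state: FieldState,
        params: SpatialParams | None = None,
        geometry: SourceGeometry | None = None,
        toggles: SourceToggles | None = None,
        dt_cap: float = 1e-3,
        cfl_safety: float = 0.8,
        transport: bool = True,
        stabilized: bool = True,
        stab_factor: float = 2.0,
        dt_update_every: int = 20,
        method: str = "euler",
        use_kernel: bool = True,
        velocity_rhs: str = "grad_mu",
    ) -> None:
        self.state = state
        self.params = params or SpatialParams()
        self.geometry = geometry or SourceGeometry()
        self.toggles = toggles or SourceToggles()
        self.dt_cap = dt_cap
        self.cfl_safety = cfl_safety
        self.transport = transport
        self.stabilized = stabilized
        self.stab_factor = stab_factor
        self.dt_update_every = dt_update_every
        self.method = method
        self.use_kernel = use_kernel
        # Per-species mobility law: cohesive phases (the cancer nest and
        # matrix-embedded CAFs) move as pressure-driven dense phases
        # (degenerate force density -phi grad mu); individually motile
        # cells (T-cells, NAFs) keep the bare -grad mu drive.
        masks = {
            "mixed": np.array([True, False, False, True]),
            "phi_grad_mu": np.ones(4, dtype=bool),
            "grad_mu": np.zeros(4, dtype=bool),
        }
        if velocity_rhs not in masks:
            raise ValueError(
                "velocity_rhs must be 'mixed', 'phi_grad_mu' or 'grad_mu'"
            )
        self.velocity_rhs = velocity_rhs
        self._weight_mask = masks[velocity_rhs]
        self.grid = state.grid
        self._mob_max = 0.0
        self._eigs = _neumann_eigs(self.grid)
        self._source_mask = self.geometry.resolve(self.grid)
        self.counters: dict = {"floor": {}, "reg": {}, "clip": 0, "steps": 0}
        self.dt_history: list[float] = []
        self._dt = dt_cap
        self._stab_denom: np.ndarray | None = None
        self._vmax = 0.0
        self.n_steps = 0

    # -- single-step pieces --------------------------------------------------

    def _rates(
        self, state: FieldState, need_mobility: bool = False
    ) -> tuple[np.ndarray, np.ndarray, float]:
        """Explicit rate d(phi)/dt, the chemoattractant, and max |v|."""
        p, g = self.params, self.grid
        c = chemical_field(np.clip(state.phi[0], 0.0, 1.0), p, g, self._eigs)
        vmax = 0.0
        rate = np.zeros_like(state.phi)
        if self.transport:
            reg = self.counters["reg"]
            floor = self.counters["floor"]
            wmask = self._weight_mask
            if self.use_kernel and _kernels.HAVE_NUMBA:
                tr, vmax, kc = _kernels.transport_rate(
                    state.phi,
                    g.dx,
                    p.diff_coeffs(),
                    p.d0 if p.d0_osmotic else 0.0,
                    p.lambda_cc,
                    p.lambda_ct,
                    p.lambda_cf,
                    p.kappa,
                    p.xi0,
                    p.xi1,
                    PHI_FLOOR,
                    PHI0_FLOOR,
                    1e-8 * p.xi0,
                    wmask,
                )
                rate += tr
                floor["phi"] = floor.get("phi", 0) + kc["phi"]
                floor["phi0"] = floor.get("phi0", 0) + kc["phi0"]
                if kc["reg"]:
                    reg["cells"] = reg.get("cells", 0) + kc["reg"]
            else:
                mu = chemical_potentials(state, p, floor)
                a = friction_matrix(state, p)
                weights = np.where(
                    wmask[:, None, None], np.clip(state.phi, 0.0, 1.0), 1.0
                )
                vx, vy = solve_velocities(
                    a, mu, g, xi0=p.xi0, reg_counter=reg, weights=weights
                )
                reg.pop("ainv", None)
                vmax = float(max(np.abs(vx).max(), np.abs(vy).max()))
                for i in range(4):
                    rate[i] -= _upwind_divergence(g, state.phi[i], vx[i], vy[i])
            if need_mobility:
                # local mobility scale phi_i^w * (A^-1)_ii for the stabilizer
                ainv = np.linalg.inv(friction_matrix(state, p))
                diag = ainv[..., np.arange(4), np.arange(4)]
                phi = np.clip(np.moveaxis(state.phi, 0, -1), 0.0, 1.0)
                phi = np.where(wmask[None, None, :], phi * phi, phi)
                self._mob_max = float(np.max(phi * np.abs(diag)))
                self._phi0_min = max(float(state.phi0.min()), 0.05)
        rate += source_terms(
            state, c, self.geometry, p, self.toggles, self._source_mask
        )
        return rate, c, vmax

    def _set_dt(self, dt: float) -> None:
        if dt <= 0 or not math.isfinite(dt):
            raise RuntimeError("time step underflow (CFL violation)")
        self._dt = dt
        if self.stabilized and self.transport:
            p = self.params
            mob = self._mob_max
            s_bar = self.stab_factor * mob * p.kappa
            # entropic stiffness scale from the *current* passive fraction:
            # an absolute worst-case floor here would smear mass globally
            d0_eff = p.d0 / getattr(self, "_phi0_min", 0.2) if p.d0_osmotic else 0.0
            d_bar = self.stab_factor * mob * (p.diff_coeffs().max() + d0_eff)
            stab_g = d_bar * self._eigs + s_bar * self._eigs**2
            self._stab_denom = 1.0 + dt * stab_g
        else:
            self._stab_denom = None

    def _update_dt(self, vmax: float) -> None:
        dt = self.dt_cap
        if vmax > 0:
            dt = min(dt, self.cfl_safety * self.grid.dx / vmax)
        if not self.stabilized and self.transport:
            # explicit bound of the gradient-penalty (hyper-diffusive) term
            p = self.params
            mob = max(self._mob_max, 1e-300)
            dt = min(dt, self.cfl_safety * self.grid.dx**4 / (32.0 * mob * p.kappa))
            dmax = mob * (p.d0 / max(PHI0_FLOOR, 1e-3) + p.diff_coeffs().max())
            dt = min(dt, self.cfl_safety * self.grid.dx**2 / (4.0 * dmax))
        self._set_dt(dt)

    def step(self, dt: float | None = None) -> FieldState:
        """Advance the state by one time step (adaptive dt unless given)."""
        st = self.state
        refresh = dt is not None or self.n_steps % self.dt_update_every == 0
        rate, c, vmax = self._rates(st, need_mobility=refresh)
        self._vmax = vmax
        if dt is not None:
            self._set_dt(dt)
        elif self.n_steps % self.dt_update_every == 0:
            self._update_dt(vmax)
        h = self._dt
        if self.method == "heun":
            pred = FieldState(st.grid, st.phi + h * rate, c, st.time + h)
            rate2, c2, _ = self._rates(pred)
            rate = 0.5 * (rate + rate2)
        new_phi = st.phi + h * rate
        if self._stab_denom is not None:
            # implicit constant-coefficient damping of the stiff linear part
            for i in range(4):
                incr = new_phi[i] - st.phi[i]
                new_phi[i] = st.phi[i] + _idct2(_dct2(incr) / self._stab_denom)
        neg = new_phi < 0.0
        if neg.any():
            # zero every negative, but budget-count only undershoots beyond
            # the tolerated -1e-6 band: the implicit stabilizer sheds
            # sub-1e-6 ripples around sharp interfaces that are repaired,
            # not clipped
            self.counters["clip"] += int((new_phi < -1e-6).sum())
            new_phi = np.where(neg, 0.0, new_phi)
        over = new_phi.sum(axis=0)
        bad = over > 1.0
        if bad.any():
            # renormalize overfull cells onto the simplex boundary
            new_phi[:, bad] /= over[bad]
        self.state = FieldState(st.grid, new_phi, c, st.time + h)
        self.n_steps += 1
        self.dt_history.append(h)
        self.counters["steps"] += 1
        return self.state

    def run(
        self,
        t_end: float,
        observer: Callable[[FieldState], None] | None = None,
        observe_every: float = 0.5,
    ) -> FieldState:
        """Step until ``t_end``, invoking ``observer`` on a time cadence."""
        next_obs = self.state.time
        while self.state.time < t_end - 1e-12:
            if observer is not None and self.state.time >= next_obs - 1e-12:
                observer(self.state)
                next_obs += observe_every
            self.step()
        if observer is not None:
            observer(self.state)
        return self.state


def step(
    state: FieldState,
    params: SpatialParams | None = None,
    geometry: SourceGeometry | None = None,
    toggles: SourceToggles | None = None,
    dt: float = 1e-3,
    transport: bool = True,
    stabilized: bool = True,
) -> FieldState:
    """One explicit update of the conservation laws (functional wrapper)."""
    sim = Simulation(
        state.copy(),
        params=params,
        geometry=geometry,
        toggles=toggles,
        dt_cap=dt,
        transport=transport,
        stabilized=stabilized,
    )
    return sim.step(dt=dt)


# ---------------------------------------------------------------------------
# Scenarios
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScenarioConfig:
    """A registered spatial scenario plus its geometry and output cadence.

    The default window (150 µm, single nest R = 20 µm, two nests
    R = 15 µm at ±30 µm from the center) is calibrated so that the
    boundary — the vasculature that supplies T-cells and fibroblasts —
    lies within a few chemoattractant penetration lengths of the nest;
    the window size of the original study is unreported.
    """

    name: str
    n: int = 128
    length: float = 150.0
    nest_radius: float | None = None  # per-scenario default when None
    interface_width: float = 10.0
    nest_offset: float = 30.0
    t_end: float = 35.0
    dt_cap: float = 1e-3
    observe_every: float = 0.5
    snapshot_every: float = 5.0
    velocity_rhs: str = "grad_mu"
    param_overrides: tuple[tuple[str, float], ...] = ()

    def grid(self) -> Grid2D:
        return Grid2D.square(self.n, self.length)

    def params(self) -> SpatialParams:
        return replace(SpatialParams(), **dict(self.param_overrides))

    def resolved_radius(self, ic_kind: str) -> float:
        if self.nest_radius is not None:
            return self.nest_radius
        return 20.0 if ic_kind == "single-nest" else 15.0


# toggles and initial condition per registered scenario
SCENARIOS: dict[str, dict] = {
    # stroma present (T and NAF influx) but T inefficient, no CAF conversion
    "free-growth": dict(
        toggles=SourceToggles(efficiency=False, activation=False),
        ic="single-nest",
    ),
    # nothing but cancer cells: no influx at all
    "free-growth-no-stroma": dict(
        toggles=SourceToggles(
            efficiency=False, activation=False, t_source=False, naf_source=False
        ),
        ic="single-nest",
    ),
    "naf-only": dict(
        toggles=SourceToggles(efficiency=False, activation=False, t_source=False),
        ic="single-nest",
    ),
    "naf-plus-inefficient-T": dict(
        toggles=SourceToggles(efficiency=False, activation=False),
        ic="single-nest",
    ),
    # CAF barrier forms and T-cells are efficient: immune-excluded tumor
    "immune-excluded": dict(toggles=SourceToggles(), ic="single-nest"),
    # CAF barrier without an efficient immune response: fibrotic confinement
    "caf-no-efficient-T": dict(
        toggles=SourceToggles(efficiency=False), ic="single-nest"
    ),
    # efficient T-cells, no CAF conversion: immune-inflamed tumor
    "immune-inflamed": dict(
        toggles=SourceToggles(activation=False), ic="single-nest"
    ),
    "two-nests-desert": dict(
        toggles=SourceToggles(efficiency=False, activation=False), ic="two-nests"
    ),
    "two-nests-excluded": dict(toggles=SourceToggles(), ic="two-nests"),
    "two-nests-inflamed": dict(
        toggles=SourceToggles(activation=False), ic="two-nests"
    ),
    "vessel-disks": dict(
        toggles=SourceToggles(activation=False),
        ic="single-nest",
        geometry="vessel-disks",
    ),
    "boundary-segment": dict(
        toggles=SourceToggles(activation=False),
        ic="single-nest",
        geometry="boundary-segment",
    ),
}


def scenario_names() -> list[str]:
    return list(SCENARIOS)


@dataclass
class ScenarioResult:
    config: ScenarioConfig
    observables: "object"  # pandas.DataFrame: time series of the run
    snapshots: list[FieldState]
    counters: dict

    def to_netcdf(self, path) -> None:
        """Write snapshots as a self-describing array container (x, y, time)."""
        self.to_dataset().to_netcdf(path, engine="scipy")

    def to_dataset(self):
        import xarray as xr

        g = self.config.grid()
        x = (np.arange(g.nx) + 0.5) * g.dx
        y = (np.arange(g.ny) + 0.5) * g.dx
        times = [s.time for s in self.snapshots]
        data = {
            name: (
                ("time", "y", "x"),
                np.stack([s.phi[i] for s in self.snapshots]),
            )
            for name, i in (("phi_c", 0), ("phi_t", 1), ("phi_na", 2), ("phi_a", 3))
        }
        data["c"] = (("time", "y", "x"), np.stack([s.c for s in self.snapshots]))
        return xr.Dataset(data, coords={"time": times, "y": y, "x": x})


def run_scenario(
    config: ScenarioConfig | str,
    progress: bool = False,
) -> ScenarioResult:
    """Run a registered scenario and collect the standard observables.

    The observable series are the thresholded area fractions (nest,
    fibrotic, T-cell-rich, threshold 0.1) and the per-species domain
    means, sampled on the configured cadence.
    """
    from tmemix import observables as obs

    if isinstance(config, str):
        config = ScenarioConfig(name=config)
    try:
        entry = SCENARIOS[config.name]
    except KeyError:
        raise KeyError(
            f"unknown scenario {config.name!r}; valid: {', '.join(SCENARIOS)}"
        ) from None
    grid = config.grid()
    params = config.params()
    geometry_kind = entry.get("geometry", "whole-boundary")
    if geometry_kind == "vessel-disks":
        r = 0.08 * config.length
        off = 0.28 * config.length
        cxy = config.length / 2.0
        geometry = SourceGeometry(
            mode="vessel-disks",
            disks=(
                ((cxy - off, cxy - off), r),
                ((cxy + off, cxy + off), r),
            ),
        )
    elif geometry_kind == "boundary-segment":
        geometry = SourceGeometry(mode="boundary-segment", segment="right")
    else:
        geometry = SourceGeometry()
    state = make_initial_condition(
        entry["ic"],
        grid,
        params,
        nest_radius=config.resolved_radius(entry["ic"]),
        interface_width=config.interface_width,
        nest_offset=config.nest_offset,
    )
    sim = Simulation(
        state,
        params=params,
        geometry=geometry,
        toggles=entry["toggles"],
        dt_cap=config.dt_cap,
        velocity_rhs=config.velocity_rhs,
    )
    rows: list[dict] = []
    snapshots: list[FieldState] = []
    next_snap = [0.0]

    def observer(s: FieldState) -> None:
        rows.append(
            {
                "time": s.time,
                "nest_area_frac": obs.area_fraction(s.phi[0], grid=grid),
                "fibrotic_area_frac": obs.area_fraction(s.phi[3], grid=grid),
                "tcell_area_frac": obs.area_fraction(s.phi[1], grid=grid),
                "n_nests": obs.label_nests(s.phi[0]),
                "mean_C": float(s.phi[0].mean()),
                "mean_T": float(s.phi[1].mean()),
                "mean_NA": float(s.phi[2].mean()),
                "mean_A": float(s.phi[3].mean()),
            }
        )
        if s.time >= next_snap[0] - 1e-9:
            snapshots.append(s.copy())
            next_snap[0] += config.snapshot_every
        if progress:
            print(
                f"[{config.name}] t={s.time:7.3f} nest={rows[-1]['nest_area_frac']:.3f}"
                f" meanC={rows[-1]['mean_C']:.4f}",
                flush=True,
            )

    sim.run(config.t_end, observer=observer, observe_every=config.observe_every)
    import pandas as pd

    counters = dict(sim.counters)
    if sim.dt_history:
        counters["dt"] = {
            "min": min(sim.dt_history),
            "max": max(sim.dt_history),
            "final": sim.dt_history[-1],
        }
    return ScenarioResult(
        config=config,
        observables=pd.DataFrame(rows),
        snapshots=snapshots,
        counters=counters,
    )
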