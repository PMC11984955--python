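"""Population dynamics of the lung tumor microenvironment.

Four interacting mass fractions — cancer cells ``C``, cytotoxic T-cells
``T``, non-activated fibroblasts ``F_NA`` and cancer-associated
(activated) fibroblasts ``F_A`` — evolve in a closed, well-mixed tissue
compartment.  Time is measured in units of the inverse cancer growth
rate, so every coefficient is dimensionless:

    dC/dt    = C - delta_ct * C*T / (1 + delta_tf * F_A) - delta_c * C*S
    dT/dt    = alpha_tc * C - delta_t * T*S
    dF_NA/dt = alpha_na + alpha_na_c * C - k_a * F_NA * C - delta_na * F_NA * S
    dF_A/dt  = k_a * F_NA * C - delta_a * F_A * S

with the active sum ``S = C + T + F_NA + F_A``; the passive fraction
``N = 1 - S`` (interstitial fluid, healthy and dead cells) never enters
the equations.  The ``delta_*`` pressure terms model competition for
space and resources; ``delta_ct`` is the rate at which T-cells kill
cancer cells, attenuated by CAF-mediated inhibition ``delta_tf``;
``alpha_tc`` is chemotactic T-cell recruitment; ``alpha_na`` is the
homeostatic fibroblast influx, ``alpha_na_c`` their attraction by the
tumor, and ``k_a`` the plasticity (NAF -> CAF) rate.

The module provides the right-hand side, time integration, a multistart
fixed-point/stability analysis, the six order-of-magnitude scenario
presets, outcome classification (invasion / persistence / eradication)
and the two-composite phase diagram of the equilibrium cancer fraction.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root
from scipy.stats import qmc

__all__ = [
    "CellState",
    "OdeParams",
    "ScalingParams",
    "FixedPoint",
    "Trajectory",
    "rhs",
    "simulate",
    "find_fixed_points",
    "scenario_params",
    "scenario_names",
    "classify_outcome",
    "phase_diagram",
    "PRESETS",
]

_SPECIES = ("c", "t", "f_na", "f_a")


@dataclass(frozen=True)
class CellState:
    """Mass fractions of the four active species.

    Each component must be non-negative and the active sum
    ``S = c + t + f_na + f_a`` may not exceed 1 (the remainder is the
    passive fraction ``N = 1 - S``).
    """

    c: float
    t: float
    f_na: float
    f_a: float

    def __post_init__(self) -> None:
        vec = self.as_array()
        if not np.all(np.isfinite(vec)):
            raise ValueError("state components must be finite")
        if np.any(vec < 0):
            raise ValueError(f"state components must be >= 0, got {tuple(vec)}")
        if vec.sum() > 1.0 + 1e-9:
            raise ValueError(f"active sum S={vec.sum():.6f} exceeds 1")

    def as_array(self) -> np.ndarray:
        return np.array([self.c, self.t, self.f_na, self.f_a], dtype=float)

    @classmethod
    def from_array(cls, vec: Sequence[float]) -> "CellState":
        c, t, f_na, f_a = (float(x) for x in vec)
        return cls(c, t, f_na, f_a)

    @property
    def active_sum(self) -> float:
        """S = C + T + F_NA + F_A."""
        return self.c + self.t + self.f_na + self.f_a

    @property
    def passive(self) -> float:
        """N = 1 - S, the inactive fraction."""
        return 1.0 - self.active_sum


@dataclass(frozen=True)
class OdeParams:
    """The ten interaction coefficients (time unit: inverse cancer growth rate).

    ``equal_pressure()`` applies the standard reduction in which all four
    pressure coefficients share a single value ``delta``.
    """

    delta_c: float = 1.0
    delta_t: float = 1.0
    delta_na: float = 1.0
    delta_a: float = 1.0
    delta_ct: float = 0.0
    delta_tf: float = 0.0
    alpha_tc: float = 0.0
    alpha_na: float = 0.0
    alpha_na_c: float = 0.0
    k_a: float = 0.0

    def __post_init__(self) -> None:
        vec = self.as_array()
        if not np.all(np.isfinite(vec)):
            raise ValueError("parameters must be finite (no NaN/inf)")
        if np.any(vec < 0):
            raise ValueError("all coefficients must be >= 0")

    def as_array(self) -> np.ndarray:
        return np.array(
            [
                self.delta_c,
                self.delta_t,
                self.delta_na,
                self.delta_a,
                self.delta_ct,
                self.delta_tf,
                self.alpha_tc,
                self.alpha_na,
                self.alpha_na_c,
                self.k_a,
            ],
            dtype=float,
        )

    @classmethod
    def equal_pressure(cls, delta: float = 1.0, **kwargs: float) -> "OdeParams":
        """All pressure coefficients set to a common ``delta``."""
        return cls(
            delta_c=delta, delta_t=delta, delta_na=delta, delta_a=delta, **kwargs
        )

    @property
    def is_equal_pressure(self) -> bool:
        return self.delta_c == self.delta_t == self.delta_na == self.delta_a


@dataclass(frozen=True)
class ScalingParams:
    """Order-of-magnitude bookkeeping for the asymptotic subsystem analysis.

    ``epsilon`` is the small parameter of the scaling ansatz
    (killing rate ``delta_ct = delta/epsilon``, recruitment
    ``alpha_tc = a0*epsilon``, inhibition ``delta_tf = d0*delta/epsilon``);
    the composite ratios quantifying T-cell efficiency and crowding are
    always recomputed from a concrete :class:`OdeParams`.
    """

    epsilon: float
    delta: float = 1.0
    a0: float = 1.0
    d0: float = 1.0
    f0: float = 1.0
    fa: float = 1.0
    fn: float = 1.0
    k: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.epsilon < 1.0:
            raise ValueError("epsilon must lie in (0, 1)")
        for name in ("delta", "a0", "d0", "f0", "fa", "fn", "k"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    def to_params(self) -> OdeParams:
        """Concrete coefficients of the fully-scaled system."""
        return OdeParams.equal_pressure(
            delta=self.delta,
            delta_ct=self.delta / self.epsilon,
            alpha_tc=self.a0 * self.epsilon,
            delta_tf=self.d0 * self.delta / self.epsilon,
            alpha_na=self.delta * self.epsilon**4,
            alpha_na_c=1.0,
            k_a=self.k * self.delta,
        )

    @staticmethod
    def kill_composite(p: OdeParams) -> float:
        """alpha_tc*delta_ct / (alpha_na_c*k_a*delta_tf): T-cell killing ability."""
        denom = p.alpha_na_c * p.k_a * p.delta_tf
        if denom == 0.0:
            return math.inf if p.alpha_tc * p.delta_ct > 0 else math.nan
        return p.alpha_tc * p.delta_ct / denom

    @staticmethod
    def crowd_composite(p: OdeParams) -> float:
        """alpha_na_c + alpha_tc: competition for space and resources."""
        return p.alpha_na_c + p.alpha_tc


@dataclass(frozen=True)
class FixedPoint:
    """A stationary state with its local linearization."""

    state: CellState
    eigenvalues: np.ndarray
    stable: bool
    marginal: bool = False
    residual: float = 0.0


@dataclass
class Trajectory:
    """Time series of the four mass fractions."""

    times: np.ndarray
    states: np.ndarray  # shape (n_times, 4), columns C, T, F_NA, F_A
    params: OdeParams | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        if self.states.shape != (self.times.size, 4):
            raise ValueError("states must have shape (len(times), 4)")

    @property
    def final_state(self) -> CellState:
        return CellState.from_array(np.clip(self.states[-1], 0.0, None))

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "time": self.times,
                "C": self.states[:, 0],
                "T": self.states[:, 1],
                "F_NA": self.states[:, 2],
                "F_A": self.states[:, 3],
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def _rhs_raw(y: np.ndarray, p: OdeParams) -> np.ndarray:
    """Right-hand side without domain checks (used by solvers)."""
    c, t, f_na, f_a = y
    s = c + t + f_na + f_a
    kill = p.delta_ct * c * t / (1.0 + p.delta_tf * f_a)
    return np.array(
        [
            c - kill - p.delta_c * c * s,
            p.alpha_tc * c - p.delta_t * t * s,
            p.alpha_na + p.alpha_na_c * c - p.k_a * f_na * c - p.delta_na * f_na * s,
            p.k_a * f_na * c - p.delta_a * f_a * s,
        ]
    )


def rhs(state: CellState, params: OdeParams) -> np.ndarray:
    """Time derivative (dC/dt, dT/dt, dF_NA/dt, dF_A/dt) at ``state``.

    Raises a ``ValueError`` for states outside the physical simplex or
    non-finite parameters (both enforced by the dataclass invariants).
    """
    if state.f_a < 0:  # guards the 1/(1 + delta_tf*F_A) denominator
        raise ValueError("F_A must be >= 0")
    return _rhs_raw(state.as_array(), params)


def _jacobian(y: np.ndarray, p: OdeParams, h: float = 1e-7) -> np.ndarray:
    """Central finite-difference Jacobian of the right-hand side."""
    n = y.size
    jac = np.empty((n, n))
    for j in range(n):
        step = h * max(1.0, abs(y[j]))
        yp, ym = y.copy(), y.copy()
        yp[j] += step
        ym[j] -= step
        jac[:, j] = (_rhs_raw(yp, p) - _rhs_raw(ym, p)) / (2.0 * step)
    return jac


def simulate(
    state0: CellState,
    params: OdeParams,
    t_end: float,
    n_out: int = 400,
    rtol: float = 1e-8,
    atol: float = 1e-12,
    method: str = "LSODA",
) -> Trajectory:
    """Integrate the system from ``state0`` to ``t_end``.

    Uses an adaptive, stiffness-switching integrator: the killing and
    inhibition coefficients sit an order of magnitude above the pressure
    scale, which makes the system mildly stiff near the CAF-dominated
    fixed points.
    """
    if t_end <= 0:
        raise ValueError("t_end must be > 0")
    t_eval = np.linspace(0.0, float(t_end), n_out)

    def _attempt(m: str):
        return solve_ivp(
            lambda _t, y: _rhs_raw(y, params),
            (0.0, float(t_end)),
            state0.as_array(),
            method=m,
            t_eval=t_eval,
            rtol=rtol,
            atol=atol,
        )

    sol = _attempt(method)
    if not sol.success and method == "LSODA":
        # very stiff corners of parameter space (e.g. delta_ct >> delta)
        # occasionally defeat LSODA's switching; Radau is slower but robust
        sol = _attempt("Radau")
    if not sol.success:
        raise RuntimeError(f"integration failed at t={sol.t[-1]:.6g}: {sol.message}")
    return Trajectory(times=sol.t, states=sol.y.T, params=params)


def find_fixed_points(
    params: OdeParams,
    n_starts: int = 50,
    seed: int = 0,
    dedupe_tol: float = 1e-6,
    residual_tol: float = 1e-10,
    stability_margin: float = 1e-8,
) -> list[FixedPoint]:
    """All distinct non-negative fixed points found by multistart root search.

    Starts are a scrambled Sobol' sample of the simplex plus the origin and
    the single-species corners; roots are deduplicated in max-norm, polished
    by Newton iteration to ``residual_tol``, and annotated with the Jacobian
    spectrum.  Eigenvalues whose real part lies within ``stability_margin``
    of zero mark the point as ``marginal`` rather than stable/unstable.
    """
    sampler = qmc.Sobol(d=4, scramble=True, seed=seed)
    starts = [np.zeros(4)] + [np.eye(4)[i] * 0.9 for i in range(4)]
    n_pow2 = 1 << max(0, (n_starts - 1).bit_length())
    raw = sampler.random(n_pow2)[:n_starts]
    # fold uniform cube samples toward the simplex: rescale rows with S > 1
    sums = raw.sum(axis=1, keepdims=True)
    raw = np.where(sums > 1.0, raw / sums, raw)
    starts.extend(raw)

    found: list[np.ndarray] = []
    for y0 in starts:
        sol = root(lambda y: _rhs_raw(y, params), y0, method="hybr", tol=1e-12)
        if not sol.success:
            continue
        y = sol.x
        # Newton polish to push the residual to solver tolerance.
        for _ in range(5):
            r = _rhs_raw(y, params)
            if np.max(np.abs(r)) < 1e-14:
                break
            try:
                y = y - np.linalg.solve(_jacobian(y, params), r)
            except np.linalg.LinAlgError:
                break
        if np.max(np.abs(_rhs_raw(y, params))) > residual_tol:
            continue
        if np.any(y < -1e-9) or y.sum() > 1.0 + 1e-6:
            continue
        y = np.clip(y, 0.0, None)
        if any(np.max(np.abs(y - f)) < dedupe_tol for f in found):
            continue
        found.append(y)

    if not found:
        warnings.warn("no fixed point converged from any start", RuntimeWarning)
        return []

    points = []
    for y in sorted(found, key=lambda v: tuple(v)):
        eig = np.linalg.eigvals(_jacobian(y, params))
        re = eig.real
        marginal = bool(np.any(np.abs(re) < stability_margin))
        stable = bool(np.all(re < 0)) and not marginal
        points.append(
            FixedPoint(
                state=CellState.from_array(y),
                eigenvalues=eig,
                stable=stable,
                marginal=marginal,
                residual=float(np.max(np.abs(_rhs_raw(y, params)))),
            )
        )
    return points


# ---------------------------------------------------------------------------
# Scenario presets: the six order-of-magnitude rows (epsilon = 0.1, delta = 1,
# alpha_na = 1e-4 as in the reference time courses).  Coefficients marked
# "no role" in a row are set to 0.
# ---------------------------------------------------------------------------

_EPS = 0.1
_ALPHA_NA = 1e-4

PRESETS: dict[str, OdeParams] = {
    # Efficient T-cells but no attraction by cancer cells (immune desert)
    "efficient-T-no-attraction": OdeParams.equal_pressure(
        delta_ct=10.0, alpha_tc=1e-2, alpha_na=_ALPHA_NA
    ),
    # Efficient T-cells but inhibited by CAFs (immune excluded)
    "efficient-T-inhibited": OdeParams.equal_pressure(
        delta_ct=10.0,
        alpha_tc=_EPS,
        delta_tf=10.0,
        alpha_na_c=1.0,
        k_a=1.0,
        alpha_na=_ALPHA_NA,
    ),
    # Inefficient T-cells, no need of fibroblasts (immune desert)
    "inefficient-T": OdeParams.equal_pressure(
        delta_ct=1.0, alpha_tc=_EPS, alpha_na=_ALPHA_NA
    ),
    # Efficient T-cells not inhibited by fibroblasts (immune inflamed)
    "efficient-T-uninhibited": OdeParams.equal_pressure(
        delta_ct=10.0,
        alpha_tc=_EPS,
        delta_tf=1.0,
        alpha_na_c=1.0,
        k_a=1.0,
        alpha_na=_ALPHA_NA,
    ),
    # Efficient T-cells and fibroblasts not attracted to the tumor
    "fibroblasts-not-attracted": OdeParams.equal_pressure(
        delta_ct=10.0,
        alpha_tc=_EPS,
        delta_tf=10.0,
        alpha_na_c=_EPS,
        k_a=1.0,
        alpha_na=_ALPHA_NA,
    ),
    # Efficient T-cells, fibroblasts not activated.  The printed attraction
    # entry for this row is internally inconsistent ("epsilon ~ 1"); we use 1
    # and leave the coefficient overridable.
    "fibroblasts-not-activated": OdeParams.equal_pressure(
        delta_ct=10.0,
        alpha_tc=_EPS,
        delta_tf=10.0,
        alpha_na_c=1.0,
        k_a=0.1,
        alpha_na=_ALPHA_NA,
    ),
}


def scenario_names() -> list[str]:
    return list(PRESETS)


def scenario_params(name: str, **overrides: float) -> OdeParams:
    """Coefficients of a named scenario preset, with optional overrides."""
    try:
        base = PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown scenario {name!r}; valid names: {', '.join(PRESETS)}"
        ) from None
    return replace(base, **overrides) if overrides else base


@dataclass(frozen=True)
class OutcomeThresholds:
    """Classification cut-offs on the final cancer fraction."""

    eradication: float = 1e-3
    invasion: float = 0.5  # divided by delta_c at evaluation time
    drift: float = 1e-4  # relative drift over final window for stationarity


def classify_outcome(
    trajectory: Trajectory,
    thresholds: OutcomeThresholds = OutcomeThresholds(),
    delta: float | None = None,
) -> tuple[str, bool]:
    """Label the long-time fate of the cancer population.

    Returns ``(label, converged)`` with label one of ``"eradication"``
    (final C below the eradication cut), ``"invasion"`` (final C above
    ``invasion/delta``) or ``"persistence"``.  ``converged`` is False when
    the final 10% window still drifts by more than the stationarity
    tolerance.
    """
    if delta is None:
        delta = trajectory.params.delta_c if trajectory.params else 1.0
    c = trajectory.states[:, 0]
    tail = max(2, int(0.1 * c.size))
    window = trajectory.states[-tail:]
    scale = max(np.abs(window).max(), 1e-12)
    drift = np.abs(window[-1] - window[0]).max() / scale
    converged = bool(drift < thresholds.drift)
    c_final = float(c[-1])
    if c_final < thresholds.eradication:
        label = "eradication"
    elif c_final > thresholds.invasion / max(delta, 1e-12):
        label = "invasion"
    else:
        label = "persistence"
    return label, converged


def _params_from_composites(
    kill: float, crowd: float, base: OdeParams
) -> OdeParams | None:
    """Reconstruct coefficients realizing the two phase-diagram composites.

    The crowding composite is split equally between ``alpha_na_c`` and
    ``alpha_tc``; ``delta_tf`` and ``k_a`` are held at the CAF-inhibited
    preset values and ``delta_ct`` is solved from the killing composite.
    Returns None when the composite is unreachable with non-negative
    coefficients.
    """
    if kill < 0 or crowd <= 0:
        return None
    half = crowd / 2.0
    delta_ct = kill * base.k_a * base.delta_tf  # alpha_tc cancels alpha_na_c
    if not np.isfinite(delta_ct) or delta_ct < 0:
        return None
    return replace(base, alpha_tc=half, alpha_na_c=half, delta_ct=delta_ct)


def phase_diagram(
    kill_axis: Iterable[float],
    crowd_axis: Iterable[float],
    base: OdeParams | None = None,
    t_end: float = 400.0,
) -> dict:
    """Equilibrium cancer fraction over the (killing, crowding) plane.

    For each grid cell the underlying coefficients are rebuilt from the two
    composites, the system is relaxed from a small seed state, and the
    stationary cancer fraction is stored.  Cells whose composites cannot be
    realized with non-negative coefficients are NaN.
    """
    if base is None:
        base = PRESETS["efficient-T-inhibited"]
    kill_axis = np.asarray(list(kill_axis), dtype=float)
    crowd_axis = np.asarray(list(crowd_axis), dtype=float)
    if np.any(kill_axis < 0) or np.any(crowd_axis <= 0):
        raise ValueError("axes must be positive")
    c_eq = np.full((crowd_axis.size, kill_axis.size), np.nan)
    seed_state = CellState(0.01, 0.01, 0.01, 0.01)
    for i, crowd in enumerate(crowd_axis):
        for j, kill in enumerate(kill_axis):
            p = _params_from_composites(kill, crowd, base)
            if p is None:
                continue
            traj = simulate(seed_state, p, t_end=t_end, n_out=60)
            c_eq[i, j] = traj.states[-1, 0]
    return {
        "kill_axis": kill_axis,
        "crowd_axis": crowd_axis,
        "equilibrium_c": c_eq,
        "base": base,
    }
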