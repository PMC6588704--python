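"""Kinetic model of antagonistic lipid/carbohydrate fuel metabolism.

State variables: x = acyl-CoA concentration (lipid-derived fuel),
y = carbohydrate concentration.  The two pathways inhibit one another
through Hill terms:

    dx/dt = -beta1 * x + alpha1 / (1 + y^n1) - alpha3 / (1 + y^n3)
    dy/dt = -beta2 * y + alpha2 / (1 + x^n2)            ("corrected")

alpha1 is the triglyceride-hydrolysing activity of ATGL feeding the
acyl-CoA pool, alpha3 the acyl-CoA-hydrolysing activity of ACOT7 draining
it, alpha2 the carbohydrate-pathway activity, beta1/beta2 consumption
rates, and n1..n3 Hill coefficients.  ATP output in carbohydrate
equivalents is z = 2.25 x + y (one unit of lipid fuel yields ~2.25 times
the energy of one unit of carbohydrate).

The published form of the carbohydrate equation drains y at a rate
proportional to x ("as_printed": dy/dt = -beta2*x + ...).  Under that form
a weaker lipid pathway also weakens steady-state carbohydrate metabolism,
contradicting the biological narrative the model supports (mutual
antagonism; losing lipid fuel promotes the alternative pathway), so this
package defaults to the self-consumption form and keeps the printed form
behind ``equation_variant="as_printed"``.

With n1 = n2 = n3 = 1 the corrected system has the closed-form fixed point
given by the positive root of

    beta1*beta2*x^2 + (beta1*beta2 + beta1*alpha2 - delta*beta2)*x - delta*beta2 = 0

with delta = max(alpha1 - alpha3, 0), and y* = alpha2 / (beta2 (1 + x*)).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "KineticParams",
    "KineticState",
    "SweepResult",
    "LIPID_ENERGY_RATIO",
    "integrate",
    "steady_state",
    "atp_output",
    "sweep",
]

#: Energy yield of one unit of acyl-CoA relative to one unit of carbohydrate.
LIPID_ENERGY_RATIO = 2.25

CORRECTED = "corrected"
AS_PRINTED = "as_printed"


@dataclass(frozen=True)
class KineticParams:
    alpha1: float = 25.0  # ATGL lipid-hydrolytic activity (acyl-CoA influx)
    alpha2: float = 5.0   # carbohydrate-pathway activity
    alpha3: float = 10.0  # ACOT7 acyl-CoA-hydrolytic activity (acyl-CoA drain)
    beta1: float = 1.0    # acyl-CoA consumption rate, 1/time
    beta2: float = 1.0    # carbohydrate consumption rate, 1/time
    n1: float = 1.0
    n2: float = 1.0
    n3: float = 1.0
    equation_variant: str = CORRECTED

    def __post_init__(self) -> None:
        for name in ("alpha1", "alpha2", "alpha3", "beta1", "beta2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("n1", "n2", "n3"):
            if getattr(self, name) < 1:
                raise ValueError(f"Hill coefficient {name} must be >= 1")
        if self.equation_variant not in (CORRECTED, AS_PRINTED):
            raise ValueError(f"unknown equation variant {self.equation_variant!r}")


@dataclass(frozen=True)
class KineticState:
    x: float
    y: float
    t: float = 0.0

    def __post_init__(self) -> None:
        if self.x < 0 or self.y < 0:
            raise ValueError("concentrations must be non-negative")

    @property
    def z(self) -> float:
        """ATP output in carbohydrate-equivalent units."""
        return LIPID_ENERGY_RATIO * self.x + self.y


def _raw_rhs(params: KineticParams):
    """Unclamped vector field (pools treated as the given non-negative values)."""
    p = params

    def rhs(t: float, s) -> np.ndarray:
        x = max(s[0], 0.0)
        y = max(s[1], 0.0)
        dx = -p.beta1 * x + p.alpha1 / (1.0 + y**p.n1) - p.alpha3 / (1.0 + y**p.n3)
        if p.equation_variant == CORRECTED:
            dy = -p.beta2 * y + p.alpha2 / (1.0 + x**p.n2)
        else:
            dy = -p.beta2 * x + p.alpha2 / (1.0 + x**p.n2)
        return np.array([dx, dy])

    return rhs


def _clamped_rhs(params: KineticParams):
    """Projected vector field: an empty pool with outflow stays at zero."""
    raw = _raw_rhs(params)

    def rhs(t: float, s) -> np.ndarray:
        d = raw(t, s)
        for i in range(2):
            if s[i] <= 0.0 and d[i] < 0.0:
                d[i] = 0.0
        return d

    return rhs


def _integrate_clamped(
    params: KineticParams,
    init: np.ndarray,
    t_end: float,
    t_eval: np.ndarray | None,
    rtol: float,
    atol: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Piecewise integration with pools projected onto the non-negative cone.

    A pool that reaches zero while its unclamped derivative is negative is
    frozen on the boundary (its derivative replaced by zero) and released when
    the unclamped derivative turns positive again; each regime is integrated
    with smooth dynamics and regime changes are located by terminal events.
    This avoids the step-size collapse a discontinuous clamp induces in
    adaptive solvers.
    """
    raw = _raw_rhs(params)
    state = np.clip(np.asarray(init, dtype=float), 0.0, None)
    frozen = [state[i] <= 0.0 and raw(0.0, state)[i] < 0.0 for i in range(2)]
    t = 0.0
    ts: list[np.ndarray] = [np.array([0.0])]
    ys: list[np.ndarray] = [state.reshape(2, 1).copy()]

    for _ in range(10_000):  # bound on regime switches
        frozen_now = tuple(frozen)

        def rhs(tt, s):
            d = raw(tt, s)
            for i in range(2):
                if frozen_now[i]:
                    d[i] = 0.0
            return d

        # Small hysteresis margins keep asymptotic decay toward the boundary
        # (which never crosses it) from chattering the event detector.
        events = []
        for i in range(2):
            if frozen_now[i]:
                def release(tt, s, i=i):
                    return raw(tt, s)[i] - 1e-10
                release.terminal = True
                release.direction = 1.0
                events.append(release)
            else:
                def hit_zero(tt, s, i=i):
                    return s[i] + 1e-9
                hit_zero.terminal = True
                hit_zero.direction = -1.0
                events.append(hit_zero)

        seg_eval = None
        if t_eval is not None:
            seg_eval = t_eval[(t_eval > t) & (t_eval <= t_end)]
        sol = solve_ivp(
            rhs, (t, t_end), state, method="LSODA", rtol=rtol, atol=atol,
            t_eval=seg_eval, events=events, dense_output=t_eval is None,
        )
        if not sol.success:
            raise RuntimeError(f"integration failed: {sol.message}")
        seg_t = np.asarray(sol.t, dtype=float)
        seg_y = np.asarray(sol.y, dtype=float)
        if seg_t.size:
            ts.append(seg_t)
            ys.append(seg_y.reshape(2, -1))
        if sol.status != 1:  # reached t_end
            ts.append(np.array([t_end]))
            last = seg_y.reshape(2, -1)[:, -1] if seg_t.size else state
            ys.append(np.clip(last, 0.0, None).reshape(2, 1))
            break
        # a terminal event fired: update regime and continue
        for i in range(2):
            if sol.t_events[i].size:
                t = float(sol.t_events[i][0])
                state = np.clip(sol.y_events[i][0], 0.0, None)
                if frozen_now[i]:
                    frozen[i] = False
                else:
                    state[i] = 0.0
                    frozen[i] = True
                break
    else:
        raise RuntimeError("too many boundary regime switches")

    tt = np.concatenate(ts)
    yy = np.clip(np.concatenate(ys, axis=1), 0.0, None)
    if t_eval is not None:
        # keep exactly the requested grid (segments already restricted to it)
        keep = np.searchsorted(tt, t_eval)
        keep = np.clip(keep, 0, tt.size - 1)
        # align by value: pick the first occurrence of each requested time
        out_y = np.empty((2, t_eval.size))
        for j, te in enumerate(t_eval):
            idx = int(np.argmin(np.abs(tt - te)))
            out_y[:, j] = yy[:, idx]
        return t_eval, out_y
    return tt, yy


def integrate(
    params: KineticParams,
    init: KineticState = KineticState(0.0, 0.0),
    t_end: float = 50.0,
    n_points: int = 501,
    rtol: float = 1e-10,
    atol: float = 1e-12,
) -> list[KineticState]:
    """Integrate the kinetic system from ``init`` to ``t_end``.

    Uses an adaptive stiffness-capable solver; the returned trajectory is
    sampled on an even time grid and clamped at zero (the boundary handling
    in the vector field already prevents meaningful negative excursions).
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    times = np.linspace(0.0, t_end, n_points)
    tt, yy = _integrate_clamped(
        params, np.array([init.x, init.y]), t_end, times, rtol, atol
    )
    return [
        KineticState(float(x), float(y), float(t)) for x, y, t in zip(yy[0], yy[1], tt)
    ]


def _closed_form_steady_state(p: KineticParams) -> KineticState:
    delta = max(p.alpha1 - p.alpha3, 0.0)
    b1, b2, a2 = p.beta1, p.beta2, p.alpha2
    # beta1*beta2*x^2 + (beta1*beta2 + beta1*alpha2 - delta*beta2)*x - delta*beta2 = 0
    a = b1 * b2
    b = b1 * b2 + b1 * a2 - delta * b2
    c = -delta * b2
    x = (-b + np.sqrt(b * b + 4.0 * a * (-c))) / (2.0 * a) if a > 0 else 0.0
    y = a2 / (b2 * (1.0 + x)) if b2 > 0 else 0.0
    return KineticState(float(max(x, 0.0)), float(max(y, 0.0)))


def steady_state(
    params: KineticParams,
    init: KineticState = KineticState(0.0, 0.0),
    max_time: float = 2000.0,
    tol: float = 1e-10,
) -> KineticState:
    """Fixed point of the kinetic system.

    The corrected system with unit Hill coefficients uses the closed-form
    quadratic solution; any other configuration is integrated until the
    vector field norm falls below ``tol``.
    """
    if (
        params.equation_variant == CORRECTED
        and params.n1 == params.n2 == params.n3 == 1.0
        and params.beta1 > 0
        and params.beta2 > 0
    ):
        return _closed_form_steady_state(params)

    rhs = _clamped_rhs(params)
    state = np.array([init.x, init.y])
    t, chunk = 0.0, 50.0
    while t < max_time:
        _, yy = _integrate_clamped(params, state, chunk, None, 1e-12, 1e-13)
        state = yy[:, -1]
        t += chunk
        if np.linalg.norm(rhs(0.0, state)) < tol:
            return KineticState(float(state[0]), float(state[1]))
    raise RuntimeError(f"no steady state reached within t={max_time}")


def atp_output(state: KineticState) -> tuple[float, float, float]:
    """(total z, lipid share, carbohydrate share) of the ATP output."""
    lipid = LIPID_ENERGY_RATIO * state.x
    carb = state.y
    return lipid + carb, lipid, carb


@dataclass
class SweepResult:
    parameter: str
    grid: np.ndarray
    x_star: np.ndarray
    y_star: np.ndarray
    lipid_energy: np.ndarray
    carb_energy: np.ndarray
    dominant: list[str]  # "lipid" or "carbohydrate" per grid value
    threshold: float | None  # parameter value at which dominance first switches
    criterion: str = "energy"

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "param": self.parameter,
                "value": self.grid,
                "x_star": self.x_star,
                "y_star": self.y_star,
                "lipid_energy": self.lipid_energy,
                "carb_energy": self.carb_energy,
                "dominant": self.dominant,
            }
        )


def sweep(
    params: KineticParams,
    parameter: str,
    grid: np.ndarray,
    criterion: str = "energy",
) -> SweepResult:
    """Steady states and fuel dominance along a monotone parameter grid.

    ``criterion="energy"`` compares the energy shares 2.25*x* vs y*;
    ``criterion="concentration"`` compares the pools x* vs y* directly.  The
    threshold is the first grid value (in traversal order) whose dominant
    fuel differs from the first grid point's; ``None`` when no switch occurs.
    """
    grid = np.asarray(grid, dtype=float)
    diffs = np.diff(grid)
    if len(grid) < 2 or not (np.all(diffs > 0) or np.all(diffs < 0)):
        raise ValueError("grid must be strictly monotone with at least two points")
    if criterion not in ("energy", "concentration"):
        raise ValueError("criterion must be 'energy' or 'concentration'")
    if parameter not in ("alpha1", "alpha2", "alpha3", "beta1", "beta2"):
        raise ValueError(f"cannot sweep parameter {parameter!r}")

    xs, ys = np.empty(len(grid)), np.empty(len(grid))
    for i, v in enumerate(grid):
        ss = steady_state(replace(params, **{parameter: float(v)}))
        xs[i], ys[i] = ss.x, ss.y
    lipid = LIPID_ENERGY_RATIO * xs
    carb = ys
    if criterion == "energy":
        dominant = ["lipid" if l > c else "carbohydrate" for l, c in zip(lipid, carb)]
    else:
        dominant = ["lipid" if x > y else "carbohydrate" for x, y in zip(xs, ys)]

    threshold: float | None = None
    for i in range(1, len(grid)):
        if dominant[i] != dominant[0]:
            threshold = float(grid[i])
            break

    return SweepResult(
        parameter=parameter,
        grid=grid,
        x_star=xs,
        y_star=ys,
        lipid_energy=lipid,
        carb_energy=carb,
        dominant=dominant,
        threshold=threshold,
        criterion=criterion,
    )
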