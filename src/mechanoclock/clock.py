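"""Three-species delay-differential model of the cellular circadian clock.

State variables are nuclear concentrations of BMAL1 (``B``), the lumped
PER/CRY pool (``P``) and REV-ERBalpha (``R``).  The core negative feedback is
delayed: REV-ERBalpha represses BMAL1 expression with delay ``tau_B`` (time
from transcription to nuclear accumulation of BMAL1), while BMAL1 activates
and PER/CRY represses E-box-driven expression of PER/CRY and REV-ERBalpha
with delays ``tau_P`` and ``tau_R``.  REV-ERBalpha expression is proportional
(factor ``zeta``) to PER/CRY expression, both genes being E-box regulated.

Mechanotransduction enters through additive expression terms: steady-state
nuclear YAP/TAZ and MRTF concentrations add Hill-type (exponent 2) production
of each clock species.  A cytosolic luciferase reporter driven by PER/CRY
expression is integrated on top of a solved trajectory for comparison with
PER2::Luc luminescence recordings.

Equations (concentrations in model units, time in hours):

    K_eB1(t) = K_eB0 / (1 + (R(t - tau_B)/K_IR)^2)
    g(B, P)  = K_eP0 * (B/K_aB)^2 / (1 + (B/K_aB)^2) / (1 + (P/K_IP)^2)
    K_eP1(t) = g(B(t - tau_P), P(t - tau_P))
    K_eR1(t) = zeta * g(B(t - tau_R), P(t - tau_R))

    K_eX2    = K_eX2_Y * Y^2/(K_Y^2 + Y^2) + K_eX2_M * M^2/(K_M^2 + M^2)
               for X in {B, P, R}  (Y, M: steady-state nuclear YAP/TAZ, MRTF)

    dB/dt = K_eB1(t) + K_eB2 - K_dB * B
    dP/dt = K_eP1(t) + K_eP2 - K_dP * P
    dR/dt = K_eR1(t) + K_eR2 - K_dR * R

    dL/dt = K_eL * (K_eP1(t) + K_eP2) - K_dL * L,  L(0) = 0
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Sequence

import numpy as np

from .dde import DDESolution, integrate_dde

__all__ = [
    "CircadianParams",
    "CouplingInput",
    "Trajectory",
    "coupling_rates",
    "dde_rhs",
    "fixed_point",
    "simulate_clock",
    "luciferase",
]

HILL_EXPONENT = 2  # fixed; does not alter qualitative model behavior


@dataclass
class CircadianParams:
    """Parameters of the clock DDEs.  Rates are per hour, delays in hours.

    Defaults are the packaged point estimates used throughout (the
    representative single cell); fitting ranges live in the parameter table
    fixture.
    """

    tau_B: float = 12.0   # REV-ERB repression delay on BMAL1 (h)
    tau_P: float = 9.0    # delay from PER/CRY transcription to nuclear protein (h)
    tau_R: float = 4.0    # delay from REV-ERB transcription to nuclear protein (h)
    K_dB: float = 0.12    # BMAL1 decay (1/h)
    K_dP: float = 0.30    # PER/CRY decay (1/h)
    K_dR: float = 0.12    # REV-ERB decay (1/h)
    K_dL: float = 0.30    # luciferase decay (1/h)
    K_eB0: float = 2.0    # max REV-ERB-repressible BMAL1 expression (conc/h)
    K_IR: float = 1.0     # REV-ERB repression half-constant
    K_eP0: float = 5.0    # max BMAL1-driven E-box expression (conc/h)
    K_aB: float = 1.0     # BMAL1 activation half-constant
    K_IP: float = 0.6     # PER/CRY self-repression half-constant
    zeta: float = 0.5     # REV-ERB / PER-CRY expression proportionality
    # mechano-coupling: magnitudes (conc/h) and half-max constants (conc)
    K_eB2_Y: float = 0.0750
    K_eB2_M: float = 0.0209
    K_eP2_Y: float = 1.500
    K_eP2_M: float = 0.4184
    K_eR2_Y: float = 0.600
    K_eR2_M: float = 0.1674
    K_Y: float = 1.7885      # YAP/TAZ Hill half-max (nuclear conc units)
    K_M: float = 4.5663      # MRTF Hill half-max
    K_eL: float = 1.0     # luciferase expression scale
    n_hill: int = HILL_EXPONENT

    def validate(self) -> None:
        positive = ("K_IR", "K_aB", "K_IP", "K_Y", "K_M", "zeta")
        for f_ in fields(self):
            v = np.asarray(getattr(self, f_.name))
            if (f_.name.startswith("tau") or f_.name.startswith("K_d")
                    or f_.name in positive):
                if np.any(v <= 0):
                    raise ValueError(f"{f_.name} must be > 0, got {v}")
            elif np.any(v < 0):
                raise ValueError(f"{f_.name} must be >= 0, got {v}")

    def with_(self, **kw) -> "CircadianParams":
        return replace(self, **kw)


@dataclass
class CouplingInput:
    """Mechano-coupled expression rates (output of :func:`coupling_rates`)."""

    K_eB2: float | np.ndarray = 0.0
    K_eP2: float | np.ndarray = 0.0
    K_eR2: float | np.ndarray = 0.0


@dataclass
class Trajectory:
    """Time-gridded clock solution.

    ``t`` in hours; ``B``, ``P``, ``R`` nuclear concentrations and optional
    luciferase ``L``; ``expr_P`` is the total PER/CRY expression rate series
    (the luciferase drive).  1-D arrays for a single cell.
    """

    t: np.ndarray
    B: np.ndarray
    P: np.ndarray
    R: np.ndarray
    L: np.ndarray | None = None
    expr_P: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def species(self, name: str) -> np.ndarray:
        return {"B": self.B, "P": self.P, "R": self.R, "L": self.L}[name]


def _hill_act(x, K):
    x = np.asarray(x, dtype=float)
    xn = x**HILL_EXPONENT
    return xn / (K**HILL_EXPONENT + xn)


def coupling_rates(Y_nuc, M_nuc, params: CircadianParams) -> CouplingInput:
    """Mechano-dependent expression terms from steady-state nuclear YAP/TAZ
    and MRTF concentrations.

    Each term is a sum of two activating Hill functions with exponent 2, one
    in YAP/TAZ and one in MRTF; monotone non-decreasing in both inputs and
    saturating at the sum of the two magnitudes.
    """
    Y_nuc = np.asarray(Y_nuc, dtype=float)
    M_nuc = np.asarray(M_nuc, dtype=float)
    if np.any(Y_nuc < 0) or np.any(M_nuc < 0):
        raise ValueError("nuclear concentrations must be non-negative")
    hY = _hill_act(Y_nuc, params.K_Y)
    hM = _hill_act(M_nuc, params.K_M)
    return CouplingInput(
        K_eB2=params.K_eB2_Y * hY + params.K_eB2_M * hM,
        K_eP2=params.K_eP2_Y * hY + params.K_eP2_M * hM,
        K_eR2=params.K_eR2_Y * hY + params.K_eR2_M * hM,
    )


def _expr_B(R_delayed, p: CircadianParams):
    return p.K_eB0 / (1.0 + (R_delayed / p.K_IR) ** HILL_EXPONENT)


def _expr_P(B_delayed, P_delayed, p: CircadianParams):
    act = (B_delayed / p.K_aB) ** HILL_EXPONENT
    return p.K_eP0 * act / (1.0 + act) / (1.0 + (P_delayed / p.K_IP) ** HILL_EXPONENT)


def dde_rhs(t, state, delayed_states, params: CircadianParams,
            coupling: CouplingInput):
    """Right-hand side of the clock DDEs.

    ``state`` has columns (B, P, R); ``delayed_states`` supplies the state at
    ``t - tau_B``, ``t - tau_P`` and ``t - tau_R`` (in that order).
    """
    if len(delayed_states) != 3:
        raise ValueError("expected delayed states at tau_B, tau_P and tau_R")
    state = np.atleast_2d(state)
    z_B, z_P, z_R = (np.atleast_2d(z) for z in delayed_states)
    B, P, R = state[:, 0], state[:, 1], state[:, 2]
    dB = _expr_B(z_B[:, 2], params) + coupling.K_eB2 - params.K_dB * B
    dP = _expr_P(z_P[:, 0], z_P[:, 1], params) + coupling.K_eP2 - params.K_dP * P
    dR = (params.zeta * _expr_P(z_R[:, 0], z_R[:, 1], params)
          + coupling.K_eR2 - params.K_dR * R)
    return np.stack([dB, dP, dR], axis=-1)


def fixed_point(params: CircadianParams, coupling: CouplingInput,
                tol: float = 1e-14) -> tuple:
    """Unique positive equilibrium (B*, P*, R*) of the clock DDEs.

    With constant state the delays drop out and the equilibrium satisfies a
    scalar equation in P*, monotone because PER/CRY production decreases both
    directly (self-repression) and through the R -> B chain; solved by
    bisection.  Accepts scalar or batched coupling inputs.
    """
    keB2 = np.atleast_1d(np.asarray(coupling.K_eB2, dtype=float))
    keP2 = np.atleast_1d(np.asarray(coupling.K_eP2, dtype=float))
    keR2 = np.atleast_1d(np.asarray(coupling.K_eR2, dtype=float))
    keB2, keP2, keR2 = np.broadcast_arrays(keB2, keP2, keR2)
    scalar = (np.ndim(coupling.K_eB2) == 0 and np.ndim(coupling.K_eP2) == 0
              and np.ndim(coupling.K_eR2) == 0)

    def B_of_P(Pv):
        # R* from P*: K_dR R = zeta*(K_dP P - K_eP2) + K_eR2
        Rv = (params.zeta * (params.K_dP * Pv - keP2) + keR2) / params.K_dR
        Rv = np.maximum(Rv, 0.0)
        return (_expr_B(Rv, params) + keB2) / params.K_dB, Rv

    def resid(Pv):
        Bv, _ = B_of_P(Pv)
        return params.K_dP * Pv - _expr_P(Bv, Pv, params) - keP2

    lo = np.zeros_like(keP2)
    hi = np.broadcast_to(
        (params.K_eP0 + keP2) / params.K_dP + 1.0, keP2.shape).astype(float).copy()
    if np.any(resid(hi) <= 0):
        raise RuntimeError("no positive clock fixed point found in bracket")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        r = resid(mid)
        hi = np.where(r > 0, mid, hi)
        lo = np.where(r > 0, lo, mid)
        if np.max(hi - lo) < tol:
            break
    P_star = 0.5 * (lo + hi)
    B_star, R_star = B_of_P(P_star)
    if np.any(P_star < 0) or np.any(B_star < 0) or np.any(R_star < 0):
        raise RuntimeError("negative clock fixed point")
    if scalar:
        return float(B_star[0]), float(P_star[0]), float(R_star[0])
    return B_star, P_star, R_star


def simulate_clock(
    params: CircadianParams,
    coupling: CouplingInput,
    duration: float = 144.0,
    dt_out: float = 0.25,
    dt: float = 0.025,
    initial_state: Sequence[float] | None = None,
) -> Trajectory:
    """Integrate the clock DDEs for a single parameter set.

    Initial conditions are B0 = 5 B*, P0 = 0.2 P*, R0 = R* at the fixed point
    of the given condition (a perturbed start that lets oscillations develop);
    history before t = 0 is held constant at the initial state.

    Parameters
    ----------
    duration : simulated time in hours (default 6 days).
    dt_out : output grid spacing in hours (<= 0.25 h).
    dt : internal integration step in hours.
    """
    params.validate()
    sol, _ = _integrate_batch(params, coupling, duration, dt,
                              initial_state=initial_state)
    return _solution_to_trajectory(sol, params, coupling, dt_out)


def _integrate_batch(params: CircadianParams, coupling: CouplingInput,
                     duration: float, dt: float,
                     initial_state=None) -> tuple[DDESolution, tuple]:
    B_s, P_s, R_s = fixed_point(params, coupling)
    if initial_state is None:
        y0 = np.stack(np.broadcast_arrays(
            5.0 * np.atleast_1d(B_s), 0.2 * np.atleast_1d(P_s),
            1.0 * np.atleast_1d(R_s)), axis=-1)
    else:
        y0 = np.atleast_2d(np.asarray(initial_state, dtype=float))
    delays = np.array([params.tau_B, params.tau_P, params.tau_R])

    def rhs(t, y, delayed):
        return dde_rhs(t, y, delayed, params, coupling)

    sol = integrate_dde(rhs, delays, y0, duration, dt)
    return sol, (B_s, P_s, R_s)


def _solution_to_trajectory(sol: DDESolution, params: CircadianParams,
                            coupling: CouplingInput, dt_out: float) -> Trajectory:
    stride = max(1, int(round(dt_out / sol.dt)))
    t = sol.t[::stride]
    Y = sol.y[::stride, 0, :]
    B, P, R = Y[:, 0], Y[:, 1], Y[:, 2]
    # delayed PER/CRY expression rate on the output grid (luciferase drive)
    s = np.maximum(t - params.tau_P, 0.0)
    idx = np.clip(np.round(s / sol.dt).astype(int), 0, sol.y.shape[0] - 1)
    Bd, Pd = sol.y[idx, 0, 0], sol.y[idx, 0, 1]
    keP2 = float(np.atleast_1d(coupling.K_eP2)[0])
    expr = _expr_P(Bd, Pd, params) + keP2
    traj = Trajectory(t=t, B=B, P=P, R=R, expr_P=expr,
                      meta={"dt": sol.dt, "coupling": coupling})
    if np.min(Y) < -1e-9:
        raise RuntimeError("clock trajectory went negative")
    return traj


def luciferase(traj: Trajectory, params: CircadianParams) -> Trajectory:
    """Attach the luciferase reporter series to a trajectory.

    Integrates dL/dt = K_eL * expr_P(t) - K_dL * L with L(0) = 0 by an
    exponential time-differencing rule that is exact for expression input
    piecewise linear (hence also piecewise constant) on the output grid.
    """
    if traj.expr_P is None:
        raise ValueError("trajectory lacks the PER/CRY expression-rate series")
    t, e = traj.t, params.K_eL * traj.expr_P
    k = params.K_dL
    L = np.zeros_like(t)
    dts = np.diff(t)
    E = np.exp(-k * dts)
    phi1 = (1.0 - E) / k
    for n in range(len(t) - 1):
        h = dts[n]
        a0, a1 = e[n], e[n + 1]
        L[n + 1] = (L[n] * E[n] + a0 * phi1[n]
                    + (a1 - a0) * (h / k - phi1[n] / k) / h)
    L = np.maximum(L, 0.0)
    return Trajectory(t=t, B=traj.B, P=traj.P, R=traj.R, L=L,
                      expr_P=traj.expr_P, meta=dict(traj.meta))
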