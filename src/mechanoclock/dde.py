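"""Method-of-steps integrator for delay differential equations.

The integrator advances a batch of independent systems (e.g. cells of a
population, or walkers of an ensemble sampler) on a shared uniform time grid
with classical fourth-order Runge-Kutta steps.  Delayed state is recovered
from the stored solution by cubic Hermite interpolation, which matches the
fourth-order accuracy of the stepper; the history for t <= 0 is the constant
initial condition.

Delays may differ between batch members but must each be either exactly zero
(the term is evaluated at the current time, so the system degenerates to an
ODE) or at least one grid step, so that every delayed lookup lands in the
already-computed part of the grid (the method-of-steps requirement).
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

__all__ = ["DDESolution", "integrate_dde"]


class DDESolution:
    """Dense solution of a batched DDE on a uniform grid.

    Attributes
    ----------
    t : (n_times,) array of grid times.
    y : (n_times, n_batch, n_dim) array of states.
    f : (n_times, n_batch, n_dim) array of stored derivatives (for Hermite
        interpolation).
    """

    def __init__(self, t: np.ndarray, y: np.ndarray, f: np.ndarray):
        self.t = t
        self.y = y
        self.f = f
        self.dt = t[1] - t[0] if len(t) > 1 else 1.0

    def __call__(self, s: np.ndarray, component: int | None = None) -> np.ndarray:
        """Interpolate the solution at times ``s`` (one time per batch member).

        Times before the grid start return the initial state (constant
        history).  Returns array (n_batch, n_dim) or (n_batch,) if a single
        component is requested.
        """
        s = np.asarray(s, dtype=float)
        out = _hermite_lookup(self.t[0], self.dt, self.y, self.f, s)
        if component is not None:
            return out[..., component]
        return out


def _hermite_lookup(t0: float, dt: float, Y: np.ndarray, F: np.ndarray,
                    s: np.ndarray) -> np.ndarray:
    """Cubic Hermite interpolation of (Y, F) grid data at per-batch times s."""
    n_grid = Y.shape[0]
    nb = Y.shape[1]
    rel = (s - t0) / dt
    j = np.floor(rel).astype(int)
    j = np.clip(j, 0, n_grid - 2)
    theta = rel - j
    # constant history before the grid
    theta = np.clip(theta, 0.0, 1.0)
    idx = np.arange(nb)
    y0 = Y[j, idx]
    y1 = Y[j + 1, idx]
    f0 = F[j, idx]
    f1 = F[j + 1, idx]
    th = theta[:, None]
    h00 = (1 + 2 * th) * (1 - th) ** 2
    h10 = th * (1 - th) ** 2
    h01 = th**2 * (3 - 2 * th)
    h11 = th**2 * (th - 1)
    return h00 * y0 + h10 * f0 * dt + h01 * y1 + h11 * f1 * dt


def integrate_dde(
    rhs: Callable[[float, np.ndarray, Sequence[np.ndarray]], np.ndarray],
    delays: np.ndarray,
    y0: np.ndarray,
    t_end: float,
    dt: float,
) -> DDESolution:
    """Integrate dy/dt = rhs(t, y, [y(t - tau_k)]) from t=0 to t_end.

    Parameters
    ----------
    rhs : callable(t, y, delayed) -> dy/dt with ``y`` of shape
        (n_batch, n_dim) and ``delayed`` a list of arrays of the same shape,
        one per delay.
    delays : array (n_delays, n_batch); each entry must be 0 or >= dt.
    y0 : (n_batch, n_dim) initial state, also the constant history.
    t_end : final time (> 0).
    dt : grid step.

    Notes
    -----
    A delay of exactly zero is replaced by the current (stage) state, which
    reduces the corresponding term to an instantaneous one.
    """
    y0 = np.atleast_2d(np.asarray(y0, dtype=float))
    nb, nd = y0.shape
    delays = np.asarray(delays, dtype=float)
    if delays.ndim == 1:
        delays = np.broadcast_to(delays[:, None], (delays.shape[0], nb)).copy()
    if np.any((delays > 0) & (delays < dt - 1e-12)):
        raise ValueError(
            f"all nonzero delays must be >= dt={dt}; got min positive delay "
            f"{delays[delays > 0].min():g}"
        )
    n_steps = int(np.ceil(t_end / dt - 1e-9))
    t = np.arange(n_steps + 1) * dt
    Y = np.empty((n_steps + 1, nb, nd))
    F = np.empty_like(Y)
    Y[0] = y0

    zero_mask = [delays[k] == 0.0 for k in range(delays.shape[0])]

    def delayed_states(ts: float, y_stage: np.ndarray, n_done: int) -> list:
        out = []
        for k in range(delays.shape[0]):
            s = ts - delays[k]
            vals = _hermite_lookup(0.0, dt, Y[: n_done + 1], F[: n_done + 1], s)
            if zero_mask[k].any():
                vals = np.where(zero_mask[k][:, None], y_stage, vals)
            out.append(vals)
        return out

    F[0] = rhs(0.0, y0, [y0.copy() for _ in range(delays.shape[0])])
    for n in range(n_steps):
        tn = t[n]
        yn = Y[n]
        k1 = F[n]
        k2 = rhs(tn + dt / 2, yn + dt / 2 * k1,
                 delayed_states(tn + dt / 2, yn + dt / 2 * k1, n))
        k3 = rhs(tn + dt / 2, yn + dt / 2 * k2,
                 delayed_states(tn + dt / 2, yn + dt / 2 * k2, n))
        k4 = rhs(tn + dt, yn + dt * k3, delayed_states(tn + dt, yn + dt * k3, n))
        ynew = yn + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        if not np.all(np.isfinite(ynew)):
            raise RuntimeError(
                f"DDE integration failed at t={tn + dt:.3f}: non-finite state"
            )
        Y[n + 1] = ynew
        F[n + 1] = rhs(tn + dt, ynew, delayed_states(tn + dt, ynew, n))
    return DDESolution(t, Y, F)
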