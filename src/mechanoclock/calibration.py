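"""Bayesian calibration of the coupled model against luminescence summaries,
and global (Sobol') sensitivity analysis.

Experimental references for fitting are period/amplitude summary statistics
(mean +/- s.d. per condition) of PER2-driven luciferase recordings.  Because
raw traces are not available, per-condition luminescence references are
reconstructed by Monte Carlo: period T and amplitude A are treated as
normal random variables and the relative luminescence waveform

    L_rel(t) = A * cos(2 pi t / T)

is averaged over draws to give a mean curve mu(t) and envelope sigma(t) on
an hourly grid (dephasing across draws makes mu decay, as in averaged
population recordings).  Model traces are shifted to their second peak,
normalized to the control-condition amplitude and mean-centered before
comparison.  The penalized Gaussian log-likelihood is sampled with the
affine-invariant ensemble sampler (emcee); convergence is assessed with the
integrated autocorrelation time.  Total-order Sobol' indices use
Saltelli-style radial sampling with Jansen's estimator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import emcee

from .clock import CircadianParams, coupling_rates, simulate_clock, luciferase
from .mechano import MechanoParams, TreatmentCondition, steady_state_network
from .metrics import NonOscillatoryError, period_amplitude

logger = logging.getLogger(__name__)

__all__ = [
    "CalibrationDataset",
    "FitSpace",
    "reconstruct_experiment",
    "normalize_model_trace",
    "log_likelihood",
    "penalized_log_likelihood",
    "run_mcmc",
    "iact",
    "sobol_total_order",
    "simulate_reporter",
]

ETA_DEFAULT = 100.0          # period-penalty weight
N_RECONSTRUCT = 1_000_000    # Monte Carlo draws per condition
FIT_HORIZON_H = 120.0        # 5 days on the hourly grid, post-shift
MCMC_WALKERS = 60
MCMC_STEPS = 1000
MCMC_BURN_IN = 500


@dataclass
class CalibrationDataset:
    """One condition's reconstructed luminescence reference."""

    condition: TreatmentCondition
    T_exp: float                 # reported period mean (h)
    T_sd: float
    A_exp: float                 # reported amplitude mean (normalized)
    A_sd: float
    t: np.ndarray = field(default=None)        # hourly grid (h)
    mu: np.ndarray = field(default=None)       # reconstructed mean
    sigma: np.ndarray = field(default=None)    # reconstructed s.d.

    def validate(self) -> None:
        if self.sigma is not None and np.any(self.sigma <= 0):
            raise ValueError("reconstructed s.d. must be > 0 at all points")


@dataclass
class FitSpace:
    """Free-parameter vector definition with uniform prior bounds.

    ``names`` use a ``circ.`` or ``mech.`` prefix selecting the parameter
    object a component updates.
    """

    names: list
    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self):
        self.lower = np.asarray(self.lower, dtype=float)
        self.upper = np.asarray(self.upper, dtype=float)
        if not (np.all(np.isfinite(self.lower)) and np.all(np.isfinite(self.upper))):
            raise ValueError("prior bounds must be finite")
        if np.any(self.lower >= self.upper):
            raise ValueError("prior bounds must satisfy lo < hi")

    @property
    def dim(self) -> int:
        return len(self.names)

    def in_bounds(self, theta: np.ndarray) -> bool:
        theta = np.asarray(theta, dtype=float)
        return bool(np.all(theta >= self.lower) and np.all(theta <= self.upper))

    def apply(self, theta, mech: MechanoParams, circ: CircadianParams):
        mk, ck = {}, {}
        for name, v in zip(self.names, theta):
            prefix, key = name.split(".", 1)
            (ck if prefix == "circ" else mk)[key] = float(v)
        return mech.with_(**mk), circ.with_(**ck)


def reconstruct_experiment(T_mean: float, T_sd: float, A_mean: float,
                           A_sd: float, n_samples: int = N_RECONSTRUCT,
                           horizon_h: float = FIT_HORIZON_H,
                           seed: int | None = 0) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Monte Carlo mean and s.d. of the reference waveform at hourly points.

    Draws (T, A) pairs from normal distributions; non-positive periods are
    rejected and redrawn (logged).  With zero s.d. the deterministic waveform
    is returned with sigma identically zero.
    """
    if T_sd < 0 or A_sd < 0:
        raise ValueError("standard deviations must be >= 0")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, horizon_h + 0.5, 1.0)
    if T_sd == 0 and A_sd == 0:
        mu = A_mean * np.cos(2 * np.pi * t / T_mean)
        return t, mu, np.zeros_like(mu)
    s = np.zeros_like(t)
    s2 = np.zeros_like(t)
    remaining = n_samples
    n_rejected = 0
    chunk = 50_000
    while remaining > 0:
        m = min(chunk, remaining)
        T = rng.normal(T_mean, T_sd, m)
        A = rng.normal(A_mean, A_sd, m)
        bad = T <= 1e-3
        while bad.any():
            n_rejected += int(bad.sum())
            T[bad] = rng.normal(T_mean, T_sd, int(bad.sum()))
            bad = T <= 1e-3
        w = A[:, None] * np.cos(2 * np.pi * t[None, :] / T[:, None])
        s += w.sum(axis=0)
        s2 += (w**2).sum(axis=0)
        remaining -= m
    if n_rejected:
        logger.info("rejected %d non-positive period draws", n_rejected)
    mu = s / n_samples
    var = np.maximum(s2 / n_samples - mu**2, 0.0)
    return t, mu, np.sqrt(var)


def simulate_reporter(mech: MechanoParams, circ: CircadianParams,
                      condition: TreatmentCondition, duration: float = 24.0 * 9,
                      dt: float = 0.05):
    """Mechano steady state -> clock DDEs -> luciferase trace (hourly-ready)."""
    state = steady_state_network(mech, condition)
    coup = coupling_rates(*state.nuclear_inputs(), circ)
    traj = simulate_clock(circ, coup, duration=duration, dt_out=0.25, dt=dt)
    return luciferase(traj, circ)


def normalize_model_trace(L_t: np.ndarray, L: np.ndarray,
                          control_amplitude: float,
                          horizon_h: float = FIT_HORIZON_H) -> tuple[np.ndarray, np.ndarray]:
    """Shift a luciferase trace to its second peak, normalize and center.

    Returns (hourly time grid starting at 0, normalized series).  Raises
    :class:`NonOscillatoryError` when fewer than two peaks exist (the
    comparison is undefined; calibration assigns -inf upstream).
    """
    if not control_amplitude > 0:
        raise ValueError("control amplitude must be > 0")
    from scipy.signal import find_peaks
    peaks, _ = find_peaks(L, prominence=1e-6 * max(np.ptp(L), 1e-30))
    if len(peaks) < 2:
        raise NonOscillatoryError("luciferase trace has fewer than two peaks")
    t_peak = L_t[peaks[1]]
    tq = np.arange(0.0, horizon_h + 0.5, 1.0)
    Lq = np.interp(tq + t_peak, L_t, L)
    Lq = Lq / control_amplitude
    return tq, Lq - Lq.mean()


def _model_period(L_t, L) -> float:
    T, _ = period_amplitude(L_t, L)
    return T


def log_likelihood(theta, fit: FitSpace, datasets: list[CalibrationDataset],
                   mech_base: MechanoParams, circ_base: CircadianParams,
                   control_condition: TreatmentCondition | None = None) -> float:
    """Gaussian log-likelihood of theta against reconstructed luminescence.

    Sum over conditions and hourly points of log N(L_model | mu_i, sigma_i).
    Simulation failure or a non-oscillatory trace yields -inf (logged).
    """
    return _objective(theta, fit, datasets, mech_base, circ_base,
                      control_condition, eta=0.0)


def penalized_log_likelihood(theta, fit: FitSpace,
                             datasets: list[CalibrationDataset],
                             mech_base: MechanoParams,
                             circ_base: CircadianParams,
                             control_condition: TreatmentCondition | None = None,
                             eta: float = ETA_DEFAULT) -> float:
    """Log-likelihood minus eta * (T_model - T_exp)^2 summed over conditions."""
    if eta < 0:
        raise ValueError("eta must be >= 0")
    return _objective(theta, fit, datasets, mech_base, circ_base,
                      control_condition, eta=eta)


def _objective(theta, fit, datasets, mech_base, circ_base, control_condition,
               eta) -> float:
    if not fit.in_bounds(theta):
        return -np.inf
    mech, circ = fit.apply(theta, mech_base, circ_base)
    try:
        circ.validate()
        mech.validate()
    except ValueError:
        return -np.inf
    control = control_condition or TreatmentCondition()
    try:
        ctrl = simulate_reporter(mech, circ, control)
        _, A_ctrl = period_amplitude(ctrl.t, ctrl.L)
        if A_ctrl <= 0:
            return -np.inf
        total = 0.0
        for ds in datasets:
            ds.validate()
            rep = simulate_reporter(mech, circ, ds.condition)
            tq, Lm = normalize_model_trace(rep.t, rep.L, A_ctrl,
                                           horizon_h=float(ds.t[-1]))
            mu = np.interp(tq, ds.t, ds.mu)
            sigma = np.interp(tq, ds.t, ds.sigma)
            total += float(np.sum(
                -0.5 * ((Lm - mu) / sigma) ** 2 - np.log(sigma * np.sqrt(2 * np.pi))))
            if eta > 0:
                T_model = _model_period(rep.t, rep.L)
                total -= eta * (T_model - ds.T_exp) ** 2
        return total
    except (NonOscillatoryError, RuntimeError) as exc:
        logger.debug("objective -inf at theta=%s: %s", np.asarray(theta), exc)
        return -np.inf


def batched_objective(fit: FitSpace, datasets: list[CalibrationDataset],
                      mech_base: MechanoParams, circ_base: CircadianParams,
                      control_condition: TreatmentCondition | None = None,
                      eta: float = ETA_DEFAULT, duration: float = 24.0 * 9,
                      dt: float = 0.05):
    """Vectorized penalized log-likelihood over rows of a theta matrix.

    All walkers are integrated in one batched DDE solve per condition, which
    is what makes ensemble sampling of this model tractable on one core.
    Returns a callable mapping (n, dim) -> (n,) log-posteriors (suitable for
    ``emcee`` with ``vectorize=True``).
    """
    import dataclasses as _dc
    from .clock import _integrate_batch, _expr_P
    from scipy.signal import find_peaks

    control = control_condition or TreatmentCondition()
    conds = [control] + [ds.condition for ds in datasets]
    # solve each distinct condition once per call
    uniq_conds: list = []
    cond_map: list = []
    for c in conds:
        for k, u in enumerate(uniq_conds):
            if u == c:
                cond_map.append(k)
                break
        else:
            cond_map.append(len(uniq_conds))
            uniq_conds.append(c)

    def logp(thetas: np.ndarray) -> np.ndarray:
        thetas = np.atleast_2d(np.asarray(thetas, dtype=float))
        n = thetas.shape[0]
        out = np.full(n, -np.inf)
        ok = np.array([fit.in_bounds(th) for th in thetas])
        idx = np.nonzero(ok)[0]
        if len(idx) == 0:
            return out if thetas.shape[0] > 1 else out[0]
        pairs = [fit.apply(thetas[i], mech_base, circ_base) for i in idx]
        # batch the clock parameters; mechano steady states stay per-walker
        kw = {}
        for f_ in _dc.fields(CircadianParams):
            vals = [getattr(c, f_.name) for _, c in pairs]
            kw[f_.name] = (vals[0] if f_.name == "n_hill" else np.array(vals))
        circ_b = CircadianParams(**kw)
        total = np.zeros(len(idx))
        alive = np.ones(len(idx), dtype=bool)
        A_ctrl = np.full(len(idx), np.nan)
        solved: dict = {}
        t = None
        for uk, cond in enumerate(uniq_conds):
            Y = np.empty(len(idx))
            M = np.empty(len(idx))
            for j, (m, _) in enumerate(pairs):
                if not alive[j]:
                    Y[j], M[j] = 1.0, 1.0
                    continue
                try:
                    st = steady_state_network(m, cond)
                    Y[j], M[j] = st.nuclear_inputs()
                except Exception:
                    alive[j] = False
                    Y[j], M[j] = 1.0, 1.0
            coup = coupling_rates(Y, M, circ_b)
            try:
                sol, _ = _integrate_batch(circ_b, coup, duration, dt)
            except Exception:
                alive[:] = False
                break
            stride = max(1, int(round(0.25 / dt)))
            t = sol.t[::stride]
            # luciferase per walker from the delayed expression series
            s = np.maximum(t[:, None] - circ_b.tau_P[None, :], 0.0)
            gi = np.clip(np.round(s / dt).astype(int), 0, sol.y.shape[0] - 1)
            wj = np.arange(len(idx))
            Bd = sol.y[gi, wj[None, :], 0]
            Pd = sol.y[gi, wj[None, :], 1]
            expr = _expr_P(Bd, Pd, circ_b) + np.atleast_1d(coup.K_eP2)[None, :]
            kd = np.atleast_1d(circ_b.K_dL)
            dtau = t[1] - t[0]
            E = np.exp(-kd * dtau)
            L = np.zeros_like(expr)
            keL = np.atleast_1d(circ_b.K_eL)
            a = keL[None, :] * expr
            phi1 = (1.0 - E) / kd
            c2 = (dtau / kd - phi1 / kd) / dtau
            for k_ in range(len(t) - 1):
                L[k_ + 1] = L[k_] * E + a[k_] * phi1 + (a[k_ + 1] - a[k_]) * c2
            solved[uk] = L
        for ci in range(len(conds)):
            if not alive.any() or t is None:
                break
            L = solved.get(cond_map[ci])
            if L is None:
                alive[:] = False
                break
            for j in range(len(idx)):
                if not alive[j]:
                    continue
                Lj = L[:, j]
                peaks, _ = find_peaks(Lj, prominence=1e-6 * max(np.ptp(Lj), 1e-30))
                if len(peaks) < 3:
                    alive[j] = False
                    continue
                if ci == 0:
                    try:
                        _, A_ctrl[j] = period_amplitude(t, Lj)
                    except NonOscillatoryError:
                        alive[j] = False
                    continue
                ds = datasets[ci - 1]
                t_peak = t[peaks[1]]
                tq = ds.t
                Lq = np.interp(tq + t_peak, t, Lj) / A_ctrl[j]
                Lq = Lq - Lq.mean()
                total[j] += float(np.sum(
                    -0.5 * ((Lq - ds.mu) / ds.sigma) ** 2
                    - np.log(ds.sigma * np.sqrt(2 * np.pi))))
                if eta > 0:
                    T_model = float(np.mean(np.diff(t[peaks])[1:])) \
                        if len(peaks) > 2 else np.nan
                    if not np.isfinite(T_model):
                        alive[j] = False
                        continue
                    total[j] -= eta * (T_model - ds.T_exp) ** 2
        out[idx[alive]] = total[alive]
        return out if thetas.ndim > 1 and thetas.shape[0] > 1 else out

    return logp


def run_mcmc(objective, fit: FitSpace, n_walkers: int = MCMC_WALKERS,
             n_steps: int = MCMC_STEPS, seed: int = 0,
             start: np.ndarray | None = None, progress: bool = False,
             vectorized: bool = False):
    """Affine-invariant ensemble MCMC over the uniform prior box.

    ``objective(theta)`` is the log-posterior up to a constant;
    out-of-bounds proposals get -inf (never accepted).  With
    ``vectorized=True`` the objective receives the full (n_walkers, dim)
    proposal matrix at once (see :func:`batched_objective`).  Returns an
    ``emcee.EnsembleSampler`` whose chain has shape (steps, walkers, dim).
    """
    if n_walkers < 2 * fit.dim:
        raise ValueError("need at least 2*dim walkers")
    rng = np.random.default_rng(seed)

    if vectorized:
        def logp(thetas):
            return objective(np.atleast_2d(thetas))
    else:
        def logp(theta):
            if not fit.in_bounds(theta):
                return -np.inf
            return objective(theta)

    if start is None:
        p0 = rng.uniform(fit.lower, fit.upper, size=(n_walkers, fit.dim))
    else:
        width = fit.upper - fit.lower
        p0 = start[None, :] + 0.01 * width * rng.standard_normal((n_walkers, fit.dim))
        p0 = np.clip(p0, fit.lower, fit.upper)
    sampler = emcee.EnsembleSampler(n_walkers, fit.dim, logp,
                                    vectorize=vectorized)
    sampler.random_state = np.random.RandomState(seed).get_state()
    sampler.run_mcmc(p0, n_steps, progress=progress, skip_initial_state_check=True)
    acc = sampler.acceptance_fraction
    if np.all(acc < 1e-3):
        logger.warning("all walkers appear stuck (acceptance ~ 0)")
    return sampler


def chain_to_frame(sampler, fit: FitSpace, burn_in: int = MCMC_BURN_IN) -> pd.DataFrame:
    """Flattened post-burn-in chain as a DataFrame (columns = bare names)."""
    chain = sampler.get_chain(discard=burn_in, flat=True)
    cols = [n.split(".", 1)[1] for n in fit.names]
    return pd.DataFrame(chain, columns=cols)


def iact(chains: np.ndarray) -> float:
    """Integrated autocorrelation time (steps) of an ensemble chain.

    ``chains`` has shape (steps, walkers) or (steps, walkers, dim); the
    maximum over dimensions is returned.  Chains much shorter than ~50x the
    IACT give unreliable estimates (warned).
    """
    x = np.asarray(chains, dtype=float)
    if x.ndim == 2:
        x = x[:, :, None]
    try:
        taus = emcee.autocorr.integrated_time(x, quiet=True)
    except Exception as exc:  # pragma: no cover - emcee internal failure
        raise RuntimeError(f"IACT estimation failed: {exc}") from exc
    tau = float(np.max(taus))
    if x.shape[0] < 50 * tau:
        logger.warning("chain length %d < 50*IACT (%.1f): estimate unreliable",
                       x.shape[0], tau)
    return tau


def sobol_total_order(func, lower, upper, n_base: int = 1024,
                      seed: int = 0) -> np.ndarray:
    """Total-order Sobol' indices by Saltelli radial sampling.

    ``func`` maps an (n, d) matrix of parameter vectors to n outputs
    (NaN for failed evaluations; the failed fraction is logged and excluded
    pairwise).  Marginals are uniform on [lower, upper].  Jansen's
    estimator: ST_i = E[(f(A) - f(A_B^i))^2] / (2 Var[f]).
    """
    from scipy.stats import qmc
    lower = np.asarray(lower, dtype=float)
    upper = np.asarray(upper, dtype=float)
    d = len(lower)
    eng = qmc.Sobol(2 * d, scramble=True, seed=seed)
    base = eng.random(n_base)
    A = lower + base[:, :d] * (upper - lower)
    B = lower + base[:, d:] * (upper - lower)
    fA = np.asarray(func(A), dtype=float)
    good = np.isfinite(fA)
    ST = np.empty(d)
    var = np.nanvar(fA[good]) if good.any() else np.nan
    if not good.all():
        logger.info("sobol: %.1f%% of base evaluations failed",
                    100 * (1 - good.mean()))
    if not np.isfinite(var) or var == 0:
        raise ValueError("output variance is zero or undefined")
    for i in range(d):
        ABi = A.copy()
        ABi[:, i] = B[:, i]
        fABi = np.asarray(func(ABi), dtype=float)
        ok = good & np.isfinite(fABi)
        ST[i] = np.mean((fA[ok] - fABi[ok]) ** 2) / (2 * var)
    return ST
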