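"""Cell-population simulation with parameter variability, and the
population-level statistics (ANOVA + Tukey compact letters, log-scale
Pearson correlation).

Cohorts of model cells differ in their kinetic parameters: every
non-exponent rate constant k is drawn log-normally around its baseline,
k = k_bar * exp(sigma * r) with r ~ N(0, 1) and sigma = 0.2 by default.
Parameters estimated by Bayesian calibration can instead be drawn jointly
from posterior MCMC chain rows (preserving their correlations).  Each cell
is then run through the full pipeline: mechano steady state -> clock
coupling -> DDE solve -> reporter noise -> oscillation metrics.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .clock import CircadianParams, CouplingInput, coupling_rates, _integrate_batch
from .mechano import MechanoParams, TreatmentCondition, steady_state_network
from . import metrics as om

__all__ = [
    "PopulationResult",
    "sample_parameters",
    "simulate_population",
    "anova_tukey",
    "pearson_log",
    "SIGMA_DEFAULT",
    "SIGMA_CIRC_DEFAULT",
]

SIGMA_DEFAULT = 0.2       # log-normal spread of cell-to-cell parameter variation
SIGMA_CIRC_DEFAULT = 0.05  # fallback spread for calibrated clock parameters
N_CELLS_DEFAULT = 200
BURN_IN_DAYS = 1.0      # transient discarded before metrics
RECORD_DAYS = 6.0       # analysis window for spectra and metrics
KYMOGRAPH_DAYS = 3.0
CHAIN_BURN_IN = 500     # MCMC steps discarded before posterior draws


def _is_sampled(name: str) -> bool:
    """Exponents and structural/config fields are held fixed across cells."""
    if name.endswith("_exp") or name in ("n_hill", "A_0", "Y5SA_tot"):
        return False
    return True


@dataclass
class PopulationResult:
    """Cohort simulation output.

    ``traces`` holds nuclear REV-ERBalpha sampled every 15 min over the
    analysis window (cells x time); ``kymograph`` is the first
    ``KYMOGRAPH_DAYS`` of that matrix; ``metrics`` has per-cell period (h),
    amplitude and circadian power fraction.
    """

    condition: TreatmentCondition
    seed: int
    t_days: np.ndarray
    traces: np.ndarray
    noisy: np.ndarray
    kymograph: np.ndarray
    metrics: pd.DataFrame
    mechano_states: list = field(default_factory=list)
    cell_params: list = field(default_factory=list)
    f_C: float = float("nan")
    failures: list = field(default_factory=list)


def sample_parameters(
    mech_base: MechanoParams,
    circ_base: CircadianParams,
    n: int,
    seed: int | np.random.SeedSequence,
    sigma: float = SIGMA_DEFAULT,
    sigma_circ: float = SIGMA_CIRC_DEFAULT,
    posterior_chain: pd.DataFrame | None = None,
) -> list[tuple[MechanoParams, CircadianParams]]:
    """Draw n per-cell parameter sets.

    Mechano parameters are always log-normal around baseline (exponents
    fixed).  If ``posterior_chain`` is given (columns = CircadianParams field
    names, rows = post-burn-in MCMC samples across walkers), whole rows are
    drawn jointly for the fitted clock parameters; otherwise clock parameters
    are drawn log-normally with the narrower spread ``sigma_circ``, a stand-in
    for the width of calibrated posteriors (period-setting parameters are far
    better constrained by rhythmic data than generic rate constants).
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    if posterior_chain is not None and len(posterior_chain) == 0:
        raise ValueError("posterior chain is empty after burn-in")
    out = []
    rows = None
    if posterior_chain is not None:
        rows = posterior_chain.iloc[
            rng.integers(0, len(posterior_chain), size=n)].to_dict("records")
    for i in range(n):
        mk = {}
        for f_ in dataclasses.fields(mech_base):
            v = getattr(mech_base, f_.name)
            if v is None or not _is_sampled(f_.name):
                mk[f_.name] = v
            else:
                mk[f_.name] = v * np.exp(sigma * rng.standard_normal())
        ck = {}
        for f_ in dataclasses.fields(circ_base):
            v = getattr(circ_base, f_.name)
            if rows is not None and f_.name in rows[i]:
                ck[f_.name] = float(rows[i][f_.name])
            elif not _is_sampled(f_.name):
                ck[f_.name] = v
            else:
                ck[f_.name] = v * np.exp(sigma_circ * rng.standard_normal())
        out.append((MechanoParams(**mk), CircadianParams(**ck)))
    return out


def _batch_circadian(params_list: list[CircadianParams]) -> CircadianParams:
    """Stack per-cell clock parameters into arrays for the batch integrator."""
    kw = {}
    for f_ in dataclasses.fields(CircadianParams):
        vals = [getattr(p, f_.name) for p in params_list]
        kw[f_.name] = np.array(vals) if _is_sampled(f_.name) else vals[0]
    return CircadianParams(**kw)


def simulate_population(
    parameter_sets: list[tuple[MechanoParams, CircadianParams]],
    condition: TreatmentCondition,
    seed: int = 0,
    snr: float | None = om.SNR_DEFAULT,
    species: str = "R",
    dt: float = 0.05,
    record_days: float = RECORD_DAYS,
    burn_in_days: float = BURN_IN_DAYS,
) -> PopulationResult:
    """Simulate a cohort under one condition and compute per-cell metrics.

    Per-cell mechano steady states feed per-cell coupling rates; all cells
    are integrated in one vectorized DDE solve.  Reporter noise at the given
    SNR (None disables noise) is added to the 15-min-sampled nuclear
    REV-ERBalpha signal before filtering and power-fraction computation,
    emulating measurement noise in live-cell recordings.
    """
    condition.validate()
    n = len(parameter_sets)
    if n < 1:
        raise ValueError("empty population")
    states, keep, failures = [], [], []
    for i, (mp, _) in enumerate(parameter_sets):
        try:
            states.append(steady_state_network(mp, condition))
            keep.append(i)
        except Exception as exc:  # individual failures recorded, not fatal
            failures.append((i, str(exc)))
    if len(failures) > 0.1 * n:
        raise RuntimeError(
            f"{len(failures)}/{n} cells failed the mechano steady state; aborting"
        )
    circ = _batch_circadian([parameter_sets[i][1] for i in keep])
    Y = np.array([s.yap_nuc_total for s in states])
    M = np.array([s.mrtf_nuc for s in states])
    coupling = coupling_rates(Y, M, circ)

    duration = 24.0 * (burn_in_days + record_days)
    sol, _ = _integrate_batch(circ, coupling, duration, dt)
    # sample every 15 min within the analysis window
    stride = max(1, int(round(0.25 / dt)))
    i0 = int(round(24.0 * burn_in_days / dt))
    comp = {"B": 0, "P": 1, "R": 2}[species]
    traces = sol.y[i0::stride, :, comp].T.copy()
    t_days = (sol.t[i0::stride] - sol.t[i0]) / 24.0

    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    noisy = om.add_noise(traces, snr, rng) if snr is not None else traces.copy()
    pre = om.preprocess_signal(noisy, om.FS_PER_DAY)
    spec_est = om.population_spectrum(pre, om.FS_PER_DAY)
    frac = om.circadian_power_fraction(pre, om.FS_PER_DAY, spectrum=spec_est)

    periods = np.full(len(keep), np.nan)
    amps = np.full(len(keep), np.nan)
    t_h = t_days * 24.0
    for j in range(len(keep)):
        try:
            periods[j], amps[j] = om.period_amplitude(t_h, traces[j])
        except om.NonOscillatoryError:
            pass
    mdf = pd.DataFrame({
        "cell_id": np.asarray(keep),
        "period_h": periods,
        "amplitude": amps,
        "power_fraction": frac,
        "yap_nuc": Y,
        "mrtf_nuc": M,
    })
    n_kym = int(KYMOGRAPH_DAYS * om.FS_PER_DAY)
    return PopulationResult(
        condition=condition, seed=seed, t_days=t_days, traces=traces,
        noisy=noisy, kymograph=noisy[:, :n_kym], metrics=mdf,
        mechano_states=states,
        cell_params=[parameter_sets[i] for i in keep],
        f_C=spec_est.f_C, failures=failures,
    )


# ----------------------------------------------------------------- statistics

def anova_tukey(groups: dict[str, np.ndarray], alpha: float = 0.05) -> dict:
    """One-way ANOVA followed by Tukey's HSD with a compact letter display.

    Returns {"anova_p": p, "letters": {group: str}, "pairwise_p": DataFrame}.
    Groups sharing a letter are not significantly different at ``alpha``.
    """
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(groups[k], dtype=float) for k in names]
    arrays = [a[~np.isnan(a)] for a in arrays]
    if any(len(a) < 2 for a in arrays):
        raise ValueError("each group needs n >= 2")
    if all(np.var(a) == 0 for a in arrays):
        raise ValueError("degenerate (zero-variance) groups")
    anova_p = float(stats.f_oneway(*arrays).pvalue)
    res = stats.tukey_hsd(*arrays)
    k = len(names)
    pmat = pd.DataFrame(res.pvalue, index=names, columns=names)
    distinct = res.pvalue < alpha
    letters = _compact_letter_display(names, distinct)
    return {"anova_p": anova_p, "letters": letters, "pairwise_p": pmat}


def _compact_letter_display(names: list[str], distinct: np.ndarray) -> dict:
    """Greedy insert-absorb assignment of letters from a significance matrix."""
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    sets: list[set] = []
    for i, _ in enumerate(names):
        placed = False
        for s in sets:
            if all(not distinct[i, j] for j in s):
                s.add(i)
                placed = True
        if not placed:
            sets.append({i})
            # absorb: add every earlier group compatible with the new set
            for j in range(len(names)):
                if j != i and all(not distinct[j, m] for m in sets[-1]):
                    sets[-1].add(j)
    # drop subsets
    sets = [s for s in sets if not any(s < t for t in sets)]
    out = {nm: "" for nm in names}
    for letter, s in zip(alphabet, sets):
        for i in sorted(s):
            out[names[i]] += letter
    return out


def pearson_log(x_medians, y_medians) -> tuple[float, float]:
    """Pearson correlation of y against log(x), with two-sided p for r = 0.

    Used for median power fraction vs median N/C ratio across conditions.
    """
    x = np.asarray(x_medians, dtype=float)
    y = np.asarray(y_medians, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least three condition points")
    if np.any(x <= 0):
        raise ValueError("x must be positive for the log scale")
    if np.var(np.log(x)) == 0 or np.var(y) == 0:
        raise ValueError("zero variance input")
    r, p = stats.pearsonr(np.log(x), y)
    return float(r), float(p)
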