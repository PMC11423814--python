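"""Calibration machinery: waveform reconstruction, trace normalization,
likelihood algebra, ensemble MCMC, IACT and Sobol' estimators."""

import numpy as np
import pytest

from mechanoclock.calibration import (CalibrationDataset, FitSpace, iact,
                                      log_likelihood, normalize_model_trace,
                                      penalized_log_likelihood,
                                      reconstruct_experiment, run_mcmc,
                                      sobol_total_order)
from mechanoclock.mechano import TreatmentCondition
from mechanoclock.metrics import NonOscillatoryError


# ------------------------------------------------------------ reconstruction

def test_reconstruct_deterministic_limit():
    t, mu, sd = reconstruct_experiment(24.0, 0.0, 1.5, 0.0, n_samples=10)
    assert np.allclose(mu, 1.5 * np.cos(2 * np.pi * t / 24.0))
    assert np.all(sd == 0)
    assert np.all(np.diff(t) == 1.0)  # hourly grid


def test_reconstruct_envelope_decays_by_dephasing():
    """Period spread dephases the cosines: the mean envelope decays with t,
    at the rate an independent large re-run reproduces."""
    t, mu, sd = reconstruct_experiment(24.0, 1.5, 1.0, 0.0,
                                       n_samples=200_000, seed=1)
    early = np.max(np.abs(mu[:24]))
    late = np.max(np.abs(mu[-24:]))
    assert late < 0.5 * early
    # independent oracle at different seed agrees closely
    t2, mu2, sd2 = reconstruct_experiment(24.0, 1.5, 1.0, 0.0,
                                          n_samples=400_000, seed=99)
    assert np.allclose(mu, mu2, atol=0.01)
    assert np.allclose(sd, sd2, atol=0.01)


def test_reconstruct_rejects_negative_sd():
    with pytest.raises(ValueError):
        reconstruct_experiment(24.0, -1.0, 1.0, 0.1)


# ------------------------------------------------------------- normalization

def test_normalize_centered_and_scaled():
    t = np.arange(0, 24 * 8, 0.25)
    L = 5.0 + 2.0 * np.cos(2 * np.pi * (t - 30.0) / 24.0)
    tq, Ln = normalize_model_trace(t, L, control_amplitude=2.0, horizon_h=96.0)
    assert abs(Ln.mean()) < 1e-12
    assert np.max(Ln) - np.min(Ln) == pytest.approx(2.0, rel=1e-3)


def test_normalize_shifts_to_second_peak():
    """The shift lands on the second detected peak of a two-frequency signal."""
    t = np.arange(0, 24 * 8, 0.25)
    L = np.cos(2 * np.pi * t / 24.0) + 0.3 * np.cos(2 * np.pi * t / 6.0)
    from scipy.signal import find_peaks
    peaks, _ = find_peaks(L)
    t2 = t[peaks[1]]
    tq, Ln = normalize_model_trace(t, L, 1.0, horizon_h=48.0)
    ref = np.interp(tq + t2, t, L)
    assert np.allclose(Ln, ref - ref.mean(), atol=1e-12)


def test_normalize_requires_two_peaks():
    t = np.arange(0, 30, 0.25)
    with pytest.raises(NonOscillatoryError):
        normalize_model_trace(t, np.exp(-t / 10.0), 1.0)


# ---------------------------------------------------------------- likelihood

def _toy_setup(mech, circ):
    cond = TreatmentCondition()
    t = np.arange(0.0, 49.0, 1.0)
    ds = CalibrationDataset(condition=cond, T_exp=23.5, T_sd=0.5,
                            A_exp=1.0, A_sd=0.1, t=t,
                            mu=np.cos(2 * np.pi * t / 23.5),
                            sigma=np.full_like(t, 0.2))
    return ds


def test_loglik_maximum_at_exact_match():
    """A model identical to mu attains -sum log(sigma sqrt(2 pi)) exactly."""
    t = np.arange(0.0, 49.0, 1.0)
    sigma = np.full_like(t, 0.3)
    mu = np.cos(2 * np.pi * t / 24.0)
    ll_max = -np.sum(np.log(sigma * np.sqrt(2 * np.pi)))
    resid = np.sum(-0.5 * ((mu - mu) / sigma) ** 2 - np.log(sigma * np.sqrt(2 * np.pi)))
    assert resid == pytest.approx(ll_max)


def test_loglik_sigma_doubling_closed_form(mech, circ):
    """Doubling sigma changes the log-likelihood by the analytic amount."""
    fit = FitSpace(names=["circ.tau_P"], lower=[8.0], upper=[10.0])
    ds = _toy_setup(mech, circ)
    theta = np.array([9.0])
    ll1 = log_likelihood(theta, fit, [ds], mech, circ)
    ds2 = CalibrationDataset(condition=ds.condition, T_exp=ds.T_exp,
                             T_sd=ds.T_sd, A_exp=ds.A_exp, A_sd=ds.A_sd,
                             t=ds.t, mu=ds.mu, sigma=2 * ds.sigma)
    ll2 = log_likelihood(theta, fit, [ds2], mech, circ)
    # residual term shrinks 4x; normalization shifts by n log 2
    n = len(ds.t)
    norm1 = -np.sum(np.log(ds.sigma * np.sqrt(2 * np.pi)))
    resid1 = ll1 - norm1
    expected_ll2 = resid1 / 4.0 + norm1 - n * np.log(2.0)
    assert ll2 == pytest.approx(expected_ll2, rel=1e-10)


def test_loglik_invariant_to_condition_order(mech, circ):
    fit = FitSpace(names=["circ.tau_P"], lower=[8.0], upper=[10.0])
    ds1 = _toy_setup(mech, circ)
    ds2 = CalibrationDataset(condition=TreatmentCondition(substrate_stiffness=1.0),
                             T_exp=24.0, T_sd=0.5, A_exp=1.8, A_sd=0.2,
                             t=ds1.t, mu=1.5 * ds1.mu,
                             sigma=np.full_like(ds1.t, 0.3))
    theta = np.array([9.0])
    a = log_likelihood(theta, fit, [ds1, ds2], mech, circ)
    b = log_likelihood(theta, fit, [ds2, ds1], mech, circ)
    assert a == pytest.approx(b, rel=1e-12)


def test_penalty_reduces_to_likelihood_at_eta_zero(mech, circ):
    fit = FitSpace(names=["circ.tau_P"], lower=[8.0], upper=[10.0])
    ds = _toy_setup(mech, circ)
    theta = np.array([9.0])
    assert penalized_log_likelihood(theta, fit, [ds], mech, circ, eta=0.0) == \
        pytest.approx(log_likelihood(theta, fit, [ds], mech, circ), rel=1e-12)


def test_penalty_increases_with_period_mismatch(mech, circ):
    """Penalized objective falls as the reference period moves away from the
    model period, and the drop grows with the mismatch."""
    fit = FitSpace(names=["circ.tau_P"], lower=[8.0], upper=[10.0])
    theta = np.array([9.0])
    ds = _toy_setup(mech, circ)
    vals = []
    for T_ref in (23.5, 25.0, 27.0):
        d = CalibrationDataset(condition=ds.condition, T_exp=T_ref,
                               T_sd=0.5, A_exp=1.0, A_sd=0.1,
                               t=ds.t, mu=ds.mu, sigma=ds.sigma)
        penalty = (penalized_log_likelihood(theta, fit, [d], mech, circ)
                   - log_likelihood(theta, fit, [d], mech, circ))
        vals.append(penalty)
    assert vals[0] > vals[1] > vals[2]


def test_out_of_bounds_is_minus_inf(mech, circ):
    fit = FitSpace(names=["circ.tau_P"], lower=[8.0], upper=[10.0])
    ds = _toy_setup(mech, circ)
    assert log_likelihood(np.array([12.0]), fit, [ds], mech, circ) == -np.inf


# --------------------------------------------------------------------- MCMC

def test_mcmc_recovers_gaussian_target():
    """2-D correlated Gaussian: posterior mean and covariance recovered
    within Monte-Carlo error; no sample ever violates the prior box."""
    mean = np.array([0.5, -0.3])
    cov = np.array([[1.0, 0.6], [0.6, 1.0]])
    icov = np.linalg.inv(cov)
    fit = FitSpace(names=["a", "b"], lower=[-10, -10], upper=[10, 10])

    def logp(theta):
        d = theta - mean
        return -0.5 * d @ icov @ d

    sampler = run_mcmc(logp, fit, n_walkers=20, n_steps=2500, seed=4)
    chain = sampler.get_chain(discard=500, flat=True)
    assert np.all(chain >= -10) and np.all(chain <= 10)
    assert np.allclose(chain.mean(axis=0), mean, atol=0.1)
    assert np.allclose(np.cov(chain.T), cov, atol=0.2)


def test_mcmc_respects_bounds():
    fit = FitSpace(names=["a"], lower=[0.0], upper=[1.0])
    sampler = run_mcmc(lambda th: 0.0, fit, n_walkers=8, n_steps=300, seed=0)
    chain = sampler.get_chain(flat=True)
    assert chain.min() >= 0.0 and chain.max() <= 1.0


def test_mcmc_walker_minimum():
    fit = FitSpace(names=["a", "b"], lower=[0, 0], upper=[1, 1])
    with pytest.raises(ValueError, match="walkers"):
        run_mcmc(lambda th: 0.0, fit, n_walkers=3, n_steps=10)


# --------------------------------------------------------------------- IACT

def test_iact_iid_near_one(rng):
    x = rng.standard_normal((4000, 8))
    assert iact(x) == pytest.approx(1.0, abs=0.3)


@pytest.mark.parametrize("rho", [0.5, 0.8])
def test_iact_ar1_analytic(rng, rho):
    """AR(1) chains have IACT = (1 + rho) / (1 - rho)."""
    n, w = 60_000, 4
    x = np.zeros((n, w))
    eps = rng.standard_normal((n, w))
    for i in range(1, n):
        x[i] = rho * x[i - 1] + eps[i]
    expected = (1 + rho) / (1 - rho)
    assert iact(x) == pytest.approx(expected, rel=0.15)


# -------------------------------------------------------------------- Sobol'

def test_sobol_additive_single_parameter():
    """f depending on one input only: its total index ~1, the others ~0."""
    ST = sobol_total_order(lambda X: 3.0 * X[:, 1], lower=[0, 0, 0],
                           upper=[1, 1, 1], n_base=2048, seed=0)
    assert ST[1] == pytest.approx(1.0, abs=0.05)
    assert ST[0] < 0.02 and ST[2] < 0.02


def test_sobol_ishigami_benchmark():
    """Ishigami function (a=7, b=0.1): analytic total-order indices
    ST = (0.5576, 0.4424, 0.2437) recovered within 0.05."""
    a, b = 7.0, 0.1

    def ishigami(X):
        return (np.sin(X[:, 0]) + a * np.sin(X[:, 1]) ** 2
                + b * X[:, 2] ** 4 * np.sin(X[:, 0]))

    lo = [-np.pi] * 3
    hi = [np.pi] * 3
    ST = sobol_total_order(ishigami, lo, hi, n_base=2 ** 14, seed=1)
    expected = np.array([0.5576, 0.4424, 0.2437])
    assert np.allclose(ST, expected, atol=0.05)


def test_sobol_nan_outputs_excluded(rng):
    def f(X):
        out = X[:, 0] ** 2
        out[::17] = np.nan  # sporadic failures
        return out

    ST = sobol_total_order(f, [0, 0], [1, 1], n_base=4096, seed=2)
    assert ST[0] > 0.9 and ST[1] < 0.05
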