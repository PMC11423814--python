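"""Oscillation metrics: period/amplitude extraction, measurement noise,
filtering, and the circadian power fraction.

The power-fraction pipeline mirrors live-cell reporter analysis: the
continuous solution is corrupted with white Gaussian noise at a fixed
signal-to-noise ratio, sampled every 15 min (f_s = 96 / day), low-pass
filtered with a zero-phase 4-tap moving-average FIR, standardized to zero
mean / unit variance, and its periodogram integrated in a narrow window
around the population-level circadian frequency ``f_C``.  The resulting
fraction is 0 for arrhythmic noise and 1 for a pure circadian sinusoid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .clock import Trajectory

__all__ = [
    "SpectralEstimate",
    "period_amplitude",
    "add_noise",
    "preprocess_signal",
    "circadian_power_fraction",
    "FS_PER_DAY",
    "SNR_DEFAULT",
    "FIR_B",
]

FS_PER_DAY = 96.0          # 15-min sampling
SNR_DEFAULT = 5.0          # linear power ratio (not dB)
FIR_B = np.full(4, 0.2)    # moving-average low-pass, applied forward-backward
FC_SEARCH = (0.7, 1.3)     # 1/day window in which f_C is located
WINDOW_HALFWIDTH = 0.1     # 1/day; half-width of the power-fraction window


@dataclass
class SpectralEstimate:
    """Periodogram-based population spectrum."""

    freqs: np.ndarray            # 1/day
    power: np.ndarray            # (n_cells, n_freqs)
    mean_power: np.ndarray       # population average over cells
    f_C: float                   # population circadian frequency (1/day)


class NonOscillatoryError(RuntimeError):
    """Raised when a trajectory has too few peaks for period estimation."""


def _peaks_after_transient(t: np.ndarray, x: np.ndarray):
    prom = 1e-3 * max(np.ptp(x), 1e-30)
    peaks, _ = sps.find_peaks(x, prominence=prom)
    troughs, _ = sps.find_peaks(-x, prominence=prom)
    return peaks, troughs


def period_amplitude(traj_or_t, x: np.ndarray | None = None,
                     species: str = "P") -> tuple[float, float]:
    """Oscillation period (h) and amplitude from a trajectory.

    The first peak is discarded as transient; the period is the mean
    peak-to-peak interval of the remaining peaks and the amplitude the mean
    half peak-to-trough excursion over the following cycles.  Raises
    :class:`NonOscillatoryError` when fewer than three peaks exist.
    """
    if isinstance(traj_or_t, Trajectory):
        t = traj_or_t.t
        x = traj_or_t.species(species)
    else:
        t = np.asarray(traj_or_t, dtype=float)
        x = np.asarray(x, dtype=float)
    peaks, troughs = _peaks_after_transient(t, x)
    if len(peaks) < 3:
        raise NonOscillatoryError(
            f"non-oscillatory trace: {len(peaks)} peaks found, need >= 3"
        )
    use = peaks[1:]
    period = float(np.mean(np.diff(t[use])))
    # half peak-to-trough excursion over cycles after the first peak
    tr_t = t[troughs]
    tr_x = x[troughs]
    if len(troughs) == 0:
        raise NonOscillatoryError("no troughs found")
    exc = []
    for pt, px in zip(t[use][:3], x[use][:3]):
        k = np.argmin(np.abs(tr_t - pt))
        exc.append(px - tr_x[k])
    amplitude = float(0.5 * np.mean(exc))
    return period, amplitude


def add_noise(x: np.ndarray, snr: float = SNR_DEFAULT,
              rng: np.random.Generator | int | None = None) -> np.ndarray:
    """Add white Gaussian noise at a linear signal-to-noise power ratio.

    Noise variance equals var(x) / snr; a zero-variance signal has no
    defined SNR and raises.
    """
    if not snr > 0:
        raise ValueError("snr must be > 0")
    x = np.asarray(x, dtype=float)
    power = np.var(x, axis=-1, keepdims=True)
    if np.any(power <= 0):
        raise ValueError("zero-power signal: SNR-scaled noise undefined")
    rng = np.random.default_rng(rng)
    return x + rng.standard_normal(x.shape) * np.sqrt(power / snr)


def preprocess_signal(samples: np.ndarray, fs: float = FS_PER_DAY) -> np.ndarray:
    """Zero-phase low-pass filtering and standardization.

    Applies the 4-tap FIR b = (0.2, 0.2, 0.2, 0.2), a = 1 forward and
    backward (zero phase), then subtracts the mean and divides by the
    standard deviation.  Requires at least two days of samples.
    """
    x = np.atleast_2d(np.asarray(samples, dtype=float))
    if x.shape[-1] < 2 * fs:
        raise ValueError("need at least two days of samples")
    y = sps.filtfilt(FIR_B, [1.0], x, axis=-1)
    sd = y.std(axis=-1, keepdims=True)
    if np.any(sd <= 0):
        raise ValueError("constant signal: standardization undefined")
    out = (y - y.mean(axis=-1, keepdims=True)) / sd
    return out if samples.ndim > 1 else out[0]


def population_spectrum(signals: np.ndarray, fs: float = FS_PER_DAY) -> SpectralEstimate:
    """Per-cell periodograms and the population circadian frequency f_C.

    ``f_C`` is the frequency of maximum population-average power within
    0.7-1.3 / day.
    """
    x = np.atleast_2d(np.asarray(signals, dtype=float))
    if x.shape[0] < 1:
        raise ValueError("empty population")
    freqs, power = sps.periodogram(x, fs=fs, axis=-1, detrend=False)
    mean_power = power.mean(axis=0)
    band = (freqs >= FC_SEARCH[0]) & (freqs <= FC_SEARCH[1])
    if not band.any():
        raise ValueError("frequency grid does not cover the circadian band")
    f_C = float(freqs[band][np.argmax(mean_power[band])])
    return SpectralEstimate(freqs=freqs, power=power, mean_power=mean_power,
                            f_C=f_C)


def circadian_power_fraction(signals: np.ndarray, fs: float = FS_PER_DAY,
                             halfwidth: float = WINDOW_HALFWIDTH,
                             spectrum: SpectralEstimate | None = None) -> np.ndarray:
    """Per-cell fraction of spectral power within f_C +/- halfwidth (1/day).

    ``signals`` are preprocessed (filtered, standardized) cell traces,
    shape (n_cells, n_samples).  The window center f_C is shared across the
    population.  Fractions lie in [0, 1].
    """
    x = np.atleast_2d(np.asarray(signals, dtype=float))
    est = spectrum if spectrum is not None else population_spectrum(x, fs)
    win = np.abs(est.freqs - est.f_C) <= halfwidth
    num = est.power[:, win].sum(axis=-1)
    den = est.power.sum(axis=-1)
    frac = np.where(den > 0, num / np.maximum(den, 1e-300), 0.0)
    return frac if np.asarray(signals).ndim > 1 else float(frac[0])
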