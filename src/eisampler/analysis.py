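"""Observables and metrics derived from sampler trajectories.

Firing rates, LFPs, autocorrelations, Welch spectra and spectrograms,
posterior-convergence curves, excitation-inhibition balance, and
stimulus-onset transient quantification.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .gsm import GSMParams, marginal_posterior, posterior_u, sample_stimulus
from .parameters import NetworkParams

__all__ = [
    "ConvergenceCurve",
    "SpectralResult",
    "BalanceResult",
    "TransientMetrics",
    "firing_rates",
    "lfp",
    "autocorrelation",
    "cross_correlation",
    "power_spectrum",
    "spectrogram",
    "spectral_mass_above",
    "convergence_curve",
    "convergence_curve_from_runs",
    "time_to_unit_mse",
    "ei_balance",
    "transient_metrics",
]


# ---------------------------------------------------------------------------
# Elementary observables
# ---------------------------------------------------------------------------

def firing_rates(u_t: np.ndarray) -> np.ndarray:
    """Rectified-linear rates: f = max(u, 0), elementwise."""
    return np.maximum(np.asarray(u_t), 0.0)


def lfp(u_t: np.ndarray) -> np.ndarray:
    """Mean over excitatory membrane potentials at each time point.

    ``u_t`` has time on axis 0; the average runs over the last axis.
    """
    u_t = np.asarray(u_t)
    if u_t.ndim == 1:
        return u_t.copy()
    return u_t.mean(axis=-1)


def autocorrelation(series: np.ndarray, max_lag: int) -> np.ndarray:
    """Mean-subtracted, variance-normalized empirical autocorrelation.

    Returns acf[0..max_lag] with acf[0] = 1.
    """
    s = np.asarray(series, dtype=float)
    if s.ndim != 1 or len(s) <= max_lag:
        raise ValueError("series must be 1-D and longer than max_lag")
    s = s - s.mean()
    var = float(s @ s) / len(s)
    if var <= 0:
        raise ValueError("autocorrelation undefined for a zero-variance series")
    n = len(s)
    acf = np.empty(max_lag + 1)
    for k in range(max_lag + 1):
        acf[k] = float(s[: n - k] @ s[k:]) / (n * var)
    return acf


def cross_correlation(
    a: np.ndarray, b: np.ndarray, max_lag: int
) -> tuple[np.ndarray, np.ndarray]:
    """Pearson correlation of a(t) with b(t + lag) over the overlap.

    Returns (lags, corr) for integer lags in [-max_lag, max_lag]; a positive
    peak lag means b lags a.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("a and b must be matching 1-D series")
    lags = np.arange(-max_lag, max_lag + 1)
    corr = np.empty(len(lags))
    for i, k in enumerate(lags):
        if k >= 0:
            x, y = a[: len(a) - k], b[k:]
        else:
            x, y = a[-k:], b[: len(b) + k]
        x = x - x.mean()
        y = y - y.mean()
        denom = np.sqrt((x @ x) * (y @ y))
        corr[i] = float(x @ y) / denom if denom > 0 else 0.0
    return lags, corr


# ---------------------------------------------------------------------------
# Spectra
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpectralResult:
    """Welch spectrum with the plotted quantity power x frequency."""

    freqs: np.ndarray
    power: np.ndarray
    power_times_freq: np.ndarray
    peak_freq: float


def power_spectrum(
    lfp_series: np.ndarray,
    fs: float,
    segment_seconds: float = 0.5,
    floor_hz: float = 5.0,
) -> SpectralResult:
    """Welch spectrum (500 ms segments, 50% overlap, Hann taper).

    ``lfp_series`` may be 1-D (one trial) or 2-D (time x trials); trials are
    averaged in the spectral domain. peak_freq is the argmax of
    power x frequency above the floor.
    """
    s = np.asarray(lfp_series, dtype=float)
    if s.ndim == 1:
        s = s[:, None]
    nperseg = int(round(segment_seconds * fs))
    if s.shape[0] < int(1.5 * nperseg):
        raise ValueError(
            f"insufficient data for spectral estimation: need at least "
            f"{int(1.5 * nperseg)} samples, got {s.shape[0]}"
        )
    freqs, P = sps.welch(
        s.T, fs=fs, nperseg=nperseg, noverlap=nperseg // 2, window="hann"
    )
    power = P.mean(axis=0)
    ptf = power * freqs
    mask = freqs >= floor_hz
    peak = float(freqs[mask][int(np.argmax(ptf[mask]))])
    return SpectralResult(freqs=freqs, power=power, power_times_freq=ptf,
                          peak_freq=peak)


def spectrogram(
    lfp_series: np.ndarray, fs: float, window_sd: float = 0.1
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Time-frequency power using a Gaussian window (sd ``window_sd`` s).

    Returns (freqs, times, power) with time resolution window_sd / 2.
    """
    s = np.asarray(lfp_series, dtype=float)
    if s.ndim != 1:
        raise ValueError("spectrogram expects a single 1-D series")
    n_win = int(round(6 * window_sd * fs)) | 1  # +-3 sd, odd length
    if len(s) < n_win:
        raise ValueError("series shorter than the spectrogram window")
    win = sps.windows.gaussian(n_win, std=window_sd * fs)
    step = max(int(round(window_sd * fs / 2)), 1)
    freqs, times, Sxx = sps.spectrogram(
        s, fs=fs, window=win, noverlap=n_win - step, detrend="constant"
    )
    return freqs, times, Sxx


def spectral_mass_above(series: np.ndarray, fs: float, f0: float = 20.0) -> float:
    """Fraction of Welch spectral power above f0 (DC excluded)."""
    res = power_spectrum(series, fs)
    m = res.freqs > 0
    total = np.trapezoid(res.power[m], res.freqs[m])
    hi = res.freqs >= f0
    return float(np.trapezoid(res.power[hi], res.freqs[hi]) / total)


# ---------------------------------------------------------------------------
# Convergence curves (sampling efficiency)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConvergenceCurve:
    """Normalized-MSE convergence of the running posterior-mean estimate."""

    times: np.ndarray
    mse_mean: np.ndarray
    mse_sem: np.ndarray
    n_reps: int


def convergence_curve_from_runs(
    times: np.ndarray,
    u_runs: np.ndarray,
    ref_means: np.ndarray,
    norm_var: np.ndarray,
) -> ConvergenceCurve:
    """Build the convergence curve from recorded post-onset trajectories.

    ``u_runs``: (n_times, n_reps, n) array from onset onwards.
    ``ref_means``: (n_reps, n) per-repetition reference posterior means.
    ``norm_var``: (n,) or (n_reps, n) normalization variances (the posterior
    variances defining the single-fair-sample error level).
    """
    n_times, n_reps, n = u_runs.shape
    if n_reps < 2:
        raise ValueError("need at least 2 repetitions")
    norm_var = np.asarray(norm_var)
    if norm_var.ndim == 1:
        norm_var = np.tile(norm_var, (n_reps, 1))
    running = np.cumsum(u_runs, axis=0) / np.arange(1, n_times + 1)[:, None, None]
    err = (running - ref_means[None, :, :]) ** 2 / norm_var[None, :, :]
    per_rep = err.mean(axis=2)  # (n_times, n_reps)
    mse_mean = per_rep.mean(axis=1)
    mse_sem = per_rep.std(axis=1, ddof=1) / np.sqrt(n_reps)
    return ConvergenceCurve(times=np.asarray(times), mse_mean=mse_mean,
                            mse_sem=mse_sem, n_reps=n_reps)


def time_to_unit_mse(curve: ConvergenceCurve) -> float:
    """First time the mean curve drops to 1; NaN if never reached."""
    idx = np.nonzero(curve.mse_mean <= 1.0)[0]
    if len(idx) == 0:
        return float("nan")
    return float(curve.times[idx[0]])


def convergence_curve(
    mode: str,
    z_gen: float,
    n_reps: int,
    rng: np.random.Generator | int,
    gsm: GSMParams,
    net: NetworkParams,
    t_post: float = 1.5,
    dt: float = 5e-5,
    record_every: int = 10,
    redraw_stimulus: bool = True,
    x: np.ndarray | None = None,
    normalization: str = "marginal",
) -> ConvergenceCurve:
    """Run the sampling-efficiency experiment and return its curve.

    Each repetition starts from a prior draw with the stimulus on from t = 0
    and uses an independent noise stream; by default each repetition sees a
    fresh stimulus draw (``redraw_stimulus=False`` shares one x). The error
    is measured to the marginal posterior mean E[u | x] (the sampler infers z
    jointly) and normalized per dimension by the marginal posterior variance
    Var[u | x] — the exact error level of a single fair sample from the
    distribution the sampler targets. ``normalization='conditional'`` uses
    the z-conditional variances at the generative contrast instead.
    """
    from .dynamics import SimulationProtocol, simulate_batch

    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    seed = int(rng.integers(2**31 - 1))
    if x is not None:
        X_post = np.tile(np.asarray(x), (n_reps, 1))
    elif redraw_stimulus:
        X_post = np.array(
            [sample_stimulus(gsm, z_gen, rng).x for _ in range(n_reps)]
        )
    else:
        x_shared = sample_stimulus(gsm, z_gen, rng).x
        X_post = np.tile(x_shared, (n_reps, 1))
    protocol = SimulationProtocol(
        t_pre=0.0, t_post=t_post, z_gen=z_gen, dt=dt, mode=mode,
        noise_seed=seed, record_every=record_every,
    )
    res = simulate_batch(protocol, net, gsm, X_post, X_post, record=("u",))
    # Running average over post-onset samples only: drop the t = 0 record,
    # which is the initial condition rather than a post-onset state.
    post = res["times"] > 0
    times = res["times"][post]
    u_runs = res["u"][post]  # (n_times, n_reps, n)
    if x is not None or not redraw_stimulus:
        marginals = [marginal_posterior(gsm, X_post[0])] * n_reps
    else:
        marginals = [marginal_posterior(gsm, X_post[r]) for r in range(n_reps)]
    ref_means = np.array([m.mean_u for m in marginals])
    if normalization == "marginal":
        norm_var = np.array([m.var_u for m in marginals])
    elif normalization == "conditional":
        norm_var = np.diag(posterior_u(gsm, X_post[0], z_gen).cov).copy()
    else:
        raise ValueError("normalization must be 'marginal' or 'conditional'")
    return convergence_curve_from_runs(times, u_runs, ref_means, norm_var)


# ---------------------------------------------------------------------------
# E-I balance
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BalanceResult:
    """Recurrent excitatory vs inhibitory currents and their co-fluctuation."""

    exc_current_t: np.ndarray
    inh_current_t: np.ndarray
    trial_mean_pairs: np.ndarray  # (n, 2): per-cell (E, I) time-averages
    xcorr_lags: np.ndarray  # seconds
    xcorr: np.ndarray
    peak_lag: float  # seconds; positive = inhibition lags


def ei_balance(trajectory, net: NetworkParams, max_lag_s: float = 0.05) -> BalanceResult:
    """Per-cell recurrent E and I currents and the population E-I lag.

    E current on cell i is [W_uu u]_i, I current [W_uv v]_i; the lag is the
    argmax of the Pearson cross-correlation between population-mean u and
    population-mean v (positive peak lag = inhibition lags excitation).
    """
    if trajectory.v_t is None:
        raise ValueError("E-I balance requires a Hamiltonian-mode trajectory")
    u_t, v_t = trajectory.u_t, trajectory.v_t
    exc = u_t @ net.W_uu.T
    inh = v_t @ net.W_uv.T
    pairs = np.column_stack([exc.mean(axis=0), inh.mean(axis=0)])
    max_lag = int(round(max_lag_s * trajectory.fs))
    lags, corr = cross_correlation(u_t.mean(axis=1), v_t.mean(axis=1), max_lag)
    peak_lag = float(lags[int(np.argmax(corr))] / trajectory.fs)
    return BalanceResult(
        exc_current_t=exc, inh_current_t=inh, trial_mean_pairs=pairs,
        xcorr_lags=lags / trajectory.fs, xcorr=corr, peak_lag=peak_lag,
    )


def tls_slope(x: np.ndarray, y: np.ndarray) -> float:
    """Total-least-squares slope of y against x (first principal axis)."""
    X = np.column_stack([x - x.mean(), y - y.mean()])
    _, _, Vt = np.linalg.svd(X, full_matrices=False)
    vx, vy = Vt[0]
    return float(vy / vx)


# ---------------------------------------------------------------------------
# Transients
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TransientMetrics:
    """Quantification of the population-rate transient at stimulus onset."""

    baseline_rate: float
    peak_rate: float
    steady_rate: float
    time_to_peak: float
    excursion_duration: float
    transient_absent: bool


def _boxcar(series: np.ndarray, width: int) -> np.ndarray:
    if width <= 1:
        return series
    kernel = np.ones(width) / width
    return np.convolve(series, kernel, mode="same")


def transient_metrics(
    rate_series: np.ndarray, onset_index: int, fs: float
) -> TransientMetrics:
    """Quantify the onset transient of a population-mean rate series.

    baseline = mean over the last 50% of the pre epoch; steady = mean over
    the last 25% of the post epoch; peak = max of the (5 ms boxcar smoothed)
    rate over the first 150 ms post-onset. The transient is flagged absent
    when the peak does not exceed the steady rate by more than three times
    the smoothed baseline's standard deviation: a noisy flat series always
    has max > mean, and the maximum of the few dozen effectively independent
    smoothed samples in the search window sits near two standard deviations
    under the null, so a three-sigma margin is required for detection.
    """
    r = np.asarray(rate_series, dtype=float)
    if onset_index <= 1 or onset_index >= len(r) - 1:
        raise ValueError("series must span pre- and post-onset epochs")
    smooth = _boxcar(r, max(int(round(0.005 * fs)), 1))
    pre = smooth[:onset_index]
    post = smooth[onset_index:]
    baseline = float(pre[len(pre) // 2 :].mean())
    baseline_sd = float(pre[len(pre) // 2 :].std())
    steady = float(post[-max(len(post) // 4, 1) :].mean())
    first = post[: max(int(round(0.150 * fs)), 2)]
    i_peak = int(np.argmax(first))
    peak = float(first[i_peak])
    time_to_peak = i_peak / fs
    absent = peak <= steady + 3.0 * baseline_sd
    if absent:
        duration = 0.0
    else:
        threshold = steady + 0.1 * (peak - steady)
        below = np.nonzero(post[i_peak:] <= threshold)[0]
        duration = (
            float((i_peak + below[0]) / fs) if len(below) else float(len(post) / fs)
        )
    return TransientMetrics(
        baseline_rate=baseline, peak_rate=peak, steady_rate=steady,
        time_to_peak=time_to_peak, excursion_duration=duration,
        transient_absent=bool(absent),
    )
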