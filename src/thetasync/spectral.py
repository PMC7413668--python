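"""Multitaper spectra, band envelopes, coherence with surrogate thresholds and
gamma-amplitude-by-theta-phase distributions."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal
from scipy.signal.windows import dpss
from scipy.stats import norm

from . import _dsp


@dataclass(frozen=True)
class BandDefinition:
    name: str
    low: float
    high: float

    def __post_init__(self):
        if not 0 < self.low < self.high:
            raise ValueError("band must satisfy 0 < low < high")

    @property
    def edges(self) -> tuple[float, float]:
        return (self.low, self.high)


DELTA = BandDefinition("delta", 1.0, 4.0)
THETA = BandDefinition("theta", 6.0, 10.0)
SLOW_GAMMA = BandDefinition("slow_gamma", 30.0, 60.0)
MEDIUM_GAMMA = BandDefinition("medium_gamma", 60.0, 100.0)
FAST_GAMMA = BandDefinition("fast_gamma", 100.0, 150.0)
CANONICAL_BANDS = (DELTA, THETA, SLOW_GAMMA, MEDIUM_GAMMA, FAST_GAMMA)


@dataclass
class SurrogateDistribution:
    """Surrogate statistic values with a fitted normal and its percentiles."""

    values: np.ndarray
    mu: float = 0.0
    sigma: float = 0.0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.mu = float(self.values.mean())
        self.sigma = float(self.values.std(ddof=1)) if self.values.size > 1 else 0.0

    @property
    def count(self) -> int:
        return self.values.size

    def threshold(self, percentile: float = 95.0) -> float:
        """Value where the fitted normal CDF reaches percentile/100."""
        return float(norm.ppf(percentile / 100.0, loc=self.mu, scale=self.sigma))

    def p_value(self, observed: float) -> float:
        """Upper-tail p of ``observed`` under the fitted normal."""
        if self.sigma == 0:
            return float(observed <= self.mu)
        return float(norm.sf(observed, loc=self.mu, scale=self.sigma))


def write_spectrum(path, freqs: np.ndarray, values: np.ndarray, **metadata) -> None:
    """Delimited text with ``# key value`` header metadata lines."""
    with open(path, "w") as fh:
        for k, v in metadata.items():
            fh.write(f"# {k}\t{v}\n")
        fh.write("frequency_hz\tvalue\n")
        for f, v in zip(freqs, values):
            fh.write(f"{f:.6g}\t{v:.8g}\n")


def multitaper_psd(series: np.ndarray, fs: float, bandwidth: float = 2.0):
    """Multitaper PSD (DPSS tapers, eigenvalue-weighted average).

    Returns ``(freqs, psd)``; the PSD integrates to the series variance
    (one-sided density).
    """
    x = np.asarray(series, dtype=float)
    n = x.size
    if n < 2 * fs:
        raise ValueError("need at least 2 s of data")
    nw = bandwidth * n / fs / 2.0
    k = max(int(2 * nw) - 1, 1)
    if nw < 1:
        raise ValueError("bandwidth incompatible with series length (NW < 1)")
    tapers, eigs = dpss(n, nw, Kmax=k, return_ratios=True)
    x = x - x.mean()
    spectra = np.abs(np.fft.rfft(tapers * x[None, :], axis=1)) ** 2
    psd = (eigs[:, None] * spectra).sum(axis=0) / eigs.sum()
    psd /= fs
    psd[1:-1] *= 2.0  # one-sided
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    return freqs, psd


def band_envelope(series: np.ndarray, fs: float, band: BandDefinition):
    """Zero-phase FIR band-pass then analytic envelope.

    Returns ``(envelope, instantaneous_power, mean_power)``.
    """
    if band.high >= fs / 2:
        raise ValueError(f"band {band.name} exceeds Nyquist at fs={fs}")
    filt = _dsp.bandpass(np.asarray(series, dtype=float), fs, band.low, band.high)
    env = _dsp.envelope(filt)
    power = env**2
    return env, power, float(power.mean())


def _circular_shift_offsets(n: int, fs: float, count: int, rng: np.random.Generator,
                            margin_s: float = 5.0) -> np.ndarray:
    lo = int(margin_s * fs)
    hi = n - lo
    if hi <= lo:  # short series: any non-trivial shift
        lo, hi = 1, n - 1
    return rng.integers(lo, hi, size=count)


def coherence_with_surrogates(
    x: np.ndarray,
    y: np.ndarray,
    fs: float,
    n_surrogates: int = 1000,
    seg_seconds: float = 2.0,
    seed: int = 0,
):
    """Magnitude-squared coherence plus a per-frequency surrogate threshold.

    Surrogates circularly displace ``y`` relative to ``x``; per frequency the
    surrogate coherences are fitted to a normal and the threshold is the
    value at which its CDF reaches 0.95.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("series must have equal length")
    nperseg = int(seg_seconds * fs)
    if x.size < 20 * nperseg // 2:
        raise ValueError("need at least 20 averaging segments")
    freqs, coh = signal.coherence(x, y, fs=fs, nperseg=nperseg)
    rng = np.random.default_rng(seed)
    shifts = _circular_shift_offsets(x.size, fs, n_surrogates, rng)
    sur = np.empty((n_surrogates, freqs.size))
    for i, s in enumerate(shifts):
        _, sur[i] = signal.coherence(x, np.roll(y, s), fs=fs, nperseg=nperseg)
    mu = sur.mean(axis=0)
    sd = sur.std(axis=0, ddof=1)
    threshold = norm.ppf(0.95, loc=mu, scale=sd)
    return freqs, coh, threshold


def gamma_phase_distribution(
    phase: np.ndarray,
    envelope: np.ndarray,
    cycle_bounds: np.ndarray,
    n_bins: int = 16,
    n_surrogates: int = 1000,
    fs: float = 625.0,
    seed: int = 0,
):
    """Mean gamma envelope in equidistant theta-phase bins, with significance.

    ``cycle_bounds`` is an (n_cycles, 2) array of [start, end) samples. Per
    cycle the envelope is averaged in equidistant phase bins, then averaged
    across cycles. Surrogates circularly shift the envelope relative to the
    phase; bins exceeding the surrogate 95th percentile are flagged.
    """
    phase = np.asarray(phase, dtype=float)
    env = np.asarray(envelope, dtype=float)
    cycle_bounds = np.asarray(cycle_bounds, dtype=int)
    if len(cycle_bounds) < 30:
        import warnings

        warnings.warn("fewer than 30 cycles: distribution is unstable")

    def profile(e):
        edges = np.linspace(0, 2 * np.pi, n_bins + 1)
        acc = np.zeros(n_bins)
        cnt = np.zeros(n_bins)
        for lo, hi in cycle_bounds:
            ph = phase[lo:hi]
            ok = np.isfinite(ph)
            idx = np.clip(np.digitize(ph[ok], edges) - 1, 0, n_bins - 1)
            cyc = np.zeros(n_bins)
            np.add.at(cyc, idx, e[lo:hi][ok])
            c = np.zeros(n_bins)
            np.add.at(c, idx, 1.0)
            with np.errstate(invalid="ignore"):
                m = np.where(c > 0, cyc / c, np.nan)
            good = c > 0
            acc[good] += m[good]
            cnt[good] += 1
        with np.errstate(invalid="ignore"):
            return np.where(cnt > 0, acc / cnt, np.nan)

    observed = profile(env)
    rng = np.random.default_rng(seed)
    shifts = _circular_shift_offsets(env.size, fs, n_surrogates, rng)
    sur = np.array([profile(np.roll(env, s)) for s in shifts])
    p95 = np.nanpercentile(sur, 95, axis=0)
    centres = (np.arange(n_bins) + 0.5) * 2 * np.pi / n_bins
    return {
        "bin_centres": centres,
        "mean_amplitude": observed,
        "threshold": p95,
        "significant": observed > p95,
    }
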