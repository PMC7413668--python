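"""Theta-gamma cross-frequency coupling and directionality.

Phase-amplitude coupling via the entropy-based modulation index on
waveform-equalized phase bins (each cycle split at its trough / ascent /
peak / descent anchors into four segments of N/4 equal-time bins), the
mean-vector-length alternative, comodulograms, cut-and-swap surrogates, and
cross-frequency directionality via the phase-slope index between the signal
and its gamma-band power envelope, with an MI mask.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _dsp
from .cycles import ThetaCycleTable, waveform_phase
from .spectral import SurrogateDistribution


@dataclass
class CouplingGrid:
    theta_freqs: np.ndarray
    gamma_freqs: np.ndarray
    values: np.ndarray  # theta x gamma
    kind: str = "mi"  # "mi" or "cfd"
    preferred_phase: np.ndarray | None = None
    lower_threshold: np.ndarray | None = None
    upper_threshold: np.ndarray | None = None

    def __post_init__(self):
        self.theta_freqs = np.asarray(self.theta_freqs, dtype=float)
        self.gamma_freqs = np.asarray(self.gamma_freqs, dtype=float)
        if np.any(np.diff(self.theta_freqs) <= 0) or np.any(np.diff(self.gamma_freqs) <= 0):
            raise ValueError("grid axes must be strictly increasing")

    def argmax_cell(self):
        i, j = np.unravel_index(np.nanargmax(np.abs(self.values)), self.values.shape)
        return self.theta_freqs[i], self.gamma_freqs[j]

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# kind\t" + self.kind + "\n")
            fh.write("# gamma_hz\t" + "\t".join(f"{g:g}" for g in self.gamma_freqs) + "\n")
            for i, tf in enumerate(self.theta_freqs):
                fh.write(f"{tf:g}\t" + "\t".join(f"{v:.8g}" for v in self.values[i]) + "\n")


# ---------------------------------------------------------------------------
# equalized phase bins
# ---------------------------------------------------------------------------

def equalized_bin_assignment(table: ThetaCycleTable, n_samples: int, n_bins: int = 20) -> np.ndarray:
    """Per-sample equalized phase-bin index (-1 outside valid cycles).

    Each cycle is split at its anchors into 4 segments; each segment into
    ``n_bins/4`` equal-time bins.
    """
    if n_bins % 4 != 0:
        raise ValueError("n_bins must be divisible by 4")
    per_seg = n_bins // 4
    assign = np.full(n_samples, -1, dtype=int)
    anchors = np.column_stack(
        [table.trough, table.ascent, table.peak, table.descent, table.next_trough]
    )
    valid = table.valid if table.valid is not None else np.ones(len(table), bool)
    for c in range(len(table)):
        if not valid[c]:
            continue
        for seg in range(4):
            a0, a1 = anchors[c, seg], anchors[c, seg + 1]
            idx = np.arange(a0, a1)
            frac = (idx - a0) / (a1 - a0)
            b = np.minimum((frac * per_seg).astype(int), per_seg - 1)
            assign[idx] = seg * per_seg + b
    return assign


def _mi_from_profile(profile: np.ndarray) -> float:
    p = profile / profile.sum()
    nz = p > 0
    h = float(-(p[nz] * np.log(p[nz])).sum())
    h_max = np.log(p.size)
    return (h_max - h) / h_max


def modulation_index(
    amplitude: np.ndarray,
    table: ThetaCycleTable | None = None,
    n_bins: int = 20,
    bin_assignment: np.ndarray | None = None,
):
    """Entropy-based MI over equalized phase bins.

    Returns ``(mi, bin_profile, preferred_phase)``; the profile is the mean
    amplitude per bin, the preferred phase the centre of the maximal bin in
    the waveform-phase coordinate.
    """
    amplitude = np.asarray(amplitude, dtype=float)
    if bin_assignment is None:
        if table is None:
            raise ValueError("either a cycle table or a bin assignment is required")
        if int(np.sum(table.valid)) < 50:
            import warnings

            warnings.warn("fewer than 50 valid cycles: MI is unstable")
        bin_assignment = equalized_bin_assignment(table, amplitude.size, n_bins)
    profile = np.zeros(n_bins)
    counts = np.zeros(n_bins)
    ok = bin_assignment >= 0
    np.add.at(profile, bin_assignment[ok], amplitude[ok])
    np.add.at(counts, bin_assignment[ok], 1.0)
    if np.any(counts == 0):
        raise ValueError(
            f"bins with zero samples: {np.nonzero(counts == 0)[0].tolist()}"
        )
    profile /= counts
    mi = _mi_from_profile(profile)
    preferred = (np.argmax(profile) + 0.5) * 2 * np.pi / n_bins
    return mi, profile, preferred


def mean_vector_length(phase: np.ndarray, amplitude: np.ndarray) -> float:
    """|mean(a * e^{i*phase})| normalized by the mean amplitude."""
    phase = np.asarray(phase, dtype=float)
    amplitude = np.asarray(amplitude, dtype=float)
    if phase.size != amplitude.size:
        raise ValueError("series must have equal length")
    ok = np.isfinite(phase) & np.isfinite(amplitude)
    a = amplitude[ok]
    if a.sum() == 0:
        raise ValueError("amplitude is zero everywhere")
    return float(np.abs((a * np.exp(1j * phase[ok])).mean()) / a.mean())


def mi_surrogates(
    amplitude: np.ndarray,
    table: ThetaCycleTable,
    n_bins: int = 20,
    n_surrogates: int = 100,
    fs: float = 625.0,
    seed: int = 0,
) -> SurrogateDistribution:
    """Cut-and-swap surrogate MI distribution.

    Each surrogate cuts the phase side (the equalized bin-assignment series)
    at a uniform random point away from the first/last 5 s, swaps the two
    segments and recomputes the MI against the unchanged amplitude.
    """
    assign = equalized_bin_assignment(table, amplitude.size, n_bins)
    rng = np.random.default_rng(seed)
    n = amplitude.size
    lo, hi = int(5 * fs), n - int(5 * fs)
    if hi <= lo:
        lo, hi = 1, n - 1
    vals = np.empty(n_surrogates)
    for i in range(n_surrogates):
        cut = int(rng.integers(lo, hi))
        swapped = np.concatenate([assign[cut:], assign[:cut]])
        vals[i], _, _ = modulation_index(amplitude, n_bins=n_bins, bin_assignment=swapped)
    return SurrogateDistribution(vals)


# ---------------------------------------------------------------------------
# comodulogram
# ---------------------------------------------------------------------------

def default_theta_grid() -> np.ndarray:
    return np.arange(4.0, 12.5, 1.0)


def default_gamma_grid() -> np.ndarray:
    return np.arange(30.0, 155.0, 5.0)


def comodulogram(
    signal: np.ndarray,
    fs: float,
    phase_signal: np.ndarray | None = None,
    theta_freqs: np.ndarray | None = None,
    gamma_freqs: np.ndarray | None = None,
    gamma_bandwidth: float = 20.0,
    theta_halfwidth: float = 1.0,
    n_bins: int = 20,
    ratio_threshold: float | None = None,
) -> CouplingGrid:
    """MI per (theta frequency, gamma frequency) cell.

    The phase comes from the waveform-aware estimator on ``phase_signal``
    (default: the signal itself) band-limited around each theta frequency;
    the amplitude is the envelope of ``signal`` filtered with the stated
    bandwidth around each gamma frequency.
    """
    theta_freqs = default_theta_grid() if theta_freqs is None else np.asarray(theta_freqs)
    gamma_freqs = default_gamma_grid() if gamma_freqs is None else np.asarray(gamma_freqs)
    if gamma_freqs.min() < 2 * theta_freqs.max():
        raise ValueError("gamma grid must lie above twice the maximal theta frequency")
    psig = signal if phase_signal is None else phase_signal
    x = np.asarray(signal, dtype=float)

    envelopes = {}
    for g in gamma_freqs:
        lo, hi = g - gamma_bandwidth / 2, g + gamma_bandwidth / 2
        if hi >= 0.95 * fs / 2 or lo <= 0:
            envelopes[g] = None  # skipped, reported as NaN
            continue
        envelopes[g] = _dsp.envelope(_dsp.bandpass(x, fs, lo, hi))

    values = np.full((theta_freqs.size, gamma_freqs.size), np.nan)
    preferred = np.full_like(values, np.nan)
    for i, tf in enumerate(theta_freqs):
        nb = (max(tf - theta_halfwidth, 0.5), tf + theta_halfwidth)
        try:
            _, table = waveform_phase(psig, fs, narrowband=nb)
        except ValueError:
            continue
        if ratio_threshold is not None:
            from .cycles import detect_theta_cycles

            table = detect_theta_cycles(np.asarray(psig, float), fs, table,
                                        ratio_threshold=ratio_threshold)
        assign = equalized_bin_assignment(table, x.size, n_bins)
        for j, g in enumerate(gamma_freqs):
            env = envelopes[g]
            if env is None:
                continue
            try:
                values[i, j], _, preferred[i, j] = modulation_index(
                    env, n_bins=n_bins, bin_assignment=assign
                )
            except ValueError:
                continue
    return CouplingGrid(theta_freqs, gamma_freqs, values, kind="mi",
                        preferred_phase=preferred)


# ---------------------------------------------------------------------------
# cross-frequency directionality (phase-slope index)
# ---------------------------------------------------------------------------

def _segment_spectra(x: np.ndarray, fs: float, seg_seconds: float):
    nseg = int(seg_seconds * fs)
    n = (x.size // nseg) * nseg
    segs = x[:n].reshape(-1, nseg)
    segs = segs - segs.mean(axis=1, keepdims=True)
    taper = np.hanning(nseg)
    spec = np.fft.rfft(segs * taper, axis=1)
    freqs = np.fft.rfftfreq(nseg, 1.0 / fs)
    return freqs, spec


def _complex_coherency(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    num = (X * np.conj(Y)).sum(axis=0)
    den = np.sqrt((np.abs(X) ** 2).sum(axis=0) * (np.abs(Y) ** 2).sum(axis=0))
    den[den == 0] = np.inf
    return num / den


def _psi(C: np.ndarray, freqs: np.ndarray, f_j: float, beta: float, dfreq: float) -> float:
    df = freqs[1] - freqs[0]
    step = int(round(dfreq / df))
    in_band = (freqs >= f_j - beta / 2) & (freqs < f_j + beta / 2)
    idx = np.nonzero(in_band)[0]
    idx = idx[idx + step < C.size]
    return float(np.imag(np.sum(np.conj(C[idx]) * C[idx + step])))


def cfd(
    signal: np.ndarray,
    fs: float,
    theta_freqs: np.ndarray | None = None,
    gamma_freqs: np.ndarray | None = None,
    beta: float = 2.0,
    dfreq: float = 0.5,
    seg_seconds: float = 2.0,
    gamma_bandwidth: float = 20.0,
) -> CouplingGrid:
    """Phase-slope index between the signal and its gamma power envelopes.

    Positive values: the slow phase leads the gamma amplitude; negative: the
    gamma amplitude leads. Segments of ``seg_seconds`` give a native
    frequency resolution of ``1/seg_seconds`` Hz; ``dfreq`` must be a
    multiple of it.
    """
    theta_freqs = default_theta_grid() if theta_freqs is None else np.asarray(theta_freqs)
    gamma_freqs = default_gamma_grid() if gamma_freqs is None else np.asarray(gamma_freqs)
    x = np.asarray(signal, dtype=float)
    n_segments = int(x.size / (seg_seconds * fs))
    if n_segments < 10:
        raise ValueError(f"only {n_segments} segments; need at least 10")
    freqs, X = _segment_spectra(x, fs, seg_seconds)
    values = np.full((theta_freqs.size, gamma_freqs.size), np.nan)
    for j, g in enumerate(gamma_freqs):
        lo, hi = g - gamma_bandwidth / 2, g + gamma_bandwidth / 2
        if hi >= 0.95 * fs / 2 or lo <= 0:
            continue
        env = _dsp.envelope(_dsp.bandpass(x, fs, lo, hi))
        _, Y = _segment_spectra(env, fs, seg_seconds)
        C = _complex_coherency(X, Y)
        for i, tf in enumerate(theta_freqs):
            values[i, j] = _psi(C, freqs, tf, beta, dfreq)
    return CouplingGrid(theta_freqs, gamma_freqs, values, kind="cfd")


def cfd_significance(
    signal: np.ndarray,
    fs: float,
    theta_freqs: np.ndarray | None = None,
    gamma_freqs: np.ndarray | None = None,
    n_surrogates: int = 100,
    seed: int = 0,
    **cfd_kwargs,
):
    """Two-tailed cut-and-swap surrogate bounds for the CFD grid.

    Returns ``(grid, flags)`` where ``grid`` carries the 2.5th / 97.5th
    percentile bounds of the per-cell surrogate normal fit and ``flags`` is
    +1 / -1 / 0 for cells above, below or inside the bounds.
    """
    grid = cfd(signal, fs, theta_freqs, gamma_freqs, **cfd_kwargs)
    x = np.asarray(signal, dtype=float)
    rng = np.random.default_rng(seed)
    lo, hi = int(5 * fs), x.size - int(5 * fs)
    if hi <= lo:
        lo, hi = 1, x.size - 1
    sur = np.empty((n_surrogates,) + grid.values.shape)
    for i in range(n_surrogates):
        cut = int(rng.integers(lo, hi))
        xs = np.concatenate([x[cut:], x[:cut]])
        # swap the phase side only: surrogate envelope comes from the intact
        # signal, so the theta-envelope alignment is broken
        sur[i] = _cfd_cross(x_phase=xs, x_amp=x, fs=fs, grid=grid, **cfd_kwargs)
    mu = sur.mean(axis=0)
    sd = sur.std(axis=0, ddof=1)
    grid.lower_threshold = mu - 1.959963984540054 * sd
    grid.upper_threshold = mu + 1.959963984540054 * sd
    flags = np.zeros(grid.values.shape, dtype=int)
    flags[grid.values > grid.upper_threshold] = 1
    flags[grid.values < grid.lower_threshold] = -1
    flags[~np.isfinite(grid.values)] = 0
    return grid, flags


def _cfd_cross(x_phase, x_amp, fs, grid, beta=2.0, dfreq=0.5, seg_seconds=2.0,
               gamma_bandwidth=20.0):
    freqs, X = _segment_spectra(np.asarray(x_phase, float), fs, seg_seconds)
    values = np.full(grid.values.shape, np.nan)
    for j, g in enumerate(grid.gamma_freqs):
        lo, hi = g - gamma_bandwidth / 2, g + gamma_bandwidth / 2
        if hi >= 0.95 * fs / 2 or lo <= 0:
            continue
        env = _dsp.envelope(_dsp.bandpass(np.asarray(x_amp, float), fs, lo, hi))
        _, Y = _segment_spectra(env, fs, seg_seconds)
        C = _complex_coherency(X, Y)
        for i, tf in enumerate(grid.theta_freqs):
            values[i, j] = _psi(C, freqs, tf, beta, dfreq)
    return values


def apply_mi_mask(mi_grid: CouplingGrid, cfd_grid: CouplingGrid) -> CouplingGrid:
    """Attenuate CFD cells without phase-amplitude coupling.

    The MI grid is min-max rescaled to [0, 1] (an all-equal grid maps to
    all ones) and multiplied cell-wise into the CFD values.
    """
    if (mi_grid.values.shape != cfd_grid.values.shape
            or not np.array_equal(mi_grid.theta_freqs, cfd_grid.theta_freqs)
            or not np.array_equal(mi_grid.gamma_freqs, cfd_grid.gamma_freqs)):
        raise ValueError("MI and CFD grids must share axes")
    mi = mi_grid.values
    lo, hi = np.nanmin(mi), np.nanmax(mi)
    if hi > lo:
        mask = (mi - lo) / (hi - lo)
    else:
        mask = np.ones_like(mi)
    return CouplingGrid(cfd_grid.theta_freqs, cfd_grid.gamma_freqs,
                        cfd_grid.values * mask, kind="cfd_masked")
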