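"""Synthetic ground-truth generators.

Provides the calibration model (per-cycle theta sinusoids plus pink noise),
a multichannel laminar-LFP forward model with fixed depth loadings, gamma
bursts phase-locked to local theta and a switching phase-lock state sequence,
a directional theta-gamma fixture with a known lead/lag, and a speed
covariate with a prescribed correlation to theta power.

Randomness is driven by a single seed that is split into independent
substreams (one per noise source / generator), so adding a generator does
not perturb the draws of the others.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np


# ---------------------------------------------------------------------------
# pink noise
# ---------------------------------------------------------------------------

def pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance pink (1/f power) noise via spectral shaping of white noise."""
    if n < 2:
        raise ValueError("need at least 2 samples")
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    scale = np.ones_like(f)
    scale[1:] = 1.0 / np.sqrt(f[1:])
    spec *= scale
    spec[0] = 0.0
    x = np.fft.irfft(spec, n)
    return x / x.std()


# ---------------------------------------------------------------------------
# theta + pink-noise calibration model
# ---------------------------------------------------------------------------

@dataclass
class ThetaNoiseModel:
    """Theta oscillation built from per-cycle sinusoids, embedded in pink noise.

    Each cycle spans one period of ``A*sin(2*pi*f_i*t + 1.5*pi)`` so the cycle
    starts exactly at its trough; cycle durations are drawn from a normal
    distribution (mean 0.125 s, sd 0.02 s) redrawn until they fall inside
    [0.1, 0.145] s.
    """

    amplitude: float = 1.0
    noise_amplitude: float = 1.0
    duration: float = 60.0
    fs: float = 625.0
    cycle_mean: float = 0.125
    cycle_sd: float = 0.02
    cycle_bounds: tuple[float, float] = (0.1, 0.145)
    seed: int = 0


def _draw_cycle_durations(rng: np.random.Generator, model: ThetaNoiseModel) -> np.ndarray:
    lo, hi = model.cycle_bounds
    durs = []
    total = 0.0
    while total < model.duration:
        d = rng.normal(model.cycle_mean, model.cycle_sd)
        while not (lo <= d <= hi):
            d = rng.normal(model.cycle_mean, model.cycle_sd)
        durs.append(d)
        total += d
    return np.asarray(durs)


def simulate_theta_noise(model: ThetaNoiseModel):
    """Simulate the calibration signal.

    Returns
    -------
    x : ndarray
        Theta + pink noise series.
    trough_times : ndarray
        Ground-truth trough times (s) — exactly the cycle start times.
    phase : ndarray
        Ground-truth phase, advancing linearly 0 -> 2*pi within each cycle.
    """
    if model.amplitude < 0:
        raise ValueError("amplitude must be non-negative")
    if model.duration < model.cycle_bounds[1]:
        raise ValueError("duration too short for a single cycle")
    if model.duration < 10:
        raise ValueError("duration must be at least 10 s")
    if model.fs < 250:
        raise ValueError("sampling rate must be at least 250 Hz")

    ss = np.random.SeedSequence(model.seed)
    rng_cycles, rng_noise = (np.random.default_rng(s) for s in ss.spawn(2))

    durs = _draw_cycle_durations(rng_cycles, model)
    starts = np.concatenate([[0.0], np.cumsum(durs)])[:-1]

    n = int(round(model.duration * model.fs))
    t = np.arange(n) / model.fs
    theta = np.zeros(n)
    phase = np.zeros(n)
    for start, d in zip(starts, durs):
        i0 = int(np.ceil(start * model.fs))
        i1 = min(n, int(np.ceil((start + d) * model.fs)))
        if i0 >= n:
            break
        ti = t[i0:i1] - start
        theta[i0:i1] = model.amplitude * np.sin(2 * np.pi * ti / d + 1.5 * np.pi)
        phase[i0:i1] = 2 * np.pi * ti / d

    x = theta
    if model.noise_amplitude > 0:
        x = x + model.noise_amplitude * pink_noise(n, rng_noise)
    trough_times = starts[starts < model.duration]
    return x, trough_times, phase


# ---------------------------------------------------------------------------
# laminar forward model
# ---------------------------------------------------------------------------

@dataclass
class GeneratorSpec:
    """One fixed-location current generator of the laminar forward model."""

    loading: np.ndarray  # one weight per channel; normalized to unit max |.|
    theta_center: float = 8.0  # Hz
    asymmetry: float = 1.0  # rise/decay duration ratio
    gamma_band: tuple[float, float] = (30.0, 60.0)
    coupling: float = 1.0  # 0..1
    preferred_phase: float = 0.0  # radians of local theta
    gamma_lag: float = 0.0  # s, negative = burst precedes the anchor phase
    phase_offset: float = 0.0  # lag to the common drive, radians
    jitter_high: float = 0.1  # phase jitter sd in "high" lock states, radians
    jitter_low: float = 1.5  # phase jitter sd in "low" lock states, radians
    theta_amplitude: float = 1.0
    gamma_amplitude: float = 0.25

    def __post_init__(self):
        self.loading = np.asarray(self.loading, dtype=float)
        m = np.max(np.abs(self.loading))
        if m == 0:
            raise ValueError("loading profile is all-zero")
        self.loading = self.loading / m
        lo, hi = self.gamma_band
        if not lo < hi:
            raise ValueError("gamma band low must be < high")
        if not 0.0 <= self.coupling <= 1.0:
            raise ValueError("coupling strength must lie in [0, 1]")


@dataclass
class SyntheticGroundTruth:
    """Everything downstream stages are graded against."""

    sources: np.ndarray  # generators x samples
    phases: np.ndarray  # generators x samples, true local theta phase
    mixing: np.ndarray  # channels x generators
    state_labels: list  # "high" / "low"
    state_bounds: np.ndarray  # (n_states, 2) start/end sample
    gamma_event_times: list  # per generator, burst centre times (s)
    speed: np.ndarray | None = None
    fs: float = 625.0

    def state_at(self, sample: int) -> str:
        idx = np.searchsorted(self.state_bounds[:, 1], sample, side="right")
        idx = min(idx, len(self.state_labels) - 1)
        return self.state_labels[idx]

    def to_json(self) -> str:
        return json.dumps(
            {
                "mixing": self.mixing.tolist(),
                "state_labels": list(self.state_labels),
                "state_bounds": self.state_bounds.tolist(),
                "gamma_event_times": [list(map(float, g)) for g in self.gamma_event_times],
                "fs": self.fs,
            }
        )


def _asymmetric_theta(troughs, asymmetry, amplitude, fs, n):
    """Two-half-sine cycles tiling the interval between consecutive troughs.

    Every cycle starts and ends at the trough value with zero slope, so the
    waveform is C1-continuous regardless of per-cycle duration jitter (no
    broadband transients at the joins). Returns ``(series, true phase)``
    with phase 0 -> pi over the rise and pi -> 2*pi over the decay.
    """
    t = np.arange(n) / fs
    x = np.full(n, -amplitude)
    phase = np.zeros(n)
    rise_frac = asymmetry / (1.0 + asymmetry)
    for k in range(len(troughs) - 1):
        t0, t1 = troughs[k], troughs[k + 1]
        d = t1 - t0
        if d <= 0:
            continue
        i0 = max(int(np.ceil(t0 * fs)), 0)
        i1 = min(int(np.ceil(t1 * fs)), n)
        if i0 >= i1:
            continue
        ti = t[i0:i1] - t0
        t_rise = rise_frac * d
        t_decay = d - t_rise
        seg = np.empty(i1 - i0)
        ph = np.empty(i1 - i0)
        rising = ti < t_rise
        seg[rising] = -np.cos(np.pi * ti[rising] / t_rise)
        ph[rising] = np.pi * ti[rising] / t_rise
        seg[~rising] = np.cos(np.pi * (ti[~rising] - t_rise) / t_decay)
        ph[~rising] = np.pi + np.pi * (ti[~rising] - t_rise) / t_decay
        x[i0:i1] = amplitude * seg
        phase[i0:i1] = ph
    return x, phase


def _gamma_bursts(burst_times, freq, fs, n, rng, amp=1.0):
    """Gaussian-windowed sinusoids (window sd = 2 gamma cycles) at given times."""
    x = np.zeros(n)
    sd = 2.0 / freq
    half = int(np.ceil(4 * sd * fs))
    t_rel = np.arange(-half, half + 1) / fs
    for bt in burst_times:
        c = int(round(bt * fs))
        if c - half >= n or c + half < 0:
            continue
        win = amp * np.exp(-0.5 * (t_rel / sd) ** 2)
        carrier = np.cos(2 * np.pi * freq * (t_rel) + rng.uniform(0, 2 * np.pi))
        lo = max(0, c - half)
        hi = min(n, c + half + 1)
        x[lo:hi] += (win * carrier)[lo - (c - half): hi - (c - half)]
    return x


def _state_sequence(duration, fs, rng, mean_len=5.0):
    """Alternating high/low phase-lock states tiling the recording."""
    n = int(round(duration * fs))
    bounds, labels = [], []
    pos = 0
    label = "high"
    while pos < n:
        length = max(int(rng.exponential(mean_len) * fs), int(1.0 * fs))
        end = min(pos + length, n)
        bounds.append((pos, end))
        labels.append(label)
        label = "low" if label == "high" else "high"
        pos = end
    return labels, np.asarray(bounds)


def simulate_laminar_lfp(
    specs: list[GeneratorSpec],
    duration: float = 60.0,
    noise_level: float = 0.1,
    fs: float = 625.0,
    seed: int = 0,
    n_channels: int | None = None,
    with_speed: bool = False,
    speed_correlation: float = 0.5,
):
    """Multichannel laminar LFP: channel m = sum_n V[m,n]*s_n(t) + pink noise.

    Returns ``(recording, truth)`` where ``recording`` is a
    :class:`~thetasync.recording.MultichannelRecording`.
    """
    from .recording import MultichannelRecording

    if len(specs) < 1:
        raise ValueError("need at least one generator")
    n_ch = len(specs[0].loading) if n_channels is None else n_channels
    if len(specs) >= 2 and n_ch < 8:
        raise ValueError("need at least 8 channels for multi-generator fixtures")
    V = np.column_stack([s.loading for s in specs])
    if len(specs) >= 2 and np.linalg.matrix_rank(V) < len(specs):
        import warnings

        warnings.warn("loading profiles are linearly dependent; ICA recovery not guaranteed")

    ss = np.random.SeedSequence(seed)
    children = ss.spawn(2 + 3 * len(specs) + n_ch)
    rng_cycles = np.random.default_rng(children[0])
    rng_states = np.random.default_rng(children[1])

    n = int(round(duration * fs))
    # common theta drive: shared cycle boundaries
    model = ThetaNoiseModel(duration=duration, fs=fs)
    durs = _draw_cycle_durations(rng_cycles, model)
    starts = np.concatenate([[0.0], np.cumsum(durs)])[:-1]
    n_cycles = len(durs)

    labels, bounds = _state_sequence(duration, fs, rng_states)
    # per-cycle state (by cycle start sample)
    start_samples = (starts * fs).astype(int)
    cycle_state = np.array([
        labels[min(np.searchsorted(bounds[:, 1], s, side="right"), len(labels) - 1)]
        for s in start_samples
    ])

    sources = np.zeros((len(specs), n))
    phases = np.zeros((len(specs), n))
    gamma_events = []
    min_gap = 0.5 * model.cycle_bounds[0]
    for g, spec in enumerate(specs):
        rng_jit = np.random.default_rng(children[2 + 3 * g])
        rng_burst = np.random.default_rng(children[2 + 3 * g + 1])
        jitter_sd = np.where(cycle_state == "high", spec.jitter_high, spec.jitter_low)
        offsets = spec.phase_offset + rng_jit.normal(0.0, 1.0, n_cycles) * jitter_sd
        troughs = starts + offsets / (2 * np.pi) * durs
        # keep the jittered trough sequence strictly increasing
        for k in range(1, troughs.size):
            if troughs[k] < troughs[k - 1] + min_gap:
                troughs[k] = troughs[k - 1] + min_gap
        # pad so the first/last samples are covered by a cycle
        troughs_ext = np.concatenate(
            [[troughs[0] - model.cycle_mean], troughs,
             [troughs[-1] + model.cycle_mean]]
        )
        theta, phase = _asymmetric_theta(
            troughs_ext, spec.asymmetry, spec.theta_amplitude, fs, n
        )
        # gamma bursts locked to the local theta at the preferred phase
        rise_frac = spec.asymmetry / (1.0 + spec.asymmetry)
        cyc_durs = np.diff(troughs_ext)
        burst_times = []
        for tt, d in zip(troughs_ext[:-1], cyc_durs):
            pp = spec.preferred_phase % (2 * np.pi)
            if pp <= np.pi:
                dt = pp / np.pi * rise_frac * d
            else:
                dt = rise_frac * d + (pp - np.pi) / np.pi * (1 - rise_frac) * d
            burst_times.append(tt + dt + spec.gamma_lag)
        burst_times = np.asarray(burst_times)
        gamma_events.append(burst_times)
        f_gamma = 0.5 * (spec.gamma_band[0] + spec.gamma_band[1])
        bursts = _gamma_bursts(burst_times, f_gamma, fs, n, rng_burst,
                               amp=spec.gamma_amplitude)
        # uncoupled gamma floor: band-limited noise in the same band
        rng_gnoise = np.random.default_rng(children[2 + 3 * g + 2])
        gnoise = rng_gnoise.standard_normal(n)
        from ._dsp import bandpass

        gnoise = bandpass(gnoise, fs, *spec.gamma_band)
        gnoise *= spec.gamma_amplitude * 0.35 / max(gnoise.std(), 1e-30)
        sources[g] = theta + spec.coupling * bursts + (1 - spec.coupling * 0.5) * gnoise
        phases[g] = phase

    data = sources.T @ V.T
    for m in range(n_ch):
        rng_noise = np.random.default_rng(children[2 + 3 * len(specs) + m])
        if noise_level > 0:
            data[:, m] += noise_level * pink_noise(n, rng_noise)

    depths = np.arange(n_ch) * 100.0
    rec = MultichannelRecording(
        data=data, fs=fs, depths_um=depths,
        labels=[f"ch{m:02d}" for m in range(n_ch)],
        provenance=[f"simulate_laminar_lfp(seed={seed})"],
    )
    truth = SyntheticGroundTruth(
        sources=sources, phases=phases, mixing=V, state_labels=labels,
        state_bounds=bounds, gamma_event_times=gamma_events, fs=fs,
    )
    if with_speed:
        from ._dsp import bandpass, envelope

        th_pow = envelope(bandpass(sources[0], fs, 6, 10)) ** 2
        truth.speed = simulate_speed_covariate(th_pow, speed_correlation, seed=seed + 1)
    return rec, truth


# ---------------------------------------------------------------------------
# directional CFC fixture
# ---------------------------------------------------------------------------

def simulate_directional_cfc(
    direction: str,
    lag: float = 0.03,
    duration: float = 120.0,
    fs: float = 625.0,
    gamma_freq: float = 45.0,
    seed: int = 0,
    coupled: bool = True,
):
    """Theta series with gamma bursts at a fixed lead or lag to the trough.

    ``direction="gamma_leads"``: each burst sits a fixed ``lag`` before the
    *next* theta trough (burst-to-trough interval constant, so gamma
    amplitude predicts theta phase). ``direction="theta_leads"``: burst a
    fixed ``lag`` after the *previous* trough. Variable cycle durations make
    the opposite interval jitter. ``coupled=False`` drops the bursts (null
    fixture).

    Returns ``(x, truth_dict)``.
    """
    if direction not in ("gamma_leads", "theta_leads"):
        raise ValueError("direction must be 'gamma_leads' or 'theta_leads'")
    model = ThetaNoiseModel(amplitude=1.0, noise_amplitude=0.0,
                            duration=duration, fs=fs, seed=seed)
    if abs(lag) >= model.cycle_bounds[0] / 2:
        raise ValueError("lag must be below half a theta period")
    x, troughs, phase = simulate_theta_noise(model)
    n = x.size
    ss = np.random.SeedSequence(seed + 104729)
    rng_burst, rng_noise = (np.random.default_rng(s) for s in ss.spawn(2))

    burst_times = np.empty(0)
    if coupled:
        if direction == "gamma_leads":
            burst_times = troughs[1:] - lag
        else:
            burst_times = troughs[:-1] + lag
        x = x + _gamma_bursts(burst_times, gamma_freq, fs, n, rng_burst, amp=0.5)
    x = x + 0.2 * pink_noise(n, rng_noise)
    truth = {
        "direction": direction,
        "lag": lag,
        "gamma_freq": gamma_freq,
        "burst_times": burst_times,
        "trough_times": troughs,
    }
    return x, truth


# ---------------------------------------------------------------------------
# speed covariate
# ---------------------------------------------------------------------------

def simulate_speed_covariate(theta_power: np.ndarray, target: float, seed: int = 0) -> np.ndarray:
    """Series whose sample correlation with ``theta_power`` equals ``target``.

    Built from the z-scored power plus an orthogonalized noise series, so the
    sample correlation is exact up to floating point; the output is shifted
    to a positive, speed-like scale.
    """
    p = np.asarray(theta_power, dtype=float)
    if not -1.0 < target < 1.0:
        raise ValueError("correlation target must lie in (-1, 1)")
    if p.std() == 0:
        raise ValueError("theta power is constant; correlation undefined")
    rng = np.random.default_rng(seed)
    z = (p - p.mean()) / p.std()
    noise = rng.standard_normal(p.size)
    noise = noise - noise.mean()
    noise = noise - (noise @ z) / (z @ z) * z  # orthogonalize
    noise = noise / noise.std()
    s = target * z + np.sqrt(1 - target**2) * noise
    return 10.0 + 3.0 * s
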