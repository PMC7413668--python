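"""Inter-cycle phase clustering (ICPC).

Static reference-based ICPC, the per-cycle dynamic variant (three-cycle
window), ICPC lag variability, and correlations of cycle features with the
binned ICPC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .spectral import SurrogateDistribution


def icpc(phases: np.ndarray):
    """Modulus and argument of the mean unit phase vector."""
    phases = np.asarray(phases, dtype=float)
    if phases.size < 2:
        raise ValueError("need at least 2 angles")
    v = np.exp(1j * phases).mean()
    return float(np.abs(v)), float(np.angle(v))


@dataclass
class ICPCSeries:
    """Per-cycle dynamic ICPC values."""

    cycle_times: np.ndarray  # s, reference trough per cycle
    pairwise: np.ndarray  # cycles x pairs
    global_icpc: np.ndarray  # cycles
    mean_angles: np.ndarray  # cycles x pairs
    pair_names: list[str]

    def __len__(self) -> int:
        return len(self.cycle_times)

    def to_dataframe(self) -> pd.DataFrame:
        d = {"time_s": self.cycle_times, "global_icpc": self.global_icpc}
        for j, name in enumerate(self.pair_names):
            d[f"icpc_{name}"] = self.pairwise[:, j]
            d[f"angle_{name}"] = self.mean_angles[:, j]
        return pd.DataFrame(d)

    def write(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)


def _phase_at(phase_series: np.ndarray, samples: np.ndarray) -> np.ndarray:
    ph = phase_series[np.clip(samples, 0, phase_series.size - 1)]
    return ph


def reference_icpc(
    phase_series: np.ndarray,
    reference_troughs: np.ndarray,
    n_surrogates: int = 1000,
    fs: float = 625.0,
    seed: int = 0,
):
    """ICPC of a component's phase sampled at the reference trough times.

    Surrogates circularly shift the phase series; the p-value comes from a
    normal fit to the surrogate ICPCs.
    """
    troughs = np.asarray(reference_troughs, dtype=int)
    if troughs.size < 100:
        raise ValueError("need at least 100 reference troughs")
    trials = _phase_at(phase_series, troughs)
    ok = np.isfinite(trials)
    if not ok.any():
        raise ValueError("no valid trough phases")
    value, angle = icpc(trials[ok])
    rng = np.random.default_rng(seed)
    lo, hi = int(5 * fs), phase_series.size - int(5 * fs)
    if hi <= lo:
        lo, hi = 1, phase_series.size - 1
    sur = np.empty(n_surrogates)
    for i in range(n_surrogates):
        shifted = np.roll(phase_series, rng.integers(lo, hi))
        tr = shifted[troughs]
        tr = tr[np.isfinite(tr)]
        sur[i], _ = icpc(tr)
    dist = SurrogateDistribution(sur)
    return value, angle, dist.p_value(value)


def dynamic_icpc(
    phase_series: dict[str, np.ndarray],
    reference: str,
    reference_troughs: np.ndarray,
    fs: float = 625.0,
    window: int = 3,
):
    """Per-cycle ICPC from ``window`` consecutive relative phases.

    The relative phase of each non-reference signal is sampled at the
    reference trough of every cycle; the ICPC at cycle c uses the phases at
    cycles ``c - w//2 .. c + w//2``. The global value is the mean of the
    pairwise values. First/last cycles are NaN.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 3")
    if reference not in phase_series:
        raise ValueError(f"reference '{reference}' not among signals")
    troughs = np.asarray(reference_troughs, dtype=int)
    others = [k for k in phase_series if k != reference]
    n_cycles = troughs.size
    half = window // 2
    pairwise = np.full((n_cycles, len(others)), np.nan)
    angles = np.full((n_cycles, len(others)), np.nan)
    rel = np.column_stack([_phase_at(phase_series[k], troughs) for k in others])
    for c in range(half, n_cycles - half):
        for j in range(len(others)):
            w = rel[c - half: c + half + 1, j]
            if np.all(np.isfinite(w)):
                pairwise[c, j], angles[c, j] = icpc(w)
    with np.errstate(invalid="ignore"):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            global_icpc = np.nanmean(pairwise, axis=1)
    return ICPCSeries(
        cycle_times=troughs / fs,
        pairwise=pairwise,
        global_icpc=global_icpc,
        mean_angles=angles,
        pair_names=[f"{reference}-{k}" for k in others],
    )


def icpc_lag_variability(
    series: ICPCSeries,
    bin_width: float = 0.125,
    max_lag: float = 3.0,
    n_boot: int = 200,
    min_pairs: int = 50,
    seed: int = 0,
):
    """Mean |ICPC difference| between cycle pairs, binned by their lag.

    Returns a dict with the lag-bin centres, mean |dICPC| per bin, bootstrap
    95% CI and a reliability flag per bin.
    """
    v = series.global_icpc
    t = series.cycle_times
    ok = np.isfinite(v)
    v, t = v[ok], t[ok]
    if v.size < 500:
        raise ValueError("need at least 500 cycles")
    dt = np.abs(t[None, :] - t[:, None])
    dv = np.abs(v[None, :] - v[:, None])
    iu = np.triu_indices(v.size, k=1)
    dt, dv = dt[iu], dv[iu]
    keep = dt <= max_lag
    dt, dv = dt[keep], dv[keep]
    edges = np.arange(0.0, max_lag + bin_width, bin_width)
    centres = 0.5 * (edges[:-1] + edges[1:])
    idx = np.digitize(dt, edges) - 1
    rng = np.random.default_rng(seed)
    means = np.full(centres.size, np.nan)
    ci = np.full((centres.size, 2), np.nan)
    reliable = np.zeros(centres.size, dtype=bool)
    for b in range(centres.size):
        vals = dv[idx == b]
        if vals.size == 0:
            continue
        means[b] = vals.mean()
        reliable[b] = vals.size >= min_pairs
        boots = np.array([
            vals[rng.integers(0, vals.size, vals.size)].mean() for _ in range(n_boot)
        ])
        ci[b] = np.percentile(boots, [2.5, 97.5])
    return {"lag": centres, "mean_abs_dicpc": means, "ci": ci, "reliable": reliable}


def bin_feature_by_icpc(
    icpc_values: np.ndarray,
    feature: np.ndarray,
    n_bins: int = 10,
    value_range: tuple[float, float] = (0.75, 1.0),
    n_surrogates: int = 100,
    seed: int = 0,
):
    """Average a per-cycle feature in equidistant ICPC bins and correlate.

    Pearson R between the non-empty bin means and bin centres; significance
    against surrogates built by circularly shifting the per-cycle feature
    sequence relative to the ICPC sequence (95th percentile of the surrogate
    R distribution).
    """
    icpc_values = np.asarray(icpc_values, dtype=float)
    feature = np.asarray(feature, dtype=float)
    ok = np.isfinite(icpc_values) & np.isfinite(feature)
    x, f = icpc_values[ok], feature[ok]

    edges = np.linspace(*value_range, n_bins + 1)
    centres = 0.5 * (edges[:-1] + edges[1:])

    def binned_r(feat):
        means = np.full(n_bins, np.nan)
        for b in range(n_bins):
            lo, hi = edges[b], edges[b + 1]
            m = (x >= lo) & (x < hi) if b < n_bins - 1 else (x >= lo) & (x <= hi)
            if m.any():
                means[b] = feat[m].mean()
        good = np.isfinite(means)
        if good.sum() < 3:
            return means, np.nan
        r, _ = pearsonr(centres[good], means[good])
        return means, r

    bin_means, r = binned_r(f)
    rng = np.random.default_rng(seed)
    sur = np.empty(n_surrogates)
    for i in range(n_surrogates):
        shift = rng.integers(1, f.size)
        _, sur[i] = binned_r(np.roll(f, shift))
    dist = SurrogateDistribution(sur[np.isfinite(sur)])
    significant = bool(np.isfinite(r) and r > dist.threshold(95.0))
    return {
        "bin_centres": centres,
        "bin_means": bin_means,
        "r": r,
        "significant": significant,
        "surrogates": dist,
    }
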