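"""Pipeline configuration and end-to-end orchestration.

A single config drives: simulate/ingest -> preprocess -> decompose ->
cycles -> ICPC -> CFC/CFD -> regression. Every numeric default equals the
analysis defaults used throughout the package (ratio threshold 4, variance
keep 99%, minimum component variance 1%, 20 MI bins, 1000/100 surrogates,
CFD beta 2 Hz at 0.5 Hz resolution, 625 Hz analysis rate, CSD with
350 ohm^-1 cm^-1 and 100 um spacing).
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

DEFAULTS = {
    "ratio_threshold": 4.0,
    "variance_keep": 0.99,
    "min_variance": 0.01,
    "mi_bins": 20,
    "n_surrogates_coherence": 1000,
    "n_surrogates_mi": 100,
    "cfd_beta_hz": 2.0,
    "cfd_dfreq_hz": 0.5,
    "analysis_fs_hz": 625.0,
    "csd_sigma": 350.0,
    "csd_spacing_um": 100.0,
}


@dataclass
class PipelineConfig:
    input_data: str | None = None  # flat-binary path (with .json sidecar)
    input_sidecar: str | None = None
    preset: str | None = "laminar"  # synthetic preset when no input files
    duration: float = 60.0
    seed: int = 0
    out_dir: str = "pipeline_out"
    bands: dict = field(default_factory=lambda: {
        "delta": (1.0, 4.0), "theta": (6.0, 10.0), "slow_gamma": (30.0, 60.0),
        "medium_gamma": (60.0, 100.0), "fast_gamma": (100.0, 150.0),
    })
    ratio_threshold: float = DEFAULTS["ratio_threshold"]
    variance_keep: float = DEFAULTS["variance_keep"]
    min_variance: float = DEFAULTS["min_variance"]
    mi_bins: int = DEFAULTS["mi_bins"]
    n_surrogates_coherence: int = DEFAULTS["n_surrogates_coherence"]
    n_surrogates_mi: int = DEFAULTS["n_surrogates_mi"]
    cfd_beta_hz: float = DEFAULTS["cfd_beta_hz"]
    cfd_dfreq_hz: float = DEFAULTS["cfd_dfreq_hz"]
    cfc_theta_step_hz: float = 1.0
    cfc_gamma_step_hz: float = 5.0
    analysis_fs_hz: float = DEFAULTS["analysis_fs_hz"]
    csd_sigma: float = DEFAULTS["csd_sigma"]
    csd_spacing_um: float = DEFAULTS["csd_spacing_um"]

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        d = json.loads(text)
        d["bands"] = {k: tuple(v) for k, v in d.get("bands", {}).items()}
        return cls(**d)


def validate_config(config: PipelineConfig | dict):
    """Fill defaults and collect out-of-range errors.

    Returns ``(normalized_config, errors)``; the config is usable only when
    ``errors`` is empty.
    """
    if isinstance(config, dict):
        try:
            config = PipelineConfig(**config)
        except TypeError as exc:
            return None, [str(exc)]
    errors = []
    if config.mi_bins % 4 != 0 or config.mi_bins <= 0:
        errors.append(f"mi_bins must be a positive multiple of 4, got {config.mi_bins}")
    if config.n_surrogates_coherence < 0 or config.n_surrogates_mi < 0:
        errors.append("surrogate counts must be non-negative")
    if not 0 < config.variance_keep <= 1:
        errors.append(f"variance_keep must lie in (0, 1], got {config.variance_keep}")
    if not 0 <= config.min_variance < 1:
        errors.append(f"min_variance must lie in [0, 1), got {config.min_variance}")
    if config.ratio_threshold <= 0:
        errors.append("ratio_threshold must be positive")
    if config.cfd_beta_hz <= 0 or config.cfd_dfreq_hz <= 0:
        errors.append("CFD parameters must be positive")
    if config.cfc_theta_step_hz <= 0 or config.cfc_gamma_step_hz <= 0:
        errors.append("CFC grid steps must be positive")
    for name, (lo, hi) in config.bands.items():
        if not 0 < lo < hi:
            errors.append(f"band '{name}' must satisfy 0 < low < high")
    if config.input_data is None and config.preset not in (
        "laminar", "theta-noise", "directional"
    ):
        errors.append(f"unknown preset '{config.preset}'")
    return config, errors


def _log(lines: list, stage: str, msg: str) -> None:
    line = f"{time.strftime('%Y-%m-%dT%H:%M:%S')}\t{stage}\t{msg}"
    lines.append(line)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full chain; returns the run report (also written to disk)."""
    from . import cfc, icpc, synth
    from .cycles import detect_theta_cycles, waveform_phase
    from .decompose import fit_decomposition, select_components, write_decomposition
    from .recording import preprocess, read_recording, write_recording

    config, errors = validate_config(config)
    if errors:
        raise ValueError("invalid config: " + "; ".join(errors))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = []
    report = {"config": json.loads(config.to_json()), "stages": {}}
    _log(log, "init", f"seed={config.seed}")

    try:
        # --- input ---------------------------------------------------------
        if config.input_data is not None:
            if not Path(config.input_data).exists():
                raise FileNotFoundError(f"input file not found: {config.input_data}")
            sidecar = config.input_sidecar or str(Path(config.input_data).with_suffix(".json"))
            rec = read_recording(config.input_data, sidecar)
            truth = None
        else:
            rec, truth = _simulate_preset(config, synth)
        _log(log, "input", f"{rec.n_samples} samples x {rec.n_channels} ch @ {rec.fs} Hz")

        # --- preprocess ----------------------------------------------------
        rec = preprocess(rec, target_fs=config.analysis_fs_hz)
        write_recording(rec, out / "preprocessed.f32", out / "preprocessed.json")
        _log(log, "preprocess", f"fs={rec.fs}")

        # --- decompose -----------------------------------------------------
        dec = fit_decomposition(rec, variance_keep=config.variance_keep,
                                seed=config.seed)
        n4 = rec.n_samples // 4
        epochs = [(i * n4, (i + 1) * n4) for i in range(4)]
        selected, stability = select_components(
            dec, rec, epochs, min_variance=config.min_variance, seed=config.seed
        )
        write_decomposition(dec, out / "decomposition")
        report["stages"]["decompose"] = {
            "n_components": dec.n_components,
            "variance_share": dec.variance_share.tolist(),
            "selected": selected.tolist(),
            "stability": stability.tolist(),
        }
        _log(log, "decompose", f"selected {selected.tolist()}")
        if len(selected) == 0:
            raise RuntimeError("no stable components selected")

        # --- cycles --------------------------------------------------------
        phases, tables = {}, {}
        for n in selected:
            name = f"ic{n}"
            ph, table = waveform_phase(dec.series[n], rec.fs)
            table = detect_theta_cycles(dec.series[n], rec.fs, table,
                                        ratio_threshold=config.ratio_threshold)
            table.write(out / f"cycles_{name}.tsv")
            phases[name], tables[name] = ph, table
        n_valid = {k: int(t.valid.sum()) for k, t in tables.items()}
        report["stages"]["cycles"] = {"n_valid": n_valid}
        _log(log, "cycles", f"valid cycles {n_valid}")

        # --- ICPC ----------------------------------------------------------
        ref = max(tables, key=lambda k: n_valid[k])
        troughs = tables[ref].trough[tables[ref].valid]
        series = icpc.dynamic_icpc(phases, ref, troughs, fs=rec.fs)
        series.write(out / "icpc.tsv")
        mean_icpc = float(np.nanmean(series.global_icpc))
        report["stages"]["icpc"] = {"reference": ref, "mean_global_icpc": mean_icpc}
        _log(log, "icpc", f"reference={ref} mean={mean_icpc:.3f}")

        # --- CFC / CFD -----------------------------------------------------
        cfc_summary = {}
        theta_grid = np.arange(4.0, 12.0 + config.cfc_theta_step_hz / 2,
                               config.cfc_theta_step_hz)
        gamma_grid = np.arange(30.0, 150.0 + config.cfc_gamma_step_hz / 2,
                               config.cfc_gamma_step_hz)
        for n in selected[:3]:
            name = f"ic{n}"
            grid = cfc.comodulogram(dec.series[n], rec.fs, n_bins=config.mi_bins,
                                    theta_freqs=theta_grid, gamma_freqs=gamma_grid)
            grid.write(out / f"mi_{name}.tsv")
            dgrid = cfc.cfd(dec.series[n], rec.fs, beta=config.cfd_beta_hz,
                            dfreq=config.cfd_dfreq_hz,
                            theta_freqs=theta_grid, gamma_freqs=gamma_grid)
            dgrid.write(out / f"cfd_{name}.tsv")
            tmax, gmax = grid.argmax_cell()
            cfc_summary[name] = {
                "mi_max": float(np.nanmax(grid.values)),
                "mi_argmax": [float(tmax), float(gmax)],
                "cfd_extreme": float(
                    dgrid.values.flat[np.nanargmax(np.abs(dgrid.values))]
                ),
            }
        report["stages"]["cfc"] = cfc_summary
        _log(log, "cfc", json.dumps(cfc_summary))

        # --- regression ----------------------------------------------------
        reg_summary = _regress_icpc(rec, dec, int(ref[2:]), tables[ref], series, truth)
        if reg_summary is not None:
            report["stages"]["regression"] = reg_summary
            _log(log, "regression", json.dumps(reg_summary))
    except Exception as exc:
        _log(log, "error", f"{type(exc).__name__}: {exc}")
        (out / "run.log").write_text("\n".join(log) + "\n")
        raise

    (out / "run.log").write_text("\n".join(log) + "\n")
    (out / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    return report


def _simulate_preset(config: PipelineConfig, synth):
    if config.preset == "laminar":
        specs = default_laminar_specs()
        return synth.simulate_laminar_lfp(
            specs, duration=config.duration, fs=config.analysis_fs_hz,
            seed=config.seed, with_speed=True,
        )
    if config.preset == "theta-noise":
        model = synth.ThetaNoiseModel(duration=config.duration,
                                      fs=config.analysis_fs_hz, seed=config.seed)
        x, _, _ = synth.simulate_theta_noise(model)
        from .recording import MultichannelRecording

        rec = MultichannelRecording(data=x[:, None], fs=config.analysis_fs_hz,
                                    depths_um=[0.0])
        return rec, None
    x, truth = synth.simulate_directional_cfc(
        "gamma_leads", duration=config.duration, fs=config.analysis_fs_hz,
        seed=config.seed,
    )
    from .recording import MultichannelRecording

    rec = MultichannelRecording(data=x[:, None], fs=config.analysis_fs_hz,
                                depths_um=[0.0])
    return rec, truth


def default_laminar_specs(n_channels: int = 16):
    """Three generators with distinct depth loadings and gamma bands."""
    from .synth import GeneratorSpec

    depths = np.arange(n_channels)

    def bump(centre, width):
        return np.exp(-0.5 * ((depths - centre) / width) ** 2)

    return [
        GeneratorSpec(loading=bump(4, 1.5), theta_center=8.0, asymmetry=0.6,
                      gamma_band=(30.0, 60.0), preferred_phase=np.pi / 2,
                      phase_offset=0.0),
        GeneratorSpec(loading=-bump(8, 1.5), theta_center=8.0, asymmetry=0.8,
                      gamma_band=(60.0, 100.0), preferred_phase=np.pi,
                      phase_offset=0.8 * np.pi),
        GeneratorSpec(loading=bump(12, 1.5), theta_center=8.0, asymmetry=1.2,
                      gamma_band=(100.0, 150.0), preferred_phase=0.2,
                      phase_offset=1.1 * np.pi),
    ]


def _regress_icpc(rec, dec, ref_idx, table, series, truth):
    """Per-cycle ranked regression of the global ICPC on theta power/frequency
    (+ speed when the fixture provides it); cycles are the ICPC reference's
    valid cycles, matching the dynamic-ICPC series one to one."""
    from . import _dsp
    from .regression import ranked_regression

    valid = table.valid
    if valid.sum() < 50:
        return None
    th = _dsp.envelope(_dsp.bandpass(dec.series[ref_idx], rec.fs, 6, 10)) ** 2
    power = np.array([
        th[t0:t1].mean() for t0, t1 in zip(table.trough[valid], table.next_trough[valid])
    ])
    freq = rec.fs / (table.next_trough[valid] - table.trough[valid])
    y = series.global_icpc
    preds = {"power": power, "frequency": freq}
    if truth is not None and getattr(truth, "speed", None) is not None:
        preds["speed"] = truth.speed[table.trough[valid]]
    ok = np.isfinite(y)
    if ok.sum() < 10 * (len(preds) + 1):
        return None
    try:
        res = ranked_regression(y[ok], {k: v[ok] for k, v in preds.items()})
    except ValueError:
        return None
    return {
        "r_squared": res.r_squared,
        "betas": res.betas.tolist(),
        "partial_r2": res.partial_r2,
        "predictors": res.predictor_names,
    }
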