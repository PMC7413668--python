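"""Multichannel recording container, flat-binary + JSON sidecar I/O and the
preprocessing chain (low-pass 300 Hz, 50/100 Hz notches, decimation to
2.5 kHz then 625 Hz, per-signal z-normalization)."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import _dsp

ANALYSIS_FS = 625.0
INTERMEDIATE_FS = 2500.0


@dataclass
class MultichannelRecording:
    """Samples x channels matrix with sampling rate and per-channel depth."""

    data: np.ndarray
    fs: float
    depths_um: np.ndarray
    labels: list[str] = field(default_factory=list)
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim == 1:
            self.data = self.data[:, None]
        self.depths_um = np.asarray(self.depths_um, dtype=float)
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains NaN or Inf")
        if self.depths_um.size != self.data.shape[1]:
            raise ValueError("one depth per channel required")
        d = np.diff(self.depths_um)
        if d.size and not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("channel depths must be strictly monotone")
        if not self.labels:
            self.labels = [f"ch{m:02d}" for m in range(self.data.shape[1])]

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def log(self, step: str) -> None:
        self.provenance.append(step)


def write_recording(rec: MultichannelRecording, data_path, sidecar_path,
                    dtype: str = "float32") -> None:
    """Flat little-endian binary (row = sample, column = channel) + JSON sidecar."""
    np_dtype = {"float32": "<f4", "int16": "<i2"}[dtype]
    Path(data_path).write_bytes(np.ascontiguousarray(rec.data.astype(np_dtype)).tobytes())
    sidecar = {
        "dtype": dtype,
        "n_samples": rec.n_samples,
        "n_channels": rec.n_channels,
        "fs_hz": rec.fs,
        "depths_um": rec.depths_um.tolist(),
        "labels": list(rec.labels),
        "provenance": list(rec.provenance),
    }
    Path(sidecar_path).write_text(json.dumps(sidecar, indent=1))


def read_recording(data_path, sidecar_path) -> MultichannelRecording:
    sidecar = json.loads(Path(sidecar_path).read_text())
    for key in ("dtype", "n_samples", "n_channels", "fs_hz", "depths_um"):
        if key not in sidecar:
            raise ValueError(f"sidecar missing required key '{key}'")
    np_dtype = {"float32": "<f4", "int16": "<i2"}[sidecar["dtype"]]
    raw = Path(data_path).read_bytes()
    itemsize = np.dtype(np_dtype).itemsize
    expected = sidecar["n_samples"] * sidecar["n_channels"] * itemsize
    if len(raw) != expected:
        raise ValueError(
            f"data file has {len(raw)} bytes, sidecar declares {expected}"
        )
    data = np.frombuffer(raw, dtype=np_dtype).reshape(
        sidecar["n_samples"], sidecar["n_channels"]
    ).astype(float)
    return MultichannelRecording(
        data=data, fs=float(sidecar["fs_hz"]),
        depths_um=np.asarray(sidecar["depths_um"], dtype=float),
        labels=sidecar.get("labels", []),
        provenance=sidecar.get("provenance", []) + [f"read_recording({data_path})"],
    )


def read_edf(path) -> MultichannelRecording:
    """Minimal read-only EDF loader (continuous int16 records, uniform rate)."""
    raw = Path(path).read_bytes()
    hdr = raw[:256]
    n_records = int(hdr[236:244].decode().strip())
    record_dur = float(hdr[244:252].decode().strip())
    ns = int(hdr[252:256].decode().strip())
    sig = raw[256:256 + ns * 256]

    def fields(offset, width):
        base = ns * offset
        return [sig[base + i * width: base + (i + 1) * width].decode().strip()
                for i in range(ns)]

    labels = fields(0, 16)
    phys_min = np.array([float(v) for v in fields(16 + 80 + 8, 8)])
    phys_max = np.array([float(v) for v in fields(16 + 80 + 8 + 8, 8)])
    dig_min = np.array([float(v) for v in fields(16 + 80 + 8 + 16, 8)])
    dig_max = np.array([float(v) for v in fields(16 + 80 + 8 + 24, 8)])
    n_samp = np.array([int(v) for v in fields(16 + 80 + 8 + 32 + 80, 8)])
    if not np.all(n_samp == n_samp[0]):
        raise ValueError("per-signal sampling rates differ; not supported")
    fs = n_samp[0] / record_dur

    body = np.frombuffer(raw[256 + ns * 256:], dtype="<i2")
    body = body.reshape(n_records, ns, n_samp[0])
    gain = (phys_max - phys_min) / (dig_max - dig_min)
    data = (body - dig_min[None, :, None]) * gain[None, :, None] + phys_min[None, :, None]
    data = data.transpose(0, 2, 1).reshape(n_records * n_samp[0], ns)
    return MultichannelRecording(
        data=data, fs=fs, depths_um=np.arange(ns) * 100.0,
        labels=labels, provenance=[f"read_edf({path})"],
    )


def _decimate(rec: MultichannelRecording, target_fs: float) -> MultichannelRecording:
    factor = rec.fs / target_fs
    if abs(factor - round(factor)) > 1e-9:
        raise ValueError(
            f"non-integer decimation from {rec.fs} to {target_fs} Hz; "
            f"admissible input rates are integer multiples of {target_fs}"
        )
    factor = int(round(factor))
    if factor == 1:
        return rec
    data = _dsp.lowpass(rec.data, rec.fs, 0.4 * target_fs)[::factor]
    out = MultichannelRecording(
        data=data, fs=target_fs, depths_um=rec.depths_um,
        labels=list(rec.labels), provenance=list(rec.provenance),
    )
    out.log(f"decimate({rec.fs}->{target_fs} Hz, anti-alias 0.4*target)")
    return out


def preprocess(rec: MultichannelRecording, target_fs: float = ANALYSIS_FS,
               reapply_highpass: bool = False) -> MultichannelRecording:
    """Full preprocessing chain to the analysis rate with z-normalization.

    At rates >= 1250 Hz: low-pass 300 Hz, notch 50 and 100 Hz, decimate to
    2.5 kHz (if above it) and then to ``target_fs``. At the analysis rate
    only normalization is applied, so preprocessing is idempotent in rate.
    """
    out = MultichannelRecording(
        data=rec.data.copy(), fs=rec.fs, depths_um=rec.depths_um,
        labels=list(rec.labels), provenance=list(rec.provenance),
    )
    if reapply_highpass:
        out.data = _dsp.highpass(out.data, out.fs, 0.5)
        out.log("highpass(0.5 Hz)")
    if out.fs >= 2 * target_fs:
        if out.fs < 1250:
            raise ValueError("full preprocessing chain requires fs >= 1250 Hz")
        out.data = _dsp.lowpass(out.data, out.fs, 300.0)
        out.log("lowpass(300 Hz)")
        for f0 in (50.0, 100.0):
            out.data = _dsp.notch(out.data, out.fs, f0)
            out.log(f"notch({f0} Hz)")
        if out.fs > INTERMEDIATE_FS:
            out = _decimate(out, INTERMEDIATE_FS)
        out = _decimate(out, target_fs)
    elif out.fs != target_fs:
        raise ValueError(
            f"cannot reach {target_fs} Hz from {rec.fs} Hz with integer decimation"
        )
    mu = out.data.mean(axis=0)
    sd = out.data.std(axis=0)
    if np.any(sd == 0):
        raise ValueError("constant channel cannot be z-normalized")
    out.data = (out.data - mu) / sd
    out.log("znorm(per channel)")
    return out
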