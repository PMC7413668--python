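"""PCA-reduced ICA decomposition of multichannel recordings.

Retains the smallest principal-component count reaching the variance-keep
target, adds two extra components, and fits an ICA (minimized mutual
statistical dependence) on the reduced space. Components are gauge-fixed so
each series has unit variance and each loading's extremum is positive; the
rank-1 products V_n * s_n(t) are the physically scaled partial LFPs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.decomposition import PCA, FastICA

from .recording import MultichannelRecording


@dataclass
class ComponentDecomposition:
    mixing: np.ndarray  # channels x components (voltage loadings)
    series: np.ndarray  # components x samples
    mean: np.ndarray  # per-channel mean removed before fitting
    variance_share: np.ndarray  # fraction of total LFP variance per component
    n_pcs: int
    fs: float
    depths_um: np.ndarray
    algorithm: str = "fastica"
    seed: int = 0

    @property
    def n_components(self) -> int:
        return self.mixing.shape[1]

    @property
    def n_channels(self) -> int:
        return self.mixing.shape[0]


def _gauge_fix(V: np.ndarray, S: np.ndarray):
    """Unit-variance series, positive loading extremum; V*s invariant."""
    sd = S.std(axis=1)
    sd[sd == 0] = 1.0
    S = S / sd[:, None]
    V = V * sd[None, :]
    for n in range(V.shape[1]):
        if V[np.argmax(np.abs(V[:, n])), n] < 0:
            V[:, n] *= -1
            S[n] *= -1
    return V, S


_GAUSS_LOGCOSH = 0.37456722  # E[log cosh(nu)], nu ~ N(0, 1)


def fit_decomposition(
    rec: MultichannelRecording,
    variance_keep: float = 0.99,
    extra_components: int = 2,
    seed: int = 0,
    n_components: int | None = None,
    n_restarts: int = 5,
    warm_start: "ComponentDecomposition | None" = None,
) -> ComponentDecomposition:
    """Fit the PCA-reduced ICA and order components by variance share."""
    X = rec.data
    if X.shape[0] < 50 * X.shape[1]:
        import warnings

        warnings.warn("fewer than 50 samples per channel: decomposition unstable")
    mean = X.mean(axis=0)
    Xc = X - mean
    rank = np.linalg.matrix_rank(Xc)
    if rank < min(Xc.shape):
        raise ValueError(f"rank-deficient input: rank {rank} < {min(Xc.shape)} channels")
    # canonical-sign PCA whitening: the whitened scores are invariant under
    # channel permutation, which makes the whole fit exactly equivariant
    U, sv, Vt = np.linalg.svd(Xc, full_matrices=False)
    for i in range(Vt.shape[0]):
        if Vt[i, np.argmax(np.abs(Vt[i]))] < 0:
            Vt[i] *= -1
            U[:, i] *= -1
    if warm_start is not None:
        n_pcs = k = warm_start.n_components
    elif n_components is None:
        evr = sv**2 / (sv**2).sum()
        cum = np.cumsum(evr)
        n_pcs = int(np.searchsorted(cum, variance_keep) + 1)
        k = min(n_pcs + extra_components, rec.n_channels)
    else:
        n_pcs = k = int(n_components)
    Z = U[:, :k] * np.sqrt(Xc.shape[0])  # samples x k, unit variance
    if warm_start is not None:
        # start at the reference solution expressed in this data's whitened
        # basis, so the fit converges to the nearest ICA fixed point
        W_full = np.linalg.pinv(warm_start.mixing)  # k x channels
        D = sv[:k] / np.sqrt(Xc.shape[0])
        M = (D[:, None] * Vt[:k]) @ W_full.T  # k x k: Z @ M ~ warm sources
        ica = FastICA(whiten=False, w_init=M.T, max_iter=5000, tol=1e-7)
        S = ica.fit_transform(Z).T
    else:
        # FastICA has multiple fixed points on correlated sources: restart
        # from several seeded inits and keep the maximal-negentropy solution
        rng = np.random.default_rng(seed)
        best_S, best_J = None, -np.inf
        for _ in range(n_restarts):
            w_init = rng.standard_normal((k, k))
            ica = FastICA(whiten=False, w_init=w_init, max_iter=5000, tol=1e-7)
            S = ica.fit_transform(Z).T  # components x samples
            Sn = S / S.std(axis=1, keepdims=True)
            J = float(np.sum(
                (np.mean(np.log(np.cosh(Sn)), axis=1) - _GAUSS_LOGCOSH) ** 2
            ))
            if J > best_J:
                best_S, best_J = S, J
        S = best_S
    # channel-space loadings of the unit-variance sources
    V = np.linalg.lstsq(S.T, Xc, rcond=None)[0].T
    V, S = _gauge_fix(V, S)
    total_var = Xc.var(axis=0).sum()
    shares = np.array([
        np.var(np.outer(S[n], V[:, n]), axis=0).sum() / total_var
        for n in range(k)
    ])
    order = np.argsort(shares)[::-1]
    return ComponentDecomposition(
        mixing=V[:, order], series=S[order], mean=mean,
        variance_share=shares[order], n_pcs=n_pcs, fs=rec.fs,
        depths_um=rec.depths_um, seed=seed,
    )


def _cosine_matrix(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    An = A / np.linalg.norm(A, axis=0, keepdims=True)
    Bn = B / np.linalg.norm(B, axis=0, keepdims=True)
    return An.T @ Bn


def match_components(decA: ComponentDecomposition, decB: ComponentDecomposition):
    """Greedy loading match maximizing |cosine similarity|.

    Returns ``(permutation, signs, similarities)``: component j of ``decB``
    matched to component ``permutation[j]`` of ``decA``; ``signs[j]`` makes
    the matched similarity positive; ``similarities[j] = |cos|``.
    """
    if decA.n_channels != decB.n_channels:
        raise ValueError("channel counts differ")
    C = _cosine_matrix(decA.mixing, decB.mixing)
    absC = np.abs(C.copy())
    perm = np.full(decB.n_components, -1)
    signs = np.ones(decB.n_components)
    sims = np.zeros(decB.n_components)
    for _ in range(min(decA.n_components, decB.n_components)):
        i, j = np.unravel_index(np.argmax(absC), absC.shape)
        perm[j] = i
        sims[j] = absC[i, j]
        signs[j] = 1.0 if C[i, j] >= 0 else -1.0
        absC[i, :] = -1
        absC[:, j] = -1
    return perm, signs, sims


def select_components(
    dec: ComponentDecomposition,
    rec: MultichannelRecording,
    epochs: list[tuple[int, int]],
    min_variance: float = 0.01,
    stability_threshold: float = 0.8,
    seed: int = 0,
):
    """Keep components with variance share > ``min_variance`` and stable
    loadings across per-epoch refits.

    Stability of a component = minimum over epoch pairs of |cosine
    similarity| between the loadings matched to it in each epoch's
    decomposition. Epochs must be non-overlapping, each at least 10 s.
    """
    if len(epochs) < 2:
        raise ValueError("need at least 2 epochs")
    epochs = sorted(epochs)
    for (a0, a1), (b0, b1) in zip(epochs, epochs[1:]):
        if b0 < a1:
            raise ValueError("epochs overlap")
    for e0, e1 in epochs:
        if (e1 - e0) / rec.fs < 10:
            raise ValueError("each epoch must be at least 10 s")

    k = dec.n_components
    epoch_loadings = []  # per epoch: loadings matched to dec's components
    for e0, e1 in epochs:
        sub = MultichannelRecording(
            data=rec.data[e0:e1], fs=rec.fs, depths_um=rec.depths_um,
            labels=list(rec.labels),
        )
        sub_dec = fit_decomposition(sub, seed=seed, warm_start=dec)
        perm, signs, _ = match_components(dec, sub_dec)
        matched = np.full((dec.n_channels, k), np.nan)
        for j in range(sub_dec.n_components):
            if perm[j] >= 0:
                matched[:, perm[j]] = signs[j] * sub_dec.mixing[:, j]
        epoch_loadings.append(matched)

    stability = np.ones(k)
    for n in range(k):
        sims = []
        for a in range(len(epochs)):
            for b in range(a + 1, len(epochs)):
                la, lb = epoch_loadings[a][:, n], epoch_loadings[b][:, n]
                if np.any(np.isnan(la)) or np.any(np.isnan(lb)):
                    sims.append(0.0)
                    continue
                sims.append(abs(float(
                    la @ lb / (np.linalg.norm(la) * np.linalg.norm(lb))
                )))
        stability[n] = min(sims) if sims else 0.0

    selected = np.nonzero(
        (dec.variance_share > min_variance) & (stability >= stability_threshold)
    )[0]
    return selected, stability


def reconstruct_partial_lfp(dec: ComponentDecomposition, component: int) -> MultichannelRecording:
    """Rank-1 partial LFP V_n * s_n(t), gauge-invariant polarity/amplitude."""
    if not 0 <= component < dec.n_components:
        raise ValueError(f"component {component} out of range")
    data = np.outer(dec.series[component], dec.mixing[:, component])
    return MultichannelRecording(
        data=data, fs=dec.fs, depths_um=dec.depths_um,
        provenance=[f"partial_lfp(component={component})"],
    )


def reconstruct_lfp(dec: ComponentDecomposition) -> MultichannelRecording:
    """Sum of all partial LFPs plus the removed mean."""
    data = dec.series.T @ dec.mixing.T + dec.mean
    return MultichannelRecording(
        data=data, fs=dec.fs, depths_um=dec.depths_um,
        provenance=["reconstruct_lfp(all components)"],
    )


def validate_band_split(rec: MultichannelRecording, cut: float = 30.0, seed: int = 0):
    """Refit on <cut and >cut filtered copies; report loading similarities."""
    from . import _dsp

    full = fit_decomposition(rec, seed=seed)
    report = {}
    for name, data in (
        ("low", _dsp.lowpass(rec.data, rec.fs, cut)),
        ("high", _dsp.highpass(rec.data, rec.fs, cut)),
    ):
        sub = MultichannelRecording(data=data, fs=rec.fs, depths_um=rec.depths_um)
        sub_dec = fit_decomposition(sub, seed=seed, n_components=full.n_components)
        perm, _, sims = match_components(full, sub_dec)
        report[name] = {
            "permutation": perm,
            "similarity": sims,
            "flagged": bool(np.any(sims < 0.9)),
        }
    return full, report


def write_decomposition(dec: ComponentDecomposition, outdir) -> None:
    """Loadings as delimited text, series as flat binary + sidecar, metadata JSON."""
    import json

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    np.savetxt(outdir / "loadings.tsv", dec.mixing, delimiter="\t")
    (outdir / "series.f32").write_bytes(dec.series.T.astype("<f4").tobytes())
    (outdir / "meta.json").write_text(json.dumps({
        "variance_share": dec.variance_share.tolist(),
        "n_pcs": dec.n_pcs,
        "fs_hz": dec.fs,
        "algorithm": dec.algorithm,
        "seed": dec.seed,
        "mean": dec.mean.tolist(),
        "depths_um": dec.depths_um.tolist(),
        "n_components": dec.n_components,
    }, indent=1))
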