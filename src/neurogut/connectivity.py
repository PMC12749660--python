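"""Functional connectivity: coherency, imaginary coherence, and weighted network metrics.

Coherency between channels i and j at frequency f is the normalized
cross-spectrum ``C_ij(f) = S_ij(f) / sqrt(S_ii(f) S_jj(f))``.  Its imaginary
part vanishes for zero-lag (volume-conducted) mixing, so the band-averaged
magnitude of the imaginary part (iCOH) isolates genuinely lagged coupling.
Cross-spectra are estimated with Welch's method (1-s Hann windows, 50%
segment shift in the reference analysis), and the per-band symmetric iCOH
matrix is read as a weighted undirected graph from which global efficiency,
local efficiency and transitivity are derived.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import signal
from scipy.sparse.csgraph import shortest_path

from .preprocess import BandSpec, EEGRecording, get_band

__all__ = [
    "CrossSpectra",
    "ICOHMatrix",
    "NetworkMetrics",
    "welch_cross_spectra",
    "icoh",
    "pairs_count",
    "global_efficiency",
    "local_efficiency",
    "transitivity",
    "network_metrics",
]


@dataclass
class CrossSpectra:
    """Channel x channel x frequency cross-spectral density matrix (Hermitian per bin)."""

    S: np.ndarray
    freqs: np.ndarray
    labels: Sequence[str]
    window_len: float
    overlap: float
    n_segments: int

    def __post_init__(self) -> None:
        if self.S.ndim != 3 or self.S.shape[0] != self.S.shape[1]:
            raise ValueError("S must be (n_channels, n_channels, n_freqs)")
        if self.S.shape[2] != len(self.freqs):
            raise ValueError("frequency axis mismatch")


@dataclass
class ICOHMatrix:
    """Symmetric band-averaged |Im(coherency)| matrix with zero diagonal."""

    W: np.ndarray
    band: BandSpec
    labels: Sequence[str]

    def __post_init__(self) -> None:
        W = np.asarray(self.W, dtype=float)
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise ValueError("W must be square")
        if not np.allclose(W, W.T, atol=1e-12):
            raise ValueError("W must be symmetric")
        if W.min() < -1e-12 or W.max() > 1 + 1e-9:
            raise ValueError("iCOH weights must lie in [0, 1]")
        self.W = W


@dataclass
class NetworkMetrics:
    """Weighted-graph summary of a connectivity matrix."""

    GE: float
    LE: np.ndarray
    T: float
    band: "BandSpec | None" = None
    labels: Sequence[str] = ()


# ---------------------------------------------------------------------------
# Spectral estimation
# ---------------------------------------------------------------------------

def welch_cross_spectra(
    rec: EEGRecording,
    window_len: float = 1.0,
    overlap: float = 0.5,
) -> CrossSpectra:
    """Welch cross-spectral densities for all channel pairs.

    Each segment is linearly detrended, Hann-tapered and Fourier transformed;
    ``S_ij(f)`` is the segment average of ``X_i(f) conj(X_j(f))`` with
    one-sided density scaling (matches ``scipy.signal.csd`` with
    ``detrend='linear'``).
    """
    if not 0 <= overlap < 1:
        raise ValueError("overlap must be in [0, 1)")
    nper = int(round(window_len * rec.fs))
    if rec.n_samples < 2 * nper:
        raise ValueError(
            f"recording of {rec.duration:.2f} s is shorter than two {window_len} s windows"
        )
    step = int(round(nper * (1 - overlap)))
    starts = np.arange(0, rec.n_samples - nper + 1, step)
    # (n_seg, n_ch, nper) segment stack
    segs = np.stack([rec.data[:, s : s + nper] for s in starts], axis=0)
    segs = signal.detrend(segs, axis=-1, type="linear")
    win = signal.get_window("hann", nper)
    X = np.fft.rfft(segs * win, axis=-1)  # (n_seg, n_ch, n_freq)
    # cross products averaged over segments: (ch_i, ch_j, freq)
    S = np.einsum("sif,sjf->ijf", X, np.conj(X)) / len(starts)
    scale = 1.0 / (rec.fs * (win**2).sum())
    S = S * scale
    S[..., 1:] *= 2.0  # one-sided density
    if nper % 2 == 0:
        S[..., -1] /= 2.0  # Nyquist bin is not doubled
    freqs = np.fft.rfftfreq(nper, 1.0 / rec.fs)
    return CrossSpectra(S, freqs, rec.labels, window_len, overlap, len(starts))


def icoh(cs: CrossSpectra, band: "str | BandSpec") -> ICOHMatrix:
    """Band-averaged imaginary coherence matrix.

    ``W[i, j]`` is the arithmetic mean over in-band frequency bins of
    ``|Im(C_ij(f))|``; the diagonal is zeroed.
    """
    band = get_band(band)
    sel = (cs.freqs >= band.lo) & (cs.freqs <= band.hi)
    if not sel.any():
        raise ValueError(f"band {band.name!r} contains no frequency bins")
    S = cs.S[:, :, sel]
    auto = np.real(np.einsum("iif->if", S))
    bad = np.flatnonzero((auto <= 0).any(axis=1))
    if bad.size:
        names = [cs.labels[i] for i in bad]
        raise ValueError(f"zero autospectrum in band {band.name!r} for channel(s) {names}")
    denom = np.sqrt(auto[:, None, :] * auto[None, :, :])
    C = S / denom
    W = np.abs(np.imag(C)).mean(axis=-1)
    W = 0.5 * (W + W.T)  # symmetrize against float asymmetry
    np.fill_diagonal(W, 0.0)
    W = np.clip(W, 0.0, 1.0)
    return ICOHMatrix(W, band, cs.labels)


def pairs_count(n_channels: int) -> int:
    """Number of unordered electrode pairs, n(n-1)/2 (210 for a 21-channel montage)."""
    if n_channels < 2:
        raise ValueError("need at least 2 channels")
    return n_channels * (n_channels - 1) // 2


# ---------------------------------------------------------------------------
# Weighted graph metrics
# ---------------------------------------------------------------------------

def _as_weight_matrix(W: "ICOHMatrix | np.ndarray") -> np.ndarray:
    if isinstance(W, ICOHMatrix):
        W = W.W
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError("weight matrix must be square")
    if (W < 0).any():
        raise ValueError("weights must be nonnegative")
    if not np.allclose(W, W.T, atol=1e-9):
        raise ValueError("weight matrix must be symmetric")
    W = W.copy()
    np.fill_diagonal(W, 0.0)
    return W


def global_efficiency(W: "ICOHMatrix | np.ndarray") -> float:
    """Weighted global efficiency: mean inverse shortest-path length.

    Edge length is the reciprocal of the weight; unreachable pairs contribute
    zero efficiency.  An empty or single-node graph has efficiency 0.
    """
    W = _as_weight_matrix(W)
    n = W.shape[0]
    if n < 2:
        return 0.0
    with np.errstate(divide="ignore"):
        lengths = np.where(W > 0, 1.0 / np.where(W > 0, W, 1.0), np.inf)
    d = shortest_path(lengths, method="D", directed=False)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    np.fill_diagonal(inv, 0.0)
    inv[~np.isfinite(inv)] = 0.0
    return float(inv.sum() / (n * (n - 1)))


def local_efficiency(W: "ICOHMatrix | np.ndarray") -> np.ndarray:
    """Per-node local efficiency: global efficiency of each node's neighbor subgraph.

    Nodes with fewer than two neighbors score 0.
    """
    W = _as_weight_matrix(W)
    n = W.shape[0]
    le = np.zeros(n)
    for i in range(n):
        nb = np.flatnonzero(W[i] > 0)
        if nb.size < 2:
            continue
        le[i] = global_efficiency(W[np.ix_(nb, nb)])
    return le


def transitivity(W: "ICOHMatrix | np.ndarray") -> float:
    """Weighted transitivity: geometric-mean triangle intensity over connected triples.

    ``T = trace((W^(1/3))^3) / sum_i k_i (k_i - 1)`` with ``k_i`` the count of
    nonzero weights at node i; 0 when no node has two neighbors.
    """
    W = _as_weight_matrix(W)
    k = (W > 0).sum(axis=1)
    denom = float((k * (k - 1)).sum())
    if denom == 0:
        return 0.0
    W13 = np.cbrt(W)
    num = float(np.trace(W13 @ W13 @ W13))
    return num / denom


def network_metrics(W: ICOHMatrix) -> NetworkMetrics:
    """Bundle GE, per-node LE and T for one band's iCOH matrix."""
    return NetworkMetrics(
        GE=global_efficiency(W),
        LE=local_efficiency(W),
        T=transitivity(W),
        band=W.band,
        labels=W.labels,
    )
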