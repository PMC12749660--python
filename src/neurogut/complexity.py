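"""Nonlinear per-channel signal metrics: Katz FD, QSE, quantile-graph and visibility-graph complexity.

All four metrics are computed on fixed-length epochs (8 s at 200 Hz = 1600
samples in the reference analysis) and averaged across epochs per channel and
band:

* **Katz fractal dimension** — waveform curve length vs. maximal excursion in
  the (sample index, amplitude) plane with unit abscissa steps; a straight
  line scores exactly 1.
* **Quadratic sample entropy (QSE)** — sample entropy SampEn(m, r·SD) plus
  ``ln(2 r SD)``, which removes the tolerance dependence so values are
  comparable across tolerance choices (Richman & Moorman).
* **Quantile-graph mean jump** — the signal is mapped to Q amplitude
  quantiles; transitions between consecutive samples form a weighted directed
  graph whose occupancy-weighted expected hop distance summarizes amplitude
  mobility.
* **Visibility-graph GIC** — natural visibility graph of the epoch; the graph
  index complexity maps the largest adjacency eigenvalue onto [0, 1]
  (0 for the path graph of a monotone ramp).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.linalg import eigsh

from .preprocess import BandedEpochs

__all__ = [
    "ComplexityParams",
    "ZeroVarianceError",
    "katz_fd",
    "sampen",
    "qse",
    "QuantileGraph",
    "quantile_graph",
    "mean_jump",
    "visibility_graph",
    "gic",
    "complexity_profile",
    "COMPLEXITY_METRICS",
]

COMPLEXITY_METRICS = ("FD", "QSE", "QG", "VG")


class ZeroVarianceError(ValueError):
    """Raised when an epoch has no amplitude variance and the metric is undefined."""


@dataclass(frozen=True)
class ComplexityParams:
    """Tunable parameters of the nonlinear metrics.

    ``m`` and ``r`` follow standard sample-entropy practice (m=2, r=0.2 of the
    epoch SD); ``Q`` is the quantile count of the quantile graph.
    """

    m: int = 2
    r: float = 0.2
    Q: int = 8
    vg_kind: str = "natural"

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if not self.r > 0:
            raise ValueError("r must be positive")
        if self.Q < 2:
            raise ValueError("Q must be >= 2")
        if self.vg_kind != "natural":
            raise ValueError("only the natural visibility graph is supported")


# ---------------------------------------------------------------------------
# Katz fractal dimension
# ---------------------------------------------------------------------------

def katz_fd(x: np.ndarray) -> float:
    """Katz fractal dimension of a waveform.

    With unit abscissa spacing, ``L`` is the Euclidean curve length summed
    over successive samples, ``d`` the maximal Euclidean distance from the
    first point, and ``n`` the number of steps:
    ``FD = log10(n) / (log10(n) + log10(d / L))``.
    A straight line has d = L and hence FD = 1; degenerate signals
    (constant, or a single step) also score 1 by convention.
    """
    x = np.asarray(x, dtype=float).ravel()
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    dx = np.diff(x)
    L = float(np.sqrt(1.0 + dx**2).sum())
    k = np.arange(1, x.size)
    d = float(np.sqrt(k**2 + (x[1:] - x[0]) ** 2).max())
    n = x.size - 1
    if d == 0.0 or L == 0.0 or n == 1:
        return 1.0
    denom = np.log10(n) + np.log10(d / L)
    if denom == 0.0:
        return 1.0
    return float(np.log10(n) / denom)


# ---------------------------------------------------------------------------
# Quadratic sample entropy
# ---------------------------------------------------------------------------

def sampen(x: np.ndarray, m: int = 2, r_abs: "float | None" = None, r: float = 0.2) -> float:
    """Sample entropy with Chebyshev distance and self-matches excluded.

    Template vectors of lengths ``m`` and ``m+1`` are both drawn from the
    first ``N - m`` positions (Richman & Moorman convention) and a pair
    matches when the Chebyshev distance is <= the tolerance.  Returns NaN
    when no template pair matches at either length.
    """
    x = np.asarray(x, dtype=float).ravel()
    N = x.size
    if N <= m + 1:
        raise ValueError(f"need more than m+1={m + 1} samples, got {N}")
    if r_abs is None:
        sd = x.std()
        if sd == 0:
            raise ZeroVarianceError("zero-variance epoch: sample entropy undefined")
        r_abs = r * sd
    T = N - m
    close = np.abs(x[:, None] - x[None, :]) <= r_abs
    match = close[:T, :T].copy()
    for k in range(1, m):
        match &= close[k : T + k, k : T + k]
    B = int(match.sum()) - T  # ordered pairs, self-matches removed
    match &= close[m : T + m, m : T + m]
    A = int(match.sum()) - T
    if A <= 0 or B <= 0:
        return float("nan")
    return float(-np.log(A / B))


def qse(x: np.ndarray, params: ComplexityParams = ComplexityParams()) -> float:
    """Quadratic sample entropy: SampEn(m, r*SD) + ln(2 r SD), in nats.

    The offset uses the absolute tolerance (r times the epoch SD), so QSE is
    expressed in nats of the signal's amplitude units.  Zero-variance epochs
    raise :class:`ZeroVarianceError`; epochs with no template matches return
    NaN and are excluded from epoch averages upstream.
    """
    x = np.asarray(x, dtype=float).ravel()
    sd = x.std()
    if sd == 0:
        raise ZeroVarianceError("zero-variance epoch: QSE undefined")
    r_abs = params.r * sd
    se = sampen(x, m=params.m, r_abs=r_abs)
    if np.isnan(se):
        return float("nan")
    return float(se + np.log(2.0 * r_abs))


# ---------------------------------------------------------------------------
# Quantile graph
# ---------------------------------------------------------------------------

@dataclass
class QuantileGraph:
    """Weighted directed transition graph over amplitude quantiles.

    ``counts[a, b]`` is the number of consecutive-sample transitions from
    quantile a to quantile b; ``W`` row-normalizes occupied rows to transition
    probabilities; ``occupancy`` is the source-sample occupancy distribution.
    """

    counts: np.ndarray
    W: np.ndarray
    occupancy: np.ndarray
    labels: np.ndarray  # per-sample quantile index


def quantile_graph(x: np.ndarray, Q: int = 8) -> QuantileGraph:
    """Map a series onto its Q empirical amplitude quantiles and count transitions.

    Quantile boundaries are the empirical k/Q quantiles; a sample equal to a
    boundary is assigned to the lower quantile.
    """
    x = np.asarray(x, dtype=float).ravel()
    if x.size < Q:
        raise ValueError(f"series of {x.size} samples is shorter than Q={Q}")
    if np.unique(x).size < Q:
        raise ValueError(
            f"only {np.unique(x).size} distinct values for Q={Q}; use a smaller Q"
        )
    bounds = np.quantile(x, np.arange(1, Q) / Q)
    labels = np.searchsorted(bounds, x, side="left")
    src, dst = labels[:-1], labels[1:]
    counts = np.zeros((Q, Q))
    np.add.at(counts, (src, dst), 1.0)
    row = counts.sum(axis=1)
    W = np.divide(counts, row[:, None], out=np.zeros_like(counts), where=row[:, None] > 0)
    occupancy = row / row.sum()
    return QuantileGraph(counts=counts, W=W, occupancy=occupancy, labels=labels)


def mean_jump(g: QuantileGraph) -> float:
    """Occupancy-weighted expected hop distance: sum_ab pi_a W_ab |a - b|."""
    Q = g.W.shape[0]
    dist = np.abs(np.arange(Q)[:, None] - np.arange(Q)[None, :])
    return float((g.occupancy[:, None] * g.W * dist).sum())


# ---------------------------------------------------------------------------
# Visibility graph
# ---------------------------------------------------------------------------

def visibility_graph(x: np.ndarray) -> np.ndarray:
    """Natural-visibility adjacency matrix (boolean, symmetric).

    Samples a < b are connected iff every intermediate sample lies strictly
    below the straight line joining them; equivalently, iff the slope from a
    to b strictly exceeds the running maximum of the slopes from a to all
    intermediate points.  Collinear points block visibility (strict
    criterion), so a monotone ramp yields exactly the path graph.
    """
    x = np.asarray(x, dtype=float).ravel()
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 samples")
    adj = np.zeros((n, n), dtype=bool)
    # absolute margin so float jitter in collinear runs cannot fake strict dominance
    tol = 1e-9 * max(1.0, float(np.abs(x).max()))
    for a in range(n - 1):
        slopes = (x[a + 1 :] - x[a]) / np.arange(1, n - a)
        vis = np.empty(slopes.size, dtype=bool)
        vis[0] = True  # adjacent samples always see each other
        if slopes.size > 1:
            cm = np.maximum.accumulate(slopes[:-1])
            vis[1:] = slopes[1:] > cm + tol
        adj[a, a + 1 :] = vis
    return adj | adj.T


def gic(adj: np.ndarray) -> float:
    """Graph index complexity of an adjacency matrix.

    ``c = (lambda_max - 2 cos(pi/(n+1))) / (n - 1 - 2 cos(pi/(n+1)))`` maps
    the largest adjacency eigenvalue from the path graph (c = 0) to the
    complete graph (c = 1); GIC = 4 c (1 - c) in [0, 1].
    """
    adj = np.asarray(adj)
    n = adj.shape[0]
    if adj.ndim != 2 or adj.shape[1] != n or n < 2:
        raise ValueError("adjacency must be square with n >= 2")
    A = adj.astype(float)
    if n <= 64:
        lam = float(np.linalg.eigvalsh(A)[-1])
    else:
        # fixed start vector keeps the Lanczos iteration deterministic
        v0 = np.full(n, 1.0 / np.sqrt(n))
        lam = float(eigsh(csr_matrix(A), k=1, which="LA", v0=v0,
                          return_eigenvectors=False)[0])
    ref = 2.0 * np.cos(np.pi / (n + 1))
    c = (lam - ref) / (n - 1 - ref)
    c = min(max(c, 0.0), 1.0)  # guard float undershoot at the path-graph limit
    return float(4.0 * c * (1.0 - c))


# ---------------------------------------------------------------------------
# Epoch-averaged profile
# ---------------------------------------------------------------------------

def _epoch_metrics(x: np.ndarray, params: ComplexityParams) -> dict:
    out = {"FD": katz_fd(x)}
    try:
        out["QSE"] = qse(x, params)
    except ZeroVarianceError:
        out["QSE"] = float("nan")
    try:
        g = quantile_graph(x, params.Q)
        out["QG"] = mean_jump(g)
    except ValueError:
        out["QG"] = float("nan")
    out["VG"] = gic(visibility_graph(x))
    return out


def complexity_profile(ep: BandedEpochs, params: ComplexityParams = ComplexityParams()) -> pd.DataFrame:
    """Epoch-averaged complexity metrics per channel and band.

    Returns a tidy frame with columns ``band, channel, metric, value,
    n_epochs_used``.  Epochs flagged NaN for a metric (zero variance, no
    entropy matches, degenerate quantile split) are excluded from that
    metric's average only.
    """
    if ep.n_epochs < 1:
        raise ValueError("no epochs to analyze")
    rows = []
    for bi, band in enumerate(ep.bands):
        for ci, ch in enumerate(ep.labels):
            per_epoch = {m: [] for m in COMPLEXITY_METRICS}
            for ei in range(ep.n_epochs):
                vals = _epoch_metrics(ep.tensor[bi, ei, ci], params)
                for m in COMPLEXITY_METRICS:
                    per_epoch[m].append(vals[m])
            for m in COMPLEXITY_METRICS:
                arr = np.asarray(per_epoch[m])
                ok = np.isfinite(arr)
                if not ok.any():
                    raise ValueError(
                        f"no valid epochs for metric {m} (band {band.name}, channel {ch})"
                    )
                rows.append(
                    {
                        "band": band.name,
                        "channel": ch,
                        "metric": m,
                        "value": float(arr[ok].mean()),
                        "n_epochs_used": int(ok.sum()),
                    }
                )
    return pd.DataFrame(rows)
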