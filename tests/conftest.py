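import numpy as np
import pytest

import neurogut as ng


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def noise_recording(rng):
    """60 s of 3-channel white noise at 500 Hz."""
    return ng.EEGRecording(rng.standard_normal((3, 30000)), 500.0, ["C3", "C4", "Cz"])


def brute_visibility(x):
    """O(n^3) natural-visibility oracle with the strict line-of-sight criterion."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    adj = np.zeros((n, n), dtype=bool)
    for a in range(n):
        for b in range(a + 1, n):
            visible = True
            for c in range(a + 1, b):
                if not x[c] < x[b] + (x[a] - x[b]) * (b - c) / (b - a):
                    visible = False
                    break
            if visible:
                adj[a, b] = adj[b, a] = True
    return adj


def brute_global_efficiency(W):
    """Floyd-Warshall mean inverse shortest-path oracle (edge length = 1/weight)."""
    W = np.asarray(W, dtype=float)
    n = W.shape[0]
    if n < 2:
        return 0.0
    L = np.where(W > 0, 1.0 / np.where(W > 0, W, 1.0), np.inf)
    np.fill_diagonal(L, 0.0)
    D = L.copy()
    for k in range(n):
        D = np.minimum(D, D[:, k, None] + D[None, k, :])
    inv = np.where((D > 0) & np.isfinite(D), 1.0 / np.where(D > 0, D, 1.0), 0.0)
    np.fill_diagonal(inv, 0.0)
    return inv.sum() / (n * (n - 1))


def brute_sampen(x, m, r_abs):
    """Quadratic-time template-matching sample-entropy oracle."""
    x = np.asarray(x, dtype=float)
    N = len(x)
    T = N - m
    A = B = 0
    for i in range(T):
        for j in range(T):
            if i == j:
                continue
            if max(abs(x[i + k] - x[j + k]) for k in range(m)) <= r_abs:
                B += 1
            if max(abs(x[i + k] - x[j + k]) for k in range(m + 1)) <= r_abs:
                A += 1
    if A == 0 or B == 0:
        return float("nan")
    return -np.log(A / B)


def random_weighted_graph(rng, max_nodes=8, density=0.6):
    n = int(rng.integers(3, max_nodes + 1))
    W = rng.random((n, n))
    W = 0.5 * (W + W.T)
    W[W < (1 - density)] = 0.0
    np.fill_diagonal(W, 0.0)
    return W
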