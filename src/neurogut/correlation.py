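"""Gut-brain correlation screen: Kendall tau over per-subject pre-post deltas.

Per-subject differences (post - pre) of every nonlinear EEG feature are
correlated with the per-subject relative-abundance shifts of every microbial
taxon.  Kendall's tau-b (tie-corrected — taxa deltas contain ties at zero)
is used as the primary association measure; p-values are exact by
enumeration of all n! orderings for n <= 9 and use the normal approximation
otherwise, so at small cohort sizes the reported p can never drop below the
attainable permutation floor.  The full feature x taxon grid is BH-corrected
as one family, and pairs with uncorrected Kendall p < 0.001 receive a
Spearman follow-up.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd
from scipy.stats import kendalltau as _scipy_kendalltau, spearmanr as _spearmanr

from .stats import bh_fdr

__all__ = ["kendall_tau", "correlation_screen", "build_delta_matrix", "SPEARMAN_P_CUTOFF"]

SPEARMAN_P_CUTOFF = 1e-3
EXACT_MAX_N = 9


def _pair_signs(v: np.ndarray) -> np.ndarray:
    return np.sign(v[:, None] - v[None, :])


def _exact_perm_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact permutation p for tau-b by full n! enumeration.

    Tie corrections in the tau-b denominator are permutation-invariant, so
    comparing the concordance numerator |S| suffices.
    """
    n = x.size
    sx = _pair_signs(x)
    sy = _pair_signs(y)
    iu, ju = np.triu_indices(n, 1)
    s_obs = float((sx[iu, ju] * sy[iu, ju]).sum())
    perms = np.array(list(itertools.permutations(range(n))))
    # S under each permutation of y
    s_perm = np.zeros(len(perms))
    for i, j in zip(iu, ju):
        s_perm += sx[i, j] * sy[perms[:, i], perms[:, j]]
    return float(np.mean(np.abs(s_perm) >= abs(s_obs) - 1e-9))


def kendall_tau(x: np.ndarray, y: np.ndarray) -> tuple:
    """Kendall tau-b and its two-sided p-value.

    Exact permutation enumeration for n <= 9 (valid under ties), normal
    approximation above.  Constant inputs are rejected.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 4:
        raise ValueError("need at least 4 observations")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise ValueError("zero variance: a constant vector has no rank correlation")
    tau = float(_scipy_kendalltau(x, y, variant="b", method="asymptotic").statistic)
    if x.size <= EXACT_MAX_N:
        p = _exact_perm_p(x, y)
    else:
        p = float(_scipy_kendalltau(x, y, variant="b", method="asymptotic").pvalue)
    return tau, min(1.0, max(p, 2.0 / math.factorial(x.size)))


def build_delta_matrix(pre: pd.DataFrame, post: pd.DataFrame) -> pd.DataFrame:
    """Subjects x features matrix of post - pre differences.

    Inputs are subject-indexed wide frames; subjects present in only one
    condition are dropped.
    """
    common = pre.index.intersection(post.index)
    if common.empty:
        raise ValueError("no subject appears in both conditions")
    return post.loc[common] - pre.loc[common]


def correlation_screen(
    eeg_deltas: pd.DataFrame,
    taxa_deltas: pd.DataFrame,
    min_pairs: int = 5,
    spearman_cutoff: float = SPEARMAN_P_CUTOFF,
) -> pd.DataFrame:
    """All-pairs Kendall screen between EEG feature deltas and taxa shifts.

    Both inputs are subject-indexed wide frames (one column per feature /
    taxon).  For each pair, subjects with a missing value in either column
    are dropped listwise; pairs with fewer than ``min_pairs`` complete
    subjects, or a constant vector, are reported untested (NaN, excluded
    from the BH family).  The output carries one row per grid cell, BH
    q-values over the tested family, Spearman follow-ups for raw Kendall
    p < ``spearman_cutoff``, and is sorted by q.
    """
    if eeg_deltas.shape[1] == 0 or taxa_deltas.shape[1] == 0:
        raise ValueError("empty correlation grid")
    subjects = eeg_deltas.index.intersection(taxa_deltas.index)
    rows = []
    for feat in eeg_deltas.columns:
        for taxon in taxa_deltas.columns:
            x = eeg_deltas.loc[subjects, feat].to_numpy(dtype=float)
            y = taxa_deltas.loc[subjects, taxon].to_numpy(dtype=float)
            ok = np.isfinite(x) & np.isfinite(y)
            row = dict(feature=feat, taxon=taxon, n=int(ok.sum()),
                       tau=np.nan, p=np.nan)
            if ok.sum() >= min_pairs:
                try:
                    row["tau"], row["p"] = kendall_tau(x[ok], y[ok])
                except ValueError:
                    pass  # constant vector: untested
            rows.append(row)
    table = pd.DataFrame(rows)
    table["q"] = np.nan
    tested = table.index[table["p"].notna()]
    if len(tested):
        table.loc[tested, "q"] = bh_fdr(table.loc[tested, "p"].to_numpy())
    table["family_size"] = len(tested)
    table["spearman_rho"] = np.nan
    table["spearman_p"] = np.nan
    follow = table.index[table["p"] < spearman_cutoff]
    for i in follow:
        feat, taxon = table.loc[i, "feature"], table.loc[i, "taxon"]
        x = eeg_deltas.loc[subjects, feat].to_numpy(dtype=float)
        y = taxa_deltas.loc[subjects, taxon].to_numpy(dtype=float)
        ok = np.isfinite(x) & np.isfinite(y)
        rho, p_rho = _spearmanr(x[ok], y[ok])
        table.loc[i, "spearman_rho"] = float(rho)
        table.loc[i, "spearman_p"] = float(p_rho)
    return table.sort_values(["q", "p"], na_position="last").reset_index(drop=True)
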