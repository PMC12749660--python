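"""Paired pre/post inference: Wilcoxon signed-rank tests with BH false-discovery control.

Every EEG feature (per-electrode complexity value, per-pair iCOH, per-node
LE, global GE/T) is compared pre vs. post with the Wilcoxon signed-rank
test.  The sign convention follows the study's reporting: the statistic is
computed on d = pre - post, so an increase after the intervention carries a
*negative* z.  P-values are exact (full 2^n sign enumeration) for n <= 12
and use the tie-corrected normal approximation (no continuity correction)
otherwise.  Benjamini-Hochberg correction is applied within each
(metric, band) family of the four nonlinear metrics, with significance read
at q < 0.10; iCOH pair tests and the global network metrics are reported
with raw p-values only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from statsmodels.stats.multitest import multipletests

__all__ = [
    "WilcoxonResult",
    "wilcoxon_signed_rank",
    "bh_fdr",
    "run_paired_analysis",
    "zmap_export",
    "FDR_METRICS",
    "ALPHA_RAW",
    "Q_THRESHOLD",
]

#: Families receiving BH correction (one family per metric x band).
FDR_METRICS = ("FD", "QSE", "QG", "VG")
ALPHA_RAW = 0.05
Q_THRESHOLD = 0.10
EXACT_MAX_N = 12


@dataclass(frozen=True)
class WilcoxonResult:
    z: float
    p: float
    direction: str  # "increase" (post > pre), "decrease", or "none"
    n: int  # pairs retained after dropping zero differences
    w_plus: float
    exact: bool


def _exact_two_sided_p(ranks: np.ndarray, w_plus: float) -> float:
    """Two-sided exact p by enumerating all 2^n sign assignments of the ranks."""
    n = ranks.size
    subsets = np.arange(2**n)[:, None]
    bits = (subsets >> np.arange(n)) & 1  # (2^n, n) inclusion mask
    dist = bits @ ranks
    lo = float(np.mean(dist <= w_plus + 1e-9))
    hi = float(np.mean(dist >= w_plus - 1e-9))
    return min(1.0, 2.0 * min(lo, hi))


def wilcoxon_signed_rank(pre: np.ndarray, post: np.ndarray) -> WilcoxonResult:
    """Paired Wilcoxon signed-rank test on d = pre - post.

    Zero differences are dropped; ties receive midranks.  The normal z uses
    the tie-corrected variance ``n(n+1)(2n+1)/24 - sum(t^3 - t)/48``; for
    n <= 12 the reported p comes from full sign enumeration instead of the
    normal tail.  Negative z means the values increased after the
    intervention.
    """
    pre = np.asarray(pre, dtype=float).ravel()
    post = np.asarray(post, dtype=float).ravel()
    if pre.size != post.size:
        raise ValueError("pre and post must have equal length")
    d = pre - post
    d = d[d != 0]
    if d.size == 0:
        raise ValueError("no signal: all paired differences are zero")
    if d.size < 5:
        raise ValueError(f"only {d.size} nonzero differences; need at least 5")
    n = d.size
    ranks = rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    mu = n * (n + 1) / 4.0
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = float(((counts**3 - counts)).sum()) / 48.0
    sigma2 = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    z = 0.0 if sigma2 == 0 else (w_plus - mu) / np.sqrt(sigma2)
    exact = n <= EXACT_MAX_N
    if exact:
        p = _exact_two_sided_p(ranks, w_plus)
    else:
        from scipy.stats import norm

        p = float(min(1.0, 2.0 * norm.sf(abs(z))))
    if z < 0:
        direction = "increase"
    elif z > 0:
        direction = "decrease"
    else:
        direction = "none"
    return WilcoxonResult(z=float(z), p=p, direction=direction, n=n, w_plus=w_plus, exact=exact)


def bh_fdr(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, original order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _tidy_check(df: pd.DataFrame, which: str) -> pd.DataFrame:
    required = {"subject", "metric", "band", "feature", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{which} table is missing columns {sorted(missing)}")
    return df


def run_paired_analysis(
    features_pre: pd.DataFrame,
    features_post: pd.DataFrame,
    alpha_raw: float = ALPHA_RAW,
    q_threshold: float = Q_THRESHOLD,
    fdr_metrics: tuple = FDR_METRICS,
) -> pd.DataFrame:
    """Per-feature Wilcoxon tests with family-wise BH correction.

    Inputs are tidy frames with columns ``subject, metric, band, feature,
    value``.  Each (metric, band) combination whose metric is in
    ``fdr_metrics`` forms one BH family over its features; other metrics
    (iCOH pairs, GE, LE, T) are reported with raw p-values only (q = NaN).
    Subjects must match between conditions for every feature.
    """
    pre = _tidy_check(features_pre, "pre")
    post = _tidy_check(features_post, "post")
    key = ["metric", "band", "feature"]
    merged = pre.merge(post, on=key + ["subject"], how="outer", suffixes=("_pre", "_post"), indicator=True)
    offenders = merged.loc[merged["_merge"] != "both", key + ["subject"]]
    if len(offenders):
        listing = offenders.head(10).to_dict("records")
        raise ValueError(f"subject/feature mismatch between conditions: {listing}")
    rows = []
    for (metric, band, feature), grp in merged.groupby(key, sort=True):
        try:
            res = wilcoxon_signed_rank(grp["value_pre"].to_numpy(), grp["value_post"].to_numpy())
        except ValueError:
            # all-zero differences or too few informative pairs: untestable feature
            rows.append(
                dict(metric=metric, band=band, feature=feature, n=len(grp),
                     z=np.nan, p=np.nan, direction="none")
            )
            continue
        rows.append(
            dict(metric=metric, band=band, feature=feature, n=res.n,
                 z=res.z, p=res.p, direction=res.direction)
        )
    table = pd.DataFrame(rows)
    table["q"] = np.nan
    table["family_size"] = 0
    for (metric, band), idx in table.groupby(["metric", "band"]).groups.items():
        idx = pd.Index(idx)
        table.loc[idx, "family_size"] = len(idx)
        if metric in fdr_metrics:
            ok = idx[table.loc[idx, "p"].notna()]
            if len(ok):
                table.loc[ok, "q"] = bh_fdr(table.loc[ok, "p"].to_numpy())
    table["sig_raw"] = table["p"] < alpha_raw
    table["sig_fdr"] = table["q"] < q_threshold
    return table


def zmap_export(table: pd.DataFrame, montage: "tuple | list" = ()) -> dict:
    """Electrode x band z matrices per metric, with significance flags.

    Returns ``{metric: (z_frame, sig_frame)}`` where rows are electrodes and
    columns bands.  Electrodes listed in ``montage`` but absent from the
    table are filled with NaN and reported via a warning.
    """
    import warnings

    out = {}
    for metric, grp in table.groupby("metric"):
        z = grp.pivot_table(index="feature", columns="band", values="z", aggfunc="first")
        sig = grp.pivot_table(index="feature", columns="band", values="sig_fdr", aggfunc="first")
        if montage:
            missing = [ch for ch in montage if ch not in z.index]
            if missing:
                warnings.warn(f"zmap_export: electrodes missing for {metric}: {missing}")
            z = z.reindex(list(montage))
            sig = sig.reindex(list(montage))
        out[metric] = (z, sig.astype("boolean"))
    return out
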