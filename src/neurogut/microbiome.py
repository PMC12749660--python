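"""Paired gut-microbiome analysis: alpha/beta diversity, PCoA, PERMANOVA and taxon shifts.

Works downstream of a taxa-by-sample count table with rank-delimited lineage
strings (phylum;class;order;family;genus;species) and a paired pre/post
sample manifest.  Alpha diversity (bias-corrected Chao1, Shannon in nats,
Simpson), Bray-Curtis / Jaccard distances and PCoA are delegated to
scikit-bio; group comparisons use Kruskal-Wallis (scipy) and an in-package
permutation PERMANOVA; per-taxon relative-abundance shifts are summarized at
every taxonomic rank with the study's percent-change convention
(100 x (post - pre) / pre on condition-mean relative abundances).

Raw counts are never rarefied; all compositional statements are made on
relative abundances.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import kruskal as _scipy_kruskal
from skbio.diversity import beta_diversity as _skbio_beta
from skbio.diversity.alpha import chao1 as _chao1, shannon as _shannon, simpson as _simpson
from skbio.stats.distance import DistanceMatrix
from skbio.stats.ordination import pcoa as _skbio_pcoa

from .stats import wilcoxon_signed_rank

__all__ = [
    "RANKS",
    "TaxaTable",
    "alpha_diversity",
    "beta_diversity",
    "pcoa",
    "kruskal_wallis",
    "permanova",
    "collapse_rank",
    "relative_abundance",
    "taxon_shifts",
    "read_taxa_table",
    "write_taxa_table",
]

RANKS = ("phylum", "class", "order", "family", "genus", "species")


@dataclass
class TaxaTable:
    """Taxa x sample count table with lineages and a paired pre/post manifest.

    ``counts`` is indexed by taxon id with one column per sample;
    ``lineages`` maps taxon id to a ';'-delimited string of the six ranks;
    ``manifest`` is indexed by sample with columns ``subject`` and
    ``condition`` in {"pre", "post"}.
    """

    counts: pd.DataFrame
    lineages: pd.Series
    manifest: pd.DataFrame

    def __post_init__(self) -> None:
        self.counts = self.counts.astype(float)
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be nonnegative")
        if (self.counts.sum(axis=0) <= 0).any():
            empty = self.counts.columns[self.counts.sum(axis=0) <= 0].tolist()
            raise ValueError(f"all-zero sample(s): {empty}")
        if not self.counts.index.equals(self.lineages.index):
            self.lineages = self.lineages.reindex(self.counts.index)
            if self.lineages.isna().any():
                raise ValueError("every taxon needs a lineage string")
        bad = [l for l in self.lineages if len(str(l).split(";")) != len(RANKS)]
        if bad:
            raise ValueError(f"malformed lineage strings (need {len(RANKS)} ranks): {bad[:3]}")
        missing = set(self.counts.columns) - set(self.manifest.index)
        if missing:
            raise ValueError(f"samples missing from manifest: {sorted(missing)}")
        dup = self.manifest.groupby(["subject", "condition"]).size()
        if (dup > 1).any():
            raise ValueError("each subject may have at most one pre and one post sample")

    @property
    def samples(self) -> list:
        return list(self.counts.columns)

    def condition_samples(self, condition: str) -> pd.Series:
        """Subject-indexed sample names for one condition."""
        m = self.manifest[self.manifest["condition"] == condition]
        return pd.Series(m.index.values, index=m["subject"].values)


# ---------------------------------------------------------------------------
# Diversity
# ---------------------------------------------------------------------------

def alpha_diversity(table: "TaxaTable | pd.DataFrame", shannon_base: float = np.e) -> pd.DataFrame:
    """Per-sample Chao1 (bias-corrected), Shannon (nats by default) and Simpson (1 - sum p^2)."""
    counts = table.counts if isinstance(table, TaxaTable) else table
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be nonnegative")
    rows = {}
    for s in counts.columns:
        c = counts[s].to_numpy()
        if c.sum() <= 0:
            raise ValueError(f"all-zero sample {s!r}")
        ci = np.round(c).astype(int)  # Chao1 needs integer singleton/doubleton counts
        rows[s] = {
            "chao1": float(_chao1(ci, bias_corrected=True)),
            "shannon": float(_shannon(c, base=shannon_base)),
            "simpson": float(_simpson(c)),
        }
    return pd.DataFrame(rows).T.rename_axis("sample")


def relative_abundance(counts: pd.DataFrame) -> pd.DataFrame:
    """Column-normalize counts to per-sample proportions."""
    total = counts.sum(axis=0)
    if (total <= 0).any():
        raise ValueError("all-zero sample")
    return counts / total


def beta_diversity(table: "TaxaTable | pd.DataFrame", metric: str = "braycurtis") -> DistanceMatrix:
    """Sample x sample distances: Bray-Curtis on proportions or Jaccard on presence/absence."""
    counts = table.counts if isinstance(table, TaxaTable) else table
    if counts.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    ids = list(counts.columns)
    if metric == "braycurtis":
        mat = relative_abundance(counts).T.to_numpy()
        return _skbio_beta("braycurtis", mat, ids=ids)
    if metric == "jaccard":
        mat = (counts.T.to_numpy() > 0).astype(float)
        return _skbio_beta("jaccard", mat, ids=ids)
    raise ValueError(f"unknown metric {metric!r}; use 'braycurtis' or 'jaccard'")


def pcoa(dm: DistanceMatrix):
    """Principal coordinates of a distance matrix.

    Gower double-centering followed by eigendecomposition; negative
    eigenvalues are reported, not dropped, and axes are ordered by
    eigenvalue.  Returns a scikit-bio ``OrdinationResults``.
    """
    return _skbio_pcoa(dm, method="eigh", number_of_dimensions=0)


# ---------------------------------------------------------------------------
# Group tests
# ---------------------------------------------------------------------------

def kruskal_wallis(*groups) -> tuple:
    """Tie-corrected Kruskal-Wallis H and its chi-square p-value."""
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("empty group")
    # identical values across all groups: H = 0, p = 1 (scipy raises instead)
    flat = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    if np.unique(flat).size == 1:
        return 0.0, 1.0
    H, p = _scipy_kruskal(*groups)
    return float(H), float(p)


def permanova(
    dm: "DistanceMatrix | np.ndarray",
    labels,
    n_perm: int = 999,
    seed: "int | None" = 0,
) -> tuple:
    """Permutation PERMANOVA pseudo-F and p on a distance matrix.

    ``pseudo-F = (SS_between / (k-1)) / (SS_within / (N-k))`` from the
    squared-distance partition (Anderson); the p-value is
    ``(1 + #{F_perm >= F_obs}) / (1 + n_perm)`` under label permutation,
    deterministic under ``seed`` and invariant to sample order.
    """
    labels = np.asarray(labels)
    if isinstance(dm, DistanceMatrix):
        # canonical sample order so p is invariant to input ordering
        order = np.argsort(np.asarray(dm.ids), kind="stable")
        D = dm.data[np.ix_(order, order)]
        labels = labels[order]
    else:
        D = np.asarray(dm, dtype=float)
    N = D.shape[0]
    if labels.size != N:
        raise ValueError("one label per sample required")
    groups, counts = np.unique(labels, return_counts=True)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if (counts < 2).any():
        small = groups[counts < 2].tolist()
        raise ValueError(f"group(s) with fewer than 2 samples: {small}")
    D2 = D**2
    sst = D2[np.triu_indices(N, 1)].sum() / N
    k = len(groups)

    def ssw(lab: np.ndarray) -> float:
        total = 0.0
        for g in groups:
            idx = np.flatnonzero(lab == g)
            sub = D2[np.ix_(idx, idx)]
            total += sub[np.triu_indices(idx.size, 1)].sum() / idx.size
        return total

    def pseudo_f(lab: np.ndarray) -> float:
        w = ssw(lab)
        b = sst - w
        return (b / (k - 1)) / (w / (N - k))

    f_obs = pseudo_f(labels)
    rng = np.random.default_rng(seed)
    # sort for order invariance of the permutation stream
    order = np.argsort(labels, kind="stable")
    base = labels[order]
    d2s = D2[np.ix_(order, order)]

    def ssw_perm(lab: np.ndarray) -> float:
        total = 0.0
        for g in groups:
            idx = np.flatnonzero(lab == g)
            sub = d2s[np.ix_(idx, idx)]
            total += sub[np.triu_indices(idx.size, 1)].sum() / idx.size
        return total

    hits = 0
    for _ in range(n_perm):
        lab = rng.permutation(base)
        w = ssw_perm(lab)
        f = ((sst - w) / (k - 1)) / (w / (N - k))
        if f >= f_obs - 1e-12:
            hits += 1
    p = (1 + hits) / (1 + n_perm)
    return float(f_obs), float(p)


# ---------------------------------------------------------------------------
# Taxon shifts
# ---------------------------------------------------------------------------

def collapse_rank(table: TaxaTable, rank: str) -> pd.DataFrame:
    """Sum counts over taxa sharing the same lineage prefix down to ``rank``."""
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}; use one of {RANKS}")
    depth = RANKS.index(rank) + 1
    prefix = table.lineages.map(lambda l: ";".join(str(l).split(";")[:depth]))
    return table.counts.groupby(prefix.values).sum()


def taxon_shifts(table: TaxaTable, rank: str) -> pd.DataFrame:
    """Condition-level relative-abundance shifts per taxon at one rank.

    Percent change is ``100 x (mean_post - mean_pre) / mean_pre`` over the
    condition means of relative abundance across subjects; taxa absent before
    the intervention are flagged ``emergent`` and carry no percentage.
    A per-taxon paired Wilcoxon test (subjects with both samples) supplies z
    and p where enough informative pairs exist.
    """
    collapsed = collapse_rank(table, rank)
    rel = relative_abundance(collapsed)
    pre_s = table.condition_samples("pre")
    post_s = table.condition_samples("post")
    subjects = sorted(set(pre_s.index) & set(post_s.index))
    if not subjects:
        raise ValueError("no subject has both a pre and a post sample")
    pre_m = rel[pre_s[subjects].tolist()]
    post_m = rel[post_s[subjects].tolist()]
    rows = []
    for taxon in collapsed.index:
        a, b = pre_m.loc[taxon].to_numpy(), post_m.loc[taxon].to_numpy()
        mean_pre, mean_post = float(a.mean()), float(b.mean())
        emergent = mean_pre == 0 and mean_post > 0
        pct = np.nan if mean_pre == 0 else 100.0 * (mean_post - mean_pre) / mean_pre
        try:
            res = wilcoxon_signed_rank(a, b)
            z, p = res.z, res.p
        except ValueError:
            z, p = np.nan, np.nan
        rows.append(
            dict(rank=rank, taxon=taxon, mean_pre=mean_pre, mean_post=mean_post,
                 pct_change=pct, emergent=emergent, z=z, p=p, n_subjects=len(subjects))
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_taxa_table(table: TaxaTable, counts_path: "str | Path", manifest_path: "str | Path") -> None:
    """Write counts as TSV (rows = 'lineage<TAB>sample counts...') and the manifest as TSV."""
    counts_path, manifest_path = Path(counts_path), Path(manifest_path)
    counts_path.parent.mkdir(parents=True, exist_ok=True)
    out = table.counts.copy()
    out.insert(0, "lineage", table.lineages)
    out.rename_axis("taxon").to_csv(counts_path, sep="\t")
    table.manifest.rename_axis("sample").to_csv(manifest_path, sep="\t")


def read_taxa_table(counts_path: "str | Path", manifest_path: "str | Path") -> TaxaTable:
    raw = pd.read_csv(counts_path, sep="\t", index_col=0)
    manifest = pd.read_csv(manifest_path, sep="\t", index_col=0)
    lineages = raw["lineage"]
    counts = raw.drop(columns=["lineage"])
    return TaxaTable(counts=counts, lineages=lineages, manifest=manifest)
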