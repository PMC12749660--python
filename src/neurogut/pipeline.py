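"""End-to-end orchestration: configuration, stage wiring, summaries and TSV round-tripping.

``run_pipeline`` drives the full paired analysis: synthesize (or load) a
cohort -> preprocess -> connectivity + complexity metrics -> paired
statistics -> microbiome diversity/shifts -> gut-brain correlation ->
report bundle.  Every stage emits a plain TSV (version-stamped header
comment) plus a JSON run manifest with all resolved parameters and seeds,
so any number in the report can be recomputed from stage outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .complexity import ComplexityParams, complexity_profile
from .connectivity import icoh, network_metrics, pairs_count, welch_cross_spectra
from .correlation import build_delta_matrix, correlation_screen
from .microbiome import (
    TaxaTable,
    alpha_diversity,
    beta_diversity,
    kruskal_wallis,
    pcoa,
    permanova,
    read_taxa_table,
    taxon_shifts,
)
from .preprocess import band_epochs, read_recording, reject_noisy_epochs, rereference_car
from .stats import run_paired_analysis
from .synthetic import Coupling, EEGSimSpec, MicrobiomeSimSpec, simulate_eeg_cohort, simulate_taxa_tables

__all__ = ["RunConfig", "run_pipeline", "summarize_pair_counts", "write_tsv", "read_tsv"]

ALL_BANDS = ("delta", "theta", "alpha", "beta1", "beta2", "beta3", "gamma", "all")


@dataclass
class RunConfig:
    """Resolved parameters of one pipeline run (serializable, versioned)."""

    out_dir: str = "neurogut_out"
    seed: int = 0
    # inputs; None -> simulate with the sim_* blocks
    eeg_dir: "str | None" = None
    taxa_counts: "str | None" = None
    taxa_manifest: "str | None" = None
    sim_eeg: dict = field(default_factory=dict)
    sim_taxa: dict = field(default_factory=dict)
    # preprocessing
    bands: tuple = ALL_BANDS
    complexity_bands: tuple = ALL_BANDS
    epoch_len: float = 8.0
    fs_out: float = 200.0
    amp_thresh: float = 500.0
    # spectral estimation
    window_len: float = 1.0
    overlap: float = 0.5
    # complexity parameters
    m: int = 2
    r: float = 0.2
    Q: int = 8
    # statistics
    alpha_raw: float = 0.05
    q_threshold: float = 0.10
    n_perm: int = 999
    shift_ranks: tuple = ("phylum", "class", "genus", "species")
    corr_metrics: tuple = ("FD", "QSE", "QG", "VG")
    corr_rank: str = "genus"
    min_pairs: int = 5

    def complexity_params(self) -> ComplexityParams:
        return ComplexityParams(m=self.m, r=self.r, Q=self.Q)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, default=str)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        raw = json.loads(text)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("bands", "complexity_bands", "shift_ranks", "corr_metrics"):
            if key in raw:
                raw[key] = tuple(raw[key])
        if "sim_eeg" in raw and "couplings" in raw.get("sim_eeg", {}):
            def as_coupling(c):
                if isinstance(c, Coupling):
                    return c
                if isinstance(c, dict):
                    return Coupling(**c)
                return Coupling(*c)

            raw["sim_eeg"]["couplings"] = tuple(
                as_coupling(c) for c in raw["sim_eeg"]["couplings"]
            )
        return cls(**raw)


# ---------------------------------------------------------------------------
# TSV with version stamp
# ---------------------------------------------------------------------------

def write_tsv(df: pd.DataFrame, path: "str | Path", index: bool = False) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# neurogut {__version__}\n")
        df.to_csv(fh, sep="\t", index=index)
    return path


def read_tsv(path: "str | Path", index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)


# ---------------------------------------------------------------------------
# EEG feature extraction
# ---------------------------------------------------------------------------

def eeg_features_for_recording(rec, config: RunConfig) -> pd.DataFrame:
    """Tidy feature rows (metric, band, feature, value) for one recording.

    Connectivity metrics (iCOH pairs, GE, LE, T) are computed on the
    continuous CAR signal at the native rate; the four nonlinear metrics on
    band-filtered 8-s epochs downsampled to 200 Hz.
    """
    rec = rereference_car(rec)
    rows = []
    cs = welch_cross_spectra(rec, window_len=config.window_len, overlap=config.overlap)
    for band in config.bands:
        W = icoh(cs, band)
        nm = network_metrics(W)
        labels = list(W.labels)
        iu, ju = np.triu_indices(len(labels), 1)
        for i, j in zip(iu, ju):
            rows.append(dict(metric="iCOH", band=band,
                             feature=f"{labels[i]}-{labels[j]}", value=W.W[i, j]))
        rows.append(dict(metric="GE", band=band, feature="global", value=nm.GE))
        rows.append(dict(metric="T", band=band, feature="global", value=nm.T))
        for i, ch in enumerate(labels):
            rows.append(dict(metric="LE", band=band, feature=ch, value=nm.LE[i]))
    ep = band_epochs(rec, config.complexity_bands, config.epoch_len, config.fs_out)
    ep = reject_noisy_epochs(ep, config.amp_thresh)
    prof = complexity_profile(ep, config.complexity_params())
    for r in prof.itertuples():
        rows.append(dict(metric=r.metric, band=r.band, feature=r.channel, value=r.value))
    return pd.DataFrame(rows)


def eeg_feature_table(cohort: dict, config: RunConfig) -> pd.DataFrame:
    """Features for every subject/condition, long format with subject and condition."""
    frames = []
    for subject, conds in sorted(cohort.items()):
        for cond, rec in conds.items():
            df = eeg_features_for_recording(rec, config)
            df.insert(0, "condition", cond)
            df.insert(0, "subject", subject)
            frames.append(df)
    return pd.concat(frames, ignore_index=True)


def summarize_pair_counts(table: pd.DataFrame, band: str, n_channels: int = 21) -> dict:
    """Directional tallies of the iCOH pair tests for one band.

    Requires all C(n_channels, 2) pair rows (210 for the 21-channel
    montage).  Ties (z = 0) count as neither increase nor decrease and are
    reported separately so the four counts plus ties partition the pairs.
    """
    expected = pairs_count(n_channels)
    rows = table[(table["metric"] == "iCOH") & (table["band"] == band)]
    if len(rows) != expected:
        raise ValueError(f"expected {expected} pair rows for band {band!r}, got {len(rows)}")
    inc = rows["z"] < 0
    dec = rows["z"] > 0
    tie = ~(inc | dec)
    sig = rows["sig_raw"].fillna(False).astype(bool)
    return {
        "band": band,
        "n_pairs": int(expected),
        "n_increased": int(inc.sum()),
        "n_decreased": int(dec.sum()),
        "n_ties": int(tie.sum()),
        "n_significant_increase": int((inc & sig).sum()),
        "n_significant_decrease": int((dec & sig).sum()),
    }


# ---------------------------------------------------------------------------
# Stage runners
# ---------------------------------------------------------------------------

def _load_or_simulate_eeg(config: RunConfig) -> dict:
    if config.eeg_dir is not None:
        cohort: dict = {}
        for f in sorted(Path(config.eeg_dir).glob("*.npy")):
            stem = f.stem  # "<subject>_<condition>"
            subject, _, cond = stem.rpartition("_")
            if cond not in ("pre", "post"):
                continue
            cohort.setdefault(subject, {})[cond] = read_recording(f)
        if not cohort:
            raise FileNotFoundError(f"no '<subject>_<pre|post>.npy' recordings in {config.eeg_dir}")
        return cohort
    spec = EEGSimSpec(seed=config.seed, **{"n_subjects": 8, **config.sim_eeg})
    return simulate_eeg_cohort(spec)


def _load_or_simulate_taxa(config: RunConfig) -> TaxaTable:
    if config.taxa_counts is not None:
        if config.taxa_manifest is None:
            raise ValueError("taxa_counts given without taxa_manifest")
        return read_taxa_table(config.taxa_counts, config.taxa_manifest)
    spec = MicrobiomeSimSpec(seed=config.seed + 1, **config.sim_taxa)
    return simulate_taxa_tables(spec)


def run_microbiome(table: TaxaTable, config: RunConfig, out: Path) -> dict:
    """Alpha/beta diversity, PCoA, group tests and per-rank shift reports."""
    alpha = alpha_diversity(table)
    alpha = alpha.join(table.manifest)
    write_tsv(alpha.reset_index(), out / "alpha_diversity.tsv")
    pre = alpha[alpha["condition"] == "pre"]
    post = alpha[alpha["condition"] == "post"]
    kw_rows = []
    for idx in ("chao1", "shannon", "simpson"):
        H, p = kruskal_wallis(pre[idx].to_numpy(), post[idx].to_numpy())
        kw_rows.append(dict(index=idx, H=H, p=p))
    kw = pd.DataFrame(kw_rows)
    kw["q"] = kw["p"]  # single pre/post comparison per index: no multiplicity
    write_tsv(kw, out / "alpha_kruskal_wallis.tsv")

    labels = table.manifest.loc[table.samples, "condition"].to_numpy()
    beta_rows = []
    for metric in ("braycurtis", "jaccard"):
        dm = beta_diversity(table, metric)
        write_tsv(pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids),
                  out / f"beta_{metric}.tsv", index=True)
        F, p = permanova(dm, labels, n_perm=config.n_perm, seed=config.seed + 2)
        beta_rows.append(dict(metric=metric, pseudo_F=F, p=p))
        if metric == "braycurtis":
            ord_res = pcoa(dm)
            coords = ord_res.samples.copy()
            coords.index = dm.ids
            write_tsv(coords.reset_index(names="sample"), out / "pcoa_braycurtis.tsv")
            eig = pd.DataFrame({
                "eigenvalue": ord_res.eigvals.to_numpy(),
                "explained": ord_res.proportion_explained.to_numpy(),
            })
            write_tsv(eig, out / "pcoa_eigenvalues.tsv")
    beta = pd.DataFrame(beta_rows)
    write_tsv(beta, out / "beta_permanova.tsv")

    shifts = pd.concat([taxon_shifts(table, r) for r in config.shift_ranks], ignore_index=True)
    write_tsv(shifts, out / "taxon_shifts.tsv")
    return {"alpha": alpha, "alpha_tests": kw, "beta_tests": beta, "shifts": shifts}


def run_correlation(features: pd.DataFrame, table: TaxaTable, config: RunConfig, out: Path) -> pd.DataFrame:
    """Kendall screen between nonlinear EEG deltas and taxa relative-abundance deltas."""
    from .microbiome import collapse_rank, relative_abundance

    nl = features[features["metric"].isin(config.corr_metrics)].copy()
    nl["feat_id"] = nl["metric"] + ":" + nl["band"] + ":" + nl["feature"]
    wide = {}
    for cond in ("pre", "post"):
        sub = nl[nl["condition"] == cond]
        wide[cond] = sub.pivot_table(index="subject", columns="feat_id", values="value")
    eeg_deltas = build_delta_matrix(wide["pre"], wide["post"])

    rel = relative_abundance(collapse_rank(table, config.corr_rank))
    pre_s = table.condition_samples("pre")
    post_s = table.condition_samples("post")
    subjects = sorted(set(pre_s.index) & set(post_s.index))
    taxa_pre = rel[pre_s[subjects].tolist()].T.set_axis(subjects, axis=0)
    taxa_post = rel[post_s[subjects].tolist()].T.set_axis(subjects, axis=0)
    taxa_deltas = build_delta_matrix(taxa_pre, taxa_post)

    # EEG subject ids must match taxa subject ids for the screen to align
    common = eeg_deltas.index.intersection(taxa_deltas.index)
    if common.empty:
        raise ValueError("EEG and taxa cohorts share no subject identifiers")
    screen = correlation_screen(
        eeg_deltas.loc[common], taxa_deltas.loc[common], min_pairs=config.min_pairs
    )
    write_tsv(screen, out / "gutbrain_correlation.tsv")
    return screen


def run_pipeline(config: RunConfig) -> dict:
    """Full paired analysis; writes all stage TSVs plus a run manifest.

    Deterministic under the config's seed: rerunning the same config yields
    byte-identical numeric outputs.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    cohort = _load_or_simulate_eeg(config)
    features = eeg_feature_table(cohort, config)
    write_tsv(features, out / "eeg_features.tsv")

    pre = features[features["condition"] == "pre"].drop(columns="condition")
    post = features[features["condition"] == "post"].drop(columns="condition")
    stats = run_paired_analysis(pre, post, alpha_raw=config.alpha_raw, q_threshold=config.q_threshold)
    write_tsv(stats, out / "paired_stats.tsv")

    n_ch = len(next(iter(cohort.values()))["pre"].labels)
    pair_summary = pd.DataFrame(
        [summarize_pair_counts(stats, b, n_channels=n_ch) for b in config.bands]
    )
    write_tsv(pair_summary, out / "icoh_pair_summary.tsv")

    taxa = _load_or_simulate_taxa(config)
    micro = run_microbiome(taxa, config, out)
    screen = run_correlation(features, taxa, config, out)

    manifest = {
        "version": __version__,
        "config": json.loads(config.to_json()),
        "n_subjects_eeg": len(cohort),
        "n_subjects_taxa": int(taxa.manifest["subject"].nunique()),
        "n_channels": n_ch,
        "n_icoh_pairs": pairs_count(n_ch),
        "correlation_family_size": int(screen["family_size"].iloc[0]) if len(screen) else 0,
    }
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=1))
    return {
        "features": features,
        "stats": stats,
        "pair_summary": pair_summary,
        "microbiome": micro,
        "correlation": screen,
        "manifest": manifest,
    }
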