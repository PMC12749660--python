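"""Synthetic paired cohorts with known effect structure.

Two generators provide ground-truth test beds for every downstream stage:

* :func:`simulate_eeg_cohort` builds paired pre/post 21-channel recordings.
  Each channel is a sum of narrowband stochastic oscillations (random-phase
  spectra confined to a configurable bandwidth around each component's
  center frequency) plus 1/f background noise synthesized by spectral
  shaping of white noise.  Narrowband *stochastic* components — rather than
  phase-locked sinusoids — are essential: deterministic tones at a shared
  frequency would be mutually coherent regardless of coupling, whereas
  independent narrowband processes give near-zero coherence unless a
  coupling explicitly injects a phase-lagged copy of the source component
  into the target channel.  A coupling of strength ``s`` and lag ``phi``
  yields an analytically predictable coherency ``s * exp(-i phi)`` at the
  component's frequencies, hence imaginary coherence ``s * sin(phi)``.

* :func:`simulate_taxa_tables` builds paired Dirichlet-multinomial taxa
  count tables with per-taxon multiplicative fold changes applied to the
  post-condition composition (renormalized), e.g. a 3.48x fold change on a
  low-abundance taxon emulates a ~248% relative-abundance increase.

Both are byte-deterministic under their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .microbiome import RANKS, TaxaTable
from .preprocess import CANONICAL_BANDS, MONTAGE_21, EEGRecording, get_band

__all__ = [
    "Coupling",
    "EEGSimSpec",
    "MicrobiomeSimSpec",
    "simulate_eeg_cohort",
    "simulate_taxa_tables",
    "default_lineages",
]

#: Default oscillatory components: (center Hz, amplitude uV), spanning the
#: physiological delta/theta/alpha/beta range with alpha dominant at rest.
DEFAULT_COMPONENTS = ((2.0, 10.0), (6.0, 8.0), (10.0, 15.0), (20.0, 5.0))


@dataclass(frozen=True)
class Coupling:
    """Phase-lagged linear coupling from channel i into channel j within one band."""

    ch_i: int
    ch_j: int
    band: str
    phase_lag: float
    strength: float


@dataclass(frozen=True)
class EEGSimSpec:
    """Specification of a paired pre/post EEG cohort.

    ``effect`` multiplies every coupling strength in the post condition
    (clipped to [0, 1]); subject-level log-normal amplitude jitter
    (``amp_jitter_sigma``) is shared between a subject's pre and post
    recordings so paired tests see realistic between-subject variance.
    """

    n_subjects: int
    n_channels: int = 21
    fs: float = 500.0
    duration: float = 60.0
    band_components: Sequence = DEFAULT_COMPONENTS
    component_bandwidth: float = 2.0
    noise_exponent: float = 1.0
    noise_scale: float = 10.0
    couplings: Sequence[Coupling] = ()
    effect: float = 1.0
    amp_jitter_sigma: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")
        if not self.duration > 0:
            raise ValueError("duration must be positive")
        fmax = max(f for f, _ in self.band_components) + self.component_bandwidth / 2
        if self.fs <= 2 * fmax:
            raise ValueError(
                f"fs={self.fs} Hz too low for components up to {fmax} Hz (need fs > 2 fmax)"
            )
        for c in self.couplings:
            if not 0 <= c.strength <= 1:
                raise ValueError(f"coupling_strength must be in [0, 1], got {c.strength}")
            if c.strength > 0 and not (0 < c.phase_lag < np.pi):
                raise ValueError(
                    f"phase_lag must lie in (0, pi) for a nonzero coupling, got {c.phase_lag}"
                )
            if not (0 <= c.ch_i < self.n_channels and 0 <= c.ch_j < self.n_channels):
                raise ValueError(f"coupling channels out of range: {c}")
        if self.effect <= 0:
            raise ValueError("effect must be positive")

    def labels(self) -> tuple:
        if self.n_channels <= len(MONTAGE_21):
            return MONTAGE_21[: self.n_channels]
        return MONTAGE_21 + tuple(f"X{i}" for i in range(self.n_channels - len(MONTAGE_21)))


def _narrowband_spectrum(rng, freqs: np.ndarray, f0: float, bw: float) -> np.ndarray:
    """Random-phase complex rfft coefficients confined to |f - f0| <= bw/2."""
    sel = np.abs(freqs - f0) <= bw / 2
    coeff = np.zeros(freqs.size, dtype=complex)
    k = int(sel.sum())
    coeff[sel] = rng.standard_normal(k) + 1j * rng.standard_normal(k)
    return coeff


def _to_time(coeff: np.ndarray, n: int, rms: float) -> np.ndarray:
    x = np.fft.irfft(coeff, n=n)
    cur = x.std()
    return x * (rms / cur) if cur > 0 else x


def _one_recording(spec: EEGSimSpec, subj: int, condition: str, jitter: float) -> EEGRecording:
    n = int(round(spec.duration * spec.fs))
    freqs = np.fft.rfftfreq(n, 1.0 / spec.fs)
    cond_idx = 0 if condition == "pre" else 1
    rng = np.random.default_rng([spec.seed % (2**31), subj, cond_idx])
    # per-channel, per-component narrowband spectra
    comp_spec = np.empty((len(spec.band_components), spec.n_channels, freqs.size), dtype=complex)
    for k, (f0, _amp) in enumerate(spec.band_components):
        for ch in range(spec.n_channels):
            comp_spec[k, ch] = _narrowband_spectrum(rng, freqs, f0, spec.component_bandwidth)
    # couplings: replace target component by sqrt(1-s^2)*own + s*phase-shifted source
    eff = spec.effect if condition == "post" else 1.0
    for c in spec.couplings:
        band = get_band(c.band)
        s = min(1.0, c.strength * eff)
        for k, (f0, _amp) in enumerate(spec.band_components):
            if band.lo <= f0 <= band.hi:
                shifted = comp_spec[k, c.ch_i] * np.exp(-1j * c.phase_lag)
                comp_spec[k, c.ch_j] = np.sqrt(1 - s**2) * comp_spec[k, c.ch_j] + s * shifted
    data = np.zeros((spec.n_channels, n))
    for k, (_f0, amp) in enumerate(spec.band_components):
        rms = jitter * amp / np.sqrt(2.0)  # amplitude quoted like a sinusoid's peak
        for ch in range(spec.n_channels):
            data[ch] += _to_time(comp_spec[k, ch], n, rms)
    if spec.noise_scale > 0:
        shape = np.ones(freqs.size)
        shape[1:] = freqs[1:] ** (-spec.noise_exponent / 2.0)
        shape[0] = 0.0
        for ch in range(spec.n_channels):
            white = rng.standard_normal(freqs.size) + 1j * rng.standard_normal(freqs.size)
            data[ch] += _to_time(white * shape, n, spec.noise_scale)
    return EEGRecording(
        data, spec.fs, spec.labels(), recording_id=f"S{subj:02d}_{condition}"
    )


def simulate_eeg_cohort(spec: EEGSimSpec) -> dict:
    """Paired pre/post recordings per subject: ``{subject_id: {"pre": rec, "post": rec}}``."""
    cohort = {}
    for subj in range(spec.n_subjects):
        jrng = np.random.default_rng([spec.seed % (2**31), subj])
        jitter = float(np.exp(jrng.normal(0.0, spec.amp_jitter_sigma)))
        cohort[f"S{subj:02d}"] = {
            cond: _one_recording(spec, subj, cond, jitter) for cond in ("pre", "post")
        }
    return cohort


# ---------------------------------------------------------------------------
# Microbiome cohort
# ---------------------------------------------------------------------------

def default_lineages(n_taxa: int) -> list:
    """Clearly synthetic six-rank lineage strings cycling over four phyla."""
    phyla = ("SynPhylumA", "SynPhylumB", "SynPhylumC", "SynPhylumD")
    out = []
    for t in range(n_taxa):
        p = phyla[t % len(phyla)]
        fam = t // len(phyla)
        out.append(
            ";".join(
                [p, f"{p}_class{fam % 3}", f"{p}_order{fam % 3}",
                 f"{p}_family{fam}", f"{p}_genus{t}", f"{p}_species{t}"]
            )
        )
    return out


@dataclass(frozen=True)
class MicrobiomeSimSpec:
    """Specification of paired Dirichlet-multinomial taxa tables.

    ``overdispersion`` is the Dirichlet concentration scaling the base
    proportions (``inf`` disables subject-level compositional variation);
    ``fold_changes`` multiplies the post composition per taxon before
    renormalization.
    """

    n_subjects: int = 13
    n_taxa: int = 40
    depth: int = 100_000
    base_proportions: "Sequence | None" = None
    lineage: "Sequence | None" = None
    fold_changes: "Sequence | None" = None
    overdispersion: float = 300.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.n_subjects < 1 or self.n_taxa < 2:
            raise ValueError("need n_subjects >= 1 and n_taxa >= 2")
        if self.base_proportions is not None:
            p = np.asarray(self.base_proportions, dtype=float)
            if p.size != self.n_taxa:
                raise ValueError("base_proportions length must equal n_taxa")
            if (p <= 0).any() or abs(p.sum() - 1.0) > 1e-8:
                raise ValueError("base_proportions must be a strictly positive simplex vector")
        if self.fold_changes is not None:
            fc = np.asarray(self.fold_changes, dtype=float)
            if fc.size != self.n_taxa:
                raise ValueError("fold_changes length must equal n_taxa")
            if (fc <= 0).any():
                raise ValueError("fold_changes must be positive")
        if self.lineage is not None and len(self.lineage) != self.n_taxa:
            raise ValueError("lineage length must equal n_taxa")
        if not self.overdispersion > 0:
            raise ValueError("overdispersion must be positive")

    def proportions(self) -> np.ndarray:
        if self.base_proportions is not None:
            return np.asarray(self.base_proportions, dtype=float)
        # geometric-style decreasing profile: few dominant taxa, long tail
        p = 0.8 ** np.arange(self.n_taxa)
        return p / p.sum()

    def folds(self) -> np.ndarray:
        if self.fold_changes is None:
            return np.ones(self.n_taxa)
        return np.asarray(self.fold_changes, dtype=float)

    def lineage_strings(self) -> list:
        return list(self.lineage) if self.lineage is not None else default_lineages(self.n_taxa)


def simulate_taxa_tables(spec: MicrobiomeSimSpec) -> TaxaTable:
    """Paired pre/post multinomial count tables with injected fold changes.

    Per subject, a composition ``p ~ Dirichlet(overdispersion x base)`` is
    drawn (the base itself when overdispersion is infinite); pre counts are
    multinomial at the requested depth, and post counts use the renormalized
    product of the subject's composition with the fold changes.
    """
    rng = np.random.default_rng(spec.seed % (2**31))
    base = spec.proportions()
    folds = spec.folds()
    lineages = spec.lineage_strings()
    taxa_ids = [f"taxon{t:03d}" for t in range(spec.n_taxa)]
    counts = {}
    manifest = []
    for subj in range(spec.n_subjects):
        if np.isinf(spec.overdispersion):
            p_pre = base
        else:
            p_pre = rng.dirichlet(spec.overdispersion * base)
            p_pre = np.clip(p_pre, 1e-12, None)
            p_pre = p_pre / p_pre.sum()
        p_post = p_pre * folds
        p_post = p_post / p_post.sum()
        sid = f"S{subj:02d}"
        counts[f"{sid}_pre"] = rng.multinomial(spec.depth, p_pre)
        counts[f"{sid}_post"] = rng.multinomial(spec.depth, p_post)
        manifest.append({"sample": f"{sid}_pre", "subject": sid, "condition": "pre"})
        manifest.append({"sample": f"{sid}_post", "subject": sid, "condition": "post"})
    counts_df = pd.DataFrame(counts, index=taxa_ids, dtype=float)
    manifest_df = pd.DataFrame(manifest).set_index("sample")
    return TaxaTable(
        counts=counts_df,
        lineages=pd.Series(lineages, index=taxa_ids, name="lineage"),
        manifest=manifest_df,
    )
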