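"""EEG preprocessing: referencing, band-limiting, epoching and quality screening.

The pipeline expects resting-state scalp EEG in a 10-20 montage (21 channels
in the reference study, 500 Hz).  Preprocessing here is deliberately
self-contained: common average referencing (CAR), zero-phase FIR band-pass
filtering, polyphase downsampling with an explicit anti-alias low-pass, fixed
non-overlapping epoching, and amplitude-threshold epoch rejection.  Spatial
filters that require third-party artifact models (surface Laplacian, ASR,
wICA) are intentionally out of scope; CAR is used for every metric, which
shifts absolute connectivity levels but leaves every paired contrast and
statistical contract intact.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from fractions import Fraction
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import signal

__all__ = [
    "MONTAGE_21",
    "CHANNEL_SYNONYMS",
    "CANONICAL_BANDS",
    "BandSpec",
    "EEGRecording",
    "BandedEpochs",
    "canonicalize_label",
    "rereference_car",
    "bandpass_fir",
    "epoch",
    "band_epochs",
    "reject_noisy_epochs",
    "read_recording",
    "write_recording",
]

#: Standard 10-20 labels of the 21-channel montage used throughout.
MONTAGE_21 = (
    "Fp1", "Fpz", "Fp2",
    "F7", "F3", "Fz", "F4", "F8",
    "T3", "C3", "Cz", "C4", "T4",
    "T5", "P3", "Pz", "P4", "T6",
    "O1", "Oz", "O2",
)

#: Modern-name synonyms mapped onto the classic temporal labels.
CHANNEL_SYNONYMS = {"T7": "T3", "T8": "T4", "P7": "T5", "P8": "T6"}


def canonicalize_label(label: str) -> str:
    """Map modern 10-10 temporal names (T7/T8/P7/P8) onto classic 10-20 ones."""
    label = label.strip()
    return CHANNEL_SYNONYMS.get(label, label)


@dataclass(frozen=True)
class BandSpec:
    """A named frequency band [lo, hi] in Hz."""

    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not (0 < self.lo < self.hi):
            raise ValueError(f"band {self.name!r}: need 0 < lo < hi, got [{self.lo}, {self.hi}]")


#: Canonical band set of the analysis: delta through gamma plus the full spectrum.
CANONICAL_BANDS = {
    "delta": BandSpec("delta", 1.0, 3.0),
    "theta": BandSpec("theta", 3.0, 7.0),
    "alpha": BandSpec("alpha", 7.0, 12.0),
    "beta1": BandSpec("beta1", 12.0, 18.0),
    "beta2": BandSpec("beta2", 18.0, 24.0),
    "beta3": BandSpec("beta3", 24.0, 30.0),
    "gamma": BandSpec("gamma", 30.0, 45.0),
    "all": BandSpec("all", 1.0, 45.0),
}


def get_band(band: "str | BandSpec") -> BandSpec:
    if isinstance(band, BandSpec):
        return band
    try:
        return CANONICAL_BANDS[band]
    except KeyError:
        raise KeyError(f"unknown band {band!r}; known: {sorted(CANONICAL_BANDS)}") from None


@dataclass
class EEGRecording:
    """A multi-channel EEG signal block.

    Parameters
    ----------
    data
        ``(n_channels, n_samples)`` array in microvolts.
    fs
        Sampling rate in Hz.
    labels
        Ordered channel names (10-20 convention; synonyms are canonicalized).
    reference
        ``"raw"`` or ``"CAR"``.
    """

    data: np.ndarray
    fs: float
    labels: Sequence[str]
    reference: str = "raw"
    recording_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a (n_channels, n_samples) matrix")
        self.labels = tuple(canonicalize_label(l) for l in self.labels)
        if len(self.labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.labels)} labels for {self.data.shape[0]} channels"
            )
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("channel labels must be unique")
        if not self.fs > 0:
            raise ValueError("fs must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains non-finite samples")
        if self.reference not in ("raw", "CAR"):
            raise ValueError("reference must be 'raw' or 'CAR'")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


@dataclass
class BandedEpochs:
    """Per-band, per-epoch signal tensor ``(n_bands, n_epochs, n_channels, n_samples)``."""

    tensor: np.ndarray
    bands: Sequence[BandSpec]
    fs_out: float
    epoch_len: float
    labels: Sequence[str]
    provenance: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.tensor = np.asarray(self.tensor, dtype=float)
        if self.tensor.ndim != 4:
            raise ValueError("tensor must be 4-D (band, epoch, channel, sample)")
        if self.tensor.shape[0] != len(self.bands):
            raise ValueError("band axis does not match band list")
        if self.tensor.shape[2] != len(self.labels):
            raise ValueError("channel axis does not match labels")

    @property
    def n_epochs(self) -> int:
        return self.tensor.shape[1]

    @property
    def samples_per_epoch(self) -> int:
        return self.tensor.shape[3]


# ---------------------------------------------------------------------------
# Referencing
# ---------------------------------------------------------------------------

def rereference_car(rec: EEGRecording) -> EEGRecording:
    """Common average reference: subtract the instantaneous cross-channel mean.

    Idempotent; requires at least two channels.
    """
    if rec.n_channels < 2:
        raise ValueError("CAR is undefined for a single channel")
    data = rec.data - rec.data.mean(axis=0, keepdims=True)
    return replace(rec, data=data, reference="CAR")


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

def _fir_taps(lo: float, hi: float, fs: float) -> np.ndarray:
    """Hamming-window FIR band-pass with transition width max(1 Hz, 10% of edge)."""
    width = max(1.0, 0.1 * lo)
    # Hamming window: transition width ~ 3.3 / numtaps (normalized frequency).
    numtaps = int(np.ceil(3.3 * fs / width))
    numtaps += (numtaps + 1) % 2  # force odd so group delay is integral
    return signal.firwin(numtaps, [lo, hi], pass_zero=False, window="hamming", fs=fs)


def bandpass_fir(rec: EEGRecording, band: "str | BandSpec") -> EEGRecording:
    """Zero-phase (forward-backward) FIR band-pass filter.

    The filter is designed with a Hamming window (>50 dB one-pass stopband,
    doubled by filtfilt) and a transition width of max(1 Hz, 10% of the lower
    band edge).
    """
    band = get_band(band)
    if band.hi >= rec.fs / 2:
        raise ValueError(
            f"band {band.name!r} upper edge {band.hi} Hz >= Nyquist {rec.fs / 2} Hz"
        )
    taps = _fir_taps(band.lo, band.hi, rec.fs)
    padlen = min(3 * len(taps), rec.n_samples - 1)
    data = signal.filtfilt(taps, [1.0], rec.data, axis=-1, padlen=padlen)
    return replace(rec, data=data)


# ---------------------------------------------------------------------------
# Downsampling and epoching
# ---------------------------------------------------------------------------

def _downsample(data: np.ndarray, fs: float, fs_out: float) -> np.ndarray:
    """Anti-alias low-pass at 0.8 x the target Nyquist, then polyphase resample."""
    if fs_out == fs:
        return data
    if fs_out > fs:
        raise ValueError("fs_out must not exceed the native sampling rate")
    cutoff = 0.8 * (fs_out / 2.0)
    numtaps = int(np.ceil(3.3 * fs / (0.2 * fs_out / 2.0)))
    numtaps += (numtaps + 1) % 2
    taps = signal.firwin(numtaps, cutoff, window="hamming", fs=fs)
    padlen = min(3 * numtaps, data.shape[-1] - 1)
    data = signal.filtfilt(taps, [1.0], data, axis=-1, padlen=padlen)
    frac = Fraction(fs_out / fs).limit_denominator(1000)
    return signal.resample_poly(data, frac.numerator, frac.denominator, axis=-1)


def epoch(rec: EEGRecording, epoch_len: float = 8.0, fs_out: float = 200.0) -> BandedEpochs:
    """Downsample and cut into non-overlapping fixed-length epochs.

    With the study geometry (8-s epochs at 200 Hz) each epoch holds exactly
    1600 samples.  The trailing remainder shorter than one epoch is dropped.
    """
    n_per = epoch_len * fs_out
    if abs(n_per - round(n_per)) > 1e-9:
        raise ValueError(f"epoch_len x fs_out = {n_per} is not an integer sample count")
    n_per = int(round(n_per))
    if rec.duration < epoch_len:
        raise ValueError(
            f"recording of {rec.duration:.3f} s is shorter than one {epoch_len} s epoch"
        )
    data = _downsample(rec.data, rec.fs, fs_out)
    n_ep = data.shape[-1] // n_per
    data = data[:, : n_ep * n_per].reshape(rec.n_channels, n_ep, n_per)
    tensor = data.transpose(1, 0, 2)[np.newaxis]  # (1, epoch, channel, sample)
    log = [f"epoch: {n_ep} x {epoch_len}s @ {fs_out} Hz from {rec.recording_id or 'unnamed'}"]
    return BandedEpochs(
        tensor=tensor,
        bands=[CANONICAL_BANDS["all"]],
        fs_out=fs_out,
        epoch_len=epoch_len,
        labels=rec.labels,
        provenance=log,
    )


def band_epochs(
    rec: EEGRecording,
    bands: Sequence["str | BandSpec"],
    epoch_len: float = 8.0,
    fs_out: float = 200.0,
) -> BandedEpochs:
    """Filter into each band at the native rate, then downsample and epoch.

    Filtering precedes decimation so the FIR transition bands are defined at
    the acquisition rate; the order matters only near the anti-alias edge.
    """
    bands = [get_band(b) for b in bands]
    per_band = [epoch(bandpass_fir(rec, b), epoch_len, fs_out) for b in bands]
    tensor = np.concatenate([p.tensor for p in per_band], axis=0)
    log = [f"band_epochs: bands={[b.name for b in bands]}"] + per_band[0].provenance
    return BandedEpochs(
        tensor=tensor,
        bands=bands,
        fs_out=fs_out,
        epoch_len=epoch_len,
        labels=rec.labels,
        provenance=log,
    )


def reject_noisy_epochs(ep: BandedEpochs, amp_thresh: float) -> BandedEpochs:
    """Drop epochs whose peak absolute amplitude (any band, any channel) exceeds the threshold.

    Raises if every epoch is rejected, which almost always means the
    threshold does not match the signal's units.
    """
    if not amp_thresh > 0:
        raise ValueError("amp_thresh must be positive")
    peak = np.abs(ep.tensor).max(axis=(0, 2, 3))  # per-epoch peak across bands/channels
    keep = peak <= amp_thresh
    if not keep.any():
        raise ValueError(
            f"all {ep.n_epochs} epochs exceed {amp_thresh} uV; review the threshold"
        )
    dropped = np.flatnonzero(~keep).tolist()
    log = ep.provenance + [f"reject_noisy_epochs: thresh={amp_thresh} uV, dropped={dropped}"]
    return BandedEpochs(
        tensor=ep.tensor[:, keep],
        bands=ep.bands,
        fs_out=ep.fs_out,
        epoch_len=ep.epoch_len,
        labels=ep.labels,
        provenance=log,
    )


# ---------------------------------------------------------------------------
# File round-tripping
# ---------------------------------------------------------------------------

def write_recording(rec: EEGRecording, path: "str | Path") -> Path:
    """Write a recording as <path>.npy matrix plus a <path>.json sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.save(path.with_suffix(".npy"), rec.data)
    sidecar = {
        "fs": rec.fs,
        "labels": list(rec.labels),
        "reference": rec.reference,
        "recording_id": rec.recording_id,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    return path.with_suffix(".npy")


def read_recording(path: "str | Path") -> EEGRecording:
    """Read an EEG recording.

    ``.npy`` / ``.tsv`` matrices are paired with a JSON sidecar carrying
    ``fs`` and ``labels``; ``.edf`` files are read through :mod:`mne` when it
    is installed.
    """
    path = Path(path)
    if path.suffix.lower() == ".edf":
        import mne  # lazy: only needed for EDF input

        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        data = raw.get_data() * 1e6  # volts -> microvolts
        return EEGRecording(data, raw.info["sfreq"], raw.ch_names, recording_id=path.stem)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    if path.suffix == ".npy":
        data = np.load(path)
    else:
        data = np.loadtxt(path, delimiter="\t")
    return EEGRecording(
        data,
        sidecar["fs"],
        sidecar["labels"],
        reference=sidecar.get("reference", "raw"),
        recording_id=sidecar.get("recording_id", path.stem),
    )
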