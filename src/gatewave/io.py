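"""Reading recordings, band-pass filtering, segmentation and dataset splits.

The pipeline mirrors standard EEG preprocessing: zero-phase band-pass in the
canonical 0.5-42 Hz range, segmentation into non-overlapping 2-second
windows, and a seeded 80/20 train/test split with 20% of the training
segments held out for validation. Artefact removal (ICA-based component
rejection) is out of scope here: the pipeline expects already-cleaned input.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

__all__ = [
    "SegmentSet",
    "FilterSpec",
    "read_recording",
    "bandpass",
    "segment",
    "split_dataset",
    "normalize_segments",
    "save_segment_set",
    "load_segment_set",
    "CHANNEL_ALIASES",
]

SCHEMA_VERSION = 1

# legacy 10-20 temporal labels -> modern equivalents
CHANNEL_ALIASES = {"T3": "T7", "T4": "T8", "T5": "P7", "T6": "P8"}


def canonical_label(label: str) -> str:
    """Normalise a channel label to montage convention (case, T3->T7 aliasing)."""
    lab = label.strip().rstrip(".")
    if lab.upper().startswith("FP"):
        lab = "Fp" + lab[2:]
    else:
        lab = lab[:1].upper() + lab[1:]
    # unify suffix case ('CZ' -> 'Cz')
    if lab and lab[-1] in "Zz":
        lab = lab[:-1].upper().replace("FP", "Fp") + "z"
    else:
        head = lab.rstrip("0123456789")
        lab = head.upper().replace("FP", "Fp") + lab[len(head):]
    return CHANNEL_ALIASES.get(lab, lab)


@dataclass
class SegmentSet:
    """Multichannel EEG segments: array (segments, channels, samples).

    ``data`` is expected in [0, 1] after normalisation; ``provenance`` keeps
    the synthetic spec or file origin plus any normalisation statistics.
    """

    data: np.ndarray
    labels: tuple[str, ...]
    fs: float
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("data must be (segments, channels, samples)")
        if self.data.shape[1] != len(self.labels):
            raise ValueError("channel axis does not match labels")
        if not np.isfinite(self.data).all():
            raise ValueError("SegmentSet contains non-finite values")
        self.labels = tuple(self.labels)

    @property
    def n_segments(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def channel(self, label: str) -> np.ndarray:
        """All segments of one channel, shape (segments, samples)."""
        try:
            i = self.labels.index(label)
        except ValueError:
            raise KeyError(f"label {label!r} not in SegmentSet") from None
        return self.data[:, i, :]

    def subset(self, indices: np.ndarray) -> "SegmentSet":
        return replace(self, data=self.data[np.asarray(indices)])


@dataclass(frozen=True)
class FilterSpec:
    """Zero-phase Butterworth band-pass specification (defaults 0.5-42 Hz)."""

    low_cut: float = 0.5
    high_cut: float = 42.0
    order: int = 4
    design: str = "butter-zerophase"

    def validate(self, fs: float) -> None:
        if not (0 < self.low_cut < self.high_cut):
            raise ValueError("need 0 < low_cut < high_cut")
        if self.high_cut >= fs / 2:
            raise ValueError(f"high_cut {self.high_cut} must be below Nyquist {fs / 2}")


def read_recording(
    path: str | Path,
    channel_subset: list[str] | None = None,
) -> tuple[np.ndarray, float, tuple[str, ...]]:
    """Read a continuous multichannel recording.

    Supports EDF/EDF+ (via :mod:`mne`) and delimited numeric text whose
    header row holds channel labels (a column named ``fs`` or a provided
    sampling rate is then required — for text files the sampling rate is
    read from a ``# fs=<Hz>`` comment on the first line).

    Returns ``(signal, fs, labels)`` with signal shaped (channels, samples)
    and labels normalised to montage convention.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    if path.suffix.lower() in {".edf", ".bdf"}:
        import mne

        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        labels = tuple(canonical_label(ch) for ch in raw.ch_names)
        data = raw.get_data()
        fs = float(raw.info["sfreq"])
    else:
        with open(path) as fh:
            first = fh.readline()
        fs = None
        skip = 0
        if first.startswith("#"):
            skip = 1
            for token in first.lstrip("#").replace(",", " ").split():
                if token.startswith("fs="):
                    fs = float(token[3:])
        if fs is None:
            raise IOError(f"text recording {path} needs a '# fs=<Hz>' first line")
        df = pd.read_csv(path, skiprows=skip, sep=None, engine="python")
        labels = tuple(canonical_label(c) for c in df.columns)
        data = df.to_numpy(dtype=np.float64).T
    if channel_subset is not None:
        wanted = [canonical_label(c) for c in channel_subset]
        missing = [c for c in wanted if c not in labels]
        if missing:
            raise KeyError(
                f"requested channels {missing} not in recording; available: {list(labels)}"
            )
        idx = [labels.index(c) for c in wanted]
        data = data[idx]
        labels = tuple(wanted)
    return np.asarray(data, dtype=np.float64), fs, labels


def bandpass(
    x: np.ndarray,
    fs: float,
    spec: FilterSpec = FilterSpec(),
) -> np.ndarray:
    """Zero-phase (forward-backward) Butterworth band-pass along the last axis."""
    spec.validate(fs)
    sos = sps.butter(spec.order, [spec.low_cut, spec.high_cut], btype="bandpass",
                     fs=fs, output="sos")
    return sps.sosfiltfilt(sos, np.asarray(x, dtype=np.float64), axis=-1)


def segment(
    x: np.ndarray,
    fs: float,
    labels: tuple[str, ...] | None = None,
    window_seconds: float = 2.0,
    overlap: float = 0.0,
) -> SegmentSet:
    """Cut a continuous (channels, samples) signal into fixed windows.

    Non-overlapping by default; the trailing remainder shorter than one
    window is dropped.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.ndim == 1:
        x = x[None, :]
    n_ch, n_samp = x.shape
    win = int(round(fs * window_seconds))
    if n_samp < win:
        raise ValueError(f"signal length {n_samp} is shorter than one window ({win})")
    step = int(round(win * (1.0 - overlap)))
    if step < 1:
        raise ValueError("overlap too large")
    starts = range(0, n_samp - win + 1, step)
    segs = np.stack([x[:, s:s + win] for s in starts], axis=0)
    if labels is None:
        labels = tuple(f"ch{i}" for i in range(n_ch))
    return SegmentSet(data=segs, labels=labels, fs=fs,
                      provenance={"origin": "segmented", "window_seconds": window_seconds})


def split_dataset(
    segments: SegmentSet,
    train_fraction: float = 0.8,
    val_fraction_of_train: float = 0.2,
    seed: int = 0,
) -> tuple[SegmentSet, SegmentSet, SegmentSet]:
    """Seeded disjoint (train, val, test) split at segment granularity."""
    n = segments.n_segments
    n_train_all = int(np.floor(n * train_fraction))
    n_val = int(np.floor(n_train_all * val_fraction_of_train))
    n_train = n_train_all - n_val
    if min(n_train, n_val, n - n_train_all) < 1:
        raise ValueError(f"too few segments ({n}) for a {train_fraction}/{val_fraction_of_train} split")
    perm = np.random.default_rng(seed).permutation(n)
    tr, va, te = perm[:n_train], perm[n_train:n_train_all], perm[n_train_all:]
    return segments.subset(tr), segments.subset(va), segments.subset(te)


def normalize_segments(
    segments: SegmentSet,
    stats: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[SegmentSet, tuple[np.ndarray, np.ndarray]]:
    """Per-channel min-max scaling to [0, 1].

    With ``stats=(lo, hi)`` from a training set, reapplies those statistics
    (values are clipped into [0, 1]); otherwise statistics are computed over
    all segments and time points of each channel.
    """
    x = segments.data
    if stats is None:
        lo = x.min(axis=(0, 2))
        hi = x.max(axis=(0, 2))
    else:
        lo, hi = (np.asarray(a, dtype=np.float64) for a in stats)
    span = np.where(hi > lo, hi - lo, 1.0)
    scaled = (x - lo[None, :, None]) / span[None, :, None]
    scaled = np.clip(scaled, 0.0, 1.0)
    prov = dict(segments.provenance, normalized=True)
    return replace(segments, data=scaled, provenance=prov), (lo, hi)


def save_segment_set(segments: SegmentSet, path: str | Path) -> None:
    """Persist a SegmentSet as a numpy archive with a schema-versioned header."""
    np.savez_compressed(
        Path(path),
        data=segments.data,
        labels=np.array(segments.labels),
        fs=np.array(segments.fs),
        provenance=np.array(json.dumps(segments.provenance, default=str)),
        schema_version=np.array(SCHEMA_VERSION),
    )


def load_segment_set(path: str | Path) -> SegmentSet:
    with np.load(Path(path), allow_pickle=False) as z:
        if int(z["schema_version"]) != SCHEMA_VERSION:
            raise IOError(f"unsupported SegmentSet schema {int(z['schema_version'])}")
        return SegmentSet(
            data=z["data"],
            labels=tuple(str(l) for l in z["labels"]),
            fs=float(z["fs"]),
            provenance=json.loads(str(z["provenance"])),
        )
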