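"""Synthetic multichannel EEG with controllable spatial structure.

The generator emulates the two spatial features the gating mechanisms
exploit in real EEG: *volume conduction* (a source's band-limited activity
leaks into every electrode with a gain that decays with scalp distance, so
nearby electrodes are correlated) and *hemispheric symmetry* (a fraction of
each source's amplitude is mirrored to the homologous position, so
left/right electrode pairs co-vary). Sources emit band-limited noise —
white noise restricted to a frequency band in the spectral domain — rather
than sinusoids, so Welch-based spectral metrics see realistic broadband
structure.

Geometry is the planar head-map of :mod:`gatewave.montage` with Euclidean
distances; this is deliberately not a physical forward model, but it is
sufficient to give the electrode layout real statistical meaning.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import SegmentSet
from .montage import ElectrodeMontage

__all__ = ["Source", "SyntheticSpec", "simulate", "planted_dependency_set",
           "default_sources"]


@dataclass(frozen=True)
class Source:
    """One oscillatory source: position on the head map, frequency band (Hz),
    and amplitude."""

    position: tuple[float, float]
    band: tuple[float, float]
    amplitude: float = 1.0


def default_sources(fs: float = 160.0) -> list[Source]:
    """A small set of canonical-band sources at plausible scalp positions.

    Band edges are clipped below the Nyquist frequency; sources whose band
    would collapse are dropped.
    """
    raw = [
        Source((0.33, -0.80), (8.0, 13.0), 1.0),    # occipital alpha
        Source((-0.30, 0.70), (4.0, 8.0), 0.8),     # frontal theta
        Source((-0.50, 0.05), (13.0, 30.0), 0.6),   # left central beta
        Source((0.90, 0.0), (1.0, 4.0), 0.7),       # right temporal delta
    ]
    out = []
    for s in raw:
        hi = min(s.band[1], 0.45 * fs)
        if s.band[0] < hi:
            out.append(Source(s.position, (s.band[0], hi), s.amplitude))
    if not out:
        raise ValueError(f"sampling rate {fs} too low for the default sources")
    return out


@dataclass
class SyntheticSpec:
    """Configuration of one synthetic recording.

    ``symmetry`` in [0, 1] is the fraction of each source's amplitude
    mirrored to the homologous (x -> -x) position; ``mixing_decay`` is the
    spatial falloff length of the source-to-electrode gain in head-map units.
    """

    montage: ElectrodeMontage
    n_segments: int = 100
    fs: float = 160.0
    duration: float = 2.0
    sources: list[Source] | None = None
    mixing_decay: float = 0.6
    symmetry: float = 0.5
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        n_samp = self.fs * self.duration
        if abs(n_samp - round(n_samp)) > 1e-9 or round(n_samp) < 2:
            raise ValueError("fs * duration must be an integer sample count >= 2")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not (0.0 <= self.symmetry <= 1.0):
            raise ValueError("symmetry must lie in [0, 1]")
        if self.mixing_decay <= 0:
            raise ValueError("mixing_decay must be positive")
        if self.sources is not None:
            if not self.sources:
                raise ValueError("source list must not be empty")
            for s in self.sources:
                if not (0.0 < s.band[0] < s.band[1] <= self.fs / 2):
                    raise ValueError(f"source band {s.band} outside (0, fs/2]")

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.duration))


def _band_limited_noise(rng: np.random.Generator, shape: tuple[int, ...],
                        band: tuple[float, float], fs: float) -> np.ndarray:
    """White noise restricted to ``band`` by masking spectral bins, unit-variance
    per trace (when the band keeps at least one bin)."""
    n = shape[-1]
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    keep = (freqs >= band[0]) & (freqs <= band[1])
    if not keep.any():
        # band falls between bins at very short lengths; keep the nearest bin
        keep = np.zeros_like(freqs, dtype=bool)
        keep[np.argmin(np.abs(freqs - 0.5 * (band[0] + band[1])))] = True
    spec[..., ~keep] = 0.0
    x = np.fft.irfft(spec, n=n, axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    return x / np.where(sd > 0, sd, 1.0)


def _mixing_gains(spec: SyntheticSpec, source: Source) -> np.ndarray:
    """Per-channel gain: direct distance term plus the mirrored-symmetry term."""
    mont = spec.montage
    sx, sy = source.position
    gains = np.empty(len(mont))
    for i, lab in enumerate(mont.labels):
        x, y = mont.position(lab)
        d_direct = np.hypot(x - sx, y - sy)
        d_mirror = np.hypot(x + sx, y - sy)
        gains[i] = source.amplitude * (
            np.exp(-d_direct / spec.mixing_decay)
            + spec.symmetry * np.exp(-d_mirror / spec.mixing_decay)
        )
    return gains


def simulate(spec: SyntheticSpec) -> SegmentSet:
    """Draw a seeded SegmentSet from the mixing model.

    Each segment is an independent draw: every source emits fresh
    band-limited noise, mixed into electrodes by distance-decayed gains
    (plus the mirrored term scaled by ``symmetry``), then per-channel
    Gaussian sensor noise is added and each channel is min-max normalised to
    [0, 1] over the whole set.
    """
    sources = spec.sources if spec.sources is not None else default_sources(spec.fs)
    if not sources:
        raise ValueError("source list must not be empty")
    rng = np.random.default_rng(spec.seed)
    n_seg, n_ch, n_samp = spec.n_segments, len(spec.montage), spec.n_samples
    data = np.zeros((n_seg, n_ch, n_samp))
    for src in sources:
        traces = _band_limited_noise(rng, (n_seg, n_samp), src.band, spec.fs)
        gains = _mixing_gains(spec, src)
        data += gains[None, :, None] * traces[:, None, :]
    if spec.noise_sd > 0:
        data += spec.noise_sd * rng.standard_normal(data.shape)
    lo = data.min(axis=(0, 2), keepdims=True)
    hi = data.max(axis=(0, 2), keepdims=True)
    span = np.where(hi > lo, hi - lo, 1.0)
    data = (data - lo) / span
    return SegmentSet(
        data=data,
        labels=tuple(spec.montage.labels),
        fs=spec.fs,
        provenance={
            "origin": "synthetic",
            "seed": spec.seed,
            "symmetry": spec.symmetry,
            "mixing_decay": spec.mixing_decay,
            "noise_sd": spec.noise_sd,
            "n_sources": len(sources),
        },
    )


def planted_dependency_set(
    montage: ElectrodeMontage,
    target_label: str,
    noise_sd: float = 0.02,
    n_segments: int = 2000,
    seed: int = 0,
    fs: float = 16.0,
    duration: float = 0.5,
    band: tuple[float, float] | None = None,
    coefficients: tuple[float, float, float] = (0.5, 0.3, 0.2),
) -> SegmentSet:
    """A test-harness dataset with one exactly known inter-channel dependency.

    All channels except ``target_label`` are independent band-limited
    processes, individually min-max normalised to [0, 1]. The target channel
    is a fixed convex combination of its three nearest montage neighbours
    plus Gaussian noise of standard deviation ``noise_sd`` (on the [0, 1]
    scale), clipped into [0, 1]. The combination is stored in ``provenance``
    (keys ``target``, ``neighbours``, ``coefficients``, ``noise_sd``) so
    oracle checks can recover it.
    """
    montage.index(target_label)  # raises MontageError if absent
    if abs(sum(coefficients) - 1.0) > 1e-12 or min(coefficients) < 0:
        raise ValueError("coefficients must be convex (non-negative, sum to 1)")
    n_samp = int(round(fs * duration))
    if band is None:
        band = (max(0.5, 1.5 * fs / n_samp), 0.45 * fs)
    rng = np.random.default_rng(seed)
    n_ch = len(montage)
    data = _band_limited_noise(rng, (n_segments, n_ch, n_samp), band, fs)
    lo = data.min(axis=(0, 2), keepdims=True)
    hi = data.max(axis=(0, 2), keepdims=True)
    data = (data - lo) / np.where(hi > lo, hi - lo, 1.0)

    neighbours = montage.nearest(target_label, 3)
    ti = montage.index(target_label)
    combo = sum(
        c * data[:, montage.index(nb), :] for c, nb in zip(coefficients, neighbours)
    )
    if noise_sd > 0:
        combo = combo + noise_sd * rng.standard_normal(combo.shape)
    data[:, ti, :] = np.clip(combo, 0.0, 1.0)
    return SegmentSet(
        data=data,
        labels=tuple(montage.labels),
        fs=fs,
        provenance={
            "origin": "synthetic-planted",
            "seed": seed,
            "target": target_label,
            "neighbours": list(neighbours),
            "coefficients": list(coefficients),
            "noise_sd": noise_sd,
        },
    )
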