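"""Gate control sequences, masks and the curriculum schedule.

Training a gate-layer autoencoder proceeds as a *curriculum*: a fixed gating
mechanism and a fixed number of simultaneously blocked channels (DVs). Each
*session* handles one sample; within a session, *lessons* move the DV block
along an ordered channel sequence so every channel is eventually predicted
from the others. Four mechanisms order that sequence:

- ``order``: left hemisphere front-to-back, then midline, then right —
  motivated by brain lateralisation.
- ``partition``: cortical lobes in anatomical order (fronto-polar, frontal,
  central/temporal, parietal, occipital), scanning left to right within each.
- ``hemisphere_rotation``: same lobe order, but inside a lobe each left
  electrode is immediately followed by its right homologue (outer pairs
  first), midline electrodes after their flanking pair — exploiting the
  brain's bilateral symmetry.
- ``random``: a seeded random permutation (the unstructured baseline).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

from .montage import ElectrodeMontage, MontageError, row_of

__all__ = [
    "MECHANISMS",
    "GateSequence",
    "GateMask",
    "CurriculumConfig",
    "generate_gate_sequence",
    "lessons_per_session",
    "make_gate_mask",
    "enumerate_curriculum",
]

MECHANISMS = ("order", "partition", "hemisphere_rotation", "random")

# lobe groups in anatomical front-to-back order; central and temporal share a band
_GROUP = {"fronto-polar": 0, "frontal": 1, "central": 2, "temporal": 2,
          "parietal": 3, "occipital": 4}


@dataclass(frozen=True)
class GateSequence:
    """An ordered DV schedule: a permutation of the montage's channels."""

    mechanism: str
    channels: tuple[str, ...]
    montage_labels: tuple[str, ...]
    seed: int | None = None

    def __post_init__(self) -> None:
        if sorted(self.channels) != sorted(self.montage_labels):
            raise ValueError("sequence channels must be a permutation of montage labels")

    def __len__(self) -> int:
        return len(self.channels)


@dataclass(frozen=True)
class GateMask:
    """Binary per-channel gate: 1 keeps a channel (IDV), 0 blocks it (DV)."""

    theta: np.ndarray
    dv_labels: tuple[str, ...]
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        theta = np.asarray(self.theta, dtype=np.int8)
        object.__setattr__(self, "theta", theta)
        if theta.shape != (len(self.labels),):
            raise ValueError("theta length must equal number of channels")
        if not set(self.dv_labels) <= set(self.labels):
            raise ValueError("dv_labels must be montage labels")
        expect = np.array([0 if l in self.dv_labels else 1 for l in self.labels], dtype=np.int8)
        if not np.array_equal(theta, expect):
            raise ValueError("theta and dv_labels disagree")

    @property
    def n_dv(self) -> int:
        return int((self.theta == 0).sum())


def _order_sequence(montage: ElectrodeMontage) -> list[str]:
    # left front->back (within a row left-to-right, i.e. outer->inner),
    # then midline front->back, then right front->back (inner->outer).
    def key(lab: str) -> tuple:
        return (row_of(lab), montage.position(lab)[0])

    left = sorted((l for l in montage.labels if montage.hemisphere(l) == "left"), key=key)
    mid = sorted((l for l in montage.labels if montage.hemisphere(l) == "midline"), key=key)
    right = sorted((l for l in montage.labels if montage.hemisphere(l) == "right"), key=key)
    return left + mid + right


def _partition_sequence(montage: ElectrodeMontage) -> list[str]:
    # lobes front->back, left->midline->right within each lobe band
    def key(lab: str) -> tuple:
        x = montage.position(lab)[0]
        return (_GROUP[montage.lobe(lab)], x, row_of(lab))

    return sorted(montage.labels, key=key)


def _hemisphere_rotation_sequence(montage: ElectrodeMontage) -> list[str]:
    seq: list[str] = []
    groups: dict[int, list[str]] = {}
    for lab in montage.labels:
        groups.setdefault(_GROUP[montage.lobe(lab)], []).append(lab)
    for g in sorted(groups):
        members = groups[g]
        lefts = [l for l in members if montage.hemisphere(l) == "left"]
        mids = [l for l in members if montage.hemisphere(l) == "midline"]
        pairs: list[tuple[str, str]] = []
        for l in lefts:
            partner = montage.homologue(l)
            if partner is None or partner not in members:
                raise MontageError(
                    f"hemisphere_rotation needs a right homologue for {l!r}"
                )
            pairs.append((l, partner))
        unpaired_right = set(m for m in members if montage.hemisphere(m) == "right")
        unpaired_right -= {r for _, r in pairs}
        if unpaired_right:
            raise MontageError(
                f"hemisphere_rotation: no left homologue for {sorted(unpaired_right)}"
            )
        # outer pairs first (descending |x| of the left member)
        pairs.sort(key=lambda p: -abs(montage.position(p[0])[0]))
        block: list[str] = []
        for l, r in pairs:
            block.extend((l, r))
        # each midline electrode goes right after its same-row pair when one
        # exists, otherwise at the end of the lobe block
        for m in sorted(mids, key=row_of):
            anchor = None
            for l, r in pairs:
                if row_of(l) == row_of(m):
                    anchor = r
            if anchor is not None:
                block.insert(block.index(anchor) + 1, m)
            else:
                block.append(m)
        seq.extend(block)
    return seq


def generate_gate_sequence(
    montage: ElectrodeMontage,
    mechanism: str,
    seed: int | None = None,
) -> GateSequence:
    """Generate the DV ordering for one curriculum.

    ``seed`` is required for (and only used by) the ``random`` mechanism; a
    fixed seed gives an identical permutation. The three structured
    mechanisms are deterministic functions of the montage geometry.
    """
    if mechanism not in MECHANISMS:
        raise ValueError(f"unknown mechanism {mechanism!r}; choose from {MECHANISMS}")
    if mechanism == "random":
        if seed is None:
            raise ValueError("mechanism 'random' requires a seed")
        rng = np.random.default_rng(seed)
        channels = tuple(montage.labels[i] for i in rng.permutation(len(montage)))
        return GateSequence("random", channels, tuple(montage.labels), seed=int(seed))
    builders = {
        "order": _order_sequence,
        "partition": _partition_sequence,
        "hemisphere_rotation": _hemisphere_rotation_sequence,
    }
    channels = tuple(builders[mechanism](montage))
    return GateSequence(mechanism, channels, tuple(montage.labels))


def lessons_per_session(n_channels: int, n_dv: int) -> int:
    """Number of lessons in one session: floor(n_channels / n_dv)."""
    if not (1 <= n_dv < n_channels):
        raise ValueError(f"need 1 <= n_dv < n_channels, got n_dv={n_dv}, n_channels={n_channels}")
    return n_channels // n_dv


def make_gate_mask(sequence: GateSequence, lesson_index: int, n_dv: int) -> GateMask:
    """The binary gate for one lesson: DVs are the lesson's contiguous block
    of the sequence; trailing ``len(sequence) mod n_dv`` channels are never
    DVs within this curriculum (floor rule)."""
    n_lessons = lessons_per_session(len(sequence), n_dv)
    if not (0 <= lesson_index < n_lessons):
        raise ValueError(
            f"lesson_index {lesson_index} out of range [0, {n_lessons})"
        )
    dv = sequence.channels[lesson_index * n_dv:(lesson_index + 1) * n_dv]
    theta = np.array([0 if l in dv else 1 for l in sequence.montage_labels], dtype=np.int8)
    return GateMask(theta=theta, dv_labels=tuple(dv), labels=sequence.montage_labels)


@dataclass
class CurriculumConfig:
    """Everything that fixes one curriculum: montage, mechanism, DV count and
    the seeds of the data/gate control sequences."""

    montage: ElectrodeMontage
    mechanism: str = "partition"
    n_dv: int = 1
    data_seed: int = 0
    gate_seed: int | None = None

    def __post_init__(self) -> None:
        if self.mechanism not in MECHANISMS:
            raise ValueError(f"unknown mechanism {self.mechanism!r}")
        lessons_per_session(len(self.montage), self.n_dv)  # validates n_dv
        if self.mechanism == "random" and self.gate_seed is None:
            raise ValueError("random mechanism requires gate_seed")

    @property
    def n_channels(self) -> int:
        return len(self.montage)

    @property
    def n_lessons(self) -> int:
        return lessons_per_session(self.n_channels, self.n_dv)

    def sequence(self) -> GateSequence:
        return generate_gate_sequence(self.montage, self.mechanism, seed=self.gate_seed)

    def masks(self) -> list[GateMask]:
        seq = self.sequence()
        return [make_gate_mask(seq, j, self.n_dv) for j in range(self.n_lessons)]


def enumerate_curriculum(
    config: CurriculumConfig,
    n_samples: int,
    epoch: int = 0,
) -> Iterator[tuple[int, GateMask]]:
    """Yield every (sample, lesson) pair exactly once for one epoch.

    Sample order is a seeded permutation refreshed per epoch (the data
    control sequence); for each sample the lessons cycle in sequence order.
    """
    masks = config.masks()
    rng = np.random.default_rng((int(config.data_seed), int(epoch)))
    for i in rng.permutation(n_samples):
        for mask in masks:
            yield int(i), mask
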