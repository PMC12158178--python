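"""Electrode montages on a 2-D head map.

Channel labels follow the international 10-20 / extended naming scheme: a
letter prefix encodes the cortical region (Fp fronto-polar, F frontal,
C central, T temporal, P parietal, O occipital, plus the intermediate rows
AF/FC/CP/PO), and the suffix encodes lateralisation — odd numbers left
hemisphere, even numbers right, 'z' on the midline.

Coordinates live in a unitless head-map frame: nose up (+y), left
hemisphere at x < 0, head radius ~1.
"""

from __future__ import annotations

import io as _io
import math
import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

__all__ = ["ElectrodeMontage", "build_montage", "MontageError"]


class MontageError(ValueError):
    """Configuration or validation problem in a montage definition."""


LOBES = ("fronto-polar", "frontal", "central", "temporal", "parietal", "occipital")

# anterior -> posterior row index by label prefix
_ROW = {"Fp": 0, "AF": 1, "F": 2, "FC": 3, "C": 4, "T": 4, "CP": 5, "P": 6, "PO": 7, "O": 8}

_PREFIX_LOBE = {
    "Fp": "fronto-polar",
    "AF": "frontal",
    "F": "frontal",
    "FC": "central",
    "C": "central",
    "T": "temporal",
    "CP": "parietal",
    "P": "parietal",
    "PO": "occipital",
    "O": "occipital",
}

_LABEL_RE = re.compile(r"^([A-Za-z]+?)(z|\d+)$")

# 19 channels of the international 10-20 system, canonical row-major order.
_POS_1020 = {
    "Fp1": (-0.31, 0.95), "Fp2": (0.31, 0.95),
    "F7": (-0.81, 0.59), "F3": (-0.45, 0.52), "Fz": (0.0, 0.50),
    "F4": (0.45, 0.52), "F8": (0.81, 0.59),
    "T7": (-1.0, 0.0), "C3": (-0.50, 0.0), "Cz": (0.0, 0.0),
    "C4": (0.50, 0.0), "T8": (1.0, 0.0),
    "P7": (-0.81, -0.59), "P3": (-0.45, -0.52), "Pz": (0.0, -0.50),
    "P4": (0.45, -0.52), "P8": (0.81, -0.59),
    "O1": (-0.31, -0.95), "O2": (0.31, -0.95),
}

# Ten additional channels of the extended 29-channel layout (10-10 subset,
# intermediate FC/CP/PO rows plus Oz; all homologue-pairable).
_POS_EXT10 = {
    "FC3": (-0.48, 0.26), "FCz": (0.0, 0.25), "FC4": (0.48, 0.26),
    "CP3": (-0.48, -0.26), "CPz": (0.0, -0.25), "CP4": (0.48, -0.26),
    "PO3": (-0.36, -0.73), "POz": (0.0, -0.72), "PO4": (0.36, -0.73),
    "Oz": (0.0, -0.98),
}

_SYSTEMS = {
    "10-20-19ch": dict(_POS_1020),
    "extended-29ch": {**_POS_1020, **_POS_EXT10},
}


def parse_label(label: str) -> tuple[str, str]:
    """Split a channel label into (prefix, suffix); raise on malformed labels."""
    m = _LABEL_RE.match(label)
    if m is None:
        raise MontageError(f"cannot parse channel label {label!r}")
    prefix = m.group(1)
    # normalise case: first letter upper, 'p' of Fp lower
    key = prefix[0].upper() + prefix[1:].lower()
    if key == "Fp" or key in _ROW:
        prefix = key
    elif prefix.upper() in _ROW:
        prefix = prefix.upper()
    else:
        raise MontageError(f"unknown region prefix in label {label!r}")
    return prefix, m.group(2)


def hemisphere_of(label: str) -> str:
    """Hemisphere implied by the label suffix: odd=left, even=right, z=midline."""
    _, suffix = parse_label(label)
    if suffix.lower() == "z":
        return "midline"
    return "left" if int(suffix) % 2 == 1 else "right"


def row_of(label: str) -> int:
    """Anterior-to-posterior row index of a label (Fp=0 ... O=8)."""
    prefix, _ = parse_label(label)
    return _ROW[prefix]


def lobe_of(label: str) -> str:
    prefix, _ = parse_label(label)
    return _PREFIX_LOBE[prefix]


def homologue_of(label: str) -> str | None:
    """The mirror-hemisphere partner label: odd 2k-1 <-> even 2k; None for midline."""
    prefix, suffix = parse_label(label)
    if suffix.lower() == "z":
        return None
    n = int(suffix)
    partner = n + 1 if n % 2 == 1 else n - 1
    return f"{prefix}{partner}"


@dataclass(frozen=True)
class ElectrodeMontage:
    """An ordered set of scalp electrodes with positions and region tags.

    Parameters
    ----------
    system_name :
        ``"10-20-19ch"``, ``"extended-29ch"``, or a custom identifier.
    labels :
        Ordered channel labels, unique.
    positions :
        Per-label 2-D head-map coordinates (nose up, left hemisphere x<0).
    lobes, hemispheres :
        Per-label region / lateralisation tags. The hemisphere tag must agree
        with the one implied by the label suffix.
    """

    system_name: str
    labels: tuple[str, ...]
    positions: Mapping[str, tuple[float, float]]
    lobes: Mapping[str, str]
    hemispheres: Mapping[str, str]
    _index: Mapping[str, int] = field(init=False, repr=False, compare=False, default=None)

    def __post_init__(self) -> None:
        if len(set(self.labels)) != len(self.labels):
            dup = sorted({l for l in self.labels if list(self.labels).count(l) > 1})
            raise MontageError(f"duplicate channel labels: {dup}")
        for lab in self.labels:
            if lab not in self.positions:
                raise MontageError(f"label {lab!r} has no position")
            if lab not in self.lobes:
                raise MontageError(f"label {lab!r} has no lobe tag")
            if self.lobes[lab] not in LOBES:
                raise MontageError(f"label {lab!r} has unknown lobe {self.lobes[lab]!r}")
            implied = hemisphere_of(lab)
            stored = self.hemispheres.get(lab)
            if stored is None:
                raise MontageError(f"label {lab!r} has no hemisphere tag")
            if stored != implied:
                raise MontageError(
                    f"hemisphere tag {stored!r} for {lab!r} disagrees with "
                    f"label-implied {implied!r}"
                )
        object.__setattr__(self, "_index", {l: i for i, l in enumerate(self.labels)})

    def __len__(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        try:
            return self._index[label]
        except KeyError:
            raise MontageError(f"label {label!r} not in montage {self.system_name!r}") from None

    def position(self, label: str) -> tuple[float, float]:
        self.index(label)
        return self.positions[label]

    def hemisphere(self, label: str) -> str:
        self.index(label)
        return self.hemispheres[label]

    def lobe(self, label: str) -> str:
        self.index(label)
        return self.lobes[label]

    def distance(self, a: str, b: str) -> float:
        xa, ya = self.position(a)
        xb, yb = self.position(b)
        return math.hypot(xa - xb, ya - yb)

    def homologue(self, label: str) -> str | None:
        """Mirror partner present in this montage, or None."""
        partner = homologue_of(label)
        if partner is not None and partner in self._index:
            return partner
        return None

    def nearest(self, label: str, k: int = 3) -> list[str]:
        """The k nearest other electrodes by head-map distance."""
        others = [l for l in self.labels if l != label]
        others.sort(key=lambda l: self.distance(label, l))
        return others[:k]

    @classmethod
    def from_table(cls, text: str, system_name: str = "custom") -> "ElectrodeMontage":
        """Build a montage from delimited text: label, x, y[, lobe[, hemisphere]].

        Lobe and hemisphere default to the tags implied by the label.
        """
        df = pd.read_csv(_io.StringIO(text), sep=None, engine="python",
                         skipinitialspace=True)
        df.columns = [c.strip().lower() for c in df.columns]
        required = {"label", "x", "y"}
        if not required.issubset(df.columns):
            raise MontageError(f"montage table needs columns {sorted(required)}")
        labels = tuple(str(l).strip() for l in df["label"])
        positions = {l: (float(x), float(y)) for l, x, y in zip(labels, df["x"], df["y"])}
        if "lobe" in df.columns:
            lobes = {l: str(v).strip() for l, v in zip(labels, df["lobe"])}
        else:
            lobes = {l: lobe_of(l) for l in labels}
        if "hemisphere" in df.columns:
            hemis = {l: str(v).strip() for l, v in zip(labels, df["hemisphere"])}
        else:
            hemis = {l: hemisphere_of(l) for l in labels}
        return cls(system_name, labels, positions, lobes, hemis)


def build_montage(system_name: str, table: str | None = None) -> ElectrodeMontage:
    """Return a named standard montage, or one built from a custom table.

    ``"10-20-19ch"`` is the 19-electrode international 10-20 layout;
    ``"extended-29ch"`` adds the intermediate FC/CP/PO rows and Oz.
    """
    if table is not None:
        return ElectrodeMontage.from_table(table, system_name=system_name)
    if system_name not in _SYSTEMS:
        raise MontageError(
            f"unknown montage system {system_name!r}; "
            f"available: {sorted(_SYSTEMS)} (or supply a custom table)"
        )
    pos = _SYSTEMS[system_name]
    labels = tuple(pos)
    return ElectrodeMontage(
        system_name=system_name,
        labels=labels,
        positions=dict(pos),
        lobes={l: lobe_of(l) for l in labels},
        hemispheres={l: hemisphere_of(l) for l in labels},
    )
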