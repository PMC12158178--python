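"""Shared fixtures: montages, tiny custom layouts, and an EDF writer helper."""

from __future__ import annotations

import struct

import numpy as np
import pytest

from gatewave import build_montage


@pytest.fixture(scope="session")
def montage19():
    return build_montage("10-20-19ch")


@pytest.fixture(scope="session")
def montage29():
    return build_montage("extended-29ch")


QUAD_TABLE = """label,x,y
F3,-0.45,0.52
F4,0.45,0.52
P3,-0.45,-0.52
P4,0.45,-0.52
"""


@pytest.fixture(scope="session")
def montage4():
    """A 4-channel symmetric layout for cheap training tests."""
    return build_montage("quad", table=QUAD_TABLE)


def write_edf(path, data: np.ndarray, fs: float, labels: list[str]) -> None:
    """Write a minimal single-record EDF file (16-bit, synthetic fixture).

    Enough of the EDF spec for round-trip testing: one data record holding
    the whole signal, physical range symmetric around zero.
    """
    n_ch, n_samp = data.shape
    # integer physical range: exactly representable in the 8-char header field
    phys_max = float(np.ceil(np.abs(data).max() * 1.05) + 1)
    dig_min, dig_max = -32768, 32767
    record_dur = n_samp / fs

    def pad(s: str, n: int) -> bytes:
        return s[:n].ljust(n).encode("ascii")

    header = b"".join([
        pad("0", 8), pad("synthetic", 80), pad("synthetic fixture", 80),
        pad("01.01.20", 8), pad("00.00.00", 8),
        pad(str(256 + 256 * n_ch), 8), pad("", 44), pad("1", 8),
        pad(f"{record_dur:g}", 8), pad(str(n_ch), 4),
    ])
    header += b"".join(pad(l, 16) for l in labels)          # label
    header += b"".join(pad("EEG", 80) for _ in labels)       # transducer
    header += b"".join(pad("uV", 8) for _ in labels)         # unit
    header += b"".join(pad(f"{-phys_max:.0f}", 8) for _ in labels)
    header += b"".join(pad(f"{phys_max:.0f}", 8) for _ in labels)
    header += b"".join(pad(str(dig_min), 8) for _ in labels)
    header += b"".join(pad(str(dig_max), 8) for _ in labels)
    header += b"".join(pad("", 80) for _ in labels)          # prefiltering
    header += b"".join(pad(str(n_samp), 8) for _ in labels)
    header += b"".join(pad("", 32) for _ in labels)

    scale = (dig_max - dig_min) / (2 * phys_max)
    digital = np.round((data + phys_max) * scale + dig_min).astype("<i2")
    with open(path, "wb") as fh:
        fh.write(header)
        for ch in range(n_ch):
            fh.write(digital[ch].tobytes())
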