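"""Shared fixtures: deterministic RNGs, tiny graphs, and a minimal EDF writer."""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from plinet.connectivity import ConnectivityMatrix
from plinet.montage import CANONICAL_MONTAGE
from plinet.network import WeightedNetwork

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20231292)


@pytest.fixture
def triangle() -> WeightedNetwork:
    """Triangle with weights w12 = w13 = 0.5, w23 = 1.0."""
    return WeightedNetwork(
        nodes=("A", "B", "C"),
        edge_index=[[0, 1], [0, 2], [1, 2]],
        weights=[0.5, 0.5, 1.0],
    )


def random_connectivity(rng: np.random.Generator, n: int = 16) -> ConnectivityMatrix:
    """Random symmetric matrix with distinct positive weights in (0, 1)."""
    values = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    values[iu] = rng.uniform(0.01, 0.99, len(iu[0]))
    values += values.T
    return ConnectivityMatrix(values, tuple(f"n{i:02d}" for i in range(n)))


@pytest.fixture
def connectivity_16(rng) -> ConnectivityMatrix:
    values = np.zeros((16, 16))
    iu = np.triu_indices(16, k=1)
    values[iu] = rng.uniform(0.01, 0.99, 120)
    values += values.T
    return ConnectivityMatrix(values, CANONICAL_MONTAGE)


def _fixed(text: str, width: int) -> bytes:
    return text.encode("ascii")[:width].ljust(width)


def write_minimal_edf(
    path: Path,
    data_uv: np.ndarray,
    channel_names: list[str],
    sampling_rate: int,
) -> Path:
    """Write a bare-bones EDF file (one data record per second, int16).

    Synthetic test fixture only: physical range is fixed at +-1000 uV, so the
    quantisation step is ~0.03 uV.
    """
    data_uv = np.asarray(data_uv, dtype=float)
    n_ch, n_samples = data_uv.shape
    if n_samples % sampling_rate:
        raise ValueError("need a whole number of 1 s records")
    n_records = n_samples // sampling_rate
    phys_min, phys_max = -1000.0, 1000.0
    dig_min, dig_max = -32768, 32767
    header_bytes = 256 + 256 * n_ch

    h = b"".join(
        [
            _fixed("0", 8),
            _fixed("X X X X", 80),
            _fixed("Startdate 01-JAN-2001 X X X", 80),
            _fixed("01.01.01", 8),
            _fixed("00.00.00", 8),
            _fixed(str(header_bytes), 8),
            _fixed("", 44),
            _fixed(str(n_records), 8),
            _fixed("1", 8),
            _fixed(str(n_ch), 4),
        ]
    )
    for getter, width in [
        (lambda c: c, 16),          # label
        (lambda c: "", 80),         # transducer
        (lambda c: "uV", 8),        # physical dimension
        (lambda c: str(phys_min), 8),
        (lambda c: str(phys_max), 8),
        (lambda c: str(dig_min), 8),
        (lambda c: str(dig_max), 8),
        (lambda c: "", 80),         # prefiltering
        (lambda c: str(sampling_rate), 8),
        (lambda c: "", 32),         # reserved
    ]:
        h += b"".join(_fixed(getter(c), width) for c in channel_names)

    scale = (dig_max - dig_min) / (phys_max - phys_min)
    digital = np.clip(
        np.round((data_uv - phys_min) * scale + dig_min), dig_min, dig_max
    ).astype("<i2")
    body = b""
    for r in range(n_records):
        for c in range(n_ch):
            body += digital[c, r * sampling_rate : (r + 1) * sampling_rate].tobytes()
    Path(path).write_bytes(h + body)
    return Path(path)
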