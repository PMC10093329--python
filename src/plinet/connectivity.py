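"""Hilbert instantaneous phase and the Phase Lag Index (PLI).

The PLI between two narrowband signals is

    PLI = | < sign(delta_phi(t)) >_t |,

where ``delta_phi`` is the wrapped instantaneous-phase difference obtained
from the analytic (Hilbert) signal of each channel.  PLI lies in [0, 1]: it
is 0 for a phase-difference distribution symmetric around zero (including
instantaneous volume-conduction mixing, which produces exactly zero lag) and
1 for a consistently one-sided lag.  It is invariant to amplitude scaling of
either channel.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import hilbert

from .montage import RhythmBand
from .recording import EpochSet

#: Fraction of samples dropped from each end of an epoch before averaging
#: the sign of the phase difference; analytic-signal estimates are least
#: reliable at window edges.
DEFAULT_EDGE_TRIM = 0.10

#: Phase differences smaller than this (radians) count as exactly zero lag.
#: Floating-point round-off in the FFT-based analytic signal produces
#: O(1e-15) pseudo-random phase differences between amplitude-scaled copies
#: of one signal; without a dead zone their arbitrary signs would turn an
#: exactly-zero-lag pair into a nonzero PLI.
ZERO_LAG_TOL = 1e-9

MIN_PHASE_SAMPLES = 64


@dataclass
class PhaseSeries:
    """Instantaneous phase of one channel (radians, wrapped to (-pi, pi])."""

    values: np.ndarray
    channel: str = ""
    band: RhythmBand | str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class ConnectivityMatrix:
    """Symmetric matrix of pairwise PLI values for one epoch (or epoch mean)."""

    values: np.ndarray
    channel_names: tuple[str, ...]
    band: RhythmBand | str | None = None
    epoch_index: int | str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.channel_names = tuple(str(c) for c in self.channel_names)
        v = self.values
        n = len(self.channel_names)
        if v.shape != (n, n):
            raise ValueError(f"matrix shape {v.shape} does not match {n} channels")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("connectivity matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("connectivity matrix must have a zero diagonal")
        if v.min() < -1e-12 or v.max() > 1 + 1e-12:
            raise ValueError("PLI values must lie in [0, 1]")

    @property
    def n_nodes(self) -> int:
        return len(self.channel_names)

    @property
    def band_name(self) -> str:
        return self.band.name if isinstance(self.band, RhythmBand) else str(self.band)

    def upper_triangle(self) -> np.ndarray:
        """The N(N-1)/2 distinct off-diagonal values, in (i, j) lexicographic order."""
        iu = np.triu_indices(self.n_nodes, k=1)
        return self.values[iu]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.channel_names), columns=list(self.channel_names)
        )

    def save(self, path: str | Path, sep: str = "\t") -> Path:
        path = Path(path)
        self.to_frame().to_csv(path, sep=sep, float_format="%.10g")
        return path

    @classmethod
    def load(cls, path: str | Path, band=None, epoch_index=None) -> "ConnectivityMatrix":
        frame = pd.read_csv(path, sep=None, engine="python", index_col=0)
        return cls(
            values=frame.to_numpy(dtype=float),
            channel_names=tuple(frame.columns),
            band=band,
            epoch_index=epoch_index,
        )


def _as_values(x) -> np.ndarray:
    return x.values if isinstance(x, PhaseSeries) else np.asarray(x, dtype=float)


def instantaneous_phase(
    signal: np.ndarray,
    sampling_rate: float | None = None,
    *,
    channel: str = "",
    band: RhythmBand | str | None = None,
) -> PhaseSeries:
    """Phase of the analytic signal ``x(t) + j H[x](t)``, wrapped to (-pi, pi].

    Meaningful only for (approximately) narrowband input — the caller is
    responsible for band-limiting first.
    """
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1:
        raise ValueError(f"signal must be 1-D, got shape {x.shape}")
    if len(x) < MIN_PHASE_SAMPLES:
        raise ValueError(
            f"signal of {len(x)} samples is too short for a stable analytic "
            f"signal (need >= {MIN_PHASE_SAMPLES})"
        )
    if not np.any(x):
        raise ValueError("instantaneous phase of an all-zero signal is undefined")
    phase = np.angle(hilbert(x))
    return PhaseSeries(values=phase, channel=channel, band=band)


def phase_difference(p1: PhaseSeries | np.ndarray, p2: PhaseSeries | np.ndarray) -> np.ndarray:
    """Element-wise circular difference arg(e^{j(phi1 - phi2)}), in (-pi, pi]."""
    a, b = _as_values(p1), _as_values(p2)
    if a.shape != b.shape:
        raise ValueError(f"phase series lengths differ: {a.shape} vs {b.shape}")
    if isinstance(p1, PhaseSeries) and isinstance(p2, PhaseSeries):
        if p1.band is not None and p2.band is not None and p1.band != p2.band:
            raise ValueError(f"bands differ: {p1.band} vs {p2.band}")
    return np.angle(np.exp(1j * (a - b)))


def pli(delta_phi: np.ndarray, *, zero_tol: float = ZERO_LAG_TOL) -> float:
    """|mean sign of the wrapped phase difference|; sign(0) contributes 0.

    ``zero_tol`` widens the exact zero of the signum to a narrow numerical
    dead zone (see :data:`ZERO_LAG_TOL`).
    """
    d = np.asarray(delta_phi, dtype=float)
    if d.size == 0:
        raise ValueError("PLI of an empty phase-difference vector is undefined")
    if not np.all(np.isfinite(d)):
        raise ValueError("phase differences contain NaN or infinite values")
    signs = np.sign(d)
    signs[np.abs(d) <= zero_tol] = 0.0
    return float(abs(signs.mean()))


def _trim_slice(n: int, edge_trim_fraction: float) -> slice:
    if not (0 <= edge_trim_fraction < 0.5):
        raise ValueError(f"edge_trim_fraction must be in [0, 0.5), got {edge_trim_fraction}")
    cut = int(n * edge_trim_fraction)
    return slice(cut, n - cut if cut else n)


def pli_matrix(
    epoch: np.ndarray,
    channel_names: Sequence[str],
    band: RhythmBand | str | None = None,
    edge_trim_fraction: float = DEFAULT_EDGE_TRIM,
    epoch_index: int | str | None = None,
) -> ConnectivityMatrix:
    """Pairwise PLI for all channels of one epoch.

    The instantaneous phase is computed per channel on the epoch, the first
    and last ``edge_trim_fraction`` of the phase-difference series is dropped,
    and the signed average is taken over the interior.
    """
    data = np.asarray(epoch, dtype=float)
    names = tuple(str(c) for c in channel_names)
    if data.ndim != 2 or data.shape[0] != len(names):
        raise ValueError(
            f"epoch shape {data.shape} does not match {len(names)} channel names"
        )
    n_ch, n_t = data.shape
    if n_ch < 2:
        raise ValueError("need at least 2 channels for connectivity")
    ptp = data.max(axis=1) - data.min(axis=1)
    for idx in np.flatnonzero(ptp == 0):
        raise ValueError(
            f"channel {names[idx]!r} is constant within the epoch; its phase is undefined"
        )
    keep = _trim_slice(n_t, edge_trim_fraction)
    if (keep.stop - keep.start) < MIN_PHASE_SAMPLES:
        raise ValueError(
            f"epoch of {n_t} samples leaves fewer than {MIN_PHASE_SAMPLES} "
            f"samples after trimming {edge_trim_fraction:.0%} per end"
        )
    phases = np.angle(hilbert(data, axis=-1))[:, keep]
    values = np.zeros((n_ch, n_ch))
    for i in range(n_ch):
        d = np.angle(np.exp(1j * (phases[i] - phases[i + 1 :])))
        signs = np.sign(d)
        signs[np.abs(d) <= ZERO_LAG_TOL] = 0.0
        values[i, i + 1 :] = np.abs(signs.mean(axis=-1))
    values = values + values.T
    return ConnectivityMatrix(
        values=values, channel_names=names, band=band, epoch_index=epoch_index
    )


def epoch_pli_matrices(
    epoch_set: EpochSet,
    edge_trim_fraction: float = DEFAULT_EDGE_TRIM,
) -> list[ConnectivityMatrix]:
    """One PLI matrix per epoch of a band-filtered :class:`EpochSet`."""
    return [
        pli_matrix(
            epoch_set.epochs[k],
            epoch_set.channel_names,
            band=epoch_set.band,
            edge_trim_fraction=edge_trim_fraction,
            epoch_index=k,
        )
        for k in range(epoch_set.n_epochs)
    ]


def mean_connectivity(matrices: Sequence[ConnectivityMatrix]) -> ConnectivityMatrix:
    """Element-wise mean of connectivity matrices sharing a montage and band."""
    if not matrices:
        raise ValueError("cannot average an empty list of matrices")
    first = matrices[0]
    for m in matrices[1:]:
        if m.channel_names != first.channel_names:
            raise ValueError("matrices have different montages")
        if m.band_name != first.band_name:
            raise ValueError("matrices have different bands")
    stack = np.stack([m.values for m in matrices])
    return ConnectivityMatrix(
        values=stack.mean(axis=0),
        channel_names=first.channel_names,
        band=first.band,
        epoch_index="mean",
    )
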