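"""Raw EEG containers and file I/O.

Two on-disk formats are supported:

* **EDF** (European Data Format), read through :mod:`mne` — the format most
  clinical EEG systems export.
* **Delimited matrix** — a plain-text table whose header row lists the
  channel names and whose subsequent rows are samples (one column per
  channel).  The sampling rate is not part of the table; it must be supplied
  by the caller or by a JSON sidecar ``<file>.meta.json`` with at least a
  ``sampling_rate`` key (``subject_id`` and ``group_label`` optional).
  Synthetic cohorts are written in this format.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .montage import CANONICAL_MONTAGE, RhythmBand

GROUP_LABELS = ("LGAD", "HGAD")


@dataclass
class EEGRecording:
    """A multichannel recording: ``data`` is channels x samples, in microvolts."""

    channel_names: tuple[str, ...]
    data: np.ndarray
    sampling_rate: float
    subject_id: str = ""
    group_label: str | None = None

    def __post_init__(self) -> None:
        self.channel_names = tuple(str(c) for c in self.channel_names)
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError(f"data must be 2-D, got shape {self.data.shape}")
        if self.data.shape[0] != len(self.channel_names):
            raise ValueError(
                f"{self.data.shape[0]} data rows but "
                f"{len(self.channel_names)} channel names"
            )
        if not self.sampling_rate > 0:
            raise ValueError(f"sampling_rate must be > 0, got {self.sampling_rate}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains NaN or infinite samples")
        if self.group_label is not None and self.group_label not in GROUP_LABELS:
            raise ValueError(
                f"group_label must be one of {GROUP_LABELS}, got {self.group_label!r}"
            )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_seconds(self) -> float:
        return self.n_samples / self.sampling_rate

    def with_data(self, data: np.ndarray, sampling_rate: float | None = None) -> "EEGRecording":
        """Copy of this recording with new samples (and optionally a new rate)."""
        rate = self.sampling_rate if sampling_rate is None else sampling_rate
        return replace(self, data=data, sampling_rate=rate)


@dataclass
class EpochSet:
    """Fixed-length overlapping windows cut from one recording.

    ``epochs`` is a 3-D array (n_epochs, n_channels, window_samples); ``band``
    is the rhythm the epochs are filtered to, or the string ``"broadband"``.
    """

    epochs: np.ndarray
    channel_names: tuple[str, ...]
    window_seconds: float
    overlap_fraction: float
    sampling_rate: float
    band: RhythmBand | str = "broadband"
    subject_id: str = ""
    group_label: str | None = None

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=float)
        self.channel_names = tuple(str(c) for c in self.channel_names)
        if self.epochs.ndim != 3:
            raise ValueError(f"epochs must be 3-D, got shape {self.epochs.shape}")
        if self.epochs.shape[1] != len(self.channel_names):
            raise ValueError("channel dimension does not match channel_names")
        if not (0 <= self.overlap_fraction < 1):
            raise ValueError(f"overlap_fraction must be in [0, 1), got {self.overlap_fraction}")

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    @property
    def window_samples(self) -> int:
        return self.epochs.shape[2]

    @property
    def band_name(self) -> str:
        return self.band.name if isinstance(self.band, RhythmBand) else str(self.band)


def _check_montage(channel_names: Sequence[str], montage: Sequence[str], source: str) -> None:
    missing = [c for c in montage if c not in channel_names]
    if missing:
        raise ValueError(
            f"{source}: channel(s) {missing} required by the configured montage "
            f"are missing (file provides {list(channel_names)})"
        )
    extra = [c for c in channel_names if c not in montage]
    if extra:
        raise ValueError(
            f"{source}: channel(s) {extra} are not part of the configured montage"
        )


def _read_edf(path: Path) -> tuple[tuple[str, ...], np.ndarray, float]:
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    try:
        data = raw.get_data(units="uV")
    except (ValueError, KeyError):  # channels without a dimension: assume volts
        data = raw.get_data() * 1e6
    return tuple(raw.ch_names), np.asarray(data, dtype=float), float(raw.info["sfreq"])


def _read_delimited(path: Path, sampling_rate: float | None) -> tuple[
    tuple[str, ...], np.ndarray, float, dict
]:
    sidecar = path.with_name(path.name + ".meta.json")
    meta: dict = {}
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    if sampling_rate is None:
        sampling_rate = meta.get("sampling_rate")
    if sampling_rate is None:
        raise ValueError(
            f"{path}: delimited recordings need a sampling rate, either as an "
            f"argument or in a sidecar {sidecar.name}"
        )
    table = pd.read_csv(path, sep=None, engine="python")
    names = tuple(str(c) for c in table.columns)
    data = table.to_numpy(dtype=float).T  # file is samples x channels
    return names, data, float(sampling_rate), meta


def read_recording(
    path: str | Path,
    format: str = "auto",
    *,
    sampling_rate: float | None = None,
    montage: Sequence[str] | None = CANONICAL_MONTAGE,
    subject_id: str | None = None,
    group_label: str | None = None,
) -> EEGRecording:
    """Load one recording from disk.

    Parameters
    ----------
    path
        File to read.
    format
        ``"edf"``, ``"delimited_matrix"``, or ``"auto"`` (by extension:
        ``.edf`` -> EDF, anything else -> delimited).
    sampling_rate
        Required for delimited files without a sidecar; ignored for EDF.
    montage
        Expected channel list; the file must contain exactly these channels
        (any order — rows are reordered to match).  Pass ``None`` to accept
        whatever the file provides.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"recording not found: {path}")
    if format == "auto":
        format = "edf" if path.suffix.lower() == ".edf" else "delimited_matrix"

    meta: dict = {}
    if format == "edf":
        names, data, rate = _read_edf(path)
    elif format == "delimited_matrix":
        names, data, rate, meta = _read_delimited(path, sampling_rate)
    else:
        raise ValueError(f"unknown recording format {format!r}")

    if montage is not None:
        _check_montage(names, montage, str(path))
        order = [names.index(c) for c in montage]
        data = data[order]
        names = tuple(montage)

    return EEGRecording(
        channel_names=names,
        data=data,
        sampling_rate=rate,
        subject_id=subject_id or meta.get("subject_id", path.stem),
        group_label=group_label or meta.get("group_label"),
    )


def write_delimited(rec: EEGRecording, path: str | Path, *, sep: str = "\t") -> Path:
    """Write a recording as a delimited matrix plus a JSON metadata sidecar."""
    path = Path(path)
    frame = pd.DataFrame(rec.data.T, columns=list(rec.channel_names))
    frame.to_csv(path, sep=sep, index=False, float_format="%.6f")
    meta = {
        "sampling_rate": rec.sampling_rate,
        "subject_id": rec.subject_id,
        "group_label": rec.group_label,
    }
    path.with_name(path.name + ".meta.json").write_text(json.dumps(meta, indent=1))
    return path


def remove_artifacts(rec: EEGRecording) -> EEGRecording:
    """Artifact-removal hook.

    Clinical pipelines run an ICA-based de-artifacting step here (ocular,
    cardiac, myogenic components).  Component selection is analyst-dependent
    and the synthetic cohorts this package validates against are generated
    artifact-free, so the default hook is the identity; replace it with a
    real cleaner when processing patient data.
    """
    return rec
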