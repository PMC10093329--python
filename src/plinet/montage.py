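"""Electrode montage and rhythm-band definitions.

The default montage is the 16-electrode subset of the international 10-20
system commonly used in clinical resting-state recordings (frontal-pole,
frontal, central, parietal, occipital and temporal rows).  The printed order
below is the canonical node index order (0-based) everywhere in the package.
"""

from __future__ import annotations

from dataclasses import dataclass

CANONICAL_MONTAGE: tuple[str, ...] = (
    "FP1", "FP2", "F3", "F4", "C3", "C4", "P3", "P4",
    "O1", "O2", "F7", "F8", "T3", "T4", "T5", "T6",
)

#: Electrodes counted as frontal when summarising significant-edge topology.
FRONTAL_ELECTRODES: frozenset[str] = frozenset(
    {"FP1", "FP2", "F3", "F4", "F7", "F8"}
)


@dataclass(frozen=True)
class RhythmBand:
    """A named EEG frequency band (half-open passband in Hz)."""

    name: str
    low_hz: float
    high_hz: float

    def __post_init__(self) -> None:
        if not (0 < self.low_hz < self.high_hz):
            raise ValueError(
                f"band {self.name!r}: need 0 < low_hz < high_hz, "
                f"got ({self.low_hz}, {self.high_hz})"
            )


THETA = RhythmBand("theta", 4.0, 8.0)
ALPHA1 = RhythmBand("alpha1", 8.0, 10.0)
ALPHA2 = RhythmBand("alpha2", 10.0, 13.0)
BETA = RhythmBand("beta", 13.0, 30.0)

#: The four rhythms analysed by default, in conventional low-to-high order.
CANONICAL_BANDS: tuple[RhythmBand, ...] = (THETA, ALPHA1, ALPHA2, BETA)

BAND_BY_NAME: dict[str, RhythmBand] = {b.name: b for b in CANONICAL_BANDS}

#: Broadband passband applied before rhythm separation.
BROADBAND = RhythmBand("broadband", 4.0, 30.0)


def get_band(band: RhythmBand | str) -> RhythmBand:
    """Resolve a band given either a :class:`RhythmBand` or a canonical name."""
    if isinstance(band, RhythmBand):
        return band
    try:
        return BAND_BY_NAME[band]
    except KeyError:
        raise KeyError(
            f"unknown rhythm band {band!r}; known: {sorted(BAND_BY_NAME)}"
        ) from None
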