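"""Synthetic multichannel cohorts with planted phase coupling.

Each channel is a sum of one narrowband oscillation per rhythm band plus
white noise.  Carriers are sinusoids whose instantaneous frequency performs
a slow, reflected random walk inside the band (pure-sinusoid mode is kept
for analytic tests).  A *coupling edge* makes the target channel's band
component share the source channel's carrier phase, offset by a fixed lag
plus von Mises phase jitter:

    phi_target(t) = phi_source(t) - lag - eps(t),   eps ~ vonMises(0, kappa)

so the phase difference source-minus-target is ``lag + eps(t)``.  The jitter
is piecewise-constant over short blocks: its marginal distribution is exactly
von Mises (which gives a closed-form expected PLI, see :func:`expected_pli`)
while remaining slow enough to survive band-pass filtering.  ``kappa`` is a
one-parameter handle from no coupling (kappa = 0, expected PLI ~ 0) to rigid
phase locking (kappa = inf, PLI = 1 for any nonzero lag).

Zero-lag instantaneous mixing between channels — the volume-conduction
confound — is invisible to the PLI by construction; planted effects must use
a nonzero lag.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .montage import ALPHA1, ALPHA2, BETA, CANONICAL_MONTAGE, THETA, RhythmBand
from .recording import EEGRecording, write_delimited

#: Seconds per piecewise-constant jitter block.
JITTER_BLOCK_SECONDS = 0.25


class CouplingEdge(NamedTuple):
    channel_i: str  # phase source
    channel_j: str  # phase target
    lag_radians: float
    concentration: float  # von Mises kappa; np.inf = rigid locking


@dataclass(frozen=True)
class CouplingSpec:
    """Oscillation and coupling recipe for one rhythm band."""

    band: RhythmBand
    edges: tuple[CouplingEdge, ...] = ()
    background_noise_sd: float = 0.5
    oscillation_amplitude: float = 1.0

    def __post_init__(self) -> None:
        if self.background_noise_sd <= 0:
            raise ValueError("background_noise_sd must be > 0")
        if self.oscillation_amplitude <= 0:
            raise ValueError("oscillation_amplitude must be > 0")
        targets: set[str] = set()
        for e in self.edges:
            if e.channel_i == e.channel_j:
                raise ValueError(f"self-coupling on {e.channel_i!r}")
            if not (-np.pi < e.lag_radians <= np.pi):
                raise ValueError(f"lag must lie in (-pi, pi], got {e.lag_radians}")
            if e.concentration < 0:
                raise ValueError("concentration must be >= 0")
            if e.channel_j in targets:
                raise ValueError(
                    f"channel {e.channel_j!r} is the coupling target of two edges "
                    f"in band {self.band.name!r}"
                )
            targets.add(e.channel_j)


@dataclass(frozen=True)
class CohortSpec:
    """Two-group cohort recipe; everything is derived from ``master_seed``."""

    n_subjects_per_group: int
    group_specs: Mapping[str, tuple[CouplingSpec, ...]]
    duration_seconds: float = 600.0
    sampling_rate: float = 250.0
    montage: tuple[str, ...] = CANONICAL_MONTAGE
    master_seed: int = 0
    pure_sinusoid: bool = False

    def __post_init__(self) -> None:
        if self.n_subjects_per_group < 1:
            raise ValueError("n_subjects_per_group must be >= 1")
        if self.duration_seconds <= 0 or self.sampling_rate <= 0:
            raise ValueError("duration and sampling rate must be positive")
        for group, specs in self.group_specs.items():
            for cs in specs:
                if cs.band.high_hz >= self.sampling_rate / 2:
                    raise ValueError(
                        f"band {cs.band.name} exceeds Nyquist at "
                        f"{self.sampling_rate} Hz"
                    )
                for e in cs.edges:
                    for ch in (e.channel_i, e.channel_j):
                        if ch not in self.montage:
                            raise ValueError(
                                f"coupling edge names channel {ch!r} outside the "
                                f"montage (group {group}, band {cs.band.name})"
                            )


def _reflect(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    span = hi - lo
    y = np.mod(x - lo, 2 * span)
    return lo + np.where(y < span, y, 2 * span - y)


def _carrier_phase(
    n_samples: int,
    sampling_rate: float,
    center_hz: float,
    drift_span_hz: float,
    rng: np.random.Generator,
    pure_sinusoid: bool = False,
) -> np.ndarray:
    """Phase of a narrowband carrier with slow random-walk frequency drift."""
    phi0 = rng.uniform(-np.pi, np.pi)
    if pure_sinusoid or drift_span_hz == 0:
        t = np.arange(n_samples) / sampling_rate
        return phi0 + 2 * np.pi * center_hz * t
    steps = rng.normal(0.0, 1.0, n_samples)
    dev = np.cumsum(steps) * (drift_span_hz / np.sqrt(n_samples))
    freq = center_hz + _reflect(dev, -drift_span_hz, drift_span_hz)
    return phi0 + 2 * np.pi * np.cumsum(freq) / sampling_rate


def _block_jitter(
    n_samples: int,
    sampling_rate: float,
    concentration: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Piecewise-constant von Mises phase jitter (marginally exact)."""
    if np.isinf(concentration):
        return np.zeros(n_samples)
    block = max(1, int(round(JITTER_BLOCK_SECONDS * sampling_rate)))
    n_blocks = -(-n_samples // block)
    if concentration == 0:
        draws = rng.uniform(-np.pi, np.pi, n_blocks)
    else:
        draws = rng.vonmises(0.0, concentration, n_blocks)
    return np.repeat(draws, block)[:n_samples]


def expected_pli(lag_radians: float, concentration: float, n_grid: int = 20001) -> float:
    """Expected PLI of a pair coupled at ``lag`` with von Mises jitter ``kappa``.

    The phase difference is ``lag + eps`` with ``eps ~ vonMises(0, kappa)``;
    PLI = |2 P(delta in (0, pi) mod 2pi) - 1|, evaluated by quadrature of the
    (periodic) von Mises density over the positive half-circle.
    """
    if np.isinf(concentration):
        return 0.0 if lag_radians == 0 else 1.0
    if concentration == 0:
        return 0.0
    x = np.linspace(0.0, np.pi, n_grid)
    dens = sps.vonmises.pdf(x - lag_radians, concentration)
    p_pos = np.trapezoid(dens, x)
    return float(abs(2 * p_pos - 1))


def generate_phase_locked_pair(
    n_samples: int,
    sampling_rate: float,
    center_hz: float,
    lag: float,
    concentration: float,
    seed: int,
    *,
    amplitude: float = 1.0,
    noise_sd: float = 0.0,
    drift_span_hz: float = 0.5,
    pure_sinusoid: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Two narrowband channels whose phase difference is ``lag + jitter``."""
    if n_samples < 256:
        raise ValueError(f"need n_samples >= 256, got {n_samples}")
    if not (0 < center_hz < sampling_rate / 2):
        raise ValueError(
            f"center frequency {center_hz} Hz outside (0, Nyquist) at "
            f"{sampling_rate} Hz"
        )
    rng = np.random.default_rng(seed)
    phi1 = _carrier_phase(
        n_samples, sampling_rate, center_hz, drift_span_hz, rng, pure_sinusoid
    )
    jitter = _block_jitter(n_samples, sampling_rate, concentration, rng)
    phi2 = phi1 - lag - jitter
    x1 = amplitude * np.cos(phi1)
    x2 = amplitude * np.cos(phi2)
    if noise_sd > 0:
        x1 = x1 + rng.normal(0.0, noise_sd, n_samples)
        x2 = x2 + rng.normal(0.0, noise_sd, n_samples)
    return x1, x2


GROUP_CODES = {"LGAD": 0, "HGAD": 1}


def _subject_rng(master_seed: int, group: str, subject_index: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence((master_seed, GROUP_CODES[group], subject_index))
    )


def generate_subject(spec: CohortSpec, group: str, subject_index: int) -> EEGRecording:
    """One subject's recording: per-band carriers, planted coupling, white noise.

    Deterministic in ``(master_seed, group, subject_index)``.
    """
    if group not in spec.group_specs:
        raise ValueError(f"group {group!r} not in cohort spec ({list(spec.group_specs)})")
    rng = _subject_rng(spec.master_seed, group, subject_index)
    n = int(round(spec.duration_seconds * spec.sampling_rate))
    n_ch = len(spec.montage)
    ch_index = {c: k for k, c in enumerate(spec.montage)}
    data = np.zeros((n_ch, n))
    for band_spec in spec.group_specs[group]:
        band = band_spec.band
        center = 0.5 * (band.low_hz + band.high_hz)
        drift = 0.25 * (band.high_hz - band.low_hz)
        phases = np.empty((n_ch, n))
        for c in range(n_ch):
            phases[c] = _carrier_phase(
                n, spec.sampling_rate, center, drift, rng, spec.pure_sinusoid
            )
        for e in band_spec.edges:
            src, dst = ch_index[e.channel_i], ch_index[e.channel_j]
            jitter = _block_jitter(n, spec.sampling_rate, e.concentration, rng)
            phases[dst] = phases[src] - e.lag_radians - jitter
        data += band_spec.oscillation_amplitude * np.cos(phases)
        data += rng.normal(0.0, band_spec.background_noise_sd, (n_ch, n))
    return EEGRecording(
        channel_names=spec.montage,
        data=data,
        sampling_rate=spec.sampling_rate,
        subject_id=f"{group.lower()}_{subject_index:03d}",
        group_label=group,
    )


def generate_cohort(
    spec: CohortSpec, out_dir: str | Path | None = None
) -> list[EEGRecording]:
    """All subjects of both groups; optionally written to disk with a manifest."""
    recordings = [
        generate_subject(spec, group, idx)
        for group in spec.group_specs
        for idx in range(spec.n_subjects_per_group)
    ]
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        rows = []
        for rec in recordings:
            fname = f"{rec.subject_id}.tsv"
            write_delimited(rec, out_dir / fname)
            rows.append(
                {
                    "subject_id": rec.subject_id,
                    "group": rec.group_label,
                    "file": fname,
                    "sampling_rate": rec.sampling_rate,
                    "master_seed": spec.master_seed,
                }
            )
        pd.DataFrame(rows).to_csv(out_dir / "manifest.tsv", sep="\t", index=False)
    return recordings


# --- stock scenarios -------------------------------------------------------

#: Default planted lag (radians) for coupled pairs.
DEFAULT_LAG = np.pi / 4

#: Jitter concentrations for strongly and weakly coupled edges.  At a pi/4
#: lag these give expected PLIs of roughly 0.88 and 0.42 respectively.
STRONG_KAPPA = 6.0
WEAK_KAPPA = 1.0


def _band_spec(band, edges=(), amplitude=1.0, noise_sd=0.5) -> CouplingSpec:
    return CouplingSpec(
        band=band,
        edges=tuple(CouplingEdge(*e) for e in edges),
        background_noise_sd=noise_sd,
        oscillation_amplitude=amplitude,
    )


def default_cohort_spec(
    n_subjects_per_group: int = 10,
    duration_seconds: float = 600.0,
    master_seed: int = 0,
    sampling_rate: float = 250.0,
) -> CohortSpec:
    """Planted-difference scenario: two groups with opposite coupling shifts.

    The HGAD-like group carries *stronger* frontal coupling in alpha2 and
    *weaker* coupling in theta and alpha1 than the LGAD-like group — the
    direction pattern the pipeline should recover.  Beta carries one edge of
    equal strength in both groups (a planted non-difference).
    """
    lag = DEFAULT_LAG
    alpha2_edges = (("FP1", "F3", lag, None), ("FP2", "F4", lag, None), ("F3", "F7", lag, None))
    theta_edges = (("FP1", "F7", lag, None),)
    alpha1_edges = (("F3", "C3", lag, None),)
    beta_edges = (("C3", "P3", lag, 3.0),)

    def with_kappa(edges, kappa):
        return tuple((i, j, l, kappa if k is None else k) for i, j, l, k in edges)

    hgad = (
        _band_spec(THETA, with_kappa(theta_edges, WEAK_KAPPA)),
        _band_spec(ALPHA1, with_kappa(alpha1_edges, WEAK_KAPPA)),
        _band_spec(ALPHA2, with_kappa(alpha2_edges, STRONG_KAPPA)),
        _band_spec(BETA, beta_edges),
    )
    lgad = (
        _band_spec(THETA, with_kappa(theta_edges, STRONG_KAPPA)),
        _band_spec(ALPHA1, with_kappa(alpha1_edges, STRONG_KAPPA)),
        _band_spec(ALPHA2, with_kappa(alpha2_edges, WEAK_KAPPA)),
        _band_spec(BETA, beta_edges),
    )
    return CohortSpec(
        n_subjects_per_group=n_subjects_per_group,
        group_specs={"LGAD": lgad, "HGAD": hgad},
        duration_seconds=duration_seconds,
        sampling_rate=sampling_rate,
        master_seed=master_seed,
    )


def null_cohort_spec(
    n_subjects_per_group: int = 10,
    duration_seconds: float = 600.0,
    master_seed: int = 0,
    sampling_rate: float = 250.0,
) -> CohortSpec:
    """Global-null scenario: both groups share an identical, uncoupled spec."""
    bands = tuple(_band_spec(b) for b in (THETA, ALPHA1, ALPHA2, BETA))
    return CohortSpec(
        n_subjects_per_group=n_subjects_per_group,
        group_specs={"LGAD": bands, "HGAD": bands},
        duration_seconds=duration_seconds,
        sampling_rate=sampling_rate,
        master_seed=master_seed,
    )


#: Planted edges of the default scenario, per band, with the group expected
#: to show the larger PLI.
DEFAULT_PLANTED_EDGES: dict[str, tuple[tuple[str, str, str], ...]] = {
    "theta": (("FP1", "F7", "LGAD"),),
    "alpha1": (("F3", "C3", "LGAD"),),
    "alpha2": (("FP1", "F3", "HGAD"), ("FP2", "F4", "HGAD"), ("F3", "F7", "HGAD")),
}
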