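"""Run configuration: defaults, validation, YAML round-trip.

The defaults reproduce the canonical analysis settings: 250 -> 125 Hz
decimation, 4th-order 4-30 Hz Butterworth broadband, 4 s epochs with 50%
overlap, the four rhythm bands, and the 25-35% (1% step) proportional
threshold sweep.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Any, Mapping

import yaml

from .montage import BAND_BY_NAME, CANONICAL_MONTAGE
from .network import DEFAULT_N_SURROGATES, DEFAULT_SWAPS_PER_EDGE, DEFAULT_SWEEP
from .synthetic import CohortSpec, CouplingEdge, CouplingSpec
from .montage import RhythmBand


@dataclass
class RunConfig:
    output_dir: str = "plinet_run"
    # input: exactly one of these
    input_dir: str | None = None
    cohort: CohortSpec | None = None

    montage: tuple[str, ...] = CANONICAL_MONTAGE
    filter_order: int = 4
    broadband: tuple[float, float] = (4.0, 30.0)
    downsample_to: float = 125.0
    window_seconds: float = 4.0
    overlap_fraction: float = 0.5
    bands: tuple[str, ...] = ("theta", "alpha1", "alpha2", "beta")
    threshold_fractions: tuple[float, ...] = DEFAULT_SWEEP
    n_surrogates: int = DEFAULT_N_SURROGATES
    swaps_per_edge: int = DEFAULT_SWAPS_PER_EDGE
    analysis_unit: str = "epoch"  # "epoch" | "subject"
    alpha: float = 0.05
    master_seed: int = 0
    edge_trim_fraction: float = 0.1
    #: "after_segment": epoch first, then band-filter each epoch;
    #: "before_segment": band-filter the whole recording, then epoch.
    band_filter_stage: str = "after_segment"


def validate_config(config: RunConfig) -> list[str]:
    """All invariant violations, as human-readable strings; empty iff valid."""
    v: list[str] = []
    if (config.input_dir is None) == (config.cohort is None):
        v.append("input: exactly one of input_dir or cohort must be set")
    if config.filter_order < 1:
        v.append(f"filter_order: must be >= 1, got {config.filter_order}")
    lo, hi = config.broadband
    if not (0 < lo < hi):
        v.append(f"broadband: need 0 < low < high, got {config.broadband}")
    elif hi >= config.downsample_to / 2:
        v.append(
            f"broadband: high edge {hi} Hz is at or above the Nyquist frequency "
            f"of the {config.downsample_to} Hz target rate"
        )
    if config.downsample_to <= 0:
        v.append(f"downsample_to: must be > 0, got {config.downsample_to}")
    if config.window_seconds <= 0:
        v.append(f"window_seconds: must be > 0, got {config.window_seconds}")
    if not (0 <= config.overlap_fraction < 1):
        v.append(
            f"overlap_fraction: must be in [0, 1), got {config.overlap_fraction}"
        )
    if not config.bands:
        v.append("bands: must be non-empty")
    for b in config.bands:
        if b not in BAND_BY_NAME:
            v.append(f"bands: unknown rhythm {b!r}")
    if not config.threshold_fractions:
        v.append("threshold_fractions: must be non-empty")
    for f in config.threshold_fractions:
        if not (0 < f <= 1):
            v.append(f"threshold_fractions: {f} outside (0, 1]")
    if config.n_surrogates < 1:
        v.append(f"n_surrogates: must be >= 1, got {config.n_surrogates}")
    if config.swaps_per_edge < 1:
        v.append(f"swaps_per_edge: must be >= 1, got {config.swaps_per_edge}")
    if config.analysis_unit not in ("epoch", "subject"):
        v.append(f"analysis_unit: must be 'epoch' or 'subject', got {config.analysis_unit!r}")
    if not (0 < config.alpha < 1):
        v.append(f"alpha: must be in (0, 1), got {config.alpha}")
    if not (0 <= config.edge_trim_fraction < 0.5):
        v.append(
            f"edge_trim_fraction: must be in [0, 0.5), got {config.edge_trim_fraction}"
        )
    if config.band_filter_stage not in ("after_segment", "before_segment"):
        v.append(
            f"band_filter_stage: must be 'after_segment' or 'before_segment', "
            f"got {config.band_filter_stage!r}"
        )
    if len(set(config.montage)) != len(config.montage):
        v.append("montage: duplicate electrode labels")
    return v


# --- serialisation ----------------------------------------------------------


def _band_to_dict(band: RhythmBand) -> dict:
    return {"name": band.name, "low_hz": band.low_hz, "high_hz": band.high_hz}


def cohort_spec_to_dict(spec: CohortSpec) -> dict:
    return {
        "n_subjects_per_group": spec.n_subjects_per_group,
        "duration_seconds": spec.duration_seconds,
        "sampling_rate": spec.sampling_rate,
        "montage": list(spec.montage),
        "master_seed": spec.master_seed,
        "pure_sinusoid": spec.pure_sinusoid,
        "group_specs": {
            group: [
                {
                    "band": _band_to_dict(cs.band),
                    "background_noise_sd": cs.background_noise_sd,
                    "oscillation_amplitude": cs.oscillation_amplitude,
                    "edges": [
                        {
                            "channel_i": e.channel_i,
                            "channel_j": e.channel_j,
                            "lag_radians": e.lag_radians,
                            "concentration": float(e.concentration),
                        }
                        for e in cs.edges
                    ],
                }
                for cs in specs
            ]
            for group, specs in spec.group_specs.items()
        },
    }


def cohort_spec_from_dict(d: Mapping[str, Any]) -> CohortSpec:
    group_specs = {
        group: tuple(
            CouplingSpec(
                band=RhythmBand(**cs["band"]),
                background_noise_sd=cs.get("background_noise_sd", 0.5),
                oscillation_amplitude=cs.get("oscillation_amplitude", 1.0),
                edges=tuple(
                    CouplingEdge(
                        e["channel_i"],
                        e["channel_j"],
                        e["lag_radians"],
                        float(e["concentration"]),
                    )
                    for e in cs.get("edges", [])
                ),
            )
            for cs in specs
        )
        for group, specs in d["group_specs"].items()
    }
    return CohortSpec(
        n_subjects_per_group=d["n_subjects_per_group"],
        group_specs=group_specs,
        duration_seconds=d.get("duration_seconds", 600.0),
        sampling_rate=d.get("sampling_rate", 250.0),
        montage=tuple(d.get("montage", CANONICAL_MONTAGE)),
        master_seed=d.get("master_seed", 0),
        pure_sinusoid=d.get("pure_sinusoid", False),
    )


def config_to_dict(config: RunConfig) -> dict:
    d = asdict(config)
    d["montage"] = list(config.montage)
    d["bands"] = list(config.bands)
    d["broadband"] = list(config.broadband)
    d["threshold_fractions"] = [float(f) for f in config.threshold_fractions]
    d["cohort"] = cohort_spec_to_dict(config.cohort) if config.cohort else None
    return d


def config_from_dict(d: Mapping[str, Any]) -> RunConfig:
    d = dict(d)
    if d.get("cohort"):
        d["cohort"] = cohort_spec_from_dict(d["cohort"])
    for key in ("montage", "bands", "broadband", "threshold_fractions"):
        if key in d and d[key] is not None:
            d[key] = tuple(d[key])
    return RunConfig(**d)


def save_config(config: RunConfig, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(config_to_dict(config), sort_keys=False))
    return path


def load_config(path: str | Path) -> RunConfig:
    return config_from_dict(yaml.safe_load(Path(path).read_text()))
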