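"""End-to-end orchestration: simulate -> connect -> network -> compare.

Each stage reads and writes plain delimited files inside the run directory,
so stages can also be run independently (see :mod:`plinet.cli`):

* ``recordings/``           delimited recordings + ``manifest.tsv``
* ``pli_<band>.tsv``        long table (subject, group, epoch, node_i, node_j, pli)
* ``metrics_<band>.tsv``    sweep-mean network metrics per analysis unit
* ``edge_stats_<band>.tsv`` per-edge ANOVA results
* ``metric_stats_<band>.tsv`` per-metric ANOVA results
* ``summary.tsv``           frontal-topology summary per band
* ``run_log.json``          config echo, seeds, per-stage counts, invariants

All randomness (cohort generation, surrogate rewiring) descends from
``config.master_seed``, so re-running an identical config reproduces every
output byte-for-byte.
"""

from __future__ import annotations

import json


from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig, config_to_dict, validate_config
from .connectivity import ConnectivityMatrix, epoch_pli_matrices, mean_connectivity
from .group_stats import edgewise_comparison, frontal_summary, metricwise_comparison
from .montage import BAND_BY_NAME, FRONTAL_ELECTRODES
from .network import metrics_over_sweep
from .preprocess import bandpass_filter, downsample, extract_rhythms, segment
from .recording import EEGRecording, read_recording, remove_artifacts
from .synthetic import generate_cohort

FLOAT_FMT = "%.10g"


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name and offending input."""

    def __init__(self, stage: str, detail: str):
        self.stage = stage
        super().__init__(f"[stage {stage}] {detail}")


def _write(frame: pd.DataFrame, path: Path) -> None:
    frame.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def stage_simulate(config: RunConfig, run_dir: Path) -> Path:
    """Generate the configured synthetic cohort under ``run_dir/recordings``."""
    if config.cohort is None:
        raise PipelineError("simulate", "config has no cohort spec")
    rec_dir = run_dir / "recordings"
    generate_cohort(config.cohort, rec_dir)
    return rec_dir


def load_recordings(config: RunConfig, rec_dir: Path) -> list[EEGRecording]:
    if not rec_dir.exists():
        raise PipelineError("read", f"input directory {rec_dir} does not exist")
    manifest = rec_dir / "manifest.tsv"
    recordings: list[EEGRecording] = []
    if manifest.exists():
        table = pd.read_csv(manifest, sep="\t")
        for row in table.itertuples():
            recordings.append(
                read_recording(
                    rec_dir / row.file,
                    sampling_rate=float(row.sampling_rate),
                    montage=config.montage,
                    subject_id=str(row.subject_id),
                    group_label=str(row.group),
                )
            )
    else:
        paths = sorted(
            p for p in rec_dir.iterdir() if p.suffix.lower() in (".edf", ".tsv", ".csv")
        )
        for p in paths:
            recordings.append(read_recording(p, montage=config.montage))
    if not recordings:
        raise PipelineError("read", f"no recordings found in {rec_dir}")
    return recordings


def _preprocess_one(config: RunConfig, rec: EEGRecording):
    """Broadband filter, decimate, epoch, band-split one recording."""
    rec = remove_artifacts(rec)
    rec = bandpass_filter(rec, *config.broadband, order=config.filter_order)
    rec = downsample(rec, config.downsample_to)
    if config.band_filter_stage == "before_segment":
        out = {}
        for name in config.bands:
            band = BAND_BY_NAME[name]
            banded = bandpass_filter(rec, band.low_hz, band.high_hz, config.filter_order)
            out[name] = segment(banded, config.window_seconds, config.overlap_fraction)
            out[name].band = band
        return out
    epochs = segment(rec, config.window_seconds, config.overlap_fraction)
    return extract_rhythms(epochs, list(config.bands), order=config.filter_order)


def stage_connect(
    config: RunConfig, recordings: Sequence[EEGRecording], run_dir: Path
) -> dict[str, pd.DataFrame]:
    """PLI matrices for every epoch, band and subject, as long tables per band."""
    per_band_rows: dict[str, list[pd.DataFrame]] = {b: [] for b in config.bands}
    for rec in recordings:
        try:
            band_epochs = _preprocess_one(config, rec)
        except ValueError as err:
            raise PipelineError("preprocess", f"subject {rec.subject_id}: {err}") from err
        for name in config.bands:
            eset = band_epochs[name]
            try:
                matrices = epoch_pli_matrices(eset, config.edge_trim_fraction)
            except ValueError as err:
                raise PipelineError(
                    "connect", f"subject {rec.subject_id}, band {name}: {err}"
                ) from err
            iu = np.triu_indices(len(config.montage), k=1)
            for m in matrices:
                per_band_rows[name].append(
                    pd.DataFrame(
                        {
                            "subject_id": rec.subject_id,
                            "group": rec.group_label,
                            "band": name,
                            "epoch": m.epoch_index,
                            "node_i": [config.montage[k] for k in iu[0]],
                            "node_j": [config.montage[k] for k in iu[1]],
                            "pli": m.values[iu],
                        }
                    )
                )
    tables = {}
    for name in config.bands:
        table = pd.concat(per_band_rows[name], ignore_index=True)
        _write(table, run_dir / f"pli_{name}.tsv")
        tables[name] = table
    return tables


def matrices_from_long(
    table: pd.DataFrame, montage: Sequence[str], band: str
) -> list[tuple[str, str, int, ConnectivityMatrix]]:
    """Rebuild (subject, group, epoch, matrix) tuples from a long PLI table."""
    montage = list(montage)
    index = {c: k for k, c in enumerate(montage)}
    out = []
    for (subject, group, epoch), chunk in table.groupby(
        ["subject_id", "group", "epoch"], sort=True
    ):
        values = np.zeros((len(montage), len(montage)))
        i = chunk["node_i"].map(index).to_numpy()
        j = chunk["node_j"].map(index).to_numpy()
        values[i, j] = chunk["pli"].to_numpy()
        values[j, i] = chunk["pli"].to_numpy()
        out.append(
            (
                str(subject),
                str(group),
                int(epoch),
                ConnectivityMatrix(values, tuple(montage), band=band, epoch_index=int(epoch)),
            )
        )
    return out


def _analysis_units(
    config: RunConfig, entries: list[tuple[str, str, int, ConnectivityMatrix]]
) -> list[tuple[str, str, str, ConnectivityMatrix]]:
    """Collapse epoch matrices to the configured unit of analysis.

    Returns (subject, group, unit_label, matrix) tuples — one per epoch for
    ``analysis_unit="epoch"``, one subject-mean matrix per subject otherwise.
    """
    if config.analysis_unit == "epoch":
        return [(s, g, str(e), m) for s, g, e, m in entries]
    by_subject: dict[tuple[str, str], list[ConnectivityMatrix]] = {}
    for s, g, _, m in entries:
        by_subject.setdefault((s, g), []).append(m)
    return [
        (s, g, "mean", mean_connectivity(ms))
        for (s, g), ms in sorted(by_subject.items())
    ]


def stage_network(
    config: RunConfig, pli_tables: Mapping[str, pd.DataFrame], run_dir: Path
) -> dict[str, pd.DataFrame]:
    """Threshold-sweep network metrics per analysis unit per band."""
    metric_tables = {}
    for band_idx, name in enumerate(config.bands):
        entries = matrices_from_long(pli_tables[name], config.montage, name)
        units = _analysis_units(config, entries)
        rows = []
        for unit_idx, (subject, group, unit_label, matrix) in enumerate(units):
            seed = int(
                np.random.SeedSequence(
                    (config.master_seed, 1000 + band_idx, unit_idx)
                ).generate_state(1)[0]
                & 0x7FFFFFFF
            )
            sweep = metrics_over_sweep(
                matrix,
                fractions=config.threshold_fractions,
                n_surrogates=config.n_surrogates,
                swaps_per_edge=config.swaps_per_edge,
                seed=seed,
            )
            s = sweep.summary
            rows.append(
                {
                    "subject_id": subject,
                    "group": group,
                    "band": name,
                    "unit": unit_label,
                    "threshold": "sweep-mean",
                    "Cw": s.clustering_mean,
                    "Lw": s.path_length,
                    "sigma": s.sigma,
                    "c_rand": s.c_rand,
                    "l_rand": s.l_rand,
                    "disconnected": s.disconnected,
                }
            )
        table = pd.DataFrame(rows)
        _write(table, run_dir / f"metrics_{name}.tsv")
        metric_tables[name] = table
    return metric_tables


def stage_compare(
    config: RunConfig,
    pli_tables: Mapping[str, pd.DataFrame],
    metric_tables: Mapping[str, pd.DataFrame],
    run_dir: Path,
) -> pd.DataFrame:
    """Edgewise and metric-wise two-group ANOVA plus frontal topology summary."""
    summary_rows = []
    for name in config.bands:
        entries = matrices_from_long(pli_tables[name], config.montage, name)
        units = _analysis_units(config, entries)
        mats_h = [m for _, g, _, m in units if g == "HGAD"]
        mats_l = [m for _, g, _, m in units if g == "LGAD"]
        if len(mats_h) < 2 or len(mats_l) < 2:
            raise PipelineError(
                "compare",
                f"band {name}: need >= 2 analysis units per group "
                f"(got HGAD={len(mats_h)}, LGAD={len(mats_l)})",
            )
        comp = edgewise_comparison(
            mats_h, mats_l, alpha=config.alpha,
            labels=("HGAD", "LGAD"), unit=config.analysis_unit,
        )
        _write(comp.edge_results, run_dir / f"edge_stats_{name}.tsv")

        mtab = metric_tables[name]
        mcomp = metricwise_comparison(
            mtab[mtab["group"] == "HGAD"],
            mtab[mtab["group"] == "LGAD"],
            alpha=config.alpha,
            band=name,
            labels=("HGAD", "LGAD"),
            unit=config.analysis_unit,
        )
        _write(mcomp.metric_results, run_dir / f"metric_stats_{name}.tsv")

        frontal = frontal_summary(comp, FRONTAL_ELECTRODES)
        summary_rows.append(
            {
                "band": name,
                "n_significant_edges": frontal.n_significant_edges,
                "n_frontal_related": frontal.n_frontal_related,
                "frontal_fraction": frontal.frontal_fraction,
                "frontal_ratio": frontal.ratio_string(),
                "n_increased_in_HGAD": frontal.n_increased_in_first_group,
            }
        )
    summary = pd.DataFrame(summary_rows)
    _write(summary, run_dir / "summary.tsv")
    return summary


def run_pipeline(config: RunConfig) -> Path:
    """Run every stage; returns the run directory.

    Aborts with :class:`PipelineError` naming the failing stage; an
    ``INCOMPLETE`` marker file is left in the run directory until the run
    finishes, so interrupted output is recognisable.
    """
    violations = validate_config(config)
    if violations:
        raise PipelineError("config", "; ".join(violations))
    run_dir = Path(config.output_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    marker = run_dir / "INCOMPLETE"
    marker.write_text("run in progress or aborted\n")

    if config.cohort is not None:
        rec_dir = stage_simulate(config, run_dir)
    else:
        rec_dir = Path(config.input_dir)
    recordings = load_recordings(config, rec_dir)
    pli_tables = stage_connect(config, recordings, run_dir)
    metric_tables = stage_network(config, pli_tables, run_dir)
    stage_compare(config, pli_tables, metric_tables, run_dir)

    n_pairs = len(config.montage) * (len(config.montage) - 1) // 2
    epochs_per_subject = {
        name: table.groupby("subject_id")["epoch"].nunique().to_dict()
        for name, table in pli_tables.items()
    }
    values_per_epoch = {
        name: int(len(table) / max(table.groupby(["subject_id", "epoch"]).ngroups, 1))
        for name, table in pli_tables.items()
    }
    log = {
        "software": {"package": "plinet", "version": __version__},
        "config": config_to_dict(config),
        "n_recordings": len(recordings),
        "pli_values_per_epoch_per_band": values_per_epoch,
        "pli_values_per_epoch_all_bands": int(sum(values_per_epoch.values())),
        "expected_values_per_epoch_per_band": n_pairs,
        "expected_values_per_epoch_all_bands": n_pairs * len(config.bands),
        "epochs_per_subject": epochs_per_subject,
        "counts_conserved": all(v == n_pairs for v in values_per_epoch.values()),
    }
    (run_dir / "run_log.json").write_text(json.dumps(log, indent=1, sort_keys=True))
    marker.unlink()
    return run_dir
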