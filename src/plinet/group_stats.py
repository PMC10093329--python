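"""Two-group comparison of connectivity and network metrics.

Edgewise: one classical one-way ANOVA per electrode pair on the PLI values
(120 tests for the 16-channel montage).  Metric-wise: one ANOVA per network
metric (Cw, Lw, sigma) per rhythm.  With exactly two groups the F statistic
equals the square of the pooled-variance t statistic, with df (1, nA+nB-2).

Significance defaults to uncorrected p < alpha to match common practice in
the clinical EEG literature; a Benjamini-Hochberg FDR option is available
because 120 uncorrected tests substantially inflate the family-wise error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .connectivity import ConnectivityMatrix
from .montage import FRONTAL_ELECTRODES
from .network import NetworkMetrics

DEFAULT_ALPHA = 0.05


@dataclass
class GroupComparison:
    """Edge- and/or metric-level ANOVA results for one rhythm band."""

    band: str
    unit: str  # "epoch" | "subject"
    alpha: float
    labels: tuple[str, str]  # (group_a, group_b)
    edge_results: pd.DataFrame | None = None
    metric_results: pd.DataFrame | None = None

    def significant_edges(self) -> pd.DataFrame:
        if self.edge_results is None:
            raise ValueError("no edgewise results in this comparison")
        return self.edge_results[self.edge_results["significant"]]


@dataclass
class TopologySummary:
    """Where the significant edges sit relative to the frontal electrodes."""

    band: str
    n_significant_edges: int
    n_frontal_related: int
    frontal_fraction: float  # NaN when there are no significant edges
    n_increased_in_first_group: int
    frontal_electrodes: frozenset[str]

    def ratio_string(self) -> str:
        return f"{self.n_frontal_related}/{self.n_significant_edges}"


def oneway_anova(group_a: np.ndarray, group_b: np.ndarray) -> tuple[float, float]:
    """Classical one-way fixed-effects ANOVA for two groups.

    Returns ``(F, p)`` with df (1, nA + nB - 2).  Degenerate inputs: if both
    the between- and within-group sums of squares vanish (all observations
    equal) the result is (0, 1); if only the within-group sum vanishes the F
    statistic is infinite with p = 0.
    """
    a = np.asarray(group_a, dtype=float).ravel()
    b = np.asarray(group_b, dtype=float).ravel()
    if len(a) < 2 or len(b) < 2:
        raise ValueError(
            f"each group needs >= 2 observations, got {len(a)} and {len(b)}"
        )
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("observations contain NaN or infinite values")
    n = len(a) + len(b)
    grand = (a.sum() + b.sum()) / n
    ssb = len(a) * (a.mean() - grand) ** 2 + len(b) * (b.mean() - grand) ** 2
    ssw = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
    df_within = n - 2
    if ssw == 0:
        if ssb == 0:
            return 0.0, 1.0
        return math.inf, 0.0
    f = (ssb / 1.0) / (ssw / df_within)
    p = float(sps.f.sf(f, 1, df_within))
    return float(f), p


def _vectorised_anova(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column-wise two-group ANOVA for observation matrices (rows = units)."""
    na, nb = a.shape[0], b.shape[0]
    mean_a, mean_b = a.mean(axis=0), b.mean(axis=0)
    grand = (a.sum(axis=0) + b.sum(axis=0)) / (na + nb)
    ssb = na * (mean_a - grand) ** 2 + nb * (mean_b - grand) ** 2
    ssw = ((a - mean_a) ** 2).sum(axis=0) + ((b - mean_b) ** 2).sum(axis=0)
    df_within = na + nb - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        f = ssb / (ssw / df_within)
    f = np.where(ssw == 0, np.where(ssb == 0, 0.0, np.inf), f)
    p = sps.f.sf(f, 1, df_within)
    p = np.where(np.isinf(f), 0.0, np.where((ssw == 0) & (ssb == 0), 1.0, p))
    return f, p


def edgewise_comparison(
    matrices_a: Sequence[ConnectivityMatrix],
    matrices_b: Sequence[ConnectivityMatrix],
    alpha: float = DEFAULT_ALPHA,
    *,
    labels: tuple[str, str] = ("HGAD", "LGAD"),
    unit: str = "epoch",
    correction: str | None = None,
) -> GroupComparison:
    """One ANOVA per upper-triangle edge between two groups of PLI matrices.

    ``labels`` names the groups behind ``matrices_a`` and ``matrices_b``; the
    per-edge ``direction`` column reads ``"<label>_higher"`` after the group
    with the larger sample mean.  ``correction="fdr_bh"`` switches the
    significance call to Benjamini-Hochberg adjusted p-values.
    """
    if len(matrices_a) < 2 or len(matrices_b) < 2:
        raise ValueError("each group needs at least 2 connectivity matrices")
    ref = matrices_a[0]
    for m in list(matrices_a) + list(matrices_b):
        if m.channel_names != ref.channel_names:
            raise ValueError(
                f"montage mismatch: {m.channel_names} vs {ref.channel_names}"
            )
        if m.band_name != ref.band_name:
            raise ValueError(f"band mismatch: {m.band_name} vs {ref.band_name}")
    a = np.stack([m.upper_triangle() for m in matrices_a])
    b = np.stack([m.upper_triangle() for m in matrices_b])
    f, p = _vectorised_anova(a, b)
    if correction == "fdr_bh":
        from statsmodels.stats.multitest import multipletests

        p_adj = multipletests(p, method="fdr_bh")[1]
    elif correction is None:
        p_adj = p
    else:
        raise ValueError(f"unknown correction {correction!r}")
    mean_a, mean_b = a.mean(axis=0), b.mean(axis=0)
    iu = np.triu_indices(ref.n_nodes, k=1)
    frame = pd.DataFrame(
        {
            "i": iu[0],
            "j": iu[1],
            "node_i": [ref.channel_names[k] for k in iu[0]],
            "node_j": [ref.channel_names[k] for k in iu[1]],
            "F": f,
            "p": p,
            "mean_a": mean_a,
            "mean_b": mean_b,
            "direction": np.where(
                mean_a >= mean_b, f"{labels[0]}_higher", f"{labels[1]}_higher"
            ),
            "significant": p_adj < alpha,
        }
    )
    return GroupComparison(
        band=ref.band_name, unit=unit, alpha=alpha, labels=labels, edge_results=frame
    )


def frontal_summary(
    comp: GroupComparison,
    frontal_electrodes: Iterable[str] = FRONTAL_ELECTRODES,
) -> TopologySummary:
    """Count significant edges touching the frontal electrodes.

    An edge is frontal-related iff at least one endpoint is frontal.  The
    fraction is NaN when no edge is significant.
    """
    frontal = frozenset(frontal_electrodes)
    if comp.edge_results is None:
        raise ValueError("comparison has no edgewise results")
    montage = set(comp.edge_results["node_i"]) | set(comp.edge_results["node_j"])
    missing = sorted(frontal - montage)
    if missing:
        raise ValueError(f"frontal electrode(s) {missing} absent from the montage")
    sig = comp.significant_edges()
    n_sig = len(sig)
    related = (
        sig["node_i"].isin(frontal) | sig["node_j"].isin(frontal)
    ).sum() if n_sig else 0
    first_higher = (
        (sig["direction"] == f"{comp.labels[0]}_higher").sum() if n_sig else 0
    )
    return TopologySummary(
        band=comp.band,
        n_significant_edges=int(n_sig),
        n_frontal_related=int(related),
        frontal_fraction=(related / n_sig) if n_sig else math.nan,
        n_increased_in_first_group=int(first_higher),
        frontal_electrodes=frontal,
    )


_METRIC_FIELDS = {"Cw": "clustering_mean", "Lw": "path_length", "sigma": "sigma"}


def _metric_table(records: Sequence[NetworkMetrics] | pd.DataFrame) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        missing = [c for c in _METRIC_FIELDS if c not in records.columns]
        if missing:
            raise ValueError(f"metric table lacks column(s) {missing}")
        return records[list(_METRIC_FIELDS)]
    return pd.DataFrame(
        {name: [getattr(r, attr) for r in records] for name, attr in _METRIC_FIELDS.items()}
    )


def metricwise_comparison(
    metrics_a: Sequence[NetworkMetrics] | pd.DataFrame,
    metrics_b: Sequence[NetworkMetrics] | pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
    *,
    band: str = "",
    labels: tuple[str, str] = ("HGAD", "LGAD"),
    unit: str = "epoch",
) -> GroupComparison:
    """One ANOVA per network metric (Cw, Lw, sigma) between two groups."""
    a = _metric_table(metrics_a)
    b = _metric_table(metrics_b)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 metric records")
    rows = []
    for metric in _METRIC_FIELDS:
        f, p = oneway_anova(a[metric].to_numpy(), b[metric].to_numpy())
        mean_a, mean_b = float(a[metric].mean()), float(b[metric].mean())
        rows.append(
            {
                "metric": metric,
                "F": f,
                "p": p,
                "mean_a": mean_a,
                "mean_b": mean_b,
                "direction": f"{labels[0]}_higher"
                if mean_a >= mean_b
                else f"{labels[1]}_higher",
                "significant": p < alpha,
            }
        )
    return GroupComparison(
        band=band, unit=unit, alpha=alpha, labels=labels,
        metric_results=pd.DataFrame(rows),
    )
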