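"""The two-level nucleoid distribution model.

Nucleoid distribution is separated into two components measured on the same
cell:

* the **array in the mitochondrial population** — how clusters are spread
  across all organelles, including the "empty" ones that carry none: the
  count histogram over {0, 1, 2, 3, >=4} clusters, the empty fraction, and
  cluster densities per organelle, per organelle area and per total
  mitochondrial area;

* the **intramitochondrial longitudinal distribution** — how clusters sit
  along the length of single organelles: per-organelle linear densities
  (clusters per micrometer), pooled normalized arc positions, and an
  ordinary least-squares regression of cluster count on organelle length
  over individual organelles.

The asymmetry is deliberate and is the heart of the model: array statistics
are computed over ALL organelles (empty ones included), while longitudinal
statistics are computed only over the filtered subset (clusters present,
optional length cap).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from ._common import InputError, logger
from .image_io import BinaryMask
from .organelles import OrganelleRecord
from .segmentation import ClusterRecord

#: Maximum centroid-to-label snap distance, in pixels, for clusters whose
#: centroid rounds onto background (mask erosion / rounding artifacts).
_SNAP_RADIUS_PX = 2.0


@dataclass
class ArrayStats:
    """Population-level ("array") statistics over all organelles."""

    n_organelles: int
    count_histogram: Tuple[float, float, float, float, float]  # 0,1,2,3,>=4
    empty_fraction: float
    mean_clusters_per_mito: float
    mean_clusters_per_area: float  # mean over organelles of count/area (per um^2)
    clusters_per_total_area: float  # total in-mask clusters / total area (per um^2)
    total_area_um2: float
    n_assigned_clusters: int
    n_unassigned_clusters: int

    def __post_init__(self) -> None:
        if abs(sum(self.count_histogram) - 1.0) > 1e-9:
            raise InputError("count histogram fractions must sum to 1")
        if abs(self.empty_fraction - self.count_histogram[0]) > 1e-12:
            raise InputError("empty_fraction must equal the zero-count bin")


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r2: float
    p_value: float
    n: int


@dataclass
class LongitudinalStats:
    """Single-organelle ("longitudinal") statistics over filtered organelles."""

    mean_clusters_per_um: float
    per_organelle_density: List[Tuple[int, float]]  # (label, clusters/um)
    arc_positions: List[float]
    regression: Optional[RegressionResult]
    n_organelles: int


def assign_clusters(
    clusters: List[ClusterRecord],
    organelles: List[OrganelleRecord],
    labeled_mask: np.ndarray,
) -> None:
    """Assign each cluster to the organelle under its centroid (in place).

    Centroids that round onto background are snapped to the nearest labeled
    pixel within 2 px, else flagged unassigned. Sets organelle_label and
    arc_position on clusters and cluster_count on organelles. The arc
    position is the absolute arc-length coordinate of the diametral-path
    node nearest the centroid (start-cap offset included), normalized by
    the organelle's length.
    """
    labels_present = set(np.unique(labeled_mask)) - {0}
    record_labels = {o.label for o in organelles}
    if not labels_present <= record_labels:
        raise InputError("labeled mask contains labels missing from the organelle list")

    by_label: Dict[int, OrganelleRecord] = {o.label: o for o in organelles}
    for o in organelles:
        o.cluster_count = 0

    h, w = labeled_mask.shape
    for cl in clusters:
        r = int(round(cl.centroid_px[0]))
        c = int(round(cl.centroid_px[1]))
        r = min(max(r, 0), h - 1)
        c = min(max(c, 0), w - 1)
        lab = int(labeled_mask[r, c])
        if lab == 0:
            lab = _snap_to_label(labeled_mask, cl.centroid_px, _SNAP_RADIUS_PX)
        if lab == 0:
            cl.unassigned = True
            cl.organelle_label = None
            cl.arc_position = None
            continue
        cl.unassigned = False
        cl.organelle_label = lab
        org = by_label[lab]
        org.cluster_count += 1
        cl.arc_position = _arc_position(org, cl.centroid_px)


def _snap_to_label(labeled: np.ndarray, centroid_px, radius: float) -> int:
    r0, c0 = centroid_px
    rad = int(np.ceil(radius))
    h, w = labeled.shape
    rlo, rhi = max(0, int(r0) - rad), min(h, int(r0) + rad + 2)
    clo, chi = max(0, int(c0) - rad), min(w, int(c0) + rad + 2)
    window = labeled[rlo:rhi, clo:chi]
    rows, cols = np.nonzero(window)
    if rows.size == 0:
        return 0
    d2 = (rows + rlo - r0) ** 2 + (cols + clo - c0) ** 2
    best = int(np.argmin(d2))
    if d2[best] > radius**2:
        return 0
    return int(window[rows[best], cols[best]])


def _arc_position(org: OrganelleRecord, centroid_px) -> Optional[float]:
    path = org.path_px
    if path is None or len(path) < 2 or org.length_um <= 0:
        return None
    d2 = ((path - np.asarray(centroid_px)) ** 2).sum(axis=1)
    idx = int(np.argmin(d2))
    # cumulative arc is absolute position along the organelle (start-cap
    # offset included); normalize by full length, clipped for edge nodes
    return float(np.clip(org.path_cumlen_um[idx] / org.length_um, 0.0, 1.0))


def population_array_stats(
    organelles: List[OrganelleRecord],
    clusters: List[ClusterRecord],
    total_mask: BinaryMask,
) -> ArrayStats:
    """Compute array statistics over ALL organelles, empty ones included."""
    if not organelles:
        raise InputError("array statistics need at least one organelle")
    if any(o.cluster_count is None for o in organelles):
        raise InputError("cluster assignment must run before array statistics")
    counts = np.array([o.cluster_count for o in organelles])
    n = len(counts)
    bins = np.array(
        [
            (counts == 0).sum(),
            (counts == 1).sum(),
            (counts == 2).sum(),
            (counts == 3).sum(),
            (counts >= 4).sum(),
        ],
        dtype=float,
    )
    hist = tuple(bins / n)
    n_assigned = int(counts.sum())
    n_unassigned = sum(1 for c in clusters if c.unassigned)
    if n_unassigned:
        logger.info("%d cluster(s) could not be assigned to an organelle", n_unassigned)
    total_area = total_mask.area_um2
    return ArrayStats(
        n_organelles=n,
        count_histogram=hist,
        empty_fraction=hist[0],
        mean_clusters_per_mito=float(counts.mean()),
        mean_clusters_per_area=float(
            np.mean([o.cluster_count / o.area_um2 for o in organelles])
        ),
        clusters_per_total_area=n_assigned / total_area if total_area > 0 else 0.0,
        total_area_um2=total_area,
        n_assigned_clusters=n_assigned,
        n_unassigned_clusters=n_unassigned,
    )


def longitudinal_stats(
    organelles: List[OrganelleRecord],
    clusters: Optional[List[ClusterRecord]] = None,
    min_n_regression: int = 3,
) -> LongitudinalStats:
    """Compute longitudinal statistics over an already-filtered organelle list.

    Regression (count on length, per individual organelle) is marked
    undefined when fewer than ``min_n_regression`` organelles are available
    or lengths are degenerate.
    """
    if any(o.cluster_count is None for o in organelles):
        raise InputError("cluster assignment must run before longitudinal statistics")
    densities = [
        (o.label, o.cluster_count / o.length_um) for o in organelles if o.length_um > 0
    ]
    mean_density = float(np.mean([d for _, d in densities])) if densities else float("nan")

    arc_positions: List[float] = []
    if clusters is not None:
        included = {o.label for o in organelles}
        arc_positions = [
            float(c.arc_position)
            for c in clusters
            if c.organelle_label in included and c.arc_position is not None
        ]

    regression = None
    lengths = np.array([o.length_um for o in organelles if o.length_um > 0])
    counts = np.array([o.cluster_count for o in organelles if o.length_um > 0])
    if len(lengths) >= min_n_regression and np.ptp(lengths) > 0:
        fit = sps.linregress(lengths, counts)
        regression = RegressionResult(
            slope=float(fit.slope),
            intercept=float(fit.intercept),
            r2=float(fit.rvalue**2),
            p_value=float(fit.pvalue),
            n=len(lengths),
        )
    return LongitudinalStats(
        mean_clusters_per_um=mean_density,
        per_organelle_density=densities,
        arc_positions=arc_positions,
        regression=regression,
        n_organelles=len(organelles),
    )


def _scalar_fields(stats) -> Dict[str, float]:
    out = {}
    for name, value in vars(stats).items():
        if isinstance(value, (int, float)) and not isinstance(value, bool):
            out[name] = float(value)
        elif name == "count_histogram":
            for k, frac in zip(("0", "1", "2", "3", "4plus"), value):
                out[f"hist_{k}"] = float(frac)
        elif name == "regression" and value is not None:
            for k in ("slope", "intercept", "r2", "p_value"):
                out[f"regression_{k}"] = float(getattr(value, k))
    return out


def compare_groups(
    stats_per_condition: Dict[str, Sequence],
) -> pd.DataFrame:
    """Descriptive aggregation: per-condition mean and SEM of every scalar
    metric, one row per condition. No hypothesis tests are performed.

    Conditions with a single cell get SEM = NaN and sem_defined = False.
    """
    rows = []
    for condition, cell_stats in stats_per_condition.items():
        if len(cell_stats) == 0:
            raise InputError(f"condition {condition!r} has no cells")
        table = pd.DataFrame([_scalar_fields(s) for s in cell_stats])
        n = len(table)
        row: Dict[str, object] = {"condition": condition, "n_cells": n,
                                  "sem_defined": n > 1}
        for col in table.columns:
            row[f"{col}_mean"] = table[col].mean()
            row[f"{col}_sem"] = table[col].sem() if n > 1 else np.nan
        rows.append(row)
    return pd.DataFrame(rows)
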