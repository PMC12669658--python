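"""Per-event geometry, per-nucleus spatial statistics and group comparisons.

Distances and volumes are always reported in physical units (µm, µm³), so
doubling the voxel spacing at fixed label geometry doubles distances and
multiplies volumes by eight.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.spatial import cKDTree
from scipy.stats import mannwhitneyu, pearsonr

from .events import Event, DUAL_TYPES
from .io import NuclearMask
from .segment import Focus, LabelVolume

__all__ = [
    "EventMetrics",
    "NucleusSummary",
    "GroupComparison",
    "centroid_distance",
    "overlap_ratio",
    "initiation_angle",
    "event_volume",
    "compute_event_metrics",
    "nearest_neighbour_distances",
    "periphery_distances",
    "summarise_nucleus",
    "compare_groups",
    "pearson_colocalization",
]


@dataclass
class EventMetrics:
    event_id: int
    type: str
    nucleus_id: int
    centroid_distance_um: float | None  # ongoing only
    overlap_ratio: float | None         # dual-colour events
    event_volume_um3: float
    angle_deg: float | None             # initiation/termination only


@dataclass
class NucleusSummary:
    nucleus_id: int
    counts: dict
    n_dual: int
    rel_freq_initiation: float | None
    rel_freq_ongoing: float | None
    rel_freq_termination: float | None
    retention_fraction: float
    median_centroid_distance_um: float | None
    median_overlap_ratio: float | None
    median_angle_deg: float | None


@dataclass
class GroupComparison:
    metric: str
    group_labels: tuple
    u_statistic: float
    p_raw: float
    p_adjusted: float
    n_per_group: tuple


# ---------------------------------------------------------------------------
# per-event geometry


def centroid_distance(event: Event, foci_by_id: dict) -> float:
    """Euclidean distance (µm) between the two centroids of an ongoing event."""
    if event.type != "ongoing":
        raise ValueError(f"centroid_distance is defined for ongoing events, "
                         f"got {event.type}")
    a = foci_by_id[("edu", event.edu_focus_ids[0])].centroid_um
    b = foci_by_id[("dutp", event.dutp_focus_ids[0])].centroid_um
    return float(np.linalg.norm(np.subtract(a, b)))


def overlap_ratio(event: Event, labels_edu: LabelVolume,
                  labels_dutp: LabelVolume) -> float:
    """(EdU ∩ dUTP voxels of the event) / (union of all member-foci voxels)."""
    if event.type not in DUAL_TYPES and event.type != "crowded":
        raise ValueError(f"overlap_ratio needs a dual-colour event, got {event.type}")
    in_e = np.isin(labels_edu.labels, event.edu_focus_ids)
    in_d = np.isin(labels_dutp.labels, event.dutp_focus_ids)
    union = int(np.count_nonzero(in_e | in_d))
    inter = int(np.count_nonzero(in_e & in_d))
    return inter / union if union else 0.0


def event_volume(event: Event, labels_edu: LabelVolume,
                 labels_dutp: LabelVolume) -> float:
    """Union voxel count of the member foci × voxel volume (µm³)."""
    in_e = np.isin(labels_edu.labels, event.edu_focus_ids)
    in_d = np.isin(labels_dutp.labels, event.dutp_focus_ids)
    return int(np.count_nonzero(in_e | in_d)) * labels_edu.spacing ** 3


def _vector_angle_deg(v1, v2) -> float:
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 == 0 or n2 == 0:
        raise ValueError("zero-length vector (coincident centroids)")
    cosine = float(np.dot(v1, v2) / (n1 * n2))
    return math.degrees(math.acos(max(-1.0, min(1.0, cosine))))


def initiation_angle(event: Event, foci_by_id: dict) -> float:
    """Angle (degrees) between the two centre→flank centroid vectors.

    For an initiation event the centre focus is the EdU focus and the flanks
    are the two dUTP foci; a termination event is handled symmetrically from
    its dUTP centroid. The cosine is clamped to [-1, 1] before arccos.
    """
    if event.type == "initiation":
        centre = foci_by_id[("edu", event.edu_focus_ids[0])].centroid_um
        flanks = [foci_by_id[("dutp", i)].centroid_um
                  for i in event.dutp_focus_ids]
    elif event.type == "termination":
        centre = foci_by_id[("dutp", event.dutp_focus_ids[0])].centroid_um
        flanks = [foci_by_id[("edu", i)].centroid_um
                  for i in event.edu_focus_ids]
    else:
        raise ValueError(f"angle is defined for initiation/termination events, "
                         f"got {event.type}")
    c = np.asarray(centre)
    return _vector_angle_deg(np.asarray(flanks[0]) - c, np.asarray(flanks[1]) - c)


def compute_event_metrics(events: list, foci_edu: list, foci_dutp: list,
                          labels_edu: LabelVolume,
                          labels_dutp: LabelVolume) -> pd.DataFrame:
    """EventMetrics for every event, as a DataFrame keyed by event_id."""
    foci_by_id = {("edu", f.focus_id): f for f in foci_edu}
    foci_by_id.update({("dutp", f.focus_id): f for f in foci_dutp})
    rows = []
    for ev in events:
        dist = centroid_distance(ev, foci_by_id) if ev.type == "ongoing" else None
        ratio = overlap_ratio(ev, labels_edu, labels_dutp) \
            if ev.type in DUAL_TYPES else None
        ang = initiation_angle(ev, foci_by_id) \
            if ev.type in ("initiation", "termination") else None
        rows.append({
            "event_id": ev.event_id, "type": ev.type,
            "nucleus_id": ev.nucleus_id,
            "centroid_distance_um": dist, "overlap_ratio": ratio,
            "event_volume_um3": event_volume(ev, labels_edu, labels_dutp),
            "angle_deg": ang,
        })
    cols = ["event_id", "type", "nucleus_id", "centroid_distance_um",
            "overlap_ratio", "event_volume_um3", "angle_deg"]
    return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------------------
# spatial statistics


def nearest_neighbour_distances(points_a, points_b=None) -> np.ndarray:
    """Per-point nearest-neighbour distance from set A to set B (µm).

    With ``points_b=None`` the within-set distance is computed, excluding
    self. Call twice (A→B and B→A) for the reciprocal analysis.
    """
    a = np.atleast_2d(np.asarray(points_a, float))
    if points_b is None:
        if len(a) < 2:
            raise ValueError("within-set nearest neighbour needs >= 2 points")
        d, _ = cKDTree(a).query(a, k=2)
        return d[:, 1]
    b = np.atleast_2d(np.asarray(points_b, float))
    if len(b) == 0:
        raise ValueError("empty target set")
    d, _ = cKDTree(b).query(a, k=1)
    return np.atleast_1d(d)


def periphery_distances(centroids_yx_um, nucleus_ids, mask: NuclearMask) -> np.ndarray:
    """In-plane distance (µm) from each focus to its nucleus boundary.

    Computed as the 2D Euclidean distance transform of the focus's own
    nucleus interior, sampled at the focus centroid pixel.
    """
    pts = np.atleast_2d(np.asarray(centroids_yx_um, float))
    nucleus_ids = np.asarray(nucleus_ids, int)
    dy, dx = mask.pixel_spacing
    edts = {}
    out = np.empty(len(pts))
    for i, ((y, x), nuc) in enumerate(zip(pts, nucleus_ids)):
        if nuc not in edts:
            edts[nuc] = ndi.distance_transform_edt(mask.labels == nuc,
                                                   sampling=(dy, dx))
        iy = int(np.clip(round(y / dy - 0.5), 0, mask.labels.shape[0] - 1))
        ix = int(np.clip(round(x / dx - 0.5), 0, mask.labels.shape[1] - 1))
        if mask.labels[iy, ix] != nuc:
            raise ValueError(f"centroid ({y:.3f},{x:.3f}) µm falls outside "
                             f"nucleus {nuc}")
        out[i] = edts[nuc][iy, ix]
    return out


def summarise_nucleus(nucleus_id: int, events: list, metrics: pd.DataFrame,
                      retention_fraction: float = 0.0) -> NucleusSummary:
    """Counts, dual-event relative frequencies and median geometry metrics."""
    evs = [e for e in events if e.nucleus_id == nucleus_id]
    counts = {}
    for e in evs:
        counts[e.type] = counts.get(e.type, 0) + 1
    n_dual = sum(counts.get(t, 0) for t in DUAL_TYPES)
    if n_dual > 0:
        rel = {t: counts.get(t, 0) / n_dual for t in DUAL_TYPES}
    else:
        rel = {t: None for t in DUAL_TYPES}
    m = metrics[metrics["nucleus_id"] == nucleus_id] if len(metrics) else metrics

    def _median(col):
        if not len(m):
            return None
        vals = m[col].dropna()
        return float(vals.median()) if len(vals) else None

    return NucleusSummary(
        nucleus_id=nucleus_id, counts=counts, n_dual=n_dual,
        rel_freq_initiation=rel["initiation"],
        rel_freq_ongoing=rel["ongoing"],
        rel_freq_termination=rel["termination"],
        retention_fraction=retention_fraction,
        median_centroid_distance_um=_median("centroid_distance_um"),
        median_overlap_ratio=_median("overlap_ratio"),
        median_angle_deg=_median("angle_deg"),
    )


def summaries_frame(summaries: list) -> pd.DataFrame:
    rows = []
    for s in summaries:
        row = {"nucleus_id": s.nucleus_id, "n_dual": s.n_dual,
               "retention_fraction": s.retention_fraction,
               "rel_freq_initiation": s.rel_freq_initiation,
               "rel_freq_ongoing": s.rel_freq_ongoing,
               "rel_freq_termination": s.rel_freq_termination,
               "median_centroid_distance_um": s.median_centroid_distance_um,
               "median_overlap_ratio": s.median_overlap_ratio,
               "median_angle_deg": s.median_angle_deg}
        for t in ("single_colour", "ongoing", "initiation", "termination",
                  "crowded"):
            row[f"n_{t}"] = s.counts.get(t, 0)
        rows.append(row)
    cols = ["nucleus_id", "n_single_colour", "n_ongoing", "n_initiation",
            "n_termination", "n_crowded", "n_dual", "rel_freq_initiation",
            "rel_freq_ongoing", "rel_freq_termination", "retention_fraction",
            "median_centroid_distance_um", "median_overlap_ratio",
            "median_angle_deg"]
    return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------------------
# statistics


def compare_groups(values_a, values_b, labels=("a", "b"), metric="",
                   n_tests: int = 1) -> GroupComparison:
    """Two-sided Mann–Whitney U with Bonferroni adjustment.

    The exact null distribution is used for small tie-free samples
    (both n ≤ 8); otherwise the normal approximation with tie correction.
    p_adjusted = min(1, p_raw × n_tests).
    """
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    method = "exact" if (len(a) <= 8 and len(b) <= 8 and not ties) \
        else "asymptotic"
    res = mannwhitneyu(a, b, alternative="two-sided", method=method)
    p = float(res.pvalue)
    return GroupComparison(
        metric=metric, group_labels=tuple(labels),
        u_statistic=float(res.statistic), p_raw=p,
        p_adjusted=min(1.0, p * n_tests),
        n_per_group=(len(a), len(b)),
    )


def pearson_colocalization(projection_a, projection_b, mask=None) -> float:
    """Pearson R between two 2D projections over the masked pixels.

    No intensity threshold is applied. Raises on zero-variance input.
    """
    a = np.asarray(projection_a, float)
    b = np.asarray(projection_b, float)
    if a.shape != b.shape:
        raise ValueError("projections must share shape")
    if mask is not None:
        sel = np.asarray(mask) > 0
        a, b = a[sel], b[sel]
    else:
        a, b = a.ravel(), b.ravel()
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero-variance channel")
    return float(pearsonr(a, b).statistic)
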