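"""Inter-channel overlap graph and replication-event classification.

Foci segmented in the two nascent-DNA channels are compared voxel-by-voxel.
Each pair of labels sharing at least one voxel is an overlap; overlaps are
pruned relative to the *largest* overlap of each focus (keep only overlaps
exceeding 20% of that maximum), and the connected components of the
resulting bipartite graph are classified:

====================  =====================================================
single_colour         isolated focus (either channel)
ongoing               1 EdU focus — 1 dUTP focus, one edge
initiation            1 EdU focus overlapping 2 dUTP foci that overlap
                      only that EdU focus (a 2-edge star)
termination           1 dUTP focus overlapping 2 EdU foci (mirror star)
crowded               anything else, incl. components of >3 foci
====================  =====================================================

Exclusivity in the initiation/termination definitions is enforced on the
kept-edge graph (overlaps are pruned first, then classified).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .io import AnalysisConfig, EVENT_COLUMNS, format_id_list
from .segment import LabelVolume

__all__ = [
    "OverlapRecord",
    "Event",
    "RetentionReport",
    "compute_overlaps",
    "select_overlaps",
    "build_components",
    "classify_component",
    "classify_events",
    "events_frame",
]

DUAL_TYPES = ("initiation", "ongoing", "termination")


@dataclass
class OverlapRecord:
    """One inter-channel label overlap with per-endpoint relative scores."""

    focus_a: int  # EdU-channel label
    focus_b: int  # dUTP-channel label
    overlap_voxels: int
    rel_score_a: float = 1.0  # overlap / max overlap of focus_a
    rel_score_b: float = 1.0
    kept: bool = True


@dataclass
class Event:
    event_id: int
    nucleus_id: int
    type: str
    edu_focus_ids: tuple
    dutp_focus_ids: tuple

    @property
    def n_foci(self) -> int:
        return len(self.edu_focus_ids) + len(self.dutp_focus_ids)


@dataclass
class RetentionReport:
    """Fraction of detected foci landing in dual-colour events, per nucleus."""

    per_nucleus: dict = field(default_factory=dict)  # nucleus -> (dual, total)

    def fraction(self, nucleus_id=None) -> float:
        if nucleus_id is None:
            dual = sum(d for d, _ in self.per_nucleus.values())
            total = sum(t for _, t in self.per_nucleus.values())
        else:
            dual, total = self.per_nucleus.get(nucleus_id, (0, 0))
        return dual / total if total else 0.0


def compute_overlaps(labels_edu: LabelVolume, labels_dutp: LabelVolume) -> list:
    """Exact voxel overlap counts for every inter-channel label pair."""
    a, b = labels_edu.labels, labels_dutp.labels
    if a.shape != b.shape:
        raise ValueError(f"label volumes differ in shape: {a.shape} vs {b.shape}")
    m = (a > 0) & (b > 0)
    if not m.any():
        return []
    pairs = np.stack([a[m], b[m]], axis=1)
    uniq, counts = np.unique(pairs, axis=0, return_counts=True)
    return [OverlapRecord(int(fa), int(fb), int(n))
            for (fa, fb), n in zip(uniq, counts)]


def select_overlaps(records: list, rel_threshold: float = 0.20,
                    rule: str = "and") -> list:
    """Score overlaps relative to each focus's maximum and flag keepers.

    For each focus, its largest overlap defines the maximum; an overlap's
    relative score is overlap / max. A record is kept iff its size is
    strictly greater than ``rel_threshold`` × the maximum. With
    ``rule="and"`` (default) the criterion must hold from both endpoints'
    perspectives; ``rule="or"`` keeps records passing from either side.
    Ties for the maximum score 1 and are always kept.
    """
    if rule not in ("and", "or"):
        raise ValueError("rule must be 'and' or 'or'")
    max_a, max_b = {}, {}
    for r in records:
        max_a[r.focus_a] = max(max_a.get(r.focus_a, 0), r.overlap_voxels)
        max_b[r.focus_b] = max(max_b.get(r.focus_b, 0), r.overlap_voxels)
    out = []
    for r in records:
        sa = r.overlap_voxels / max_a[r.focus_a]
        sb = r.overlap_voxels / max_b[r.focus_b]
        pass_a = r.overlap_voxels > rel_threshold * max_a[r.focus_a]
        pass_b = r.overlap_voxels > rel_threshold * max_b[r.focus_b]
        kept = (pass_a and pass_b) if rule == "and" else (pass_a or pass_b)
        out.append(OverlapRecord(r.focus_a, r.focus_b, r.overlap_voxels,
                                 rel_score_a=sa, rel_score_b=sb, kept=kept))
    return out


def build_components(edu_ids, dutp_ids, records) -> list:
    """Connected components of the bipartite focus graph.

    Nodes are ("edu", id) / ("dutp", id); kept overlap records are edges.
    Isolated foci form singleton components. Returns a list of
    (edu_set, dutp_set, edges) tuples, deterministically ordered.
    """
    g = nx.Graph()
    g.add_nodes_from(("edu", int(i)) for i in edu_ids)
    g.add_nodes_from(("dutp", int(i)) for i in dutp_ids)
    for r in records:
        if not r.kept:
            continue
        for side, fid in (("edu", r.focus_a), ("dutp", r.focus_b)):
            if (side, int(fid)) not in g:
                raise ValueError(f"overlap references unknown focus {side}:{fid}")
        g.add_edge(("edu", int(r.focus_a)), ("dutp", int(r.focus_b)))
    comps = []
    for nodes in nx.connected_components(g):
        edu = frozenset(i for s, i in nodes if s == "edu")
        dutp = frozenset(i for s, i in nodes if s == "dutp")
        edges = frozenset((u[1], v[1]) if u[0] == "edu" else (v[1], u[1])
                          for u, v in g.subgraph(nodes).edges)
        comps.append((edu, dutp, edges))
    comps.sort(key=lambda c: (min(c[0]) if c[0] else -1,
                              min(c[1]) if c[1] else -1))
    return comps


def classify_component(edu_set, dutp_set, edges,
                       max_foci_per_event: int = 3) -> str:
    """Map one component to its event type (see module docstring)."""
    n_e, n_d = len(edu_set), len(dutp_set)
    if n_e + n_d == 0:
        raise ValueError("empty component")
    if n_e + n_d == 1:
        return "single_colour"
    if n_e + n_d > max_foci_per_event:
        return "crowded"
    if n_e == 1 and n_d == 1 and len(edges) == 1:
        return "ongoing"
    if n_e == 1 and n_d == 2 and len(edges) == 2:
        return "initiation"  # the 2 dUTP foci link only to the single EdU
    if n_e == 2 and n_d == 1 and len(edges) == 2:
        return "termination"
    return "crowded"


def classify_events(foci_edu: list, foci_dutp: list, records: list,
                    config: AnalysisConfig | None = None):
    """Prune overlaps, build components, classify, and report retention.

    ``foci_edu`` / ``foci_dutp`` are :class:`~spark3d.segment.Focus` lists.
    Returns ``(events, retention)``: every retained focus belongs to exactly
    one event; retention is the per-nucleus fraction of foci that end up in
    dual-colour (initiation/ongoing/termination) events.
    """
    config = config or AnalysisConfig()
    selected = select_overlaps(records, config.overlap_rel_threshold,
                               config.overlap_rule)
    edu_by_id = {f.focus_id: f for f in foci_edu}
    dutp_by_id = {f.focus_id: f for f in foci_dutp}
    comps = build_components(edu_by_id.keys(), dutp_by_id.keys(), selected)
    events = []
    for i, (edu, dutp, edges) in enumerate(comps, start=1):
        etype = classify_component(edu, dutp, edges, config.max_foci_per_event)
        members = [edu_by_id[j] for j in sorted(edu)] + \
                  [dutp_by_id[j] for j in sorted(dutp)]
        nucleus = members[0].nucleus_id
        events.append(Event(event_id=i, nucleus_id=nucleus, type=etype,
                            edu_focus_ids=tuple(sorted(edu)),
                            dutp_focus_ids=tuple(sorted(dutp))))
    retention = RetentionReport()
    per = {}
    for ev in events:
        members = [edu_by_id[j] for j in ev.edu_focus_ids] + \
                  [dutp_by_id[j] for j in ev.dutp_focus_ids]
        for f in members:
            dual, total = per.get(f.nucleus_id, (0, 0))
            per[f.nucleus_id] = (dual + (ev.type in DUAL_TYPES), total + 1)
    retention.per_nucleus = per
    return events, retention


def events_frame(events: list) -> pd.DataFrame:
    rows = [{
        "event_id": ev.event_id, "nucleus_id": ev.nucleus_id, "type": ev.type,
        "edu_focus_ids": format_id_list(ev.edu_focus_ids),
        "dutp_focus_ids": format_id_list(ev.dutp_focus_ids),
    } for ev in events]
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)
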