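"""Topological-height analytics over a staged reconstruction timeline.

The topological height (TH) of a node measures how much structure hangs
below it: tips have TH = 1 and each branching point adds 1 to the highest TH
among its children (pass-through nodes inherit their child's TH, so TH is a
branch-level quantity, invariant under resampling).  Normalizing by the
maximum TH observed across the reconstruction stages of the same neuron
yields NTH in (0, 1], which makes error locations comparable across neurons:
an unmatched structure at high NTH is an error that would be expensive to
correct.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .collab import EditLog, replay, state_to_tree
from .compare import sample_arc_elements
from .swc import NeuronTree


@dataclass
class StageSeries:
    """Snapshots of a reconstruction at evenly spaced cuts of its timeline."""

    stages: list  # list of NeuronTree
    timeline: tuple  # (start, end) timestamps
    cut_times: list = field(default_factory=list)

    @property
    def n_stages(self) -> int:
        return len(self.stages)


@dataclass
class NTHTable:
    """Per-stage matched/unmatched length accumulated into NTH bins."""

    bin_edges: np.ndarray  # len bins+1, spanning (0, 1]
    matched: np.ndarray  # (n_stages, bins)
    unmatched: np.ndarray  # (n_stages, bins)
    max_th: int
    node_nth: list = field(default_factory=list)  # per stage: {node id: NTH}


def topological_height(tree: NeuronTree) -> dict:
    """Map node id -> TH.  Tips are 1; a branching point is 1 + the max TH of
    its children; pass-through nodes inherit the child maximum."""
    if not tree.nodes:
        return {}
    ch = tree.children_map()
    th: dict = {}
    # iterative post-order over all roots/fragments
    for start in (n.id for n in tree.roots()):
        stack = [(start, False)]
        while stack:
            nid, expanded = stack.pop()
            kids = ch.get(nid, [])
            if not kids:
                th[nid] = 1
                continue
            if not expanded:
                stack.append((nid, True))
                stack.extend((k, False) for k in kids)
            else:
                m = max(th[k] for k in kids)
                th[nid] = m + 1 if len(kids) >= 2 else m
    return th


def stage_snapshots(log: EditLog, n_stages: int = 8) -> StageSeries:
    """Recover the reconstruction at ``n_stages`` evenly spaced moments.

    Cut i sits at t_first + i * span / n_stages; the snapshot replays every
    add/delete event at or before the cut (confirmations do not change
    geometry).
    """
    if not log.events:
        raise ValueError("cannot stage an empty edit log")
    times = [e.timestamp for e in log.events]
    t0, t1 = min(times), max(times)
    span = t1 - t0
    cuts = [t0 + (i + 1) * span / n_stages for i in range(n_stages)]
    stages = [state_to_tree(replay(log, until=c)) for c in cuts]
    return StageSeries(stages=stages, timeline=(t0, t1), cut_times=cuts)


def _tree_max_th(tree: NeuronTree) -> int:
    th = topological_height(tree)
    return max(th.values()) if th else 0


def normalized_topological_height(series: StageSeries) -> list:
    """Per-stage mapping node id -> NTH = TH / max TH over all stages."""
    maxima = [_tree_max_th(t) for t in series.stages]
    denom = max(maxima) if maxima else 0
    if denom == 0:
        raise ValueError("all stages empty: NTH undefined")
    return [
        {nid: th / denom for nid, th in topological_height(t).items()}
        for t in series.stages
    ]


def matched_unmatched_by_nth(
    series: StageSeries,
    ref: NeuronTree,
    bins: int = 10,
    dist_threshold: float = 2.0,
) -> NTHTable:
    """Per stage, split arc length into matched/unmatched against ``ref`` and
    accumulate it into NTH bins.

    Each resampled arc element inherits the TH of the resampled node ending
    its edge (TH is resampling-invariant); the NTH denominator is the global
    maximum TH across stages.
    """
    if len(ref.nodes) == 0:
        raise ValueError("reference tree must be non-empty")
    denom = max((_tree_max_th(t) for t in series.stages), default=0)
    if denom == 0:
        raise ValueError("all stages empty: NTH undefined")
    step = min(1.0, dist_threshold / 2.0)
    ref_pos = sample_arc_elements(ref, step)[2]
    ref_tree = cKDTree(ref_pos)
    edges = np.linspace(0.0, 1.0, bins + 1)
    matched = np.zeros((series.n_stages, bins))
    unmatched = np.zeros((series.n_stages, bins))
    node_nth = []
    for si, stage in enumerate(series.stages):
        if len(stage.nodes) == 0:
            node_nth.append({})
            continue
        mids, lengths, _, rs = sample_arc_elements(stage, step)
        th = topological_height(rs)
        node_nth.append({nid: v / denom for nid, v in th.items()})
        if len(mids) == 0:
            continue
        child_ids = [c.id for _, c in rs.edges()]
        nth = np.array([th[c] for c in child_ids], dtype=float) / denom
        d, _ = ref_tree.query(mids)
        ok = d <= dist_threshold
        # NTH lies in (0, 1]; bin index via right-closed intervals
        bi = np.clip(np.searchsorted(edges, nth, side="left") - 1, 0, bins - 1)
        np.add.at(matched[si], bi[ok], lengths[ok])
        np.add.at(unmatched[si], bi[~ok], lengths[~ok])
    return NTHTable(
        bin_edges=edges, matched=matched, unmatched=unmatched,
        max_th=denom, node_nth=node_nth,
    )
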