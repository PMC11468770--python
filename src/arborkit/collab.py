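"""Collaborative reconstruction protocol: state machine, simulator, analyses.

Several annotators jointly trace one neuron.  The atomic unit is a *segment*
(a polyline neurite between topological events).  Four rules govern edits:

1. a user may add a segment only where it originates from the soma, from a
   segment of their own, or from a segment that has been confirmed;
2. a user may confirm / delete / modify a segment made by *another* user only
   if that segment originates from the soma or extends an already confirmed
   segment;
3. no user may confirm their own segment;
4. the reconstruction is complete only when every remaining segment has been
   confirmed.

A *modify* is represented as a delete + re-add pair sharing a lineage id.
The edit log (time-ordered events) supports replay at any moment, which is
what stage-wise analyses and the collaborative-vs-noncollaborative contrast
are built on.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from .compare import sample_arc_elements
from .swc import SOMA as SOMA_TYPE
from .swc import AXON, NeuronNode, NeuronTree

SOMA_ATTACH = "SOMA"


class ProtocolViolation(Exception):
    """Raised when an event breaks a protocol rule; the state is unchanged.

    ``kind`` is one of ``self_confirm``, ``unanchored_add``,
    ``unconfirmed_parent``, ``unknown_segment``.
    """

    def __init__(self, kind: str, message: str):
        super().__init__(f"{kind}: {message}")
        self.kind = kind


@dataclass
class AnnotationEvent:
    timestamp: float
    user: str
    action: str  # "add" | "delete" | "confirm"
    segment_id: str
    segment_geometry: Optional[list] = None  # list of (x, y, z, radius) for adds
    parent_attachment: Union[str, tuple, None] = None  # SOMA or (segment_id, index)
    lineage: Optional[str] = None  # shared by the delete+add halves of a modify

    def to_json(self) -> str:
        d = {
            "v": 1,
            "t": self.timestamp,
            "user": self.user,
            "action": self.action,
            "segment_id": self.segment_id,
        }
        if self.segment_geometry is not None:
            d["geometry"] = [list(p) for p in self.segment_geometry]
        if self.parent_attachment is not None:
            d["parent"] = (
                self.parent_attachment
                if self.parent_attachment == SOMA_ATTACH
                else list(self.parent_attachment)
            )
        if self.lineage is not None:
            d["lineage"] = self.lineage
        return json.dumps(d, sort_keys=True)

    @classmethod
    def from_json(cls, line: str) -> "AnnotationEvent":
        d = json.loads(line)
        parent = d.get("parent")
        if isinstance(parent, list):
            parent = (parent[0], int(parent[1]))
        geom = d.get("geometry")
        if geom is not None:
            geom = [tuple(p) for p in geom]
        return cls(
            timestamp=float(d["t"]),
            user=d["user"],
            action=d["action"],
            segment_id=d["segment_id"],
            segment_geometry=geom,
            parent_attachment=parent,
            lineage=d.get("lineage"),
        )


@dataclass
class Segment:
    geometry: list  # [(x, y, z, r), ...]
    author: str
    parent: Union[str, tuple]  # SOMA or (segment_id, node_index)
    status: str = "unvalidated"  # unvalidated | confirmed | deleted
    confirmer: Optional[str] = None

    def attachment_point(self, state: "ProtocolState") -> np.ndarray:
        if self.parent == SOMA_ATTACH:
            return np.array(state.soma[:3], dtype=float)
        sid, idx = self.parent
        return np.array(state.segments[sid].geometry[idx][:3], dtype=float)

    def length(self, state: "ProtocolState") -> float:
        pts = np.vstack(
            [self.attachment_point(state)]
            + [np.array(p[:3], dtype=float) for p in self.geometry]
        )
        return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())


@dataclass
class ProtocolState:
    """Mutable reconstruction state: a soma plus attributed segments."""

    soma: tuple = (0.0, 0.0, 0.0, 1.0)  # x, y, z, radius
    segments: dict = field(default_factory=dict)  # id -> Segment

    def live_segments(self) -> dict:
        return {k: s for k, s in self.segments.items() if s.status != "deleted"}


@dataclass
class EditLog:
    events: list = field(default_factory=list)
    ground_truth: Optional[NeuronTree] = None
    soma: tuple = (0.0, 0.0, 0.0, 1.0)

    def write_jsonl(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(json.dumps({"v": 1, "soma": list(self.soma)}, sort_keys=True) + "\n")
            for e in self.events:
                fh.write(e.to_json() + "\n")

    @classmethod
    def read_jsonl(cls, path) -> "EditLog":
        with open(path) as fh:
            lines = [ln for ln in fh if ln.strip()]
        header = json.loads(lines[0])
        events = [AnnotationEvent.from_json(ln) for ln in lines[1:]]
        return cls(events=events, soma=tuple(header.get("soma", (0, 0, 0, 1))))

    @classmethod
    def read_csv(cls, path) -> "EditLog":
        """Import events from CSV.

        Columns: timestamp, user, action, segment_id, parent, geometry,
        lineage.  ``parent`` is SOMA or ``segment_id:index``; ``geometry``
        packs nodes as ``x y z r`` separated by ``;``.
        """
        import csv

        events = []
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                parent = row.get("parent") or None
                if parent and parent != SOMA_ATTACH:
                    sid, idx = parent.rsplit(":", 1)
                    parent = (sid, int(idx))
                geom_txt = row.get("geometry") or ""
                geom = [
                    tuple(float(v) for v in pt.split())
                    for pt in geom_txt.split(";")
                    if pt.strip()
                ] or None
                events.append(
                    AnnotationEvent(
                        timestamp=float(row["timestamp"]),
                        user=row["user"],
                        action=row["action"],
                        segment_id=row["segment_id"],
                        segment_geometry=geom,
                        parent_attachment=parent,
                        lineage=row.get("lineage") or None,
                    )
                )
        return cls(events=events)


# ---------------------------------------------------------------------------
# The state machine


def _anchored(state: ProtocolState, seg: Segment) -> bool:
    """Rule-2 anchor: the segment originates from the soma or extends a
    confirmed segment."""
    if seg.parent == SOMA_ATTACH:
        return True
    return state.segments[seg.parent[0]].status == "confirmed"


def apply_event(state: ProtocolState, event: AnnotationEvent) -> ProtocolState:
    """Apply one annotation event in place, enforcing the protocol rules.

    Returns the state for chaining.  On violation a :class:`ProtocolViolation`
    is raised and the state is untouched.
    """
    if event.action == "add":
        if event.segment_id in state.segments:
            raise ProtocolViolation(
                "unknown_segment", f"segment id {event.segment_id} already used"
            )
        if not event.segment_geometry:
            raise ProtocolViolation("unanchored_add", "add without geometry")
        parent = event.parent_attachment
        if parent is None:
            raise ProtocolViolation("unanchored_add", "add without attachment")
        if parent != SOMA_ATTACH:
            sid, idx = parent
            pseg = state.segments.get(sid)
            if pseg is None or pseg.status == "deleted":
                raise ProtocolViolation("unknown_segment", f"parent {sid} not live")
            if not (0 <= idx < len(pseg.geometry)):
                raise ProtocolViolation(
                    "unknown_segment", f"parent node index {idx} out of range"
                )
            if pseg.author != event.user and pseg.status != "confirmed":
                raise ProtocolViolation(
                    "unconfirmed_parent",
                    f"{event.user} may not extend unconfirmed segment {sid} "
                    f"authored by {pseg.author}",
                )
        state.segments[event.segment_id] = Segment(
            geometry=list(event.segment_geometry),
            author=event.user,
            parent=parent,
        )
        return state

    seg = state.segments.get(event.segment_id)
    if seg is None or seg.status == "deleted":
        raise ProtocolViolation(
            "unknown_segment", f"segment {event.segment_id} not live"
        )

    if event.action == "confirm":
        if event.user == seg.author:
            raise ProtocolViolation(
                "self_confirm", f"{event.user} may not confirm their own segment"
            )
        if not _anchored(state, seg):
            raise ProtocolViolation(
                "unconfirmed_parent",
                f"segment {event.segment_id} does not extend a confirmed segment",
            )
        seg.status = "confirmed"
        seg.confirmer = event.user
        return state

    if event.action == "delete":
        # deleting one's own work is always permitted; cross-user deletion
        # requires the rule-2 anchor condition
        if event.user != seg.author and not _anchored(state, seg):
            raise ProtocolViolation(
                "unconfirmed_parent",
                f"{event.user} may not delete unanchored segment "
                f"{event.segment_id} authored by {seg.author}",
            )
        _delete_cascade(state, event.segment_id)
        return state

    raise ProtocolViolation("unknown_segment", f"unknown action {event.action!r}")


def _delete_cascade(state: ProtocolState, seg_id: str) -> None:
    """Delete a segment and every live descendant attached through it."""
    stack = [seg_id]
    while stack:
        sid = stack.pop()
        state.segments[sid].status = "deleted"
        for cid, c in state.segments.items():
            if (
                c.status != "deleted"
                and c.parent != SOMA_ATTACH
                and c.parent[0] == sid
            ):
                stack.append(cid)


def is_complete(state: ProtocolState) -> bool:
    """Rule 4: complete when every live segment has been confirmed."""
    return all(s.status == "confirmed" for s in state.live_segments().values())


def agreement(state: ProtocolState) -> float:
    """Fraction of live reconstructed length that has been confirmed by a
    collaborator (confirmed implies touched by >= 2 distinct users)."""
    live = state.live_segments()
    if not live:
        raise ValueError("agreement undefined: no live segments")
    total = sum(s.length(state) for s in live.values())
    confirmed = sum(s.length(state) for s in live.values() if s.status == "confirmed")
    return confirmed / total if total > 0 else 1.0


# ---------------------------------------------------------------------------
# Replay


def replay(log: EditLog, until: Optional[float] = None) -> ProtocolState:
    """Replay events with timestamp <= ``until`` through the state machine."""
    state = ProtocolState(soma=log.soma)
    for e in log.events:
        if until is not None and e.timestamp > until:
            break
        apply_event(state, e)
    return state


def replay_raw(
    log: EditLog, ignore: Sequence[int] = (), until: Optional[float] = None
) -> ProtocolState:
    """Replay add/delete events without protocol validation, skipping event
    indices in ``ignore`` and any event whose references are missing.

    Used for counterfactual replays (e.g. revoking cross-user edits) where
    skipped events can leave later ones dangling.
    """
    ignore = set(ignore)
    state = ProtocolState(soma=log.soma)
    for i, e in enumerate(log.events):
        if until is not None and e.timestamp > until:
            break
        if i in ignore:
            continue
        if e.action == "add":
            parent = e.parent_attachment
            if parent != SOMA_ATTACH:
                pseg = state.segments.get(parent[0])
                if pseg is None or pseg.status == "deleted":
                    continue
            if e.segment_id in state.segments:
                continue
            state.segments[e.segment_id] = Segment(
                geometry=list(e.segment_geometry), author=e.user, parent=parent
            )
        elif e.action == "delete":
            seg = state.segments.get(e.segment_id)
            if seg is not None and seg.status != "deleted":
                _delete_cascade(state, e.segment_id)
        elif e.action == "confirm":
            seg = state.segments.get(e.segment_id)
            if seg is not None and seg.status != "deleted":
                seg.status = "confirmed"
                seg.confirmer = e.user
    return state


def state_to_tree(state: ProtocolState) -> NeuronTree:
    """Materialize the live segments as a NeuronTree rooted at the soma."""
    nodes = [
        NeuronNode(1, SOMA_TYPE, *map(float, state.soma[:3]), float(state.soma[3]), -1)
    ]
    next_id = 2
    node_of: dict = {}  # (segment_id, node_index) -> tree node id
    live = state.live_segments()
    resolved: set = set()
    # insertion order is creation order, so parents come first; loop until
    # no progress in case of odd orderings
    pending = list(live.items())
    while pending:
        progressed = False
        rest = []
        for sid, seg in pending:
            if seg.parent == SOMA_ATTACH:
                parent_node = 1
            elif seg.parent[0] in resolved:
                parent_node = node_of[(seg.parent[0], seg.parent[1])]
            elif seg.parent[0] not in live:
                continue  # dangling after a counterfactual replay; drop
            else:
                rest.append((sid, seg))
                continue
            for j, p in enumerate(seg.geometry):
                nodes.append(
                    NeuronNode(
                        next_id, AXON, float(p[0]), float(p[1]), float(p[2]),
                        float(p[3]), parent_node,
                    )
                )
                node_of[(sid, j)] = next_id
                parent_node = next_id
                next_id += 1
            resolved.add(sid)
            progressed = True
        if not progressed:
            break
        pending = rest
    return NeuronTree(nodes, unit="um")


def revoke_cross_edits(log: EditLog) -> NeuronTree:
    """The noncollaborative counterfactual: replay as if modifications made
    by one user to another's segments never happened.

    Every cross-user delete is revoked, and for a cross-user *modify*
    (delete + re-add sharing a lineage) the replacement add is revoked too.
    """
    ignored: set = set()
    revoked_lineages: set = set()
    shadow = ProtocolState(soma=log.soma)
    for i, e in enumerate(log.events):
        if e.action == "delete":
            seg = shadow.segments.get(e.segment_id)
            if seg is not None and e.user != seg.author:
                ignored.add(i)
                if e.lineage is not None:
                    revoked_lineages.add((e.lineage, e.user))
        elif e.action == "add":
            if e.lineage is not None and (e.lineage, e.user) in revoked_lineages:
                ignored.add(i)
        # maintain the shadow state so authorship lookups see live segments
        try:
            if i not in ignored:
                apply_event(shadow, e)
        except ProtocolViolation:
            pass
    return state_to_tree(replay_raw(log, ignore=ignored))


# ---------------------------------------------------------------------------
# Simulator


def _truth_branches(truth: NeuronTree):
    """Decompose a tree into branches between topological nodes.

    Returns a list of dicts: {id, parent_branch (or None for soma-attached),
    parent_index (node index within parent branch geometry, or None),
    geometry [(x, y, z, r), ...]} — geometry excludes the attachment node.
    """
    nm = truth.node_map()
    ch = truth.children_map()
    root = truth.root
    topo = {
        n.id
        for n in truth.nodes
        if n.id == root.id or len(ch.get(n.id, [])) != 1
    }
    branches = []
    branch_of_end: dict = {}  # topo node id -> (branch index, node index)
    stack = [root.id]
    while stack:
        top = stack.pop()
        for child in ch.get(top, []):
            run = [nm[child]]
            while run[-1].id not in topo:
                run.append(nm[ch[run[-1].id][0]])
            end = run[-1]
            if top == root.id:
                pb, pi = None, None
            else:
                pb, pi = branch_of_end[top]
            bid = len(branches)
            branches.append(
                {
                    "id": bid,
                    "parent_branch": pb,
                    "parent_index": pi,
                    "geometry": [(n.x, n.y, n.z, n.radius) for n in run],
                }
            )
            branch_of_end[end.id] = (bid, len(run) - 1)
            stack.append(end.id)
    return branches


def simulate_collaboration(
    truth: NeuronTree,
    annotators: Sequence[dict],
    seed: int,
    turn_cap_factor: int = 50,
) -> EditLog:
    """Simulate round-robin collaborative tracing of ``truth``.

    Each annotator is a dict with ``error_rate`` (probability a tracing turn
    produces a spurious or perturbed segment instead of a correct one) and
    ``confirm_diligence`` (probability a review of an erroneous segment
    deletes/repairs it rather than wrongly confirming).  Every event passes
    the protocol state machine; timestamps are turn indices, so the log is
    fully reproducible from the seed.
    """
    if len(annotators) < 2:
        raise ValueError(
            "at least 2 annotators required: no user may confirm their own work"
        )
    rng = np.random.default_rng(seed)
    root = truth.root
    soma = (root.x, root.y, root.z, root.radius)
    branches = _truth_branches(truth)
    users = [f"user{i + 1}" for i in range(len(annotators))]
    params = {u: a for u, a in zip(users, annotators)}

    state = ProtocolState(soma=soma)
    log = EditLog(events=[], ground_truth=truth, soma=soma)
    seg_counter = [0]
    # bookkeeping outside the protocol: segment id -> (kind, branch id)
    seg_meta: dict = {}
    branch_seg: dict = {}  # branch id -> live segment id (traced branches)

    def new_sid():
        seg_counter[0] += 1
        return f"s{seg_counter[0]}"

    def do(event):
        apply_event(state, event)
        log.events.append(event)

    def attachment_for(branch):
        if branch["parent_branch"] is None:
            return SOMA_ATTACH
        psid = branch_seg.get(branch["parent_branch"])
        if psid is None or state.segments[psid].status == "deleted":
            return None
        pseg = state.segments[psid]
        idx = min(branch["parent_index"], len(pseg.geometry) - 1)
        return (psid, idx)

    def mark_deleted_branches():
        for bid, sid in list(branch_seg.items()):
            if state.segments[sid].status == "deleted":
                del branch_seg[bid]

    n_branches = len(branches)
    cap = turn_cap_factor * max(1, n_branches)
    for turn in range(1, cap + 1):
        user = users[(turn - 1) % len(users)]
        p = params[user]
        t = float(turn)

        reviewable = [
            sid
            for sid, s in state.segments.items()
            if s.status == "unvalidated" and s.author != user and _anchored(state, s)
        ]
        traceable = []
        for b in branches:
            if b["id"] in branch_seg:
                continue
            att = attachment_for(b)
            if att is None:
                continue
            if att != SOMA_ATTACH:
                pseg = state.segments[att[0]]
                if pseg.author != user and pseg.status != "confirmed":
                    continue
            traceable.append((b, att))

        if reviewable:
            sid = reviewable[int(rng.integers(len(reviewable)))]
            seg = state.segments[sid]
            kind, bid = seg_meta[sid]
            diligent = rng.random() < p["confirm_diligence"]
            if kind == "true" or not diligent:
                do(AnnotationEvent(t, user, "confirm", sid))
            elif kind == "false":
                do(AnnotationEvent(t, user, "delete", sid))
                mark_deleted_branches()
            else:  # perturbed: modify = delete + corrected re-add
                lineage = f"lin-{sid}"
                parent = seg.parent
                do(AnnotationEvent(t, user, "delete", sid, lineage=lineage))
                mark_deleted_branches()
                new_id = new_sid()
                do(
                    AnnotationEvent(
                        t, user, "add", new_id,
                        segment_geometry=branches[bid]["geometry"],
                        parent_attachment=parent, lineage=lineage,
                    )
                )
                seg_meta[new_id] = ("true", bid)
                branch_seg[bid] = new_id
        elif traceable:
            b, att = traceable[int(rng.integers(len(traceable)))]
            sid = new_sid()
            if rng.random() < p["error_rate"]:
                if rng.random() < 0.5:
                    # spurious branch: a random short polyline; the true
                    # branch remains untraced
                    start = (
                        np.array(soma[:3])
                        if att == SOMA_ATTACH
                        else np.array(
                            state.segments[att[0]].geometry[att[1]][:3]
                        )
                    )
                    direction = rng.normal(size=3)
                    direction /= np.linalg.norm(direction)
                    geom = [
                        tuple(np.r_[start + direction * 2.0 * (k + 1), 1.0])
                        for k in range(5)
                    ]
                    do(
                        AnnotationEvent(
                            t, user, "add", sid,
                            segment_geometry=geom, parent_attachment=att,
                        )
                    )
                    seg_meta[sid] = ("false", None)
                else:
                    # perturbed tracing: premature termination of the branch
                    geom = b["geometry"][: max(1, len(b["geometry"]) * 3 // 5)]
                    do(
                        AnnotationEvent(
                            t, user, "add", sid,
                            segment_geometry=geom, parent_attachment=att,
                        )
                    )
                    seg_meta[sid] = ("perturbed", b["id"])
                    branch_seg[b["id"]] = sid
            else:
                do(
                    AnnotationEvent(
                        t, user, "add", sid,
                        segment_geometry=b["geometry"], parent_attachment=att,
                    )
                )
                seg_meta[sid] = ("true", b["id"])
                branch_seg[b["id"]] = sid
        if is_complete(state) and len(branch_seg) == n_branches:
            break
    return log


# ---------------------------------------------------------------------------
# Contrast projection map


def contrast_projection_map(
    collab: NeuronTree,
    noncollab: NeuronTree,
    regions: np.ndarray,
    dist_threshold: float = 2.0,
) -> dict:
    """Per-region added/subtracted length between the collaborative result
    and its noncollaborative counterfactual.

    ``regions`` is an integer label volume indexed [x, y, z] in the trees'
    coordinate frame (voxel units).  Added = length present in ``collab``
    only; subtracted = length present in ``noncollab`` only.  The dominant
    symbol is '+', '-' or 'o' (no collaborative editing).
    """
    regions = np.asarray(regions)
    if regions.ndim != 3:
        raise ValueError("regions must be a 3-D label volume")

    step = min(1.0, dist_threshold / 2.0)

    def unmatched_by_region(a: NeuronTree, b: NeuronTree):
        out: dict = {}
        if len(a.nodes) == 0:
            return out
        mids, lengths, _, _ = sample_arc_elements(a, step)
        if len(mids) == 0:
            return out
        if len(b.nodes):
            from scipy.spatial import cKDTree

            bpos = sample_arc_elements(b, step)[2]
            d, _ = cKDTree(bpos).query(mids)
            unmatched = d > dist_threshold
        else:
            unmatched = np.ones(len(mids), dtype=bool)
        idx = np.round(mids).astype(int)
        if (idx < 0).any() or (idx >= np.array(regions.shape)).any():
            raise ValueError("tree extends outside the region label volume")
        labels = regions[idx[:, 0], idx[:, 1], idx[:, 2]]
        for lab, ln in zip(labels[unmatched], lengths[unmatched]):
            out[int(lab)] = out.get(int(lab), 0.0) + float(ln)
        return out

    added = unmatched_by_region(collab, noncollab)
    subtracted = unmatched_by_region(noncollab, collab)
    result = {}
    eps = 1e-6
    for lab in sorted(np.unique(regions)):
        a = added.get(int(lab), 0.0)
        s = subtracted.get(int(lab), 0.0)
        if a < eps and s < eps:
            sym = "o"
        elif a > s:
            sym = "+"
        elif s > a:
            sym = "-"
        else:
            sym = "o"
        result[int(lab)] = {
            "added_length": a,
            "subtracted_length": s,
            "dominant_symbol": sym,
        }
    return result
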