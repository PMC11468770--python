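"""Neuron reconstructions as rooted trees of typed, positioned, radius-bearing nodes.

The on-disk representation is the SWC interchange format: one node per line,
seven whitespace-separated columns ``id type x y z radius parent``, with
``parent = -1`` marking a root.  The extended variant (ESWC) appends four
columns (segment id, level, mode, timestamp) which are carried through
verbatim.  Reconstructions follow the quasi-binary convention: only the soma
node (type 1) may have more than two children.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

SOMA = 1
AXON = 2
BASAL_DENDRITE = 3
APICAL_DENDRITE = 4

#: number of extra ESWC columns beyond the 7 SWC ones
_ESWC_EXTRA = 4


@dataclass
class NeuronNode:
    """A single SWC record.

    Positions are in the unit declared by the owning tree (voxels or
    micrometers); radius uses the same unit.
    """

    id: int
    structure_type: int
    x: float
    y: float
    z: float
    radius: float
    parent_id: int

    @property
    def position(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)


@dataclass
class NeuronTree:
    """A neuron reconstruction: an ordered collection of nodes forming a rooted tree.

    ``unit`` is ``"voxel"`` or ``"um"``; ``voxel_size`` gives micrometers per
    voxel along (x, y, z) and is used by :meth:`to_micrometers`.  ``metadata``
    holds free-form keys; ESWC extra columns live under ``metadata["eswc"]``
    as a mapping from node id to the list of extra fields.
    """

    nodes: list[NeuronNode] = field(default_factory=list)
    unit: str = "um"
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    metadata: dict = field(default_factory=dict)

    # -- indexing helpers -------------------------------------------------

    def node_map(self) -> dict[int, NeuronNode]:
        return {n.id: n for n in self.nodes}

    def children_map(self) -> dict[int, list[int]]:
        ch: dict[int, list[int]] = {n.id: [] for n in self.nodes}
        for n in self.nodes:
            if n.parent_id != -1 and n.parent_id in ch:
                ch[n.parent_id].append(n.id)
        return ch

    def roots(self) -> list[NeuronNode]:
        ids = {n.id for n in self.nodes}
        return [n for n in self.nodes if n.parent_id == -1 or n.parent_id not in ids]

    @property
    def root(self) -> NeuronNode:
        roots = [n for n in self.nodes if n.parent_id == -1]
        if len(roots) != 1:
            raise ValueError(f"tree has {len(roots)} roots, expected exactly 1")
        return roots[0]

    def __len__(self) -> int:
        return len(self.nodes)

    def positions(self) -> np.ndarray:
        """(n, 3) array of node positions in node order."""
        if not self.nodes:
            return np.zeros((0, 3))
        return np.array([[n.x, n.y, n.z] for n in self.nodes], dtype=float)

    def edges(self) -> list[tuple[NeuronNode, NeuronNode]]:
        """(parent, child) pairs for every non-root node with a resolvable parent."""
        nm = self.node_map()
        return [
            (nm[n.parent_id], n)
            for n in self.nodes
            if n.parent_id != -1 and n.parent_id in nm
        ]

    def to_micrometers(self) -> "NeuronTree":
        """Return a copy with coordinates scaled from voxels to micrometers."""
        if self.unit == "um":
            return self
        dx, dy, dz = self.voxel_size
        r_scale = float(np.mean(self.voxel_size))
        nodes = [
            replace(n, x=n.x * dx, y=n.y * dy, z=n.z * dz, radius=n.radius * r_scale)
            for n in self.nodes
        ]
        return NeuronTree(nodes, "um", self.voxel_size, dict(self.metadata))


@dataclass
class GlobalFeatures:
    """Whole-arbor morphometric summary (L-Measure-style definitions)."""

    total_length: float
    n_bifurcations: int
    n_tips: int
    topological_depth: int
    volume: float


class SWCParseError(ValueError):
    pass


# ---------------------------------------------------------------------------
# I/O


def read_swc(path, unit: str = "um", voxel_size=(1.0, 1.0, 1.0)) -> NeuronTree:
    """Read an SWC or ESWC file.

    Comment lines (leading ``#``) and blank lines are skipped.  Extra ESWC
    columns are preserved in ``metadata["eswc"]``.  Multi-root fragment files
    are representable; use :func:`validate_tree` to check single-root status.

    Raises
    ------
    SWCParseError
        On a malformed line (names the line number) or a duplicate node id.
    """
    nodes: list[NeuronNode] = []
    eswc: dict[int, list[str]] = {}
    seen: set[int] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 7:
                raise SWCParseError(
                    f"{path}:{lineno}: expected >= 7 fields, got {len(parts)}"
                )
            try:
                nid = int(parts[0])
                stype = int(parts[1])
                x, y, z, r = (float(v) for v in parts[2:6])
                pid = int(parts[6])
            except ValueError as exc:
                raise SWCParseError(f"{path}:{lineno}: {exc}") from None
            if nid in seen:
                raise SWCParseError(f"{path}:{lineno}: duplicate node id {nid}")
            seen.add(nid)
            nodes.append(NeuronNode(nid, stype, x, y, z, r, pid))
            if len(parts) > 7:
                eswc[nid] = parts[7 : 7 + _ESWC_EXTRA]
    meta: dict = {}
    if eswc:
        meta["eswc"] = eswc
    return NeuronTree(nodes, unit, tuple(voxel_size), meta)


def write_swc(tree: NeuronTree, path) -> None:
    """Write a tree in SWC form, parents before children.

    ESWC extra columns in ``metadata["eswc"]`` are appended when present.
    Floats are printed with 3 decimals (sub-nanometer precision is
    meaningless at light-microscope resolution).
    """
    eswc = tree.metadata.get("eswc", {})
    order = _topological_order(tree)
    with open(path, "w") as fh:
        fh.write("#id type x y z radius parent\n")
        for n in order:
            line = (
                f"{n.id} {n.structure_type} {n.x:.3f} {n.y:.3f} {n.z:.3f} "
                f"{n.radius:.3f} {n.parent_id}"
            )
            extra = eswc.get(n.id)
            if extra:
                line += " " + " ".join(str(v) for v in extra)
            fh.write(line + "\n")


def _topological_order(tree: NeuronTree) -> list[NeuronNode]:
    """Nodes ordered so every parent precedes its children; orphans and
    multi-root fragments are emitted in file order after their component root."""
    nm = tree.node_map()
    ch = tree.children_map()
    out: list[NeuronNode] = []
    visited: set[int] = set()
    for start in tree.nodes:
        if start.id in visited:
            continue
        if start.parent_id != -1 and start.parent_id in nm:
            continue  # reachable from some root; handled below
        stack = [start.id]
        while stack:
            nid = stack.pop()
            if nid in visited:
                continue
            visited.add(nid)
            out.append(nm[nid])
            stack.extend(reversed(ch.get(nid, [])))
    # nodes in cycles are unreachable from any root; append in file order
    for n in tree.nodes:
        if n.id not in visited:
            out.append(n)
    return out


# ---------------------------------------------------------------------------
# Validation


def validate_tree(tree: NeuronTree) -> list[str]:
    """Report structural violations; an empty list means the tree is valid.

    Checks: multiple/zero roots, orphan parent references, cycles,
    quasi-binary rule (non-soma node with more than 2 children), negative
    radius, non-finite positions.
    """
    report: list[str] = []
    if not tree.nodes:
        return report
    ids = {n.id for n in tree.nodes}
    roots = [n for n in tree.nodes if n.parent_id == -1]
    if len(roots) == 0:
        report.append("no root: no node has parent_id -1")
    elif len(roots) > 1:
        report.append(
            "multiple roots: nodes " + ", ".join(str(n.id) for n in roots)
        )
    for n in tree.nodes:
        if n.parent_id != -1 and n.parent_id not in ids:
            report.append(f"orphan parent reference: node {n.id} -> {n.parent_id}")
        if n.radius < 0:
            report.append(f"negative radius: node {n.id}")
        if not all(math.isfinite(v) for v in (n.x, n.y, n.z)):
            report.append(f"non-finite position: node {n.id}")
    # cycle detection: walk up from each node
    nm = tree.node_map()
    state: dict[int, int] = {}  # 0 in-progress, 1 clean
    for n in tree.nodes:
        path = []
        cur = n.id
        while cur in nm and state.get(cur) is None:
            state[cur] = 0
            path.append(cur)
            pid = nm[cur].parent_id
            if pid == -1 or pid not in nm:
                break
            if state.get(pid) == 0:
                report.append(f"cycle involving node {pid}")
                break
            cur = pid
        for p in path:
            state[p] = 1
    ch = tree.children_map()
    for n in tree.nodes:
        if n.structure_type != SOMA and len(ch.get(n.id, [])) > 2:
            report.append(
                f"quasi-binary violation: non-soma node {n.id} has "
                f"{len(ch[n.id])} children"
            )
    return report


# ---------------------------------------------------------------------------
# Editing operations


def prune_short_terminal_branches(tree: NeuronTree, min_nodes: int = 6) -> NeuronTree:
    """Remove terminal branches shorter than ``min_nodes`` SWC records.

    A terminal branch is the path from a tip up to, but excluding, the
    nearest branching point.  Branches attached directly to the root are
    exempt (pruning them could delete an entire small tree).  Applied
    iteratively until no further branch qualifies; the root is never removed.
    """
    nodes = list(tree.nodes)
    while True:
        t = NeuronTree(nodes, tree.unit, tree.voxel_size, tree.metadata)
        nm = t.node_map()
        ch = t.children_map()
        root_ids = {n.id for n in t.roots()}
        to_remove: set[int] = set()
        for n in nodes:
            if ch.get(n.id) or n.id in root_ids:
                continue  # not a tip
            branch = [n.id]
            cur = n
            exempt = False
            while True:
                pid = cur.parent_id
                if pid == -1 or pid not in nm:
                    exempt = True  # ran into the root: branch attaches to it
                    break
                parent = nm[pid]
                if len(ch.get(pid, [])) >= 2 or pid in root_ids:
                    exempt = pid in root_ids
                    break
                branch.append(pid)
                cur = parent
            if not exempt and len(branch) < min_nodes:
                to_remove.update(branch)
        if not to_remove:
            return NeuronTree(nodes, tree.unit, tree.voxel_size, dict(tree.metadata))
        nodes = [n for n in nodes if n.id not in to_remove]


def resample(tree: NeuronTree, step: float) -> NeuronTree:
    """Resample every unbranched path to ~``step`` spacing.

    Positions and radii are linearly interpolated along the arc; branching
    points, tips and the root are preserved exactly, so the topology (and
    hence tip / bifurcation counts) is unchanged.
    """
    if step <= 0:
        raise ValueError(f"step must be positive, got {step}")
    if len(tree.nodes) <= 1:
        return NeuronTree(
            list(tree.nodes), tree.unit, tree.voxel_size, dict(tree.metadata)
        )
    nm = tree.node_map()
    ch = tree.children_map()
    root_ids = {n.id for n in tree.roots()}
    topo = {
        n.id
        for n in tree.nodes
        if n.id in root_ids or len(ch.get(n.id, [])) != 1
    }  # roots, branching points, tips

    new_nodes: list[NeuronNode] = []
    id_of: dict[int, int] = {}  # original topo node id -> new id
    next_id = 1

    def emit(stype, pos, radius, parent_new_id):
        nonlocal next_id
        node = NeuronNode(
            next_id, stype, float(pos[0]), float(pos[1]), float(pos[2]),
            float(radius), parent_new_id,
        )
        new_nodes.append(node)
        next_id += 1
        return node.id

    for root in tree.roots():
        rid = emit(root.structure_type, root.position, root.radius, -1)
        id_of[root.id] = rid
        # walk branches from each topological node
        stack = [root.id]
        while stack:
            top_id = stack.pop()
            for child_id in ch.get(top_id, []):
                # collect the unbranched run down to the next topological node
                run = [nm[top_id], nm[child_id]]
                while run[-1].id not in topo:
                    run.append(nm[ch[run[-1].id][0]])
                end = run[-1]
                pts = np.array([[n.x, n.y, n.z] for n in run])
                radii = np.array([n.radius for n in run])
                seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
                arc = np.concatenate([[0.0], np.cumsum(seg)])
                total = arc[-1]
                n_int = max(1, int(round(total / step))) if total > 0 else 1
                targets = np.linspace(0.0, total, n_int + 1)[1:]
                parent_new = id_of[top_id]
                for k, s in enumerate(targets):
                    last = k == len(targets) - 1
                    if last:
                        pos, rad = end.position, end.radius
                    else:
                        pos = np.array(
                            [np.interp(s, arc, pts[:, d]) for d in range(3)]
                        )
                        rad = float(np.interp(s, arc, radii))
                    stype = end.structure_type
                    parent_new = emit(stype, pos, rad, parent_new)
                id_of[end.id] = parent_new
                stack.append(end.id)
    return NeuronTree(new_nodes, tree.unit, tree.voxel_size, dict(tree.metadata))


# ---------------------------------------------------------------------------
# Features


def total_length(tree: NeuronTree) -> float:
    """Sum of Euclidean edge lengths."""
    return float(
        sum(np.linalg.norm(p.position - c.position) for p, c in tree.edges())
    )


def global_features(tree: NeuronTree) -> GlobalFeatures:
    """Whole-arbor features: length, bifurcations, tips, topological depth,
    and volume as the sum of conical-frustum volumes over edges."""
    if not tree.nodes:
        return GlobalFeatures(0.0, 0, 0, 0, 0.0)
    ch = tree.children_map()
    root_ids = {n.id for n in tree.roots()}
    n_bif = sum(
        1
        for n in tree.nodes
        if (len(ch.get(n.id, [])) == 2 and n.id not in root_ids)
        or (n.id in root_ids and len(ch.get(n.id, [])) >= 2)
    )
    n_tips = sum(1 for n in tree.nodes if not ch.get(n.id))
    vol = 0.0
    for p, c in tree.edges():
        h = float(np.linalg.norm(p.position - c.position))
        r1, r2 = p.radius, c.radius
        vol += math.pi * h * (r1 * r1 + r1 * r2 + r2 * r2) / 3.0
    # topological depth: max bifurcations along any root->tip path, + 1
    nm = tree.node_map()
    depth = 0
    for root in tree.roots():
        stack = [(root.id, 0)]
        while stack:
            nid, nbif = stack.pop()
            kids = ch.get(nid, [])
            is_bif = (len(kids) == 2 and nid not in root_ids) or (
                nid in root_ids and len(kids) >= 2
            )
            nb = nbif + (1 if is_bif else 0)
            if not kids:
                depth = max(depth, nb + 1)
            for k in kids:
                stack.append((k, nb))
    return GlobalFeatures(total_length(tree), n_bif, n_tips, depth, vol)
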