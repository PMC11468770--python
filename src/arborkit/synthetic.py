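"""Synthetic fixtures: ground-truth trees, rendered volumes, region labels.

The generator emulates sparse fluorescence microscopy of single neurons:
tubular neurites with Gaussian cross-sections (peak intensity on the axis,
sigma = radius / 2), a bright quasi-spherical soma, varicosity swellings
along the axon (recorded as ground-truth bouton markers), additive Gaussian
detector noise, and optional bright blob artifacts standing in for blood
vessels / dye leakage.  All geometry is in voxel units; the declared voxel
size is metadata for unit conversion.  Every generator is a pure function of
its spec, seed included.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .swc import AXON, SOMA, NeuronNode, NeuronTree
from .volume import ImageVolume, PointAnnotation


@dataclass
class BoutonSpec:
    count: int = 10
    radius_ratio: float = 1.8  # varicosity radius vs local shaft radius
    spacing: float = 12.0  # minimum arc spacing between varicosities, voxels
    intensity_factor: float = 1.4  # peak brightness vs shaft


@dataclass
class IntensitySpec:
    shaft: float = 160.0
    soma: float = 230.0
    background_mean: float = 40.0
    noise_sigma: float = 30.0  # SNR = (shaft - background) / sigma
    artifact_blobs: int = 2
    artifact_radius_range: tuple = (2.0, 4.0)


@dataclass
class PhantomSpec:
    volume_shape: tuple = (128, 128, 128)
    voxel_size: tuple = (0.46, 0.46, 2.0)  # micrometers per voxel
    n_branches: int = 8
    branch_length_range: tuple = (25.0, 50.0)  # voxels
    shaft_radius_range: tuple = (1.5, 2.5)  # voxels
    soma_radius: float = 8.0
    bouton: BoutonSpec = field(default_factory=BoutonSpec)
    intensity: IntensitySpec = field(default_factory=IntensitySpec)
    bit_depth: int = 8
    seed: int = 0

    @property
    def snr(self) -> float:
        i = self.intensity
        return (i.shaft - i.background_mean) / i.noise_sigma


def make_tree(spec: PhantomSpec, node_step: float = 2.0) -> NeuronTree:
    """Random quasi-binary tree grown from a central soma.

    Branches take wobbly straight runs of a sampled length; each completed
    branch spawns two children while the branch budget lasts.  Directions
    bounce off the volume margin so the tree always fits.
    """
    rng = np.random.default_rng(spec.seed)
    shape = np.asarray(spec.volume_shape, dtype=float)
    margin = max(spec.soma_radius, spec.shaft_radius_range[1]) + 3.0
    for _ in range(60):  # bounded retries for infeasible draws
        tree = _grow_tree(rng, spec, shape, margin, node_step)
        if tree is not None and _self_avoiding(tree, clearance=5.0, graph_gap=8):
            return tree
    raise ValueError("could not fit a tree into the requested volume")


def _self_avoiding(tree, clearance: float, graph_gap: int) -> bool:
    """True when nodes far apart on the tree stay apart in space.

    Neurites are self-avoiding at submicrometer resolution; without this the
    random walk can let two branches graze each other, which would read as a
    varicosity in any intensity/radius profile.
    """
    nodes = tree.nodes
    pos = tree.positions()
    n = len(nodes)
    # graph distance by bounded BFS from each node over the undirected tree
    adj: dict = {nd.id: [] for nd in nodes}
    for p, c in tree.edges():
        adj[p.id].append(c.id)
        adj[c.id].append(p.id)
    index = {nd.id: i for i, nd in enumerate(nodes)}
    from scipy.spatial import cKDTree as _KD

    kd = _KD(pos)
    pairs = kd.query_pairs(clearance)
    if not pairs:
        return True
    for i, j in pairs:
        # BFS depth-limited from node i to see if j is within graph_gap hops
        start, goal = nodes[i].id, nodes[j].id
        frontier = {start}
        seen = {start}
        found = False
        for _ in range(graph_gap):
            frontier = {
                nb for f in frontier for nb in adj[f] if nb not in seen
            }
            seen |= frontier
            if goal in seen:
                found = True
                break
        if not found:
            return False
    return True


def _grow_tree(rng, spec, shape, margin, node_step):
    center = shape / 2.0
    nodes = [
        NeuronNode(1, SOMA, *map(float, center), float(spec.soma_radius), -1)
    ]
    next_id = 2
    branches_left = spec.n_branches
    # queue entries: (start position, direction, parent node id)
    d0 = _unit(rng.normal(size=3))
    queue = [(center.copy(), d0, 1)]
    while queue and branches_left > 0:
        start, direction, parent = queue.pop(0)
        branches_left -= 1
        length = rng.uniform(*spec.branch_length_range)
        radius = rng.uniform(*spec.shaft_radius_range)
        n_steps = max(3, int(round(length / node_step)))
        pos = start.copy()
        d = direction.copy()
        for _ in range(n_steps):
            d = _unit(d + rng.normal(scale=0.12, size=3))
            nxt = pos + d * node_step
            for ax in range(3):
                if nxt[ax] < margin or nxt[ax] > shape[ax] - margin:
                    d[ax] = -d[ax]
                    nxt = pos + d * node_step
            pos = np.clip(nxt, margin, shape - margin)
            nodes.append(
                NeuronNode(
                    next_id, AXON, *map(float, pos), float(radius), parent
                )
            )
            parent = next_id
            next_id += 1
        if branches_left > 0:
            for sign in (1.0, -1.0):
                angle = rng.uniform(0.6, 1.2) * sign
                queue.append((pos.copy(), _rotate(d, angle, rng), parent))
    if len(nodes) < 2:
        return None
    return NeuronTree(nodes, unit="voxel", voxel_size=spec.voxel_size)


def _unit(v):
    n = np.linalg.norm(v)
    return v / n if n > 0 else np.array([1.0, 0.0, 0.0])


def _rotate(d, angle, rng):
    # rotate d by `angle` around a random axis perpendicular to it
    perp = _unit(np.cross(d, rng.normal(size=3)))
    return _unit(np.cos(angle) * d + np.sin(angle) * perp)


def _paint_ball(canvas, center, radius, peak, hard_core=True, edge_sigma=1.5):
    shape = np.array(canvas.shape)
    c = np.asarray(center, dtype=float)
    reach = radius + 3.0 * edge_sigma
    lo = np.clip(np.floor(c - reach).astype(int), 0, shape)
    hi = np.clip(np.ceil(c + reach).astype(int) + 1, 0, shape)
    if (hi <= lo).any():
        return
    gx, gy, gz = np.meshgrid(
        *(np.arange(lo[d], hi[d]) for d in range(3)), indexing="ij"
    )
    d = np.sqrt((gx - c[0]) ** 2 + (gy - c[1]) ** 2 + (gz - c[2]) ** 2)
    if hard_core:
        prof = peak * np.exp(-np.maximum(d - radius, 0.0) ** 2 / (2 * edge_sigma**2))
    else:
        prof = peak * np.exp(-(d**2) / (2 * (radius / 2.0) ** 2))
    view = canvas[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
    np.maximum(view, prof, out=view)


def _paint_tube(canvas, p0, p1, radius, peak):
    """Gaussian-profile tube: peak on the axis, sigma = radius / 2."""
    from .volume import _point_segment_distance

    shape = np.array(canvas.shape)
    sigma = radius / 2.0
    reach = radius + 3.0 * sigma
    lo = np.clip(np.floor(np.minimum(p0, p1) - reach).astype(int), 0, shape)
    hi = np.clip(np.ceil(np.maximum(p0, p1) + reach).astype(int) + 1, 0, shape)
    if (hi <= lo).any():
        return
    gx, gy, gz = np.meshgrid(
        *(np.arange(lo[d], hi[d]) for d in range(3)), indexing="ij"
    )
    pts = np.stack([gx, gy, gz], axis=-1).reshape(-1, 3).astype(float)
    d = _point_segment_distance(pts, p0, p1).reshape(gx.shape)
    prof = peak * np.exp(-(d**2) / (2 * sigma**2))
    view = canvas[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
    np.maximum(view, prof, out=view)


def render_volume(tree: NeuronTree, spec: PhantomSpec):
    """Render a tree into a noisy intensity volume.

    Returns ``(ImageVolume, truth_markers)`` where the markers record the
    planted varicosities (label ``bouton``).  Rendering order: neurite tubes
    and soma by maximum composition, varicosities, artifact blobs, then
    background offset and additive Gaussian noise, clipped to bit depth.
    """
    rng = np.random.default_rng(spec.seed + 1)
    shape = tuple(int(s) for s in spec.volume_shape)
    canvas = np.zeros(shape, dtype=np.float32)
    inten = spec.intensity
    nm = tree.node_map()
    for p, c in tree.edges():
        _paint_tube(canvas, p.position, c.position, c.radius, inten.shaft)
    root = tree.root
    if root.structure_type == SOMA:
        _paint_ball(canvas, root.position, root.radius, inten.soma)

    markers = _plant_varicosities(canvas, tree, spec, rng)

    for _ in range(inten.artifact_blobs):
        r = rng.uniform(*inten.artifact_radius_range)
        pos = rng.uniform(r + 2, np.asarray(shape, dtype=float) - r - 2)
        if np.linalg.norm(pos - root.position) < 3 * root.radius:
            continue
        _paint_ball(canvas, pos, r, inten.soma)

    img = (
        canvas
        + inten.background_mean
        + rng.normal(scale=inten.noise_sigma, size=shape).astype(np.float32)
    )
    maxval = 255 if spec.bit_depth == 8 else 65535
    dtype = np.uint8 if spec.bit_depth == 8 else np.uint16
    data = np.clip(img, 0, maxval).astype(dtype)
    return ImageVolume(data, spec.voxel_size), markers


def _plant_varicosities(canvas, tree, spec, rng):
    bspec = spec.bouton
    if bspec.count <= 0:
        return []
    nm = tree.node_map()
    ch = tree.children_map()
    # varicosities sit along shafts: keep clear of branch points and tips,
    # where a swelling would be indistinguishable from the topology itself
    topo_pos = [
        n.position for n in tree.nodes if len(ch.get(n.id, [])) != 1
    ]
    axon = [n for n in tree.nodes if n.structure_type == AXON]
    chosen: list = []
    order = rng.permutation(len(axon))
    for i in order:
        n = axon[i]
        if len(chosen) >= bspec.count:
            break
        if n.parent_id == -1 or n.parent_id not in nm:
            continue
        if np.linalg.norm(n.position - tree.root.position) < tree.root.radius + 4:
            continue
        if any(np.linalg.norm(n.position - p) < 6.0 for p in topo_pos):
            continue
        if any(
            np.linalg.norm(n.position - c.position) < bspec.spacing
            for c in chosen
        ):
            continue
        chosen.append(n)
    markers = []
    for n in chosen:
        r = bspec.radius_ratio * n.radius
        peak = min(bspec.intensity_factor * spec.intensity.shaft, 255.0)
        _paint_ball(canvas, n.position, r, peak, hard_core=False, edge_sigma=r / 2)
        markers.append(
            PointAnnotation(
                x=n.x, y=n.y, z=n.z, radius=float(r),
                score=1.0, label="bouton",
            )
        )
    return markers


def make_region_labels(shape, n_regions: int, seed: int) -> np.ndarray:
    """Voronoi partition of the volume around seeded sites; labels 1..n."""
    if n_regions < 1:
        raise ValueError("n_regions must be >= 1")
    shape = tuple(int(s) for s in shape)
    rng = np.random.default_rng(seed)
    sites = rng.uniform(0, np.asarray(shape, dtype=float), size=(n_regions, 3))
    grid = np.stack(
        np.meshgrid(*(np.arange(s) for s in shape), indexing="ij"), axis=-1
    ).reshape(-1, 3)
    _, idx = cKDTree(sites).query(grid)
    return (idx + 1).astype(np.int32).reshape(shape)


# ---------------------------------------------------------------------------
# Soma-screening phantoms


def make_soma_phantom(
    shape=(256, 256, 256),
    seed: int = 0,
    n_somas: int | None = None,
    radius_range=(6.0, 25.0),
    snr: float = 4.0,
    max_occupancy: float = 0.008,
):
    """16-bit block with 1-5 planted spherical somas for detector tests.

    The noise sigma follows the generator's shaft-referenced SNR convention
    (sigma = (shaft_ref - background)/SNR with somas twice as far above
    background as the shaft reference, as in labeled tissue).  Soma
    occupancy is capped at ``max_occupancy`` of the block and centers are
    kept well separated, emulating the sparseness of whole-brain blocks that
    the percentile binarization presumes.

    Returns ``(ImageVolume, truth)`` with truth as soma-labeled markers.
    """
    rng = np.random.default_rng(seed)
    shape = tuple(int(s) for s in shape)
    background = 100.0
    shaft_ref = 250.0
    soma_int = background + 2.0 * (shaft_ref - background)  # = 400
    sigma = (shaft_ref - background) / snr
    if n_somas is None:
        n_somas = int(rng.integers(1, 6))
    vol_total = float(np.prod(shape))
    for _ in range(100):
        radii = rng.uniform(*radius_range, size=n_somas)
        if (4.0 / 3.0 * np.pi * (radii**3)).sum() <= max_occupancy * vol_total:
            break
    centers: list = []
    for r in radii:
        for _ in range(200):
            c = rng.uniform(r + 6, np.asarray(shape, dtype=float) - r - 6)
            if all(
                np.linalg.norm(c - c2) >= r + r2 + 17.0
                for c2, r2 in centers
            ):
                centers.append((c, r))
                break
        else:
            raise ValueError("could not place non-overlapping somas")
    canvas = np.zeros(shape, dtype=np.float32)
    for c, r in centers:
        _paint_ball(canvas, c, r, soma_int - background)
    img = canvas + background + rng.normal(scale=sigma, size=shape).astype(
        np.float32
    )
    data = np.clip(img, 0, 65535).astype(np.uint16)
    truth = [
        PointAnnotation(
            x=float(c[0]), y=float(c[1]), z=float(c[2]), radius=float(r),
            score=1.0, label="soma_confirmed",
        )
        for c, r in centers
    ]
    return ImageVolume(data), truth
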