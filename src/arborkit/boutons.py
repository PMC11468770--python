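"""Axonal bouton (varicosity) detection along traced axons.

Boutons are localized swellings that appear as coincident peaks in the
intensity profile and the radius profile sampled along an axonal shaft.
Candidates are intensity peaks with an overlapping radius peak; heuristic
filters then require the candidate radius to be at least 1.5x the median
radius of surrounding shaft nodes and the 8-bit intensity to exceed 120,
and candidates closer than 5 voxels keep only the brighter one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import RegularGridInterpolator
from scipy.signal import argrelextrema

from .compare import confusion_metrics
from .swc import AXON, NeuronTree, resample
from .volume import ImageVolume, PointAnnotation


@dataclass
class BoutonParams:
    radius_ratio: float = 1.5  # candidate vs surrounding-median radius
    min_intensity: float = 120.0  # 8-bit intensity floor (exclusive)
    dedupe_voxels: float = 5.0  # Euclidean de-duplication distance
    surround: int = 10  # surrounding-node window, per side
    overlap: int = 3  # intensity/radius peak overlap window, nodes
    smooth: int = 3  # moving-average width


@dataclass
class AxonProfile:
    """Intensity/radius profiles along resampled axon branches.

    All arrays are concatenated over branches; ``branch_ids`` delimits them
    so peaks never span a bifurcation.
    """

    arc_positions: np.ndarray  # cumulative arc length, branch-local (um)
    intensities: np.ndarray  # 8-bit scale
    radii: np.ndarray  # voxels
    positions: np.ndarray  # (n, 3) voxel coordinates
    branch_ids: np.ndarray  # int per sample
    node_refs: list = field(default_factory=list)  # resampled node ids


_SPHERE_CACHE: dict = {}


def _sphere_shell(r: int) -> np.ndarray:
    """Integer offsets with r - 0.5 <= |d| < r + 0.5 (surface voxels)."""
    if r not in _SPHERE_CACHE:
        rng = np.arange(-r, r + 1)
        gx, gy, gz = np.meshgrid(rng, rng, rng, indexing="ij")
        d = np.sqrt(gx**2 + gy**2 + gz**2)
        sel = (d >= r - 0.5) & (d < r + 0.5)
        _SPHERE_CACHE[r] = np.stack([gx[sel], gy[sel], gz[sel]], axis=1)
    return _SPHERE_CACHE[r]


def estimate_radius(
    volume: ImageVolume,
    point,
    background_threshold: float,
    r_max: int = 15,
    surface_fraction: float = 0.85,
) -> int:
    """Largest integer r such that >= 85% of the sphere surface of radius r
    around ``point`` is above ``background_threshold``; 0 if the point itself
    is background."""
    p = np.round(np.asarray(point, dtype=float)).astype(int)
    shape = np.array(volume.shape)
    if (p < 0).any() or (p >= shape).any():
        raise ValueError(f"point {tuple(point)} outside volume")
    if volume.data[tuple(p)] <= background_threshold:
        return 0
    best = 0
    for r in range(1, r_max + 1):
        coords = p + _sphere_shell(r)
        inside = ((coords >= 0) & (coords < shape)).all(axis=1)
        if not inside.any():
            break
        vals = volume.data[tuple(coords[inside].T)]
        if (vals > background_threshold).mean() >= surface_fraction:
            best = r
        else:
            break
    return best


def _to_uint8(data: np.ndarray) -> np.ndarray:
    """Min-max rescale a 16-bit block to 8-bit; 8-bit passes through."""
    if data.dtype == np.uint8:
        return data
    lo, hi = int(data.min()), int(data.max())
    if hi == lo:
        return np.zeros(data.shape, dtype=np.uint8)
    return ((data.astype(np.float64) - lo) / (hi - lo) * 255.0).astype(np.uint8)


def profile_axon(
    volume: ImageVolume,
    tree: NeuronTree,
    step: float = 1.0,
    background_threshold: float | None = None,
) -> AxonProfile:
    """Sample intensity (trilinear, 8-bit scale) and estimated radius along
    the axon of ``tree``, resampled at ``step``, branch by branch."""
    axon_nodes = [n for n in tree.nodes if n.structure_type == AXON]
    if not axon_nodes:
        raise ValueError("tree contains no axon-typed nodes")
    img8 = _to_uint8(volume.data)
    if background_threshold is None:
        background_threshold = float(np.median(img8)) + 10.0
    shape = volume.shape
    rel = ImageVolume(img8, volume.voxel_size, volume.origin)
    interp = RegularGridInterpolator(
        tuple(np.arange(s) for s in shape),
        img8.astype(np.float64),
        bounds_error=False,
        fill_value=None,
    )
    rs = resample(tree, step)
    nm = rs.node_map()
    ch = rs.children_map()
    root_ids = {n.id for n in rs.roots()}
    origin = np.asarray(volume.origin, dtype=float)

    outside = [
        n.id
        for n in rs.nodes
        if n.structure_type == AXON
        and (
            ((n.position - origin) < 0).any()
            or ((n.position - origin) >= np.array(shape)).any()
        )
    ]
    if outside:
        raise ValueError(f"axon nodes outside volume: {outside[:10]}")

    arcs, inten, radii, pos, bids, refs = [], [], [], [], [], []
    branch_id = 0
    topo = {
        n.id for n in rs.nodes if n.id in root_ids or len(ch.get(n.id, [])) != 1
    }
    stack = [r.id for r in rs.roots()]
    seen = set()
    while stack:
        top = stack.pop()
        if top in seen:
            continue
        seen.add(top)
        for child in ch.get(top, []):
            run = [nm[top], nm[child]]
            while run[-1].id not in topo:
                run.append(nm[ch[run[-1].id][0]])
            stack.append(run[-1].id)
            if not any(n.structure_type == AXON for n in run[1:]):
                continue
            arc = 0.0
            prev = run[0]
            for n in run[1:]:
                arc += float(np.linalg.norm(n.position - prev.position))
                prev = n
                p = n.position - origin
                arcs.append(arc)
                inten.append(float(np.asarray(interp(p)).item()))
                radii.append(
                    float(
                        estimate_radius(rel, p, background_threshold)
                    )
                )
                pos.append(n.position)
                bids.append(branch_id)
                refs.append(n.id)
            branch_id += 1
    return AxonProfile(
        arc_positions=np.array(arcs),
        intensities=np.array(inten),
        radii=np.array(radii),
        positions=np.array(pos).reshape(-1, 3),
        branch_ids=np.array(bids, dtype=int),
        node_refs=refs,
    )


def _smooth(x: np.ndarray, width: int) -> np.ndarray:
    if width <= 1 or len(x) < width:
        return x.astype(float)
    kernel = np.ones(width) / width
    pad = width // 2
    xp = np.pad(x.astype(float), pad, mode="edge")
    return np.convolve(xp, kernel, mode="valid")[: len(x)]


def _local_maxima(x: np.ndarray) -> np.ndarray:
    if len(x) < 3:
        return np.array([], dtype=int)
    (idx,) = argrelextrema(x, np.greater_equal, order=1)
    # drop flat ends and plateau duplicates
    keep = []
    for i in idx:
        if 0 < i < len(x) - 1 and (x[i] > x[i - 1] or x[i] > x[i + 1]):
            if not keep or i - keep[-1] > 1 or x[i] != x[keep[-1]]:
                keep.append(i)
    return np.array(keep, dtype=int)


def detect_boutons(profile: AxonProfile, params: BoutonParams | None = None):
    """Detect boutons on an axon profile.

    Peaks are found per branch in the smoothed intensity and radius
    profiles; a candidate needs a radius peak within the overlap window,
    radius >= ratio x median surrounding radius, intensity > the 8-bit
    floor, and survives 5-voxel de-duplication (brighter one kept).
    """
    if params is None:
        params = BoutonParams()
    if len(profile.intensities) == 0:
        raise ValueError("empty axon profile")
    out: list[PointAnnotation] = []
    for b in np.unique(profile.branch_ids):
        sel = profile.branch_ids == b
        inten = profile.intensities[sel]
        radii = profile.radii[sel]
        pos = profile.positions[sel]
        si = _smooth(inten, params.smooth)
        sr = _smooth(radii, params.smooth)
        ipeaks = _local_maxima(si)
        rpeaks = set()
        for rp in _local_maxima(sr):
            rpeaks.update(range(rp - params.overlap, rp + params.overlap + 1))
        for i in ipeaks:
            if i not in rpeaks:
                continue
            lo = max(0, i - params.surround - 1)
            hi = min(len(radii), i + params.surround + 2)
            surround = np.concatenate([radii[lo : max(lo, i - 1)], radii[i + 2 : hi]])
            if len(surround) == 0:
                continue
            med = float(np.median(surround))
            # peak radius from the smoothed profile (max around the peak
            # index): robust to single-sample estimator spikes, and immune to
            # the one-sample shift smoothing can introduce
            peak_r = float(sr[max(0, i - 1) : i + 2].max())
            if med <= 0 or peak_r < params.radius_ratio * med:
                continue
            if inten[i] <= params.min_intensity:
                continue
            out.append(
                PointAnnotation(
                    x=float(pos[i, 0]), y=float(pos[i, 1]), z=float(pos[i, 2]),
                    radius=peak_r, score=float(inten[i]), label="bouton",
                )
            )
    # 5-voxel de-duplication, keep the higher-intensity candidate
    out.sort(key=lambda a: (-a.score, a.x, a.y, a.z))
    kept: list[PointAnnotation] = []
    for c in out:
        if all(
            np.linalg.norm(c.position - k.position) >= params.dedupe_voxels
            for k in kept
        ):
            kept.append(c)
    return kept


def evaluate_boutons(detected, truth, match_radius: float = 5.0):
    """(precision, recall, F1) under greedy one-to-one matching by ascending
    distance within ``match_radius``; TN = 0 by convention."""
    pairs = []
    for i, d in enumerate(detected):
        for j, t in enumerate(truth):
            dist = float(np.linalg.norm(d.position - t.position))
            if dist <= match_radius:
                pairs.append((dist, i, j))
    pairs.sort()
    used_d: set = set()
    used_t: set = set()
    tp = 0
    for _, i, j in pairs:
        if i in used_d or j in used_t:
            continue
        used_d.add(i)
        used_t.add(j)
        tp += 1
    fp = len(detected) - tp
    fn = len(truth) - tp
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        precision, recall, _ = confusion_metrics(tp, 0, fp, fn)
    if np.isnan(precision) or np.isnan(recall) or precision + recall == 0:
        f1 = 0.0 if (len(detected) or len(truth)) else 1.0
        precision = precision if not np.isnan(precision) else 0.0
        recall = recall if not np.isnan(recall) else 0.0
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return precision, recall, f1
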