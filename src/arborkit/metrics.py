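"""Descriptive metrics over volumes and trees: signal complexity, Sholl-style
local structural complexity, user attention, and NMF-based image quality."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import NMF

from .collab import EditLog, replay_raw
from .swc import NeuronTree
from .volume import ImageVolume, rasterize_tree_mask


@dataclass
class QualityReport:
    signal_median: float
    signal_rsd: float  # sd(signal) / median(signal)
    contrast: float
    n_components: int


def signal_complexity_map(
    volume: ImageVolume, tree: NeuronTree, cube: int = 20
) -> ImageVolume:
    """Cube-wise foreground/background intensity ratio, rescaled to 8 bits.

    Foreground voxels lie within node radius of the reconstruction skeleton;
    each ``cube``^3 cell scores mean(foreground)/mean(background), 0 where
    the cell has no foreground.  The map is min-max rescaled onto (0, 255).
    """
    fg_mask = rasterize_tree_mask(tree, volume.shape, min_radius=1.0)
    shape = volume.shape
    grid = tuple(int(np.ceil(s / cube)) for s in shape)
    raw = np.zeros(grid, dtype=float)
    data = volume.data.astype(float)
    for i in range(grid[0]):
        for j in range(grid[1]):
            for k in range(grid[2]):
                sl = (
                    slice(i * cube, min((i + 1) * cube, shape[0])),
                    slice(j * cube, min((j + 1) * cube, shape[1])),
                    slice(k * cube, min((k + 1) * cube, shape[2])),
                )
                m = fg_mask[sl]
                if not m.any():
                    continue
                fg = data[sl][m]
                bg = data[sl][~m]
                bg_mean = bg.mean() if bg.size else 0.0
                raw[i, j, k] = fg.mean() / bg_mean if bg_mean > 0 else 0.0
    if raw.max() == raw.min():
        warnings.warn("all-background volume: complexity map is zero", stacklevel=2)
        return ImageVolume(np.zeros(grid, dtype=np.uint8), volume.voxel_size)
    scaled = (raw - raw.min()) / (raw.max() - raw.min()) * 255.0
    return ImageVolume(scaled.astype(np.uint8), volume.voxel_size)


def local_structural_complexity(tree: NeuronTree, radii) -> dict:
    """Sholl-style score per node: total number of tree-edge crossings of
    concentric spheres of the given radii centered at that node.

    A straight edge can cross a sphere 0, 1 or 2 times; the count is exact
    for line segments.
    """
    radii = np.asarray(radii, dtype=float)
    edges = [(p.position, c.position) for p, c in tree.edges()]
    scores: dict = {}
    for n in tree.nodes:
        c = n.position
        total = 0
        for a, b in edges:
            da = np.linalg.norm(a - c)
            db = np.linalg.norm(b - c)
            # minimum distance from c to segment [a, b]
            ab = b - a
            L2 = float(ab @ ab)
            t = np.clip(((c - a) @ ab) / L2, 0.0, 1.0) if L2 > 0 else 0.0
            dmin = np.linalg.norm(a + t * ab - c)
            for r in radii:
                if (da - r) * (db - r) < 0:
                    total += 1
                elif da > r and db > r and dmin < r:
                    total += 2
        scores[n.id] = total
    return scores


def user_attention(tree: NeuronTree, log: EditLog, box: float = 20.0) -> dict:
    """Per node, the number of *distinct* users whose edit events fall inside
    an axis-aligned ``box``-micrometer cube centered at the node (closed on
    the lower face, open on the upper)."""
    # collect (user, position) pairs; delete/confirm events inherit the
    # geometry of the segment they touch
    state_like = replay_raw(log)
    touches: list = []
    for e in log.events:
        if e.action == "add" and e.segment_geometry:
            touches.extend((e.user, np.array(p[:3], float)) for p in e.segment_geometry)
        else:
            seg = state_like.segments.get(e.segment_id)
            if seg is not None:
                touches.extend(
                    (e.user, np.array(p[:3], float)) for p in seg.geometry
                )
    half = box / 2.0
    out: dict = {}
    for n in tree.nodes:
        lo = n.position - half
        hi = n.position + half
        users = {
            u for u, p in touches if ((p >= lo) & (p < hi)).all()
        }
        out[n.id] = len(users)
    return out


def nmf_image_quality(
    volume: ImageVolume,
    slab: int = 10,
    rank: int = 3,
    signed_contrast: bool = False,
) -> QualityReport:
    """Image-quality statistics from a low-rank background decomposition.

    Every ``slab`` consecutive z-slices are averaged and flattened into one
    column of a non-negative matrix; a rank-``rank`` NMF (deterministic
    NNDSVD-A initialization) factors it.  The background is the component
    whose spatial loading has the smallest coefficient of variation; signal
    is the residual clipped at zero.  Statistics apply percentile filters to
    suppress cross-contamination between the two estimates: signal values
    above their 90th percentile, background values below their 99th.  ``contrast`` is reported as the magnitude of
    the filtered-median difference unless ``signed_contrast`` (literal
    background-minus-signal) is requested.
    """
    data = volume.data.astype(float)
    if data.shape[2] < slab:
        raise ValueError(f"volume needs >= {slab} z-slices, got {data.shape[2]}")
    if data.max() == data.min():
        raise ValueError("constant volume: NMF decomposition is degenerate")
    n_slabs = data.shape[2] // slab
    cols = [
        data[:, :, i * slab : (i + 1) * slab].mean(axis=2).ravel()
        for i in range(n_slabs)
    ]
    X = np.stack(cols, axis=1)  # (pixels, n_slabs)
    k = min(rank, min(X.shape))
    model = NMF(n_components=k, init="nndsvda", max_iter=500, tol=1e-6)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        W = model.fit_transform(X)  # (pixels, k)
        H = model.components_  # (k, n_slabs)
    # background component: flattest spatial loading (smallest CV)
    cv = np.array(
        [W[:, i].std() / W[:, i].mean() if W[:, i].mean() > 0 else np.inf
         for i in range(k)]
    )
    bg_i = int(np.argmin(cv))
    background = np.outer(W[:, bg_i], H[bg_i, :])
    signal = np.clip(X - background, 0.0, None)
    sig_vals = signal[signal > np.percentile(signal, 90.0)]
    bg_vals = background[background < np.percentile(background, 99.0)]
    if sig_vals.size == 0 or bg_vals.size == 0:
        raise ValueError("degenerate decomposition: empty signal or background")
    s_med = float(np.median(sig_vals))
    b_med = float(np.median(bg_vals))
    rsd = float(sig_vals.std() / s_med) if s_med > 0 else float("inf")
    contrast = b_med - s_med if signed_contrast else abs(s_med - b_med)
    return QualityReport(
        signal_median=s_med, signal_rsd=rsd, contrast=float(contrast),
        n_components=k,
    )
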