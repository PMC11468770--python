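"""3-D image volumes, point annotations, and shared raster utilities.

Volumes are unsigned-integer intensity grids indexed ``[x, y, z]`` with an
anisotropic voxel size in micrometers and an origin recording where a block
sits inside the whole-volume voxel frame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import tifffile


@dataclass
class ImageVolume:
    data: np.ndarray  # 3-D uint8 or uint16, indexed [x, y, z]
    voxel_size: tuple = (1.0, 1.0, 1.0)  # micrometers per voxel
    origin: tuple = (0, 0, 0)  # block offset in whole-volume voxels

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("volume data must be 3-D")
        if self.data.dtype not in (np.uint8, np.uint16):
            raise ValueError(f"bit depth must be 8 or 16, got {self.data.dtype}")

    @property
    def shape(self):
        return self.data.shape

    @classmethod
    def from_tiff(cls, path, voxel_size=(1.0, 1.0, 1.0)) -> "ImageVolume":
        # TIFF stacks are stored (z, y, x); transpose to [x, y, z]
        arr = tifffile.imread(path)
        return cls(np.ascontiguousarray(arr.T), voxel_size)

    def to_tiff(self, path) -> None:
        tifffile.imwrite(path, np.ascontiguousarray(self.data.T))


@dataclass
class PointAnnotation:
    """A marker: soma/bouton/critical-point with whole-volume coordinates."""

    x: float
    y: float
    z: float
    radius: float = 0.0
    score: float = 0.0
    label: str = "soma_candidate"
    user: str = ""

    @property
    def position(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)


def write_markers(annotations, path) -> None:
    """Marker CSV: one header line, columns x,y,z,radius,score,label,user."""
    df = pd.DataFrame(
        [
            (a.x, a.y, a.z, a.radius, a.score, a.label, a.user)
            for a in annotations
        ],
        columns=["x", "y", "z", "radius", "score", "label", "user"],
    )
    df.to_csv(path, index=False, float_format="%.3f")


def read_markers(path) -> list:
    df = pd.read_csv(path, keep_default_na=False)
    return [
        PointAnnotation(
            float(r.x), float(r.y), float(r.z), float(r.radius),
            float(r.score), str(r.label), str(r.user),
        )
        for r in df.itertuples()
    ]


def rasterize_tree_mask(
    tree, shape, min_radius: float = 1.0, bounds_origin=(0, 0, 0)
) -> np.ndarray:
    """Binary mask of voxels within per-node radius (floor ``min_radius``) of
    any tree edge; coordinates are voxel units relative to ``bounds_origin``.

    Single-node trees are rasterized as a ball around the node.
    """
    mask = np.zeros(shape, dtype=bool)
    origin = np.asarray(bounds_origin, dtype=float)
    shape_arr = np.array(shape)

    def paint_segment(p0, p1, r0, r1):
        r = max(float(r0), float(r1), min_radius)
        lo = np.floor(np.minimum(p0, p1) - r - 1).astype(int)
        hi = np.ceil(np.maximum(p0, p1) + r + 1).astype(int) + 1
        lo = np.clip(lo, 0, shape_arr)
        hi = np.clip(hi, 0, shape_arr)
        if (hi <= lo).any():
            return
        gx, gy, gz = np.meshgrid(
            *(np.arange(lo[d], hi[d]) for d in range(3)), indexing="ij"
        )
        pts = np.stack([gx, gy, gz], axis=-1).astype(float)
        d = _point_segment_distance(pts.reshape(-1, 3), p0, p1)
        # per-voxel radius: interpolate along the segment projection
        seg = p1 - p0
        L2 = float(seg @ seg)
        if L2 > 0:
            t = np.clip(((pts.reshape(-1, 3) - p0) @ seg) / L2, 0.0, 1.0)
        else:
            t = np.zeros(len(d))
        rad = np.maximum(r0 + t * (r1 - r0), min_radius)
        sub = (d <= rad).reshape(gx.shape)
        mask[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] |= sub

    nm = tree.node_map()
    painted = False
    for n in tree.nodes:
        if n.parent_id != -1 and n.parent_id in nm:
            p = nm[n.parent_id]
            paint_segment(
                p.position - origin, n.position - origin, p.radius, n.radius
            )
            painted = True
    if not painted and tree.nodes:
        for n in tree.nodes:
            paint_segment(
                n.position - origin, n.position - origin, n.radius, n.radius
            )
    return mask


def _point_segment_distance(points: np.ndarray, a, b) -> np.ndarray:
    """Euclidean distance from each point (m, 3) to segment [a, b]."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ab = b - a
    L2 = float(ab @ ab)
    if L2 == 0:
        return np.linalg.norm(points - a, axis=1)
    t = np.clip((points - a) @ ab / L2, 0.0, 1.0)
    proj = a + t[:, None] * ab
    return np.linalg.norm(points - proj, axis=1)
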