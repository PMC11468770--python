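"""Critical-point (branching/terminal) candidate extraction and verification.

Candidates come from the reconstruction itself: after pruning tiny terminal
branches, every bifurcation and every tip is a candidate.  Each candidate is
turned into a 32^3 two-channel patch (image crop + mask rasterized from the
local reconstruction) and handed to a pluggable verifier: any callable
mapping (patch pair, kind) to a probability.  A reference heuristic verifier
based on boundary-component counting ships with the package; trained
classifiers can be plugged in through the same contract.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .compare import confusion_metrics
from .swc import NeuronTree, prune_short_terminal_branches
from .volume import ImageVolume, rasterize_tree_mask


@dataclass
class CriticalPointCandidate:
    position: np.ndarray  # voxel coordinate in the image frame
    kind: str  # "branching" | "terminal"
    source_node: int
    stage: Optional[int] = None


@dataclass
class PatchPair:
    image_patch: np.ndarray  # 32^3 intensities, zero-padded at borders
    mask_patch: np.ndarray  # 32^3 binary raster of the local reconstruction
    center: tuple  # whole-frame voxel coordinate


VerifierContract = Callable[[PatchPair, str], float]


def extract_candidates(
    tree: NeuronTree, resolution_scale=(1.0, 1.0, 1.0), min_branch_nodes: int = 6
):
    """Branching and terminal candidates of a reconstruction.

    Tiny terminal branches (< ``min_branch_nodes`` records) are pruned first;
    coordinates are scaled per axis into the image frame.
    """
    pruned = prune_short_terminal_branches(tree, min_branch_nodes)
    ch = pruned.children_map()
    root_ids = {n.id for n in pruned.roots()}
    scale = np.asarray(resolution_scale, dtype=float)
    out = []
    for n in pruned.nodes:
        kids = ch.get(n.id, [])
        if (len(kids) >= 2 and n.id not in root_ids) or (
            n.id in root_ids and len(kids) >= 2
        ):
            out.append(
                CriticalPointCandidate(n.position * scale, "branching", n.id)
            )
        elif len(kids) == 0 and n.id not in root_ids:
            out.append(
                CriticalPointCandidate(n.position * scale, "terminal", n.id)
            )
    return out


def make_patch_pair(
    volume: ImageVolume, tree: NeuronTree, center, size: int = 32
) -> PatchPair:
    """Image crop + reconstruction mask, both exactly ``size``^3.

    The crop is zero-padded where it exceeds the volume; the mask marks
    voxels within per-node radius (floor 1 voxel) of any tree edge
    intersecting the patch.
    """
    center = np.asarray(center, dtype=float)
    half = size // 2
    lo = np.round(center).astype(int) - half
    img = np.zeros((size, size, size), dtype=volume.data.dtype)
    shape = np.array(volume.shape)
    src_lo = np.clip(lo, 0, shape)
    src_hi = np.clip(lo + size, 0, shape)
    dst_lo = src_lo - lo
    dst_hi = dst_lo + (src_hi - src_lo)
    if (src_hi > src_lo).all():
        img[
            dst_lo[0] : dst_hi[0], dst_lo[1] : dst_hi[1], dst_lo[2] : dst_hi[2]
        ] = volume.data[
            src_lo[0] : src_hi[0], src_lo[1] : src_hi[1], src_lo[2] : src_hi[2]
        ]
    mask = rasterize_tree_mask(
        tree, (size, size, size), min_radius=1.0, bounds_origin=lo
    )
    return PatchPair(img, mask.astype(np.uint8), tuple(int(v) for v in lo + half))


# ---------------------------------------------------------------------------
# Reference heuristic verifier


def _center_component(fg: np.ndarray) -> np.ndarray:
    """Foreground component containing (or nearest to) the patch center."""
    labels, n = ndimage.label(fg)
    if n == 0:
        return fg
    c = np.array(fg.shape) // 2
    lab = labels[tuple(c)]
    if lab == 0:
        idx = np.argwhere(fg)
        d = np.linalg.norm(idx - c, axis=1)
        lab = labels[tuple(idx[np.argmin(d)])]
    return labels == lab


def _boundary_shell(shape) -> np.ndarray:
    shell = np.zeros(shape, dtype=bool)
    shell[0, :, :] = shell[-1, :, :] = True
    shell[:, 0, :] = shell[:, -1, :] = True
    shell[:, :, 0] = shell[:, :, -1] = True
    return shell


def _exit_clusters(comp: np.ndarray, min_size: int = 3):
    """Connected clusters where the component touches the patch boundary.

    3-D connectivity keeps clusters that wrap around a patch edge together;
    clusters below ``min_size`` voxels are residual noise, not neurite exits.
    Returns a list of boolean masks, one per exit.
    """
    touch = comp & _boundary_shell(comp.shape)
    if not touch.any():
        return []
    lab, k = ndimage.label(touch, structure=np.ones((3, 3, 3), dtype=bool))
    out = []
    for i in range(1, k + 1):
        m = lab == i
        if m.sum() >= min_size:
            out.append(m)
    return out


def heuristic_verifier(pair: PatchPair, kind: str) -> float:
    """Reference classifier: 1.0 when the image supports the candidate.

    The smoothed patch is Otsu-thresholded and the component at the patch
    center analyzed.  Branching: a genuine junction sends the component to
    the patch boundary in >= 3 disjoint regions.  Terminal: every boundary
    exit of the component must be explained by the reconstruction mask — a
    prematurely terminated neurite leaves an image exit (the continuation)
    with no reconstructed structure near it, while exits of bystander
    branches crossing the patch are masked and tolerated.
    """
    img = ndimage.gaussian_filter(pair.image_patch.astype(float), sigma=1.0)
    if img.max() == img.min():
        return 0.0
    thr = threshold_otsu(img)
    fg = img > thr
    # drop tiny speckle components the smoothing did not kill
    lab, n = ndimage.label(fg)
    if n:
        sizes = ndimage.sum_labels(fg, lab, index=range(1, n + 1))
        small = np.flatnonzero(np.asarray(sizes) < 10) + 1
        if small.size:
            fg &= ~np.isin(lab, small)
    if kind == "branching":
        # branching is a local question: evaluate exits on the central
        # half-size sub-patch, where bystander branches rarely merge with
        # the candidate's own component
        q = np.array(fg.shape) // 4
        sub = fg[q[0] : -q[0] or None, q[1] : -q[1] or None, q[2] : -q[2] or None]
        comp = _center_component(sub)
        return 1.0 if len(_exit_clusters(comp, min_size=2)) >= 3 else 0.0
    comp = _center_component(fg)
    exits = _exit_clusters(comp)
    if kind == "terminal":
        masked = ndimage.binary_dilation(
            pair.mask_patch.astype(bool), iterations=2
        )
        return 1.0 if all((e & masked).any() for e in exits) else 0.0
    raise ValueError(f"unknown candidate kind {kind!r}")


def verify_candidates(
    pairs, kinds, classifier: VerifierContract = heuristic_verifier
):
    """Apply a verifier to (patch, kind) pairs; label = probability >= 0.5.

    The classifier must return a probability in [0, 1]; anything else is a
    contract violation.
    """
    labels = []
    for pair, kind in zip(pairs, kinds):
        p = float(classifier(pair, kind))
        if not (0.0 <= p <= 1.0):
            raise ValueError(
                f"verifier contract violation: probability {p} outside [0, 1]"
            )
        labels.append(p >= 0.5)
    return labels


def evaluate_verifier(
    candidates, predicted, expert_tree: NeuronTree, match_radius: float = 4.0
):
    """(precision, recall, accuracy) of verifier labels against an
    expert-proofed reconstruction.

    A branching candidate's true class is positive iff the expert tree has a
    branching point within ``match_radius``; a terminal candidate's iff it
    has a terminal there.
    """
    exp_branch = [
        c.position for c in extract_candidates(expert_tree, min_branch_nodes=1)
        if c.kind == "branching"
    ]
    exp_term = [
        c.position for c in extract_candidates(expert_tree, min_branch_nodes=1)
        if c.kind == "terminal"
    ]

    def near(pos, pts):
        return any(np.linalg.norm(pos - p) <= match_radius for p in pts)

    tp = tn = fp = fn = 0
    for cand, pred in zip(candidates, predicted):
        truth = near(
            cand.position, exp_branch if cand.kind == "branching" else exp_term
        )
        if pred and truth:
            tp += 1
        elif pred and not truth:
            fp += 1
        elif not pred and truth:
            fn += 1
        else:
            tn += 1
    return confusion_metrics(tp, tn, fp, fn)
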