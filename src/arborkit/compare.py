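"""Agreement metrics between neuron reconstructions.

The central quantity is a length-based decomposition: after resampling both
trees to a common fine step, every arc-length element of the test tree is
*matched* if it lies within a distance threshold of the reference, and vice
versa.  Rc (fraction of test length that is correct) and Rm (fraction of
reference length that is recovered) combine into a single accuracy score via
their harmonic mean, accuracy = 2*Rc*Rm/(Rc+Rm).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .swc import NeuronTree, resample


@dataclass
class MatchReport:
    matched_length_test: float
    unmatched_length_test: float
    matched_length_ref: float
    unmatched_length_ref: float
    Rc: float
    Rm: float
    accuracy: float
    distance_threshold: float

    def as_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class ConsistencyReport:
    mean_bidirectional_distance: float
    fraction_within: float
    threshold_voxels: float


def accuracy_statistic(Rc: float, Rm: float) -> float:
    """Harmonic mean of the correctly-traced and recovered ratios;
    0 when both ratios are 0."""
    if not (0.0 <= Rc <= 1.0) or not (0.0 <= Rm <= 1.0):
        raise ValueError(f"Rc and Rm must lie in [0, 1], got {Rc}, {Rm}")
    if Rc + Rm == 0.0:
        return 0.0
    return 2.0 * Rc * Rm / (Rc + Rm)


def sample_arc_elements(tree: NeuronTree, step: float):
    """Resample and return (midpoints (m,3), lengths (m,), node_positions (n,3)).

    Each resampled edge contributes one element located at its midpoint and
    weighted by its length; the node positions support nearest-point queries.
    """
    rs = resample(tree, step)
    pos = rs.positions()
    mids, lengths = [], []
    for p, c in rs.edges():
        mids.append((p.position + c.position) / 2.0)
        lengths.append(float(np.linalg.norm(p.position - c.position)))
    if mids:
        return np.array(mids), np.array(lengths), pos, rs
    return np.zeros((0, 3)), np.zeros(0), pos, rs


def _directional_match(mids, lengths, other_pos, threshold):
    """(matched_length, unmatched_length) of elements whose nearest point in
    ``other_pos`` lies within ``threshold``."""
    if len(mids) == 0:
        return 0.0, 0.0
    if len(other_pos) == 0:
        return 0.0, float(lengths.sum())
    tree = cKDTree(other_pos)
    d, _ = tree.query(mids)
    matched = lengths[d <= threshold].sum()
    return float(matched), float(lengths.sum() - matched)


def match_length(
    test: NeuronTree, ref: NeuronTree, dist_threshold: float = 2.0
) -> MatchReport:
    """Length-based matching between a test and a reference reconstruction.

    Both trees are resampled internally at min(1, threshold/2) so the ratios
    are arc-length-based rather than node-count-based.  Degenerate inputs:
    two empty trees agree perfectly (accuracy 1); one empty tree scores 0.
    """
    if len(test.nodes) == 0 and len(ref.nodes) == 0:
        return MatchReport(0, 0, 0, 0, 1.0, 1.0, 1.0, dist_threshold)
    if len(test.nodes) == 0 or len(ref.nodes) == 0:
        return MatchReport(0, 0, 0, 0, 0.0, 0.0, 0.0, dist_threshold)
    step = min(1.0, dist_threshold / 2.0)
    t_mid, t_len, t_pos, _ = sample_arc_elements(test, step)
    r_mid, r_len, r_pos, _ = sample_arc_elements(ref, step)
    mt, ut = _directional_match(t_mid, t_len, r_pos, dist_threshold)
    mr, ur = _directional_match(r_mid, r_len, t_pos, dist_threshold)
    Rc = mt / (mt + ut) if mt + ut > 0 else 1.0
    Rm = mr / (mr + ur) if mr + ur > 0 else 1.0
    return MatchReport(mt, ut, mr, ur, Rc, Rm, accuracy_statistic(Rc, Rm), dist_threshold)


def consistency(
    a: NeuronTree,
    b: NeuronTree,
    threshold_voxels: float = 2.0,
    voxel_size=(1.0, 1.0, 1.0),
) -> ConsistencyReport:
    """Bidirectional nearest-node consistency between two reconstructions of
    the same neuron.

    For every node of one tree the nearest node of the other is found; the
    report gives the mean of the two directional mean distances (symmetric in
    argument order) and the pooled fraction of nodes whose nearest-neighbor
    distance is below ``threshold_voxels`` (converted with ``voxel_size``).
    """
    if len(a.nodes) == 0 or len(b.nodes) == 0:
        raise ValueError("consistency is undefined for empty reconstructions")
    pa, pb = a.positions(), b.positions()
    da, _ = cKDTree(pb).query(pa)
    db, _ = cKDTree(pa).query(pb)
    thr = threshold_voxels * float(np.mean(voxel_size))
    pooled = np.concatenate([da, db])
    return ConsistencyReport(
        mean_bidirectional_distance=float((da.mean() + db.mean()) / 2.0),
        fraction_within=float((pooled < thr).mean()),
        threshold_voxels=threshold_voxels,
    )


def confusion_metrics(tp: int, tn: int, fp: int, fn: int):
    """(precision, recall, accuracy) from confusion counts.

    Undefined ratios (zero denominator) are reported as NaN with a warning.
    """
    for name, v in (("tp", tp), ("tn", tn), ("fp", fp), ("fn", fn)):
        if v < 0:
            raise ValueError(f"{name} must be non-negative, got {v}")
    precision = recall = accuracy = float("nan")
    if tp + fp > 0:
        precision = tp / (tp + fp)
    else:
        warnings.warn("precision undefined: TP + FP = 0", stacklevel=2)
    if tp + fn > 0:
        recall = tp / (tp + fn)
    else:
        warnings.warn("recall undefined: TP + FN = 0", stacklevel=2)
    total = tp + tn + fp + fn
    if total > 0:
        accuracy = (tp + tn) / total
    else:
        warnings.warn("accuracy undefined: no counts", stacklevel=2)
    return precision, recall, accuracy
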