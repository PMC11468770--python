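# Methods

`arborkit` re-creates, at desk scale, the computational core of a
collaborative neuron-reconstruction platform: the data model and metrics for
SWC neuron trees, the server-side detectors for somas and axonal boutons,
the critical-point verification scaffolding, image-quality statistics, and
an executable model of the multi-annotator reconstruction protocol.  Every
component is testable against synthetic volumes and trees; no whole-brain
data, trained network weights, or human annotators are required.

## Neuron trees

A reconstruction is a rooted tree of typed, positioned, radius-bearing
nodes (the SWC convention; ESWC adds four columns that are carried through
verbatim).  Trees are *quasi-binary*: only the soma node may have more than
two children.  `validate_tree` reports violations rather than raising, so
fragment files remain representable.

Key operations and their conventions:

* **Pruning** removes terminal branches with fewer than 6 SWC records,
  counting the nodes from the tip up to but excluding the nearest branching
  point, iterating to a fixpoint.  Branches attached directly to the root
  are exempt — otherwise a small unbranched tree would prune itself away.
  A "unit" is read as an SWC record, not a micrometer; the boundary tests
  (5 pruned / 6 kept) pin this choice.
* **Resampling** interpolates positions and radii linearly along each
  unbranched run at a uniform arc-length step, preserving root, branching
  points and tips exactly, so tip/bifurcation counts and topological height
  are invariant.
* **Global features** follow the L-Measure definitions: total Euclidean
  length, bifurcation count (root counted once when it has ≥ 2 children),
  tip count, topological depth (max bifurcations on a root→tip path + 1)
  and volume as a sum of conical frustums.

## Comparison metrics

Two reconstructions are compared by length matching: both trees are
resampled at min(1, threshold/2), each resampled edge contributes an
element at its midpoint weighted by its length, and an element is matched
when its nearest resampled node of the other tree lies within the distance
threshold (default 2 voxels, the same threshold the consistency metric
uses; the field does not agree on a canonical value, so it is exposed as a
parameter).  Rc is the matched fraction of the test tree's length, Rm the
covered fraction of the reference length, and the accuracy score is their
harmonic mean 2·Rc·Rm/(Rc+Rm) — 1 for a perfect reconstruction, 0 when
either side is entirely wrong.  Rm is implemented as "1 − missing
fraction" so that perfect reconstructions score 1.

Consistency between two reconstructions of the same neuron is node-based:
the mean of the two directional mean nearest-node distances plus the pooled
fraction of nodes with a nearest neighbor closer than 2 voxels.  Both
statistics are symmetric in argument order by construction.

Tolerances: the matching machinery is checked for exact equality (1e-9)
against an exhaustive O(n²) reimplementation; deletion-recovery checks use
a 1-voxel threshold because each cut boundary contributes up to a threshold
of spuriously matched reference length, which must stay below the ±0.02
recovery tolerance.

## Topological height and stage recovery

Tips have TH = 1; a branching point takes 1 + the maximum TH of its
children; pass-through nodes inherit their child's TH, making TH a
branch-level quantity that resampling cannot change.  NTH divides by the
maximum TH observed across all reconstruction stages of the same neuron
(never per stage), so NTH ∈ (0, 1] and the final structure attains 1.

Stage snapshots cut the edit-log timeline at t₀ + i·span/n (i = 1..n,
default n = 8) and replay all add/delete events at or before each cut;
confirmations do not change geometry.  The timeline is divided by wall
clock, not event count.  Per stage, every resampled arc element is labeled
matched/unmatched against a reference and accumulated into NTH bins of the
node ending its edge — errors caught early should appear only at low NTH.

## Soma detection

The block pipeline mirrors server-side screening of 16-bit whole-brain
volumes: blocks of ~256³ voxels are discarded when their maximum intensity
is below 250 (no labeled structure); survivors are z-score normalized
(clipped at ±3σ, mapped affinely to [0, 255] — the mapping itself is a
convention choice, 3σ clipping being standard), binarized at the block's
own 99th intensity percentile, and Euclidean-distance-transformed.  Voxels
whose transform value falls in the soma-radius band [5, 30] become
candidates, scored and radius-tagged by that value, and thinned by greedy
non-maximum suppression (radius 15 voxels ≈ the mean of the band; ties
broken by coordinate order, so NMS is order-independent).

Two deliberate choices:

* Candidates are restricted to local maxima of the transform (3³
  neighborhood, plateau-tolerant).  A plain in-band selection leaves shell
  voxels of large somas (transform ≥ 5 at > 15 voxels from the center)
  that NMS cannot suppress, producing ring artifacts.
* The "grayscale distance transform" is read as the Euclidean transform of
  the binarized foreground, since binarization immediately precedes it; a
  gray-weighted variant ships behind `transform="gray_geodesic"`.

The percentile binarization presumes sparse foreground: if somas occupied
more than ~1% of a block, the 99th percentile would land inside the soma
intensity distribution and fragment the foreground.  The synthetic
soma-phantom generator therefore caps soma occupancy at 0.8% of the block
and keeps centers separated beyond the NMS radius — both properties of the
whole-brain data this pipeline is built for, not tuning knobs.  Its noise
level follows the generator-wide convention SNR = (shaft − background)/σ,
with somas twice as far above background as the shaft reference, as in
labeled tissue.

## Bouton detection

Boutons (presynaptic varicosities) appear as coincident peaks in the
intensity and radius profiles along an axonal shaft.  The axon is resampled
at 1 voxel per branch (peaks never span a bifurcation); intensity is
trilinear-interpolated on the 8-bit scale (16-bit blocks are min–max
rescaled first, since the intensity threshold is defined for 8-bit images);
the radius estimate at a point is the largest integer r such that ≥ 85% of
the sphere surface of radius r is above a background threshold.

Candidates are local maxima of the moving-average-smoothed (width 3)
intensity profile with a radius peak within a 3-node overlap window.  Two
filters follow: candidate radius ≥ 1.5 × the median radius of surrounding
nodes (10 resampled nodes per side, excluding the candidate and its
immediate neighbors) and intensity > 120; candidates closer than 5 voxels
(Euclidean) keep only the brighter one.  The candidate radius is read from
the smoothed profile (maximum over the peak index ± 1): the raw integer
estimator flickers by ±1 voxel under noise, and a single-sample spike must
not pass a ratio test that a real swelling passes over several samples.

The phantom generator plants varicosities along shafts only, away from
branch points and tips (a swelling at a topological node is not a shaft
varicosity), and generated trees are self-avoiding (nodes far apart on the
tree stay ≥ 5 voxels apart in space): real neurites do not graze each other
at submicrometer resolution, and a grazing pair reads as a false
varicosity in any profile-based detector.

## Critical-point verification

After pruning, every bifurcation and tip of a reconstruction is a
candidate.  Each candidate becomes a 32³ image patch (zero-padded at
volume borders) plus a mask rasterized from the reconstruction (voxels
within per-node radius of any edge, floor 1 voxel) — the two-channel input
a plug-in classifier consumes.  The classifier contract is a callable
(patch pair, kind) → probability; trained CNNs can be plugged in without
changing the scaffolding.  The reference heuristic works on the
Otsu-thresholded, Gaussian-smoothed patch:

* *branching*: the component at the patch center must reach the boundary
  of the central 16³ sub-patch in ≥ 3 disjoint places.  The sub-patch
  matters: at full 32³ scale, bystander branches of the same arbor merge
  with the candidate's component and inflate the exit count.
* *terminal*: every boundary exit of the center component must overlap the
  dilated reconstruction mask.  A prematurely terminated trace leaves an
  image exit (the continuation) with no reconstructed structure near it;
  exits of masked bystander branches are tolerated.

Candidates are scored against an expert tree by distance (4 voxels,
roughly half the patch radius): a branching candidate is truly positive
iff an expert bifurcation lies within range.  On sparse phantoms with
injected false bifurcations and premature terminations the heuristic
reaches pooled accuracy ≈ 0.84 — a sanity floor, far below what trained
networks achieve on real data, which is exactly why the classifier is a
contract.

## Image metrics

* *Signal complexity*: with the reconstruction (dilated by node radius) as
  the foreground mask, each 20³ cube scores mean(foreground) /
  mean(background); the cube map is min–max rescaled to 8 bits.
* *Local structural complexity*: Sholl-style crossing counts with every
  node as a center; segment–sphere crossings are counted exactly (0, 1 or
  2 per edge and radius).
* *User attention*: the number of distinct users whose edit events fall in
  a 20 µm axis-aligned cube around each node (closed below, open above);
  delete/confirm events inherit the geometry of the segment they touch.
* *NMF quality*: every 10 z-slices are averaged and flattened into one
  column of a non-negative matrix; a rank-3 NMF (deterministic NNDSVD-A
  initialization) factors it.  The background is the component whose
  pixel-space loading has the smallest coefficient of variation (the
  flattest one); signal is the residual clipped at 0.  Statistics apply
  the percentile filters (signal above its 90th percentile, background
  below its 99th); `signal_rsd` = sd/median of the filtered signal, and
  contrast is reported as the magnitude of the filtered-median difference
  (the literal signed convention is available via `signed_contrast=True`).
  On the tube-phantom family, `signal_rsd` decreases strictly with added
  noise — the clean image's tube tail stands far above the residual bulk,
  maximizing relative dispersion of the top decile — so the noise ordering
  of a phantom series is recoverable from `signal_rsd` alone; the
  direction of the relationship is family-specific.

## The collaboration protocol and its simulator

Segments (polylines between topological events) are the atomic unit.  The
state machine enforces: adds must anchor to the soma, to the author's own
segment, or to a confirmed segment; cross-user confirm/delete/modify
requires the target to originate from the soma or extend a confirmed
segment; nobody confirms their own work; completion means every live
segment is confirmed.  Deleting one's own unconfirmed segment is always
allowed (managing one's own work is part of annotating it); deletion
cascades to attached descendants.  A modify is a delete + re-add pair
sharing a lineage id, which re-authors the segment — its confirmation by a
third user then follows from the ordinary rules.

Agreement is the confirmed fraction of live reconstructed length; by the
self-confirmation ban, confirmed implies at least two distinct users
touched the structure.  Deleted-and-unreplaced structure is excluded from
the denominator.

The simulator runs round-robin agents with one action per turn (timestamps
are turn indices, so logs are byte-reproducible from the seed).  An agent
reviews an eligible peer segment when one exists — confirming correct
segments, deleting spurious ones and repairing truncated ones with
probability `confirm_diligence`, otherwise wrongly confirming — and
otherwise traces an untraced true branch, which with probability
`error_rate` instead produces a spurious branch or a premature
termination.  Every event passes the state machine; a turn cap of
50 × branches guarantees termination.  With 3 annotators at error 0.1 and
diligence 0.9, 50 seeded runs all complete with final accuracy ≈ 0.999,
stage-wise mean accuracy non-decreasing, and residual unmatched structure
confined to low NTH.

The noncollaborative counterfactual revokes every cross-user delete and
the replacement half of every cross-user modify, then replays leniently
(dangling references are dropped).  The contrast projection map assigns
added/subtracted length to integer-labeled regions and marks each region
'+', '−' or 'o'.

## Synthetic data

The generator emulates sparse single-neuron fluorescence microscopy:
Gaussian-profile tubes (peak on the axis, σ = radius/2 — a one-parameter
stand-in for the point-spread function), a bright soma ball with a soft
edge, varicosities as soft balls with peak 1.4 × shaft intensity (a larger
swelling gathers more fluorophore), sphere artifacts with soma-like
intensity (blood-vessel/leakage stand-ins, radius 2–4 voxels so the
soma-detection band rejects them), additive Gaussian noise and bit-depth
clipping.  Default conditions: 128³ voxels at (0.46, 0.46, 2.0) µm — the
whole-brain block geometry — 8 branches of 25–50 voxels, shaft radius
1.5–2.5 voxels, soma radius 8, 10 varicosities at ratio 1.8 and spacing 12,
intensities shaft 160 / soma 230 / background 40 with σ 30 (SNR 4).  All
geometry is generated in voxel units; the voxel size is a unit tag.

What the phantoms do *not* emulate: anisotropic point-spread functions,
depth-dependent attenuation, autofluorescence texture, vessel trees (only
sphere artifacts), and real annotator behavior (simulated agents err
independently; humans err systematically).  Passing tests therefore
demonstrate the correctness and internal coherence of the algorithms under
the stated conditions, not field performance on microscope data.

## Problem sizes and determinism

The default test suite and the acceptance script use 10–20 phantoms of
128³–256³ voxels, 50-run protocol simulations, and 10⁵-event fuzzing; a
full run of each finishes in a few minutes on one CPU.  All randomness
flows through `numpy.random.default_rng` seeded from the caller;
NMF uses deterministic NNDSVD-A initialization, and the quality CLI rounds
its JSON to 6 decimals, below the solver's numerical noise, so fixed-seed
runs are byte-reproducible.

## Known limitations

* The matching threshold ("correctly traced") is not canonically defined in
  the field; results depend on it near the resolution limit.
* The integer sphere-surface radius estimator quantizes small radii
  (1–3 voxels) coarsely; the ratio filter compensates via the smoothed
  profile but sub-voxel radii are not resolved.
* The heuristic critical-point verifier is a reference implementation for
  the classifier contract, not a replacement for trained models.
* The simulator's agents act round-robin with a single action per turn;
  concurrency effects (locking, message latency) are out of scope.
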