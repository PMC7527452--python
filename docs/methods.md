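# Methods

## The measurement problem

Monoaminergic innervation density is quantified from multi-channel confocal
z-stacks: a fiber channel (SERT, NET or a membrane-bound YFP reporter), a
synaptophysin channel, and one or two postsynaptic scaffold channels
(gephyrin = inhibitory, PSD95 = excitatory). The derived quantities —
axonal volume density, varicosity density, bouton density, proximity-defined
synapse and triad densities — are all normalized to the tissue (ROI) volume
so they are intensive and comparable across animals and groups.

All geometry is physical: the internal axis order is (channel, z, y, x),
a voxel's coordinate is its center, and distances are Euclidean in
micrometers. The pairing distance that defines a synapse (0.6 μm,
center-to-center) is a single shared constant used by both the simulator's
constructed arrangements and the analysis. 0.6 μm is also the spot-detection
floor: a sphere of that diameter intersects at least two optical slices at
the 0.3 μm z-step of the emulated acquisition, so detected spots are real
3-D objects rather than single-slice artifacts.

## Synthetic stacks

The simulator emulates the study design end-to-end so the analysis can be
validated by ground-truth recovery.

**Axons.** Fixed-step persistence random walks (step 1 μm, persistence 0.9,
default 50 μm of path per axon) reflected at the box faces, drawn as tubes
of radius 0.3 μm. The default field is 256 × 256 × 30 voxels at
0.13/0.13/0.3 μm (33.28 × 33.28 × 9 μm) with 40 axons, giving a fiber
volume fraction near 0.05 — dense innervation, but with tubes far enough
apart that blob detection operates in its validated regime. The true volume
fraction is computed as the voxel-union of all tubes on a fine sub-grid
(spacing ≤ radius/4 per axis), so axon overlap is not double-counted; for
straight non-overlapping tubes it matches the closed-form cylinder volume
within ~2 %.

**Varicosities and boutons.** Varicosities are spheres of twice the axon
radius placed along each centerline at 0.1 per μm of axon (about one per
10 μm, in the range reported for cortical monoaminergic fibers). Counts are
quasi-deterministic (the fractional part of rate × length is resolved by a
single Bernoulli draw) rather than Poisson: animals within a group are meant
to differ by geometry and measurement noise, not by generator-injected count
scatter, which keeps per-group variance representative of a well-controlled
imaging experiment. 70 % of varicosities carry a synaptophysin punctum (a
bouton), rendered offset half a varicosity radius from the center — the
vesicle cluster apposed to the membrane — which also makes bouton-adjacent
constructed arrangements geometrically feasible.

**Puncta.** Outside-fiber synaptophysin (0.25/μm³) and postsynaptic puncta
(0.3/μm³) are sampled uniformly in the fiber-free volume; their centers must
clear the tube (and varicosity) surfaces by half a punctum radius, so the
center-voxel compartment rule can separate them from true boutons while
still allowing the partial interdigitation seen in real neuropil. Rendered
puncta are 0.6 μm diameter spheres — the detection floor.

**Constructed arrangements.** Three fractions control ground-truth synaptic
structure: `sero_paired_fraction` (0.4) of boutons receive an apposed
postsynaptic punctum just outside the fiber; `paired_fraction` (0.3) of
outside-synaptophysin puncta receive a postsynaptic partner within the
pairing distance; `triad_fraction` (0.2) of boutons receive a constructed
(Syn_out, postsyn) pair whose midpoint lies within the pairing distance,
oriented tangent to the local fiber so both members keep their clearance.
Anchors for which placement is locally infeasible are swapped for other
anchors; if the requested number still cannot be placed, the generator
raises with the shortfall. The recorded true pair/triad counts are an
exhaustive O(n²) recount over the emitted coordinates with the same greedy
unique matching the analysis uses (the analysis implements it independently
with a KD-tree; tests require exact agreement).

**Optics and noise.** Each channel is drawn as anti-aliased ideal intensity
in [0, 1], convolved with an anisotropic Gaussian PSF (default σ =
0.1/0.1/0.2 μm — narrow, emulating deconvolved data), scaled to an expected
photon count (50 at full intensity over a background of 5, i.e. peak SNR
≈ 6–7), then Poisson shot noise and Gaussian read noise (σ = 1) are applied.
Determinism: a master seed spawns separate substreams for axon growth,
punctum placement and rendering, so identical configurations give
bit-identical stacks.

**What the simulator does not emulate.** No autofluorescence gradients,
chromatic aberration, stage drift, partial antibody penetration, or
SERT/NET co-release biology; puncta are spheres of a single size; axons
have no branching. Reflection at the box faces produces occasional sharp
fiber folds whose 3-D thickness resembles a varicosity — a boundary
artifact of the walk model, visible as rare false-positive varicosities in
crowded stacks (see Limitations). Passing tests therefore show that the
analysis recovers structure under idealized, known optics — not that it is
robust to every artifact of real tissue.

## Fiber segmentation

Background subtraction (rectangular white top-hat, 2 μm radius), Gaussian
smoothing (σ = 0.1 μm, matched to the lateral PSF width — wider smoothing
measurably inflates the apparent volume of 0.6 μm fibers), then a global
threshold and removal of connected components below 0.05 μm³.

The default threshold is **half the robust signal plateau**, estimated as
the mean of the brightest 0.02 % of voxels (≥ 20). Under a symmetric PSF
the half-maximum surface tracks the true object boundary, so measured fiber
volume scales linearly through zero with true volume — a property Otsu's
threshold lacks on noisy stacks, where its additive offset distorts
between-group ratios. Otsu, absolute and quantile thresholds remain
available (`threshold="otsu"`, a number, or `"q99"`), and an all-background
channel yields an empty mask with a warning.

Skeletonization uses a 3-D medial axis; branches are polylines between
junctions/endpoints, with arc length measured after light moving-average
smoothing (discrete voxel paths zigzag on anisotropic grids and otherwise
overestimate length by ~10 %). A leaf branch's trunk radius is the median
Euclidean-distance-transform value along the longest other branch at its
junction; leaves with length/trunk-radius below `min_ratio` (default 2.0,
meaningful range 1.5–2.5) are removed as background spurs, as are isolated
fragments shorter than the 0.6 μm filament diameter. The minimum-fragment
rule is the only "additional filtering" implemented; commercial packages
apply further unpublished heuristics.

## Spot detection

Both varicosity and punctum detection use scale-normalized LoG filtering in
*physical* coordinates: the per-axis filter σ is the physical scale divided
by that axis's voxel size, which the 0.3 μm z-step over 0.13 μm pixels
requires. Scales span diameters from the 0.6 μm floor to 3× (varicosities)
or 2× (puncta) that value; blob diameter is 2σ√3 at the best scale, so no
detection falls below the floor by construction. Intensities are first
normalized to background-noise units (median/MAD), making thresholds
comparable across stacks and exposure levels.

- **Puncta**: LoG response threshold 3.0 (noise units); detections closer
  than half the minimum diameter are merged keeping the stronger; sub-voxel
  centers by intensity-weighted centroid in a one-diameter neighborhood.
  At peak SNR ≥ 5 and spacing ≥ 1.2 μm this yields recall and precision
  above 0.9 at a 0.5 μm match radius.
- **Varicosities**: the thin tube signal is first suppressed by a
  grey-scale ellipsoid opening (ball diameter 1.5× the 0.6 μm filament
  diameter — structures thinner than a varicosity cannot contain the ball
  and erode away; semi-axes round *down* in voxels so the coarse z axis
  never inflates the ball). LoG detection then runs on the opened image
  restricted to the fiber mask dilated by one voxel, with threshold 6.0 —
  calibrated to sit above residual tube-ridge and fold responses while
  solid-sphere responses at SNR ≥ 5 lie near 8–11.

Compartment labeling is a separate, idempotent step: a synaptophysin
punctum is `in_fiber` iff its center voxel lies in the (undilated) fiber
mask; gephyrin/PSD95 puncta inside the mask are discarded, as the
postsynaptic classes are defined outside the fiber surface. A configurable
dilation is exposed for sensitivity analysis. Detecting on the masked
channel versus detecting then partitioning gives the same in-fiber set on
clean input (tested).

## Synapse and triad calling

`pair_within` supports two modes: `all` (every qualifying pair) and the
default `unique` — greedy globally-shortest-distance-first matching with
deterministic tie-breaking (distance, then first index, then second), each
punctum used at most once, which avoids double-counting in crowded
neuropil. Serotonergic calls pair in-fiber synaptophysin with a
postsynaptic channel; "other" calls pair outside-fiber synaptophysin with
the same channel; the two matchings are independent.

Triads attach an in-fiber bouton to a non-serotonergic pair when the
bouton's distance to the pair's reference point is within the pairing
distance. The default reference is the pair **midpoint** (symmetric in the
two members); `nearest-member` and `both-members` are provided as
alternatives. Each bouton joins at most one triad (nearest reference wins).
Polarity is presynaptic when the bouton is nearer the pair's synaptophysin
member, postsynaptic when nearer the scaffold member; exact ties resolve as
presynaptic. These conventions — center-to-center distances, midpoint
reference, at-most-one membership, nearest-member polarity — are
operational choices where the underlying biology defines none, and all are
exposed as parameters.

Colocalization between two fiber channels is volume(a ∩ b)/volume(a) with
b dilated by one voxel by default: the two channels carry independent
photon noise, so their segmentation boundaries jitter by about a voxel and
a strict intersection undercounts surface volume by several percent.
`tolerance_voxels=0` gives the strict definition.

## Statistics

Animals are the unit of analysis; multiple ROIs per animal are averaged
before testing. Each (measure, region) is tested independently by classical
one-way ANOVA, with Tukey's studentized-range HSD for pairwise post-hocs
(q = |Δmean|/√(MSW/2·(1/nᵢ+1/nⱼ)), p from the studentized-range
distribution with N−k error df); no cross-measure multiplicity correction
is applied, matching per-panel practice in small histology cohorts.
Summaries are mean ± SEM. Both statistics agree with independent reference
implementations to 6 decimals and are calibrated: the *full simulated
pipeline* (simulate → render → segment → density → ANOVA on three no-effect
groups of four animals, run on reduced 50 × 50 × 10-voxel stacks so 500
replicates complete in minutes) rejects at 4–5 % at nominal α = 0.05.

## Problem sizes and determinism

Validation uses scaled-down problems chosen to exercise every code path:
256 × 256 × 30-voxel stacks for cohort recovery (16 animals across four
groups, effect multipliers 1.0/0.5/0.5/1.0 on the axon count), 2000 puncta
per class for oracle-equivalence checks, and 50 × 50 × 10-voxel stacks for
null-calibration replicates. The full 1024 × 1024 acquisition geometry is
available through `SimulationConfig`. Every entry point is deterministic
given its configuration and seed; cohorts derive per-animal seeds from the
master seed via `numpy` seed sequences.

## Limitations

- The segmentation half-max rule is unbiased for objects at or above the
  resolution limit; for structures much thinner than the PSF it would
  underestimate. The 0.5–0.6 μm fibers targeted here sit at the boundary,
  and absolute volumes carry a ±10–15 % scale uncertainty even on clean
  input — between-group *ratios* are unaffected, which is what the group
  statistics consume.
- Varicosity detection degrades gracefully with crowding (neighboring
  tubes raise the LoG surround and suppress responses); at the default
  innervation density recall is ~0.9 and group ratios are preserved, but
  at several-fold higher density counts would saturate.
- Sharp fiber folds (including wall-reflection kinks of the synthetic
  walk) are genuinely swelling-shaped and can produce rare false-positive
  varicosities; they are not distinguishable from true swellings by shape
  alone at this resolution.
- Proximity-defined synapses are putative: a 0.6 μm center distance does
  not establish ultrastructural contact, and the postsynaptic neuron type
  is not identified.
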