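# Methods

## The atlas fixture

The cell-type atlas ships as three text fixtures under `mbatlas/atlas/data/`:
`cell_types.csv` (56 rows: 7 KC types, 21 MBON types, 20 DAN types and 8
other modulatory/atypical types), `innervation_matrix.csv` (41 MBON/DAN rows
× 37 elemental subdivisions, entry codes `N`/`Dd`/`Ds`/`Xd`/`Xs`/`O`), and
`pam_counts.json` (the nine per-compartment PAM-cluster counts from split-
GAL4 labeling and from photoactivation tracing).  Greek letters and primes in
names are normalized to an ASCII canonical form (γ→`g`, α′→`ap`, β′→`bp`) so
the fixtures are encoding-safe; the mapping is bidirectional.

Conventions that matter for the census arithmetic:

* **Region sets are derived from the systematic nomenclature** and validated
  by a round-trip test: parsing every MBON/DAN name must reproduce the stored
  dendrite/terminal sets exactly.
* **Counts are (min, max) ranges**; census sums use the minimum unless asked
  otherwise.  Count queries on KCs support rounding to the nearest hundred
  (the seven per-type counts sum to 2015, quoted as ~2000).
* **Compartment multiplicity**: MBON types are tallied over dendritic
  compartments with the pedunculus core counting as an extra region (a
  compartment plus the pedc makes a type multi-compartment); DAN types are
  tallied over the 15 lobe compartments only, so a DAN innervating a
  compartment plus the pedc still counts as single-compartment.  These are
  the conventions under which the atlas' printed 13/8 (MBON) and 17/3 (DAN)
  splits are exact.
* **Convergence ratios** assume every KC forms synapses in each elemental
  subdivision its axon traverses: the ratio for an MBON is the summed count
  of KC types occupying its dendritic subdivisions, doubled for the three
  types with bilateral dendrites.  The derived ratio for MBON-β2β′2a is
  2400:1; the printed approximation (~2300:1) is recorded alongside
  (`queries.REPORTED_CONVERGENCE`) and deliberately not forced to agree,
  since it is not recoverable from the rounded per-type KC counts.
* **The feedforward graph** is built from the innervation matrix: a KC
  source node feeds every MBON, and an MBON→MBON edge exists wherever one
  type's in-lobe axon subdivisions (`X` entries) intersect another's
  dendritic subdivisions.  The graph is checked to be acyclic over MBONs and
  no edge may re-enter its source's own dendritic compartment.  Longest-path
  depth is counted in MBON nodes.
* The pedunculus core is modeled as a 16th region, excluded from
  "15 compartments" counts; its KC occupancy is all three α/β types.
  MBON-calyx (the atypical output neuron with dendrites in the calyx) is
  stored with class `other-modulatory` so MBON censuses run over the 21 lobe
  MBON types.

## Synthetic phantoms

The generators emulate the inputs the imaging pipeline consumes; all are
deterministic functions of (spec, seed).

**Standard brain.** The three lobes are straight tubes (radius 7 voxels)
along y on a 128×128×96 grid at 0.76 µm isotropic — twice the real working
resolution, so tests run in seconds.  Each tube carries five ordered
compartment spans; the α/β tube inserts a short `pedc` span between α1 and
β1.  Five ellipsoids provide the MBON projection zones (CRE, SMP, SIP, SLP,
LH) and three more (AL, AVLP, PLP) give stray signal somewhere to land; the
remaining cataloged neuropils have no geometry.  The reference channel (a
pan-synaptic density stain) is 1 inside neuropils with a multiplicative dip
(default 0.4 over a ±2-voxel band, smoothed at σ=0.8) at four designated
compartment borders — synthetic stand-ins for borders with reduced synaptic
density, and the ground truth for border-gap detection.

**Specimens.** An expressed MBON's dendrites (or a DAN's terminals) fill
their compartment spans; an axon shaft (radius 1.4 voxels) runs to each of
the type's projection zones and ends in a bouton blob (radius 3.5).  The
presynaptic channel is 10 in terminal voxels and 0.3 elsewhere in the arbor
— a deliberately comfortable version of the >5-fold bouton enrichment the
terminal/dendrite splitter assumes.  Channels are pulled back through a
specimen transform (random affine: ±10° rotation, ±10 % per-axis scale,
±5-voxel translation, composed with a band-limited displacement field of
bounded amplitude, default 2 voxels, σ=8; the generator halves the amplitude
until the total map's Jacobian determinant is positive everywhere) and
corrupted with Poisson shot noise (gain 200 photons/unit) plus Gaussian read
noise (σ=0.01).  Transforms map fixed (standard-grid) physical µm
coordinates to moving coordinates, field first, then affine.

**Nucleus fields.** Nuclei are flat-top blobs with a linear soft edge
(width 1.4 voxels) at 0.5 µm spacing, diameters Normal(4.5, 0.35 µm)
truncated at ±0.8 SD, amplitudes in [0.95, 1].  The truncation plus the
soft-edge geometry keep every nucleus inside a mean ± 2 SD sphere-volume
gate at both counting thresholds (thresholding a soft-edged blob biases its
apparent radius by ± ≈ edge_width × (0.5 − t)); these parameters were fixed
from that arithmetic, not per-dataset.  A touching pair places two surfaces
1.4 voxels apart: close enough that the soft edges and 26-connectivity merge
the pair at the low threshold (0.3), far enough that the high threshold
(0.7) leaves two gate-passing cores.  The membrane channel is a shell two
voxels off the surface with a known bleed-through (0.3) into the nuclear
channel, which the counter regresses out (least squares over
membrane-dominated voxels).

**Photoactivation pairs.** Cells are soma spheres plus arbor tubes; `post`
adds full brightness inside the activated region of each intersecting arbor
and an attenuated gain — `min(1, intersecting_fraction / dilution_threshold)`
— over the remaining cytoplasm, emulating label dilution in large cells.
The dilution threshold (default 0.05) is a free parameter of the phantom,
not a measured quantity.

## Registration

The cascade is translation → affine → deformable, each stage seeded by the
last, scored by `w·MI + (1−w)·NCC` with w = 0.5; MI uses a 32-bin joint
histogram normalized by the smaller marginal entropy so both terms live in
[0, 1].  Tile placement is exhaustive FFT normalized cross-correlation with
quadratic subvoxel refinement (skipped at an exact-match peak).  The affine
stage optimizes 12 parameters (translation, rotation, log-scale, shear) by
Powell over a 3-level pyramid (factors 4/2/1, Gaussian antialiasing before
decimation), evaluating the metric on a deterministic strided sample of
≤30 000 fixed-grid points; the result never scores below its initialization.
The deformable stage is a greedy symmetric demons scheme: force
`(F−M∘u)·∇ / (|∇|² + diff²)` with the symmetric gradient, fluid smoothing
σ=1, field smoothing σ=1.5, and an explicit positive-Jacobian guard that
halves the update step until `min det J > 0.05` (aborting if impossible);
the field is estimated per pyramid level and upsampled.  Specimen gating
keeps the top `ceil(keep_fraction·n)` by blended score with ties broken by
input order.  Before/after pairs use phase correlation with Fourier
upsampling; a pair whose aligned NCC stays below 0.2 is flagged
low-confidence rather than trusted.

Numerical notes: transforms are always pull-back maps in physical µm on
0-based (z, y, x) grids; affine degrees of freedom are 12 and the MI
estimator is a plain joint histogram — both configuration choices, not
claims about the original tooling.

## Segmentation

Nucleus counting subtracts the fitted membrane bleed, thresholds at `t_low`,
keeps 26-connected components whose volume lies inside the sphere-volume
gate, deletes those voxels, re-thresholds the remainder at `t_high` and
gates again; the union is the count (no intensity floor beyond `t_low`).
Default thresholds are Otsu and Otsu + 1.5× the inter-class spread; the
tests drive them explicitly (0.3/0.7) because the original operator-chosen
values are not stated anywhere.  QC rendering assigns seeded random colors
and numbers to counted objects.  Photoactivated-cell detection thresholds
the post image at mean − 2 SD over the known-positive ROIs and calls a
candidate activated when more than `majority_fraction` (default 0.5,
"most") of its voxels exceed the threshold; the rule is exactly invariant
to adding a constant to both images.  Dopaminergic classification is a
median marker-intensity threshold over the soma.  The terminal/dendrite
split compares local means (radius-3 cube) of the presynaptic and membrane
channels and labels voxels with ratio ≥ 5 as terminal; terminal and
dendrite masks are complementary within the membrane mask by construction.

## Quantification

Compartment masks: per-compartment mean intensity → 3D Gaussian blur
(σ=2 voxels) → argmax over compartments restricted to the lobe mask, ties
broken by canonical compartment order — a deterministic, automated stand-in
for manual border tracing, so the output always partitions the lobes.
Border gaps are flagged when the mean coverage in a border's 2-voxel shell
falls below 50 % of the two compartments' interior mean; the 50 % level is
an artifact choice (the source observation is only that gaps exist at four
borders).  Projection fractions normalize each cell-type volume to unit
total signal before group summation and divide per-neuropil totals by the
total over all cataloged neuropils, so rows sum to 1 and reporter gain
cancels.  Density grids average 10×10×10-voxel cubes (trailing partial
cubes over their actual voxels), scale each group column to 0–255 by its own
maximum, and sort rows by cross-group sum (ties by cube index).  The overlap
score is directional coverage — the fraction of A's voxels within a
tolerance radius (default 1 voxel) of B — symmetrized by averaging both
directions; the exact formula of the originally cited overlap measure is not
restated in the source, so this documented stand-in keeps the tolerance
exposed in configuration.  Matrices average scores over all image pairs with
hemispheres as independent samples and record pair counts.  Ward clustering
runs on `1 − score/max(score)` and cuts at k = 3.

## Pipeline and reproducibility

One YAML config (schema-versioned, unknown keys rejected) drives the
end-to-end run; every stage derives its seed from the root seed through
named substreams, and the resolved config is archived next to the outputs,
making every numeric table reproducible byte-for-byte.  The pipeline's
default grid (96×96×64 voxels in x, y, z at 0.76 µm) and its specimen count
are desk-scale choices; the phantom generators accept larger grids
unchanged.

## What the phantoms do and do not show

The generators reproduce the *structure* the procedures rely on —
compartment tiling, presynaptic enrichment, nucleus size statistics and
touching, specimen deformation within a diffeomorphic family, Poisson–
Gaussian noise — but not real microscopy: there is no PSF anisotropy beyond
Gaussian smoothing, no depth-dependent attenuation or bleaching, no
segmentation ambiguity from neighboring off-target neurons, and arbor
geometry is schematic (compartment fills plus tubes rather than true
dendritic trees; KC layers are not geometrically resolved inside
compartments, so subdivision-level recovery is not tested).  Passing tests
therefore demonstrate that the implementations satisfy their stated
contracts under controlled conditions, not that the pipeline would match
expert performance on real confocal data.  The real imaging results are not
reproducible here in any case — no raw volumes are publicly deposited — so
the atlas arithmetic rests on the packaged fixture and the imaging claims on
phantom recovery.
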