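# Methods

This note documents the models implemented in `sdscam`, the parameter
choices that matter, and what the synthetic benchmarks do and do not
demonstrate.

## Aggregation percentage

A micrograph is reduced to a single intensity image by the per-pixel
maximum of the red and green channels (a pixel lit by either fluorophore is
a cell pixel), then binarized. Two thresholding rules are exposed: Otsu's
method on the merged image (default) and a fixed threshold in [0, 1];
published descriptions of this assay rarely state the rule, so both are
first-class. A constant image makes Otsu undefined; we fall back to 0.5
with a warning rather than fail.

Foreground pixels are grouped into connected objects (8-connectivity by
default, matching the common default of image-analysis environments;
4-connectivity is available). Objects of **300 px or fewer** — about three
cells at the reference magnification — are classified as "no aggregation";
the aggregation percentage is the pixel sum of objects **larger than
300 px** divided by the pixel sum of all objects. The boundary is strict
and tested at 300 vs 301 px. The 300-px rule is calibrated to a
2160 × 2560 frame; for other resolutions `rescaled_min_pixels` scales the
threshold by pixel-area ratio, but only under an explicit flag — never
silently.

## CoAg index

The image is partitioned (a true tiling, not a sliding window) into squares
of side ⌈2.4 × cell radius⌉ — "slightly larger than a single cell", with a
20% margin over the cell diameter since no exact size is standard. A color
is present in a square when at least max(1, 5% of the square's area) pixels
of that channel exceed the channel threshold (0.5 by default); the 5% floor
makes presence calls robust to single-pixel bleed between neighboring
squares. Squares with no color are "black" and removed; the CoAg index is
mixed / (single + mixed). When every square is black the index is
*undefined* (reported as `None`), deliberately distinct from 0.

Classification follows the conventional bands verbatim: index < 0.1 ⇒
segregated, ≥ 0.2 ⇒ intermixed, the half-open interval [0.1, 0.2) ⇒
indeterminate. The index is invariant to swapping the two channels, and on
fields with ≥ 200 cells its standard deviation over random grid origins is
below 0.05 (tested).

## Repertoire overlap

Two neurons each draw k isoforms uniformly without replacement from a pool
of N. The shared count m is hypergeometric,
P(m) = C(k, m)·C(N−k, k−m)/C(N, k), with mean k²/N, and

    P(overlap) = 1 − C(N−k, k)/C(N, k)

evaluated through log-gamma arithmetic (direct factorials overflow at
N = 20,000). At the canonical N = 20,000, k = 50 this gives 0.117777
(≈ 12%). The Monte-Carlo estimator draws seeded repertoire pairs with
numpy's without-replacement sampler and reports the binomial standard
error; analytic and simulated values agree within 3 SE across the tested
(N, k) grid, and exactly match brute-force enumeration for all N ≤ 8.

## Zipper chain-termination model

The structural picture: cis-dimers (FNIII-mediated, same membrane)
alternate with trans Ig1:Ig1 links (apposed membranes) to form a linear
zipper; an incoming cis-dimer joins only if it carries an isoform matching
the one exposed at the growing end; recognition (a switch-like repulsion
response) fires when the chain reaches a threshold of L* links.

The verbal model is made quantitative with the *availability* reading:

- each extension exposes an arm isoform drawn uniformly from the extending
  cell's k isoforms,
- it succeeds iff the apposed cell's repertoire contains that isoform
  (copy numbers unlimited — no expression-level data exist, so there is no
  depletion; `max_links` caps supply instead),
- steps are i.i.d., so the per-step success probability is
  q = |A ∩ B| / k and the chain reaches L* with probability q^L*; the
  expected terminated length is q/(1 − q).

Alternation of the extending side is recorded but, under i.i.d. gating with
equal k, does not change the law; it is kept as a hook for asymmetric
extensions of the model. Runs are independent nucleations — whether a real
chain could re-nucleate after a mismatch is unknown, and re-nucleation
would simply multiply the number of runs. Isoforms that cannot form trans
links at all (as reported for many sDscamβ isoforms) can be modeled with an
`inert_fraction` that multiplies q by (1 − f); this is an exploratory knob,
not a mechanistic claim.

The tolerance curve combines both layers: conditional on sharing m,
recognition probability is (m/k)^L*; marginally over the hypergeometric m,
the false-recognition probability between two random neurons is
Σ_m P(m)·(m/k)^L*. For k = 50 and L* = 10 this is more than 100× below the
raw overlap probability — the model's quantitative statement of
common-isoform tolerance. L* has no measured value; it is a free parameter
throughout.

## Structure metrics

**Superposition.** Kabsch's closed-form least-squares rigid alignment via
SVD of the cross-covariance, with the reflection branch excluded
(det R = +1 enforced). Atoms are paired by chain id + residue number + atom
name when the models share chain naming, or residue number + atom name for
single chains; Cα-only by default. Rank-deficient (collinear) point sets
are flagged. `asu_rmsd_summary` reports the full pairwise matrix plus the
three conventions a single printed RMSD could mean — mean pairwise, max
pairwise, and mean onto a reference copy — because published numbers
rarely say which was used. Tests pin the implementation to a ground-truth
transform generator, to a derivative-free rotation-search oracle
(agreement ≤ 10⁻³ Å), and to an independent library implementation.

**SASA.** Shrake–Rupley with a deterministic golden-section-spiral point
set (960 points per atom by default; results move < 2% versus 4000 points),
probe radius 1.4 Å, and a fixed shipped vdW table (C 1.70, N 1.55, O 1.52,
S 1.80, H 1.10, P 1.80, Se 1.90 Å; unknown elements fall back to 1.80 Å
with a warning). Waters, glycans, other heteroatoms, and hydrogens are
excluded by default — whether published buried-area figures include
glycans is usually unstated, and the glycan-free value is the most
reproducible. Accuracy is checked against the exact spherical-cap area of
two overlapping spheres (< 1%).

**Buried surface area.** ΔSASA = SASA(A) + SASA(B) − SASA(A∪B). The
two-protomer total and the per-side half (PISA-style) are always
co-reported, since either convention appears in print. Passing the same
coordinates twice is an error, not a zero.

**Interfaces.** Residue pairs with any heavy-atom distance ≤ 4.5 Å (the
common interface convention, exposed as a flag), sorted by minimum
distance; salt bridges are annotated when an Arg/Lys/His side-chain
nitrogen sits within 4.0 Å of an Asp/Glu carboxylate oxygen.

**Sequences.** Sequon scanning finds N-X-S/T with X ≠ P (the proline
exclusion can be disabled); logo-style conservation is IC = log₂20 − H per
column over non-gap residues, with columns above 50% gaps flagged and
all-gap columns undefined; per-column inner/outer-facing annotations
support contrasting buried versus interface-forming conservation. Pairwise
identity counts positions with at most one gap member in the denominator
and non-gap matches in the numerator.

**Intermembrane geometry.** The zipper unit cell is parameterized by the
Ig1-3 arm length L_arm (centroid of the first to the last Ig domain along
the principal axis), the antiparallel Ig1:Ig1 overlap o, and the FNIII
cis-dimer height h normal to the membrane; the intermembrane distance is
d = 2h + (2·L_arm − o)·sin θ. Solving for θ at a given d is exact
(round-trip to 10⁻⁹) and infeasible distances raise an error reporting the
attainable [2h, 2h + span] range. With arm dimensions typical of a
three-Ig/three-FNIII ectodomain (L_arm ≈ 14 nm, o ≈ 3 nm, h ≈ 2 nm), a
24 nm spacing — the adhesion-interface distance measured for Drosophila
Dscam1 by electron microscopy — implies an arm tilt of ≈ 53°.

## Synthetic data

`generate_cell_field` emulates the two-color Sf9 aggregation assay at its
reference frame of 2160 × 2560 px. Cells are anti-aliased disks of uniform
intensity 1.0 on a 0 background, giving binarization-independent ground
truth; centers, cluster centers, mode, and seed are stored in provenance so
downstream results can be verified by construction. Defaults:

- **cell radius 5.6 px**, so three cell disks cover ≈ 300 px, preserving
  the "300 px ≈ 3 cells" meaning of the aggregation threshold (the only
  calibration anchor available);
- **cluster radius 80 px** for ~100 cells per cluster (~50% area fill),
  emulating the dense, contiguous aggregates that shaken adhesion assays
  produce;
- segregate-mode cluster centers at least 4.5 cluster radii apart, so no
  analysis square can straddle two monochrome clusters;
- rejection sampling with a cap of 10⁴ attempts per placement, raising a
  placement error naming the limiting parameter rather than looping
  forever.

What the generator does **not** emulate: point-spread blur, shot noise
(an optional Gaussian-noise flag exists), uneven illumination, cell shape
variation, or touching-cell occlusion between colors. Passing the CoAg and
aggregation benchmarks on these images therefore shows the *procedures*
are correct and well-calibrated on clean fields, not that they are robust
to every imaging artifact of real micrographs.

`generate_repertoire_pair` draws both repertoires and their exact shared
block from a single uniform without-replacement sample, which by
exchangeability makes every admissible pair equally likely given the
shared count. `generate_toy_dimer` builds CA-only helix/strand/coil traces
whose second chain is a known rigid transform plus optional isotropic
noise, with the ground truth stored for superposition tests.

## Problem sizes and determinism

Every stochastic routine takes an explicit seed and is bit-reproducible.
The test suite runs the image benchmarks at 20 seeds per mode on the full
2160 × 2560 frame, the zipper grid at 10⁵ runs per (q, L*) cell, and
Monte-Carlo overlap checks at 2 × 10⁴–10⁵ pairs; statistical assertions
use 3-standard-error bands against analytic oracles.

## Known limitations

- The zipper model is one explicit quantitative reading of a qualitative
  mechanism; other readings (cooperative gating, depletion of rare
  isoforms, re-nucleation, 2-D lattice growth) would change the q^L* law.
- The CoAg square side and presence rule are conventions; results are
  stable under grid translation but the absolute index does depend on the
  square side relative to cell size.
- BSA values depend on the vdW table, probe, and glycan handling; the
  shipped defaults are fixed for reproducibility, not canonical.
- The geometry solver treats arms as rigid straight segments meeting the
  membrane plane at a single angle; linker flexibility is ignored.
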