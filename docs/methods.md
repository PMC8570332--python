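# Methods

## The lattice model

A contractile tail sheath is modeled as an ideal n-start helical lattice.
One strand is generated by the screw operation (twist ω, rise Δz): subunit k
of strand s sits at

    z       = k · Δz
    azimuth = φ0 + s · 360°/n + h · k · ω      (h = +1 right-handed)
    radius  = (D_outer + D_inner) / 4

with the +z axis pointing from baseplate toward head and right-handedness
defined as azimuth increasing with +z. All strands share layer planes, so the
lattice is C_n-symmetric about the axis and invariant under the screw
operation — the two facts the symmetry search exploits.

Only diameters are reported for the sheath, not the subunit center-of-mass
radius; placing centers at the mid-radius (the mean of inner and outer
radius) is a modeling choice. Subunit counts use floor division
(⌊4500 / 41.53⌋ = 108 whole subunits per strand), matching the published
counts of 108 per strand and ~648 total.

Two pitch conventions are provided. The continuous pitch Δz·360/ω is the
standard axial distance for one full turn. Published sheath pitches, however,
correspond to Δz·⌊360/ω⌋ — the rise times the number of *completed* subunits
per turn (17 × 41.53 = 706.01 Å; 13 × 18.89 = 245.57 Å). `pitch_integer_turn`
implements that convention (flagged as such in CLI output);
`pitch_continuous` gives the textbook value. Note that 360/20.57 = 17.5012,
so a nearest-integer rule would give 18 turns and a pitch of 747.5 Å; only
the floor rule reproduces the printed values, which is why the convention is
stated as "completed turns".

## Synthetic maps and projections

The generator emulates the processed scale of the source data: 3.484 Å/pixel
sampling in a 224-voxel box by default (small symmetry-search boxes enlarge
the voxel just enough that the scoring mask fits). Subunits are isotropic
Gaussian pseudo-atoms of σ = 8 Å, giving map features at roughly the 7–8 Å
resolution of the experimental reconstructions. The tail tube is a z-uniform
annulus whose radial edges are softened by an error-function profile of one
voxel width — hard voxelized edges are not band-limited and would both be
unphysical at this resolution and alias under the Fourier resampling used by
the symmetry search. For symmetry-search maps the lattice is extended past
the box in z so the in-box density is exactly helical.

The outer coil — a feature so far unique to phage G — is rendered as a blob
helix with fixed 210 Å axial pitch and state-dependent diameter (390 Å
non-contracted, 490 Å contracted). Strand count and handedness of the coil
are not experimentally established; the default is one right-handed strand,
recorded in the CoilSpec. Coil pitch is measured from a side-view projection
as the median axial spacing of density peaks along the two outermost
significant image columns (the helix crosses each lateral flank once per
period), times the pixel size.

Noise is additive white Gaussian with an explicit seed; when a target
signal-to-noise ratio is requested, the noise variance is set to the signal
variance inside the cylindrical analysis mask (radius 1.1 × sheath outer
radius). No CTF, dose weighting, motion blur or particle-picking artifacts
are simulated: passing recovery tests demonstrates the estimator's behavior
under idealized imaging statistics, not robustness to the full cryo-EM
pipeline.

Volumes are written as MRC2014 mode-2 maps through gemmi; the voxel size is
carried in the unit-cell header and write-then-read round-trips the float32
grid exactly.

## Symmetry determination

Candidate (twist, rise) pairs are scored by self-consistency. The map is
first averaged over its C_n rotations (parameter independent, done once).
Each non-identity screw copy k·(ω, Δz), k = −⌊n_copies/2⌋ … ⌊n_copies/2⌋, is
then resampled and Pearson-correlated with the raw map inside a cylindrical
mask; the score is the mean of those per-copy correlations. The default of
five copies mirrors the five-subunit segment spacing used when the
experimental segments were extracted.

Two numerical choices matter and were made deliberately:

* **Per-copy correlation, not correlation against the symmetrized average.**
  Correlating the raw map with the *average* of its screw copies is nearly
  flat in (twist, rise): as copies misalign, the average loses variance at
  the same rate its covariance with the raw map falls, and Pearson
  normalization cancels the two. Scoring each copy separately keeps the
  misalignment signal (a single copy's correlation falls from ~0.999 to
  ~0.995 per Å of rise error on a clean synthetic map).
* **Band-limited resampling.** In-plane rotations use the three-pass FFT
  shear decomposition (each shear a sinc-exact row translation, right-angle
  parts factored out exactly) and axial translations use sinc shifts along z.
  Interpolated (trilinear/cubic) z-shifts smooth fractional-voxel shifts more
  than whole-voxel ones, which biases the score toward rises near integer
  voxel multiples; sinc shifts remove that bias. The FFTs treat the box as
  periodic, so scoring excludes the z rows any copy can wrap into.

The mask is a cylinder of radius 1.1 × sheath outer radius (excluding box
corners); the z range is trimmed by ⌊n_copies/2⌋ × the largest rise under
consideration, fixed across a grid search so every candidate is scored on the
same voxels. Grid search is exhaustive with a deterministic tie-break (lowest
rise, then lowest twist); refinement is Nelder–Mead on the negative score
with a parameter tolerance (default 0.05 °/Å) and is contracted never to
return a score below its starting point. Scoring many rises at one twist
reuses the rotated copies through a small FFT cache, so a 16 × 11 grid plus
refinement on a 64³ map runs in a few seconds.

`symmetrize` (the plain symmetry-averaging operation, including the identity
copy and C_n rotations) is provided for map averaging; on an exactly
symmetric synthetic map at the true parameters it changes the masked volume
by a normalized RMS of ~0.001.

On synthetic maps of both phage G states at signal-to-noise 1 (64³ box), grid
search plus refinement recovers the generating parameters to better than
0.1 ° / 0.1 Å across seeds. The tests cross-check the fast scorer against an
independent whole-volume implementation (scipy cubic rotation + sinc shift):
grid argmaxes must agree exactly, scores to ~0.02.

## Census classification

An axial profile (apparent outer diameter vs position, z = 0 at the head)
is thresholded at the midpoint of the expected thick (contracted sheath,
320 Å) and thin (bare tube, 60 Å) diameters. The longest contiguous
above-threshold run is the sheath span. A span covering ≥ 90% of the tail is
"non-contracted" (uniform thickness); the published states are well
separated by any cutoff between ~50% and ~95%, since a contracted sheath
occupies ~45% of the tail, and 90% leaves margin for edge effects. Contracted
calls are localized by the tercile of the tail containing the span centroid
(near-head / middle / near-tip) — the source classification was visual and
defines no quantitative boundary, so terciles are this package's
operationalization and are configurable. Multiple disjoint thick runs are
flagged ambiguous and the longest is used. Head DNA state (full / partial /
empty) is an input label; image-based head classification is out of scope.

The profile simulator draws (head state, tail state) from the empirical joint
distribution of the packaged 364-particle census, builds ideal step profiles
with the phage G lengths (4500 Å tail, 2040 Å sheath, 240 Å uniform
non-contracted diameter) and adds seeded Gaussian diameter jitter (default
10 Å). At that jitter the classifier is effectively error-free, so end-to-end
recovery tests reduce to multinomial sampling error — which is the point:
they validate the bookkeeping, not robustness to segmentation noise in real
micrographs.

## Atlas analysis

The atlas CSV mirrors the published comparison table (17 tail structures; the
phage G contracted twist appears there as 27.18°, a printed variant of the
27.13° refined value — the fixture keeps 27.18 as printed and a
`canonical_phage_g` flag substitutes 27.13 for cross-module consistency).
Non-contractile siphophage tails without an explicit structure label are
stored as "tail".

`by_state` groups records by structure label into contracted sheaths vs
everything non-contracted-like (non-contracted sheaths, tubes, tails) and
reports min–max twist/rise ranges after removing records farther than a
threshold (default 10, Euclidean in degrees/Å treated equally — about half
the separation between the two sheath-state clusters) from their group
median. This reports SPP1 — whose tube parameters (38.5°, 21.9 Å) sit far
from every non-contracted tail — as an outlier, along with TP901-1, T5 and
p2. `kmeans2` clusters standardized (twist, rise) with a seeded k-means and
flags records whose cluster side disagrees with their structure label or
that lie beyond 2 standardized units from their centroid; SPP1 and TP901-1
land on the contracted side despite being tubes/tails and are flagged.
Araucaria (26°, 38 Å) sits between the clusters and is *not* flagged by
either rule — a known limitation of these simple criteria relative to a
visual reading of the parameter scatter.

Contraction ratios divide published contracted by extended sheath lengths
(T4 420/925 = 0.454, phi812 808/2020 = 0.400, phage G 2040/4500 = 0.453) and
report whether all fall inside a band (default 0.35–0.50) — the observation
being that phages spanning a five-fold length range contract by a similar
factor.

## Problem sizes and determinism

Symmetry-search tests use 64³ boxes (voxel size 4.875 Å non-contracted,
6.5 Å contracted — the smallest sampling that keeps the 1.1 × outer-radius
mask inside the box), five seeds per state at signal-to-noise 1, and a
1 °/1 Å coarse grid before refinement; coil measurements use the full
224-voxel box at 3.484 Å/pixel. All stochastic operations take explicit
seeds and are reproducible array-for-array.

## Known limitations

* The noise model is white and additive; no CTF or alignment error, so
  recovery results bound idealized performance only.
* The symmetry objective assumes the helical axis is the box z-axis through
  the center; no axis search or out-of-plane tilt refinement is performed.
* The integer-turn pitch convention is reverse-engineered from the printed
  values; whether those pitches were instead derived from an unreported
  lattice indexing cannot be determined from the published numbers.
* Atlas outlier rules are simple distance criteria and do not reproduce
  every judgment a human would make from the scatter (see Araucaria above).
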