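# Methods

## The detection problem

Glomeruli — the kidney's filtration units — appear in bright-field
microscopy of desmin-immunostained sections as roughly circular,
densely textured objects of widely varying diameter and staining
intensity, sometimes ringed by a darker Bowman's capsule, surrounded by
stained distractors such as blood vessels.  `seghog` detects them in
three stages, each built on a linear SVM over a HOG-family descriptor:

1. **Pre-screening.**  A 200×200 px window slides over the image at a
   configurable stride (default 20 px).  Each placement is scored with a
   linear SVM on the R-HOG descriptor (8×8 grid of 25×25 px cells, 8
   unsigned orientation bins, 512 dimensions; per-cell L2
   normalization).  Windows above the pre-screening threshold are thinned
   by greedy non-maximal suppression (descending score, suppression
   radius default 60 px); surviving window centers become candidates.
2. **Segmentation.**  From each candidate center, m = 36 rays are cast
   at uniform angles; each ray carries n = 22 samples from 17 px to
   80 px from the center (3 px apart), 792 locations in all.  A 30×15 px
   window aligned with the ray is resampled bilinearly at each sample,
   orientations re-expressed relative to the ray direction, and split
   into three 10×15 radial blocks of 9 bins (27 dimensions).  A second
   linear SVM scores this descriptor; the score is the *boundary
   likeliness* L_i(p) of sample p on ray i.  The boundary polygon is
   the exact maximizer of Σᵢ L_i(p_i) subject to the cyclic smoothness
   constraints |p_i − p_{i+1}| ≤ ς (default ς = 1), solved by DCDP
   (below).
3. **Classification.**  The Segmental HOG (S-HOG) descriptor is built
   on the estimated boundary: three radial zones (inner [0, 0.7·r_b),
   middle [0.7, 1.1), outer [1.1, 1.4] of the interpolated per-direction
   boundary radius r_b) intersected with eight 45° sectors give 24
   disjoint blocks of 9 bins (216 dimensions).  A third linear SVM
   accepts the candidate iff its score strictly exceeds the
   classification threshold.

All three SVMs use L2-regularized hinge loss with C = 10.

## Exact boundary inference (DCDP)

Dropping the wrap constraint |p_m − p_1| ≤ ς makes the problem a chain,
solvable by a Viterbi-style dynamic program in O(nmς).  DCDP restores
the wrap constraint by branch and bound over contiguous intervals I of
the admissible endpoint values p_m: solve the relaxed chain problem over
S_L(I) (endpoint in I, start point in the ς-dilation of I); prune the
branch if the relaxed optimum is below the incumbent bound (Rule A);
accept the relaxed optimizer if it already satisfies the wrap constraint
(Rule B); otherwise split I in two and recurse, threading the first
branch's bound into the second (Rule C).  The chain DP runs at most
2n − 1 times, and the returned solution is a certified global optimum.

Three splitting schemes are provided.  *Half* cuts the interval in the
middle; *Max* cuts just after the argmax of the last ray's likeliness;
*Adap* cuts at the mean of the first and last entries of the current
relaxed optimizer — the two entries whose disagreement is exactly what
violates the wrap constraint, which is why Adap branches least.  All
schemes order the two sub-intervals heuristically (Half: the side with
the larger last-ray likeliness first; Max/Adap: the smaller side first)
so that a strong incumbent bound is available early.  Ties in the DP
backtrack break toward the smallest index, making every solver
deterministic.

Two baselines serve as independent cross-checks: EDP solves one chain
sub-problem per endpoint value h (p_m = h fixed, p_1 within ς of h), so
its DP-call count is always n; a vectorized brute-force enumerator
(guarded to n^m ≤ 10⁷) is the oracle in the tests.

## MPLP baseline

The same problem read as MAP inference on a cycle MRF is handled by
MPLP block coordinate descent on the LP-relaxation dual Ψ(λ).  Each
block step re-optimizes the two message vectors of one edge given the
neighbouring edges' messages, so Ψ is non-increasing and, by weak
duality, always an upper bound on the optimum.  MPLP sweeps edges
sequentially; MPLP+ updates all odd-numbered edges simultaneously and
then all even-numbered edges (for even m these blocks share no dual
term, so the simultaneous step is still an exact block minimization; an
odd m puts the closing edge into the odd group).  Decoding takes the
per-node argmax of L_i + incoming messages (smallest index on ties);
the run stops when the decoded polygon is cyclically feasible and the
duality gap is ≤ 10⁻⁹ (defaults; both configurable), or after
`max_iters` passes, returning the best feasible decode found with a
convergence flag.  Convergence to the exact optimum is not guaranteed —
the LP relaxation of a cycle can be loose — which is precisely why the
exact DCDP solver exists; in practice random integer tables at the
operating scale almost always converge, at an iteration cost one to two
orders of magnitude above DCDP's DP-call count.

## Training and calibration

Training data come from annotated images (at desk scale: synthetic
scenes with exact truth).  Pre-screening: positives are windows centered
on each annotated glomerulus with diameter ≥ 50 px; negatives are
windows at seeded random locations whose centers are > 100 px from every
annotation, three negatives per positive (the negative pool should
sample the background broadly — including vessels — which a 1:1 ratio
under-represents).  Segmentation: on each ray from an annotated center,
the sample nearest the true boundary crossing is the positive and
samples ≥ 2 steps (6 px) away are negatives; rays whose crossing lies
outside the 17–80 px sampled span are skipped.  Classification: the same
positive and negative window centers as pre-screening, but each window
is first segmented with the trained boundary SVM and the S-HOG
descriptor is extracted on the *estimated* boundary — negatives too,
even though they contain no object.

SVM scores live in arbitrary margin units, so the two decision
thresholds are calibrated on a held-out validation image set (train,
validation and evaluation sets are disjoint).  Both stages are tuned
recall-first, because only later stages can remove false positives
while a dropped true positive is unrecoverable: the pre-screening
threshold sits 0.05 below the weakest best-window score over all
validation glomeruli, and the classification threshold sits 0.25 below
the weakest validation true-candidate score (the highest threshold that
keeps every validation true positive).  The config defaults carry the
conventional operating point for this detector (θ = 2 for
pre-screening, θ = −1.5 for classification), which presumes score
scales from large, non-separable training corpora; on cleanly separable synthetic data a max-margin SVM
scores positives near +1, so running with the defaults and no
calibration leaves the pre-screening stage silent.  On our synthetic
suites the calibrated classification threshold lands near −1.4,
incidentally close to the conventional default.

## The synthetic scene generator

`generate_scene` emulates desmin-stained kidney sections in grayscale,
on a bright (0.85) background with smooth low-frequency undulation
(σ = 15 px, sd 0.04):

* **Glomeruli** (default 4 per 600×600 scene) with boundary
  r(θ) = r₀(1 + Σ_{k≤4} a_k cos(kθ + φ_k)), r₀ ~ U(30, 90) px and
  |a_k| ≤ 0.05 — mostly circular, deformed to some extent, with exactly
  one boundary crossing per ray.  Interiors are darkened (0.10 + 0.15 ×
  stain) and speckled with cell-scale texture (σ = 1.2 px, sd 0.12 ×
  stain), so the interior gradient magnitude is well above background —
  the property the descriptors exploit.  Staining levels are
  heterogeneous (stain ~ U(0.35, 1)); 70% of objects get a darker
  capsule ring (4 px thick) along the boundary.
* **Vessels** (default 5) as smooth random-walk ribbons 10–24 px wide,
  darkened and speckled like stained tissue; they are the distractors
  that produce pre-screening false positives.
* Pixel noise sd 0.02; centers ≥ 110 px from borders (a 200×200 window
  always fits) and non-overlapping.

The generator is a pure function of its parameters, seed included.
What it does **not** emulate: color (DAB brown is rendered as gray
levels), tubular background tissue, staining artifacts and tears,
out-of-focus blur, and the 10⁸-px scale of whole-slide images.  Passing
tests therefore demonstrate the correctness and internal consistency of
the machinery — exact inference, descriptor structure, stage filtering
behaviour — not performance on real slides.  Note that the radius range
extends to 90 px while the rays sample 17–80 px, so the largest objects
are detectable but not perfectly segmentable, which is the main source
of residual classification-score spread on synthetic data.

## Numerical choices

* Gradients: central differences (one-sided at borders) on luminance
  (RGB weights 0.299/0.587/0.114); orientations unsigned in [0, π),
  9 bins (8 for R-HOG), hard assignment, per-block L2 normalization
  with an ε = 10⁻¹² zero guard.
* Orientation binning adds 10⁻⁷ of a bin before flooring and wraps
  mod n_bins: a gradient that is analytically radial sits exactly on
  the 0/π wrap, and without the tolerance float rounding scatters such
  samples between the first and last bin arbitrarily per ray.
* Ray-window resampling interpolates the gx/gy fields bilinearly
  (out-of-image samples contribute zero magnitude); for a field with
  linear gx/gy the resampling is exact, which the rotational-invariance
  tests exploit.
* Solver objectives are compared exactly; test fixtures use integer
  likeliness tables so cross-solver equality has no float-tie
  ambiguity.
* Rasterization uses the even-odd rule; a pixel belongs to a polygon
  iff its center is inside.

## Problem sizes used in the shipped runs

The test-suite and the reproduction script run at desk scale: 16
training, 8 validation and 20 evaluation scenes of 600×600 px with 4
glomeruli each; 150–200 random solver instances at the operating scale
(36×22), 100 planted-recovery instances, 25 MPLP comparisons.  These
sizes were chosen so the whole stack (training included) reruns in a
few minutes on one CPU while every stage still sees several dozen
objects.

## Known limitations

* The fixed ray span (17–80 px) cannot represent boundaries of objects
  with radius outside it; multi-resolution windows are out of scope.
* Greedy center-in-polygon matching is one of several defensible
  detection-scoring rules; a center-distance criterion is provided as an
  alternative.
* MPLP convergence (and hence its reported iteration counts) depends on
  tie structure in the likeliness table; iteration counts are
  comparable across solvers only qualitatively.
* The classifier is only as good as the synthetic distractors are hard;
  real-slide performance claims are explicitly not made.
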