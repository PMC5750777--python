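# Methods

This note records the models and procedures qfuzzy implements, the
conventions chosen where the method description leaves room, and what the
synthetic benchmarks do and do not establish.

## Feature extraction

Input is a `SegmentedCell`: an 8-bit grayscale raster (RGB input is
collapsed with ITU-R 601 luma weights 0.299/0.587/0.114) and a same-shape
label mask with 0 = background, 1 = cytoplasm, 2 = nucleus. Both the
nucleus and cytoplasm must be non-empty; a loader maps colour-coded
ground-truth masks onto this encoding through a user-supplied colour table.

The 54-entry vector is 16 scalars plus 38 LBP-HF entries. Conventions:

* **Ellipse axes** (`L_n`, `D_n`): the moments-equivalent ellipse (same
  second central moments as the region, the regionprops convention). A
  literal minimal enclosing ellipse is ill-conditioned on rasters; the
  moments ellipse is reproducible and rotation-consistent. For a filled
  ellipse with semi-axes 20/10 px it recovers axis lengths 40/20 within 3%.
* **Perimeter** (`P_n`, and `P_cell` inside compactness): the weighted
  chain-code estimator (`skimage.measure.perimeter`). A raw boundary-pixel
  count converges to (8/√2)·r on rasterised disks, biasing compactness
  P²/A to 32/π ≈ 10.2 (−19% from the continuum 4π); the chain-code
  estimator stays within a few percent of 2πr, and the disk-compactness
  check is asserted at ±15%.
* **Aspect ratio** `R_n`: width/height of the nucleus's axis-aligned
  bounding box.
* **Local extrema** (`Max_n`, `Min_n`, `Max_c`, `Min_c`): a pixel counts
  when strictly greater/less than every *available* 8-neighbour; neighbours
  outside the image or outside the region are ignored, plateaus never
  count, and a pixel with no available neighbour never counts.
* **GLCM homogeneity** `H_n`: 8 gray levels (uniform quantisation of
  0–255), single offset (0, 1), symmetric counts, pairs with either pixel
  outside the nucleus excluded, normalised before Σ p(i,j)/(1+|i−j|).
  Levels and offset are configurable; these defaults give H = 1 exactly on
  constant regions and 0.5 on a two-level checkerboard.
* **LBP-HF** (38 entries): LBP with the 8 integer-grid neighbours at
  radius 1 (no interpolation), bit = 1 when neighbour ≥ centre, computed at
  every whole-cell pixel whose 3×3 patch is inside the image. The
  uniform-pattern histogram is normalised; each of the 7 rotation orbits
  (1–7 set bits, 8 rotations) is DFT'd along its rotation index and the 5
  unique magnitudes kept; all-zeros, all-ones and non-uniform bins are
  appended: 7·5 + 3 = 38. P = 8 is the only neighbour count that produces
  38 entries; the radius-1 integer grid additionally makes invariance to
  90° image rotations exact, which the property tests assert at 1e−6.
  Radius/neighbour layout are configurable only by swapping the LBP code
  map, by design: the 38-entry schema is fixed.

Feature extraction is deterministic and exactly translation-invariant
(pad-and-shift equality is part of the test suite).

## Fuzzy k-NN

Features are min–max scaled per column with training-fold statistics
(constant columns map to 0; out-of-range test values clip to [0, 1]).
Training memberships are crisp one-hot rows; the aggregation accepts any
row-stochastic matrix, so fuzzified initialisations can be plugged in
later without touching the predictor. Distances are Euclidean. The k
nearest rows (ties broken by lower training index; implemented as an
unstable sort with a stable re-sort on the rare rows where a tie straddles
the k-th rank, which is the only case stability can change the selected
set) contribute weights d^(−2/(m−1)); a zero-distance neighbour takes the
limit of the formula — the query inherits that row's membership, or the
mean over several zero-distance rows. Output memberships are convex
combinations, so rows sum to 1 and are invariant to rescaling all
distances. Defaults k = 4 (the best-performing neighbourhood on the
historical benchmark; useful range 2–7) and m = 2.

## Binary QPSO and PSO

Particles hold real positions initialised U(−1, 1) per dimension, mapped
to bit masks by the sigmoid transfer (bit = 1 when expit(x) > U(0, 1)).
QPSO jumps around the attractor p = φ·pbest + (1−φ)·gbest with step
α·|mbest − x|·ln(1/u); the step sign is an independent fair coin per
dimension (the two printed update branches otherwise coincide, which
would collapse the sampling to one side — the ± form is the standard
QPSO sampler, and the Monte-Carlo test checks E|x′ − p| = α·|mbest − x|
to 2%). The per-particle search scope Q = 2α·|mbest − x| is recorded as a
diagnostic only; it does not enter the update. α anneals linearly
1.0 → 0.5 (common practice; the original description does not state a
value — a constant-α option is retained). Personal bests move only on
strict fitness improvement, global best is the running max of personal
bests, so traces are monotone and a constant-fitness surface freezes the
initial global best. The PSO baseline uses inertia 0.9 → 0.4,
c₁ = c₂ = 2.0, velocity clip ±4.0, and the same sigmoid binarisation.
One seeded generator drives a whole run; identical seeds give identical
traces.

## The wrapper

`CrossValFitness` freezes the stratified folds (per-class round-robin
deal after a seeded shuffle — classes smaller than the fold count are
spread as evenly as possible rather than rejected), fits the fold-wise
min–max normalisation once per fold over all columns (column-wise
scaling is unaffected by which subset a mask later selects), and caches
per-fold squared column differences so a mask evaluation is a single
fixed-order `einsum` contraction plus neighbour ranking. The contraction
deliberately avoids BLAS so results do not depend on thread count or
vendor reduction order. Fitness is the mean over folds of macro-F1
(computed by a vectorised path that the tests pin to the evaluation
module's implementation); the all-zero mask scores 0 by convention, and
evaluations are memoised per mask. Whether to cross-validate inside the
wrapper or hold out a split is left open by the method description;
full-data stratified CV with folds fixed per run seed was chosen so that
fitness is a deterministic function of the mask.

Final reported metrics are computed from fold-pooled predictions
(confusion counts summed over folds), separate from the per-fold-averaged
fitness estimate.

## Evaluation

Multi-class precision/recall are one-vs-rest; a degenerate denominator
yields 0 (logged semantics, never NaN); overall figures are unweighted
macro means (the published tables do not state their averaging; macro
keeps the seven classes on an equal footing despite the 70–197 per-class
counts). Cohen's kappa uses product-of-marginal chance agreement; two
constant, identical raters get κ = 1 by continuity.

The published benchmark tables (k-sweep and per-class) ship in
`qfuzzy.reference` as worked-example inputs. Recombining each printed
precision/recall pair under F1 = 2PR/(P+R) reproduces the printed F1 to
±0.005 for all rows except three (moderate-dysplastic Q-Fuzzy, and the
light- and severe-dysplastic All-Features rows), where the printed
two-decimal rounding of P and R makes the point check impossible; for
those rows the tests assert interval consistency — the printed F1 is
reachable from some (P, R) that round to the printed values.

## Synthetic data

The image generator emulates the qualitative cytology of the seven
classes: ellipse-with-harmonic-perturbation nucleus inside a larger
cytoplasm blob on a bright (≈228) background, Gaussian texture with a
class-specific grain, nucleus radius growing ≈5 → 18 px and nucleus
brightness falling ≈190 → 92 along the normal → carcinoma axis, with the
cytoplasm shrinking so the N/C ratio rises monotonically. Default
per-class counts follow the historical 74/70/98/150/182/146/197
distribution. These parameter values are package defaults chosen to
reproduce the documented qualitative ordering (larger, darker, more
irregular nuclei with grade); they are not claims about any real dataset,
and the images carry none of the staining variability, debris, occlusion
or segmentation error of real smears — passing tests on them demonstrates
the pipeline's correctness and the wrapper's behaviour under its own
assumptions, not clinical performance.

The planted-table generator draws informative columns with
class-conditional means on an effect·{0, 1, …, C−1} grid (randomly
permuted per column) and iid standard-normal noise columns, returning the
ground-truth informative indices.

## Benchmark problem sizes

The optimiser-vs-enumeration check uses 12-bit deterministic surfaces
(exhaustive optimum by 2¹² enumeration) with the default 20 particles ×
200 iterations, 100 seeded repetitions. The recovery benchmark uses the
planted table at n = 300, 5 informative + 25 noise columns, effect size
3 sd, 3 classes, 100 seeded repetitions at 20 particles × 100 iterations —
convergence on this 30-bit problem completes well before 100 iterations,
so the shorter budget is used for the repeated benchmark while 200
remains the package default. With effect size 3, three informative
columns usually already separate the classes, so the cross-validated
fitness saturates at 1.0 and the strict-improvement rule freezes the
global best at the first perfect mask; runs that recover only 3 of 5
planted columns are almost always such ties, a property of the benchmark
conditions rather than of the optimiser.

## Known limitations

* Crisp training memberships only (the fuzzified-initialisation hook
  exists but is not implemented).
* Single-offset GLCM and single-radius LBP; no multi-scale texture.
* The synthetic images are not photorealistic and contain exactly one
  cell; segmentation itself is out of scope — masks are inputs.
* Macro averaging is a choice; micro/weighted averages of the same
  confusion counts are not exposed.
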