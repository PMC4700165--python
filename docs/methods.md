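# Methods

`hrctex` classifies 40×40-pixel patches of lung parenchyma from chest HRCT
into four patterns — normal (NOR), ground glass (GG), honeycombing (HC)
and emphysema (EMP) — or into normal vs pathological. This note records
the model, its parameters and defaults, the numerical conventions, and
what the synthetic phantoms do and do not establish.

## Patch sampling and quantization

Radiologists outline freehand regions (FH-ROIs) on a slice; the pipeline
tiles each region with non-overlapping 40×40 patches and keeps only
patches 100% inside the boundary. The tiling grid is anchored at the
top-left corner of the mask bounding box — the anchoring is a free choice;
a fixed corner makes sampling deterministic and reproducible. Every patch
carries its parent region id so that data splits can keep whole regions
on one side.

Classical texture features operate on patches quantized to L = 32 gray
levels against the **dataset-wide** HU range: level =
⌊(h − min) / (max − min + 1) · L⌋, with out-of-range pixels clamped. The
integer-width divisor (max − min + 1) pins min to level 0 and max to
level L − 1 with uniform bins and lower-bin ties. A consequence worth
knowing: the rule is exactly invariant under a common HU *shift* of data
and range, but not under rescaling (the +1 is not scaled); with CT data
already calibrated in HU this has no practical effect.

## Feature families

* **First order (6):** mean, variance, standardized skewness and kurtosis,
  energy and entropy of the normalized histogram. Entropy is in bits
  (0·log 0 := 0); skewness/kurtosis are 0 for a constant patch.
* **Co-occurrence / SGLDM (4 × 6):** symmetric gray-level pair matrices at
  distance d = 1 along 0°, 45°, 90°, 135° ((row, col) offsets (0,1),
  (−1,1), (−1,0), (−1,−1)); from each matrix: angular second moment,
  entropy, inverse difference moment, correlation, contrast, variance.
  Correlation := 0 when a marginal is degenerate.
* **Run length / GLRLM (4 × 11):** maximal constant-level runs per
  direction; the canonical Galloway/Chu feature set (SRE, LRE, GLN, RLN,
  RP, LGRE, HGRE, SRLGE, SRHGE, LRLGE, LRHGE) with runs normalized by the
  total run count, RP = runs/pixels, and gray levels indexed from 1 in the
  low/high emphasis terms.
* Directional features are **concatenated**, not averaged: averaging
  would discard anisotropy, and the stepwise filter removes redundant
  directions anyway.

## Differential lacunarity

DLac works on the raw Hounsfield scale, clamped to [−1000, +1000]
(2001 integer levels), not on the 32-level quantization: the point of the
measure is to exploit the full CT dynamic range. For box side r:

* levels g = round(h − hu_min); cube index = ⌊g/r⌋ + 1 (cubes of height r
  level units, stacked from the bottom);
* differential column height of an r×r box: n = max(v − u − 1, 0) where
  v, u are the cube indices of the box max and min. The −1 (rather than
  the +1 of classic differential box counting) follows the worked
  construction this implementation reproduces; flat boxes would give −1,
  which is clamped to 0 since a negative height is meaningless;
* box mass of a w×w window: sum of n over all (w − r + 1)² box positions
  (box stride 1); windows glide over the patch with stride 1 as well;
* Λ(w, r) = E[M²]/E[M]² over window positions; Λ := 1 when every mass is
  0 (a perfectly translation-invariant field). Jensen's inequality gives
  Λ ≥ 1 always, with equality iff all masses are equal.

Curves use r = 4 with w = 5..35 and are normalized by Λ(w_min) so patches
share a common reference; the first point is constant 1 and is dropped,
leaving 30 features `dlac.r4.w6` … `dlac.r4.w35`.

The implementation computes the height map once per patch (sliding-window
min/max of cube indices) and aggregates each scale with an integral
image; it is tested for exact (integer-mass) agreement with a brute-force
triple-loop oracle.

## Feature selection

Stepwise multilinear regression with partial-F tests: starting from an
intercept-only model, the excluded feature with the smallest partial-F
p-value is added while p < 0.01 (entrance tolerance); included terms with
p > 0.02 (exit tolerance) are removed. The exit tolerance is not part of
the published protocol; any value above the entrance tolerance prevents
add/remove cycling, and 0.02 is the conventional pairing. Ties prefer the
lowest column index; collinear candidates (residual norm ≈ 0 against the
current model) are skipped. Class labels enter through one-vs-rest 0/1
indicator responses (a single indicator in the binary case) and the final
selection is the union over indicators — the multiclass encoding is a
design choice, since a class label has no numeric scale of its own.
Features enter raw: the F statistic is scale-invariant.

Under a pure-noise response the expected number of admitted features per
scan is ≈ m·p_enter, so the per-feature admission rate calibrates to the
entrance tolerance; the test suite checks this within 3 binomial standard
errors over 200 seeded replicates, and checks that standardized effects
of size ≥ 1 at n = 300 are recovered in ≥ 95% of replicates.

## Classifier and model selection

Soft-margin SVM with RBF kernel K(x, y) = exp(−‖x − y‖²/(2σ²)).
Multiclass uses one-vs-one: n(n−1)/2 pairwise machines, winner-takes-all
voting, vote ties broken by the summed signed decision values toward each
tied class, then by class order. Features are z-scored with statistics
from the training material only — standardization is a design addition:
a single shared σ is only meaningful if feature scales are comparable.

Hyperparameters (C, σ) are chosen on the training side of a group-aware
stratified 2/3–1/3 holdout (whole FH-ROI groups on one side; per-class
patch proportions ≈ the dataset's). Each grid point is scored by
stratified 10-fold CV in which the stepwise selection is re-run on the
nine training folds of every iteration, so the held fold leaks into
neither the selection nor the scaling — asserted in the suite by checking
that permuting held-fold labels leaves the fold-trained machines
bit-identical. Because the selection does not depend on (C, σ), it is
computed once per fold and shared across grid points.

Grids are powers of two: the coarse grid spans C = 2⁻⁵..2¹⁵ and
σ = 2⁻²..2⁷ at exponent step 0.5 (779 points); the default is the reduced
grid C = 2³..2¹³, σ = 2⁻²..2¹ that the wide search identifies as the
relevant region. The best point (ties → smallest C, then smallest σ;
smoother machines preferred) is refined on a ±0.5 exponent neighbourhood
at step 0.25, and the final machine is retrained on the full training
side with features selected on it. Experiments repeat
holdout → search → test evaluation over independent iterations (50 by
default) and report mean ± SD of the contingency-table metrics; all
randomness fans out from one master seed through a seed-sequence spawn.

## Evaluation

From the actual×predicted count table: per-class sensitivity a_ii/row_i,
precision a_ii/col_i, specificity TN_i/(TN_i + FP_i), and overall
accuracy trace/total (equal to the support-weighted mean sensitivity).
Ratios with zero denominators are reported as NaN, not 0, so absent
classes are visibly missing rather than silently penalized.

## Synthetic phantoms

Clinical HRCT with radiologist annotations cannot be redistributed, so
the pipeline is exercised on synthetic 40×40 phantoms: smoothed Gaussian
random fields (class-specific mean, SD, correlation length) with
structural elements stamped on top — sparse bright vessel dots on a dark
background (NOR), a smooth raised-attenuation haze (GG), a jittered
lattice of dark cysts rimmed by bright walls (HC), large near-air blobs
(EMP). All values are clamped to [−1000, 1000] HU. Groups of patches
share one jittered parameter draw (mean shift SD 40 HU, scale factors
0.85–1.15) to mimic patches cut from one freehand region of one patient;
between-region attenuation differences dominate within-region variation,
as they do clinically.

What the phantoms establish: that every stage — sampling, quantization,
both feature families, selection, group-aware model selection,
evaluation — is wired correctly, leaks nothing, and that the feature set
separates textures with the stated gap structure. What they do not
establish: clinical performance. The phantom classes are far better
separated than real ILD patterns (real GG vs NOR confusion is the
documented hard case), contain no anatomy, scanner noise model, or
slice-thickness effects, and near-ceiling phantom accuracy should not be
read as a clinical claim.

## Problem sizes and defaults

The end-to-end test uses 4 classes × 20 groups × 5 patches (400 patches),
the full set-2 feature vector (104 features), the reduced grid, 10-fold
CV and 10 holdout iterations — sizes chosen so the whole suite runs on a
single CPU in a few minutes while still exercising every code path at
realistic dimensionality. The acceptance criterion there is mean overall
accuracy ≥ 0.90.

## Known limitations

* No lung segmentation, 3-D sampling, or annotation tooling: input is a
  slice plus a mask.
* Global (dataset-wide) quantization range follows the protocol; when a
  trained model is applied to new data the stored range is reused and
  out-of-range pixels clamp.
* The stepwise filter inherits the instability of all greedy selection
  under strong collinearity; the per-fold selections are exposed in the
  grid-search result for inspection.
* NaN metrics propagate to the mean/SD aggregation via nan-aware
  reductions; iterations where a class is absent from the test side
  simply contribute nothing to that class's metric.
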