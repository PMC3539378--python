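# Methods

## The texture operator

Plain local binary patterns (LBP) code, for each pixel, the signs of the
differences between the P circular neighbors and the center:

    LBP_{P,R} = sum_{p=0}^{P-1} s(g_p - g_c) 2^p,   s(x) = 1 if x >= 0 else 0.

Neighbor p sits at angle 2πp/P (counter-clockwise from east) on a circle
of radius R; off-grid positions are bilinearly interpolated.  Because the
code depends only on differences, two tissue regions with the same local
structure but different absolute brightness are indistinguishable — yet
in mammography absolute gray level tracks tissue density and is itself
diagnostic.

The GLLD (gray level and local difference) operator implemented here
codes three complementary quantities per pixel.  First the center value
is replaced by the 3×3 neighborhood mean `gc_mean` (9 pixels, center
included), and the local difference vector `diff_p = g_p − gc_mean` is
split into sign and modulus, `diff_p = m_p · s_p` with `s_p = +1` iff
`diff_p ≥ 0` and `m_p = |diff_p|`. Then:

* **SGLLD** packs the signs into a binary word (`s_p = −1` → bit 0);
* **MGLLD** thresholds the moduli at `c` = the mean modulus over the
  whole ROI (adaptive per ROI);
* **CGLLD** is a single bit `gc_mean ≥ c_I`, with `c_I` the mean gray
  level of the whole ROI.

All inequality thresholds are inclusive (`≥`).  SGLLD and MGLLD words are
reduced by the rotation-invariant uniform (riu2) mapping: a circular
pattern with at most two 0↔1 transitions keeps its popcount (P+1
possible values); all other patterns collapse into one miscellaneous
label P+1, so the codomain has exactly P+2 members.

The per-ROI descriptor is a histogram over the valid interior (a border
of width ⌈R⌉+1 is excluded so that the sampling circle and the 3×3
window always fit; no padding is ever used).  Two assembly modes exist:

* `joint` (default): the flattened 3-D joint histogram over
  (SGLLD^riu2, MGLLD^riu2, CGLLD), (P+2)·(P+2)·2 bins — 1352 at the
  standard (P, R) = (24, 3) operating point;
* `concat`: the three marginal histograms concatenated, 2(P+2)+2 bins
  (54 at P=24).

`joint` is the default because only it produces the 1352-input network
of the reference architecture; the marginals of the joint histogram
reproduce the concatenated form exactly (tested).  Features are
L1-normalized by default so ROI size drops out.

Properties that follow from this construction, all verified in the test
suite: invariance to an additive gray shift (differences, the modulus
threshold and both sides of the CGLLD comparison shift together);
invariance of the riu2 histograms under quarter-turn rotations (for P
divisible by 4 the sample-point set is 90°-symmetric and bilinear
interpolation commutes with quarter turns); and histogram conservation
(bins sum to the valid-pixel count, or 1 after normalization).

### Conventions that the definitions leave open

* Angular origin east, counter-clockwise, row offset −R·sin (rows grow
  downward).  Any consistent convention yields the same riu2 histograms;
  this one is fixed for raw-code reproducibility.
* The modulus threshold `c` is the mean of the m_p over the ROI being
  coded — not the mean gray level, which is what `c_I` uses.  Both
  thresholds are per-ROI quantities.
* Neighbors g_p are raw (interpolated) gray values; only the center is
  mean-filtered before differencing.
* Near-integer sample coordinates (|frac| < 1e-9) are snapped to the
  grid so that axial neighbors return exact pixel values.

## Classification

Three binary classifiers (mass = 1) share one interface:

* **MLP** — one hidden layer of 20 sigmoid units and a single sigmoid
  output, trained by backpropagation on the mean squared error, stopping
  at MSE ≤ 0.001 or 2000 iterations.  The error measure E = Σ(y−T)/n is
  also exposed as `relative_error` (a signed mean; residuals of opposite
  sign cancel), but the squared form drives training.  The optimizer is
  full-batch Adam with learning rate 0.05, seeded uniform(−0.5, 0.5)
  initialization, and per-feature standardization fitted on the training
  set and stored with the model; these choices are not dictated by the
  architecture and are documented here because L1-normalized 1352-bin
  histograms have entries of order 1e-3, on which unscaled plain
  gradient descent converges impractically slowly.  The sigmoid output
  in (0, 1) is the ROC score.
* **SVM** — decision function C(x) = Σ_i a_i ⟨s_i, x⟩ + b over the
  support vectors (linear kernel, C = 1); C(x) ≥ 0 assigns the mass
  class.  Fitting uses scikit-learn's SVC; the stored dual form makes
  the model JSON-serializable and the decision explicit.
* **kNN** — Euclidean metric, majority vote, default k = 5 (k is a free
  parameter).  The score is the positive-class vote fraction; distance
  ties are broken by training-set order (stable sort).

## Evaluation

The ROC curve (sensitivity vs. false positive rate) is swept over all
distinct continuous scores; A_z is the trapezoidal area, which equals
the tie-corrected Mann–Whitney statistic — a property the tests assert
against an independent pairwise oracle.  A reasonable classifier
satisfies 0.5 ≤ A_z ≤ 1.  Two protocols: a stratified half/half
train/test split (the 500/500 design, run here at reduced n) and
leave-one-out.  Leave-one-out retrains per fold and is used with the
cheap classifiers (kNN, SVM); the split protocol is used with the MLP.

## Synthetic data

Real screening ROIs cannot be shipped, so the generator emulates only
the statistics the operator must detect.  Mass-free ROIs are white
Gaussian noise blurred with σ = 4 px, centered at K/2 with gain 60
(realized std ≈ 4 gray levels), clipped to [0, 255].  Mass ROIs add a
centered Gaussian-profiled elliptical blob with random eccentricity in
[1, 2] and orientation, amplitude = contrast × the realized background
std (default contrast 3).  The mass area is the pixel count of the
blob's half-amplitude level set × (0.2 mm/px)²; the target area is drawn
from one of six clinical size classes (<10, 10–60, 60–120, 120–190,
190–270, ≥270 mm²), drawn 8 % inside the interval edges so the
discretized area stays in class.  The default 128-px ROI represents
classes 1–5 and moderate class-6 masses; infeasible class/ROI
combinations raise immediately.

What the generator does **not** emulate: spiculated margins,
architectural distortion, microcalcifications, pectoral muscle or skin
line, scanner noise characteristics, or inter-patient density variation.
A high A_z on synthetic data therefore demonstrates that the pipeline is
wired correctly and that the descriptor separates additive
blob-on-texture contrast — not clinical-grade detection performance.

## Problem sizes and determinism

Default experiment: 50 mass / 50 mass-free 128-px ROIs, (24, 3) riu2
joint features, stratified half/half split, seeded end to end (dataset
seeds are spawned from one master seed; MLP init, the split and the
permutations all derive from the same integer).  At these sizes a full
pipeline run takes a few seconds on one core.  Chance-level behavior is
checked as the mean A_z over 5 label permutations, which tightens the
sampling noise of a single 50-sample test split (SD ≈ 0.08) without
enlarging the dataset.

## Known limitations

* Raw (non-riu2) codes are exposed for P ≤ 62 only (int64 packing);
  riu2 coding, the intended use, has no such limit.
* `leave_one_out_eval` refits n times; with the MLP this is O(n) full
  trainings and is deliberately not the default protocol.
* The generator's blob is radially monotone; descriptors that key on
  edge texture rather than brightness would not be stressed by it.
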