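# mammotex

Texture features for mammographic mass detection: a completed-LBP-style
**gray level and local difference (GLLD)** operator, three reference
classifiers (MLP, SVM, kNN), and ROC (A_z) evaluation, exercised on a
seeded synthetic ROI generator.

## The problem

Screening mammography CAD systems must decide whether a cropped region
of interest (ROI) contains a mass or only normal breast tissue.  Local
binary patterns (LBP) are a standard texture descriptor for this task,
but they encode only the *signs* of local gray-level differences: two
regions with identical structure and different absolute brightness get
identical LBP histograms.  In breast imaging the absolute gray level
tracks tissue density and is itself discriminative, so LBP throws away
exactly the information a mass detector needs.

## The operator

For each pixel, with `gc_mean` the 3×3 neighborhood mean and
`diff_p = g_p − gc_mean` the differences to the P circular neighbors at
radius R (bilinearly interpolated off-grid), three rotation-invariant
binary codes are formed:

* **SGLLD** = Σ_p [diff_p ≥ 0] · 2^p — the sign (structure) component,
* **MGLLD** = Σ_p [|diff_p| ≥ c] · 2^p with c the mean modulus of the
  ROI — the contrast component,
* **CGLLD** = [gc_mean ≥ c_I] with c_I the ROI mean gray level — the
  absolute-brightness component.

SGLLD and MGLLD are reduced by the rotation-invariant uniform (riu2)
mapping to P+2 values each, and the per-ROI descriptor is the joint
histogram over (SGLLD^riu2, MGLLD^riu2, CGLLD): at the standard
operating point (P, R) = (24, 3) this is a 1352-component vector, which
feeds a single-hidden-layer sigmoid MLP (20 hidden units, trained on MSE
to 0.001 or 2000 iterations).  Performance is the area under the ROC
curve, A_z, with 0.5 ≤ A_z ≤ 1 for any reasonable classifier.

See `docs/methods.md` for the full model description, conventions and
limitations.

## Worked example

Run the full pipeline — simulate 50 mass / 50 mass-free 128-px ROIs,
extract GLLD(24,3)^riu2 joint features, train the MLP on a stratified
half and score the held-out half:

```
$ mammotex run --seed 7 --out runs/demo
{
  "auc": 0.9904,
  "n": 100,
  "n_pos": 25,
  "n_neg": 25,
  "protocol": "split",
  "classifier": "mlp",
  "feature_mode": "joint",
  "P": 24,
  "R": 3.0,
  "feature_dims": 1352,
  "seed": 7,
  "config_hash": "a6a52e548b97"
}
```

`auc` is A_z on the 50 held-out ROIs (25 per class): the descriptor
separates synthetic masses from mass-free tissue almost perfectly at
contrast 3× the background standard deviation.  `runs/demo/` contains
`features.csv` (one row per ROI: id, label, mode, P, R, f0…f1351),
`model.json`, `roc.csv` and `summary.json`.  The same library surface is
available in Python:

```python
import mammotex as mx

roi, area_mm2 = mx.generate_mass_roi(mx.SynthConfig(seed=7))   # 109.7 mm², class 3
fv = mx.glld_feature(roi.pixels)                               # 1352 bins, sums to 1
```

Individual stages are exposed as `mammotex simulate / extract / train /
predict / evaluate` for working with image directories and feature CSVs.

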