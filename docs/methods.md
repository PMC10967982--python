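# Methods

## The model

An image is summarised by local first-order statistics only: after cropping
the dark margin, a 10×10 grid of non-overlapping windows is laid over the
image and each window contributes two normalized 8-bin histograms — one of
raw intensities, one of Sobel gradient magnitudes. The classifier never
sees pixels, only the resulting 100×16 table. The working assumptions are:

- the diagnostically relevant structures (fluid-filled cysts, calcified
  stones, textured tumour masses) change the *local* distribution of
  intensity and edge strength, so window-level histograms carry the signal;
- CT slices and especially their gradient images are dominated by values
  near zero, so unequal bin edges that are dense near zero resolve the
  informative part of the distribution better than equal-width bins.

The 100 window histograms are read as a sequence (row-major over the grid)
by an LSTM whose final hidden state feeds a softmax layer. Because the LSTM
weights are shared across timesteps, a lesion signature is recognisable
regardless of which window it falls in — the sequence view buys positional
invariance that a flat dense layer on the 1600-vector would have to learn
separately for every window.

## Windowing and binning conventions

- Window bounds are `floor(i·dim/10)`; windows tile the image exactly and
  differ by at most one pixel per dimension when `dim` is not divisible by
  10. Images smaller than 10×10 are rejected.
- Bin `k` (k = 0..6) covers `[e_k, e_{k+1})`; the last bin is the closed
  interval `[e_7, 255]`. This makes membership at interior edges
  unambiguous and gives the conventional closed top bin.
- The gradient image is `round(clip(sqrt(Gx² + Gy²), 0, 255))` from 3×3
  Sobel kernels with replicate borders (scipy.ndimage). Clipping rather
  than rescaling keeps the gradient image on the same 0–255 scale the
  gradient bin edges are defined on; saturated responses (a step of ≥ 64
  gray levels already clips) all land in the top bin, which is where the
  edge-density signal lives anyway.

## Bin-edge optimisation

The discriminative quality of an interior-edge candidate `e` is

    J(e) = mean_r(same-class pairs) − mean_r(different-class pairs)

with Pearson `r` computed between corresponding 8-bin window histograms of
every unordered pair of distinct images, every window weighted equally.
Pairs where either histogram has zero variance are skipped and counted (a
constant histogram has no defined correlation; substituting r = 0 would
bias both means). If no comparable pair remains the objective raises.

The search is a genetic algorithm over 7 strictly increasing integers in
[1, 254]: tournament selection (size 3), uniform crossover (rate 0.8),
per-gene resampling mutation (rate 0.1), elitism (2), population 60,
300 generations by default. After every variation step a repair pass
sorts, deduplicates (resampling collisions) and snaps to the allowed
domain, so every individual ever evaluated is a valid edge set. Scores are
memoised; elitism makes the best-score history non-decreasing; a seed makes
runs bit-reproducible. An optional `allowed_values` grid restricts the
alleles, which is how the test suite compares the GA against exhaustive
enumeration of all C(14,7) = 3432 candidates on a small phantom set.
Intensity and gradient edges are optimised in two independent runs. The
shipped default edges are treated as fixed constants of the method, not as
something the package tries to re-derive.

## The classifier

Standard LSTM cell — sigmoid forget/input/output gates, tanh candidate,
additive cell update `c_t = f⊙c_{t−1} + i⊙g`, output `h_t = o⊙tanh(c_t)` —
over 100 timesteps of 16 features, final state → dropout (training only,
inverted scaling) → affine map to 4 logits → softmax; categorical
cross-entropy with ε = 1e-12 clipping; Adam (β = 0.9/0.999). Defaults:
128 hidden units, dropout 0.2, 100 epochs, batch 32, learning rate 1e-3.
Implemented in NumPy (forward pass and backpropagation through time); the
gradients are verified against central differences in the development
history and the forward pass against a per-unit oracle in the test suite.

Two conditioning choices matter and are deliberate:

- **Per-channel feature standardisation.** Each of the 16 per-timestep
  channels is standardised with mean/variance pooled over *all* windows and
  training images (not per window position). Pooling keeps the encoding of
  a given histogram value identical at every timestep, so the shared
  weights generalise across lesion positions; the fitted scaler is stored
  on the model and applied at prediction time.
- **Chrono-style gate initialisation.** Forget biases start at
  `log U(1, T−1)` with input biases negated, spreading the units' memory
  timescales up to the sequence length T = 100. A lesion often occupies
  only one or two windows; with conventional small forget biases its trace
  decays out of the cell state long before the last-mode readout, and in
  development the classifier could not learn the stone-vs-normal
  distinction at any training-set size without this initialisation.

Prediction is the argmax of the softmax probabilities, ties broken toward
the lowest class index in the fixed order (cyst, normal, stone, tumour).
Models serialise to a single `.npz` with a `format_version` field.

## Evaluation

One-vs-rest reduction per class: TP is the diagonal cell, FN/FP the
remaining row/column mass, TN the rest. Precision, recall, F1, and MCC in
its square-root-denominator form; any metric with a zero denominator is
reported as 0 and flagged rather than NaN. Reports carry raw values plus
3-decimal roundings, per-class and unweighted macro rows, as CSV and JSON.

The package embeds, as reference constants, the published test confusion
matrix of the combined-features model on the public CT kidney dataset and
the per-class metrics that go with it; the test suite verifies that the
metric implementation reproduces those values from the matrix. One cell is
internally inconsistent in the source: the printed stone F1 (0.991) does
not follow from the printed matrix (0.9904 → 0.990); the constants store
the matrix-derived value, with a comment.

## Synthetic phantoms

Phantoms are statistical look-alikes of cropped CT exports, not anatomical
renderings — sufficient because every stage of the method consumes only
local histogram statistics. Each image (128² by default) is a near-zero
margin (12 px, values ≤ 5, mimicking lossy-compressed black frames) around
an elliptical body of Gaussian texture (mean 120, sd 15). The texture is
spatially correlated (Gaussian-filtered noise, σ = 3, variance restored):
tissue in CT is locally smooth, and this is what makes the body's gradient
mass concentrate near zero — the premise behind the dense-near-zero
gradient bin edges. White-noise texture would give the body itself
near-saturating Sobel responses everywhere and destroy the gradient
channel's information.

Class insertions at a uniformly jittered position well inside the body:

| class  | insertion | intensity signature | gradient signature |
|--------|-----------|---------------------|--------------------|
| normal | none | — | — |
| cyst | smooth dark blob, r = 10 + 16 px taper, I ≈ 40 | dark-bin mass | none (by design) |
| stone | small bright disc, r = 4, I ≥ 240 | top-bin mass, overlaps body | small strong ring |
| tumour | irregular wobbled blob, r ≈ 12, I ≈ 150, texture sd 60 | mid bins | large rough area |

The cyst deliberately has *no* gradient signature: its mean drops to the
cyst intensity over a wide soft ramp while the body's noise texture is
preserved (CT noise is acquisition noise and is present in fluid too), so
its boundary gradients stay within the body-texture range. Conversely the
stone's intensity signature overlaps the body's local bright fluctuations
under the default wide top bin. Neither channel alone therefore separates
all four classes — intensity-only misses stone-vs-normal, gradient-only
misses cyst-vs-normal — which is the premise the combined-features design
rests on, and the phantom ablation reproduces that direction (combined
above both single channels). The symmetric-vs-asymmetric edge comparison
of the original study is dataset-dependent and is *not* reproduced by
phantoms: equal-width bins capture the phantoms' coarse signatures well,
so the symmetric ablation is exposed for structural completeness, not as a
performance claim.

What the phantoms do **not** model: CT physics (beam hardening, noise
spectra), contrast phases, anatomy, slice geometry, multiple lesions, or
inter-patient variability. Passing phantom tests therefore demonstrates
that the pipeline's machinery is correct and that it can exploit exactly
the statistics it claims to use — it does not predict accuracy on real CT.

## Problem sizes

The test suite and `scripts/acceptance.py` use sizes chosen to exercise
every stage meaningfully: GA-vs-exhaustive on 40×40 phantoms, 2 per class,
with a 14-value allele grid (3432 candidates is exhaustively enumerable;
the GA runs 200 generations on the same workspace); end-to-end runs on 100
phantoms per class with the fixed-quota split at 50 (disjoint 50/50 per
class), default classifier settings; the GA-vs-symmetric objective
comparison on a 10-per-class subset with population 20 × 30 generations.
Phantom end-to-end accuracy at these sizes is ~0.98–0.995 depending on the
seed; the residual errors are normal↔stone confusions, the hardest pair by
construction (the stone's footprint is a single window). The single-channel
ablations land around 0.73 (intensity-only) and 0.92 (gradient-only),
below the combined model, as the phantom design intends.

## Known limitations

- The LSTM is a sequence model applied to a spatial scan order; it is
  position-robust but not rotation- or scale-invariant.
- Bin-edge optimisation assumes at least two images per class and
  non-constant histograms; tiny or blank images degenerate.
- Training is single-threaded NumPy; wall-clock scales linearly with
  epochs × samples (seconds to minutes at phantom scale, not suited to
  tens of thousands of real images without patience).
- The fixed-quota split warns rather than errors when a class has exactly
  quota-many samples, leaving that class untested.
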