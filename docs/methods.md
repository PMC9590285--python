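# Methods

This note records the models, conventions and design choices behind
`ecgconvit`, in the order data flows through the pipeline.

## Beat extraction and labels

Input records are a single-channel voltage trace (nominally 360 Hz) plus an
annotation stream of `(sample_index, symbol)` pairs marking R peaks. The 15
MIT-BIH beat symbols are mapped onto the five AAMI classes
(`F→F; N,L,R,e,j→N; /,f,U→Q; A,a,J,S→S; V,E→V`); any other symbol (rhythm
change, noise marker, …) raises and is skipped by the extractor. Windows are
300 samples, half-open `[r−150, r+150)`, so the R peak sits at in-window
index 150; a window that would cross a record edge is skipped and counted
rather than padded — padding would fabricate signal. Windows of adjacent
beats may overlap; no de-overlapping is attempted. R-peak *detection* is out
of scope: annotations are taken as given.

The dataset split is performed twice at ratio 8:2 with floors: `test =
floor(0.2 n)`, then `val = floor(0.2 (n − test))` of the remaining pool, the
rest is training data (100 → 64/16/20). The split is a seeded random
permutation over beats, not patients; patient-wise splitting is stricter and
supported by splitting per record upstream, but beat-wise is the default.
SMOTE runs on the train+val pool only, strictly after the test split, so
synthetic beats can never leak into evaluation.

## Time-frequency front end

The STFT uses a truncated Gaussian window `g(m) = exp(−m²/2σ²)/(σ√2π)` with
σ = 8 samples and length 65 (≈ ±4σ), hop 1, and 160 one-sided frequency
bins spanning 0–180 Hz (FFT length 318). The phase convention references
absolute time (`e^{−jωτ}` inside the sum), which matters for the group-delay
identity below. Edges are zero-padded so the time axis covers every sample.
None of these values is canonical; they were chosen once so that a
300-sample beat yields a 300×160 grid needing minimal resampling into the
160×160 classifier input.

Time reassignment computes `t̂ = Re(t − F^{τg}/F^{g})` from two STFTs, the
second with window `τg(m) = m·g(m)`. Cells with `|F| ≤ ε` (default
`10⁻⁸·max|F|`) are masked — the ratio is numerically meaningless there. The
TSST then scatter-adds each *complex* coefficient into the time bin nearest
`t̂` (clipped to the grid), per frequency row; masked coefficients stay
where they are. Squared magnitude is taken only afterwards, for display and
rasterization. Consequences, all tested: per-row complex sums are conserved
(up to float summation order); a unit impulse at n₀ reassigns every valid
cell exactly to n₀, concentrating ≥ 99% of each row's energy in one column,
whereas the plain spectrogram smears it over the window support. The
integral form of the reassignment has a known notational ambiguity (the
integration variable vs the delta argument); the implementation follows the
standard time-reassigned synchrosqueezing construction, which is what
reproduces the impulse behaviour.

Rasterization maps `|S|²` (rows = frequency ascending, columns = time)
through optional log compression `log(1 + k·p/p_max)` (k = 1000), bilinear
resampling to 160×160, then min–max scaling to [0, 1] — scaling after
resampling so the output range contract is exact. All-zero grids map to
all-zero images.

## Class imbalance

SMOTE operates on 1-D time-domain beats (before the transform), with k = 5
Euclidean nearest neighbours, index-order tie-breaking, and per-class target
counts (defaulting to the majority count). The default construction is the
standard interpolation `Z + r(Z_r − Z)`, r ~ U(0,1), whose output provably
lies on the segment between two same-class originals. A `paper_literal`
mode implements the elementwise absolute-difference variant
`Z + r·|Z − Z_r|` found in some write-ups; it biases synthetic beats upward
and is kept only for comparison.

Focal loss is `−(1 − p_t)^γ ln p_t` with γ = 2 by default; γ = 0 recovers
cross-entropy exactly (tested against an independent implementation at
1e−12). `p_t` is clamped at 1e−12 with a warning to avoid the log
singularity. Optional per-class weights multiply the per-sample losses.

## The ConViT classifier

Architecture (defaults = the published configuration): 160×160 input, 8×8
non-overlapping 20×20 patches, linear embedding to D_emb = 12; 12 blocks of
(attention + 2-layer GELU FFN), the first 10 using gated positional
self-attention, the last 2 plain self-attention; dropout 0.5 inside the FFN
and L2 (1e−4) on FFN weights; 5-way linear head. Training: focal loss
(γ = 2), Adam, lr 1e−4, batch 32, 120 epochs, lr ×0.98 every 10 epochs.

Choices the source configuration leaves open, fixed here:

* **Head count** — D_emb = 12 forces N_h ∈ {1,2,3,4,6,12}; default N_h = 4
  (head width 3, matching the 3-dimensional positional encoding). The
  9-head configuration used to demonstrate 3×3 convolution equivalence is
  constructed separately in the functional API.
* **Content-logit scaling** — the gated attention is implemented as printed,
  without the 1/√d factor on `K^T Q` (plain SA blocks keep it);
  `scale_content=True` restores it.
* **Gate and locality init** — λ = 1 (gate ≈ 0.73 toward positional),
  locality strength α = 1, head centres on a square offset grid.
* **Blocks** — pre-LN residual blocks (LN → attention → add, LN → FFN →
  add), no affine LN parameters, final LN before pooling. The published
  figure is schematic; this is the standard ViT block.
* **Pooling** — mean over tokens, then linear; no class token.
* **Decay reading** — "0.02 / 10 epoch" is read as lr ← lr·(1−0.02) every
  10 epochs (`TrainConfig.lr_at_epoch`); a weight-decay reading would be a
  different optimizer configuration and is not implemented.
* **Optimizer** — unstated in the source configuration; Adam
  (β = 0.9/0.999), single-threaded float64, bit-reproducible per seed.
* **Positional information** — learned absolute position embeddings
  (std 0.5) are added to the patch tokens. With mean pooling and no class
  token the network is otherwise nearly permutation-invariant over patches,
  and spectrogram classes differ precisely in *where* energy lies; without
  this term the pooled representation is close to location-blind.
* **Head parametrization** — the zero-initialized linear head feeds the
  softmax through a fixed gain of 16. This is a µP-style multiplier choice:
  with a small learning rate and short schedules, confident logits must be
  reachable with small weight magnitudes. The gain is a constant, never
  trained.

The desk-scale pipeline default (4 blocks: 3 GPSA + 1 SA, 30 epochs) turns
dropout off: regularization sized for a 120-epoch schedule on tens of
thousands of beats starves a 30-epoch run on ~1000 beats. The estimator
default remains 0.5 for the full configuration.

## Synthetic data: what it does and does not show

The generator emits 300-sample beats at 360 Hz as sums of Gaussian bumps
(P/QRS/T caricatures), one template per AAMI class: narrow-QRS N, wide
bizarre-QRS V with discordant T, premature-P narrow S, intermediate-width F
(fusion morphology), pacing-spike + wide-QRS Q. Corruptions are i.i.d.
Gaussian amplitude noise (default σ = 0.05 against a unit R peak, a
realistic-looking SNR for a clean lead) and Gaussian jitter of bump centres
(default 1 sample). Pairwise template correlations stay below 0.95 by
construction (max ≈ 0.80), so the classes are separable and a
nearest-template classifier is the sanity oracle at zero noise.

What passing tests on this data *show*: the transform, imbalance handling,
training loop and metrics are wired correctly end to end, and the
architecture can learn the mapping under the stated schedule. What they do
*not* show: performance on real ECG, where inter-patient morphology drift,
baseline wander, electrode artefacts and genuinely ambiguous beats dominate
the difficulty. The generator has no baseline wander, no multi-lead
information, and no physiological dynamics (no dynamical-systems ECG
model). Headline accuracies on clinical archives are out of scope here.

## Numerical conventions and degenerate inputs

* Indices are 0-based; windows half-open; the frequency axis is in Hz.
* All-zero signals: fully masked group delay, zero TSST grid, all-zero
  image — no NaNs anywhere.
* Metric cells with zero denominators (e.g. Ppv when a class is never
  predicted) return 0 and set a per-class `degenerate` flag, keeping macro
  averages finite; per-class "Acc" is one-vs-rest accuracy, the overall
  accuracy is trace/total. F1 defaults to the standard harmonic-mean form
  with the factor 2; a `paper_literal` convention without it is selectable.
* ROC classes without positives or negatives are flagged `undefined`
  rather than given an AUC.
* SMOTE requires k+1 samples in every class it augments and refuses
  targets below existing counts.
* The WFDB-dialect reader covers header + format 16/212 signals + the MIT
  annotation stream (including SKIP intervals); multi-segment records,
  checksums and other signal formats are unsupported.

## Problem sizes

The test-suite and acceptance-script sizes — 1500 beats (300 per class) for
the end-to-end run, 20 random signals for the transform oracle, 100 random
confusion matrices, 1000 focal-loss cases — were chosen as the smallest
sizes at which each property is convincingly exercised on a single CPU
core; the end-to-end run takes about six minutes, everything else seconds.
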