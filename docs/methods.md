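# Methods

This note records the modelling assumptions, parameter choices and
numerical conventions behind `stabforge`, and what the synthetic-corpus
experiments do and do not demonstrate.

## Encodings and coordinates

Primary sequences (≤ 145 residues) are one-hot encoded into a 23 × 175
window: 20 amino acids plus padding `X`, start `J` and end `O`, placed in
the middle 145 columns (0-based columns 15–159) with `J`/`O` immediately
flanking the residues.  The placement offset is "random but consistent":
uniform over the legal range as a function of SHA-256 of
`(global_seed, sequence)` — never the interpreter's randomized string hash
— so encodings are reproducible across processes.  Secondary strings over
{L, E, H} are encoded 6 × 175 with identical placement.  All coordinates in
the codebase are 0-based half-open.

## Unfolded-state model

One network per protease: 100 kernels of width 5 (23 rows) convolved over
the flanked sequence, each kernel max-pooled over the positions whose
window overlaps the sequence, then a linear head.  Restricting the maximum
to sequence-overlapping windows makes predictions independent of batch
padding.  Kernel width, optimizer (Adam, lr 3·10⁻³), epochs and the
early-stop patience are config fields; kernels are initialized at 0.1×
Glorot scale because max-pooling amplifies initial activation variance and
a near-bias-only starting point converges faster on weakly structured
targets.  The USM consumes a fixed placement, so each sequence has exactly
one prediction.  The two proteases are trained fully separately.

## Evaluator model

Architecture (full scale): conv layers of 400 kernels 23 × 5 (output
171 × 400), 200 of 1 × 9, 100 of 1 × 17, all valid, ReLU, 20 % dropout;
dense 80 → 40 → 2 (chymotrypsin, trypsin) with a third output defined as
their minimum inside the graph; a separate dense layer from the flattened
final conv layer to the 6 × 175 secondary softmax.  The default config is
the full-scale architecture; `EMConfig.desk_scale()` (32/16/12 kernels,
dense 32/16) is what the tests and the synthetic study train, sized so the
end-to-end study fits in minutes of one CPU.

Losses, per minibatch of 64 triplets:

* `Ls = mean((X−X̂)²) − 5·R²(x_m) − R²(x_{c,t})`, R² computed with
  minibatch means.  The first term is the mean squared error (an RMSE
  variant changes nothing qualitative; the −6 perfect-fit value is the
  same either way).  If a minibatch has zero target variance the R²
  terms are set to 0 rather than dividing by zero.
* `Lc = 2.5·σ(ỹ_m − ŷ_m) + 0.001·mean((ŷ_c − ŷ_t)²)`.  The sign of the
  exponent is chosen so the term is *low* when naturals out-score their
  scrambles; the opposite sign is available as
  `comparator_printed_sign=True` for ablation experiments.
* `Ld` = categorical cross-entropy of the secondary softmax plus
  `0.8·mean L*(Ẑ01) + 0.4·max L*(Ẑ01) + 0.1·mean L*(Ẑ) + 0.05·max L*(Ẑ)`,
  where `L*` is the grammar-kernel invalidity (below) and `Ẑ01` the
  per-column argmax binarization (ties broken toward the lowest row, i.e.
  L first).  Cross-entropy is averaged over the 175 columns so the term
  does not scale with the window width.
* `L = 0.2·Ls + 0.1·Lc + 2·Ld`, optimized with Adadelta; training stops
  after five epochs without validation improvement and restores the best
  snapshot.  The validation split is 10 % (capped at 10,000 samples).

Grammar kernels: six 6 × 2 kernels, one per symbol, +1 at the focal symbol
in column 1 and −1 at each allowed successor in column 2 (L→{L,E,H,O},
E→{L,E}, H→{L,H}, X→{X,J}, J→{L}, O→{X}).  Convolving with a one-hot
secondary encoding and clipping to [0, 1] yields, per adjacent pair,
exactly the indicator of an illegal succession; the clip gradient is zero
outside (0, 1).  Note the successor table lets a protein begin only with a
loop and end only after a loop; a documented `permissive_start` option
additionally allows J→E and J→H, off by default.

## Generator model

Secondary→primary translation with equal lengths.  Encoder: same-padded
width-5 convolution (tanh).  Attention: additive — learned keys from the
encoder features, query from the decoder state.  Decoder: an LSTM whose
input concatenates the previous-token embedding, the attention context,
and the encoder feature at the position currently being emitted; the last
term exploits the 1:1 source/target alignment and makes small desk-scale
models trainable in seconds (the attention path still carries non-local
context).  The output vocabulary is 19 amino acids (no cysteine, which
invalidates the display assay) plus a stop token; generation is
length-constrained by the input, so the stop token is masked during
decoding and only appears in training targets.  Beam ranking uses pure
summed log-probability (all hypotheses share a length, so no length
normalization), ties broken lexicographically.  The Reverse GM swaps the
vocabularies; "65 iterations" of training is read as 65 epochs and is a
config field.  A production-scale run of this architecture class would use
a parameter budget orders of magnitude larger; the default config here is
desk-scale, and the parameter count is available via
`Module.n_parameters()`.

Stability-weighted training subsets resample designs with replacement,
proportionally to `max(score, 0.05)`; the floor handles negative scores,
which the weighting otherwise leaves undefined.

## Refinement

Each round pools all single-site substitutions of all current bases,
applies constraints (forbidden replacement residues; optionally a
requirement that neither protease's USM prediction fall below the
reference — the immediate parent by default, or the round-0 original),
deduplicates, and ranks by the scorer.  Exactly the top-*k* pooled children
become the next bases, and the overall top-1 is the round product.  Ties
break by mutation position then replacement letter, making refinement
reproducible; reversions of earlier substitutions are allowed, and the
reported substitution count is the net Hamming distance to the origin.
The substitution-effect matrix compares guided and random per-(from, to)
mean score changes with Welch two-sample two-tailed t-tests, reported
uncorrected (cells with under two samples per condition get no p-value).

## Calibration

Ladder regression is total least squares with error-variance ratio 1
(configurable), computed from the leading principal component of the
centered ladder pairs.  The expression-vector map is `f(x) = x` for
`x ≤ c`, `c + s(x − c)` above, fit by minimizing summed squared orthogonal
distances to the two-segment curve: a grid over x-quantile candidates for
`c` with an inner bounded slope search seeds a Nelder–Mead polish
(tolerances 10⁻¹⁰), which recovers noiseless parameters to < 10⁻⁶.  A
fitted slope within 0.05 of 1 is reported as a flat fit (`c = max(x)`),
since no inflection is identifiable.  Per chip and per protease, maps are
fit independently; reconciliation inverts the vector map first, then
applies the ladder line.

## Synthetic corpus

The generator emulates the *structure* of a protease-resistance design
corpus, not its biophysics:

* designs 25–65 residues over topologies HHH, EHEE, HEEH, EEHEE; element
  lengths drawn per design (helices 8–14, strands 5–8, loops ≥ 2);
* residues drawn by position class — helix/strand positions hydrophobic
  ({A,F,I,L,M,V,W,Y}, one definition shared with the refinement
  constraint) with probability 0.9, loops hydrophilic with G/P enriched
  3×; a per-design corruption rate q ~ U(0, 0.5) flips positions to the
  wrong class, spreading pattern quality;
* latent protection = `2.5·clip((m − 0.70)/0.30, 0, 1)` where m is the
  fraction of positions whose hydrophobicity class matches its secondary
  symbol's preference.  The 0.70 onset encodes folding cooperativity: a
  full scramble has m ≈ 0.5 and sits on a flat-zero plateau roughly ten
  substitutions wide, so no short refinement can conjure protection —
  mirroring the empirical finding that scrambles cannot be refined —
  while designs occupy a smooth slope reaching the observed score range
  (≈ −1 to 2.5).  Scrambled controls are additionally assigned exactly
  zero protection in the assay simulation;
* observed EC₅₀ = unfolded baseline + protection + N(0, 0.1), where the
  baselines fall linearly in cleavage-prone content (K/R for trypsin,
  F/Y/W/L for chymotrypsin); an optional soft ceiling (c, s) compresses
  high values as a saturating expression vector would; credible-interval
  widths are log-normal (σ = 0.55, ~10 % exceeding the width-2 filter);
* paired chips share ladder designs spanning the EC₅₀ range, with an
  injected linear distortion and optional ceiling for calibration tests.

Everything is bit-reproducible from `(SynthConfig, seed)`.

What passing tests on this corpus show: that each algorithm recovers the
structure it was built to recover (baseline subtraction, pattern-quality
regression, guided-beats-random refinement, distortion inversion) when the
data-generating process is known.  What they do not show: performance on
real assay data, whose noise is heteroscedastic and correlated, whose
stability landscape is not a function of hydrophobic patterning alone, and
whose topology classes differ far more than these templates.

## The end-to-end study (as run in the test suite)

2,000 designs (+400 scrambles, +300 natural-protein stand-ins), seed 11.
The USM trains on the scrambles' simulated EC₅₀s; stability scores are
observed minus USM-predicted; a desk-scale EM trains ≤ 12 epochs on 1,700
designs with the natural-sequence comparator stream enabled.  On the 300
held-out designs the predicted combined score reaches R² ≈ 0.5 against
latent protection (threshold 0.3).  One hundred held-out designs and one
hundred full scrambles then undergo three rounds of EM-guided greedy
refinement (k = 1; k = 50 is the production default — the narrow beam keeps
the study inside a CPU-minutes budget and only weakens the guided arm)
against three random constrained substitutions; guided refinement raises
latent protection on designs (Welch one-sided p ≪ 0.01) and not on
scrambles.  Problem sizes here are the package's testing defaults; the
library itself has no such limits.

## Known limitations

* The autodiff core is float64 and single-threaded; the full-scale EM
  config builds and runs forward passes but is not practical to train on
  CPU.
* The EM's secondary head predicts over the whole 175-column window, so
  predicted strings include flank codes; callers strip padding.
* The piecewise calibration fit assumes the lower branch is exactly
  `y = x`; chips that disagree below the inflection need the ladder map
  first.
* `perplexity` floors reference-token probabilities at 10⁻¹², bounding the
  per-residue contribution at ~27.6 nats; a model can therefore never
  score worse than e²⁷·⁶ per residue, which is irrelevant in practice but
  worth knowing when comparing degenerate models.
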