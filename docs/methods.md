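# Methods

This note documents the models, numerical choices and known
limitations of `mbnf`: what each stage computes, which parameters
matter, what the synthetic cohorts do and do not emulate, and where
the design was genuinely open.

## Signal model and normalisation

The unit of analysis is a subject's ROI-by-time matrix `X ∈ R^{P×T}`
of parcellated BOLD signals (typical scale: P around 100 ROIs,
T around 140 volumes, TR 2–3 s, band-passed to 0.015–0.15 Hz upstream).
Each row is standardised to zero mean and unit variance before any
network estimation; a zero-variance row is an acquisition error and is
rejected with its ROI index rather than silently propagated.

## Empirical mode decomposition

`emd` sifts a series into intrinsic mode functions ordered from high
to low frequency. Numerical choices:

- **Envelopes.** Cubic splines through the interior maxima/minima.
  With fewer than four support points the envelope degrades to linear
  interpolation; with one point it is constant. Plateaus count as a
  single extremum at their left edge.
- **Boundaries.** Up to two extrema are mirrored about each end of the
  support before splining, the standard mitigation for end swings.
  End effects are the dominant error source for slow components at
  T ≈ 137 and are the reason frequency-ordering checks carry a 10%
  tolerance.
- **Stopping.** A sift is accepted when the Cauchy criterion
  `SD = Σ(h_prev − h)²/Σ h_prev² < 0.2` or after 50 sifts (both
  configurable). Extraction ends when the residual is monotone, has
  fewer than two interior extrema, or the sifted candidate has fewer
  than two zero crossings — a component without a full oscillation is
  a trend and belongs to the residual. Without the zero-crossing
  guard, short noisy series over-decompose into trend-like "IMFs"
  followed by spline artifacts that violate the frequency ordering.
- **Exactness.** The residual is what remains after subtracting the
  accepted IMFs, so `Σ IMF + residual` rebuilds the input to machine
  precision; tests assert 1e-9.

`eemd` averages EMD over an ensemble of white-noise-perturbed copies
(defaults: M = 100 trials, noise sd = 0.2·sd(x) — the canonical
settings; the study-scale experiments in the tests and the acceptance
script use M = 16, which we found sufficient for stable band splits at
T = 137). Trials may produce different IMF counts; the f-th output is
the mean over trials with missing components contributing zeros. Only
components produced by at least half the trials are kept: a mode that
appears in a small minority of noise realisations is a vestige of that
noise — its zero-padded average has negligible energy and an
arbitrary spectral centroid — and folding it into the residual is
what keeps the per-index average frequencies monotone. The EEMD
residual (input minus averaged IMFs) absorbs whatever the averaging
does not explain, so reconstruction stays exact.

**Band split.** The high band is IMF1 per ROI; the low band is the sum
of the remaining IMFs. The residual is excluded from the low band: it
is a monotone trend, and inputs are assumed detrended/band-passed. An
ROI yielding a single IMF gets an all-zero low row and a logged
warning. **Average frequency** is the spectral centroid of the
one-sided periodogram over (0, Nyquist]; a zero-crossing-rate
estimator is available behind a flag for cross-checking.

## Network construction

- **Pearson (`pc`).** `W_ij = corr(x_i, x_j)`, unit diagonal,
  symmetrised to remove last-bit asymmetry. Optional sparsification
  keeps the fraction of upper-triangle edges with largest `|W_ij|`
  (magnitude, not signed value — strong negative correlations are
  information, and the sign policy is ours since "strongest" is
  otherwise ambiguous); ties at the cutoff are all retained so the
  result is deterministic.
- **Sparse representation (`sr`).** For each node,
  `min ‖x_i − Σ_{j≠i} W_ij x_j‖² + λ Σ|W_ij|`, solved by cyclic
  coordinate descent (scikit-learn's lasso with `alpha = λ/(2T)`,
  which makes sklearn's objective proportional to the one above;
  tolerance 1e-8, max 10⁴ sweeps, non-convergence warned with the ROI
  index). λ multiplies the ℓ1 term directly — no 1/2T factor — so the
  λ grid below is on the objective's own scale. Rows are estimated
  independently and symmetrised as `(W + Wᵀ)/2`, since downstream
  edge features and fusion need one value per pair;
  `symmetrize=False` exposes the raw rows, which satisfy the lasso
  KKT conditions exactly (checked at 1e-5 in the tests).
- **Hyperparameter grids.** Pearson kept-edge fractions
  `{0.05, 0.10, …, 0.95, 0.99}` (20 values) and λ in
  `{0.10, 0.15, …, 0.95, 1.00}` (19 values). Each construction method
  grids its own hyperparameter in the inner CV.

## Similarity network fusion

Both band networks are mapped to non-negative affinities `A = |W|`
(diffusion needs non-negativity; magnitude preserves edge-strength
semantics). Per column, the k = 11 strongest off-diagonal affinities
form the sparse kernel S (ties at rank k all kept). Two modes:

- **`normalized` (default).** The dense iterates use the kernel
  convention that holds half the mass on the diagonal (diag 1/2,
  off-diagonal rows summing to 1/2), and the diffusion kernel is
  `S ← 0.5·rownorm(S) + 0.5·I` — a node is always its own nearest
  neighbour. Both halves matter: with plain row normalisation and a
  zero-diagonal S, the cross-diffusion `S·P·Sᵀ` mixes only
  shared-neighbour terms and converges to the uniform matrix, erasing
  subject-specific structure entirely (we measured fused networks
  identical across subjects to ~1e-5 under that variant). The
  self-affinity re-injects each node's own edges every iteration and
  keeps the fixed point subject-specific.
- **`literal`.** The raw products `S·P·Sᵀ` with no normalisation,
  used by the hand-computed oracle tests; scales can grow or shrink
  across iterations, so it is not the default.

Updates are simultaneous — each band diffuses through the other band's
previous iterate — and symmetrised after every product. Iteration
stops when the Frobenius-norm change (our reading of the unspecified
matrix norm) of **both** iterates is at most 0.01, or at `max_iter`
(100), in which case the result is returned with `converged=False`
and both deltas reported. The fused network is the elementwise average
of the two final iterates with a zero diagonal. On random 20-node
pairs the default mode converges in ~3 iterations.

The feature-level baseline `concatenate_baseline` splices both upper
triangles into one vector of length `P(P−1)`.

## Frequency variability

`FV_i = 1 − mean over unordered band pairs of
corr(FC_{f,i}, FC_{g,i})`, with the self-connection removed from each
profile. Averaging over *unordered* pairs makes FV = 0 for identical
bands and 2 for anti-correlated ones, matching the statistic's
intended reading (higher = more cross-band difference); a sum over
ordered pairs with the same denominator would give −1 for identical
bands, which is evidently not intended. ROIs with a zero-variance
profile in any band get NaN and are reported, not guessed.

## Classification protocol

Edge features are the row-major upper triangle of each subject's
network (E = P(P−1)/2; for P = 116, E = 6670). Selection is a
two-sample pooled-variance t-test per edge at α = 0.05 with no
multiple-testing correction (the protocol treats selection as a
filter, not an inference); Welch's form is a flag. Edges with zero
variance in both groups are excluded. If nothing passes, the single
smallest-p edge is kept so the classifier always has input. The
classifier is a linear SVM with C = 1 — linear because E ≫ N makes
kernels pointless and the filter+margin combination is the field's
standard; the positive class is the patient group for SEN/SPE.

Nested CV: for each of `n_repeats` repeats (default 10; raise it for
publication-grade error bars), a fresh stratified outer 5-fold split;
per outer fold, an inner stratified 5-fold on the outer-training
subjects scores every grid value by mean inner accuracy (ties break
toward the smaller value — more parsimony, deterministic), and the
selector + SVM are refit on the full outer-training set at the chosen
value. Selection and model choice therefore never see test subjects;
an instrumentation test asserts no fit ever receives the full cohort,
and permuted labels drive accuracy to the binomial band around 50%.
Per-repeat ACC/SEN/SPE pool the outer folds' confusion counts; AUC
pools decision scores. Means and sds are over repeats. All fold
seeds derive from one master seed; identical seeds give byte-identical
reports.

`noise_robustness_experiment` perturbs every subject's network with
symmetric Gaussian noise (drawn on the upper triangle, mirrored) at
each sd in an ascending grid and reruns the pipeline with the same CV
seed, so the sd = 0 row reproduces the clean result exactly.

## Synthetic cohorts

Each ROI signal is `low + high + noise_sd·white`, where the band
components follow a factor model: ROI i in community c loads
`√within_corr` on a shared band-limited community latent,
`√effect_size` on a per-edge pair latent (patient group only), and the
remainder on a private latent, keeping every band component at unit
variance — group effects change mixing weights, not signal power.
Latents are white noise masked to the band in the Fourier domain, so
spectra are exactly controllable. The generator returns the implied
ground-truth correlation matrices `L·Lᵀ` per band and group.

Defaults define the study conditions: bands (0.015–0.06) and
(0.06–0.15) Hz, TR = 3 s, T = 137, P = 20, 30 subjects per group,
`within_corr = 0.5`, `noise_sd = 0.3` (moderate measurement noise that
keeps both spectral peaks visible), two communities per band with the
high-band partition rotated by P/4 so the bands carry different
structure. `effect_band="both"` splits the sorted effect edges
alternately between bands, giving a cohort with complementary
group differences. The classification studies in the tests and
acceptance script plant a 0.4 shift on ten disjoint cross-community
edges and search `{0.3, 0.5, 0.7}` kept-edge fractions.

What the generator does **not** emulate: hemodynamics, neural-mass
dynamics, motion or physiological artifacts, scanner drift,
inter-subject variability in community structure, and signed
(anti-correlated) group effects. Passing tests show the pipeline's
statistical machinery behaves correctly on controllable inputs; they
do not certify performance on real fMRI.

### When fusion helps — an honest caveat

On these sharp planted-edge cohorts, the fused network does *not*
outperform the better single band: SNF averages the two bands' values
on every edge, which roughly halves each planted effect (top edge |t|
drops from ~12 in-band to ~4 after fusion) while spreading signal onto
neighbouring edges. When a single band is already near ceiling, the
dilution outweighs the gain from covering both bands' edges; the
feature-level concatenation baseline, which keeps every edge at full
strength, beats both. We verified this is not an artifact of our
diffusion variant — a from-scratch implementation of the canonical
fusion iteration performs strictly worse here. Fusion's advantages
(noise averaging, neighbourhood reinforcement) should matter more when
group differences are diffuse and correlated with community structure,
as in real cohorts, than when they are a handful of independent sharp
edges. The corresponding ordering test is left asserting the
fused-best expectation and currently fails on this regime; we prefer
that honest failure to a test tuned until it passes.

## Interfaces

Everything is plain text: per-subject ROI×time TSVs, a tab-separated
manifest with one header line for (P, T, TR), P×P network TSVs with an
ROI-index header, YAML configs with strict key checking, and JSON
reports. The `mbnf` CLI (`simulate`, `decompose`, `construct`, `fuse`,
`fv`, `classify`, `noise-test`, `run`) is a thin layer over the
library; exit code 1 flags validation errors, 2 runtime failures.
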