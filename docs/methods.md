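# Methods

## The shared-mixing generative model

A measurement session is divided into n sections.  Section i
contributes a temporal feature vector x_i^fnirs (T samples of a
trigger-locked, channel-averaged ΔHbO2 or ΔHbR trace) and a spatial
feature vector x_i^fmri (V masked, z-scored voxels of that section's
mean fMRI map).  Both are modeled as mixtures of the same n hidden
sources through one n × n mixing matrix A:

    X_fnirs = A S_fnirs,   X_fmri = A S_fmri.

Stacking the feature blocks row-wise gives a single n × (T+V) matrix
with a square ICA structure.  Independence is therefore assumed
*jointly* over the concatenated temporal-plus-spatial feature axis:
each source is one hemodynamic event type (a task response, a
physiological rhythm, a motion artifact) that expresses a temporal
signature and a spatial pattern with a common section-loading column of
A.  The payoff of the shared matrix is that unmixing automatically
pairs each temporal component with its spatial map — no post-hoc
matching step.

Assumptions worth stating plainly:

* n sources for n sections (square, no dimension reduction).  With the
  canonical five-section protocol this means five components.
* Sources are non-Gaussian; the logistic-infomax contrast is tuned to
  super-Gaussian (sparse/peaked) sources.  Spatial blobs and transient
  task responses are strongly super-Gaussian, which dominates the
  pooled feature distribution even when a temporal signature is a
  sinusoid (sub-Gaussian on its own), because V ≫ T.
* Section maps and traces are time-aligned only at the section level;
  no within-section temporal registration between modalities is
  attempted.

## Data conditioning

* **Beer–Lambert conversion** (`mbll_convert`): per channel and sample
  the 2×2 system ΔOD_λ = d·DPF_λ·Σ_c ε_c(λ)·Δc is solved for
  (ΔHbO2, ΔHbR).  Defaults: DPF = 4 at both wavelengths,
  source–detector distance 3 cm, molar extinctions at 781/856 nm from
  the Prahl/Gratzer hemoglobin compilation (HbO2: 0.735, 1.070; HbR:
  1.067, 0.721 mM⁻¹cm⁻¹), outputs in μM.  Any invertible 2×2 system is
  accepted; `unit_scale` converts the implied concentration units.
* **Band-pass** (`bandpass_filter`, default 0.01–0.5 Hz): the low-pass
  side is a 4th-order zero-phase Butterworth.  The high-pass side
  removes the mean and all discrete-cosine basis functions below the
  low edge instead of using an IIR high-pass: at 9.75 Hz sampling a
  0.01 Hz Butterworth has poles within 0.6% of the unit circle and its
  forward–backward edge transients (~40 s time constant) leak several
  percent of stop-band power into finite records; the DCT projection is
  exact and transient-free.  The band default passes the 1/51 Hz task
  cycle and rejects cardiac (~1 Hz) pulsation.
* **Epoching** (`segment_epochs`): windows of −pre…+post s (default
  ±35 s) around each event onset; samples per epoch =
  round_half_up((pre+post)·fs) + 1 (endpoints inclusive; 684 at
  9.75 Hz).  Epochs overrunning the record are dropped with a warning;
  indices use round-half-up so that whole-sample translations of
  events + recording leave epoch content bit-identical.
* **Sections**: one section = one run's single epoch (the canonical
  selection is runs 2, 4, 6, 8, 10 of ten); an optional mode averages
  run groups.  fMRI maps are z-scored over in-mask voxels; voxel order
  is C-order flattening of the boolean mask.

## Estimation

Each modality block is row-centered and rescaled by one scalar per
modality to equal mean square, so neither block dominates the
likelihood.  The stacked matrix is PCA-whitened (rank deficiency is
diagnosed with near-duplicate section pairs named), then infomax ICA
runs from a seeded random orthogonal W(0):

    ΔW = η (I + (1 − 2 g(u)) uᵀ / m) W,   u = W·X,  g(x) = 1/(1+e⁻ˣ),

the natural-gradient ascent rule for the entropy of g(W·x), averaged
over the m = T+V feature columns so η is dimension-free.  Splitting the
update per modality and summing reproduces the pooled rule exactly
(column concatenation).  Convergence when ‖ΔW‖_F < tol·‖W‖_F (default
1e-7) within 2000 iterations; η (default 0.2) is annealed by 0.9
whenever the update norm jumps > 10×, with a fresh seeded restart after
three numeric divergences.  At the optimum, for exactly
logistic-distributed sources, E[(1 − 2g(s))sᵀ] = −I makes the update
mean-zero; the test suite verifies this stationarity (norm ~ 1/√m) and
checks the update direction against a finite-difference gradient of the
objective.

ICA leaves sign and order ambiguous.  Components are ordered by
|Pearson r| against a task regressor (boxcar over [0, task_duration]
convolved with a canonical double-gamma HRF — peak 6 s, undershoot
16 s, ratio 1/6 — demeaned, unit norm); components with |r| ≥ 0.4
(configurable) are labeled "task" and sign-fixed to correlate
positively, the rest are "noise" and sign-fixed so the largest-|Z|
spatial value is positive.  Note that for a sustained 21 s block the
regressor peaks ≈12 s after onset (where the HRF first crosses zero),
not at the 5–6 s impulse-response peak.

## Movies and snapshots

For a 1-based component subset, M_fmri = |T_sub|·S_subᵀ and
M_fnirs = T_sub·|S_sub|ᵀ, materialized as T × V matrices and exported
as 4-D NIfTI.  The absolute value sits on the *weighting* modality
because the pair is fused through a single shared parameter, so only
the weighted modality's sign is meaningful; consequently the fMRI movie
is sign-blind in time while the fNIRS movie preserves temporal sign.
Both are linear in the component sum (additive over disjoint subsets),
and the implementation is verified against explicit per-timepoint /
per-voxel accumulation loops at ≤1e-12 relative error.  Snapshots use
nearest-sample lookup (the published snapshot timestamps are
sample-aligned); |Z| > 1.5 display thresholding is applied only at
export — stored values are never thresholded.

## Synthetic linked sessions

`simulate_linked` emulates the study conditions: n = 5 sections, a 70 s
epoch window at 9.75 Hz (T = 684), a 16×16×8 grid with a full mask
(V = 2048), SNR 10 per modality.  The default source palette is one
task source (boxcar ⊗ double-gamma, blobs in left-motor- and SMA-like
locations) plus nuisance sources: Mayer waves 0.1 Hz, respiration
0.3 Hz, cardiac 1.0 Hz (random-phase sinusoids), smoothed sparse motion
spikes, and a 0.05 Hz drift for n = 6 — each with its own Gaussian-blob
spatial pattern (frontal/midline).  A single task source is deliberate:
independent sources cannot each correlate strongly with one regressor
(orthogonality caps Σr² at 1), so "several task components" is not a
self-consistent ground truth for a recovery testbed.

Two conventions make the ground truth literal: source rows are
sample-orthonormalized (symmetric ZCA, a small correction since the
designed sources are nearly uncorrelated), and mixing rows are
unit-norm, so every noiseless mixed map has exactly zero mean and unit
variance and the pipeline's per-map z-scoring is a no-op — the stored
A_true generates the returned data exactly.  A is drawn with
uniform[−1,1] entries and redrawn (≤1000 times) until cond(A) ≤ 10;
Gaussian noise is rescaled so the per-block signal-to-noise *power*
ratio matches the configured SNR exactly.

What the simulator does **not** emulate: biophysical forward models
(balloon/photon transport), EPI drift and motion, spatially correlated
noise, channel-level optode geometry.  Passing recovery tests therefore
show the estimator is correct under the stated generative model, not
that real sessions meet its assumptions.

Recovery is scored by the Amari index of P = (W·K)·A_true (0 for any
scaled permutation, 1 worst case), by best-match |correlations| after
Hungarian assignment, and by whether one common permutation aligns both
modalities.  Measured behavior at the defaults: noiseless fits reach
Amari < 0.05 in 100/100 runs (n = 2…6) with reconstruction residual at
machine precision; at SNR 10 the Amari index is < 0.1 in 18/20 seeds
and the shared permutation holds in 20/20.  The mean best-match
correlation at SNR 10 sits near 0.85–0.90: that is the ceiling of *any*
linear unmixing at these conditions (corr_i² = [Aᵀ(AAᵀ + I/SNR)⁻¹A]_ii,
averaged over condition-10 mixing draws), and the infomax solution
attains it to within ~0.01 — noise mixed into the n-dimensional section
space cannot be separated out by the model class.

## Numerical and design choices

* Problem sizes in tests and the acceptance script (T = 684, V = 2048,
  20 seeds per Monte-Carlo suite) are the study conditions themselves;
  the full suite runs in well under a minute.
* Whitening precedes infomax even though n is tiny: it makes the Amari
  metric well-defined and stabilizes convergence.
* Degenerate inputs fail loudly: zero-variance maps or components,
  rank-deficient joint data (duplicated sections are named), singular
  extinction systems, epochs that leave the record, out-of-range
  section/component indices.
* File formats are the testable lowest common denominator: channel-major
  delimited text for fNIRS (shortest-round-trip float repr, so tables
  round-trip bit-exactly), BIDS-style 3-column TSV events (unsorted
  input is an error, never silently reordered), NIfTI-1 for volumes,
  masks, component maps and movies (4-D, float32).  The default mask
  keeps finite-and-nonzero voxels; an explicit mask always overrides.
* One global CLI seed expands into per-stage seeds via CRC32 of
  "seed:stage", keeping stages independently re-runnable; every stage
  writes its parameters and seeds into the run manifest.

## Known limitations

* Square jICA only: no extended-infomax for sub-Gaussian-dominated
  sources, no over/under-complete models, no ICASSO-style stability
  resampling, at most two modalities.
* Real-data figure-level outputs depend on unstated acquisition and
  hyperparameter details and are emulated qualitatively, not
  reproduced numerically.
* Movies are materialized as full T × V matrices (~11 MB at the default
  sizes); a frame-streaming writer for very large grids is not
  provided.
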