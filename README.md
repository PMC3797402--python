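# nirsfuse

Joint independent component analysis (jICA) fusion of fNIRS temporal
recordings with fMRI spatial maps, plus the spatiotemporal
"snapshot/movie" reconstruction that shows **where** (fMRI) and **when**
(fNIRS) hemodynamic signals change.

fNIRS measures cortical ΔHbO2/ΔHbR at high temporal resolution but
coarse spatial localization; BOLD fMRI has the opposite profile.  Given
n paired measurement sections — each contributing a trigger-locked,
channel-averaged fNIRS trace (T samples) and a mean fMRI map (V masked
voxels) — the two feature blocks are assumed to share one n × n mixing
matrix A:

    X_fnirs = A · S_fnirs,    X_fmri = A · S_fmri
    [X_fnirs | X_fmri] = A · [S_fnirs | S_fmri]

Unmixing the stacked n × (T+V) matrix with infomax ICA (natural-gradient
entropy maximization through the logistic nonlinearity,
ΔW = η(I + (1 − 2g(u))uᵀ/m)W) yields *paired* components: each hidden
source gets a temporal signature tᵢ and a spatial map sᵢ linked by the
same mixing column.  From a component subset the two movie duals are

    M_fmri  = |T| · Sᵀ   (spatial maps animated by temporal magnitudes)
    M_fnirs = T · |S|ᵀ   (per-voxel time courses, signs preserved)

with |Z| > 1.5 display thresholding applied at export.

The package targets the canonical right-finger-tapping block protocol
(first trigger 42 s, 21 s task / 30 s rest × 10 → 552 s at 9.75 Hz;
epochs −35…+35 s; motor channels 8–12 averaged; sections = runs
2, 4, 6, 8, 10) but every parameter is configurable.  A ground-truthed
synthetic generator (`nirsfuse.simulate`) produces linked sections with
an HRF-shaped task source and physiological/movement nuisance sources
for end-to-end validation.

## Worked example

```python
import numpy as np
from nirsfuse import (
    SimulationConfig, simulate_linked, stack_joint, fit_jica, InfomaxConfig,
    extract_components, task_regressor, StimulusParadigm, evaluate_recovery,
    compute_fmri_movie, snapshot_at, threshold_display,
)

# 1. a synthetic five-section finger-tapping session (T=684, V=2048, SNR 10)
traces, maps, truth = simulate_linked(SimulationConfig(seed=1))

# 2. joint ICA with one shared mixing matrix
X = stack_joint(traces, maps)
model = fit_jica(X, InfomaxConfig(seed=1))

# 3. label components against the block-design task regressor
paradigm = StimulusParadigm(first_onset=42, task_duration=21, rest_duration=30, n_cycles=10)
reg = task_regressor(paradigm, traces[0].time_axis)
comps = extract_components(model, X, reg)
print("labels:             ", comps.labels)
print("task correlations:  ", np.round(comps.task_correlations, 3))

# 4. how well did we recover the planted sources?
rep = evaluate_recovery(model, truth)
print("Amari index:        ", round(rep.amari, 3))
print("shared permutation: ", rep.shared_permutation)

# 5. the task movie and one snapshot near the response peak
frames = compute_fmri_movie(comps, subset=[1])
snap = snapshot_at(frames, t=12.0)
thr = threshold_display(comps.spatial[:, 0], z_abs=1.5)
print("snapshot at         ", round(snap.time, 2), "s, frame max", round(snap.frame.max(), 2))
print("voxels with |Z|>1.5:", thr.n_survivors, "of", comps.spatial.shape[0])
```

Output:

```
labels:              ('task', 'noise', 'noise', 'noise', 'noise')
task correlations:   [ 0.89  -0.116 -0.063 -0.045  0.043]
Amari index:         0.072
shared permutation:  True
snapshot at          11.97 s, frame max 29.67
voxels with |Z|>1.5: 126 of 2048
```

The planted task source is found, labeled, and ranked first (|r| = 0.89
with the boxcar ⊗ double-gamma regressor); the Amari index of 0.072
means the five estimated unmixing directions align with the five true
sources up to permutation and scale; the same permutation aligns both
the temporal and the spatial sources — the defining check that one
mixing matrix really links the two modalities.  The snapshot is the
numeric content of a published snapshot panel: a |t|-weighted spatial
field at ~12 s after task onset plus the component values at that
instant.

## Command line

```bash
nirsfuse all --seed 7 --out-dir run1          # simulate -> fuse -> movie
nirsfuse simulate --n-sections 5 --snr 10 --out-dir run2
nirsfuse preprocess --fnirs raw.tsv --events events.tsv \
    --fmri sections.nii.gz --avg-channels 8-12 --sections 2,4,6,8,10 --out-dir run3
nirsfuse fuse --out-dir run3
nirsfuse movie --subset 2,4,5 --kind fmri --zthresh 1.5 --out-dir run3
```

Each run writes a `manifest.json` with all parameters, derived stage
seeds, input checksums and output paths; a YAML `--config` file can set
any parameter, with flags overriding.

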