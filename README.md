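# simca

Analysis toolkit for **single-molecule colocalization immunoassays**: a
two-color sandwich assay read out by TIRF microscopy, where capture
antibodies (cAb, green channel) and detection antibodies (dAb, red channel)
are imaged as individual diffraction-limited spots and a *binding event* is a
dAb spot that colocalizes with a cAb spot. Counting only colocalized spots
suppresses non-specific dAb background; normalizing by the per-field cAb
count cancels heterogeneous surface loading. The package is aimed at
single-molecule microscopists and assay developers who want the full
computational chain — spot detection, channel registration, colocalization
counting, calibration, limit of detection and diagnostic classification —
with a ground-truth simulator in place of raw microscopy data.

## What it computes

Each stitched frame (capture channel left, detection channel right) goes
through Gaussian denoising (σ = 0.8 px), background removal by morphological
reconstruction, an inverse-hyperbolic-sine intensity transform, and
8-connected local-maxima selection at `median + 1.2·std` of the transformed
image. The detection channel is mapped into the capture frame with an affine
transform `T` estimated from multi-color fiducial beads
(least squares over homogeneous coordinates, averaged across bead frames),
and a cAb–dAb pair within **1.5 px** (Euclidean, one-to-one) is counted as
colocalized. Per field of view (FOV):

    normalized colocalized count = colocalized counts / cAb counts

Titrations are calibrated with the Langmuir isotherm

    y(c) = B_max · c / (K_d + c),      c(y) = K_d · y / (B_max − y)

by unweighted nonlinear least squares. The limit of detection is the
concentration at the blank mean plus three blank standard deviations, with
its uncertainty propagated in quadrature through the inverse curve.
Quantification error is the mean absolute percentage log error (MAPLE) under
an out-of-bag bootstrap; diagnostic performance is the ROC/AUC of an
unregularized logistic classifier under a class-stratified out-of-bag
bootstrap. A separate Monte-Carlo module reproduces the false-colocalization
rate of purely non-specific dAb events as a function of the cutoff distance,
with the Poisson-coverage closed form `100·(1 − exp(−ρπr²))` as its oracle.

## Worked example

Simulate a titration (ladder 0–20 000 pM, 8 FOVs each, generative truth
K_d = 404 pM, saturation fraction 0.65), register the channels from
simulated bead frames, count and normalize, then calibrate:

```python
import pandas as pd
from simca import (SimulationConfig, simulate_titration, simulate_bead_frames,
                   LangmuirModel, bootstrap_maple, bootstrap_classification,
                   colocalize, normalize)
from simca.detection import detect_both
from simca.pipeline import estimate_channel_transform

cfg = SimulationConfig(seed=1)
data = simulate_titration(cfg, [0, 10, 100, 300, 1000, 20000], 8, rng_seed=1)
beads = simulate_bead_frames(cfg.true_transform, 5, 50, 0.0, rng_seed=2,
                             image_height_px=cfg.image_height_px,
                             image_width_px=cfg.image_width_px)
T = estimate_channel_transform([f for f, _ in beads])

rows = []
for conc, frame, _ in data:
    cap, det = detect_both(frame)
    counts = normalize(colocalize(cap, det, T)[0])
    rows.append({"concentration_pm": conc,
                 "normalized_coloc": counts.normalized_coloc})
df = pd.DataFrame(rows)

fit = LangmuirModel.from_dataframe(df).fit()
print(fit.summary())
```

```
Langmuir calibration
====================
signal kind : normalized_coloc
n FOVs      : 48
K_d   [pM]  :      433.1  +/- 25.5
B_max       :     0.6431  +/- 0.01051
half-saturation signal (B_max/2): 0.3215
```

The fit recovers the generative truth (K_d 404 pM within two standard
errors; B_max 0.65). Continuing with the same `df`:

```python
lod = fit.lod(df.loc[df.concentration_pm == 0, "normalized_coloc"].to_numpy())
mp = bootstrap_maple(df.concentration_pm, df.normalized_coloc,
                     n_boot=200, rng_seed=3)
roc = bootstrap_classification(
    df.loc[df.concentration_pm == 100, "normalized_coloc"],
    df.loc[df.concentration_pm == 0, "normalized_coloc"],
    n_boot=500, rng_seed=4)
```

prints a limit of detection of `5.79 pM (± 1.69)`, a quantification error of
`MAPLE 12.76% ± 6.01%` over 200 out-of-bag bootstraps, and
`bootstrap AUC median 1.0000, IQR [1.0000, 1.0000]` for discriminating
100 pM from the 0 pM control — picomolar detection despite ~30 non-specific
dAb spots per FOV, because non-colocalized background never enters the
statistic.

The same chain runs from the shell:

```bash
simca simulate --config run.yaml --out data/ --seed 1
simca detect --in data/frames.tiff --out spots.csv
simca register --beads beads.tiff --out transform.json
simca colocalize --spots spots.csv --transform transform.json --out counts.csv
simca calibrate --counts counts.csv --out calibration.json
simca pipeline --config run.yaml --out results/   # everything, plus manifest
```

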