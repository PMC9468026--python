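# Methods

## Assay model

The assay is a sandwich immunoassay read out molecule by molecule. A
coverslip carries surface-immobilized capture antibodies (cAb) labeled with
a green-excited dye; the sample is incubated with red-labeled detection
antibodies (dAb). Both channels are imaged by TIRF microscopy and stitched
side by side into one 16-bit frame (capture left, detection right). Three
populations appear: non-specifically adsorbed dAbs, unbound cAbs, and true
sandwiches. Only the third shows a dAb spot whose registered coordinates
coincide with a cAb spot, so the colocalized count is the assay's signal and
the per-FOV cAb count its natural normalizer.

Binding follows the Langmuir isotherm: at analyte concentration `c` (pM),
each cAb is occupied with probability `f·c/(K_d + c)`, where `K_d` is the
equilibrium dissociation constant and `f ≤ 1` the fraction of capture sites
that can ever produce signal (active, labeled, correctly oriented). The
calibration curve `y(c) = B_max·c/(K_d + c)` is the counting-statistic
version of the same law; its inverse `c(y) = K_d·y/(B_max − y)` converts a
measured signal into a concentration. (The partial derivatives used in the
LOD error propagation are exactly those of this inverse, which fixes its
algebraic form.)

## Synthetic data generator

`simca.synthetic` emulates the raw data with exact ground truth. Defaults
(one `SimulationConfig`):

| parameter | default | meaning |
|---|---|---|
| frame | 512 × 1024 px | stitched; two 512 × 512 half-channels |
| pixel size | 100 nm/px | 512 px spanning 51.2 µm |
| PSF σ | 1.2 px | isotropic Gaussian, diffraction-limited at ~600 nm emission |
| cAb per FOV | uniform 150–300 | observed surface loading range |
| K_d | 404 pM | generative truth for titrations |
| saturation fraction | 0.65 | keeps normalized saturation < 1 (incomplete labeling/activity) |
| non-specific dAb per FOV | Poisson(30) | same order as the specific signal at the low end of the titration |
| degree of labeling (DOL) | Poisson(4) dyes/antibody | labeling chemistry; 3–5 typical |
| spot amplitude | 150 photons/dye at peak | SNR ≈ 25 at background 100 |
| camera | Poisson shot + Gaussian read (σ = 3) | EM-gain excess noise omitted |
| bound-dAb jitter | σ = 0.45 px | antibody size (~10 nm) + localization error |
| channel misregistration | 0.3°, scale 1.002, (+2, −1.5) px | near-identity affine, detection → capture |

A bound dAb is placed at the inverse-transformed position of its cAb plus
Gaussian jitter; σ = 0.45 px makes a true pair survive the 1.5-px criterion
with probability `1 − exp(−1.5²/2σ²) = 0.996` (Rayleigh closed form). A
zero-dye antibody (probability `e^-DOL` ≈ 1.8%) exists in the ground truth
but renders no photons; tests that compare detected counts against truth
therefore compare against the *rendered* (dye ≥ 1) population, and pairing
recovery is assessed on pairs whose members are rendered — no detector can
see a dark antibody.

What the generator deliberately does not model: photobleaching/blinking,
FRET between the channels, spectral cross-talk, EM-gain excess noise,
clustered (non-Poisson) surface loading, and drift. Passing tests therefore
demonstrate correctness of the counting and statistical machinery under the
stated noise model, not robustness to every optical artifact of real data.

## Spot detection

The recipe runs once per stitched frame and splits the maxima by half
(a spot at exactly the boundary column belongs to the detection half):

1. **Denoise**: Gaussian filter, σ = 0.8 px.
2. **Background**: subtract the morphological reconstruction by dilation of
   `smoothed − h` under `smoothed`. The reconstruction recovers everything
   except peaks more prominent than `h`, so the difference isolates spots
   (heights capped at `h`) and removes smooth illumination structure. The
   default `h` is 0.8 × the maximum *spot relief* — the smoothed image minus
   its grey opening with a 15 × 15 structuring element (much wider than the
   PSF). A plain range-based `h` fails when an illumination gradient
   dominates the intensity range: the residual dome near the illumination
   maximum then dominates the threshold statistics. The opening passes
   smooth gradients through untouched, so `h` tracks the brightest genuine
   spot in any illumination field. One artifact remains by construction: the
   illumination field's own regional maximum can survive as a single extra
   detection.
3. **Intensity transform**: `asinh(v/s)` with `s` = 99.9th percentile of the
   background-subtracted image, floored at one count. Only the extreme
   bright tail is compressed; the threshold statistics stay dominated by
   real spot structure (a small `s` would squeeze spots toward the noise
   scale and destroy the separation).
4. **Maxima**: 8-connected local maxima with transformed value ≥
   `median + 1.2·std` of the transformed *stitched* image. Computing the
   statistics globally (not per half) lets the capture channel's dense spot
   field set a meaningful bar for a nearly empty detection half — the 0 pM
   control would otherwise be thresholded against pure noise. Equal-valued
   plateaus collapse to one spot at their centroid (saturated spots count
   once); maxima in the border ring are kept. A zero-contrast image returns
   no spots.

Per-FOV quality control: a frame is discarded when the mean y-coordinate of
its capture spots lies more than 75 px from the vertical middle — the
signature of bubbles or large dust patches; clean simulated FOVs essentially
never trip it.

Limitations: the `median + 1.2·std` criterion is only meaningful when the
image contains substantial bright structure; on a frame with no spots at all
in either channel the threshold degenerates toward the noise level. The
detector reports pixel-grid centroids (median localization error ≈ 0.4 px);
no sub-pixel PSF fitting and no intensity-based molecule counting.

## Channel registration

Fiducial beads visible in both channels are detected with the same recipe,
paired across channels by *mutual* nearest neighbor (KD-tree, 5 px gate —
symmetric matching prevents many-to-one pairs when a bead is missing from
one channel), and a least-squares affine over homogeneous coordinates is
fitted per frame (exact for three non-collinear beads, the pseudo-inverse
solution beyond). Per-frame matrices are averaged element-wise, appropriate
for the near-identity transforms involved; no per-frame outlier rejection is
applied. Collinear or insufficient geometry raises a degenerate-geometry
error. With five frames of 50 beads, a jitter-free recovery is exact to
< 1e-9 px and 0.2 px bead jitter leaves a translation error below 0.05 px.

## Colocalization and normalization

dAb coordinates are mapped into the capture frame, candidate pairs within
1.5 px are sorted by (distance, capture index, detection index) — the index
order breaks ties deterministically — and accepted greedily while both
members are unassigned. One-to-one matching encodes single-sandwich
chemistry and guarantees `coloc ≤ min(cab, dab)`; it reproduces an
exhaustive all-pairs greedy oracle exactly. Per-FOV ratios
`coloc/cab` and `dab/cab` are defined for `cab > 0`; FOVs without capture
spots are flagged invalid and excluded from aggregation. Condition summaries
report mean, sample standard deviation (n−1) and CV per statistic.

## Calibration, LOD, MAPLE

`LangmuirModel.fit()` uses unweighted nonlinear least squares
(`scipy.optimize.curve_fit`), initialized at K_d = median non-zero
concentration and B_max = maximum signal, both bounded positive; standard
errors come from the Jacobian-based covariance scaled by the residual
variance. At least three distinct non-zero concentrations are required.
Inversion clamps negative signals to concentration 0 and maps signals at or
above B_max to +inf, each with a warning.

LOD: `lod_signal = ȳ + 3·s_y` over the blank FOVs (sample SD), converted
through the inverse curve; its uncertainty is the three-term quadrature of
the inverse function's partials times (s_Bmax, s_Kd, s_y), ignoring
parameter cross-covariance. The propagation agrees with a 1e5-draw Monte
Carlo within 10% in the small-uncertainty regime; when `lod_signal ≥ B_max`
the LOD is reported as +inf with a warning rather than extrapolated.

MAPLE: per bootstrap iteration the FOVs are resampled with replacement as a
training set, the curve refitted, and every out-of-bag FOV's concentration
predicted through the inverse curve;
`MAPLE = 100/n · Σ |log T − log P| / |log T|` over out-of-bag FOVs with
non-zero truth (the statistic is log-base invariant but unit-dependent;
concentrations are fixed in pM so the denominators are positive over the
10 pM–20 nM range). Predictions are clipped into [1e-3, 1e9] pM before
logging so a single pathological draw cannot make the statistic infinite.
Iterations with no usable out-of-bag FOV or an unfittable training set are
redrawn and counted.

## Classification

A single-feature logistic regression without regularization (convex, hence
deterministic) is fitted with scikit-learn; perfect class separation is
detected explicitly and reported as a warning, the scores remaining valid
for ranking. The ROC is computed over all score thresholds with ties
grouped, and the trapezoidal AUC equals the Mann–Whitney pairwise statistic
of the raw feature for any monotone model — the cross-check used in the
tests. The bootstrap resamples each class with replacement for training and
tests on the union of out-of-bag FOVs (pooled across coverslips),
redrawing iterations whose test set lacks a class; AUC samples are
summarized by median and quartiles.

Two statistical facts matter when interpreting the null case: the
out-of-bag scheme is slightly pessimistic, and the bootstrap distribution
is centered on the *dataset's* sample AUC, which itself scatters around 0.5
with SD ≈ 0.05 at 64 FOVs per class. A single null dataset's IQR therefore
misses 0.5 for a non-trivial fraction of seeds; the test suite pools AUC
samples over several independent null datasets to assess the property.

## False-colocalization Monte Carlo

Non-specific dAb events land uniformly at random; one is falsely counted
whenever a cAb lies within the cutoff r. For cAbs forming a Poisson process
of density ρ (µm⁻²), the closed form is `100·(1 − exp(−ρπr²))` per 100
events, quadratic in r at low coverage — which is why tightening the cutoff
from 200 nm to 100 nm cuts the false rate ~4-fold and 10 nm makes it
negligible. The simulation uses a 40 000 µm² torus (no edge bias against the
infinite-plane form) and redraws the cAb realization for every 100 000-event
chunk, so the estimate averages over the process ensemble rather than
conditioning on one surface (a single realization contributes a
configuration variance comparable to the binomial error at 10⁶ draws).
Density can be anchored by inverting the closed form at a reference rate
and cutoff (e.g. 4.5 per 100 at 200 nm → ρ ≈ 0.366 µm⁻²).

## Pipeline, determinism, problem sizes

`run_pipeline` composes the stages in acquisition order and writes counts,
calibration, LOD, MAPLE, ROC outputs plus a manifest (seed, config hash,
QC decisions). Every source of randomness flows through
`numpy.random.default_rng` seeded from the run seed; a rerun reproduces all
CSV/JSON outputs byte for byte. All tables carry units in column names
(px, pM, %); coordinates are 0-based pixel centers, x = column, in the
half-image frame of the named channel.

The test suite runs the statistical checks at deliberately modest problem
sizes chosen to keep the full suite around a minute while leaving the
assertions well-powered: 128 × 256-px frames for per-FOV checks, 200 FOVs
for detection exactness, 100 replicates for calibration coverage, 10⁶ draws
for the false-colocalization rates, and 16 FOVs per arm (the assay's
minimum-sufficiency count) with 1000 bootstraps for the two-arm end-to-end
comparison. The calibration-coverage check generates homoscedastic signal
noise (SD = 5% of B_max), the model the unweighted fit actually assumes;
image-derived counts are naturally heteroscedastic, and their fitted
uncertainties should be read accordingly.
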