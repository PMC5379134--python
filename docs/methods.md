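# Methods

This note documents the models and procedures implemented in `madetect`,
the assumptions behind them, the tunable parameters, and the design choices
made where the method leaves details open.

## Problem and pipeline

A microaneurysm (MA) appears in a color fundus photograph as a dark,
roughly isotropic blob a few pixels across whose intensity profile is close
to a 2-D Gaussian. The detector treats the task in two stages — a
high-sensitivity candidate generator followed by a discriminative
classifier — because no single local filter separates MAs from vessel
crossings, noise dimples, and hemorrhage fragments.

Pipeline order: green channel → FOV mask → CLAHE → Gaussian smoothing →
resize to the working resolution → MSCF response → threshold + vessel
exclusion → region growing + size filter → per-candidate feature stack →
fused-dictionary classification. The order FOV → CLAHE → smooth → resize is
a fixed convention of this package (enhancement before resampling keeps
CLAHE tiles aligned with the native sensor resolution).

## Preprocessing

* **Green channel.** MAs have their strongest contrast in the green plane;
  red is often saturated and blue is noisy.
* **FOV.** Otsu threshold on the green plane, morphological opening then
  closing with a disc of radius 2, largest connected component. Constant
  images are rejected as degenerate (Otsu needs bimodality). Non-circular
  FOVs are accepted — only connectivity is enforced.
* **CLAHE.** Tile grid 8×8, clip limit 0.01 on the [0,1] scale (both
  configurable). A perfectly flat field is passed through unchanged; CLAHE
  of a constant image is ill-defined and the identity is the natural limit.
* **Smoothing.** Gaussian, σ = 1, support exactly 5×5 (`radius=2`),
  reflection boundary.
* **Resize.** Bicubic to 850×850 (the scale at which all size-dependent
  defaults — 120-px area cap, 5-px match radius, σ range — are expressed).
  The FOV mask is resized nearest-neighbor. Annotation coordinates scale by
  the same factors.

## Candidate extraction (MSCF + region growing)

At each pixel the Pearson correlation coefficient between a Gaussian
template and the local image window is computed. Correlation is performed
against the *inverted* image (1 − I): a positive template correlated
directly with a dark blob would score negatively, and inversion realizes
the intended [0, 1] response range with negatives clamped to zero.
Zero-variance windows map to 0. The template half-width is ceil(3σ)
(≥ 99 % of Gaussian mass), giving 9×9 windows for σ ≤ 1.3 and 11×11 for
σ ∈ {1.4, 1.5}. Five scales σ = 1.1, 1.2, …, 1.5 are combined by pixelwise
maximum. Numerics: the correlations are computed by direct (non-FFT)
windowed sums, which keeps the map within ~1e-12 of a literal per-pixel
Pearson computation.

Pearson correlation is contrast-invariant, so the candidate stage is
deliberately permissive: faint noise dimples score as highly as strong
lesions. This is by design — the classifier, not the filter, carries the
specificity burden (candidate counts in the hundreds to thousands per image
are expected and handled).

**Vessel exclusion.** MAs do not lie on vessels, so seed pixels on the
vasculature are removed before growing. The built-in heuristic is a
bottom-hat transform with a disc (radius 8, larger than MA scale),
thresholded at 0.1, keeping only components that are both large
(area > 150) and elongated (eccentricity ≥ 0.9). Anything small or compact
enough to be MA-like stays out of the mask. An externally supplied vessel
mask bypasses the heuristic.

**Region growing.** Each seed component (8-connected pixels with response
≥ threshold, default 0.6 inclusive) is dilated by 2 px; the darkest pixel
of that locality is the growing seed, I_darkest. The background level I_bg
is the mean intensity of a 25×25 window at the seed. Growth includes
8-connected pixels with intensity ≤ t where

    t = I_darkest − β (I_darkest − I_bg),   β = 0.5 by default,

so β = 0 grows only the darkest level and β = 1 grows up to the background
estimate. Growth is confined to an 81×81 window around the seed; a region
touching that artificial border is treated as oversized (any region
escaping the window is far beyond the 120-px lesion cap; a sub-120-px
region that wanders 40 px from its seed does not occur for blob-like
lesions). Regions with more than 120 px are discarded; exactly 120 is
kept. Two seed components that share a darkest pixel grow the same region
and are deduplicated by seed.

## Patch features and Fisher fusion

Each candidate is represented by the 11×11 window at its region centroid
(rounded to the nearest pixel; reflection padding at image borders). Eight
feature images are computed **per window** (not on the whole image — the
two differ only at patch borders):

| code | feature | details chosen here |
|------|---------|---------------------|
| F1 | raw grayscale | — |
| F2 | histogram equalization | global, 256 bins on the window |
| F3 | Canny edges of F1 | σ = 1, hysteresis at 40 %/80 % of the gradient range |
| F4 | Canny edges of F2 | same thresholds |
| F5 | morphological closing | disc radius 1 |
| F6 | morphological opening | disc radius 1 |
| F7 | gradient magnitude | Sobel |
| F8 | wavelet denoising | db2, 1 level, soft universal threshold |

Each feature image is flattened and l2-normalized into one column of the
p×K stack (p = 121, K = 8); all-zero columns (e.g. no edges in a flat
window) are left as zeros and tolerated downstream.

The fusion matrix W (K×M, default M = 3) solves the generalized eigenvalue
problem S_b φ = λ S_w φ, with scatter accumulated over the feature axis of
the stacks: S_b = Σ_c N_c (X̄_c − X̄)ᵀ(X̄_c − X̄) and
S_w = Σ_c Σ_{i∈c} (X_i − X̄_c)ᵀ(X_i − X̄_c). S_w is ridge-regularized with
ε = 1e-6 · trace(S_w)/K to guarantee invertibility; eigenvectors are
normalized to φᵀ(S_w+εI)φ = 1 and signed so the largest-magnitude entry is
positive (reproducibility). M is capped at K.

## Dictionary learning and classification

For every class c ∈ {MA, non-MA} and fused channel m, a p×d subdictionary
Q_m^c is learned by K-SVD on the m-th fused column of the class-c training
stacks: alternate batch OMP coding (sparsity T) with sequential rank-1 SVD
atom updates; dead atoms (used by no signal) are replaced by the
worst-represented training vector. Two deliberate numerical choices:

* the coding step keeps a signal's previous code when fresh OMP would
  increase its residual, making the objective non-increasing per iteration
  by construction (plain OMP re-coding carries no such guarantee);
* atoms are initialized from d distinct training vectors and sign-fixed.

Defaults: d = 256 atoms (reduced with a warning when a class has fewer
vectors), T = 5, 15 iterations — unstated by the method, chosen as standard
K-SVD practice; all configurable. An unconstrained least-squares fit over
an overcomplete Q would give zero residual for every class, so the sparsity
constraint in coding is what makes the reconstruction errors
discriminative.

A query stack X is fused (Y = XW) and each channel OMP-coded against each
class's subdictionary; the label is the argmin over classes of the
channel-summed squared residuals. Exact ties go to the MA class (screening
favors sensitivity; configurable). The FROC ranking score of a detection is
its candidate's peak MSCF response, not a classifier margin: operating
points are produced by sweeping the candidate threshold over 0.1–0.9 with
the trained classifier fixed, implemented by extracting once at the lowest
threshold and filtering on score (which makes FROC sensitivity
non-decreasing in FPPI by construction).

## Evaluation

Greedy nearest-first one-to-one matching per image within a 5-px radius (at
850×850); unmatched detections are FPs, unmatched truths FNs. Conventions
for empty denominators: sensitivity is 1 when both truth and detections are
empty, 0 when detections exist without truth; precision is NaN (with a
warning) when nothing was detected. Fixed-FPPI sensitivities (1, 2, 4, 8,
12, 16, 20) are linearly interpolated between measured points, clamped at
the endpoints; the summary value is their unweighted mean.

## Synthetic scenes: what they emulate, and what not

A scene is a bright disk FOV (radius 0.46·size) on a dark surround, a
smooth two-sinusoid background (base 0.55, amplitude 0.08), 8 dark
smoothed-random-walk vessels (width 2–5 px, depth 0.15–0.30), n dark
Gaussian MAs (σ ∈ [1.1, 1.5] matching the filter bank, contrast ∈
[0.15, 0.40]), bright Gaussian spots (polarity distractors), flat-topped
dark blobs with area > 120 px (size-filter distractors), and white noise
(sd 0.01), assembled into RGB with the structure dominant in green. MA
centers are constrained inside the FOV (15-px margin), ≥ 10 px off
vessels, and ≥ 22 px (2× patch size) apart. Everything derives from one
seed; identical seeds give byte-identical scenes.

The generator is *not* photorealistic: vessels are non-anatomical random
walks (no branching tree, no optic disc), there are no exudates or
hemorrhages, illumination artifacts are a smooth sinusoid, and noise is
white rather than camera-correlated. Passing tests on these scenes
demonstrates that the implementation realizes the method's mechanics
(matched-filter recall, size filtering, fusion, dictionary
discrimination) — not clinical-grade performance on real retinas, where
near-perfect synthetic metrics will not transfer.

`generate_patch_dataset` harvests training patches from denser scenes
(60 MAs per 850×850 image rather than 10) purely so that a few scenes
yield hundreds of balanced patches; the per-lesion appearance model is
identical. Negative patches mix distractor centers, on-vessel points, and
random background locations ≥ 22 px from any MA.

## Problem sizes used by the reproduction script

`scripts/acceptance.py` uses 10 scenes for the candidate stage, 500
patches per class for training and for testing the classifier (M = 3 and
M = 1), and 4 held-out scenes with a 0.3–0.9 threshold sweep for the
detection FROC — sizes chosen so a single-CPU run finishes in a few
minutes while keeping the per-stage estimates stable across seeds.

## Known limitations

* The vessel heuristic is a stand-in for a proper vessel segmentation; on
  real images it under-segments thin vessels (an external mask input is
  provided for that reason).
* Candidate-stage FPPI on noisy images is high by design; total runtime is
  dominated by classifying those candidates at low thresholds.
* The 120-px size cap, 5-px match radius and σ range are all expressed at
  the 850×850 working resolution; images with very different native scales
  rely on the resize step to make those defaults meaningful.
* Group-level joint sparsity across fused channels is realized as
  independent per-channel OMP against per-class subdictionaries (the
  restriction "atoms from the same class" is enforced structurally), not
  as an explicit joint penalty.
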