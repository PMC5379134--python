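# madetect

Automatic microaneurysm (MA) detection in color fundus photographs.

Microaneurysms — tiny saccular dilations of retinal capillaries that image
as small dark round blobs — are the earliest visible lesion of diabetic
retinopathy, and finding them reliably is the core task of automated DR
screening. `madetect` implements a complete detector for them:

1. **Preprocessing** — green-channel extraction (best MA contrast), field-of-
   view segmentation (Otsu + morphological cleanup), CLAHE contrast
   enhancement, Gaussian smoothing (5×5, σ=1), and bicubic resizing to a
   fixed 850×850 working resolution.
2. **Candidate extraction** — multiscale Gaussian correlation filtering
   (MSCF): at every pixel, the Pearson correlation between a Gaussian
   template and the local window of the inverted image, for five scales
   σ ∈ {1.1, …, 1.5}, combined by pixelwise maximum. Pixels with response
   ≥ 0.6 (off the vasculature, inside the FOV) seed candidates whose extent
   is refined by region growing with the adaptive threshold
   t = I_darkest − β·(I_darkest − I_bg), β = 0.5; regions larger than
   120 px are discarded.
3. **Classification** — each candidate's 11×11 patch is described by K = 8
   feature images (raw, histogram-equalized, two Canny edge maps,
   morphological close/open, gradient magnitude, wavelet-denoised), fused to
   M = 3 channels by the Fisher-criterion projection W (generalized
   eigenvectors of S_b φ = λ S_w φ). One K-SVD dictionary Q_m^c per class
   (MA / non-MA) and fused channel is learned; a query is labeled by the
   class with the smallest accumulated OMP reconstruction error
   Σ_m min_β ‖y_m − Q_m^c β‖², |β|₀ ≤ T.
4. **Evaluation** — lesion-level one-to-one matching, sensitivity
   (TP/(TP+FN)), false positives per image (FPPI = FP/#images), precision,
   and FROC curves with the sensitivity read out at FPPI 1, 2, 4, 8, 12, 16
   and 20.

Because clinical datasets with MA ground truth are not redistributable, the
package ships a **synthetic fundus generator** (circular FOV, smooth
background, random-walk vessels, Gaussian-profile MAs with known centers,
bright and oversized-dark distractors) so that the entire pipeline is
trainable and testable from a single seed.

## Worked example

```python
import numpy as np
import madetect as md

cfg = md.PipelineConfig(atoms_per_subdictionary=128, rng_seed=5)

# train the fused-dictionary classifier on synthetic patches
train = md.generate_patch_dataset(md.harvest_params(seed=100), 150, cfg)
model = md.train_model(train, cfg)

# detect on an unseen synthetic image (850x850, 10 implanted MAs)
scene = md.generate_scene(md.SimulationParams(seed=77))
dets = md.detect(scene.image, model, cfg)
print(len(dets), int((dets["label"] == "MA").sum()))

match = md.match_detections(dets, scene.annotations, radius=5.0)
print(match.TP, match.FP, match.FN)
```

Output:

```
1235 10
10 0 0
```

1235 candidate regions survive correlation filtering at threshold 0.6 on this
scene (most are faint noise dimples — Pearson correlation is
contrast-invariant, so the candidate stage is deliberately permissive, and
this mirrors the high candidate-stage FPPI seen on real fundus data).
The dictionary classifier then labels exactly the 10 implanted
microaneurysms as MA and rejects every other candidate: 10 true positives,
0 false positives, 0 misses within the 5-px match radius.

The same pipeline is scriptable from the shell:

```bash
madetect simulate --n-images 2 --seed 7 --out scenes/
madetect train --synthetic 150 --out model/ --rng-seed 5
madetect detect --image scenes/sim00007_000.png --model model/ --out dets.csv
madetect evaluate --detections dets.csv --annotations scenes/annotations.csv \
                  --out metrics.json
```

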