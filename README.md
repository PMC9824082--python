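# thermact

Human activity recognition from **low-resolution infrared (LRIR)** frame
streams — the kind of 8×8 thermopile arrays (Grid-EYE-class sensors) used
for privacy-preserving monitoring in care environments. The package is
aimed at researchers working with multi-sensor LRIR recordings who need a
complete, testable pipeline: reading timestamped frame CSVs, building
spatiotemporal maps, removing the periodic stripe noise those maps carry,
extracting features, classifying activities, and running the standard
evaluation protocols (repeated holdout, noise A/B, layout transfer, sensor
selection). A seeded thermal-scene simulator generates datasets with the
structure of the published acquisition designs, so everything is testable
without downloading sensor deposits.

## The pipeline

A record of `n` frames (10 frames/s, 2–28 s) is equalized to 40 frames and
vectorized into a 40×64 map `X` (rows = time, columns = row-major pixels).
Stacked over records this gives a `Z×40×64` tensor.

**Periodic noise removal** (the core algorithm). In the centered 2D DFT

    F[u,v] = Σ_m Σ_n X[m,n] · exp(−j2π(um/40 + vn/64)),

unchanged pixels (vertical stripes) and repeated frames (horizontal
stripes) appear as mirror-symmetric peak pairs on the central horizontal
and vertical lines through DC (row 20, column 32). On the log power
spectrum `P = log(1+|F|)` each stripe gets a per-map threshold

    T = μ + i1 · 0.5 · σ        (μ, σ over the stripe, DC excluded),

and the `num` largest pairs above `T` are rescaled to log-power `μ` (phase
preserved, both mirror members, DC untouched) before inverting. The two
integers per stripe, `i1 ∈ {−2..8}` and `num`, are learned by K-fold
cross-validation against downstream classification accuracy over the
feasible candidate grid; thresholds always stay per-map.

**Features:** SVD subspace projection (k = 45), ridge-regularized Fisher
canonical variables (≤ Q−1 components), block 2D-DCT zigzag coefficients
(240), and patchwise GLCM texture statistics (120).
**Classifiers:** linear SVM, random forest (100 trees), 1-NN, and
multinomial logistic regression, all seeded, with stratified 10-fold CV
model selection.
**Deep route:** a numpy CNN-LSTM (three 3×3 conv layers over each frame,
two 32-unit LSTMs, softmax) on the raw 40×8×8 sequences.

See `docs/methods.md` for assumptions, parameter defaults, and what the
simulator does and does not emulate.

## Worked example

Simulate the full two-layout study design, corrupt the 15-class large-layout
tensor with stripe noise, and compare the SVD + logistic-regression pipeline
with and without the learned denoiser on matched splits:

```python
import numpy as np
from thermact import synthetic_data as sd, preprocess, augment_eval
from thermact.classify import ClassifierSpec

scene = sd.SceneConfig(seed=0)
records = sd.build_coventry_like(scene, seed=0)          # 480 + 210 records
large = [r for r in records if r.layout == "large"]
data = preprocess.build_dataset(large, "S1")             # Z=450 maps, 15 classes

noisy = data.replace_maps(sd.inject_noise_dataset(
    data.maps, sd.NoiseInjection("both", (9,), (2.0,)), seed=5))

cfg = augment_eval.PipelineConfig(extractor="svd",
                                  classifier=ClassifierSpec("lr"))
off, on = augment_eval.ab_noise_test(noisy, cfg, repeats=10, seed=0)
print("denoise off:", off.summary())
print("denoise on: ", on.summary())
```

prints

```
denoise off: 83.89% +/- 2.24% over 10 repeats
denoise on:  84.87% +/- 2.52% over 10 repeats
```

Both arms share the same ten 75/25 stratified splits; the denoiser, the
SVD basis and the classifier are refit on each training portion, so the
~1-percentage-point gain is the effect of suppressing the injected stripes
(9-cycle sinusoids in both directions, 2 °C amplitude) before feature
extraction. On clean data the same A/B moves accuracy by well under 2
points — the denoiser does no harm when there is nothing to remove.

The same machinery is scriptable from the shell:

```sh
thermact simulate --design coventry --seed 0 --out scratch/coventry
thermact ab-test --manifest scratch/coventry/manifest.yaml --repeats 5
thermact sensors --manifest scratch/coventry/manifest.yaml
```

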