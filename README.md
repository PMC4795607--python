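# wdgrain

Segmentation-free quality classification of grain imagery (e.g. rice on a
processing line).  Instead of segmenting individual kernels, an image is
treated as a texture of overlapping homogeneous particles and summarized by
the statistics of its oriented derivative responses:

1. **Steerable Gaussian-derivative filtering.**  Responses at any
   orientation θ are exact linear combinations of k + 1 basis responses,
   so one convolution per basis kernel covers all N directions.
2. **Weibull contrast model (WDMP features).**  Each oriented response
   histogram is fitted with the integral-form Weibull density
   p(x|λ, β) = C·exp(−(1/λ)|x/β|^λ), C = λ/(2λ^{1/λ}βΓ(1/λ)),
   by Newton–Raphson maximum likelihood.  The shape λ tracks particle
   granularity (λ=2 Gaussian, λ=1 Laplace, λ≪1 power-law-like; fractal
   dimension D_f = −3λ) and the scale β tracks contrast.  The feature
   vector concatenates (β, λ) over directions, scales and derivative
   orders.
3. **SMK–LSSVM classifier.**  A least-squares SVM with the combined kernel
   K = η(1 + u·v/c)^d + (1−η)·exp(−‖u−v‖²/2σ²), class-weighted penalties
   for imbalanced data, and a pivoted Gram-Schmidt (Nyström-style)
   sparsification that keeps only γ support pivots.
4. **PSO tuning.**  Hyperparameters (typically the RBF width σ and the
   class penalties) are chosen by particle swarm optimization of the
   cross-validated classification error CE = (1/N)Σ|ŷ−y|/2 · 100 %.

Because production grain imagery is proprietary, the package ships a
dead-leaves scene generator (occluding elliptical particles with
controllable size, density, contrast, elongation and noise) so the whole
pipeline is testable end to end.

## Worked example (library)

```python
import numpy as np
from wdgrain import WDParams, sample_wd, fit_wd

x = sample_wd(WDParams(0.7, 2.0), 100_000, seed=3)   # heavy-tailed draws
res = fit_wd(x)
print(res.params, res.iterations, res.converged)
```

prints

```
WDParams(lambda_shape=0.6995659004671492, beta_scale=2.001984948709993) 6 True
```

— the true shape 0.7 and scale 2.0 are recovered to 0.1 % after 6 Newton
steps.  A two-class classification run:

```python
from wdgrain import GrainSceneConfig, generate_labeled_dataset, WDMPExtractor
from wdgrain import SMKLSSVMClassifier, evaluate_error

fine   = GrainSceneConfig(mean_radius=3.0, contrast_spread=0.12)
coarse = GrainSceneConfig(mean_radius=6.0, contrast_spread=0.2)
imgs, y = generate_labeled_dataset(fine, coarse, 100, 100, seed=1)
X = WDMPExtractor(orders=(1, 2, 3), scales=(0.5, 1.0, 2.0),
                  n_directions=36).fit(imgs).transform(imgs)
clf = SMKLSSVMClassifier(rbf_sigma=5.0).fit(X, y)       # r=8.4, eta=0.4, d=0.25
print(evaluate_error(clf, X, y))                        # training CE in percent
```

`WDMPExtractor` and `SMKLSSVMClassifier` follow scikit-learn conventions
(`get_params`/`set_params`, `fit`/`transform`/`predict`,
`decision_function`) and compose with sklearn pipelines and model
selection.

## Command line

```sh
wdgrain simulate --n-a 50 --n-b 50 --seed 1 --out scenes/
wdgrain extract scenes/ --n-directions 36 --out features.csv
wdgrain tune features.csv --tunable rbf_sigma --bounds 0.5:50 --out best.json
wdgrain train features.csv --rbf-sigma 5.1 --out model.json
wdgrain evaluate features.csv model.json
wdgrain fit-wd samples.txt
```

Feature tables are CSV (one row per image, columns
`order{k}_s{sigma}_{beta|lambda}_{i}`) with a JSON sidecar recording the
filter-bank configuration; models are JSON.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the full pipeline from scratch: it generates the two-class
synthetic benchmark (100 train + 50 test images per class), extracts WDMP
features (orders 1–3, scales {0.5, 1, 2}, 36 directions), PSO-tunes the
RBF width against 3-fold cross-validated error, trains the SMK–LSSVM with
the standard defaults, and reports the held-out accuracy on stderr before
writing the JSON result object to `--out`.  A typical run prints

```
seed=1  rbf_sigma*=5.135  cv_error=2.00%  heldout_accuracy=98.00%
```

See `docs/methods.md` for the model details, parameter meanings, numerical
choices and known limitations.
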