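# nitrospec

Classification of crop-leaf nitrogen status from hyperspectral reflectance.

Excess nitrogen fertilisation leaves a spectral fingerprint in leaves well
before visible symptoms appear. `nitrospec` implements a complete analysis
for distinguishing four nitrogen-treatment classes of cucumber leaves —
D0 (the day before an excess-nitrogen application) and D1–D3 (the three
days after) — from 400–1100 nm reflectance spectra:

1. **Preprocessing** — absorbance transform *A* = log₁₀(1/*R*),
   multiplicative scatter correction (per-spectrum regression
   *x* ≈ *a* + *b*·ref against the training-mean spectrum, corrected to
   (*x* − *a*)/*b*), and a running-median smooth.
2. **Effective-wavelength selection** — biogeography-based optimization
   (BBO) searches band subsets; the fitness of a subset is the validation
   mean squared error of a fixed 18-16 rectifier/softmax feed-forward
   network trained on those bands alone (ANN-BBO).
3. **Five classifiers** — feed-forward networks trained by the imperialist
   competitive algorithm (ANN-ICA) and by harmony search (ANN-HS),
   k-nearest neighbours, stepwise linear discriminant analysis
   (Wilks'-lambda partial-F entry/removal), and a Gaussian radial-basis-
   function network ω\_i(x) = exp(−‖x−C\_i‖²/2∂\_i²), Out\_j = Σ\_i β\_ij ω\_i(x).
4. **Majority voting** — the ensemble label is the plurality vote, ties
   broken by summed classifier scores, evaluated by a repeated
   60% train / 30% test / 10% validation split protocol with pooled
   confusion matrices, CCR, per-class recall/precision/F, and one-vs-rest
   ROC/AUC.

Because no public measurement data exist for this problem, the package
includes a first-class synthetic-spectra generator that emulates the
statistical structure the analysis assumes: leaf-like base spectra,
class-dependent absorption features at 723/781/901 nm, multiplicative
scatter, spectrally correlated noise, and a D1/D3 confusability structure.
Every stage is therefore testable end to end without any download.

## Worked example

```python
from nitrospec import (GeneratorConfig, NitrogenClassificationModel,
                       SplitScheme, generate_dataset)

data = generate_dataset(GeneratorConfig(seed=7))        # 400 labelled spectra
model = NitrogenClassificationModel(
    data, bands="auto", selection_k=3,
    scheme=SplitScheme(iterations=20, seed=1), seed=0)
results = model.fit()
print(results.summary())
```

prints (abridged):

```
Nitrogen-treatment classification from leaf spectra
====================================================
Selected wavelengths (ANN-BBO): 728 nm, 778 nm, 902 nm
Iterations: 20   classes: D0, D1, D2, D3

Pooled correct classification rate (%):
  ANN-ICA   94.12
  ANN-HS    96.50
  KNN       97.17
  LDA       97.75
  RBF       93.12
  MV        97.38

Majority-vote per-class metrics (%):
    recall  accuracy  specificity  precision      f
D0   99.82     99.96       100.00     100.00  99.91
D1   95.92     97.62        98.21      94.83  95.37
D2   98.95     99.67        99.89      99.65  99.30
D3   95.22     97.50        98.34      95.51  95.36
```

The selected wavelengths land within a few nm of the planted 723/781/901
centres (the generator's ground truth), the majority vote pools to a CCR
near the mid-90s with D1/D3 the weakest classes (their spectra overlap by
design), and the deliberately small RBF network trails the ensemble — the
qualitative ordering this analysis is designed to exhibit.

The same pipeline is scriptable from the shell:

```sh
nitrospec generate --out data.csv --seed 7
nitrospec preprocess --in data.csv --out prep.csv --window 5
nitrospec select --in prep.csv --k 3 --seed 0 --out selection.json
nitrospec evaluate --in prep.csv --bands selection.json --iterations 20 \
    --seed 1 --report report.json
nitrospec run --config pipeline.yaml        # all stages, one master seed
```

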