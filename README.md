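# vacuoquant

Automated quantification of **lymphocyte vacuolization** in peripheral blood
smear images. Vacuolization — round pale clearings in lymphocyte cytoplasm —
is a morphological hallmark of CLN3 (Batten) disease, and the fraction of
vacuolated lymphocytes on a smear tracks disease severity. Manual counting is
slow and subjective enough that laboratories average two independent readers;
`vacuoquant` automates it with a two-stage deep-learning pipeline and ships
the statistical machinery to validate the automated method against manual
readers. A synthetic stained-cell generator with pixel-perfect ground truth
lets the whole pipeline be trained and validated without patient data.

Intended users: clinical-laboratory and biomedical-imaging researchers who
want a transparent, CPU-scale, fully reproducible reference implementation of
this kind of morphology-quantification pipeline.

## What it does

For each single-cell crop (one centered leukocyte, RGB):

1. **Segment** — two U-Net models predict the cell mask and the nucleus
   mask; the cytoplasm mask is their difference, and the image is blacked
   out outside it. Segmentation quality is scored with the dice
   coefficient, `2·|A∩B| / (|A|+|B|)`.
2. **Classify** — a residual CNN with a 2-neuron softmax head returns
   `P(vacuolated)`; a cell is called vacuolated when `P(vacuolated) ≥ τ`
   (τ = 0.65, inclusive). Grad-CAM heatmaps show which image regions drive
   the score.
3. **Aggregate** — per smear,
   `percent_vacuolated = 100 · n_vacuolated / (n_total − n_excluded)`,
   where excluded cells are segmentation failures (counted, never silently
   dropped).

Method agreement between automated (y) and reference (x) percentages is
assessed with Passing-Bablok regression (slope = shifted median of pairwise
slopes, percentile-bootstrap CIs over 999 resamples), Bland-Altman limits of
agreement (mean ± 1.96 SD of differences), Pearson r, and Levene's test of
variance homogeneity across paired-difference groups — all implemented from
first principles and cross-checked against independent oracles in the test
suite.

The CNNs run on a compact numpy autodiff engine included in the package
(`vacuoquant.nn`); training is CPU-only, float32, seeded and deterministic.
See `docs/methods.md` for the full model description and design rationale.

## Worked example

Generate a synthetic dataset, train everything, quantify and compare — in
one command:

```bash
vacuoquant run-all --seed 1 --out run1
```

or stage by stage via the `synth`, `augment`, `train-seg`, `train-cls`,
`quantify`, `gradcam` and `compare` subcommands. The equivalent library
calls:

```python
from vacuoquant import SyntheticParams, generate_cell, generate_smear
from vacuoquant.segmentation import SegTrainConfig, train_segmenter
from vacuoquant.classifier import ClsTrainConfig, DecisionThreshold, train_classifier
from vacuoquant.masks import apply_mask, cytoplasm_mask
from vacuoquant.pipeline import quantify_smear

params = SyntheticParams.for_image_size(64, seed=101)
pool = [generate_cell(params, vacuolated=i % 2 == 0, seed=i) for i in range(200)]
cell_model = train_segmenter(pool, SegTrainConfig(target="cell", seed=103))
nucleus_model = train_segmenter(pool, SegTrainConfig(target="nucleus", seed=104))

labeled = [generate_cell(params, vacuolated=i % 2 == 0, seed=500_000 + i)
           for i in range(1200)]
masked = [apply_mask(c, cytoplasm_mask(c.cell_mask, c.nucleus_mask)) for c in labeled]
classifier = train_classifier(masked, ClsTrainConfig(seed=105))

cells, manifest = generate_smear(30, 0.4, params, seed=42)
result = quantify_smear(cells, cell_model, nucleus_model, classifier,
                        DecisionThreshold(0.65))
print(result.percent_vacuolated)
```

A full training run prints progress like this (seed 1, one CPU):

```
[1/4] training segmenters on 200 synthetic cells ...
      cell dice 0.9942, nucleus dice 0.9956
[2/4] training classifier on 1200 masked cells ...
      validation accuracy 1.0000
[3/4] quantifying 8 synthetic smears ...
[4/4] method comparison ...
      r 0.9965; slope 0.925 (95% CI 0.833-1.000)
```

Reading the numbers: both segmenters exceed dice 0.95 on their held-out
validation cells; the classifier separates vacuolated from healthy masked
cells on its validation split; and across eight smears spanning 0–70%
true vacuolization, the automated percentages track ground truth almost
perfectly (Pearson r) with a Passing-Bablok slope whose CI includes 1 — no
proportional bias between the automated and reference quantification.

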