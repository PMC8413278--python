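# cytophase

Label-free discrimination of alive, apoptotic and necroptotic cells from
quantitative phase images.

Digital holographic microscopy (DHM) records the phase delay Δφ that
transmitted light accumulates when it crosses a transparent cell. The delay
relates to the specimen's apparent ("optical") height h through

    Δφ = (2π / λ) · (η_i − η_media) · h

with λ the illumination wavelength, η_i the mean refractive index of the
cell and η_media that of the medium. Because cell-death programmes remodel
both morphology and refractive index — apoptotic cells shrink, bleb and
*gain* optical height; necroptotic cells swell into large flat domes and
*lose* it — the phase image alone carries enough signal to classify cell
death without fluorescent labels.

`cytophase` implements the full analysis pipeline for such experiments:

1. **phase_optics** — phase ↔ optical-height conversion and float32 TIFF +
   JSON capture I/O;
2. **segmentation** — threshold-based cell localization, 66×66 crop
   extraction with strict area (80–600 px) and border filters;
3. **sad_filter** — a supervised anomaly-detection (SAD) filter: an
   Alive-vs-Death SVM over crop embeddings that discards cells whose
   appearance contradicts their experiment's condition, purifying labels
   before training;
4. **classifier** — class balancing, stratified 80/20 splitting, and a
   transfer-learning classifier: a VGG-19-style backbone whose final
   classification stack is replaced by a new FC-64 → ReLU → FC-3 → softmax
   head (a compact `small_cnn` backbone is the desk-scale default);
5. **evaluation** — per-class accuracy, confusion matrix, one-vs-rest
   ROC/AUC with a brute-force pair-counting oracle;
6. **synthetic_data** — a seeded generator of captures with planted
   morphologies, so the whole pipeline runs and is tested without any
   microscope data;
7. **pipeline / cli** — end-to-end orchestration and a `cytophase`
   command-line interface.

It is aimed at cell-death and quantitative-phase-imaging researchers who
want a reproducible, scriptable version of this analysis, and at method
developers who need a fully synthetic test bed for it.

## Worked example

```python
from cytophase.pipeline import (
    PipelineConfig, run_training_pipeline,
    generate_condition_captures, run_holdout_evaluation,
)

config = PipelineConfig(seed=1)          # fully synthetic run
result = run_training_pipeline(config)
print(result.stage_counts)

holdout = generate_condition_captures(config, seed_offset=500_000)
report = run_holdout_evaluation(
    config, result.classifier, holdout,
    result.train_capture_ids, result.sad_model,
)
print(report.per_class_accuracy)
print(report.auc)
```

prints (seed 1):

```
{'captures': 18, 'detections': 288, 'segmentation_discard_area': 0,
 'segmentation_discard_border': 0, 'crops': 288, 'sad_input': 288,
 'sad_kept': 260, 'sad_discard_class_mismatch': 28,
 'sad_discard_below_threshold': 0, 'balanced': 243, 'train': 195, 'val': 48}
{'alive': 0.958..., 'apoptosis': 0.988..., 'necroptosis': 1.0}
{'alive': 0.999..., 'apoptosis': 0.995..., 'necroptosis': 0.999...}
```

Reading the output: 18 synthetic captures (6 per condition, 16 cells each)
yield 288 candidate crops; the SAD filter removes the 28 crops whose
alive/dead appearance contradicts their dish's condition (the planted
"impurity" of induced experiments); after balancing to the smallest class
and an 80/20 stratified split, the classifier is trained and then evaluated
on captures from experiments it has never seen. Per-class holdout accuracy
is ≥ 0.95 and each one-vs-rest AUC is ≥ 0.99 on these well-separated
synthetic morphologies.

The same run from the shell:

```bash
cytophase run-all --seed 1 --out run/
```

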