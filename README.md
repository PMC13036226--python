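# mmfluorfuse

Multimodal classification of soybean salt-tolerance levels from
chlorophyll-fluorescence phenotyping data.

## The problem

Screening soybean germplasm for salt tolerance by eye is slow and
subjective. Chlorophyll-fluorescence imaging (CFI) offers a non-destructive
readout of photosystem II (PSII) status: after dark adaptation, the maximum
quantum yield of PSII photochemistry, QY_max = Fv/Fm, drops as salt stress
damages the photosynthetic apparatus. A FluorCam-style acquisition yields
two coupled modalities per plant:

* a pseudo-colored fluorescence **image** (nominally 1024 x 768), and
* a table of **80 named fluorescence parameters** (Fm, QY_max, NPQ_Lss,
  qP_Lss, Rfd_Lss, ...).

Plants are graded into five ordinal salt-tolerance levels by QY_max bins:

| level | QY_max          | phenotype                                  |
|-------|-----------------|--------------------------------------------|
| 1     | >= 0.79         | healthy green                               |
| 2     | [0.61, 0.79)    | slight tip/edge chlorosis                   |
| 3     | [0.46, 0.61)    | brown spots, chlorosis                      |
| 4     | [0.31, 0.46)    | severe chlorosis, curled softened edges     |
| 5     | < 0.31          | wilted grayish margins, extensive browning  |

This package implements a gated image-text interaction network
(Mm-VitnNet) that fuses both modalities, together with the full data
pipeline and a synthetic paired-data generator so everything runs and is
testable without instrument exports.

## The model

Images are center-cropped to 664 x 664, resized to 224 x 224 and
tokenized by a convolutional stem (3x3 stride-2 conv + 2x2 max pool,
224 -> 56 grid). The 80 parameters are z-scored and reduced by PCA to
k = 6 components ("text"), each embedded as one token. Two sets of
learnable global tokens ride along the sequence
`[image | text | global]`.

Four stages (depths 1, 3, 3, 1) process the sequence; image grids shrink
56 -> 28 -> 14 -> 7 via 2x2 token merging. Each block in stages 1-3
combines:

* **ITSAI** — windowed local self-attention on image tokens and global
  self-attention on text tokens (from one shared QKV projection,
  partitioned by index), a directed cross-attention with image queries
  and text keys/values, and a learned scalar gate
  `g = sigmoid(W2 relu(W1 [GAP(I); GAP(T)])) in (0, 1)` that scales how
  much text-retrieved information is fused into the image stream
  (`I <- I + g * CrossAttn(I, T)`); four variants (`ai`, `b`, `aip`,
  `bip`) cover unidirectional/bidirectional retrieval with one or two
  gates.
* **ITLeSAMM** — each global-token set queries its own modality to
  aggregate a global summary, then image and text tokens query the
  refreshed global tokens to receive it back.

Stage 4 is ITLeSAMM-only. A linear head over pooled image, text and
global tokens emits the 5 class logits. Training uses Adam with a cosine
learning-rate schedule (1e-4 -> 1e-6 over 200 epochs by default) and
inverse-frequency class-weighted cross-entropy.

The network, its attention primitives and the training loop are
implemented on a small in-repo reverse-mode autodiff engine over numpy
(`mmfluorfuse.autodiff`), so the package runs on any CPU-only
scientific-Python installation.

## Worked example

```python
import numpy as np
from sklearn.preprocessing import StandardScaler
from mmfluorfuse import (GeneratorConfig, generate_dataset, fit_reduction,
                         apply_reduction, select_cluster_count, assign_level,
                         center_crop, resize, MmVitnNetClassifier, ModelConfig,
                         TrainConfig, evaluate)

# 1. synthetic paired dataset (levels drawn per the observed proportions)
cfg = GeneratorConfig(n_samples=60, seed=1, image_size=(96, 96))
samples, manifest = generate_dataset(cfg)
print("levels:", np.bincount([s.level for s in samples], minlength=6)[1:])
print("QY_max of sample 0:", round(samples[0].params.qy_max, 3),
      "-> level", assign_level(samples[0].params.qy_max))

# 2. cluster-count criterion on the parameter vectors
X = np.stack([s.params.as_array() for s in samples])
k = select_cluster_count(StandardScaler().fit_transform(X), range(2, 11), seed=1)
print("Calinski-Harabasz selected k =", k)

# 3. reduce parameters to 6 PCs, train a reduced-width model
red = fit_reduction([s.params for s in samples], k=6)
text = np.stack([apply_reduction(red, s.params).values for s in samples])
images = np.stack([resize(center_crop(s.image, 96), 64).pixels for s in samples])
levels = np.array([s.level for s in samples])

clf = MmVitnNetClassifier(
    model_config=ModelConfig(stage_depths=(1, 1, 1, 1), stage_widths=(8, 16, 24, 32),
                             heads=(2, 2, 2, 4), window=2, img_size=64),
    train_config=TrainConfig(batch_size=16, epochs=30, lr_max=3e-3, lr_min=1e-5),
    seed=0)
clf.fit((images, text), levels)
report, counts, mat = evaluate(levels, clf.predict((images, text)))
print(f"train accuracy {report.accuracy:.3f}, macro-F1 {report.macro_f1:.3f}")
```

Output:

```
levels: [13 10  9  9 19]
QY_max of sample 0: 0.325 -> level 4
Calinski-Harabasz selected k = 5
train accuracy 0.967, macro-F1 0.963
```

The level histogram follows the configured proportions; the
Calinski-Harabasz criterion recovers the five-level structure from the
parameter vectors alone; and the reduced-width network fits the 60-sample
set to 96.7% training accuracy in 30 epochs — a capacity/smoke check, not
a generalization claim.

## Command-line pipeline

```bash
mmfluorfuse generate --config cfg.yaml     # synthetic images + params + manifest
mmfluorfuse prepare  --config cfg.yaml     # crop/resize, 8:1:1 split, 6-fold augment,
                                           # jitter, PCA reduction
mmfluorfuse train    --config cfg.yaml     # cosine-annealed Adam; best-val checkpoint
mmfluorfuse evaluate --config cfg.yaml     # metrics.json + confusion.csv on the test split
mmfluorfuse inspect  --config cfg.yaml     # parameter/FLOP accounting incl. depth ablation
```

Exit codes: 0 success, 2 configuration error, 3 data error. Every stage
writes a `meta.json` with the config hash and seed; reruns with the same
configuration are byte-identical.

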