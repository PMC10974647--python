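# admetfuse

Multi-task prediction of ADMET properties (absorption, distribution,
metabolism, excretion, toxicity) for drug-like compounds, fusing two views
of a molecule: its **SMILES string**, read by a transformer encoder
pre-trainable with a masked-language-model (MLM) objective, and its
**physicochemical feature block** (1 Boolean, 5 integer and 7 float
descriptors such as LogP, pKa and polar surface area), read by small
embedding/affine layers. The package is aimed at computational chemists and
ML practitioners who want a self-contained, CPU-scale testbed for
QSAR-style multi-label models — every component, from the BPE tokenizer to
the ensemble vote, runs and is tested without any external dataset, using
a synthetic molecule generator with planted, controllable signal.

## The models

Each compound is mapped to 21 binary ADMET outcomes
ŷ = σ(W h + b) ∈ (0, 1)²¹, where the hidden representation h depends on
the architecture:

| architecture | inputs | hidden representation h |
|---|---|---|
| `dnn` | features | Boolean → 10-d embedding; 5 ints → 10-d affine; 7 floats → 10-d affine; concatenated to **30-d** |
| `encoder` | SMILES | transformer CLS vector, **H = 768-d** by default |
| `concat` | both | [30-d ‖ H-d] = **798-d** at defaults |
| `pipe` | SMILES (+features as targets) | encoder → 13 predicted physchem values → DNN trunk → 30-d |
| `dnn_a`, `pipe_a` | as dnn / pipe | dot-product self-attention over the three 10-d group vectors (Q = K = V), tanh-activated |

Heads are plain affine stacks — no hidden nonlinearity except the tanh
inside the attention block (`activation="relu"` opts into nonlinear heads).
Training follows a fixed protocol: data split 7 : 1.5 : 1.5, batches of 32,
AdamW at learning rate 5 × 10⁻⁵ (defaults; small-scale runs override),
binary cross-entropy (plus MSE for the pipe's intermediate regression),
early stopping after 5 non-improving validation epochs, at most 30 epochs,
five replicate seeds reported as "mean (SD)".

Evaluation computes per-label accuracy, AUROC (Mann–Whitney concordance,
ties half), F1, precision and recall; a six-model majority vote with a
mean-probability tie-break at 3 : 3; and three CYP450-substrate
aggregations, including soft voting weighted by hepatic enzyme abundance
(2C9 : 12%, 2D6 : 4%, 3A4 : 30%, normalized by the weight sum).

Everything is implemented on numpy, including a small reverse-mode
autodiff engine (`admetfuse.autodiff`), the transformer encoder, AdamW,
and the byte-pair-encoding SMILES tokenizer.

## Worked example

Generate 1000 synthetic molecules whose labels follow a planted logistic
rule on the feature block, then fit the feature-only DNN three times:

```python
from admetfuse import (
    GeneratorConfig, generate_dataset, default_schema, fit_normalization,
    apply_normalization, split, train_model, TrainConfig, format_mean_sd,
)
from admetfuse.data import records_to_frame, label_matrix

schema = default_schema()
records, truth = generate_dataset(
    GeneratorConfig(n_molecules=1000, seed=7, label_mode="feature_driven", noise_rate=0.05)
)
train_recs, val_recs, test_recs = split(records, seed=0)   # 700 / 150 / 150
stats = fit_normalization(train_recs)                      # train-split z-scoring
parts = [apply_normalization(r, stats) for r in (train_recs, val_recs, test_recs)]
Xs = [records_to_frame(p).drop(columns=list(schema.final_label_names)) for p in parts]
ys = [label_matrix(r) for r in (train_recs, val_recs, test_recs)]

aurocs = []
for seed in range(3):
    record = train_model("dnn", Xs[0], ys[0], Xs[1], ys[1], Xs[2], ys[2],
                         config=TrainConfig(learning_rate=1e-3), seed=seed)
    aurocs.append(record.test_metrics["macro_auroc"])
    print(f"seed {seed}: stopped after epoch {record.stopped_epoch}, "
          f"test macro AUROC {record.test_metrics['macro_auroc']:.3f}")
print("replicates:", format_mean_sd(aurocs))
```

Output:

```
seed 0: stopped after epoch 30, test macro AUROC 0.896
seed 1: stopped after epoch 30, test macro AUROC 0.896
seed 2: stopped after epoch 30, test macro AUROC 0.889
replicates: 89.4 (0.4)
```

A macro AUROC near 0.9 means the DNN recovered the planted logistic rule
(the generator's Bayes ceiling under 5% label noise is about 0.9); the
"89.4 (0.4)" line is the mean (SD) over the three replicate seeds. Had the
labels been planted in a SMILES substructure instead
(`label_mode="structure_driven"`), the feature-only DNN would stay near
0.5 while the `encoder` and `concat` models reach ≈ 0.93 — the feature
block is blind to structure by construction.

The same pipeline is available from the shell:

```sh
admetfuse simulate --n 1000 --seed 7 --label-mode structure_driven --out mols.csv
admetfuse tokenize --corpus mols.csv --vocab-size 150 --out vocab.json
admetfuse pretrain --corpus mols.csv --vocab vocab.json --hidden 64 --layers 2 \
                   --heads 4 --ffn 128 --max-len 32 --out encoder.npz
admetfuse train    --data mols.csv --arch concat --vocab vocab.json \
                   --checkpoint encoder.npz --learning-rate 1e-3 --out-dir runs/
```

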