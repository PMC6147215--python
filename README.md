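# doctriage

Neural-network ensemble document triage for biomedical literature
screening: five document encoders (LSTM, CNN, LSTM-CNN, RCNN and a
hierarchical LSTM), an attention-BiLSTM module pre-trained on a larger
auxiliary corpus whose representation is concatenated to each model's
own (static/frozen or fine-tuned), and three combiners over the models'
predictions (majority vote, grid-searched weighted vote, and
logistic-regression stacking). All networks run on a small NumPy
reverse-mode autodiff core — no deep-learning framework is required —
and a synthetic-corpus generator makes every stage testable offline.

## Package layout

| module | contents |
| --- | --- |
| `doctriage.corpus_io` | JSONL corpora: read/write/split (round-half-up dev size) |
| `doctriage.preprocess` | sentence splitting, tokenization (dashes become tokens), lowercasing |
| `doctriage.features` | vocabularies, word/POS/NER(BIO) embedding tables, featurization |
| `doctriage.nn` | autodiff core, layers, the five architectures, auxiliary module, optimizers, training loop, checkpoints |
| `doctriage.ensemble` | majority vote, exhaustive simplex-grid weighted vote, logistic stacking |
| `doctriage.evaluation` | confusion matrix, precision/recall/F1, McNemar's paired test |
| `doctriage.synthetic` | planted-keyword corpus generator, synthetic tags, toy vector files |
| `doctriage.cli` | `doctriage` command-line pipeline |

## CLI pipeline

```bash
doctriage simulate --out-dir run/ --seed 1 --n-docs 500 --aux-n-docs 2000
doctriage preprocess --in run/target.jsonl --out run/prep.jsonl
doctriage preprocess --in run/auxiliary.jsonl --out run/aux-prep.jsonl
doctriage pretrain-ppi --in run/aux-prep.jsonl --out run/ppi.json --seed 1
doctriage train --train run/prep.jsonl --arch lstm \
    --ppi-module run/ppi.json --ppi-mode tuned --out run/model.json --seed 1
doctriage predict --model run/model.json --in run/prep.jsonl --out run/preds.tsv
doctriage ensemble --method stack --pred a.tsv --pred b.tsv \
    --dev-pred a-dev.tsv --dev-pred b-dev.tsv --dev run/dev.jsonl --out run/ens.tsv
doctriage evaluate --pred run/preds.tsv --in run/prep.jsonl --out run/report.json
```

Every command writes a `.run.json` log with its effective configuration
and seed; two runs with identical configuration and seed produce
byte-identical artifacts.

## Tests

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance suite: exact metric
arithmetic on the reference confusion matrix, exhaustive combiner
oracles, scalar forward-pass oracles for all architectures, and the
end-to-end / transfer / ensemble recovery experiments on synthetic
corpora (the slowest, a few minutes total).

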