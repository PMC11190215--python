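# audiotype

Classification of hearing-loss type from pure-tone audiometry data.

Pure-tone audiometry measures, for one ear, the softest audible level (dB HL)
of pure tones at octave frequencies — by **air conduction** (AC, 125–8000 Hz,
through the whole auditory pathway) and by **bone conduction** (BC,
250–4000 Hz, bypassing the outer and middle ear).  The relation between the
two curves determines the *type* of hearing loss, which in turn determines
treatment:

| type | air PTA₄ | bone PTA₄ | air–bone gap |
|---|---|---|---|
| normal | < 20 dB | < 20 dB | absent |
| conductive | ≥ 20 dB | < 20 dB | present |
| sensorineural | ≥ 20 dB (also at 4–8 kHz) | ≥ 20 dB (also at 4 kHz) | absent |
| mixed | ≥ 20 dB | ≥ 20 dB | present |

where PTA₄ is the pure-tone average over 0.5/1/2/4 kHz and the air–bone gap
(AC − BC) counts as *present* when it reaches 10 dB at ≥ 3 of those
frequencies or 15 dB at any single one (bounds inclusive).

The package is aimed at clinical-audiology and ML researchers who want a
complete, testable pipeline for this problem:

* **IO** — per-ear records as flat CSV, JSON-lines, or an XML dialect of
  per-point tonal records (`audiotype.core`);
* **QC** — five validity screens (completeness, instrument ranges,
  octave-step plausibility, air–bone consistency) (`audiotype.qc`);
* **rule engine** — the deterministic four-class diagnosis above, with an
  explicit `indeterminate` label for combinations no rule row matches
  (`audiotype.rules`);
* **synthetic data** — a seeded generator of QC-valid, rule-labelled
  audiograms at configurable class proportions (clinical datasets are
  confidential) (`audiotype.synth`);
* **preprocessing** — 7-step × 2-channel sequence encoding, four scalers
  (z-score / min–max / robust / max-abs) fitted on training data only, and
  balanced class weights w_c = N/(K·n_c) (`audiotype.preprocessing`);
* **models** — a Bi-LSTM → dropout → LSTM → dropout → softmax sequence
  classifier written in numpy (explicit BPTT, Adam, early stopping, fully
  seeded), its LSTM-only variant, and a C4.5-style gain-ratio decision tree
  (`audiotype.models`);
* **evaluation** — stratified K-fold CV, per-class precision/recall/F1,
  pooled confusion matrices, micro-averaged one-vs-rest ROC-AUC, and
  McNemar's paired test (`audiotype.evaluation`).

## Worked example

```python
from audiotype import (Audiogram, classify, GeneratorConfig, generate_dataset,
                       apply_qc, run_cv_experiment, TreeConfig)

# diagnose one ear: elevated air, normal bone, 40-dB gaps -> conductive
a = Audiogram("p001", "left",
              ac={250: 45, 500: 50, 1000: 55, 2000: 55, 4000: 60, 8000: 65},
              bc={500: 10, 1000: 15, 2000: 15, 4000: 20})
print("diagnosis:", classify(a))

# a small synthetic study: 1,000 ears at clinical class proportions
ds = generate_dataset(GeneratorConfig(n=1000, seed=7))
print("QC kept:", len(apply_qc(ds).kept), "of", len(ds))
result = run_cv_experiment(ds, TreeConfig(), k=5, seed=7)
m, s = result.cv_report.mean, result.cv_report.sd
print(f"tree 5-fold accuracy: {100*m['accuracy']:.2f}% (+/- {100*s['accuracy']:.2f}%)")
print(f"micro-OvR AUC: {result.auc:.4f}")
print("pooled confusion (N,C,M,S):")
print(result.pooled_confusion.counts)
```

prints

```
diagnosis: conductive
QC kept: 1000 of 1000
tree 5-fold accuracy: 97.10% (+/- 1.02%)
micro-OvR AUC: 0.9891
pooled confusion (N,C,M,S):
[[176   0   0   0]
 [  3  55   0   0]
 [  0   0 246  12]
 [  0   0  14 494]]
```

Every generated record passes QC and carries the rule engine's own label, so
a classifier's held-out error directly measures how well it has recovered
the diagnostic rule.  The confusion matrix rows are true classes in the
fixed order normal/conductive/mixed/sensorineural; here all residual errors
are the clinically benign mixed ↔ sensorineural confusions plus a few
conductive ears from the rarest class (4.4% of the data).

The same workflow is available from the shell:

```sh
audiotype simulate --n 10000 --seed 7 --out data.csv
audiotype validate --in data.csv --report qc.json
audiotype evaluate --data data.csv --model bilstm --k 10 --seed 7 --out report.json
```

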