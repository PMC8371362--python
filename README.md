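# eegpf

Personality-first, channel-attention BiLSTM pipeline for cross-subject
EEG emotion recognition — with a synthetic data generator so the whole
pipeline is exercisable end-to-end without any restricted dataset.

The method has two levels:

* **macro ("personality first", PF)** — subjects are clustered by their
  Big-Five (OCEAN) personality vectors with plain Lloyd k-means; one
  emotion classifier is trained per cluster, and an unseen subject is
  routed to the nearest personality centroid.
* **micro** — per trial, the multi-channel EEG is common-average
  referenced, band filtered (1–16 Hz), cut into one-second windows, and
  summarised as five-band differential-entropy (DE) features
  (δ 1–4, θ 4–8, low-α 8–11, high-α 11–14, β 14–16 Hz). Nine adjacent
  windows form one `(bands × channels × segments)` sample. The
  classifier embeds each channel separately, re-weights channels with a
  learned column-stochastic attention matrix, encodes the channel
  sequence and then the segment sequence with two BiLSTMs, and ends in
  a linear-softmax head. Binary valence/arousal labels come from a
  median split of the ratings, with the threshold always computed on
  training data only.

The network is pure NumPy (double precision) on a ~300-line
reverse-mode autodiff tape (`eegpf/_autodiff.py`); gradients are
verified against finite differences in the test suite.

## Layout

| module | contents |
| --- | --- |
| `eegpf.synthetic` | personality-clustered synthetic EEG generator + text I/O |
| `eegpf.preprocessing` | CAR + Butterworth filtering, windowing, DE features, median-split labels |
| `eegpf.clustering` | Lloyd k-means on OCEAN vectors, elbow curve, held-out routing |
| `eegpf.network` | channel embedding, channel attention, spatial/temporal BiLSTMs, classifier |
| `eegpf.evaluation` | cross-entropy training loop, k-fold and leave-one-subject-out (LOSO) protocols, PF scheme, SVM / gradient-boosting baselines, attention report |
| `eegpf.experiments` | frozen experiment designs shared by the test suite and the acceptance script |
| `eegpf.cli` | `eegpf simulate | cluster | run` |

## CLI

```bash
# write a synthetic dataset (CSV per trial + personalities.csv + ratings.csv)
eegpf simulate --out data/demo --seed 1

# elbow curve + cluster assignments
eegpf cluster --data data/demo --out results/clu --n-clusters 5

# the full methods x PF grid under one protocol
eegpf run --data data/demo --out results/run --protocol loso --seed 1
```

`eegpf run` writes a results table shaped like the published comparison
(rows valence/arousal; columns SVM / gradient boosting / network
without attention / full network, each without and with PF), plus
per-fold JSON-lines logs and a run manifest with every seed. A YAML
config file (`--config`) can override generator, preprocessing, model
and training settings; `--dry-run` prints the resolved config.

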