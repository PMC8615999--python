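# kfcs

Detection of emergency-braking vs. normal-driving brain states from
multichannel EEG epochs, from a functional-network perspective:

1. **preprocess** — zero-phase 0.5–45 Hz band-pass; pluggable artifact-cleaner hook.
2. **connectivity** — pairwise cross-sample entropy (Richman–Moorman, Chebyshev
   distance) assembled into a weighted adjacency matrix per 1-s epoch.
3. **netgraph** — threshold binarization (`Tri`), z-score-based thresholds,
   BFS shortest paths, diameter.
4. **kprop** — K-order propagation number node importance: per-K neighbourhood
   counts, structure entropies, entropy-derived weights, per-node score `Q`.
5. **pipeline_select** — RBF-SVM classification with stratified k-fold CV,
   threshold sweep, general optimal threshold value (GOTV) pooling,
   montage-KNN channel grouping and greedy LOOCV core-channel selection.
6. **synthgen** — synthetic multichannel epochs with class-dependent hub
   coupling, so the whole pipeline is testable without real EEG.
7. **io_epochs** — delimited-text recordings/events/montages, epoch
   extraction, a packaged 64-channel 10-10 montage. EDF input works when the
   optional `pyedflib` is installed.

## CLI

```sh
# generate a synthetic subject (recording + events TSV)
kfcs synth --out data/ --n-channels 16 --fs 125 --epochs-per-class 20 --hubs 1,5,9 --seed 1

# per-node importance Q for a 0-1 graph (adjacency TSV or edge list)
kfcs kprop graph.tsv --ordering channel

# threshold sweep for one subject
kfcs sweep --recording data/recording.tsv --events data/recording_events.tsv \
    --fs 125 --grid-size 20 --folds 10

# full pipeline over a cohort described in a TOML config
kfcs run --config config.toml --out results/
```

Example `config.toml`:

```toml
[data]
fs = 125.0
duration = 1.0
subjects = [
  { id = "S01", recording = "data/S01.tsv", events = "data/S01_events.tsv" },
]
# montage = "montage.tsv"        # optional "label x y" file

[pipeline]
m = 2                            # embedding dimension
r_coeff = 0.2                    # tolerance = r_coeff x pooled epoch SD
grid_size = 50
folds = 10
seed = 0
edge_rule = "ge"                 # or "le" (low entropy = edge)
knn_k = 3
band = [0.5, 45.0]
normalize = true
```

## Notes

- Edge rule: the default `ge` makes higher thresholds give sparser networks;
  `le` is available for the "low entropy = strong coupling = edge" reading.
- Zero-match cross-sample entropy entries are capped at `-ln(1/(N-m)^2)` by
  default (`undefined="strict"` raises instead) — needed for short 1-s epochs.
- Everything is deterministic given the configured seeds.
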