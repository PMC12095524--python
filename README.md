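# erkdyn

Tools for relating **single-cell ERK signaling dynamics** to **endpoint
target-gene state**. Live-cell FRET biosensors report each cell's ERK
activity history at minute resolution; multiplexed immunofluorescence
measures the same cell's downstream ERK-target proteins (Fra-1, Egr-1,
c-Fos, c-Myc, c-Jun, pERK, pRb, …) once, at fixation. `erkdyn` implements
the full analysis chain that connects the two:

- **Calibration** of raw donor/acceptor FRET intensities into quantitative
  ERK activity, `x = (f_A − K_AU)/(K_AP − f_A)`, anchored by Phos-tag
  measurements of the phosphorylated reporter fraction, plus log-space
  median scaling that removes replicate batch effects from stain panels.
- **Featurization** of each activity trace into nine dynamic features
  (mean, max, pulse durations/heights, derivative, inter-pulse interval,
  frequency) via prominence-based pulse detection.
- **Forward models** predicting endpoint stains from activity histories:
  per-timepoint linear regression, featurized regression, and a small 1-D
  convolutional network with integrated-gradients attribution of which
  timepoints matter.
- **Reverse models** inferring dynamic features from stain panels:
  cross-validated single and multiple regression, incremental predictors,
  condition averages, condition exclusion.
- **History classification**: k-means prototypes of signaling histories
  (k = 5), an r ≥ 0.7 membership filter, a 500-round boosted tree ensemble
  predicting the prototype from stains, and spatial aggregation over 50-µm
  hexagonal regions and whole images.
- **A delay-ODE simulator** of ERK-driven gene expression (TF
  phosphorylation → delayed transcription with negative feedback → delayed
  translation → ERK-dependent protein phosphorylation) used both to survey
  what hypothetical genes *could* encode about dynamics and to generate
  realistic synthetic stain panels.
- **Replicate-aware statistics** (a variance-corrected t-test composing
  cell-level and experiment-level error, Benjamini–Hochberg control) and
  proximity ordering of cells for spatial heatmaps.
- **A synthetic-data module** generating full plates — dose-responsive,
  pulsatile, inhibitor-interrupted traces; spatially clustered activity
  bursts; ODE-derived stains with noise and batch factors — with known
  ground truth, so every inference step can be validated end to end.

The intended users are quantitative cell biologists analyzing paired
live-cell/fixed-cell experiments, and modelers studying what endpoint
snapshots can reveal about signaling history.

## Worked example

```python
import numpy as np
from erkdyn import (SimConfig, default_layout, generate_dataset,
                    featurize_table, fit_mlr, cluster_prototypes,
                    filter_members, fit_history_classifier)

ds = generate_dataset(default_layout(n_cells_per_well=30, replicates=3),
                      SimConfig(), seed=11)
feats = featurize_table(ds.traces, ds.t_min)

# reverse inference: how well does the 8-stain panel encode mean activity?
res = fit_mlr(ds.stains, feats["mean"].to_numpy(), "mean")
print(f"MLR R^2 for mean activity: {res.r2:.3f}")

# history classes from stains
proto = cluster_prototypes(ds.traces, k=5, seed=0)
kept = filter_members(proto, r_min=0.7)
hc = fit_history_classifier(ds.stains[kept], proto.labels[kept],
                            n_rounds=200, folds=5, seed=0)
print(f"held-out class accuracy: {hc.accuracy:.3f} (chance 0.200)")
```

Output:

```
MLR R^2 for mean activity: 0.604
held-out class accuracy: 0.948 (chance 0.200)
```

The first number says the stain panel explains about 60% of the
single-cell variance in time-averaged ERK activity; the second says
signaling-history classes are recoverable from a fixed-cell snapshot far
above the 20% five-class chance level on this synthetic plate.

An end-to-end run (simulate → calibrate → featurize → forward/reverse
models → classify → statistics) is one command:

```bash
erkdyn run --seed 1 --outdir out/
```

which writes `traces.csv`, `stains.csv`, `features.csv`,
`forward_metrics.csv`, `reverse_metrics.csv`, `classifier_report.json`,
`overlay.csv`, `stats.csv` and a summary `report.json`. Individual stages
are available as subcommands (`simulate`, `calibrate`, `featurize`,
`fit-forward`, `fit-reverse`, `classify`, `simetg`, `stats`,
`spatial-order`); see `erkdyn --help`.

## Documentation

`docs/methods.md` describes the models, parameter defaults, numerical
choices, and the limits of what the synthetic-data validation shows.
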