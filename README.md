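# norcircuit

Event-locked functional-connectivity analysis of the olfactory bulb →
entorhinal cortex → dorsal hippocampus (OB–EC–dHPC) circuit during the
novel object recognition (NOR) task, for labs recording multichannel
LFP alongside animal tracking. The package scores NOR behavior from
tracking, extracts epochs locked to novel-object exploration, and
quantifies inter-regional coupling by Welch magnitude-squared
coherence and normalized time-lagged cross-correlation, with a
statistics layer for group contrasts and brain–behavior correlations.
A synthetic-cohort generator with analytic ground truth makes every
stage verifiable by parameter recovery.

## The measures

- **Discrimination index.** With exploration defined as the nose
  staying within 2.5 cm of an object,
  `DI = (t_novel − t_familiar) / (t_novel + t_familiar)`;
  positive DI indicates intact recognition memory.
- **Coherence.** For channels x, y the Welch magnitude-squared
  coherence `C_xy(f) = |P_xy(f)|² / (P_xx(f) P_yy(f)) ∈ [0, 1]`,
  averaged over theta (4–12 Hz) and gamma (30–80 Hz) bands, estimated
  from 1 s Hann segments (50 % overlap) pooled across the 3 s epochs
  (2 s before to 1 s after each novel-object bout onset).
- **Synchrony and lead–lag.** The normalized cross-correlogram
  `r_xy(l) = Σ_t x(t) y(t+l) / √(Σx² Σy²)` of band-passed epochs; the
  peak coefficient `r_max` and its signed lag are averaged per animal.
  Positive lag means the first-named region leads (direction of
  information influx, e.g. OB→EC).
- **Statistics.** Lilliefors-corrected KS normality screening,
  unpaired Student's t contrasts, one-sample t of lags against 0, and
  Pearson DI-vs-connectivity correlations with a one-pass Grubbs
  outlier screen on studentized residuals (α = 0.05 throughout).

## Worked example

```sh
norcircuit simulate --out demo --seed 7 --n-per-group 6
norcircuit connectivity --data demo --out demo/report
```

which logs, for a default synthetic cohort (control coupling gains vs
an impaired group at half gain and weak novelty preference):

```
wrote cohort of 12 animals to demo (seed=7)
wrote cohort + stats tables to demo/report
```

`demo/report/cohort.tsv` then holds one row per animal; e.g. the
group means of the key columns from that run:

| group  | di    | pct_novel | coh_EC-dHPC_theta | lag_OB-EC_gamma (ms) |
|--------|-------|-----------|-------------------|----------------------|
| saline | 0.591 | 79.6      | 0.704             | 20.0                 |
| abeta  | 0.105 | 55.3      | 0.366             | 20.0                 |

i.e. the impaired group explores the novel object at chance (DI ≈ 0,
pct ≈ 50 %), its theta coherence is roughly halved, while the injected
20 ms OB→EC conduction delay is recovered exactly in both groups.
`demo/report/stats.tsv` lists every group contrast, lag-vs-zero test
and DI correlation with p-values and outlier notes.

The same steps run from Python via `norcircuit.generate_cohort`,
`norcircuit.run_pipeline` and friends; `norcircuit all --config
run.yaml` drives a full run from a config file.

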