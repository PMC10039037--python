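# actisleep

Actigraphy — estimating sleep from a wrist-worn accelerometer — underlies
four decades of sleep research, but the algorithms in circulation range from
1980s linear-regression scorers operating on proprietary "activity counts"
to modern heuristics and machine-learning models operating on raw
acceleration. `actisleep` is a toolkit for running these algorithms side by
side against polysomnography (PSG) ground truth and validating the sleep
endpoints they produce. It is aimed at sleep researchers and digital-health
engineers who need a transparent, reproducible harness rather than a black
box.

The toolkit covers the full chain:

* **Counts** — raw tri-axial acceleration (g) is block-averaged to 40 Hz,
  resampled to 30 Hz, band-pass filtered (0.25–2.5 Hz), rectified, clipped
  at 2.13 g, dead-banded below 0.068 g, quantized at 8-bit resolution and
  accumulated into 30-s epochs, following the published description of the
  legacy ActiGraph counts chain.
* **Classifiers** — Cole–Kripke, Oakley, Sadeh, Sazonov (count-based, with
  their literature coefficients in an auditable preset file), the van Hees
  z-angle posture heuristic, a trainable random-forest harness on raw
  acceleration features, and all-sleep / all-wake reference baselines.
* **Webster rescoring** — the classic post-hoc rules converting sleep
  epochs near long wake runs to wake.
* **Validation** — per-subject confusion statistics with sleep as the
  positive class (sensitivity TP/(TP+FN), specificity TN/(TN+FP), precision
  TP/(TP+FP), F1 the harmonic mean of precision and sensitivity), sleep
  endpoints WASO / TST / SE, cohort "mean (SD)" aggregation, Bland–Altman
  agreement (ME, RMSE, Pearson r, limits of agreement ME ± 1.96·SD of the
  differences), and a sensitivity ≥ 75% / specificity ≥ 45% selection rule.
* **Synthetic cohorts** — a seeded generator producing paired hypnograms
  and raw acceleration with alternating sleep/wake bouts, wake movement and
  posture shifts, and configurable disturbed-sleep movement bursts, so the
  entire pipeline is testable without clinical data.

## Worked example

Run the pipeline on a small synthetic cohort (3 subjects, 2-h nights):

```bash
actisleep run --seed 3 --out out_demo
cat out_demo/table1.csv
```

```
algorithm,selected,accuracy,sensitivity,specificity,precision,f1
all_sleep,false,"56.8 (6.0)","100.0 (0.0)","0.0 (0.0)","56.8 (6.0)","72.3 (5.0)"
all_wake,false,"43.2 (6.0)","0.0 (0.0)","100.0 (0.0)","undefined","0.0 (0.0)"
cole_kripke,false,"61.0 (1.0)","30.6 (7.1)","100.0 (0.0)","100.0 (0.0)","46.3 (8.6)"
...
vanhees,true,"89.2 (4.8)","81.3 (7.5)","99.7 (0.4)","99.7 (0.5)","89.4 (4.6)"
```

(The demo above used a run config with `synthetic: {n_subjects: 3,
night_duration_min: 120}`; pass it via `--config`.) Each cell is the
cohort mean over subjects with its standard deviation in brackets. The
reference rows are identities: scoring everything sleep gives 100%
sensitivity and 0% specificity; scoring everything wake gives 100%
specificity and F1 = 0. The van Hees posture heuristic is the only
algorithm passing the 75/45 selection rule here and is flagged
`selected`. The legacy count scorers show the opposite failure mode they
exhibit clinically (low sensitivity, perfect specificity) because the
synthetic generator produces perfectly still sleep and much larger count
magnitudes than the devices these 1990s coefficients were tuned on — see
`docs/methods.md` for why, and for what the synthetic results do and do
not demonstrate.

`out_demo/table2.csv` holds the Bland–Altman grid (ME, RMSE, correlation,
95% limits of agreement and their width) for WASO, TST and SE per
algorithm, and `out_demo/report.json` is the canonical machine-readable
twin of both tables plus a manifest (config hash, seed, preset version).
Re-running with the same config and seed reproduces `report.json`
byte-for-byte.

Library use mirrors the CLI:

```python
from actisleep import (SynthConfig, gen_cohort, binarize_hypnogram,
                       downsample_mean, compute_counts, combine_axes,
                       LinearWindowModel, classify_linear_window, confusion)

rec, truth = gen_cohort(SynthConfig(n_subjects=1, night_duration_min=120, seed=3))[0]
counts = compute_counts(downsample_mean(rec))
pred = classify_linear_window(combine_axes(counts),
                              LinearWindowModel.from_preset("cole_kripke"),
                              counts.grid)
print(confusion(pred, binarize_hypnogram(truth.hypnogram)))
```

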