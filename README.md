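# albicoord

Biparental foraging coordination from saltwater-immersion loggers.

Long-lived seabirds with obligate biparental care — the motivating
system is the wandering albatross *Diomedea exulans* — alternate
foraging trips: one parent forages at sea while the other incubates or
broods, and the pair never leaves the nest unattended. Whether mates
*coordinate* (match their trip durations to each other's last trip) and
whether intrinsic traits such as sex, age, boldness, and pair
familiarity shape trip duration and coordination strength, can be
answered from a single leg-mounted saltwater-immersion logger per pair.
`albicoord` implements that full chain:

1. **Segmentation** — parse either logger dialect (10-min binned wet
   seconds, classified wet at >45 s; or exact wet/dry transition times)
   into bouts; a dry spell strictly longer than the species' ~12-h
   maximum continuous flight time marks a nest shift, and a foraging
   trip runs from the first wet bout after a shift to the next shift.
2. **Partner inference** — one parent's land periods are its mate's
   trips; dual-tagged pairs quantify the accuracy of this inference and
   the nest-relief overlap.
3. **Phenology** — per-pair hatch dates detected as a change point in
   trip durations (fallback: the population mean hatch date of 15 Mar),
   with incubation fixed to start 16 Dec and brooding to end 11 Apr.
4. **Boldness** — repeated ordinal (0–5) responses to an approaching
   human reduced to one mean-centered score per bird.
5. **Features** — sqrt-transformed trip durations, the coordination
   covariate (partner's previous-trip deviation from its expanding
   in-stage mean), collapsed age categories, pooled scaling, and the
   documented row-filtering rules.
6. **Models** — per breeding stage, linear mixed models (random
   intercepts for pair and year, by-pair random slope on the partner
   deviation) over every marginality-valid fixed-effect subset, ranked
   by AICc; the ΔAICc < 2 set minus nested models is Akaike-weight
   averaged, with Nakagawa–Schielzeth R² and a coordination report.
7. **Synthetic data** — a paired-schedule generator with known trait
   effects and coordination slopes, rendered into raw logger streams in
   both dialects, so every stage above is testable against ground truth.

The core statistic: for focal trip *i* with partner's previous-trip
deviation *d* (hours), the model is

    sqrt(duration_i) = β₀ + β_coord · d̃ + x_iᵀβ + u_pair + b_pair · d̃ + v_year + ε

where d̃ is *d* standardized, and a positive β_coord (the slope of trip
duration on the partner's deviation from its own average) is
coordination. `b_pair` lets coordination strength vary between pairs.

## Worked example

```python
from albicoord import run_synthetic_pipeline
from albicoord.simulate import SimulationConfig

result = run_synthetic_pipeline(SimulationConfig(), seed=1)
print(result.accuracy)
print(result.overlap)
print(result.report[["stage", "coordination_slope", "coordination_se",
                     "marginal_r2", "conditional_r2"]])
```

prints (seed 1):

```
AccuracySummary(mean_pct=91.1989..., sd_pct=19.8980..., n_matched=24, n_unmatched=0)
OverlapSummary(mean_h=1.8636..., n_events=55, n_excluded=0, pct_of_mean_trip={'brooding': 2.4325..., 'incubation': 1.2061...})
        stage  coordination_slope  coordination_se  marginal_r2  conditional_r2
0  incubation            0.265425         0.138273     0.118307        0.384369
1    brooding                 NaN              NaN     0.022154        0.317262
```

Reading this: partner trips inferred from the tagged bird's land
periods are ~91% accurate against the second logger of dual-tagged
pairs; the mean nest-relief overlap of 1.86 h (1.2% of a mean
incubation trip, 2.4% of a brooding trip) matches the generative 1.9-h
relief lag; and the incubation analysis recovers a positive
coordination slope of 0.27 ± 0.14 sqrt-h per SD of partner deviation
(the study was generated with a true slope of 0.2). In the brooding
stage of this particular run the coordination term did not survive the
ΔAICc < 2 / nested-exclusion filter, so its slope is reported as
absent (NaN), not as zero — the reporting contract for unretained
terms.

Each stage is also available separately (`parse_binned`,
`extract_trips_and_shifts`, `infer_partner_trips`, `detect_hatch`,
`score_boldness`, `build_model_table`, `select_and_average`, ...), and a
thin CLI mirrors the pipeline: `albicoord simulate | boldness | segment
| phenology | features | fit`.

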