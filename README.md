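# passmon

In-home health-behavior indicators from interval-level occupancy sensing.

Smart-thermostat remote motion sensors report, for every 5-minute interval,
which sensors saw movement. `passmon` turns such streams into:

- **behavior labels** for every interval — sleep, disturbed sleep, sedentary,
  physical activity, away — via transparent count-and-clock rules, with
  step-outlier and noise filters;
- **daily indicators** per house — nighttime sleep (h), disturbed sleep (h),
  sedentary time (h), in-house physical activity (min), away period (h) —
  that exactly partition each 24-hour day, stratified into single-occupant
  (*individual*) vs multi-occupant (*household*) homes and compared against
  fixed national reference values;
- **validation statistics** — Spearman rank correlation between per-interval
  activation counts and step counts (pooled and per house), with a
  step-outlier threshold-sensitivity sweep (100 → 400 steps by 50);
- **synthetic data** — a seeded agent-based household simulator (floorplan
  graph, occupant schedule, sensor/step/noise models) that emits the same CSV
  dialects with ground-truth labels, so the whole pipeline is testable
  without access to proprietary sensor exports.

## Layout

| module               | role                                                    |
|----------------------|---------------------------------------------------------|
| `passmon.simulate`   | floorplans, schedules, household/cohort simulation      |
| `passmon.io`         | CSV readers/writers, record types, metadata hygiene     |
| `passmon.classify`   | interval labeling rules, noise & step-outlier filters   |
| `passmon.indicators` | daily indicator totals, stratified summaries, reports   |
| `passmon.validate`   | Spearman validation and threshold sweep                 |
| `passmon.cli`        | `passmon` command-line pipeline with run manifests      |

## CLI

Every stage is independently runnable; `run-all` chains them:

```sh
passmon simulate   --out out/sim --seed 1 --n-houses 8 --n-days 7
passmon classify   --intervals out/sim/intervals.csv --steps out/sim/steps.csv \
                   --out out/classify
passmon indicators --labeled out/classify/labeled.csv \
                   --metadata out/sim/metadata.csv --out out/indicators
passmon validate   --intervals out/sim/intervals.csv --steps out/sim/steps.csv \
                   --out out/validate
passmon run-all    --out out --seed 1
```

Classification knobs (`--pa-min-sensors`, `--three-way`,
`--outlier-threshold`, `--no-noise-filter`, or a YAML/JSON `--config`)
mirror `ClassifierConfig`. The literature defines the physical-activity cut
both as ≥2 and as ≥3 activated sensors; the default is 2 and `--three-way`
selects the ≥3 variant (1–2 sensors then count as sedentary). Each stage
writes a `manifest.json` capturing config, input digests, seed, versions,
and exclusion tallies, so reruns are reproducible and auditable.

### Rules at a glance

Within the waking window (default 08:00–22:00): count ≥ threshold →
physical activity; 1 ≤ count < threshold → sedentary; count = 0 → away.
In the complementary sleep window: count = 0 → sleep; any movement →
disturbed sleep, with consecutive disturbed intervals counting as a single
interruption. Intervals with more than 100 steps (strictly; the boundary is
retained) are excluded as outliers, e.g. treadmill use. An isolated
single-sensor activation with silent neighbors and zero steps is excluded
as noise.

## CSV dialects

- intervals: `house_id, timestamp, sensor_1..sensor_K` (0/1 flags; ISO-8601
  naive timestamps on the 5-minute grid)
- steps: `house_id, timestamp, steps`
- metadata: `house_id, style, floor_area, num_floors, num_occupants`
- labeled output: `house_id, timestamp, activation_count, steps, label,
  exclusion_reason`

Gaps in a day are materialized as missing intervals and excluded, never
imputed. This interval dialect is a declared stand-in for proprietary
thermostat exports, whose exact schema is not public.
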