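# mesocam

Analysis toolkit for camera-trap surveys of mid-sized carnivore communities.

Camera traps yield timestamped photo records at baited stations; ecologists
use them to ask how sympatric species partition space and time.  `mesocam`
implements the complete quantitative pipeline for such a study:

* **Independent detections & effort** — collapse photo bursts into
  independent events (photos of the same species at the same station > 0.5 h
  apart), compute camera-day effort pro-rated over calendar months, and
  monthly relative activity indices (RAI, detections per 1,000 camera-days).
* **Solar-anchored diel activity** — per-station sunrise/sunset and
  astronomical-twilight times from standard solar geometry; clock times
  transformed to *sun time* (sunrise ≡ 06:00, sunset ≡ 18:00) to remove
  seasonal photoperiod drift; detections classified as crepuscular, diurnal,
  or nocturnal.
* **Circular kernel densities & overlap** — von Mises kernel density
  estimates of diel activity with the plug-in concentration
  κ_h = [3 n κ̂² I₂(2κ̂) / (4√π I₁(κ̂)²)]^(2/5) / adjust, and the coefficient
  of overlap Δ̂ = ∫ min(f̂, ĝ) (estimators Δ̂1 and Δ̂4) with smoothed-bootstrap
  confidence intervals.
* **Diel time budgets** — Manly selection ratios w_i = o_i / π̂_i of period
  use versus availability, a χ² random-use test, and a directional
  multinomial randomization test (10,000 replicates, add-one correction).
* **Two-species occupancy co-occurrence** — site × 15-day-occasion joint
  detection histories; maximum-likelihood fits of the two-species occupancy
  model with a species interaction factor (SIF) γ
  (P(both) = γ ψ_A ψ_B; γ < 1 avoidance, γ = 1 independence, γ > 1
  aggregation), detection covariates for scent-lure age and camera trigger
  speed, and AIC ranking of the 16-model candidate set.
* **Synthetic surveys** — a generator with known occupancy, co-occurrence,
  diel, and seasonal structure, so every stage can be validated against
  ground truth without field data.

## Worked example

Simulate a small survey (60 stations, four species, two focal pairs with
true γ = 0.6 and γ = 1.0), filter it to independent events, and analyse it:

```sh
$ mesocam simulate --out demo --seed 42
wrote 526 photos, 60 deployments to demo
$ mesocam events --photos demo/photos.csv --out demo/events.csv
526 photos (0 rejected) -> 423 events
$ mesocam effort --deployments demo/deployments.csv --out demo/effort.csv
total 2082.5 camera-days (warm 2061.8, winter 20.7)
```

```python
import numpy as np
from mesocam import read_photo_records, read_deployments, independent_events
from mesocam.solar import sun_times_for_events, period_availability, PERIODS
from mesocam.activity import bootstrap_overlap_ci, hours_to_radians
from mesocam.timebudget import analyse_time_budget

photos, _ = read_photo_records("demo/photos.csv")
deps, _ = read_deployments("demo/deployments.csv")
events = sun_times_for_events(independent_events(photos), deps)
warm = events[events["season"] == "warm"]

civet = hours_to_radians(warm.loc[warm.species == "civet", "sun_hour"])
marten = hours_to_radians(warm.loc[warm.species == "marten", "sun_hour"])
est = bootstrap_overlap_ci(civet, marten, n_boot=10_000, seed=42)
print(f"overlap = {est.delta:.2f} ({est.estimator}), "
      f"95% CI ({est.ci_low:.2f}, {est.ci_high:.2f})")
# overlap = 0.24 (Dhat1), 95% CI (0.19, 0.37)

avail = period_availability(deps, months=set(range(3, 12)))
print(np.round(avail.as_array(), 3))   # [0.124 0.536 0.34]
counts = [int((warm.loc[warm.species == "civet", "period"] == p).sum())
          for p in PERIODS]
res = analyse_time_budget(counts, avail, seed=42)
print(counts, np.round(res.ratios, 2), f"chi2={res.chi2:.2f}")
# [19, 20, 55] [1.63 0.4  1.72] chi2=39.53
```

The nocturnal civet and diurnal marten overlap little (Δ̂ = 0.24), and the
civet's selection ratios flag crepuscular (w = 1.63) and nocturnal (1.72)
selection with diurnal avoidance (0.40) — the pattern its simulated diel
archetype encodes.  Availability here, (0.12, 0.54, 0.34), is what a
mid-latitude warm season offers: ~3 h of twilight, ~13 h of daylight.

Co-occurrence for the avoiding pair:

```python
from mesocam import build_detection_histories
from mesocam.cooccur import fit_model_set
hist = build_detection_histories(independent_events(photos), deps, "civet", "badger")
table, sif = fit_model_set(hist, seed=42)
print(sif.interpretation, round(sif.gamma_hat, 2))
```

At 60 stations the true avoidance (γ = 0.6) is only weakly identifiable and
the top-model set typically mixes hypotheses ("unclear") — exactly why the
estimator-calibration checks below use 500-site surveys, where γ̂ lands
within sampling error of the truth.

## Layout

```
src/mesocam/
  io_camtrap.py    photo/deployment IO, event filter, effort, RAI
  solar.py         solar geometry, diel periods, sun time, availability
  activity.py      circular KDE, overlap coefficient, bootstrap CIs
  timebudget.py    selection ratios, chi-square and randomization tests
  cooccur.py       detection histories, two-species occupancy, SIF, AIC
  synth.py         synthetic survey generator (ground truth included)
  datasets.py      published summary tables used as consistency-check inputs
  pipeline_cli.py  end-to-end orchestration + the `mesocam` CLI
docs/methods.md    modelling assumptions, parameter choices, limitations
```
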