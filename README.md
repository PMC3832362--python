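# sicklekit

Quantitative analysis of red-blood-cell sickling in vitro, for
researchers evaluating anti-sickling interventions (for example globin
gene therapies) on cultured red blood cells (cRBCs).  The package
implements the two complementary assays used to score sickling after
chemical deoxygenation, together with a ground-truthed synthetic
cell-image and time-lapse generator so the whole analysis runs without
patient material:

* **Imaging cytometry**: per-event morphometry on multi-channel
  single-cell crops, a sequential gating chain that isolates mature
  cRBCs (non-nucleated → non-debris → mid-focus → marker-positive), and
  a morphology classifier built from Fisher's-discriminant-ranked
  metrics.
* **Video microscopy**: per-cell detection of the rapid disc→crescent
  transition in 30-minute, 4 frames-per-second recordings sampled at
  256-frame intervals, with survival-style kinetic endpoints and group
  tests.

## The statistics at the core

For a metric *x* measured on two cell populations, the separation is
Fisher's discriminant of means

    Fd = |μ₁ − μ₂| / (σ₁ + σ₂).

The classifier is the **Sickle Score** *S₂ / SR*, where *S₂*
("Symmetry 2") is the 2-fold harmonic content |c₂|/|c₀| of the boundary
radius function r(θ), and *SR* ("Shape Ratio") is minimum thickness over
length, Tmin/L, from the brightfield mask.  Elongated sickled cells have
high *S₂* and low *SR*, so the score rises steeply with sickling.  The
positivity gate is placed at the 90th percentile of a non-sickling
control population (~10% spillover), and the endpoint is the percent of
gated mature cRBCs scoring positive.

Sickling kinetics follow a delay + exponential model: a susceptible
fraction p_s of cells sickles at times t₀ + Exp(λ); the observed sickled
fraction over a window T is p_s·(1 − e^(−λ(T−t₀))).  Detected event
times are quantized to the frame-sampling grid (64 s at 4 fps / 256
frames).  Groups are compared with the Gehan-Breslow-Wilcoxon weighted
log-rank test (censoring at T honoured) and the rank-sum test on event
times.

## Worked example

Simulate one control-like and one treated-like video trial of 200 cells
and score them:

```sh
$ sicklekit kinetics --n-cells 200 --seed 1 --out control
pct sickled 54.0%, median 8.533333333333333 min, delay 5.333333333333333 min, max rate 1.25e-03 /s

$ sicklekit kinetics --n-cells 200 --seed 1 --susceptible 0.455 --hazard 0.131 --out treated
pct sickled 44.5%, median 9.6 min, delay 5.333333333333333 min, max rate 1.09e-03 /s
```

Reading the numbers: 54.0% of control cells showed a detected
morphological transition within the 30-minute window versus 44.5% under
the treated kinetics; the median time to sickling lengthens from 8.53 to
9.6 min (both multiples of the 64-s sampling interval); the first event
is detected at the first sampled frame after the 4.3-min polymerization
delay; and the peak sickling rate (cells sickling per total cells per
second, per sampled interval) drops accordingly.  Per-cell timelines and
a JSON summary are written next to each output prefix.

The same from Python, for the cytometry arm:

```python
from sicklekit.simulate import PopulationConfig, sample_population
from sicklekit.morphometry import featurize_events
from sicklekit.gating import calibrate_gates, apply_gates
from sicklekit.scoring import sickle_score, calibrate_sickle_gate, percent_sickled

events, truth = sample_population(PopulationConfig(n_events=4000, seed=11))
feats = featurize_events(events)
gates = calibrate_gates(feats)
mature = feats.loc[apply_gates(feats, gates).final_index]
scores = sickle_score(mature).dropna()
```

`sicklekit run` executes the full pipeline (simulate → featurize → gate
→ score → kinetics → report) and writes `report.json` plus all
intermediate tables; identical seeds reproduce the report bit-exactly.

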