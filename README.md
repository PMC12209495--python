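# schedetect

Can you tell what schedule of stimulus delivery an animal is under just by
watching where it moves? `schedetect` is a pipeline for detecting the
components of **time-based (noncontingent) water-delivery schedules** in rats
from spatiotemporal behavior alone — no lever presses, no key pecks. It is
aimed at behavior analysts and computational ethologists who want to move
beyond the single-discrete-response paradigm and treat trajectories as the
primary measurement.

The pipeline covers four stages, each usable on its own:

* **simulate** — a synthetic 92 × 92 cm open-field chamber with a water
  dispenser at each wall midpoint, generating 20-min sessions (x, y at 5 Hz,
  head-entry and delivery logs) under fixed-time (FT 30 s) or variable-time
  (VT 30 s, intervals {3, 7, 13, 21, 31, 47, 88} s) schedules crossed with
  fixed or variable delivery location, plus no-schedule extinction sessions;
* **featurize** — eight measures per session: head entries at each of the
  four dispensers, traveled distance (cm), SD of frame-by-frame speed, the
  Shannon entropy of the time-in-zone distribution over a 10 × 10 grid,

  H(X, P) = −Σᵢ P(xᵢ) ln P(xᵢ),

  and the Kullback–Leibler divergence of the current session's occupancy P
  from the preceding session's Q,

  D(P ‖ Q) = Σᵢ P(xᵢ) ln [P(xᵢ)/Q(xᵢ)];

* **detect** — three binary tasks (schedule vs. none, fixed vs. variable
  space, FT vs. VT) under 12-fold leave-one-subject-out cross-validation,
  with minority oversampling, z-scoring, and four classifiers: logistic
  regression, RBF support-vector classifier, 100-tree random forest, and a
  dense (5, 3)-hidden-layer neural network;
* **stats** — signal-detection outcomes per held-out rat, d′ = z(H) − z(F)
  and c = −(z(H) + z(F))/2 with the 1/(2n) extreme-proportion correction
  (2AFC form √2·z(p) when the test set has a single class), exact one-sample
  Wilcoxon signed-rank tests per model (Bonferroni threshold .05/12), and a
  tie-corrected Friedman test per task.

See `docs/methods.md` for the model, parameter defaults, and design choices.

## Worked example

```python
from schedetect import (ChamberGeometry, ScheduleSpec, TimeType, SpaceType,
                        simulate_session, occupancy_grid, location_entropy,
                        head_entry_counts, dprime_yesno)

geom = ChamberGeometry()
spec = ScheduleSpec(TimeType.VT, SpaceType.FIXED, fixed_dispenser=0)
session = simulate_session(spec, geom, seed=42)

grid = occupancy_grid(session, geom)
print("location entropy (nats):", round(location_entropy(grid), 3))
print("head entries per dispenser:", head_entry_counts(session))

d, c = dprime_yesno(sensitivity=0.84, specificity=1.00, n_signal=25, n_noise=5)
print(f"d' = {d:.2f}, c = {c:.2f}")
```

prints

```
location entropy (nats): 2.073
head entries per dispenser: (580, 0, 0, 1)
d' = 2.28, c = 0.14
```

A fixed-space VT session concentrates its time near the one active dispenser:
entropy 2.07 nats is far below the ln 100 ≈ 4.61 ceiling of a uniformly
wandering animal, and 580 of 581 head entries land at dispenser 0. The last
line scores a held-out rat whose classifier hit 84% of schedule sessions with
no false alarms across 5 extinction sessions: d′ = 2.28 (strong detection),
c = 0.14 (nearly unbiased).

The whole experiment — 12 subjects × (30 schedule + 10 extinction) sessions,
4 algorithms × 3 tasks × 12 folds — runs from one command:

```sh
schedetect run-all --seed 1 --out runs/demo
```

which writes the session files, the feature table, per-fold predictions, the
metric grid, and the Wilcoxon/Friedman results under `runs/demo/`.

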