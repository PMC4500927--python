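# bcisim

A closed-loop simulator of an intracortical brain–computer interface (BCI)
controlling three-dimensional arm reaches, for researchers comparing how
useful different *kinds* of movement-tuned neurons — position, velocity, and
goal — are as inputs to a neural prosthesis, and how performance scales with
the number of recorded cells.

One simulated reach closes the loop at 30 ms steps:

* a **multiple-submovement controller** builds the commanded trajectory as a
  sum of minimum-jerk submovements
  `pos_i(t) = d_i (6τ⁵ − 15τ⁴ + 10τ³)`, launching a corrective submovement
  (amplitude `0.9 × predicted miss`) whenever the decoded position is
  predicted to miss the target by more than 1 cm;
* a **neural encoder** turns the commanded state into noisy firing rates:
  gain-modulated cosine tuning `f = f_base (1 + f_depth · p̂ · x)` for
  position/velocity/linear-goal cells, radial Gaussian tuning
  `f = f_min + f_amp exp(−‖goal − q_pos‖²/2q_std²)` for spatial goal cells, a
  common saturation `g(x) = 150/(1 + 9.305 e^{−0.01602(x+190)})^{6.015}`
  squashing rates into (0, 150) Hz, and Poisson or truncated-normal spike
  counts per 30 ms bin;
* an **Extended Kalman Filter** decodes the rates over the 12-D state
  `[pos, vel, acc, goal]`, using a least-squares linear trajectory model and
  the exact encoding model as its (ideal) nonlinear measurement model, with
  the goal initialized uninformatively (variance 1000 per axis).

Performance is the **Minimum Attainable Target Radius (MATR)** — the smallest
target radius within which the decoded position dwells continuously for 1 s —
averaged over targets (MATR-T) and neuron parameter sets (MATR-TP, with 95%
confidence intervals).

See `docs/methods.md` for the full model description, parameter defaults and
limitations.

## Worked example

Generate the reference 33-target reach set and run one closed-loop reach
with 15 mixed position/velocity neurons plus 10 Gaussian goal neurons:

```
$ bcisim targets --n 33 --seed 1
33 targets: distance-to-start mean 49.6 cm, min 37.8 cm, max 59.7 cm

$ bcisim simulate --seed 3 --n-m1 15 --n-goal 10
initial distance 56.71 cm, MATR 5.05 cm, submovements 18
```

The hand starts 56.7 cm from the target; over the 3 s reach the controller
launches 18 corrective submovements, and the decoded position settles well
enough to dwell for 1 s inside a 5.05 cm sphere around the target — that
sphere radius is the MATR for this reach. More neurons shrink it: the same
library call with 50 mixed neurons yields MATR-TP near 2 cm, the asymptote
reached at roughly 30 neurons.

The two full analyses are exposed both as library functions
(`bcisim.run_analysis1`, `bcisim.run_analysis2`) and as CLI commands writing
tidy CSV tables plus JSON config snapshots:

```sh
bcisim analysis1 --seed 0 --n-paramsets 10 --out results/   # neuron-count grid
bcisim analysis2 --seed 0 --n-paramsets 10 --out results/   # per-type comparison
bcisim report results/analysis2.csv                         # MATR-TP summary
```

Typical findings at full scale: velocity-only ensembles attain the smallest
targets; goal ensembles (except very narrow 10 cm Gaussian tuning) beat
position ensembles given enough movement time; the closed-loop controller
beats a constant target-pinned command for 20–40 cm Gaussian and linear goal
tuning; and per-target MATR grows with distance from the origin for position
and linear-goal cells (whose rates saturate at large offsets) but not for
velocity cells.

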