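# flyforage

Trial-based analysis of probabilistic-reward foraging in walking flies.
The package simulates single-fly linear-track sessions with a closed-loop
optogenetic-style trigger rule, segments continuous trajectories into
discrete reward/return trials, and analyses the resulting binary choice
sequences with reward-history logistic regression and three
reinforcement-learning models (Rescorla–Wagner, forgetting-Q, and
forgetting-Q with an independent forgetting rate), including
maximum-likelihood fitting, AIC model selection, held-out predictive F1
scoring, and generative run-length tests.

## Layout

| module                 | role |
|------------------------|------|
| `flyforage.config`     | arena geometry (50×5 mm track, 6 mm reward + 3 mm reset zones), run configuration, deterministic sub-seeding |
| `flyforage.synthgen`   | synthetic sessions: trial-level agents, the reset→reward trigger rule, scripted ground-truth itineraries, stochastic closed-loop walks |
| `flyforage.kinematics` | trajectory preprocessing (gap/jump repair, zero-phase Butterworth), stops, turns, occupancy, preference index, heading-angle entropy |
| `flyforage.trials`     | trial segmentation, ≥50-trial session filter, return statistics, run lengths, first-reward summaries |
| `flyforage.kernel`     | logistic regression of current returns on reward/choice history, per fly and population-averaged |
| `flyforage.rlmodels`   | RW / FQ / FQaF value updates, logistic choice rule, agent simulation (incl. decaying positive initial value) |
| `flyforage.fitcompare` | multistart MLE, AIC comparison, predictive F1, generative tests |
| `flyforage.cli`        | pipeline orchestration and `flyforage` command-line interface |

## CLI

Every stage takes `--config` (TOML) and `--seed`:

```sh
flyforage all --config run.toml --seed 1
flyforage simulate --config run.toml   # or: segment / kinematics / kernel /
                                       #     fit / compare / report
```

Minimal `run.toml`:

```toml
conditions = [0.05, 0.15, 0.30]
n_flies = 10
n_trials = 400
seed = 1
outdir = "flyforage_out"

[arena]
stim_probability_zone1 = 0.3
```

Outputs are plain CSV/JSON under `outdir`, plus `report.json`,
`report.txt` and a `manifest.json` with a checksum of every file —
re-running the same config reproduces all outputs bit-identically.

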