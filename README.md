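# stn-gammaburst

Analysis pipeline for movement-related gamma (40–90 Hz) activity in
subthalamic local field potentials (LFP), built for the setting of
Parkinson's disease patients performing cued forearm pronations of
three amplitudes while externalised DBS electrodes record bipolar LFP.
Because such patient recordings are not public, the package pairs every
analysis stage with a seeded synthetic session generator that emulates
the paradigm's signal structure and records ground truth, so the whole
chain is testable end to end.

The pipeline covers:

* **Kinematics** — movement onset (last upward crossing of 10% of the
  trial's peak velocity), maximal velocity and maximal amplitude from
  the rotation trace; reaction time and accuracy.
* **Preprocessing** — bipolar montage (contact pairs 01/12/23),
  zero-phase 5th-order Butterworth high-pass (1 Hz) and band-stop
  (48–52 Hz), epochs −2…+3 s around movement, data-relative artifact
  flags.
* **Spectral** — Morlet time-frequency maps (1–100 Hz, 7 cycles),
  percent change from a pre-movement baseline, 6 Hz × 200 ms Gaussian
  smoothing, bisquare robust trial averaging, band summaries
  (theta 2–8, beta 13–30, gamma 40–90 Hz; 0–0.5 s window) with
  contact → hemisphere → subject averaging.
* **Gamma bursts** — band-passed, rectified, 100 ms-smoothed envelope;
  per-electrode threshold at the 75th percentile of the whole
  recording; bursts are supra-threshold runs of at least one gamma
  cycle at the subject's gamma peak frequency; rate / amplitude (area
  over threshold) / duration per 0.5 s windows; ON-state thresholds
  re-used on matched OFF recordings. Burst *rate* is the property that
  carries movement, condition, velocity and medication effects.
* **Statistics** — Monte-Carlo permutation tests (sign-flip and label
  exchange, p = (r+1)/(n+1)), Benjamini–Hochberg FDR, ≥150-bin
  4-connected cluster filtering, single-trial power–velocity Spearman
  correlation maps with group-level sign-flip tests, and
  normality-gated (Lilliefors KS) Pearson/Spearman clinical
  correlations against the packaged per-patient UPDRS table.

## Worked example

```python
import numpy as np
from stn_gammaburst import SimConfig, generate_session
from stn_gammaburst.kinematics import extract_trials
from stn_gammaburst.pipeline import analyze_session_bursts

changes = {30.0: [], 60.0: [], 90.0: []}
peaks, overall = [], []
for seed in range(6):                     # a small simulated cohort
    rec, truth = generate_session(SimConfig(seed=seed))
    res = analyze_session_bursts(rec, extract_trials(rec))
    peaks.append(res["contra"]["peak_frequency"])
    overall.append(np.mean([res[el]["stats"].relative_change["rate"]
                            for el in res]))
    for cond in changes:
        changes[cond].append(np.mean(
            [res[el]["stats_by_condition"][cond].relative_change["rate"]
             for el in res]))

print(f"gamma peak {np.mean(peaks):.1f} Hz (cohort of 6)")
print(f"movement burst-rate change {np.mean(overall):+.0f}%")
for cond, vals in changes.items():
    print(f"  {cond:.0f} deg: {np.mean(vals):+.0f}%")
```

prints:

```
gamma peak 69.3 Hz (cohort of 6)
movement burst-rate change +19%
  30 deg: +18%
  60 deg: +15%
  90 deg: +23%
```

i.e. the detected subject-level gamma peak matches the injected 70 Hz
burst frequency and bursting becomes more frequent in the 0.5 s after
movement onset, most for the largest movements. Condition contrasts
are noisy at this scale (the medium condition dips here); per-subject
Poisson counting noise makes the condition ordering a cohort-level
claim, resolved reliably only at ~20+ subjects — see `docs/methods.md`
and the recovery tests.

The numbered drivers under `analysis/` run the full study analogue and
write tidy tables under `results/`:

```bash
python analysis/01_simulate_sessions.py --seed 0
python analysis/02_kinematics.py       --seed 0
python analysis/03_time_frequency.py   --seed 0
python analysis/04_bursts.py           --seed 0
python analysis/05_velocity_correlation.py --seed 0
python analysis/06_clinical.py         --seed 0
```

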