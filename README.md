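# neckbrace

Computational toolkit for a wearable six-revolute serial-chain neck brace
that measures head–neck range of motion, paired with surface EMG of the
neck muscles. The package covers the full measurement stack:

- **`neckbrace.chain`** — Denavit–Hartenberg kinematics of the 6R chain
  (parallel J1/J2 axes, J3/J4 perpendicular to them, distal three axes
  concurrent at a wrist point *C*), forward kinematics, closed-form /
  damped-least-squares inverse kinematics, and anatomical head-angle
  extraction (flexion–extension, lateral bending, axial rotation).
- **`neckbrace.design`** — design-phase workspace analysis from an
  eight-marker motion-capture session: trunk/head reference frames,
  workspace point clouds in the trunk (C7) frame, rotation-centre sphere
  fitting, exhaustive grid search over link parameters with reachability
  and shoulder-plane clearance checks, and joint operating ranges.
- **`neckbrace.calibration`** — per-joint polynomial maps from
  potentiometer voltage to joint angle, fitted against IK joint angles
  derived from motion capture, with optional joint refinement minimising
  reconstructed head-angle error; validation reports (max / RMS error on
  the primary angle per single-plane motion).
- **`neckbrace.signals`** — zero-phase 4th-order 6 Hz low-pass for the
  100 Hz brace angles; the six-step EMG pipeline (optional cardiac
  suppression, DC removal, 60–200 Hz band-pass, full-wave rectification,
  300-sample / 0.2 s moving-average envelope, visit-wide normalisation);
  trigger-edge synchronization of brace and EMG streams.
- **`neckbrace.analysis`** — segmentation of continuous single-plane
  trials into biphasic movement cycles (neutral → extreme → opposite
  extreme → neutral), 101-point time normalisation and averaging,
  outcome variables (completion time, peak angles, RoM, EMG peak timing
  in % cycle), and paired pre/post t statistics with 95% CIs.
- **`neckbrace.synthetic`** — a ground-truthed digital twin of a clinic
  session: raised-cosine head-angle cycles, joint trajectories via IK, a
  monotone nonlinear sensor map, marker/voltage/EMG streams with a
  shared trigger, and EMG bursts phase-locked per the rope activation
  model (e.g. right axial rotation ← left SCM + right SC + left TR).
- **`neckbrace.cli`** — command-line workflows and session I/O.

## CLI

```bash
# synthetic session (markers @200 Hz, voltages @100 Hz, EMG @1.5 kHz)
neckbrace simulate --seed 10 --out cal_session
neckbrace simulate --seed 11 --out val_session

# fit the voltage->angle calibration from the first session
neckbrace calibrate --manifest cal_session/manifest.json --out model.json

# validate against motion capture on the held-out session
neckbrace validate --manifest val_session/manifest.json \
    --model model.json --out report.csv

# filtered angles + EMG envelopes
neckbrace process --manifest val_session/manifest.json \
    --model model.json --out processed/

# workspace clouds, sphere fit, link-parameter grid search
neckbrace design-search --manifest cal_session/manifest.json \
    --out candidates.csv --span-mm 5

# pre/post cohort outcomes and paired statistics, then a text summary
neckbrace analyze --cohort cohort.json --model model.json --out analysis/
neckbrace report --in analysis/
```

Exit codes: 0 ok, 1 usage error, 2 data error. Every run logs the
config hash and seed; deterministic subcommands are byte-reproducible
from `(config, seed)`.

All protocol constants (sample rates, filter bands, the 300-sample
envelope window, segmentation hysteresis, significance level) live in a
single validated YAML config; see `neckbrace.config.Config`.

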