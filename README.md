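# emogo — emotional Go/NoGo ERP pipeline

`emogo` is a tested, reusable implementation of a dimensional ERP study of
response inhibition and disordered eating in preadolescents. Children
perform an adaptive emotional Go/NoGo task (face gender is the Go cue;
facial emotion — angry / neutral / happy — is task-irrelevant) while
32-channel EEG is recorded at 500 Hz, and complete the ChEAT (disordered
eating), the RCADS-25 (anxiety / depression), and a morphed-expression
card-sorting task. The package implements every stage — task scheduling,
EEG cleaning, ERP extraction, scoring, and inference — plus a synthetic
cohort generator with known ground truth, so the whole analysis is
testable end to end without any participant data.

## The measures at the core

For each subject and each condition × emotion cell, stimulus-locked
epochs (−100…1000 ms, 100 ms baseline) are averaged and two
frontocentral components are scored at Fz as mean amplitudes:

* **N2** (negative, 300–400 ms), larger on NoGo trials; conflict
  monitoring;
* **P3** (positive, 480–600 ms), larger on NoGo trials; inhibitory
  processing.

Inhibition-specific difference waves subtract Go from NoGo:

```
P3d(e) = P3_NoGo(e) − P3_Go(e),   N2d(e) = N2_NoGo(e) − N2_Go(e)
```

and a second family isolates emotional content by subtracting neutral
from angry/happy within each condition. The inference layer correlates
these (and behavior / recognition scores) with ChEAT and Log10(+1)-
transformed RCADS totals — age or gender partialled out, Bonferroni
correction per 3-emotion family — and, where a trait–ERP association is
found, runs a hierarchical regression (step 1: anxiety + depression;
step 2: the ERP score) with the ΔR² F test

```
ΔF = (ΔR²/q) / ((1 − R²_full)/(n − k_full − 1)),
```

and VIF collinearity diagnostics. A sensitivity utility reports the
critical |r| = t_{1−α/2,n−2}/√(t²+n−2) — 0.271 for n = 53 at α = .05.

## Worked example

`analysis/` contains the numbered study drivers. Running them in order on
the default 53-subject synthetic cohort:

```bash
python analysis/01_simulate_cohort.py
python analysis/02_preprocess_and_erp.py
python analysis/03_score_subjects.py
python analysis/04_inference.py
```

prints, among other things:

```
processed 53 subjects; valid-trial counts per cell:
                    mean  min  max
condition emotion
Go        angry    17.51   12   22
...
NoGo      happy     7.87    3   12

53 subjects scored; 0 with exclusions
ChEAT total: M=85.1 SD=34.7
Go accuracy: M=73.4%  NoGo accuracy: M=72.7%
Go RT: M=447 ms  NoGo RT: M=403 ms

n = 53 ERP-included subjects; critical |r| at alpha=.05: 0.271
```

Valid-trial counts fall well below the nominal 32 Go / 16 NoGo per
emotion because practice trials, anticipatory responses (<200 ms),
incorrect trials, and epochs overlapping ±200 µV or blink spans are
excluded — the same attrition real recordings show. The correlation
tables, the hierarchical-regression report (with ΔR², ΔF, VIFs) and the
grand-average Fz waveforms land under `results/`. At n = 53 the
trait–P3d(happy) coupling built into the generator (ρ ≈ 0.32) is below
the 0.271 sensitivity threshold roughly a third of the time; the
large-cohort recovery checks below are the calibrated validation.

`analysis/05_recovery_checks.py` runs those checks (n = 2000), and
`emogo simulate|run-all|erp|stats` expose the same stages as a CLI for
on-disk BrainVision/CSV studies.

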