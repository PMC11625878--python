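# Methods

This note documents the models, conventions and design choices behind
`emogo`, in the order data flow through the pipeline.

## Conventions

Sample indices are 0-based; ms → sample conversion is
`round(ms·rate/1000)` with round-half-to-even; epochs and bad spans are
half-open `[start, end)` in samples; scoring windows use **inclusive**
endpoints (a "300–400 ms" window includes both edge samples). All
voltages are µV in memory. BrainVision triplets are read through MNE and
written directly (IEEE float32, multiplexed, 1 µV resolution); the
stimulus-marker coding is `1000·practice + 100·condition + 10·emotion +
identity` (condition 1=Go/2=NoGo; emotion 1=angry/2=neutral/3=happy;
identity 1–8), a package convention since the original recordings'
scheme is not public.

## Task engine

The schedule is 2 blocks × 72 trials (48 Go / 24 NoGo), emotions
balanced exactly within condition per block (16 Go / 8 NoGo per emotion
per block → 32/16 per session), preceded by 20 practice trials. Face
gender is the Go cue; identities are drawn so no two consecutive trials
share a face (shuffle, then constrained identity assignment — with ≥2
models per gender a repair always exists, so the construction is exact
and seed-deterministic).

The display-duration staircase starts at 550 ms, −50 ms after every 3rd
consecutive correct response, +150 ms after every 3rd consecutive
incorrect NoGo response, clamped to [200, 1300] ms. Two rules needed
interpretation and are configurable:

* the correct-run counter counts correct responses of **either** trial
  type (the incorrect rule names NoGo explicitly; the correct rule does
  not);
* both counters reset on any outcome that breaks their run, and the
  triggering counter resets when its adjustment fires.

The NoGo response window is the current duration + 200 ms (deliberate
non-response check). Adaptation is off during practice by default: the
stated 550 ms starting value would otherwise not hold at block 1.
Clamp bounds are configurable because the published supplementary table
of per-condition display extrema is not available; [200, 1300] keeps all
windows inside the 200–1200 ms deliberate-response band plus the NoGo
extension.

## Synthetic cohorts

The generator is first-class, tested code: its job is to produce data
with exactly the statistical structure the analysis assumes, with ground
truth exposed.

**Traits and questionnaires.** Latents (disordered eating, anxiety,
depression) are drawn from a correlation matrix defaulting to
r(DE,anx)=0.64, r(DE,dep)=0.43, r(anx,dep)=0.60 — the first two are the
study-reported values; the third is not printed anywhere and 0.60 is a
typical community-sample value (configurable). Items follow a
single-factor graded model: continuous item = 0.9·latent + √(1−0.9²)·ε,
cut at equal-probability normal thresholds into 6 (ChEAT) or 4 (RCADS)
categories. With 26/15/10 items at loading 0.9, observed-total
correlations attenuate the latent ones by under 0.02, so the printed
trait correlations are recoverable targets, not assumptions. The
RCADS-25 subscale partition (items 1–15 anxiety, 16–25 depression) is a
package convention — only the 15/10 split is substantive.

**Behavior.** Go hits with p=0.75, NoGo commissions with p=0.29
(matching ~73%/71% scored accuracies), anticipatory (<200 ms) responses
with p=0.03; RTs are a shifted log-normal (shift 150 ms, median ≈430 ms)
truncated to the 200–1200 ms collection band — children keep responding
after stimulus offset, so the collection band, not the display duration,
bounds RT. Commission RTs are scaled ×0.85 (commissions are fast
failures of inhibition). Trial outcomes drive the real staircase.

**EEG.** Sessions are Cz-referenced by construction: a component with
scalp weight `w_c` contributes `(w_c − w_Cz)·s(t)` to channel c, so the
average re-reference downstream yields `(w_c − mean(w))·s(t)`;
`effective_gain("Fz")` (≈0.55 with the default frontocentral topography
peaking at Fz) converts kernel amplitudes to post-reference Fz
amplitudes for closed-form checks. Components are Gaussian bumps — the
waveform shape is unspecified in the literature this emulates, and a
Gaussian makes window averages analytic — N2 at 350±40 ms (−3 µV Go,
−2 µV NoGo increment), P3 at 540±60 ms (+5 µV Go, +4 µV NoGo
increment). Between-subject SD of the P3 NoGo increment defaults to
6 µV: large, but consistent with the scale of child ERP difference
scores implied by published regression coefficients on these measures.
The disordered-eating latent shifts the happy-trial P3 increment by
`coupling_p3d_happy` µV/SD; the default (2.027) calibrates the
generator-level corr(DE, P3d happy) to ≈0.32 via
β = ρ/√(1−ρ²)·σ_subject. Background noise is 1/f (3-pole/3-zero
pinking filter on white noise, per-channel independent, default SD
10 µV) plus a 10 Hz alpha sinusoid. Blinks are triangular pulses at
Fp1/Fp2 (rise 140–200 ms, fall 220–320 ms, amplitude 190–240 µV, ≥700 ms
apart): the ranges guarantee every injected blink clears the detector's
thresholds even after the band-pass (whose high-pass limb trims pulse
amplitude and undershoots the tail) and average reference (~0.9 frontal
scaling). Gross artifacts are half-sine excursions of 250–400 µV on one
channel. Every injected event carries a ground-truth span, so detectors
are scored by recall/precision rather than eyeballed.

What the generator does **not** emulate: realistic full-scalp
topographies, non-blink ocular activity, developmental age effects,
channel-correlated noise, latency jitter of components. Passing tests
therefore validate the pipeline's arithmetic and its exclusion logic
under controlled violations — not its robustness to every property of
real recordings.

## Preprocessing

Fixed order, each stage logged: 0.3–100 Hz band-pass → average
reference → ±200 µV threshold marking → blink detection → 30 Hz
low-pass for the ERP branch. All filters are 4th-order Butterworth run
forward–backward (zero-phase; peak-latency shift ≤2 ms by test).
"Exclusion" is span-marking: epochs overlapping any bad span are dropped
at epoching time, which preserves continuous timing. Threshold spans are
padded by 100 ms per side and merged.

Blink detection at Fp1/Fp2 applies the three published thresholds
(rise >100 ms, fall >150 ms, amplitude >125 µV) to candidate deflections
of either polarity. The measurement rule — unspecified in the source
description — is: smooth the frontal trace with a zero-phase 15 Hz
low-pass (blinks live well below 15 Hz; this stops single noise samples
from deciding a threshold), take local extrema above a 40 µV pre-screen,
measure amplitude against the local median baseline (±1.5 s), and take
rise/fall from the crossings of baseline + 10% of peak-to-baseline
amplitude. The manual visual-inspection follow-up of the original
procedure is replaced by precision/recall scoring against the
generator's ground truth (100% recall, ≥95% precision required).

## ERP extraction

Epochs span −100…1000 ms; dropped with logged reasons: practice,
anticipatory (RT <200 ms), bad-span overlap, recording-edge overrun.
Baseline is the mean over [−100, 0). Averages are computed from correct
trials only by default (correct Go responses; successfully withheld
NoGo) — the valid-trial counts reported for the original study are far
below the nominal 32/16, implying trial-level exclusion of this kind —
configurable via `correct_only`. N2 is scored 300–400 ms and P3
480–600 ms at Fz as mean amplitudes (windows are fixed configuration,
not re-fit per dataset). Difference scores: P3d/N2d = NoGo − Go per
emotion, and emotion − neutral contrasts per condition with their
NoGo − Go. The identity `NoGo−Go of (e − neutral) = P3d(e) −
P3d(neutral)` is asserted exactly in tests.

Subject QC: overall Go/NoGo accuracy <50% excludes a subject from all
analyses; any condition × emotion cell with fewer than 3 valid epochs
excludes the subject from ERP analyses (3 = the smallest valid-trial
count reported for the original sample; configurable).

## Behavioral scoring

Responses outside 200–1200 ms are non-deliberate and discarded before
scoring. For Go accuracy the default denominator keeps the trial and
counts it as an omission (`excluded_response="omission"`); the
alternative (`"drop"`) removes the trial. Both are tested; which the
original used is not decidable from its text. NoGo RT is the mean RT of
commission errors — the only NoGo responses that exist. The sorting task
scores each emotion out of 20 cards (2 models × 10 intensities); the
overall score averages the three emotion accuracies; the 6 neutral cards
are scored separately and never enter the overall mean.

## Questionnaires

ChEAT alternative scoring maps the six options in scale order
(never, very rarely, rarely, often, very often, always) to 1–6 and sums
(range 26–156); traditional scoring gives 0,0,0,1,2,3 (range 0–78). The
published anchor text for the alternative scale reads "1 (never) to 6
(very often)" while the canonical option set ends at "always"; the
package keeps canonical order with "always"=6 and exposes
`option_order` for the other reading. No reverse-scored items by default
(a configurable mask exists). Missing items are a hard error — no
imputation. RCADS-25: 0–3 per item, 15 anxiety / 10 depression sums.
Cronbach's alpha is the standard k/(k−1)(1 − Σs²ᵢ/s²_total); on
synthetic cohorts it runs ≈0.97–0.98, higher than real scales — the
single-factor generator has no content heterogeneity.

## Inference

Pearson r with exact-t p-values (df = n−2); covariate adjustment by
residualizing both variables on [1, covariates] and correlating
residuals (df = n−2−k); age is the ERP covariate, gender the behavioral
one. Bonferroni: α/m per 3-emotion family — 0.05/3 = 0.0167, which the
package reports at full precision (a published rounding of this quantity
to 0.02 is not reproduced). Hierarchical regression is OLS per step;
standardized β by refitting on z-scored variables; ΔF as in the README,
with p from F(q, n−k−1); ΔF = t² when one predictor is added (tested).
VIF via statsmodels. `critical_r(n, α)` returns the significance
threshold (0.271 at n=53, α=.05, two-tailed — the value a sensitivity
analysis at this n prints); the companion `detectable_rho(n, α, power)`
gives the Fisher-z power-based detectable effect, which is larger —
both are exposed because sensitivity analyses are often loosely worded
about which of the two they mean.

## Validation protocols and problem sizes

`emogo.protocols` freezes the package's reference validation runs:

* **Trait recovery** — 2000-subject questionnaire cohorts; recovered
  ChEAT × RCADS-anxiety r within ±0.06 of 0.64 (±3 sampling SEs).
* **ERP coupling recovery** — 2000-subject EEG cohorts at desk scale:
  one 72-trial block, no practice, clean behavior, no injected
  blink/gross artifacts, pink noise 3 µV. These conditions are chosen so
  each subject has all 8 NoGo-happy trials valid and trial-averaging
  noise attenuates the between-subject P3d signal by <5%; the run then
  checks that the full chain (band-pass → reference → span marking →
  blink detection → low-pass → epoch → baseline → average → window
  means → differences) returns the calibrated 0.32 coupling within
  ±0.06. With default noise (10 µV) and full trial attrition the same
  chain attenuates the correlation to ≈0.2 — visible in the n=53 study
  scripts — which is a property of small trial counts, not of the
  implementation.
* **Null calibration** — 1000 generator-level replicate cohorts of
  n=53 with zero coupling; the Bonferroni-corrected 3-emotion P3d screen
  must keep its family-wise error within the 99% binomial envelope of
  α=0.05. This check exercises the trait/effect generator and the
  decision rule directly rather than re-running 1000 full EEG cohorts,
  which adds nothing to a calibration of the decision layer.

Tolerances used in tests: exact identities at 1e−9 µV; noiseless
kernel-recovery at 0.01 µV (grid oracle) / 5% through filters;
stochastic recoveries at 3 standard errors of the relevant estimator.

## Known limitations

Single scoring site (Fz) and fixed windows; no peak-latency measures,
topographic maps, ICA or channel interpolation (none were part of the
procedure this implements); the emotion-recognition generator makes no
claim about a disordered-eating → happy-recognition coupling (the knob
exists, default 0); EDF/BDF input is out of scope.
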