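# Methods

This note documents the models, the synthetic study conditions, the
numerical choices, and the limits of what the package's tests demonstrate.

## 1. The discrete-time survival model

Time from the index ECG is cut into seven intervals with edges
`[0, 60 d, 1 y, 2 y, 3 y, 4 y, 5 y, ∞)`. The first interval spans the
60-day ECG–echo pairing window, so "disease in interval 1" and "prevalent
disease at the paired baseline echo" coincide; this is what lets one
network both diagnose and predict. The grid is configurable; the choice to
align interval 1 with the pairing window and to extend yearly to the 5-year
prediction horizon is ours.

For each interval the network emits a logit; `h_k = σ(logit_k)` is the
conditional probability of first developing (or, for k = 1, already
having) significant disease in interval *k* given event-free survival to
its start. The label for one ECG–echo pair is `(y, M)`: `y_k = 1` in the
event interval, `y_k = 0` in fully observed event-free intervals, and
`k ∉ M` (masked) after the event, after censoring, and in any interval only
partially covered by follow-up. The loss is the masked Bernoulli
negative log-likelihood, averaged over pairs. Two properties are enforced
by tests rather than assumed: the analytic gradient matches central finite
differences to 1e-5 relative error, and perturbing hazards in masked
intervals changes neither loss nor gradient.

Readouts: diagnosis score `h_1`; 5-year risk
`1 − Π(1 − h_k)` over post-baseline intervals ending at or before 5 years.
The baseline hazard `h_1` is deliberately excluded from the 5-year risk:
prediction is evaluated (and should be interpreted) conditional on no
prevalent disease, matching the evaluation protocol that removes prevalent
cases and blanks the first 60 days. With the default grid, events inside
the blanking window are encoded as first-interval (prevalent) outcomes, so
blanking is structural rather than a post-hoc filter.

## 2. Architecture and training

The backbone is a residual 1-D CNN: a strided stem convolution, then
residual blocks (conv–BN–ReLU–dropout–conv–BN plus a projected shortcut),
global average pooling, dropout, and a dense head (K logits for survival,
one for classification). The default profile mirrors common deep ECG
classifiers (4 blocks, channels 64/128/196/256, kernel 17, stride-4
downsampling, dropout 0.2, input 12×4096 at 400 Hz). The **tiny profile**
used throughout the tests keeps the same topology at CPU scale: 2 blocks
(16, 32 channels), kernel 9, input 12×1024 at 100 Hz (the same power-of-2
padding convention, decimated ×4). All layers, including batch
normalization and Adam, are implemented in NumPy with hand-written
backpropagation; every layer's backward pass is finite-difference checked.

Training: Adam (lr 1e-3), batch 64, reduce-on-plateau (×0.5, patience 2),
early stopping (patience 5), model selection on tuning-set loss, at most
25 epochs in the desk-scale runs. Optimizer settings and the interval
count are configuration, not claims: the source architecture's exact depth
and schedule are not public, so these are standard defaults. Training is
bit-reproducible given (init seed, train seed): dropout and shuffling
streams are reseeded at the start of `train_model`.

Class imbalance is not re-weighted by default; a per-interval positive
weighting flag is the natural extension point but is not needed on the
synthetic conditions.

## 3. Signal preprocessing

Zero-phase (forward–backward) 4th-order Butterworth bandpass 0.5–100 Hz,
zero-phase IIR notch (60 Hz default, Q = 30; 50 Hz available), polyphase
rational resampling to 400 Hz, tail zero-padding to 4096 samples (centre
crop if longer). Zero-phase filtering and the notch bandwidth are our
choices — only the cutoffs and the 400 Hz/4096 contract are fixed
externally. Poor-quality ECGs are deliberately **not** excluded. NaNs are
zeroed with a logged warning. The measurable contract, asserted in tests:
a 10-s 500 Hz recording → exactly 4096 samples at 400 Hz with zeros after
sample 4000; ≥20 dB attenuation at 60 Hz; ≤1 dB change at 10 Hz; linearity;
re-preprocessing an already-preprocessed signal changes the interior by
<1% RMS (the 0.5 Hz high-pass rings for ~3 s, so "interior" excludes ~1200
samples at each end).

R peaks: Pan–Tompkins-style (5–15 Hz bandpass → derivative → squaring →
150 ms moving-window integration) on lead II, falling back to the lead with
maximal 10–25 Hz energy. The detection threshold is 0.4× the median of the
top candidate peaks (the beat count a 40 bpm rhythm would give), with a
floor of 3% of the maximum: the median makes it robust to a single large
artefact, the floor rejects filter-ringing ghosts. Median beats use a
600 ms window (200 pre-R/400 post-R), cross-correlation alignment within
±50 ms against the first beat, and require ≥3 full-window beats.

## 4. The synthetic cohort: what it emulates

Each patient carries latent standard-normal morphology scores (QRS width,
P amplitude, QRS amplitude), a frailty term (SD 0.3), and a log-hazard
`η = 0.5·z_QRS − 0.5·z_P + frailty` (the effect map is configurable).
Per-valve times to significant regurgitation are exponential with rate
`base_v · e^η` (defaults MR/AR/TR = 0.08/0.05/0.08 per year); prevalent
disease at entry is Bernoulli (5.5/3.0/5.0%). Echo exams occur at entry and
then roughly annually (±20% jitter) until exponential loss to follow-up
(rate 0.12/y) or 6 years; each exam has a nearby ECG (±15 days). Grades are
none/mild before the event (mild with probability 0.35), moderate from the
event day, severe two years later; grades never regress. Chamber
measurements (LA volume/dimension, LVEDD, aortic diameters, RV diameter,
LVEF) shift with disease state plus noise, with ~5% missingness. About 3%
of patients carry a surgery/device exclusion flag. Dates are day offsets
from a fixed epoch.

Waveforms are sums of Gaussian bumps (P, Q, R, S, T) at a heart rate drawn
from 50–100 bpm, with white noise (σ 0.02 mV) and sub-0.5 Hz baseline
wander, projected to 12 leads through fixed stylized gain vectors.
Disease morphology follows a ramp `d(t)`: zero until 2.5 years before the
event, rising to 0.8 at the event and 1.0 two years after; it widens the
QRS (+30 ms at d=1), attenuates the P wave (−55%), raises QRS voltage
(+25%), and inverts the T wave. The 2.5-year pre-event ramp is the
calibration knob that places the generator's perfect-morphology-reader
C-index at ≈0.78, inside the intended 0.75–0.85 "learnable but imperfect"
band; with morphology frozen at baseline the ceiling would be ≈0.70.
Event rates are set higher than real-world progression rates so that a
~1000-patient cohort carries enough events for stable rank statistics —
the simulation validates machinery, it does not emulate incidence.

What the generator does **not** model: physiologic beat-to-beat
variability beyond timing jitter, arrhythmias, conduction-system morphology
(true LBBB shapes), multi-valve interactions, grade regression, informative
censoring, and site effects. Consequently, passing tests demonstrate that
the pipeline recovers planted signal under known conditions — not that any
trained model generalizes to hospital data.

## 5. Cohort construction conventions

* Grade recalibration takes the **least severe** grade token in a
  statement ("moderate-severe" → moderate).
* Pairing: nearest echo within ±60 days, one echo per ECG; equidistant ties
  go to the earlier exam (deterministic, biased toward pre-ECG status).
* Outcome: first follow-up echo with grade ≥ moderate; event time is that
  echo's date minus the ECG date; if a later echo regressed, the first
  qualifying echo still counts.
* Splits are 50/10/40 at patient level, seeded; multiple ECGs per patient
  train the model, only the earliest evaluates it.
* Surgery/device-flagged patients train but are excluded from evaluation;
  patients under 14 years are excluded throughout.
* A significant follow-up echo dated on or before an ECG whose baseline
  grade is below moderate is logged as a data inconsistency and treated as
  prevalent.

## 6. Evaluation statistics

Harrell's C uses the convention: usable pairs have distinct observed times
with the earlier subject an event; tied risks count ½; tied times are
excluded (lifelines agrees on tie-free data; the O(n²) oracle agrees
always). The hot loop is numba-compiled because the bootstrap-coverage
check evaluates it ~150 000 times. Kaplan–Meier and Cox fits go through
lifelines (Efron ties); AUROC/AUPRC through scikit-learn; DeLong's
variance/test and continuous NRI are implemented here (no in-environment
implementation exists) with enumeration oracles.

Horizon status for the Brier score and NRI: event at or before the horizon
→ outcome 1; followed beyond it → outcome 0; censored before it →
**excluded**. This transparent rule (rather than IPCW) is slightly
optimistic under heavy censoring and is flagged as a difference one should
expect against IPCW-based numbers. Risk quartiles use linear-interpolation
(type-7) quantiles of tuning-set scores, frozen before touching test data;
hazard ratios come from an age/sex-adjusted Cox model on quartile
indicators. Bootstrap CIs are percentile, patient-level, seeded (2000
replicates by default; tests use fewer). Imaging associations are OLS of
the standardized measurement on the standardized prediction adjusted for
sex, age, and age²; complete cases per measurement.

Fine–Gray competing-risk models and the partial likelihood ratio test for
non-nested Cox models are out of scope; the API reserves their names and
raises `NotImplementedError` so results tables can say "not computed".

## 7. Explainability

The VAE is fully connected (one hidden layer of 128 units each side) on
flattened lead×beat matrices, diagonal Gaussian posterior, Gaussian
likelihood with scale σ_x = 0.5 in globally standardized units, β = 1 —
depth, β, and schedule are our defaults, exposed in config. Latent ranking
regresses the prediction on all posterior means and sorts by |t|; it is
invariant to affine rescaling of predictions. Traversal sweeps one
coordinate over ±3 empirical posterior SDs around the dataset's mean code.
Extreme-group averaging takes the n lowest- and highest-prediction median
beats (n auto-shrinks to half the cohort; the reference analysis used
10 000 on a hospital-scale test set, desk-scale runs use 50–200) and plots
mean ± SD per lead.

## 8. Problem sizes and determinism

Desk-scale study conditions used by the tests and the acceptance script:
1000 patients (≈4700 ECGs, ≈2370 training pairs — the planted-signal
recovery checks run at roughly the 2000-ECG scale), tiny backbone, ≤25
epochs, three matched training seeds for head comparisons and three
independently shuffled label permutations for the null control.
Calibration checks: 1000 replicates for the nested-LRT type-I error at
n=150; 500 replicates × 300 bootstrap resamples for C-index CI coverage at
n=500 against a Gauss–Hermite closed form for the true concordance.
WFDB output quantizes at 1 µV (int16, gain 1000), far below the generator's
20 µV noise floor. Every stochastic component — simulation, splits,
initialization, dropout, shuffling, bootstrap — draws from explicit seeds,
and identical (config, seed) reproduce cohorts byte-for-byte and trained
models exactly.

## 9. Known limitations

* The NumPy networks are small by design; nothing here speaks to
  full-resolution, hospital-scale training dynamics.
* The classification head's repurposed prediction C-index is highly
  variable at desk scale (it was never trained on time information); only
  its ordering below the survival head is a stable claim.
* Percentile bootstrap CIs undercover slightly for extreme AUROC/C values;
  the coverage check targets the realistic mid-range.
* The horizon-status rule (Section 6) and the absence of IPCW are the two
  conventions most likely to differ from other implementations of the same
  metrics.
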