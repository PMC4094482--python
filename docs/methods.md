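# Methods

This note documents the models, algorithms and design choices behind
`rvdyn`: what each stage assumes, which parameters matter, what the
synthetic-data generator does and does not emulate, and where the design
was genuinely open.

## 1. Protocol model

The extrastimulus schedule is realised as a pure function of a capture
oracle: drive trains at S1 = 400 ms (8 beats), S2 reduced from 400 ms in
20 ms steps to 300 ms, then 5 ms steps until capture failure, then an
8 ms increase and 2 ms decrements. The **VERP** is defined as the longest
tested non-capturing interval after refinement and the **pre-VERP**
measurement beat as VERP + 2 ms. A failure during the coarse scan also
triggers the bump/refine phase, so the VERP is always resolved on the
2 ms grid; for any monotone oracle with threshold θ the resolved VERP
satisfies |VERP − (θ−1)| ≤ 2 ms (property-tested by sweeping θ). The
pacing floor below which the protocol aborts is configurable
(default 150 ms). Two-second inter-train gaps are carried as metadata
only; no analysis step uses them.

Times are stored in ms relative to each train's S2 stimulus; sample
indexing is 0-based; intervals are closed on the left, open on the right.

## 2. Electrode layout

24 virtual electrodes in 4 columns × 6 rows on an idealised cylindrical
RV shell (radius 15 mm, 13 mm row spacing). Rows 1–2 are apex, 3–4
mid-ventricle, 5–6 outflow tract; apex and outflow tract map onto 4
two-electrode segments each and the mid-ventricle onto 8 single-electrode
segments (16 segments total). Explicit positions can be supplied instead;
the 24/8-8-8/16 invariants are enforced either way.

## 3. Electrogram measurement

* **AT** = time of the minimum least-squares local-quadratic slope
  (Savitzky–Golay, 5 ms kernel) within the activation window, default
  stimulus + 5 ms (artifact blanking) to + 200 ms.
* **RT** = time of the *signed maximum* slope in the T window, default
  AT + 80 ms to min(AT + 450 ms, next stimulus − 20 ms) — the classical
  (Wyatt) convention, identical for positive and negative T waves. The
  T-wave derivative uses a wider kernel (9 ms) than the RS downstroke:
  at 1200 Hz a 5 ms slope estimate has a noise floor above the gentle
  T-wave upstroke, whereas the timing of the sharp RS downstroke needs
  the short kernel. Brute-force discrete differences are kept as the
  test oracle; on noiseless traces both agree within one sample.
* Detection criteria are **ratios** (window slope depth vs the quiet
  pre-diastolic segment's slope range, default minimum 3), so all
  detectors are invariant to amplitude scaling and degrade to explicit
  `NoActivation` / `NoTWave` / `TruncatedWindow` flags rather than
  numbers. For S1S2 windows the quiet reference segment is taken before
  the *S1* stimulus, since the drive beat's T wave occupies the
  pre-S2 interval. Only negative-going slope counts toward activation
  detection: capture classification must not mistake the drive beat's
  T upstroke for an evoked response.
* **DI** = A₁A₂ − steady-state ARI, with A₁A₂ the measured local
  interval between drive-beat and extrastimulus activations and the
  steady-state ARI measured from the 400 ms steady epoch. Beats with
  DI ≤ 0 are flagged `EncroachingDI` and excluded from ARI-restitution
  fitting; their AT/RT remain valid (the pre-VERP delay of a patient
  whose extrastimulus encroaches on repolarisation is still a
  measurement).
* **Fractionation index** = number of distinct downstrokes in the
  activation complex: 30–250 Hz zero-phase band-pass (2nd-order
  Butterworth, forward–backward), local-quadratic slope, then
  zero-crossing-bounded negative lobes of the derivative. A lobe counts
  when its peak downstroke rate exceeds both `snr_cutoff` (default 0.4)
  × the pre-stimulus noise amplitude and `relative_floor` (default
  0.20) × the dominant lobe; counted lobes closer than 5 ms merge.
  The relative floor exists because the 30 Hz high-pass surrounds every
  genuine deflection with wide, shallow recovery lobes (~10% of the
  dominant downstroke rate); peak-rate amplitude rather than voltage
  swing keeps those recovery lobes far under the floor. A clean RS
  complex therefore counts exactly 1. When no pre-stimulus segment
  exists the noise estimate falls back to a MAD-based estimate from the
  trace tail (logged).

## 4. Restitution metrics

Curves are assembled per electrode (repeated measurements at the same
coupling interval averaged; electrodes with < 4 valid points excluded).

* **ΔAT, ΔRT pre-VERP**: value at the pre-VERP coupling interval minus
  the steady-state reference.
* **Max ARI-restitution slope**: points sorted by DI; straight lines
  fitted over every 5-consecutive-point window spanning ≥ 10 ms of DI;
  the maximum fitted slope is reported (exhaustive window enumeration is
  the test oracle).
* **Mean increase in delay (MID)**: with delay d(ci) = AT(ci) − steady
  AT, per-step rates r_j = Δd/Δci over successive capturing fine-scan
  points (ci ≤ 300 ms); MID = κ · mean(r_j), κ = 1 by default. κ is
  exposed because published values of this metric have appeared in
  mutually inconsistent units (ms/ms definitions against printed ms²
  medians of 3–7); the implemented definition is declared rather than
  guessed, and the generator prescribes values through the *implemented*
  formula by inversion (§6).
* **Sinus RV activation time** = latest − earliest local sinus AT;
  **repolarisation dispersion** = max − min RT across electrodes,
  emitted for both the steady state and the pre-VERP beat (which state
  the original analysis used is unstated). Range rather than SD is the
  mapping-literature convention.
* **Activation-gradient statistics**: per beat, apparent speed along
  each lattice-adjacent electrode pair = distance / |ΔAT| (pairs with
  |ΔAT| < 1 ms or coincident positions skipped); the slowest pair speed
  is averaged over beats. Consistency r² = squared Pearson correlation
  between successive beats' 24-electrode AT vectors, averaged. This is
  a declared simplification of the published activation-gradient
  quantification algorithm, which operates on full reconstructed
  activation fields.

Patient-level metrics are electrode means, reported globally and per
region (apex / mid / outflow tract). The patient's VERP is re-derived
from the waveform-level capture outcomes (longest tested non-capturing
interval), not copied from the protocol object.

## 5. Paced-ECG delineation

Signals are band-passed 0.1–50 Hz (zero phase) and referenced to the
median pre-stimulus baseline. With a 14 ms derivative kernel:

* **QRS peak** = largest |V| between blanking and 200 ms;
* **latency** (QRS onset) = end of the last ≥ 4 ms run with |dV/dt|
  below 10% of the maximum QRS slope before the peak (searching backward
  from the peak makes the onset robust to stimulus-artifact ringing);
* **J-point** = first sustained (≥ 10 ms) return of |V| below 7% of the
  QRS peak amplitude. An amplitude criterion replaces a slope criterion
  here deliberately: a wide paced QRS ends with a slope so shallow that
  any slope threshold low enough to find it sits below the noise floor
  of the derivative;
* **T peak** = largest |V| in (J + 40 ms, stimulus + 450 ms);
* **T end** = tangent method: a straight line regressed over the
  descending terminal limb (between 65% and 10% of the T amplitude,
  bracketing its steepest sustained slope) intersected with the
  isoelectric baseline. Regressing the slope instead of taking the
  single steepest sample keeps the intercept unbiased under noise.

All thresholds are configurable (`EcgDetectorParams`). Landmarks out of
order reject the beat with a reason. Aggregation is the median over ≤ 3
repeats within a lead, then the median across available limb leads, with
the lower-median convention for even counts (so aggregates are always
observed values). Chest leads are excluded by default. Hysteresis = the
pre-ERP minus steady-state difference of each of the eight
stimulus-to-landmark/derived intervals; the derived-interval identities
(QRS duration = J − latency, Tpeak–Tend, QT = Tend − latency) hold
exactly by construction.

## 6. Synthetic-data generator

The generator is the package's acceptance surface: it emulates exactly
the features the detectors measure, with analytic control of their true
values.

**Electrogram beat**: 1 ms biphasic stimulus spike; RS complex as a
derivative-of-Gaussian biphasic wave (width 4 ms) whose steepest negative
slope is exactly at the prescribed AT; T wave as a tanh upstroke (rise
constant 5 ms) with a 25 ms plateau and slow Gaussian decay, whose
steepest upstroke is exactly at the prescribed RT — a negative T is the
time mirror, so its steepest (recovery-limb) upstroke stays at RT. The
distinct intrinsic T upstroke mirrors real unipolar T waves and is what
makes the Wyatt point localisable under noise. Fractionation deflections
are narrow Gaussian bumps (σ = 2.2 ms, default 0.6 mV) inserted at
jittered slots ±18/28/38 ms around the RS: 10 ms spacing so neighbouring
downstrokes never cancel, ≥ 18 ms from the RS so its derivative does not
mask them, each adding exactly one countable downstroke. Additive white
Gaussian noise, default 0.02 mV (electrograms) and 0.01 mV (filtered
limb leads) — representative of clean clinical recordings; detector
tolerances (≤ 2 ms per-beat AT/RT, ≤ 4 ms ECG landmarks at the 90th
percentile) hold at these defaults and are re-verified by the test
suite.

**Restitution dataset**: capture oracle `ci > true VERP`. Activation
delay d(ci) is constructed by inversion, one of two ways:

* *pre-VERP prescription*: d(ci) = ΔAT·exp(−(ci − pre-VERP)/τ), τ =
  25 ms — monotone, pinned to the prescribed ΔAT at the pre-VERP point;
* *MID prescription*: per-step rates over the realised fine scan
  allocated ∝ 1/step-width, so every step contributes equal delay and
  the implemented MID formula evaluates exactly to the prescribed
  value. Since the per-step-rate average weights the narrow 2 ms
  refinement steps as heavily as the 5 ms steps, large MID values are
  only realisable with bounded total delay when the fine scan is short;
  the MID study therefore fixes the true VERP at 288 ms (≈ 4 fine-scan
  steps), which keeps 40 ms of total delay per 7 ms/ms of MID. An
  infeasible inversion (< 3 capturing fine-scan points) raises a
  GeneratorError naming the constraint.

RT(ci) = AT(ci) + ARI(DI(ci)) with mono-exponential restitution
ARI(DI) = ARI_max − a·e^(−DI/τ), τ = 60 ms. The amplitude *a* is solved
per electrode from the steady-state ARI and the prescribed pre-VERP
repolarisation change; it is **signed**, because jointly prescribed
ΔAT ≈ 48 ± 21 ms and ΔRT ≈ 15 ± 29 ms imply ARI *lengthening* at short
DI for roughly a sixth of patients — an a ≥ 0 constraint cannot hold
jointly with the calibrated prescriptions. Synthesised ARIs are floored
at 100 ms (the physiological lower range and the detectable limit of
the default T window).

**Cohorts**: per-patient parameters drawn from group-level normal
distributions (lognormal for MID, fitted to the printed median and IQR
*ratio*; a printed lower quartile of 0 falls back to the median-to-Q3
ratio). Each parameter's variance is split 70% between patients / 30%
within (per-electrode) — the published group SDs describe all
measurements throughout the ventricle, and the true partition is not
reported; the fraction is configurable. Draws are truncated to the
kinetics invariants (e.g. VERP ∈ [158, 302] ms so every protocol
resolves above the pacing floor). Per-electrode steady AT includes a
systematic apex-to-outflow gradient plus scatter. Deflection counts are
1 + Poisson(mean − 1) per beat, truncated to the available slots.

Sampling is iid by default. The cohort *studies* (and the acceptance
script) use permuted-quantile **stratified** sampling for the primary
prescribed parameter of each study: each patient's draw still follows
the group marginal, but the cohort-level mean/median pins the
distribution's location, so the reported recovery reflects pipeline
calibration rather than Monte-Carlo noise. The 2-SE parameter-recovery
property tests use iid draws.

**Paced ECG**: raised-cosine monophasic QRS, isoelectric ST, T wave with
a slope-corner peak and an exactly linear terminal limb (the tangent
intercept is then invariant to where on the limb the steepest-slope
point falls). Because threshold-based onset/offset definitions have
shape-dependent offsets of 1–2 ms, the generator self-calibrates: 2–3
fixed-point iterations against the package's own delineator at zero
noise adjust the internal segment boundaries until the *detected*
landmarks equal the prescription (exactly, at zero noise, to within one
sample). Per-lead amplitude scaling (0.75–1.25) emulates projection
differences without moving landmarks; ordering margins are enforced on
drawn landmark sets without moving the J-point (the headline feature).

**What the generator does not emulate**, hence what passing tests do not
show about real data: no biophysical (ionic/monodomain) propagation — the
activation "field" is a prescribed timing surface, so the
activation-gradient metrics are validated only against analytic plane
waves; no far-field ventricular components, respiration/baseline wander,
electrode contact artifacts, or ectopic beats; morphology within a
patient is stationary apart from the prescribed kinetics; ECG leads are
amplitude-scaled copies rather than projections of a dipole. Recovery
results certify the measurement chain, not clinical performance.

## 7. Statistics

* **Group tests**: pairwise Welch t-tests across the group pairs with
  Holm correction (family-wise type-I error verified ≤ 6% under the
  null in 1000 simulations).
* **Mixed-effects logistic regression**: single Gaussian random
  intercept per grouping unit, fitted by maximising the
  Laplace-approximated marginal likelihood (inner Newton iterations for
  the per-group modes are vectorised; covariates are max-abs scaled for
  conditioning; a tiny ridge (1e-6) stabilises near-separation, with a
  warning and stronger penalty on detected separation). Standard errors
  come from the numerical Hessian at the optimum. With the
  random-intercept variance fixed at 0 the fit agrees with ordinary
  logistic regression to 1e-4 relative (tested against statsmodels).
  Optional backward stepwise elimination by AIC. A reference coefficient
  fixture (intercept 3.57; ΔAT pre-VERP −0.03; sinus fractionation 0.37;
  fractionation at VERP 0.40; sinus RT −0.01; steady AT −0.05; location
  random-intercept SD 0.26) ships with the package so the previously
  reported diagnostic model can be applied without refitting; the
  printed z-values of that model are not consistent with the printed
  estimate/SE ratios (rounding in the source), so the fixture stores the
  printed values verbatim. Reported AUCs (0.85 definite-vs-RVOT, 0.73
  combined) and CART thresholds (48 / −6 / −11 ms) derive from the
  original patient data and are documentation here, not reproduction
  targets.
* **ROC/AUC**: scikit-learn's trapezoidal implementation behind the
  module surface; permutation-null calibration verified.
* **CART**: authored greedy binary Gini trees — candidate thresholds are
  midpoints of sorted unique values, ties break toward the lower feature
  index then lower threshold, recursion stops at depth 3 (the depth of
  the published tree), `min_leaf` 5, or zero gain; cost-complexity
  pruning is intentionally omitted. scikit-learn's tree is used only as
  an independent cross-check in tests.
* **Random-intercept linear models** for electrode-level contrasts are
  a thin statsmodels MixedLM wrapper (supporting machinery, REML).

## 8. Problem sizes and numerical choices

Cohort studies use n = 50 patients per arm, 24 electrodes, the full
S1S2 protocol (~30 trains) with waveforms at 1200 Hz for electrograms
and 1000 Hz for ECG (both comfortably above the 250 Hz analysis band;
the source acquisition rates are unstated). One full endocardial cohort
(simulate + measure + metrics) takes about a minute on one CPU. The MID
study is curve-level (ground-truth beat tables through the same
assembly and metric code), since its purpose is to verify the
formula/inversion pair rather than the waveform detectors.

Degenerate inputs are handled explicitly throughout: flat traces,
missing T waves and truncated windows flag rather than return numbers;
electrodes with too few valid points are excluded and logged; metrics
with insufficient support return null; a non-monotone capture oracle,
an unresolvable VERP, unordered ECG landmarks and infeasible inversions
raise typed errors. QC counts every rejection by reason.

## 9. Known limitations

* The activation-gradient algorithm is a lattice-pair simplification
  (§4); absolute speeds depend on the idealised geometry.
* The J-point criterion is an algorithmic surrogate for manual
  calipers; its 7% amplitude threshold was chosen to satisfy the
  synthetic-morphology recovery property and is configurable, but no
  claim is made that it matches human readers on real ECGs.
* MID units follow the implemented ms/ms definition with κ exposed; the
  generator's MID study design (short fine scan) is required for large
  prescribed values and is itself synthetic.
* The mixed logistic uses a Laplace approximation; for very small
  cluster sizes adaptive quadrature would be more accurate.
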