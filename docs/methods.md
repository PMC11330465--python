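# Methods

## Circuit model

The leak port is modelled as a volumeless junction (node) joining three
signed flows, all positive toward the patient: patient-side flow `Q_pat`,
ventilator-limb flow `Q_vent`, and the intentional leak `Q_leak = k·P`
leaving the port. Mass balance at the node holds at every step:

    Q_vent = Q_pat + Q_leak.

**Leak law.** The leak is a linear conductance `k` (ml/s per cmH₂O). A real
exhalation port is closer to an orifice (`Q ∝ √P`); the linear law was
chosen for analytic tractability — the reversal condition
`|Q_pat| > k·EPAP` and the washout volume then have closed forms — at the
cost of overestimating leak flow at IPAP relative to a √P device
calibrated at EPAP. The default `k = 100` gives ≈ 24 L/min of bias flow at
EPAP 4 cmH₂O, in the range of common intentional leak ports; no published
volumes or leak characteristics exist for the specific port modelled, so
all circuit geometry defaults are plausible values, not measured ones.

**Ventilator.** An ideal pressure source alternating IPAP/EPAP with fixed
timing (respiratory rate, inspiratory-time fraction) plus per-cycle
log-normal duration jitter (`cycle_jitter_cv`, default 0.05). Pressure
follows a first-order response with `pressure_tau = 0.05 s`. There is no
patient-trigger model: pressure-support triggering is irrelevant to the
CO₂-movement question the simulator serves.

**Patient flows.** Inspiratory and expiratory flows are decaying
exponentials (`τ_insp = Ti/3`; `exp_flow_tau`, default 0.4 s) multiplied
by a raised-cosine envelope (`transition_time`, default 0.05 s) that makes
flow continuous and zero at each phase boundary, as in real breathing.
Each phase's amplitude is normalized by sampling-rate-independent
quadrature so the integral equals the tidal volume exactly regardless of
discretization.

**CO₂.** The expiratory capnogram rises as `FetCO₂·(1 − e^(−t/τ_cap))`
with `τ_cap = 0.15 s`. The ventilator limb is discretized into N = 20
well-mixed cells in series (default limb volume 500 ml) with upwind
advective exchange only; sub-stepping keeps each fractional exchange below
0.9 cell volumes, so the scheme is conservative and stable. Molecular
diffusion is neglected; the scheme's numerical diffusion stands in for the
small physical mixing. Gas displaced past the far (ventilator) end of the
modelled limb is accounted as circuit content that does not return. The
patient-side CO₂ sensor is a small well-mixed volume at the port
(`pat_limb_volume`, default 10 ml — the apparatus dead space between the
sensor and the patient connector) flushed by `Q_pat`; this is what gives
type I/II cycles their small nonzero inspired-CO₂ volume (≈ 0.5 ml at
FetCO₂ 5 %) even though no rebreathing from the ventilator limb occurs.

**Ground truth.** Per expiration→inspiration cycle, from the noiseless
ventilator-limb state: type I if the cell nearest the port never exceeds
ε during expiration; type II if it does but is ≤ ε at inspiration onset;
type III otherwise. ε defaults to 0.05 %CO₂, the same operational "zero"
the rule labeler applies to measured signals, so agreement between the two
on clean signals is structural rather than numerical. Rebreathed CO₂ is
the volume advected from the limb to the patient during the following
inspiration; in this truth model it is exactly 0 for types I/II
(sub-threshold residue counts as flushed) and positive for type III.

**Noise.** Additive Gaussian per channel (defaults 0.2 cmH₂O, 5 ml/s,
0.02 %CO₂), applied after all dynamics and truth bookkeeping; CO₂ channels
are clipped to [0, 15] %.

**Mass balance.** Exhaled CO₂ = (vented through the leak) + (re-inhaled) +
(change in circuit content). The bookkeeping uses the same discrete fluxes
as the advection scheme, so the per-cycle balance closes to machine
precision; the test asserts the ≤ 1 % contract.

## Sidestream capnometer

A sidestream capnometer delays both CO₂ channels by
`60 s/min · V_line / Q_pump` (1.6 s for the 4.0 ml kit at 150 ml/min;
2.4 s at the 100 ml/min factory preset). The forward model
(`apply_capnometer`) applies this delay plus an optional first-order cell
response; `align_capnogram` undoes it by advancing the CO₂ channels,
quantized to whole samples (block shift, no sub-sample interpolation — the
delay uncertainty of a real line exceeds one sample at 200 Hz, and a block
shift is exactly invertible). Edges are padded with the boundary value so
cycle counts stay stable; partial edge cycles are discarded downstream.
Automatic delay estimation by cross-correlation is deliberately out of
scope (future work).

## Segmentation

Inspiration/expiration boundaries are patient-flow zero crossings
(inspiratory flow positive by convention). Robustness additions, since no
acquisition software's internal handling is documented: a crossing is
accepted only once flow exceeds a ±10 ml/s hysteresis band in the new
direction, and crossings closer than 0.2 s to the previously accepted one
are suppressed — values chosen so adult breathing at up to 60/min is never
clipped while baseline flow noise of a few ml/s cannot split a phase. The
analysis unit pairs each expiration with the following inspiration,
because rebreathing during an inspiration is determined by the preceding
expiration. The crossing sample is the first sample past zero in the new
direction; phases are half-open, consecutive cycles sharing the boundary
sample.

## Per-cycle parameters

All integrals are trapezoidal over the phase windows including both
boundary samples (flow is ≈ 0 at the boundaries by construction, so the
shared sample is immaterial). Choices made where the measurement protocol
was underdetermined:

* the pressure-curve "surface" is reported as the time integral in
  cmH₂O·s — chart area on a strip recorder depends on device gain; the
  time integral is the underlying quantity;
* PEEP is the mean patient-side pressure over the final 50 ms of
  expiration;
* breathing frequency is the instantaneous per-cycle value `60/(Ti+Te)`;
* ventilator-side tidal volumes are signed — flow toward the patient
  positive for the inspiratory volume, flow away from the patient positive
  for the expiratory volume — so the expiratory ventilator-side volume is
  genuinely negative for type I cycles, whose ventilator-side flow never
  reverses.

## Rule labeler

"Zero" and "positive" on the ventilator-side CO₂ trace are
operationalized as `zero_epsilon = 0.05 %` and `borderline_band = 0.10 %`:
onset values in (0.05, 0.10] are *borderline* and excluded from all
statistics and training, mirroring a visual protocol that only keeps
indisputable cycles; the type III boundary coincides with the 0.1 %
inspired-CO₂ level conventionally regarded as significant rebreathing.
The inspiration-onset value is read at the single boundary sample.
Exclusion counts are always reported. With the default channel noise
(SD 0.02 %) the pipeline smooths CO₂ with a 50 ms moving average before
labeling; without smoothing, noise peaks near the 0.05 % threshold can
misclassify type I cycles as II.

## Statistics

One-way fixed-effects ANOVA per feature; Newman–Keuls stepwise pairwise
comparisons on the ordered group means using studentized-range critical
values `q(α, r, df)` with the classical balanced formula and the harmonic
mean of the two group sizes when unbalanced (a non-significant stretch
protects every pair inside it). Canonical discriminant analysis solves the
generalized symmetric eigenproblem `B v = λ W v`; variates are scaled to
unit pooled within-class variance, discrimination is summarized by
Wilks' Λ = Π 1/(1+λᵢ), and classification is nearest class centroid in
canonical space with equal priors (no priors are published for the
protocol being mirrored; equal priors is the symmetric default). The
classification matrix is resubstitution, matching the printed-matrix
protocol. A singular within-class scatter raises unless a ridge is
enabled (`ridge · tr(W)/p · I`), and its use is flagged; the pipeline
enables a 1e-8 ridge because the invasive flag can be constant within a
class in simulated data. Composition percentages are truncated (not
rounded) to one decimal so the three shares never sum above 100 %.

## Classifier

A two-hidden-layer MLP with logistic (sigmoid) hidden activations and
softmax output on the 16 standardized CO₂-free predictors (every per-cycle
parameter except the inspired CO₂ volume, whose measurement the classifier
is meant to replace; the invasive/noninvasive flag is included by default
and the predictor list is configurable). "Auto" hidden sizing is
`(min(64, 4p), ⌈·/2⌉)` — fixed and documented, since the original sizing
was delegated to closed-source software. Folds are simple random equal
splits (stratification behind a flag); standardization is fitted on each
training portion only. Within each training fold, 30 % of rows define the
early-stopping condition: training (adam, learning rate 0.01, chosen for
stable convergence at n ≈ 5000; at 0.001 the sigmoid layers can sit on
their initial plateau past the patience window) stops once validation
cross-entropy has not improved for 20 epochs (max 500), and the
best-validation-loss weights are restored. Stopping on the loss rather
than accuracy keeps the class probabilities training after the decisions
have stabilized, which is what makes scores comparable across folds under
the pooled-ROC strategy. AUC is the trapezoidal area under the empirical
pooled ROC per class (one-vs-rest); the 95 % CI uses the Hanley–McNeil
variance formula (no CI method is published for the protocol mirrored).

## What the generator does and does not emulate

It emulates: bilevel pressure waveforms with timing jitter; biphasic
ventilator-side expiratory flow with mid-expiratory reversal; the three
CO₂-movement regimes with controllable severity (tidal volume, rate,
expiratory time constant, leak conductance); sidestream transport delay
and sensor smoothing; channel noise; apparatus dead-space CO₂ on the
patient side.

It does not emulate: patient triggering or patient–ventilator asynchrony;
non-intentional mask leaks; PaCO₂/respiratory-drive feedback; within-
scenario drift of the breathing pattern. Consequently the demo's three
scenarios are separable almost perfectly by *any* of the pressure/flow
features — passing classifier tests on simulated recordings shows the
pipeline is wired correctly, not that real bedside cycles are this easy.
The feature-table sampler (published per-type means/SDs, independent
coordinates, nonnegative features rectified at zero) is the harder,
overlapping-class benchmark used for the statistics and classifier
acceptance tests; it in turn ignores the substantial between-feature
correlations of real cycles unless a correlation matrix is supplied.

## Problem sizes and tolerances used in the tests

Unit tests simulate 30–60 s recordings (10–30 cycles) at 200 Hz; the
labeler-vs-truth acceptance property uses three 1100 s clean recordings
(≥ 1000 cycles); classifier acceptance uses the sampled feature table at
the published class sizes (4747 rows) and a 3000-row permutation null.
Integral features are checked against closed forms at 1e-9 relative
tolerance and against a 10×-refined cubic-spline quadrature at 1 %;
per-cycle mass balance at 1 %; boundary detection at ±2 samples.

## Known limitations

* Linear leak law (see above); no √P option yet.
* The ventilator limb beyond the modelled volume is a one-way sink;
  CO₂ pushed past it never returns, which slightly underestimates
  rebreathing in extreme configurations whose expired bolus exceeds the
  limb volume.
* The labeler's thresholds operationalize a visual protocol; no claim is
  made that 0.05/0.10 % reproduce any particular rater's judgment.
* Real-data headline figures (e.g. a specific Wilks' Λ or CV accuracy)
  require the original per-cycle recordings and are intentionally not
  targets of the simulated benchmarks.
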