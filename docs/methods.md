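# Methods

This note documents the model, the numerical choices and the known
limitations of `vqshunt`. It is the package's own account of its science;
every empirical number quoted here is computed by the test suite or by
`scripts/acceptance.py`.

## The forward lung model

Pulmonary blood flow is split into a shunt fraction `s` (V/Q = 0) and a
log-normal distribution over 20 gas-exchanging compartments. Writing `z`
for a standard normal variate, perfusion is distributed over
`V/Q = μ · exp(σ z)` where `μ` ("mean V/Q") is the perfusion-weighted
*median* (geometric mean) of the distribution and `σ` ("log SD") its
dispersion in natural-log units. The 20 compartments are log-equally
spaced over `μ·exp(±3.5σ)` and carry bin-integrated normal masses
(renormalized), so the discrete weights converge to quadrature of the
log-normal density.

Two conventions deserve emphasis because they are genuinely open choices:

* **Mean V/Q is the median, not the arithmetic mean.** Under the
  arithmetic reading the admissible parameter box cannot reach the low end
  of the observed mean-alveolar-PCO2 envelope (≈14 mmHg requires an
  expired alveolar ventilation ≈2.3× cardiac output); under the median
  reading the whole envelope is reachable.
* **Compartment V/Q is defined on *expired* alveolar ventilation** (the
  convention of multiple-inert-gas analyses). With inspired-defined V/Q,
  low-V/Q units at high FiO2 can absorb their entire inspired volume and
  have no steady state (the absorption-atelectasis regime); the
  expired-defined formulation always admits one, with inspired ventilation
  `vai = vq + net uptake`.

Each ventilated compartment is solved for steady-state `(PAO2, PACO2)`
from two flux balances (gas delivery = blood uptake for O2 and CO2), with
N2 closing total alveolar pressure at `PB − PH2O = 713 mmHg` and the
inspired/expired ventilation difference equal to the net gas volume
exchanged (R ≠ 1 plus N2 flux). Dissolved N2 is carried with solubility
0.0015 mL/dL/mmHg; mixed-venous N2 equals arterial N2 at whole-body steady
state (no net tissue N2 exchange), closed by the outer loop. The constant
0.863 converts between BTPS ventilation × mmHg and STPD mL/min.

The whole lung is an outer fixed point: guess mixed-venous blood;
equilibrate all compartments; mix arterial blood by perfusion-weighted
content averaging (the shunt contributes venous blood); update the venous
state by the Fick principle, `CvO2 = CaO2 − VO2/(10·CO)` and
`CvCO2 = CaCO2 + VCO2/(10·CO)`; repeat to convergence.

**Mean alveolar PCO2** is the expired-ventilation-weighted mean of
compartmental PACO2 — the steady-state counterpart of the Phase-3
geometric midpoint reported by volumetric capnography (synchronous
emptying assumed; the single-breath waveform itself is not modelled). At
convergence it satisfies the identity
`meanPACO2 = 0.863·VCO2 / VA_E` with `VA_E` the total expired alveolar
ventilation.

**Venous admixture** uses the classic ideal-compartment construction:
`VenAd = (Cc′O2 − CaO2) / (Cc′O2 − CvO2)` with the end-capillary content
`Cc′O2` evaluated at the ideal alveolar PO2
`PIO2 − PaCO2·(FiO2 + (1−FiO2)/R)`. One formula is used everywhere
(forward labels and record-side estimates). Because the ideal alveolar
equation evaluates at *arterial* PCO2, which admixture raises slightly
above compartmental PACO2, VenAd can undershoot the true shunt by up to
≈0.2 percentage points in near-homogeneous lungs; low V/Q = VenAd − shunt
is therefore only guaranteed non-negative to a −0.5 pp tolerance.

## Blood chemistry

* **O2 saturation**: the Severinghaus reference curve
  `S = (x³+150x)/(x³+150x+23400)` at virtual tension
  `x = PO2 · 26.86 / P50`, with in-vivo
  `P50 = P50st · 10^(−0.48(pH−7.40) + 0.0013·BE)`. P50st (standard P50)
  scales hemoglobin-O2 affinity; the pH term is the Bohr shift; the small
  BE term carries the residual non-pH effect at fixed pH.
* **O2 content**: `1.34·Hb·SO2 + 0.003·PO2` mL/dL (Hüfner constant and
  physical solubility, both config-overridable).
* **CO2 content**: the Douglas–Jones–Reed whole-blood formulation —
  plasma CO2 from Henderson–Hasselbalch (solubility 0.0307 mmol/L/mmHg,
  pK′ 6.09072 at 37 °C) scaled to whole blood by a hemoglobin/saturation
  factor that reproduces the Haldane effect. The small pH-dependence of
  pK′ is neglected (≤0.01 over the viable pH range).
* **Acid–base**: the Van Slyke buffer relation
  `BE = (1−0.0143·Hb)·[HCO3 − 24.5 + (9.5+1.63·Hb)(pH−7.40)]`, anchored so
  that pH(PCO2 40, BE 0) = 7.400 exactly; pH is obtained by Newton
  inversion. Temperature is fixed at 37 °C; fetal/dysfunctional
  hemoglobins and 2,3-DPG beyond the P50st scalar are out of scope.

All functions broadcast over numpy arrays; the batch engine exploits this
to solve thousands of scenarios simultaneously.

## Numerical choices

* Compartment solves: damped 2-D Newton with finite-difference Jacobians,
  steps clipped (40 mmHg O2, 25 mmHg CO2), tensions clipped into
  `(0, 713)`, scaled flux-residual tolerance 1e-11, active-set masking.
* In multi-equilibrium regimes (very low V/Q at high FiO2 — the classic
  critical-V/Q multiplicity) the solver deterministically tracks the branch
  continuous with an initial guess that interpolates venous→inspired along
  V/Q. Compartment state is therefore *never* warm-started across different
  distribution parameters (that can hop branches); warm starts are used
  only across FiO2 steps of the same scenario during titration.
* Outer venous loop: undamped fixed-point iteration with a periodic
  componentwise Aitken extrapolation (the CO2-side contraction approaches
  1 for low-V/Q-dominated scenarios, where plain damped iteration needs
  hundreds of passes); convergence when successive venous contents change
  < 1e-6 mL/dL (1e-9 inside the inversion), max 200 iterations. A damping
  knob remains in `SolverSettings`.
* FiO2 titration: bisection of the monotone SaO2(FiO2) map on
  [0.21, 0.99] toward a per-scenario target saturation, tolerance 0.002.
  Scenarios infeasible on room air (venous O2 ≤ 0) are treated as
  "saturation far below target" and titrated upward.
* Infeasible venous states abort a scenario; nothing is clamped into
  pseudo-viability, so training labels are never corrupted.

## The scenario generator

The generator defines the simulated study conditions. The nine inputs are
sampled independently and uniformly within: shunt 7.3–36.5 % of blood
flow, log SD 0.36–1.83, mean V/Q 0.21–1.25, VCO2 185–223 mL/min,
R 0.57–1.05, Hb 6.0–17.3 g/dL, P50st 20.8–31.2 mmHg, BE −6.5–4.9 mEq/L,
CO 4.32–6.28 L/min. For each draw the FiO2 is titrated so that SaO2 lands
in [0.87, 0.98]; the per-scenario target saturation is itself uniform in
the band, which spreads operating FiO2 over its full 0.21–0.99 range as a
clinician titrating to different targets would.

Retained records must (i) converge, (ii) have a feasible venous state,
(iii) have SaO2 in band, and (iv) fall inside the bedside observable
envelope pH 7.02–7.56, PaO2 41.8–127.7, PaCO2 23.8–111.6, mean PACO2
14.2–77.1 mmHg. The envelope screen represents viability of a monitored
living patient: unconstrained uniform sampling of the input box otherwise
produces steady states (PaCO2 ≈ 150–190 mmHg, pH < 7.0) that bedside
monitoring would never record. Rejected draws are resampled until the
requested count (default 15,236) is reached and the rejection reasons are
tallied in the dataset metadata; the retained set is randomized into
14,736 training and 500 test rows.

What the synthetic data does *not* emulate: measurement noise and device
bias (records are exact model outputs), biological covariance between
inputs (independent uniforms), temporal dynamics and breath-to-breath
variability, and capnogram waveform artifacts. Passing tests therefore
demonstrate internal consistency of the method — that the ten observables
identify shunt under the model — not robustness to real measurement error,
which the sensitivity sweeps quantify instead.

## The ML inverter

A dense MLP (10 inputs → 6×128 rectified-linear hidden layers → 1 linear
output; 84,097 trainable parameters) is trained with mean-squared-error
loss and an adaptive per-parameter gradient optimizer (adam via
scikit-learn's `MLPRegressor`; learning rate 1e-3, minibatch 200,
500 epochs) on z-scored features, statistics taken from training rows
only. An optional held-out fraction (default 0.1) is monitored, never
fitted. With noiseless simulated data the network interpolates the forward
map essentially perfectly; overfitting is not a practical concern, and no
hyperparameter search is performed.

## The direct back-calculation

From one record, the two blood parameters that are not monitored are
derived first: BE from the Van Slyke relation at the record's pH, PaCO2
and Hb; P50st by inverting the dissociation curve so the record's
PaO2/SaO2 pair lies on it (PaO2 and pH thus serve as consistency inputs,
not fitted residuals). The three matched observables are SaO2, PaCO2 and
mean PACO2. Mean PACO2 is matched exactly through the ventilation
identity above, which fixes mean V/Q given (shunt, log SD); the remaining
two residuals are minimized over (shunt, log SD) by bounded trust-region
least squares, multistarted from the best cells of a coarse batched grid
scan.

The inversion is genuinely multi-rooted: a large-dispersion lung can trade
true shunt against near-zero-V/Q flow almost exactly (distinct exact roots
up to ~10 pp apart in shunt were observed). When several roots exist, the
one whose parameters lie inside (a padded version of) the sampled
physiological envelope is preferred — the same prior the ML inverter
absorbs from its training distribution. Reports carry the raw residuals
and a convergence flag; sweep points failing to invert are recorded and
skipped.

### Worked example and its uncertainty

For the bundled example record (FiO2 0.38, Hb 9.30 g/dL, SaO2 0.94,
pH 7.364, PaO2 69.0, PaCO2 39.4, mean PACO2 30.1 mmHg, CO 5.25 L/min,
VCO2 187 mL/min, R 0.74) the package computes VenAd ≈ 19.8 % and
shunt ≈ 15.2 % of pulmonary blood flow (low V/Q ≈ 4.6 %). The shunt/low-V/Q
split — unlike VenAd — is structurally sensitive to how a model turns the
V/Q distribution into a mean alveolar PCO2: the recovered shunt moves
≈1.3 pp per mmHg of mean PACO2 at this operating point, and plausible
alternative weighting/discretization conventions (quantile-binned
compartments, output-weighted means) shift the model's mean PACO2 by
2–4 mmHg at fixed physiology. Reference implementations of this method
family that use a different (unpublished) mean-PACO2 formulation can
therefore report a shunt several percentage points lower for the same
record while agreeing on VenAd; comparisons of the split across
implementations should be read with that caveat.

## Evaluation statistics

Agreement between actual and blinded-estimated shunt is summarized by OLS
of actual on estimate (slope, intercept, R², 95 % CI, p), by the
deviation vector actual − estimate (mean/SD, median/IQR, range, skewness,
Shapiro–Wilk normality), and by Gaussian-KDE overlays (Silverman
bandwidth). The deviation sign convention is configurable; the default is
actual − estimate.

## Problem sizes used by the checks

The acceptance script and the end-to-end test run the full design:
15,236 scenarios (14,736 train / 500 test) and 500 training epochs. Unit
tests use a 600-scenario dataset and lighter networks. The back-calculation
round-trip check inverts 50 independently drawn scenarios; sensitivity
sweeps use 3–9 grid points per input (±10 % relative; ±2 mmHg for the two
PCO2 inputs; ±0.05 for pH, a physiologic measurement-error scale rather
than a relative one).

## Known limitations

* No dead-space compartment beyond the log-normal high-V/Q tail; no
  diffusion limitation; no hypoxic vasoconstriction; no temperature
  correction of blood gases.
* The pK′ of the bicarbonate system is treated as pH-independent.
* VenAd inherits the ideal-compartment construction's small (−0.2 pp)
  undershoot in near-homogeneous lungs.
* The shunt/low-V/Q split depends on the mean-PACO2 formulation (above);
  only the ventilation-weighted convention is implemented.
* Recovery accuracy is demonstrated on noiseless model-generated records;
  the sensitivity sweeps, not the round-trip tests, indicate behavior
  under measurement error.
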