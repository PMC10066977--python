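# vqshunt

Single-FiO2 quantification of pulmonary gas exchange: a
ventilation/perfusion (V/Q) lung simulator plus two inverters that recover
**true shunt** and **low-V/Q blood flow** from ten bedside monitoring
values measured at one inspired-oxygen fraction.

## The problem

Hypoxemia has two very different mechanical causes: blood traversing
unventilated lung (**shunt**, V/Q = 0) and blood traversing poorly
ventilated lung (**low V/Q**, 0 < V/Q ≪ 1). The classic three-compartment
analysis lumps both into a single *venous admixture* (VenAd) figure, yet
the distinction matters at the bedside — consolidation with large shunt
invites recruitment and PEEP, while micro-thrombotic low-V/Q disease does
not. Reference methods that separate the two require measurements at
several inspired-oxygen settings, with re-equilibration delays and
FiO2-induced artifacts.

This package implements and evaluates, *in silico*, a single-FiO2
alternative for critical-care research: adding the mean alveolar PCO2
(measurable by volumetric capnography) to the usual blood-gas, calorimetry
and cardiac-output data makes the shunt / low-V/Q split identifiable from
one snapshot of ten observables — FiO2, Hb, SaO2, pH, PaO2, PaCO2, mean
PACO2, cardiac output, VCO2 and R.

## The model

Pulmonary blood flow is distributed log-normally over 20 compartments with
`V/Q = μ·exp(σz)` (`μ` = median V/Q of perfusion, `σ` = log SD) plus a
shunt compartment (fraction `s`, V/Q = 0). Each compartment is solved for
steady-state O2, CO2 and N2 exchange (N2 closes alveolar pressure at
PB − PH2O); arterial blood is the perfusion-weighted content mixture; the
mixed-venous state closes through the Fick principle. Saturation follows
the Severinghaus curve with Bohr/base-excess P50 shifts, CO2 content the
Douglas whole-blood formulation, and acid–base the Van Slyke relation.
Venous admixture uses the Riley construction

    VenAd = (Cc'O2 − CaO2) / (Cc'O2 − CvO2),   low V/Q = VenAd − shunt,

with end-capillary content evaluated at the ideal alveolar PO2. The
simulated universe (defaults: 15,236 scenarios, FiO2 titrated so SaO2 ∈
[0.87, 0.98], split 14,736 train / 500 test) feeds two inverters:

* **shuntml** — a 10-feature dense MLP (6×128 ReLU units, 84,097
  parameters, MSE loss, adaptive-gradient training) that predicts shunt
  from the ten observables;
* **backcalc** — a direct solve of the forward model for
  `(s, σ, μ)` matching the observed (SaO2, PaCO2, mean PACO2), plus
  input-error sensitivity sweeps.

See `docs/methods.md` for formulations, conventions and limitations.

## Worked example

Invert a single bedside record from the command line:

```bash
cat > record.json <<'EOF'
{"fio2": 0.38, "hb": 9.30, "sao2": 0.94, "ph": 7.364, "pao2": 69.0,
 "paco2": 39.4, "mean_paco2": 30.1, "co": 5.25, "vco2": 187.0, "r": 0.74}
EOF
vqshunt backcalc --record record.json
```

prints

```json
{
  "shunt_est": 15.177475013471318,
  "venad_est": 19.761021416151607,
  "low_vq_est": 4.583546402680289,
  "log_sd_est": 1.1191005417329503,
  "mean_vq_est": 0.6450187694443166,
  "residuals": {
    "sao2": 1.1102230246251565e-16,
    "paco2": 1.1581846592889633e-12,
    "mean_paco2": 0.0
  },
  "converged": true
}
```

Reading: of this patient's pulmonary blood flow, 19.8 % behaves as venous
admixture; the model attributes 15.2 pp of that to true shunt and 4.6 pp
to perfusion of low-V/Q regions, with the fitted distribution
(σ ≈ 1.12, median V/Q ≈ 0.65) reproducing the observed SaO2, PaCO2 and
mean PACO2 to numerical precision. The shunt/low-V/Q split (not VenAd)
depends structurally on the mean-alveolar-PCO2 formulation — see the
worked-example section of `docs/methods.md` before comparing against
other implementations.

The same library surface is available from Python:

```python
from vqshunt import EXAMPLE_RECORD, recover, sensitivity_sweep
report = recover(EXAMPLE_RECORD)
sweep = sensitivity_sweep(EXAMPLE_RECORD, "mean_paco2")  # input-error curve
```

Other subcommands: `vqshunt simulate` (scenario CSV), `train`, `evaluate`
(blinded test-set regression + error reports), `sensitivity` (tidy sweep
CSVs), `pipeline` (the full seeded loop).

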