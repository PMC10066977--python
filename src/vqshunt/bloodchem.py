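"""Blood oxygen and carbon dioxide carriage.

Implements the dissociation-curve, content and acid-base relations that every
lung-model evaluation calls, plus the Fick mixed-venous closure:

* Hemoglobin-O2 saturation: the Severinghaus (1979) curve
  ``S = (x^3 + 150 x) / (x^3 + 150 x + 23400)`` evaluated at a *virtual* PO2
  ``x = PO2 * P50_ref / P50_invivo``, where the in-vivo P50 carries the Bohr
  shift ``P50 = P50st * 10**(-0.48 (pH - 7.40) + 0.0013 BE)``.  P50st scales
  the whole curve left/right (hemoglobin-O2 affinity).
* O2 content: Hufner binding plus physically dissolved O2.
* CO2 content: Douglas, Jones & Reed (1988) — plasma CO2 from
  Henderson-Hasselbalch scaled to whole blood with a hemoglobin/saturation
  correction that reproduces the Haldane effect.
* Acid-base: the Van Slyke buffer relation of Siggaard-Andersen linking pH,
  PCO2 and base excess at a given hemoglobin.

All functions are numpy ufunc-like: they broadcast over array inputs, which
is what makes the batched 21-compartment solver fast.

Units: pressures mmHg, contents mL/dL (CO2 content also mL/dL), Hb g/dL,
BE mEq/L, flows L/min, VO2/VCO2 mL/min STPD.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import DEFAULT_CONSTANTS, PhysConstants

__all__ = [
    "BloodParams",
    "BloodGasState",
    "MetabolicState",
    "InfeasibleScenarioError",
    "in_vivo_p50",
    "odc_saturation",
    "odc_po2",
    "o2_content",
    "co2_content",
    "base_excess",
    "acid_base_ph",
    "blood_state_from_contents",
    "mixed_venous",
]


class InfeasibleScenarioError(ValueError):
    """The requested scenario has no physically possible blood state."""


@dataclass(frozen=True)
class BloodParams:
    """Hemoglobin, O2 affinity and metabolic acid-base status of the blood."""

    hb: float              # g/dL
    p50st: float = 26.86   # mmHg, standard P50
    be: float = 0.0        # mEq/L

    def __post_init__(self) -> None:
        if self.hb <= 0:
            raise ValueError(f"Hb must be positive, got {self.hb}")
        if not 15.0 <= self.p50st <= 40.0:
            raise ValueError(f"P50st out of [15, 40]: {self.p50st}")
        if not -30.0 <= self.be <= 30.0:
            raise ValueError(f"BE out of [-30, 30]: {self.be}")


@dataclass(frozen=True)
class BloodGasState:
    """One blood sample: tensions, pH, saturation and total gas contents."""

    po2: float         # mmHg
    pco2: float        # mmHg
    ph: float
    so2: float         # fraction
    o2_content: float  # mL/dL
    co2_content: float  # mL/dL

    def __post_init__(self) -> None:
        if not 0.0 <= self.so2 <= 1.0:
            raise ValueError(f"SO2 out of [0,1]: {self.so2}")
        if self.o2_content < 0 or self.co2_content < 0:
            raise ValueError("gas contents must be non-negative")
        # wide enough for extreme high-V/Q end-capillary blood (PCO2 -> 0);
        # arterial and venous states lie well inside [6.8, 7.8]
        if not 6.0 <= self.ph <= 8.5:
            raise ValueError(f"pH out of [6.0, 8.5]: {self.ph}")


@dataclass(frozen=True)
class MetabolicState:
    """Whole-body gas exchange: VCO2, R and cardiac output (VO2 derived)."""

    vco2: float  # mL/min STPD
    r: float     # respiratory exchange ratio VCO2/VO2
    co: float    # L/min
    vo2: float = field(init=False)

    def __post_init__(self) -> None:
        if self.vco2 <= 0 or self.r <= 0 or self.co <= 0:
            raise ValueError("VCO2, R and CO must all be positive")
        object.__setattr__(self, "vo2", self.vco2 / self.r)


# ---------------------------------------------------------------------------
# Oxyhemoglobin dissociation
# ---------------------------------------------------------------------------

def in_vivo_p50(ph, be=0.0, p50st=26.86, constants: PhysConstants = DEFAULT_CONSTANTS):
    """In-vivo P50: standard P50 shifted by the Bohr effect (pH) and BE.

    Acidemia right-shifts the curve (higher P50); the small BE term carries
    the residual direct-CO2/carbamino influence at fixed pH.
    """
    shift = constants.bohr_ph * (np.asarray(ph) - 7.40) + constants.be_p50 * np.asarray(be)
    return np.asarray(p50st) * 10.0 ** shift


def _sev(x):
    """Severinghaus 1979 curve at virtual PO2 x (curve's own P50 = 26.86)."""
    p = x * x * x + 150.0 * x
    return p / (p + 23400.0)


def _sev_inverse(so2):
    """Exact inverse of the Severinghaus curve via Cardano (unique real root)."""
    so2 = np.asarray(so2, dtype=float)
    k = 23400.0 * so2 / (1.0 - so2)
    # x^3 + 150 x - k = 0, discriminant always positive
    disc = np.sqrt((k / 2.0) ** 2 + 125000.0)
    return np.cbrt(k / 2.0 + disc) + np.cbrt(k / 2.0 - disc)


def odc_saturation(po2, ph=7.40, pco2=40.0, be=0.0, p50st=26.86,
                   constants: PhysConstants = DEFAULT_CONSTANTS):
    """Hemoglobin O2 saturation (fraction) at the given tension and milieu.

    ``pco2`` is accepted for interface symmetry; its Bohr influence is carried
    through pH (computed from PCO2/BE upstream), so it does not shift the
    curve again here.
    """
    po2 = np.asarray(po2, dtype=float)
    if np.any(po2 < 0):
        raise ValueError("PO2 must be non-negative")
    p50 = in_vivo_p50(ph, be, p50st, constants)
    return _sev(po2 * (constants.p50_reference / p50))


def odc_po2(so2, ph=7.40, pco2=40.0, be=0.0, p50st=26.86,
            constants: PhysConstants = DEFAULT_CONSTANTS):
    """Inverse dissociation curve: PO2 (mmHg) at the given saturation."""
    so2 = np.asarray(so2, dtype=float)
    if np.any((so2 <= 0) | (so2 >= 1)):
        raise ValueError("SO2 must lie strictly inside (0, 1) for inversion")
    p50 = in_vivo_p50(ph, be, p50st, constants)
    return _sev_inverse(so2) * (p50 / constants.p50_reference)


# ---------------------------------------------------------------------------
# Contents
# ---------------------------------------------------------------------------

def o2_content(po2, so2, hb, constants: PhysConstants = DEFAULT_CONSTANTS):
    """Total O2 content, mL/dL: bound (Hufner) + dissolved."""
    return constants.hufner * np.asarray(hb) * np.asarray(so2) \
        + constants.o2_solubility * np.asarray(po2)


def co2_content(pco2, ph, so2, hb, constants: PhysConstants = DEFAULT_CONSTANTS):
    """Total blood CO2 content, mL/dL (Douglas et al. 1988).

    Plasma CO2 (dissolved + bicarbonate) from Henderson-Hasselbalch, scaled
    to whole blood by a factor depending on Hb and SO2; lower SO2 raises
    content at fixed PCO2 (Haldane effect).
    """
    pco2 = np.asarray(pco2, dtype=float)
    ph = np.asarray(ph, dtype=float)
    s = constants.co2_solubility
    plasma_mmol = s * pco2 * (1.0 + 10.0 ** (ph - constants.pk_bicarb))
    blood_factor = 1.0 - (0.0289 * np.asarray(hb)) / (
        (3.352 - 0.456 * np.asarray(so2)) * (8.142 - ph))
    return 2.226 * plasma_mmol * blood_factor


# ---------------------------------------------------------------------------
# Acid-base (Van Slyke)
# ---------------------------------------------------------------------------

def _hco3_ref(constants: PhysConstants) -> float:
    """Plasma bicarbonate at the normal point (pH 7.40, PCO2 40), mmol/L."""
    return constants.co2_solubility * 40.0 * 10.0 ** (7.40 - constants.pk_bicarb)


def base_excess(ph, pco2, hb, constants: PhysConstants = DEFAULT_CONSTANTS):
    """Base excess (mEq/L) from pH and PCO2 at a given Hb (Van Slyke)."""
    ph = np.asarray(ph, dtype=float)
    pco2 = np.asarray(pco2, dtype=float)
    hb = np.asarray(hb, dtype=float)
    hco3 = constants.co2_solubility * pco2 * 10.0 ** (ph - constants.pk_bicarb)
    return (1.0 - 0.0143 * hb) * (hco3 - _hco3_ref(constants)
                                  + (9.5 + 1.63 * hb) * (ph - 7.40))


def acid_base_ph(pco2, be, hb, constants: PhysConstants = DEFAULT_CONSTANTS):
    """pH from PCO2 and base excess (inverts the Van Slyke relation).

    Monotone decreasing in PCO2, increasing in BE; pH(40, 0) = 7.40 by
    construction of the buffer reference point.
    """
    pco2 = np.asarray(pco2, dtype=float)
    if np.any(pco2 <= 0):
        raise ValueError("PCO2 must be positive")
    be = np.asarray(be, dtype=float)
    hb = np.asarray(hb, dtype=float)
    s, pk = constants.co2_solubility, constants.pk_bicarb
    href = _hco3_ref(constants)
    buf = 9.5 + 1.63 * hb
    scale = 1.0 - 0.0143 * hb
    # Newton on f(pH) = BE(pH) - be, strictly increasing in pH
    ph = np.full(np.broadcast(pco2, be, hb).shape, 7.40, dtype=float)
    for _ in range(12):
        hco3 = s * pco2 * 10.0 ** (ph - pk)
        f = scale * (hco3 - href + buf * (ph - 7.40)) - be
        df = scale * (np.log(10.0) * hco3 + buf)
        step = np.clip(f / df, -0.5, 0.5)
        ph = np.clip(ph - step, 6.0, 8.2)
        if np.all(np.abs(step) < 1e-12):
            break
    return ph


# ---------------------------------------------------------------------------
# Contents -> state inversion and the Fick venous loop
# ---------------------------------------------------------------------------

def _state_arrays_from_contents(o2c, co2c, hb, p50st, be,
                                constants: PhysConstants = DEFAULT_CONSTANTS,
                                tol: float = 1e-10, max_iter: int = 60):
    """Vectorized 2-D Newton solve for (PO2, PCO2) given both gas contents.

    Returns (po2, pco2, ph, so2) arrays.  Raises InfeasibleScenarioError if
    any requested O2 content is not attainable (<= dissolved-only floor or
    above full saturation at extreme tension).
    """
    o2c = np.atleast_1d(np.asarray(o2c, dtype=float))
    co2c = np.atleast_1d(np.asarray(co2c, dtype=float))
    shape = np.broadcast(o2c, co2c, np.asarray(hb), np.asarray(p50st),
                         np.asarray(be)).shape
    o2c, co2c = np.broadcast_to(o2c, shape).copy(), np.broadcast_to(co2c, shape).copy()
    hb = np.broadcast_to(np.asarray(hb, dtype=float), shape)
    p50st = np.broadcast_to(np.asarray(p50st, dtype=float), shape)
    be = np.broadcast_to(np.asarray(be, dtype=float), shape)

    if np.any(o2c <= 0.0):
        raise InfeasibleScenarioError("O2 content must be positive")

    # initial PCO2 by fixed-point on the plasma relation, then PO2 via the ODC
    pco2 = np.full(shape, 45.0)
    for _ in range(4):
        ph = acid_base_ph(pco2, be, hb, constants)
        bf = 1.0 - (0.0289 * hb) / ((3.352 - 0.456 * 0.8) * (8.142 - ph))
        denom = 2.226 * constants.co2_solubility * (1.0 + 10.0 ** (ph - constants.pk_bicarb)) * bf
        pco2 = np.clip(co2c / denom, 3.0, 250.0)
    ph = acid_base_ph(pco2, be, hb, constants)
    so2_guess = np.clip((o2c - constants.o2_solubility * 40.0) / (constants.hufner * hb),
                        1e-6, 0.99999)
    po2 = np.clip(odc_po2(so2_guess, ph, pco2, be, p50st, constants), 0.5, 650.0)

    def residuals(po2, pco2):
        ph = acid_base_ph(pco2, be, hb, constants)
        so2 = odc_saturation(po2, ph, pco2, be, p50st, constants)
        f1 = o2_content(po2, so2, hb, constants) - o2c
        f2 = co2_content(pco2, ph, so2, hb, constants) - co2c
        return f1, f2, ph, so2

    f1, f2, ph, so2 = residuals(po2, pco2)
    for _ in range(max_iter):
        if np.all((np.abs(f1) < tol) & (np.abs(f2) < tol)):
            break
        e1 = 1e-5 * (1.0 + po2)
        e2 = 1e-5 * (1.0 + pco2)
        g1, g2, _, _ = residuals(po2 + e1, pco2)
        h1, h2, _, _ = residuals(po2, pco2 + e2)
        j11 = (g1 - f1) / e1
        j21 = (g2 - f2) / e1
        j12 = (h1 - f1) / e2
        j22 = (h2 - f2) / e2
        det = j11 * j22 - j12 * j21
        det = np.where(np.abs(det) < 1e-300, 1e-300, det)
        dpo2 = -(f1 * j22 - f2 * j12) / det
        dpco2 = -(j11 * f2 - j21 * f1) / det
        po2 = np.clip(po2 + np.clip(dpo2, -80.0, 80.0), 0.05, 680.0)
        pco2 = np.clip(pco2 + np.clip(dpco2, -40.0, 40.0), 0.5, 280.0)
        f1, f2, ph, so2 = residuals(po2, pco2)

    ok = (np.abs(f1) < 1e-6) & (np.abs(f2) < 1e-6)
    return po2, pco2, ph, so2, ok


def blood_state_from_contents(o2c: float, co2c: float, params: BloodParams,
                              constants: PhysConstants = DEFAULT_CONSTANTS) -> BloodGasState:
    """Blood gas state (tensions, pH, SO2) consistent with the given contents."""
    po2, pco2, ph, so2, ok = _state_arrays_from_contents(
        o2c, co2c, params.hb, params.p50st, params.be, constants)
    if not bool(ok[0]):
        raise InfeasibleScenarioError(
            f"no blood state matches contents O2={o2c:.3f}, CO2={co2c:.3f} mL/dL")
    return BloodGasState(po2=float(po2[0]), pco2=float(pco2[0]), ph=float(ph[0]),
                         so2=float(so2[0]), o2_content=float(o2c),
                         co2_content=float(co2c))


def mixed_venous(arterial: BloodGasState, metab: MetabolicState, params: BloodParams,
                 constants: PhysConstants = DEFAULT_CONSTANTS) -> BloodGasState:
    """Mixed-venous blood implied by the Fick principle.

    Venous O2 content = arterial - VO2/(10 CO); venous CO2 content =
    arterial + VCO2/(10 CO); the factor 10 converts mL/dL to mL/L.  Tensions,
    pH and SO2 are recovered by inverting the content relations.
    """
    cv_o2 = arterial.o2_content - metab.vo2 / (10.0 * metab.co)
    cv_co2 = arterial.co2_content + metab.vco2 / (10.0 * metab.co)
    if cv_o2 <= 0.0:
        raise InfeasibleScenarioError(
            f"venous O2 content {cv_o2:.3f} mL/dL <= 0: O2 delivery cannot meet VO2")
    return blood_state_from_contents(cv_o2, cv_co2, params, constants)
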