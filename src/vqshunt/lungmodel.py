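"""Forward ventilation/perfusion lung model.

Pulmonary blood flow is distributed log-normally over 20 gas-exchanging
compartments spanning a broad range of V/Q ratios, plus a separate shunt
compartment (V/Q = 0) that transmits mixed-venous blood unchanged.  Each
ventilated compartment is solved for steady-state O2, CO2 and N2 exchange:
the inspired-to-expired ventilation difference equals the net gas volume
taken up by blood (R != 1 and N2 flux), and N2 acts as the closure gas that
pins total alveolar pressure at barometric minus water vapor.

Compartment V/Q is defined on *expired* alveolar ventilation (the MIGET
convention).  With inspired-defined V/Q, low-V/Q units at high FiO2 can
absorb their entire inspired volume and have no steady solution (the
absorption-atelectasis regime); the expired-defined formulation always
admits one, with inspired ventilation vai = vq + net uptake.

A whole-lung evaluation iterates an outer fixed point: guess mixed-venous
blood, equilibrate all compartments, mix arterial blood by perfusion-weighted
content averaging (shunt contributes venous blood), update the venous state
through the Fick principle, repeat to convergence.  Mean alveolar PCO2 is the
ventilation-weighted mean of compartmental PACO2 — the model counterpart of
the volumetric-capnography measurement.

The module exposes a scalar public API (``run_forward``, ``titrate_fio2``,
``equilibrate_compartment``) built on an internal batch engine that solves
thousands of scenarios simultaneously as numpy arrays; the scenario generator
drives the batch engine directly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import ndtr

from . import bloodchem as bc
from .bloodchem import (BloodGasState, BloodParams, InfeasibleScenarioError,
                        MetabolicState)
from .config import DEFAULT_CONSTANTS, DEFAULT_SOLVER, PhysConstants, SolverSettings

__all__ = [
    "LungInputs",
    "CompartmentState",
    "ForwardResult",
    "ConvergenceError",
    "ScenarioRejected",
    "perfusion_distribution",
    "equilibrate_compartment",
    "run_forward",
    "titrate_fio2",
    "venad",
    "ideal_alveolar_po2",
]


class ConvergenceError(RuntimeError):
    """A compartment or whole-lung solve failed to converge."""


class ScenarioRejected(Exception):
    """No FiO2 in [0.21, 0.99] places SaO2 inside the required band."""


@dataclass(frozen=True)
class LungInputs:
    """The nine physiological inputs that drive one forward simulation."""

    shunt_frac: float        # fraction of pulmonary blood flow at V/Q = 0
    log_sd: float            # dispersion of the log-normal perfusion distribution
    mean_vq: float           # median (geometric mean) V/Q of perfused lung
    metab: MetabolicState
    blood: BloodParams

    def __post_init__(self) -> None:
        if not 0.0 <= self.shunt_frac <= 0.5:
            raise ValueError(f"shunt fraction out of [0, 0.5]: {self.shunt_frac}")
        if self.log_sd <= 0:
            raise ValueError("log SD must be positive")
        if self.mean_vq <= 0:
            raise ValueError("mean V/Q must be positive")


@dataclass(frozen=True)
class CompartmentState:
    """Steady state of one V/Q compartment."""

    vq: float                # expired alveolar ventilation / perfusion
    q_frac: float            # fraction of total pulmonary blood flow
    v_frac: float            # fraction of total expired alveolar ventilation
    pao2: float              # mmHg
    paco2: float             # mmHg
    pan2: float              # mmHg
    endcap: BloodGasState    # end-capillary blood
    vai: float = float("nan")       # inspired ventilation per unit perfusion
    o2_flux: float = float("nan")   # mL O2 /min per L/min perfusion (into blood)
    co2_flux: float = float("nan")  # mL CO2/min per L/min perfusion (out of blood)


@dataclass(frozen=True)
class ForwardResult:
    """Whole-lung steady state: bedside observables plus truth labels."""

    inputs: LungInputs
    fio2: float
    sao2: float
    pao2: float
    paco2: float
    ph: float
    mean_paco2: float
    venad: float             # venous admixture, fraction of pulmonary blood flow
    low_vq: float            # venad - shunt_frac
    arterial: BloodGasState
    venous: BloodGasState
    compartments: tuple[CompartmentState, ...] = ()
    n_iter: int = 0


# ---------------------------------------------------------------------------
# Perfusion distribution
# ---------------------------------------------------------------------------

def _grid(n: int, span: float) -> tuple[np.ndarray, np.ndarray]:
    """Standard-normal bin centers and bin-integrated masses (renormalized)."""
    edges = np.linspace(-span, span, n + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    q = np.diff(ndtr(edges))
    return centers, q / q.sum()


def perfusion_distribution(mean_vq: float, log_sd: float, n_compartments: int = 20,
                           span: float = 3.5) -> list[tuple[float, float]]:
    """Log-normal perfusion distribution over V/Q compartments.

    Returns ``n_compartments`` pairs ``(vq, q_frac)`` on log-equally-spaced
    V/Q centers covering ``mean_vq * exp(+-span*log_sd)``; q_frac is the
    log-normal mass integrated over each bin, renormalized to sum to 1.
    The shunt compartment is handled separately by the caller.
    """
    if mean_vq <= 0 or log_sd <= 0:
        raise ValueError("mean_vq and log_sd must be positive")
    zc, q = _grid(n_compartments, span)
    vq = mean_vq * np.exp(log_sd * zc)
    return list(zip(vq.tolist(), q.tolist()))


# ---------------------------------------------------------------------------
# Batched compartment equilibration
# ---------------------------------------------------------------------------

def _equilibrate_batch(vq, pio2, pin2, cv_o2c, cv_co2c, pv_n2, hb, p50st, be,
                       pv_po2, pv_pco2,
                       constants: PhysConstants, solver: SolverSettings,
                       warm: tuple[np.ndarray, np.ndarray] | None = None):
    """Solve steady-state (PAO2, PACO2) for every ventilated compartment.

    All arguments broadcast to shape (S, C): ``vq`` per compartment, the
    rest per scenario (S, 1).  Unknowns are the two alveolar tensions; N2
    closes total pressure and the inspired ventilation follows from net
    uptake.  Damped Newton with finite-difference Jacobian, warm-startable.

    Returns (pao2, paco2, vai, cc_o2, cc_co2, converged).
    """
    pd_ = constants.dry_pressure
    kk = 10.0 * constants.k_gas   # contents are per dL, flows per L
    an2 = constants.n2_solubility

    shape = np.broadcast_shapes(vq.shape, pio2.shape, hb.shape)
    flat = lambda a: np.broadcast_to(a, shape).ravel()
    vq_f, pio2_f, pin2_f = flat(vq), flat(pio2), flat(pin2)
    cvo_f, cvc_f, pvn2_f = flat(cv_o2c), flat(cv_co2c), flat(pv_n2)
    hb_f, p50_f, be_f = flat(hb), flat(p50st), flat(be)

    def residuals(pao2, paco2, ix):
        ph = bc.acid_base_ph(paco2, be_f[ix], hb_f[ix], constants)
        so2 = bc.odc_saturation(pao2, ph, paco2, be_f[ix], p50_f[ix], constants)
        cc_o2 = bc.o2_content(pao2, so2, hb_f[ix], constants)
        cc_co2 = bc.co2_content(paco2, ph, so2, hb_f[ix], constants)
        pan2 = pd_ - pao2 - paco2
        d_o = cc_o2 - cvo_f[ix]
        d_c = cc_co2 - cvc_f[ix]
        d_n = an2 * (pan2 - pvn2_f[ix])
        vai = vq_f[ix] + (kk / pd_) * (d_o + d_c + d_n)
        f1 = ((vai * pio2_f[ix] - vq_f[ix] * pao2) / kk - d_o) / (1.0 + vq_f[ix])
        f2 = ((-vq_f[ix] * paco2) / kk - d_c) / (1.0 + vq_f[ix])
        return f1, f2, vai, cc_o2, cc_co2

    if warm is not None:
        pao2 = np.broadcast_to(warm[0], shape).ravel().copy()
        paco2 = np.broadcast_to(warm[1], shape).ravel().copy()
    else:
        paco2 = np.clip(flat(pv_pco2) / (1.0 + vq_f), 0.2, None)
        pao2 = (pio2_f * vq_f + flat(pv_po2)) / (1.0 + vq_f)
    pao2 = np.clip(pao2, 0.05, pd_ - 0.2)
    paco2 = np.clip(paco2, 0.02, pd_ - pao2 - 0.1)

    n = pao2.size
    all_ix = np.arange(n)
    F1 = np.empty(n)
    F2 = np.empty(n)
    VAI = np.empty(n)
    CCO = np.empty(n)
    CCC = np.empty(n)
    F1[:], F2[:], VAI[:], CCO[:], CCC[:] = residuals(pao2, paco2, all_ix)

    tol = solver.newton_tol
    act = np.flatnonzero((np.abs(F1) > tol) | (np.abs(F2) > tol))
    for _ in range(solver.max_newton_iter):
        if act.size == 0:
            break
        x, y = pao2[act], paco2[act]
        f1, f2 = F1[act], F2[act]
        e1 = 1e-5 * (1.0 + x)
        e2 = 1e-5 * (1.0 + y)
        g1, g2, _, _, _ = residuals(x + e1, y, act)
        h1, h2, _, _, _ = residuals(x, y + e2, act)
        j11 = (g1 - f1) / e1
        j21 = (g2 - f2) / e1
        j12 = (h1 - f1) / e2
        j22 = (h2 - f2) / e2
        det = j11 * j22 - j12 * j21
        det = np.where(np.abs(det) < 1e-300, 1e-300, det)
        dx = -(f1 * j22 - f2 * j12) / det
        dy = -(j11 * f2 - j21 * f1) / det
        x = np.clip(x + np.clip(dx, -40.0, 40.0), 0.05, pd_ - 0.2)
        y = np.clip(y + np.clip(dy, -25.0, 25.0), 0.02, pd_ - x - 0.1)
        pao2[act], paco2[act] = x, y
        f1, f2, vai_a, cco_a, ccc_a = residuals(x, y, act)
        F1[act], F2[act] = f1, f2
        VAI[act], CCO[act], CCC[act] = vai_a, cco_a, ccc_a
        act = act[(np.abs(f1) > tol) | (np.abs(f2) > tol)]

    converged = (np.abs(F1) <= tol) & (np.abs(F2) <= tol)
    rs = lambda a: a.reshape(shape)
    return rs(pao2), rs(paco2), rs(VAI), rs(CCO), rs(CCC), rs(converged)


# ---------------------------------------------------------------------------
# Batched whole-lung forward solve
# ---------------------------------------------------------------------------

def _forward_batch(params: dict[str, np.ndarray], fio2: np.ndarray,
                   constants: PhysConstants = DEFAULT_CONSTANTS,
                   solver: SolverSettings = DEFAULT_SOLVER,
                   state: dict[str, np.ndarray] | None = None,
                   venous_tol: float | None = None,
                   detail: bool = False) -> dict[str, np.ndarray]:
    """Run the forward model for a batch of scenarios.

    ``params`` holds per-scenario arrays: shunt, log_sd, mean_vq, vco2, r,
    co, hb, p50st, be.  ``state`` is an optional warm start (previous venous
    contents and compartment tensions) from a nearby FiO2 — used heavily by
    the titration loop.  Returns a dict of per-scenario output arrays plus a
    reusable ``state``; scenarios that fail are flagged, never raised.
    """
    shunt = np.asarray(params["shunt"], dtype=float)
    S = shunt.shape[0]
    log_sd = np.asarray(params["log_sd"], dtype=float)
    mean_vq = np.asarray(params["mean_vq"], dtype=float)
    vco2 = np.asarray(params["vco2"], dtype=float)
    r = np.asarray(params["r"], dtype=float)
    co = np.asarray(params["co"], dtype=float)
    hb = np.asarray(params["hb"], dtype=float)
    p50st = np.asarray(params["p50st"], dtype=float)
    be = np.asarray(params["be"], dtype=float)
    fio2 = np.broadcast_to(np.asarray(fio2, dtype=float), (S,))
    vo2 = vco2 / r

    pd_ = constants.dry_pressure
    zc, qbin = _grid(solver.n_compartments, solver.grid_span)
    vq = mean_vq[:, None] * np.exp(log_sd[:, None] * zc[None, :])   # (S, C)
    pio2 = (fio2 * pd_)[:, None]
    pin2 = ((1.0 - fio2) * pd_)[:, None]

    col = lambda a: a[:, None]
    hb_c, p50_c, be_c = col(hb), col(p50st), col(be)

    fick_o2 = vo2 / (10.0 * co)
    fick_co2 = vco2 / (10.0 * co)

    if state is not None:
        cv_o2c = state["cv_o2c"].copy()
        cv_co2c = state["cv_co2c"].copy()
        pv_n2 = state["pv_n2"].copy()
        warm = (state["pao2_c"].copy(), state["paco2_c"].copy())
    else:
        sa0 = 0.96
        ca_o2_0 = constants.hufner * hb * sa0 + constants.o2_solubility * 90.0
        ph40 = bc.acid_base_ph(np.full(S, 40.0), be, hb, constants)
        ca_co2_0 = bc.co2_content(np.full(S, 40.0), ph40, sa0, hb, constants)
        cv_o2c = np.maximum(ca_o2_0 - fick_o2, 0.30)
        cv_co2c = ca_co2_0 + fick_co2
        pv_n2 = (1.0 - fio2) * pd_
        warm = None

    tol = solver.venous_tol if venous_tol is None else venous_tol
    damp = solver.venous_damping
    infeasible = np.zeros(S, dtype=bool)
    comp_ok = np.ones(S, dtype=bool)
    n_iter = np.zeros(S, dtype=int)
    converged = np.zeros(S, dtype=bool)
    prev_delta = None  # for Aitken extrapolation of the venous fixed point

    # venous tensions for the cold-start compartment guess only
    pv_po2, pv_pco2, _, _, ok_v = bc._state_arrays_from_contents(
        cv_o2c, cv_co2c, hb, p50st, be, constants, tol=1e-8, max_iter=40)
    infeasible |= ~ok_v

    pao2_c = paco2_c = vai = cc_o2 = cc_co2 = None
    ca_o2 = cv_o2c + fick_o2
    ca_co2 = cv_co2c - fick_co2
    pa_n2 = pv_n2.copy()

    for it in range(solver.max_outer_iter):
        pao2_c, paco2_c, vai, cc_o2, cc_co2, okc = _equilibrate_batch(
            vq, pio2, pin2, col(cv_o2c), col(cv_co2c), col(pv_n2),
            hb_c, p50_c, be_c, col(pv_po2), col(pv_pco2),
            constants, solver, warm=warm)
        warm = (pao2_c, paco2_c)
        comp_ok = okc.all(axis=1)

        pan2_c = pd_ - pao2_c - paco2_c
        mix_o2 = (cc_o2 * qbin).sum(axis=1)
        mix_co2 = (cc_co2 * qbin).sum(axis=1)
        mix_n2 = (pan2_c * qbin).sum(axis=1)
        ca_o2 = (1.0 - shunt) * mix_o2 + shunt * cv_o2c
        ca_co2 = (1.0 - shunt) * mix_co2 + shunt * cv_co2c
        pa_n2 = (1.0 - shunt) * mix_n2 + shunt * pv_n2

        cv_o2_new = ca_o2 - fick_o2
        cv_co2_new = ca_co2 + fick_co2
        infeasible |= cv_o2_new <= 0.05
        cv_o2_new = np.maximum(cv_o2_new, 0.05)

        delta = np.stack([cv_o2_new - cv_o2c, cv_co2_new - cv_co2c,
                          constants.n2_solubility * (pa_n2 - pv_n2)])
        newly = (np.abs(delta) < tol).all(axis=0) & ~infeasible
        n_iter = np.where(newly & ~converged, it + 1, n_iter)
        converged = newly

        # relaxed update with periodic Aitken extrapolation: the venous fixed
        # point is linearly convergent with a contraction that approaches 1
        # for low-V/Q-dominated scenarios, so plain (damped) iteration is slow
        gain = np.ones_like(delta)
        if prev_delta is not None and (it % 3) == 2:
            with np.errstate(divide="ignore", invalid="ignore"):
                lam = delta / prev_delta
            lam = np.where(np.isfinite(lam), np.clip(lam, -0.9, 0.97), 0.0)
            gain = 1.0 + lam / (1.0 - lam)
        prev_delta = delta
        step = (1.0 - damp) * gain * delta
        cv_o2c = np.maximum(cv_o2c + step[0], 0.05)
        cv_co2c = np.maximum(cv_co2c + step[1], 1.0)
        pv_n2 = np.clip(pv_n2 + step[2] / constants.n2_solubility, 0.0, pd_)
        if (converged | infeasible).all():
            break

    ok = converged & comp_ok & ~infeasible

    # arterial and venous states for the surviving scenarios
    pao2_a, paco2_a, ph_a, sao2, ok_a = bc._state_arrays_from_contents(
        ca_o2, ca_co2, hb, p50st, be, constants, tol=solver.content_tol)
    pv_po2, pv_pco2, ph_v, so2_v, ok_v = bc._state_arrays_from_contents(
        cv_o2c, cv_co2c, hb, p50st, be, constants, tol=solver.content_tol)
    ok &= ok_a & ok_v

    vent = qbin[None, :] * vq                      # expired ventilation weights
    mean_paco2 = (vent * paco2_c).sum(axis=1) / vent.sum(axis=1)

    # venous admixture from the ideal-compartment construction
    pao2_ideal = ideal_alveolar_po2(fio2, paco2_a, r, constants)
    ideal_ok = pao2_ideal > 0.5
    so2_ideal = bc.odc_saturation(np.clip(pao2_ideal, 0.5, None), ph_a, paco2_a,
                                  be, p50st, constants)
    cc_ideal = bc.o2_content(pao2_ideal, so2_ideal, hb, constants)
    with np.errstate(divide="ignore", invalid="ignore"):
        va = (cc_ideal - ca_o2) / (cc_ideal - cv_o2c)
    va = np.where(ideal_ok & (cc_ideal > cv_o2c), va, np.nan)

    out = {
        "fio2": fio2.copy(), "sao2": sao2, "pao2": pao2_a, "paco2": paco2_a,
        "ph": ph_a, "mean_paco2": mean_paco2,
        "ca_o2": ca_o2, "ca_co2": ca_co2, "cv_o2": cv_o2c, "cv_co2": cv_co2c,
        "pv_po2": pv_po2, "pv_pco2": pv_pco2, "ph_v": ph_v, "so2_v": so2_v,
        "venad": va, "low_vq": va - shunt,
        "ok": ok, "infeasible": infeasible, "n_iter": n_iter,
        "state": {"cv_o2c": cv_o2c, "cv_co2c": cv_co2c, "pv_n2": pv_n2,
                  "pao2_c": pao2_c, "paco2_c": paco2_c},
    }
    if detail:
        out["detail"] = {
            "vq": vq, "q_frac": (1.0 - shunt)[:, None] * qbin[None, :],
            "pao2_c": pao2_c, "paco2_c": paco2_c, "pan2_c": pd_ - pao2_c - paco2_c,
            "vai": vai, "cc_o2": cc_o2, "cc_co2": cc_co2, "pv_n2": pv_n2,
        }
    return out


def ideal_alveolar_po2(fio2, paco2, r, constants: PhysConstants = DEFAULT_CONSTANTS):
    """Ideal alveolar PO2 (classic alveolar gas equation with R correction)."""
    pio2 = np.asarray(fio2) * constants.dry_pressure
    return pio2 - np.asarray(paco2) * (np.asarray(fio2) + (1.0 - np.asarray(fio2)) / np.asarray(r))


def venad(cc_o2: float, ca_o2: float, cv_o2: float) -> float:
    """Venous admixture fraction from end-capillary, arterial, venous O2 contents."""
    if cc_o2 <= cv_o2:
        raise InfeasibleScenarioError(
            f"degenerate admixture: end-capillary content {cc_o2:.3f} <= venous {cv_o2:.3f}")
    return (cc_o2 - ca_o2) / (cc_o2 - cv_o2)


# ---------------------------------------------------------------------------
# Scalar public API
# ---------------------------------------------------------------------------

def _inputs_to_arrays(inputs_list: list[LungInputs]) -> dict[str, np.ndarray]:
    return {
        "shunt": np.array([x.shunt_frac for x in inputs_list]),
        "log_sd": np.array([x.log_sd for x in inputs_list]),
        "mean_vq": np.array([x.mean_vq for x in inputs_list]),
        "vco2": np.array([x.metab.vco2 for x in inputs_list]),
        "r": np.array([x.metab.r for x in inputs_list]),
        "co": np.array([x.metab.co for x in inputs_list]),
        "hb": np.array([x.blood.hb for x in inputs_list]),
        "p50st": np.array([x.blood.p50st for x in inputs_list]),
        "be": np.array([x.blood.be for x in inputs_list]),
    }


def equilibrate_compartment(vq: float, fio2: float, venous: BloodGasState,
                            blood: BloodParams, pv_n2: float | None = None,
                            constants: PhysConstants = DEFAULT_CONSTANTS,
                            solver: SolverSettings = DEFAULT_SOLVER) -> CompartmentState:
    """Steady state of a single compartment against a fixed venous inflow.

    ``pv_n2`` defaults to the inspired N2 tension (a lung fully equilibrated
    at this FiO2).  ``vq = 0`` returns the venous blood unchanged (shunt).
    """
    pd_ = constants.dry_pressure
    if vq < 0:
        raise ValueError("vq must be non-negative")
    if vq == 0.0:
        return CompartmentState(vq=0.0, q_frac=float("nan"), v_frac=0.0,
                                pao2=venous.po2, paco2=venous.pco2,
                                pan2=pd_ - venous.po2 - venous.pco2,
                                endcap=venous, vai=0.0, o2_flux=0.0, co2_flux=0.0)
    if pv_n2 is None:
        pv_n2 = (1.0 - fio2) * pd_
    one = np.ones((1, 1))
    pao2, paco2, vai, cc_o2, cc_co2, okc = _equilibrate_batch(
        vq * one, fio2 * pd_ * one, (1.0 - fio2) * pd_ * one,
        venous.o2_content * one, venous.co2_content * one, pv_n2 * one,
        blood.hb * one, blood.p50st * one, blood.be * one,
        venous.po2 * one, venous.pco2 * one, constants, solver)
    if not bool(okc[0, 0]):
        raise ConvergenceError(
            f"compartment vq={vq} failed to equilibrate at FiO2={fio2}")
    pao2, paco2, vai = float(pao2[0, 0]), float(paco2[0, 0]), float(vai[0, 0])
    ph = float(bc.acid_base_ph(paco2, blood.be, blood.hb, constants))
    so2 = float(bc.odc_saturation(pao2, ph, paco2, blood.be, blood.p50st, constants))
    endcap = BloodGasState(po2=pao2, pco2=paco2, ph=ph, so2=so2,
                           o2_content=float(cc_o2[0, 0]),
                           co2_content=float(cc_co2[0, 0]))
    return CompartmentState(
        vq=vq, q_frac=float("nan"), v_frac=float("nan"),
        pao2=pao2, paco2=paco2, pan2=pd_ - pao2 - paco2, endcap=endcap, vai=vai,
        o2_flux=10.0 * (endcap.o2_content - venous.o2_content),
        co2_flux=-10.0 * (endcap.co2_content - venous.co2_content))


def run_forward(inputs: LungInputs, fio2: float,
                constants: PhysConstants = DEFAULT_CONSTANTS,
                solver: SolverSettings = DEFAULT_SOLVER,
                save_compartments: bool = True) -> ForwardResult:
    """Solve the whole lung at a fixed FiO2 and emit the bedside observables."""
    if not 0.21 <= fio2 <= 1.0:
        raise ValueError(f"FiO2 out of [0.21, 1.0]: {fio2}")
    params = _inputs_to_arrays([inputs])
    out = _forward_batch(params, np.array([fio2]), constants, solver, detail=True)
    if bool(out["infeasible"][0]):
        raise InfeasibleScenarioError("venous O2 content fell to zero: scenario infeasible")
    if not bool(out["ok"][0]):
        raise ConvergenceError(
            f"forward model did not converge in {solver.max_outer_iter} iterations")

    g = lambda k: float(out[k][0])
    arterial = BloodGasState(po2=g("pao2"), pco2=g("paco2"), ph=g("ph"),
                             so2=g("sao2"), o2_content=g("ca_o2"),
                             co2_content=g("ca_co2"))
    venous = BloodGasState(po2=g("pv_po2"), pco2=g("pv_pco2"), ph=g("ph_v"),
                           so2=g("so2_v"), o2_content=g("cv_o2"),
                           co2_content=g("cv_co2"))
    compartments: list[CompartmentState] = []
    if save_compartments:
        d = out["detail"]
        pd_ = constants.dry_pressure
        vent = d["vq"][0] * d["q_frac"][0]
        vfrac = vent / vent.sum()
        shunt_state = CompartmentState(
            vq=0.0, q_frac=inputs.shunt_frac, v_frac=0.0,
            pao2=venous.po2, paco2=venous.pco2,
            pan2=pd_ - venous.po2 - venous.pco2, endcap=venous,
            vai=0.0, o2_flux=0.0, co2_flux=0.0)
        compartments.append(shunt_state)
        for j in range(solver.n_compartments):
            pao2_j = float(d["pao2_c"][0, j])
            paco2_j = float(d["paco2_c"][0, j])
            ph_j = float(bc.acid_base_ph(paco2_j, inputs.blood.be, inputs.blood.hb, constants))
            so2_j = float(bc.odc_saturation(pao2_j, ph_j, paco2_j, inputs.blood.be,
                                            inputs.blood.p50st, constants))
            endcap_j = BloodGasState(po2=pao2_j, pco2=paco2_j, ph=ph_j, so2=so2_j,
                                     o2_content=float(d["cc_o2"][0, j]),
                                     co2_content=float(d["cc_co2"][0, j]))
            compartments.append(CompartmentState(
                vq=float(d["vq"][0, j]), q_frac=float(d["q_frac"][0, j]),
                v_frac=float(vfrac[j]), pao2=pao2_j, paco2=paco2_j,
                pan2=float(d["pan2_c"][0, j]), endcap=endcap_j,
                vai=float(d["vai"][0, j]),
                o2_flux=10.0 * (endcap_j.o2_content - venous.o2_content),
                co2_flux=-10.0 * (endcap_j.co2_content - venous.co2_content)))

    return ForwardResult(
        inputs=inputs, fio2=fio2, sao2=g("sao2"), pao2=g("pao2"),
        paco2=g("paco2"), ph=g("ph"), mean_paco2=g("mean_paco2"),
        venad=g("venad"), low_vq=g("low_vq"), arterial=arterial, venous=venous,
        compartments=tuple(compartments), n_iter=int(out["n_iter"][0]))


def titrate_fio2(inputs: LungInputs, sat_band: tuple[float, float] = (0.87, 0.98),
                 target: float | None = None,
                 constants: PhysConstants = DEFAULT_CONSTANTS,
                 solver: SolverSettings = DEFAULT_SOLVER) -> float:
    """Find an FiO2 in [0.21, 0.99] whose steady-state SaO2 lies in the band.

    Bisects the monotone SaO2(FiO2) map toward ``target`` (default: band
    midpoint).  Returns 0.21 when the scenario is already in band on air;
    raises :class:`ScenarioRejected` when no FiO2 attains the band.
    """
    lo_sat, hi_sat = sat_band
    if target is None:
        target = 0.5 * (lo_sat + hi_sat)
    target = float(np.clip(target, lo_sat + 0.002, hi_sat - 0.002))

    def sao2_at(fio2: float) -> float:
        # an infeasible venous state at this FiO2 reads as "far too low"
        try:
            return run_forward(inputs, fio2, constants, solver,
                               save_compartments=False).sao2
        except InfeasibleScenarioError:
            return -1.0

    sa21 = sao2_at(0.21)
    if lo_sat <= sa21 <= hi_sat:
        return 0.21
    if sa21 > hi_sat:
        raise ScenarioRejected(f"SaO2 {sa21:.3f} already above band on room air")
    sa99 = sao2_at(0.99)
    if sa99 < lo_sat:
        raise ScenarioRejected(f"SaO2 only {sa99:.3f} at FiO2 0.99")

    lo, hi = 0.21, 0.99
    fio2 = hi
    for _ in range(solver.max_titration_iter):
        mid = 0.5 * (lo + hi)
        sa = sao2_at(mid)
        fio2 = mid
        if abs(sa - target) < solver.titration_tol:
            break
        if sa < target:
            lo = mid
        else:
            hi = mid
    sa = sao2_at(fio2)
    if not lo_sat <= sa <= hi_sat:
        raise ScenarioRejected(f"titration landed at SaO2 {sa:.3f}, outside band")
    return fio2
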