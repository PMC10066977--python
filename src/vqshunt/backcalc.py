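"""Direct (non-ML) inversion of the lung model from one bedside record.

Given the ten observable features, the inversion first derives the blood
parameters that are not directly monitored — base excess from the Van Slyke
relation at the record's pH/PaCO2/Hb, and standard P50 by inverting the
dissociation curve at the record's PaO2/SaO2 pair (PaO2 and pH thus act as
consistency inputs to the content calculations, not as matched residuals).
It then solves for the three distribution parameters (shunt fraction,
log SD, mean V/Q) that make the forward model reproduce the observed SaO2,
PaCO2 and mean alveolar PCO2 at the record's FiO2: three residuals, three
unknowns, solved by bounded trust-region least squares with multistart.

Venous admixture is computed directly from the record via the classic
ideal-compartment construction (ideal alveolar PO2 from FiO2, arterial PCO2
and R; mixed venous via Fick), so VenAd and the low-V/Q component
(VenAd - shunt) accompany every shunt estimate.

The sensitivity machinery re-runs the inversion while one input is swept
above and below its recorded value, reproducing the input-error analyses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from . import bloodchem as bc
from . import lungmodel as lm
from .config import (DEFAULT_CONSTANTS, DEFAULT_SOLVER, PhysConstants,
                     SolverSettings)
from .scenarios import BedsideRecord

log = logging.getLogger(__name__)

__all__ = ["RecoveryReport", "SensitivityResult", "EXAMPLE_RECORD",
           "derive_blood_params", "venad_from_record", "recover",
           "sensitivity_sweep", "SWEEPABLE_INPUTS"]

#: the nine monitoring inputs that may be perturbed (FiO2 assumed accurate)
SWEEPABLE_INPUTS = ["hb", "sao2", "ph", "pao2", "paco2", "mean_paco2",
                    "co", "vco2", "r"]

#: a representative bedside record in which shunt and low-V/Q blood flow
#: both contribute materially to the venous admixture (used by the worked
#: example and the sensitivity analyses)
EXAMPLE_RECORD = BedsideRecord(
    fio2=0.38, hb=9.30, sao2=0.94, ph=7.364, pao2=69.0, paco2=39.4,
    mean_paco2=30.1, co=5.25, vco2=187.0, r=0.74)


@dataclass(frozen=True)
class RecoveryReport:
    """Result of inverting the lung model for one bedside record."""

    shunt_est: float    # % of pulmonary blood flow
    venad_est: float    # % of pulmonary blood flow
    low_vq_est: float   # venad_est - shunt_est, %
    log_sd_est: float
    mean_vq_est: float
    residuals: dict[str, float]   # raw residuals on the matched observables
    converged: bool
    n_starts: int = 1
    cost: float = float("nan")


@dataclass(frozen=True)
class SensitivityResult:
    """Shunt/VenAd estimates as one monitoring input sweeps a grid."""

    input_name: str
    values: np.ndarray
    shunt_est: np.ndarray
    venad_est: np.ndarray
    converged: np.ndarray
    base: RecoveryReport
    slope: float          # pp of shunt per unit of input, central difference

    @property
    def low_vq_est(self) -> np.ndarray:
        return self.venad_est - self.shunt_est


# ---------------------------------------------------------------------------
# Derived blood parameters and the record-side venous admixture
# ---------------------------------------------------------------------------

def derive_blood_params(record: BedsideRecord,
                        constants: PhysConstants = DEFAULT_CONSTANTS) -> bc.BloodParams:
    """Blood parameters implied by the record (BE and P50st are not monitored).

    BE follows from the Van Slyke relation at the record's pH, PaCO2 and Hb;
    P50st from inverting the dissociation curve so that the record's
    PaO2/SaO2 pair lies on it at the record's pH and that BE.
    """
    be = float(bc.base_excess(record.ph, record.paco2, record.hb, constants))
    be = float(np.clip(be, -29.9, 29.9))
    x = bc._sev_inverse(record.sao2)  # virtual PO2 on the reference curve
    p50_vivo = record.pao2 * constants.p50_reference / x
    shift = 10.0 ** (constants.bohr_ph * (record.ph - 7.40) + constants.be_p50 * be)
    p50st = float(np.clip(p50_vivo / shift, 15.0, 40.0))
    return bc.BloodParams(hb=record.hb, p50st=p50st, be=be)


def venad_from_record(record: BedsideRecord,
                      constants: PhysConstants = DEFAULT_CONSTANTS,
                      blood: bc.BloodParams | None = None) -> float:
    """Venous admixture (%) from the bedside record alone.

    Ideal-compartment end-capillary content at the ideal alveolar PO2,
    arterial content from the measured SaO2/PaO2, mixed-venous content via
    Fick with VO2 = VCO2/R.
    """
    blood = blood or derive_blood_params(record, constants)
    ca_o2 = float(bc.o2_content(record.pao2, record.sao2, record.hb, constants))
    vo2 = record.vco2 / record.r
    cv_o2 = ca_o2 - vo2 / (10.0 * record.co)
    if cv_o2 <= 0:
        raise bc.InfeasibleScenarioError(
            f"record implies venous O2 content {cv_o2:.2f} mL/dL <= 0")
    pao2_ideal = float(lm.ideal_alveolar_po2(record.fio2, record.paco2,
                                             record.r, constants))
    if pao2_ideal <= record.pao2:
        raise bc.InfeasibleScenarioError(
            f"ideal alveolar PO2 {pao2_ideal:.1f} not above arterial {record.pao2:.1f}")
    so2_ideal = float(bc.odc_saturation(pao2_ideal, record.ph, record.paco2,
                                        blood.be, blood.p50st, constants))
    cc_o2 = float(bc.o2_content(pao2_ideal, so2_ideal, record.hb, constants))
    return 100.0 * lm.venad(cc_o2, ca_o2, cv_o2)


# ---------------------------------------------------------------------------
# Inversion
# ---------------------------------------------------------------------------

#: residual scales: 0.002 SaO2 units and 0.2 mmHg PaCO2 count as "matched";
#: a tenth of that counts as an exact root
_SCALES = np.array([0.002, 0.2])
_BOUNDS = (np.array([0.0, 0.05]), np.array([0.5, 2.5]))
_MU_BOUNDS = (0.02, 4.5)
#: the physiological sampling envelope (padded) on (shunt, log SD, mean V/Q):
#: the inversion can be multi-rooted -- a large-dispersion lung can trade
#: true shunt against near-zero-V/Q flow almost exactly -- and roots with
#: parameters outside the envelope the training universe samples are
#: rejected in favor of roots inside it when both exist
_ENVELOPE = (np.array([0.033, 0.16, 0.11]), np.array([0.405, 2.03, 1.40]))


def _in_envelope(x3: np.ndarray) -> bool:
    return bool(np.all(x3 >= _ENVELOPE[0]) and np.all(x3 <= _ENVELOPE[1]))


def recover(record: BedsideRecord,
            constants: PhysConstants = DEFAULT_CONSTANTS,
            solver: SolverSettings = DEFAULT_SOLVER,
            x0: tuple[float, float, float] | None = None) -> RecoveryReport:
    """Back-calculate (shunt, log SD, mean V/Q) from one bedside record.

    The three matched observables are SaO2, PaCO2 and mean PACO2.  Mean
    PACO2 is matched exactly through a conservation identity: at steady
    state the expired alveolar ventilation is VA_E = 0.863 VCO2 / meanPACO2,
    which fixes mean V/Q once (shunt, log SD) are given.  The remaining two
    residuals (SaO2, PaCO2) are solved over (shunt, log SD) by trust-region
    least squares, multistarted from the best cells of a coarse batched
    grid scan so that every root basin is visited.  The inversion can be
    multi-rooted (near-zero-V/Q flow mimics shunt); roots inside the
    physiological sampling envelope are preferred.

    ``x0`` prepends a (shunt_frac, log_sd, mean_vq) start, used to
    warm-start sweep points from the base solution.
    """
    blood = derive_blood_params(record, constants)
    # a tight venous fixed point keeps the residual surface smooth enough
    # for finite-difference Jacobians
    import dataclasses as _dc
    solver = _dc.replace(solver, venous_tol=min(solver.venous_tol, 1e-9))
    base_params = {
        "vco2": np.array([record.vco2]), "r": np.array([record.r]),
        "co": np.array([record.co]), "hb": np.array([record.hb]),
        "p50st": np.array([blood.p50st]), "be": np.array([blood.be]),
    }
    observed = np.array([record.sao2, record.paco2])
    zc, qbin = lm._grid(solver.n_compartments, solver.grid_span)
    va_e = constants.k_gas * record.vco2 / record.mean_paco2   # L/min BTPS

    def mean_vq_of(shunt, log_sd):
        """Mean V/Q implied by the ventilation identity (exact in-model)."""
        m = (qbin[None, :] * np.exp(np.atleast_1d(log_sd)[:, None] * zc[None, :])).sum(axis=1)
        mu = va_e / (record.co * (1.0 - np.atleast_1d(shunt)) * m)
        return np.clip(mu, *_MU_BOUNDS)

    def forward(xs: np.ndarray) -> np.ndarray:
        """Scaled (SaO2, PaCO2) residuals for a stack of (shunt, logSD) pairs.

        Every evaluation cold-starts the forward solver: reusing compartment
        state across *different* distribution parameters can hop between
        branches of the multi-equilibrium compartment problem and corrupt
        the residual surface.
        """
        n = xs.shape[0]
        params = {k: np.repeat(v, n) for k, v in base_params.items()}
        params["shunt"] = xs[:, 0]
        params["log_sd"] = xs[:, 1]
        params["mean_vq"] = mean_vq_of(xs[:, 0], xs[:, 1])
        out = lm._forward_batch(params, np.full(n, record.fio2), constants,
                                solver)
        model = np.stack([out["sao2"], out["paco2"]], axis=1)
        res = (model - observed[None, :]) / _SCALES[None, :]
        res[~out["ok"]] = 1e3   # repel the solver from non-converged regions
        return res

    def fun(x: np.ndarray) -> np.ndarray:
        return forward(x[None, :])[0]

    def jac(x: np.ndarray) -> np.ndarray:
        h = np.array([1e-4, 5e-4])
        f0 = forward(x[None, :])[0]
        xs = np.repeat(x[None, :], 2, axis=0) + np.diag(h)
        fs = forward(xs)
        return (fs - f0[None, :]).T / h[None, :]

    # coarse scan over (shunt, log SD) in one batched call: candidate starts
    ss, sds = np.meshgrid(np.linspace(0.015, 0.45, 10),
                          np.linspace(0.15, 2.2, 9))
    grid = np.column_stack([ss.ravel(), sds.ravel()])
    norms = np.abs(forward(grid)).max(axis=1)
    order = np.argsort(norms)
    starts = [grid[i] for i in order[:8]]
    if x0 is not None:
        starts.insert(0, np.asarray(x0[:2], dtype=float))

    def triple(x: np.ndarray) -> np.ndarray:
        return np.array([x[0], x[1], float(mean_vq_of(x[0], x[1])[0])])

    best = None        # (rank, cost, sol); lower rank wins, then cost
    n_used = 0
    for s in starts:
        n_used += 1
        s = np.clip(s, _BOUNDS[0] + 1e-6, _BOUNDS[1] - 1e-6)
        try:
            sol = least_squares(fun, s, jac=jac, bounds=_BOUNDS,
                                x_scale=[0.1, 0.5], xtol=1e-10,
                                ftol=1e-12, gtol=1e-12, max_nfev=60)
        except Exception as exc:  # pragma: no cover - solver pathologies
            log.warning("back-calculation start %s failed: %s", s, exc)
            continue
        maxres = float(np.max(np.abs(sol.fun)))
        in_env = _in_envelope(triple(sol.x))
        if maxres < 0.1:
            rank = 0 if in_env else 1    # exact root
        elif maxres < 1.0:
            rank = 2 if in_env else 3    # acceptable fit
        else:
            rank = 4
        if best is None or (rank, sol.cost) < (best[0], best[1]):
            best = (rank, sol.cost, sol)
        if rank == 0:
            break

    if best is None:
        raise lm.ConvergenceError("back-calculation failed from every start")
    rank, _, sol = best
    matched = rank <= 3
    shunt, log_sd = sol.x
    mean_vq = float(mean_vq_of(shunt, log_sd)[0])
    raw = sol.fun * _SCALES
    venad_est = venad_from_record(record, constants, blood)
    return RecoveryReport(
        shunt_est=100.0 * shunt, venad_est=venad_est,
        low_vq_est=venad_est - 100.0 * shunt,
        log_sd_est=float(log_sd), mean_vq_est=mean_vq,
        residuals={"sao2": float(raw[0]), "paco2": float(raw[1]),
                   "mean_paco2": 0.0},
        converged=bool(matched), n_starts=n_used, cost=float(sol.cost))


# ---------------------------------------------------------------------------
# Sensitivity sweeps
# ---------------------------------------------------------------------------

def default_grid(record: BedsideRecord, input_name: str,
                 n_points: int = 9) -> np.ndarray:
    """Perturbation grid for one input, centered on the recorded value.

    +-2 mmHg absolute for the two PCO2 inputs, +-0.05 absolute for pH
    (a physiologic measurement-error scale), +-10% relative otherwise.
    """
    v = getattr(record, input_name)
    if input_name in ("paco2", "mean_paco2"):
        half = 2.0
    elif input_name == "ph":
        half = 0.05
    else:
        half = 0.10 * abs(v)
    return np.linspace(v - half, v + half, n_points)


def sensitivity_sweep(record: BedsideRecord, input_name: str,
                      grid: np.ndarray | None = None, n_points: int = 9,
                      constants: PhysConstants = DEFAULT_CONSTANTS,
                      solver: SolverSettings = DEFAULT_SOLVER) -> SensitivityResult:
    """Re-run the back-calculation as one monitoring input sweeps a grid.

    Per-point failures are recorded and the sweep continues.  The grid
    always contains the unperturbed value; estimates there equal the base
    recovery report.
    """
    if input_name not in SWEEPABLE_INPUTS:
        raise ValueError(f"{input_name!r} is not one of the nine sweepable "
                         f"inputs: {SWEEPABLE_INPUTS}")
    if grid is None:
        grid = default_grid(record, input_name, n_points)
    grid = np.asarray(grid, dtype=float)
    v0 = getattr(record, input_name)
    if not np.any(np.isclose(grid, v0, rtol=0, atol=1e-9)):
        grid = np.sort(np.append(grid, v0))

    base = recover(record, constants, solver)
    x_base = (base.shunt_est / 100.0, base.log_sd_est, base.mean_vq_est)

    shunt_est = np.full(grid.shape, np.nan)
    venad_est = np.full(grid.shape, np.nan)
    conv = np.zeros(grid.shape, dtype=bool)
    for i, v in enumerate(grid):
        if np.isclose(v, v0, rtol=0, atol=1e-9):
            rep = base
        else:
            rec_i = BedsideRecord(**{**record.features(), input_name: float(v)})
            try:
                rep = recover(rec_i, constants, solver, x0=x_base)
            except Exception as exc:
                log.warning("sweep %s=%.4g failed: %s", input_name, v, exc)
                continue
        shunt_est[i] = rep.shunt_est
        venad_est[i] = rep.venad_est
        conv[i] = rep.converged

    # central slope at the unperturbed point
    i0 = int(np.argmin(np.abs(grid - v0)))
    lo, hi = max(i0 - 1, 0), min(i0 + 1, len(grid) - 1)
    with np.errstate(invalid="ignore"):
        slope = (shunt_est[hi] - shunt_est[lo]) / (grid[hi] - grid[lo])
    return SensitivityResult(input_name=input_name, values=grid,
                             shunt_est=shunt_est, venad_est=venad_est,
                             converged=conv, base=base, slope=float(slope))
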