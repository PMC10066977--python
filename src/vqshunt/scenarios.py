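"""Scenario generation: the simulated training/test universe.

Samples the nine model inputs uniformly within their physiological ranges,
runs the forward lung model with per-scenario FiO2 titration into the target
SaO2 band, and assembles the table of ten bedside features plus hidden truth
labels (shunt, venous admixture, low V/Q, distribution parameters).  Records
are retained only when the forward solve converges, the venous state is
feasible, SaO2 lies in the band and arterial pH is within the viability
window; rejected scenarios are resampled until the requested count is
reached, with rejection reasons tallied.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import lungmodel as lm
from .bloodchem import BloodParams, MetabolicState
from .config import (DEFAULT_CONSTANTS, DEFAULT_SOLVER, InputRanges,
                     OutputEnvelope, PhysConstants, RunConfig, SolverSettings)
from .lungmodel import LungInputs

log = logging.getLogger(__name__)

__all__ = ["BedsideRecord", "ScenarioDataset", "FEATURE_COLUMNS",
           "sample_inputs", "build_dataset", "randomize_split", "generate"]

#: the ten bedside features, in canonical column order
FEATURE_COLUMNS = ["fio2", "hb", "sao2", "ph", "pao2", "paco2",
                   "mean_paco2", "co", "vco2", "r"]
#: hidden truth labels (shunt/venad/low_vq as % of pulmonary blood flow)
LABEL_COLUMNS = ["shunt", "venad", "low_vq", "log_sd", "mean_vq"]
ALL_COLUMNS = FEATURE_COLUMNS + LABEL_COLUMNS + ["split"]


@dataclass(frozen=True)
class BedsideRecord:
    """One monitoring snapshot: ten observable features plus truth labels."""

    fio2: float
    hb: float          # g/dL
    sao2: float        # fraction
    ph: float
    pao2: float        # mmHg
    paco2: float       # mmHg
    mean_paco2: float  # mmHg
    co: float          # L/min
    vco2: float        # mL/min STPD
    r: float
    # hidden labels, % of pulmonary blood flow (nan when unknown)
    shunt: float = float("nan")
    venad: float = float("nan")
    low_vq: float = float("nan")
    log_sd: float = float("nan")
    mean_vq: float = float("nan")

    @classmethod
    def from_forward(cls, result: lm.ForwardResult) -> "BedsideRecord":
        x = result.inputs
        return cls(fio2=result.fio2, hb=x.blood.hb, sao2=result.sao2,
                   ph=result.ph, pao2=result.pao2, paco2=result.paco2,
                   mean_paco2=result.mean_paco2, co=x.metab.co,
                   vco2=x.metab.vco2, r=x.metab.r,
                   shunt=100.0 * x.shunt_frac, venad=100.0 * result.venad,
                   low_vq=100.0 * result.low_vq, log_sd=x.log_sd,
                   mean_vq=x.mean_vq)

    def features(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in FEATURE_COLUMNS}


@dataclass
class ScenarioDataset:
    """Generated records with their train/test partition and provenance."""

    records: pd.DataFrame
    seed: int
    rejections: dict[str, int] = field(default_factory=dict)
    meta: dict[str, str] = field(default_factory=dict)

    @property
    def train(self) -> pd.DataFrame:
        return self.records[self.records["split"] == "train"]

    @property
    def test(self) -> pd.DataFrame:
        return self.records[self.records["split"] == "test"]

    def to_csv(self, path: str | Path) -> None:
        """Write records as CSV with a commented metadata header."""
        with open(path, "w") as fh:
            fh.write(f"# seed: {self.seed}\n")
            for k, v in sorted(self.meta.items()):
                fh.write(f"# {k}: {v}\n")
            for k, v in sorted(self.rejections.items()):
                fh.write(f"# rejected_{k}: {v}\n")
            self.records.to_csv(fh, index=False, float_format="%.9g")

    @classmethod
    def from_csv(cls, path: str | Path) -> "ScenarioDataset":
        meta: dict[str, str] = {}
        lines = []
        with open(path) as fh:
            for line in fh:
                if line.startswith("#"):
                    k, _, v = line[1:].strip().partition(":")
                    meta[k.strip()] = v.strip()
                else:
                    lines.append(line)
        records = pd.read_csv(io.StringIO("".join(lines)))
        seed = int(meta.pop("seed", "0"))
        rej = {k[len("rejected_"):]: int(v) for k, v in meta.items()
               if k.startswith("rejected_")}
        meta = {k: v for k, v in meta.items() if not k.startswith("rejected_")}
        return cls(records=records, seed=seed, rejections=rej, meta=meta)


# ---------------------------------------------------------------------------
# Sampling
# ---------------------------------------------------------------------------

def _sample_arrays(n: int, ranges: InputRanges, rng: np.random.Generator) -> dict[str, np.ndarray]:
    rd = ranges.as_dict()
    return {
        "shunt": rng.uniform(*rd["shunt"], n),
        "log_sd": rng.uniform(*rd["log_sd"], n),
        "mean_vq": rng.uniform(*rd["mean_vq"], n),
        "vco2": rng.uniform(*rd["vco2"], n),
        "r": rng.uniform(*rd["r"], n),
        "co": rng.uniform(*rd["co"], n),
        "hb": rng.uniform(*rd["hb"], n),
        "p50st": rng.uniform(*rd["p50st"], n),
        "be": rng.uniform(*rd["be"], n),
    }


def _arrays_to_inputs(arr: dict[str, np.ndarray]) -> list[LungInputs]:
    return [
        LungInputs(shunt_frac=float(arr["shunt"][i]), log_sd=float(arr["log_sd"][i]),
                   mean_vq=float(arr["mean_vq"][i]),
                   metab=MetabolicState(vco2=float(arr["vco2"][i]),
                                        r=float(arr["r"][i]), co=float(arr["co"][i])),
                   blood=BloodParams(hb=float(arr["hb"][i]), p50st=float(arr["p50st"][i]),
                                     be=float(arr["be"][i])))
        for i in range(len(arr["shunt"]))
    ]


def sample_inputs(n: int, ranges: InputRanges = InputRanges(),
                  seed: int = 0) -> list[LungInputs]:
    """Draw n model-input tuples, independently uniform within the ranges."""
    if n < 1:
        raise ValueError("n must be >= 1")
    ranges.validate()
    rng = np.random.default_rng(seed)
    return _arrays_to_inputs(_sample_arrays(n, ranges, rng))


# ---------------------------------------------------------------------------
# Batched titration + forward simulation
# ---------------------------------------------------------------------------

def _titrate_and_run(arr: dict[str, np.ndarray], targets: np.ndarray,
                     sat_band: tuple[float, float],
                     constants: PhysConstants, solver: SolverSettings
                     ) -> tuple[dict[str, np.ndarray], np.ndarray, dict[str, np.ndarray]]:
    """Titrate FiO2 into the SaO2 band for a whole batch, synchronously.

    Returns (final forward outputs, fio2, reason masks).  Scenarios whose
    SaO2 on room air is already in band keep FiO2 0.21; scenarios that
    cannot reach the band are flagged.
    """
    S = len(targets)
    lo_sat, hi_sat = sat_band
    coarse = max(solver.venous_tol, 2e-5)

    out21 = lm._forward_batch(arr, np.full(S, 0.21), constants, solver,
                              venous_tol=coarse)
    sa21 = out21["sao2"]
    bad = ~out21["ok"] & ~out21["infeasible"]
    too_healthy = out21["ok"] & (sa21 > hi_sat)
    in_band_air = out21["ok"] & (sa21 >= lo_sat) & (sa21 <= hi_sat)
    # infeasible on air just means SaO2 is far below target: titrate upward
    need = (out21["ok"] & (sa21 < lo_sat)) | out21["infeasible"]

    state = out21["state"]
    out99 = lm._forward_batch(arr, np.full(S, 0.99), constants, solver,
                              state=state, venous_tol=coarse)
    unreachable = need & out99["ok"] & (out99["sao2"] < lo_sat)
    infeasible_everywhere = need & out99["infeasible"]
    bad |= need & ~out99["ok"] & ~out99["infeasible"]
    active = need & out99["ok"] & ~unreachable

    lo = np.full(S, 0.21)
    hi = np.full(S, 0.99)
    fio2 = np.where(in_band_air, 0.21, 0.99)
    done = in_band_air.copy()
    state = out99["state"]
    for _ in range(solver.max_titration_iter):
        if not (active & ~done).any():
            break
        mid = 0.5 * (lo + hi)
        fio2 = np.where(active & ~done, mid, fio2)
        out = lm._forward_batch(arr, fio2, constants, solver, state=state,
                                venous_tol=coarse)
        state = out["state"]
        # an infeasible venous state at this FiO2 reads as "far too low"
        sa = np.where(out["infeasible"], -1.0, out["sao2"])
        hit = active & ~done & out["ok"] & (np.abs(sa - targets) < solver.titration_tol)
        done |= hit
        low = active & ~done & (sa < targets)
        lo = np.where(low, mid, lo)
        hi = np.where(active & ~done & ~low, mid, hi)

    # final run is cold-started so the emitted record is branch-consistent
    # with any later cold re-evaluation (inversion, label checks)
    final = lm._forward_batch(arr, fio2, constants, solver)
    reasons = {
        "infeasible_venous": infeasible_everywhere | final["infeasible"],
        "solver_failure": bad | (~final["ok"] & ~final["infeasible"]),
        "sao2_unreachable": unreachable,
        "sao2_above_band_on_air": too_healthy,
    }
    return final, fio2, reasons


def build_dataset(inputs: list[LungInputs], seed: int = 0,
                  sat_band: tuple[float, float] = (0.87, 0.98),
                  envelope: OutputEnvelope | None = OutputEnvelope(),
                  constants: PhysConstants = DEFAULT_CONSTANTS,
                  solver: SolverSettings = DEFAULT_SOLVER) -> ScenarioDataset:
    """Titrate and forward-simulate every input; keep viable in-band records.

    Per-scenario failures are logged and counted, never raised.  The
    returned dataset has no split labels yet (all rows marked "train").
    """
    arr = lm._inputs_to_arrays(inputs)
    rng = np.random.default_rng(seed)
    S = len(inputs)
    targets = rng.uniform(sat_band[0] + 0.002, sat_band[1] - 0.002, S)
    final, fio2, reasons = _titrate_and_run(arr, targets, sat_band,
                                            constants, solver)

    keep = final["ok"].copy()
    in_band = (final["sao2"] >= sat_band[0]) & (final["sao2"] <= sat_band[1])
    in_env = np.ones(S, dtype=bool)
    if envelope is not None:
        for name, (lo, hi) in envelope.as_dict().items():
            in_env &= (final[name] >= lo) & (final[name] <= hi)
    venad_ok = np.isfinite(final["venad"])

    # mutually exclusive rejection tally, in priority order
    rejections: dict[str, int] = {}
    accounted = np.zeros(S, dtype=bool)
    ordered = list(reasons.items()) + [
        ("sao2_out_of_band", keep & ~in_band),
        ("outside_bedside_envelope", keep & in_band & ~in_env),
        ("degenerate_venad", keep & in_band & in_env & ~venad_ok),
    ]
    for name, mask in ordered:
        mask = mask & ~accounted
        rejections[name] = int(mask.sum())
        accounted |= mask
    keep &= in_band & in_env & venad_ok

    df = pd.DataFrame({
        "fio2": fio2, "hb": arr["hb"], "sao2": final["sao2"], "ph": final["ph"],
        "pao2": final["pao2"], "paco2": final["paco2"],
        "mean_paco2": final["mean_paco2"], "co": arr["co"], "vco2": arr["vco2"],
        "r": arr["r"], "shunt": 100.0 * arr["shunt"],
        "venad": 100.0 * final["venad"], "low_vq": 100.0 * final["low_vq"],
        "log_sd": arr["log_sd"], "mean_vq": arr["mean_vq"],
    })[ALL_COLUMNS[:-1]]
    df = df[keep].reset_index(drop=True)
    df["split"] = "train"
    n_rej = S - int(keep.sum())
    if n_rej:
        log.info("rejected %d/%d scenarios: %s", n_rej, S,
                 {k: v for k, v in rejections.items() if v})
    return ScenarioDataset(records=df, seed=seed, rejections=rejections)


def randomize_split(ds: ScenarioDataset, n_test: int = 500,
                    seed: int = 0) -> ScenarioDataset:
    """Simple randomization into disjoint train/test sets (test size exact)."""
    n = len(ds.records)
    if n_test >= n:
        raise ValueError(f"n_test={n_test} must be smaller than the dataset ({n} rows)")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    split = np.full(n, "train", dtype=object)
    split[order[:n_test]] = "test"
    records = ds.records.copy()
    records["split"] = split
    return ScenarioDataset(records=records, seed=ds.seed,
                           rejections=dict(ds.rejections), meta=dict(ds.meta))


def generate(cfg: RunConfig | None = None, seed: int | None = None,
             n_scenarios: int | None = None, n_test: int | None = None,
             batch_size: int = 4096) -> ScenarioDataset:
    """End-to-end dataset generation: sample, simulate, resample, split.

    Rejected scenarios are replaced by fresh draws until ``n_scenarios``
    retained records exist (the rejection rate is recorded); the result is
    then randomized into train/test.
    """
    cfg = cfg or RunConfig()
    seed = cfg.seed if seed is None else seed
    n_total = cfg.n_scenarios if n_scenarios is None else n_scenarios
    n_test = cfg.n_test if n_test is None else n_test
    rng = np.random.default_rng(seed)

    frames = []
    rejections: dict[str, int] = {}
    retained = 0
    attempted = 0
    while retained < n_total:
        n_draw = min(batch_size, max(256, int(1.3 * (n_total - retained))))
        arr = _sample_arrays(n_draw, cfg.ranges, rng)
        inputs = _arrays_to_inputs(arr)
        part = build_dataset(inputs, seed=int(rng.integers(2**31 - 1)),
                             sat_band=cfg.sat_band, envelope=cfg.envelope,
                             constants=cfg.constants, solver=cfg.solver)
        frames.append(part.records)
        retained += len(part.records)
        attempted += n_draw
        for k, v in part.rejections.items():
            rejections[k] = rejections.get(k, 0) + v

    records = pd.concat(frames, ignore_index=True).iloc[:n_total].reset_index(drop=True)
    ds = ScenarioDataset(records=records, seed=seed, rejections=rejections,
                         meta={"attempted": str(attempted),
                               "config_digest": cfg.digest()})
    return randomize_split(ds, n_test=n_test, seed=seed)
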