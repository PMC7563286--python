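"""Two-stage flux balance analysis.

Stage one maximizes the biomass objective

    max Z = C'v   s.t.   S v = 0,   L_i <= v_i <= U_i,

a linear program over the steady-state flux cone.  Because the
optimum is usually degenerate, stage two selects among the
alternative optima the distribution with minimal total absolute flux
(parsimonious FBA),

    min sum_i |v_i|   s.t.   S v = 0,  L <= v <= U,  C'v >= gamma * Z*,

linearized by splitting v = v+ - v- with v+, v- >= 0.  Both stages
are solved with the HiGHS simplex/IPM through scipy; single-threaded
with a fixed variable order, so results are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path

import numpy as np
from scipy.optimize import linprog

from .constraints import BoundSet, apply_eflux, knockout, overexpress
from .gpr import MissingPolicy
from .model_io import MetabolicModel
from .proteome import ExpressionMap

#: relative relaxation of the biomass-fixing constraint, absorbs LP round-off
BIOMASS_RELAX = 1e-9

FEASIBILITY_TOL = 1e-9


class SolverStatus(str, Enum):
    OPTIMAL = "optimal"
    INFEASIBLE = "infeasible"
    UNBOUNDED = "unbounded"


class Stage(str, Enum):
    FBA = "fba"
    PFBA = "pfba"


class FBAError(RuntimeError):
    def __init__(self, stage: Stage, status: SolverStatus):
        super().__init__(f"{stage.value} stage ended with status {status.value}")
        self.stage = stage
        self.status = status


@dataclass
class FluxDistribution:
    fluxes: dict[str, float]
    objective_value: float
    status: SolverStatus
    stage: Stage

    def vector(self, reaction_ids: list[str]) -> np.ndarray:
        return np.array([self.fluxes[r] for r in reaction_ids])

    def total_absolute_flux(self) -> float:
        return float(sum(abs(v) for v in self.fluxes.values()))

    def to_tsv(self, path: str | Path, bounds: BoundSet | None = None) -> None:
        with open(Path(path), "w") as fh:
            if bounds is None:
                fh.write("reaction_id\tflux\n")
                for rid, v in self.fluxes.items():
                    fh.write(f"{rid}\t{v!r}\n")
            else:
                fh.write("reaction_id\tflux\tlower_bound\tupper_bound\n")
                for rid, v in self.fluxes.items():
                    lb, ub = bounds.bounds[rid]
                    fh.write(f"{rid}\t{v!r}\t{lb!r}\t{ub!r}\n")

    @classmethod
    def from_tsv(cls, path: str | Path, stage: Stage = Stage.PFBA) -> "FluxDistribution":
        fluxes: dict[str, float] = {}
        lines = Path(path).read_text().splitlines()
        header = lines[0].split("\t")
        for line in lines[1:]:
            if not line.strip():
                continue
            vals = dict(zip(header, line.split("\t")))
            fluxes[vals["reaction_id"]] = float(vals["flux"])
        return cls(fluxes, float("nan"), SolverStatus.OPTIMAL, stage)


_STATUS_MAP = {
    0: SolverStatus.OPTIMAL,
    2: SolverStatus.INFEASIBLE,
    3: SolverStatus.UNBOUNDED,
}


def _lp_arrays(model: MetabolicModel, bounds: BoundSet):
    rxn_ids = model.reaction_ids()
    missing = [r for r in rxn_ids if r not in bounds.bounds]
    if missing:
        raise KeyError(f"bounds missing for reactions: {missing[:5]}")
    S = model.stoichiometric_matrix()
    c = np.array([r.objective_coefficient for r in model.reactions])
    lb = np.array([bounds.bounds[r][0] for r in rxn_ids])
    ub = np.array([bounds.bounds[r][1] for r in rxn_ids])
    return rxn_ids, S, c, lb, ub


def solve_fba(model: MetabolicModel, bounds: BoundSet | None = None) -> FluxDistribution:
    """Maximize the biomass objective over the steady-state flux cone."""
    if bounds is None:
        bounds = BoundSet.from_model(model)
    rxn_ids, S, c, lb, ub = _lp_arrays(model, bounds)
    res = linprog(
        -c,
        A_eq=S,
        b_eq=np.zeros(S.shape[0]),
        bounds=list(zip(lb, ub)),
        method="highs",
    )
    status = _STATUS_MAP.get(res.status, SolverStatus.INFEASIBLE)
    if status is not SolverStatus.OPTIMAL:
        return FluxDistribution({}, float("nan"), status, Stage.FBA)
    fluxes = dict(zip(rxn_ids, (float(v) for v in res.x)))
    return FluxDistribution(fluxes, float(-res.fun), status, Stage.FBA)


def minimize_total_flux(
    model: MetabolicModel,
    bounds: BoundSet,
    z_opt: float,
    gamma: float = 1.0,
    exclude: set[str] | None = None,
) -> FluxDistribution:
    """L1-minimal flux distribution retaining ``gamma * z_opt`` biomass.

    Flux splitting v = v+ - v- turns min sum|v| into an LP; the prior
    optimum enters as the linear constraint C'v >= gamma*z_opt (with a
    tiny relative relaxation for solver round-off).  ``exclude`` names
    reactions left out of the L1 objective (e.g. exchanges).
    """
    if not 0 < gamma <= 1:
        raise ValueError(f"gamma must be in (0, 1], got {gamma}")
    rxn_ids, S, c, lb, ub = _lp_arrays(model, bounds)
    n = len(rxn_ids)
    # variables: [v+, v-]
    weights = np.ones(n)
    if exclude:
        for i, rid in enumerate(rxn_ids):
            if rid in exclude:
                weights[i] = 0.0
    obj = np.concatenate([weights, weights])
    A_eq = np.hstack([S, -S])
    target = gamma * z_opt - BIOMASS_RELAX * max(1.0, abs(z_opt))
    A_ub = -np.concatenate([c, -c])[None, :]
    b_ub = np.array([-target])
    # box bounds on the split variables reproduce lb <= v+ - v- <= ub
    var_bounds = [(max(lb[i], 0.0), max(ub[i], 0.0)) for i in range(n)] + [
        (max(-ub[i], 0.0), max(-lb[i], 0.0)) for i in range(n)
    ]
    res = linprog(
        obj,
        A_eq=A_eq,
        b_eq=np.zeros(S.shape[0]),
        A_ub=A_ub,
        b_ub=b_ub,
        bounds=var_bounds,
        method="highs",
    )
    status = _STATUS_MAP.get(res.status, SolverStatus.INFEASIBLE)
    if status is not SolverStatus.OPTIMAL:
        return FluxDistribution({}, float("nan"), status, Stage.PFBA)
    v = res.x[:n] - res.x[n:]
    fluxes = dict(zip(rxn_ids, (float(x) for x in v)))
    return FluxDistribution(fluxes, float(c @ v), status, Stage.PFBA)


def simulate(
    model: MetabolicModel,
    levels: ExpressionMap | None = None,
    knockouts: list[str] | None = None,
    overexpressions: list[tuple[str, float]] | None = None,
    scale: float = 1.0,
    gamma: float = 1.0,
    missing_policy: MissingPolicy | str = MissingPolicy.UNBOUNDED,
    cap_at_default: bool = False,
) -> tuple[FluxDistribution, BoundSet]:
    """Full pipeline: E-flux bounds -> mutants -> FBA -> pFBA.

    Returns the parsimonious flux distribution and the bound set it
    was solved under.  Raises :class:`FBAError` naming the failing
    stage if either LP is infeasible or unbounded.
    """
    if levels is not None:
        bounds = apply_eflux(
            model,
            levels,
            scale=scale,
            missing_policy=missing_policy,
            cap_at_default=cap_at_default,
        )
    else:
        bounds = BoundSet.from_model(model)
    if knockouts:
        bounds = knockout(bounds, knockouts)
    for rid, factor in overexpressions or []:
        bounds = overexpress(bounds, [rid], factor=factor)
    fba_sol = solve_fba(model, bounds)
    if fba_sol.status is not SolverStatus.OPTIMAL:
        raise FBAError(Stage.FBA, fba_sol.status)
    pfba_sol = minimize_total_flux(model, bounds, fba_sol.objective_value, gamma=gamma)
    if pfba_sol.status is not SolverStatus.OPTIMAL:
        raise FBAError(Stage.PFBA, pfba_sol.status)
    return pfba_sol, bounds
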