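"""Expression-derived flux bounds and in silico mutants.

The E-flux rule maps each reaction's GPR evaluation p onto its flux
bounds: [-p, +p] for reversible reactions, [0, +p] for irreversible
ones.  Reactions whose GPR cannot be evaluated (no rule, or the gene
was not measured under the chosen missing-gene policy) keep their
default model bounds.  Knockouts pin bounds to (0, 0); overexpression
multiplies both bounds by a factor >= 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

from .gpr import UNMEASURED, MissingPolicy, evaluate_gpr
from .model_io import MetabolicModel
from .proteome import ExpressionMap


class BoundProvenance(str, Enum):
    EXPRESSION = "expression"
    DEFAULT = "default"
    KNOCKOUT = "knockout"
    OVEREXPRESSION = "overexpression"


@dataclass
class BoundSet:
    """Per-reaction (lower, upper) flux bounds plus their origin."""

    bounds: dict[str, tuple[float, float]]
    provenance: dict[str, BoundProvenance] = field(default_factory=dict)

    def __post_init__(self):
        for rid, (lb, ub) in self.bounds.items():
            if lb > ub:
                raise ValueError(f"reaction {rid}: lower bound {lb} > upper {ub}")

    def copy(self) -> "BoundSet":
        return BoundSet(dict(self.bounds), dict(self.provenance))

    def to_tsv(self, path: str | Path) -> None:
        with open(Path(path), "w") as fh:
            fh.write("reaction_id\tlower_bound\tupper_bound\tprovenance\n")
            for rid, (lb, ub) in self.bounds.items():
                prov = self.provenance.get(rid, BoundProvenance.DEFAULT)
                fh.write(f"{rid}\t{lb!r}\t{ub!r}\t{prov.value}\n")

    @classmethod
    def from_model(cls, model: MetabolicModel) -> "BoundSet":
        """Default bounds as stored in the model."""
        return cls(
            {r.id: (r.lower_bound, r.upper_bound) for r in model.reactions},
            {r.id: BoundProvenance.DEFAULT for r in model.reactions},
        )


def apply_eflux(
    model: MetabolicModel,
    levels: ExpressionMap,
    scale: float = 1.0,
    missing_policy: MissingPolicy | str = MissingPolicy.UNBOUNDED,
    cap_at_default: bool = False,
) -> BoundSet:
    """Derive flux bounds from expression levels via each reaction's GPR.

    A reaction whose GPR evaluates to a measured level p gets bounds
    (-scale*p, +scale*p) if reversible, (0, +scale*p) otherwise.
    Reactions with no GPR, or whose evaluation is unmeasured, keep
    the model's default bounds.  ``cap_at_default`` additionally
    intersects expression bounds with the defaults so an abundant
    protein cannot widen the flux space beyond the model's limits.
    """
    if scale <= 0:
        raise ValueError(f"scale must be positive, got {scale}")
    out = BoundSet.from_model(model)
    for rxn in model.reactions:
        if rxn.gpr is None:
            continue
        value = evaluate_gpr(rxn.gpr, levels, missing_policy)
        if value is UNMEASURED:
            continue
        p = scale * value  # type: ignore[operator]
        lb, ub = (-p, p) if rxn.reversible else (0.0, p)
        if cap_at_default:
            lb = max(lb, rxn.lower_bound)
            ub = min(ub, rxn.upper_bound)
            if lb > ub:  # disjoint: collapse to the nearer default edge
                lb = ub = max(rxn.lower_bound, min(rxn.upper_bound, 0.0))
        out.bounds[rxn.id] = (lb, ub)
        out.provenance[rxn.id] = BoundProvenance.EXPRESSION
    return out


def _check_ids(bounds: BoundSet, reaction_ids: list[str]) -> None:
    unknown = [rid for rid in reaction_ids if rid not in bounds.bounds]
    if unknown:
        raise KeyError(f"unknown reaction ids: {unknown}")


def knockout(bounds: BoundSet, reaction_ids: list[str]) -> BoundSet:
    """Zero out the named reactions (bounds (0, 0))."""
    _check_ids(bounds, reaction_ids)
    out = bounds.copy()
    for rid in reaction_ids:
        out.bounds[rid] = (0.0, 0.0)
        out.provenance[rid] = BoundProvenance.KNOCKOUT
    return out


def overexpress(
    bounds: BoundSet, reaction_ids: list[str], factor: float = 2.0
) -> BoundSet:
    """Multiply both bounds of the named reactions by ``factor`` (>= 1)."""
    if factor < 1:
        raise ValueError(f"overexpression factor must be >= 1, got {factor}")
    _check_ids(bounds, reaction_ids)
    out = bounds.copy()
    for rid in reaction_ids:
        lb, ub = out.bounds[rid]
        out.bounds[rid] = (lb * factor, ub * factor)
        out.provenance[rid] = BoundProvenance.OVEREXPRESSION
    return out


def gene_knockout(
    model: MetabolicModel, bounds: BoundSet, genes: list[str], levels: ExpressionMap
) -> BoundSet:
    """Convenience gene-level knockout.

    Re-evaluates each GPR with the deleted genes forced to level 0
    (policy ``zero``); reactions whose rule then evaluates to 0 are
    knocked out at the reaction level.
    """
    forced = dict(levels)
    for g in genes:
        forced[g] = 0.0
    hit = []
    for rxn in model.reactions:
        if rxn.gpr is None or not (rxn.gpr.genes() & set(genes)):
            continue
        value = evaluate_gpr(rxn.gpr, forced, MissingPolicy.ZERO)
        if value == 0.0:
            hit.append(rxn.id)
    return knockout(bounds, hit)
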