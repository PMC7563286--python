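"""End-to-end drivers tying proteome, constraints and FBA together."""

from __future__ import annotations

from .fba import FluxDistribution, simulate
from .gpr import MissingPolicy
from .model_io import MetabolicModel
from .proteome import (
    DEResult,
    ProteomeTable,
    normalize_proteome,
    select_de,
    to_expression_map,
)


def simulate_condition(
    model: MetabolicModel,
    proteome: ProteomeTable,
    condition: str,
    control: str,
    fc_threshold: float = 1.2,
    alpha: float = 0.05,
    de_only: bool = True,
    normalization: str = "total_intensity",
    knockouts: list[str] | None = None,
    overexpressions: list[tuple[str, float]] | None = None,
    scale: float = 1.0,
    gamma: float = 1.0,
    missing_policy: MissingPolicy | str = MissingPolicy.UNBOUNDED,
) -> tuple[FluxDistribution, list[DEResult]]:
    """Simulate fluxes for one condition from a replicate proteome.

    Normalizes the table, calls DE proteins between ``condition`` and
    ``control``, converts the condition means of the (DE) proteins
    into expression bounds and runs the two-stage FBA with optional
    knockout / overexpression directives.  For ``condition ==
    control`` the same DE list is used but the control means bound
    the fluxes, so a control simulation is directly comparable to the
    stress one.
    """
    table = normalize_proteome(proteome, method=normalization)
    de_condition = condition if condition != control else (
        next(c for c in table.conditions if c != control)
    )
    de = select_de(table, de_condition, control, fc_threshold=fc_threshold, alpha=alpha)
    levels = to_expression_map(table, condition, de_only=de_only, de=de)
    dist, _ = simulate(
        model,
        levels=levels,
        knockouts=knockouts,
        overexpressions=overexpressions,
        scale=scale,
        gamma=gamma,
        missing_policy=missing_policy,
    )
    return dist, de
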