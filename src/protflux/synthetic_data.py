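"""Synthetic fixtures: toy metabolic networks and replicate proteomes.

The toy model is built from motifs with analytically known LP
behavior: a capped uptake feeding a linear chain into a biomass sink
(optimum = the uptake cap; L1-minimal total flux = cap x number of
active reactions), optional two-reaction detours parallel to the
first chain step (FBA-degenerate, resolved by L1 minimization), and
optional three-reaction futile cycles (carry arbitrary flux at the
FBA stage, driven to zero by L1 minimization).

The proteome generator draws replicate intensities log-normally
around per-protein baselines and injects differential expression as a
fixed log2 shift in every non-control condition, recording ground
truth so recovery can be scored.  It emulates the structure of a
multi-condition temperature-series proteome (control + stress
conditions, a few replicates each); it does not emulate peptide-level
artifacts, missing values, or intensity-dependent variance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .model_io import (
    DEFAULT_BOUND,
    MetabolicModel,
    Metabolite,
    Reaction,
    save_model,
    validate_model,
)
from .gpr import parse_gpr
from .proteome import ProteomeTable


@dataclass
class ToyModelSpec:
    n_linear_chain: int = 3
    n_parallel_paths: int = 1
    n_cycles: int = 1
    exchange_cap: float = 10.0
    seed: int = 0

    def __post_init__(self):
        if self.n_linear_chain < 2:
            raise ValueError("n_linear_chain must be >= 2")
        if self.n_parallel_paths < 0 or self.n_cycles < 0:
            raise ValueError("motif counts must be >= 0")
        if not 0 < self.exchange_cap <= DEFAULT_BOUND:
            raise ValueError(
                f"exchange_cap must be in (0, {DEFAULT_BOUND}]"
            )


@dataclass
class ProteomeSpec:
    n_proteins: int = 200
    n_replicates: int = 3
    conditions: tuple[str, ...] = ("T35", "T22")
    baseline_mean: float = 50.0
    noise_sigma: float = 0.2  # SD of replicate noise, log2 scale
    de_fraction: float = 0.1
    de_log2_shift: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if self.n_replicates < 2:
            raise ValueError("need >= 2 replicates per condition")
        if not 0 <= self.de_fraction <= 1:
            raise ValueError("de_fraction must be in [0, 1]")
        if self.baseline_mean <= 0 or self.noise_sigma < 0:
            raise ValueError("baseline_mean > 0 and noise_sigma >= 0 required")
        if len(self.conditions) < 2:
            raise ValueError("need a control and >= 1 other condition")


def make_toy_model(spec: ToyModelSpec) -> tuple[MetabolicModel, float, float]:
    """Build the motif model; returns (model, known_optimum, known_min_l1).

    Construction guarantees: the biomass optimum equals the uptake cap
    (the chain is unconstrained downstream), and the L1-minimal total
    flux at that optimum is cap x (chain length + 2) — uptake, the
    chain steps, and the biomass sink each carry the cap; detours and
    cycles carry zero.
    """
    n = spec.n_linear_chain
    cap = spec.exchange_cap
    mets = [Metabolite(f"M{i}", compartment="c") for i in range(n + 1)]
    rxns: list[Reaction] = []

    rxns.append(
        Reaction(
            id="EX_M0",
            name="uptake of M0",
            stoichiometry={"M0": 1.0},
            lower_bound=0.0,
            upper_bound=cap,
            subsystem="exchange",
            categories=frozenset({"exchange"}),
        )
    )
    # first step is an enzyme complex, second an isoenzyme pair,
    # the rest single-gene reactions
    gprs = {1: "gA1 and gA2", 2: "gB1 or gB2"}
    for i in range(1, n + 1):
        gpr_text = gprs.get(i, f"gC{i}")
        rxns.append(
            Reaction(
                id=f"CHAIN{i}",
                name=f"chain step {i}",
                stoichiometry={f"M{i-1}": -1.0, f"M{i}": 1.0},
                gpr=parse_gpr(gpr_text),
                subsystem="glycolysis" if i % 2 else "tca_cycle",
                categories=frozenset(
                    {"carbon", "catabolic"} if i % 2 else {"nitrogen", "anabolic"}
                ),
            )
        )
    for k in range(1, spec.n_parallel_paths + 1):
        mets.append(Metabolite(f"P{k}", compartment="c"))
        rxns.append(
            Reaction(
                id=f"PAR{k}a",
                name=f"detour {k} entry",
                stoichiometry={"M0": -1.0, f"P{k}": 1.0},
                gpr=parse_gpr(f"gP{k}a"),
                subsystem="bypass",
                categories=frozenset({"carbon", "anabolic"}),
            )
        )
        rxns.append(
            Reaction(
                id=f"PAR{k}b",
                name=f"detour {k} exit",
                stoichiometry={f"P{k}": -1.0, "M1": 1.0},
                gpr=parse_gpr(f"gP{k}b"),
                subsystem="bypass",
                categories=frozenset({"carbon", "anabolic"}),
            )
        )
    for k in range(1, spec.n_cycles + 1):
        mets.append(Metabolite(f"Z{k}1", compartment="c"))
        mets.append(Metabolite(f"Z{k}2", compartment="c"))
        cycle = [
            (f"CYC{k}a", {"M1": -1.0, f"Z{k}1": 1.0}),
            (f"CYC{k}b", {f"Z{k}1": -1.0, f"Z{k}2": 1.0}),
            (f"CYC{k}c", {f"Z{k}2": -1.0, "M1": 1.0}),
        ]
        for rid, stoich in cycle:
            rxns.append(
                Reaction(
                    id=rid,
                    name=f"futile cycle {k}",
                    stoichiometry=stoich,
                    subsystem="futile_cycle",
                    categories=frozenset({"catabolic"}),
                )
            )
    rxns.append(
        Reaction(
            id="BIOMASS",
            name="biomass sink",
            stoichiometry={f"M{n}": -1.0},
            objective_coefficient=1.0,
            subsystem="biomass",
            categories=frozenset({"anabolic"}),
        )
    )
    model = MetabolicModel(
        id=f"toy_chain{n}_par{spec.n_parallel_paths}_cyc{spec.n_cycles}",
        metabolites=mets,
        reactions=rxns,
        biomass_reaction_id="BIOMASS",
    )
    report = validate_model(model)
    if report.errors:
        raise AssertionError(f"generator produced an invalid model: {report.errors}")
    known_optimum = cap
    known_min_l1 = cap * (n + 2)
    return model, known_optimum, known_min_l1


def make_random_model(rng: np.random.Generator) -> MetabolicModel:
    """Random stoichiometrically closed model with <= 12 reactions.

    Intended for solver cross-checks: a capped uptake and a demanded
    sink keep a nonzero optimum likely; internal reactions get random
    sparse stoichiometry and bounds that always include zero, so
    v = 0 is feasible and the LP is bounded.
    """
    n_mets = int(rng.integers(3, 7))
    mets = [Metabolite(f"m{i}") for i in range(n_mets)]
    rxns = [
        Reaction(
            id="EX_in",
            stoichiometry={"m0": 1.0},
            upper_bound=float(rng.uniform(1, 10)),
        )
    ]
    n_internal = int(rng.integers(2, 10))
    for j in range(n_internal):
        k = int(rng.integers(2, min(4, n_mets) + 1))
        chosen = rng.choice(n_mets, size=k, replace=False)
        coefs = rng.choice([-2.0, -1.0, 1.0, 2.0], size=k)
        if (coefs > 0).all():
            coefs[0] = -1.0
        if (coefs < 0).all():
            coefs[-1] = 1.0
        reversible = bool(rng.random() < 0.4)
        rxns.append(
            Reaction(
                id=f"r{j}",
                stoichiometry={f"m{m}": float(c) for m, c in zip(chosen, coefs)},
                reversible=reversible,
                lower_bound=-float(rng.uniform(1, 20)) if reversible else 0.0,
                upper_bound=float(rng.uniform(1, 20)),
            )
        )
    sink_met = f"m{int(rng.integers(0, n_mets))}"
    rxns.append(
        Reaction(
            id="BIOMASS",
            stoichiometry={sink_met: -1.0},
            objective_coefficient=1.0,
        )
    )
    return MetabolicModel(
        id="random", metabolites=mets, reactions=rxns, biomass_reaction_id="BIOMASS"
    )


def make_proteome(
    spec: ProteomeSpec,
    genes: list[str],
    de_genes: list[str] | None = None,
) -> tuple[ProteomeTable, list[str]]:
    """Replicate intensity table with injected DE; returns (table, truth).

    Proteins are the model genes, padded with null background proteins
    up to ``n_proteins``.  DE identities default to a seeded random
    draw of ``de_fraction`` of all proteins; pass ``de_genes`` to pin
    them (e.g. to the genes on the biomass path).  DE proteins are
    shifted by ``de_log2_shift`` in every non-control condition.
    """
    if not genes:
        raise ValueError("gene list must be non-empty")
    rng = np.random.default_rng(spec.seed)
    proteins = list(genes)
    for i in range(len(proteins), spec.n_proteins):
        proteins.append(f"null{i:04d}")

    if de_genes is None:
        n_de = int(round(spec.de_fraction * len(proteins)))
        if spec.de_fraction > 0 and n_de < 1:
            import warnings

            warnings.warn("de_fraction too small: no DE proteins injected")
        de_set = set(rng.choice(proteins, size=n_de, replace=False)) if n_de else set()
    else:
        unknown = set(de_genes) - set(proteins)
        if unknown:
            raise ValueError(f"de_genes not in protein list: {sorted(unknown)}")
        de_set = set(de_genes)

    # per-protein baselines spread log-uniformly within 2x either way
    baselines = spec.baseline_mean * 2.0 ** rng.uniform(-1, 1, size=len(proteins))
    control = spec.conditions[0]
    records = []
    for p_idx, protein in enumerate(proteins):
        for condition in spec.conditions:
            shift = (
                spec.de_log2_shift
                if (protein in de_set and condition != control)
                else 0.0
            )
            noise = rng.normal(0.0, spec.noise_sigma, size=spec.n_replicates)
            for rep in range(1, spec.n_replicates + 1):
                intensity = baselines[p_idx] * 2.0 ** (shift + noise[rep - 1])
                records.append((protein, condition, rep, float(intensity)))
    table = ProteomeTable(
        pd.DataFrame(records, columns=ProteomeTable.COLUMNS)
    )
    return table, sorted(de_set)


def make_bundle(
    outdir: str | Path,
    model_spec: ToyModelSpec | None = None,
    proteome_spec: ProteomeSpec | None = None,
    de_genes: list[str] | None = None,
) -> dict[str, Path]:
    """Write a self-contained fixture directory for the full pipeline.

    Emits model.json, proteome.tsv, annotation.tsv (reaction -> mock
    KEGG ids) and truth.json (known optimum, known minimal L1, DE
    ground truth, condition labels).
    """
    model_spec = model_spec or ToyModelSpec()
    model, z_opt, min_l1 = make_toy_model(model_spec)
    genes = sorted(model.genes)
    proteome_spec = proteome_spec or ProteomeSpec(
        n_proteins=max(20, len(genes)), seed=model_spec.seed
    )
    table, truth_de = make_proteome(proteome_spec, genes, de_genes=de_genes)

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "model": outdir / "model.json",
        "proteome": outdir / "proteome.tsv",
        "annotation": outdir / "annotation.tsv",
        "truth": outdir / "truth.json",
    }
    save_model(model, paths["model"], format="json")
    table.to_tsv(paths["proteome"])
    with open(paths["annotation"], "w") as fh:
        fh.write("reaction_id\tkegg_id\n")
        for j, rxn in enumerate(model.reactions, start=1):
            fh.write(f"{rxn.id}\tR{j:05d}\n")
    paths["truth"].write_text(
        json.dumps(
            {
                "known_optimum": z_opt,
                "known_min_l1": min_l1,
                "de_proteins": truth_de,
                "conditions": list(proteome_spec.conditions),
                "control": proteome_spec.conditions[0],
                "de_log2_shift": proteome_spec.de_log2_shift,
            },
            indent=1,
        )
    )
    return paths


def stress_bundle(
    outdir: str | Path, seed: int = 0, de_log2_shift: float = -4.0
) -> dict[str, Path]:
    """Bundle emulating a temperature-stress proteome experiment.

    All genes on the biomass path (the chain steps) are injected as DE
    with a log2 downshift in the stress condition, so the
    expression-constrained optimum under stress falls below the
    control optimum — the qualitative growth-vs-stress readout the
    pipeline is meant to recover.  The default downshift of 4 log2
    units exceeds the 2-log2 spread of the baselines around 50, so
    every shifted level lands below the uptake cap of 10 regardless
    of seed.
    """
    model_spec = ToyModelSpec(seed=seed)
    model, _, _ = make_toy_model(model_spec)
    chain_genes = sorted(
        g
        for rxn in model.reactions
        if rxn.id.startswith("CHAIN") and rxn.gpr is not None
        for g in rxn.gpr.genes()
    )
    proteome_spec = ProteomeSpec(
        n_proteins=max(20, len(model.genes)),
        seed=seed,
        de_log2_shift=de_log2_shift,
    )
    return make_bundle(
        outdir,
        model_spec=model_spec,
        proteome_spec=proteome_spec,
        de_genes=chain_genes,
    )
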