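"""Metabolic model data types and I/O (JSON, SBML, TSV dialects).

The in-memory representation is deliberately small: metabolites,
reactions with stoichiometry and bounds, a biomass objective, GPR
rules and optional pathway annotations — exactly what the
constraint-based pipeline consumes.  JSON is the canonical lossless
format; SBML Level 3 (fbc gene associations) and a three-file TSV
dialect are supported for interoperability.

Default bounds follow the community convention of +/-1000 arbitrary
flux units (mmol gDW^-1 h^-1 implied, never enforced).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import numpy as np

from .gpr import GPRExpression, parse_gpr

DEFAULT_BOUND = 1000.0

#: reaction category tags recognised by the pathway summaries
CATEGORY_TAGS = {"carbon", "nitrogen", "anabolic", "catabolic", "exchange"}

ModelFormat = Literal["json", "sbml", "tsv"]


class ModelIOError(ValueError):
    """Raised when a model file cannot be parsed."""


@dataclass
class Metabolite:
    id: str
    name: str = ""
    compartment: str = "c"


@dataclass
class Reaction:
    id: str
    stoichiometry: dict[str, float]
    reversible: bool = False
    lower_bound: float = 0.0
    upper_bound: float = DEFAULT_BOUND
    gpr: GPRExpression | None = None
    objective_coefficient: float = 0.0
    subsystem: str | None = None
    categories: frozenset[str] = frozenset()
    name: str = ""

    @property
    def is_exchange(self) -> bool:
        """Boundary reactions touch a single metabolite."""
        return len(self.stoichiometry) <= 1


@dataclass
class MetabolicModel:
    metabolites: list[Metabolite]
    reactions: list[Reaction]
    biomass_reaction_id: str
    id: str = "model"

    @property
    def genes(self) -> set[str]:
        """Union of all GPR leaf genes."""
        out: set[str] = set()
        for rxn in self.reactions:
            if rxn.gpr is not None:
                out |= rxn.gpr.genes()
        return out

    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def get_reaction(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(f"unknown reaction {rid!r}")

    def stoichiometric_matrix(self) -> np.ndarray:
        """Dense S (metabolites x reactions), signs as stored."""
        met_index = {m.id: i for i, m in enumerate(self.metabolites)}
        S = np.zeros((len(self.metabolites), len(self.reactions)))
        for j, rxn in enumerate(self.reactions):
            for mid, coef in rxn.stoichiometry.items():
                S[met_index[mid], j] = coef
        return S


@dataclass
class ValidationReport:
    errors: list[tuple[str, str]] = field(default_factory=list)
    warnings: list[tuple[str, str]] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


def validate_model(model: MetabolicModel) -> ValidationReport:
    """Check structural invariants; reports, never raises."""
    rep = ValidationReport()
    if not model.reactions:
        rep.errors.append(("no_reactions", "model has no reactions"))
    met_ids = model.metabolite_ids()
    dup_mets = {m for m in met_ids if met_ids.count(m) > 1}
    for m in sorted(dup_mets):
        rep.errors.append(("duplicate_metabolite", f"metabolite id {m!r} duplicated"))
    for m in model.metabolites:
        if not m.id:
            rep.errors.append(("empty_metabolite_id", "metabolite with empty id"))
    rxn_ids = model.reaction_ids()
    dup_rxns = {r for r in rxn_ids if rxn_ids.count(r) > 1}
    for r in sorted(dup_rxns):
        rep.errors.append(("duplicate_reaction", f"reaction id {r!r} duplicated"))
    met_set = set(met_ids)
    for rxn in model.reactions:
        if rxn.lower_bound > rxn.upper_bound:
            rep.errors.append(
                (
                    "bound_order",
                    f"reaction {rxn.id}: lower_bound {rxn.lower_bound} > "
                    f"upper_bound {rxn.upper_bound}",
                )
            )
        if rxn.lower_bound < 0 and not rxn.reversible:
            rep.errors.append(
                (
                    "irreversible_negative_lb",
                    f"reaction {rxn.id}: negative lower bound on an "
                    "irreversible reaction",
                )
            )
        for mid in rxn.stoichiometry:
            if mid not in met_set:
                rep.errors.append(
                    (
                        "dangling_metabolite",
                        f"reaction {rxn.id} references unknown metabolite {mid!r}",
                    )
                )
        if not rxn.stoichiometry and not rxn.is_exchange:
            rep.errors.append(
                ("empty_stoichiometry", f"reaction {rxn.id} has no stoichiometry")
            )
        bad_tags = rxn.categories - CATEGORY_TAGS
        if bad_tags:
            rep.warnings.append(
                (
                    "unknown_category",
                    f"reaction {rxn.id}: unknown category tags {sorted(bad_tags)}",
                )
            )
        if rxn.subsystem is None and not rxn.is_exchange:
            rep.warnings.append(
                ("no_subsystem", f"reaction {rxn.id} has no subsystem annotation")
            )
    if model.reactions and model.biomass_reaction_id not in set(rxn_ids):
        rep.errors.append(
            (
                "missing_biomass",
                f"biomass reaction {model.biomass_reaction_id!r} not in model",
            )
        )
    if model.reactions and not any(
        r.objective_coefficient != 0 for r in model.reactions
    ):
        rep.errors.append(("no_objective", "no reaction has a nonzero objective"))
    return rep


# ---------------------------------------------------------------------------
# JSON dialect (canonical, lossless)
# ---------------------------------------------------------------------------


def _reaction_to_dict(rxn: Reaction) -> dict:
    return {
        "id": rxn.id,
        "name": rxn.name,
        "stoichiometry": rxn.stoichiometry,
        "reversible": rxn.reversible,
        "lower_bound": rxn.lower_bound,
        "upper_bound": rxn.upper_bound,
        "gpr": rxn.gpr.unparse() if rxn.gpr is not None else None,
        "objective_coefficient": rxn.objective_coefficient,
        "subsystem": rxn.subsystem,
        "categories": sorted(rxn.categories),
    }


def _reaction_from_dict(d: dict) -> Reaction:
    gpr_text = d.get("gpr")
    return Reaction(
        id=d["id"],
        name=d.get("name", ""),
        stoichiometry={k: float(v) for k, v in d["stoichiometry"].items()},
        reversible=bool(d.get("reversible", False)),
        lower_bound=float(d.get("lower_bound", 0.0)),
        upper_bound=float(d.get("upper_bound", DEFAULT_BOUND)),
        gpr=parse_gpr(gpr_text) if gpr_text else None,
        objective_coefficient=float(d.get("objective_coefficient", 0.0)),
        subsystem=d.get("subsystem"),
        categories=frozenset(d.get("categories", [])),
    )


def _model_to_json_dict(model: MetabolicModel) -> dict:
    return {
        "id": model.id,
        "biomass_reaction_id": model.biomass_reaction_id,
        "metabolites": [
            {"id": m.id, "name": m.name, "compartment": m.compartment}
            for m in model.metabolites
        ],
        "reactions": [_reaction_to_dict(r) for r in model.reactions],
    }


def _model_from_json_dict(d: dict) -> MetabolicModel:
    return MetabolicModel(
        id=d.get("id", "model"),
        biomass_reaction_id=d["biomass_reaction_id"],
        metabolites=[
            Metabolite(m["id"], m.get("name", ""), m.get("compartment", "c"))
            for m in d["metabolites"]
        ],
        reactions=[_reaction_from_dict(r) for r in d["reactions"]],
    )


# ---------------------------------------------------------------------------
# TSV dialect: metabolites.tsv / reactions.tsv / stoichiometry.tsv
# ---------------------------------------------------------------------------


def _save_tsv(model: MetabolicModel, path: Path) -> None:
    path.mkdir(parents=True, exist_ok=True)
    with open(path / "metabolites.tsv", "w") as fh:
        fh.write("metabolite_id\tname\tcompartment\n")
        for m in model.metabolites:
            fh.write(f"{m.id}\t{m.name}\t{m.compartment}\n")
    with open(path / "reactions.tsv", "w") as fh:
        fh.write(
            "reaction_id\tname\treversible\tlower_bound\tupper_bound\t"
            "gpr\tobjective_coefficient\tsubsystem\tcategories\n"
        )
        for r in model.reactions:
            gpr = r.gpr.unparse() if r.gpr is not None else ""
            fh.write(
                f"{r.id}\t{r.name}\t{int(r.reversible)}\t"
                f"{r.lower_bound!r}\t{r.upper_bound!r}\t{gpr}\t"
                f"{r.objective_coefficient!r}\t{r.subsystem or ''}\t"
                f"{';'.join(sorted(r.categories))}\n"
            )
    with open(path / "stoichiometry.tsv", "w") as fh:
        fh.write("reaction_id\tmetabolite_id\tcoefficient\n")
        for r in model.reactions:
            for mid, coef in r.stoichiometry.items():
                fh.write(f"{r.id}\t{mid}\t{coef!r}\n")
    meta = {"id": model.id, "biomass_reaction_id": model.biomass_reaction_id}
    (path / "model.json").write_text(json.dumps(meta, indent=1))


def _read_tsv_rows(fp: Path) -> list[dict[str, str]]:
    lines = fp.read_text().splitlines()
    if not lines:
        raise ModelIOError(f"{fp}: empty file")
    header = lines[0].split("\t")
    rows = []
    for ln, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        vals = line.split("\t")
        if len(vals) != len(header):
            raise ModelIOError(f"{fp}:{ln}: expected {len(header)} columns")
        rows.append(dict(zip(header, vals)))
    return rows


def _load_tsv(path: Path) -> MetabolicModel:
    meta = json.loads((path / "model.json").read_text())
    mets = [
        Metabolite(r["metabolite_id"], r["name"], r["compartment"])
        for r in _read_tsv_rows(path / "metabolites.tsv")
    ]
    stoich: dict[str, dict[str, float]] = {}
    for r in _read_tsv_rows(path / "stoichiometry.tsv"):
        stoich.setdefault(r["reaction_id"], {})[r["metabolite_id"]] = float(
            r["coefficient"]
        )
    rxns = []
    for r in _read_tsv_rows(path / "reactions.tsv"):
        rxns.append(
            Reaction(
                id=r["reaction_id"],
                name=r["name"],
                stoichiometry=stoich.get(r["reaction_id"], {}),
                reversible=bool(int(r["reversible"])),
                lower_bound=float(r["lower_bound"]),
                upper_bound=float(r["upper_bound"]),
                gpr=parse_gpr(r["gpr"]) if r["gpr"] else None,
                objective_coefficient=float(r["objective_coefficient"]),
                subsystem=r["subsystem"] or None,
                categories=frozenset(
                    t for t in r["categories"].split(";") if t
                ),
            )
        )
    return MetabolicModel(
        id=meta["id"],
        biomass_reaction_id=meta["biomass_reaction_id"],
        metabolites=mets,
        reactions=rxns,
    )


# ---------------------------------------------------------------------------
# SBML Level 3 + fbc
# ---------------------------------------------------------------------------


def _gpr_to_association(expr: GPRExpression, fbc_parent, libsbml) -> None:
    from .gpr import And, Gene, Or

    if isinstance(expr, Gene):
        ref = fbc_parent.createGeneProductRef()
        ref.setGeneProduct(_sbml_safe(expr.id))
        return
    assoc = (
        fbc_parent.createAnd() if isinstance(expr, And) else fbc_parent.createOr()
    )
    for child in expr.children:
        _gpr_to_association(child, assoc, libsbml)


def _association_to_gpr(assoc, id_map: dict[str, str]) -> GPRExpression:
    import libsbml

    from .gpr import And, Gene, Or

    if assoc.isGeneProductRef():
        return Gene(id_map[assoc.getGeneProduct()])
    children = tuple(
        _association_to_gpr(assoc.getAssociation(i), id_map)
        for i in range(assoc.getNumAssociations())
    )
    if assoc.isFbcAnd():
        return And(children)
    if assoc.isFbcOr():
        return Or(children)
    raise ModelIOError("unsupported gene association node")


def _sbml_safe(identifier: str) -> str:
    """SBML SIds must match [A-Za-z_][A-Za-z0-9_]*."""
    out = "".join(c if c.isalnum() or c == "_" else "_" for c in identifier)
    if not out or not (out[0].isalpha() or out[0] == "_"):
        out = "x_" + out
    return out


def _save_sbml(model: MetabolicModel, path: Path) -> None:
    import libsbml

    ns = libsbml.SBMLNamespaces(3, 1)
    ns.addPackageNamespace("fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sbml_model = doc.createModel()
    sbml_model.setId(_sbml_safe(model.id))
    mplug = sbml_model.getPlugin("fbc")
    mplug.setStrict(False)

    compartments = sorted({m.compartment for m in model.metabolites} or {"c"})
    for cid in compartments:
        comp = sbml_model.createCompartment()
        comp.setId(_sbml_safe(cid))
        comp.setConstant(True)

    met_map = {}
    for m in model.metabolites:
        sp = sbml_model.createSpecies()
        sid = _sbml_safe("M_" + m.id)
        met_map[m.id] = sid
        sp.setId(sid)
        sp.setName(m.name or m.id)
        sp.setCompartment(_sbml_safe(m.compartment))
        sp.setHasOnlySubstanceUnits(False)
        sp.setBoundaryCondition(False)
        sp.setConstant(False)

    gene_map = {}
    for gene in sorted(model.genes):
        gp = mplug.createGeneProduct()
        gid = _sbml_safe("G_" + gene)
        gene_map[gene] = gid
        gp.setId(gid)
        gp.setLabel(gene)

    # distinct parameters per bound keep values lossless
    def bound_param(value: float, tag: str) -> str:
        pid = _sbml_safe(f"bnd_{tag}")
        if sbml_model.getParameter(pid) is None:
            par = sbml_model.createParameter()
            par.setId(pid)
            par.setValue(value)
            par.setConstant(True)
        return pid

    objective = mplug.createObjective()
    objective.setId("obj")
    objective.setType("maximize")
    mplug.setActiveObjectiveId("obj")

    for j, rxn in enumerate(model.reactions):
        rx = sbml_model.createReaction()
        rid = _sbml_safe("R_" + rxn.id)
        rx.setId(rid)
        rx.setName(rxn.name or rxn.id)
        rx.setReversible(rxn.reversible)
        rx.setFast(False)
        for mid, coef in rxn.stoichiometry.items():
            if coef < 0:
                ref = rx.createReactant()
                ref.setStoichiometry(-coef)
            else:
                ref = rx.createProduct()
                ref.setStoichiometry(coef)
            ref.setSpecies(met_map[mid])
            ref.setConstant(True)
        rplug = rx.getPlugin("fbc")
        rplug.setLowerFluxBound(bound_param(rxn.lower_bound, f"lb_{j}"))
        rplug.setUpperFluxBound(bound_param(rxn.upper_bound, f"ub_{j}"))
        if rxn.gpr is not None:
            ga = rplug.createGeneProductAssociation()
            _gpr_to_association(_rename_gpr(rxn.gpr, gene_map), ga, libsbml)
        if rxn.objective_coefficient != 0:
            fo = objective.createFluxObjective()
            fo.setReaction(rid)
            fo.setCoefficient(rxn.objective_coefficient)
        # non-SBML annotations survive in notes
        notes = []
        if rxn.subsystem:
            notes.append(f"<p>SUBSYSTEM: {rxn.subsystem}</p>")
        if rxn.categories:
            notes.append(f"<p>CATEGORIES: {';'.join(sorted(rxn.categories))}</p>")
        notes.append(f"<p>ORIGINAL_ID: {rxn.id}</p>")
        rx.setNotes(
            "<body xmlns='http://www.w3.org/1999/xhtml'>"
            + "".join(notes)
            + "</body>"
        )

    for m, sid in met_map.items():
        sp = sbml_model.getSpecies(sid)
        sp.setNotes(
            "<body xmlns='http://www.w3.org/1999/xhtml'>"
            f"<p>ORIGINAL_ID: {m}</p></body>"
        )
    sbml_model.setNotes(
        "<body xmlns='http://www.w3.org/1999/xhtml'>"
        f"<p>BIOMASS: {model.biomass_reaction_id}</p>"
        f"<p>ORIGINAL_ID: {model.id}</p></body>"
    )
    if libsbml.writeSBMLToFile(doc, str(path)) != 1:
        raise ModelIOError(f"could not write SBML to {path}")


def _rename_gpr(expr: GPRExpression, mapping: dict[str, str]) -> GPRExpression:
    from .gpr import And, Gene, Or

    if isinstance(expr, Gene):
        return Gene(mapping[expr.id])
    cls = And if isinstance(expr, And) else Or
    return cls(tuple(_rename_gpr(c, mapping) for c in expr.children))


def _notes_field(notes_str: str, key: str) -> str | None:
    for line in notes_str.splitlines():
        text = line.strip()
        for tag in ("<p>", "</p>"):
            text = text.replace(tag, "")
        if text.startswith(f"{key}:"):
            return text[len(key) + 1 :].strip()
    return None


def _load_sbml(path: Path) -> MetabolicModel:
    import libsbml

    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise ModelIOError(
            f"SBML parse error at line {err.getLine()}: {err.getMessage()}"
        )
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise ModelIOError("SBML file contains no model")
    mplug = sbml_model.getPlugin("fbc")

    def original_id(element, fallback: str) -> str:
        if element.isSetNotes():
            val = _notes_field(element.getNotesString(), "ORIGINAL_ID")
            if val:
                return val
        return fallback

    mets = []
    met_map = {}
    for i in range(sbml_model.getNumSpecies()):
        sp = sbml_model.getSpecies(i)
        mid = original_id(sp, sp.getId())
        met_map[sp.getId()] = mid
        mets.append(Metabolite(mid, sp.getName(), sp.getCompartment()))

    gene_map = {}
    if mplug is not None:
        for i in range(mplug.getNumGeneProducts()):
            gp = mplug.getGeneProduct(i)
            gene_map[gp.getId()] = gp.getLabel() or gp.getId()

    obj_coefs: dict[str, float] = {}
    if mplug is not None and mplug.getActiveObjective() is not None:
        obj = mplug.getActiveObjective()
        for i in range(obj.getNumFluxObjectives()):
            fo = obj.getFluxObjective(i)
            obj_coefs[fo.getReaction()] = fo.getCoefficient()

    rxns = []
    for i in range(sbml_model.getNumReactions()):
        rx = sbml_model.getReaction(i)
        rid = original_id(rx, rx.getId())
        stoich: dict[str, float] = {}
        for k in range(rx.getNumReactants()):
            ref = rx.getReactant(k)
            mid = met_map[ref.getSpecies()]
            stoich[mid] = stoich.get(mid, 0.0) - ref.getStoichiometry()
        for k in range(rx.getNumProducts()):
            ref = rx.getProduct(k)
            mid = met_map[ref.getSpecies()]
            stoich[mid] = stoich.get(mid, 0.0) + ref.getStoichiometry()
        rplug = rx.getPlugin("fbc")
        lb, ub = -DEFAULT_BOUND, DEFAULT_BOUND
        gpr = None
        if rplug is not None:
            lbp = sbml_model.getParameter(rplug.getLowerFluxBound())
            ubp = sbml_model.getParameter(rplug.getUpperFluxBound())
            if lbp is not None:
                lb = lbp.getValue()
            if ubp is not None:
                ub = ubp.getValue()
            if rplug.isSetGeneProductAssociation():
                gpr = _association_to_gpr(
                    rplug.getGeneProductAssociation().getAssociation(), gene_map
                )
        subsystem = categories = None
        if rx.isSetNotes():
            notes = rx.getNotesString()
            subsystem = _notes_field(notes, "SUBSYSTEM")
            categories = _notes_field(notes, "CATEGORIES")
        rxns.append(
            Reaction(
                id=rid,
                name=rx.getName(),
                stoichiometry=stoich,
                reversible=rx.getReversible(),
                lower_bound=lb,
                upper_bound=ub,
                gpr=gpr,
                objective_coefficient=obj_coefs.get(rx.getId(), 0.0),
                subsystem=subsystem,
                categories=frozenset(
                    t for t in (categories or "").split(";") if t
                ),
            )
        )

    biomass = None
    if sbml_model.isSetNotes():
        biomass = _notes_field(sbml_model.getNotesString(), "BIOMASS")
    if biomass is None:
        with_obj = [r.id for r in rxns if r.objective_coefficient != 0]
        if not with_obj:
            raise ModelIOError("SBML model declares no objective reaction")
        biomass = with_obj[0]
    return MetabolicModel(
        id=original_id(sbml_model, sbml_model.getId()),
        biomass_reaction_id=biomass,
        metabolites=mets,
        reactions=rxns,
    )


# ---------------------------------------------------------------------------
# public entry points
# ---------------------------------------------------------------------------


def load_model(path: str | Path, format: ModelFormat | None = None) -> MetabolicModel:
    """Load a model, validate it, and return it.

    ``format`` is inferred from the path when omitted (``.json``,
    ``.xml``/``.sbml``, or a directory for the TSV triple).
    """
    path = Path(path)
    if format is None:
        format = _infer_format(path)
    if format == "json":
        try:
            model = _model_from_json_dict(json.loads(path.read_text()))
        except (KeyError, json.JSONDecodeError) as exc:
            raise ModelIOError(f"{path}: invalid model JSON: {exc}") from exc
    elif format == "sbml":
        model = _load_sbml(path)
    elif format == "tsv":
        model = _load_tsv(path)
    else:
        raise ModelIOError(f"unknown model format {format!r}")
    report = validate_model(model)
    if report.errors:
        msgs = "; ".join(m for _, m in report.errors)
        raise ModelIOError(f"{path}: model fails validation: {msgs}")
    return model


def save_model(
    model: MetabolicModel, path: str | Path, format: ModelFormat | None = None
) -> None:
    path = Path(path)
    if format is None:
        format = _infer_format(path)
    if format == "json":
        path.write_text(json.dumps(_model_to_json_dict(model), indent=1))
    elif format == "sbml":
        _save_sbml(model, path)
    elif format == "tsv":
        _save_tsv(model, path)
    else:
        raise ModelIOError(f"unknown model format {format!r}")


def _infer_format(path: Path) -> ModelFormat:
    if path.suffix == ".json":
        return "json"
    if path.suffix in (".xml", ".sbml"):
        return "sbml"
    if path.is_dir() or not path.suffix:
        return "tsv"
    raise ModelIOError(f"cannot infer model format from {path}")
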