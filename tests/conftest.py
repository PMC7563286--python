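import pytest

from protflux import (
    BoundSet,
    MetabolicModel,
    ToyModelSpec,
    make_toy_model,
    stress_bundle,
)


@pytest.fixture(scope="session")
def toy():
    """Default toy model with its analytically known LP optima."""
    model, z_opt, min_l1 = make_toy_model(ToyModelSpec())
    return model, z_opt, min_l1


@pytest.fixture(scope="session")
def toy_model(toy):
    return toy[0]


@pytest.fixture(scope="session")
def bundle_dir(tmp_path_factory):
    """Stress bundle: biomass-path genes downshifted in T22."""
    out = tmp_path_factory.mktemp("bundle")
    return stress_bundle(out, seed=1)


def build_cobra_model(model: MetabolicModel):
    """Independent LP route: the same model in cobrapy/optlang."""
    import cobra

    cm = cobra.Model(model.id)
    mets = {
        m.id: cobra.Metabolite(m.id, compartment=m.compartment or "c")
        for m in model.metabolites
    }
    reactions = []
    for r in model.reactions:
        cr = cobra.Reaction(r.id, lower_bound=r.lower_bound, upper_bound=r.upper_bound)
        reactions.append(cr)
    cm.add_reactions(reactions)
    for r, cr in zip(model.reactions, reactions):
        cr.add_metabolites({mets[k]: v for k, v in r.stoichiometry.items()})
        if r.objective_coefficient:
            cr.objective_coefficient = r.objective_coefficient
    return cm


def apply_bounds_to_cobra(cm, bounds: BoundSet):
    for rid, (lb, ub) in bounds.bounds.items():
        rxn = cm.reactions.get_by_id(rid)
        rxn.bounds = (lb, ub)
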