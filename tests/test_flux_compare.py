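"""Flux transform, fold-change classification, cut-off rule, summaries."""

import numpy as np
import pandas as pd
import pytest

from protflux import (
    FluxDistribution,
    SolverStatus,
    Stage,
    classify,
    compare,
    correlation,
    determine_cutoff,
    fold_changes,
    kegg_export,
    pathway_summary,
    transform_flux,
)


def dist(fluxes: dict[str, float]) -> FluxDistribution:
    return FluxDistribution(fluxes, 1.0, SolverStatus.OPTIMAL, Stage.PFBA)


class TestTransform:
    def test_log2_arithmetic_with_unit_sd(self):
        # {4, 8, 16, 32} -> log2 {2..5}, sd(log2) forced to 1 by spacing
        fd = dist({"a": 4.0, "b": 8.0, "c": 16.0, "d": 32.0})
        out, flags, sd = transform_flux(fd)
        assert sd == pytest.approx(np.std([2, 3, 4, 5], ddof=1))
        assert out["a"] * sd == pytest.approx(2.0)
        assert out["b"] * sd == pytest.approx(3.0)

    def test_zero_flux_flagged_and_carried(self):
        fd = dist({"a": 4.0, "b": 0.0, "c": 8.0, "d": -2.5})
        out, flags, _ = transform_flux(fd)
        assert flags["b"] and flags["d"] and not flags["a"]
        assert out["b"] == 0.0
        assert out["d"] == -2.5

    def test_transformed_values_have_unit_sd(self):
        rng = np.random.default_rng(0)
        fd = dist({f"r{i}": float(v) for i, v in enumerate(rng.lognormal(1, 1, 50))})
        out, flags, _ = transform_flux(fd)
        assert np.std(list(out.values()), ddof=1) == pytest.approx(1.0)

    def test_all_nonpositive_warns(self):
        with pytest.warns(UserWarning, match="nonpositive"):
            transform_flux(dist({"a": 0.0, "b": -1.0}))


class TestFoldChanges:
    def test_identical_distributions_are_zero(self):
        fd = dist({"a": 4.0, "b": 9.0, "c": 1.5})
        df, _, _ = fold_changes(fd, fd)
        assert df["fold_change"].abs().max() == pytest.approx(0.0)

    def test_doubling_with_matched_spread(self):
        # both datasets have the same log2 spread, so both SDs cancel
        fd_a = dist({"a": 4.0, "b": 8.0, "c": 16.0})
        fd_b = dist({"a": 8.0, "b": 16.0, "c": 32.0})
        df, sd_a, sd_b = fold_changes(fd_a, fd_b)
        assert sd_a == pytest.approx(sd_b)
        assert df.loc["a", "fold_change"] == pytest.approx(1.0 / sd_a)

    def test_antisymmetry(self):
        rng = np.random.default_rng(5)
        fd_a = dist({f"r{i}": float(v) for i, v in enumerate(rng.lognormal(0, 1, 30))})
        fd_b = dist({f"r{i}": float(v) for i, v in enumerate(rng.lognormal(0, 1, 30))})
        fwd, _, _ = fold_changes(fd_a, fd_b)
        rev, _, _ = fold_changes(fd_b, fd_a)
        assert fwd["fold_change"].to_numpy() == pytest.approx(
            -rev["fold_change"].to_numpy()
        )

    def test_nonpositive_in_either_excluded(self):
        df, _, _ = fold_changes(dist({"a": 4.0, "b": 0.0}), dist({"a": 8.0, "b": 2.0}))
        assert np.isnan(df.loc["b", "fold_change"])

    def test_mismatched_reaction_sets_error(self):
        with pytest.raises(ValueError, match="mismatched"):
            fold_changes(dist({"a": 1.0}), dist({"b": 1.0}))


class TestCutoff:
    def test_single_outlier(self):
        # {0,0,0,5}: 1/4 < 0.30 already once only the 5 exceeds
        c = determine_cutoff(np.array([0.0, 0.0, 0.0, 5.0]))
        assert 0.0 < c < 5.0
        assert c == pytest.approx(0.001)

    def test_all_zero_returns_smallest_candidate(self):
        assert determine_cutoff(np.zeros(10)) == 0.001

    def test_brute_force_agreement(self):
        rng = np.random.default_rng(9)
        for _ in range(25):
            fcs = rng.normal(0, 2, 40)
            grid = np.arange(0.001, np.abs(fcs).max() + 0.001, 0.001)
            got = determine_cutoff(fcs)
            want = next(
                c for c in grid if np.count_nonzero(np.abs(fcs) > c) / len(fcs) < 0.30
            )
            assert got == pytest.approx(want)

    def test_exceedance_nonincreasing_in_cutoff(self):
        rng = np.random.default_rng(13)
        fcs = rng.normal(0, 2, 100)
        grid = np.linspace(0, np.abs(fcs).max(), 500)
        counts = [np.count_nonzero(np.abs(fcs) > c) for c in grid]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_classification_never_exceeds_max_proportion(self):
        rng = np.random.default_rng(17)
        for _ in range(1000):
            n = int(rng.integers(5, 200))
            fcs = rng.normal(0, rng.uniform(0.5, 3), n)
            c = determine_cutoff(fcs)
            affected = np.count_nonzero(np.abs(fcs) > c)
            assert affected / n < 0.30

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            determine_cutoff(np.array([]))


class TestClassify:
    @pytest.mark.parametrize(
        "fc,expected", [(1.5, "up"), (-1.5, "down"), (0.3, "unchanged")]
    )
    def test_classes_at_published_style_cutoff(self, fc, expected):
        df = pd.DataFrame(
            {"fold_change": [fc]}, index=pd.Index(["r1"], name="reaction_id")
        )
        cmp = classify(df, cutoff=1.206)
        assert cmp.classes()["r1"] == expected

    def test_nonpositive_class(self):
        df = pd.DataFrame(
            {"fold_change": [np.nan, 2.0]},
            index=pd.Index(["rz", "ru"], name="reaction_id"),
        )
        cmp = classify(df, cutoff=1.0)
        assert cmp.classes()["rz"] == "nonpositive"
        assert cmp.classes()["ru"] == "up"

    def test_counts_partition_reaction_set(self):
        rng = np.random.default_rng(23)
        vals = rng.normal(0, 2, 60)
        vals[:10] = np.nan
        df = pd.DataFrame(
            {"fold_change": vals},
            index=pd.Index([f"r{i}" for i in range(60)], name="reaction_id"),
        )
        cmp = classify(df, cutoff=1.0)
        assert sum(cmp.counts().values()) == 60

    def test_self_comparison_has_no_changes_at_any_positive_cutoff(self):
        fd = dist({f"r{i}": float(1 + i) for i in range(10)})
        df, _, _ = fold_changes(fd, fd)
        for cutoff in (0.001, 0.5, 1.206):
            counts = classify(df, cutoff).counts()
            assert counts["up"] == 0 and counts["down"] == 0


class TestCorrelation:
    def test_identity_is_one(self):
        fd = dist({"a": 1.0, "b": 2.0, "c": 5.0})
        assert correlation(fd, fd) == pytest.approx(1.0)

    def test_negation_is_minus_one(self):
        fd = dist({"a": 1.0, "b": 2.0, "c": 5.0})
        neg = dist({k: -v for k, v in fd.fluxes.items()})
        assert correlation(fd, neg, "pearson") == pytest.approx(-1.0)

    def test_matches_reference_oracle(self):
        from scipy import stats

        rng = np.random.default_rng(31)
        xa, xb = rng.normal(0, 1, 40), rng.normal(0, 1, 40)
        fd_a = dist({f"r{i}": float(v) for i, v in enumerate(xa)})
        fd_b = dist({f"r{i}": float(v) for i, v in enumerate(xb)})
        assert correlation(fd_a, fd_b, "pearson") == pytest.approx(
            stats.pearsonr(xa, xb).statistic, abs=1e-10
        )
        assert correlation(fd_a, fd_b, "spearman") == pytest.approx(
            stats.spearmanr(xa, xb).statistic, abs=1e-10
        )

    def test_constant_vector_undefined(self):
        fd_a = dist({"a": 1.0, "b": 1.0, "c": 1.0})
        fd_b = dist({"a": 1.0, "b": 2.0, "c": 3.0})
        with pytest.warns(UserWarning, match="constant"):
            assert np.isnan(correlation(fd_a, fd_b))


class TestPathwaySummary:
    def test_hand_counted_cn_ratio(self, toy_model):
        # build a classification by hand: 1 of 2 carbon up, 1 of 4 nitrogen up
        from protflux import MetabolicModel, Metabolite, Reaction

        mets = [Metabolite("X")]
        rxns = []
        for i in range(2):
            rxns.append(
                Reaction(f"c{i}", {"X": 1.0}, categories=frozenset({"carbon"}),
                         subsystem="carbon_path")
            )
        for i in range(4):
            rxns.append(
                Reaction(f"n{i}", {"X": -1.0}, categories=frozenset({"nitrogen"}),
                         subsystem="nitrogen_path", objective_coefficient=1.0)
            )
        model = MetabolicModel(mets, rxns, "n0")
        fcs = {"c0": 2.0, "c1": 0.0, "n0": 2.0, "n1": 0.0, "n2": 0.0, "n3": 0.0}
        df = pd.DataFrame(
            {"fold_change": list(fcs.values())},
            index=pd.Index(list(fcs), name="reaction_id"),
        )
        cmp = classify(df, cutoff=1.0)
        summ = pathway_summary(cmp, model)
        assert summ.per_category.loc["carbon", "pct_affected"] == pytest.approx(50.0)
        assert summ.per_category.loc["nitrogen", "pct_affected"] == pytest.approx(25.0)
        assert summ.cn_ratio == pytest.approx(2.0)
        assert summ.nc_ratio == pytest.approx(0.5)

    def test_all_unchanged_gives_undefined_ratio(self, toy_model):
        fd = dist({r: 2.0 ** (i + 1) for i, r in enumerate(toy_model.reaction_ids())})
        cmp = compare(fd, fd)
        summ = pathway_summary(cmp, toy_model)
        assert (summ.per_pathway["pct_affected"] == 0).all()
        assert np.isnan(summ.cn_ratio)

    def test_pathway_counts_sum_to_total(self, toy_model):
        rng = np.random.default_rng(41)
        fd_a = dist(
            {r: float(rng.lognormal(0, 1)) for r in toy_model.reaction_ids()}
        )
        fd_b = dist(
            {r: float(rng.lognormal(0, 1)) for r in toy_model.reaction_ids()}
        )
        summ = pathway_summary(compare(fd_a, fd_b), toy_model)
        per = summ.per_pathway
        total = per["n_up"] + per["n_down"] + per["n_unchanged"] + per["n_nonpositive"]
        assert (total == per["n_total"]).all()
        assert per["n_total"].sum() == len(toy_model.reactions)


class TestKeggExport:
    def test_up_reaction_line(self, tmp_path):
        df = pd.DataFrame(
            {"fold_change": [2.0]}, index=pd.Index(["r1"], name="reaction_id")
        )
        cmp = classify(df, cutoff=1.206)
        path = tmp_path / "kegg.txt"
        n = kegg_export(cmp, {"r1": "R00243"}, path)
        assert n == 1
        assert path.read_text() == "R00243 blue\n"

    def test_color_per_class(self, tmp_path):
        df = pd.DataFrame(
            {"fold_change": [2.0, -2.0, 0.1, np.nan]},
            index=pd.Index(["u", "d", "s", "z"], name="reaction_id"),
        )
        cmp = classify(df, cutoff=1.0)
        path = tmp_path / "kegg.txt"
        kegg_export(cmp, {"u": "R1", "d": "R2", "s": "R3", "z": "R4"}, path)
        colors = dict(line.split() for line in path.read_text().splitlines())
        assert colors == {"R1": "blue", "R2": "red", "R3": "lightgreen", "R4": "gray"}

    def test_empty_annotation_warns_and_writes_nothing(self, tmp_path):
        df = pd.DataFrame(
            {"fold_change": [2.0]}, index=pd.Index(["r1"], name="reaction_id")
        )
        cmp = classify(df, cutoff=1.0)
        path = tmp_path / "kegg.txt"
        with pytest.warns(UserWarning, match="empty"):
            assert kegg_export(cmp, {}, path) == 0
        assert path.read_text() == ""

    def test_line_count_equals_annotated_reactions(self, tmp_path):
        df = pd.DataFrame(
            {"fold_change": np.zeros(6)},
            index=pd.Index([f"r{i}" for i in range(6)], name="reaction_id"),
        )
        cmp = classify(df, cutoff=0.5)
        annotation = {f"r{i}": f"R{i}" for i in range(4)}
        path = tmp_path / "kegg.txt"
        assert kegg_export(cmp, annotation, path) == 4
        assert len(path.read_text().splitlines()) == 4
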