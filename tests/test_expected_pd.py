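"""Expected PD loss, expected-PD change, and EDGE scoring."""

import numpy as np
import pytest

from phylorisk import (
    ConservationScenario,
    ExtinctionModel,
    branch_loss_probability,
    edge_score,
    expected_pd_change,
    expected_pd_loss,
    iucn_to_probability,
    pd_value,
    rank_by_expected_pd_gain,
    read_newick,
    synthesize,
)


class TestConversion:
    @pytest.mark.parametrize(
        "category,expected",
        [("CE", 0.99), ("E", 0.9), ("V", 0.8), ("NT", 0.4), ("LC", 0.2)],
    )
    def test_pessimistic_scheme(self, category, expected):
        assert iucn_to_probability(category) == expected

    @pytest.mark.parametrize("category", ["DD", "NE"])
    def test_no_conversion_for_unassessed(self, category):
        with pytest.raises(ValueError):
            iucn_to_probability(category)

    def test_model_requires_default_for_unassessed_tips(self, caribbean):
        meta = dict(caribbean.metadata)
        from phylorisk import TipMetadata

        meta["A_prolifera"] = TipMetadata("A_prolifera", "NE")  # drop explicit p
        with pytest.raises(ValueError, match="A_prolifera"):
            ExtinctionModel.from_metadata(meta)
        model = ExtinctionModel.from_metadata(meta, default=0.5)
        assert model.probability("A_prolifera") == 0.5

    def test_explicit_probability_overrides_category(self, caribbean):
        model = ExtinctionModel.from_metadata(caribbean.metadata)
        assert model.probability("A_prolifera") == 0.99  # NE with explicit p


class TestBranchLossProbability:
    def test_three_critically_endangered_descendants(self, caribbean, caribbean_model):
        stem = caribbean.tree.root  # branch above all three species
        q = branch_loss_probability(stem, caribbean_model)
        assert q == pytest.approx(0.99**3)
        assert round(q, 2) == 0.97

    def test_terminal_branch_is_tip_probability(self, caribbean, caribbean_model):
        tip = caribbean.tree.tip("A_cervicornis")
        assert branch_loss_probability(tip, caribbean_model) == 0.99

    def test_four_descendant_deep_branch(self, nasuta_pichoni):
        model = ExtinctionModel.from_metadata(nasuta_pichoni.metadata)
        clade = nasuta_pichoni.tree.find_clade("nasuta_clade")
        q = branch_loss_probability(clade, model)
        assert q == pytest.approx(0.4 * 0.8 * 0.8 * 0.4)
        assert round(q, 2) == 0.10

    def test_three_descendant_secure_branch(self, nasuta_pichoni):
        model = ExtinctionModel.from_metadata(nasuta_pichoni.metadata)
        clade = nasuta_pichoni.tree.find_clade("pichoni_clade")
        q = branch_loss_probability(clade, model)
        assert q == pytest.approx(0.4 * 0.4 * 0.2)
        assert round(q, 2) == 0.03

    def test_parent_branch_never_likelier_lost_than_child(self, random_fixture_12):
        fx = random_fixture_12
        model = ExtinctionModel.from_metadata(fx.metadata)
        for b in fx.tree.branches():
            for child in b.children:
                assert branch_loss_probability(b, model) <= branch_loss_probability(
                    child, model
                ) + 1e-12


class TestExpectedPDLoss:
    def test_caribbean_clade_expected_loss_82_29(self, caribbean, caribbean_model):
        # per-branch probabilities presented at two decimals:
        # 32(0.99) + 17(0.98) + 35(0.97)
        loss = expected_pd_loss(caribbean.tree, caribbean_model, prob_decimals=2)
        assert loss == pytest.approx(82.29)

    def test_full_precision_differs_only_in_rounding(self, caribbean, caribbean_model):
        exact = expected_pd_loss(caribbean.tree, caribbean_model)
        assert exact == pytest.approx(32 * 0.99 + 17 * 0.99**2 + 35 * 0.99**3)

    def test_certain_survival_and_certain_loss(self, fig1):
        tips = fig1.tree.tip_labels
        zero = ExtinctionModel({t: 0.0 for t in tips})
        one = ExtinctionModel({t: 1.0 for t in tips})
        assert expected_pd_loss(fig1.tree, zero) == 0.0
        assert expected_pd_loss(fig1.tree, one) == pytest.approx(pd_value(fig1.tree))

    def test_bounded_by_scope_pd(self, random_fixture_12):
        fx = random_fixture_12
        model = ExtinctionModel.from_metadata(fx.metadata)
        loss = expected_pd_loss(fx.tree, model)
        assert 0.0 <= loss <= pd_value(fx.tree)


class TestExpectedPDChange:
    def test_batunai_protection_gains_22_6(self, batunai_abrotanoides):
        fx = batunai_abrotanoides
        model = ExtinctionModel.from_metadata(fx.metadata)
        scenario = next(s for s in fx.scenarios if s.label == "protect_batunai")
        assert expected_pd_change(fx.tree, model, scenario) == pytest.approx(113 * 0.2)

    def test_abrotanoides_protection_gains_24_16_full_precision(self, batunai_abrotanoides):
        # 0.2*66 + 0.04*154 + 0.032*150, per-branch enumeration at full precision
        fx = batunai_abrotanoides
        model = ExtinctionModel.from_metadata(fx.metadata)
        scenario = next(s for s in fx.scenarios if s.label == "protect_abrotanoides")
        assert expected_pd_change(fx.tree, model, scenario) == pytest.approx(24.16)

    def test_caribbean_all_to_near_threatened_improves_64_67(
        self, caribbean, caribbean_model
    ):
        # with the two-decimal branch-probability convention:
        # 32(0.99-0.40) + 17(0.98-0.16) + 35(0.97-0.06) = 64.67;
        # full precision gives 64.54
        scenario = next(
            s for s in caribbean.scenarios if s.label == "all_to_near_threatened"
        )
        rounded = expected_pd_change(
            caribbean.tree, caribbean_model, scenario, prob_decimals=2
        )
        assert rounded == pytest.approx(64.67)
        exact = expected_pd_change(caribbean.tree, caribbean_model, scenario)
        assert exact == pytest.approx(
            32 * (0.99 - 0.4) + 17 * (0.99**2 - 0.4**2) + 35 * (0.99**3 - 0.4**3)
        )

    def test_empty_scenario_changes_nothing(self, batunai_abrotanoides):
        fx = batunai_abrotanoides
        model = ExtinctionModel.from_metadata(fx.metadata)
        assert expected_pd_change(fx.tree, model, ConservationScenario("noop")) == 0.0

    def test_additive_over_disjoint_clades(self, batunai_abrotanoides):
        fx = batunai_abrotanoides
        model = ExtinctionModel.from_metadata(fx.metadata)
        a, b = fx.scenarios
        combined = ConservationScenario("both", {**a.changes, **b.changes})
        assert expected_pd_change(fx.tree, model, combined) == pytest.approx(
            expected_pd_change(fx.tree, model, a)
            + expected_pd_change(fx.tree, model, b)
        )

    def test_raising_a_probability_warns(self, batunai_abrotanoides):
        fx = batunai_abrotanoides
        model = ExtinctionModel.from_metadata(fx.metadata)
        worse = ConservationScenario("worse", {"A_batunai": 0.9})
        with pytest.warns(UserWarning, match="raises"):
            change = expected_pd_change(fx.tree, model, worse)
        assert change < 0


class TestEdgeScore:
    def test_deep_branch_credits_one_third_and_one_quarter(self, nasuta_pichoni):
        # count-mode credit of the deepest in-scope branch: 1/n descendants
        tree = nasuta_pichoni.tree
        assert 1 / len(tree.find_clade("pichoni_clade").tipset) == pytest.approx(1 / 3)
        assert 1 / len(tree.find_clade("nasuta_clade").tipset) == pytest.approx(1 / 4)

    def test_count_mode_scores_within_clade_scopes(self, nasuta_pichoni):
        fx = nasuta_pichoni
        model = ExtinctionModel.from_metadata(fx.metadata)
        s_nas = edge_score(fx.tree, model, "A_nasuta", "count", scope="nasuta_clade")
        s_pic = edge_score(fx.tree, model, "A_pichoni", "count", scope="pichoni_clade")
        assert s_nas == pytest.approx((1 + 1 / 4) * 0.4)
        assert s_pic == pytest.approx((1 + 1 / 3) * 0.4)
        assert s_pic > s_nas  # EDGE prefers A. pichoni...

    def test_edge_rank_reversal_against_expected_pd_gain(self, nasuta_pichoni):
        # ...but the expected-PD gain of securing A. nasuta is larger, because
        # its deep branch is at real risk (complementarity)
        fx = nasuta_pichoni
        model = ExtinctionModel.from_metadata(fx.metadata)
        gain_nas = expected_pd_change(
            fx.tree, model, ConservationScenario("n", {"A_nasuta": 0.0})
        )
        gain_pic = expected_pd_change(
            fx.tree, model, ConservationScenario("p", {"A_pichoni": 0.0})
        )
        assert gain_nas > gain_pic

    def test_star_tree_symmetry(self):
        tree = read_newick("(x:2,y:2,z:2);")
        model = ExtinctionModel({t: 0.5 for t in "xyz"})
        scores = {t: edge_score(tree, model, t) for t in "xyz"}
        assert len(set(round(v, 12) for v in scores.values())) == 1


class TestRanking:
    def test_abrotanoides_option_ranks_first(self, batunai_abrotanoides):
        fx = batunai_abrotanoides
        model = ExtinctionModel.from_metadata(fx.metadata)
        ranked = rank_by_expected_pd_gain(fx.tree, model, fx.scenarios)
        assert ranked[0][0].label == "protect_abrotanoides"
        assert ranked[0][1] == pytest.approx(24.16)
        assert ranked[1][1] == pytest.approx(22.6)

    def test_single_option_returned(self, batunai_abrotanoides):
        fx = batunai_abrotanoides
        model = ExtinctionModel.from_metadata(fx.metadata)
        ranked = rank_by_expected_pd_gain(fx.tree, model, fx.scenarios[:1])
        assert len(ranked) == 1

    def test_order_matches_independent_recomputation(self):
        fx = synthesize(10, seed=21)
        model = ExtinctionModel.from_metadata(fx.metadata)
        rng = np.random.default_rng(4)
        scenarios = []
        for i, tip in enumerate(fx.tree.tip_labels[:5]):
            new_p = float(rng.uniform(0, model.probability(tip)))
            scenarios.append(ConservationScenario(f"s{i}", {tip: new_p}))
        ranked = rank_by_expected_pd_gain(fx.tree, model, scenarios)
        gains = {
            s.label: expected_pd_change(fx.tree, model, s) for s in scenarios
        }
        expected_order = sorted(gains, key=lambda lab: (-gains[lab], lab))
        assert [s.label for s, _ in ranked] == expected_order
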