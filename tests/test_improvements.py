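"""Improvement economics: ratios, ranking, recommendation, stability."""

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from star_allocate import (
    ICSDataset,
    ImprovementScenario,
    cost_phb_ratio,
    cost_ratio,
    is_undefined,
    load_fixture,
    net_cost,
    rank_improvements,
    rank_stability,
    recommend,
    round_half_away,
)


class TestNetCost:
    def test_no_savings_passthrough(self):
        assert net_cost(12_345, 0) == 12_345

    def test_break_even(self):
        assert net_cost(500, 500) == 0

    def test_savings_exceeding_cost_go_negative(self):
        # gross/savings pair whose net equals the Nottingham top-ranked
        # targeted-screening scenario's published net cost
        assert net_cost(480_019, 1_824_074) == -1_344_055

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            net_cost(-1, 0)
        with pytest.raises(ValueError):
            net_cost(0, -1)


class TestCostRatio:
    def test_zero_savings(self):
        assert cost_ratio(100, 0) == 0.0

    def test_zero_cost_is_infinite(self):
        assert cost_ratio(0, 500) == math.inf

    def test_zero_over_zero_undefined(self):
        assert is_undefined(cost_ratio(0, 0))

    def test_pounds_saved_per_pound_spent(self):
        assert round_half_away(cost_ratio(480_019, 1_824_074), 2) == 3.80


class TestCostPhbRatio:
    @pytest.mark.parametrize(
        "net,phb,expected",
        [
            (-1_344_055, 254_505, -5.28),
            (-553_523, 24_820, -22.30),
            (0, 79_200, 0.00),
            (25_836, 1_932, 13.37),
        ],
    )
    def test_two_decimal_display_values(self, net, phb, expected):
        assert round_half_away(cost_phb_ratio(net, phb), 2) == expected

    def test_zero_benefit_is_undefined(self):
        assert is_undefined(cost_phb_ratio(100, 0))

    def test_sign_coherence(self):
        assert cost_phb_ratio(-10, 5) < 0
        assert cost_phb_ratio(10, 5) > 0


def scen(iid, phb, net, label="base", **kw):
    return ImprovementScenario(
        improvement_id=iid, scenario_label=label, phb_gain=phb, net_cost=net, **kw
    )


class TestRanking:
    def test_gloucestershire_top_five_order(self):
        ds = load_fixture("gloucestershire")
        ranked = rank_improvements(ds.improvements)
        top = [(r.improvement_id, round_half_away(r.cost_phb_ratio, 2))
               for r in ranked[:5]]
        assert top == [
            ("vw_effective_use", -19.09),
            ("proactive_case_finding", -6.87),
            ("pr_uptake", -0.66),
            ("mindsong_kiactiv", -0.39),
            ("vba_tobacco", -0.03),
        ]

    def test_single_scenario_rank_one(self):
        (r,) = rank_improvements([scen("only", 10, 5)])
        assert r.rank == 1

    def test_equal_ratio_tie_broken_by_phb(self):
        ranked = rank_improvements([scen("small", 10, 0), scen("large", 79_200, 0)])
        assert [r.improvement_id for r in ranked] == ["large", "small"]

    def test_undefined_ratio_last(self):
        ranked = rank_improvements([scen("nophb", 0, 100), scen("ok", 10, 50)])
        assert ranked[-1].improvement_id == "nophb"
        assert is_undefined(ranked[-1].cost_phb_ratio)

    def test_ranks_are_a_permutation(self):
        ds = load_fixture("birmingham_solihull")
        ranked = rank_improvements(ds.improvements)
        assert sorted(r.rank for r in ranked) == list(range(1, len(ranked) + 1))

    @given(st.permutations(range(6)))
    def test_input_order_irrelevant(self, perm):
        base = [scen(f"s{i}", 10 + i, 100 - 30 * i) for i in range(6)]
        shuffled = [base[i] for i in perm]
        assert [r.key for r in rank_improvements(base)] == [
            r.key for r in rank_improvements(shuffled)
        ]

    @given(
        st.lists(
            st.tuples(st.floats(1, 1000), st.floats(0, 1000), st.floats(0, 1000)),
            min_size=2,
            max_size=6,
        ),
        st.floats(1, 500),
    )
    def test_more_savings_never_worsens_rank(self, rows, extra):
        scens = [
            ImprovementScenario(
                improvement_id=f"s{i}", phb_gain=phb,
                implementation_cost=gross, offset_savings=sav,
            )
            for i, (phb, gross, sav) in enumerate(rows)
        ]
        before = {r.key: r.rank for r in rank_improvements(scens)}
        target = scens[0]
        bumped = target.model_copy(
            update={"offset_savings": target.offset_savings + extra}
        )
        after = {r.key: r.rank for r in rank_improvements([bumped] + scens[1:])}
        assert after[target.key] <= before[target.key]


class TestRecommend:
    def test_zero_cap_admits_net_saver(self):
        ranked = rank_improvements([scen("saver", 100, -500), scen("buyer", 100, 50)])
        rec = recommend(ranked, budget_cap=0)
        assert [r.improvement_id for r in rec.selected] == ["saver", "buyer"]
        assert rec.cumulative_net_cost == -450

    def test_minus_infinity_cap_selects_nothing(self):
        ranked = rank_improvements([scen("saver", 100, -500)])
        assert recommend(ranked, budget_cap=-math.inf).selected == ()

    def test_ratio_threshold_stops_selection(self):
        ranked = rank_improvements([scen("good", 100, 50), scen("bad", 10, 100)])
        rec = recommend(ranked, ratio_threshold=1.0)
        assert [r.improvement_id for r in rec.selected] == ["good"]

    @given(
        st.lists(
            st.tuples(st.floats(1, 100), st.floats(-500, 500)),
            min_size=1,
            max_size=8,
        ),
        st.floats(-200, 1000),
    )
    def test_greedy_respects_cap_and_rank_order(self, rows, cap):
        ranked = rank_improvements(
            [scen(f"s{i}", phb, net) for i, (phb, net) in enumerate(rows)]
        )
        rec = recommend(ranked, budget_cap=cap)
        # brute-force re-walk: selection is a prefix of rank order and every
        # running total stays under the cap
        running = 0.0
        for picked, item in zip(rec.selected, ranked):
            assert picked.key == item.key
            running += picked.net_cost
            assert running <= cap
        assert rec.cumulative_net_cost == pytest.approx(running)


class TestStability:
    def make_ds(self, scenarios):
        return ICSDataset(name="s", population_copd=100, improvements=scenarios)

    def test_zero_noise_reproduces_point_ranking(self):
        ds = load_fixture("coventry_place")
        df = rank_stability(ds, delta=0.0, n_draws=25, seed=5, top_k=3)
        assert set(df["top_k_freq"]) <= {0.0, 1.0}
        assert (df["mean_rank"] == df["point_rank"]).all()
        assert ((df["top_k_freq"] == 1.0) == (df["point_rank"] <= 3)).all()

    def test_same_seed_identical_output(self, synthetic_dataset):
        a = rank_stability(synthetic_dataset, delta=5, n_draws=50, seed=42)
        b = rank_stability(synthetic_dataset, delta=5, n_draws=50, seed=42)
        assert a.equals(b)

    def test_separated_ratios_keep_top_rank(self):
        # ratios -20 and +15; a one-point VAS wobble cannot cross them
        ds = self.make_ds(
            [
                ImprovementScenario(
                    improvement_id="saver", additional_treated=2, nnt=1,
                    benefit_score=50, implementation_cost=0, offset_savings=2000,
                ),
                ImprovementScenario(
                    improvement_id="spender", additional_treated=2, nnt=1,
                    benefit_score=50, implementation_cost=1500, offset_savings=0,
                ),
            ]
        )
        df = rank_stability(ds, delta=1.0, n_draws=1000, seed=7, top_k=1)
        saver = df[df["improvement_id"] == "saver"].iloc[0]
        assert saver["top_k_freq"] >= 0.99

    def test_empty_dataset(self):
        df = rank_stability(self.make_ds([]), delta=1, n_draws=10, seed=0)
        assert df.empty

    def test_bad_params_rejected(self, synthetic_dataset):
        with pytest.raises(ValueError):
            rank_stability(synthetic_dataset, delta=-1, n_draws=10, seed=0)
        with pytest.raises(ValueError):
            rank_stability(synthetic_dataset, delta=1, n_draws=0, seed=0)
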