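"""Share computation, gram allocation and purchase-quantity conversion."""

import numpy as np
import pandas as pd
import pytest

from basketcost import basket_builder as bb
from conftest import make_records


class TestComputeGroupShares:
    def test_two_item_proportions(self):
        shares = bb.compute_group_shares(make_records({"A": 30, "B": 70}), "Q1")
        assert shares.set_index("item")["share"].to_dict() == pytest.approx(
            {"A": 0.30, "B": 0.70}
        )

    def test_single_item_identity(self):
        shares = bb.compute_group_shares(make_records({"A": 100}), "Q1")
        assert shares["share"].tolist() == [1.0]

    def test_unknown_stratum(self):
        with pytest.raises(ValueError, match="stratum not found"):
            bb.compute_group_shares(make_records({"A": 1}), "Q9")

    def test_all_zero_subgroup_gives_empty_set(self):
        shares = bb.compute_group_shares(make_records({"A": 0.0, "B": 0.0}), "Q1")
        assert shares.empty

    def test_unmapped_items_excluded_with_warning(self, caplog):
        rec = make_records({"A": 50, "B": 50})
        rec.loc[rec["item"] == "B", "subgroup"] = None
        with caplog.at_level("WARNING"):
            shares = bb.compute_group_shares(rec, "Q1")
        assert shares["item"].tolist() == ["A"]
        assert "no subgroup mapping" in caplog.text

    def test_min_share_drops_and_renormalizes(self):
        shares = bb.compute_group_shares(
            make_records({"A": 90, "B": 8, "C": 2}), "Q1", min_share=0.05
        )
        got = shares.set_index("item")["share"]
        assert "C" not in got.index
        assert got.sum() == pytest.approx(1.0)
        assert got["A"] == pytest.approx(90 / 98)

    def test_coverage_cutoff(self):
        shares = bb.compute_group_shares(
            make_records({"A": 60, "B": 30, "C": 10}), "Q1", coverage=0.85
        )
        assert set(shares["item"]) == {"A", "B"}
        assert shares["share"].sum() == pytest.approx(1.0)

    def test_marginal_fraction_excludes_subgroup(self):
        rec = pd.concat(
            [
                make_records({"A": 1000}, subgroup="veg"),
                make_records({"N": 0.5}, subgroup="nuts"),
            ]
        )
        shares = bb.compute_group_shares(rec, "Q1", marginal_fraction=0.01)
        assert set(shares["subgroup"]) == {"veg"}

    def test_scale_invariance(self, rng):
        q = dict(zip("ABCDE", rng.uniform(1, 100, 5)))
        a = bb.compute_group_shares(make_records(q), "Q1")
        b = bb.compute_group_shares(make_records({k: 7.3 * v for k, v in q.items()}), "Q1")
        assert np.allclose(a["share"], b["share"])

    def test_share_monotonicity(self, rng):
        q = dict(zip("ABCD", rng.uniform(1, 50, 4)))
        before = bb.compute_group_shares(make_records(q), "Q1").set_index("item")["share"]
        q["B"] += 25.0
        after = bb.compute_group_shares(make_records(q), "Q1").set_index("item")["share"]
        assert after["B"] >= before["B"]
        assert all(after[i] <= before[i] for i in "ACD")


class TestAllocation:
    def test_tomato_worked_example(self, reference_basket):
        # quantity table proportional to the published basket: tomato holds
        # 22.57% of vegetable mass, which of 300 g/day is 67.72 g/day
        veg = reference_basket[reference_basket["subgroup"] == "All Types of Vegetables"]
        records = make_records(dict(zip(veg["item"], veg["grams_consume"])))
        shares = bb.compute_group_shares(records, "Q1").set_index("item")["share"]
        assert round(shares["Tomatoes"] * 100, 2) == 22.57
        grams = bb.allocate_group_target(
            300.0, pd.DataFrame({"subgroup": "veg", "item": shares.index,
                                 "share": shares.to_numpy()})
        )
        assert grams["Tomatoes"] == pytest.approx(67.72, abs=0.005)

    def test_conservation(self):
        shares = pd.DataFrame({"subgroup": "g", "item": ["A", "B"], "share": [0.3, 0.7]})
        grams = bb.allocate_group_target(200.0, shares)
        assert grams.to_dict() == pytest.approx({"A": 60.0, "B": 140.0})
        assert grams.sum() == pytest.approx(200.0, abs=1e-9)

    def test_single_item_and_empty(self):
        one = pd.DataFrame({"subgroup": "g", "item": ["A"], "share": [1.0]})
        assert bb.allocate_group_target(100.0, one)["A"] == pytest.approx(100.0)
        assert bb.allocate_group_target(100.0, one.iloc[:0]).empty

    def test_negative_target_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            bb.allocate_group_target(-1.0, pd.DataFrame({"item": [], "share": []}))


class TestApplyFti:
    @pytest.mark.parametrize(
        "grams,factor,expected",
        [(100.00, 1.04, 96.15), (28.14, 2.5, 11.26), (42.0, 1.0, 42.0)],
    )
    def test_worked_examples(self, grams, factor, expected):
        assert bb.apply_fti(grams, factor) == pytest.approx(expected, abs=0.005)

    def test_direction(self, rng):
        # loss factor (<1) means buying more; gain factor (>1) means buying less
        for factor in rng.uniform(0.2, 3.0, 20):
            if abs(factor - 1) < 1e-9:
                continue
            out = bb.apply_fti(50.0, factor)
            assert np.sign(out - 50.0) == np.sign(1 - factor)

    def test_nonpositive_factor_rejected(self):
        with pytest.raises(ValueError, match="Lentils"):
            bb.apply_fti(10.0, 0.0, item="Lentils")


class TestBuildBasket:
    def test_reference_reproduction(self, targets, reference_shares, reference_fti,
                                    reference_basket):
        basket = bb.build_basket(targets, reference_shares, reference_fti)
        merged = basket.merge(reference_basket, on=["subgroup", "item"], suffixes=("", "_ref"))
        assert len(merged) == 65  # nuts & seeds excluded (empty share set)
        err = (merged["grams_purchase"] - merged["grams_purchase_printed"]).abs()
        assert err.max() < 0.02

    def test_consumed_totals_equal_targets(self, targets, reference_shares, reference_fti):
        basket = bb.build_basket(targets, reference_shares, reference_fti)
        tot = bb.subgroup_totals(basket).set_index("subgroup")["grams_consume"]
        tgt = targets.set_index("subgroup")["grams_per_day"]
        for sub in tot.index:  # nuts & seeds absent: zero allocation
            assert tot[sub] == pytest.approx(tgt[sub], abs=1e-9)

    def test_unit_factors_make_purchase_equal_consume(self, targets, reference_shares):
        fti = reference_shares.assign(factor=1.0)[["subgroup", "item", "factor"]]
        basket = bb.build_basket(targets, reference_shares, fti)
        assert np.allclose(basket["grams_purchase"], basket["grams_consume"])

    def test_missing_fti_defaults_to_one(self, targets, reference_shares, caplog):
        fti = pd.DataFrame({"subgroup": [], "item": [], "factor": []})
        with caplog.at_level("WARNING"):
            basket = bb.build_basket(targets, reference_shares, fti)
        assert np.allclose(basket["grams_purchase"], basket["grams_consume"])
        assert "defaulting to 1" in caplog.text

    def test_duplicate_item_rejected(self, targets, reference_fti):
        shares = pd.DataFrame(
            {"subgroup": ["All Types of Sugars"] * 2, "item": ["Sugar", "Sugar"],
             "share": [0.5, 0.5]}
        )
        with pytest.raises(ValueError, match="duplicate"):
            bb.build_basket(targets, shares, reference_fti)

    def test_round_trip(self, targets, reference_shares, reference_fti):
        basket = bb.build_basket(targets, reference_shares, reference_fti)
        rebuilt = bb.build_basket(
            targets,
            basket[["subgroup", "item", "share"]],
            basket.rename(columns={"fti": "factor"})[["subgroup", "item", "factor"]],
        )
        pd.testing.assert_frame_equal(basket, rebuilt)
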