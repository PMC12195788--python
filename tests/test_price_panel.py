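"""Splicing, outlier screening, monthly collapse and imputation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from basketcost import price_panel as pp


def obs_frame(rows):
    """rows: (item, year, month, price, segment)."""
    df = pd.DataFrame(rows, columns=["item", "year", "month", "price", "segment"])
    df["obs_id"] = range(len(df))
    return df


class TestSplice:
    def test_identical_overlap_is_identity(self):
        rows = [("A", 2020, 1, 100.0, "s1"), ("A", 2020, 2, 100.0, "s1"),
                ("A", 2020, 2, 100.0, "s2"), ("A", 2020, 3, 100.0, "s2")]
        out, rep = pp.standardize_and_splice(obs_frame(rows))
        assert np.allclose(out["price"], 100.0)
        assert rep.ratios[("s1", "A")] == pytest.approx(1.0)

    def test_ratio_rescaling_toy_panel(self):
        # hand oracle: overlap month means 100 (s1) vs 110 (s2) -> s1 scaled x1.10
        rows = [("A", 2020, 1, 90.0, "s1"), ("A", 2020, 2, 100.0, "s1"),
                ("A", 2020, 2, 110.0, "s2"), ("A", 2020, 3, 120.0, "s2")]
        out, rep = pp.standardize_and_splice(obs_frame(rows))
        assert rep.ratios[("s1", "A")] == pytest.approx(1.10)
        jan = out[(out["month"] == 1)]["price"].iloc[0]
        assert jan == pytest.approx(99.0)
        # later segment authoritative in the overlap month
        feb = out[out["month"] == 2]
        assert feb["price"].tolist() == [110.0]

    def test_three_segments_chain_like_sequential_pairs(self):
        # oracle: apply the two-segment rule twice by hand
        rows = [("A", 2020, 1, 50.0, "s1"), ("A", 2020, 2, 50.0, "s1"),
                ("A", 2020, 2, 100.0, "s2"), ("A", 2020, 3, 100.0, "s2"),
                ("A", 2020, 3, 300.0, "s3"), ("A", 2020, 4, 300.0, "s3")]
        out, rep = pp.standardize_and_splice(obs_frame(rows))
        assert rep.ratios[("s2", "A")] == pytest.approx(3.0)
        assert rep.ratios[("s1", "A")] == pytest.approx(2.0 * 3.0)
        assert out.sort_values("month")["price"].tolist() == [300.0, 300.0, 300.0, 300.0]

    def test_unmapped_labels_reported_not_silent(self):
        df = obs_frame([("x", 2020, 1, 10.0, "s1")]).rename(columns={"item": "item_raw"})
        out, rep = pp.standardize_and_splice(df, name_map={"y": "Y"})
        assert out.empty
        assert rep.unmapped == ["x"]


class TestScreenOutliers:
    def test_hard_range_rule(self):
        df = obs_frame([("A", 2020, 1, 100.0, "s"), ("A", 2020, 1, 102.0, "s"),
                        ("A", 2020, 1, 5000.0, "s")])
        ranges = pd.DataFrame({"item": ["A"], "low": [50.0], "high": [500.0]})
        out = pp.screen_outliers(df, ranges)
        assert out["outlier"].tolist() == [False, False, True]

    def test_all_within_range_unchanged(self):
        df = obs_frame([("A", 2020, m, 100.0 + m, "s") for m in range(1, 13)])
        out = pp.screen_outliers(df, pd.DataFrame({"item": ["A"], "low": [1.0],
                                                   "high": [1000.0]}))
        assert not out["outlier"].any()

    def test_mad_fallback_catches_injected_spikes(self, rng):
        rows = []
        for m in range(1, 13):
            for _ in range(4):
                rows.append(("A", 2021, m, 100.0 * rng.lognormal(0, 0.03), "s"))
        df = obs_frame(rows)
        spiked = df.copy()
        inject = [5, 17, 29]
        spiked.loc[inject, "price"] *= 10
        out = pp.screen_outliers(spiked, ranges=None, k=5.0)
        assert out.loc[inject, "outlier"].all()
        assert not out.drop(index=inject)["outlier"].any()

    def test_no_ranges_no_fallback_is_error(self):
        with pytest.raises(ValueError, match="fallback"):
            pp.screen_outliers(obs_frame([("A", 2020, 1, 1.0, "s")]), None, fallback=False)

    def test_bad_range_rejected(self):
        with pytest.raises(ValueError, match="low"):
            pp.screen_outliers(obs_frame([("A", 2020, 1, 1.0, "s")]),
                               pd.DataFrame({"item": ["A"], "low": [5.0], "high": [1.0]}))


class TestMonthlyStats:
    def test_mean_and_min(self):
        df = obs_frame([("A", 2020, 1, p, "s") for p in (100.0, 102.0, 98.0)])
        panel = pp.monthly_stats(df)
        row = panel.iloc[0]
        assert (row["mean_price"], row["min_price"], row["n_obs"]) == (100.0, 98.0, 3)
        assert row["status"] == "observed"

    def test_single_observation(self):
        panel = pp.monthly_stats(obs_frame([("A", 2020, 1, 77.0, "s")]))
        assert panel.iloc[0]["mean_price"] == panel.iloc[0]["min_price"] == 77.0

    def test_min_le_mean_everywhere(self, rng):
        rows = [("I" + str(i), 2020, m, float(p), "s")
                for i in range(4) for m in range(1, 13)
                for p in rng.uniform(10, 500, 3)]
        panel = pp.monthly_stats(obs_frame(rows))
        assert (panel["min_price"] <= panel["mean_price"] + 1e-12).all()

    def test_corrected_cells_exclude_flagged_prices(self):
        df = obs_frame([("A", 2020, 1, 100.0, "s"), ("A", 2020, 1, 9000.0, "s")])
        df["outlier"] = [False, True]
        panel = pp.monthly_stats(df)
        assert panel.iloc[0]["mean_price"] == 100.0
        assert panel.iloc[0]["status"] == "corrected"


def brute_force_nearest(panel, items, months):
    """Independent oracle: exhaustive nearest-neighbour search per cell."""
    out = {}
    for it in items:
        g = panel[panel["item"] == it]
        obs = {(y, m): (r["min_price"], r["mean_price"]) for (_, r) in g.iterrows()
               for (y, m) in [(r["year"], r["month"])]}
        for (y, m) in months:
            if (y, m) in obs:
                out[(it, y, m)] = obs[(y, m)]
                continue
            mi = y * 12 + m - 1
            dists = {k: abs(k[0] * 12 + k[1] - 1 - mi) for k in obs}
            best = min(dists.values())
            vals = [obs[k] for k, d in dists.items() if d == best]
            out[(it, y, m)] = (float(np.mean([v[0] for v in vals])),
                               float(np.mean([v[1] for v in vals])))
    return out


def panel_from_series(values_by_item, year=2021):
    rows = []
    for it, series in values_by_item.items():
        for m, v in series.items():
            if v is not None:
                rows.append({"item": it, "year": year, "month": m, "min_price": v,
                             "mean_price": v * 1.1, "n_obs": 2, "status": "observed"})
    return pd.DataFrame(rows)


class TestImputeMissing:
    def test_tie_uses_neighbour_mean(self):
        panel = panel_from_series({"A": {1: 100.0, 2: None, 3: 120.0}})
        out = pp.impute_missing(panel, window=((2021, 1), (2021, 3)))
        feb = out[(out["month"] == 2)].iloc[0]
        assert feb["min_price"] == pytest.approx(110.0)
        assert feb["status"] == "imputed" and feb["n_obs"] == 0

    def test_two_gap_months_take_nearest_sides(self):
        panel = panel_from_series({"A": {1: 100.0, 2: None, 3: None, 4: 130.0}})
        out = pp.impute_missing(panel, window=((2021, 1), (2021, 4)))
        by_month = out.set_index("month")["min_price"]
        assert by_month[2] == pytest.approx(100.0)
        assert by_month[3] == pytest.approx(130.0)

    def test_complete_panel_is_identity(self):
        panel = panel_from_series({"A": {m: float(m) for m in range(1, 13)}})
        out = pp.impute_missing(panel, window=((2021, 1), (2021, 12)))
        pd.testing.assert_frame_equal(
            out.reset_index(drop=True), panel.sort_values(["item", "year", "month"])
            .reset_index(drop=True), check_dtype=False
        )

    def test_item_with_no_observations_is_error(self):
        panel = panel_from_series({"A": {1: 10.0}})
        with pytest.raises(ValueError, match="B"):
            pp.impute_missing(panel, window=((2021, 1), (2021, 2)), items=["A", "B"])

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        st.lists(  # per item: 12 slots, each observed price or missing
            st.lists(st.one_of(st.none(), st.floats(1, 100)), min_size=12, max_size=12)
            .filter(lambda s: any(v is not None for v in s)),
            min_size=1, max_size=5,
        )
    )
    def test_matches_exhaustive_oracle(self, series_list):
        values = {f"I{i}": {m + 1: (None if v is None else float(v))
                            for m, v in enumerate(series)}
                  for i, series in enumerate(series_list)}
        panel = panel_from_series(values)
        months = [(2021, m) for m in range(1, 13)]
        out = pp.impute_missing(panel, window=((2021, 1), (2021, 12)))
        oracle = brute_force_nearest(panel, list(values), months)
        for _, r in out.iterrows():
            exp_min, exp_mean = oracle[(r["item"], r["year"], r["month"])]
            assert r["min_price"] == pytest.approx(exp_min)
            assert r["mean_price"] == pytest.approx(exp_mean)

    def test_provenance_conservation(self):
        panel = panel_from_series({"A": {1: 100.0, 3: 90.0}, "B": {2: 50.0}})
        out = pp.impute_missing(panel, window=((2021, 1), (2021, 6)))
        counts = out["status"].value_counts()
        assert counts.sum() == 2 * 6
        assert counts.get("observed", 0) == 3
        assert counts.get("imputed", 0) == 9
        # observed cells never altered
        a1 = out[(out["item"] == "A") & (out["month"] == 1)].iloc[0]
        assert a1["min_price"] == 100.0 and a1["status"] == "observed"

    def test_donor_method_uses_correlated_item(self):
        a = {m: 100.0 + m for m in range(1, 13) if m != 6}
        b = {m: 200.0 + 2 * m for m in range(1, 13)}
        panel = panel_from_series({"A": a, "B": b})
        out = pp.impute_missing(panel, window=((2021, 1), (2021, 12)), method="donor")
        jun = out[(out["item"] == "A") & (out["month"] == 6)].iloc[0]
        level_a = np.mean([v * 1.1 for v in a.values()])
        level_b = np.mean([v * 1.1 for v in b.values()])
        assert jun["min_price"] == pytest.approx(212.0 * level_a / level_b)
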