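"""Build the healthy-basket item table two ways and report what it contains.

First from the packaged published fixture (shares implied by the printed
consumed grams), reproducing the printed purchased-gram column; then from
the synthetic survey of step 01, exercising the full share-computation path
including the marginal-subgroup exclusion. Tables land in results/.
"""

import sys
from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

from basketcost import basket_builder as bb, data  # noqa: E402

RESULTS = ROOT / "results"
SURVEY = ROOT / "scratch" / "synthetic_inputs" / "survey.csv"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    targets = data.load_targets()

    # packaged fixture route
    basket = bb.build_basket(targets, data.reference_shares(), data.reference_fti())
    bb.round_for_report(basket).to_csv(RESULTS / "basket_reference.csv", index=False)
    ref = data.load_reference_basket()
    merged = basket.merge(ref, on=["subgroup", "item"], suffixes=("", "_ref"))
    err = (merged["grams_purchase"] - merged["grams_purchase_printed"]).abs()
    tot = bb.subgroup_totals(basket).set_index("subgroup")["grams_purchase"]
    tomato = basket.set_index("item").loc["Tomatoes"]
    print(f"fixture basket: {len(basket)} items; max purchased-gram deviation "
          f"from the published table {err.max():.4f} g")
    print(f"  tomato: share {100 * tomato['share']:.2f}% of vegetables -> "
          f"{tomato['grams_consume']:.2f} g/day consumed")
    print(f"  purchased totals: vegetables {tot['All Types of Vegetables']:.2f} g, "
          f"whole grains {tot['Rice, Wheat, Corn, and Others']:.2f} g, "
          f"fruits {tot['All Types of Fruits']:.2f} g, legumes {tot['Legumes']:.2f} g")

    # synthetic-survey route
    if SURVEY.exists():
        records = pd.read_csv(SURVEY)
        shares = bb.compute_group_shares(records, "Q1", marginal_fraction=0.001)
        basket_syn = bb.build_basket(targets, shares, data.reference_fti())
        bb.round_for_report(basket_syn).to_csv(RESULTS / "basket_synthetic.csv", index=False)
        excluded = set(targets["subgroup"]) - set(basket_syn["subgroup"])
        print(f"synthetic-survey basket: {len(basket_syn)} items; "
              f"marginal subgroups excluded: {sorted(excluded)}")
    else:
        print("synthetic survey not found - run analysis/01_simulate.py first")


if __name__ == "__main__":
    main()
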