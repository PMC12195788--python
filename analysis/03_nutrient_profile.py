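"""Energy and macronutrient profile of the fixture basket.

Attaches the packaged synthetic per-item nutrient table (constructed to be
consistent with the published subgroup totals) to the basket of step 02 and
reports daily energy and Atwater macronutrient shares.
"""

import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

from basketcost import basket_builder as bb, data, nutrient_profile as npr  # noqa: E402

RESULTS = ROOT / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    basket = bb.build_basket(data.load_targets(), data.reference_shares(),
                             data.reference_fti())
    contrib = npr.attach_profiles(basket, data.load_synthetic_nutrients())
    totals = npr.aggregate_totals(contrib)
    totals.as_frame().round(2).to_csv(RESULTS / "nutrient_totals.csv", index=False)
    pct = npr.macro_percentages(totals)
    print(f"daily energy: {totals.total['energy_kcal']:.2f} kcal "
          f"({totals.total['protein_g']:.2f} g protein, "
          f"{totals.total['carb_g']:.2f} g carbohydrate, "
          f"{totals.total['lipid_g']:.2f} g lipid)")
    print(f"energy shares: protein {pct['protein']:.2f}%, "
          f"carbohydrate {pct['carbohydrate']:.2f}%, lipid {pct['lipid']:.2f}%")


if __name__ == "__main__":
    main()
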