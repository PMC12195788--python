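"""Packaged reference tables and their loaders.

Ships four small CSVs:

* ``eat_lancet_targets.csv`` — daily gram targets per food group/subgroup.
* ``reference_basket.csv`` — the published basket: consumed grams, adjustment
  factor (edible-portion / yield ratio) and printed purchased grams per item.
  One factor (Melons) is back-solved from the printed purchased column,
  which is inconsistent with the printed factor; its source column says so.
* ``reference_nutrient_totals.csv`` — published energy/macronutrient totals by
  subgroup.
* ``synthetic_item_nutrients.csv`` — a synthetic per-item nutrient table
  (kcal and grams per 100 g consumed) constructed so that aggregating it
  over the published basket reproduces the published subgroup totals
  exactly: within each subgroup every item carries the subgroup-average
  density, the minimal solution consistent with the subgroup constraints.
  It is a self-contained stand-in for a food-composition database, not
  measured composition data.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

def _read(name: str) -> pd.DataFrame:
    path = resources.files("basketcost").joinpath("data", name)
    with path.open("r", encoding="utf-8") as fh:
        return pd.read_csv(fh)


def load_targets() -> pd.DataFrame:
    """Group/subgroup daily gram targets (`group, subgroup, grams_per_day`)."""
    return _read("eat_lancet_targets.csv")


def load_reference_basket() -> pd.DataFrame:
    """The published basket table, one row per (subgroup, item)."""
    return _read("reference_basket.csv")


def load_reference_nutrient_totals() -> pd.DataFrame:
    """Published energy and macronutrient totals per subgroup."""
    return _read("reference_nutrient_totals.csv")


def load_synthetic_nutrients() -> pd.DataFrame:
    """Synthetic per-100 g-consumed nutrient table keyed by (subgroup, item)."""
    return _read("synthetic_item_nutrients.csv")


def reference_shares() -> pd.DataFrame:
    """Item shares implied by the published basket's consumed grams.

    Within each subgroup share_i = grams_i / subgroup total; a subgroup with
    zero total (marginal consumption, excluded from the basket) yields no
    rows, i.e. an empty share set.
    """
    t2 = load_reference_basket()
    tot = t2.groupby("subgroup")["grams_consume"].transform("sum")
    out = t2.loc[tot > 0, ["subgroup", "item"]].copy()
    out["share"] = (t2["grams_consume"] / tot)[tot > 0]
    return out.reset_index(drop=True)


def reference_fti() -> pd.DataFrame:
    """Adjustment-factor table (`subgroup, item, factor, source`) from the basket."""
    t2 = load_reference_basket()
    return t2.rename(columns={"fti": "factor", "fti_source": "source"})[
        ["subgroup", "item", "factor", "source"]
    ].copy()
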