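"""Energy and macronutrient aggregation for a built basket.

Per-item nutrient values (kcal and grams per 100 g) are scaled by the daily
gram column, summed by subgroup and overall, and turned into macronutrient
energy shares with Atwater factors (4 kcal/g protein, 4 kcal/g carbohydrate,
9 kcal/g lipid by default). The nutrient table's basis decides which gram
column it multiplies: values per 100 g of prepared food go with consumed
grams, values per 100 g as-purchased with purchased grams.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

NUTRIENT_COLS = ["energy_kcal", "protein_g", "carb_g", "lipid_g"]
_PER100_COLS = ["energy_kcal_100g", "protein_g_100g", "carb_g_100g", "lipid_g_100g"]

#: kcal per gram of protein, carbohydrate, lipid
ATWATER_DEFAULT = (4.0, 4.0, 9.0)


@dataclass(frozen=True)
class NutrientTotals:
    """Daily nutrient aggregates: per-subgroup rows and the grand total."""

    by_subgroup: pd.DataFrame  # group, subgroup, energy_kcal, protein_g, carb_g, lipid_g
    total: pd.Series  # the four nutrient columns summed over subgroups

    def as_frame(self) -> pd.DataFrame:
        """Subgroup rows followed by a TOTAL row, as printed tables do."""
        tot = pd.DataFrame([{"group": "TOTAL", "subgroup": "", **self.total.to_dict()}])
        return pd.concat([self.by_subgroup, tot], ignore_index=True)


def attach_profiles(
    basket: pd.DataFrame,
    nutrients: pd.DataFrame,
    basis: str = "consumed",
) -> pd.DataFrame:
    """Per-item daily nutrient contributions: grams/100 x per-100 g value.

    ``nutrients`` needs ``item`` plus the four ``*_100g`` columns; an
    optional ``subgroup`` column scopes the key, since one item name can
    occur in two subgroups. ``basis`` is ``"consumed"`` or ``"purchased"``.
    """
    if basis not in ("consumed", "purchased"):
        raise ValueError(f"basis must be 'consumed' or 'purchased', got {basis!r}")
    gram_col = "grams_consume" if basis == "consumed" else "grams_purchase"

    keys = ["subgroup", "item"] if "subgroup" in nutrients.columns else ["item"]
    merged = basket.merge(nutrients[keys + _PER100_COLS], on=keys, how="left", validate="m:1")
    missing = merged["energy_kcal_100g"].isna()
    if missing.any():
        items = sorted(set(zip(merged.loc[missing, "subgroup"], merged.loc[missing, "item"])))
        raise KeyError(f"no nutrient entry for: {items}")

    out = basket.copy()
    for per100, daily in zip(_PER100_COLS, NUTRIENT_COLS):
        out[daily] = merged[gram_col].to_numpy() / 100.0 * merged[per100].to_numpy()
    return out


def aggregate_totals(contributions: pd.DataFrame) -> NutrientTotals:
    """Sum contributions by (group, subgroup); grand total = sum of subgroups."""
    if contributions.empty:
        raise ValueError("no nutrient contributions to aggregate")
    by_sub = (
        contributions.groupby(["group", "subgroup"], sort=False)[NUTRIENT_COLS]
        .sum()
        .reset_index()
    )
    return NutrientTotals(by_subgroup=by_sub, total=by_sub[NUTRIENT_COLS].sum())


def macro_percentages(
    totals: NutrientTotals | pd.Series,
    factors: tuple[float, float, float] = ATWATER_DEFAULT,
) -> dict[str, float]:
    """Percent of total energy from protein, carbohydrate and lipid.

    percent_m = 100 * grams_m * atwater_m / total energy. The three shares
    need not reach 100: energy from fibre, alcohol or rounding is left
    unaccounted.
    """
    total = totals.total if isinstance(totals, NutrientTotals) else totals
    energy = float(total["energy_kcal"])
    if energy <= 0:
        raise ValueError("total energy must be positive")
    fp, fc, fl = factors
    return {
        "protein": 100.0 * float(total["protein_g"]) * fp / energy,
        "carbohydrate": 100.0 * float(total["carb_g"]) * fc / energy,
        "lipid": 100.0 * float(total["lipid_g"]) * fl / energy,
    }
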