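"""Build the basket item table: shares, gram allocation, purchase conversion.

The procedure mirrors how a basic food basket is adapted to a dietary
standard: (1) within each food subgroup, compute each item's share of the
total quantity purchased by a reference stratum (e.g. the lowest income
quintile); (2) distribute the subgroup's recommended daily grams over items
in proportion to those shares; (3) divide consumed grams by each item's
adjustment factor (edible-portion / cooking-yield ratio, prepared mass per
purchased mass) to obtain the grams that must be purchased.

All arithmetic is carried unrounded; rounding belongs to presentation.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: columns of a basket table
BASKET_COLUMNS = [
    "group",
    "subgroup",
    "item",
    "share",
    "grams_consume",
    "fti",
    "grams_purchase",
]


def compute_group_shares(
    records: pd.DataFrame,
    stratum: str,
    *,
    min_share: float = 0.0,
    coverage: float = 1.0,
    marginal_quantity: float = 0.0,
    marginal_fraction: float = 0.0,
) -> pd.DataFrame:
    """Per-subgroup item shares of purchased quantity for one stratum.

    Parameters
    ----------
    records
        Consumption records with columns ``item, stratum, subgroup,
        quantity`` (a single declared mass unit throughout). Records with a
        missing subgroup mapping are excluded with a warning.
    stratum
        Stratum label to select (e.g. ``"Q1"``).
    min_share
        Items below this share of their subgroup are dropped and the rest
        renormalised.
    coverage
        Optional cumulative-coverage cutoff: keep the largest items until
        this fraction of subgroup mass is covered, then renormalise.
        ``1.0`` keeps everything.
    marginal_quantity, marginal_fraction
        A subgroup whose total quantity is below ``marginal_quantity``
        (absolute, same unit as ``quantity``) or below ``marginal_fraction``
        of the stratum's total purchased mass is treated as marginal
        consumption and yields an empty share set (zero allocation).

    Returns
    -------
    DataFrame with columns ``subgroup, item, share``; within each retained
    subgroup the shares sum to 1.
    """
    required = {"item", "stratum", "subgroup", "quantity"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"records missing columns: {sorted(missing)}")
    sel = records[records["stratum"] == stratum]
    if sel.empty:
        raise ValueError(f"stratum not found: {stratum!r}")
    if (sel["quantity"] < 0).any():
        raise ValueError("negative quantities in consumption records")

    unmapped = sel["subgroup"].isna() | (sel["subgroup"].astype(str).str.strip() == "")
    if unmapped.any():
        items = sorted(sel.loc[unmapped, "item"].unique())
        logger.warning("excluding %d records with no subgroup mapping: %s",
                       int(unmapped.sum()), items)
        sel = sel[~unmapped]

    totals = sel.groupby(["subgroup", "item"], sort=False)["quantity"].sum().reset_index()
    stratum_total = totals["quantity"].sum()

    out = []
    for subgroup, grp in totals.groupby("subgroup", sort=False):
        sub_total = grp["quantity"].sum()
        if sub_total <= 0:
            logger.warning("subgroup %r has all-zero quantities; empty share set", subgroup)
            continue
        if sub_total < marginal_quantity or (
            stratum_total > 0 and sub_total < marginal_fraction * stratum_total
        ):
            logger.info("subgroup %r marginal (total %.3g); excluded", subgroup, sub_total)
            continue
        share = grp["quantity"] / sub_total
        keep = share >= min_share
        grp, share = grp[keep], share[keep]
        if coverage < 1.0 and not grp.empty:
            order = np.argsort(-share.to_numpy(), kind="stable")
            cum = np.cumsum(share.to_numpy()[order])
            n_keep = int(np.searchsorted(cum, coverage) + 1)
            idx = grp.index[order[:n_keep]]
            grp, share = grp.loc[idx], share.loc[idx]
        share = share / share.sum()
        out.append(pd.DataFrame({"subgroup": subgroup, "item": grp["item"], "share": share}))
    if not out:
        return pd.DataFrame(columns=["subgroup", "item", "share"])
    return pd.concat(out, ignore_index=True)


def allocate_group_target(grams_per_day: float, shares: pd.DataFrame) -> pd.Series:
    """Distribute a subgroup's daily gram target across items by share.

    ``shares`` holds one subgroup's rows (`item, share`); returns grams per
    day indexed by item. An empty share set allocates nothing. The allocated
    grams sum to the target by construction.
    """
    if grams_per_day < 0:
        raise ValueError(f"negative gram target: {grams_per_day}")
    if shares.empty:
        return pd.Series(dtype=float)
    return pd.Series(
        shares["share"].to_numpy() * grams_per_day,
        index=pd.Index(shares["item"], name="item"),
        name="grams_consume",
    )


def apply_fti(grams_consume: float, factor: float, item: str = "?") -> float:
    """Convert consumed grams to purchased grams via the adjustment factor.

    ``purchased = consumed / factor``: a factor below 1 (preparation loss,
    e.g. peel) raises the purchase quantity; above 1 (cooking gain, e.g.
    rice absorbing water) lowers it.
    """
    if factor <= 0:
        raise ValueError(f"adjustment factor must be > 0 for item {item!r}, got {factor}")
    return grams_consume / factor


def build_basket(
    targets: pd.DataFrame,
    shares: pd.DataFrame,
    fti_table: pd.DataFrame,
) -> pd.DataFrame:
    """Assemble the full basket table (one row per retained item).

    Parameters
    ----------
    targets
        ``group, subgroup, grams_per_day``.
    shares
        ``subgroup, item, share`` from :func:`compute_group_shares`.
    fti_table
        ``item, factor[, subgroup, source]``. Keyed by (subgroup, item) when
        a ``subgroup`` column is present — the same item name may appear in
        two subgroups with different factors — otherwise by item. A missing
        entry defaults to factor 1 with a warning.
    """
    dup = shares.duplicated(subset=["subgroup", "item"])
    if dup.any():
        dupes = shares.loc[dup, ["subgroup", "item"]].to_records(index=False).tolist()
        raise ValueError(f"duplicate item(s) within a subgroup: {dupes}")
    if targets.duplicated(subset=["group", "subgroup"]).any():
        raise ValueError("duplicate (group, subgroup) in targets")

    fti_keys = ["subgroup", "item"] if "subgroup" in fti_table.columns else ["item"]
    fti = fti_table.drop_duplicates(subset=fti_keys).set_index(fti_keys)["factor"]

    rows = []
    for _, tgt in targets.iterrows():
        sub_shares = shares[shares["subgroup"] == tgt["subgroup"]]
        grams = allocate_group_target(float(tgt["grams_per_day"]), sub_shares)
        for (_, srow), g in zip(sub_shares.iterrows(), grams):
            key = (srow["subgroup"], srow["item"]) if len(fti_keys) == 2 else srow["item"]
            try:
                factor = float(fti.loc[key])
            except KeyError:
                logger.warning("no adjustment factor for %r; defaulting to 1", key)
                factor = 1.0
            rows.append({
                "group": tgt["group"],
                "subgroup": tgt["subgroup"],
                "item": srow["item"],
                "share": srow["share"],
                "grams_consume": g,
                "fti": factor,
                "grams_purchase": apply_fti(g, factor, item=srow["item"]),
            })
    return pd.DataFrame(rows, columns=BASKET_COLUMNS)


def subgroup_totals(basket: pd.DataFrame) -> pd.DataFrame:
    """Consumed and purchased gram totals per (group, subgroup)."""
    return (
        basket.groupby(["group", "subgroup"], sort=False)[["grams_consume", "grams_purchase"]]
        .sum()
        .reset_index()
    )


def round_for_report(basket: pd.DataFrame, decimals: int = 2) -> pd.DataFrame:
    """Presentation copy with gram and share columns rounded."""
    out = basket.copy()
    for col in ("share", "grams_consume", "grams_purchase"):
        if col in out:
            out[col] = out[col].round(decimals if col != "share" else 4)
    return out
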