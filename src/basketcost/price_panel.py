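"""Continuous monthly item-price panel from consumer-price-index segments.

A CPI price series is collected in base-year segments, each with its own
item portfolio and level; building a usable panel means standardising item
names, splicing segments into one continuous series per item, screening
implausible prices, collapsing outlet-level observations to monthly mean
and minimum prices, and filling the remaining holes.

Observation tables are long-format DataFrames with columns
``item, year, month, price, segment`` (plus optional ``item_raw`` and
``obs_id``); panels have one row per item-month with ``min_price,
mean_price, n_obs, status`` where status is ``observed`` (raw cell),
``corrected`` (cell recomputed after outlier removal) or ``imputed``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from basketcost.months import Month, month_index, month_range

logger = logging.getLogger(__name__)

PANEL_COLUMNS = ["item", "year", "month", "min_price", "mean_price", "n_obs", "status"]


@dataclass
class SpliceReport:
    """What splicing did: rejected labels and per-item scaling ratios."""

    unmapped: list[str] = field(default_factory=list)
    ratios: dict[tuple[str, str], float] = field(default_factory=dict)  # (segment, item) -> ratio


def _ym(df: pd.DataFrame) -> pd.Series:
    return df["year"] * 12 + (df["month"] - 1)


def standardize_and_splice(
    observations: pd.DataFrame,
    name_map: dict[str, str] | None = None,
) -> tuple[pd.DataFrame, SpliceReport]:
    """Map raw labels to canonical items and link segments into one series.

    Segments are ordered chronologically by first observed month; the latest
    segment is authoritative. Working backwards, each earlier segment is
    rescaled, per item, by the ratio of the two segments' mean prices in
    their overlap months (ratio splicing); items lacking an overlap use the
    median ratio of the items that have one (1.0 if no item overlaps). In an
    overlap month the earlier segment's observations are discarded.

    Returns the unified observations and a :class:`SpliceReport`; raw labels
    absent from ``name_map`` are listed there and their rows dropped, never
    silently. Rows already flagged ``outlier=True`` (screen first, splice
    second) are rescaled like the rest but never enter the overlap means.
    """
    obs = observations.copy()
    report = SpliceReport()
    if name_map is not None:
        raw = obs["item_raw"] if "item_raw" in obs.columns else obs["item"]
        mapped = raw.map(name_map)
        bad = mapped.isna()
        if bad.any():
            report.unmapped = sorted(raw[bad].unique())
            logger.warning("dropping %d observations with unmapped labels: %s",
                           int(bad.sum()), report.unmapped)
            obs, mapped = obs[~bad], mapped[~bad]
        obs = obs.assign(item=mapped.to_numpy())
    if obs.empty:
        return obs.reset_index(drop=True), report
    if (obs["price"] <= 0).any():
        raise ValueError("non-positive prices in observations")

    seg_order = obs.groupby("segment")["year"].apply(
        lambda s: _ym(obs.loc[s.index]).min()
    ).sort_values().index.tolist()

    def _clean(df: pd.DataFrame) -> pd.Series:
        return ~df["outlier"] if "outlier" in df.columns else pd.Series(True, index=df.index)

    result = obs[obs["segment"] == seg_order[-1]].copy()
    for seg in reversed(seg_order[:-1]):
        earlier = obs[obs["segment"] == seg].copy()
        e_ym, r_ym = _ym(earlier), _ym(result)
        overlap = np.intersect1d(e_ym.unique(), r_ym.unique())
        ratios: dict[str, float] = {}
        for item in earlier["item"].unique():
            e_sel = earlier[(earlier["item"] == item) & e_ym.isin(overlap) & _clean(earlier)]
            r_sel = result[(result["item"] == item) & r_ym.isin(overlap) & _clean(result)]
            common = np.intersect1d(_ym(e_sel).unique(), _ym(r_sel).unique())
            if len(common):
                e_mean = e_sel[_ym(e_sel).isin(common)]["price"].mean()
                r_mean = r_sel[_ym(r_sel).isin(common)]["price"].mean()
                ratios[item] = float(r_mean / e_mean)
        default = float(np.median(list(ratios.values()))) if ratios else 1.0
        factor = earlier["item"].map(ratios).fillna(default)
        earlier["price"] = earlier["price"] * factor
        for item, r in ratios.items():
            report.ratios[(seg, item)] = r
        # later segment authoritative in overlap months
        drop = e_ym.isin(overlap) & (
            earlier["item"].isin(result.loc[r_ym.isin(overlap), "item"].unique())
        )
        earlier = earlier[~drop]
        result = pd.concat([earlier, result], ignore_index=True)
    return result.sort_values(["item", "year", "month"]).reset_index(drop=True), report


def screen_outliers(
    observations: pd.DataFrame,
    ranges: pd.DataFrame | None = None,
    *,
    k: float = 5.0,
    window: int = 12,
    rel_floor: float = 0.5,
    fallback: bool = True,
    group_col: str = "item",
) -> pd.DataFrame:
    """Flag prices outside an admissible range; flagged rows get ``outlier=True``.

    Items present in ``ranges`` (``item, low, high``, matched against the
    ``item`` column) use the hard bounds. Items without a range fall back to
    a robust self-range — median +/- k*MAD over a centred rolling window of
    months — unless ``fallback`` is off, in which case having no usable
    range at all is an error. Because this fallback emulates *admissible
    ranges*, which target gross recording errors rather than ordinary
    dispersion, the band is never narrower than ``rel_floor`` times the
    window median. Flagged observations are excluded downstream from
    monthly minima and means.

    Screen *before* splicing: set ``group_col="item_raw"`` so each base-year
    segment's series is screened on its own level, and so gross outliers
    cannot corrupt the overlap-month means that splicing rescales by.
    """
    if (ranges is None or len(ranges) == 0) and not fallback:
        raise ValueError("no admissible ranges provided and fallback disabled")
    obs = observations.copy()
    obs["outlier"] = False

    bounded: set[str] = set()
    if ranges is not None and len(ranges):
        if (ranges["low"] <= 0).any() or (ranges["low"] > ranges["high"]).any():
            raise ValueError("admissible ranges must satisfy 0 < low <= high")
        r = ranges.set_index("item")
        bounded = set(r.index)
        low = obs["item"].map(r["low"])
        high = obs["item"].map(r["high"])
        obs.loc[low.notna() & ((obs["price"] < low) | (obs["price"] > high)), "outlier"] = True

    if fallback:
        half = max(window // 2, 1)
        ym = _ym(obs)
        for item, grp in obs.groupby(group_col, sort=False):
            canonical = grp["item"].iloc[0] if "item" in grp.columns else item
            if canonical in bounded:
                continue
            g_ym = ym.loc[grp.index].to_numpy()
            prices = grp["price"].to_numpy()
            flags = np.zeros(len(grp), dtype=bool)
            for m in np.unique(g_ym):
                in_win = np.abs(g_ym - m) <= half
                med = np.median(prices[in_win])
                mad = np.median(np.abs(prices[in_win] - med))
                band = max(k * mad, rel_floor * med)
                here = g_ym == m
                if band > 0:
                    flags[here] = np.abs(prices[here] - med) > band
            obs.loc[grp.index[flags], "outlier"] = True

    n = int(obs["outlier"].sum())
    if n:
        logger.info("flagged %d of %d observations as outliers", n, len(obs))
    return obs


def monthly_stats(observations: pd.DataFrame) -> pd.DataFrame:
    """Collapse outlet-level observations to a per-item-month panel.

    Retained (non-flagged) prices give the monthly mean and minimum; cells
    where at least one observation was removed are marked ``corrected``.
    Item-months whose every observation was flagged yield no row (left for
    imputation).
    """
    obs = observations.copy()
    if "outlier" not in obs.columns:
        obs["outlier"] = False
    had_flag = obs.groupby(["item", "year", "month"])["outlier"].any()
    kept = obs[~obs["outlier"]]
    panel = (
        kept.groupby(["item", "year", "month"])["price"]
        .agg(min_price="min", mean_price="mean", n_obs="size")
        .reset_index()
    )
    flagged = had_flag.reindex(
        pd.MultiIndex.from_frame(panel[["item", "year", "month"]])
    ).to_numpy()
    panel["status"] = np.where(flagged, "corrected", "observed")
    return panel[PANEL_COLUMNS]


def impute_missing(
    panel: pd.DataFrame,
    window: tuple[Month, Month] | None = None,
    items: list[str] | None = None,
    method: str = "temporal",
) -> pd.DataFrame:
    """Fill every missing item-month in the window; observed cells untouched.

    ``temporal`` (default): take the value of the same item's temporally
    nearest observed month; an exact tie uses the mean of the two
    neighbours. ``donor``: fill from the most price-correlated other item
    observed that month, rescaled by the ratio of the two items' mean prices
    over their common months. Filled cells get ``status='imputed'`` and
    ``n_obs=0``. An item with no observed month at all is an error.
    """
    if method not in ("temporal", "donor"):
        raise ValueError(f"unknown imputation method: {method!r}")
    if items is None:
        items = sorted(panel["item"].unique())
    if window is None:
        ym = _ym(panel)
        window = ((int(panel.loc[ym.idxmin(), "year"]), int(panel.loc[ym.idxmin(), "month"])),
                  (int(panel.loc[ym.idxmax(), "year"]), int(panel.loc[ym.idxmax(), "month"])))
    months = month_range(*window)
    month_idx = np.array([month_index(m) for m in months])

    by_item = {it: g.set_index(g["year"] * 12 + g["month"] - 1)
               for it, g in panel.groupby("item", sort=False)}
    empty = [it for it in items if it not in by_item or by_item[it].empty]
    if empty:
        raise ValueError(f"cannot impute items with no observations: {empty}")

    mean_level = {it: g["mean_price"].mean() for it, g in by_item.items()}
    rows = []
    for it in items:
        g = by_item[it]
        obs_idx = g.index.to_numpy()
        for m, mi in zip(months, month_idx):
            if mi in g.index:
                r = g.loc[mi]
                rows.append({"item": it, "year": m[0], "month": m[1],
                             "min_price": r["min_price"], "mean_price": r["mean_price"],
                             "n_obs": int(r["n_obs"]), "status": r["status"]})
                continue
            if method == "temporal":
                dist = np.abs(obs_idx - mi)
                best = dist.min()
                nearest = obs_idx[dist == best]
                minp = float(g.loc[nearest, "min_price"].mean())
                meanp = float(g.loc[nearest, "mean_price"].mean())
            else:
                minp, meanp = _donor_fill(it, mi, by_item, mean_level)
            rows.append({"item": it, "year": m[0], "month": m[1],
                         "min_price": minp, "mean_price": meanp,
                         "n_obs": 0, "status": "imputed"})
    return pd.DataFrame(rows, columns=PANEL_COLUMNS)


def _donor_fill(item, mi, by_item, mean_level):
    """Most-correlated donor item observed at month ``mi``, level-rescaled."""
    g = by_item[item]
    best_corr, best = -np.inf, None
    for other, h in by_item.items():
        if other == item or mi not in h.index:
            continue
        common = g.index.intersection(h.index)
        if len(common) < 3:
            continue
        corr = np.corrcoef(g.loc[common, "mean_price"], h.loc[common, "mean_price"])[0, 1]
        if np.isnan(corr):
            continue
        if corr > best_corr:
            best_corr, best = corr, other
    if best is None:
        raise ValueError(f"no donor available for item {item!r}")
    scale = mean_level[item] / mean_level[best]
    row = by_item[best].loc[mi]
    return float(row["min_price"]) * scale, float(row["mean_price"]) * scale
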