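"""Synthetic inputs with the statistical structure the analysis assumes.

Stands in for the three data sources the real study draws on — a household
budget survey (stratified item-level purchase quantities with a
concentrated, right-skewed share structure), CPI price microdata (monthly
outlet prices with seasonality, trend, base-year level breaks, missing
months and gross outliers), and a daily exchange-rate series — plus a
paired reference/target monthly cost series carrying a configured seasonal
premium. Every generator emits its ground truth (true shares, outlier
labels, missing cells, unbroken price path, premium profile) so each
pipeline stage can be tested closed-loop. All draws are keyed to
``SyntheticConfig.seed`` through independent, stage-tagged streams.

No attempt is made to match any country's actual price levels or inflation
history; magnitudes are merely plausible (CLP-like).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from basketcost import data as _data
from basketcost.months import Month, days_in_month, month_range

# stage tags for independent seed streams
_SURVEY, _PRICES, _FX, _REFCOST = 11, 12, 13, 14

#: typical price level per subgroup, currency per kg (or per litre)
DEFAULT_PRICE_LEVELS = {
    "Rice, Wheat, Corn, and Others": 1500.0,
    "Potatoes and Cassava": 800.0,
    "All Types of Vegetables": 1000.0,
    "All Types of Fruits": 1200.0,
    "Whole Milk or Equivalents": 1000.0,
    "Beef, Lamb, and Pork": 6000.0,
    "Chicken and Other Poultry": 3500.0,
    "Eggs": 3000.0,
    "Fish": 7000.0,
    "Legumes": 2500.0,
    "Nuts and Seeds": 8000.0,
    "Unsaturated Oils": 3000.0,
    "Saturated Oils": 8000.0,
    "All Types of Sugars": 1000.0,
}

#: subgroups priced/generated as fresh produce (stronger seasonality)
FRESH_SUBGROUPS = ("All Types of Vegetables", "All Types of Fruits")


@dataclass(frozen=True)
class PremiumProfile:
    """Seasonal cost premium of the target basket over the reference one.

    premium(month) = mean + amplitude * cos(2*pi*(month - peak_month)/12),
    so the premium peaks at ``peak_month`` and bottoms out half a year away.
    """

    mean: float = 0.139
    amplitude: float = 0.07
    peak_month: int = 10

    def at(self, month: int) -> float:
        return self.mean + self.amplitude * np.cos(2 * np.pi * (month - self.peak_month) / 12)


@dataclass
class SyntheticConfig:
    seed: int = 0
    # survey
    n_households: int = 2000
    strata: tuple[str, ...] = ("Q1", "Q2", "Q3", "Q4", "Q5")
    share_concentration: float = 50.0  # Dirichlet mass for stratum-level true shares
    household_concentration: float = 25.0  # Dirichlet mass for within-household splits
    geometric_decay: float = 0.8  # base weight of the i-th most popular item ~ decay**i
    household_sd: float = 0.4  # lognormal sd of household subgroup totals
    marginal_scales: dict[str, float] = field(
        default_factory=lambda: {"Nuts and Seeds": 3.0}
    )  # g/household/month overrides for marginally consumed subgroups
    # price panel
    window_start: Month = (2013, 4)
    window_end: Month = (2023, 12)
    n_outlets: int = 4
    seasonal_amplitude: float = 0.10  # fresh produce
    seasonal_amplitude_other: float = 0.03
    trend: float = 0.04  # fractional price growth per year
    noise_sd: float = 0.03  # lognormal sigma per observation
    missing_rate: float = 0.05
    outlier_rate: float = 0.02
    outlier_multiplier: float = 10.0
    segment_breaks: tuple[Month, ...] = ((2018, 4),)
    segment_shift_sd: float = 0.15  # lognormal sigma of pre-break level shifts
    # fx
    fx_level: float = 800.0
    fx_volatility: float = 0.004  # daily log-return sd
    # reference costs
    ref_level: float = 40000.0  # currency per month
    ref_trend: float = 0.05
    ref_amplitude: float = 0.02
    ref_peak_month: int = 3
    ref_noise_sd: float = 0.01
    premium_noise_sd: float = 0.01

    def __post_init__(self):
        for name in ("missing_rate", "outlier_rate"):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise ValueError(f"{name} must be in [0, 1), got {v}")
        if self.share_concentration <= 0 or self.household_concentration <= 0:
            raise ValueError("concentration parameters must be positive")


def default_catalogue() -> pd.DataFrame:
    """Item catalogue (`group, subgroup, item`) from the packaged basket."""
    return _data.load_reference_basket()[["group", "subgroup", "item"]].copy()


def gen_consumption_survey(
    cfg: SyntheticConfig,
    catalogue: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Household-level purchase records plus the generator's true shares.

    For each stratum and subgroup a true share vector is drawn from a
    Dirichlet centred on geometrically decaying weights — a few dominant
    items and a long tail. Households draw a lognormal subgroup total and
    split it across items by a Dirichlet around the true shares, so
    aggregated stratum shares converge to the truth as households grow.
    Subgroups listed in ``marginal_scales`` get tiny totals, emulating
    marginally consumed groups that downstream share computation excludes.

    Returns ``(records, truth)``: records have columns ``household,
    stratum, group, subgroup, item, quantity`` (grams per month); truth has
    ``stratum, subgroup, item, share``.
    """
    if catalogue is None:
        catalogue = default_catalogue()
    if catalogue.empty:
        raise ValueError("empty item catalogue")
    rng = np.random.default_rng([cfg.seed, _SURVEY])
    targets = _data.load_targets().set_index("subgroup")["grams_per_day"]

    records, truths = [], []
    for stratum in cfg.strata:
        for (group, subgroup), grp in catalogue.groupby(["group", "subgroup"], sort=False):
            items = grp["item"].tolist()
            k = len(items)
            w = cfg.geometric_decay ** np.arange(k)
            w /= w.sum()
            true_shares = rng.dirichlet(cfg.share_concentration * w) if k > 1 else np.ones(1)
            truths.append(pd.DataFrame({
                "stratum": stratum, "subgroup": subgroup,
                "item": items, "share": true_shares,
            }))
            scale = cfg.marginal_scales.get(
                subgroup, float(targets.get(subgroup, 50.0)) * 30.0
            )
            scale = max(scale, 1e-9)
            totals = scale * rng.lognormal(
                -cfg.household_sd ** 2 / 2, cfg.household_sd, cfg.n_households
            )
            splits = (
                rng.dirichlet(cfg.household_concentration * np.maximum(true_shares, 1e-6),
                              size=cfg.n_households)
                if k > 1 else np.ones((cfg.n_households, 1))
            )
            qty = splits * totals[:, None]
            records.append(pd.DataFrame({
                "household": np.repeat(np.arange(cfg.n_households), k),
                "stratum": stratum,
                "group": group,
                "subgroup": subgroup,
                "item": np.tile(items, cfg.n_households),
                "quantity": qty.ravel(),
            }))
    return (
        pd.concat(records, ignore_index=True),
        pd.concat(truths, ignore_index=True),
    )


def _true_price_series(cfg: SyntheticConfig, catalogue: pd.DataFrame, rng) -> pd.DataFrame:
    """Noise- and break-free monthly price path per item (final-segment scale)."""
    months = month_range(cfg.window_start, cfg.window_end)
    uniq = catalogue.drop_duplicates("item")
    rows = []
    for _, r in uniq.iterrows():
        level = DEFAULT_PRICE_LEVELS.get(r["subgroup"], 2000.0) * rng.lognormal(0, 0.3)
        amp = (cfg.seasonal_amplitude if r["subgroup"] in FRESH_SUBGROUPS
               else cfg.seasonal_amplitude_other)
        peak = int(rng.integers(1, 13))
        for i, (y, m) in enumerate(months):
            t = i / 12.0
            price = level * (1 + cfg.trend * t) * (
                1 + amp * np.sin(2 * np.pi * (m - peak) / 12)
            )
            rows.append({"item": r["item"], "year": y, "month": m, "price_true": price})
    return pd.DataFrame(rows)


def _segments(cfg: SyntheticConfig) -> list[tuple[str, Month, Month]]:
    """Base-year segments covering the window, overlapping at each break month."""
    bounds = [cfg.window_start, *cfg.segment_breaks, cfg.window_end]
    segs = []
    for i in range(len(bounds) - 2):
        segs.append((f"base{bounds[i][0]}", bounds[i], bounds[i + 1]))  # incl. break month
    segs.append((f"base{bounds[-2][0]}", bounds[-2], bounds[-1]))
    return segs


def gen_price_panel(
    cfg: SyntheticConfig,
    catalogue: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Outlet-level price observations across base-year segments, with truth.

    Monthly true price = level x (1 + trend*t) x seasonal factor; each
    observation multiplies in lognormal noise, each pre-break segment a
    known level shift, raw labels are segment-scoped (exercising name
    standardisation), whole item-months go missing at ``missing_rate``
    (never a break month, so splicing overlap survives) and observations
    are inflated ``outlier_multiplier``-fold at ``outlier_rate``.

    Returns ``(observations, truth)``; observations carry a ``true_outlier``
    label column, truth holds the clean series, segment shifts, missing
    cells and the name map.
    """
    if catalogue is None:
        catalogue = default_catalogue()
    months = month_range(cfg.window_start, cfg.window_end)
    if len(months) < 2:
        raise ValueError("price window must span at least 2 months")
    rng = np.random.default_rng([cfg.seed, _PRICES])
    clean = _true_price_series(cfg, catalogue, rng)
    segs = _segments(cfg)
    shifts = {name: (1.0 if i == len(segs) - 1 else rng.lognormal(0, cfg.segment_shift_sd))
              for i, (name, _, _) in enumerate(segs)}
    break_months = set(cfg.segment_breaks)

    idx = {(r["item"], r["year"], r["month"]): r["price_true"]
           for _, r in clean.iterrows()}
    items = clean["item"].unique().tolist()
    missing_cells = []
    rows = []
    for seg_name, seg_start, seg_end in segs:
        seg_months = month_range(seg_start, seg_end)
        for item in items:
            raw = f"{item} [{seg_name}]"
            for (y, m) in seg_months:
                if (y, m) not in break_months and rng.random() < cfg.missing_rate:
                    missing_cells.append({"segment": seg_name, "item": item,
                                          "year": y, "month": m})
                    continue
                base = idx[(item, y, m)] * shifts[seg_name]
                noise = rng.lognormal(-cfg.noise_sd ** 2 / 2, cfg.noise_sd, cfg.n_outlets)
                flags = rng.random(cfg.n_outlets) < cfg.outlier_rate
                prices = base * noise * np.where(flags, cfg.outlier_multiplier, 1.0)
                for j in range(cfg.n_outlets):
                    rows.append({"item_raw": raw, "item": item, "year": y, "month": m,
                                 "price": prices[j], "segment": seg_name,
                                 "obs_id": j, "true_outlier": bool(flags[j])})
    obs = pd.DataFrame(rows)
    name_map = {f"{it} [{s}]": it for it in items for s, _, _ in segs}
    truth = {
        "clean_series": clean,
        "segment_shifts": shifts,
        "missing_cells": pd.DataFrame(missing_cells),
        "name_map": name_map,
    }
    return obs, truth


def gen_fx_series(cfg: SyntheticConfig) -> pd.DataFrame:
    """Daily exchange rates (currency per USD) as a geometric random walk."""
    rng = np.random.default_rng([cfg.seed, _FX])
    (y0, m0), (y1, m1) = cfg.window_start, cfg.window_end
    start = pd.Timestamp(y0, m0, 1)
    end = pd.Timestamp(y1, m1, days_in_month((y1, m1)))
    dates = pd.date_range(start, end, freq="D")
    steps = rng.normal(-cfg.fx_volatility ** 2 / 2, cfg.fx_volatility, len(dates))
    rates = cfg.fx_level * np.exp(np.cumsum(steps))
    return pd.DataFrame({"date": dates.strftime("%Y-%m-%d"), "rate": rates})


def gen_reference_costs(
    cfg: SyntheticConfig,
    premium: PremiumProfile | None = None,
    window: tuple[Month, Month] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Paired monthly cost series: a reference basket and a pricier target.

    The reference follows trend + mild seasonality + noise; the target is
    the reference times ``1 + premium(month)`` times independent noise, so
    the expected monthly gap equals the premium profile exactly.

    Returns ``(reference, target, truth)`` where reference/target have
    ``year, month, cost_local`` and truth has the month-by-month premium.
    """
    premium = premium or PremiumProfile()
    window = window or (cfg.window_start, cfg.window_end)
    rng = np.random.default_rng([cfg.seed, _REFCOST])
    rows_r, rows_t, rows_p = [], [], []
    for i, (y, m) in enumerate(month_range(*window)):
        t = i / 12.0
        base = cfg.ref_level * (1 + cfg.ref_trend * t) * (
            1 + cfg.ref_amplitude * np.sin(2 * np.pi * (m - cfg.ref_peak_month) / 12)
        )
        ref = base * rng.lognormal(-cfg.ref_noise_sd ** 2 / 2, cfg.ref_noise_sd)
        p = premium.at(m)
        tgt = ref * (1 + p) * rng.lognormal(
            -cfg.premium_noise_sd ** 2 / 2, cfg.premium_noise_sd
        )
        rows_r.append({"year": y, "month": m, "cost_local": ref})
        rows_t.append({"year": y, "month": m, "cost_local": tgt})
        rows_p.append({"year": y, "month": m, "premium": p})
    return pd.DataFrame(rows_r), pd.DataFrame(rows_t), pd.DataFrame(rows_p)
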