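"""Monthly basket costing, basket-vs-basket gaps, USD conversion, poverty lines.

The basket is costed at the monthly minimum observed price by default —
the convention used for the official reference basket that anchors the
poverty line — with monthly cost = sum over items of daily purchased
kilograms x price per kg x days in the month. Poverty thresholds follow the
Orshansky approach: total line = coefficient x food-basket cost, extreme
line = a fraction (two-thirds) of the total line.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from basketcost.months import Month, days_in_month, month_range

COST_COLUMNS = ["year", "month", "cost_local"]


@dataclass(frozen=True)
class GapSummary:
    """Percentage cost gap of series A over series B, month by month.

    ``max_month``/``min_month`` are the single widest/narrowest months on
    record; ``peak_season_month``/``trough_season_month`` locate the
    seasonal extremes as the calendar months with the highest/lowest
    average gap across years, which is robust to single-month noise.
    ``peak_phase_month`` estimates the seasonal peak by first-harmonic
    (annual cosine) regression on the monthly gaps — the right estimator
    when the seasonal pattern is smooth, since it pools every month of
    every year instead of comparing twelve noisy averages.
    """

    monthly: pd.DataFrame  # year, month, gap_percent
    mean_gap: float
    max_month: Month
    max_gap: float
    min_month: Month
    min_gap: float
    seasonal: pd.Series  # mean gap_percent by calendar month (1..12)
    peak_season_month: int
    trough_season_month: int
    peak_phase_month: int


@dataclass(frozen=True)
class PovertyThresholds:
    basket_cost: float
    orshansky: float
    extreme_fraction: float
    poverty_line: float
    extreme_line: float


def basket_cost_monthly(
    basket: pd.DataFrame,
    panel: pd.DataFrame,
    *,
    basis: str = "min",
    days_policy: str = "calendar",
    window: tuple[Month, Month] | None = None,
) -> pd.DataFrame:
    """Monthly basket cost in local currency.

    ``basket`` needs ``item, grams_purchase`` (daily purchased grams);
    ``panel`` is a complete item-month grid with prices per kilogram.
    ``basis`` selects ``min_price`` (default, the reference-basket
    convention) or ``mean_price``. Every basket item must be priced in
    every month of the window.
    """
    if basis not in ("min", "mean"):
        raise ValueError(f"basis must be 'min' or 'mean', got {basis!r}")
    price_col = f"{basis}_price"
    months = month_range(*window) if window else sorted(
        {(int(y), int(m)) for y, m in zip(panel["year"], panel["month"])}
    )
    items = basket["item"].tolist()
    if len(set(items)) != len(items):
        # same name in two subgroups: price is per item name, grams add up
        basket = basket.groupby("item", as_index=False)["grams_purchase"].sum()
        items = basket["item"].tolist()

    grid = panel.set_index(["item", "year", "month"])[price_col]
    missing = [(it, y, m) for y, m in months for it in items if (it, y, m) not in grid.index]
    if missing:
        raise KeyError(f"missing item-month prices (first few): {missing[:5]} "
                       f"({len(missing)} total)")
    daily_kg = basket["grams_purchase"].to_numpy() / 1000.0
    rows = []
    for y, m in months:
        prices = grid.loc[[(it, y, m) for it in items]].to_numpy()
        cost = float((daily_kg * prices).sum()) * days_in_month((y, m), days_policy)
        rows.append({"year": y, "month": m, "cost_local": cost})
    return pd.DataFrame(rows, columns=COST_COLUMNS)


def monthly_fx(fx_daily: pd.DataFrame) -> pd.DataFrame:
    """Collapse a daily exchange-rate series to monthly arithmetic means.

    ``fx_daily`` has ``date`` (parseable) and ``rate`` (local currency per
    USD) columns.
    """
    if (fx_daily["rate"] <= 0).any():
        raise ValueError("exchange rates must be positive")
    d = pd.to_datetime(fx_daily["date"])
    out = (
        fx_daily.assign(year=d.dt.year, month=d.dt.month)
        .groupby(["year", "month"], as_index=False)["rate"]
        .mean()
    )
    return out


def to_usd(
    series: pd.DataFrame,
    fx_monthly: pd.DataFrame,
    days_policy: str = "calendar",
) -> pd.DataFrame:
    """Add USD columns: monthly cost / monthly mean rate, and per-day USD."""
    merged = series.merge(fx_monthly, on=["year", "month"], how="left", validate="1:1")
    if merged["rate"].isna().any():
        miss = merged.loc[merged["rate"].isna(), ["year", "month"]].to_records(index=False)
        raise ValueError(f"missing exchange rate for months: {list(miss)}")
    out = series.copy()
    out["cost_usd_month"] = merged["cost_local"] / merged["rate"]
    days = [days_in_month((y, m), days_policy) for y, m in zip(out["year"], out["month"])]
    out["cost_usd_day"] = out["cost_usd_month"] / days
    return out


def compare_costs(
    series_a: pd.DataFrame,
    series_b: pd.DataFrame,
    value_col: str = "cost_local",
) -> GapSummary:
    """Monthly percentage gap of A over B plus mean and seasonal extremes."""
    a = series_a.sort_values(["year", "month"]).reset_index(drop=True)
    b = series_b.sort_values(["year", "month"]).reset_index(drop=True)
    if not a[["year", "month"]].equals(b[["year", "month"]]):
        raise ValueError("cost series cover different months")
    gap = 100.0 * (a[value_col] - b[value_col]) / b[value_col]
    monthly = pd.DataFrame({"year": a["year"], "month": a["month"], "gap_percent": gap})
    imax, imin = int(gap.idxmax()), int(gap.idxmin())
    seasonal = monthly.groupby("month")["gap_percent"].mean()
    return GapSummary(
        peak_phase_month=_harmonic_peak_month(a["month"].to_numpy(), gap.to_numpy()),
        monthly=monthly,
        mean_gap=float(gap.mean()),
        max_month=(int(a.loc[imax, "year"]), int(a.loc[imax, "month"])),
        max_gap=float(gap[imax]),
        min_month=(int(a.loc[imin, "year"]), int(a.loc[imin, "month"])),
        min_gap=float(gap[imin]),
        seasonal=seasonal,
        peak_season_month=int(seasonal.idxmax()),
        trough_season_month=int(seasonal.idxmin()),
    )


def _harmonic_peak_month(months: np.ndarray, gaps: np.ndarray) -> int:
    """Calendar month maximising the fitted annual harmonic of the gap series."""
    omega = 2 * np.pi / 12.0
    design = np.column_stack(
        [np.ones_like(gaps), np.cos(omega * months), np.sin(omega * months)]
    )
    _, b, c = np.linalg.lstsq(design, gaps, rcond=None)[0]
    phase = np.arctan2(c, b)  # gap ~ a + r*cos(omega*m - phase), peak at m = phase/omega
    m = int(np.round(phase / omega)) % 12
    return 12 if m == 0 else m


def poverty_thresholds(
    basket_cost: float,
    orshansky: float = 2.68,
    extreme_fraction: float = 2.0 / 3.0,
) -> PovertyThresholds:
    """Poverty and extreme-poverty lines from a monthly food-basket cost."""
    if basket_cost <= 0 or orshansky <= 0 or not 0 < extreme_fraction <= 1:
        raise ValueError("basket cost and multipliers must be positive "
                         "(extreme fraction in (0, 1])")
    line = orshansky * basket_cost
    return PovertyThresholds(
        basket_cost=basket_cost,
        orshansky=orshansky,
        extreme_fraction=extreme_fraction,
        poverty_line=line,
        extreme_line=extreme_fraction * line,
    )


def summarize_period(
    series: pd.DataFrame,
    sub_windows: dict[str, tuple[Month, Month]],
    value_col: str = "cost_usd_day",
) -> dict[str, float]:
    """Arithmetic mean of a cost column over each named month window."""
    ym = series["year"] * 12 + (series["month"] - 1)
    out = {}
    for name, (start, end) in sub_windows.items():
        months = month_range(start, end)
        lo = start[0] * 12 + start[1] - 1
        hi = end[0] * 12 + end[1] - 1
        sel = series[(ym >= lo) & (ym <= hi)]
        if sel.empty:
            raise ValueError(f"window {name!r} ({start}..{end}) has no data")
        if len(sel) != len(months):
            raise ValueError(f"window {name!r} incompletely covered: "
                             f"{len(sel)} of {len(months)} months present")
        out[name] = float(sel[value_col].mean())
    return out
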