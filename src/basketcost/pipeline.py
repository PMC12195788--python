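"""End-to-end orchestration: inputs -> basket -> nutrients -> panel -> costs.

Each stage consumes and produces delimited text files in the run directory,
so any stage can be rerun from disk and the whole run is reproducible from
its provenance record (config hash + seed). When no survey/price/fx inputs
are supplied the synthetic generator provides them, which makes a
fixture-backed default run possible with no external data.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from basketcost import __version__, basket_builder, cost_engine, data, nutrient_profile
from basketcost import price_panel as pp
from basketcost import synthetic_data as synth
from basketcost.months import Month, month_range, parse_month

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the offending input."""


@dataclass
class RunConfig:
    out_dir: str = "run_output"
    seed: int = 0
    # inputs; None means "use the packaged fixture or the synthetic generator"
    survey: str | None = None
    targets: str | None = None
    fti: str | None = None
    nutrients: str | None = None
    price_obs: str | None = None
    ranges: str | None = None
    fx: str | None = None
    reference_costs: str | None = None
    # analysis choices (defaults follow the reference-basket conventions)
    window_start: Month = (2014, 4)
    window_end: Month = (2023, 12)
    stratum: str = "Q1"
    basis: str = "min"
    days_policy: str = "calendar"
    atwater: tuple[float, float, float] = nutrient_profile.ATWATER_DEFAULT
    nutrient_basis: str = "consumed"
    orshansky: float = 2.68
    extreme_fraction: float = 2.0 / 3.0
    min_share: float = 0.0
    coverage: float = 1.0
    marginal_fraction: float = 0.001
    outlier_k: float = 5.0
    imputation: str = "temporal"
    synthetic: synth.SyntheticConfig = field(default_factory=synth.SyntheticConfig)

    def __post_init__(self):
        if tuple(self.window_start) > tuple(self.window_end):
            raise ValueError("window start after window end")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        syn = raw.pop("synthetic", None)
        for key in ("window_start", "window_end"):
            if key in raw and isinstance(raw[key], str):
                raw[key] = parse_month(raw[key])
        cfg = cls(**raw)
        if syn:
            for key in ("window_start", "window_end"):
                if key in syn and isinstance(syn[key], str):
                    syn[key] = parse_month(syn[key])
            cfg.synthetic = synth.SyntheticConfig(**syn)
        return cfg

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raise with stage context
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return inner
    return wrap


@_stage("simulate")
def _simulate_inputs(cfg: RunConfig, out: Path) -> dict[str, Path]:
    scfg = dataclasses.replace(cfg.synthetic, seed=cfg.seed)
    truth_dir = out / "truth"
    truth_dir.mkdir(parents=True, exist_ok=True)
    paths = {}

    records, true_shares = synth.gen_consumption_survey(scfg)
    paths["survey"] = out / "survey.csv"
    records.to_csv(paths["survey"], index=False)
    true_shares.to_csv(truth_dir / "true_shares.csv", index=False)

    obs, truth = synth.gen_price_panel(scfg)
    paths["price_obs"] = out / "price_observations.csv"
    obs.to_csv(paths["price_obs"], index=False)
    truth["clean_series"].to_csv(truth_dir / "clean_prices.csv", index=False)
    if len(truth["missing_cells"]):
        truth["missing_cells"].to_csv(truth_dir / "missing_cells.csv", index=False)
    (truth_dir / "segment_shifts.json").write_text(json.dumps(truth["segment_shifts"]))
    (out / "name_map.json").write_text(json.dumps(truth["name_map"]))

    fx = synth.gen_fx_series(scfg)
    paths["fx"] = out / "fx_daily.csv"
    fx.to_csv(paths["fx"], index=False)

    ref, _tgt, premium = synth.gen_reference_costs(
        scfg, window=(cfg.window_start, cfg.window_end)
    )
    paths["reference_costs"] = out / "reference_costs.csv"
    ref.to_csv(paths["reference_costs"], index=False)
    premium.to_csv(truth_dir / "premium_profile.csv", index=False)
    return paths


@_stage("basket")
def _build_basket(cfg: RunConfig, survey_path: Path, out: Path) -> Path:
    records = pd.read_csv(survey_path)
    targets = pd.read_csv(cfg.targets) if cfg.targets else data.load_targets()
    fti = pd.read_csv(cfg.fti) if cfg.fti else data.reference_fti()
    shares = basket_builder.compute_group_shares(
        records, cfg.stratum,
        min_share=cfg.min_share, coverage=cfg.coverage,
        marginal_fraction=cfg.marginal_fraction,
    )
    basket = basket_builder.build_basket(targets, shares, fti)
    path = out / "basket.csv"
    basket.to_csv(path, index=False)
    return path


@_stage("nutrients")
def _profile_nutrients(cfg: RunConfig, basket_path: Path, out: Path) -> Path:
    basket = pd.read_csv(basket_path)
    nutrients = pd.read_csv(cfg.nutrients) if cfg.nutrients else data.load_synthetic_nutrients()
    contrib = nutrient_profile.attach_profiles(basket, nutrients, basis=cfg.nutrient_basis)
    totals = nutrient_profile.aggregate_totals(contrib)
    path = out / "nutrient_totals.csv"
    totals.as_frame().to_csv(path, index=False)
    pct = nutrient_profile.macro_percentages(totals, cfg.atwater)
    (out / "macro_percentages.json").write_text(json.dumps(pct, indent=2))
    return path


@_stage("price_panel")
def _build_panel(cfg: RunConfig, obs_path: Path, out: Path) -> Path:
    obs = pd.read_csv(obs_path)
    name_map = None
    nm_path = out / "name_map.json"
    if "item_raw" in obs.columns and nm_path.exists():
        name_map = json.loads(nm_path.read_text())
    ranges = pd.read_csv(cfg.ranges) if cfg.ranges else None
    # screen each base-year segment's raw series first, then splice, so gross
    # outliers never enter the overlap means used for rescaling
    group_col = "item_raw" if "item_raw" in obs.columns else "item"
    screened = pp.screen_outliers(obs, ranges, k=cfg.outlier_k, group_col=group_col)
    unified, report = pp.standardize_and_splice(screened, name_map)
    if report.unmapped:
        (out / "unmapped_labels.json").write_text(json.dumps(report.unmapped))
    panel = pp.monthly_stats(unified)
    panel = pp.impute_missing(
        panel, window=(cfg.window_start, cfg.window_end), method=cfg.imputation
    )
    path = out / "price_panel.csv"
    panel.to_csv(path, index=False)
    return path


@_stage("costs")
def _cost_and_compare(cfg: RunConfig, basket_path: Path, panel_path: Path,
                      fx_path: Path, ref_path: Path | None, out: Path) -> dict:
    basket = pd.read_csv(basket_path)
    panel = pd.read_csv(panel_path)
    window = (cfg.window_start, cfg.window_end)
    series = cost_engine.basket_cost_monthly(
        basket, panel, basis=cfg.basis, days_policy=cfg.days_policy, window=window
    )
    fx_m = cost_engine.monthly_fx(pd.read_csv(fx_path))
    series = cost_engine.to_usd(series, fx_m, days_policy=cfg.days_policy)
    series.to_csv(out / "basket_costs.csv", index=False)

    summary: dict = {
        "window": [f"{window[0][0]}-{window[0][1]:02d}", f"{window[1][0]}-{window[1][1]:02d}"],
        "n_months": len(month_range(*window)),
        "mean_usd_per_day": float(series["cost_usd_day"].mean()),
    }
    last = series.iloc[-1]
    thresholds = cost_engine.poverty_thresholds(
        float(last["cost_local"]), cfg.orshansky, cfg.extreme_fraction
    )
    summary["poverty_line_last_month"] = thresholds.poverty_line
    summary["extreme_poverty_line_last_month"] = thresholds.extreme_line

    if ref_path is not None:
        ref = pd.read_csv(ref_path)
        gaps = cost_engine.compare_costs(series[cost_engine.COST_COLUMNS], ref)
        gaps.monthly.to_csv(out / "monthly_gaps.csv", index=False)
        summary.update({
            "mean_gap_percent": gaps.mean_gap,
            "max_gap_percent": gaps.max_gap, "max_gap_month": list(gaps.max_month),
            "min_gap_percent": gaps.min_gap, "min_gap_month": list(gaps.min_month),
        })
    (out / "cost_summary.json").write_text(json.dumps(summary, indent=2))
    return summary


def _write_report(cfg: RunConfig, out: Path, summary: dict) -> None:
    basket = pd.read_csv(out / "basket.csv")
    totals = basket_builder.subgroup_totals(basket).round(2)
    nut = pd.read_csv(out / "nutrient_totals.csv").round(2)
    pct = json.loads((out / "macro_percentages.json").read_text())
    lines = [
        "# Basket cost run report",
        "",
        f"- config hash: `{cfg.config_hash()}`  seed: {cfg.seed}  version: {__version__}",
        f"- window: {summary['window'][0]} .. {summary['window'][1]} "
        f"({summary['n_months']} months), stratum {cfg.stratum}, {cfg.basis}-price basis",
        "",
        "## Basket grams by subgroup (consumed / purchased, g/day)",
        "",
        totals.to_markdown(index=False),
        "",
        "## Daily energy and macronutrients by subgroup",
        "",
        nut.to_markdown(index=False),
        "",
        f"Macronutrient energy shares: protein {pct['protein']:.2f}%, "
        f"carbohydrate {pct['carbohydrate']:.2f}%, lipid {pct['lipid']:.2f}%",
        "",
        "## Costs",
        "",
        f"- mean cost: USD {summary['mean_usd_per_day']:.2f} per day",
        f"- poverty line (last month): {summary['poverty_line_last_month']:,.2f}; "
        f"extreme: {summary['extreme_poverty_line_last_month']:,.2f}",
    ]
    if "mean_gap_percent" in summary:
        mx, mn = summary["max_gap_month"], summary["min_gap_month"]
        lines += [
            f"- mean gap vs reference: {summary['mean_gap_percent']:.1f}%",
            f"- widest gap: {summary['max_gap_percent']:.1f}% in {mx[0]}-{mx[1]:02d}",
            f"- narrowest gap: {summary['min_gap_percent']:.1f}% in {mn[0]}-{mn[1]:02d}",
        ]
    (out / "report.md").write_text("\n".join(lines) + "\n")


def run_pipeline(cfg: RunConfig) -> dict:
    """Run every stage, writing all artifacts under ``cfg.out_dir``.

    Returns the cost summary dict. Deterministic for a fixed config: the
    provenance record (`provenance.json`) carries the config hash and seed.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    need_synth = cfg.survey is None or cfg.price_obs is None or cfg.fx is None
    sim = _simulate_inputs(cfg, out) if need_synth else {}
    survey = Path(cfg.survey) if cfg.survey else sim["survey"]
    obs = Path(cfg.price_obs) if cfg.price_obs else sim["price_obs"]
    fx = Path(cfg.fx) if cfg.fx else sim["fx"]
    ref = (Path(cfg.reference_costs) if cfg.reference_costs
           else sim.get("reference_costs"))

    basket_path = _build_basket(cfg, survey, out)
    _profile_nutrients(cfg, basket_path, out)
    panel_path = _build_panel(cfg, obs, out)
    summary = _cost_and_compare(cfg, basket_path, panel_path, fx, ref, out)
    _write_report(cfg, out, summary)

    provenance = {
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "version": __version__,
        "config": dataclasses.asdict(cfg),
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2, default=str))
    return summary
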