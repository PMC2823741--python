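"""End-to-end pipeline: survey -> index -> weighted shares -> comparison.

Ties the stages together in the order the analysis runs them: screen
variables, fit the first-principal-component scoring model, score
households, aggregate to districts, normalize, weight populations under
both indicators, compute capitation shares, split the budget, and compare
the two schemes.  Every intermediate table is persisted as CSV and a
manifest (config echo, package version, seed) makes a run reproducible
bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import __version__
from .allocation import allocate_by_indicator, compute_shares, round_to_currency
from .comparison import ComparisonSummary, compare_allocations, compare_shares, render_report
from .index import AssetIndex, aggregate_to_districts, normalize_indices, score_households
from .io import (
    DISTRICT_COLUMN,
    derive_implied_stunting,
    load_published_table,
    read_district_table,
    read_household_survey,
    write_district_table,
)
from .simulate import SurveyDesign, default_populations, generate_survey, true_district_table

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration of one end-to-end run.

    ``source`` selects the survey input: ``"fixture"`` (the published
    district table; no microdata, the index columns are taken as printed),
    ``"synthetic"`` (generate a survey from ``design``), or a path to a
    survey CSV (then ``district_path`` must provide populations and
    stunting rates).
    """

    source: str = "fixture"
    design: SurveyDesign | None = None
    district_path: str | None = None
    total_budget: float = 1_000_000.0
    currency_unit: float = 1.0
    alpha: float = 0.01
    seed: int | None = None

    def resolved_design(self) -> SurveyDesign:
        design = self.design or SurveyDesign()
        if self.seed is not None:
            design = dataclasses.replace(design, seed=self.seed)
        elif self.design is None:
            raise ValueError("synthetic source requires a seed")
        return design


def fixture_district_table(recompute_shares: bool = True) -> pd.DataFrame:
    """The published district table with stunting rates and shares derived.

    Stunting rates are implied by inverting the population weighting;
    shares are recomputed at full precision from the weighted-population
    columns (the printed share columns are kept under ``*_printed``).
    """
    table = derive_implied_stunting(load_published_table("table3"))
    if recompute_shares:
        table = table.rename(
            columns={
                "share_asset_pct": "share_asset_pct_printed",
                "share_stunting_pct": "share_stunting_pct_printed",
            }
        )
        table["share_asset_pct"] = compute_shares(
            table["weighted_population_asset"]
        ).to_numpy()
        table["share_stunting_pct"] = compute_shares(
            table["weighted_population_stunting"]
        ).to_numpy()
    return table


def index_district_table(
    survey: pd.DataFrame, base_table: pd.DataFrame, alpha: float = 0.01
) -> tuple[pd.DataFrame, AssetIndex]:
    """Fit the asset index on a survey and attach it to a district table.

    Runs screen -> fit -> score -> aggregate -> normalize and merges the
    normalized index onto ``base_table`` (which carries populations and
    stunting rates), then fills both weighted-population and share columns.
    """
    model = AssetIndex(alpha=alpha).fit(survey)
    scores = score_households(survey, model)
    raw = aggregate_to_districts(scores, survey[DISTRICT_COLUMN])
    idx = normalize_indices(raw)
    table = base_table.merge(
        idx.normalized_index.rename("normalized_asset_index"),
        left_on=DISTRICT_COLUMN,
        right_index=True,
        how="left",
    )
    if table["normalized_asset_index"].isna().any():
        missing = table.loc[
            table["normalized_asset_index"].isna(), DISTRICT_COLUMN
        ].tolist()
        raise ValueError(f"districts with no surveyed households: {missing}")
    table["weighted_population_asset"] = (
        table["population_2008"] * table["normalized_asset_index"]
    )
    table["weighted_population_stunting"] = table["population_2008"] * (
        1.0 + table["stunting_rate"]
    )
    table["share_asset_pct"] = compute_shares(
        table["weighted_population_asset"]
    ).to_numpy()
    table["share_stunting_pct"] = compute_shares(
        table["weighted_population_stunting"]
    ).to_numpy()
    return table, model


def model_frame(model: AssetIndex) -> pd.DataFrame:
    """Scoring model as a table: variable, mean, sd, PC1 loading."""
    return pd.DataFrame(
        {
            "variable": model.retained_variables_,
            "mean": model.means_,
            "std_dev": model.stds_,
            "factor_score": model.loadings_,
        }
    )


def run_pipeline(config: PipelineConfig, output_dir: str | Path) -> dict:
    """Execute the full pipeline and persist all artifacts.

    Returns a dict with the comparison summary, the district table, the two
    allocation results and the paths written.
    """
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict = {}
    model = None

    if config.source == "fixture":
        table = fixture_district_table()
    elif config.source == "synthetic":
        design = config.resolved_design()
        survey, truth = generate_survey(design)
        base = true_district_table(truth, default_populations(design.n_districts))
        table, model = index_district_table(survey, base, alpha=config.alpha)
        survey.to_csv(out / "survey.csv", index=False)
        truth.to_csv(out / "ground_truth.csv", index=False)
    else:
        survey = read_household_survey(config.source)
        if config.district_path is None:
            raise ValueError("file source requires district_path")
        base = read_district_table(config.district_path)
        table, model = index_district_table(survey, base, alpha=config.alpha)

    if model is not None:
        model_frame(model).to_csv(out / "model.csv", index=False)
    write_district_table(table, out / "district_table.csv")

    alloc_asset = round_to_currency(
        allocate_by_indicator(table, "asset", config.total_budget),
        config.currency_unit,
    )
    alloc_stunting = round_to_currency(
        allocate_by_indicator(table, "stunting", config.total_budget),
        config.currency_unit,
    )
    pd.DataFrame(
        {
            DISTRICT_COLUMN: alloc_asset.allocations.index,
            "allocation_asset": alloc_asset.allocations.to_numpy(),
            "allocation_stunting": alloc_stunting.allocations.to_numpy(),
        }
    ).to_csv(out / "allocations.csv", index=False)

    summary = compare_shares(table, alpha=config.alpha)
    alloc_cmp = compare_allocations(alloc_stunting, alloc_asset)
    paths = render_report(summary, out)

    manifest = {
        "package": "needsalloc",
        "version": __version__,
        "seed": config.seed,
        "config": _config_echo(config),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))

    artifacts.update(
        summary=summary,
        allocation_comparison=alloc_cmp,
        table=table,
        model=model,
        alloc_asset=alloc_asset,
        alloc_stunting=alloc_stunting,
        paths=paths,
        output_dir=out,
    )
    logger.info(
        "pipeline complete: %d districts, rho=%.4f, simple higher in %d",
        len(table), summary.rho, summary.n_higher_simple,
    )
    return artifacts


def _config_echo(config: PipelineConfig) -> dict:
    def convert(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: convert(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, (list, tuple)):
            return [convert(v) for v in obj]
        if isinstance(obj, Path):
            return str(obj)
        return obj

    return convert(config)


def reproduce_published_comparison() -> dict:
    """Recompute the published §Results-style quantities from the fixture.

    Returns the recomputed values alongside the published ones so they can
    be printed side by side.
    """
    table = fixture_district_table()
    summary: ComparisonSummary = compare_shares(table)
    from .comparison import population_summaries
    from .io import match_district

    big_mean, rest_mean = population_summaries(
        table,
        ["Blantyre", "Lilongwe", "Mzimba"],
        national_total=13_066_320,
        n_total_districts=28,
    )
    lilongwe = match_district(table, "Lilongwe")
    blantyre = match_district(table, "Blantyre")
    return {
        "lilongwe_share_asset_pct": (float(lilongwe["share_asset_pct"]), 19.43),
        "blantyre_share_stunting_pct": (float(blantyre["share_stunting_pct"]), 7.44),
        "spearman_rho_shares": (summary.rho, 0.97),
        "rho_significant_at_1pct": (summary.significant_at_1pct, True),
        "n_higher_simple": (summary.n_higher_simple, 21),
        "n_higher_composite": (summary.n_higher_composite, 5),
        "mean_pp_higher_simple": (summary.mean_pp_higher_simple, 0.6),
        "mean_pp_higher_composite": (summary.mean_pp_higher_composite, 2.0),
        "blantyre_composite_gain_pp": (summary.named_gains.get("Blantyre"), 5.98),
        "lilongwe_composite_gain_pp": (summary.named_gains.get("Lilongwe"), 4.55),
        "largest3_mean_population": (big_mean, 1_249_988),
        "remainder_mean_population": (rest_mean, 372_654),
    }
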