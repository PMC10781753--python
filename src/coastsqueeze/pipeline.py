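"""End-to-end composition of the squeeze analysis on in-memory layers.

Chains the spec'd stages — transect casting, width measurement,
natural-obstruction exclusion, population sampling, protection/urban
labelling, regional summaries, the socio-economic regression, the
protection rank tests and the sea-level-rise exposure accounting — and
returns every intermediate table.  This is what both the CLI and the
acceptance checks drive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import (
    aggregation_stats,
    obstruction_filter,
    protection_analysis,
    slr_exposure,
    socioeconomic_model,
    squeeze_measurement,
)
from .synthetic_world import SyntheticWorld


@dataclass
class PipelineResult:
    records: pd.DataFrame          # width records with exclusion labels
    densities: pd.DataFrame        # per-transect median population density
    labels: pd.DataFrame           # protection / urban group labels
    summary_global: pd.DataFrame
    summary_continent: pd.DataFrame
    country_table: pd.DataFrame
    fit: socioeconomic_model.RegressionFit | None
    wilcoxon: protection_analysis.RankTestResult | None
    kruskal: protection_analysis.RankTestResult | None
    matches: pd.DataFrame
    exposure: pd.DataFrame


def run_world(world: SyntheticWorld, thresholds_m=(100.0, 300.0)) -> PipelineResult:
    """Run the full analysis against a (synthetic or loaded) world."""
    spec = world.spec
    transects = world.transects
    latitudes = world.assignment["latitude_deg"].to_numpy(float)

    records = squeeze_measurement.measure_all(
        transects, world.infrastructure, latitudes=latitudes
    )
    profiles = {}
    for t, lat in zip(transects, latitudes):
        if lat > obstruction_filter.DEM_LAT_MAX_DEG:
            continue  # no DEM validity there; excluded by latitude
        profiles[t.id] = obstruction_filter.slope_profile(t, world.dem)
    records = obstruction_filter.apply_exclusions(
        records, profiles, world.shoreline, transects
    )

    densities = socioeconomic_model.sample_population_all(transects, world.population)
    protected = protection_analysis.assign_protection_all(transects, world.protected_areas)
    urban = [
        protection_analysis.assign_urban(d) for d in densities["pop_density"].to_numpy()
    ]
    labels = protection_analysis.label_groups(
        protected, urban, densities["transect_id"].to_numpy()
    )

    summary_global = aggregation_stats.summarize(
        records, world.assignment, "global", thresholds_m
    )
    summary_continent = aggregation_stats.summarize(
        records, world.assignment, "continent", thresholds_m
    )

    country_table = socioeconomic_model.build_country_table(
        records, world.assignment, densities, world.gdp
    )
    try:
        fit = socioeconomic_model.fit_country_model(country_table)
    except ValueError:
        fit = None

    kept = records[records["exclusion"] == "none"].merge(labels, on="transect_id")
    widths = squeeze_measurement.effective_width(kept)
    prot_mask = kept["protected"].to_numpy(bool)
    wilcoxon = kruskal = None
    if prot_mask.sum() >= 2 and (~prot_mask).sum() >= 2:
        wilcoxon = protection_analysis.rank_sum_test(
            widths[prot_mask], widths[~prot_mask], method="asymptotic"
        )
        groups = {
            g: widths[kept["group"].to_numpy() == g]
            for g in np.unique(kept["group"])
        }
        if len(groups) >= 2:
            kruskal = protection_analysis.kruskal_wallis_posthoc(groups)

    field = world.retreat_points
    matches = slr_exposure.match_retreat(transects, field)
    exposure = slr_exposure.exposure_fractions(records, matches)
    return PipelineResult(
        records=records,
        densities=densities,
        labels=labels,
        summary_global=summary_global,
        summary_continent=summary_continent,
        country_table=country_table,
        fit=fit,
        wilcoxon=wilcoxon,
        kruskal=kruskal,
        matches=matches,
        exposure=exposure,
    )
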