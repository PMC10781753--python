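"""Socio-economic regression: squeeze vs population density and GDP.

Population density is sampled along each full transect from a coarse
(~1 km) density raster with nearest-cell lookup, reduced to a per-transect
median, then to country medians.  The country-level model is an ordinary
least-squares fit of median infrastructure-free width on the base-10
logarithms of median coastal population density and GDP per capita; only
the explanatory variables are log-transformed (a log-response variant is
available behind a flag for sensitivity checks).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .aggregation_stats import censored_median
from .raster import Raster
from .squeeze_measurement import effective_width
from .transect_engine import Transect

logger = logging.getLogger(__name__)


def sample_population(
    transect: Transect, pop: Raster, step_m: float = 1000.0
) -> tuple[np.ndarray, float]:
    """Nearest-cell densities at transect stations and their median.

    Nodata stations are dropped; with no valid station the median is NaN
    (the transect is then skipped in country aggregation).  The median is
    the standard (interpolated) median, matching the raster's continuous
    density field.
    """
    vals = pop.sample_nearest(transect.stations(step_m))
    valid = vals[~np.isnan(vals)]
    med = float(np.median(valid)) if valid.size else float("nan")
    return vals, med


def sample_population_all(
    transects: list[Transect], pop: Raster, step_m: float = 1000.0
) -> pd.DataFrame:
    """Per-transect median density table (transect_id, pop_density)."""
    rows = [
        {"transect_id": t.id, "pop_density": sample_population(t, pop, step_m)[1]}
        for t in transects
    ]
    return pd.DataFrame(rows, columns=["transect_id", "pop_density"])


def build_country_table(
    records: pd.DataFrame,
    assignment: pd.DataFrame,
    densities: pd.DataFrame,
    gdp: pd.DataFrame,
    category: str = "all",
) -> pd.DataFrame:
    """One regression row per country: median width, median density, GDP.

    Countries whose width median is only a censoring lower bound are
    reported with ``median_is_lower_bound=True``; the regression rejects
    them (no numeric response exists).  ``gdp`` needs columns
    ``country, gdp_per_capita``.
    """
    excl_col = "exclusion" if category == "all" else "exclusion_heavy"
    kept = records[records[excl_col] == "none"]
    merged = kept.merge(assignment, on="transect_id").merge(densities, on="transect_id")
    widths = effective_width(merged, category)
    limit = float(merged["censor_limit_m"].max()) if len(merged) else float("nan")
    rows = []
    for country, grp in merged.groupby("country"):
        w = widths[merged["country"].to_numpy() == country]
        med, bound = censored_median(w, limit)
        dens = grp["pop_density"].dropna()
        rows.append(
            {
                "country": country,
                "median_width_m": med,
                "median_is_lower_bound": bound,
                "median_pop_density": float(np.median(dens)) if len(dens) else float("nan"),
                "n_transects": len(grp),
            }
        )
    table = pd.DataFrame(rows).merge(gdp, on="country", how="left")
    return table


@dataclass
class RegressionFit:
    """OLS fit of country median width on log10 predictors."""

    params: pd.Series  # intercept, b_pop, b_gdp
    bse: pd.Series
    rsquared: float
    n: int
    residuals: np.ndarray
    predictor_corr: float  # Pearson r between the two log10 predictors
    log_base: float = 10.0
    log_response: bool = False
    n_rejected: int = 0

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        from scipy import stats

        t = stats.t.ppf(1 - alpha / 2, self.n - len(self.params))
        return pd.DataFrame(
            {"lower": self.params - t * self.bse, "upper": self.params + t * self.bse}
        )


def fit_country_model(
    table: pd.DataFrame, log_response: bool = False
) -> RegressionFit:
    """OLS of median width on log10(pop density) and log10(GDP per capita).

    Rows with non-positive predictors (log undefined), missing values, or
    a censoring-bound response are rejected with a logged report.  Needs
    at least 4 usable countries and a full-rank design.
    """
    t = table.copy()
    usable = (
        (t["median_pop_density"] > 0)
        & (t["gdp_per_capita"] > 0)
        & np.isfinite(t["median_width_m"])
        & ~t.get("median_is_lower_bound", pd.Series(False, index=t.index)).astype(bool)
    )
    n_rejected = int((~usable).sum())
    if n_rejected:
        logger.info("rejected %d country rows (non-positive predictor or censored median)",
                    n_rejected)
    t = t[usable]
    if len(t) < 4:
        raise ValueError("need at least 4 usable countries for the regression")
    x_pop = np.log10(t["median_pop_density"].to_numpy(float))
    x_gdp = np.log10(t["gdp_per_capita"].to_numpy(float))
    y = t["median_width_m"].to_numpy(float)
    if log_response:
        y = np.log10(y)
    X = sm.add_constant(np.column_stack([x_pop, x_gdp]))
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    res = sm.OLS(y, X).fit()
    names = ["intercept", "b_pop", "b_gdp"]
    return RegressionFit(
        params=pd.Series(res.params, index=names),
        bse=pd.Series(res.bse, index=names),
        rsquared=float(res.rsquared),
        n=len(t),
        residuals=np.asarray(res.resid),
        predictor_corr=float(np.corrcoef(x_pop, x_gdp)[0, 1]),
        log_response=log_response,
        n_rejected=n_rejected,
    )
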