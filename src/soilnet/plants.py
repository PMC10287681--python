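"""Plant community descriptors.

Per-mesocosm metrics computed from the long-format biomass table: Shannon
diversity of the species biomass shares, temporal stability of aboveground
productivity (inverse coefficient of variation), the biomass proportion of
invading species, and the "past" community parameters — the initial impact
of species invasion (a before/after difference) and developmental
trajectories (standardized slopes over years).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DataError, DegenerateSeriesError

__all__ = [
    "StabilityResult",
    "shannon_diversity",
    "temporal_stability",
    "invasion_impact",
    "trajectory_beta",
    "invader_proportion",
    "community_time_series",
    "mesocosm_metrics",
]

#: Default census years for the invasion-impact difference: last year without
#: invasion and first year with invasion.  Diversity reacts over two seasons,
#: so its default post year is one later.
IMPACT_PRE_YEAR = 2011
IMPACT_POST_YEAR = 2012
IMPACT_POST_YEAR_DIVERSITY = 2013
TRAJECTORY_YEARS = (2012, 2019)


@dataclass(frozen=True)
class StabilityResult:
    """Temporal stability of one mesocosm: mean/sd of productivity."""

    mesocosm_id: str
    temporal_stability: float
    mean_productivity: float
    sd_productivity: float
    years: tuple[int, ...]


def shannon_diversity(biomass: Sequence[float]) -> float:
    """Shannon index H = -sum p ln p (nats) over positive biomass shares.

    Zero-biomass species contribute nothing; an all-zero vector is an error.
    """
    b = np.asarray(biomass, dtype=float)
    if b.size == 0 or not np.any(b > 0):
        raise DataError("Shannon diversity needs at least one positive biomass")
    if np.any(b < 0):
        raise DataError("negative biomass")
    p = b[b > 0]
    p = p / p.sum()
    return float(-(p * np.log(p)).sum())


def temporal_stability(
    productivity_by_year: Mapping[int, float],
    *,
    drop_first_year: bool = True,
    mesocosm_id: str = "",
) -> StabilityResult:
    """Inverse coefficient of variation (mean/sd, sample sd) of productivity.

    The first census year is dropped by default: establishing communities
    fluctuate disproportionately.  A constant series has no defined
    stability and raises :class:`DegenerateSeriesError`.
    """
    years = sorted(productivity_by_year)
    if drop_first_year and len(years) > 1:
        years = years[1:]
    values = np.array([productivity_by_year[y] for y in years], dtype=float)
    if len(values) < 3:
        raise DataError(f"need >= 3 included years, got {len(values)}")
    mu = float(values.mean())
    if mu <= 0:
        raise DataError("non-positive mean productivity")
    sd = float(values.std(ddof=1))
    if sd == 0:
        raise DegenerateSeriesError("constant productivity series: stability undefined")
    return StabilityResult(
        mesocosm_id=mesocosm_id,
        temporal_stability=mu / sd,
        mean_productivity=mu,
        sd_productivity=sd,
        years=tuple(years),
    )


def invasion_impact(
    series_by_year: Mapping[int, float],
    pre_year: int = IMPACT_PRE_YEAR,
    post_year: int = IMPACT_POST_YEAR,
) -> float:
    """Difference value(post_year) - value(pre_year), in the parameter's units."""
    for y in (pre_year, post_year):
        if y not in series_by_year:
            raise DataError(f"year {y} missing from series")
    return float(series_by_year[post_year] - series_by_year[pre_year])


def trajectory_beta(
    series_by_year: Mapping[int, float],
    year_range: tuple[int, int] = TRAJECTORY_YEARS,
) -> float:
    """Standardized slope of value on year over the inclusive year range.

    Equals the Pearson correlation between value and year; years are centered
    before regression for numerical stability (identical beta).
    """
    years = np.array(
        sorted(y for y in series_by_year if year_range[0] <= y <= year_range[1]),
        dtype=float,
    )
    if len(years) < 3:
        raise DataError(f"need >= 3 years within {year_range}, got {len(years)}")
    values = np.array([series_by_year[int(y)] for y in years], dtype=float)
    x = years - years.mean()
    sd_y = values.std(ddof=1)
    if sd_y == 0:
        raise DegenerateSeriesError("constant series: trajectory undefined")
    slope = float((x * (values - values.mean())).sum() / (x**2).sum())
    return slope * float(x.std(ddof=1)) / float(sd_y)


def invader_proportion(biomass: Sequence[float], invader_flag: Sequence[bool]) -> float:
    """Biomass share of invader-flagged species in one mesocosm-year."""
    b = np.asarray(biomass, dtype=float)
    flags = np.asarray(invader_flag, dtype=bool)
    total = b.sum()
    if total <= 0:
        raise DataError("zero total biomass")
    return float(b[flags].sum() / total)


def community_time_series(plant_table: pd.DataFrame) -> pd.DataFrame:
    """Per mesocosm-year summaries from the long biomass table.

    Expects columns mesocosm_id, soil, sowing_density, year, species_id,
    invader_flag, biomass_g.  Returns one row per mesocosm-year with total
    productivity, Shannon diversity and invader proportion.
    """
    required = {"mesocosm_id", "soil", "sowing_density", "year", "species_id",
                "invader_flag", "biomass_g"}
    missing = required - set(plant_table.columns)
    if missing:
        raise DataError(f"plant table missing columns: {sorted(missing)}")

    rows = []
    for (mid, year), grp in plant_table.groupby(["mesocosm_id", "year"], sort=True):
        b = grp["biomass_g"].to_numpy(dtype=float)
        rows.append(
            {
                "mesocosm_id": mid,
                "soil": grp["soil"].iloc[0],
                "sowing_density": grp["sowing_density"].iloc[0],
                "year": int(year),
                "productivity": float(b.sum()),
                "shannon": shannon_diversity(b),
                "invader_proportion": invader_proportion(
                    b, grp["invader_flag"].to_numpy(dtype=bool)
                ),
            }
        )
    return pd.DataFrame(rows)


def mesocosm_metrics(
    plant_table: pd.DataFrame,
    axes: pd.DataFrame | None = None,
    *,
    drop_first_year: bool = True,
) -> pd.DataFrame:
    """Per-mesocosm metric table: stability, final-year state, past parameters.

    ``axes`` optionally supplies compositional axis scores (columns
    mesocosm_id, year, axis1..axis3); past parameters are then computed for
    the axes as well.  The final census year provides the "year of sampling"
    values used downstream.
    """
    ts = community_time_series(plant_table)
    final_year = int(ts["year"].max())
    if axes is not None:
        axes = axes.copy()
        axes["year"] = axes["year"].astype(int)

    rows = []
    for mid, grp in ts.groupby("mesocosm_id", sort=True):
        series = grp.set_index("year")
        prod = series["productivity"].to_dict()
        div = series["shannon"].to_dict()
        stab = temporal_stability(prod, drop_first_year=drop_first_year,
                                  mesocosm_id=str(mid))
        row = {
            "mesocosm_id": mid,
            "soil": grp["soil"].iloc[0],
            "sowing_density": grp["sowing_density"].iloc[0],
            "temporal_stability": stab.temporal_stability,
            "productivity": prod[final_year],
            "diversity": div[final_year],
            "invader_proportion": series["invader_proportion"].loc[final_year],
            "impact_productivity": invasion_impact(prod),
            "impact_diversity": invasion_impact(
                div, post_year=IMPACT_POST_YEAR_DIVERSITY
            ),
            "trajectory_productivity": trajectory_beta(prod),
            "trajectory_diversity": trajectory_beta(div),
        }
        if axes is not None:
            ax = axes[axes["mesocosm_id"] == mid].set_index("year")
            for k in (1, 2, 3):
                col = ax[f"axis{k}"].to_dict()
                row[f"axis{k}"] = col[final_year]
                row[f"impact_axis{k}"] = invasion_impact(col)
                row[f"trajectory_axis{k}"] = trajectory_beta(col)
        rows.append(row)
    return pd.DataFrame(rows)
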