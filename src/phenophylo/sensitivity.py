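"""Preseason identification and climate sensitivity of spring phenophases.

For each species and phenophase (first-leaf date FLD, first-flower date
FFD, in day-of-year), the preseason is the window of L days (L scanned
1..120) immediately before the multi-year mean phenophase date whose mean
climate correlates best (highest |r|) with the interannual phenophase
variation.  The sensitivity is then the OLS slope of the day-of-year on
the preseason mean predictor across years: days/degC for temperature,
days/mm for (mean daily) precipitation.

Windows are walked on real calendar dates, so they may reach into the
preceding calendar year and leap days are handled naturally.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DailyClimate",
    "PhenoSeries",
    "PreseasonResult",
    "SensitivityResult",
    "window_mean",
    "window_means",
    "find_preseason",
    "sensitivity_slope",
    "filter_min_years",
    "read_climate_csv",
    "read_phenology_csv",
]

logger = logging.getLogger(__name__)

PHENOPHASES = ("FLD", "FFD")
VARIABLES = ("temperature", "precipitation")
_VAR_COL = {"temperature": "tmean_c", "precipitation": "prcp_mm"}


@dataclass
class DailyClimate:
    """Contiguous daily meteorological series.

    ``data`` is indexed by calendar date with columns ``tmean_c`` (mean
    temperature, degC) and ``prcp_mm`` (precipitation, mm >= 0).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if not isinstance(df.index, pd.DatetimeIndex):
            raise TypeError("DailyClimate needs a DatetimeIndex")
        if df.index.has_duplicates:
            dupes = df.index[df.index.duplicated()].unique()
            raise ValueError(f"duplicate dates in climate record: {list(dupes[:3])}")
        if not df.index.is_monotonic_increasing:
            self.data = df = df.sort_index()
        full = pd.date_range(df.index[0], df.index[-1], freq="D")
        if len(full) != len(df):
            gaps = full.difference(df.index)
            raise ValueError(
                f"{len(gaps)} missing days in climate record, first {gaps[0].date()}"
            )
        missing = [c for c in ("tmean_c", "prcp_mm") if c not in df.columns]
        if missing:
            raise ValueError(f"climate record lacks columns {missing}")
        if (df["prcp_mm"] < 0).any():
            raise ValueError("negative precipitation in climate record")

    @property
    def start(self) -> pd.Timestamp:
        return self.data.index[0]

    @property
    def end(self) -> pd.Timestamp:
        return self.data.index[-1]


@dataclass
class PhenoSeries:
    """Yearly day-of-year record of one phenophase for one species."""

    species: str
    phenophase: str  # "FLD" | "FFD"
    doy_by_year: dict[int, int]

    def __post_init__(self) -> None:
        if self.phenophase not in PHENOPHASES:
            raise ValueError(f"unknown phenophase {self.phenophase!r}")
        bad = {y: d for y, d in self.doy_by_year.items() if not 1 <= d <= 366}
        if bad:
            raise ValueError(f"day-of-year out of [1, 366]: {bad}")

    @property
    def years(self) -> list[int]:
        return sorted(self.doy_by_year)

    @property
    def n_years(self) -> int:
        return len(self.doy_by_year)

    def mean_doy(self) -> float:
        return float(np.mean(list(self.doy_by_year.values())))


@dataclass(frozen=True)
class PreseasonResult:
    variable: str
    length: int  # preseason L in days
    anchor_doy: int  # rounded multi-year mean phenophase DOY
    pearson_r: float
    n_years: int


@dataclass(frozen=True)
class SensitivityResult:
    slope: float  # days/degC or days/mm
    intercept: float  # days
    pearson_r: float
    preseason: PreseasonResult


def _anchor_date(year: int, anchor_doy: int) -> pd.Timestamp:
    return pd.Timestamp(year=year, month=1, day=1) + pd.Timedelta(days=anchor_doy - 1)


def window_mean(
    climate: DailyClimate,
    year: int,
    anchor_doy: int,
    length: int,
    variable: str,
    *,
    statistic: str = "mean",
) -> float:
    """Mean (or, with ``statistic="sum"``, total) of a climate variable
    over the L days ending the day before the anchor date (anchor
    excluded; the window may cross the year boundary into the previous
    calendar year)."""
    if length < 1:
        raise ValueError("window length must be >= 1")
    anchor = _anchor_date(year, anchor_doy)
    lo, hi = anchor - pd.Timedelta(days=length), anchor - pd.Timedelta(days=1)
    if lo < climate.start or hi > climate.end:
        raise ValueError(
            f"window [{lo.date()}, {hi.date()}] not covered by climate record "
            f"[{climate.start.date()}, {climate.end.date()}]"
        )
    col = _VAR_COL[variable]
    vals = climate.data.loc[lo:hi, col]
    return float(vals.sum() if statistic == "sum" else vals.mean())


def window_means(
    climate: DailyClimate,
    years,
    anchor_doy: int,
    max_length: int,
    variable: str,
) -> np.ndarray:
    """Window means for all L = 1..max_length and all years at once.

    Returns an array of shape (len(years), max_length); entry [i, L-1] is
    the mean over the L days ending the day before the anchor in years[i].
    Computed from one cumulative sum over each year's 120-day (max_length)
    trailing block, equivalent to calling :func:`window_mean` per (year, L).
    """
    col = _VAR_COL[variable]
    series = climate.data[col]
    out = np.empty((len(years), max_length))
    for i, year in enumerate(years):
        anchor = _anchor_date(int(year), anchor_doy)
        lo = anchor - pd.Timedelta(days=max_length)
        hi = anchor - pd.Timedelta(days=1)
        if lo < climate.start or hi > climate.end:
            raise ValueError(
                f"window [{lo.date()}, {hi.date()}] not covered by climate record"
            )
        block = series.loc[lo:hi].to_numpy()  # chronological, length max_length
        rev_cumsum = np.cumsum(block[::-1])  # sum of last L days
        out[i] = rev_cumsum / np.arange(1, max_length + 1)
    return out


def find_preseason(
    pheno: PhenoSeries,
    climate: DailyClimate,
    variable: str,
    max_length: int = 120,
    *,
    min_years: int = 10,
    use_abs_r: bool = True,
) -> PreseasonResult:
    """Scan L = 1..max_length and return the window with the best
    correlation between the per-year window mean and the phenophase DOY.

    ``use_abs_r=True`` (default) maximizes |r| — spring phenology advances
    with warmth, so the informative correlations are negative; maximizing
    raw r would systematically pick spurious positive windows.  Ties go to
    the smallest L.
    """
    anchor0 = int(round(pheno.mean_doy()))
    covered = [
        y
        for y in pheno.years
        if _anchor_date(y, anchor0) - pd.Timedelta(days=max_length) >= climate.start
        and _anchor_date(y, anchor0) - pd.Timedelta(days=1) <= climate.end
    ]
    if len(covered) < len(pheno.years):
        logger.warning(
            "%s %s: dropping %d years without full %d-day climate coverage",
            pheno.species, pheno.phenophase, len(pheno.years) - len(covered),
            max_length,
        )
    years = covered
    if len(years) < min_years:
        raise ValueError(
            f"{pheno.species} {pheno.phenophase}: {len(years)} overlapping years "
            f"< required {min_years}"
        )
    doy = np.array([pheno.doy_by_year[y] for y in years], dtype=float)
    if np.ptp(doy) == 0:
        raise ValueError("constant phenophase series: correlation undefined")
    anchor = int(round(pheno.mean_doy()))
    W = window_means(climate, years, anchor, max_length, variable)  # (Y, L)
    dc = doy - doy.mean()
    Wc = W - W.mean(axis=0)
    sw = np.sqrt((Wc**2).sum(axis=0))
    valid = sw > 0
    if not valid.any():
        raise ValueError("climate predictor constant at every window length")
    r = np.full(max_length, np.nan)
    r[valid] = (Wc[:, valid] * dc[:, None]).sum(axis=0) / (
        sw[valid] * np.sqrt((dc**2).sum())
    )
    score = np.abs(r) if use_abs_r else r
    best = int(np.nanargmax(score))  # first occurrence wins ties -> smallest L
    return PreseasonResult(
        variable=variable,
        length=best + 1,
        anchor_doy=anchor,
        pearson_r=float(r[best]),
        n_years=len(years),
    )


def sensitivity_slope(
    pheno: PhenoSeries, climate: DailyClimate, preseason: PreseasonResult
) -> SensitivityResult:
    """OLS slope of phenophase DOY on the preseason mean predictor."""
    years = pheno.years
    if len(years) < 3:
        raise ValueError(f"need >= 3 years, got {len(years)}")
    doy = np.array([pheno.doy_by_year[y] for y in years], dtype=float)
    pred = np.array(
        [
            window_mean(climate, y, preseason.anchor_doy, preseason.length,
                        preseason.variable)
            for y in years
        ]
    )
    fit = stats.linregress(pred, doy)
    return SensitivityResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        pearson_r=float(fit.rvalue),
        preseason=preseason,
    )


def filter_min_years(
    series: dict[str, dict[str, PhenoSeries]], min_years: int = 50
) -> dict[str, dict[str, PhenoSeries]]:
    """Keep species whose FLD and FFD series each span >= min_years years.

    ``series`` maps species -> phenophase -> PhenoSeries.  Species lacking
    either phenophase, or with a short series, are excluded (logged).
    """
    kept: dict[str, dict[str, PhenoSeries]] = {}
    for sp in sorted(series):
        byph = series[sp]
        counts = {ph: byph[ph].n_years if ph in byph else 0 for ph in PHENOPHASES}
        if all(c >= min_years for c in counts.values()):
            kept[sp] = byph
            logger.info("retained %s (FLD %d y, FFD %d y)", sp, counts["FLD"],
                        counts["FFD"])
        else:
            logger.info("excluded %s (FLD %d y, FFD %d y < %d)", sp, counts["FLD"],
                        counts["FFD"], min_years)
    if not kept:
        logger.warning("min-years filter removed every species")
    return kept


def read_climate_csv(path) -> DailyClimate:
    """Climate CSV: columns date (ISO-8601), tmean_c, prcp_mm."""
    df = pd.read_csv(path, parse_dates=["date"]).set_index("date")
    return DailyClimate(df)


def read_phenology_csv(path) -> dict[str, dict[str, PhenoSeries]]:
    """Long phenology CSV (species, phenophase, year, doy) -> nested series."""
    df = pd.read_csv(path)
    out: dict[str, dict[str, PhenoSeries]] = {}
    for (sp, ph), grp in df.groupby(["species", "phenophase"], sort=True):
        dup = grp["year"].duplicated()
        if dup.any():
            raise ValueError(
                f"{sp} {ph}: duplicate years {sorted(grp.loc[dup, 'year'])[:3]}"
            )
        out.setdefault(str(sp), {})[str(ph)] = PhenoSeries(
            str(sp), str(ph), dict(zip(grp["year"].astype(int), grp["doy"].astype(int)))
        )
    return out
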