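"""Downstream impact calculus: rescaled-emission correlations in major
cities, PM2.5-attributable disease fractions, and the forest CO2 offset.

Rescaling divides out the mean population scaling — ``E_c~ = E_CO2 / P**beta``
and ``E_p~ = E_PM2.5 / P**gamma`` — so that residual correlations between
emissions of large cities are not driven by city size itself.  Ambient PM2.5
concentration is *not* rescaled: its conditional mean is flat in population
for large cities.

The population attributable fraction (PAF) is read from an empirical
monotone exposure-response relation (concentration in ug/m3 -> fraction of
disease burden attributable to PM2.5), interpolated piecewise linearly and
clamped outside the tabulated range.

The regional CO2 balance is emitted minus captured; the offset fraction is
captured/emitted, and the aggregate offset is total captured over total
emitted (never a mean of ratios).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .geodata import CityTable, RegionTable

__all__ = [
    "RescaledEmissions",
    "CorrelationResult",
    "ExposureResponseCurve",
    "RegionBalance",
    "rescale_large_cities",
    "pearson",
    "paf_at",
    "regional_paf",
    "forest_capture_model",
    "co2_balance",
    "offset_scenario",
]

logger = logging.getLogger(__name__)


@dataclass
class RescaledEmissions:
    """Per-city rescaled emissions for cities above a population threshold."""

    df: pd.DataFrame  # city_id, population, e_co2_rescaled, e_pm25_rescaled, c_pm25
    beta: float
    gamma: float
    threshold: float


@dataclass
class CorrelationResult:
    r: float
    p: float
    n: int


@dataclass
class ExposureResponseCurve:
    """Monotone tabulated relation concentration (ug/m3) -> attributable
    fraction in [0, 1], interpolated linearly between knots."""

    concentrations: np.ndarray
    fractions: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.concentrations, dtype=float)
        f = np.asarray(self.fractions, dtype=float)
        if c.size == 0:
            raise ValueError("empty exposure-response curve")
        if c.size != f.size:
            raise ValueError("knot arrays must have equal length")
        if np.any(np.diff(c) <= 0):
            raise ValueError("concentrations must be strictly increasing")
        if np.any((f < 0) | (f > 1)):
            raise ValueError("fractions must lie in [0, 1]")
        if np.any(np.diff(f) < 0):
            raise ValueError("exposure-response must be nondecreasing")
        self.concentrations = c
        self.fractions = f

    @classmethod
    def from_csv(cls, path) -> "ExposureResponseCurve":
        df = pd.read_csv(path)
        return cls(df.iloc[:, 0].to_numpy(), df.iloc[:, 1].to_numpy())


@dataclass
class RegionBalance:
    region_id: str
    emitted: float
    captured: float

    @property
    def balance(self) -> float:
        return self.emitted - self.captured

    @property
    def offset_fraction(self) -> float:
        return self.captured / self.emitted


def rescale_large_cities(
    table: CityTable, beta: float, gamma: float, threshold: float = 700_000
) -> RescaledEmissions:
    """Filter to cities with P >= threshold and divide out the population
    scaling of both emission measures; concentration passes through as is."""
    df = table.df
    sel = df["population"] >= threshold
    if not sel.any():
        raise ValueError(f"no city with population >= {threshold:g}")
    sub = df.loc[sel].copy()
    P = sub["population"].to_numpy(dtype=float)
    out = pd.DataFrame(
        {
            "city_id": sub["city_id"].to_numpy(),
            "population": P,
            "e_co2_rescaled": sub["e_co2"].to_numpy(dtype=float) / P**beta,
            "e_pm25_rescaled": sub["e_pm25"].to_numpy(dtype=float) / P**gamma,
            "c_pm25": sub["c_pm25"].to_numpy(dtype=float),
        }
    )
    return RescaledEmissions(out, beta=beta, gamma=gamma, threshold=threshold)


def pearson(x, y) -> CorrelationResult:
    """Pearson correlation with the two-sided p-value from the t transform
    (n - 2 degrees of freedom)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in one of the variables")
    res = stats.pearsonr(x, y)
    return CorrelationResult(r=float(res.statistic), p=float(res.pvalue), n=int(x.size))


def paf_at(curve: ExposureResponseCurve, c) -> np.ndarray | float:
    """PAF at concentration ``c`` by piecewise-linear interpolation; values
    outside the knot range are clamped to the end knots (with a warning)."""
    c_arr = np.asarray(c, dtype=float)
    lo, hi = curve.concentrations[0], curve.concentrations[-1]
    if np.any(c_arr < lo) or np.any(c_arr > hi):
        logger.warning(
            "concentration outside exposure-response range [%g, %g]; clamping", lo, hi
        )
    out = np.interp(c_arr, curve.concentrations, curve.fractions)
    return float(out) if np.isscalar(c) or c_arr.ndim == 0 else out


def regional_paf(
    regions: RegionTable, curves: dict[str, ExposureResponseCurve] | ExposureResponseCurve
) -> pd.DataFrame:
    """PAF per region per disease curve; regions without a concentration are
    skipped with a warning and absent from the output."""
    if isinstance(curves, ExposureResponseCurve):
        curves = {"paf": curves}
    df = regions.df
    has_c = df["c_pm25"].notna()
    for rid in df.loc[~has_c, "region_id"]:
        logger.warning("region %s has no concentration; skipped", rid)
    sub = df.loc[has_c]
    out = {"region_id": sub["region_id"].to_numpy()}
    for name, curve in curves.items():
        out[name] = paf_at(curve, sub["c_pm25"].to_numpy(dtype=float))
    return pd.DataFrame(out)


def forest_capture_model(regions: RegionTable) -> tuple[float, float, float]:
    """Through-origin least squares of capture (tons CO2/yr) on forest area
    (km2): returns ``(slope, stderr, r_squared)``.

    The slope is the regional capture rate per km2 of forest; r-squared is
    the uncentered coefficient of determination appropriate to a
    through-origin model.
    """
    df = regions.df
    ok = df["forest_area"].notna() & df["capture"].notna()
    x = df.loc[ok, "forest_area"].to_numpy(dtype=float)
    y = df.loc[ok, "capture"].to_numpy(dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 regions with forest area and capture")
    sxx = float(np.sum(x * x))
    if sxx == 0:
        raise ValueError("all forest areas are zero")
    slope = float(np.sum(x * y)) / sxx
    resid = y - slope * x
    dof = max(x.size - 1, 1)
    stderr = float(np.sqrt(np.sum(resid**2) / dof / sxx))
    ss_tot = float(np.sum(y * y))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else np.nan
    return slope, stderr, r2


def co2_balance(regions: RegionTable) -> list[RegionBalance]:
    """Per-region CO2 balance (emitted - captured) and offset fraction.

    Regions with zero or missing emission have an undefined offset and are
    flagged via warning; they are excluded from the returned list.
    """
    out: list[RegionBalance] = []
    for _, row in regions.df.iterrows():
        emitted = row["e_co2"]
        captured = row["capture"] if np.isfinite(row["capture"]) else 0.0
        if not np.isfinite(emitted) or emitted <= 0:
            logger.warning(
                "region %s: offset undefined (emission %r)", row["region_id"], emitted
            )
            continue
        out.append(RegionBalance(str(row["region_id"]), float(emitted), float(captured)))
    if not out:
        raise ValueError("no region with positive emission")
    return out


def aggregate_offset(balances: list[RegionBalance]) -> float:
    """Total captured over total emitted — not the mean of regional ratios."""
    return sum(b.captured for b in balances) / sum(b.emitted for b in balances)


def offset_scenario(regions: RegionTable, target_forest_fraction: float) -> float:
    """Aggregate offset fraction if each region's forest cover were set to
    ``target_forest_fraction`` of its land area (capped at the full land
    area), with capture scaling linearly in forest area at the region's own
    rate.  Requires ``land_area``, ``forest_area``, ``capture``, ``e_co2``.
    """
    if not 0 <= target_forest_fraction:
        raise ValueError("target_forest_fraction must be nonnegative")
    df = regions.df
    needed = ["land_area", "forest_area", "capture", "e_co2"]
    ok = np.all([df[c].notna() for c in needed], axis=0) & (df["forest_area"] > 0) & (
        df["e_co2"] > 0
    )
    sub = df.loc[ok]
    if sub.empty:
        raise ValueError("no region with land area, forest area, capture and emission")
    new_forest = np.minimum(target_forest_fraction, 1.0) * sub["land_area"].to_numpy(
        dtype=float
    )
    new_forest = np.minimum(new_forest, sub["land_area"].to_numpy(dtype=float))
    scale = new_forest / sub["forest_area"].to_numpy(dtype=float)
    new_capture = sub["capture"].to_numpy(dtype=float) * scale
    return float(new_capture.sum() / sub["e_co2"].to_numpy(dtype=float).sum())
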