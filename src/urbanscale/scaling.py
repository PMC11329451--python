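"""Urban scaling laws: log-binned conditional statistics, power-law fits and
the data collapse of conditional distributions.

Two exponent estimators are provided, matching the two conventions in the
urban-scaling literature:

* the *conditional-mean* estimator (``binned_conditional_mean`` +
  ``fit_power_law_binned``): least squares of ``log10 <Y|P>`` on ``log10 P``
  over logarithmically spaced population bins, restricted to the linear part
  of the curve;
* the *all-data* estimator (``fit_power_law_all``): ordinary least squares of
  ``log10 Y`` on ``log10 P`` over every city.

The two agree on noiseless power laws but can differ on heteroscedastic or
unevenly sampled data, which is why both are reported.

If the conditional distribution obeys the scaling form
``rho(Y|P) = P**-beta * F(Y * P**-beta)`` (the exponent is forced to appear
with the same value in prefactor and argument by normalization of the
conditional density), then plotting ``P**beta * rho`` against
``z = Y * P**-beta`` superimposes the curves from all population bins.
``rescale_collapse`` performs the transformation and ``collapse_quality``
scores the superposition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .geodata import CityTable

__all__ = [
    "LogBinnedStat",
    "PowerLawFit",
    "ConditionalDensity",
    "ConditionalDensitySet",
    "CollapseResult",
    "binned_conditional_mean",
    "fit_power_law_binned",
    "fit_power_law_all",
    "conditional_density",
    "rescale_collapse",
    "collapse_quality",
    "fit_by_group",
]

logger = logging.getLogger(__name__)

DEFAULT_BINS_PER_DECADE = 6
DEFAULT_MIN_COUNT = 10


@dataclass
class LogBinnedStat:
    """Conditional mean of a measure on log-spaced population bins.

    ``bin_edges`` and ``bin_centers`` are in log10(population); ``means`` are
    arithmetic means of the (linear) measure, NaN where the bin count is
    below ``min_count``.
    """

    bin_edges: np.ndarray
    bin_centers: np.ndarray
    means: np.ndarray
    counts: np.ndarray
    min_count: int

    @property
    def mask(self) -> np.ndarray:
        """True for bins with a valid mean."""
        return np.isfinite(self.means)


@dataclass
class PowerLawFit:
    """Least-squares power-law fit ``y = 10**log10_prefactor * x**exponent``."""

    exponent: float
    log10_prefactor: float
    exponent_stderr: float
    r_squared: float
    fit_range: tuple[float, float]
    n_points: int

    def __post_init__(self) -> None:
        if not self.fit_range[0] < self.fit_range[1]:
            raise ValueError("fit_range must satisfy P_low < P_high")

    def predict(self, x: np.ndarray) -> np.ndarray:
        return 10.0**self.log10_prefactor * np.asarray(x, dtype=float) ** self.exponent


@dataclass
class ConditionalDensity:
    """Density of a measure within one population bin, on log-spaced measure
    bins, normalized in the *linear* measure variable (integral 1)."""

    pop_center: float
    pop_range: tuple[float, float]
    measure_edges: np.ndarray
    density: np.ndarray
    count: int

    def integral(self) -> float:
        return float(np.sum(self.density * np.diff(self.measure_edges)))


@dataclass
class ConditionalDensitySet:
    densities: list[ConditionalDensity]
    normalization: str = "linear-measure, integral 1 per population bin"

    def __len__(self) -> int:
        return len(self.densities)


@dataclass
class CollapseResult:
    """Rescaled conditional densities: abscissa ``z = y * P**-exponent``,
    ordinate ``P**exponent * rho``; each curve still integrates to 1 in z."""

    exponent: float
    curves: list[ConditionalDensity]  # measure_edges reinterpreted as z edges
    quality: float | None = None


def _positive_pair(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    ok = np.isfinite(x) & np.isfinite(y) & (x > 0) & (y > 0)
    dropped = x.size - int(ok.sum())
    if dropped:
        logger.info("dropping %d non-positive/missing observations", dropped)
    return x[ok], y[ok]


def binned_conditional_mean(
    x,
    y,
    n_bins: int | None = None,
    min_count: int = DEFAULT_MIN_COUNT,
) -> LogBinnedStat:
    """Conditional mean <y|x> on bins linearly spaced in log10(x).

    ``n_bins`` defaults to ~6 per decade of the populated range.  Bins with
    fewer than ``min_count`` observations are masked (mean NaN).
    """
    x, y = _positive_pair(x, y)
    if x.size == 0:
        raise ValueError("no positive observations")
    lx = np.log10(x)
    lo, hi = lx.min(), lx.max()
    if hi <= lo:
        raise ValueError("x spans a single value; cannot bin")
    if n_bins is None:
        n_bins = max(int(np.ceil(DEFAULT_BINS_PER_DECADE * (hi - lo))), 2)
    edges = np.linspace(lo, hi, n_bins + 1)
    idx = np.clip(np.digitize(lx, edges) - 1, 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    sums = np.bincount(idx, weights=y, minlength=n_bins)
    with np.errstate(invalid="ignore"):
        means = np.where(counts >= max(min_count, 1), sums / np.maximum(counts, 1), np.nan)
    if np.isfinite(means).sum() < 2:
        raise ValueError("fewer than 2 bins meet min_count; widen bins or lower it")
    centers = 0.5 * (edges[:-1] + edges[1:])
    return LogBinnedStat(edges, centers, means, counts, min_count)


def _ols_loglog(lx: np.ndarray, ly: np.ndarray, fit_range: tuple[float, float]) -> PowerLawFit:
    res = stats.linregress(lx, ly)
    return PowerLawFit(
        exponent=float(res.slope),
        log10_prefactor=float(res.intercept),
        exponent_stderr=float(res.stderr),
        r_squared=float(res.rvalue**2),
        fit_range=fit_range,
        n_points=len(lx),
    )


def fit_power_law_binned(
    stat: LogBinnedStat,
    fit_range: tuple[float, float] | None = None,
    min_span_fraction: float = 0.6,
) -> PowerLawFit:
    """Fit log10(mean) vs log10(P) over the binned conditional mean.

    With ``fit_range=(P_low, P_high)`` the fit uses the bins whose centers
    fall in that (linear population) interval.  Without it, the linear part is
    selected automatically: among contiguous windows of unmasked bins spanning
    at least ``min_span_fraction`` of the populated decade range, the window
    with the highest r-squared wins.  The selected window is returned in
    ``fit_range`` so every fit is auditable.
    """
    ok = stat.mask
    centers = stat.bin_centers
    if fit_range is not None:
        lo, hi = np.log10(fit_range[0]), np.log10(fit_range[1])
        if not lo < hi:
            raise ValueError("degenerate fit_range")
        sel = ok & (centers >= lo) & (centers <= hi)
        if sel.sum() < 3:
            raise ValueError("fewer than 3 unmasked bins in fit_range")
        return _ols_loglog(centers[sel], np.log10(stat.means[sel]), fit_range)

    valid = np.flatnonzero(ok)
    if len(valid) < 3:
        raise ValueError("fewer than 3 unmasked bins")
    span = centers[valid[-1]] - centers[valid[0]]
    best: PowerLawFit | None = None
    for a in range(len(valid)):
        for b in range(a + 2, len(valid)):
            win = valid[a : b + 1]
            if centers[win[-1]] - centers[win[0]] < min_span_fraction * span:
                continue
            fit = _ols_loglog(
                centers[win],
                np.log10(stat.means[win]),
                (10.0 ** stat.bin_edges[win[0]], 10.0 ** stat.bin_edges[win[-1] + 1]),
            )
            if best is None or fit.r_squared > best.r_squared:
                best = fit
    assert best is not None  # at least the full window qualifies
    logger.info(
        "auto fit window: P in [%.3g, %.3g], r^2=%.5f",
        best.fit_range[0],
        best.fit_range[1],
        best.r_squared,
    )
    return best


def fit_power_law_all(x, y) -> PowerLawFit:
    """All-data estimator: OLS of log10(y) on log10(x) over every point."""
    x, y = _positive_pair(x, y)
    if x.size < 3:
        raise ValueError("need at least 3 points")
    return _ols_loglog(np.log10(x), np.log10(y), (float(x.min()), float(x.max())))


def conditional_density(
    x,
    y,
    n_pop_bins: int = 6,
    n_measure_bins: int = 30,
    min_count: int = DEFAULT_MIN_COUNT,
) -> ConditionalDensitySet:
    """Estimate rho(y|P) per population bin on log-spaced measure bins.

    Each density is normalized so that its integral over the *linear* measure
    axis is 1; population bins with fewer than ``min_count`` observations are
    omitted.
    """
    x, y = _positive_pair(x, y)
    if x.size == 0:
        raise ValueError("no positive observations")
    lx = np.log10(x)
    pop_edges = np.linspace(lx.min(), lx.max(), n_pop_bins + 1)
    idx = np.clip(np.digitize(lx, pop_edges) - 1, 0, n_pop_bins - 1)
    out: list[ConditionalDensity] = []
    for k in range(n_pop_bins):
        yk = y[idx == k]
        if yk.size < max(min_count, 1):
            continue
        ly = np.log10(yk)
        lo, hi = ly.min(), ly.max()
        if hi <= lo:  # all values equal: single occupied bin
            width = max(abs(lo) * 1e-9, 1e-12)
            lo, hi = lo - width, hi + width
        # histogram in log space so boundary values are never dropped,
        # then normalize in the linear measure variable
        ledges = np.linspace(lo, hi, n_measure_bins + 1)
        counts, _ = np.histogram(ly, bins=ledges)
        medges = 10.0**ledges
        density = counts / (yk.size * np.diff(medges))
        out.append(
            ConditionalDensity(
                pop_center=10.0 ** (0.5 * (pop_edges[k] + pop_edges[k + 1])),
                pop_range=(10.0 ** pop_edges[k], 10.0 ** pop_edges[k + 1]),
                measure_edges=medges,
                density=density,
                count=int(yk.size),
            )
        )
    if not out:
        raise ValueError("no population bin meets min_count")
    return ConditionalDensitySet(out)


def rescale_collapse(densities: ConditionalDensitySet, exponent: float) -> CollapseResult:
    """Apply the scaling-function rescaling to every conditional density.

    For each population bin with center ``P_c``: abscissa
    ``z = y * P_c**-exponent`` and ordinate ``P_c**exponent * rho(y|P)``.
    Because the same exponent appears in argument and prefactor, each rescaled
    curve still integrates to 1 in z — the normalization that forces the two
    exponents of a generic scaling form to coincide.
    """
    if not np.isfinite(exponent):
        raise ValueError("exponent must be finite")
    curves = []
    for d in densities.densities:
        scale = d.pop_center ** (-exponent)
        curves.append(
            ConditionalDensity(
                pop_center=d.pop_center,
                pop_range=d.pop_range,
                measure_edges=d.measure_edges * scale,
                density=d.density / scale,
                count=d.count,
            )
        )
    return CollapseResult(exponent=exponent, curves=curves)


def collapse_quality(result: CollapseResult, n_grid: int = 60) -> float:
    """Mean between-curve variance of log-density over the shared z-support.

    Each rescaled curve is linearly interpolated in (log10 z, log10 rho) onto
    a common log-spaced grid restricted to its own occupied support; grid
    points where at least two curves are defined contribute the across-curve
    variance of log10 density, and the score is the mean of those
    contributions.  Identical curves score 0; shifted or misscaled curves
    score strictly positive.
    """
    if len(result.curves) < 2:
        raise ValueError("need at least 2 curves")
    supports = []
    for c in result.curves:
        occ = c.density > 0
        if not occ.any():
            continue
        zc = np.sqrt(c.measure_edges[:-1] * c.measure_edges[1:])  # geometric centers
        supports.append((np.log10(zc[occ]), np.log10(c.density[occ])))
    if len(supports) < 2:
        raise ValueError("fewer than 2 non-empty curves")
    zmin = min(s[0].min() for s in supports)
    zmax = max(s[0].max() for s in supports)
    grid = np.linspace(zmin, zmax, n_grid)
    vals = np.full((len(supports), n_grid), np.nan)
    for i, (lz, lrho) in enumerate(supports):
        inside = (grid >= lz.min()) & (grid <= lz.max())
        vals[i, inside] = np.interp(grid[inside], lz, lrho)
    n_def = np.isfinite(vals).sum(axis=0)
    shared = n_def >= 2
    if not shared.any():
        raise ValueError("curves have no shared z-support")
    var = np.nanvar(vals[:, shared], axis=0)
    quality = float(var.mean())
    result.quality = quality
    return quality


def fit_by_group(
    table: CityTable,
    measure: str,
    group_label: str,
    n_bins: int | None = None,
    min_count: int = DEFAULT_MIN_COUNT,
) -> tuple[dict[str, PowerLawFit], dict[str, str]]:
    """Per-group conditional-mean power-law fit (e.g. country by country).

    Returns ``(fits, skipped)``; groups whose data cannot support a fit are
    reported in ``skipped`` with the reason, never raised.
    """
    if group_label not in table.df.columns:
        raise KeyError(f"no group column {group_label!r}")
    fits: dict[str, PowerLawFit] = {}
    skipped: dict[str, str] = {}
    for name, sub in table.df.groupby(group_label):
        try:
            stat = binned_conditional_mean(
                sub["population"], sub[measure], n_bins=n_bins, min_count=min_count
            )
            fits[str(name)] = fit_power_law_binned(stat)
        except (ValueError, KeyError) as exc:
            skipped[str(name)] = str(exc)
    return fits, skipped
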