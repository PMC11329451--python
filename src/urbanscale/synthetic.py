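"""Synthetic city tables and gridded measures with known generating parameters.

City populations follow a Zipf-like (discrete Pareto) distribution, emissions
follow a conditional power law ``E = A * P**beta * 10**eps`` with lognormal
scatter ``eps ~ N(0, sigma)`` in decades, and concentrations follow a weak
power law below a population knee and are flat above it.  Gridded measures
come from multiplicative 2x2 cascades whose moment exponents have the closed
form ``tau(q) = -log2(sum_i w_i**q)``, which makes them exact oracles for the
box-counting pipeline.

All randomness flows from the config seed through a named
:func:`numpy.random.default_rng` stream per operation, so adding operations
does not perturb existing streams.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geodata import CityTable, GridMeasure

__all__ = [
    "CityGenConfig",
    "CascadeConfig",
    "generate_populations",
    "generate_conditional_measure",
    "generate_concentration",
    "generate_cascade",
    "generate_uniform_measure",
    "generate_city_table",
]


def _rng(seed: int, stream: str) -> np.random.Generator:
    """Independent generator for a named stream derived from one seed."""
    return np.random.default_rng([seed, zlib.crc32(stream.encode())])


@dataclass(frozen=True)
class CityGenConfig:
    """Parameters of the synthetic city ensemble.

    ``zipf_exponent`` is the probability-density exponent ``a`` of
    ``p(P) ~ P**-a`` (so the CCDF decays with exponent ``a - 1``);
    ``beta_true`` and ``prefactor_A`` define the conditional law
    ``E = A * P**beta``; ``log_scatter_sigma`` is the lognormal scatter in
    decades.
    """

    n_cities: int = 50_000
    pop_min: int = 1_000
    zipf_exponent: float = 2.0
    beta_true: float = 0.81
    prefactor_A: float = 1.0
    log_scatter_sigma: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cities < 1:
            raise ValueError("n_cities must be >= 1")
        if self.pop_min < 1:
            raise ValueError("pop_min must be >= 1")
        if self.zipf_exponent <= 1:
            raise ValueError("zipf_exponent must exceed 1 for a normalizable tail")
        if self.log_scatter_sigma < 0:
            raise ValueError("log_scatter_sigma must be >= 0")


@dataclass(frozen=True)
class CascadeConfig:
    """Multiplicative 2x2 cascade: ``depth`` subdivision levels and four
    nonnegative ``weights`` summing to 1.  With ``randomized=False`` the weight
    layout is identical in every cell and the closed-form ``tau(q)`` is exact;
    with ``randomized=True`` the four weights are permuted independently per
    subdivision, preserving ``tau(q)`` in expectation."""

    depth: int = 8
    weights: tuple[float, float, float, float] = (0.4, 0.3, 0.2, 0.1)
    randomized: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (4,):
            raise ValueError("exactly 4 weights required")
        if np.any(w < 0):
            raise ValueError("weights must be nonnegative")
        if abs(w.sum() - 1.0) > 1e-12:
            raise ValueError("weights must sum to 1 within 1e-12")


def generate_populations(cfg: CityGenConfig) -> np.ndarray:
    """Draw city populations from a Zipf-like tail.

    Inverse-CDF sampling of a continuous Pareto with shape
    ``zipf_exponent - 1`` and scale ``pop_min``, rounded up to an integer —
    a discrete power-law tail that is simple and exactly reproducible.
    """
    rng = _rng(cfg.seed, "populations")
    u = rng.random(cfg.n_cities)
    shape = cfg.zipf_exponent - 1.0
    pops = np.ceil(cfg.pop_min * u ** (-1.0 / shape))
    return pops.astype(float)


def generate_conditional_measure(
    populations: np.ndarray,
    beta_true: float,
    prefactor_A: float,
    log_scatter_sigma: float,
    seed: int,
    stream: str = "measure",
) -> np.ndarray:
    """``measure_i = A * P_i**beta * 10**eps_i`` with ``eps ~ N(0, sigma)``.

    This realises the scaling-function form of the conditional distribution
    exactly by construction: rescaling by ``P**-beta`` removes all population
    dependence, so conditional densities from different population bins
    collapse onto the lognormal scatter law.
    """
    populations = np.asarray(populations, dtype=float)
    if np.any(populations <= 0):
        raise ValueError("populations must be positive")
    if log_scatter_sigma < 0:
        raise ValueError("log_scatter_sigma must be >= 0")
    rng = _rng(seed, stream)
    eps = rng.normal(0.0, log_scatter_sigma, size=populations.shape)
    return prefactor_A * populations**beta_true * 10.0**eps


def generate_concentration(
    populations: np.ndarray,
    delta_true: float,
    knee_population: float,
    sigma: float,
    seed: int,
    prefactor: float = 1.0,
) -> np.ndarray:
    """Concentration with median ``prefactor * P**delta`` below the knee and a
    constant (continuous at the knee) median above it, times ``10**N(0, sigma)``
    scatter.  Emulates the weak concentration–population dependence that holds
    only for small settlements."""
    populations = np.asarray(populations, dtype=float)
    if np.any(populations <= 0):
        raise ValueError("populations must be positive")
    if knee_population <= 0:
        raise ValueError("knee_population must be positive")
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    capped = np.minimum(populations, knee_population)
    median = prefactor * capped**delta_true
    rng = _rng(seed, "concentration")
    eps = rng.normal(0.0, sigma, size=populations.shape)
    return median * 10.0**eps


def generate_cascade(cfg: CascadeConfig) -> GridMeasure:
    """Build a multiplicative cascade on a ``2**depth`` square grid.

    Starting from unit mass on one cell, every level splits each cell 2x2,
    children receiving the parent mass times the four weights.  For the
    deterministic cascade the partition function at box side ``2**k`` cells is
    exactly ``(sum_i w_i**q)**(depth - k)``.
    """
    w = np.asarray(cfg.weights, dtype=float)
    grid = np.array([[1.0]])
    if not cfg.randomized:
        block = w.reshape(2, 2)
        for _ in range(cfg.depth):
            grid = np.kron(grid, block)
    else:
        rng = _rng(cfg.seed, "cascade")
        for _ in range(cfg.depth):
            n = grid.shape[0]
            new = np.empty((2 * n, 2 * n))
            # independent weight permutation per parent cell
            perms = rng.permuted(np.tile(w, (n * n, 1)), axis=1)
            blocks = perms.reshape(n, n, 2, 2)
            new = (grid[:, :, None, None] * blocks).transpose(0, 2, 1, 3).reshape(
                2 * n, 2 * n
            )
            grid = new
    return GridMeasure(grid, origin=(0.0, 0.0), cell_size=1.0, units="mass")


def generate_uniform_measure(side_cells: int, total_mass: float = 1.0) -> GridMeasure:
    """Spatially uniform measure: the non-multifractal reference with
    ``tau(q) = 2(q-1)`` and ``D_q = 2`` on a filled square."""
    if side_cells < 2:
        raise ValueError("side_cells must be >= 2")
    values = np.full((side_cells, side_cells), total_mass / side_cells**2)
    return GridMeasure(values, origin=(0.0, 0.0), cell_size=1.0)


def generate_city_table(
    cfg: CityGenConfig,
    gamma_true: float = 0.72,
    prefactor_pm: float = 1.0,
    delta_true: float = 0.08,
    knee_population: float = 1e4,
    concentration_sigma: float = 0.2,
    concentration_prefactor: float = 7.2,
) -> CityTable:
    """Full synthetic city table: populations, CO2 and PM2.5 emissions, and
    PM2.5 concentration, with independent scatter per measure.

    CO2 uses ``cfg.beta_true``; PM2.5 emissions use ``gamma_true`` with the
    same scatter; concentration uses the knee model.  The concentration
    prefactor default puts the flat regime near 15 ug/m3, a realistic ambient
    PM2.5 level.
    """
    pops = generate_populations(cfg)
    e_co2 = generate_conditional_measure(
        pops, cfg.beta_true, cfg.prefactor_A, cfg.log_scatter_sigma, cfg.seed, "e_co2"
    )
    e_pm25 = generate_conditional_measure(
        pops, gamma_true, prefactor_pm, cfg.log_scatter_sigma, cfg.seed, "e_pm25"
    )
    c_pm25 = generate_concentration(
        pops,
        delta_true,
        knee_population,
        concentration_sigma,
        cfg.seed,
        prefactor=concentration_prefactor,
    )
    df = pd.DataFrame(
        {
            "city_id": [f"city_{i:06d}" for i in range(len(pops))],
            "population": pops,
            "e_co2": e_co2,
            "e_pm25": e_pm25,
            "c_pm25": c_pm25,
        }
    )
    return CityTable(df)
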