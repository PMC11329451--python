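"""Box-counting multifractal analysis of gridded measures.

The partition function at box side ``b`` (in cell multiples) is

    Z_q(b) = sum_i mu_b(i)**q

over *occupied* boxes (mu > 0; empty boxes are excluded at every q, so q=0
counts occupied boxes).  The moment exponents tau(q) come from the power-law
decay Z_q(b) ~ b**tau(q), the Renyi dimensions are D_q = tau(q)/(q-1) with
D_1 from the information-dimension limit, and the singularity spectrum
(alpha, f(alpha)) from the Legendre transform f = q*alpha - tau with
alpha = dtau/dq by finite differences.

A measure on a filled 2-D support that is not multifractal satisfies
tau(q) = 2(q-1), i.e. constant D_q = 2; curvature of tau(q) diagnoses
multifractality.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .geodata import GridMeasure

__all__ = [
    "PartitionTable",
    "MultifractalSpectrum",
    "aggregate_boxes",
    "partition_function",
    "default_box_sizes",
    "estimate_tau",
    "renyi_dimensions",
    "legendre_spectrum",
    "analyze_grid",
    "DEFAULT_Q",
]

# 26 moments, uniform on [0, 5]; negative q excluded (unstable on near-empty boxes)
DEFAULT_Q = np.round(np.arange(0.0, 5.0 + 1e-9, 0.2), 10)


@dataclass
class PartitionTable:
    """Partition-function values Z[iq, ib] on a (q, box size) grid, computed on
    the measure normalized to unit mass; ``norm_factor`` is the mass divided
    out.  ``entropy[ib]`` holds sum mu_b log mu_b (for the information
    dimension D_1)."""

    q_values: np.ndarray
    box_sizes: np.ndarray
    Z: np.ndarray
    norm_factor: float = 1.0
    entropy: np.ndarray | None = None


@dataclass
class MultifractalSpectrum:
    q_values: np.ndarray
    tau: np.ndarray
    tau_stderr: np.ndarray
    D_q: np.ndarray | None = None
    alpha: np.ndarray | None = None
    f_alpha: np.ndarray | None = None


def aggregate_boxes(grid: GridMeasure, b: int) -> GridMeasure:
    """Coarsen a grid by summing square blocks of ``b`` x ``b`` cells.

    Trailing partial boxes are zero-padded before blocking; padding cells are
    empty so they never contribute to the partition function.  Total mass is
    conserved exactly.
    """
    if b < 1:
        raise ValueError("box size must be >= 1")
    nrow, ncol = grid.shape
    if b > max(nrow, ncol):
        raise ValueError(f"box size {b} exceeds grid side {max(nrow, ncol)}")
    pr = (-nrow) % b
    pc = (-ncol) % b
    values = np.pad(grid.values, ((0, pr), (0, pc)))
    coarse = values.reshape(
        (nrow + pr) // b, b, (ncol + pc) // b, b
    ).sum(axis=(1, 3))
    return GridMeasure(
        coarse, origin=grid.origin, cell_size=grid.cell_size * b, units=grid.units
    )


def default_box_sizes(grid: GridMeasure) -> np.ndarray:
    """Dyadic box sizes 1, 2, 4, ... up to a quarter of the (longer) grid side."""
    side = max(grid.shape)
    kmax = int(np.floor(np.log2(side / 4)))
    if kmax < 2:
        raise ValueError("grid too small for at least 3 dyadic box sizes")
    return 2 ** np.arange(0, kmax + 1)


def partition_function(
    grid: GridMeasure,
    q_values: np.ndarray | None = None,
    box_sizes: np.ndarray | None = None,
) -> PartitionTable:
    """Evaluate Z_q(b) over occupied boxes for each box size.

    The measure is normalized to unit mass internally (factor recorded), so
    Z_1(b) = 1 for every b and tau(1) = 0 by construction.
    """
    total = grid.total_mass
    if total <= 0:
        raise ValueError("grid has zero total mass")
    q_values = DEFAULT_Q if q_values is None else np.asarray(q_values, dtype=float)
    box_sizes = (
        default_box_sizes(grid) if box_sizes is None else np.asarray(box_sizes, dtype=int)
    )
    Z = np.empty((len(q_values), len(box_sizes)))
    entropy = np.empty(len(box_sizes))
    for ib, b in enumerate(box_sizes):
        coarse = aggregate_boxes(grid, int(b))
        mu = coarse.values[coarse.values > 0] / total
        # mu**q with the occupied-box convention 0**0 := excluded
        Z[:, ib] = np.power(mu[None, :], q_values[:, None]).sum(axis=1)
        entropy[ib] = float(np.sum(mu * np.log(mu)))
    return PartitionTable(q_values, box_sizes, Z, norm_factor=total, entropy=entropy)


def estimate_tau(table: PartitionTable) -> MultifractalSpectrum:
    """Per-q least-squares slope of log Z_q(b) against log b."""
    if len(table.box_sizes) < 3:
        raise ValueError("need at least 3 box sizes to fit tau(q)")
    logb = np.log(table.box_sizes.astype(float))
    tau = np.empty(len(table.q_values))
    stderr = np.empty(len(table.q_values))
    for iq in range(len(table.q_values)):
        res = stats.linregress(logb, np.log(table.Z[iq]))
        tau[iq] = res.slope
        stderr[iq] = res.stderr
    return MultifractalSpectrum(table.q_values, tau, stderr)


def renyi_dimensions(
    spec: MultifractalSpectrum, table: PartitionTable | None = None
) -> np.ndarray:
    """D_q = tau(q)/(q-1) for q != 1; at q = 1 the information dimension,
    the slope of sum mu_b log mu_b versus log b (requires the table)."""
    q = spec.q_values
    D = np.empty_like(spec.tau)
    near1 = np.isclose(q, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        D[~near1] = spec.tau[~near1] / (q[~near1] - 1.0)
    if near1.any():
        if table is None or table.entropy is None:
            raise ValueError("information dimension at q=1 needs the PartitionTable")
        logb = np.log(table.box_sizes.astype(float))
        D1 = stats.linregress(logb, table.entropy).slope
        D[near1] = D1
    spec.D_q = D
    return D


def legendre_spectrum(spec: MultifractalSpectrum) -> tuple[np.ndarray, np.ndarray]:
    """Singularity spectrum by the Legendre transform of tau(q).

    alpha = dtau/dq by central differences (one-sided at the ends) on a
    uniform q grid; f(alpha) = q*alpha - tau(q).
    """
    q = spec.q_values
    if len(q) < 3:
        raise ValueError("need at least 3 q points")
    dq = np.diff(q)
    if not np.allclose(dq, dq[0], rtol=1e-8, atol=1e-12):
        raise ValueError("legendre_spectrum requires a uniform q grid")
    alpha = np.gradient(spec.tau, q)
    f_alpha = q * alpha - spec.tau
    spec.alpha = alpha
    spec.f_alpha = f_alpha
    return alpha, f_alpha


def analyze_grid(
    grid: GridMeasure,
    q_values: np.ndarray | None = None,
    box_sizes: np.ndarray | None = None,
) -> tuple[PartitionTable, MultifractalSpectrum]:
    """Full pipeline: partition function, tau(q), D_q and (alpha, f(alpha))."""
    table = partition_function(grid, q_values, box_sizes)
    spec = estimate_tau(table)
    renyi_dimensions(spec, table)
    legendre_spectrum(spec)
    return table, spec
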