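"""Closed-form physiological quantities derived from a fitted turnover rate.

Given tumor measurements (diameter, cell size, volume doubling time, number
of sampled cells) and the fitted growth rate 1 - delta, these functions
chain together: total cell count, naive and simulated tree heights, the
in-vivo cell division rate, the tumor's lifetime, and the sampling-ratio
correction of the birth rate.  Each step is a separate auditable function;
all lengths are taken with explicit units in the argument names (mm, um,
days) and converted internally.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .trees import TreeEnsemble

__all__ = [
    "TumorMeasurements",
    "tumor_cell_count",
    "naive_tree_height",
    "mean_sim_tree_height",
    "division_rate",
    "tumor_lifetime",
    "sampling_ratio",
    "sampling_corrected_birth_rate",
]

DAYS_PER_YEAR = 365.0
MM_PER_UM = 1e-3


@dataclass(frozen=True)
class TumorMeasurements:
    """Measured inputs of the physiological chain."""

    diameter_mm: float
    cell_length_um: float
    doubling_time_days: float
    n_sampled_cells: int

    def __post_init__(self) -> None:
        for name in ("diameter_mm", "cell_length_um", "doubling_time_days"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_sampled_cells < 1:
            raise ValueError("n_sampled_cells must be positive")

    @property
    def n_total_cells(self) -> float:
        return tumor_cell_count(self.diameter_mm, self.cell_length_um)


def tumor_cell_count(diameter_mm: float, cell_length_um: float) -> float:
    """Total cell count as the cube of the diameter-to-cell-length ratio.

    The cube (not a sphere volume) is used: stacking (d / l) cells along
    each axis.  35 mm diameter and 25 um cells give ~2.7e9 cells.
    """
    if diameter_mm <= 0 or cell_length_um <= 0:
        raise ValueError("lengths must be positive")
    return float((diameter_mm / (cell_length_um * MM_PER_UM)) ** 3)


def naive_tree_height(n_cells: float, growth: float) -> float:
    """Naive height guess: log2(n) root-to-leaf branches of mean length 1/(1-delta).

    ``growth`` is the net growth rate 1 - delta in units of the birth rate.
    Real near-critical lineage trees are much shorter than this guess
    because their shape differs from a uniformly stretched pure-birth tree.
    """
    if n_cells < 2:
        raise ValueError("n_cells must be >= 2")
    if not (0.0 < growth <= 1.0):
        raise ValueError("growth must be in (0, 1]")
    return float(np.log2(n_cells) / growth)


def mean_sim_tree_height(ensemble: TreeEnsemble) -> float:
    """Mean root-to-leaf height (cell divisions) over a tree ensemble."""
    return float(np.mean([t.height for t in ensemble]))


def division_rate(
    tree_height: float, n_cells: float, doubling_time_days: float
) -> float:
    """Cell division rate (per day): tree height divided by the tumor age.

    The tumor age is log2(n_cells) doublings times the volume doubling time.
    """
    if tree_height < 0:
        raise ValueError("tree_height must be non-negative")
    return float(tree_height / (np.log2(n_cells) * doubling_time_days))


def tumor_lifetime(
    n_cells: float, doubling_time_days: float, rounded: bool = False
) -> float:
    """Tumor lifetime in years: log2(n_cells) volume doublings.

    With ``rounded=True`` the value is rounded to the nearest whole year.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    years = np.log2(n_cells) * doubling_time_days / DAYS_PER_YEAR
    return float(round(years)) if rounded else float(years)


def sampling_ratio(n_sampled: float, n_total: float) -> float:
    """Fraction of tumor cells in the sequenced sample."""
    if not (0 < n_sampled <= n_total):
        raise ValueError("need 0 < n_sampled <= n_total")
    return float(n_sampled / n_total)


def sampling_corrected_birth_rate(b_prime: float, rho: float) -> float:
    """Birth rate under uniform random sampling from a well-mixed tumor.

    b = b' / rho, where b' is the rate inferred as if the sample were the
    whole population and rho the sampling ratio.
    """
    if not (0.0 < rho <= 1.0):
        raise ValueError("rho must be in (0, 1]")
    if b_prime < 0:
        raise ValueError("b_prime must be non-negative")
    return float(b_prime / rho)
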