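"""Direct mutation-rate estimation from significant mutant read counts.

Rather than profiling mu inside the likelihood, mu is estimated directly
from the data given (delta, eps): count the sites whose mutant read count
clears a depth-dependent significance threshold (chosen so that the expected
number of sites whose mutant reads are pure sequencing error is below one
dataset-wide), divide by the expected tree length over which such counts are
detectable, and average over the tree ensemble.
"""

from __future__ import annotations

import warnings
from functools import lru_cache

import numpy as np
from scipy import stats

from .mutsim import ReadCountTable
from .trees import LineageTree, TreeEnsemble

__all__ = [
    "mutant_read_threshold",
    "significance_thresholds",
    "significant_branch_length",
    "count_significant_sites",
    "estimate_mu",
]


@lru_cache(maxsize=65536)
def mutant_read_threshold(
    r: int, eps: float, n_sites: int, rule: str = "pmf"
) -> int:
    """Smallest significant mutant read count at depth r.

    rule="pmf" (default): smallest m with Binom(m, r, eps) < 1/n_sites and
    m > eps*r, reading Binom as the probability mass at exactly m.
    rule="tail": same with the upper tail P(M >= m) in place of the pmf —
    the reading suggested by "expected number of error-only sites below one".
    Returns r + 1 if no m <= r qualifies (no count at this depth can be
    significant).
    """
    if r < 1:
        raise ValueError("depth r must be >= 1")
    if not (0.0 <= eps < 1.0):
        raise ValueError("eps must be in [0, 1)")
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    m = np.arange(r + 1)
    if rule == "pmf":
        crit = stats.binom.pmf(m, r, eps)
    elif rule == "tail":
        crit = stats.binom.sf(m - 1, r, eps)
    else:
        raise ValueError(f"unknown rule: {rule}")
    ok = (crit < 1.0 / n_sites) & (m > eps * r)
    hits = np.nonzero(ok)[0]
    if hits.size == 0:
        warnings.warn(
            f"no significant mutant count possible at depth r={r} "
            f"(eps={eps}, n_sites={n_sites}); returning r+1",
            stacklevel=2,
        )
        return r + 1
    return int(hits[0])


def significance_thresholds(
    depths, eps: float, n_sites: int, rule: str = "pmf"
) -> dict:
    """Map depth r -> m_th(r, eps) for every distinct depth given."""
    return {
        int(r): mutant_read_threshold(int(r), float(eps), int(n_sites), rule)
        for r in np.unique(np.asarray(depths))
    }


def significant_branch_length(
    tree: LineageTree,
    depth_histogram: dict,
    eps: float,
    n_sites: int,
    rule: str = "pmf",
) -> float:
    """Expected tree length on which a mutation would be called significant.

    L_sig(T, eps) = sum_{r,k} (n_r / n_sites) * l_k * P(Binom(r, f_k) >= m_th(r, eps)),
    where n_r is the number of sites sequenced at depth r.  Lies in [0, L].
    """
    lengths = tree.branch_lengths
    fracs = tree.leaf_fractions
    total = 0.0
    for r, n_r in depth_histogram.items():
        m_th = mutant_read_threshold(int(r), float(eps), int(n_sites), rule)
        if m_th > r:
            continue
        tail = stats.binom.sf(m_th - 1, int(r), fracs)
        total += (n_r / n_sites) * float(np.dot(lengths, tail))
    return total


def count_significant_sites(
    table: ReadCountTable, eps: float, rule: str = "pmf"
) -> int:
    """Number of sites whose mutant reads clear the significance threshold.

    For 4-state tables the three mutant-type counts are summed before
    thresholding.
    """
    m = table.mutant_totals
    r = table.r
    th = significance_thresholds(r, eps, table.n_sites, rule)
    th_per_site = np.array([th[int(x)] for x in r])
    return int(np.sum(m >= th_per_site))


def estimate_mu(
    table: ReadCountTable,
    ensemble: TreeEnsemble,
    eps: float,
    rule: str = "pmf",
) -> float:
    """Plug-in mutation-rate estimate at the ensemble's delta.

    mu_est = E[ M_sig / (n_sites * L_sig(T, eps)) ] over the ensemble.
    Trees with L_sig = 0 are excluded with a warning; if every tree is
    excluded the estimate is undefined and an error is raised.
    """
    m_sig = count_significant_sites(table, eps, rule)
    if m_sig == 0:
        return 0.0
    hist = table.depth_histogram()
    n_sites = table.n_sites
    vals = []
    dropped = 0
    for tree in ensemble:
        l_sig = significant_branch_length(tree, hist, eps, n_sites, rule)
        if l_sig <= 0.0:
            dropped += 1
            continue
        vals.append(m_sig / (n_sites * l_sig))
    if dropped:
        warnings.warn(
            f"{dropped} ensemble tree(s) with zero significant branch length "
            "excluded from the mutation-rate estimate",
            stacklevel=2,
        )
    if not vals:
        raise ValueError(
            "mutation rate undefined: all ensemble trees have zero "
            "significant branch length"
        )
    return float(np.mean(vals))
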