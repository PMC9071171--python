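"""Synthetic bulk-sequencing data along a cell lineage tree.

Reproduces the generative model the inference assumes: each site mutates at
most once, landing on branch ``k`` with probability ``mu * l_k`` (valid while
``mu * L << 1``); a mutation on branch ``k`` is carried by the fraction
``f_k`` of sampled cells; reads are drawn without replacement from the
sampled allele pool (hypergeometric at the branch frequency); sequencing
errors corrupt each read independently to one of the three other nucleotide
states with probability ``eps/3`` each.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .trees import LineageTree, TreeEnsemble

__all__ = [
    "MutationRate",
    "DepthModel",
    "SeqErrorRate",
    "ReadCountTable",
    "assign_mutations",
    "simulate_reads",
    "expected_observed_mutations",
    "choose_mu_for_target",
    "vaf_spectrum",
]

# the single-hit approximation P(mutation on k) ~ mu*l_k needs mu*L small
MU_L_ERROR = 0.1
MU_L_WARN = 0.01


@dataclass(frozen=True)
class MutationRate:
    """Mutations per site per cell division."""

    mu: float

    def __post_init__(self) -> None:
        if self.mu < 0:
            raise ValueError("mu must be non-negative")

    def check_tree(self, total_length: float) -> None:
        muL = self.mu * total_length
        if muL >= MU_L_ERROR:
            raise ValueError(
                f"mu*L = {muL:.3g} >= {MU_L_ERROR}: single-hit approximation invalid"
            )
        if muL >= MU_L_WARN:
            warnings.warn(
                f"mu*L = {muL:.3g} >= {MU_L_WARN}: single-hit approximation is "
                "becoming strained",
                stacklevel=2,
            )


@dataclass(frozen=True)
class SeqErrorRate:
    """Probability of a sequencing error per site per read."""

    eps: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.eps < 0.5):
            raise ValueError("eps must be in [0, 0.5)")


@dataclass
class DepthModel:
    """Per-site total read count distribution.

    kind:
        "fixed"     — every site has ``mean_depth`` reads,
        "poisson"   — 1 + Poisson(mean_depth - 1), so depths stay >= 1,
        "empirical" — resampled from a (depth, n_sites_with_depth) histogram.
    """

    kind: str = "fixed"
    mean_depth: float = 1000.0
    histogram: Optional[dict] = field(default=None)

    def __post_init__(self) -> None:
        if self.kind not in ("fixed", "poisson", "empirical"):
            raise ValueError(f"unknown depth model kind: {self.kind}")
        if self.kind == "empirical":
            if not self.histogram:
                raise ValueError("empirical depth model needs a histogram")
            if min(self.histogram) < 1:
                raise ValueError("depths must be >= 1")
            tot = float(sum(self.histogram.values()))
            self.mean_depth = sum(r * c for r, c in self.histogram.items()) / tot
        elif self.mean_depth < 1:
            raise ValueError("mean_depth must be >= 1")

    def sample(self, n_sites: int, rng: np.random.Generator) -> np.ndarray:
        if self.kind == "fixed":
            return np.full(n_sites, int(round(self.mean_depth)), dtype=np.int64)
        if self.kind == "poisson":
            return 1 + rng.poisson(self.mean_depth - 1.0, size=n_sites)
        rs = np.fromiter(self.histogram.keys(), dtype=np.int64)
        ws = np.fromiter(self.histogram.values(), dtype=float)
        return rng.choice(rs, size=n_sites, p=ws / ws.sum())


@dataclass
class ReadCountTable:
    """Observed per-site read counts, the data D of the inference.

    2-state: total reads ``r`` and mutant reads ``m`` per site.
    4-state: mutant reads split by nucleotide type, ``m1, m2, m3``.
    """

    r: np.ndarray
    m: Optional[np.ndarray] = None
    m_types: Optional[np.ndarray] = None  # shape (n_sites, 3)
    site_ids: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=np.int64)
        if (self.m is None) == (self.m_types is None):
            raise ValueError("provide exactly one of m (2-state) or m_types (4-state)")
        if self.m is not None:
            self.m = np.asarray(self.m, dtype=np.int64)
            if self.m.shape != self.r.shape:
                raise ValueError("m and r must have the same length")
            bad = np.nonzero(self.m > self.r)[0]
        else:
            self.m_types = np.asarray(self.m_types, dtype=np.int64)
            if self.m_types.shape != (self.r.size, 3):
                raise ValueError("m_types must have shape (n_sites, 3)")
            bad = np.nonzero(self.m_types.sum(axis=1) > self.r)[0]
        if bad.size:
            raise ValueError(f"mutant reads exceed total reads at rows {bad[:5].tolist()}")

    @property
    def n_sites(self) -> int:
        return self.r.size

    @property
    def is_four_state(self) -> bool:
        return self.m_types is not None

    @property
    def mutant_totals(self) -> np.ndarray:
        """Summed mutant reads per site (collapses 4-state to 2-state)."""
        return self.m if self.m is not None else self.m_types.sum(axis=1)

    def to_two_state(self) -> "ReadCountTable":
        return ReadCountTable(r=self.r.copy(), m=self.mutant_totals.copy(),
                              site_ids=None if self.site_ids is None else self.site_ids.copy())

    def depth_histogram(self) -> dict:
        rs, cs = np.unique(self.r, return_counts=True)
        return dict(zip(rs.tolist(), cs.tolist()))


def assign_mutations(
    tree: LineageTree,
    mu: MutationRate | float,
    n_sites: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Per-site branch assignment: index into the tree's branch arrays, or -1.

    Single uniform draw per site against the cumulative mu*l_k over branches
    in canonical order — equivalent to checking branches for a first hit
    with probability ~mu*l_k each, to first order in mu*l_k.
    """
    if not isinstance(mu, MutationRate):
        mu = MutationRate(float(mu))
    lengths = tree.branch_lengths
    mu.check_tree(float(lengths.sum()))
    edges = np.concatenate([[0.0], np.cumsum(mu.mu * lengths)])
    u = rng.random(n_sites)
    idx = np.searchsorted(edges, u, side="right") - 1
    idx[u >= edges[-1]] = -1
    idx[idx >= lengths.size] = -1
    return idx


def simulate_reads(
    assignments: np.ndarray,
    tree: LineageTree,
    depth: DepthModel,
    eps: SeqErrorRate | float,
    rng: np.random.Generator,
    ploidy: int = 1,
) -> ReadCountTable:
    """Noisy read counts for each site given its mutated branch (or none).

    Reads are drawn without replacement from ``ploidy * n`` alleles of which
    ``round(n * f_k)`` carry the mutation (heterozygous at ploidy 2); each
    read is then independently mis-read to one of the 3 other states with
    probability eps/3.  Returns a 4-state table (type 1 is the true mutant
    type of each site, chosen uniformly among the three).
    """
    if not isinstance(eps, SeqErrorRate):
        eps = SeqErrorRate(float(eps))
    if ploidy not in (1, 2):
        raise ValueError("ploidy must be 1 or 2")
    n = tree.n_leaves
    counts = tree.branch_leaf_counts
    n_sites = assignments.size
    r = depth.sample(n_sites, rng)
    pool = ploidy * n
    if np.any(r > pool):
        raise ValueError(
            f"depth exceeds allele pool: max r = {r.max()} > ploidy*n = {pool}"
        )
    k_mut = np.where(assignments >= 0, counts[np.clip(assignments, 0, None)], 0)
    true_mut = rng.hypergeometric(k_mut, pool - k_mut, r)

    e = eps.eps
    m_types = np.zeros((n_sites, 3), dtype=np.int64)
    wild = r - true_mut
    if e > 0.0:
        # each read keeps its state w.p. 1-eps, else one of the 3 others
        probs = [1.0 - e, e / 3.0, e / 3.0, e / 3.0]
        out_mut = rng.multinomial(true_mut, probs)  # stay, ->wild, ->type2, ->type3
        out_wt = rng.multinomial(wild, probs)  # stay, ->type1, ->type2, ->type3
        m_types[:, 0] = out_mut[:, 0] + out_wt[:, 1]
        m_types[:, 1] = out_mut[:, 2] + out_wt[:, 2]
        m_types[:, 2] = out_mut[:, 3] + out_wt[:, 3]
    else:
        m_types[:, 0] = true_mut
    return ReadCountTable(r=r, m_types=m_types)


def expected_observed_mutations(
    mu: float, ensemble: TreeEnsemble, mean_depth: float
) -> float:
    """Expected observed mutations per site at average depth ``mean_depth``.

    E[ mu * sum_k l_k * (1 - (1 - f_k)^rbar) ] averaged over the ensemble;
    a branch's mutation is observed if at least one of rbar reads samples a
    mutant cell.  Linear in mu.
    """
    acc = 0.0
    for tree in ensemble:
        l = tree.branch_lengths
        f = tree.leaf_fractions
        acc += float(np.sum(l * (1.0 - np.exp(mean_depth * np.log1p(-f)))))
    return mu * acc / len(ensemble)


def choose_mu_for_target(
    target_mutations: float,
    ensemble: TreeEnsemble,
    mean_depth: float,
    n_sites: int = 1,
) -> MutationRate:
    """Invert :func:`expected_observed_mutations` by linearity.

    ``target_mutations`` is the desired expected number of observed mutations
    over ``n_sites`` sites (pass n_sites=1 for a per-site target).
    """
    if target_mutations <= 0:
        raise ValueError("target must be positive")
    per_unit = expected_observed_mutations(1.0, ensemble, mean_depth)
    if per_unit <= 0:
        raise ValueError("degenerate ensemble: zero expected observable length")
    return MutationRate((target_mutations / n_sites) / per_unit)


def vaf_spectrum(
    table: ReadCountTable, bins: np.ndarray, scale: str = "linear"
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of variant allele frequencies m_i / r_i over mutant sites.

    ``bins`` are strictly increasing edges in (0, 1]; with scale="log" the
    edges are interpreted as log10(VAF).  Returns (counts, edges).
    """
    bins = np.asarray(bins, dtype=float)
    if bins.size < 2 or np.any(np.diff(bins) <= 0):
        raise ValueError("bins must be strictly increasing edges")
    m = table.mutant_totals
    mask = m > 0
    vaf = m[mask] / table.r[mask]
    x = np.log10(vaf) if scale == "log" else vaf
    counts, edges = np.histogram(x, bins=bins)
    return counts, edges
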