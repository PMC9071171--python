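"""Read-count likelihood on a fixed lineage tree, and its ensemble average.

For a fixed tree T the sites are independent, so the log-likelihood is a sum
over sites of log p(m_i | mu, T, r_i, eps).  A site's probability mixes over
the branch carrying its (single) mutation:

    p(m | r) = sum_k mu*l_k * Binom(m, r, f_k*(1-eps) + (1-f_k)*eps)
               + (1 - mu*L) * Binom(m, r, eps),

which at eps = 0 reduces to the error-free two-case form (the no-mutation
term then only contributes at m = 0).  The 4-state version replaces the
binomial with a multinomial over (true mutant, two false mutant types, wild
type), averaging 1/3 over which observed type is the true mutant.

Because only a small fraction of trees can ever be sampled, the inference
maximizes the arithmetic mean of per-tree log-likelihoods over a tree
ensemble rather than the log of the averaged likelihood (which is dominated
by single trees); the latter is retained as a diagnostic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.special import gammaln, logsumexp

from .mutsim import ReadCountTable
from .trees import LineageTree, TreeEnsemble

__all__ = [
    "SiteClassTable",
    "site_prob_2state",
    "site_prob_4state",
    "tree_loglik",
    "mean_loglik",
    "ensemble_logavg_lik",
]


@dataclass
class SiteClassTable:
    """Distinct read-count configurations with multiplicities.

    The per-site product over identical (m, r) — or (m1, m2, m3, r) —
    configurations factorizes, so the likelihood cost scales with the number
    of distinct classes, not sites.  Aggregation is lossless.
    """

    counts: np.ndarray  # shape (n_classes, 2) for 2-state, (n_classes, 4) for 4-state
    multiplicity: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        self.multiplicity = np.asarray(self.multiplicity, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape[1] not in (2, 4):
            raise ValueError("counts must be (n_classes, 2) or (n_classes, 4)")
        if self.multiplicity.shape != (self.counts.shape[0],):
            raise ValueError("multiplicity length mismatch")

    @classmethod
    def from_table(cls, table: ReadCountTable, model: str = "auto") -> "SiteClassTable":
        if model == "auto":
            model = "4state" if table.is_four_state else "2state"
        if model == "2state":
            rows = np.column_stack([table.mutant_totals, table.r])
        elif model == "4state":
            if not table.is_four_state:
                raise ValueError("table has no per-type mutant counts")
            rows = np.column_stack([table.m_types, table.r])
        else:
            raise ValueError(f"unknown model: {model}")
        uniq, mult = np.unique(rows, axis=0, return_counts=True)
        return cls(counts=uniq, multiplicity=mult)

    @property
    def n_sites(self) -> int:
        return int(self.multiplicity.sum())

    @property
    def model(self) -> str:
        return "2state" if self.counts.shape[1] == 2 else "4state"


def _log_binom_pmf(m: np.ndarray, r: np.ndarray, p: np.ndarray) -> np.ndarray:
    """log Binom(m, r, p), broadcasting, with exact handling of p in {0, 1}."""
    m = np.asarray(m, dtype=float)
    r = np.asarray(r, dtype=float)
    p = np.asarray(p, dtype=float)
    coef = gammaln(r + 1.0) - gammaln(m + 1.0) - gammaln(r - m + 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = coef + m * np.log(p) + (r - m) * np.log1p(-p)
        out = np.where((p == 0.0) & (m == 0.0), 0.0, out)
        out = np.where((p == 0.0) & (m > 0.0), -np.inf, out)
        out = np.where((p == 1.0) & (m == r), 0.0, out)
        out = np.where((p == 1.0) & (m < r), -np.inf, out)
    return out


def _merged_summary(tree: LineageTree) -> tuple[np.ndarray, np.ndarray, float]:
    """(lengths, fractions) pooled by identical leaf counts, and L."""
    counts = tree.branch_leaf_counts
    lengths = tree.branch_lengths
    pooled = np.bincount(counts, weights=lengths)
    nz = np.nonzero(pooled)[0]
    return pooled[nz], nz / tree.n_leaves, float(lengths.sum())


def _log_site_prob_2state(
    m: np.ndarray,
    r: np.ndarray,
    mu: float,
    lengths: np.ndarray,
    fracs: np.ndarray,
    total_length: float,
    eps: float,
) -> np.ndarray:
    """log p(m | r) for arrays of site classes against one branch summary."""
    muL = mu * total_length
    if muL >= 1.0:
        raise ValueError(f"mu*L = {muL:.3g} >= 1: negative no-mutation probability")
    m = np.asarray(m)[:, None]
    r = np.asarray(r)[:, None]
    p_eff = fracs * (1.0 - eps) + (1.0 - fracs) * eps
    with np.errstate(divide="ignore"):
        log_w = np.log(mu * lengths)
    terms = log_w[None, :] + _log_binom_pmf(m, r, p_eff[None, :])
    # no-mutation term: Binom(m, r, eps); at eps = 0 this is the m = 0 case
    no_mut = _log_binom_pmf(m[:, 0], r[:, 0], eps)
    with np.errstate(divide="ignore"):
        no_mut = no_mut + np.log(1.0 - muL)
    all_terms = np.concatenate([terms, no_mut[:, None]], axis=1)
    return logsumexp(all_terms, axis=1)


def site_prob_2state(m, r, mu, summary, eps=0.0) -> float:
    """Probability of m mutant reads out of r on a tree given as a branch
    summary (sequence of (l_k, f_k) pairs).

    With eps = 0 this is the exact two-case mixture over branches; with
    eps > 0 each branch frequency is error-shifted to f(1-eps) + (1-f)eps
    and a (1 - mu*L) * Binom(m, r, eps) no-mutation term is added.
    """
    summary = np.asarray(summary, dtype=float)
    lengths = summary[:, 0]
    fracs = summary[:, 1]
    L = float(lengths.sum())
    lp = _log_site_prob_2state(
        np.array([m]), np.array([r]), mu, lengths, fracs, L, eps
    )
    return float(np.exp(lp[0]))


def _log_multinomial_pmf(counts: np.ndarray, log_p: np.ndarray) -> np.ndarray:
    """log Mult(counts; r; p) with counts (..., 4) and log_p (..., 4)."""
    r = counts.sum(axis=-1)
    coef = gammaln(r + 1.0) - gammaln(counts + 1.0).sum(axis=-1)
    with np.errstate(invalid="ignore"):
        body = np.where(counts > 0, counts * log_p, 0.0).sum(axis=-1)
    return coef + body


def _log_site_prob_4state(
    m3: np.ndarray,
    r: np.ndarray,
    mu: float,
    lengths: np.ndarray,
    fracs: np.ndarray,
    total_length: float,
    eps: float,
) -> np.ndarray:
    """log p(m1, m2, m3 | r); m3 has shape (n_classes, 3)."""
    muL = mu * total_length
    if muL >= 1.0:
        raise ValueError(f"mu*L = {muL:.3g} >= 1: negative no-mutation probability")
    w = r - m3.sum(axis=1)
    e = eps
    # state probabilities: true mutant, false mutant x2, wild
    p_true = fracs * (1.0 - e) + (1.0 - fracs) * e / 3.0
    p_false = np.full_like(fracs, e / 3.0)
    p_wild = fracs * e / 3.0 + (1.0 - fracs) * (1.0 - e)
    with np.errstate(divide="ignore"):
        lp_true = np.log(p_true)
        lp_false = np.log(p_false)
        lp_wild = np.log(p_wild)
        log_w_br = np.log(mu * lengths)

    # cyclic 1/3 average over which observed type j is the true mutant
    parts = []
    for j in range(3):
        # counts per (class, branch): (m_{j}, m_{j+1}, m_{j+2}, wild)
        c_true = m3[:, j][:, None]
        c_f1 = m3[:, (j + 1) % 3][:, None]
        c_f2 = m3[:, (j + 2) % 3][:, None]
        c_w = w[:, None]
        coef = (
            gammaln(r + 1.0)
            - gammaln(m3 + 1.0).sum(axis=1)
            - gammaln(w + 1.0)
        )[:, None]
        with np.errstate(invalid="ignore"):
            body = (
                np.where(c_true > 0, c_true * lp_true[None, :], 0.0)
                + np.where(c_f1 > 0, c_f1 * lp_false[None, :], 0.0)
                + np.where(c_f2 > 0, c_f2 * lp_false[None, :], 0.0)
                + np.where(c_w > 0, c_w * lp_wild[None, :], 0.0)
            )
        parts.append(coef + body)
    stacked = np.stack(parts, axis=2)  # classes x branches x 3
    log_mix = logsumexp(stacked, axis=2) - np.log(3.0)
    terms = log_w_br[None, :] + log_mix

    # no-mutation term (f = 0): each mutant type is pure error eps/3
    with np.errstate(divide="ignore"):
        lp0 = np.array([np.log(e / 3.0) if e > 0 else -np.inf] * 3 + [np.log1p(-e)])
    counts4 = np.column_stack([m3, w])
    no_mut = _log_multinomial_pmf(counts4, lp0[None, :])
    with np.errstate(divide="ignore"):
        no_mut = no_mut + np.log(1.0 - muL)
    all_terms = np.concatenate([terms, no_mut[:, None]], axis=1)
    return logsumexp(all_terms, axis=1)


def site_prob_4state(m1, m2, m3, r, mu, summary, eps=0.0) -> float:
    """Probability of per-type mutant read counts (m1, m2, m3) out of r.

    Multinomial over (true mutant, two false mutant types, wild type) with a
    cyclic 1/3 average over which observed type carries the real mutation.
    """
    if m1 + m2 + m3 > r:
        raise ValueError("mutant reads exceed total reads")
    summary = np.asarray(summary, dtype=float)
    lengths = summary[:, 0]
    fracs = summary[:, 1]
    L = float(lengths.sum())
    lp = _log_site_prob_4state(
        np.array([[m1, m2, m3]], dtype=np.int64),
        np.array([r], dtype=np.int64),
        mu,
        lengths,
        fracs,
        L,
        eps,
    )
    return float(np.exp(lp[0]))


def _class_logprobs(
    classes: SiteClassTable, mu: float, tree: LineageTree, eps: float
) -> np.ndarray:
    lengths, fracs, L = _merged_summary(tree)
    if classes.model == "2state":
        return _log_site_prob_2state(
            classes.counts[:, 0], classes.counts[:, 1], mu, lengths, fracs, L, eps
        )
    return _log_site_prob_4state(
        classes.counts[:, :3], classes.counts[:, 3], mu, lengths, fracs, L, eps
    )


def tree_loglik(
    table: ReadCountTable | SiteClassTable,
    mu: float,
    tree: LineageTree,
    eps: float = 0.0,
    model: str = "auto",
) -> float:
    """Log-likelihood of the read counts on a fixed tree.

    Returns -inf (with a diagnostic warning naming the offending class) only
    if some observed class has probability exactly zero.
    """
    classes = (
        table
        if isinstance(table, SiteClassTable)
        else SiteClassTable.from_table(table, model)
    )
    lp = _class_logprobs(classes, mu, tree, eps)
    dead = ~np.isfinite(lp)
    if np.any(dead):
        first = classes.counts[np.nonzero(dead)[0][0]]
        warnings.warn(
            f"site class {first.tolist()} has zero probability "
            f"(mu={mu}, eps={eps}); log-likelihood is -inf",
            stacklevel=2,
        )
        return -np.inf
    return float(np.dot(classes.multiplicity, lp))


def mean_loglik(
    table: ReadCountTable | SiteClassTable,
    mu: float,
    ensemble: TreeEnsemble,
    eps: float = 0.0,
    model: str = "auto",
) -> float:
    """Arithmetic mean of per-tree log-likelihoods over the ensemble."""
    classes = (
        table
        if isinstance(table, SiteClassTable)
        else SiteClassTable.from_table(table, model)
    )
    vals = [tree_loglik(classes, mu, t, eps) for t in ensemble]
    return float(np.mean(vals))


def ensemble_logavg_lik(
    table: ReadCountTable | SiteClassTable,
    mu: float,
    ensemble: TreeEnsemble,
    eps: float = 0.0,
    model: str = "auto",
) -> float:
    """log of the tree-averaged likelihood (diagnostic only).

    This Monte-Carlo version of the full sum over trees is typically
    dominated by a single tree, which is why the mean log-likelihood is the
    optimization target instead.
    """
    classes = (
        table
        if isinstance(table, SiteClassTable)
        else SiteClassTable.from_table(table, model)
    )
    vals = np.array([tree_loglik(classes, mu, t, eps) for t in ensemble])
    return float(logsumexp(vals) - np.log(len(ensemble)))
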