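"""Cell lineage trees from a conditioned birth-death process.

The tumor is modelled as a supercritical birth-death process with birth
rate ``b = 1`` (the unit of time, so branch lengths are expected cell
divisions) and death rate ``delta`` (the death-to-birth ratio, 0 <= delta < 1).
A bulk sample of ``n`` extant cells defines the *cell lineage tree*: the
ultrametric bifurcating tree spanned by the sampled cells, rooted at their
most recent common ancestor.

Sampling uses the coalescent point-process construction: under a uniform
(improper) prior on the time of origin, conditional on ``n`` extant tips, the
joint density of the ``n - 1`` bifurcation depths ``h_i`` (measured from the
present) is proportional to

    prod_i f(h_i) * (1 - F(max_i h_i)),

where ``f`` is the density with CDF

    F(s) = (1 - exp(-r s)) / (1 - delta * exp(-r s)),   r = 1 - delta.

This is realized exactly by drawing ``n`` i.i.d. depths from ``F`` and
discarding the largest: the remaining ``n - 1`` depths, laid out left to
right between the ``n`` leaves, define the tree (the root is their maximum).
A forward Gillespie simulation with sojourn-time weighting is provided as an
independent cross-check of this construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "BDParams",
    "LineageTree",
    "TreeEnsemble",
    "DriverSpec",
    "sample_depths",
    "sample_tree",
    "sample_ensemble",
    "branch_summary",
    "sample_tree_forward",
    "forward_sojourn_sample",
    "write_newick",
    "read_newick",
]


@dataclass(frozen=True)
class BDParams:
    """Parameters of the conditioned birth-death process.

    delta: death-to-birth ratio d/b (dimensionless), 0 <= delta < 1 —
        only exponentially growing populations are considered.
    n_leaves: number of sampled extant cells, >= 2.
    """

    delta: float
    n_leaves: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.delta < 1.0):
            raise ValueError(
                f"delta must be in [0, 1) for a growing population, got {self.delta}"
            )
        if self.n_leaves < 2:
            raise ValueError(f"n_leaves must be >= 2, got {self.n_leaves}")


class LineageTree:
    """Ultrametric bifurcating cell lineage tree over ``n`` sampled cells.

    Canonically stored as its coalescent point-process representation: the
    sequence of ``n - 1`` bifurcation depths (time before present, in units
    of expected cell divisions) read off between consecutive leaves in the
    planar embedding.  The most recent common ancestor is the deepest
    bifurcation; there is no stem branch above it, so the tree has exactly
    ``2 n - 2`` branches.
    """

    def __init__(self, depths: Sequence[float]):
        d = np.asarray(depths, dtype=float)
        if d.ndim != 1 or d.size < 1:
            raise ValueError("need at least one bifurcation depth (n >= 2)")
        if np.any(d < 0) or not np.all(np.isfinite(d)):
            raise ValueError("bifurcation depths must be finite and non-negative")
        self.depths = d
        self._summary: Optional[tuple] = None

    @property
    def n_leaves(self) -> int:
        return self.depths.size + 1

    @property
    def height(self) -> float:
        """Root-to-leaf time (depth of the MRCA), in cell divisions."""
        return float(self.depths.max())

    def _compute_branches(self) -> tuple:
        """Branch lengths and subtended-leaf counts for all 2n-2 branches.

        The tree is the max-Cartesian tree of the depth sequence; spans and
        parent depths come from nearest-greater-element scans (O(n)).  Ties
        are broken so the leftmost of an equal-depth run is the ancestor.
        """
        if self._summary is not None:
            return self._summary
        d = self.depths
        m = d.size  # internal nodes
        n = m + 1  # leaves
        INF = np.inf

        # nearest index to the left with depth strictly greater
        left_g = np.full(m, -1, dtype=np.int64)
        stack: list[int] = []
        for i in range(m):
            while stack and d[stack[-1]] <= d[i]:
                stack.pop()
            left_g[i] = stack[-1] if stack else -1
            stack.append(i)
        # nearest index to the right with depth greater or equal
        right_ge = np.full(m, m, dtype=np.int64)
        stack = []
        for i in range(m - 1, -1, -1):
            while stack and d[stack[-1]] < d[i]:
                stack.pop()
            right_ge[i] = stack[-1] if stack else m
            stack.append(i)

        parent_depth = np.minimum(
            np.where(left_g >= 0, d[np.maximum(left_g, 0)], INF),
            np.where(right_ge < m, d[np.minimum(right_ge, m - 1)], INF),
        )
        root = int(np.argmax(parent_depth == INF))
        internal_len = parent_depth - d
        internal_leaves = (right_ge - left_g)  # (b_i - a_i + 2) with a=left_g+1, b=right_ge-1

        keep = np.arange(m) != root
        # pendant branches: leaf j hangs below the shallower adjacent bifurcation
        dd = np.concatenate(([INF], d, [INF]))
        pendant = np.minimum(dd[:-1], dd[1:])

        lengths = np.concatenate([pendant, internal_len[keep]])
        leaf_counts = np.concatenate(
            [np.ones(n, dtype=np.int64), internal_leaves[keep]]
        )
        self._summary = (lengths, leaf_counts)
        return self._summary

    @property
    def branch_lengths(self) -> np.ndarray:
        return self._compute_branches()[0]

    @property
    def branch_leaf_counts(self) -> np.ndarray:
        return self._compute_branches()[1]

    @property
    def leaf_fractions(self) -> np.ndarray:
        return self.branch_leaf_counts / self.n_leaves

    @property
    def total_length(self) -> float:
        return float(self.branch_lengths.sum())


@dataclass
class TreeEnsemble:
    """Independent lineage trees drawn at a common death-to-birth ratio.

    Stands in (Monte Carlo) for the intractable sum over all trees in the
    tree-averaged likelihood.
    """

    delta: float
    trees: list
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.trees:
            raise ValueError("ensemble must contain at least one tree")
        n = self.trees[0].n_leaves
        if any(t.n_leaves != n for t in self.trees):
            raise ValueError("all ensemble trees must share n_leaves")

    def __len__(self) -> int:
        return len(self.trees)

    def __iter__(self):
        return iter(self.trees)

    @property
    def n_leaves(self) -> int:
        return self.trees[0].n_leaves


@dataclass(frozen=True)
class DriverSpec:
    """A positively selected lineage with boosted growth.

    growth_boost: multiplicative increase of the net growth rate 1 - delta
        in the driver lineage (e.g. 1.3 for +30%); the boosted 1 - delta
        must stay <= 1 (death rate cannot go negative).
    origin_fraction: the driver arises on a uniformly chosen extant lineage
        when the population first reaches this fraction of the target n.
    """

    growth_boost: float
    origin_fraction: float = 0.1

    def __post_init__(self) -> None:
        if self.growth_boost < 1.0:
            raise ValueError("growth_boost must be >= 1")
        if not (0.0 < self.origin_fraction <= 1.0):
            raise ValueError("origin_fraction must be in (0, 1]")

    def boosted_delta(self, delta: float) -> float:
        g = self.growth_boost * (1.0 - delta)
        if g > 1.0 + 1e-12:
            raise ValueError(
                f"boosted growth rate {g} exceeds 1 (delta={delta}, "
                f"boost={self.growth_boost})"
            )
        return max(0.0, 1.0 - g)


def sample_depths(delta: float, size: int, rng: np.random.Generator) -> np.ndarray:
    """i.i.d. bifurcation depths with CDF F(s) = (1-e^{-rs})/(1-delta e^{-rs})."""
    u = rng.random(size)
    x = (1.0 - u) / (1.0 - delta * u)  # x = exp(-r s)
    return -np.log(x) / (1.0 - delta)


def sample_tree(params: BDParams, rng: np.random.Generator) -> LineageTree:
    """Draw one lineage tree from the conditioned birth-death point process.

    Draws ``n`` i.i.d. depths from F and discards the largest, which realizes
    the exact conditional law of the n-1 bifurcation depths given n tips
    under a uniform prior on the origin time (see module docstring).
    """
    h = sample_depths(params.delta, params.n_leaves, rng)
    h = np.delete(h, int(np.argmax(h)))
    return LineageTree(h)


def sample_ensemble(
    params: BDParams, count: int, rng: np.random.Generator
) -> TreeEnsemble:
    """``count`` independent draws from :func:`sample_tree`."""
    if count < 1:
        raise ValueError("count must be >= 1")
    trees = [sample_tree(params, rng) for _ in range(count)]
    return TreeEnsemble(delta=params.delta, trees=trees)


def branch_summary(tree: LineageTree, merge: bool = False):
    """Branch lengths l_k and leaf fractions f_k — the likelihood's
    sufficient statistic.

    Returns ``(lengths, fractions, total_length)``.  With ``merge=True``,
    branches subtending the same number of leaves are pooled (lengths
    summed); merged and unmerged summaries yield identical likelihoods
    because the site probability depends on branches only through
    sum_k l_k * pmf(... f_k ...).
    """
    lengths = tree.branch_lengths
    counts = tree.branch_leaf_counts
    n = tree.n_leaves
    if merge:
        pooled = np.bincount(counts, weights=lengths, minlength=n + 1)
        nz = np.nonzero(pooled)[0]
        lengths = pooled[nz]
        counts = nz
    return lengths, counts / n, float(tree.branch_lengths.sum())


# ---------------------------------------------------------------------------
# forward (Gillespie) birth-death simulation — oracle and driver scenarios
# ---------------------------------------------------------------------------


class _Genealogy:
    """Event log of a forward birth-death simulation."""

    __slots__ = ("birth", "tend", "child_a", "child_b", "parent", "is_driver")

    def __init__(self) -> None:
        self.birth = [0.0]
        self.tend = [np.inf]  # division or death time
        self.child_a = [-1]
        self.child_b = [-1]
        self.parent = [-1]
        self.is_driver = [False]

    def divide(self, v: int, t: float, driver: bool) -> tuple[int, int]:
        self.tend[v] = t
        a = len(self.birth)
        for _ in range(2):
            self.birth.append(t)
            self.tend.append(np.inf)
            self.child_a.append(-1)
            self.child_b.append(-1)
            self.parent.append(v)
            self.is_driver.append(driver)
        self.child_a[v], self.child_b[v] = a, a + 1
        return a, a + 1

    def die(self, v: int, t: float) -> None:
        self.tend[v] = t

    def spanned_depths(self, extant: Sequence[int], t_obs: float) -> np.ndarray:
        """Depth sequence of the tree spanned by `extant` cells at t_obs."""
        marked = set(extant)
        for v in list(extant):
            p = self.parent[v]
            while p >= 0 and p not in marked:
                marked.add(p)
                p = self.parent[p]
        extant_set = set(extant)
        depths: list[float] = []
        # iterative in-order traversal; unary chains are suppressed
        stack: list[tuple[int, int]] = [(0, 0)]
        while stack:
            v, state = stack.pop()
            if v in extant_set:
                continue  # leaf: nothing to emit
            a, b = self.child_a[v], self.child_b[v]
            kids = [c for c in (a, b) if c >= 0 and c in marked]
            if len(kids) == 1:
                stack.append((kids[0], 0))
            elif len(kids) == 2:
                if state == 0:
                    stack.append((v, 1))
                    stack.append((kids[0], 0))
                else:
                    depths.append(t_obs - self.tend[v])
                    stack.append((kids[1], 0))
        return np.asarray(depths)


class _Alive:
    """Extant lineages, split by driver status, O(1) removal."""

    def __init__(self) -> None:
        self.wild: list[int] = [0]
        self.drv: list[int] = []

    def remove(self, pool: list[int], idx: int) -> int:
        v = pool[idx]
        pool[idx] = pool[-1]
        pool.pop()
        return v

    @property
    def total(self) -> int:
        return len(self.wild) + len(self.drv)


def _run_forward(
    params: BDParams,
    driver: Optional[DriverSpec],
    rng: np.random.Generator,
    observe: str,
    n_cap: int,
):
    """One forward trajectory.

    Returns (genealogy, snapshot_time, extant_ids, weight) or None if the
    trajectory never yields a valid observation (extinction before reaching
    n in first-passage mode; zero sojourn at n in sojourn mode).
    """
    n = params.n_leaves
    delta_w = params.delta
    delta_d = driver.boosted_delta(params.delta) if driver is not None else delta_w
    trigger = max(2, int(np.ceil(driver.origin_fraction * n))) if driver else None

    gen = _Genealogy()
    alive = _Alive()
    t = 0.0
    intervals: list[tuple[float, float]] = []

    while True:
        nw, nd = len(alive.wild), len(alive.drv)
        pop = nw + nd
        if pop == 0:
            break
        if trigger is not None and pop >= trigger:
            # driver arises on a uniformly chosen extant lineage
            idx = int(rng.integers(pop))
            if idx < nw:
                v = alive.remove(alive.wild, idx)
            else:
                v = alive.remove(alive.drv, idx - nw)
            gen.is_driver[v] = True
            alive.drv.append(v)
            trigger = None
            nw, nd = len(alive.wild), len(alive.drv)
        rate = nw * (1.0 + delta_w) + nd * (1.0 + delta_d)
        dt = rng.exponential(1.0 / rate)
        t_next = t + dt
        if observe == "sojourn" and pop == n:
            intervals.append((t, t_next))
        if observe == "first-passage" and pop == n:
            return gen, t, alive.wild + alive.drv, 1.0
        if observe == "sojourn" and pop >= n_cap:
            break
        t = t_next
        # pick class, lineage, event type
        u = rng.random() * rate
        if u < nw * (1.0 + delta_w):
            pool, dlt, drv = alive.wild, delta_w, False
            idx = int(u / (1.0 + delta_w))
        else:
            pool, dlt, drv = alive.drv, delta_d, True
            idx = int((u - nw * (1.0 + delta_w)) / (1.0 + delta_d))
        idx = min(idx, len(pool) - 1)
        v = alive.remove(pool, idx)
        if rng.random() < 1.0 / (1.0 + dlt):
            a, b = gen.divide(v, t, drv)
            pool.append(a)
            pool.append(b)
        else:
            gen.die(v, t)

    if observe != "sojourn" or not intervals:
        return None
    lens = np.array([b - a for a, b in intervals])
    weight = float(lens.sum())
    j = int(rng.choice(lens.size, p=lens / weight))
    t_obs = intervals[j][0] + rng.random() * lens[j]
    extant = [
        v
        for v in range(len(gen.birth))
        if gen.birth[v] <= t_obs < gen.tend[v]
    ]
    return gen, t_obs, extant, weight


def _default_n_cap(delta: float, n: int) -> int:
    # once the population exceeds n_cap, the chance of ever returning to n
    # is < ~1e-9 (each excess lineage survives forever w.p. 1 - delta)
    if delta <= 0.0:
        return n + 1
    return n + 1 + int(np.ceil(-9.0 * np.log(10.0) / np.log(delta)))


def sample_tree_forward(
    params: BDParams,
    driver: Optional[DriverSpec] = None,
    rng: Optional[np.random.Generator] = None,
    max_attempts: int = 10**6,
) -> LineageTree:
    """Forward birth-death simulation, observed at first passage to n cells.

    Runs a Gillespie simulation with per-lineage birth rate 1 and death rate
    delta (boosted in the driver lineage, if any) until the extant population
    first reaches ``n``; extinct runs are rejected.  Returns the tree spanned
    by the n extant cells.  Note the first-passage stopping rule observes the
    population at the instant of the n-th birth, so the youngest bifurcation
    has depth exactly zero; this differs from the point-process law by about
    one division interval (see :func:`forward_sojourn_sample` for the exact
    match).
    """
    if rng is None:
        rng = np.random.default_rng()
    for _ in range(max_attempts):
        out = _run_forward(params, driver, rng, "first-passage", n_cap=0)
        if out is not None:
            gen, t_obs, extant, _ = out
            return LineageTree(gen.spanned_depths(extant, t_obs))
    raise RuntimeError(
        f"extinction-rejection budget exceeded: no surviving trajectory "
        f"reached n={params.n_leaves} within {max_attempts} attempts "
        f"(delta={params.delta})"
    )


def forward_sojourn_sample(
    params: BDParams,
    rng: Optional[np.random.Generator] = None,
    max_attempts: int = 10**6,
) -> tuple[LineageTree, float]:
    """Forward simulation observed at a uniform random time with n extant cells.

    Matches the point-process conditioning exactly: under an (improper)
    uniform prior on the observation time, a trajectory contributes in
    proportion to the total time it spends with exactly n extant cells.
    Returns ``(tree, weight)`` where ``weight`` is that total sojourn time;
    weighted samples from this function are distributed as
    :func:`sample_tree` draws.  The trajectory is truncated once the
    population exceeds a cap from which return to n has probability < 1e-9.
    """
    if rng is None:
        rng = np.random.default_rng()
    n_cap = _default_n_cap(params.delta, params.n_leaves)
    for _ in range(max_attempts):
        out = _run_forward(params, None, rng, "sojourn", n_cap=n_cap)
        if out is not None:
            gen, t_obs, extant, weight = out
            return LineageTree(gen.spanned_depths(extant, t_obs)), weight
    raise RuntimeError(
        f"extinction-rejection budget exceeded: no trajectory visited "
        f"n={params.n_leaves} within {max_attempts} attempts "
        f"(delta={params.delta})"
    )


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------


def write_newick(tree: LineageTree, sink) -> None:
    """Write the tree in standard Newick (branch lengths in cell divisions)."""
    s = _newick_string(tree.depths, 0, tree.n_leaves - 1, None)
    text = s + ";\n"
    if hasattr(sink, "write"):
        sink.write(text)
    else:
        with open(sink, "w") as fh:
            fh.write(text)


def _newick_string(d: np.ndarray, lo: int, hi: int, top: Optional[float]) -> str:
    """Newick for leaves lo..hi; `top` is the parent bifurcation depth."""
    frames: list[tuple[int, int, Optional[float], int]] = [(lo, hi, top, 0)]
    results: dict[tuple[int, int], str] = {}
    while frames:
        a, b, tp, state = frames.pop()
        if a == b:
            results[(a, b)] = f"c{a}:{tp:.17g}"
            continue
        i = a + int(np.argmax(d[a:b]))
        if state == 0:
            frames.append((a, b, tp, 1))
            frames.append((a, i, float(d[i]), 0))
            frames.append((i + 1, b, float(d[i]), 0))
        else:
            s = f"({results.pop((a, i))},{results.pop((i + 1, b))})"
            if tp is not None:
                s += f":{tp - d[i]:.17g}"
            results[(a, b)] = s
    return results[(lo, hi)]


def read_newick(source) -> LineageTree:
    """Read an ultrametric bifurcating Newick tree as a LineageTree.

    Topology and branch lengths round-trip losslessly; leaf fractions are
    recomputed from the topology.  Non-binary trees and trees whose leaves
    are not contemporaneous (non-ultrametric) are rejected.
    """
    import dendropy

    if hasattr(source, "read"):
        text = source.read()
    else:
        with open(source) as fh:
            text = fh.read()
    try:
        dtree = dendropy.Tree.get(data=text, schema="newick")
    except Exception as exc:  # dendropy raises its own parse errors
        raise ValueError(f"malformed Newick: {exc}") from exc

    # distances from root
    dist = {dtree.seed_node: 0.0}
    order = []
    stack = [dtree.seed_node]
    while stack:
        nd = stack.pop()
        order.append(nd)
        kids = nd.child_nodes()
        if kids and len(kids) != 2:
            raise ValueError(
                f"tree is not strictly bifurcating: a node has {len(kids)} children"
            )
        for ch in kids:
            if ch.edge.length is None:
                raise ValueError("every branch needs a length")
            dist[ch] = dist[nd] + float(ch.edge.length)
            stack.append(ch)
    leaf_d = np.array([dist[nd] for nd in order if not nd.child_nodes()])
    height = leaf_d.max()
    if height > 0 and not np.allclose(leaf_d, height, rtol=1e-6, atol=1e-9 * height):
        raise ValueError("tree is not ultrametric: leaves are at unequal depths")

    # in-order traversal emits internal-node depths between leaves
    depths: list[float] = []
    frames = [(dtree.seed_node, 0)]
    while frames:
        nd, state = frames.pop()
        kids = nd.child_nodes()
        if not kids:
            continue
        if state == 0:
            frames.append((nd, 1))
            frames.append((kids[0], 0))
        else:
            depths.append(height - dist[nd])
            frames.append((kids[1], 0))
    return LineageTree(np.asarray(depths))
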