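# Methods

## Model and assumptions

Tumor growth is a supercritical linear birth–death process: every cell
divides at rate b and dies at rate d, with δ = d/b < 1. Branch lengths are
measured in expected cell divisions, so b ≡ 1 acts purely as the unit of
time; the only shape parameter of the lineage tree is δ. A bulk sample of
n cells defines the ultrametric tree spanned by those cells, rooted at
their most recent common ancestor (no stem branch), with 2n−2 branches.

Mutations are neutral, occur at rate μ per site per division, and each
site is hit at most once — a first-order approximation enforced at
μ·L < 0.1 (error) and flagged from μ·L ≥ 0.01 (warning), L being the total
tree length. A mutation on branch k is carried by the fraction f_k of
sampled cells. Reads sample cells with replacement in the likelihood
(binomial at f_k), and sequencing errors flip each read independently to
one of the three other nucleotide states with probability ε/3 each. Sites
are independent.

The per-site probability of m mutant reads among r is the branch mixture

p(m|r) = Σ_k μ l_k Binom(m, r, f_k(1−ε) + (1−f_k)ε) + (1−μL) Binom(m, r, ε),

whose ε = 0 limit is the exact two-case (mutated / not mutated) form. The
4-state version uses a multinomial over (true mutant, two false mutant
types, wild type) with state probabilities

- true mutant: f(1−ε) + (1−f)ε/3
- each false mutant: ε/3
- wild type: fε/3 + (1−f)(1−ε)

and a uniform 1/3 average over which observed mutant type is the true one;
the no-mutation term is the same expression at f = 0. Both forms sum
exactly to one over all read-count outcomes (tested exhaustively for small
r), and both are invariant under rescaling time (lengths ×c, μ/c).

## Tree sampling

Conditioned on n sampled cells, with an improper uniform prior on the time
of origin, the joint density of the n−1 bifurcation depths h_i (time before
present) is

∝ Π_i f(h_i) · (1 − F(max_i h_i)),   F(s) = (1−e^{−rs})/(1−δ e^{−rs}),  r = 1−δ,

where f = F′. The implementation realizes this *exactly* by drawing n
i.i.d. depths from F (analytic inverse CDF) and discarding the largest;
the root is the maximum of the rest. Two closed-form checks anchor the
construction: for a pure-birth process the n = 2 root age is Exp(2) and the
n = 3 expected height is 5/6, both reproduced analytically from the density
above and numerically by the sampler. Tree topology and branch summaries
come from the max-Cartesian tree of the depth sequence (O(n) monotone-stack
scans); ties resolve to the leftmost of an equal-depth run.

An independent forward Gillespie simulation guards the construction. Its
exact observation rule weights each trajectory by the total time it spends
with exactly n extant cells and snapshots a uniformly chosen instant of
that time (`forward_sojourn_sample`; trajectories are truncated once the
population exceeds a level from which return to n has probability < 10⁻⁹).
Weighted two-sample KS tests on total length and height at
δ ∈ {0, 0.5, 0.9} × n ∈ {10, 100} confirm agreement. The simpler
first-passage rule (`sample_tree_forward`: stop at the instant the
population reaches n) is *not* exactly equivalent — it forces the youngest
bifurcation to depth zero and shortens the expected total length by about
one division interval (pure birth: n−2 versus n−1) — but is retained as
the semantics for driver-lineage simulations, where a boosted net growth
rate (1−δ multiplied by a configurable factor ≥ 1) is introduced on a
uniformly chosen lineage once the population reaches a configurable
fraction (default 10%) of the target n.

## Synthetic read counts

The generator mirrors the inference model except in one deliberate respect:
mutant reads are drawn *hypergeometrically* from the finite pool of
ploidy·n sampled alleles, round(n·f_k) of which are mutant (all mutations
heterozygous at ploidy 2). The binomial likelihood is the infinite-pool
limit of this; the discrepancy is O(r/n) and measurable — at r/n = 0.1 the
plug-in mutation-rate estimator is biased high by roughly 4% because
detection probabilities of singleton branches differ between the two laws.
Unbiasedness checks therefore run in the sparse-read regime (r/n = 0.02),
where the mismatch is far below sampling scatter. Sequencing errors corrupt
each read independently via a multinomial with probabilities
(1−ε, ε/3, ε/3, ε/3). Depth models: fixed (default, matching the simulated
spectra at depth 1000), shifted Poisson (always ≥ 1), or an empirical
(depth, site-count) histogram to mimic a real coverage distribution.
Contamination, copy-number variation, mutational signatures and
context-dependent error are not simulated; the inference assumes counts
pre-corrected for ploidy and CNV, so validation on these data says nothing
about the robustness of that preprocessing.

The expected number of observed mutations per site at mean depth r̄ is
μ·E[Σ_k l_k (1 − (1−f_k)^r̄)]; being linear in μ it is inverted to choose μ
for a target mutation count (`choose_mu_for_target`; the target may be
genome-wide via `n_sites`). The average depth enters this formula directly
rather than through the full depth distribution, matching its use as an
isoline label.

## Mutation-rate plug-in

Given (δ, ε), μ is estimated without optimization. A mutant read count is
significant at depth r if m ≥ m_th(r, ε), the smallest m with
Binom(m, r, ε) < 1/n_sites and m > εr, where Binom is read as the
probability mass at exactly m (an upper-tail reading, arguably closer to
the motivation "fewer than one error-only site dataset-wide", is available
via `rule="tail"`; it gives thresholds at least as large). If no m ≤ r
qualifies the threshold is r+1 and that depth contributes nothing. The
expected significant tree length is

L_sig(T, ε) = Σ_{r,k} (n_r/n_sites) · l_k · P(Binom(r, f_k) ≥ m_th(r, ε)),

with the depth histogram n_r always taken from the data table, and

μ_est = E[ M_sig / (n_sites · L_sig(T, ε)) ] over the ensemble,

M_sig being the number of significant sites (4-state tables are summed over
mutant types before thresholding). Trees with L_sig = 0 are excluded with a
warning; if all are excluded the estimate is an error, never a silent zero.

## Fitting procedure

The δ grid is uniform in x = log₁₀(1−δ) (the natural coordinate: regimes of
interest span 1−δ from 1 down to 10⁻⁶), default 9 points. Per grid point a
fresh ensemble (default 100 trees, seeded by spawned child seeds of the
master seed) is drawn, μ is plugged in, and ε is either fixed or maximized
by bounded Brent search in log₁₀ ε over [10⁻⁹, 10⁻²] (covering studied
error rates 10⁻⁸–10⁻³), with explicit endpoint checks because a bounded
scalar search can miss an edge optimum; a grid-of-ε mode cross-validates
Brent. ε is optimized independently per grid point. The mean log-likelihood
is interpolated by a natural cubic spline in x and maximized on a dense
(4001-point) grid; a boundary maximum, or fewer than 4 finite profile
points, falls back to the best grid point with a warning, and exact ties
break toward smaller δ (the weaker cell-death assumption). Non-finite
profile points are flagged and excluded from the spline, never dropped
silently. Final μ̂ and ε̂ are recomputed on a fresh ensemble at δ̂.

On error-free data the ε profile typically shows a weak interior optimum a
few decades above the lower bound rather than exactly at it: a vanishing
but positive ε slightly compensates the mismatch between the finite fitting
ensemble and the single generating tree. The effect is immaterial (the
optimum sits orders of magnitude below real sequencing error rates) but
worth knowing when reading fitted ε values near the bound.

Numerical choices throughout: all pmfs are evaluated in log space (gammaln
forms with exact handling of p ∈ {0, 1}) and mixed by logsumexp; branches
with identical leaf counts are merged (summing lengths) before likelihood
evaluation, which is exact because the site probability depends on branches
only through Σ l_k·pmf(f_k); sites with identical read-count configurations
are collapsed to multiplicity classes, also exact. A site class with
probability exactly zero makes the tree log-likelihood −∞ and is named in a
diagnostic warning.

## Problem sizes and validation scope

Desk-scale defaults — 10³-leaf trees, 100 trees per grid point, 10⁵ sites —
were chosen so a full profile fit runs in seconds and the whole validation
suite in a couple of minutes, while still exhibiting the behaviors of
interest: recovery of 1−δ to within a grid decade and μ to within a factor
of two at 1−δ = 0.1, and ε recovery at 10⁻⁴ under deep coverage. Accuracy
improves with both tree size and ensemble size; near-critical δ
(1−δ ≲ 10⁻³) genuinely requires larger trees to resolve. The mean height of
10⁴-leaf trees at 1−δ = 1.1×10⁻³ computes to ≈1930–1950 divisions across
large ensembles (per-tree sd ≈ 700); note that a two-significant-digit
growth rate moves this mean by ±5%.

The full-scale recipe (`paper_scale_config()`) fits a deep-sequenced
empirical table — 10⁶-site scale, mean depth ~900 — with 10⁴ trees of 10⁴
leaves per grid point, 4-state likelihood, ε optimized. It reproduces
estimates of the kind ε = 10⁻⁷, δ = 1 − 1.1×10⁻³, μ ≈ 9×10⁻⁸ per site per
division, but needs the external read-count table (not distributed here)
and orders of magnitude more compute than the desk scale; it ships as a
configuration plus this recipe, not as a test.

## Physiological chain

From measured inputs — tumor diameter, cell length, volume doubling time,
sampled cell count — plus the fitted growth rate: total cell count is the
*cube* of the diameter-to-cell-length ratio (stacking cells along each
axis, not a sphere volume); the naive tree height is log₂(n_cells)/(1−δ),
an overestimate for near-critical trees whose shape differs from a
stretched pure-birth tree; the division rate is (simulated mean tree
height)/(log₂(n_cells)·doubling time); lifetime is log₂(n_cells) doublings
(a year is 365 days; reported raw and rounded to the nearest year); and
under uniform sampling from a well-mixed tumor the birth rate transforms as
b = b′/ρ with sampling ratio ρ. Units are explicit in argument names
(mm, μm, days) and converted internally; non-positive inputs are rejected.

## Known limitations

Constant δ and μ over the whole history (a driver lineage is simulable, but
the inference model remains neutral and homogeneous — fits to driver data
show a small systematic upward shift in both μ̂ and δ̂); well-mixed growth
and uniform sampling (no spatial structure); at most one mutation and one
error per site; no contamination or purity modelling; error rates near
10⁻³ leave δ̂ with large variance, so standard short-read data without
error suppression is a poor fit for the method.
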