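# vaftree

Tumors often carry orders of magnitude more mutations than healthy tissue.
Two very different mechanisms produce the same mutation count: an elevated
per-division mutation rate, or frequent cell death with correspondingly
rapid cell turnover. Bulk sequencing mixes the reads of all sampled cells,
so the cell lineage tree that would separate the two is not observable.

`vaftree` disentangles them anyway. It jointly estimates, from a single
bulk sample's per-site read counts,

- the per-site, per-cell-division mutation rate **μ**,
- the death-to-birth ratio **δ = d/b** of the growing tumor (0 ≤ δ < 1),
- the per-read sequencing error rate **ε**,

by treating the unknown cell lineage tree as a nuisance parameter: the
read-count log-likelihood is averaged over lineage trees sampled from a
birth–death process conditioned on the number of sequenced cells. The key
signal is that δ reshapes the tree (and hence the variant allele frequency
spectrum), while μ only rescales it. It is aimed at cancer genomicists with
deep-coverage, low-error bulk data (the error model matters: at Illumina-like
ε ≈ 10⁻³ the δ estimate degrades badly).

## Model

A tumor of `n` sequenced cells descends through a birth–death process with
birth rate b = 1 (the time unit; branch lengths are expected cell
divisions) and death rate δ. The lineage tree T spanned by the sampled
cells is ultrametric with 2n−2 branches; branch k has length l_k and
subtends a fraction f_k of the sample, L = Σ_k l_k. Each site mutates at
most once (valid while μ·L ≪ 1), landing on branch k with probability
μ·l_k. Observing m mutant reads among r at a site:

```
p(m | r) = Σ_k μ l_k · Binom(m, r, f_k(1−ε) + (1−f_k)ε)
           + (1 − μL) · Binom(m, r, ε)
```

with a 4-state multinomial variant that distinguishes the three mutant
nucleotide types. The fitted score is the *mean* of log L(D | μ, T) over a
Monte-Carlo ensemble T(δ) (the averaged likelihood itself is dominated by
single trees). μ is not profiled: it is plugged in directly from the number
of sites whose mutant read counts are too high to be sequencing error,
divided by the expected detectable tree length. δ is profiled on a grid
uniform in log₁₀(1−δ), with ε optimized by bounded Brent search per grid
point, and the maximizer located by a cubic spline.

Trees are sampled exactly via the coalescent point process: draw n i.i.d.
bifurcation depths with CDF F(s) = (1−e^{−rs})/(1−δe^{−rs}), r = 1−δ, and
discard the largest; a forward Gillespie simulation with sojourn-time
weighting cross-checks this construction in the test suite.

## Worked example

Simulate a tumor with 10% net growth per division (δ = 0.9), 1000 sampled
cells, 10⁵ sites at depth 100, error-free, with μ chosen so that about 2000
mutations are visible — then fit it back:

```python
import numpy as np, vaftree as vt

rng = np.random.default_rng(1)
params = vt.BDParams(delta=0.9, n_leaves=1000)
ref = vt.sample_ensemble(params, 20, rng)
mu_true = vt.choose_mu_for_target(2000, ref, mean_depth=100, n_sites=10**5)

tree = vt.sample_tree(params, rng)
assignments = vt.assign_mutations(tree, mu_true, 10**5, rng)
table = vt.simulate_reads(assignments, tree, vt.DepthModel("fixed", 100),
                          eps=0.0, rng=rng).to_two_state()

config = vt.FitConfig(n_leaves=1000, trees_per_point=100,
                      delta_grid=vt.default_delta_grid(-4, 0, 9),
                      eps=0.0, seed=0)
result = vt.fit(table, config)
print(f"delta_hat = {result.delta_hat:.4f}")
print(f"mu_hat    = {result.mu_hat:.3g}  (true {mu_true.mu:.3g})")
```

Output:

```
delta_hat = 0.9161
mu_hat    = 1.68e-05  (true 2.1e-05)
```

The fitted death-to-birth ratio 0.916 recovers the true 0.9 (equivalently,
1−δ̂ = 0.084 vs 0.1: correct to well within a grid decade), and μ̂ is within
25% of truth — typical desk-scale accuracy; precision grows with ensemble
and tree size. The same run is available from the shell:

```sh
vaftree simulate-reads --delta 0.9 --n-leaves 1000 --mu 2.1e-5 \
    --n-sites 100000 --depth 100 --seed 1 --out-tsv reads.tsv
vaftree fit --reads reads.tsv --delta-grid -4:0:9 --eps fixed:0 \
    --trees-per-point 100 --n-leaves 1000 --seed 0 --out-json fit.json
```

Other subcommands: `simulate-tree` (Newick ensembles), `physiology`
(tumor-scale arithmetic from a fitted growth rate), `fixtures` (named
reproducible scenario bundles).

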