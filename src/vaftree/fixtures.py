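"""Named, reproducible synthetic scenarios used by the tests and docs.

Each scenario writes a small bundle (read-count TSVs, Newick trees, a JSON
manifest with the generating parameters) at desk scale.  All randomness
derives from the single seed, so regenerated bundles are bit-identical.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from . import __version__
from .mutsim import DepthModel, assign_mutations, choose_mu_for_target, simulate_reads
from .trees import BDParams, DriverSpec, sample_ensemble, sample_tree, sample_tree_forward, write_newick
from .io import write_counts_tsv

__all__ = ["SCENARIOS", "fixture_generator"]


def _recovery(seed: int, out: Path) -> dict:
    """Parameter-recovery bundle: three growth regimes, shared target
    mutation count, error-free reads at depth 100."""
    rng = np.random.default_rng(seed)
    n_leaves, n_sites, depth, target = 200, 20000, 100, 500
    entries = []
    for growth in (1.0, 0.1, 0.01):
        delta = 1.0 - growth
        params = BDParams(delta, n_leaves)
        ref = sample_ensemble(params, 20, rng)
        mu = choose_mu_for_target(target, ref, depth, n_sites=n_sites)
        tree = sample_tree(params, rng)
        asn = assign_mutations(tree, mu, n_sites, rng)
        table = simulate_reads(asn, tree, DepthModel("fixed", depth), 0.0, rng)
        name = f"recovery_growth{growth:g}"
        write_counts_tsv(table.to_two_state(), out / f"{name}.tsv")
        with open(out / f"{name}.nwk", "w") as fh:
            write_newick(tree, fh)
        entries.append(
            {"file": f"{name}.tsv", "delta": delta, "mu": mu.mu, "eps": 0.0,
             "n_leaves": n_leaves, "n_sites": n_sites, "depth": depth}
        )
    return {"datasets": entries}


def _error_sweep(seed: int, out: Path) -> dict:
    """One dataset re-corrupted at several sequencing error rates."""
    rng = np.random.default_rng(seed)
    n_leaves, n_sites, depth, target = 2000, 20000, 1000, 500
    delta = 0.5
    params = BDParams(delta, n_leaves)
    ref = sample_ensemble(params, 20, rng)
    mu = choose_mu_for_target(target, ref, depth, n_sites=n_sites)
    tree = sample_tree(params, rng)
    asn = assign_mutations(tree, mu, n_sites, rng)
    entries = []
    for eps in (0.0, 1e-5, 1e-4, 1e-3):
        table = simulate_reads(asn, tree, DepthModel("fixed", depth), eps, rng)
        name = f"errors_eps{eps:g}"
        write_counts_tsv(table, out / f"{name}.tsv")
        entries.append(
            {"file": f"{name}.tsv", "delta": delta, "mu": mu.mu, "eps": eps,
             "n_leaves": n_leaves, "n_sites": n_sites, "depth": depth}
        )
    return {"datasets": entries}


def _driver(seed: int, out: Path) -> dict:
    """Forward-simulated trees with a growth-boosting driver lineage."""
    rng = np.random.default_rng(seed)
    n_leaves, n_sites, depth = 100, 10000, 100
    delta = 0.5
    spec = DriverSpec(growth_boost=1.3)
    entries = []
    for i, drv in enumerate((None, spec)):
        tree = sample_tree_forward(BDParams(delta, n_leaves), driver=drv, rng=rng)
        mu = 2e-3 / max(tree.total_length, 1.0)
        asn = assign_mutations(tree, mu, n_sites, rng)
        table = simulate_reads(asn, tree, DepthModel("fixed", depth), 0.0, rng)
        name = "driver_off" if drv is None else "driver_on"
        write_counts_tsv(table.to_two_state(), out / f"{name}.tsv")
        with open(out / f"{name}.nwk", "w") as fh:
            write_newick(tree, fh)
        entries.append(
            {"file": f"{name}.tsv", "delta": delta, "mu": mu,
             "growth_boost": None if drv is None else drv.growth_boost,
             "n_leaves": n_leaves, "n_sites": n_sites, "depth": depth}
        )
    return {"datasets": entries}


def _physiology(seed: int, out: Path) -> dict:
    """Worked physiological example: measured inputs of the HCC analysis."""
    inputs = {
        "diameter_mm": 35.0,
        "cell_length_um": 25.0,
        "doubling_time_days": 86.0,
        "n_sampled_cells": 10**4,
        "growth_rate": 1.1e-3,
        "tree_height_divisions": 2023.0,
    }
    with open(out / "physiology_inputs.json", "w") as fh:
        json.dump(inputs, fh, indent=2)
    return {"datasets": [{"file": "physiology_inputs.json", **inputs}]}


SCENARIOS = {
    "recovery": _recovery,
    "error-sweep": _error_sweep,
    "driver": _driver,
    "physiology": _physiology,
}


def fixture_generator(scenario: str, seed: int, out_dir) -> dict:
    """Generate the named scenario bundle under ``out_dir``.

    Returns the manifest (also written as ``manifest.json``).
    """
    if scenario not in SCENARIOS:
        raise ValueError(
            f"unknown scenario {scenario!r}; choose from {sorted(SCENARIOS)}"
        )
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "scenario": scenario,
        "seed": int(seed),
        "version": __version__,
    }
    manifest.update(SCENARIOS[scenario](seed, out))
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
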