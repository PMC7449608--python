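#!/usr/bin/env python
"""Phylogenetic signal in taxon niches: Mantel correlograms.

Three niche constructions on a common footing: the Brownian trait itself
(maximal conserved signal), abundance-weighted niche values computed from
a trait-matched divergent scenario whose replicate reactors hold
different environmental optima (the realistic pipeline path), and an
i.i.d.-noise control.  Each is tested with the 50-bin Mantel correlogram
(1,000 permutations, 5% FDR).
"""

from pathlib import Path

import numpy as np
import pandas as pd

from ecoassembly.data import read_tree_distances, tree_distances_from_string
from ecoassembly.phylo import mantel_correlogram, niche_values
from ecoassembly.simulate import ScenarioConfig, simulate_scenario

ROOT = Path("results/scenarios")


def main() -> None:
    dist = read_tree_distances(ROOT / "convergent" / "tree.nwk")
    trait = pd.read_csv(ROOT / "convergent" / "trait.tsv", sep="\t", index_col=0)["trait"]

    frames = []
    niche_trait = pd.DataFrame({"trait": trait.reindex(dist.tips).to_numpy()}, index=dist.tips)
    cg_trait = mantel_correlogram(niche_trait, dist, n_bins=50, n_perm=1000, fdr=0.05, seed=601)
    cg_trait.insert(0, "niche", "brownian_trait")
    frames.append(cg_trait)

    # realistic path: replicate reactors hold different optima along the
    # trait axis; taxon niches are abundance-weighted means of the
    # environment over the samples where each taxon occurs
    b = simulate_scenario(
        ScenarioConfig(seed=605, S=200, depth=2000, n_days=5, filter_mode="divergent",
                       filter_strength=1.0, use_tree=True)
    )
    d2 = tree_distances_from_string(b["newick"])
    niche_env = niche_values(b["table"], b["environment"])
    cg_env = mantel_correlogram(niche_env, d2, n_bins=50, n_perm=1000, fdr=0.05, seed=602)
    cg_env.insert(0, "niche", "abundance_weighted_env")
    frames.append(cg_env)

    noise = pd.DataFrame(
        {"noise": np.random.default_rng(603).normal(size=len(dist.tips))}, index=dist.tips
    )
    cg_noise = mantel_correlogram(noise, dist, n_bins=50, n_perm=1000, fdr=0.05, seed=604)
    cg_noise.insert(0, "niche", "iid_noise")
    frames.append(cg_noise)

    out = pd.concat(frames, ignore_index=True)
    Path("results").mkdir(exist_ok=True)
    out.to_csv("results/mantel_correlogram.tsv", sep="\t", index=False)

    for name, cg in (
        ("brownian_trait", cg_trait),
        ("abundance_weighted_env", cg_env),
        ("iid_noise", cg_noise),
    ):
        sig = cg[(cg["significant"]) & (cg["r"] > 0)]
        n_valid = int(cg["valid"].sum())
        if len(sig):
            print(
                f"{name}: {len(sig)}/{n_valid} significant positive bins, "
                f"first at bin {int(sig['bin'].min())} "
                f"(signal starts at {sig['dist_low'].min():.2f} branch-length units)"
            )
        else:
            print(f"{name}: 0/{n_valid} significant positive bins")


if __name__ == "__main__":
    main()
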