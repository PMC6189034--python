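"""Clade definitions, the four clade metrics, and the permutation bias test.

Clades are the lineages crossing a 33.9 Myr time slice (singletons
dropped).  For each clade: crown age, richness, subsampled clade niche
size in the resampled space, multivariate niche evolution rate (trace
of the contrast-based BM rate matrix of the selected traits), and the
clade competition index (mean within-clade rescaled Schoener x
geographic overlap).  A tip-shuffle permutation test checks that the
competition index carries no clade-size bias.

Run after 03:  python analysis/04_clade_metrics.py [--seed 1]
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from nichediv import clade_metrics as cm
from nichediv.trees import TimeTree

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "results" / "data"
OUT = ROOT / "results"

SLICE_AGE = 33.9  # Myr


def main(seed: int) -> None:
    tree = TimeTree.read_newick(DATA / "tree.nwk")
    traits = pd.read_csv(DATA / "traits_raw.csv", index_col=0)
    occ = pd.read_csv(DATA / "occurrences.csv")
    species = json.load(open(DATA / "surface_species.json"))
    surfaces = dict(zip(species, np.load(DATA / "surfaces_geographic.npy")))
    occupancy = dict(zip(species, np.load(DATA / "occupancy_resampled.npy")))

    partition = cm.clades_by_time_slice(tree, slice_age=SLICE_AGE)
    sizes = partition.sizes()
    print(
        f"time slice at {SLICE_AGE} Myr: {len(sizes)} clades "
        f"(sizes {sorted(sizes.values())}), {len(partition.dropped_tips)} "
        "singletons dropped"
    )

    occsets = {s: occ[occ["species"] == s] for s in species}
    overlaps = cm.OverlapMatrices.build(surfaces, occsets)
    overlaps.schoener.to_csv(OUT / "schoener_rescaled.tsv", sep="\t")
    overlaps.schoener_raw.to_csv(OUT / "schoener_raw.tsv", sep="\t")
    overlaps.geographic.to_csv(OUT / "geographic_overlap.tsv", sep="\t")

    m = min(sizes.values())
    metrics = cm.clade_metrics_table(
        tree, partition, traits, occupancy, overlaps,
        m=m, reps=2000, mode="multivariate", seed=seed,
    )
    metrics.to_csv(OUT / "clade_metrics.tsv", sep="\t", index=False)
    print(metrics.to_string(index=False, float_format=lambda x: f"{x:.3f}"))

    bias = cm.permutation_bias_test(
        overlaps, list(sizes.values()), reps=2000, seed=seed
    )
    print(
        f"permutation bias test: slope {bias['slope']:.2e} "
        f"(p = {bias['p_value']:.3f}); global mean pairwise competition "
        f"{bias['global_mean']:.3f}"
    )
    pd.DataFrame(
        {
            "clade_size": bias["clade_sizes"],
            "null_mean": bias["null_mean"],
            "null_se": bias["null_se"],
        }
    ).to_csv(OUT / "competition_null.tsv", sep="\t", index=False)

    with open(DATA / "clades.json", "w") as fh:
        json.dump(partition.clades, fh)


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    main(ap.parse_args().seed)
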