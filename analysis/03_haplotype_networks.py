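#!/usr/bin/env python
"""Haplotype networks per species: edge lists, membership, shape summaries.

Collapses each species' sequences to haplotypes, builds the
minimum-spanning network (with equal-weight alternative links), and
summarises shape: number of haplotypes, haplotype diversity, maximum
within-bird haplotype sharing, and the star score (fraction of non-hub
haplotypes attached directly to the modal haplotype). Star-like networks
(score near 1) flag recent expansions or founder events. Writes TSVs and
a panel figure under results/networks/.
"""

import argparse
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from infrapopgen import (
    build_network,
    build_species_datasets,
    collapse_haplotypes,
    network_summary,
    read_alignment,
    read_loads,
    read_metadata,
)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--fixture", type=Path, default=Path("results/fixture"))
    ap.add_argument("--out", type=Path, default=Path("results/networks"))
    ap.add_argument("--no-plot", action="store_true")
    args = ap.parse_args()

    alignment = read_alignment(args.fixture / "alignment.fasta")
    metadata = read_metadata(args.fixture / "metadata.tsv")
    loads = read_loads(args.fixture / "loads.tsv")
    datasets = build_species_datasets(alignment, metadata, loads)
    args.out.mkdir(parents=True, exist_ok=True)

    summaries, edge_rows, member_rows = [], [], []
    networks = []
    for d in datasets:
        table = collapse_haplotypes(d.alignment, d.metadata)
        net = build_network(table)
        s = network_summary(net, table)
        networks.append((d.species, net, table))
        summaries.append({
            "species": d.species, "n": d.n,
            "n_haplotypes": s.n_haplotypes,
            "haplotype_diversity": s.haplotype_diversity,
            "max_within_bird_sharing": s.max_within_bird_sharing,
            "star_score": s.star_score, "n_alt_edges": s.n_alt_edges,
        })
        for i, j, w in net.tree_edges:
            edge_rows.append({"species": d.species, "h1": i, "h2": j,
                              "distance": w, "kind": "tree"})
        for i, j, w in net.alt_edges:
            edge_rows.append({"species": d.species, "h1": i, "h2": j,
                              "distance": w, "kind": "alternative"})
        for h, members in enumerate(table.membership):
            for sid in members:
                member_rows.append({"species": d.species, "haplotype": h,
                                    "sample_id": sid})

    summary = pd.DataFrame(summaries)
    summary.to_csv(args.out / "network_summary.tsv", sep="\t", index=False,
                   float_format="%.4g")
    pd.DataFrame(edge_rows).to_csv(args.out / "edges.tsv", sep="\t", index=False)
    pd.DataFrame(member_rows).to_csv(args.out / "membership.tsv", sep="\t",
                                     index=False)
    print(summary.to_string(index=False, float_format=lambda x: f"{x:.3g}"))
    star = summary.sort_values("star_score", ascending=False).head(3)
    print("\nmost star-like species:", ", ".join(star["species"]))

    if not args.no_plot:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        from infrapopgen.network import plot_network

        ncol = 6
        nrow = -(-len(networks) // ncol)
        fig, axes = plt.subplots(nrow, ncol, figsize=(3 * ncol, 3 * nrow))
        for ax in axes.flat:
            ax.axis("off")
        for ax, (species, net, table) in zip(axes.flat, networks):
            plot_network(net, table, ax=ax)
            ax.set_title(species, fontsize=9)
        fig.savefig(args.out / "networks.png", dpi=120, bbox_inches="tight")
        print(f"figure: {args.out / 'networks.png'}")


if __name__ == "__main__":
    main()
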