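"""Haplotype collapsing and minimum-spanning haplotype networks.

Distinct sequences are collapsed to haplotypes (positions where either
sequence carries a non-ACGT symbol are ignored in the identity
comparison, first-occurrence tie-break), then connected by a minimum
spanning tree on pairwise Hamming distances. Non-tree pairs whose
distance equals the bottleneck (the maximum edge weight on the tree path
between them) are reported as alternative equal-weight links — the
reticulations one sees in published haplotype networks.

``star_score`` — the fraction of non-hub haplotypes whose tree edge
attaches directly to the modal (hub) haplotype — is this package's own
diagnostic for quantifying the qualitative "star-like vs reticulated"
contrast; it never feeds any regression.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .io import Alignment, SampleMetadata


@dataclass
class HaplotypeTable:
    """Distinct haplotypes with frequencies, membership and per-bird composition."""

    haplotypes: list[str]  # representative sequence per haplotype
    freq: list[int]
    membership: list[list[str]]  # haplotype index -> sample ids
    bird_composition: list[dict[str, int]]  # haplotype index -> bird_id -> count

    @property
    def n_haplotypes(self) -> int:
        return len(self.haplotypes)

    @property
    def n_samples(self) -> int:
        return sum(self.freq)

    def haplotype_diversity(self) -> float:
        """Unbiased gene (haplotype) diversity H = n/(n−1) (1 − Σ p_i²)."""
        n = self.n_samples
        if n < 2:
            return 0.0
        p = np.asarray(self.freq, dtype=float) / n
        return float(n / (n - 1) * (1.0 - np.sum(p**2)))


def _codes(seq: str) -> np.ndarray:
    from .io import _encode

    return _encode(seq)


def _hamming(a: np.ndarray, b: np.ndarray) -> int:
    both = (a != 255) & (b != 255)
    return int(((a != b) & both).sum())


def collapse_haplotypes(
    alignment: Alignment, metadata: list[SampleMetadata] | None = None
) -> HaplotypeTable:
    """Group sequences that are identical over their shared unambiguous sites.

    Sequences are scanned in input order; each joins the first existing
    haplotype it matches (Hamming distance 0 under pairwise deletion), so
    numbering is deterministic by first occurrence.
    """
    bird_of = {}
    if metadata is not None:
        bird_of = {m.sample_id: m.bird_id for m in metadata}
    reps: list[np.ndarray] = []
    haplotypes: list[str] = []
    freq: list[int] = []
    membership: list[list[str]] = []
    composition: list[dict[str, int]] = []
    for sid, seq in zip(alignment.ids, alignment.seqs):
        c = _codes(seq)
        for h, rep in enumerate(reps):
            if _hamming(c, rep) == 0:
                freq[h] += 1
                membership[h].append(sid)
                if sid in bird_of:
                    comp = composition[h]
                    comp[bird_of[sid]] = comp.get(bird_of[sid], 0) + 1
                break
        else:
            reps.append(c)
            haplotypes.append(seq)
            freq.append(1)
            membership.append([sid])
            composition.append({bird_of[sid]: 1} if sid in bird_of else {})
    return HaplotypeTable(haplotypes, freq, membership, composition)


@dataclass
class HaploNetwork:
    """Minimum-spanning haplotype network with alternative equal-weight links."""

    n_nodes: int
    freq: list[int]
    tree_edges: list[tuple[int, int, int]]  # (i, j, hamming distance)
    alt_edges: list[tuple[int, int, int]]
    hub: int  # modal haplotype index


def _pairwise_hamming(table: HaplotypeTable) -> np.ndarray:
    H = table.n_haplotypes
    codes = [_codes(s) for s in table.haplotypes]
    d = np.zeros((H, H), dtype=np.int64)
    for i in range(H):
        for j in range(i + 1, H):
            d[i, j] = d[j, i] = _hamming(codes[i], codes[j])
    return d


def build_network(table: HaplotypeTable) -> HaploNetwork:
    """Deterministic Kruskal MST on haplotype Hamming distances.

    Edges are sorted by (weight, smaller index, larger index) so ties are
    stable. Every non-tree pair whose distance equals the maximum edge
    weight on its tree path is recorded as an alternative link.
    """
    H = table.n_haplotypes
    hub = int(np.argmax(table.freq))  # first-occurrence tie-break via argmax
    if H == 1:
        return HaploNetwork(1, list(table.freq), [], [], hub)
    dist = _pairwise_hamming(table)
    edges = sorted(
        (int(dist[i, j]), i, j) for i in range(H) for j in range(i + 1, H)
    )
    parent = list(range(H))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    tree: list[tuple[int, int, int]] = []
    G = nx.Graph()
    G.add_nodes_from(range(H))
    for w, i, j in edges:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
            tree.append((i, j, w))
            G.add_edge(i, j, weight=w)
            if len(tree) == H - 1:
                break

    # bottleneck (max edge on tree path) for every pair, via BFS from each node
    alt: list[tuple[int, int, int]] = []
    in_tree = {(i, j) for i, j, _ in tree} | {(j, i) for i, j, _ in tree}
    for i in range(H):
        bottleneck = {i: 0}
        stack = [i]
        while stack:
            u = stack.pop()
            for v in G.neighbors(u):
                if v not in bottleneck:
                    bottleneck[v] = max(bottleneck[u], G[u][v]["weight"])
                    stack.append(v)
        for j in range(i + 1, H):
            if (i, j) not in in_tree and dist[i, j] == bottleneck[j]:
                alt.append((i, j, int(dist[i, j])))
    return HaploNetwork(H, list(table.freq), tree, alt, hub)


@dataclass
class NetworkSummary:
    n_haplotypes: int
    haplotype_diversity: float
    max_within_bird_sharing: int
    star_score: float  # NaN for a single-haplotype network
    n_alt_edges: int


def network_summary(network: HaploNetwork, table: HaplotypeTable) -> NetworkSummary:
    """Shape and sharing diagnostics for one haplotype network.

    ``max_within_bird_sharing`` is the maximum number of mites from one
    bird carrying the same haplotype — the within-host kin-structure
    signature of vertical transmission.
    """
    max_share = 0
    for comp in table.bird_composition:
        if comp:
            max_share = max(max_share, max(comp.values()))
    if network.n_nodes < 2:
        star = float("nan")
    else:
        attached = sum(
            1 for i, j, _ in network.tree_edges if i == network.hub or j == network.hub
        )
        star = attached / (network.n_nodes - 1)
    return NetworkSummary(
        n_haplotypes=network.n_nodes,
        haplotype_diversity=table.haplotype_diversity(),
        max_within_bird_sharing=max_share,
        star_score=star,
        n_alt_edges=len(network.alt_edges),
    )


def plot_network(
    network: HaploNetwork, table: HaplotypeTable, ax=None, seed: int = 0
):
    """Draw the network: node size ∝ frequency, pies partitioned by bird."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 6))
    G = nx.Graph()
    G.add_nodes_from(range(network.n_nodes))
    for i, j, w in network.tree_edges:
        G.add_edge(i, j, weight=w)
    pos = nx.spring_layout(G, seed=seed)
    for i, j, _ in network.alt_edges:
        ax.plot(*zip(pos[i], pos[j]), ls=":", c="grey", lw=0.8, zorder=0)
    for i, j, _ in network.tree_edges:
        ax.plot(*zip(pos[i], pos[j]), c="black", lw=1.2, zorder=1)
    cmap = plt.get_cmap("tab20")
    birds = sorted({b for comp in table.bird_composition for b in comp})
    color = {b: cmap(k % 20) for k, b in enumerate(birds)}
    for h in range(network.n_nodes):
        x, y = pos[h]
        r = 0.03 * np.sqrt(network.freq[h])
        comp = table.bird_composition[h] or {"": network.freq[h]}
        total = sum(comp.values())
        theta = 0.0
        for b, cnt in sorted(comp.items()):
            frac = cnt / total
            wedge = plt.matplotlib.patches.Wedge(
                (x, y), r, 360 * theta, 360 * (theta + frac),
                fc=color.get(b, "lightgrey"), ec="black", lw=0.3, zorder=2,
            )
            ax.add_patch(wedge)
            theta += frac
    ax.set_aspect("equal")
    ax.axis("off")
    return ax
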