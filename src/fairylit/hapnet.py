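"""Haplotype collapsing and minimum-spanning haplotype networks.

Identical aligned sequences collapse to one haplotype node whose size is
the number of carrying specimens.  Edges weigh the integer number of base
differences between haplotypes (sites with a gap or ambiguity in either
sequence are skipped).  The strict minimum spanning tree uses Kruskal with
a deterministic tie order; the `msn_with_ties` variant additionally keeps
every non-tree edge whose weight equals the largest weight on the tree
path between its endpoints, showing alternative equally short connections.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import pandas as pd

from .core_io import Alignment, Partition
from .distmat import _encode

__all__ = ["HaplotypeSet", "HaplotypeNetwork", "collapse", "msn", "base_differences"]


@dataclass(frozen=True)
class HaplotypeSet:
    """Unique sequences with their carrying specimens."""

    haplotypes: tuple[tuple[str, str, tuple[str, ...]], ...]  # (id, sequence, members)

    def __post_init__(self) -> None:
        seen: set = set()
        for _, _, members in self.haplotypes:
            if seen & set(members):
                raise ValueError("specimen in more than one haplotype")
            seen |= set(members)

    @property
    def counts(self) -> dict[str, int]:
        return {hid: len(members) for hid, _, members in self.haplotypes}

    @property
    def n_specimens(self) -> int:
        return sum(self.counts.values())

    def __len__(self) -> int:
        return len(self.haplotypes)

    def sequence(self, hid: str) -> str:
        for h, seq, _ in self.haplotypes:
            if h == hid:
                return seq
        raise KeyError(hid)

    def haplotype_map(self) -> dict[str, str]:
        """specimen_id -> haplotype_id."""
        out = {}
        for hid, _, members in self.haplotypes:
            for m in members:
                out[m] = hid
        return out


@dataclass(frozen=True)
class HaplotypeNetwork:
    nodes: tuple[str, ...]
    counts: dict
    cluster_of: dict  # haplotype_id -> cluster colour key ("" if no partition)
    edges: tuple[tuple[str, str, int], ...]
    kind: str  # strict_mst | msn_with_ties

    def total_weight(self) -> int:
        return sum(w for _, _, w in self.edges)

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        for n in self.nodes:
            g.add_node(n, count=self.counts[n], cluster=self.cluster_of.get(n, ""))
        for a, b, w in self.edges:
            g.add_edge(a, b, weight=w)
        return g

    def write_graphml(self, path) -> None:
        nx.write_graphml(self.to_graph(), str(path))

    def write_dot(self, path) -> None:
        lines = ["graph hapnet {"]
        for n in self.nodes:
            lines.append(
                f'  "{n}" [label="{n} ({self.counts[n]})", cluster="{self.cluster_of.get(n, "")}"];'
            )
        for a, b, w in self.edges:
            lines.append(f'  "{a}" -- "{b}" [label="{w}"];')
        lines.append("}")
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")

    def node_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "haplotype_id": list(self.nodes),
                "count": [self.counts[n] for n in self.nodes],
                "cluster": [self.cluster_of.get(n, "") for n in self.nodes],
            }
        )


def collapse(aln: Alignment) -> HaplotypeSet:
    """Group identical (uppercased) aligned sequences; gaps are significant.

    Haplotype ids are assigned by descending abundance, ties broken by the
    sequence string, so they do not depend on input order.
    """
    groups: dict[str, list[str]] = {}
    for sid, row in zip(aln.ids, aln.rows):
        groups.setdefault(row, []).append(sid)
    ordered = sorted(groups.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    width = max(3, len(str(len(ordered))))
    return HaplotypeSet(
        haplotypes=tuple(
            (f"H{i+1:0{width}d}", seq, tuple(sorted(members)))
            for i, (seq, members) in enumerate(ordered)
        )
    )


def base_differences(a: str, b: str) -> int:
    """Number of differing sites where both sequences hold A/C/G/T."""
    if len(a) != len(b):
        raise ValueError("sequences differ in length")
    ea = _encode((a.upper(),))[0]
    eb = _encode((b.upper(),))[0]
    comp = (ea >= 0) & (eb >= 0)
    return int(((ea != eb) & comp).sum())


def msn(
    hs: HaplotypeSet, part: Partition | None = None, kind: str = "strict_mst"
) -> HaplotypeNetwork:
    """Minimum spanning haplotype network.

    Kruskal over all haplotype pairs sorted by (weight, haplotype-id pair)
    yields the deterministic strict MST; ``msn_with_ties`` then adds every
    non-tree edge whose weight equals the maximum weight on the tree path
    between its endpoints.
    """
    if kind not in ("strict_mst", "msn_with_ties"):
        raise ValueError(f"unknown network kind {kind!r}")
    ids = [hid for hid, _, _ in hs.haplotypes]
    seqs = {hid: seq for hid, seq, _ in hs.haplotypes}
    cluster_of: dict[str, str] = {}
    if part is not None:
        assignment = part.assignment()
        for hid, _, members in hs.haplotypes:
            clusters = sorted({assignment[m] for m in members if m in assignment})
            cluster_of[hid] = clusters[0] if len(clusters) == 1 else "|".join(clusters)
    else:
        cluster_of = {hid: "" for hid in ids}

    all_edges = []
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            pair = tuple(sorted((a, b)))
            all_edges.append((base_differences(seqs[a], seqs[b]), pair[0], pair[1]))
    all_edges.sort()

    # Kruskal with union-find
    uf = nx.utils.UnionFind(ids)
    tree = []
    for w, a, b in all_edges:
        if uf[a] != uf[b]:
            uf.union(a, b)
            tree.append((a, b, w))
    edges = list(tree)

    if kind == "msn_with_ties" and len(ids) > 1:
        g = nx.Graph()
        g.add_weighted_edges_from(tree)
        in_tree = {(a, b) for a, b, _ in tree}
        for w, a, b in all_edges:
            if (a, b) in in_tree:
                continue
            path = nx.shortest_path(g, a, b)
            path_max = max(
                g[u][v]["weight"] for u, v in zip(path, path[1:])
            )
            if w == path_max:
                edges.append((a, b, w))
        edges.sort(key=lambda e: (e[2], e[0], e[1]))

    return HaplotypeNetwork(
        nodes=tuple(ids),
        counts=hs.counts,
        cluster_of=cluster_of,
        edges=tuple(edges),
        kind=kind,
    )
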