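"""Monopartite TE sequence-similarity networks (SSNs).

Nodes are individual TE copies; an edge's weight is the best local-alignment
bitscore between the two copies. Clusters are found either by Louvain
modularity maximisation or by connected components, and the two partitions
are compared with the Rand index. Flag-based analyses (catalytic-domain
presence, cryptic protein-derived hits) operate on boolean node attributes.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

from .model import AlignmentHit, TECopy
from .stats import TestResult, fisher_exact_2x2, wilcoxon_rank_sum

__all__ = [
    "Partition",
    "build_ssn",
    "flag_nodes",
    "louvain_partition",
    "component_partition",
    "rand_index",
    "connectivity_by_flag",
    "cluster_composition",
    "cryptic_hit_enrichment",
    "cluster_persistence",
]


@dataclass(frozen=True)
class Partition:
    """Assignment of every network node to exactly one cluster."""

    mapping: Mapping[str, int]
    method: str
    modularity: float | None = None

    def clusters(self) -> dict[int, set[str]]:
        out: dict[int, set[str]] = {}
        for node, cid in self.mapping.items():
            out.setdefault(cid, set()).add(node)
        return out

    @property
    def n_clusters(self) -> int:
        return len(set(self.mapping.values()))

    def __len__(self) -> int:
        return len(self.mapping)


def build_ssn(hits: Iterable[AlignmentHit], copies: Iterable[TECopy],
              min_copy_length: int = 0,
              max_evalue: float | None = None) -> nx.Graph:
    """Build the sequence-similarity network from pairwise alignment hits.

    Copies shorter than ``min_copy_length`` are excluded; hits with e-value
    above ``max_evalue`` are dropped. Multiple hits for one unordered pair
    (including the two alignment directions) collapse to the maximum
    bitscore. Copies without any surviving hit remain as degree-0 nodes.
    The human L1 preset of the method corresponds to
    ``min_copy_length=500, max_evalue=1e-30``.
    """
    copies = list(copies)
    kept = {c.copy_id: c for c in copies if c.length_bp >= min_copy_length}
    all_ids = {c.copy_id for c in copies}

    net = nx.Graph()
    for c in kept.values():
        net.add_node(c.copy_id, genome_id=c.genome_id, family=c.family,
                     superfamily=c.superfamily, length_bp=c.length_bp,
                     has_dde3=False, cryptic_hit=False)

    unknown: set[str] = set()
    for hit in hits:
        for cid in (hit.query_id, hit.subject_id):
            if cid not in all_ids:
                unknown.add(cid)
        if unknown:
            continue
        if hit.query_id == hit.subject_id:
            continue
        if max_evalue is not None and hit.evalue > max_evalue:
            continue
        a, b = hit.query_id, hit.subject_id
        if a not in kept or b not in kept:
            continue  # endpoint removed by the length filter
        if net.has_edge(a, b):
            if hit.bitscore > net[a][b]["weight"]:
                net[a][b]["weight"] = hit.bitscore
        else:
            net.add_edge(a, b, weight=hit.bitscore)
    if unknown:
        raise ValueError(
            "hits reference unknown copy ids: " + ", ".join(sorted(unknown)))
    return net


def flag_nodes(net: nx.Graph, flag: str, true_ids: Iterable[str]) -> None:
    """Set boolean node attribute ``flag`` True for ``true_ids``, False elsewhere."""
    true_ids = set(true_ids)
    for node in net.nodes:
        net.nodes[node][flag] = node in true_ids


def louvain_partition(net: nx.Graph, resolution: float = 1.0,
                      seed: int = 0) -> Partition:
    """Louvain community detection on edge weights at the given resolution.

    Deterministic for a fixed seed; the weighted modularity of the returned
    partition is reported alongside it.
    """
    if net.number_of_nodes() == 0:
        return Partition(mapping={}, method="louvain", modularity=None)
    communities = nx.community.louvain_communities(
        net, weight="weight", resolution=resolution, seed=seed)
    communities = sorted((sorted(c) for c in communities), key=lambda c: c[0])
    mapping = {node: cid for cid, members in enumerate(communities)
               for node in members}
    mod = nx.community.modularity(net, [set(c) for c in communities],
                                  weight="weight", resolution=resolution) \
        if net.number_of_edges() else 0.0
    return Partition(mapping=mapping, method="louvain", modularity=mod)


def component_partition(net: nx.Graph) -> Partition:
    """Clusters = connected components (depth-first search)."""
    components = sorted((sorted(c) for c in nx.connected_components(net)),
                        key=lambda c: c[0])
    mapping = {node: cid for cid, members in enumerate(components)
               for node in members}
    return Partition(mapping=mapping, method="connected_components")


def rand_index(p1: Partition, p2: Partition) -> float:
    """Fraction of node pairs on which two partitions agree.

    A pair agrees when it is co-clustered in both partitions or separated in
    both. Computed from the contingency table of cluster co-occurrences.
    """
    nodes1, nodes2 = set(p1.mapping), set(p2.mapping)
    if nodes1 != nodes2:
        raise ValueError("partitions cover different node sets")
    n = len(nodes1)
    if n < 2:
        return 1.0
    contingency: dict[tuple[int, int], int] = {}
    counts1: dict[int, int] = {}
    counts2: dict[int, int] = {}
    for node in nodes1:
        c1, c2 = p1.mapping[node], p2.mapping[node]
        contingency[(c1, c2)] = contingency.get((c1, c2), 0) + 1
        counts1[c1] = counts1.get(c1, 0) + 1
        counts2[c2] = counts2.get(c2, 0) + 1
    def comb2(k: int) -> int:
        return k * (k - 1) // 2
    total = comb2(n)
    same_both = sum(comb2(v) for v in contingency.values())
    same1 = sum(comb2(v) for v in counts1.values())
    same2 = sum(comb2(v) for v in counts2.values())
    # pairs split in both = total - same1 - same2 + same_both
    agree = same_both + (total - same1 - same2 + same_both)
    return agree / total


def connectivity_by_flag(net: nx.Graph, flag: str,
                         weighted: bool = False) -> tuple[np.ndarray, np.ndarray, TestResult]:
    """Compare node connectivity between flagged and unflagged nodes.

    Connectivity is the unweighted degree by default (``weighted=True`` sums
    incident edge weights instead). Returns both samples and a two-sided
    Wilcoxon rank-sum result.
    """
    degree = net.degree(weight="weight" if weighted else None)
    flagged, unflagged = [], []
    for node, deg in degree:
        (flagged if net.nodes[node][flag] else unflagged).append(deg)
    if not flagged or not unflagged:
        raise ValueError(f"flag {flag!r}: one group is empty")
    flagged = np.asarray(flagged, dtype=float)
    unflagged = np.asarray(unflagged, dtype=float)
    return flagged, unflagged, wilcoxon_rank_sum(flagged, unflagged)


def cluster_composition(net: nx.Graph, partition: Partition,
                        subfamily_attr: str = "family"):
    """Per-cluster composition table, sorted by cluster size (descending).

    A cluster is "mixed" when its members span two or more subfamilies —
    the signature used to hunt for convergent sequence capture.
    """
    import pandas as pd

    rows = []
    for cid, members in partition.clusters().items():
        subfams: dict[str, int] = {}
        genomes: set[str] = set()
        for node in members:
            sf = net.nodes[node][subfamily_attr]
            subfams[sf] = subfams.get(sf, 0) + 1
            genomes.add(net.nodes[node]["genome_id"])
        rows.append({
            "cluster_id": cid,
            "n_nodes": len(members),
            "n_subfamilies": len(subfams),
            "subfamilies": ";".join(f"{k}:{v}" for k, v in sorted(subfams.items())),
            "n_genomes": len(genomes),
            "mixed": len(subfams) >= 2,
        })
    df = pd.DataFrame(rows, columns=["cluster_id", "n_nodes", "n_subfamilies",
                                     "subfamilies", "n_genomes", "mixed"])
    return df.sort_values(["n_nodes", "cluster_id"],
                          ascending=[False, True]).reset_index(drop=True)


def cryptic_hit_enrichment(net: nx.Graph, partition: Partition, cluster_id: int,
                           hit_flag: str = "cryptic_hit") -> dict:
    """Enrichment of a boolean hit flag inside one cluster vs the rest.

    Returns the in-cluster and out-of-cluster hit proportions and a
    two-sided Fisher exact test on the 2x2 table.
    """
    clusters = partition.clusters()
    if cluster_id not in clusters:
        raise ValueError(f"cluster {cluster_id!r} not present in partition")
    members = clusters[cluster_id]
    in_hit = sum(1 for n in members if net.nodes[n][hit_flag])
    in_tot = len(members)
    outside = [n for n in partition.mapping if n not in members]
    out_hit = sum(1 for n in outside if net.nodes[n][hit_flag])
    out_tot = len(outside)
    table = [[in_hit, in_tot - in_hit], [out_hit, out_tot - out_hit]]
    result = fisher_exact_2x2(table)
    return {
        "in_cluster_hits": in_hit,
        "in_cluster_total": in_tot,
        "in_cluster_proportion": in_hit / in_tot,
        "out_cluster_hits": out_hit,
        "out_cluster_total": out_tot,
        "out_cluster_proportion": out_hit / out_tot if out_tot else float("nan"),
        "test": result,
    }


def cluster_persistence(partition_before: Partition, partition_after: Partition,
                        cluster_id: int, threshold: float = 0.5) -> dict:
    """Does a named cluster survive a perturb-and-rebuild of the network?

    The cluster is matched to its best-overlapping cluster in the rebuilt
    partition by Jaccard similarity; it "persists" when that overlap reaches
    ``threshold``.
    """
    before = partition_before.clusters()
    if cluster_id not in before:
        raise ValueError(f"cluster {cluster_id!r} not present in baseline partition")
    target = before[cluster_id]
    best_jaccard, best_cid = 0.0, None
    for cid, members in partition_after.clusters().items():
        inter = len(target & members)
        if inter == 0:
            continue
        jac = inter / len(target | members)
        if jac > best_jaccard:
            best_jaccard, best_cid = jac, cid
    return {"jaccard": best_jaccard, "best_match_cluster": best_cid,
            "persists": best_jaccard >= threshold}
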