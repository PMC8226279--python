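"""Bipartite genome-TE content networks and their perturbation analyses.

One side of the network is genomes, the other TE families (consensus/library
names); an edge's weight is a per-genome abundance metric for that family.
Four metrics are supported: copy count, total coverage in base pairs
("TE length", the default of the method), coverage as a percentage of the
genome, and coverage as a percentage of all TE content in the genome.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .model import SpeciesAnnotation, TECopy
from .ssn import Partition, component_partition, louvain_partition, rand_index
from .stats import TestResult, wilcoxon_rank_sum

__all__ = [
    "METRICS",
    "PerturbationProfile",
    "build_content_network",
    "genome_statistics",
    "group_comparison",
    "metric_concordance",
    "family_knockout",
    "random_subset_knockout",
    "family_summary",
]

METRICS = ("count", "total_bp", "pct_genome", "pct_of_te")


@dataclass(frozen=True)
class PerturbationProfile:
    """Network statistics before and after removing a set of TE nodes."""

    target: str
    removed_nodes: tuple[str, ...]
    before: Mapping[str, float]
    after: Mapping[str, float]
    genome_rand_vs_baseline: float

    @property
    def delta(self) -> dict[str, float]:
        return {k: self.after[k] - self.before[k] for k in self.before}


def build_content_network(copies: Iterable[TECopy],
                          annotations: Iterable[SpeciesAnnotation],
                          metric: str = "total_bp") -> nx.Graph:
    """Build the bipartite genome-TE network under the chosen weight metric.

    Genome nodes carry their species annotation; TE-family nodes carry the
    superfamily classification. A family with no copies in a genome has no
    edge to it. Node membership is identical across metrics; only weights
    differ.
    """
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")
    copies = list(copies)
    ann_by_id = {a.genome_id: a for a in annotations}

    count: dict[tuple[str, str], int] = {}
    total_bp: dict[tuple[str, str], int] = {}
    fam_super: dict[str, str] = {}
    genome_te_bp: dict[str, int] = {}
    for c in copies:
        key = (c.genome_id, c.family)
        count[key] = count.get(key, 0) + 1
        total_bp[key] = total_bp.get(key, 0) + c.length_bp
        fam_super.setdefault(c.family, c.superfamily)
        genome_te_bp[c.genome_id] = genome_te_bp.get(c.genome_id, 0) + c.length_bp

    genomes = sorted({c.genome_id for c in copies} | set(ann_by_id))
    families = sorted(fam_super)
    clash = set(genomes) & set(families)
    if clash:
        raise ValueError(f"genome and family identifiers collide: {sorted(clash)}")

    if metric == "pct_genome":
        missing = [g for g in genomes
                   if g not in ann_by_id or ann_by_id[g].genome_size_bp is None]
        if missing:
            raise ValueError(
                "pct_genome metric requires genome_size_bp for: " + ", ".join(missing))

    net = nx.Graph(metric=metric)
    for g in genomes:
        ann = ann_by_id.get(g)
        net.add_node(g, type="genome", bipartite=0,
                     clade_label=ann.clade_label if ann else "",
                     has_dnmt=ann.has_dnmt if ann else False,
                     has_piwi=ann.has_piwi if ann else False)
    for f in families:
        net.add_node(f, type="te", bipartite=1, superfamily=fam_super[f])

    for (g, f), bp in total_bp.items():
        if metric == "count":
            w = float(count[(g, f)])
        elif metric == "total_bp":
            w = float(bp)
        elif metric == "pct_genome":
            w = 100.0 * bp / ann_by_id[g].genome_size_bp
        else:  # pct_of_te
            w = 100.0 * bp / genome_te_bp[g]
        net.add_edge(g, f, weight=w)
    return net


def _te_nodes(net: nx.Graph) -> list[str]:
    return [n for n, d in net.nodes(data=True) if d["type"] == "te"]


def _genome_nodes(net: nx.Graph) -> list[str]:
    return [n for n, d in net.nodes(data=True) if d["type"] == "genome"]


def genome_statistics(net: nx.Graph) -> pd.DataFrame:
    """Per-genome degree, weighted degree, and singleton count.

    A singleton is a TE-family node connected to exactly one genome node;
    it counts toward that genome alone.
    """
    rows = []
    for g in _genome_nodes(net):
        n_singletons = sum(1 for f in net.neighbors(g) if net.degree(f) == 1)
        rows.append({
            "genome_id": g,
            "degree": net.degree(g),
            "weighted_degree": float(net.degree(g, weight="weight")),
            "n_singletons": n_singletons,
        })
    return pd.DataFrame(rows, columns=["genome_id", "degree", "weighted_degree",
                                       "n_singletons"]).set_index("genome_id")


def group_comparison(stat_table: pd.DataFrame,
                     annotations: Iterable[SpeciesAnnotation],
                     grouping: str, statistic: str) -> tuple[dict, TestResult]:
    """Wilcoxon rank-sum comparison of a per-genome statistic between the
    with/without groups of a silencing mechanism (``has_dnmt``/``has_piwi``)."""
    if grouping not in {"has_dnmt", "has_piwi"}:
        raise ValueError(f"grouping must be has_dnmt or has_piwi, got {grouping!r}")
    ann_by_id = {a.genome_id: a for a in annotations}
    missing = [g for g in stat_table.index if g not in ann_by_id]
    if missing:
        raise ValueError("genomes without annotation: " + ", ".join(missing))
    with_group = [stat_table.loc[g, statistic] for g in stat_table.index
                  if getattr(ann_by_id[g], grouping)]
    without_group = [stat_table.loc[g, statistic] for g in stat_table.index
                     if not getattr(ann_by_id[g], grouping)]
    if len(with_group) < 2 or len(without_group) < 2:
        raise ValueError(
            f"{grouping}: need >= 2 genomes per group, got "
            f"{len(with_group)} vs {len(without_group)}")
    samples = {"with": np.asarray(with_group, dtype=float),
               "without": np.asarray(without_group, dtype=float)}
    return samples, wilcoxon_rank_sum(samples["with"], samples["without"])


def _genome_partition(net: nx.Graph, method: str, resolution: float,
                      seed: int) -> Partition:
    if method == "louvain":
        part = louvain_partition(net, resolution=resolution, seed=seed)
    elif method == "components":
        part = component_partition(net)
    else:
        raise ValueError(f"unknown clustering method {method!r}")
    genome_nodes = set(_genome_nodes(net))
    return Partition(mapping={n: c for n, c in part.mapping.items()
                              if n in genome_nodes},
                     method=part.method, modularity=part.modularity)


def metric_concordance(copies: Iterable[TECopy],
                       annotations: Iterable[SpeciesAnnotation],
                       metric_a: str, metric_b: str, seed: int = 0,
                       method: str = "louvain",
                       resolution: float = 1.0) -> float:
    """Rand index between the genome partitions induced by two weight metrics."""
    copies = list(copies)
    annotations = list(annotations)
    net_a = build_content_network(copies, annotations, metric_a)
    net_b = build_content_network(copies, annotations, metric_b)
    assert set(net_a.nodes) == set(net_b.nodes), \
        "metrics must not change node membership"
    part_a = _genome_partition(net_a, method, resolution, seed)
    part_b = _genome_partition(net_b, method, resolution, seed)
    return rand_index(part_a, part_b)


def _network_stats(net: nx.Graph, resolution: float, seed: int) -> tuple[dict, Partition]:
    part = louvain_partition(net, resolution=resolution, seed=seed)
    stats = {
        "n_nodes": float(net.number_of_nodes()),
        "n_edges": float(net.number_of_edges()),
        "n_clusters": float(part.n_clusters),
        "modularity": float(part.modularity) if part.modularity is not None else 0.0,
        "n_components": float(nx.number_connected_components(net))
        if net.number_of_nodes() else 0.0,
    }
    genome_nodes = set(_genome_nodes(net))
    genome_part = Partition(mapping={n: c for n, c in part.mapping.items()
                                     if n in genome_nodes}, method=part.method)
    return stats, genome_part


def _knockout_targets(net: nx.Graph, target: str) -> list[str]:
    hits = [n for n in _te_nodes(net)
            if n == target or net.nodes[n].get("superfamily") == target]
    if not hits:
        raise ValueError(f"no TE node matches family or superfamily {target!r}")
    return hits


def family_knockout(net: nx.Graph, family_or_superfamily: str,
                    cluster_seed: int = 0,
                    resolution: float = 1.0) -> PerturbationProfile:
    """Remove every TE node of a family (or superfamily) and recompute the
    key network statistics with identical clustering parameters."""
    targets = _knockout_targets(net, family_or_superfamily)
    return _profile_removal(net, family_or_superfamily, targets,
                            cluster_seed, resolution)


def _profile_removal(net: nx.Graph, label: str, targets: Sequence[str],
                     seed: int, resolution: float) -> PerturbationProfile:
    before, genome_part_before = _network_stats(net, resolution, seed)
    reduced = net.copy()
    reduced.remove_nodes_from(targets)
    after, genome_part_after = _network_stats(reduced, resolution, seed)
    ri = rand_index(genome_part_before, genome_part_after) \
        if len(genome_part_before.mapping) == len(genome_part_after.mapping) \
        and set(genome_part_before.mapping) == set(genome_part_after.mapping) \
        else float("nan")
    return PerturbationProfile(target=label, removed_nodes=tuple(sorted(targets)),
                               before=before, after=after,
                               genome_rand_vs_baseline=ri)


def random_subset_knockout(net: nx.Graph, family_or_superfamily: str,
                           fraction: float = 0.10, reps: int = 20,
                           seed: int = 0,
                           resolution: float = 1.0) -> list[PerturbationProfile]:
    """Repeatedly remove a random fraction of one family's TE nodes.

    Each replicate removes ``floor(fraction * n)`` nodes drawn without
    replacement, profiling the perturbation as in :func:`family_knockout`.
    """
    if not (0.0 < fraction < 1.0):
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    targets = _knockout_targets(net, family_or_superfamily)
    k = math.floor(fraction * len(targets))
    if k < 1:
        raise ValueError(
            f"{family_or_superfamily}: {len(targets)} nodes is too few for "
            f"fraction {fraction}")
    rng = np.random.default_rng(seed)
    profiles = []
    for _ in range(reps):
        subset = list(rng.choice(targets, size=k, replace=False))
        profiles.append(_profile_removal(net, family_or_superfamily, subset,
                                         seed, resolution))
    return profiles


def family_summary(copies: Iterable[TECopy]) -> pd.DataFrame:
    """Per-family copy count, total bp, and number of genomes of occurrence,
    sorted by copy count (descending)."""
    rows: dict[str, dict] = {}
    for c in copies:
        entry = rows.setdefault(c.family, {"family": c.family,
                                           "superfamily": c.superfamily,
                                           "n_copies": 0, "total_bp": 0,
                                           "genomes": set()})
        entry["n_copies"] += 1
        entry["total_bp"] += c.length_bp
        entry["genomes"].add(c.genome_id)
    records = [{"family": e["family"], "superfamily": e["superfamily"],
                "n_copies": e["n_copies"], "total_bp": e["total_bp"],
                "n_genomes": len(e["genomes"])} for e in rows.values()]
    df = pd.DataFrame(records, columns=["family", "superfamily", "n_copies",
                                        "total_bp", "n_genomes"])
    return df.sort_values(["n_copies", "family"],
                          ascending=[False, True]).reset_index(drop=True)
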