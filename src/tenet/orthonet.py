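"""Phylogeny-aware "orthonetwork": the bipartite content network augmented
with genome-genome edges weighted by shared-orthogroup counts.

Closely related genomes share many orthogroups and are pulled into common
clusters, so collapsing the Louvain clusters to group nodes counts each
clade of related species once. This controls phylogenetic pseudoreplication
when comparing TE statistics between silencing regimes.

Edge weights are normalised onto a common (0, 1] scale:

* genome-TE: ``LengthAdj = log(total TE bp of family in genome) /
  log(max such total)`` — a log-compressed abundance;
* genome-genome: shared orthogroups divided by the maximum over retained
  pairs, where pairs below the sparsity threshold ``tau`` (default 4,500
  orthogroups) get no edge at all.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

from .model import OrthoTable, SpeciesAnnotation, TECopy
from .ssn import louvain_partition
from .stats import TestResult, wilcoxon_rank_sum

__all__ = ["GroupNode", "build_orthonet", "collapse_to_groups",
           "group_comparison", "group_table"]

DEFAULT_ORTHOGROUP_THRESHOLD = 4500


@dataclass(frozen=True)
class GroupNode:
    """One collapsed cluster of related genomes with group-level TE statistics."""

    cluster_id: int
    genome_ids: tuple[str, ...]
    clade_label: str
    clade_agreement: float
    has_dnmt: bool
    dnmt_agreement: float
    has_piwi: bool
    piwi_agreement: float
    degree: int
    weighted_degree: float
    n_singletons: int


def build_orthonet(copies: Iterable[TECopy], ortho_table: OrthoTable,
                   annotations: Iterable[SpeciesAnnotation],
                   threshold: int = DEFAULT_ORTHOGROUP_THRESHOLD,
                   max_scope: str = "global") -> nx.Graph:
    """Build the orthonetwork.

    ``max_scope`` selects the normaliser of the genome-TE LengthAdj weight:
    ``"global"`` (default) divides by the log of the largest per-genome
    family total anywhere in the network, ``"family"`` by the largest total
    of that same family.
    """
    if max_scope not in {"global", "family"}:
        raise ValueError(f"max_scope must be 'global' or 'family', got {max_scope!r}")
    copies = list(copies)
    annotations = list(annotations)
    ann_by_id = {a.genome_id: a for a in annotations}

    totals: dict[tuple[str, str], int] = {}
    fam_super: dict[str, str] = {}
    for c in copies:
        key = (c.genome_id, c.family)
        totals[key] = totals.get(key, 0) + c.length_bp
        fam_super.setdefault(c.family, c.superfamily)
    bad = sorted(f"{g}/{f} ({bp} bp)" for (g, f), bp in totals.items() if bp <= 1)
    if bad:
        raise ValueError(
            "per-genome family totals must exceed 1 bp for the log weight; "
            "offending edges: " + ", ".join(bad))

    genomes = sorted({c.genome_id for c in copies} | set(ann_by_id))
    missing_pairs = [(a, b) for i, a in enumerate(genomes) for b in genomes[i + 1:]
                     if (a, b) not in ortho_table]
    if missing_pairs:
        raise ValueError("orthogroup table missing pairs: " +
                         ", ".join(f"({a},{b})" for a, b in missing_pairs[:10]))

    global_max = max(totals.values())
    family_max = {f: max(bp for (g2, f2), bp in totals.items() if f2 == f)
                  for f in fam_super}

    net = nx.Graph(threshold=threshold)
    for g in genomes:
        ann = ann_by_id.get(g)
        net.add_node(g, type="genome", bipartite=0,
                     clade_label=ann.clade_label if ann else "",
                     has_dnmt=ann.has_dnmt if ann else False,
                     has_piwi=ann.has_piwi if ann else False)
    for f in sorted(fam_super):
        net.add_node(f, type="te", bipartite=1, superfamily=fam_super[f])

    for (g, f), bp in totals.items():
        norm = global_max if max_scope == "global" else family_max[f]
        weight = 1.0 if bp == norm else math.log(bp) / math.log(norm)
        net.add_edge(g, f, weight=weight, kind="content")

    retained = [(a, b, n) for a, b, n in ortho_table.pairs()
                if a in net and b in net and n >= threshold]
    if retained:
        max_shared = max(n for _, _, n in retained)
        for a, b, n in retained:
            net.add_edge(a, b, weight=n / max_shared, kind="ortho")
    return net


def collapse_to_groups(orthonet: nx.Graph, seed: int = 0,
                       resolution: float = 1.0) -> list[GroupNode]:
    """Louvain-cluster the mixed network and collapse each genome-containing
    cluster to one group node with group-level TE statistics.

    Group degree counts the distinct TE families incident to any member;
    weighted degree sums the members' genome-TE edge weights; singletons are
    families connected to no genome outside the group. Silencing labels are
    majority votes with the within-group agreement fraction recorded.
    """
    part = louvain_partition(orthonet, resolution=resolution, seed=seed)
    groups: list[GroupNode] = []
    for cid, members in sorted(part.clusters().items()):
        genomes = sorted(n for n in members
                         if orthonet.nodes[n]["type"] == "genome")
        if not genomes:
            warnings.warn(f"cluster {cid} contains no genome nodes; skipped",
                          stacklevel=2)
            continue
        families: set[str] = set()
        weighted = 0.0
        for g in genomes:
            for f in orthonet.neighbors(g):
                if orthonet.nodes[f]["type"] != "te":
                    continue
                families.add(f)
                weighted += orthonet[g][f]["weight"]
        genome_set = set(genomes)
        n_singletons = sum(
            1 for f in families
            if all(g in genome_set for g in orthonet.neighbors(f)
                   if orthonet.nodes[g]["type"] == "genome"))
        clade, clade_frac = _majority([orthonet.nodes[g]["clade_label"]
                                       for g in genomes])
        dnmt, dnmt_frac = _majority([orthonet.nodes[g]["has_dnmt"]
                                     for g in genomes])
        piwi, piwi_frac = _majority([orthonet.nodes[g]["has_piwi"]
                                     for g in genomes])
        groups.append(GroupNode(
            cluster_id=cid, genome_ids=tuple(genomes),
            clade_label=clade, clade_agreement=clade_frac,
            has_dnmt=dnmt, dnmt_agreement=dnmt_frac,
            has_piwi=piwi, piwi_agreement=piwi_frac,
            degree=len(families), weighted_degree=weighted,
            n_singletons=n_singletons))
    return groups


def _majority(values: Sequence) -> tuple:
    counts = Counter(values)
    value, n = counts.most_common(1)[0]
    return value, n / len(values)


def group_comparison(groups: Sequence[GroupNode], grouping: str,
                     statistic: str) -> tuple[dict, TestResult]:
    """Group-level Wilcoxon rank-sum: one observation per collapsed group."""
    if grouping not in {"has_dnmt", "has_piwi"}:
        raise ValueError(f"grouping must be has_dnmt or has_piwi, got {grouping!r}")
    with_group = [getattr(g, statistic) for g in groups if getattr(g, grouping)]
    without_group = [getattr(g, statistic) for g in groups
                     if not getattr(g, grouping)]
    if len(with_group) < 2 or len(without_group) < 2:
        raise ValueError(
            f"{grouping}: need >= 2 groups per side, got "
            f"{len(with_group)} vs {len(without_group)}")
    samples = {"with": with_group, "without": without_group}
    return samples, wilcoxon_rank_sum(with_group, without_group)


def group_table(groups: Sequence[GroupNode]) -> pd.DataFrame:
    """Flatten group nodes to a DataFrame (one row per collapsed group)."""
    return pd.DataFrame([{
        "cluster_id": g.cluster_id,
        "n_genomes": len(g.genome_ids),
        "genome_ids": ";".join(g.genome_ids),
        "clade_label": g.clade_label,
        "clade_agreement": g.clade_agreement,
        "has_dnmt": g.has_dnmt,
        "dnmt_agreement": g.dnmt_agreement,
        "has_piwi": g.has_piwi,
        "piwi_agreement": g.piwi_agreement,
        "degree": g.degree,
        "weighted_degree": g.weighted_degree,
        "n_singletons": g.n_singletons,
    } for g in groups])
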