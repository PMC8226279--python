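"""Active/inactive TE classification from transposition-domain hits, and the
singleton bootstrap.

A TE (family or copy) is called potentially active when at least one of six
Pfam domains associated with transposition machinery is found in its
translated sequence: DDE_1 (PF03184), DDE_2 (PF02914), DDE_3 (PF13358),
retrotransposon gag (PF03732), integrase core (PF00665) and retroviral
aspartyl protease (PF00077). With no such domain it is called inactive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .model import DomainHit, SpeciesAnnotation, TECopy
from .stats import TestResult, wilcoxon_rank_sum, wilcoxon_signed_rank

__all__ = ["ACTIVE_DOMAIN_WHITELIST", "ActivityCall", "classify_activity",
           "family_activity", "singletons_by_activity", "bootstrap_singletons",
           "BootstrapResult"]

#: Pfam accessions whose presence marks a TE as potentially active
ACTIVE_DOMAIN_WHITELIST = frozenset({
    "PF03184",  # DDE_1 transposase
    "PF02914",  # DDE_2 transposase
    "PF13358",  # DDE_3 transposase
    "PF03732",  # retrotransposon gag protein
    "PF00665",  # integrase core domain
    "PF00077",  # retroviral aspartyl protease
})


@dataclass(frozen=True)
class ActivityCall:
    target_id: str
    active: bool
    matched_domains: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.active != bool(self.matched_domains):
            raise ValueError("active flag must mirror matched_domains")


def classify_activity(domain_hits: Iterable[DomainHit],
                      targets: Iterable[str],
                      whitelist: frozenset[str] = ACTIVE_DOMAIN_WHITELIST,
                      ) -> dict[str, ActivityCall]:
    """Per-copy activity calls over a universe of ``targets`` copy ids.

    A target is active iff it has at least one hit to the whitelist; hits to
    other accessions are ignored.
    """
    matched: dict[str, set[str]] = {t: set() for t in targets}
    for hit in domain_hits:
        if hit.pfam_accession in whitelist and hit.copy_id in matched:
            matched[hit.copy_id].add(hit.pfam_accession)
    return {t: ActivityCall(t, bool(doms), tuple(sorted(doms)))
            for t, doms in matched.items()}


def family_activity(copies: Iterable[TECopy],
                    domain_hits: Iterable[DomainHit],
                    whitelist: frozenset[str] = ACTIVE_DOMAIN_WHITELIST,
                    ) -> dict[str, ActivityCall]:
    """Family-level activity: a family is active when any of its copies
    carries a whitelisted domain."""
    copies = list(copies)
    fam_of = {c.copy_id: c.family for c in copies}
    matched: dict[str, set[str]] = {c.family: set() for c in copies}
    for hit in domain_hits:
        fam = fam_of.get(hit.copy_id)
        if fam is not None and hit.pfam_accession in whitelist:
            matched[fam].add(hit.pfam_accession)
    return {f: ActivityCall(f, bool(doms), tuple(sorted(doms)))
            for f, doms in matched.items()}


def singletons_by_activity(content_net: nx.Graph,
                           activity_calls: Mapping[str, ActivityCall],
                           annotations: Iterable[SpeciesAnnotation],
                           grouping: str = "has_dnmt",
                           ) -> tuple[pd.DataFrame, dict[str, TestResult]]:
    """Split each genome's singleton families into active vs inactive and
    compare each split between silencing groups.

    Returns the per-genome count table and one rank-sum result per split
    (``{"active": ..., "inactive": ...}``).
    """
    annotations = list(annotations)
    ann_by_id = {a.genome_id: a for a in annotations}
    rows = []
    for g in (n for n, d in content_net.nodes(data=True) if d["type"] == "genome"):
        active = inactive = 0
        for f in content_net.neighbors(g):
            if content_net.degree(f) != 1:
                continue
            call = activity_calls.get(f)
            if call is not None and call.active:
                active += 1
            else:
                inactive += 1
        rows.append({"genome_id": g, "active_singletons": active,
                     "inactive_singletons": inactive})
    table = pd.DataFrame(rows, columns=["genome_id", "active_singletons",
                                        "inactive_singletons"]).set_index("genome_id")
    tests: dict[str, TestResult] = {}
    for split, column in (("active", "active_singletons"),
                          ("inactive", "inactive_singletons")):
        with_group = [table.loc[g, column] for g in table.index
                      if getattr(ann_by_id[g], grouping)]
        without_group = [table.loc[g, column] for g in table.index
                         if not getattr(ann_by_id[g], grouping)]
        if len(with_group) >= 2 and len(without_group) >= 2:
            tests[split] = wilcoxon_rank_sum(with_group, without_group)
    return table, tests


@dataclass(frozen=True)
class BootstrapResult:
    group: str
    p_values: np.ndarray
    sample_size: int
    reps: int

    def quantiles(self, q=(0.05, 0.25, 0.5, 0.75, 0.95)) -> dict[float, float]:
        return {float(qq): float(v)
                for qq, v in zip(q, np.quantile(self.p_values, q))}


def bootstrap_singletons(counts: pd.DataFrame, group_genomes: Sequence[str],
                         group_label: str = "", sample_size: int = 30,
                         reps: int = 1000, seed: int = 0,
                         paired: bool = True) -> BootstrapResult:
    """Bootstrap the active-vs-inactive singleton comparison within a group.

    Each replicate samples ``sample_size`` genomes from the group and runs a
    Wilcoxon test between their active and inactive singleton counts —
    paired (signed-rank) by default, since both counts come from the same
    genome; ``paired=False`` switches to the rank-sum variant. Groups
    smaller than ``sample_size`` are resampled with replacement (warned).
    """
    if sample_size < 2:
        raise ValueError(f"sample_size must be >= 2, got {sample_size}")
    group_genomes = list(group_genomes)
    missing = [g for g in group_genomes if g not in counts.index]
    if missing:
        raise ValueError("genomes absent from count table: " + ", ".join(missing))
    replace = len(group_genomes) < sample_size
    if replace:
        warnings.warn(
            f"group {group_label!r} has {len(group_genomes)} genomes "
            f"< sample_size {sample_size}; sampling with replacement",
            stacklevel=2)
    rng = np.random.default_rng(seed)
    active = counts.loc[group_genomes, "active_singletons"].to_numpy(dtype=float)
    inactive = counts.loc[group_genomes, "inactive_singletons"].to_numpy(dtype=float)
    p_values = np.empty(reps)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # all-zero-difference replicates
        for i in range(reps):
            idx = rng.choice(len(group_genomes), size=sample_size, replace=replace)
            if paired:
                result = wilcoxon_signed_rank(active[idx] - inactive[idx])
            else:
                result = wilcoxon_rank_sum(active[idx], inactive[idx])
            p_values[i] = result.p_value
    return BootstrapResult(group=group_label, p_values=p_values,
                           sample_size=sample_size, reps=reps)
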