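"""Shared data model for the TE network pipeline.

Coordinates are stored 0-based half-open throughout; conversion from the
1-based inclusive conventions of annotation tools happens at parse time in
:mod:`tenet.repeat_io`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

__all__ = [
    "TECopy",
    "AlignmentHit",
    "DomainHit",
    "SpeciesAnnotation",
    "OrthoTable",
    "make_copy_id",
]

_PFAM_RE = re.compile(r"^PF\d{5}$")


def make_copy_id(genome_id: str, seq_id: str, start: int, end: int,
                 strand: str, family: str, n: int) -> str:
    """Synthesise a unique, human-readable copy identifier.

    ``n`` is a per-dataset ordinal that guarantees uniqueness even for
    duplicated annotation rows.
    """
    return f"{genome_id}:{seq_id}:{start}-{end}:{strand}:{family}#{n}"


@dataclass(frozen=True, slots=True)
class TECopy:
    """One annotated transposable-element interval in one genome."""

    copy_id: str
    genome_id: str
    seq_id: str
    start: int  # 0-based inclusive
    end: int    # exclusive
    strand: str
    family: str
    superfamily: str

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"{self.copy_id}: end ({self.end}) must exceed start ({self.start})")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"{self.copy_id}: strand must be '+' or '-', got {self.strand!r}")

    @property
    def length_bp(self) -> int:
        return self.end - self.start


@dataclass(frozen=True, slots=True)
class AlignmentHit:
    """One pairwise local-alignment record between two TE copies."""

    query_id: str
    subject_id: str
    pct_identity: float
    aln_length: int
    qstart: int
    qend: int
    sstart: int
    send: int
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if self.bitscore <= 0:
            raise ValueError(f"bitscore must be > 0, got {self.bitscore}")
        if self.evalue < 0:
            raise ValueError(f"evalue must be >= 0, got {self.evalue}")


@dataclass(frozen=True, slots=True)
class DomainHit:
    """One profile-HMM domain match in a (translated) TE copy."""

    copy_id: str
    pfam_accession: str
    domain_name: str
    evalue: float
    env_start: int
    env_end: int

    def __post_init__(self) -> None:
        if not _PFAM_RE.match(self.pfam_accession):
            raise ValueError(
                f"pfam_accession must match PF#####, got {self.pfam_accession!r}")


@dataclass(frozen=True, slots=True)
class SpeciesAnnotation:
    """Per-genome metadata: clade plus silencing-machinery presence.

    ``has_dnmt`` records the presence of a DNMT1/DNMT3 orthologue
    (cytosine-methylation machinery); ``has_piwi`` the presence of a PIWI
    orthologue (piRNA pathway). ``genome_size_bp`` may be None when no
    percentage metric is requested.
    """

    genome_id: str
    clade_label: str
    has_dnmt: bool
    has_piwi: bool
    genome_size_bp: int | None = None

    def __post_init__(self) -> None:
        if self.genome_size_bp is not None and self.genome_size_bp <= 0:
            raise ValueError(f"{self.genome_id}: genome_size_bp must be > 0")


class OrthoTable:
    """Symmetric (genome, genome) -> shared-orthogroup count lookup.

    The diagonal is ignored; inserting both orientations of a pair with
    conflicting counts is an error.
    """

    def __init__(self) -> None:
        self._counts: dict[frozenset[str], int] = {}

    @classmethod
    def from_pairs(cls, triples: Iterable[tuple[str, str, int]]) -> "OrthoTable":
        table = cls()
        for a, b, count in triples:
            table.set(a, b, count)
        return table

    def set(self, a: str, b: str, count: int) -> None:
        if a == b:
            return
        count = int(count)
        if count < 0:
            raise ValueError(f"shared-orthogroup count for ({a},{b}) is negative: {count}")
        key = frozenset((a, b))
        existing = self._counts.get(key)
        if existing is not None and existing != count:
            raise ValueError(
                f"asymmetric duplicate for pair ({a},{b}): {existing} vs {count}")
        self._counts[key] = count

    def get(self, a: str, b: str) -> int:
        try:
            return self._counts[frozenset((a, b))]
        except KeyError:
            raise KeyError(f"pair ({a},{b}) missing from orthogroup table") from None

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return frozenset(pair) in self._counts

    def pairs(self) -> Iterator[tuple[str, str, int]]:
        for key, count in sorted(self._counts.items(), key=lambda kv: tuple(sorted(kv[0]))):
            a, b = sorted(key)
            yield a, b, count

    def genomes(self) -> set[str]:
        out: set[str] = set()
        for key in self._counts:
            out.update(key)
        return out

    def max_count(self) -> int:
        if not self._counts:
            raise ValueError("empty orthogroup table has no maximum")
        return max(self._counts.values())

    def __len__(self) -> int:
        return len(self._counts)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, OrthoTable):
            return NotImplemented
        return self._counts == other._counts
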