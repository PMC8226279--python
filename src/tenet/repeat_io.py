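"""Parsers and writers for the standard annotation formats the pipeline consumes.

Readers convert external conventions (1-based inclusive coordinates, 'C' for
the reverse strand) into the internal model at the boundary. Each record type
also has a canonical TSV form that round-trips losslessly.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .model import (
    AlignmentHit,
    DomainHit,
    OrthoTable,
    SpeciesAnnotation,
    TECopy,
    make_copy_id,
)

__all__ = [
    "read_repeatmasker",
    "read_tabular_hits",
    "read_domain_table",
    "read_ortho_table",
    "read_copies_tsv",
    "write_copies_tsv",
    "read_hits_tsv",
    "write_hits_tsv",
    "read_domains_tsv",
    "write_domains_tsv",
    "read_annotations_tsv",
    "write_annotations_tsv",
    "read_ortho_tsv",
    "write_ortho_tsv",
]

log = logging.getLogger(__name__)

#: classification strings treated as "unclassified" and excluded by default
UNCLASSIFIED_LABELS = ("Unknown", "Unclassified")


def read_repeatmasker(path: str | Path, genome_id: str | None = None,
                      include_unclassified: bool = False) -> list[TECopy]:
    """Parse a RepeatMasker ``.out`` annotation table into TE copies.

    The dialect has three header lines followed by whitespace-delimited rows
    (score, divergence, deletions, insertions, query, begin, end, left,
    strand, repeat name, class/family, ...). Input coordinates are 1-based
    inclusive; strand ``C`` means the reverse complement. Rows whose
    class/family is Unknown/Unclassified are excluded unless
    ``include_unclassified`` is set.
    """
    path = Path(path)
    if genome_id is None:
        genome_id = path.stem
    copies: list[TECopy] = []
    n_unclassified = 0
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if lineno <= 3:  # column headers + blank line
                continue
            line = line.strip()
            if not line:
                continue
            fields = line.split()
            if len(fields) < 11:
                raise ValueError(
                    f"{path}:{lineno}: malformed RepeatMasker row "
                    f"({len(fields)} fields, expected >= 11)")
            try:
                begin_1based = int(fields[5])
                end_1based = int(fields[6])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            strand = fields[8]
            if strand == "C":
                strand = "-"
            if strand not in {"+", "-"}:
                raise ValueError(f"{path}:{lineno}: unrecognised strand {fields[8]!r}")
            family = fields[9]
            classification = fields[10]
            if not include_unclassified and any(
                    classification.startswith(label) for label in UNCLASSIFIED_LABELS):
                n_unclassified += 1
                continue
            start = begin_1based - 1  # to 0-based half-open
            end = end_1based
            copies.append(TECopy(
                copy_id=make_copy_id(genome_id, fields[4], start, end, strand,
                                     family, len(copies)),
                genome_id=genome_id,
                seq_id=fields[4],
                start=start,
                end=end,
                strand=strand,
                family=family,
                superfamily=classification,
            ))
    if n_unclassified:
        log.info("%s: excluded %d unclassified repeat rows", path, n_unclassified)
    if not copies:
        warnings.warn(f"{path}: no TE copies after filtering", stacklevel=2)
    return copies


def read_tabular_hits(path: str | Path) -> list[AlignmentHit]:
    """Parse 12-column tab-separated all-vs-all alignment hits.

    Columns: query, subject, %identity, alignment length, mismatches,
    gap opens, qstart, qend, sstart, send, e-value, bitscore. Self-hits
    (query == subject) are dropped and counted.
    """
    path = Path(path)
    hits: list[AlignmentHit] = []
    n_self = 0
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise ValueError(
                    f"{path}:{lineno}: expected 12 tab-separated columns, got {len(fields)}")
            if fields[0] == fields[1]:
                n_self += 1
                continue
            try:
                hits.append(AlignmentHit(
                    query_id=fields[0],
                    subject_id=fields[1],
                    pct_identity=float(fields[2]),
                    aln_length=int(fields[3]),
                    qstart=int(fields[6]),
                    qend=int(fields[7]),
                    sstart=int(fields[8]),
                    send=int(fields[9]),
                    evalue=float(fields[10]),
                    bitscore=float(fields[11]),
                ))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    if n_self:
        log.info("%s: dropped %d self-hits", path, n_self)
    return hits


def read_domain_table(path: str | Path, max_evalue: float = 1e-5) -> list[DomainHit]:
    """Parse an HMMER per-domain table (``--domtblout`` dialect).

    One :class:`DomainHit` is produced per domain row whose independent
    e-value passes ``max_evalue``. The sequence is the search target and the
    profile the query, so the copy id is column 1 and the Pfam accession
    column 5 of the whitespace-delimited row. Accession version suffixes
    (``PF13358.6``) are stripped.
    """
    path = Path(path)
    hits: list[DomainHit] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 21:
                raise ValueError(
                    f"{path}:{lineno}: malformed domtblout row "
                    f"({len(fields)} fields, expected >= 21)")
            accession = fields[4].split(".")[0]
            if accession == "-":
                raise ValueError(f"{path}:{lineno}: missing profile accession")
            evalue = float(fields[12])  # independent e-value of this domain
            if evalue > max_evalue:
                continue
            hits.append(DomainHit(
                copy_id=fields[0],
                pfam_accession=accession,
                domain_name=fields[3],
                evalue=evalue,
                env_start=int(fields[19]),
                env_end=int(fields[20]),
            ))
    log.info("%s: %d domain hits at e-value <= %g", path, len(hits), max_evalue)
    return hits


def read_ortho_table(path: str | Path) -> OrthoTable:
    """Read a shared-orthogroup table, either long-format triples
    (genome_a, genome_b, count) or a labelled symmetric matrix."""
    path = Path(path)
    with path.open() as fh:
        first = fh.readline()
    fields = first.rstrip("\n").split("\t")
    # A matrix is recognised by an empty top-left cell (labelled header row
    # and column); anything 3-column is long-format triples, with or without
    # a header row.
    is_long = fields[0] != "" and len(fields) == 3
    if is_long:
        df = pd.read_csv(path, sep="\t", header=None if _is_int(fields[2]) else 0,
                         names=["genome_a", "genome_b", "count"])
        return OrthoTable.from_pairs(
            (str(r.genome_a), str(r.genome_b), int(r.count)) for r in df.itertuples())
    df = pd.read_csv(path, sep="\t", index_col=0)
    table = OrthoTable()
    for a in df.index:
        for b in df.columns:
            if str(a) == str(b):
                continue
            value = df.at[a, b]
            if pd.isna(value):
                continue
            table.set(str(a), str(b), int(value))
    return table


def _is_int(token: str) -> bool:
    try:
        int(token)
    except ValueError:
        return False
    return True


# ---------------------------------------------------------------------------
# canonical TSV forms

_COPY_COLS = ["copy_id", "genome_id", "seq_id", "start", "end", "strand",
              "family", "superfamily"]
_HIT_COLS = ["query_id", "subject_id", "pct_identity", "aln_length",
             "qstart", "qend", "sstart", "send", "evalue", "bitscore"]
_DOMAIN_COLS = ["copy_id", "pfam_accession", "domain_name", "evalue",
                "env_start", "env_end"]
_ANNOT_COLS = ["genome_id", "clade_label", "has_dnmt", "has_piwi", "genome_size_bp"]


def write_copies_tsv(copies: Iterable[TECopy], path: str | Path) -> None:
    rows = [[c.copy_id, c.genome_id, c.seq_id, c.start, c.end, c.strand,
             c.family, c.superfamily] for c in copies]
    pd.DataFrame(rows, columns=_COPY_COLS).to_csv(path, sep="\t", index=False)


def read_copies_tsv(path: str | Path) -> list[TECopy]:
    df = pd.read_csv(path, sep="\t", dtype={c: str for c in
                                            ("copy_id", "genome_id", "seq_id",
                                             "strand", "family", "superfamily")})
    return [TECopy(r.copy_id, r.genome_id, r.seq_id, int(r.start), int(r.end),
                   r.strand, r.family, r.superfamily) for r in df.itertuples()]


def write_hits_tsv(hits: Iterable[AlignmentHit], path: str | Path) -> None:
    rows = [[h.query_id, h.subject_id, h.pct_identity, h.aln_length, h.qstart,
             h.qend, h.sstart, h.send, h.evalue, h.bitscore] for h in hits]
    pd.DataFrame(rows, columns=_HIT_COLS).to_csv(path, sep="\t", index=False)


def read_hits_tsv(path: str | Path) -> list[AlignmentHit]:
    df = pd.read_csv(path, sep="\t", dtype={"query_id": str, "subject_id": str},
                     float_precision="round_trip")
    return [AlignmentHit(r.query_id, r.subject_id, float(r.pct_identity),
                         int(r.aln_length), int(r.qstart), int(r.qend),
                         int(r.sstart), int(r.send), float(r.evalue),
                         float(r.bitscore)) for r in df.itertuples()]


def write_domains_tsv(hits: Iterable[DomainHit], path: str | Path) -> None:
    rows = [[h.copy_id, h.pfam_accession, h.domain_name, h.evalue,
             h.env_start, h.env_end] for h in hits]
    pd.DataFrame(rows, columns=_DOMAIN_COLS).to_csv(path, sep="\t", index=False)


def read_domains_tsv(path: str | Path) -> list[DomainHit]:
    df = pd.read_csv(path, sep="\t", dtype={"copy_id": str, "pfam_accession": str,
                                            "domain_name": str},
                     float_precision="round_trip")
    return [DomainHit(r.copy_id, r.pfam_accession, r.domain_name,
                      float(r.evalue), int(r.env_start), int(r.env_end))
            for r in df.itertuples()]


def write_annotations_tsv(annotations: Iterable[SpeciesAnnotation],
                          path: str | Path) -> None:
    rows = [[a.genome_id, a.clade_label, a.has_dnmt, a.has_piwi,
             "" if a.genome_size_bp is None else a.genome_size_bp]
            for a in annotations]
    pd.DataFrame(rows, columns=_ANNOT_COLS).to_csv(path, sep="\t", index=False)


def read_annotations_tsv(path: str | Path) -> list[SpeciesAnnotation]:
    df = pd.read_csv(path, sep="\t", dtype={"genome_id": str, "clade_label": str})
    out = []
    for r in df.itertuples():
        size = None if pd.isna(r.genome_size_bp) else int(r.genome_size_bp)
        out.append(SpeciesAnnotation(r.genome_id, r.clade_label,
                                     bool(r.has_dnmt), bool(r.has_piwi), size))
    return out


def write_ortho_tsv(table: OrthoTable, path: str | Path) -> None:
    rows = list(table.pairs())
    pd.DataFrame(rows, columns=["genome_a", "genome_b", "count"]).to_csv(
        path, sep="\t", index=False)


def read_ortho_tsv(path: str | Path) -> OrthoTable:
    return read_ortho_table(path)
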