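"""Synthetic TE landscapes with planted structure.

The generator emulates, at the level of annotation tables and alignment-hit
tables, the statistical structure the pipeline is designed to detect:

* a clade-structured set of species with piRNA (PIWI) and DNA-methylation
  (DNMT) regimes assigned per clade;
* per-species TE family repertoires where piRNA+ species carry more distinct
  families but fewer copies of each, with total TE content matched in
  expectation between regimes (so degree and weighted degree dissociate);
* extra inactive species-private ("singleton") families in DNMT+ species;
* shared-orthogroup counts that are high within clades and low between them;
* all-vs-all alignment hits forming dense high-bitscore subgraphs within
  families, an optional moderate-bitscore "convergent segment" linking two
  designated families (the signature of independent capture of the same
  host-gene sequence), optional recent-activity boosts with catalytic-domain
  hits, and planted horizontal-transfer events.

Sequence content itself is not simulated: similarity is modelled directly at
the hit level. Every draw is a pure function of (config, seed), and the
planted truth (family membership, activity, transferred copies, convergent
pair) is returned alongside the data.
"""

from __future__ import annotations

import itertools
import math
import zlib
from dataclasses import dataclass, field, replace
from typing import Iterable, NamedTuple, Sequence

import numpy as np

from .model import (
    AlignmentHit,
    DomainHit,
    OrthoTable,
    SpeciesAnnotation,
    TECopy,
    make_copy_id,
)

__all__ = ["LandscapeConfig", "HitModelConfig", "Landscape", "HitSet",
           "simulate_landscape", "simulate_hits", "plant_horizontal_transfer",
           "expected_total_bp"]

_SUPERFAMILIES = ("DNA/TcMar-Tc1", "LINE/L1", "LTR/Gypsy", "DNA/hAT",
                  "LINE/RTE", "LTR/Copia")
_ACTIVE_DOMAINS = ("PF13358", "PF03184", "PF02914", "PF03732", "PF00665",
                   "PF00077")


@dataclass(frozen=True)
class LandscapeConfig:
    """Parameters of the synthetic TE landscape.

    Family-richness and copy-number means are Poisson means of the
    1-truncated form ``1 + Poisson(mean - 1)`` (so the mean is exact and
    every species/family is non-empty); copy lengths are log-normal in bp.
    The piRNA factors implement the planted dissociation: richness x2 and
    copies x0.5 leave expected total content unchanged.
    """

    seed: int
    n_species: int = 40
    n_clades: int = 4
    fam_mean: float = 12.0          # baseline TE families per species
    copy_mean: float = 8.0          # baseline copies per family
    piwi_fam_factor: float = 2.0    # family-richness multiplier, piRNA+ species
    piwi_copy_factor: float = 0.5   # copies-per-family multiplier, piRNA+ species
    singleton_fraction: float = 0.3  # fraction of a species' families that are private
    dnmt_inactive_singletons: float = 4.0  # extra inactive private families, DNMT+
    inactive_copy_mean: float = 2.0  # copies per extra inactive singleton family
    active_family_fraction: float = 0.5  # chance a regular family is active
    length_meanlog: float = 6.6     # log-normal copy length (~735 bp median)
    length_sdlog: float = 0.5
    min_length: int = 50
    genome_size_bp: int = 100_000_000
    ortho_within_clade: float = 8000.0   # shared orthogroups, same clade
    ortho_between_clade: float = 2000.0  # shared orthogroups, different clades
    ortho_sd: float = 200.0

    def __post_init__(self) -> None:
        for name in ("fam_mean", "copy_mean", "piwi_fam_factor",
                     "piwi_copy_factor", "inactive_copy_mean",
                     "dnmt_inactive_singletons", "ortho_within_clade",
                     "ortho_between_clade", "ortho_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not (0.0 <= self.singleton_fraction <= 1.0):
            raise ValueError("singleton_fraction must be in [0, 1]")
        if self.n_species < self.n_clades:
            raise ValueError("need at least one species per clade")
        for mean, factor in ((self.fam_mean, self.piwi_fam_factor),
                             (self.copy_mean, self.piwi_copy_factor)):
            if mean * factor < 1.0 or mean < 1.0:
                raise ValueError(
                    "truncated-Poisson means must stay >= 1 under the piRNA factors")


@dataclass(frozen=True)
class HitModelConfig:
    """Parameters of the alignment-hit (and domain-hit) model.

    Within-family pairs connect with probability ``p_within`` at bitscores
    around ``within_mean``; between-family hits are absent by default. A
    convergent pair of families additionally shares moderate-bitscore hits
    (``convergent_mean`` < ``within_mean``), which is what merges them into
    one mixed cluster. Families in ``dde3_families`` model recent activity:
    fully connected at boosted bitscores, with catalytic-domain hits emitted
    for their copies.
    """

    seed: int
    within_mean: float = 450.0
    within_sd: float = 40.0
    p_within: float = 0.8
    between_mean: float = 0.0      # 0 disables between-family background hits
    between_sd: float = 5.0
    p_between: float = 0.0
    convergent_pair: tuple[str, str] | None = None
    convergent_mean: float = 150.0
    convergent_sd: float = 20.0
    p_convergent: float = 0.6
    dde3_families: tuple[str, ...] = ()
    dde3_boost: float = 1.3        # bitscore multiplier for recently active families
    active_families: tuple[str, ...] = ()  # emit transposition-domain hits

    def __post_init__(self) -> None:
        if self.convergent_pair is not None:
            if not (self.within_mean > self.convergent_mean > 0):
                raise ValueError(
                    "need within_mean > convergent_mean > 0 for a planted "
                    "convergent segment")
        for name in ("p_within", "p_between", "p_convergent"):
            p = getattr(self, name)
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")


class Landscape(NamedTuple):
    copies: list[TECopy]
    annotations: list[SpeciesAnnotation]
    ortho: OrthoTable
    truth: dict


class HitSet(NamedTuple):
    hits: list[AlignmentHit]
    domain_hits: list[DomainHit]


def _trunc_poisson(rng: np.random.Generator, mean: float, size: int | None = None):
    """1 + Poisson(mean - 1): support >= 1, expectation exactly ``mean``."""
    return 1 + rng.poisson(mean - 1.0, size=size)


def expected_total_bp(cfg: LandscapeConfig, has_piwi: bool, has_dnmt: bool) -> float:
    """Config-implied expected total TE bp of one genome (before length
    rounding/clipping, which is negligible at the default scales)."""
    mean_len = math.exp(cfg.length_meanlog + cfg.length_sdlog ** 2 / 2)
    fam = cfg.fam_mean * (cfg.piwi_fam_factor if has_piwi else 1.0)
    cpy = cfg.copy_mean * (cfg.piwi_copy_factor if has_piwi else 1.0)
    total = fam * cpy * mean_len
    if has_dnmt:
        total += cfg.dnmt_inactive_singletons * cfg.inactive_copy_mean * mean_len
    return total


def _clade_regimes(n_clades: int) -> list[tuple[bool, bool]]:
    """Assign (has_piwi, has_dnmt) per clade on an alternating grid so the
    two mechanisms are as close to orthogonal as the clade count allows."""
    return [((c % 2) == 0, ((c // 2) % 2) == 0) for c in range(n_clades)]


def simulate_landscape(cfg: LandscapeConfig) -> Landscape:
    """Draw a full landscape: TE copies, species annotations, orthogroup
    counts, and the planted truth."""
    rng = np.random.default_rng(cfg.seed)
    regimes = _clade_regimes(cfg.n_clades)

    clade_of: dict[str, int] = {}
    annotations: list[SpeciesAnnotation] = []
    for i in range(cfg.n_species):
        clade = i % cfg.n_clades
        gid = f"sp{i:03d}"
        clade_of[gid] = clade
        piwi, dnmt = regimes[clade]
        annotations.append(SpeciesAnnotation(
            genome_id=gid, clade_label=f"clade{clade:02d}",
            has_dnmt=dnmt, has_piwi=piwi, genome_size_bp=cfg.genome_size_bp))

    # clade-shared family pools, large enough for the richest species
    pool_size = max(4, int(math.ceil(cfg.fam_mean * cfg.piwi_fam_factor * 3)))
    clade_pool = {c: [f"clade{c:02d}_fam{j:03d}" for j in range(pool_size)]
                  for c in range(cfg.n_clades)}
    fam_superfamily: dict[str, str] = {}
    fam_active: dict[str, bool] = {}
    fam_kind: dict[str, str] = {}

    def register(fam: str, kind: str, active: bool) -> None:
        if fam not in fam_superfamily:
            # crc32 rather than hash(): stable across processes
            fam_superfamily[fam] = _SUPERFAMILIES[
                zlib.crc32(fam.encode()) % len(_SUPERFAMILIES)]
            fam_active[fam] = active
            fam_kind[fam] = kind

    copies: list[TECopy] = []

    def emit_copies(gid: str, fam: str, n: int) -> None:
        lengths = np.maximum(
            cfg.min_length,
            np.round(rng.lognormal(cfg.length_meanlog, cfg.length_sdlog,
                                   size=n)).astype(int))
        for length in lengths:
            start = int(rng.integers(0, cfg.genome_size_bp - int(length)))
            strand = "+" if rng.random() < 0.5 else "-"
            copies.append(TECopy(
                copy_id=make_copy_id(gid, "chr1", start, start + int(length),
                                     strand, fam, len(copies)),
                genome_id=gid, seq_id="chr1", start=start,
                end=start + int(length), strand=strand, family=fam,
                superfamily=fam_superfamily[fam]))

    for ann in annotations:
        gid = ann.genome_id
        clade = clade_of[gid]
        fam_mult = cfg.piwi_fam_factor if ann.has_piwi else 1.0
        copy_mult = cfg.piwi_copy_factor if ann.has_piwi else 1.0
        n_fams = int(_trunc_poisson(rng, cfg.fam_mean * fam_mult))
        n_private = int(rng.binomial(n_fams, cfg.singleton_fraction))
        n_shared = min(n_fams - n_private, pool_size)
        shared = rng.choice(clade_pool[clade], size=n_shared, replace=False)
        for fam in shared:
            register(str(fam), "clade",
                     bool(rng.random() < cfg.active_family_fraction))
        private = [f"{gid}_fam{j:03d}" for j in range(n_private)]
        for fam in private:
            register(fam, "singleton",
                     bool(rng.random() < cfg.active_family_fraction))
        for fam in itertools.chain((str(f) for f in shared), private):
            emit_copies(gid, fam, int(_trunc_poisson(rng, cfg.copy_mean * copy_mult)))
        if ann.has_dnmt:
            n_extra = int(rng.poisson(cfg.dnmt_inactive_singletons))
            for j in range(n_extra):
                fam = f"{gid}_inactive{j:03d}"
                register(fam, "dnmt_inactive_singleton", False)
                emit_copies(gid, fam, int(_trunc_poisson(rng, cfg.inactive_copy_mean)))

    ortho = OrthoTable()
    gids = [a.genome_id for a in annotations]
    for i, a in enumerate(gids):
        for b in gids[i + 1:]:
            mean = (cfg.ortho_within_clade if clade_of[a] == clade_of[b]
                    else cfg.ortho_between_clade)
            ortho.set(a, b, max(0, int(round(rng.normal(mean, cfg.ortho_sd)))))

    truth = {
        "clade_of": clade_of,
        "clade_regimes": {c: {"has_piwi": p, "has_dnmt": d}
                          for c, (p, d) in enumerate(regimes)},
        "family_superfamily": fam_superfamily,
        "family_active": fam_active,
        "family_kind": fam_kind,
    }
    return Landscape(copies=copies, annotations=annotations, ortho=ortho,
                     truth=truth)


def simulate_hits(copies: Sequence[TECopy], cfg: HitModelConfig) -> HitSet:
    """Draw pairwise alignment hits (and domain hits) over a set of copies.

    Hits are emitted once per unordered pair; the SSN builder's max
    symmetrisation makes direction irrelevant.
    """
    rng = np.random.default_rng(cfg.seed)
    by_family: dict[str, list[TECopy]] = {}
    for c in copies:
        by_family.setdefault(c.family, []).append(c)

    hits: list[AlignmentHit] = []

    def emit(a: TECopy, b: TECopy, mean: float, sd: float) -> None:
        bitscore = max(1.0, rng.normal(mean, sd))
        aln = max(20, int(0.8 * min(a.length_bp, b.length_bp)))
        hits.append(AlignmentHit(
            query_id=a.copy_id, subject_id=b.copy_id,
            pct_identity=float(np.round(rng.uniform(80.0, 100.0), 1)),
            aln_length=aln, qstart=1, qend=aln, sstart=1, send=aln,
            evalue=float(10.0 ** -rng.uniform(20, 120)),
            bitscore=float(np.round(bitscore, 1))))

    families = sorted(by_family)
    for fam in families:
        members = by_family[fam]
        boosted = fam in cfg.dde3_families
        p = 1.0 if boosted else cfg.p_within
        mean = cfg.within_mean * (cfg.dde3_boost if boosted else 1.0)
        for i, a in enumerate(members):
            for b in members[i + 1:]:
                if rng.random() < p:
                    emit(a, b, mean, cfg.within_sd)

    if cfg.p_between > 0 and cfg.between_mean > 0:
        for i, fam_a in enumerate(families):
            for fam_b in families[i + 1:]:
                for a in by_family[fam_a]:
                    for b in by_family[fam_b]:
                        if rng.random() < cfg.p_between:
                            emit(a, b, cfg.between_mean, cfg.between_sd)

    if cfg.convergent_pair is not None:
        fam_a, fam_b = cfg.convergent_pair
        for fam in (fam_a, fam_b):
            if fam not in by_family:
                raise ValueError(f"convergent family {fam!r} has no copies")
        for a in by_family[fam_a]:
            for b in by_family[fam_b]:
                if rng.random() < cfg.p_convergent:
                    emit(a, b, cfg.convergent_mean, cfg.convergent_sd)

    domain_hits: list[DomainHit] = []
    domain_families = set(cfg.active_families) | set(cfg.dde3_families)
    for fam in sorted(domain_families):
        for k, c in enumerate(by_family.get(fam, ())):
            accession = "PF13358" if fam in cfg.dde3_families \
                else _ACTIVE_DOMAINS[k % len(_ACTIVE_DOMAINS)]
            aa_len = max(10, c.length_bp // 3 - 5)
            domain_hits.append(DomainHit(
                copy_id=c.copy_id, pfam_accession=accession,
                domain_name="synthetic_domain",
                evalue=float(10.0 ** -rng.uniform(10, 40)),
                env_start=1, env_end=aa_len))
    return HitSet(hits=hits, domain_hits=domain_hits)


def plant_horizontal_transfer(copies: Sequence[TECopy], donor_family: str,
                              donor_genome: str, recipient_genome: str,
                              n_copies: int = 5,
                              seed: int = 0) -> tuple[list[TECopy], list[str]]:
    """Plant a horizontal-transfer event: new copies of a donor-genome family
    appear in the recipient genome.

    The transferred copies keep the donor family label, so a subsequent
    :func:`simulate_hits` links them tightly to the donor family and the
    rebuilt SSN should place them in the donor family's cluster. Returns the
    augmented copy list and the ids of the transferred copies.
    """
    copies = list(copies)
    if n_copies == 0:
        return copies, []
    if n_copies < 0:
        raise ValueError(f"n_copies must be >= 0, got {n_copies}")
    donors = [c for c in copies if c.family == donor_family
              and c.genome_id == donor_genome]
    if not donors:
        raise ValueError(
            f"donor family {donor_family!r} absent from genome {donor_genome!r}")
    if recipient_genome not in {c.genome_id for c in copies}:
        raise ValueError(f"recipient genome {recipient_genome!r} unknown")
    rng = np.random.default_rng(seed)
    new_ids: list[str] = []
    out = copies[:]
    for _ in range(n_copies):
        template = donors[int(rng.integers(len(donors)))]
        start = int(rng.integers(0, 10_000_000))
        copy_id = make_copy_id(recipient_genome, "chr1", start,
                               start + template.length_bp, template.strand,
                               donor_family, len(out))
        out.append(TECopy(copy_id=copy_id, genome_id=recipient_genome,
                          seq_id="chr1", start=start,
                          end=start + template.length_bp,
                          strand=template.strand, family=donor_family,
                          superfamily=template.superfamily))
        new_ids.append(copy_id)
    return out, new_ids
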