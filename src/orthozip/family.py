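"""bZIP family identification from whole-proteome scans.

The basic leucine zipper (bZIP) DNA-binding module consists of two parts:

* a *basic region* whose core is an invariant asparagine followed, seven
  residues later, by an arginine or lysine (the N-x7-R/K motif), and
* a *leucine zipper*, a heptad repeat of leucine or another bulky
  hydrophobic residue (Ile, Val, Phe or Met) that begins exactly nine
  residues C-terminal of the basic region and mediates dimerization.

:func:`scan_bzip_domain` is a transparent surrogate for a profile-HMM
search: it enumerates every position of a protein satisfying those
constraints.  :func:`identify_family` wraps the scan in the standard
family-cataloguing pipeline (candidate scan, contig removal, domain
verification, redundancy collapse) with explicit audit counts, and
:func:`assign_gene_names` applies the chromosomal naming convention
(short arm before long arm, chromosome 1 to 7, genome A before B before
D).  :func:`protein_properties` computes the usual catalogue columns
(length, average molecular weight, isoelectric point).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

from Bio.SeqUtils import molecular_weight as _bio_molecular_weight

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")
EXTENDED_AA = STANDARD_AA | {"X"}

#: residues accepted at leucine-zipper heptad positions
BULKY_HYDROPHOBIC = set("LIVFM")

#: offset of the first zipper residue from the basic region's R/K
ZIPPER_OFFSET = 9

#: Henderson-Hasselbalch pKa set (EMBOSS-style defaults); overridable.
DEFAULT_PKA = {
    "Nterm": 8.6,
    "Cterm": 3.6,
    "C": 8.5,
    "D": 3.9,
    "E": 4.1,
    "H": 6.5,
    "K": 10.8,
    "R": 12.5,
    "Y": 10.1,
}

_ARM_RANK = {"S": 0, "L": 1, "unknown": 2}


@dataclass(frozen=True)
class ProteinRecord:
    """A single annotated protein with its chromosomal placement.

    ``chromosome`` is a label such as ``"1A"`` or ``"3Bd"``; unplaced
    records use the ``"u<genome>"`` convention (e.g. ``"uA"``).
    Coordinates are 0-based internally.
    """

    id: str
    species: str
    residues: str
    chromosome: Optional[str] = None
    arm: str = "unknown"
    position: int = 0
    is_contig: bool = False

    def __post_init__(self) -> None:
        if self.arm not in _ARM_RANK:
            raise ValueError(f"arm must be S, L or unknown, got {self.arm!r}")
        if self.position < 0:
            raise ValueError("position must be non-negative")

    @property
    def is_placed(self) -> bool:
        return self.chromosome is not None and not self.chromosome.startswith("u")

    @property
    def genome(self) -> str:
        """Genome letter (sub-genome tag) parsed from the chromosome label."""
        if self.chromosome is None:
            return ""
        if self.chromosome.startswith("u"):
            return self.chromosome[1:]
        tag = self.chromosome.lstrip("0123456789")
        return tag

    @property
    def chromosome_number(self) -> int:
        if not self.is_placed:
            return 0
        digits = "".join(ch for ch in self.chromosome if ch.isdigit())
        return int(digits) if digits else 0

    @property
    def chromosomal_location(self) -> str:
        """Human-readable location, e.g. ``1AS`` (Table-2 style)."""
        if self.chromosome is None:
            return "unknown"
        arm = self.arm if self.arm in ("S", "L") else ""
        return f"{self.chromosome}{arm}"


@dataclass(frozen=True)
class DomainHit:
    """One bZIP domain occurrence (0-based indices).

    ``basic_start`` indexes the invariant Asn, ``basic_end`` the R/K
    eight positions later, ``zipper_start`` the first heptad residue and
    ``span`` is the half-open interval covering the whole hit.
    """

    basic_start: int
    basic_end: int
    zipper_start: int
    heptad_count: int
    span: tuple[int, int]


def scan_bzip_domain(
    residues: str,
    min_heptads: int = 2,
    zipper_anchor: str = "rk",
) -> list[DomainHit]:
    """Return every bZIP domain occurrence in ``residues``.

    A hit at position ``i`` requires ``N`` at ``i``, ``R`` or ``K`` at
    ``i + 8``, and at least ``min_heptads`` consecutive heptad positions
    occupied by a bulky hydrophobic residue, the first one
    ``ZIPPER_OFFSET`` residues after the anchor.  ``zipper_anchor``
    selects the anchoring convention: ``"rk"`` (default) measures the
    nine-residue spacing from the basic region's R/K; ``"basic16"``
    measures it from the end of a canonical 16-residue basic region
    starting at the invariant Asn.

    Overlapping hits are all reported, in ascending ``basic_start``.
    Raises :class:`ValueError` on characters outside the amino-acid
    alphabet (20 letters plus X).
    """
    if min_heptads < 1:
        raise ValueError("min_heptads must be >= 1")
    bad = set(residues) - EXTENDED_AA
    if bad:
        raise ValueError(f"non amino-acid characters in sequence: {sorted(bad)}")
    if zipper_anchor == "rk":
        zipper_from_start = 8 + ZIPPER_OFFSET
    elif zipper_anchor == "basic16":
        zipper_from_start = 15 + ZIPPER_OFFSET
    else:
        raise ValueError("zipper_anchor must be 'rk' or 'basic16'")

    n = len(residues)
    hits: list[DomainHit] = []
    for i in range(n):
        if residues[i] != "N":
            continue
        if i + 8 >= n or residues[i + 8] not in ("R", "K"):
            continue
        zipper_start = i + zipper_from_start
        count = 0
        pos = zipper_start
        while pos < n and residues[pos] in BULKY_HYDROPHOBIC:
            count += 1
            pos += 7
        if count >= min_heptads:
            last = zipper_start + 7 * (count - 1)
            hits.append(
                DomainHit(
                    basic_start=i,
                    basic_end=i + 8,
                    zipper_start=zipper_start,
                    heptad_count=count,
                    span=(i, last + 1),
                )
            )
    return hits


@dataclass(frozen=True)
class AuditCounts:
    """Stage-by-stage record sizes of the family identification pipeline.

    The counts telescope: ``candidates - contigs_removed -
    domainless_removed - duplicates_collapsed == members``.
    """

    candidates: int
    contigs_removed: int
    domainless_removed: int
    duplicates_collapsed: int
    members: int

    def telescopes(self) -> bool:
        return (
            self.candidates
            - self.contigs_removed
            - self.domainless_removed
            - self.duplicates_collapsed
            == self.members
        )


@dataclass
class FamilyMember:
    """One family catalogue entry (Table-2 style columns)."""

    record: ProteinRecord
    domain_span: tuple[int, int]  # 1-based inclusive, catalogue convention
    assigned_name: Optional[str] = None
    cds_length: Optional[int] = None
    protein_length: int = 0
    molecular_weight: Optional[float] = None  # kDa
    isoelectric_point: Optional[float] = None

    @property
    def source_id(self) -> str:
        return self.record.id

    @property
    def chromosomal_location(self) -> str:
        return self.record.chromosomal_location


def identify_family(
    proteome: Sequence[ProteinRecord],
    min_heptads: int = 2,
    candidate_min_heptads: Optional[int] = None,
    zipper_anchor: str = "rk",
    cds_lengths: Optional[Mapping[str, int]] = None,
) -> tuple[list[FamilyMember], AuditCounts]:
    """Identify family members in a proteome.

    Pipeline: (1) candidate set — every record with at least one domain
    hit (at ``candidate_min_heptads`` if given, else ``min_heptads``);
    (2) remove contig-derived records; (3) verify the domain at the
    strict ``min_heptads`` threshold and drop records failing it (a
    no-op when both thresholds coincide, retained as an explicit audit
    stage); (4) collapse exact duplicate sequences, keeping the first
    id in input order.  Returns the members and the audit counts.
    """
    loose = candidate_min_heptads if candidate_min_heptads is not None else min_heptads
    if loose > min_heptads:
        raise ValueError("candidate_min_heptads must not exceed min_heptads")

    candidates = [
        rec
        for rec in proteome
        if scan_bzip_domain(rec.residues, loose, zipper_anchor)
    ]
    n_candidates = len(candidates)

    non_contig = [rec for rec in candidates if not rec.is_contig]
    n_contigs_removed = n_candidates - len(non_contig)

    verified: list[tuple[ProteinRecord, list[DomainHit]]] = []
    for rec in non_contig:
        hits = scan_bzip_domain(rec.residues, min_heptads, zipper_anchor)
        if hits:
            verified.append((rec, hits))
    n_domainless_removed = len(non_contig) - len(verified)

    seen: dict[str, str] = {}
    unique: list[tuple[ProteinRecord, list[DomainHit]]] = []
    for rec, hits in verified:
        if rec.residues in seen:
            continue
        seen[rec.residues] = rec.id
        unique.append((rec, hits))
    n_dupes = len(verified) - len(unique)

    members = []
    for rec, hits in unique:
        first = hits[0]
        cds_len = cds_lengths.get(rec.id) if cds_lengths else None
        if set(rec.residues) <= STANDARD_AA:
            length, mw, pi = protein_properties(rec.residues, cds_len)
        else:  # X residues: properties undefined, length still known
            length, mw, pi = len(rec.residues), None, None
        members.append(
            FamilyMember(
                record=rec,
                domain_span=(first.span[0] + 1, first.span[1]),
                cds_length=cds_len,
                protein_length=length,
                molecular_weight=mw,
                isoelectric_point=pi,
            )
        )
    audit = AuditCounts(
        candidates=n_candidates,
        contigs_removed=n_contigs_removed,
        domainless_removed=n_domainless_removed,
        duplicates_collapsed=n_dupes,
        members=len(members),
    )
    return members, audit


def assign_gene_names(
    members: Sequence[FamilyMember], prefix: str
) -> list[FamilyMember]:
    """Assign ``prefix1..prefixN`` by chromosomal order.

    Sort key: genome letter (A < B < D, alphabetical), chromosome number
    1..7, arm (S before L), ascending position.  Unplaced records sort
    after all placed ones, ordered by id.  Raises on duplicated
    (chromosome, arm, position, id) tuples.
    """
    keys = set()
    for m in members:
        key = (m.record.chromosome, m.record.arm, m.record.position, m.record.id)
        if key in keys:
            raise ValueError(f"duplicate placement {key}")
        keys.add(key)

    def sort_key(m: FamilyMember):
        r = m.record
        if r.is_placed:
            return (0, r.genome, r.chromosome_number, _ARM_RANK[r.arm], r.position, r.id)
        return (1, "", 0, 0, 0, r.id)

    ordered = sorted(members, key=sort_key)
    return [
        replace_name(m, f"{prefix}{i + 1}") for i, m in enumerate(ordered)
    ]


def replace_name(member: FamilyMember, name: str) -> FamilyMember:
    out = FamilyMember(
        record=member.record,
        domain_span=member.domain_span,
        assigned_name=name,
        cds_length=member.cds_length,
        protein_length=member.protein_length,
        molecular_weight=member.molecular_weight,
        isoelectric_point=member.isoelectric_point,
    )
    return out


def merge_curated(
    members: Sequence[FamilyMember], curated_ids: Iterable[str]
) -> list[str]:
    """Append literature-curated gene ids absent from the scan catalogue.

    Returns the full catalogue id list; duplicates of existing source
    ids are ignored, mirroring the usual practice of adding previously
    published members to a genome-scan catalogue.
    """
    catalogue = [m.source_id for m in members]
    known = set(catalogue)
    for gid in curated_ids:
        if gid not in known:
            catalogue.append(gid)
            known.add(gid)
    return catalogue


def net_charge(residues: str, ph: float, pka: Optional[Mapping[str, float]] = None) -> float:
    """Net protein charge at ``ph`` under the Henderson–Hasselbalch model.

    Termini plus D, E, C, Y (acidic) and H, K, R (basic) side chains.
    """
    pk = dict(DEFAULT_PKA)
    if pka:
        pk.update(pka)
    pos = 1.0 / (1.0 + 10 ** (ph - pk["Nterm"]))
    neg = 1.0 / (1.0 + 10 ** (pk["Cterm"] - ph))
    for aa in "KRH":
        pos += residues.count(aa) / (1.0 + 10 ** (ph - pk[aa]))
    for aa in "DECY":
        neg += residues.count(aa) / (1.0 + 10 ** (pk[aa] - ph))
    return pos - neg


def isoelectric_point(
    residues: str,
    pka: Optional[Mapping[str, float]] = None,
    tol: float = 0.01,
) -> float:
    """pH at which the net charge crosses zero, by bisection on [0, 14]."""
    lo, hi = 0.0, 14.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if net_charge(residues, mid, pka) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def protein_properties(
    residues: str,
    cds_length: Optional[int] = None,
    pka: Optional[Mapping[str, float]] = None,
) -> tuple[int, float, float]:
    """Return (length, molecular weight in kDa, isoelectric point).

    Molecular weight is the sum of average residue masses plus one water
    mass.  If ``cds_length`` is given it must be a multiple of three and
    satisfy ``length == cds_length / 3 - 1`` (the stop codon is not
    translated).
    """
    if not residues:
        raise ValueError("empty residue string")
    bad = set(residues) - STANDARD_AA
    if bad:
        raise ValueError(f"non-standard residues: {sorted(bad)}")
    length = len(residues)
    if cds_length is not None:
        if cds_length % 3 != 0:
            raise ValueError(f"cds_length {cds_length} not a multiple of 3")
        expected = cds_length // 3 - 1
        if length != expected:
            raise ValueError(
                f"protein length {length} != cds_length/3 - 1 = {expected}"
            )
    mw_kda = _bio_molecular_weight(residues, seq_type="protein") / 1000.0
    pi = isoelectric_point(residues, pka)
    return length, mw_kda, pi
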