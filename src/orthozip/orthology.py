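"""Pairwise protein scoring and InParanoid-style ortholog clustering.

Within a pair of species, *seed orthologs* are the mutually
best-scoring cross-species gene pairs (reciprocal best hits).
*In-paralogs* are same-species genes that score at least as well
against their seed as the seed pair scores against each other — i.e.
duplicates postdating the speciation — and each carries a *confidence*
on a 0–100 % scale interpolating between the seed pair's cross-species
score (0 %) and the seed's self-score (100 %).

Scoring follows the BLAST conventions the original InParanoid workflow
consumes: Smith–Waterman local alignment under BLOSUM62 with affine
gaps, raw scores converted to bits through the Karlin–Altschul
transform ``(lambda * S - ln K) / ln 2``.  Candidate pairs must pass
both a bit-score cutoff (default 50 bits) and an overlap cutoff (the
aligned region must exceed half of the longer sequence, default 0.5).

This is a deterministic distillation of InParanoid 7: the bootstrap
confidence estimate and multi-step group-merging heuristics are
replaced by the explicit rules above, with lexicographic gene-id
tie-breaks throughout, so results are exactly reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from .family import ProteinRecord


@dataclass(frozen=True)
class ScoringScheme:
    """Alignment scoring parameters and Karlin–Altschul constants.

    A gap of length k costs ``gap_open + k * gap_extend`` (BLAST
    convention).  Defaults are the conventional gapped-protein values:
    BLOSUM62, open 11, extend 1, lambda 0.267, K 0.041.
    """

    matrix: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0
    karlin_lambda: float = 0.267
    karlin_k: float = 0.041

    def bits(self, raw_score: float) -> float:
        return (self.karlin_lambda * raw_score - math.log(self.karlin_k)) / math.log(2)


DEFAULT_SCHEME = ScoringScheme()

#: BLASTN-like nucleotide scheme used by the probe-mapping step.
NUCLEOTIDE_SCHEME = ScoringScheme(
    matrix="NUC.4.4", gap_open=2.0, gap_extend=2.0, karlin_lambda=1.28, karlin_k=0.46
)


def _make_aligner(scheme: ScoringScheme, nucleotide: bool = False) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    if nucleotide:
        aligner.match_score = 1.0
        aligner.mismatch_score = -2.0
    else:
        aligner.substitution_matrix = substitution_matrices.load(scheme.matrix)
    # PairwiseAligner charges open_gap_score for the first gap position
    # and extend_gap_score for each further one; shift to cost(k) = open + k*extend.
    aligner.open_gap_score = -(scheme.gap_open + scheme.gap_extend)
    aligner.extend_gap_score = -scheme.gap_extend
    return aligner


@dataclass(frozen=True)
class ScoredPair:
    """One pairwise comparison surviving (or not) the cutoffs."""

    query_id: str
    subject_id: str
    raw_score: float
    bit_score: float
    overlap_fraction: float


def local_align_bitscore(
    a: str,
    b: str,
    scheme: ScoringScheme = DEFAULT_SCHEME,
    query_id: str = "a",
    subject_id: str = "b",
    nucleotide: bool = False,
) -> ScoredPair:
    """Smith–Waterman local alignment of ``a`` vs ``b`` in bits.

    ``overlap_fraction`` is the span of the optimal local alignment on
    the longer sequence divided by that sequence's length.  Empty
    sequences (or a zero raw score) give bit_score 0 and overlap 0.
    """
    if not a or not b:
        return ScoredPair(query_id, subject_id, 0.0, 0.0, 0.0)
    aligner = _make_aligner(scheme, nucleotide)
    raw = aligner.score(a, b)
    if raw <= 0:
        return ScoredPair(query_id, subject_id, float(raw), 0.0, 0.0)
    alignment = aligner.align(a, b)[0]
    blocks_a, blocks_b = alignment.aligned
    span_a = int(blocks_a[-1][1] - blocks_a[0][0])
    span_b = int(blocks_b[-1][1] - blocks_b[0][0])
    if len(a) > len(b):
        overlap = span_a / len(a)
    elif len(b) > len(a):
        overlap = span_b / len(b)
    else:
        overlap = max(span_a, span_b) / len(a)
    return ScoredPair(query_id, subject_id, float(raw), scheme.bits(raw), overlap)


@dataclass
class ScoreTable:
    """Symmetric table of pairwise scores passing both cutoffs.

    ``pairs`` maps the sorted id pair to the surviving :class:`ScoredPair`;
    ``self_scores`` keeps every gene's self-alignment bit score
    (needed for the confidence denominator) regardless of cutoffs.
    """

    species_of: dict[str, str]
    pairs: dict[tuple[str, str], ScoredPair] = field(default_factory=dict)
    self_scores: dict[str, float] = field(default_factory=dict)

    @staticmethod
    def _key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def get_bits(self, a: str, b: str) -> Optional[float]:
        if a == b:
            return self.self_scores.get(a)
        pair = self.pairs.get(self._key(a, b))
        return pair.bit_score if pair is not None else None

    def has_pair(self, a: str, b: str) -> bool:
        return self._key(a, b) in self.pairs

    def species(self) -> list[str]:
        return sorted(set(self.species_of.values()))

    def genes(self, species: str) -> list[str]:
        return sorted(g for g, sp in self.species_of.items() if sp == species)


def all_vs_all(
    proteome_a: Sequence[ProteinRecord],
    proteome_b: Sequence[ProteinRecord],
    scheme: ScoringScheme = DEFAULT_SCHEME,
    bit_cutoff: float = 50.0,
    overlap_cutoff: float = 0.5,
) -> ScoreTable:
    """All-against-all scoring of two proteomes with the stated cutoffs.

    Retains only pairs with ``bit_score >= bit_cutoff`` AND
    ``overlap_fraction > overlap_cutoff``.  Within-species pairs are
    included (they drive in-paralog detection).  The table is symmetric
    by construction.  Self-scores are recorded separately for every gene.
    """
    records = list(proteome_a) + list(proteome_b)
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("gene ids must be unique across both proteomes")
    table = ScoreTable(species_of={r.id: r.species for r in records})
    aligner = _make_aligner(scheme)
    for rec in records:
        if rec.residues:
            table.self_scores[rec.id] = scheme.bits(
                float(aligner.score(rec.residues, rec.residues))
            )
        else:
            table.self_scores[rec.id] = 0.0
    for i, ri in enumerate(records):
        for rj in records[i + 1 :]:
            if not ri.residues or not rj.residues:
                continue
            raw = float(aligner.score(ri.residues, rj.residues))
            if raw <= 0 or scheme.bits(raw) < bit_cutoff:
                continue
            pair = local_align_bitscore(
                ri.residues, rj.residues, scheme, ri.id, rj.id
            )
            if pair.bit_score >= bit_cutoff and pair.overlap_fraction > overlap_cutoff:
                table.pairs[ScoreTable._key(ri.id, rj.id)] = pair
    return table


@dataclass
class OrthologGroup:
    """A seed ortholog pair with its per-species in-paralogs.

    ``members_a``/``members_b`` list ``(gene_id, confidence)`` with the
    seed first at 100 %, then in-paralogs by descending confidence
    (ties broken by gene id).
    """

    group_id: str
    species_pair: tuple[str, str]
    seed_a: str
    seed_b: str
    seed_score: float  # cross-species bit score of the seed pair
    members_a: list[tuple[str, float]]
    members_b: list[tuple[str, float]]

    def gene_ids(self) -> set[str]:
        return {g for g, _ in self.members_a} | {g for g, _ in self.members_b}

    def members(self, species: str) -> list[tuple[str, float]]:
        if species == self.species_pair[0]:
            return self.members_a
        if species == self.species_pair[1]:
            return self.members_b
        raise KeyError(species)


def _confidence(bits_to_seed: float, seed_cross: float, seed_self: float) -> float:
    denom = seed_self - seed_cross
    if denom <= 0:
        return 100.0
    conf = 100.0 * (bits_to_seed - seed_cross) / denom
    return min(100.0, max(0.0, conf))


def cluster_orthologs(
    table: ScoreTable, species_a: str, species_b: str
) -> list[OrthologGroup]:
    """Cluster a two-species score table into ortholog groups.

    1. Seed orthologs are the mutually best-scoring cross-species pairs
       (best-partner ties broken by lexicographic gene id).
    2. Each seed attracts, as in-paralog candidates, the same-species
       genes whose surviving score to the seed is at least the seed
       pair's cross-species score.
    3. Confidence interpolates between the seed cross score (0 %) and
       the seed self score (100 %), clipped to [0, 100]; seeds are 100 %.
    4. A gene eligible for several groups joins the one where its
       confidence is highest; ties go to the higher-scoring seed, then
       to the lexicographically smaller seed pair.  Seed genes stay with
       their own group.

    Groups are returned in descending seed score (ties by seed ids).
    """
    species = set(table.species_of.values())
    if not species <= {species_a, species_b}:
        raise ValueError(
            f"score table spans {sorted(species)}, expected subset of "
            f"{{{species_a!r}, {species_b!r}}}"
        )
    genes_a = table.genes(species_a)
    genes_b = table.genes(species_b)

    cross: dict[str, dict[str, float]] = {g: {} for g in genes_a + genes_b}
    for (x, y), pair in table.pairs.items():
        if table.species_of[x] != table.species_of[y]:
            cross[x][y] = pair.bit_score
            cross[y][x] = pair.bit_score

    # deterministic best partner: max bits, ties -> lexicographically smaller id
    def best(g: str) -> Optional[str]:
        partners = cross[g]
        if not partners:
            return None
        top = max(partners.values())
        return min(p for p, s in partners.items() if s == top)

    seeds = []
    for ga in genes_a:
        gb = best(ga)
        if gb is not None and best(gb) == ga:
            seeds.append((ga, gb))
    seeds.sort(key=lambda s: (-cross[s[0]][s[1]], s[0], s[1]))
    seed_genes = {g for pair in seeds for g in pair}

    # candidate confidences: gene -> list of (conf, seed index)
    candidacies: dict[str, list[tuple[float, int]]] = {}
    for idx, (sa, sb) in enumerate(seeds):
        seed_cross = cross[sa][sb]
        for seed_gene in (sa, sb):
            sp = table.species_of[seed_gene]
            pool = genes_a if sp == species_a else genes_b
            seed_self = table.self_scores.get(seed_gene, 0.0)
            for x in pool:
                if x in seed_genes:
                    continue
                if not table.has_pair(x, seed_gene):
                    continue
                bits = table.get_bits(x, seed_gene)
                if bits is None or bits < seed_cross:
                    continue
                conf = _confidence(bits, seed_cross, seed_self)
                candidacies.setdefault(x, []).append((conf, idx))

    assignment: dict[str, tuple[float, int]] = {}
    for gene, cands in candidacies.items():
        # highest confidence; ties -> higher seed score, then smaller seed ids,
        # which is exactly ascending seed index given the seed sort order.
        best_cand = max(cands, key=lambda c: (c[0], -c[1]))
        assignment[gene] = best_cand

    groups: list[OrthologGroup] = []
    for idx, (sa, sb) in enumerate(seeds):
        in_a: list[tuple[str, float]] = []
        in_b: list[tuple[str, float]] = []
        for gene, (conf, gidx) in assignment.items():
            if gidx != idx:
                continue
            if table.species_of[gene] == species_a:
                in_a.append((gene, conf))
            else:
                in_b.append((gene, conf))
        in_a.sort(key=lambda t: (-t[1], t[0]))
        in_b.sort(key=lambda t: (-t[1], t[0]))
        groups.append(
            OrthologGroup(
                group_id=f"OG{idx + 1}",
                species_pair=(species_a, species_b),
                seed_a=sa,
                seed_b=sb,
                seed_score=cross[sa][sb],
                members_a=[(sa, 100.0)] + in_a,
                members_b=[(sb, 100.0)] + in_b,
            )
        )
    return groups
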