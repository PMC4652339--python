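"""Independent brute-force oracles used only by the test suite.

Each oracle re-derives an expected result from first principles with no
shared code path: a plain Gotoh dynamic program for local alignment, an
exhaustive constraint scan for the bZIP motif, a literal rule-by-rule
clustering, and a grid search for the isoelectric point.
"""

from __future__ import annotations

import numpy as np
from Bio.Align import substitution_matrices

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def sw_affine_score(
    a: str,
    b: str,
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
    match: float | None = None,
    mismatch: float | None = None,
) -> float:
    """Smith-Waterman with affine gaps; a gap of length k costs open + k*extend.

    Protein scoring uses BLOSUM62 unless explicit match/mismatch scores
    are given (nucleotide mode).
    """
    n, m = len(a), len(b)
    if n == 0 or m == 0:
        return 0.0
    neg = -1e9
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), neg)  # gap in a (consume b)
    F = np.full((n + 1, m + 1), neg)  # gap in b (consume a)
    best = 0.0
    first_cost = gap_open + gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            if match is not None:
                s = match if a[i - 1] == b[j - 1] else mismatch
            else:
                s = _BLOSUM62[a[i - 1]][b[j - 1]]
            E[i][j] = max(H[i][j - 1] - first_cost, E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - first_cost, F[i - 1][j] - gap_extend)
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            if H[i][j] > best:
                best = H[i][j]
    return float(best)


def exhaustive_bzip_scan(
    residues: str, min_heptads: int = 2, zipper_offset_from_start: int = 17
) -> list[tuple[int, int]]:
    """Every (basic_start, heptad_count) satisfying the motif constraints.

    Checks each start position independently: N at i, R/K at i+8, then
    counts consecutive heptad positions (stride 7 from
    i + zipper_offset_from_start) holding L/I/V/F/M.
    """
    hydrophobic = set("LIVFM")
    found = []
    for i in range(len(residues)):
        if residues[i] != "N":
            continue
        j = i + 8
        if j >= len(residues) or residues[j] not in {"R", "K"}:
            continue
        count = 0
        p = i + zipper_offset_from_start
        while p < len(residues) and residues[p] in hydrophobic:
            count += 1
            p += 7
        if count >= min_heptads:
            found.append((i, count))
    return found


def grid_search_pi(residues: str, pka: dict, step: float = 0.001) -> float:
    """pH on a uniform grid minimizing |net charge| of the HH model."""
    best_ph, best_abs = 0.0, float("inf")
    ph = 0.0
    while ph <= 14.0 + 1e-9:
        pos = 1.0 / (1.0 + 10 ** (ph - pka["Nterm"]))
        neg = 1.0 / (1.0 + 10 ** (pka["Cterm"] - ph))
        for aa in "KRH":
            pos += residues.count(aa) / (1.0 + 10 ** (ph - pka[aa]))
        for aa in "DECY":
            neg += residues.count(aa) / (1.0 + 10 ** (pka[aa] - ph))
        q = abs(pos - neg)
        if q < best_abs:
            best_abs, best_ph = q, ph
        ph += step
    return best_ph


def brute_force_cluster(table, species_a: str, species_b: str):
    """Literal application of the seed/in-paralog/confidence rules.

    Returns a list of dicts {"seed": (a, b), "members": {gene: conf}}
    in descending seed score, mirroring the published rule set with
    plain list scans (no indexing structures).
    """
    ids = sorted(table.species_of)
    genes_a = [g for g in ids if table.species_of[g] == species_a]
    genes_b = [g for g in ids if table.species_of[g] == species_b]

    def cross_score(x, y):
        if table.species_of[x] == table.species_of[y]:
            return None
        key = (x, y) if x <= y else (y, x)
        pair = table.pairs.get(key)
        return pair.bit_score if pair else None

    def within_score(x, y):
        if table.species_of[x] != table.species_of[y]:
            return None
        key = (x, y) if x <= y else (y, x)
        pair = table.pairs.get(key)
        return pair.bit_score if pair else None

    def best_cross(g):
        best, best_s = None, None
        for other in ids:
            s = cross_score(g, other)
            if s is None:
                continue
            if best_s is None or s > best_s or (s == best_s and other < best):
                best, best_s = other, s
        return best

    seeds = []
    for ga in genes_a:
        gb = best_cross(ga)
        if gb is not None and best_cross(gb) == ga:
            seeds.append((ga, gb))
    seeds.sort(key=lambda p: (-cross_score(p[0], p[1]), p[0], p[1]))
    seed_genes = set()
    for pair in seeds:
        seed_genes.update(pair)

    # candidate confidences per gene
    cands = {}
    for idx, (sa, sb) in enumerate(seeds):
        s_cross = cross_score(sa, sb)
        for seed_gene in (sa, sb):
            pool = genes_a if table.species_of[seed_gene] == species_a else genes_b
            s_self = table.self_scores.get(seed_gene, 0.0)
            for x in pool:
                if x in seed_genes or x == seed_gene:
                    continue
                s = within_score(x, seed_gene)
                if s is None or s < s_cross:
                    continue
                if s_self - s_cross > 0:
                    conf = 100.0 * (s - s_cross) / (s_self - s_cross)
                    conf = max(0.0, min(100.0, conf))
                else:
                    conf = 100.0
                cands.setdefault(x, []).append((conf, idx))

    groups = [
        {"seed": (sa, sb), "members": {sa: 100.0, sb: 100.0}} for sa, sb in seeds
    ]
    for gene, options in cands.items():
        chosen = None
        for conf, idx in options:
            if chosen is None:
                chosen = (conf, idx)
                continue
            c0, i0 = chosen
            if conf > c0 or (conf == c0 and idx < i0):
                chosen = (conf, idx)
        conf, idx = chosen
        groups[idx]["members"][gene] = conf
    return groups
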