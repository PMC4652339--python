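"""Family identification: motif scan, pipeline audit, naming, properties."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from orthozip import (
    ProteinRecord,
    assign_gene_names,
    identify_family,
    isoelectric_point,
    merge_curated,
    protein_properties,
    scan_bzip_domain,
)
from orthozip.family import DEFAULT_PKA

from .oracles import exhaustive_bzip_scan, grid_search_pi


def _rec(id, residues, species="sp", chrom="1A", arm="S", pos=0, contig=False):
    return ProteinRecord(
        id=id,
        species=species,
        residues=residues,
        chromosome=chrom,
        arm=arm,
        position=pos,
        is_contig=contig,
    )


# sequence with a clean domain: N at 2, K at 10, L at 19 and 26
DOMAIN_SEQ = "MANAAAAAAAKAAAAAAAALAAAAAALAAA"
# same but zipper broken (G where the first heptad residue should sit)
BROKEN_ZIPPER = "MANAAAAAAAKAAAAAAAAGAAAAAAGAAA"


class TestScan:
    def test_known_motif_coordinates(self):
        hits = scan_bzip_domain(DOMAIN_SEQ)
        assert len(hits) == 1
        hit = hits[0]
        assert hit.basic_start == 2
        assert hit.basic_end == 10
        assert hit.zipper_start == 19
        assert hit.heptad_count == 2
        assert hit.span == (2, 27)

    @pytest.mark.parametrize(
        "sequence",
        ["AAAAAAAAAAAAAAAAAAAA", BROKEN_ZIPPER, "", "NAAAAAAAK"],
        ids=["no-asn", "zipper-unmet", "empty", "too-short"],
    )
    def test_no_hit(self, sequence):
        assert scan_bzip_domain(sequence) == []

    def test_rejects_non_amino_characters(self):
        with pytest.raises(ValueError):
            scan_bzip_domain("MANB1AAAK")

    def test_matches_exhaustive_oracle_on_random_strings(self):
        """Scan agrees exactly with a constraint-checking oracle."""
        rnd = random.Random(7)
        alphabet = "ACDEFGHIKLMNPQRSTVWYX"
        for _ in range(1000):
            length = rnd.randint(0, 200)
            # enrich motif characters so hits actually occur
            seq = "".join(rnd.choice(alphabet + "NNKKRLLIV") for _ in range(length))
            hits = scan_bzip_domain(seq)
            oracle = exhaustive_bzip_scan(seq)
            assert [(h.basic_start, h.heptad_count) for h in hits] == oracle
            assert [h.basic_start for h in hits] == sorted(h.basic_start for h in hits)

    def test_basic16_anchor_shifts_zipper(self):
        # zipper anchored 9 residues after a 16-residue basic region
        seq = "N" + "A" * 7 + "K" + "A" * 15 + "L" + "A" * 6 + "L"
        assert scan_bzip_domain(seq, zipper_anchor="rk") == []
        hits = scan_bzip_domain(seq, zipper_anchor="basic16")
        assert len(hits) == 1 and hits[0].zipper_start == 24


class TestIdentifyFamily:
    def test_empty_proteome(self):
        members, audit = identify_family([])
        assert members == []
        assert audit.candidates == audit.members == 0
        assert audit.telescopes()

    def test_contig_and_verification_filters(self):
        """100 candidates, 3 contig-derived, 1 failing strict verification."""
        proteome = []
        for i in range(96):
            proteome.append(_rec(f"ok{i}", DOMAIN_SEQ + "V" * i))
        for i in range(3):
            proteome.append(_rec(f"contig|c{i}", DOMAIN_SEQ + "W" * (i + 1), contig=True))
        # one heptad only: passes the loose candidate scan, fails verification
        proteome.append(_rec("weak", "MANAAAAAAAKAAAAAAAALAAAAAAGAAA"))
        members, audit = identify_family(
            proteome, min_heptads=2, candidate_min_heptads=1
        )
        assert audit.candidates == 100
        assert audit.contigs_removed == 3
        assert audit.domainless_removed == 1
        assert audit.members == len(members) == 96
        assert audit.telescopes()

    def test_duplicate_collapse_keeps_first(self):
        proteome = [_rec("a", DOMAIN_SEQ), _rec("b", DOMAIN_SEQ)]
        members, audit = identify_family(proteome)
        assert [m.source_id for m in members] == ["a"]
        assert audit.duplicates_collapsed == 1

    def test_idempotent(self, two_species_cohort):
        proteome = two_species_cohort.proteomes["aspec"]
        members, _ = identify_family(proteome)
        again, audit = identify_family([m.record for m in members])
        assert [m.source_id for m in again] == [m.source_id for m in members]
        assert audit.contigs_removed == audit.duplicates_collapsed == 0

    def test_recovers_planted_carriers(self, two_species_cohort):
        """Family scan finds exactly the genes carrying a planted domain."""
        for species, proteome in two_species_cohort.proteomes.items():
            members, _ = identify_family(proteome)
            found = {m.source_id for m in members}
            planted = {
                r.id
                for r in proteome
                if r.id in two_species_cohort.truth_bzip_ids and not r.is_contig
            }
            assert found == planted

    def test_curated_additions_extend_catalogue(self):
        members, _ = identify_family([_rec("a", DOMAIN_SEQ)])
        catalogue = merge_curated(members, ["lit1", "lit2", "a"])
        assert catalogue == ["a", "lit1", "lit2"]


class TestNaming:
    def test_short_arm_before_long_arm_before_next_chromosome(self):
        members, _ = identify_family(
            [
                _rec("x", DOMAIN_SEQ, chrom="1A", arm="S", pos=100),
                _rec("y", DOMAIN_SEQ + "V", chrom="1A", arm="L", pos=50),
                _rec("z", DOMAIN_SEQ + "W", chrom="2A", arm="S", pos=10),
            ]
        )
        named = assign_gene_names(members, "TabZIP")
        assert [(m.source_id, m.assigned_name) for m in named] == [
            ("x", "TabZIP1"),
            ("y", "TabZIP2"),
            ("z", "TabZIP3"),
        ]

    def test_genome_order_dominates(self):
        members, _ = identify_family(
            [
                _rec("late", DOMAIN_SEQ, chrom="7D", arm="L", pos=1),
                _rec("early", DOMAIN_SEQ + "V", chrom="1A", arm="S", pos=999),
            ]
        )
        named = assign_gene_names(members, "N")
        by_name = {m.assigned_name: m.source_id for m in named}
        assert by_name["N1"] == "early" and by_name["N2"] == "late"

    def test_unplaced_sorted_after_placed_by_id(self):
        members, _ = identify_family(
            [
                _rec("u2", DOMAIN_SEQ, chrom="uA", arm="unknown"),
                _rec("u1", DOMAIN_SEQ + "V", chrom="uA", arm="unknown"),
                _rec("p", DOMAIN_SEQ + "W", chrom="3A", arm="L", pos=5),
            ]
        )
        named = assign_gene_names(members, "N")
        assert [m.source_id for m in named] == ["p", "u1", "u2"]

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.permutations(range(6)))
    def test_order_invariance(self, perm):
        """Naming is a bijection independent of input permutation."""
        base = [
            _rec(f"g{i}", DOMAIN_SEQ + "V" * i, chrom=f"{1 + i % 3}A",
                 arm="S" if i % 2 else "L", pos=i * 13)
            for i in range(6)
        ]
        members, _ = identify_family(base)
        reference = {
            m.source_id: m.assigned_name for m in assign_gene_names(members, "N")
        }
        shuffled, _ = identify_family([base[i] for i in perm])
        renamed = {
            m.source_id: m.assigned_name for m in assign_gene_names(shuffled, "N")
        }
        assert renamed == reference
        assert len(set(renamed.values())) == len(renamed)

    def test_duplicate_placement_rejected(self):
        members, _ = identify_family([_rec("a", DOMAIN_SEQ)])
        with pytest.raises(ValueError):
            assign_gene_names(members + members, "N")


class TestProperties:
    def test_glycine_closed_form(self):
        length, mw, _pi = protein_properties("G")
        assert length == 1
        assert mw == pytest.approx(0.07507, abs=2e-4)

    def test_cds_length_consistency(self):
        seq = "A" * 150
        length, _, _ = protein_properties(seq, cds_length=453)
        assert length == 150
        with pytest.raises(ValueError):
            protein_properties(seq, cds_length=452)  # not a codon multiple
        with pytest.raises(ValueError):
            protein_properties(seq, cds_length=300)  # inconsistent length

    def test_against_independent_mass_table_and_grid_pi(self):
        """Mw equals an independent residue-mass sum; pI matches a grid search."""
        masses = {  # standard average residue masses (Da)
            "A": 71.0788, "C": 103.1388, "D": 115.0886, "E": 129.1155,
            "G": 57.0519, "H": 137.1411, "I": 113.1594, "K": 128.1741,
        }
        seq = "ACDEGHIK"
        length, mw, pi = protein_properties(seq)
        expected = (sum(masses[aa] for aa in seq) + 18.0153) / 1000.0
        assert mw == pytest.approx(expected, rel=1e-4)
        assert pi == pytest.approx(grid_search_pi(seq, DEFAULT_PKA), abs=0.01)

    @pytest.mark.parametrize("seq", ["KKKKRRRR", "DDEEDDEE", "ACDEFGHIKLMNPQRSTVWY"])
    def test_pi_matches_grid_search(self, seq):
        pi = isoelectric_point(seq, tol=0.001)
        assert pi == pytest.approx(grid_search_pi(seq, DEFAULT_PKA), abs=0.01)

    def test_basic_protein_has_high_pi(self):
        assert isoelectric_point("KKKKRRRR") > 10
        assert isoelectric_point("DDEEDDEE") < 4
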