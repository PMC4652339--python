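"""Relative quantification, DE filtering, probe mapping and mode calls."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from orthozip import (
    CtTable,
    classify_expression_mode,
    de_filter,
    delta_delta_ct,
    map_probes_to_genes,
    responsiveness_class,
    simulate_ct_panel,
)
from orthozip.expression import (
    MODE_HIGH,
    MODE_LOW,
    MODE_OVER,
    MODE_UNCLASSIFIED,
    MODE_UNDER,
)


def _ct_table(values, conditions, reference="ref", calibrator="c0"):
    frame = pd.DataFrame(values)
    return CtTable(
        values=frame,
        sample_condition=conditions,
        reference_gene=reference,
        calibrator=calibrator,
    )


class TestDeltaDeltaCt:
    def test_equal_cts_give_unit_folds(self):
        table = _ct_table(
            {"s1": {"ref": 20.0, "g": 25.0}, "s2": {"ref": 20.0, "g": 25.0}},
            {"s1": "c0", "s2": "c1"},
        )
        rel = delta_delta_ct(table)
        assert rel.folds.loc["g", "c0"] == 1.0
        assert rel.folds.loc["g", "c1"] == 1.0

    def test_one_cycle_earlier_doubles_expression(self):
        table = _ct_table(
            {"s1": {"ref": 20.0, "g": 25.0}, "s2": {"ref": 20.0, "g": 24.0}},
            {"s1": "c0", "s2": "c1"},
        )
        assert delta_delta_ct(table).folds.loc["g", "c1"] == 2.0

    def test_positive_ddct_means_downregulation(self):
        table = _ct_table(
            {"s1": {"ref": 20.0, "g": 25.0}, "s2": {"ref": 20.0, "g": 27.0}},
            {"s1": "c0", "s2": "c1"},
        )
        assert delta_delta_ct(table).folds.loc["g", "c1"] == 0.25

    def test_reference_required_everywhere(self):
        table = _ct_table(
            {"s1": {"ref": 20.0, "g": 25.0}, "s2": {"ref": np.nan, "g": 24.0}},
            {"s1": "c0", "s2": "c1"},
        )
        with pytest.raises(ValueError):
            delta_delta_ct(table)

    def test_inverts_simulated_panel_at_zero_noise(self):
        folds = {"g1": 1.0, "g2": 8.0, "g3": 0.3}
        rel = delta_delta_ct(simulate_ct_panel(folds, noise_sd=0.0, seed=2))
        for gene, fold in folds.items():
            assert rel.folds.loc[gene, "control"] == pytest.approx(1.0)
            assert rel.folds.loc[gene, "treated"] == pytest.approx(fold)

    def test_fold_eight_is_three_cycles(self):
        ct = simulate_ct_panel({"g": 8.0}, noise_sd=0.0)
        control = ct.values.loc["g", ct.samples_of("control")].mean()
        treated = ct.values.loc["g", ct.samples_of("treated")].mean()
        assert control - treated == pytest.approx(3.0)  # log2(8)

    def test_rejects_nonpositive_folds(self):
        with pytest.raises(ValueError):
            simulate_ct_panel({"g": 0.0})


class TestDeFilter:
    def test_constant_matrix_passes_nothing(self):
        mat = pd.DataFrame(5.0, index=["g1", "g2"], columns=list("abcd"))
        res = de_filter(mat, ["a", "b"], ["c", "d"])
        assert (res["p_value"] == 1.0).all()
        assert not res["passes"].any()

    def test_planted_fold_changes_detected_with_direction(self, rng):
        n_null, n_de = 80, 20
        a = rng.normal(8.0, 0.1, size=(n_null + n_de, 3))
        b = a + rng.normal(0, 0.1, size=a.shape)
        b[:n_de] += 2.0  # 4-fold down in group A relative to B
        mat = pd.DataFrame(
            np.hstack([a, b]), columns=[f"a{i}" for i in range(3)] + [f"b{i}" for i in range(3)]
        )
        res = de_filter(mat, [f"a{i}" for i in range(3)], [f"b{i}" for i in range(3)])
        assert res["passes"].iloc[:n_de].all()
        assert (res["direction"].iloc[:n_de] == "down").all()

    def test_null_type_one_error_calibrated(self):
        rng = np.random.default_rng(5)
        mat = pd.DataFrame(
            rng.normal(size=(2000, 6)), columns=[f"s{i}" for i in range(6)]
        )
        res = de_filter(mat, ["s0", "s1", "s2"], ["s3", "s4", "s5"])
        frac = (res["p_value"] < 0.05).mean()
        assert 0.03 <= frac <= 0.07

    def test_bh_adjustment_monotone_and_alpha_nested(self):
        rng = np.random.default_rng(8)
        mat = pd.DataFrame(
            rng.normal(size=(300, 6)), columns=[f"s{i}" for i in range(6)]
        )
        mat.iloc[:30, 3:] += 3.0
        res = de_filter(mat, ["s0", "s1", "s2"], ["s3", "s4", "s5"])
        assert (res["adjusted_p"] >= res["p_value"] - 1e-12).all()
        ordered = res.sort_values("p_value")
        assert ordered["adjusted_p"].is_monotonic_increasing
        strict = de_filter(mat, ["s0", "s1", "s2"], ["s3", "s4", "s5"], alpha=0.01)
        assert set(strict.index[strict["passes"]]) <= set(res.index[res["passes"]])

    def test_requires_two_replicates(self):
        mat = pd.DataFrame(np.zeros((3, 3)), columns=["a", "b", "c"])
        with pytest.raises(ValueError):
            de_filter(mat, ["a"], ["b", "c"])


class TestProbeMapping:
    CDS = (
        "ATGGCTGAGCGTAAACTGGTTGACGAAATCCGTGCTGCTCTGGCTGAAGCTGGTATCGAA"
        "CGTCTGGAAGCTATCGCTGAAGCTCTGCGTGAAGCTGGTATCGACCTGGCTGAAAAATAA"
    )

    @staticmethod
    def _protein(cds):
        from Bio.Seq import Seq

        return str(Seq(cds).translate()).rstrip("*")

    def test_exact_substring_probe_maps(self):
        probe = self.CDS[15:75]
        res = map_probes_to_genes(
            {"p1": probe}, {"g1": self.CDS}, {"g1": self._protein(self.CDS)}
        )
        row = res.iloc[0]
        assert row["mapped"]
        assert row["e_value_cds"] < 1e-5
        assert row["e_value_protein"] < 1e-3

    def test_random_probe_does_not_map(self, rng):
        probe = "".join(rng.choice(list("ACGT"), size=60))
        cds = "".join(rng.choice(list("ACGT"), size=999))
        res = map_probes_to_genes({"p1": probe}, {"g1": cds}, {"g1": self._protein(cds)})
        assert not res.iloc[0]["mapped"]
        assert res.iloc[0]["e_value_cds"] > 1e-5

    def test_conjunction_rule(self, rng):
        # nucleotide-exact probe vs a gene whose protein entry is unrelated
        probe = self.CDS[:60]
        unrelated_protein = "TYTRPSPSNWYQCDEKHMG" * 8
        res = map_probes_to_genes(
            {"p1": probe}, {"g1": self.CDS}, {"g1": unrelated_protein}
        )
        row = res.iloc[0]
        assert row["e_value_cds"] <= 1e-5 and row["e_value_protein"] > 1e-3
        assert not row["mapped"]

    def test_multi_gene_hits_flagged_ambiguous(self):
        probe = self.CDS[15:75]
        prot = self._protein(self.CDS)
        res = map_probes_to_genes(
            {"p1": probe},
            {"g1": self.CDS, "g2": self.CDS},
            {"g1": prot, "g2": prot},
        )
        assert res["mapped"].all()
        assert res["ambiguous"].all()


class TestResponsiveness:
    @pytest.mark.parametrize(
        "course,expected",
        [
            ([1, 12, 30, 8], "strong"),
            ([1, 59.4, 2.0], "strong"),
            ([1, 1.1, 0.95], "unresponsive"),
            ([1, 3.0, 0.8], "weak"),
            ([1, 1.2, 0.4], "weak"),
        ],
    )
    def test_classes(self, course, expected):
        assert responsiveness_class(course) == expected

    def test_empty_course_rejected(self):
        with pytest.raises(ValueError):
            responsiveness_class([])
        with pytest.raises(ValueError):
            responsiveness_class([1.0])


class TestModeClassification:
    def test_over_dominance(self):
        call = classify_expression_mode(
            [10.0, 10.2, 9.8], [5.0, 5.1, 4.9], [6.0, 6.2, 5.8]
        )
        assert call.mode == MODE_OVER
        assert call.p_parent1 < 0.05 and call.p_parent2 < 0.05
        assert call.mid_parent_deviation_sign == 1

    def test_under_dominance(self):
        call = classify_expression_mode(
            [1.0, 1.1, 0.9], [5.0, 5.1, 4.9], [6.0, 6.2, 5.8]
        )
        assert call.mode == MODE_UNDER

    def test_low_parent_dominance(self):
        call = classify_expression_mode(
            [2.0, 2.1, 1.9], [8.0, 8.2, 7.8], [2.05, 1.95, 2.0]
        )
        assert call.mode == MODE_LOW

    def test_high_parent_dominance(self):
        call = classify_expression_mode(
            [8.1, 7.9, 8.0], [8.0, 8.2, 7.8], [2.05, 1.95, 2.0]
        )
        assert call.mode == MODE_HIGH

    def test_identical_replicates_unclassified_with_warning(self):
        with pytest.warns(UserWarning):
            call = classify_expression_mode([2.0, 2.0], [2.0, 2.0], [2.0, 2.0])
        assert call.mode == MODE_UNCLASSIFIED

    def test_no_significant_contrast_unclassified(self, rng):
        base = rng.normal(5.0, 0.5, size=9)
        call = classify_expression_mode(base[:3], base[3:6], base[6:])
        assert call.mode == MODE_UNCLASSIFIED

    def test_matches_welch_oracle_pvalues(self):
        f1, p1, p2 = [10.0, 10.2, 9.8], [5.0, 5.1, 4.9], [6.0, 6.2, 5.8]
        call = classify_expression_mode(f1, p1, p2)
        assert call.p_parent1 == pytest.approx(
            stats.ttest_ind(f1, p1, equal_var=False).pvalue
        )
        assert call.p_parent2 == pytest.approx(
            stats.ttest_ind(f1, p2, equal_var=False).pvalue
        )

    def test_invariant_under_parent_swap(self, rng):
        """Over/under unchanged; high/low follow the parents, not labels."""
        for _ in range(50):
            f1 = rng.normal(rng.uniform(0, 10), 0.2, size=3)
            p1 = rng.normal(rng.uniform(0, 10), 0.2, size=3)
            p2 = rng.normal(rng.uniform(0, 10), 0.2, size=3)
            a = classify_expression_mode(f1, p1, p2)
            b = classify_expression_mode(f1, p2, p1)
            assert a.mode == b.mode
            assert a.p_parent1 == pytest.approx(b.p_parent2)
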