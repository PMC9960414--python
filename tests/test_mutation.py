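import numpy as np
import pandas as pd
import pytest

from metabosub.data_io import GeneCoordinates, MutationTable, SegmentTable
from metabosub.errors import ValidationError
from metabosub.mutation import (
    build_mutation_matrix,
    call_cnv_from_ploidy,
    call_cnv_from_segments,
    chi2_on_table,
    subtype_frequencies,
)
from metabosub.mutation import test_gene_by_subtype as gene_subtype_test  # noqa: avoid pytest collection
from metabosub.subtyping import SubtypeCall


def coords(genes=("G1",), chrom="1", start=1000, end=2000, spacing=10_000):
    return GeneCoordinates(pd.DataFrame({
        "gene": list(genes), "chrom": [chrom] * len(genes),
        "start": [start + i * spacing for i in range(len(genes))],
        "end": [end + i * spacing for i in range(len(genes))]}))


def seg(rows):
    return SegmentTable(pd.DataFrame(
        rows, columns=["sample_id", "chrom", "start", "end",
                       "num_probes", "seg_mean"]))


class TestPloidyCalls:
    @pytest.mark.parametrize("status,expected", [
        (0, "deleted"), (1, "deleted"), (2, None), (3, "amplified"), (5, "amplified"),
    ])
    def test_thresholds(self, status, expected):
        calls = call_cnv_from_ploidy(pd.DataFrame({"G1": [status]}, index=["S1"]))
        if expected is None:
            assert calls == []
        else:
            assert len(calls) == 1
            assert calls[0].direction == expected
            assert calls[0].source == "ploidy"

    def test_negative_status_is_error(self):
        with pytest.raises(ValidationError):
            call_cnv_from_ploidy(pd.DataFrame({"G1": [-1]}, index=["S1"]))


class TestSegmentCalls:
    def test_passing_segment_amplifies_overlapping_gene(self):
        calls = call_cnv_from_segments(seg([("S1", "1", 900, 1500, 12, 0.25)]),
                                       coords())
        assert [(c.gene, c.direction) for c in calls] == [("G1", "amplified")]

    def test_mean_threshold_is_strict(self):
        assert call_cnv_from_segments(seg([("S1", "1", 900, 1500, 50, 0.2)]),
                                      coords()) == []
        assert call_cnv_from_segments(seg([("S1", "1", 900, 1500, 50, -0.2)]),
                                      coords()) == []

    def test_probe_threshold_is_inclusive(self):
        assert call_cnv_from_segments(seg([("S1", "1", 900, 1500, 9, 0.9)]),
                                      coords()) == []
        assert len(call_cnv_from_segments(seg([("S1", "1", 900, 1500, 10, 0.9)]),
                                          coords())) == 1

    def test_deletion_direction(self):
        calls = call_cnv_from_segments(seg([("S1", "1", 900, 1500, 30, -0.5)]),
                                       coords())
        assert calls[0].direction == "deleted"

    def test_single_base_overlap_counts(self):
        calls = call_cnv_from_segments(seg([("S1", "1", 2000, 3000, 30, 0.5)]),
                                       coords())  # gene ends at 2000
        assert len(calls) == 1
        assert call_cnv_from_segments(seg([("S1", "1", 2001, 3000, 30, 0.5)]),
                                      coords()) == []

    def test_unknown_chromosome_is_error(self):
        with pytest.raises(ValidationError, match="chr7"):
            call_cnv_from_segments(seg([("S1", "chr7", 1, 10, 30, 0.5)]), coords())

    def test_segment_order_invariance(self):
        rows = [("S1", "1", 900, 1500, 30, 0.5), ("S2", "1", 900, 1500, 30, -0.5)]
        a = call_cnv_from_segments(seg(rows), coords())
        b = call_cnv_from_segments(seg(rows[::-1]), coords())
        assert sorted((c.sample_id, c.gene, c.direction) for c in a) == \
            sorted((c.sample_id, c.gene, c.direction) for c in b)

    def test_split_segment_invariance(self):
        whole = call_cnv_from_segments(seg([("S1", "1", 900, 1500, 40, 0.5)]),
                                       coords())
        halves = call_cnv_from_segments(
            seg([("S1", "1", 900, 1200, 20, 0.5), ("S1", "1", 1201, 1500, 20, 0.5)]),
            coords())
        assert [(c.gene, c.direction) for c in whole] == \
            [(c.gene, c.direction) for c in halves]

    def test_conflicting_calls_both_recorded(self, caplog):
        import logging
        with caplog.at_level(logging.WARNING):
            calls = call_cnv_from_segments(
                seg([("S1", "1", 900, 1200, 20, 0.5),
                     ("S1", "1", 1300, 1600, 20, -0.5)]), coords())
        assert {c.direction for c in calls} == {"amplified", "deleted"}
        assert any("conflicting" in r.message for r in caplog.records)


class TestBuildMatrix:
    def muts(self, rows):
        return MutationTable(pd.DataFrame(
            rows, columns=["sample_id", "gene", "variant_class", "chrom", "pos"]))

    def test_multiple_snvs_collapse_to_binary(self):
        m = self.muts([("S1", "TP53", "SNV", "1", i) for i in range(3)])
        matrix = build_mutation_matrix(m, [], ["S1"], ["TP53"])
        assert matrix.altered.loc["S1", "TP53"] == True  # noqa: E712
        assert matrix.snv_indel.to_numpy().sum() == 1

    def test_absent_sample_is_wild_type(self):
        m = self.muts([("S1", "TP53", "SNV", "1", 5)])
        matrix = build_mutation_matrix(m, [], ["S1", "S2"], ["TP53"])
        assert matrix.altered.loc["S2", "TP53"] == False  # noqa: E712

    def test_cnv_only_alteration(self):
        from metabosub.mutation import CnvCall
        matrix = build_mutation_matrix(
            self.muts([]), [CnvCall("S1", "TP53", "amplified", "segment")],
            ["S1"], ["TP53"])
        assert matrix.altered.loc["S1", "TP53"] == True  # noqa: E712
        assert matrix.snv_indel.loc["S1", "TP53"] == False  # noqa: E712

    def test_altered_is_or_of_classes(self):
        from metabosub.mutation import CnvCall
        m = self.muts([("S1", "TP53", "SNV", "1", 5)])
        matrix = build_mutation_matrix(
            m, [CnvCall("S2", "TP53", "deleted", "ploidy")], ["S1", "S2", "S3"],
            ["TP53"])
        expected = matrix.snv_indel | matrix.amplified | matrix.deleted
        pd.testing.assert_frame_equal(matrix.altered, expected)

    def test_empty_panel_is_error(self):
        with pytest.raises(ValidationError):
            build_mutation_matrix(self.muts([]), [], ["S1"], [])


def make_calls(subtype_counts):
    calls = []
    i = 0
    for subtype, count in subtype_counts.items():
        for _ in range(count):
            calls.append(SubtypeCall(f"S{i}", subtype, 0.0, 0.0))
            i += 1
    return calls


class TestContingency:
    def matrix_from_flags(self, flags, gene="TP53"):
        samples = [f"S{i}" for i in range(len(flags))]
        df = pd.DataFrame({gene: [bool(f) for f in flags]}, index=samples)
        from metabosub.mutation import GeneMutationMatrix
        false = pd.DataFrame(False, index=samples, columns=[gene])
        return GeneMutationMatrix(df, false.copy(), false.copy(), df.copy())

    def test_homogeneous_table_p_one(self):
        counts = {"quiescent": 20, "glycolytic": 20, "cholesterogenic": 20,
                  "mixed": 20}
        calls = make_calls(counts)
        flags = ([1] * 10 + [0] * 10) * 4
        results = gene_subtype_test(self.matrix_from_flags(flags), calls)
        assert results[0].statistic == pytest.approx(0.0, abs=1e-12)
        assert results[0].p_value == pytest.approx(1.0)

    def test_chi2_matches_textbook_oracle(self):
        table = np.array([[20, 5, 5, 5], [30, 45, 45, 45]], dtype=float)
        statistic, p = chi2_on_table(table)
        # textbook formula: sum (O - E)^2 / E with E = row*col/total
        row = table.sum(axis=1, keepdims=True)
        col = table.sum(axis=0, keepdims=True)
        expected = row @ col / table.sum()
        oracle = ((table - expected) ** 2 / expected).sum()
        assert statistic == pytest.approx(oracle, abs=1e-8)
        from scipy import stats
        assert p == pytest.approx(stats.chi2.sf(oracle, 3), abs=1e-10)

    def test_small_counts_use_monte_carlo(self):
        counts = {"quiescent": 6, "glycolytic": 6}
        calls = make_calls(counts)
        flags = [1, 0, 0, 0, 0, 0, 1, 1, 1, 1, 1, 0]
        results = gene_subtype_test(self.matrix_from_flags(flags), calls,
                                       mc_reps=2000, seed=1)
        assert results[0].test_used == "fisher"
        assert 0 < results[0].p_value <= 1

    def test_monte_carlo_deterministic_under_seed(self):
        counts = {"quiescent": 6, "glycolytic": 6}
        calls = make_calls(counts)
        flags = [1, 0, 0, 0, 0, 0, 1, 1, 1, 1, 1, 0]
        a = gene_subtype_test(self.matrix_from_flags(flags), calls,
                                 mc_reps=2000, seed=7)
        b = gene_subtype_test(self.matrix_from_flags(flags), calls,
                                 mc_reps=2000, seed=7)
        assert a[0].p_value == b[0].p_value

    def test_single_subtype_is_error(self):
        calls = make_calls({"quiescent": 10})
        with pytest.raises(ValidationError):
            gene_subtype_test(self.matrix_from_flags([1] * 5 + [0] * 5), calls)

    def test_q_values_are_bh_adjusted(self):
        rng = np.random.default_rng(3)
        counts = {"quiescent": 40, "glycolytic": 40, "cholesterogenic": 40,
                  "mixed": 40}
        calls = make_calls(counts)
        samples = [c.sample_id for c in calls]
        genes = [f"G{i}" for i in range(5)]
        df = pd.DataFrame(rng.random((160, 5)) < 0.4, index=samples, columns=genes)
        from metabosub.mutation import GeneMutationMatrix
        false = pd.DataFrame(False, index=samples, columns=genes)
        matrix = GeneMutationMatrix(df, false.copy(), false.copy(), df.copy())
        results = gene_subtype_test(matrix, calls)
        from statsmodels.stats.multitest import multipletests
        expected_q = multipletests([r.p_value for r in results], method="fdr_bh")[1]
        np.testing.assert_allclose([r.q_value for r in results], expected_q)


class TestSyntheticFrequencies:
    def test_planted_frequencies_recovered(self, default_cohort):
        cohort = default_cohort
        truth = cohort.truth_subtypes
        calls = [SubtypeCall(s, truth[s], 0.0, 0.0) for s in truth.index]
        matrix = build_mutation_matrix(cohort.mutations, [],
                                       list(truth.index),
                                       list(cohort.gene_coords.df["gene"]))
        freqs = subtype_frequencies(matrix, calls)
        from metabosub.synthetic_data import DEFAULT_MUTATION_FREQS
        from metabosub.subtyping import SUBTYPES
        counts = truth.value_counts()
        for gene, planted in DEFAULT_MUTATION_FREQS.items():
            for subtype, p in zip(SUBTYPES, planted):
                n = counts[subtype]
                se = np.sqrt(p * (1 - p) / n)
                assert abs(freqs.loc[gene, subtype] - p) <= 3 * se + 1e-9, \
                    (gene, subtype)
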