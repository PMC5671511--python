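import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

from codonlab import (
    CdsSimConfig,
    CodonCounts,
    ExpressionTable,
    StratificationConfig,
    adjust_fdr,
    codon_bias_test,
    count_codons,
    detect_bias,
    fisher_exact_two_sided,
    pool_counts,
    rank_scan,
    simulate_cds_set,
    simulate_expression,
    standard_code,
    stratify_by_expression,
)
from codonlab.bias_detection import UntestableCodonError

from _oracles import all_tables_with_margins_at_most, fisher_two_sided_oracle


class TestStratify:
    @pytest.fixture()
    def expr(self):
        return ExpressionTable.from_pairs(
            [("g1", 500_000.0), ("g2", 300_000.0), ("g3", 100_000.0)]
        )

    def test_threshold_mode(self, expr):
        strata = stratify_by_expression(expr, StratificationConfig())
        assert strata["strong"] == {"g1", "g2"}
        assert strata["high"] == {"g1"}
        assert strata["all"] == {"g1", "g2", "g3"}

    def test_background_is_inclusive(self, expr):
        strata = stratify_by_expression(expr, StratificationConfig())
        assert strata["high"] <= strata["all"]

    def test_top_n_mode(self, expr):
        strata = stratify_by_expression(
            expr, StratificationConfig(mode="top_n", n=2)
        )
        assert strata["top"] == {"g1", "g2"}

    def test_top_n_too_large(self, expr):
        with pytest.raises(ValueError, match="exceeds"):
            stratify_by_expression(expr, StratificationConfig(mode="top_n", n=4))

    def test_cutoff_order_enforced(self):
        with pytest.raises(ValueError, match="high_cutoff"):
            StratificationConfig(strong_cutoff=1000, high_cutoff=10)

    def test_duplicate_gene_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            ExpressionTable.from_pairs([("g1", 1.0), ("g1", 2.0)])


class TestFisherExact:
    def test_derived_example_8_2_50_50(self):
        # frozen from the exact hypergeometric enumeration oracle
        expected = fisher_two_sided_oracle(8, 2, 50, 50)
        assert expected == pytest.approx(0.09852833648227365, abs=1e-15)
        assert fisher_exact_two_sided(8, 2, 50, 50) == pytest.approx(expected, abs=1e-12)

    def test_identical_proportions_give_p_one(self):
        assert fisher_exact_two_sided(5, 5, 50, 50) == 1.0

    def test_degenerate_margins_give_p_one(self):
        assert fisher_exact_two_sided(0, 0, 3, 4) == 1.0
        assert fisher_exact_two_sided(0, 3, 0, 4) == 1.0

    def test_negative_entries_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_two_sided(-1, 2, 3, 4)

    def test_oracle_agreement_small_margins(self):
        for a, b, c, d in all_tables_with_margins_at_most(8):
            assert fisher_exact_two_sided(a, b, c, d) == pytest.approx(
                fisher_two_sided_oracle(a, b, c, d), abs=1e-12
            )

    def test_large_table_path_matches_scipy(self):
        from scipy.stats import fisher_exact

        table = (700, 1500, 900, 1400)  # total > exact-arithmetic limit
        expected = fisher_exact([[700, 1500], [900, 1400]])[1]
        assert fisher_exact_two_sided(*table) == pytest.approx(expected, rel=1e-12)


class TestCodonBiasTest:
    def test_derived_example_direction_over(self):
        group = CodonCounts.from_mapping({"AAA": 8, "AAG": 2})
        background = CodonCounts.from_mapping({"AAA": 50, "AAG": 50})
        p, direction = codon_bias_test(group, background, "AAA")
        assert p == pytest.approx(fisher_two_sided_oracle(8, 2, 50, 50), abs=1e-12)
        assert direction == "over"

    def test_no_association_p_one(self):
        group = CodonCounts.from_mapping({"AAA": 5, "AAG": 5})
        background = CodonCounts.from_mapping({"AAA": 50, "AAG": 50})
        p, direction = codon_bias_test(group, background, "AAA")
        assert p == 1.0
        assert direction == "tie"

    def test_single_codon_family_untestable(self):
        group = CodonCounts.from_mapping({"ATG": 5})
        background = CodonCounts.from_mapping({"ATG": 50})
        with pytest.raises(UntestableCodonError):
            codon_bias_test(group, background, "ATG")

    def test_stop_codon_untestable(self):
        group = CodonCounts.from_mapping({"TAA": 5})
        with pytest.raises(UntestableCodonError):
            codon_bias_test(group, group, "TAA")

    def test_vs_all_mode_uses_sense_totals(self):
        group = CodonCounts.from_mapping({"AAA": 8, "GGG": 2})
        background = CodonCounts.from_mapping({"AAA": 5, "GGG": 5})
        p, direction = codon_bias_test(group, background, "AAA", mode="vs_all")
        assert p == pytest.approx(fisher_two_sided_oracle(8, 2, 5, 5), abs=1e-12)
        assert direction == "over"


class TestAdjustFdr:
    def test_hand_computed_stepup(self):
        assert adjust_fdr([0.01, 0.02, 0.03, 0.04]) == pytest.approx(
            [0.04, 0.04, 0.04, 0.04], abs=1e-15
        )

    def test_single_value_identity(self):
        assert adjust_fdr([0.03]) == [0.03]

    def test_all_ones(self):
        assert adjust_fdr([1.0, 1.0]) == [1.0, 1.0]

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_fdr([0.5, 1.5])

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=50))
    @settings(max_examples=200)
    def test_matches_statsmodels_bh(self, p):
        expected = multipletests(p, method="fdr_bh")[1]
        assert adjust_fdr(p) == pytest.approx(list(expected), abs=1e-12)

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=50))
    @settings(max_examples=100)
    def test_matches_statsmodels_holm(self, p):
        expected = multipletests(p, method="holm")[1]
        assert adjust_fdr(p, method="holm") == pytest.approx(list(expected), abs=1e-12)

    def test_permutation_equivariance(self, rng):
        p = rng.uniform(size=30)
        q = np.array(adjust_fdr(p.tolist()))
        perm = rng.permutation(30)
        q_perm = np.array(adjust_fdr(p[perm].tolist()))
        assert np.allclose(q[perm], q_perm, atol=1e-15)

    def test_monotone_in_p(self, rng):
        p = rng.uniform(size=40)
        q = np.array(adjust_fdr(p.tolist()))
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)


class TestDetectBias:
    def test_group_equal_background_no_findings(self, planted_sim):
        _, _, _, _, background = planted_sim
        for alpha in (0.05, 0.5, 0.99):
            result = detect_bias(background, background, alpha=alpha)
            assert result.significant_codons == frozenset()
            assert result.biased_amino_acids == frozenset()

    def test_planted_families_recovered(self, planted_sim):
        _, truth, _, group, background = planted_sim
        result = detect_bias(group, background, alpha=0.05)
        assert set(truth.biased_families) <= result.biased_amino_acids

    def test_m_counts_only_testable_codons(self, planted_sim):
        _, _, _, group, background = planted_sim
        result = detect_bias(group, background)
        tested = {r.codon for r in result.results}
        assert "ATG" not in tested and "TGG" not in tested
        assert "TAA" not in tested
        assert len(tested) == 59

    def test_result_counts_bounded_by_family_totals(self, planted_sim):
        _, _, _, group, background = planted_sim
        for r in detect_bias(group, background):
            assert r.group_count <= r.group_family_total
            assert r.background_count <= r.background_family_total

    def test_parameter_recovery_across_seeds(self):
        """Planted recall >= 80% and family-level false positives <= 1 over 20 seeds."""
        planted = ("E", "F", "K", "N", "Q")
        recalls, false_positives = [], []
        for seed in range(20):
            cfg = CdsSimConfig(
                n_genes=220, biased_subset_size=20, bias_strength=5.0,
                biased_families=planted, seed=seed,
            )
            records, truth = simulate_cds_set(cfg)
            counts = [count_codons(r) for r in records]
            group = pool_counts(counts[:20])
            background = pool_counts(counts)
            found = detect_bias(group, background).biased_amino_acids
            recalls.append(len(found & set(planted)) / len(planted))
            false_positives.append(len(found - set(planted)))
        assert np.mean(recalls) >= 0.8
        assert max(false_positives) <= 1

    def test_null_simulation_error_rate(self):
        """Group drawn from background frequencies: few significant codons."""
        n_sig = []
        for seed in range(40):
            cfg = CdsSimConfig(
                n_genes=120, biased_subset_size=12, bias_strength=1.0, seed=seed
            )
            records, truth = simulate_cds_set(cfg)
            counts = [count_codons(r) for r in records]
            group = pool_counts(counts[:12])
            background = pool_counts(counts)
            n_sig.append(len(detect_bias(group, background).significant_codons))
        assert np.mean(n_sig) <= 0.05 * 59


@pytest.fixture(scope="module")
def scan_inputs():
    cfg = CdsSimConfig(
        n_genes=150, biased_subset_size=50, bias_strength=6.0, seed=99
    )
    records, truth = simulate_cds_set(cfg)
    expr = simulate_expression(
        [r.id for r in records], truth.biased_gene_ids,
        loc_background=11.0, loc_biased=14.0, sigma=0.3, seed=100,
    )
    cds_index = {r.id: count_codons(r) for r in records}
    return expr, cds_index, truth


class TestRankScan:

    def test_recovers_planted_families_at_subset_size(self, scan_inputs):
        expr, cds_index, truth = scan_inputs
        code = standard_code()
        table = rank_scan(expr, cds_index, [50, 150])
        row_50 = table.rows[0]
        found_aas = {code.aa_of(c) for c in row_50.significant_codons}
        assert set(truth.biased_families) <= found_aas

    def test_full_table_self_comparison_is_null(self, scan_inputs):
        expr, cds_index, _ = scan_inputs
        table = rank_scan(expr, cds_index, [len(expr)])
        assert table.rows[0].significant_codons == ()
        assert table.rows[0].n_significant_amino_acids == 0

    def test_non_increasing_grid_rejected(self, scan_inputs):
        expr, cds_index, _ = scan_inputs
        with pytest.raises(ValueError, match="strictly increasing"):
            rank_scan(expr, cds_index, [50, 50])

    def test_grid_exceeding_gene_count_rejected(self, scan_inputs):
        expr, cds_index, _ = scan_inputs
        with pytest.raises(ValueError, match="exceeds"):
            rank_scan(expr, cds_index, [10, 10_000])

    def test_rows_strictly_increasing_invariant(self, scan_inputs):
        expr, cds_index, _ = scan_inputs
        table = rank_scan(expr, cds_index, [10, 50, 150])
        ns = [r.n_top for r in table.rows]
        assert ns == sorted(set(ns))
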