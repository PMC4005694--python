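"""Expected-count model and the three deviation statistics."""

from __future__ import annotations

import math

import numpy as np
import pytest

from codonreuse.genome_io import read_fasta_cds
from codonreuse.pair_counting import ClassProfile, PairCountTable, class_profile, count_pairs, family_stream
from codonreuse.pair_stats import (
    assemble_deviation_table,
    binomial_z,
    expected_counts,
    log2_norm,
    percent_deviation,
)
from codonreuse.synthetic_data import SyntheticConfig, generate_genome


def ser2_profile(families):
    # codon class counts back-solved from the published expected block
    return ClassProfile(family="Ser2", codons=families["Ser2"].codons,
                        counts=np.array([1637, 1092]))


class TestExpectedCounts:
    def test_class_occurrence_normalization(self, families):
        exp = expected_counts(ser2_profile(families))
        assert exp.n_used == 2729
        assert exp.expected[0, 0] == pytest.approx(1637**2 / 2729)
        assert exp.expected[0, 0] == pytest.approx(982, abs=0.5)
        assert exp.expected.sum() == pytest.approx(exp.n_used, rel=1e-9)

    def test_uniform_frequencies_give_flat_expected(self, families):
        p = ClassProfile(family="Ser4", codons=families["Ser4"].codons,
                         counts=np.full(4, 400))
        exp = expected_counts(p)
        np.testing.assert_allclose(exp.expected, 100.0)

    def test_degenerate_single_codon_profile(self, families):
        p = ClassProfile(family="Ser2", codons=families["Ser2"].codons,
                         counts=np.array([50, 0]))
        exp = expected_counts(p)
        assert exp.expected[0, 0] == pytest.approx(50)

    def test_empty_profile_skipped(self, families):
        p = ClassProfile(family="Ser2", codons=families["Ser2"].codons,
                         counts=np.zeros(2, dtype=int))
        assert expected_counts(p) is None

    def test_pair_total_normalization_sums_to_pair_count(self, families):
        fam = families["Ser2"]
        pairs = PairCountTable(family="Ser2", codons=fam.codons,
                               counts=np.array([[5, 3], [2, 4]]), strategy="consecutive")
        exp = expected_counts(ser2_profile(families), "pair_total", pairs)
        assert exp.expected.sum() == pytest.approx(pairs.n_pairs, rel=1e-9)


class TestPercentDeviation:
    @pytest.mark.parametrize("count, expected, want", [
        (3680, 3505, 4.993),    # Ser4 TCA-TCA
        (1149, 982, 17.006),    # Ser2 AGC-AGC
        (300, 246, 21.951),     # Ser4 TCT-TCT
        (214, 165, 29.697),     # Arg4 CGG-CGG
    ])
    def test_published_cells_to_three_decimals(self, count, expected, want):
        assert percent_deviation(count, expected) == pytest.approx(want, abs=5e-4)

    def test_zero_when_count_equals_expected(self):
        assert percent_deviation(400, 400.0) == 0.0

    def test_zero_expected_with_positive_count_is_nan(self):
        assert math.isnan(percent_deviation(3, 0.0))


class TestBinomialZ:
    def test_direct_evaluation(self):
        # frozen from an independent evaluation of (C-E)/sqrt(N p (1-p))
        n, e, c = 14857, 3505.0, 3680
        p = e / n
        want = (c - e) / math.sqrt(n * p * (1 - p))
        assert binomial_z(c, e, n, math.sqrt(p), math.sqrt(p)) == pytest.approx(want)
        assert want == pytest.approx(3.382, abs=2e-3)

    def test_zero_at_expected(self):
        assert binomial_z(100, 100.0, 1000, 0.2, 0.5) == 0.0

    def test_scales_with_sqrt_n_at_fixed_frequencies(self):
        f_i = f_j = 0.5
        z1 = binomial_z(300, 250.0, 1000, f_i, f_j)
        z2 = binomial_z(600, 500.0, 2000, f_i, f_j)
        assert z2 == pytest.approx(z1 * math.sqrt(2))

    def test_degenerate_probability_is_nan(self):
        assert math.isnan(binomial_z(5, 5.0, 100, 1.0, 1.0))


class TestLog2Norm:
    def test_zero_under_exact_independence(self):
        # C / n_pairs exactly f_i * f_j
        assert log2_norm(25, 400, 0.25, 0.25, 4, pseudocount=0.0) == pytest.approx(0.0)

    def test_matches_count_ratio_and_pct_identity(self):
        # with pair-total normalisation: log2(C/E) = log2(1 + pct/100)
        n, f = 14857, 3505.0 / 14857
        val = log2_norm(3680, n, math.sqrt(f), math.sqrt(f), 4, pseudocount=0.0)
        assert val == pytest.approx(math.log2(3680 / 3505.0), abs=1e-9)
        pct = percent_deviation(3680, 3505.0)
        assert val == pytest.approx(math.log2(1 + pct / 100), abs=1e-9)
        assert val == pytest.approx(0.0703, abs=5e-4)

    def test_pseudocount_guards_zero_counts(self):
        val = log2_norm(0, 100, 0.25, 0.25, 4, pseudocount=0.5)
        assert math.isfinite(val) and val < 0


class TestAssembleDeviationTable:
    def test_ser2_block_reproduces_published_percent_deviations(self, families):
        """Counts + class profile through the full assembly path match the
        four published Ser2 percent deviations (rounded-expected precision)."""
        fam = families["Ser2"]
        counts = np.array([[1149, 718], [677, 513]])
        pairs = PairCountTable(family="Ser2", codons=fam.codons, counts=counts,
                               strategy="consecutive")
        profile = ser2_profile(families)
        table = assemble_deviation_table(pairs, expected_counts(profile), profile)
        got = table.matrix("pct_dev")
        want = np.array([[17.006, 9.618], [3.359, 17.391]])
        # published cells use integer-rounded expected counts
        np.testing.assert_allclose(got, want, atol=0.06)

    def test_identity_input_all_zero_statistics(self, families):
        fam = families["Ser4"]
        profile = ClassProfile(family="Ser4", codons=fam.codons, counts=np.full(4, 400))
        pairs = PairCountTable(family="Ser4", codons=fam.codons,
                               counts=np.full((4, 4), 100), strategy="consecutive")
        exp = expected_counts(profile, "pair_total", pairs)
        table = assemble_deviation_table(pairs, exp, profile)
        np.testing.assert_allclose(table.matrix("pct_dev"), 0.0, atol=1e-9)
        np.testing.assert_allclose(table.matrix("z"), 0.0, atol=1e-9)

    def test_family_mismatch_rejected(self, families):
        fam = families["Ser2"]
        pairs = PairCountTable(family="Ser2", codons=fam.codons,
                               counts=np.ones((2, 2), dtype=int), strategy="consecutive")
        profile = ser2_profile(families)
        exp = expected_counts(profile)
        exp.family = "Arg2"
        with pytest.raises(ValueError, match="mismatch"):
            assemble_deviation_table(pairs, exp, profile)


class TestStatisticalInvariants:
    def test_pair_total_count_weighted_mean_pct_is_zero(self, families):
        rng = np.random.default_rng(11)
        fam = families["Val4"]
        counts = rng.integers(1, 200, size=(4, 4))
        pairs = PairCountTable(family="Val4", codons=fam.codons, counts=counts,
                               strategy="consecutive")
        profile = ClassProfile(family="Val4", codons=fam.codons,
                               counts=rng.integers(100, 500, size=4))
        exp = expected_counts(profile, "pair_total", pairs)
        table = assemble_deviation_table(pairs, exp, profile)
        d = table.data
        weighted = (d["expected"] * d["pct_dev"]).sum() / d["expected"].sum()
        assert abs(weighted) < 1e-9  # E-weighted mean of 100(C-E)/E with sum C = sum E

    def test_binomial_z_is_standard_normal_under_no_reuse(self, families):
        """At rho=0, z computed against the generating frequencies pools to
        |mean| < 0.1 and sd in [0.8, 1.2] across pairs and replicates
        (binomial approximation sanity; overlapping adjacent pairs make the
        per-cell variance deviate mildly from the pure binomial)."""
        fam = families["Val4"]
        f = 0.25
        zs = []
        for seed in range(12):
            cfg = SyntheticConfig(n_genes=250, gene_length=60, rho=0.0, seed=seed,
                                  background={"Val4": 1.0})
            records, _ = generate_genome(cfg, families=[fam])
            streams = [family_stream(r, fam) for r in records]
            pairs = count_pairs(streams, fam, "consecutive")
            assert pairs.n_pairs >= 10_000
            n = pairs.n_pairs
            for i in range(4):
                for j in range(4):
                    zs.append(binomial_z(pairs.counts[i, j], n * f * f, n, f, f))
        zs = np.array(zs)
        assert abs(zs.mean()) < 0.1
        assert 0.8 <= zs.std() <= 1.2
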