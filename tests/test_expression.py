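import numpy as np
import pandas as pd
import pytest

from codonbias import (
    CODONS,
    ExpressionMatrix,
    codon_frequency,
    count_elongator_codons,
    aggregate_genome_usage,
    max_normalize_usage,
    median_of_ratios_size_factors,
    normalize_counts,
    weighted_codon_usage,
)

from conftest import make_catalog
from _naive import naive_weighted_usage


def em(rows, cols, values, size_factors=None):
    matrix = ExpressionMatrix(pd.DataFrame(values, index=rows, columns=cols, dtype=float))
    if size_factors is not None:
        matrix.size_factors = pd.Series(size_factors, index=cols, dtype=float)
    return matrix


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        matrix = em(["g1", "g2"], ["a", "b"], [[10, 10], [3, 3]])
        factors = median_of_ratios_size_factors(matrix)
        assert np.allclose(factors, 1.0)
        assert matrix.size_factors is not None  # attached

    def test_hand_computed_oracle(self):
        """[[2,4],[8,16],[5,10]]: every row ratio to its geometric mean is
        identical, so the median equals it: s = (1/sqrt(2), sqrt(2))."""
        matrix = em(["g1", "g2", "g3"], ["a", "b"], [[2, 4], [8, 16], [5, 10]])
        factors = median_of_ratios_size_factors(matrix)
        assert factors["a"] == pytest.approx(1 / np.sqrt(2), rel=1e-12)
        assert factors["b"] == pytest.approx(np.sqrt(2), rel=1e-12)

    def test_doubling_a_column_doubles_its_relative_factor(self):
        rng = np.random.default_rng(0)
        base = rng.integers(5, 100, size=(40, 3)).astype(float)
        m1 = em([f"g{i}" for i in range(40)], ["a", "b", "c"], base)
        doubled = base.copy()
        doubled[:, 1] *= 2
        m2 = em([f"g{i}" for i in range(40)], ["a", "b", "c"], doubled)
        s1 = median_of_ratios_size_factors(m1)
        s2 = median_of_ratios_size_factors(m2)
        assert (s2["b"] / s2["a"]) == pytest.approx(2 * s1["b"] / s1["a"], rel=1e-9)

    def test_no_reference_row_errors_and_fallback_works(self):
        matrix = em(["g1", "g2"], ["a", "b"], [[0, 4], [8, 0]])
        with pytest.raises(ValueError, match="reference"):
            median_of_ratios_size_factors(matrix)
        factors = median_of_ratios_size_factors(matrix, max_zero_columns=1)
        assert (factors > 0).all()

    def test_single_column_rejected(self):
        matrix = em(["g1"], ["a"], [[5]])
        with pytest.raises(ValueError, match="two columns"):
            median_of_ratios_size_factors(matrix)

    def test_agrees_with_deseq2_reference_implementation(self):
        """Independent cross-check: our median-of-ratios factors match
        pydeseq2's normalisation on a random dense matrix."""
        pydeseq2_pre = pytest.importorskip("pydeseq2.preprocessing")
        rng = np.random.default_rng(21)
        # odd gene count: the median is then transform-equivariant, so the
        # log-space median pydeseq2 uses equals our ratio-space median
        values = rng.integers(1, 500, size=(61, 4)).astype(float)
        rows = [f"g{i}" for i in range(61)]
        cols = ["a", "b", "c", "d"]
        ours = median_of_ratios_size_factors(em(rows, cols, values))
        # pydeseq2 expects samples x genes
        _, theirs = pydeseq2_pre.deseq2_norm(pd.DataFrame(values, index=rows, columns=cols).T)
        assert np.allclose(ours.to_numpy(), np.asarray(theirs), rtol=1e-10)


class TestNormalizeCounts:
    def test_unit_factors_identity(self):
        matrix = em(["g1"], ["a", "b"], [[4, 6]], size_factors=[1, 1])
        assert normalize_counts(matrix).data.equals(matrix.data)

    def test_column_divided_by_factor(self):
        matrix = em(["g1"], ["a", "b"], [[4, 6]], size_factors=[2, 1])
        normalized = normalize_counts(matrix)
        assert normalized.data.loc["g1", "a"] == 2.0
        assert normalized.data.loc["g1", "b"] == 6.0

    def test_idempotent(self):
        matrix = em(["g1", "g2"], ["a", "b"], [[4, 6], [2, 8]], size_factors=[2, 0.5])
        once = normalize_counts(matrix)
        twice = normalize_counts(once)
        assert twice.data.equals(once.data)

    def test_unset_factors_require_flag(self):
        matrix = em(["g1"], ["a", "b"], [[4, 6]])
        with pytest.raises(ValueError, match="size factors"):
            normalize_counts(matrix)
        assert normalize_counts(matrix, pre_normalized=True).data.equals(matrix.data)


class TestWeightedCodonUsage:
    def test_single_gene_usage_is_count_times_frequency(self):
        catalog = make_catalog([("t1", "g1", "ATG" + "ACT" * 5 + "TAA")])
        matrix = em(["g1"], ["fat_body", "muscle"], [[10, 3]], size_factors=[1, 1])
        usage = weighted_codon_usage(catalog, normalize_counts(matrix), "fat_body")
        assert usage.raw_usage["ACT"] == pytest.approx(10.0)
        assert usage.n_genes_used == 1

    def test_disjoint_single_codon_genes_symmetric(self):
        catalog = make_catalog(
            [("t1", "g1", "ATG" + "ACT" * 4 + "TAA"), ("t2", "g2", "ATG" + "GGT" * 4 + "TAA")]
        )
        matrix = em(["g1", "g2"], ["a", "b"], [[7, 1], [7, 1]], size_factors=[1, 1])
        usage = weighted_codon_usage(catalog, normalize_counts(matrix), "a")
        assert usage.raw_usage["ACT"] == pytest.approx(usage.raw_usage["GGT"])

    def test_matches_naive_double_loop(self):
        rng = np.random.default_rng(11)
        sense = [c for c in CODONS if c not in {"TAA", "TAG", "TGA"}]
        records, counts = [], {}
        for i in range(20):
            gid = f"g{i:02d}"
            body = "".join(rng.choice(sense, size=rng.integers(40, 120)))
            records.append((f"t{i:02d}", gid, "ATG" + body + "TAA"))
            counts[gid] = float(rng.integers(0, 500))
        catalog = make_catalog(records)
        matrix = em(list(counts), ["x", "y"],
                    [[v, 1.0] for v in counts.values()], size_factors=[1, 1])
        usage = weighted_codon_usage(catalog, normalize_counts(matrix), "x")
        gene_freqs = {
            rec.gene_id: codon_frequency(count_elongator_codons(rec)).values
            for rec in catalog
        }
        oracle = naive_weighted_usage(counts, gene_freqs)
        assert np.allclose(usage.raw_usage.values, oracle, rtol=1e-12)

    def test_gene_list_restricts_and_transcript_rows_resolve(self):
        catalog = make_catalog(
            [("t1", "g1", "ATG" + "ACT" * 4 + "TAA"), ("t2", "g2", "ATG" + "GGT" * 4 + "TAA")]
        )
        matrix = em(["t1", "t2"], ["a", "b"], [[5, 5], [5, 5]], size_factors=[1, 1])
        usage = weighted_codon_usage(
            catalog, normalize_counts(matrix), "a", gene_list={"g1"}
        )
        assert usage.n_genes_used == 1 and usage.raw_usage["GGT"] == 0.0

    def test_unmatched_rows_skipped_not_fatal(self):
        catalog = make_catalog([("t1", "g1", "ATG" + "ACT" * 4 + "TAA")])
        matrix = em(["g1", "ghost"], ["a", "b"], [[5, 5], [9, 9]], size_factors=[1, 1])
        usage = weighted_codon_usage(catalog, normalize_counts(matrix), "a")
        assert usage.n_genes_used == 1
        assert usage.raw_usage["ACT"] == pytest.approx(5.0)

    def test_errors_for_missing_tissue_and_no_match(self):
        catalog = make_catalog([("t1", "g1", "ATG" + "ACT" * 4 + "TAA")])
        matrix = em(["g1"], ["a", "b"], [[5, 5]], size_factors=[1, 1])
        with pytest.raises(ValueError, match="tissue"):
            weighted_codon_usage(catalog, matrix, "zz")
        ghost = em(["nope"], ["a", "b"], [[5, 5]], size_factors=[1, 1])
        with pytest.raises(ValueError, match="matched"):
            weighted_codon_usage(catalog, ghost, "a")

    def test_linearity_over_disjoint_gene_sets(self):
        rng = np.random.default_rng(3)
        sense = [c for c in CODONS if c not in {"TAA", "TAG", "TGA"}]
        records = [
            (f"t{i}", f"g{i}", "ATG" + "".join(rng.choice(sense, size=60)) + "TAA")
            for i in range(10)
        ]
        catalog = make_catalog(records)
        values = [[float(rng.integers(1, 200)), 1.0] for _ in range(10)]
        matrix = normalize_counts(
            em([f"g{i}" for i in range(10)], ["a", "b"], values, size_factors=[1, 1])
        )
        set1 = {f"g{i}" for i in range(5)}
        set2 = {f"g{i}" for i in range(5, 10)}
        u_all = weighted_codon_usage(catalog, matrix, "a").raw_usage.values
        u1 = weighted_codon_usage(catalog, matrix, "a", gene_list=set1).raw_usage.values
        u2 = weighted_codon_usage(catalog, matrix, "a", gene_list=set2).raw_usage.values
        assert np.allclose(u_all, u1 + u2, rtol=1e-12)

    def test_equal_counts_usage_differs_from_genome_aggregate_when_lengths_vary(self):
        """With uniform counts the weighted usage is the *mean* per-CDS
        frequency, not the length-weighted genome frequency."""
        catalog = make_catalog(
            [
                ("t1", "g1", "ATG" + "ACT" * 2 + "TAA"),
                ("t2", "g2", "ATG" + "GGT" * 50 + "TAA"),
            ]
        )
        matrix = em(["g1", "g2"], ["a", "b"], [[1, 1], [1, 1]], size_factors=[1, 1])
        usage = weighted_codon_usage(catalog, normalize_counts(matrix), "a")
        mean_usage = usage.raw_usage.values / usage.raw_usage.values.sum()
        _, genome = aggregate_genome_usage(catalog)
        act = CODONS.index("ACT")
        assert mean_usage[act] > genome.values[act]  # short ACT gene up-weighted


class TestMaxNormalizeUsage:
    def test_peak_is_exactly_one_and_values_scale(self):
        catalog = make_catalog([("t1", "g1", "ATG" + "ACT" * 3 + "GGT" + "TAA")])
        matrix = em(["g1"], ["a", "b"], [[8, 8]], size_factors=[1, 1])
        usage = max_normalize_usage(
            weighted_codon_usage(catalog, normalize_counts(matrix), "a")
        )
        assert usage.scaled_usage["ACT"] == 1.0
        assert usage.scaled_usage["GGT"] == pytest.approx(1 / 3)

    def test_scale_invariance_under_global_rescaling(self):
        catalog = make_catalog(
            [("t1", "g1", "ATG" + "ACT" * 4 + "GGT" * 2 + "TAA")]
        )
        small = em(["g1"], ["a", "b"], [[3, 3]], size_factors=[1, 1])
        big = em(["g1"], ["a", "b"], [[3000, 3000]], size_factors=[1, 1])
        u_small = max_normalize_usage(
            weighted_codon_usage(catalog, normalize_counts(small), "a")
        )
        u_big = max_normalize_usage(
            weighted_codon_usage(catalog, normalize_counts(big), "a")
        )
        assert np.allclose(u_small.scaled_usage.values, u_big.scaled_usage.values)
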