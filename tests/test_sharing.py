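"""Pairwise gene sharing, the two bias corrections, and outlier tests."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from panlineage import (
    SharingConfig,
    ValidationError,
    classify_pangenome,
    outlier_lineages,
    per_isolate_sharing,
    phylo_filter,
    shared_gene_counts,
    sharing_vs_size_regression,
    subsampled_sharing,
)
from panlineage.sharing import SharingResult, _ranksum_p


def three_lineage_toy():
    """gene1 intermediate in L1 and rare in L2, absent in L3."""
    genomes = (
        [f"a{i}" for i in range(10)]
        + [f"b{i}" for i in range(10)]
        + [f"c{i}" for i in range(10)]
    )
    row = [1] * 5 + [0] * 5 + [1] + [0] * 9 + [0] * 10
    matrix = pd.DataFrame(
        [row, [1] * 30], index=["gene1", "gene2"], columns=genomes,
        dtype=np.int8,
    )
    assignment = pd.Series(
        ["L1"] * 10 + ["L2"] * 10 + ["L3"] * 10, index=genomes
    )
    return matrix, assignment


class TestSharedCounts:
    def test_pair_membership(self):
        matrix, assignment = three_lineage_toy()
        cls = classify_pangenome(matrix, assignment)
        assert cls.classes["gene1"] == "intermediate and rare"
        counts = shared_gene_counts(matrix, assignment, cls)
        assert counts.loc["L1", "L2"] == 1
        assert counts.loc["L1", "L3"] == 0
        assert counts.loc["L2", "L3"] == 0

    def test_symmetry_and_brute_force(self):
        rng = np.random.default_rng(21)
        genomes = [f"g{i}" for i in range(80)]
        matrix = pd.DataFrame(
            (rng.random((60, 80)) < 0.2).astype(np.int8),
            index=[f"gene{i}" for i in range(60)], columns=genomes,
        )
        assignment = pd.Series(rng.choice(["L1", "L2", "L3", "L4"], 80),
                               index=genomes)
        cls = classify_pangenome(matrix, assignment)
        classes = frozenset(set(cls.classes.unique()) - {"absent"})
        counts = shared_gene_counts(matrix, assignment, cls, classes)
        assert (counts.to_numpy() == counts.to_numpy().T).all()
        selected = cls.classes.index[cls.classes.isin(classes)]
        for la, lb in itertools.combinations(["L1", "L2", "L3", "L4"], 2):
            expected = 0
            for gene in selected:
                in_a = matrix.loc[gene, assignment.index[assignment == la]].any()
                in_b = matrix.loc[gene, assignment.index[assignment == lb]].any()
                expected += int(in_a and in_b)
            assert counts.loc[la, lb] == expected

    def test_unknown_class_rejected(self):
        matrix, assignment = three_lineage_toy()
        cls = classify_pangenome(matrix, assignment)
        with pytest.raises(ValidationError, match="valid names"):
            shared_gene_counts(matrix, assignment, cls, {"mega core"})


class TestPhyloFilter:
    def test_threshold_semantics(self):
        d = pd.DataFrame(
            [[0.0, 0.16, 0.14], [0.16, 0.0, 0.2], [0.14, 0.2, 0.0]],
            index=["L1", "L2", "L3"], columns=["L1", "L2", "L3"],
        )
        mask = phylo_filter(["L1", "L2", "L3"], d, 0.15)
        assert mask.loc["L1", "L2"]
        assert not mask.loc["L1", "L3"]
        assert not mask.loc["L1", "L1"]

    def test_zero_threshold_keeps_all_pairs(self):
        d = pd.DataFrame(np.ones((3, 3)) * 0.01, index=list("abc"),
                         columns=list("abc"))
        mask = phylo_filter(list("abc"), d, 0.0)
        assert mask.to_numpy().sum() == 6  # all off-diagonal entries

    def test_missing_lineage_rejected(self):
        d = pd.DataFrame([[0.0]], index=["L1"], columns=["L1"])
        with pytest.raises(ValidationError, match="missing"):
            phylo_filter(["L1", "L2"], d, 0.15)

    def test_matches_brute_force_on_random_distances(self):
        rng = np.random.default_rng(2)
        labels = [f"L{i}" for i in range(6)]
        m = rng.uniform(0, 0.3, (6, 6))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        d = pd.DataFrame(m, index=labels, columns=labels)
        mask = phylo_filter(labels, d, 0.15)
        for i, j in itertools.permutations(range(6), 2):
            assert mask.iloc[i, j] == (m[i, j] >= 0.15)


class TestSubsampledSharing:
    def test_exact_size_lineage_reproduces_raw_count(self):
        rng = np.random.default_rng(6)
        genomes = [f"g{i}" for i in range(10)]
        matrix = pd.DataFrame(
            (rng.random((30, 10)) < 0.3).astype(np.int8),
            index=[f"gene{i}" for i in range(30)], columns=genomes,
        )
        assignment = pd.Series(["L1"] * 5 + ["L2"] * 5, index=genomes)
        cls = classify_pangenome(matrix, assignment)
        classes = frozenset(set(cls.classes.unique()) - {"absent"})
        config = SharingConfig(subsample_size=5, n_repeats=10, seed=1,
                               classes=classes)
        result = subsampled_sharing(matrix, assignment, cls, config)
        # lineage size == subsample size: every repeat sees the full data
        assert (result.repeat_counts == result.repeat_counts[0]).all()
        assert result.corrected_mean.loc["L1", "L2"] == result.raw_counts.loc[
            "L1", "L2"
        ]

    def test_ubiquitous_gene_contributes_exactly_one(self):
        genomes = [f"g{i}" for i in range(60)]
        matrix = pd.DataFrame(
            [[1] * 60, [1] * 30 + [0] * 30],
            index=["everywhere", "partial"], columns=genomes, dtype=np.int8,
        )
        assignment = pd.Series(["L1"] * 30 + ["L2"] * 30, index=genomes)
        classes = pd.Series(["intermediate and rare", "intermediate and rare"],
                            index=["everywhere", "partial"])
        config = SharingConfig(subsample_size=20, n_repeats=15, seed=3)
        result = subsampled_sharing(matrix, assignment, classes, config)
        # 'everywhere' is drawn in every subsample of both lineages;
        # 'partial' never reaches L2
        assert result.corrected_mean.loc["L1", "L2"] == 1.0

    def test_hypergeometric_expectation(self):
        """Mean corrected count on a 2-lineage toy sits within 3 MC
        standard errors of the closed-form expectation."""
        rng = np.random.default_rng(12)
        n1, n2, sub = 60, 45, 20
        genomes = [f"a{i}" for i in range(n1)] + [f"b{i}" for i in range(n2)]
        carriers = {}
        rows = []
        for g in range(25):
            k1, k2 = int(rng.integers(1, 9)), int(rng.integers(1, 9))
            row = np.zeros(n1 + n2, dtype=np.int8)
            row[rng.choice(n1, k1, replace=False)] = 1
            row[n1 + rng.choice(n2, k2, replace=False)] = 1
            rows.append(row)
            carriers[f"gene{g}"] = (k1, k2)
        matrix = pd.DataFrame(rows, index=list(carriers), columns=genomes)
        assignment = pd.Series(["L1"] * n1 + ["L2"] * n2, index=genomes)
        classes = pd.Series("intermediate and rare", index=list(carriers))
        config = SharingConfig(subsample_size=sub, n_repeats=40, seed=5)
        result = subsampled_sharing(matrix, assignment, classes, config)

        def p_hit(n, k):
            return 1 - math.comb(n - k, sub) / math.comb(n, sub)

        expected = sum(
            p_hit(n1, k1) * p_hit(n2, k2) for k1, k2 in carriers.values()
        )
        reps = result.repeat_counts[:, 0, 1].astype(float)
        se = max(reps.std(ddof=1) / math.sqrt(len(reps)), 1e-9)
        assert abs(reps.mean() - expected) <= 3 * se

    def test_seeded_reproducibility(self):
        matrix, assignment = three_lineage_toy()
        cls = classify_pangenome(matrix, assignment)
        config = SharingConfig(subsample_size=10, n_repeats=8, seed=42)
        a = subsampled_sharing(matrix, assignment, cls, config)
        b = subsampled_sharing(matrix, assignment, cls, config)
        assert (a.repeat_counts == b.repeat_counts).all()

    def test_small_lineage_excluded_with_warning(self, caplog):
        matrix, assignment = three_lineage_toy()
        assignment = assignment.copy()
        assignment[assignment.index[-1]] = "L4"  # 1-genome lineage
        cls = classify_pangenome(matrix, assignment)
        config = SharingConfig(subsample_size=9, n_repeats=3, seed=0)
        with caplog.at_level("WARNING", logger="panlineage.sharing"):
            result = subsampled_sharing(matrix, assignment, cls, config)
        assert "L4" in caplog.text
        assert "L4" not in result.lineages


class TestPerIsolateSharing:
    def test_counts_selected_class_genes_per_genome(self):
        matrix, assignment = three_lineage_toy()
        cls = classify_pangenome(matrix, assignment)
        counts = per_isolate_sharing(matrix, assignment, cls)
        # gene1 is the only 'intermediate and rare' gene; its carriers are
        # a0..a4 and b0
        assert counts["a0"] == 1
        assert counts["b0"] == 1
        assert counts["c0"] == 0
        assert counts.sum() == matrix.loc["gene1"].sum()


class TestOutlierLineages:
    def test_degenerate_equal_counts_give_p_one(self):
        counts = pd.DataFrame(np.full((4, 4), 7.0),
                              index=list("abcd"), columns=list("abcd"))
        result = SharingResult(
            lineages=list("abcd"), raw_counts=counts, corrected_mean=counts,
            repeat_counts=np.zeros((1, 4, 4)), config=SharingConfig(),
        )
        out = outlier_lineages(result)
        assert (out["p_adjusted"] == 1.0).all()

    def test_ranksum_matches_exact_permutation(self):
        """Two-sided rank-sum p for {1,2,3} vs {4,5,6} equals the exact
        enumeration over all 20 group splits."""
        x, y = np.array([1.0, 2, 3]), np.array([4.0, 5, 6])
        _, p = _ranksum_p(x, y)
        pooled = np.concatenate([x, y])
        observed = x.sum()
        extremes = 0
        total = 0
        mu = pooled.sum() / 2
        for combo in itertools.combinations(range(6), 3):
            s = pooled[list(combo)].sum()
            total += 1
            if abs(s - mu) >= abs(observed - mu):
                extremes += 1
        assert p == pytest.approx(extremes / total)

    def test_bh_adjustment_step_up(self):
        p = stats.false_discovery_control([0.01, 0.02, 0.03], method="bh")
        assert np.allclose(p, [0.03, 0.03, 0.03])

    def test_planted_outlier_is_flagged(self):
        """A lineage seeded with extra mobile genes shared with random
        partners gets a small adjusted p."""
        rng = np.random.default_rng(99)
        n_lin, size = 10, 25
        genomes, lineage_of = [], []
        for li in range(n_lin):
            for k in range(size):
                genomes.append(f"L{li}_g{k}")
                lineage_of.append(f"L{li}")
        assignment = pd.Series(lineage_of, index=genomes)
        rows, names = [], []
        # background: sparse mobile genes everywhere
        for g in range(60):
            rows.append((rng.random(len(genomes)) < 0.02).astype(np.int8))
            names.append(f"bg{g}")
        # planted: genes shared between L0 and one random partner
        for g in range(120):
            row = np.zeros(len(genomes), dtype=np.int8)
            partner = int(rng.integers(1, n_lin))
            for li in (0, partner):
                row[li * size + rng.choice(size, 3, replace=False)] = 1
            rows.append(row)
            names.append(f"hot{g}")
        matrix = pd.DataFrame(rows, index=names, columns=genomes)
        cls = classify_pangenome(matrix, assignment)
        classes = frozenset(set(cls.classes.unique()) - {"absent"})
        config = SharingConfig(subsample_size=20, n_repeats=20, seed=1,
                               classes=classes)
        result = subsampled_sharing(matrix, assignment, cls, config)
        out = outlier_lineages(result)
        assert out.loc["L0", "p_adjusted"] < 0.05
        assert out["p_adjusted"].ge(out["p_value"]).all()


class TestSizeRegression:
    def make_result(self, pair_values, lineages):
        n = len(lineages)
        counts = pd.DataFrame(np.zeros((n, n)), index=lineages, columns=lineages)
        k = 0
        for i in range(n):
            for j in range(i + 1, n):
                counts.iloc[i, j] = counts.iloc[j, i] = pair_values[k]
                k += 1
        return SharingResult(
            lineages=lineages, raw_counts=counts, corrected_mean=counts,
            repeat_counts=np.zeros((1, n, n)), config=SharingConfig(),
        )

    def test_collinear_points_r2_one(self):
        lineages = ["L1", "L2", "L3", "L4"]
        sizes = pd.Series([10, 20, 30, 40], index=lineages)
        # log(count+1) exactly linear in min size
        pair_values = []
        for i in range(4):
            for j in range(i + 1, 4):
                pair_values.append(math.exp(0.1 * min(sizes.iloc[i], sizes.iloc[j])) - 1)
        fit = sharing_vs_size_regression(self.make_result(pair_values, lineages), sizes)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.slope == pytest.approx(0.1)

    def test_constant_response_r2_zero(self):
        lineages = ["L1", "L2", "L3", "L4"]
        sizes = pd.Series([10, 20, 30, 40], index=lineages)
        fit = sharing_vs_size_regression(self.make_result([5.0] * 6, lineages), sizes)
        assert fit.r_squared == 0.0

    def test_closed_form_ols(self):
        rng = np.random.default_rng(8)
        lineages = [f"L{i}" for i in range(5)]
        sizes = pd.Series(rng.integers(10, 100, 5), index=lineages)
        pair_values = rng.uniform(0, 50, 10).tolist()
        fit = sharing_vs_size_regression(self.make_result(pair_values, lineages), sizes)
        # normal-equations oracle
        result = self.make_result(pair_values, lineages)
        tab = result.pair_table(sizes=sizes)
        x = tab["min_size"].to_numpy(float)
        y = np.log1p(tab["raw_count"].to_numpy(float))
        beta = np.cov(x, y, ddof=1)[0, 1] / np.var(x, ddof=1)
        alpha = y.mean() - beta * x.mean()
        assert fit.slope == pytest.approx(beta)
        assert fit.intercept == pytest.approx(alpha)

    def test_too_few_pairs_rejected(self):
        lineages = ["L1", "L2"]
        sizes = pd.Series([10, 20], index=lineages)
        with pytest.raises(ValidationError, match=">= 3"):
            sharing_vs_size_regression(self.make_result([1.0], lineages), sizes)


class TestSizeCorrectionRemovesSizeSignal:
    def test_duplication_invariance_of_corrected_counts(self):
        """Raw counts respond to replicating a lineage's genomes only via
        lineage size; subsampled counts drawn from the original genomes are
        unchanged in distribution. Here: doubling a lineage's genomes does
        not change the expected corrected count (same carrier pattern)."""
        rng = np.random.default_rng(14)
        genomes = [f"g{i}" for i in range(80)]
        matrix = pd.DataFrame(
            (rng.random((40, 80)) < 0.1).astype(np.int8),
            index=[f"gene{i}" for i in range(40)], columns=genomes,
        )
        assignment = pd.Series(["L1"] * 40 + ["L2"] * 40, index=genomes)
        cls = classify_pangenome(matrix, assignment)
        classes = frozenset(set(cls.classes.unique()) - {"absent"})
        config = SharingConfig(subsample_size=40, n_repeats=5, seed=7,
                               classes=classes)
        base = subsampled_sharing(matrix, assignment, cls, config)
        # subsample == lineage size: corrected equals raw, deterministic
        assert base.corrected_mean.loc["L1", "L2"] == base.raw_counts.loc["L1", "L2"]
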