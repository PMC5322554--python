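"""Expression binning, two-class clustering, concordance, normalization,
PCA and tissue fold-change ANOVA."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from epiensemble.expression import (
    ConfigError,
    DEFAULT_BREAKPOINTS,
    ExpressionClassLabels,
    bin_expression,
    cluster_two_class,
    concordance,
    normalize_to_reference,
    pca_tissue,
    tissue_fold_change_anova,
)
from epiensemble.io_formats import ExpressionMatrix, InputError
from epiensemble.synthetic_data import (
    ExpressionConfig,
    SimulationConfig,
    simulate_expression,
    simulate_families,
)


def _matrix(data, genes, conditions, species="sp"):
    return ExpressionMatrix(
        species=species,
        values=pd.DataFrame(data, index=genes, columns=conditions),
    )


class TestBinExpression:
    def test_extremes_map_to_0_and_6(self):
        m = _matrix([[0.0, 0.5, 5000.0]], ["g"], ["a", "b", "c"])
        binned = bin_expression(m)
        assert binned.loc["g"].tolist() == [0, 0, 6]

    def test_monotone_and_idempotent_on_random_values(self, rng):
        values = rng.uniform(0, 2000, size=1000)
        m = _matrix(values.reshape(1, -1), ["g"], [f"c{i}" for i in range(1000)])
        binned = bin_expression(m).loc["g"].to_numpy()
        order = np.argsort(values)
        assert (np.diff(binned[order]) >= 0).all()
        # rebinning bin midpoints reproduces the bins
        edges = list(DEFAULT_BREAKPOINTS) + [4096.0]
        mids = np.array([(edges[i] + edges[i + 1]) / 2 for i in binned])
        m2 = _matrix(mids.reshape(1, -1), ["g"], [f"c{i}" for i in range(1000)])
        assert (bin_expression(m2).loc["g"].to_numpy() == binned).all()

    def test_unordered_breakpoints_rejected(self):
        m = _matrix([[1.0, 2.0]], ["g"], ["a", "b"])
        with pytest.raises(ConfigError):
            bin_expression(m, breakpoints=(0, 4, 1, 16, 64, 256, 1024))


class TestClusterTwoClass:
    def test_recovers_planted_classes_across_10_seeds(self):
        # >= 95% label agreement at >= 3-sd class separation
        agree = total = 0
        for seed in range(10):
            cfg = SimulationConfig(
                n_families=60, seed=seed,
                expression=ExpressionConfig(lognormal_sd=0.5),
            )
            gt = simulate_families(cfg).ground_truth
            mats = simulate_expression(gt, cfg, seed=500 + seed)
            labels = cluster_two_class(mats["A"])
            agree += sum(
                1 for g, c in labels.labels.items()
                if gt.expression_class[g] == c
            )
            total += len(labels.labels)
        assert agree / total >= 0.95

    def test_anticorrelated_profiles_split(self):
        m = _matrix(
            [[10, 20, 30, 40], [40, 30, 20, 10]], ["up", "down"], list("abcd")
        )
        labels = cluster_two_class(m)
        assert labels.labels["up"] != labels.labels["down"]

    def test_invariant_under_row_permutation(self, rng):
        data = rng.lognormal(2, 1, size=(20, 5))
        genes = [f"g{i}" for i in range(20)]
        m = _matrix(data, genes, list("abcde"))
        ref = cluster_two_class(m).labels
        perm = rng.permutation(20)
        m2 = _matrix(data[perm], [genes[i] for i in perm], list("abcde"))
        assert cluster_two_class(m2).labels == ref

    def test_zero_variance_rows_assigned_low(self):
        m = _matrix(
            [[5.0, 5.0, 5.0], [10, 20, 30], [30, 20, 10]],
            ["flat", "up", "down"], list("abc"),
        )
        labels = cluster_two_class(m, log_transform=False)
        assert labels.labels["flat"] == "low"

    def test_single_gene_rejected(self):
        with pytest.raises(InputError):
            cluster_two_class(_matrix([[1, 2]], ["g"], ["a", "b"]))


class TestConcordance:
    def test_identical_labelings_fully_concordant(self):
        la = ExpressionClassLabels(labels={"a1": "high", "a2": "low"})
        lb = ExpressionClassLabels(labels={"b1": "high", "b2": "low"})
        res = concordance(la, lb, [("a1", "b1"), ("a2", "b2")])
        assert res.n_diff == 0 and res.n_same == 2
        assert res.n_same_high == 1 and res.n_same_low == 1

    def test_single_discordant_pair(self):
        la = ExpressionClassLabels(labels={"a": "high"})
        lb = ExpressionClassLabels(labels={"b": "low"})
        assert concordance(la, lb, [("a", "b")]).n_diff == 1

    def test_counts_conserve_pair_total(self, rng):
        n = 50
        la = ExpressionClassLabels(
            labels={f"a{i}": rng.choice(["high", "low"]) for i in range(n)}
        )
        lb = ExpressionClassLabels(
            labels={f"b{i}": rng.choice(["high", "low"]) for i in range(n)}
        )
        pairs = [(f"a{i}", f"b{i}") for i in range(n)]
        res = concordance(la, lb, pairs)
        assert res.n_same + res.n_diff == n

    def test_swap_fraction_discordance_in_binomial_interval(self):
        cfg = SimulationConfig(
            n_families=200, seed=1,
            expression=ExpressionConfig(swap_fraction=0.3),
        )
        gt = simulate_families(cfg).ground_truth
        la = ExpressionClassLabels(
            labels={g: c for g, c in gt.expression_class.items() if "_A_" in g}
        )
        lb = ExpressionClassLabels(
            labels={g: c for g, c in gt.expression_class.items() if "_B_" in g}
        )
        pairs = []
        for p in gt.ortholog_pairs:
            a = next((g for g in p if "_A_" in g), None)
            b = next((g for g in p if "_B_" in g), None)
            if a and b:
                pairs.append((a, b))
        res = concordance(la, lb, pairs)
        lo, hi = stats.binom.ppf([0.0005, 0.9995], len(pairs), 0.3)
        assert lo <= res.n_diff <= hi

    def test_unlabeled_gene_rejected(self):
        la = ExpressionClassLabels(labels={"a": "high"})
        lb = ExpressionClassLabels(labels={})
        with pytest.raises(InputError):
            concordance(la, lb, [("a", "b")])


class TestNormalizeToReference:
    def test_reference_row_maps_to_zeros(self):
        m = _matrix([[10, 20], [5, 8]], ["Act5C", "g"], ["t1", "t2"])
        out = normalize_to_reference(m, "Act5C")
        np.testing.assert_allclose(out.loc["Act5C"].to_numpy(), 0.0)

    def test_scale_invariance_per_tissue(self):
        m1 = _matrix([[10, 20], [5, 8]], ["ref", "g"], ["t1", "t2"])
        m2 = _matrix([[20, 20], [10, 8]], ["ref", "g"], ["t1", "t2"])
        o1 = normalize_to_reference(m1, "ref", pseudocount=0)
        o2 = normalize_to_reference(m2, "ref", pseudocount=0)
        np.testing.assert_allclose(o1.to_numpy(), o2.to_numpy())

    def test_hand_computed_two_by_two(self):
        m = _matrix([[10.0, 100.0], [1.0, 10.0]], ["ref", "g"], ["t1", "t2"])
        out = normalize_to_reference(m, "ref", pseudocount=0)
        np.testing.assert_allclose(out.loc["g"].to_numpy(), [-1.0, -1.0])

    def test_zero_reference_without_pseudocount_rejected(self):
        m = _matrix([[0.0, 10.0], [1.0, 1.0]], ["ref", "g"], ["t1", "t2"])
        with pytest.raises(InputError):
            normalize_to_reference(m, "ref", pseudocount=0)


class TestPcaTissue:
    def test_rank_one_data_loads_on_first_component(self, rng):
        u = rng.normal(size=20)
        v = rng.normal(size=5)
        data = np.outer(u, v)
        a = pd.DataFrame(data[:10], index=[f"g{i}" for i in range(10)],
                         columns=list("abcde"))
        b = pd.DataFrame(data[10:], index=[f"g{i}" for i in range(10)],
                         columns=list("abcde"))
        res = pca_tissue(a, b)
        assert res.variance_fractions[0] == pytest.approx(1.0, abs=1e-9)

    def test_fractions_sum_to_one_and_descend(self, rng):
        a = pd.DataFrame(rng.normal(size=(30, 7)),
                         columns=[f"t{i}" for i in range(7)])
        b = pd.DataFrame(rng.normal(size=(30, 7)),
                         columns=[f"t{i}" for i in range(7)])
        res = pca_tissue(a, b)
        assert res.variance_fractions.sum() == pytest.approx(1.0)
        assert (np.diff(res.variance_fractions) <= 1e-12).all()

    def test_planted_two_factor_structure(self, rng):
        # factor variances 9:1 -> leading fractions ~0.9/0.1
        n = 2000
        f1 = rng.normal(0, 3, size=n)
        f2 = rng.normal(0, 1, size=n)
        basis1 = np.array([1, 1, 1, 1, 0, 0]) / 2.0
        basis2 = np.array([0, 0, 0, 0, 1, -1]) / np.sqrt(2)
        data = np.outer(f1, basis1) + np.outer(f2, basis2)
        cols = [f"t{i}" for i in range(6)]
        a = pd.DataFrame(data[: n // 2], columns=cols)
        b = pd.DataFrame(data[n // 2 :], columns=cols)
        res = pca_tissue(a, b)
        assert res.variance_fractions[0] == pytest.approx(0.9, abs=0.02)
        assert res.variance_fractions[1] == pytest.approx(0.1, abs=0.02)

    def test_gene_order_permutation_invariant(self, rng):
        data = rng.normal(size=(20, 4))
        cols = list("abcd")
        a = pd.DataFrame(data[:10], index=[f"g{i}" for i in range(10)], columns=cols)
        b = pd.DataFrame(data[10:], index=[f"h{i}" for i in range(10)], columns=cols)
        ref = pca_tissue(a, b).variance_fractions
        perm = rng.permutation(10)
        a2 = a.iloc[perm]
        got = pca_tissue(a2, b).variance_fractions
        np.testing.assert_allclose(got, ref, atol=1e-12)

    def test_single_tissue_rejected(self):
        a = pd.DataFrame([[1.0]], columns=["t"])
        with pytest.raises(InputError):
            pca_tissue(a, a)


class TestTissueFoldChangeAnova:
    def test_identical_matrices_give_zero_means_and_p_one(self):
        data = [[10.0, 20.0, 5.0], [3.0, 7.0, 9.0]]
        a = _matrix(data, ["a1", "a2"], ["t1", "t2", "t3"], "A")
        b = _matrix(data, ["b1", "b2"], ["t1", "t2", "t3"], "B")
        res = tissue_fold_change_anova(a, b, [("a1", "b1"), ("a2", "b2")])
        assert all(v == pytest.approx(0.0) for v in res.per_tissue_mean.values())
        assert res.p_value > 0.99

    def test_planted_shift_recovered_in_that_tissue(self, rng):
        base = rng.lognormal(2, 0.1, size=(10, 3))
        shifted = base.copy()
        shifted[:, 1] *= 10  # +1 in log10 in tissue t2 of species A
        a = _matrix(shifted, [f"a{i}" for i in range(10)], ["t1", "t2", "t3"], "A")
        b = _matrix(base, [f"b{i}" for i in range(10)], ["t1", "t2", "t3"], "B")
        pairs = [(f"a{i}", f"b{i}") for i in range(10)]
        res = tissue_fold_change_anova(a, b, pairs, pseudocount=0)
        assert res.per_tissue_mean["t2"] == pytest.approx(1.0)
        assert res.per_tissue_mean["t1"] == pytest.approx(0.0)
        assert res.p_value < 1e-6

    def test_pair_order_permutation_invariant(self, rng):
        a_data = rng.lognormal(2, 0.5, size=(8, 3))
        b_data = rng.lognormal(2, 0.5, size=(8, 3))
        a = _matrix(a_data, [f"a{i}" for i in range(8)], ["t1", "t2", "t3"], "A")
        b = _matrix(b_data, [f"b{i}" for i in range(8)], ["t1", "t2", "t3"], "B")
        pairs = [(f"a{i}", f"b{i}") for i in range(8)]
        r1 = tissue_fold_change_anova(a, b, pairs)
        r2 = tissue_fold_change_anova(a, b, pairs[::-1])
        assert r1.per_tissue_mean == r2.per_tissue_mean
        assert r1.p_value == pytest.approx(r2.p_value)
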