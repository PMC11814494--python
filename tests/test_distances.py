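import numpy as np
import pytest
from skbio.diversity import beta_diversity

from mdsclust import distances as dist
from mdsclust.distances import MetricSpec
from mdsclust.io import OtuTable, ValidationError
from mdsclust.simulate import random_tree

from conftest import random_binary_tree, random_composition


def brute_unifrac(a, b, tree, otu_ids, kind, alpha=0.5):
    """Independent oracle: explicit enumeration of every branch and its
    descendant leaf set."""
    idx = {o: i for i, o in enumerate(otu_ids)}
    rows = []
    for node in tree.traverse(include_self=False):
        leaves = [node.name] if node.is_tip() else [t.name for t in node.tips()]
        pa = sum(a[idx[n]] for n in leaves if n in idx)
        pb = sum(b[idx[n]] for n in leaves if n in idx)
        rows.append((node.length, pa, pb))
    if kind == "unweighted":
        num = sum(l for l, pa, pb in rows if (pa > 0) != (pb > 0))
        den = sum(l for l, pa, pb in rows if pa > 0 or pb > 0)
        return num / den
    if kind == "weighted":
        num = sum(l * abs(pa - pb) for l, pa, pb in rows)
        den = sum(l * (pa + pb) for l, pa, pb in rows)
        return num / den
    num = sum(l * (pa + pb) ** alpha * abs(pa - pb) / (pa + pb) for l, pa, pb in rows if pa + pb > 0)
    den = sum(l * (pa + pb) ** alpha for l, pa, pb in rows if pa + pb > 0)
    return num / den


class TestSimplexMetrics:
    def test_bray_curtis_hand_value(self):
        assert dist.bray_curtis([0.5, 0.3, 0.2], [0.2, 0.3, 0.5]) == pytest.approx(0.3)

    def test_bray_curtis_extremes(self):
        assert dist.bray_curtis([0.5, 0.5, 0.0], [0.5, 0.5, 0.0]) == 0.0
        assert dist.bray_curtis([1.0, 0.0], [0.0, 1.0]) == 1.0

    def test_jaccard_hand_value(self):
        a = np.array([0.2, 0.4, 0.4, 0.0])
        b = np.array([0.0, 0.3, 0.3, 0.4])
        assert dist.jaccard(a, b) == pytest.approx(0.5)  # 1 - 2/4

    def test_jaccard_extremes(self):
        assert dist.jaccard([0.5, 0.5, 0.0], [0.9, 0.1, 0.0]) == 0.0
        assert dist.jaccard([1.0, 0.0], [0.0, 1.0]) == 1.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            dist.bray_curtis([0.5, 0.5], [1.0])


class TestUniFrac:
    def test_unweighted_star_tree(self, star3):
        a = np.array([0.5, 0.5, 0.0])  # support {A, B}
        b = np.array([0.0, 0.5, 0.5])  # support {B, C}
        got = dist.unifrac_unweighted(a, b, star3, otu_ids=["A", "B", "C"])
        assert got == pytest.approx(2.0 / 3.0)

    def test_unweighted_disjoint_is_one(self, star3):
        a = np.array([1.0, 0.0, 0.0])
        b = np.array([0.0, 0.0, 1.0])
        assert dist.unifrac_unweighted(a, b, star3, otu_ids=["A", "B", "C"]) == 1.0

    def test_weighted_two_leaf_swap(self, two_leaf):
        a, b = np.array([1.0, 0.0]), np.array([0.0, 1.0])
        assert dist.unifrac_weighted(a, b, two_leaf, otu_ids=["A", "B"]) == pytest.approx(1.0)

    def test_generalized_half_alpha_two_leaf(self):
        import io as _io

        from skbio import TreeNode

        tree = TreeNode.read(_io.StringIO("(A:1,B:1);"))
        a, b = np.array([1.0, 0.0]), np.array([0.0, 1.0])
        got = dist.unifrac_generalized(a, b, tree, alpha=0.5, otu_ids=["A", "B"])
        assert got == pytest.approx(1.0)

    def test_generalized_alpha_one_is_weighted(self):
        rng = np.random.default_rng(7)
        tree = random_binary_tree(rng, [f"t{i}" for i in range(6)])
        ids = [f"t{i}" for i in range(6)]
        for _ in range(10):
            a, b = random_composition(rng, 6), random_composition(rng, 6)
            w = dist.unifrac_weighted(a, b, tree, otu_ids=ids)
            g = dist.unifrac_generalized(a, b, tree, alpha=1.0, otu_ids=ids)
            assert abs(w - g) < 1e-12

    def test_generalized_continuous_in_alpha(self):
        rng = np.random.default_rng(11)
        ids = [f"t{i}" for i in range(8)]
        tree = random_binary_tree(rng, ids)
        a, b = random_composition(rng, 8, zeros=True), random_composition(rng, 8, zeros=True)
        alphas = np.linspace(0.0, 1.0, 21)
        vals = [dist.unifrac_generalized(a, b, tree, alpha=al, otu_ids=ids) for al in alphas]
        assert max(abs(np.diff(vals))) < 0.1

    @pytest.mark.parametrize("kind", ["unweighted", "weighted", "generalized"])
    def test_brute_force_branch_enumeration_oracle(self, kind):
        # random 8-leaf trees, 50 random sample pairs
        rng = np.random.default_rng(202)
        ids = [f"t{i}" for i in range(8)]
        fn = {
            "unweighted": lambda a, b, t: dist.unifrac_unweighted(a, b, t, otu_ids=ids),
            "weighted": lambda a, b, t: dist.unifrac_weighted(a, b, t, otu_ids=ids),
            "generalized": lambda a, b, t: dist.unifrac_generalized(a, b, t, 0.5, otu_ids=ids),
        }[kind]
        for _ in range(50):
            tree = random_binary_tree(rng, ids)
            a = random_composition(rng, 8, zeros=True)
            b = random_composition(rng, 8, zeros=True)
            assert fn(a, b, tree) == pytest.approx(
                brute_unifrac(a, b, tree, ids, kind), abs=1e-10
            )

    def test_abundant_otu_missing_from_tree_rejected(self, star3):
        a = np.array([0.5, 0.25, 0.25, 0.0])
        b = np.array([0.25, 0.25, 0.25, 0.25])
        with pytest.raises(ValidationError, match="X"):
            dist.unifrac_unweighted(a, b, star3, otu_ids=["A", "B", "C", "X"])

    def test_cross_check_against_skbio(self):
        """Independent library route for the two classic UniFrac variants."""
        rng = np.random.default_rng(5)
        ids = [f"t{i}" for i in range(10)]
        tree = random_tree(ids, seed=3)
        counts = rng.integers(0, 50, size=(5, 10))
        counts[0, :5] = 0
        props = counts / counts.sum(axis=1, keepdims=True)
        t = OtuTable(
            sample_ids=[f"s{i}" for i in range(5)],
            otu_ids=ids,
            values=props,
            is_proportion=True,
        )
        ours_u = dist.pairwise(t, MetricSpec(name="unifrac_unweighted", tree=tree))
        skb_u = beta_diversity("unweighted_unifrac", counts, ids=t.sample_ids, taxa=ids, tree=tree)
        np.testing.assert_allclose(ours_u.data, skb_u.data, atol=1e-10)
        ours_w = dist.pairwise(t, MetricSpec(name="unifrac_weighted", tree=tree))
        skb_w = beta_diversity(
            "weighted_unifrac", counts, ids=t.sample_ids, taxa=ids, tree=tree, normalized=True
        )
        np.testing.assert_allclose(ours_w.data, skb_w.data, atol=1e-10)


class TestLogRatio:
    def test_clr_hand_value(self):
        got = dist.clr_transform([0.5, 0.25, 0.25])
        np.testing.assert_allclose(got, [0.4621, -0.2310, -0.2310], atol=5e-5)
        assert got.sum() == pytest.approx(0.0, abs=1e-12)

    def test_clr_scale_invariance(self):
        rng = np.random.default_rng(1)
        a = random_composition(rng, 12)
        np.testing.assert_allclose(dist.clr_transform(a), dist.clr_transform(3.7 * a), atol=1e-12)

    def test_clr_equal_proportions_zero(self):
        np.testing.assert_allclose(dist.clr_transform(np.full(5, 0.2)), 0.0, atol=1e-12)

    def test_clr_zero_rejected(self):
        with pytest.raises(ValidationError):
            dist.clr_transform([0.5, 0.5, 0.0])

    def test_philr_hand_value(self, cherry3):
        got = dist.philr_transform(np.array([0.25, 0.25, 0.5]), cherry3, otu_ids=["A", "B", "C"])
        assert got.shape == (2,)
        root_balance = np.sqrt(2.0 / 3.0) * np.log(0.5)
        np.testing.assert_allclose(sorted(got), sorted([root_balance, 0.0]), atol=1e-12)

    def test_philr_equal_proportions_all_zero(self, cherry3):
        got = dist.philr_transform(np.full(3, 1 / 3), cherry3, otu_ids=["A", "B", "C"])
        np.testing.assert_allclose(got, 0.0, atol=1e-12)

    def test_philr_output_length(self):
        rng = np.random.default_rng(3)
        ids = [f"t{i}" for i in range(9)]
        tree = random_binary_tree(rng, ids)
        out = dist.philr_transform(random_composition(rng, 9), tree, otu_ids=ids)
        assert out.shape == (8,)

    def test_philr_is_isometry_of_aitchison_distance(self):
        rng = np.random.default_rng(17)
        for _ in range(10):
            P = int(rng.integers(4, 12))
            ids = [f"t{i}" for i in range(P)]
            tree = random_binary_tree(rng, ids)
            a, b = random_composition(rng, P), random_composition(rng, P)
            d_philr = np.linalg.norm(
                dist.philr_transform(a, tree, otu_ids=ids) - dist.philr_transform(b, tree, otu_ids=ids)
            )
            d_aitch = np.linalg.norm(dist.clr_transform(a) - dist.clr_transform(b))
            assert d_philr == pytest.approx(d_aitch, abs=1e-9)

    def test_philr_handles_multifurcation(self, star3):
        got = dist.philr_transform(np.array([0.2, 0.3, 0.5]), star3, otu_ids=["A", "B", "C"])
        assert got.shape == (2,) and np.isfinite(got).all()


class TestPairwise:
    @pytest.mark.parametrize(
        "name", ["bray_curtis", "jaccard", "unifrac_unweighted", "unifrac_weighted",
                 "unifrac_generalized", "clr", "philr"]
    )
    def test_metric_axioms_on_random_compositions(self, name):
        # d(a, a) = 0, symmetry, non-negativity
        rng = np.random.default_rng(23)
        P = 8
        ids = [f"t{i}" for i in range(P)]
        tree = random_binary_tree(rng, ids) if name in dist.PHYLOGENETIC else None
        zeros = name not in dist.LOG_RATIO
        X = np.array([random_composition(rng, P, zeros=zeros) for _ in range(20)])
        t = OtuTable(
            sample_ids=[f"s{i}" for i in range(20)], otu_ids=ids, values=X, is_proportion=True
        )
        dm = dist.pairwise(t, MetricSpec(name=name, tree=tree))
        assert np.allclose(dm.data, dm.data.T, atol=1e-10)
        assert np.allclose(np.diag(dm.data), 0.0)
        assert (dm.data >= -1e-12).all() and np.isfinite(dm.data).all()

    def test_duplicated_sample_row_has_zero_distance(self):
        X = np.array([[0.5, 0.3, 0.2], [0.5, 0.3, 0.2], [0.1, 0.1, 0.8]])
        t = OtuTable(
            sample_ids=["a", "b", "c"], otu_ids=["x", "y", "z"], values=X, is_proportion=True
        )
        dm = dist.pairwise(t, MetricSpec(name="bray_curtis"))
        assert dm["a", "b"] == 0.0

    def test_pairwise_matches_per_pair_calls(self):
        X = np.array([[0.5, 0.3, 0.2], [0.2, 0.3, 0.5], [0.1, 0.1, 0.8]])
        t = OtuTable(
            sample_ids=["a", "b", "c"], otu_ids=["x", "y", "z"], values=X, is_proportion=True
        )
        dm = dist.pairwise(t, MetricSpec(name="bray_curtis"))
        for i in range(3):
            for j in range(3):
                assert dm.data[i, j] == pytest.approx(dist.bray_curtis(X[i], X[j]), abs=1e-12)
        assert dm["a", "b"] == pytest.approx(0.3)

    def test_pairwise_unifrac_matches_per_pair(self):
        rng = np.random.default_rng(31)
        ids = [f"t{i}" for i in range(6)]
        tree = random_binary_tree(rng, ids)
        X = np.array([random_composition(rng, 6, zeros=True) for _ in range(4)])
        t = OtuTable(
            sample_ids=[f"s{i}" for i in range(4)], otu_ids=ids, values=X, is_proportion=True
        )
        for name, fn in [
            ("unifrac_unweighted", lambda a, b: dist.unifrac_unweighted(a, b, tree, otu_ids=ids)),
            ("unifrac_weighted", lambda a, b: dist.unifrac_weighted(a, b, tree, otu_ids=ids)),
            ("unifrac_generalized", lambda a, b: dist.unifrac_generalized(a, b, tree, 0.5, otu_ids=ids)),
        ]:
            dm = dist.pairwise(t, MetricSpec(name=name, tree=tree))
            for i in range(4):
                for j in range(i + 1, 4):
                    assert dm.data[i, j] == pytest.approx(fn(X[i], X[j]), abs=1e-12)

    def test_log_ratio_invariant_to_pre_closure_scaling(self):
        rng = np.random.default_rng(41)
        raw = rng.gamma(1.0, size=(5, 7)) + 0.1
        t1 = OtuTable(
            sample_ids=[f"s{i}" for i in range(5)],
            otu_ids=[f"o{i}" for i in range(7)],
            values=raw / raw.sum(axis=1, keepdims=True),
            is_proportion=True,
        )
        scaled = raw * rng.uniform(0.5, 2.0, size=(5, 1))
        t2 = OtuTable(
            sample_ids=t1.sample_ids,
            otu_ids=t1.otu_ids,
            values=scaled / scaled.sum(axis=1, keepdims=True),
            is_proportion=True,
        )
        d1 = dist.pairwise(t1, MetricSpec(name="clr"))
        d2 = dist.pairwise(t2, MetricSpec(name="clr"))
        np.testing.assert_allclose(d1.data, d2.data, atol=1e-10)

    def test_with_pseudocount_makes_counts_usable(self, toy_counts):
        t = dist.with_pseudocount(toy_counts, 0.5)
        assert t.is_proportion and (t.values > 0).all()
        np.testing.assert_allclose(t.values.sum(axis=1), 1.0, atol=1e-12)
        np.testing.assert_allclose(t.values[0], np.array([2.5, 3.5, 5.5, 0.5]) / 12.0)
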