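"""Summary statistics: tip metrics, assemblage metrics, shape, collinearity.

Brute-force oracles are implemented here independently of the package code
(explicit path enumeration, dendropy's distance matrix and gamma).
"""

import dendropy
import numpy as np
import pandas as pd
import pytest

from conftest import random_tree
from evospeed.summaries import (
    CladeBundle,
    assemblage_metrics,
    collinearity_filter,
    patristic_matrix,
    read_bundle,
    species_spatial_traits,
    summarize,
    tip_metrics,
    trait_distribution_stats,
    tree_shape,
    write_bundle,
)


def get_tree(newick: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=newick, schema="newick")


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def oracle_tip_metrics(tree: dendropy.Tree) -> pd.DataFrame:
    """ES/DR/ED/MRD by explicit root-to-tip path enumeration."""
    rows = {}
    # ED: iterate edges globally, share each among descendant tips
    ed = {leaf.taxon.label: 0.0 for leaf in tree.leaf_node_iter()}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        below = [l.taxon.label for l in node.leaf_iter()]
        for lab in below:
            ed[lab] += (node.edge.length or 0.0) / len(below)
    for leaf in tree.leaf_node_iter():
        path = []
        node = leaf
        while node.parent_node is not None:
            path.append(node)
            node = node.parent_node
        path = path[::-1]  # root-side first
        k = len(path)
        es = 0.0
        for i, n in enumerate(path):
            div = 1.0
            for j in range(i, k - 1):
                div *= len(path[j].child_nodes())
            es += (n.edge.length or 0.0) / div
        rows[leaf.taxon.label] = {
            "ES": es,
            "DR": 1.0 / es if es > 0 else np.nan,
            "ED": ed[leaf.taxon.label],
            "MRD": float(k),
        }
    return pd.DataFrame.from_dict(rows, orient="index").sort_index()


def oracle_patristic(tree: dendropy.Tree) -> tuple[np.ndarray, list]:
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    labels = [t.label for t in taxa]
    n = len(taxa)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i != j:
                D[i, j] = pdm.patristic_distance(taxa[i], taxa[j])
    return D, labels


def oracle_pd(tree: dendropy.Tree, present: set) -> float:
    """PD by union of root-to-tip edge sets."""
    edges = set()
    total = 0.0
    for leaf in tree.leaf_node_iter():
        if leaf.taxon.label not in present:
            continue
        node = leaf
        while node.parent_node is not None:
            if id(node) not in edges:
                edges.add(id(node))
                total += node.edge.length or 0.0
            node = node.parent_node
    return total


# ---------------------------------------------------------------------------
# hand-computed examples
# ---------------------------------------------------------------------------


class TestTipMetricsExamples:
    def test_two_tip_tree(self):
        t = get_tree("(t0:3.0,t1:3.0);")
        m = tip_metrics(t)
        assert np.allclose(m["ES"], 3.0)
        assert np.allclose(m["DR"], 1.0 / 3.0)
        assert np.allclose(m["ED"], 3.0)
        assert np.allclose(m["MRD"], 1.0)

    def test_balanced_four_tip_unit_edges(self):
        t = get_tree("((a:1,b:1):1,(c:1,d:1):1);")
        m = tip_metrics(t)
        assert np.allclose(m["ES"], 1.5)
        assert np.allclose(m["DR"], 2.0 / 3.0)
        assert np.allclose(m["MRD"], 2.0)

    def test_ed_sums_to_total_tree_length(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            t = random_tree(rng, int(rng.integers(2, 13)))
            total = sum(
                n.edge.length or 0.0 for n in t.preorder_node_iter() if n.parent_node
            )
            assert tip_metrics(t)["ED"].sum() == pytest.approx(total, rel=1e-10)

    def test_dr_is_inverse_es(self):
        rng = np.random.default_rng(1)
        t = random_tree(rng, 10)
        m = tip_metrics(t)
        assert np.allclose(m["DR"], 1.0 / m["ES"])


class TestTipMetricsOracle:
    def test_matches_bruteforce_on_random_trees(self):
        rng = np.random.default_rng(2024)
        for _ in range(100):
            t = random_tree(rng, int(rng.integers(2, 13)))
            got = tip_metrics(t)
            want = oracle_tip_metrics(t)
            for col in ("ES", "DR", "ED", "MRD"):
                assert np.allclose(got[col], want[col], atol=1e-10), col

    def test_patristic_matches_dendropy(self):
        rng = np.random.default_rng(7)
        for _ in range(15):
            t = random_tree(rng, int(rng.integers(2, 13)))
            got, labels = patristic_matrix(t)
            want, labels2 = oracle_patristic(t)
            assert labels == labels2
            assert np.allclose(got, want, atol=1e-10)


# ---------------------------------------------------------------------------
# assemblage metrics
# ---------------------------------------------------------------------------


def make_bundle(newick: str, occupancy_rows, body_size: dict, cells_rows) -> CladeBundle:
    return CladeBundle(
        tree=get_tree(newick),
        occupancy=pd.DataFrame(occupancy_rows, columns=["species_id", "cell_row", "cell_col"]),
        body_size=pd.Series(body_size, name="body_size"),
        cells=pd.DataFrame(cells_rows, columns=["cell_row", "cell_col", "temperature", "latitude"]),
    )


@pytest.fixture
def small_bundle():
    newick = "((a:1,b:1):1,(c:1,d:1):1);"
    occ = [
        ("a", 0, 0),
        ("b", 0, 0),
        ("c", 0, 0),
        ("a", 0, 1),
        ("b", 0, 1),
        ("c", 0, 1),
        ("d", 0, 1),
        ("d", 1, 0),
    ]
    bs = {"a": 0.2, "b": 0.4, "c": 0.6, "d": 0.8}
    cells = [(0, 0, 0.3, 10.0), (0, 1, 0.6, 30.0), (1, 0, 0.9, 50.0), (1, 1, 0.1, 70.0)]
    return make_bundle(newick, occ, bs, cells)


class TestAssemblageMetrics:
    def test_single_species_cell(self, small_bundle):
        out = assemblage_metrics(small_bundle).set_index(["cell_row", "cell_col"])
        row = out.loc[(1, 0)]
        assert row["richness"] == 1
        assert row["PD"] == pytest.approx(2.0)  # d's root-to-tip path
        assert np.isnan(row["MPD"]) and np.isnan(row["MNTD"]) and np.isnan(row["sd_body_size"])

    def test_all_species_cell_pd_is_total_length(self, small_bundle):
        out = assemblage_metrics(small_bundle).set_index(["cell_row", "cell_col"])
        assert out.loc[(0, 1), "PD"] == pytest.approx(6.0)

    def test_empty_cell_missing(self, small_bundle):
        out = assemblage_metrics(small_bundle).set_index(["cell_row", "cell_col"])
        assert out.loc[(1, 1), "richness"] == 0
        assert np.isnan(out.loc[(1, 1), "PD"])

    def test_mpd_three_species_bruteforce(self, small_bundle):
        out = assemblage_metrics(small_bundle).set_index(["cell_row", "cell_col"])
        # cell (0,0) holds a,b,c: pairwise distances ab=2, ac=4, bc=4
        assert out.loc[(0, 0), "MPD"] == pytest.approx((2 + 4 + 4) / 3)
        assert out.loc[(0, 0), "MNTD"] == pytest.approx((2 + 2 + 4) / 3)

    def test_pd_matches_bruteforce_on_random_assemblages(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            n = int(rng.integers(3, 13))
            tree = random_tree(rng, n)
            labels = sorted(l.taxon.label for l in tree.leaf_node_iter())
            occ = []
            for c in range(4):
                members = [s for s in labels if rng.random() < 0.5]
                occ.extend((s, 0, c) for s in members)
            if not occ:
                continue
            bundle = make_bundle(
                tree.as_string(schema="newick"),
                occ,
                {s: float(rng.uniform()) for s in labels},
                [(0, c, float(rng.uniform()), float(c)) for c in range(4)],
            )
            out = assemblage_metrics(bundle).set_index(["cell_row", "cell_col"])
            D, dl = patristic_matrix(bundle.tree)
            occ_df = pd.DataFrame(occ, columns=["species_id", "cell_row", "cell_col"])
            for c in range(4):
                present = set(occ_df[occ_df["cell_col"] == c]["species_id"])
                present &= set(dl)
                if not present:
                    continue
                assert out.loc[(0, c), "PD"] == pytest.approx(
                    oracle_pd(bundle.tree, present), abs=1e-10
                )
                if len(present) >= 2:
                    idx = [dl.index(s) for s in sorted(present)]
                    sub = D[np.ix_(idx, idx)]
                    iu = np.triu_indices(len(idx), 1)
                    assert out.loc[(0, c), "MPD"] == pytest.approx(sub[iu].mean(), abs=1e-10)
                    np.fill_diagonal(sub, np.inf)
                    assert out.loc[(0, c), "MNTD"] == pytest.approx(
                        sub.min(axis=1).mean(), abs=1e-10
                    )


class TestTreeShape:
    def test_three_tip_half_depth_gamma(self):
        t = get_tree("((a:0.5,b:0.5):0.5,c:1.0);")
        shape = tree_shape(t)
        # closed form: T_2=1, T_3=2.5 -> (1 - 1.25)/(2.5*sqrt(1/12))
        assert shape["gamma"] == pytest.approx(-0.25 / (2.5 * np.sqrt(1 / 12.0)))

    def test_gamma_matches_dendropy_on_random_ultrametric(self):
        from dendropy.calculate import treemeasure

        rng = np.random.default_rng(11)
        for _ in range(20):
            t = random_tree(rng, int(rng.integers(3, 13)), ultrametric=True)
            got = tree_shape(t)["gamma"]
            want = treemeasure.pybus_harvey_gamma(t)
            assert got == pytest.approx(want, abs=1e-8)

    def test_sackin_balanced_four_tip(self):
        t = get_tree("((a:1,b:1):1,(c:1,d:1):1);")
        shape = tree_shape(t)
        assert shape["sackin"] * shape["clade_size"] == pytest.approx(8.0)
        assert shape["clade_size"] == 4

    def test_caterpillar_more_imbalanced_than_balanced(self):
        balanced = tree_shape(get_tree("((a:1,b:1):1,(c:1,d:1):1);"))
        caterpillar = tree_shape(get_tree("(((a:1,b:1):1,c:2):1,d:3);"))
        assert caterpillar["sackin"] > balanced["sackin"]

    def test_non_ultrametric_warns(self):
        with pytest.warns(UserWarning, match="ultrametric"):
            tree_shape(get_tree("((a:1,b:5):1,c:1);"))


class TestSpeciesTraitsAndDistributions:
    def test_single_and_two_cell_species(self, small_bundle):
        out = species_spatial_traits(small_bundle)
        assert out.loc["d", "range_size"] == 2
        assert out.loc["a", "mean_range_temperature"] == pytest.approx((0.3 + 0.6) / 2)

    def test_range_sizes_sum_to_occupancy(self, small_bundle):
        out = species_spatial_traits(small_bundle)
        assert out["range_size"].sum() == len(small_bundle.occupancy)

    def test_symmetric_skewness_zero(self):
        m = trait_distribution_stats([1.0, 2.0, 3.0])
        assert m["skewness"] == pytest.approx(0.0, abs=1e-12)

    def test_right_tail_positive_skewness(self):
        assert trait_distribution_stats([0.0, 0.0, 0.0, 1.0])["skewness"] > 0

    def test_skewness_matches_moment_formula(self):
        x = np.array([0.1, 0.4, 0.2, 0.8, 0.9, 0.15, 0.33, 0.41, 0.05, 0.66])
        n = len(x)
        m2 = ((x - x.mean()) ** 2).mean()
        m3 = ((x - x.mean()) ** 3).mean()
        g1 = m3 / m2**1.5
        adj = np.sqrt(n * (n - 1)) / (n - 2) * g1
        assert trait_distribution_stats(x)["skewness"] == pytest.approx(adj, rel=1e-12)

    def test_degenerate_input_missing_moments(self):
        m = trait_distribution_stats([2.0, 2.0, 2.0, 2.0])
        assert np.isnan(m["skewness"]) and np.isnan(m["kurtosis"])
        assert m["mean"] == 2.0 and m["range"] == 0.0


class TestSummarizeVector:
    def test_deterministic_and_order_invariant(self, small_bundle):
        v1 = summarize(small_bundle)
        shuffled = CladeBundle(
            tree=get_tree(small_bundle.tree.as_string(schema="newick")),
            occupancy=small_bundle.occupancy.sample(frac=1.0, random_state=3).reset_index(
                drop=True
            ),
            body_size=small_bundle.body_size.sample(frac=1.0, random_state=4),
            cells=small_bundle.cells.sample(frac=1.0, random_state=5).reset_index(drop=True),
        )
        v2 = summarize(shuffled)
        assert v1.values.keys() == v2.values.keys()
        for k in v1.values:
            a, b = v1.values[k], v2.values[k]
            assert (np.isnan(a) and np.isnan(b)) or a == pytest.approx(b, rel=1e-12)

    def test_categories_partition_and_coverage(self, small_bundle):
        v = summarize(small_bundle)
        assert set(v.categories.values()) == {
            "phylo_corr",
            "spatial_corr",
            "trait_dist",
            "tree_shape",
        }
        assert len(v.values) >= 30
        assert set(v.values) == set(v.categories)

    def test_correlations_within_bounds_or_missing(self, small_bundle):
        v = summarize(small_bundle)
        for k, val in v.values.items():
            if k.startswith("cor_") and np.isfinite(val):
                assert -1.0 <= val <= 1.0

    def test_two_species_bundle_flags_missing(self):
        bundle = make_bundle(
            "(a:1,b:1);",
            [("a", 0, 0), ("b", 0, 1)],
            {"a": 0.3, "b": 0.5},
            [(0, 0, 0.2, 0.0), (0, 1, 0.7, 20.0)],
        )
        v = summarize(bundle)
        assert np.isnan(v.values["cor_ES_body_size"])  # n < 3 species
        assert np.isnan(v.values["gamma"])  # n < 3 tips


class TestCollinearityFilter:
    def test_identical_columns_one_retained(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=30)
        df = pd.DataFrame({"a": x, "b": x, "c": rng.normal(size=30)})
        kept = collinearity_filter(df, 0.9)
        assert sorted(kept) in (["a", "c"], ["b", "c"])
        assert len(kept) == 2

    def test_orthogonal_columns_all_retained(self):
        df = pd.DataFrame(
            {
                "a": [1.0, -1.0, 1.0, -1.0],
                "b": [1.0, 1.0, -1.0, -1.0],
                "c": [1.0, -1.0, -1.0, 1.0],
            }
        )
        assert sorted(collinearity_filter(df, 0.9)) == ["a", "b", "c"]

    def test_duplicated_pair_matches_exhaustive_search(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=50)
        y = rng.normal(size=50)
        z = rng.normal(size=50)
        df = pd.DataFrame({"a": x, "b": x + rng.normal(scale=0.01, size=50), "c": y, "d": z})
        kept = collinearity_filter(df, 0.90)
        assert len(kept) == 3
        # exhaustive: the largest subsets with no |r| > 0.9
        from itertools import combinations

        corr = df.corr().abs()
        best = 0
        valid_subsets = []
        for r in range(1, 5):
            for combo in combinations(df.columns, r):
                ok = all(
                    corr.loc[i, j] <= 0.90 for i, j in combinations(combo, 2)
                )
                if ok and r >= best:
                    if r > best:
                        valid_subsets = []
                    best = r
                    valid_subsets.append(set(combo))
        assert best == 3
        assert set(kept) in valid_subsets

    def test_constant_column_dropped_with_report(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame({"a": rng.normal(size=20), "b": np.ones(20), "c": rng.normal(size=20)})
        with pytest.warns(UserWarning, match="constant"):
            kept = collinearity_filter(df, 0.9)
        assert "b" not in kept

    def test_invariant_to_column_order(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=40)
        df = pd.DataFrame(
            {"a": x, "b": x * 1.001 + rng.normal(scale=1e-4, size=40), "c": rng.normal(size=40)}
        )
        kept1 = collinearity_filter(df, 0.9)
        kept2 = collinearity_filter(df[["c", "b", "a"]], 0.9)
        assert sorted(kept1) == sorted(kept2)


class TestBundleIO:
    def test_roundtrip_preserves_summary(self, small_bundle, tmp_path):
        v1 = summarize(small_bundle)
        write_bundle(small_bundle, tmp_path / "bundle")
        back = read_bundle(tmp_path / "bundle")
        v2 = summarize(back)
        for k in v1.values:
            a, b = v1.values[k], v2.values[k]
            assert (np.isnan(a) and np.isnan(b)) or a == pytest.approx(b, rel=1e-9)

    def test_mismatched_species_pruned_with_warning(self, small_bundle):
        occ = small_bundle.occupancy[small_bundle.occupancy["species_id"] != "d"]
        with pytest.warns(UserWarning, match="pruning"):
            bundle = CladeBundle(
                tree=get_tree(small_bundle.tree.as_string(schema="newick")),
                occupancy=occ.reset_index(drop=True),
                body_size=small_bundle.body_size,
                cells=small_bundle.cells,
            )
        assert bundle.n_species == 3
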