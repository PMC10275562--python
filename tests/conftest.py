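"""Shared fixtures: small landscapes and random-tree generation."""

from __future__ import annotations

import dendropy
import numpy as np
import pytest

from evospeed.landscape import LandscapeConfig, generate_landscape


@pytest.fixture(scope="session")
def flat_landscape():
    """A tiny all-land landscape with no terrain, for deterministic units."""
    cfg = LandscapeConfig(
        n_rows=10,
        n_cols=8,
        n_steps=12,
        land_fraction=1.0,
        elevation_scale_km=0.0,
        equator_pole_gradient=[30.0] * 12,
        global_anomaly=[0.0] * 12,
    )
    return generate_landscape(cfg)


@pytest.fixture(scope="session")
def default_landscape():
    """The package's default synthetic world (archipelago continents)."""
    return generate_landscape(LandscapeConfig())


def random_tree(rng: np.random.Generator, n_tips: int, ultrametric: bool = False) -> dendropy.Tree:
    """Random bifurcating tree with positive branch lengths.

    Topology by random sequential attachment; lengths U(0.1, 2).  With
    ``ultrametric`` the tree is a random coalescent-style tree whose tips all
    sit at the same depth.
    """
    assert n_tips >= 2
    if not ultrametric:
        labels = [f"t{i}" for i in range(n_tips)]
        newick = labels[0]
        # grow by splitting a random current leaf
        tree = dendropy.Tree()
        tree.seed_node.taxon = dendropy.Taxon(label=labels[0])
        leaves = [tree.seed_node]
        tns = tree.taxon_namespace
        for i in range(1, n_tips):
            node = leaves[rng.integers(len(leaves))]
            node.taxon = None
            left = node.new_child()
            right = node.new_child()
            left.taxon = dendropy.Taxon(label=f"t{2 * i}")
            right.taxon = dendropy.Taxon(label=f"t{2 * i + 1}")
            leaves.remove(node)
            leaves.extend([left, right])
        for node in tree.preorder_node_iter():
            if node.parent_node is not None:
                node.edge.length = float(rng.uniform(0.1, 2.0))
        for leaf in tree.leaf_node_iter():
            tns.add_taxon(leaf.taxon)
        return dendropy.Tree.get(data=tree.as_string(schema="newick"), schema="newick")
    # ultrametric: coalesce lineages at increasing heights
    height = 0.0
    nodes = []
    for i in range(n_tips):
        n = dendropy.Node(taxon=dendropy.Taxon(label=f"t{i}"))
        n._h = 0.0
        nodes.append(n)
    while len(nodes) > 1:
        height += float(rng.uniform(0.1, 1.0))
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = dendropy.Node()
        parent._h = height
        a, b = nodes[i], nodes[j]
        parent.add_child(a)
        parent.add_child(b)
        a.edge.length = height - a._h
        b.edge.length = height - b._h
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    tree = dendropy.Tree(seed_node=nodes[0])
    for leaf in tree.leaf_node_iter():
        tree.taxon_namespace.add_taxon(leaf.taxon)
    return dendropy.Tree.get(data=tree.as_string(schema="newick"), schema="newick")
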