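"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from kefirmeta.taxonomy import RANK_ORDER, TaxonNode, TaxonomyTree


def make_random_tree(rng: np.random.Generator, n_nodes: int) -> TaxonomyTree:
    """Random rooted tree: node i attaches to a uniformly chosen earlier node.

    Ranks are drawn at random (including no_rank), so rank queries see
    arbitrary interleavings rather than tidy lineages.
    """
    ranks = RANK_ORDER[1:] + ["no_rank"]
    nodes = [TaxonNode("t0", "root", "root", "t0")]
    for i in range(1, n_nodes):
        parent = f"t{int(rng.integers(0, i))}"
        rank = ranks[int(rng.integers(0, len(ranks)))]
        nodes.append(TaxonNode(f"t{i}", f"node {i}", rank, parent))
    return TaxonomyTree(nodes)


def brute_force_lca(tree: TaxonomyTree, taxa) -> str:
    """Oracle: intersect explicit root paths, return the deepest common node."""
    common = None
    for t in taxa:
        path = set(tree.root_path(t))
        common = path if common is None else (common & path)
    assert common
    return max(common, key=tree.depth)


@pytest.fixture
def simple_tree() -> TaxonomyTree:
    """Hand-built lineage: root → domain → phylum → family → two genera with
    species/subspecies, plus a no_rank clade between family and genus."""
    nodes = [
        TaxonNode("root", "root", "root", "root"),
        TaxonNode("dom", "Bacteria", "domain", "root"),
        TaxonNode("phy", "Firmicutes", "phylum", "dom"),
        TaxonNode("fam", "Lactobacillaceae", "family", "phy"),
        TaxonNode("clade", "unranked clade", "no_rank", "fam"),
        TaxonNode("genA", "Lactobacillus", "genus", "clade"),
        TaxonNode("genB", "Pediococcus", "genus", "fam"),
        TaxonNode("spgrp", "casei group", "species_group", "genA"),
        TaxonNode("spA1", "L. hilgardii", "species", "genA"),
        TaxonNode("spA2", "L. nagelii", "species", "genA"),
        TaxonNode("spA3", "L. paracasei", "species", "spgrp"),
        TaxonNode("subA3", "L. paracasei subsp.", "subspecies", "spA3"),
        TaxonNode("spB1", "P. damnosus", "species", "genB"),
    ]
    return TaxonomyTree(nodes)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20190313)
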