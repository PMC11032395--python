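"""Shared fixtures: tiny handcrafted taxonomies and oracle helpers."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.optimize import linprog

from metaprof.taxonomy import EVAL_RANKS, TaxonNode, TaxonomyTree


def build_tree(edges: list[tuple[str, str, str]]) -> TaxonomyTree:
    """Tree from (taxon_id, parent_id, rank) triples; a root node is added."""
    nodes = [TaxonNode("1", "1", "root", "root")]
    nodes += [TaxonNode(t, p, r, t) for t, p, r in edges]
    return TaxonomyTree(nodes)


@pytest.fixture
def small_tree() -> TaxonomyTree:
    """Two genera in one family; two species per genus, full rank chain."""
    return build_tree([
        ("sk1", "1", "superkingdom"),
        ("p1", "sk1", "phylum"),
        ("c1", "p1", "class"),
        ("o1", "c1", "order"),
        ("f1", "o1", "family"),
        ("g1", "f1", "genus"),
        ("g2", "f1", "genus"),
        ("sA", "g1", "species"),
        ("sB", "g1", "species"),
        ("sC", "g2", "species"),
        ("sD", "g2", "species"),
    ])


@pytest.fixture
def two_phylum_tree() -> TaxonomyTree:
    """Two phyla with one species each (for disjoint-profile cases)."""
    edges = [("sk1", "1", "superkingdom")]
    for i, sp in enumerate(["sX", "sY"], start=1):
        edges += [
            (f"p{i}", "sk1", "phylum"),
            (f"c{i}", f"p{i}", "class"),
            (f"o{i}", f"c{i}", "order"),
            (f"f{i}", f"o{i}", "family"),
            (f"g{i}", f"f{i}", "genus"),
            (sp, f"g{i}", "species"),
        ]
    return build_tree(edges)


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def tree_distance(tree: TaxonomyTree, a: str, b: str) -> int:
    """Official-rank steps between two nodes via their LCA (oracle metric)."""
    lca = tree.lca({a, b})
    ia = tree.official_rank_index(a)
    ib = tree.official_rank_index(b)
    il = tree.official_rank_index(lca)
    return (ia - il) + (ib - il)


def emd_lp_oracle(tree: TaxonomyTree, m1: dict[str, float], m2: dict[str, float]) -> float:
    """Exhaustive min-cost transport LP between two node-mass distributions."""
    src = sorted(t for t, m in m1.items() if m > 0)
    dst = sorted(t for t, m in m2.items() if m > 0)
    if not src and not dst:
        return 0.0
    cost = np.array([[tree_distance(tree, a, b) for b in dst] for a in src], dtype=float)
    n, m = len(src), len(dst)
    a_eq = []
    b_eq = []
    for i in range(n):
        row = np.zeros(n * m)
        row[i * m:(i + 1) * m] = 1
        a_eq.append(row)
        b_eq.append(m1[src[i]])
    for j in range(m):
        row = np.zeros(n * m)
        row[j::m] = 1
        a_eq.append(row)
        b_eq.append(m2[dst[j]])
    res = linprog(cost.ravel(), A_eq=np.array(a_eq), b_eq=np.array(b_eq),
                  bounds=(0, None), method="highs")
    assert res.success, res.message
    return float(res.fun)


def unifrac_node_masses(tree: TaxonomyTree, annotations) -> dict[str, float]:
    """Oracle mass placement: one unit per read on its annotation node,
    counting only reads annotated at phylum rank or deeper, normalised."""
    phylum_idx = tree.rank_index("phylum")
    counts: dict[str, float] = {}
    for a in annotations:
        if a.taxon is None:
            continue
        if tree.official_rank_index(a.taxon) < phylum_idx:
            continue
        # clamp below-species structure: mass sits on the deepest official-rank
        # projection of the annotation (profiles only see official ranks)
        node = a.taxon
        for rank in reversed(EVAL_RANKS):
            t = tree.taxon_at_rank(a.taxon, rank)
            if t is not None:
                node = t
                break
        counts[node] = counts.get(node, 0.0) + 1.0
    total = sum(counts.values())
    return {t: c / total for t, c in counts.items()} if total else {}
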