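"""Independent brute-force oracles used by the test suite.

The delineation oracle is deliberately written against scikit-bio's
TreeNode (a different tree library and traversal path than the
implementation) and enumerates *every* clade of the tree, so agreement is
meaningful.
"""

from __future__ import annotations

import io
from typing import Iterable

from skbio import TreeNode


def brute_force_partition(newick: str, ref_ids: Iterable[str]):
    """Per-query minimal anchored clade by exhaustive clade enumeration.

    Returns ``(partition, anchor_refs)`` where *partition* is a set of
    frozensets of query tips sharing a minimal anchored clade and
    *anchor_refs* maps each member frozenset to the reference tips of that
    clade.
    """
    refs = set(ref_ids)
    tree = TreeNode.read(io.StringIO(newick))
    clades: list[frozenset[str]] = []
    for node in tree.traverse(include_self=True):
        if node.is_tip():
            clades.append(frozenset([node.name]))
        else:
            clades.append(frozenset(t.name for t in node.tips()))
    queries = {t.name for t in tree.tips()} - refs

    anchor_of: dict[str, frozenset[str]] = {}
    for q in queries:
        anchored = [c for c in clades if q in c and c & refs]
        anchor_of[q] = min(anchored, key=len)

    groups: dict[frozenset[str], set[str]] = {}
    for q, clade in anchor_of.items():
        groups.setdefault(clade, set()).add(q)
    partition = {frozenset(v) for v in groups.values()}
    anchors = {frozenset(v): frozenset(k & refs) for k, v in groups.items()}
    return partition, anchors


def random_anchored_tree(rng, max_tips: int = 20) -> tuple[str, list[str]]:
    """Random rooted tree (bifurcating root, occasional polytomies below)
    with at least one reference and one query tip.  Returns (newick, refs)."""
    n = rng.randint(3, max_tips)
    n_ref = rng.randint(1, n - 1)
    labels = [f"R{i}" for i in range(n_ref)] + [f"q{i}" for i in range(n - n_ref)]
    rng.shuffle(labels)
    frags = [f"{lab}:{rng.uniform(0.05, 1.0):.3f}" for lab in labels]
    while len(frags) > 2:
        a = frags.pop(rng.randrange(len(frags)))
        b = frags.pop(rng.randrange(len(frags)))
        if rng.random() < 0.2 and len(frags) > 1:
            c = frags.pop(rng.randrange(len(frags)))
            frags.append(f"({a},{b},{c}):{rng.uniform(0.05, 1.0):.3f}")
        else:
            frags.append(f"({a},{b}):{rng.uniform(0.05, 1.0):.3f}")
    newick = f"({frags[0]},{frags[1]});"
    return newick, [f"R{i}" for i in range(n_ref)]
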