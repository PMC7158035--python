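"""Rooted-tree plumbing shared by the simulator and the gain/loss inference.

Trees are Newick strings with branch lengths in million years (My), parsed
with dendropy.  A branch is identified by the set of leaf labels below its
child node; the canonical key is those labels sorted and joined with '|',
which is stable across independent parses of the same topology.
"""

from __future__ import annotations

import dendropy


def parse_tree(newick: str) -> dendropy.Tree:
    tree = dendropy.Tree.get(data=newick, schema="newick")
    tree.is_rooted = True
    return tree


def leaf_labels(node) -> list[str]:
    return sorted(lf.taxon.label for lf in node.leaf_iter())


def branch_key(node) -> str:
    """Canonical identifier of the branch above `node`."""
    return "|".join(leaf_labels(node))


def branch_table(tree: dendropy.Tree) -> dict[str, float]:
    """branch key -> length (My) for every branch, including the root branch
    (length 0 if the Newick gives the root no edge length)."""
    out = {}
    for node in tree.preorder_node_iter():
        length = node.edge.length if node.edge.length is not None else 0.0
        out[branch_key(node)] = float(length)
    return out
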