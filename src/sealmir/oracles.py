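"""Independent brute-force oracles used to cross-check the fast paths.

These deliberately avoid the implementations they check: the folding
oracle enumerates nested structures recursively with no DP table, and the
Dollo oracle minimizes losses over every possible single-gain placement.
"""

from __future__ import annotations

from ._seq import CAN_PAIR
from .fold import MIN_LOOP


def enumerate_max_pairs(seq: str, lo: int = 0, hi: int | None = None) -> int:
    """Maximum nested pair count by exhaustive recursion: position `lo` is
    left unpaired, or paired with every admissible partner k."""
    if hi is None:
        hi = len(seq)
    if hi - lo <= MIN_LOOP:
        return 0
    best = enumerate_max_pairs(seq, lo + 1, hi)
    for k in range(lo + MIN_LOOP + 1, hi):
        if (seq[lo], seq[k]) in CAN_PAIR:
            cand = (1 + enumerate_max_pairs(seq, lo + 1, k)
                    + enumerate_max_pairs(seq, k + 1, hi))
            if cand > best:
                best = cand
    return best


def dollo_min_losses(tree, present: set[str]) -> int:
    """Minimum loss count over all single-gain placements on a dendropy
    tree for a leaf presence set (brute force over gain nodes)."""
    leafsets = {}
    for node in tree.preorder_node_iter():
        leafsets[node] = {lf.taxon.label for lf in node.leaf_iter()}
    best = None
    for gain in tree.preorder_node_iter():
        if not present <= leafsets[gain]:
            continue
        losses = 0
        stack = [gain]
        while stack:
            nd = stack.pop()
            for ch in nd.child_nodes():
                if leafsets[ch] & present:
                    stack.append(ch)
                else:
                    losses += 1
        if best is None or losses < best:
            best = losses
    return best
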