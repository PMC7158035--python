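"""RNA secondary structure by base-pair maximization.

A Nussinov-style dynamic program over Watson-Crick plus G:U wobble pairs,
with a minimum hairpin loop of 3 nt and a deterministic traceback.  The
result is a nested (pseudoknot-free) structure with the maximum number of
base pairs; ties are broken by always pairing the smallest available 5'
index with the smallest admissible partner.  This is a deliberately simple,
oracle-verifiable stand-in for thermodynamic folding: pair count, not free
energy, is the optimized quantity.
"""

from __future__ import annotations

from dataclasses import dataclass

from ._seq import CAN_PAIR

MIN_LOOP = 3  # unpaired nt strictly inside any pair
MIN_HAIRPIN_LEN = 40
MAX_HAIRPIN_LEN = 300


@dataclass
class FoldStructure:
    """A folded sequence summarized for miR-likeness classification.

    duplex_pairs counts the pairs stacked on the path enclosing the dominant
    hairpin loop (the pairs joining the two arms of that stem); n_stems counts
    hairpin loops whose closing chains carry at least 3 pairs.
    """

    sequence: str
    dotbracket: str
    pairs: list[tuple[int, int]]
    n_pairs: int
    n_stems: int
    loop_size: int
    loop_span: tuple[int, int] | None
    duplex_pairs: int
    unpaired_fraction: float


def _pairable(a: str, b: str) -> bool:
    return (a, b) in CAN_PAIR


def _pair_matrix(seq: str, forbidden: set[int] | None = None):
    import numpy as np

    n = len(seq)
    can = np.zeros((n, n), dtype=bool)
    for a, b in CAN_PAIR:
        ia = np.flatnonzero(np.frombuffer(seq.encode(), np.uint8)
                            == ord(a))
        ib = np.flatnonzero(np.frombuffer(seq.encode(), np.uint8)
                            == ord(b))
        if len(ia) and len(ib):
            can[np.ix_(ia, ib)] = True
    if forbidden:
        idx = sorted(forbidden)
        can[idx, :] = False
        can[:, idx] = False
    return can


def max_pairs_table(seq: str, forbidden: set[int] | None = None):
    """DP table M[i][j] = max nested pairs on seq[i..j]; padded ndarray."""
    import numpy as np

    n = len(seq)
    M = np.zeros((n + 2, n + 2), dtype=np.int32)
    if n == 0:
        return M
    can = _pair_matrix(seq, forbidden)
    for span in range(MIN_LOOP + 1, n):
        for i in range(0, n - span):
            j = i + span
            ks = np.arange(i + MIN_LOOP + 1, j + 1)
            ok = can[i, ks]
            best = int(M[i + 1, j])
            if ok.any():
                cand = 1 + M[i + 1, ks - 1] + M[ks + 1, j]
                best = max(best, int(cand[ok].max()))
            M[i, j] = best
    return M


def _traceback(seq: str, M: list[list[int]]) -> list[tuple[int, int]]:
    pairs: list[tuple[int, int]] = []
    if not seq:
        return pairs
    stack = [(0, len(seq) - 1)]
    while stack:
        i, j = stack.pop()
        if j - i <= MIN_LOOP:
            continue
        # prefer pairing the 5'-most index; among partners take the smallest k
        paired = False
        for k in range(i + MIN_LOOP + 1, j + 1):
            if _pairable(seq[i], seq[k]):
                inner = M[i + 1][k - 1] if k - 1 > i else 0
                right = M[k + 1][j] if k + 1 <= j else 0
                if 1 + inner + right == M[i][j]:
                    pairs.append((i, k))
                    if k - 1 > i + 1:
                        stack.append((i + 1, k - 1))
                    if k + 1 < j:
                        stack.append((k + 1, j))
                    paired = True
                    break
        if not paired:
            stack.append((i + 1, j))
    return sorted(pairs)


def _pair_forest(pairset: list[tuple[int, int]]):
    """parent/children maps of the nesting forest of a nested pair set."""
    parent: dict[tuple[int, int], tuple[int, int] | None] = {}
    children: dict[tuple[int, int] | None, list[tuple[int, int]]] = {None: []}
    stack: list[tuple[int, int]] = []
    for p in pairset:  # sorted by i; nestedness makes this a valid sweep
        while stack and not (stack[-1][0] < p[0] and p[1] < stack[-1][1]):
            stack.pop()
        par = stack[-1] if stack else None
        parent[p] = par
        children.setdefault(par, []).append(p)
        children.setdefault(p, [])
        stack.append(p)
    return parent, children


def _terminal_chain(leaf, parent, children):
    """The stem chain ending in `leaf`: the leaf plus ancestors passed
    through while each carries a single nested branch (bulges and internal
    loops extend a stem; multiloops end it)."""
    chain = [leaf]
    node = leaf
    while True:
        par = parent.get(node)
        if par is None or len(children[par]) != 1:
            break
        chain.append(par)
        node = par
    return chain


def _annotate(seq: str, pairs: list[tuple[int, int]]) -> FoldStructure:
    n = len(seq)
    db = ["."] * n
    for i, j in pairs:
        db[i], db[j] = "(", ")"
    pairset = sorted(pairs)

    # Pair maximization decorates real stems with spurious lone pairs and
    # 1-2 pair stems; for the stem-level statistics (not n_pairs, which
    # stays the true maximum) drop helices stacked fewer than 3 deep, then
    # prune terminal chains under 3 pairs while more than one hairpin loop
    # remains, so the dominant stem is read cleanly.
    kept = list(pairset)
    while True:
        helices: list[list[tuple[int, int]]] = []
        ks = set(kept)
        for p in sorted(kept):
            if (p[0] - 1, p[1] + 1) in ks:
                helices[-1].append(p)
            else:
                helices.append([p])
        drop = {p for h in helices if len(h) <= 2 for p in h}
        if not drop or len(drop) == len(kept):
            break
        kept = [p for p in kept if p not in drop]
    while True:
        parent, children = _pair_forest(kept)
        leaves = [p for p in kept if not children[p]]
        if len(leaves) <= 1:
            break
        chains = {lf: _terminal_chain(lf, parent, children) for lf in leaves}
        small = [lf for lf in leaves if len(chains[lf]) < 3]
        if not small:
            break
        if len(small) == len(leaves):
            small.sort(key=lambda lf: (len(chains[lf]), lf))
            small = small[:-1]  # keep the largest terminal stem
            if not small:
                break
        drop = set()
        for lf in small:
            drop.update(chains[lf])
        kept = [p for p in kept if p not in drop]
        if not kept:
            kept = list(pairset)
            break

    parent, children = _pair_forest(kept)
    leaves = [p for p in kept if not children[p]]
    stems = [(lf, _terminal_chain(lf, parent, children)) for lf in leaves]
    n_stems = sum(1 for _, chain in stems if len(chain) >= 3)
    if stems:
        (li, lj), chain = max(stems, key=lambda s: (len(s[1]), -s[0][0]))
        loop_size = lj - li - 1
        loop_span = (li + 1, lj)
        duplex_pairs = len(chain)
    else:
        loop_size = n
        loop_span = None
        duplex_pairs = 0

    return FoldStructure(
        sequence=seq,
        dotbracket="".join(db),
        pairs=pairset,
        n_pairs=len(pairset),
        n_stems=n_stems,
        loop_size=loop_size,
        loop_span=loop_span,
        duplex_pairs=duplex_pairs,
        unpaired_fraction=(n - 2 * len(pairset)) / n if n else 1.0,
    )


def fold_sequence(seq: str) -> FoldStructure:
    """Fold an arbitrary-length sequence (no length policing)."""
    seq = seq.upper().replace("U", "T")
    M = max_pairs_table(seq)
    pairs = _traceback(seq, M)
    return _annotate(seq, pairs)


def fold_hairpin(seq: str) -> FoldStructure:
    """Fold a candidate pre-miRNA; rejects sequences outside 40-300 nt."""
    if not (MIN_HAIRPIN_LEN <= len(seq) <= MAX_HAIRPIN_LEN):
        raise ValueError(
            f"hairpin length {len(seq)} outside [{MIN_HAIRPIN_LEN}, "
            f"{MAX_HAIRPIN_LEN}] nt"
        )
    return fold_sequence(seq)


def max_pairs_constrained(seq: str, forbidden: set[int]) -> int:
    """Maximum pair count when positions in `forbidden` must stay unpaired."""
    seq = seq.upper().replace("U", "T")
    n = len(seq)
    if n < 2:
        return 0
    M = max_pairs_table(seq, forbidden=forbidden)
    return int(M[0, n - 1])
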