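"""Independent brute-force oracles used by the test suite.

These deliberately re-derive expected values by enumeration or direct
recomputation, sharing no code path with the implementation they check.
"""

from __future__ import annotations

import numpy as np

from ghmotif.io import AA_INDEX
from ghmotif.signatures import NEG_INF


def brute_force_glocal(profile, seq: str) -> float:
    """Best glocal alignment score by exhaustive enumeration.

    Grammar mirrors the documented scorer contract: optional leading
    deletion run, gap runs separated by at least one match, no
    insertion adjacent to a deletion, at least one match, trailing
    deletion run allowed, sequence flanks free. Affine run cost
    open + (k-1)·extend.
    """
    m = profile.length
    L = profile.log_odds
    go, ge = profile.gap_open, profile.gap_extend
    n = len(seq)
    aa = [AA_INDEX.get(c, -1) for c in seq.upper()]
    best = [NEG_INF]

    def gap_cost(k: int) -> float:
        return go + (k - 1) * ge

    def try_match(i: int, j: int, score: float, nmatch: int) -> None:
        if aa[j] >= 0:
            e = L[i, aa[j]]
            if e > NEG_INF:
                extend(i + 1, j + 1, score + e, nmatch + 1)

    def extend(i: int, j: int, score: float, nmatch: int) -> None:
        """Continue after a match at profile i-1 / sequence j-1."""
        if i == m:
            best[0] = max(best[0], score)
            return
        if j < n:
            try_match(i, j, score, nmatch)
        # insertion run, must be followed by a match
        for k in range(1, n - j):
            try_match(i, j + k, score - gap_cost(k), nmatch)
        # deletion run: ends the alignment or is followed by a match
        for k in range(1, m - i + 1):
            if i + k == m:
                best[0] = max(best[0], score - gap_cost(k))
            elif j < n:
                try_match(i + k, j, score - gap_cost(k), nmatch)

    for js in range(n):          # free choice of first matched position
        try_match(0, js, 0.0, 0)
        for k in range(1, m):    # leading deletion run then first match
            if aa[js] >= 0:
                e = L[k, aa[js]]
                if e > NEG_INF:
                    extend(k + 1, js + 1, -gap_cost(k) + e, 1)
    return best[0]


def cophenetic_by_traversal(tree) -> dict[frozenset, float]:
    """Pairwise leaf distances recomputed by explicit path traversal."""
    parents = {}

    def walk(node, parent):
        parents[id(node)] = (node, parent)
        for c in node.children:
            walk(c, node)

    walk(tree.root, None)
    leaves = {}

    def collect(node):
        if node.is_leaf:
            leaves[node.label] = node
        for c in node.children:
            collect(c)

    collect(tree.root)

    def ancestors(node):
        chain = []
        cur = node
        while cur is not None:
            chain.append(cur)
            cur = parents[id(cur)][1]
        return chain

    out = {}
    labels = sorted(leaves)
    for i, a in enumerate(labels):
        chain_a = ancestors(leaves[a])
        ids_a = [id(x) for x in chain_a]
        for b in labels[i + 1:]:
            cur = leaves[b]
            while id(cur) not in ids_a:
                cur = parents[id(cur)][1]
            out[frozenset((a, b))] = 2.0 * cur.height
    return out


def best_motif_window_scan(z: np.ndarray, hairpin: tuple[int, int],
                           min_length: int = 8, max_length: int = 18):
    """Reference window scan: maximal summed z-score containing the hairpin."""
    h0, h1 = hairpin
    n = len(z)
    best = None
    for length in range(max(min_length, h1 - h0 + 1), max_length + 1):
        for start in range(0, n - length + 1):
            end = start + length - 1
            if start <= h0 and h1 <= end:
                key = (-float(np.sum(z[start:end + 1])), length, start)
                if best is None or key < best:
                    best = key
    assert best is not None
    return best[2], best[2] + best[1] - 1
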