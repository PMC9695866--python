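"""Independent oracles used by the test suite.

Everything here is deliberately naive and self-contained (own IUPAC tables,
pure-python loops) so it checks the library implementation without sharing
code paths with it.
"""

from __future__ import annotations

import math
import random

# independent IUPAC table (typed afresh, not imported from the package)
SETS = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
    "R": {"A", "G"}, "Y": {"C", "T"}, "S": {"C", "G"}, "W": {"A", "T"},
    "K": {"G", "T"}, "M": {"A", "C"},
    "B": {"C", "G", "T"}, "D": {"A", "G", "T"}, "H": {"A", "C", "T"},
    "V": {"A", "C", "G"}, "N": {"A", "C", "G", "T"},
}
COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}


def compatible(a: str, b: str) -> bool:
    return bool(SETS[a] & SETS[b])


def revcomp(s: str) -> str:
    out = []
    for ch in reversed(s):
        comp_set = frozenset(COMP[b] for b in SETS[ch])
        code = next(k for k, v in SETS.items() if frozenset(v) == comp_set)
        out.append(code)
    return "".join(out)


def window_mismatch_offsets_plus(primer: str, window: str) -> list[int]:
    """3'-offsets of mismatches for a forward primer laid on a plus window."""
    k = len(primer)
    return sorted(k - 1 - i for i in range(k) if not compatible(primer[i], window[i]))


def window_mismatch_offsets_minus(primer: str, window: str) -> list[int]:
    """3'-offsets for a reverse primer whose site is the plus-strand window."""
    rc = revcomp(primer)
    return sorted(i for i in range(len(rc)) if not compatible(rc[i], window[i]))


def brute_force_sites(primer: str, template: str):
    """Every window on both strands: (strand, start, offsets)."""
    k = len(primer)
    out = []
    for start in range(len(template) - k + 1):
        window = template[start : start + k]
        out.append(("plus", start, window_mismatch_offsets_plus(primer, window)))
        out.append(("minus", start, window_mismatch_offsets_minus(primer, window)))
    return out


def brute_force_best(primer: str, template: str, strand: str):
    sites = [s for s in brute_force_sites(primer, template) if s[0] == strand]
    return min(sites, key=lambda s: (len(s[2]), s[1]))


def random_iupac(rng: random.Random, length: int, degenerate_frac: float = 0.1) -> str:
    codes = list(SETS)
    plain = "ACGT"
    return "".join(
        rng.choice(codes) if rng.random() < degenerate_frac else rng.choice(plain)
        for _ in range(length)
    )


def random_dna(rng: random.Random, length: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(length))


# --- additive trees for NJ oracles -----------------------------------------


def random_additive_tree(rng: random.Random, n_taxa: int):
    """Random binary topology with positive branch lengths.

    Returns (adjacency dict node -> [(neighbor, length)], leaf names).
    Built by sequential attachment of leaves to random edges.
    """
    adj: dict[str, list[tuple[str, float]]] = {}

    def add_edge(a, b, w):
        adj.setdefault(a, []).append((b, w))
        adj.setdefault(b, []).append((a, w))

    def del_edge(a, b):
        adj[a] = [(x, w) for x, w in adj[a] if x != b]
        adj[b] = [(x, w) for x, w in adj[b] if x != a]

    def blen():
        return rng.uniform(0.05, 1.0)

    leaves = [f"L{i}" for i in range(n_taxa)]
    add_edge(leaves[0], leaves[1], blen())
    internal = 0
    for leaf in leaves[2:]:
        edges = sorted(
            {tuple(sorted((a, b))) for a in adj for b, _ in adj[a]}
        )
        a, b = edges[rng.randrange(len(edges))]
        w = next(w for x, w in adj[a] if x == b)
        internal += 1
        mid = f"I{internal}"
        split = rng.uniform(0.2, 0.8) * w
        del_edge(a, b)
        add_edge(a, mid, split)
        add_edge(mid, b, w - split)
        add_edge(mid, leaf, blen())
    return adj, leaves


def path_length_matrix(adj, leaves):
    """All-pairs leaf path lengths by BFS (the additive-matrix oracle)."""
    import collections

    n = len(leaves)
    mat = [[0.0] * n for _ in range(n)]
    for i, src in enumerate(leaves):
        dist = {src: 0.0}
        queue = collections.deque([src])
        while queue:
            u = queue.popleft()
            for v, w in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + w
                    queue.append(v)
        for j, dst in enumerate(leaves):
            mat[i][j] = dist[dst]
    return mat


def tree_bipartitions(adj, leaves) -> set[frozenset[str]]:
    """Non-trivial bipartitions (as the smaller/canonical leaf set) of an
    adjacency-list tree."""
    import collections

    out = set()
    edges = {tuple(sorted((a, b))) for a in adj for b, _ in adj[a]}
    leafset = set(leaves)
    for a, b in edges:
        # leaves on b's side when edge (a, b) is cut
        seen = {a, b}
        queue = collections.deque([b])
        side = set()
        while queue:
            u = queue.popleft()
            if u in leafset:
                side.add(u)
            for v, _ in adj[u]:
                if v not in seen:
                    seen.add(v)
                    queue.append(v)
        if 1 < len(side) < len(leaves) - 1:
            out.add(frozenset(sorted(side if leaves[0] not in side else leafset - side)))
    return out


def jc_expected_p(d: float) -> float:
    return 0.75 * (1.0 - math.exp(-4.0 * d / 3.0))


def tn93_invert(p1: float, p2: float, q: float, freqs) -> float:
    """Moment (closed-form) TN93 distance — independent inverse formula."""
    pa, pc, pg, pt = freqs
    pr, py = pa + pg, pc + pt
    a1 = -math.log(1 - pr * p1 / (2 * pa * pg) - q / (2 * pr))
    a2 = -math.log(1 - py * p2 / (2 * pc * pt) - q / (2 * py))
    b = -math.log(1 - q / (2 * pr * py))
    return (
        2 * pa * pg / pr * (a1 - py * b)
        + 2 * pc * pt / py * (a2 - pr * b)
        + 2 * pr * py * b
    )
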