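"""Pairwise evolutionary distances, neighbor-joining, bootstrap, rooting.

Distances are substitutions per site between aligned COI sequences with
*pairwise deletion*: for each sequence pair, only columns where both rows
carry an unambiguous A/C/G/T are retained.  Three estimators are provided:

``p_distance``
    the raw proportion of differing retained columns;
``jc``
    Jukes-Cantor correction, the equal-rate limit;
``mcl``
    a composite-likelihood scheme on the Tamura-Nei (TN93) model: base
    frequencies are taken from the whole alignment and the two
    transition/transversion rate ratios (purine k1 = alpha1/beta,
    pyrimidine k2 = alpha2/beta) are estimated once by maximizing the sum
    of pairwise log-likelihoods over all pairs; each pair's distance is
    then the 1-D maximum-likelihood fit given those shared parameters.

Trees are built with the Saitou-Nei neighbor-joining agglomeration and are
exact on additive matrices.  Bootstrap supports resample alignment columns
with replacement, rebuild distance + NJ per replicate, and annotate each
internal edge of the full-data tree with the percentage of replicates whose
tree contains the same bipartition.  Trees are dendropy objects; Newick
export goes through dendropy.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy import optimize

from .seq_core import Alignment, NucleotideSequence

__all__ = [
    "DistanceMatrix",
    "pairwise_deletion_mask",
    "p_distance",
    "jc_distance",
    "distance_matrix",
    "mcl_distance_matrix",
    "tn93_expected_differences",
    "neighbor_joining",
    "bootstrap_supports",
    "root_with_outgroup",
    "barcoding_gap",
    "write_newick",
]

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
#: distances larger than this are treated as saturated and flagged
SATURATION_BOUND = 10.0
_MIN_FREQ = 1e-4


# ---------------------------------------------------------------------------
# encoding and masks


def _residues(x: str | NucleotideSequence) -> str:
    return x.residues if isinstance(x, NucleotideSequence) else x.upper()


def _encode(s: str) -> np.ndarray:
    """A/C/G/T -> 0..3; gaps and ambiguity codes -> -1 (dropped pairwise)."""
    return np.array([_CODE.get(c, -1) for c in s], dtype=np.int8)


def pairwise_deletion_mask(a: str | NucleotideSequence, b: str | NucleotideSequence) -> np.ndarray:
    """Indices of columns where both rows are unambiguous A/C/G/T."""
    ca, cb = _encode(_residues(a)), _encode(_residues(b))
    if len(ca) != len(cb):
        raise ValueError(f"rows differ in length: {len(ca)} vs {len(cb)}")
    return np.flatnonzero((ca >= 0) & (cb >= 0))


def p_distance(a: str | NucleotideSequence, b: str | NucleotideSequence) -> float:
    """Proportion of differing sites among pairwise-retained columns."""
    ca, cb = _encode(_residues(a)), _encode(_residues(b))
    if len(ca) != len(cb):
        raise ValueError(f"rows differ in length: {len(ca)} vs {len(cb)}")
    keep = (ca >= 0) & (cb >= 0)
    n = int(keep.sum())
    if n == 0:
        raise ValueError("no retained columns for this pair")
    return float((ca[keep] != cb[keep]).sum() / n)


def jc_distance(a: str | NucleotideSequence, b: str | NucleotideSequence) -> float:
    """Jukes-Cantor distance; saturated pairs (p >= 3/4) return inf."""
    p = p_distance(a, b)
    if p >= 0.75:
        return math.inf
    return -0.75 * math.log1p(-4.0 * p / 3.0)


# ---------------------------------------------------------------------------
# distance matrix container


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix in substitutions per site.

    ``sites_used[i, j]`` is the number of retained columns for the pair,
    ``flagged[i, j]`` marks saturated cells replaced by the fallback value
    (the largest finite unflagged distance in the matrix).
    """

    taxa: list[str]
    values: np.ndarray
    method: str
    deletion: str = "pairwise"
    sites_used: np.ndarray | None = None
    flagged: np.ndarray | None = None
    model_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.taxa), len(self.taxa)):
            raise ValueError("matrix shape does not match taxa")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("diagonal must be exactly zero")
        if np.any(v < 0):
            raise ValueError("distances must be non-negative")
        self.values = v
        if self.flagged is None:
            self.flagged = np.zeros_like(v, dtype=bool)

    def __len__(self) -> int:
        return len(self.taxa)

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.taxa.index(a), self.taxa.index(b)])

    def to_dataframe(self, scale: float = 1.0) -> pd.DataFrame:
        return pd.DataFrame(self.values * scale, index=self.taxa, columns=self.taxa)

    def to_csv(self, path: str | Path, scale: float = 1.0, lower_triangular: bool = False) -> None:
        """Full or MEGA-style lower-triangular CSV (optionally x100 scaled)."""
        df = self.to_dataframe(scale)
        if lower_triangular:
            arr = df.to_numpy().astype(object)
            arr[np.triu_indices(len(self.taxa))] = ""
            df = pd.DataFrame(arr, index=self.taxa, columns=self.taxa)
        df.to_csv(path, index_label="taxon")


# ---------------------------------------------------------------------------
# TN93 composite-likelihood machinery


def _base_frequencies(codes: np.ndarray) -> np.ndarray:
    """Global base frequencies over unambiguous residues, floor-clamped."""
    counts = np.array([(codes == i).sum() for i in range(4)], dtype=float)
    if counts.sum() == 0:
        raise ValueError("alignment contains no unambiguous residues")
    freqs = counts / counts.sum()
    freqs = np.maximum(freqs, _MIN_FREQ)
    return freqs / freqs.sum()


def _pair_counts(ci: np.ndarray, cj: np.ndarray) -> tuple[int, int, int, int]:
    """(matches, purine transitions, pyrimidine transitions, transversions)."""
    keep = (ci >= 0) & (cj >= 0)
    a, b = ci[keep], cj[keep]
    same = int((a == b).sum())
    lo = np.minimum(a, b)
    hi = np.maximum(a, b)
    p1 = int(((lo == 0) & (hi == 2)).sum())  # A<->G
    p2 = int(((lo == 1) & (hi == 3)).sum())  # C<->T
    q = int(len(a)) - same - p1 - p2
    return same, p1, p2, q


def tn93_expected_differences(
    d: float, k1: float, k2: float, freqs: Sequence[float]
) -> tuple[float, float, float]:
    """Expected (P1, P2, Q) difference proportions at TN93 distance ``d``.

    ``k1``/``k2`` are the purine/pyrimidine transition-to-transversion rate
    ratios; ``freqs`` are (piA, piC, piG, piT).
    """
    pa, pc, pg, pt = freqs
    pr, py = pa + pg, pc + pt
    if d <= 0:
        return 0.0, 0.0, 0.0
    # beta*tau from d = tau * 2(alpha1 piA piG + alpha2 piC piT + beta piR piY)
    bt = d / (2.0 * (k1 * pa * pg + k2 * pc * pt + pr * py))
    e_b = math.exp(-bt)
    e1 = math.exp(-(pr * k1 + py) * bt)
    e2 = math.exp(-(py * k2 + pr) * bt)
    p1 = 2.0 * pa * pg / pr * (pr + py * e_b - e1)
    p2 = 2.0 * pc * pt / py * (py + pr * e_b - e2)
    q = 2.0 * pr * py * (1.0 - e_b)
    return p1, p2, q


def _pair_negloglik(
    d: float, counts: tuple[int, int, int, int], k1: float, k2: float, freqs: Sequence[float]
) -> float:
    m, c1, c2, q = counts
    p1, p2, pq = tn93_expected_differences(d, k1, k2, freqs)
    pm = 1.0 - p1 - p2 - pq
    ll = 0.0
    for count, prob in ((m, pm), (c1, p1), (c2, p2), (q, pq)):
        if count:
            if prob <= 0:
                return math.inf
            ll += count * math.log(prob)
    return -ll


def _fit_pair_distance(
    counts: tuple[int, int, int, int], k1: float, k2: float, freqs: Sequence[float]
) -> float:
    m, c1, c2, q = counts
    if c1 + c2 + q == 0:
        return 0.0
    res = optimize.minimize_scalar(
        _pair_negloglik,
        bounds=(1e-9, SATURATION_BOUND),
        args=(counts, k1, k2, freqs),
        method="bounded",
        options={"xatol": 1e-8},
    )
    return float(res.x)


def _moment_rate_ratios(
    pooled: tuple[int, int, int, int], freqs: Sequence[float]
) -> tuple[float, float]:
    """Moment (inverse-formula) estimate of k1, k2 from pooled counts."""
    m, c1, c2, q = pooled
    n = m + c1 + c2 + q
    if n == 0 or q == 0:
        return 2.0, 2.0
    pa, pc, pg, pt = freqs
    pr, py = pa + pg, pc + pt
    P1, P2, Q = c1 / n, c2 / n, q / n
    try:
        a1 = -math.log(1.0 - pr * P1 / (2.0 * pa * pg) - Q / (2.0 * pr))
        a2 = -math.log(1.0 - py * P2 / (2.0 * pc * pt) - Q / (2.0 * py))
        b = -math.log(1.0 - Q / (2.0 * pr * py))
    except ValueError:
        return 2.0, 2.0
    if b <= 0:
        return 2.0, 2.0
    k1 = max((a1 - py * b) / (pr * b), 0.05)
    k2 = max((a2 - pr * b) / (py * b), 0.05)
    return k1, k2


def _estimate_rate_ratios(
    pair_counts: list[tuple[int, int, int, int]], freqs: Sequence[float]
) -> tuple[float, float]:
    """Shared (k1, k2) maximizing the composite (sum-of-pairs) likelihood.

    Each pair's distance is profiled out by a nested 1-D ML fit.  Started
    from the pooled moment estimate and refined by Nelder-Mead on the log
    scale.
    """
    pooled = tuple(int(x) for x in np.sum(pair_counts, axis=0))
    k1_0, k2_0 = _moment_rate_ratios(pooled, freqs)
    informative = [c for c in pair_counts if c[1] + c[2] + c[3] > 0]
    if not informative:
        return k1_0, k2_0

    def neg_composite(logk: np.ndarray) -> float:
        k1, k2 = math.exp(logk[0]), math.exp(logk[1])
        if not (1e-3 < k1 < 1e3 and 1e-3 < k2 < 1e3):
            return math.inf
        total = 0.0
        for c in informative:
            d = _fit_pair_distance(c, k1, k2, freqs)
            total += _pair_negloglik(d, c, k1, k2, freqs)
        return total

    res = optimize.minimize(
        neg_composite,
        x0=[math.log(k1_0), math.log(k2_0)],
        method="Nelder-Mead",
        options={"maxiter": 80, "xatol": 1e-3, "fatol": 1e-4},
    )
    return float(math.exp(res.x[0])), float(math.exp(res.x[1]))


def _apply_saturation_fallback(values: np.ndarray, flagged: np.ndarray) -> None:
    """Replace saturated cells by the largest finite unflagged distance."""
    if not flagged.any():
        return
    finite_ok = values[~flagged & np.isfinite(values)]
    fallback = float(finite_ok.max()) if finite_ok.size else SATURATION_BOUND
    values[flagged] = fallback


def _alignment_codes(alignment: Alignment) -> np.ndarray:
    return np.vstack([_encode(r.residues) for r in alignment.rows])


def distance_matrix(alignment: Alignment, method: str = "mcl") -> DistanceMatrix:
    """Pairwise-deletion distance matrix under the chosen estimator."""
    if method == "mcl":
        return mcl_distance_matrix(alignment)
    codes = _alignment_codes(alignment)
    n = len(alignment.rows)
    values = np.zeros((n, n))
    sites = np.zeros((n, n), dtype=int)
    flagged = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            m, c1, c2, q = _pair_counts(codes[i], codes[j])
            tot = m + c1 + c2 + q
            if tot == 0:
                raise ValueError(
                    f"no retained columns for pair ({alignment.ids[i]}, {alignment.ids[j]})"
                )
            sites[i, j] = sites[j, i] = tot
            p = (c1 + c2 + q) / tot
            if method == "p_distance":
                d = p
            elif method == "jc":
                d = math.inf if p >= 0.75 else -0.75 * math.log1p(-4.0 * p / 3.0)
                if not math.isfinite(d):
                    flagged[i, j] = flagged[j, i] = True
            else:
                raise ValueError(f"unknown distance method {method!r}")
            values[i, j] = values[j, i] = d
    _apply_saturation_fallback(values, flagged)
    return DistanceMatrix(
        taxa=list(alignment.ids),
        values=values,
        method=method,
        sites_used=sites,
        flagged=flagged,
    )


def mcl_distance_matrix(alignment: Alignment) -> DistanceMatrix:
    """TN93-form composite-likelihood distances with pairwise deletion.

    Base frequencies and the two transition/transversion rate ratios are
    estimated once from the whole alignment, then each pair's distance is
    the 1-D ML fit given those shared parameters.  Cells hitting the
    saturation bound are flagged and set to the largest finite unflagged
    distance so downstream NJ stays runnable.
    """
    codes = _alignment_codes(alignment)
    n = len(alignment.rows)
    if n < 2:
        raise ValueError("need at least 2 rows")
    freqs = _base_frequencies(codes)
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    counts = []
    sites = np.zeros((n, n), dtype=int)
    for i, j in pairs:
        c = _pair_counts(codes[i], codes[j])
        tot = sum(c)
        if tot == 0:
            raise ValueError(
                f"no retained columns for pair ({alignment.ids[i]}, {alignment.ids[j]})"
            )
        sites[i, j] = sites[j, i] = tot
        counts.append(c)
    k1, k2 = _estimate_rate_ratios(counts, freqs)
    values = np.zeros((n, n))
    flagged = np.zeros((n, n), dtype=bool)
    for (i, j), c in zip(pairs, counts):
        d = _fit_pair_distance(c, k1, k2, freqs)
        if d >= SATURATION_BOUND * 0.999:
            flagged[i, j] = flagged[j, i] = True
        values[i, j] = values[j, i] = d
    _apply_saturation_fallback(values, flagged)
    return DistanceMatrix(
        taxa=list(alignment.ids),
        values=values,
        method="mcl",
        sites_used=sites,
        flagged=flagged,
        model_params={"k1": k1, "k2": k2, "freqs": tuple(float(f) for f in freqs)},
    )


# ---------------------------------------------------------------------------
# neighbor joining


def neighbor_joining(
    dm: DistanceMatrix, taxon_namespace: dendropy.TaxonNamespace | None = None
) -> dendropy.Tree:
    """Saitou-Nei neighbor joining; unrooted dendropy tree.

    Q-matrix minimization with deterministic first-minimum tie-break;
    negative branch lengths are clamped to zero with the deficit moved to
    the sibling branch of the same join.
    """
    n = len(dm.taxa)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    tns = taxon_namespace or dendropy.TaxonNamespace(dm.taxa)
    nodes: list[dendropy.Node] = []
    for t in dm.taxa:
        node = dendropy.Node(taxon=tns.require_taxon(t))
        nodes.append(node)
    D = dm.values.astype(float).copy()

    def _clamp_pair(li: float, lj: float) -> tuple[float, float]:
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        return max(li, 0.0), max(lj, 0.0)

    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        i, j = np.unravel_index(np.argmin(Q), Q.shape)
        if i > j:
            i, j = j, i
        dij = D[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        li, lj = _clamp_pair(li, lj)
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        nodes[i].edge.length = li
        parent.add_child(nodes[j])
        nodes[j].edge.length = lj
        new_row = 0.5 * (D[i, :] + D[j, :] - dij)
        keep = [k for k in range(m) if k not in (i, j)]
        D = np.vstack([D[keep][:, keep], new_row[keep]])
        D = np.hstack([D, np.append(new_row[keep], 0.0)[:, None]])
        nodes = [nodes[k] for k in keep] + [parent]

    # final three nodes join at an unrooted trifurcation
    d01, d02, d12 = D[0, 1], D[0, 2], D[1, 2]
    lengths = [
        0.5 * (d01 + d02 - d12),
        0.5 * (d01 + d12 - d02),
        0.5 * (d02 + d12 - d01),
    ]
    center = dendropy.Node()
    for node, length in zip(nodes, lengths):
        center.add_child(node)
        node.edge.length = max(length, 0.0)
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = center
    tree.is_rooted = False
    return tree


def _internal_edges(tree: dendropy.Tree) -> list[dendropy.Edge]:
    return [
        e
        for e in tree.preorder_edge_iter()
        if e.tail_node is not None and not e.head_node.is_leaf()
    ]


# ---------------------------------------------------------------------------
# bootstrap


def bootstrap_supports(
    alignment: Alignment,
    replicates: int = 1000,
    seed: int = 0,
    method: str = "mcl",
) -> dendropy.Tree:
    """Full-data NJ tree with bootstrap support percentages on internal edges.

    Columns are resampled with replacement per replicate (single seeded
    stream, deterministic replicate order); distances and NJ are recomputed
    per replicate and each internal edge of the full-data tree is annotated
    with the percentage of replicate trees containing its bipartition.
    Replicates where some pair retains no columns are dropped, counted in
    ``tree.bootstrap_dropped``, and reported with a warning.
    """
    codes = _alignment_codes(alignment)
    n, L = codes.shape
    taxa = list(alignment.ids)
    full_dm = distance_matrix(alignment, method)
    tns = dendropy.TaxonNamespace(taxa)
    tree = neighbor_joining(full_dm, tns)
    tree.encode_bipartitions()
    target = {e.bipartition.split_bitmask: e for e in _internal_edges(tree)}
    hit_counts = {mask: 0 for mask in target}

    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    # per-pair per-column category: 0 unusable, 1 match, 2 A<->G, 3 C<->T, 4 tv
    cat = np.zeros((len(pairs), L), dtype=np.uint8)
    for p, (i, j) in enumerate(pairs):
        a, b = codes[i], codes[j]
        usable = (a >= 0) & (b >= 0)
        lo, hi = np.minimum(a, b), np.maximum(a, b)
        c = np.full(L, 4, dtype=np.uint8)
        c[a == b] = 1
        c[(lo == 0) & (hi == 2)] = 2
        c[(lo == 1) & (hi == 3)] = 3
        c[~usable] = 0
        cat[p] = c
    onehot = np.stack([(cat == k) for k in (1, 2, 3, 4)]).astype(float)

    if method == "mcl":
        k1 = full_dm.model_params["k1"]
        k2 = full_dm.model_params["k2"]
        freqs = full_dm.model_params["freqs"]

    rng = np.random.default_rng(seed)
    dropped = 0
    effective = 0
    for _ in range(replicates):
        draw = rng.integers(0, L, size=L)
        w = np.bincount(draw, minlength=L).astype(float)
        cnt = onehot @ w  # (4, n_pairs)
        totals = cnt.sum(axis=0)
        if np.any(totals == 0):
            dropped += 1
            continue
        values = np.zeros((n, n))
        for p, (i, j) in enumerate(pairs):
            m_, c1, c2, q = (int(round(cnt[k, p])) for k in range(4))
            if method == "mcl":
                d = _fit_pair_distance((m_, c1, c2, q), k1, k2, freqs)
            else:
                prop = (c1 + c2 + q) / (m_ + c1 + c2 + q)
                if method == "p_distance":
                    d = prop
                else:  # jc
                    d = SATURATION_BOUND if prop >= 0.75 else -0.75 * math.log1p(-4 * prop / 3)
            values[i, j] = values[j, i] = d
        rep_dm = DistanceMatrix(taxa=taxa, values=values, method=method)
        rep_tree = neighbor_joining(rep_dm, tns)
        rep_tree.encode_bipartitions()
        rep_splits = {e.bipartition.split_bitmask for e in _internal_edges(rep_tree)}
        for mask in hit_counts:
            if mask in rep_splits:
                hit_counts[mask] += 1
        effective += 1

    if dropped:
        warnings.warn(
            f"{dropped} of {replicates} bootstrap replicates dropped "
            "(a pair retained no columns)"
        )
    supports: dict[int, float] = {}
    for mask, edge in target.items():
        pct = 100.0 * hit_counts[mask] / effective if effective else float("nan")
        supports[mask] = pct
        edge.head_node.label = str(int(round(pct)))
    tree.bipartition_supports = supports
    tree.bootstrap_replicates = replicates
    tree.bootstrap_effective = effective
    tree.bootstrap_dropped = dropped
    return tree


def support_for_clade(tree: dendropy.Tree, labels: Sequence[str]) -> float:
    """Bootstrap support (%) of the edge separating ``labels`` from the rest."""
    tns = tree.taxon_namespace
    mask = 0
    for lab in labels:
        taxon = tns.get_taxon(lab)
        if taxon is None:
            raise KeyError(lab)
        mask |= tns.taxon_bitmask(taxon)
    tree.encode_bipartitions()
    norm = dendropy.Bipartition.normalize_bitmask(mask, tns.all_taxa_bitmask())
    supports = getattr(tree, "bipartition_supports", None)
    if supports is None or norm not in supports:
        raise KeyError(f"no internal edge separates {list(labels)}")
    return supports[norm]


# ---------------------------------------------------------------------------
# rooting and reports


def root_with_outgroup(tree: dendropy.Tree, outgroup_labels: Sequence[str]) -> dendropy.Tree:
    """Root on the edge separating a monophyletic outgroup from the ingroup.

    The edge length is split evenly across the new root.  A non-monophyletic
    outgroup raises, naming the smallest clade containing all outgroup taxa.
    """
    if not outgroup_labels:
        raise ValueError("no outgroup labels given")
    tns = tree.taxon_namespace
    mask = 0
    for lab in outgroup_labels:
        taxon = tns.get_taxon(lab)
        if taxon is None:
            raise KeyError(f"outgroup taxon {lab!r} not in tree")
        mask |= tns.taxon_bitmask(taxon)
    full = tns.all_taxa_bitmask()
    if mask == full:
        raise ValueError("outgroup cannot contain every taxon")
    tree.encode_bipartitions()
    edge = None
    for e in tree.preorder_edge_iter():
        if e.tail_node is None:
            continue
        leafset = e.bipartition.leafset_bitmask
        if leafset == mask or leafset == (full & ~mask):
            edge = e
            break
    if edge is None:
        # name the conflict: smallest clade containing all outgroup taxa
        best = full
        for e in tree.preorder_edge_iter():
            ls = e.bipartition.leafset_bitmask
            if ls & mask == mask and bin(ls).count("1") < bin(best).count("1"):
                best = ls
        clade = [t.label for t in tns if tns.taxon_bitmask(t) & best]
        raise ValueError(
            f"outgroup {list(outgroup_labels)} is not monophyletic; smallest "
            f"containing clade is {sorted(clade)}"
        )
    half = (edge.length or 0.0) / 2.0
    tree.reroot_at_edge(edge, length1=half, length2=half)
    tree.is_rooted = True
    _relabel_supports(tree)
    return tree


def _relabel_supports(tree: dendropy.Tree) -> None:
    """Re-derive internal node labels from stored bipartition supports.

    Node labels travel with nodes when a tree is rerooted, but a support
    value belongs to an *edge* (bipartition); after rerooting the labels
    must be reassigned from the bipartition table."""
    supports = getattr(tree, "bipartition_supports", None)
    if supports is None:
        return
    tree.encode_bipartitions()
    full = tree.taxon_namespace.all_taxa_bitmask()
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            continue
        node.label = None
        if node.parent_node is None:
            continue
        mask = dendropy.Bipartition.normalize_bitmask(
            node.edge.bipartition.leafset_bitmask, full
        )
        if mask in supports:
            node.label = str(int(round(supports[mask])))


def barcoding_gap(
    dm: DistanceMatrix,
    groups: Mapping[str, str],
    exclude: Sequence[str] = (),
) -> dict:
    """Largest intraspecific vs smallest interspecific distance.

    ``groups`` maps taxon id -> species label; taxa in ``exclude`` (e.g.
    outgroups) are ignored.  The gap is positive when the smallest
    between-species distance exceeds the largest within-species distance —
    the condition for barcode-based species discrimination.
    """
    keep = [t for t in dm.taxa if t not in set(exclude)]
    intra, inter = [], []
    for x, a in enumerate(keep):
        for b in keep[x + 1 :]:
            d = dm.get(a, b)
            (intra if groups[a] == groups[b] else inter).append(d)
    max_intra = max(intra) if intra else None
    min_inter = min(inter) if inter else None
    gap = None
    if max_intra is not None and min_inter is not None:
        gap = min_inter - max_intra
    return {
        "max_intraspecific": max_intra,
        "min_interspecific": min_inter,
        "gap": gap,
        "gap_positive": (gap is not None and gap > 0),
    }


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    Path(path).write_text(
        tree.as_string(schema="newick", suppress_rooting=False)
    )
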