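"""Search for species-specific primer pairs on a target COI alignment.

The design criterion mirrors how diagnostic COI primers are built: a
candidate primer must match *every* target sequence perfectly while showing
mismatches — ideally at its 3' end, where they block extension — against
every non-target.  Candidates are drawn from the target consensus; reverse
candidates are reverse complements of consensus windows.  Non-targets are
screened by best-binding-site search over the full sequence (they may be
unalignable with the targets), in the orientation that would amplify the
homologous locus.

The scan is exact and exhaustive over all window positions and lengths; a
diagonal cumulative-sum trick makes the all-windows x all-placements
mismatch table O(L_target x L_nontarget) per window length.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .seq_core import (
    IUPAC_BITS,
    IUPAC_SETS,
    Alignment,
    NucleotideSequence,
    Primer,
    PrimerRole,
    SequenceSource,
    reverse_complement,
)

__all__ = [
    "DesignConstraints",
    "PrimerPairCandidate",
    "consensus",
    "enumerate_discriminative_primers",
    "candidates_to_dataframe",
]


@dataclass(frozen=True)
class DesignConstraints:
    """Constraints for the discriminative primer-pair search.

    ``clamp_window`` defines the 3'-terminal region (nt) in which
    ``min_clamp_mismatches`` must fall for every non-target and both
    primers; it is wider than the polymerase-blocking clamp of the
    extension rule because design wants a margin of 3'-proximal
    discrimination, not just the terminal two bases.
    """

    primer_length: tuple[int, int] = (18, 32)
    product_length: tuple[int, int] = (150, 1200)
    min_mismatches: int = 1
    min_clamp_mismatches: int = 1
    clamp_window: int = 5
    max_degeneracy: int = 1
    gc_bounds: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        lo, hi = self.primer_length
        if not (10 <= lo <= hi):
            raise ValueError("invalid primer length range")
        plo, phi = self.product_length
        if not (2 * lo <= plo <= phi):
            raise ValueError("product length range inconsistent with primer lengths")


@dataclass
class PrimerPairCandidate:
    """A forward/reverse pair matching all targets and mismatching non-targets.

    ``per_nontarget[id] = {"fw": (total, clamp), "rv": (total, clamp)}``
    records, at each primer's best binding site on that non-target, the total
    mismatch count and the count within the 3' clamp window.
    """

    forward: Primer
    reverse: Primer
    fw_start: int
    rv_start: int
    product_length: int
    per_nontarget: dict[str, dict[str, tuple[int, int]]] = field(default_factory=dict)

    @property
    def worst_clamp_mismatches(self) -> int:
        """Minimum 3'-window mismatch count over non-targets and primers."""
        return min(
            min(v["fw"][1], v["rv"][1]) for v in self.per_nontarget.values()
        )

    @property
    def worst_total_mismatches(self) -> int:
        return min(
            min(v["fw"][0], v["rv"][0]) for v in self.per_nontarget.values()
        )


def consensus(target_alignment: Alignment | Sequence[NucleotideSequence]) -> NucleotideSequence:
    """Strict-majority consensus; ties and gap-majority columns become N.

    A base wins a column when more than half of *all* rows carry it
    unambiguously; ambiguity codes and gaps never vote.
    """
    rows = (
        target_alignment.rows
        if isinstance(target_alignment, Alignment)
        else list(target_alignment)
    )
    if not rows:
        raise ValueError("empty target alignment")
    if len(rows) == 1:
        return NucleotideSequence(
            id="consensus", residues=rows[0].residues, source=SequenceSource.SYNTHETIC,
            allow_gaps=True,
        )
    n = len(rows)
    cols = len(rows[0])
    out = []
    for c in range(cols):
        counts: dict[str, int] = {}
        for r in rows:
            ch = r.residues[c]
            if ch in "ACGT":
                counts[ch] = counts.get(ch, 0) + 1
        best = max(counts, key=counts.get) if counts else None
        out.append(best if best is not None and counts[best] * 2 > n else "N")
    return NucleotideSequence(
        id="consensus", residues="".join(out), source=SequenceSource.SYNTHETIC,
        allow_gaps=True,
    )


def _bits(s: str) -> np.ndarray:
    return np.array([IUPAC_BITS.get(c, 0) for c in s], dtype=np.uint8)


def _diagonal_cumsum(compat: np.ndarray) -> np.ndarray:
    """D[x, y] = number of compatible pairs on the diagonal ending at (x, y),
    with a zero-padded first row/column for O(1) window sums."""
    lc, lt = compat.shape
    D = np.zeros((lc + 1, lt + 1), dtype=np.int32)
    for x in range(lc):
        D[x + 1, 1:] = np.concatenate(([0], D[x, 1:-1])) + compat[x]
    return D


class _NonTargetScan:
    """Best-placement mismatch tables of consensus windows on one non-target."""

    def __init__(self, cons_bits: np.ndarray, template: NucleotideSequence):
        tbits = _bits(template.residues)
        self.lt = len(tbits)
        compat = (cons_bits[:, None] & tbits[None, :]) != 0
        self.D = _diagonal_cumsum(compat)

    def window_profiles(self, k: int, clamp: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(total, fw_clamp, rv_clamp) mismatch counts at the best placement
        of every length-k consensus window; best = max matches, first on tie
        (matching find_best_binding_site's tie rule)."""
        lc = self.D.shape[0] - 1
        n_windows = lc - k + 1
        cw = min(clamp, k)
        if self.lt < k:
            full = np.full(n_windows, k, dtype=int)
            cl = np.full(n_windows, cw, dtype=int)
            return full, cl, cl
        # matches[s, t] = D[s+k, t+k] - D[s, t]
        M = self.D[k:, k:] - self.D[:-k, :-k]  # (n_windows, placements)
        t_best = M.argmax(axis=1)
        s_idx = np.arange(n_windows)
        total = k - M[s_idx, t_best]
        # forward 3' clamp = last cw columns; reverse 3' clamp = first cw
        fw_matches = (
            self.D[s_idx + k, t_best + k] - self.D[s_idx + k - cw, t_best + k - cw]
        )
        rv_matches = self.D[s_idx + cw, t_best + cw] - self.D[s_idx, t_best]
        return total, cw - fw_matches, cw - rv_matches


def _column_degeneracy(residues: str) -> np.ndarray:
    degen = np.array(
        [len(IUPAC_SETS[c]) if c in IUPAC_SETS else 0 for c in residues], dtype=float
    )
    return degen  # per-column degeneracy (0 marks gaps)


def enumerate_discriminative_primers(
    target_alignment: Alignment | Sequence[NucleotideSequence],
    nontargets: Sequence[NucleotideSequence],
    constraints: DesignConstraints | None = None,
) -> list[PrimerPairCandidate]:
    """All primer pairs perfectly matching the targets and mismatching every
    non-target in the 3' clamp window.

    Ranked by (worst-case clamp mismatches, then worst-case total mismatches,
    descending); ties broken by product length then coordinates, so the
    order is deterministic.  No candidate is an error condition: the result
    is simply empty (e.g. when a non-target is indistinguishable from the
    target consensus).
    """
    c = constraints or DesignConstraints()
    cons = consensus(target_alignment)
    rows = (
        target_alignment.rows
        if isinstance(target_alignment, Alignment)
        else list(target_alignment)
    )
    lc = len(cons)
    cons_bits = _bits(cons.residues)

    # per-column: every target row compatible with the consensus base
    col_ok = np.ones(lc, dtype=bool)
    degen = _column_degeneracy(cons.residues)
    col_ok &= degen > 0  # gaps never enter a primer
    for r in rows:
        rbits = _bits(r.residues)
        col_ok &= (rbits & cons_bits) != 0
    ok_cum = np.concatenate(([0], np.cumsum(col_ok)))
    log_degen = np.concatenate(([0.0], np.cumsum(np.log(np.maximum(degen, 1e-9)))))
    gc = np.array([ch in "GCS" for ch in cons.residues], dtype=float)
    gc_cum = np.concatenate(([0.0], np.cumsum(gc)))

    scans = [_NonTargetScan(cons_bits, t) for t in nontargets]
    ntg_ids = [t.id for t in nontargets]

    fw_windows: list[tuple[int, int, list[tuple[int, int]]]] = []
    rv_windows: list[tuple[int, int, list[tuple[int, int]]]] = []
    kmin, kmax = c.primer_length
    for k in range(kmin, kmax + 1):
        if k > lc:
            break
        n_windows = lc - k + 1
        starts = np.arange(n_windows)
        valid = (ok_cum[starts + k] - ok_cum[starts]) == k
        valid &= np.exp(log_degen[starts + k] - log_degen[starts]) <= c.max_degeneracy + 0.5
        if c.gc_bounds is not None:
            frac = (gc_cum[starts + k] - gc_cum[starts]) / k
            valid &= (frac >= c.gc_bounds[0]) & (frac <= c.gc_bounds[1])
        if not valid.any():
            continue
        profiles = [scan.window_profiles(k, c.clamp_window) for scan in scans]
        fw_ok = valid.copy()
        rv_ok = valid.copy()
        for total, fw_clamp, rv_clamp in profiles:
            fw_ok &= (total >= c.min_mismatches) & (fw_clamp >= c.min_clamp_mismatches)
            rv_ok &= (total >= c.min_mismatches) & (rv_clamp >= c.min_clamp_mismatches)
        for s in np.flatnonzero(fw_ok):
            summary = [(int(p[0][s]), int(p[1][s])) for p in profiles]
            fw_windows.append((int(s), k, summary))
        for s in np.flatnonzero(rv_ok):
            summary = [(int(p[0][s]), int(p[2][s])) for p in profiles]
            rv_windows.append((int(s), k, summary))

    plo, phi = c.product_length
    candidates: list[PrimerPairCandidate] = []
    for fs, fk, fsum in fw_windows:
        for rs, rk, rsum in rv_windows:
            if fs + fk > rs:
                continue
            product = rs + rk - fs
            if not (plo <= product <= phi):
                continue
            fw_seq = cons.residues[fs : fs + fk]
            rv_seq = reverse_complement(cons.residues[rs : rs + rk])
            candidates.append(
                PrimerPairCandidate(
                    forward=Primer(f"fw_{fs}_{fk}", fw_seq, PrimerRole.FORWARD),
                    reverse=Primer(f"rv_{rs}_{rk}", rv_seq, PrimerRole.REVERSE),
                    fw_start=fs,
                    rv_start=rs,
                    product_length=product,
                    per_nontarget={
                        tid: {"fw": f, "rv": r}
                        for tid, f, r in zip(ntg_ids, fsum, rsum)
                    },
                )
            )
    candidates.sort(
        key=lambda cand: (
            -cand.worst_clamp_mismatches,
            -cand.worst_total_mismatches,
            cand.product_length,
            cand.fw_start,
            cand.rv_start,
        )
    )
    return candidates


def candidates_to_dataframe(candidates: Sequence[PrimerPairCandidate]) -> pd.DataFrame:
    """Candidate table: sequences, product length, worst-case discrimination."""
    return pd.DataFrame(
        [
            {
                "forward": cand.forward.sequence,
                "reverse": cand.reverse.sequence,
                "fw_start": cand.fw_start,
                "rv_start": cand.rv_start,
                "product_length": cand.product_length,
                "worst_clamp_mismatches": cand.worst_clamp_mismatches,
                "worst_total_mismatches": cand.worst_total_mismatches,
            }
            for cand in candidates
        ],
        columns=[
            "forward",
            "reverse",
            "fw_start",
            "rv_start",
            "product_length",
            "worst_clamp_mismatches",
            "worst_total_mismatches",
        ],
    )
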