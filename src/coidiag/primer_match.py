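"""Primer/template binding-site search and 3'-end extension prediction.

A primer is slid over every window of a template (both strands); at each
window, aligned (primer code, template code) pairs are compared by IUPAC
base-set intersection.  Mismatch positions are recorded as offsets from the
primer's 3' terminus (offset 0 = terminal base), because Taq-family
polymerases are blocked by 3'-terminal mispairs: a mismatch within the last
couple of bases prevents extension, which is the mechanism species-specific
primers exploit.  Whether a site supports amplification is decided by an
:class:`ExtensionRule` — no mismatch inside the 3' clamp and a bounded total
mismatch count.  Matching is purely combinatorial; there is no melting
temperature or duplex free-energy model.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .seq_core import IUPAC_BITS, NucleotideSequence, Primer, reverse_complement

__all__ = [
    "Strand",
    "MatchProfile",
    "ExtensionRule",
    "find_best_binding_site",
    "all_binding_sites",
    "predicts_extension",
    "mismatch_report",
]


class Strand(str, enum.Enum):
    PLUS = "plus"
    MINUS = "minus"


@dataclass(frozen=True)
class MatchProfile:
    """One primer/template binding site with its per-position mismatch record.

    ``interval`` is 0-based half-open on the template's plus strand
    regardless of strand.  ``mismatch_positions`` are offsets from the
    primer's 3' terminus (0 = terminal base), sorted ascending.
    """

    primer_name: str
    template_id: str
    strand: Strand
    start: int
    end: int
    mismatch_positions: tuple[int, ...]
    window_sequence: str

    def __post_init__(self) -> None:
        if self.end - self.start != len(self.window_sequence):
            raise ValueError("interval length must equal window length")
        if any(o < 0 or o >= self.end - self.start for o in self.mismatch_positions):
            raise ValueError("mismatch offset outside primer length")

    @property
    def total_mismatches(self) -> int:
        return len(self.mismatch_positions)

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass(frozen=True)
class ExtensionRule:
    """When does a binding site support polymerase extension?

    ``clamp_length`` 3'-terminal positions must be mismatch-free and the
    total mismatch count must not exceed ``max_total_mismatches``.  The
    defaults (clamp 2, total 4) reproduce the observed panel behaviour:
    primers with a single internal mismatch amplify, primers with a mismatch
    on the last or next-to-last base do not.
    """

    max_total_mismatches: int = 4
    clamp_length: int = 2

    def __post_init__(self) -> None:
        if self.clamp_length < 1:
            raise ValueError("clamp_length must be >= 1")
        if self.max_total_mismatches < 0:
            raise ValueError("max_total_mismatches must be >= 0")


Ambiguity = Literal["optimistic", "pessimistic"]


def _bits(s: str) -> np.ndarray:
    return np.array([IUPAC_BITS[c] for c in s], dtype=np.uint8)


def _window_match_matrix(
    primer_bits: np.ndarray, template_bits: np.ndarray, ambiguous: Ambiguity
) -> np.ndarray:
    """Boolean matrix (windows x primer positions): aligned pair matches."""
    windows = np.lib.stride_tricks.sliding_window_view(
        template_bits, len(primer_bits)
    )
    if ambiguous == "optimistic":
        return (windows & primer_bits) != 0
    # pessimistic: template code must be wholly contained in the primer code,
    # so an N in a database record can never be counted as a match
    return (windows & ~primer_bits) == 0


def _profiles_for_strand(
    primer: Primer,
    template: NucleotideSequence,
    strand: Strand,
    ambiguous: Ambiguity,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-window mismatch counts and per-window boolean mismatch matrix.

    Rows of the matrix are indexed by plus-strand window start; columns are
    offsets from the primer 3' end.
    """
    if "-" in template.residues:
        raise ValueError("templates must be ungapped for binding-site search")
    k = len(primer)
    if len(template) < k:
        raise ValueError(
            f"template {template.id!r} ({len(template)} nt) "
            f"shorter than primer {primer.name!r} ({k} nt)"
        )
    tbits = _bits(template.residues)
    if strand is Strand.PLUS:
        pbits = _bits(primer.sequence)
        match = _window_match_matrix(pbits, tbits, ambiguous)
        # primer 3' end sits at the window's right edge: offset o from the
        # 3' terminus is window column k-1-o
        mismatch = ~match[:, ::-1]
    else:
        pbits = _bits(reverse_complement(primer.sequence))
        match = _window_match_matrix(pbits, tbits, ambiguous)
        # on the minus strand the primer 3' end maps to the window's LEFT
        # edge, so column o already is the 3' offset
        mismatch = ~match
    return mismatch.sum(axis=1), mismatch


def _make_profile(
    primer: Primer,
    template: NucleotideSequence,
    strand: Strand,
    start: int,
    mismatch_row: np.ndarray,
) -> MatchProfile:
    k = len(primer)
    return MatchProfile(
        primer_name=primer.name,
        template_id=template.id,
        strand=strand,
        start=int(start),
        end=int(start) + k,
        mismatch_positions=tuple(int(o) for o in np.flatnonzero(mismatch_row)),
        window_sequence=template.residues[start : start + k],
    )


def find_best_binding_site(
    primer: Primer,
    template: NucleotideSequence,
    strand: Strand | str = Strand.PLUS,
    *,
    ambiguous: Ambiguity = "optimistic",
) -> MatchProfile:
    """Best (minimum-mismatch) binding site of a primer on one strand.

    Ties are broken by the smallest plus-strand start.  Degenerate codes
    count as a match when their base sets intersect (``optimistic``); with
    ``pessimistic`` a degenerate template code matches only when every base
    it denotes is covered by the primer code.
    """
    strand = Strand(strand)
    counts, mismatch = _profiles_for_strand(primer, template, strand, ambiguous)
    best = int(np.argmin(counts))  # argmin takes the first minimum
    return _make_profile(primer, template, strand, best, mismatch[best])


def all_binding_sites(
    primer: Primer,
    template: NucleotideSequence,
    max_mismatches: int,
    *,
    ambiguous: Ambiguity = "optimistic",
) -> list[MatchProfile]:
    """Every window on either strand with at most ``max_mismatches``.

    Sorted by plus-strand start (plus before minus at equal start).
    Overlapping sites are all reported.
    """
    out: list[MatchProfile] = []
    for strand in (Strand.PLUS, Strand.MINUS):
        counts, mismatch = _profiles_for_strand(primer, template, strand, ambiguous)
        for start in np.flatnonzero(counts <= max_mismatches):
            out.append(_make_profile(primer, template, strand, start, mismatch[start]))
    out.sort(key=lambda p: (p.start, p.strand is Strand.MINUS))
    return out


def predicts_extension(profile: MatchProfile, rule: ExtensionRule | None = None) -> bool:
    """True iff the site supports extension under the 3'-clamp rule."""
    rule = rule or ExtensionRule()
    if profile.total_mismatches > rule.max_total_mismatches:
        return False
    return all(o >= rule.clamp_length for o in profile.mismatch_positions)


def mismatch_report(profiles: Sequence[MatchProfile]) -> pd.DataFrame:
    """Tabular mismatch report, one row per binding site.

    The machine-readable analogue of a primer/template alignment figure;
    write with ``df.to_csv(path, sep='\\t', index=False)``.
    """
    return pd.DataFrame(
        [
            {
                "primer": p.primer_name,
                "template": p.template_id,
                "strand": p.strand.value,
                "start": p.start,
                "end": p.end,
                "total_mismatches": p.total_mismatches,
                "three_prime_offsets": ";".join(map(str, p.mismatch_positions)),
            }
            for p in profiles
        ],
        columns=[
            "primer",
            "template",
            "strand",
            "start",
            "end",
            "total_mismatches",
            "three_prime_offsets",
        ],
    )
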