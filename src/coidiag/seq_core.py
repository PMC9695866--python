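"""Sequence and primer data model with IUPAC-degeneracy semantics.

DNA sequences (templates, alignment rows) and oligonucleotide primers are
represented over the 15-letter IUPAC nucleotide alphabet plus the gap
character ``-``.  Degenerate codes denote *sets* of bases (R = {A,G},
N = {A,C,G,T}, ...); two codes are *compatible* when their base sets
intersect, which is the matching semantics used throughout primer/template
comparison.  FASTA reading and writing delegates to Bio.SeqIO.
"""

from __future__ import annotations

import enum
import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "IUPAC_SETS",
    "NucleotideSequence",
    "Primer",
    "Alignment",
    "SequenceSource",
    "PrimerRole",
    "bases_compatible",
    "reverse_complement",
    "read_fasta",
    "write_fasta",
]

#: IUPAC nucleotide codes mapped to the set of unambiguous bases they denote.
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

GAP = "-"
ALPHABET = frozenset(IUPAC_SETS) | {GAP}

# 4-bit encoding (A=1, C=2, G=4, T=8); compatibility = non-zero AND.
_BIT = {"A": 1, "C": 2, "G": 4, "T": 8}
IUPAC_BITS: dict[str, int] = {
    code: sum(_BIT[b] for b in bases) for code, bases in IUPAC_SETS.items()
}

# complement as a set operation: complement each member base, look the set up
_COMPL_BASE = {"A": "T", "C": "G", "G": "C", "T": "A"}
_SET_TO_CODE = {bases: code for code, bases in IUPAC_SETS.items()}
IUPAC_COMPLEMENT: dict[str, str] = {
    code: _SET_TO_CODE[frozenset(_COMPL_BASE[b] for b in bases)]
    for code, bases in IUPAC_SETS.items()
}


class SequenceSource(str, enum.Enum):
    DATABASE = "database"
    STUDY = "study"
    SYNTHETIC = "synthetic"


class PrimerRole(str, enum.Enum):
    FORWARD = "forward"
    REVERSE = "reverse"


def _normalize_residues(raw: str, *, allow_gaps: bool, context: str = "sequence") -> str:
    """Uppercase, map U->T, and validate against the IUPAC alphabet."""
    s = raw.upper().replace("U", "T")
    allowed = ALPHABET if allow_gaps else frozenset(IUPAC_SETS)
    for i, ch in enumerate(s):
        if ch not in allowed:
            raise ValueError(
                f"illegal character {ch!r} at position {i} in {context}"
            )
    return s


@dataclass(frozen=True)
class NucleotideSequence:
    """An identified IUPAC DNA sequence (template or alignment row).

    Residues are stored uppercase with U normalized to T.  Gap characters
    are only legal for alignment rows (``allow_gaps=True``); templates are
    ungapped, matching the ungapped database records the pipeline consumes.
    """

    id: str
    residues: str
    description: str = ""
    source: SequenceSource = SequenceSource.DATABASE
    allow_gaps: bool = False

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} has no residues")
        object.__setattr__(
            self,
            "residues",
            _normalize_residues(
                self.residues, allow_gaps=self.allow_gaps, context=f"sequence {self.id!r}"
            ),
        )

    def __len__(self) -> int:
        return len(self.residues)

    def ungapped(self) -> str:
        return self.residues.replace(GAP, "")


@dataclass(frozen=True)
class Primer:
    """A named, oriented, possibly degenerate oligo (5'->3').

    ``degeneracy`` is the product of per-position base-set sizes, i.e. the
    number of distinct unambiguous oligos the degenerate sequence encodes.
    """

    name: str
    sequence: str
    role: PrimerRole
    expected_product_partner: str | None = None

    def __post_init__(self) -> None:
        seq = _normalize_residues(
            self.sequence, allow_gaps=False, context=f"primer {self.name!r}"
        )
        if len(seq) < 10:
            raise ValueError(f"primer {self.name!r} shorter than 10 nt")
        object.__setattr__(self, "sequence", seq)
        object.__setattr__(self, "role", PrimerRole(self.role))

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def degeneracy(self) -> int:
        return math.prod(len(IUPAC_SETS[c]) for c in self.sequence)

    def expansions(self) -> Iterable[str]:
        """All unambiguous oligos encoded by the degenerate sequence."""
        pools = [sorted(IUPAC_SETS[c]) for c in self.sequence]
        return ("".join(p) for p in itertools.product(*pools))


@dataclass
class Alignment:
    """A multiple alignment: >=2 equal-length rows (gaps allowed)."""

    rows: list[NucleotideSequence] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.rows) < 2:
            raise ValueError("alignment needs at least 2 rows")
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise ValueError(f"alignment rows differ in length: {sorted(lengths)}")
        ids = [r.id for r in self.rows]
        if len(set(ids)) != len(ids):
            raise ValueError("alignment row ids must be unique")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.rows]

    def row(self, seq_id: str) -> NucleotideSequence:
        for r in self.rows:
            if r.id == seq_id:
                return r
        raise KeyError(seq_id)


def bases_compatible(a: str, b: str) -> bool:
    """True iff the base sets of two IUPAC codes intersect.

    Gap characters are rejected: compatibility is defined for residues only.
    """
    try:
        return bool(IUPAC_BITS[a.upper()] & IUPAC_BITS[b.upper()])
    except KeyError:
        raise ValueError(f"not an IUPAC nucleotide code: {a!r} / {b!r}") from None


def reverse_complement(s: str) -> str:
    """Reverse complement of a gap-free IUPAC string (sets complemented)."""
    out = []
    for i, ch in enumerate(s.upper().replace("U", "T")):
        try:
            out.append(IUPAC_COMPLEMENT[ch])
        except KeyError:
            raise ValueError(
                f"cannot reverse-complement character {ch!r} at position {i}"
            ) from None
    return "".join(reversed(out))


def read_fasta(
    path: str | Path,
    *,
    allow_gaps: bool = False,
    source: SequenceSource = SequenceSource.DATABASE,
) -> list[NucleotideSequence]:
    """Read FASTA records as NucleotideSequence objects.

    The first whitespace-delimited header token is the id (accessions in
    longer headers land in ``description``).  Ids are made unique by
    suffixing ``.2``, ``.3``, ... on collision.  Empty files are an error.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    seen: dict[str, int] = {}
    out: list[NucleotideSequence] = []
    for rec in records:
        rid = rec.id
        n = seen.get(rid, 0) + 1
        seen[rid] = n
        if n > 1:
            rid = f"{rid}.{n}"
        out.append(
            NucleotideSequence(
                id=rid,
                residues=str(rec.seq),
                description=rec.description,
                source=source,
                allow_gaps=allow_gaps,
            )
        )
    return out


def write_fasta(
    sequences: Sequence[NucleotideSequence], path: str | Path, *, wrap: int = 70
) -> None:
    """Write sequences as FASTA, wrapped at ``wrap`` columns (cosmetic)."""
    records = [
        SeqRecord(Seq(s.residues), id=s.id, description=s.description)
        for s in sequences
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=wrap)
        writer.write_file(records)
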