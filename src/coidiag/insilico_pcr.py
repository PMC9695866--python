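"""Predict PCR amplicons from primer binding sites and build specificity panels.

A forward site (plus strand) and a reverse site (minus strand) in productive
orientation define a candidate amplicon; it is *predicted* when both sites
pass the 3'-clamp extension rule.  Crossing primer pairs with a panel of
templates yields a specificity matrix — the in-silico counterpart of running
the PCR assay over a collection of specimens and scoring bands on a gel.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .primer_match import (
    ExtensionRule,
    MatchProfile,
    Strand,
    all_binding_sites,
    predicts_extension,
)
from .seq_core import NucleotideSequence, Primer, SequenceSource, write_fasta

__all__ = [
    "AmpliconPrediction",
    "SpecificityMatrix",
    "simulate_pcr",
    "specificity_matrix",
    "amplicon_records",
]

DEFAULT_MAX_PRODUCT = 3000


@dataclass(frozen=True)
class AmpliconPrediction:
    """A productive forward/reverse site pair and its amplification verdict.

    ``product_length`` is outer edge to outer edge, inclusive of both primer
    footprints (reverse interval end minus forward interval start).
    """

    forward: MatchProfile
    reverse: MatchProfile
    predicted: bool

    def __post_init__(self) -> None:
        if self.forward.strand is not Strand.PLUS or self.reverse.strand is not Strand.MINUS:
            raise ValueError("forward site must be plus-strand, reverse minus-strand")
        if self.forward.end > self.reverse.start:
            raise ValueError("forward footprint must lie upstream of the reverse footprint")

    @property
    def product_length(self) -> int:
        return self.reverse.end - self.forward.start

    @property
    def template_id(self) -> str:
        return self.forward.template_id

    def sequence(self, template: NucleotideSequence) -> str:
        if template.id != self.template_id:
            raise ValueError("template does not match the prediction")
        return template.residues[self.forward.start : self.reverse.end]


def simulate_pcr(
    fw: Primer,
    rv: Primer,
    template: NucleotideSequence,
    rule: ExtensionRule | None = None,
    max_product: int = DEFAULT_MAX_PRODUCT,
    *,
    site_max_mismatches: int | None = None,
) -> list[AmpliconPrediction]:
    """All candidate amplicons of a primer pair on one template.

    Binding sites are enumerated up to ``site_max_mismatches`` (defaults to
    the rule's total-mismatch cap); every productive forward x reverse
    combination with product length <= ``max_product`` is returned, sorted by
    product length, each flagged ``predicted`` iff both sites pass the
    extension rule.  Nested or inverted site configurations are not
    productive and are dropped.
    """
    rule = rule or ExtensionRule()
    if max_product < len(fw) + len(rv):
        raise ValueError("max_product smaller than the combined primer footprints")
    cap = rule.max_total_mismatches if site_max_mismatches is None else site_max_mismatches
    fw_sites = [
        p
        for p in all_binding_sites(fw, template, cap)
        if p.strand is Strand.PLUS
    ]
    rv_sites = [
        p
        for p in all_binding_sites(rv, template, cap)
        if p.strand is Strand.MINUS
    ]
    preds = [
        AmpliconPrediction(
            forward=f,
            reverse=r,
            predicted=predicts_extension(f, rule) and predicts_extension(r, rule),
        )
        for f in fw_sites
        for r in rv_sites
        if f.end <= r.start and r.end - f.start <= max_product
    ]
    preds.sort(key=lambda a: a.product_length)
    return preds


@dataclass
class SpecificityMatrix:
    """Templates x primer pairs amplification panel.

    ``amplified`` is a boolean DataFrame (row index: template ids, columns:
    pair names); ``product_lengths`` holds, per cell, the lengths of all
    predicted amplicons (empty tuple when not amplified).
    """

    amplified: pd.DataFrame
    product_lengths: pd.DataFrame
    predictions: dict[tuple[str, str], list[AmpliconPrediction]]

    def to_dataframe(self) -> pd.DataFrame:
        """Human-readable panel: 'amplified(341)' / 'not_amplified' cells."""

        def cell(tid: str, pair: str) -> str:
            if self.amplified.loc[tid, pair]:
                sizes = ";".join(map(str, self.product_lengths.loc[tid, pair]))
                return f"amplified({sizes})"
            return "not_amplified"

        return pd.DataFrame(
            {
                pair: [cell(tid, pair) for tid in self.amplified.index]
                for pair in self.amplified.columns
            },
            index=self.amplified.index,
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index_label="template")


def specificity_matrix(
    pairs: Sequence[tuple[Primer, Primer]],
    templates: Sequence[NucleotideSequence],
    rule: ExtensionRule | None = None,
    max_product: int = DEFAULT_MAX_PRODUCT,
) -> SpecificityMatrix:
    """Cross every primer pair with every template.

    A cell is *amplified* iff at least one predicted amplicon exists for the
    pair on that template (multiple bands are recorded but do not change the
    verdict).  Deterministic; duplicate template ids are rejected.
    """
    if not pairs or not templates:
        raise ValueError("need at least one primer pair and one template")
    ids = [t.id for t in templates]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate template ids in specificity panel")
    rule = rule or ExtensionRule()
    pair_names = [f"{fw.name}/{rv.name}" for fw, rv in pairs]
    amp = pd.DataFrame(False, index=ids, columns=pair_names)
    lengths = pd.DataFrame([[() for _ in pair_names] for _ in ids], index=ids, columns=pair_names)
    predictions: dict[tuple[str, str], list[AmpliconPrediction]] = {}
    for (fw, rv), pname in zip(pairs, pair_names):
        for t in templates:
            preds = simulate_pcr(fw, rv, t, rule, max_product)
            hits = [p for p in preds if p.predicted]
            predictions[(t.id, pname)] = preds
            amp.loc[t.id, pname] = bool(hits)
            lengths.loc[t.id, pname] = tuple(p.product_length for p in hits)
    return SpecificityMatrix(amplified=amp, product_lengths=lengths, predictions=predictions)


def amplicon_records(
    matrix: SpecificityMatrix, templates: Sequence[NucleotideSequence]
) -> list[NucleotideSequence]:
    """Predicted amplicon sequences as records (id = template|pair|length)."""
    by_id = {t.id: t for t in templates}
    out = []
    for (tid, pair), preds in sorted(matrix.predictions.items()):
        for p in preds:
            if p.predicted:
                out.append(
                    NucleotideSequence(
                        id=f"{tid}|{pair.replace('/', '+')}|{p.product_length}",
                        residues=p.sequence(by_id[tid]),
                        source=SequenceSource.SYNTHETIC,
                    )
                )
    return out


def write_amplicons(
    matrix: SpecificityMatrix,
    templates: Sequence[NucleotideSequence],
    path: str | Path,
) -> None:
    records = amplicon_records(matrix, templates)
    if records:
        write_fasta(records, path)
    else:
        Path(path).write_text("")
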