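"""Deterministic *synthetic* stand-ins for the COI reference sequences.

The real assay was designed against public COI database records of
Pentastiridius leporinus and its cixiid look-alikes.  Those records cannot
be bundled here, so this module constructs, from a fixed seed, a synthetic
COI-like reference panel that embodies the published primer/template
alignment facts exactly:

* the P. leporinus template matches fw1/rv1 perfectly and yields a single
  341 bp product; Ron/Calvin and UEA3 bind with at most one internal
  mismatch; UEA8 has three mismatches, one of them on the next-to-last
  (3'-offset 1) base — the site that blocks universal UEA3/UEA8
  amplification from P. leporinus;
* each Reptalus / Hyalesthes template carries 1-4 mismatches to fw1 and
  3-9 to rv1, always including at least one mismatch within the 3' clamp
  of both primers, so the specific pair never amplifies them;
* Ron/Calvin and UEA3/UEA8 amplify R. quinquecostatus and H. obsoletus.

Every sequence is synthetic (ids say so); background residues are random
with insect-mitochondrial AT-rich composition.  The barcoding alignment
mirrors the published distance structure of the specific 341 bp amplicon:
conspecific records at 0.0 and 0.6 substitutions per 100 sites, the
closest congener at ~5.1, the other genera and two outgroup families much
further.
"""

from __future__ import annotations

import numpy as np

from .primers import CALVIN, FW1, RON, RV1, UEA3, UEA8
from .seq_core import Alignment, NucleotideSequence, SequenceSource
from .synthetic_data import realize_forward_site, realize_reverse_site

__all__ = [
    "REFERENCE_SEED",
    "synthetic_reference_panel",
    "synthetic_barcoding_alignment",
    "AMPLICON_START",
    "AMPLICON_END",
]

REFERENCE_SEED = 992
TEMPLATE_LENGTH = 1063
#: AT-rich composition typical of insect mitochondrial COI (A, C, G, T)
BASE_FREQS = (0.30, 0.17, 0.15, 0.38)

# plus-strand footprints on the synthetic COI-like template
RON_START = 10          # Ron fw, 23 nt -> [10, 33)
UEA3_START = 21         # UEA3 fw, 24 nt -> [21, 45); overlaps Ron's 3' half
FW1_START = 350         # fw1, 20 nt -> [350, 370)
AMPLICON_START = FW1_START
AMPLICON_END = FW1_START + 341          # rv1 footprint [660, 691)
RV1_START = AMPLICON_END - len(RV1)
UEA8_START = 955        # UEA8 rv, 24 nt -> [955, 979)
CALVIN_START = 987      # Calvin rv, 23 nt -> [987, 1010); Ron->Calvin = 1000 bp

#: per-species planted 3'-offset mismatch sets against each primer
#: (fw1 totals span 1-4, rv1 totals span 3-9; both primers always carry at
#: least one mismatch within the terminal two bases)
_SPECIES_SITES: dict[str, dict[str, tuple[int, ...]]] = {
    "P_leporinus_synthetic": {
        "fw1": (), "rv1": (), "Ron": (12,), "UEA3": (7,),
        "UEA8": (1, 8, 15), "Calvin": (9,),
    },
    "R_quinquecostatus_synthetic": {
        "fw1": (0, 6), "rv1": (1, 5, 12, 20), "Ron": (), "UEA3": (5,),
        "UEA8": (7,), "Calvin": (9,),
    },
    "R_melanochaetus_synthetic": {
        "fw1": (1,), "rv1": (0, 3, 9), "Ron": (13,), "UEA3": (4,),
        "UEA8": (6, 11), "Calvin": (),
    },
    "R_panzeri_synthetic": {
        "fw1": (0, 4, 11, 15), "rv1": (1, 4, 8, 13, 22), "Ron": (), "UEA3": (),
        "UEA8": (5,), "Calvin": (8,),
    },
    "H_obsoletus_synthetic": {
        "fw1": (1, 9), "rv1": (0, 2, 7, 14, 19, 25), "Ron": (13,), "UEA3": (),
        "UEA8": (3, 9), "Calvin": (),
    },
    "H_luteipes_synthetic": {
        "fw1": (0,), "rv1": (1, 3, 6, 10, 16, 21, 24), "Ron": (), "UEA3": (6,),
        "UEA8": (4, 12), "Calvin": (7,),
    },
    "H_scotti_synthetic": {
        "fw1": (1, 5, 12), "rv1": (0, 1, 4, 9, 13, 18, 23, 27, 29),
        "Ron": (12,), "UEA3": (3,), "UEA8": (2, 10), "Calvin": (9,),
    },
}

_FOOTPRINTS = [
    (RON_START, RON_START + len(RON)),
    (UEA3_START, UEA3_START + len(UEA3)),
    (FW1_START, FW1_START + len(FW1)),
    (RV1_START, RV1_START + len(RV1)),
    (UEA8_START, UEA8_START + len(UEA8)),
    (CALVIN_START, CALVIN_START + len(CALVIN)),
]


def _in_footprint(pos: int) -> bool:
    return any(a <= pos < b for a, b in _FOOTPRINTS)


def _write_sites(residues: list[str], sites: dict[str, tuple[int, ...]],
                 rng: np.random.Generator) -> None:
    """Realize all six primer sites.  Ron before UEA3: their footprints
    overlap and the two primers are sequence-identical in the overlap, so
    planted offsets are restricted to the non-overlapping halves."""
    for primer, start, realize in (
        (RON, RON_START, realize_forward_site),
        (UEA3, UEA3_START, realize_forward_site),
        (FW1, FW1_START, realize_forward_site),
        (RV1, RV1_START, realize_reverse_site),
        (UEA8, UEA8_START, realize_reverse_site),
        (CALVIN, CALVIN_START, realize_reverse_site),
    ):
        window = realize(primer, sites[primer.name], rng)
        residues[start : start + len(primer)] = window


def _mutate_background(residues: list[str], n_subs: int, rng: np.random.Generator) -> None:
    """Random substitutions outside every primer footprint."""
    free = [i for i in range(len(residues)) if not _in_footprint(i)]
    for pos in rng.choice(free, size=n_subs, replace=False):
        choices = [b for b in "ACGT" if b != residues[pos]]
        residues[pos] = str(rng.choice(choices))


def synthetic_reference_panel(
    seed: int = REFERENCE_SEED, n_target_specimens: int = 3
) -> tuple[list[NucleotideSequence], list[NucleotideSequence]]:
    """(targets, non-targets): the synthetic COI reference panel.

    Targets are P. leporinus-like specimens (identical primer sites, a few
    background substitutions apart); non-targets are the six Reptalus /
    Hyalesthes-like templates with their planted mismatch profiles.
    """
    rng = np.random.default_rng(seed)
    backbone = list(
        rng.choice(list("ACGT"), size=TEMPLATE_LENGTH, p=list(BASE_FREQS))
    )

    def build(species: str, background_subs: int, sub_rng: np.random.Generator) -> NucleotideSequence:
        residues = backbone.copy()
        if background_subs:
            _mutate_background(residues, background_subs, sub_rng)
        _write_sites(residues, _SPECIES_SITES[species], sub_rng)
        return NucleotideSequence(
            id=species, residues="".join(residues),
            description=f"{species.replace('_', ' ')} COI-like synthetic stand-in",
            source=SequenceSource.SYNTHETIC,
        )

    targets = []
    for i in range(1, n_target_specimens + 1):
        spec_rng = np.random.default_rng(seed + i)
        rec = build("P_leporinus_synthetic", 0 if i == 1 else 6, spec_rng)
        targets.append(
            NucleotideSequence(
                id=f"P_leporinus_synthetic_{i}" if i > 1 else "P_leporinus_synthetic",
                residues=rec.residues, description=rec.description,
                source=SequenceSource.SYNTHETIC,
            )
        )
    nontargets = []
    for idx, species in enumerate(_SPECIES_SITES):
        if species.startswith("P_leporinus"):
            continue
        spec_rng = np.random.default_rng(seed + 100 + idx)
        nontargets.append(build(species, 53, spec_rng))  # ~5% background
    return targets, nontargets


def _apply_subs(
    seq: list[str], n: int, rng: np.random.Generator,
    positions: list[int] | None = None,
) -> list[str]:
    out = seq.copy()
    pool = positions if positions is not None else list(range(len(seq)))
    for pos in rng.choice(pool, size=n, replace=False):
        choices = [b for b in "ACGT" if b != out[pos]]
        out[pos] = str(rng.choice(choices))
    return out


def synthetic_barcoding_alignment(
    seed: int = REFERENCE_SEED,
) -> tuple[Alignment, dict[str, str], list[str]]:
    """341-column barcoding alignment mirroring the published distances.

    Returns (alignment, species-groups mapping, outgroup ids).  Rows are the
    study amplicon plus synthetic stand-ins: a conspecific identical record
    (planted distance 0.0 per 100 sites), a conspecific record two
    substitutions away (~0.6), the closest congener (~5.1; 17 substitutions,
    the closest value realizable on 341 discrete sites), three Reptalus-like
    and three Hyalesthes-like records, and two distant outgroups.
    """
    targets, _ = synthetic_reference_panel(seed)
    study = list(targets[0].residues[AMPLICON_START:AMPLICON_END])
    rng = np.random.default_rng(seed + 7717)

    # conspecific variation sits between the primer footprints, as in the
    # published alignment (no mismatch to either specific primer)
    interior = list(range(len(FW1), 341 - len(RV1)))

    # nested backbone: the conspecific trio, then P. beieri, then the other
    # cixiid genera, then the outgroup families branch at increasing depth;
    # the beieri branch uses positions disjoint from the shared 5-substitution
    # stem so the planted 17-difference congener distance is exact
    stem_pos = [int(p) for p in rng.choice(341, size=5, replace=False)]
    p1 = _apply_subs(study, 5, rng, stem_pos)
    beieri = _apply_subs(p1, 12, rng, [i for i in range(341) if i not in stem_pos])
    p2 = _apply_subs(p1, 20, rng)       # cixiid-genera ancestor
    p3 = _apply_subs(p2, 20, rng)       # outgroup-side ancestor
    reptalus_anc = _apply_subs(p2, 15, rng)
    hyalesthes_anc = _apply_subs(p2, 18, rng)

    rows: list[tuple[str, list[str]]] = [
        ("Plep_study_DE", study),
        ("Plep_Russia_synthetic", study.copy()),
        ("Plep_France_synthetic", _apply_subs(study, 2, rng, interior)),
        ("P_beieri_synthetic", beieri),
    ]
    for name in ("R_quinquecostatus", "R_melanochaetus", "R_panzeri"):
        rows.append((f"{name}_synthetic", _apply_subs(reptalus_anc, 8, rng)))
    for name in ("H_obsoletus", "H_luteipes", "H_scotti"):
        rows.append((f"{name}_synthetic", _apply_subs(hyalesthes_anc, 8, rng)))
    outgroups = ["Catonia_carolina_synthetic", "Tettigometra_virescens_synthetic"]
    for name in outgroups:
        rows.append((name, _apply_subs(p3, 25, rng)))

    alignment = Alignment(
        rows=[
            NucleotideSequence(
                id=name, residues="".join(res), source=SequenceSource.SYNTHETIC,
                allow_gaps=True,
            )
            for name, res in rows
        ]
    )
    groups = {
        "Plep_study_DE": "P_leporinus",
        "Plep_Russia_synthetic": "P_leporinus",
        "Plep_France_synthetic": "P_leporinus",
        "P_beieri_synthetic": "P_beieri",
        "R_quinquecostatus_synthetic": "R_quinquecostatus",
        "R_melanochaetus_synthetic": "R_melanochaetus",
        "R_panzeri_synthetic": "R_panzeri",
        "H_obsoletus_synthetic": "H_obsoletus",
        "H_luteipes_synthetic": "H_luteipes",
        "H_scotti_synthetic": "H_scotti",
        "Catonia_carolina_synthetic": "Catonia_carolina",
        "Tettigometra_virescens_synthetic": "Tettigometra_virescens",
    }
    return alignment, groups, outgroups
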