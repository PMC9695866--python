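"""Seeded generators for COI-like sequence families and primer-site templates.

Two fixtures back the whole pipeline without any downloads:

* :func:`simulate_family` evolves a random root sequence along a symmetric
  ultrametric species tree (Jukes-Cantor by default, Kimura two-parameter
  optionally), producing several species with small within-species and
  larger between-species divergence — the statistical structure of a COI
  barcoding panel (defaults: 0.6% within, 5.1% between, mirroring the
  distances the specific amplicon resolves).
* :func:`implant_primer_sites` writes a forward and a reverse primer binding
  site with exactly controlled mismatch counts and 3'-offsets into a
  template, so binding-site search and amplicon prediction can be tested
  against known truth.

Everything is deterministic given the seed.  No indels are simulated: all
in-scope primer and distance comparisons are ungapped.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np

from .seq_core import (
    IUPAC_SETS,
    NucleotideSequence,
    Primer,
    SequenceSource,
    reverse_complement,
    write_fasta,
)
from . import primer_match
from .primer_match import Strand

__all__ = [
    "FamilyParams",
    "PlantedPrimerTemplate",
    "simulate_family",
    "implant_primer_sites",
    "expected_p_distance",
    "random_sequence",
    "write_truth_bundle",
]

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}


@dataclass(frozen=True)
class FamilyParams:
    """Shape and divergence structure of a simulated COI family.

    ``intraspecific``/``interspecific`` are expected substitutions per site
    between two individuals of the same / of different species.  Defaults
    mirror the per-100-site distances a specific COI amplicon resolves in
    cixiid planthoppers (0.6 within species, 5.1 between close species).
    """

    n_species: int = 3
    n_per_species: int = 4
    length: int = 341
    intraspecific: float = 0.006
    interspecific: float = 0.051
    model: str = "JC"  # or "K2P"
    kappa: float = 2.0
    base_freqs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    tree_shape: str = "symmetric"  # or "caterpillar"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.intraspecific < self.interspecific < 0.75):
            raise ValueError("need 0 <= intraspecific < interspecific < 0.75")
        if self.length < 100:
            raise ValueError("length must be >= 100")
        if self.model not in ("JC", "K2P"):
            raise ValueError("model must be JC or K2P")
        if self.tree_shape not in ("symmetric", "caterpillar"):
            raise ValueError("tree_shape must be symmetric or caterpillar")
        if abs(sum(self.base_freqs) - 1.0) > 1e-9:
            raise ValueError("base_freqs must sum to 1")


def expected_p_distance(d: float) -> float:
    """Expected raw difference proportion at JC distance ``d``."""
    return 0.75 * (1.0 - np.exp(-4.0 * d / 3.0))


def _substitution_probs(d: float, model: str, kappa: float) -> np.ndarray:
    """4x4 substitution probability matrix after ``d`` expected subs/site."""
    if d < 0:
        raise ValueError("negative branch length")
    k = 1.0 if model == "JC" else kappa
    # K2P closed form; JC is kappa = 1
    bt = d / (k + 2.0)
    at = k * bt
    e4 = np.exp(-4.0 * bt)
    e2 = np.exp(-2.0 * (at + bt))
    p_ts = 0.25 + 0.25 * e4 - 0.5 * e2
    p_tv = 0.25 - 0.25 * e4  # each of the two transversion targets
    p_same = 1.0 - p_ts - 2.0 * p_tv
    # base order A C G T; transition partners: A<->G, C<->T
    P = np.full((4, 4), p_tv)
    for i, j in ((0, 2), (2, 0), (1, 3), (3, 1)):
        P[i, j] = p_ts
    np.fill_diagonal(P, p_same)
    return P


def random_sequence(length: int, rng: np.random.Generator,
                    base_freqs: Sequence[float] = (0.25, 0.25, 0.25, 0.25)) -> str:
    return "".join(rng.choice(list(_BASES), size=length, p=list(base_freqs)))


def _evolve(parent: np.ndarray, d: float, model: str, kappa: float,
            rng: np.random.Generator) -> np.ndarray:
    if d == 0:
        return parent.copy()
    P = _substitution_probs(d, model, kappa)
    cum = P.cumsum(axis=1)
    u = rng.random(parent.shape[0])
    return (u[:, None] > cum[parent]).sum(axis=1).astype(np.int8)


def _species_join_heights(params: FamilyParams) -> list[float]:
    """Heights (above the species-ancestor level) of successive joins."""
    depth = (params.interspecific - params.intraspecific) / 2.0
    s = params.n_species
    if params.tree_shape == "symmetric" or s == 2:
        return [depth] * (s - 1)
    # ultrametric caterpillar: evenly spaced join heights, deepest = depth
    return [depth * (k + 1) / (s - 1) for k in range(s - 1)]


def simulate_family(params: FamilyParams) -> tuple[list[NucleotideSequence], dendropy.Tree]:
    """Simulate a multi-species COI family; returns (records, true tree).

    Individuals are named ``sp{i}_{j}``.  Under the symmetric shape every
    between-species pair has expected divergence ``interspecific`` and every
    within-species pair ``intraspecific`` (species radiate from a single
    polytomy); the caterpillar shape staggers the species joins for
    tree-reconstruction stress tests.
    """
    rng = np.random.default_rng(params.seed)
    root = np.array(
        rng.choice(4, size=params.length, p=list(params.base_freqs)), dtype=np.int8
    )
    half_intra = params.intraspecific / 2.0
    s = params.n_species
    heights = _species_join_heights(params)  # ascending; heights[-1] = depth
    model, kappa = params.model, params.kappa

    anc: list[np.ndarray | None] = [None] * s
    if params.tree_shape == "symmetric" or s == 2:
        depth = heights[-1]
        for k in range(s):
            anc[k] = _evolve(root, depth, model, kappa, rng)
    else:
        # caterpillar: join node j (1..s-1) at height heights[j-1]; species
        # j+1 attaches at node j, species 1 and 2 both at node 1
        chain = root  # at the root join node (j = s-1)
        for j in range(s - 1, 0, -1):
            if j < s - 1:
                chain = _evolve(chain, heights[j] - heights[j - 1], model, kappa, rng)
            anc[j] = _evolve(chain, heights[j - 1], model, kappa, rng)
        anc[0] = _evolve(chain, heights[0], model, kappa, rng)

    records: list[NucleotideSequence] = []
    leaf_clades = []
    for sp, a in enumerate(anc, start=1):
        names = []
        for ind in range(1, params.n_per_species + 1):
            seq = _evolve(a, half_intra, model, kappa, rng)
            name = f"sp{sp}_{ind}"
            names.append(name)
            records.append(
                NucleotideSequence(
                    id=name,
                    residues="".join(_BASES[b] for b in seq),
                    source=SequenceSource.SYNTHETIC,
                )
            )
        leaf_clades.append("(" + ",".join(f"{n}:{half_intra}" for n in names) + ")")

    if params.tree_shape == "symmetric" or s == 2:
        newick = "(" + ",".join(f"{c}:{heights[-1]}" for c in leaf_clades) + ");"
    else:
        cur = f"({leaf_clades[0]}:{heights[0]},{leaf_clades[1]}:{heights[0]})"
        for j in range(2, s):
            step = heights[j - 1] - heights[j - 2]
            cur = f"({cur}:{step},{leaf_clades[j]}:{heights[j - 1]})"
        newick = cur + ";"
    tree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    return records, tree


@dataclass(frozen=True)
class PlantedPrimerTemplate:
    """A template carrying one forward and one reverse primer site with
    exactly known mismatch offsets (verified against the matching module)."""

    template: NucleotideSequence
    fw_start: int
    fw_end: int
    fw_mismatch_offsets: tuple[int, ...]
    rv_start: int
    rv_end: int
    rv_mismatch_offsets: tuple[int, ...]
    product_length: int


def _realize_site(
    primer_seq: str, mismatch_cols: set[int], rng: np.random.Generator
) -> str:
    """A concrete window: compatible base per position, incompatible at
    planted columns.  ``mismatch_cols`` are window-column indices."""
    out = []
    for col, code in enumerate(primer_seq):
        bases = sorted(IUPAC_SETS[code])
        if col in mismatch_cols:
            complement_pool = sorted(set(_BASES) - set(bases))
            if not complement_pool:
                raise ValueError(
                    f"cannot plant a mismatch against all-base code {code!r}"
                )
            out.append(str(rng.choice(complement_pool)))
        else:
            out.append(str(rng.choice(bases)))
    return "".join(out)


def realize_forward_site(primer: Primer, offsets: Sequence[int], rng: np.random.Generator) -> str:
    """Plus-strand window hosting a forward primer with given 3'-offsets."""
    k = len(primer)
    cols = {k - 1 - o for o in offsets}
    return _realize_site(primer.sequence, cols, rng)


def realize_reverse_site(primer: Primer, offsets: Sequence[int], rng: np.random.Generator) -> str:
    """Plus-strand window hosting a reverse (minus-strand) primer site.

    Window column ``o`` pairs with the primer base at 3'-offset ``o``.
    """
    return _realize_site(reverse_complement(primer.sequence), set(offsets), rng)


def implant_primer_sites(
    base: NucleotideSequence,
    fw: Primer,
    rv: Primer,
    product_length: int,
    fw_mismatch_offsets: Sequence[int] = (),
    rv_mismatch_offsets: Sequence[int] = (),
    seed: int = 0,
    fw_start: int | None = None,
) -> PlantedPrimerTemplate:
    """Write a forward and a reverse primer site into ``base``.

    The sites delimit a product of exactly ``product_length`` bp (outer edge
    to outer edge).  Planted mismatch offsets (counted from each primer's 3'
    terminus) are realized with bases incompatible with the primer code at
    that position and verified post-construction via best-site search; a
    handful of re-randomizations guard against coincidental better sites in
    the background sequence.
    """
    if product_length < len(fw) + len(rv):
        raise ValueError("product_length smaller than combined primer footprints")
    if product_length > len(base):
        raise ValueError("product_length exceeds template length")
    if any(o < 0 or o >= len(fw) for o in fw_mismatch_offsets):
        raise ValueError("forward mismatch offset outside primer")
    if any(o < 0 or o >= len(rv) for o in rv_mismatch_offsets):
        raise ValueError("reverse mismatch offset outside primer")
    rng = np.random.default_rng(seed)
    if fw_start is None:
        fw_start = int(rng.integers(0, len(base) - product_length + 1))
    elif fw_start + product_length > len(base):
        raise ValueError("fw_start leaves no room for the product")
    rv_end = fw_start + product_length
    rv_start = rv_end - len(rv)
    if fw_start + len(fw) > rv_start:
        raise ValueError("primer footprints overlap at this product length")

    for _ in range(30):
        residues = list(base.residues)
        fw_site = realize_forward_site(fw, fw_mismatch_offsets, rng)
        rv_site = realize_reverse_site(rv, rv_mismatch_offsets, rng)
        residues[fw_start : fw_start + len(fw)] = fw_site
        residues[rv_start:rv_end] = rv_site
        template = NucleotideSequence(
            id=base.id, residues="".join(residues),
            description=base.description, source=SequenceSource.SYNTHETIC,
        )
        best_fw = primer_match.find_best_binding_site(fw, template, Strand.PLUS)
        best_rv = primer_match.find_best_binding_site(rv, template, Strand.MINUS)
        if (
            best_fw.start == fw_start
            and best_fw.mismatch_positions == tuple(sorted(fw_mismatch_offsets))
            and best_rv.start == rv_start
            and best_rv.mismatch_positions == tuple(sorted(rv_mismatch_offsets))
        ):
            return PlantedPrimerTemplate(
                template=template,
                fw_start=fw_start,
                fw_end=fw_start + len(fw),
                fw_mismatch_offsets=tuple(sorted(fw_mismatch_offsets)),
                rv_start=rv_start,
                rv_end=rv_end,
                rv_mismatch_offsets=tuple(sorted(rv_mismatch_offsets)),
                product_length=product_length,
            )
    raise RuntimeError(
        "could not realize the planted sites as the best binding sites; "
        "the background sequence keeps producing a better window"
    )


def write_truth_bundle(
    records: Sequence[NucleotideSequence],
    path_prefix: str | Path,
    tree: dendropy.Tree | None = None,
    planted: Sequence[PlantedPrimerTemplate] = (),
    params: FamilyParams | None = None,
) -> tuple[Path, Path]:
    """Write FASTA plus a JSON sidecar holding the generating truth."""
    prefix = Path(path_prefix)
    fasta = prefix.with_suffix(".fasta")
    sidecar = prefix.with_suffix(".json")
    write_fasta(records, fasta)
    truth: dict = {"ids": [r.id for r in records]}
    if params is not None:
        truth["params"] = asdict(params)
    if tree is not None:
        truth["tree_newick"] = tree.as_string(schema="newick").strip()
    if planted:
        truth["planted_sites"] = [
            {
                "template": p.template.id,
                "fw_interval": [p.fw_start, p.fw_end],
                "fw_mismatch_offsets": list(p.fw_mismatch_offsets),
                "rv_interval": [p.rv_start, p.rv_end],
                "rv_mismatch_offsets": list(p.rv_mismatch_offsets),
                "product_length": p.product_length,
            }
            for p in planted
        ]
    sidecar.write_text(json.dumps(truth, indent=2))
    return fasta, sidecar
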