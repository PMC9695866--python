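"""End-to-end runs: primer specificity report and barcoding phylogeny.

Both analyses are driven by a :class:`RunConfig` (a flat, human-editable
YAML file or a dataclass built in code), write their outputs into one
directory, and record a manifest (config, seed, SHA-256 of every input,
package version) sufficient to reproduce the run byte-for-byte.  Log
messages go to stderr; numeric outputs only to files.

Exit conventions (used by the CLI): 0 = clean, 2 = specificity violated,
i.e. some non-target template is predicted to amplify with a pair listed in
``specific_pairs``.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .insilico_pcr import specificity_matrix, write_amplicons
from .phylo import (
    barcoding_gap,
    bootstrap_supports,
    distance_matrix,
    root_with_outgroup,
    write_newick,
)
from .primer_design import (
    DesignConstraints,
    candidates_to_dataframe,
    enumerate_discriminative_primers,
)
from .primer_match import ExtensionRule, Strand, find_best_binding_site, mismatch_report
from .primers import primer_by_name
from .seq_core import Alignment, PrimerRole, read_fasta
from .synthetic_data import FamilyParams, simulate_family, write_truth_bundle

logger = logging.getLogger("coidiag")

__all__ = [
    "RunConfig",
    "run_specificity",
    "run_phylogeny",
    "run_design",
    "run_simulate",
]


@dataclass
class RunConfig:
    """Flat run configuration; unknown file paths fail before any computation."""

    targets: str | None = None
    nontargets: str | None = None
    alignment: str | None = None
    outdir: str = "coidiag_out"
    # primer panel (bundled names); the specific pair drives the exit status
    primer_pairs: list[str] = field(
        default_factory=lambda: ["fw1/rv1", "Ron/Calvin", "UEA3/UEA8"]
    )
    specific_pairs: list[str] = field(default_factory=lambda: ["fw1/rv1"])
    # extension rule
    max_total_mismatches: int = 4
    clamp_length: int = 2
    max_product: int = 3000
    # phylogeny
    distance_method: str = "mcl"
    replicates: int = 1000
    seed: int = 1
    outgroups: list[str] = field(default_factory=list)
    scale_x100: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in cls.__dataclass_fields__.values()}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def rule(self) -> ExtensionRule:
        return ExtensionRule(
            max_total_mismatches=self.max_total_mismatches,
            clamp_length=self.clamp_length,
        )


def _sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _write_manifest(config: RunConfig, outdir: Path, inputs: list[str | Path]) -> Path:
    from . import __version__

    manifest = {
        "version": __version__,
        "config": asdict(config),
        "seed": config.seed,
        "input_checksums": {str(p): _sha256(p) for p in inputs},
    }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path


def _resolve_pairs(names: list[str]):
    pairs = []
    for name in names:
        fw_name, rv_name = name.split("/")
        pairs.append((primer_by_name(fw_name), primer_by_name(rv_name)))
    return pairs


def run_specificity(config: RunConfig) -> dict:
    """Mismatch table, specificity matrix, amplicon FASTA for a panel.

    Returns a summary dict including ``exit_code`` (2 when any non-target is
    predicted to amplify with a specific pair).
    """
    if not config.targets:
        raise ValueError("specificity run needs a targets FASTA")
    for p in (config.targets, config.nontargets):
        if p and not Path(p).exists():
            raise FileNotFoundError(p)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    targets = read_fasta(config.targets)
    nontargets = read_fasta(config.nontargets) if config.nontargets else []
    templates = targets + nontargets
    pairs = _resolve_pairs(config.primer_pairs)
    rule = config.rule()

    logger.info(
        "specificity: %d targets, %d non-targets, %d pairs",
        len(targets), len(nontargets), len(pairs),
    )
    primers = {p.name: p for pair in pairs for p in pair}
    profiles = [
        find_best_binding_site(
            primer, t,
            Strand.PLUS if primer.role is PrimerRole.FORWARD else Strand.MINUS,
        )
        for primer in primers.values()
        for t in templates
    ]
    mismatch_report(profiles).to_csv(outdir / "mismatch_report.tsv", sep="\t", index=False)

    matrix = specificity_matrix(pairs, templates, rule, config.max_product)
    matrix.to_csv(outdir / "specificity_matrix.csv")
    write_amplicons(matrix, templates, outdir / "amplicons.fasta")

    target_ids = {t.id for t in targets}
    violations = [
        (tid, pair)
        for pair in config.specific_pairs
        for tid in matrix.amplified.index
        if tid not in target_ids and matrix.amplified.loc[tid, pair]
    ]
    inputs = [config.targets] + ([config.nontargets] if config.nontargets else [])
    _write_manifest(config, outdir, inputs)
    if violations:
        logger.warning("specificity violated: %s", violations)
    return {
        "exit_code": 2 if violations else 0,
        "violations": violations,
        "matrix": matrix,
        "outdir": str(outdir),
    }


def run_phylogeny(config: RunConfig) -> dict:
    """Distances, NJ tree with bootstrap supports, barcoding-gap summary."""
    if not config.alignment:
        raise ValueError("phylogeny run needs an aligned FASTA")
    if not Path(config.alignment).exists():
        raise FileNotFoundError(config.alignment)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = read_fasta(config.alignment, allow_gaps=True)
    aln = Alignment(rows=rows)

    dm = distance_matrix(aln, config.distance_method)
    dm.to_csv(outdir / "distances.csv")
    dm.to_csv(outdir / "distances_x100.csv", scale=100.0)
    dm.to_csv(outdir / "distances_x100_lower.csv", scale=100.0, lower_triangular=True)

    tree = None
    if len(aln.rows) < 3:
        warnings.warn("fewer than 3 taxa: distances computed, no tree built")
    else:
        tree = bootstrap_supports(
            aln, replicates=config.replicates, seed=config.seed,
            method=config.distance_method,
        )
        if config.outgroups:
            tree = root_with_outgroup(tree, config.outgroups)
        write_newick(tree, outdir / "tree.newick")

    groups = {t: t.split("_")[0] for t in dm.taxa}
    gap = barcoding_gap(dm, groups, exclude=config.outgroups)
    scale = 100.0 if config.scale_x100 else 1.0
    unit = "per 100 sites" if config.scale_x100 else "per site"
    lines = [
        f"taxa: {len(dm.taxa)}",
        f"distance method: {dm.method} (pairwise deletion)",
        f"max intraspecific distance ({unit}): "
        + (f"{gap['max_intraspecific'] * scale:.4f}" if gap["max_intraspecific"] is not None else "n/a"),
        f"min interspecific distance ({unit}): "
        + (f"{gap['min_interspecific'] * scale:.4f}" if gap["min_interspecific"] is not None else "n/a"),
        f"barcoding gap positive: {gap['gap_positive']}",
    ]
    (outdir / "gap_summary.txt").write_text("\n".join(lines) + "\n")
    _write_manifest(config, outdir, [config.alignment])
    return {"exit_code": 0, "distance_matrix": dm, "tree": tree, "gap": gap,
            "outdir": str(outdir)}


def run_design(config: RunConfig, constraints: DesignConstraints | None = None) -> dict:
    """Discriminative primer-pair search; candidate table as CSV."""
    if not (config.targets and config.nontargets):
        raise ValueError("design run needs targets (aligned) and non-targets")
    for p in (config.targets, config.nontargets):
        if not Path(p).exists():
            raise FileNotFoundError(p)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    targets = read_fasta(config.targets, allow_gaps=True)
    nontargets = read_fasta(config.nontargets)
    candidates = enumerate_discriminative_primers(targets, nontargets, constraints)
    candidates_to_dataframe(candidates).to_csv(outdir / "primer_candidates.csv", index=False)
    _write_manifest(config, outdir, [config.targets, config.nontargets])
    return {"exit_code": 0, "candidates": candidates, "outdir": str(outdir)}


def run_simulate(config: RunConfig, params: FamilyParams | None = None) -> dict:
    """Simulate a COI family and write FASTA plus the generating truth."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    params = params or FamilyParams(seed=config.seed)
    records, tree = simulate_family(params)
    fasta, sidecar = write_truth_bundle(
        records, outdir / "family", tree=tree, params=params
    )
    _write_manifest(config, outdir, [])
    return {"exit_code": 0, "fasta": str(fasta), "truth": str(sidecar),
            "outdir": str(outdir)}
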