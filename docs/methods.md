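# Methods

This note documents the models, conventions and numerical choices behind
`coidiag`, and what the synthetic fixtures do and do not establish.

## Primer–template matching

Primers and templates are strings over the 15-letter IUPAC alphabet. Two
codes *match* when their base sets intersect (optimistic semantics): a
degenerate primer position such as R pairs with A or G, and an N in a
database template matches anything. A `pessimistic` flag inverts the
treatment of template ambiguity (the template code must be wholly contained
in the primer code), for users who prefer to count unknown template bases
as potential mismatches. Matching is ungapped: primer/template indels are
out of scope, and templates must be gap-free.

Binding sites are scored by sliding the primer over every window of the
template. On the plus strand a forward primer's 3' terminus sits at the
right edge of the window; a reverse primer anneals to the minus strand, so
its site is reported in plus-strand coordinates with the 3' terminus at the
*left* edge. Mismatch positions are recorded as offsets from the 3'
terminus (offset 0 = terminal base) because extension chemistry cares about
3'-proximity, not absolute position. Best-site search minimizes the total
mismatch count with ties broken by the smallest plus-strand start; when a
primer has several plausible sites this deterministic minimum is the one
scored.

There is no thermodynamic model (no melting temperature, ΔG, dimer or
hairpin screen). The assay logic being reproduced is purely positional:
whether mismatches exist and where they sit relative to the 3' end.

## Extension rule

A site supports extension when (i) no mismatch falls within the
`clamp_length` 3'-terminal positions and (ii) the total mismatch count is
at most `max_total_mismatches`. Defaults are `clamp_length = 2` and
`max_total_mismatches = 4`. This calibration reproduces all observed panel
behaviour simultaneously: universal primers with a single internal mismatch
amplify; a reverse universal primer with a mismatch on the next-to-last
base fails; and the specific pair fails on every confounder because each
carries at least one clamp mismatch on both primers even when the total
count (1–4 on the forward primer) would pass. Both parameters are
configurable; the clamp, not the total, is the decisive criterion in the
bundled panel.

## In-silico PCR

Binding sites with at most `max_total_mismatches` mismatches are enumerated
on both strands; every forward-site × reverse-site combination in
productive orientation (forward footprint entirely upstream of the reverse
footprint, nested/inverted configurations rejected) with product length ≤
`max_product` (default 3000 bp, generous for COI work) becomes an
`AmpliconPrediction`, flagged `predicted` when both sites pass the
extension rule. Product length is outer edge to outer edge, inclusive of
both primer footprints — the convention under which the bundled specific
pair yields its 341 bp product. A specificity-matrix cell is *amplified*
iff at least one predicted amplicon exists; multiple bands are recorded but
do not change the boolean.

## Discriminative primer design

Candidates are drawn from the strict-majority consensus of the target
alignment (ties and gap-majority columns become N and are excluded from
windows; degenerate candidates are off by default since the reference assay
uses non-degenerate primers). A window qualifies as a forward (reverse)
candidate when every target row matches it at every column and, for every
non-target, its best binding site — searched over the full non-target
sequence in the orientation that would amplify the homologous locus —
shows at least `min_mismatches` total and `min_clamp_mismatches` inside the
3' `clamp_window`.

`clamp_window` (default 5 nt) is deliberately wider than the extension
rule's 2-nt clamp: design wants a margin of 3'-proximal discrimination
(mismatches "accumulating at the 3' end"), while the extension rule models
the hard polymerase block. The discrimination constraint applies to *both*
primers of a pair against *every* non-target, since amplification fails if
either primer fails. Pairs are ranked by worst-case clamp mismatches, then
worst-case totals (both descending), with deterministic coordinate
tie-breaks. How many windows the original assay's designers considered is
unknowable; this exhaustive enumeration plus ranking is this package's own
design.

The scan is exact: per window length, a diagonal cumulative-sum table gives
every window × placement mismatch count in O(L_target × L_nontarget),
so full enumeration over lengths 18–32 stays interactive on COI-scale
inputs.

## Distances

All distances use **pairwise deletion**: for each sequence pair, only
columns where both rows carry an unambiguous A/C/G/T are retained.

* `p_distance` — proportion of differing retained columns.
* `jc` — Jukes–Cantor correction, the equal-rate limit; p ≥ 3/4 saturates.
* `mcl` — maximum composite likelihood on the Tamura–Nei (TN93) model.
  Base frequencies are taken from the whole alignment (floor-clamped at
  1e-4 so degenerate toy alignments remain computable). The two
  transition/transversion rate ratios k1 = α1/β (purine) and k2 = α2/β
  (pyrimidine) are estimated **once** by maximizing the sum of pairwise
  log-likelihoods (Nelder–Mead on the log scale, started from the pooled
  moment estimate, each pair's distance profiled out by a nested 1-D ML
  fit). Each pair's distance is then the bounded 1-D ML fit given the
  shared parameters. The method is named only by citation in the source
  assay's description; this shared-parameter composite-likelihood reading
  is the package's interpretation, with p-distance and JC provided as
  fallbacks.

Saturated cells (fit at the bound of 10 substitutions/site, or an undefined
JC log) are flagged and set to the largest finite unflagged distance in the
matrix, keeping neighbor joining runnable while the flag array reports the
problem loudly.

Distances are substitutions per site; reporting utilities also emit a ×100
scale ("per 100 sites") because published COI distances in this domain are
conventionally printed on that scale.

Bootstrap replicates reuse the full-data frequencies and rate ratios and
refit only the per-pair distances. This is a deliberate speed/fidelity
trade: supports then do not reflect rate-parameter uncertainty, which is
negligible beside topological resampling noise at COI alignment sizes.

## Neighbor joining, bootstrap, rooting

NJ is the standard Saitou–Nei agglomeration (Q-matrix minimization,
two-branch split, matrix reduction), with a deterministic first-minimum
tie-break, finishing at an unrooted trifurcation. Negative branch lengths
are clamped to zero with the deficit moved to the sibling branch of the
same join — standard practice; the algorithm is exact on additive matrices
(verified to 1e-9 against a path-length oracle).

Bootstrap: alignment columns are resampled with replacement (one seeded
stream, deterministic replicate order; default 1000 replicates), distances
and NJ recomputed per replicate, and each internal edge of the *full-data*
tree — not a consensus — annotated with the percentage of replicate trees
containing its bipartition. Replicates in which some pair retains no
columns are dropped, counted and reported with a warning; supports are
percentages of effective replicates. Support values belong to bipartitions,
so rerooting re-derives node labels from the bipartition table rather than
letting labels travel with nodes.

Outgroup rooting places the root midway on the edge separating a
monophyletic outgroup from the ingroup; a non-monophyletic outgroup raises
an error naming the smallest clade containing all outgroup taxa.

## Synthetic data

`simulate_family` evolves a root sequence (drawn from configurable base
frequencies, uniform by default) along an ultrametric species tree:
species radiate from a single polytomy at depth (inter − intra)/2 so every
between-species pair has expected divergence `interspecific` and every
within-species pair `intraspecific`; a caterpillar shape with staggered
join heights is available for tree-reconstruction stress tests.
Substitutions follow JC or K2P (closed-form transition probabilities, no
matrix exponentials), with no indels and no rate heterogeneity across
sites — deliberate simplifications matching the ungapped, single-locus
scope. Defaults mirror the divergence structure the specific amplicon
resolves: 0.6% within species, 5.1% between close species, lengths 341 or
~1000 matching the two amplicon scales.

`implant_primer_sites` writes a forward and a reverse site with exactly
controlled 3'-offset mismatches into a template (mismatched bases chosen
incompatible with the primer code; a handful of re-randomizations guard
against coincidental better sites in the background) and verifies the
construction through the matching module — closure under recovery is the
fixture's definition of correctness.

### The synthetic reference panel

Real COI database records cannot be bundled, so `coidiag.reference` builds,
from a fixed seed, an AT-rich COI-like template family embodying the
published alignment facts exactly: specific-pair sites (perfect on targets;
1–4 forward / 3–9 reverse mismatches with at least one clamp mismatch on
both primers in every non-target), universal-primer sites (≤ 1 internal
mismatch for Ron/Calvin; three mismatches for UEA8 on the target, one at
3'-offset 1), and a 341-column barcoding alignment with planted distances
(0, 2 and 17 substitutions for the conspecific and closest-congener rows;
17 is the closest realizable count to 5.1 per 100 sites on 341 discrete
sites, giving a fixture resolution of ~0.29 per 100 sites). Ron and UEA3
overlap on the template exactly as their shared subsequence dictates, so
planted mismatches are restricted to the non-overlapping halves.

A green test on this panel establishes that the *machinery* reproduces the
assay's logic and numbers; it does not establish anything about real
specimens — no sequencing error, heteroplasmy, pseudogenes (NUMTs),
alignment uncertainty, or within-species site-pattern structure is
modelled, and real GenBank records remain the validation path when network
access exists.

## Pipelines

`run_specificity` and `run_phylogeny` orchestrate the above from a flat
YAML config (flags override file values); outputs are CSV/TSV/FASTA/Newick
plus a JSON manifest (config, seed, input SHA-256 checksums, package
version) sufficient to reproduce any run byte-for-byte. The specificity run
exits 2 when a non-target is predicted to amplify with a pair listed in
`specific_pairs` (default: the specific pair only — the universal control
pairs amplify non-targets by design). Barcoding-gap grouping uses the
leading `_`-delimited id token by default; library users can pass explicit
groups.

## Known limitations

* No thermodynamics: primers that pass the combinatorial rule can still
  fail in the lab (Tm imbalance, dimers, secondary structure).
* The extension rule is a binary calibration, not a polymerase model;
  mismatch identity (e.g. G·T vs A·A) is ignored.
* MCL rate ratios are global; strongly heterogeneous pairs would be better
  served by per-pair TN93.
* The simulator's uniform-rate, indel-free model understates real COI
  rate heterogeneity (third-position bias).
* Candidate enumeration is exhaustive within the constraint box; it does
  not optimize primer count or multiplexing.
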