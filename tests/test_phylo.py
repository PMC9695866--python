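import math
import random

import dendropy
import numpy as np
import pytest

import helpers
from coidiag.phylo import (
    DistanceMatrix,
    barcoding_gap,
    bootstrap_supports,
    distance_matrix,
    jc_distance,
    mcl_distance_matrix,
    neighbor_joining,
    p_distance,
    pairwise_deletion_mask,
    root_with_outgroup,
    support_for_clade,
    tn93_expected_differences,
)
from coidiag.seq_core import Alignment, NucleotideSequence
from coidiag.synthetic_data import FamilyParams, simulate_family


def _aln(rows: dict[str, str]) -> Alignment:
    return Alignment(
        rows=[
            NucleotideSequence(id=k, residues=v, allow_gaps=True)
            for k, v in rows.items()
        ]
    )


class TestPairwiseDeletion:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ("ACGT", "ACGT", [0, 1, 2, 3]),
            ("ACN-", "ACGT", [0, 1]),
            ("RCGT", "ACGT", [1, 2, 3]),  # ambiguity codes are removed too
        ],
    )
    def test_examples(self, a, b, expected):
        assert pairwise_deletion_mask(a, b).tolist() == expected

    def test_planted_ambiguity_complement(self):
        rng = random.Random(21)
        n = 120
        a = list(helpers.random_dna(rng, n))
        b = list(helpers.random_dna(rng, n))
        planted = sorted(rng.sample(range(n), 17))
        for i, pos in enumerate(planted):
            (a if i % 2 else b)[pos] = "N" if i % 3 else "-"
        mask = pairwise_deletion_mask("".join(a), "".join(b))
        assert sorted(set(range(n)) - set(planted)) == mask.tolist()

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="length"):
            pairwise_deletion_mask("ACG", "AC")


class TestPDistance:
    def test_identical_and_quarter(self):
        assert p_distance("ACGT", "ACGT") == 0.0
        assert p_distance("ACGT", "ACGA") == 0.25

    @pytest.mark.parametrize("case", range(10))
    def test_matches_naive_count(self, case):
        rng = random.Random(400 + case)
        n = 200
        a = helpers.random_dna(rng, n)
        b = "".join(
            ch if rng.random() > 0.1 else rng.choice("ACGT-N") for ch in a
        )
        kept = [
            i for i in range(n) if a[i] in "ACGT" and b[i] in "ACGT"
        ]
        expected = sum(a[i] != b[i] for i in kept) / len(kept)
        assert p_distance(a, b) == pytest.approx(expected)

    def test_no_retained_columns(self):
        with pytest.raises(ValueError, match="no retained columns"):
            p_distance("NNNN", "ACGT")


class TestTn93Machinery:
    @pytest.mark.parametrize("case", range(15))
    def test_forward_inverts_with_moment_formula(self, case):
        """Expected (P1,P2,Q) at distance d invert back to d through the
        independent closed-form TN93 estimator."""
        rng = random.Random(500 + case)
        freqs = np.array([rng.uniform(0.1, 0.4) for _ in range(4)])
        freqs /= freqs.sum()
        d = rng.uniform(0.005, 0.8)
        k1, k2 = rng.uniform(0.5, 8), rng.uniform(0.5, 8)
        p1, p2, q = tn93_expected_differences(d, k1, k2, freqs)
        assert helpers.tn93_invert(p1, p2, q, freqs) == pytest.approx(d, abs=1e-8)

    def test_identical_rows_zero_matrix(self):
        aln = _aln({"a": "ACGTACGTAA", "b": "ACGTACGTAA", "c": "ACGTACGTAA"})
        dm = mcl_distance_matrix(aln)
        assert np.allclose(dm.values, 0.0)

    def test_p_distance_never_exceeds_mcl(self, barcoding):
        aln, _, _ = barcoding
        mcl = mcl_distance_matrix(aln)
        p = distance_matrix(aln, "p_distance")
        assert np.all(mcl.values + 1e-12 >= p.values)

    def test_mcl_close_to_jc_on_equal_rate_data(self):
        """On JC-simulated sequences the composite-likelihood distance agrees
        with Jukes-Cantor within Monte-Carlo error (small replicate count
        here; the full check runs in the acceptance suite)."""
        diffs = []
        for seed in range(15):
            records, _ = simulate_family(
                FamilyParams(n_species=3, n_per_species=1, length=800,
                             intraspecific=0.0, interspecific=0.05, seed=seed)
            )
            aln = Alignment(rows=records)
            mcl = mcl_distance_matrix(aln)
            iu = np.triu_indices(3, 1)
            jc = np.array(
                [jc_distance(records[i].residues, records[j].residues)
                 for i, j in zip(*iu)]
            )
            diffs.append(np.mean(mcl.values[iu] - jc))
        se = np.std(diffs, ddof=1) / math.sqrt(len(diffs))
        assert abs(np.mean(diffs)) < 3 * se + 1e-4

    def test_degenerate_pair_rejected(self):
        aln = _aln({"a": "NNNNACGT", "b": "ACGTNNNN", "c": "ACGTACGT"})
        with pytest.raises(ValueError, match="no retained columns"):
            mcl_distance_matrix(aln)

    def test_saturation_flagged_with_fallback(self):
        # complementary strands: p-distance near 1 saturates JC
        aln = _aln({"a": "ACGT" * 10, "b": "TGCA" * 10, "c": "ACGT" * 10})
        dm = distance_matrix(aln, "jc")
        assert dm.flagged[0, 1]
        assert np.isfinite(dm.values).all()

    def test_matrix_validation(self):
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [2.0, 0.0]]), "p_distance")
        with pytest.raises(ValueError, match="diagonal"):
            DistanceMatrix(["a", "b"], np.array([[0.1, 1.0], [1.0, 0.0]]), "p_distance")


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        dm = DistanceMatrix(
            ["a", "b", "c"],
            np.array([[0.0, 3.0, 4.0], [3.0, 0.0, 5.0], [4.0, 5.0, 0.0]]),
            "p_distance",
        )
        tree = neighbor_joining(dm)
        lengths = {
            leaf.taxon.label: leaf.edge.length for leaf in tree.leaf_node_iter()
        }
        assert lengths == pytest.approx({"a": 1.0, "b": 2.0, "c": 3.0})

    def test_too_few_taxa(self):
        dm = DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [1.0, 0.0]]), "p_distance")
        with pytest.raises(ValueError, match="at least 3"):
            neighbor_joining(dm)

    @pytest.mark.parametrize("case", range(8))
    def test_additive_matrix_recovered_exactly(self, case):
        """NJ is exact on additive matrices: path lengths in the built tree
        reproduce the input to 1e-9 and the topology matches the generator."""
        rng = random.Random(600 + case)
        adj, leaves = helpers.random_additive_tree(rng, 6)
        mat = np.array(helpers.path_length_matrix(adj, leaves))
        dm = DistanceMatrix(leaves, mat, "p_distance")
        tree = neighbor_joining(dm)
        pdm = tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in tree.taxon_namespace}
        for i, a in enumerate(leaves):
            for j, b in enumerate(leaves):
                if i < j:
                    assert pdm.distance(taxa[a], taxa[b]) == pytest.approx(
                        mat[i, j], abs=1e-9
                    )
        got = _bipartitions_of(tree, leaves)
        assert got == helpers.tree_bipartitions(adj, leaves)

    @pytest.mark.parametrize("case", range(4))
    def test_agrees_with_scikit_bio_on_additive_input(self, case):
        """Independent cross-check: same topology as scikit-bio's NJ."""
        skbio_tree = pytest.importorskip("skbio.tree")
        from skbio import DistanceMatrix as SkbioDM

        rng = random.Random(700 + case)
        adj, leaves = helpers.random_additive_tree(rng, 7)
        mat = np.array(helpers.path_length_matrix(adj, leaves))
        mat = (mat + mat.T) / 2.0  # exact symmetry for skbio's validator
        ours = neighbor_joining(DistanceMatrix(leaves, mat, "p_distance"))
        theirs = skbio_tree.nj(SkbioDM(mat, ids=leaves))
        theirs_bips = set()
        for node in theirs.non_tips():
            names = frozenset(t.name for t in node.tips())
            if 1 < len(names) < len(leaves) - 1:
                if leaves[0] in names:
                    names = frozenset(set(leaves) - names)
                theirs_bips.add(names)
        assert _bipartitions_of(ours, leaves) == theirs_bips


def _bipartitions_of(tree: dendropy.Tree, leaves) -> set[frozenset[str]]:
    tree.encode_bipartitions()
    out = set()
    for edge in tree.preorder_edge_iter():
        if edge.tail_node is None or edge.head_node.is_leaf():
            continue
        side = {l.taxon.label for l in edge.head_node.leaf_iter()}
        if 1 < len(side) < len(leaves) - 1:
            if leaves[0] in side:
                side = set(leaves) - side
            out.add(frozenset(side))
    return out


class TestBootstrap:
    def test_determinism_and_range(self, barcoding):
        aln, _, _ = barcoding
        t1 = bootstrap_supports(aln, replicates=60, seed=42)
        t2 = bootstrap_supports(aln, replicates=60, seed=42)
        assert t1.bipartition_supports == t2.bipartition_supports
        assert all(0 <= v <= 100 for v in t1.bipartition_supports.values())
        assert t1.bootstrap_effective == 60

    def test_default_replicates_is_1000(self):
        import inspect

        assert inspect.signature(bootstrap_supports).parameters["replicates"].default == 1000

    def test_well_separated_clades_get_high_support(self):
        records, _ = simulate_family(
            FamilyParams(n_species=3, n_per_species=3, length=600,
                         intraspecific=0.005, interspecific=0.05, seed=77)
        )
        aln = Alignment(rows=records)
        tree = bootstrap_supports(aln, replicates=60, seed=1)
        for s in (1, 2, 3):
            clade = [r.id for r in records if r.id.startswith(f"sp{s}_")]
            assert support_for_clade(tree, clade) >= 90.0


class TestRooting:
    def test_single_leaf_outgroup(self):
        dm = DistanceMatrix(
            ["a", "b", "c", "out"],
            np.array(
                [
                    [0.0, 0.2, 0.3, 1.0],
                    [0.2, 0.0, 0.3, 1.0],
                    [0.3, 0.3, 0.0, 1.1],
                    [1.0, 1.0, 1.1, 0.0],
                ]
            ),
            "p_distance",
        )
        tree = root_with_outgroup(neighbor_joining(dm), ["out"])
        assert tree.is_rooted
        kids = tree.seed_node.child_nodes()
        sides = [{l.taxon.label for l in k.leaf_iter()} for k in kids]
        assert {"out"} in sides

    def test_two_taxon_outgroup_keeps_ingroup_together(self, barcoding):
        aln, _, outgroups = barcoding
        tree = root_with_outgroup(
            neighbor_joining(mcl_distance_matrix(aln)), outgroups
        )
        sides = [
            {l.taxon.label for l in k.leaf_iter()}
            for k in tree.seed_node.child_nodes()
        ]
        assert set(outgroups) in sides
        ingroup = next(s for s in sides if s != set(outgroups))
        assert all(not t.startswith(("Catonia", "Tettigometra")) for t in ingroup)

    def test_non_monophyletic_outgroup_errors_with_clade(self, barcoding):
        aln, _, _ = barcoding
        tree = neighbor_joining(mcl_distance_matrix(aln))
        with pytest.raises(ValueError, match="not monophyletic"):
            root_with_outgroup(tree, ["Plep_study_DE", "H_scotti_synthetic"])

    def test_missing_outgroup_taxon(self, barcoding):
        aln, _, _ = barcoding
        tree = neighbor_joining(mcl_distance_matrix(aln))
        with pytest.raises(KeyError):
            root_with_outgroup(tree, ["nonexistent"])

    def test_root_unroot_round_trip(self, barcoding):
        """Rooting then derooting preserves the bipartition set."""
        aln, _, outgroups = barcoding
        leaves = list(aln.ids)
        tree = neighbor_joining(mcl_distance_matrix(aln))
        before = _bipartitions_of(tree, leaves)
        rooted = root_with_outgroup(tree, outgroups)
        rooted.deroot()
        assert _bipartitions_of(rooted, leaves) == before


def test_barcoding_gap_summary(barcoding):
    aln, groups, outgroups = barcoding
    dm = mcl_distance_matrix(aln)
    gap = barcoding_gap(dm, groups, exclude=outgroups)
    assert gap["gap_positive"]
    assert gap["max_intraspecific"] < 0.01
    assert gap["min_interspecific"] > 0.04
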