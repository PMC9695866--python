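import random

import numpy as np
import pytest

import helpers
from coidiag.primer_design import (
    DesignConstraints,
    candidates_to_dataframe,
    consensus,
    enumerate_discriminative_primers,
)
from coidiag.primer_match import Strand, find_best_binding_site
from coidiag.primers import FW1, RV1
from coidiag.reference import AMPLICON_END, AMPLICON_START
from coidiag.seq_core import Alignment, NucleotideSequence


def _seq(id_, residues, gaps=False):
    return NucleotideSequence(id=id_, residues=residues, allow_gaps=gaps)


class TestConsensus:
    def test_single_row_identity(self):
        row = _seq("a", "ACGTACGTAC")
        assert consensus([row]).residues == row.residues

    def test_tie_becomes_n(self):
        aln = Alignment(rows=[_seq("a", "ACGT"), _seq("b", "ACGA")])
        assert consensus(aln).residues == "ACGN"

    def test_gap_majority_becomes_n(self):
        aln = Alignment(
            rows=[_seq("a", "A-GT", True), _seq("b", "A-GT", True), _seq("c", "ACGT")]
        )
        assert consensus(aln).residues == "ANGT"

    def test_recovers_root_of_diverged_family(self):
        """Consensus of 10 rows at ~1% divergence equals the generating root
        at >= 95% of columns (seeded)."""
        rng = random.Random(55)
        root = helpers.random_dna(rng, 400)
        rows = []
        for i in range(10):
            seq = list(root)
            for pos in rng.sample(range(400), 4):
                seq[pos] = rng.choice([b for b in "ACGT" if b != seq[pos]])
            rows.append(_seq(f"r{i}", "".join(seq)))
        cons = consensus(Alignment(rows=rows))
        agree = sum(a == b for a, b in zip(cons.residues, root))
        assert agree >= 0.95 * 400

    def test_empty_errors(self):
        with pytest.raises(ValueError, match="empty"):
            consensus([])


def _toy_constraints(**kw):
    defaults = dict(
        primer_length=(18, 20), product_length=(40, 60),
        min_mismatches=1, min_clamp_mismatches=1, clamp_window=5,
    )
    defaults.update(kw)
    return DesignConstraints(**defaults)


class TestEnumerate:
    def test_identical_nontarget_gives_empty_list(self):
        rng = random.Random(66)
        target = helpers.random_dna(rng, 60)
        targets = [_seq("t1", target), _seq("t2", target)]
        assert (
            enumerate_discriminative_primers(
                targets, [_seq("nt", target)], _toy_constraints()
            )
            == []
        )

    def test_diagnostic_column_oracle(self):
        """Two diagnostic columns: exactly the window pairs whose 3' clamp
        regions cover them qualify, verified by exhaustive enumeration of
        every (length, start) window pair."""
        rng = random.Random(67)
        length = 140
        target = helpers.random_dna(rng, length)
        diags = (45, 95)
        flip = {"A": "C", "C": "A", "G": "T", "T": "G"}
        nt = list(target)
        for d in diags:
            nt[d] = flip[nt[d]]
        nontarget = _seq("nt", "".join(nt))
        c = _toy_constraints(product_length=(40, 130))
        got = {
            (cand.fw_start, len(cand.forward), cand.rv_start, len(cand.reverse))
            for cand in enumerate_discriminative_primers(
                [_seq("t", target)], [nontarget], c
            )
        }

        # oracle: the only mismatches are the two diagnostic columns, so a
        # window's best placement is the homologous one; qualify by whether
        # a diagnostic column falls into the 3' clamp region
        def diag_in(lo, hi):
            return any(lo <= d < hi for d in diags)

        expected = set()
        kmin, kmax = c.primer_length
        for fk in range(kmin, kmax + 1):
            for fs in range(length - fk + 1):
                if not diag_in(fs + fk - c.clamp_window, fs + fk):
                    continue
                for rk in range(kmin, kmax + 1):
                    for rs in range(fs + fk, length - rk + 1):
                        if not diag_in(rs, rs + c.clamp_window):
                            continue
                        if c.product_length[0] <= rs + rk - fs <= c.product_length[1]:
                            expected.add((fs, fk, rs, rk))
        assert expected  # the geometry admits qualifying pairs
        assert got == expected

    def test_fw1_rv1_footprints_recovered_on_reference(self, reference_panel, barcoding):
        """The bundled specific pair's footprints appear among candidates when
        designing on the target amplicon against the cixiid panel."""
        aln, _, _ = barcoding
        targets = [aln.row(t) for t in
                   ("Plep_study_DE", "Plep_Russia_synthetic", "Plep_France_synthetic")]
        _, nontargets = reference_panel
        candidates = enumerate_discriminative_primers(targets, nontargets)
        fw1_len, rv1_len = len(FW1), len(RV1)
        rv1_start = 341 - rv1_len
        hits = [
            cand
            for cand in candidates
            if cand.fw_start == 0 and len(cand.forward) == fw1_len
            and cand.rv_start == rv1_start and len(cand.reverse) == rv1_len
        ]
        assert len(hits) == 1
        (hit,) = hits
        assert hit.forward.sequence == FW1.sequence
        assert hit.reverse.sequence == RV1.sequence
        assert hit.product_length == 341

    def test_candidates_revalidate_under_primer_match(self, reference_panel, barcoding):
        """Emitted candidates reproduce their recorded non-target mismatch
        totals under independent best-site search, and match targets with
        zero mismatches."""
        aln, _, _ = barcoding
        targets = [aln.row(t) for t in
                   ("Plep_study_DE", "Plep_Russia_synthetic", "Plep_France_synthetic")]
        _, nontargets = reference_panel
        candidates = enumerate_discriminative_primers(targets, nontargets)
        assert candidates
        for cand in candidates[:10]:
            for t in targets:
                prof = find_best_binding_site(cand.forward, t, Strand.PLUS)
                assert prof.total_mismatches == 0
                prof = find_best_binding_site(cand.reverse, t, Strand.MINUS)
                assert prof.total_mismatches == 0
            for nt in nontargets:
                fw_prof = find_best_binding_site(cand.forward, nt, Strand.PLUS)
                rv_prof = find_best_binding_site(cand.reverse, nt, Strand.MINUS)
                rec = cand.per_nontarget[nt.id]
                assert fw_prof.total_mismatches == rec["fw"][0]
                assert rv_prof.total_mismatches == rec["rv"][0]

    def test_tightening_constraints_yields_subset(self, reference_panel, barcoding):
        aln, _, _ = barcoding
        targets = [aln.row("Plep_study_DE"), aln.row("Plep_Russia_synthetic")]
        _, nontargets = reference_panel
        loose = enumerate_discriminative_primers(
            targets, nontargets, DesignConstraints(min_clamp_mismatches=1)
        )
        tight = enumerate_discriminative_primers(
            targets, nontargets,
            DesignConstraints(min_clamp_mismatches=1, min_mismatches=3),
        )
        key = lambda cand: (cand.fw_start, len(cand.forward), cand.rv_start, len(cand.reverse))
        assert {key(c) for c in tight} <= {key(c) for c in loose}

    def test_planted_diagnostic_pair_ranks_first(self):
        """A family where non-targets mismatch only inside two planted
        footprints: the top-ranked candidate's 3' ends sit on the planted
        diagnostic columns."""
        rng = random.Random(68)
        target = helpers.random_dna(rng, 220)
        fw_diag, rv_diag = 80, 140  # fw 3'-terminal column; rv 3' column
        flip = {"A": "C", "C": "A", "G": "T", "T": "G"}
        nontargets = []
        for i in range(3):
            nt = list(target)
            nt[fw_diag] = flip[nt[fw_diag]]
            nt[rv_diag] = flip[nt[rv_diag]]
            nontargets.append(_seq(f"nt{i}", "".join(nt)))
        c = DesignConstraints(
            primer_length=(18, 22), product_length=(60, 120),
            clamp_window=3, min_clamp_mismatches=1,
        )
        candidates = enumerate_discriminative_primers([_seq("t", target)], nontargets, c)
        assert candidates
        top = candidates[0]
        # both diagnostic columns inside the respective 3' clamp windows
        fw_end = top.fw_start + len(top.forward)
        assert fw_end - c.clamp_window <= fw_diag < fw_end
        assert top.rv_start <= rv_diag < top.rv_start + c.clamp_window
        df = candidates_to_dataframe(candidates)
        assert df.iloc[0]["worst_clamp_mismatches"] == top.worst_clamp_mismatches


def test_dataframe_columns_empty_ok():
    df = candidates_to_dataframe([])
    assert list(df.columns)[:3] == ["forward", "reverse", "fw_start"]
    assert df.empty
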