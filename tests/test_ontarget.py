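"""Read classification: anchors, orientation, arm-length filter, extraction."""

import numpy as np
import pytest

from repeatgate import (CcsRead, Rejection, SimulationSpec, classify_read,
                        extract_repeat, get_design, orient_read,
                        reverse_complement, simulate_sample)
from repeatgate.ontarget import (ARM_LENGTH, BAD_ORDER, MISSING_DOWNSTREAM,
                                 MISSING_UPSTREAM)

from conftest import perfect_htt_read, random_dna


class TestClassifyRead:
    def test_perfect_read_accepted_with_exact_arms(self, htt_design):
        read, tract = perfect_htt_read(cag=21, ccg=7)
        out = classify_read(read, htt_design)
        assert not isinstance(out, Rejection)
        assert out.orientation == "forward"
        assert out.l1_observed == 913 and out.l2_observed == 155
        assert out.matched_l1_expected == 913
        assert out.upstream_match.edits == 0 and out.downstream_match.edits == 0
        assert extract_repeat(out) == tract == "CAG" * 21 + "CAACAGCCGCCA" + "CCG" * 7

    @pytest.mark.parametrize("l1,accepted", [(1004, True), (1005, False)])
    def test_ten_percent_arm_boundary(self, htt_design, l1, accepted):
        """913 x 1.10 = 1004.3: a 1004-bp arm passes, 1005 bp does not."""
        read, _ = perfect_htt_read(l1=l1)
        out = classify_read(read, htt_design)
        if accepted:
            assert not isinstance(out, Rejection)
            assert out.l1_observed == l1
        else:
            assert isinstance(out, Rejection) and out.reason == ARM_LENGTH

    def test_alternative_upstream_arm_length_accepted(self, htt_design):
        read, _ = perfect_htt_read(l1=2649)
        out = classify_read(read, htt_design)
        assert not isinstance(out, Rejection)
        assert out.matched_l1_expected == 2649

    def test_scrambled_downstream_site_rejected(self, htt_design):
        read, _ = perfect_htt_read(seed=3)
        seq = read.sequence.replace(htt_design.downstream_site, "GTATGTCCTATGCA")
        out = classify_read(CcsRead("x", seq), htt_design)
        assert isinstance(out, Rejection) and out.reason == MISSING_DOWNSTREAM

    def test_missing_upstream_site_rejected(self, htt_design):
        read, _ = perfect_htt_read(seed=4)
        seq = read.sequence.replace(htt_design.upstream_site, "GTATGTCCTATGCA")
        out = classify_read(CcsRead("x", seq), htt_design)
        assert isinstance(out, Rejection) and out.reason == MISSING_UPSTREAM

    def test_swapped_sites_rejected_as_bad_order(self, htt_design):
        rng = np.random.default_rng(5)
        seq = (random_dna(rng, 200) + htt_design.downstream_site
               + "CAG" * 20 + htt_design.upstream_site + random_dna(rng, 200))
        out = classify_read(CcsRead("x", seq), htt_design)
        assert isinstance(out, Rejection) and out.reason == BAD_ORDER

    def test_anchor_with_one_edit_still_anchors(self, htt_design):
        read, tract = perfect_htt_read(seed=6)
        site = htt_design.upstream_site
        seq = read.sequence.replace(site, site[:6] + site[7:])  # 1 deletion
        out = classify_read(CcsRead("x", seq), htt_design)
        assert not isinstance(out, Rejection)
        assert out.upstream_match.edits == 1
        assert extract_repeat(out) == tract

    def test_empty_inter_anchor_span_gives_empty_tract(self, htt_design):
        rng = np.random.default_rng(8)
        seq = (random_dna(rng, 913 - 14) + htt_design.upstream_site
               + htt_design.downstream_site + random_dna(rng, 155 - 14))
        out = classify_read(CcsRead("x", seq), htt_design)
        # l2 within tolerance but the tract between anchors is empty
        assert isinstance(out, Rejection) and out.reason == ARM_LENGTH or \
            extract_repeat(out) == ""


class TestOrientation:
    def test_forward_read_keeps_sequence(self, htt_design):
        read, _ = perfect_htt_read(seed=9)
        oriented, orientation = orient_read(read, htt_design)
        assert orientation == "forward" and oriented == read.sequence

    def test_reverse_complement_is_restored(self, htt_design):
        read, _ = perfect_htt_read(seed=9)
        rc = CcsRead("rc", reverse_complement(read.sequence))
        oriented, orientation = orient_read(rc, htt_design)
        assert orientation == "reverse" and oriented == read.sequence

    def test_read_with_only_downstream_site_is_none(self, htt_design):
        rng = np.random.default_rng(10)
        seq = random_dna(rng, 400) + htt_design.downstream_site + random_dna(rng, 100)
        assert orient_read(CcsRead("x", seq), htt_design) is None

    def test_strand_symmetry_of_classification(self, htt_design):
        """classify(read) and classify(revcomp(read)) agree except the flag."""
        spec = SimulationSpec(design=htt_design,
                              genotype={"CAG": (21, 29), "CCG": (7, 7)},
                              n_reads=30, error_rates=(0.002, 0.005, 0.005),
                              reverse_fraction=0.0, seed=13)
        reads, _ = simulate_sample(spec)
        for read in reads[:15]:
            fwd = classify_read(read, htt_design)
            rev = classify_read(
                CcsRead(read.read_id, reverse_complement(read.sequence)),
                htt_design)
            if isinstance(fwd, Rejection):
                assert isinstance(rev, Rejection) and rev.reason == fwd.reason
            else:
                assert not isinstance(rev, Rejection)
                assert {fwd.orientation, rev.orientation} == {"forward", "reverse"}
                assert rev.repeat_tract == fwd.repeat_tract
                assert (rev.l1_observed, rev.l2_observed) == \
                    (fwd.l1_observed, fwd.l2_observed)
                assert rev.upstream_match == fwd.upstream_match


class TestAcceptanceMonotonicity:
    def test_looser_thresholds_never_reject_an_accepted_read(self, htt_design):
        spec = SimulationSpec(design=htt_design,
                              genotype={"CAG": (17, 41), "CCG": (7, 10)},
                              n_reads=40, error_rates=(0.003, 0.006, 0.006),
                              seed=21)
        reads, _ = simulate_sample(spec)
        loose_edits = htt_design.with_overrides(max_site_edits=3)
        loose_tol = htt_design.with_overrides(length_tolerance=0.2)
        for read in reads:
            if not isinstance(classify_read(read, htt_design), Rejection):
                assert not isinstance(classify_read(read, loose_edits), Rejection)
                assert not isinstance(classify_read(read, loose_tol), Rejection)

    def test_zero_error_acceptance_is_total_and_offtarget_rejected(self, htt_design):
        spec = SimulationSpec(design=htt_design,
                              genotype={"CAG": (21, 29), "CCG": (7, 7)},
                              n_reads=100, error_rates=(0.0, 0.0, 0.0),
                              offtarget_fraction=0.5, seed=17)
        reads, truth = simulate_sample(spec)
        flags = dict(zip(truth["read_id"], truth["is_offtarget"]))
        for read in reads:
            rejected = isinstance(classify_read(read, htt_design), Rejection)
            assert rejected == flags[read.read_id]
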