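"""Indel correction, unit decomposition and counting."""

import pytest
from hypothesis import given, settings, strategies as st

from repeatgate import (correct_indels, decompose, get_design, repeat_count,
                        track_rle)


class TestCorrectIndels:
    def test_worked_deletion_example_restores_five_units(self):
        assert correct_indels("CAGCAGCGCAGCAG", "CAG") == "CAG" * 5

    def test_clean_tract_is_fixed_point(self):
        assert correct_indels("CAGCAGCAGCAG", "CAG") == "CAGCAGCAGCAG"

    def test_single_insertion_inside_unit(self):
        # third unit carries an inserted A
        assert correct_indels("CAGCAGCAAGCAGCAG", "CAG") == "CAG" * 5

    def test_boundary_insertion_removed(self):
        assert correct_indels("CAGCAG" + "T" + "CAGCAG", "CAG") == "CAG" * 4

    def test_insufficient_left_flank_left_alone(self):
        assert correct_indels("CAGCGCAGCAG", "CAG") == "CAGCGCAGCAG"

    def test_insufficient_right_flank_left_alone(self):
        assert correct_indels("CAGCAGCGCAG", "CAG") == "CAGCAGCGCAG"

    def test_substitution_window_not_touched(self):
        # a full-length window with a substitution is not an indel defect
        tract = "CAGCAG" + "CTG" + "CAGCAG"
        assert correct_indels(tract, "CAG") == tract

    def test_multi_error_window_not_touched(self):
        # a 4-bp gap that is not one-insertion-derivable from the unit
        tract = "CAGCAG" + "GGGG" + "CAGCAG"
        assert correct_indels(tract, "CAG") == tract

    def test_correction_cascades_to_fixed_point(self):
        # the left defect becomes correctable once the right one is fixed
        tract = "CAGCAG" + "CG" + "CAGCAG" + "CA" + "CAGCAG"
        assert correct_indels(tract, "CAG") == "CAG" * 8

    def test_secondary_unit_runs_correct_with_their_own_unit(self):
        assert correct_indels("CCGCCGCGCCGCCG", "CCG") == "CCG" * 5

    @settings(max_examples=100, derandomize=True)
    @given(n=st.integers(min_value=1, max_value=60))
    def test_exact_concatenations_never_change(self, n):
        for unit in ("CAG", "CGG", "ATTCT", "GGGGCC"):
            assert correct_indels(unit * n, unit) == unit * n

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(n=st.integers(min_value=5, max_value=40),
           pos=st.integers(min_value=0, max_value=1000),
           base=st.sampled_from("ACGT"),
           kind=st.sampled_from(["del", "ins"]))
    def test_single_interior_indel_always_restored(self, n, pos, base, kind):
        """Any lone indel >= 2 units from both run ends is repaired exactly."""
        unit = "CAG"
        u = 2 + pos % (n - 4)  # defective unit index in [2, n-3]
        if kind == "del":
            broken = unit * u + unit[1:] + unit * (n - u - 1)
        else:
            broken = unit * u + unit[0] + base + unit[1:] + unit * (n - u - 1)
        assert correct_indels(broken, unit) == unit * n


class TestDecompose:
    def test_pure_fmr1_tract(self, fmr1_design):
        comp = decompose("CGG" * 5, fmr1_design)
        assert comp.unit_track == ("CGG",) * 5
        assert comp.counts == {"CGG": 5}
        assert comp.interruptions == ()

    def test_htt_linker_decomposition(self, htt_design):
        comp = decompose("CAG" * 3 + "CAACAGCCGCCA" + "CCG" * 3, htt_design)
        assert comp.unit_track == ("CAG", "CAG", "CAG", "other", "CAG",
                                   "CCG", "other", "CCG", "CCG", "CCG")
        assert comp.longest_runs == {"CAG": 3, "other": 1, "CCG": 3}
        assert [s for _, s in comp.interruptions] == ["CAA", "CCA"]

    def test_agg_interruption_recorded_with_position(self, fmr1_design):
        comp = decompose("CGG" * 9 + "AGG" + "CGG" * 2, fmr1_design)
        assert comp.counts == {"CGG": 11, "AGG": 1}
        assert comp.interruptions == ((9, "AGG"),)

    def test_leading_junk_becomes_other_windows(self, htt_design):
        comp = decompose("TT" + "CAG" * 4, htt_design)
        assert comp.frame_offset == 2
        assert comp.unit_track.count("CAG") == 4

    def test_tract_shorter_than_one_unit_is_empty(self, htt_design):
        comp = decompose("CA", htt_design)
        assert comp.unit_track == ()
        assert comp.counts == {}

    def test_frame_resynchronises_after_interior_deletion(self, htt_design):
        # one deleted base must cost one window, not the rest of the tract
        broken = "CAG" * 4 + "AG" + "CAG" * 16
        comp = decompose(broken, htt_design)
        assert comp.counts["other"] == 1
        assert comp.longest_runs["CAG"] == 16

    @settings(max_examples=60, derandomize=True)
    @given(n=st.integers(min_value=1, max_value=50))
    def test_label_counts_partition_the_track(self, n):
        htt = get_design("HTT")
        comp = decompose("CAG" * n + "CAACAGCCGCCA" + "CCG" * 7, htt)
        assert sum(comp.counts.values()) == len(comp.unit_track)


class TestRepeatCount:
    def test_htt_longest_runs_exclude_the_linker(self, htt_design):
        comp = decompose("CAG" * 21 + "CAACAGCCGCCA" + "CCG" * 7, htt_design)
        assert repeat_count(comp, htt_design) == {"CAG": 21, "CCG": 7}

    def test_fmr1_tract_total_includes_interruptions(self, fmr1_design):
        comp = decompose("CGG" * 9 + "AGG" + "CGG" * 12, fmr1_design)
        counts = repeat_count(comp, fmr1_design)
        assert counts == {"CGG": 22, "AGG": 1}

    def test_empty_tract_counts_zero(self, htt_design, fmr1_design):
        for design in (htt_design, fmr1_design):
            comp = decompose("", design)
            assert all(v == 0 for v in repeat_count(comp, design).values())

    @settings(max_examples=60, derandomize=True)
    @given(n=st.integers(min_value=1, max_value=80))
    def test_pure_tract_counts_n_under_both_modes(self, n):
        for name in ("HTT", "FMR1", "ATXN10", "C9orf72"):
            design = get_design(name)
            comp = decompose(design.primary_unit * n, design)
            assert repeat_count(comp, design)[design.primary_unit] == n


class TestCorrectionReducesInterruptions:
    def test_other_windows_never_increase_on_noisy_reads(self, htt_design,
                                                         noisy_htt_sample):
        from repeatgate import Rejection, classify_read, extract_repeat
        _, reads, _ = noisy_htt_sample
        for read in reads:
            out = classify_read(read, htt_design)
            if isinstance(out, Rejection):
                continue
            tract = extract_repeat(out)
            corrected = tract
            for unit in htt_design.units:
                corrected = correct_indels(corrected, unit)
            pre = decompose(tract, htt_design).n_other
            post = decompose(corrected, htt_design).n_other
            assert post <= pre

    def test_compensating_indel_pair_stays_monotone(self, htt_design):
        # uncorrectable insertion near the run edge plus a correctable
        # deletion further in: fixing the deletion must not add interruptions
        broken = "CAG" + "CAGT" + "CAG" * 3 + "AG" + "CAG" * 10
        pre = decompose(broken, htt_design).n_other
        post = decompose(correct_indels(broken, "CAG"), htt_design).n_other
        assert post < pre


def test_track_rle_round_trips_labels():
    assert track_rle(("CAG",) * 3 + ("other",) + ("CCG",) * 2) == \
        "CAG:3,other:1,CCG:2"
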