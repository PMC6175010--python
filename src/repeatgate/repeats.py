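"""Repeat-tract decomposition, unit counting and indel error correction.

The tract extracted from an on-target read is decomposed into consecutive
unit-length windows, each labelled with the repeat unit it matches exactly
(primary first, then secondary units in declared order) or ``other``.  CCS
errors are dominated by residual single-base indels; an optional correction
step restores a repeat unit that contains exactly one indel, provided it is
flanked on both sides by at least two intact copies of the unit.

Frame handling: the window frame is anchored at the first exact occurrence
of the primary unit, and — unlike a single fixed frame for the whole
tract — the frame *re-synchronises* at the next exact unit occurrence after
every defective window.  A lone indel therefore shows up as one isolated
``other`` window instead of cascading through the rest of the tract, which
is what makes uncorrected per-read counts and repeat-content plots usable
(isolated gray interruptions) and the longest-run count robust.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass
from itertools import groupby

from .designs import TargetDesign

OTHER = "other"


@dataclass(frozen=True)
class RepeatComposition:
    """In-frame unit track over one repeat tract.

    ``unit_track`` holds one label per window (a unit string or ``other``);
    ``counts`` tallies labels; ``longest_runs`` gives, per label, the longest
    run of consecutive windows with that label; ``interruptions`` lists
    ``(window_index, observed_sequence)`` for every window that interrupts
    the repeat — ``other`` windows always, plus secondary-unit windows at
    loci where those are defined as interruptions (FMR1 AGG inside CGG,
    i.e. designs counted in ``tract_total`` mode).
    """

    tract: str
    frame_offset: int
    unit_track: tuple[str, ...]
    counts: dict
    longest_runs: dict
    interruptions: tuple

    @property
    def n_other(self) -> int:
        return self.counts.get(OTHER, 0)


# ---------------------------------------------------------------------------
# Indel error correction
# ---------------------------------------------------------------------------

def _one_deletion_derivable(window: str, unit: str) -> bool:
    return any(unit[:i] + unit[i + 1:] == window for i in range(len(unit)))


def _one_insertion_derivable(window: str, unit: str) -> bool:
    return any(window[:i] + window[i + 1:] == unit for i in range(len(window)))


def _gap_fix(gap: str, unit: str) -> str | None:
    """Replacement for an inter-run gap if it is a single-indel defect."""
    ul = len(unit)
    if len(gap) == 1:
        # a single base inserted at a unit boundary: remove it
        return ""
    if len(gap) == ul - 1 and _one_deletion_derivable(gap, unit):
        return unit
    if len(gap) == ul + 1 and _one_insertion_derivable(gap, unit):
        return unit
    return None


def correct_indels(tract: str, unit: str) -> str:
    """Correct single-base indels inside runs of ``unit``.

    A defective window holding one indel — a ``len(unit)-1`` window (one
    deletion), a ``len(unit)+1`` window (one insertion), or a lone inserted
    base at a unit boundary — is restored to an exact unit copy when at
    least two consecutive exact copies flank it on *each* side.  Scanning is
    left to right, each gap corrected at most once per pass, and passes
    repeat until a fixed point (a correction can merge runs and make a
    neighbouring gap correctable).  Everything outside such windows,
    including the first/last two units of any clean flank, is untouched;
    tracts that are exact unit concatenations are returned unchanged.

    Correction is optional in the pipeline: modifying reads is not always
    advisable, so callers can skip this step.
    """
    if len(unit) < 2:
        raise ValueError("repeat unit must be at least 2 bases for correction")
    pat = re.compile(f"(?:{re.escape(unit)})+")
    min_flank = 2 * len(unit)
    while True:
        runs = [(m.start(), m.end()) for m in pat.finditer(tract)]
        if len(runs) < 2:
            return tract
        out = [tract[:runs[0][1]]]
        changed = False
        for (s1, e1), (s2, e2) in zip(runs, runs[1:]):
            gap = tract[e1:s2]
            fix = None
            if e1 - s1 >= min_flank and e2 - s2 >= min_flank:
                fix = _gap_fix(gap, unit)
            if fix is None:
                out.append(gap)
            else:
                out.append(fix)
                changed = True
            out.append(tract[s2:e2])
        out.append(tract[runs[-1][1]:])
        if not changed:
            return tract
        tract = "".join(out)


# ---------------------------------------------------------------------------
# Decomposition and counting
# ---------------------------------------------------------------------------

def decompose(tract: str, design: TargetDesign) -> RepeatComposition:
    """Decompose a tract into an in-frame unit track.

    The frame starts at the offset of the first exact primary-unit
    occurrence modulo the unit length (0 if the primary unit is absent), so
    residual junk at the tract boundary after anchor trimming is tolerated.
    After a window that matches no unit, the frame re-anchors at the next
    exact occurrence of any unit; the skipped gap contributes
    ``max(1, round(gap/unit_length))`` ``other`` windows.  A tract shorter
    than one unit yields an empty track.
    """
    units = design.units
    ul = design.unit_length
    secondary_are_interruptions = design.counting_mode == "tract_total"
    first = tract.find(design.primary_unit)
    p = (first % ul) if first >= 0 else 0
    n = len(tract)
    track: list[str] = []
    interruptions: list[tuple[int, str]] = []
    while p + ul <= n:
        window = tract[p:p + ul]
        if window in units:
            track.append(window)
            if secondary_are_interruptions and window != design.primary_unit:
                interruptions.append((len(track) - 1, window))
            p += ul
            continue
        hits = [f for f in (tract.find(u, p + 1) for u in units) if f >= 0]
        q = min(hits) if hits else n
        gap = tract[p:q]
        n_other = max(1, int(len(gap) / ul + 0.5))
        for k in range(n_other):
            frag = gap[k * ul:(k + 1) * ul] or gap[-ul:]
            track.append(OTHER)
            interruptions.append((len(track) - 1, frag))
        p = q
    counts = dict(Counter(track))
    longest = {label: max(len(list(g)) for lab2, g in groupby(track) if lab2 == label)
               for label in counts}
    return RepeatComposition(
        tract=tract,
        frame_offset=(first % ul) if first >= 0 else 0,
        unit_track=tuple(track),
        counts=counts,
        longest_runs=longest,
        interruptions=tuple(interruptions),
    )


def repeat_count(composition: RepeatComposition, design: TargetDesign) -> dict:
    """Per-unit reported counts for one read, under the design's mode.

    ``longest_run``: the longest run of consecutive exact windows, per unit
    (HTT: pure CAG tract and pure CCG tract, excluding the junction).
    ``tract_total``: the total number of windows of any label, reported
    under the primary unit, with each secondary unit's window count (its
    interruptions) alongside (FMR1: a CGG count that includes AGG positions,
    plus the AGG count itself).
    """
    if design.counting_mode == "longest_run":
        return {u: composition.longest_runs.get(u, 0) for u in design.units}
    out = {design.primary_unit: len(composition.unit_track)}
    for u in design.secondary_units:
        out[u] = composition.counts.get(u, 0)
    return out


def track_rle(track) -> str:
    """Run-length encode a unit track, e.g. ``CAG:21,other:1,CCG:7``."""
    return ",".join(f"{label}:{len(list(g))}" for label, g in groupby(track))
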