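"""End-to-end per-sample analysis: reads in, allele calls out.

``analyze_sample`` runs the whole chain for one sample at one locus:
classify every read against the design, extract the repeat tract of each
accepted read, optionally correct single-base indels inside the repeat
runs, decompose each tract into a unit track, tally per-read counts into
per-unit histograms, call the diploid alleles, phase a flanking repeat onto
the primary alleles where the design has one (HTT CCG), and summarise
somatic mosaicism around each called allele.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .alleles import (AlleleCall, CountHistogram, HETEROZYGOUS, HOMOZYGOUS,
                      build_histogram, call_alleles, phase_secondary,
                      summarize_mosaicism)
from .designs import TargetDesign
from .errors import LowCoverageError
from .io import CcsRead
from .ontarget import OnTargetRead, Rejection, classify_read, extract_repeat
from .repeats import RepeatComposition, correct_indels, decompose, repeat_count, track_rle

log = logging.getLogger("repeatgate")


@dataclass
class SampleResult:
    """Everything the pipeline derives from one sample at one locus."""

    design: TargetDesign
    corrected: bool
    n_reads: int
    accepted: list[OnTargetRead]
    rejections: list[Rejection]
    compositions: list[RepeatComposition]
    per_read_counts: list[dict]
    histograms: dict
    calls: dict
    mosaicism: dict
    #: tract_total designs with an interrupting unit: per primary allele,
    #: the modal number of interrupting units (e.g. AGG per FMR1 allele).
    interruption_profile: dict = field(default_factory=dict)

    @property
    def n_on_target(self) -> int:
        return len(self.accepted)

    def rejection_counts(self) -> dict:
        return dict(Counter(r.reason for r in self.rejections))


def _call_secondary(design, hist, per_read_counts, primary_call,
                    min_support, het_fraction):
    """Call a longest-run secondary unit, phased onto the primary alleles."""
    unit = design.secondary_units[0]
    if primary_call is not None and primary_call.zygosity == HETEROZYGOUS:
        joint = [(c[design.primary_unit], c[unit]) for c in per_read_counts]
        s1, s2 = phase_secondary(joint, primary_call)
        group1 = [c for p, c in joint
                  if abs(p - primary_call.allele1) <= abs(p - primary_call.allele2)]
        group2 = [c for p, c in joint
                  if abs(p - primary_call.allele1) > abs(p - primary_call.allele2)]
        zyg = HOMOZYGOUS if s1 == s2 else HETEROZYGOUS
        return AlleleCall(design.name, unit, s1, s2, zyg,
                          sum(1 for c in group1 if c == s1),
                          sum(1 for c in group2 if c == s2), hist)
    return call_alleles(hist, min_support, het_fraction)


def analyze_sample(reads: Sequence[CcsRead], design: TargetDesign, *,
                   correct: bool = True, min_support: int = 10,
                   het_fraction: float = 0.2, noise_floor: int = 2) -> SampleResult:
    """Run the full analysis for one sample at one locus.

    Allele calls that fail the coverage threshold are stored as ``None``
    (with a warning) rather than aborting the sample.
    """
    accepted: list[OnTargetRead] = []
    rejections: list[Rejection] = []
    compositions: list[RepeatComposition] = []
    per_read_counts: list[dict] = []

    for read in reads:
        outcome = classify_read(read, design)
        if isinstance(outcome, Rejection):
            rejections.append(outcome)
            continue
        accepted.append(outcome)
        tract = extract_repeat(outcome)
        if correct:
            for unit in design.units:
                tract = correct_indels(tract, unit)
        comp = decompose(tract, design)
        compositions.append(comp)
        per_read_counts.append(repeat_count(comp, design))

    histograms = {
        unit: build_histogram([c[unit] for c in per_read_counts], design.name, unit)
        for unit in design.units}

    calls: dict = {}
    primary_call = None
    try:
        primary_call = call_alleles(histograms[design.primary_unit],
                                    min_support, het_fraction)
    except LowCoverageError as exc:
        log.warning("no %s call: %s", design.primary_unit, exc)
    calls[design.primary_unit] = primary_call

    interruption_profile: dict = {}
    if design.secondary_units:
        unit = design.secondary_units[0]
        if design.counting_mode == "longest_run":
            try:
                calls[unit] = _call_secondary(design, histograms[unit],
                                              per_read_counts, primary_call,
                                              min_support, het_fraction)
            except LowCoverageError as exc:
                log.warning("no %s call: %s", unit, exc)
                calls[unit] = None
        else:
            # interrupting unit: profile it per primary allele instead
            if primary_call is not None and per_read_counts:
                groups: dict[int, Counter] = {a: Counter()
                                              for a in set(primary_call.alleles)}
                for c in per_read_counts:
                    a = min(set(primary_call.alleles),
                            key=lambda x: (abs(c[design.primary_unit] - x), x))
                    groups[a][c[unit]] += 1
                interruption_profile = {
                    a: min(cnt, key=lambda k: (-cnt[k], k))
                    for a, cnt in groups.items() if cnt}

    mosaicism = {}
    if primary_call is not None:
        mosaicism = summarize_mosaicism(histograms[design.primary_unit],
                                        primary_call, noise_floor)

    return SampleResult(
        design=design, corrected=correct, n_reads=len(reads),
        accepted=accepted, rejections=rejections, compositions=compositions,
        per_read_counts=per_read_counts, histograms=histograms, calls=calls,
        mosaicism=mosaicism, interruption_profile=interruption_profile)


# ---------------------------------------------------------------------------
# Tabular views (the TSV surfaces)
# ---------------------------------------------------------------------------

def reads_table(result: SampleResult) -> pd.DataFrame:
    """Per-read classification TSV surface."""
    rows = []
    for r in result.accepted:
        rows.append(dict(read_id=r.read_id, locus=r.locus, status="on_target",
                         reason="", orientation=r.orientation,
                         edits_up=r.upstream_match.edits,
                         edits_down=r.downstream_match.edits,
                         l1_observed=r.l1_observed, l2_observed=r.l2_observed,
                         tract_length=len(r.repeat_tract),
                         tract_sequence=r.repeat_tract))
    for r in result.rejections:
        rows.append(dict(read_id=r.read_id, locus=result.design.name,
                         status="rejected", reason=r.reason, orientation="",
                         edits_up="", edits_down="", l1_observed="",
                         l2_observed="", tract_length="", tract_sequence=""))
    cols = ["read_id", "locus", "status", "reason", "orientation", "edits_up",
            "edits_down", "l1_observed", "l2_observed", "tract_length",
            "tract_sequence"]
    return pd.DataFrame(rows, columns=cols)


def compositions_table(result: SampleResult) -> pd.DataFrame:
    """Per-read composition TSV surface (run-length-encoded tracks)."""
    design = result.design
    rows = []
    for acc, comp, counts in zip(result.accepted, result.compositions,
                                 result.per_read_counts):
        row = dict(read_id=acc.read_id, locus=design.name,
                   corrected=result.corrected, frame_offset=comp.frame_offset,
                   unit_track=track_rle(comp.unit_track),
                   interruptions=";".join(f"{i}:{s}" for i, s in comp.interruptions))
        for unit in design.units:
            row[f"count_{unit}"] = counts[unit]
        rows.append(row)
    cols = (["read_id", "locus", "corrected", "frame_offset", "unit_track"]
            + [f"count_{u}" for u in design.units] + ["interruptions"])
    return pd.DataFrame(rows, columns=cols)


def alleles_table(result: SampleResult, sample: str = "sample") -> pd.DataFrame:
    """Per-sample allele TSV surface (one row; Table-style columns)."""
    row = dict(sample=sample, ccs_reads=result.n_reads,
               on_target_reads=result.n_on_target)
    for unit in result.design.units:
        call = result.calls.get(unit)
        row[f"{unit}_allele1"] = call.allele1 if call else ""
        row[f"{unit}_allele2"] = call.allele2 if call else ""
        row[f"{unit}_zygosity"] = call.zygosity if call else ""
    if result.design.name == "HTT":
        from .alleles import hd_repeat_class
        call = result.calls.get("CAG")
        row["hd_class_allele1"] = hd_repeat_class(call.allele1) if call else ""
        row["hd_class_allele2"] = hd_repeat_class(call.allele2) if call else ""
    return pd.DataFrame([row])
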