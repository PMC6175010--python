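"""Allele calling, somatic-mosaicism summaries and cohort statistics.

Per-read repeat counts at a locus are tallied into a histogram; the two
alleles are the two best-supported modes.  The caller must resolve adjacent
genuine alleles (e.g. a 17/18 heterozygote) without promoting the mosaicism
shoulder of an expanded allele (e.g. reads at 53–57 around a 54 allele) to a
third allele, which a fixed masking window around the mode cannot do — hence
the relative-support rule below.

Calling rule: allele A is the global modal bin (ties -> smaller count);
allele B is the best-supported remaining bin; the call is heterozygous iff
``support(B) >= max(min_support, het_fraction * support(A))`` (defaults 10
and 0.2), else homozygous A/A.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import LowCoverageError

HOMOZYGOUS = "homozygous"
HETEROZYGOUS = "heterozygous"


@dataclass(frozen=True)
class CountHistogram:
    """Distribution of per-read repeat counts for one unit at one locus."""

    locus: str
    unit: str
    bins: dict

    @property
    def total(self) -> int:
        return sum(self.bins.values())

    def as_frame(self) -> pd.DataFrame:
        rows = sorted(self.bins.items())
        return pd.DataFrame(rows, columns=["repeat_count", "n_reads"])


@dataclass(frozen=True)
class AlleleCall:
    """Diploid call for one unit at one locus; allele1 <= allele2."""

    locus: str
    unit: str
    allele1: int
    allele2: int
    zygosity: str
    support1: int
    support2: int
    histogram: CountHistogram

    @property
    def alleles(self) -> tuple[int, int]:
        return (self.allele1, self.allele2)


@dataclass(frozen=True)
class MosaicismSummary:
    """Spread of repeat counts around one called allele.

    ``bins`` holds the (count -> support) table of bins with support at or
    above the noise floor that lie nearer to this allele than to the other;
    ``count_range`` is their min–max; ``off_modal_fraction`` is the share of
    those reads not at the modal count.  Wider ranges for larger alleles are
    the signature of somatic repeat instability.
    """

    allele: int
    modal_count: int
    count_range: tuple[int, int]
    off_modal_fraction: float
    bins: dict


@dataclass(frozen=True)
class CohortSummary:
    """Allele frequencies and zygosity counts for one unit across samples."""

    unit: str
    n_samples: int
    allele_counts: dict
    allele_shares_pct: dict
    n_homozygous: int
    n_heterozygous: int
    genotype_counts: dict


def build_histogram(counts: Iterable[int], locus: str, unit: str) -> CountHistogram:
    """Exact tally of per-read reported counts (empty input -> empty bins)."""
    return CountHistogram(locus=locus, unit=unit, bins=dict(Counter(counts)))


def _best_bin(bins: Mapping[int, int]) -> int:
    """Highest-support bin; ties broken toward the smaller repeat count."""
    return min(bins, key=lambda c: (-bins[c], c))


def call_alleles(histogram: CountHistogram, min_support: int = 10,
                 het_fraction: float = 0.2) -> AlleleCall:
    """Call the two alleles from a repeat-count histogram.

    Raises :class:`LowCoverageError` when total support is below
    ``min_support``.  The call is order-invariant in the underlying reads
    (it sees only the tally) and raising ``min_support`` can only turn a
    heterozygous call homozygous, never the reverse.
    """
    total = histogram.total
    if total < min_support:
        raise LowCoverageError(histogram.locus, histogram.unit, total, min_support)
    bins = histogram.bins
    a = _best_bin(bins)
    rest = {c: s for c, s in bins.items() if c != a}
    if rest:
        b = _best_bin(rest)
        if bins[b] >= max(min_support, het_fraction * bins[a]):
            a1, a2 = sorted((a, b))
            return AlleleCall(histogram.locus, histogram.unit, a1, a2,
                              HETEROZYGOUS, bins[a1], bins[a2], histogram)
    return AlleleCall(histogram.locus, histogram.unit, a, a,
                      HOMOZYGOUS, bins[a], bins[a], histogram)


def summarize_mosaicism(histogram: CountHistogram, call: AlleleCall,
                        noise_floor: int = 2) -> dict:
    """Per-allele mosaicism summaries keyed by allele repeat count.

    Bins with support >= ``noise_floor`` are assigned to the nearer called
    allele (ties toward the smaller allele); each allele's summary reports
    the min–max range of its bins and the fraction of its reads off the
    modal count.
    """
    alleles = sorted(set(call.alleles))
    kept = {c: s for c, s in histogram.bins.items() if s >= noise_floor}
    assigned: dict[int, dict[int, int]] = {a: {} for a in alleles}
    for c, s in kept.items():
        nearest = min(alleles, key=lambda a: (abs(c - a), a))
        assigned[nearest][c] = s
    out = {}
    for a in alleles:
        bins = assigned[a]
        if a not in bins:  # the allele bin itself always belongs to its range
            bins[a] = histogram.bins.get(a, 0)
        total = sum(bins.values())
        off = 1.0 - bins[a] / total if total else 0.0
        out[a] = MosaicismSummary(
            allele=a,
            modal_count=a,
            count_range=(min(bins), max(bins)),
            off_modal_fraction=off,
            bins=dict(sorted(bins.items())),
        )
    return out


def cohort_summary(calls: Sequence[AlleleCall]) -> CohortSummary:
    """Allele-frequency table over 2N haplotypes plus zygosity counts.

    All calls must be for the same unit; shares are percentages of the 2N
    called haplotypes (one decimal) and sum to 100 within rounding.
    """
    if not calls:
        raise ValueError("cohort_summary requires at least one sample call")
    units = {c.unit for c in calls}
    if len(units) != 1:
        raise ValueError(f"mixed units in cohort: {sorted(units)}")
    allele_counts: Counter = Counter()
    genotype_counts: Counter = Counter()
    n_hom = 0
    for call in calls:
        allele_counts[call.allele1] += 1
        allele_counts[call.allele2] += 1
        genotype_counts[(call.allele1, call.allele2)] += 1
        n_hom += call.zygosity == HOMOZYGOUS
    n_haplotypes = 2 * len(calls)
    shares = {a: round(100.0 * c / n_haplotypes, 1)
              for a, c in sorted(allele_counts.items())}
    return CohortSummary(
        unit=units.pop(),
        n_samples=len(calls),
        allele_counts=dict(sorted(allele_counts.items())),
        allele_shares_pct=shares,
        n_homozygous=n_hom,
        n_heterozygous=len(calls) - n_hom,
        genotype_counts=dict(sorted(genotype_counts.items())),
    )


def phase_secondary(joint_counts: Sequence[tuple[int, int]],
                    primary_call: AlleleCall) -> tuple[int, int]:
    """Phase a flanking repeat onto the primary alleles, read by read.

    Each read carries a joint (primary, secondary) count pair.  Reads are
    assigned to the nearer primary allele (ties toward allele1) and the
    secondary allele reported with primary allele *i* is the modal secondary
    count among the reads assigned to it.  At the HTT locus this turns "the
    longer CCG repeat flanks the shorter CAG repeat" into a checkable output
    instead of an assumption.
    """
    a1, a2 = primary_call.alleles
    groups: dict[int, Counter] = {a1: Counter(), a2: Counter()}
    for primary, secondary in joint_counts:
        nearest = min((a1, a2), key=lambda a: (abs(primary - a), a))
        groups[nearest][secondary] += 1
    out = []
    for a in (a1, a2):
        if not groups[a]:
            raise LowCoverageError(primary_call.locus, primary_call.unit, 0, 1)
        out.append(_best_bin(groups[a]))
    return tuple(out)


def hd_repeat_class(cag_count: int) -> str:
    """Standard HD CAG-count band, as an annotation only (no diagnostic claim).

    <=26 normal; 27-35 intermediate; 36-39 reduced penetrance; >=40 full
    penetrance.
    """
    if cag_count <= 26:
        return "normal"
    if cag_count <= 35:
        return "intermediate"
    if cag_count <= 39:
        return "reduced_penetrance"
    return "full_penetrance"


# ---------------------------------------------------------------------------
# Reference cohort fixture
# ---------------------------------------------------------------------------

def load_reference_cohort() -> pd.DataFrame:
    """The packaged 11-sample HD cohort reference genotype table.

    Columns: sample, ccs_reads, on_target, cag1, cag2, ccg1, ccg2 — the
    published per-sample HTT CAG/CCG genotype calls (CAG concordant with
    fragment analysis for all 22 alleles), shipped as input for cohort
    summaries.
    """
    path = resources.files("repeatgate").joinpath("data/htt_cohort_genotypes.tsv")
    with resources.as_file(path) as p:
        return pd.read_csv(p, sep="\t")


def cohort_calls_from_table(table: pd.DataFrame, unit: str = "CCG",
                            locus: str = "HTT") -> list[AlleleCall]:
    """Build AlleleCall objects from a genotype table (columns e.g. ccg1/ccg2)."""
    c1, c2 = unit.lower() + "1", unit.lower() + "2"
    calls = []
    for _, row in table.iterrows():
        a1, a2 = sorted((int(row[c1]), int(row[c2])))
        support = max(1, int(row.get("on_target", 2)) // 2)
        zyg = HOMOZYGOUS if a1 == a2 else HETEROZYGOUS
        hist = build_histogram([a1] * support + [a2] * support, locus, unit)
        calls.append(AlleleCall(locus, unit, a1, a2, zyg, support, support, hist))
    return calls
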