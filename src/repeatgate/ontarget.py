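"""On-target read identification and repeat-tract extraction.

The pipeline identifies reads carrying a target repeat without aligning to a
reference: a read is on-target when both 14-bp recognition sites flanking the
repeat are found (approximately, within a small edit budget) in the correct
order on one strand, and the observed arm lengths on either side of the
tract agree with the design's expected lengths to within a tolerance
(default 10%).  The repeat tract is then the sequence between the two anchor
matches.

Approximate anchor search is unit-cost Levenshtein (substitutions count as
well as indels: single-base indels dominate the CCS error profile, but
excluding substitutions from the edit alphabet would be an unmotivated
restriction — the edit *budget*, default 2, is the operative constraint).
Ties among minimum-cost occurrences are broken by smallest start, then
shortest span, so matching is fully deterministic.  Coordinates are 0-based,
half-open.
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib
import numpy as np

from .designs import TargetDesign
from .io import CcsRead

FORWARD = "forward"
REVERSE = "reverse"

# Rejection reason codes, in the order the checks run.
MISSING_UPSTREAM = "missing_upstream_site"
MISSING_DOWNSTREAM = "missing_downstream_site"
BAD_ORDER = "bad_order"
ARM_LENGTH = "arm_length_out_of_tolerance"
AMBIGUOUS = "multiple_ambiguous_matches"
REJECTION_REASONS = (MISSING_UPSTREAM, MISSING_DOWNSTREAM, BAD_ORDER,
                     ARM_LENGTH, AMBIGUOUS)

_RC_TABLE = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_RC_TABLE)[::-1]


@dataclass(frozen=True)
class AnchorMatch:
    """An approximate occurrence of a recognition site in a read.

    ``start``/``end`` are 0-based half-open offsets on the oriented read;
    ``edits`` is the unit-cost Levenshtein distance of the matched span to
    the site.
    """

    start: int
    end: int
    edits: int


@dataclass(frozen=True)
class OnTargetRead:
    """A read accepted for a locus, with its anchor matches and tract."""

    read_id: str
    locus: str
    orientation: str
    upstream_match: AnchorMatch
    downstream_match: AnchorMatch
    l1_observed: int
    l2_observed: int
    matched_l1_expected: int
    repeat_tract: str


@dataclass(frozen=True)
class Rejection:
    """A read excluded from a locus, with the first failing check."""

    read_id: str
    reason: str

    def __post_init__(self):
        if self.reason not in REJECTION_REASONS:
            raise ValueError(f"unknown rejection reason {self.reason!r}")


# ---------------------------------------------------------------------------
# Approximate site search
# ---------------------------------------------------------------------------

def _cost_by_start(sequence: str, site: str) -> np.ndarray:
    """Minimum edit cost of matching the whole site starting at each offset.

    Semi-global DP (free right end) vectorised over sequence offsets:
    ``E[j][i]`` is the cheapest alignment of ``site[j:]`` against a substring
    of ``sequence`` beginning at ``i``.  The horizontal dependency
    (consuming a sequence base against a gap) is resolved with a suffix
    running-minimum, so each of the ``len(site)`` rows is O(n) in numpy.
    Returns ``E[0]`` over starts 0..n.
    """
    arr = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    n, m = len(arr), len(site)
    site_b = site.encode("ascii")
    idx = np.arange(n + 1, dtype=np.int32)
    E = np.zeros(n + 1, dtype=np.int32)  # row j = m: nothing left to match
    cand = np.empty(n + 1, dtype=np.int32)
    for j in range(m - 1, -1, -1):
        mismatch = (arr != site_b[j]).astype(np.int32)
        # diagonal (match/substitute) vs. site-gap (delete site[j])
        np.minimum(E[1:] + mismatch, E[:n] + 1, out=cand[:n])
        cand[n] = m - j  # only deletions remain past the sequence end
        # fold in sequence-gap moves: E[i] = min_{k>=i} cand[k] + (k - i)
        tmp = cand + idx
        E = np.minimum.accumulate(tmp[::-1])[::-1] - idx
    return E


def _smallest_end(sequence: str, site: str, start: int, cost: int) -> int:
    """Smallest end offset e such that dist(site, sequence[start:e]) == cost."""
    m = len(site)
    window = sequence[start:start + m + cost]
    prev = list(range(len(window) + 1))  # dist(site[:0], window[:l]) = l
    for j in range(1, m + 1):
        cur = [j] + [0] * len(window)
        sj = site[j - 1]
        for l in range(1, len(window) + 1):
            cur[l] = min(prev[l - 1] + (sj != window[l - 1]),
                         prev[l] + 1,
                         cur[l - 1] + 1)
        prev = cur
    for l, c in enumerate(prev):
        if c == cost:
            return start + l
    # unreachable by construction of _cost_by_start
    raise AssertionError("no end position achieves the optimal cost")


def find_site(sequence: str, site: str, max_edits: int) -> AnchorMatch | None:
    """Best approximate occurrence of ``site`` in ``sequence``.

    Returns the minimum-edit-cost occurrence under unit-cost Levenshtein
    distance, or ``None`` when the minimum over all substrings exceeds
    ``max_edits``.  Ties are broken by smallest start, then shortest span.
    ``N`` bases mismatch everything (cost 1).
    """
    if not site:
        raise ValueError("site must be non-empty")
    if max_edits < 0:
        raise ValueError("max_edits must be >= 0")
    n, m = len(sequence), len(site)
    if n == 0:
        return None
    exact = sequence.find(site)
    if exact >= 0:  # leftmost exact match is optimal on every tie-break
        return AnchorMatch(exact, exact + m, 0)
    if max_edits == 0:
        return None
    # cheap cost-only prefilter before the exact-location DP
    res = edlib.align(site, sequence, mode="HW", task="distance", k=max_edits)
    if res["editDistance"] < 0:
        return None
    costs = _cost_by_start(sequence, site)
    best = int(costs[:n].min())
    if best > max_edits:  # pragma: no cover - prefilter already excluded this
        return None
    start = int(np.argmin(costs[:n]))
    end = _smallest_end(sequence, site, start, best)
    return AnchorMatch(start, end, best)


# ---------------------------------------------------------------------------
# Orientation and classification
# ---------------------------------------------------------------------------

def _scan_strand(seq: str, design: TargetDesign, *, lazy: bool = False):
    """Find both anchors on one strand.

    With ``lazy=True`` the downstream search is skipped when the upstream
    site is absent (the strand can then never qualify) — used for the
    cheaper of the two strand scans.
    """
    up = find_site(seq, design.upstream_site, design.max_site_edits)
    if lazy and up is None:
        return None, None
    down = find_site(seq, design.downstream_site, design.max_site_edits)
    return up, down


def _in_order(up: AnchorMatch | None, down: AnchorMatch | None) -> bool:
    return up is not None and down is not None and up.end <= down.start


def _pick_strand(fu, fd, ru, rd) -> str | None:
    """Choose the qualifying strand, or AMBIGUOUS on an exact-cost tie.

    When both strands carry both anchors in order, the strand whose anchors
    cost strictly fewer total edits wins (a genuine capture is always
    cheaper than a spurious opposite-strand hit, which keeps acceptance
    monotone in the edit budget); only an exact tie — the palindromic
    pathology — is ambiguous.
    """
    fwd_ok, rev_ok = _in_order(fu, fd), _in_order(ru, rd)
    if not (fwd_ok or rev_ok):
        return None
    if fwd_ok and rev_ok:
        f_cost = fu.edits + fd.edits
        r_cost = ru.edits + rd.edits
        if f_cost == r_cost:
            return AMBIGUOUS
        return FORWARD if f_cost < r_cost else REVERSE
    return FORWARD if fwd_ok else REVERSE


def orient_read(read: CcsRead, design: TargetDesign):
    """Determine the strand on which both anchors occur in order.

    Returns ``(oriented_sequence, orientation)`` with orientation
    ``"forward"`` or ``"reverse"``, ``None`` when neither strand qualifies,
    or a :class:`Rejection` with reason ``multiple_ambiguous_matches`` when
    both strands qualify (palindromic pathology).
    """
    fwd = read.sequence
    rev = reverse_complement(fwd)
    fu, fd = _scan_strand(fwd, design)
    ru, rd = _scan_strand(rev, design, lazy=True)
    strand = _pick_strand(fu, fd, ru, rd)
    if strand == AMBIGUOUS:
        return Rejection(read.read_id, AMBIGUOUS)
    if strand == FORWARD:
        return fwd, FORWARD
    if strand == REVERSE:
        return rev, REVERSE
    return None


def _within(observed: int, expected: int, tolerance: float) -> bool:
    return abs(observed - expected) <= tolerance * expected


def classify_read(read: CcsRead, design: TargetDesign) -> OnTargetRead | Rejection:
    """Full on-target decision for one read.

    Checks run in a fixed order and the first failure wins:
    sites present (upstream, then downstream) -> anchor order -> arm
    lengths.  The upstream arm must match *some* entry of ``l1_expected``
    within ``length_tolerance``; the downstream arm must match
    ``l2_expected``.
    """
    fwd = read.sequence
    rev = reverse_complement(fwd)
    fu, fd = _scan_strand(fwd, design)
    ru, rd = _scan_strand(rev, design, lazy=True)
    strand = _pick_strand(fu, fd, ru, rd)

    if strand == AMBIGUOUS:
        return Rejection(read.read_id, AMBIGUOUS)
    if strand is None:
        # report the first failing check on the strand with more anchors hit
        if rd is None and ru is not None:
            rd = find_site(rev, design.downstream_site, design.max_site_edits)
        n_f = (fu is not None) + (fd is not None)
        n_r = (ru is not None) + (rd is not None)
        up, down = (fu, fd) if n_f >= n_r else (ru, rd)
        if up is None:
            return Rejection(read.read_id, MISSING_UPSTREAM)
        if down is None:
            return Rejection(read.read_id, MISSING_DOWNSTREAM)
        return Rejection(read.read_id, BAD_ORDER)

    oriented, orientation, up, down = (
        (fwd, FORWARD, fu, fd) if strand == FORWARD else (rev, REVERSE, ru, rd))
    l1_observed = up.end
    l2_observed = len(oriented) - down.start
    matched_l1 = min(design.l1_expected, key=lambda e: abs(l1_observed - e))
    if not (_within(l1_observed, matched_l1, design.length_tolerance)
            and _within(l2_observed, design.l2_expected, design.length_tolerance)):
        return Rejection(read.read_id, ARM_LENGTH)
    return OnTargetRead(
        read_id=read.read_id,
        locus=design.name,
        orientation=orientation,
        upstream_match=up,
        downstream_match=down,
        l1_observed=l1_observed,
        l2_observed=l2_observed,
        matched_l1_expected=matched_l1,
        repeat_tract=oriented[up.end:down.start],
    )


def extract_repeat(on_target: OnTargetRead) -> str:
    """The repeat tract of an accepted read (the inter-anchor substring)."""
    return on_target.repeat_tract
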