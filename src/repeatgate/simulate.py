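"""Synthetic CCS-read generator with a per-read truth table.

Reads are built exactly the way the classifier assumes real captured
molecules look: a pseudo-random upstream arm *ending in* the upstream
recognition site (total length drawn from the design's expected l1 values),
a repeat tract assembled from the seeded per-allele unit counts (with the
locus linker between primary and secondary blocks where the design has
one), and a downstream arm *starting with* the downstream recognition site
(total length l2).  Substitution/insertion/deletion errors are injected
i.i.d. per base at configurable rates, a configurable fraction of reads is
reverse-complemented, and a configurable fraction is replaced by random
off-target sequence of matched length.

Somatic mosaicism is modelled as a rounded symmetric zero-mean spread of
the primary repeat count with a per-allele scale (sd), reflecting that
expanded alleles show wider per-read count distributions; no directional
expansion-bias model is asserted.  Arm sequences are uniform-random (GC
0.5) rather than copied from a genome, keeping the generator download-free.

The truth table records every read's seeded counts, class and orientation,
plus per-region injected-error counts and the number of *correctable
defects* in the tract — units carrying exactly one indel with two
error-free exact units on each side, i.e. the defects the indel-correction
rule is defined on.  Identical seeds give byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .designs import TargetDesign
from .errors import ValidationError
from .io import CcsRead
from .ontarget import reverse_complement

_CODE_TO_BASE = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_TO_CODE = np.zeros(256, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_TO_CODE[_b] = _i


@dataclass(frozen=True)
class SimulationSpec:
    """Study conditions for one simulated sample.

    ``genotype`` maps each repeat unit to its (allele1, allele2) counts,
    e.g. ``{"CAG": (21, 29), "CCG": (7, 7)}``.  ``mosaicism_sd`` is a single
    scale or an (allele1, allele2) pair applied to the primary unit's
    per-read count (0 = no spread).  ``error_rates`` are per-base
    (substitution, insertion, deletion) probabilities; the defaults model a
    CCS error profile dominated by residual single-base indels.
    ``interruptions`` optionally maps an allele index (0/1) to primary-unit
    positions replaced by the first secondary unit (FMR1 AGG interruptions).
    """

    design: TargetDesign
    genotype: Mapping[str, tuple[int, int]]
    mosaicism_sd: float | tuple[float, float] = 0.0
    n_reads: int = 200
    error_rates: tuple[float, float, float] = (0.002, 0.005, 0.005)
    offtarget_fraction: float = 0.0
    reverse_fraction: float = 0.5
    seed: int = 0
    interruptions: Mapping[int, Sequence[int]] | None = None

    def __post_init__(self):
        d = self.design
        if d.primary_unit not in self.genotype:
            raise ValidationError(
                f"genotype must include the primary unit {d.primary_unit!r}")
        for unit, pair in self.genotype.items():
            if unit not in d.units:
                raise ValidationError(f"genotype unit {unit!r} not in design {d.name!r}")
            if len(tuple(pair)) != 2 or any(int(c) < 0 for c in pair):
                raise ValidationError(f"genotype[{unit!r}] must be two counts >= 0")
        if any(not 0.0 <= r <= 1.0 for r in self.error_rates) \
                or sum(self.error_rates) >= 1.0:
            raise ValidationError("error_rates must lie in [0,1] and sum below 1")
        for name in ("offtarget_fraction", "reverse_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValidationError(f"{name} must lie in [0,1]")
        if self.n_reads < 0:
            raise ValidationError("n_reads must be >= 0")
        if any(s < 0 for s in self.sd_pair):
            raise ValidationError("mosaicism_sd must be >= 0")

    @property
    def sd_pair(self) -> tuple[float, float]:
        sd = self.mosaicism_sd
        if isinstance(sd, (int, float)):
            return (float(sd), float(sd))
        a, b = sd
        return (float(a), float(b))


def _random_seq(rng: np.random.Generator, n: int) -> str:
    if n <= 0:
        return ""
    return _CODE_TO_BASE[rng.integers(0, 4, n)].tobytes().decode("ascii")


def _apply_errors(seq: str, rng: np.random.Generator,
                  rates: tuple[float, float, float]):
    """Inject i.i.d. per-base errors; returns (mutated_seq, events).

    Events are ``(kind, clean_position)`` with kind in sub/ins/del;
    insertions occur immediately *before* the clean position (position
    ``len(seq)`` appends at the end).
    """
    sub, ins, dele = rates
    n = len(seq)
    if n == 0:
        return seq, []
    r = rng.random(n)
    ri = rng.random(n + 1)
    del_mask = r < dele
    sub_mask = (~del_mask) & (r < dele + sub)
    ins_mask = ri < ins
    events = ([("del", int(p)) for p in np.nonzero(del_mask)[0]]
              + [("sub", int(p)) for p in np.nonzero(sub_mask)[0]]
              + [("ins", int(p)) for p in np.nonzero(ins_mask)[0]])
    if not events:
        return seq, []
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    subs = np.nonzero(sub_mask)[0]
    if len(subs):
        codes = _BASE_TO_CODE[arr[subs]]
        arr[subs] = _CODE_TO_BASE[(codes + rng.integers(1, 4, len(subs))) % 4]
    kept = arr[~del_mask]
    ins_pos = np.nonzero(ins_mask)[0]
    if len(ins_pos):
        cum = np.concatenate(([0], np.cumsum(~del_mask)))
        new_pos = cum[ins_pos]
        values = _CODE_TO_BASE[rng.integers(0, 4, len(ins_pos))]
        kept = np.insert(kept, new_pos, values)
    return kept.tobytes().decode("ascii"), events


# ---------------------------------------------------------------------------
# Tract construction and defect accounting
# ---------------------------------------------------------------------------

def _build_tract(spec: SimulationSpec, allele: int, primary_count: int):
    """Clean tract string plus per-unit spans ``(start, end, run_id, k, run_len)``.

    Runs are maximal stretches of identical consecutive units; the linker
    and interrupting units break runs, so the span table directly encodes
    which units have two same-unit neighbours on each side.
    """
    d = spec.design
    blocks: list[tuple[str, bool]] = []  # (unit_or_linker, is_unit)
    primary_units = [d.primary_unit] * primary_count
    if spec.interruptions and allele in spec.interruptions and d.secondary_units:
        for pos in spec.interruptions[allele]:
            if 0 <= pos < primary_count:
                primary_units[pos] = d.secondary_units[0]
    blocks.extend((u, True) for u in primary_units)
    for u in d.secondary_units:
        count = int(spec.genotype.get(u, (0, 0))[allele])
        if count and d.linker:
            blocks.append((d.linker, False))
        blocks.extend((u, True) for _ in range(count))
    tract_parts: list[str] = []
    spans: list[tuple[int, int, int, int, int]] = []
    pos = 0
    run_id = -1
    prev_unit = None
    run_members: list[int] = []
    runs: list[list[int]] = []
    for text, is_unit in blocks:
        if is_unit:
            if text != prev_unit:
                run_id += 1
                runs.append([])
                prev_unit = text
            runs[run_id].append(len(spans))
            spans.append((pos, pos + len(text), run_id, len(runs[run_id]) - 1, -1))
        else:
            prev_unit = None
        tract_parts.append(text)
        pos += len(text)
    # back-fill run lengths
    run_lens = [len(r) for r in runs]
    spans = [(s, e, rid, k, run_lens[rid]) for (s, e, rid, k, _) in spans]
    return "".join(tract_parts), spans


def _count_correctable_defects(spans, events) -> int:
    """Units with exactly one indel and two error-free exact units each side.

    A boundary insertion (landing exactly between two units of a run) is a
    defect of the boundary; it needs the two units on each side of the
    boundary to be error-free.  These are precisely the defects the
    correction rule is defined on; clustered or run-edge errors do not
    qualify.
    """
    if not events:
        return 0
    unit_errors: dict[int, int] = {}   # span index -> any-error count
    unit_indels: dict[int, int] = {}
    boundary_ins: dict[tuple[int, int], int] = {}  # (run_id, boundary k) -> count

    def span_at(p: int):
        for i, (s, e, *_rest) in enumerate(spans):
            if s <= p < e:
                return i
        return None

    for kind, p in events:
        if kind == "ins":
            i = span_at(p)
            if i is not None:
                s, e, rid, k, rlen = spans[i]
                if p == s and k > 0:  # between unit k-1 and k of the same run
                    boundary_ins[(rid, k)] = boundary_ins.get((rid, k), 0) + 1
                    continue
            if i is None:
                continue
            unit_errors[i] = unit_errors.get(i, 0) + 1
            unit_indels[i] = unit_indels.get(i, 0) + 1
        else:
            i = span_at(p)
            if i is None:
                continue
            unit_errors[i] = unit_errors.get(i, 0) + 1
            if kind == "del":
                unit_indels[i] = unit_indels.get(i, 0) + 1

    by_run_k: dict[tuple[int, int], int] = {}
    for i, (s, e, rid, k, rlen) in enumerate(spans):
        by_run_k[(rid, k)] = i

    def clean(rid: int, k: int) -> bool:
        i = by_run_k.get((rid, k))
        return i is not None and unit_errors.get(i, 0) == 0

    def no_boundary(rid: int, *ks: int) -> bool:
        # a boundary insertion merges with an adjacent defect window or
        # splits the flanking run, so it voids the two-intact-units premise
        return all(boundary_ins.get((rid, k), 0) == 0 for k in ks)

    n = 0
    for i, (s, e, rid, k, rlen) in enumerate(spans):
        if unit_indels.get(i, 0) == 1 and unit_errors.get(i, 0) == 1:
            if (2 <= k <= rlen - 3
                    and all(clean(rid, j) for j in (k - 2, k - 1, k + 1, k + 2))
                    and no_boundary(rid, k - 1, k, k + 1, k + 2)):
                n += 1
    for (rid, k), cnt in boundary_ins.items():
        if cnt != 1:
            continue
        rlen = spans[by_run_k[(rid, k)]][4]
        if (2 <= k <= rlen - 2
                and all(clean(rid, j) for j in (k - 2, k - 1, k, k + 1))
                and no_boundary(rid, k - 1, k + 1)):
            n += 1
    return n


# ---------------------------------------------------------------------------
# Sample simulation
# ---------------------------------------------------------------------------

def simulate_sample(spec: SimulationSpec):
    """Generate one sample; returns ``(reads, truth)``.

    ``truth`` is a DataFrame with one row per read: class, orientation,
    seeded allele index and per-unit counts, injected-error counts per
    region, and the number of correctable tract defects.  With all error
    rates 0 and no mosaicism the pipeline is the identity on the seeded
    counts.
    """
    d = spec.design
    rng = np.random.default_rng(spec.seed)
    sd = spec.sd_pair
    up_site, down_site = d.upstream_site, d.downstream_site
    modal_tract_len = len(_build_tract(spec, 0, int(spec.genotype[d.primary_unit][0]))[0])
    off_len = d.l1_expected[0] + modal_tract_len + d.l2_expected

    reads: list[CcsRead] = []
    rows = []
    for i in range(spec.n_reads):
        read_id = f"sim{i:05d}"
        is_off = bool(rng.random() < spec.offtarget_fraction)
        is_rev = bool(rng.random() < spec.reverse_fraction)
        if is_off:
            seq = _random_seq(rng, off_len)
            row = dict(read_id=read_id, is_offtarget=True,
                       orientation="reverse" if is_rev else "forward",
                       allele_index=-1, l1_true=0,
                       n_errors_upstream=0, n_errors_tract=0,
                       n_errors_downstream=0, n_indels_tract=0,
                       n_correctable_defects=0, read_length=len(seq))
            for u in d.units:
                row[f"true_{u}"] = -1
            if is_rev:
                seq = reverse_complement(seq)
            reads.append(CcsRead(read_id, seq))
            rows.append(row)
            continue

        allele = int(rng.integers(0, 2))
        base_primary = int(spec.genotype[d.primary_unit][allele])
        drawn = base_primary
        if sd[allele] > 0:
            drawn = max(0, base_primary + int(round(rng.normal(0.0, sd[allele]))))
        l1 = int(d.l1_expected[rng.integers(0, len(d.l1_expected))])
        tract, spans = _build_tract(spec, allele, drawn)
        up_arm = _random_seq(rng, l1 - len(up_site)) + up_site
        down_arm = down_site + _random_seq(rng, d.l2_expected - len(down_site))

        up_mut, up_ev = _apply_errors(up_arm, rng, spec.error_rates)
        tract_mut, tract_ev = _apply_errors(tract, rng, spec.error_rates)
        down_mut, down_ev = _apply_errors(down_arm, rng, spec.error_rates)
        seq = up_mut + tract_mut + down_mut
        n_indels = sum(1 for k, _ in tract_ev if k in ("ins", "del"))
        row = dict(read_id=read_id, is_offtarget=False,
                   orientation="reverse" if is_rev else "forward",
                   allele_index=allele, l1_true=l1,
                   n_errors_upstream=len(up_ev), n_errors_tract=len(tract_ev),
                   n_errors_downstream=len(down_ev), n_indels_tract=n_indels,
                   n_correctable_defects=_count_correctable_defects(spans, tract_ev),
                   read_length=len(seq))
        for u in d.units:
            if u == d.primary_unit:
                row[f"true_{u}"] = drawn
            else:
                row[f"true_{u}"] = int(spec.genotype.get(u, (0, 0))[allele])
        if is_rev:
            seq = reverse_complement(seq)
        reads.append(CcsRead(read_id, seq))
        rows.append(row)

    columns = (["read_id", "is_offtarget", "orientation", "allele_index",
                "l1_true"]
               + [f"true_{u}" for u in d.units]
               + ["n_errors_upstream", "n_errors_tract", "n_errors_downstream",
                  "n_indels_tract", "n_correctable_defects", "read_length"])
    truth = pd.DataFrame(rows, columns=columns) if rows else pd.DataFrame(columns=columns)
    return reads, truth
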