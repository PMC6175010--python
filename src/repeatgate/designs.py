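"""Target-design definitions and capture-span arithmetic.

A *target design* describes one repeat locus as captured by the
amplification-free (CRISPR/Cas9) enrichment protocol: the two short
recognition sites that flank the repeat tract in the captured fragment, the
expected lengths of the sequence arms on either side of the tract, the repeat
unit(s) to count, and how to count them.  Reads are identified and trimmed
purely from these anchors — no reference alignment is involved — so the
design is the only locus-specific knowledge the pipeline needs.

Arm-length convention used throughout the package: ``l1`` is measured from
the 5' end of the (oriented) read through the last base of the upstream
recognition site, and ``l2`` from the first base of the downstream
recognition site through the 3' end of the read.  The anchors therefore count
toward the arms, and the repeat tract is exactly the sequence between the two
anchors.  ``l1_expected`` is a list because a SNP can destroy the proximal
restriction site used for fragmentation, in which case the next site further
upstream produces a longer — but equally valid — upstream arm (this happens
at the HTT locus, where rs2857935 removes the proximal BamHI site and the
alternative site lies 1736 bp further upstream).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

from .errors import ConfigError, ValidationError

_BASES = frozenset("ACGT")

#: Allowed per-unit counting semantics.
#:
#: ``longest_run``  — report, for each unit, the longest run of consecutive
#:                    exact copies in the decomposed tract (HTT: the pure CAG
#:                    tract and the pure CCG tract are counted separately,
#:                    excluding the CAACAGCCGCCA junction between them).
#: ``tract_total``  — report the total number of unit windows in the tract,
#:                    whatever their label, with interrupting units reported
#:                    alongside (FMR1: the CGG count includes AGG positions,
#:                    which are also listed as interruptions).
COUNTING_MODES = ("longest_run", "tract_total")


@dataclass(frozen=True)
class TargetDesign:
    """Capture geometry and counting rules for one repeat locus."""

    name: str
    upstream_site: str
    downstream_site: str
    l1_expected: tuple[int, ...]
    l2_expected: int
    primary_unit: str
    secondary_units: tuple[str, ...] = ()
    counting_mode: str = "longest_run"
    length_tolerance: float = 0.10
    max_site_edits: int = 2
    #: Fixed sequence between the primary and first secondary repeat block
    #: (HTT: the CAACAGCCGCCA junction between the CAG and CCG tracts).
    linker: str = ""

    def __post_init__(self):
        object.__setattr__(self, "l1_expected", tuple(int(v) for v in self.l1_expected))
        object.__setattr__(self, "secondary_units", tuple(self.secondary_units))
        self._validate()

    def _validate(self) -> None:
        def bad(fieldname: str, msg: str):
            return ValidationError(f"design {self.name!r}, field {fieldname!r}: {msg}")

        if not self.name:
            raise ValidationError("design name must be non-empty")
        for fieldname in ("upstream_site", "downstream_site"):
            site = getattr(self, fieldname)
            if not site or set(site) - _BASES:
                raise bad(fieldname, "must be a non-empty string over A/C/G/T")
        if not self.l1_expected or any(v <= 0 for v in self.l1_expected):
            raise bad("l1_expected", "requires at least one positive integer length")
        if self.l2_expected <= 0:
            raise bad("l2_expected", "must be a positive integer")
        units = (self.primary_unit,) + self.secondary_units
        for u in units:
            if not u or set(u) - _BASES:
                raise bad("primary_unit/secondary_units",
                          f"unit {u!r} must be non-empty over A/C/G/T")
        if len({len(u) for u in units}) != 1:
            raise bad("secondary_units", "all units must share one length")
        if len(set(units)) != len(units):
            raise bad("secondary_units", "units must be pairwise distinct")
        if not 0.0 < self.length_tolerance < 1.0:
            raise bad("length_tolerance", "must lie strictly between 0 and 1")
        if self.max_site_edits < 0:
            raise bad("max_site_edits", "must be >= 0")
        if self.counting_mode not in COUNTING_MODES:
            raise bad("counting_mode", f"must be one of {COUNTING_MODES}")
        if self.linker and set(self.linker) - _BASES:
            raise bad("linker", "must be over A/C/G/T")

    # -- derived views ----------------------------------------------------

    @property
    def units(self) -> tuple[str, ...]:
        """Primary unit first, then secondary units in declared order."""
        return (self.primary_unit,) + self.secondary_units

    @property
    def unit_length(self) -> int:
        return len(self.primary_unit)

    def capture_span(self, repeat_count: int, which_l1: int = 0) -> int:
        """Design-level capture span in bp for a given primary repeat count.

        This is the fragmentation-site-to-Cas9-cut arithmetic used when a
        capture design is drawn up: ``l1 + repeat_count * unit_length + l2``.
        """
        return capture_span(self, repeat_count, which_l1)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "upstream_site": self.upstream_site,
            "downstream_site": self.downstream_site,
            "l1_expected": list(self.l1_expected),
            "l2_expected": self.l2_expected,
            "primary_unit": self.primary_unit,
            "secondary_units": list(self.secondary_units),
            "counting_mode": self.counting_mode,
            "length_tolerance": self.length_tolerance,
            "max_site_edits": self.max_site_edits,
            "linker": self.linker,
        }

    def with_overrides(self, **kwargs) -> "TargetDesign":
        return replace(self, **kwargs)


def capture_span(design: TargetDesign, repeat_count: int, which_l1: int = 0) -> int:
    """``l1_expected[which_l1] + repeat_count * len(primary_unit) + l2_expected``.

    For the HTT design (l1 = 913, l2 = 155) a reference CAG count of 19 gives
    the 1125-bp capture design.  Strictly increasing in ``repeat_count`` with
    slope ``len(primary_unit)``.
    """
    if repeat_count < 0:
        raise ValueError("repeat_count must be >= 0")
    return (design.l1_expected[which_l1]
            + repeat_count * design.unit_length
            + design.l2_expected)


# ---------------------------------------------------------------------------
# Shipped designs
# ---------------------------------------------------------------------------

#: HTT geometry and recognition sites are the published capture design:
#: 14-bp anchors CCCTCAAGTCCTTC / CCTCCTCAGCTTCC, BamHI site 913 bp upstream
#: of the CAG repeat (2649 bp via the alternative BamHI site when rs2857935
#: destroys the proximal one), Cas9 cut 155 bp downstream.  The CAG and CCG
#: tracts are separated by the fixed CAACAGCCGCCA junction and counted as
#: separate longest pure runs.
_HTT = TargetDesign(
    name="HTT",
    upstream_site="CCCTCAAGTCCTTC",
    downstream_site="CCTCCTCAGCTTCC",
    l1_expected=(913, 2649),
    l2_expected=155,
    primary_unit="CAG",
    secondary_units=("CCG",),
    counting_mode="longest_run",
    linker="CAACAGCCGCCA",
)

# The genomic flank sequences of the three multiplexed loci below are not
# part of the published main text; the shipped anchors are SYNTHETIC
# placeholder 14-mers (adequate for simulation and testing) and the arm
# lengths are representative ~1-kb capture geometries.  For real data,
# override them with the true flanks via a design config.
_FMR1 = TargetDesign(
    name="FMR1",
    upstream_site="AGCTGACGGTACTC",   # synthetic placeholder anchor
    downstream_site="TCGGATCCAGTGCA",  # synthetic placeholder anchor
    l1_expected=(600,),
    l2_expected=400,
    primary_unit="CGG",
    secondary_units=("AGG",),
    counting_mode="tract_total",
)

_ATXN10 = TargetDesign(
    name="ATXN10",
    upstream_site="GATCCTGAACGTAG",   # synthetic placeholder anchor
    downstream_site="CCATGGTTGACTCA",  # synthetic placeholder anchor
    l1_expected=(500,),
    l2_expected=480,
    primary_unit="ATTCT",
    counting_mode="tract_total",
)

_C9ORF72 = TargetDesign(
    name="C9orf72",
    upstream_site="TGCAACGGATTCAG",   # synthetic placeholder anchor
    downstream_site="ACGGTCATGCAGTT",  # synthetic placeholder anchor
    l1_expected=(450,),
    l2_expected=420,
    primary_unit="GGGGCC",
    counting_mode="tract_total",
)

DEFAULT_DESIGNS: tuple[TargetDesign, ...] = (_HTT, _FMR1, _ATXN10, _C9ORF72)

_REQUIRED_FIELDS = ("name", "upstream_site", "downstream_site",
                    "l1_expected", "l2_expected", "primary_unit")
_OPTIONAL_FIELDS = ("secondary_units", "counting_mode", "length_tolerance",
                    "max_site_edits", "linker")


def get_design(name: str, designs: Sequence[TargetDesign] | None = None) -> TargetDesign:
    """Look up a design by (case-insensitive) name."""
    pool = designs if designs is not None else DEFAULT_DESIGNS
    for d in pool:
        if d.name.lower() == name.lower():
            return d
    raise ConfigError(
        f"unknown design {name!r}; available: {', '.join(d.name for d in pool)}")


def _design_from_record(record: Mapping) -> TargetDesign:
    if not isinstance(record, Mapping):
        raise ConfigError(f"design record must be a mapping, got {type(record).__name__}")
    missing = [f for f in _REQUIRED_FIELDS if f not in record]
    if missing:
        name = record.get("name", "<unnamed>")
        raise ConfigError(f"design {name!r}: missing required field(s) {missing}")
    unknown = set(record) - set(_REQUIRED_FIELDS) - set(_OPTIONAL_FIELDS)
    if unknown:
        raise ConfigError(f"design {record['name']!r}: unknown field(s) {sorted(unknown)}")
    kwargs = dict(record)
    l1 = kwargs["l1_expected"]
    if isinstance(l1, (int, float)):
        l1 = [l1]
    try:
        kwargs["l1_expected"] = tuple(int(v) for v in l1)
    except (TypeError, ValueError) as exc:
        raise ConfigError(
            f"design {record['name']!r}, field 'l1_expected': {exc}") from None
    if "secondary_units" in kwargs:
        kwargs["secondary_units"] = tuple(kwargs["secondary_units"])
    return TargetDesign(**kwargs)


def load_designs(config_source=None) -> list[TargetDesign]:
    """Load and validate target designs.

    ``config_source`` may be ``None`` (return the shipped defaults), a path
    to a YAML/JSON document, a YAML/JSON string, a mapping with a ``designs``
    key, a single design record, or a list of records.  Defaults apply for
    any optional field a record omits (e.g. ``length_tolerance`` 0.10,
    ``max_site_edits`` 2).
    """
    if config_source is None:
        return list(DEFAULT_DESIGNS)
    doc = config_source
    if isinstance(doc, (str, Path)):
        p = Path(doc)
        try:
            is_file = p.is_file()
        except OSError:  # e.g. an inline document too long for a file name
            is_file = False
        text = p.read_text() if is_file else str(doc)
        try:
            doc = yaml.safe_load(text)
        except yaml.YAMLError as exc:
            raise ConfigError(f"malformed design config: {exc}") from exc
    if isinstance(doc, Mapping) and "designs" in doc:
        doc = doc["designs"]
    if isinstance(doc, Mapping):
        doc = [doc]
    if not isinstance(doc, Iterable):
        raise ConfigError("design config must be a record or list of records")
    designs = [_design_from_record(rec) for rec in doc]
    if not designs:
        raise ConfigError("design config contains no records")
    names = [d.name for d in designs]
    if len(set(names)) != len(names):
        raise ConfigError(f"duplicate design names in config: {names}")
    return designs


def dump_designs(designs: Sequence[TargetDesign]) -> str:
    """Serialize designs to a YAML document that round-trips via load_designs."""
    return yaml.safe_dump({"designs": [d.to_dict() for d in designs]},
                          sort_keys=False)
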