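"""Sequence input/output: CCS reads from FASTA/FASTQ (plain or gzipped).

Format and compression are sniffed from content, never from file suffixes,
so e.g. a gzipped FASTQ named ``reads.txt`` still loads.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

from .errors import InputError

log = logging.getLogger("repeatgate")

_READ_ALPHABET = frozenset("ACGTN")


@dataclass
class CcsRead:
    """One circular-consensus read: id, sequence, optional per-base qualities.

    Sequences are normalised to upper case; the alphabet is A/C/G/T/N.
    """

    read_id: str
    sequence: str
    qualities: list[int] | None = None

    def __post_init__(self):
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise InputError(f"read {self.read_id!r}: empty sequence")
        bad = set(self.sequence) - _READ_ALPHABET
        if bad:
            raise InputError(
                f"read {self.read_id!r}: invalid characters {sorted(bad)}")
        if self.qualities is not None and len(self.qualities) != len(self.sequence):
            raise InputError(
                f"read {self.read_id!r}: quality length {len(self.qualities)} "
                f"!= sequence length {len(self.sequence)}")

    def __len__(self) -> int:
        return len(self.sequence)


def _open_text(path: Path):
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _sniff_format(handle) -> str | None:
    pos = handle.tell()
    first = ""
    for line in handle:
        if line.strip():
            first = line.lstrip()[0]
            break
    handle.seek(pos)
    if not first:
        return None
    if first == ">":
        return "fasta"
    if first == "@":
        return "fastq"
    raise InputError(f"unrecognized sequence format (first record starts with {first!r})")


def read_reads(path) -> list[CcsRead]:
    """Load all CCS reads from a FASTA or FASTQ file (optionally gzipped).

    FASTQ per-base qualities are kept.  An empty file yields an empty list
    with a warning; a malformed record raises :class:`InputError`.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"input file not found: {path}")
    reads: list[CcsRead] = []
    with _open_text(path) as handle:
        fmt = _sniff_format(handle)
        if fmt is None:
            log.warning("input file %s is empty", path)
            return []
        try:
            for rec in SeqIO.parse(handle, fmt):
                quals = None
                if fmt == "fastq":
                    quals = list(rec.letter_annotations["phred_quality"])
                reads.append(CcsRead(rec.id, str(rec.seq), quals))
        except ValueError as exc:
            raise InputError(
                f"malformed {fmt.upper()} record in {path} "
                f"(after {len(reads)} parsed reads): {exc}") from exc
    if not reads:
        log.warning("no sequence records found in %s", path)
    return reads


def write_fasta(reads: Iterable[CcsRead], path, width: int = 80) -> None:
    """Write reads as plain FASTA, deterministically (fixed line width)."""
    path = Path(path)
    with open(path, "wt") as out:
        for read in reads:
            out.write(f">{read.read_id}\n")
            seq = read.sequence
            for i in range(0, len(seq), width):
                out.write(seq[i:i + width] + "\n")


def write_tsv(frame, path) -> None:
    """Write a pandas DataFrame as a plain TSV (the bit-exact test surface)."""
    frame.to_csv(path, sep="\t", index=False)
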