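"""Sequence file I/O and the catalog record-naming codec.

Readers and writers for FASTA and FASTQ (Phred+33, transparently gzipped),
plus the codec that packs a catalog entry's provenance — domain type,
sequential index, recognition domain, source record, start and length —
into a single FASTA record id and unpacks it again losslessly.
"""

from __future__ import annotations

import gzip
import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

__all__ = [
    "SeqRecord",
    "CatalogEntryName",
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "write_fastq",
    "encode_entry_name",
    "decode_entry_name",
]


@dataclass
class SeqRecord:
    """A sequence with an id, free-text description and optional qualities.

    ``qualities`` are integer Phred scores, one per base; ``None`` for
    FASTA-derived records.
    """

    id: str
    sequence: str
    description: str = ""
    qualities: list[int] | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: empty sequence")
        if self.qualities is not None and len(self.qualities) != len(self.sequence):
            raise ValueError(
                f"record {self.id!r}: quality length {len(self.qualities)} "
                f"!= sequence length {len(self.sequence)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path: str | Path) -> list[SeqRecord]:
    """Read a FASTA file, accepting wrapped and unwrapped sequence lines.

    An empty file yields an empty list with a warning; a file whose first
    non-blank character is not ``>`` is a format error.
    """
    records: list[SeqRecord] = []
    header: str | None = None
    desc = ""
    chunks: list[str] = []
    lineno = 0
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(">"):
                if header is not None:
                    records.append(SeqRecord(header, "".join(chunks), desc))
                fields = line[1:].split(None, 1)
                if not fields:
                    raise ValueError(f"{path}: malformed FASTA header at line {lineno}")
                header = fields[0]
                desc = fields[1] if len(fields) > 1 else ""
                chunks = []
            else:
                if header is None:
                    raise ValueError(
                        f"{path}: expected '>' header, got sequence data at line {lineno}"
                    )
                chunks.append(line.strip())
    if header is not None:
        records.append(SeqRecord(header, "".join(chunks), desc))
    if not records:
        warnings.warn(f"{path}: no FASTA records found", stacklevel=2)
    return records


def write_fasta(records: Iterable[SeqRecord], path: str | Path, width: int = 70) -> None:
    with _open_text(path, "wt") as fh:
        for rec in records:
            head = f">{rec.id}"
            if rec.description:
                head += f" {rec.description}"
            fh.write(head + "\n")
            seq = rec.sequence
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def iter_fastq(path: str | Path) -> Iterator[SeqRecord]:
    """Stream 4-line FASTQ records (Phred+33); gzip handled transparently."""
    with _open_text(path) as fh:
        while True:
            head = fh.readline()
            if not head:
                return
            head = head.rstrip("\n")
            if not head.startswith("@"):
                raise ValueError(f"{path}: expected '@' header, got {head[:30]!r}")
            seq = fh.readline().rstrip("\n")
            plus = fh.readline()
            qual = fh.readline().rstrip("\n")
            if not plus.startswith("+"):
                raise ValueError(f"{path}: missing '+' separator for {head[1:]!r}")
            fields = head[1:].split(None, 1)
            rid = fields[0]
            desc = fields[1] if len(fields) > 1 else ""
            if len(qual) != len(seq):
                raise ValueError(
                    f"{path}: record {rid!r}: quality length {len(qual)} "
                    f"!= sequence length {len(seq)}"
                )
            quals = [ord(c) - 33 for c in qual]
            yield SeqRecord(rid, seq, desc, quals)


def read_fastq(path: str | Path) -> list[SeqRecord]:
    return list(iter_fastq(path))


def write_fastq(records: Iterable[SeqRecord], path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        for rec in records:
            if rec.qualities is None:
                raise ValueError(f"record {rec.id!r} has no qualities; cannot write FASTQ")
            head = f"@{rec.id}"
            if rec.description:
                head += f" {rec.description}"
            qual = "".join(chr(q + 33) for q in rec.qualities)
            fh.write(f"{head}\n{rec.sequence}\n+\n{qual}\n")


# --- catalog entry name codec -------------------------------------------------

_SUFFIX_DELIM = "|"


@dataclass(frozen=True)
class CatalogEntryName:
    """Structured name of one catalog entry.

    Encodes as ``<DOMAIN>_U<k>|<recognition>|<source>|<start>|<length>``
    with a 1-based inclusive start (the internal convention everywhere else
    is 0-based half-open; the codec is the only place the shift occurs).
    """

    domain_type: str
    unique_index: int
    recognition_domain: str
    source_id: str
    start: int  # 1-based inclusive
    length: int  # nt

    def __post_init__(self) -> None:
        if self.unique_index < 1:
            raise ValueError("unique_index must be >= 1")
        if self.length <= 0:
            raise ValueError("length must be > 0")
        if self.start < 1:
            raise ValueError("start must be >= 1 (1-based)")
        for label in (self.domain_type, self.recognition_domain, self.source_id):
            if _SUFFIX_DELIM in label:
                raise ValueError(f"field {label!r} contains the reserved delimiter")

    @property
    def code(self) -> str:
        """The short unique code, e.g. ``GAG_U21``."""
        return f"{self.domain_type}_U{self.unique_index}"


def encode_entry_name(name: CatalogEntryName) -> str:
    return _SUFFIX_DELIM.join(
        [
            name.code,
            name.recognition_domain,
            name.source_id,
            str(name.start),
            str(name.length),
        ]
    )


def decode_entry_name(encoded: str) -> CatalogEntryName:
    parts = encoded.split(_SUFFIX_DELIM)
    if len(parts) != 5:
        raise ValueError(
            f"cannot decode entry name {encoded!r}: expected 5 pipe-delimited "
            f"fields, got {len(parts)}"
        )
    code, recognition, source, start_s, length_s = parts
    dom, _, idx_s = code.rpartition("_U")
    if not dom or not idx_s.isdigit():
        raise ValueError(f"cannot decode entry code {code!r}: expected '<DOMAIN>_U<int>'")
    return CatalogEntryName(
        domain_type=dom,
        unique_index=int(idx_s),
        recognition_domain=recognition,
        source_id=source,
        start=int(start_s),
        length=int(length_s),
    )
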