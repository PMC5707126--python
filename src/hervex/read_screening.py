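"""Quality filtering and host subtraction.

Reads surviving the mean-Phred / ambiguous-base filter are "HQ reads"; HQ
reads that align end-to-end to the host genome or transcript set (either
strand, bounded substitutions) are removed, leaving "screened reads". The
HQ count is the denominator used downstream for hit-rate normalization.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .seq_io import SeqRecord
from .synthetic_data import revcomp

__all__ = [
    "ScreeningConfig",
    "ScreeningSummary",
    "quality_filter",
    "host_subtract",
    "screen_reads",
]


@dataclass
class ScreeningConfig:
    min_mean_phred: float = 20.0
    max_n_bases: int = 2
    host_kmer_size: int = 14
    max_mismatches_host: int = 2

    def __post_init__(self) -> None:
        if self.min_mean_phred < 0 or self.max_n_bases < 0 or self.max_mismatches_host < 0:
            raise ValueError("thresholds must be non-negative")
        if self.host_kmer_size < 1:
            raise ValueError("k-mer size must be >= 1")


@dataclass
class ScreeningSummary:
    total_reads: int = 0
    hq_reads: int = 0
    host_removed: int = 0
    screened_reads: int = 0

    def validate(self) -> None:
        assert self.total_reads >= self.hq_reads >= self.screened_reads
        assert self.hq_reads - self.host_removed == self.screened_reads


def quality_filter(reads: Sequence[SeqRecord],
                   config: ScreeningConfig | None = None
                   ) -> tuple[list[SeqRecord], ScreeningSummary]:
    """Retain reads with mean Phred >= threshold and few ambiguous bases."""
    config = config or ScreeningConfig()
    kept = []
    summary = ScreeningSummary()
    for read in reads:
        summary.total_reads += 1
        if read.qualities is None:
            raise ValueError(
                f"read {read.id!r} has no quality scores; quality filtering "
                "requires FASTQ input (use host_subtract directly for FASTA)")
        mean_q = sum(read.qualities) / len(read.qualities)
        n_count = read.sequence.upper().count("N")
        if mean_q >= config.min_mean_phred and n_count <= config.max_n_bases:
            kept.append(read)
    summary.hq_reads = len(kept)
    return kept, summary


class HostIndex:
    """Exact k-mer index over host references for seeded end-to-end alignment."""

    def __init__(self, references: Iterable[SeqRecord], k: int):
        self.k = k
        self.seqs: list[str] = []
        self.index: dict[str, list[tuple[int, int]]] = {}
        for ref in references:
            ri = len(self.seqs)
            seq = ref.sequence.upper()
            self.seqs.append(seq)
            for i in range(len(seq) - k + 1):
                word = seq[i:i + k]
                if "N" in word:
                    continue
                self.index.setdefault(word, []).append((ri, i))

    def aligns(self, read: str, max_mismatches: int) -> bool:
        """True if the read aligns end-to-end with <= max_mismatches substitutions.

        Pigeonhole seeding: the read is cut into ``max_mismatches + 1``
        disjoint k-mers; any valid alignment leaves at least one exact.
        """
        read = read.upper()
        n_chunks = max_mismatches + 1
        if len(read) < self.k:
            return False
        for target in (read, revcomp(read)):
            offsets = [c * self.k for c in range(n_chunks)
                       if c * self.k + self.k <= len(target)]
            if not offsets:
                offsets = [0]
            seen: set[tuple[int, int]] = set()
            for off in offsets:
                for ri, pos in self.index.get(target[off:off + self.k], ()):
                    start = pos - off
                    if start < 0 or (ri, start) in seen:
                        continue
                    seen.add((ri, start))
                    seq = self.seqs[ri]
                    if start + len(target) > len(seq):
                        continue
                    mm = sum(a != b for a, b in zip(target, seq[start:start + len(target)]))
                    if mm <= max_mismatches:
                        return True
        return False


def host_subtract(hq_reads: Sequence[SeqRecord],
                  host_genome: Sequence[SeqRecord],
                  host_transcripts: Sequence[SeqRecord] = (),
                  config: ScreeningConfig | None = None,
                  summary: ScreeningSummary | None = None
                  ) -> tuple[list[SeqRecord], ScreeningSummary]:
    """Remove HQ reads aligning end-to-end to host genome or transcripts."""
    config = config or ScreeningConfig()
    refs = list(host_genome) + list(host_transcripts)
    if not refs:
        raise ValueError("host references must be non-empty")
    index = HostIndex(refs, config.host_kmer_size)
    summary = summary or ScreeningSummary(total_reads=len(hq_reads),
                                          hq_reads=len(hq_reads))
    kept = []
    removed = 0
    for read in hq_reads:
        if index.aligns(read.sequence, config.max_mismatches_host):
            removed += 1
        else:
            kept.append(read)
    summary.host_removed = removed
    summary.screened_reads = len(kept)
    summary.validate()
    return kept, summary


def screen_reads(reads: Sequence[SeqRecord],
                 host_genome: Sequence[SeqRecord],
                 host_transcripts: Sequence[SeqRecord] = (),
                 config: ScreeningConfig | None = None
                 ) -> tuple[list[SeqRecord], ScreeningSummary]:
    """quality_filter followed by host_subtract, sharing one summary."""
    config = config or ScreeningConfig()
    hq, summary = quality_filter(reads, config)
    return host_subtract(hq, host_genome, host_transcripts, config, summary)
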