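"""Build a retroviral gene catalog by translated homology search.

The genome is translated in all six frames, translations are split at stop
codons, and each segment sharing an exact amino-acid word with a domain
protein is locally aligned to it (BLOSUM62, affine gaps). Hits passing the
expect cutoff and the alignment-length/subject-length coverage rule become
named nucleotide catalog entries; overlapping same-domain, same-strand hits
are union-merged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import pandas as pd
from Bio.Align import PairwiseAligner, substitution_matrices

from .seq_io import CatalogEntryName, SeqRecord, encode_entry_name
from .synthetic_data import parse_protein_labels, revcomp

__all__ = [
    "TranslatedHit",
    "six_frame_translate",
    "translated_search",
    "coverage_filter",
    "build_catalog",
    "catalog_recall_precision",
]

_STANDARD_CODE = {}
_BASES = "TCAG"
_AMINO = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
for _i, (_b1, _b2, _b3) in enumerate(
        (b1, b2, b3) for b1 in _BASES for b2 in _BASES for b3 in _BASES):
    _STANDARD_CODE[_b1 + _b2 + _b3] = _AMINO[_i]

_IUPAC_NT = set("ACGTURYSWKMBDHVN")

# ungapped BLOSUM62 Karlin-Altschul parameters
_LAMBDA = 0.318
_K = 0.13


def _translate_codon(codon: str) -> str:
    codon = codon.upper().replace("U", "T")
    aa = _STANDARD_CODE.get(codon)
    if aa is not None:
        return aa
    for ch in codon:
        if ch not in _IUPAC_NT:
            raise ValueError(f"non-IUPAC nucleotide {ch!r} in codon {codon!r}")
    return "X"  # ambiguity codes


def translate(seq: str) -> str:
    if len(seq) < 3:
        return ""
    return "".join(_translate_codon(seq[i:i + 3])
                   for i in range(0, len(seq) - 2, 3))


def six_frame_translate(seq: str) -> list[tuple[str, int, str]]:
    """All six translations as (strand, frame, protein) tuples.

    Frames 0-2 on the forward strand and on the reverse complement; stop
    codons are rendered ``*``, ambiguity codes as ``X``.
    """
    if len(seq) < 3:
        raise ValueError("sequence must be >= 3 nt")
    out = []
    rc = revcomp(seq)
    for strand, s in (("+", seq), ("-", rc)):
        for frame in range(3):
            out.append((strand, frame, translate(s[frame:])))
    return out


@dataclass
class TranslatedHit:
    start: int  # 0-based half-open nt coordinates on the forward genome
    end: int
    strand: str
    frame: int
    protein_id: str
    domain_type: str
    recognition_domain: str
    aln_length_aa: int
    subject_length_aa: int
    score: float  # bits
    expect: float

    def __post_init__(self) -> None:
        if self.aln_length_aa <= 0:
            raise ValueError("alignment length must be > 0")
        if (self.end - self.start) % 3 != 0:
            raise ValueError("hit interval must be a whole number of codons")


def _make_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


def _split_segments(protein: str, min_len: int) -> list[tuple[int, str]]:
    """(offset_aa, segment) pieces of a frame translation between stops."""
    segments = []
    start = 0
    for i, aa in enumerate(protein + "*"):
        if aa == "*":
            if i - start >= min_len:
                segments.append((start, protein[start:i]))
            start = i + 1
    return segments


def translated_search(genome: str, proteins: Sequence[SeqRecord],
                      expect_cutoff: float = 0.1,
                      seed_word: int = 4,
                      min_segment_aa: int = 15) -> list[TranslatedHit]:
    """Six-frame local-alignment search of the genome against domain proteins.

    A segment/protein pair is aligned only if they share an exact
    ``seed_word``-mer; hits with expect <= ``expect_cutoff`` are reported
    with their nucleotide coordinates mapped back through frame and strand.
    """
    if not genome or not proteins:
        raise ValueError("genome and protein set must be non-empty")
    labels = parse_protein_labels(proteins)
    aligner = _make_aligner()
    # amino-acid search space: both strands, one residue per codon
    m_space = max(1, (2 * len(genome)) // 3)

    word_index: dict[str, set[int]] = {}
    for pi, prot in enumerate(proteins):
        for i in range(len(prot.sequence) - seed_word + 1):
            word_index.setdefault(prot.sequence[i:i + seed_word], set()).add(pi)

    hits: list[TranslatedHit] = []
    L = len(genome)
    for strand, frame, trans in six_frame_translate(genome):
        for offset, segment in _split_segments(trans, min_segment_aa):
            candidates: set[int] = set()
            for i in range(len(segment) - seed_word + 1):
                candidates |= word_index.get(segment[i:i + seed_word], set())
            for pi in candidates:
                prot = proteins[pi]
                aln = aligner.align(segment, prot.sequence)
                if len(aln) == 0:
                    continue
                best = aln[0]
                raw = best.score
                bits = (_LAMBDA * raw - math.log(_K)) / math.log(2.0)
                expect = m_space * len(prot.sequence) * math.pow(2.0, -bits)
                if expect > expect_cutoff:
                    continue
                tblocks = best.aligned[0]
                a = offset + int(tblocks[0][0])
                b = offset + int(tblocks[-1][1])
                if strand == "+":
                    start, end = frame + 3 * a, frame + 3 * b
                else:
                    start, end = L - (frame + 3 * b), L - (frame + 3 * a)
                dt, rec = labels[prot.id]
                hits.append(TranslatedHit(
                    start=start, end=end, strand=strand, frame=frame,
                    protein_id=prot.id, domain_type=dt, recognition_domain=rec,
                    aln_length_aa=int(best.length),
                    subject_length_aa=len(prot.sequence),
                    score=bits, expect=expect))
    return hits


def coverage_filter(hits: Sequence[TranslatedHit],
                    min_coverage: float = 0.5) -> list[TranslatedHit]:
    """Keep hits whose alignment spans >= ``min_coverage`` of the subject."""
    return [h for h in hits
            if h.aln_length_aa >= min_coverage * h.subject_length_aa]


def build_catalog(hits: Sequence[TranslatedHit], genome: str,
                  source_id: str = "host_genome"
                  ) -> tuple[list[SeqRecord], pd.DataFrame]:
    """Turn filtered hits into named nucleotide entries plus a TSV table.

    Overlapping hits of the same (domain type, strand) are union-merged;
    entries are numbered sequentially within each domain type in genomic
    order. Minus-strand entries carry the reverse-complemented sequence.
    """
    for h in hits:
        if h.start < 0 or h.end > len(genome):
            raise ValueError(f"hit {h.start}-{h.end} outside genome of {len(genome)} nt")

    groups: dict[tuple[str, str], list[TranslatedHit]] = {}
    for h in hits:
        groups.setdefault((h.domain_type, h.strand), []).append(h)

    merged: list[tuple[str, str, int, int, TranslatedHit]] = []
    for (dt, strand), hs in groups.items():
        hs = sorted(hs, key=lambda h: (h.start, h.end))
        cur_start, cur_end, cur_best = hs[0].start, hs[0].end, hs[0]
        for h in hs[1:]:
            if h.start < cur_end:  # overlap: extend the union
                cur_end = max(cur_end, h.end)
                if h.score > cur_best.score:
                    cur_best = h
            else:
                merged.append((dt, strand, cur_start, cur_end, cur_best))
                cur_start, cur_end, cur_best = h.start, h.end, h
        merged.append((dt, strand, cur_start, cur_end, cur_best))

    merged.sort(key=lambda t: (t[0], t[2], t[3]))
    counters: dict[str, int] = {}
    records: list[SeqRecord] = []
    rows = []
    for dt, strand, start, end, best in merged:
        counters[dt] = counters.get(dt, 0) + 1
        name = CatalogEntryName(
            domain_type=dt, unique_index=counters[dt],
            recognition_domain=best.recognition_domain,
            source_id=source_id, start=start + 1, length=end - start)
        seq = genome[start:end]
        if strand == "-":
            seq = revcomp(seq)
        records.append(SeqRecord(encode_entry_name(name), seq,
                                 description=f"strand={strand}"))
        rows.append({
            "code": name.code, "domain_type": dt,
            "recognition_domain": best.recognition_domain,
            "source_id": source_id, "start": start + 1,
            "length": end - start, "strand": strand,
        })
    return records, pd.DataFrame(rows)


def catalog_recall_precision(table: pd.DataFrame, loci,
                             min_overlap: float = 0.5) -> tuple[float, float]:
    """Recall/precision of catalog entries against planted ground-truth loci.

    A locus counts as recovered if an entry of the same domain type overlaps
    at least ``min_overlap`` of it; an entry is a true positive if it
    overlaps any same-type locus at all.
    """
    entries = [(r["domain_type"], int(r["start"]) - 1,
                int(r["start"]) - 1 + int(r["length"]))
               for _, r in table.iterrows()]
    recovered = 0
    for loc in loci:
        need = min_overlap * (loc.end - loc.start)
        for dt, s, e in entries:
            if dt == loc.domain_type and min(e, loc.end) - max(s, loc.start) >= need:
                recovered += 1
                break
    tp = 0
    for dt, s, e in entries:
        if any(l.domain_type == dt and min(e, l.end) > max(s, l.start) for l in loci):
            tp += 1
    recall = recovered / len(loci) if loci else 1.0
    precision = tp / len(entries) if entries else 1.0
    return recall, precision
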