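"""Seeded alignment of screened reads to a viral reference set.

Alignment is exact-word seeding (28 nt by default) with ungapped extension
under a running identity floor — a self-contained stand-in for a
large-word nucleotide BLAST. Hits are tabulated per taxon as viral hit
rates (distinct hit reads / HQ reads), log-displayed with a half-hit floor
for zero counts, and screened per case specimen against the control
distribution with a Bonferroni-corrected z-test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .group_stats import bonferroni, z_test_case_vs_controls
from .seq_io import SeqRecord
from .synthetic_data import revcomp

__all__ = [
    "ViralHit",
    "HitRateTable",
    "ViralIndex",
    "seed_and_extend",
    "search_reads",
    "tabulate_vhr",
    "log_hit_rates",
    "screen_overrepresented_taxa",
]


@dataclass
class ViralHit:
    read_id: str
    viral_record_id: str
    taxon: str
    seed_position: int  # position in the viral record
    extended_identity: float
    extended_length: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not 0.0 <= self.extended_identity <= 1.0:
            raise ValueError("identity must lie in [0, 1]")


@dataclass
class HitRateTable:
    specimens: list[str]
    taxa: list[str]
    vhr: np.ndarray  # specimens x taxa
    hq_denominators: list[int]

    def counts(self) -> np.ndarray:
        return np.rint(self.vhr * np.array(self.hq_denominators)[:, None]).astype(int)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.vhr, index=self.specimens, columns=self.taxa)


class ViralIndex:
    """Exact word index over both strands of the viral reference set."""

    def __init__(self, references: Sequence[SeqRecord], taxon_map: Mapping[str, str],
                 word_size: int = 28):
        self.word_size = word_size
        self.taxon_map = dict(taxon_map)
        self.records: list[tuple[str, str]] = []
        self.index: dict[str, list[tuple[int, int]]] = {}
        for ref in references:
            if ref.id not in self.taxon_map:
                raise KeyError(f"viral record {ref.id!r} has no taxon mapping")
            ri = len(self.records)
            seq = ref.sequence.upper()
            self.records.append((ref.id, seq))
            for i in range(len(seq) - word_size + 1):
                self.index.setdefault(seq[i:i + word_size], []).append((ri, i))


def _extend(read: str, ref: str, read_pos: int, ref_pos: int, word: int,
            min_identity: float) -> tuple[int, int, int]:
    """Ungapped extension both ways while cumulative identity holds.

    Returns (matches, length, ref_start) of the extended alignment.
    """
    matches = word
    length = word
    left_r, left_g = read_pos, ref_pos
    # extend left
    while left_r > 0 and left_g > 0:
        m = matches + (read[left_r - 1] == ref[left_g - 1])
        if m / (length + 1) < min_identity:
            break
        left_r -= 1
        left_g -= 1
        matches = m
        length += 1
    right_r, right_g = read_pos + word, ref_pos + word
    while right_r < len(read) and right_g < len(ref):
        m = matches + (read[right_r] == ref[right_g])
        if m / (length + 1) < min_identity:
            break
        right_r += 1
        right_g += 1
        matches = m
        length += 1
    return matches, length, left_g


def seed_and_extend(read: SeqRecord, index: ViralIndex,
                    min_identity: float = 0.9,
                    min_length: int = 40) -> list[ViralHit]:
    """All per-record best hits of one read against the indexed references."""
    w = index.word_size
    best: dict[str, ViralHit] = {}
    for strand, seq in (("+", read.sequence.upper()),
                        ("-", revcomp(read.sequence.upper()))):
        if len(seq) < w:
            continue
        for i in range(len(seq) - w + 1):
            for ri, pos in index.index.get(seq[i:i + w], ()):
                rec_id, ref = index.records[ri]
                matches, length, ref_start = _extend(
                    seq, ref, i, pos, w, min_identity)
                if length < min_length:
                    continue
                hit = ViralHit(
                    read_id=read.id, viral_record_id=rec_id,
                    taxon=index.taxon_map[rec_id], seed_position=ref_start,
                    extended_identity=matches / length,
                    extended_length=length, strand=strand)
                prev = best.get(rec_id)
                if prev is None or (hit.extended_identity * hit.extended_length
                                    > prev.extended_identity * prev.extended_length):
                    best[rec_id] = hit
    return list(best.values())


def search_reads(reads: Sequence[SeqRecord], index: ViralIndex,
                 min_identity: float = 0.9, min_length: int = 40) -> list[ViralHit]:
    hits: list[ViralHit] = []
    for read in reads:
        hits.extend(seed_and_extend(read, index, min_identity, min_length))
    return hits


def tabulate_vhr(hits_per_specimen: Mapping[str, Sequence[ViralHit]],
                 taxon_map: Mapping[str, str],
                 hq_counts: Mapping[str, int]) -> HitRateTable:
    """Distinct-read hit counts per (specimen, taxon), divided by HQ reads."""
    taxa = sorted(set(taxon_map.values()))
    specimens = list(hits_per_specimen)
    vhr = np.zeros((len(specimens), len(taxa)))
    tindex = {t: j for j, t in enumerate(taxa)}
    for i, spec in enumerate(specimens):
        seen: dict[str, set[str]] = {}
        for hit in hits_per_specimen[spec]:
            if hit.viral_record_id not in taxon_map:
                raise KeyError(f"viral record {hit.viral_record_id!r} unmapped")
            seen.setdefault(hit.taxon, set()).add(hit.read_id)
        hq = hq_counts[spec]
        for taxon, read_ids in seen.items():
            vhr[i, tindex[taxon]] = len(read_ids) / hq
    return HitRateTable(specimens, taxa, vhr, [hq_counts[s] for s in specimens])


def log_hit_rates(table: HitRateTable, base: float = 10.0) -> pd.DataFrame:
    """Log-transformed display matrix with a half-hit floor for zero counts."""
    out = np.empty_like(table.vhr)
    for i, hq in enumerate(table.hq_denominators):
        floor = math.log(0.5 / hq, base)
        for j, v in enumerate(table.vhr[i]):
            out[i, j] = math.log(v, base) if v > 0 else floor
    return pd.DataFrame(out, index=table.specimens, columns=table.taxa)


@dataclass
class TaxonScreenResult:
    retained: list[str]
    degenerate: list[str] = field(default_factory=list)
    min_corrected_p: dict[str, float] = field(default_factory=dict)


def screen_overrepresented_taxa(table: HitRateTable, design: pd.DataFrame,
                                alpha: float = 0.05,
                                control_group: str = "control"
                                ) -> TaxonScreenResult:
    """Retain taxa where any case specimen is significantly above controls.

    Per (case specimen, taxon): z against the control VHR distribution,
    two-sided p, Bonferroni family = n_case_specimens x n_taxa; a taxon is
    retained if any corrected p < alpha with the case value above the
    control mean. Zero control variance with a departing case value flags
    the taxon as degenerate (kept for manual review).
    """
    groups = dict(zip(design["specimen_id"].astype(str), design["group"].astype(str)))
    ctrl_idx = [i for i, s in enumerate(table.specimens)
                if groups.get(s) == control_group]
    case_idx = [i for i, s in enumerate(table.specimens)
                if groups.get(s) not in (control_group, None)]
    if len(ctrl_idx) < 2:
        raise ValueError("need >= 2 control specimens")
    m = len(case_idx) * len(table.taxa)
    retained: list[str] = []
    degenerate: list[str] = []
    min_p: dict[str, float] = {}
    for j, taxon in enumerate(table.taxa):
        controls = table.vhr[ctrl_idx, j]
        ctrl_mean = controls.mean()
        best_p = 1.0
        keep = False
        for i in case_idx:
            x = table.vhr[i, j]
            res = z_test_case_vs_controls(x, controls)
            if res.degenerate and x != ctrl_mean:
                if taxon not in degenerate:
                    degenerate.append(taxon)
                if x > ctrl_mean:
                    keep = True
                continue
            p_corr = bonferroni(res.p_value, m)
            best_p = min(best_p, p_corr)
            if p_corr < alpha and x > ctrl_mean:
                keep = True
        min_p[taxon] = best_p
        if keep:
            retained.append(taxon)
    return TaxonScreenResult(retained=retained, degenerate=degenerate,
                             min_corrected_p=min_p)
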