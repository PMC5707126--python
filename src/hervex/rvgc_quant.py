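"""Catalog quantification: dual-scheme read counting and FPKM reporting.

Reads are aligned end-to-end (substitutions only, either strand) to the
catalog entries. Two counting schemes are supported: best (each read
credits its single best entry, ties broken by smallest entry code) and
comprehensive (each reported alignment credits its entry). Counts are
scaled to FPKM x 1000 and compared between groups with Mann-Whitney plus
Benjamini-Hochberg adjustment computed within each domain type.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .group_stats import bh_fdr, mann_whitney_u, tukey_hsd
from .seq_io import SeqRecord, decode_entry_name
from .synthetic_data import revcomp

__all__ = [
    "RvgcAlignment",
    "CatalogIndex",
    "align_to_catalog",
    "count_best",
    "count_comprehensive",
    "fpkm",
    "group_compare",
]


@dataclass
class RvgcAlignment:
    read_id: str
    entry_code: str
    mismatches: int
    score: int  # -(mismatches)
    strand: str


class CatalogIndex:
    """Pigeonhole k-mer index over catalog entries for end-to-end alignment.

    With ``max_mismatches`` substitutions allowed, a read is cut into
    ``max_mismatches + 1`` disjoint seeds of length ``k``; every valid
    alignment leaves at least one seed exact, so seeded verification is
    complete whenever ``(max_mismatches + 1) * k <= read length``.
    """

    def __init__(self, catalog: Sequence[SeqRecord], k: int = 12):
        if not catalog:
            raise ValueError("catalog must be non-empty")
        self.k = k
        self.entries: list[tuple[str, str]] = []  # (code, sequence)
        self.lengths: dict[str, int] = {}
        self.index: dict[str, list[tuple[int, int]]] = {}
        for rec in catalog:
            code = decode_entry_name(rec.id).code
            ei = len(self.entries)
            seq = rec.sequence.upper()
            self.entries.append((code, seq))
            self.lengths[code] = len(seq)
            for i in range(len(seq) - k + 1):
                self.index.setdefault(seq[i:i + k], []).append((ei, i))


def _align_one(read: str, index: CatalogIndex,
               max_mismatches: int) -> dict[str, tuple[int, str]]:
    """Best (mismatches, strand) per entry for one read, end-to-end."""
    k = index.k
    n_chunks = max_mismatches + 1
    best: dict[str, tuple[int, str]] = {}
    for strand, seq in (("+", read), ("-", revcomp(read))):
        if len(seq) < k:
            continue
        offsets = [c * k for c in range(n_chunks) if c * k + k <= len(seq)]
        seen: set[tuple[int, int]] = set()
        for off in offsets:
            for ei, pos in index.index.get(seq[off:off + k], ()):
                start = pos - off
                if start < 0 or (ei, start) in seen:
                    continue
                seen.add((ei, start))
                code, entry_seq = index.entries[ei]
                if start + len(seq) > len(entry_seq):
                    continue
                mm = sum(a != b for a, b in zip(seq, entry_seq[start:start + len(seq)]))
                if mm <= max_mismatches:
                    prev = best.get(code)
                    if prev is None or mm < prev[0]:
                        best[code] = (mm, strand)
    return best


def align_to_catalog(reads: Sequence[SeqRecord], catalog: Sequence[SeqRecord],
                     max_mismatches: int = 3, k: int = 12) -> list[RvgcAlignment]:
    """All end-to-end alignments (best per read/entry pair) of every read."""
    index = catalog if isinstance(catalog, CatalogIndex) else CatalogIndex(catalog, k)
    out: list[RvgcAlignment] = []
    for read in reads:
        for code, (mm, strand) in sorted(_align_one(
                read.sequence.upper(), index, max_mismatches).items()):
            out.append(RvgcAlignment(read.id, code, mm, -mm, strand))
    return out


def count_best(alignments: Sequence[RvgcAlignment]) -> dict[str, int]:
    """Each read credits its single best-scoring entry (ties: smallest code)."""
    best: dict[str, tuple[int, str]] = {}
    for aln in alignments:
        prev = best.get(aln.read_id)
        key = (-aln.score, aln.entry_code)
        if prev is None or key < prev:
            best[aln.read_id] = key
    counts: dict[str, int] = {}
    for _, code in best.values():
        counts[code] = counts.get(code, 0) + 1
    return counts


def count_comprehensive(alignments: Sequence[RvgcAlignment]) -> dict[str, int]:
    """Every reported alignment credits its entry."""
    counts: dict[str, int] = {}
    for aln in alignments:
        counts[aln.entry_code] = counts.get(aln.entry_code, 0) + 1
    return counts


def fpkm(counts: Mapping[str, int], entry_lengths: Mapping[str, int],
         norm_mass: float, scale: float = 1000.0) -> dict[str, float]:
    """FPKM x ``scale`` per entry: count / ((len/1e3) * (norm_mass/1e6))."""
    if norm_mass <= 0:
        raise ValueError("norm_mass must be > 0")
    out = {}
    for code, length in entry_lengths.items():
        if length <= 0:
            raise ValueError(f"entry {code!r} has non-positive length")
        c = counts.get(code, 0)
        out[code] = scale * c / ((length / 1e3) * (norm_mass / 1e6))
    return out


def quantify_specimens(reads_per_specimen: Mapping[str, Sequence[SeqRecord]],
                       catalog: Sequence[SeqRecord],
                       scheme: str = "comprehensive",
                       max_mismatches: int = 3,
                       norm_mass_mode: str = "aligned",
                       hq_counts: Mapping[str, int] | None = None) -> pd.DataFrame:
    """FPKM x 1000 table (entries x specimens) under one counting scheme.

    ``norm_mass_mode`` selects the FPKM denominator: "aligned" uses the
    per-specimen total of fragments aligned to the catalog under the active
    scheme; "hq" uses the specimen's HQ read count.
    """
    if scheme not in ("best", "comprehensive"):
        raise ValueError("scheme must be 'best' or 'comprehensive'")
    index = CatalogIndex(catalog)
    lengths = index.lengths
    columns = {}
    for spec, reads in reads_per_specimen.items():
        alignments = align_to_catalog(reads, index, max_mismatches)
        counts = count_best(alignments) if scheme == "best" \
            else count_comprehensive(alignments)
        if norm_mass_mode == "hq":
            if hq_counts is None:
                raise ValueError("hq norm-mass mode requires hq_counts")
            norm = hq_counts[spec]
        else:
            norm = sum(counts.values())
        if norm == 0:
            columns[spec] = {code: 0.0 for code in lengths}
        else:
            columns[spec] = fpkm(counts, lengths, norm)
    frame = pd.DataFrame(columns)
    frame.index.name = "entry_code"
    return frame.sort_index()


def group_compare(expression: pd.DataFrame, design: pd.DataFrame,
                  entry_domains: Mapping[str, str],
                  case_group: str = "demyelination",
                  control_group: str = "control",
                  case_specimens: Sequence[str] | None = None,
                  test: str = "mann-whitney",
                  q_threshold: float = 0.05) -> pd.DataFrame:
    """Per-entry case/control comparison with domain-wise BH adjustment.

    ``expression`` is an entries x specimens FPKM table. ``case_specimens``
    optionally restricts the case group (e.g. a diagnosis subset). Returns a
    table with group means, ratio, p, q and a significance flag; q-values
    are computed within each domain type separately.
    """
    groups = dict(zip(design["specimen_id"].astype(str), design["group"].astype(str)))
    case_cols = [c for c in expression.columns if groups.get(c) == case_group]
    if case_specimens is not None:
        case_cols = [c for c in case_cols if c in set(case_specimens)]
    ctrl_cols = [c for c in expression.columns if groups.get(c) == control_group]
    if len(case_cols) < 3 or len(ctrl_cols) < 3:
        raise ValueError("need >= 3 specimens per group")

    rows = []
    for code, row in expression.iterrows():
        x = row[case_cols].to_numpy(dtype=float)
        y = row[ctrl_cols].to_numpy(dtype=float)
        case_mean, ctrl_mean = float(x.mean()), float(y.mean())
        uninformative = not (np.any(x) or np.any(y))
        if uninformative:
            p = 1.0
        elif test == "tukey":
            p = tukey_hsd(x, y)[(0, 1)].p_value
        else:
            p = mann_whitney_u(x, y).p_value
        ratio = case_mean / ctrl_mean if ctrl_mean > 0 else float("inf") \
            if case_mean > 0 else float("nan")
        rows.append({
            "entry_code": code,
            "domain_type": entry_domains.get(code, "UNK"),
            "case_mean": case_mean, "control_mean": ctrl_mean,
            "ratio": ratio, "p": p, "uninformative": uninformative,
        })
    result = pd.DataFrame(rows)
    result["q"] = np.nan
    for dt, sub in result.groupby("domain_type"):
        result.loc[sub.index, "q"] = bh_fdr(sub["p"].to_numpy())
    result["significant"] = result["q"] <= q_threshold
    return result.set_index("entry_code")
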