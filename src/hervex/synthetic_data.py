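"""Synthetic study generator with recorded ground truth.

Produces every input the pipeline consumes — a host genome with planted
ERV-like loci, a retroviral domain-protein set, a viral reference set with
one exogenous virus plus decoy taxa, a three-group design table, and
per-specimen FASTQ reads — while recording per-read provenance so that
parameter-recovery tests can compare estimates against truth.

Group effects are multiplicative on locus read probability: a locus of
domain type *d* is sampled with probability ``base * ratio_d`` in the
demyelination-like group and ``base`` elsewhere, so the configured ratio is
exactly the expected ratio of read fractions between groups.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .seq_io import SeqRecord, write_fasta, write_fastq

__all__ = [
    "SimulationConfig",
    "ErvLocus",
    "GroundTruth",
    "simulate_host_genome",
    "simulate_domain_proteins",
    "plant_erv_loci",
    "simulate_viral_refs",
    "make_design_table",
    "simulate_reads",
    "simulate_study",
    "simulate_transcripts",
    "mask_loci",
    "parse_protein_labels",
    "revcomp",
]

GROUPS = ("demyelination", "control", "OND")

DEFAULT_DOMAIN_TYPES = ("GAG", "POL", "RT", "INT", "ENV", "PRO", "CHR", "KRAB", "SCAN")

# multiplicative expression ratios in the demyelination-like group,
# spanning the 1.5-2.8 range of the reported per-entry ratios
DEFAULT_EFFECT_RATIOS = {
    "GAG": 2.5,
    "POL": 1.6,
    "RT": 1.7,
    "INT": 1.7,
    "ENV": 1.7,
    "PRO": 1.5,
    "CHR": 1.6,
    "KRAB": 1.8,
    "SCAN": 1.5,
}

_AA = "ACDEFGHIKLMNPQRSTVWY"

# standard codons per amino acid (no stops); uniform choice on back-translation
_CODONS = {
    "A": ["GCT", "GCC", "GCA", "GCG"],
    "C": ["TGT", "TGC"],
    "D": ["GAT", "GAC"],
    "E": ["GAA", "GAG"],
    "F": ["TTT", "TTC"],
    "G": ["GGT", "GGC", "GGA", "GGG"],
    "H": ["CAT", "CAC"],
    "I": ["ATT", "ATC", "ATA"],
    "K": ["AAA", "AAG"],
    "L": ["TTA", "TTG", "CTT", "CTC", "CTA", "CTG"],
    "M": ["ATG"],
    "N": ["AAT", "AAC"],
    "P": ["CCT", "CCC", "CCA", "CCG"],
    "Q": ["CAA", "CAG"],
    "R": ["CGT", "CGC", "CGA", "CGG", "AGA", "AGG"],
    "S": ["TCT", "TCC", "TCA", "TCG", "AGT", "AGC"],
    "T": ["ACT", "ACC", "ACA", "ACG"],
    "V": ["GTT", "GTC", "GTA", "GTG"],
    "W": ["TGG"],
    "Y": ["TAT", "TAC"],
}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class SimulationConfig:
    seed: int = 0
    n_per_group: tuple[int, int, int] = (14, 14, 7)  # demyelination, control, OND
    read_length: int = 50
    reads_per_specimen: int = 100_000
    host_genome_length: int = 200_000
    n_loci_per_domain: int = 2
    domain_types: tuple[str, ...] = DEFAULT_DOMAIN_TYPES
    effect_ratios: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EFFECT_RATIOS))
    base_error_rate: float = 0.005
    exogenous_viral_fraction_ond: float = 1e-4
    aa_divergence: float = 0.2
    erv_base_fraction: float = 0.08  # aggregate locus read probability, control group
    low_quality_fraction: float = 0.02  # reads emitted uniformly at Phred 5
    proteins_per_domain: int = 2
    gc_content: float = 0.41
    n_decoy_taxa: int = 4
    exo_genome_length: int = 10_000
    n_transcripts: int = 20

    def __post_init__(self) -> None:
        for name in ("read_length", "reads_per_specimen", "host_genome_length",
                     "n_loci_per_domain", "proteins_per_domain"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if any(n <= 0 for n in self.n_per_group):
            raise ValueError("all group sizes must be > 0")
        if not self.domain_types:
            raise ValueError("need >= 1 domain type")
        for prob in (self.base_error_rate, self.exogenous_viral_fraction_ond,
                     self.aa_divergence, self.erv_base_fraction,
                     self.low_quality_fraction, self.gc_content):
            if not 0.0 <= prob <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if any(r <= 0 for r in self.effect_ratios.values()):
            raise ValueError("effect ratios must be > 0")

    def ratio_for(self, domain_type: str) -> float:
        return float(self.effect_ratios.get(domain_type, 1.0))


@dataclass
class ErvLocus:
    locus_id: str
    domain_type: str
    protein_id: str
    start: int  # 0-based half-open, in the modified genome
    end: int
    strand: str  # '+' or '-'


@dataclass
class GroundTruth:
    loci: list[ErvLocus] = field(default_factory=list)
    # specimen -> read_id -> provenance ("host" | locus_id | "exogenous")
    read_provenance: dict[str, dict[str, str]] = field(default_factory=dict)
    # group -> locus_id -> expected read fraction
    expected_fractions: dict[str, dict[str, float]] = field(default_factory=dict)

    def locus_by_id(self, locus_id: str) -> ErvLocus:
        for loc in self.loci:
            if loc.locus_id == locus_id:
                return loc
        raise KeyError(locus_id)


def _rng(config: SimulationConfig, tag: int) -> np.random.Generator:
    # independent, deterministic stream per operation
    return np.random.default_rng([config.seed, tag])


def simulate_host_genome(config: SimulationConfig) -> str:
    """Random host genome at the configured GC content."""
    if config.host_genome_length < 1000:
        raise ValueError("host genome must be >= 1000 nt to hold loci")
    rng = _rng(config, 1)
    gc = config.gc_content
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=config.host_genome_length, p=probs))


def simulate_domain_proteins(config: SimulationConfig) -> list[SeqRecord]:
    """Labeled domain proteins, ``proteins_per_domain`` per domain type.

    The description carries ``domain=<type> recognition=<name>``; the
    recognition names stand in for named reference domains.
    """
    rng = _rng(config, 2)
    records = []
    for dt in config.domain_types:
        for i in range(config.proteins_per_domain):
            length = int(rng.integers(80, 401))
            seq = "".join(rng.choice(list(_AA), size=length))
            rec_name = f"RV-{dt}{i + 1}"
            records.append(SeqRecord(
                id=f"{dt}_prot{i + 1}",
                sequence=seq,
                description=f"domain={dt} recognition={rec_name}",
            ))
    return records


def parse_protein_labels(records: Sequence[SeqRecord]) -> dict[str, tuple[str, str]]:
    """Map protein id -> (domain_type, recognition_domain) from descriptions."""
    out = {}
    for rec in records:
        fields = dict(part.split("=", 1) for part in rec.description.split()
                      if "=" in part)
        out[rec.id] = (fields.get("domain", "UNK"), fields.get("recognition", rec.id))
    return out


def _mutate_protein(seq: str, divergence: float, rng: np.random.Generator) -> str:
    out = list(seq)
    for i, aa in enumerate(out):
        if rng.random() < divergence:
            choices = _AA.replace(aa, "")
            out[i] = choices[int(rng.integers(len(choices)))]
    return "".join(out)


def _back_translate(protein: str, rng: np.random.Generator) -> str:
    return "".join(_CODONS[aa][int(rng.integers(len(_CODONS[aa])))] for aa in protein)


def plant_erv_loci(genome: str, proteins: Sequence[SeqRecord],
                   config: SimulationConfig) -> tuple[str, GroundTruth]:
    """Insert diverged back-translations of domain proteins into the genome.

    Each locus is a domain protein mutated at ``aa_divergence``,
    back-translated with uniform codon choice, and spliced into the genome
    at a recorded non-overlapping position on a random strand. Coordinates
    in the returned :class:`GroundTruth` refer to the modified genome.
    """
    rng = _rng(config, 3)
    labels = parse_protein_labels(proteins)
    by_domain: dict[str, list[SeqRecord]] = {}
    for rec in proteins:
        by_domain.setdefault(labels[rec.id][0], []).append(rec)

    inserts: list[tuple[int, str, str, str, str]] = []  # (pos, seq, dt, prot, strand)
    total_insert = 0
    for dt in config.domain_types:
        pool = by_domain.get(dt, [])
        if not pool:
            raise ValueError(f"no proteins for domain type {dt!r}")
        for j in range(config.n_loci_per_domain):
            prot = pool[j % len(pool)]
            mutated = _mutate_protein(prot.sequence, config.aa_divergence, rng)
            nt = _back_translate(mutated, rng)
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "-":
                nt = revcomp(nt)
            inserts.append((0, nt, dt, prot.id, strand))
            total_insert += len(nt)

    if total_insert + 1000 > len(genome):
        raise ValueError(
            f"genome too small to plant loci: need > {total_insert + 1000} nt, "
            f"have {len(genome)}")

    # choose non-overlapping insertion points in the background genome
    n = len(inserts)
    while True:
        points = sorted(int(p) for p in rng.integers(0, len(genome), size=n))
        if all(points[i + 1] - points[i] >= 1 for i in range(n - 1)):
            break
    inserts = [(points[i], *inserts[i][1:]) for i in range(n)]

    gt = GroundTruth()
    pieces = []
    cursor = 0
    offset = 0
    counter: dict[str, int] = {}
    for pos, nt, dt, prot_id, strand in inserts:
        pieces.append(genome[cursor:pos])
        start = pos + offset
        counter[dt] = counter.get(dt, 0) + 1
        gt.loci.append(ErvLocus(
            locus_id=f"locus_{dt}_{counter[dt]}",
            domain_type=dt, protein_id=prot_id,
            start=start, end=start + len(nt), strand=strand))
        pieces.append(nt)
        offset += len(nt)
        cursor = pos
    pieces.append(genome[cursor:])
    modified = "".join(pieces)

    # expected per-locus read fractions per group
    n_loci = len(gt.loci)
    base = config.erv_base_fraction / n_loci
    for group in GROUPS:
        fractions = {}
        for loc in gt.loci:
            r = config.ratio_for(loc.domain_type) if group == "demyelination" else 1.0
            fractions[loc.locus_id] = base * r
        gt.expected_fractions[group] = fractions
    return modified, gt


def mask_loci(genome: str, gt: GroundTruth) -> str:
    """Replace every planted locus with N — the host screening reference."""
    arr = list(genome)
    for loc in gt.loci:
        arr[loc.start:loc.end] = "N" * (loc.end - loc.start)
    return "".join(arr)


def simulate_viral_refs(config: SimulationConfig) -> tuple[list[SeqRecord], dict[str, str]]:
    """Viral reference set: one exogenous virus plus random decoy taxa.

    Returns (records, record_id -> taxon map). The exogenous virus carries
    taxon label ``exovirus``.
    """
    rng = _rng(config, 4)
    records = []
    taxa = {}
    exo = "".join(rng.choice(list("ACGT"), size=config.exo_genome_length))
    records.append(SeqRecord("exo_1", exo, "taxon=exovirus"))
    taxa["exo_1"] = "exovirus"
    for i in range(config.n_decoy_taxa):
        seq = "".join(rng.choice(list("ACGT"), size=config.exo_genome_length))
        rid = f"decoy_{i + 1}"
        records.append(SeqRecord(rid, seq, f"taxon=decoy{i + 1}"))
        taxa[rid] = f"decoy{i + 1}"
    return records, taxa


def make_design_table(config: SimulationConfig) -> pd.DataFrame:
    """Specimen/group design table with plausible demographic columns."""
    rng = _rng(config, 5)
    rows = []
    prefixes = {"demyelination": "DEM", "control": "CTL", "OND": "OND"}
    for group, n in zip(GROUPS, config.n_per_group):
        for i in range(n):
            rows.append({
                "specimen_id": f"{prefixes[group]}{i + 1:02d}",
                "group": group,
                "age": int(rng.integers(37, 94)),
                "sex": "F" if rng.random() < 0.5 else "M",
                "pmi_hours": int(rng.integers(2, 27)),
            })
    return pd.DataFrame(rows)


def simulate_transcripts(genome: str, gt: GroundTruth,
                         config: SimulationConfig) -> list[SeqRecord]:
    """Host transcript stand-ins: random non-locus genome intervals."""
    rng = _rng(config, 6)
    locus_ivs = [(l.start, l.end) for l in gt.loci]
    records = []
    tries = 0
    while len(records) < config.n_transcripts and tries < 10_000:
        tries += 1
        length = int(rng.integers(500, 3001))
        start = int(rng.integers(0, max(1, len(genome) - length)))
        if any(start < e and start + length > s for s, e in locus_ivs):
            continue
        records.append(SeqRecord(f"tx_{len(records) + 1}", genome[start:start + length]))
    return records


def _apply_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    out = list(seq)
    n_err = rng.binomial(len(seq), rate)
    if n_err == 0:
        return seq
    for pos in rng.choice(len(seq), size=n_err, replace=False):
        choices = "ACGT".replace(out[pos], "") if out[pos] in "ACGT" else "ACGT"
        out[pos] = choices[int(rng.integers(len(choices)))]
    return "".join(out)


def simulate_reads(genome: str, gt: GroundTruth, design: pd.DataFrame,
                   config: SimulationConfig,
                   exogenous_genome: str | None = None) -> dict[str, list[SeqRecord]]:
    """Per-specimen single-end reads with recorded provenance.

    Each read is drawn from host background (non-locus genome), one ERV
    locus (probability base x group ratio), or — in the OND group — the
    exogenous viral genome. Substitution errors at ``base_error_rate``;
    a ``low_quality_fraction`` of reads is emitted at uniform Phred 5 to
    exercise the quality filter, the rest at Phred 38.
    """
    unknown = set(design["group"]) - set(GROUPS)
    if unknown:
        raise ValueError(f"unknown group labels: {sorted(unknown)}")
    rl = config.read_length
    loci = gt.loci
    out: dict[str, list[SeqRecord]] = {}

    for spec_index, (_, row) in enumerate(design.iterrows()):
        spec = str(row["specimen_id"])
        group = str(row["group"])
        # per-specimen stream keyed by row position: stable across processes
        rng = np.random.default_rng([config.seed, 7, spec_index])
        locus_probs = np.array(
            [gt.expected_fractions[group][l.locus_id] for l in loci])
        exo_p = config.exogenous_viral_fraction_ond if group == "OND" else 0.0
        if exogenous_genome is None:
            exo_p = 0.0
        host_p = 1.0 - locus_probs.sum() - exo_p
        if host_p <= 0:
            raise ValueError("locus + exogenous probabilities exceed 1")
        probs = np.concatenate([[host_p], locus_probs, [exo_p]])
        sources = rng.choice(len(probs), size=config.reads_per_specimen, p=probs)

        reads: list[SeqRecord] = []
        prov: dict[str, str] = {}
        locus_ivs = [(l.start, l.end) for l in loci]
        for i, src in enumerate(sources):
            rid = f"{spec}_r{i:07d}"
            if src == 0:
                # host background: rejection-sample a non-locus window
                while True:
                    pos = int(rng.integers(0, len(genome) - rl + 1))
                    if not any(pos < e and pos + rl > s for s, e in locus_ivs):
                        break
                frag = genome[pos:pos + rl]
                prov[rid] = "host"
            elif src <= len(loci):
                loc = loci[src - 1]
                span = loc.end - loc.start
                pos = int(rng.integers(0, max(1, span - rl + 1)))
                frag = genome[loc.start + pos:loc.start + pos + rl]
                if len(frag) < rl:  # locus shorter than a read
                    frag = (frag + genome[loc.end:loc.end + rl])[:rl]
                prov[rid] = loc.locus_id
            else:
                pos = int(rng.integers(0, len(exogenous_genome) - rl + 1))
                frag = exogenous_genome[pos:pos + rl]
                prov[rid] = "exogenous"
            if rng.random() < 0.5:
                frag = revcomp(frag)
            frag = _apply_errors(frag, config.base_error_rate, rng)
            phred = 5 if rng.random() < config.low_quality_fraction else 38
            reads.append(SeqRecord(rid, frag, qualities=[phred] * rl))
        out[spec] = reads
        gt.read_provenance[spec] = prov
    return out


def ground_truth_to_json(gt: GroundTruth) -> str:
    return json.dumps({
        "loci": [asdict(l) for l in gt.loci],
        "expected_fractions": gt.expected_fractions,
        "read_provenance": gt.read_provenance,
    }, indent=None)


def simulate_study(config: SimulationConfig, outdir: str | Path) -> dict[str, Path]:
    """Generate and write the full synthetic study; returns output paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    background = simulate_host_genome(config)
    proteins = simulate_domain_proteins(config)
    genome, gt = plant_erv_loci(background, proteins, config)
    transcripts = simulate_transcripts(genome, gt, config)
    viral, taxa = simulate_viral_refs(config)
    design = make_design_table(config)
    reads = simulate_reads(genome, gt, design, config,
                           exogenous_genome=viral[0].sequence)

    paths = {
        "genome": outdir / "genome.fasta",
        "host_screen": outdir / "host_screen.fasta",
        "transcripts": outdir / "transcripts.fasta",
        "domains": outdir / "domains.fasta",
        "viral": outdir / "viral.fasta",
        "taxa": outdir / "taxa.tsv",
        "design": outdir / "design.tsv",
        "ground_truth": outdir / "ground_truth.json",
        "reads_dir": outdir / "reads",
    }
    write_fasta([SeqRecord("host_genome", genome)], paths["genome"])
    write_fasta([SeqRecord("host_genome", mask_loci(genome, gt))], paths["host_screen"])
    write_fasta(transcripts, paths["transcripts"])
    write_fasta(proteins, paths["domains"])
    write_fasta(viral, paths["viral"])
    pd.DataFrame(
        [{"record_id": k, "taxon": v} for k, v in taxa.items()]
    ).to_csv(paths["taxa"], sep="\t", index=False)
    design.to_csv(paths["design"], sep="\t", index=False)
    paths["ground_truth"].write_text(ground_truth_to_json(gt))
    paths["reads_dir"].mkdir(exist_ok=True)
    for spec, recs in reads.items():
        write_fastq(recs, paths["reads_dir"] / f"{spec}.fastq")
    return paths
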