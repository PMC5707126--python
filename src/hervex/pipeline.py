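"""End-to-end orchestration of the synthetic study.

One call runs simulation, screening, viral search, catalog construction,
quantification, domain discrimination and the group statistics, writing
plain-text outputs, a checksum manifest and a human-readable report.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import cohort
from .catalog_builder import build_catalog, coverage_filter, translated_search
from .domain_discrimination import (cluster_specimens, domain_hit_rates,
                                    log2_center, split_and_test)
from .read_screening import ScreeningConfig, screen_reads
from .rvgc_quant import (CatalogIndex, align_to_catalog, count_best,
                         count_comprehensive, fpkm, group_compare)
from .seq_io import SeqRecord
from .synthetic_data import (SimulationConfig, make_design_table, mask_loci,
                             plant_erv_loci, simulate_domain_proteins,
                             simulate_host_genome, simulate_reads,
                             simulate_transcripts, simulate_viral_refs)
from .viral_search import (ViralIndex, log_hit_rates,
                           screen_overrepresented_taxa, search_reads,
                           tabulate_vhr)

__all__ = ["PipelineConfig", "run_all"]

log = logging.getLogger("hervex")


@dataclass
class PipelineConfig:
    outdir: Path = Path("hervex_out")
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    screening: ScreeningConfig = field(default_factory=ScreeningConfig)
    expect_cutoff: float = 0.1
    min_coverage: float = 0.5
    viral_word_size: int = 28
    viral_min_identity: float = 0.9
    viral_min_length: int = 40
    max_mismatches: int = 3
    scheme: str = "comprehensive"
    grouping: str = "demyelination"  # or "ppms" to subset the case group
    run_viral_search: bool = True
    run_discrimination: bool = True

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        if self.scheme not in ("best", "comprehensive"):
            raise ValueError("scheme must be 'best' or 'comprehensive'")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(config: PipelineConfig) -> dict:
    """Run every stage on freshly simulated data; returns a result bundle."""
    out = config.outdir
    out.mkdir(parents=True, exist_ok=True)
    written: list[tuple[str, Path]] = []

    def save_frame(frame: pd.DataFrame, name: str, stage: str, **kw) -> None:
        path = out / name
        frame.to_csv(path, sep="\t", **kw)
        written.append((stage, path))

    # --- simulation -----------------------------------------------------
    sim = config.sim
    background = simulate_host_genome(sim)
    proteins = simulate_domain_proteins(sim)
    genome, gt = plant_erv_loci(background, proteins, sim)
    transcripts = simulate_transcripts(genome, gt, sim)
    viral_refs, taxon_map = simulate_viral_refs(sim)
    design = make_design_table(sim)
    reads = simulate_reads(genome, gt, design, sim,
                           exogenous_genome=viral_refs[0].sequence)
    save_frame(design, "design.tsv", "simulate", index=False)
    log.info("simulate: %d specimens, %d reads each, %d loci",
             len(reads), sim.reads_per_specimen, len(gt.loci))

    # --- screening ------------------------------------------------------
    host_screen = [SeqRecord("host_genome", mask_loci(genome, gt))]
    screened: dict[str, list[SeqRecord]] = {}
    hq_counts: dict[str, int] = {}
    summary_rows = []
    for spec, recs in reads.items():
        kept, summary = screen_reads(recs, host_screen, transcripts,
                                     config.screening)
        screened[spec] = kept
        hq_counts[spec] = summary.hq_reads
        summary_rows.append({"specimen_id": spec, **summary.__dict__})
    save_frame(pd.DataFrame(summary_rows), "screen_summary.tsv", "screen",
               index=False)
    log.info("screen: mean HQ %.0f, mean screened %.0f",
             pd.DataFrame(summary_rows)["hq_reads"].mean(),
             pd.DataFrame(summary_rows)["screened_reads"].mean())

    results: dict = {"design": design, "hq_counts": hq_counts,
                     "ground_truth": gt, "screen_summary": pd.DataFrame(summary_rows)}

    # --- viral search ---------------------------------------------------
    if config.run_viral_search:
        vindex = ViralIndex(viral_refs, taxon_map, config.viral_word_size)
        hits = {spec: search_reads(recs, vindex, config.viral_min_identity,
                                   config.viral_min_length)
                for spec, recs in screened.items()}
        vhr = tabulate_vhr(hits, taxon_map, hq_counts)
        screen_res = screen_overrepresented_taxa(vhr, design)
        save_frame(vhr.to_frame(), "vhr.tsv", "viral-screen",
                   index_label="specimen_id")
        save_frame(log_hit_rates(vhr), "loghits.tsv", "viral-screen",
                   index_label="specimen_id")
        results["vhr"] = vhr
        results["retained_taxa"] = screen_res.retained
        log.info("viral-screen: %d taxa retained", len(screen_res.retained))

    # --- catalog --------------------------------------------------------
    raw_hits = translated_search(genome, proteins, config.expect_cutoff)
    kept_hits = coverage_filter(raw_hits, config.min_coverage)
    catalog, catalog_table = build_catalog(kept_hits, genome)
    if not catalog:
        raise RuntimeError("catalog construction produced no entries")
    from .seq_io import write_fasta
    write_fasta(catalog, out / "catalog.fasta")
    written.append(("build-catalog", out / "catalog.fasta"))
    save_frame(catalog_table, "catalog.tsv", "build-catalog", index=False)
    results["catalog_table"] = catalog_table
    log.info("build-catalog: %d hits -> %d entries", len(raw_hits), len(catalog))

    # --- quantification -------------------------------------------------
    cindex = CatalogIndex(catalog)
    entry_domains = dict(zip(catalog_table["code"], catalog_table["domain_type"]))
    best_counts: dict[str, dict[str, int]] = {}
    comp_counts: dict[str, dict[str, int]] = {}
    for spec, recs in screened.items():
        alns = align_to_catalog(recs, cindex, config.max_mismatches)
        best_counts[spec] = count_best(alns)
        comp_counts[spec] = count_comprehensive(alns)
    counts = best_counts if config.scheme == "best" else comp_counts
    expression = pd.DataFrame({
        spec: fpkm(c, cindex.lengths, max(1, sum(c.values())))
        for spec, c in counts.items()})
    expression.index.name = "entry_code"
    expression = expression.sort_index()
    save_frame(expression, "expression.tsv", "quantify")

    case_specs = None
    if config.grouping == "ppms":
        # diagnosis subset of the case group when the design provides one
        if "diagnosis" in design.columns:
            case_specs = design.loc[design["diagnosis"] == "PPMS",
                                    "specimen_id"].astype(str).tolist()
    comparison = group_compare(expression, design, entry_domains,
                               case_specimens=case_specs)
    save_frame(comparison, "comparison.tsv", "quantify")
    results["expression"] = expression
    results["comparison"] = comparison
    log.info("quantify: %d entries, %d significant at q<=0.05",
             len(comparison), int(comparison["significant"].sum()))

    # --- domain discrimination ------------------------------------------
    if config.run_discrimination:
        rates = domain_hit_rates(comp_counts, entry_domains, hq_counts)
        profile = log2_center(rates, hq_counts=hq_counts)
        merges = cluster_specimens(profile)
        split = split_and_test(merges, profile.specimens, design)
        save_frame(pd.DataFrame(profile.values, index=profile.domain_types,
                                columns=profile.specimens),
                   "profile.tsv", "discriminate")
        (out / "dendrogram.json").write_text(json.dumps(
            {"specimens": profile.specimens, "merges": split.merges}))
        (out / "cluster_split.json").write_text(json.dumps({
            "left": split.left_members, "right": split.right_members,
            "contingency": split.contingency, "fisher_p": split.fisher.p_value}))
        written += [("discriminate", out / "dendrogram.json"),
                    ("discriminate", out / "cluster_split.json")]
        results["cluster_split"] = split
        log.info("discriminate: fisher p=%.4g on %s", split.fisher.p_value,
                 split.contingency)

    # --- report + manifest ----------------------------------------------
    report = _render_report(results, config)
    (out / "report.txt").write_text(report)
    written.append(("report", out / "report.txt"))
    manifest = pd.DataFrame(
        [{"stage": stage, "file": p.name, "sha256": _sha256(p)}
         for stage, p in written])
    manifest.to_csv(out / "manifest.tsv", sep="\t", index=False)
    results["manifest"] = manifest
    results["report"] = report
    return results


def _render_report(results: dict, config: PipelineConfig) -> str:
    lines = ["# Synthetic study report", ""]
    lines.append("## Group summary")
    design = results["design"]
    for group, sub in design.groupby("group"):
        hq = [results["hq_counts"][s] for s in sub["specimen_id"]]
        lines.append(f"- {group}: n={len(sub)}, mean HQ reads={sum(hq) / len(hq):.0f}")
    ref = cohort.summarize()
    lines.append("")
    lines.append("## Reference cohort (bundled design table)")
    for group, info in ref["groups"].items():
        lines.append(f"- {group}: n={info['n']}, "
                     f"mean HQ={info['mean_hq_reads_millions']} M")
    if "retained_taxa" in results:
        lines += ["", "## Viral hit-rate screen",
                  f"- retained taxa: {results['retained_taxa'] or 'none'}"]
    comp = results["comparison"]
    sig = comp[comp["significant"]]
    lines += ["", f"## Expression ({config.scheme} counting)",
              f"- entries tested: {len(comp)}",
              f"- significant at q<=0.05: {len(sig)}"]
    for code, row in sig.iterrows():
        lines.append(f"  - {code}: ratio={row['ratio']:.2f} p={row['p']:.2g} "
                     f"q={row['q']:.2g}")
    if "cluster_split" in results:
        split = results["cluster_split"]
        lines += ["", "## Domain discrimination",
                  f"- contingency {split.contingency}",
                  f"- two-tailed Fisher p = {split.fisher.p_value:.4g}"]
    return "\n".join(lines) + "\n"
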