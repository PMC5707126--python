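import pytest

from hervex.seq_io import SeqRecord
from hervex.synthetic_data import (SimulationConfig, make_design_table,
                                   mask_loci, plant_erv_loci,
                                   simulate_domain_proteins,
                                   simulate_host_genome, simulate_reads,
                                   simulate_transcripts, simulate_viral_refs)


@pytest.fixture(scope="session")
def tiny_config():
    return SimulationConfig(
        seed=11, host_genome_length=30_000, reads_per_specimen=2_000,
        n_per_group=(4, 4, 2), n_loci_per_domain=1,
        domain_types=("GAG", "ENV", "RT"), proteins_per_domain=1,
        exogenous_viral_fraction_ond=0.01)


@pytest.fixture(scope="session")
def tiny_study(tiny_config):
    """One small simulated study shared by read-level tests."""
    cfg = tiny_config
    background = simulate_host_genome(cfg)
    proteins = simulate_domain_proteins(cfg)
    genome, gt = plant_erv_loci(background, proteins, cfg)
    transcripts = simulate_transcripts(genome, gt, cfg)
    viral_refs, taxon_map = simulate_viral_refs(cfg)
    design = make_design_table(cfg)
    reads = simulate_reads(genome, gt, design, cfg,
                           exogenous_genome=viral_refs[0].sequence)
    return {
        "config": cfg, "genome": genome, "ground_truth": gt,
        "proteins": proteins, "transcripts": transcripts,
        "viral_refs": viral_refs, "taxon_map": taxon_map,
        "design": design, "reads": reads,
        "host_screen": [SeqRecord("host_genome", mask_loci(genome, gt))],
    }
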