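import numpy as np
import pytest

import spatialcite as sc
from spatialcite.demux import TranscriptReference, demux_fastq
from spatialcite.simulate import (
    default_gene_list,
    emit_fastq,
    make_reference_transcripts,
    make_tissue,
)

SIM_SEED = 7


@pytest.fixture(scope="session")
def design20():
    return sc.default_chip_design(n_rows=20, n_cols=20)


@pytest.fixture(scope="session")
def panel():
    return sc.small_panel()


@pytest.fixture(scope="session")
def gene_seqs():
    return make_reference_transcripts(default_gene_list(), seed=SIM_SEED)


@pytest.fixture(scope="session")
def clean_sim(design20, panel, gene_seqs, tmp_path_factory):
    """One zero-error simulated experiment shared across tests."""
    truth = make_tissue(
        3, (20, 20), 8.0, seed=SIM_SEED, protein_features=panel.names, error_rate=0.0
    )
    outdir = tmp_path_factory.mktemp("sim_clean")
    return emit_fastq(truth, design20, panel, gene_seqs, str(outdir), seed=SIM_SEED)


@pytest.fixture(scope="session")
def clean_demux(clean_sim, design20, panel, gene_seqs):
    """Demultiplexed matrices + summaries for the zero-error experiment."""
    ref = TranscriptReference(gene_seqs)
    prot, prot_summary, _ = demux_fastq(
        clean_sim.protein_r1, clean_sim.protein_r2, design20, "protein", panel=panel
    )
    rna, rna_summary, _ = demux_fastq(
        clean_sim.rna_r1, clean_sim.rna_r2, design20, "rna", reference=ref
    )
    return {
        "protein": (prot, prot_summary),
        "rna": (rna, rna_summary),
    }


@pytest.fixture
def rng():
    return np.random.default_rng(0)
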