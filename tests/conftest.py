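import numpy as np
import pytest

from eisa.annotation import GeneModel, TranscriptModel
from eisa.simulate import SimConfig, simulate_annotation, simulate_counts, simulate_truth


def make_gene(gene_id, isoform_exons, strand="+", chrom="chr1", cds=None, source="ensembl"):
    """Build a GeneModel from a list of per-isoform exon block lists."""
    transcripts = [
        TranscriptModel(f"{gene_id}.T{i + 1}", gene_id, source, chrom, strand,
                        exons=list(exons), cds=(cds if i == 0 else None))
        for i, exons in enumerate(isoform_exons)
    ]
    return GeneModel(gene_id, gene_id, transcripts)


@pytest.fixture(scope="session")
def sim_bundle():
    """A small simulated dataset shared across tests (annotation + counts)."""
    config = SimConfig(n_genes=150, seed=42)
    ann = simulate_annotation(config, 42)
    cm_exon, cm_intron, lib = simulate_counts(ann.truth, 42)
    return ann, cm_exon, cm_intron, lib


@pytest.fixture(scope="session")
def de_results():
    """Fitted DE results at both levels on a default-sized simulation."""
    from eisa.diffexp import NegativeBinomialDE

    config = SimConfig(n_genes=1000, seed=7)
    truth = simulate_truth(config, 7)
    cm_exon, cm_intron, _ = simulate_counts(truth, 7)
    res_ex = NegativeBinomialDE.from_count_matrix(cm_exon).fit()
    res_in = NegativeBinomialDE.from_count_matrix(cm_intron).fit()
    return truth, res_ex, res_in


@pytest.fixture
def rng():
    return np.random.default_rng(0)
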