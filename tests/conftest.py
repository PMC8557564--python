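import numpy as np
import pytest

from splicemeth import nbglm, simulate
from splicemeth.annotation import flatten_gene


@pytest.fixture(scope="session")
def small_cfg():
    return simulate.SimulationConfig(seed=7, n_genes=30)


@pytest.fixture(scope="session")
def small_dataset(small_cfg):
    """One small simulated dataset shared across tests (read-only)."""
    genes = simulate.generate_annotation(small_cfg)
    iso, bins, design, truth = simulate.generate_counts(small_cfg, genes)
    meth, design_meth = simulate.generate_methylome(small_cfg, genes, truth)
    flat = {gid: flatten_gene(g) for gid, g in genes.items()}
    return dict(
        cfg=small_cfg, genes=genes, flat=flat, iso=iso, bins=bins,
        design=design, meth=meth, design_meth=design_meth, truth=truth,
    )


@pytest.fixture(scope="session")
def rna_design(small_dataset):
    return nbglm.DesignInfo.from_frame(small_dataset["design"])


def random_gene_model(rng, gene_id="G1", chrom="chr9"):
    """Random multi-transcript gene model for property tests."""
    from splicemeth.annotation import GeneModel, GenomicInterval

    strand = "+" if rng.random() < 0.5 else "-"
    n_ex = int(rng.integers(1, 7))
    pos = int(rng.integers(1, 500))
    skeleton = []
    for _ in range(n_ex):
        length = int(rng.integers(5, 60))
        skeleton.append((pos, pos + length - 1))
        pos += length + int(rng.integers(1, 80))
    transcripts = {}
    n_tx = int(rng.integers(1, 4))
    for j in range(n_tx):
        keep = [e for e in skeleton if rng.random() < 0.8]
        if not keep:
            keep = [skeleton[0]]
        # random boundary jitter inside kept exons creates overlapping,
        # non-identical exon structures across transcripts
        exons = []
        for s, e in keep:
            s2 = s + int(rng.integers(0, max(1, (e - s) // 2)))
            exons.append(GenomicInterval(chrom, s2, e, strand))
        transcripts[f"{gene_id}.t{j + 1}"] = exons
    return GeneModel(gene_id, chrom, strand, transcripts)
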