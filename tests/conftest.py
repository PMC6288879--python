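import numpy as np
import pandas as pd
import pytest

from evoreseq.config import EvolveConfig, PoolSeqConfig, RnaSimConfig
from evoreseq import sim


@pytest.fixture(scope="session")
def labels8():
    return sim.line_labels(4)


@pytest.fixture(scope="session")
def regime8():
    return [1, 0] * 4


@pytest.fixture(scope="session")
def drift_run(tmp_path_factory):
    """Drift-only pooled-seq run: sim truth, sync file and filtered table."""
    from evoreseq import sync_io

    cfg = EvolveConfig(n_pairs=4, generations=10, n_mothers=50, n_loci=600, s=0.0)
    pool = PoolSeqConfig(mean_coverage_per_library=[60] * 8, coverage_dispersion=0.05, error_rate=0.001)
    truth, freqs = sim.simulate_er(cfg, 101)
    sync = sim.sample_pool_reads(truth, pool, 102)
    path = tmp_path_factory.mktemp("drift") / "pool.sync"
    sim.write_sync(sync, path)
    table, reasons = sync_io.filter_sync(sync_io.read_sync(path), labels=sim.line_labels(4))
    return {"cfg": cfg, "truth": truth, "freqs": freqs, "sync_path": path, "table": table, "reasons": reasons}


@pytest.fixture(scope="session")
def rna_planted():
    cfg = RnaSimConfig(n_transcripts=2000, n_de=80, n_onoff=10)
    counts, truth = sim.simulate_rnaseq(cfg, 4, 301)
    return cfg, counts, truth


def make_toy_annotation(tmp_path):
    """Two-gene toy annotation: one plus-strand, one minus-strand gene.

    Both genes encode the same 4-codon peptide (M K G *), the minus-strand
    gene as the reverse complement, so strand handling can be checked by
    construction. Returns (gff_path, fasta_path, sequence).
    """
    # plus-strand CDS at 101..112: ATG AAA GGG TAA
    cds_plus = "ATGAAAGGGTAA"
    # minus-strand gene: genomic segment 201..212 is revcomp of the same CDS
    comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
    cds_minus_genomic = "".join(comp[b] for b in reversed(cds_plus))
    seq = ["A"] * 400
    seq[100:112] = list(cds_plus)
    seq[200:212] = list(cds_minus_genomic)
    seq = "".join(seq)
    fasta = tmp_path / "toy.fa"
    fasta.write_text(">chr1\n" + seq + "\n")
    gff = tmp_path / "toy.gff3"
    gff.write_text(
        "##gff-version 3\n"
        "chr1\ttoy\tgene\t95\t120\t.\t+\t.\tID=geneP\n"
        "chr1\ttoy\tmRNA\t95\t120\t.\t+\t.\tID=mP;Parent=geneP\n"
        "chr1\ttoy\tCDS\t101\t112\t.\t+\t0\tID=cP;Parent=mP\n"
        "chr1\ttoy\tgene\t195\t220\t.\t-\t.\tID=geneM\n"
        "chr1\ttoy\tmRNA\t195\t220\t.\t-\t.\tID=mM;Parent=geneM\n"
        "chr1\ttoy\tCDS\t201\t212\t.\t-\t0\tID=cM;Parent=mM\n"
    )
    return gff, fasta, seq
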