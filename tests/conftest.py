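import numpy as np
import pandas as pd
import pysam
import pytest

from apamix.pipeline import RunConfig, run_pipeline
from apamix.simulate import SimConfig, simulate_dataset

TOY_GTF = """\
chr1\ttest\tgene\t1\t1500\t.\t+\t.\tgene_id "gA";
chr1\ttest\ttranscript\t1\t1500\t.\t+\t.\tgene_id "gA"; transcript_id "gA.t1";
chr1\ttest\texon\t1\t1500\t.\t+\t.\tgene_id "gA"; transcript_id "gA.t1";
chr1\ttest\tthree_prime_utr\t1001\t1500\t.\t+\t.\tgene_id "gA"; transcript_id "gA.t1";
"""


@pytest.fixture
def toy_gtf(tmp_path):
    p = tmp_path / "toy.gtf"
    p.write_text(TOY_GTF)
    return str(p)


@pytest.fixture
def tiny_fasta(tmp_path):
    """Single small chromosome with a handful of planted features."""
    import pyfaidx
    seq = "AACC" + "G" * 96 + "CCAATAAAGG" + "C" * 90
    p = tmp_path / "tiny.fa"
    p.write_text(">chrT\n" + seq + "\n")
    pyfaidx.Faidx(str(p))
    return pyfaidx.Fasta(str(p))


def make_bam(path, reads, chrom="chrT", length=100000):
    """Write a tiny sorted+indexed BAM from (qname, pos, cigar, tags, flag)."""
    header = {"HD": {"VN": "1.6"}, "SQ": [{"SN": chrom, "LN": length}]}
    unsorted = str(path) + ".unsorted.bam"
    with pysam.AlignmentFile(unsorted, "wb", header=header) as bam:
        for qname, pos, cigar, tags, flag in reads:
            a = pysam.AlignedSegment(bam.header)
            a.query_name = qname
            a.flag = flag
            a.reference_id = 0
            a.reference_start = pos
            a.mapping_quality = 255
            a.cigartuples = cigar
            a.query_sequence = "A" * sum(n for op, n in cigar if op == 0)
            for tag, value in tags.items():
                a.set_tag(tag, value)
            bam.write(a)
    pysam.sort("-o", str(path), unsorted)
    pysam.index(str(path))
    import os
    os.remove(unsorted)
    return str(path)


# ---------------------------------------------------------------------------
# Session-scoped end-to-end fixture: 20 genes, 2-3 PAs each, >=300 bp apart,
# 10% internal-priming genes, 10% unannotated (de novo) PAs.
# ---------------------------------------------------------------------------

E2E_SEED = 7
E2E_SID = (70.0, 130.0)


@pytest.fixture(scope="session")
def sim_e2e(tmp_path_factory):
    out = tmp_path_factory.mktemp("sim_e2e")
    config = SimConfig(seed=E2E_SEED, n_genes=20, cells_per_group=60)
    paths, truth = simulate_dataset(config, str(out))
    return config, paths, truth


@pytest.fixture(scope="session")
def pipeline_e2e(sim_e2e, tmp_path_factory):
    config, paths, truth = sim_e2e
    out = tmp_path_factory.mktemp("pipe_e2e")
    cfg = RunConfig(
        bam=paths["bam"], gtf=paths["gtf"], pa_bed=paths["pa_bed"],
        fasta=paths["fasta"], barcodes=paths["barcodes"],
        groups=paths["groups"], out_dir=str(out), sid_override=E2E_SID,
    )
    run_pipeline(cfg)
    return cfg, str(out), truth


@pytest.fixture(scope="session")
def annotated_e2e(pipeline_e2e):
    cfg, out, truth = pipeline_e2e
    return pd.read_csv(f"{out}/annotated_peaks.tsv", sep="\t")
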