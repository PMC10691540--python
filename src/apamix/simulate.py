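"""Fully synthetic, ground-truthed 3'-end sequencing data.

The generator emits everything the pipeline consumes — genome FASTA, gene
annotation GTF, known-PA BED, a coordinate-sorted tagged BAM with CB/UB
tags, barcode and group tables — together with truth tables recording the
planted cleavage sites and the per-cell per-peak molecule counts.

The generative model mirrors the pipeline's assumptions: each gene carries
2-3 cleavage sites in its 3' UTR, each cell draws its usage proportions
from a group-specific Dirichlet, each molecule's read starts at a
Gaussian-jittered distance upstream of its cleavage site, and a PAS
hexamer (AATAAA) is planted ~20 bp upstream of every true site.  Two
artifact classes are planted on demand: genomic A-stretches with reads
piled on them (internal priming) and cleavage sites withheld from the
known-PA BED (de novo sites).  Random sequence is scrubbed of accidental
runs of eight or more adenosines before planting, so the only A-stretches
are the registered ones.

What this emulates and what it does not: peak shapes are exactly Gaussian,
barcodes are error-free, expression is uniform across genes, and there is
no ambient RNA — passing tests on this data demonstrate the machinery,
not robustness to every artifact of real libraries.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import (
    GeneModel, GenomicInterval, KnownPA, Transcript, reverse_complement,
    write_gene_models_gtf, write_pa_bed,
)

CHROM = "chrSim"
EXON1_LEN = 200
INTRON_LEN = 200
CDS2_LEN = 103          # coding stub + stop codon inside the last exon
FIRST_PA_OFFSET = 400   # first cleavage site, bp into the 3' UTR
IP_STRETCH_GAP = 500    # A-stretch distance downstream of the last PA
IP_STRETCH_LEN = 15
UTR_TAIL = 300          # UTR continues past the A-stretch slot
GENE_GAP = 3000
CHROM_PAD = 6000
PAS_OFFSET = 26         # planted AATAAA starts this far upstream of cleavage


@dataclass
class SimConfig:
    """Study conditions for the synthetic dataset."""

    seed: int
    n_genes: int = 20
    peaks_per_gene: tuple[int, int] = (2, 3)   # inclusive range
    spacing: int = 400                         # bp between cleavage sites
    peak_sigma: float = 30.0                   # read-start jitter (bp)
    groups: tuple[str, ...] = ("base", "alt")
    alpha_precision: float = 15.0              # per-group Dirichlet sum
    cells_per_group: int = 60
    umi_mean: float = 8.0                      # NB mean UMIs/cell/gene
    umi_dispersion: float = 10.0               # NB size parameter
    duplication_rate: float = 0.15             # P(one extra duplicate read)
    ip_gene_fraction: float = 0.1
    ip_umi_mean: float = 2.0                   # Poisson, per cell per ip gene
    denovo_gene_fraction: float = 0.1
    spliced_fraction: float = 0.02
    read_length: int = 91
    mode_offset: int = 100                     # designed mode-to-PA distance

    def __post_init__(self):
        for frac in (self.duplication_rate, self.ip_gene_fraction,
                     self.denovo_gene_fraction, self.spliced_fraction):
            if not 0 <= frac <= 1:
                raise ValueError("fractions must lie in [0, 1]")


@dataclass
class SimGene:
    gene_id: str
    strand: str
    start: int                       # genomic start of the gene body
    length: int
    cleavages: list[int]             # genomic, proximal -> distal
    annotated: list[bool]            # withheld-from-BED sites are False
    expected_modes: list[int]        # genomic positions of the true modes
    is_ip: bool = False
    ip_stretch: int | None = None    # genomic start of the planted A-run
    ip_expected_mode: int | None = None

    def t2g(self, t: int) -> int:
        """Transcription offset (0 = gene 5' end) -> genomic position."""
        if self.strand == "+":
            return self.start + t
        return self.start + self.length - 1 - t


@dataclass
class SimReference:
    config: SimConfig
    genome: str                      # the single simulated chromosome
    genes: list[SimGene]
    models: list[GeneModel]
    pa_sites: list[KnownPA]          # the annotated (emitted) sites only

    def gene_truth(self) -> pd.DataFrame:
        rows = []
        for g in self.genes:
            for k, (c, ann, m) in enumerate(
                zip(g.cleavages, g.annotated, g.expected_modes)
            ):
                rows.append({
                    "gene_id": g.gene_id, "peak_index": k, "strand": g.strand,
                    "cleavage": c, "expected_mode": m, "annotated": ann,
                    "is_ip_gene": g.is_ip, "ip_stretch": g.ip_stretch,
                })
        return pd.DataFrame(rows)


@dataclass
class TruthTables:
    reference: SimReference
    counts: pd.DataFrame             # gene_id, peak_index, barcode, count
    barcodes: list[str] = field(default_factory=list)
    groups: pd.Series | None = None  # barcode -> group label

    def matrix_for_gene(self, gene_id: str) -> pd.DataFrame:
        """True peak-by-cell counts for one gene (all barcodes as columns)."""
        sub = self.counts[self.counts["gene_id"] == gene_id]
        mat = sub.pivot_table(index="peak_index", columns="barcode",
                              values="count", aggfunc="sum", fill_value=0)
        return mat.reindex(columns=self.barcodes, fill_value=0)


# ---------------------------------------------------------------------------
# Reference construction
# ---------------------------------------------------------------------------

def _scrub_a_runs(bases: np.ndarray, max_run: int = 7) -> None:
    """Break every run of more than ``max_run`` adenosines in place."""
    is_a = bases == "A"
    run = 0
    for i in range(len(bases)):
        if is_a[i]:
            run += 1
            if run > max_run:
                bases[i] = "G"
                run = 0
        else:
            run = 0


def build_reference(config: SimConfig) -> SimReference:
    """Lay out genes, plant PAS hexamers and artifacts, build truth."""
    rng = np.random.default_rng(config.seed)
    lo, hi = config.peaks_per_gene
    n_peaks = rng.integers(lo, hi + 1, size=config.n_genes)

    n_ip = int(round(config.ip_gene_fraction * config.n_genes))
    n_dn = int(round(config.denovo_gene_fraction * config.n_genes))
    special = rng.choice(config.n_genes, size=n_ip + n_dn, replace=False)
    ip_set = set(special[:n_ip].tolist())
    dn_set = set(special[n_ip:].tolist())

    genes: list[SimGene] = []
    cursor = CHROM_PAD
    for gi in range(config.n_genes):
        strand = "+" if gi % 2 == 0 else "-"
        K = int(n_peaks[gi])
        utr_start = EXON1_LEN + INTRON_LEN + CDS2_LEN
        last_pa = utr_start + FIRST_PA_OFFSET + (K - 1) * config.spacing
        length = last_pa + IP_STRETCH_GAP + IP_STRETCH_LEN + UTR_TAIL
        g = SimGene(
            gene_id=f"G{gi + 1:03d}", strand=strand, start=cursor,
            length=length, cleavages=[], annotated=[], expected_modes=[],
            is_ip=gi in ip_set,
        )
        for k in range(K):
            t_clv = utr_start + FIRST_PA_OFFSET + k * config.spacing
            g.cleavages.append(g.t2g(t_clv))
            # the distal-most site of a de novo gene is withheld from BED
            g.annotated.append(not (gi in dn_set and k == K - 1))
            g.expected_modes.append(g.t2g(t_clv - config.mode_offset))
        if g.is_ip:
            t_stretch = last_pa + IP_STRETCH_GAP
            g.ip_stretch = min(g.t2g(t_stretch),
                               g.t2g(t_stretch + IP_STRETCH_LEN - 1))
            g.ip_expected_mode = g.t2g(t_stretch - config.mode_offset)
        genes.append(g)
        cursor += length + GENE_GAP
    chrom_len = cursor + CHROM_PAD

    bases = rng.choice(np.array(list("ACGT")), size=chrom_len)
    _scrub_a_runs(bases)

    def plant(gene: SimGene, t_offset: int, seq: str) -> None:
        """Write ``seq`` so it reads in transcription orientation."""
        if gene.strand == "+":
            start = gene.t2g(t_offset)
            bases[start:start + len(seq)] = list(seq)
        else:
            end = gene.t2g(t_offset)          # genomic pos of seq[0]
            rc = reverse_complement(seq)
            bases[end - len(seq) + 1:end + 1] = list(rc)

    utr_start = EXON1_LEN + INTRON_LEN + CDS2_LEN
    for g in genes:
        for k in range(len(g.cleavages)):
            t_clv = utr_start + FIRST_PA_OFFSET + k * config.spacing
            plant(g, t_clv - PAS_OFFSET, "AATAAA")
        if g.is_ip:
            last_t = utr_start + FIRST_PA_OFFSET + (len(g.cleavages) - 1) \
                * config.spacing
            plant(g, last_t + IP_STRETCH_GAP, "A" * IP_STRETCH_LEN)
    genome = "".join(bases)

    models = [_gene_model(g) for g in genes]
    pa_sites = [
        KnownPA(CHROM, c, g.strand, source="sim")
        for g in genes for c, ann in zip(g.cleavages, g.annotated) if ann
    ]
    return SimReference(config, genome, genes, models, pa_sites)


def _gene_model(g: SimGene) -> GeneModel:
    def iv(t0, t1):
        a, b = g.t2g(t0), g.t2g(t1 - 1)
        return GenomicInterval(CHROM, min(a, b), max(a, b) + 1, g.strand)

    exon1 = iv(0, EXON1_LEN)
    exon2 = iv(EXON1_LEN + INTRON_LEN, g.length)
    utr = iv(EXON1_LEN + INTRON_LEN + CDS2_LEN, g.length)
    tx = Transcript(f"{g.gene_id}.t1", sorted([exon1, exon2]), utr)
    return GeneModel(g.gene_id, CHROM, g.strand, [tx])


def write_reference(ref: SimReference, out_dir: str) -> dict[str, str]:
    """Write genome.fa (+ .fai), annotation.gtf and known_pa.bed."""
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "fasta": os.path.join(out_dir, "genome.fa"),
        "gtf": os.path.join(out_dir, "annotation.gtf"),
        "pa_bed": os.path.join(out_dir, "known_pa.bed"),
    }
    with open(paths["fasta"], "w") as fh:
        fh.write(f">{CHROM}\n")
        for i in range(0, len(ref.genome), 60):
            fh.write(ref.genome[i:i + 60] + "\n")
    import pyfaidx
    pyfaidx.Faidx(paths["fasta"])
    write_gene_models_gtf(ref.models, paths["gtf"])
    write_pa_bed(ref.pa_sites, paths["pa_bed"])
    return paths


# ---------------------------------------------------------------------------
# Count-level simulation (shared by the read simulator and the test
# calibration/power studies)
# ---------------------------------------------------------------------------

def simulate_gene_counts(alpha_by_group: dict, cells_per_group: int,
                         umi_mean: float, umi_dispersion: float,
                         rng: np.random.Generator):
    """Per-cell peak counts under the Dirichlet-multinomial model.

    Returns ``(counts, labels)`` with counts of shape
    (n_groups * cells_per_group, J).
    """
    blocks, labels = [], []
    for group in alpha_by_group:
        alpha = np.asarray(alpha_by_group[group], dtype=float)
        p = umi_dispersion / (umi_dispersion + umi_mean)
        n = rng.negative_binomial(umi_dispersion, p, size=cells_per_group)
        props = rng.dirichlet(alpha, size=cells_per_group)
        counts = np.vstack([rng.multinomial(ni, pi)
                            for ni, pi in zip(n, props)])
        blocks.append(counts)
        labels.extend([group] * cells_per_group)
    return np.vstack(blocks), np.asarray(labels)


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------

def _alpha_for(config: SimConfig, group: str, J: int) -> np.ndarray:
    """Symmetric per-group Dirichlet unless the caller overrides."""
    return np.full(J, config.alpha_precision / J)


def simulate_reads(config: SimConfig, ref: SimReference, out_dir: str,
                   alpha_fn=None) -> TruthTables:
    """Emit the tagged, sorted, indexed BAM plus barcode/group tables.

    ``alpha_fn(config, group, J)`` may override the per-group Dirichlet
    (e.g. to plant a proximal-to-distal shift between groups).
    """
    import pysam

    os.makedirs(out_dir, exist_ok=True)
    rng = np.random.default_rng(config.seed + 1)
    alpha_fn = alpha_fn or _alpha_for
    L = config.read_length
    start_offset = config.mode_offset + L // 2   # 5' end sits this far
    #                                              upstream of the cleavage

    barcodes, labels = [], []
    for g_idx, group in enumerate(config.groups):
        for c_idx in range(config.cells_per_group):
            barcodes.append(f"{group}-{c_idx:04d}")
            labels.append(group)
    groups = pd.Series(labels, index=barcodes, name="group")

    header = {"HD": {"VN": "1.6", "SO": "unknown"},
              "SQ": [{"SN": CHROM, "LN": len(ref.genome)}]}
    reads = []           # (genomic_start, record fields)
    truth_rows = []
    umi_counter = 0

    for gene in ref.genes:
        J = len(gene.cleavages)
        for barcode, group in zip(barcodes, labels):
            alpha = alpha_fn(config, group, J)
            n = int(rng.negative_binomial(
                config.umi_dispersion,
                config.umi_dispersion / (config.umi_dispersion + config.umi_mean),
            ))
            if n > 0:
                p = rng.dirichlet(alpha)
                per_peak = rng.multinomial(n, p)
            else:
                per_peak = np.zeros(J, dtype=int)
            for k, cnt in enumerate(per_peak):
                if cnt:
                    truth_rows.append({
                        "gene_id": gene.gene_id, "peak_index": k,
                        "barcode": barcode, "count": int(cnt),
                    })
                for _ in range(cnt):
                    umi_counter += 1
                    _emit_umi(reads, rng, config, gene,
                              gene.cleavages[k], barcode,
                              f"UMI{umi_counter:08d}", start_offset)
            if gene.is_ip:
                n_ip = int(rng.poisson(config.ip_umi_mean))
                stretch_site = gene.t2g(
                    _gene_t_of(gene, config, ip=True))
                for _ in range(n_ip):
                    umi_counter += 1
                    _emit_umi(reads, rng, config, gene, stretch_site,
                              barcode, f"UMI{umi_counter:08d}", start_offset,
                              is_artifact=True)

    bam_path = os.path.join(out_dir, "reads.bam")
    unsorted = os.path.join(out_dir, ".unsorted.bam")
    with pysam.AlignmentFile(unsorted, "wb", header=header) as bam:
        for _, rec in sorted(reads, key=lambda r: (r[0], r[1]["qname"])):
            a = pysam.AlignedSegment(bam.header)
            a.query_name = rec["qname"]
            a.flag = 16 if rec["reverse"] else 0
            a.reference_id = 0
            a.reference_start = rec["pos"]
            a.mapping_quality = 255
            a.cigartuples = rec["cigar"]
            a.query_sequence = rec["seq"]
            a.set_tag("CB", rec["cb"])
            a.set_tag("UB", rec["ub"])
            bam.write(a)
    pysam.sort("-o", bam_path, unsorted)
    os.remove(unsorted)
    pysam.index(bam_path)

    with open(os.path.join(out_dir, "barcodes.tsv"), "w") as fh:
        fh.write("".join(b + "\n" for b in barcodes))
    groups.to_csv(os.path.join(out_dir, "groups.tsv"), sep="\t", header=False)

    counts = pd.DataFrame(truth_rows,
                          columns=["gene_id", "peak_index", "barcode", "count"])
    return TruthTables(ref, counts, barcodes, groups)


def _gene_t_of(gene: SimGene, config: SimConfig, ip: bool) -> int:
    utr_start = EXON1_LEN + INTRON_LEN + CDS2_LEN
    last_t = utr_start + FIRST_PA_OFFSET + (len(gene.cleavages) - 1) \
        * config.spacing
    return last_t + IP_STRETCH_GAP


def _emit_umi(reads, rng, config, gene, cleavage_site, barcode, umi,
              start_offset, is_artifact=False):
    """One molecule: representative read plus optional duplicate."""
    L = config.read_length
    n_copies = 1 + (rng.random() < config.duplication_rate)
    spliced = rng.random() < config.spliced_fraction
    base_jitter = rng.normal(0.0, config.peak_sigma)
    for copy in range(n_copies):
        jitter = base_jitter + (rng.integers(-2, 3) if copy else 0)
        # transcription offset of the read 5' end within the genome
        if gene.strand == "+":
            five = cleavage_site - start_offset + int(round(jitter))
            if spliced:
                blocks = [(five - 100, five - 70), (five + 130, five + 191)]
            else:
                blocks = [(five, five + L)]
        else:
            five = cleavage_site + start_offset - int(round(jitter))
            if spliced:
                blocks = [(five - 190, five - 129), (five + 71, five + 101)]
            else:
                blocks = [(five - L + 1, five + 1)]
        blocks.sort()
        cigar = []
        for bi, (b0, b1) in enumerate(blocks):
            if bi:
                cigar.append((3, b0 - blocks[bi - 1][1]))   # N
            cigar.append((0, b1 - b0))                      # M
        seq_len = sum(b1 - b0 for b0, b1 in blocks)
        reads.append((blocks[0][0], {
            "qname": f"read:{umi}:{copy}",
            "pos": blocks[0][0],
            "cigar": cigar,
            "seq": "A" * seq_len,
            "cb": barcode, "ub": umi,
            "reverse": gene.strand == "-",
        }))


def simulate_dataset(config: SimConfig, out_dir: str, alpha_fn=None):
    """Reference + reads in one call; returns (paths, truth)."""
    ref = build_reference(config)
    paths = write_reference(ref, out_dir)
    truth = simulate_reads(config, ref, out_dir, alpha_fn=alpha_fn)
    paths["bam"] = os.path.join(out_dir, "reads.bam")
    paths["barcodes"] = os.path.join(out_dir, "barcodes.tsv")
    paths["groups"] = os.path.join(out_dir, "groups.tsv")
    return paths, truth
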