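"""Reference input handling: gene models, known polyadenylation sites, genome sequence.

All coordinates are normalized to a single internal convention — 0-based,
half-open, as in BED — at the moment a file is read.  GTF/GFF input
(1-based, closed) is converted exactly once, here.  Every genomic position
the package reports can therefore be audited against the input by adding
one to starts.

The 3'-UTR intervals of a gene form the search space for polyadenylation
peaks.  Because 3'-end reads frequently extend past the annotated UTR end
(annotations lag the true cleavage repertoire), each UTR is extended
downstream in the transcription direction, truncated at the next annotated
same-strand gene so that reads from a neighbouring gene are never counted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A stranded genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"interval start {self.start} > end {self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class Transcript:
    transcript_id: str
    exons: list[GenomicInterval]
    utr: GenomicInterval | None = None

    @property
    def last_exon(self) -> GenomicInterval:
        """Exon containing the transcript 3' end (strand-aware)."""
        if self.exons[0].strand == "+":
            return max(self.exons, key=lambda e: e.end)
        return min(self.exons, key=lambda e: e.start)


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    transcripts: list[Transcript]
    extended_utr_regions: list[GenomicInterval] = field(default_factory=list)

    @property
    def utr_regions(self) -> list[GenomicInterval]:
        """Merged annotated 3'-UTR intervals across transcripts."""
        return merge_intervals(
            [t.utr for t in self.transcripts if t.utr is not None]
        )

    def span(self) -> GenomicInterval:
        """Hull of the extended (or annotated) UTR regions."""
        regions = self.extended_utr_regions or self.utr_regions
        if not regions:
            raise ValueError(f"gene {self.gene_id} has no 3'-UTR regions")
        return GenomicInterval(
            self.chrom,
            min(r.start for r in regions),
            max(r.end for r in regions),
            self.strand,
        )

    def gene_start(self) -> int:
        """5'-most transcribed position (transcription direction)."""
        exons = [e for t in self.transcripts for e in t.exons]
        if self.strand == "+":
            return min(e.start for e in exons)
        return max(e.end for e in exons)


@dataclass(frozen=True)
class KnownPA:
    """A single-base annotated cleavage site."""

    chrom: str
    position: int
    strand: str
    source: str = "merged"
    gene_id: str | None = None


def merge_intervals(intervals: list[GenomicInterval]) -> list[GenomicInterval]:
    """Union of same-chrom same-strand intervals, sorted by start."""
    if not intervals:
        return []
    ivs = sorted(intervals, key=lambda i: (i.chrom, i.strand, i.start))
    out = [ivs[0]]
    for iv in ivs[1:]:
        last = out[-1]
        if iv.chrom == last.chrom and iv.strand == last.strand and iv.start <= last.end:
            if iv.end > last.end:
                out[-1] = replace(last, end=iv.end)
        else:
            out.append(iv)
    return out


# ---------------------------------------------------------------------------
# GTF reading / writing
# ---------------------------------------------------------------------------

def load_gene_models(gtf_path: str) -> list[GeneModel]:
    """Parse a GTF into :class:`GeneModel` objects.

    The 3' UTR of each transcript is taken from ``three_prime_utr`` features
    when present; otherwise it is the part of the last exon downstream of
    the ``stop_codon`` (the whole last exon if no stop codon is annotated).
    Genes with no stranded exons are skipped with a warning.
    """
    import gffutils

    db = gffutils.create_db(
        gtf_path,
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    models: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        if gene.strand not in ("+", "-"):
            warnings.warn(
                f"gene {gene.id} has no strand; skipped", stacklevel=2
            )
            continue
        transcripts = []
        for tx in db.children(gene, featuretype="transcript"):
            exons = [
                GenomicInterval(e.seqid, e.start - 1, e.end, e.strand)
                for e in db.children(tx, featuretype="exon")
            ]
            if not exons:
                continue
            utrs = [
                GenomicInterval(u.seqid, u.start - 1, u.end, u.strand)
                for u in db.children(tx, featuretype="three_prime_utr")
            ]
            if utrs:
                utr = GenomicInterval(
                    gene.seqid,
                    min(u.start for u in utrs),
                    max(u.end for u in utrs),
                    gene.strand,
                )
            else:
                utr = _utr_from_last_exon(db, tx, exons, gene.strand)
            transcripts.append(Transcript(tx.id, sorted(exons), utr))
        if not transcripts:
            warnings.warn(f"gene {gene.id} has no transcripts; skipped", stacklevel=2)
            continue
        models.append(GeneModel(gene.id, gene.seqid, gene.strand, transcripts))
    return models


def _utr_from_last_exon(db, tx, exons, strand) -> GenomicInterval | None:
    last = max(exons, key=lambda e: e.end) if strand == "+" else min(
        exons, key=lambda e: e.start
    )
    stops = list(db.children(tx, featuretype="stop_codon"))
    if not stops:
        return last
    if strand == "+":
        stop_end = max(s.end for s in stops)  # 1-based closed end == internal end
        if stop_end >= last.end:
            return None
        return GenomicInterval(last.chrom, stop_end, last.end, strand)
    stop_start = min(s.start for s in stops) - 1
    if stop_start <= last.start:
        return None
    return GenomicInterval(last.chrom, last.start, stop_start, strand)


def write_gene_models_gtf(models: list[GeneModel], path: str) -> None:
    """Write models back out as GTF (the read conversion, inverted)."""
    with open(path, "w") as fh:
        for g in models:
            g_start = min(e.start for t in g.transcripts for e in t.exons)
            g_end = max(e.end for t in g.transcripts for e in t.exons)
            fh.write(_gtf_line(g.chrom, "gene", g_start, g_end, g.strand,
                               f'gene_id "{g.gene_id}";'))
            for t in g.transcripts:
                attrs = f'gene_id "{g.gene_id}"; transcript_id "{t.transcript_id}";'
                t_start = min(e.start for e in t.exons)
                t_end = max(e.end for e in t.exons)
                fh.write(_gtf_line(g.chrom, "transcript", t_start, t_end,
                                   g.strand, attrs))
                for e in sorted(t.exons):
                    fh.write(_gtf_line(g.chrom, "exon", e.start, e.end,
                                       g.strand, attrs))
                if t.utr is not None:
                    fh.write(_gtf_line(g.chrom, "three_prime_utr",
                                       t.utr.start, t.utr.end, g.strand, attrs))


def _gtf_line(chrom, feature, start, end, strand, attrs) -> str:
    # internal 0-based half-open -> GTF 1-based closed
    return f"{chrom}\tapamix\t{feature}\t{start + 1}\t{end}\t.\t{strand}\t.\t{attrs}\n"


# ---------------------------------------------------------------------------
# UTR extension
# ---------------------------------------------------------------------------

def extend_utrs(
    models: list[GeneModel],
    extension: int = 2000,
    boundary_models: list[GeneModel] | None = None,
) -> list[GeneModel]:
    """Extend each annotated 3' UTR downstream by ``extension`` bp.

    The extension is truncated at the 5' start of the nearest downstream
    same-strand gene in ``boundary_models`` (default: ``models`` itself), so
    coverage from a neighbouring gene's 3' end cannot bleed into this
    gene's peak search space.  Antisense neighbours are ignored: 3'-end
    libraries are stranded.
    """
    if extension < 0:
        raise ValueError("extension must be >= 0")
    boundary_models = models if boundary_models is None else boundary_models
    starts: dict[tuple[str, str], np.ndarray] = {}
    for key, group in _group_by(boundary_models):
        starts[key] = np.array(sorted(g.gene_start() for g in group))

    out = []
    for g in models:
        bnd = starts.get((g.chrom, g.strand), np.array([]))
        regions = []
        for utr in g.utr_regions:
            if g.strand == "+":
                new_end = utr.end + extension
                downstream = bnd[bnd >= utr.end]
                if downstream.size:
                    new_end = min(new_end, int(downstream[0]))
                new_end = max(new_end, utr.end)
                regions.append(replace(utr, end=new_end))
            else:
                new_start = utr.start - extension
                upstream = bnd[bnd <= utr.start]
                if upstream.size:
                    new_start = max(new_start, int(upstream[-1]))
                new_start = max(0, min(new_start, utr.start))
                regions.append(replace(utr, start=new_start))
        g2 = GeneModel(g.gene_id, g.chrom, g.strand, g.transcripts,
                       merge_intervals(regions))
        out.append(g2)
    return out


def _group_by(models):
    groups: dict[tuple[str, str], list[GeneModel]] = {}
    for g in models:
        groups.setdefault((g.chrom, g.strand), []).append(g)
    return groups.items()


# ---------------------------------------------------------------------------
# Known-PA BED reading / writing
# ---------------------------------------------------------------------------

def load_pa_reference(bed_path: str) -> list[KnownPA]:
    """Read a BED of known cleavage sites.

    Interval records are collapsed to the single strand-appropriate
    cleavage base (the 3'-most base in the transcription direction).
    Records listing the same (chrom, position, strand) across sources are
    merged into one site.
    """
    df = pd.read_csv(
        bed_path, sep="\t", header=None, comment="#", dtype={0: str},
    )
    if df.shape[1] < 6:
        raise ValueError(
            f"{bed_path}: BED6 with a strand column is required "
            f"(got {df.shape[1]} columns)"
        )
    seen: dict[tuple[str, int, str], KnownPA] = {}
    for chrom, start, end, name, _score, strand in df.iloc[:, :6].itertuples(
        index=False
    ):
        if strand not in ("+", "-"):
            raise ValueError(
                f"{bed_path}: record {chrom}:{start}-{end} lacks a strand"
            )
        pos = int(end) - 1 if strand == "+" else int(start)
        key = (chrom, pos, strand)
        if key in seen:
            if seen[key].source != str(name):
                seen[key] = replace(seen[key], source="merged")
        else:
            seen[key] = KnownPA(chrom, pos, strand, source=str(name))
    return sorted(seen.values(), key=lambda p: (p.chrom, p.position, p.strand))


def write_pa_bed(sites: list[KnownPA], path: str) -> None:
    with open(path, "w") as fh:
        for s in sorted(sites, key=lambda p: (p.chrom, p.position, p.strand)):
            fh.write(
                f"{s.chrom}\t{s.position}\t{s.position + 1}\t{s.source}\t0\t{s.strand}\n"
            )


# ---------------------------------------------------------------------------
# Sequence access
# ---------------------------------------------------------------------------

def fetch_sequence(fasta, interval: GenomicInterval) -> str:
    """Fetch the sequence of ``interval`` in transcription orientation.

    ``fasta`` is a :class:`pyfaidx.Fasta`.  Minus-strand intervals are
    reverse-complemented.  Out-of-bounds intervals are clipped with a
    warning; an unknown chromosome raises ``KeyError``.
    """
    if interval.chrom not in fasta:
        raise KeyError(f"chromosome {interval.chrom!r} not in FASTA")
    chrom_len = len(fasta[interval.chrom])
    start = max(0, interval.start)
    end = min(chrom_len, interval.end)
    if (start, end) != (interval.start, interval.end):
        warnings.warn(
            f"interval {interval.chrom}:{interval.start}-{interval.end} "
            f"clipped to chromosome bounds [0,{chrom_len})", stacklevel=2
        )
    if start >= end:
        return ""
    seq = str(fasta[interval.chrom][start:end]).upper()
    if interval.strand == "-":
        seq = reverse_complement(seq)
    return seq
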