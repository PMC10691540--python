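"""Peak-by-cell quantification.

Each retained peak j claims the region mu_j +/- 3 sigma_j from its fitted
shape.  Every deduplicated UMI (one representative read per cell x UMI,
the one at the group's lower-median location) is assigned to a peak: if
its M-covered bases overlap exactly one peak region it goes there; if they
overlap several, the peak with the maximum posterior probability
w_k N(x | mu_k, sigma_k) at the representative location wins (isolated
peaks participate with weight 1); if none, the UMI is tallied unassigned.
The result is a sparse peak-by-cell count matrix plus a QC conservation
summary: assigned + unassigned + tag-dropped == UMIs observed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .annotation import GeneModel
from .pa_filter import STATUS_RETAINED
from .peaks import DEFAULT_MIN_MAPQ, iter_gene_umis


@dataclass(frozen=True)
class PeakRegion:
    peak_id: str
    gene_id: str
    chrom: str
    strand: str
    start: int          # floor(mu - 3 sigma)
    end: int            # ceil(mu + 3 sigma) + 1, half-open
    mu: float
    sigma: float
    weight: float

    @classmethod
    def from_row(cls, row) -> "PeakRegion":
        mu, sigma = float(row["mu"]), float(row["sigma"])
        return cls(
            row["peak_id"], row["gene_id"], row["chrom"], row["strand"],
            int(math.floor(mu - 3 * sigma)), int(math.ceil(mu + 3 * sigma)) + 1,
            mu, sigma, float(row["weight"]),
        )


@dataclass
class QCSummary:
    n_observed: int = 0
    n_assigned: int = 0
    n_unassigned: int = 0
    n_dropped_tags: int = 0

    def add(self, other: "QCSummary") -> None:
        self.n_observed += other.n_observed
        self.n_assigned += other.n_assigned
        self.n_unassigned += other.n_unassigned
        self.n_dropped_tags += other.n_dropped_tags


def regions_from_peaks(annotated: pd.DataFrame,
                       retained_only: bool = True) -> dict[str, list[PeakRegion]]:
    """Peak regions per gene, in transcription order."""
    table = annotated
    if retained_only and "status" in annotated.columns:
        table = annotated[annotated["status"] == STATUS_RETAINED]
    out: dict[str, list[PeakRegion]] = {}
    for gene_id, sub in table.groupby("gene_id", sort=True):
        regions = [PeakRegion.from_row(r) for _, r in sub.iterrows()]
        regions.sort(key=lambda r: r.mu, reverse=(regions[0].strand == "-"))
        out[gene_id] = regions
    return out


def assign_umi(location: int, blocks: list[tuple[int, int]],
               regions: list[PeakRegion]) -> PeakRegion | None:
    """Assign one UMI representative to a peak region, or ``None``.

    Overlap is computed on M-covered bases only.  Multi-overlap resolves
    by the mixture posterior at the representative location; exact ties go
    to the downstream peak.
    """
    hits = [r for r in regions
            if any(b0 < r.end and r.start < b1 for b0, b1 in blocks)]
    if not hits:
        return None
    if len(hits) == 1:
        return hits[0]
    best, best_score = None, -np.inf
    for r in hits:
        score = (math.log(max(r.weight, 1e-300))
                 - math.log(r.sigma)
                 - 0.5 * ((location - r.mu) / r.sigma) ** 2)
        downstream = (location is not None and best is not None and (
            (r.strand == "+" and r.mu > best.mu)
            or (r.strand == "-" and r.mu < best.mu)))
        if score > best_score or (score == best_score and downstream):
            best, best_score = r, score
    return best


def count_gene(bam, gene: GeneModel, regions: list[PeakRegion],
               cb_tag="CB", ub_tag="UB", min_mapq=DEFAULT_MIN_MAPQ):
    """Per-cell UMI counts for one gene's peaks.

    Returns ``(counts, qc)`` where counts maps (peak_id, barcode) -> n.
    """
    qc = QCSummary()
    counts: dict[tuple[str, str], int] = {}
    n_dropped, umis = iter_gene_umis(bam, gene, cb_tag, ub_tag, min_mapq)
    for cb, ub, read, loc, blocks in umis:
        qc.n_observed += 1
        region = assign_umi(loc, blocks, regions)
        if region is None:
            qc.n_unassigned += 1
            continue
        qc.n_assigned += 1
        key = (region.peak_id, cb)
        counts[key] = counts.get(key, 0) + 1
    qc.n_dropped_tags = n_dropped
    qc.n_observed += n_dropped
    return counts, qc


@dataclass
class PeakCellMatrix:
    """Sparse peak-by-cell UMI count matrix with peak metadata."""

    matrix: sparse.csr_matrix          # peaks x cells, int
    peaks: pd.DataFrame                # row metadata, index aligned
    barcodes: list[str]
    qc: QCSummary

    def to_dense(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix.toarray(),
                            index=self.peaks["peak_id"], columns=self.barcodes)


def build_matrix(bam, models: list[GeneModel], annotated: pd.DataFrame,
                 barcodes: list[str], cb_tag="CB", ub_tag="UB",
                 min_mapq=DEFAULT_MIN_MAPQ) -> PeakCellMatrix:
    """One pass over the alignments; returns the peak-by-cell matrix.

    Columns are restricted to (and ordered by) the provided barcode list.
    """
    if not barcodes:
        raise ValueError("barcode list is empty")
    regions_by_gene = regions_from_peaks(annotated)
    peak_rows = []
    for gene_id in sorted(regions_by_gene):
        for r in regions_by_gene[gene_id]:
            peak_rows.append({
                "peak_id": r.peak_id, "gene_id": r.gene_id, "chrom": r.chrom,
                "strand": r.strand, "start": r.start, "end": r.end,
                "mu": r.mu, "sigma": r.sigma,
            })
    peaks_meta = pd.DataFrame(peak_rows)
    row_of = {p: i for i, p in enumerate(peaks_meta["peak_id"])}
    col_of = {b: i for i, b in enumerate(barcodes)}

    mat = sparse.dok_matrix((len(peaks_meta), len(barcodes)), dtype=np.int64)
    qc = QCSummary()
    gene_by_id = {g.gene_id: g for g in models}
    for gene_id, regions in regions_by_gene.items():
        gene = gene_by_id.get(gene_id)
        if gene is None:
            continue
        counts, gene_qc = count_gene(bam, gene, regions, cb_tag, ub_tag,
                                     min_mapq)
        qc.add(gene_qc)
        for (peak_id, cb), n in counts.items():
            col = col_of.get(cb)
            if col is None:
                qc.n_assigned -= n
                qc.n_unassigned += n
                continue
            mat[row_of[peak_id], col] += n
    return PeakCellMatrix(mat.tocsr(), peaks_meta, list(barcodes), qc)


# ---------------------------------------------------------------------------
# MatrixMarket I/O
# ---------------------------------------------------------------------------

def write_matrix(pcm: PeakCellMatrix, out_dir) -> None:
    import os
    os.makedirs(out_dir, exist_ok=True)
    spio.mmwrite(os.path.join(out_dir, "matrix.mtx"), pcm.matrix.tocoo(),
                 field="integer")
    pcm.peaks.to_csv(os.path.join(out_dir, "peaks.tsv"), sep="\t", index=False)
    with open(os.path.join(out_dir, "barcodes.tsv"), "w") as fh:
        fh.write("".join(b + "\n" for b in pcm.barcodes))


def read_matrix(out_dir) -> PeakCellMatrix:
    import os
    mat = sparse.csr_matrix(spio.mmread(os.path.join(out_dir, "matrix.mtx")))
    peaks = pd.read_csv(os.path.join(out_dir, "peaks.tsv"), sep="\t")
    with open(os.path.join(out_dir, "barcodes.tsv")) as fh:
        barcodes = [line.strip() for line in fh if line.strip()]
    return PeakCellMatrix(mat.astype(np.int64), peaks, barcodes, QCSummary())
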