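"""Peak detection and fitting on deduplicated-UMI 3'-end coverage.

Pipeline per gene: build per-base coverage from UMI-deduplicated reads over
the extended 3'-UTR span, smooth it with a Gaussian kernel, take local
maxima as candidate peak modes, filter minor modes and merge near-duplicate
modes, then fit peak shapes.  Modes with no neighbour within a 300-bp
radius are fit as single Gaussians by least squares; modes that crowd
together are fit jointly with a K-component Gaussian mixture by EM, which
deconvolves overlapping cleavage-site pileups that a single-peak fit would
blur into one.

Coverage tracks are stored in *transcription orientation*: index 0 is the
5'-most base of the gene's extended-UTR span in the direction of
transcription, so minus-strand genes are flipped once here and all
downstream windowing arithmetic (peak-to-cleavage distances, motif
windows) is strand-free.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage, optimize

from .annotation import GeneModel, GenomicInterval

DEFAULT_BANDWIDTH = 25.0
DEFAULT_MIN_READS = 10
DEFAULT_MIN_FRAC = 0.05
DEFAULT_MERGE_DIST = 50
DEFAULT_CLUSTER_RADIUS = 300
DEFAULT_FIT_WINDOW = 150
SIGMA_BOUNDS = (5.0, 350.0)
DEFAULT_MIN_MAPQ = 255


@dataclass
class CoverageTrack:
    """Per-base deduplicated-UMI coverage, transcription-oriented."""

    gene_id: str
    region: GenomicInterval        # genomic hull of the extended-UTR span
    counts: np.ndarray             # int, len == len(region)
    in_utr: np.ndarray             # bool mask, same orientation as counts
    rep_offsets: np.ndarray        # representative location per UMI (offsets)
    n_umis: int = 0
    n_dropped_tags: int = 0

    def __post_init__(self):
        assert len(self.counts) == len(self.region)

    @property
    def strand(self) -> str:
        return self.region.strand

    def offset_to_genomic(self, offset: float) -> float:
        if self.strand == "+":
            return self.region.start + offset
        return self.region.end - 1 - offset

    def genomic_to_offset(self, pos: float) -> float:
        if self.strand == "+":
            return pos - self.region.start
        return self.region.end - 1 - pos


@dataclass
class PeakMode:
    position: int          # offset into the track (transcription direction)
    height: float          # smoothed coverage at the mode
    raw_reads: int = 0     # UMIs whose representative is nearest this mode
    in_utr: bool = True


@dataclass
class FittedPeak:
    mu: float              # track offset
    sigma: float
    weight: float          # mixture proportion (1.0 for isolated peaks)
    amplitude: float
    kind: str              # "isolated" | "overlapped"
    cluster_id: int | None = None
    raw_reads: int = 0
    in_utr: bool = True
    converged: bool = True


# ---------------------------------------------------------------------------
# Coverage
# ---------------------------------------------------------------------------

def iter_gene_umis(bam, gene: GeneModel, cb_tag="CB", ub_tag="UB",
                   min_mapq=DEFAULT_MIN_MAPQ):
    """Yield one representative read per (cell, UMI) for a gene.

    Reads are grouped by (cell barcode, UMI); within a group the
    representative is the read whose location — the midpoint of its
    M-covered genomic span — is the lower median of the group's locations.
    Returns ``(n_dropped_tags, iterator of (cell, umi, read, location,
    blocks))`` where blocks are the read's aligned (M) reference segments.
    """
    span = gene.span()
    want_reverse = gene.strand == "-"
    groups: dict[tuple[str, str], list] = {}
    n_dropped = 0
    for read in bam.fetch(span.chrom, span.start, span.end):
        if read.is_unmapped or read.is_secondary or read.is_supplementary:
            continue
        if read.mapping_quality < min_mapq:
            continue
        if read.is_reverse != want_reverse:
            continue
        try:
            cb = read.get_tag(cb_tag)
            ub = read.get_tag(ub_tag)
        except KeyError:
            n_dropped += 1
            continue
        blocks = read.get_blocks()
        if not blocks:
            continue
        loc = (blocks[0][0] + blocks[-1][1] - 1) // 2
        groups.setdefault((cb, ub), []).append((loc, read.query_name, blocks, read))

    def representatives():
        for (cb, ub), members in groups.items():
            members.sort(key=lambda m: (m[0], m[1]))
            loc, _, blocks, read = members[(len(members) - 1) // 2]
            yield cb, ub, read, loc, blocks

    return n_dropped, representatives()


def build_coverage(bam, gene: GeneModel, cb_tag="CB", ub_tag="UB",
                   min_mapq=DEFAULT_MIN_MAPQ) -> CoverageTrack:
    """Deduplicated-UMI per-base coverage over the gene's extended-UTR span.

    Each retained UMI contributes the M-covered bases of its representative
    read.  UMIs whose representative location falls outside the span are
    ignored for mode detection.
    """
    span = gene.span()
    n = len(span)
    cov = np.zeros(n, dtype=np.int64)
    reps = []
    n_dropped, umis = iter_gene_umis(bam, gene, cb_tag, ub_tag, min_mapq)
    n_umis = 0
    for cb, ub, read, loc, blocks in umis:
        n_umis += 1
        for b0, b1 in blocks:
            s, e = max(b0, span.start), min(b1, span.end)
            if s < e:
                cov[s - span.start:e - span.start] += 1
        if span.start <= loc < span.end:
            reps.append(loc - span.start)
    in_utr = np.zeros(n, dtype=bool)
    for r in gene.extended_utr_regions or gene.utr_regions:
        in_utr[max(0, r.start - span.start):max(0, r.end - span.start)] = True
    if gene.strand == "-":
        cov = cov[::-1].copy()
        in_utr = in_utr[::-1].copy()
        reps = [n - 1 - r for r in reps]
    return CoverageTrack(gene.gene_id, span, cov, in_utr,
                         np.asarray(sorted(reps), dtype=np.int64),
                         n_umis=n_umis, n_dropped_tags=n_dropped)


def smooth_coverage(counts: np.ndarray, bandwidth: float = DEFAULT_BANDWIDTH,
                    truncate: float = 8.0) -> np.ndarray:
    """Gaussian-kernel smoothing of raw per-base counts.

    Mass is conserved up to truncation at the region boundaries.  The
    kernel support is wide (8 bandwidths): a tightly truncated kernel can
    manufacture a spurious micro-mode exactly midway between two sparse
    spikes one support-width apart.
    """
    if bandwidth <= 0:
        raise ValueError("bandwidth must be > 0")
    return ndimage.gaussian_filter1d(
        counts.astype(float), sigma=bandwidth, mode="constant",
        truncate=truncate,
    )


# ---------------------------------------------------------------------------
# Mode detection, filtering, merging, clustering
# ---------------------------------------------------------------------------

def detect_modes(curve: np.ndarray, in_utr: np.ndarray | None = None
                 ) -> list[PeakMode]:
    """Strict local maxima of the smoothed curve, in transcription order.

    A plateau of equal values that is higher than both neighbours reports
    its center (floor).  Array endpoints are never modes.
    """
    n = len(curve)
    modes = []
    i = 1
    while i < n - 1:
        j = i
        while j + 1 < n and curve[j + 1] == curve[i]:
            j += 1
        if curve[i] > 0 and curve[i - 1] < curve[i] and (
            j + 1 < n and curve[j + 1] < curve[i]
        ):
            pos = (i + j) // 2
            modes.append(PeakMode(
                pos, float(curve[pos]),
                in_utr=bool(in_utr[pos]) if in_utr is not None else True,
            ))
        i = j + 1
    return modes


def attribute_reads_to_modes(modes: list[PeakMode], rep_offsets: np.ndarray
                             ) -> None:
    """Nearest-mode partition of deduplicated UMIs; fills ``raw_reads``."""
    if not modes:
        return
    pos = np.array([m.position for m in modes])
    if len(rep_offsets):
        nearest = np.argmin(np.abs(rep_offsets[:, None] - pos[None, :]), axis=1)
        counts = np.bincount(nearest, minlength=len(modes))
    else:
        counts = np.zeros(len(modes), dtype=int)
    for m, c in zip(modes, counts):
        m.raw_reads = int(c)


def filter_and_merge_modes(
    modes: list[PeakMode],
    min_reads: int = DEFAULT_MIN_READS,
    min_frac: float = DEFAULT_MIN_FRAC,
    merge_dist: int = DEFAULT_MERGE_DIST,
    keep_outside: bool = False,
    in_utr: np.ndarray | None = None,
) -> list[PeakMode]:
    """Drop minor and extra-UTR modes, then merge near-duplicate modes.

    A mode is dropped if it has fewer than ``min_reads`` deduplicated UMIs
    or no more than ``min_frac`` of the largest in-UTR mode's UMIs.  Modes
    outside the extended UTR regions are dropped unless ``keep_outside``
    (they are then retained temporarily so that joint mixture fits of
    boundary clusters stay well conditioned, and discarded after fitting).
    Surviving modes closer than ``merge_dist`` are merged left-to-right,
    the merged mode sitting at the floored mean of the pair.  The
    filter+merge pass is iterated to a fixed point (merging sums read
    counts, which can re-trigger the relative-abundance rule), which makes
    the operation idempotent.
    """
    while True:
        merged = _filter_and_merge_once(modes, min_reads, min_frac,
                                        merge_dist, keep_outside, in_utr)
        if [(m.position, m.raw_reads) for m in merged] == [
            (m.position, m.raw_reads) for m in modes
        ]:
            return merged
        modes = merged


def _filter_and_merge_once(modes, min_reads, min_frac, merge_dist,
                           keep_outside, in_utr):
    in_modes = [m for m in modes if m.in_utr]
    if not in_modes:
        return []
    largest = max(m.raw_reads for m in in_modes)
    kept = [
        m for m in modes
        if (m.in_utr or keep_outside)
        and m.raw_reads >= min_reads
        and m.raw_reads > min_frac * largest
    ]
    kept.sort(key=lambda m: m.position)
    merged: list[PeakMode] = []
    for m in kept:
        if merged and m.position - merged[-1].position <= merge_dist:
            prev = merged.pop()
            pos = (prev.position + m.position) // 2
            merged.append(PeakMode(
                pos,
                max(prev.height, m.height),
                raw_reads=prev.raw_reads + m.raw_reads,
                in_utr=bool(in_utr[pos]) if in_utr is not None
                else (prev.in_utr or m.in_utr),
            ))
        else:
            merged.append(m)
    return merged


def cluster_modes(modes: list[PeakMode],
                  radius: int = DEFAULT_CLUSTER_RADIUS) -> list[list[PeakMode]]:
    """Transitive closure of the "within ``radius`` bp" relation.

    Because modes are sorted, the closure reduces to chaining consecutive
    modes whose gap is at most ``radius``.  Singleton clusters are the
    isolated peaks.
    """
    clusters: list[list[PeakMode]] = []
    for m in sorted(modes, key=lambda x: x.position):
        if clusters and m.position - clusters[-1][-1].position <= radius:
            clusters[-1].append(m)
        else:
            clusters.append([m])
    return clusters


# ---------------------------------------------------------------------------
# Peak fitting
# ---------------------------------------------------------------------------

def _gaussian(x, amp, mu, sigma):
    return amp * np.exp(-0.5 * ((x - mu) / sigma) ** 2)


def _empirical_sd(x, w):
    tot = w.sum()
    if tot <= 0:
        return SIGMA_BOUNDS[0]
    mu = (x * w).sum() / tot
    var = ((x - mu) ** 2 * w).sum() / tot
    return float(np.clip(math.sqrt(max(var, 0.0)), *SIGMA_BOUNDS))


def fit_isolated(track: CoverageTrack, mode: PeakMode,
                 window: int = DEFAULT_FIT_WINDOW) -> FittedPeak:
    """Least-squares single-Gaussian fit of the raw counts around a mode."""
    lo = max(0, mode.position - window)
    hi = min(len(track.counts), mode.position + window + 1)
    x = np.arange(lo, hi, dtype=float)
    y = track.counts[lo:hi].astype(float)
    sd0 = _empirical_sd(x, y)
    a0 = max(y.max(), 1.0)
    try:
        (amp, mu, sigma), _ = optimize.curve_fit(
            _gaussian, x, y,
            p0=[a0, float(mode.position), sd0],
            bounds=([0.0, lo, SIGMA_BOUNDS[0]],
                    [np.inf, hi - 1, SIGMA_BOUNDS[1]]),
            maxfev=2000,
        )
        ok = True
    except RuntimeError:
        amp, mu, sigma, ok = a0, float(mode.position), sd0, False
    return FittedPeak(float(mu), float(sigma), 1.0, float(amp), "isolated",
                      raw_reads=mode.raw_reads, in_utr=mode.in_utr,
                      converged=ok)


def fit_cluster_em(
    track: CoverageTrack,
    cluster: list[PeakMode],
    window: int = DEFAULT_FIT_WINDOW,
    sigma_init: float = 50.0,
    tol: float = 1e-4,
    max_iter: int = 200,
    weight_floor: float = 1e-3,
    return_trace: bool = False,
):
    """K-component Gaussian mixture fit of an overlapped peak cluster.

    Per-base counts are treated as weighted position observations and the
    mixture is fit by EM, with component means initialized at the raw
    modes, a common initial spread and equal weights.  Convergence is a
    relative log-likelihood change below ``tol``.  A collapsing component
    (spread at the lower clamp with negligible weight) is removed and the
    cluster refit with K-1 components.
    """
    K = len(cluster)
    lo = max(0, min(m.position for m in cluster) - window)
    hi = min(len(track.counts), max(m.position for m in cluster) + window + 1)
    x = np.arange(lo, hi, dtype=float)
    w = track.counts[lo:hi].astype(float)
    keep = w > 0
    x, w = x[keep], w[keep]
    total = w.sum()
    if total <= 0 or K == 0:
        return ([], []) if return_trace else []

    mu = np.array([float(m.position) for m in cluster])
    sigma = np.full(K, float(sigma_init))
    pi = np.full(K, 1.0 / K)
    trace: list[float] = []
    converged = True
    for _ in range(max_iter):
        # E-step: responsibilities from weighted Gaussian densities
        dens = (pi / (sigma * math.sqrt(2 * math.pi)))[None, :] * np.exp(
            -0.5 * ((x[:, None] - mu[None, :]) / sigma[None, :]) ** 2
        )
        row = dens.sum(axis=1)
        row = np.maximum(row, 1e-300)
        ll = float((w * np.log(row)).sum())
        if trace and abs(ll - trace[-1]) <= tol * abs(trace[-1]):
            trace.append(ll)
            break
        trace.append(ll)
        resp = dens / row[:, None]
        # M-step
        nk = (w[:, None] * resp).sum(axis=0)
        nk = np.maximum(nk, 1e-300)
        pi = nk / total
        mu = (w[:, None] * resp * x[:, None]).sum(axis=0) / nk
        var = (w[:, None] * resp * (x[:, None] - mu[None, :]) ** 2).sum(axis=0) / nk
        sigma = np.clip(np.sqrt(np.maximum(var, 0.0)), *SIGMA_BOUNDS)
    else:
        converged = False

    collapsed = (sigma <= SIGMA_BOUNDS[0] + 1e-9) & (pi < weight_floor)
    if collapsed.any() and K > 1:
        survivors = [c for c, bad in zip(cluster, collapsed) if not bad]
        peaks = fit_cluster_em(track, survivors, window, sigma_init, tol,
                               max_iter, weight_floor)
        for p in peaks:
            p.converged = False
        return (peaks, trace) if return_trace else peaks

    order = np.argsort(mu)
    peaks = []
    for rank, k in enumerate(order):
        m = cluster[k]
        peaks.append(FittedPeak(
            float(mu[k]), float(sigma[k]), float(pi[k]),
            float(pi[k] * total), "overlapped",
            raw_reads=m.raw_reads, in_utr=m.in_utr, converged=converged,
        ))
    return (peaks, trace) if return_trace else peaks


# ---------------------------------------------------------------------------
# Gene-level driver and peak tables
# ---------------------------------------------------------------------------

PEAK_COLUMNS = [
    "gene_id", "peak_id", "chrom", "strand", "region_start", "region_end",
    "mu", "sigma", "weight", "amplitude", "kind", "cluster_id", "raw_reads",
    "converged",
]


def call_gene_peaks(
    track: CoverageTrack,
    bandwidth: float = DEFAULT_BANDWIDTH,
    min_reads: int = DEFAULT_MIN_READS,
    min_frac: float = DEFAULT_MIN_FRAC,
    merge_dist: int = DEFAULT_MERGE_DIST,
    cluster_radius: int = DEFAULT_CLUSTER_RADIUS,
    window: int = DEFAULT_FIT_WINDOW,
) -> list[FittedPeak]:
    """Detect, filter, cluster and fit a gene's peaks.

    Extra-UTR modes are kept through cluster fitting and removed afterwards
    (a fitted peak whose mean lies outside the extended UTR mask is
    dropped).
    """
    curve = smooth_coverage(track.counts, bandwidth)
    modes = detect_modes(curve, track.in_utr)
    attribute_reads_to_modes(modes, track.rep_offsets)
    modes = filter_and_merge_modes(modes, min_reads, min_frac, merge_dist,
                                   keep_outside=True, in_utr=track.in_utr)
    attribute_reads_to_modes(modes, track.rep_offsets)
    fitted: list[FittedPeak] = []
    for cid, cluster in enumerate(cluster_modes(modes, cluster_radius)):
        if len(cluster) == 1:
            peak = fit_isolated(track, cluster[0], window)
            peak.cluster_id = cid
            fitted.append(peak)
        else:
            for p in fit_cluster_em(track, cluster, window):
                p.cluster_id = cid
                fitted.append(p)
    kept = []
    for p in fitted:
        idx = int(np.clip(round(p.mu), 0, len(track.in_utr) - 1))
        if track.in_utr[idx]:
            kept.append(p)
    return kept


def call_peaks(bam, models: list[GeneModel], **params) -> pd.DataFrame:
    """Run peak calling over all genes; returns the peak table.

    ``mu`` in the table is genomic; rows are in transcription order within
    each gene.
    """
    cov_params = {k: params.pop(k) for k in ("cb_tag", "ub_tag", "min_mapq")
                  if k in params}
    rows = []
    for gene in models:
        track = build_coverage(bam, gene, **cov_params)
        if track.n_umis == 0:
            continue
        for i, p in enumerate(call_gene_peaks(track, **params)):
            rows.append({
                "gene_id": gene.gene_id,
                "peak_id": f"{gene.gene_id}:P{i + 1}",
                "chrom": track.region.chrom,
                "strand": track.strand,
                "region_start": track.region.start,
                "region_end": track.region.end,
                "mu": track.offset_to_genomic(p.mu),
                "sigma": p.sigma,
                "weight": p.weight,
                "amplitude": p.amplitude,
                "kind": p.kind,
                "cluster_id": p.cluster_id,
                "raw_reads": p.raw_reads,
                "converged": p.converged,
            })
    return pd.DataFrame(rows, columns=PEAK_COLUMNS)


def peak_mu_offset(row, length=None) -> float:
    """Transcription-direction offset of a peak-table row's mode."""
    if row["strand"] == "+":
        return row["mu"] - row["region_start"]
    return row["region_end"] - 1 - row["mu"]
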