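"""End-to-end orchestration: prepare -> callpeaks -> annotate -> count -> test.

Each stage reads the previous stage's files, so stages can be re-run
independently; :func:`run_pipeline` simply chains them.  The resolved
configuration is echoed into the output directory for provenance, and a
log records parameters and QC tallies.
"""

from __future__ import annotations

import dataclasses
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import annotation, differential, pa_filter, peaks, quantify

log = logging.getLogger("apamix")


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """All stage parameters with their documented defaults."""

    # inputs
    bam: str = ""
    gtf: str = ""
    pa_bed: str = ""
    fasta: str = ""
    barcodes: str = ""
    groups: str = ""
    taxonomy: str = ""
    out_dir: str = "apamix_out"
    # prepare
    utr_extension: int = 2000
    # callpeaks
    bandwidth: float = peaks.DEFAULT_BANDWIDTH
    min_reads: int = peaks.DEFAULT_MIN_READS
    min_frac: float = peaks.DEFAULT_MIN_FRAC
    merge_dist: int = peaks.DEFAULT_MERGE_DIST
    cluster_radius: int = peaks.DEFAULT_CLUSTER_RADIUS
    fit_window: int = peaks.DEFAULT_FIT_WINDOW
    min_mapq: int = peaks.DEFAULT_MIN_MAPQ
    cb_tag: str = "CB"
    ub_tag: str = "UB"
    # annotate
    min_controls: int = pa_filter.DEFAULT_MIN_CONTROLS
    sid_override: tuple[float, float] | None = None
    pas_shift: int = pa_filter.DEFAULT_PAS_SHIFT
    a_stretch: int = pa_filter.DEFAULT_A_STRETCH
    # test
    alpha: float = 0.05
    min_expr_frac: float = 0.05
    min_mpro: float = 0.2
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        import yaml
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if isinstance(data.get("sid_override"), list):
            data["sid_override"] = tuple(data["sid_override"])
        return cls(**data)

    def echo(self, out_dir: str) -> None:
        import yaml
        os.makedirs(out_dir, exist_ok=True)
        data = dataclasses.asdict(self)
        if data["sid_override"] is not None:
            data["sid_override"] = list(data["sid_override"])
        with open(os.path.join(out_dir, "config_used.yaml"), "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


def _require(path: str, what: str, stage: str) -> str:
    if not path:
        raise StageError(stage, f"no {what} given (see --{what.replace('_', '-')})")
    if not os.path.exists(path):
        raise StageError(stage, f"{what} file not found: {path}")
    return path


def load_models(cfg: RunConfig):
    _require(cfg.gtf, "gtf", "prepare")
    models = annotation.load_gene_models(cfg.gtf)
    return annotation.extend_utrs(models, cfg.utr_extension)


def stage_callpeaks(cfg: RunConfig, models=None) -> pd.DataFrame:
    import pysam
    _require(cfg.bam, "bam", "callpeaks")
    models = models if models is not None else load_models(cfg)
    with pysam.AlignmentFile(cfg.bam) as bam:
        table = peaks.call_peaks(
            bam, models, bandwidth=cfg.bandwidth, min_reads=cfg.min_reads,
            min_frac=cfg.min_frac, merge_dist=cfg.merge_dist,
            cluster_radius=cfg.cluster_radius, window=cfg.fit_window,
            cb_tag=cfg.cb_tag, ub_tag=cfg.ub_tag, min_mapq=cfg.min_mapq,
        )
    log.info("callpeaks: %d peaks in %d genes", len(table),
             table["gene_id"].nunique() if len(table) else 0)
    return table


def stage_annotate(cfg: RunConfig, peak_table: pd.DataFrame) -> pd.DataFrame:
    import pyfaidx
    _require(cfg.pa_bed, "pa_bed", "annotate")
    _require(cfg.fasta, "fasta", "annotate")
    pa_sites = annotation.load_pa_reference(cfg.pa_bed)
    fasta = pyfaidx.Fasta(cfg.fasta)
    if cfg.sid_override is not None:
        lo, hi = cfg.sid_override
        sid = pa_filter.SID(lo, hi, (lo + hi) / 2.0, 0)
        log.info("annotate: SID override (%.1f, %.1f)", lo, hi)
    else:
        sid = pa_filter.estimate_sid(peak_table, pa_sites, cfg.min_controls)
        log.info("annotate: SID (%.1f, %.1f) from %d controls",
                 sid.lower, sid.upper, sid.n_controls)
    annotated = pa_filter.annotate_peaks(
        peak_table, sid, pa_sites, fasta,
        pas_shift=cfg.pas_shift, a_stretch=cfg.a_stretch,
    )
    n_kept = int((annotated["status"] == pa_filter.STATUS_RETAINED).sum())
    log.info("annotate: %d/%d peaks retained", n_kept, len(annotated))
    return annotated


def stage_count(cfg: RunConfig, annotated: pd.DataFrame, models=None
                ) -> quantify.PeakCellMatrix:
    import pysam
    _require(cfg.bam, "bam", "count")
    _require(cfg.barcodes, "barcodes", "count")
    with open(cfg.barcodes) as fh:
        barcodes = [line.strip() for line in fh if line.strip()]
    if not barcodes:
        raise StageError("count", f"barcode file {cfg.barcodes} is empty")
    models = models if models is not None else load_models(cfg)
    with pysam.AlignmentFile(cfg.bam) as bam:
        pcm = quantify.build_matrix(
            bam, models, annotated, barcodes,
            cb_tag=cfg.cb_tag, ub_tag=cfg.ub_tag, min_mapq=cfg.min_mapq,
        )
    qc = pcm.qc
    log.info("count: %d UMIs observed, %d assigned, %d unassigned, "
             "%d dropped (missing tags)", qc.n_observed, qc.n_assigned,
             qc.n_unassigned, qc.n_dropped_tags)
    return pcm


def stage_test(cfg: RunConfig, pcm: quantify.PeakCellMatrix) -> pd.DataFrame:
    _require(cfg.groups, "groups", "test")
    groups = pd.read_csv(cfg.groups, sep="\t", header=None,
                         index_col=0).iloc[:, 0]
    thresholds = differential.SignalThresholds(
        cfg.alpha, cfg.min_expr_frac, cfg.min_mpro)
    if cfg.taxonomy:
        tree = differential.TaxonomyTree.from_tsv(cfg.taxonomy)
        results = differential.hierarchical_tests(pcm, groups, tree,
                                                  thresholds)
    else:
        results = differential.run_comparison(pcm, groups,
                                              thresholds=thresholds)
    log.info("test: %d genes tested, %d significant", len(results),
             int(results["significant"].sum()) if len(results) else 0)
    return results


def cell_warm_table(pcm: quantify.PeakCellMatrix) -> pd.DataFrame:
    """Per-cell average WARM over multipeak genes (equal weighting)."""
    counts = np.asarray(pcm.matrix.todense())
    gene_index = pcm.peaks["gene_id"].to_numpy()
    positions = {}
    for gene_id, sub in pcm.peaks.groupby("gene_id"):
        positions[gene_id] = np.sort(
            differential.peak_transcription_positions(sub))
    warm = differential.compute_cell_warm(counts, gene_index, positions)
    return pd.DataFrame({"barcode": pcm.barcodes, "cell_warm": warm})


def run_pipeline(cfg: RunConfig) -> str:
    """Run all stages in order; returns the output directory."""
    out = cfg.out_dir
    os.makedirs(out, exist_ok=True)
    cfg.echo(out)
    models = load_models(cfg)

    peak_table = stage_callpeaks(cfg, models)
    peak_table.to_csv(os.path.join(out, "peaks.tsv"), sep="\t", index=False)

    annotated = stage_annotate(cfg, peak_table)
    annotated.to_csv(os.path.join(out, "annotated_peaks.tsv"), sep="\t",
                     index=False)
    pa_filter.assigned_pa_bed(annotated).to_csv(
        os.path.join(out, "assigned_pa.bed"), sep="\t", index=False,
        header=False)

    pcm = stage_count(cfg, annotated, models)
    quantify.write_matrix(pcm, os.path.join(out, "matrix"))
    cell_warm_table(pcm).to_csv(os.path.join(out, "cell_warm.tsv"), sep="\t",
                                index=False)

    if cfg.groups:
        results = stage_test(cfg, pcm)
        results.to_csv(os.path.join(out, "results.tsv"), sep="\t",
                       index=False)
    return out
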