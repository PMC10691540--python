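"""Simulate a small 3'-end dataset and call polyadenylation peaks.

Builds a ground-truthed synthetic genome/BAM (8 genes, 2-3 cleavage sites
each), runs coverage -> smoothing -> mode detection -> Gaussian fitting,
and compares the fitted peak modes with the planted truth.
"""

import tempfile

import pandas as pd

from apamix.pipeline import RunConfig, stage_callpeaks
from apamix.simulate import SimConfig, simulate_dataset

with tempfile.TemporaryDirectory() as tmp:
    config = SimConfig(seed=11, n_genes=8, cells_per_group=40,
                       ip_gene_fraction=0.0, denovo_gene_fraction=0.0)
    paths, truth = simulate_dataset(config, tmp)

    cfg = RunConfig(bam=paths["bam"], gtf=paths["gtf"])
    peaks = stage_callpeaks(cfg)

    gt = truth.reference.gene_truth()
    print(f"planted PA sites : {len(gt)}")
    print(f"fitted peaks     : {len(peaks)}")
    print(peaks[["gene_id", "peak_id", "mu", "sigma", "kind",
                 "raw_reads"]].head(8).to_string(index=False))

    merged = peaks.sort_values(["gene_id", "mu"]).reset_index(drop=True)
    gt_sorted = gt.sort_values(["gene_id", "expected_mode"]
                               ).reset_index(drop=True)
    if len(merged) == len(gt_sorted):
        err = (merged["mu"] - gt_sorted["expected_mode"]).abs()
        print(f"mean |mode error|: {err.mean():.2f} bp "
              f"(each peak mode sits ~100 bp upstream of its cleavage site)")
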