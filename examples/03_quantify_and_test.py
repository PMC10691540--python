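"""Quantify peaks per cell and test for differential PA between groups.

Plants a proximal-to-distal usage shift between the two cell groups
(Dirichlet alpha (8,2) vs (2,8) for two-peak genes), then runs the full
pipeline and the combined chi-square + Dirichlet-multinomial test.
"""

import tempfile

import numpy as np
import pandas as pd

from apamix.pipeline import RunConfig, run_pipeline
from apamix.simulate import SimConfig, simulate_dataset


def shifted_alpha(config, group, n_peaks):
    """Two-peak genes get opposite usage in the two groups."""
    if n_peaks == 2:
        return np.array([8.0, 2.0]) if group == "base" else np.array([2.0, 8.0])
    return np.full(n_peaks, config.alpha_precision / n_peaks)


with tempfile.TemporaryDirectory() as tmp:
    config = SimConfig(seed=31, n_genes=10, cells_per_group=80,
                       umi_mean=12.0, ip_gene_fraction=0.0,
                       denovo_gene_fraction=0.0)
    paths, truth = simulate_dataset(config, f"{tmp}/sim",
                                    alpha_fn=shifted_alpha)

    cfg = RunConfig(bam=paths["bam"], gtf=paths["gtf"],
                    pa_bed=paths["pa_bed"], fasta=paths["fasta"],
                    barcodes=paths["barcodes"], groups=paths["groups"],
                    out_dir=f"{tmp}/run", sid_override=(70.0, 130.0))
    out = run_pipeline(cfg)

    results = pd.read_csv(f"{out}/results.tsv", sep="\t")
    two_peak = results[results["n_peaks"] == 2]
    print(results[["gene_id", "n_peaks", "base_group", "p_adj", "warm_base",
                   "warm_alt", "mpro", "significant"]].to_string(index=False))
    print()
    print(f"{int(results['significant'].sum())} of "
          f"{len(results)} multipeak genes called significant.")
    print("MPRO is oriented by 'base_group' (first label alphabetically: "
          "'alt' here).  The 'alt' cells favour the distal peak, so the "
          "oracle MPRO in this orientation is +1.2, and WARM(base) ~ 0.2 "
          "vs WARM(alt) ~ 0.8: 'base' cells use shorter 3' UTRs.")
    print(f"measured: mean two-peak MPRO = {two_peak['mpro'].mean():.3f}")
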