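"""Per-gene coverage/peak reports: a figure plus its TSV twin.

Every number in a figure is also emitted as a TSV so figures are never
the only record of a result.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .pa_filter import STATUS_RETAINED
from .peaks import CoverageTrack, smooth_coverage


def render_gene_report(gene_id: str, track: CoverageTrack,
                       annotated: pd.DataFrame, out_dir: str,
                       bandwidth: float = 25.0) -> dict[str, str]:
    """Coverage curve, smoothed curve, peak regions and PA ticks.

    ``annotated`` is the annotated-peak table restricted or not; rows for
    other genes are ignored.  Discarded peaks are drawn hatched/grey with
    their discard reason.  Returns the written file paths.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    os.makedirs(out_dir, exist_ok=True)
    rows = annotated[annotated["gene_id"] == gene_id]
    x_genomic = (np.arange(len(track.counts))
                 if track.strand == "+" else
                 np.arange(len(track.counts))[::-1]) + track.region.start
    smoothed = smooth_coverage(track.counts, bandwidth)

    tsv_path = os.path.join(out_dir, f"{gene_id}_coverage.tsv")
    pd.DataFrame({
        "position": x_genomic,
        "coverage": track.counts,
        "smoothed": smoothed,
    }).to_csv(tsv_path, sep="\t", index=False)

    fig, ax = plt.subplots(figsize=(10, 3.2))
    if track.counts.sum() == 0:
        ax.text(0.5, 0.5, f"{gene_id}: no coverage", ha="center",
                va="center", transform=ax.transAxes)
    else:
        ax.fill_between(x_genomic, track.counts, step="mid", alpha=0.4,
                        color="#7f9ecf", label="UMI coverage")
        ax.plot(x_genomic, smoothed, color="#1f4e96", lw=1.2,
                label="smoothed")
        for _, row in rows.iterrows():
            retained = row["status"] == STATUS_RETAINED
            lo, hi = row["mu"] - 3 * row["sigma"], row["mu"] + 3 * row["sigma"]
            ax.axvspan(lo, hi, alpha=0.25 if retained else 0.12,
                       color="#58a86c" if retained else "#999999",
                       hatch=None if retained else "//")
            if not retained:
                ax.text(row["mu"], ax.get_ylim()[1] * 0.9,
                        row["status"].replace("discarded_", ""),
                        ha="center", fontsize=7, color="#555555")
            if retained and row["pa_pos"] >= 0:
                ax.axvline(row["pa_pos"], color="#c23b3b", lw=1.5)
        ax.legend(loc="upper right", fontsize=8)
    ax.set_xlabel(f"{track.region.chrom} position ({track.strand} strand)")
    ax.set_ylabel("deduplicated UMI coverage")
    ax.set_title(gene_id)
    fig_path = os.path.join(out_dir, f"{gene_id}_report.png")
    fig.tight_layout()
    fig.savefig(fig_path, dpi=120)
    plt.close(fig)
    return {"figure": fig_path, "tsv": tsv_path}
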