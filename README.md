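# apamix

Alternative-polyadenylation (APA) analysis for 3'-end barcoded single-cell
and spatial transcriptomics (10x Chromium / Visium-style libraries, BAM
files with `CB`/`UB` tags).

Most scRNA-seq protocols sequence the 3' end of each transcript, so the
read pileup near a gene's 3' UTR encodes *which* polyadenylation site (PA)
each molecule used.  `apamix` turns coordinate-sorted tagged alignments
into PA-level biology in four steps:

1. **Peak calling** — per-gene, per-base deduplicated-UMI coverage over the
   extended 3'-UTR region is smoothed with a Gaussian kernel; local maxima
   are candidate peak modes.  Minor modes (<10 UMIs or ≤5% of the largest
   mode) are dropped and modes within 50 bp are merged.  Isolated modes are
   fit as single Gaussians by least squares; modes with a neighbour within
   300 bp are fit jointly with a K-component Gaussian mixture by EM,
   deconvolving overlapping cleavage-site pileups.
2. **PA annotation and filtering** — the signed peak-mode-to-cleavage-site
   distance interval (SID: 5%–95% quantiles) is learned from genes with one
   known PA and one peak.  A peak is retained iff it has a known PA in the
   SID (rule 1) **or** a polyadenylation-signal hexamer (AATAAA family) in
   the SID window shifted 20 bp upstream (rule 2), **and** no run of ≥13
   genomic adenosines in the SID (rule 3, the internal-priming signature of
   oligo(dT) mispriming).  Peaks passing via rule 2 alone become *de novo*
   PAs.
3. **Quantification** — every deduplicated UMI (median-location
   representative per cell×UMI) is assigned to the peak region μ±3σ it
   overlaps, ambiguous overlaps resolved by the mixture posterior
   w·N(x|μ,σ), yielding a sparse peak-by-cell count matrix (MatrixMarket).
4. **Differential testing** — per multipeak gene, a Pearson chi-square test
   on the pooled group×peak table is combined (max-p) with a
   Dirichlet-multinomial likelihood-ratio test that absorbs within-group
   overdispersion (cell usage p_i ~ Dirichlet(α_k); H₀: α₁=…=α_K,
   Λ ~ χ²((K−1)J)).  Effect sizes: **WARM**, the count-weighted average
   relative mode position (proximal=0, distal=1; higher = longer 3' UTRs),
   and **MPRO**, the most extreme downstream-minus-upstream difference in
   per-peak proportion change between two groups.  A gene is a final signal
   when BH-adjusted p ≤ 0.05, each group expresses a peak in >5% of cells,
   and |MPRO| > 0.2.  Tests can run over a cell-type taxonomy tree
   (each node vs the rest of its parent).

A fully synthetic, ground-truthed generator (`apamix.simulate`) emits
genome FASTA, GTF, known-PA BED, tagged BAM and truth tables, so every
stage is testable without downloads.

## Worked example

`examples/03_quantify_and_test.py` plants a proximal↔distal usage swap
between two cell groups (Dirichlet α=(8,2) vs (2,8) on two-peak genes,
80 cells/group), runs the full pipeline, and prints:

```
gene_id  n_peaks base_group        p_adj  warm_base  warm_alt      mpro  significant
   G003        2        alt 3.559733e-43   0.168410  0.778564  1.220308         True
   G004        2        alt 1.143608e-38   0.232892  0.813520  1.161256         True
   G005        3        alt 8.156358e-01   0.467226  0.487338  0.040244        False
...
5 of 10 multipeak genes called significant.
measured: mean two-peak MPRO = 1.188
```

Reading: every planted two-peak shift gene (and no symmetric three-peak
gene) is called.  WARM ≈ 0.2 vs 0.8 says one group's molecules sit near the
proximal peak and the other's near the distal peak; MPRO ≈ +1.2 matches the
enumeration oracle on the planted Dirichlet means ((0.8,0.2) vs (0.2,0.8)
→ δ = (−0.6,+0.6) in this orientation, distal−proximal = +1.2; for J=2
MPRO ranges over [−2,2]).

The other examples cover peak calling against planted truth
(`01_simulate_and_call_peaks.py`), the three-rule internal-priming filter
(`02_annotate_and_filter.py`) and hierarchical taxonomy testing
(`04_hierarchical_taxonomy_test.py`).

## Command line

A thin CLI wraps the library:

```bash
apamix simulate  --seed 3 --n-genes 20 --out-dir sim/
apamix run-all   --bam sim/reads.bam --gtf sim/annotation.gtf \
                 --pa-bed sim/known_pa.bed --fasta sim/genome.fa \
                 --barcodes sim/barcodes.tsv --groups sim/groups.tsv \
                 --out-dir run/
apamix report    --gene G001 --bam sim/reads.bam --gtf sim/annotation.gtf \
                 --peaks run/annotated_peaks.tsv --out-dir run/
```

Stages (`callpeaks`, `annotate`, `count`, `test`) also run individually and
exchange plain TSV/BED/MatrixMarket files.  Exit codes: 0 success, 2 input
error, 3 stage failure.

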