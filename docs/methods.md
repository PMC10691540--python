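# Methods

## Coordinates and orientation

All coordinates are 0-based half-open internally; GTF (1-based closed) is
converted exactly once at parse time and inverted once at write time, so
round-trips are byte-stable.  Per-gene coverage tracks are stored in
*transcription orientation* (index 0 = 5'-most base of the extended-UTR
span in the direction of transcription).  Minus-strand genes are flipped
once at track construction; every downstream window — SID intervals, PAS
windows, A-stretch scans — is then strand-free arithmetic on offsets.

## Peak search space

The search space for peaks is the annotated 3' UTR of each transcript
(from `three_prime_utr` features, else the last exon downstream of the
stop codon, else the whole last exon) extended downstream by
`utr_extension` (default 2000 bp) and truncated at the 5' start of the
nearest downstream *same-strand* gene.  Antisense neighbours never
truncate: 3'-end libraries are stranded, so antisense reads cannot be
confused with the gene's own.  The extension length is exposed because
annotation completeness varies by species and assembly.

## Coverage and deduplication

Reads failing the mapping-quality filter (default MAPQ ≥ 255, the
STAR/CellRanger unique-mapper convention) or missing `CB`/`UB` tags are
excluded (the latter QC-tallied).  Reads sharing (cell, UMI) within a gene
collapse to one representative: the read whose *location* — the midpoint
of its M-covered genomic span — is the lower median of the group's
locations.  Only the representative's M-aligned bases (CIGAR M; N/D gaps
excluded) increment coverage, so spliced reads contribute only where they
align.

## Peak detection and fitting

- **Smoothing**: discrete Gaussian kernel, bandwidth 25 bp (default).
  The kernel support is 8 bandwidths; a tightly truncated kernel can
  manufacture a spurious micro-mode exactly midway between two sparse
  spikes one support-width apart, which a wide support removes.  Mass is
  conserved except at region boundaries.
- **Modes**: strict local maxima of the smoothed curve; a flat plateau
  that is higher than both neighbours reports its center (floored).
  Array endpoints are never modes.
- **Mode-local read mass**: each mode's `raw_reads` is the number of
  deduplicated UMIs whose representative location is nearer to it than to
  any other mode (nearest-mode partition) — the simplest attribution
  consistent with a subsequent per-mode read filter.
- **Filter + merge**: modes with <10 UMIs or ≤5% of the largest in-UTR
  mode's UMIs are dropped; surviving modes within 50 bp merge pairwise
  left-to-right at the floored mean of the pair, read counts summing.
  The pass iterates to a fixed point: merging increases read counts and
  could re-trigger the relative-abundance rule, and a fixed point makes
  the operation idempotent (it differs from a single pass only in that
  edge case).
- **Clustering**: transitive closure of "within 300 bp"; singletons are
  isolated.
- **Isolated fit**: nonlinear least squares of A·exp(−(x−μ)²/2σ²) on the
  raw counts over mode ± 150 bp, initialized at the mode and the local
  empirical sd; non-convergence falls back to the initializer with a
  flag.
- **Cluster fit**: K-component Gaussian mixture on per-base counts
  treated as weighted position observations, fit by EM (means at the raw
  modes, common initial spread 50 bp, equal weights; convergence at
  relative log-likelihood change < 1e-4, ≤200 iterations).  The
  log-likelihood is non-decreasing by construction and asserted in tests.
  σ is clamped to [5, 350] bp in both fit paths; a component collapsing
  onto the clamp with weight < 1e-3 is removed and the cluster refit with
  K−1 components, flagged.  Modes outside the extended UTR are retained
  *through* cluster fitting (so boundary mixtures stay well conditioned)
  and their fitted components discarded afterwards.

## SID and the three-rule filter

Control genes have exactly one known PA inside their extended UTR and
exactly one detected peak.  Signed distances d = (PA − mode) in
transcription direction; the SID is the (5%, 95%) linear-interpolation
(type-7) quantile pair — signed, not absolute, because 3'-end peak modes
sit upstream of cleavage sites.  At least `min_controls` (default 50)
controls are required; small runs pass `--sid-override`.

For a peak with mode m:

- rule 1 — a known PA in [m+lower, m+upper];
- rule 2 — a PAS hexamer (AATAAA, ATTAAA and the ten variants TTTAAA,
  AAGAAA, AACAAA, TATAAA, AATGAA, AGTAAA, AATATA, CATAAA, ACTAAA,
  GATAAA; exact match, no weight matrix, and a plain A₆ run is *not* a
  signal) whose occurrence starts in the SID window translated 20 bp
  toward 5' — candidate cleavage positions lie in the SID, and the PAS
  sits ~20 bp upstream of a cleavage site;
- rule 3 — a run of ≥13 consecutive adenosines within the SID window
  itself (scanned literally within the window, not beyond it).

Retained ⇔ (rule 1 ∨ rule 2) ∧ ¬rule 3.  The assigned PA is the matched
known site (if several fall in the SID: the one nearest m + median control
distance, ties to the downstream site) or, for rule-2-only peaks, a de
novo site at m + median control distance.  Windows overrunning the
chromosome are clipped and flags computed on the available sequence.

## Quantification

Peak j claims [μⱼ−3σⱼ, μⱼ+3σⱼ].  A UMI representative overlapping exactly
one region (on M bases) is assigned there; overlapping several, to the
peak maximizing wₖ·N(x|μₖ,σₖ) at the representative location (isolated
peaks enter with weight 1; exact ties go downstream); overlapping none,
it is tallied unassigned.  Assignment uses the point location rather than
the covered span — the span already decided *eligibility*, the posterior
only arbitrates.  Conservation (assigned + unassigned + tag-dropped =
observed) is asserted in tests.  Spot barcodes from spatial data are
treated exactly as cell barcodes.

## Differential testing

For gene g with J ≥ 2 retained peaks (only multipeak genes are eligible),
cell i's counts X_i are multinomial(n_i, p_i).

- **Chi-square**: Pearson test on the pooled K×J group-by-peak table
  (zero rows/columns dropped, df adjusted; degenerate tables return p=1
  flagged).  The pooled table is the natural aggregation for a
  homogeneity test; cell-level score tests are a different design and
  out of scope here.
- **Dirichlet-multinomial LRT**: p_i ~ Dirichlet(α_k) within group k;
  H₀: α₁=…=α_K.  α is estimated by the digamma fixed-point iteration
  (moment-based start, tolerance 1e-6 on the max relative change, ≤500
  iterations, components clamped to [1e-8, 1e6]; clamp hits — e.g. all
  counts on one peak, where the MLE is unbounded — flag a boundary fit).
  Cells with n_i = 0 carry no information about p_i and are excluded.
  Λ = 2(Σₖ llₖ − ll_pooled) is referred to χ² with (K−1)·J df (each
  group contributes one free J-vector α).  The multinomial coefficient
  is omitted from the log-likelihood; it cancels in every ratio used.
- **Combination**: p = max(p_chisq, p_dm) — a call requires both the
  pooled proportions and the DM parameters to differ, which restores
  calibration under overdispersion where chi-square alone is badly
  anti-conservative (measured in the acceptance suite: 0.05-level
  rejection ~0.44 for chi-square alone vs ~0.05 combined under a
  precision-3 Dirichlet null).  BH correction is applied across the
  genes of one comparison (per comparison, not across taxonomy levels,
  so each node's gene ranking is self-contained).

### Effect sizes

- **WARM** ∈ [0,1]: relative peak positions with proximal = 0 and distal
  = 1 — linear interpolation in genomic distance when all peaks share a
  3' UTR, rank-based spacing (rank−1)/(n−1) otherwise — averaged with
  per-peak read counts as weights.  The rank formula is chosen so the
  endpoint convention (0 and 1 exactly) holds for every n; an interior
  rank/n spacing cannot meet it.  Per-cell WARM averages gene-level WARM
  over expressed multipeak genes with equal or expression weights.
- **MPRO**: with δⱼ = (proportion in base) − (proportion in alt) per
  peak, MPRO is the dδ = δ_downstream − δ_upstream of largest magnitude
  over all ordered peak pairs, signed.  Positive ⇒ the base group uses
  more distal peaks.  For J = 2, MPRO = 2·δ_distal, so its range is
  [−2, 2] — deliberately *not* rescaled to [−1, 1]; the |MPRO| > 0.2
  significance threshold therefore corresponds to a 10% usage change for
  two-peak genes.

### Final signals and hierarchy

Significant ⇔ BH-adjusted p ≤ 0.05 (inclusive; configurable) ∧ each
group has ≥1 peak with nonzero counts in strictly >5% of its cells ∧
|MPRO| strictly > 0.2.  Over a taxonomy tree, each non-root node c is
tested against its parent's remaining cells (cells belong to c when
their leaf label is c or a descendant); nodes with an empty complement
are skipped.  A shift confined to deep siblings thus surfaces once, at
that node, instead of contaminating every ancestral comparison.

## Synthetic data

The generator emulates the pipeline's own generative assumptions — which
is exactly what makes it a *machinery* test, not a robustness benchmark:

- genes alternate strands along one chromosome, each with 2–3 cleavage
  sites 400 bp apart in the 3' UTR; AATAAA planted 26–21 bp upstream of
  every site;
- per cell per gene, n ~ NB(mean 8, size 10); peak choice multinomial
  with p ~ Dirichlet(α_group) (symmetric precision 15 by default; a
  caller-supplied `alpha_fn` plants group shifts);
- read 5' ends ~ Normal(cleavage − 145, σ=30), read length 91, so the
  coverage mode sits ~100 bp upstream of the cleavage site (the designed
  mode-to-PA distance the SID should learn); duplicates (rate 0.15) get
  ±2 bp jitter; a 2% spliced fraction gets a 30M200N61M CIGAR whose
  M-span midpoint equals the unspliced read's, exercising M-only
  counting without moving representatives;
- internal-priming genes (10%) carry a planted 15-adenosine stretch
  500 bp past their last PA with its own read pileup; de novo genes
  (10%) have their distal site withheld from the emitted BED; random
  sequence is scrubbed of runs of ≥8 adenosines *before* planting, so
  the only A-stretches are registered ones;
- truth tables record cleavage positions, expected modes, per-cell
  per-peak molecule counts (artifact reads excluded) and the planted
  artifact registry; the same seed reproduces FASTA/GTF/BED byte-for-byte
  and the read set exactly.

Not modelled: sequencing errors, barcode collisions, ambient RNA,
expression heterogeneity across genes, non-Gaussian peak shapes,
overlapping genes.  Passing tests on this data demonstrates correct
machinery under the stated model, not performance on real libraries.

The fixed problem sizes used by the test and acceptance suites (20-gene
end-to-end runs at 60 cells/group; 500 null genes and 50 power
replicates at the 200/300-cell count level) keep a full run in tens of
seconds while leaving every estimate's Monte-Carlo error well inside the
asserted tolerances.

## Known limitations

- The SID needs ≥50 single-PA–single-peak controls; tiny gene panels
  must supply `--sid-override`.
- Rule 3 scans only within the SID window; classic internal-priming
  filters sometimes scan further downstream of the apparent site.  The
  literal window is used here.
- Intronic PAs are found only insofar as they fall inside the extended
  UTR regions of an annotated transcript (e.g. alternative last exons
  with annotated 3' UTRs); no de novo intron-wide search is performed.
- The chi-square component uses the pooled contingency table; cell-level
  score tests are out of scope.
- BAM files are required to carry corrected barcode tags; no barcode
  whitelisting or correction is performed.
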