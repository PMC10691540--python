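"""Peak annotation and internal-priming filtering.

A detected coverage peak sits upstream of the cleavage site it reports
(3'-end reads start upstream of the poly(A) junction), so the peak
mode-to-cleavage-site distance must be learned from the data.  Genes with
exactly one known PA and exactly one detected peak serve as controls; the
5% and 95% quantiles of their signed mode-to-PA distances define the
standard interval of distances (SID).

Three rules then classify each peak:

1. a known annotated PA lies within the SID downstream of the mode;
2. a polyadenylation-signal hexamer occurs in the SID window shifted
   20 bp upstream (the PAS sits ~20 bp upstream of the cleavage site);
3. a run of >= 13 consecutive adenosines (an A-stretch) lies within the
   SID — the signature of oligo(dT) priming on genomic A-rich sequence
   rather than on a real poly(A) tail.

A peak is retained iff (rule 1 or rule 2) and not rule 3.  Retained peaks
get an assigned cleavage site: the matched known PA, or a de novo site
placed the median control distance downstream of the mode.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotation import GenomicInterval, KnownPA, fetch_sequence

#: The canonical A[A/T]TAAA polyadenylation signals and their ten
#: single-base variants.  A plain A6 run is deliberately not a signal.
PAS_HEXAMERS = (
    "AATAAA", "ATTAAA", "TTTAAA", "AAGAAA", "AACAAA", "TATAAA",
    "AATGAA", "AGTAAA", "AATATA", "CATAAA", "ACTAAA", "GATAAA",
)

DEFAULT_A_STRETCH = 13
DEFAULT_PAS_SHIFT = 20
DEFAULT_MIN_CONTROLS = 50

STATUS_RETAINED = "retained"
STATUS_INTERNAL_PRIMING = "discarded_internal_priming"
STATUS_NO_EVIDENCE = "discarded_no_evidence"


@dataclass(frozen=True)
class SID:
    """Standard interval of signed peak-mode-to-PA distances (bp)."""

    lower: float
    upper: float
    median: float
    n_controls: int = 0

    def __post_init__(self):
        if self.lower > self.upper:
            raise ValueError("SID lower bound exceeds upper bound")

    @property
    def width(self) -> float:
        return self.upper - self.lower


class TooFewControlsError(ValueError):
    pass


def estimate_sid(
    peaks: pd.DataFrame,
    pa_sites: list[KnownPA],
    min_controls: int = DEFAULT_MIN_CONTROLS,
) -> SID:
    """Estimate the SID from single-PA-single-peak control genes.

    ``peaks`` is a peak table (see :mod:`apamix.peaks`).  A gene qualifies
    as a control when exactly one known PA falls inside its extended-UTR
    region and exactly one peak was detected.  Distances are signed in the
    transcription direction (positive = PA downstream of the mode) and the
    SID is the 5%/95% linear-interpolation quantile pair.
    """
    distances = []
    for gene_id, sub in peaks.groupby("gene_id", sort=True):
        if len(sub) != 1:
            continue
        row = sub.iloc[0]
        region = GenomicInterval(row["chrom"], int(row["region_start"]),
                                 int(row["region_end"]), row["strand"])
        in_gene = [p for p in pa_sites
                   if p.strand == region.strand and p.chrom == region.chrom
                   and region.contains(p.position)]
        if len(in_gene) != 1:
            continue
        pa = in_gene[0]
        if region.strand == "+":
            d = pa.position - row["mu"]
        else:
            d = row["mu"] - pa.position
        distances.append(float(d))
    if len(distances) < min_controls:
        raise TooFewControlsError(
            f"only {len(distances)} single-PA-single-peak control genes "
            f"(need {min_controls}); supply an explicit SID via "
            f"sid_override / --sid-override"
        )
    arr = np.asarray(distances)
    lo, hi = np.quantile(arr, [0.05, 0.95])
    return SID(float(lo), float(hi), float(np.median(arr)), len(arr))


# ---------------------------------------------------------------------------
# Sequence scans
# ---------------------------------------------------------------------------

def scan_pas_motifs(seq: str) -> list[tuple[str, int]]:
    """All (possibly overlapping) PAS hexamer occurrences in ``seq``.

    ``seq`` must be in transcription orientation.  ``N`` never matches;
    other non-nucleotide characters are rejected.
    """
    seq = seq.upper()
    if re.search(r"[^ACGTN]", seq):
        raise ValueError("sequence contains characters outside ACGTN")
    hits = []
    for i in range(len(seq) - 5):
        hexamer = seq[i:i + 6]
        if hexamer in PAS_HEXAMERS:
            hits.append((hexamer, i))
    return hits


def detect_a_stretch(seq: str, min_len: int = DEFAULT_A_STRETCH
                     ) -> tuple[bool, tuple[int, int] | None]:
    """First run of >= ``min_len`` consecutive adenosines, if any."""
    m = re.search("A{%d,}" % min_len, seq.upper())
    if m:
        return True, (m.start(), m.end())
    return False, None


# ---------------------------------------------------------------------------
# Rule application
# ---------------------------------------------------------------------------

ANNOT_COLUMNS = [
    "rule1_known_pa", "rule2_pas_motif", "rule3_a_stretch", "status",
    "pa_pos", "pa_provenance", "matched_pa_source", "pas_motif",
    "pas_motif_pos", "a_stretch_start", "a_stretch_end",
]


def annotate_peaks(
    peaks: pd.DataFrame,
    sid: SID,
    pa_sites: list[KnownPA],
    fasta,
    pas_shift: int = DEFAULT_PAS_SHIFT,
    a_stretch: int = DEFAULT_A_STRETCH,
) -> pd.DataFrame:
    """Apply the three filtering rules to a peak table.

    Returns a copy of ``peaks`` with rule flags, retention status and the
    assigned PA.  Windows run in the transcription direction from each
    mode; sequence windows that overrun the chromosome are clipped and the
    flags computed on the available sequence.
    """
    lower, upper = int(np.floor(sid.lower)), int(np.ceil(sid.upper))
    med = int(round(sid.median))
    by_pos: dict[tuple[str, str], np.ndarray] = {}
    site_index: dict[tuple[str, str], list[KnownPA]] = {}
    for p in pa_sites:
        site_index.setdefault((p.chrom, p.strand), []).append(p)
    for key, sites in site_index.items():
        sites.sort(key=lambda s: s.position)
        by_pos[key] = np.array([s.position for s in sites])

    out = peaks.copy()
    annot = {c: [] for c in ANNOT_COLUMNS}
    for _, row in peaks.iterrows():
        chrom, strand = row["chrom"], row["strand"]
        m = float(row["mu"])
        sign = 1 if strand == "+" else -1

        # --- rule 1: known PA within the SID
        positions = by_pos.get((chrom, strand), np.array([]))
        offsets = sign * (positions - m)
        in_sid = (offsets >= sid.lower) & (offsets <= sid.upper)
        matched = None
        if in_sid.any():
            cands = np.where(in_sid)[0]
            # nearest to the expected cleavage position; ties -> downstream
            dist = np.abs(offsets[cands] - sid.median)
            best = cands[np.lexsort((-offsets[cands], dist))][0]
            matched = site_index[(chrom, strand)][best]
        rule1 = matched is not None

        # --- rule 2: PAS hexamer in the SID window shifted 20 bp upstream
        pas_window = _window_seq(fasta, chrom, strand, m,
                                 lower - pas_shift, upper - pas_shift, pad=5)
        hits = [(h, off) for h, off in scan_pas_motifs(pas_window)
                if off <= upper - lower]
        rule2 = bool(hits)

        # --- rule 3: A-stretch within the SID
        sid_window = _window_seq(fasta, chrom, strand, m, lower, upper)
        rule3, stretch = detect_a_stretch(sid_window, a_stretch)

        if (rule1 or rule2) and not rule3:
            status = STATUS_RETAINED
        elif rule3:
            status = STATUS_INTERNAL_PRIMING
        else:
            status = STATUS_NO_EVIDENCE

        if status == STATUS_RETAINED:
            if rule1:
                pa_pos, provenance = matched.position, "known"
                source = matched.source
            else:
                pa_pos, provenance = int(round(m)) + sign * med, "de_novo"
                source = ""
        else:
            pa_pos, provenance, source = -1, "", ""

        annot["rule1_known_pa"].append(rule1)
        annot["rule2_pas_motif"].append(rule2)
        annot["rule3_a_stretch"].append(rule3)
        annot["status"].append(status)
        annot["pa_pos"].append(pa_pos)
        annot["pa_provenance"].append(provenance)
        annot["matched_pa_source"].append(source)
        annot["pas_motif"].append(hits[0][0] if hits else "")
        annot["pas_motif_pos"].append(hits[0][1] + lower - pas_shift if hits else 0)
        annot["a_stretch_start"].append(stretch[0] + lower if stretch else 0)
        annot["a_stretch_end"].append(stretch[1] + lower if stretch else 0)
    for c in ANNOT_COLUMNS:
        out[c] = annot[c]
    return out


def _window_seq(fasta, chrom, strand, mode_pos, lo, hi, pad=0):
    """Sequence of [mode+lo, mode+hi] (transcription offsets), oriented.

    ``pad`` extends the window downstream so that a hexamer *starting*
    inside it is fully visible to the scanner.
    """
    m = int(round(mode_pos))
    if strand == "+":
        iv = GenomicInterval(chrom, max(0, m + lo), m + hi + 1 + pad, "+")
    else:
        iv = GenomicInterval(chrom, max(0, m - hi - pad), m - lo + 1, "-")
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return fetch_sequence(fasta, iv)


def retention_status(rule1: bool, rule2: bool, rule3: bool) -> str:
    """The retention rule on explicit flags: (r1 or r2) and not r3."""
    if rule3:
        return STATUS_INTERNAL_PRIMING
    if rule1 or rule2:
        return STATUS_RETAINED
    return STATUS_NO_EVIDENCE


def assigned_pa_bed(annotated: pd.DataFrame) -> pd.DataFrame:
    """BED-like frame of assigned PAs for retained peaks."""
    kept = annotated[annotated["status"] == STATUS_RETAINED]
    return pd.DataFrame({
        "chrom": kept["chrom"],
        "start": kept["pa_pos"].astype(int),
        "end": kept["pa_pos"].astype(int) + 1,
        "name": kept["peak_id"],
        "score": 0,
        "strand": kept["strand"],
        "provenance": kept["pa_provenance"],
    })
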