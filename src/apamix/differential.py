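"""Differential polyadenylation testing across cell groups.

For a gene with J >= 2 retained peaks, the per-cell peak counts
X_i = (X_i1 .. X_iJ) are multinomial given the cell's usage proportions
p_i.  A plain chi-square homogeneity test on the pooled group-by-peak
table assumes p_i is constant within a group; real cells are
overdispersed, which inflates chi-square false positives.  The
Dirichlet-multinomial (DM) model absorbs that heterogeneity —
p_i ~ Dirichlet(alpha_k) within group k — and a likelihood-ratio test of
alpha_1 = ... = alpha_K detects group differences while tolerating
within-group noise.  The gene's final p-value is the maximum of the two
tests' p-values: a call requires both the pooled proportions and the DM
parameters to differ.

Two effect sizes summarize a two-group comparison:

* WARM — the count-weighted average relative mode position (proximal peak
  = 0, distal = 1); higher means longer-3'-UTR usage.
* MPRO — the most extreme downstream-minus-upstream difference in per-peak
  proportion change between the groups; positive means the base group
  uses more distal peaks.  For J = 2 its range is [-2, 2].

A gene is a final differential signal when the BH-adjusted combined
p-value passes, each group expresses at least one peak in more than 5% of
its cells, and |MPRO| > 0.2.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln, psi
from statsmodels.stats.multitest import multipletests

ALPHA_FLOOR = 1e-8
ALPHA_CAP = 1e6
DM_TOL = 1e-6
DM_MAX_ITER = 500


# ---------------------------------------------------------------------------
# Chi-square homogeneity test on the pooled table
# ---------------------------------------------------------------------------

def chisq_test(counts: np.ndarray, labels: np.ndarray) -> tuple[float, bool]:
    """Pearson chi-square on the pooled group-by-peak table.

    ``counts`` is cells x J; ``labels`` assigns each cell to a group.
    Rows/columns whose total is zero are dropped (df adjusts); a table
    degenerate after dropping returns p = 1 with a flag.
    Returns ``(p_value, degenerate_flag)``.
    """
    groups = np.unique(labels)
    table = np.vstack([counts[labels == g].sum(axis=0) for g in groups])
    table = table[table.sum(axis=1) > 0][:, table.sum(axis=0) > 0]
    if table.shape[0] < 2 or table.shape[1] < 2:
        return 1.0, True
    stat, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(p), False


# ---------------------------------------------------------------------------
# Dirichlet-multinomial likelihood, MLE and LRT
# ---------------------------------------------------------------------------

def dm_loglik(counts: np.ndarray, alpha: np.ndarray) -> float:
    """DM log-likelihood of cells x J ``counts`` (multinomial coefficient
    omitted; it cancels in every likelihood ratio used here)."""
    counts = counts[counts.sum(axis=1) > 0]
    if counts.size == 0:
        return 0.0
    a0 = alpha.sum()
    n = counts.sum(axis=1)
    return float(
        (gammaln(a0) - gammaln(n + a0)).sum()
        + (gammaln(counts + alpha) - gammaln(alpha)).sum()
    )


@dataclass
class DMFit:
    alpha: np.ndarray
    loglik: float
    converged: bool = True
    boundary: bool = False   # alpha pinned at the floor/cap


def fit_dm(counts: np.ndarray, tol: float = DM_TOL,
           max_iter: int = DM_MAX_ITER) -> DMFit:
    """Maximum-likelihood Dirichlet parameters by fixed-point iteration.

    Uses the digamma fixed-point update
    ``alpha_j <- alpha_j * sum_i [psi(x_ij + a_j) - psi(a_j)]
    / sum_i [psi(n_i + a0) - psi(a0)]``
    with a moment-based start.  Components are clamped to
    [ALPHA_FLOOR, ALPHA_CAP]; hitting a clamp flags a boundary fit (e.g.
    all counts on one peak, where the MLE is unbounded).
    """
    counts = np.asarray(counts, dtype=float)
    counts = counts[counts.sum(axis=1) > 0]
    J = counts.shape[1]
    if counts.shape[0] == 0 or J < 2:
        return DMFit(np.ones(max(J, 1)), 0.0)
    n = counts.sum(axis=1)
    props = counts / n[:, None]
    mean_p = props.mean(axis=0)
    var_p = props.var(axis=0)
    # moment estimate of the precision from the first component with
    # usable variance; fall back to a diffuse start
    with np.errstate(divide="ignore", invalid="ignore"):
        s = mean_p * (1 - mean_p) / np.maximum(var_p, 1e-12) - 1
    s = s[(s > 0) & np.isfinite(s)]
    a0 = float(np.median(s)) if s.size else float(J)
    a0 = np.clip(a0, 1e-2, 1e4)
    alpha = np.maximum(mean_p * a0, ALPHA_FLOOR)

    converged = False
    for _ in range(max_iter):
        a0 = alpha.sum()
        num = (psi(counts + alpha) - psi(alpha)).sum(axis=0)
        den = (psi(n + a0) - psi(a0)).sum()
        if den <= 0:
            break
        new = alpha * num / den
        new = np.clip(new, ALPHA_FLOOR, ALPHA_CAP)
        rel = np.max(np.abs(new - alpha) / np.maximum(alpha, ALPHA_FLOOR))
        alpha = new
        if rel < tol:
            converged = True
            break
    boundary = bool((alpha <= ALPHA_FLOOR * 1.01).any()
                    or (alpha >= ALPHA_CAP * 0.99).any())
    return DMFit(alpha, dm_loglik(counts, alpha), converged, boundary)


def dm_lrt(counts: np.ndarray, labels: np.ndarray) -> tuple[float, bool]:
    """Likelihood-ratio test of equal Dirichlet parameters across groups.

    Lambda = 2 (sum_k ll_k - ll_pooled), referred to chi-square with
    (K-1) J degrees of freedom.  Returns ``(p, flagged)`` where the flag
    marks boundary fits.
    """
    groups = np.unique(labels)
    K, J = len(groups), counts.shape[1]
    if K < 2:
        return 1.0, True
    pooled = fit_dm(counts)
    per_group = [fit_dm(counts[labels == g]) for g in groups]
    lam = max(0.0, 2.0 * (sum(f.loglik for f in per_group) - pooled.loglik))
    p = float(stats.chi2.sf(lam, (K - 1) * J))
    flagged = pooled.boundary or any(f.boundary for f in per_group)
    return p, flagged


def combine_pvalues(p_chisq: float, p_dm: float) -> float:
    """The conservative max-p combination of the two tests."""
    return max(p_chisq, p_dm)


def adjust_bh(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values across one comparison."""
    arr = np.asarray(pvalues, dtype=float)
    if arr.size == 0:
        return arr
    return multipletests(arr, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Effect sizes
# ---------------------------------------------------------------------------

def relative_positions(positions: np.ndarray, same_utr: bool = True
                       ) -> np.ndarray:
    """Relative peak positions in [0, 1], proximal = 0, distal = 1.

    ``positions`` are transcription-direction coordinates in
    proximal-to-distal order.  Same-UTR peaks interpolate linearly in
    genomic distance; peaks from different 3' UTRs space evenly by rank,
    (rank - 1)/(n - 1), so the endpoint convention is met exactly.
    """
    pos = np.asarray(positions, dtype=float)
    n = len(pos)
    if n < 2:
        raise ValueError("need at least two peaks")
    if np.any(np.diff(pos) <= 0):
        raise ValueError("positions must be strictly increasing "
                         "(proximal to distal)")
    if same_utr:
        return (pos - pos[0]) / (pos[-1] - pos[0])
    return np.arange(n) / (n - 1)


def compute_warm(positions, counts, same_utr: bool = True) -> float:
    """Count-weighted average relative mode position in [0, 1]."""
    c = np.asarray(counts, dtype=float)
    total = c.sum()
    if total <= 0:
        return float("nan")
    rel = relative_positions(positions, same_utr)
    return float((c * rel).sum() / total)


def compute_mpro(base_counts, alt_counts) -> tuple[float, tuple[int, int]]:
    """Maximum difference in proportion change between two groups.

    Counts are per-peak totals in proximal-to-distal order.  For each
    peak pair (upstream j, downstream i), d-delta = delta_i - delta_j with
    delta = base proportion - alt proportion; MPRO is the d-delta of
    largest magnitude (signed), together with the (j, i) pair.
    Positive MPRO: the base group favours distal peaks.
    """
    b = np.asarray(base_counts, dtype=float)
    a = np.asarray(alt_counts, dtype=float)
    if b.sum() <= 0 or a.sum() <= 0:
        return float("nan"), (-1, -1)
    delta = b / b.sum() - a / a.sum()
    best, pair = 0.0, (0, min(1, len(delta) - 1))
    for j, i in itertools.combinations(range(len(delta)), 2):
        dd = delta[i] - delta[j]
        if abs(dd) > abs(best):
            best, pair = float(dd), (j, i)
    return best, pair


def compute_cell_warm(counts: np.ndarray, gene_index: np.ndarray,
                      positions_by_gene: dict, same_utr_by_gene: dict | None = None,
                      weighting: str = "equal") -> np.ndarray:
    """Per-cell average WARM over expressed multipeak genes.

    ``counts`` is peaks x cells; ``gene_index`` labels each row's gene.
    Cells with no multipeak-gene counts get NaN.
    """
    if weighting not in ("equal", "expression"):
        raise ValueError("weighting must be 'equal' or 'expression'")
    n_cells = counts.shape[1]
    num = np.zeros(n_cells)
    den = np.zeros(n_cells)
    for gene in np.unique(gene_index):
        rows = np.where(gene_index == gene)[0]
        if len(rows) < 2:
            continue
        pos = positions_by_gene[gene]
        same = True if same_utr_by_gene is None else same_utr_by_gene[gene]
        rel = relative_positions(pos, same)
        sub = counts[rows]
        tot = sub.sum(axis=0)
        expressed = tot > 0
        with np.errstate(invalid="ignore", divide="ignore"):
            warm = (rel[:, None] * sub).sum(axis=0) / tot
        w = tot if weighting == "expression" else (tot > 0).astype(float)
        num[expressed] += (warm * w)[expressed]
        den[expressed] += w[expressed]
    out = np.full(n_cells, np.nan)
    ok = den > 0
    out[ok] = num[ok] / den[ok]
    return out


# ---------------------------------------------------------------------------
# Per-gene driver, final-signal rules, hierarchy
# ---------------------------------------------------------------------------

@dataclass
class SignalThresholds:
    alpha: float = 0.05          # BH-adjusted p cutoff (inclusive)
    min_expr_frac: float = 0.05  # strict >: peak expressed in >5% of cells
    min_mpro: float = 0.2        # strict >: |MPRO| must exceed this


def expressed_fraction(counts: np.ndarray, labels: np.ndarray) -> dict:
    """Per group, per peak: fraction of the group's cells with count > 0."""
    return {g: (counts[labels == g] > 0).mean(axis=0)
            for g in np.unique(labels)}


def test_gene(counts: np.ndarray, labels: np.ndarray, positions,
              same_utr: bool = True, base=None, alt=None) -> dict:
    """All statistics for one gene: tests, WARM per group, MPRO.

    ``positions`` are peak coordinates in transcription direction
    (proximal to distal, matching the column order of ``counts``).
    ``base``/``alt`` name the two groups for MPRO; default is the first
    two group labels in sorted order.
    """
    groups = sorted(np.unique(labels))
    if base is None or alt is None:
        base, alt = groups[0], groups[1]
    p_chi, chi_flag = chisq_test(counts, labels)
    p_dm, dm_flag = dm_lrt(counts, labels)
    warm = {g: compute_warm(positions, counts[labels == g].sum(axis=0),
                            same_utr) for g in groups}
    mpro, pair = compute_mpro(counts[labels == base].sum(axis=0),
                              counts[labels == alt].sum(axis=0))
    return {
        "p_chisq": p_chi, "p_dm": p_dm,
        "p_combined": combine_pvalues(p_chi, p_dm),
        "warm": warm, "mpro": mpro, "mpro_pair": pair,
        "expr_frac": expressed_fraction(counts, labels),
        "flagged": chi_flag or dm_flag,
    }


def is_significant(p_adj: float, expr_frac: dict, mpro: float,
                   thresholds: SignalThresholds = SignalThresholds()) -> bool:
    """The three final-signal rules."""
    if not (p_adj <= thresholds.alpha):
        return False
    for frac in expr_frac.values():
        if not (np.max(frac) > thresholds.min_expr_frac):
            return False
    return bool(np.isfinite(mpro) and abs(mpro) > thresholds.min_mpro)


def peak_transcription_positions(peaks_meta: pd.DataFrame) -> np.ndarray:
    """Strand-aware proximal-to-distal coordinates for one gene's peaks."""
    mu = peaks_meta["mu"].to_numpy(dtype=float)
    if (peaks_meta["strand"] == "-").all():
        return -mu
    return mu


def run_comparison(pcm, groups: pd.Series, base=None, alt=None,
                   thresholds: SignalThresholds = SignalThresholds(),
                   min_cells: int = 1) -> pd.DataFrame:
    """Test every multipeak gene between cell groups.

    ``pcm`` is a :class:`apamix.quantify.PeakCellMatrix`; ``groups`` maps
    barcode -> label.  Only barcodes present in both are used.  Returns a
    per-gene results table with BH adjustment across the comparison.
    """
    barcodes = [b for b in pcm.barcodes if b in groups.index]
    cols = [pcm.barcodes.index(b) for b in barcodes]
    labels = groups.loc[barcodes].to_numpy()
    dense = np.asarray(pcm.matrix.todense())[:, cols]
    rows = []
    for gene_id, sub in pcm.peaks.groupby("gene_id", sort=True):
        if len(sub) < 2:
            continue
        idx = sub.index.to_numpy()
        order = np.argsort(peak_transcription_positions(sub))
        idx = idx[order]
        counts = dense[idx].T    # cells x J
        if (counts.sum(axis=1) > 0).sum() < min_cells:
            continue
        res = test_gene(counts, labels, np.sort(
            peak_transcription_positions(sub)), base=base, alt=alt)
        groups_sorted = sorted(np.unique(labels))
        mpro_base = base if base is not None else groups_sorted[0]
        mpro_alt = alt if alt is not None else groups_sorted[1]
        row = {
            "gene_id": gene_id,
            "base_group": mpro_base, "alt_group": mpro_alt,
            "peaks": ",".join(sub.loc[i, "peak_id"] for i in idx),
            "n_peaks": len(idx),
            "p_chisq": res["p_chisq"], "p_dm": res["p_dm"],
            "p_combined": res["p_combined"],
            "mpro": res["mpro"], "flagged": res["flagged"],
        }
        for g in groups_sorted:
            row[f"warm_{g}"] = res["warm"][g]
            row[f"max_expr_frac_{g}"] = float(np.max(res["expr_frac"][g]))
        rows.append((row, res))
    if not rows:
        return pd.DataFrame()
    table = pd.DataFrame([r for r, _ in rows])
    table["p_adj"] = adjust_bh(table["p_combined"])
    table["significant"] = [
        is_significant(p_adj, res["expr_frac"], res["mpro"], thresholds)
        for p_adj, (_, res) in zip(table["p_adj"], rows)
    ]
    return table


# ---------------------------------------------------------------------------
# Hierarchical testing over a cell-type taxonomy
# ---------------------------------------------------------------------------

@dataclass
class TaxonomyTree:
    """Rooted cell-type taxonomy as a child -> parent mapping."""

    parent: dict[str, str]
    root: str = "root"

    @classmethod
    def from_edges(cls, edges: list[tuple[str, str]], root: str = "root"):
        return cls({child: parent for parent, child in edges}, root)

    @classmethod
    def from_tsv(cls, path, root: str = "root") -> "TaxonomyTree":
        df = pd.read_csv(path, sep="\t", header=None, names=["parent", "child"])
        return cls.from_edges(list(df.itertuples(index=False)), root)

    def path_to_root(self, node: str) -> list[str]:
        path = [node]
        while path[-1] != self.root:
            path.append(self.parent[path[-1]])
        return path

    def level(self, node: str) -> int:
        return len(self.path_to_root(node)) - 1

    def nodes(self) -> list[str]:
        seen = {self.root}
        for child, parent in self.parent.items():
            seen.add(child)
            seen.add(parent)
        return sorted(seen)

    def descendants_and_self(self, node: str) -> set[str]:
        out = {node}
        changed = True
        while changed:
            changed = False
            for child, parent in self.parent.items():
                if parent in out and child not in out:
                    out.add(child)
                    changed = True
        return out


def hierarchical_tests(pcm, leaf_labels: pd.Series, tree: TaxonomyTree,
                       thresholds: SignalThresholds = SignalThresholds()
                       ) -> pd.DataFrame:
    """Run the node-vs-rest-of-parent comparison at every taxonomy level.

    Each cell carries a leaf label; a cell belongs to node c when its leaf
    is c or a descendant of c.  For every non-root node whose complement
    within its parent is non-empty, cells of the node are tested against
    the remaining cells of the parent.  BH correction is applied per
    comparison; results are tagged with the node and its level.
    """
    frames = []
    for node in tree.nodes():
        if node == tree.root:
            continue
        parent = tree.parent[node]
        in_node = leaf_labels.isin(tree.descendants_and_self(node))
        in_parent = leaf_labels.isin(tree.descendants_and_self(parent))
        complement = in_parent & ~in_node
        if not complement.any() or not in_node.any():
            continue
        groups = pd.Series("__other__", index=leaf_labels.index)
        groups[in_node] = node
        groups = groups[in_parent]
        res = run_comparison(pcm, groups, base=node, alt="__other__",
                             thresholds=thresholds)
        if res.empty:
            continue
        res.insert(0, "node", node)
        res.insert(1, "level", tree.level(node))
        frames.append(res)
    if not frames:
        return pd.DataFrame()
    return pd.concat(frames, ignore_index=True)
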