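"""Differential-expression filtering and integration with binding data.

Fold changes use the signed-ratio convention of expression tables: |fold| >= 1,
with -1.5 meaning 1.5-fold down. A gene is called up in a system when its fold
change is >= the threshold (inclusive) and its FDR-adjusted p-value is < alpha
(strict); down symmetrically. Chi-square tests are Pearson tests of
independence, df = 1, without continuity correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from statsmodels.stats.multitest import multipletests

DEFAULT_FOLD_THRESHOLD = 2.0
DEFAULT_ALPHA = 0.01

EXPRESSION_COLUMNS = ["gene_id", "system", "fold_change", "fdr_p"]


def signed_ratio_to_log2(fold: np.ndarray) -> np.ndarray:
    """Map signed-ratio folds (|r| >= 1; -r = r-fold down) to log2 space."""
    fold = np.asarray(fold, dtype=float)
    return np.where(fold >= 0, np.log2(np.maximum(fold, 1e-12)), -np.log2(-fold))


def differential_calls(
    records: pd.DataFrame,
    fold_threshold: float = DEFAULT_FOLD_THRESHOLD,
    alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """Per-(gene, system) status: up / down / unchanged.

    Inclusive on the fold threshold ("2-fold or greater"), strict on alpha
    ("p < 0.01"). Duplicate (gene, system) pairs are an error.
    """
    missing = [c for c in EXPRESSION_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"expression table missing columns: {missing}")
    dupes = records.duplicated(subset=["gene_id", "system"])
    if dupes.any():
        bad = records.loc[dupes, ["gene_id", "system"]].iloc[0]
        raise ValueError(f"duplicate expression record: {tuple(bad)}")
    if ((records["fdr_p"] < 0) | (records["fdr_p"] > 1)).any():
        raise ValueError("fdr_p outside [0, 1]")
    out = records.copy()
    sig = out["fdr_p"] < alpha
    up = sig & (out["fold_change"] >= fold_threshold)
    down = sig & (out["fold_change"] <= -fold_threshold)
    out["status"] = np.where(up, "up", np.where(down, "down", "unchanged"))
    return out


def calls_to_sets(calls: pd.DataFrame, system: str) -> dict[str, set[str]]:
    sub = calls[calls["system"] == system]
    return {
        "up": set(sub.loc[sub["status"] == "up", "gene_id"]),
        "down": set(sub.loc[sub["status"] == "down", "gene_id"]),
        "changed": set(sub.loc[sub["status"] != "unchanged", "gene_id"]),
    }


def bh_fdr(raw_pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(raw_pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values outside [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# --- Venn / list intersection ------------------------------------------------

@dataclass
class VennCounts:
    """7-region Venn over (bound genes, DE in system A, DE in system B)."""

    only_bound: int
    only_a: int
    only_b: int
    bound_a: int
    bound_b: int
    a_b: int
    all_three: int
    regions: dict[str, set[str]] = field(repr=False, default_factory=dict)

    @property
    def total_union(self) -> int:
        return (
            self.only_bound
            + self.only_a
            + self.only_b
            + self.bound_a
            + self.bound_b
            + self.a_b
            + self.all_three
        )

    @property
    def one_system_count(self) -> int:
        """DE genes responsive in exactly one of the two systems."""
        return self.only_a + self.only_b + self.bound_a + self.bound_b

    @property
    def one_system_fraction(self) -> float:
        n_de = self.one_system_count + self.a_b + self.all_three
        return self.one_system_count / n_de if n_de else float("nan")


def intersect_lists(
    bound_genes: set[str], calls_a: set[str], calls_b: set[str]
) -> VennCounts:
    regions = {
        "only_bound": bound_genes - calls_a - calls_b,
        "only_a": calls_a - bound_genes - calls_b,
        "only_b": calls_b - bound_genes - calls_a,
        "bound_a": (bound_genes & calls_a) - calls_b,
        "bound_b": (bound_genes & calls_b) - calls_a,
        "a_b": (calls_a & calls_b) - bound_genes,
        "all_three": bound_genes & calls_a & calls_b,
    }
    return VennCounts(
        **{k: len(v) for k, v in regions.items()}, regions=regions
    )


def one_system_fraction_from_counts(n_a: int, n_b: int, n_both: int) -> float:
    """Fraction of DE genes responsive in exactly one system, from set sizes."""
    exclusive = n_a + n_b - 2 * n_both
    union = n_a + n_b - n_both
    return exclusive / union


# --- binding / expression association ----------------------------------------

def gene_site_association(
    annotation, segments, radius: int = 1250
) -> set[str]:
    """Genes associated with a bound segment.

    A gene qualifies when (a) any segment peak lies within the gene's
    transcribed span (isoform union), or (b) any isoform TSS lies within
    ``radius`` bp of a segment peak center.
    """
    associated: set[str] = set()
    for seg in segments:
        for gene, _iso in annotation.isoforms_containing(seg.chrom, seg.peak_center):
            associated.add(gene.gene_id)
        for tss, gene, _iso in annotation.tss_entries(seg.chrom):
            if abs(tss - seg.peak_center) <= radius:
                associated.add(gene.gene_id)
    return associated


def distance_to_nearest_site(
    gene_tss: dict[str, tuple[str, int, str]],
    peak_centers: list[tuple[str, int]],
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Signed distance from each gene's TSS to its nearest peak, plus summary.

    ``gene_tss`` maps gene id -> (chrom, tss, strand); the sign convention is
    positive when the peak lies downstream of the TSS in transcription
    direction. The summary (mean/median) is on absolute distances.
    """
    if not peak_centers:
        raise ValueError("peak list must be non-empty")
    peaks_by_chrom: dict[str, np.ndarray] = {}
    for chrom, center in peak_centers:
        peaks_by_chrom.setdefault(chrom, []).append(center)
    peaks_by_chrom = {c: np.array(sorted(v)) for c, v in peaks_by_chrom.items()}
    rows = []
    for gene_id, (chrom, tss, strand) in gene_tss.items():
        centers = peaks_by_chrom.get(chrom)
        if centers is None or len(centers) == 0:
            rows.append({"gene_id": gene_id, "distance": np.nan})
            continue
        nearest = centers[np.argmin(np.abs(centers - tss))]
        signed = nearest - tss if strand == "+" else tss - nearest
        rows.append({"gene_id": gene_id, "distance": int(signed)})
    frame = pd.DataFrame(rows)
    dists = frame["distance"].dropna().abs()
    summary = {
        "mean": float(dists.mean()) if len(dists) else float("nan"),
        "median": float(dists.median()) if len(dists) else float("nan"),
    }
    return frame, summary


@dataclass
class Chi2Result:
    chi2: float
    p_value: float
    undefined: bool = False


def chi2_2x2(table) -> Chi2Result:
    """Pearson chi-square of independence on a 2x2 table, df=1, no correction."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t < 0):
        raise ValueError("counts must be non-negative")
    if t.sum() == 0:
        raise ValueError("table total must be positive")
    if t.sum(axis=0).min() == 0 or t.sum(axis=1).min() == 0:
        return Chi2Result(float("nan"), 1.0, undefined=True)
    chi2, p, _, _ = stats.chi2_contingency(t, correction=False)
    return Chi2Result(float(chi2), float(p))


@dataclass
class MotifInductionReport:
    """Counts of induced vs non-induced bound promoters carrying a motif and/or
    an externally measured binding interval (a Table-4-style contingency)."""

    n_induced: int
    n_noninduced: int
    motif_induced: int
    motif_noninduced: int
    binding_induced: int
    binding_noninduced: int
    both_induced: int
    both_noninduced: int
    motif_pct_induced: float
    motif_pct_noninduced: float
    binding_pct_induced: float
    binding_pct_noninduced: float
    motif_test: Chi2Result
    binding_test: Chi2Result

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "induced": [
                    self.motif_induced,
                    self.binding_induced,
                    self.both_induced,
                    self.n_induced,
                ],
                "non_induced": [
                    self.motif_noninduced,
                    self.binding_noninduced,
                    self.both_noninduced,
                    self.n_noninduced,
                ],
            },
            index=[
                "promoters_with_motif",
                "promoters_bound_externally",
                "promoters_with_both",
                "total_promoters",
            ],
        )


def motif_induction_report(
    induced_promoters: set[str],
    noninduced_promoters: set[str],
    motif_positive: set[str],
    externally_bound: set[str],
) -> MotifInductionReport:
    """Contingency analysis of motif presence / external binding by induction.

    Inputs are gene-id sets: bound promoters split by induction status, genes
    whose promoter carries at least one motif match, and genes whose promoter
    overlaps an external binding interval set. Both associations are tested
    with the df=1 Pearson chi-square (no continuity correction).
    """
    overlap = induced_promoters & noninduced_promoters
    if overlap:
        raise ValueError(f"promoters in both groups: {sorted(overlap)[:5]}")
    n_i, n_n = len(induced_promoters), len(noninduced_promoters)
    m_i = len(induced_promoters & motif_positive)
    m_n = len(noninduced_promoters & motif_positive)
    b_i = len(induced_promoters & externally_bound)
    b_n = len(noninduced_promoters & externally_bound)
    both_i = len(induced_promoters & motif_positive & externally_bound)
    both_n = len(noninduced_promoters & motif_positive & externally_bound)

    def _pct(k: int, n: int) -> float:
        return 100.0 * k / n if n else float("nan")

    def _test(k_i: int, k_n: int) -> Chi2Result:
        if n_i == 0 or n_n == 0 or (k_i + k_n) == 0 or (
            (n_i - k_i) + (n_n - k_n)
        ) == 0:
            return Chi2Result(float("nan"), 1.0, undefined=True)
        return chi2_2x2([[k_i, n_i - k_i], [k_n, n_n - k_n]])

    return MotifInductionReport(
        n_induced=n_i,
        n_noninduced=n_n,
        motif_induced=m_i,
        motif_noninduced=m_n,
        binding_induced=b_i,
        binding_noninduced=b_n,
        both_induced=both_i,
        both_noninduced=both_n,
        motif_pct_induced=_pct(m_i, n_i),
        motif_pct_noninduced=_pct(m_n, n_n),
        binding_pct_induced=_pct(b_i, n_i),
        binding_pct_noninduced=_pct(b_n, n_n),
        motif_test=_test(m_i, m_n),
        binding_test=_test(b_i, b_n),
    )


# --- clustering ---------------------------------------------------------------

@dataclass
class ClusterResult:
    linkage: np.ndarray
    leaf_order: list[str]
    ordered_matrix: pd.DataFrame
    newick: str


def cluster_profiles(log2_matrix: pd.DataFrame) -> ClusterResult:
    """Agglomerative clustering of expression profiles.

    Manhattan (L1) distance with unweighted average linkage; scipy's
    deterministic smallest-index tie-break. Rows are genes, columns are
    conditions; non-finite entries are an error naming the genes.
    """
    values = log2_matrix.to_numpy(dtype=float)
    bad = ~np.isfinite(values).all(axis=1)
    if bad.any():
        raise ValueError(
            f"non-finite expression values for genes: {list(log2_matrix.index[bad])}"
        )
    if len(log2_matrix) < 2:
        raise ValueError("clustering needs at least two profiles")
    z = hierarchy.linkage(values, method="average", metric="cityblock")
    order = hierarchy.leaves_list(z)
    labels = [str(g) for g in log2_matrix.index]
    newick = _linkage_to_newick(z, labels)
    return ClusterResult(
        linkage=z,
        leaf_order=[labels[i] for i in order],
        ordered_matrix=log2_matrix.iloc[order],
        newick=newick,
    )


def _linkage_to_newick(z: np.ndarray, labels: list[str]) -> str:
    tree = hierarchy.to_tree(z)

    def _walk(node, parent_height: float) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = _walk(node.left, node.dist)
        right = _walk(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return _walk(tree, tree.dist) + ";"


# --- term enrichment ----------------------------------------------------------

def term_enrichment(
    gene_list: set[str],
    background_genes: set[str],
    term_map: dict[str, set[str]],
) -> pd.DataFrame:
    """One-sided hypergeometric enrichment of term membership in a gene list.

    ``term_map`` maps term -> set of background genes annotated with it. For a
    term with K background members, the p-value is the upper tail
    P(X >= k) of Hypergeometric(N=|background|, K, n=|gene_list|). BH-adjusted
    p-values are appended.
    """
    stray = gene_list - background_genes
    if stray:
        raise ValueError(f"genes not in background: {sorted(stray)[:5]}")
    n_bg = len(background_genes)
    n_list = len(gene_list)
    rows = []
    for term, members in sorted(term_map.items()):
        members = members & background_genes
        k = len(gene_list & members)
        big_k = len(members)
        p = float(stats.hypergeom.sf(k - 1, n_bg, big_k, n_list)) if n_list else 1.0
        rows.append(
            {"term": term, "overlap": k, "term_size": big_k, "list_size": n_list, "p": p}
        )
    frame = pd.DataFrame(rows)
    if len(frame):
        frame["p_adjusted"] = bh_fdr(frame["p"].to_numpy())
    return frame
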