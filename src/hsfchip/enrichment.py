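"""Windowed motif-match statistics around bound-segment peaks.

For each peak, up to ``half_range`` bp of flanking sequence on either side is
scanned for PWM matches; match start offsets relative to the peak center are
pooled over peaks into fixed-width windows. Local enrichment is tested by a
one-degree-of-freedom goodness-of-fit chi-square of the match counts in a
center interval (default -500..+500) against flank intervals (default
-1000..-550 and +550..+1000), with the expected split proportional to the
covered interval lengths (1001:902 for full windows; truncation at chromosome
ends is length-adjusted). A match straddling a window boundary is binned by
its start and never split.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .motifs import (
    MotifMatch,
    PositionWeightMatrix,
    ScoreDistribution,
    TRIPLET_ARRANGEMENTS,
    make_triplet_pwm,
    scan,
    score_pvalue_distribution,
    scramble_columns,
)

DEFAULT_HALF_RANGE = 2500
DEFAULT_WINDOW_WIDTH = 50
CENTER_INTERVAL = (-500, 500)
FLANK_INTERVALS = ((-1000, -550), (550, 1000))


@dataclass
class WindowHistogram:
    """Matches per fixed-width offset window, pooled across peaks."""

    pwm_id: str
    window_width: int
    half_range: int
    counts: np.ndarray
    offsets: np.ndarray  # raw match-start offsets (one entry per match)
    n_peaks: int
    p_threshold: float
    n_windows_skipped: int = 0
    # summed covered length (bp) per offset, needed for truncation-aware
    # expectations: coverage[k] = number of peaks whose scanned range includes
    # offset (k - half_range)
    coverage: np.ndarray = field(default=None, repr=False)

    @property
    def window_edges(self) -> np.ndarray:
        return np.arange(-self.half_range, self.half_range + 1, self.window_width)

    def covered_length(self, lo: int, hi: int) -> float:
        """Total covered bases (summed over peaks) in offsets lo..hi inclusive."""
        if self.coverage is None:
            return float(self.n_peaks * (hi - lo + 1))
        i0 = lo + self.half_range
        i1 = hi + self.half_range + 1
        return float(self.coverage[i0:i1].sum())

    def count_in(self, lo: int, hi: int) -> int:
        return int(((self.offsets >= lo) & (self.offsets <= hi)).sum())


def match_histogram(
    peaks: list[tuple[str, int]],
    genome: dict[str, str],
    pwm: PositionWeightMatrix,
    p_threshold: float,
    half_range: int = DEFAULT_HALF_RANGE,
    window_width: int = DEFAULT_WINDOW_WIDTH,
    distribution: ScoreDistribution | None = None,
) -> WindowHistogram:
    """Histogram of PWM match starts relative to peak centers.

    ``peaks`` is a list of (chrom, peak_center). Ranges truncated at
    chromosome ends contribute shorter scans, tracked in the coverage vector.
    """
    if half_range % window_width:
        raise ValueError("half_range must be a multiple of window_width")
    dist = distribution or score_pvalue_distribution(pwm)
    n_windows = 2 * half_range // window_width
    counts = np.zeros(n_windows, dtype=int)
    coverage = np.zeros(2 * half_range + 1, dtype=int)
    offsets: list[int] = []
    skipped = 0
    for chrom, center in peaks:
        if chrom not in genome:
            raise KeyError(f"peak on unknown chromosome {chrom!r}")
        seq = genome[chrom]
        lo = max(0, center - half_range)
        hi = min(len(seq), center + half_range + 1)
        result = scan(
            seq[lo:hi],
            pwm,
            p_threshold,
            chrom=chrom,
            offset=lo,
            distribution=dist,
        )
        skipped += result.n_windows_skipped
        coverage[(lo - center + half_range) : (hi - center + half_range)] += 1
        for m in result.matches:
            off = m.position - center
            if -half_range <= off < half_range:
                counts[(off + half_range) // window_width] += 1
                offsets.append(off)
    return WindowHistogram(
        pwm_id=pwm.id,
        window_width=window_width,
        half_range=half_range,
        counts=counts,
        offsets=np.array(sorted(offsets), dtype=int),
        n_peaks=len(peaks),
        p_threshold=p_threshold,
        n_windows_skipped=skipped,
        coverage=coverage,
    )


@dataclass
class CenterFlankTest:
    center_count: int
    flank_count: int
    expected_center: float
    expected_flank: float
    chi2: float
    p_value: float
    undefined: bool = False


def center_vs_flank_chi2(
    histogram: WindowHistogram,
    center: tuple[int, int] = CENTER_INTERVAL,
    flanks: tuple[tuple[int, int], ...] = FLANK_INTERVALS,
) -> CenterFlankTest:
    """Goodness-of-fit chi-square of center vs flank match counts.

    Expected counts are proportional to the covered lengths of the intervals
    (1001 vs 902 bp for untruncated +-1000 windows); df = 1, no continuity
    correction. With zero total matches the test is undefined and returns
    p = 1 with a flag.
    """
    if histogram.half_range < max(abs(v) for pair in flanks for v in pair):
        raise ValueError("histogram does not cover the flank intervals")
    c_obs = histogram.count_in(*center)
    f_obs = sum(histogram.count_in(*fl) for fl in flanks)
    c_len = histogram.covered_length(*center)
    f_len = sum(histogram.covered_length(*fl) for fl in flanks)
    total = c_obs + f_obs
    if total == 0 or c_len + f_len == 0:
        return CenterFlankTest(c_obs, f_obs, 0.0, 0.0, 0.0, 1.0, undefined=True)
    exp_c = total * c_len / (c_len + f_len)
    exp_f = total * f_len / (c_len + f_len)
    chi2, p = stats.chisquare([c_obs, f_obs], f_exp=[exp_c, exp_f])
    return CenterFlankTest(c_obs, f_obs, exp_c, exp_f, float(chi2), float(p))


# --- HSE orientation comparison ----------------------------------------------

@dataclass
class OrientationReport:
    histograms: dict[tuple[tuple[str, str, str], float], WindowHistogram]
    tests: dict[tuple[tuple[str, str, str], float], CenterFlankTest]
    ranking: dict[float, list[tuple[str, str, str]]]

    def center_excess(self, arrangement, threshold) -> float:
        t = self.tests[(arrangement, threshold)]
        return t.center_count - t.expected_center


def orientation_comparison(
    peaks: list[tuple[str, int]],
    genome: dict[str, str],
    thresholds: tuple[float, ...] = (1e-4, 1e-5),
    half_range: int = DEFAULT_HALF_RANGE,
    window_width: int = DEFAULT_WINDOW_WIDTH,
) -> OrientationReport:
    """Histograms and center-vs-flank tests for all 8 nGAAn 3-way arrangements.

    Arrangements are ranked per threshold by center enrichment (observed minus
    expected center count).
    """
    histograms = {}
    tests = {}
    for arrangement in TRIPLET_ARRANGEMENTS:
        pwm = make_triplet_pwm(arrangement)
        dist = score_pvalue_distribution(pwm)
        for thr in thresholds:
            hist = match_histogram(
                peaks, genome, pwm, thr, half_range, window_width, distribution=dist
            )
            histograms[(arrangement, thr)] = hist
            tests[(arrangement, thr)] = center_vs_flank_chi2(hist)
    ranking = {
        thr: sorted(
            TRIPLET_ARRANGEMENTS,
            key=lambda a: -(tests[(a, thr)].center_count - tests[(a, thr)].expected_center),
        )
        for thr in thresholds
    }
    return OrientationReport(histograms, tests, ranking)


# --- promoter motif presence -------------------------------------------------

PROMOTER_SCAN_WINDOW = (-200, 0)  # match-start offsets relative to the TSS


def promoter_motif_presence(
    annotation,
    gene_ids,
    genome: dict[str, str],
    pwm: PositionWeightMatrix,
    p_threshold: float = 5e-4,
    window: tuple[int, int] = PROMOTER_SCAN_WINDOW,
    distribution: ScoreDistribution | None = None,
) -> set[str]:
    """Genes with at least one PWM match in their TSS-proximal promoter window.

    The window is given in transcription-direction offsets of the match start
    relative to the principal (first) isoform's TSS; both strands are scanned.
    The default window covers the first 200 bp upstream of the TSS, where
    insulator (BEAF-type) sites concentrate.
    """
    dist = distribution or score_pvalue_distribution(pwm)
    a, b = window
    width = pwm.width
    gene_index = {g.gene_id: g for g in annotation.genes}
    positive: set[str] = set()
    for gene_id in gene_ids:
        gene = gene_index[gene_id]
        iso = gene.isoforms[0]
        tss = iso.tss
        if iso.strand == "+":
            lo, hi = tss + a, tss + b + width
        else:
            lo, hi = tss - b - width + 1, tss - a + 1
        seq = genome[gene.chrom]
        lo, hi = max(0, lo), min(len(seq), hi)
        if hi - lo >= width and scan(
            seq[lo:hi], pwm, p_threshold, distribution=dist
        ).matches:
            positive.add(gene_id)
    return positive


def chance_presence_probability(
    pwm: PositionWeightMatrix,
    p_threshold: float = 5e-4,
    window: tuple[int, int] = PROMOTER_SCAN_WINDOW,
    distribution: ScoreDistribution | None = None,
) -> float:
    """P(>= 1 background match in a promoter scan window), both strands.

    Uses the achieved per-window tail rate at the threshold (which can be much
    smaller than the nominal cut-off for discrete score distributions) and
    treats window positions as independent, which is accurate for the sharp
    matrices used here.
    """
    dist = distribution or score_pvalue_distribution(pwm)
    rate = dist.tail_bin(dist.threshold_bin(p_threshold))
    n_positions = window[1] - window[0] + 1
    return 1.0 - (1.0 - rate) ** (2 * n_positions)


# --- PWM library screen over peak groups -------------------------------------

@dataclass
class ScreenRecord:
    pwm_id: str
    group_tests: dict[str, CenterFlankTest]
    bonferroni_p: dict[str, float]
    passes: dict[str, bool]
    scrambled_passes: dict[str, bool]
    flagged_groups: list[str]
    between_group_chi2: float | None = None
    between_group_p: float | None = None


@dataclass
class GroupScreenReport:
    records: list[ScreenRecord]
    library_size: int
    alpha: float
    skipped_groups: list[str]

    def flagged(self, group: str) -> list[str]:
        return [r.pwm_id for r in self.records if group in r.flagged_groups]


def group_screen(
    peak_groups: dict[str, list[tuple[str, int]]],
    genome: dict[str, str],
    pwm_library: list[PositionWeightMatrix],
    alpha: float = 5.6e-2,
    p_match: float = 1e-4,
    scramble_seed: int = 0,
    half_range: int = DEFAULT_HALF_RANGE,
    window_width: int = DEFAULT_WINDOW_WIDTH,
) -> GroupScreenReport:
    """Screen a PWM library for positional enrichment in each peak group.

    For every PWM and group (e.g. promoter peaks vs intron peaks): a
    center-vs-flank chi-square whose p-value, Bonferroni-multiplied by the
    library size, must fall below ``alpha``. Every passing (PWM, group) is
    re-tested with a column-scrambled version of the matrix as a base
    composition control; PWMs whose scrambled form also passes are excluded
    from the flag list. A 2x2 between-group chi-square on (center, flank)
    counts tests differential enrichment between the first two groups.
    """
    names = list(peak_groups)
    skipped = [g for g in names if not peak_groups[g]]
    active = [g for g in names if peak_groups[g]]
    records: list[ScreenRecord] = []
    m = len(pwm_library)
    for pwm in pwm_library:
        dist = score_pvalue_distribution(pwm)
        group_tests: dict[str, CenterFlankTest] = {}
        bonf: dict[str, float] = {}
        passes: dict[str, bool] = {}
        scr_passes: dict[str, bool] = {}
        hists: dict[str, WindowHistogram] = {}
        for g in active:
            hist = match_histogram(
                peak_groups[g], genome, pwm, p_match, half_range, window_width,
                distribution=dist,
            )
            hists[g] = hist
            test = center_vs_flank_chi2(hist)
            group_tests[g] = test
            bonf[g] = min(1.0, test.p_value * m)
            enriched = test.center_count > test.expected_center
            passes[g] = (not test.undefined) and enriched and bonf[g] < alpha
        if any(passes.values()):
            scrambled = scramble_columns(pwm, scramble_seed)
            scr_dist = score_pvalue_distribution(scrambled)
            for g in active:
                if not passes[g]:
                    scr_passes[g] = False
                    continue
                s_hist = match_histogram(
                    peak_groups[g], genome, scrambled, p_match, half_range,
                    window_width, distribution=scr_dist,
                )
                s_test = center_vs_flank_chi2(s_hist)
                s_enriched = s_test.center_count > s_test.expected_center
                scr_passes[g] = (
                    (not s_test.undefined)
                    and s_enriched
                    and min(1.0, s_test.p_value * m) < alpha
                )
        else:
            scr_passes = {g: False for g in active}
        flagged = [g for g in active if passes[g] and not scr_passes.get(g, False)]
        rec = ScreenRecord(
            pwm_id=pwm.id,
            group_tests=group_tests,
            bonferroni_p=bonf,
            passes=passes,
            scrambled_passes=scr_passes,
            flagged_groups=flagged,
        )
        if len(active) >= 2:
            g1, g2 = active[0], active[1]
            t1, t2 = group_tests[g1], group_tests[g2]
            table = np.array(
                [
                    [t1.center_count, t1.flank_count],
                    [t2.center_count, t2.flank_count],
                ]
            )
            if table.sum(axis=0).min() > 0 and table.sum(axis=1).min() > 0:
                chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
                rec.between_group_chi2 = float(chi2)
                rec.between_group_p = float(p)
        records.append(rec)
    return GroupScreenReport(records, m, alpha, skipped)
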