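"""Probe-level segment calling, peak assignment, mock filtering, HS/RT comparison.

The caller is a thresholded run-joiner over tiling probes: maximal runs of
probes whose P[Xbar] falls below a significance threshold, tolerating a bounded
number of interior non-significant probes, become bound segments. This
substitutes for vendor neighborhood models upstream; downstream consumers only
need the segment/peak data shape. Each segment's peak is the center of its
lowest-P[Xbar] probe.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

PROBE_COLUMNS = ["chrom", "start", "end", "fold", "pxbar"]

DEFAULT_PXBAR_THRESHOLD = 1e-3
DEFAULT_MAX_GAP_PROBES = 1
DEFAULT_MIN_PROBES = 2
DEFAULT_PXBAR_RATIO_KEEP = 100.0


def validate_probes(probes: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in PROBE_COLUMNS if c not in probes.columns]
    if missing:
        raise ValueError(f"probe table missing columns: {missing}")
    if len(probes):
        if (probes["end"] <= probes["start"]).any():
            raise ValueError("probe spans must have end > start")
        if (probes["fold"] <= 0).any():
            raise ValueError("probe fold enrichment must be > 0")
        if ((probes["pxbar"] <= 0) | (probes["pxbar"] > 1)).any():
            raise ValueError("P[Xbar] must lie in (0, 1]")
    return probes


@dataclass
class BoundSegment:
    """A run of enriched probes with an assigned peak."""

    chrom: str
    start: int
    end: int
    probes: pd.DataFrame = field(repr=False)
    peak_start: int = 0
    peak_end: int = 0
    peak_center: int = 0
    max_fold: float = 0.0
    min_pxbar: float = 1.0

    @classmethod
    def from_probes(cls, probes: pd.DataFrame) -> "BoundSegment":
        if len(probes) == 0:
            raise ValueError("segment needs at least one probe")
        probes = probes.sort_values("start").reset_index(drop=True)
        seg = cls(
            chrom=str(probes["chrom"].iloc[0]),
            start=int(probes["start"].iloc[0]),
            end=int(probes["end"].iloc[-1]),
            probes=probes,
        )
        assign_peak(seg)
        return seg

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)

    def overlaps(self, other: "BoundSegment") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


def assign_peak(segment: BoundSegment) -> tuple[tuple[int, int], int]:
    """Set the segment peak to its lowest-P[Xbar] probe.

    Ties break toward the higher fold change, then the leftmost probe; the
    result is invariant to probe input order. The peak center is the floor
    midpoint of the winning probe's span.
    """
    probes = segment.probes
    order = np.lexsort(
        (probes["start"].to_numpy(), -probes["fold"].to_numpy(), probes["pxbar"].to_numpy())
    )
    best = probes.iloc[order[0]]
    segment.peak_start = int(best["start"])
    segment.peak_end = int(best["end"])
    segment.peak_center = (segment.peak_start + segment.peak_end) // 2
    segment.min_pxbar = float(probes["pxbar"].min())
    segment.max_fold = float(probes["fold"].max())
    return (segment.peak_start, segment.peak_end), segment.peak_center


def call_segments(
    probes: pd.DataFrame,
    pxbar_threshold: float = DEFAULT_PXBAR_THRESHOLD,
    max_gap_probes: int = DEFAULT_MAX_GAP_PROBES,
    min_probes: int = DEFAULT_MIN_PROBES,
) -> list[BoundSegment]:
    """Call maximal runs of significant probes as bound segments.

    A run may bridge up to ``max_gap_probes`` consecutive non-significant
    probes and is retained when it contains at least ``min_probes`` significant
    members. The segment span runs from the first to the last *significant*
    probe of the run.
    """
    if not 0 < pxbar_threshold <= 1:
        raise ValueError("pxbar_threshold must be in (0, 1]")
    if max_gap_probes < 0 or min_probes < 1:
        raise ValueError("invalid run-joining thresholds")
    validate_probes(probes)
    segments: list[BoundSegment] = []
    for chrom, group in probes.groupby("chrom", sort=True):
        group = group.sort_values("start").reset_index(drop=True)
        sig = (group["pxbar"] < pxbar_threshold).to_numpy()
        sig_idx = np.nonzero(sig)[0]
        if len(sig_idx) == 0:
            continue
        run_start = 0
        runs = []
        for k in range(1, len(sig_idx)):
            if sig_idx[k] - sig_idx[k - 1] - 1 > max_gap_probes:
                runs.append(sig_idx[run_start:k])
                run_start = k
        runs.append(sig_idx[run_start:])
        for run in runs:
            if len(run) < min_probes:
                continue
            members = group.iloc[run[0] : run[-1] + 1]
            segments.append(BoundSegment.from_probes(members))
    segments.sort(key=lambda s: (s.chrom, s.start))
    return segments


@dataclass
class FilterDecision:
    segment: BoundSegment
    kept: bool
    reason: str


@dataclass
class MockFilterResult:
    kept: list[BoundSegment]
    dropped: list[BoundSegment]
    decisions: list[FilterDecision]


def _merged_intervals(segments: list[BoundSegment], chrom: str) -> list[tuple[int, int]]:
    spans = sorted(s.span for s in segments if s.chrom == chrom)
    merged: list[tuple[int, int]] = []
    for start, end in spans:
        if merged and start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


def filter_against_mock(
    segments: list[BoundSegment],
    mock_segments: list[BoundSegment],
    pxbar_ratio_keep: float = DEFAULT_PXBAR_RATIO_KEEP,
) -> MockFilterResult:
    """Drop segments explained by the mock ChIP.

    A segment is dropped iff it is fully contained in the union of overlapping
    mock segments AND its min P[Xbar] is not at least ``pxbar_ratio_keep``-fold
    lower (stronger) than the best overlapping mock segment's. Every decision
    is annotated with its reason.
    """
    if pxbar_ratio_keep <= 0:
        raise ValueError("pxbar_ratio_keep must be positive")
    kept, dropped, decisions = [], [], []
    merged_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for seg in segments:
        overlapping = [m for m in mock_segments if seg.overlaps(m)]
        if not overlapping:
            decision = FilterDecision(seg, True, "no mock overlap")
        else:
            if seg.chrom not in merged_by_chrom:
                merged_by_chrom[seg.chrom] = _merged_intervals(mock_segments, seg.chrom)
            contained = any(
                start <= seg.start and seg.end <= end
                for start, end in merged_by_chrom[seg.chrom]
            )
            best_mock = min(m.min_pxbar for m in overlapping)
            much_stronger = seg.min_pxbar < best_mock / pxbar_ratio_keep
            if contained and not much_stronger:
                decision = FilterDecision(
                    seg,
                    False,
                    "completely contained in mock union with comparable min P[Xbar] "
                    f"({seg.min_pxbar:.3g} vs mock {best_mock:.3g})",
                )
            elif contained:
                decision = FilterDecision(
                    seg,
                    True,
                    "contained in mock union but much stronger min P[Xbar] "
                    f"({seg.min_pxbar:.3g} vs mock {best_mock:.3g})",
                )
            else:
                decision = FilterDecision(
                    seg,
                    True,
                    "partial mock overlap "
                    f"({seg.min_pxbar:.3g} vs mock {best_mock:.3g})",
                )
        decisions.append(decision)
        (kept if decision.kept else dropped).append(seg)
    return MockFilterResult(kept, dropped, decisions)


@dataclass
class ConditionComparison:
    """Overlap report between two segment sets (e.g. RT vs HS binding)."""

    n_query: int
    n_overlapping: int
    fraction_overlapping: float
    fold_ratios: list[float]
    mean_fold_ratio: float
    pairs: list[tuple[BoundSegment, BoundSegment]] = field(repr=False, default_factory=list)


def compare_conditions(
    hs_segments: list[BoundSegment], rt_segments: list[BoundSegment]
) -> ConditionComparison:
    """Fraction of RT segments overlapping an HS segment, with peak fold ratios.

    Overlap is any base-pair intersection. For each overlapping pair the fold
    ratio is HS peak fold / RT peak fold using the representative (max-fold)
    probe of each segment; a RT segment overlapping several HS segments pairs
    with the strongest one.
    """
    ratios: list[float] = []
    pairs: list[tuple[BoundSegment, BoundSegment]] = []
    n_overlap = 0
    for rt in rt_segments:
        overlapping = [hs for hs in hs_segments if hs.overlaps(rt)]
        if not overlapping:
            continue
        n_overlap += 1
        hs = max(overlapping, key=lambda s: s.max_fold)
        pairs.append((hs, rt))
        ratios.append(hs.max_fold / rt.max_fold)
    fraction = n_overlap / len(rt_segments) if rt_segments else 0.0
    mean_ratio = float(np.mean(ratios)) if ratios else float("nan")
    return ConditionComparison(
        n_query=len(rt_segments),
        n_overlapping=n_overlap,
        fraction_overlapping=fraction,
        fold_ratios=ratios,
        mean_fold_ratio=mean_ratio,
        pairs=pairs,
    )


# --- tabular round-trip ------------------------------------------------------

SEGMENT_COLUMNS = [
    "chrom",
    "start",
    "end",
    "max_fold",
    "min_pxbar",
    "peak_start",
    "peak_end",
    "peak_center",
]


def segments_to_frame(segments: list[BoundSegment]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": s.chrom,
                "start": s.start,
                "end": s.end,
                "max_fold": s.max_fold,
                "min_pxbar": s.min_pxbar,
                "peak_start": s.peak_start,
                "peak_end": s.peak_end,
                "peak_center": s.peak_center,
            }
            for s in segments
        ],
        columns=SEGMENT_COLUMNS,
    )


def frame_to_segments(frame: pd.DataFrame) -> list[BoundSegment]:
    """Rebuild segments from a table (single representative probe per segment)."""
    out = []
    for _, row in frame.iterrows():
        probe = pd.DataFrame(
            [
                {
                    "chrom": row["chrom"],
                    "start": int(row["peak_start"]),
                    "end": int(row["peak_end"]),
                    "fold": float(row["max_fold"]),
                    "pxbar": float(row["min_pxbar"]),
                }
            ]
        )
        seg = BoundSegment.from_probes(probe)
        seg.start, seg.end = int(row["start"]), int(row["end"])
        out.append(seg)
    return out
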