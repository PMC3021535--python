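"""Gene models, peak-to-gene assignment, site classification, cytology overlap.

Coordinates are 0-based half-open internally. The promoter is bidirectional:
within ``promoter_radius`` (default 1250 bp) of any isoform's transcription
start site. A site inside a transcribed span is intragenic; intragenic sites
that are additionally near a TSS form the ambiguous "promoter_intragenic"
class. Intronic/exonic sub-labels are numbered ordinally on the nearest-TSS
isoform ("Intron1", "Exon2", ...).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

DEFAULT_PROMOTER_RADIUS = 1250
DEFAULT_DOWNSTREAM_RADIUS = 1250

CATEGORIES = [
    "promoter_intergenic",
    "promoter_intragenic",
    "intron",
    "exon",
    "UTR",
    "downstream",
    "intergenic",
]


@dataclass
class Isoform:
    isoform_id: str
    start: int  # transcribed span, 0-based half-open
    end: int
    strand: str
    exons: list[tuple[int, int]]  # ordered by genomic coordinate
    utrs: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 < e1:
                raise ValueError(f"isoform {self.isoform_id}: overlapping exons")

    @property
    def tss(self) -> int:
        """Coordinate of the first transcribed base (strand-aware)."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def introns(self) -> list[tuple[int, int]]:
        return [
            (e1, s2) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:]) if s2 > e1
        ]

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def feature_at(self, pos: int) -> tuple[str, str] | None:
        """(category, ordinal label) of the feature containing ``pos``.

        Exons/introns are numbered in transcription order (Exon1 holds the TSS).
        """
        if not self.contains(pos):
            return None
        for s, e in self.utrs:
            if s <= pos < e:
                return ("UTR", "UTR")
        exons = self.exons if self.strand == "+" else self.exons[::-1]
        introns = self.introns if self.strand == "+" else self.introns[::-1]
        for i, (s, e) in enumerate(exons, start=1):
            if s <= pos < e:
                return ("exon", f"Exon{i}")
        for i, (s, e) in enumerate(introns, start=1):
            if s <= pos < e:
                return ("intron", f"Intron{i}")
        return None


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    isoforms: list[Isoform]

    @property
    def span(self) -> tuple[int, int]:
        return (
            min(i.start for i in self.isoforms),
            max(i.end for i in self.isoforms),
        )

    @property
    def tss_list(self) -> list[int]:
        return sorted({i.tss for i in self.isoforms})

    @property
    def three_prime_end(self) -> int:
        start, end = self.span
        return end if self.strand == "+" else start


class GenomeAnnotation:
    """A set of gene models with fast positional lookup."""

    def __init__(self, genes: list[GeneModel], chrom_lengths: dict[str, int]):
        self.genes = list(genes)
        self.chrom_lengths = dict(chrom_lengths)
        self._span_trees: dict[str, IntervalTree] = {}
        self._tss: dict[str, list[tuple[int, GeneModel, Isoform]]] = {}
        for gene in self.genes:
            tree = self._span_trees.setdefault(gene.chrom, IntervalTree())
            for iso in gene.isoforms:
                if iso.end > iso.start:
                    tree.addi(iso.start, iso.end, (gene, iso))
                self._tss.setdefault(gene.chrom, []).append((iso.tss, gene, iso))
        for entries in self._tss.values():
            entries.sort(key=lambda t: t[0])

    def __len__(self) -> int:
        return len(self.genes)

    def isoforms_containing(self, chrom: str, pos: int) -> list[tuple[GeneModel, Isoform]]:
        tree = self._span_trees.get(chrom)
        if tree is None:
            return []
        return [iv.data for iv in tree.at(pos)]

    def tss_entries(self, chrom: str) -> list[tuple[int, GeneModel, Isoform]]:
        return self._tss.get(chrom, [])


def signed_tss_distance(peak_center: int, tss: int, strand: str) -> int:
    """Positive downstream of the TSS in transcription direction, negative upstream."""
    return peak_center - tss if strand == "+" else tss - peak_center


def nearest_tss(
    annotation: GenomeAnnotation, chrom: str, peak_center: int
) -> tuple[GeneModel, Isoform, int]:
    """Nearest isoform TSS to a peak, with the signed distance.

    Ties (equal |distance|) break toward a gene whose body contains the peak,
    then lexicographically by gene id.
    """
    entries = annotation.tss_entries(chrom)
    if not entries:
        raise ValueError(f"no annotated genes on chromosome {chrom!r}")
    best = None
    for tss, gene, iso in entries:
        dist = abs(peak_center - tss)
        contains = any(i.contains(peak_center) for i in gene.isoforms)
        key = (dist, 0 if contains else 1, gene.gene_id)
        if best is None or key < best[0]:
            best = (key, gene, iso)
    _, gene, iso = best
    return gene, iso, signed_tss_distance(peak_center, iso.tss, iso.strand)


def genes_within_window(
    annotation: GenomeAnnotation,
    chrom: str,
    peak_center: int,
    half_width: int = DEFAULT_PROMOTER_RADIUS,
) -> list[tuple[GeneModel, int]]:
    """Genes whose TSS or transcribed span intersects peak +- half_width.

    Returned in order of proximity (|signed distance| of the gene's nearest
    isoform TSS). The window is truncated at chromosome boundaries.
    """
    if half_width <= 0:
        raise ValueError("half_width must be positive")
    lo = max(0, peak_center - half_width)
    hi = peak_center + half_width
    hits: dict[str, tuple[GeneModel, int]] = {}
    for tss, gene, iso in annotation.tss_entries(chrom):
        if lo <= tss <= hi:
            d = signed_tss_distance(peak_center, iso.tss, iso.strand)
            prev = hits.get(gene.gene_id)
            if prev is None or abs(d) < abs(prev[1]):
                hits[gene.gene_id] = (gene, d)
    tree = annotation._span_trees.get(chrom)
    if tree is not None:
        for iv in tree.overlap(lo, hi + 1):
            gene, iso = iv.data
            if gene.gene_id not in hits:
                dists = [
                    signed_tss_distance(peak_center, i.tss, i.strand)
                    for i in gene.isoforms
                ]
                hits[gene.gene_id] = (gene, min(dists, key=abs))
    return sorted(hits.values(), key=lambda t: (abs(t[1]), t[0].gene_id))


@dataclass
class SiteAnnotation:
    chrom: str
    peak_center: int
    nearest_gene: str
    signed_distance_to_tss: int
    genes_in_window: list[tuple[str, int]]
    category: str
    location_label: str


def classify_site(
    annotation: GenomeAnnotation,
    chrom: str,
    peak_center: int,
    promoter_radius: int = DEFAULT_PROMOTER_RADIUS,
    downstream_radius: int = DEFAULT_DOWNSTREAM_RADIUS,
) -> SiteAnnotation:
    """Assign a peak to the promoter/exon/intron/downstream/intergenic partition.

    Rules, over the union of isoforms: (1) inside any transcribed span ->
    intragenic, sub-labelled exon/intron/UTR on the nearest-TSS containing
    isoform, or "promoter_intragenic" when additionally within
    ``promoter_radius`` of any TSS; (2) otherwise within ``promoter_radius``
    of a TSS -> promoter_intergenic; (3) otherwise within
    ``downstream_radius`` past a gene's 3' end -> downstream; (4) else
    intergenic.
    """
    containing = annotation.isoforms_containing(chrom, peak_center)
    near_tss = any(
        abs(peak_center - tss) <= promoter_radius
        for tss, _, _ in annotation.tss_entries(chrom)
    )
    if annotation.tss_entries(chrom):
        gene, iso, signed_dist = nearest_tss(annotation, chrom, peak_center)
        nearest_id = gene.gene_id
    else:
        gene, iso, signed_dist, nearest_id = None, None, 0, ""
    window = [
        (g.gene_id, d)
        for g, d in genes_within_window(annotation, chrom, peak_center, promoter_radius)
    ] if annotation.tss_entries(chrom) else []

    if containing:
        if near_tss:
            category, label = "promoter_intragenic", "Promoter(intragenic)"
        else:
            # label by the containing isoform nearest by TSS distance
            containing.sort(
                key=lambda gi: (abs(peak_center - gi[1].tss), gi[0].gene_id)
            )
            feature = None
            for g, i in containing:
                feature = i.feature_at(peak_center)
                if feature is not None:
                    break
            category, label = feature if feature else ("exon", "Exon1")
    elif near_tss:
        category, label = "promoter_intergenic", "Promoter"
    else:
        downstream = False
        for g in annotation.genes:
            if g.chrom != chrom:
                continue
            end3 = g.three_prime_end
            if g.strand == "+" and 0 <= peak_center - end3 <= downstream_radius:
                downstream = True
            elif g.strand == "-" and 0 <= end3 - peak_center <= downstream_radius:
                downstream = True
            if downstream:
                break
        category, label = ("downstream", "Downstream") if downstream else (
            "intergenic",
            "Intergenic",
        )
    return SiteAnnotation(
        chrom=chrom,
        peak_center=peak_center,
        nearest_gene=nearest_id,
        signed_distance_to_tss=signed_dist,
        genes_in_window=window,
        category=category,
        location_label=label,
    )


def category_breakdown(sites: list[SiteAnnotation]) -> dict[str, float]:
    """Fractions per exclusive category plus derived aggregates.

    Aggregates: ``intragenic`` (exon + intron + UTR + promoter_intragenic) and
    ``promoter_any`` (promoter_intergenic + promoter_intragenic). Exclusive
    fractions sum to 1.
    """
    if not sites:
        raise ValueError("category_breakdown needs at least one site")
    n = len(sites)
    out = {c: 0.0 for c in CATEGORIES}
    for site in sites:
        out[site.category] += 1.0
    out = {c: v / n for c, v in out.items()}
    out["intragenic"] = (
        out["exon"] + out["intron"] + out["UTR"] + out["promoter_intragenic"]
    )
    out["promoter_any"] = out["promoter_intergenic"] + out["promoter_intragenic"]
    return out


# --- genome composition ------------------------------------------------------

def _union_length(intervals: list[tuple[int, int]]) -> int:
    total = 0
    last_end = None
    for start, end in sorted(intervals):
        if last_end is None or start > last_end:
            total += end - start
            last_end = end
        elif end > last_end:
            total += end - last_end
            last_end = end
    return total


def _merge(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for start, end in sorted(intervals):
        if merged and start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


def _subtract(base: list[tuple[int, int]], holes: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    holes = _merge(holes)
    for bs, be in _merge(base):
        cur = bs
        for hs, he in holes:
            if he <= cur or hs >= be:
                continue
            if hs > cur:
                out.append((cur, min(hs, be)))
            cur = max(cur, he)
            if cur >= be:
                break
        if cur < be:
            out.append((cur, be))
    return out


def genome_composition(
    annotation: GenomeAnnotation, promoter_radius: int = DEFAULT_PROMOTER_RADIUS
) -> dict[str, float]:
    """Base-pair fractions of the genome that are intragenic, promoter, intronic.

    Intragenic: union of all isoform transcribed spans. Promoter: union of
    TSS +- promoter_radius windows (clipped to the chromosome). Intronic:
    transcribed union minus the union of all exons.
    """
    genome_size = sum(annotation.chrom_lengths.values())
    if genome_size <= 0:
        raise ValueError("chromosome lengths required")
    intragenic = 0
    promoter = 0
    intronic = 0
    for chrom, length in annotation.chrom_lengths.items():
        spans: list[tuple[int, int]] = []
        exons: list[tuple[int, int]] = []
        proms: list[tuple[int, int]] = []
        for gene in annotation.genes:
            if gene.chrom != chrom:
                continue
            for iso in gene.isoforms:
                spans.append((iso.start, iso.end))
                exons.extend(iso.exons)
                proms.append(
                    (max(0, iso.tss - promoter_radius), min(length, iso.tss + promoter_radius + 1))
                )
        intragenic += _union_length(spans)
        promoter += _union_length(proms)
        intronic += sum(e - s for s, e in _subtract(spans, exons))
    return {
        "intragenic": intragenic / genome_size,
        "promoter": promoter / genome_size,
        "intronic": intronic / genome_size,
    }


# --- cytology ----------------------------------------------------------------

BAND_COLUMNS = ["band", "chrom", "start", "end", "index"]


def validate_band_map(band_map: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in BAND_COLUMNS if c not in band_map.columns]
    if missing:
        raise ValueError(f"band map missing columns: {missing}")
    for chrom, group in band_map.groupby("chrom"):
        group = group.sort_values("start")
        ends = group["end"].to_numpy()
        starts = group["start"].to_numpy()
        if not (starts[1:] == ends[:-1]).all():
            raise ValueError(f"bands on {chrom} do not tile contiguously")
    return band_map


def map_to_band(band_map: pd.DataFrame, chrom: str, position: int) -> str:
    """Unique band containing a position (bands are left-closed, right-open)."""
    rows = band_map[
        (band_map["chrom"] == chrom)
        & (band_map["start"] <= position)
        & (position < band_map["end"])
    ]
    if len(rows) == 0:
        raise ValueError(f"position {chrom}:{position} outside all bands")
    return str(rows["band"].iloc[0])


@dataclass
class PolyteneOverlap:
    n_bands: int
    n_site_bands: int
    n_locus_bands: int
    direct_overlap: int
    overlap_within_tolerance: int
    coverage_fraction: float
    table: np.ndarray
    chi2: float
    p_value: float


def polytene_overlap(
    site_bands: set[str],
    polytene_loci: set[str],
    band_map: pd.DataFrame,
    offset_tolerance: int = 0,
) -> PolyteneOverlap:
    """Independence test between ChIP-site bands and stained polytene loci.

    Over all bands of the map, a 2x2 table is formed: (band within
    ``offset_tolerance`` band indices of a site band, on the same chromosome)
    x (band in the locus list); Pearson chi-square, df=1, no continuity
    correction. The coverage fraction is the share of locus bands within
    tolerance of a site band.
    """
    if offset_tolerance not in (0, 1):
        raise ValueError("offset_tolerance must be 0 or 1")
    index_of = {
        str(r["band"]): (str(r["chrom"]), int(r["index"]))
        for _, r in band_map.iterrows()
    }
    unknown = (site_bands | polytene_loci) - set(index_of)
    if unknown:
        raise ValueError(f"bands not in band map: {sorted(unknown)[:5]}")
    site_idx = {index_of[b] for b in site_bands}

    def _hit(band: str) -> bool:
        chrom, idx = index_of[band]
        return any(
            (chrom, idx + off) in site_idx
            for off in range(-offset_tolerance, offset_tolerance + 1)
        )

    a = b = c = d = 0
    direct = 0
    within = 0
    for band in index_of:
        hit = _hit(band)
        in_loci = band in polytene_loci
        if hit and in_loci:
            a += 1
        elif hit:
            b += 1
        elif in_loci:
            c += 1
        else:
            d += 1
    for band in polytene_loci:
        if band in site_bands:
            direct += 1
        if _hit(band):
            within += 1
    table = np.array([[a, b], [c, d]])
    if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
        chi2, p = float("nan"), 1.0
    else:
        chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    coverage = within / len(polytene_loci) if polytene_loci else 0.0
    return PolyteneOverlap(
        n_bands=len(index_of),
        n_site_bands=len(site_bands),
        n_locus_bands=len(polytene_loci),
        direct_overlap=direct,
        overlap_within_tolerance=within,
        coverage_fraction=coverage,
        table=table,
        chi2=float(chi2),
        p_value=float(p),
    )


def sites_to_frame(sites: list[SiteAnnotation]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": s.chrom,
                "peak_center": s.peak_center,
                "nearest_gene": s.nearest_gene,
                "distance_to_tss": s.signed_distance_to_tss,
                "category": s.category,
                "location": s.location_label,
                "genes_in_window": ";".join(
                    f"{g}:{d}" for g, d in s.genes_in_window
                ),
            }
            for s in sites
        ]
    )
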