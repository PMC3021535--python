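"""Synthetic HSF ChIP-chip study generator with planted ground truth.

Generates a complete miniature study — genome, multi-isoform annotation,
tiling probes with repeat-masked gaps, heat-shock (HS) / room-temperature (RT)
/ mock ChIP probe tables, two-system expression tables with an optional
binding-deficient mutant, and a cytological band map with a polytene locus
list — so that every downstream stage of the pipeline can be exercised and
its recovery of the planted truth measured.

Default parameters mirror the study conditions the pipeline targets: 434
bound segments averaging ~1.4 kb, a probe every 233 bp (60-mers), heat shock
elements concentrated at -400..+300 bp of peaks, RT binding retained at 81%
of HS segments and attenuated 5-fold, mostly-disjoint responsive gene sets
between the two expression systems (8% shared), and insulator (BEAF-like)
motifs planted in 27% of induced vs 66% of non-induced bound promoters. The
genome itself is scaled to a few megabases so a full run stays at desk scale.

Noise model: probe fold changes carry multiplicative log-normal noise around
a unimodal (semicircular) profile peaking at the planted peak; P[Xbar] is a
deterministic monotone transform of the noise-free fold with log-normal noise
on its exponent, so lower P[Xbar] tracks higher fold on average and exactly in
the noise-free limit. Planted peaks are snapped to the nearest probe midpoint
so that "the peak is the center of a probe" holds by construction.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as hio
from .annotation import GenomeAnnotation, classify_site
from .motifs import PositionWeightMatrix, reverse_complement

HSE_MOTIF_ID = "HSE_canonical"
BEAF_MOTIF_ID = "BEAF_synthetic"
#: planted insulator-like motif consensus (CGATA-repeat core, synthetic)
BEAF_CONSENSUS = "CGATACGATA"


def beaf_pwm() -> PositionWeightMatrix:
    """Synthetic BEAF-like PWM matching the planted consensus (97:1:1:1 columns)."""
    from .motifs import _BASE_INDEX

    counts = []
    for base in BEAF_CONSENSUS:
        col = np.full(4, 1.0)
        col[_BASE_INDEX[base]] = 97.0
        counts.append(col)
    return PositionWeightMatrix(id=BEAF_MOTIF_ID, counts=np.array(counts))


@dataclass
class SyntheticConfig:
    """Knobs of the synthetic study. All coordinates in bp."""

    # genome / annotation
    genome_length: int = 2_250_000  # per chromosome
    n_chromosomes: int = 4
    n_genes: int = 600
    gene_length_range: tuple[int, int] = (4_000, 8_000)
    extra_isoform_mean: float = 0.6  # Poisson mean of additional isoforms (cap 2)
    base_composition: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    # probes
    probe_spacing: int = 233
    probe_length: int = 60
    masked_gap_fraction: float = 0.01
    super_gap_length: int = 3_000  # one always-planted masked gap >= 10x spacing
    # bound segments
    n_segments: int = 434
    category_mix: dict = field(
        default_factory=lambda: {
            "promoter": 0.27,
            "intron": 0.35,
            "exon": 0.10,
            "intergenic": 0.28,
        }
    )
    segment_half_width: int = 700
    # planted peaks are kept isolated beyond the +-2.5 kb motif-scan range so
    # one peak's planted elements never appear in a neighbour's scan window
    min_peak_separation: int = 5_400
    hse_window: tuple[int, int] = (-400, 300)
    fold_log_mean: float = float(np.log(30.0))
    fold_log_sigma: float = 0.45
    fold_min: float = 15.0
    fold_max: float = 100.0
    # RT condition
    rt_retained_fraction: float = 0.81
    rt_attenuation: float = 5.0
    rt_ratio_sigma: float = 0.10
    # signal model
    # log10 P[Xbar] decrease per unit of fold above 1; 3.0 keeps the exponent
    # above the double-precision floor for folds up to 100 so P[Xbar] stays a
    # strictly monotone transform of the clean fold
    pxbar_gain: float = 3.0
    fold_noise_sigma: float = 0.15
    pxbar_noise_sigma: float = 0.5
    background_fp_rate: float = 5e-5
    n_mock_segments: int = 5
    # expression
    de_fraction_per_system: float = 0.05
    de_overlap_fraction: float = 0.08
    induced_bound_fraction: float = 11.0 / 115.0
    mutant_responsive_count: int = 8
    up_probability: float = 0.9
    expression_noise_sigma: float = 0.10
    # BEAF planting
    beaf_plant_prob_induced: float = 0.27
    beaf_plant_prob_noninduced: float = 0.66
    beaf_tss_offset_range: tuple[int, int] = (20, 180)  # upstream of TSS
    # cytology
    band_size: int = 20_000
    locus_rate: float = 0.75
    locus_jitter: int = 1
    locus_jitter_prob: float = 0.3
    background_locus_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        fractions = {
            "masked_gap_fraction": self.masked_gap_fraction,
            "rt_retained_fraction": self.rt_retained_fraction,
            "de_fraction_per_system": self.de_fraction_per_system,
            "de_overlap_fraction": self.de_overlap_fraction,
            "induced_bound_fraction": self.induced_bound_fraction,
            "beaf_plant_prob_induced": self.beaf_plant_prob_induced,
            "beaf_plant_prob_noninduced": self.beaf_plant_prob_noninduced,
            "locus_rate": self.locus_rate,
            "locus_jitter_prob": self.locus_jitter_prob,
            "background_locus_rate": self.background_locus_rate,
            "up_probability": self.up_probability,
            "background_fp_rate": self.background_fp_rate,
        }
        for name, value in fractions.items():
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {value}")
        if abs(sum(self.category_mix.values()) - 1.0) > 1e-9:
            raise ValueError("category_mix must sum to 1")
        if self.probe_spacing <= 0:
            raise ValueError("probe_spacing must be positive")
        if self.probe_length > self.probe_spacing:
            warnings.warn(
                "probe_length exceeds probe_spacing: probes overlap", stacklevel=2
            )
        if abs(sum(self.base_composition) - 1.0) > 1e-9:
            raise ValueError("base_composition must sum to 1")
        if self.hse_window[0] >= self.hse_window[1]:
            raise ValueError("hse_window must be a non-empty interval")

    def rng_for(self, stage: int) -> np.random.Generator:
        """Deterministic per-stage generator derived from the config seed."""
        return np.random.default_rng(np.random.SeedSequence([self.seed, stage]))

    @classmethod
    def from_yaml(cls, path) -> "SyntheticConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        for key in ("gene_length_range", "hse_window", "beaf_tss_offset_range",
                    "base_composition"):
            if key in payload and isinstance(payload[key], list):
                payload[key] = tuple(payload[key])
        return cls(**payload)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class PlantedSegment:
    chrom: str
    start: int
    end: int
    peak: int
    category: str
    max_fold: float
    has_rt_signal: bool
    gene_id: str | None = None  # owner gene for promoter-category segments

    def __post_init__(self) -> None:
        if not self.start <= self.peak < self.end:
            raise ValueError("planted peak must lie within its span")


@dataclass
class PlantedMotif:
    chrom: str
    position: int
    strand: str
    motif_id: str
    offset: int  # match start minus owning peak (HSE) or TSS (BEAF)
    segment_index: int


@dataclass
class GroundTruth:
    planted_segments: list[PlantedSegment]
    planted_motifs: list[PlantedMotif]
    responsive_genes: dict[str, dict[str, float]] = field(default_factory=dict)
    beaf_promoters: set[str] = field(default_factory=set)
    induced_bound_genes: set[str] = field(default_factory=set)
    noninduced_bound_genes: set[str] = field(default_factory=set)
    mock_segments: list[PlantedSegment] = field(default_factory=list)
    hse_window: tuple[int, int] = (-400, 300)

    def __post_init__(self) -> None:
        for motif in self.planted_motifs:
            if motif.motif_id == HSE_MOTIF_ID and not (
                self.hse_window[0] <= motif.offset <= self.hse_window[1]
            ):
                raise ValueError(
                    f"planted HSE offset {motif.offset} outside {self.hse_window}"
                )

    def segments_frame(self) -> pd.DataFrame:
        return pd.DataFrame([dataclasses.asdict(s) for s in self.planted_segments])

    def motifs_frame(self) -> pd.DataFrame:
        return pd.DataFrame([dataclasses.asdict(m) for m in self.planted_motifs])


# --- genome + annotation ------------------------------------------------------

def generate_genome(config: SyntheticConfig) -> tuple[dict[str, str], GenomeAnnotation]:
    """Random genome and a non-overlapping multi-isoform gene annotation.

    Genes are laid out in per-chromosome slots with flanking margins so that
    promoters and planted segments never collide between neighbours. Extra
    isoforms start at alternative TSSs inside an intron of the primary
    isoform, mirroring alternative first exons.
    """
    from .annotation import GeneModel, Isoform

    rng = config.rng_for(stage=1)
    chroms = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    genome = {
        chrom: "".join(
            np.array(list("ACGT"))[
                rng.choice(4, size=config.genome_length, p=list(config.base_composition))
            ]
        )
        for chrom in chroms
    }

    per_chrom = np.full(config.n_chromosomes, config.n_genes // config.n_chromosomes)
    per_chrom[: config.n_genes % config.n_chromosomes] += 1
    margin = 3_000
    genes = []
    gene_no = 0
    for chrom, n_here in zip(chroms, per_chrom):
        if n_here == 0:
            continue
        slot = config.genome_length // n_here
        if slot < config.gene_length_range[0] + 2 * margin:
            raise ValueError(
                "genome too small to place genes: need slot >= "
                f"{config.gene_length_range[0] + 2 * margin} bp per gene on {chrom}, "
                f"got {slot} (genome_length={config.genome_length}, n_genes={config.n_genes})"
            )
        for k in range(n_here):
            gene_no += 1
            gene_id = f"g{gene_no:04d}"
            slot_start = k * slot
            max_len = min(config.gene_length_range[1], slot - 2 * margin)
            length = int(rng.integers(config.gene_length_range[0], max_len + 1))
            start = slot_start + margin + int(
                rng.integers(0, max(1, slot - 2 * margin - length + 1))
            )
            end = start + length
            strand = "+" if rng.random() < 0.5 else "-"
            exons = _make_exons(rng, start, end)
            primary = Isoform(f"{gene_id}.t1", start, end, strand, exons)
            isoforms = [primary]
            n_extra = min(2, int(rng.poisson(config.extra_isoform_mean)))
            for alt_no in range(n_extra):
                alt = _make_alt_isoform(
                    rng, f"{gene_id}.t{alt_no + 2}", primary
                )
                if alt is not None:
                    isoforms.append(alt)
            genes.append(GeneModel(gene_id, chrom, strand, isoforms))
    annotation = GenomeAnnotation(genes, {c: config.genome_length for c in chroms})
    return genome, annotation


def _make_exons(rng: np.random.Generator, start: int, end: int) -> list[tuple[int, int]]:
    length = end - start
    n_exons = int(rng.integers(2, 6))
    exon_lengths = list(rng.integers(200, 401, size=n_exons))
    while n_exons > 1 and sum(exon_lengths) + 60 * (n_exons - 1) > length:
        n_exons -= 1
        exon_lengths = exon_lengths[:n_exons]
    if n_exons == 1:
        return [(start, end)]
    intron_total = length - sum(int(v) for v in exon_lengths)
    weights = rng.random(n_exons - 1) + 0.2
    weights /= weights.sum()
    intron_lengths = [int(intron_total * w) for w in weights]
    intron_lengths[-1] = intron_total - sum(intron_lengths[:-1])
    exons = []
    pos = start
    for i in range(n_exons):
        exons.append((pos, pos + int(exon_lengths[i])))
        pos = exons[-1][1]
        if i < n_exons - 1:
            pos += intron_lengths[i]
    # the layout sums exactly to the span, so the last exon ends at `end`
    assert exons[-1][1] == end
    return exons


def _make_alt_isoform(rng, isoform_id, primary):
    """Alternative-TSS isoform starting inside an intron of the primary."""
    from .annotation import Isoform

    introns = primary.introns
    if not introns:
        return None
    intron = introns[int(rng.integers(0, len(introns)))]
    if intron[1] - intron[0] < 400:
        return None
    alt_tss = int(rng.integers(intron[0] + 100, intron[1] - 100))
    if primary.strand == "+":
        # alternative first exon runs from the alt TSS through the next
        # primary exon; downstream structure is shared
        after = [(es, ee) for es, ee in primary.exons if es >= intron[1]]
        exons = [(alt_tss, after[0][1])] + after[1:]
        return Isoform(isoform_id, alt_tss, primary.end, primary.strand, exons)
    before = [(es, ee) for es, ee in primary.exons if ee <= intron[0]]
    exons = before[:-1] + [(before[-1][0], alt_tss + 1)]
    return Isoform(isoform_id, primary.start, alt_tss + 1, primary.strand, exons)


# --- probes -------------------------------------------------------------------

def generate_probes(
    chrom_lengths: dict[str, int], config: SyntheticConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tiling probe coordinates and the masked (probe-free) intervals.

    Probes are ``probe_length``-mers every ``probe_spacing`` bp. One contiguous
    super-gap of at least 10x the spacing is always planted (the analogue of a
    repeat-masked region with no array coverage); additional masked intervals
    are drawn until ``masked_gap_fraction`` of the genome is covered. Probes
    intersecting any mask are dropped.
    """
    rng = config.rng_for(stage=2)
    chroms = sorted(chrom_lengths)
    masks: list[dict] = []
    total = 0
    if config.super_gap_length > 0:
        super_len = max(config.super_gap_length, 10 * config.probe_spacing)
        super_chrom = chroms[int(rng.integers(0, len(chroms)))]
        super_start = int(
            rng.integers(0, max(1, chrom_lengths[super_chrom] - super_len))
        )
        masks.append(
            {"chrom": super_chrom, "start": super_start, "end": super_start + super_len}
        )
        total = super_len
    genome_total = sum(chrom_lengths.values())
    target = config.masked_gap_fraction * genome_total
    while total < target:
        length = int(rng.integers(300, 1501))
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        start = int(rng.integers(0, max(1, chrom_lengths[chrom] - length)))
        masks.append({"chrom": chrom, "start": start, "end": start + length})
        total += length
    mask_frame = pd.DataFrame(masks, columns=["chrom", "start", "end"])

    rows = []
    for chrom in chroms:
        length = chrom_lengths[chrom]
        chrom_masks = mask_frame[mask_frame["chrom"] == chrom]
        offset = 0
        while offset + config.probe_length <= length:
            end = offset + config.probe_length
            hit = (
                (chrom_masks["start"] < end) & (offset < chrom_masks["end"])
            ).any()
            if not hit:
                rows.append({"chrom": chrom, "start": offset, "end": end})
            offset += config.probe_spacing
    return pd.DataFrame(rows, columns=["chrom", "start", "end"]), mask_frame


# --- planted truth ------------------------------------------------------------

_CATEGORY_OK = {
    "promoter": {"promoter_intergenic", "promoter_intragenic"},
    "intron": {"intron"},
    "exon": {"exon"},
    "intergenic": {"intergenic"},
}


def plant_truth(
    genome: dict[str, str],
    annotation: GenomeAnnotation,
    probes: pd.DataFrame,
    masks: pd.DataFrame,
    config: SyntheticConfig,
) -> tuple[dict[str, str], GroundTruth]:
    """Choose segment locations per category mix and plant motifs in sequence.

    Returns the modified genome (HSE and BEAF consensus instances written in)
    and the ground-truth record. Peaks snap to the nearest probe midpoint.
    """
    rng = config.rng_for(stage=3)
    seqs = {c: bytearray(s.encode()) for c, s in genome.items()}
    probe_centers = {
        chrom: np.sort(((g["start"] + g["end"]) // 2).to_numpy())
        for chrom, g in probes.groupby("chrom")
    }
    mask_iv = {
        chrom: sorted(zip(g["start"], g["end"]))
        for chrom, g in masks.groupby("chrom")
    }
    hw = config.segment_half_width
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in genome}

    counts = _category_counts(config)
    categories = [c for c, n in counts.items() for _ in range(n)]
    rng.shuffle(categories)

    used_promoter_genes: set[str] = set()
    planted: list[PlantedSegment] = []
    motifs: list[PlantedMotif] = []
    planted_iv: dict[str, list[tuple[int, int]]] = {c: [] for c in genome}

    for category in categories:
        placed = False
        for _try in range(400):
            chrom, candidate, gene_id = _propose_peak(
                rng, annotation, config, category, used_promoter_genes
            )
            centers = probe_centers.get(chrom)
            if centers is None or len(centers) == 0:
                continue
            idx = int(np.searchsorted(centers, candidate))
            best = min(
                (i for i in (idx - 1, idx, idx + 1) if 0 <= i < len(centers)),
                key=lambda i: abs(int(centers[i]) - candidate),
            )
            peak = int(centers[best])
            if abs(peak - candidate) > config.probe_spacing:
                continue  # candidate fell in a probe gap
            start, end = peak - hw, peak + hw
            if start < 2_600 or end > config.genome_length - 2_600:
                continue
            if _intersects(mask_iv.get(chrom, []), start - 100, end + 100):
                continue
            margin = max(600, config.min_peak_separation - 2 * hw)
            if _intersects(occupied[chrom], start - margin, end + margin):
                continue
            site = classify_site(annotation, chrom, peak)
            if site.category not in _CATEGORY_OK[category]:
                continue
            owner = site.nearest_gene if category == "promoter" else gene_id
            if category == "promoter":
                if owner in used_promoter_genes:
                    continue
                used_promoter_genes.add(owner)
            seg = PlantedSegment(
                chrom=chrom,
                start=start,
                end=end,
                peak=peak,
                category=category,
                max_fold=float(
                    np.clip(
                        np.exp(rng.normal(config.fold_log_mean, config.fold_log_sigma)),
                        config.fold_min,
                        config.fold_max,
                    )
                ),
                has_rt_signal=bool(rng.random() < config.rt_retained_fraction),
                gene_id=owner if category == "promoter" else None,
            )
            occupied[chrom].append((start, end))
            motif = _plant_hse(
                rng, seqs[chrom], chrom, peak, len(planted), config, planted_iv[chrom]
            )
            planted.append(seg)
            if motif is not None:
                motifs.append(motif)
            placed = True
            break
        if not placed:
            raise ValueError(
                f"could not place a {category!r} segment after 400 tries; "
                "genome or annotation too small for the requested n_segments"
            )

    # BEAF planting on bound promoters, split by planned induction status
    promoter_segments = [s for s in planted if s.category == "promoter"]
    promoter_genes = [s.gene_id for s in promoter_segments]
    n_induced = int(round(config.induced_bound_fraction * len(promoter_genes)))
    induced = set(
        rng.choice(promoter_genes, size=n_induced, replace=False)
    ) if n_induced else set()
    noninduced = set(promoter_genes) - induced
    beaf_promoters: set[str] = set()
    gene_index = {g.gene_id: g for g in annotation.genes}
    for seg in promoter_segments:
        gene = gene_index[seg.gene_id]
        prob = (
            config.beaf_plant_prob_induced
            if seg.gene_id in induced
            else config.beaf_plant_prob_noninduced
        )
        if rng.random() >= prob:
            continue
        motif = _plant_beaf(
            rng, seqs[gene.chrom], gene, config, planted_iv[gene.chrom]
        )
        if motif is not None:
            motifs.append(motif)
            beaf_promoters.add(seg.gene_id)

    # mock-only segments away from real ones
    mock: list[PlantedSegment] = []
    for _ in range(config.n_mock_segments):
        for _try in range(200):
            chrom = list(genome)[int(rng.integers(0, len(genome)))]
            centers = probe_centers.get(chrom)
            if centers is None or len(centers) == 0:
                continue
            peak = int(centers[int(rng.integers(0, len(centers)))])
            start, end = peak - hw, peak + hw
            if start < 0 or end > config.genome_length:
                continue
            if _intersects(occupied[chrom], start - 600, end + 600):
                continue
            occupied[chrom].append((start, end))
            mock.append(
                PlantedSegment(
                    chrom, start, end, peak, "mock",
                    float(rng.uniform(5, 15)), False,
                )
            )
            break

    truth = GroundTruth(
        planted_segments=planted,
        planted_motifs=motifs,
        beaf_promoters=beaf_promoters,
        induced_bound_genes=induced,
        noninduced_bound_genes=noninduced,
        mock_segments=mock,
        hse_window=config.hse_window,
    )
    return {c: bytes(b).decode() for c, b in seqs.items()}, truth


def _category_counts(config: SyntheticConfig) -> dict[str, int]:
    raw = {c: config.n_segments * f for c, f in config.category_mix.items()}
    counts = {c: int(np.floor(v)) for c, v in raw.items()}
    remainder = config.n_segments - sum(counts.values())
    for c in sorted(raw, key=lambda c: raw[c] - counts[c], reverse=True):
        if remainder == 0:
            break
        counts[c] += 1
        remainder -= 1
    return counts


def _propose_peak(rng, annotation, config, category, used_promoter_genes):
    genes = annotation.genes
    gene = genes[int(rng.integers(0, len(genes)))]
    chrom = gene.chrom
    if category == "promoter":
        # HSF promoter binding concentrates at TSS-proximal HSEs of the
        # principal promoter (the same promoter insulator motifs occupy)
        iso = gene.isoforms[0]
        delta = int(rng.integers(-350, 351))
        return chrom, iso.tss + delta, gene.gene_id
    if category == "intron":
        iso = gene.isoforms[0]
        introns = iso.introns
        if not introns:
            return chrom, -1, None  # will fail the snap check and retry
        s, e = introns[int(rng.integers(0, len(introns)))]
        if e - s < 4:
            return chrom, -1, None
        return chrom, int(rng.integers(s, e)), gene.gene_id
    if category == "exon":
        iso = gene.isoforms[0]
        s, e = iso.exons[int(rng.integers(0, len(iso.exons)))]
        return chrom, int(rng.integers(s, e)), gene.gene_id
    # intergenic: anywhere on the gene's chromosome
    return chrom, int(rng.integers(0, config.genome_length)), None


def _intersects(intervals, start, end) -> bool:
    return any(s < end and start < e for s, e in intervals)


def _random_base(rng) -> str:
    return "ACGT"[int(rng.integers(0, 4))]


def _hse_sequence(rng) -> str:
    n = lambda: _random_base(rng)  # noqa: E731
    return f"{n()}GAA{n()}{n()}TTC{n()}{n()}GAA{n()}"


def _plant_hse(rng, seq: bytearray, chrom, peak, segment_index, config, planted_iv):
    w0, w1 = config.hse_window
    for _try in range(50):
        offset = int(rng.integers(w0, w1 - 15 + 2))  # whole 15-mer inside window
        pos = peak + offset
        if pos < 0 or pos + 15 > len(seq):
            continue
        if _intersects(planted_iv, pos, pos + 15):
            continue
        motif_seq = _hse_sequence(rng)
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            motif_seq = reverse_complement(motif_seq)
        seq[pos : pos + 15] = motif_seq.encode()
        planted_iv.append((pos, pos + 15))
        return PlantedMotif(chrom, pos, strand, HSE_MOTIF_ID, offset, segment_index)
    return None


def _plant_beaf(rng, seq: bytearray, gene, config, planted_iv):
    iso = gene.isoforms[0]
    tss = iso.tss
    lo, hi = config.beaf_tss_offset_range
    width = len(BEAF_CONSENSUS)
    for _try in range(50):
        upstream = int(rng.integers(lo, hi + 1))
        if iso.strand == "+":
            pos = tss - upstream - width
            offset = pos - tss
        else:
            pos = tss + upstream
            offset = tss - (pos + width - 1)
        if pos < 0 or pos + width > len(seq):
            continue
        if _intersects(planted_iv, pos, pos + width):
            continue
        motif_seq = BEAF_CONSENSUS
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            motif_seq = reverse_complement(motif_seq)
        seq[pos : pos + width] = motif_seq.encode()
        planted_iv.append((pos, pos + width))
        return PlantedMotif(gene.chrom, pos, strand, BEAF_MOTIF_ID, offset, -1)
    return None


# --- ChIP signal ---------------------------------------------------------------

def generate_chip_signal(
    probes: pd.DataFrame, truth: GroundTruth, config: SyntheticConfig
) -> dict[str, pd.DataFrame]:
    """Probe tables (chrom, start, end, fold, pxbar) for HS, RT, and mock.

    Fold changes follow a semicircular profile over each planted span with
    multiplicative log-normal noise; P[Xbar] is 10**(-gain*(fold_clean - 1))
    with log-normal noise on the exponent, clipped to (0, 1]. RT retains the
    configured subset of segments with folds attenuated ~``rt_attenuation``;
    the mock table is background plus the mock-only planted segments.
    """
    rng = config.rng_for(stage=4)
    out: dict[str, pd.DataFrame] = {}
    retained = [s for s in truth.planted_segments if s.has_rt_signal]
    rt_ratios = config.rt_attenuation * np.exp(
        rng.normal(0, config.rt_ratio_sigma, len(retained))
    )
    plan = {
        "hs": [(s, s.max_fold) for s in truth.planted_segments],
        "rt": [(s, s.max_fold / r) for s, r in zip(retained, rt_ratios)],
        "mock": [(s, s.max_fold) for s in truth.mock_segments],
    }

    centers = ((probes["start"] + probes["end"]) // 2).to_numpy()
    chrom_arr = probes["chrom"].to_numpy()
    n = len(probes)
    hw = config.segment_half_width
    for condition, segments in plan.items():
        fold_clean = np.ones(n)
        for seg, peak_fold in segments:
            in_span = (
                (chrom_arr == seg.chrom)
                & (centers >= seg.start)
                & (centers < seg.end)
            )
            d = centers[in_span] - seg.peak
            profile = np.sqrt(np.clip(1.0 - (d / hw) ** 2, 0.0, None))
            fold_clean[in_span] = 1.0 + (peak_fold - 1.0) * profile
        fold = fold_clean * np.exp(rng.normal(0, config.fold_noise_sigma, n))
        exponent = -config.pxbar_gain * (fold_clean - 1.0) + rng.normal(
            0, config.pxbar_noise_sigma, n
        )
        pxbar = np.clip(10.0 ** np.clip(exponent, -305, 0), 1e-305, 1.0)
        fp = rng.random(n) < config.background_fp_rate
        background = fold_clean == 1.0
        pxbar[fp & background] = 10.0 ** (-rng.uniform(3, 5, int((fp & background).sum())))
        table = probes.copy()
        table["fold"] = np.maximum(fold, 1e-6)
        table["pxbar"] = pxbar
        out[condition] = table
    return out


# --- expression -----------------------------------------------------------------

def generate_expression(
    truth: GroundTruth, annotation: GenomeAnnotation, config: SyntheticConfig
) -> pd.DataFrame:
    """Two-system (+mutant) expression tables with planted responsive sets.

    The cells-system responsive set contains the planned induced bound
    promoter genes; the two wild-type systems share ``de_overlap_fraction`` of
    their union. The mutant system retains only ``mutant_responsive_count``
    weakly induced genes, emulating loss of binding-competent HSF.
    """
    rng = config.rng_for(stage=5)
    gene_ids = [g.gene_id for g in annotation.genes]
    n_genes = len(gene_ids)
    n_per = int(round(config.de_fraction_per_system * n_genes))
    n_per = max(n_per, len(truth.induced_bound_genes))
    shared_n = int(round(config.de_overlap_fraction * 2 * n_per / (1 + config.de_overlap_fraction)))
    pool = [g for g in gene_ids if g not in truth.induced_bound_genes]
    rng.shuffle(pool)
    shared = set(pool[:shared_n])
    pool = pool[shared_n:]
    cells_only_needed = n_per - shared_n - len(truth.induced_bound_genes)
    cells_only = set(pool[: max(0, cells_only_needed)])
    pool = pool[max(0, cells_only_needed):]
    larvae_only = set(pool[: n_per - shared_n])

    cells = truth.induced_bound_genes | shared | cells_only
    larvae = shared | larvae_only

    def _planted_folds(members: set[str], force_up: set[str]) -> dict[str, float]:
        folds = {}
        for g in sorted(members):
            lfc = 1.0 + float(rng.exponential(0.8))
            up = g in force_up or rng.random() < config.up_probability
            folds[g] = float(2.0 ** lfc) if up else -float(2.0 ** lfc)
        return folds

    truth.responsive_genes = {
        "cells": _planted_folds(cells, truth.induced_bound_genes),
        "larvae": _planted_folds(larvae, set()),
    }
    mutant_pool = sorted(larvae)
    rng.shuffle(mutant_pool)
    mutant = mutant_pool[: config.mutant_responsive_count]
    truth.responsive_genes["mutant"] = {
        g: float(2.0 ** max(1.1, 0.5 * np.log2(abs(truth.responsive_genes["larvae"][g]))))
        for g in mutant
    }

    rows = []
    for system in ("cells", "larvae", "mutant"):
        planted = truth.responsive_genes[system]
        for g in gene_ids:
            if g in planted:
                signed = planted[g]
                lfc = np.log2(abs(signed)) * (1 if signed > 0 else -1)
                lfc_obs = lfc + rng.normal(0, config.expression_noise_sigma)
                p = 10.0 ** (-rng.uniform(2.5, 9.0))
            else:
                lfc_obs = rng.normal(0, config.expression_noise_sigma)
                p = float(rng.uniform(0.02, 1.0))
            ratio = 2.0 ** lfc_obs
            fold = ratio if ratio >= 1.0 else -1.0 / ratio
            rows.append(
                {"gene_id": g, "system": system, "fold_change": float(fold), "fdr_p": p}
            )
    return pd.DataFrame(rows)


# --- cytology -------------------------------------------------------------------

def generate_cytology(
    chrom_lengths: dict[str, int], truth: GroundTruth, config: SyntheticConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Contiguous band map per chromosome and a polytene locus list.

    Bands tile each chromosome without gaps. Each band holding a planted
    segment enters the locus list with probability ``locus_rate``, optionally
    jittered by one band index; background bands enter at
    ``background_locus_rate``. Loci carry an ordinal staining intensity.
    """
    rng = config.rng_for(stage=6)
    rows = []
    for chrom in sorted(chrom_lengths):
        length = chrom_lengths[chrom]
        pos = 0
        index = 0
        while pos < length:
            size = int(rng.integers(int(0.8 * config.band_size), int(1.2 * config.band_size)))
            end = min(length, pos + size)
            rows.append(
                {
                    "band": f"{chrom}-{index:03d}",
                    "chrom": chrom,
                    "start": pos,
                    "end": end,
                    "index": index,
                }
            )
            pos = end
            index += 1
    band_map = pd.DataFrame(rows)

    index_by_chrom = {
        chrom: g.sort_values("index") for chrom, g in band_map.groupby("chrom")
    }

    def band_at(chrom: str, position: int) -> tuple[str, int]:
        g = index_by_chrom[chrom]
        row = g[(g["start"] <= position) & (position < g["end"])].iloc[0]
        return str(row["band"]), int(row["index"])

    site_bands = {}
    for seg in truth.planted_segments:
        band, idx = band_at(seg.chrom, seg.peak)
        site_bands[band] = (seg.chrom, idx)

    loci = []
    chosen: set[str] = set()
    for band, (chrom, idx) in sorted(site_bands.items()):
        if rng.random() >= config.locus_rate:
            continue
        offset = 0
        if config.locus_jitter > 0 and rng.random() < config.locus_jitter_prob:
            offset = int(rng.choice([-1, 1]))
        g = index_by_chrom[chrom]
        max_idx = int(g["index"].max())
        target_idx = min(max(idx + offset, 0), max_idx)
        target = str(g[g["index"] == target_idx]["band"].iloc[0])
        if target not in chosen:
            chosen.add(target)
            loci.append({"band": target, "staining": float(rng.choice([0.5, 1, 1.5, 2, 3, 4, 5]))})
    for _, row in band_map.iterrows():
        band = str(row["band"])
        if band in chosen or band in site_bands:
            continue
        if rng.random() < config.background_locus_rate:
            chosen.add(band)
            loci.append({"band": band, "staining": float(rng.choice([0.5, 1, 1.5]))})
    return band_map, pd.DataFrame(loci, columns=["band", "staining"])


# --- whole-study orchestration --------------------------------------------------

@dataclass
class SyntheticStudy:
    config: SyntheticConfig
    genome: dict[str, str]
    annotation: GenomeAnnotation
    probes: pd.DataFrame
    masks: pd.DataFrame
    chip: dict[str, pd.DataFrame]
    expression: pd.DataFrame
    band_map: pd.DataFrame
    polytene_loci: pd.DataFrame
    truth: GroundTruth

    def write(self, outdir) -> Path:
        out = hio.ensure_dir(outdir)
        hio.write_fasta(self.genome, out / "genome.fa")
        hio.write_gff3(self.annotation, out / "annotation.gff3")
        hio.write_probes_bed(self.probes, out / "probes.bed")
        hio.write_tsv(self.masks, out / "masked_regions.tsv")
        for condition, table in self.chip.items():
            hio.write_tsv(table, out / f"chip_{condition}.tsv")
        hio.write_tsv(self.expression, out / "expression.tsv")
        hio.write_tsv(self.band_map, out / "band_map.tsv")
        hio.write_tsv(self.polytene_loci, out / "polytene_loci.tsv")
        hio.write_tsv(self.truth.segments_frame(), out / "truth_segments.tsv")
        hio.write_tsv(self.truth.motifs_frame(), out / "truth_motifs.tsv")
        hio.write_json(
            {
                "seed": self.config.seed,
                "config": self.config.to_dict(),
                "responsive_genes": {
                    k: v for k, v in self.truth.responsive_genes.items()
                },
                "beaf_promoters": sorted(self.truth.beaf_promoters),
                "induced_bound_genes": sorted(self.truth.induced_bound_genes),
                "noninduced_bound_genes": sorted(self.truth.noninduced_bound_genes),
            },
            out / "manifest.json",
        )
        return out


def simulate_study(config: SyntheticConfig | None = None) -> SyntheticStudy:
    """Run every generator stage in order and return the assembled study."""
    config = config or SyntheticConfig()
    genome, annotation = generate_genome(config)
    probes, masks = generate_probes(annotation.chrom_lengths, config)
    genome, truth = plant_truth(genome, annotation, probes, masks, config)
    chip = generate_chip_signal(probes, truth, config)
    expression = generate_expression(truth, annotation, config)
    band_map, loci = generate_cytology(annotation.chrom_lengths, truth, config)
    return SyntheticStudy(
        config=config,
        genome=genome,
        annotation=annotation,
        probes=probes,
        masks=masks,
        chip=chip,
        expression=expression,
        band_map=band_map,
        polytene_loci=loci,
        truth=truth,
    )
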