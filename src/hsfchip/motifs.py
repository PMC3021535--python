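"""Position weight matrices: parsing, log-odds scoring, exact match p-values, scanning.

A PWM here is a per-position base-count model over {A, C, G, T} with an i.i.d.
background. Match significance follows the pattern-matcher convention: the
p-value of a log-odds score *s* is the tail probability ``P(score >= s)`` for a
single window of background sequence, computed exactly by position-wise
convolution of the discretized score distribution. No multiple-testing
adjustment happens inside :func:`scan`; thresholds such as 1e-4 or 1e-5 are
therefore directly comparable across matrices.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = np.array([3, 2, 1, 0], dtype=np.int64)

UNIFORM_BACKGROUND = np.full(4, 0.25)


def encode_sequence(seq: str) -> np.ndarray:
    """Encode a DNA string as int codes A=0 C=1 G=2 T=3; anything else -> 4."""
    table = np.full(256, 4, dtype=np.int8)
    for b, i in _BASE_INDEX.items():
        table[ord(b)] = i
        table[ord(b.lower())] = i
    return table[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)].astype(np.int64)


def reverse_complement(seq: str) -> str:
    comp = str.maketrans("ACGTacgtN", "TGCAtgcaN")
    return seq.translate(comp)[::-1]


@dataclass
class PositionWeightMatrix:
    """Per-position base counts with a pseudocount and background model.

    ``counts`` has shape (width, 4) in A, C, G, T order. ``pseudocount`` is the
    total pseudo-observation mass added per column, split according to the
    background frequencies (so a uniform background adds pseudocount/4 to each
    base).
    """

    id: str
    counts: np.ndarray
    pseudocount: float | None = None
    background: np.ndarray = field(default_factory=lambda: UNIFORM_BACKGROUND.copy())

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[1] != 4:
            raise ValueError(f"PWM {self.id!r}: counts must be (width, 4)")
        if self.counts.shape[0] < 1:
            raise ValueError(f"PWM {self.id!r}: width must be >= 1")
        if np.any(self.counts < 0):
            raise ValueError(f"PWM {self.id!r}: negative counts")
        self.background = np.asarray(self.background, dtype=float)
        if self.background.shape != (4,) or np.any(self.background <= 0):
            raise ValueError("background must be 4 positive frequencies")
        if abs(self.background.sum() - 1.0) > 1e-9:
            raise ValueError("background frequencies must sum to 1")
        if self.pseudocount is None:
            # default: 1% of the (maximum) column total, avoids -inf log-odds
            # while leaving threshold-crossing at printed cut-offs unaffected
            # for well-populated matrices.
            self.pseudocount = 0.01 * float(self.counts.sum(axis=1).max())
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be non-negative")

    @property
    def width(self) -> int:
        return int(self.counts.shape[0])

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in np.argmax(self.counts, axis=1))

    def log_odds(self) -> np.ndarray:
        """Natural-log odds matrix, shape (width, 4).

        entry(i, b) = log((counts(i,b) + pc*bg(b)) / (col_total(i) + pc)) - log(bg(b))
        """
        totals = self.counts.sum(axis=1, keepdims=True)
        if self.pseudocount == 0 and np.any(totals == 0):
            raise ValueError(
                f"PWM {self.id!r}: zero total counts at a position with pseudocount 0"
            )
        freqs = (self.counts + self.pseudocount * self.background) / (
            totals + self.pseudocount
        )
        with np.errstate(divide="ignore"):  # -inf is legitimate at pc = 0
            return np.log(freqs) - np.log(self.background)

    def reverse_complement(self) -> "PositionWeightMatrix":
        return PositionWeightMatrix(
            id=self.id + "_rc",
            counts=self.counts[::-1, ::-1].copy(),
            pseudocount=self.pseudocount,
            background=self.background.copy(),
        )


def log_odds(pwm: PositionWeightMatrix) -> np.ndarray:
    return pwm.log_odds()


@dataclass
class ScoreDistribution:
    """Exact discretized distribution of the log-odds score under the background.

    ``mass[k]`` is the probability of the score bin with index ``offset + k``;
    a score *s* maps to bin ``round(s / bin_width)``.
    """

    bin_width: float
    offset: int
    mass: np.ndarray

    def __post_init__(self) -> None:
        total = float(self.mass.sum())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"score distribution mass sums to {total}, not 1")
        # survival[k] = P(bin >= offset + k)
        self._survival = np.cumsum(self.mass[::-1])[::-1]

    def bin_of(self, score: float) -> int:
        return int(round(score / self.bin_width))

    def tail_bin(self, bin_index: int) -> float:
        """P(score bin >= bin_index) on the distribution's own support."""
        k = bin_index - self.offset
        if k <= 0:
            return 1.0
        if k >= len(self.mass):
            return 0.0
        return float(self._survival[k])

    def tail(self, score: float) -> float:
        """P(score' >= score) with both scores resolved to discretization bins."""
        return self.tail_bin(self.bin_of(score))

    def threshold_bin(self, p_threshold: float) -> int:
        """Smallest bin index whose tail probability is < p_threshold."""
        idx = np.nonzero(self._survival < p_threshold)[0]
        if len(idx) == 0:
            return self.offset + len(self.mass)  # beyond the support
        return self.offset + int(idx[0])

    def score_threshold(self, p_threshold: float) -> float:
        """Smallest representable score whose tail probability is < p_threshold.

        Returns +inf when no score is that extreme.
        """
        idx = np.nonzero(self._survival < p_threshold)[0]
        if len(idx) == 0:
            return math.inf
        return (self.offset + int(idx[0])) * self.bin_width


def score_pvalue_distribution(
    pwm: PositionWeightMatrix, bin_width: float = 1e-3
) -> ScoreDistribution:
    """Exact score distribution by position-wise convolution over score bins."""
    lom = pwm.log_odds()
    bins = np.rint(lom / bin_width).astype(np.int64)
    lo = int(bins.min(axis=1).sum())
    hi = int(bins.max(axis=1).sum())
    mass = np.zeros(hi - lo + 1)
    # running support starts at offset 0 relative to the eventual minimum
    cur = np.array([1.0])
    cur_lo = 0
    for i in range(pwm.width):
        step_lo = int(bins[i].min())
        width = int(bins[i].max()) - step_lo + 1
        kernel = np.zeros(width)
        for b in range(4):
            kernel[bins[i, b] - step_lo] += pwm.background[b]
        cur = np.convolve(cur, kernel)
        cur_lo += step_lo
    mass[cur_lo - lo : cur_lo - lo + len(cur)] = cur
    return ScoreDistribution(bin_width=bin_width, offset=lo, mass=mass)


@dataclass(frozen=True)
class MotifMatch:
    chrom: str
    position: int  # 0-based match start on the forward strand
    strand: str
    score: float
    p_value: float
    pwm_id: str


@dataclass
class ScanResult:
    matches: list[MotifMatch]
    n_windows_scanned: int
    n_windows_skipped: int  # windows containing N

    def __iter__(self):
        return iter(self.matches)

    def __len__(self) -> int:
        return len(self.matches)


def scan(
    sequence: str,
    pwm: PositionWeightMatrix,
    p_threshold: float,
    chrom: str = "",
    offset: int = 0,
    distribution: ScoreDistribution | None = None,
    both_strands: bool = True,
) -> ScanResult:
    """Scan both strands for matches with tail probability < p_threshold.

    Matches are reported by their forward-strand start coordinate
    (``offset`` + position within ``sequence``); windows containing N are
    skipped and counted. Output is sorted by position with '+' before '-' at
    equal positions.
    """
    if not 0 < p_threshold <= 1:
        raise ValueError("p_threshold must be in (0, 1]")
    w = pwm.width
    codes = encode_sequence(sequence)
    n_pos = len(codes) - w + 1
    if n_pos <= 0:
        return ScanResult([], 0, 0)
    dist = distribution or score_pvalue_distribution(pwm)
    bin_min = dist.threshold_bin(p_threshold)

    windows = np.lib.stride_tricks.sliding_window_view(codes, w)  # (n_pos, w)
    valid = ~(windows == 4).any(axis=1)
    n_skipped = int(n_pos - valid.sum())

    def _collect(lom: np.ndarray, strand: str) -> list[MotifMatch]:
        safe = np.where(windows == 4, 0, windows)
        # score each window on the distribution's own discretized support so
        # that match p-values and the exact tail distribution agree bin-for-bin
        blom = np.rint(lom / dist.bin_width).astype(np.int64)
        idx = np.arange(w)[None, :]
        bin_scores = blom[idx, safe].sum(axis=1)
        hits = np.nonzero(valid & (bin_scores >= bin_min))[0]
        scores = lom[idx, safe[hits]].sum(axis=1) if len(hits) else np.array([])
        return [
            MotifMatch(
                chrom,
                offset + int(p),
                strand,
                float(s),
                dist.tail_bin(int(bin_scores[p])),
                pwm.id,
            )
            for p, s in zip(hits, scores)
        ]

    lom_fwd = pwm.log_odds()
    matches = _collect(lom_fwd, "+")
    if both_strands:
        lom_rev = lom_fwd[::-1, ::-1]  # rc-matrix scored on the forward strand
        matches += _collect(lom_rev, "-")
    matches.sort(key=lambda m: (m.position, m.strand))
    total_scanned = int(valid.sum()) * (2 if both_strands else 1)
    return ScanResult(matches, total_scanned, n_skipped)


def scramble_columns(pwm: PositionWeightMatrix, seed: int) -> PositionWeightMatrix:
    """Permute the position columns with a seeded uniform permutation."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(pwm.width)
    return PositionWeightMatrix(
        id=pwm.id + "_scrambled",
        counts=pwm.counts[perm].copy(),
        pseudocount=pwm.pseudocount,
        background=pwm.background.copy(),
    )


# --- nGAAn triplet (heat shock element) matrices -----------------------------

#: 5-bp unit: n + three informative positions + n. The flanking "n" columns are
#: uniform; informative columns are strongly biased (97:1:1:1).
_UNIT_N = np.array([25.0, 25.0, 25.0, 25.0])


def _unit_counts(core: str) -> np.ndarray:
    rows = [_UNIT_N.copy()]
    for base in core:
        col = np.full(4, 1.0)
        col[_BASE_INDEX[base]] = 97.0
        rows.append(col)
    rows.append(_UNIT_N.copy())
    return np.array(rows)


_UNITS = {"GAA": _unit_counts("GAA"), "TTC": _unit_counts("TTC")}

TRIPLET_ARRANGEMENTS = [
    ("GAA", "GAA", "GAA"),
    ("GAA", "GAA", "TTC"),
    ("GAA", "TTC", "GAA"),  # canonical inverted repeat nGAAnnTTCnnGAAn
    ("GAA", "TTC", "TTC"),
    ("TTC", "GAA", "GAA"),
    ("TTC", "GAA", "TTC"),
    ("TTC", "TTC", "GAA"),
    ("TTC", "TTC", "TTC"),
]

CANONICAL_HSE = ("GAA", "TTC", "GAA")


def make_triplet_pwm(
    arrangement: tuple[str, str, str],
    background: np.ndarray | None = None,
) -> PositionWeightMatrix:
    """Assemble a 15-position HSE matrix from three 5-bp nGAAn/nTTCn units."""
    for unit in arrangement:
        if unit not in _UNITS:
            raise ValueError(f"invalid arrangement token {unit!r}; use 'GAA' or 'TTC'")
    counts = np.vstack([_UNITS[u] for u in arrangement])
    return PositionWeightMatrix(
        id="HSE_" + "-".join(arrangement),
        counts=counts,
        background=UNIFORM_BACKGROUND.copy() if background is None else background,
    )


# --- TRANSFAC-dialect I/O ----------------------------------------------------

def read_transfac(path) -> list[PositionWeightMatrix]:
    """Parse a TRANSFAC-dialect count matrix file.

    Records start with an ``ID`` (or ``NA``) line, the matrix block is headed
    by ``P0`` or ``PO`` with column order given by the header (normally
    A C G T), position rows carry four numbers (an optional trailing consensus
    letter is ignored), and ``//`` terminates a record.
    """
    with open(path) as fh:
        lines = fh.readlines()
    pwms: list[PositionWeightMatrix] = []
    ident: str | None = None
    order: list[int] | None = None
    rows: list[list[float]] = []

    def _flush(line_no: int) -> None:
        nonlocal ident, order, rows
        if rows:
            counts = np.zeros((len(rows), 4))
            for i, row in enumerate(rows):
                for j, idx in enumerate(order):  # type: ignore[arg-type]
                    counts[i, idx] = row[j]
            pwms.append(
                PositionWeightMatrix(id=ident or f"matrix_{len(pwms) + 1}", counts=counts)
            )
        ident, order, rows = None, None, []

    for line_no, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line:
            continue
        tag = line.split()[0]
        if tag == "//":
            _flush(line_no)
        elif tag in ("ID", "NA") and ident is None:
            ident = line.split(maxsplit=1)[1] if len(line.split(maxsplit=1)) > 1 else None
        elif tag in ("P0", "PO"):
            cols = line.split()[1:5]
            try:
                order = [_BASE_INDEX[c.upper()] for c in cols]
            except KeyError as exc:
                raise ValueError(f"line {line_no}: bad P0 header {line!r}") from exc
            if len(order) != 4:
                raise ValueError(f"line {line_no}: P0 header needs 4 base columns")
        elif order is not None and tag[0].isdigit():
            fields = line.split()[1:]
            if fields and not _is_number(fields[-1]):
                fields = fields[:-1]  # trailing consensus letter
            if len(fields) != 4:
                raise ValueError(
                    f"line {line_no}: expected 4 counts in position row, got "
                    f"{len(fields)}: {line!r}"
                )
            rows.append([float(x) for x in fields])
    _flush(len(lines))
    return pwms


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


def write_transfac(pwms: list[PositionWeightMatrix], path) -> None:
    with open(path, "w") as fh:
        for pwm in pwms:
            fh.write(f"ID {pwm.id}\nP0 A C G T\n")
            for i, row in enumerate(pwm.counts, start=1):
                vals = " ".join(_fmt_count(v) for v in row)
                fh.write(f"{i:02d} {vals}\n")
            fh.write("//\n")


def _fmt_count(v: float) -> str:
    return str(int(v)) if float(v).is_integer() else f"{v:g}"


def read_json_matrices(path) -> list[PositionWeightMatrix]:
    """Read matrices from a simple JSON format: [{id, counts[, background]}]."""
    with open(path) as fh:
        payload = json.load(fh)
    out = []
    for rec in payload:
        out.append(
            PositionWeightMatrix(
                id=rec["id"],
                counts=np.array(rec["counts"], dtype=float),
                background=np.array(rec.get("background", UNIFORM_BACKGROUND), dtype=float),
            )
        )
    return out


def write_matches_bed(matches: list[MotifMatch], pwm_width: int, path) -> None:
    """Write matches as BED6: name = pwm id, score = -log10 p (capped at 999)."""
    with open(path, "w") as fh:
        for m in matches:
            score = min(999.0, -math.log10(max(m.p_value, 1e-300)))
            fh.write(
                f"{m.chrom}\t{m.position}\t{m.position + pwm_width}\t"
                f"{m.pwm_id}\t{score:.3f}\t{m.strand}\n"
            )
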