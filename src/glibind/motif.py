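"""MATCH-style matrix-similarity motif scoring.

A :class:`WeightMatrix` stores per-position base frequencies f(i, b) and the
derived information vector I(i) = sum_b f(i,b) * ln(4 f(i,b)) (with the
0*ln 0 := 0 convention). A window w of matrix length scores

    MSS = (Current - Min) / (Max - Min)

where Current = sum_i I(i) f(i, w_i), and Min/Max substitute the per-position
minimum/maximum frequency. MSS lies in [0, 1]; 1.0 is attained exactly when
every position holds a maximal-frequency base. Natural logarithms, no
pseudocounts: zero-frequency bases contribute 0 to I(i) and can drive
Min = 0. Only the matrix-similarity score is computed (no separate core
score), and thresholds are compared strictly (score > threshold).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import cached_property
from typing import Mapping, Sequence

import numpy as np

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

IUPAC_CODES: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

# byte -> base code lookup; 4 marks anything that is not an unambiguous base
_CODE_LUT = np.full(256, 4, dtype=np.uint8)
for _b, _i in _BASE_INDEX.items():
    _CODE_LUT[ord(_b)] = _i
    _CODE_LUT[ord(_b.lower())] = _i


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class WeightMatrix:
    """Per-position base-frequency matrix with its information vector.

    ``freqs`` is an (L, 4) array over A, C, G, T; every row sums to 1.
    """

    name: str
    freqs: np.ndarray

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.freqs.ndim != 2 or self.freqs.shape[1] != 4:
            raise ValueError("freqs must be an (L, 4) array")
        if np.any(self.freqs < 0):
            raise ValueError("frequencies must be non-negative")
        if not np.allclose(self.freqs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("each position's frequencies must sum to 1")

    @property
    def length(self) -> int:
        return self.freqs.shape[0]

    @cached_property
    def information(self) -> np.ndarray:
        """I(i) = sum_b f(i,b) ln(4 f(i,b)), non-negative, 0 for uniform rows."""
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(self.freqs > 0, self.freqs * np.log(4.0 * self.freqs), 0.0)
        info = terms.sum(axis=1)
        return np.maximum(info, 0.0)  # clip -0.0 / rounding residue

    @cached_property
    def _score_bounds(self) -> tuple[float, float]:
        info = self.information
        return (
            float((info * self.freqs.min(axis=1)).sum()),
            float((info * self.freqs.max(axis=1)).sum()),
        )

    @property
    def consensus(self) -> str:
        """Maximal-frequency base per position (leftmost of ties in ACGT order)."""
        return "".join(BASES[i] for i in self.freqs.argmax(axis=1))


def matrix_from_iupac(consensus: str, name: str | None = None) -> WeightMatrix:
    """Build a frequency matrix from an IUPAC consensus: each position gives
    frequency 1/k to each of the k bases its code allows, 0 to the rest."""
    consensus = consensus.upper()
    freqs = np.zeros((len(consensus), 4))
    for i, code in enumerate(consensus):
        try:
            allowed = IUPAC_CODES[code]
        except KeyError:
            raise ValueError(f"invalid IUPAC code {code!r} at position {i}") from None
        for base in allowed:
            freqs[i, _BASE_INDEX[base]] = 1.0 / len(allowed)
    return WeightMatrix(name=name or consensus, freqs=freqs)


def read_transfac(path) -> WeightMatrix:
    """Read a TRANSFAC-like plain-text count/frequency table.

    Expected layout: an optional ``ID``/``NA`` line giving the name, a header
    line whose fields end with A C G T (in any order), then one line per
    position: index followed by four counts. Counts are converted to
    per-position frequencies.
    """
    name = "matrix"
    order = list(BASES)
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            fields = line.split()
            if not fields or fields[0] in ("XX", "//"):
                continue
            if fields[0] in ("ID", "NA"):
                name = fields[-1]
            elif fields[0] in ("P0", "PO"):
                order = fields[1:5]
            elif fields[0][0].isdigit():
                rows.append([float(x) for x in fields[1:5]])
    if not rows:
        raise ValueError(f"no matrix rows found in {path}")
    counts = np.array(rows)
    # reorder columns to A C G T
    idx = [order.index(b) for b in BASES]
    counts = counts[:, idx]
    totals = counts.sum(axis=1, keepdims=True)
    if np.any(totals <= 0):
        raise ValueError("every position must have a positive total count")
    return WeightMatrix(name=name, freqs=counts / totals)


@dataclass(frozen=True)
class MotifHit:
    """A scored motif occurrence; ``position`` is the match start in forward
    coordinates regardless of strand."""

    chrom: str
    position: int
    strand: str
    score: float
    motif: str

    def __post_init__(self) -> None:
        if not (0.0 <= self.score <= 1.0 + 1e-12):
            raise ValueError(f"score {self.score} outside [0, 1]")


def match_score(matrix: WeightMatrix, window: str) -> float:
    """Matrix-similarity score of a single window (must be over A/C/G/T and of
    matrix length). Degenerate matrices with Max == Min (every window equally
    maximal) score 1.0."""
    if len(window) != matrix.length:
        raise ValueError(f"window length {len(window)} != matrix length {matrix.length}")
    codes = _CODE_LUT[np.frombuffer(window.upper().encode(), dtype=np.uint8)]
    if np.any(codes == 4):
        raise ValueError(f"ambiguous base in window {window!r}")
    info = matrix.information
    current = float((info * matrix.freqs[np.arange(matrix.length), codes]).sum())
    lo, hi = matrix._score_bounds
    if hi - lo <= 0:
        return 1.0
    return (current - lo) / (hi - lo)


def _scan_forward(codes: np.ndarray, matrix: WeightMatrix) -> np.ndarray:
    """MSS per offset on one strand; NaN where the window holds an ambiguous
    base. ``codes`` is the uint8-encoded sequence."""
    L = matrix.length
    n = len(codes) - L + 1
    if n <= 0:
        return np.zeros(0)
    weights = matrix.information[:, None] * matrix.freqs  # (L, 4)
    padded = np.concatenate([weights, np.zeros((L, 1))], axis=1)  # code 4 -> 0
    current = np.zeros(n)
    for i in range(L):
        current += padded[i, codes[i : i + n]]
    lo, hi = matrix._score_bounds
    scores = np.full(n, 1.0) if hi - lo <= 0 else (current - lo) / (hi - lo)
    bad = np.cumsum(np.concatenate([[0], (codes == 4).astype(np.int64)]))
    invalid = (bad[L:] - bad[:-L]) > 0
    scores = scores.astype(float)
    scores[invalid] = np.nan
    return scores


def scan_sequence(
    seq: str,
    matrix: WeightMatrix,
    threshold: float = 0.65,
    chrom: str = "",
    offset: int = 0,
) -> list[MotifHit]:
    """Scan both strands of ``seq`` at every offset; return hits with
    score > threshold, sorted by forward-strand position. Reverse-strand
    scores are computed on the reverse complement; windows containing
    ambiguous bases are skipped."""
    codes = _CODE_LUT[np.frombuffer(seq.upper().encode(), dtype=np.uint8)]
    L = matrix.length
    hits: list[MotifHit] = []
    fwd = _scan_forward(codes, matrix)
    for pos in np.flatnonzero(fwd > threshold):
        hits.append(MotifHit(chrom, offset + int(pos), "+", float(fwd[pos]), matrix.name))
    rc_codes = _CODE_LUT[
        np.frombuffer(reverse_complement(seq).upper().encode(), dtype=np.uint8)
    ]
    rev = _scan_forward(rc_codes, matrix)
    for pos in np.flatnonzero(rev > threshold):
        fwd_pos = len(seq) - L - int(pos)
        hits.append(MotifHit(chrom, offset + fwd_pos, "-", float(rev[pos]), matrix.name))
    hits.sort(key=lambda h: (h.position, h.strand))
    return hits


def _get_sequence(genome, chrom: str) -> str:
    """Accept a plain chrom->sequence mapping or an object exposing one via a
    ``sequence`` attribute (e.g. the synthetic genome container)."""
    source = getattr(genome, "sequence", genome)
    return source[chrom]


def scan_interval(
    genome,
    chrom: str,
    start: int,
    end: int,
    matrix: WeightMatrix,
    threshold: float = 0.65,
) -> list[MotifHit]:
    """Scan one genomic interval on both strands. Intervals extending past the
    chromosome are clipped with a warning; hit positions are genomic."""
    seq = _get_sequence(genome, chrom)
    lo, hi = max(0, start), min(len(seq), end)
    if (lo, hi) != (start, end):
        warnings.warn(
            f"interval {chrom}:{start}-{end} clipped to {lo}-{hi}", stacklevel=2
        )
    if hi <= lo:
        return []
    return scan_sequence(seq[lo:hi], matrix, threshold, chrom=chrom, offset=lo)


def motif_presence(
    peaks: Sequence,
    genome,
    matrix: WeightMatrix,
    flank: int = 250,
    threshold: float = 0.65,
) -> tuple[float, list[bool]]:
    """Fraction of peaks with at least one motif hit within ``flank`` bp of
    the summit (window [summit - flank, summit + flank)).

    Records without a summit attribute (e.g. merged co-occupied regions) use
    their interval midpoint. Returns (fraction, per-peak flags).
    """
    peaks = list(peaks)
    if not peaks:
        raise ValueError("motif presence is undefined for an empty peak list")
    flags: list[bool] = []
    for peak in peaks:
        center = getattr(peak, "summit", None)
        if center is None:
            center = (peak.start + peak.end) // 2
        hits = scan_interval(
            genome, peak.chrom, center - flank, center + flank, matrix, threshold
        )
        flags.append(bool(hits))
    return sum(flags) / len(flags), flags
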