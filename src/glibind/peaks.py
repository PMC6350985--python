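"""Enrichment-region detection and the three-criteria peak selection.

The caller is a thresholded run-merger: after normalization and control
subtraction, maximal runs of positions above a background threshold become
candidate regions, runs separated by less than the bandwidth (250 bp by
default, roughly the sonicated fragment size) are merged, and regions
narrower than a minimum width are discarded. The summit is the leftmost
position of maximum signal; the intensity score is the signal there.

Selection keeps a peak if it satisfies any of:
  (a) intensity greater than the mean + 1 SD of its fraction's peak scores,
  (b) >= 1 bp overlap with an evolutionarily conserved element,
  (c) a peak of the other fraction within 250 bp (edge gap; overlap = 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .coverage import CoverageTrack
from .regions import DEFAULT_DISTANCE, overlaps_any, within_distance

DEFAULT_BANDWIDTH = 250
DEFAULT_MIN_WIDTH = 50


@dataclass(frozen=True)
class Peak:
    """A called enrichment region (0-based half-open) with its summit."""

    chrom: str
    start: int
    end: int
    summit: int
    intensity: float
    fraction: str = ""
    reasons: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if not (self.start <= self.summit < self.end):
            raise ValueError(
                f"summit {self.summit} outside [{self.start}, {self.end})"
            )
        if self.intensity <= 0:
            raise ValueError("peak intensity must be positive")


def _runs(mask: np.ndarray) -> np.ndarray:
    """(k, 2) array of [start, end) bounds of True runs."""
    padded = np.concatenate([[False], mask, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return edges.reshape(-1, 2)


def auto_background(track: CoverageTrack) -> float:
    """Parameter-free background threshold: the mean of all nonzero values of
    the (normalized, control-subtracted) track. Zero if the track is empty."""
    nonzero = [v[v > 0] for v in track.values.values()]
    nonzero = [v for v in nonzero if v.size]
    if not nonzero:
        return 0.0
    concat = np.concatenate(nonzero)
    return float(concat.mean())


def detect_enriched_regions(
    track: CoverageTrack,
    bandwidth: int = DEFAULT_BANDWIDTH,
    background: float | str = "auto",
    min_width: int = DEFAULT_MIN_WIDTH,
    fraction: str = "",
) -> list[Peak]:
    """Call enrichment regions on a normalized, control-subtracted track.

    Returns peaks sorted by (chrom, start); within a chromosome the calls are
    pairwise separated by at least ``bandwidth`` (closer runs were merged).
    """
    bg = auto_background(track) if background == "auto" else float(background)
    peaks: list[Peak] = []
    for chrom in track.chroms:
        values = track.values[chrom]
        runs = _runs(values > bg)
        if runs.size == 0:
            continue
        merged: list[list[int]] = [list(runs[0])]
        for start, end in runs[1:]:
            if start - merged[-1][1] < bandwidth:
                merged[-1][1] = end
            else:
                merged.append([start, end])
        for start, end in merged:
            if end - start < min_width:
                continue
            summit = start + int(np.argmax(values[start:end]))  # leftmost tie
            peaks.append(
                Peak(
                    chrom=chrom,
                    start=int(start),
                    end=int(end),
                    summit=summit,
                    intensity=float(values[summit]),
                    fraction=fraction,
                )
            )
    return peaks


def intensity_cutoff(values: Sequence[float]) -> tuple[float, float, float]:
    """(mean, sample SD, mean + 1 SD) of a collection of intensity scores."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("intensity statistics require at least 2 values")
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1))
    return mean, sd, mean + sd


def intensity_filter(peaks: Sequence[Peak]) -> tuple[list[Peak], float, float]:
    """Keep peaks with intensity strictly greater than mean + 1 SD of the
    input intensities; also return the statistics used."""
    mean, sd, cutoff = intensity_cutoff([p.intensity for p in peaks])
    kept = [p for p in peaks if p.intensity > cutoff]
    return kept, mean, sd


def select_peaks(
    peaks: Sequence[Peak],
    conserved: Sequence,
    other_fraction: Sequence[Peak],
    distance: int = DEFAULT_DISTANCE,
) -> list[Peak]:
    """Union of the three selection criteria, with reasons recorded per peak.

    A peak is kept if it passes the intensity filter ("intensity"), overlaps
    a conserved element by >= 1 bp ("conserved"), or lies within ``distance``
    of a peak of the other fraction ("cooccupied").
    """
    peaks = list(peaks)
    if not peaks:
        return []
    _, _, cutoff = intensity_cutoff([p.intensity for p in peaks])
    pass_a = np.array([p.intensity > cutoff for p in peaks])
    pass_b = overlaps_any(peaks, list(conserved)) if len(conserved) else np.zeros(len(peaks), bool)
    pass_c = (
        within_distance(peaks, list(other_fraction), distance)
        if len(other_fraction)
        else np.zeros(len(peaks), bool)
    )
    selected = []
    for peak, a, b, c in zip(peaks, pass_a, pass_b, pass_c):
        reasons = tuple(
            name for name, flag in (("intensity", a), ("conserved", b), ("cooccupied", c)) if flag
        )
        if reasons:
            selected.append(replace(peak, reasons=reasons))
    return selected
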