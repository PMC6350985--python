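"""Per-base coverage tracks: normalization and control subtraction.

A :class:`CoverageTrack` holds dense per-base signal for one or more
chromosomes together with the sequencing library size. Tracks are exchanged
on disk as bedGraph (0-based, half-open); see :mod:`glibind.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np


@dataclass
class CoverageTrack:
    """Dense coverage signal per chromosome.

    Parameters
    ----------
    values
        Mapping chromosome name -> per-base signal (non-negative floats).
    library_size
        Total aligned reads in the library the track was derived from.
        Must be positive; used for per-million normalization.
    normalized
        Whether :func:`normalize_coverage` has been applied.
    """

    values: dict[str, np.ndarray]
    library_size: int
    normalized: bool = field(default=False)

    def __post_init__(self) -> None:
        if self.library_size <= 0:
            raise ValueError(f"library_size must be positive, got {self.library_size}")
        self.values = {c: np.asarray(v, dtype=float) for c, v in self.values.items()}

    @property
    def chroms(self) -> list[str]:
        return sorted(self.values)

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: len(v) for c, v in self.values.items()}

    def total_signal(self) -> float:
        return float(sum(v.sum() for v in self.values.values()))


def normalize_coverage(track: CoverageTrack) -> CoverageTrack:
    """Scale a track to reads-per-million: every value times 1e6/library_size.

    The library size is preserved as metadata so the scaling law
    ``normalize(k*reads)/k == normalize(reads)`` holds.
    """
    if track.library_size <= 0:
        raise ValueError("cannot normalize a track with non-positive library size")
    factor = 1e6 / track.library_size
    return CoverageTrack(
        values={c: v * factor for c, v in track.values.items()},
        library_size=track.library_size,
        normalized=True,
    )


def subtract_control(tf: CoverageTrack, control: CoverageTrack) -> CoverageTrack:
    """Per-base ``max(0, tf - control)``.

    Both tracks must cover the same chromosomes at the same lengths (positions
    absent from a chromosome a track does not carry would be ambiguous, so a
    mismatch is an input error). Output keeps the TF track's library size.
    """
    if set(tf.values) != set(control.values):
        raise ValueError(
            f"chromosome mismatch: {sorted(tf.values)} vs {sorted(control.values)}"
        )
    out: dict[str, np.ndarray] = {}
    for chrom in tf.values:
        a, b = tf.values[chrom], control.values[chrom]
        if len(a) != len(b):
            raise ValueError(f"length mismatch on {chrom}: {len(a)} vs {len(b)}")
        out[chrom] = np.maximum(a - b, 0.0)
    return CoverageTrack(values=out, library_size=tf.library_size, normalized=tf.normalized)
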