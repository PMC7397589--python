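"""Fixed-bin-size coverage tracks.

A :class:`BinnedTrack` holds the binned read counts of one chromosome for one
condition; a "genome track" is a plain dict mapping chromosome name to
BinnedTrack, the shape all calling functions consume.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class GridError(ValueError):
    """Two tracks do not share a bin grid."""


@dataclass
class BinnedTrack:
    chrom: str
    bin_size: int
    counts: np.ndarray
    condition: str = ""

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.float64)
        if (self.counts < 0).any():
            raise ValueError(f"negative counts in track {self.condition}/{self.chrom}")

    @property
    def n_bins(self) -> int:
        return len(self.counts)

    @property
    def chrom_length(self) -> int:
        return self.n_bins * self.bin_size  # upper bound; last bin may be partial

    def bin_of(self, position: np.ndarray | int) -> np.ndarray | int:
        return np.asarray(position) // self.bin_size


GenomeTrack = dict  # chrom -> BinnedTrack


def library_size(track: GenomeTrack) -> float:
    return float(sum(t.counts.sum() for t in track.values()))


def check_same_grid(a: GenomeTrack, b: GenomeTrack) -> None:
    if set(a) != set(b):
        raise GridError(f"chromosome sets differ: {sorted(a)} vs {sorted(b)}")
    for chrom in a:
        ta, tb = a[chrom], b[chrom]
        if ta.bin_size != tb.bin_size or ta.n_bins != tb.n_bins:
            raise GridError(
                f"grid mismatch on {chrom}: {ta.bin_size}bp x {ta.n_bins} vs {tb.bin_size}bp x {tb.n_bins}"
            )


def concat_counts(track: GenomeTrack, chrom_order: list[str] | None = None) -> np.ndarray:
    order = chrom_order or sorted(track)
    return np.concatenate([track[c].counts for c in order])


def normalized(track: GenomeTrack, scale: float = 1e6) -> GenomeTrack:
    """Library-size-normalized copy (counts per `scale` total reads)."""
    lib = library_size(track)
    if lib <= 0:
        raise ValueError("cannot normalize an empty track")
    return {
        c: BinnedTrack(t.chrom, t.bin_size, t.counts * (scale / lib), t.condition)
        for c, t in track.items()
    }
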