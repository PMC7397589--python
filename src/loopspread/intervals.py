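"""Genomic interval container and arithmetic.

All coordinates are 0-based half-open, as in BED. Intervals live in an
:class:`IntervalSet`, a thin wrapper around a pandas DataFrame sorted by
(chrom, start, end) that supports the handful of operations the pipeline
needs: overlap flags, nearest-feature distances, complements and BED I/O.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

_CORE_COLS = ["chrom", "start", "end"]


class CoordinateError(ValueError):
    """An interval falls outside its chromosome or is malformed."""


def _as_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        df = pd.DataFrame(list(records), columns=_CORE_COLS)
    for col in _CORE_COLS:
        if col not in df.columns:
            raise ValueError(f"interval frame missing column {col!r}")
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    return df


@dataclass
class IntervalSet:
    """Named, sorted set of 0-based half-open genomic intervals.

    Extra columns (name, score, factor flags, ...) are carried through all
    operations untouched.
    """

    df: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=_CORE_COLS))

    def __post_init__(self) -> None:
        df = _as_frame(self.df)
        if len(df) and (df["end"] <= df["start"]).any():
            bad = df[df["end"] <= df["start"]].iloc[0]
            raise CoordinateError(f"empty/negative interval {bad['chrom']}:{bad['start']}-{bad['end']}")
        self.df = df.sort_values(["chrom", "start", "end"], kind="stable").reset_index(drop=True)

    # -- basics ----------------------------------------------------------
    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self):
        return iter(self.df.itertuples(index=False))

    @property
    def chroms(self) -> list[str]:
        return sorted(self.df["chrom"].unique().tolist())

    def for_chrom(self, chrom: str) -> pd.DataFrame:
        return self.df[self.df["chrom"] == chrom]

    def midpoints(self) -> pd.DataFrame:
        out = self.df[_CORE_COLS].copy()
        out["mid"] = (out["start"] + out["end"]) // 2
        return out

    def validate_bounds(self, chrom_sizes: Mapping[str, int]) -> None:
        """Raise :class:`CoordinateError` if any interval leaves its chromosome."""
        for row in self.df.itertuples(index=False):
            size = chrom_sizes.get(row.chrom)
            if size is None:
                raise CoordinateError(f"unknown chromosome {row.chrom!r}")
            if row.start < 0 or row.end > size:
                raise CoordinateError(
                    f"interval {row.chrom}:{row.start}-{row.end} outside chromosome (size {size})"
                )

    # -- set operations --------------------------------------------------
    def overlaps_point_sorted(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Boolean per position: is it inside any interval on `chrom`?

        Assumes this set's intervals are non-overlapping (domains are).
        """
        sub = self.for_chrom(chrom)
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        if len(starts) == 0:
            return np.zeros(len(positions), dtype=bool)
        idx = np.searchsorted(starts, positions, side="right") - 1
        ok = idx >= 0
        inside = np.zeros(len(positions), dtype=bool)
        inside[ok] = positions[ok] < ends[idx[ok]]
        return inside

    def overlap_flags(self, other: "IntervalSet") -> np.ndarray:
        """Per interval of self: does it overlap any interval of `other`?"""
        flags = np.zeros(len(self), dtype=bool)
        for chrom in self.chroms:
            mask = (self.df["chrom"] == chrom).to_numpy()
            sub = self.df[mask]
            osub = other.for_chrom(chrom)
            if len(osub) == 0:
                continue
            ostarts = osub["start"].to_numpy()
            oends = osub["end"].to_numpy()
            order = np.argsort(ostarts, kind="stable")
            ostarts, oends = ostarts[order], oends[order]
            cummax_end = np.maximum.accumulate(oends)
            s = sub["start"].to_numpy()
            e = sub["end"].to_numpy()
            # candidate: last interval starting before e
            j = np.searchsorted(ostarts, e, side="left") - 1
            hit = (j >= 0) & (np.where(j >= 0, cummax_end[np.clip(j, 0, None)], 0) > s)
            flags[np.flatnonzero(mask)] = hit
        return flags

    def nearest_distance(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Distance from each position to the nearest interval (0 if inside).

        Returns +inf where the chromosome has no intervals.
        """
        sub = self.for_chrom(chrom)
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        if len(starts) == 0:
            return np.full(len(positions), np.inf)
        order = np.argsort(starts, kind="stable")
        starts, ends = starts[order], ends[order]
        # distance to following interval start
        i = np.searchsorted(starts, positions, side="left")
        d_next = np.where(i < len(starts), starts[np.clip(i, 0, len(starts) - 1)] - positions, np.inf)
        # distance past any preceding interval end (ends may not be sorted if
        # intervals nest; use running max of ends)
        cummax_end = np.maximum.accumulate(ends)
        j = np.searchsorted(starts, positions, side="right") - 1
        prev_end = np.where(j >= 0, cummax_end[np.clip(j, 0, None)], -np.inf)
        d_prev = positions - prev_end + 1  # position >= end means outside by (pos-end+1)... see below
        # inside test: position < running-max end of intervals starting at/before it
        inside = (j >= 0) & (positions < prev_end)
        d_prev = np.where(j >= 0, np.maximum(positions - prev_end + 1, 0), np.inf)
        dist = np.minimum(np.maximum(d_next, 0), d_prev)
        dist[inside] = 0
        return dist.astype(float)

    def complement(self, chrom_sizes: Mapping[str, int]) -> "IntervalSet":
        """Gaps not covered by this set, per chromosome (assumes sorted)."""
        rows = []
        for chrom, size in chrom_sizes.items():
            cursor = 0
            for row in self.for_chrom(chrom).itertuples(index=False):
                if row.start > cursor:
                    rows.append((chrom, cursor, row.start))
                cursor = max(cursor, row.end)
            if cursor < size:
                rows.append((chrom, cursor, size))
        return IntervalSet(pd.DataFrame(rows, columns=_CORE_COLS))

    # -- I/O --------------------------------------------------------------
    def to_bed(self, path: str | Path, extra_cols: Iterable[str] = ()) -> None:
        cols = _CORE_COLS + [c for c in extra_cols if c in self.df.columns]
        self.df[cols].to_csv(path, sep="\t", header=False, index=False)

    @classmethod
    def from_bed(cls, path: str | Path, extra_names: Iterable[str] = ()) -> "IntervalSet":
        path = Path(path)
        if path.stat().st_size == 0:
            return cls()
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
        names = _CORE_COLS + list(extra_names)
        df.columns = names[: df.shape[1]] + [f"col{i}" for i in range(len(names), df.shape[1])]
        return cls(df)


def concat(sets: Iterable[IntervalSet]) -> IntervalSet:
    frames = [s.df for s in sets if len(s)]
    if not frames:
        return IntervalSet()
    return IntervalSet(pd.concat(frames, ignore_index=True))
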