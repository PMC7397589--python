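"""Plain-text genomics I/O: bedGraph, chrom.sizes, Hi-C triplet TSV, TSV tables.

Everything is text so datasets round-trip exactly and diffs stay readable.
Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .tracks import BinnedTrack, GenomeTrack


# -- chrom.sizes ----------------------------------------------------------

def write_chrom_sizes(sizes: Mapping[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, size in sizes.items():
            fh.write(f"{chrom}\t{size}\n")


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    out: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if line.strip():
                chrom, size = line.split()[:2]
                out[chrom] = int(size)
    return out


# -- bedGraph -------------------------------------------------------------

def write_bedgraph(track: GenomeTrack, path: str | Path) -> None:
    """One record per bin (no run-length merging, so the grid round-trips)."""
    with open(path, "w") as fh:
        for chrom in sorted(track):
            t = track[chrom]
            for i, v in enumerate(t.counts):
                val = int(v) if float(v).is_integer() else v
                fh.write(f"{chrom}\t{i * t.bin_size}\t{(i + 1) * t.bin_size}\t{val}\n")


def read_bedgraph(path: str | Path, bin_size: int, chrom_sizes: Mapping[str, int],
                  condition: str = "") -> GenomeTrack:
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "value"],
                     dtype={"chrom": str})
    out: GenomeTrack = {}
    for chrom, size in chrom_sizes.items():
        n_bins = -(-size // bin_size)
        counts = np.zeros(n_bins, dtype=np.float64)
        sub = df[df["chrom"] == chrom]
        if len(sub):
            idx = sub["start"].to_numpy() // bin_size
            if (sub["start"].to_numpy() % bin_size).any():
                raise ValueError(f"bedGraph {path} not aligned to {bin_size} bp grid on {chrom}")
            counts[idx] = sub["value"].to_numpy()
        out[chrom] = BinnedTrack(chrom, bin_size, counts, condition)
    return out


# -- Hi-C triplet TSV -----------------------------------------------------

def write_triplets(matrix: np.ndarray, path: str | Path) -> None:
    """Upper-triangle (bin_i <= bin_j) sparse triplets of a symmetric matrix."""
    iu, ju = np.triu_indices_from(matrix)
    vals = matrix[iu, ju]
    keep = vals != 0
    df = pd.DataFrame({"bin_i": iu[keep], "bin_j": ju[keep], "count": vals[keep]})
    if np.all(vals == np.round(vals)):
        df["count"] = df["count"].astype(np.int64)
    df.to_csv(path, sep="\t", index=False)


def read_triplets(path: str | Path, n_bins: int) -> np.ndarray:
    df = pd.read_csv(path, sep="\t")
    i = df["bin_i"].to_numpy(dtype=np.int64)
    j = df["bin_j"].to_numpy(dtype=np.int64)
    if len(i) and (i.max() >= n_bins or j.max() >= n_bins or i.min() < 0 or j.min() < 0):
        raise ValueError(f"triplet index out of range in {path} (n_bins={n_bins})")
    mat = np.zeros((n_bins, n_bins), dtype=np.float64)
    mat[i, j] = df["count"].to_numpy()
    mat[j, i] = mat[i, j]
    return mat


# -- tables ---------------------------------------------------------------

def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
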