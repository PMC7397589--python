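"""Hi-C matrix engineering and long-range interaction (LRI) scores.

Per chromosome: Knight-Ruiz-style symmetric balancing, distance-expected
normalization (O/E), A/B compartment eigenvector, aggregate peak analysis
over anchor pairs, and the three LRI zone scores —

* LRI-1: compartment-level contact, the mean O/E of the outer flank block
  (upstream of anchor A x downstream of anchor B, beyond the window core);
* LRI-2: TAD-level contact density, the mean O/E of the block strictly
  between the two anchors;
* LRI-3: focal loop strength, the APA-style log2 ratio of the center block
  to the four corner background blocks of the window submatrix.

ΔLRI between two conditions is computed on O/E matrices so sequencing-depth
differences cancel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .intervals import IntervalSet


class BalancingError(RuntimeError):
    def __init__(self, message: str, trace: list[float] | None = None):
        super().__init__(message)
        self.trace = trace or []


@dataclass
class ContactMatrix:
    chrom: str
    bin_size: int
    counts: np.ndarray
    condition: str = ""

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.float64)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("contact matrix must be square")
        if not np.array_equal(self.counts, self.counts.T):
            raise ValueError("contact matrix must be symmetric")
        if (self.counts < 0).any():
            raise ValueError("contact matrix must be non-negative")

    @property
    def n_bins(self) -> int:
        return self.counts.shape[0]


# ---------------------------------------------------------------------------
# balancing
# ---------------------------------------------------------------------------

def coverage_mask(matrix: np.ndarray, percentile: float = 1.0) -> np.ndarray:
    """True = masked.  Masks zero-coverage rows and the bottom `percentile`."""
    cov = matrix.sum(axis=1)
    masked = cov <= 0
    if percentile > 0 and (~masked).any():
        thr = np.percentile(cov[~masked], percentile)
        masked |= cov < thr
    return masked


def kr_balance(
    matrix: np.ndarray,
    tol: float = 1e-10,
    max_iter: int = 3000,
    mask: np.ndarray | None = None,
    mask_percentile: float = 1.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Symmetric matrix balancing to unit row sums (Knight-Ruiz normalization).

    Finds per-bin weights x with diag(x)·A·diag(x) having all unmasked row
    sums equal to 1, by the damped fixed-point iteration x ← x/√(x∘Ax).
    Returns (weights, balanced, mask); masked bins get NaN weight and NaN
    rows/columns in the balanced matrix.  Scale-invariant: A and c·A balance
    to the same matrix.
    """
    a = np.asarray(matrix, dtype=np.float64)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("matrix must be square")
    if not np.allclose(a, a.T):
        raise ValueError("matrix must be symmetric")
    n = a.shape[0]
    masked = coverage_mask(a, mask_percentile) if mask is None else np.asarray(mask, bool).copy()
    free = ~masked
    sub = a[np.ix_(free, free)]
    m = sub.shape[0]
    if m == 0:
        raise BalancingError("all bins masked")

    x = np.full(m, 1.0 / np.sqrt(max(sub.sum() / m, 1e-300)))
    trace: list[float] = []
    err = np.inf
    for _ in range(max_iter):
        r = x * (sub @ x)
        err = float(np.abs(r - 1.0).max())
        trace.append(err)
        if err < tol:
            break
        x = x / np.sqrt(np.maximum(r, 1e-300))
    if err >= tol:
        raise BalancingError(
            f"balancing did not reach tol={tol} in {max_iter} iterations (err={err:.3g})",
            trace,
        )

    weights = np.full(n, np.nan)
    weights[free] = x
    balanced = np.full_like(a, np.nan)
    balanced[np.ix_(free, free)] = sub * np.outer(x, x)
    return weights, balanced, masked


# ---------------------------------------------------------------------------
# expected by distance and O/E
# ---------------------------------------------------------------------------

def expected_by_distance(balanced: np.ndarray, mask: np.ndarray | None = None
                         ) -> tuple[np.ndarray, list[int]]:
    """Per-diagonal mean of unmasked entries; empty/zero diagonals pooled.

    Returns (expected vector indexed by separation, list of pooled
    separations).  Pooling interpolates log(expected) over log(1+d) from the
    informative diagonals.
    """
    n = balanced.shape[0]
    masked = np.zeros(n, bool) if mask is None else np.asarray(mask, bool)
    good_bin = ~masked
    exp = np.full(n, np.nan)
    for d in range(n):
        vals = np.diagonal(balanced, d)
        ok = good_bin[: n - d] & good_bin[d:] & np.isfinite(vals)
        if ok.any():
            exp[d] = vals[ok].mean()
    pooled = [d for d in range(n) if not np.isfinite(exp[d]) or exp[d] <= 0]
    informative = [d for d in range(n) if np.isfinite(exp[d]) and exp[d] > 0]
    if not informative:
        raise ValueError("no informative diagonal")
    if pooled:
        logx = np.log1p(np.array(informative, float))
        logy = np.log(exp[informative])
        exp[pooled] = np.exp(np.interp(np.log1p(np.array(pooled, float)), logx, logy))
    return exp, pooled


def oe_normalize(balanced: np.ndarray, mask: np.ndarray | None = None
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Observed-over-expected matrix; masked bins propagate as NaN."""
    n = balanced.shape[0]
    exp, _ = expected_by_distance(balanced, mask)
    d = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
    oe = balanced / exp[d]
    if mask is not None:
        oe[np.asarray(mask, bool), :] = np.nan
        oe[:, np.asarray(mask, bool)] = np.nan
    return oe, exp


def balance_and_oe(matrix: np.ndarray, tol: float = 1e-10,
                   mask_percentile: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """Counts → (O/E matrix, mask): balance then distance-normalize."""
    _, balanced, masked = kr_balance(matrix, tol=tol, mask_percentile=mask_percentile)
    oe, _ = oe_normalize(balanced, masked)
    return oe, masked


# ---------------------------------------------------------------------------
# compartments
# ---------------------------------------------------------------------------

def compartment_eigenvector(
    oe: np.ndarray,
    orientation_track: np.ndarray,
    mask: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Leading eigenvector of the O/E Pearson correlation matrix.

    The sign is oriented so that bins with higher orientation-track signal
    (an active-chromatin proxy) are positive; labels are +1 (A) / -1 (B) / 0
    for masked bins.  Raises on degenerate (constant-row) input.
    """
    n = oe.shape[0]
    masked = np.zeros(n, bool) if mask is None else np.asarray(mask, bool)
    free = np.flatnonzero(~masked)
    sub = oe[np.ix_(free, free)]
    if np.any(np.nanstd(sub, axis=1) == 0):
        raise ValueError("degenerate O/E: constant rows")
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(np.nan_to_num(sub, nan=1.0))
    evals, evecs = np.linalg.eigh(corr)
    vec = evecs[:, -1]
    track = np.asarray(orientation_track, float)[free]
    pos_mean = track[vec > 0].mean() if (vec > 0).any() else -np.inf
    neg_mean = track[vec < 0].mean() if (vec < 0).any() else -np.inf
    if neg_mean > pos_mean:
        vec = -vec
    full = np.full(n, np.nan)
    full[free] = vec
    labels = np.zeros(n, dtype=np.int8)
    labels[free] = np.where(vec > 0, 1, -1)
    return full, labels


def eigen_of_intervals(
    eigenvector: np.ndarray,
    bin_size: int,
    intervals: IntervalSet,
    chrom: str,
) -> np.ndarray:
    """Per-interval mean eigenvector value (NaN for fully masked intervals)."""
    out = np.full(len(intervals.for_chrom(chrom)), np.nan)
    for k, row in enumerate(intervals.for_chrom(chrom).itertuples(index=False)):
        b0 = row.start // bin_size
        b1 = max(b0 + 1, -(-row.end // bin_size))
        vals = eigenvector[b0:b1]
        if np.isfinite(vals).any():
            out[k] = float(np.nanmean(vals))
    return out


# ---------------------------------------------------------------------------
# aggregation (APA) and LRI scores
# ---------------------------------------------------------------------------

@dataclass
class ZoneGeometry:
    """Block layout of the LRI scores, echoed into every output."""

    window_bins: int = 10     # APA half-width w; submatrix (2w+1)^2
    center_bins: int = 3      # center / corner block edge c
    flank_bins: int = 10      # LRI-1 flank block edge

    def as_dict(self) -> dict:
        return {"window_bins": self.window_bins, "center_bins": self.center_bins,
                "flank_bins": self.flank_bins}


@dataclass
class AggregateMatrix:
    matrix: np.ndarray
    n_pairs: int
    window_bins: int
    pairs: list[tuple[int, int]]


def anchors_to_bins(catalog: IntervalSet, chrom: str, bin_size: int) -> np.ndarray:
    """Anchor midpoints mapped to Hi-C bins (site midpoint decides the bin)."""
    sub = catalog.for_chrom(chrom)
    mids = (sub["start"].to_numpy() + sub["end"].to_numpy()) // 2
    return np.unique(mids // bin_size)


def admissible_pairs(
    anchors_a: np.ndarray,
    anchors_b: np.ndarray,
    n_bins: int,
    window_bins: int,
    min_sep_bins: int,
    max_sep_bins: int | None = None,
) -> list[tuple[int, int]]:
    """Ordered (left, right) anchor-bin pairs within the separation band."""
    max_sep_bins = max_sep_bins if max_sep_bins is not None else n_bins
    pairs = set()
    for a in np.asarray(anchors_a, int):
        for b in np.asarray(anchors_b, int):
            lo, hi = (a, b) if a < b else (b, a)
            sep = hi - lo
            if sep <= min_sep_bins or sep > max_sep_bins:
                continue
            if lo - window_bins < 0 or hi + window_bins >= n_bins:
                continue
            pairs.add((lo, hi))
    return sorted(pairs)


def aggregate_pairs(
    oe: np.ndarray,
    anchors_a: np.ndarray,
    anchors_b: np.ndarray,
    window_bins: int = 10,
    min_sep_bins: int = 3,
    max_sep_bins: int | None = None,
) -> AggregateMatrix:
    """Element-wise mean of O/E submatrices centered on all admissible pairs.

    Pairs whose window contains a masked (NaN) pixel are excluded.
    """
    w = window_bins
    pairs = admissible_pairs(anchors_a, anchors_b, oe.shape[0], w, min_sep_bins, max_sep_bins)
    used, acc = [], np.zeros((2 * w + 1, 2 * w + 1))
    for a, b in pairs:
        sub = oe[a - w: a + w + 1, b - w: b + w + 1]
        if np.isnan(sub).any():
            continue
        acc += sub
        used.append((a, b))
    if not used:
        raise ValueError(
            f"no admissible pairs (|A|={len(anchors_a)}, |B|={len(anchors_b)}, "
            f"window={w}, min_sep={min_sep_bins}, max_sep={max_sep_bins})"
        )
    return AggregateMatrix(acc / len(used), len(used), w, used)


def score_apa(submatrix: np.ndarray, center_bins: int = 3) -> float:
    """APA loop score: log2(center block mean / four-corner background mean)."""
    c = center_bins
    m = submatrix.shape[0]
    mid = m // 2
    lo, hi = mid - c // 2, mid + c // 2 + 1
    center = submatrix[lo:hi, lo:hi]
    corners = np.concatenate([
        submatrix[:c, :c].ravel(), submatrix[:c, -c:].ravel(),
        submatrix[-c:, :c].ravel(), submatrix[-c:, -c:].ravel(),
    ])
    bg = np.nanmean(corners)
    ctr = np.nanmean(center)
    if not np.isfinite(bg) or bg <= 0 or not np.isfinite(ctr) or ctr <= 0:
        return np.nan
    return float(np.log2(ctr / bg))


def score_lri_pair(
    oe: np.ndarray,
    a: int,
    b: int,
    geometry: ZoneGeometry = ZoneGeometry(),
) -> tuple[float, float, float]:
    """(lri1, lri2, lri3) for one anchor pair (bins a < b) on an O/E matrix.

    lri3 uses the local corner background (APA); lri1 and lri2 are global
    O/E block means (log2 against the distance expectation of 1).
    """
    if a >= b:
        raise ValueError("anchor bins must satisfy a < b")
    n = oe.shape[0]
    w, f = geometry.window_bins, geometry.flank_bins

    lri3 = np.nan
    if a - w >= 0 and b + w < n:
        sub = oe[a - w: a + w + 1, b - w: b + w + 1]
        lri3 = score_apa(sub, geometry.center_bins)

    # margin keeps the anchors' own focal enrichment out of the domain score,
    # mirroring the center/background separation of the APA zones
    m = geometry.center_bins // 2 + 1
    lri2 = np.nan
    if b - a >= 2 * m + 2:
        block = oe[a + m: b - m + 1, a + m: b - m + 1]
        iu = np.triu_indices_from(block, k=1)
        vals = block[iu]
        vals = vals[np.isfinite(vals) & (vals > 0)]
        if len(vals):
            lri2 = float(np.log2(vals.mean()))

    lri1 = np.nan
    r0, r1 = a - w - f, a - w
    c0, c1 = b + w + 1, b + w + 1 + f
    if r0 >= 0 and c1 <= n:
        block = oe[r0:r1, c0:c1]
        vals = block[np.isfinite(block) & (block > 0)]
        if len(vals):
            lri1 = float(np.log2(vals.mean()))
    return lri1, lri2, lri3


def score_lri_records(
    oe: np.ndarray,
    pairs: list[tuple[int, int]],
    bin_size: int,
    chrom: str = "",
    condition: str = "",
    geometry: ZoneGeometry = ZoneGeometry(),
) -> pd.DataFrame:
    """Score a list of anchor-bin pairs; one row per pair with the geometry echoed."""
    rows = []
    for a, b in pairs:
        l1, l2, l3 = score_lri_pair(oe, a, b, geometry)
        rows.append((f"{chrom}:{a}-{b}", chrom, a, b, (b - a) * bin_size, l1, l2, l3))
    df = pd.DataFrame(rows, columns=["pair_id", "chrom", "bin_a", "bin_b",
                                     "separation", "lri1", "lri2", "lri3"])
    df.attrs["geometry"] = geometry.as_dict()
    df.attrs["condition"] = condition
    return df


def delta_lri(records_wt: pd.DataFrame, records_kd: pd.DataFrame) -> pd.DataFrame:
    """Per-pair ΔLRI = score(KD) − score(WT); pairs NA in either side dropped.

    Raises when the two score tables do not cover the same pair universe.
    """
    if set(records_wt["pair_id"]) != set(records_kd["pair_id"]):
        missing = set(records_wt["pair_id"]) ^ set(records_kd["pair_id"])
        raise ValueError(f"pair universes differ; offenders: {sorted(missing)[:5]} ...")
    merged = records_wt.merge(records_kd, on=["pair_id", "chrom", "bin_a", "bin_b", "separation"],
                              suffixes=("_wt", "_kd"))
    for z in (1, 2, 3):
        merged[f"delta_lri{z}"] = merged[f"lri{z}_kd"] - merged[f"lri{z}_wt"]
    n_before = len(merged)
    merged = merged.dropna(subset=[f"delta_lri{z}" for z in (1, 2, 3)], how="all")
    merged.attrs["n_dropped"] = n_before - len(merged)
    return merged.reset_index(drop=True)


# ---------------------------------------------------------------------------
# TAD strength
# ---------------------------------------------------------------------------

def tad_strength(oe: np.ndarray, tad_bins: list[tuple[int, int]]) -> np.ndarray:
    """Per-TAD LRI-2 score: within-TAD vs border-straddling O/E at matched distances.

    score = log2( Σ_d n_d·within(d) / Σ_d n_d·straddle(d) ), where d runs over
    the within-TAD separations, within(d) is the mean O/E of intra-TAD pairs
    at separation d and straddle(d) the mean over pairs crossing either TAD
    border at the same separation.  NaN for fully masked TADs.
    """
    n = oe.shape[0]
    out = np.full(len(tad_bins), np.nan)
    for k, (s, e) in enumerate(tad_bins):
        if e - s < 2:
            continue
        num = den = wsum = 0.0
        for d in range(1, e - s):
            i = np.arange(s, e - d)
            within = oe[i, i + d]
            within = within[np.isfinite(within)]
            if len(within) == 0:
                continue
            cross_vals = []
            for border in (s, e):
                i2 = np.arange(max(0, border - d), border)
                j2 = i2 + d
                keep = (j2 < n) & (j2 >= border)
                if border == s:
                    keep &= i2 < s
                else:
                    keep &= (i2 >= s) & (i2 < e) & (j2 >= e)
                v = oe[i2[keep], j2[keep]]
                cross_vals.append(v[np.isfinite(v)])
            cross = np.concatenate(cross_vals) if cross_vals else np.array([])
            if len(cross) == 0:
                continue
            w_d = len(within)
            num += w_d * within.mean()
            den += w_d * cross.mean()
            wsum += w_d
        if wsum > 0 and den > 0 and num > 0:
            out[k] = float(np.log2(num / den))
    return out


def tads_to_bins(tads: IntervalSet, chrom: str, bin_size: int) -> list[tuple[int, int]]:
    return [(row.start // bin_size, row.end // bin_size)
            for row in tads.for_chrom(chrom).itertuples(index=False)]


# ---------------------------------------------------------------------------
# per-factor summary (TAD strength vs loop strength scatter)
# ---------------------------------------------------------------------------

def factor_lri_scatter(
    oe: np.ndarray,
    tad_bins: list[tuple[int, int]],
    factor_bins: dict[str, np.ndarray],
    bin_size: int,
    geometry: ZoneGeometry = ZoneGeometry(),
    min_sep_bins: int = 3,
    max_sep_bins: int | None = None,
    top_quantile: float = 0.05,
    seed: int = 0,
) -> dict:
    """Per-factor (mean LRI-2 of bordered TADs, mean LRI-3 between its sites).

    Each `factor_bins` value is one of: a flat array of anchor bins (all
    within-set pairs are scored), a 2-tuple of arrays (cross pairs of a
    factor combination, e.g. Beaf32 x GAF+CP190), or an (n, 2) array of
    explicit anchor pairs.  Thresholds are the empirical (1 − top_quantile)
    quantiles of the pooled per-TAD LRI-2 scores and of LRI-3 over random
    bin pairs matched in separation; a random control factor matched in site
    count is included.
    """
    rng = np.random.default_rng(seed)
    n = oe.shape[0]
    all_tad_scores = tad_strength(oe, tad_bins)

    def _pairs_of(spec_val):
        if isinstance(spec_val, tuple) and len(spec_val) == 2:
            a, b = (np.asarray(v, int) for v in spec_val)
            return np.concatenate([a, b]), admissible_pairs(
                a, b, n, geometry.window_bins, min_sep_bins, max_sep_bins)
        arr = np.asarray(spec_val, int)
        if arr.ndim == 2 and arr.shape[1] == 2:
            keep = [(min(x, y), max(x, y)) for x, y in arr
                    if abs(y - x) > min_sep_bins
                    and min(x, y) - geometry.window_bins >= 0
                    and max(x, y) + geometry.window_bins < n]
            return np.unique(arr.ravel()), sorted(set(keep))
        return arr, admissible_pairs(arr, arr, n, geometry.window_bins,
                                     min_sep_bins, max_sep_bins)

    def _factor_point(spec_val) -> tuple[float, float, int]:
        bins, pairs = _pairs_of(spec_val)
        bins = np.asarray(bins, dtype=float)
        bordered = [k for k, (s, e) in enumerate(tad_bins)
                    if len(bins) and (np.abs(bins - s).min() <= 1
                                      or np.abs(bins - e).min() <= 1)]
        lri2 = float(np.nanmean(all_tad_scores[bordered])) if bordered else np.nan
        if pairs:
            rec = [score_lri_pair(oe, a, b, geometry)[2] for a, b in pairs]
            lri3 = float(np.nanmean(rec))
        else:
            lri3 = np.nan
        return lri2, lri3, len(pairs)

    rows = {}
    for name, spec_val in factor_bins.items():
        lri2, lri3, n_pairs = _factor_point(spec_val)
        if np.isnan(lri2) and np.isnan(lri3):
            continue
        rows[name] = {"mean_lri2": lri2, "mean_lri3": lri3, "n_pairs": n_pairs}

    n_sites = max((len(_pairs_of(v)[0]) for v in factor_bins.values()), default=10)
    ctrl_bins = rng.choice(np.arange(geometry.window_bins, n - geometry.window_bins),
                           size=min(n_sites, n // 4), replace=False)
    lri2c, lri3c, n_pairs_c = _factor_point(np.sort(ctrl_bins))
    rows["random_control"] = {"mean_lri2": lri2c, "mean_lri3": lri3c, "n_pairs": n_pairs_c}

    rand_pairs = []
    for _ in range(2000):
        a = int(rng.integers(geometry.window_bins, n - geometry.window_bins))
        b = int(rng.integers(geometry.window_bins, n - geometry.window_bins))
        lo, hi = min(a, b), max(a, b)
        if min_sep_bins < hi - lo <= (max_sep_bins or n):
            rand_pairs.append((lo, hi))
    rand_lri3 = np.array([score_lri_pair(oe, a, b, geometry)[2] for a, b in rand_pairs[:500]])
    thresholds = {
        "lri2": float(np.nanquantile(all_tad_scores, 1 - top_quantile)),
        "lri3": float(np.nanquantile(rand_lri3, 1 - top_quantile)),
    }
    return {"factors": rows, "thresholds": thresholds, "geometry": geometry.as_dict()}
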