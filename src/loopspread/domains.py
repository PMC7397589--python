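"""Heterochromatin and euchromatic H3K27me3 micro-domain calling.

The chain: a 2-state Gaussian HMM on the smoothed ChIP/input log-ratio calls
large heterochromatin domains; a two-regime binomial mixture fitted by EM on
40-bp bins (treatment count conditional on treatment+control) yields per-bin
enrichment p-values; BH correction and a differential run against the
depleted condition flag bins that are enriched over input AND lose signal in
KD; maximal runs of qualifying bins outside heterochromatin, shorter than
2 kb, become micro-domains whose sizes cluster in ~200-bp nucleosome "mers".
A label-swap (half-genome exchange) control estimates the empirical FDR.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .intervals import IntervalSet
from .stats import bh_fdr
from .tracks import BinnedTrack, GenomeTrack, check_same_grid, library_size
from .synthetic import MER_BP


class DegenerateInputError(ValueError):
    pass


class InsufficientDataError(ValueError):
    pass


# ---------------------------------------------------------------------------
# heterochromatin HMM
# ---------------------------------------------------------------------------

def _log_ratio(chip: GenomeTrack, input_: GenomeTrack, pseudocount: float = 1.0) -> dict[str, np.ndarray]:
    check_same_grid(chip, input_)
    lib_c, lib_i = library_size(chip), library_size(input_)
    if lib_c <= 0 or lib_i <= 0:
        raise DegenerateInputError("all-zero track")
    sf = lib_c / lib_i  # scale input to the treatment library
    return {
        c: np.log2((chip[c].counts + pseudocount) / (input_[c].counts * sf + pseudocount))
        for c in chip
    }


def _smooth(x: np.ndarray, w: int) -> np.ndarray:
    if w <= 1:
        return x
    pad = w // 2
    xp = np.pad(x, pad, mode="edge")
    return np.convolve(xp, np.ones(w) / w, mode="valid")[: len(x)]


def call_heterochromatin_hmm(
    h3k27me3: GenomeTrack,
    input_: GenomeTrack,
    n_states: int = 2,
    min_size_bp: int = 5000,
    smooth_bins: int = 3,
    min_state_separation: float = 0.5,
    max_iter: int = 100,
) -> IntervalSet:
    """Segment the genome into heterochromatin domains with a Gaussian HMM.

    Emissions are the 3-bin-smoothed log2 ChIP/input ratio; the state with
    the higher emission mean is heterochromatin.  If the two state means are
    separated by less than `min_state_separation` log2 units the track is
    considered domain-free.  Domains shorter than `min_size_bp` are dropped.
    Returned domains carry a `mean_enrichment` column (mean log-ratio).
    """
    from hmmlearn import hmm as _hmm

    ratios = _log_ratio(h3k27me3, input_)
    chroms = sorted(ratios)
    series = [_smooth(ratios[c], smooth_bins) for c in chroms]
    X = np.concatenate(series)[:, None]
    lengths = [len(s) for s in series]
    if np.ptp(X) == 0:
        return IntervalSet()

    model = _hmm.GaussianHMM(
        n_components=n_states, covariance_type="diag",
        n_iter=max_iter, random_state=0, min_covar=1e-3,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(X, lengths)
    if not model.monitor_.converged:
        warnings.warn("heterochromatin HMM did not converge; using best fit", RuntimeWarning)
    means = model.means_.ravel()
    het_state = int(np.argmax(means))
    if np.ptp(means) < min_state_separation:
        return IntervalSet()

    rows = []
    for chrom, x in zip(chroms, series):
        states = model.predict(x[:, None])
        bin_size = h3k27me3[chrom].bin_size
        het = states == het_state
        # runs of het bins
        edges = np.flatnonzero(np.diff(np.concatenate([[0], het.astype(int), [0]])))
        for s, e in zip(edges[::2], edges[1::2]):
            if (e - s) * bin_size >= min_size_bp:
                rows.append((chrom, s * bin_size, e * bin_size, float(ratios[chrom][s:e].mean())))
    if not rows:
        return IntervalSet()
    return IntervalSet(pd.DataFrame(rows, columns=["chrom", "start", "end", "mean_enrichment"]))


def annotate_borders(het_domains: IntervalSet, beaf_catalog: IntervalSet,
                     window_bp: int = 500) -> IntervalSet:
    """Add beaf_left/beaf_right presence flags and arrangement_class.

    A border carries Beaf32 if any catalog site midpoint is within
    `window_bp` of the domain edge.
    """
    if len(het_domains) == 0:
        return het_domains
    df = het_domains.df.copy()
    left_flags, right_flags, classes = [], [], []
    for row in df.itertuples(index=False):
        sub = beaf_catalog.for_chrom(row.chrom)
        mids = ((sub["start"] + sub["end"]) // 2).to_numpy() if len(sub) else np.array([])
        left = bool(len(mids)) and bool((np.abs(mids - row.start) <= window_bp).any())
        right = bool(len(mids)) and bool((np.abs(mids - row.end) <= window_bp).any())
        left_flags.append(left)
        right_flags.append(right)
        classes.append({(False, False): "none", (True, False): "left-only",
                        (False, True): "right-only", (True, True): "both"}[(left, right)])
    df["beaf_left"] = left_flags
    df["beaf_right"] = right_flags
    df["arrangement_class"] = classes
    return IntervalSet(df)


# ---------------------------------------------------------------------------
# binomial mixture (two-regime enrichment model)
# ---------------------------------------------------------------------------

@dataclass
class MixtureFit:
    theta_bg: float
    theta_enr: float
    weights: tuple[float, float]          # (background, enriched), sum to 1
    loglik_trace: list[float]
    converged: bool
    degenerate: bool = False


def _binom_logpmf(t, n, theta):
    theta = np.clip(theta, 1e-12, 1 - 1e-12)
    return (gammaln(n + 1) - gammaln(t + 1) - gammaln(n - t + 1)
            + t * np.log(theta) + (n - t) * np.log1p(-theta))


def fit_binomial_mixture(
    treatment: GenomeTrack,
    control: GenomeTrack,
    max_iter: int = 500,
    tol: float = 1e-8,
) -> MixtureFit:
    """EM fit of t_i | n_i ~ w Binom(n_i, θ_bg) + (1-w) Binom(n_i, θ_enr).

    Conditional on the per-bin total n_i = t_i + c_i, the treatment count is
    a two-component binomial mixture; the background proportion θ_bg absorbs
    the library-size ratio so no explicit depth normalization is needed.
    Bins with n_i = 0 are excluded.  Components are returned ordered
    θ_bg < θ_enr; the fit is flagged degenerate when they coincide.
    """
    check_same_grid(treatment, control)
    chroms = sorted(treatment)
    t = np.concatenate([treatment[c].counts for c in chroms])
    c = np.concatenate([control[c].counts for c in chroms])
    n = t + c
    keep = n > 0
    t, n = t[keep], n[keep]
    if keep.sum() < 100:
        raise InsufficientDataError(f"only {int(keep.sum())} informative bins (< 100)")

    frac = t / n
    theta = np.array([np.quantile(frac, 0.25), np.quantile(frac, 0.95)])
    if theta[1] <= theta[0]:
        theta[1] = min(theta[0] + 0.05, 0.999)
    w = np.array([0.9, 0.1])

    trace: list[float] = []
    converged = False
    for _ in range(max_iter):
        log_comp = np.stack([np.log(w[k]) + _binom_logpmf(t, n, theta[k]) for k in range(2)])
        m = log_comp.max(axis=0)
        log_mix = m + np.log(np.exp(log_comp - m).sum(axis=0))
        ll = float(log_mix.sum())
        resp = np.exp(log_comp - log_mix)        # responsibilities, 2 x bins
        w = resp.sum(axis=1) / len(t)
        theta = (resp * t).sum(axis=1) / np.maximum((resp * n).sum(axis=1), 1e-300)
        if trace and abs(ll - trace[-1]) <= tol * (abs(trace[-1]) + 1e-12):
            trace.append(ll)
            converged = True
            break
        trace.append(ll)

    order = np.argsort(theta)
    theta, w = theta[order], w[order]
    degenerate = abs(theta[1] - theta[0]) < 1e-4
    return MixtureFit(float(theta[0]), float(theta[1]), (float(w[0]), float(w[1])),
                      trace, converged, degenerate)


# ---------------------------------------------------------------------------
# per-bin calling
# ---------------------------------------------------------------------------

@dataclass
class BinCalls:
    """Per-bin q-values and flags, aligned to the shared bin grid."""

    chroms: list[str]
    bin_size: int
    p: dict[str, np.ndarray]
    q: dict[str, np.ndarray]
    enriched: dict[str, np.ndarray]
    fit: MixtureFit
    fdr: float


def call_enriched_bins(
    treatment: GenomeTrack,
    control: GenomeTrack,
    fdr: float = 0.05,
    fit: MixtureFit | None = None,
) -> BinCalls:
    """Flag bins where treatment exceeds the background regime.

    Per-bin p = upper-tail Binomial(n_i, θ_bg) probability of >= t_i;
    BH-corrected over informative bins; enriched ⇔ q < fdr and t_i/n_i > θ_bg.
    """
    from scipy.stats import binom

    fit = fit or fit_binomial_mixture(treatment, control)
    chroms = sorted(treatment)
    p_out, q_out, enr_out = {}, {}, {}
    t_all = np.concatenate([treatment[c].counts for c in chroms])
    c_all = np.concatenate([control[c].counts for c in chroms])
    n_all = t_all + c_all
    keep = n_all > 0
    p_keep = binom.sf(t_all[keep] - 1, n_all[keep], fit.theta_bg)
    p = np.ones_like(t_all, dtype=float)
    p[keep] = p_keep
    q = np.ones_like(t_all, dtype=float)
    q[keep] = bh_fdr(p_keep)
    above = np.zeros_like(keep)
    above[keep] = t_all[keep] / n_all[keep] > fit.theta_bg
    enriched = (q < fdr) & above

    offset = 0
    for c in chroms:
        nb = treatment[c].n_bins
        p_out[c] = p[offset: offset + nb]
        q_out[c] = q[offset: offset + nb]
        enr_out[c] = enriched[offset: offset + nb]
        offset += nb
    return BinCalls(chroms, treatment[chroms[0]].bin_size, p_out, q_out, enr_out, fit, fdr)


@dataclass
class DifferentialCalls:
    """Per-bin decrease/increase-in-KD labels from label-swapped mixture runs."""

    chroms: list[str]
    bin_size: int
    decrease: dict[str, np.ndarray]
    increase: dict[str, np.ndarray]
    q_decrease: dict[str, np.ndarray]
    q_increase: dict[str, np.ndarray]
    n_ties: int
    fdr: float


def call_differential_bins(wt: GenomeTrack, kd: GenomeTrack, fdr: float = 0.05) -> DifferentialCalls:
    """Label bins {decrease, increase, none} between WT and depleted tracks.

    Treatment=WT vs control=KD flags decrease-in-KD bins; the label-swapped
    run flags increase-in-KD; a bin significant in both directions (possible
    only through disjoint regimes; counted) is set to none.
    """
    dec = call_enriched_bins(wt, kd, fdr)
    inc = call_enriched_bins(kd, wt, fdr)
    n_ties = 0
    decrease, increase = {}, {}
    for c in dec.chroms:
        both = dec.enriched[c] & inc.enriched[c]
        n_ties += int(both.sum())
        decrease[c] = dec.enriched[c] & ~both
        increase[c] = inc.enriched[c] & ~both
    return DifferentialCalls(dec.chroms, dec.bin_size, decrease, increase,
                             dec.q, inc.q, n_ties, fdr)


# ---------------------------------------------------------------------------
# domain assembly
# ---------------------------------------------------------------------------

def _runs_with_gaps(mask: np.ndarray, max_gap: int) -> list[tuple[int, int]]:
    """Maximal runs of True allowing up to `max_gap` interior False bins."""
    idx = np.flatnonzero(mask)
    if len(idx) == 0:
        return []
    runs = []
    start = prev = idx[0]
    for i in idx[1:]:
        if i - prev <= max_gap + 1:
            prev = i
        else:
            runs.append((start, prev + 1))
            start = prev = i
    runs.append((start, prev + 1))
    return runs


def assemble_micro_domains(
    diff: DifferentialCalls,
    enriched_wt: BinCalls,
    het_domains: IntervalSet,
    tss_catalog: IntervalSet | None = None,
    type2_catalog: IntervalSet | None = None,
    max_gap_bins: int = 1,
    size_max_bp: int = 2000,
    size_min_bp: int = 120,
    require: str = "and",
) -> IntervalSet:
    """Merge qualifying bins into euchromatic micro-domains (< `size_max_bp`).

    A bin qualifies when it is enriched over input in WT AND (default) lost
    in KD; `require="or"` relaxes to either.  Heterochromatin bins never
    qualify.  One interior non-qualifying bin is tolerated by default: a
    nucleosome array with a single noisy bin is still one array.  Calls
    shorter than `size_min_bp` are dropped — below ~half a nucleosome mer a
    run of bins cannot represent an array.  Domain q-value = minimum bin q;
    n_mers = round(size/200 bp), floor 1.  Distances to the nearest TSS and
    heterochromatin border and overlapping Type-2 sites are annotated when
    catalogs are given.
    """
    if require not in ("and", "or"):
        raise ValueError("require must be 'and' or 'or'")
    if diff.bin_size != enriched_wt.bin_size or diff.chroms != enriched_wt.chroms:
        raise ValueError("differential and enrichment calls use different grids")
    bs = diff.bin_size
    rows = []
    for chrom in diff.chroms:
        if require == "and":
            mask = enriched_wt.enriched[chrom] & diff.decrease[chrom]
        else:
            mask = enriched_wt.enriched[chrom] | diff.decrease[chrom]
        mids = np.arange(len(mask)) * bs + bs // 2
        mask = mask & ~het_domains.overlaps_point_sorted(chrom, mids)
        qmin = np.minimum(diff.q_decrease[chrom], enriched_wt.q[chrom])
        for s, e in _runs_with_gaps(mask, max_gap_bins):
            size = (e - s) * bs
            if size >= size_max_bp or size < size_min_bp:
                continue
            q = float(qmin[s:e][mask[s:e]].min())
            rows.append((chrom, s * bs, e * bs, e - s, size,
                         max(1, round(size / MER_BP)), q))
    if not rows:
        return IntervalSet()
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "n_bins", "size_bp",
                                     "n_mers", "q_value"])
    out = IntervalSet(df)

    mids = (out.df["start"].to_numpy() + out.df["end"].to_numpy()) // 2
    if tss_catalog is not None and len(tss_catalog):
        out.df["distance_to_nearest_tss"] = [
            tss_catalog.nearest_distance(r.chrom, np.array([m]))[0]
            for r, m in zip(out.df.itertuples(index=False), mids)
        ]
    if len(het_domains):
        out.df["distance_to_nearest_border"] = _border_distances(out, het_domains)
    if type2_catalog is not None and len(type2_catalog):
        out.df["n_partner_type2"] = _overlap_counts(out, type2_catalog, pad=500)
    return out


def _border_distances(domains: IntervalSet, het: IntervalSet) -> list[float]:
    dists = []
    for row in domains.df.itertuples(index=False):
        sub = het.for_chrom(row.chrom)
        if len(sub) == 0:
            dists.append(np.inf)
            continue
        borders = np.concatenate([sub["start"].to_numpy(), sub["end"].to_numpy()])
        mid = (row.start + row.end) // 2
        dists.append(float(np.abs(borders - mid).min()))
    return dists


def _overlap_counts(domains: IntervalSet, sites: IntervalSet, pad: int = 0) -> list[int]:
    counts = []
    for row in domains.df.itertuples(index=False):
        sub = sites.for_chrom(row.chrom)
        if len(sub) == 0:
            counts.append(0)
            continue
        s = sub["start"].to_numpy()
        e = sub["end"].to_numpy()
        counts.append(int(((e > row.start - pad) & (s < row.end + pad)).sum()))
    return counts


def call_microdomain_pipeline(
    wt: GenomeTrack,
    kd: GenomeTrack,
    input_: GenomeTrack,
    fdr: float = 0.05,
    het_domains: IntervalSet | None = None,
    max_gap_bins: int = 1,
    size_max_bp: int = 2000,
    **assemble_kwargs,
) -> IntervalSet:
    """Convenience: HMM heterochromatin + enrichment + differential + assembly."""
    if het_domains is None:
        het_domains = call_heterochromatin_hmm(wt, input_)
    enr = call_enriched_bins(wt, input_, fdr)
    diff = call_differential_bins(wt, kd, fdr)
    return assemble_micro_domains(diff, enr, het_domains,
                                  max_gap_bins=max_gap_bins,
                                  size_max_bp=size_max_bp, **assemble_kwargs)


# ---------------------------------------------------------------------------
# swap control
# ---------------------------------------------------------------------------

@dataclass
class SwapControlResult:
    n_real: int
    swap_counts: list[int]
    estimate: float       # mean swap detections / real detections; NaN if real = 0


def swap_control_fdr(
    wt: GenomeTrack,
    kd: GenomeTrack,
    input_: GenomeTrack,
    het_domains: IntervalSet,
    n_swaps: int = 4,
    seed: int = 0,
    fdr: float = 0.05,
    **pipeline_kwargs,
) -> SwapControlResult:
    """Condition-label exchange at the pseudo-replicate level as an FDR control.

    Single pooled tracks carry no replicate structure, so each swap splits
    every track into two pseudo-replicates by binomial count-splitting and
    exchanges condition labels between the halves: pseudo-WT = WT-half-A +
    KD-half-B and pseudo-KD = KD-half-A + WT-half-B have identical expected
    counts in every bin, so any detection on the swapped data is a false
    call.  Returns mean swap detections / real detections.
    """
    if n_swaps < 2:
        raise ValueError("n_swaps must be >= 2")
    real = call_microdomain_pipeline(wt, kd, input_, fdr=fdr,
                                     het_domains=het_domains, **pipeline_kwargs)
    rng = np.random.default_rng(seed)
    swap_counts = []
    for _ in range(n_swaps):
        pseudo_wt: GenomeTrack = {}
        pseudo_kd: GenomeTrack = {}
        for chrom in wt:
            w = wt[chrom].counts.astype(np.int64)
            k = kd[chrom].counts.astype(np.int64)
            w_half = rng.binomial(w, 0.5)
            k_half = rng.binomial(k, 0.5)
            pw = (w_half + (k - k_half)).astype(np.float64)
            pk = (k_half + (w - w_half)).astype(np.float64)
            pseudo_wt[chrom] = BinnedTrack(chrom, wt[chrom].bin_size, pw, "swapWT")
            pseudo_kd[chrom] = BinnedTrack(chrom, wt[chrom].bin_size, pk, "swapKD")
        swapped = call_microdomain_pipeline(pseudo_wt, pseudo_kd, input_, fdr=fdr,
                                            het_domains=het_domains, **pipeline_kwargs)
        swap_counts.append(len(swapped))
    est = np.nan if len(real) == 0 else float(np.mean(swap_counts) / len(real))
    return SwapControlResult(len(real), swap_counts, est)


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def mer_size_distribution(domains: IntervalSet, mer_bp: int = MER_BP) -> dict:
    """Domain-size histogram on the nucleosome-mer grid.

    Returns sizes, per-mer counts, the fraction of domains under 2 kb and a
    histogram with bin edges at multiples of `mer_bp`.
    """
    if len(domains) == 0:
        warnings.warn("no domains; empty histogram", RuntimeWarning)
        return {"sizes": np.array([]), "mer_counts": pd.Series(dtype=int),
                "fraction_below_2kb": np.nan, "hist": (np.array([]), np.array([]))}
    sizes = (domains.df["end"] - domains.df["start"]).to_numpy()
    mers = np.maximum(1, np.round(sizes / mer_bp).astype(int))
    mer_counts = pd.Series(mers).value_counts().sort_index()
    edges = np.arange(0, sizes.max() + 2 * mer_bp, mer_bp)
    hist = np.histogram(sizes, bins=edges)
    return {
        "sizes": sizes,
        "mer_counts": mer_counts,
        "fraction_below_2kb": float((sizes < 2000).mean()),
        "hist": hist,
    }


def quantify_track_in_intervals(
    track: GenomeTrack,
    intervals: IntervalSet,
    chrom_sizes: dict[str, int] | None = None,
    normalization: str = "library",
) -> np.ndarray:
    """Mean normalized signal per interval (bp-overlap-weighted).

    `normalization="library"` scales counts to reads per million before
    averaging over bins; `"per-bp"` additionally divides by bin size.
    """
    if normalization not in ("library", "per-bp"):
        raise ValueError("normalization must be 'library' or 'per-bp'")
    lib = library_size(track)
    if lib <= 0:
        raise ValueError("empty track")
    scale = 1e6 / lib
    out = np.empty(len(intervals))
    for k, row in enumerate(intervals.df.itertuples(index=False)):
        if row.chrom not in track:
            raise KeyError(f"interval on unknown chromosome {row.chrom}")
        t = track[row.chrom]
        if row.start < 0 or row.end > t.n_bins * t.bin_size:
            raise ValueError(f"interval {row.chrom}:{row.start}-{row.end} off chromosome")
        b0, b1 = row.start // t.bin_size, -(-row.end // t.bin_size)
        bins = np.arange(b0, b1)
        starts = np.maximum(bins * t.bin_size, row.start)
        ends = np.minimum((bins + 1) * t.bin_size, row.end)
        weights = (ends - starts).astype(float)
        vals = t.counts[b0:b1] * scale
        if normalization == "per-bp":
            vals = vals / t.bin_size
        out[k] = float(np.average(vals, weights=weights))
    return out


def matched_control_intervals(
    intervals: IntervalSet,
    allowed_regions: IntervalSet,
    seed: int = 0,
    max_tries: int = 1000,
) -> IntervalSet:
    """Random control intervals with the same size distribution.

    Each control is placed uniformly inside `allowed_regions` (e.g. the
    euchromatin or heterochromatin domains), one per input interval.
    """
    rng = np.random.default_rng(seed)
    regions = allowed_regions.df
    if len(regions) == 0:
        raise ValueError("no allowed regions to sample from")
    widths = (regions["end"] - regions["start"]).to_numpy().astype(float)
    rows = []
    for row in intervals.df.itertuples(index=False):
        size = row.end - row.start
        ok = widths >= size
        if not ok.any():
            raise ValueError(f"no allowed region can hold an interval of {size} bp")
        probs = np.where(ok, widths - size + 1, 0.0)
        probs /= probs.sum()
        for _ in range(max_tries):
            ri = int(rng.choice(len(regions), p=probs))
            reg = regions.iloc[ri]
            start = int(rng.integers(reg.start, reg.end - size + 1))
            rows.append((reg.chrom, start, start + size))
            break
    return IntervalSet(pd.DataFrame(rows, columns=["chrom", "start", "end"]))
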