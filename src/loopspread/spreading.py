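"""Border-spreading and interval-level enrichment statistics.

Heterochromatin domain borders are oriented so that every profile runs
heterochromatin → euchromatin; averaged H3K27me3 meta-profiles, paired
WT-vs-KD spreading tests in the first 0–4 kb of euchromatin, distance
distributions of differential bins, TSS-quintile log-odds enrichment
matrices, border-arrangement enrichment of micro-domains, positional
distributions within euchromatin gaps, bracketing classes and expression
group comparisons all live here.  Every Fisher/Wilcoxon call routes through
:mod:`loopspread.stats`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .intervals import IntervalSet
from .stats import TestResult, fisher_exact, log_odds_ratio, wilcoxon_rank_sum, wilcoxon_signed_rank
from .tracks import GenomeTrack, library_size


# ---------------------------------------------------------------------------
# oriented borders
# ---------------------------------------------------------------------------

def orient_borders(
    domains: IntervalSet,
    site_catalogs: dict[str, IntervalSet] | None = None,
    window_bp: int = 500,
    chrom_sizes: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Two oriented borders per heterochromatin domain.

    `het_left` is True when heterochromatin lies left of the border position
    (the domain's right edge).  Per-factor presence flags mark a catalog site
    midpoint within `window_bp` of the border.  Borders whose flank would
    leave the chromosome are kept but flagged `truncated` when `chrom_sizes`
    is supplied.
    """
    site_catalogs = site_catalogs or {}
    rows = []
    for idx, row in enumerate(domains.df.itertuples(index=False)):
        for pos, het_left in ((row.start, False), (row.end, True)):
            rec = {"chrom": row.chrom, "position": int(pos), "het_left": het_left,
                   "domain_idx": idx}
            if chrom_sizes is not None:
                size = chrom_sizes[row.chrom]
                rec["truncated"] = pos - window_bp < 0 or pos + window_bp > size
            for name, catalog in site_catalogs.items():
                sub = catalog.for_chrom(row.chrom)
                if len(sub):
                    mids = ((sub["start"] + sub["end"]) // 2).to_numpy()
                    rec[f"has_{name}"] = bool((np.abs(mids - pos) <= window_bp).any())
                else:
                    rec[f"has_{name}"] = False
            rows.append(rec)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# meta-profiles
# ---------------------------------------------------------------------------

def _border_window_signal(track: GenomeTrack, border: pd.Series,
                          start_bp: int, end_bp: int, scale: float) -> float:
    """Mean normalized signal in [start_bp, end_bp) on the euchromatin side."""
    t = track[border.chrom]
    bs = t.bin_size
    if border.het_left:          # euchromatin runs rightward
        lo, hi = border.position + start_bp, border.position + end_bp
    else:
        lo, hi = border.position - end_bp, border.position - start_bp
    b0, b1 = max(0, lo // bs), min(t.n_bins, -(-hi // bs))
    if b1 <= b0:
        return np.nan
    return float(t.counts[b0:b1].mean() * scale)


def average_profile(
    track: GenomeTrack,
    borders: pd.DataFrame,
    flank_bp: int = 10_000,
    n_boot: int = 1000,
    seed: int = 0,
    normalize: bool = True,
) -> dict:
    """Oriented meta-profile over borders (mean with a bootstrap 95% band).

    Offsets are bp relative to the border, negative = heterochromatin side;
    borders too close to a chromosome edge are skipped.
    """
    any_track = next(iter(track.values()))
    bs = any_track.bin_size
    n_flank = flank_bp // bs
    scale = 1e6 / library_size(track) if normalize else 1.0
    profiles = []
    for border in borders.itertuples(index=False):
        t = track[border.chrom]
        cbin = border.position // bs
        if cbin - n_flank < 0 or cbin + n_flank > t.n_bins:
            continue
        prof = t.counts[cbin - n_flank: cbin + n_flank] * scale
        if not border.het_left:
            prof = prof[::-1]
        profiles.append(prof)
    if not profiles:
        raise ValueError("no usable borders within the genome for this flank")
    mat = np.vstack(profiles)
    mean = mat.mean(axis=0)
    rng = np.random.default_rng(seed)
    boots = np.empty((n_boot, mat.shape[1]))
    for k in range(n_boot):
        boots[k] = mat[rng.integers(0, len(mat), len(mat))].mean(axis=0)
    lo, hi = np.percentile(boots, [2.5, 97.5], axis=0)
    offsets = (np.arange(-n_flank, n_flank) + 0.5) * bs
    return {"offsets": offsets, "mean": mean, "lo": lo, "hi": hi, "n_borders": len(mat)}


# ---------------------------------------------------------------------------
# spreading tests
# ---------------------------------------------------------------------------

def test_border_spreading(
    wt: GenomeTrack,
    kd: GenomeTrack,
    borders: pd.DataFrame,
    groups: dict[str, np.ndarray] | None = None,
    window: tuple[int, int] = (0, 4000),
    min_borders: int = 10,
) -> pd.DataFrame:
    """Paired WT-vs-KD test of euchromatin-side signal per border group.

    Per border, the mean library-normalized signal in `window` bp of
    euchromatin next to the border; per group a Wilcoxon signed-rank paired
    test (KD vs WT) with the median paired difference as effect size.  Groups
    with fewer than `min_borders` usable borders get an insufficient-data
    flag and no p-value.
    """
    if groups is None:
        groups = {"all": np.arange(len(borders))}
    scale_wt = 1e6 / library_size(wt)
    scale_kd = 1e6 / library_size(kd)
    rows = []
    for name, idx in groups.items():
        sub = borders.iloc[np.asarray(idx, int)]
        w_vals, k_vals = [], []
        for border in sub.itertuples(index=False):
            w = _border_window_signal(wt, border, *window, scale_wt)
            k = _border_window_signal(kd, border, *window, scale_kd)
            if np.isfinite(w) and np.isfinite(k):
                w_vals.append(w)
                k_vals.append(k)
        n = len(w_vals)
        if n < min_borders:
            rows.append((name, n, np.nan, np.nan, "insufficient-data"))
            continue
        res = wilcoxon_signed_rank(np.array(k_vals), np.array(w_vals))
        effect = float(np.median(np.array(k_vals) - np.array(w_vals)))
        rows.append((name, n, effect, res.p_value, res.flag))
    return pd.DataFrame(rows, columns=["group", "n_borders", "median_diff", "p_value", "flag"])


def bracketing_classes(
    borders: pd.DataFrame,
    type2_catalog: IntervalSet,
    cp190_catalog: IntervalSet,
    bracket_reach: int = 30_000,
) -> pd.Series:
    """Classify borders by bracketing of the adjacent euchromatin segment.

    A border is Beaf32-bracketed when it carries a Beaf32 site (`has_Beaf32`
    from :func:`orient_borders`); Type2+CP190-bracketed when a GAF/dCTCF site
    co-bound by CP190 lies within `bracket_reach` bp on the euchromatin side.
    Classes: none / Beaf32-only / Type2CP190-only / both.
    """
    cp_mids: dict[str, np.ndarray] = {}
    for chrom in cp190_catalog.chroms:
        sub = cp190_catalog.for_chrom(chrom)
        cp_mids[chrom] = ((sub["start"] + sub["end"]) // 2).to_numpy()
    labels = []
    for border in borders.itertuples(index=False):
        beaf = bool(getattr(border, "has_Beaf32", False))
        sub = type2_catalog.for_chrom(border.chrom)
        t2cp = False
        if len(sub):
            mids = ((sub["start"] + sub["end"]) // 2).to_numpy()
            cp = cp_mids.get(border.chrom, np.array([]))
            co = np.array([len(cp) and np.abs(cp - m).min() <= 500 for m in mids], bool)
            if border.het_left:
                inside = (mids > border.position) & (mids <= border.position + bracket_reach)
            else:
                inside = (mids < border.position) & (mids >= border.position - bracket_reach)
            t2cp = bool((inside & co).any())
        labels.append({(False, False): "none", (True, False): "Beaf32-only",
                       (False, True): "Type2CP190-only", (True, True): "both"}[(beaf, t2cp)])
    return pd.Series(labels, index=borders.index, name="bracket_class")


def bracketing_spread_test(
    borders: pd.DataFrame,
    classes: pd.Series,
    wt: GenomeTrack,
    kd: GenomeTrack,
    window: tuple[int, int] = (0, 4000),
) -> dict:
    """Per-class KD/WT border-signal ratios and pairwise rank-sum tests."""
    scale_wt = 1e6 / library_size(wt)
    scale_kd = 1e6 / library_size(kd)
    ratios: dict[str, list[float]] = {}
    for (_, border), cls in zip(borders.iterrows(), classes):
        w = _border_window_signal(wt, border, *window, scale_wt)
        k = _border_window_signal(kd, border, *window, scale_kd)
        if np.isfinite(w) and np.isfinite(k) and w > 0:
            ratios.setdefault(cls, []).append(k / w)
    dists = {k: np.array(v) for k, v in ratios.items()}
    tests = {}
    names = sorted(dists)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            if len(dists[a]) and len(dists[b]):
                tests[(a, b)] = wilcoxon_rank_sum(dists[a], dists[b])
    import warnings as _w
    for cls in ("none", "Beaf32-only", "Type2CP190-only", "both"):
        if cls not in dists:
            _w.warn(f"bracketing class {cls!r} is empty", RuntimeWarning)
    return {"ratios": dists, "tests": tests}


# ---------------------------------------------------------------------------
# distance distributions
# ---------------------------------------------------------------------------

def signed_border_distance(borders: pd.DataFrame, chrom: str, positions: np.ndarray) -> np.ndarray:
    """Signed distance to the nearest oriented border (positive = euchromatin side)."""
    sub = borders[borders["chrom"] == chrom]
    if len(sub) == 0:
        return np.full(len(positions), np.inf)
    bpos = sub["position"].to_numpy()
    het_left = sub["het_left"].to_numpy()
    diff = positions[:, None] - bpos[None, :]
    nearest = np.argmin(np.abs(diff), axis=1)
    d = diff[np.arange(len(positions)), nearest]
    # het_left: euchromatin to the right, so positive raw offset = euch side
    sign_ok = np.where(het_left[nearest], 1.0, -1.0)
    return d * sign_ok


def changed_bin_distance_distribution(
    diff_calls,
    reference: pd.DataFrame | IntervalSet,
    direction: str = "increase",
    strata: dict[str, pd.DataFrame | IntervalSet] | None = None,
    edges: np.ndarray | None = None,
) -> pd.DataFrame:
    """Histogram of labeled-bin distances to borders (signed) or sites (unsigned).

    `reference` is either an oriented-border frame (signed distances,
    positive into euchromatin) or a site catalog (unsigned).  Counts come
    with a half-genome-split standard error per distance bin.
    """
    if edges is None:
        edges = np.arange(-30_000, 30_001, 2000).astype(float)
    strata = strata or {"all": reference}
    label_attr = "increase" if direction == "increase" else "decrease"
    rows = []
    for name, ref in strata.items():
        dists_all, halves = [], []
        for chrom in diff_calls.chroms:
            mask = getattr(diff_calls, label_attr)[chrom]
            bs = diff_calls.bin_size
            mids = np.flatnonzero(mask) * bs + bs // 2
            if len(mids) == 0:
                continue
            if isinstance(ref, IntervalSet):
                d = ref.nearest_distance(chrom, mids)
            else:
                d = signed_border_distance(ref, chrom, mids.astype(float))
            dists_all.append(d)
            halves.append(mids < (len(mask) * bs) // 2)
        if dists_all:
            d = np.concatenate(dists_all)
            half = np.concatenate(halves)
            counts, _ = np.histogram(d[np.isfinite(d)], bins=edges)
            c1, _ = np.histogram(d[np.isfinite(d) & half], bins=edges)
            c2, _ = np.histogram(d[np.isfinite(d) & ~half], bins=edges)
            err = np.abs(c1 - c2) / 2.0
        else:
            counts = np.zeros(len(edges) - 1, dtype=int)
            err = np.zeros(len(edges) - 1)
        for k in range(len(edges) - 1):
            rows.append((name, edges[k], edges[k + 1], int(counts[k]), float(err[k])))
    return pd.DataFrame(rows, columns=["stratum", "d_lo", "d_hi", "count", "err"])


# ---------------------------------------------------------------------------
# enrichment matrices
# ---------------------------------------------------------------------------

@dataclass
class EnrichmentMatrix:
    log_odds: pd.DataFrame     # rows = quintiles/groups, cols = factors
    p_values: pd.DataFrame
    tables: dict               # (row, col) -> 2x2 counts, so each OR is auditable


def tss_quintile_enrichment(
    wt: GenomeTrack,
    kd: GenomeTrack,
    tss_catalog: IntervalSet,
    site_catalogs: dict[str, IntervalSet],
    window_bp: int = 1000,
    n_quantiles: int = 5,
) -> EnrichmentMatrix:
    """Quintile × factor log-odds enrichment of insulator sites at TSSs.

    TSSs are ranked by Δ = normalized KD − WT signal in TSS ± `window_bp`
    (stable tie-break by (Δ, chrom, position)), cut into `n_quantiles` equal
    groups; each (quintile, factor) cell holds the Fisher test of
    site-within-window membership against all other TSSs.
    """
    if len(tss_catalog) < n_quantiles * 20:
        raise ValueError(f"need at least {n_quantiles * 20} TSSs")
    scale_wt = 1e6 / library_size(wt)
    scale_kd = 1e6 / library_size(kd)
    tss = tss_catalog.df
    deltas = np.empty(len(tss))
    for k, row in enumerate(tss.itertuples(index=False)):
        t_wt, t_kd = wt[row.chrom], kd[row.chrom]
        bs = t_wt.bin_size
        b0 = max(0, (row.start - window_bp) // bs)
        b1 = min(t_wt.n_bins, -(-(row.start + window_bp) // bs))
        deltas[k] = (t_kd.counts[b0:b1].mean() * scale_kd
                     - t_wt.counts[b0:b1].mean() * scale_wt)

    order = np.lexsort((tss["start"].to_numpy(), tss["chrom"].to_numpy(), deltas))
    quint = np.empty(len(tss), dtype=int)
    for qi, chunk in enumerate(np.array_split(order, n_quantiles)):
        quint[chunk] = qi

    has_site = {}
    for name, catalog in site_catalogs.items():
        flags = np.zeros(len(tss), bool)
        for chrom in tss["chrom"].unique():
            sub = catalog.for_chrom(chrom)
            sel = (tss["chrom"] == chrom).to_numpy()
            if len(sub) == 0:
                continue
            mids = ((sub["start"] + sub["end"]) // 2).to_numpy()
            pos = tss["start"].to_numpy()[sel]
            flags[sel] = np.abs(pos[:, None] - mids[None, :]).min(axis=1) <= window_bp
        has_site[name] = flags

    factors = list(site_catalogs)
    rows_q = [f"Q{q + 1}" for q in range(n_quantiles)]
    lo = pd.DataFrame(index=rows_q, columns=factors, dtype=float)
    pv = pd.DataFrame(index=rows_q, columns=factors, dtype=float)
    tables = {}
    for q in range(n_quantiles):
        in_q = quint == q
        for name in factors:
            s = has_site[name]
            table = [[int((in_q & s).sum()), int((in_q & ~s).sum())],
                     [int((~in_q & s).sum()), int((~in_q & ~s).sum())]]
            _, p = fisher_exact(table)
            lo.loc[rows_q[q], name] = log_odds_ratio(table)
            pv.loc[rows_q[q], name] = p
            tables[(rows_q[q], name)] = table
    return EnrichmentMatrix(lo, pv, tables)


def arrangement_enrichment(
    microdomains: IntervalSet,
    het_domains: IntervalSet,
    chrom_sizes: dict[str, int],
    reference_class: str = "none",
) -> pd.DataFrame:
    """Micro-domain enrichment in euchromatin gaps by Beaf32 border arrangement.

    For single-side arrangements the tested gap is the one opposite the
    Beaf32-bearing border; `both`/`none` check either flanking gap.  Each
    class is Fisher-tested against the reference class.
    """
    if "arrangement_class" not in het_domains.df.columns:
        raise ValueError("het_domains must carry arrangement_class (see annotate_borders)")
    gaps = het_domains.complement(chrom_sizes)
    micro_mids = {
        chrom: ((microdomains.for_chrom(chrom)["start"]
                 + microdomains.for_chrom(chrom)["end"]) // 2).to_numpy()
        for chrom in chrom_sizes
    }

    def _gap_has_micro(chrom: str, boundary: int, side: str) -> bool:
        sub = gaps.for_chrom(chrom)
        if side == "left":
            g = sub[sub["end"] == boundary]
        else:
            g = sub[sub["start"] == boundary]
        if len(g) == 0:
            return False
        g = g.iloc[0]
        mids = micro_mids.get(chrom, np.array([]))
        return bool(((mids >= g.start) & (mids < g.end)).any())

    flags: dict[str, list[bool]] = {}
    for row in het_domains.df.itertuples(index=False):
        cls = row.arrangement_class
        if cls == "left-only":        # Beaf32 on the left border -> opposite (right) gap
            hit = _gap_has_micro(row.chrom, row.end, "right")
        elif cls == "right-only":
            hit = _gap_has_micro(row.chrom, row.start, "left")
        else:                          # both / none: either flanking gap
            hit = (_gap_has_micro(row.chrom, row.start, "left")
                   or _gap_has_micro(row.chrom, row.end, "right"))
        flags.setdefault(cls, []).append(hit)

    if reference_class not in flags:
        raise ValueError(f"reference arrangement class {reference_class!r} is empty")
    ref = flags[reference_class]
    ref_with, ref_without = sum(ref), len(ref) - sum(ref)
    rows = []
    for cls, hits in flags.items():
        n_with, n_without = sum(hits), len(hits) - sum(hits)
        if cls == reference_class:
            rows.append((cls, len(hits), n_with, np.nan, np.nan))
            continue
        if len(hits) == 0 or (n_with + n_without) == 0:
            rows.append((cls, 0, 0, np.nan, np.nan))
            continue
        table = [[n_with, n_without], [ref_with, ref_without]]
        if n_with + ref_with == 0 or n_without + ref_without == 0:
            rows.append((cls, len(hits), n_with, np.nan, np.nan))
            continue
        odds, p = fisher_exact(table)
        rows.append((cls, len(hits), n_with, odds, p))
    return pd.DataFrame(rows, columns=["arrangement", "n_domains", "n_with_micro",
                                       "odds_ratio", "p_value"])


def relative_position_distribution(
    features: IntervalSet,
    euchromatin_gaps: IntervalSet,
) -> tuple[np.ndarray, int]:
    """Feature midpoints as percent position (0–100) within their gap.

    Features outside every gap are excluded; their count is returned.
    """
    percents, excluded = [], 0
    for row in features.df.itertuples(index=False):
        mid = (row.start + row.end) // 2
        sub = euchromatin_gaps.for_chrom(row.chrom)
        hit = sub[(sub["start"] <= mid) & (mid < sub["end"])]
        if len(hit) == 0:
            excluded += 1
            continue
        g = hit.iloc[0]
        percents.append(100.0 * (mid - g.start) / (g.end - g.start))
    return np.array(percents), excluded


# ---------------------------------------------------------------------------
# expression groups
# ---------------------------------------------------------------------------

def expression_group_compare(
    expression: pd.DataFrame,
    gene_groups: dict[str, list[str]],
    condition: str = "KD",
    control_condition: str = "WT",
    control_group: str = "control",
    pseudocount: float = 1.0,
) -> dict:
    """Per-group log2(condition/control) distributions + rank-sum vs control group.

    Genes absent from the table are excluded and counted per group.
    """
    table = expression.set_index("gene")
    log_ratios: dict[str, np.ndarray] = {}
    n_missing: dict[str, int] = {}
    for name, genes in gene_groups.items():
        present = [g for g in genes if g in table.index]
        n_missing[name] = len(genes) - len(present)
        sub = table.loc[present]
        log_ratios[name] = np.log2((sub[condition] + pseudocount)
                                   / (sub[control_condition] + pseudocount)).to_numpy()
    tests: dict[str, TestResult] = {}
    if control_group in log_ratios:
        ctrl = log_ratios[control_group]
        for name, vals in log_ratios.items():
            if name == control_group:
                continue
            if len(vals) < 10 or len(ctrl) < 10:
                tests[name] = TestResult(np.nan, np.nan, "rank-sum", flag="insufficient-data")
            else:
                tests[name] = wilcoxon_rank_sum(vals, ctrl)
    return {"log_ratios": log_ratios, "tests": tests, "n_missing": n_missing}
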