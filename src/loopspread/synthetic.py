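"""Seeded synthetic datasets with the structure the pipeline assumes.

The generator emulates a compact fly-like genome in which large H3K27me3
heterochromatin domains sit in a euchromatic background, insulator sites
(Beaf32 at a fraction of heterochromatin borders; GAF/dCTCF "Type-2" sites in
euchromatin, optionally co-bound by CP190) anchor long-range loops, and small
euchromatic H3K27me3 micro-domains are planted at the Type-2 partner of a
Beaf32-border loop.  Perturbed conditions mimic insulator depletion: in "KD"
micro-domain signal is attenuated, H3K27me3 spreads across Beaf32-flanked
borders and Beaf32-anchored Hi-C loops weaken; the looping "mutant" loses
micro-domain signal without the border gain.

Every planted feature is recorded in a :class:`GroundTruthManifest` so that
recovery tests can compare calls against truth.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as lio
from .intervals import IntervalSet
from .tracks import BinnedTrack, GenomeTrack

MER_BP = 200  # one nucleosome plus linker

CHIP_CONDITIONS = ("input", "H3", "WT", "KD", "mutant")
HIC_CONDITIONS = ("WT", "KD")

_FACTORS = ("Beaf32", "GAF", "dCTCF", "CP190", "cohesin", "TSS", "enhancer")


class SimulationError(ValueError):
    pass


class PackingError(SimulationError):
    """Requested features do not fit on a chromosome."""


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass
class GenomeSpec:
    """Chromosome layout and the two bin grids (ChIP 40 bp, Hi-C 2 kb)."""

    chrom_names: tuple[str, ...] = ("chr2L", "chr2R")
    chrom_lengths: tuple[int, ...] = (2_000_000, 2_000_000)
    chip_bin_size: int = 40
    hic_bin_size: int = 2000

    def __post_init__(self) -> None:
        if len(self.chrom_names) != len(self.chrom_lengths):
            raise SimulationError("chrom_names and chrom_lengths differ in length")
        for name, length in zip(self.chrom_names, self.chrom_lengths):
            if length <= 0 or length % self.hic_bin_size:
                raise SimulationError(
                    f"{name}: length {length} must be a positive multiple of hic_bin_size"
                )
        if self.hic_bin_size % self.chip_bin_size:
            raise SimulationError("chip_bin_size must divide hic_bin_size")

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return dict(zip(self.chrom_names, self.chrom_lengths))

    def n_chip_bins(self, chrom: str) -> int:
        return self.chrom_sizes[chrom] // self.chip_bin_size

    def n_hic_bins(self, chrom: str) -> int:
        return self.chrom_sizes[chrom] // self.hic_bin_size


@dataclass
class SimulationParams:
    """Effect sizes and rates of the planted features.

    All fold parameters are >= 1; `kd_*_loss` factors live in (0, 1] with 1
    meaning "no change in KD".  `dispersion` is the negative-binomial
    overdispersion (variance = mean + dispersion * mean^2; 0 means Poisson).
    """

    n_het_domains: int = 24
    het_size_range: tuple[int, int] = (20_000, 50_000)
    het_enrichment: float = 6.0
    n_microdomains: int = 50
    micro_size_mers: tuple[int, int] = (2, 8)
    micro_enrichment: float = 3.0
    kd_micro_loss: float = 0.3
    kd_spread_gain: float = 2.0
    spread_length: float = 1000.0
    seq_depth: float = 100.0
    dispersion: float = 0.1
    hic_decay_exponent: float = 1.0
    hic_depth: float = 500.0
    compartment_amplitude: float = 0.6
    compartment_block_bp: int = 100_000
    tad_amplitude: float = 1.0
    tad_size_range: tuple[int, int] = (40_000, 120_000)
    loop_strength: float = 4.0
    kd_loop_loss: float = 0.5
    loop_distance_range: tuple[int, int] = (20_000, 200_000)
    fraction_looped_type2: float = 0.5
    fraction_beaf_borders: float = 0.5
    fraction_cp190: float = 0.7
    n_type2_sites: int = 100
    n_cohesin_sites: int = 30
    n_control_loops: int = 10
    n_background_genes: int = 150
    min_het_gap: int = 30_000
    expression_effect: float = 2.0
    expression_noise: float = 0.1
    mutant_spread_gain: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("het_enrichment", "micro_enrichment", "kd_spread_gain",
                     "loop_strength", "expression_effect"):
            if getattr(self, name) < 1:
                raise SimulationError(f"{name} must be >= 1 (fold over background)")
        for name in ("kd_micro_loss", "kd_loop_loss"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise SimulationError(f"{name} must lie in (0, 1]")
        lo, hi = self.micro_size_mers
        if not (1 <= lo <= hi <= 10):
            raise SimulationError("micro_size_mers must lie within [1, 10]")
        if self.loop_distance_range[0] <= 5000:
            raise SimulationError("loop distance floor must exceed 5 kb")
        if self.hic_decay_exponent <= 0:
            raise SimulationError("hic_decay_exponent must be positive")
        if self.dispersion < 0:
            raise SimulationError("dispersion must be non-negative")


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------

@dataclass
class GroundTruthManifest:
    """Every planted feature of one synthetic dataset."""

    spec: GenomeSpec
    params: SimulationParams
    het_domains: IntervalSet          # + beaf_left / beaf_right flags
    microdomains: IntervalSet         # + n_mers, site_id, loop_id, gene
    site_catalogs: dict[str, IntervalSet]
    planted_loops: pd.DataFrame       # loop_id, chrom, anchor_a, anchor_b, strength, kd_factor, beaf_anchored
    compartment_labels: dict[str, np.ndarray]   # per hic bin, +1 (A) / -1 (B)
    tad_intervals: IntervalSet
    seed: int

    # -- serialization ----------------------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        doc = {
            "seed": int(self.seed),
            "spec": _plain(dataclasses.asdict(self.spec)),
            "params": _plain(dataclasses.asdict(self.params)),
            "het_domains": self.het_domains.df.to_dict("list"),
            "microdomains": self.microdomains.df.to_dict("list"),
            "site_catalogs": {k: v.df.to_dict("list") for k, v in self.site_catalogs.items()},
            "planted_loops": self.planted_loops.to_dict("list"),
            "compartment_labels": {c: v.astype(int).tolist() for c, v in self.compartment_labels.items()},
            "tad_intervals": self.tad_intervals.df.to_dict("list"),
        }
        Path(path).write_text(yaml.safe_dump(_plain(doc), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GroundTruthManifest":
        doc = yaml.safe_load(Path(path).read_text())
        spec_d = doc["spec"]
        spec = GenomeSpec(tuple(spec_d["chrom_names"]), tuple(spec_d["chrom_lengths"]),
                          spec_d["chip_bin_size"], spec_d["hic_bin_size"])
        params_d = dict(doc["params"])
        for key in ("het_size_range", "micro_size_mers", "loop_distance_range", "tad_size_range"):
            params_d[key] = tuple(params_d[key])
        params = SimulationParams(**params_d)
        return cls(
            spec=spec,
            params=params,
            het_domains=IntervalSet(pd.DataFrame(doc["het_domains"])),
            microdomains=IntervalSet(pd.DataFrame(doc["microdomains"])),
            site_catalogs={k: IntervalSet(pd.DataFrame(v)) for k, v in doc["site_catalogs"].items()},
            planted_loops=pd.DataFrame(doc["planted_loops"]),
            compartment_labels={c: np.asarray(v, dtype=np.int8) for c, v in doc["compartment_labels"].items()},
            tad_intervals=IntervalSet(pd.DataFrame(doc["tad_intervals"])),
            seed=doc["seed"],
        )


def _plain(obj):
    """Recursively convert numpy scalars/containers for YAML round-trips."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


# ---------------------------------------------------------------------------
# genome construction
# ---------------------------------------------------------------------------

def _rng(params: SimulationParams, *tags: int) -> np.random.Generator:
    return np.random.default_rng([int(params.seed) % (2**31), *tags])


def build_genome(spec: GenomeSpec, params: SimulationParams) -> GroundTruthManifest:
    """Place heterochromatin domains, insulator sites, loops and micro-domains.

    Deterministic for a given (spec, params, seed).  Raises
    :class:`PackingError` when the requested domains do not fit.
    """
    rng = _rng(params, 0)
    cb = spec.chip_bin_size

    # -- heterochromatin domains, round-robin over chromosomes ------------
    per_chrom: dict[str, int] = {c: 0 for c in spec.chrom_names}
    for k in range(params.n_het_domains):
        per_chrom[spec.chrom_names[k % len(spec.chrom_names)]] += 1

    het_rows = []
    for chrom in spec.chrom_names:
        n = per_chrom[chrom]
        if n == 0:
            continue
        length = spec.chrom_sizes[chrom]
        sizes = rng.integers(params.het_size_range[0], params.het_size_range[1] + 1, n)
        sizes = (sizes // cb) * cb
        min_gap = params.min_het_gap
        slack = length - int(sizes.sum()) - (n + 1) * min_gap
        if slack < 0:
            raise PackingError(
                f"{chrom}: {n} heterochromatin domains of total {int(sizes.sum())} bp "
                f"do not fit in {length} bp with {min_gap} bp gaps"
            )
        cuts = np.sort(rng.uniform(0, slack, n))
        extras = np.diff(np.concatenate([[0.0], cuts, [float(slack)]]))
        cursor = 0
        for i in range(n):
            cursor += min_gap + int(extras[i])
            start = (cursor // cb) * cb
            end = start + int(sizes[i])
            het_rows.append((chrom, start, end))
            cursor = end

    beaf_left = rng.random(len(het_rows)) < params.fraction_beaf_borders
    beaf_right = rng.random(len(het_rows)) < params.fraction_beaf_borders
    het_df = pd.DataFrame(het_rows, columns=["chrom", "start", "end"])
    het_df["beaf_left"] = beaf_left[: len(het_rows)]
    het_df["beaf_right"] = beaf_right[: len(het_rows)]
    het = IntervalSet(het_df) if len(het_df) else IntervalSet()

    site_w = 200  # footprint of one binding site

    # -- Beaf32 sites at flagged borders ----------------------------------
    beaf_rows = []   # (chrom, start, end, border_pos, domain_idx, side)
    for idx, row in enumerate(het.df.itertuples(index=False)):
        if row.beaf_left:
            beaf_rows.append((row.chrom, row.start - site_w // 2, row.start + site_w // 2, row.start))
        if row.beaf_right:
            beaf_rows.append((row.chrom, row.end - site_w // 2, row.end + site_w // 2, row.end))
    beaf_df = pd.DataFrame(beaf_rows, columns=["chrom", "start", "end", "border_pos"])

    het_arrays = {
        c: (het.for_chrom(c)["start"].to_numpy(), het.for_chrom(c)["end"].to_numpy())
        for c in spec.chrom_names
    }

    def _in_het(chrom: str, pos: np.ndarray) -> np.ndarray:
        starts, ends = het_arrays[chrom]
        if len(starts) == 0:
            return np.zeros(len(np.atleast_1d(pos)), dtype=bool)
        pos = np.atleast_1d(pos)
        idx = np.searchsorted(starts, pos, side="right") - 1
        ok = idx >= 0
        inside = np.zeros(len(pos), dtype=bool)
        inside[ok] = pos[ok] < ends[idx[ok]]
        return inside

    def _range_touches_het(chrom: str, lo: int, hi: int) -> bool:
        starts, ends = het_arrays[chrom]
        if len(starts) == 0:
            return False
        j = np.searchsorted(starts, hi, side="left") - 1
        return bool(j >= 0 and ends[j] > lo)

    # -- Type-2 (GAF/dCTCF) sites -----------------------------------------
    n_looped = int(round(params.fraction_looped_type2 * params.n_type2_sites))
    if params.n_microdomains > params.n_type2_sites:
        raise PackingError("n_microdomains exceeds n_type2_sites")
    margin = 2_000 + params.micro_size_mers[1] * MER_BP // 2
    occupied: dict[str, list[int]] = {c: [] for c in spec.chrom_names}

    def _free(chrom: str, pos: int) -> bool:
        lo, hi = pos - 1500, pos + 1500
        if lo < margin or hi > spec.chrom_sizes[chrom] - margin:
            return False
        if _range_touches_het(chrom, lo, hi):
            return False
        occ = occupied[chrom]
        return not occ or min(abs(pos - p) for p in occ) > 3000

    type2_rows = []   # chrom, start, end, factor, looped, loop_id, partner_border
    loops_rows = []   # loop_id, chrom, anchor_a, anchor_b, strength, kd_factor, beaf_anchored
    loop_id = 0
    lo_d, hi_d = params.loop_distance_range
    n_placed_looped = 0
    if len(beaf_df):
        for _ in range(n_looped):
            placed = False
            for _try in range(200):
                b = beaf_df.iloc[int(rng.integers(len(beaf_df)))]
                d = int(rng.integers(lo_d, hi_d + 1))
                side = int(rng.integers(2)) * 2 - 1
                pos = int(b.border_pos + side * d)
                if _free(b.chrom, pos):
                    factor = "GAF" if rng.random() < 0.5 else "dCTCF"
                    type2_rows.append((b.chrom, pos - site_w // 2, pos + site_w // 2,
                                       factor, True, loop_id, int(b.border_pos)))
                    loops_rows.append((loop_id, b.chrom, int(b.border_pos), pos,
                                       params.loop_strength, params.kd_loop_loss, True))
                    occupied[b.chrom].append(pos)
                    loop_id += 1
                    n_placed_looped += 1
                    placed = True
                    break
            if not placed:
                raise PackingError("could not place a looped Type-2 site; genome too crowded")

    for _ in range(params.n_type2_sites - n_placed_looped):
        for _try in range(500):
            chrom = spec.chrom_names[int(rng.integers(len(spec.chrom_names)))]
            pos = int(rng.integers(margin, spec.chrom_sizes[chrom] - margin))
            if _free(chrom, pos):
                factor = "GAF" if rng.random() < 0.5 else "dCTCF"
                type2_rows.append((chrom, pos - site_w // 2, pos + site_w // 2,
                                   factor, False, -1, -1))
                occupied[chrom].append(pos)
                break
        else:
            raise PackingError("could not place a Type-2 site; genome too crowded")

    type2_df = pd.DataFrame(
        type2_rows,
        columns=["chrom", "start", "end", "factor", "looped", "loop_id", "partner_border"],
    )

    # -- micro-domains at looped Type-2 sites (fallback: non-looped) ------
    looped_idx = type2_df.index[type2_df["looped"]].to_numpy()
    other_idx = type2_df.index[~type2_df["looped"]].to_numpy()
    order = np.concatenate([rng.permutation(looped_idx), rng.permutation(other_idx)])
    chosen = order[: params.n_microdomains]
    micro_rows = []
    mer_lo, mer_hi = params.micro_size_mers
    for k, si in enumerate(chosen):
        site = type2_df.loc[si]
        mer = int(rng.integers(mer_lo, mer_hi + 1))
        size = mer * MER_BP
        center = (int(site.start) + int(site.end)) // 2
        start = ((center - size // 2) // cb) * cb
        micro_rows.append((site.chrom, start, start + size, mer, int(si),
                           int(site.loop_id), f"g{si:04d}"))
    micro_df = pd.DataFrame(
        micro_rows,
        columns=["chrom", "start", "end", "n_mers", "site_id", "loop_id", "gene"],
    )
    microdomains = IntervalSet(micro_df) if len(micro_df) else IntervalSet()
    for row in microdomains.df.itertuples(index=False):
        pos = np.arange(row.start, row.end, cb)
        if _in_het(row.chrom, pos).any():
            raise SimulationError("planted micro-domain overlaps heterochromatin")

    # -- other catalogs ----------------------------------------------------
    cohesin_rows = []
    for _ in range(params.n_cohesin_sites):
        for _try in range(500):
            chrom = spec.chrom_names[int(rng.integers(len(spec.chrom_names)))]
            pos = int(rng.integers(margin, spec.chrom_sizes[chrom] - margin))
            if _free(chrom, pos):
                cohesin_rows.append((chrom, pos - site_w // 2, pos + site_w // 2))
                occupied[chrom].append(pos)
                break
    cohesin_df = pd.DataFrame(cohesin_rows, columns=["chrom", "start", "end"])

    # control loops between cohesin sites; unaffected by KD
    by_chrom = {c: cohesin_df[cohesin_df["chrom"] == c] for c in spec.chrom_names}
    n_ctrl = 0
    for _try in range(2000):
        if n_ctrl >= params.n_control_loops:
            break
        chrom = spec.chrom_names[int(rng.integers(len(spec.chrom_names)))]
        sub = by_chrom[chrom]
        if len(sub) < 2:
            continue
        a, b = rng.choice(len(sub), 2, replace=False)
        pa = (int(sub.iloc[a].start) + int(sub.iloc[a].end)) // 2
        pb = (int(sub.iloc[b].start) + int(sub.iloc[b].end)) // 2
        if lo_d <= abs(pa - pb) <= hi_d:
            loops_rows.append((loop_id, chrom, min(pa, pb), max(pa, pb),
                               params.loop_strength, 1.0, False))
            loop_id += 1
            n_ctrl += 1

    loops_df = pd.DataFrame(
        loops_rows,
        columns=["loop_id", "chrom", "anchor_a", "anchor_b", "strength", "kd_factor", "beaf_anchored"],
    )

    # genes: one TSS near every Type-2 site plus background TSSs
    tss_rows = []
    for si, site in type2_df.iterrows():
        center = (int(site.start) + int(site.end)) // 2
        off = int(rng.integers(200, 600)) * (1 if rng.random() < 0.5 else -1)
        pos = center + off
        tss_rows.append((site.chrom, pos, pos + 1, f"g{si:04d}"))
    for k in range(params.n_background_genes):
        for _try in range(500):
            chrom = spec.chrom_names[int(rng.integers(len(spec.chrom_names)))]
            pos = int(rng.integers(margin, spec.chrom_sizes[chrom] - margin))
            if _free(chrom, pos):
                tss_rows.append((chrom, pos, pos + 1, f"bg{k:04d}"))
                occupied[chrom].append(pos)
                break
    tss_df = pd.DataFrame(tss_rows, columns=["chrom", "start", "end", "gene"])

    enh_rows = []
    for k in range(30):
        chrom = spec.chrom_names[int(rng.integers(len(spec.chrom_names)))]
        pos = int(rng.integers(margin, spec.chrom_sizes[chrom] - margin))
        if not _in_het(chrom, np.array([pos]))[0]:
            enh_rows.append((chrom, pos - 100, pos + 100))
    enh_df = pd.DataFrame(enh_rows, columns=["chrom", "start", "end"])

    # CP190 co-binding on a fraction of all insulator sites
    insulator_sites = pd.concat(
        [beaf_df[["chrom", "start", "end"]], type2_df[["chrom", "start", "end"]]],
        ignore_index=True,
    )
    cp_mask = rng.random(len(insulator_sites)) < params.fraction_cp190
    cp190_df = insulator_sites[cp_mask].reset_index(drop=True)

    catalogs = {
        "Beaf32": IntervalSet(beaf_df) if len(beaf_df) else IntervalSet(),
        "GAF": IntervalSet(type2_df[type2_df["factor"] == "GAF"].reset_index(drop=True))
        if (type2_df["factor"] == "GAF").any() else IntervalSet(),
        "dCTCF": IntervalSet(type2_df[type2_df["factor"] == "dCTCF"].reset_index(drop=True))
        if (type2_df["factor"] == "dCTCF").any() else IntervalSet(),
        "Type2": IntervalSet(type2_df) if len(type2_df) else IntervalSet(),
        "CP190": IntervalSet(cp190_df) if len(cp190_df) else IntervalSet(),
        "cohesin": IntervalSet(cohesin_df) if len(cohesin_df) else IntervalSet(),
        "TSS": IntervalSet(tss_df) if len(tss_df) else IntervalSet(),
        "enhancer": IntervalSet(enh_df) if len(enh_df) else IntervalSet(),
    }

    # compartments: alternating A/B blocks on the Hi-C grid
    comp: dict[str, np.ndarray] = {}
    block_bins = max(1, params.compartment_block_bp // spec.hic_bin_size)
    for ci, chrom in enumerate(spec.chrom_names):
        n = spec.n_hic_bins(chrom)
        first = 1 if rng.random() < 0.5 else -1
        labels = np.where((np.arange(n) // block_bins) % 2 == 0, first, -first)
        comp[chrom] = labels.astype(np.int8)

    # TADs: random partition on the Hi-C grid
    tad_rows = []
    lo_t = max(2, params.tad_size_range[0] // spec.hic_bin_size)
    hi_t = max(lo_t + 1, params.tad_size_range[1] // spec.hic_bin_size)
    for chrom in spec.chrom_names:
        n = spec.n_hic_bins(chrom)
        cursor = 0
        while cursor < n:
            size = int(rng.integers(lo_t, hi_t + 1))
            end = min(cursor + size, n)
            if n - end < lo_t:
                end = n
            tad_rows.append((chrom, cursor * spec.hic_bin_size, end * spec.hic_bin_size))
            cursor = end
    tads = IntervalSet(pd.DataFrame(tad_rows, columns=["chrom", "start", "end"]))

    # loop invariants
    if len(loops_df):
        sep = (loops_df["anchor_b"] - loops_df["anchor_a"]).abs()
        if (sep < lo_d).any() or (sep > hi_d).any():
            raise SimulationError("planted loop violates loop_distance_range")

    return GroundTruthManifest(
        spec=spec, params=params, het_domains=het, microdomains=microdomains,
        site_catalogs=catalogs, planted_loops=loops_df,
        compartment_labels=comp, tad_intervals=tads, seed=params.seed,
    )


# ---------------------------------------------------------------------------
# ChIP-seq tracks
# ---------------------------------------------------------------------------

def _bin_enrichment(manifest: GroundTruthManifest, chrom: str, condition: str) -> np.ndarray:
    """Expected fold-enrichment over flat background per ChIP bin."""
    spec, params = manifest.spec, manifest.params
    cb = spec.chip_bin_size
    n = spec.n_chip_bins(chrom)
    enr = np.ones(n)
    if condition in ("input", "H3"):
        return enr
    mids = np.arange(n) * cb + cb // 2

    in_het = manifest.het_domains.overlaps_point_sorted(chrom, mids)
    enr[in_het] = params.het_enrichment

    in_micro = manifest.microdomains.overlaps_point_sorted(chrom, mids)
    if condition == "WT":
        enr[in_micro] = params.micro_enrichment
    else:
        # depletion attenuates the micro-domain excess over background
        enr[in_micro] = 1.0 + (params.micro_enrichment - 1.0) * params.kd_micro_loss

    spreading = condition == "KD" or (condition == "mutant" and params.mutant_spread_gain)
    if spreading and params.kd_spread_gain > 1 and len(manifest.het_domains):
        reach = int(8 * params.spread_length)
        gain = np.ones(n)
        for row in manifest.het_domains.df.itertuples(index=False):
            if row.chrom != chrom:
                continue
            for border, flagged, direction in ((row.start, row.beaf_left, -1),
                                               (row.end, row.beaf_right, +1)):
                if not flagged:
                    continue
                if direction < 0:
                    lo, hi = max(0, (border - reach) // cb), border // cb
                    d = border - mids[lo:hi]
                else:
                    lo, hi = border // cb, min(n, (border + reach) // cb)
                    d = mids[lo:hi] - border
                factor = 1.0 + (params.kd_spread_gain - 1.0) * np.exp(-d / params.spread_length)
                gain[lo:hi] = np.maximum(gain[lo:hi], factor)
        gain[in_het] = 1.0  # spreading applies to the euchromatin side only
        enr *= gain
    return enr


_COND_TAG = {c: i for i, c in enumerate(CHIP_CONDITIONS)}


def simulate_chip_tracks(
    manifest: GroundTruthManifest,
    spec: GenomeSpec | None = None,
    params: SimulationParams | None = None,
    conditions: tuple[str, ...] = CHIP_CONDITIONS,
) -> dict[str, GenomeTrack]:
    """Draw per-bin NB (or Poisson) counts for each requested condition."""
    spec = spec or manifest.spec
    params = params or manifest.params
    for cond in conditions:
        if cond not in CHIP_CONDITIONS:
            raise SimulationError(f"unknown condition {cond!r}; choose from {CHIP_CONDITIONS}")
    # Bin-specific efficiency factors (mappability/accessibility) are drawn
    # once per bin and shared across conditions, as in real libraries of the
    # same genome.  Marginally every track is NB(mean, dispersion); the
    # treatment count conditional on the bin total stays binomial, which is
    # the regime the enrichment caller models.
    gamma_factors: dict[str, np.ndarray] = {}
    for ci, chrom in enumerate(spec.chrom_names):
        if params.dispersion > 0:
            rng_g = _rng(params, 4, ci)
            shape = 1.0 / params.dispersion
            gamma_factors[chrom] = rng_g.gamma(shape, params.dispersion,
                                               spec.n_chip_bins(chrom))
        else:
            gamma_factors[chrom] = np.ones(spec.n_chip_bins(chrom))

    out: dict[str, GenomeTrack] = {}
    for cond in conditions:
        track: GenomeTrack = {}
        for ci, chrom in enumerate(spec.chrom_names):
            rng = _rng(params, 1, _COND_TAG[cond], ci)
            mean = params.seq_depth * _bin_enrichment(manifest, chrom, cond)
            counts = rng.poisson(mean * gamma_factors[chrom])
            track[chrom] = BinnedTrack(chrom, spec.chip_bin_size,
                                       counts.astype(np.float64), cond)
        out[cond] = track
    return out


# ---------------------------------------------------------------------------
# Hi-C
# ---------------------------------------------------------------------------

def expected_hic_matrix(manifest: GroundTruthManifest, chrom: str, condition: str) -> np.ndarray:
    """Noise-free expected contact matrix for one chromosome/condition."""
    spec, params = manifest.spec, manifest.params
    n = spec.n_hic_bins(chrom)
    d = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
    exp = params.hic_depth * (d + 1.0) ** (-params.hic_decay_exponent)

    if params.compartment_amplitude > 0:
        lab = manifest.compartment_labels[chrom]
        same = np.equal.outer(lab, lab)
        exp = exp * np.where(same, 1.0 + params.compartment_amplitude, 1.0)

    if params.tad_amplitude > 0:
        tad_id = np.full(n, -1)
        for t, row in enumerate(manifest.tad_intervals.for_chrom(chrom).itertuples(index=False)):
            tad_id[row.start // spec.hic_bin_size: row.end // spec.hic_bin_size] = t
        same_tad = np.equal.outer(tad_id, tad_id) & (tad_id >= 0)[:, None] & (tad_id >= 0)[None, :]
        exp = exp * np.where(same_tad, 1.0 + params.tad_amplitude, 1.0)

    for loop in manifest.planted_loops.itertuples(index=False):
        if loop.chrom != chrom:
            continue
        strength = loop.strength
        if condition == "KD":
            strength = strength * loop.kd_factor
        a = int(loop.anchor_a) // spec.hic_bin_size
        b = int(loop.anchor_b) // spec.hic_bin_size
        sl_a = slice(max(0, a - 1), min(n, a + 2))
        sl_b = slice(max(0, b - 1), min(n, b + 2))
        exp[sl_a, sl_b] *= strength
        exp[sl_b, sl_a] *= strength
    return exp


def simulate_hic(
    manifest: GroundTruthManifest,
    spec: GenomeSpec | None = None,
    params: SimulationParams | None = None,
    conditions: tuple[str, ...] = HIC_CONDITIONS,
) -> dict[str, dict[str, np.ndarray]]:
    """Poisson-sampled symmetric contact matrices per condition and chromosome."""
    spec = spec or manifest.spec
    params = params or manifest.params
    out: dict[str, dict[str, np.ndarray]] = {}
    for k, cond in enumerate(conditions):
        per_chrom: dict[str, np.ndarray] = {}
        for ci, chrom in enumerate(spec.chrom_names):
            rng = _rng(params, 2, k, ci)
            exp = expected_hic_matrix(manifest, chrom, cond)
            n = exp.shape[0]
            iu, ju = np.triu_indices(n)
            counts = rng.poisson(exp[iu, ju])
            mat = np.zeros_like(exp)
            mat[iu, ju] = counts
            mat[ju, iu] = counts
            per_chrom[chrom] = mat
        out[cond] = per_chrom
    return out


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def simulate_expression(
    manifest: GroundTruthManifest,
    params: SimulationParams | None = None,
    flank_bp: int = 1000,
) -> pd.DataFrame:
    """Normalized per-gene expression in WT/KD/mutant.

    Genes whose TSS lies within `flank_bp` of a planted micro-domain are
    up-regulated by `expression_effect` in KD and mutant; all genes carry
    multiplicative log-normal noise.
    """
    params = params or manifest.params
    tss = manifest.site_catalogs["TSS"]
    if len(tss) == 0:
        raise SimulationError("manifest has no TSS catalog")
    rng = _rng(params, 3)
    rows = []
    for row in tss.df.itertuples(index=False):
        dist = manifest.microdomains.nearest_distance(row.chrom, np.array([row.start]))[0]
        flanked = dist < flank_bp
        base = float(rng.lognormal(np.log(500.0), 0.5))
        noise = rng.lognormal(0.0, params.expression_noise, 3)
        effect = params.expression_effect if flanked else 1.0
        rows.append((row.gene, row.chrom, int(row.start), bool(flanked),
                     base * noise[0], base * effect * noise[1], base * effect * noise[2]))
    return pd.DataFrame(rows, columns=["gene", "chrom", "tss", "micro_flanked",
                                       "WT", "KD", "mutant"])


# ---------------------------------------------------------------------------
# dataset bundle + on-disk layout
# ---------------------------------------------------------------------------

@dataclass
class SyntheticDataset:
    manifest: GroundTruthManifest
    chip: dict[str, GenomeTrack]
    hic: dict[str, dict[str, np.ndarray]]
    expression: pd.DataFrame


def simulate(spec: GenomeSpec | None = None,
             params: SimulationParams | None = None) -> SyntheticDataset:
    """Full dataset: genome, ChIP tracks, Hi-C and expression, one seed."""
    spec = spec or GenomeSpec()
    params = params or SimulationParams()
    manifest = build_genome(spec, params)
    return SyntheticDataset(
        manifest=manifest,
        chip=simulate_chip_tracks(manifest, spec, params),
        hic=simulate_hic(manifest, spec, params),
        expression=simulate_expression(manifest, params),
    )


def write_dataset(dataset: SyntheticDataset, directory: str | Path) -> None:
    d = Path(directory)
    for sub in ("tracks", "sites", "hic"):
        (d / sub).mkdir(parents=True, exist_ok=True)
    spec = dataset.manifest.spec
    lio.write_chrom_sizes(spec.chrom_sizes, d / "chrom.sizes")
    for cond, track in dataset.chip.items():
        lio.write_bedgraph(track, d / "tracks" / f"{cond}.bedGraph")
    dataset.manifest.het_domains.to_bed(d / "sites" / "het_domains.bed")
    dataset.manifest.microdomains.to_bed(d / "sites" / "planted_microdomains.bed",
                                         extra_cols=["gene"])
    for factor, catalog in dataset.manifest.site_catalogs.items():
        catalog.to_bed(d / "sites" / f"{factor}.bed")
    for cond, per_chrom in dataset.hic.items():
        for chrom, mat in per_chrom.items():
            lio.write_triplets(mat, d / "hic" / f"{cond}.{chrom}.triplets.tsv")
    lio.write_table(dataset.expression, d / "expression.tsv")
    dataset.manifest.to_yaml(d / "manifest.yaml")


def read_dataset(directory: str | Path) -> SyntheticDataset:
    d = Path(directory)
    manifest = GroundTruthManifest.from_yaml(d / "manifest.yaml")
    spec = manifest.spec
    sizes = lio.read_chrom_sizes(d / "chrom.sizes")
    chip = {}
    for path in sorted((d / "tracks").glob("*.bedGraph")):
        cond = path.stem
        chip[cond] = lio.read_bedgraph(path, spec.chip_bin_size, sizes, cond)
    hic: dict[str, dict[str, np.ndarray]] = {}
    for path in sorted((d / "hic").glob("*.triplets.tsv")):
        cond, chrom = path.name.split(".")[:2]
        hic.setdefault(cond, {})[chrom] = lio.read_triplets(path, sizes[chrom] // spec.hic_bin_size)
    expression = lio.read_table(d / "expression.tsv")
    return SyntheticDataset(manifest=manifest, chip=chip, hic=hic, expression=expression)
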