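"""End-to-end orchestration: config schema, stage runner, input validation.

`run_pipeline` executes simulate → domains → spreading → hic-lri → gsea from
a single validated config, writes every stage's tables under the output
directory together with a provenance manifest (config, seeds, package
version, input checksums), and returns the in-memory results bundle.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict

from . import __version__, domains as dm, gsea as gs, hic, io as lio, spreading as sp
from .intervals import IntervalSet
from .synthetic import (
    GenomeSpec, SimulationParams, SyntheticDataset, simulate, write_dataset,
)
from .tracks import library_size


class PipelineError(RuntimeError):
    pass


class DependencyError(PipelineError):
    """A stage ran without the outputs of the stage it depends on."""


# ---------------------------------------------------------------------------
# config schema (unknown keys rejected everywhere)
# ---------------------------------------------------------------------------

class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SimulationBlock(_Block):
    spec: dict = {}
    params: dict = {}


class CallingBlock(_Block):
    fdr: float = 0.05
    max_gap_bins: int = 1
    size_max_bp: int = 2000
    size_min_bp: int = 120
    min_het_size_bp: int = 5000
    n_swaps: int = 4


class SpreadingBlock(_Block):
    border_window_bp: int = 500
    euchromatin_window: tuple[int, int] = (0, 4000)
    flank_bp: int = 10_000
    tss_window_bp: int = 1000
    n_quantiles: int = 5


class HicBlock(_Block):
    window_bins: int = 10
    center_bins: int = 3
    flank_bins: int = 10
    min_sep_bp: int = 5000
    max_sep_bp: int = 250_000
    mask_percentile: float = 1.0
    tol: float = 1e-10


class GseaBlock(_Block):
    metrics: tuple[str, ...] = ("delta_lri1", "delta_lri2", "delta_lri3")
    aggregation: str | None = None      # None -> per-metric default (min for loops)
    n_perm: int = 1000
    weight_exponent: float = 1.0


class PipelineConfig(_Block):
    seed: int = 0
    outdir: str = "loopspread_out"
    stages: tuple[str, ...] = ("simulate", "domains", "spreading", "hic-lri", "gsea")
    simulation: SimulationBlock = SimulationBlock()
    calling: CallingBlock = CallingBlock()
    spreading: SpreadingBlock = SpreadingBlock()
    hic: HicBlock = HicBlock()
    gsea: GseaBlock = GseaBlock()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.model_validate(yaml.safe_load(Path(path).read_text()) or {})


def _tupleize(d: dict) -> dict:
    return {k: tuple(v) if isinstance(v, list) else v for k, v in d.items()}


def build_simulation(config: PipelineConfig) -> tuple[GenomeSpec, SimulationParams]:
    spec_kwargs = _tupleize(config.simulation.spec)
    params_kwargs = _tupleize(config.simulation.params)
    params_kwargs.setdefault("seed", config.seed)
    return GenomeSpec(**spec_kwargs), SimulationParams(**params_kwargs)


# ---------------------------------------------------------------------------
# gene-pair ΔLRI records
# ---------------------------------------------------------------------------

def gene_pair_delta_records(
    beaf_catalog: IntervalSet,
    tss_catalog: IntervalSet,
    oe_wt: dict[str, np.ndarray],
    oe_kd: dict[str, np.ndarray],
    bin_size: int,
    geometry: hic.ZoneGeometry = hic.ZoneGeometry(),
    min_sep_bp: int = 5000,
    max_sep_bp: int = 250_000,
) -> pd.DataFrame:
    """ΔLRI-1/2/3 for every (Beaf32 site, distant gene) pair.

    Pairs couple one Beaf32 anchor bin with the bin of a gene TSS more than
    `min_sep_bp` away; both conditions are scored on O/E so depth cancels.
    """
    frames = []
    min_sep_bins = max(1, min_sep_bp // bin_size)
    max_sep_bins = max_sep_bp // bin_size
    for chrom in sorted(set(beaf_catalog.chroms) & set(oe_wt)):
        beaf_bins = hic.anchors_to_bins(beaf_catalog, chrom, bin_size)
        tss = tss_catalog.for_chrom(chrom)
        if len(beaf_bins) == 0 or len(tss) == 0:
            continue
        n = oe_wt[chrom].shape[0]
        pair_rows = []
        for row in tss.itertuples(index=False):
            g_bin = row.start // bin_size
            for a in beaf_bins:
                lo, hi = (int(a), int(g_bin)) if a < g_bin else (int(g_bin), int(a))
                sep = hi - lo
                if sep <= min_sep_bins or sep > max_sep_bins:
                    continue
                if lo - geometry.window_bins < 0 or hi + geometry.window_bins >= n:
                    continue
                pair_rows.append((row.gene, lo, hi))
        if not pair_rows:
            continue
        pairs = sorted({(a, b) for _, a, b in pair_rows})
        rec_wt = hic.score_lri_records(oe_wt[chrom], pairs, bin_size, chrom, "WT")
        rec_kd = hic.score_lri_records(oe_kd[chrom], pairs, bin_size, chrom, "KD")
        delta = hic.delta_lri(rec_wt, rec_kd).set_index(["bin_a", "bin_b"])
        rows = []
        for gene, a, b in pair_rows:
            if (a, b) not in delta.index:
                continue
            rec = delta.loc[(a, b)]
            rows.append((gene, chrom, a, b, (b - a) * bin_size,
                         rec["delta_lri1"], rec["delta_lri2"], rec["delta_lri3"]))
        frames.append(pd.DataFrame(rows, columns=[
            "gene", "chrom", "bin_a", "bin_b", "separation",
            "delta_lri1", "delta_lri2", "delta_lri3"]))
    if not frames:
        raise PipelineError("no (Beaf32, gene) pairs within the separation band")
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# stage runner
# ---------------------------------------------------------------------------

def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages in dependency order; write all outputs."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {"config": config}
    order = ("simulate", "domains", "spreading", "hic-lri", "gsea")
    requested = [s for s in order if s in config.stages]
    unknown = set(config.stages) - set(order)
    if unknown:
        raise PipelineError(f"unknown stages: {sorted(unknown)}")

    for stage in requested:
        _STAGES[stage](config, results, out)

    provenance = {
        "version": __version__,
        "config": json.loads(config.model_dump_json()),
        "stages_run": requested,
        "file_checksums": {
            str(p.relative_to(out)): hashlib.sha256(p.read_bytes()).hexdigest()
            for p in sorted(out.rglob("*")) if p.is_file() and p.name != "provenance.json"
        },
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=1, sort_keys=True))
    return results


def _need(results: dict, key: str, stage: str, needed_by: str):
    if key not in results:
        raise DependencyError(
            f"stage {needed_by!r} requires outputs of stage {stage!r}, which did not run"
        )
    return results[key]


def _stage_simulate(config: PipelineConfig, results: dict, out: Path) -> None:
    spec, params = build_simulation(config)
    dataset = simulate(spec, params)
    write_dataset(dataset, out / "data")
    results["dataset"] = dataset


def _stage_domains(config: PipelineConfig, results: dict, out: Path) -> None:
    ds: SyntheticDataset = _need(results, "dataset", "simulate", "domains")
    cb = config.calling
    chip = ds.chip
    het = dm.call_heterochromatin_hmm(chip["WT"], chip["input"],
                                      min_size_bp=cb.min_het_size_bp)
    het = dm.annotate_borders(het, ds.manifest.site_catalogs["Beaf32"])
    enr = dm.call_enriched_bins(chip["WT"], chip["input"], cb.fdr)
    diff = dm.call_differential_bins(chip["WT"], chip["KD"], cb.fdr)
    micro = dm.assemble_micro_domains(
        diff, enr, het,
        tss_catalog=ds.manifest.site_catalogs["TSS"],
        type2_catalog=ds.manifest.site_catalogs["Type2"],
        max_gap_bins=cb.max_gap_bins, size_max_bp=cb.size_max_bp,
        size_min_bp=cb.size_min_bp)
    swap = dm.swap_control_fdr(chip["WT"], chip["KD"], chip["input"], het,
                               n_swaps=cb.n_swaps, seed=config.seed, fdr=cb.fdr,
                               max_gap_bins=cb.max_gap_bins,
                               size_max_bp=cb.size_max_bp, size_min_bp=cb.size_min_bp)
    mers = dm.mer_size_distribution(micro)

    bed = micro.df.copy()
    bed["name"] = [f"micro{k}" for k in range(len(bed))]
    bed["score"] = np.minimum(1000, -10 * np.log10(np.maximum(bed["q_value"], 1e-100))).astype(int)
    bed["strand"] = "."
    IntervalSet(bed).to_bed(out / "microdomains.bed", extra_cols=["name", "score", "strand"])
    lio.write_table(micro.df, out / "microdomains.tsv")
    lio.write_table(het.df, out / "het_domains.tsv")
    if len(mers["mer_counts"]):
        lio.write_table(mers["mer_counts"].rename_axis("n_mers").reset_index(name="count"),
                        out / "mer_histogram.tsv")
    results.update(het=het, enr=enr, diff=diff, micro=micro, swap=swap, mers=mers)


def _stage_spreading(config: PipelineConfig, results: dict, out: Path) -> None:
    ds: SyntheticDataset = _need(results, "dataset", "simulate", "spreading")
    het = _need(results, "het", "domains", "spreading")
    micro = _need(results, "micro", "domains", "spreading")
    diff = _need(results, "diff", "domains", "spreading")
    sb = config.spreading
    catalogs = ds.manifest.site_catalogs
    chrom_sizes = ds.manifest.spec.chrom_sizes

    borders = sp.orient_borders(het, {"Beaf32": catalogs["Beaf32"]},
                                window_bp=sb.border_window_bp, chrom_sizes=chrom_sizes)
    groups = {
        "beaf32": np.flatnonzero(borders["has_Beaf32"]),
        "no_beaf32": np.flatnonzero(~borders["has_Beaf32"]),
    }
    spread = sp.test_border_spreading(ds.chip["WT"], ds.chip["KD"], borders,
                                      groups, window=sb.euchromatin_window)
    lio.write_table(spread, out / "border_spreading.tsv")

    enrich = sp.tss_quintile_enrichment(
        ds.chip["WT"], ds.chip["KD"], catalogs["TSS"],
        {f: catalogs[f] for f in ("Beaf32", "GAF", "dCTCF", "CP190", "cohesin")},
        window_bp=sb.tss_window_bp, n_quantiles=sb.n_quantiles)
    lio.write_table(enrich.log_odds.rename_axis("quintile").reset_index(),
                    out / "tss_quintile_log_odds.tsv")
    lio.write_table(enrich.p_values.rename_axis("quintile").reset_index(),
                    out / "tss_quintile_p.tsv")

    arrange = sp.arrangement_enrichment(micro, het, chrom_sizes)
    lio.write_table(arrange, out / "arrangement_enrichment.tsv")

    gaps = het.complement(chrom_sizes)
    pct, n_excl = sp.relative_position_distribution(micro, gaps)
    lio.write_table(pd.DataFrame({"percent": pct}), out / "micro_relative_position.tsv")

    dist = sp.changed_bin_distance_distribution(diff, borders, direction="increase")
    lio.write_table(dist, out / "increase_bin_border_distance.tsv")

    expr_groups = {
        "microdomain": ds.expression.loc[ds.expression["micro_flanked"], "gene"].tolist(),
        "control": ds.expression.loc[~ds.expression["micro_flanked"], "gene"].tolist(),
    }
    expr_cmp = sp.expression_group_compare(ds.expression, expr_groups)
    results.update(borders=borders, spread=spread, enrich=enrich,
                   arrange=arrange, expr_cmp=expr_cmp)


def _stage_hic(config: PipelineConfig, results: dict, out: Path) -> None:
    ds: SyntheticDataset = _need(results, "dataset", "simulate", "hic-lri")
    hb = config.hic
    spec = ds.manifest.spec
    bs = spec.hic_bin_size
    geometry = hic.ZoneGeometry(hb.window_bins, hb.center_bins, hb.flank_bins)

    oe, masks = {}, {}
    for cond, per_chrom in ds.hic.items():
        oe[cond], masks[cond] = {}, {}
        for chrom, mat in per_chrom.items():
            oe[cond][chrom], masks[cond][chrom] = hic.balance_and_oe(
                mat, tol=hb.tol, mask_percentile=hb.mask_percentile)

    records = gene_pair_delta_records(
        ds.manifest.site_catalogs["Beaf32"], ds.manifest.site_catalogs["TSS"],
        oe["WT"], oe["KD"], bs, geometry, hb.min_sep_bp, hb.max_sep_bp)
    lio.write_table(records, out / "gene_pair_delta_lri.tsv")

    apa = {}
    for cond in ("WT", "KD"):
        mats = []
        for chrom in spec.chrom_names:
            a = hic.anchors_to_bins(ds.manifest.site_catalogs["Beaf32"], chrom, bs)
            b = hic.anchors_to_bins(ds.manifest.site_catalogs["Type2"], chrom, bs)
            try:
                agg = hic.aggregate_pairs(oe[cond][chrom], a, b, hb.window_bins,
                                          max(1, hb.min_sep_bp // bs), hb.max_sep_bp // bs)
            except ValueError:
                continue
            mats.append((agg.matrix, agg.n_pairs))
        if mats:
            total = sum(n for _, n in mats)
            apa[cond] = sum(m * n for m, n in mats) / total
            np.savetxt(out / f"apa_{cond}.tsv", apa[cond], delimiter="\t")

    eigvec, labels = {}, {}
    for chrom in spec.chrom_names:
        orientation = np.zeros(spec.n_hic_bins(chrom))
        tss = ds.manifest.site_catalogs["TSS"].for_chrom(chrom)
        np.add.at(orientation, tss["start"].to_numpy() // bs, 1.0)
        eigvec[chrom], labels[chrom] = hic.compartment_eigenvector(
            oe["WT"][chrom], orientation, masks["WT"][chrom])

    tad_scores = {}
    for chrom in spec.chrom_names:
        tb = hic.tads_to_bins(ds.manifest.tad_intervals, chrom, bs)
        tad_scores[chrom] = hic.tad_strength(oe["WT"][chrom], tb)
    lio.write_table(
        pd.DataFrame({"chrom": np.concatenate([[c] * len(v) for c, v in tad_scores.items()]),
                      "lri2": np.concatenate(list(tad_scores.values()))}),
        out / "tad_strength.tsv")
    results.update(oe=oe, masks=masks, records=records, apa=apa,
                   eigvec=eigvec, comp_labels=labels, tad_scores=tad_scores)


def _stage_gsea(config: PipelineConfig, results: dict, out: Path) -> None:
    ds: SyntheticDataset = _need(results, "dataset", "simulate", "gsea")
    records = _need(results, "records", "hic-lri", "gsea")
    micro = _need(results, "micro", "domains", "gsea")
    gb = config.gsea
    gene_set = microdomain_gene_set(micro, ds.manifest.site_catalogs["TSS"])
    rows = []
    gsea_results = {}
    for metric in gb.metrics:
        ranked = gs.rank_loci(records, metric, gb.aggregation,
                              min_sep=config.hic.min_sep_bp)
        res = gs.gsea_permutation_p(ranked, gene_set, n_perm=gb.n_perm,
                                    seed=config.seed, weight_exponent=gb.weight_exponent)
        gsea_results[metric] = res
        rows.append((metric, res.es, res.nes, res.p_value, res.fisher_p,
                     len(res.leading_edge), res.n_permutations))
    lio.write_table(pd.DataFrame(rows, columns=[
        "metric", "es", "nes", "p_permutation", "p_fisher_leading_edge",
        "n_leading_edge", "n_permutations"]), out / "gsea.tsv")
    results["gsea"] = gsea_results


_STAGES = {
    "simulate": _stage_simulate,
    "domains": _stage_domains,
    "spreading": _stage_spreading,
    "hic-lri": _stage_hic,
    "gsea": _stage_gsea,
}


def microdomain_gene_set(micro: IntervalSet, tss_catalog: IntervalSet,
                         flank_bp: int = 1000) -> list[str]:
    """Genes whose TSS lies within `flank_bp` of a called micro-domain."""
    genes = []
    for row in tss_catalog.df.itertuples(index=False):
        d = micro.nearest_distance(row.chrom, np.array([row.start]))[0]
        if d < flank_bp:
            genes.append(row.gene)
    return genes


# ---------------------------------------------------------------------------
# input validation (report-only)
# ---------------------------------------------------------------------------

def validate_inputs(directory: str | Path) -> list[str]:
    """Check a dataset tree for structural violations; returns messages.

    Checks BED sortedness and chromosome bounds, bedGraph grid alignment,
    Hi-C triplet index bounds and upper-triangle form, against chrom.sizes.
    """
    d = Path(directory)
    violations: list[str] = []
    sizes_path = d / "chrom.sizes"
    if not sizes_path.exists():
        return [f"{sizes_path}: missing chrom.sizes"]
    sizes = lio.read_chrom_sizes(sizes_path)

    for bed in sorted(d.glob("sites/*.bed")):
        last: dict[str, int] = {}
        for ln, line in enumerate(bed.read_text().splitlines(), 1):
            if not line.strip():
                continue
            parts = line.split("\t")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if chrom not in sizes:
                violations.append(f"{bed.name}:{ln}: unknown chromosome {chrom}")
                continue
            if start < 0 or end > sizes[chrom]:
                violations.append(f"{bed.name}:{ln}: record {chrom}:{start}-{end} outside chromosome")
            if end <= start:
                violations.append(f"{bed.name}:{ln}: empty interval")
            if last.get(chrom, -1) > start:
                violations.append(f"{bed.name}:{ln}: not sorted by start within {chrom}")
            last[chrom] = start

    for bg in sorted(d.glob("tracks/*.bedGraph")):
        seen_bin = None
        for ln, line in enumerate(bg.read_text().splitlines(), 1):
            parts = line.split("\t")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            width = end - start
            if seen_bin is None:
                seen_bin = width
            if chrom in sizes and end > sizes[chrom] + seen_bin:
                violations.append(f"{bg.name}:{ln}: bin beyond chromosome end")
            if start % seen_bin:
                violations.append(f"{bg.name}:{ln}: bin not aligned to {seen_bin} bp grid")

    for trip in sorted(d.glob("hic/*.triplets.tsv")):
        chrom = trip.name.split(".")[1]
        if chrom not in sizes:
            violations.append(f"{trip.name}: unknown chromosome {chrom}")
            continue
        df = pd.read_csv(trip, sep="\t")
        n_bins = None
        man = d / "manifest.yaml"
        if man.exists():
            doc = yaml.safe_load(man.read_text())
            n_bins = sizes[chrom] // doc["spec"]["hic_bin_size"]
        if n_bins is not None and len(df) and (df["bin_i"].max() >= n_bins or df["bin_j"].max() >= n_bins):
            violations.append(f"{trip.name}: triplet index >= n_bins ({n_bins})")
        bad = df[df["bin_i"] > df["bin_j"]]
        if len(bad):
            r = bad.iloc[0]
            violations.append(f"{trip.name}: not upper-triangle at ({int(r.bin_i)},{int(r.bin_j)})")
        dup = df.duplicated(subset=["bin_i", "bin_j"])
        if dup.any():
            k = int(np.flatnonzero(dup)[0])
            violations.append(f"{trip.name}: duplicate pixel at row {k}")
    return violations
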