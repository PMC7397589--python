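# loopspread

Analysis toolkit for studying how insulator-anchored chromatin loops shape
small euchromatic H3K27me3 domains ("micro-domains") in a fly-like genome.

Repressive H3K27me3 heterochromatin domains are often flanked by insulator
protein binding sites (Beaf32 at the borders; GAF/dCTCF — "Type-2"
insulators — out in euchromatin, frequently co-bound by CP190). Two
phenomena tie them together:

* **local spreading** — on insulator depletion (Beaf-KD), H3K27me3 encroaches
  from the heterochromatin domain across its border into the first kilobases
  of euchromatin, specifically at Beaf32-flanked borders;
* **3D spreading** — distant euchromatic loci that loop back to a Beaf32
  border acquire small H3K27me3 micro-domains (< 2 kb, 2–8 nucleosome
  "mers" of ~200 bp), which lose signal when the loops are broken.

`loopspread` implements the full computational chain for both: differential
binned ChIP-seq calling of micro-domains, border-spreading statistics, Hi-C
matrix engineering with three long-range-interaction (LRI) zone scores, and
a GSEA test of which ΔLRI metric predicts micro-domain formation. A seeded
synthetic-data module generates genomes with planted domains, loops and
perturbations so that every stage is testable offline against ground truth.

## The model in brief

**Micro-domain calling.** ChIP reads are binned at 40 bp. Conditional on the
per-bin total n\_i = t\_i + c\_i of treatment and control, the treatment
count follows a two-component binomial mixture
t\_i | n\_i ~ w·Bin(n\_i, θ\_bg) + (1−w)·Bin(n\_i, θ\_enr), fitted by EM.
Per-bin p-values are upper-tail Bin(n\_i, θ\_bg) probabilities,
BH-corrected (FDR < 0.05). Bins enriched over input in WT **and**
significantly decreased in the depleted condition, outside HMM-called
heterochromatin, are merged into micro-domains (< 2 kb); sizes are reported
in nucleosome mers (round(size/200 bp)). A label-swap control on
count-split pseudo-replicates estimates the empirical FDR.

**Hi-C LRI scores.** Contact matrices are Knight–Ruiz balanced and
normalized by distance-expected contact (O/E). For an anchor pair (a, b):

* LRI-3 = log2(center block mean / four-corner background mean) of the APA
  submatrix — focal loop strength;
* LRI-2 = log2(mean O/E strictly between the anchors) — TAD/domain contact
  density;
* LRI-1 = log2(mean O/E of the outer flank block) — compartment-level
  contact.

ΔLRI = score(KD) − score(WT), computed on O/E so depth cancels. Genes are
ranked by their aggregated ΔLRI over (Beaf32 site, gene) pairs > 5 kb apart,
and a weighted Kolmogorov–Smirnov GSEA with set-membership permutations
tests whether micro-domain genes concentrate at the loop-loss end of the
ranking.

## Worked example

```bash
loopspread run --config configs/demo.yaml --seed 1 --outdir demo_out
```

simulates a 2 × 2 Mb genome (24 heterochromatin domains, 50 planted
micro-domains looped to Beaf32 borders, Hi-C with loop strength 4 halved in
KD) and runs every stage. The log ends with:

```
... INFO called 50 micro-domains
... INFO GSEA delta_lri1: ES=-0.260 p=0.6084
... INFO GSEA delta_lri2: ES=0.309 p=0.6274
... INFO GSEA delta_lri3: ES=-0.938 p=0.000999
```

Reading: all 50 planted micro-domains were recovered
(`demo_out/microdomains.tsv`, with per-domain q-values, mer counts and
distances); `demo_out/border_spreading.tsv` shows the paired WT-vs-KD
Wilcoxon test significant only at Beaf32-flanked borders; and the GSEA table
(`demo_out/gsea.tsv`) shows that only the focal-loop metric ΔLRI-3 predicts
which genes carry a micro-domain (permutation p ≈ 1e-3, the floor at 1000
permutations), while compartment (ΔLRI-1) and TAD-strength (ΔLRI-2)
rankings do not — the looping-not-insulation contrast at the heart of the
analysis.

Other entry points: `loopspread simulate`, `loopspread call-domains` (on
bedGraph files), `loopspread gsea`, `loopspread validate`.

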