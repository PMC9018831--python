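# microcast

Impute nucleosome-resolution (200-bp) chromatin contact maps from epigenomic
signal tracks and a lower-resolution Hi-C contact map, with gradient-based
attribution, 1-kb loop/stripe calling, and a quantitative evaluation suite.

## The problem

Micro-C resolves chromatin contacts at nucleosome resolution and reveals
fine-scale structures — short-range loops, architectural stripes, polycomb
interactions — that conventional Hi-C misses. Micro-C data exist for only a
handful of cell types, while epigenomic tracks (ATAC-seq/DNase-seq, CTCF,
histone modifications) and at least shallow Hi-C are available for hundreds.
`microcast` is for researchers who want Micro-C-like contact maps, and the
regulatory interactions visible in them, for cell types where only those
cheaper assays exist.

## The model

The imputation network learns a mapping F: ℝ^(m×n) → ℝ^(n×n) from m
epigenomic signals over n 200-bp bins to the contact map between those bins.
A 250-kb window slides along the diagonal with a 50-kb step; within each
window the coarse Hi-C map is O/E-normalized (each contact divided by its
distance-stratum mean), bilinearly interpolated to 200 bp, and used as the
weighted adjacency of a graph 𝒢 whose nodes are bins and whose node
attributes are the epigenomic signals plus a sinusoidal positional encoding.

Two trunks extract per-bin hidden vectors: 1D convolutions capture local
patterns along the chromatin fiber, and graph convolutions
σ(D̃^(−1/2)ÃD̃^(−1/2)HW) capture patterns over the spatial neighborhood
defined by 𝒢. Their concatenation feeds two output heads whose sum is the
prediction:

* a fully connected **profile head** predicting each bin's contact profile
  out to the 200-kb band (symmetrized by averaging i→j and j→i);
* an inner-product **loop head** ReLU(EEᵀ) over per-bin embeddings E,
  capturing focal pairwise contacts.

Training is sequential, by MSE with Adam against log1p Micro-C counts:
first the loop head on 10 kb × 10 kb squares centered at known Micro-C
loops, then the profile head on the residual map (target minus the frozen
loop component). Per-window predictions are stitched into a chromosome-scale
band matrix by averaging overlaps.

Around the model, the package provides:

* **attribution** — integrated gradients A(X_i^(s_t)) = ∫₀¹ ∂y/∂γ · ∂γ/∂α dα
  along a straight-line path from an all-zeros epigenomic background,
  for the full map or any output region (a loop, a stripe);
* **structures** — donut-background Poisson loop calling and flank-median
  stripe calling at 1 kb, pile-up aggregation, and Venn-style matching of
  call sets;
* **evaluation** — stratum-adjusted correlation coefficient (SCC),
  distance-stratified Pearson, 250-kb fragment Spearman with
  conservation/compartment/replication-timing stratification, eigenvector
  A/B compartment calling, one-sided Welch tests, and eQTL–TSS pile-ups;
* **synthetic** — a seeded generator of ground-truth maps with planted
  loops/stripes/compartments, matched tracks, and degraded Hi-C, used as
  the test substrate throughout.

## Worked example

Train on a seeded synthetic benchmark (20 planted loops, 10 stripes over
~1 Mb at 200-bp bins) and impute the region from the degraded Hi-C:

```python
import microcast as mc

res = mc.run_end_to_end(seed=1, n_windows=100)
print(res.fit.summary())
m = res.metrics
print(f"SCC vs truth:        imputed {m['scc_imputed']:.3f} | "
      f"interpolated Hi-C {m['scc_input_hic']:.3f}")
print(f"planted loops found: imputed {m['loop_recall_imputed_pct']:.0f}% | "
      f"input Hi-C {m['loop_recall_input_hic_pct']:.0f}%")
```

prints

```
Micro-C imputation model fit
============================================================
features:        ATAC-seq, CTCF, H3K4me1, H3K4me3, H3K27ac, H3K27me3
window/step/band: 50,000 / 10,000 / 40,000 bp
hidden dim:      128 (conv (32, 64), gcn (64, 64))
loop embedding:  64
phases trained:  loop -> profile
initial band MSE: 1.307710
final band MSE:   0.234103
MSE reduction:    82.1%
------------------------------------------------------------
loop     phase: 10 epochs, MSE 0.551567 -> 0.335987
profile  phase: 25 epochs, MSE 0.944307 -> 0.235068

SCC vs truth:        imputed 0.940 | interpolated Hi-C 0.777
planted loops found: imputed 100% | input Hi-C 0%
```

Reading the numbers: two-phase training cuts the band-masked MSE against
log1p Micro-C counts by 82%; the imputed map correlates with the held-out
truth far better than the interpolated input Hi-C does (SCC 0.94 vs 0.78);
and the 1-kb loop caller recovers every planted loop from the imputed map
while recovering none from the degraded Hi-C input — the qualitative
signature of resolution enhancement.

The same pipeline is scriptable from the shell:

```sh
microcast simulate --seed 7 --n-windows 100 --out fixtures/
microcast call-loops --map fixtures/truth.microc.h5 --chrom chrS \
    --resolution 200 --max-distance 40000 --out loops.bedpe
microcast evaluate --pred imputed.h5 --obs fixtures/truth.microc.h5 \
    --chrom chrS --resolution 200 --report report.json
```

plus `train`, `impute`, `attribute`, `call-stripes`, `pileup`,
`compartments`, and `eqtl-pileup` subcommands.

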