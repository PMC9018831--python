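# Methods

## Model

The imputation network maps m epigenomic signals binned at 200 bp (plus an
8-dim sinusoidal positional encoding) to the contact map of a 250-kb window,
restricted to a 200-kb band around the diagonal — contacts beyond that range
carry almost no epigenomic signal and are excluded from both the loss and
the output. The input Hi-C map enters twice: as the graph adjacency (after
O/E normalization and bilinear interpolation to 200 bp, with identity
self-loops added), and implicitly as the baseline the imputation is judged
against.

Per-bin hidden vectors are the concatenation of a 1D-convolutional trunk
(kernels 11 and 5 bins, 32→64 channels, ReLU) and a graph-convolutional
trunk (two 64-unit layers of σ(D̃^(−1/2)ÃD̃^(−1/2)HW)). Both trunks see the
full node-feature matrix including the positional rows. The heads:

* profile head — affine map from the 128-dim hidden vector of bin i to its
  contact profile over bins i−w…i+w (w = band/200). The assembled matrix is
  symmetrized by averaging the i→j and j→i predictions.
* loop head — affine map to a 64-dim embedding E; the loop component is
  ReLU(EEᵀ), guaranteeing nonnegative focal contributions.

The output is the band-masked sum of the two components; the target is
log1p of raw Micro-C counts (variance stabilization standard for count
matrices; predictions are expm1-inverted before O/E normalization or
structure calling).

Assumptions worth stating: contacts are strandless; the epigenome→structure
mapping is local (nothing outside the window informs it); one model serves
a whole genome (no per-chromosome parameters); the 200-kb band covers the
structures of interest.

### Sequential training

Phase 1 fits the loop head (and, by default, the shared trunk) by MSE
restricted to 10 kb × 10 kb squares centered at known loop anchor pairs.
Phase 2 fits the profile head against the residual map — the target minus
the loop component evaluated once with the phase-1-final parameters — with
the loop head frozen.

Two stability choices here are deliberate package design. First, the
residual targets are computed once at phase-2 entry rather than re-derived
each step: the loop component is quadratic in the hidden vectors, and
chasing a moving residual lets errors feed back multiplicatively. Second,
the shared trunk is frozen in phase 2 by default
(`train_trunk_in_profile_phase=False`): fine-tuning a trunk that the frozen
loop head still depends on silently invalidates the phase-1 fit — in
experiments the summed output's band MSE diverged by many orders of
magnitude — whereas freezing keeps the two components consistent at
inference. The flag restores trunk fine-tuning for users who train the loop
head last or retrain it afterwards. Adam runs at lr 1e-3, β=(0.9, 0.999),
with global-norm gradient clipping at 5.0; without clipping the profile
phase can diverge in its first epochs at this learning rate.

### Parameters that matter

| parameter | default | unit | note |
|---|---|---|---|
| window / step | 250,000 / 50,000 | bp | sliding-window geometry along the diagonal |
| band | 200,000 | bp | prediction range; also the loss mask |
| resolution | 200 | bp | nucleosome-scale bin size |
| encoding_dim | 8 | — | sinusoidal positional rows; data-independent |
| conv kernels | 11, 5 | bins | 2.2 kb / 1 kb local context |
| gcn_units | 64, 64 | — | spatial-neighborhood features |
| embed_dim | 64 | — | loop-head embedding |
| lr / grad_clip | 1e-3 / 5.0 | — | Adam step and global-norm clip |
| loop square | 10,000 | bp | phase-1 target mask per loop |

## Attribution

Integrated gradients along the straight-line path from an all-zeros
epigenomic background, midpoint Riemann rule, default 300 steps. Only the
epigenomic rows vary along the path; positional-encoding rows are held at
their true values and are excluded from the attribution matrix (they are
not epigenomic inputs). The target scalar of a region is the sum of
predicted values over its upper-triangle pixels, so disjoint regions have
additive attributions and the diagonal is not double-counted. The relative
completeness gap |ΣA − (y(X) − y(X₀))| / |y(X) − y(X₀)| is exposed on every
result as a self-diagnostic; at 300 steps it is ~1e-3 on the models tested
here, and exactly 0 for a linear network, where the midpoint rule is exact.

## Structure calling

Both callers operate at 1 kb. 200-bp maps are pooled 5×5 — block sums for
raw counts; log1p maps are pooled on the count scale (expm1 → sum → log1p)
so pooled pseudo-counts remain commensurate with pooled raw counts; O/E
maps are block-averaged.

Loops: a pixel is a candidate when its count is ≥2 and its O/E exceeds each
of six local background estimates by ≥1.75-fold — a donut (Chebyshev radius
5, 2-pixel core, row/column cross excluded), the lower-left quadrant, and
one-sided row and column segments (left/right of the pixel, above/below).
The row/column backgrounds are one-sided on purpose: a two-sided mean
dilutes a stripe with off-stripe cells, and stripe-body and stripe-end
pixels then masquerade as loops; compared one-sidedly, an on-stripe pixel
is measured against the stripe itself on at least one side and is
suppressed. Each candidate's Poisson upper tail against every
background-derived expectation is Benjamini–Hochberg controlled at FDR 0.1;
surviving pixels within Chebyshev distance 2 are clustered (union-find) and
the cluster's maximal pixel is reported, ties broken by genomic order. The
caller needs count-scale input (raw or log1p); a pure O/E map cannot feed
the Poisson test.

Stripes: for each anchor, contiguous runs (≥10 px) of offsets whose O/E is
≥2× the median of the flanking anchors (±3) at the same offsets, scanned in
both orientations (vertical = anchor at the smaller coordinate extending
right); overlapping runs from adjacent anchors are merged keeping the best
score.

Matching between call sets is greedy one-to-one (anchor midpoints within
5 kb; stripes also match on orientation), ties broken by smallest distance
then genomic order, so Venn counts are deterministic. Pile-ups drop
edge-clipped regions rather than zero-padding (padding biases the mean);
enrichment judgments (center 5×5 vs surroundings) should be made on O/E
maps, since on raw counts the near-diagonal side of any square window
dominates through distance decay.

## Evaluation statistics

* SCC: both maps smoothed with a (2h+1)² mean filter (h=5), per-stratum
  Pearson r_k, combined with weights N_k·√(var_a·var_b); strata with zero
  variance are skipped. Defaults (h=5, 200-kb range) follow the common
  reproducibility-analysis convention for contact maps.
* Fragment scores: mutually exclusive 250-kb fragments, 5×5 uniform
  smoothing, Spearman over band pixels; constant fragments are flagged
  undefined and excluded. Conservation tiers are top 10% / top 10–50% /
  rest by rank; replication timing is early iff the repli-seq value is
  strictly positive (0 counts as late; configurable).
* Compartments: leading eigenvector of (O/E − 1). The subtraction matters:
  a strictly positive O/E matrix has an all-positive Perron eigenvector, so
  the sign of the raw leading eigenvector can never split bins. Bins split
  by eigenvector sign; the group with higher mean H3K27ac is labeled A,
  making the labels invariant to the eigenvector's arbitrary sign. A
  correlation-matrix variant is available. Constant matrices and
  non-splitting eigenvectors raise errors rather than guessing.
* Group tests: one-sided Welch (unequal-variance) t, directions A>B,
  early>late, more-conserved > less.
* eQTL filter: variant and TSS binned at 200 bp; pairs ≥180 kb apart are
  dropped (the 200-kb prediction range minus a 20-kb window margin), as are
  bin pairs reported in more than one tissue; malformed rows are rejected
  with their row numbers logged.

## Synthetic data

The generator emulates the statistical structure of the inputs, not their
biology. The expected intensity of the truth map is
(1+d)^(−α) · c_i · c_j · (1 + fold_ij): power-law distance decay (α=1),
alternating 100-kb compartment blocks (multiplier 1±0.3), and planted
structures expressed as multiplicative folds over the local base — Gaussian
loop foci (8×, σ=3 fine bins) and stripe ridges (4×, 25–30-kb extent) with
anchors snapped to the 1-kb calling grid. Multiplicative planting is what
makes "amplitude" mean fold-over-local-background at calling resolution by
construction, independent of decay or compartment. Counts are Poisson at a
stated depth (default 5e6 for the ~1-Mb benchmark region).

The Hi-C surrogate shares the base intensity but sees planted structures at
only 0.25× their amplitude, carries 1% of the depth, and is pooled to 1-kb
bins. The attenuation models the protocol-visibility gap: real Hi-C fails
to *detect* these fine structures even when deeply sequenced, so a
depth-only degradation would leave the surrogate too informative about the
planted loops. `degrade_to_hic` (pure thinning + pooling) remains available
as the generic degradation operation.

Tracks: gamma background plus Gaussian peaks — ATAC-seq/CTCF at every
anchor, H3K4me1 flanking anchors (±1 kb), H3K4me3 at stripe anchors,
H3K27ac at loop anchors and elevated across A blocks, H3K27me3 elevated
across B blocks — normalized by their genome-wide mean. The coupling
between tracks and structures is deliberately strong so a small model can
learn the mapping; consequently, passing the end-to-end tests demonstrates
that the pipeline's machinery (windowing, graph construction, two-phase
optimization, stitching, calling, scoring) works, not that real epigenomes
determine real Micro-C maps with this fidelity. The generator also omits:
read-level artifacts and mappability bias, unbalanced (un-ICEd) matrix
structure, TADs as such, biologically realistic conservation or
replication-timing fields (those labels are arbitrary block assignments),
and any cell-type specificity.

### Desk-scale study conditions

The bundled benchmark runs at reduced geometry so the full experiment fits
interactive use: ~1.04-Mb region, 50-kb windows, 10-kb step, 40-kb band
(n=250 bins per window), 100 windows split into thirds
(train/tune/test), 10 loop-phase + 25 profile-phase epochs — about half a
minute end to end on one CPU. Library defaults for real data keep the full
250-kb/50-kb/200-kb geometry; nothing in the code depends on the reduced
sizes.

## Numerical choices

* Bilinear interpolation on bin centers for coarse→fine maps, clamped at 0,
  constant extrapolation outside the hull of coarse centers; coarse-center
  values are preserved exactly. Nearest-neighbor is not provided — bilinear
  is smooth and exact at centers, which the graph construction relies on.
* O/E stratum means are computed per chromosome over the map's extent,
  counting absent entries as zeros (stratum size n−d).
* Contact matrices store the upper triangle and mirror on access; a full
  symmetric input is folded without double-counting (upper triangle
  preferred; entries present only in the lower triangle are mirrored up);
  the diagonal counts once in totals.
* Window stitching averages overlapping predictions (median available);
  a truncated terminal window is right-aligned at the chromosome end so
  coverage is complete.
* Spearman ties use average ranks (scipy convention).
* Seeds are mandatory for every stochastic operation; numpy Generator
  streams are derived per component so runs are bitwise reproducible.

## Limitations

* The network and its training loop are implemented directly in
  numpy/scipy with hand-written backpropagation; this keeps the model and
  its input-gradients in one self-contained, dependency-light stack, but it
  is CPU-bound and sized for the desk-scale geometry, not for genome-wide
  training runs.
* The inner-product loop head scores any pair of anchor-like bins within
  the band, so anchors of *different* planted loops can receive spurious
  focal predictions (visible as extra calls near true anchors). Recall is
  unaffected; precision on the imputed map is the price of the
  inner-product decoder.
* The loop caller's significance model is Poisson on (pseudo-)counts; for
  deterministic imputed maps this is a heuristic, calibrated only in the
  sense that the FDR control behaves sensibly on the benchmarks.
* Cross-assembly coordinate mapping, ICE/KR balancing, and .hic (Juicer)
  binary I/O are out of scope.
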