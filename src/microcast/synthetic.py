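"""Seeded generator of ground-truth contact maps, tracks, and degraded Hi-C.

The generator emulates the statistical structure of the real inputs at desk
scale: a 200-bp "Micro-C" truth map with power-law distance decay,
compartment blocks, planted Gaussian loop foci and stripe ridges, Poisson
count noise; a degraded "Hi-C" surrogate obtained by binomial thinning and
1-kb pooling; and six epigenomic tracks whose peaks co-locate with the
planted anchors (accessibility/CTCF at anchors, H3K4me1 flanking them,
H3K27me3 over repressive blocks).

The track/structure coupling is deliberately strong so the epigenome ->
structure mapping is learnable by a small model: this is a test harness, not
a biological simulator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .core_data import BinTrack, ContactMap, StructureCall, normalize_track
from .preprocess import band_mask, build_graph, extract_windows, interpolate_contacts, oe_normalize
from .preprocess import WindowSample, downsample_contacts

__all__ = [
    "SyntheticSpec",
    "SyntheticDataset",
    "FEATURES_6EPI",
    "generate_truth",
    "generate_hic",
    "degrade_to_hic",
    "generate_tracks",
    "compartment_labels",
    "truth_structure_calls",
    "make_dataset",
]

FEATURES_6EPI = ("ATAC-seq", "CTCF", "H3K4me1", "H3K4me3", "H3K27ac", "H3K27me3")


@dataclass
class SyntheticSpec:
    """Ground-truth description of one synthetic region.

    Loops are (anchor1_bp, anchor2_bp, amplitude, sigma_bins): a 2D Gaussian
    focus of the given fold amplitude over the local decay background.
    Stripes are (anchor_bp, orientation, extent_bp, amplitude).
    """

    seed: int
    region_length_bp: int = 1_040_000
    resolution: int = 200
    decay_alpha: float = 1.0
    loops: list[tuple] = field(default_factory=list)
    stripes: list[tuple] = field(default_factory=list)
    compartment_block_bp: int = 100_000
    compartment_strength: float = 0.3
    micro_depth: float = 5e6
    hic_depth_fraction: float = 0.01
    hic_resolution: int = 1000
    # Hi-C sees fine structures only faintly: planted amplitudes are scaled
    # by this factor in the Hi-C intensity (the protocol-visibility gap)
    hic_structure_attenuation: float = 0.25
    max_distance_bp: int = 50_000
    track_peak_amp: float = 5.0
    track_peak_sigma_bins: float = 2.0
    track_background: float = 0.2
    chrom: str = "chrS"

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for a1, a2, amp, sig in self.loops:
            if amp <= 0 or sig <= 0:
                raise ValueError("loop amplitude and width must be positive")
            if not (0 <= a1 < a2 < self.region_length_bp):
                raise ValueError("loop anchors must be ordered and within the region")
        for a, orient, ext, amp in self.stripes:
            if amp <= 0 or ext <= 0:
                raise ValueError("stripe amplitude and extent must be positive")
            if orient not in ("vertical", "horizontal"):
                raise ValueError(f"unknown stripe orientation {orient!r}")
            if not (0 <= a < self.region_length_bp):
                raise ValueError("stripe anchor must be within the region")

    @property
    def n_bins(self) -> int:
        return self.region_length_bp // self.resolution

    @classmethod
    def benchmark(
        cls,
        seed: int,
        n_loops: int = 20,
        n_stripes: int = 10,
        region_length_bp: int = 1_040_000,
        loop_amplitude: float = 8.0,
        stripe_amplitude: float = 4.0,
        **kwargs,
    ) -> "SyntheticSpec":
        """Standard planted-structure benchmark: structures laid out in
        disjoint slots so every planted anchor is unambiguous to a caller."""
        rng = np.random.default_rng(seed)
        n_slots = n_loops + n_stripes
        slot = (region_length_bp // n_slots) // 1000 * 1000
        kinds = np.array(["loop"] * n_loops + ["stripe"] * n_stripes)
        rng.shuffle(kinds)
        loops, stripes = [], []
        for k, kind in enumerate(kinds):
            start = k * slot
            if kind == "loop":
                # anchors snapped to the 1-kb calling grid so planted truth
                # is unambiguous at calling resolution
                a1 = start + 2_000 + 1_000 * int(rng.integers(0, 2))
                dist = 1_000 * int(rng.integers(12, min(28, (slot - 6_000) // 1_000)))
                loops.append((a1, a1 + dist, loop_amplitude, 3.0))
            else:
                extent = 1_000 * int(rng.integers(25, 31))
                if rng.random() < 0.5:
                    anchor = start + 2_000
                    stripes.append((anchor, "vertical", extent, stripe_amplitude))
                else:
                    anchor = start + 2_000 + extent
                    stripes.append((anchor, "horizontal", extent, stripe_amplitude))
        return cls(
            seed=seed,
            region_length_bp=region_length_bp,
            loops=loops,
            stripes=stripes,
            **kwargs,
        )


def compartment_labels(spec: SyntheticSpec, resolution: int | None = None) -> np.ndarray:
    """'A'/'B' per bin, alternating blocks starting with A."""
    res = resolution or spec.resolution
    n = spec.region_length_bp // res
    block = spec.compartment_block_bp // res
    return np.where((np.arange(n) // block) % 2 == 0, "A", "B")


# ---------------------------------------------------------------------------
# truth map
# ---------------------------------------------------------------------------


def _expected_band(spec: SyntheticSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """Expected-intensity decomposition for pixels (i, i+d), d = 0..W.

    Returns (base, fold, inside, W): base is decay x compartment intensity,
    fold the planted-structure fold-enrichment field, inside the validity
    mask; the full intensity is base * (1 + fold)."""
    nb = spec.n_bins
    W = spec.max_distance_bp // spec.resolution
    d = np.arange(W + 1, dtype=float)
    decay = (1.0 + d) ** (-spec.decay_alpha)
    comp = np.where(compartment_labels(spec) == "A",
                    1.0 + spec.compartment_strength,
                    1.0 - spec.compartment_strength)
    i = np.arange(nb)
    # intensity = decay(d) * comp[i] * comp[j], j = i + d; out-of-range zeroed
    J = i[:, None] + np.arange(W + 1)[None, :]
    inside = J < nb
    B = decay[None, :] * comp[:, None] * np.where(inside, comp[np.minimum(J, nb - 1)], 0.0)

    # planted structures are multiplicative folds over the local base
    # intensity, so their enrichment over the local background is the stated
    # amplitude by construction, independent of decay or compartment
    fold = np.zeros_like(B)
    res = spec.resolution
    width = 1000 // res  # fine bins per 1-kb calling pixel

    for a1, a2, amp, sig in spec.loops:
        p = a1 // res + width // 2
        q = a2 // res + width // 2
        rad = int(np.ceil(4 * sig))
        ii = np.arange(max(0, p - rad), min(nb, p + rad + 1))
        jj = np.arange(max(0, q - rad), min(nb, q + rad + 1))
        gi = np.exp(-((ii - p) ** 2) / (2 * sig**2))
        gj = np.exp(-((jj - q) ** 2) / (2 * sig**2))
        bump = amp * np.outer(gi, gj)
        for xi, row in zip(ii, bump):
            dd = jj - xi
            ok = (dd >= 0) & (dd <= W)
            fold[xi, dd[ok]] += row[ok]

    for a, orient, ext, amp in spec.stripes:
        ab = a // res
        eb = ext // res
        ts = np.arange(width, min(eb, W) + 1)
        for widx in range(width):
            if orient == "vertical":
                row = ab + widx
                if 0 <= row < nb:
                    ok = (row + ts) < nb
                    fold[row, ts[ok]] += amp
            else:
                rows = ab - ts
                col = ab + widx
                ok = (rows >= 0) & (col - rows >= 0) & (col - rows <= W) & (col < nb)
                fold[rows[ok], (col - rows)[ok]] += amp

    return B, fold, inside, W


def _band_to_map(B: np.ndarray, spec: SyntheticSpec) -> ContactMap:
    nb = spec.n_bins
    rows, offs = np.nonzero(B)
    mat = sp.coo_matrix((B[rows, offs], (rows, rows + offs)), shape=(nb, nb))
    return ContactMap(spec.chrom, spec.resolution, mat, state="raw", n_bins=nb)


def generate_truth(spec: SyntheticSpec, expectation: bool = False) -> ContactMap:
    """Ground-truth 200-bp contact map: expected intensity scaled to the
    stated depth, then Poisson-sampled (unless ``expectation``)."""
    base, fold, inside, W = _expected_band(spec)
    B = base * (1.0 + fold)
    B[~inside] = 0.0
    B *= spec.micro_depth / B.sum()
    if not expectation:
        rng = np.random.default_rng(spec.seed)
        B = rng.poisson(B).astype(float)
    return _band_to_map(B, spec)


def generate_hic(spec: SyntheticSpec, seed: int | None = None) -> ContactMap:
    """The low-information Hi-C input the imputation starts from.

    Same decay/compartment base as the truth, but planted structures appear
    only at ``hic_structure_attenuation`` of their amplitude, the depth is
    ``hic_depth_fraction`` of the Micro-C depth, and counts are pooled to
    ``hic_resolution`` bins.
    """
    base, fold, inside, W = _expected_band(spec)
    B = base * (1.0 + spec.hic_structure_attenuation * fold)
    B[~inside] = 0.0
    B *= spec.micro_depth * spec.hic_depth_fraction / B.sum()
    rng = np.random.default_rng(spec.seed + 7 if seed is None else seed)
    fine = _band_to_map(rng.poisson(B).astype(float), spec)
    return degrade_to_hic(fine, 1.0, spec.hic_resolution, rng)


def degrade_to_hic(
    truth: ContactMap,
    depth_fraction: float,
    coarse_resolution: int = 1000,
    seed: int | np.random.Generator = 0,
) -> ContactMap:
    """Binomial thinning to a fraction of the depth, then block-sum pooling."""
    if not (0 < depth_fraction <= 1):
        raise ValueError("depth_fraction must be in (0, 1]")
    if coarse_resolution % truth.resolution != 0:
        raise ValueError("coarse resolution must be a multiple of the fine one")
    thinned = (
        truth
        if depth_fraction == 1.0
        else downsample_contacts(truth, depth_fraction * truth.total_contacts, seed)
    )
    f = coarse_resolution // truth.resolution
    nc = -(-truth.n_bins // f)
    coo = thinned.upper_coo()
    mat = sp.coo_matrix((coo.data, (coo.row // f, coo.col // f)), shape=(nc, nc))
    mat.sum_duplicates()
    return ContactMap(
        truth.chrom, coarse_resolution, mat, state="raw",
        offset_bin=truth.offset_bin // f, n_bins=nc,
    )


# ---------------------------------------------------------------------------
# tracks
# ---------------------------------------------------------------------------


def _add_peaks(values: np.ndarray, centers_bp, spec: SyntheticSpec, amp=None, shift_bins=0):
    amp = amp if amp is not None else spec.track_peak_amp
    sig = spec.track_peak_sigma_bins
    n = len(values)
    x = np.arange(n)
    for c_bp in centers_bp:
        c = c_bp // spec.resolution + shift_bins
        lo, hi = max(0, int(c - 5 * sig)), min(n, int(c + 5 * sig) + 1)
        values[lo:hi] += amp * np.exp(-((x[lo:hi] - c) ** 2) / (2 * sig**2))


def generate_tracks(spec: SyntheticSpec, features=FEATURES_6EPI) -> dict[str, BinTrack]:
    """The 6-epi feature set with peaks co-located with planted structures."""
    unknown = set(features) - set(FEATURES_6EPI)
    if unknown:
        raise ValueError(f"unknown features: {sorted(unknown)}")
    rng = np.random.default_rng(spec.seed + 101)
    n = spec.n_bins
    comp = compartment_labels(spec)
    loop_anchors = [a for l in spec.loops for a in (l[0], l[1])]
    stripe_anchors = [s[0] for s in spec.stripes]
    all_anchors = loop_anchors + stripe_anchors

    def background():
        return rng.gamma(2.0, spec.track_background / 2.0, size=n)

    tracks: dict[str, BinTrack] = {}
    for name in features:
        v = background()
        if name == "ATAC-seq":
            _add_peaks(v, all_anchors, spec)
        elif name == "CTCF":
            _add_peaks(v, all_anchors, spec, amp=spec.track_peak_amp * 1.2)
        elif name == "H3K4me1":
            _add_peaks(v, all_anchors, spec, amp=spec.track_peak_amp * 0.5, shift_bins=-5)
            _add_peaks(v, all_anchors, spec, amp=spec.track_peak_amp * 0.5, shift_bins=5)
        elif name == "H3K4me3":
            _add_peaks(v, stripe_anchors, spec)
        elif name == "H3K27ac":
            _add_peaks(v, loop_anchors, spec, amp=spec.track_peak_amp * 0.8)
            v[comp == "A"] += spec.track_background * 2.0
        elif name == "H3K27me3":
            v[comp == "B"] += 1.0
        track = BinTrack(spec.chrom, 0, spec.resolution, v, feature=name)
        tracks[name] = normalize_track(track, float(track.values.mean()))
    return tracks


# ---------------------------------------------------------------------------
# ground-truth structure calls
# ---------------------------------------------------------------------------


def truth_structure_calls(spec: SyntheticSpec, resolution: int = 1000):
    """Planted loops/stripes as calls on the 1-kb grid."""
    loops = [
        StructureCall(
            "loop", spec.chrom,
            (a1 // resolution, a1 // resolution + 1),
            (a2 // resolution, a2 // resolution + 1),
            resolution=resolution, score=amp,
        )
        for a1, a2, amp, _ in spec.loops
    ]
    stripes = []
    for a, orient, ext, amp in spec.stripes:
        ab = a // resolution
        eb = ext // resolution
        extent = (ab, ab + eb) if orient == "vertical" else (ab - eb, ab)
        stripes.append(
            StructureCall(
                "stripe", spec.chrom, (ab, ab + 1), extent,
                resolution=resolution, orientation=orient, score=amp,
            )
        )
    return loops, stripes


# ---------------------------------------------------------------------------
# datasets
# ---------------------------------------------------------------------------


@dataclass
class SyntheticDataset:
    """Everything the pipeline needs for a desk-scale experiment."""

    spec: SyntheticSpec
    windows: list[WindowSample]
    train: list[WindowSample]
    tune: list[WindowSample]
    test: list[WindowSample]
    truth: ContactMap
    hic: ContactMap
    tracks: dict[str, BinTrack]
    truth_loops: list[StructureCall]
    truth_stripes: list[StructureCall]
    window_bp: int
    step_bp: int
    band_bp: int


def make_dataset(
    spec: SyntheticSpec,
    n_windows: int,
    split_fractions: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3),
    seed: int | None = None,
    window_bp: int = 50_000,
    step_bp: int = 10_000,
    band_bp: int = 40_000,
    features=FEATURES_6EPI,
    encoding_dim: int = 8,
) -> SyntheticDataset:
    """Generate truth + Hi-C + tracks, preprocess into windows, split.

    The window geometry defaults to the desk-scale study conditions
    (50-kb windows, 10-kb step, 40-kb band at 200-bp bins).
    """
    if abs(sum(split_fractions) - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")
    needed = window_bp + (n_windows - 1) * step_bp
    if needed > spec.region_length_bp:
        raise ValueError(
            f"{n_windows} windows need {needed} bp but region is {spec.region_length_bp} bp"
        )
    n_nonzero = sum(1 for f in split_fractions if f > 0)
    if n_windows < n_nonzero:
        raise ValueError("n_windows too small for the requested split")

    seed = spec.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    truth = generate_truth(spec)
    hic = generate_hic(spec, seed=seed + 7)
    tracks = generate_tracks(spec, features)
    oe_hic = oe_normalize(hic)

    res = spec.resolution
    n_bins = window_bp // res
    w = band_bp // res
    bmask = band_mask(n_bins, w)
    cres = spec.hic_resolution
    windows = []
    for k in range(n_windows):
        start_bp = k * step_bp
        c0, c1 = start_bp // cres, (start_bp + window_bp) // cres
        fine = interpolate_contacts(oe_hic.slice_bins(c0, c1), res)
        b0 = start_bp // res
        X = np.vstack([tracks[f].slice_bins(b0, b0 + n_bins).values for f in features])
        graph = build_graph(fine, X, encoding_dim=encoding_dim)
        Y = np.log1p(truth.slice_bins(b0, b0 + n_bins).to_dense()) * bmask
        windows.append(
            WindowSample(
                chrom=spec.chrom, start_bp=start_bp, window_bp=window_bp,
                X=X, graph=graph, band_bp=band_bp, Y=Y,
                feature_names=tuple(features), resolution=res,
            )
        )

    order = rng.permutation(n_windows)
    n_train = int(round(split_fractions[0] * n_windows))
    n_tune = int(round(split_fractions[1] * n_windows))
    train = [windows[i] for i in sorted(order[:n_train])]
    tune = [windows[i] for i in sorted(order[n_train : n_train + n_tune])]
    test = [windows[i] for i in sorted(order[n_train + n_tune :])]

    loops, stripes = truth_structure_calls(spec)
    return SyntheticDataset(
        spec=spec, windows=windows, train=train, tune=tune, test=test,
        truth=truth, hic=hic, tracks=tracks,
        truth_loops=loops, truth_stripes=stripes,
        window_bp=window_bp, step_bp=step_bp, band_bp=band_bp,
    )
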