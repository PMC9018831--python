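"""From raw Hi-C + tracks to model-ready windows, and back to a chromosome map.

The imputation model consumes 250-kb windows slid along the diagonal with a
50-kb step. Within a window, the low-resolution Hi-C map is O/E-normalized,
bilinearly interpolated to 200-bp bins, and turned into a weighted graph whose
node attributes are the epigenomic signals plus a sinusoidal positional
encoding. Per-window predictions are stitched back into a chromosome-scale
band matrix by averaging overlaps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.interpolate import RegularGridInterpolator

from .core_data import BinTrack, ContactMap

__all__ = [
    "ChromGraph",
    "WindowSample",
    "interpolate_contacts",
    "oe_normalize",
    "expected_by_distance",
    "positional_encoding",
    "build_graph",
    "extract_windows",
    "downsample_contacts",
    "aggregate_surrogate",
    "stitch_predictions",
    "band_mask",
]


@dataclass
class ChromGraph:
    """Window-level contact graph: self-looped adjacency + node features."""

    n_nodes: int
    adjacency: sp.csr_matrix            # symmetric, nonnegative, self-loops on the diagonal
    node_features: np.ndarray           # (m_features + p_encoding) x n_nodes

    def __post_init__(self) -> None:
        if self.adjacency.shape != (self.n_nodes, self.n_nodes):
            raise ValueError("adjacency shape mismatch")
        if self.node_features.shape[1] != self.n_nodes:
            raise ValueError("node_features column count must equal n_nodes")


@dataclass
class WindowSample:
    """One training / inference unit: a 250-kb window at defaults."""

    chrom: str
    start_bp: int
    window_bp: int
    X: np.ndarray                        # m signals x n bins
    graph: ChromGraph
    band_bp: int = 200_000
    Y: np.ndarray | None = None          # n x n, band-masked symmetric target
    feature_names: tuple[str, ...] = ()
    resolution: int = 200

    @property
    def n_bins(self) -> int:
        return self.window_bp // self.resolution

    @property
    def band_bins(self) -> int:
        return self.band_bp // self.resolution


def band_mask(n: int, w: int) -> np.ndarray:
    """Boolean n x n mask of pixels within ``w`` bins of the diagonal."""
    idx = np.arange(n)
    return np.abs(idx[:, None] - idx[None, :]) <= w


# ---------------------------------------------------------------------------
# interpolation and O/E
# ---------------------------------------------------------------------------


def interpolate_contacts(cmap: ContactMap, target_resolution: int = 200) -> ContactMap:
    """Bilinear interpolation of a coarse map onto a finer bin grid.

    Coarse bin centers are preserved exactly; positions outside the hull of
    coarse centers are clamped to the nearest center (constant extrapolation).
    Output values are clamped at 0.
    """
    if cmap.resolution == target_resolution:
        return cmap
    if cmap.resolution % target_resolution != 0:
        raise ValueError(
            f"coarse resolution {cmap.resolution} not divisible by {target_resolution}"
        )
    f = cmap.resolution // target_resolution
    nc = cmap.n_bins
    nf = nc * f
    dense = cmap.to_dense()
    centers = np.arange(nc, dtype=float)
    interp = RegularGridInterpolator((centers, centers), dense, method="linear")
    # fine bin k covers coarse coordinate (k + 0.5)/f - 0.5
    pos = (np.arange(nf) + 0.5) / f - 0.5
    pos = np.clip(pos, 0.0, nc - 1.0)
    pi, pj = np.meshgrid(pos, pos, indexing="ij")
    fine = interp(np.stack([pi.ravel(), pj.ravel()], axis=-1)).reshape(nf, nf)
    fine = np.maximum(fine, 0.0)
    fine[np.tril_indices(nf, -1)] = 0.0
    return ContactMap(
        cmap.chrom,
        target_resolution,
        sp.coo_matrix(fine),
        state=cmap.state,
        offset_bin=cmap.offset_bin * f,
        n_bins=nf,
    )


def expected_by_distance(cmap: ContactMap) -> np.ndarray:
    """Mean contact per distance stratum d = |i-j| over the map's extent.

    Stratum d has ``n_bins - d`` pairs; absent entries count as 0.
    """
    n = cmap.n_bins
    if n == 0 or cmap.matrix.nnz == 0:
        raise ValueError("cannot compute distance expectation of an empty map")
    coo = cmap.upper_coo()
    d = coo.col - coo.row
    sums = np.bincount(d, weights=coo.data, minlength=n)
    counts = n - np.arange(n)
    return sums / counts


def oe_normalize(cmap: ContactMap) -> ContactMap:
    """Observed/expected normalization: divide by the distance-stratum mean."""
    if cmap.state != "raw":
        raise ValueError(f"oe_normalize expects a raw map, got state={cmap.state!r}")
    expected = expected_by_distance(cmap)
    coo = cmap.upper_coo()
    d = coo.col - coo.row
    exp = expected[d]
    data = np.where(exp > 0, coo.data / np.where(exp > 0, exp, 1.0), 0.0)
    mat = sp.coo_matrix((data, (coo.row, coo.col)), shape=coo.shape)
    return cmap.with_matrix(mat, state="oe")


# ---------------------------------------------------------------------------
# graph construction
# ---------------------------------------------------------------------------


def positional_encoding(n_bins: int, encoding_dim: int = 8) -> np.ndarray:
    """Transformer-style sinusoidal encoding of bin order.

    Row ``2k`` is sin, row ``2k+1`` is cos, at geometrically spaced
    wavelengths; deterministic and independent of any data.
    """
    if encoding_dim % 2 != 0:
        raise ValueError("encoding_dim must be even")
    pos = np.arange(n_bins, dtype=float)
    pe = np.empty((encoding_dim, n_bins))
    for k in range(encoding_dim // 2):
        wavelength = 10000.0 ** (2 * k / encoding_dim)
        pe[2 * k] = np.sin(pos / wavelength)
        pe[2 * k + 1] = np.cos(pos / wavelength)
    return pe


def build_graph(
    fine_map: ContactMap,
    X: np.ndarray,
    encoding_dim: int = 8,
    edge_threshold: float = 0.0,
    top_k: int | None = None,
) -> ChromGraph:
    """Window graph: thresholded fine-map adjacency + self-loops; features + encoding.

    ``fine_map`` must cover exactly the window at 200 bp; ``X`` is the
    m x n feature matrix. Entries strictly below ``edge_threshold`` are
    dropped; identity self-loops are always added.
    """
    n = fine_map.n_bins
    if X.shape[1] != n:
        raise ValueError(f"feature matrix has {X.shape[1]} columns, window has {n} bins")
    coo = fine_map.upper_coo()
    keep = coo.data >= edge_threshold if edge_threshold > 0 else coo.data != 0
    r, c, v = coo.row[keep], coo.col[keep], coo.data[keep]
    off = r != c
    r, c, v = r[off], c[off], v[off]
    adj = sp.coo_matrix((np.concatenate([v, v]), (np.concatenate([r, c]), np.concatenate([c, r]))), shape=(n, n)).tocsr()
    if top_k is not None:
        adj = _sparsify_top_k(adj, top_k)
    adj = adj + sp.identity(n, format="csr")
    feats = np.vstack([X, positional_encoding(n, encoding_dim)])
    return ChromGraph(n_nodes=n, adjacency=adj.tocsr(), node_features=feats)


def _sparsify_top_k(adj: sp.csr_matrix, k: int) -> sp.csr_matrix:
    """Keep the k strongest neighbors per node (union over rows, symmetric)."""
    lil = adj.tolil()
    keep = sp.lil_matrix(adj.shape)
    for i in range(adj.shape[0]):
        cols = np.array(lil.rows[i])
        vals = np.array(lil.data[i])
        if cols.size > k:
            sel = np.argsort(vals)[-k:]
            cols, vals = cols[sel], vals[sel]
        keep[i, cols] = vals
    keep = keep.tocsr()
    return keep.maximum(keep.T)


# ---------------------------------------------------------------------------
# windows
# ---------------------------------------------------------------------------


def extract_windows(
    chrom_length: int,
    window_bp: int = 250_000,
    step_bp: int = 50_000,
    include_short: bool = False,
) -> list[tuple[int, int]]:
    """Sliding-window coordinates (start, end) along the diagonal.

    Starts run 0, step, 2*step, ... while start + window fits. If the tail of
    the chromosome is uncovered, one final window right-aligned at the
    chromosome end is appended so coverage is complete. A chromosome shorter
    than the window yields one truncated window when ``include_short`` else
    an empty list.
    """
    if window_bp % step_bp != 0 or window_bp % 200 != 0:
        raise ValueError("window_bp must be a multiple of step_bp and of 200")
    if chrom_length < window_bp:
        return [(0, chrom_length)] if include_short else []
    starts = list(range(0, chrom_length - window_bp + 1, step_bp))
    if starts[-1] + window_bp < chrom_length:
        starts.append(chrom_length - window_bp)
    return [(s, s + window_bp) for s in starts]


# ---------------------------------------------------------------------------
# downsampling and surrogate aggregation
# ---------------------------------------------------------------------------


def downsample_contacts(
    cmap: ContactMap, target_total: float, seed: int | np.random.Generator
) -> ContactMap:
    """Binomial thinning of a raw map to an expected total of ``target_total``."""
    if cmap.state != "raw":
        raise ValueError("downsampling applies to raw counts")
    total = cmap.total_contacts
    if target_total > total:
        raise ValueError(f"target_total {target_total} exceeds map total {total}")
    rate = target_total / total
    if rate == 1.0:
        return cmap.with_matrix(cmap.matrix.copy())
    rng = np.random.default_rng(seed)
    coo = cmap.upper_coo()
    counts = np.rint(coo.data).astype(np.int64)
    thinned = rng.binomial(counts, rate).astype(float)
    mat = sp.coo_matrix((thinned, (coo.row, coo.col)), shape=coo.shape)
    return cmap.with_matrix(mat)


def aggregate_surrogate(
    maps: list[ContactMap], target_total: float, seed: int | np.random.Generator
) -> ContactMap:
    """Surrogate map: thin each input to target/k contacts and sum entrywise.

    Emulates building a deep surrogate Hi-C map from several unmatched cell
    lines in equal proportions.
    """
    if len(maps) < 2:
        raise ValueError("need at least two maps to aggregate")
    ref = maps[0]
    for m in maps[1:]:
        if (m.n_bins, m.resolution, m.offset_bin) != (ref.n_bins, ref.resolution, ref.offset_bin):
            raise ValueError("all maps must share the same bin grid")
    rng = np.random.default_rng(seed)
    per_map = target_total / len(maps)
    acc = None
    for m in maps:
        if m.total_contacts == 0:
            continue  # empty map contributes nothing
        thinned = downsample_contacts(m, min(per_map, m.total_contacts), rng)
        acc = thinned.matrix if acc is None else acc + thinned.matrix
    if acc is None:
        raise ValueError("all input maps are empty")
    return ContactMap(
        ref.chrom, ref.resolution, acc, state="raw", offset_bin=ref.offset_bin, n_bins=ref.n_bins
    )


# ---------------------------------------------------------------------------
# stitching per-window predictions
# ---------------------------------------------------------------------------


def stitch_predictions(
    predictions: list[tuple[int, np.ndarray]],
    chrom: str,
    chrom_length: int,
    band_bp: int,
    resolution: int = 200,
    state: str = "log1p",
    reducer: str = "mean",
) -> ContactMap:
    """Assemble per-window n x n predictions into a chromosome band matrix.

    ``predictions`` holds (start_bp, matrix) pairs from one chromosome. Where
    k windows cover a pixel, the stitched value is their mean (or median).
    Pixels farther than ``band_bp`` from the diagonal are absent.
    """
    if not predictions:
        raise ValueError("no predictions to stitch")
    w = band_bp // resolution
    nb = -(-chrom_length // resolution)
    if reducer not in ("mean", "median"):
        raise ValueError("reducer must be 'mean' or 'median'")
    if reducer == "median":
        return _stitch_median(predictions, chrom, nb, w, resolution, state)
    sums = np.zeros((nb, w + 1))
    counts = np.zeros((nb, w + 1))
    for start_bp, mat in predictions:
        if start_bp % resolution != 0:
            raise ValueError("window start must align with the bin grid")
        b0 = start_bp // resolution
        n = mat.shape[0]
        ii, dd = _band_indices(n, w)
        np.add.at(sums, (b0 + ii, dd), mat[ii, ii + dd])
        np.add.at(counts, (b0 + ii, dd), 1.0)
    have = counts > 0
    vals = sums[have] / counts[have]
    rows, offs = np.nonzero(have)
    mat = sp.coo_matrix((vals, (rows, rows + offs)), shape=(nb, nb))
    return ContactMap(chrom, resolution, mat, state=state, n_bins=nb)


def _band_indices(n: int, w: int) -> tuple[np.ndarray, np.ndarray]:
    ii, jj = np.triu_indices(n)
    keep = (jj - ii) <= w
    return ii[keep], (jj - ii)[keep]


def _stitch_median(predictions, chrom, nb, w, resolution, state) -> ContactMap:
    from collections import defaultdict

    bucket: dict[tuple[int, int], list[float]] = defaultdict(list)
    for start_bp, mat in predictions:
        b0 = start_bp // resolution
        n = mat.shape[0]
        ii, dd = _band_indices(n, w)
        for i, d, v in zip(b0 + ii, dd, mat[ii, ii + dd]):
            bucket[(int(i), int(d))].append(float(v))
    rows = np.array([k[0] for k in bucket])
    offs = np.array([k[1] for k in bucket])
    vals = np.array([float(np.median(v)) for v in bucket.values()])
    mat = sp.coo_matrix((vals, (rows, rows + offs)), shape=(nb, nb))
    return ContactMap(chrom, resolution, mat, state=state, n_bins=nb)
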