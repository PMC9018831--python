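"""Loop and stripe calling at 1-kb resolution, pile-ups, and call matching.

The loop caller is a donut-style multi-background enrichment test: a pixel is
a loop candidate when its observed count exceeds each of four local
background estimates (donut, lower-left, horizontal, vertical neighborhoods
of radius 5 around the pixel, excluding a 2-pixel core) by a fold threshold,
and its Poisson upper tail against each background-derived expectation
survives Benjamini-Hochberg control. Nearby significant pixels are clustered
and each cluster reports its maximal pixel.

The stripe caller scans each anchor row/column for contiguous runs of pixels
whose O/E exceeds the median of the flanking rows/columns by a fold
threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy import signal, stats

from .core_data import ContactMap, StructureCall
from .preprocess import expected_by_distance

__all__ = [
    "PileupResult",
    "pool_to_1kb",
    "call_loops",
    "call_stripes",
    "match_calls",
    "pileup",
]


@dataclass
class PileupResult:
    """Mean submatrix around a set of centers."""

    matrix: np.ndarray
    n_regions: int

    @property
    def side(self) -> int:
        return self.matrix.shape[0]

    @property
    def center_score(self) -> float:
        """Mean of the central 5 x 5 block."""
        c = self.side // 2
        return float(self.matrix[c - 2 : c + 3, c - 2 : c + 3].mean())


# ---------------------------------------------------------------------------
# pooling
# ---------------------------------------------------------------------------


def pool_to_1kb(cmap: ContactMap) -> ContactMap:
    """Aggregate a 200-bp map into 1-kb bins.

    Raw counts are block-summed; log1p maps are pooled on the count scale
    (expm1 -> block sum -> log1p) so pooled pseudo-counts stay commensurate
    with pooled raw counts; O/E-normalized maps are block-averaged.
    """
    if cmap.resolution != 200:
        raise ValueError(f"expected a 200-bp map, got {cmap.resolution}")
    f = 5
    n1 = -(-cmap.n_bins // f)
    coo = cmap.upper_coo()
    r, c = coo.row // f, coo.col // f
    data = np.expm1(coo.data) if cmap.state == "log1p" else coo.data
    mat = sp.coo_matrix((data, (r, c)), shape=(n1, n1))
    mat.sum_duplicates()
    if cmap.state == "log1p":
        mat.data = np.log1p(np.maximum(mat.data, 0.0))
    elif cmap.state != "raw":
        mat = mat.multiply(1.0 / f**2)
    return ContactMap(
        cmap.chrom, 1000, mat, state=cmap.state, offset_bin=cmap.offset_bin // f, n_bins=n1
    )


# ---------------------------------------------------------------------------
# loop calling
# ---------------------------------------------------------------------------


def _pseudo_counts(cmap: ContactMap) -> np.ndarray:
    """Dense symmetric count-scale matrix for enrichment testing."""
    if cmap.state == "raw":
        return cmap.to_dense()
    if cmap.state == "log1p":
        # slightly negative predictions are clamped to zero counts
        return np.maximum(np.expm1(cmap.to_dense()), 0.0)
    raise ValueError(
        f"loop/stripe calling needs a count-scale map (raw or log1p), got {cmap.state!r}"
    )


def _background_kernels(radius: int, core: int) -> dict[str, np.ndarray]:
    """Boolean kernels over a (2R+1)^2 neighborhood, center excluded."""
    R, C = radius, core
    di, dj = np.meshgrid(np.arange(-R, R + 1), np.arange(-R, R + 1), indexing="ij")
    cheb = np.maximum(np.abs(di), np.abs(dj))
    outside_core = cheb > C
    donut = outside_core & (di != 0) & (dj != 0)
    lower_left = (di > C) & (dj < -C)
    # the row/column backgrounds are one-sided (left/right, up/down) so a
    # pixel sitting on a stripe is compared against the stripe itself on at
    # least one side and is not called as a loop
    return {
        "donut": donut.astype(float),
        "lower_left": lower_left.astype(float),
        "horiz_left": ((dj < -C) & (di == 0)).astype(float),
        "horiz_right": ((dj > C) & (di == 0)).astype(float),
        "vert_up": ((di < -C) & (dj == 0)).astype(float),
        "vert_down": ((di > C) & (dj == 0)).astype(float),
    }


def _local_means(mat: np.ndarray, valid: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Mean of ``mat`` over the kernel footprint, restricted to valid pixels."""
    k = kernel[::-1, ::-1]
    num = signal.convolve(mat * valid, k, mode="same")
    den = signal.convolve(valid.astype(float), k, mode="same")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den
    out[den == 0] = np.nan
    return out


def call_loops(
    cmap: ContactMap,
    fdr: float = 0.1,
    min_distance_bp: int = 10_000,
    max_distance_bp: int = 200_000,
    fold: float = 1.75,
    radius: int = 5,
    core: int = 2,
    merge_radius: int = 2,
    min_count: float = 2.0,
) -> list[StructureCall]:
    """Call focal contact enrichments (loops) on a 1-kb contact map."""
    res = cmap.resolution
    n = cmap.n_bins
    if n <= 2 * radius + 1:
        raise ValueError("map narrower than the background neighborhood")
    counts = _pseudo_counts(cmap)
    expected = expected_by_distance(
        cmap if cmap.state == "raw" else cmap.with_matrix(sp.coo_matrix(np.triu(counts)), state="raw")
    )
    idx = np.arange(n)
    dist = np.abs(idx[:, None] - idx[None, :])
    with np.errstate(invalid="ignore", divide="ignore"):
        oe = counts / expected[dist]
    oe[~np.isfinite(oe)] = 0.0

    dmin = min_distance_bp // res
    dmax = max_distance_bp // res
    valid = (dist >= max(1, dmin - radius)) & (dist <= dmax + radius) & (expected[dist] > 0)
    kernels = _background_kernels(radius, core)
    bg = {name: _local_means(oe, valid, k) for name, k in kernels.items()}

    cand = np.triu(dist >= dmin) & (dist <= dmax) & (counts >= min_count)
    for b in bg.values():
        cand &= np.isfinite(b)
    ci, cj = np.nonzero(cand)
    if ci.size == 0:
        return []

    obs = np.rint(counts[ci, cj]).astype(np.int64)
    pmax = np.zeros(ci.size)
    fold_ok = np.ones(ci.size, dtype=bool)
    for b in bg.values():
        lam = np.maximum(b[ci, cj], 1e-12) * expected[dist[ci, cj]]
        pmax = np.maximum(pmax, stats.poisson.sf(obs - 1, lam))
        fold_ok &= oe[ci, cj] >= fold * np.maximum(b[ci, cj], 1e-12)
    q = stats.false_discovery_control(np.clip(pmax, 0, 1), method="bh")
    sel = (q <= fdr) & fold_ok
    if not sel.any():
        return []

    calls = []
    for pi, pj, score in _cluster_maxima(
        ci[sel], cj[sel], counts[ci[sel], cj[sel]], oe, bg["donut"], merge_radius
    ):
        calls.append(
            StructureCall(
                "loop", cmap.chrom, (int(pi), int(pi) + 1), (int(pj), int(pj) + 1),
                resolution=res, score=float(score),
            )
        )
    calls.sort(key=lambda c: (c.anchor1[0], c.anchor2[0]))
    return calls


def _cluster_maxima(ci, cj, vals, oe, donut_bg, merge_radius):
    """Cluster significant pixels within Chebyshev distance merge_radius and
    yield each cluster's maximal pixel with its donut enrichment score."""
    order = np.lexsort((cj, ci))
    pts = np.stack([ci[order], cj[order]], axis=1)
    vv = vals[order]
    n = len(pts)
    parent = list(range(n))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for a in range(n):
        near = np.nonzero(
            (np.abs(pts[:, 0] - pts[a, 0]) <= merge_radius)
            & (np.abs(pts[:, 1] - pts[a, 1]) <= merge_radius)
        )[0]
        for b in near:
            ra, rb = find(a), find(int(b))
            if ra != rb:
                parent[max(ra, rb)] = min(ra, rb)
    groups: dict[int, list[int]] = {}
    for a in range(n):
        groups.setdefault(find(a), []).append(a)
    for members in groups.values():
        best = max(members, key=lambda a: (vv[a], -pts[a, 0], -pts[a, 1]))
        pi, pj = pts[best]
        denom = donut_bg[pi, pj]
        score = oe[pi, pj] / denom if denom and np.isfinite(denom) else oe[pi, pj]
        yield pi, pj, score


# ---------------------------------------------------------------------------
# stripe calling
# ---------------------------------------------------------------------------


def call_stripes(
    cmap: ContactMap,
    min_length: int = 10,
    fold: float = 2.0,
    flank: int = 3,
    max_distance_bp: int = 200_000,
    min_offset: int = 2,
) -> list[StructureCall]:
    """Call architectural stripes on a 1-kb contact map.

    A vertical stripe anchored at bin a occupies pixels (a, a+t); it is
    called when a contiguous run of >= min_length offsets t has O/E at least
    ``fold`` times the median O/E of the flanking anchors a-flank..a+flank at
    the same offsets. Horizontal stripes are the transpose case.
    """
    res = cmap.resolution
    n = cmap.n_bins
    if n <= 2 * flank + 1:
        raise ValueError("map narrower than the flanking neighborhood")
    counts = _pseudo_counts(cmap)
    expected = expected_by_distance(
        cmap if cmap.state == "raw" else cmap.with_matrix(sp.coo_matrix(np.triu(counts)), state="raw")
    )
    idx = np.arange(n)
    dist = np.abs(idx[:, None] - idx[None, :])
    with np.errstate(invalid="ignore", divide="ignore"):
        oe = counts / expected[dist]
    oe[~np.isfinite(oe)] = 0.0
    dmax = min(max_distance_bp // res, n - 1)

    raw_calls: list[StructureCall] = []
    for orientation in ("vertical", "horizontal"):
        for a in range(n):
            tmax = min(dmax, (n - 1 - a) if orientation == "vertical" else a)
            if tmax < min_length:
                continue
            ts = np.arange(min_offset, tmax + 1)
            if orientation == "vertical":
                vals = oe[a, a + ts]
            else:
                vals = oe[a - ts, a]
            flanks = []
            for f in range(-flank, flank + 1):
                if f == 0 or not (0 <= a + f < n):
                    continue
                b = a + f
                if orientation == "vertical":
                    cols = b + ts
                    ok = cols < n
                    row = np.full(len(ts), np.nan)
                    row[ok] = oe[b, cols[ok]]
                else:
                    rows = b - ts
                    ok = rows >= 0
                    row = np.full(len(ts), np.nan)
                    row[ok] = oe[rows[ok], b]
                flanks.append(row)
            med = np.nanmedian(np.stack(flanks), axis=0)
            hit = (vals >= fold * np.maximum(med, 1e-12)) & (vals > 0) & np.isfinite(med)
            for t0, t1 in _runs(hit):
                if t1 - t0 < min_length:
                    continue
                lo, hi = int(ts[t0]), int(ts[t1 - 1]) + 1
                ext = (a + lo, a + hi) if orientation == "vertical" else (a - hi + 1, a - lo + 1)
                score = float(np.mean(vals[t0:t1] / np.maximum(med[t0:t1], 1e-12)))
                raw_calls.append(
                    StructureCall(
                        "stripe", cmap.chrom, (a, a + 1), ext,
                        resolution=res, orientation=orientation, score=score,
                    )
                )
    return _merge_stripes(raw_calls)


def _runs(mask: np.ndarray):
    """(start, end) index pairs of contiguous True runs."""
    if not mask.any():
        return
    padded = np.concatenate([[False], mask, [False]])
    starts = np.nonzero(padded[1:] & ~padded[:-1])[0]
    ends = np.nonzero(~padded[1:] & padded[:-1])[0]
    yield from zip(starts, ends)


def _merge_stripes(calls: list[StructureCall], anchor_tol: int = 1) -> list[StructureCall]:
    """Suppress overlapping runs from adjacent anchors, keeping the best score."""
    kept: list[StructureCall] = []
    for c in sorted(calls, key=lambda c: -c.score):
        clash = False
        for k in kept:
            if (
                k.orientation == c.orientation
                and abs(k.anchor1[0] - c.anchor1[0]) <= anchor_tol
                and min(k.anchor2[1], c.anchor2[1]) > max(k.anchor2[0], c.anchor2[0])
            ):
                clash = True
                break
        if not clash:
            kept.append(c)
    kept.sort(key=lambda c: (c.anchor1[0], c.anchor2[0]))
    return kept


# ---------------------------------------------------------------------------
# matching / Venn counts
# ---------------------------------------------------------------------------


def match_calls(
    set_a: list[StructureCall],
    set_b: list[StructureCall],
    tolerance_bp: int = 5000,
) -> dict[str, int]:
    """Greedy one-to-one matching; returns Venn counts a_only / both / b_only.

    Loops match when both anchor midpoints differ by at most the tolerance;
    stripes match on anchor midpoint and orientation. Ties are broken by
    smallest anchor distance, then genomic order, so counts are
    deterministic.
    """
    kinds = {c.kind for c in set_a} | {c.kind for c in set_b}
    if len(kinds) > 1:
        raise ValueError("cannot match loops against stripes")
    pairs = []
    for ia, a in enumerate(set_a):
        for ib, b in enumerate(set_b):
            d1 = abs(a.midpoint1_bp - b.midpoint1_bp)
            if a.kind == "loop":
                d2 = abs(a.midpoint2_bp - b.midpoint2_bp)
                if d1 <= tolerance_bp and d2 <= tolerance_bp and a.chrom == b.chrom:
                    pairs.append((d1 + d2, a.midpoint1_bp, b.midpoint1_bp, ia, ib))
            else:
                if d1 <= tolerance_bp and a.orientation == b.orientation and a.chrom == b.chrom:
                    pairs.append((d1, a.midpoint1_bp, b.midpoint1_bp, ia, ib))
    pairs.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    both = 0
    for _, _, _, ia, ib in pairs:
        if ia in used_a or ib in used_b:
            continue
        used_a.add(ia)
        used_b.add(ib)
        both += 1
    return {"a_only": len(set_a) - both, "both": both, "b_only": len(set_b) - both}


# ---------------------------------------------------------------------------
# pile-up aggregation
# ---------------------------------------------------------------------------


def pileup(
    cmap: ContactMap,
    centers: list[tuple[int, int]],
    side: int = 101,
) -> PileupResult:
    """Mean ``side x side`` submatrix around the given pixel centers.

    Regions clipped by the matrix edge are dropped rather than zero-padded.
    """
    if side % 2 != 1:
        raise ValueError("side must be odd")
    h = side // 2
    n = cmap.n_bins
    dense = cmap.to_dense()
    acc = np.zeros((side, side))
    used = 0
    for i, j in centers:
        if i - h < 0 or j - h < 0 or i + h >= n or j + h >= n:
            continue
        acc += dense[i - h : i + h + 1, j - h : j + h + 1]
        used += 1
    if used == 0:
        raise ValueError("no usable centers (all clipped by the map edge)")
    return PileupResult(matrix=acc / used, n_regions=used)
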