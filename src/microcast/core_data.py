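"""Domain types and readers/writers for the standard genomic formats.

Coordinate conventions used throughout the package:

* all genomic coordinates are 0-based, half-open;
* a position ``p`` falls in bin ``p // resolution``;
* contact matrices are stored as the upper triangle of a sparse symmetric
  matrix and mirrored on access, so the diagonal is counted once in totals;
* features and contacts are strandless.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
import h5py

__all__ = [
    "BinTrack",
    "ContactMap",
    "StructureCall",
    "EqtlPair",
    "read_contact_map",
    "write_contact_map",
    "read_track",
    "normalize_track",
    "write_structures",
    "read_structures",
    "FormatError",
    "CoordinateError",
]

#: valid normalization states of a ContactMap
CONTACT_STATES = ("raw", "oe", "log_oe", "log1p")


class FormatError(ValueError):
    """A file does not contain what was requested."""


class CoordinateError(ValueError):
    """A genomic interval is outside chromosome bounds or malformed."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class BinTrack:
    """One epigenomic feature binned over a region.

    ``values[k]`` is the mean base-pair signal over
    ``[(start_bin + k) * resolution, (start_bin + k + 1) * resolution)``.
    """

    chrom: str
    start_bin: int
    resolution: int
    values: np.ndarray
    feature: str
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("track values must be finite")

    @property
    def n_bins(self) -> int:
        return len(self.values)

    def slice_bins(self, b0: int, b1: int) -> "BinTrack":
        """Sub-track over absolute bin indices ``[b0, b1)`` (zero-filled outside)."""
        out = np.zeros(b1 - b0)
        lo = max(b0, self.start_bin)
        hi = min(b1, self.start_bin + self.n_bins)
        if hi > lo:
            out[lo - b0 : hi - b0] = self.values[lo - self.start_bin : hi - self.start_bin]
        return replace(self, start_bin=b0, values=out)


def normalize_track(track: BinTrack, genome_mean: float) -> BinTrack:
    """Divide values by the genome-wide average of the feature."""
    if genome_mean <= 0:
        raise ValueError("genome_mean must be > 0")
    return replace(track, values=track.values / float(genome_mean), normalized=True)


class ContactMap:
    """Sparse symmetric binned contact matrix.

    Only the upper triangle (row <= col) is stored; the symmetric value is
    reconstructed on access. ``total_contacts`` for a raw map is the sum of
    stored entries, i.e. the diagonal is counted once.
    """

    def __init__(
        self,
        chrom: str,
        resolution: int,
        matrix: sp.spmatrix | np.ndarray,
        state: str = "raw",
        offset_bin: int = 0,
        n_bins: int | None = None,
    ) -> None:
        if state not in CONTACT_STATES:
            raise ValueError(f"unknown state {state!r}; expected one of {CONTACT_STATES}")
        mat = sp.coo_matrix(matrix)
        if mat.shape[0] != mat.shape[1]:
            raise ValueError("contact matrix must be square")
        if not np.all(np.isfinite(mat.data)):
            raise ValueError("contact entries must be finite")
        if state == "raw" and mat.data.size and mat.data.min() < 0:
            raise ValueError("raw contact counts must be nonnegative")
        # keep the upper triangle; entries present only in the lower triangle
        # are mirrored up, so a full symmetric input is not double-counted
        r, c, v = mat.row, mat.col, mat.data
        up = r <= c
        lin_up = r[up] * mat.shape[0] + c[up]
        lo = ~up
        lin_lo = c[lo] * mat.shape[0] + r[lo]
        only_lower = ~np.isin(lin_lo, lin_up)
        rows = np.concatenate([r[up], c[lo][only_lower]])
        cols = np.concatenate([c[up], r[lo][only_lower]])
        vals = np.concatenate([v[up], v[lo][only_lower]])
        upper = sp.coo_matrix((vals, (rows, cols)), shape=mat.shape)
        upper.sum_duplicates()
        self.chrom = chrom
        self.resolution = int(resolution)
        self.offset_bin = int(offset_bin)
        self.matrix = upper.tocsr()
        self.state = state
        self._n_bins = int(n_bins) if n_bins is not None else mat.shape[0]

    # -- basic accessors ----------------------------------------------------

    @property
    def n_bins(self) -> int:
        return self._n_bins

    @property
    def total_contacts(self) -> float:
        return float(self.matrix.sum())

    def get(self, i: int, j: int) -> float:
        """Symmetric accessor in local bin coordinates."""
        if i > j:
            i, j = j, i
        return float(self.matrix[i, j])

    def to_dense(self) -> np.ndarray:
        """Full symmetric dense matrix (use only for modest extents)."""
        up = self.matrix.toarray()
        return up + np.triu(up, 1).T

    def upper_coo(self) -> sp.coo_matrix:
        return self.matrix.tocoo()

    def with_matrix(self, matrix, state: str | None = None) -> "ContactMap":
        return ContactMap(
            self.chrom,
            self.resolution,
            matrix,
            state=state or self.state,
            offset_bin=self.offset_bin,
            n_bins=self.n_bins,
        )

    def slice_bins(self, b0: int, b1: int) -> "ContactMap":
        """Square sub-map over local bins ``[b0, b1)``."""
        sub = self.matrix[b0:b1, b0:b1]
        return ContactMap(
            self.chrom,
            self.resolution,
            sub,
            state=self.state,
            offset_bin=self.offset_bin + b0,
            n_bins=b1 - b0,
        )

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"ContactMap({self.chrom}, res={self.resolution}, bins={self.n_bins}, "
            f"state={self.state}, nnz={self.matrix.nnz})"
        )


@dataclass
class StructureCall:
    """A called chromatin loop or stripe at a fixed bin resolution.

    For loops ``anchor1``/``anchor2`` are the two anchor bin intervals
    (genomically ordered). For stripes ``anchor1`` is the anchor interval and
    ``anchor2`` the extent interval; ``orientation`` is ``vertical`` when the
    anchor sits at the smaller coordinate and extends right, ``horizontal``
    for the converse.
    """

    kind: str  # "loop" | "stripe"
    chrom: str
    anchor1: tuple[int, int]
    anchor2: tuple[int, int]
    resolution: int = 1000
    orientation: str = "na"
    score: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("loop", "stripe"):
            raise ValueError("kind must be 'loop' or 'stripe'")
        if self.anchor1[0] > self.anchor1[1]:
            raise ValueError("anchor1 interval reversed")
        if self.kind == "loop" and self.anchor1[0] > self.anchor2[0]:
            raise ValueError("loop anchors must be genomically ordered")

    @property
    def midpoint1_bp(self) -> float:
        return (self.anchor1[0] + self.anchor1[1]) / 2 * self.resolution

    @property
    def midpoint2_bp(self) -> float:
        return (self.anchor2[0] + self.anchor2[1]) / 2 * self.resolution


@dataclass
class EqtlPair:
    """A variant–TSS pair binned at 200 bp, specific to one tissue."""

    chrom: str
    variant_bin: int
    tss_bin: int
    tissue: str
    distance_bp: int

    def __post_init__(self) -> None:
        if not self.tissue:
            raise ValueError("tissue must be nonempty")


# ---------------------------------------------------------------------------
# cooler-schema HDF5 contact files
# ---------------------------------------------------------------------------

_COOLER_FORMAT = "HDF5::Cooler"


def _write_cooler_group(grp: h5py.Group, cmap: ContactMap, chrom_length: int) -> None:
    res = cmap.resolution
    n = cmap.n_bins
    grp.attrs["format"] = _COOLER_FORMAT
    grp.attrs["bin-size"] = res
    chroms = grp.create_group("chroms")
    chroms.create_dataset("name", data=np.array([cmap.chrom.encode()]))
    chroms.create_dataset("length", data=np.array([chrom_length], dtype=np.int64))
    bins = grp.create_group("bins")
    starts = (np.arange(n) + cmap.offset_bin) * res
    bins.create_dataset("chrom", data=np.zeros(n, dtype=np.int32))
    bins.create_dataset("start", data=starts.astype(np.int64))
    bins.create_dataset("end", data=np.minimum(starts + res, chrom_length).astype(np.int64))
    coo = cmap.upper_coo()
    pixels = grp.create_group("pixels")
    pixels.create_dataset("bin1_id", data=coo.row.astype(np.int64))
    pixels.create_dataset("bin2_id", data=coo.col.astype(np.int64))
    pixels.create_dataset("count", data=coo.data)
    grp.attrs["state"] = cmap.state
    grp.attrs["offset_bin"] = cmap.offset_bin
    grp.attrs["n_bins"] = n


def write_contact_map(cmap: ContactMap, path: str | Path, chrom_length: int | None = None) -> None:
    """Write a single-resolution cooler-schema HDF5 file."""
    if chrom_length is None:
        chrom_length = (cmap.offset_bin + cmap.n_bins) * cmap.resolution
    with h5py.File(path, "w") as f:
        _write_cooler_group(f, cmap, chrom_length)


def write_multires_contact_maps(
    cmaps: Sequence[ContactMap], path: str | Path, chrom_length: int | None = None
) -> None:
    """Write several resolutions of one map into ``resolutions/<res>`` groups."""
    if chrom_length is None:
        chrom_length = max((m.offset_bin + m.n_bins) * m.resolution for m in cmaps)
    with h5py.File(path, "w") as f:
        root = f.create_group("resolutions")
        for m in cmaps:
            _write_cooler_group(root.create_group(str(m.resolution)), m, chrom_length)


def _available_resolutions(f: h5py.File) -> dict[int, h5py.Group]:
    if "pixels" in f:
        return {int(f.attrs["bin-size"]): f["/"]}
    if "resolutions" in f:
        return {int(k): f["resolutions"][k] for k in f["resolutions"]}
    raise FormatError("file contains neither a root cooler group nor a 'resolutions' group")


def read_contact_map(path: str | Path, chrom: str, resolution: int) -> ContactMap:
    """Read one chromosome at one resolution from a cooler-schema HDF5 file."""
    with h5py.File(path, "r") as f:
        avail = _available_resolutions(f)
        if resolution not in avail:
            raise FormatError(
                f"resolution {resolution} not in file; available: {sorted(avail)}"
            )
        grp = avail[resolution]
        names = [n.decode() if isinstance(n, bytes) else str(n) for n in grp["chroms/name"][:]]
        if chrom not in names:
            raise FormatError(f"chromosome {chrom!r} not in file; available: {names}")
        cix = names.index(chrom)
        bin_chrom = grp["bins/chrom"][:]
        sel = np.flatnonzero(bin_chrom == cix)
        b1 = grp["pixels/bin1_id"][:]
        b2 = grp["pixels/bin2_id"][:]
        cnt = grp["pixels/count"][:]
        keep = np.isin(b1, sel) & np.isin(b2, sel)
        lo = sel.min() if sel.size else 0
        n = int(sel.size)
        mat = sp.coo_matrix((cnt[keep], (b1[keep] - lo, b2[keep] - lo)), shape=(n, n))
        state = str(grp.attrs.get("state", "raw"))
        offset = int(grp.attrs.get("offset_bin", 0))
        return ContactMap(chrom, resolution, mat, state=state, offset_bin=offset, n_bins=n)


# ---------------------------------------------------------------------------
# signal tracks
# ---------------------------------------------------------------------------


def _read_bedgraph_values(path: Path, chrom: str, start: int, end: int) -> np.ndarray:
    """Per-bp signal over [start, end); missing data is 0."""
    out = np.zeros(end - start)
    df = pd.read_csv(
        path,
        sep=r"\s+",
        comment="#",
        header=None,
        names=["chrom", "start", "end", "value"],
        dtype={"chrom": str},
    )
    df = df[(df["chrom"] == chrom) & (df["end"] > start) & (df["start"] < end)]
    for s, e, v in zip(df["start"], df["end"], df["value"]):
        out[max(int(s), start) - start : min(int(e), end) - start] = v
    return out


def _read_bigwig_values(path: Path, chrom: str, start: int, end: int) -> np.ndarray:
    import pyBigWig  # optional dependency, only needed for .bw input

    with pyBigWig.open(str(path)) as bw:
        if chrom not in bw.chroms():
            raise CoordinateError(f"chromosome {chrom!r} not in {path}")
        if end > bw.chroms()[chrom]:
            raise CoordinateError(f"interval [{start},{end}) beyond {chrom} length")
        vals = np.array(bw.values(chrom, start, end), dtype=float)
    return np.nan_to_num(vals, nan=0.0)


def read_track(
    path: str | Path,
    chrom: str,
    start: int,
    end: int,
    resolution: int = 200,
    feature: str | None = None,
) -> BinTrack:
    """Read a bigWig or bedGraph interval into a BinTrack of per-bin means.

    The interval is 0-based half-open and must align reasonably with bins;
    a ragged tail bin is averaged over its full ``resolution`` width so that
    missing bases count as 0 signal.
    """
    path = Path(path)
    if start < 0 or end <= start:
        raise CoordinateError(f"bad interval [{start}, {end})")
    if path.suffix.lower() in (".bw", ".bigwig"):
        bp = _read_bigwig_values(path, chrom, start, end)
    else:
        bp = _read_bedgraph_values(path, chrom, start, end)
    n = -(-(end - start) // resolution)
    padded = np.zeros(n * resolution)
    padded[: end - start] = bp
    values = padded.reshape(n, resolution).mean(axis=1)
    return BinTrack(
        chrom=chrom,
        start_bin=start // resolution,
        resolution=resolution,
        values=values,
        feature=feature or path.stem,
    )


def write_bedgraph(track: BinTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        for k, v in enumerate(track.values):
            s = (track.start_bin + k) * track.resolution
            fh.write(f"{track.chrom}\t{s}\t{s + track.resolution}\t{v:.6g}\n")


# ---------------------------------------------------------------------------
# structure calls (BEDPE / BED)
# ---------------------------------------------------------------------------

_LOOP_HEADER = "#chrom1\tstart1\tend1\tchrom2\tstart2\tend2\tname\tscore"
_STRIPE_HEADER = "#chrom\tstart\tend\tname\tscore\torientation\textent_start\textent_end"


def write_structures(calls: Sequence[StructureCall], path: str | Path) -> None:
    """Write loops as BEDPE or stripes as BED (one kind per file)."""
    calls = list(calls)
    if calls:
        resolutions = {c.resolution for c in calls}
        if len(resolutions) > 1:
            raise ValueError(f"mixed resolutions in one file: {sorted(resolutions)}")
        kinds = {c.kind for c in calls}
        if len(kinds) > 1:
            raise ValueError("loops and stripes go to separate files")
        kind = calls[0].kind
    else:
        kind = "loop"
    with open(path, "w") as fh:
        fh.write((_LOOP_HEADER if kind == "loop" else _STRIPE_HEADER) + "\n")
        for c in calls:
            r = c.resolution
            if c.kind == "loop":
                fh.write(
                    f"{c.chrom}\t{c.anchor1[0] * r}\t{c.anchor1[1] * r}\t"
                    f"{c.chrom}\t{c.anchor2[0] * r}\t{c.anchor2[1] * r}\t.\t{c.score:.6g}\n"
                )
            else:
                fh.write(
                    f"{c.chrom}\t{c.anchor1[0] * r}\t{c.anchor1[1] * r}\t.\t{c.score:.6g}\t"
                    f"{c.orientation}\t{c.anchor2[0] * r}\t{c.anchor2[1] * r}\n"
                )


def read_structures(path: str | Path, resolution: int = 1000) -> list[StructureCall]:
    calls: list[StructureCall] = []
    with open(path) as fh:
        header = fh.readline().strip()
        kind = "loop" if header.startswith("#chrom1") else "stripe"
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if not parts or parts == [""]:
                continue
            if kind == "loop":
                chrom, s1, e1, _, s2, e2, _, score = parts[:8]
                calls.append(
                    StructureCall(
                        "loop",
                        chrom,
                        (int(s1) // resolution, int(e1) // resolution),
                        (int(s2) // resolution, int(e2) // resolution),
                        resolution=resolution,
                        score=float(score),
                    )
                )
            else:
                chrom, s, e, _, score, orient, xs, xe = parts[:8]
                calls.append(
                    StructureCall(
                        "stripe",
                        chrom,
                        (int(s) // resolution, int(e) // resolution),
                        (int(xs) // resolution, int(xe) // resolution),
                        resolution=resolution,
                        orientation=orient,
                        score=float(score),
                    )
                )
    return calls


# ---------------------------------------------------------------------------
# eQTL tables
# ---------------------------------------------------------------------------


def read_eqtl_table(path: str | Path) -> pd.DataFrame:
    """TSV with columns chrom, variant_pos, tss_pos, gene, tissue."""
    return pd.read_csv(path, sep="\t", dtype={"chrom": str, "tissue": str})
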