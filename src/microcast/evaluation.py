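"""Quantitative comparison of contact maps.

Implements the reproducibility and performance statistics used to judge
imputed maps: the stratum-adjusted correlation coefficient (SCC),
distance-stratified Pearson correlation, 250-kb fragment-level Spearman
correlation with stratification by conservation / compartment / replication
timing, eigenvector A/B compartment calling, one-sided group tests, and
eQTL-TSS pile-up enrichment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.ndimage import uniform_filter

from .core_data import ContactMap, EqtlPair
from .structures import PileupResult, pileup

logger = logging.getLogger(__name__)

__all__ = [
    "SCCReport",
    "scc",
    "distance_stratified_pearson",
    "fragment_spearman",
    "annotate_fragments",
    "call_compartments",
    "group_test",
    "filter_eqtl_pairs",
    "eqtl_pileup",
]


@dataclass
class SCCReport:
    """Stratum-adjusted correlation: per-stratum r_k weighted by
    w_k = N_k * sqrt(var_a,k * var_b,k)."""

    scc: float
    r: np.ndarray          # per-stratum Pearson (NaN where undefined)
    n: np.ndarray          # stratum sizes
    weights: np.ndarray
    h: int
    max_distance_bp: int


def _dense_pair(map_a: ContactMap, map_b: ContactMap):
    if (map_a.n_bins, map_a.resolution) != (map_b.n_bins, map_b.resolution):
        raise ValueError("maps must share the same bin grid and extent")
    return map_a.to_dense(), map_b.to_dense()


def _smooth(mat: np.ndarray, h: int) -> np.ndarray:
    return uniform_filter(mat, size=2 * h + 1, mode="constant", cval=0.0) if h > 0 else mat


def scc(
    map_a: ContactMap,
    map_b: ContactMap,
    h: int = 5,
    max_distance_bp: int = 200_000,
) -> SCCReport:
    """Stratum-adjusted correlation coefficient between two maps.

    Both maps are mean-filtered with a (2h+1)^2 kernel, Pearson correlation
    is computed per distance stratum, and strata are combined with weights
    N_k * sqrt(var_a * var_b). Zero-variance strata are skipped.
    """
    a, b = _dense_pair(map_a, map_b)
    a, b = _smooth(a, h), _smooth(b, h)
    n = a.shape[0]
    dmax = min(max_distance_bp // map_a.resolution, n - 1)
    r = np.full(dmax + 1, np.nan)
    nk = np.zeros(dmax + 1, dtype=int)
    wk = np.zeros(dmax + 1)
    for d in range(dmax + 1):
        xa = np.diagonal(a, d)
        xb = np.diagonal(b, d)
        nk[d] = len(xa)
        va, vb = xa.var(), xb.var()
        if va <= 0 or vb <= 0 or len(xa) < 2:
            continue
        r[d] = float(np.corrcoef(xa, xb)[0, 1])
        wk[d] = nk[d] * np.sqrt(va * vb)
    total = wk.sum()
    val = float(np.nansum(wk * np.nan_to_num(r)) / total) if total > 0 else np.nan
    return SCCReport(scc=val, r=r, n=nk, weights=wk, h=h, max_distance_bp=max_distance_bp)


def distance_stratified_pearson(
    map_a: ContactMap,
    map_b: ContactMap,
    max_distance_bp: int = 200_000,
) -> np.ndarray:
    """Pearson r per distance stratum d = 1..max (NaN where undefined)."""
    a, b = _dense_pair(map_a, map_b)
    n = a.shape[0]
    dmax = min(max_distance_bp // map_a.resolution, n - 1)
    out = np.full(dmax + 1, np.nan)
    for d in range(1, dmax + 1):
        xa, xb = np.diagonal(a, d), np.diagonal(b, d)
        if len(xa) >= 2 and xa.var() > 0 and xb.var() > 0:
            out[d] = float(np.corrcoef(xa, xb)[0, 1])
    return out


# ---------------------------------------------------------------------------
# fragment-level performance
# ---------------------------------------------------------------------------


def fragment_spearman(
    pred: ContactMap,
    obs: ContactMap,
    fragment_bp: int = 250_000,
    smooth_h: int = 2,
    band_bp: int | None = None,
) -> pd.DataFrame:
    """Spearman rho between smoothed maps per mutually exclusive fragment.

    Both maps are smoothed with a 5x5 uniform kernel (smooth_h=2) inside
    each fragment; rho is computed over the upper-triangle pixels (within
    the band if given). Fragments where either map is constant are flagged
    undefined.
    """
    if fragment_bp % pred.resolution != 0:
        raise ValueError("fragment_bp must be a multiple of the map resolution")
    a, b = _dense_pair(pred, obs)
    n = a.shape[0]
    fb = fragment_bp // pred.resolution
    wband = band_bp // pred.resolution if band_bp else None
    rows = []
    for k, s in enumerate(range(0, n - fb + 1, fb)):
        sa = _smooth(a[s : s + fb, s : s + fb], smooth_h)
        sb = _smooth(b[s : s + fb, s : s + fb], smooth_h)
        ii, jj = np.triu_indices(fb)
        if wband is not None:
            keep = (jj - ii) <= wband
            ii, jj = ii[keep], jj[keep]
        xa, xb = sa[ii, jj], sb[ii, jj]
        defined = xa.std() > 0 and xb.std() > 0
        rho = float(stats.spearmanr(xa, xb).statistic) if defined else np.nan
        rows.append(
            {
                "fragment": k,
                "start_bp": s * pred.resolution,
                "end_bp": (s + fb) * pred.resolution,
                "rho": rho,
                "defined": defined,
            }
        )
    return pd.DataFrame(rows)


def annotate_fragments(
    scores: pd.DataFrame,
    phastcons: np.ndarray | None = None,
    compartments: np.ndarray | None = None,
    repliseq: np.ndarray | None = None,
) -> pd.DataFrame:
    """Attach conservation tier, A/B compartment, and replication-timing labels.

    ``phastcons``/``repliseq`` are per-fragment values, ``compartments`` per-
    fragment 'A'/'B' labels. Conservation tiers are top 10%, top 10-50%, and
    the rest by rank; timing is early iff the repli-seq value is strictly
    positive (0 counts as late).
    """
    out = scores.copy()
    nf = len(out)
    if phastcons is not None:
        phastcons = np.asarray(phastcons, dtype=float)
        order = np.argsort(-phastcons, kind="stable")
        rank = np.empty(nf, dtype=int)
        rank[order] = np.arange(nf)
        k10 = int(np.ceil(0.1 * nf))
        k50 = int(np.ceil(0.5 * nf))
        tier = np.where(rank < k10, "top10", np.where(rank < k50, "top10_50", "rest"))
        out["conservation"] = tier
    if compartments is not None:
        out["compartment"] = np.asarray(compartments)
    if repliseq is not None:
        out["timing"] = np.where(np.asarray(repliseq, dtype=float) > 0, "early", "late")
    return out


# ---------------------------------------------------------------------------
# compartments
# ---------------------------------------------------------------------------


def call_compartments(
    cmap: ContactMap,
    h3k27ac: np.ndarray,
    method: str = "oe",
) -> np.ndarray:
    """A/B labels per bin from the leading eigenvector of the normalized map.

    The eigenvector is computed on (O/E - 1) (``method='oe'``) or on the
    correlation matrix of the O/E map (``method='corr'``); bins split by the
    eigenvector sign, and the sign group with the higher mean H3K27ac is
    labeled A, making the result invariant to the eigenvector's arbitrary
    sign.
    """
    if cmap.state not in ("oe", "log_oe"):
        raise ValueError("compartment calling expects an O/E-normalized map")
    dense = cmap.to_dense()
    n = dense.shape[0]
    if n < 2:
        raise ValueError("need at least two bins")
    if np.allclose(dense, dense.flat[0]):
        raise ValueError("constant matrix: compartment eigenproblem is degenerate")
    if method == "oe":
        M = dense - 1.0
    elif method == "corr":
        with np.errstate(invalid="ignore"):
            M = np.corrcoef(dense)
        M = np.nan_to_num(M)
    else:
        raise ValueError("method must be 'oe' or 'corr'")
    vals, vecs = np.linalg.eigh(M)
    lead = vecs[:, np.argmax(np.abs(vals))]
    pos = lead >= 0
    h3k27ac = np.asarray(h3k27ac, dtype=float)
    if pos.all() or (~pos).all():
        raise ValueError("leading eigenvector does not split the bins")
    labels = np.where(pos, "A", "B")
    if h3k27ac[~pos].mean() > h3k27ac[pos].mean():
        labels = np.where(pos, "B", "A")
    return labels


# ---------------------------------------------------------------------------
# group comparison
# ---------------------------------------------------------------------------


def group_test(
    scores: pd.DataFrame,
    column: str,
    greater: str,
    lesser: str,
    value: str = "rho",
) -> tuple[float, float]:
    """One-sided Welch t test that ``greater`` group scores exceed ``lesser``.

    Directions follow the biology: A > B compartment, early > late
    replication, higher > lower conservation.
    """
    a = scores.loc[scores[column] == greater, value].dropna().to_numpy()
    b = scores.loc[scores[column] == lesser, value].dropna().to_numpy()
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two defined scores")
    res = stats.ttest_ind(a, b, equal_var=False, alternative="greater")
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# eQTL validation
# ---------------------------------------------------------------------------


def filter_eqtl_pairs(
    table: pd.DataFrame,
    resolution: int = 200,
    max_distance_bp: int = 180_000,
) -> list[EqtlPair]:
    """Bin variant/TSS positions at 200 bp and apply the validation filters.

    Pairs are kept only when (1) variant and TSS are less than 180 kb apart
    (the 200-kb prediction range minus a 20-kb window margin) and (2) the bin
    pair is specific to a single tissue. Malformed rows are rejected and
    logged with their row numbers.
    """
    required = {"chrom", "variant_pos", "tss_pos", "tissue"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"eQTL table missing columns: {sorted(missing)}")
    rows = []
    for idx, row in table.iterrows():
        try:
            vpos, tpos = int(row["variant_pos"]), int(row["tss_pos"])
            tissue = str(row["tissue"])
            if not tissue or tissue == "nan":
                raise ValueError("empty tissue")
        except (TypeError, ValueError):
            logger.warning("rejecting malformed eQTL row %s", idx)
            continue
        dist = abs(vpos - tpos)
        if dist >= max_distance_bp:
            continue
        rows.append(
            dict(
                chrom=str(row["chrom"]),
                variant_bin=vpos // resolution,
                tss_bin=tpos // resolution,
                tissue=tissue,
                distance_bp=dist,
            )
        )
    if not rows:
        return []
    df = pd.DataFrame(rows)
    per_pair = df.groupby(["chrom", "variant_bin", "tss_bin"])["tissue"].nunique()
    specific = per_pair[per_pair == 1].index
    df = df.set_index(["chrom", "variant_bin", "tss_bin"]).loc[specific].reset_index()
    df = df.drop_duplicates(["chrom", "variant_bin", "tss_bin", "tissue"])
    return [EqtlPair(**rec) for rec in df.to_dict("records")]


def eqtl_pileup(
    cmap: ContactMap,
    pairs: list[EqtlPair],
    side: int = 101,
) -> PileupResult:
    """Pile up 101 x 101 regions centered at each variant-TSS pixel."""
    centers = [
        (min(p.variant_bin, p.tss_bin), max(p.variant_bin, p.tss_bin))
        for p in pairs
        if p.chrom == cmap.chrom
    ]
    if not centers:
        raise ValueError("no pairs on this map's chromosome")
    return pileup(cmap, centers, side=side)
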