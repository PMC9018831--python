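"""The desk-scale end-to-end benchmark experiment.

Generates a seeded synthetic region, trains the imputation model with the
two-phase sequential procedure, imputes the region from the degraded Hi-C +
tracks, and scores the result against the planted truth: band MSE reduction,
SCC against the truth versus the interpolated-Hi-C baseline, and planted
loop/stripe recovery from the imputed versus the input map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from . import synthetic
from .core_data import ContactMap
from .evaluation import scc
from .model import ImputationResults, MicrocImputationModel, ModelConfig
from .preprocess import extract_windows, interpolate_contacts, stitch_predictions
from .structures import call_loops, call_stripes, match_calls, pool_to_1kb

__all__ = ["EndToEndResult", "run_end_to_end", "truth_log1p_band", "interpolated_baseline"]


def truth_log1p_band(ds: synthetic.SyntheticDataset) -> ContactMap:
    """Planted truth as a log1p band map on the 200-bp grid."""
    coo = ds.truth.upper_coo()
    keep = (coo.col - coo.row) <= ds.band_bp // ds.truth.resolution
    mat = sp.coo_matrix(
        (np.log1p(coo.data[keep]), (coo.row[keep], coo.col[keep])), shape=coo.shape
    )
    return ContactMap(ds.truth.chrom, ds.truth.resolution, mat, state="log1p",
                      n_bins=ds.truth.n_bins)


def interpolated_baseline(ds: synthetic.SyntheticDataset) -> ContactMap:
    """The no-model baseline: depth-matched interpolated input Hi-C.

    Each 1-kb Hi-C count is spread over its 25 fine pixels, rescaled to the
    truth map's depth, bilinearly interpolated to 200 bp window by window,
    log1p-transformed, and stitched exactly like model predictions.
    """
    L = ds.spec.region_length_bp
    cres = ds.hic.resolution
    f2 = (cres // ds.truth.resolution) ** 2
    scale = ds.truth.total_contacts / ds.hic.total_contacts
    preds = []
    for start_bp, _ in extract_windows(L, ds.window_bp, ds.step_bp):
        c0, c1 = start_bp // cres, (start_bp + ds.window_bp) // cres
        fine = interpolate_contacts(ds.hic.slice_bins(c0, c1), ds.truth.resolution)
        preds.append((start_bp, np.log1p(fine.to_dense() * scale / f2)))
    return stitch_predictions(preds, ds.truth.chrom, L, ds.band_bp,
                              resolution=ds.truth.resolution, state="log1p")


@dataclass
class EndToEndResult:
    """Everything the end-to-end experiment measured, plus the objects."""

    metrics: dict
    model: MicrocImputationModel
    fit: ImputationResults
    dataset: synthetic.SyntheticDataset
    imputed: ContactMap
    baseline: ContactMap
    truth_log: ContactMap


def run_end_to_end(
    seed: int,
    n_windows: int = 100,
    epochs_loop: int = 10,
    epochs_profile: int = 25,
    match_tolerance_bp: int = 5000,
) -> EndToEndResult:
    """Run the full pipeline on one seeded synthetic region."""
    spec = synthetic.SyntheticSpec.benchmark(seed)
    ds = synthetic.make_dataset(spec, n_windows)
    cfg = ModelConfig(
        feature_names=tuple(synthetic.FEATURES_6EPI),
        window_bp=ds.window_bp, step_bp=ds.step_bp, band_bp=ds.band_bp, seed=seed,
    )
    model = MicrocImputationModel(cfg)
    fit = model.fit(ds.train, ds.truth_loops,
                    epochs_loop=epochs_loop, epochs_profile=epochs_profile, seed=seed)

    imputed = model.impute(ds.hic, ds.tracks, spec.chrom, spec.region_length_bp)
    baseline = interpolated_baseline(ds)
    truth_log = truth_log1p_band(ds)

    scc_imp = scc(imputed, truth_log, max_distance_bp=ds.band_bp).scc
    scc_base = scc(baseline, truth_log, max_distance_bp=ds.band_bp).scc

    n_loops = len(ds.truth_loops)
    n_stripes = len(ds.truth_stripes)
    loops_imp = call_loops(pool_to_1kb(imputed), max_distance_bp=ds.band_bp)
    loops_hic = call_loops(ds.hic, max_distance_bp=ds.band_bp)
    v_imp = match_calls(ds.truth_loops, loops_imp, tolerance_bp=match_tolerance_bp)
    v_hic = match_calls(ds.truth_loops, loops_hic, tolerance_bp=match_tolerance_bp)
    stripes_imp = call_stripes(pool_to_1kb(imputed), max_distance_bp=ds.band_bp)
    vs_imp = match_calls(ds.truth_stripes, stripes_imp, tolerance_bp=match_tolerance_bp)

    # caller benchmark directly on the observed (truth) Micro-C map
    truth_1kb = pool_to_1kb(ds.truth)
    loops_obs = call_loops(truth_1kb, max_distance_bp=ds.band_bp)
    stripes_obs = call_stripes(truth_1kb, max_distance_bp=ds.band_bp)
    v_obs = match_calls(ds.truth_loops, loops_obs, tolerance_bp=match_tolerance_bp)
    vs_obs = match_calls(ds.truth_stripes, stripes_obs, tolerance_bp=match_tolerance_bp)

    from .preprocess import oe_normalize
    from .structures import pileup

    # pile-up enrichment is judged on the distance-normalized (O/E) map
    centers = [(c.anchor1[0], c.anchor2[0]) for c in ds.truth_loops]
    pile = pileup(pool_to_1kb(oe_normalize(ds.truth)), centers, side=21)
    ring = np.concatenate([
        pile.matrix[0, :], pile.matrix[-1, :], pile.matrix[:, 0], pile.matrix[:, -1]
    ])

    metrics = {
        "initial_band_mse": fit.initial_band_mse,
        "final_band_mse": fit.final_band_mse,
        "band_mse_reduction_pct": 100.0 * fit.mse_reduction,
        "scc_imputed": scc_imp,
        "scc_input_hic": scc_base,
        "loop_recall_imputed_pct": 100.0 * v_imp["both"] / n_loops,
        "loop_recall_input_hic_pct": 100.0 * v_hic["both"] / n_loops,
        "stripe_recall_imputed_pct": 100.0 * vs_imp["both"] / n_stripes,
        "loop_recall_observed_pct": 100.0 * v_obs["both"] / n_loops,
        "loop_false_positives_observed": float(v_obs["b_only"]),
        "stripe_recall_observed_pct": 100.0 * vs_obs["both"] / n_stripes,
        "pileup_center_to_ring_ratio": pile.center_score / float(ring.mean()),
        "n_loops_planted": n_loops,
        "n_stripes_planted": n_stripes,
    }
    return EndToEndResult(
        metrics=metrics, model=model, fit=fit, dataset=ds,
        imputed=imputed, baseline=baseline, truth_log=truth_log,
    )
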