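"""The imputation network F: R^{m x n} -> R^{n x n} and its training loop.

Architecture. Epigenomic signals (plus a sinusoidal positional encoding) feed
two parallel trunks: a stack of 1D convolutions extracting local patterns
along the chromatin fiber, and a stack of graph convolutions extracting
spatial patterns over the Hi-C contact graph. The per-bin hidden vectors are
the concatenation of both trunk outputs and feed two output heads:

* a fully connected *profile head* predicting, for bin i, its contact
  profile to bins i-w..i+w (w = band / 200); the resulting matrix is
  symmetrized by averaging the i->j and j->i predictions;
* an *inner-product loop head* mapping hidden vectors to embeddings E and
  predicting focal contacts as ReLU(E E^T).

The two head outputs are summed, masked to the prediction band, and trained
against log1p Micro-C counts by MSE with Adam, sequentially: first the loop
head (targets restricted to 10 kb x 10 kb squares centered at known loops),
then the profile head against the residual map (target minus the frozen loop
component).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import scipy.sparse as sp

from . import nn
from .core_data import BinTrack, ContactMap, StructureCall
from .preprocess import (
    WindowSample,
    band_mask,
    build_graph,
    extract_windows,
    interpolate_contacts,
    oe_normalize,
    stitch_predictions,
)

__all__ = [
    "ModelConfig",
    "MicrocImputationModel",
    "ImputationResults",
    "TrainState",
    "ConfigurationError",
]

LOOP_SQUARE_BP = 10_000  # side of the training mask square centered at a loop


class ConfigurationError(ValueError):
    pass


@dataclass
class ModelConfig:
    """Hyperparameters of the imputation network.

    Defaults are the smallest stack that exercises both trunks: two 1D conv
    layers (kernels 11 and 5 bins, 32 -> 64 channels), two 64-unit GCN
    layers, a 128-dim concatenated hidden vector, and a 64-dim loop
    embedding.
    """

    feature_names: tuple[str, ...]
    window_bp: int = 250_000
    step_bp: int = 50_000
    band_bp: int = 200_000
    resolution: int = 200
    encoding_dim: int = 8
    conv_channels: tuple[int, int] = (32, 64)
    conv_kernels: tuple[int, int] = (11, 5)
    gcn_units: tuple[int, int] = (64, 64)
    embed_dim: int = 64
    lr: float = 1e-3
    betas: tuple[float, float] = (0.9, 0.999)
    activation: str = "relu"  # "relu" | "identity" (identity gives a linear map)
    grad_clip: float | None = 5.0
    train_trunk_in_loop_phase: bool = True
    train_trunk_in_profile_phase: bool = False
    seed: int = 0

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    @property
    def input_dim(self) -> int:
        return self.n_features + self.encoding_dim

    @property
    def hidden_dim(self) -> int:
        return self.conv_channels[-1] + self.gcn_units[-1]

    @property
    def band_bins(self) -> int:
        return self.band_bp // self.resolution


@dataclass
class TrainState:
    """Bookkeeping for the sequential training procedure."""

    phase: str                      # "loop" | "profile"
    epoch: int
    history: list[dict] = field(default_factory=list)
    seed: int = 0


class MicrocImputationModel:
    """Contact-map imputation model (build, then ``fit`` on window samples)."""

    PROFILE_PARAMS = {"prof_W", "prof_b"}
    LOOP_PARAMS = {"loop_W", "loop_b"}

    def __init__(self, config: ModelConfig):
        self.config = config
        self.params = self._init_params(np.random.default_rng(config.seed))
        self.trained_phases: list[str] = []

    # ------------------------------------------------------------------
    # parameters
    # ------------------------------------------------------------------

    def _init_params(self, rng: np.random.Generator) -> dict[str, np.ndarray]:
        cfg = self.config
        F = cfg.input_dim
        c1, c2 = cfg.conv_channels
        k1, k2 = cfg.conv_kernels
        g1, g2 = cfg.gcn_units
        h = cfg.hidden_dim
        w = cfg.band_bins
        d = cfg.embed_dim

        def he(shape, fan_in):
            return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)

        return {
            "conv0_W": he((c1, F, k1), F * k1),
            "conv0_b": np.zeros(c1),
            "conv1_W": he((c2, c1, k2), c1 * k2),
            "conv1_b": np.zeros(c2),
            "gcn0_W": he((F, g1), F),
            "gcn0_b": np.zeros(g1),
            "gcn1_W": he((g1, g2), g1),
            "gcn1_b": np.zeros(g2),
            "prof_W": he((h, 2 * w + 1), h) * 0.1,
            "prof_b": np.zeros(2 * w + 1),
            "loop_W": he((h, d), h) * 0.1,
            "loop_b": np.zeros(d),
        }

    @property
    def trunk_params(self) -> set[str]:
        return set(self.params) - self.PROFILE_PARAMS - self.LOOP_PARAMS

    # ------------------------------------------------------------------
    # forward / backward
    # ------------------------------------------------------------------

    def _a_hat(self, graph) -> sp.csr_matrix:
        a_hat = getattr(graph, "_a_hat", None)
        if a_hat is None:
            a_hat = nn.normalize_adjacency(graph.adjacency)
            graph._a_hat = a_hat
        return a_hat

    def _act(self, Z: np.ndarray) -> np.ndarray:
        return nn.relu(Z) if self.config.activation == "relu" else Z

    def _act_grad(self, Z: np.ndarray, dOut: np.ndarray) -> np.ndarray:
        return dOut * (Z > 0) if self.config.activation == "relu" else dOut

    def _profile_indices(self, n: int):
        w = self.config.band_bins
        i = np.repeat(np.arange(n), 2 * w + 1).reshape(n, 2 * w + 1)
        j = i + (np.arange(2 * w + 1) - w)[None, :]
        valid = (j >= 0) & (j < n)
        return i, j, valid

    def _forward(self, Xfull: np.ndarray, graph):
        """Full forward pass with cache; Xfull is (m + p) x n node features."""
        cfg = self.config
        p = self.params
        if Xfull.shape[0] != cfg.input_dim:
            raise ConfigurationError(
                f"expected {cfg.input_dim} input rows "
                f"({cfg.n_features} features {list(cfg.feature_names)} "
                f"+ {cfg.encoding_dim} positional); got {Xfull.shape[0]}"
            )
        n = Xfull.shape[1]
        A_hat = self._a_hat(graph)

        Z0, cc0 = nn.conv1d_forward(Xfull, p["conv0_W"], p["conv0_b"])
        A0 = self._act(Z0)
        Z1, cc1 = nn.conv1d_forward(A0, p["conv1_W"], p["conv1_b"])
        A1 = self._act(Z1)                               # (c2, n)

        H0 = Xfull.T                                     # (n, F)
        M0 = A_hat @ H0
        G0z = M0 @ p["gcn0_W"] + p["gcn0_b"]
        G0 = self._act(G0z)
        M1 = A_hat @ G0
        G1z = M1 @ p["gcn1_W"] + p["gcn1_b"]
        G1 = self._act(G1z)                              # (n, g2)

        Hcat = np.concatenate([A1.T, G1], axis=1)        # (n, h)

        P = Hcat @ p["prof_W"] + p["prof_b"]             # (n, 2w+1)
        i_idx, j_idx, valid = self._profile_indices(n)
        S = np.zeros((n, n))
        S[i_idx[valid], j_idx[valid]] = P[valid]
        profile = 0.5 * (S + S.T)

        E = Hcat @ p["loop_W"] + p["loop_b"]             # (n, d)
        Lpre = E @ E.T
        loop = nn.relu(Lpre)

        mask = band_mask(n, cfg.band_bins)
        out = np.where(mask, profile + loop, 0.0)
        cache = dict(
            Xfull=Xfull, A_hat=A_hat, Z0=Z0, cc0=cc0, A0=A0, Z1=Z1, cc1=cc1,
            H0=H0, M0=M0, G0z=G0z, G0=G0, M1=M1, G1z=G1z, G1=G1, Hcat=Hcat,
            P=P, E=E, Lpre=Lpre, mask=mask, n=n,
            profile=np.where(mask, profile, 0.0), loop=np.where(mask, loop, 0.0),
        )
        return out, cache

    def _backward(self, dOut: np.ndarray, cache, heads=("profile", "loop")):
        """Backprop a gradient on the output matrix to params and input.

        Returns (grads dict, dXfull). ``heads`` selects which output heads
        the gradient flows through (the other head is treated as detached).
        """
        cfg = self.config
        p = self.params
        n = cache["n"]
        dOut = np.where(cache["mask"], dOut, 0.0)
        Hcat = cache["Hcat"]
        dHcat = np.zeros_like(Hcat)
        grads: dict[str, np.ndarray] = {}

        if "profile" in heads:
            dS = 0.5 * (dOut + dOut.T)
            i_idx, j_idx, valid = self._profile_indices(n)
            dP = np.zeros_like(cache["P"])
            dP[valid] = dS[i_idx[valid], j_idx[valid]]
            grads["prof_W"] = Hcat.T @ dP
            grads["prof_b"] = dP.sum(axis=0)
            dHcat += dP @ p["prof_W"].T

        if "loop" in heads:
            dLpre = dOut * (cache["Lpre"] > 0)
            dE = (dLpre + dLpre.T) @ cache["E"]
            grads["loop_W"] = Hcat.T @ dE
            grads["loop_b"] = dE.sum(axis=0)
            dHcat += dE @ p["loop_W"].T

        c2 = cfg.conv_channels[-1]
        dA1 = dHcat[:, :c2].T
        dG1 = dHcat[:, c2:]

        # conv trunk
        dZ1 = self._act_grad(cache["Z1"], dA1)
        dA0, dW1, db1 = nn.conv1d_backward(dZ1, cache["cc1"])
        dZ0 = self._act_grad(cache["Z0"], dA0)
        dXconv, dW0, db0 = nn.conv1d_backward(dZ0, cache["cc0"])
        grads.update(conv0_W=dW0, conv0_b=db0, conv1_W=dW1, conv1_b=db1)

        # gcn trunk (A_hat symmetric)
        A_hat = cache["A_hat"]
        dG1z = self._act_grad(cache["G1z"], dG1)
        grads["gcn1_W"] = cache["M1"].T @ dG1z
        grads["gcn1_b"] = dG1z.sum(axis=0)
        dG0 = (A_hat @ dG1z) @ p["gcn1_W"].T
        dG0z = self._act_grad(cache["G0z"], dG0)
        grads["gcn0_W"] = cache["M0"].T @ dG0z
        grads["gcn0_b"] = dG0z.sum(axis=0)
        dH0 = (A_hat @ dG0z) @ p["gcn0_W"].T

        dXfull = dXconv + dH0.T
        return grads, dXfull

    # ------------------------------------------------------------------
    # public forward surface
    # ------------------------------------------------------------------

    def forward(self, sample: WindowSample) -> np.ndarray:
        """Predicted n x n matrix: symmetric, band-limited, sum of both heads."""
        out, _ = self._forward(sample.graph.node_features, sample.graph)
        return out

    def forward_components(self, sample: WindowSample):
        """(total, profile_component, loop_component)."""
        out, cache = self._forward(sample.graph.node_features, sample.graph)
        return out, cache["profile"], cache["loop"]

    def loop_component(self, sample: WindowSample) -> np.ndarray:
        return self.forward_components(sample)[2]

    def residual_target(self, sample: WindowSample) -> np.ndarray:
        """Phase-2 target: observed map minus the (frozen) loop component."""
        if sample.Y is None:
            raise ValueError("sample has no target")
        return sample.Y - self.loop_component(sample)

    # ------------------------------------------------------------------
    # training
    # ------------------------------------------------------------------

    @staticmethod
    def loop_mask_for_window(
        sample: WindowSample, loop_calls: list[StructureCall]
    ) -> np.ndarray:
        """Union of 10 kb x 10 kb squares centered at loop anchor pairs.

        Loop anchors (1-kb calls or finer) are mapped to fine pixels within
        the window; squares are clipped at window edges and intersected with
        the prediction band. Symmetric by construction.
        """
        n = sample.n_bins
        res = sample.resolution
        half = LOOP_SQUARE_BP // (2 * res)
        mask = np.zeros((n, n), dtype=bool)
        for call in loop_calls:
            if call.kind != "loop" or call.chrom != sample.chrom:
                continue
            pi = int(call.midpoint1_bp - sample.start_bp) // res
            pj = int(call.midpoint2_bp - sample.start_bp) // res
            if not (0 <= pi < n and 0 <= pj < n):
                continue
            i0, i1 = max(0, pi - half), min(n, pi + half)
            j0, j1 = max(0, pj - half), min(n, pj + half)
            mask[i0:i1, j0:j1] = True
            mask[j0:j1, i0:i1] = True
        return mask & band_mask(n, sample.band_bins)

    def _masked_mse(self, pred, Y, mask) -> float:
        m = mask.sum()
        return float(((pred - Y) ** 2 * mask).sum() / m) if m else 0.0

    def train_loop_branch(
        self,
        dataset: list[WindowSample],
        loop_calls: list[StructureCall],
        epochs: int = 20,
        seed: int = 0,
        callback=None,
    ) -> TrainState:
        """Phase 1: fit the loop head (and optionally the trunk) on loop squares."""
        if "loop" in self.trained_phases:
            raise RuntimeError("loop phase already trained")
        masks = [self.loop_mask_for_window(s, loop_calls) for s in dataset]
        usable = [k for k, m in enumerate(masks) if m.any()]
        if not usable:
            raise ValueError("no loops overlap the dataset windows")
        allowed = self.LOOP_PARAMS | (
            self.trunk_params if self.config.train_trunk_in_loop_phase else set()
        )
        opt = nn.Adam(self.params, lr=self.config.lr, betas=self.config.betas)
        rng = np.random.default_rng(seed)
        state = TrainState(phase="loop", epoch=0, seed=seed)
        for epoch in range(epochs):
            order = rng.permutation(usable)
            losses = []
            for k in order:
                s = dataset[k]
                out, cache = self._forward(s.graph.node_features, s.graph)
                L = cache["loop"]
                m = masks[k]
                loss = self._masked_mse(L, s.Y, m)
                dOut = 2.0 * (L - s.Y) * m / m.sum()
                grads, _ = self._backward(dOut, cache, heads=("loop",))
                opt.step(grads, only=allowed, max_norm=self.config.grad_clip)
                losses.append(loss)
            state.epoch = epoch + 1
            rec = {"phase": "loop", "epoch": epoch + 1, "mse": float(np.mean(losses))}
            state.history.append(rec)
            if callback:
                callback(rec)
        self.trained_phases.append("loop")
        return state

    def train_profile_branch(
        self,
        dataset: list[WindowSample],
        epochs: int = 30,
        seed: int = 1,
        callback=None,
    ) -> TrainState:
        """Phase 2: fit the profile head + trunk on the residual map.

        The loop head is frozen and the residual targets (Y minus the loop
        component) are computed once with the phase-1-final parameters, so
        the profile part is fitted against a fixed residual contact map.
        """
        if "loop" not in self.trained_phases:
            raise RuntimeError("profile phase requires the loop phase first")
        if "profile" in self.trained_phases:
            raise RuntimeError("profile phase already trained")
        opt = nn.Adam(self.params, lr=self.config.lr, betas=self.config.betas)
        allowed = self.PROFILE_PARAMS | (
            self.trunk_params if self.config.train_trunk_in_profile_phase else set()
        )
        rng = np.random.default_rng(seed)
        state = TrainState(phase="profile", epoch=0, seed=seed)
        usable = [k for k, s in enumerate(dataset) if s.Y is not None]
        if not usable:
            raise ValueError("no targets in dataset")
        residuals = {k: self.residual_target(dataset[k]) for k in usable}
        for epoch in range(epochs):
            order = rng.permutation(usable)
            losses = []
            for k in order:
                s = dataset[k]
                out, cache = self._forward(s.graph.node_features, s.graph)
                prof = cache["profile"]
                m = cache["mask"]
                R = residuals[k]
                loss = self._masked_mse(prof, R, m)
                dOut = 2.0 * (prof - R) * m / m.sum()
                grads, _ = self._backward(dOut, cache, heads=("profile",))
                opt.step(grads, only=allowed, max_norm=self.config.grad_clip)
                losses.append(loss)
            state.epoch = epoch + 1
            rec = {"phase": "profile", "epoch": epoch + 1, "mse": float(np.mean(losses))}
            state.history.append(rec)
            if callback:
                callback(rec)
        self.trained_phases.append("profile")
        return state

    def band_mse(self, dataset: list[WindowSample]) -> float:
        """Band-masked MSE of the full model over a dataset."""
        losses = []
        for s in dataset:
            if s.Y is None:
                continue
            out, cache = self._forward(s.graph.node_features, s.graph)
            losses.append(self._masked_mse(out, s.Y, cache["mask"]))
        return float(np.mean(losses))

    def fit(
        self,
        dataset: list[WindowSample],
        loop_calls: list[StructureCall],
        epochs_loop: int = 20,
        epochs_profile: int = 30,
        seed: int = 0,
        callback=None,
    ) -> "ImputationResults":
        """Two-phase sequential training; returns a results object."""
        initial_mse = self.band_mse(dataset)
        st1 = self.train_loop_branch(dataset, loop_calls, epochs=epochs_loop, seed=seed,
                                     callback=callback)
        st2 = self.train_profile_branch(dataset, epochs=epochs_profile, seed=seed + 1,
                                        callback=callback)
        final_mse = self.band_mse(dataset)
        return ImputationResults(
            model=self,
            history=st1.history + st2.history,
            initial_band_mse=initial_mse,
            final_band_mse=final_mse,
        )

    # ------------------------------------------------------------------
    # imputation pipeline
    # ------------------------------------------------------------------

    def prepare_window(
        self,
        oe_hic: ContactMap,
        tracks: dict[str, BinTrack],
        chrom: str,
        start_bp: int,
        Y: np.ndarray | None = None,
    ) -> WindowSample:
        """Build one model-ready window from an O/E Hi-C map and tracks."""
        cfg = self.config
        missing = [f for f in cfg.feature_names if f not in tracks]
        if missing:
            raise ConfigurationError(f"missing required tracks: {missing}")
        cres = oe_hic.resolution
        if start_bp % cres or cfg.window_bp % cres:
            raise ValueError("window must align with the coarse Hi-C grid")
        c0, c1 = start_bp // cres, (start_bp + cfg.window_bp) // cres
        fine = interpolate_contacts(oe_hic.slice_bins(c0, c1), cfg.resolution)
        b0 = start_bp // cfg.resolution
        n = cfg.window_bp // cfg.resolution
        X = np.vstack(
            [tracks[f].slice_bins(b0, b0 + n).values for f in cfg.feature_names]
        )
        graph = build_graph(fine, X, encoding_dim=cfg.encoding_dim)
        return WindowSample(
            chrom=chrom,
            start_bp=start_bp,
            window_bp=cfg.window_bp,
            X=X,
            graph=graph,
            band_bp=cfg.band_bp,
            Y=Y,
            feature_names=cfg.feature_names,
            resolution=cfg.resolution,
        )

    def impute(
        self,
        hic: ContactMap,
        tracks: dict[str, BinTrack],
        chrom: str,
        chrom_length: int | None = None,
    ) -> ContactMap:
        """Preprocess -> per-window forward -> stitch; log1p-scale band map."""
        cfg = self.config
        if chrom_length is None:
            chrom_length = hic.n_bins * hic.resolution
        oe = oe_normalize(hic) if hic.state == "raw" else hic
        windows = extract_windows(chrom_length, cfg.window_bp, cfg.step_bp)
        preds = []
        for start_bp, _ in windows:
            sample = self.prepare_window(oe, tracks, chrom, start_bp)
            preds.append((start_bp, self.forward(sample)))
        return stitch_predictions(
            preds, chrom, chrom_length, cfg.band_bp, resolution=cfg.resolution,
            state="log1p",
        )

    # ------------------------------------------------------------------
    # checkpointing
    # ------------------------------------------------------------------

    def save(self, path: str | Path) -> None:
        cfg = asdict(self.config)
        np.savez(
            path,
            __config__=np.frombuffer(json.dumps(cfg).encode(), dtype=np.uint8),
            __phases__=np.frombuffer(json.dumps(self.trained_phases).encode(), dtype=np.uint8),
            **self.params,
        )

    @classmethod
    def load(cls, path: str | Path) -> "MicrocImputationModel":
        with np.load(path) as data:
            cfg = json.loads(bytes(data["__config__"]).decode())
            phases = json.loads(bytes(data["__phases__"]).decode())
            for key in ("feature_names", "conv_channels", "conv_kernels", "gcn_units", "betas"):
                cfg[key] = tuple(cfg[key])
            model = cls(ModelConfig(**cfg))
            for k in model.params:
                model.params[k] = data[k]
            model.trained_phases = phases
        return model


@dataclass
class ImputationResults:
    """Fit results: trained model, loss history, and summary diagnostics."""

    model: MicrocImputationModel
    history: list[dict]
    initial_band_mse: float
    final_band_mse: float

    @property
    def mse_reduction(self) -> float:
        """Fractional reduction of band MSE relative to initialization."""
        return 1.0 - self.final_band_mse / self.initial_band_mse

    def impute(self, *args, **kwargs) -> ContactMap:
        return self.model.impute(*args, **kwargs)

    def predict(self, sample: WindowSample) -> np.ndarray:
        return self.model.forward(sample)

    def summary(self) -> str:
        cfg = self.model.config
        lines = [
            "Micro-C imputation model fit",
            "=" * 60,
            f"features:        {', '.join(cfg.feature_names)}",
            f"window/step/band: {cfg.window_bp:,} / {cfg.step_bp:,} / {cfg.band_bp:,} bp",
            f"hidden dim:      {cfg.hidden_dim} (conv {cfg.conv_channels}, gcn {cfg.gcn_units})",
            f"loop embedding:  {cfg.embed_dim}",
            f"phases trained:  {' -> '.join(self.model.trained_phases)}",
            f"initial band MSE: {self.initial_band_mse:.6f}",
            f"final band MSE:   {self.final_band_mse:.6f}",
            f"MSE reduction:    {100 * self.mse_reduction:.1f}%",
            "-" * 60,
        ]
        for phase in ("loop", "profile"):
            hist = [h for h in self.history if h["phase"] == phase]
            if hist:
                lines.append(
                    f"{phase:8s} phase: {len(hist)} epochs, "
                    f"MSE {hist[0]['mse']:.6f} -> {hist[-1]['mse']:.6f}"
                )
        return "\n".join(lines)
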