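"""Two-path convolutional classifier with channel attention, in NumPy.

The model maps the five selected environmental predictors of one cell-dekad
to high/low RRA probabilities. A stem convolution lifts the length-5 input
to a 5x16 feature map which splits into two paths: a squeeze-and-excitation
style attention path (global average pooling over the factor axis, a small
fully connected bottleneck, sigmoid gate of one weight per channel) and a
local path of two further convolutions capturing interactions between
neighbouring factors. The paths fuse by element-wise product (each local
channel scaled by its gate), pass one more convolution, and a dense layer
produces two softmax logits.

The network is small enough that forward and backward passes are written
directly with NumPy (im2col convolutions, analytic gradients, Adam), which
keeps training single-threaded and bit-reproducible under a fixed seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

LABELS = ("low", "high")  # class index 0 = low, 1 = high


@dataclass(frozen=True)
class ArchitectureConfig:
    """Shape of the network; defaults give the 5x1x16 stem feature map."""

    n_factors: int = 5
    n_channels: int = 16
    attention_hidden: int = 8
    kernel_size: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kernel_size % 2 != 1:
            raise ValueError("kernel_size must be odd (same-padding)")
        if min(self.n_factors, self.n_channels, self.attention_hidden) < 1:
            raise ValueError("sizes must be positive")


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation budget and logging cadence.

    ``steps`` counts mini-batch gradient updates. The study-scale budget is
    50,000 steps; tests and the worked examples use a reduced budget, which
    the loss curves show is already past the plateau for synthetic data.
    """

    steps: int = 50_000
    batch_size: int = 64
    learning_rate: float = 1e-3
    val_fraction: float = 0.2
    eval_interval: int = 250
    seed: int = 0

    def __post_init__(self) -> None:
        if self.steps <= 0:
            raise ValueError("steps must be positive")
        if not 0.0 < self.val_fraction < 1.0:
            raise ValueError("val_fraction must be in (0, 1)")


def _conv1d_forward(x: np.ndarray, W: np.ndarray, b: np.ndarray):
    """Same-padded 1-D convolution. x: (B, Cin, L), W: (Cout, Cin, K)."""
    B, Cin, L = x.shape
    Cout, _, K = W.shape
    pad = K // 2
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad)))
    cols = np.stack([xp[:, :, k : k + L] for k in range(K)], axis=3)  # B,Cin,L,K
    cols = cols.transpose(0, 2, 1, 3).reshape(B, L, Cin * K)
    out = cols @ W.reshape(Cout, -1).T + b  # B,L,Cout
    return out.transpose(0, 2, 1), (x.shape, cols, W)


def _conv1d_backward(dout: np.ndarray, cache):
    (B, Cin, L), cols, W = cache
    Cout, _, K = W.shape
    d = dout.transpose(0, 2, 1).reshape(-1, Cout)  # B*L, Cout
    dW = (d.T @ cols.reshape(-1, Cin * K)).reshape(Cout, Cin, K)
    db = d.sum(axis=0)
    dcols = (d @ W.reshape(Cout, -1)).reshape(B, L, Cin, K)
    pad = K // 2
    dxp = np.zeros((B, Cin, L + 2 * pad))
    for k in range(K):
        dxp[:, :, k : k + L] += dcols[:, :, :, k].transpose(0, 2, 1)
    return dxp[:, :, pad : pad + L], dW, db


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class AttentionCNN:
    """Forward/backward network; parameters live in a flat dict of arrays."""

    def __init__(self, cfg: ArchitectureConfig | None = None):
        self.cfg = cfg or ArchitectureConfig()
        c, h, k = self.cfg.n_channels, self.cfg.attention_hidden, self.cfg.kernel_size
        rng = np.random.default_rng(self.cfg.seed)

        def he(*shape):
            fan_in = int(np.prod(shape[1:])) if len(shape) > 1 else shape[0]
            return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)

        L = self.cfg.n_factors
        self.params: dict[str, np.ndarray] = {
            "W_stem": he(c, 1, k), "b_stem": np.zeros(c),
            "W_att1": he(h, c), "b_att1": np.zeros(h),
            "W_att2": he(c, h), "b_att2": np.zeros(c),
            "W_loc1": he(c, c, k), "b_loc1": np.zeros(c),
            "W_loc2": he(c, c, k), "b_loc2": np.zeros(c),
            "W_head": he(c, c, k), "b_head": np.zeros(c),
            "W_fc": he(2, c * L), "b_fc": np.zeros(2),
        }

    # ---- forward -----------------------------------------------------
    def forward(self, x: np.ndarray, gate_override: np.ndarray | None = None):
        """Class probabilities for a (B, n_factors) batch.

        ``gate_override`` replaces the attention gate by a fixed per-channel
        vector (used to verify the fusion wiring: an all-ones gate reduces
        the fused map to the local path; a zeroed channel silences it).
        Returns (probs, cache).
        """
        p = self.params
        x = np.asarray(x, dtype=float)
        if x.ndim != 2 or x.shape[1] != self.cfg.n_factors:
            raise ValueError(f"expected (B, {self.cfg.n_factors}) input, got {x.shape}")
        B = x.shape[0]

        h0_pre, c_stem = _conv1d_forward(x[:, None, :], p["W_stem"], p["b_stem"])
        h0 = np.maximum(h0_pre, 0.0)  # (B, C, L)

        # attention path: GAP -> FC -> relu -> FC -> sigmoid gate
        gap = h0.mean(axis=2)  # (B, C)
        a1_pre = gap @ p["W_att1"].T + p["b_att1"]
        a1 = np.maximum(a1_pre, 0.0)
        gate_pre = a1 @ p["W_att2"].T + p["b_att2"]
        gate = _sigmoid(gate_pre)  # (B, C)
        if gate_override is not None:
            gate = np.broadcast_to(np.asarray(gate_override, dtype=float), gate.shape)

        # local path: two convolutions
        l1_pre, c_loc1 = _conv1d_forward(h0, p["W_loc1"], p["b_loc1"])
        l1 = np.maximum(l1_pre, 0.0)
        l2_pre, c_loc2 = _conv1d_forward(l1, p["W_loc2"], p["b_loc2"])
        l2 = np.maximum(l2_pre, 0.0)

        fused = l2 * gate[:, :, None]

        hh_pre, c_head = _conv1d_forward(fused, p["W_head"], p["b_head"])
        hh = np.maximum(hh_pre, 0.0)
        flat = hh.reshape(B, -1)
        logits = flat @ p["W_fc"].T + p["b_fc"]
        z = logits - logits.max(axis=1, keepdims=True)
        ez = np.exp(z)
        probs = ez / ez.sum(axis=1, keepdims=True)

        cache = {
            "x": x, "h0_pre": h0_pre, "h0": h0, "c_stem": c_stem,
            "gap": gap, "a1_pre": a1_pre, "a1": a1, "gate": gate,
            "override": gate_override is not None,
            "l1_pre": l1_pre, "c_loc1": c_loc1, "l2_pre": l2_pre, "c_loc2": c_loc2,
            "l2": l2, "fused": fused, "hh_pre": hh_pre, "c_head": c_head,
            "flat": flat, "probs": probs,
        }
        return probs, cache

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)[0]

    # ---- backward ----------------------------------------------------
    def loss_and_grads(self, x: np.ndarray, y_idx: np.ndarray):
        """Mean cross-entropy and analytic gradients for a batch."""
        p = self.params
        probs, c = self.forward(x)
        B = len(y_idx)
        eps = 1e-12
        loss = float(-np.log(probs[np.arange(B), y_idx] + eps).mean())

        grads = {k: np.zeros_like(v) for k, v in p.items()}
        dlogits = probs.copy()
        dlogits[np.arange(B), y_idx] -= 1.0
        dlogits /= B

        grads["W_fc"] = dlogits.T @ c["flat"]
        grads["b_fc"] = dlogits.sum(axis=0)
        dflat = dlogits @ p["W_fc"]
        dhh = dflat.reshape(c["hh_pre"].shape) * (c["hh_pre"] > 0)
        dfused, grads["W_head"], grads["b_head"] = _conv1d_backward(dhh, c["c_head"])

        dl2 = dfused * c["gate"][:, :, None]
        dgate = (dfused * c["l2"]).sum(axis=2)

        dl2_pre = dl2 * (c["l2_pre"] > 0)
        dl1, grads["W_loc2"], grads["b_loc2"] = _conv1d_backward(dl2_pre, c["c_loc2"])
        dl1_pre = dl1 * (c["l1_pre"] > 0)
        dh0_local, grads["W_loc1"], grads["b_loc1"] = _conv1d_backward(dl1_pre, c["c_loc1"])

        dh0 = dh0_local
        if not c["override"]:
            dgate_pre = dgate * c["gate"] * (1.0 - c["gate"])
            grads["W_att2"] = dgate_pre.T @ c["a1"]
            grads["b_att2"] = dgate_pre.sum(axis=0)
            da1 = dgate_pre @ p["W_att2"]
            da1_pre = da1 * (c["a1_pre"] > 0)
            grads["W_att1"] = da1_pre.T @ c["gap"]
            grads["b_att1"] = da1_pre.sum(axis=0)
            dgap = da1_pre @ p["W_att1"]
            dh0 = dh0 + dgap[:, :, None] / self.cfg.n_factors

        dh0_pre = dh0 * (c["h0_pre"] > 0)
        _, grads["W_stem"], grads["b_stem"] = _conv1d_backward(dh0_pre, c["c_stem"])
        return loss, grads


@dataclass
class TrainingCurves:
    """Aligned per-logged-step train/validation accuracy and loss."""

    frame: pd.DataFrame = field(default_factory=pd.DataFrame)

    def append(self, step, train_acc, train_loss, val_acc, val_loss) -> None:
        row = pd.DataFrame(
            [
                {
                    "step": step,
                    "train_acc": train_acc,
                    "train_loss": train_loss,
                    "val_acc": val_acc,
                    "val_loss": val_loss,
                }
            ]
        )
        self.frame = row if self.frame.empty else pd.concat([self.frame, row], ignore_index=True)


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float):
        self.lr = lr
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-8
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for k in params:
            g = grads[k]
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            params[k] -= self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)


def _stratified_split(y_idx: np.ndarray, val_fraction: float, rng: np.random.Generator):
    tr, va = [], []
    for cls in np.unique(y_idx):
        idx = np.flatnonzero(y_idx == cls)
        idx = rng.permutation(idx)
        n_val = max(1, int(round(val_fraction * len(idx))))
        va.append(idx[:n_val])
        tr.append(idx[n_val:])
    return np.sort(np.concatenate(tr)), np.sort(np.concatenate(va))


def _eval(model: AttentionCNN, x: np.ndarray, y_idx: np.ndarray) -> tuple[float, float]:
    probs = model.predict_proba(x)
    acc = float((probs.argmax(axis=1) == y_idx).mean())
    loss = float(-np.log(probs[np.arange(len(y_idx)), y_idx] + 1e-12).mean())
    return acc, loss


def train(
    model: AttentionCNN,
    X: np.ndarray,
    labels: Sequence[str],
    tcfg: TrainConfig | None = None,
) -> tuple[AttentionCNN, TrainingCurves]:
    """Minimise cross-entropy by Adam over mini-batches; log curves.

    ``X`` must already be scaled to [0, 1] with scalers fitted on training
    rows (see :class:`RRAClassifier` for the managed pipeline). An 80/20
    stratified split (by default) provides the validation curves. Training
    aborts on a non-finite loss, reporting the step.
    """
    tcfg = tcfg or TrainConfig()
    X = np.asarray(X, dtype=float)
    y_idx = np.array([LABELS.index(l) for l in labels], dtype=int)
    if len(np.unique(y_idx)) < 2:
        raise ValueError("need both classes present")
    rng = np.random.default_rng(tcfg.seed)
    tr, va = _stratified_split(y_idx, tcfg.val_fraction, rng)
    if len(np.unique(y_idx[tr])) < 2 or len(np.unique(y_idx[va])) < 2:
        raise ValueError("a split half lost a class; provide more rows")

    opt = _Adam(model.params, tcfg.learning_rate)
    curves = TrainingCurves()
    Xtr, ytr = X[tr], y_idx[tr]
    Xva, yva = X[va], y_idx[va]
    for step in range(1, tcfg.steps + 1):
        batch = rng.integers(0, len(tr), size=min(tcfg.batch_size, len(tr)))
        loss, grads = model.loss_and_grads(Xtr[batch], ytr[batch])
        if not np.isfinite(loss):
            raise FloatingPointError(f"training diverged at step {step}")
        opt.step(model.params, grads)
        if step % tcfg.eval_interval == 0 or step == tcfg.steps:
            ta, tl = _eval(model, Xtr, ytr)
            vaa, vl = _eval(model, Xva, yva)
            curves.append(step, ta, tl, vaa, vl)
    return model, curves


@dataclass
class RRAClassifier:
    """Trained model bundle: factors, min-max scalers, network weights."""

    factors: tuple[str, ...]
    model: AttentionCNN
    scaler_min: np.ndarray
    scaler_range: np.ndarray

    @classmethod
    def fit(
        cls,
        features: pd.DataFrame,
        factors: Sequence[str],
        acfg: ArchitectureConfig | None = None,
        tcfg: TrainConfig | None = None,
    ) -> tuple["RRAClassifier", TrainingCurves]:
        """Scale the selected factors (fit on training rows only) and train."""
        tcfg = tcfg or TrainConfig()
        acfg = acfg or ArchitectureConfig(n_factors=len(factors))
        if acfg.n_factors != len(factors):
            raise ValueError("architecture n_factors must match the factor list")
        X_raw = features[list(factors)].to_numpy(dtype=float)
        if not np.isfinite(X_raw).all():
            raise ValueError("feature rows must be complete in the selected factors")
        y_idx = np.array([LABELS.index(l) for l in features["rra_label"]])
        rng = np.random.default_rng(tcfg.seed)
        tr, _ = _stratified_split(y_idx, tcfg.val_fraction, rng)
        mins = X_raw[tr].min(axis=0)
        ranges = X_raw[tr].max(axis=0) - mins
        ranges = np.where(ranges > 0, ranges, 1.0)
        X = (X_raw - mins) / ranges
        model = AttentionCNN(acfg)
        model, curves = train(model, X, list(features["rra_label"]), tcfg)
        return cls(tuple(factors), model, mins, ranges), curves

    def transform(self, features: pd.DataFrame) -> np.ndarray:
        X = features[list(self.factors)].to_numpy(dtype=float)
        if not np.isfinite(X).all():
            raise ValueError("feature rows must be complete in the selected factors")
        return (X - self.scaler_min) / self.scaler_range

    def predict_map(self, features: pd.DataFrame) -> pd.DataFrame:
        """Per cell-dekad label and probability pair for a feature table."""
        probs = self.model.predict_proba(self.transform(features))
        out = features[["i", "j", "dekad"]].copy()
        out["prob_high"] = probs[:, 1]
        out["prob_low"] = probs[:, 0]
        out["pred_label"] = np.where(probs[:, 1] > probs[:, 0], "high", "low")
        return out

    # ---- persistence ---------------------------------------------------
    def save(self, path) -> None:
        meta = {
            "factors": list(self.factors),
            "cfg": self.model.cfg.__dict__,
        }
        np.savez(
            path,
            meta=json.dumps(meta),
            scaler_min=self.scaler_min,
            scaler_range=self.scaler_range,
            **{f"param_{k}": v for k, v in self.model.params.items()},
        )

    @classmethod
    def load(cls, path) -> "RRAClassifier":
        with np.load(path, allow_pickle=False) as z:
            meta = json.loads(str(z["meta"]))
            model = AttentionCNN(ArchitectureConfig(**meta["cfg"]))
            for k in model.params:
                model.params[k] = z[f"param_{k}"]
            return cls(
                tuple(meta["factors"]), model, z["scaler_min"], z["scaler_range"]
            )
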