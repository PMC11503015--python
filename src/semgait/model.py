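"""The three-branch CNN-GRU network with fusion and two task heads.

Branch 1 (time series): the standardized 320 x 8 sEMG window goes through two
valid 1-D convolutions (kernel 3, stride 1), each followed by ReLU and max
pooling of 2, then a three-layer GRU whose final hidden state is the branch
embedding.  Length arithmetic for a 320-sample window:
320 -> 318 (conv) -> 159 (pool) -> 157 (conv) -> 78 (pool).

Branch 2 (spectrogram): the 9 x 9 x 8 STFT tensor goes through one valid 2-D
convolution (3 x 3, stride 2; 9 -> 4 per axis), ReLU, 2 x 2 max pooling
(4 -> 2) and is flattened.

Branch 3 (time-domain matrix): the 5 x 8 feature matrix is read by a
three-layer GRU with the 5 feature rows as time steps and the 8 channels as
input dimensions.

The three embeddings are concatenated (in that fixed order) and fed to two
fully separate fully-connected heads: a 4-way softmax gait classifier and a
3-output linear joint-angle regressor (degrees, no terminal nonlinearity).

Training minimizes  L = CE(gait) + lambda * MSE(angles);  the default
lambda = 0.1 balances the O(1) cross-entropy against squared-degree errors of
order 10^2 early in training.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from . import nn
from .errors import ConfigurationError, DataError

__all__ = ["ModelConfig", "ModelOutput", "MultiBranchNet", "multitask_loss"]


@dataclass(frozen=True)
class ModelConfig:
    """Architecture widths and the loss weighting.

    Kernel sizes, strides, pooling and layer counts are fixed by the
    architecture; the widths here only size the embeddings and are chosen so
    the default synthetic study trains in minutes on one CPU core.
    """

    window_samples: int = 320
    n_channels: int = 8
    spec_shape: tuple[int, int, int] = (9, 9, 8)
    td_rows: int = 5
    conv1d_channels: tuple[int, int] = (32, 64)
    conv2d_channels: int = 32
    gru_hidden: int = 64
    fc_hidden: int = 128
    n_classes: int = 4
    n_angles: int = 3
    loss_lambda: float = 0.1

    def validate(self) -> None:
        # two conv(k3,s1)+pool(2) stages must leave at least one time step
        t = self.window_samples
        for _ in range(2):
            t = (t - 2) // 2
        if t < 1:
            raise ConfigurationError(
                f"window of {self.window_samples} samples does not survive the "
                "two conv+pool stages"
            )
        if min(self.spec_shape[:2]) < 3:
            raise ConfigurationError("spectrogram too small for a 3x3 convolution")


@dataclass
class ModelOutput:
    """Per-window prediction: gait class probabilities and joint angles."""

    gait_probs: np.ndarray  # (B, 4), rows sum to 1
    angles: np.ndarray      # (B, 3) degrees


class MultiBranchNet:
    """Three-branch multi-task network; weights initialized from ``seed``."""

    def __init__(self, cfg: ModelConfig = ModelConfig(), seed: int = 0) -> None:
        cfg.validate()
        self.cfg = cfg
        self.seed = int(seed)
        rng = np.random.default_rng(np.random.SeedSequence([self.seed & 0x7FFFFFFF, 101]))
        c1, c2 = cfg.conv1d_channels
        h = cfg.gru_hidden
        self.conv_stack = nn.Sequential(
            nn.Conv1d(cfg.n_channels, c1, rng), nn.ReLU(), nn.MaxPool1d(2),
            nn.Conv1d(c1, c2, rng), nn.ReLU(), nn.MaxPool1d(2),
        )
        self.gru1 = nn.GRUStack(c2, h, rng)
        self.branch2 = nn.Sequential(
            nn.Conv2d(cfg.spec_shape[2], cfg.conv2d_channels, rng, kernel=3, stride=2),
            nn.ReLU(), nn.MaxPool2d(2), nn.Flatten(),
        )
        sh = (cfg.spec_shape[0] - 3) // 2 + 1
        sw = (cfg.spec_shape[1] - 3) // 2 + 1
        flat2 = (sh // 2) * (sw // 2) * cfg.conv2d_channels
        self.gru3 = nn.GRUStack(cfg.n_channels, h, rng)
        fused = h + flat2 + h
        self._dims = {"embed1": h, "embed2": flat2, "embed3": h, "fused": fused}
        self.gait_head = nn.Sequential(
            nn.Dense(fused, cfg.fc_hidden, rng), nn.ReLU(),
            nn.Dense(cfg.fc_hidden, cfg.n_classes, rng),
        )
        self.angle_head = nn.Sequential(
            nn.Dense(fused, cfg.fc_hidden, rng), nn.ReLU(),
            nn.Dense(cfg.fc_hidden, cfg.n_angles, rng),
        )
        self._audit_shapes()

    # -- plumbing -----------------------------------------------------------

    def _audit_shapes(self) -> None:
        """Run one dummy example through every branch and assert the declared
        embedding sizes match the executed ones."""
        cfg = self.cfg
        raw = np.zeros((1, cfg.window_samples, cfg.n_channels))
        spec = np.zeros((1,) + cfg.spec_shape)
        td = np.zeros((1, cfg.td_rows, cfg.n_channels))
        e1, e2, e3 = self._branches(raw, spec, td)
        got = {"embed1": e1.shape[1], "embed2": e2.shape[1], "embed3": e3.shape[1]}
        for k, v in got.items():
            if v != self._dims[k]:
                raise ConfigurationError(f"shape audit failed: {k} is {v}, "
                                         f"declared {self._dims[k]}")

    def parameters(self) -> list[nn.Param]:
        mods = (self.conv_stack, self.gru1, self.branch2, self.gru3,
                self.gait_head, self.angle_head)
        return [p for m in mods for p in m.params()]

    def state_dict(self) -> dict[str, np.ndarray]:
        return {f"p{i}": p.value.copy() for i, p in enumerate(self.parameters())}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.parameters()
        if len(state) != len(params):
            raise DataError("checkpoint parameter count mismatch")
        for i, p in enumerate(params):
            arr = np.asarray(state[f"p{i}"])
            if arr.shape != p.value.shape:
                raise DataError(f"checkpoint shape mismatch at p{i}")
            p.value[...] = arr

    def config_hash(self) -> str:
        import hashlib

        blob = json.dumps(asdict(self.cfg), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    # -- forward / backward -------------------------------------------------

    def _branches(self, raw, spec, td):
        e1 = self.gru1.forward(self.conv_stack.forward(raw))
        e2 = self.branch2.forward(spec)
        e3 = self.gru3.forward(td)
        return e1, e2, e3

    def forward(self, raw: np.ndarray, spec: np.ndarray, td: np.ndarray
                ) -> tuple[np.ndarray, np.ndarray]:
        """Returns (gait logits (B,4), predicted angles (B,3))."""
        if td.shape[1] != self.cfg.td_rows:
            raise DataError(f"time-domain matrix must have {self.cfg.td_rows} rows")
        e1, e2, e3 = self._branches(raw, spec, td)
        fused = np.concatenate([e1, e2, e3], axis=1)
        self._split = (e1.shape[1], e2.shape[1], e3.shape[1])
        return self.gait_head.forward(fused), self.angle_head.forward(fused)

    def backward(self, g_logits: np.ndarray, g_angles: np.ndarray) -> None:
        g_fused = self.gait_head.backward(g_logits) + self.angle_head.backward(g_angles)
        d1, d2, _ = self._split
        g1, g2, g3 = np.split(g_fused, [d1, d1 + d2], axis=1)
        self.conv_stack.backward(self.gru1.backward(g1))
        self.branch2.backward(g2)
        self.gru3.backward(g3)

    def predict(self, raw: np.ndarray, spec: np.ndarray, td: np.ndarray
                ) -> ModelOutput:
        logits, ang = self.forward(raw, spec, td)
        return ModelOutput(gait_probs=nn.softmax(logits), angles=ang)

    def summary(self) -> dict:
        """Architecture summary for the JSON dump."""
        return {
            "config": asdict(self.cfg),
            "dims": dict(self._dims),
            "n_parameters": int(sum(p.value.size for p in self.parameters())),
            "config_hash": self.config_hash(),
        }


def multitask_loss(logits: np.ndarray, pred_angles: np.ndarray,
                   gait: np.ndarray, angles: np.ndarray,
                   lam: float = 0.1) -> tuple[float, np.ndarray, np.ndarray, dict]:
    """Joint loss  CE(gait) + lam * MSE(angles)  with gradients for both heads.

    Returns (loss, d_logits, d_angles, parts) where parts holds the two
    unweighted components.
    """
    ce, g_logits = nn.softmax_cross_entropy(logits, gait)
    mse, g_ang = nn.mse_loss(pred_angles, angles)
    return ce + lam * mse, g_logits, lam * g_ang, {"ce": ce, "mse": mse}
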