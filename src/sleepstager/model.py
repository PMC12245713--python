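"""The sleep-staging network: residual CNN epoch encoder + LSTM + softmax head.

Each 10 s epoch (5,000 samples at the native 500 Hz) is encoded
independently by a stack of three residual blocks — each block being three
(convolution, layer norm, ReLU) sequences with an elementwise residual
connection added before the block's final ReLU — followed by global average
pooling over time.  The nine per-epoch feature vectors of a context window
are then integrated by a single-layer unidirectional LSTM whose final
hidden state is linearly projected to three logits and mapped through a
softmax, yielding a probability triple over (P, S, W) for the center epoch.
One decision therefore consumes ``window_k * epoch_samples`` raw samples
(45,000 at the defaults).

The network is implemented directly in NumPy (see :mod:`sleepstager._nn`)
with hand-derived gradients, so training is single-threaded deterministic
given a seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional

import numpy as np

from . import _nn
from ._nn import F32
from .io_edf import Hypnogram, Recording, STAGES
from . import preprocess


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    ``block_channels`` sets the width of each residual block; the encoder
    output dimension equals the last block's width.  Defaults follow the
    native configuration: 9-epoch windows of 5,000-sample epochs, kernel
    sizes 8, 5, 3 for the three blocks, and a 64-dimensional LSTM.
    """

    n_classes: int = 3
    window_k: int = 9
    epoch_samples: int = 5000
    epoch_length_s: float = 10.0
    block_kernels: tuple = (8, 5, 3)
    block_channels: tuple = (32, 64, 64)
    lstm_dim: int = 64
    lstm_output: str = "last"  # "last": hidden state after the 9th epoch; "center": after the center epoch
    seed: int = 0

    def __post_init__(self) -> None:
        self.block_kernels = tuple(int(k) for k in self.block_kernels)
        self.block_channels = tuple(int(c) for c in self.block_channels)
        if len(self.block_kernels) != 3 or len(self.block_channels) != 3:
            raise ValueError("block_kernels and block_channels must each have 3 entries")
        if self.window_k % 2 == 0 or self.window_k < 1:
            raise ValueError("window_k must be odd")
        if min(self.block_channels) < 1 or self.epoch_samples < 1:
            raise ValueError("block_channels and epoch_samples must be positive")
        if self.lstm_output not in ("last", "center"):
            raise ValueError("lstm_output must be 'last' or 'center'")

    @property
    def encoder_dim(self) -> int:
        return self.block_channels[-1]

    @property
    def input_rate(self) -> float:
        """Sampling rate implied by epoch_samples over epoch_length_s."""
        return self.epoch_samples / self.epoch_length_s

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, s: str) -> "ModelConfig":
        return cls(**json.loads(s))


@dataclass
class StagePrediction:
    """Softmax output for one epoch: a probability triple over (P, S, W)."""

    probabilities: np.ndarray  # shape (3,), sums to 1

    def __post_init__(self) -> None:
        self.probabilities = np.asarray(self.probabilities, dtype=np.float64)
        if self.probabilities.shape != (3,):
            raise ValueError("probabilities must be a triple")
        if np.any(self.probabilities < 0) or abs(self.probabilities.sum() - 1) > 1e-6:
            raise ValueError("probabilities must be nonnegative and sum to 1")

    @property
    def predicted_stage(self) -> str:
        # np.argmax breaks exact ties toward the lowest class index (P<S<W)
        return STAGES[int(np.argmax(self.probabilities))]

    @property
    def confidence(self) -> float:
        return float(self.probabilities.max())


@dataclass
class RecordingPrediction:
    """Per-epoch predictions for a whole recording."""

    hypnogram: Hypnogram
    probabilities: np.ndarray  # (n_epochs, 3)

    @property
    def confidences(self) -> np.ndarray:
        return self.probabilities.max(axis=1)

    def predictions(self) -> list[StagePrediction]:
        return [StagePrediction(p) for p in self.probabilities]


class SleepStager:
    """CNN-LSTM sleep stager with explicit NumPy parameters and gradients."""

    def __init__(self, cfg: ModelConfig):
        self.cfg = cfg
        self.train_fingerprint: str = ""
        rng = np.random.default_rng(cfg.seed)
        p: dict[str, np.ndarray] = {}
        c_in = 1
        for b, (c_out, k) in enumerate(zip(cfg.block_channels, cfg.block_kernels)):
            widths = [(c_in, c_out), (c_out, c_out), (c_out, c_out)]
            for l, (ci, co) in enumerate(widths):
                p[f"b{b}_conv{l}_W"] = _nn.he_conv(rng, co, ci, k)
                p[f"b{b}_conv{l}_b"] = np.zeros(co, dtype=F32)
                p[f"b{b}_ln{l}_g"] = np.ones(co, dtype=F32)
                p[f"b{b}_ln{l}_b"] = np.zeros(co, dtype=F32)
            if c_in != c_out:
                p[f"b{b}_proj_W"] = _nn.he_conv(rng, c_out, c_in, 1)
                p[f"b{b}_proj_b"] = np.zeros(c_out, dtype=F32)
            c_in = c_out
        p["lstm_Wx"], p["lstm_Wh"], p["lstm_b"] = _nn.lstm_init(
            rng, cfg.encoder_dim, cfg.lstm_dim)
        p["head_W"], p["head_b"] = _nn.glorot_linear(rng, cfg.lstm_dim, cfg.n_classes)
        self.params = p

    # ------------------------------------------------------------ blocks

    def _block_forward(self, x: np.ndarray, b: int, want_cache: bool):
        """One residual block.  Returns (out, pre_relu, cache)."""
        p = self.params
        caches = []
        h = x
        for l in range(3):
            y, cc = _nn.conv1d_forward(h, p[f"b{b}_conv{l}_W"], p[f"b{b}_conv{l}_b"])
            z, lc = _nn.layernorm_forward(y, p[f"b{b}_ln{l}_g"], p[f"b{b}_ln{l}_b"])
            if l < 2:
                h, rc = _nn.relu_forward(z)
            else:
                h, rc = z, None
            caches.append((cc, lc, rc) if want_cache else None)
        if f"b{b}_proj_W" in p:
            s, sc = _nn.conv1d_forward(x, p[f"b{b}_proj_W"], p[f"b{b}_proj_b"])
        else:
            s, sc = x, None
        pre = h + s
        out, orc = _nn.relu_forward(pre)
        cache = (caches, sc, orc) if want_cache else None
        return out, pre, cache

    def _block_backward(self, dout: np.ndarray, b: int, cache, grads: dict):
        caches, sc, orc = cache
        p = self.params
        dpre = _nn.relu_backward(dout, orc)
        dh = dpre
        for l in (2, 1, 0):
            cc, lc, rc = caches[l]
            if rc is not None:
                dh = _nn.relu_backward(dh, rc)
            dh, dg, dbeta = _nn.layernorm_backward(dh, lc)
            grads[f"b{b}_ln{l}_g"] = dg
            grads[f"b{b}_ln{l}_b"] = dbeta
            dh, dW, dbias = _nn.conv1d_backward(dh, cc)
            grads[f"b{b}_conv{l}_W"] = dW
            grads[f"b{b}_conv{l}_b"] = dbias
        if sc is not None:
            ds, dWp, dbp = _nn.conv1d_backward(dpre, sc)
            grads[f"b{b}_proj_W"] = dWp
            grads[f"b{b}_proj_b"] = dbp
            dx = dh + ds
        else:
            dx = dh + dpre
        return dx

    # ----------------------------------------------------------- encoder

    def _encoder_forward(self, seg: np.ndarray, want_cache: bool):
        """seg: (N, L) raw segments -> (N, encoder_dim) pooled features.

        Internally channel-first (C, N, L) so convolutions are single GEMMs.
        """
        x = seg[None, :, :].astype(self.params["head_W"].dtype, copy=False)
        caches = []
        for b in range(3):
            x, _, c = self._block_forward(x, b, want_cache)
            caches.append(c)
        feat = x.mean(axis=2).T  # global average pooling over time -> (N, C)
        return np.ascontiguousarray(feat), (caches, x.shape)

    def _encoder_backward(self, dfeat: np.ndarray, cache, grads: dict):
        caches, last_shape = cache
        L = last_shape[2]
        dx = np.broadcast_to(dfeat.T[:, :, None] / L, last_shape).astype(dfeat.dtype)
        for b in (2, 1, 0):
            dx = self._block_backward(dx, b, caches[b], grads)
        return dx

    # ----------------------------------------------------------- forward

    def forward(self, X: np.ndarray, want_cache: bool = False):
        """X: (B, k, L) context windows -> (B, 3) logits [+ cache]."""
        cfg = self.cfg
        B, k, L = X.shape
        if k != cfg.window_k or L != cfg.epoch_samples:
            raise ValueError(
                f"expected windows of shape (*, {cfg.window_k}, {cfg.epoch_samples}), "
                f"got (*, {k}, {L})"
            )
        seg = X.reshape(B * k, L)
        feat, enc_cache = self._encoder_forward(seg, want_cache)
        seq = feat.reshape(B, k, cfg.encoder_dim)
        if cfg.lstm_output == "center":
            # hidden state taken at the center step: epochs after the center
            # cannot influence it, so the LSTM consumes the window up to there
            seq = seq[:, :k // 2 + 1]
        h, lstm_cache = _nn.lstm_forward(
            seq, self.params["lstm_Wx"], self.params["lstm_Wh"], self.params["lstm_b"])
        logits, lin_cache = _nn.linear_forward(h, self.params["head_W"], self.params["head_b"])
        if want_cache:
            return logits, (enc_cache, lstm_cache, lin_cache, (B, k, L))
        return logits

    def loss_and_grads(self, X: np.ndarray, y: np.ndarray, class_weights=None):
        logits, cache = self.forward(X, want_cache=True)
        loss, dlogits = _nn.softmax_xent(logits, y, class_weights)
        enc_cache, lstm_cache, lin_cache, (B, k, L) = cache
        grads: dict[str, np.ndarray] = {}
        dh, grads["head_W"], grads["head_b"] = _nn.linear_backward(
            dlogits, lin_cache, self.params["head_W"])
        dseq, grads["lstm_Wx"], grads["lstm_Wh"], grads["lstm_b"] = _nn.lstm_backward(
            dh, lstm_cache)
        if self.cfg.lstm_output == "center":
            full = np.zeros((B, k, self.cfg.encoder_dim), dtype=dseq.dtype)
            full[:, :k // 2 + 1] = dseq
            dseq = full
        dfeat = dseq.reshape(B * k, self.cfg.encoder_dim)
        self._encoder_backward(dfeat, enc_cache, grads)
        return loss, grads

    # --------------------------------------------------------- inference

    def predict_proba(self, X: np.ndarray, batch_size: int = 64) -> np.ndarray:
        """Softmax probabilities for a stack of windows, batched for memory."""
        out = np.empty((X.shape[0], self.cfg.n_classes), dtype=np.float64)
        for i in range(0, X.shape[0], batch_size):
            logits = self.forward(X[i:i + batch_size])
            out[i:i + batch_size] = _nn.softmax(logits.astype(np.float64))
        return out

    def encode_epoch(self, segment: np.ndarray) -> np.ndarray:
        """Encode a single epoch segment into its pooled feature vector."""
        segment = np.asarray(segment, dtype=F32)
        if segment.shape != (self.cfg.epoch_samples,):
            raise ValueError(
                f"segment must have {self.cfg.epoch_samples} samples, got {segment.shape}"
            )
        feat, _ = self._encoder_forward(segment[None, :], want_cache=False)
        return feat[0]

    def temporal_encode(self, features: np.ndarray) -> np.ndarray:
        """LSTM context vector for a (window_k, encoder_dim) feature sequence."""
        features = np.asarray(features, dtype=F32)
        if features.shape != (self.cfg.window_k, self.cfg.encoder_dim):
            raise ValueError(
                f"expected ({self.cfg.window_k}, {self.cfg.encoder_dim}) features, "
                f"got {features.shape}"
            )
        h, _ = _nn.lstm_forward(
            features[None], self.params["lstm_Wx"], self.params["lstm_Wh"],
            self.params["lstm_b"])
        return h[0]

    def classify_window(self, context: np.ndarray) -> StagePrediction:
        """Full forward pass on one k-epoch context window."""
        context = np.asarray(context, dtype=F32)
        if context.shape != (self.cfg.window_k, self.cfg.epoch_samples):
            raise ValueError(
                f"window must be ({self.cfg.window_k}, {self.cfg.epoch_samples}), "
                f"got {context.shape}"
            )
        return StagePrediction(self.predict_proba(context[None])[0])

    def classify_recording(self, r: Recording, batch_size: int = 64) -> RecordingPrediction:
        """Resample -> epoch -> window -> classify every epoch of a recording."""
        cfg = self.cfg
        r = preprocess.resample_recording(r, cfg.input_rate)
        epoched = preprocess.epoch_signal(r, cfg.epoch_length_s)
        ds = preprocess.make_windows(epoched, k=cfg.window_k)
        probs = np.empty((ds.n_windows, cfg.n_classes), dtype=np.float64)
        for i in range(0, ds.n_windows, batch_size):
            idx = np.arange(i, min(i + batch_size, ds.n_windows))
            probs[idx] = self.predict_proba(ds.batch(idx), batch_size=batch_size)
        stages = np.array([STAGES[j] for j in probs.argmax(axis=1)], dtype="U1")
        hyp = Hypnogram(subject_id=r.subject_id, epoch_length_s=cfg.epoch_length_s,
                        stages=stages)
        return RecordingPrediction(hypnogram=hyp, probabilities=probs)

    # -------------------------------------------------------- checkpoint

    def n_parameters(self) -> int:
        return int(sum(v.size for v in self.params.values()))

    def copy_params(self) -> dict:
        return {k: v.copy() for k, v in self.params.items()}

    def set_params(self, params: dict) -> None:
        for k in self.params:
            self.params[k] = params[k].copy()

    def save(self, path) -> Path:
        path = Path(path)
        np.savez(
            path,
            __config__=np.array(self.cfg.to_json()),
            __fingerprint__=np.array(self.train_fingerprint),
            **self.params,
        )
        # np.savez appends .npz when missing; normalize the returned path
        return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")

    @classmethod
    def load(cls, path, expect_config: Optional[ModelConfig] = None) -> "SleepStager":
        with np.load(path, allow_pickle=False) as z:
            cfg = ModelConfig.from_json(str(z["__config__"]))
            if expect_config is not None and cfg != expect_config:
                raise ValueError(
                    f"checkpoint config {cfg} incompatible with expected {expect_config}"
                )
            model = cls(cfg)
            model.train_fingerprint = str(z["__fingerprint__"])
            for k in model.params:
                model.params[k] = z[k].astype(F32)
        return model
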