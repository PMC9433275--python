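"""Transformer-encoder + multichannel-CNN PPII classifier, in NumPy.

Architecture: learned token embeddings plus sinusoidal position encoding; a
stack of encoder blocks (multi-head scaled dot-product self-attention with a
residual connection and layer standardization, then a position-wise
feed-forward sublayer with its own residual and standardization); the CLS row
is the global feature; the remaining residue rows feed parallel 1-D
convolution channels (kernel sizes m, stride 1, no padding, feature maps of
length n-m+1) that are global-max-pooled and concatenated into the local
feature vector eta; concat(CLS, eta) goes through a linear softmax head.

Everything — forward, analytic backward, Adam — is implemented here on
float64 arrays, so gradients can be validated against finite differences and
training is bit-reproducible for a fixed seed on one machine.
"""

from __future__ import annotations

import copy
import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from sklearn.metrics import roc_auc_score

from .dataset import AMINO_ACIDS, DatasetSplit, WindowSample
from .errors import ConfigError, InputError, TrainingError

CLS_TOKEN = "[CLS]"
TOKENS = list(AMINO_ACIDS) + ["X", CLS_TOKEN]
TOKEN_INDEX = {t: i for i, t in enumerate(TOKENS)}
PAD_ID = TOKEN_INDEX["X"]
CLS_ID = TOKEN_INDEX[CLS_TOKEN]
VOCAB_SIZE = len(TOKENS)

_NEG_INF = -1e9


@dataclass
class EncoderConfig:
    """Encoder hyperparameters.  Defaults follow the BERT-base shape
    (768 x 12 layers x 12 heads); ``tiny()`` gives a CPU-friendly size."""

    d_model: int = 768
    n_heads: int = 12
    n_layers: int = 12
    d_ff: Optional[int] = None
    max_len: int = 64
    epsilon: float = 1e-12
    dropout: float = 0.0
    mask_padding: bool = False

    def __post_init__(self):
        if self.d_model <= 0 or self.d_model % 2:
            raise ConfigError("d_model must be positive and even")
        if self.d_model % self.n_heads:
            raise ConfigError("d_model must be divisible by n_heads")
        if self.n_layers < 0:
            raise ConfigError("n_layers must be >= 0")
        if self.max_len < 2:
            raise ConfigError("max_len must be >= 2")
        if not 0.0 <= self.dropout < 1.0:
            raise ConfigError("dropout must be in [0, 1)")
        if self.d_ff is None:
            self.d_ff = 4 * self.d_model

    @classmethod
    def tiny(cls, **kw) -> "EncoderConfig":
        base = dict(d_model=32, n_heads=2, n_layers=2, d_ff=64, max_len=32)
        base.update(kw)
        return cls(**base)


@dataclass
class CNNConfig:
    """Multichannel convolution hyperparameters: kernel sizes m and the
    number of filters q per channel."""

    kernel_sizes: tuple[int, ...] = (3, 4, 5)
    filters_q: int = 64

    def __post_init__(self):
        self.kernel_sizes = tuple(int(m) for m in self.kernel_sizes)
        if not self.kernel_sizes:
            raise ConfigError("kernel_sizes must be nonempty")
        if len(set(self.kernel_sizes)) != len(self.kernel_sizes):
            raise ConfigError("kernel_sizes must be distinct")
        if any(m < 1 for m in self.kernel_sizes):
            raise ConfigError("kernel sizes must be positive")
        if self.filters_q < 1:
            raise ConfigError("filters_q must be positive")

    @classmethod
    def tiny(cls, **kw) -> "CNNConfig":
        base = dict(kernel_sizes=(3, 4, 5), filters_q=16)
        base.update(kw)
        return cls(**base)


@dataclass
class TrainConfig:
    epochs: int = 12
    batch_size: int = 64
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self):
        if self.epochs < 1 or self.batch_size < 1:
            raise ConfigError("epochs and batch_size must be positive")
        if self.learning_rate <= 0:
            raise ConfigError("learning_rate must be positive")


@dataclass
class EncodedSample:
    """CLS global feature and the n x d_model residue matrix B = {H_1..H_n}."""

    cls_vector: np.ndarray
    token_matrix: np.ndarray


# ---------------------------------------------------------------------------
# functional pieces

def position_encoding(pos: int, d_model: int) -> np.ndarray:
    """Sinusoidal position code: component j is sin(pos/10000^(j/d)) for even
    j and cos(pos/10000^((j-1)/d)) for odd j."""
    if d_model % 2:
        raise ConfigError("d_model must be even")
    j = np.arange(d_model)
    expo = np.where(j % 2 == 0, j, j - 1) / d_model
    angle = pos / np.power(10000.0, expo)
    return np.where(j % 2 == 0, np.sin(angle), np.cos(angle))


def position_encoding_matrix(length: int, d_model: int) -> np.ndarray:
    return np.stack([position_encoding(p, d_model) for p in range(length)])


def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    z = x - np.max(x, axis=axis, keepdims=True)
    e = np.exp(z)
    return e / np.sum(e, axis=axis, keepdims=True)


def self_attention(x: np.ndarray, wq: np.ndarray, wk: np.ndarray,
                   wv: np.ndarray, n_heads: int = 1,
                   return_weights: bool = False):
    """Scaled dot-product self-attention softmax(Q K^T / sqrt(d_k)) V for a
    single sequence (t x d).  Rows of the attention matrix sum to 1."""
    if x.ndim != 2 or wq.shape != wk.shape or wk.shape != wv.shape \
            or x.shape[1] != wq.shape[0]:
        raise ConfigError("self_attention: non-conformant shapes")
    d = wq.shape[1]
    if d % n_heads:
        raise ConfigError("projection width must be divisible by n_heads")
    dk = d // n_heads
    t = x.shape[0]
    q = (x @ wq).reshape(t, n_heads, dk).transpose(1, 0, 2)
    k = (x @ wk).reshape(t, n_heads, dk).transpose(1, 0, 2)
    v = (x @ wv).reshape(t, n_heads, dk).transpose(1, 0, 2)
    scores = q @ k.transpose(0, 2, 1) / np.sqrt(dk)
    weights = softmax(scores, axis=-1)
    ctx = (weights @ v).transpose(1, 0, 2).reshape(t, d)
    if return_weights:
        return ctx, weights
    return ctx


def layer_norm_forward(x: np.ndarray, gamma: np.ndarray, beta: np.ndarray,
                       eps: float):
    """Row-wise standardization (x - mu) / (sigma + eps), then affine.

    The epsilon sits on sigma itself so a constant row maps to beta rather
    than dividing by zero.
    """
    mu = x.mean(axis=-1, keepdims=True)
    xc = x - mu
    sigma = np.sqrt((xc ** 2).mean(axis=-1, keepdims=True))
    s = sigma + eps
    xhat = xc / s
    return gamma * xhat + beta, (xhat, s, sigma)


def layer_norm_backward(dy: np.ndarray, cache, gamma: np.ndarray):
    xhat, s, sigma = cache
    dxhat = dy * gamma
    axes = tuple(range(dy.ndim - 1))
    dgamma = (dy * xhat).sum(axis=axes)
    dbeta = dy.sum(axis=axes)
    sigma_safe = np.where(sigma > 0, sigma, 1.0)
    dx = (dxhat - dxhat.mean(axis=-1, keepdims=True)) / s \
        - xhat * (dxhat * xhat).mean(axis=-1, keepdims=True) / sigma_safe
    return dx, dgamma, dbeta


def residual_then_norm(x_input: np.ndarray, sublayer_output: np.ndarray,
                       gamma: Optional[np.ndarray] = None,
                       beta: Optional[np.ndarray] = None,
                       eps: float = 1e-12) -> np.ndarray:
    """Residual connection followed by layer standardization."""
    if x_input.shape != sublayer_output.shape:
        raise ConfigError("residual_then_norm: shape mismatch")
    d = x_input.shape[-1]
    gamma = np.ones(d) if gamma is None else gamma
    beta = np.zeros(d) if beta is None else beta
    y, _ = layer_norm_forward(x_input + sublayer_output, gamma, beta, eps)
    return y


def conv_channel(token_matrix: np.ndarray, weights: np.ndarray,
                 bias: np.ndarray) -> np.ndarray:
    """One convolution channel: feature map C = {c_1..c_{n-m+1}} with
    c_i = W^T concat(H_i..H_{i+m-1}) + b, then global max pooling per filter.

    ``weights`` has shape (m*d, q); returns the pooled vector of length q.
    """
    n, d = token_matrix.shape
    md, q = weights.shape
    if md % d:
        raise ConfigError("conv weights incompatible with embedding width")
    m = md // d
    if m > n:
        raise ConfigError(f"kernel size {m} exceeds sequence length {n}")
    maps = _conv_maps(token_matrix[None], weights, bias, m)[0]
    return maps.max(axis=0)


def _conv_maps(tok: np.ndarray, weights: np.ndarray, bias: np.ndarray,
               m: int) -> np.ndarray:
    """(B, n, d) -> feature maps (B, n-m+1, q)."""
    u = _conv_patches(tok, m)
    return u @ weights + bias


def _conv_patches(tok: np.ndarray, m: int) -> np.ndarray:
    b, n, d = tok.shape
    view = np.lib.stride_tricks.sliding_window_view(tok, m, axis=1)
    # view: (B, n-m+1, d, m) -> (B, n-m+1, m*d) with residue-major layout
    return view.transpose(0, 1, 3, 2).reshape(b, n - m + 1, m * d)


def local_features(token_matrix: np.ndarray, params: dict,
                   kernel_sizes: Sequence[int]) -> np.ndarray:
    """Concatenate pooled channel outputs in kernel-size declaration order."""
    return np.concatenate([
        conv_channel(token_matrix, params[f"conv{m}.W"], params[f"conv{m}.b"])
        for m in kernel_sizes])


def fuse_and_classify(cls_vector: np.ndarray, eta: np.ndarray,
                      weights: np.ndarray, bias: np.ndarray) -> np.ndarray:
    """M = concat(CLS, eta) -> linear -> softmax class probabilities
    (non-PPII, PPII)."""
    fused = np.concatenate([cls_vector, eta])
    return softmax(fused @ weights + bias)


def windows_to_tokens(samples: Sequence[WindowSample] | Sequence[str]
                      ) -> np.ndarray:
    """Token-id matrix (N, w) from window samples or raw window strings."""
    windows = [s.window if isinstance(s, WindowSample) else s for s in samples]
    out = np.empty((len(windows), len(windows[0])), dtype=np.int64)
    for i, w in enumerate(windows):
        for j, ch in enumerate(w):
            tid = TOKEN_INDEX.get(ch)
            if tid is None or ch == CLS_TOKEN:
                raise InputError(f"unknown token {ch!r} in window {w!r}")
            out[i, j] = tid
    return out


def labels_array(samples: Sequence[WindowSample]) -> np.ndarray:
    return np.array([s.label for s in samples], dtype=np.int64)


# ---------------------------------------------------------------------------
# the trainable model

class PPIIClassifier:
    """Size-configurable encoder+CNN classifier with analytic gradients."""

    def __init__(self, encoder: EncoderConfig, cnn: CNNConfig,
                 seed: int | np.random.Generator = 0):
        self.encoder = encoder
        self.cnn = cnn
        rng = seed if isinstance(seed, np.random.Generator) \
            else np.random.default_rng(seed)
        self.params = self._init_params(rng)
        self._pe = position_encoding_matrix(encoder.max_len, encoder.d_model)

    def _init_params(self, rng: np.random.Generator) -> dict[str, np.ndarray]:
        d, dff = self.encoder.d_model, self.encoder.d_ff
        p: dict[str, np.ndarray] = {}
        p["emb"] = rng.normal(0.0, 0.02, (VOCAB_SIZE, d))
        for layer in range(self.encoder.n_layers):
            pre = f"l{layer}."
            for name in ("Wq", "Wk", "Wv", "Wo"):
                p[pre + name] = rng.normal(0.0, 0.02, (d, d))
                p[pre + name.replace("W", "b")] = np.zeros(d)
            p[pre + "ln1.g"] = np.ones(d)
            p[pre + "ln1.b"] = np.zeros(d)
            p[pre + "W1"] = rng.normal(0.0, 0.02, (d, dff))
            p[pre + "b1"] = np.zeros(dff)
            p[pre + "W2"] = rng.normal(0.0, 0.02, (dff, d))
            p[pre + "b2"] = np.zeros(d)
            p[pre + "ln2.g"] = np.ones(d)
            p[pre + "ln2.b"] = np.zeros(d)
        q = self.cnn.filters_q
        for m in self.cnn.kernel_sizes:
            # convolution kernels drawn from a random uniform distribution
            limit = np.sqrt(6.0 / (m * d + q))
            p[f"conv{m}.W"] = rng.uniform(-limit, limit, (m * d, q))
            p[f"conv{m}.b"] = np.zeros(q)
        fused = d + q * len(self.cnn.kernel_sizes)
        p["clf.W"] = rng.normal(0.0, 0.02, (fused, 2))
        p["clf.b"] = np.zeros(2)
        return p

    @property
    def fused_dim(self) -> int:
        return self.encoder.d_model + \
            self.cnn.filters_q * len(self.cnn.kernel_sizes)

    # -- forward ----------------------------------------------------------

    def embed(self, tokens: np.ndarray) -> np.ndarray:
        """X_input = WQ(X) + PE with CLS prepended at position 0.

        Accepts (n,) or (B, n) token ids; returns (n+1, d) or (B, n+1, d).
        """
        single = tokens.ndim == 1
        tok = np.atleast_2d(np.asarray(tokens))
        t = tok.shape[1] + 1
        if t > self.encoder.max_len:
            raise InputError(
                f"window of {tok.shape[1]} tokens exceeds max_len "
                f"{self.encoder.max_len}")
        ids = np.concatenate(
            [np.full((tok.shape[0], 1), CLS_ID, dtype=np.int64), tok], axis=1)
        x = self.params["emb"][ids] + self._pe[:t]
        return x[0] if single else x

    def _forward(self, tokens: np.ndarray, train: bool = False,
                 rng: Optional[np.random.Generator] = None):
        """Full forward pass; returns (logits, cache)."""
        enc = self.encoder
        p = self.params
        bsz, n = tokens.shape
        t = n + 1
        if t > enc.max_len:
            raise InputError(f"window of {n} tokens exceeds max_len "
                             f"{enc.max_len}")
        ids = np.concatenate(
            [np.full((bsz, 1), CLS_ID, dtype=np.int64), tokens], axis=1)
        x = p["emb"][ids] + self._pe[:t]
        key_mask = None
        if enc.mask_padding:
            key_mask = ids == PAD_ID  # (B, T); CLS is never a pad
        h = enc.n_heads
        dk = enc.d_model // h
        drop = enc.dropout if train else 0.0
        cache = {"ids": ids, "layers": [], "drop": drop}
        for layer in range(enc.n_layers):
            pre = f"l{layer}."
            qm = x @ p[pre + "Wq"] + p[pre + "bq"]
            km = x @ p[pre + "Wk"] + p[pre + "bk"]
            vm = x @ p[pre + "Wv"] + p[pre + "bv"]
            qh = qm.reshape(bsz, t, h, dk).transpose(0, 2, 1, 3)
            kh = km.reshape(bsz, t, h, dk).transpose(0, 2, 1, 3)
            vh = vm.reshape(bsz, t, h, dk).transpose(0, 2, 1, 3)
            scores = qh @ kh.transpose(0, 1, 3, 2) / np.sqrt(dk)
            if key_mask is not None:
                scores = np.where(key_mask[:, None, None, :], _NEG_INF, scores)
            attn = softmax(scores, axis=-1)
            ctx = (attn @ vh).transpose(0, 2, 1, 3).reshape(bsz, t, enc.d_model)
            out = ctx @ p[pre + "Wo"] + p[pre + "bo"]
            mask1 = None
            if drop > 0:
                mask1 = (rng.random(out.shape) >= drop) / (1.0 - drop)
                out = out * mask1
            r1 = x + out
            h1, ln1c = layer_norm_forward(
                r1, p[pre + "ln1.g"], p[pre + "ln1.b"], enc.epsilon)
            f1 = h1 @ p[pre + "W1"] + p[pre + "b1"]
            act = np.maximum(f1, 0.0)
            f2 = act @ p[pre + "W2"] + p[pre + "b2"]
            mask2 = None
            if drop > 0:
                mask2 = (rng.random(f2.shape) >= drop) / (1.0 - drop)
                f2 = f2 * mask2
            r2 = h1 + f2
            x_next, ln2c = layer_norm_forward(
                r2, p[pre + "ln2.g"], p[pre + "ln2.b"], enc.epsilon)
            cache["layers"].append({
                "x": x, "qh": qh, "kh": kh, "vh": vh, "attn": attn,
                "ctx": ctx, "ln1c": ln1c, "h1": h1, "f1": f1, "act": act,
                "ln2c": ln2c, "mask1": mask1, "mask2": mask2,
            })
            x = x_next
        cls = x[:, 0, :]
        tokmat = x[:, 1:, :]
        pooled = []
        conv_cache = []
        for m in self.cnn.kernel_sizes:
            u = _conv_patches(tokmat, m)
            cmap = u @ p[f"conv{m}.W"] + p[f"conv{m}.b"]
            arg = cmap.argmax(axis=1)
            pooled.append(np.take_along_axis(cmap, arg[:, None, :], axis=1)[:, 0, :])
            conv_cache.append({"u": u, "arg": arg, "shape": cmap.shape})
        eta = np.concatenate(pooled, axis=1)
        fused = np.concatenate([cls, eta], axis=1)
        logits = fused @ p["clf.W"] + p["clf.b"]
        cache.update({"cls": cls, "tokmat": tokmat, "conv": conv_cache,
                      "fused": fused})
        return logits, cache

    def _backward(self, dlogits: np.ndarray, cache) -> dict[str, np.ndarray]:
        enc = self.encoder
        p = self.params
        grads = {k: np.zeros_like(v) for k, v in p.items()}
        fused = cache["fused"]
        grads["clf.W"] = fused.T @ dlogits
        grads["clf.b"] = dlogits.sum(axis=0)
        dfused = dlogits @ p["clf.W"].T
        d = enc.d_model
        dcls = dfused[:, :d]
        deta = dfused[:, d:]
        tokmat = cache["tokmat"]
        bsz, n, _ = tokmat.shape
        dtok = np.zeros_like(tokmat)
        off = 0
        q = self.cnn.filters_q
        for m, cc in zip(self.cnn.kernel_sizes, cache["conv"]):
            dpool = deta[:, off:off + q]
            off += q
            dmap = np.zeros(cc["shape"])
            np.put_along_axis(dmap, cc["arg"][:, None, :],
                              dpool[:, None, :], axis=1)
            grads[f"conv{m}.W"] = np.einsum("blk,blq->kq", cc["u"], dmap)
            grads[f"conv{m}.b"] = dmap.sum(axis=(0, 1))
            du = dmap @ p[f"conv{m}.W"].T
            dur = du.reshape(bsz, -1, m, d)
            ln = dur.shape[1]
            for j in range(m):
                dtok[:, j:j + ln, :] += dur[:, :, j, :]
        dx = np.concatenate([dcls[:, None, :], dtok], axis=1)

        h = enc.n_heads
        dk = d // h
        t = dx.shape[1]
        for layer in reversed(range(enc.n_layers)):
            pre = f"l{layer}."
            lc = cache["layers"][layer]
            dr2, dg2, db2 = layer_norm_backward(dx, lc["ln2c"],
                                                p[pre + "ln2.g"])
            grads[pre + "ln2.g"] += dg2
            grads[pre + "ln2.b"] += db2
            df2 = dr2 if lc["mask2"] is None else dr2 * lc["mask2"]
            grads[pre + "W2"] += np.einsum("btf,btd->fd", lc["act"], df2)
            grads[pre + "b2"] += df2.sum(axis=(0, 1))
            dact = df2 @ p[pre + "W2"].T
            df1 = dact * (lc["f1"] > 0)
            grads[pre + "W1"] += np.einsum("btd,btf->df", lc["h1"], df1)
            grads[pre + "b1"] += df1.sum(axis=(0, 1))
            dh1 = dr2 + df1 @ p[pre + "W1"].T
            dr1, dg1, db1 = layer_norm_backward(dh1, lc["ln1c"],
                                                p[pre + "ln1.g"])
            grads[pre + "ln1.g"] += dg1
            grads[pre + "ln1.b"] += db1
            dout = dr1 if lc["mask1"] is None else dr1 * lc["mask1"]
            grads[pre + "Wo"] += np.einsum("btd,bte->de", lc["ctx"], dout)
            grads[pre + "bo"] += dout.sum(axis=(0, 1))
            dctx = (dout @ p[pre + "Wo"].T).reshape(bsz, t, h, dk) \
                .transpose(0, 2, 1, 3)
            dattn = dctx @ lc["vh"].transpose(0, 1, 3, 2)
            dvh = lc["attn"].transpose(0, 1, 3, 2) @ dctx
            a = lc["attn"]
            dscore = a * (dattn - (dattn * a).sum(axis=-1, keepdims=True))
            dscore /= np.sqrt(dk)
            dqh = dscore @ lc["kh"]
            dkh = dscore.transpose(0, 1, 3, 2) @ lc["qh"]
            dqm = dqh.transpose(0, 2, 1, 3).reshape(bsz, t, d)
            dkm = dkh.transpose(0, 2, 1, 3).reshape(bsz, t, d)
            dvm = dvh.transpose(0, 2, 1, 3).reshape(bsz, t, d)
            x_in = lc["x"]
            grads[pre + "Wq"] += np.einsum("btd,bte->de", x_in, dqm)
            grads[pre + "bq"] += dqm.sum(axis=(0, 1))
            grads[pre + "Wk"] += np.einsum("btd,bte->de", x_in, dkm)
            grads[pre + "bk"] += dkm.sum(axis=(0, 1))
            grads[pre + "Wv"] += np.einsum("btd,bte->de", x_in, dvm)
            grads[pre + "bv"] += dvm.sum(axis=(0, 1))
            dx = dr1 + dqm @ p[pre + "Wq"].T + dkm @ p[pre + "Wk"].T \
                + dvm @ p[pre + "Wv"].T
        np.add.at(grads["emb"], cache["ids"].reshape(-1),
                  dx.reshape(-1, d))
        return grads

    # -- public API --------------------------------------------------------

    def encode(self, tokens: np.ndarray) -> EncodedSample:
        """Run the encoder stack on one window; returns the CLS feature and
        the residue-row matrix."""
        tokens = np.asarray(tokens)
        if tokens.ndim != 1:
            raise InputError("encode expects a single window")
        _, cache = self._forward(tokens[None])
        return EncodedSample(cls_vector=cache["cls"][0],
                             token_matrix=cache["tokmat"][0])

    def predict_proba(self, tokens: np.ndarray,
                      batch_size: int = 256) -> np.ndarray:
        """PPII probability per window; tokens is (N, w) ids."""
        out = []
        for i in range(0, len(tokens), batch_size):
            logits, _ = self._forward(tokens[i:i + batch_size])
            out.append(softmax(logits, axis=-1)[:, 1])
        return np.concatenate(out) if out else np.empty(0)

    def predict_samples(self, samples: Sequence[WindowSample]) -> np.ndarray:
        return self.predict_proba(windows_to_tokens(samples))

    def loss_and_grads(self, tokens: np.ndarray, labels: np.ndarray,
                       train: bool = False,
                       rng: Optional[np.random.Generator] = None):
        """Mean cross-entropy over the batch and analytic parameter grads."""
        logits, cache = self._forward(tokens, train=train, rng=rng)
        probs = softmax(logits, axis=-1)
        bsz = len(labels)
        eps = 1e-300
        loss = float(-np.mean(np.log(probs[np.arange(bsz), labels] + eps)))
        dlogits = probs.copy()
        dlogits[np.arange(bsz), labels] -= 1.0
        dlogits /= bsz
        return loss, self._backward(dlogits, cache)

    def loss(self, tokens: np.ndarray, labels: np.ndarray) -> float:
        logits, _ = self._forward(tokens)
        probs = softmax(logits, axis=-1)
        return float(-np.mean(
            np.log(probs[np.arange(len(labels)), labels] + 1e-300)))

    # -- persistence -------------------------------------------------------

    def save(self, out_dir) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        cfg = {"encoder": asdict(self.encoder), "cnn": asdict(self.cnn)}
        (out_dir / "model_config.json").write_text(json.dumps(cfg, indent=1))
        np.savez(out_dir / "weights.npz", **self.params)

    @classmethod
    def load(cls, in_dir) -> "PPIIClassifier":
        in_dir = Path(in_dir)
        cfg = json.loads((in_dir / "model_config.json").read_text())
        cfg["cnn"]["kernel_sizes"] = tuple(cfg["cnn"]["kernel_sizes"])
        model = cls(EncoderConfig(**cfg["encoder"]), CNNConfig(**cfg["cnn"]))
        with np.load(in_dir / "weights.npz") as data:
            model.params = {k: data[k] for k in data.files}
        return model


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray],
             grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            params[k] -= self.lr * (self.m[k] / b1t) / \
                (np.sqrt(self.v[k] / b2t) + self.eps)


def train(split: DatasetSplit, encoder: EncoderConfig, cnn: CNNConfig,
          cfg: TrainConfig) -> tuple[PPIIClassifier, list[dict]]:
    """Train with Adam on cross-entropy; the checkpoint with the best
    validation AUC is returned.  Reproducible per seed on one machine."""
    if not split.train or not split.val:
        raise InputError("train: empty train or val part")
    ss = np.random.SeedSequence(cfg.seed)
    init_rng, batch_rng, drop_rng = (np.random.default_rng(s)
                                     for s in ss.spawn(3))
    model = PPIIClassifier(encoder, cnn, seed=init_rng)
    opt = _Adam(model.params, cfg.learning_rate)
    xtr = windows_to_tokens(split.train)
    ytr = labels_array(split.train)
    xval = windows_to_tokens(split.val)
    yval = labels_array(split.val)
    log: list[dict] = []
    best_auc = -np.inf
    best_params = None
    for epoch in range(1, cfg.epochs + 1):
        order = batch_rng.permutation(len(ytr))
        losses = []
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            loss, grads = model.loss_and_grads(
                xtr[idx], ytr[idx], train=True, rng=drop_rng)
            if not np.isfinite(loss):
                raise TrainingError(f"non-finite loss at epoch {epoch}")
            opt.step(model.params, grads)
            losses.append(loss)
        val_loss = model.loss(xval, yval)
        val_scores = model.predict_proba(xval)
        val_auc = float(roc_auc_score(yval, val_scores)) \
            if len(np.unique(yval)) > 1 else float("nan")
        log.append({"epoch": epoch, "train_loss": float(np.mean(losses)),
                    "val_loss": val_loss, "val_auc": val_auc})
        if np.isfinite(val_auc) and val_auc > best_auc:
            best_auc = val_auc
            best_params = copy.deepcopy(model.params)
    if best_params is not None:
        model.params = best_params
    return model, log
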