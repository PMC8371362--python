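"""Channel-attention BiLSTM classifier for band-feature EEG samples.

The forward computation, for one sample ``X`` of shape (F, M, N):

1. *per-channel embedding* — each channel ``j`` owns a matrix ``M_j``
   (d_a x F) and bias, mapping its F band features to a d_a column of
   ``A_i`` (per segment ``i``);
2. *channel attention* — raw scores ``(Q tanh(H A_i + B))^T`` are
   column-softmaxed into a column-stochastic M x M weight matrix ``W``
   and applied as ``A_i W`` (skipped entirely in the no-attention
   ablation);
3. *spatial encoding* — the M weighted channel columns run through a
   BiLSTM (hidden ``u`` per direction); the resulting 2u x M sequence is
   compressed to length K by a ReLU linear map;
4. *temporal encoding* — the N per-segment encodings, each flattened
   column-by-column to a 2uK vector, run through a second BiLSTM
   (hidden ``v`` per direction); the final-position output ``e_N`` feeds
5. a linear layer + softmax over T classes.

Everything is double precision NumPy on the autodiff tape in
:mod:`eegpf._autodiff`; training lives in :mod:`eegpf.evaluation`.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import Sequence

import numpy as np

from ._autodiff import Tensor, concat, stack

__all__ = [
    "ModelConfig",
    "ModelParams",
    "init_params",
    "channel_embed",
    "channel_attention",
    "spatial_encode",
    "temporal_encode",
    "forward_batch",
    "predict_proba",
    "parameter_count",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyper-parameters.

    ``use_channel_attention=False`` is the "-C" ablation: the weighting
    layer is removed (skipped), not replaced by an identity weight.
    """

    n_bands: int = 5          # F
    n_channels: int = 8       # M
    n_segments: int = 9       # N
    d_embed: int = 32         # d_a, per-channel embedding width
    d_attn: int = 32          # d_h, attention hidden width
    u_spatial: int = 32       # spatial BiLSTM hidden per direction
    k_compress: int = 6       # K, compressed spatial sequence length
    v_temporal: int = 64      # temporal BiLSTM hidden per direction
    n_classes: int = 2        # T
    use_channel_attention: bool = True
    seed: int = 0

    def __post_init__(self):
        for name in ("n_bands", "n_channels", "n_segments", "d_embed", "d_attn",
                     "u_spatial", "k_compress", "v_temporal"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")


class ModelParams(dict):
    """Named parameter dict (str -> Tensor with requires_grad=True)."""

    def tensors(self) -> Sequence[Tensor]:
        return list(self.values())

    def zero_grad(self) -> None:
        for t in self.values():
            t.zero_grad()

    def copy_values(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.items()}


def _uniform(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    bound = 1.0 / np.sqrt(max(fan_in, 1))
    return rng.uniform(-bound, bound, size=shape)


def _lstm_params(rng: np.random.Generator, prefix: str, d_in: int, d_h: int,
                 out: ModelParams) -> None:
    # gate order: input, forget, cell, output; forget bias starts at 1
    out[f"{prefix}_Wx"] = Tensor(_uniform(rng, (d_in, 4 * d_h), d_in), requires_grad=True)
    out[f"{prefix}_Wh"] = Tensor(_uniform(rng, (d_h, 4 * d_h), d_h), requires_grad=True)
    b = np.zeros(4 * d_h)
    b[d_h:2 * d_h] = 1.0
    out[f"{prefix}_b"] = Tensor(b, requires_grad=True)


def init_params(config: ModelConfig) -> ModelParams:
    """Seeded uniform fan-in initialisation of every layer."""
    rng = np.random.default_rng(config.seed)
    F, M = config.n_bands, config.n_channels
    da, dh = config.d_embed, config.d_attn
    u, K, v, T = config.u_spatial, config.k_compress, config.v_temporal, config.n_classes
    p = ModelParams()
    # per-channel embedding: M distinct (d_a x F) matrices, stacked
    p["embed_M"] = Tensor(_uniform(rng, (M, da, F), F), requires_grad=True)
    p["embed_b"] = Tensor(np.zeros((M, da)), requires_grad=True)
    if config.use_channel_attention:
        p["attn_H"] = Tensor(_uniform(rng, (dh, da), da), requires_grad=True)
        p["attn_B"] = Tensor(np.zeros((dh, M)), requires_grad=True)
        p["attn_Q"] = Tensor(_uniform(rng, (M, dh), dh), requires_grad=True)
    for direction in ("fwd", "bwd"):
        _lstm_params(rng, f"sp_{direction}", da, u, p)
    p["comp_G"] = Tensor(_uniform(rng, (M, K), M), requires_grad=True)
    p["comp_b"] = Tensor(np.zeros(2 * u), requires_grad=True)
    for direction in ("fwd", "bwd"):
        _lstm_params(rng, f"tm_{direction}", 2 * u * K, v, p)
    p["cls_G"] = Tensor(_uniform(rng, (T, 2 * v), 2 * v), requires_grad=True)
    p["cls_b"] = Tensor(np.zeros(T), requires_grad=True)
    return p


def parameter_count(config: ModelConfig) -> int:
    """Closed-form total number of scalar parameters."""
    F, M = config.n_bands, config.n_channels
    da, dh = config.d_embed, config.d_attn
    u, K, v, T = config.u_spatial, config.k_compress, config.v_temporal, config.n_classes
    n = M * da * F + M * da                       # embedding
    if config.use_channel_attention:
        n += dh * da + dh * M + M * dh            # H, B, Q
    n += 2 * (da * 4 * u + u * 4 * u + 4 * u)     # spatial BiLSTM
    n += M * K + 2 * u                            # compression
    d_in = 2 * u * K
    n += 2 * (d_in * 4 * v + v * 4 * v + 4 * v)   # temporal BiLSTM
    n += T * 2 * v + T                            # classifier
    return n


# --------------------------------------------------------------------- stages

def _check_sample_shape(X: np.ndarray, config: ModelConfig) -> None:
    expected = (config.n_bands, config.n_channels, config.n_segments)
    if X.shape[-3:] != expected:
        raise ValueError(
            f"sample shape {X.shape[-3:]} does not match configured "
            f"(F, M, N) = {expected}")
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite entries in input sample")


def channel_embed(x: Tensor, params: ModelParams) -> Tensor:
    """Per-channel linear embedding.

    ``x``: (..., M, F) channel-major band features; returns (..., M, d_a)
    where row j is ``M_j m_j + b_j`` with a distinct matrix per channel.
    """
    M = params["embed_M"].shape[0]
    if x.shape[-2] != M:
        raise ValueError(f"expected {M} channels, got {x.shape[-2]} (axis -2)")
    if x.shape[-1] != params["embed_M"].shape[2]:
        raise ValueError(
            f"expected {params['embed_M'].shape[2]} band features, got {x.shape[-1]} (axis -1)")
    cols = []
    for j in range(M):
        mj = x[..., j, :]                          # (..., F)
        Wj = params["embed_M"][j].transpose()      # (F, d_a)
        cols.append(mj @ Wj + params["embed_b"][j])
    return stack(cols, axis=-2)                    # (..., M, d_a)


def channel_attention(A: Tensor, params: ModelParams,
                      use_channel_attention: bool = True):
    """Column-stochastic channel weighting.

    ``A``: (..., M, d_a) channel-major embedding.  Returns
    ``(A_weighted, W)`` where ``W`` (..., M, M) has unit column sums, or
    ``(A, None)`` when the ablation switch is off.
    """
    if not use_channel_attention:
        return A, None
    At = A.swapaxes(-1, -2)                        # d_a x M, the paper-orientation A_i
    H, B, Q = params["attn_H"], params["attn_B"], params["attn_Q"]
    scores = (Q @ (H @ At + B).tanh()).swapaxes(-1, -2)   # (..., M, M) raw W
    if not np.all(np.isfinite(scores.data)):
        raise FloatingPointError("non-finite attention scores (upstream explosion)")
    W = scores.softmax(axis=-2)                    # normalise over rows j within column k
    A_hat = (At @ W).swapaxes(-1, -2)              # back to (..., M, d_a)
    return A_hat, W


def _lstm_scan(seq: list[Tensor], params: ModelParams, prefix: str, d_h: int) -> list[Tensor]:
    """Unidirectional LSTM over a list of (batch, d_in) steps."""
    Wx, Wh, b = params[f"{prefix}_Wx"], params[f"{prefix}_Wh"], params[f"{prefix}_b"]
    batch = seq[0].shape[0]
    h = Tensor(np.zeros((batch, d_h)))
    c = Tensor(np.zeros((batch, d_h)))
    outputs = []
    for x in seq:
        gates = x @ Wx + h @ Wh + b
        i = gates[:, 0 * d_h:1 * d_h].sigmoid()
        f = gates[:, 1 * d_h:2 * d_h].sigmoid()
        g = gates[:, 2 * d_h:3 * d_h].tanh()
        o = gates[:, 3 * d_h:4 * d_h].sigmoid()
        c = f * c + i * g
        h = o * c.tanh()
        outputs.append(h)
    return outputs


def _bilstm(seq: list[Tensor], params: ModelParams, prefix: str, d_h: int) -> list[Tensor]:
    """Bidirectional LSTM; output per position is [fwd ; bwd], each 2*d_h."""
    fwd = _lstm_scan(seq, params, f"{prefix}_fwd", d_h)
    bwd = _lstm_scan(seq[::-1], params, f"{prefix}_bwd", d_h)[::-1]
    return [concat([f, b], axis=-1) for f, b in zip(fwd, bwd)]


def spatial_encode(A_hat: Tensor, params: ModelParams, config: ModelConfig) -> Tensor:
    """BiLSTM over the channel sequence, then ReLU compression to length K.

    ``A_hat``: (batch, M, d_a).  Returns (batch, 2u, K).
    """
    M, u, K = config.n_channels, config.u_spatial, config.k_compress
    if A_hat.shape[-2] != M:
        raise ValueError(f"expected {M} channel positions, got {A_hat.shape[-2]}")
    steps = [A_hat[:, j, :] for j in range(M)]
    C = stack(_bilstm(steps, params, "sp", u), axis=-1)       # (batch, 2u, M)
    comp = C @ params["comp_G"]                               # (batch, 2u, K)
    return (comp + params["comp_b"].reshape(-1, 1)).relu()


def temporal_encode(C_hats: list[Tensor], params: ModelParams, config: ModelConfig) -> Tensor:
    """BiLSTM over the N flattened segment encodings; returns e_N (batch, 2v)."""
    if len(C_hats) != config.n_segments:
        raise ValueError(f"expected {config.n_segments} segment encodings, got {len(C_hats)}")
    batch = C_hats[0].shape[0]
    # flatten column-by-column: c_hat_1 stacked over c_hat_2 ... (2uK,)
    steps = [c.swapaxes(-1, -2).reshape(batch, -1) for c in C_hats]
    E = _bilstm(steps, params, "tm", config.v_temporal)
    return E[-1]


def forward_batch(X: np.ndarray, params: ModelParams, config: ModelConfig,
                  return_attention: bool = False):
    """Full forward pass on a batch.

    ``X``: (batch, F, M, N) float array.  Returns ``(logits, probs, W)``
    where logits/probs are Tensors of shape (batch, T) and ``W`` is a
    (batch, N, M, M) array of attention matrices (or None).
    """
    X = np.asarray(X, dtype=np.float64)
    if X.ndim == 3:
        X = X[None]
    _check_sample_shape(X, config)
    N = config.n_segments
    # (batch, N, M, F): segment-major, channel rows
    Xr = Tensor(np.ascontiguousarray(X.transpose(0, 3, 2, 1)))
    A = channel_embed(Xr, params)                             # (batch, N, M, d_a)
    A_hat, W = channel_attention(A, params, config.use_channel_attention)
    batch = X.shape[0]
    # fold segments into the batch for the per-segment spatial stage
    folded = A_hat.reshape(batch * N, config.n_channels, config.d_embed)
    C_hat = spatial_encode(folded, params, config)            # (batch*N, 2u, K)
    C_hat = C_hat.reshape(batch, N, 2 * config.u_spatial, config.k_compress)
    segs = [C_hat[:, i] for i in range(N)]
    e_N = temporal_encode(segs, params, config)               # (batch, 2v)
    logits = e_N @ params["cls_G"].transpose() + params["cls_b"]
    probs = logits.softmax(axis=-1)
    if not np.all(np.isfinite(probs.data)):
        raise FloatingPointError("non-finite activations in classifier stage")
    attn = W.data if (return_attention and W is not None) else None
    return logits, probs, attn


def predict_proba(X: np.ndarray, params: ModelParams, config: ModelConfig,
                  return_attention: bool = False):
    """Class probabilities for one sample (F, M, N) or a batch.

    Returns the probability array, plus the per-segment attention
    matrices when ``return_attention`` is set (None under the ablation).
    """
    single = np.asarray(X).ndim == 3
    _, probs, attn = forward_batch(X, params, config, return_attention=return_attention)
    out = probs.data[0] if single else probs.data
    if return_attention:
        return out, (attn[0] if (single and attn is not None) else attn)
    return out


# ----------------------------------------------------------------- checkpoint

def save_checkpoint(path, config: ModelConfig, params: ModelParams) -> None:
    """Single-file JSON container with config and named parameter arrays."""
    payload = {
        "config": asdict(config),
        "params": {k: v.data.tolist() for k, v in params.items()},
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_checkpoint(path):
    with open(path) as fh:
        payload = json.load(fh)
    config = ModelConfig(**payload["config"])
    params = ModelParams()
    for k, v in payload["params"].items():
        params[k] = Tensor(np.asarray(v, dtype=np.float64), requires_grad=True)
    return config, params
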