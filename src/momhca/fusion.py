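"""Bidirectional multi-head cross-attention fusion of the two modality
latents, with supervised contrastive refinement.

RNA queries attend over ATAC keys/values and vice versa:

    head_i^h = Attention(Z_i W_Q^h, Z_j W_K^h, Z_j W_V^h)
    head_j^h = Attention(Z_j W_Q^h, Z_i W_K^h, Z_i W_V^h)
    Attention(Q, K, V) = softmax(Q Kᵀ / √d_k) V

Heads are concatenated and projected back to d, wrapped in a residual
connection with layer normalisation, and the two directions are fused by a
two-layer feed-forward network on their concatenation:

    Z = FFN([head_i' ‖ head_j']),  FFN(x) = σ(x W1 + b1) W2 + b2.

The fused embedding is refined with a supervised contrastive loss (SupCon,
multi-positive averaging) on L2-normalised embeddings at temperature τ.
Baseline fusers (concatenation, sum, average, self-attention) are provided
for ablation under the identical training protocol.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from . import nn
from .autoencoder import Autoencoder

__all__ = [
    "AttentionConfig",
    "ContrastiveConfig",
    "FusionFFNConfig",
    "scaled_dot_attention",
    "init_attention_params",
    "cross_attention_heads",
    "attention_weights",
    "residual_layernorm",
    "fuse",
    "supervised_contrastive_loss",
    "baseline_fuse",
    "MHCAFusion",
    "BaselineFusion",
    "train_fusion",
]

BASELINE_METHODS = ("concat", "sum", "average", "self_attention")


@dataclass
class AttentionConfig:
    n_heads: int = 4
    model_dim: int = 128
    head_dim: int | None = None  # defaults to model_dim // n_heads

    def __post_init__(self):
        if self.n_heads < 1:
            raise ValueError("n_heads must be >= 1")
        if self.head_dim is None:
            if self.model_dim % self.n_heads != 0:
                raise ValueError(
                    f"model_dim {self.model_dim} not divisible by n_heads {self.n_heads}")
            self.head_dim = self.model_dim // self.n_heads
        if self.head_dim < 1:
            raise ValueError("head_dim must be >= 1")


@dataclass
class ContrastiveConfig:
    temperature: float = 0.5
    loss_weight: float = 1.0

    def __post_init__(self):
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.loss_weight < 0:
            raise ValueError("loss_weight must be nonnegative")


@dataclass
class FusionFFNConfig:
    hidden_dim: int = 256
    output_dim: int = 128
    activation: str = "relu"


# ---------------------------------------------------------------------------
# stateless reference operations (plain NumPy)


def scaled_dot_attention(Q: np.ndarray, K: np.ndarray, V: np.ndarray) -> np.ndarray:
    """softmax(Q Kᵀ / √d_k) V."""
    Q, K, V = (np.asarray(a, dtype=np.float64) for a in (Q, K, V))
    if K.shape[0] != V.shape[0]:
        raise ValueError("K and V must have equal row counts")
    if Q.shape[1] != K.shape[1]:
        raise ValueError("Q and K must have equal feature dimension")
    dk = Q.shape[1]
    if dk == 0:
        raise ValueError("key dimension d_k must be positive")
    scores = Q @ K.T / math.sqrt(dk)
    scores -= scores.max(axis=1, keepdims=True)
    w = np.exp(scores)
    w /= w.sum(axis=1, keepdims=True)
    return w @ V


def init_attention_params(cfg: AttentionConfig, rng: np.random.Generator) -> dict:
    """Glorot-initialised per-head Q/K/V projections for both directions and
    the output projections W: (h·d_k) × d."""
    d, dk, h = cfg.model_dim, cfg.head_dim, cfg.n_heads

    def glorot(n_in, n_out):
        lim = math.sqrt(6.0 / (n_in + n_out))
        return rng.uniform(-lim, lim, size=(n_in, n_out))

    params = {}
    for direction in ("i", "j"):
        params[direction] = {
            "Wq": [glorot(d, dk) for _ in range(h)],
            "Wk": [glorot(d, dk) for _ in range(h)],
            "Wv": [glorot(d, dk) for _ in range(h)],
            "Wo": glorot(h * dk, d),
        }
    return params


def cross_attention_heads(Z_i: np.ndarray, Z_j: np.ndarray,
                          params: dict | None = None,
                          config: AttentionConfig | None = None,
                          seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Bidirectional multi-head cross-attention (concatenated heads,
    projected back to d). Queries of direction i come from Z_i with
    keys/values from Z_j, and conversely for direction j."""
    Z_i, Z_j = np.asarray(Z_i, float), np.asarray(Z_j, float)
    if Z_i.shape != Z_j.shape:
        raise ValueError(f"latent shapes differ: {Z_i.shape} vs {Z_j.shape}")
    config = config or AttentionConfig(model_dim=Z_i.shape[1])
    if params is None:
        params = init_attention_params(config, np.random.default_rng(seed))

    def one_direction(Zq, Zkv, p):
        heads = [scaled_dot_attention(Zq @ Wq, Zkv @ Wk, Zkv @ Wv)
                 for Wq, Wk, Wv in zip(p["Wq"], p["Wk"], p["Wv"])]
        return np.concatenate(heads, axis=1) @ p["Wo"]

    return (one_direction(Z_i, Z_j, params["i"]),
            one_direction(Z_j, Z_i, params["j"]))


def attention_weights(Z_i: np.ndarray, Z_j: np.ndarray, params: dict,
                      ) -> dict[str, list[np.ndarray]]:
    """Per-head row-stochastic attention weight matrices for both
    directions (softmax(Q Kᵀ/√d_k) before the value product)."""
    out: dict[str, list[np.ndarray]] = {}
    for direction, (Zq, Zkv) in (("i", (Z_i, Z_j)), ("j", (Z_j, Z_i))):
        p = params[direction]
        mats = []
        for Wq, Wk in zip(p["Wq"], p["Wk"]):
            Q, K = Zq @ Wq, Zkv @ Wk
            scores = Q @ K.T / math.sqrt(Q.shape[1])
            scores -= scores.max(axis=1, keepdims=True)
            w = np.exp(scores)
            mats.append(w / w.sum(axis=1, keepdims=True))
        out[direction] = mats
    return out


def residual_layernorm(head: np.ndarray, Z: np.ndarray,
                       gain: np.ndarray | None = None,
                       bias: np.ndarray | None = None,
                       eps: float = 1e-5) -> np.ndarray:
    """head' = LayerNorm(head + Z), row-wise, optional affine parameters."""
    head, Z = np.asarray(head, float), np.asarray(Z, float)
    if head.shape != Z.shape:
        raise ValueError("head and Z shapes differ")
    x = head + Z
    mu = x.mean(axis=1, keepdims=True)
    var = x.var(axis=1, keepdims=True)
    y = (x - mu) / np.sqrt(var + eps)
    if gain is not None:
        y = y * gain
    if bias is not None:
        y = y + bias
    return y


def fuse(head_i: np.ndarray, head_j: np.ndarray,
         W1: np.ndarray, b1: np.ndarray, W2: np.ndarray, b2: np.ndarray,
         activation: str = "relu") -> np.ndarray:
    """Z = FFN([head_i' ‖ head_j']) with FFN(x) = σ(x W1 + b1) W2 + b2."""
    head_i, head_j = np.asarray(head_i, float), np.asarray(head_j, float)
    if head_i.shape != head_j.shape:
        raise ValueError("fusion inputs must have equal shapes")
    x = np.concatenate([head_i, head_j], axis=1)
    h = x @ W1 + b1
    if activation == "relu":
        h = np.maximum(h, 0.0)
    elif activation == "gelu":
        from scipy.special import erf
        h = 0.5 * h * (1.0 + erf(h / math.sqrt(2.0)))
    elif activation != "linear":
        raise ValueError(f"unknown activation {activation!r}")
    return h @ W2 + b2


def _contrastive_masks(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels)
    same = labels[:, None] == labels[None, :]
    eye = np.eye(len(labels), dtype=bool)
    pos = same & ~eye
    neg = ~same
    return pos, neg


def supervised_contrastive_loss(Z: np.ndarray, labels: np.ndarray,
                                cfg: ContrastiveConfig | None = None) -> float:
    """Supervised contrastive loss on L2-normalised embeddings.

    For each anchor a and each same-class positive a⁺ the per-pair term is
    −log[exp(s(a,a⁺)/τ) / (exp(s(a,a⁺)/τ) + Σ_neg exp(s(a,a⁻)/τ))] with s
    the cosine similarity; the loss is the mean over anchor–positive pairs.
    Anchors without any positive are skipped with a warning.
    """
    cfg = cfg or ContrastiveConfig()
    Z = np.asarray(Z, dtype=np.float64)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("contrastive loss needs at least two classes")
    Zn = Z / np.maximum(np.linalg.norm(Z, axis=1, keepdims=True), 1e-12)
    S = Zn @ Zn.T / cfg.temperature
    pos, neg = _contrastive_masks(labels)
    if np.any(~pos.any(axis=1)):
        warnings.warn("anchors without same-class positives were skipped")
    E = np.exp(S)
    neg_sum = (E * neg).sum(axis=1)
    a_idx, p_idx = np.nonzero(pos)
    terms = np.log(E[a_idx, p_idx] + neg_sum[a_idx]) - S[a_idx, p_idx]
    return float(terms.mean())


def baseline_fuse(Z_i: np.ndarray, Z_j: np.ndarray, method: str,
                  seed: int = 0, projection: np.ndarray | None = None) -> np.ndarray:
    """Stateless baseline fusers for ablation: concat (+ seeded linear
    projection back to d), sum, average, and self-attention over the
    concatenated features."""
    Z_i, Z_j = np.asarray(Z_i, float), np.asarray(Z_j, float)
    if Z_i.shape != Z_j.shape:
        raise ValueError("baseline fusion inputs must have equal shapes")
    d = Z_i.shape[1]
    if method == "sum":
        return Z_i + Z_j
    if method == "average":
        return 0.5 * (Z_i + Z_j)
    if method == "concat":
        X = np.concatenate([Z_i, Z_j], axis=1)
        if projection is None:
            rng = np.random.default_rng(seed)
            lim = math.sqrt(6.0 / (2 * d + d))
            projection = rng.uniform(-lim, lim, size=(2 * d, d))
        return X @ projection
    if method == "self_attention":
        X = np.concatenate([Z_i, Z_j], axis=1)
        if projection is None:
            rng = np.random.default_rng(seed)
            lim = math.sqrt(6.0 / (2 * d + d))
            projection = rng.uniform(-lim, lim, size=(2 * d, d))
        H = X @ projection
        return scaled_dot_attention(H, H, H)
    raise ValueError(f"unknown baseline fusion method {method!r}")


# ---------------------------------------------------------------------------
# trainable modules


class MHCAFusion:
    """Trainable bidirectional MHCA + residual LayerNorm + FFN fusion.

    Separate Q/K/V/output projections per direction; LayerNorm affine
    parameters are learnable. Linear reconstruction heads map the fused
    embedding back to each modality latent so a reconstruction objective is
    available even when the autoencoders are frozen.
    """

    def __init__(self, attn_cfg: AttentionConfig, ffn_cfg: FusionFFNConfig,
                 rng: np.random.Generator):
        self.attn_cfg = attn_cfg
        self.ffn_cfg = ffn_cfg
        d, dk, h = attn_cfg.model_dim, attn_cfg.head_dim, attn_cfg.n_heads

        def glorot(n_in, n_out):
            lim = math.sqrt(6.0 / (n_in + n_out))
            return nn.Parameter(rng.uniform(-lim, lim, size=(n_in, n_out)))

        self.proj = {
            direction: {
                "Wq": [glorot(d, dk) for _ in range(h)],
                "Wk": [glorot(d, dk) for _ in range(h)],
                "Wv": [glorot(d, dk) for _ in range(h)],
                "Wo": glorot(h * dk, d),
            } for direction in ("i", "j")
        }
        self.ln_gain = {dr: nn.Parameter(np.ones(d)) for dr in ("i", "j")}
        self.ln_bias = {dr: nn.Parameter(np.zeros(d)) for dr in ("i", "j")}
        self.ffn1 = nn.Linear(2 * d, ffn_cfg.hidden_dim, rng)
        self.ffn2 = nn.Linear(ffn_cfg.hidden_dim, ffn_cfg.output_dim, rng)
        self._ffn_act = nn.activation(ffn_cfg.activation)
        self.recon_i = nn.Linear(ffn_cfg.output_dim, d, rng)
        self.recon_j = nn.Linear(ffn_cfg.output_dim, d, rng)

    def numpy_params(self) -> dict:
        """Current attention projections as plain arrays (for the stateless
        `cross_attention_heads` reference path)."""
        return {dr: {"Wq": [w.data for w in p["Wq"]],
                     "Wk": [w.data for w in p["Wk"]],
                     "Wv": [w.data for w in p["Wv"]],
                     "Wo": p["Wo"].data}
                for dr, p in self.proj.items()}

    def _attend(self, Zq: nn.Tensor, Zkv: nn.Tensor, p: dict) -> nn.Tensor:
        dk = self.attn_cfg.head_dim
        outs = []
        for Wq, Wk, Wv in zip(p["Wq"], p["Wk"], p["Wv"]):
            scores = (Zq @ Wq) @ (Zkv @ Wk).T * (1.0 / math.sqrt(dk))
            outs.append(nn.softmax_rows(scores) @ (Zkv @ Wv))
        cat = outs[0]
        for o in outs[1:]:
            cat = cat.concat(o, axis=1)
        return cat @ p["Wo"]

    def forward(self, Zi: nn.Tensor, Zj: nn.Tensor
                ) -> tuple[nn.Tensor, nn.Tensor, nn.Tensor]:
        head_i = self._attend(Zi, Zj, self.proj["i"])
        head_j = self._attend(Zj, Zi, self.proj["j"])
        hi = nn.layer_norm(head_i + Zi, self.ln_gain["i"], self.ln_bias["i"])
        hj = nn.layer_norm(head_j + Zj, self.ln_gain["j"], self.ln_bias["j"])
        fused = self.ffn2(self._ffn_act(self.ffn1(hi.concat(hj, axis=1))))
        return hi, hj, fused

    def transform(self, Zi: np.ndarray, Zj: np.ndarray) -> np.ndarray:
        """Eval-mode fused embedding for plain arrays."""
        _, _, fused = self.forward(nn.Tensor(np.asarray(Zi, float)),
                                   nn.Tensor(np.asarray(Zj, float)))
        return fused.data

    def parameters(self) -> list[nn.Parameter]:
        ps: list[nn.Parameter] = []
        for p in self.proj.values():
            ps += p["Wq"] + p["Wk"] + p["Wv"] + [p["Wo"]]
        ps += list(self.ln_gain.values()) + list(self.ln_bias.values())
        ps += self.ffn1.parameters() + self.ffn2.parameters()
        ps += self.recon_i.parameters() + self.recon_j.parameters()
        return ps


class BaselineFusion:
    """Trainable ablation fusers sharing the MHCA training protocol.

    concat / self_attention learn a 2d → d projection; sum / average learn
    a d → d projection applied after the elementwise merge.
    """

    def __init__(self, method: str, model_dim: int, rng: np.random.Generator):
        if method not in BASELINE_METHODS:
            raise ValueError(f"unknown baseline fusion method {method!r}")
        self.method = method
        d = model_dim
        n_in = 2 * d if method in ("concat", "self_attention") else d
        self.proj = nn.Linear(n_in, d, rng)
        self.recon_i = nn.Linear(d, d, rng)
        self.recon_j = nn.Linear(d, d, rng)

    def forward(self, Zi: nn.Tensor, Zj: nn.Tensor) -> nn.Tensor:
        if self.method == "sum":
            return self.proj(Zi + Zj)
        if self.method == "average":
            return self.proj((Zi + Zj) * 0.5)
        X = Zi.concat(Zj, axis=1)
        H = self.proj(X)
        if self.method == "concat":
            return H
        d = H.data.shape[1]
        scores = H @ H.T * (1.0 / math.sqrt(d))
        return nn.softmax_rows(scores) @ H

    def transform(self, Zi: np.ndarray, Zj: np.ndarray) -> np.ndarray:
        return self.forward(nn.Tensor(np.asarray(Zi, float)),
                            nn.Tensor(np.asarray(Zj, float))).data

    def parameters(self) -> list[nn.Parameter]:
        return (self.proj.parameters() + self.recon_i.parameters()
                + self.recon_j.parameters())


def _contrastive_loss_t(fused: nn.Tensor, labels: np.ndarray,
                        temperature: float) -> nn.Tensor:
    """Differentiable multi-positive SupCon term (train cells only)."""
    pos, neg = _contrastive_masks(labels)
    n_pairs = int(pos.sum())
    if n_pairs == 0:
        return nn.Tensor(0.0)
    Zn = nn.l2_normalize_rows(fused)
    S = Zn @ Zn.T * (1.0 / temperature)
    E = S.exp()
    neg_sum = (E * nn.Tensor(neg.astype(float))).sum(axis=1, keepdims=True)
    # log(exp(s_ap) + Σ_neg) − s_ap, summed over anchor–positive pairs
    per_pair = ((E + neg_sum).log() - S) * nn.Tensor(pos.astype(float))
    return per_pair.sum() * (1.0 / n_pairs)


def train_fusion(Z_i: np.ndarray, Z_j: np.ndarray, labels: np.ndarray,
                 train_mask: np.ndarray,
                 attn_cfg: AttentionConfig | None = None,
                 con_cfg: ContrastiveConfig | None = None,
                 ffn_cfg: FusionFFNConfig | None = None,
                 epochs: int = 60, lr: float = 1e-3, seed: int = 0,
                 method: str = "mhca",
                 autoencoders: tuple[Autoencoder, Autoencoder] | None = None,
                 inputs: tuple[np.ndarray, np.ndarray] | None = None,
                 freeze_encoders: bool = False,
                 ) -> tuple[object, np.ndarray, dict[str, list[float]]]:
    """Train the fusion module on L_total = L_recon + λ_c · L_contrastive.

    The contrastive term uses labels of train-mask cells only; test labels
    are never touched. When an autoencoder pair (and its input matrices)
    is supplied, the encoders are fine-tuned jointly and L_recon is the
    weighted joint reconstruction objective; otherwise the latents are fixed
    and L_recon reconstructs them from the fused embedding through linear
    heads. Returns (model, fused Z for all cells, loss history).
    """
    Z_i = np.asarray(Z_i, dtype=np.float64)
    Z_j = np.asarray(Z_j, dtype=np.float64)
    if Z_i.shape != Z_j.shape:
        raise ValueError("latent shapes differ")
    train_mask = np.asarray(train_mask, dtype=bool)
    if train_mask.sum() == 0:
        raise ValueError("train mask is empty")
    labels = np.asarray(labels)
    train_idx = np.flatnonzero(train_mask)
    train_labels = labels[train_idx]

    d = Z_i.shape[1]
    attn_cfg = attn_cfg or AttentionConfig(model_dim=d)
    con_cfg = con_cfg or ContrastiveConfig()
    ffn_cfg = ffn_cfg or FusionFFNConfig(hidden_dim=2 * d, output_dim=d)
    rng = np.random.default_rng(seed)

    if method == "mhca":
        model: MHCAFusion | BaselineFusion = MHCAFusion(attn_cfg, ffn_cfg, rng)
    else:
        model = BaselineFusion(method, d, rng)

    params = list(model.parameters())
    finetune_ae = autoencoders is not None and inputs is not None and not freeze_encoders
    if finetune_ae:
        ae_i, ae_j = autoencoders
        Xi_t, Xj_t = nn.Tensor(np.asarray(inputs[0], float)), nn.Tensor(np.asarray(inputs[1], float))
        params += ae_i.parameters() + ae_j.parameters()
        alpha, beta = ae_i.cfg.alpha, ae_i.cfg.beta
    else:
        Zi_fix, Zj_fix = nn.Tensor(Z_i), nn.Tensor(Z_j)

    opt = nn.Adam(params, lr=lr)
    history: dict[str, list[float]] = {"total": [], "recon": [], "contrastive": []}
    for _ in range(epochs):
        opt.zero_grad()
        if finetune_ae:
            Zi_t = ae_i.encode_t(Xi_t, training=True)
            Zj_t = ae_j.encode_t(Xj_t, training=True)
        else:
            Zi_t, Zj_t = Zi_fix, Zj_fix
        if method == "mhca":
            _, _, fused = model.forward(Zi_t, Zj_t)
        else:
            fused = model.forward(Zi_t, Zj_t)
        if finetune_ae:
            recon = (alpha * nn.mse(Xi_t, ae_i.decode_t(Zi_t))
                     + beta * nn.mse(Xj_t, ae_j.decode_t(Zj_t)))
        else:
            recon = (0.5 * nn.mse(Zi_t, model.recon_i(fused))
                     + 0.5 * nn.mse(Zj_t, model.recon_j(fused)))
        if con_cfg.loss_weight > 0:
            con = _contrastive_loss_t(fused.rows(train_idx), train_labels,
                                      con_cfg.temperature)
        else:
            con = nn.Tensor(0.0)
        loss = recon + con_cfg.loss_weight * con
        loss.backward()
        opt.step()
        history["total"].append(float(loss.data))
        history["recon"].append(float(recon.data))
        history["contrastive"].append(float(con.data))

    if finetune_ae:
        Zi_out = ae_i.encode(Xi_t.data)
        Zj_out = ae_j.encode(Xj_t.data)
    else:
        Zi_out, Zj_out = Z_i, Z_j
    fused_final = model.transform(Zi_out, Zj_out)
    return model, fused_final, history
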