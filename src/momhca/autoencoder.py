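"""Dual modality-specific autoencoders.

One encoder–decoder pathway per omics modality (d_m → 512 → 128 and back),
GELU activations with batch normalisation after the hidden layer, trained
jointly on the weighted reconstruction objective

    L = α · MSE(X_i, X_i') + β · MSE(X_j, X_j'),   α + β = 1,

so both pathways converge into a shared 128-dimensional latent space.
Weights are not shared between modalities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .preprocess import LatentEmbedding, OmicsMatrix

__all__ = ["AEConfig", "Autoencoder", "joint_reconstruction_loss", "train_dual_ae"]


@dataclass
class AEConfig:
    input_dim: int
    hidden_dim: int = 512
    latent_dim: int = 128
    activation: str = "gelu"
    use_batchnorm: bool = True
    alpha: float = 0.5
    beta: float = 0.5

    def __post_init__(self):
        if abs(self.alpha + self.beta - 1.0) > 1e-9:
            raise ValueError(f"alpha + beta must equal 1, got {self.alpha + self.beta}")
        if min(self.input_dim, self.hidden_dim, self.latent_dim) <= 0:
            raise ValueError("dimensions must be positive")


class Autoencoder:
    """Encoder d_m → hidden → latent; mirrored decoder with linear output."""

    def __init__(self, cfg: AEConfig, rng: np.random.Generator):
        self.cfg = cfg
        act = nn.activation(cfg.activation)
        self._act = act
        self.enc1 = nn.Linear(cfg.input_dim, cfg.hidden_dim, rng)
        self.enc2 = nn.Linear(cfg.hidden_dim, cfg.latent_dim, rng)
        self.dec1 = nn.Linear(cfg.latent_dim, cfg.hidden_dim, rng)
        self.dec2 = nn.Linear(cfg.hidden_dim, cfg.input_dim, rng)
        self.bn = nn.BatchNorm1d(cfg.hidden_dim) if cfg.use_batchnorm else None

    # -- forward ----------------------------------------------------------
    def encode_t(self, x: nn.Tensor, training: bool = False) -> nn.Tensor:
        h = self.enc1(x)
        if self.bn is not None:
            h = self.bn(h, training=training)
        return self.enc2(self._act(h))

    def decode_t(self, z: nn.Tensor) -> nn.Tensor:
        return self.dec2(self._act(self.dec1(z)))

    def encode(self, x: np.ndarray) -> np.ndarray:
        """Deterministic (eval-mode) encoding of an N × d_m matrix."""
        x = np.asarray(x, dtype=np.float64)
        if x.ndim != 2 or x.shape[1] != self.cfg.input_dim:
            raise ValueError(f"expected N×{self.cfg.input_dim} input, got {x.shape}")
        return self.encode_t(nn.Tensor(x), training=False).data

    def decode(self, z: np.ndarray) -> np.ndarray:
        z = np.asarray(z, dtype=np.float64)
        if z.ndim != 2 or z.shape[1] != self.cfg.latent_dim:
            raise ValueError(f"expected N×{self.cfg.latent_dim} latent, got {z.shape}")
        return self.decode_t(nn.Tensor(z)).data

    def parameters(self) -> list[nn.Parameter]:
        ps = (self.enc1.parameters() + self.enc2.parameters()
              + self.dec1.parameters() + self.dec2.parameters())
        if self.bn is not None:
            ps += self.bn.parameters()
        return ps

    # -- persistence ------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        d = {}
        for name in ("enc1", "enc2", "dec1", "dec2"):
            layer = getattr(self, name)
            d[f"{name}.W"] = layer.W.data
            d[f"{name}.b"] = layer.b.data
        if self.bn is not None:
            d["bn.gamma"] = self.bn.gamma.data
            d["bn.beta"] = self.bn.beta.data
            d["bn.running_mean"] = self.bn.running_mean
            d["bn.running_var"] = self.bn.running_var
        return d

    def load_state_dict(self, d: dict[str, np.ndarray]) -> None:
        for name in ("enc1", "enc2", "dec1", "dec2"):
            layer = getattr(self, name)
            layer.W.data = np.asarray(d[f"{name}.W"], dtype=np.float64)
            layer.b.data = np.asarray(d[f"{name}.b"], dtype=np.float64)
        if self.bn is not None:
            self.bn.gamma.data = np.asarray(d["bn.gamma"], dtype=np.float64)
            self.bn.beta.data = np.asarray(d["bn.beta"], dtype=np.float64)
            self.bn.running_mean = np.asarray(d["bn.running_mean"], dtype=np.float64)
            self.bn.running_var = np.asarray(d["bn.running_var"], dtype=np.float64)


def joint_reconstruction_loss(Xi: np.ndarray, Xi_hat: np.ndarray,
                              Xj: np.ndarray, Xj_hat: np.ndarray,
                              alpha: float = 0.5, beta: float = 0.5) -> float:
    """α·MSE(X_i, X_i') + β·MSE(X_j, X_j'), means over all matrix entries."""
    if abs(alpha + beta - 1.0) > 1e-9:
        raise ValueError("alpha + beta must equal 1")
    Xi, Xi_hat = np.asarray(Xi, float), np.asarray(Xi_hat, float)
    Xj, Xj_hat = np.asarray(Xj, float), np.asarray(Xj_hat, float)
    if Xi.shape != Xi_hat.shape or Xj.shape != Xj_hat.shape:
        raise ValueError("reconstruction shapes do not match inputs")
    return float(alpha * np.mean((Xi - Xi_hat) ** 2) + beta * np.mean((Xj - Xj_hat) ** 2))


def _as_array(x) -> tuple[np.ndarray, list[str] | None]:
    if isinstance(x, OmicsMatrix):
        return x.dense(), list(x.cell_ids)
    if isinstance(x, LatentEmbedding):
        return x.values, list(x.cell_ids) if x.cell_ids is not None else None
    return np.asarray(x, dtype=np.float64), None


def train_dual_ae(rna, atac, config: AEConfig | None = None, epochs: int = 200,
                  lr: float = 1e-3, seed: int = 0,
                  atac_config: AEConfig | None = None,
                  ) -> tuple[tuple[Autoencoder, Autoencoder], np.ndarray, np.ndarray, list[float]]:
    """Jointly train both autoencoders on the weighted reconstruction loss.

    Accepts reduced/scaled matrices (arrays, OmicsMatrix or LatentEmbedding)
    with identical cell order. Returns the trained autoencoder pair, the two
    latent embeddings Z_i (RNA) and Z_j (ATAC), and the per-epoch loss
    history. Full-batch Adam; reproducible given `seed`.
    """
    Xi, ids_i = _as_array(rna)
    Xj, ids_j = _as_array(atac)
    if Xi.shape[0] != Xj.shape[0]:
        raise ValueError(f"cell counts differ: {Xi.shape[0]} vs {Xj.shape[0]}")
    if ids_i is not None and ids_j is not None:
        for a, b in zip(ids_i, ids_j):
            if a != b:
                raise ValueError(f"cell order mismatch at id {a!r} vs {b!r}")
    rng = np.random.default_rng(seed)
    cfg_i = config or AEConfig(input_dim=Xi.shape[1])
    cfg_j = atac_config or AEConfig(
        input_dim=Xj.shape[1], hidden_dim=cfg_i.hidden_dim,
        latent_dim=cfg_i.latent_dim, activation=cfg_i.activation,
        use_batchnorm=cfg_i.use_batchnorm, alpha=cfg_i.alpha, beta=cfg_i.beta)
    ae_i = Autoencoder(cfg_i, rng)
    ae_j = Autoencoder(cfg_j, rng)
    opt = nn.Adam(ae_i.parameters() + ae_j.parameters(), lr=lr)
    ti, tj = nn.Tensor(Xi), nn.Tensor(Xj)
    history: list[float] = []
    for _ in range(epochs):
        opt.zero_grad()
        zi = ae_i.encode_t(ti, training=True)
        zj = ae_j.encode_t(tj, training=True)
        loss = (cfg_i.alpha * nn.mse(ti, ae_i.decode_t(zi))
                + cfg_i.beta * nn.mse(tj, ae_j.decode_t(zj)))
        loss.backward()
        opt.step()
        history.append(float(loss.data))
    Zi = ae_i.encode(Xi)
    Zj = ae_j.encode(Xj)
    return (ae_i, ae_j), Zi, Zj, history
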