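"""Graph-convolutional contrastive autoencoder.

Two-layer GCN encoders embed the corrupted graph views; an InfoNCE
objective with a community-strength bonus pulls the two views of each spot
together; an attention layer fuses the spatial and histology embeddings into
the final latent matrix Z; a GCN decoder on the fused graph reconstructs the
normalized expression, which doubles as denoising.

The total objective is

    L_total = lambda_topo * L_topo + lambda_HE * L_HE + lambda_recon * L_recon

with defaults lambda_topo = 0.1, lambda_HE = 0.1, lambda_recon = 1.0; when no
histology features are available lambda_HE is forced to 0 and fusion is
bypassed (Z = Z_s).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import scipy.sparse as sp

from .autodiff import Adam, Tensor, spmm
from .community import CommunityPartition, community_strength, generate_views
from .dataset import SpatialDataset
from .graphs import SpotGraph

__all__ = [
    "ModelConfig",
    "TrainedModel",
    "gcn_encode",
    "gamma_schedule",
    "contrastive_loss",
    "attention_fuse",
    "gcn_decode",
    "reconstruction_loss",
    "total_loss",
    "train",
]


@dataclass
class ModelConfig:
    """Hyperparameters of the contrastive autoencoder."""

    latent_dim: int = 64
    hidden_dim: int = 256
    attention_dim: int = 32
    tau: float = 0.5
    k0: int = 20
    gamma_max: float = 1.0
    lambda_topo: float = 0.1
    lambda_he: float = 0.1
    lambda_recon: float = 1.0
    lambda_a1: float = 0.1
    lambda_a2: float = 0.2
    lambda_e1: float = 0.2
    lambda_e2: float = 0.3
    epochs: int = 300
    learning_rate: float = 1e-3
    seed: int = 0
    use_histology: bool = False

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if min(self.lambda_topo, self.lambda_he, self.lambda_recon) < 0:
            raise ValueError("loss weights must be nonnegative")
        if self.gamma_max < 0:
            raise ValueError("gamma_max must be nonnegative")
        if not self.use_histology:
            self.lambda_he = 0.0

    @property
    def view_lambdas(self) -> dict:
        return {
            "lambda_a1": self.lambda_a1,
            "lambda_a2": self.lambda_a2,
            "lambda_e1": self.lambda_e1,
            "lambda_e2": self.lambda_e2,
        }


@dataclass
class TrainedModel:
    """Fitted parameters plus the final embedding and denoised matrix."""

    encoder_params: dict
    decoder_params: dict
    attention_params: Optional[dict]
    final_embedding: np.ndarray
    attention_scores: Optional[np.ndarray]
    denoised: np.ndarray
    loss_history: list
    config: ModelConfig


# -- adjacency normalization ----------------------------------------------


def normalize_adjacency(A: sp.spmatrix, add_self_loops: bool = True) -> sp.csr_matrix:
    """Symmetric degree normalization D^{-1/2} (A [+ I]) D^{-1/2}."""
    A = sp.csr_matrix(A, dtype=float)
    if add_self_loops:
        A = A + sp.identity(A.shape[0], format="csr")
    deg = np.asarray(A.sum(axis=1)).ravel()
    dinv = np.where(deg > 0, 1.0 / np.sqrt(deg), 0.0)
    D = sp.diags(dinv)
    return (D @ A @ D).tocsr()


# -- functional ops (numpy surface; training uses the autodiff twins) ------


def gcn_encode(features: np.ndarray, adjacency, params: dict) -> np.ndarray:
    """Two-layer GCN forward pass Z = A_hat relu(A_hat X W0) W1.

    ``adjacency`` is the raw symmetric adjacency (self-loops are added during
    normalization); ``params`` holds the weight matrices ``W0`` and ``W1``.
    """
    A = adjacency.adjacency if isinstance(adjacency, SpotGraph) else adjacency
    Ahat = normalize_adjacency(A, add_self_loops=True)
    X = np.asarray(features, dtype=float)
    W0 = np.asarray(params["W0"], dtype=float)
    W1 = np.asarray(params["W1"], dtype=float)
    H = np.maximum(Ahat @ (X @ W0), 0.0)
    Z = Ahat @ (H @ W1)
    if not np.all(np.isfinite(Z)):
        raise FloatingPointError("encoder produced non-finite values")
    return Z


def gamma_schedule(k: int, k0: int, gamma_max: float) -> float:
    """Piecewise-linear ramp min{max{0, k - k0}, gamma_max}."""
    if gamma_max < 0:
        raise ValueError("gamma_max must be nonnegative")
    return float(min(max(0, k - k0), gamma_max))


def _strength_bonus(n: int, gamma: float, part: Optional[CommunityPartition]) -> np.ndarray:
    """Additive same-community similarity bonus gamma * S_{c_i} (0 off-community)."""
    if part is None or gamma == 0.0:
        return np.zeros((n, n))
    s = part.node_strength()
    same = part.assignment[:, None] == part.assignment[None, :]
    return np.where(same, gamma * s[:, None], 0.0)


def _infonce_pair(Z1n: Tensor, Z2n: Tensor, tau: float, B: Optional[np.ndarray]) -> Tensor:
    """Symmetrized InfoNCE on row-normalized embeddings as one tape node.

    The gradient with respect to the logit matrices has the closed softmax
    form, so both directions are evaluated in a single fused operation with a
    log-sum-exp shift for stability; ``B`` is the (constant) additive
    community bonus already divided by tau.
    """
    A1, A2 = Z1n.data, Z2n.data
    n = A1.shape[0]
    S11 = A1 @ A1.T / tau
    S22 = A2 @ A2.T / tau
    S12 = A1 @ A2.T / tau
    if B is not None:
        S11 = S11 + B
        S22 = S22 + B
        S12 = S12 + B
    diag = np.diag_indices(n)
    off = ~np.eye(n, dtype=bool)

    def direction(Saa, Sab):
        masked = np.where(off, Saa, -np.inf)
        M = np.maximum(masked.max(axis=1), Sab.max(axis=1))
        Eaa = np.exp(Saa - M[:, None])
        Eaa[diag] = 0.0
        Eab = np.exp(Sab - M[:, None])
        den = Eaa.sum(axis=1) + Eab.sum(axis=1)
        loss = -float(np.mean(Sab[diag] - (M + np.log(den))))
        Gaa = Eaa / (n * den[:, None])
        Gab = Eab / (n * den[:, None])
        Gab[diag] -= 1.0 / n
        return loss, Gaa, Gab

    L1, G1aa, G1ab = direction(S11, S12)
    L2, G2bb, G2ba = direction(S22, np.ascontiguousarray(S12.T))
    out = Tensor(0.5 * (L1 + L2))
    if Z1n.requires_grad or Z1n._parents or Z2n.requires_grad or Z2n._parents:
        def bw(g):
            s = 0.5 * float(g) / tau
            Z1n._accumulate(s * ((G1aa + G1aa.T) @ A1 + G1ab @ A2 + G2ba.T @ A2))
            Z2n._accumulate(s * ((G2bb + G2bb.T) @ A2 + G1ab.T @ A1 + G2ba @ A1))

        out.requires_grad = True
        out._parents = (Z1n, Z2n)
        out._backward = bw
    return out


def _contrastive_tensor(
    Z1: Tensor,
    Z2: Tensor,
    tau: float,
    gamma: float,
    part: Optional[CommunityPartition],
) -> Tensor:
    n = Z1.shape[0]
    for Z in (Z1, Z2):
        norms = np.linalg.norm(Z.data, axis=1)
        if np.any(norms == 0):
            raise ValueError("zero-norm embedding row: cosine similarity undefined")
    B = _strength_bonus(n, gamma, part) / tau if (part is not None and gamma) else None
    return _infonce_pair(Z1.row_normalize(), Z2.row_normalize(), tau, B)


def contrastive_loss(
    Z1: np.ndarray,
    Z2: np.ndarray,
    tau: float = 0.5,
    gamma: float = 0.0,
    part: Optional[CommunityPartition] = None,
) -> float:
    """Community-strength-enhanced InfoNCE between two view embeddings.

    Cosine-similarity logits at temperature ``tau``; pairs of spots sharing a
    community receive an additive bonus ``gamma * S_c``. ``gamma = 0``
    recovers plain symmetrized InfoNCE.
    """
    Z1 = np.asarray(Z1, dtype=float)
    Z2 = np.asarray(Z2, dtype=float)
    if Z1.shape != Z2.shape:
        raise ValueError("view embeddings must share a shape")
    return float(_contrastive_tensor(Tensor(Z1), Tensor(Z2), tau, gamma, part).data)


def _attention_tensor(Zs: Tensor, Zh: Tensor, params: dict) -> tuple[Tensor, Tensor, Tensor]:
    W1, b1, W2, b2 = params["W1"], params["b1"], params["W2"], params["b2"]

    def score(Z):
        return (Z @ W1 + b1).tanh() @ W2 + b2  # (n, 1)

    ls, lh = score(Zs), score(Zh)
    m = np.maximum(ls.data, lh.data)  # constant shift for a stable softmax
    es, eh = (ls - m).exp(), (lh - m).exp()
    den = es + eh
    a_s, a_h = es / den, eh / den
    Z = a_s * Zs + a_h * Zh
    return Z, a_s, a_h


def attention_fuse(
    Zs: np.ndarray, Zh: np.ndarray, params: dict
) -> tuple[np.ndarray, np.ndarray]:
    """Per-spot softmax gating of the spatial and histology embeddings.

    Returns the fused embedding and the (n, 2) score matrix alpha whose rows
    sum to 1.
    """
    Zs = np.asarray(Zs, dtype=float)
    Zh = np.asarray(Zh, dtype=float)
    if Zs.shape != Zh.shape:
        raise ValueError("embeddings must share a shape")
    p = {k: Tensor(np.asarray(v, dtype=float)) for k, v in params.items()}
    Z, a_s, a_h = _attention_tensor(Tensor(Zs), Tensor(Zh), p)
    alpha = np.column_stack([a_s.data.ravel(), a_h.data.ravel()])
    return Z.data, alpha


def gcn_decode(Z: np.ndarray, gw: SpotGraph, params: dict) -> np.ndarray:
    """Single graph-conv layer on the degree-normalized fused graph.

    ``gw`` already carries its identity term, so no extra self-loops are
    added before normalization.
    """
    Ghat = normalize_adjacency(gw.adjacency, add_self_loops=False)
    Z = np.asarray(Z, dtype=float)
    return Ghat @ (Z @ np.asarray(params["Wd"], dtype=float)) + np.asarray(
        params["bd"], dtype=float
    )


def reconstruction_loss(Xhat: np.ndarray, X: np.ndarray) -> float:
    """Mean squared error over all entries."""
    Xhat = np.asarray(Xhat, dtype=float)
    X = np.asarray(X, dtype=float)
    if Xhat.shape != X.shape:
        raise ValueError("shapes must match")
    return float(np.mean((Xhat - X) ** 2))


def total_loss(l_topo: float, l_he: float, l_recon: float, cfg: ModelConfig) -> float:
    """Weighted sum lambda_topo*L_topo + lambda_HE*L_HE + lambda_recon*L_recon."""
    return cfg.lambda_topo * l_topo + cfg.lambda_he * l_he + cfg.lambda_recon * l_recon


# -- training --------------------------------------------------------------


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def _init_params(cfg: ModelConfig, n_genes: int, rng: np.random.Generator) -> dict:
    p: dict[str, Tensor] = {}

    def add(name, arr):
        p[name] = Tensor(arr, requires_grad=True)

    add("enc_s/W0", _glorot(rng, n_genes, cfg.hidden_dim))
    add("enc_s/W1", _glorot(rng, cfg.hidden_dim, cfg.latent_dim))
    if cfg.use_histology:
        add("enc_h/W0", _glorot(rng, n_genes, cfg.hidden_dim))
        add("enc_h/W1", _glorot(rng, cfg.hidden_dim, cfg.latent_dim))
        add("att/W1", _glorot(rng, cfg.latent_dim, cfg.attention_dim))
        add("att/b1", np.zeros(cfg.attention_dim))
        add("att/W2", _glorot(rng, cfg.attention_dim, 1))
        add("att/b2", np.zeros(1))
    add("dec/Wd", _glorot(rng, cfg.latent_dim, n_genes))
    add("dec/bd", np.zeros(n_genes))
    return p


def _encode_t(X: Tensor, Ahat: sp.csr_matrix, W0: Tensor, W1: Tensor) -> Tensor:
    return spmm(Ahat, spmm(Ahat, X @ W0).relu() @ W1)


def _check_finite(value: float, term: str) -> float:
    if not np.isfinite(value):
        raise RuntimeError(f"non-finite loss in term '{term}'")
    return value


def train(
    ds: SpatialDataset,
    gs: SpotGraph,
    gh: Optional[SpotGraph],
    gw: SpotGraph,
    part: CommunityPartition,
    cfg: ModelConfig,
) -> TrainedModel:
    """Fit the contrastive graph autoencoder.

    Each epoch regenerates two corrupted views of the spatial graph (and of
    the histology graph when present), computes the topology (and histology)
    contrastive losses on the view embeddings, decodes the fused clean
    embedding on ``gw`` and takes one Adam step on the weighted total loss.
    Fully deterministic for a fixed ``cfg.seed``.
    """
    if cfg.use_histology and gh is None:
        raise ValueError("use_histology is set but no histology graph was given")
    X = ds.dense_expression()
    n, p_genes = X.shape
    for g, name in ((gs, "spatial"), (gw, "fused")):
        if g.n_nodes != n:
            raise ValueError(f"{name} graph node count does not match dataset")
    if gh is not None and gh.n_nodes != n:
        raise ValueError("histology graph node count does not match dataset")

    rng = np.random.default_rng(cfg.seed)
    params = _init_params(cfg, p_genes, rng)
    opt = Adam(list(params.values()), lr=cfg.learning_rate)

    part_s = part.with_strength(community_strength(gs, part))
    part_h = (
        part.with_strength(community_strength(gh, part))
        if (gh is not None and cfg.use_histology)
        else None
    )
    Xc = Tensor(X)
    Ahat_s = normalize_adjacency(gs.adjacency, add_self_loops=True)
    Ahat_h = (
        normalize_adjacency(gh.adjacency, add_self_loops=True)
        if part_h is not None
        else None
    )
    Ghat_w = normalize_adjacency(gw.adjacency, add_self_loops=False)

    def clean_forward():
        Zs = _encode_t(Xc, Ahat_s, params["enc_s/W0"], params["enc_s/W1"])
        alpha = None
        if part_h is not None:
            Zh = _encode_t(Xc, Ahat_h, params["enc_h/W0"], params["enc_h/W1"])
            att = {k.split("/")[1]: params[k] for k in params if k.startswith("att/")}
            Z, a_s, a_h = _attention_tensor(Zs, Zh, att)
            alpha = (a_s, a_h)
        else:
            Z = Zs
        Xhat = spmm(Ghat_w, Z @ params["dec/Wd"]) + params["dec/bd"]
        return Z, alpha, Xhat

    def view_loss(graph, strength_part, Ahat_base, W0, W1, epoch_seed, gamma):
        v1, v2 = generate_views(
            graph, X, strength_part, cfg.view_lambdas, seed=epoch_seed
        )
        Z1 = _encode_t(
            Tensor(v1.features), normalize_adjacency(v1.adjacency, True), W0, W1
        )
        Z2 = _encode_t(
            Tensor(v2.features), normalize_adjacency(v2.adjacency, True), W0, W1
        )
        return _contrastive_tensor(Z1, Z2, cfg.tau, gamma, strength_part)

    history: list[dict] = []
    for epoch in range(cfg.epochs):
        gamma = gamma_schedule(epoch, cfg.k0, cfg.gamma_max)
        seed_s = int(
            np.random.SeedSequence([cfg.seed, epoch, 0]).generate_state(1)[0] % 2**31
        )
        opt.zero_grad()
        l_topo_t = view_loss(
            gs, part_s, Ahat_s, params["enc_s/W0"], params["enc_s/W1"], seed_s, gamma
        )
        l_he_t = None
        if part_h is not None:
            seed_h = int(
                np.random.SeedSequence([cfg.seed, epoch, 1]).generate_state(1)[0]
                % 2**31
            )
            l_he_t = view_loss(
                gh, part_h, Ahat_h, params["enc_h/W0"], params["enc_h/W1"],
                seed_h, gamma,
            )
        _, _, Xhat = clean_forward()
        diff = Xhat - Xc
        l_recon_t = (diff * diff).mean()

        l_topo = _check_finite(float(l_topo_t.data), "L_topo")
        l_he = _check_finite(float(l_he_t.data), "L_HE") if l_he_t is not None else 0.0
        l_recon = _check_finite(float(l_recon_t.data), "L_recon")

        total_t = l_topo_t * cfg.lambda_topo + l_recon_t * cfg.lambda_recon
        if l_he_t is not None:
            total_t = total_t + l_he_t * cfg.lambda_he
        total_t.backward()
        opt.step()
        history.append(
            {
                "epoch": epoch,
                "l_topo": l_topo,
                "l_he": l_he,
                "l_recon": l_recon,
                "total": total_loss(l_topo, l_he, l_recon, cfg),
            }
        )

    Z_t, alpha_t, Xhat_t = clean_forward()
    alpha = (
        np.column_stack([alpha_t[0].data.ravel(), alpha_t[1].data.ravel()])
        if alpha_t is not None
        else None
    )
    enc = {k: params[k].data.copy() for k in params if k.startswith("enc")}
    dec = {k.split("/")[1]: params[k].data.copy() for k in params if k.startswith("dec/")}
    att = (
        {k.split("/")[1]: params[k].data.copy() for k in params if k.startswith("att/")}
        or None
    )
    return TrainedModel(
        encoder_params=enc,
        decoder_params=dec,
        attention_params=att,
        final_embedding=Z_t.data.copy(),
        attention_scores=alpha,
        denoised=Xhat_t.data.copy(),
        loss_history=history,
        config=cfg,
    )
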