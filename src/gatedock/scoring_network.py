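"""The full decoy-scoring network.

Architecture (all defaults fixed by :class:`NetworkConfig`):

1. affine embedding of the 23-dim atom features into F = 140;
2. four gate-augmented attention layers; each layer runs once with
   the covalent adjacency A1 and once with the covalent +
   cross-molecular adjacency A2 using the *same* layer parameters,
   and the node embedding passed on is the difference
   ``GAT(x, A2) - GAT(x, A1)``, which cancels everything except the
   signal contributed by cross-molecular edges;
3. sum pooling over nodes into a single graph vector;
4. a 4-layer fully connected head (140 -> 128 -> 128 -> 128 -> 1)
   with rectifier activations and a logistic output: the probability
   that the decoy is of acceptable quality.

Dropout (p = 0.3) is applied in training mode after the embedding,
after each subtracted GAT layer, and after FC layers 1-3.

The Gaussian cross-edge weights of A2 are rebuilt from the stored
cross-distance matrix inside every forward pass so that gradients
reach the edge parameters mu and sigma.

Graphs in a batch are grouped by node count internally; graphs with
equal N are stacked and processed in one pass.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .gated_attention import GatLayerParams, attention_weights, gated_update
from .interface_graph import SIGMA_FLOOR, EdgeParams, InterfaceGraphPair

CHECKPOINT_VERSION = 1


@dataclass
class NetworkConfig:
    input_dim: int = 23
    feature_width: int = 140
    n_gat_layers: int = 4
    fc_dims: tuple = (140, 128, 128, 128, 1)
    dropout: float = 0.3

    def validate(self) -> None:
        if self.fc_dims[0] != self.feature_width or self.fc_dims[-1] != 1:
            raise ValueError("fc head must map feature_width -> ... -> 1")
        if len(self.fc_dims) != 5:
            raise ValueError("fc head has exactly 4 weight layers")


@dataclass
class DecoyScore:
    probability: float

    def __post_init__(self):
        if not (0.0 <= self.probability <= 1.0):
            raise ValueError(f"probability out of range: {self.probability}")


@dataclass
class NetworkParams:
    config: NetworkConfig
    embed_w: Tensor  # (F, 23)
    embed_b: Tensor  # (F,)
    gat_layers: list[GatLayerParams]
    fc: list[tuple[Tensor, Tensor]]  # [(W_out_in, b_out), ...]
    mu: Tensor  # () Gaussian edge center
    sigma: Tensor  # () Gaussian edge width

    def parameters(self) -> list[Tensor]:
        out = [self.embed_w, self.embed_b]
        for layer in self.gat_layers:
            out += [layer.W, layer.E_att, layer.D, layer.b]
        for w, b in self.fc:
            out += [w, b]
        out += [self.mu, self.sigma]
        return out

    def edge_params(self) -> EdgeParams:
        return EdgeParams(float(self.mu.data), float(self.sigma.data))

    def copy(self) -> "NetworkParams":
        def t(x: Tensor) -> Tensor:
            return Tensor(x.data.copy(), requires_grad=True)

        return NetworkParams(
            config=self.config,
            embed_w=t(self.embed_w),
            embed_b=t(self.embed_b),
            gat_layers=[GatLayerParams(t(l.W), t(l.E_att), t(l.D), t(l.b))
                        for l in self.gat_layers],
            fc=[(t(w), t(b)) for w, b in self.fc],
            mu=t(self.mu),
            sigma=t(self.sigma),
        )


def _glorot(rng: np.random.Generator, fan_out: int, fan_in: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_out, fan_in))


def init_params(config: NetworkConfig | None = None, seed: int = 0) -> NetworkParams:
    """Glorot-uniform weights, zero biases, mu = 0.0, sigma = 1.0."""
    if config is None:
        config = NetworkConfig()
    config.validate()
    rng = np.random.default_rng(seed)
    f = config.feature_width

    def p(data) -> Tensor:
        return Tensor(data, requires_grad=True)

    embed_w = p(_glorot(rng, f, config.input_dim))
    embed_b = p(np.zeros(f))
    layers = []
    for _ in range(config.n_gat_layers):
        layers.append(GatLayerParams(
            W=p(_glorot(rng, f, f)),
            E_att=p(_glorot(rng, f, f)),
            D=p(_glorot(rng, 2 * f, 1).reshape(2 * f, 1)),
            b=p(np.zeros(())),
        ))
    fc = []
    for din, dout in zip(config.fc_dims[:-1], config.fc_dims[1:]):
        fc.append((p(_glorot(rng, dout, din)), p(np.zeros(dout))))
    return NetworkParams(
        config=config,
        embed_w=embed_w,
        embed_b=embed_b,
        gat_layers=layers,
        fc=fc,
        mu=p(np.zeros(())),
        sigma=p(np.ones(())),
    )


# ---------------------------------------------------------------------------
# forward pass
# ---------------------------------------------------------------------------

def _dropout(x: Tensor, p: float, training: bool,
             rng: np.random.Generator | None) -> Tensor:
    if not training or p <= 0.0:
        return x
    if rng is None:
        raise ValueError("training-mode forward needs a random generator")
    keep = (rng.random(x.shape) >= p) / (1.0 - p)
    return ad.mul(x, keep)


def _a2_tensor(a1: np.ndarray, cross_dist: np.ndarray,
               params: NetworkParams) -> Tensor:
    """Differentiable A2 = A1 (within) + Gaussian cross weights."""
    mask = np.isfinite(cross_dist)
    d = np.where(mask, cross_dist, 0.0)
    sigma = ad.clip(params.sigma, SIGMA_FLOOR, np.inf)
    diff = ad.sub(d, params.mu)
    weights = ad.exp(ad.neg(ad.div(ad.square(diff), sigma)))
    return ad.add(a1, ad.where_const(mask, weights, 0.0))


def _forward_stack(features: np.ndarray, a1: np.ndarray,
                   cross_dist: np.ndarray, params: NetworkParams,
                   training: bool, rng) -> Tensor:
    """Logits for a stack of same-size graphs.

    ``features`` (B, N, 23), ``a1``/``cross_dist`` (B, N, N).
    Returns logits of shape (B, 1).
    """
    cfg = params.config
    a2 = _a2_tensor(a1, cross_dist, params)

    x = ad.add(ad.matmul(ad.tensor(features), params.embed_w.T), params.embed_b)
    x = _dropout(x, cfg.dropout, training, rng)

    for layer in params.gat_layers:
        # x' and the symmetric bilinear logits do not depend on the
        # adjacency, so they are shared between the A1 and A2 passes
        # (the layer parameters are shared by construction).
        xp = ad.matmul(x, layer.W.T)
        s = ad.matmul(ad.matmul(xp, layer.E_att), xp.T)
        e = ad.add(s, s.T)
        outs = []
        for adj in (a1, a2):
            a = attention_weights(e, adj)
            xagg = ad.matmul(a, xp)
            outs.append(gated_update(x, xagg, layer))
        x = ad.sub(outs[1], outs[0])
        x = _dropout(x, cfg.dropout, training, rng)

    graph_vec = ad.tsum(x, axis=-2)  # (B, F)
    h = graph_vec
    n_fc = len(params.fc)
    for i, (w, b) in enumerate(params.fc):
        h = ad.add(ad.matmul(h, w.T), b)
        if i < n_fc - 1:
            h = ad.relu(h)
            h = _dropout(h, cfg.dropout, training, rng)
    return h  # (B, 1) logits


def forward_logits(pairs: list[InterfaceGraphPair], params: NetworkParams,
                   training_mode: bool = False,
                   rng: np.random.Generator | None = None) -> Tensor:
    """Logits for a batch of graphs (grouped by node count internally)."""
    if not pairs:
        raise ValueError("empty batch")
    for pair in pairs:
        if pair.n_nodes == 0:
            raise ValueError("graph with zero nodes")
    groups: dict[int, list[int]] = {}
    for i, pair in enumerate(pairs):
        groups.setdefault(pair.n_nodes, []).append(i)

    chunks: list[tuple[list[int], Tensor]] = []
    for n, idxs in groups.items():
        feats = np.stack([pairs[i].features for i in idxs])
        a1 = np.stack([pairs[i].a1 for i in idxs])
        cd = np.stack([pairs[i].cross_dist for i in idxs])
        chunks.append((idxs, _forward_stack(feats, a1, cd, params,
                                            training_mode, rng)))
    if len(chunks) == 1:
        idxs, logits = chunks[0]
        if idxs == list(range(len(pairs))):
            return logits
    # reassemble original order with a permutation matrix (differentiable)
    parts = ad.concat([c[1] for c in chunks], axis=0)
    chunk_order = np.concatenate([c[0] for c in chunks])
    perm = np.zeros((len(pairs), len(pairs)))
    perm[chunk_order, np.arange(len(pairs))] = 1.0
    return ad.matmul(Tensor(perm), parts)


def forward(pair: InterfaceGraphPair, params: NetworkParams,
            training_mode: bool = False,
            rng: np.random.Generator | None = None) -> DecoyScore:
    """Score one decoy graph: probability of acceptable quality."""
    logits = forward_logits([pair], params, training_mode, rng)
    prob = 1.0 / (1.0 + np.exp(-float(logits.data[0, 0])))
    return DecoyScore(probability=prob)


def score_many(pairs: list[InterfaceGraphPair], params: NetworkParams) -> np.ndarray:
    """Probabilities for many graphs, dropout off."""
    logits = forward_logits(pairs, params, training_mode=False)
    return 1.0 / (1.0 + np.exp(-logits.data[:, 0]))


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(params: NetworkParams, path) -> None:
    arrays = {"embed_w": params.embed_w.data, "embed_b": params.embed_b.data,
              "mu": params.mu.data, "sigma": params.sigma.data}
    for i, layer in enumerate(params.gat_layers):
        arrays[f"gat{i}_W"] = layer.W.data
        arrays[f"gat{i}_E"] = layer.E_att.data
        arrays[f"gat{i}_D"] = layer.D.data
        arrays[f"gat{i}_b"] = layer.b.data
    for i, (w, b) in enumerate(params.fc):
        arrays[f"fc{i}_W"] = w.data
        arrays[f"fc{i}_b"] = b.data
    cfg = params.config
    meta = json.dumps({
        "version": CHECKPOINT_VERSION,
        "input_dim": cfg.input_dim,
        "feature_width": cfg.feature_width,
        "n_gat_layers": cfg.n_gat_layers,
        "fc_dims": list(cfg.fc_dims),
        "dropout": cfg.dropout,
    })
    np.savez(path, __meta__=np.array([meta]), **arrays)


def load_checkpoint(path) -> NetworkParams:
    try:
        archive = np.load(path, allow_pickle=False)
    except Exception as exc:
        raise ValueError(f"cannot read checkpoint {path}: {exc}") from exc
    with archive as z:
        if "__meta__" not in z:
            raise ValueError(f"not a checkpoint file: {path}")
        meta = json.loads(str(z["__meta__"][0]))
        if meta.get("version") != CHECKPOINT_VERSION:
            raise ValueError(
                f"checkpoint version {meta.get('version')} unsupported "
                f"(expected {CHECKPOINT_VERSION})")
        cfg = NetworkConfig(
            input_dim=meta["input_dim"],
            feature_width=meta["feature_width"],
            n_gat_layers=meta["n_gat_layers"],
            fc_dims=tuple(meta["fc_dims"]),
            dropout=meta["dropout"],
        )

        def p(key) -> Tensor:
            return Tensor(z[key], requires_grad=True)

        layers = [GatLayerParams(W=p(f"gat{i}_W"), E_att=p(f"gat{i}_E"),
                                 D=p(f"gat{i}_D"), b=p(f"gat{i}_b"))
                  for i in range(cfg.n_gat_layers)]
        fc = [(p(f"fc{i}_W"), p(f"fc{i}_b"))
              for i in range(len(cfg.fc_dims) - 1)]
        return NetworkParams(
            config=cfg,
            embed_w=p("embed_w"),
            embed_b=p("embed_b"),
            gat_layers=layers,
            fc=fc,
            mu=p("mu"),
            sigma=p("sigma"),
        )
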