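"""The attention-propagation graph neural network.

Architecture: a cascade of graph convolution blocks, each performing one
attention-based propagation step followed by a GIN-style embedding update

    X' = Theta( Gamma X + (1 + eps) X )

where Gamma is row-stochastic over N(i) ∪ {i} with entries

    gamma_ij = exp(beta cos(x_i, x_j)) / sum_{k in N(i) ∪ {i}} exp(beta cos(x_i, x_k))

(beta and eps trainable; Theta a two-layer transform).  Setting
``attention_enabled=False`` swaps Gamma for the symmetric-normalized operator
D^{-1/2} A D^{-1/2}, i.e. plain equal propagation.  Per-block node embeddings
are aggregated by jumping-knowledge elementwise max-pooling, read out by a
Set2Set layer (iterated LSTM attention, permutation invariant) and classified
by a fully connected head into cytotoxic-vs-cytostatic probabilities.

Edge confidence weights do not enter the propagation: adjacency only defines
neighborhoods, the attention operates purely in feature space.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Callable, Sequence

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .errors import DrugraphError, ValidationError
from .graph import FEATURE_DIM, CancerGraph

MODEL_FORMAT_VERSION = "1"

_NORM_FLOOR = 1e-12  # additive floor in cosine norms; zero rows get cosine 0


# ---------------------------------------------------------------------------
# dense single-graph reference operations (numpy, no gradients)
# ---------------------------------------------------------------------------

def _neighbor_lists(neighbors) -> list[np.ndarray]:
    """Accept an adjacency matrix, a CancerGraph, or explicit lists."""
    if isinstance(neighbors, CancerGraph):
        neighbors = neighbors.adjacency()
    arr = np.asarray(neighbors)
    if arr.ndim == 2 and arr.shape[0] == arr.shape[1] and arr.dtype != object:
        return [np.flatnonzero(arr[i]) for i in range(arr.shape[0])]
    return [np.asarray(ns, dtype=np.int64) for ns in neighbors]


def cosine_similarity_rows(X: np.ndarray) -> np.ndarray:
    """Pairwise cosine similarity with the zero-row guard."""
    norms = np.sqrt((X ** 2).sum(axis=1) + _NORM_FLOOR)
    return (X @ X.T) / np.outer(norms, norms)


def attention_matrix(X: np.ndarray, neighbors, beta: float) -> np.ndarray:
    """Dense attention propagation matrix Gamma.

    Row i is the softmax of ``beta * cos(x_i, x_j)`` over j in N(i) ∪ {i};
    entries outside the support are exactly 0 and every row sums to 1.
    """
    X = np.asarray(X, dtype=np.float64)
    nbrs = _neighbor_lists(neighbors)
    n = X.shape[0]
    if len(nbrs) != n:
        raise ValidationError("neighbor structure does not match feature rows")
    cos = cosine_similarity_rows(X)
    Gamma = np.zeros((n, n))
    for i in range(n):
        support = np.unique(np.append(nbrs[i], i))
        w = np.exp(beta * (cos[i, support] - cos[i, support].max()))
        Gamma[i, support] = w / w.sum()
    return Gamma


def equal_propagation(A: np.ndarray, X: np.ndarray) -> np.ndarray:
    """One symmetric-normalized propagation step X' = D^{-1/2} A D^{-1/2} X.

    Isolated nodes pass through unchanged instead of being zeroed.
    """
    A = np.asarray(A, dtype=np.float64)
    X = np.asarray(X, dtype=np.float64)
    if A.shape[0] != A.shape[1] or A.shape[0] != X.shape[0]:
        raise ValidationError("adjacency/feature dimension mismatch")
    d = A.sum(axis=1)
    inv_sqrt = np.where(d > 0, 1.0 / np.sqrt(np.maximum(d, 1.0)), 0.0)
    Xp = (A * np.outer(inv_sqrt, inv_sqrt)) @ X
    isolated = d == 0
    Xp[isolated] = X[isolated]
    return Xp


@dataclass
class PropagationState:
    """Snapshot of one propagation step, for inspection and testing.

    ``Gamma`` is row-stochastic with support exactly N(i) ∪ {i}; ``A`` and
    ``D`` are the adjacency and degree matrices defining the neighborhoods.
    """

    X_t: np.ndarray
    Gamma: np.ndarray
    A: np.ndarray
    D: np.ndarray
    neighbors: list[np.ndarray]

    def validate(self, atol: float = 1e-8) -> None:
        n = self.A.shape[0]
        if not np.allclose(self.Gamma.sum(axis=1), 1.0, atol=atol):
            raise ValidationError("Gamma rows must sum to 1")
        support = self.A.astype(bool) | np.eye(n, dtype=bool)
        if np.any(self.Gamma[~support] != 0):
            raise ValidationError("Gamma support exceeds N(i) ∪ {i}")


def propagation_state(X: np.ndarray, graph, beta: float) -> PropagationState:
    """Compute one attention-propagation step on a dense graph and return
    the full state (propagated features, Gamma, A, D, neighbor lists)."""
    A = graph.adjacency() if isinstance(graph, CancerGraph) else np.asarray(graph, float)
    Gamma = attention_matrix(X, A, beta)
    state = PropagationState(
        X_t=Gamma @ np.asarray(X, dtype=np.float64),
        Gamma=Gamma,
        A=A,
        D=np.diag(A.sum(axis=1)),
        neighbors=_neighbor_lists(A),
    )
    state.validate()
    return state


@dataclass
class AttentionConvBlock:
    """One propagation + update block (dense reference form).

    ``theta`` is the update transform applied after aggregation; ``None``
    means the identity, which is handy for verifying the update formula.
    """

    beta: float = 1.0
    epsilon: float = 0.0
    theta: Callable[[np.ndarray], np.ndarray] | None = None
    attention_enabled: bool = True


def conv_block_forward(X: np.ndarray, graph, block: AttentionConvBlock) -> np.ndarray:
    """Dense reference forward pass of one convolution block."""
    X = np.asarray(X, dtype=np.float64)
    A = graph.adjacency() if isinstance(graph, CancerGraph) else np.asarray(graph, float)
    if block.attention_enabled:
        prop = attention_matrix(X, A, block.beta) @ X
    else:
        prop = equal_propagation(A, X)
    H = prop + (1.0 + block.epsilon) * X
    out = H if block.theta is None else block.theta(H)
    if not np.all(np.isfinite(out)):
        raise DrugraphError("non-finite values in convolution block output")
    return out


def jk_max_pool(embeddings_per_block: Sequence[np.ndarray]) -> np.ndarray:
    """Jumping-knowledge aggregation: elementwise max across blocks."""
    mats = [np.asarray(m, dtype=np.float64) for m in embeddings_per_block]
    if len({m.shape for m in mats}) != 1:
        raise ValidationError("JK max-pool requires equal-shaped block outputs")
    return np.maximum.reduce(mats)


def set2set_readout(X_agg: np.ndarray, steps: int, params: dict[str, np.ndarray]) -> np.ndarray:
    """Dense reference Set2Set readout of one node set.

    At each step an LSTM cell consumes the previous query-plus-readout vector
    q*, its hidden state queries the node set with dot-product attention, and
    the attended sum is concatenated back: the result is a permutation-
    invariant vector of length 2*hidden.
    """
    X_agg = np.asarray(X_agg, dtype=np.float64)
    if X_agg.shape[0] == 0:
        raise ValidationError("Set2Set readout of an empty node set")
    if steps < 1:
        raise ValidationError("Set2Set needs at least one step")
    h_dim = X_agg.shape[1]
    q_star = np.zeros(2 * h_dim)
    h = np.zeros(h_dim)
    c = np.zeros(h_dim)
    for _ in range(steps):
        z = q_star @ params["Wx"] + h @ params["Wh"] + params["b"]
        i = _sig(z[:h_dim])
        f = _sig(z[h_dim:2 * h_dim])
        g = np.tanh(z[2 * h_dim:3 * h_dim])
        o = _sig(z[3 * h_dim:])
        c = f * c + i * g
        h = o * np.tanh(c)
        e = X_agg @ h
        a = np.exp(e - e.max())
        a /= a.sum()
        r = a @ X_agg
        q_star = np.concatenate([h, r])
    return q_star


def _sig(x):
    return 1.0 / (1.0 + np.exp(-x))


# ---------------------------------------------------------------------------
# configuration and trainable model
# ---------------------------------------------------------------------------

@dataclass
class GNNConfig:
    """Hyperparameters.  The method fixes three convolution blocks and
    max-pool jumping knowledge; sizes, optimizer settings and the decision
    threshold are this package's defaults."""

    n_blocks: int = 3
    in_dim: int = FEATURE_DIM
    hidden_dim: int = 16
    set2set_steps: int = 3
    classifier_dims: tuple[int, ...] = (32,)
    dropout: float = 0.1
    learning_rate: float = 1e-2
    epochs: int = 60
    batch_size: int = 32
    seed: int = 0
    attention_enabled: bool = True

    def __post_init__(self):
        if self.n_blocks < 1:
            raise ValidationError("n_blocks must be >= 1")
        if min(self.hidden_dim, self.in_dim, *self.classifier_dims) <= 0:
            raise ValidationError("all dimensions must be > 0")
        self.classifier_dims = tuple(self.classifier_dims)


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> Tensor:
    s = np.sqrt(6.0 / (fan_in + fan_out))
    return Tensor(rng.uniform(-s, s, size=(fan_in, fan_out)), requires_grad=True)


def _zeros(*shape) -> Tensor:
    return Tensor(np.zeros(shape), requires_grad=True)


def prepare_instance(graph: CancerGraph) -> dict:
    """Precompute the arrays the batched forward pass needs for one graph."""
    if graph.n_nodes == 0:
        raise ValidationError(f"empty graph {graph.instance_id}")
    ei = graph.edge_index()
    return {
        "X": graph.X,
        "row": ei[0],
        "col": ei[1],
        "n": graph.n_nodes,
        "label": graph.label,
        "instance_id": graph.instance_id,
        "tissue": graph.tissue,
    }


def _collate(preps: list[dict]) -> dict:
    """Disjoint union of several prepared graphs into one batch."""
    Xs, rows, cols, gids = [], [], [], []
    offset = 0
    for gi, p in enumerate(preps):
        Xs.append(p["X"])
        rows.append(p["row"] + offset)
        cols.append(p["col"] + offset)
        gids.append(np.full(p["n"], gi, dtype=np.int64))
        offset += p["n"]
    row = np.concatenate(rows) if rows else np.zeros(0, dtype=np.int64)
    col = np.concatenate(cols) if cols else np.zeros(0, dtype=np.int64)
    n = offset
    deg = np.bincount(row, minlength=n).astype(np.float64)
    inv = np.where(deg > 0, 1.0 / np.sqrt(np.maximum(deg, 1.0)), 0.0)
    return {
        "X0": np.concatenate(Xs, axis=0),
        "row": row,
        "col": col,
        "graph_id": np.concatenate(gids),
        "n_nodes": n,
        "n_graphs": len(preps),
        # equal-propagation constants: per-edge 1/sqrt(d_i d_j), self weight 1
        # for isolated nodes (identity pass-through)
        "eq_coef": inv[row] * inv[col],
        "eq_self": (deg == 0).astype(np.float64),
        "labels": np.array([-1 if p["label"] is None else p["label"] for p in preps]),
    }


class GNNModel:
    """Trainable model: parameters plus the batched differentiable forward."""

    def __init__(self, config: GNNConfig, rng: np.random.Generator | None = None):
        self.config = config
        rng = rng or np.random.default_rng(config.seed)
        h = config.hidden_dim
        self.blocks = []
        d_in = config.in_dim
        for _ in range(config.n_blocks):
            self.blocks.append(
                {
                    "beta": Tensor(1.0, requires_grad=True),
                    "eps": Tensor(0.0, requires_grad=True),
                    "W1": _glorot(rng, d_in, h),
                    "b1": _zeros(h),
                    "W2": _glorot(rng, h, h),
                    "b2": _zeros(h),
                }
            )
            d_in = h
        self.set2set = {
            "Wx": _glorot(rng, 2 * h, 4 * h),
            "Wh": _glorot(rng, h, 4 * h),
            "b": _zeros(4 * h),
        }
        self.classifier = []
        d = 2 * h
        for c in config.classifier_dims:
            self.classifier.append({"W": _glorot(rng, d, c), "b": _zeros(c)})
            d = c
        self.classifier.append({"W": _glorot(rng, d, 2), "b": _zeros(2)})

    # -- parameter plumbing ---------------------------------------------------

    def parameters(self) -> list[Tensor]:
        out = []
        for blk in self.blocks:
            out.extend(blk.values())
        out.extend(self.set2set.values())
        for layer in self.classifier:
            out.extend(layer.values())
        return out

    # -- forward --------------------------------------------------------------

    def _propagate(self, X: Tensor, batch: dict, beta: Tensor) -> Tensor:
        n = batch["n_nodes"]
        row, col = batch["row"], batch["col"]
        if self.config.attention_enabled:
            norms = ad.sqrt(ad.sum_(X * X, axis=1, keepdims=True) + _NORM_FLOOR)
            xn = X / norms
            self_idx = np.arange(n)
            seg = np.concatenate([row, self_idx])
            src = np.concatenate([col, self_idx])
            cos_e = ad.sum_(ad.gather_rows(xn, row) * ad.gather_rows(xn, col), axis=1)
            cos_self = ad.sum_(xn * xn, axis=1)
            logits = beta * ad.concat([cos_e, cos_self], axis=0)
            gamma = ad.segment_softmax(logits, seg, n)
            msg = ad.gather_rows(X, src) * ad.reshape(gamma, (-1, 1))
            return ad.segment_sum(msg, seg, n)
        msg = ad.gather_rows(X, col) * Tensor(batch["eq_coef"][:, None])
        prop = ad.segment_sum(msg, row, n)
        return prop + X * Tensor(batch["eq_self"][:, None])

    def _forward(self, batch: dict, train: bool = False,
                 rng: np.random.Generator | None = None) -> tuple[Tensor, Tensor]:
        """Return (logits, post-JK node embeddings) for one collated batch."""
        X = Tensor(batch["X0"])
        per_block = []
        for blk in self.blocks:
            prop = self._propagate(X, batch, blk["beta"])
            H = prop + X * (blk["eps"] + 1.0)
            X = ad.relu(H @ blk["W1"] + blk["b1"]) @ blk["W2"] + blk["b2"]
            per_block.append(X)
        jk = per_block[0]
        for m in per_block[1:]:
            jk = ad.maximum(jk, m)

        h = self.config.hidden_dim
        B = batch["n_graphs"]
        gid = batch["graph_id"]
        q_star = Tensor(np.zeros((B, 2 * h)))
        h_state = Tensor(np.zeros((B, h)))
        c_state = Tensor(np.zeros((B, h)))
        s2s = self.set2set
        for _ in range(self.config.set2set_steps):
            z = q_star @ s2s["Wx"] + h_state @ s2s["Wh"] + s2s["b"]
            i = ad.sigmoid(z[:, :h])
            f = ad.sigmoid(z[:, h:2 * h])
            g = ad.tanh(z[:, 2 * h:3 * h])
            o = ad.sigmoid(z[:, 3 * h:])
            c_state = f * c_state + i * g
            h_state = o * ad.tanh(c_state)
            e = ad.sum_(jk * ad.gather_rows(h_state, gid), axis=1)
            a = ad.segment_softmax(e, gid, B)
            r = ad.segment_sum(jk * ad.reshape(a, (-1, 1)), gid, B)
            q_star = ad.concat([h_state, r], axis=1)

        out = q_star
        for layer in self.classifier[:-1]:
            out = ad.relu(out @ layer["W"] + layer["b"])
            if train and self.config.dropout > 0:
                if rng is None:
                    raise DrugraphError("training forward needs an rng for dropout")
                keep = 1.0 - self.config.dropout
                mask = (rng.random(out.shape) < keep) / keep
                out = out * Tensor(mask)
        last = self.classifier[-1]
        logits = out @ last["W"] + last["b"]
        if not np.all(np.isfinite(logits.data)):
            raise DrugraphError("non-finite logits")
        return logits, jk

    # -- inference ------------------------------------------------------------

    def predict_proba(self, graphs: Sequence[CancerGraph | dict]) -> np.ndarray:
        """Probability of the positive (cytotoxic) class for each graph."""
        preps = [g if isinstance(g, dict) else prepare_instance(g) for g in graphs]
        probs = []
        for lo in range(0, len(preps), 256):
            batch = _collate(preps[lo:lo + 256])
            logits, _ = self._forward(batch, train=False)
            probs.append(ad.softmax_probs(logits.data)[:, 1])
        return np.concatenate(probs) if probs else np.zeros(0)

    def node_embeddings(self, graph: CancerGraph | dict) -> np.ndarray:
        """Post-JK node embeddings (before readout) for one graph."""
        prep = graph if isinstance(graph, dict) else prepare_instance(graph)
        _, jk = self._forward(_collate([prep]), train=False)
        return jk.data.copy()

    # -- checkpointing --------------------------------------------------------

    def save(self, path) -> None:
        def dump(d):
            return {k: v.data.tolist() for k, v in d.items()}

        payload = {
            "format_version": MODEL_FORMAT_VERSION,
            "config": asdict(self.config),
            "blocks": [dump(b) for b in self.blocks],
            "set2set": dump(self.set2set),
            "classifier": [dump(l) for l in self.classifier],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path) -> "GNNModel":
        with open(path) as fh:
            payload = json.load(fh)
        if payload.get("format_version") != MODEL_FORMAT_VERSION:
            raise DrugraphError(
                f"unsupported model format version {payload.get('format_version')!r}"
            )
        cfg_d = payload["config"]
        cfg_d["classifier_dims"] = tuple(cfg_d["classifier_dims"])
        model = cls(GNNConfig(**cfg_d))

        def load_into(dst, src):
            for k in dst:
                dst[k] = Tensor(np.asarray(src[k]), requires_grad=True)

        for blk, src in zip(model.blocks, payload["blocks"]):
            load_into(blk, src)
        load_into(model.set2set, payload["set2set"])
        for layer, src in zip(model.classifier, payload["classifier"]):
            load_into(layer, src)
        return model


def model_forward(graph: CancerGraph, model: GNNModel) -> float:
    """Probability that the drug response for this instance is cytotoxic."""
    return float(model.predict_proba([graph])[0])
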