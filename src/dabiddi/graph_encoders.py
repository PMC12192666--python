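"""Molecular graph encoders: GAT attention, granule interactions, fusion.

Implements the per-node graph attention update (softmax of LeakyReLU-scored
neighbor pairs, multi-head with mean or concat combination), decomposition
of molecules into granules (ring systems + non-ring fragments, with a
singleton fallback), the granule-granule interaction (GGI) score and its
masked total, the fusion MLP with importance-based input pruning, and an
attention-pooling model whose trained weights yield per-granule substructure
importance scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from ._autodiff import Adam, Tensor, bce_loss, softmax as ad_softmax
from .molecular_features import MolecularGraph, atom_features

__all__ = [
    "GATParams", "gat_attention", "gat_layer",
    "GranuleSet", "granulate",
    "GGIParams", "ggi_score", "ggi_total",
    "FusionParams", "fuse_features",
    "GranuleAttentionModel", "attention_importance",
    "molecule_embedding",
]


# ---------------------------------------------------------------------------
# GAT attention
# ---------------------------------------------------------------------------

@dataclass
class GATParams:
    """Parameters of one graph-attention layer.

    W: per-head weight matrices (K, d_in, d_out); a: per-head attention
    vectors (K, 2*d_out).  ``head_combine`` follows the printed update
    (mean over heads) by default; ``concat`` is available.
    """

    W: np.ndarray
    a: np.ndarray
    leaky_slope: float = 0.2
    head_combine: str = "mean"

    def __post_init__(self):
        self.W = np.asarray(self.W, dtype=float)
        self.a = np.asarray(self.a, dtype=float)
        if self.W.ndim == 2:
            self.W = self.W[None]
        if self.a.ndim == 1:
            self.a = self.a[None]
        if not 0.0 < self.leaky_slope < 1.0:
            raise ValueError("leaky_slope must lie in (0, 1)")
        if self.a.shape != (self.K, 2 * self.W.shape[2]):
            raise ValueError("attention vector shape inconsistent with W")
        if self.head_combine not in ("mean", "concat"):
            raise ValueError("head_combine must be 'mean' or 'concat'")

    @property
    def K(self) -> int:
        return self.W.shape[0]

    @classmethod
    def init(cls, d_in: int, d_out: int, n_heads: int = 16, seed: int = 0,
             **kw) -> "GATParams":
        rng = np.random.default_rng(seed)
        scale = 1.0 / np.sqrt(d_in)
        return cls(
            W=rng.normal(scale=scale, size=(n_heads, d_in, d_out)),
            a=rng.normal(scale=scale, size=(n_heads, 2 * d_out)),
            **kw,
        )


def _leaky_relu(x: np.ndarray, slope: float) -> np.ndarray:
    return np.where(x > 0, x, slope * x)


def gat_attention(h_i: np.ndarray, neighbors: np.ndarray, params: GATParams,
                  head: int = 0) -> np.ndarray:
    """Attention weights of node i over its neighbors for one head.

    alpha_j = softmax_j( LeakyReLU( a^T [W h_i || W h_j] ) ); the weights
    are strictly positive and sum to one.
    """
    neighbors = np.atleast_2d(np.asarray(neighbors, dtype=float))
    if neighbors.shape[0] == 0:
        raise ValueError("at least one neighbor required (add a self-loop)")
    W, a = params.W[head], params.a[head]
    wi = np.asarray(h_i, dtype=float) @ W
    wj = neighbors @ W
    d = W.shape[1]
    logits = _leaky_relu(a[:d] @ wi + wj @ a[d:], params.leaky_slope)
    logits = logits - logits.max()
    e = np.exp(logits)
    return e / e.sum()


def gat_layer(X: np.ndarray, adjacency: np.ndarray, params: GATParams,
              sigma=np.tanh) -> np.ndarray:
    """One multi-head graph-attention update of all node features.

    h_i' = sigma( (1/K) sum_k sum_{j in N_i} alpha_ij^k W^k h_j ) for the
    default mean combination; ``concat`` stacks the K head outputs instead.
    Self-loops are always added so no neighborhood is empty.
    """
    X = np.asarray(X, dtype=float)
    A = np.asarray(adjacency, dtype=float)
    n = X.shape[0]
    if A.shape != (n, n):
        raise ValueError("adjacency shape does not match node count")
    if X.shape[1] != params.W.shape[1]:
        raise ValueError("feature dimension does not match W")
    A = A.copy()
    np.fill_diagonal(A, 1.0)  # self-loops

    head_outputs = []
    for k in range(params.K):
        W, a = params.W[k], params.a[k]
        H = X @ W                       # (n, d_out)
        d = W.shape[1]
        si = H @ a[:d]                  # source term per node i
        sj = H @ a[d:]                  # neighbor term per node j
        logits = _leaky_relu(si[:, None] + sj[None, :], params.leaky_slope)
        logits = np.where(A > 0, logits, -np.inf)
        logits = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(logits) * (A > 0)
        alpha = e / e.sum(axis=1, keepdims=True)
        head_outputs.append(alpha @ H)
    if params.head_combine == "mean":
        out = np.mean(head_outputs, axis=0)
    else:
        out = np.concatenate(head_outputs, axis=1)
    return sigma(out)


# ---------------------------------------------------------------------------
# granulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GranuleSet:
    """Granules of one molecule: (atom-index subset, pooled feature vector)."""

    granules: tuple      # tuple of (tuple of atom indices, np.ndarray)
    scheme: str
    mol_id: str = ""

    @property
    def n(self) -> int:
        return len(self.granules)

    @property
    def vectors(self) -> np.ndarray:
        return np.stack([v for _, v in self.granules])


def granulate(g: MolecularGraph, scheme: str = "ring-fragment") -> GranuleSet:
    """Decompose a molecule into granules.

    ``ring-fragment`` (default): each ring system (connected component of
    cycle bonds) is one granule; each maximal connected non-ring fragment
    left after removing ring atoms is one granule.  ``singleton``: every
    atom is its own granule.  Pooled vectors sum the atom feature rows.
    """
    X = atom_features(g)
    if scheme == "singleton":
        granules = tuple(((i,), X[i].copy()) for i in range(g.n_atoms))
        return GranuleSet(granules, scheme, g.id)
    if scheme != "ring-fragment":
        raise ValueError(f"unknown granulation scheme: {scheme!r}")

    G = nx.Graph()
    G.add_nodes_from(range(g.n_atoms))
    G.add_edges_from((i, j) for i, j, _ in g.bonds)
    bridges = set(frozenset(e) for e in nx.bridges(G))
    ring_edges = [
        (i, j) for i, j, _ in g.bonds
        if frozenset((i, j)) not in bridges and G.degree(i) > 1 and G.degree(j) > 1
    ]
    # a non-bridge edge lies on a cycle; ring systems are the components of
    # the cycle-edge subgraph
    ring_graph = nx.Graph(ring_edges)
    ring_atoms = set(ring_graph.nodes)
    subsets = [tuple(sorted(c)) for c in nx.connected_components(ring_graph)]
    # non-ring fragments: components of the graph with ring atoms removed
    rest = G.subgraph(set(G.nodes) - ring_atoms)
    subsets += [tuple(sorted(c)) for c in nx.connected_components(rest)]
    subsets.sort(key=lambda s: s[0])
    if not subsets:  # single atom, no bonds
        subsets = [tuple(range(g.n_atoms))]
    granules = tuple((s, X[list(s)].sum(axis=0)) for s in subsets)
    return GranuleSet(granules, scheme, g.id)


# ---------------------------------------------------------------------------
# granule-granule interaction
# ---------------------------------------------------------------------------

@dataclass
class GGIParams:
    """Affine granule-pair scorer: sigmoid(sum(W1 g_i + W2 g_j + b))."""

    W1: np.ndarray
    W2: np.ndarray
    b: np.ndarray

    def __post_init__(self):
        self.W1 = np.atleast_2d(np.asarray(self.W1, dtype=float))
        self.W2 = np.atleast_2d(np.asarray(self.W2, dtype=float))
        self.b = np.atleast_1d(np.asarray(self.b, dtype=float))
        if self.W1.shape != self.W2.shape or self.b.shape[0] != self.W1.shape[0]:
            raise ValueError("GGI parameter shapes inconsistent")

    @classmethod
    def init(cls, d: int, d_out: int = 4, seed: int = 0) -> "GGIParams":
        rng = np.random.default_rng(seed)
        s = 1.0 / np.sqrt(d)
        return cls(rng.normal(scale=s, size=(d_out, d)),
                   rng.normal(scale=s, size=(d_out, d)),
                   np.zeros(d_out))


def _sigmoid(x):
    return np.where(x >= 0, 1.0 / (1.0 + np.exp(-np.abs(x))),
                    np.exp(-np.abs(x)) / (1.0 + np.exp(-np.abs(x))))


def ggi_score(g_i: np.ndarray, g_j: np.ndarray, params: GGIParams) -> float:
    """Interaction score of one granule pair, in (0, 1).

    The affine output W1 g_i + W2 g_j + b is reduced to a scalar by summing
    over output units before the sigmoid, keeping the score a probability-
    scale quantity (zero parameters give exactly 0.5).
    """
    g_i = np.asarray(g_i, dtype=float)
    g_j = np.asarray(g_j, dtype=float)
    if g_i.shape[0] != params.W1.shape[1] or g_j.shape[0] != params.W2.shape[1]:
        raise ValueError("granule vector shape mismatch")
    z = params.W1 @ g_i + params.W2 @ g_j + params.b
    return float(_sigmoid(z.sum()))


def ggi_total(gs_a: GranuleSet, gs_b: GranuleSet, params: GGIParams,
              mask: np.ndarray = None) -> float:
    """Masked double sum of pairwise GGI scores (mask defaults to all-ones)."""
    na, nb = gs_a.n, gs_b.n
    if mask is None:
        mask = np.ones((na, nb))
    mask = np.asarray(mask, dtype=float)
    if mask.shape != (na, nb):
        raise ValueError("mask shape must be (Ng_A, Ng_B)")
    total = 0.0
    for i, (_, gi) in enumerate(gs_a.granules):
        for j, (_, gj) in enumerate(gs_b.granules):
            if mask[i, j]:
                total += mask[i, j] * ggi_score(gi, gj, params)
    return float(total)


# ---------------------------------------------------------------------------
# feature fusion with pruning
# ---------------------------------------------------------------------------

@dataclass
class FusionParams:
    """Fusion MLP: layer sizes, dropout (train-time only), prune threshold."""

    layer_sizes: tuple = (64, 32)
    dropout: float = 0.3
    prune_threshold: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if any(s <= 0 for s in self.layer_sizes):
            raise ValueError("layer sizes must be positive")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")


def fuse_features(components: dict, params: FusionParams,
                  weights: list = None, return_layout: bool = False):
    """Concatenate multi-source feature blocks, prune, and pass an MLP.

    ``components`` maps block name -> vector (None allowed: zero-filled to
    the width recorded for that block, so ablations keep the layout).
    Input coordinates whose importance (mean absolute first-layer weight)
    falls below ``prune_threshold`` are zeroed out; a threshold above the
    maximum importance would empty the vector and raises.
    """
    names = list(components)
    vecs = []
    for name in names:
        v = components[name]
        if v is None:
            raise ValueError(f"component {name!r} is None; pass a zero "
                             "vector of the block width to ablate it")
        vecs.append(np.asarray(v, dtype=float).ravel())
    if not vecs or all(np.allclose(v, 0) for v in vecs):
        raise ValueError("all fusion components missing or zero")
    x = np.concatenate(vecs)
    layout = {}
    off = 0
    for name, v in zip(names, vecs):
        layout[name] = (off, off + v.size)
        off += v.size

    sizes = (x.size,) + tuple(params.layer_sizes)
    if weights is None:
        rng = np.random.default_rng(params.seed)
        weights = [rng.normal(scale=1.0 / np.sqrt(sizes[i]),
                              size=(sizes[i], sizes[i + 1]))
                   for i in range(len(sizes) - 1)]
    importance = np.abs(weights[0]).mean(axis=1)
    if params.prune_threshold > 0:
        keep = importance >= params.prune_threshold
        if not keep.any():
            raise ValueError("prune threshold above maximum importance; "
                             "would remove every coordinate")
        x = np.where(keep, x, 0.0)
    h = x
    for W in weights[:-1]:
        h = np.tanh(h @ W)
    out = h @ weights[-1]
    if return_layout:
        return out, layout
    return out


# ---------------------------------------------------------------------------
# attention-based substructure importance
# ---------------------------------------------------------------------------

class GranuleAttentionModel:
    """Attention-pooling classifier over granules.

    Per granule: score e_i = v . tanh(W g_i + b); alpha = softmax(e);
    value u . (U g_i); logit = sum_i alpha_i * value_i + c.  Trained with
    Adam on binary cross-entropy.  Importance of granule i is
    alpha_i * |value_i| normalized to sum one: attention weight times the
    magnitude of that granule's contribution to the decision.
    """

    def __init__(self, d_in: int, d_att: int = 8, d_val: int = 8,
                 seed: int = 0):
        rng = np.random.default_rng(seed)
        s = 1.0 / np.sqrt(d_in)
        self.W = Tensor(rng.normal(scale=s, size=(d_in, d_att)), requires_grad=True)
        self.b = Tensor(np.zeros(d_att), requires_grad=True)
        self.v = Tensor(rng.normal(scale=1.0 / np.sqrt(d_att), size=d_att),
                        requires_grad=True)
        self.U = Tensor(rng.normal(scale=s, size=(d_in, d_val)), requires_grad=True)
        self.u = Tensor(rng.normal(scale=1.0 / np.sqrt(d_val), size=d_val),
                        requires_grad=True)
        self.c = Tensor(np.zeros(1), requires_grad=True)
        self.trained = False

    @property
    def params(self):
        return [self.W, self.b, self.v, self.U, self.u, self.c]

    def _forward(self, G: Tensor):
        e = (G @ self.W + self.b).tanh() @ self.v       # (Ng,)
        alpha = ad_softmax(e, axis=0)
        values = (G @ self.U) @ self.u                  # (Ng,)
        logit = (alpha * values).sum() + self.c[0]
        return logit.sigmoid(), alpha, values

    def predict(self, granule_matrix: np.ndarray) -> float:
        p, _, _ = self._forward(Tensor(granule_matrix))
        return float(p.data)

    def fit(self, granule_matrices, labels, epochs: int = 200,
            lr: float = 0.05):
        opt = Adam(self.params, lr=lr)
        labels = np.asarray(labels, dtype=float)
        for _ in range(epochs):
            opt.zero_grad()
            probs = [self._forward(Tensor(G))[0] for G in granule_matrices]
            from ._autodiff import stack
            loss = bce_loss(stack(probs), labels)
            loss.backward()
            opt.step()
        self.trained = True
        return self

    def importances(self, granule_matrix: np.ndarray) -> np.ndarray:
        _, alpha, values = self._forward(Tensor(granule_matrix))
        raw = alpha.data * np.abs(values.data)
        if raw.sum() <= 0:
            return np.full(len(raw), 1.0 / len(raw))
        return raw / raw.sum()


def attention_importance(model: GranuleAttentionModel, g: MolecularGraph,
                         scheme: str = "ring-fragment"):
    """Per-granule importance scores of a trained attention model.

    Returns ``(granule_subsets, scores)``; scores are non-negative and sum
    to one over the molecule.  Raises on an untrained model.
    """
    if not getattr(model, "trained", False):
        raise ValueError("model must be trained before importance scoring")
    gs = granulate(g, scheme)
    scores = model.importances(gs.vectors)
    return [s for s, _ in gs.granules], scores


# ---------------------------------------------------------------------------
# molecule embeddings (descriptor + pooled atom features + GAT encoding)
# ---------------------------------------------------------------------------

def molecule_embedding(g: MolecularGraph, gat: GATParams = None,
                       d_out: int = 8) -> np.ndarray:
    """Fixed-width structural embedding of one molecule.

    Concatenates scaled descriptors, mean atom features, and a mean-pooled
    GAT encoding (seeded parameters unless provided).
    """
    from .molecular_features import N_ATOM_FEATURES, descriptors

    X = atom_features(g)
    if gat is None:
        gat = GATParams.init(N_ATOM_FEATURES, d_out, n_heads=2, seed=12345)
    enc = gat_layer(X, g.adjacency(), gat)
    d = descriptors(g)
    desc = np.array([d.mol_weight / 100.0, d.heavy_atom_count / 10.0,
                     d.bond_count / 10.0, d.hbd, d.hba], dtype=float)
    return np.concatenate([desc, X.mean(axis=0), enc.mean(axis=0)])
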