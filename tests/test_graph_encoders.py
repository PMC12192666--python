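"""GAT attention, granulation, GGI scoring, fusion and importance."""

import numpy as np
import pytest

from dabiddi.graph_encoders import (FusionParams, GATParams, GGIParams,
                                    GranuleAttentionModel, attention_importance,
                                    fuse_features, gat_attention, gat_layer,
                                    ggi_score, ggi_total, granulate,
                                    molecule_embedding)
from dabiddi.molecular_features import (N_ATOM_FEATURES, atom_features,
                                        parse_smiles)


# ---------------------------------------------------------------------------
# gat_attention
# ---------------------------------------------------------------------------

def test_attention_single_neighbor_is_one():
    p = GATParams.init(3, 2, n_heads=1, seed=0)
    a = gat_attention(np.ones(3), np.ones((1, 3)), p)
    assert a == pytest.approx([1.0])


def test_attention_uniform_over_identical_neighbors():
    p = GATParams.init(4, 3, n_heads=2, seed=1)
    nbrs = np.tile(np.array([0.3, -1.0, 2.0, 0.0]), (5, 1))
    for head in range(2):
        a = gat_attention(np.ones(4), nbrs, p, head=head)
        assert a == pytest.approx(np.full(5, 0.2))
        assert a.sum() == pytest.approx(1.0)
        assert (a > 0).all()


def test_attention_hand_evaluated_1d():
    # W=1, a=(1,1), slope 0.2, h_i=1, neighbors {1, -3}:
    # logits LeakyReLU(1+1)=2 and LeakyReLU(1-3)=-0.4
    p = GATParams(W=np.array([[1.0]]), a=np.array([1.0, 1.0]),
                  leaky_slope=0.2)
    a = gat_attention(np.array([1.0]), np.array([[1.0], [-3.0]]), p)
    want = np.exp([2.0, -0.4])
    want /= want.sum()
    assert a == pytest.approx(want)


def test_attention_permutation_equivariant(rng):
    p = GATParams.init(4, 3, n_heads=1, seed=3)
    nbrs = rng.normal(size=(6, 4))
    h = rng.normal(size=4)
    a = gat_attention(h, nbrs, p)
    perm = rng.permutation(6)
    assert gat_attention(h, nbrs[perm], p) == pytest.approx(a[perm])


# ---------------------------------------------------------------------------
# gat_layer
# ---------------------------------------------------------------------------

def test_layer_identity_on_self_loop_node():
    p = GATParams(W=np.eye(2), a=np.zeros(4))
    out = gat_layer(np.array([[0.3, -0.7]]), np.zeros((1, 1)), p,
                    sigma=lambda x: x)
    assert out == pytest.approx(np.array([[0.3, -0.7]]))


def test_layer_zero_weights():
    p = GATParams(W=np.zeros((2, 3, 3)), a=np.zeros((2, 6)))
    X = np.random.default_rng(0).normal(size=(4, 3))
    A = np.ones((4, 4))
    out = gat_layer(X, A, p, sigma=np.tanh)
    assert out == pytest.approx(np.zeros((4, 3)))


def _gat_layer_loops(X, A, params, sigma=np.tanh):
    """Naive double-loop evaluation of the head-averaged update."""
    n = X.shape[0]
    A = A.copy()
    np.fill_diagonal(A, 1.0)
    out = np.zeros((n, params.W.shape[2]))
    for k in range(params.K):
        W, a = params.W[k], params.a[k]
        d = W.shape[1]
        for i in range(n):
            nbrs = [j for j in range(n) if A[i, j] > 0]
            logits = []
            for j in nbrs:
                s = a[:d] @ (X[i] @ W) + a[d:] @ (X[j] @ W)
                logits.append(s if s > 0 else params.leaky_slope * s)
            logits = np.array(logits)
            alpha = np.exp(logits - logits.max())
            alpha /= alpha.sum()
            for alpha_j, j in zip(alpha, nbrs):
                out[i] += alpha_j * (X[j] @ W) / params.K
    return sigma(out)


def test_layer_matches_double_loop_oracle(rng):
    X = rng.normal(size=(5, 4))
    A = np.array([[0, 1, 0, 0, 1],
                  [1, 0, 1, 0, 0],
                  [0, 1, 0, 1, 0],
                  [0, 0, 1, 0, 1],
                  [1, 0, 0, 1, 0]], dtype=float)
    p = GATParams.init(4, 3, n_heads=3, seed=7)
    assert gat_layer(X, A, p) == pytest.approx(_gat_layer_loops(X, A, p))


def test_layer_shape_errors():
    p = GATParams.init(4, 3, n_heads=1)
    with pytest.raises(ValueError):
        gat_layer(np.zeros((3, 4)), np.zeros((2, 2)), p)
    with pytest.raises(ValueError):
        gat_layer(np.zeros((3, 5)), np.zeros((3, 3)), p)


def test_layer_concat_combination(rng):
    p = GATParams.init(4, 3, n_heads=2, seed=0, head_combine="concat")
    out = gat_layer(rng.normal(size=(3, 4)), np.ones((3, 3)), p)
    assert out.shape == (3, 6)


# ---------------------------------------------------------------------------
# granulation
# ---------------------------------------------------------------------------

def test_granulate_trivial_molecules():
    assert granulate(parse_smiles("C")).n == 1       # methane: singleton
    assert granulate(parse_smiles("c1ccccc1")).n == 1  # benzene: one ring


def test_granulate_aspirin_matches_flood_fill_oracle(aspirin_graph):
    gs = granulate(aspirin_graph)
    # independent oracle: ring atoms via cycle detection, then flood fill
    import networkx as nx
    G = nx.Graph()
    G.add_nodes_from(range(aspirin_graph.n_atoms))
    G.add_edges_from((i, j) for i, j, _ in aspirin_graph.bonds)
    ring_atoms = set()
    for cyc in nx.cycle_basis(G):
        ring_atoms.update(cyc)
    ring_systems = list(nx.connected_components(G.subgraph(ring_atoms)))
    fragments = list(nx.connected_components(
        G.subgraph(set(G.nodes) - ring_atoms)))
    assert gs.n == len(ring_systems) + len(fragments)
    union = sorted(i for subset, _ in gs.granules for i in subset)
    assert union == list(range(aspirin_graph.n_atoms))


def test_granulate_biphenyl_two_ring_systems():
    gs = granulate(parse_smiles("c1ccccc1-c2ccccc2"))
    assert gs.n == 2
    assert all(len(s) == 6 for s, _ in gs.granules)


def test_granulate_singleton_scheme(aspirin_graph):
    gs = granulate(aspirin_graph, scheme="singleton")
    assert gs.n == aspirin_graph.n_atoms
    X = atom_features(aspirin_graph)
    assert gs.vectors == pytest.approx(X)


# ---------------------------------------------------------------------------
# GGI
# ---------------------------------------------------------------------------

def test_ggi_zero_params_is_half():
    p = GGIParams(np.zeros((3, 2)), np.zeros((3, 2)), np.zeros(3))
    assert ggi_score(np.ones(2), np.ones(2), p) == pytest.approx(0.5)


def test_ggi_saturates_with_large_bias():
    p = GGIParams(np.zeros((1, 2)), np.zeros((1, 2)), np.array([50.0]))
    assert ggi_score(np.zeros(2), np.zeros(2), p) == pytest.approx(1.0)


def test_ggi_hand_evaluated_2d():
    p = GGIParams(W1=np.array([[1.0, -1.0]]), W2=np.array([[0.5, 0.5]]),
                  b=np.array([0.25]))
    gi, gj = np.array([2.0, 1.0]), np.array([1.0, 3.0])
    z = (1 * 2 - 1 * 1) + (0.5 * 1 + 0.5 * 3) + 0.25
    assert ggi_score(gi, gj, p) == pytest.approx(1 / (1 + np.exp(-z)))


def test_ggi_total_mask_contracts(rng):
    p = GGIParams(np.zeros((1, N_ATOM_FEATURES)),
                  np.zeros((1, N_ATOM_FEATURES)), np.zeros(1))
    ga = granulate(parse_smiles("CC(=O)OC1=CC=CC=C1C(=O)O"))
    gb = granulate(parse_smiles("c1ccccc1CCO"))
    # zero mask -> 0; all-ones with zero params -> 0.5 per pair
    assert ggi_total(ga, gb, p, mask=np.zeros((ga.n, gb.n))) == 0.0
    assert ggi_total(ga, gb, p) == pytest.approx(0.5 * ga.n * gb.n)
    with pytest.raises(ValueError):
        ggi_total(ga, gb, p, mask=np.zeros((ga.n + 1, gb.n)))


def test_ggi_total_matches_double_loop_and_linear_in_mask(rng):
    p = GGIParams.init(N_ATOM_FEATURES, seed=2)
    ga = granulate(parse_smiles("O=C(O)c1ccc(N)cc1"))
    gb = granulate(parse_smiles("CCOC(=O)C"))
    mask = rng.integers(0, 2, size=(ga.n, gb.n)).astype(float)
    direct = sum(
        mask[i, j] * ggi_score(ga.granules[i][1], gb.granules[j][1], p)
        for i in range(ga.n) for j in range(gb.n))
    assert ggi_total(ga, gb, p, mask) == pytest.approx(direct)
    assert ggi_total(ga, gb, p, 2 * mask) == pytest.approx(2 * direct)


# ---------------------------------------------------------------------------
# fusion
# ---------------------------------------------------------------------------

def test_fusion_layout_and_pruning(rng):
    comps = {"drugA": rng.normal(size=5), "drugB": rng.normal(size=5),
             "ggi": np.array([0.7]), "ctf": rng.normal(size=4),
             "cell": rng.normal(size=6)}
    out, layout = fuse_features(comps, FusionParams(layer_sizes=(8, 4)),
                                return_layout=True)
    assert out.shape == (4,)
    widths = {k: b - a for k, (a, b) in layout.items()}
    assert widths == {"drugA": 5, "drugB": 5, "ggi": 1, "ctf": 4, "cell": 6}
    offsets = [layout[k] for k in comps]
    assert offsets == sorted(offsets)  # declared order preserved

    # threshold 0 -> identical result; absurd threshold -> error
    same = fuse_features(comps, FusionParams(layer_sizes=(8, 4),
                                             prune_threshold=0.0))
    assert same == pytest.approx(out)
    with pytest.raises(ValueError):
        fuse_features(comps, FusionParams(layer_sizes=(8, 4),
                                          prune_threshold=1e9))
    with pytest.raises(ValueError):
        fuse_features({"a": np.zeros(3)}, FusionParams())


# ---------------------------------------------------------------------------
# attention importance
# ---------------------------------------------------------------------------

def test_importance_requires_training(aspirin_graph):
    model = GranuleAttentionModel(N_ATOM_FEATURES)
    with pytest.raises(ValueError):
        attention_importance(model, aspirin_graph)


def test_importance_normalized_and_single_granule():
    mols = ["c1ccccc1", "C1CCCCC1", "c1ccncc1"]
    mats = [granulate(parse_smiles(s)).vectors for s in mols]
    model = GranuleAttentionModel(N_ATOM_FEATURES, seed=0)
    model.fit(mats, [1, 0, 1], epochs=30)
    # single-granule molecule: importance exactly 1
    subsets, scores = attention_importance(model, parse_smiles("c1ccccc1"))
    assert scores == pytest.approx([1.0])
    # multi-granule: non-negative, sums to one
    subsets, scores = attention_importance(
        model, parse_smiles("CC(=O)OC1=CC=CC=C1C(=O)O"))
    assert scores.sum() == pytest.approx(1.0)
    assert (scores >= 0).all()


def test_importance_recovers_planted_ring_rule():
    """Label depends only on ring aromaticity; the trained model should
    put the maximal importance on the ring granule in most molecules."""
    aromatic = ["c1ccccc1CC", "c1ccncc1CO", "c1ccccc1C(=O)O", "c1ccccc1CCN",
                "c1ccncc1CC", "c1ccccc1OC"]
    aliphatic = ["C1CCCCC1CC", "C1CCCCC1CO", "C1CCCCC1C(=O)O", "C1CCCCC1CCN",
                 "C1CCOCC1CC", "C1CCCCC1OC"]
    hits = trials = 0
    for seed in range(5):
        model = GranuleAttentionModel(N_ATOM_FEATURES, seed=seed)
        graphs = [parse_smiles(s) for s in aromatic + aliphatic]
        mats = [granulate(g).vectors for g in graphs]
        labels = [1] * len(aromatic) + [0] * len(aliphatic)
        model.fit(mats, labels, epochs=150)
        for g in graphs:
            subsets, scores = attention_importance(model, g)
            ring_idx = max(range(len(subsets)), key=lambda i: len(subsets[i]))
            trials += 1
            hits += int(np.argmax(scores) == ring_idx)
    assert hits / trials >= 0.8


def test_molecule_embedding_fixed_width(molecule_set):
    widths = {molecule_embedding(parse_smiles(s, i)).shape[0]
              for i, s in molecule_set[:10]}
    assert len(widths) == 1
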