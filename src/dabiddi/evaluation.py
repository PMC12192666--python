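"""Metrics, cross-validation, detector benchmarking and ablations.

The module also hosts the packaged synthetic benchmark: a multi-source
feature pipeline over generated molecules, cell lines and spontaneous
reports (each component contributing a noisy view of the decision rule),
the Bayes-factor detector benchmark against the classical
disproportionality baselines, and the single/pairwise ablation harness
with the documented neutral stand-ins (zero features for encoder blocks,
identity pass-through for the LSTM, random sampling for active learning,
raw model scores when the Bayesian calibration is off).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold

from . import bayes_signal, synthetic_data
from .graph_encoders import (GGIParams, ggi_total, granulate,
                             molecule_embedding)
from .molecular_features import parse_smiles
from .sequence_model import DARNN, TrainConfig, make_sequence_batch, train
from .tensor_factorization import (CTFConfig, build_similarity_tensor,
                                   ctf_fit, drug_ctf_embedding)

__all__ = [
    "MetricReport", "metrics", "stratified_folds", "kfold_cv",
    "Benchmark", "build_benchmark", "train_benchmark_model",
    "detector_benchmark", "al_experiment", "run_ablation", "ABLATABLE",
]

ABLATABLE = ("mfsyndcp", "ggi", "ctf", "lstm", "active_learning", "bayes")


@dataclass(frozen=True)
class MetricReport:
    auroc: float
    pr_auc: float
    acc: float
    bacc: float
    prec: float
    recall: float
    f1: float
    mse: float
    rmse: float

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("auroc", "pr_auc", "acc", "bacc", "prec", "recall", "f1",
                 "mse", "rmse")}


def metrics(scores, labels, threshold: float = 0.5) -> MetricReport:
    """Threshold-free and thresholded classification metrics.

    AUROC is the rank statistic with 0.5 tie credit; PR_AUC uses step-wise
    precision-recall integration; confusion metrics use ``score >
    threshold``; MSE averages (score - label)^2.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(scores) != len(labels):
        raise ValueError("scores and labels must have equal length")
    if len(np.unique(labels)) < 2:
        raise ValueError("AUROC undefined for single-class labels")
    auroc = float(roc_auc_score(labels, scores))
    pr = float(average_precision_score(labels, scores))
    pred = scores > threshold
    tp = int(np.sum(pred & (labels == 1)))
    tn = int(np.sum(~pred & (labels == 0)))
    fp = int(np.sum(pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    acc = (tp + tn) / len(labels)
    sens = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    prec = tp / (tp + fp) if tp + fp else 0.0
    f1 = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else 0.0
    mse = float(np.mean((scores - labels) ** 2))
    return MetricReport(auroc=auroc, pr_auc=pr, acc=acc,
                        bacc=(sens + spec) / 2, prec=prec, recall=sens,
                        f1=f1, mse=mse, rmse=float(np.sqrt(mse)))


def stratified_folds(labels, k: int = 5, seed: int = 0):
    """Shuffled stratified fold memberships (list of index arrays)."""
    labels = np.asarray(labels)
    if k > len(labels):
        raise ValueError("k may not exceed the sample count")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [test for _, test in skf.split(np.zeros(len(labels)), labels)]


def kfold_cv(X, y, fit_predict, k: int = 5, seed: int = 0):
    """k-fold cross-validation of a ``fit_predict(Xtr, ytr, Xte)`` callable.

    Returns (per-fold MetricReport list, dict of metric means).
    """
    X = np.asarray(X)
    y = np.asarray(y)
    folds = stratified_folds(y, k, seed)
    reports = []
    for test_idx in folds:
        train_idx = np.setdiff1d(np.arange(len(y)), test_idx)
        scores = fit_predict(X[train_idx], y[train_idx], X[test_idx])
        reports.append(metrics(scores, y[test_idx]))
    means = {m: float(np.mean([getattr(r, m) for r in reports]))
             for m in reports[0].as_dict()}
    return reports, means


# ---------------------------------------------------------------------------
# Bayes-factor detector benchmark (signal detection on simulated reports)
# ---------------------------------------------------------------------------

def detector_benchmark(config: synthetic_data.SimReportConfig = None,
                       n_seeds: int = 10, base_seed: int = 0) -> pd.DataFrame:
    """AUROC of BF ranking vs Omega/LLR/IntSS/delta_add over seeds.

    Per seed: simulate reports, stratify every (pair, AE) triple, score
    with the empirical-Bayes detector and the four baselines, and measure
    each statistic's AUROC against the injected ground truth.  Rows are
    seeds, columns ``auroc_bf`` etc.
    """
    rows = []
    for s in range(n_seeds):
        cfg = config or synthetic_data.SimReportConfig()
        cfg = synthetic_data.SimReportConfig(
            **{**cfg.__dict__, "seed": base_seed + s})
        reports, truth = synthetic_data.gen_reports(cfg)
        table = bayes_signal.signals_table(reports, cfg.drug_ids, cfg.ae_ids)
        labels = np.array([
            truth.is_signal(r.drugA, r.drugB, r.ae)
            for r in table.itertuples(index=False)], dtype=int)
        ok = np.isfinite(table["log_bf"].to_numpy())
        for col in ("omega", "llr", "intss", "delta_add"):
            ok &= np.isfinite(table[col].to_numpy())
        sub, lab = table[ok], labels[ok]
        row = {"seed": cfg.seed}
        for name, col in (("bf", "log_bf"), ("omega", "omega"),
                          ("llr", "llr"), ("intss", "intss"),
                          ("delta_add", "delta_add")):
            row[f"auroc_{name}"] = float(
                roc_auc_score(lab, sub[col].to_numpy()))
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# packaged synthetic benchmark pipeline
# ---------------------------------------------------------------------------

@dataclass
class Benchmark:
    """Assembled multi-source benchmark: feature blocks + labels + reports."""

    blocks: dict                 # name -> (n_samples, width) arrays
    labels: np.ndarray
    pair_evidence: np.ndarray    # per-sample posterior interaction probability
    samples: list
    info: dict


def _pair_features(gs_a, gs_b, ggi_params) -> np.ndarray:
    ring_a = sum(1 for s, _ in gs_a.granules if len(s) >= 3)
    ring_b = sum(1 for s, _ in gs_b.granules if len(s) >= 3)
    return np.array([
        ggi_total(gs_a, gs_b, ggi_params),
        gs_a.n + gs_b.n,
        ring_a + ring_b,
        abs(gs_a.n - gs_b.n),
    ], dtype=float)


def build_benchmark(n_molecules: int = 20, n_cells: int = 5,
                    n_triplets: int = 1200, n_reports: int = 20_000,
                    seed: int = 0, view_noise: float = 0.5,
                    lam_latent: float = 0.0) -> Benchmark:
    """Build the synthetic multi-source benchmark.

    Triplet labels follow the default deterministic rule (structural term
    + latent pair propensity + cell factor); each feature block is a noisy
    view (per-sample Gaussian jitter on z-scored features), mimicking that
    structural, granular, similarity and report-derived measurements are
    imperfect witnesses of the interaction signal.  Spontaneous reports
    are generated with the pair-level part of the rule (structural +
    latent) as the injected interaction set, so the Bayesian evidence
    block — the detector's posterior interaction probability per pair —
    is the only feature that carries the latent propensity.
    """
    rng = np.random.default_rng(seed + 777)
    molecules = synthetic_data.gen_molecules(n_molecules, seed=seed)
    samples, info = synthetic_data.gen_triplets(
        molecules, n_cells=n_cells, seed=seed, n_triplets=n_triplets,
        lam_latent=lam_latent)
    graphs = {mid: parse_smiles(smi, mid) for mid, smi in molecules}
    emb = {mid: molecule_embedding(g) for mid, g in graphs.items()}
    grans = {mid: granulate(g) for mid, g in graphs.items()}
    d_feat = next(iter(emb.values())).shape[0] - 13  # atom-feature width
    ggi_params = GGIParams.init(next(iter(grans.values())).vectors.shape[1],
                                seed=seed)

    # CTF embedding from three cosine-similarity views of the embeddings
    ids = [mid for mid, _ in molecules]
    E = np.stack([emb[mid] for mid in ids])

    def cosine_slice(M):
        nrm = np.linalg.norm(M, axis=1, keepdims=True)
        nrm[nrm == 0] = 1.0
        S = (M / nrm) @ (M / nrm).T
        S = np.clip((S + 1.0) / 2.0, 0.0, 1.0)  # map to [0, 1]
        np.fill_diagonal(S, 1.0)
        return (S + S.T) / 2.0

    chi = build_similarity_tensor([
        cosine_slice(E[:, :5]),       # descriptor view
        cosine_slice(E[:, 5:5 + d_feat]),  # composition view
        cosine_slice(E[:, 5 + d_feat:]),   # encoder view
    ])
    factors, _ = ctf_fit(chi, CTFConfig(rank=4, max_iter=150, seed=seed))
    U = drug_ctf_embedding(factors)
    ctf_emb = {mid: U[i] for i, mid in enumerate(ids)}

    # spontaneous reports: interacting pairs = pair-level part of the rule
    # (structural term + latent propensity above its median)
    rp = info["rule_params"]
    heavy, latent = info["heavy"], info["pair_latent"]
    pair_ids = [(i, k) for i in range(n_molecules)
                for k in range(i + 1, n_molecules)]
    pair_score = np.array([
        (heavy[ids[i]] + heavy[ids[k]] - rp["med_h"]) / rp["scale_h"]
        + rp["lam_p"] * latent[frozenset((ids[i], ids[k]))]
        for i, k in pair_ids])
    cut = float(np.median(pair_score))
    cfg = synthetic_data.SimReportConfig(
        n_drugs=n_molecules, n_reports=n_reports, seed=seed, n_aes=5)
    inject = [(cfg.drug_ids[i], cfg.drug_ids[k], cfg.ae_ids[0])
              for (i, k), s in zip(pair_ids, pair_score) if s >= cut]
    reports, _ = synthetic_data.gen_reports(cfg, interacting_pairs=inject)
    table = bayes_signal.signals_table(reports, cfg.drug_ids, cfg.ae_ids)
    pi = table.attrs["signal_model"]["pi"]
    pi = min(max(pi if np.isfinite(pi) else 0.05, 1e-4), 1 - 1e-4)
    sub = table[table["ae"] == cfg.ae_ids[0]].set_index(["drugA", "drugB"])
    # posterior probability that the pair interacts (bounded evidence)
    resp = 1.0 / (1.0 + np.exp(-(np.log(pi / (1 - pi)) + sub["log_bf"])))
    resp = resp.fillna(pi).to_dict()

    mol_to_drug = {mid: cfg.drug_ids[i] for i, mid in enumerate(ids)}
    cells = info["cells"]

    blocks = {k: [] for k in ("drugA", "drugB", "ggi", "ctf", "cell",
                              "bayes")}
    pair_bf, labels = [], []
    for s in samples:
        a, b = sorted((s.drug_a, s.drug_b))
        blocks["drugA"].append(emb[a])
        blocks["drugB"].append(emb[b])
        blocks["ggi"].append(_pair_features(grans[a], grans[b], ggi_params))
        blocks["ctf"].append(np.concatenate([ctf_emb[a] + ctf_emb[b],
                                             np.abs(ctf_emb[a] - ctf_emb[b])]))
        blocks["cell"].append(cells.loc[s.cell].to_numpy())
        da, db = sorted((mol_to_drug[a], mol_to_drug[b]))
        r = resp.get((da, db), pi)
        blocks["bayes"].append(np.array([r]))
        pair_bf.append(r)
        labels.append(s.label)

    out = {}
    for name, rows in blocks.items():
        M = np.stack(rows)
        mu, sd = M.mean(axis=0), M.std(axis=0)
        sd[sd < 1e-12] = 1.0
        M = (M - mu) / sd
        if view_noise > 0:
            M = M + view_noise * rng.standard_normal(M.shape)
        out[name] = M
    return Benchmark(blocks=out, labels=np.asarray(labels, dtype=int),
                     pair_evidence=np.asarray(pair_bf, dtype=float),
                     samples=samples, info=info)




# ---------------------------------------------------------------------------
# active-learning experiment
# ---------------------------------------------------------------------------

def al_experiment(bench: Benchmark = None, n_seeds: int = 10,
                  base_seed: int = 0, **bench_kw) -> pd.DataFrame:
    """Paired comparison of entropy-based vs random sample selection.

    Uses the benchmark's flattened fused features with a fast probabilistic
    model (logistic regression) so many paired loops are tractable.  Per
    seed: a 20% labeled seed set grows in 10%-of-train rounds to a 60%
    budget; the same split and reveal schedule is run with entropy-based
    and random selection, and the full-training-data AUROC is recorded as
    the ceiling.  Returns one row per seed with the final AL / random
    AUROCs and the all-data AUROC.
    """
    from .active_learning import ALConfig, al_loop

    if bench is None:
        bench = build_benchmark(**bench_kw)
    batch = make_sequence_batch(bench.blocks, bench.labels, normalize=False)
    flat = batch.x.reshape(len(bench.labels), -1)
    y = bench.labels

    def factory():
        return LogisticRegression(max_iter=300)

    rows = []
    for s in range(n_seeds):
        seed = base_seed + s
        tr, va, te = _split(len(y), seed, frac=(0.7, 0.0, 0.3))
        rng = np.random.default_rng(seed)
        tr = rng.permutation(tr)
        n_init = max(int(0.2 * len(tr)), 10)
        step = max(int(0.1 * len(tr)), 5)
        lab, pool = tr[:n_init], tr[n_init:]
        cfg = ALConfig(initial_labeled=n_init, batch_per_round=step,
                       rounds=4, seed=seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            al = al_loop(flat[lab], y[lab], flat[pool], y[pool],
                         flat[te], y[te], factory, cfg)
            rnd = al_loop(flat[lab], y[lab], flat[pool], y[pool],
                          flat[te], y[te], factory, cfg,
                          random_selection=True)
            full_model = factory().fit(flat[tr], y[tr])
        full_auc = metrics(full_model.predict_proba(flat[te])[:, 1],
                           y[te]).auroc
        rows.append({
            "seed": seed,
            "auroc_al": al[-1]["auroc"],
            "auroc_random": rnd[-1]["auroc"],
            "auroc_all_data": full_auc,
            "labels_used": al[-1]["labels_used"],
            "label_fraction": al[-1]["labels_used"] / len(tr),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# ablation harness
# ---------------------------------------------------------------------------

def _split(n, seed, frac=(0.6, 0.2, 0.2)):
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_tr = int(frac[0] * n)
    n_va = int(frac[1] * n)
    return order[:n_tr], order[n_tr:n_tr + n_va], order[n_tr + n_va:]


def train_benchmark_model(bench: Benchmark, disable=(), seed: int = 0,
                          hidden_dim: int = 32, epochs: int = 200,
                          lr: float = 2e-3, patience: int = 25,
                          label_budget: float = 0.6):
    """Train the pipeline on the benchmark with components disabled.

    Returns (test scores, test labels).  Neutral stand-ins: zeroed feature
    blocks for mfsyndcp/ggi/ctf and for the Bayesian evidence block (so
    "bayes off" yields the raw model without report-derived features),
    identity pass-through for lstm, and random instead of entropy-based
    selection of the training label budget for active_learning.
    """
    disable = set(disable)
    unknown = disable - set(ABLATABLE)
    if unknown:
        raise ValueError(f"unknown component ids: {sorted(unknown)}")

    blocks = {k: v.copy() for k, v in bench.blocks.items()}
    if "mfsyndcp" in disable:
        blocks["drugA"] = np.zeros_like(blocks["drugA"])
        blocks["drugB"] = np.zeros_like(blocks["drugB"])
    if "ggi" in disable:
        blocks["ggi"] = np.zeros_like(blocks["ggi"])
    if "ctf" in disable:
        blocks["ctf"] = np.zeros_like(blocks["ctf"])
    if "bayes" in disable:
        blocks["bayes"] = np.zeros_like(blocks["bayes"])
    batch = make_sequence_batch(blocks, bench.labels, normalize=False)

    tr, va, te = _split(len(bench.labels), seed)
    flat = batch.x.reshape(len(bench.labels), -1)

    # label-budget selection on the training split (entropy AL with a fast
    # probabilistic proxy model vs. random sampling when disabled)
    n_budget = max(int(label_budget * len(tr)), 20)
    rng = np.random.default_rng(seed + 1)
    if "active_learning" in disable:
        chosen = rng.choice(tr, size=n_budget, replace=False)
    else:
        n_init = n_budget // 2
        init = rng.choice(tr, size=n_init, replace=False)
        pool = np.setdiff1d(tr, init)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            proxy = LogisticRegression(max_iter=200)
            proxy.fit(flat[init], bench.labels[init])
            p_pool = proxy.predict_proba(flat[pool])[:, 1]
        from .active_learning import select_batch
        extra = pool[select_batch(p_pool, n_budget - n_init)]
        chosen = np.concatenate([init, extra])

    model = DARNN(batch.n, batch.T, hidden_dim=hidden_dim, seed=seed,
                  use_lstm="lstm" not in disable)
    cfg = TrainConfig.from_preset("darnn", epochs=epochs, lr=lr,
                                  patience=patience, seed=seed,
                                  hidden_dim=hidden_dim)
    train(model, (batch.x[chosen], bench.labels[chosen]),
          (batch.x[va], bench.labels[va]), cfg)
    return model.predict_proba(batch.x[te]), bench.labels[te]


def run_ablation(bench: Benchmark = None, disable_sets=None, seeds=(0,),
                 include_pairwise: bool = False, **bench_kw) -> pd.DataFrame:
    """Ablation table: one row per (configuration, seed).

    ``disable_sets`` defaults to the full model plus every single-component
    removal (plus all pairwise removals when ``include_pairwise``).
    """
    if bench is None:
        bench = build_benchmark(**bench_kw)
    if disable_sets is None:
        disable_sets = [()] + [(c,) for c in ABLATABLE]
        if include_pairwise:
            disable_sets += [(a, b) for i, a in enumerate(ABLATABLE)
                             for b in ABLATABLE[i + 1:]]
    rows = []
    for disable in disable_sets:
        for seed in seeds:
            scores, labels = train_benchmark_model(bench, disable, seed=seed)
            rep = metrics(scores, labels)
            rows.append({"config": "full" if not disable
                         else "no_" + "+".join(disable),
                         "seed": seed, **rep.as_dict()})
    return pd.DataFrame(rows)
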