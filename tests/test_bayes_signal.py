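"""Beta-binomial inference, stratification and disproportionality baselines."""

import numpy as np
import pytest
from scipy import integrate, stats

from dabiddi import bayes_signal as bs
from dabiddi.bayes_signal import (AEClassifier, BetaParams, PairAEContingency,
                                  baseline_stats, bayes_factor,
                                  choose_threshold, fit_prior_mom, posterior,
                                  prob_excess, stratify, stratify_all)


# ---------------------------------------------------------------------------
# stratification
# ---------------------------------------------------------------------------

def test_stratify_toy_counts():
    reports = [
        ({"A", "B"}, {"ae"}), ({"A", "B"}, set()),
        ({"A"}, {"ae"}), ({"A"}, set()),
        ({"B"}, {"ae"}), ({"B"}, set()),
    ]
    c = stratify(reports, "A", "B", "ae")
    assert (c.d_combo, c.d_first, c.d_second) == (1, 1, 1)
    assert (c.n_combo, c.n_first, c.n_second) == (2, 2, 2)
    assert c.expected_rate == pytest.approx(0.5 + 0.5 - 0.25)


def test_stratify_empty_and_same_drug():
    c = stratify([], "A", "B", "ae")
    assert (c.d_combo, c.n_combo, c.n_first, c.n_second) == (0, 0, 0, 0)
    with pytest.raises(ValueError):
        stratify([], "A", "A", "ae")


def test_stratify_all_matches_per_triple_recount(small_corpus):
    """Single-pass table equals the independent per-triple recount."""
    cfg, reports, _ = small_corpus
    table = stratify_all(reports, cfg.drug_ids, cfg.ae_ids)
    rng = np.random.default_rng(5)
    rows = table.sample(25, random_state=7)
    for row in rows.itertuples(index=False):
        c = stratify(reports, row.drugA, row.drugB, row.ae)
        assert (c.d_combo, c.n_combo, c.d_first, c.n_first,
                c.d_second, c.n_second) == (
            row.d_combo, row.n_combo, row.d_first, row.n_first,
            row.d_second, row.n_second)


def test_contingency_validation():
    with pytest.raises(ValueError):
        PairAEContingency(3, 2, 0, 0, 0, 0)


# ---------------------------------------------------------------------------
# prior fitting and conjugate updates
# ---------------------------------------------------------------------------

def test_mom_closed_form():
    # two rates with mean 0.2 and sample variance 0.016:
    # c = 0.2*0.8/0.016 - 1 = 9 -> Beta(1.8, 7.2)
    d = np.sqrt(0.016 / 2)
    prior = fit_prior_mom(rates=np.array([0.2 - d, 0.2 + d]))
    assert prior.alpha == pytest.approx(1.8)
    assert prior.beta == pytest.approx(7.2)


def test_mom_degenerate_falls_back_flat():
    with pytest.warns(UserWarning):
        prior = fit_prior_mom(rates=[0.3, 0.3, 0.3])
    assert (prior.alpha, prior.beta) == (1.0, 1.0)


def test_mom_parameter_recovery(rng):
    draws = rng.beta(2, 8, size=5000)
    prior = fit_prior_mom(rates=draws)
    assert abs(prior.alpha - 2) / 2 < 0.15
    assert abs(prior.beta - 8) / 8 < 0.15


def test_posterior_conjugate_update():
    post = posterior(BetaParams(1, 1), 3, 10)
    assert (post.alpha, post.beta) == (4, 8)
    assert post.mean == pytest.approx(1 / 3)
    # no data: prior unchanged
    same = posterior(BetaParams(2.5, 7.5), 0, 0)
    assert (same.alpha, same.beta) == (2.5, 7.5)
    with pytest.raises(ValueError):
        posterior(BetaParams(1, 1), 5, 3)


def test_posterior_mean_between_prior_and_mle():
    prior = BetaParams(2, 8)
    post = posterior(prior, 9, 10)
    assert prior.mean < post.mean < 0.9


def test_conjugacy_coherence():
    """Sequential updates equal one pooled update."""
    prior = BetaParams(1.5, 4.5)
    stepwise = posterior(posterior(prior, 3, 7), 2, 5)
    pooled = posterior(prior, 5, 12)
    assert (stepwise.alpha, stepwise.beta) == (pooled.alpha, pooled.beta)


def test_posterior_mean_matches_sampling(rng):
    post = posterior(BetaParams(2, 5), 7, 30)
    draws = rng.beta(post.alpha, post.beta, size=1_000_000)
    assert draws.mean() == pytest.approx(post.mean, abs=1e-3)


# ---------------------------------------------------------------------------
# Bayes factors
# ---------------------------------------------------------------------------

def test_bf_equal_priors_is_exactly_one():
    assert bayes_factor(7, 12, BetaParams(2, 3), BetaParams(2, 3)) == 1.0


def test_bf_ordering_at_extreme_counts():
    h1, h0 = BetaParams(5, 2), BetaParams(2, 5)  # mean 5/7 vs 2/7
    assert bayes_factor(10, 10, h1, h0) > 1
    assert bayes_factor(0, 10, h1, h0) < 1


def _quad_marginal(x, n, prior):
    from scipy.special import comb
    val, _ = integrate.quad(
        lambda t: comb(n, x) * t**x * (1 - t)**(n - x)
        * stats.beta.pdf(t, prior.alpha, prior.beta), 0, 1,
        limit=500, epsabs=1e-14, epsrel=1e-12)
    return val


@pytest.mark.parametrize("x,n,h1,h0", [
    (8, 10, (2, 2), (1, 9)),
    (3, 17, (1.5, 6.0), (0.8, 12.0)),
    (0, 5, (2, 2), (1, 1)),
])
def test_bf_matches_quadrature(x, n, h1, h0):
    got = bayes_factor(x, n, BetaParams(*h1), BetaParams(*h0))
    want = _quad_marginal(x, n, BetaParams(*h1)) / _quad_marginal(
        x, n, BetaParams(*h0))
    assert got == pytest.approx(want, rel=1e-6)


def test_bf_quadrature_sweep_small_n():
    rng = np.random.default_rng(0)
    for _ in range(10):
        n = int(rng.integers(1, 51))
        x = int(rng.integers(0, n + 1))
        h1 = BetaParams(*rng.uniform(0.5, 5, 2))
        h0 = BetaParams(*rng.uniform(0.5, 5, 2))
        got = bayes_factor(x, n, h1, h0)
        want = _quad_marginal(x, n, h1) / _quad_marginal(x, n, h0)
        assert got == pytest.approx(want, rel=1e-6)


# ---------------------------------------------------------------------------
# excess-risk probability
# ---------------------------------------------------------------------------

def test_prob_excess_symmetric_and_closed_form(rng):
    assert prob_excess(BetaParams(3, 4), BetaParams(3, 4)) == pytest.approx(0.5)
    # Beta(2,1) vs Beta(1,1): P = E[F_uniform(theta)] = E[theta] = 2/3
    assert prob_excess(BetaParams(2, 1), BetaParams(1, 1)) == pytest.approx(
        2 / 3, abs=1e-9)
    # Monte-Carlo agreement on random posteriors
    for _ in range(3):
        a = BetaParams(*rng.uniform(0.5, 10, 2))
        b = BetaParams(*rng.uniform(0.5, 10, 2))
        mc = (rng.beta(a.alpha, a.beta, 1_000_000)
              > rng.beta(b.alpha, b.beta, 1_000_000)).mean()
        assert prob_excess(a, b) == pytest.approx(mc, abs=2e-3)


# ---------------------------------------------------------------------------
# threshold selection
# ---------------------------------------------------------------------------

def test_threshold_separable_case():
    res = choose_threshold([0.1, 0.2, 5, 10], [0, 0, 1, 1])
    assert res.tau == pytest.approx(2.6)
    assert res.f1 == 1.0


def test_threshold_single_class_errors():
    with pytest.raises(ValueError):
        choose_threshold([1, 2, 3], [1, 1, 1])


def test_threshold_matches_grid_oracle(rng):
    for _ in range(5):
        bf = rng.lognormal(size=40)
        labels = rng.integers(0, 2, size=40)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        res = choose_threshold(bf, labels)
        # brute force: any rule "BF > t" predicts some top-k of the sorted
        # scores positive; enumerate all k
        order = np.argsort(-bf)
        best = 0.0
        for k in range(len(bf) + 1):
            pred = np.zeros(len(bf), dtype=bool)
            pred[order[:k]] = True
            tp = np.sum(pred & (labels == 1))
            denom = 2 * tp + np.sum(pred & (labels == 0)) + np.sum(
                ~pred & (labels == 1))
            best = max(best, 2 * tp / denom if denom else 0.0)
        assert res.f1 == pytest.approx(best, abs=1e-12)


# ---------------------------------------------------------------------------
# baseline statistics
# ---------------------------------------------------------------------------

def test_baselines_at_null_point():
    # choose counts so that O = E exactly: p1=p2=0.1 -> e=0.19, n=100, O=19
    c = PairAEContingency(19, 100, 10, 100, 10, 100)
    out = baseline_stats(c)
    assert out["omega"] == pytest.approx(0.0)
    assert out["intss"] == pytest.approx(1.0)
    assert out["delta_add"] == pytest.approx(0.0)
    assert out["llr"] == pytest.approx(0.0)


def test_baselines_match_direct_formulas(rng):
    for _ in range(10):
        n1, n2, n = (int(v) for v in rng.integers(20, 200, 3))
        d1, d2 = int(rng.integers(0, n1 // 2)), int(rng.integers(0, n2 // 2))
        d = int(rng.integers(0, n))
        c = PairAEContingency(d, n, d1, n1, d2, n2)
        out = baseline_stats(c)
        p1, p2 = d1 / n1, d2 / n2
        e = p1 + p2 - p1 * p2
        O, E = d, e * n
        assert out["intss"] == pytest.approx((O + 0.5) / (E + 0.5))
        assert out["omega"] == pytest.approx(np.log2((O + 0.5) / (E + 0.5)))
        assert out["delta_add"] == pytest.approx(d / n - e)
        p_hat = d / n
        if p_hat <= e:
            assert out["llr"] == 0.0
        else:
            def ll(p):
                p = min(max(p, 1e-12), 1 - 1e-12)
                return O * np.log(p) + (n - O) * np.log(1 - p)
            assert out["llr"] == pytest.approx(ll(p_hat) - ll(e))


def test_baselines_flag_zero_monotherapy():
    out = baseline_stats(PairAEContingency(2, 10, 0, 0, 1, 5))
    assert all(np.isnan(v) for v in out.values())


# ---------------------------------------------------------------------------
# posterior-feature classifier and ranking
# ---------------------------------------------------------------------------

def test_classifier_separable_and_ranking(rng):
    X = np.vstack([rng.normal(0, 0.1, (30, 2)), rng.normal(3, 0.1, (30, 2))])
    y = np.array(["nausea"] * 30 + ["rash"] * 30)
    clf = AEClassifier().fit(X, y)
    pred_conf = clf.confidence(X, "rash")
    assert ((pred_conf > 0.5) == (y == "rash")).mean() == 1.0
    combos = [f"c{i}" for i in range(len(X))]
    ranked = clf.rank_for_ae("rash", combos, X)
    scores = [s for _, s in ranked]
    assert sorted(scores, reverse=True) == scores
    assert sorted(c for c, _ in ranked) == sorted(combos)
    with pytest.raises(ValueError):
        clf.confidence(X, "unseen")
    with pytest.raises(ValueError):
        AEClassifier().fit(X, np.array(["same"] * len(X)))
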