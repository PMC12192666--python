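"""Beta-binomial Bayesian calibration of adverse-event count data.

Spontaneous reports are stratified per (drugA, drugB, AE) triple into the
six counts of the control-stratification table: AE counts and exposure
totals under concurrent administration and under each drug alone.  A
beta-binomial model with empirical-Bayes (method-of-moments) priors turns
these counts into posterior AE-rate distributions, Bayes factors for
"interaction present" vs "no interaction", excess-risk probabilities, and
an F1-optimal decision threshold.  Classical disproportionality baselines
(Omega, LLR, IntSS, delta_add) and a posterior-feature Gaussian naive-Bayes
classifier with per-AE confidence ranking are included for comparison.

The no-interaction reference rate for a drug pair is the independence of
causes surrogate  e = p1 + p2 - p1*p2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import integrate, special, stats
from sklearn.naive_bayes import GaussianNB

__all__ = [
    "BetaParams", "PairAEContingency", "SignalScores", "ThresholdResult",
    "stratify", "stratify_all", "fit_prior_mom", "posterior", "bayes_factor",
    "fit_signal_model", "prob_excess", "choose_threshold",
    "baseline_stats", "score_pairs",
    "AEClassifier", "signals_table",
]


@dataclass(frozen=True)
class BetaParams:
    """A Beta(alpha, beta) distribution over an AE rate theta."""

    alpha: float
    beta: float

    def __post_init__(self):
        if not (self.alpha > 0 and self.beta > 0):
            raise ValueError("Beta parameters must be strictly positive")

    @property
    def mean(self) -> float:
        return self.alpha / (self.alpha + self.beta)

    @property
    def var(self) -> float:
        s = self.alpha + self.beta
        return self.alpha * self.beta / (s * s * (s + 1.0))


@dataclass(frozen=True)
class PairAEContingency:
    """Six stratified counts for a (drugA, drugB, AE) triple.

    ``combo`` strata cover reports listing both drugs, ``first``/``second``
    reports listing exactly one of them; the three report subsets are
    disjoint by construction.
    """

    d_combo: int
    n_combo: int
    d_first: int
    n_first: int
    d_second: int
    n_second: int

    def __post_init__(self):
        for d, n in ((self.d_combo, self.n_combo), (self.d_first, self.n_first),
                     (self.d_second, self.n_second)):
            if not (0 <= d <= n):
                raise ValueError("require 0 <= d <= n in every stratum")

    def rate(self, stratum: str) -> float:
        d = getattr(self, f"d_{stratum}")
        n = getattr(self, f"n_{stratum}")
        return d / n if n > 0 else np.nan

    @property
    def expected_rate(self) -> float:
        """Independence-of-causes no-interaction rate p1 + p2 - p1*p2."""
        p1, p2 = self.rate("first"), self.rate("second")
        return p1 + p2 - p1 * p2


@dataclass(frozen=True)
class SignalScores:
    posterior: BetaParams
    posterior_mean: float
    prob_excess: float
    bf: float
    omega: float
    llr: float
    intss: float
    delta_add: float


@dataclass(frozen=True)
class ThresholdResult:
    tau: float
    f1: float
    n_labels: int


# ---------------------------------------------------------------------------
# stratification
# ---------------------------------------------------------------------------

def _drug_ae_sets(report):
    """Accept ReportRecord-like objects or (drugs, aes) pairs."""
    if hasattr(report, "drugs"):
        return report.drugs, report.aes
    drugs, aes = report
    return drugs, aes


def stratify(reports, drug_a: str, drug_b: str, ae: str) -> PairAEContingency:
    """Count the six control-stratification categories from raw reports."""
    if drug_a == drug_b:
        raise ValueError("drug_a and drug_b must differ")
    d_c = n_c = d_f = n_f = d_s = n_s = 0
    for rep in reports:
        drugs, aes = _drug_ae_sets(rep)
        has_a, has_b = drug_a in drugs, drug_b in drugs
        if has_a and has_b:
            n_c += 1
            d_c += ae in aes
        elif has_a:
            n_f += 1
            d_f += ae in aes
        elif has_b:
            n_s += 1
            d_s += ae in aes
    return PairAEContingency(d_c, n_c, d_f, n_f, d_s, n_s)


def stratify_all(reports, drug_ids, ae_ids) -> pd.DataFrame:
    """Vectorized stratification over every drug pair and AE term.

    Returns one row per (drugA, drugB, ae) with the six counts; equivalent
    to calling :func:`stratify` per triple but in a single pass.
    """
    drug_ix = {d: i for i, d in enumerate(drug_ids)}
    ae_ix = {a: j for j, a in enumerate(ae_ids)}
    nd, na = len(drug_ids), len(ae_ids)

    # exposure and AE counts per drug (any report containing it) and per
    # pair (reports containing both); "A alone" for a pair (A, B) is then
    # contains-A minus contains-both, matching the per-triple stratifier
    n_with = np.zeros(nd, dtype=np.int64)
    d_with = np.zeros((nd, na), dtype=np.int64)
    n_pair = np.zeros((nd, nd), dtype=np.int64)
    d_pair = np.zeros((nd, nd, na), dtype=np.int64)

    for rep in reports:
        drugs, aes = _drug_ae_sets(rep)
        idx = sorted(drug_ix[d] for d in drugs if d in drug_ix)
        aj = [ae_ix[a] for a in aes if a in ae_ix]
        for i in idx:
            n_with[i] += 1
            for j in aj:
                d_with[i, j] += 1
        for u in range(len(idx)):
            for v in range(u + 1, len(idx)):
                i, k = idx[u], idx[v]
                n_pair[i, k] += 1
                for j in aj:
                    d_pair[i, k, j] += 1

    rows = []
    for i in range(nd):
        for k in range(i + 1, nd):
            for j in range(na):
                rows.append(
                    (drug_ids[i], drug_ids[k], ae_ids[j],
                     d_pair[i, k, j], n_pair[i, k],
                     d_with[i, j] - d_pair[i, k, j],
                     n_with[i] - n_pair[i, k],
                     d_with[k, j] - d_pair[i, k, j],
                     n_with[k] - n_pair[i, k])
                )
    return pd.DataFrame(
        rows,
        columns=["drugA", "drugB", "ae", "d_combo", "n_combo",
                 "d_first", "n_first", "d_second", "n_second"],
    )


# ---------------------------------------------------------------------------
# beta-binomial inference
# ---------------------------------------------------------------------------

def fit_prior_mom(rates=None, counts=None) -> BetaParams:
    """Empirical-Bayes Beta prior by method of moments.

    Given observed AE rates (or (d, n) count pairs converted to rates),
    match the Beta mean and variance:  with sample mean m and variance v,
    c = m(1-m)/v - 1, alpha = m*c, beta = (1-m)*c.  Degenerate moments
    (zero variance, mean at 0 or 1, or v >= m(1-m)) fall back to the flat
    Beta(1, 1) prior with a warning.
    """
    if rates is None:
        if counts is None:
            raise ValueError("provide rates or counts")
        rates = np.array([d / n for d, n in counts if n > 0], dtype=float)
    rates = np.asarray(rates, dtype=float)
    rates = rates[np.isfinite(rates)]
    if rates.size < 2:
        raise ValueError("need at least two rate observations")
    m = float(rates.mean())
    v = float(rates.var(ddof=1))
    if v <= 0 or m <= 0 or m >= 1 or v >= m * (1.0 - m):
        warnings.warn(
            "rate moments outside Beta support; falling back to Beta(1, 1)",
            stacklevel=2,
        )
        return BetaParams(1.0, 1.0)
    c = m * (1.0 - m) / v - 1.0
    return BetaParams(m * c, (1.0 - m) * c)


def posterior(prior: BetaParams, x: int, n: int) -> BetaParams:
    """Conjugate update: Beta(a, b) + Binomial(n, theta) data -> Beta(a+x, b+n-x)."""
    if not 0 <= x <= n:
        raise ValueError("require 0 <= x <= n")
    return BetaParams(prior.alpha + x, prior.beta + n - x)


def _log_betabinom_marginal(x: int, n: int, prior: BetaParams) -> float:
    """log m(x, n) = log C(n,x) + log B(a+x, b+n-x) - log B(a, b)."""
    a, b = prior.alpha, prior.beta
    return (
        special.gammaln(n + 1) - special.gammaln(x + 1) - special.gammaln(n - x + 1)
        + special.betaln(a + x, b + n - x) - special.betaln(a, b)
    )


def bayes_factor(x: int, n: int, prior_h1: BetaParams, prior_h0: BetaParams,
                 log: bool = False) -> float:
    """Bayes factor m1(x, n) / m0(x, n) of the beta-binomial marginals.

    Computed in log space via log-gamma; the binomial coefficient cancels
    between numerator and denominator.
    """
    if not 0 <= x <= n:
        raise ValueError("require 0 <= x <= n")
    # grouped so identical priors cancel exactly (BF = 1 without roundoff)
    logbf = (
        special.betaln(prior_h1.alpha + x, prior_h1.beta + n - x)
        - special.betaln(prior_h0.alpha + x, prior_h0.beta + n - x)
    ) + (
        special.betaln(prior_h0.alpha, prior_h0.beta)
        - special.betaln(prior_h1.alpha, prior_h1.beta)
    )
    return logbf if log else float(np.exp(logbf))


def prob_excess(post_combo: BetaParams, post_ref: BetaParams) -> float:
    """P(theta_combo > theta_ref) for independent Beta posteriors.

    Evaluated as E[F_ref(theta_combo)] by adaptive quadrature of
    f_combo(x) * F_ref(x) on [0, 1].
    """
    fc = stats.beta(post_combo.alpha, post_combo.beta)
    Fr = stats.beta(post_ref.alpha, post_ref.beta).cdf
    val, _ = integrate.quad(lambda x: fc.pdf(x) * Fr(x), 0.0, 1.0, limit=200)
    return float(min(max(val, 0.0), 1.0))


def choose_threshold(bf_values, labels) -> ThresholdResult:
    """F1-optimal threshold tau for the rule ``BF > tau``.

    Candidates are midpoints between sorted unique BF values plus the two
    open ends; ties resolve to the smallest tau.
    """
    bf_values = np.asarray(bf_values, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(set(labels.tolist())) < 2:
        raise ValueError("both classes must be present to tune the threshold")
    uniq = np.unique(bf_values)
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    candidates = np.concatenate(([uniq[0] - 1.0], mids, [uniq[-1] + 1.0]))
    best_tau, best_f1 = candidates[0], -1.0
    for tau in candidates:
        pred = bf_values > tau
        tp = int(np.sum(pred & (labels == 1)))
        fp = int(np.sum(pred & (labels == 0)))
        fn = int(np.sum(~pred & (labels == 1)))
        denom = 2 * tp + fp + fn
        f1 = 2 * tp / denom if denom > 0 else 0.0
        if f1 > best_f1:  # strict: ties keep the smallest tau
            best_tau, best_f1 = float(tau), f1
    return ThresholdResult(tau=best_tau, f1=best_f1, n_labels=len(labels))


# ---------------------------------------------------------------------------
# classical disproportionality baselines
# ---------------------------------------------------------------------------

def baseline_stats(c: PairAEContingency):
    """Omega, one-sided binomial LLR, IntSS and delta_add for one triple.

    With monotherapy rates p1, p2, expected no-interaction rate
    e = p1 + p2 - p1*p2, observed O = d_combo and E = e * n_combo:
    omega = log2((O+0.5)/(E+0.5)); intss = (O+0.5)/(E+0.5);
    delta_add = O/n_combo - e; llr is the one-sided binomial log-likelihood
    ratio of the MLE rate vs e (0 when O/n_combo <= e).  Zero monotherapy
    exposure flags every statistic as missing (NaN).
    """
    if c.n_combo <= 0:
        raise ValueError("n_combo must be positive")
    if c.n_first == 0 or c.n_second == 0:
        return dict(omega=np.nan, llr=np.nan, intss=np.nan, delta_add=np.nan)
    e = c.expected_rate
    O = c.d_combo
    E = e * c.n_combo
    intss = (O + 0.5) / (E + 0.5)
    omega = float(np.log2(intss))
    p_hat = O / c.n_combo

    def loglik(p):
        p = min(max(p, 1e-12), 1 - 1e-12)
        return O * np.log(p) + (c.n_combo - O) * np.log(1.0 - p)

    llr = float(loglik(p_hat) - loglik(e)) if p_hat > e else 0.0
    return dict(omega=omega, llr=llr, intss=float(intss),
                delta_add=float(p_hat - e))


# ---------------------------------------------------------------------------
# full scoring pipeline
# ---------------------------------------------------------------------------

def _log_betabinom(x, n, a, b):
    """Vectorized beta-binomial log pmf via log-gamma."""
    return (special.gammaln(n + 1) - special.gammaln(x + 1)
            - special.gammaln(n - x + 1)
            + special.betaln(a + x, b + n - x) - special.betaln(a, b))


def fit_signal_model(x, n, e_hat, var_e, rho_grid=(1.05, 8.0, 60),
                     kappa_grid=(0.3, 1.5, 49), em_iters: int = 20):
    """Empirical-Bayes two-component beta-binomial signal model.

    Combination counts x ~ BetaBinomial(n, prior) where the prior over the
    AE rate theta is centered, for each pair, either at kappa * e (null
    component) or at rho * kappa * e (interaction component), with e the
    pair's no-interaction rate.  The global calibration factor kappa plays
    the role of the observed/expected normalization of classical
    empirical-Bayes disproportionality: the monotherapy strata ("contains
    A without B") include co-medicated reports, which inflates e
    systematically, and kappa re-centers the null on the corpus itself.
    The prior precision nu absorbs the uncertainty of e (matched to
    ``var_e``); kappa, the risk multiplier rho and the mixing weight pi
    are estimated from the whole table by EM — the "hyperparameters
    progressively optimized" step.  Returns (log_bf, rho, pi, nu) with
    per-triple log marginal-likelihood ratios m1/m0; kappa is folded into
    both marginals.
    """
    x = np.asarray(x, dtype=float)
    n = np.asarray(n, dtype=float)
    e_hat = np.clip(np.asarray(e_hat, dtype=float), 1e-6, 1 - 1e-6)
    var_e = np.maximum(np.asarray(var_e, dtype=float), 1e-9)
    nu = np.maximum(e_hat * (1 - e_hat) / var_e - 1.0, 5.0)

    def lm(center):
        m = np.clip(center, 1e-6, 0.99)
        return _log_betabinom(x, n, nu * m, nu * (1 - m))

    r_lo, r_hi, r_n = rho_grid
    k_lo, k_hi, k_n = kappa_grid
    rhos = np.linspace(r_lo, r_hi, int(r_n))
    kappas = np.linspace(k_lo, k_hi, int(k_n))
    rho, pi, kappa = 2.0, 0.05, 1.0
    for _ in range(em_iters):
        lm0 = lm(kappa * e_hat)
        l1 = np.log(pi) + lm(rho * kappa * e_hat)
        l0 = np.log(1 - pi) + lm0
        mx = np.maximum(l1, l0)
        resp = np.exp(l1 - mx) / (np.exp(l1 - mx) + np.exp(l0 - mx))
        pi = float(np.clip(resp.mean(), 1e-4, 0.5))
        kappa = float(kappas[int(np.argmax(
            [np.sum((1 - resp) * lm(k * e_hat)) for k in kappas]))])
        rho = float(rhos[int(np.argmax(
            [np.sum(resp * lm(g * kappa * e_hat)) for g in rhos]))])
    log_bf = lm(rho * kappa * e_hat) - lm(kappa * e_hat)
    return log_bf, rho, pi, nu, kappa


def _solo_counts(table: pd.DataFrame):
    """Reconstruct monotherapy-only exposure/AE counts per table row.

    For a complete all-pairs table, reports containing drug A alone equal
    "contains A" (first stratum + pair stratum of any row with A) minus
    the pair exposures of A summed over partners.  Exact when reports
    list at most two drugs; a conservative clip at zero guards corpora
    with larger drug sets.  Returns (d1, n1, d2, n2) arrays aligned with
    the table, or None when the reconstruction is not well determined.
    """
    n_with, d_with = {}, {}
    pair_n, pair_d = {}, {}
    for row in table.itertuples(index=False):
        key = (row.drugA, row.drugB)
        pair_n[key] = row.n_combo
        pair_d.setdefault(key, {})[row.ae] = row.d_combo
        for drug, dd, nn in ((row.drugA, row.d_first, row.n_first),
                             (row.drugB, row.d_second, row.n_second)):
            total = nn + row.n_combo
            if drug in n_with and n_with[drug] != total:
                return None  # inconsistent: not an all-pairs table
            n_with[drug] = total
            d_with.setdefault(drug, {})[row.ae] = dd + pair_d[key][row.ae]
    n_pairsum = {d: 0 for d in n_with}
    d_pairsum = {d: {} for d in n_with}
    for (a, b), nn in pair_n.items():
        n_pairsum[a] += nn
        n_pairsum[b] += nn
        for ae, dd in pair_d[(a, b)].items():
            d_pairsum[a][ae] = d_pairsum[a].get(ae, 0) + dd
            d_pairsum[b][ae] = d_pairsum[b].get(ae, 0) + dd
    out = [[], [], [], []]
    for row in table.itertuples(index=False):
        for k, drug in ((0, row.drugA), (2, row.drugB)):
            n_solo = max(n_with[drug] - n_pairsum[drug], 0)
            d_solo = max(d_with[drug][row.ae]
                         - d_pairsum[drug].get(row.ae, 0), 0)
            out[k].append(min(d_solo, n_solo))
            out[k + 1].append(n_solo)
    return tuple(np.asarray(a, dtype=float) for a in out)


def score_pairs(table: pd.DataFrame, single_prior: BetaParams = None,
                compute_prob_excess: bool = False) -> pd.DataFrame:
    """Score every (drugA, drugB, ae) row of a stratified count table.

    Pipeline: (1) empirical-Bayes prior over monotherapy AE rates by
    method of moments; (2) posterior-mean monotherapy rates give each
    pair's no-interaction rate e = p1 + p2 - p1*p2 and its estimation
    variance; (3) the two-component beta-binomial model of
    :func:`fit_signal_model` yields the interaction log Bayes factor per
    triple; (4) the classical baselines (Omega, LLR, IntSS, delta_add) are
    computed from the raw stratified rates.  Optionally (the slow part)
    adds the posterior excess-risk probability P(theta_combo > theta_ref).

    Rows with an empty stratum have NaN in the affected columns.  The
    fitted hyperparameters are stored in ``out.attrs``.
    """
    out = table.copy()
    d1 = table["d_first"].to_numpy(float)
    n1 = table["n_first"].to_numpy(float)
    d2 = table["d_second"].to_numpy(float)
    n2 = table["n_second"].to_numpy(float)
    x = table["d_combo"].to_numpy(float)
    n = table["n_combo"].to_numpy(float)
    ok = (n > 0) & (n1 > 0) & (n2 > 0)

    if single_prior is None:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            single_prior = fit_prior_mom(
                rates=np.concatenate([d1[ok] / n1[ok], d2[ok] / n2[ok]]))
    a_s, b_s = single_prior.alpha, single_prior.beta

    log_bf = np.full(len(table), np.nan)
    post_mean = np.full(len(table), np.nan)
    base = {k: np.full(len(table), np.nan) for k in
            ("omega", "llr", "intss", "delta_add")}
    rho = pi = kappa = np.nan
    if ok.sum() >= 2:
        solo = _solo_counts(table)
        if solo is not None:
            # monotherapy-only rates reconstructed from the pairwise table
            # ("contains A" minus every pair exposure of A): the "A without
            # B" strata include co-medicated reports, which inflates the
            # per-drug rate; the reconstruction removes that bias for the
            # Bayesian model (the classical baselines keep the raw strata)
            ds1, ns1, ds2, ns2 = (arr[ok] for arr in solo)
        else:
            ds1, ns1, ds2, ns2 = d1[ok], n1[ok], d2[ok], n2[ok]
        ns1 = np.maximum(ns1, 1.0)
        ns2 = np.maximum(ns2, 1.0)
        p1 = (a_s + ds1) / (a_s + b_s + ns1)
        p2 = (a_s + ds2) / (a_s + b_s + ns2)
        e_hat = p1 + p2 - p1 * p2
        v1 = p1 * (1 - p1) / (a_s + b_s + ns1 + 1)
        v2 = p2 * (1 - p2) / (a_s + b_s + ns2 + 1)
        var_e = (1 - p2) ** 2 * v1 + (1 - p1) ** 2 * v2
        lbf, rho, pi, nu, kappa = fit_signal_model(x[ok], n[ok], e_hat,
                                                   var_e)
        log_bf[ok] = lbf
        post_mean[ok] = (nu * kappa * e_hat + x[ok]) / (nu + n[ok])

        # classical baselines from raw stratified rates
        r1, r2 = d1[ok] / n1[ok], d2[ok] / n2[ok]
        e_raw = np.clip(r1 + r2 - r1 * r2, 1e-12, 1 - 1e-12)
        O, E = x[ok], e_raw * n[ok]
        intss = (O + 0.5) / (E + 0.5)
        base["intss"][ok] = intss
        base["omega"][ok] = np.log2(intss)
        p_hat = O / n[ok]
        base["delta_add"][ok] = p_hat - e_raw
        ph = np.clip(p_hat, 1e-12, 1 - 1e-12)
        ll = O * np.log(ph / e_raw) + (n[ok] - O) * np.log((1 - ph) / (1 - e_raw))
        base["llr"][ok] = np.where(p_hat > e_raw, ll, 0.0)

    p_exc = np.full(len(table), np.nan)
    if compute_prob_excess:
        idx = np.flatnonzero(ok)
        p1r, p2r = d1[ok] / n1[ok], d2[ok] / n2[ok]
        for j, i in enumerate(idx):
            # reference posterior: flat prior updated with pooled
            # monotherapy counts at the independence-expected rate
            n_ref = n1[i] + n2[i]
            e_ref = p1r[j] + p2r[j] - p1r[j] * p2r[j]
            p_exc[i] = prob_excess(
                posterior(BetaParams(1, 1), int(x[i]), int(n[i])),
                posterior(BetaParams(1, 1), round(e_ref * n_ref), int(n_ref)))

    out["log_bf"] = log_bf
    out["bf"] = np.exp(log_bf)
    out["posterior_mean"] = post_mean
    out["prob_excess"] = p_exc
    for k, v in base.items():
        out[k] = v
    out.attrs["signal_model"] = {"rho": rho, "pi": pi, "kappa": kappa,
                                 "single_prior": single_prior}
    return out


def signals_table(reports, drug_ids, ae_ids, **kwargs) -> pd.DataFrame:
    """Stratify raw reports and score every triple in one call."""
    return score_pairs(stratify_all(reports, drug_ids, ae_ids), **kwargs)


# ---------------------------------------------------------------------------
# posterior-feature Bayesian classifier and per-AE confidence ranking
# ---------------------------------------------------------------------------

class AEClassifier:
    """Gaussian naive-Bayes over (posterior probability, log usage frequency).

    Fit per AE category; ranking a queried AE sorts drug combinations by the
    predicted class probability for that category, descending.
    """

    def __init__(self):
        self._nb = GaussianNB()
        self._classes = None

    def fit(self, features, categories):
        X = np.asarray(features, dtype=float)
        y = np.asarray(categories)
        if len(np.unique(y)) < 2:
            raise ValueError("need at least two AE categories to fit")
        self._nb.fit(X, y)
        self._classes = list(self._nb.classes_)
        return self

    def confidence(self, features, ae):
        if self._classes is None or ae not in self._classes:
            raise ValueError(f"unknown AE category: {ae!r}")
        X = np.asarray(features, dtype=float)
        return self._nb.predict_proba(X)[:, self._classes.index(ae)]

    def rank_for_ae(self, ae, combos, features):
        """Rank combination labels for one AE by classifier confidence."""
        scores = self.confidence(features, ae)
        order = np.argsort(-scores, kind="stable")
        return [(combos[i], float(scores[i])) for i in order]
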