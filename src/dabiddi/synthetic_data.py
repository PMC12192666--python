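"""Synthetic inputs for the full pipeline.

Generates everything the other modules consume offline: spontaneous-report
tables with injected interaction signals (post-curation style — one record
per report, standardized drug/AE identifiers, one or two drugs per report),
small drug-like molecules as SMILES, cell-line feature matrices with a
known latent factor, labeled (drugA, drugB, cell) triplets produced by a
documented deterministic rule, and a toy drug-target-enzyme-transporter-AE
attribute network.

Null model: for a non-interacting drug pair the combination AE probability
is the independence-of-causes baseline p1 + p2 - p1*p2; an injected signal
multiplies that baseline by ``risk_ratio`` (clipped to 1).  One master seed
is split into independent per-generator streams.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bayes_signal import BetaParams
from .molecular_features import descriptors, parse_smiles

__all__ = [
    "ReportRecord", "SimReportConfig", "GroundTruth", "TripletSample",
    "gen_reports", "gen_molecules", "gen_cell_features", "gen_triplets",
    "gen_bio_network", "reports_to_frame", "write_reports_csv",
    "read_reports_csv",
]


@dataclass(frozen=True)
class ReportRecord:
    """One spontaneous report: identifier, drug set, AE term set."""

    report_id: str
    drugs: frozenset
    aes: frozenset


@dataclass(frozen=True)
class SimReportConfig:
    """Study conditions for the report simulator.

    Defaults mirror a curated FAERS-like corpus: 41.68% of reports list
    more than one drug (p_combo), per-drug per-AE baseline rates are drawn
    from a right-skewed Beta(1.5, 30) (mean ~4.7%), 10% of drug pairs carry
    a true interaction signal at rate ratio 3, and drug report frequencies
    are Zipf-skewed (weight of the r-th drug proportional to 1/r^s with
    s = ``popularity_s``; 0 gives uniform exposure) — spontaneous-report
    corpora are dominated by a few heavily reported drugs, leaving most
    combinations sparse.
    """

    n_drugs: int = 20
    n_reports: int = 50_000
    p_combo: float = 0.4168
    baseline_prior: BetaParams = field(default_factory=lambda: BetaParams(1.5, 30.0))
    frac_interacting: float = 0.1
    risk_ratio: float = 3.0
    n_aes: int = 10
    popularity_s: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_drugs < 2 or self.n_reports < 1 or self.n_aes < 1:
            raise ValueError("counts must be positive (n_drugs >= 2)")
        if not 0.0 <= self.p_combo <= 1.0:
            raise ValueError("p_combo must lie in [0, 1]")
        if not 0.0 <= self.frac_interacting <= 1.0:
            raise ValueError("frac_interacting must lie in [0, 1]")
        if self.risk_ratio < 1.0:
            raise ValueError("risk_ratio must be >= 1")

    @property
    def drug_ids(self):
        return [f"D{i:03d}" for i in range(self.n_drugs)]

    @property
    def ae_ids(self):
        return [f"AE{j:02d}" for j in range(self.n_aes)]


@dataclass(frozen=True)
class GroundTruth:
    """Injected signals and the baseline rates behind a simulated corpus."""

    interacting: dict           # frozenset{a, b} -> (ae, risk_ratio)
    baseline_rates: np.ndarray  # n_drugs x n_aes
    drug_ids: list
    ae_ids: list

    def is_signal(self, drug_a: str, drug_b: str, ae: str) -> bool:
        hit = self.interacting.get(frozenset((drug_a, drug_b)))
        return hit is not None and hit[0] == ae

    def pair_rate(self, drug_a: str, drug_b: str, ae: str) -> float:
        """True combination AE probability for a pair (with injection)."""
        i = self.drug_ids.index(drug_a)
        k = self.drug_ids.index(drug_b)
        j = self.ae_ids.index(ae)
        p1, p2 = self.baseline_rates[i, j], self.baseline_rates[k, j]
        base = p1 + p2 - p1 * p2
        if self.is_signal(drug_a, drug_b, ae):
            rr = self.interacting[frozenset((drug_a, drug_b))][1]
            return min(1.0, rr * base)
        return base


def _split_seed(seed: int, stream: str) -> np.random.Generator:
    """Independent per-generator stream derived from one master seed."""
    tag = zlib.crc32(stream.encode()) % (2**31)
    return np.random.default_rng(np.random.SeedSequence([seed, tag]))


def gen_reports(config: SimReportConfig, interacting_pairs=None):
    """Simulate spontaneous reports with injected interaction signals.

    Returns ``(reports, truth)``.  Each report lists one drug (prob
    1 - p_combo) or an unordered pair; each AE term occurs independently at
    the drug's baseline rate, the pair's independence baseline, or the
    risk-ratio-inflated rate for the pair's injected AE.  By default
    ``frac_interacting`` of the pairs are flagged at random; an explicit
    list of (drugA, drugB, ae) triples overrides the random choice.
    """
    rng = _split_seed(config.seed, "reports")
    nd, na = config.n_drugs, config.n_aes
    drug_ids, ae_ids = config.drug_ids, config.ae_ids

    rates = rng.beta(config.baseline_prior.alpha, config.baseline_prior.beta,
                     size=(nd, na))

    pairs = [(i, k) for i in range(nd) for k in range(i + 1, nd)]
    pair_index = {frozenset(p): s for s, p in enumerate(pairs)}
    interacting = {}
    if interacting_pairs is not None:
        sig_idx = []
        for da, db, ae in interacting_pairs:
            key = frozenset((drug_ids.index(da), drug_ids.index(db)))
            sig_idx.append(pair_index[key])
            interacting[frozenset((da, db))] = (ae, config.risk_ratio)
    else:
        n_sig = int(round(config.frac_interacting * len(pairs)))
        sig_idx = (rng.choice(len(pairs), size=n_sig, replace=False)
                   if n_sig else [])
        for s in sig_idx:
            i, k = pairs[s]
            ae = ae_ids[int(rng.integers(na))]
            interacting[frozenset((drug_ids[i], drug_ids[k]))] = (
                ae, config.risk_ratio)

    # per-pair AE rate matrix (independence baseline + injections), clipped
    pair_rates = np.empty((len(pairs), na))
    for p, (i, k) in enumerate(pairs):
        p1, p2 = rates[i], rates[k]
        pair_rates[p] = p1 + p2 - p1 * p2
    for s in sig_idx:
        i, k = pairs[s]
        ae, rr = interacting[frozenset((drug_ids[i], drug_ids[k]))]
        j = ae_ids.index(ae)
        pair_rates[s, j] = min(1.0, rr * pair_rates[s, j])
    pair_rates = np.clip(pair_rates, 0.0, 1.0)

    # Zipf-skewed drug report frequencies; pair exposure follows the
    # product of the two drugs' popularities
    w = 1.0 / np.arange(1, nd + 1) ** config.popularity_s
    w /= w.sum()
    pw = np.array([w[i] * w[k] for i, k in pairs])
    pw /= pw.sum()

    is_combo = rng.random(config.n_reports) < config.p_combo
    single_drug = rng.choice(nd, size=config.n_reports, p=w)
    combo_pair = rng.choice(len(pairs), size=config.n_reports, p=pw)
    u = rng.random((config.n_reports, na))

    reports = []
    for r in range(config.n_reports):
        if is_combo[r]:
            i, k = pairs[combo_pair[r]]
            drugs = frozenset((drug_ids[i], drug_ids[k]))
            hit = u[r] < pair_rates[combo_pair[r]]
        else:
            i = single_drug[r]
            drugs = frozenset((drug_ids[i],))
            hit = u[r] < rates[i]
        aes = frozenset(ae_ids[j] for j in np.flatnonzero(hit))
        reports.append(ReportRecord(f"R{r:07d}", drugs, aes))

    truth = GroundTruth(interacting=interacting, baseline_rates=rates,
                        drug_ids=drug_ids, ae_ids=ae_ids)
    return reports, truth


# ---------------------------------------------------------------------------
# molecules
# ---------------------------------------------------------------------------

# small drug-like scaffolds with one substitution point
_SCAFFOLDS = [
    "c1ccc({R})cc1",          # benzene
    "C1CCC({R})CC1",          # cyclohexane
    "c1ccnc({R})c1",          # pyridine
    "O=C(O)c1ccc({R})cc1",    # benzoic acid
    "CC(=O)Nc1ccc({R})cc1",   # acetanilide
    "{R}CCO",                 # short chain alcohols
    "{R}C(=O)OC",             # methyl esters
    "c1ccc2c(c1)cccc2{R}",    # naphthalene
]
_SUBSTITUENTS = ["C", "CC", "O", "N", "Cl", "F", "OC", "C(=O)O", "N(C)C",
                 "CO", "C#N", "CCN"]


def gen_molecules(n: int, seed: int = 0) -> list:
    """Generate ``n`` parseable drug-like (id, SMILES) pairs.

    Drawn deterministically from a scaffold/substituent template library;
    every output parses and has at least 3 heavy atoms.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = _split_seed(seed, "molecules")
    out = []
    k = 0
    while len(out) < n:
        scaffold = _SCAFFOLDS[int(rng.integers(len(_SCAFFOLDS)))]
        sub = _SUBSTITUENTS[int(rng.integers(len(_SUBSTITUENTS)))]
        smiles = scaffold.format(R=sub)
        try:
            g = parse_smiles(smiles)
        except ValueError:  # pragma: no cover - templates are all valid
            continue
        if g.n_atoms < 3:  # pragma: no cover
            continue
        out.append((f"M{k:03d}", smiles))
        k += 1
    return out


def gen_cell_features(n_cells: int, n_genes: int = 20, seed: int = 0):
    """Cell-line gene-feature matrix with one dominant latent factor.

    Returns ``(frame, factors)``: a cells x genes DataFrame whose rows are
    factor * loading + noise, and the latent factor per cell (the quantity
    the default triplet label rule reads).
    """
    rng = _split_seed(seed, "cells")
    factors = rng.normal(size=n_cells)
    loading = rng.normal(size=n_genes)
    expr = np.outer(factors, loading) + 0.3 * rng.normal(size=(n_cells, n_genes))
    frame = pd.DataFrame(
        expr,
        index=[f"CELL{c:02d}" for c in range(n_cells)],
        columns=[f"G{g:03d}" for g in range(n_genes)],
    )
    return frame, factors


# ---------------------------------------------------------------------------
# triplets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TripletSample:
    drug_a: str
    drug_b: str
    cell: str
    label: int


def default_rule(heavy_sum: float, cell_factor: float, pair_latent: float,
                 params: dict) -> int:
    """Deterministic symmetric label rule for a (pair, cell) triplet.

    z_pair = (hA + hB - median_pair_heavy)/scale_h + lam_p * pair_latent
    z_cell = (factor - median_factor)/scale_f
    z = z_pair + z_cell + lam_int * z_pair * tanh(z_cell)

    label = 1 iff z >= z_med.  The structural term is readable from
    descriptors, the cell term from the cell-line latent factor, and
    ``pair_latent`` is an idiosyncratic pair interaction propensity
    (unmeasured pharmacology: it is what the spontaneous-report stream,
    not molecular structure, can reveal).  The multiplicative term makes
    the synergy context-dependent — the same pair can flip outcome across
    cell lines — so the decision surface is not additive in the feature
    blocks.  All population constants are recorded in ``params`` so every
    label can be re-derived independently.
    """
    z_pair = ((heavy_sum - params["med_h"]) / params["scale_h"]
              + params["lam_p"] * pair_latent)
    z_cell = (cell_factor - params["med_f"]) / params["scale_f"]
    z = z_pair + z_cell + params["lam_int"] * z_pair * np.tanh(z_cell)
    return int(z >= params["z_med"])


def gen_triplets(molecules, n_cells: int = 5, rule: str = "default",
                 seed: int = 0, n_triplets: int = 2000,
                 lam_latent: float = 0.0, lam_interact: float = 1.5):
    """Labeled (drugA, drugB, cell) triplets with a known decision rule.

    Returns ``(samples, info)`` where ``info`` carries the cell feature
    frame, latent cell factors, per-pair latent interaction propensities
    and the rule constants needed to re-derive every label independently.
    Labels are symmetric in the drug pair by construction (the rule reads
    the unordered heavy-atom sum and the unordered pair's latent).  The
    median threshold makes the classes balanced.

    With the default ``lam_latent = 0`` the rule is fully determined by
    descriptors and the cell factor; a positive weight adds an
    idiosyncratic per-pair propensity that no molecular feature carries
    (used by the ablation benchmark, where the spontaneous-report stream
    is the only witness of that term).
    """
    if len(molecules) < 2:
        raise ValueError("need at least two molecules")
    if rule != "default":
        raise ValueError(f"unknown rule id: {rule!r}")
    rng = _split_seed(seed, "triplets")
    cells, factors = gen_cell_features(n_cells, seed=seed)

    heavy = {mid: descriptors(parse_smiles(smi, mid)).heavy_atom_count
             for mid, smi in molecules}
    ids = [mid for mid, _ in molecules]
    pairs = [(ids[i], ids[k]) for i in range(len(ids))
             for k in range(i + 1, len(ids))]
    latents = rng.normal(size=len(pairs))
    pair_latent = {frozenset(p): float(v) for p, v in zip(pairs, latents)}

    n_total = len(pairs) * n_cells
    take = min(n_triplets, n_total)
    chosen = rng.choice(n_total, size=take, replace=False)

    hsums = np.array([heavy[a] + heavy[b] for a, b in pairs], dtype=float)
    med_h = float(np.median(hsums))
    scale_h = float(np.std(hsums)) or 1.0
    med_f = float(np.median(factors))
    scale_f = float(np.std(factors)) or 1.0
    params = dict(med_h=med_h, scale_h=scale_h, med_f=med_f, scale_f=scale_f,
                  lam_p=float(lam_latent), lam_int=float(lam_interact),
                  z_med=0.0)

    # raw scores of the chosen triplets; the median sets a balanced cut
    zs = []
    for c in chosen:
        p, cell_ix = divmod(int(c), n_cells)
        a, b = pairs[p]
        z_pair = ((heavy[a] + heavy[b] - med_h) / scale_h
                  + params["lam_p"] * latents[p])
        z_cell = (factors[cell_ix] - med_f) / scale_f
        zs.append(z_pair + z_cell
                  + params["lam_int"] * z_pair * np.tanh(z_cell))
    params["z_med"] = float(np.median(zs))

    samples = []
    for c in chosen:
        p, cell_ix = divmod(int(c), n_cells)
        a, b = pairs[p]
        lab = default_rule(heavy[a] + heavy[b], factors[cell_ix],
                           latents[p], params)
        samples.append(TripletSample(a, b, cells.index[cell_ix], lab))

    info = dict(cells=cells, factors=factors, rule_params=params,
                heavy=heavy, pair_latent=pair_latent, rule=rule)
    return samples, info


# ---------------------------------------------------------------------------
# biological attribute network
# ---------------------------------------------------------------------------

def gen_bio_network(n_drugs: int = 4, n_targets: int = 6, n_enzymes: int = 3,
                    n_transporters: int = 2, n_aes: int = 3, seed: int = 0,
                    ppi_confidence: tuple = (400, 1000)) -> pd.DataFrame:
    """Toy typed edge list ``src,dst,type,weight``.

    PPI edges carry integer confidences in ``ppi_confidence`` range
    (0-1000); other edges carry weights in [0, 1].  Every drug is wired
    through at least one enzyme to an AE so a drug -> AE path always exists
    before filtering.
    """
    for v in (n_drugs, n_targets, n_enzymes, n_transporters, n_aes):
        if v < 1:
            raise ValueError("all node counts must be positive")
    rng = _split_seed(seed, "network")
    drugs = [f"D{i:03d}" for i in range(n_drugs)]
    targets = [f"T{i:02d}" for i in range(n_targets)]
    enzymes = [f"CYP{i}" for i in range(n_enzymes)]
    transporters = [f"ABC{i}" for i in range(n_transporters)]
    aes = [f"AE{i:02d}" for i in range(n_aes)]

    rows = []

    def w():
        return round(float(rng.uniform(0.3, 1.0)), 3)

    # injected mechanism per drug: drug -> enzyme -> AE
    for i, d in enumerate(drugs):
        enz = enzymes[i % n_enzymes]
        ae = aes[i % n_aes]
        rows.append((d, enz, "drug-enzyme", w()))
        rows.append((enz, ae, "enzyme-ae", w()))
    # extra typed edges
    for d in drugs:
        for t in rng.choice(targets, size=min(2, n_targets), replace=False):
            rows.append((d, t, "drug-target", w()))
        if rng.random() < 0.8:
            tr = transporters[int(rng.integers(n_transporters))]
            rows.append((d, tr, "drug-transporter", w()))
            rows.append((tr, aes[int(rng.integers(n_aes))], "transporter-ae", w()))
    # PPI edges among targets with integer confidences
    lo, hi = ppi_confidence
    for i in range(n_targets):
        for k in range(i + 1, n_targets):
            if rng.random() < 0.5:
                rows.append((targets[i], targets[k], "ppi",
                             int(rng.integers(lo, hi + 1))))
    for t in targets:
        if rng.random() < 0.6:
            rows.append((t, aes[int(rng.integers(n_aes))], "target-ae", w()))

    return pd.DataFrame(rows, columns=["src", "dst", "type", "weight"])


# ---------------------------------------------------------------------------
# I/O dialects
# ---------------------------------------------------------------------------

def reports_to_frame(reports) -> pd.DataFrame:
    """Reports as a ``report_id,drugs,aes`` frame with ';'-separated sets."""
    return pd.DataFrame(
        {
            "report_id": [r.report_id for r in reports],
            "drugs": [";".join(sorted(r.drugs)) for r in reports],
            "aes": [";".join(sorted(r.aes)) for r in reports],
        }
    )


def write_reports_csv(reports, path):
    reports_to_frame(reports).to_csv(path, index=False)


def read_reports_csv(path) -> list:
    frame = pd.read_csv(path, keep_default_na=False)
    out = []
    for row in frame.itertuples(index=False):
        drugs = frozenset(str(row.drugs).split(";")) if row.drugs else frozenset()
        aes = frozenset(str(row.aes).split(";")) if row.aes else frozenset()
        out.append(ReportRecord(str(row.report_id), drugs, aes))
    return out
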