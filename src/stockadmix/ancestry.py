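"""Two-population admixture estimation and per-lake summaries.

Each individual i carries a domestic ancestry fraction q_i; each locus j has
alternate-allele frequencies f_dj (domestic cluster) and f_wj (wild
cluster). Genotypes are modeled as Binomial(2, q_i f_dj + (1-q_i) f_wj).
The log-likelihood

    l = sum_ij [ g_ij log(q_i f_dj + (1-q_i) f_wj)
               + (2 - g_ij) log(1 - q_i f_dj - (1-q_i) f_wj) ]

is maximized over (q, f_d, f_w) by expectation-maximization on the latent
cluster-of-origin of each allele copy — the classic block-relaxation scheme
of model-based ancestry estimators — which yields closed-form updates and a
monotone non-decreasing log-likelihood. Estimation is unsupervised; cluster
labels are anchored afterwards so that the cluster with the higher mean
ancestry among the domestic hatchery reference individuals is called
"domestic". Multiple seeded restarts guard against local optima.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import MISSING, ROLE_DOMESTIC, ROLE_WILD, GenotypeMatrix

EPS = 1e-6

#: minimum split-half correlation of q-hat for ancestry to count as
#: identifiable (see ``estimate_admixture_k2``).
IDENTIFIABILITY_MIN_CORRELATION = 0.5


@dataclass
class AncestryEstimate:
    """Result of a K=2 admixture fit."""

    q: np.ndarray
    f_domestic: np.ndarray
    f_wild: np.ndarray
    loglik: float
    loglik_history: np.ndarray
    n_iter: int
    converged: bool
    q_defined: bool = True
    individual_ids: list[str] = field(default_factory=list)
    roles: list[str] = field(default_factory=list)
    populations: list[str] = field(default_factory=list)


@dataclass
class LakeSummary:
    lake_id: str
    mean_q: float
    sd_q: float
    n_individuals: int
    type_counts: dict[str, int]


def admixture_loglik(
    g: np.ndarray, q: np.ndarray, f_dom: np.ndarray, f_wild: np.ndarray
) -> float:
    """Binomial admixture log-likelihood (without the constant C(2, g) term)."""
    p = q[:, None] * f_dom[None, :] + (1.0 - q[:, None]) * f_wild[None, :]
    p = np.clip(p, EPS, 1.0 - EPS)
    return float(np.sum(g * np.log(p) + (2.0 - g) * np.log1p(-p)))


def _em_run(
    g: np.ndarray,
    q: np.ndarray,
    f_dom: np.ndarray,
    f_wild: np.ndarray,
    tol: float,
    max_iter: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, int, bool]:
    a = g.astype(float)          # alternate-allele copies
    b = 2.0 - a                  # reference-allele copies
    history = []
    prev = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        qc = q[:, None]
        # responsibilities: probability an allele copy originated in the
        # domestic cluster, separately for alternate and reference copies
        num1 = qc * f_dom[None, :]
        r1 = num1 / (num1 + (1.0 - qc) * f_wild[None, :])
        num0 = qc * (1.0 - f_dom[None, :])
        r0 = num0 / (num0 + (1.0 - qc) * (1.0 - f_wild[None, :]))

        dom_alt = a * r1
        dom_ref = b * r0
        q = (dom_alt + dom_ref).sum(axis=1) / (2.0 * g.shape[1])
        dom_total = dom_alt.sum(axis=0) + dom_ref.sum(axis=0)
        wild_alt = (a * (1.0 - r1)).sum(axis=0)
        wild_total = wild_alt + (b * (1.0 - r0)).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            f_dom = np.where(dom_total > 0, dom_alt.sum(axis=0) / dom_total, 0.5)
            f_wild = np.where(wild_total > 0, wild_alt / wild_total, 0.5)

        q = np.clip(q, EPS, 1.0 - EPS)
        f_dom = np.clip(f_dom, EPS, 1.0 - EPS)
        f_wild = np.clip(f_wild, EPS, 1.0 - EPS)

        ll = admixture_loglik(g, q, f_dom, f_wild)
        history.append(ll)
        if ll < prev - 1e-8:  # EM guarantees monotonicity up to clipping noise
            warnings.warn(f"log-likelihood decreased at iteration {it} ({prev} -> {ll})")
        if ll - prev < tol and it > 1:
            converged = True
            break
        prev = ll
    return q, f_dom, f_wild, np.asarray(history), it, converged


def estimate_admixture_k2(
    G: GenotypeMatrix,
    tol: float = 1e-4,
    max_iter: int = 2000,
    seed: int = 0,
    n_restarts: int = 5,
) -> AncestryEstimate:
    """Fit the K=2 admixture model by multi-start EM.

    Requires an imputed (no-missing) matrix containing both wild-lake and
    domestic-reference individuals. Returns per-individual domestic ancestry
    fractions with labels anchored by the domestic reference panel. When the
    two estimated frequency vectors are (near) identical, q is meaningless
    and the estimate is flagged ``q_defined=False``.
    """
    g = np.asarray(G.genotypes, dtype=float)
    if (g == MISSING).any():
        raise ValueError("genotype matrix contains missing calls; impute first")
    roles = np.asarray(G.roles)
    if ROLE_DOMESTIC not in roles or ROLE_WILD not in roles:
        raise ValueError("both wild and domestic-reference individuals are required")

    n, m = g.shape
    ss = np.random.SeedSequence(seed)
    best = None
    for child in ss.spawn(max(1, n_restarts)):
        rng = np.random.default_rng(child)
        q0 = rng.uniform(0.2, 0.8, size=n)
        # perturb the empirical frequencies so restarts explore distinct basins
        emp = g.mean(axis=0) / 2.0
        f_d0 = np.clip(emp + rng.uniform(-0.2, 0.2, size=m), EPS, 1 - EPS)
        f_w0 = np.clip(emp + rng.uniform(-0.2, 0.2, size=m), EPS, 1 - EPS)
        run = _em_run(g, q0, f_d0, f_w0, tol, max_iter)
        if best is None or run[3][-1] > best[3][-1]:
            best = run
    q, f_dom, f_wild, history, n_iter, converged = best

    # anchor: the "domestic" cluster is the one the hatchery panel loads on
    dom_rows = roles == ROLE_DOMESTIC
    if q[dom_rows].mean() < 0.5:
        q = 1.0 - q
        f_dom, f_wild = f_wild, f_dom

    # identifiability: with two truly divergent source populations, ancestry
    # signal accumulates across loci, so q estimated from disjoint locus
    # subsets must agree; when the sources are identical the two half-panel
    # estimates are independent noise and decorrelate.
    q_defined = True
    if m >= 40:
        halves = []
        for offset in (0, 1):
            rng = np.random.default_rng(np.random.SeedSequence((seed, 7, offset)))
            sub = g[:, offset::2]
            q0 = rng.uniform(0.2, 0.8, size=n)
            emp = sub.mean(axis=0) / 2.0
            f0 = np.clip(emp + rng.uniform(-0.2, 0.2, size=sub.shape[1]), EPS, 1 - EPS)
            f1 = np.clip(emp + rng.uniform(-0.2, 0.2, size=sub.shape[1]), EPS, 1 - EPS)
            qh = _em_run(sub, q0, f0, f1, tol, min(max_iter, 300))[0]
            if qh[dom_rows].mean() < 0.5:
                qh = 1.0 - qh
            halves.append(qh)
        if np.std(halves[0]) < 1e-8 or np.std(halves[1]) < 1e-8:
            split_corr = 0.0
        else:
            split_corr = float(np.corrcoef(halves[0], halves[1])[0, 1])
        if split_corr < IDENTIFIABILITY_MIN_CORRELATION:
            warnings.warn(
                "ancestry fractions estimated from disjoint locus subsets do "
                "not agree (split-half r = "
                f"{split_corr:.2f}); the two source populations are too "
                "similar and q is unidentifiable"
            )
            q_defined = False

    return AncestryEstimate(
        q=q,
        f_domestic=f_dom,
        f_wild=f_wild,
        loglik=float(history[-1]),
        loglik_history=history,
        n_iter=n_iter,
        converged=converged,
        q_defined=q_defined,
        individual_ids=list(G.individual_ids),
        roles=list(G.roles),
        populations=list(G.populations),
    )


def classify_individual(q: float) -> str:
    """Wild (q <= 0.1), domestic (q >= 0.9) or admixed (in between)."""
    if not 0.0 <= q <= 1.0:
        raise ValueError(f"ancestry fraction outside [0, 1]: {q}")
    if q <= 0.1:
        return "wild"
    if q >= 0.9:
        return "domestic"
    return "admixed"


def summarize_lake(est: AncestryEstimate, lake_id: str | None = None) -> LakeSummary:
    """Mean and SD of q over wild-caught individuals (hatchery panel excluded).

    SD uses the n-1 denominator. The classification tally covers the same
    individuals.
    """
    roles = np.asarray(est.roles)
    wild_rows = roles == ROLE_WILD
    if not wild_rows.any():
        raise ValueError("no wild-caught individuals to summarize")
    if lake_id is None:
        pops = {est.populations[i] for i in np.flatnonzero(wild_rows)}
        lake_id = pops.pop() if len(pops) == 1 else "+".join(sorted(pops))
    qs = est.q[wild_rows]
    counts = {"wild": 0, "admixed": 0, "domestic": 0}
    for value in qs:
        counts[classify_individual(float(value))] += 1
    sd = float(np.std(qs, ddof=1)) if qs.size > 1 else 0.0
    return LakeSummary(
        lake_id=lake_id,
        mean_q=float(np.mean(qs)),
        sd_q=sd,
        n_individuals=int(qs.size),
        type_counts=counts,
    )


def ancestry_table(est: AncestryEstimate) -> pd.DataFrame:
    """Per-individual q and classification, ready to write as CSV."""
    return pd.DataFrame(
        {
            "individual_id": est.individual_ids,
            "population": est.populations,
            "role": est.roles,
            "q_domestic": est.q,
            "class": [classify_individual(float(v)) for v in est.q],
        }
    )
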