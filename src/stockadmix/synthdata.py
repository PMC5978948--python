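"""Synthetic genotype and lake-covariate generators with known truth.

Two generators mirror the two data layers of the analysis:

* :func:`generate_genotypes` draws admixed diploid genotypes from a
  two-population binomial model — a wild lake population and a divergent
  domestic hatchery strain — with each individual's true domestic ancestry
  fraction ``q`` known, so the admixture estimator can be scored against
  truth.
* :func:`generate_lake_table` draws a lake covariate table whose mean
  domestic membership response follows a beta distribution around a logistic
  function of standardized predictors, i.e. exactly the data-generating
  process the beta-regression stage assumes.

Defaults emulate the study's sampling design: ~30 wild fish per lake plus a
domestic reference panel, thousands of SNPs after filtering, 29 lakes, and
per-lake mean domestic membership concentrated below ~0.3.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .datasets import PREDICTOR_RANGES, PREDICTOR_VARIABLES
from .genotypes import MISSING, ROLE_DOMESTIC, ROLE_WILD, GenotypeMatrix

#: Default mixture of true ancestry fractions: half the wild-caught fish are
#: pure wild (q = 0), the rest carry a modest domestic fraction (Beta(1, 6),
#: mean ~0.14) — reproducing lake-level means in the observed 0–0.3 range.
DEFAULT_Q_DISTRIBUTION = (("point", 0.0, 0.5), ("beta", 1.0, 6.0, 0.5))


@dataclass
class GenotypeScenario:
    """Sampling design for one synthetic lake + domestic reference pair.

    ``divergence`` in [0, 1] sets the mean absolute allele-frequency
    difference between the wild and domestic source populations: 0 makes the
    populations identical (ancestry unidentifiable, the negative control),
    1 makes every locus a fixed difference.

    ``q_distribution`` is a tuple of mixture components, each either
    ``("point", value, weight)`` or ``("beta", a, b, weight)``, from which
    wild-caught individuals' true domestic ancestry fractions are drawn.
    """

    n_wild: int = 30
    n_domestic_ref: int = 30
    n_loci: int = 1000
    divergence: float = 0.5
    q_distribution: tuple = DEFAULT_Q_DISTRIBUTION
    missing_rate: float = 0.05
    seed: int = 0
    lake_id: str = "SIM"

    def __post_init__(self) -> None:
        for name in ("n_wild", "n_domestic_ref", "n_loci"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.divergence <= 1.0:
            raise ValueError("divergence must be in [0, 1]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        for comp in self.q_distribution:
            kind = comp[0]
            if kind == "point":
                _, value, _ = comp
                if not 0.0 <= value <= 1.0:
                    raise ValueError(f"point-mass q outside [0, 1]: {value}")
            elif kind == "beta":
                _, a, b, _ = comp
                if a <= 0 or b <= 0:
                    raise ValueError("beta component needs positive shapes")
            else:
                raise ValueError(f"unknown q_distribution component {kind!r}")


def _draw_q(scenario: GenotypeScenario, rng: np.random.Generator) -> np.ndarray:
    weights = np.array([comp[-1] for comp in scenario.q_distribution], dtype=float)
    weights = weights / weights.sum()
    which = rng.choice(len(weights), size=scenario.n_wild, p=weights)
    q = np.empty(scenario.n_wild)
    for k, comp in enumerate(scenario.q_distribution):
        rows = which == k
        if comp[0] == "point":
            q[rows] = comp[1]
        else:
            q[rows] = rng.beta(comp[1], comp[2], size=rows.sum())
    return q


def source_frequencies(
    n_loci: int, divergence: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Wild and domestic allele-frequency vectors at the given divergence.

    An ancestral frequency p0 ~ U(0.1, 0.9) is shrunk toward 0 for the wild
    population and shifted toward 1 for the domestic one so that
    |p_d - p_w| = divergence at every locus: divergence 0 gives identical
    vectors, divergence 1 gives fixed differences (p_w = 0, p_d = 1).
    """
    p0 = rng.uniform(0.1, 0.9, size=n_loci)
    p_wild = p0 * (1.0 - divergence)
    p_dom = p_wild + divergence
    return p_wild, p_dom


def generate_genotypes(scenario: GenotypeScenario) -> tuple[GenotypeMatrix, np.ndarray]:
    """Draw one admixed genotype matrix; returns it with the true q vector.

    Genotypes are Binomial(2, q·p_d + (1-q)·p_w) per individual x locus;
    domestic reference individuals have q = 1; missing calls are injected
    uniformly at ``missing_rate``.
    """
    rng = np.random.default_rng(scenario.seed)
    p_wild, p_dom = source_frequencies(scenario.n_loci, scenario.divergence, rng)
    q_wild = _draw_q(scenario, rng)
    q = np.concatenate([q_wild, np.ones(scenario.n_domestic_ref)])

    p_ind = q[:, None] * p_dom[None, :] + (1.0 - q[:, None]) * p_wild[None, :]
    g = rng.binomial(2, p_ind).astype(np.int16)
    if scenario.missing_rate > 0:
        mask = rng.random(g.shape) < scenario.missing_rate
        g[mask] = MISSING

    n_total = scenario.n_wild + scenario.n_domestic_ref
    ids = [f"{scenario.lake_id}_{i:03d}" for i in range(scenario.n_wild)]
    ids += [f"DOM_{i:03d}" for i in range(scenario.n_domestic_ref)]
    populations = [scenario.lake_id] * scenario.n_wild + ["DOM"] * scenario.n_domestic_ref
    roles = [ROLE_WILD] * scenario.n_wild + [ROLE_DOMESTIC] * scenario.n_domestic_ref
    matrix = GenotypeMatrix(
        genotypes=g,
        individual_ids=ids,
        populations=populations,
        roles=roles,
        locus_ids=[f"L{j:06d}" for j in range(scenario.n_loci)],
        snp_positions=np.zeros(scenario.n_loci, dtype=np.int64),
        chrom=["1"] * scenario.n_loci,
        pos=np.arange(1, scenario.n_loci + 1, dtype=np.int64),
    )
    assert matrix.n_individuals == n_total
    return matrix, q


# ---------------------------------------------------------------------------
# Lake covariate tables


@dataclass
class LakeScenario:
    """Data-generating process for a lake covariate table.

    ``coefficients`` maps standardized predictor terms (main effects from
    the nine-variable dictionary, interactions written ``"A:B"``) to effect
    sizes on the logit scale; ``intercept`` is the logit of the grand-mean
    domestic membership; ``precision`` is the beta precision φ (response
    variance μ(1-μ)/(1+φ)). Predictor marginals are Beta(2, 2) scaled to
    ``predictor_ranges``; optional pairwise correlations are induced via a
    Gaussian copula.
    """

    n_lakes: int = 29
    coefficients: dict[str, float] = field(
        default_factory=lambda: {"SinceMeanYear": -0.44, "MeanFishStock": 0.30}
    )
    intercept: float = -2.4  # inv-logit ~= 0.083, a typical lake mean
    precision: float = 20.0
    predictor_ranges: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(PREDICTOR_RANGES)
    )
    predictor_correlations: dict[tuple[str, str], float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.precision <= 0:
            raise ValueError("precision must be positive")
        known = set(self.predictor_ranges)
        for term in self.coefficients:
            for var in term.split(":"):
                if var not in known:
                    raise ValueError(f"unknown predictor {var!r} in term {term!r}")
        for (a, b), rho in self.predictor_correlations.items():
            if a not in known or b not in known:
                raise ValueError(f"correlation names unknown predictor: {(a, b)}")
            if not -1.0 < rho < 1.0:
                raise ValueError(f"correlation target outside (-1, 1): {rho}")
        for var, rng_ in self.predictor_ranges.items():
            if rng_[0] >= rng_[1]:
                raise ValueError(f"range of {var} has min >= max")
        n_terms = len(self.coefficients)
        if self.n_lakes < n_terms + 2:
            raise ValueError("n_lakes must be at least number of model terms + 2")


def _copula_correlation(scenario: LakeScenario, variables: list[str]) -> np.ndarray:
    k = len(variables)
    corr = np.eye(k)
    index = {v: i for i, v in enumerate(variables)}
    for (a, b), rho in scenario.predictor_correlations.items():
        i, j = index[a], index[b]
        corr[i, j] = corr[j, i] = rho
    # nudge to positive definite if the user-declared targets conflict
    w, v = np.linalg.eigh(corr)
    if w.min() <= 1e-8:
        w = np.clip(w, 1e-6, None)
        corr = v @ np.diag(w) @ v.T
        d = np.sqrt(np.diag(corr))
        corr = corr / np.outer(d, d)
    return corr


def generate_lake_table(scenario: LakeScenario) -> pd.DataFrame:
    """Draw a lake table with columns for all nine predictors plus qDomestic.

    The response is Beta(μφ, (1-μ)φ) with logit μ linear in the sample-
    standardized predictors; interaction columns are products of
    standardized main effects. Responses are strictly inside (0, 1).
    """
    rng = np.random.default_rng(scenario.seed)
    variables = [v for v in PREDICTOR_VARIABLES if v in scenario.predictor_ranges]
    corr = _copula_correlation(scenario, variables)
    z = rng.multivariate_normal(np.zeros(len(variables)), corr, size=scenario.n_lakes)
    u = stats.norm.cdf(z)
    table = {}
    for k, var in enumerate(variables):
        lo, hi = scenario.predictor_ranges[var][:2]
        table[var] = lo + (hi - lo) * stats.beta.ppf(u[:, k], 2.0, 2.0)
    df = pd.DataFrame(table)

    std = (df - df.mean()) / df.std(ddof=1)
    eta = np.full(scenario.n_lakes, scenario.intercept)
    for term, beta in scenario.coefficients.items():
        vars_ = term.split(":")
        col = np.ones(scenario.n_lakes)
        for v in vars_:
            col = col * std[v].to_numpy()
        eta += beta * col
    mu = expit(eta)
    y = rng.beta(mu * scenario.precision, (1.0 - mu) * scenario.precision)
    eps = 1e-12
    y = np.clip(y, eps, 1.0 - eps)  # guard against float underflow at the ends

    df.insert(0, "lake", [f"SL{i + 1:02d}" for i in range(scenario.n_lakes)])
    df["qDomestic"] = y
    return df
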