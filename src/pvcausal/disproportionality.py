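"""Classical pharmacovigilance signal statistics: PRR, ROR, EBGM/EB05.

Each term x endpoint 2x2 table counts a (term & positive), b (term &
negative), c (no term & positive), d (no term & negative), restricted to
reports whose feature is observed — the same cohort the do-calculus
partition uses, so the two analyses are head-to-head comparable.

Signal rules follow the standard cut-offs: PRR >= 2 with chi-square >= 4 and
at least 3 co-occurrences; ROR with the lower 95% two-sided confidence limit
above 1; EBGM with EB05 (lower one-sided 95% limit of the empirical-Bayes
geometric mean) at or above 2.  EBGM uses the gamma-Poisson shrinker:
a ~ Poisson(lambda * E) with E from the table margins, lambda drawn from a
two-component gamma mixture whose hyperparameters maximize the marginal
(negative-binomial mixture) likelihood.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import brentq, minimize
from scipy.special import digamma, gammaln
from scipy.stats import gamma as gamma_dist

from .data_model import CaseReport, FeatureSchema
from .preprocess import EndpointLabel, label_endpoint

__all__ = [
    "ContingencyTable",
    "SignalScore",
    "EBGMPrior",
    "build_contingency",
    "prr",
    "ror",
    "ebgm_fit",
    "ebgm_fit_counts",
    "ebgm_score",
    "compare_methods",
]


@dataclass(frozen=True)
class ContingencyTable:
    a: int  # term present, endpoint positive
    b: int  # term present, endpoint negative
    c: int  # term absent (feature observed), endpoint positive
    d: int  # term absent (feature observed), endpoint negative

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def expected(self) -> float:
        """Expected co-occurrence count under row/column independence."""
        if self.n == 0:
            return 0.0
        return (self.a + self.b) * (self.a + self.c) / self.n


@dataclass(frozen=True)
class SignalScore:
    term: str
    feature: str
    method: str  # PRR | ROR | EBGM
    score: float
    is_signal: bool
    chi2: float | None = None
    ci_low: float | None = None
    eb05: float | None = None


def build_contingency(
    reports: Sequence[CaseReport],
    term: str,
    feature: str,
    schema: FeatureSchema,
) -> ContingencyTable:
    """Count the term x endpoint table over observed-feature, labeled reports."""
    if term not in schema.vocab[feature]:
        raise ValueError(f"term {term!r} not in vocabulary of feature {feature!r}")
    a = b = c = d = 0
    for r in reports:
        label = label_endpoint(r, schema)
        if label is EndpointLabel.EXCLUDED:
            continue
        terms = r.terms(feature)
        if not terms:
            continue
        pos = label is EndpointLabel.POSITIVE
        if term in terms:
            a, b = (a + 1, b) if pos else (a, b + 1)
        else:
            c, d = (c + 1, d) if pos else (c, d + 1)
    return ContingencyTable(a=a, b=b, c=c, d=d)


def _chi2_pearson(t: ContingencyTable, yates: bool = False) -> float:
    a, b, c, d = t.a, t.b, t.c, t.d
    n = t.n
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        return 0.0
    diff = abs(a * d - b * c)
    if yates:
        diff = max(0.0, diff - n / 2)
    return n * diff * diff / denom


def prr(
    t: ContingencyTable, term: str = "", feature: str = "", yates: bool = False
) -> SignalScore:
    """Proportional reporting ratio with its Pearson chi-square.

    Signal rule: a >= 3, PRR >= 2 and chi-square >= 4.  A zero not-do
    positive count gives an infinite PRR sentinel; the remaining criteria
    still gate the signal.
    """
    if t.a + t.b == 0 or t.c + t.d == 0:
        raise ValueError("PRR requires nonempty term and no-term cohorts")
    rate_do = t.a / (t.a + t.b)
    if t.c == 0:
        score = math.inf if rate_do > 0 else 1.0
    else:
        score = rate_do / (t.c / (t.c + t.d))
    chi2 = _chi2_pearson(t, yates=yates)
    return SignalScore(
        term=term,
        feature=feature,
        method="PRR",
        score=score,
        chi2=chi2,
        is_signal=(t.a >= 3) and (score >= 2) and (chi2 >= 4),
    )


def ror(t: ContingencyTable, term: str = "", feature: str = "") -> SignalScore:
    """Reporting odds ratio with a log-normal 95% confidence interval.

    Any zero cell triggers the Haldane-Anscombe correction (+0.5 to every
    cell).  Signal rule: lower confidence limit above 1.
    """
    a, b, c, d = (float(x) for x in (t.a, t.b, t.c, t.d))
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    score = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    ci_low = math.exp(math.log(score) - 1.96 * se)
    return SignalScore(
        term=term,
        feature=feature,
        method="ROR",
        score=score,
        ci_low=ci_low,
        is_signal=ci_low > 1.0,
    )


# ---------------------------------------------------------------------------
# EBGM: DuMouchel's gamma-Poisson shrinker
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EBGMPrior:
    """Two-component gamma mixture prior on the reporting-rate multiplier."""

    alpha1: float
    beta1: float
    alpha2: float
    beta2: float
    p: float  # mixture weight of component 1
    loglik: float = math.nan


def _nb_loglik(a: np.ndarray, E: np.ndarray, alpha: float, beta: float) -> np.ndarray:
    """log P(a | E) when lambda ~ Gamma(alpha, rate beta): negative binomial."""
    return (
        gammaln(alpha + a)
        - gammaln(alpha)
        - gammaln(a + 1)
        + alpha * (np.log(beta) - np.log(beta + E))
        + a * (np.log(E) - np.log(beta + E))
    )


def _mixture_loglik(theta: np.ndarray, a: np.ndarray, E: np.ndarray) -> float:
    la1, lb1, la2, lb2, logit_p = theta
    p = 1.0 / (1.0 + math.exp(-logit_p))
    l1 = _nb_loglik(a, E, math.exp(la1), math.exp(lb1)) + math.log(p)
    l2 = _nb_loglik(a, E, math.exp(la2), math.exp(lb2)) + math.log1p(-p)
    m = np.maximum(l1, l2)
    return float(np.sum(m + np.log(np.exp(l1 - m) + np.exp(l2 - m))))


def ebgm_fit(
    tables: Sequence[ContingencyTable],
    seed: int = 0,
    n_starts: int = 5,
) -> EBGMPrior:
    """Maximum-marginal-likelihood fit of the gamma-mixture hyperparameters.

    Expected counts come from each table's margins (independence model).
    Multi-start bounded quasi-Newton (L-BFGS-B) on log-parameterized shapes
    and rates and the logit mixture weight; the best of ``n_starts`` seeded
    starts is returned with its log-likelihood.
    """
    if len(tables) < 20:
        raise ValueError("EBGM fitting needs at least 20 tables")
    a = np.array([t.a for t in tables], dtype=float)
    E = np.array([max(t.expected, 1e-10) for t in tables], dtype=float)
    return ebgm_fit_counts(a, E, seed=seed, n_starts=n_starts)


def ebgm_fit_counts(
    a: np.ndarray, E: np.ndarray, seed: int = 0, n_starts: int = 5
) -> EBGMPrior:
    """Fit the shrinker directly from observed and expected counts."""
    a = np.asarray(a, dtype=float)
    E = np.asarray(E, dtype=float)
    rng = np.random.default_rng(seed)
    bounds = [(-7, 7)] * 4 + [(-7, 7)]
    starts = [np.array([0.0, 0.0, math.log(0.2), math.log(0.2), 0.0])]
    for _ in range(n_starts - 1):
        starts.append(rng.uniform(-2, 2, size=5))
    best = None
    diagnostics = []
    for x0 in starts:
        res = minimize(
            lambda th: -_mixture_loglik(th, a, E),
            x0,
            method="L-BFGS-B",
            bounds=bounds,
        )
        diagnostics.append((res.success, res.fun, res.message))
        if res.success and (best is None or res.fun < best.fun):
            best = res
    if best is None:
        raise RuntimeError(f"EBGM hyperparameter optimization failed: {diagnostics}")
    la1, lb1, la2, lb2, logit_p = best.x
    return EBGMPrior(
        alpha1=math.exp(la1),
        beta1=math.exp(lb1),
        alpha2=math.exp(la2),
        beta2=math.exp(lb2),
        p=1.0 / (1.0 + math.exp(-logit_p)),
        loglik=-float(best.fun),
    )


def _posterior(t: ContingencyTable, prior: EBGMPrior):
    """Posterior mixture over lambda given the observed count: weights and
    updated gamma (shape, rate) pairs."""
    a = float(t.a)
    E = max(t.expected, 1e-10)
    l1 = _nb_loglik(np.array([a]), np.array([E]), prior.alpha1, prior.beta1)[0]
    l2 = _nb_loglik(np.array([a]), np.array([E]), prior.alpha2, prior.beta2)[0]
    w1 = math.log(prior.p) + l1
    w2 = math.log1p(-prior.p) + l2
    m = max(w1, w2)
    q1 = math.exp(w1 - m) / (math.exp(w1 - m) + math.exp(w2 - m))
    return (
        (q1, prior.alpha1 + a, prior.beta1 + E),
        (1.0 - q1, prior.alpha2 + a, prior.beta2 + E),
    )


def ebgm_score(
    t: ContingencyTable, prior: EBGMPrior, term: str = "", feature: str = ""
) -> SignalScore:
    """EBGM = exp(E[ln lambda | a]) and EB05, the posterior 5th percentile.

    The posterior is the closed-form two-component gamma mixture; EB05 is
    found by root-finding on its CDF.  Signal rule: EB05 >= 2.
    """
    comps = _posterior(t, prior)
    mean_log = sum(q * (digamma(shape) - math.log(rate)) for q, shape, rate in comps)
    ebgm = math.exp(mean_log)

    def cdf(x: float) -> float:
        return sum(
            q * gamma_dist.cdf(x, shape, scale=1.0 / rate) for q, shape, rate in comps
        )

    lo, hi = 1e-12, 1.0
    while cdf(hi) < 0.05:
        hi *= 2.0
        if hi > 1e9:  # pragma: no cover - defensive
            break
    eb05 = float(brentq(lambda x: cdf(x) - 0.05, lo, hi, xtol=1e-12, rtol=1e-12))
    return SignalScore(
        term=term,
        feature=feature,
        method="EBGM",
        score=ebgm,
        eb05=eb05,
        is_signal=eb05 >= 2.0,
    )


def compare_methods(
    causal_terms: Sequence[str],
    prr_signals: dict[str, bool],
    ror_signals: dict[str, bool],
    ebgm_signals: dict[str, bool],
) -> dict:
    """Overlap report between the do-calculus enriched set and the three
    conventional signal sets, all over one shared term universe.

    ``causal_terms`` lists the enriched term keys; each ``*_signals`` maps
    every term of the universe to its signal flag.
    """
    universe = set(prr_signals)
    if set(ror_signals) != universe or set(ebgm_signals) != universe:
        raise ValueError("signal dictionaries cover different term universes")
    unknown = set(causal_terms) - universe
    if unknown:
        raise ValueError(f"causal terms outside the shared universe: {sorted(unknown)}")
    sets = {
        "do_calculus": set(causal_terms),
        "PRR": {t for t, s in prr_signals.items() if s},
        "ROR": {t for t, s in ror_signals.items() if s},
        "EBGM": {t for t, s in ebgm_signals.items() if s},
    }
    methods = list(sets)
    pairwise = {
        f"{m1} & {m2}": sorted(sets[m1] & sets[m2])
        for i, m1 in enumerate(methods)
        for m2 in methods[i + 1 :]
    }
    return {
        "universe_size": len(universe),
        "counts": {m: len(s) for m, s in sets.items()},
        "sets": {m: sorted(s) for m, s in sets.items()},
        "pairwise_intersections": pairwise,
        "four_way_intersection": sorted(
            sets["do_calculus"] & sets["PRR"] & sets["ROR"] & sets["EBGM"]
        ),
    }
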