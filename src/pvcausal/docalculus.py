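"""Interventional probing of a fitted endpoint classifier.

For every term t of every non-endpoint clinical feature, reports are split
into the "do" stratum L1 (reports containing t) and the "not-do" stratum L2
(reports whose feature is observed but lacks t); reports with the feature
missing enter neither.  The classifier's predicted positive-endpoint
probabilities of the two strata are compared with a one-tailed two-sample
z-test (alternative: the do-mean exceeds the not-do mean), and terms whose
multiplicity-adjusted p falls below alpha form the enriched causal-term set.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.stats import norm

from .data_model import CaseReport, FeatureSchema, ProbabilityTable

__all__ = [
    "TermPartition",
    "CausalTerm",
    "InferenceResult",
    "partition_by_term",
    "ztest_one_tailed",
    "adjust_pvalues",
    "infer_causes",
]

logger = logging.getLogger(__name__)

DEFAULT_MIN_GROUP_SIZE = 30


@dataclass
class TermPartition:
    """Do / not-do strata of predicted probabilities for one term."""

    feature: str
    term: str
    l1_ids: list[str]
    l2_ids: list[str]
    l1: np.ndarray  # probabilities of reports containing the term
    l2: np.ndarray  # probabilities of observed-feature reports lacking it

    def __post_init__(self) -> None:
        if set(self.l1_ids) & set(self.l2_ids):
            raise ValueError("do and not-do strata overlap")


@dataclass(frozen=True)
class CausalTerm:
    """An enriched term with its test statistics and group summaries."""

    feature: str
    term: str
    z: float
    p_raw: float
    p_adj: float
    mean_do: float
    mean_notdo: float
    n1: int
    n2: int

    def __post_init__(self) -> None:
        if self.p_adj < self.p_raw - 1e-12:
            raise ValueError("adjusted p cannot be below raw p")

    @property
    def key(self) -> str:
        return f"{self.feature}:{self.term}"


def partition_by_term(
    reports: Sequence[CaseReport],
    probs: ProbabilityTable,
    feature: str,
    term: str,
    schema: FeatureSchema,
) -> TermPartition:
    """Split predicted probabilities into the do/not-do strata of one term.

    Reports with the feature missing (empty term set) are excluded from both
    strata; only reports present in ``probs`` participate.
    """
    if term not in schema.vocab[feature]:
        raise ValueError(f"term {term!r} not in vocabulary of feature {feature!r}")
    if feature == schema.endpoint_feature:
        raise ValueError("cannot probe the endpoint feature itself")
    l1_ids, l2_ids, l1, l2 = [], [], [], []
    for r in reports:
        if r.report_id not in probs:
            continue
        terms = r.terms(feature)
        if not terms:
            continue
        if term in terms:
            l1_ids.append(r.report_id)
            l1.append(probs[r.report_id])
        else:
            l2_ids.append(r.report_id)
            l2.append(probs[r.report_id])
    return TermPartition(
        feature=feature,
        term=term,
        l1_ids=l1_ids,
        l2_ids=l2_ids,
        l1=np.asarray(l1, dtype=float),
        l2=np.asarray(l2, dtype=float),
    )


def ztest_one_tailed(
    l1: Sequence[float], l2: Sequence[float], pooled: bool = False
) -> tuple[float, float]:
    """Upper-tailed two-sample z-test on probability means.

    z = (mean(L1) - mean(L2)) / sqrt(s1^2/n1 + s2^2/n2) with unbiased sample
    variances (Welch form); ``pooled=True`` substitutes the pooled variance
    for sensitivity analysis.  p is the upper-tail standard-normal
    probability (alternative: mean_do > mean_notdo).

    Degenerate zero-variance strata: equal means give (0, 0.5); unequal means
    give a signed infinite sentinel, (+inf, 0) when the do-mean is larger and
    (-inf, 1) when it is smaller.
    """
    a = np.asarray(l1, dtype=float)
    b = np.asarray(l2, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each stratum needs at least two observations")
    # exactly-constant strata short-circuit before the variance estimate:
    # summing n identical floats perturbs the mean at machine precision, which
    # would otherwise turn 0/0 into an arbitrary large ratio
    if a.min() == a.max() and b.min() == b.max():
        if a[0] == b[0]:
            return 0.0, 0.5
        return (math.inf, 0.0) if a[0] > b[0] else (-math.inf, 1.0)
    d = a.mean() - b.mean()
    if pooled:
        sp2 = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / (
            a.size + b.size - 2
        )
        se2 = sp2 * (1.0 / a.size + 1.0 / b.size)
    else:
        se2 = a.var(ddof=1) / a.size + b.var(ddof=1) / b.size
    if se2 == 0.0:  # pragma: no cover - caught by the constant check above
        if d == 0.0:
            return 0.0, 0.5
        return (math.inf, 0.0) if d > 0 else (-math.inf, 1.0)
    z = d / math.sqrt(se2)
    return float(z), float(norm.sf(z))


def adjust_pvalues(
    p_list: Sequence[float], method: Literal["bonferroni", "bh"] = "bonferroni"
) -> list[float]:
    """Multiplicity adjustment over one run's whole family of tested terms."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p_list, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    name = {"bonferroni": "bonferroni", "bh": "fdr_bh"}[method]
    return multipletests(p, method=name)[1].tolist()


@dataclass
class InferenceResult:
    """Outcome of one do-calculus enrichment run.

    ``enriched`` is the causal-term set L (p_adj < alpha, sorted by z
    descending, alphabetical on ties); ``tested`` holds every term that met
    the group-size requirement; ``root_causes`` maps each feature to its
    highest-z enriched term; ``skipped`` records untestable terms and why.
    """

    enriched: list[CausalTerm]
    tested: list[CausalTerm]
    root_causes: dict[str, CausalTerm]
    skipped: list[tuple[str, str, str]] = field(default_factory=list)
    alpha: float = 0.05

    def ranked_keys(self) -> list[str]:
        return [t.key for t in self.enriched]


def _sort_terms(terms: list[CausalTerm]) -> list[CausalTerm]:
    return sorted(terms, key=lambda t: (-t.z, t.feature, t.term))


def infer_causes(
    reports: Sequence[CaseReport],
    probs: ProbabilityTable,
    schema: FeatureSchema,
    alpha: float = 0.05,
    min_group_size: int = DEFAULT_MIN_GROUP_SIZE,
    adjust: Literal["bonferroni", "bh"] = "bonferroni",
    pooled: bool = False,
    features: Sequence[str] | None = None,
) -> InferenceResult:
    """Probe every term of every non-endpoint feature; return the enriched set.

    The multiple-testing family is all terms tested in this run, across all
    features.  ``features`` restricts probing to a subset of non-endpoint
    features (used by the recursive tree construction to skip features
    already fixed on the path).
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    probe = list(features) if features is not None else list(schema.non_endpoint_features)
    bad = [f for f in probe if f == schema.endpoint_feature or f not in schema.features]
    if bad:
        raise ValueError(f"cannot probe features {bad}")

    stats: list[tuple[TermPartition, float, float]] = []
    skipped: list[tuple[str, str, str]] = []
    for feature in probe:
        for term in sorted(schema.vocab[feature]):
            part = partition_by_term(reports, probs, feature, term, schema)
            n1, n2 = len(part.l1), len(part.l2)
            if n1 < min_group_size or n2 < min_group_size:
                reason = f"group sizes {n1}/{n2} below minimum {min_group_size}"
                logger.info("skipping %s:%s — %s", feature, term, reason)
                skipped.append((feature, term, reason))
                continue
            z, p = ztest_one_tailed(part.l1, part.l2, pooled=pooled)
            stats.append((part, z, p))

    if not stats:
        logger.warning("no testable terms; enriched set is empty")
        return InferenceResult(
            enriched=[], tested=[], root_causes={}, skipped=skipped, alpha=alpha
        )

    p_adj = adjust_pvalues([p for _, _, p in stats], method=adjust)
    tested = [
        CausalTerm(
            feature=part.feature,
            term=part.term,
            z=z,
            p_raw=p,
            p_adj=pa,
            mean_do=float(part.l1.mean()),
            mean_notdo=float(part.l2.mean()),
            n1=len(part.l1),
            n2=len(part.l2),
        )
        for (part, z, p), pa in zip(stats, p_adj)
    ]
    enriched = _sort_terms([t for t in tested if t.p_adj < alpha])
    root_causes: dict[str, CausalTerm] = {}
    for t in enriched:  # already z-descending, so first hit per feature wins
        root_causes.setdefault(t.feature, t)
    return InferenceResult(
        enriched=enriched,
        tested=_sort_terms(tested),
        root_causes=root_causes,
        skipped=skipped,
        alpha=alpha,
    )
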