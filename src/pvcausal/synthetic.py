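"""Synthetic adverse-event case reports with planted causal structure.

Reports mimic spontaneous-report extracts: M categorical clinical features
with small term vocabularies, optional multi-valued features, missing
values, and a binary endpoint drawn from a logistic model over planted
causal terms.  One interaction effect is active only inside a parent-term
stratum, giving the causal tree a known second-level edge to recover.

The default configuration defines the package's reference study conditions:
n = 5,000 reports over a seven-feature schema (gender, age group, primary
suspect drug, dose class, indication, adverse events, outcomes), a main
effect of +2.0 log-odds on the primary suspect drug APAP (prevalence 0.3),
a main effect of +1.5 on the high-dose class, and a +1.5 interaction for
female patients within the APAP stratum.  Every feature keeps zero-effect
terms as negative controls.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .data_model import CaseReport, FeatureSchema

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "default_schema",
    "default_config",
    "null_schema",
    "null_config",
    "generate_cases",
    "ground_truth",
]

TermKey = tuple[str, str]  # (feature, term)


def default_schema() -> FeatureSchema:
    """Seven-feature schema shaped like a cleaned spontaneous-report extract."""
    return FeatureSchema(
        features=(
            "gender",
            "age",
            "primary suspect drug",
            "dose",
            "indication",
            "adverse events",
            "outcomes",
        ),
        vocab={
            "gender": frozenset({"male", "female"}),
            "age": frozenset({"<18", "18-39", "40-64", "65+"}),
            "primary suspect drug": frozenset(
                {"APAP", "tramadol", "ibuprofen", "oxycodone", "naproxen"}
            ),
            "dose": frozenset({"less than 100 mg", "larger than 100 mg"}),
            "indication": frozenset(
                {"pain", "fever", "arthritis", "depression", "insomnia"}
            ),
            "adverse events": frozenset(
                {"nausea", "vomiting", "headache", "dizziness", "rash", "somnolence"}
            ),
            "outcomes": frozenset(
                {"death", "recovered", "hospitalization", "disability"}
            ),
        },
        endpoint_feature="outcomes",
        endpoint_term="death",
        multi_valued=frozenset({"adverse events"}),
    )


@dataclass(frozen=True)
class GroundTruth:
    """Planted causal structure: main-effect terms and conditional pairs."""

    causal_terms: frozenset[TermKey]
    causal_pairs: frozenset[tuple[TermKey, TermKey]]


@dataclass
class GeneratorConfig:
    """Sampling model for synthetic case reports.

    ``term_prevalences[feature][term]`` are marginal probabilities: for
    single-valued features they are normalized into one categorical draw,
    for multi-valued features each term is included independently.
    ``effects`` are log-odds contributions of present terms to the endpoint;
    ``interaction_effects`` add extra log-odds only when both members of the
    (parent, child) pair are present.
    """

    n_reports: int
    schema: FeatureSchema
    term_prevalences: Mapping[str, Mapping[str, float]]
    missing_rates: Mapping[str, float] = field(default_factory=dict)
    effects: Mapping[TermKey, float] = field(default_factory=dict)
    interaction_effects: Mapping[tuple[TermKey, TermKey], float] = field(
        default_factory=dict
    )
    intercept: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for feature, prevs in self.term_prevalences.items():
            for term, p in prevs.items():
                if not 0.0 < p < 1.0:
                    raise ValueError(
                        f"prevalence of {feature}:{term} must lie in (0, 1), got {p}"
                    )
        for feature in self.schema.non_endpoint_features:
            terms = self.schema.vocab[feature]
            if all(self.effects.get((feature, t), 0.0) != 0.0 for t in terms):
                raise ValueError(
                    f"feature {feature!r} needs at least one zero-effect term "
                    "as a negative control"
                )


def default_config(n_reports: int = 5000, seed: int = 0) -> GeneratorConfig:
    """Reference study conditions with planted main and interaction effects."""
    schema = default_schema()
    prevalences = {
        "gender": {"male": 0.5, "female": 0.5},
        "age": {"<18": 0.1, "18-39": 0.35, "40-64": 0.35, "65+": 0.2},
        "primary suspect drug": {
            "APAP": 0.3,
            "tramadol": 0.175,
            "ibuprofen": 0.175,
            "oxycodone": 0.175,
            "naproxen": 0.175,
        },
        "dose": {"less than 100 mg": 0.6, "larger than 100 mg": 0.4},
        "indication": {
            "pain": 0.4,
            "fever": 0.15,
            "arthritis": 0.15,
            "depression": 0.15,
            "insomnia": 0.15,
        },
        "adverse events": {
            "nausea": 0.3,
            "vomiting": 0.2,
            "headache": 0.2,
            "dizziness": 0.15,
            "rash": 0.1,
            "somnolence": 0.1,
        },
        "outcomes": {
            "recovered": 0.5,
            "hospitalization": 0.3,
            "disability": 0.2,
        },
    }
    return GeneratorConfig(
        n_reports=n_reports,
        schema=schema,
        term_prevalences=prevalences,
        missing_rates={
            "gender": 0.05,
            "age": 0.05,
            "dose": 0.10,
            "indication": 0.10,
            "outcomes": 0.0,
        },
        effects={
            ("primary suspect drug", "APAP"): 2.0,
            ("dose", "larger than 100 mg"): 1.5,
        },
        interaction_effects={
            (("primary suspect drug", "APAP"), ("gender", "female")): 1.5,
        },
        intercept=-1.5,
        seed=seed,
    )


def null_schema() -> FeatureSchema:
    """Six non-endpoint features x five terms each (30 probe terms)."""
    return FeatureSchema(
        features=(
            "primary suspect drug",
            "concomitant drug",
            "indication",
            "adverse events",
            "country",
            "reporter",
            "outcomes",
        ),
        vocab={
            "primary suspect drug": frozenset(
                {"APAP", "tramadol", "ibuprofen", "oxycodone", "naproxen"}
            ),
            "concomitant drug": frozenset(
                {"aspirin", "warfarin", "metformin", "lisinopril", "omeprazole"}
            ),
            "indication": frozenset(
                {"pain", "fever", "arthritis", "depression", "insomnia"}
            ),
            "adverse events": frozenset(
                {"nausea", "vomiting", "headache", "dizziness", "rash"}
            ),
            "country": frozenset({"US", "UK", "France", "Japan", "Canada"}),
            "reporter": frozenset(
                {"physician", "pharmacist", "consumer", "nurse", "other"}
            ),
            "outcomes": frozenset({"death", "recovered"}),
        },
        endpoint_feature="outcomes",
        endpoint_term="death",
        multi_valued=frozenset({"adverse events"}),
    )


def null_config(n_reports: int = 3000, seed: int = 0) -> GeneratorConfig:
    """No planted effects: the endpoint is an unbiased coin, independent of
    every feature.  Used for type-I-error calibration studies."""
    schema = null_schema()
    prevalences = {
        f: {t: 1.0 / len(schema.vocab[f]) for t in schema.vocab[f]}
        for f in schema.non_endpoint_features
    }
    prevalences["adverse events"] = {
        t: 0.3 for t in schema.vocab["adverse events"]
    }
    prevalences["outcomes"] = {"recovered": 1.0 - 1e-9}  # negatives all recover
    return GeneratorConfig(
        n_reports=n_reports,
        schema=schema,
        term_prevalences=prevalences,
        missing_rates={},
        effects={},
        interaction_effects={},
        intercept=0.0,
        seed=seed,
    )


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * x))


def generate_cases(config: GeneratorConfig) -> list[CaseReport]:
    """Sample case reports and write the endpoint into the endpoint feature.

    Single-valued features draw one term from the normalized prevalences;
    multi-valued features include each term independently; missingness then
    empties the feature.  The endpoint is Bernoulli(logistic(intercept +
    sum of present-term effects + active interactions)); positives carry the
    endpoint term, negatives draw another term of the endpoint feature.
    """
    rng = np.random.default_rng(config.seed)
    schema = config.schema
    n = config.n_reports
    reports: list[CaseReport] = []
    values_per_report: list[dict[str, set[str]]] = []

    for feature in schema.non_endpoint_features:
        prevs = config.term_prevalences[feature]
        terms = sorted(prevs)
        miss = config.missing_rates.get(feature, 0.0)
        missing_mask = rng.random(n) < miss
        if feature in schema.multi_valued:
            include = rng.random((n, len(terms))) < np.array([prevs[t] for t in terms])
            col = [
                set() if missing_mask[i] else {t for j, t in enumerate(terms) if include[i, j]}
                for i in range(n)
            ]
        else:
            w = np.array([prevs[t] for t in terms], dtype=float)
            w /= w.sum()
            picks = rng.choice(len(terms), size=n, p=w)
            col = [
                set() if missing_mask[i] else {terms[picks[i]]} for i in range(n)
            ]
        if not values_per_report:
            values_per_report = [{} for _ in range(n)]
        for i in range(n):
            values_per_report[i][feature] = col[i]

    # endpoint from the logistic model over the sampled terms
    logit = np.full(n, config.intercept, dtype=float)
    for i, values in enumerate(values_per_report):
        for (feature, term), eff in config.effects.items():
            if term in values.get(feature, ()):
                logit[i] += eff
        for ((f1, t1), (f2, t2)), eff in config.interaction_effects.items():
            if t1 in values.get(f1, ()) and t2 in values.get(f2, ()):
                logit[i] += eff
    positive = rng.random(n) < _sigmoid(logit)

    ef = schema.endpoint_feature
    neg_prevs = {
        t: p
        for t, p in config.term_prevalences.get(ef, {}).items()
        if t != schema.endpoint_term
    }
    neg_terms = sorted(neg_prevs)
    if neg_terms:
        w = np.array([neg_prevs[t] for t in neg_terms], dtype=float)
        w /= w.sum()
        neg_picks = rng.choice(len(neg_terms), size=n, p=w)
    miss_ep = rng.random(n) < config.missing_rates.get(ef, 0.0)
    for i in range(n):
        if miss_ep[i]:
            endpoint: set[str] = set()
        elif positive[i]:
            endpoint = {schema.endpoint_term}
        elif neg_terms:
            endpoint = {neg_terms[neg_picks[i]]}
        else:  # degenerate vocabulary: only the endpoint term exists
            endpoint = set()
        values_per_report[i][ef] = endpoint
        reports.append(CaseReport(report_id=f"r{i:06d}", values=values_per_report[i]))
    return reports


def ground_truth(config: GeneratorConfig) -> GroundTruth:
    """Read the planted structure off the configuration (seed-invariant)."""
    return GroundTruth(
        causal_terms=frozenset(k for k, v in config.effects.items() if v != 0.0),
        causal_pairs=frozenset(
            k for k, v in config.interaction_effects.items() if v != 0.0
        ),
    )
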