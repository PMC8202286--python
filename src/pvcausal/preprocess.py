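"""Cleaning, endpoint labeling, sentence templating, splitting, summaries.

The cleaning rules mirror standard spontaneous-report practice: tokens such
as "UNK"/"UNKNOWN"/"()" are missing values; doses are unified to milligrams
and dichotomized at 100 mg; ages fall into four groups (<18, 18-39, 40-64,
65+).  Each cleaned report is rendered into one template sentence

    Patient (gender and age) takes a primary suspect drug to treat which
    disease and cause some adverse events, leading to outcomes.

and labeled by the presence of the endpoint term.  To keep the label out of
the classifier's input, the endpoint term is excised from the rendered text
(adverse-event endpoints) or the whole outcomes clause is dropped (outcome
endpoints).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .data_model import CaseReport, FeatureSchema, SentenceRecord, SplitDataset

__all__ = [
    "MISSING",
    "PreprocessConfig",
    "EndpointLabel",
    "normalize_missing",
    "normalize_report",
    "convert_dose_to_mg",
    "categorize_dose",
    "categorize_age",
    "label_endpoint",
    "generate_sentence",
    "generate_sentences",
    "stratified_split",
    "dataset_summary",
    "tfidf_top_terms",
    "DatasetSummary",
]

#: Sentinel for a missing (empty) feature value.
MISSING = None

DOSE_CLASSES = ("less than 100 mg", "larger than 100 mg")
AGE_CLASSES = ("<18", "18-39", "40-64", "65+")

#: Unit -> multiplier into milligrams; unknown units yield a missing dose.
DEFAULT_DOSE_UNITS = {"mg": 1.0, "g": 1000.0, "ug": 0.001, "µg": 0.001, "mcg": 0.001}


@dataclass(frozen=True)
class PreprocessConfig:
    missing_tokens: frozenset[str] = frozenset({"unk", "unknown", "()"})
    dose_threshold_mg: float = 100.0
    age_bins: tuple[float, ...] = (18.0, 40.0, 65.0)
    split_ratios: tuple[float, float, float] = (0.64, 0.16, 0.20)
    seed: int = 0
    dose_units: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DOSE_UNITS)
    )

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "missing_tokens", frozenset(t.lower() for t in self.missing_tokens)
        )
        if any(r <= 0 for r in self.split_ratios):
            raise ValueError("split ratios must be positive")
        if abs(sum(self.split_ratios) - 1.0) > 1e-9:
            raise ValueError("split ratios must sum to 1")
        if list(self.age_bins) != sorted(set(self.age_bins)):
            raise ValueError("age bins must be strictly increasing")


class EndpointLabel(enum.Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"
    EXCLUDED = "excluded"


def normalize_missing(raw: str, config: PreprocessConfig | None = None):
    """Map placeholder tokens ("UNK", "UNKNOWN", "()", blanks) to :data:`MISSING`.

    Any other input is returned trimmed.
    """
    config = config or PreprocessConfig()
    term = raw.strip()
    if not term or term.lower() in config.missing_tokens:
        return MISSING
    return term


def normalize_report(
    report: CaseReport, config: PreprocessConfig | None = None
) -> CaseReport:
    """Apply :func:`normalize_missing` to every term of every feature."""
    config = config or PreprocessConfig()
    values: dict[str, set[str]] = {}
    for feature, terms in report.values.items():
        kept = {t for t in (normalize_missing(raw, config) for raw in terms) if t is not MISSING}
        values[feature] = kept
    return CaseReport(report_id=report.report_id, values=values)


def convert_dose_to_mg(
    value: float, unit: str, config: PreprocessConfig | None = None
) -> float | None:
    """Unify a dose to milligrams; an unknown unit yields a missing dose."""
    config = config or PreprocessConfig()
    factor = config.dose_units.get(unit.strip().lower())
    if factor is None:
        return MISSING
    return value * factor


def categorize_dose(dose_mg: float, config: PreprocessConfig | None = None) -> str:
    """Dichotomize a milligram dose at the threshold (strictly above -> large).

    Exactly 100 mg falls in the "less than 100 mg" class: the large class is
    defined by a strict inequality.
    """
    config = config or PreprocessConfig()
    if dose_mg < 0:
        raise ValueError(f"negative dose {dose_mg}")
    return DOSE_CLASSES[1] if dose_mg > config.dose_threshold_mg else DOSE_CLASSES[0]


def categorize_age(age_years: float, config: PreprocessConfig | None = None) -> str:
    """Assign age to <18 / 18-39 / 40-64 / 65+ (65 goes to the oldest bin)."""
    config = config or PreprocessConfig()
    if age_years < 0:
        raise ValueError(f"negative age {age_years}")
    idx = int(np.searchsorted(config.age_bins, age_years, side="right"))
    return AGE_CLASSES[idx]


def label_endpoint(report: CaseReport, schema: FeatureSchema) -> EndpointLabel:
    """POSITIVE if the endpoint term is present, EXCLUDED if the endpoint
    feature is missing, NEGATIVE otherwise."""
    if schema.endpoint_feature not in schema.features:  # pragma: no cover - schema enforces
        raise ValueError("schema lacks an endpoint feature")
    terms = report.terms(schema.endpoint_feature)
    if not terms:
        return EndpointLabel.EXCLUDED
    if schema.endpoint_term in terms:
        return EndpointLabel.POSITIVE
    return EndpointLabel.NEGATIVE


_PLACEHOLDER = "unknown"


def _slot(report: CaseReport, feature: str, exclude: set[str] = frozenset()) -> str:
    terms = sorted(report.terms(feature) - set(exclude))
    if not terms:
        return _PLACEHOLDER
    return " and ".join(terms)


def generate_sentence(report: CaseReport, schema: FeatureSchema) -> SentenceRecord:
    """Render one report into the fixed clinical template sentence.

    The endpoint never leaks into the text: if the endpoint lives in the
    adverse-events feature only that term is excised; if it lives in the
    outcomes feature the entire trailing clause is dropped.
    """
    label = label_endpoint(report, schema)
    if label is EndpointLabel.EXCLUDED:
        raise ValueError(
            f"report {report.report_id} has no endpoint information; "
            "excluded reports cannot be rendered"
        )
    exclude_ae: set[str] = set()
    drop_outcomes = schema.endpoint_feature == "outcomes"
    if schema.endpoint_feature == "adverse events":
        exclude_ae = {schema.endpoint_term}

    parts = [
        "Patient",
        _slot(report, "gender"),
        _slot(report, "age"),
        "takes",
        _slot(report, "primary suspect drug"),
        "at dose",
        _slot(report, "dose"),
        "to treat",
        _slot(report, "indication"),
        "and cause",
        _slot(report, "adverse events", exclude=exclude_ae),
    ]
    text = " ".join(p for p in parts if p)
    if not drop_outcomes and "outcomes" in schema.features:
        text += ", leading to " + _slot(report, "outcomes")
    return SentenceRecord(
        report_id=report.report_id,
        text=text,
        label=1 if label is EndpointLabel.POSITIVE else 0,
    )


def generate_sentences(
    reports: Iterable[CaseReport], schema: FeatureSchema
) -> list[SentenceRecord]:
    """Render every non-excluded report; excluded reports are dropped."""
    out = []
    for r in reports:
        if label_endpoint(r, schema) is EndpointLabel.EXCLUDED:
            continue
        out.append(generate_sentence(r, schema))
    return out


def _allocate(n: int, ratios: Sequence[float]) -> list[int]:
    """Largest-remainder allocation of n items over ratios (remainders go to
    the earliest split, i.e. train first)."""
    raw = [n * r for r in ratios]
    counts = [math.floor(x) for x in raw]
    remainder = n - sum(counts)
    order = sorted(range(len(ratios)), key=lambda i: (-(raw[i] - counts[i]), i))
    for i in order[:remainder]:
        counts[i] += 1
    return counts


def stratified_split(
    records: Sequence[SentenceRecord],
    ratios: tuple[float, float, float] = (0.64, 0.16, 0.20),
    seed: int = 0,
) -> SplitDataset:
    """Class-stratified train/dev/test split with a seeded per-class shuffle.

    Per-class counts follow a floor allocation with largest-remainder
    correction, so class totals are conserved exactly and each split's
    positive fraction tracks the global one.
    """
    if any(r <= 0 for r in ratios):
        raise ValueError("split ratios must be positive")
    pos = [r for r in records if r.label == 1]
    neg = [r for r in records if r.label == 0]
    if not pos or not neg:
        raise ValueError("stratified split needs at least one record per class")
    rng = np.random.default_rng(seed)
    parts: list[list[SentenceRecord]] = [[], [], []]
    for cls in (pos, neg):
        idx = rng.permutation(len(cls))
        shuffled = [cls[i] for i in idx]
        counts = _allocate(len(cls), ratios)
        start = 0
        for part, c in zip(parts, counts):
            part.extend(shuffled[start : start + c])
            start += c
    return SplitDataset(train=parts[0], dev=parts[1], test=parts[2])


@dataclass(frozen=True)
class DatasetSummary:
    n_pos: int
    n_neg: int
    pos_neg_ratio: float | None  # rounded to 2 d.p.; None when n_neg == 0
    mean_length: float
    sd_length: float


def dataset_summary(records: Sequence[SentenceRecord]) -> DatasetSummary:
    """Counts, positive/negative ratio (2 d.p.), and whitespace-token
    sequence-length mean and SD over the rendered sentences."""
    if not records:
        raise ValueError("empty record set")
    n_pos = sum(r.label for r in records)
    n_neg = len(records) - n_pos
    ratio = round(n_pos / n_neg, 2) if n_neg else None
    lengths = np.array([len(r.text.split()) for r in records], dtype=float)
    sd = float(lengths.std(ddof=1)) if len(lengths) > 1 else 0.0
    return DatasetSummary(
        n_pos=n_pos,
        n_neg=n_neg,
        pos_neg_ratio=ratio,
        mean_length=float(lengths.mean()),
        sd_length=sd,
    )


def tfidf_matrix(records: Sequence[SentenceRecord]):
    """Per-document tf-idf matrix and its term vocabulary.

    Dialect: smoothed idf ``log((1+N)/(1+df)) + 1`` with L2 document
    normalization (scikit-learn's default).
    """
    from sklearn.feature_extraction.text import TfidfVectorizer

    if not records:
        raise ValueError("empty corpus")
    vec = TfidfVectorizer(norm="l2", smooth_idf=True, sublinear_tf=False)
    mat = vec.fit_transform([r.text for r in records])
    return vec.get_feature_names_out(), mat


def tfidf_top_terms(
    records: Sequence[SentenceRecord], k: int
) -> list[tuple[str, float]]:
    """Top-k corpus terms by tf-idf score averaged over all documents,
    ties broken alphabetically."""
    if k <= 0:
        raise ValueError("k must be positive")
    terms, mat = tfidf_matrix(records)
    scores = np.asarray(mat.mean(axis=0)).ravel()
    order = sorted(range(len(terms)), key=lambda i: (-scores[i], terms[i]))
    return [(terms[i], float(scores[i])) for i in order[:k]]
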