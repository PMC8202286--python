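"""Shared domain types and tabular I/O for adverse-event case reports.

A case report is a bag of categorical clinical features (gender, age group,
primary suspect drug, ...); each feature holds a *set* of terms, and an empty
set means the feature is missing for that report.  Reports are rendered into
template sentences, classified, and causally probed downstream; everything in
this module is format plumbing and invariant enforcement.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

__all__ = [
    "FeatureSchema",
    "CaseReport",
    "SentenceRecord",
    "ProbabilityTable",
    "SplitDataset",
    "read_case_reports",
    "write_case_reports",
    "write_sentences",
    "read_sentences",
    "write_results",
    "read_results",
]


@dataclass(frozen=True)
class FeatureSchema:
    """Names the clinical features, their term vocabularies, and the endpoint.

    Parameters
    ----------
    features
        Ordered feature names (the M clinical features).
    vocab
        Mapping feature name -> admissible terms for that feature.
    endpoint_feature
        The feature whose content defines the binary endpoint.
    endpoint_term
        The term whose presence in ``endpoint_feature`` makes a report
        endpoint-positive (e.g. ``"death"`` in ``"outcomes"``).
    multi_valued
        Features that may carry several terms per report (e.g. adverse
        events); all others carry at most one.
    """

    features: tuple[str, ...]
    vocab: Mapping[str, frozenset[str]]
    endpoint_feature: str
    endpoint_term: str
    multi_valued: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "features", tuple(self.features))
        object.__setattr__(
            self, "vocab", {f: frozenset(t) for f, t in self.vocab.items()}
        )
        object.__setattr__(self, "multi_valued", frozenset(self.multi_valued))
        if len(set(self.features)) != len(self.features):
            raise ValueError("feature names must be unique")
        if self.endpoint_feature not in self.features:
            raise ValueError(
                f"endpoint feature {self.endpoint_feature!r} not in schema"
            )
        missing = [f for f in self.features if f not in self.vocab]
        if missing:
            raise ValueError(f"features without vocabulary: {missing}")
        if self.endpoint_term not in self.vocab[self.endpoint_feature]:
            raise ValueError(
                f"endpoint term {self.endpoint_term!r} not in vocabulary of "
                f"{self.endpoint_feature!r}"
            )

    @property
    def non_endpoint_features(self) -> tuple[str, ...]:
        return tuple(f for f in self.features if f != self.endpoint_feature)


@dataclass
class CaseReport:
    """One adverse-event report: feature name -> set of terms (empty = missing)."""

    report_id: str
    values: dict[str, set[str]]

    def terms(self, feature: str) -> set[str]:
        return self.values.get(feature, set())


@dataclass(frozen=True)
class SentenceRecord:
    """A report rendered as a template sentence plus its binary endpoint label."""

    report_id: str
    text: str
    label: int

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label!r}")
        if not self.text:
            raise ValueError("sentence text must be non-empty")


class ProbabilityTable(Mapping[str, float]):
    """Per-report predicted probability that the endpoint is positive."""

    def __init__(self, probs: Mapping[str, float]):
        bad = {k: v for k, v in probs.items() if not 0.0 <= v <= 1.0}
        if bad:
            raise ValueError(f"probabilities outside [0, 1]: {bad}")
        self._probs = dict(probs)

    def __getitem__(self, report_id: str) -> float:
        return self._probs[report_id]

    def __iter__(self) -> Iterator[str]:
        return iter(self._probs)

    def __len__(self) -> int:
        return len(self._probs)

    def __repr__(self) -> str:
        return f"ProbabilityTable({len(self)} reports)"


@dataclass
class SplitDataset:
    """Stratified train/dev/test partition of labeled sentence records."""

    train: list[SentenceRecord]
    dev: list[SentenceRecord]
    test: list[SentenceRecord]

    def __post_init__(self) -> None:
        ids = [r.report_id for part in (self.train, self.dev, self.test) for r in part]
        if len(set(ids)) != len(ids):
            raise ValueError("splits share report ids")

    @property
    def all_records(self) -> list[SentenceRecord]:
        return [*self.train, *self.dev, *self.test]


# ---------------------------------------------------------------------------
# Case-report I/O.  CSV: one column per feature, multi-valued cells joined by
# a delimiter.  JSONL: one object per line, lists for multi-valued features.
# Raw cell strings pass through verbatim; missing-token normalization is a
# separate preprocessing step so the loaded data stays inspectable.
# ---------------------------------------------------------------------------


def _split_cell(raw: str, delimiter: str) -> set[str]:
    if raw == "":
        return {""}
    return {part for part in raw.split(delimiter)}


def read_case_reports(
    path,
    schema: FeatureSchema,
    format: str = "csv",
    delimiter: str = "|",
    id_column: str = "report_id",
) -> list[CaseReport]:
    """Load one :class:`CaseReport` per row/line of a CSV or JSONL file.

    Unknown columns trigger a warning and are ignored; a row that cannot be
    parsed raises an error naming its line number; duplicate report ids are
    rejected.
    """
    if format not in ("csv", "jsonl"):
        raise ValueError(f"unsupported format {format!r}")
    reports: list[CaseReport] = []
    seen: set[str] = set()
    if format == "csv":
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            header = reader.fieldnames or []
            unknown = [c for c in header if c != id_column and c not in schema.features]
            if unknown:
                warnings.warn(f"ignoring unknown columns {unknown}", stacklevel=2)
            absent = [f for f in schema.features if f not in header]
            if absent:
                raise ValueError(f"missing feature columns {absent} in {path}")
            for lineno, row in enumerate(reader, start=2):
                try:
                    rid = row[id_column]
                    values = {
                        f: _split_cell(row[f] if row[f] is not None else "", delimiter)
                        for f in schema.features
                    }
                except (KeyError, AttributeError) as exc:
                    raise ValueError(f"unreadable row at line {lineno} of {path}") from exc
                _check_duplicate(rid, seen, lineno)
                reports.append(CaseReport(report_id=rid, values=values))
    else:
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                try:
                    obj = json.loads(line)
                    rid = obj[id_column]
                except (json.JSONDecodeError, KeyError) as exc:
                    raise ValueError(f"unreadable row at line {lineno} of {path}") from exc
                unknown = [
                    k for k in obj if k != id_column and k not in schema.features
                ]
                if unknown:
                    warnings.warn(f"ignoring unknown keys {unknown}", stacklevel=2)
                values: dict[str, set[str]] = {}
                for f in schema.features:
                    raw = obj.get(f, "")
                    if isinstance(raw, list):
                        values[f] = set(raw)
                    else:
                        values[f] = {str(raw)}
                _check_duplicate(rid, seen, lineno)
                reports.append(CaseReport(report_id=rid, values=values))
    return reports


def _check_duplicate(rid: str, seen: set[str], lineno: int) -> None:
    if rid in seen:
        raise ValueError(f"duplicate report id {rid!r} at line {lineno}")
    seen.add(rid)


def write_case_reports(
    reports: Iterable[CaseReport],
    path,
    schema: FeatureSchema,
    format: str = "csv",
    delimiter: str = "|",
    id_column: str = "report_id",
) -> None:
    """Inverse of :func:`read_case_reports`; ``read(write(x)) == x``."""
    reports = list(reports)
    if format == "csv":
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow([id_column, *schema.features])
            for r in reports:
                row = [r.report_id]
                for f in schema.features:
                    terms = sorted(r.terms(f))
                    row.append(delimiter.join(terms))
                writer.writerow(row)
    elif format == "jsonl":
        with open(path, "w", encoding="utf-8") as fh:
            for r in reports:
                obj: dict = {id_column: r.report_id}
                for f in schema.features:
                    obj[f] = sorted(r.terms(f))
                fh.write(json.dumps(obj) + "\n")
    else:
        raise ValueError(f"unsupported format {format!r}")


def write_sentences(records: Iterable[SentenceRecord], path) -> None:
    """Three-column TSV: report_id, rendered text, binary label."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("report_id\ttext\tlabel\n")
        for r in records:
            fh.write(f"{r.report_id}\t{r.text}\t{r.label}\n")


def read_sentences(path) -> list[SentenceRecord]:
    with open(path, encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        return [
            SentenceRecord(row["report_id"], row["text"], int(row["label"]))
            for row in reader
        ]


# ---------------------------------------------------------------------------
# Enriched-term result I/O (TSV for the terminal, JSON for round-trips).
# ---------------------------------------------------------------------------

_RESULT_COLUMNS = (
    "feature",
    "term",
    "z",
    "p_raw",
    "p_adj",
    "mean_do",
    "mean_notdo",
    "n1",
    "n2",
)


def write_results(terms, path, format: str = "tsv") -> None:
    """Serialize a list of enriched causal terms (TSV or JSON)."""
    if format == "tsv":
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("\t".join(_RESULT_COLUMNS) + "\n")
            for t in terms:
                fh.write(
                    "\t".join(
                        repr(getattr(t, c)) if c in ("z", "p_raw", "p_adj", "mean_do", "mean_notdo")
                        else str(getattr(t, c))
                        for c in _RESULT_COLUMNS
                    )
                    + "\n"
                )
    elif format == "json":
        with open(path, "w", encoding="utf-8") as fh:
            json.dump([{c: getattr(t, c) for c in _RESULT_COLUMNS} for t in terms], fh)
    else:
        raise ValueError(f"unsupported format {format!r}")


def read_results(path, format: str = "tsv"):
    """Read back what :func:`write_results` wrote, losslessly."""
    from .docalculus import CausalTerm  # local import to avoid a cycle

    def build(d: dict) -> CausalTerm:
        return CausalTerm(
            feature=d["feature"],
            term=d["term"],
            z=float(d["z"]),
            p_raw=float(d["p_raw"]),
            p_adj=float(d["p_adj"]),
            mean_do=float(d["mean_do"]),
            mean_notdo=float(d["mean_notdo"]),
            n1=int(d["n1"]),
            n2=int(d["n2"]),
        )

    if format == "tsv":
        with open(path, encoding="utf-8") as fh:
            reader = csv.DictReader(fh, delimiter="\t")
            return [build(row) for row in reader]
    elif format == "json":
        with open(path, encoding="utf-8") as fh:
            return [build(d) for d in json.load(fh)]
    raise ValueError(f"unsupported format {format!r}")
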