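"""Run-to-run reproducibility of the enriched causal-term set.

Repeated pipeline runs under different seeds give ranked term lists (by z,
descending).  Two metrics summarize their agreement: the average percentage
of terms common to all runs relative to each run's size, and the
percentage-of-overlapped-terms (POT) curve, the prefix-intersection size at
each rank k divided by k.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .classifier import ClassifierConfig, predict_proba, train_classifier
from .data_model import CaseReport, FeatureSchema, SplitDataset
from .docalculus import DEFAULT_MIN_GROUP_SIZE, infer_causes

__all__ = [
    "RunCollection",
    "average_pct_enriched",
    "pot_curve",
    "repeat_runs",
    "venn_counts",
]


@dataclass
class RunCollection:
    """Ranked enriched-term lists from T repeated runs (z high to low)."""

    runs: list[list[str]]

    def __post_init__(self) -> None:
        if len(self.runs) < 2:
            raise ValueError("need at least two runs")
        for i, run in enumerate(self.runs):
            if len(set(run)) != len(run):
                raise ValueError(f"run {i} contains duplicate terms")

    @property
    def T(self) -> int:
        return len(self.runs)


def average_pct_enriched(runs: RunCollection | Sequence[Sequence[str]]) -> float:
    """Mean over runs of |common terms| / |run|, as a percentage.

    "Common" means present in every run; 100 iff all runs are set-equal.
    """
    lists = runs.runs if isinstance(runs, RunCollection) else [list(r) for r in runs]
    if any(not r for r in lists):
        raise ValueError("every run must be nonempty")
    common = set(lists[0])
    for r in lists[1:]:
        common &= set(r)
    return 100.0 * sum(len(common) / len(r) for r in lists) / len(lists)


def pot_curve(
    runs: RunCollection | Sequence[Sequence[str]],
) -> list[tuple[int, float]]:
    """POT(k) = |intersection of every run's top-k prefix| / k, k = 1..min length."""
    lists = runs.runs if isinstance(runs, RunCollection) else [list(r) for r in runs]
    kmax = min(len(r) for r in lists)
    curve = []
    for k in range(1, kmax + 1):
        inter = set(lists[0][:k])
        for r in lists[1:]:
            inter &= set(r[:k])
        curve.append((k, len(inter) / k))
    return curve


def repeat_runs(
    split: SplitDataset,
    reports: Sequence[CaseReport],
    schema: FeatureSchema,
    config: ClassifierConfig,
    seeds: Sequence[int],
    alpha: float = 0.05,
    min_group_size: int = DEFAULT_MIN_GROUP_SIZE,
    adjust: str = "bonferroni",
) -> RunCollection:
    """Re-run train -> predict -> enrich once per seed, all else fixed.

    Each run reseeds only the classifier; the data and split stay fixed, so
    differences between runs isolate training stochasticity.  Rankings break
    z-ties alphabetically, making the POT curve well defined.
    """
    if len(seeds) < 2:
        raise ValueError("need at least two seeds")
    runs = []
    for seed in seeds:
        cfg = ClassifierConfig(**{**config.__dict__, "seed": int(seed)})
        try:
            model, _ = train_classifier(split.train, split.dev, cfg)
            probs = predict_proba(model, split.all_records)
            result = infer_causes(
                reports, probs, schema,
                alpha=alpha, min_group_size=min_group_size, adjust=adjust,
            )
        except Exception as exc:
            raise RuntimeError(f"repeated run with seed {seed} failed") from exc
        runs.append(result.ranked_keys())
    return RunCollection(runs=runs)


def venn_counts(runs: RunCollection | Sequence[Sequence[str]]) -> dict[str, int]:
    """Seven-region Venn tally for exactly three runs (plot-ready)."""
    lists = runs.runs if isinstance(runs, RunCollection) else [list(r) for r in runs]
    if len(lists) != 3:
        raise ValueError("Venn tally is defined for exactly three runs")
    A, B, C = (set(r) for r in lists)
    return {
        "A_only": len(A - B - C),
        "B_only": len(B - A - C),
        "C_only": len(C - A - B),
        "AB_only": len((A & B) - C),
        "AC_only": len((A & C) - B),
        "BC_only": len((B & C) - A),
        "ABC": len(A & B & C),
    }
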