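"""Hierarchical causal tree by recursive do-calculus within do-strata.

The root level holds the single globally highest-z enriched term.  For each
node, the analysis restricts to the stratum of reports containing every term
fixed on the path, re-runs the enrichment over the remaining features, and
pools candidate children across the level's parents; at tree level N at most
N nodes are retained, chosen by descending z.  Recursion stops at the depth
cap, at an empty enrichment, or at an undersized stratum.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Literal, Sequence

from .data_model import CaseReport, FeatureSchema, ProbabilityTable
from .docalculus import (
    DEFAULT_MIN_GROUP_SIZE,
    CausalTerm,
    infer_causes,
)

__all__ = [
    "CausalTreeNode",
    "infer_secondary_causes",
    "build_causal_tree",
    "export_tree",
    "tree_from_json",
]

logger = logging.getLogger(__name__)


@dataclass
class CausalTreeNode:
    """One node of the causal tree; the virtual root has term=None, depth=0."""

    term: str | None
    feature: str | None
    z: float | None
    p_adj: float | None
    depth: int
    children: list["CausalTreeNode"] = field(default_factory=list)

    @property
    def is_root(self) -> bool:
        return self.term is None

    def node_count(self) -> int:
        """Number of real (non-virtual) nodes in the subtree."""
        n = 0 if self.is_root else 1
        return n + sum(c.node_count() for c in self.children)

    def to_dict(self) -> dict:
        return {
            "term": self.term,
            "feature": self.feature,
            "z": self.z,
            "p_adj": self.p_adj,
            "depth": self.depth,
            "children": [c.to_dict() for c in self.children],
        }


def _stratum(
    reports: Sequence[CaseReport], parent_terms: Sequence[tuple[str, str]]
) -> list[CaseReport]:
    out = []
    for r in reports:
        if all(term in r.terms(feature) for feature, term in parent_terms):
            out.append(r)
    return out


def infer_secondary_causes(
    reports: Sequence[CaseReport],
    probs: ProbabilityTable,
    schema: FeatureSchema,
    parent_terms: Sequence[tuple[str, str]],
    alpha: float = 0.05,
    min_group_size: int = DEFAULT_MIN_GROUP_SIZE,
    adjust: str = "bonferroni",
) -> list[CausalTerm]:
    """Enriched terms within the stratum of reports fixing all parent terms.

    With an empty parent list this reduces exactly to the whole-dataset
    enrichment.  Features already fixed on the path are not re-tested
    (conditioning a feature on itself is degenerate).  A stratum smaller than
    twice the minimum group size cannot produce two testable groups and
    yields an empty list.
    """
    stratum = _stratum(reports, parent_terms)
    if len(stratum) < 2 * min_group_size:
        logger.info(
            "stratum %s too small (%d reports); no secondary causes",
            parent_terms,
            len(stratum),
        )
        return []
    fixed = {feature for feature, _ in parent_terms}
    features = [f for f in schema.non_endpoint_features if f not in fixed]
    result = infer_causes(
        stratum,
        probs,
        schema,
        alpha=alpha,
        min_group_size=min_group_size,
        adjust=adjust,
        features=features,
    )
    return result.enriched


def build_causal_tree(
    reports: Sequence[CaseReport],
    probs: ProbabilityTable,
    schema: FeatureSchema,
    alpha: float = 0.05,
    max_depth: int = 4,
    min_group_size: int = DEFAULT_MIN_GROUP_SIZE,
    adjust: str = "bonferroni",
    per_feature_roots: bool = False,
) -> CausalTreeNode:
    """Grow the causal tree from a virtual root.

    Level 1 is the single highest-z enriched term (or, with
    ``per_feature_roots``, one root per feature's top enriched term); level
    N retains at most N nodes, ranked by z across all of the level's
    parents.  Every retained node records the z and adjusted p of its test
    within the parent stratum.
    """
    root = CausalTreeNode(term=None, feature=None, z=None, p_adj=None, depth=0)
    base = infer_causes(
        reports, probs, schema, alpha=alpha, min_group_size=min_group_size, adjust=adjust
    )
    if not base.enriched:
        return root
    if per_feature_roots:
        # Table-style alternative: one root per feature (its top enriched term)
        level_terms = sorted(base.root_causes.values(), key=lambda t: (-t.z, t.feature))
    else:
        level_terms = [base.enriched[0]]
    paths: list[tuple[CausalTreeNode, list[tuple[str, str]]]] = []
    for t in level_terms:
        node = CausalTreeNode(term=t.term, feature=t.feature, z=t.z, p_adj=t.p_adj, depth=1)
        root.children.append(node)
        paths.append((node, [(t.feature, t.term)]))

    depth = 1
    while depth < max_depth and paths:
        candidates: list[tuple[CausalTerm, CausalTreeNode, list[tuple[str, str]]]] = []
        for node, path in paths:
            for t in infer_secondary_causes(
                reports, probs, schema, path,
                alpha=alpha, min_group_size=min_group_size, adjust=adjust,
            ):
                candidates.append((t, node, path))
        if not candidates:
            break
        depth += 1
        candidates.sort(key=lambda c: (-c[0].z, c[0].feature, c[0].term))
        retained = candidates[:depth]  # level-N cap: at most N nodes
        paths = []
        for t, parent, path in retained:
            child = CausalTreeNode(
                term=t.term, feature=t.feature, z=t.z, p_adj=t.p_adj, depth=depth
            )
            parent.children.append(child)
            paths.append((child, path + [(t.feature, t.term)]))
    return root


def export_tree(
    tree: CausalTreeNode, path, format: Literal["json", "dot"] = "json"
) -> None:
    """Write the tree as nested JSON (lossless) or a z-labeled DOT digraph."""
    if format == "json":
        with open(path, "w", encoding="utf-8") as fh:
            json.dump({} if not tree.children and tree.is_root else tree.to_dict(), fh, indent=2)
    elif format == "dot":
        lines = ["digraph causal_tree {"]
        counter = [0]

        def walk(node: CausalTreeNode, parent_id: str | None) -> None:
            if node.is_root:
                nid = "root"
                lines.append('  root [label="endpoint"];')
            else:
                counter[0] += 1
                nid = f"n{counter[0]}"
                lines.append(f'  {nid} [label="{node.feature}: {node.term}"];')
                if parent_id is not None:
                    lines.append(f'  {parent_id} -> {nid} [label="z={node.z:.2f}"];')
            for c in node.children:
                walk(c, nid)

        walk(tree, None)
        lines.append("}")
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unsupported format {format!r}")


def tree_from_json(path) -> CausalTreeNode:
    """Read back a JSON tree written by :func:`export_tree`."""
    with open(path, encoding="utf-8") as fh:
        obj = json.load(fh)
    if not obj:
        return CausalTreeNode(term=None, feature=None, z=None, p_adj=None, depth=0)

    def build(d: dict) -> CausalTreeNode:
        return CausalTreeNode(
            term=d["term"],
            feature=d["feature"],
            z=d["z"],
            p_adj=d["p_adj"],
            depth=d["depth"],
            children=[build(c) for c in d["children"]],
        )

    return build(obj)
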