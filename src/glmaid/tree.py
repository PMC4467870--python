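"""GLM-AID characterization trees.

Recursive partitioning of a factorial cohort in which, at every node, the
three-way factorial GLM is fitted to every chemical parameter and the
split is made on the parameter that

(i)   has exactly one significant single-factor main effect (the
      parameter "depends on one predictor"; interactions do not define
      predictors),
(ii)  among such candidates has the lowest p-value for that main effect,
(iii) on ties, the highest explained variance (then canonical parameter
      order).

The selected factor's levels are grouped into Bonferroni homogeneous
subsets; each disjoint block of the subset cover becomes a child node.
Recursion stops when nothing is significant, no parameter satisfies the
one-predictor criterion, a level holds a single sample, every remaining
factor is down to one level, or no candidate yields more than one block.

Standardization (zero mean, unit variance per parameter) is applied once,
globally, before any GLM fit; node summaries report raw-scale means.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import pandas as pd
from sklearn.base import BaseEstimator

from . import reference as ref
from .glm import (GLMResult, SingletonLevelError, SubsetPartition,
                  bonferroni_subsets, fit_factorial_glm, terms_for_factors)
from .preprocessing import parameter_columns, standardize

STOP_REASONS = ("no-candidate", "no-significance", "singleton-level",
                "factors-exhausted", "no-split")


@dataclass
class PredictorSelection:
    """The winning parameter/factor of criteria (i)-(iii) at one node."""

    parameter: str
    factor: str
    p_value: float
    explained_variance_pct: float
    alternates: list[tuple[str, str, float, float]] = field(
        default_factory=list)  # (parameter, factor, p, EV), rank order


def select_predictor(results: list[GLMResult], alpha: float = 0.05
                     ) -> PredictorSelection | None:
    """Apply the one-predictor selection criteria to a set of GLM results.

    A parameter is a candidate when exactly one of the single-factor main
    effects is significant (p < alpha): it "depends on one predictor",
    the predictors being the design factors.  Interaction terms do not
    define predictors and do not disqualify a candidate — a reading that
    keeps the selection stable under resampling, which is the stated
    purpose of the criterion (interaction-only parameters have no
    significant main effect and are excluded either way).  Candidates are
    ranked by the main effect's p-value ascending, ties broken by
    explained variance descending, then by canonical parameter order.
    Returns None when no candidate exists.
    """
    candidates = []
    for r in results:
        sig_mains = [t for t in r.significant_terms(alpha)
                     if t in ref.MAIN_EFFECTS]
        if len(sig_mains) != 1:
            continue
        term = sig_mains[0]
        order = (ref.PARAMETER_NAMES.index(r.parameter)
                 if r.parameter in ref.PARAMETER_NAMES else len(ref.PARAMETER_NAMES))
        candidates.append((r.p_values[term], -r.explained_variance_pct,
                           order, r.parameter, ref.FACTOR_OF_MAIN[term]))
    if not candidates:
        return None
    candidates.sort()
    ranked = [(name, fac, p, -neg_ev)
              for p, neg_ev, _, name, fac in candidates]
    best = ranked[0]
    return PredictorSelection(parameter=best[0], factor=best[1],
                              p_value=best[2], explained_variance_pct=best[3],
                              alternates=ranked[1:])


@dataclass
class AidNode:
    node_id: int
    depth: int
    sample_ids: tuple[str, ...]
    levels: dict[str, tuple[str, ...]]          # present levels per factor
    branch: tuple[str, tuple[str, ...]] | None = None  # (factor, levels) from parent
    summary: dict | None = None    # raw mean/sd of parent's split parameter
    selection: PredictorSelection | None = None
    partition: SubsetPartition | None = None
    children: list["AidNode"] = field(default_factory=list)
    stop_reason: str | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    @property
    def n(self) -> int:
        return len(self.sample_ids)


@dataclass
class AidTree:
    root: AidNode
    alpha: float
    standardization: pd.DataFrame   # per-parameter (mean, sd) used globally
    n_nodes: int

    @property
    def depth(self) -> int:
        def _d(node):
            return node.depth if node.is_leaf else max(_d(c) for c in node.children)
        return _d(self.root)

    def nodes(self) -> list[AidNode]:
        out, queue = [], [self.root]
        while queue:
            node = queue.pop(0)
            out.append(node)
            queue.extend(node.children)
        return out

    def level_nodes(self, depth: int) -> list[AidNode]:
        return [n for n in self.nodes() if n.depth == depth]


class GlmAidTree(BaseEstimator):
    """Estimator interface to GLM-AID tree construction.

    Parameters
    ----------
    alpha : significance threshold for term tests and pairwise Bonferroni
        comparisons (family-adjusted internally), default 0.05.
    max_depth : depth cap; with three factors a root-to-leaf path can
        split at most three times.

    Attributes (after ``fit``)
    --------------------------
    tree_ : the :class:`AidTree`.
    root_, depth_, n_nodes_ : convenience views of the same.
    """

    def __init__(self, alpha: float = 0.05, max_depth: int = 3):
        self.alpha = alpha
        self.max_depth = max_depth

    def fit(self, table: pd.DataFrame, y=None):
        self.tree_ = build_tree(table, alpha=self.alpha,
                                max_depth=self.max_depth)
        self.root_ = self.tree_.root
        self.depth_ = self.tree_.depth
        self.n_nodes_ = self.tree_.n_nodes
        return self


def _active_factors(levels: dict[str, tuple[str, ...]]) -> list[str]:
    return [f for f, lv in levels.items() if len(lv) >= 2]


def split_node(node: AidNode, table: pd.DataFrame, alpha: float = 0.05,
               _counter: list[int] | None = None) -> AidNode:
    """Attempt one split of ``node`` in place.

    ``table`` must already be standardized for the GLM fits; raw-scale
    summaries are taken from the ``_raw`` columns if present (build_tree
    provides them), else from the table itself.  Sets either ``children``
    (plus selection and partition) or ``stop_reason``.
    """
    counter = _counter if _counter is not None else [node.node_id + 1]
    sub = table[table["sample_id"].isin(node.sample_ids)]
    active = _active_factors(node.levels)
    if not active:
        node.stop_reason = "factors-exhausted"
        return node

    params = [c for c in parameter_columns(sub) if not c.endswith("_raw")]
    terms = terms_for_factors(tuple(active))
    results = []
    any_significant = False
    for p in params:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                r = fit_factorial_glm(sub[p].to_numpy(), sub[active],
                                      terms=terms, parameter=p)
        except ValueError:
            continue    # constant response or no residual df in this node
        results.append(r)
        if r.significant_terms(alpha):
            any_significant = True
    if not any_significant:
        node.stop_reason = "no-significance"
        return node

    selection = select_predictor(results, alpha)
    if selection is None:
        node.stop_reason = "no-candidate"
        return node

    ranked = [(selection.parameter, selection.factor, selection.p_value,
               selection.explained_variance_pct)] + selection.alternates
    for name, factor, p, ev in ranked:
        try:
            partition = bonferroni_subsets(
                sub[name].to_numpy(), sub[factor], alpha=alpha, factor=factor)
        except SingletonLevelError:
            node.stop_reason = "singleton-level"
            return node
        blocks = partition.blocks()
        if len(blocks) < 2:
            continue
        node.selection = PredictorSelection(
            parameter=name, factor=factor, p_value=p,
            explained_variance_pct=ev, alternates=selection.alternates)
        node.partition = partition
        raw_col = name + "_raw" if name + "_raw" in sub.columns else name
        for block in blocks:
            mask = sub[factor].isin(block)
            child_sub = sub[mask]
            levels = dict(node.levels)
            levels[factor] = tuple(l for l in node.levels[factor]
                                   if l in block)
            child = AidNode(
                node_id=counter[0], depth=node.depth + 1,
                sample_ids=tuple(child_sub["sample_id"]),
                levels=levels, branch=(factor, tuple(block)),
                summary={"parameter": name,
                         "mean": float(child_sub[raw_col].mean()),
                         "sd": float(child_sub[raw_col].std(ddof=1))
                         if len(child_sub) > 1 else 0.0,
                         "n": int(len(child_sub))})
            counter[0] += 1
            node.children.append(child)
        return node
    node.stop_reason = "no-split"
    return node


def build_tree(table: pd.DataFrame, alpha: float = 0.05, max_depth: int = 3
               ) -> AidTree:
    """Grow the GLM-AID tree breadth-first on a cohort table."""
    if len(table) == 0:
        raise ValueError("empty cohort")
    params = parameter_columns(table)
    ztable, stats = standardize(table)
    for p in params:   # keep raw values alongside for node summaries
        ztable[p + "_raw"] = table[p].to_numpy()

    levels = {f: tuple(l for l in ref.LEVELS.get(f, ())
                       if l in set(table[f])) or
              tuple(pd.unique(table[f])) for f in ref.FACTORS}
    root = AidNode(node_id=0, depth=0,
                   sample_ids=tuple(table["sample_id"]), levels=levels)
    counter = [1]
    queue = [root]
    while queue:
        node = queue.pop(0)
        if node.depth >= max_depth:
            node.stop_reason = "factors-exhausted"
            continue
        split_node(node, ztable, alpha=alpha, _counter=counter)
        queue.extend(node.children)
    return AidTree(root=root, alpha=alpha, standardization=stats,
                   n_nodes=counter[0])


def level1_purity(tree: AidTree, table: pd.DataFrame,
                  factor: str = "harvest") -> float:
    """Percentage of samples whose ``factor`` label is uniquely determined
    by membership in a first-level node (i.e. lying in a label-pure node)."""
    label = table.set_index("sample_id")[factor]
    pure_n = 0
    for node in tree.level_nodes(1):
        vals = label.loc[list(node.sample_ids)]
        if vals.nunique() == 1:
            pure_n += len(vals)
    return 100.0 * pure_n / len(table)


# ---------------------------------------------------------------------------
# rendering / serialization

TREE_SCHEMA = "glmaid-tree/1"


def _node_to_dict(node: AidNode) -> dict:
    d = {
        "node_id": node.node_id, "depth": node.depth, "n": node.n,
        "sample_ids": list(node.sample_ids),
        "levels": {f: list(lv) for f, lv in node.levels.items()},
        "branch": None if node.branch is None else
            {"factor": node.branch[0], "levels": list(node.branch[1])},
        "summary": node.summary,
        "stop_reason": node.stop_reason,
        "selection": None, "partition": None,
        "children": [_node_to_dict(c) for c in node.children],
    }
    if node.selection is not None:
        s = node.selection
        d["selection"] = {
            "parameter": s.parameter, "factor": s.factor,
            "p_value": s.p_value,
            "explained_variance_pct": s.explained_variance_pct,
            "alternates": [list(a) for a in s.alternates]}
    if node.partition is not None:
        p = node.partition
        d["partition"] = {
            "factor": p.factor, "levels": list(p.levels),
            "means": p.means, "sds": p.sds, "counts": p.counts,
            "alpha": p.alpha,
            "subsets": [{"letter": l, "levels": list(lv)}
                        for l, lv in p.subsets],
            "pairwise_p": [{"pair": sorted(k), "p": v}
                           for k, v in p.pairwise_p.items()]}
    return d


def _node_from_dict(d: dict) -> AidNode:
    node = AidNode(
        node_id=d["node_id"], depth=d["depth"],
        sample_ids=tuple(d["sample_ids"]),
        levels={f: tuple(lv) for f, lv in d["levels"].items()},
        branch=None if d["branch"] is None else
            (d["branch"]["factor"], tuple(d["branch"]["levels"])),
        summary=d["summary"], stop_reason=d["stop_reason"])
    if d["selection"] is not None:
        s = d["selection"]
        node.selection = PredictorSelection(
            parameter=s["parameter"], factor=s["factor"],
            p_value=s["p_value"],
            explained_variance_pct=s["explained_variance_pct"],
            alternates=[tuple(a) for a in s["alternates"]])
    if d["partition"] is not None:
        p = d["partition"]
        node.partition = SubsetPartition(
            factor=p["factor"], levels=tuple(p["levels"]), means=p["means"],
            sds=p["sds"], counts=p["counts"],
            subsets=[(e["letter"], tuple(e["levels"]))
                     for e in p["subsets"]],
            alpha=p["alpha"],
            pairwise_p={frozenset(e["pair"]): e["p"]
                        for e in p["pairwise_p"]})
    node.children = [_node_from_dict(c) for c in d["children"]]
    return node


def tree_to_json(tree: AidTree) -> str:
    return json.dumps({
        "schema": TREE_SCHEMA, "alpha": tree.alpha,
        "n_nodes": tree.n_nodes,
        "standardization": {
            c: {"mean": float(tree.standardization.loc[c, "mean"]),
                "sd": float(tree.standardization.loc[c, "sd"])}
            for c in tree.standardization.index},
        "root": _node_to_dict(tree.root)}, indent=1)


def tree_from_json(text: str) -> AidTree:
    d = json.loads(text)
    if d.get("schema") != TREE_SCHEMA:
        raise ValueError(f"unsupported tree schema: {d.get('schema')!r}")
    stats = pd.DataFrame(d["standardization"]).T[["mean", "sd"]]
    return AidTree(root=_node_from_dict(d["root"]), alpha=d["alpha"],
                   standardization=stats, n_nodes=d["n_nodes"])


def _node_label(node: AidNode) -> str:
    parts = [f"node {node.node_id} (n={node.n})"]
    if node.branch is not None:
        factor, lv = node.branch
        parts.append(f"{factor} = {', '.join(lv)}")
    if node.summary is not None:
        s = node.summary
        parts.append(f"{s['parameter']}: {s['mean']:.3g} ± {s['sd']:.2g}")
    if node.selection is not None:
        parts.append(f"split: {node.selection.parameter} by "
                     f"{node.selection.factor}")
    if node.stop_reason:
        parts.append(f"[{node.stop_reason}]")
    return " | ".join(parts)


def tree_to_text(tree: AidTree) -> str:
    lines = []

    def _walk(node, indent):
        lines.append("  " * indent + _node_label(node))
        for c in node.children:
            _walk(c, indent + 1)

    _walk(tree.root, 0)
    return "\n".join(lines)


def tree_to_dot(tree: AidTree) -> str:
    lines = ["digraph glmaid {", '  node [shape=box, fontsize=10];']
    for node in tree.nodes():
        label = _node_label(node).replace('"', "'").replace(" | ", r"\n")
        lines.append(f'  n{node.node_id} [label="{label}"];')
        for c in node.children:
            lines.append(f"  n{node.node_id} -> n{c.node_id};")
    lines.append("}")
    return "\n".join(lines)
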