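"""APS scoring, weight-sum importance, input reduction, model selection
and the end-to-end pipeline.

The success metric for the discrete outputs (harvest date, production
type, cultivar) is the Average Percentage of Success,
APS = 100 * matches / N, computed separately for the training and
validation phases; the pooled "average" phase merges both sample sets
(sample-weighted; a plain mean of the two phase values is available
behind a flag).

Input-variable importance is the sum of absolute input-to-hidden weights
per input neuron, normalized to percent shares; the reduction step keeps
the top-k inputs by share averaged over a set of reference models.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd

from . import cohort as cohort_mod
from . import reference as ref
from . import tree as tree_mod
from .nn import (Network, Topology, TrainingConfig, init_network,
                 network_to_dict, predict, train, train_until_plateau)
from .preprocessing import (UnitIntervalScaler, encode_target,
                            split_train_validation)

OUTPUT_VARS = ("harvest", "production", "cultivar")

#: factor column backing each output variable
OUTPUT_FACTOR = {"harvest": "harvest", "production": "practice",
                 "cultivar": "cultivar"}


def round1(x: float) -> float:
    """Round to one decimal, half up (reporting convention)."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.1"),
                                                  rounding=ROUND_HALF_UP))


def aps(successes: int, n: int) -> float:
    """Average Percentage of Success: 100 * successes / n."""
    if n <= 0:
        raise ValueError("n must be > 0")
    if not 0 <= successes <= n:
        raise ValueError("need 0 <= successes <= n")
    return 100.0 * successes / n


@dataclass
class APSReport:
    """Per-output APS for training/validation/pooled phases, plus pooled
    per-class success percentages and confusion tallies."""

    outputs: tuple[str, ...]
    training: dict[str, float]
    validation: dict[str, float]
    average: dict[str, float]
    per_class: dict[str, dict[str, float]]
    confusion: dict[str, pd.DataFrame]
    n_train: int
    n_validation: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for out in self.outputs:
            rows.append({"output": out,
                         "training": round1(self.training[out]),
                         "validation": round1(self.validation[out]),
                         "average": round1(self.average[out])})
        return pd.DataFrame(rows).set_index("output")


def evaluate(net: Network, X_train, y_train, X_val, y_val,
             outputs: tuple[str, ...], codebooks: list,
             pooled: str = "weighted") -> APSReport:
    """Score a trained network on both phases.

    ``y_train`` / ``y_val`` are label matrices with one column per output
    variable (order matching ``outputs`` and ``codebooks``).
    ``pooled="weighted"`` merges both phases sample-weighted;
    ``pooled="mean"`` averages the two phase APS values instead.
    """
    y_train = np.asarray(y_train, dtype=object).reshape(len(X_train), -1)
    y_val = np.asarray(y_val, dtype=object).reshape(len(X_val), -1)
    for y, name in ((y_train, "training"), (y_val, "validation")):
        for k, levels in enumerate(codebooks):
            unseen = set(y[:, k]) - set(levels)
            if unseen:
                raise ValueError(
                    f"unseen {outputs[k]} level(s) in {name} data: {unseen}")
    pred_train = predict(net, X_train, codebooks)
    pred_val = predict(net, X_val, codebooks)

    training, validation, average, per_class, confusion = {}, {}, {}, {}, {}
    for k, out in enumerate(outputs):
        hit_t = pred_train[:, k] == y_train[:, k]
        hit_v = pred_val[:, k] == y_val[:, k]
        training[out] = aps(int(hit_t.sum()), len(hit_t))
        validation[out] = aps(int(hit_v.sum()), len(hit_v))
        if pooled == "weighted":
            average[out] = aps(int(hit_t.sum() + hit_v.sum()),
                               len(hit_t) + len(hit_v))
        elif pooled == "mean":
            average[out] = (training[out] + validation[out]) / 2.0
        else:
            raise ValueError(f"unknown pooling {pooled!r}")
        truth = np.concatenate([y_train[:, k], y_val[:, k]])
        pred = np.concatenate([pred_train[:, k], pred_val[:, k]])
        levels = list(codebooks[k])
        per_class[out] = {
            lev: aps(int(np.sum((truth == lev) & (pred == lev))),
                     max(int(np.sum(truth == lev)), 1))
            for lev in levels}
        confusion[out] = pd.crosstab(
            pd.Series(truth, name="true"), pd.Series(pred, name="predicted")
        ).reindex(index=levels, columns=levels, fill_value=0)
    return APSReport(outputs=tuple(outputs), training=training,
                     validation=validation, average=average,
                     per_class=per_class, confusion=confusion,
                     n_train=len(X_train), n_validation=len(X_val))


def input_importance(net: Network, input_names: list[str] | None = None,
                     model_id: str = "") -> pd.DataFrame:
    """Weight-sum importance: sum of |input->hidden weights| per input.

    Returns a DataFrame indexed by input name with columns ``importance``
    (raw sum) and ``share_pct`` (percent of the total); the model id is
    kept in ``DataFrame.attrs['model_id']``.
    """
    raw = np.abs(net.w1).sum(axis=1)
    total = raw.sum()
    if total == 0:
        raise ValueError("all input->hidden weights are zero; "
                         "importance shares undefined")
    if input_names is None:
        input_names = [f"x{i}" for i in range(len(raw))]
    if len(input_names) != len(raw):
        raise ValueError("one name per input neuron required")
    table = pd.DataFrame({"importance": raw,
                          "share_pct": 100.0 * raw / total},
                         index=pd.Index(input_names, name="input"))
    table.attrs["model_id"] = model_id
    return table


def reduce_inputs(importances: list[pd.DataFrame], k: int = 10
                  ) -> tuple[str, ...]:
    """Top-k inputs by percent share averaged over importance tables.

    Ties are broken by canonical parameter order; the returned tuple is in
    canonical order as well.
    """
    if not importances:
        raise ValueError("need at least one importance table")
    base = set(importances[0].index)
    for t in importances[1:]:
        if set(t.index) != base:
            raise ValueError("importance tables cover different inputs")
    if k > len(base):
        raise ValueError(f"k={k} exceeds number of inputs {len(base)}")
    mean_share = pd.concat([t["share_pct"] for t in importances],
                           axis=1).mean(axis=1)

    def canon(name):
        return (ref.PARAMETER_NAMES.index(name)
                if name in ref.PARAMETER_NAMES else len(ref.PARAMETER_NAMES))

    ranked = sorted(mean_share.index, key=lambda n: (-mean_share[n], canon(n)))
    chosen = set(ranked[:k])
    return tuple(sorted(chosen, key=canon))


@dataclass
class CatalogEntry:
    model_type: str          # ANN_1 .. ANN_4
    topology: str
    cycles: int
    report: APSReport


def select_models(catalog: list[CatalogEntry]
                  ) -> dict[str, CatalogEntry]:
    """Choose, per output variable, the catalog model with the best
    validation APS (ties: higher pooled average, then smaller hidden
    layer)."""
    if not catalog:
        raise ValueError("empty catalog")
    chosen: dict[str, CatalogEntry] = {}
    for out in OUTPUT_VARS:
        entries = [e for e in catalog if out in e.report.outputs]
        if not entries:
            raise ValueError(f"no catalog entry predicts {out}")
        entries.sort(key=lambda e: (
            -e.report.validation[out], -e.report.average[out],
            int(e.topology.split("-")[1])))
        chosen[out] = entries[0]
    return chosen


# ---------------------------------------------------------------------------
# end-to-end pipeline

def _fit_entry(model_type: str, hidden: int, cycles: int,
               X_train, y_train, X_val, y_val,
               outputs, codebooks, seed: int, plateau: bool = False
               ) -> tuple[CatalogEntry, Network]:
    topo = Topology(X_train.shape[1], hidden, len(outputs))
    D = np.column_stack([encode_target(np.asarray(y_train, dtype=object)
                                       .reshape(len(X_train), -1)[:, k],
                                       codebooks[k])
                         for k in range(len(outputs))])
    cfg = TrainingConfig(cycles=cycles, seed=seed)
    net = init_network(topo, seed=seed)
    if plateau:
        net, _ = train_until_plateau(net, X_train, D, cfg, max_cycles=cycles)
    else:
        net, _ = train(net, X_train, D, cfg)
    report = evaluate(net, X_train, y_train, X_val, y_val, outputs, codebooks)
    return CatalogEntry(model_type, str(topo), cycles, report), net


def run_pipeline(config: cohort_mod.GeneratorConfig | None = None,
                 table: pd.DataFrame | None = None,
                 out_dir: str | Path = "glmaid-run",
                 seed: int = 0, alpha: float = 0.05,
                 skip_ann: bool = False, skip_tree: bool = False,
                 hidden_grid: tuple[int, ...] = (9, 13, 18),
                 cycles: int = 1000, plateau_cycles: int = 20_000
                 ) -> dict:
    """simulate -> split -> GLM-AID tree -> 25-input sweep -> importance
    reduction -> 10-input sweep -> model selection -> evaluation.

    Writes tree JSON/DOT/text, model JSONs, APS and importance CSVs and a
    plain-text summary under ``out_dir``; returns the artifact paths and
    headline numbers.  Fully seeded and deterministic.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict = {"seed": seed, "out_dir": str(out)}

    if table is None:
        config = config or cohort_mod.default_config()
        table = cohort_mod.generate(config, seed_override=seed)
        cohort_mod.write_cohort(table, out / "cohort.csv")
        artifacts["cohort"] = str(out / "cohort.csv")

    if not skip_tree:
        fitted = tree_mod.GlmAidTree(alpha=alpha).fit(table)
        (out / "tree.json").write_text(tree_mod.tree_to_json(fitted.tree_))
        (out / "tree.dot").write_text(tree_mod.tree_to_dot(fitted.tree_))
        (out / "tree.txt").write_text(tree_mod.tree_to_text(fitted.tree_))
        artifacts["tree"] = str(out / "tree.json")
        artifacts["level1_purity_pct"] = round1(
            tree_mod.level1_purity(fitted.tree_, table))

    if skip_ann:
        return artifacts

    train_tab, val_tab = split_train_validation(table, seed=seed)
    outputs = OUTPUT_VARS
    codebooks = [ref.LEVELS[OUTPUT_FACTOR[o]] for o in outputs]
    y_cols = [OUTPUT_FACTOR[o] for o in outputs]
    all_params = [p for p in ref.PARAMETER_NAMES if p in table.columns]

    def matrices(cols):
        scaler = UnitIntervalScaler().fit(train_tab[cols].to_numpy())
        return (scaler.transform(train_tab[cols].to_numpy()),
                scaler.transform(val_tab[cols].to_numpy()))

    X_tr, X_va = matrices(all_params)
    y_tr = train_tab[y_cols].to_numpy(dtype=object)
    y_va = val_tab[y_cols].to_numpy(dtype=object)

    catalog: list[CatalogEntry] = []
    networks: dict[str, Network] = {}
    # 25-input models: joint (ANN_1) and per-output (ANN_2)
    importance_tables = []
    for hidden in hidden_grid:
        entry, net = _fit_entry("ANN_1", hidden, cycles, X_tr, y_tr,
                                X_va, y_va, outputs, codebooks, seed)
        catalog.append(entry)
        networks[f"ANN_1:{entry.topology}"] = net
    best_joint = max((e for e in catalog if e.model_type == "ANN_1"),
                     key=lambda e: np.mean(list(e.report.validation.values())))
    importance_tables.append(input_importance(
        networks[f"ANN_1:{best_joint.topology}"], all_params,
        model_id=f"ANN_1:{best_joint.topology}"))
    for k, outvar in enumerate(outputs):
        entry, net = _fit_entry("ANN_2", hidden_grid[-1], cycles,
                                X_tr, y_tr[:, [k]], X_va, y_va[:, [k]],
                                (outvar,), [codebooks[k]], seed)
        catalog.append(entry)
        networks[f"ANN_2:{entry.topology}:{outvar}"] = net
        importance_tables.append(input_importance(
            net, all_params, model_id=f"ANN_2:{entry.topology}:{outvar}"))

    reduced = reduce_inputs(importance_tables, k=min(10, len(all_params)))
    artifacts["reduced_inputs"] = list(reduced)
    pd.concat([t["share_pct"] for t in importance_tables], axis=1).mean(
        axis=1).rename("mean_share_pct").to_csv(out / "importance.csv")

    Xr_tr, Xr_va = matrices(list(reduced))
    for hidden in hidden_grid:
        entry, net = _fit_entry("ANN_3", hidden, plateau_cycles, Xr_tr, y_tr,
                                Xr_va, y_va, outputs, codebooks, seed,
                                plateau=True)
        catalog.append(entry)
        networks[f"ANN_3:{entry.topology}"] = net
    for k, outvar in enumerate(outputs):
        entry, net = _fit_entry("ANN_4", hidden_grid[-1], cycles,
                                Xr_tr, y_tr[:, [k]], Xr_va, y_va[:, [k]],
                                (outvar,), [codebooks[k]], seed)
        catalog.append(entry)
        networks[f"ANN_4:{entry.topology}:{outvar}"] = net

    chosen = select_models([e for e in catalog
                            if e.model_type in ("ANN_3", "ANN_4")])
    rows = []
    for e in catalog:
        for out_var in e.report.outputs:
            rows.append({
                "model_type": e.model_type, "topology": e.topology,
                "cycles": e.cycles, "output": out_var,
                "training": round1(e.report.training[out_var]),
                "validation": round1(e.report.validation[out_var]),
                "average": round1(e.report.average[out_var])})
    pd.DataFrame(rows).to_csv(out / "aps.csv", index=False)
    for key, net in networks.items():
        fname = "model_" + key.replace(":", "_") + ".json"
        (out / fname).write_text(json.dumps(network_to_dict(net)))
    artifacts["selected"] = {
        o: {"model_type": e.model_type, "topology": e.topology,
            "validation_aps": round1(e.report.validation[o])}
        for o, e in chosen.items()}
    summary = ["GLM-AID + ANN pipeline summary",
               f"seed: {seed}", f"samples: {len(table)}"]
    if "level1_purity_pct" in artifacts:
        summary.append(
            f"harvest purity of first tree level: "
            f"{artifacts['level1_purity_pct']}%")
    for o, sel in artifacts["selected"].items():
        summary.append(f"best {o} model: {sel['model_type']} "
                       f"{sel['topology']} "
                       f"(validation APS {sel['validation_aps']}%)")
    (out / "summary.txt").write_text("\n".join(summary) + "\n")
    artifacts["aps"] = str(out / "aps.csv")
    return artifacts
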