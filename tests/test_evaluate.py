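"""APS, weight-sum importance, input reduction, model selection and the
pipeline orchestration."""

import numpy as np
import pandas as pd
import pytest

from glmaid import evaluate as ev
from glmaid.evaluate import (APSReport, CatalogEntry, aps, evaluate,
                             input_importance, reduce_inputs, round1,
                             run_pipeline, select_models)
from glmaid.nn import Network, Topology, init_network, network_from_dict, \
    network_to_dict


class TestAps:
    def test_all_correct(self):
        assert aps(16, 16) == 100.0

    def test_arithmetic(self):
        assert aps(14, 16) == 87.5

    def test_published_training_count(self):
        # 149 successes of 151 training cases prints as 98.7 at one decimal
        assert round1(aps(149, 151)) == 98.7

    def test_errors(self):
        with pytest.raises(ValueError):
            aps(1, 0)
        with pytest.raises(ValueError):
            aps(5, 4)


class TestRound1:
    def test_half_up(self):
        assert round1(93.75) == 93.8
        assert round1(98.85) == 98.9
        assert round1(0.25) == 0.3


def _hand_net(w1_rows, w2_col=None):
    w1 = np.array(w1_rows, dtype=float)
    n_in, n_hid = w1.shape
    w2 = np.ones((n_hid, 1)) if w2_col is None else np.array(w2_col)
    return Network(Topology(n_in, n_hid, w2.shape[1]), w1,
                   np.zeros(n_hid), w2, np.zeros(w2.shape[1]))


class TestImportance:
    def test_single_active_input_takes_full_share(self):
        net = _hand_net([[2.0, -1.0], [0.0, 0.0]])
        table = input_importance(net, ["a", "b"])
        assert table.loc["a", "share_pct"] == 100.0
        assert table.loc["b", "share_pct"] == 0.0

    def test_hand_summed_shares(self):
        net = _hand_net([[1.0, -2.0], [3.0, -4.0]])
        table = input_importance(net, ["a", "b"])
        assert table["importance"].tolist() == [3.0, 7.0]
        assert table["share_pct"].tolist() == [30.0, 70.0]

    def test_shares_sum_to_100_random_nets(self):
        for seed in range(5):
            net = init_network(Topology(6, 9, 2), seed=seed)
            table = input_importance(net)
            assert table["share_pct"].sum() == pytest.approx(100.0,
                                                             abs=1e-9)
            assert (table["importance"] >= 0).all()

    def test_scaling_leaves_shares_unchanged(self):
        net = init_network(Topology(5, 4, 1), seed=3)
        before = input_importance(net)
        net.w1 *= 7.5
        after = input_importance(net)
        assert np.allclose(after["importance"], 7.5 * before["importance"])
        assert np.allclose(after["share_pct"], before["share_pct"])

    def test_zero_weights_rejected(self):
        net = _hand_net([[0.0, 0.0], [0.0, 0.0]])
        with pytest.raises(ValueError, match="zero"):
            input_importance(net)


class TestReduceInputs:
    def _table(self, shares, names):
        df = pd.DataFrame({"importance": shares,
                           "share_pct": shares},
                          index=pd.Index(names, name="input"))
        return df

    def test_top_k_single_table(self):
        t = self._table([50, 30, 15, 5], ["w", "x", "y", "z"])
        assert set(reduce_inputs([t], k=3)) == {"w", "x", "y"}

    def test_averaging_decides_reversed_rankings(self):
        names = ["a", "b", "c"]
        t1 = self._table([60, 30, 10], names)
        t2 = self._table([10, 50, 40], names)
        # averages: a 35, b 40, c 25
        assert set(reduce_inputs([t1, t2], k=2)) == {"a", "b"}

    def test_k_equal_to_all_is_identity(self):
        t = self._table([1, 2, 3], ["a", "b", "c"])
        assert set(reduce_inputs([t], k=3)) == {"a", "b", "c"}

    def test_inconsistent_variable_sets_rejected(self):
        t1 = self._table([1, 2], ["a", "b"])
        t2 = self._table([1, 2], ["a", "c"])
        with pytest.raises(ValueError, match="different inputs"):
            reduce_inputs([t1, t2], k=1)


def _step_net():
    """1-input, 1-output network implementing a sharp 2-class threshold at
    x = 0.5."""
    return Network(Topology(1, 1, 1), np.array([[40.0]]), np.array([-20.0]),
                   np.array([[40.0]]), np.array([-20.0]))


class TestEvaluate:
    def test_perfect_two_class_predictor(self):
        net = _step_net()
        Xt = np.array([[0.1], [0.2], [0.8], [0.9]])
        yt = np.array([["lo"], ["lo"], ["hi"], ["hi"]], dtype=object)
        Xv = np.array([[0.15], [0.85]])
        yv = np.array([["lo"], ["hi"]], dtype=object)
        rep = evaluate(net, Xt, yt, Xv, yv, ("practice",), [("lo", "hi")])
        assert rep.training["practice"] == 100.0
        assert rep.validation["practice"] == 100.0
        assert rep.average["practice"] == 100.0
        assert all(v == 100.0 for v in rep.per_class["practice"].values())

    def test_constant_predictor_on_balanced_four_classes(self):
        net = Network(Topology(1, 1, 1), np.zeros((1, 1)), np.zeros(1),
                      np.zeros((1, 1)), np.zeros(1))   # outputs 0.5
        levels = ("w", "x", "y", "z")
        X = np.zeros((8, 1))
        y = np.array(list(levels) * 2, dtype=object).reshape(-1, 1)
        rep = evaluate(net, X, y, X[:4], y[:4], ("out",), [levels])
        # 0.5 ties between codes 1/3 and 2/3; decodes to the lower level
        assert rep.training["out"] == 25.0

    def test_pooled_average_between_phase_values(self):
        net = _step_net()
        Xt = np.array([[0.1], [0.9], [0.9], [0.4]])   # last one wrong
        yt = np.array([["lo"], ["hi"], ["hi"], ["hi"]], dtype=object)
        Xv = np.array([[0.2], [0.8]])
        yv = np.array([["lo"], ["hi"]], dtype=object)
        rep = evaluate(net, Xt, yt, Xv, yv, ("p",), [("lo", "hi")])
        lo, hi = sorted((rep.training["p"], rep.validation["p"]))
        assert lo <= rep.average["p"] <= hi
        # sample-weighted: 5 of 6 correct
        assert rep.average["p"] == pytest.approx(aps(5, 6))
        plain = evaluate(net, Xt, yt, Xv, yv, ("p",), [("lo", "hi")],
                         pooled="mean")
        assert plain.average["p"] == pytest.approx(
            (rep.training["p"] + rep.validation["p"]) / 2)

    def test_unseen_level_rejected(self):
        net = _step_net()
        X = np.array([[0.1]])
        y = np.array([["unknown"]], dtype=object)
        with pytest.raises(ValueError, match="unseen"):
            evaluate(net, X, y, X, y, ("p",), [("lo", "hi")])

    def test_reloaded_model_evaluates_identically(self, tmp_path):
        net = init_network(Topology(3, 5, 1), seed=2)
        rng = np.random.default_rng(0)
        X = rng.random((10, 3))
        y = np.array([["a"] if v < 0.5 else ["b"] for v in X[:, 0]],
                     dtype=object)
        rep1 = evaluate(net, X, y, X, y, ("p",), [("a", "b")])
        back, _ = network_from_dict(network_to_dict(net))
        rep2 = evaluate(back, X, y, X, y, ("p",), [("a", "b")])
        assert rep1.training == rep2.training
        assert rep1.validation == rep2.validation


def _entry(model_type, topology, val, avg, outputs=("harvest",)):
    rep = APSReport(outputs=outputs,
                    training={o: 99.0 for o in outputs},
                    validation={o: val for o in outputs},
                    average={o: avg for o in outputs},
                    per_class={o: {} for o in outputs},
                    confusion={o: pd.DataFrame() for o in outputs},
                    n_train=151, n_validation=16)
    return CatalogEntry(model_type, topology, 1000, rep)


def _published_reduced_catalog():
    """The published 10-input model catalog (validation and pooled APS per
    output), used as a worked example for the selection rule."""
    def rep(tr, va, avg):
        outs = tuple(tr)
        return APSReport(outputs=outs, training=tr, validation=va,
                         average=avg, per_class={o: {} for o in outs},
                         confusion={o: pd.DataFrame() for o in outs},
                         n_train=151, n_validation=16)

    H, P, C = "harvest", "production", "cultivar"
    return [
        CatalogEntry("ANN_3", "10-13-3", 200_000, rep(
            {H: 87.4, P: 90.1, C: 82.8}, {H: 68.8, P: 68.8, C: 43.8},
            {H: 85.6, P: 88.0, C: 79.0})),
        CatalogEntry("ANN_3", "10-10-3", 200_000, rep(
            {H: 88.7, P: 85.4, C: 64.9}, {H: 93.8, P: 56.3, C: 31.3},
            {H: 89.2, P: 82.6, C: 61.7})),
        CatalogEntry("ANN_3", "10-9-3", 400_000, rep(
            {H: 68.2, P: 84.1, C: 46.4}, {H: 75.0, P: 93.8, C: 18.8},
            {H: 68.9, P: 85.0, C: 43.7})),
        CatalogEntry("ANN_4", "10-18-1", 1000, rep(
            {H: 98.7}, {H: 100.0}, {H: 98.8})),
        CatalogEntry("ANN_4", "10-8-1", 64_000, rep(
            {P: 93.4}, {P: 81.3}, {P: 92.2})),
        CatalogEntry("ANN_4", "10-18-1", 32_000, rep(
            {C: 61.6}, {C: 31.3}, {C: 58.7})),
    ]


class TestSelectModels:
    def test_published_catalog_choices(self):
        chosen = select_models(_published_reduced_catalog())
        assert (chosen["harvest"].model_type,
                chosen["harvest"].topology) == ("ANN_4", "10-18-1")
        assert chosen["harvest"].report.validation["harvest"] == 100.0
        assert (chosen["production"].model_type,
                chosen["production"].topology) == ("ANN_3", "10-9-3")
        assert chosen["production"].report.validation["production"] == 93.8
        assert (chosen["cultivar"].model_type,
                chosen["cultivar"].topology) == ("ANN_3", "10-13-3")
        assert chosen["cultivar"].report.validation["cultivar"] == 43.8

    def test_single_entry(self):
        e = _entry("ANN_4", "10-18-1", 90.0, 95.0)
        chosen = select_models([
            e,
            _entry("ANN_4", "10-9-1", 80.0, 99.0,
                   outputs=("production",)),
            _entry("ANN_4", "10-9-1", 80.0, 99.0, outputs=("cultivar",))])
        assert chosen["harvest"] is e

    def test_tie_broken_by_average_then_hidden(self):
        a = _entry("ANN_4", "10-18-1", 90.0, 95.0)
        b = _entry("ANN_4", "10-12-1", 90.0, 97.0)
        c = _entry("ANN_4", "10-6-1", 90.0, 97.0)
        others = [_entry("ANN_4", "10-9-1", 1.0, 1.0, ("production",)),
                  _entry("ANN_4", "10-9-1", 1.0, 1.0, ("cultivar",))]
        chosen = select_models([a, b, c] + others)
        assert chosen["harvest"] is c  # higher average, smaller hidden

    def test_order_invariance(self):
        catalog = _published_reduced_catalog()
        first = select_models(catalog)
        second = select_models(list(reversed(catalog)))
        for out in first:
            assert first[out].topology == second[out].topology

    def test_empty_catalog_rejected(self):
        with pytest.raises(ValueError):
            select_models([])


class TestPipeline:
    def test_smoke_run_produces_artifacts(self, tmp_path, default_cfg):
        art = run_pipeline(config=default_cfg, out_dir=tmp_path / "run",
                           seed=0, hidden_grid=(4,), cycles=15,
                           plateau_cycles=60)
        base = tmp_path / "run"
        for fname in ("cohort.csv", "tree.json", "tree.dot", "tree.txt",
                      "aps.csv", "importance.csv", "summary.txt"):
            assert (base / fname).exists(), fname
        assert set(art["selected"]) == {"harvest", "production", "cultivar"}
        assert len(art["reduced_inputs"]) == 10

    def test_rerun_is_deterministic(self, tmp_path, default_cfg):
        a = run_pipeline(config=default_cfg, out_dir=tmp_path / "a", seed=1,
                         skip_tree=True, hidden_grid=(3,), cycles=10,
                         plateau_cycles=40)
        b = run_pipeline(config=default_cfg, out_dir=tmp_path / "b", seed=1,
                         skip_tree=True, hidden_grid=(3,), cycles=10,
                         plateau_cycles=40)
        assert (tmp_path / "a" / "aps.csv").read_bytes() == \
            (tmp_path / "b" / "aps.csv").read_bytes()
        assert a["selected"] == b["selected"]

    def test_skip_ann_emits_tree_only(self, tmp_path, default_cfg):
        run_pipeline(config=default_cfg, out_dir=tmp_path / "t", seed=0,
                     skip_ann=True)
        assert (tmp_path / "t" / "tree.json").exists()
        assert not (tmp_path / "t" / "aps.csv").exists()
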