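"""Comparison metrics: unique calls, Jaccard, knockdown, discovery counts."""

import numpy as np
import pandas as pd
import pytest

import guidecall as gc
from guidecall.core import EvaluationError, ParameterError
from guidecall.evaluate import (
    DiscoveryResult,
    count_discoveries,
    count_false_discoveries,
    median_target_downregulation,
)

from conftest import make_expression_context, matrix_from_dict


def table(pairs, method="m", probs=None):
    return gc.AssignmentTable.from_pairs(method, pairs, probs=probs)


def test_unique_assignments_keeps_single_call_cells():
    t = table([("c1", "gA"), ("c2", "gA"), ("c2", "gB")])
    assert gc.unique_assignments(t).pairs == {("c1", "gA")}
    one_each = table([("c1", "gA"), ("c2", "gB")])
    assert gc.unique_assignments(one_each).pairs == one_each.pairs
    assert len(gc.unique_assignments(table([]))) == 0


def test_jaccard_matrix_arithmetic():
    a = table([("c1", "gA"), ("c2", "gB")], "a")
    b = table([("c2", "gB"), ("c3", "gC")], "b")
    jac = gc.jaccard_matrix([a, b, table([], "empty1"), table([], "empty2")])
    assert jac.loc["a", "b"] == pytest.approx(1 / 3)
    assert jac.loc["a", "a"] == 1.0
    assert jac.loc["empty1", "empty2"] == 1.0  # empty vs empty agrees
    assert jac.loc["a", "empty1"] == 0.0
    np.testing.assert_allclose(jac.to_numpy(), jac.to_numpy().T)
    assert ((jac.to_numpy() >= 0) & (jac.to_numpy() <= 1)).all()


def test_target_downregulation_closed_form():
    """Assigned cells at half the controls' normalized expression -> -log2FC = 1."""
    ctx = make_expression_context(
        assigned={"a1": 50.0, "a2": 50.0}, controls={"n1": 100.0, "n2": 100.0}
    )
    t = table([("a1", "gT"), ("a2", "gT"), ("n1", "gNT"), ("n2", "gNT")])
    lfc = gc.target_downregulation(t, ctx, pseudocount=0.0)
    assert lfc["gT"] == pytest.approx(-1.0)

    same = make_expression_context(
        assigned={"a1": 80.0}, controls={"n1": 80.0, "n2": 80.0}
    )
    t2 = table([("a1", "gT"), ("n1", "gNT"), ("n2", "gNT")])
    assert gc.target_downregulation(t2, same, pseudocount=0.0)["gT"] == pytest.approx(0.0)


def test_downregulation_recovers_simulated_knockdown(separated_screen):
    """A 2^-2 knockdown reads out as median -log2FC ~ 2 under separation."""
    m, ctx, _ = separated_screen
    t = gc.assign_umi_threshold(m, 5)
    assert median_target_downregulation(t, ctx) == pytest.approx(2.0, abs=0.2)


def test_no_control_cells_is_an_error(separated_screen):
    m, ctx, _ = separated_screen
    only_targeting = gc.AssignmentTable.from_pairs("t", [("cell_0000", "gRNA_T0000")])
    with pytest.raises(EvaluationError, match="control"):
        gc.target_downregulation(only_targeting, ctx)


def test_count_discoveries_finds_all_strong_targets(separated_screen):
    """4-fold knockdown of 20 targets under separation: all 20 significant."""
    m, ctx, _ = separated_screen
    t = gc.assign_umi_threshold(m, 5)
    result = count_discoveries(t, ctx)
    assert isinstance(result, DiscoveryResult)
    assert result.n_significant_targets == 20
    assert result.n_discoveries >= 20
    assert result.n_tested == 20 * ctx.expr.shape[1]


def test_discovery_counts_on_empty_assignment(separated_screen):
    _, ctx, _ = separated_screen
    assert count_discoveries(table([]), ctx).n_discoveries == 0
    assert count_false_discoveries(table([]), ctx).n_false_discoveries == 0


def test_false_discoveries_need_two_nontargeting(separated_screen):
    m, ctx, _ = separated_screen
    t = table([("cell_0000", "gRNA_NT0000"), ("cell_0001", "gRNA_NT0000")])
    with pytest.raises(EvaluationError, match="non-targeting"):
        count_false_discoveries(t, ctx)


def test_threshold_grid_search_picks_gap():
    """Ambient background up to ~2 counts, signal >= 20: thresholds at or
    below the background range flood cells with spurious calls (few unique
    cells, lost significance), so the chosen threshold lands in the gap."""
    from guidecall.synthetic import SimConfig

    cfg = SimConfig(
        seed=2, n_cells=800, n_guides=6, n_nontargeting=3, moi_lambda=0.1,
        ambient_rate=0.8, signal_mean=40.0, signal_dispersion=10.0,
        depth_sigma=0.2, knockdown_log2fc=0.5, expr_mean=20.0,
        expr_dispersion=10.0, n_extra_genes=10,
    )
    m, ctx, _ = gc.simulate_screen(cfg)
    chosen, frame = gc.threshold_grid_search(
        m, ctx, "umi_threshold", grid=[1, 2, 5, 10, 20]
    )
    assert 2 < chosen <= 20
    assert set(frame["value"]) == {1, 2, 5, 10, 20}
    assert (frame["n_significant_targets"] <= 6).all()


def test_threshold_grid_search_edge_cases(separated_screen, caplog):
    m, ctx, _ = separated_screen
    chosen, _ = gc.threshold_grid_search(
        m, ctx, "umi_threshold", grid=[7], genes=list(ctx.expr.columns[:5])
    )
    assert chosen == 7
    with pytest.raises(ParameterError, match="empty"):
        gc.threshold_grid_search(m, ctx, "umi_threshold", grid=[])
    with pytest.raises(ParameterError):
        gc.threshold_grid_search(m, ctx, "maximum", grid=[1])
    # no significant target at an absurd threshold: smallest value + warning
    import logging

    with caplog.at_level(logging.WARNING, logger="guidecall.evaluate"):
        chosen, frame = gc.threshold_grid_search(
            m, ctx, "umi_threshold", grid=[5000, 9000], genes=[ctx.expr.columns[0]]
        )
    assert chosen == 5000
    assert (frame["n_significant_targets"] == 0).all()
    assert any("significant" in r.message for r in caplog.records)


def test_score_vs_truth_arithmetic():
    truth = gc.AssignmentTable.from_pairs("truth", [(f"c{i}", "gA") for i in range(99)])
    exact = table(truth.pairs)
    assert gc.score_vs_truth(exact, truth) == (1.0, 1.0, 1.0)
    p, r, f1 = gc.score_vs_truth(table(list(truth.pairs) + [("cX", "gB")]), truth)
    assert p == pytest.approx(0.99)
    assert r == 1.0
    p, r, f1 = gc.score_vs_truth(table([]), truth)
    assert np.isnan(p)
    assert r == 0.0


def test_summary_and_report(separated_screen):
    m, ctx, truth = separated_screen
    tables = [gc.assign_umi_threshold(m, 5), gc.assign_maximum(m)]
    report = gc.build_report(tables, ctx=ctx, truth=truth, run_de=False)
    s = report.summary
    assert (
        s["n_uniquely_assigned_cells"] <= s["n_total_assigned_cells"]
    ).all()
    assert s.loc["maximum", "median_cells_per_targeting_guide"] > 0
    assert report.jaccard.loc["umi_threshold", "maximum"] > 0.9
    assert (report.truth_scores["f1"] > 0.95).all()
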