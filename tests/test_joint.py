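"""Poisson GLM with library-size offset and per-batch Beta mixtures."""

import numpy as np
import pytest

import guidecall as gc
from guidecall.core import DegenerateFitError, ParameterError
from guidecall.joint import (
    compute_max_frequencies,
    fit_beta_mixture,
    fit_poisson_glm_counts,
)
from guidecall.mixture import fit_pois_gauss

from conftest import matrix_from_dict


def glm_sim(seed=7, n=3000, rate_ratio=50.0, base=1e-4, pi=0.1):
    rng = np.random.default_rng(seed)
    L = np.round(rng.lognormal(np.log(1000), 0.4, n))
    z = rng.random(n) < pi
    k = rng.poisson(base * np.where(z, rate_ratio, 1.0) * L)
    return k, L, z


def test_glm_parameter_recovery():
    k, L, z = glm_sim()
    fit = fit_poisson_glm_counts(k, L)
    assert fit.beta1 == pytest.approx(np.log(50), abs=0.2)
    assert fit.pi == pytest.approx(0.1, abs=0.02)
    assert fit.beta0 == pytest.approx(np.log(1e-4), abs=0.2)
    # responsibilities recover the latent indicator
    assert np.mean((fit.responsibilities > 0.5) == z) > 0.98


def test_glm_library_size_scale_invariance():
    """Scaling all library sizes shifts beta0 and nothing else."""
    k, L, _ = glm_sim()
    a = fit_poisson_glm_counts(k, L)
    b = fit_poisson_glm_counts(k, 10.0 * L)
    assert b.beta0 == pytest.approx(a.beta0 - np.log(10.0), abs=1e-6)
    assert b.beta1 == pytest.approx(a.beta1, abs=1e-6)
    np.testing.assert_allclose(a.responsibilities, b.responsibilities, atol=1e-9)


def test_glm_fixed_pi_zero_gives_zero_responsibilities():
    k, L, _ = glm_sim()
    fit = fit_poisson_glm_counts(k, L, fix_pi=0.0)
    assert np.all(fit.responsibilities == 0.0)


def test_glm_degenerate_column():
    with pytest.raises(DegenerateFitError):
        fit_poisson_glm_counts(np.zeros(100), np.full(100, 50.0))


def test_glm_matches_poisson_mixture_with_equal_library_sizes():
    """With constant L the GLM decision boundary agrees with the
    Poisson-Gaussian mixture's within one count."""
    rng = np.random.default_rng(5)
    n = 4000
    z = rng.random(n) < 0.2
    y = np.where(z, np.round(2 ** rng.normal(3, 0.5, n)), rng.poisson(0.2, n)).astype(int)
    t_mix = fit_pois_gauss(y).decision_threshold(int(y.max()))
    glm = fit_poisson_glm_counts(y, np.full(n, 50.0))
    t_glm = glm.decision_threshold(50.0, int(y.max()))
    assert abs(t_glm - t_mix) <= 1


def test_max_frequencies_clipping_and_exclusion():
    m = matrix_from_dict(
        {"c1": {"gA": 9, "gB": 1}, "c2": {"gA": 4}, "c3": {}},
        guides=["gA", "gB"],
    )
    profile = compute_max_frequencies(m).set_index("cell")
    assert profile.loc["c1", "f"] == pytest.approx(0.9)
    assert profile.loc["c2", "f"] == pytest.approx(1 - 1e-4)  # clipped
    assert "c3" not in profile.index


def test_beta_mixture_recovery_two_components():
    rng = np.random.default_rng(21)
    n = 4000
    f = np.where(rng.random(n) < 0.4, rng.beta(20, 2, n), rng.beta(2, 10, n))
    fit = fit_beta_mixture(np.clip(f, 1e-4, 1 - 1e-4), 2)
    assert fit.means[0] == pytest.approx(2 / 12, abs=0.03)
    assert fit.means[1] == pytest.approx(20 / 22, abs=0.03)
    assert 0.4 < fit.threshold < 0.8
    assert np.all(np.diff(fit.loglik_trace) >= -1e-8)


def test_beta_mixture_recovery_three_components():
    rng = np.random.default_rng(22)
    n = 4000
    comp = rng.choice(3, n, p=[0.5, 0.2, 0.3])
    pool = np.stack([rng.beta(2, 10, n), rng.beta(5, 5, n), rng.beta(30, 2, n)])
    f = np.clip(pool[comp, np.arange(n)], 1e-4, 1 - 1e-4)
    fit = fit_beta_mixture(f, 3)
    assert len(fit.means) == 3
    np.testing.assert_allclose(fit.means, [2 / 12, 0.5, 30 / 32], atol=0.05)
    assert np.all(np.diff(fit.means) > 0)
    assert np.allclose(fit.weights.sum(), 1.0)


def test_beta_mixture_degenerate_inputs():
    with pytest.raises(DegenerateFitError, match="identical"):
        fit_beta_mixture(np.full(100, 0.7), 2)
    with pytest.raises(DegenerateFitError, match=">= 10"):
        fit_beta_mixture(np.linspace(0.1, 0.9, 5), 2)
    with pytest.raises(ParameterError):
        fit_beta_mixture(np.linspace(0.1, 0.9, 50), 4)


def test_assign_beta_matches_ratio_at_learnt_threshold(separated_screen):
    """Single batch: 2-Beta calls equal ratio calls at the learnt threshold."""
    m, _, _ = separated_screen
    table = gc.assign_beta(m, n_components=2)
    thr = table.params["batches"]["batch0"]["threshold"]
    ratio = gc.assign_ratio(m, r=thr)
    assert table.pairs == ratio.pairs


def test_assign_beta_perfect_separation_recovers_singletons(separated_screen):
    m, _, truth = separated_screen
    table = gc.assign_beta(m, n_components=2)
    precision, recall, f1 = gc.score_vs_truth(table, truth)
    assert precision >= 0.99
    assert f1 >= 0.95


def test_assign_beta_learns_batch_specific_thresholds(two_batch_screen):
    """Batches with different ambient contamination get different thresholds."""
    m, _, truth = two_batch_screen
    table = gc.assign_beta(m, n_components=2)
    thr = {b: p["threshold"] for b, p in table.params["batches"].items()}
    assert len(thr) == 2
    assert abs(thr["batch0"] - thr["batch1"]) > 0.01
    # the clean batch learns the stricter threshold; imposing it globally
    # cuts into the contaminated batch's true cells and degrades F1
    assert thr["batch0"] > thr["batch1"]
    _, _, f1_beta = gc.score_vs_truth(table, truth)
    _, _, f1_strict_global = gc.score_vs_truth(
        gc.assign_ratio(m, max(thr.values())), truth
    )
    assert f1_beta > f1_strict_global


def test_assign_beta_cutoff_one_is_empty(separated_screen):
    m, _, _ = separated_screen
    assert len(gc.assign_beta(m, 2, prob_cutoff=1.0)) == 0


def test_assign_beta_three_components_reports_ambiguous(separated_screen):
    m, _, _ = separated_screen
    table = gc.assign_beta(m, n_components=3)
    assert "ambiguous_cells" in table.params
    assert table.calls["cell"].is_unique
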