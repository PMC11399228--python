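"""Per-gRNA background/signal mixture models: EM behavior and assignment."""

import numpy as np
import pytest
from scipy.stats import norm

import guidecall as gc
from guidecall.core import DegenerateFitError, ParameterError
from guidecall.mixture import (
    MODELS,
    fit_gauss_gauss,
    fit_gauss_gauss_nonzero,
    fit_nb_gauss,
    fit_pois_gauss,
)
from guidecall.synthetic import SimConfig

from conftest import matrix_from_dict

FITTERS = {
    "gauss": fit_gauss_gauss,
    "gauss_nonzero": fit_gauss_gauss_nonzero,
    "pois_gauss": fit_pois_gauss,
    "nb_gauss": fit_nb_gauss,
}


def mixed_counts(seed=0, n=600):
    rng = np.random.default_rng(seed)
    lab = rng.random(n) < 0.3
    return np.where(
        lab, np.round(2 ** rng.normal(5, 0.5, n)), rng.poisson(0.5, n)
    ).astype(int)


def test_gauss_two_point_symmetry():
    """Half the mass at 0, half at 64: components at 0 and log2(65), pi ~ 1/2."""
    y = np.array([0] * 100 + [64] * 100)
    fit = fit_gauss_gauss(y)
    assert fit.params["mu0"] == pytest.approx(0.0, abs=0.05)
    assert fit.params["mu1"] == pytest.approx(np.log2(65), abs=0.05)
    assert fit.pi == pytest.approx(0.5, abs=0.02)


@pytest.mark.parametrize("model", MODELS)
def test_degenerate_input_raises(model):
    with pytest.raises(DegenerateFitError):
        FITTERS[model](np.zeros(50, dtype=int))


def test_nonzero_fit_needs_two_distinct_nonzero():
    with pytest.raises(DegenerateFitError):
        fit_gauss_gauss_nonzero(np.array([0] * 30 + [7] * 5))


@pytest.mark.parametrize("model", MODELS)
def test_loglik_nondecreasing(model):
    """EM must never decrease the observed-data log-likelihood."""
    fit = FITTERS[model](mixed_counts())
    assert np.all(np.diff(fit.loglik_trace) >= -1e-8)
    assert fit.converged


@pytest.mark.parametrize("model", ["gauss", "gauss_nonzero"])
def test_signal_component_above_background(model):
    fit = FITTERS[model](mixed_counts())
    assert fit.params["mu1"] > fit.params["mu0"]


def test_nonzero_fit_excludes_zeros_and_matches_grid_oracle():
    """Zeros get responsibility 0; EM on the 6 nonzero points beats a grid."""
    y = np.array([0] * 999 + [8, 9, 10, 200, 210, 220])
    fit = fit_gauss_gauss_nonzero(y)
    assert np.all(fit.responsibilities[y == 0] == 0)
    assert fit.params["mu0"] == pytest.approx(np.log2(10), abs=0.3)
    assert fit.params["mu1"] == pytest.approx(np.log2(211), abs=0.3)

    x = np.log2(y[y > 0] + 1.0)
    best = -np.inf
    grid = np.linspace(x.min(), x.max(), 25)
    for mu0 in grid:
        for mu1 in grid:
            if mu1 <= mu0:
                continue
            for s in np.linspace(0.25, 1.5, 8):
                for pi in np.linspace(0.1, 0.9, 9):
                    ll = np.logaddexp(
                        np.log(pi) + norm.logpdf(x, mu0, s),
                        np.log1p(-pi) + norm.logpdf(x, mu1, s),
                    ).sum()
                    best = max(best, ll)
    assert fit.loglik_trace[-1] >= best - 1e-3


def test_pois_gauss_perfectly_separated():
    y = np.array([0] * 1000 + [1000] * 50)
    fit = fit_pois_gauss(y)
    assert fit.params["lam"] == pytest.approx(0.0, abs=1e-3)
    assert fit.params["mu1"] == pytest.approx(np.log2(1001), abs=0.05)


def test_pois_gauss_responsibility_monotone_above_crossing():
    fit = fit_pois_gauss(mixed_counts())
    ks = np.arange(0, 200)
    resp = fit.signal_responsibility(ks)
    crossing = np.flatnonzero(resp > 0.5)[0]
    assert np.all(np.diff(resp[crossing:]) >= -1e-12)


def test_nb_gauss_poisson_limit():
    """On Poisson background the NB fit recovers a huge dispersion and the
    same rate as the Poisson-Gaussian fit."""
    rng = np.random.default_rng(4)
    n = 3000
    lab = rng.random(n) < 0.2
    y = np.where(lab, np.round(2 ** rng.normal(5, 0.6, n)), rng.poisson(0.2, n)).astype(int)
    fp = fit_pois_gauss(y)
    fn = fit_nb_gauss(y)
    assert fn.params["lam"] == pytest.approx(fp.params["lam"], abs=0.02)
    assert fn.params["mu1"] == pytest.approx(fp.params["mu1"], abs=0.05)
    assert fn.pi == pytest.approx(fp.pi, abs=0.01)
    # fitted background variance collapses to the Poisson value
    lam, alpha = fn.params["lam"], fn.params["alpha"]
    assert lam + lam**2 / alpha == pytest.approx(lam, rel=0.05)
    # dispersion is weakly identified on a near-Poisson background, so the
    # tail-driven decision threshold may shift by at most one count
    assert abs(fn.decision_threshold(100) - fp.decision_threshold(100)) <= 1


def test_random_initializations_agree_on_threshold():
    """Well-separated data: the decision threshold is init-independent."""
    y = mixed_counts(seed=1)
    thresholds = {
        fit_gauss_gauss(y, seed=s, init="random").decision_threshold(int(y.max()))
        for s in range(5)
    }
    assert len(thresholds) == 1


def separated_mini_screen():
    cfg = SimConfig(
        seed=5, n_cells=800, n_guides=8, n_nontargeting=2, moi_lambda=0.05,
        ambient_rate=0.0005, signal_mean=60, signal_dispersion=10,
        depth_sigma=0.2, n_extra_genes=5,
    )
    return gc.simulate_screen(cfg)


@pytest.mark.parametrize("model", MODELS)
def test_assignment_recovers_truth_when_separated(model):
    m, _, truth = separated_mini_screen()
    table = gc.assign_from_mixture(m, model)
    precision, recall, f1 = gc.score_vs_truth(table, truth)
    assert f1 >= 0.95


def test_prob_cutoff_boundary_and_monotonicity():
    m, _, _ = separated_mini_screen()
    assert len(gc.assign_from_mixture(m, "pois_gauss", prob_cutoff=1.0)) == 0
    lo = gc.assign_from_mixture(m, "pois_gauss", prob_cutoff=0.5)
    hi = gc.assign_from_mixture(m, "pois_gauss", prob_cutoff=0.9)
    assert hi.pairs <= lo.pairs


def test_degenerate_guides_are_skipped_not_fatal():
    m = matrix_from_dict(
        {
            "c1": {"gA": 5},
            "c2": {"gA": 1, "gB": 0},
            "c3": {"gA": 50},
            "c4": {"gA": 2},
        },
        guides=["gA", "gB"],
    )
    table = gc.assign_from_mixture(m, "gauss")
    assert table.params["n_failed_guides"] == 1  # gB is all zeros
    assert set(table.calls["guide"]) <= {"gA"}


def test_unknown_model_rejected(two_cell_matrix):
    with pytest.raises(ParameterError):
        gc.assign_from_mixture(two_cell_matrix, "weibull")


def test_gauss_fit_agrees_with_independent_gmm_oracle():
    """On well-separated data the Gaussian fit matches an independently
    implemented 1-D GMM (scikit-learn) on means and weights."""
    from sklearn.mixture import GaussianMixture

    y = mixed_counts(seed=2, n=2000)
    x = np.log2(y + 1.0).reshape(-1, 1)
    oracle = GaussianMixture(n_components=2, n_init=3, random_state=0).fit(x)
    order = np.argsort(oracle.means_.ravel())
    o_means = oracle.means_.ravel()[order]
    o_weights = oracle.weights_[order]
    fit = fit_gauss_gauss(y)
    assert fit.params["mu0"] == pytest.approx(o_means[0], abs=0.1)
    assert fit.params["mu1"] == pytest.approx(o_means[1], abs=0.1)
    assert fit.pi == pytest.approx(o_weights[0], abs=0.05)
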