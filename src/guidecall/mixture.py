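"""Per-gRNA two-component mixture models ("across cells" family).

Each gRNA's UMI counts across cells are modeled as a mixture of a
*background* component (ambient contamination in cells that do not carry
the guide) and a *signal* component (true guide presence).  Four variants
are provided:

``gauss``
    Gaussian-Gaussian mixture on log2(y+1), zeros included -- the model
    used by 10X Genomics Cell Ranger for guide calling.
``gauss_nonzero``
    The same model fitted only on nonzero counts.  With many guides the
    zero point mass otherwise swallows the background component and drags
    the decision threshold down to 1; dropping zeros restores a sensible
    background/signal split.
``pois_gauss``
    Poisson background on raw counts k plus a discretized log-normal
    signal: the Normal density at log2(k+1) with the change-of-variables
    factor 1/((k+1) ln 2).
``nb_gauss``
    As above with a negative-binomial background (mean lambda, dispersion
    alpha; variance lambda + lambda^2/alpha, Poisson as alpha -> inf).

All fits use expectation-maximization with closed-form (or exactly
profiled) M-steps, so the log-likelihood is non-decreasing by
construction.  Initialization is deterministic: background location from
the 10th percentile, signal location from the 90th percentile of the
log2-transformed data, mixing weight from the fraction of observations
below their midpoint.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.stats import nbinom, norm, poisson

from .core import AssignmentTable, DegenerateFitError, GuideCountMatrix, ParameterError

logger = logging.getLogger(__name__)

LN2 = np.log(2.0)
# Gaussian scale floor on the log2(count+1) axis.  Counts live on a lattice
# whose spacing near the origin is log2(2)-log2(1) ~ 0.58; components narrower
# than ~half that spacing just wrap a single count value in a density spike,
# which is degenerate for count data.
SIGMA_FLOOR = 0.25
MODELS = ("gauss", "gauss_nonzero", "pois_gauss", "nb_gauss")

__all__ = [
    "MixtureFit",
    "fit_gauss_gauss",
    "fit_gauss_gauss_nonzero",
    "fit_pois_gauss",
    "fit_nb_gauss",
    "assign_from_mixture",
    "MODELS",
]


@dataclass
class MixtureFit:
    """Fitted two-component background/signal mixture for one gRNA.

    ``pi`` is the background mixing weight; ``responsibilities`` holds the
    posterior signal probability per input observation (zeros receive 0
    for the nonzero-only model).  ``params`` holds the component
    parameters; the signal mean always exceeds the background location on
    the shared log2 scale after relabeling.
    """

    model: str
    params: dict
    pi: float
    responsibilities: np.ndarray
    loglik_trace: np.ndarray
    converged: bool
    n_iter: int
    seed: int | None = None
    extras: dict = field(default_factory=dict)

    def component_logpdfs(self, k: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Log background pmf/density and log signal density at counts k."""
        k = np.asarray(k, dtype=float)
        x = np.log2(k + 1.0)
        p = self.params
        if self.model in ("gauss", "gauss_nonzero"):
            lb = norm.logpdf(x, p["mu0"], p["sigma0"])
            ls = norm.logpdf(x, p["mu1"], p["sigma1"])
        elif self.model == "pois_gauss":
            lb = poisson.logpmf(np.round(k), max(p["lam"], 1e-12))
            ls = norm.logpdf(x, p["mu1"], p["sigma1"]) - np.log((k + 1.0) * LN2)
        elif self.model == "nb_gauss":
            lam, alpha = max(p["lam"], 1e-12), p["alpha"]
            lb = nbinom.logpmf(np.round(k), alpha, alpha / (alpha + lam))
            ls = norm.logpdf(x, p["mu1"], p["sigma1"]) - np.log((k + 1.0) * LN2)
        else:  # pragma: no cover
            raise ValueError(self.model)
        return lb, ls

    def signal_responsibility(self, k: np.ndarray) -> np.ndarray:
        """Posterior probability that count k came from the signal component."""
        k = np.atleast_1d(np.asarray(k, dtype=float))
        lb, ls = self.component_logpdfs(k)
        lb = lb + np.log(max(self.pi, 1e-300))
        ls = ls + np.log(max(1.0 - self.pi, 1e-300))
        resp = np.exp(ls - np.logaddexp(lb, ls))
        if self.model == "gauss_nonzero":
            resp = np.where(k == 0, 0.0, resp)
        return resp

    def decision_threshold(
        self, max_count: int, prob_cutoff: float = 0.5
    ) -> int | None:
        """Smallest integer count whose signal responsibility exceeds the cutoff."""
        ks = np.arange(0, max_count + 1)
        resp = self.signal_responsibility(ks)
        hits = np.flatnonzero(resp > prob_cutoff)
        return int(ks[hits[0]]) if hits.size else None


def _prepare(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y)
    if y.size == 0:
        raise DegenerateFitError("empty input")
    if np.any(y < 0) or not np.allclose(y, np.round(y)):
        raise DegenerateFitError("counts must be non-negative integers")
    return y.astype(float)


def _init_locations(
    x: np.ndarray, init: str, rng: np.random.Generator | None
) -> tuple[float, float, float, float]:
    """(loc0, loc1, sigma, pi) starting values on the log2 scale."""
    if init == "random" and rng is not None:
        lo, hi = np.sort(rng.choice(x, size=2, replace=False))
        if hi - lo < 1e-3:
            lo, hi = np.percentile(x, [10, 90])
        pi = float(rng.uniform(0.2, 0.8))
    else:
        lo, hi = np.percentile(x, [10, 90])
        pi = float(np.mean(x <= (lo + hi) / 2.0))
    if hi - lo < 1e-3:
        hi = lo + max(x.std(), 0.5)
    sigma = max(x.std() / 2.0, SIGMA_FLOOR)
    pi = min(max(pi, 0.05), 0.95)
    return float(lo), float(hi), float(sigma), pi


def _em_loop(e_step, m_step, theta, max_iter: int, tol: float):
    """Generic EM driver; returns (theta, resp, trace, converged, n_iter)."""
    trace = []
    resp = None
    for it in range(1, max_iter + 1):
        ll, resp = e_step(theta)
        trace.append(ll)
        if len(trace) > 1 and abs(trace[-1] - trace[-2]) < tol * (abs(trace[-2]) + 1.0):
            return theta, resp, np.array(trace), True, it
        theta = m_step(resp, theta)
    ll, resp = e_step(theta)
    trace.append(ll)
    return theta, resp, np.array(trace), False, max_iter


def _weighted_norm_params(x, w, floor=SIGMA_FLOOR):
    wsum = max(w.sum(), 1e-12)
    mu = float((w * x).sum() / wsum)
    var = float((w * (x - mu) ** 2).sum() / wsum)
    return mu, max(np.sqrt(var), floor)


def fit_gauss_gauss(
    y: np.ndarray,
    max_iter: int = 500,
    tol: float = 1e-6,
    seed: int | None = None,
    init: str = "quantile",
) -> MixtureFit:
    """EM fit of pi*N(mu0,s0) + (1-pi)*N(mu1,s1) on x = log2(y+1), zeros included."""
    y = _prepare(y)
    x = np.log2(y + 1.0)
    if len(np.unique(x)) < 2:
        raise DegenerateFitError("all observations identical")
    rng = np.random.default_rng(seed) if seed is not None else None
    mu0, mu1, sigma, pi = _init_locations(x, init, rng)
    theta = dict(mu0=mu0, sigma0=sigma, mu1=mu1, sigma1=sigma, pi=pi)

    def e_step(th):
        lb = np.log(th["pi"]) + norm.logpdf(x, th["mu0"], th["sigma0"])
        ls = np.log1p(-th["pi"]) + norm.logpdf(x, th["mu1"], th["sigma1"])
        tot = np.logaddexp(lb, ls)
        return float(tot.sum()), np.exp(ls - tot)

    def m_step(r1, th):
        r0 = 1.0 - r1
        pi = float(np.clip(r0.mean(), 1e-6, 1 - 1e-6))
        mu0, s0 = _weighted_norm_params(x, r0)
        mu1, s1 = _weighted_norm_params(x, r1)
        return dict(mu0=mu0, sigma0=s0, mu1=mu1, sigma1=s1, pi=pi)

    theta, resp, trace, converged, n_iter = _em_loop(e_step, m_step, theta, max_iter, tol)
    if theta["mu0"] > theta["mu1"]:  # identifiability: signal is the upper component
        theta = dict(
            mu0=theta["mu1"],
            sigma0=theta["sigma1"],
            mu1=theta["mu0"],
            sigma1=theta["sigma0"],
            pi=1.0 - theta["pi"],
        )
        resp = 1.0 - resp
    pi = theta.pop("pi")
    return MixtureFit("gauss", theta, pi, resp, trace, converged, n_iter, seed)


def fit_gauss_gauss_nonzero(
    y: np.ndarray,
    max_iter: int = 500,
    tol: float = 1e-6,
    seed: int | None = None,
    init: str = "quantile",
) -> MixtureFit:
    """Gaussian-Gaussian mixture fitted on nonzero counts only.

    Cells with y = 0 take no part in the fit and receive signal
    responsibility 0.

    Dropping the zeros removes the background class the full model
    relies on, so the nonzero counts may form a single (signal) cluster
    with no ambient cluster below it.  A two-component fit would then
    split the signal in half.  The fit therefore checks whether the data
    support two components at all -- Ashman's D >= 2 (components
    separated relative to their widths) and a BIC preference for two
    components over one -- and otherwise declares the nonzero counts
    unimodal signal: background weight 0, signal responsibility 1 for
    every nonzero count.  A guide whose nonzero counts are pure ambient
    is mis-called by this rule (its decision threshold degenerates to 1,
    which is visible in the assignment parameters).
    """
    y = _prepare(y)
    nz = y > 0
    if len(np.unique(y[nz])) < 2:
        raise DegenerateFitError("fewer than 2 distinct nonzero values")
    sub = fit_gauss_gauss(y[nz], max_iter=max_iter, tol=tol, seed=seed, init=init)
    p = sub.params
    ashman_d = np.sqrt(2.0) * abs(p["mu1"] - p["mu0"]) / np.sqrt(
        p["sigma0"] ** 2 + p["sigma1"] ** 2
    )
    x = np.log2(y[nz] + 1.0)
    n = x.size
    ll1 = float(norm.logpdf(x, x.mean(), max(x.std(), SIGMA_FLOOR)).sum())
    bic1 = -2.0 * ll1 + 2.0 * np.log(n)
    bic2 = -2.0 * float(sub.loglik_trace[-1]) + 5.0 * np.log(n)
    # ambient molecules come in ones and twos; a "background" component
    # centered at >= ~3 UMIs (log2 scale >= 2) cannot be ambient, so a weak
    # two-component split there is read as one signal cluster instead
    lower_is_high = p["mu0"] >= 2.0
    unimodal = lower_is_high and (ashman_d < 2.0 or bic1 <= bic2)
    extras = {
        "n_zero_excluded": int((~nz).sum()),
        "ashman_d": float(ashman_d),
        "bic_one_component": bic1,
        "bic_two_component": bic2,
        "unimodal": bool(unimodal),
    }
    resp = np.zeros(y.size)
    if unimodal:
        resp[nz] = 1.0
        params = {
            "mu0": 0.0,
            "sigma0": SIGMA_FLOOR,
            "mu1": float(x.mean()),
            "sigma1": float(max(x.std(), SIGMA_FLOOR)),
        }
        return MixtureFit(
            "gauss_nonzero", params, 0.0, resp, sub.loglik_trace,
            sub.converged, sub.n_iter, seed, extras,
        )
    resp[nz] = sub.responsibilities
    return MixtureFit(
        "gauss_nonzero", sub.params, sub.pi, resp, sub.loglik_trace,
        sub.converged, sub.n_iter, seed, extras,
    )


def _signal_logpdf(k: np.ndarray, x: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    # discretized log-normal: Normal at log2(k+1) with change-of-variables factor
    return norm.logpdf(x, mu, sigma) - np.log((k + 1.0) * LN2)


def fit_pois_gauss(
    y: np.ndarray,
    max_iter: int = 500,
    tol: float = 1e-6,
    seed: int | None = None,
    init: str = "quantile",
) -> MixtureFit:
    """EM fit of pi*Poisson(k; lam) + (1-pi)*LogNormalDiscrete(k; mu, sigma)."""
    y = _prepare(y)
    x = np.log2(y + 1.0)
    if len(np.unique(y)) < 2:
        raise DegenerateFitError("all observations identical")
    rng = np.random.default_rng(seed) if seed is not None else None
    loc0, mu1, sigma, pi = _init_locations(x, init, rng)
    theta = dict(lam=max(2.0**loc0 - 1.0, 1e-3), mu1=mu1, sigma1=sigma, pi=pi)

    def e_step(th):
        lb = np.log(th["pi"]) + poisson.logpmf(y, max(th["lam"], 1e-12))
        ls = np.log1p(-th["pi"]) + _signal_logpdf(y, x, th["mu1"], th["sigma1"])
        tot = np.logaddexp(lb, ls)
        return float(tot.sum()), np.exp(ls - tot)

    def m_step(r1, th):
        r0 = 1.0 - r1
        lam = float((r0 * y).sum() / max(r0.sum(), 1e-12))
        mu1, s1 = _weighted_norm_params(x, r1)
        pi = float(np.clip(r0.mean(), 1e-6, 1 - 1e-6))
        return dict(lam=lam, mu1=mu1, sigma1=s1, pi=pi)

    theta, resp, trace, converged, n_iter = _em_loop(e_step, m_step, theta, max_iter, tol)
    pi = theta.pop("pi")
    fit = MixtureFit("pois_gauss", theta, pi, resp, trace, converged, n_iter, seed)
    if theta["mu1"] < np.log2(theta["lam"] + 1.0):
        logger.warning("pois_gauss: signal mean below background on log2 scale")
        fit.extras["labels_ok"] = False
    return fit


def _nb_logpmf(k: np.ndarray, lam: float, alpha: float) -> np.ndarray:
    lam = max(lam, 1e-12)
    return nbinom.logpmf(k, alpha, alpha / (alpha + lam))


def fit_nb_gauss(
    y: np.ndarray,
    max_iter: int = 500,
    tol: float = 1e-6,
    seed: int | None = None,
    init: str = "quantile",
    alpha_bounds: tuple[float, float] = (1e-2, 1e6),
) -> MixtureFit:
    """As :func:`fit_pois_gauss` with a negative-binomial background.

    The background has mean ``lam`` and dispersion ``alpha`` (variance
    lam + lam^2/alpha).  In each M-step the mean is the weighted average
    (its exact MLE for any fixed alpha) and alpha maximizes the weighted
    NB log-likelihood by bounded scalar optimization, so the EM
    log-likelihood is non-decreasing.  Large fitted alpha means the
    background is effectively Poisson.
    """
    y = _prepare(y)
    x = np.log2(y + 1.0)
    if len(np.unique(y)) < 2:
        raise DegenerateFitError("all observations identical")
    rng = np.random.default_rng(seed) if seed is not None else None
    loc0, mu1, sigma, pi = _init_locations(x, init, rng)
    theta = dict(
        lam=max(2.0**loc0 - 1.0, 1e-3), alpha=10.0, mu1=mu1, sigma1=sigma, pi=pi
    )

    def e_step(th):
        lb = np.log(th["pi"]) + _nb_logpmf(y, th["lam"], th["alpha"])
        ls = np.log1p(-th["pi"]) + _signal_logpdf(y, x, th["mu1"], th["sigma1"])
        tot = np.logaddexp(lb, ls)
        return float(tot.sum()), np.exp(ls - tot)

    def m_step(r1, th):
        r0 = 1.0 - r1
        lam = float((r0 * y).sum() / max(r0.sum(), 1e-12))

        def neg_ll(log_alpha):
            return -float((r0 * _nb_logpmf(y, lam, 10.0**log_alpha)).sum())

        res = minimize_scalar(
            neg_ll,
            bounds=(np.log10(alpha_bounds[0]), np.log10(alpha_bounds[1])),
            method="bounded",
            options={"xatol": 1e-8},
        )
        # keep the previous dispersion when the search lands on a marginally
        # worse point of the (often flat) profile likelihood, so the EM
        # log-likelihood stays non-decreasing
        alpha = float(10.0**res.x)
        if neg_ll(np.log10(th["alpha"])) < res.fun:
            alpha = th["alpha"]
        mu1, s1 = _weighted_norm_params(x, r1)
        pi = float(np.clip(r0.mean(), 1e-6, 1 - 1e-6))
        return dict(lam=lam, alpha=alpha, mu1=mu1, sigma1=s1, pi=pi)

    theta, resp, trace, converged, n_iter = _em_loop(e_step, m_step, theta, max_iter, tol)
    pi = theta.pop("pi")
    return MixtureFit("nb_gauss", theta, pi, resp, trace, converged, n_iter, seed)


_FITTERS = {
    "gauss": fit_gauss_gauss,
    "gauss_nonzero": fit_gauss_gauss_nonzero,
    "pois_gauss": fit_pois_gauss,
    "nb_gauss": fit_nb_gauss,
}


def assign_from_mixture(
    matrix: GuideCountMatrix,
    model: str,
    prob_cutoff: float = 0.5,
    seed: int | None = None,
    **fit_kwargs,
) -> AssignmentTable:
    """Assign guides by per-gRNA mixture fits.

    Every (cell, guide) pair whose signal responsibility exceeds
    ``prob_cutoff`` is called.  Cells with zero total guide counts are
    excluded from all fits and never assigned.  Guides whose fit is
    degenerate are skipped with a warning and yield no calls.  The
    per-guide integer decision threshold (smallest count whose
    responsibility exceeds the cutoff) is recorded in ``params``.
    """
    if model not in _FITTERS:
        raise ParameterError(f"unknown mixture model {model!r}; choose from {MODELS}")
    if not 0 <= prob_cutoff <= 1:
        raise ParameterError("prob_cutoff must lie in [0, 1]")
    fitter = _FITTERS[model]
    included = matrix.total_counts() > 0
    cell_ids = matrix.cell_ids[included]
    csc = matrix.counts.tocsc()

    frames = []
    thresholds: dict[str, int | None] = {}
    n_failed = 0
    for j, guide in enumerate(matrix.guide_ids):
        y = np.zeros(matrix.n_cells)
        col = csc.getcol(j).tocoo()
        y[col.row] = col.data
        y = y[included]
        try:
            fit = fitter(y, seed=seed, **fit_kwargs)
        except DegenerateFitError as exc:
            logger.warning("skipping guide %s: %s", guide, exc)
            thresholds[str(guide)] = None
            n_failed += 1
            continue
        hit = fit.responsibilities > prob_cutoff
        if hit.any():
            frames.append(
                pd.DataFrame(
                    {
                        "cell": cell_ids[hit],
                        "guide": guide,
                        "prob": fit.responsibilities[hit],
                    }
                )
            )
        thresholds[str(guide)] = fit.decision_threshold(
            int(y.max()) + 1, prob_cutoff
        )
    calls = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["cell", "guide", "prob"])
    )
    return AssignmentTable(
        model,
        calls,
        {
            "model": model,
            "prob_cutoff": prob_cutoff,
            "seed": seed,
            "thresholds": thresholds,
            "n_failed_guides": n_failed,
        },
    )
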