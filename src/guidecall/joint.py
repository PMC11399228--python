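"""Strategies using information across cells *and* gRNAs.

Two families:

* A per-gRNA Poisson GLM with the cell's total guide UMIs as library-size
  offset: k_cg ~ Poisson(exp(beta0 + beta1 * z_c + log L_c)) with a latent
  perturbation indicator z_c.  Fitted by EM; the M-step solves the
  weighted Poisson GLM in closed form (two weighted rate estimates).
* Beta mixtures (2 or 3 components) on the per-cell maximal relative
  guide frequency f_c, fitted per batch.  These replace the user-defined
  ratio threshold by a learnt per-batch threshold: the smallest frequency
  whose top-component posterior exceeds the probability cutoff.  With
  three components the middle component absorbs ambiguous/multiplet cells,
  which are reported separately and never called.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import betaln
from scipy.stats import poisson

from .core import AssignmentTable, DegenerateFitError, GuideCountMatrix, ParameterError
from .simple import ratio_profile

logger = logging.getLogger(__name__)

FREQ_EPS = 1e-4

__all__ = [
    "GlmMixtureFit",
    "BetaMixtureFit",
    "fit_poisson_glm",
    "fit_poisson_glm_counts",
    "assign_glm",
    "compute_max_frequencies",
    "fit_beta_mixture",
    "assign_beta",
]


@dataclass
class GlmMixtureFit:
    """Fitted latent-indicator Poisson GLM for one gRNA.

    ``beta0`` is the background log-rate per library-size unit, ``beta1``
    the perturbation log-rate increment (constrained positive by component
    relabeling), ``pi`` the perturbed fraction.
    """

    beta0: float
    beta1: float
    pi: float
    responsibilities: np.ndarray
    loglik_trace: np.ndarray
    converged: bool
    n_iter: int
    extras: dict = field(default_factory=dict)

    def responsibility(self, k: np.ndarray, lib_size: np.ndarray) -> np.ndarray:
        """Posterior P(z=1 | k, L) at counts k and library sizes L."""
        k = np.atleast_1d(np.asarray(k, dtype=float))
        lib = np.atleast_1d(np.asarray(lib_size, dtype=float))
        mu0 = np.exp(self.beta0) * lib
        mu1 = np.exp(self.beta0 + self.beta1) * lib
        with np.errstate(divide="ignore"):
            l0 = np.log(max(1.0 - self.pi, 1e-300)) + poisson.logpmf(k, mu0)
            l1 = np.log(self.pi) + poisson.logpmf(k, mu1) if self.pi > 0 else np.full_like(k, -np.inf)
        out = np.exp(l1 - np.logaddexp(l0, l1))
        return np.where(np.isfinite(out), out, 0.0)

    def decision_threshold(
        self, lib_size: float, max_count: int, prob_cutoff: float = 0.5
    ) -> int | None:
        ks = np.arange(0, max_count + 1)
        resp = self.responsibility(ks, np.full(ks.shape, lib_size))
        hits = np.flatnonzero(resp > prob_cutoff)
        return int(ks[hits[0]]) if hits.size else None


def fit_poisson_glm_counts(
    y: np.ndarray,
    lib_size: np.ndarray,
    max_iter: int = 500,
    tol: float = 1e-6,
    fix_pi: float | None = None,
) -> GlmMixtureFit:
    """EM fit of the latent-indicator Poisson GLM from raw arrays."""
    y = np.asarray(y, dtype=float)
    lib = np.asarray(lib_size, dtype=float)
    if y.size == 0 or y.sum() == 0:
        raise DegenerateFitError("guide column has no counts")
    if np.any(lib <= 0):
        raise DegenerateFitError("library sizes must be positive for modeled cells")

    base = y.sum() / lib.sum()
    rate0, rate1 = base / 10.0, base * 10.0
    pi = 0.1 if fix_pi is None else float(fix_pi)

    def e_step(th):
        r0, r1, p = th
        with np.errstate(divide="ignore"):
            l0 = np.log(max(1 - p, 1e-300)) + poisson.logpmf(y, np.maximum(r0 * lib, 1e-300))
            l1 = (np.log(p) + poisson.logpmf(y, np.maximum(r1 * lib, 1e-300))
                  if p > 0 else np.full_like(y, -np.inf))
        tot = np.logaddexp(l0, l1)
        resp = np.exp(l1 - tot)
        return float(tot.sum()), np.where(np.isfinite(resp), resp, 0.0)

    def m_step(resp, th):
        w1, w0 = resp, 1.0 - resp
        r1 = (w1 * y).sum() / max((w1 * lib).sum(), 1e-300) if w1.sum() > 1e-12 else th[1]
        r0 = (w0 * y).sum() / max((w0 * lib).sum(), 1e-300)
        p = float(np.clip(resp.mean(), 1e-6, 1 - 1e-6)) if fix_pi is None else float(fix_pi)
        return (max(r0, 1e-300), max(r1, 1e-300), p)

    theta = (max(rate0, 1e-300), max(rate1, 1e-300), pi)
    trace = []
    resp = np.zeros_like(y)
    converged = False
    n_iter = max_iter
    for it in range(1, max_iter + 1):
        ll, resp = e_step(theta)
        trace.append(ll)
        if len(trace) > 1 and abs(trace[-1] - trace[-2]) < tol * (abs(trace[-2]) + 1.0):
            converged, n_iter = True, it
            break
        theta = m_step(resp, theta)
    if not converged:
        ll, resp = e_step(theta)
        trace.append(ll)
    rate0, rate1, pi = theta
    if rate1 < rate0 and fix_pi is None:  # enforce beta1 > 0 by component swap
        rate0, rate1 = rate1, rate0
        pi = 1.0 - pi
        resp = 1.0 - resp
    return GlmMixtureFit(
        beta0=float(np.log(rate0)),
        beta1=float(np.log(rate1 / rate0)),
        pi=float(pi),
        responsibilities=resp,
        loglik_trace=np.asarray(trace),
        converged=converged,
        n_iter=n_iter,
    )


def fit_poisson_glm(
    matrix: GuideCountMatrix, guide_id: str, **kwargs
) -> GlmMixtureFit:
    """Fit the latent-indicator Poisson GLM for one guide of a matrix.

    Only cells with positive total guide counts are modeled.
    """
    totals = matrix.total_counts()
    included = totals > 0
    y = matrix.guide_column(guide_id)[included]
    fit = fit_poisson_glm_counts(y, totals[included], **kwargs)
    fit.extras["included_cells"] = matrix.cell_ids[included]
    return fit


def assign_glm(
    matrix: GuideCountMatrix, prob_cutoff: float = 0.5, **kwargs
) -> AssignmentTable:
    """Assign guides by per-gRNA Poisson GLM fits (calls where P(z=1) > cutoff)."""
    if not 0 <= prob_cutoff <= 1:
        raise ParameterError("prob_cutoff must lie in [0, 1]")
    totals = matrix.total_counts()
    included = totals > 0
    cell_ids = matrix.cell_ids[included]
    lib = totals[included]
    csc = matrix.counts.tocsc()
    frames = []
    thresholds: dict[str, int | None] = {}
    for j, guide in enumerate(matrix.guide_ids):
        y = np.zeros(matrix.n_cells)
        col = csc.getcol(j).tocoo()
        y[col.row] = col.data
        y = y[included]
        try:
            fit = fit_poisson_glm_counts(y, lib, **kwargs)
        except DegenerateFitError as exc:
            logger.warning("skipping guide %s: %s", guide, exc)
            thresholds[str(guide)] = None
            continue
        hit = fit.responsibilities > prob_cutoff
        if hit.any():
            frames.append(
                pd.DataFrame(
                    {"cell": cell_ids[hit], "guide": guide, "prob": fit.responsibilities[hit]}
                )
            )
        thresholds[str(guide)] = fit.decision_threshold(
            float(np.median(lib)), int(y.max()) + 1, prob_cutoff
        )
    calls = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["cell", "guide", "prob"])
    )
    return AssignmentTable(
        "glm", calls, {"prob_cutoff": prob_cutoff, "thresholds_at_median_L": thresholds}
    )


def compute_max_frequencies(
    matrix: GuideCountMatrix, eps: float = FREQ_EPS
) -> pd.DataFrame:
    """Top-guide relative frequency per cell, clipped to [eps, 1-eps].

    Returns the :func:`ratio_profile` frame with an extra column ``f``
    holding the clipped frequency (Beta support excludes 0 and 1; only
    cells whose counts all come from a single guide are affected by the
    clip).  Zero-count cells are excluded.
    """
    profile = ratio_profile(matrix)
    profile["f"] = np.clip(profile["top_fraction"], eps, 1.0 - eps)
    return profile


@dataclass
class BetaMixtureFit:
    """Per-batch Beta mixture on maximal relative guide frequencies.

    Components are sorted by mean; only the highest-mean ("top")
    component yields assignment calls.  ``threshold`` is the learnt
    frequency threshold: the smallest f whose top-component posterior
    exceeds the probability cutoff used at fit time.
    """

    a: np.ndarray
    b: np.ndarray
    weights: np.ndarray
    threshold: float | None
    responsibilities: np.ndarray  # n_obs x n_components
    loglik_trace: np.ndarray
    converged: bool
    n_iter: int
    batch: str | None = None

    @property
    def means(self) -> np.ndarray:
        return self.a / (self.a + self.b)

    def posterior(self, f: np.ndarray) -> np.ndarray:
        """Component responsibilities at frequencies f (rows sum to 1)."""
        f = np.atleast_1d(np.asarray(f, dtype=float))
        logp = _beta_logpdf(f[:, None], self.a[None, :], self.b[None, :])
        logp = logp + np.log(self.weights)[None, :]
        logp -= logp.max(axis=1, keepdims=True)
        p = np.exp(logp)
        return p / p.sum(axis=1, keepdims=True)


def _beta_logpdf(f, a, b):
    return (a - 1.0) * np.log(f) + (b - 1.0) * np.log1p(-f) - betaln(a, b)


def _moment_init(f: np.ndarray, n_components: int) -> tuple[np.ndarray, np.ndarray]:
    """Method-of-moments Beta shapes from quantile-sliced chunks.

    Chunks are sliced over the *distinct* frequencies so that heavily
    repeated values (e.g. the clip boundary when many cells carry a
    single guide) cannot seed two identical components.
    """
    order = np.unique(f)
    if len(order) < n_components:
        order = np.sort(f)
    chunks = np.array_split(order, n_components)
    a, b = [], []
    for chunk in chunks:
        m = float(np.clip(chunk.mean(), 1e-3, 1 - 1e-3))
        v = float(max(chunk.var(), 1e-6))
        common = max(m * (1 - m) / v - 1.0, 0.1)
        a.append(np.clip(m * common, 1e-2, 1e4))
        b.append(np.clip((1 - m) * common, 1e-2, 1e4))
    return np.array(a), np.array(b)


def fit_beta_mixture(
    f: np.ndarray,
    n_components: int = 2,
    max_iter: int = 500,
    tol: float = 1e-6,
    prob_cutoff: float = 0.5,
    batch: str | None = None,
) -> BetaMixtureFit:
    """EM fit of a 2- or 3-component Beta mixture on frequencies in (0, 1).

    The M-step updates each component's shape pair by numerically
    maximizing its weighted Beta log-likelihood (Newton-type updates with
    method-of-moments initialization); there is no closed form.
    """
    if n_components not in (2, 3):
        raise ParameterError("n_components must be 2 or 3")
    f = np.asarray(f, dtype=float)
    if f.size < 10:
        raise DegenerateFitError(f"need >= 10 observations, got {f.size}")
    if np.any((f <= 0) | (f >= 1)):
        raise DegenerateFitError("frequencies must lie strictly in (0, 1)")
    if np.unique(f).size < 2:
        raise DegenerateFitError("all frequencies identical")

    a, b = _moment_init(f, n_components)
    w = np.full(n_components, 1.0 / n_components)
    logf, log1mf = np.log(f), np.log1p(-f)

    def e_step(a, b, w):
        logp = _beta_logpdf(f[:, None], a[None, :], b[None, :]) + np.log(w)[None, :]
        mx = logp.max(axis=1, keepdims=True)
        tot = mx.ravel() + np.log(np.exp(logp - mx).sum(axis=1))
        resp = np.exp(logp - tot[:, None])
        return float(tot.sum()), resp

    def mle_component(r, a0, b0):
        rsum = max(r.sum(), 1e-12)
        s1, s2 = (r * logf).sum() / rsum, (r * log1mf).sum() / rsum

        def neg_ll(t):
            ai, bi = np.exp(t)
            return -((ai - 1) * s1 + (bi - 1) * s2 - betaln(ai, bi))

        res = minimize(
            neg_ll,
            x0=np.log([a0, b0]),
            method="L-BFGS-B",
            bounds=[(np.log(1e-2), np.log(1e6))] * 2,
        )
        return np.exp(res.x)

    trace = []
    resp = None
    converged = False
    n_iter = max_iter
    for it in range(1, max_iter + 1):
        ll, resp = e_step(a, b, w)
        trace.append(ll)
        if len(trace) > 1 and abs(trace[-1] - trace[-2]) < tol * (abs(trace[-2]) + 1.0):
            converged, n_iter = True, it
            break
        for i in range(n_components):
            a[i], b[i] = mle_component(resp[:, i], a[i], b[i])
        w = np.clip(resp.mean(axis=0), 1e-6, None)
        w = w / w.sum()
    if not converged:
        ll, resp = e_step(a, b, w)
        trace.append(ll)

    order = np.argsort(a / (a + b))
    a, b, w = a[order], b[order], w[order]
    # merge components that collapsed onto each other during EM: they are
    # exchangeable, so splitting their weight would halve the posterior of
    # what is really one component
    keep = [0]
    for i in range(1, len(a)):
        j = keep[-1]
        same_mean = abs(a[i] / (a[i] + b[i]) - a[j] / (a[j] + b[j])) < 1e-4
        same_conc = abs(np.log(a[i] + b[i]) - np.log(a[j] + b[j])) < 0.1
        if same_mean and same_conc:
            w[j] += w[i]
        else:
            keep.append(i)
    a, b, w = a[keep], b[keep], w[keep]
    fit = BetaMixtureFit(
        a, b, w, None, np.empty((0, len(a))), np.asarray(trace), converged,
        n_iter, batch,
    )
    fit.responsibilities = fit.posterior(f)
    grid = np.arange(1, 10000) / 10000.0
    top = fit.posterior(grid)[:, -1]
    hits = np.flatnonzero(top > prob_cutoff)
    fit.threshold = float(grid[hits[0]]) if hits.size else None
    return fit


def assign_beta(
    matrix: GuideCountMatrix,
    n_components: int = 2,
    prob_cutoff: float = 0.5,
    min_batch: int = 10,
    eps: float = FREQ_EPS,
) -> AssignmentTable:
    """Assign the top guide per cell using per-batch Beta mixtures.

    A cell is called when its top guide is unique and its clipped maximal
    frequency reaches the batch's learnt threshold (the smallest f whose
    top-component posterior exceeds ``prob_cutoff``).  Batches smaller
    than ``min_batch`` fall back to the pooled fit.  For ``n_components=3``
    the cells dominated by the middle component are reported in
    ``params['ambiguous_cells']`` and never called.
    """
    if not 0 <= prob_cutoff <= 1:
        raise ParameterError("prob_cutoff must lie in [0, 1]")
    profile = compute_max_frequencies(matrix, eps=eps)
    pooled_fit = None

    def get_pooled():
        nonlocal pooled_fit
        if pooled_fit is None:
            pooled_fit = fit_beta_mixture(
                profile["f"].to_numpy(), n_components, prob_cutoff=prob_cutoff,
                batch="pooled",
            )
        return pooled_fit

    frames = []
    ambiguous: list[str] = []
    batch_params: dict[str, dict] = {}
    for batch, grp in profile.groupby("batch", sort=True):
        fvals = grp["f"].to_numpy()
        try:
            if len(grp) < min_batch:
                logger.warning(
                    "batch %s has %d cells (< %d); using pooled fit",
                    batch, len(grp), min_batch,
                )
                fit = get_pooled()
            else:
                fit = fit_beta_mixture(
                    fvals, n_components, prob_cutoff=prob_cutoff, batch=str(batch)
                )
        except DegenerateFitError as exc:
            logger.warning("skipping batch %s: %s", batch, exc)
            continue
        batch_params[str(batch)] = {
            "a": fit.a.tolist(),
            "b": fit.b.tolist(),
            "weights": fit.weights.tolist(),
            "threshold": fit.threshold,
        }
        if fit.threshold is None:
            continue
        post = fit.posterior(fvals)
        callable_ = (~grp["tie"].to_numpy()) & (fvals >= fit.threshold)
        if n_components == 3 and post.shape[1] == 3:
            mid = post.argmax(axis=1) == 1
            ambiguous.extend(grp["cell"].to_numpy()[mid & ~callable_].tolist())
        if callable_.any():
            frames.append(
                pd.DataFrame(
                    {
                        "cell": grp["cell"].to_numpy()[callable_],
                        "guide": grp["top_guide"].to_numpy()[callable_],
                        "prob": post[callable_, -1],
                    }
                )
            )
    calls = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["cell", "guide", "prob"])
    )
    params = {
        "n_components": n_components,
        "prob_cutoff": prob_cutoff,
        "batches": batch_params,
    }
    if n_components == 3:
        params["ambiguous_cells"] = ambiguous
    return AssignmentTable(f"beta_{n_components}", calls, params)
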