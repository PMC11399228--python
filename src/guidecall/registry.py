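"""Registry of all guide-assignment strategies behind one call signature.

Every entry maps a method name to ``fn(matrix, seed=None, **overrides)``
returning an :class:`~guidecall.core.AssignmentTable`.  Threshold-style
methods carry sensible low-MOI defaults (UMI threshold 5, ratio 0.8);
model-based methods default to a posterior cutoff of 0.5.  Overrides are
passed straight through to the underlying function.
"""

from __future__ import annotations

from typing import Callable

from .core import AssignmentTable, GuideCountMatrix, ParameterError
from .joint import assign_beta, assign_glm
from .mixture import assign_from_mixture
from .simple import assign_maximum, assign_ratio, assign_umi_threshold

__all__ = ["METHODS", "run_method", "run_all_methods"]


def _umi(m, seed=None, t=5, **kw):
    return assign_umi_threshold(m, t=t, **kw)


def _maximum(m, seed=None, **kw):
    return assign_maximum(m, **kw)


def _ratio(m, seed=None, r=0.8, **kw):
    return assign_ratio(m, r=r, **kw)


def _mixture(model):
    def run(m, seed=None, **kw):
        return assign_from_mixture(m, model=model, seed=seed, **kw)

    return run


def _glm(m, seed=None, **kw):
    return assign_glm(m, **kw)


def _beta(n):
    def run(m, seed=None, **kw):
        return assign_beta(m, n_components=n, **kw)

    return run


METHODS: dict[str, Callable[..., AssignmentTable]] = {
    "umi_threshold": _umi,
    "maximum": _maximum,
    "ratio": _ratio,
    "gauss": _mixture("gauss"),
    "gauss_nonzero": _mixture("gauss_nonzero"),
    "pois_gauss": _mixture("pois_gauss"),
    "nb_gauss": _mixture("nb_gauss"),
    "glm": _glm,
    "beta_2": _beta(2),
    "beta_3": _beta(3),
}


def run_method(
    name: str, matrix: GuideCountMatrix, seed: int | None = None, **overrides
) -> AssignmentTable:
    """Run one named strategy on a guide count matrix."""
    if name not in METHODS:
        raise ParameterError(f"unknown method {name!r}; choose from {sorted(METHODS)}")
    table = METHODS[name](matrix, seed=seed, **overrides)
    table.method_name = name
    return table


def run_all_methods(
    matrix: GuideCountMatrix,
    seed: int | None = None,
    overrides: dict[str, dict] | None = None,
) -> list[AssignmentTable]:
    """Run every registered strategy; per-method overrides by name."""
    overrides = overrides or {}
    return [
        run_method(name, matrix, seed=seed, **overrides.get(name, {}))
        for name in METHODS
    ]
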