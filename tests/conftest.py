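"""Shared fixtures: handwritten matrices and cached simulated screens."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

import guidecall as gc


def matrix_from_dict(rows: dict[str, dict[str, int]], guides=None) -> gc.GuideCountMatrix:
    """Build a GuideCountMatrix from {cell: {guide: count}}."""
    cells = list(rows)
    if guides is None:
        guides = sorted({g for r in rows.values() for g in r})
    dense = np.array(
        [[rows[c].get(g, 0) for g in guides] for c in cells], dtype=np.int64
    )
    return gc.GuideCountMatrix(
        sp.csr_matrix(dense),
        cell_ids=np.array(cells, dtype=object),
        guide_ids=np.array(guides, dtype=object),
    )


@pytest.fixture
def two_cell_matrix() -> gc.GuideCountMatrix:
    """c1: (gA=5, gB=0); c2: (gA=1, gB=3)."""
    return matrix_from_dict({"c1": {"gA": 5}, "c2": {"gA": 1, "gB": 3}})


@pytest.fixture(scope="session")
def separated_screen():
    return gc.simulate_screen(gc.scenario_config("separated", seed=11))


@pytest.fixture(scope="session")
def contaminated_screen():
    return gc.simulate_screen(gc.scenario_config("contaminated", seed=11))


@pytest.fixture(scope="session")
def two_batch_screen():
    return gc.simulate_screen(gc.scenario_config("two_batch", seed=11))


def make_expression_context(
    assigned: dict[str, float], controls: dict[str, float], target="geneT"
) -> gc.ExpressionContext:
    """Context with one target gene whose per-10k expression is given exactly.

    Each cell gets a filler gene bringing its total to the normalization
    target, so the normalized target expression equals the raw value.
    """
    cells = list(assigned) + list(controls)
    vals = list(assigned.values()) + list(controls.values())
    expr = pd.DataFrame(
        {target: vals, "filler": [1e4 - v for v in vals]}, index=cells
    )
    guide_map = pd.DataFrame(
        {"target_gene": [target, ""], "targeting": [True, False]},
        index=["gT", "gNT"],
    )
    return gc.ExpressionContext(expr, guide_map)
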