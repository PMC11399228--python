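"""Comparison framework for guide-assignment strategies.

Implements the four comparison criteria used to judge an assignment in a
CRISPRi screen: (i) the number of (uniquely) assigned cells, (ii)
downregulation of the target gene in assigned cells, (iii) the number of
discoveries -- genes differentially expressed between cells assigned to a
targeting gRNA and control cells -- and (iv) the number of false
discoveries from testing one non-targeting gRNA's cells against the
remaining control cells, where no true effect exists.  Also provides the
pairwise Jaccard similarity of assignments, a threshold grid search that
picks the value maximizing the number of significant target genes, and
precision/recall scoring against simulated ground truth.

Differential expression is deliberately simple plumbing: a rank-sum
(Mann-Whitney) test on log-normalized expression with Benjamini-Hochberg
correction across all tested pairs.  It makes discovery counts computable
and calibrated but is not a replacement for dedicated single-cell DE
engines.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .core import AssignmentTable, EvaluationError, GuideCountMatrix, ParameterError
from .simple import assign_ratio, assign_umi_threshold

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionContext",
    "EvalReport",
    "unique_assignments",
    "jaccard_matrix",
    "target_downregulation",
    "median_target_downregulation",
    "count_discoveries",
    "count_false_discoveries",
    "threshold_grid_search",
    "score_vs_truth",
    "summarize_assignments",
    "build_report",
]


@dataclass
class ExpressionContext:
    """Gene expression read-out plus the gRNA -> target-gene map.

    ``expr`` holds raw counts (cells x genes).  ``guide_map`` is indexed
    by guide id with columns ``target_gene`` (empty for non-targeting
    guides) and ``targeting`` (bool).  Normalization is counts-per-10k
    followed by log1p, the common single-cell default.
    """

    expr: pd.DataFrame
    guide_map: pd.DataFrame
    norm_target: float = 1e4
    _normed: pd.DataFrame | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        need = {"target_gene", "targeting"}
        if not need.issubset(self.guide_map.columns):
            raise EvaluationError(f"guide_map needs columns {sorted(need)}")
        targets = self.guide_map.loc[
            self.guide_map["targeting"], "target_gene"
        ].unique()
        missing = set(targets) - set(self.expr.columns)
        if missing:
            raise EvaluationError(
                f"target genes absent from expression matrix: {sorted(missing)[:5]}"
            )

    @property
    def targeting_guides(self) -> np.ndarray:
        return self.guide_map.index[self.guide_map["targeting"]].to_numpy()

    @property
    def nontargeting_guides(self) -> np.ndarray:
        return self.guide_map.index[~self.guide_map["targeting"]].to_numpy()

    def normalized_linear(self) -> pd.DataFrame:
        """Counts-per-``norm_target`` expression (linear scale), cached.

        Fold changes are computed on this scale so that a simulated
        2^-k knockdown reads out as a log2 fold change of -k.
        """
        if self._normed is None:
            totals = self.expr.sum(axis=1).to_numpy()[:, None]
            scaled = self.expr.to_numpy(float) / np.maximum(totals, 1) * self.norm_target
            self._normed = pd.DataFrame(
                scaled, index=self.expr.index, columns=self.expr.columns
            )
        return self._normed

    def normalized(self) -> pd.DataFrame:
        """log1p of the counts-per-``norm_target`` expression.

        The rank tests are invariant to this monotone transform; it is
        provided as the conventional representation for display and for
        external DE tools.
        """
        return np.log1p(self.normalized_linear())


def unique_assignments(table: AssignmentTable) -> AssignmentTable:
    """Restrict a table to cells carrying exactly one call."""
    counts = table.calls["cell"].value_counts()
    singles = counts.index[counts == 1]
    kept = table.calls[table.calls["cell"].isin(singles)]
    return AssignmentTable(table.method_name, kept.copy(), dict(table.params))


def _unique_pairs(table: AssignmentTable) -> set[tuple[str, str]]:
    return unique_assignments(table).pairs


def jaccard_matrix(tables: Sequence[AssignmentTable]) -> pd.DataFrame:
    """Pairwise Jaccard index of uniquely-assigned (cell, guide) pairs.

    Two empty assignments are defined to agree perfectly (index 1.0).
    """
    names = [t.method_name for t in tables]
    sets = [_unique_pairs(t) for t in tables]
    n = len(tables)
    out = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            union = len(sets[i] | sets[j])
            out[i, j] = out[j, i] = (
                len(sets[i] & sets[j]) / union if union else 1.0
            )
    return pd.DataFrame(out, index=names, columns=names)


def control_cells(table: AssignmentTable, ctx: ExpressionContext) -> np.ndarray:
    """Cells uniquely assigned to any non-targeting gRNA."""
    uniq = unique_assignments(table).calls
    nt = set(ctx.nontargeting_guides)
    return uniq.loc[uniq["guide"].isin(nt), "cell"].to_numpy()


def target_downregulation(
    table: AssignmentTable, ctx: ExpressionContext, pseudocount: float = 0.01
) -> pd.Series:
    """Per targeting gRNA: log2 fold change of its target gene.

    log2FC = log2[(mean normalized target expression in cells uniquely
    assigned to the guide + p) / (mean in control cells + p)], with
    normalization on the linear counts-per-10k scale.  Guides without
    assigned cells are omitted (NaN-free series).
    """
    normed = ctx.normalized_linear()
    uniq = unique_assignments(table).calls
    controls = control_cells(table, ctx)
    controls = [c for c in controls if c in normed.index]
    if not controls:
        raise EvaluationError("no control cells (uniquely assigned to NT guides)")
    ctrl_mean = normed.loc[controls].mean(axis=0)
    out = {}
    for guide in ctx.targeting_guides:
        cells = uniq.loc[uniq["guide"] == guide, "cell"]
        cells = [c for c in cells if c in normed.index]
        if not cells:
            continue
        gene = ctx.guide_map.loc[guide, "target_gene"]
        num = normed.loc[cells, gene].mean() + pseudocount
        den = ctrl_mean[gene] + pseudocount
        out[guide] = float(np.log2(num / den))
    return pd.Series(out, name="log2fc", dtype=float)


def median_target_downregulation(
    table: AssignmentTable, ctx: ExpressionContext, pseudocount: float = 0.01
) -> float:
    """Median over targeting gRNAs of the negative target log2 fold change."""
    lfc = target_downregulation(table, ctx, pseudocount)
    return float(np.median(-lfc.to_numpy())) if len(lfc) else float("nan")


def _rank_test_block(
    normed: pd.DataFrame,
    group_cells: Sequence[str],
    ctrl_cells: Sequence[str],
    genes: Sequence[str],
) -> np.ndarray:
    """Two-sided rank-sum p-values for one cell group vs controls, all genes."""
    x = normed.loc[list(group_cells), list(genes)].to_numpy()
    y = normed.loc[list(ctrl_cells), list(genes)].to_numpy()
    res = mannwhitneyu(x, y, axis=0, alternative="two-sided", method="asymptotic")
    return np.asarray(res.pvalue)


@dataclass
class DiscoveryResult:
    n_discoveries: int
    n_significant_targets: int
    n_tested: int
    results: pd.DataFrame


def count_discoveries(
    table: AssignmentTable,
    ctx: ExpressionContext,
    alpha: float = 0.05,
    genes: Sequence[str] | None = None,
    guides: Sequence[str] | None = None,
    min_cells: int = 2,
) -> DiscoveryResult:
    """Count differentially expressed (gRNA, gene) pairs vs control cells.

    Tests every targeting gRNA with at least ``min_cells`` uniquely
    assigned cells against the control cells over the configured gene
    universe (default: all genes), then applies Benjamini-Hochberg across
    all tested pairs at FDR ``alpha``.  Returns the number of significant
    pairs and the number of significant (gRNA, own-target) pairs.
    """
    empty = pd.DataFrame(
        columns=["guide", "gene", "pvalue", "is_target", "significant"]
    )
    if len(table) == 0:
        return DiscoveryResult(0, 0, 0, empty)
    normed = ctx.normalized()
    genes = list(genes) if genes is not None else list(ctx.expr.columns)
    guide_list = (
        list(guides) if guides is not None else list(ctx.targeting_guides)
    )
    uniq = unique_assignments(table).calls
    controls = [c for c in control_cells(table, ctx) if c in normed.index]
    if not controls:
        raise EvaluationError("no control cells for differential expression")
    rows = []
    for guide in guide_list:
        cells = [
            c for c in uniq.loc[uniq["guide"] == guide, "cell"] if c in normed.index
        ]
        if len(cells) < min_cells:
            continue
        pvals = _rank_test_block(normed, cells, controls, genes)
        target = ctx.guide_map.loc[guide, "target_gene"]
        for gene, p in zip(genes, pvals):
            rows.append((guide, gene, p, gene == target))
    results = pd.DataFrame(rows, columns=["guide", "gene", "pvalue", "is_target"])
    if results.empty:
        return DiscoveryResult(0, 0, 0, results.assign(significant=False))
    reject = multipletests(results["pvalue"], alpha=alpha, method="fdr_bh")[0]
    results["significant"] = reject
    return DiscoveryResult(
        n_discoveries=int(reject.sum()),
        n_significant_targets=int((reject & results["is_target"]).sum()),
        n_tested=len(results),
        results=results,
    )


@dataclass
class FalseDiscoveryResult:
    n_false_discoveries: int
    false_positive_rate: float
    n_tested: int
    results: pd.DataFrame


def count_false_discoveries(
    table: AssignmentTable,
    ctx: ExpressionContext,
    alpha: float = 0.05,
    genes: Sequence[str] | None = None,
    min_cells: int = 2,
) -> FalseDiscoveryResult:
    """Leave-one-out test of each non-targeting gRNA vs the other controls.

    No true expression difference exists between these groups, so any
    significant gene is a false discovery; the rate is significant count
    over tested pairs.  An empty assignment yields zero counts.
    """
    if len(table) == 0:
        return FalseDiscoveryResult(
            0, 0.0, 0, pd.DataFrame(columns=["guide", "gene", "pvalue", "significant"])
        )
    normed = ctx.normalized()
    genes = list(genes) if genes is not None else list(ctx.expr.columns)
    uniq = unique_assignments(table).calls
    nt = ctx.nontargeting_guides
    by_guide = {
        g: [
            c for c in uniq.loc[uniq["guide"] == g, "cell"] if c in normed.index
        ]
        for g in nt
    }
    with_cells = [g for g in nt if len(by_guide[g]) >= min_cells]
    if len(with_cells) < 2:
        raise EvaluationError(
            "need >= 2 non-targeting gRNAs with assigned cells"
        )
    rows = []
    for guide in with_cells:
        others = [c for g in with_cells if g != guide for c in by_guide[g]]
        pvals = _rank_test_block(normed, by_guide[guide], others, genes)
        rows.extend((guide, gene, p) for gene, p in zip(genes, pvals))
    results = pd.DataFrame(rows, columns=["guide", "gene", "pvalue"])
    reject = multipletests(results["pvalue"], alpha=alpha, method="fdr_bh")[0]
    results["significant"] = reject
    return FalseDiscoveryResult(
        n_false_discoveries=int(reject.sum()),
        false_positive_rate=float(reject.mean()),
        n_tested=len(results),
        results=results,
    )


def threshold_grid_search(
    matrix: GuideCountMatrix,
    ctx: ExpressionContext,
    method: str,
    grid: Iterable[float],
    alpha: float = 0.05,
    genes: Sequence[str] | None = None,
) -> tuple[float, pd.DataFrame]:
    """Pick the UMI or ratio threshold maximizing significant target genes.

    Runs the method at every grid value, counts significant (gRNA,
    own-target) pairs, and returns the argmax (ties break toward the
    smaller threshold, mirroring the preference for more assigned cells).
    If no value yields any significant target the smallest grid value is
    returned with a warning.
    """
    grid = list(grid)
    if not grid:
        raise ParameterError("empty threshold grid")
    if method not in ("umi_threshold", "ratio"):
        raise ParameterError("grid search supports 'umi_threshold' and 'ratio'")
    rows = []
    for value in sorted(grid):
        if method == "umi_threshold":
            table = assign_umi_threshold(matrix, int(value))
        else:
            table = assign_ratio(matrix, float(value))
        uniq = unique_assignments(table)
        try:
            disc = count_discoveries(table, ctx, alpha=alpha, genes=genes)
            n_sig = disc.n_significant_targets
            n_disc = disc.n_discoveries
        except EvaluationError:
            n_sig, n_disc = 0, 0
        rows.append(
            {
                "value": value,
                "n_total_calls": len(table),
                "n_unique_cells": len(uniq),
                "n_significant_targets": n_sig,
                "n_discoveries": n_disc,
            }
        )
    frame = pd.DataFrame(rows)
    best = frame["n_significant_targets"].max()
    if best == 0:
        logger.warning("no grid value yields a significant target; returning smallest")
    chosen = float(frame.loc[frame["n_significant_targets"] == best, "value"].iloc[0])
    return chosen, frame


def score_vs_truth(table: AssignmentTable, truth) -> tuple[float, float, float]:
    """Precision, recall and F1 of calls against ground-truth infections.

    ``truth`` is any object with a ``pairs`` attribute holding the true
    (cell, guide) set.  With no calls precision (and F1) is undefined and
    reported as NaN; recall is 0.
    """
    calls = table.pairs
    true_pairs = truth.pairs if hasattr(truth, "pairs") else set(truth)
    tp = len(calls & true_pairs)
    recall = tp / len(true_pairs) if true_pairs else float("nan")
    if not calls:
        return float("nan"), recall, float("nan")
    precision = tp / len(calls)
    f1 = (
        2 * precision * recall / (precision + recall)
        if precision + recall > 0
        else 0.0
    )
    return precision, recall, f1


def summarize_assignments(
    tables: Sequence[AssignmentTable], ctx: ExpressionContext | None = None
) -> pd.DataFrame:
    """Per-method call counts: total assigned cells, uniquely assigned cells,
    control cells and median cells per targeting gRNA."""
    rows = []
    for table in tables:
        uniq = unique_assignments(table)
        row = {
            "method": table.method_name,
            "n_calls": len(table),
            "n_total_assigned_cells": table.calls["cell"].nunique(),
            "n_uniquely_assigned_cells": len(uniq),
        }
        if ctx is not None:
            row["n_control_cells"] = len(control_cells(table, ctx))
            per_guide = (
                uniq.calls[uniq.calls["guide"].isin(ctx.targeting_guides)]
                .groupby("guide")
                .size()
            )
            row["median_cells_per_targeting_guide"] = (
                float(per_guide.median()) if len(per_guide) else 0.0
            )
        rows.append(row)
    return pd.DataFrame(rows).set_index("method")


@dataclass
class EvalReport:
    """Bundle of per-method comparison metrics."""

    summary: pd.DataFrame
    jaccard: pd.DataFrame
    downregulation: pd.DataFrame | None = None
    discoveries: pd.DataFrame | None = None
    truth_scores: pd.DataFrame | None = None


def build_report(
    tables: Sequence[AssignmentTable],
    ctx: ExpressionContext | None = None,
    truth=None,
    alpha: float = 0.05,
    run_de: bool = True,
) -> EvalReport:
    """Compute the full method-comparison report."""
    report = EvalReport(
        summary=summarize_assignments(tables, ctx), jaccard=jaccard_matrix(tables)
    )
    if ctx is not None:
        rows = []
        for table in tables:
            try:
                med = median_target_downregulation(table, ctx)
            except EvaluationError:
                med = float("nan")
            row = {"method": table.method_name, "median_neg_log2fc": med}
            if run_de:
                try:
                    disc = count_discoveries(table, ctx, alpha=alpha)
                    row["n_discoveries"] = disc.n_discoveries
                    row["n_significant_targets"] = disc.n_significant_targets
                except EvaluationError:
                    row["n_discoveries"] = row["n_significant_targets"] = np.nan
                try:
                    fd = count_false_discoveries(table, ctx, alpha=alpha)
                    row["n_false_discoveries"] = fd.n_false_discoveries
                    row["false_positive_rate"] = fd.false_positive_rate
                except EvaluationError:
                    row["n_false_discoveries"] = np.nan
                    row["false_positive_rate"] = np.nan
            rows.append(row)
        report.downregulation = pd.DataFrame(rows).set_index("method")
    if truth is not None:
        rows = []
        for table in tables:
            p, r, f1 = score_vs_truth(table, truth)
            rows.append(
                {"method": table.method_name, "precision": p, "recall": r, "f1": f1}
            )
        report.truth_scores = pd.DataFrame(rows).set_index("method")
    return report
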