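"""Optional figures for the comparison report."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .evaluate import EvalReport

__all__ = ["plot_report"]


def plot_report(report: EvalReport, out_dir: Path) -> None:
    """Write assigned-cell scatter and Jaccard heatmap PNGs."""
    out_dir = Path(out_dir)

    fig, ax = plt.subplots(figsize=(6, 4))
    s = report.summary
    ax.scatter(s.index, s["n_total_assigned_cells"], marker="x", label="total")
    ax.scatter(
        s.index, s["n_uniquely_assigned_cells"], marker="o", label="unique"
    )
    ax.set_ylabel("assigned cells")
    ax.tick_params(axis="x", rotation=60)
    ax.legend()
    fig.tight_layout()
    fig.savefig(out_dir / "assigned_cells.png", dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(5, 4.2))
    im = ax.imshow(report.jaccard.to_numpy(), vmin=0, vmax=1, cmap="viridis")
    ax.set_xticks(range(len(report.jaccard)))
    ax.set_xticklabels(report.jaccard.columns, rotation=60, ha="right")
    ax.set_yticks(range(len(report.jaccard)))
    ax.set_yticklabels(report.jaccard.index)
    fig.colorbar(im, ax=ax, label="Jaccard index")
    fig.tight_layout()
    fig.savefig(out_dir / "jaccard.png", dpi=120)
    plt.close(fig)

    if report.downregulation is not None and "median_neg_log2fc" in report.downregulation:
        fig, ax = plt.subplots(figsize=(6, 4))
        d = report.downregulation.join(report.summary)
        ax.scatter(d["n_uniquely_assigned_cells"], d["median_neg_log2fc"])
        for name, row in d.iterrows():
            ax.annotate(name, (row["n_uniquely_assigned_cells"], row["median_neg_log2fc"]),
                        fontsize=7)
        ax.set_xlabel("uniquely assigned cells")
        ax.set_ylabel("median -log2FC of target")
        fig.tight_layout()
        fig.savefig(out_dir / "downregulation.png", dpi=120)
        plt.close(fig)
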