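"""Genomic-window variance decomposition and reporting.

The additive genetic variance captured by the SNP effects is attributed to
non-overlapping windows of consecutive SNPs spanning at most 1 Mb.  For a
window w with member SNPs j, the window genetic value per individual is
a_w = sum_j Z_j u_hat_j, and the window's share is
Var(a_w)/sigma2_a * 100, with Var the empirical variance across genotyped
individuals (which is invariant to per-SNP centering constants).

Windows whose share exceeds a percent-of-genetic-variance threshold
(default 1%) are declared significant; the report also carries the expected
average share 100/n_windows and the fold of the threshold over it, so the
stringency of the rule is explicit.  Significant windows can be annotated
offline against user-supplied BED intervals (half-open convention).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .io import AnnotationIntervals, GenotypePanel

logger = logging.getLogger(__name__)


@dataclass
class Window:
    chrom: int
    start_bp: int  # anchor SNP position
    end_bp: int  # half-open genomic extent: start_bp + size
    snp_indices: np.ndarray


@dataclass
class WindowVarianceTable:
    table: pd.DataFrame  # chrom, start_bp, end_bp, n_snp, gvar_pct, member_snps, annotations
    n_windows: int
    threshold_pct: float = 1.0

    @property
    def expected_avg_pct(self) -> float:
        return 100.0 / self.n_windows

    @property
    def threshold_fold(self) -> float:
        return self.threshold_pct / self.expected_avg_pct


def define_windows(
    chrom: np.ndarray,
    pos: np.ndarray,
    size_bp: int = 1_000_000,
    mode: str = "snp",
) -> list[Window]:
    """Partition the SNP map into non-overlapping windows of span <= size_bp.

    mode="snp" (default): greedy consecutive-SNP spans anchored at each
    chromosome's first unassigned SNP, membership by pos in
    [anchor, anchor + size_bp).  mode="bins": fixed genomic bins
    [k*size_bp, (k+1)*size_bp).  Every SNP lands in exactly one window;
    empty windows are not emitted.
    """
    chrom = np.asarray(chrom)
    pos = np.asarray(pos)
    if np.any(np.lexsort((pos, chrom)) != np.arange(len(pos))):
        raise ValueError("SNP map must be sorted by (chromosome, position)")
    windows: list[Window] = []
    for c in pd.unique(chrom):
        idx = np.flatnonzero(chrom == c)
        cpos = pos[idx]
        if mode == "bins":
            bins = cpos // size_bp
            for b in pd.unique(bins):
                members = idx[bins == b]
                windows.append(
                    Window(int(c), int(b * size_bp), int((b + 1) * size_bp), members)
                )
        elif mode == "snp":
            i = 0
            while i < len(idx):
                anchor = cpos[i]
                j = int(np.searchsorted(cpos, anchor + size_bp, side="left"))
                windows.append(
                    Window(int(c), int(anchor), int(anchor + size_bp), idx[i:j])
                )
                i = j
        else:
            raise ValueError(f"unknown window mode {mode!r}")
    return windows


def window_variance(
    windows: list[Window],
    panel: GenotypePanel,
    u_hat: np.ndarray,
    sigma2_a: float,
    threshold_pct: float = 1.0,
) -> WindowVarianceTable:
    """Percent of total additive genetic variance per window.

    Uses the raw gene-content columns (centering shifts a_w by a constant
    and leaves its variance unchanged); Var is the unbiased empirical
    variance across genotyped individuals.
    """
    if sigma2_a <= 0:
        raise ValueError("sigma2_a must be positive")
    g = panel.gene_content
    rows = []
    for w in windows:
        a_w = g[:, w.snp_indices] @ u_hat[w.snp_indices]
        gvar = float(np.var(a_w, ddof=1)) if a_w.size > 1 else 0.0
        rows.append(
            {
                "chrom": w.chrom,
                "start_bp": w.start_bp,
                "end_bp": w.end_bp,
                "n_snp": len(w.snp_indices),
                "gvar_pct": 100.0 * gvar / sigma2_a,
                "member_snps": ",".join(panel.snp_ids[j] for j in w.snp_indices),
                "annotations": "",
            }
        )
    df = pd.DataFrame(rows).sort_values(["chrom", "start_bp"]).reset_index(drop=True)
    return WindowVarianceTable(df, n_windows=len(windows), threshold_pct=threshold_pct)


def significant_windows(
    table: WindowVarianceTable, threshold_pct: float | None = None
) -> WindowVarianceTable:
    """Windows with gvar_pct strictly above the threshold, ranked by share
    (ties broken by chromosome then start)."""
    thr = table.threshold_pct if threshold_pct is None else threshold_pct
    sub = table.table[table.table["gvar_pct"] > thr]
    sub = sub.sort_values(
        ["gvar_pct", "chrom", "start_bp"], ascending=[False, True, True]
    ).reset_index(drop=True)
    out = WindowVarianceTable(sub, n_windows=table.n_windows, threshold_pct=thr)
    logger.info(
        "%d/%d windows exceed %.3g%% (expected average %.4f%%, fold %.1f)",
        len(sub), table.n_windows, thr, out.expected_avg_pct, out.threshold_fold,
    )
    return out


def annotate(
    table: WindowVarianceTable, intervals: AnnotationIntervals
) -> WindowVarianceTable:
    """Attach interval names overlapping each window (half-open on both
    sides: overlap iff start < window_end and end > window_start)."""
    trees: dict[str, IntervalTree] = {}
    for i in range(len(intervals)):
        trees.setdefault(str(intervals.chrom[i]), IntervalTree()).addi(
            int(intervals.start[i]), int(intervals.end[i]), intervals.name[i]
        )
    df = table.table.copy()
    unmatched = set(trees) - {str(c) for c in df["chrom"].unique()}
    if unmatched:
        logger.warning(
            "%d annotation chromosomes not present in windows: %s",
            len(unmatched), sorted(unmatched)[:5],
        )
    ann = []
    for row in df.itertuples(index=False):
        tree = trees.get(str(row.chrom))
        if tree is None:
            ann.append("")
            continue
        hits = sorted(iv.data for iv in tree.overlap(row.start_bp, row.end_bp))
        ann.append(",".join(hits))
    df["annotations"] = ann
    return WindowVarianceTable(df, table.n_windows, table.threshold_pct)


def manhattan_plot(
    table: WindowVarianceTable,
    threshold_pct: float,
    out,
    title: str = "",
) -> None:
    """Per-window gVar(%) against genomic position, chromosomes alternately
    shaded, dashed horizontal threshold line.  Deterministic given inputs."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = table.table.sort_values(["chrom", "start_bp"])
    if df.empty:
        raise ValueError("empty window table")
    fig, ax = plt.subplots(figsize=(10, 4))
    offset = 0
    ticks, ticklabels = [], []
    colors = ("#4C72B0", "#9FB4D6")
    for k, (c, sub) in enumerate(df.groupby("chrom", sort=True)):
        x = offset + (sub["start_bp"] + sub["end_bp"]) / 2
        ax.scatter(x, sub["gvar_pct"], s=8, color=colors[k % 2])
        ticks.append(float(x.mean()))
        ticklabels.append(str(c))
        offset += int(sub["end_bp"].max()) + 1
    ax.axhline(threshold_pct, color="red", linestyle="--", linewidth=1)
    ax.set_xticks(ticks)
    ax.set_xticklabels(ticklabels, fontsize=7)
    ax.set_xlabel("Chromosome")
    ax.set_ylabel("gVar (%)")
    ax.set_ylim(0, max(float(df["gvar_pct"].max()) * 1.1, threshold_pct * 1.5))
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(out, dpi=120, metadata={"Software": "sswas"})
    plt.close(fig)
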