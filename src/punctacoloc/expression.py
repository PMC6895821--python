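"""Pairwise Pearson correlation screen and dead-vs-alive group comparison.

Operates on a genes x samples matrix of log-scale expression values with a
per-sample vital-status label.  The screen computes Pearson's R for every
(panel_x, panel_y) gene pair over pairwise-complete samples, with two-sided
p-values from the t transform on n - 2 degrees of freedom; no
multiple-testing correction is applied (the number of tests is reported
instead).  The group comparison is a two-sided two-sample t test of a
gene's log-scale expression between dead and alive samples,
unequal-variance by default, excluding unknown-status samples.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ExpressionMatrix",
    "GroupComparison",
    "pearson_screen",
    "group_compare",
    "significance_stars",
    "expression_report",
]

log = logging.getLogger(__name__)

_STATUSES = {"alive", "dead", "unknown"}

# star annotation thresholds, strictest first
_STAR_LEVELS: tuple[tuple[float, str], ...] = ((0.005, "***"), (0.02, "**"), (0.05, "*"))


@dataclass(frozen=True)
class ExpressionMatrix:
    """Genes x samples log-scale expression values plus vital-status labels."""

    values: pd.DataFrame  # index: gene names; columns: sample ids
    sample_status: list[str]

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].tolist()
            raise ValueError(f"duplicated gene names: {dupes}")
        if len(self.sample_status) != self.values.shape[1]:
            raise ValueError(
                f"sample_status has {len(self.sample_status)} entries for "
                f"{self.values.shape[1]} samples"
            )
        bad = set(self.sample_status) - _STATUSES
        if bad:
            raise ValueError(f"unknown status labels: {sorted(bad)}")
        if not np.isfinite(self.values.to_numpy()).all():
            # NaN marks a missing measurement; infinities are invalid
            if np.isinf(self.values.to_numpy()).any():
                raise ValueError("expression values must be finite (or NaN for missing)")

    @property
    def gene_names(self) -> list[str]:
        return list(self.values.index)

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def gene(self, name: str) -> np.ndarray:
        if name not in self.values.index:
            raise KeyError(f"gene {name!r} not in matrix")
        return self.values.loc[name].to_numpy(dtype=float)

    @classmethod
    def from_csv(cls, path: str | Path, status_row: str = "status") -> "ExpressionMatrix":
        """Read a genes x samples CSV whose `status_row` row holds the labels."""
        df = pd.read_csv(path, index_col=0)
        status = df.loc[status_row].astype(str).tolist()
        values = df.drop(index=status_row).astype(float)
        return cls(values=values, sample_status=status)

    def to_csv(self, path: str | Path, status_row: str = "status") -> None:
        out = self.values.copy()
        out.loc[status_row] = self.sample_status
        out.to_csv(path)


@dataclass(frozen=True)
class GroupComparison:
    """Two-sample t test of one gene between dead and alive samples."""

    gene: str
    t: float
    p: float
    mean_dead: float
    mean_alive: float
    n_dead: int
    n_alive: int
    equal_var: bool


def pearson_screen(
    matrix: ExpressionMatrix,
    panel_x: list[str],
    panel_y: list[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Pearson R for every (x, y) gene pair, with two-sided p and a
    significance flag at ``alpha``.

    Samples with a missing value in either gene are dropped pairwise; the
    n actually used is reported per pair.  A zero-variance gene yields
    NaN r/p with a logged warning rather than an error.  No
    multiple-testing correction is applied.
    """
    for g in set(panel_x) | set(panel_y):
        if g not in matrix.values.index:
            raise KeyError(f"panel gene {g!r} not in matrix")
    rows = []
    for gx in panel_x:
        x_all = matrix.gene(gx)
        for gy in panel_y:
            y_all = matrix.gene(gy)
            ok = np.isfinite(x_all) & np.isfinite(y_all)
            x, y = x_all[ok], y_all[ok]
            n = int(ok.sum())
            if n < 3:
                raise ValueError(
                    f"pair ({gx}, {gy}) has only {n} complete samples; need >= 3"
                )
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                log.warning(
                    "zero-variance gene in pair (%s, %s): correlation undefined",
                    gx,
                    gy,
                )
                r, p = math.nan, math.nan
            else:
                r, p = stats.pearsonr(x, y)
            rows.append(
                {
                    "gene_x": gx,
                    "gene_y": gy,
                    "r": float(r),
                    "n": n,
                    "p": float(p),
                    "significant": bool(p < alpha) if not math.isnan(p) else False,
                }
            )
    return pd.DataFrame(rows)


def group_compare(
    matrix: ExpressionMatrix, gene: str, equal_var: bool = False
) -> GroupComparison:
    """Two-sided t test of `gene` between dead and alive samples.

    Unknown-status samples are excluded.  ``equal_var=False`` (default)
    gives the unequal-variance (Welch) test; True the pooled-variance test.
    """
    vals = matrix.gene(gene)
    status = np.array(matrix.sample_status)
    dead = vals[(status == "dead") & np.isfinite(vals)]
    alive = vals[(status == "alive") & np.isfinite(vals)]
    for name, grp in (("dead", dead), ("alive", alive)):
        if len(grp) < 2:
            raise ValueError(
                f"group '{name}' has {len(grp)} samples for gene {gene!r}; "
                "need >= 2 per group"
            )
    t, p = stats.ttest_ind(dead, alive, equal_var=equal_var)
    return GroupComparison(
        gene=gene,
        t=float(t),
        p=float(p),
        mean_dead=float(dead.mean()),
        mean_alive=float(alive.mean()),
        n_dead=len(dead),
        n_alive=len(alive),
        equal_var=equal_var,
    )


def significance_stars(p: float) -> str:
    """Star annotation: * p<0.05, ** p<0.02, *** p<0.005 (monotone)."""
    if math.isnan(p):
        return ""
    for thresh, stars in _STAR_LEVELS:
        if p < thresh:
            return stars
    return ""


def expression_report(
    table: pd.DataFrame,
    comparisons: list[GroupComparison],
    out_dir: str | Path | None = None,
    matrix: ExpressionMatrix | None = None,
) -> dict:
    """Assemble the screen output: a starred correlation grid (panel-y genes
    as rows, panel-x genes as columns), the group-comparison table, and —
    when the matrix is supplied — per-gene dead/alive histograms on a log10
    axis.

    Returns a dict with the pivoted grid (`correlation_grid`), the raw CSV
    text (`correlation_csv`, footer states the number of tests performed),
    the comparison DataFrame (`comparisons`), and any figure paths.
    Writes files only when ``out_dir`` is given.
    """
    grid = table.copy()
    grid["annotated"] = [
        ("" if math.isnan(r) else f"{r:.4f}") + significance_stars(p)
        for r, p in zip(grid["r"], grid["p"])
    ]
    pivot = grid.pivot(index="gene_y", columns="gene_x", values="annotated")
    pivot = pivot.reindex(
        index=pd.unique(table["gene_y"]), columns=pd.unique(table["gene_x"])
    )
    n_tests = len(table)
    csv_text = pivot.to_csv() + f"# {n_tests} correlation tests, uncorrected\n"

    comp_df = pd.DataFrame([vars(c) for c in comparisons]) if comparisons else pd.DataFrame()

    figures: list[Path] = []
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "correlation_table.csv").write_text(csv_text)
        if not comp_df.empty:
            comp_df.to_csv(out / "group_comparisons.csv", index=False)
        if matrix is not None and comparisons:
            figures = _plot_group_histograms(matrix, comparisons, out)

    return {
        "correlation_grid": pivot,
        "correlation_csv": csv_text,
        "n_tests": n_tests,
        "comparisons": comp_df,
        "figures": figures,
    }


def _plot_group_histograms(
    matrix: ExpressionMatrix, comparisons: list[GroupComparison], out: Path
) -> list[Path]:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    status = np.array(matrix.sample_status)
    paths = []
    for comp in comparisons:
        vals = matrix.gene(comp.gene)
        fig, ax = plt.subplots(figsize=(4, 3))
        for label, color in (("alive", "tab:blue"), ("dead", "tab:red")):
            ax.hist(
                vals[status == label],
                bins=12,
                alpha=0.6,
                label=f"{label} (n={int((status == label).sum())})",
                color=color,
            )
        ax.set_xlabel(f"{comp.gene} expression (log10 axis)")
        if np.nanmin(vals) > 0:
            ax.set_xscale("log", base=10)
        ax.set_ylabel("patients")
        ax.legend(frameon=False)
        ax.set_title(f"{comp.gene}: t={comp.t:.2f}, p={comp.p:.3f}")
        fig.tight_layout()
        p = out / f"hist_{comp.gene}.png"
        fig.savefig(p, dpi=100)
        plt.close(fig)
        paths.append(p)
    return paths
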