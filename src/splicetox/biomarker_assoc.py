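"""Expression–Emax biomarker ranking across a cell-line panel.

Given a gene x cell-line matrix of log2(TPM+1) expression and a
per-cell-line Emax (maximal killing, -100..0 %), genes are ranked by the
Pearson correlation of expression with Emax.  Because lower Emax means
stronger killing, a *positive* correlation marks an insensitivity gene
(high expression, weak killing) — rank 1 is the most positive R.
Quartile grouping compares Emax between the cells in the top and bottom
expression quartiles of a single gene.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "correlate_expression_emax",
    "pearson_with_p",
    "QuartileGroups",
    "quartile_group_compare",
    "emax_by_lineage",
]


def pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson R with the two-sided p from t = R sqrt(n-2) / sqrt(1-R^2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("need >= 3 observations")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc**2).sum() * (yc**2).sum())
    if denom == 0:
        raise ValueError("zero variance input")
    r = float(np.clip((xc * yc).sum() / denom, -1.0, 1.0))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(abs(t), n - 2)
    return r, float(p)


def correlate_expression_emax(panel: pd.DataFrame, emax: pd.Series) -> pd.DataFrame:
    """Per-gene Pearson correlation of expression with Emax, BH-adjusted.

    ``panel`` is genes x cell lines; ``emax`` is indexed by cell line.
    Cell lines are intersected; lines with missing Emax are excluded
    (complete case).  Zero-variance genes are excluded with a log entry.
    Output is sorted descending by R with ``rank`` 1 = most positive
    correlation (insensitivity marker).
    """
    common = [c for c in panel.columns if c in emax.index and np.isfinite(emax[c])]
    if len(common) < 3:
        raise ValueError("need >= 3 overlapping cell lines with Emax")
    x = panel[common].to_numpy(dtype=float)
    y = emax[common].to_numpy(dtype=float)
    n = len(common)
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    sx = np.sqrt((xc**2).sum(axis=1))
    sy = float(np.sqrt((yc**2).sum()))
    nonconst = sx > 0
    if (~nonconst).any():
        logger.info(
            "correlate_expression_emax: excluding %d zero-variance genes", int((~nonconst).sum())
        )
    r = np.full(x.shape[0], np.nan)
    r[nonconst] = np.clip((xc[nonconst] @ yc) / (sx[nonconst] * sy), -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = np.where(np.abs(r) == 1.0, 0.0, 2.0 * stats.t.sf(np.abs(t), n - 2))
    out = pd.DataFrame({"gene": panel.index, "r": r, "p": p, "n": n})
    out = out[nonconst].copy()
    out["adj_p"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    out = out.sort_values(["r", "gene"], ascending=[False, True], kind="mergesort").reset_index(
        drop=True
    )
    out["rank"] = np.arange(1, len(out) + 1)
    return out


@dataclass
class QuartileGroups:
    gene: str
    high_lines: list  # expression strictly above Q3
    low_lines: list  # expression strictly below Q1
    q1: float
    q3: float
    mean_emax_high: float
    mean_emax_low: float
    t: float
    p: float


def quartile_group_compare(
    panel: pd.DataFrame,
    emax: pd.Series,
    gene: str,
    *,
    equal_var: bool = False,
) -> QuartileGroups:
    """Compare Emax between high- and low-expression quartile groups.

    Quartiles use linear interpolation between order statistics; group
    membership is strict (> Q3 / < Q1).  Welch's t by default;
    ``equal_var=True`` switches to the pooled-variance Student test.
    Massive ties that empty a group raise, naming the gene.
    """
    if gene not in panel.index:
        raise KeyError(f"gene {gene!r} not in panel")
    common = [c for c in panel.columns if c in emax.index and np.isfinite(emax[c])]
    if len(common) < 8:
        raise ValueError("need >= 8 cell lines for quartile grouping")
    expr = panel.loc[gene, common].astype(float)
    q1, q3 = np.percentile(expr.to_numpy(), [25, 75])
    high = expr.index[expr > q3].tolist()
    low = expr.index[expr < q1].tolist()
    if not high or not low:
        raise ValueError(f"gene {gene!r}: quartile grouping produced an empty group (ties)")
    e_high = emax[high].to_numpy(dtype=float)
    e_low = emax[low].to_numpy(dtype=float)
    res = stats.ttest_ind(e_high, e_low, equal_var=equal_var)
    return QuartileGroups(
        gene=gene,
        high_lines=high,
        low_lines=low,
        q1=float(q1),
        q3=float(q3),
        mean_emax_high=float(e_high.mean()),
        mean_emax_low=float(e_low.mean()),
        t=float(res.statistic),
        p=float(res.pvalue),
    )


def emax_by_lineage(
    emax: pd.Series,
    lineages: pd.Series,
    *,
    known_lineages: list[str] | None = None,
) -> pd.DataFrame:
    """Five-number Emax summary (min, Q1, median, Q3, max) per lineage.

    Cell lines whose label is not in ``known_lineages`` (when given) are
    grouped under ``other`` with a warning.  Box-plot-ready output.
    """
    common = emax.index.intersection(lineages.index)
    labels = lineages[common].astype(str)
    if known_lineages is not None:
        unknown = ~labels.isin(known_lineages)
        if unknown.any():
            logger.warning(
                "emax_by_lineage: %d lines with unknown lineage grouped as 'other'",
                int(unknown.sum()),
            )
            labels = labels.where(~unknown, "other")
    rows = []
    for lineage, idx in labels.groupby(labels).groups.items():
        vals = emax[idx].to_numpy(dtype=float)
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        rows.append(
            {
                "lineage": lineage,
                "n": vals.size,
                "min": float(vals.min()),
                "q1": float(q1),
                "median": float(med),
                "q3": float(q3),
                "max": float(vals.max()),
            }
        )
    return pd.DataFrame(rows).sort_values("lineage").reset_index(drop=True)
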