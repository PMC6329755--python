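"""Isoform-class splicing-response summarization.

Transcript-level abundances (TPM and estimated counts) are annotated into
three classes per gene:

* ``CDS-L`` — coding sequence of the antiapoptotic long-form protein,
* ``CDS-S`` — coding sequence of the proapoptotic short-form protein,
* ``AS``    — aberrantly spliced transcripts (intron retention and other
  mis-splicing) not expected to encode functional protein.

Class abundances are transcript sums per (gene, class, sample); contrasts
between treated and control arms run a two-sample moderated t on logCPM
(shared machinery with the screen module) with BH adjustment across all
(gene, class) contrasts and significance tiers at 0.01 and 0.001.
Direction flags classify significant shifts as pro- or antiapoptotic
events, gated on a median expression of log2(TPM+1) > 2 in the relevant
arm so lowly expressed noise is never flagged.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .screen_analysis import moderated_t_two_sample

logger = logging.getLogger(__name__)

__all__ = [
    "ISOFORM_CLASSES",
    "DEFAULT_DIRECTION_MAP",
    "aggregate_classes",
    "logcpm_transform",
    "class_contrast",
    "direction_flags",
]

ISOFORM_CLASSES = ("CDS-L", "CDS-S", "AS")

# which apoptotic program an *increase* of each class serves
DEFAULT_DIRECTION_MAP: Mapping[str, str] = {
    "CDS-L": "antiapoptotic",
    "CDS-S": "proapoptotic",
    "AS": "proapoptotic",
}


def aggregate_classes(
    transcripts: pd.DataFrame,
    sample_cols: Sequence[str],
    *,
    value: str = "tpm",
) -> pd.DataFrame:
    """Sum transcript abundances to (gene, class) per sample.

    ``transcripts`` holds one row per transcript with ``transcript_id``,
    ``gene`` and ``tclass`` columns plus per-sample values.  Class labels
    outside the fixed vocabulary or missing genes are errors.  Returns one
    row per (gene, class) with summed sample columns; class sums conserve
    the per-gene transcript totals.
    """
    required = {"transcript_id", "gene", "tclass"}
    if not required <= set(transcripts.columns):
        raise ValueError(f"transcript table needs columns {sorted(required)}")
    if transcripts["gene"].isna().any():
        raise ValueError("transcript with unknown gene")
    bad = set(transcripts["tclass"]) - set(ISOFORM_CLASSES)
    if bad:
        raise ValueError(f"unknown isoform classes: {sorted(bad)}")
    if (transcripts[list(sample_cols)] < 0).any().any():
        raise ValueError(f"negative {value} values")
    out = (
        transcripts.groupby(["gene", "tclass"], sort=True)[list(sample_cols)]
        .sum()
        .reset_index()
    )
    return out


def log_tpm(class_table: pd.DataFrame, sample_cols: Sequence[str]) -> pd.DataFrame:
    """log2(TPM + 1) view of a class-level TPM table."""
    out = class_table.copy()
    out[list(sample_cols)] = np.log2(class_table[list(sample_cols)].to_numpy(dtype=float) + 1.0)
    return out


def logcpm_transform(
    counts: pd.DataFrame,
    sample_cols: Sequence[str],
    *,
    library_sizes: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """log2 counts per million: log2((count + 0.5) / (libsize + 1) * 1e6).

    Library sizes default to the per-sample column sums; a zero library
    size is an error.  The half-count pseudocount keeps zeros finite and
    the transform is monotone in counts within a sample.
    """
    out = counts.copy()
    for col in sample_cols:
        lib = float(library_sizes[col]) if library_sizes else float(counts[col].sum())
        if lib <= 0:
            raise ValueError(f"sample {col!r} has zero library size")
        vals = counts[col].to_numpy(dtype=float)
        out[col] = np.log2((vals + 0.5) / (lib + 1.0) * 1e6)
    return out


def class_contrast(
    class_counts: pd.DataFrame,
    control_cols: Sequence[str],
    treated_cols: Sequence[str],
    *,
    prior_df: float | None = None,
) -> pd.DataFrame:
    """Treated-vs-control moderated t per (gene, class) on logCPM.

    Requires >= 2 replicates per arm.  Returns logFC (treated - control),
    raw and BH-adjusted p across all contrasts, and significance ``tier``
    (2 for adj p < 0.01, 3 for adj p < 0.001, 0 otherwise).
    """
    if len(control_cols) < 2 or len(treated_cols) < 2:
        raise ValueError("need >= 2 replicates per arm")
    logcpm = logcpm_transform(class_counts, list(control_cols) + list(treated_cols))
    res = moderated_t_two_sample(
        logcpm, treated_cols, control_cols, prior_df=prior_df
    )
    tier = np.zeros(len(res), dtype=int)
    tier[res["adj_p"].to_numpy() < 0.01] = 2
    tier[res["adj_p"].to_numpy() < 0.001] = 3
    res["tier"] = tier
    return res


def direction_flags(
    class_tpm: pd.DataFrame,
    contrasts: pd.DataFrame,
    control_cols: Sequence[str],
    treated_cols: Sequence[str],
    *,
    direction_map: Mapping[str, str] = DEFAULT_DIRECTION_MAP,
    alpha: float = 0.01,
    min_median_log_tpm: float = 2.0,
) -> pd.DataFrame:
    """Pro-/antiapoptotic event flags for significant class shifts.

    A (gene, class) contrast is flagged only when it is significant at
    BH-adjusted ``alpha`` AND the median log2(TPM+1) in the relevant arm
    (treated for inductions, control for reductions) exceeds
    ``min_median_log_tpm``.  The event direction follows the class's
    apoptotic role: an induced proapoptotic class (CDS-S, AS) or a reduced
    antiapoptotic class (CDS-L) is a proapoptotic event, and vice versa.
    Unmapped classes get a warning and no flag.
    """
    merged = contrasts.merge(class_tpm, on=["gene", "tclass"], how="left", suffixes=("", "_tpm"))
    log_t = np.log2(merged[list(treated_cols)].to_numpy(dtype=float) + 1.0)
    log_c = np.log2(merged[list(control_cols)].to_numpy(dtype=float) + 1.0)
    med_treated = np.median(log_t, axis=1)
    med_control = np.median(log_c, axis=1)
    flags = []
    for i, row in enumerate(merged.itertuples(index=False)):
        tclass = row.tclass
        if tclass not in direction_map:
            logger.warning("direction_flags: unmapped class %r, no flag", tclass)
            flags.append(None)
            continue
        if row.adj_p >= alpha or row.logFC == 0:
            flags.append(None)
            continue
        up = row.logFC > 0
        median_expr = med_treated[i] if up else med_control[i]
        if median_expr <= min_median_log_tpm:
            flags.append(None)
            continue
        role = direction_map[tclass]
        if up:
            flags.append(role)
        else:
            flags.append("proapoptotic" if role == "antiapoptotic" else "antiapoptotic")
    out = contrasts.copy()
    out["median_log_tpm_treated"] = med_treated
    out["median_log_tpm_control"] = med_control
    out["flag"] = flags
    return out
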