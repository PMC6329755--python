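"""Pooled shRNA dropout-screen quantification and hit calling.

A pooled screen reads out, per sample, the number of sequencing reads
carrying each shRNA's barcode.  The pipeline here goes

    FASTQ / count table
        -> per-sample CPTM normalization  (n_i / N_total * 1e6)
        -> log2(CPTM + 1)
        -> paired treated-vs-vehicle log ratios per replicate
        -> empirical-Bayes moderated t per shRNA, BH adjustment
        -> gene-level aggregation (mean shRNA log fold change, waterfall rank)

Negative log ratios are drop-out (sensitization), positive are enrichment.
The moderated t shrinks each shRNA's variance toward an ensemble prior
(d0, s0^2) estimated by moment matching on the log sample variances, which
is what gives the test power at duplicate-level replication.
"""

from __future__ import annotations

import gzip
import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma, polygamma
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "BarcodeLibrary",
    "count_barcodes",
    "count_barcode_samples",
    "cptm_normalize",
    "screen_log_ratios",
    "estimate_variance_prior",
    "squeeze_variances",
    "moderated_t_test",
    "moderated_t_two_sample",
    "gene_aggregate",
    "call_gene_hits",
    "gfp_depletion_test",
]

CPTM_SCALE = 1e6  # the printed normalization constant
LOG_BASE = 2.0  # log2 throughout; fold changes are reported in log2 units
PSEUDOCOUNT = 1.0  # log-count = log2(CPTM + 1)


# ---------------------------------------------------------------------------
# library + counting
# ---------------------------------------------------------------------------


@dataclass
class BarcodeLibrary:
    """Barcode -> shRNA -> gene annotation of a pooled library.

    Barcodes must be unique, all of one length, and each shRNA maps to
    exactly one gene.
    """

    table: pd.DataFrame  # columns: barcode, shRNA_id, gene

    def __post_init__(self) -> None:
        required = {"barcode", "shRNA_id", "gene"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"library table missing columns: {sorted(missing)}")
        if self.table["barcode"].duplicated().any():
            dups = self.table.loc[self.table["barcode"].duplicated(), "barcode"]
            raise ValueError(f"duplicate barcodes in library: {list(dups[:3])} ...")
        lengths = self.table["barcode"].str.len().unique()
        if len(lengths) != 1:
            raise ValueError(f"library barcodes have mixed lengths: {sorted(lengths)}")
        per_shrna = self.table.groupby("shRNA_id")["gene"].nunique()
        if (per_shrna > 1).any():
            bad = per_shrna[per_shrna > 1].index[:3].tolist()
            raise ValueError(f"shRNAs mapped to multiple genes: {bad}")

    @property
    def barcode_length(self) -> int:
        return int(self.table["barcode"].str.len().iloc[0])

    @classmethod
    def from_tsv(cls, path) -> "BarcodeLibrary":
        return cls(pd.read_csv(path, sep="\t", dtype=str))

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def _iter_fastq(source) -> Iterable[str]:
    """Yield read sequences from a FASTQ path (optionally gzipped), an open
    handle, or an iterable of sequence strings."""
    if isinstance(source, (str, bytes)) or hasattr(source, "__fspath__"):
        opener = gzip.open if str(source).endswith(".gz") else open
        with opener(source, "rt") as handle:
            from Bio import SeqIO

            for rec in SeqIO.parse(handle, "fastq"):
                yield str(rec.seq)
        return
    if hasattr(source, "read"):
        from Bio import SeqIO

        for rec in SeqIO.parse(source, "fastq"):
            yield str(rec.seq)
        return
    for seq in source:
        yield str(seq)


def _hamming1_variants(seq: str) -> Iterable[str]:
    for i, base in enumerate(seq):
        for sub in "ACGT":
            if sub != base:
                yield seq[:i] + sub + seq[i + 1 :]


def count_barcodes(
    reads,
    library: BarcodeLibrary,
    *,
    offset: int = 0,
    max_mismatch: int = 0,
) -> tuple[pd.Series, dict]:
    """Tally reads per library barcode for one sample.

    The barcode is extracted as a fixed window ``[offset, offset+L)`` of
    each read and matched exactly against the library; with
    ``max_mismatch=1`` unmatched windows are rescued when exactly one
    library barcode lies at Hamming distance 1 (two candidates -> the read
    is discarded as ambiguous).  Reads too short to cover the window are
    skipped and tallied.

    Returns ``(counts, stats)`` where ``counts`` is indexed by barcode
    (every library barcode present, zero-filled) and ``stats`` reports
    ``assigned / unassigned / too_short / ambiguous`` read numbers.
    """
    if max_mismatch not in (0, 1):
        raise ValueError("max_mismatch must be 0 or 1")
    length = library.barcode_length
    lut = {bc: i for i, bc in enumerate(library.table["barcode"])}
    counts = np.zeros(len(lut), dtype=np.int64)
    n_unassigned = n_short = n_ambiguous = 0
    for seq in _iter_fastq(reads):
        if len(seq) < offset + length:
            n_short += 1
            continue
        window = seq[offset : offset + length]
        idx = lut.get(window)
        if idx is None and max_mismatch == 1:
            hits = {lut[v] for v in _hamming1_variants(window) if v in lut}
            if len(hits) == 1:
                idx = hits.pop()
            elif len(hits) > 1:
                n_ambiguous += 1
                continue
        if idx is None:
            n_unassigned += 1
        else:
            counts[idx] += 1
    if n_short:
        logger.info("count_barcodes: skipped %d reads shorter than window", n_short)
    stats_out = {
        "assigned": int(counts.sum()),
        "unassigned": n_unassigned,
        "too_short": n_short,
        "ambiguous": n_ambiguous,
    }
    return pd.Series(counts, index=library.table["barcode"].to_numpy(), name="count"), stats_out


def count_barcode_samples(
    sample_reads: Mapping[str, object],
    library: BarcodeLibrary,
    *,
    offset: int = 0,
    max_mismatch: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Count several samples (name -> FASTQ source) into one count table.

    Returns a DataFrame with barcode/shRNA_id/gene annotation columns plus
    one integer count column per sample, and per-sample read statistics.
    """
    out = library.table.copy()
    all_stats: dict[str, dict] = {}
    for name, source in sample_reads.items():
        counts, st = count_barcodes(source, library, offset=offset, max_mismatch=max_mismatch)
        out[name] = counts.to_numpy()
        all_stats[name] = st
    return out, all_stats


# ---------------------------------------------------------------------------
# normalization + ratios
# ---------------------------------------------------------------------------


def cptm_normalize(counts: pd.DataFrame, sample_cols: Sequence[str] | None = None) -> pd.DataFrame:
    """Counts-per-ten-million normalization: CPTM_i = n_i / N_total * 1e6.

    ``counts`` holds one row per barcode with integer sample columns; the
    annotation columns (barcode, shRNA_id, gene, ...) are carried through.
    Each normalized sample column sums to 1e6.  An all-zero sample is an
    error (nothing to normalize), reported by name.
    """
    if sample_cols is None:
        sample_cols = [c for c in counts.columns if pd.api.types.is_numeric_dtype(counts[c])]
    out = counts.copy()
    for col in sample_cols:
        total = float(counts[col].sum())
        if total <= 0:
            raise ValueError(f"sample {col!r} has zero total count")
        if (counts[col] < 0).any():
            raise ValueError(f"sample {col!r} contains negative counts")
        out[col] = counts[col].to_numpy(dtype=float) / total * CPTM_SCALE
    return out


def screen_log_ratios(
    normalized: pd.DataFrame,
    pairing: Sequence[tuple[str, str]],
    *,
    id_cols: Sequence[str] = ("barcode", "shRNA_id", "gene"),
) -> pd.DataFrame:
    """Per-replicate log ratios log2(CPTM_treated + 1) - log2(CPTM_vehicle + 1).

    ``pairing`` lists ``(treated_column, vehicle_column)`` per replicate;
    each pair yields one ``ratio_<k>`` column.  Negative values are
    drop-out (sensitization), positive enrichment.
    """
    if not pairing:
        raise ValueError("pairing is empty")
    keep = [c for c in id_cols if c in normalized.columns]
    out = normalized[keep].copy()
    for k, (treated, vehicle) in enumerate(pairing, start=1):
        for col in (treated, vehicle):
            if col not in normalized.columns:
                raise ValueError(f"unpaired sample: column {col!r} not in table")
        t = np.log2(normalized[treated].to_numpy(dtype=float) + PSEUDOCOUNT)
        d = np.log2(normalized[vehicle].to_numpy(dtype=float) + PSEUDOCOUNT)
        out[f"ratio_{k}"] = t - d
    return out


# ---------------------------------------------------------------------------
# empirical-Bayes moderated t
# ---------------------------------------------------------------------------


@dataclass
class VariancePrior:
    """Ensemble variance prior (d0, s0^2) for empirical-Bayes shrinkage."""

    df_prior: float  # d0; may be +inf when the sample variances are homogeneous
    var_prior: float  # s0^2


def _trigamma(x: np.ndarray | float) -> np.ndarray | float:
    return polygamma(1, x)


def estimate_variance_prior(s2: np.ndarray, df: np.ndarray) -> VariancePrior:
    """Moment-match (d0, s0^2) from per-feature sample variances.

    Works on e_g = ln s_g^2 - psi(d_g/2) + ln(d_g/2), whose ensemble mean
    and variance identify the prior:  ln s0^2 = mean(e) + psi(d0/2) -
    ln(d0/2) and var(e) = trigamma(d0/2) + mean trigamma(d_g/2).  d0 is
    found by monotone bisection on (0.1, 1e6]; when the empirical var(e)
    does not exceed the trigamma term the prior df is effectively infinite
    and every posterior variance equals s0^2.

    Features with zero sample variance contribute through a floor at the
    smallest positive variance (they cannot be log-transformed); an
    all-zero ensemble raises.
    """
    s2 = np.asarray(s2, dtype=float)
    df = np.broadcast_to(np.asarray(df, dtype=float), s2.shape)
    if s2.size < 2:
        raise ValueError("need at least two features to estimate a variance prior")
    if np.any(df < 1):
        raise ValueError("residual df must be >= 1 for every feature")
    positive = s2[s2 > 0]
    if positive.size == 0:
        raise ValueError("all sample variances are zero; nothing to moderate over")
    s2 = np.maximum(s2, positive.min())
    e = np.log(s2) - digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(e.mean())
    e_var = float(e.var(ddof=1))
    target = e_var - float(_trigamma(df / 2.0).mean())
    lo, hi = 0.1, 1e6
    if target <= _trigamma(hi / 2.0):
        d0 = np.inf
    elif target >= _trigamma(lo / 2.0):
        d0 = lo
    else:
        # trigamma(d0/2) is strictly decreasing in d0: plain bisection.
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if _trigamma(mid / 2.0) > target:
                lo = mid
            else:
                hi = mid
            if hi - lo <= 1e-10 * max(1.0, lo):
                break
        d0 = 0.5 * (lo + hi)
    if np.isinf(d0):
        s0_2 = float(np.exp(e_mean))
    else:
        s0_2 = float(np.exp(e_mean + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return VariancePrior(df_prior=float(d0), var_prior=s0_2)


def squeeze_variances(s2: np.ndarray, df: np.ndarray, prior: VariancePrior) -> np.ndarray:
    """Posterior variances s~^2 = (d0 s0^2 + d_g s_g^2) / (d0 + d_g)."""
    s2 = np.asarray(s2, dtype=float)
    df = np.broadcast_to(np.asarray(df, dtype=float), s2.shape)
    if np.isinf(prior.df_prior):
        return np.full_like(s2, prior.var_prior)
    return (prior.df_prior * prior.var_prior + df * s2) / (prior.df_prior + df)


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    return multipletests(p, method="fdr_bh")[1]


def _moderated_from_summary(
    mean: np.ndarray,
    s2: np.ndarray,
    df: np.ndarray,
    se_factor: np.ndarray,
    prior_df: float | None,
) -> tuple[np.ndarray, np.ndarray, VariancePrior, np.ndarray]:
    """Shared moderated-t core for one- and two-sample designs.

    ``se_factor`` converts a standard deviation into the standard error of
    ``mean`` (1/sqrt(n) for one-sample, sqrt(1/n1+1/n2) for two-sample).
    ``prior_df`` overrides the estimated d0 (0 recovers the ordinary t).
    """
    if np.all(s2 == 0):
        warnings.warn(
            "all sample variances are zero; falling back to ordinary t", RuntimeWarning
        )
        prior = VariancePrior(df_prior=0.0, var_prior=0.0)
    elif prior_df is not None:
        base = estimate_variance_prior(s2, df) if prior_df > 0 else None
        var_prior = base.var_prior if base is not None else 0.0
        prior = VariancePrior(df_prior=float(prior_df), var_prior=var_prior)
    else:
        prior = estimate_variance_prior(s2, df)
    if prior.df_prior == 0:
        s2_post = np.asarray(s2, dtype=float)
        df_total = np.asarray(df, dtype=float)
    else:
        s2_post = squeeze_variances(s2, df, prior)
        df_total = prior.df_prior + np.asarray(df, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (np.sqrt(s2_post) * se_factor)
        t = np.where(np.isfinite(t), t, np.sign(mean) * np.inf)
        t = np.where(mean == 0, 0.0, t)
    p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.clip(p, 0.0, 1.0)
    return t, p, prior, s2_post


def moderated_t_test(
    ratios: pd.DataFrame,
    *,
    ratio_cols: Sequence[str] | None = None,
    prior_df: float | None = None,
) -> pd.DataFrame:
    """Per-shRNA one-sample moderated t on replicate log ratios.

    Each feature's replicate log2 ratios give a mean (the log fold change),
    a sample variance with d_g = n-1 residual df, and a moderated
    t = mean / (s~ / sqrt(n)) referred to a t distribution on d0 + d_g df.
    Raw p values are BH-adjusted across all features in one family.

    Returns the annotation columns plus ``logFC, t, p, adj_p, n, s2,
    s2_post`` with the fitted prior in ``DataFrame.attrs['prior']``.
    """
    if ratio_cols is None:
        ratio_cols = [c for c in ratios.columns if str(c).startswith("ratio_")]
    if len(ratio_cols) < 2:
        raise ValueError("need >= 2 replicate ratio columns for a moderated t test")
    data = ratios[list(ratio_cols)].to_numpy(dtype=float)
    if data.shape[0] < 2:
        raise ValueError("need >= 2 shRNAs to moderate over")
    n = data.shape[1]
    mean = data.mean(axis=1)
    s2 = data.var(axis=1, ddof=1)
    df = np.full(data.shape[0], n - 1, dtype=float)
    t, p, prior, s2_post = _moderated_from_summary(
        mean, s2, df, se_factor=np.full_like(mean, 1.0 / np.sqrt(n)), prior_df=prior_df
    )
    keep = [c for c in ("barcode", "shRNA_id", "gene") if c in ratios.columns]
    out = ratios[keep].copy()
    out["logFC"] = mean
    out["t"] = t
    out["p"] = p
    out["adj_p"] = _bh_adjust(p)
    out["n"] = n
    out["s2"] = s2
    out["s2_post"] = s2_post
    out.attrs["prior"] = prior
    return out


def moderated_t_two_sample(
    data: pd.DataFrame,
    group1_cols: Sequence[str],
    group2_cols: Sequence[str],
    *,
    prior_df: float | None = None,
) -> pd.DataFrame:
    """Two-sample moderated t (group1 - group2) on per-feature values.

    Pooled variance with d_g = n1 + n2 - 2 residual df, shrunk with the
    same empirical-Bayes machinery as the one-sample screen test.  Used by
    the isoform module for treated-vs-control contrasts on logCPM.
    """
    x1 = data[list(group1_cols)].to_numpy(dtype=float)
    x2 = data[list(group2_cols)].to_numpy(dtype=float)
    n1, n2 = x1.shape[1], x2.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError("need >= 2 replicates per arm")
    if x1.shape[0] < 2:
        raise ValueError("need >= 2 features to moderate over")
    mean = x1.mean(axis=1) - x2.mean(axis=1)
    s2 = (x1.var(axis=1, ddof=1) * (n1 - 1) + x2.var(axis=1, ddof=1) * (n2 - 1)) / (n1 + n2 - 2)
    df = np.full(x1.shape[0], n1 + n2 - 2, dtype=float)
    se_factor = np.full_like(mean, np.sqrt(1.0 / n1 + 1.0 / n2))
    t, p, prior, s2_post = _moderated_from_summary(mean, s2, df, se_factor, prior_df)
    annot = [c for c in data.columns if c not in set(group1_cols) | set(group2_cols)]
    out = data[annot].copy()
    out["logFC"] = mean
    out["t"] = t
    out["p"] = p
    out["adj_p"] = _bh_adjust(p)
    out["s2"] = s2
    out["s2_post"] = s2_post
    out.attrs["prior"] = prior
    return out


# ---------------------------------------------------------------------------
# gene level
# ---------------------------------------------------------------------------


def gene_aggregate(results: pd.DataFrame, library: BarcodeLibrary | None = None) -> pd.DataFrame:
    """Gene-level waterfall: arithmetic mean of member-shRNA log fold changes.

    Sorted ascending (most negative = strongest sensitization first), ties
    broken by gene symbol; ``rank`` 1 is the top sensitizer.
    """
    df = results
    if "gene" not in df.columns:
        if library is None:
            raise ValueError("results lack a gene column and no library was given")
        df = df.merge(library.table[["shRNA_id", "gene"]], on="shRNA_id", how="left")
    if df["gene"].isna().any():
        raise ValueError("some shRNAs are not annotated to a gene")
    grouped = (
        df.groupby("gene", sort=False)
        .agg(mean_logFC=("logFC", "mean"), n_shRNAs=("logFC", "size"))
        .reset_index()
    )
    grouped = grouped.sort_values(
        ["mean_logFC", "gene"], ascending=[True, True], kind="mergesort"
    ).reset_index(drop=True)
    grouped["rank"] = np.arange(1, len(grouped) + 1)
    return grouped


def call_gene_hits(
    results: pd.DataFrame,
    *,
    alpha: float = 0.05,
    min_shrnas: int = 2,
    direction: str = "dropout",
) -> pd.DataFrame:
    """Call gene hits from shRNA-level moderated-t results.

    A gene is a hit when at least ``min_shrnas`` of its shRNAs are
    significant at BH-adjusted ``alpha`` with the requested sign
    (``dropout`` = negative logFC, ``enrichment`` = positive, ``any``).
    """
    if direction not in ("dropout", "enrichment", "any"):
        raise ValueError("direction must be dropout, enrichment or any")
    sig = results["adj_p"] < alpha
    if direction == "dropout":
        sig &= results["logFC"] < 0
    elif direction == "enrichment":
        sig &= results["logFC"] > 0
    tally = (
        results.assign(sig=sig)
        .groupby("gene")
        .agg(n_sig=("sig", "sum"), n_shRNAs=("sig", "size"), mean_logFC=("logFC", "mean"))
        .reset_index()
    )
    tally["hit"] = tally["n_sig"] >= min_shrnas
    return tally.sort_values(["hit", "mean_logFC"], ascending=[False, True]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# single-hairpin GFP validation
# ---------------------------------------------------------------------------


def gfp_depletion_test(
    vehicle_pct: Sequence[float],
    treated_pct: Sequence[float],
    *,
    alpha: float = 0.05,
) -> tuple[float, bool]:
    """Two-sided pooled-variance t test on GFP-positive percentages.

    Compares the GFP+ fraction of hairpin-infected cells between vehicle
    and drug arms; a significant reduction means the hairpin sensitized the
    cells.  Degenerate zero-variance arms: equal means -> p = 1 by
    convention, unequal -> p = 0.  Returns ``(p, significant)``.
    """
    a = np.asarray(vehicle_pct, dtype=float)
    b = np.asarray(treated_pct, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 replicates per arm")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        p = 1.0 if a.mean() == b.mean() else 0.0
    else:
        p = float(stats.ttest_ind(a, b, equal_var=True).pvalue)
    return p, bool(p < alpha)
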