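"""Synthetic inputs with planted ground truth for every pipeline stage.

Each simulator emulates one assay of the study design at desk scale and
returns (data, truth) so recovery tests can score the analysis modules
against what was planted:

* ``simulate_screen``          — pooled shRNA screen barcode counts
  (negative-binomial, gamma-Poisson mixture, var = mu + phi mu^2) with
  vehicle/treated arms per replicate and planted dropout effects;
  optional FASTQ emission so the barcode counter is testable end to end.
* ``simulate_dose_response``   — CellTiter-Glo-style plate tables on the
  raw luminescence scale from an exact 4PL plus Gaussian noise, with T0
  and vehicle wells.
* ``simulate_panel``           — a gene x cell-line log2(TPM+1) expression
  panel with one biomarker gene constructed to correlate with Emax at a
  target Pearson rho; all other genes are independent noise.
* ``simulate_matrix``          — dose-matrix combination grids built to be
  exactly Loewe-additive (numerical dose-equivalence solution via Brent's
  method at 1e-13 tolerance — deliberately a different root-finder and a
  finer tolerance than the analysis module's bisection, so simulator and
  analyzer are not circular), with an optional multiplicative synergy
  bump and additive noise.
* ``simulate_transcripts``     — transcript TPM/count tables with per-class
  (CDS-L / CDS-S / AS) treatment shifts such as intron-retention
  induction.

All randomness derives from a single config seed through named substreams
(:mod:`splicetox.rng`), so identical configs give byte-identical outputs
and partial re-runs are reproducible.  Dispersion or noise set exactly to
zero means the deterministic (expectation) limit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .rng import substream
from .screen_analysis import BarcodeLibrary

__all__ = [
    "PlantedEffect",
    "SimScreenConfig",
    "SimDoseConfig",
    "SimPanelConfig",
    "SimMatrixConfig",
    "SimTranscriptConfig",
    "simulate_screen",
    "write_screen_fastq",
    "simulate_dose_response",
    "threefold_series",
    "simulate_panel",
    "simulate_matrix",
    "simulate_transcripts",
    "write_truth",
]

_BASES = np.array(list("ACGT"))


def write_truth(truth: dict, path) -> None:
    """Write a machine-readable truth file consumed by recovery tests."""
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True, default=str)


# ---------------------------------------------------------------------------
# pooled shRNA screen
# ---------------------------------------------------------------------------


@dataclass
class PlantedEffect:
    """A sensitizer (or desensitizer) gene planted into a screen.

    ``log2_fc`` is the signed per-shRNA log2 change under treatment
    (negative = dropout / sensitization); ``n_shrnas`` limits the effect
    to the first k hairpins of the gene (None = all).
    """

    gene: str
    log2_fc: float
    n_shrnas: int | None = None


@dataclass
class SimScreenConfig:
    """Pooled-screen generator configuration.

    Defaults mirror the screened library scale: 841 genes at ~8 hairpins
    each trimmed to 6500 barcodes, duplicate replicates, and a
    ten-million-read sequencing budget per sample.  ``baseline_dispersion``
    is the negative-binomial phi in var = mu + phi mu^2 (0 = deterministic
    expectation limit); 0.05 reflects a well-behaved replicate screen.
    """

    n_genes: int = 841
    shrnas_per_gene: int = 8
    n_replicates: int = 2
    library_size_per_sample: int = 10_000_000
    baseline_dispersion: float = 0.05
    sensitizer_genes: Sequence[PlantedEffect] = field(default_factory=list)
    total_barcodes: int | None = 6500
    barcode_length: int = 18
    abundance_log_sd: float = 0.5  # lognormal spread of baseline representation
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.shrnas_per_gene <= 0 or self.n_replicates <= 0:
            raise ValueError("counts must be positive")
        if self.library_size_per_sample <= 0:
            raise ValueError("library size must be positive")
        if self.baseline_dispersion < 0:
            raise ValueError("dispersion must be non-negative")
        for eff in self.sensitizer_genes:
            if not np.isfinite(eff.log2_fc):
                raise ValueError("planted effects must be finite")
        if self.total_barcodes is not None and self.total_barcodes > (
            self.n_genes * self.shrnas_per_gene
        ):
            raise ValueError("total_barcodes exceeds n_genes * shrnas_per_gene")


def _make_library(cfg: SimScreenConfig) -> BarcodeLibrary:
    rng = substream(cfg.seed, "screen/barcodes")
    n = cfg.n_genes * cfg.shrnas_per_gene
    per_gene = np.full(cfg.n_genes, cfg.shrnas_per_gene)
    if cfg.total_barcodes is not None:
        # spread the trim across genes so every gene keeps ~shrnas_per_gene
        n = cfg.total_barcodes
        base, extra = divmod(n, cfg.n_genes)
        if base == 0:
            raise ValueError("total_barcodes smaller than n_genes")
        per_gene = np.full(cfg.n_genes, base)
        per_gene[:extra] += 1
    genes = [f"GENE{g + 1:04d}" for g in range(cfg.n_genes) for _ in range(per_gene[g])]
    shrnas = [f"sh{(i + 1):05d}" for i in range(n)]
    # rejection-free unique barcodes: draw until distinct (lengths >=12 make
    # collisions vanishingly rare at these scales)
    seen: set[str] = set()
    barcodes: list[str] = []
    while len(barcodes) < n:
        draw = rng.integers(0, 4, size=(n - len(barcodes), cfg.barcode_length))
        for row in draw:
            bc = "".join(_BASES[row])
            if bc not in seen:
                seen.add(bc)
                barcodes.append(bc)
    return BarcodeLibrary(pd.DataFrame({"barcode": barcodes, "shRNA_id": shrnas, "gene": genes}))


def _nb_sample(rng: np.random.Generator, mu: np.ndarray, phi: float) -> np.ndarray:
    """Gamma-Poisson negative binomial with var = mu + phi mu^2.

    phi = 0 is the deterministic expectation limit (rounded means), the
    noise-free reference used by null-calibration examples.
    """
    if phi == 0:
        return np.rint(mu).astype(np.int64)
    lam = rng.gamma(shape=1.0 / phi, scale=mu * phi)
    return rng.poisson(lam).astype(np.int64)


def simulate_screen(cfg: SimScreenConfig) -> tuple[pd.DataFrame, BarcodeLibrary, dict]:
    """Generate a pooled-screen count table with planted dropout effects.

    Returns ``(counts, library, truth)``.  ``counts`` carries the library
    annotation plus per-replicate ``vehicle_<r>`` / ``treated_<r>`` integer
    columns.  Treated counts for planted shRNAs are NB-sampled around
    baseline x 2^log2_fc.  ``truth`` records the per-shRNA planted effect.
    """
    library = _make_library(cfg)
    n = len(library.table)
    rng_ab = substream(cfg.seed, "screen/abundance")
    weights = np.exp(rng_ab.normal(0.0, cfg.abundance_log_sd, size=n))
    base_prop = weights / weights.sum()

    effect = np.zeros(n)
    gene_arr = library.table["gene"].to_numpy()
    for planted in cfg.sensitizer_genes:
        idx = np.nonzero(gene_arr == planted.gene)[0]
        if idx.size == 0:
            raise ValueError(f"planted gene {planted.gene!r} not in library")
        if planted.n_shrnas is not None:
            idx = idx[: planted.n_shrnas]
        effect[idx] = planted.log2_fc

    counts = library.table.copy()
    mu_vehicle = base_prop * cfg.library_size_per_sample
    treated_prop = base_prop * 2.0**effect
    mu_treated = treated_prop / treated_prop.sum() * cfg.library_size_per_sample
    for r in range(1, cfg.n_replicates + 1):
        rng_v = substream(cfg.seed, f"screen/counts/vehicle/{r}")
        rng_t = substream(cfg.seed, f"screen/counts/treated/{r}")
        counts[f"vehicle_{r}"] = _nb_sample(rng_v, mu_vehicle, cfg.baseline_dispersion)
        counts[f"treated_{r}"] = _nb_sample(rng_t, mu_treated, cfg.baseline_dispersion)
    truth = {
        "planted": {
            library.table["shRNA_id"].iloc[i]: float(effect[i])
            for i in np.nonzero(effect != 0)[0]
        },
        "planted_genes": sorted({p.gene for p in cfg.sensitizer_genes}),
        "n_barcodes": n,
        "pairing": [[f"treated_{r}", f"vehicle_{r}"] for r in range(1, cfg.n_replicates + 1)],
    }
    return counts, library, truth


def write_screen_fastq(
    counts: pd.DataFrame,
    sample: str,
    path,
    *,
    prefix: str = "ACCG",
    suffix: str = "TTAC",
    seed: int = 0,
) -> None:
    """Emit a FASTQ whose reads are prefix + barcode + suffix.

    One read per count, deterministically shuffled, so the counter can be
    exercised end to end (the barcode window starts at ``len(prefix)``).
    """
    barcodes = counts["barcode"].to_numpy()
    n_per = counts[sample].to_numpy(dtype=np.int64)
    reads = np.repeat(barcodes, n_per)
    substream(seed, f"fastq/{sample}").shuffle(reads)
    qual = "I" * (len(prefix) + len(barcodes[0]) + len(suffix))
    with open(path, "w") as fh:
        for i, bc in enumerate(reads):
            fh.write(f"@read{i}\n{prefix}{bc}{suffix}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# dose response plates
# ---------------------------------------------------------------------------


def threefold_series(top_nm: float = 10_000.0, n_points: int = 11) -> np.ndarray:
    """Ascending three-fold serial dilution from a top concentration (nM).

    The assay default: 11 points from 10 uM, lowest dose 10 uM / 3^10.
    """
    return top_nm / 3.0 ** np.arange(n_points - 1, -1, -1)


@dataclass
class SimDoseConfig:
    """Plate-table generator configuration.

    ``four_pl`` is (bottom, top, ec50, hill) of the treated signal on the
    raw luminescence scale; the vehicle reads t0 x growth factor (a 4-fold
    growth over the assay window is typical of the 96-h readout).
    """

    four_pl: tuple[float, float, float, float] = (0.0, 4000.0, 50.0, 1.0)
    t0_signal: float = 1000.0
    vehicle_growth_factor: float = 4.0
    noise_sd: float = 0.0
    doses: np.ndarray = field(default_factory=threefold_series)
    n_replicates: int = 3
    n_control_wells: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        bottom, top, ec50, hill = self.four_pl
        if top < bottom:
            raise ValueError("4PL top must be >= bottom")
        if ec50 <= 0:
            raise ValueError("4PL ec50 must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        self.doses = np.asarray(self.doses, dtype=float)
        if np.any(self.doses <= 0) or np.any(np.diff(self.doses) <= 0):
            raise ValueError("doses must be strictly positive and sorted ascending")
        if self.t0_signal <= 0 or self.vehicle_growth_factor <= 0:
            raise ValueError("T0 signal and growth factor must be positive")


def simulate_dose_response(cfg: SimDoseConfig) -> tuple[pd.DataFrame, dict]:
    """Generate a plate table (well, role, concentration, signal).

    Noise-free output lies exactly on the configured 4PL; noisy signals
    are floored at zero (luminescence cannot go negative).
    """
    from .dose_response import four_pl  # local import to avoid cycle at import time

    rng = substream(cfg.seed, "dose/noise")
    rows = []
    for w in range(cfg.n_control_wells):
        noise = rng.normal(0, cfg.noise_sd) if cfg.noise_sd else 0.0
        rows.append(("T0", f"T0_{w + 1}", 0.0, max(0.0, cfg.t0_signal + noise)))
    vehicle_signal = cfg.t0_signal * cfg.vehicle_growth_factor
    for w in range(cfg.n_control_wells):
        noise = rng.normal(0, cfg.noise_sd) if cfg.noise_sd else 0.0
        rows.append(("vehicle", f"VEH_{w + 1}", 0.0, max(0.0, vehicle_signal + noise)))
    clean = four_pl(cfg.doses, *cfg.four_pl)
    for j, dose in enumerate(cfg.doses):
        for r in range(cfg.n_replicates):
            noise = rng.normal(0, cfg.noise_sd) if cfg.noise_sd else 0.0
            rows.append(("dose", f"D{j + 1}_{r + 1}", float(dose), max(0.0, clean[j] + noise)))
    table = pd.DataFrame(rows, columns=["role", "well", "concentration", "signal"])
    truth = {
        "four_pl": list(cfg.four_pl),
        "t0": cfg.t0_signal,
        "vehicle": vehicle_signal,
        "doses": cfg.doses.tolist(),
    }
    return table, truth


# ---------------------------------------------------------------------------
# expression / Emax panel
# ---------------------------------------------------------------------------


@dataclass
class SimPanelConfig:
    """Expression-panel generator configuration.

    Defaults emulate the profiled panel scale: 478 cell lines, Emax
    uniform over the full -100..0 % range, and one biomarker gene whose
    expression correlates with Emax at ``biomarker_rho``.  ``n_genes``
    defaults to 1000 background genes of independent noise (desk-scale
    stand-in for a transcriptome).
    """

    n_genes: int = 1000
    n_cell_lines: int = 478
    biomarker_gene: str = "BIOMARKER"
    biomarker_rho: float = 0.6
    emax_range: tuple[float, float] = (-100.0, 0.0)
    expr_mean: float = 6.0
    expr_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.emax_range
        if not (-100.0 <= lo <= hi <= 0.0):
            raise ValueError("emax_range must satisfy -100 <= low <= high <= 0")
        if abs(self.biomarker_rho) > 1.0:
            raise ValueError("|rho| must be <= 1")
        if self.n_genes <= 0 or self.n_cell_lines <= 0:
            raise ValueError("counts must be positive")


def simulate_panel(cfg: SimPanelConfig) -> tuple[pd.DataFrame, pd.Series, dict]:
    """Generate (expression panel, Emax vector, truth).

    The biomarker column is ``rho * z(Emax) + sqrt(1 - rho^2) * noise``
    rescaled to the expression location/scale, so its empirical Pearson
    correlation with Emax converges to rho as the panel grows (exactly an
    affine transform of Emax at |rho| = 1).  Background genes are
    independent Gaussians clipped at zero (log2(TPM+1) floor).
    """
    rng_e = substream(cfg.seed, "panel/emax")
    rng_b = substream(cfg.seed, "panel/biomarker")
    rng_x = substream(cfg.seed, "panel/background")
    lines = [f"CL{i + 1:04d}" for i in range(cfg.n_cell_lines)]
    emax = rng_e.uniform(cfg.emax_range[0], cfg.emax_range[1], size=cfg.n_cell_lines)
    z = (emax - emax.mean()) / emax.std()
    rho = cfg.biomarker_rho
    mix = rho * z
    if abs(rho) < 1.0:
        mix = mix + np.sqrt(1.0 - rho**2) * rng_b.standard_normal(cfg.n_cell_lines)
    biomarker = cfg.expr_mean + cfg.expr_sd * mix
    background = rng_x.normal(
        cfg.expr_mean, cfg.expr_sd, size=(cfg.n_genes - 1, cfg.n_cell_lines)
    )
    genes = [cfg.biomarker_gene] + [f"G{i + 1:05d}" for i in range(cfg.n_genes - 1)]
    data = np.vstack([biomarker[None, :], background])
    data = np.clip(data, 0.0, None)
    panel = pd.DataFrame(data, index=pd.Index(genes, name="gene"), columns=lines)
    truth = {"biomarker_gene": cfg.biomarker_gene, "rho": rho}
    return panel, pd.Series(emax, index=lines, name="emax"), truth


# ---------------------------------------------------------------------------
# combination dose matrices
# ---------------------------------------------------------------------------


def _margin_curve(d: np.ndarray, params: tuple[float, float, float, float]) -> np.ndarray:
    """Single-agent inhibition margin: bottom + (top-bottom)/(1+(ec50/d)^hill)."""
    bottom, top, ec50, hill = params
    d = np.asarray(d, dtype=float)
    with np.errstate(divide="ignore", over="ignore"):
        ratio = np.where(d > 0, (ec50 / d) ** hill, np.inf)
    return bottom + (top - bottom) / (1.0 + ratio)


def _margin_inverse(e: float, params: tuple[float, float, float, float]) -> float:
    bottom, top, ec50, hill = params
    if e <= bottom:
        return 0.0
    if e >= top:
        return float("inf")
    return float(ec50 * ((e - bottom) / (top - e)) ** (1.0 / hill))


def _loewe_reference(
    d1: float, d2: float, px: tuple, py: tuple
) -> float:
    """Reference Loewe-additive effect via Brent's method at 1e-13.

    Deliberately a different solver (scipy brentq) and a much finer
    tolerance than the analysis module's plain bisection, keeping the
    simulator an independent construction rather than a mirror of the
    analyzer.
    """
    cap = min(px[1], py[1])

    def g(e: float) -> float:
        s = 0.0
        ix, iy = _margin_inverse(e, px), _margin_inverse(e, py)
        s += d1 / ix if np.isfinite(ix) else 0.0
        s += d2 / iy if np.isfinite(iy) else 0.0
        return s - 1.0

    hi = cap * (1.0 - 1e-12)
    if g(hi) > 0:
        return cap
    lo = cap * 1e-15
    while g(lo) < 0:  # ensure a bracket arbitrarily close to zero effect
        lo *= 0.1
        if lo < 1e-300:
            return 0.0
    return float(brentq(g, lo, hi, xtol=1e-13))


@dataclass
class SimMatrixConfig:
    """Combination-matrix generator configuration.

    Agent curves are 4PL tuples (bottom, top, ec50, hill) on the
    fractional-inhibition scale (top <= 1).  The default grid is the
    8 x 8 layout: a zero dose plus 7 three-fold dilutions per axis.
    ``synergy_bump`` multiplies the additive interior (0 = exactly
    additive); noise is additive Gaussian on the inhibition scale.
    """

    agent_x_curve: tuple[float, float, float, float] = (0.0, 1.0, 1.0, 1.0)
    agent_y_curve: tuple[float, float, float, float] = (0.0, 1.0, 1.0, 1.0)
    dx: np.ndarray = field(default_factory=lambda: np.concatenate([[0.0], 1.0 / 3.0 ** np.arange(3, -4, -1)]))
    dy: np.ndarray = field(default_factory=lambda: np.concatenate([[0.0], 1.0 / 3.0 ** np.arange(3, -4, -1)]))
    synergy_bump: float = 0.0
    noise_sd: float = 0.0
    corner_signal: float = 1000.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.dx = np.asarray(self.dx, dtype=float)
        self.dy = np.asarray(self.dy, dtype=float)
        if self.dx[0] != 0 or self.dy[0] != 0:
            raise ValueError("grid must include zero-dose margins (first row/col)")
        if np.any(np.diff(self.dx) <= 0) or np.any(np.diff(self.dy) <= 0):
            raise ValueError("dose vectors must be strictly ascending")
        if self.synergy_bump < 0:
            raise ValueError("synergy bump must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        for params in (self.agent_x_curve, self.agent_y_curve):
            if params[1] < params[0] or params[2] <= 0:
                raise ValueError("agent curves need top >= bottom and ec50 > 0")


def simulate_matrix(cfg: SimMatrixConfig) -> tuple[pd.DataFrame, dict]:
    """Generate a raw-signal dose matrix (doses as index/columns).

    With bump = 0 and noise = 0 the grid is exactly Loewe-additive by
    construction.  A positive bump multiplies the additive interior by
    (1 + bump), capped at full inhibition, so the interior is >= additive
    everywhere.  Signal = corner x (1 - inhibition) + noise.
    """
    px, py = cfg.agent_x_curve, cfg.agent_y_curve
    n, m = cfg.dx.size, cfg.dy.size
    inhib = np.zeros((n, m))
    inhib[:, 0] = _margin_curve(cfg.dx, px)
    inhib[0, :] = _margin_curve(cfg.dy, py)
    for i in range(1, n):
        for j in range(1, m):
            add = _loewe_reference(cfg.dx[i], cfg.dy[j], px, py)
            inhib[i, j] = min(1.0, add * (1.0 + cfg.synergy_bump))
    truth_additive = inhib.copy()
    if cfg.noise_sd:
        rng = substream(cfg.seed, "matrix/noise")
        inhib = inhib + rng.normal(0.0, cfg.noise_sd, size=inhib.shape)
    signal = cfg.corner_signal * (1.0 - inhib)
    signal[0, 0] = cfg.corner_signal  # untreated corner defines the scale
    frame = pd.DataFrame(signal, index=cfg.dx, columns=cfg.dy)
    truth = {
        "inhibition_clean": truth_additive.tolist(),
        "synergy_bump": cfg.synergy_bump,
        "noise_sd": cfg.noise_sd,
    }
    return frame, truth


# ---------------------------------------------------------------------------
# transcript tables
# ---------------------------------------------------------------------------


@dataclass
class GeneIsoformSpec:
    """Per-gene baseline TPM and treatment shift per isoform class."""

    gene: str
    baseline_tpm: dict  # class -> TPM, classes in {CDS-L, CDS-S, AS}
    treatment_log2fc: dict = field(default_factory=dict)  # class -> log2 shift
    n_transcripts_per_class: int = 2


#: a splicing-sensitive gene: long-form CDS falls, short form and aberrant
#: transcripts are induced under treatment
MCL1_LIKE = GeneIsoformSpec(
    gene="MCL1like",
    baseline_tpm={"CDS-L": 30.0, "CDS-S": 1.0, "AS": 0.5},
    treatment_log2fc={"CDS-L": -1.0, "CDS-S": 2.0, "AS": 3.0},
)

#: a splicing-resistant gene: highly expressed long form, nothing shifts
BCL2L1_LIKE = GeneIsoformSpec(
    gene="BCL2L1like",
    baseline_tpm={"CDS-L": 60.0, "CDS-S": 0.8, "AS": 0.4},
    treatment_log2fc={},
)


@dataclass
class SimTranscriptConfig:
    """Transcript-table generator configuration.

    ``noise_ln_sd`` is the sd of multiplicative lognormal measurement
    noise in natural-log space (0.2 ~ 30 % CV, typical of transcript
    quantification at moderate depth); triplicate arms match the assay
    design.  Counts are derived from TPM at ``library_size`` reads.
    """

    genes: Sequence[GeneIsoformSpec] = field(default_factory=lambda: [MCL1_LIKE, BCL2L1_LIKE])
    n_replicates: int = 3
    noise_ln_sd: float = 0.2
    library_size: int = 10_000_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_replicates <= 0 or self.library_size <= 0:
            raise ValueError("replicates and library size must be positive")
        if self.noise_ln_sd < 0:
            raise ValueError("noise sd must be non-negative")
        from .isoform_response import ISOFORM_CLASSES

        for spec in self.genes:
            for cls, tpm in spec.baseline_tpm.items():
                if cls not in ISOFORM_CLASSES:
                    raise ValueError(f"unknown class {cls!r}")
                if tpm < 0:
                    raise ValueError(f"negative baseline TPM for {spec.gene}/{cls}")


def simulate_transcripts(cfg: SimTranscriptConfig) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Generate (tpm_table, count_table, truth).

    Both tables carry transcript_id / gene / tclass plus ``control_<r>``
    and ``treated_<r>`` sample columns.  Treated replicates are shifted by
    the per-class log2 effects; counts = TPM x libsize / 1e6 rounded.
    """
    rows = []
    for spec in cfg.genes:
        for cls, tpm in spec.baseline_tpm.items():
            per_tx = tpm / spec.n_transcripts_per_class
            for k in range(spec.n_transcripts_per_class):
                rows.append(
                    {
                        "transcript_id": f"{spec.gene}.{cls}.{k + 1}",
                        "gene": spec.gene,
                        "tclass": cls,
                        "baseline": per_tx,
                        "log2fc": spec.treatment_log2fc.get(cls, 0.0),
                    }
                )
    base = pd.DataFrame(rows)
    n_tx = len(base)
    tpm = base[["transcript_id", "gene", "tclass"]].copy()
    sample_cols = []
    for arm, shift in (("control", 0.0), ("treated", 1.0)):
        for r in range(1, cfg.n_replicates + 1):
            rng = substream(cfg.seed, f"transcripts/{arm}/{r}")
            mean = base["baseline"].to_numpy() * 2.0 ** (shift * base["log2fc"].to_numpy())
            noise = (
                np.exp(rng.normal(0.0, cfg.noise_ln_sd, size=n_tx)) if cfg.noise_ln_sd else 1.0
            )
            col = f"{arm}_{r}"
            tpm[col] = mean * noise
            sample_cols.append(col)
    counts = tpm.copy()
    counts[sample_cols] = np.rint(
        tpm[sample_cols].to_numpy(dtype=float) * cfg.library_size / 1e6
    ).astype(np.int64)
    truth = {
        "effects": {
            spec.gene: dict(spec.treatment_log2fc) for spec in cfg.genes
        },
        "control_cols": [c for c in sample_cols if c.startswith("control")],
        "treated_cols": [c for c in sample_cols if c.startswith("treated")],
    }
    return tpm, counts, truth
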