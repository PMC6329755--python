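"""T0-anchored dose-response pharmacology.

Viability plates carry three well roles: day-0 (T0) wells read before
compound addition, end-point vehicle wells (C), and treated wells at each
concentration.  Metrics follow the NCI-style two-regime convention:

* growth inhibition is measured against vehicle growth over T0 —
  GI50 is the concentration where the fitted signal crosses
  T0 + 0.5 (C - T0), GI90 where it crosses T0 + 0.1 (C - T0);
* lethality is measured against T0 — LD50 is the concentration where the
  signal falls to 0.5 T0;
* Emax is the maximal effect versus T0 on a -100 % (complete kill) to 0 %
  (no net loss) scale: 100 * min(0, (T_best - T0) / T0), with T_best the
  minimum observed per-dose mean over the tested range.

Crossings are solved on a four-parameter logistic (4PL) fit of signal vs
log dose and are never extrapolated beyond the tested concentrations.
The module also hosts the small assay-QC and auxiliary quantifications:
Z'-factor, delta-delta-Ct relative qPCR quantities, the caspase activation
index, and the caliper tumor-volume formula.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

logger = logging.getLogger(__name__)

__all__ = [
    "DoseResponse",
    "FourPLFit",
    "PharmMetrics",
    "QcMetrics",
    "four_pl",
    "inverse_four_pl",
    "fit_4pl",
    "compute_metrics",
    "zprime",
    "ddct_quantify",
    "caspase_index",
    "tumor_volume",
]


def four_pl(d: np.ndarray, bottom: float, top: float, ec50: float, hill: float) -> np.ndarray:
    """4PL response at dose d: bottom + (top - bottom) / (1 + (d/ec50)^hill).

    With hill > 0 the curve decreases from ``top`` (zero dose) to
    ``bottom`` (infinite dose); at d = ec50 it sits at the midpoint.
    """
    d = np.asarray(d, dtype=float)
    with np.errstate(divide="ignore", over="ignore"):
        ratio = np.where(d > 0, (d / ec50) ** hill, 0.0)
    return bottom + (top - bottom) / (1.0 + ratio)


def inverse_four_pl(y: float, bottom: float, top: float, ec50: float, hill: float) -> float:
    """Closed-form dose at which the 4PL attains response ``y``.

    Returns nan when ``y`` is outside the open (bottom, top) range.
    """
    if not (min(bottom, top) < y < max(bottom, top)):
        return float("nan")
    return float(ec50 * ((top - y) / (y - bottom)) ** (1.0 / hill))


@dataclass
class DoseResponse:
    """One (cell line, compound) dose series anchored by T0 and vehicle."""

    doses: np.ndarray  # ascending, positive concentrations (nM)
    signal: np.ndarray  # treated mean signal per dose
    t0: float  # day-0 signal
    vehicle: float  # end-point vehicle control signal
    replicate_signal: pd.DataFrame | None = None  # per-dose replicate wells (optional)

    def __post_init__(self) -> None:
        self.doses = np.asarray(self.doses, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.doses.ndim != 1 or self.doses.shape != self.signal.shape:
            raise ValueError("doses and signal must be 1-D and the same length")
        if np.any(self.doses <= 0):
            raise ValueError("doses must be strictly positive")
        if np.any(np.diff(self.doses) <= 0):
            raise ValueError("doses must be strictly ascending")
        if self.t0 <= 0:
            raise ValueError("T0 signal must be positive")
        if self.vehicle <= 0:
            raise ValueError("vehicle signal must be positive")
        if np.any(self.signal < 0):
            raise ValueError("signals must be non-negative")

    @classmethod
    def from_plate_table(cls, table: pd.DataFrame) -> "DoseResponse":
        """Build from a plate TSV with columns well, role, concentration, signal.

        Roles are ``T0``, ``vehicle`` and ``dose``; replicate wells of one
        role/concentration are averaged (and retained).
        """
        required = {"role", "concentration", "signal"}
        if not required <= set(table.columns):
            raise ValueError(f"plate table needs columns {sorted(required)}")
        t0_wells = table.loc[table["role"] == "T0", "signal"]
        veh_wells = table.loc[table["role"] == "vehicle", "signal"]
        if t0_wells.empty or veh_wells.empty:
            raise ValueError("plate table must contain T0 and vehicle wells")
        dosed = table[table["role"] == "dose"]
        means = dosed.groupby("concentration")["signal"].mean().sort_index()
        return cls(
            doses=means.index.to_numpy(dtype=float),
            signal=means.to_numpy(dtype=float),
            t0=float(t0_wells.mean()),
            vehicle=float(veh_wells.mean()),
            replicate_signal=dosed[["concentration", "signal"]].reset_index(drop=True),
        )


@dataclass
class FourPLFit:
    params: tuple[float, float, float, float] | None  # (bottom, top, ec50, hill)
    r2: float
    ok: bool  # False -> interpolation fallback in force
    method: str  # "4pl" or "interp"

    def predict(self, d: np.ndarray) -> np.ndarray:
        if self.params is None:
            raise ValueError("no 4PL parameters (interpolation-only fit)")
        return four_pl(np.asarray(d, dtype=float), *self.params)


def fit_4pl(
    doses: np.ndarray,
    signal: np.ndarray,
    *,
    r2_threshold: float = 0.8,
) -> FourPLFit:
    """Least-squares 4PL fit of signal against log dose.

    Falls back to a flagged monotone piecewise-linear interpolation mode
    when fewer than four distinct doses are supplied, the optimizer fails,
    or the fit explains the data poorly (R^2 below threshold) — degenerate
    flat responses land there via a near-zero Hill slope.
    """
    doses = np.asarray(doses, dtype=float)
    signal = np.asarray(signal, dtype=float)
    if len(np.unique(doses)) < 4:
        logger.warning("fit_4pl: <4 distinct doses, interpolation-only mode")
        return FourPLFit(params=None, r2=float("nan"), ok=False, method="interp")
    span = signal.max() - signal.min()
    p0 = (
        float(signal.min()),
        float(signal.max()),
        float(np.exp(np.mean(np.log(doses)))),
        1.0,
    )
    bounds = (
        [-0.05 * max(span, 1.0), -0.05 * max(span, 1.0), doses.min() / 1e3, 1e-6],
        [signal.max() * 2 + 1, signal.max() * 2 + 1, doses.max() * 1e3, 20.0],
    )
    try:
        popt, _ = curve_fit(four_pl, doses, signal, p0=p0, bounds=bounds, maxfev=20000)
    except (RuntimeError, ValueError):
        return FourPLFit(params=None, r2=float("nan"), ok=False, method="interp")
    resid = signal - four_pl(doses, *popt)
    ss_tot = float(np.sum((signal - signal.mean()) ** 2))
    if ss_tot == 0:
        # flat response: nothing to explain, degenerate fit
        return FourPLFit(params=None, r2=float("nan"), ok=False, method="interp")
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot
    if r2 < r2_threshold:
        return FourPLFit(params=None, r2=r2, ok=False, method="interp")
    return FourPLFit(params=tuple(float(v) for v in popt), r2=r2, ok=True, method="4pl")


@dataclass
class PharmMetrics:
    gi50: float  # nM, nan when undefined
    gi90: float
    ld50: float
    emax: float  # percent in [-100, 0]
    fit: FourPLFit
    flags: dict = field(default_factory=dict)


def _first_crossing_fitted(
    fit: FourPLFit, doses: np.ndarray, target: float, *, n_grid: int = 512, rel_tol: float = 1e-6
) -> float:
    """Smallest tested-range dose where the fitted curve crosses ``target``.

    Scans a log-spaced grid over [min dose, max dose] for the first sign
    change, then bisects on log dose; nan when the curve never crosses
    inside the tested range (no extrapolation).
    """
    lo, hi = np.log10(doses.min()), np.log10(doses.max())
    grid = np.logspace(lo, hi, n_grid)
    vals = fit.predict(grid) - target
    if vals[0] == 0:
        return float(grid[0])
    sign0 = np.sign(vals[0])
    idx = np.nonzero(np.sign(vals) != sign0)[0]
    if idx.size == 0:
        return float("nan")
    a, b = np.log10(grid[idx[0] - 1]), np.log10(grid[idx[0]])
    fa = fit.predict(10**a) - target
    for _ in range(100):
        m = 0.5 * (a + b)
        fm = fit.predict(10**m) - target
        if fa * fm <= 0:
            b = m
        else:
            a, fa = m, fm
        if b - a <= rel_tol * max(1.0, abs(m)):
            break
    return float(10 ** (0.5 * (a + b)))


def _first_crossing_interp(doses: np.ndarray, signal: np.ndarray, target: float) -> float:
    """Interpolation fallback: first bracketing dose pair, linear in log dose."""
    for i in range(len(doses) - 1):
        y0, y1 = signal[i] - target, signal[i + 1] - target
        if y0 == 0:
            return float(doses[i])
        if y0 * y1 < 0:
            f = y0 / (y0 - y1)
            return float(10 ** (np.log10(doses[i]) + f * (np.log10(doses[i + 1]) - np.log10(doses[i]))))
    if signal[-1] == target:
        return float(doses[-1])
    return float("nan")


def compute_metrics(curve: DoseResponse) -> PharmMetrics:
    """GI50 / GI90 / LD50 / Emax for one dose series.

    Undefined metrics are returned as nan with a reason flag rather than
    extrapolated; a vehicle that failed to outgrow T0 voids the GI metrics.
    """
    fit = fit_4pl(curve.doses, curve.signal)
    flags: dict = {"fit_method": fit.method}

    def crossing(target: float) -> float:
        if fit.ok:
            return _first_crossing_fitted(fit, curve.doses, target)
        return _first_crossing_interp(curve.doses, curve.signal, target)

    if curve.vehicle <= curve.t0:
        gi50 = gi90 = float("nan")
        flags["gi_reason"] = "vehicle_no_growth"
    else:
        gi50 = crossing(curve.t0 + 0.5 * (curve.vehicle - curve.t0))
        gi90 = crossing(curve.t0 + 0.1 * (curve.vehicle - curve.t0))
    ld50 = crossing(0.5 * curve.t0)
    t_best = float(curve.signal.min())
    emax = 100.0 * min(0.0, (t_best - curve.t0) / curve.t0)
    emax = float(np.clip(emax, -100.0, 0.0))
    return PharmMetrics(gi50=gi50, gi90=gi90, ld50=ld50, emax=emax, fit=fit, flags=flags)


@dataclass
class QcMetrics:
    zprime: float
    passed: bool


def zprime(
    neg_wells: Sequence[float], pos_wells: Sequence[float], *, threshold: float = 0.6
) -> QcMetrics:
    """Z'-factor assay quality: 1 - 3 (sd_pos + sd_neg) / |mean_pos - mean_neg|.

    Sample standard deviations (ddof=1); coincident control means make the
    statistic undefined (nan, fail flag).
    """
    neg = np.asarray(neg_wells, dtype=float)
    pos = np.asarray(pos_wells, dtype=float)
    if neg.size < 2 or pos.size < 2:
        raise ValueError("need >= 2 wells per control arm")
    sep = abs(pos.mean() - neg.mean())
    if sep == 0:
        return QcMetrics(zprime=float("nan"), passed=False)
    z = 1.0 - 3.0 * (pos.std(ddof=1) + neg.std(ddof=1)) / sep
    return QcMetrics(zprime=float(z), passed=bool(z > threshold))


def ddct_quantify(
    ct_table: pd.DataFrame,
    calibrator: str,
    *,
    sample_col: str = "sample",
    target_col: str = "ct_target",
    ref_col: str = "ct_ref",
) -> pd.DataFrame:
    """Delta-delta-Ct relative quantification against a reference gene.

    dCt = Ct_target - Ct_ref per sample; ddCt = dCt - dCt_calibrator;
    relative quantity RQ = 2^(-ddCt) (1 for the calibrator by
    construction).  Samples missing the reference Ct are dropped with a
    log entry.
    """
    df = ct_table.copy()
    missing = df[ref_col].isna() | df[target_col].isna()
    if missing.any():
        logger.info("ddct_quantify: dropping %d samples with missing Ct", int(missing.sum()))
        df = df[~missing]
    if calibrator not in set(df[sample_col]):
        raise ValueError(f"calibrator sample {calibrator!r} not present (or dropped)")
    df = df.copy()
    df["dct"] = df[target_col] - df[ref_col]
    cal_dct = float(df.loc[df[sample_col] == calibrator, "dct"].mean())
    df["ddct"] = df["dct"] - cal_dct
    df["rq"] = 2.0 ** (-df["ddct"])
    return df.reset_index(drop=True)


def caspase_index(green_intensity: float, confluence_percent: float) -> float:
    """Apoptosis index: total green (caspase reporter) intensity / % confluence.

    Zero confluence leaves the index undefined (nan).
    """
    if confluence_percent < 0 or green_intensity < 0:
        raise ValueError("intensity and confluence must be non-negative")
    if confluence_percent == 0:
        logger.warning("caspase_index: zero confluence, index undefined")
        return float("nan")
    return float(green_intensity) / float(confluence_percent)


def tumor_volume(length_mm: float, width_mm: float) -> float:
    """Caliper tumor volume V = (L x W^2) / 2, with L the larger measure."""
    if length_mm <= 0 or width_mm <= 0:
        raise ValueError("caliper measurements must be positive")
    long_, short = max(length_mm, width_mm), min(length_mm, width_mm)
    return float(long_ * short**2 / 2.0)
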