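"""Loewe-additivity surface and synergy scoring for dose-matrix assays.

An n x m combination matrix holds viability signal at every pairing of
two agents' dose series (first row/column = zero dose).  Fractional
inhibition is normalized to the untreated corner, the single-agent
margins are fitted with monotone 4PL curves, and the Loewe-additive
expectation at a dose pair (d1, d2) is the effect E solving the
dose-equivalence condition

    d1 / D_x(E) + d2 / D_y(E) = 1,

where D_x, D_y are the single-agent doses producing E.  For a compound
crossed with itself this reduces to margin(d1 + d2), the additive null the
assay uses as its control.  Loewe excess is observed minus additive
inhibition, and the scalar synergy score is a dilution-weighted volume of
positive excess:

    score = ln(f_x) * ln(f_y) * sum_cells max(0, I_data) * max(0, excess)

with f_x, f_y the per-axis dilution factors.  Exact additivity scores 0.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

logger = logging.getLogger(__name__)

__all__ = [
    "DoseMatrix",
    "MarginModel",
    "LoeweSurface",
    "SynergyResult",
    "build_inhibition_matrix",
    "fit_margin",
    "invert_margin",
    "loewe_surface",
    "synergy_score",
]

EFFECT_TOL = 1e-6  # bisection tolerance on the effect (inhibition) scale


@dataclass
class DoseMatrix:
    """Fractional-inhibition grid with zero-dose margins.

    ``inhibition[i, j]`` is the inhibition at (dx[i], dy[j]); row 0 and
    column 0 are the single-agent margins of agents y and x respectively.
    """

    dx: np.ndarray  # doses along axis 0, dx[0] == 0
    dy: np.ndarray  # doses along axis 1, dy[0] == 0
    inhibition: np.ndarray  # in [0, 1], inhibition[0, 0] == 0
    signal: np.ndarray | None = None  # raw signal grid, if built from one

    def __post_init__(self) -> None:
        self.dx = np.asarray(self.dx, dtype=float)
        self.dy = np.asarray(self.dy, dtype=float)
        self.inhibition = np.asarray(self.inhibition, dtype=float)
        if self.dx[0] != 0 or self.dy[0] != 0:
            raise ValueError("dose vectors must start at zero (untreated margins)")
        if np.any(np.diff(self.dx) <= 0) or np.any(np.diff(self.dy) <= 0):
            raise ValueError("dose vectors must be strictly ascending")
        if self.inhibition.shape != (self.dx.size, self.dy.size):
            raise ValueError("inhibition grid shape does not match dose vectors")

    @property
    def margin_x(self) -> np.ndarray:
        """Single-agent inhibition of agent x: I(dx, 0)."""
        return self.inhibition[:, 0]

    @property
    def margin_y(self) -> np.ndarray:
        """Single-agent inhibition of agent y: I(0, dy)."""
        return self.inhibition[0, :]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.inhibition, index=self.dx, columns=self.dy)


def build_inhibition_matrix(raw: pd.DataFrame | np.ndarray, dx=None, dy=None) -> DoseMatrix:
    """Normalize a raw signal grid to fractional inhibition.

    ``raw`` is a signal DataFrame whose index/columns are the dose vectors
    (CSV layout), or a 2-D array with explicit ``dx, dy``.  Inhibition is
    1 - signal / signal(0, 0), clipped to [0, 1]; a non-positive untreated
    corner is an error.
    """
    if isinstance(raw, pd.DataFrame):
        dx = raw.index.to_numpy(dtype=float)
        dy = raw.columns.to_numpy(dtype=float)
        grid = raw.to_numpy(dtype=float)
    else:
        if dx is None or dy is None:
            raise ValueError("dose vectors required with an array input")
        grid = np.asarray(raw, dtype=float)
        dx = np.asarray(dx, dtype=float)
        dy = np.asarray(dy, dtype=float)
    if dx[0] != 0 or dy[0] != 0:
        raise ValueError("matrix must include zero-dose margins (first row/col)")
    corner = grid[0, 0]
    if corner <= 0:
        raise ValueError("untreated corner signal must be positive")
    inhib = np.clip(1.0 - grid / corner, 0.0, 1.0)
    inhib[0, 0] = 0.0
    return DoseMatrix(dx=dx, dy=dy, inhibition=inhib, signal=grid)


def _inhib_4pl(d, top, ec50, hill):
    # monotone-increasing inhibition margin with zero bottom
    d = np.asarray(d, dtype=float)
    with np.errstate(divide="ignore", over="ignore"):
        ratio = np.where(d > 0, (ec50 / d) ** hill, np.inf)
    return top / (1.0 + ratio)


@dataclass
class MarginModel:
    """Fitted (or interpolated) monotone single-agent inhibition curve."""

    doses: np.ndarray
    inhibition: np.ndarray  # monotone non-decreasing representation
    params: tuple[float, float, float] | None  # (top, ec50, hill) or None
    method: str  # "4pl" or "isotonic-interp"

    @property
    def plateau(self) -> float:
        """Maximum attainable inhibition of the fitted margin."""
        if self.params is not None:
            return float(self.params[0])
        return float(self.inhibition.max())

    def effect(self, d) -> np.ndarray:
        if self.params is not None:
            return _inhib_4pl(d, *self.params)
        return np.interp(np.asarray(d, dtype=float), self.doses, self.inhibition)

    def inverse(self, e: float) -> float:
        """Smallest dose achieving effect ``e``; +inf beyond the plateau."""
        if e <= 0:
            return 0.0
        if e >= self.plateau:
            return float("inf")
        if self.params is not None:
            top, ec50, hill = self.params
            return float(ec50 * (e / (top - e)) ** (1.0 / hill))
        idx = np.searchsorted(self.inhibition, e, side="left")
        if idx == 0:
            return float(self.doses[0])
        y0, y1 = self.inhibition[idx - 1], self.inhibition[idx]
        if y1 == y0:
            return float(self.doses[idx])
        f = (e - y0) / (y1 - y0)
        return float(self.doses[idx - 1] + f * (self.doses[idx] - self.doses[idx - 1]))


def fit_margin(doses: np.ndarray, inhibition: np.ndarray) -> MarginModel:
    """Fit a monotone 4PL (bottom fixed at 0) to a single-agent margin.

    Falls back to an isotonic monotone interpolation when the optimizer
    fails or the fitted curve is a poor description (R^2 < 0.5) — the
    fallback pools non-monotone stretches with a running maximum before
    linear interpolation.
    """
    doses = np.asarray(doses, dtype=float)
    inhibition = np.asarray(inhibition, dtype=float)
    pos = doses > 0
    try:
        top0 = max(float(inhibition.max()), 1e-3)
        p0 = (top0, float(np.exp(np.mean(np.log(doses[pos])))), 1.0)
        popt, _ = curve_fit(
            _inhib_4pl,
            doses,
            inhibition,
            p0=p0,
            bounds=([1e-6, doses[pos].min() / 1e3, 1e-3], [1.05, doses.max() * 1e3, 20.0]),
            maxfev=20000,
        )
        resid = inhibition - _inhib_4pl(doses, *popt)
        ss_tot = float(np.sum((inhibition - inhibition.mean()) ** 2))
        r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 0.0
        if r2 >= 0.5:
            return MarginModel(
                doses=doses,
                inhibition=_inhib_4pl(doses, *popt),
                params=tuple(float(v) for v in popt),
                method="4pl",
            )
    except (RuntimeError, ValueError):
        pass
    logger.warning("fit_margin: non-monotone or poorly fit margin, isotonic fallback")
    mono = np.maximum.accumulate(inhibition)
    return MarginModel(doses=doses, inhibition=mono, params=None, method="isotonic-interp")


def invert_margin(margin: MarginModel, effect: float) -> float:
    """Dose achieving ``effect`` on a fitted margin (+inf past the plateau)."""
    return margin.inverse(effect)


@dataclass
class LoeweSurface:
    i_loewe: np.ndarray  # additive expectation per cell
    excess: np.ndarray  # observed - additive
    capped: np.ndarray  # cells where the combined dose exceeded both plateaus
    margin_x: MarginModel
    margin_y: MarginModel


def _solve_loewe_cell(d1: float, d2: float, mx: MarginModel, my: MarginModel) -> tuple[float, bool]:
    """Bisection on E of d1/Dx(E) + d2/Dy(E) = 1 over (0, min plateau)."""
    cap = min(mx.plateau, my.plateau)

    def g(e: float) -> float:
        s = 0.0
        inv_x = mx.inverse(e)
        inv_y = my.inverse(e)
        s += d1 / inv_x if np.isfinite(inv_x) else 0.0
        s += d2 / inv_y if np.isfinite(inv_y) else 0.0
        return s - 1.0

    hi = cap * (1.0 - 1e-9)
    if g(hi) > 0:
        # combined dose beyond both plateaus: cap at the lower plateau
        return cap, True
    lo = 0.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if g(mid) > 0:
            lo = mid
        else:
            hi = mid
        if hi - lo <= EFFECT_TOL:
            break
    return 0.5 * (lo + hi), False


def loewe_surface(matrix: DoseMatrix) -> LoeweSurface:
    """Additive (Loewe) expectation and excess for every cell of the grid.

    Margins are fitted from the zero-dose row/column; the zero-zero corner
    is additive at 0 by construction, pure-margin cells reduce to the
    fitted single-agent curves.
    """
    mx = fit_margin(matrix.dx, matrix.margin_x)
    my = fit_margin(matrix.dy, matrix.margin_y)
    n, m = matrix.inhibition.shape
    i_loewe = np.zeros((n, m))
    capped = np.zeros((n, m), dtype=bool)
    for i in range(n):
        for j in range(m):
            d1, d2 = matrix.dx[i], matrix.dy[j]
            if d1 == 0 and d2 == 0:
                continue
            if d2 == 0:
                i_loewe[i, j] = float(mx.effect(d1))
            elif d1 == 0:
                i_loewe[i, j] = float(my.effect(d2))
            else:
                i_loewe[i, j], capped[i, j] = _solve_loewe_cell(d1, d2, mx, my)
    excess = matrix.inhibition - i_loewe
    return LoeweSurface(i_loewe=i_loewe, excess=excess, capped=capped, margin_x=mx, margin_y=my)


@dataclass
class SynergyResult:
    score: float
    fx: float  # dilution factor along x
    fy: float
    positive_excess_volume: float  # ungated sum of positive excess
    excess: np.ndarray


def _dilution_factor(doses: np.ndarray, axis_name: str) -> float:
    nz = doses[doses > 0]
    if nz.size < 2:
        raise ValueError(f"axis {axis_name}: need >= 2 non-zero doses")
    ratios = nz[1:] / nz[:-1]
    factor = float(np.exp(np.mean(np.log(ratios))))
    if not np.allclose(ratios, ratios[0], rtol=1e-6):
        warnings.warn(
            f"axis {axis_name}: non-uniform dilution, using geometric-mean factor",
            RuntimeWarning,
        )
    return factor


def synergy_score(
    surface: LoeweSurface, matrix: DoseMatrix, *, gate: str = "both", excess_tol: float = 1e-5
) -> SynergyResult:
    """Scalar synergy score from the excess grid.

    ``score = ln(fx) ln(fy) * sum_interior w(cell)`` where with the default
    ``gate="both"`` each interior cell contributes
    ``max(0, I_data) * max(0, excess)`` and with ``gate="excess"`` simply
    ``max(0, excess)``.  Excess below ``excess_tol`` — the additive
    surface is only resolved to the effect-solver tolerance — counts as
    zero, so exactly additive data scores exactly 0; the score never
    decreases when excess increases.
    """
    if gate not in ("both", "excess"):
        raise ValueError("gate must be 'both' or 'excess'")
    fx = _dilution_factor(matrix.dx, "x")
    fy = _dilution_factor(matrix.dy, "y")
    interior = surface.excess[1:, 1:]
    data = matrix.inhibition[1:, 1:]
    pos_excess = np.where(interior > excess_tol, interior, 0.0)
    if gate == "both":
        contrib = np.maximum(0.0, data) * pos_excess
    else:
        contrib = pos_excess
    score = float(np.log(fx) * np.log(fy) * contrib.sum())
    return SynergyResult(
        score=score,
        fx=fx,
        fy=fy,
        positive_excess_volume=float(pos_excess.sum()),
        excess=surface.excess,
    )
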