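"""Hill-equation fitting, curve classification and AUC for qHTS titrations.

Every compound in a quantitative high-throughput screen is tested as a
multi-point titration, so the primary readout is a concentration-response
curve (CRC) in percent activity (0 = neutral control, -100 = positive
control, i.e. full loss of viability).  This module fits the four-parameter
Hill equation

    a(c) = zero + (inf - zero) / (1 + (ac50 / c) ** h)

to each titration, assigns the signed qHTS curve class, and integrates the
fitted curve into a single area-under-curve (AUC) statistic on which all
downstream hit calling operates.

Curve-class taxonomy (negative sign = decreasing response):

====== ==========================================================
class  meaning
====== ==========================================================
-1.1   complete curve, both asymptotes, |efficacy| >= 80
-1.2   complete curve, both asymptotes, |efficacy| < 80
-2.1   incomplete curve (single asymptote), |efficacy| >= 80
-2.2   incomplete curve (single asymptote), |efficacy| < 80
-3     significant activity only at the highest concentration
 4     inactive (|efficacy| below the inactivity band)
 5     active but poorly fit (r^2 below the quality threshold)
====== ==========================================================
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "Titration",
    "HillFit",
    "hill",
    "fit_hill",
    "classify_curve",
    "compute_auc",
    "profile_titrations",
    "ACTIVE_CLASSES",
    "INACTIVITY_BAND",
    "HIGH_EFFICACY",
    "R2_THRESHOLD",
]

#: classes counted as "high-quality CRC" by the hit-calling rules
ACTIVE_CLASSES = (-1.1, -1.2, -2.1, -2.2)

#: |efficacy| below this (percent) is called inactive (class 4)
INACTIVITY_BAND = 25.0
#: |efficacy| at or above this splits x.1 from x.2 sub-classes
HIGH_EFFICACY = 80.0
#: minimum r^2 for class -1/-2 assignment
R2_THRESHOLD = 0.9
#: a dose "observes" an asymptote when the fitted curve is within this
#: fraction of the efficacy span of it
PLATEAU_FRACTION = 0.1

# fit bounds (percent activity / dimensionless slope)
ZERO_BOUNDS = (-30.0, 30.0)
INF_BOUNDS = (-130.0, 30.0)
SLOPE_BOUNDS = (0.3, 8.0)


@dataclass
class Titration:
    """Dose-response vector for one compound x cell line x channel.

    ``activities`` is the replicate-aggregated (median) percent-activity
    vector aligned with ``concs`` (µM, strictly increasing).  Per-replicate
    activities, when available, are kept in ``replicates`` as a
    (n_replicates, n_points) array with NaN for missing wells.
    """

    compound_id: str
    cell_line: str
    channel: str
    concs: np.ndarray
    activities: np.ndarray
    replicates: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.concs = np.asarray(self.concs, dtype=float)
        self.activities = np.asarray(self.activities, dtype=float)
        if self.concs.shape != self.activities.shape:
            raise ValueError("concs and activities must have the same length")
        if np.any(np.diff(self.concs) <= 0):
            raise ValueError("concs must be strictly increasing")

    @property
    def n_points(self) -> int:
        return self.concs.size


@dataclass
class HillFit:
    """Fitted Hill parameters plus goodness of fit.

    ``zero_activity`` is the low-concentration asymptote ("Zero activity"),
    ``inf_activity`` the high-concentration asymptote; their difference is
    the efficacy.  ``ac50`` is in µM.
    """

    zero_activity: float
    inf_activity: float
    ac50: float
    hill_slope: float
    r2: float
    converged: bool
    residual_ss: float = field(default=np.nan, repr=False)

    @property
    def efficacy(self) -> float:
        return self.inf_activity - self.zero_activity

    def predict(self, concs: np.ndarray) -> np.ndarray:
        return hill(np.asarray(concs, dtype=float), self.zero_activity,
                    self.inf_activity, self.ac50, self.hill_slope)


def hill(c: np.ndarray, zero: float, inf_: float, ac50: float, h: float) -> np.ndarray:
    """Four-parameter Hill curve evaluated at concentrations ``c`` (µM)."""
    c = np.asarray(c, dtype=float)
    return zero + (inf_ - zero) / (1.0 + (ac50 / c) ** h)


def _r2(y: np.ndarray, resid_ss: float) -> float:
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        return 1.0 if resid_ss < 1e-12 else 0.0
    return 1.0 - resid_ss / ss_tot


def _grid_start(concs: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float]:
    """Coarse search over (ac50, h); zero/inf solved by linear least squares.

    For fixed (ac50, h) the Hill model is linear in (zero, inf):
    a = zero * (1 - f) + inf * f with f = 1 / (1 + (ac50/c)^h), so each grid
    node costs a 2x2 solve.  This gives a robust start for the bounded
    refinement without a full four-dimensional search.
    """
    ac50_grid = np.geomspace(concs[0] / 3.0, concs[-1] * 3.0, 17)
    h_grid = np.array([0.5, 0.8, 1.2, 1.8, 2.8, 4.5])
    best = (np.inf, 0.0, 0.0, 1.0, 1.0)
    for h in h_grid:
        # f: (n_ac50, n_conc)
        f = 1.0 / (1.0 + (ac50_grid[:, None] / concs[None, :]) ** h)
        g = 1.0 - f
        # normal equations per ac50
        a11 = np.einsum("ij,ij->i", g, g)
        a12 = np.einsum("ij,ij->i", g, f)
        a22 = np.einsum("ij,ij->i", f, f)
        b1 = g @ y
        b2 = f @ y
        det = a11 * a22 - a12 * a12
        det = np.where(np.abs(det) < 1e-12, np.nan, det)
        zero = (b1 * a22 - b2 * a12) / det
        inf_ = (a11 * b2 - a12 * b1) / det
        zero = np.clip(np.nan_to_num(zero), *ZERO_BOUNDS)
        inf_ = np.clip(np.nan_to_num(inf_), *INF_BOUNDS)
        pred = zero[:, None] * g + inf_[:, None] * f
        sse = np.sum((pred - y[None, :]) ** 2, axis=1)
        i = int(np.argmin(sse))
        if sse[i] < best[0]:
            best = (float(sse[i]), float(zero[i]), float(inf_[i]),
                    float(ac50_grid[i]), float(h))
    return best[1], best[2], best[3], best[4]


def fit_hill(t: Titration) -> HillFit:
    """Least-squares Hill fit of a titration's median activities.

    A coarse (AC50, slope) grid with analytic asymptote solves seeds a
    bounded trust-region refinement.  Bounds: zero in [-30, 30], inf in
    [-130, 30], slope in [0.3, 8], AC50 within a decade of the tested range.
    """
    if t.n_points < 4:
        raise ValueError("need at least 4 dose points to fit the Hill equation")
    y = t.activities
    if np.any(~np.isfinite(y)):
        keep = np.isfinite(y)
        if keep.sum() < 4:
            return HillFit(np.nan, np.nan, np.nan, np.nan, np.nan, False)
        t = Titration(t.compound_id, t.cell_line, t.channel,
                      t.concs[keep], y[keep])
        y = t.activities
    concs = t.concs

    z0, i0, a0, h0 = _grid_start(concs, y)
    lo = np.array([ZERO_BOUNDS[0], INF_BOUNDS[0], concs[0] / 10.0, SLOPE_BOUNDS[0]])
    hi = np.array([ZERO_BOUNDS[1], INF_BOUNDS[1], concs[-1] * 10.0, SLOPE_BOUNDS[1]])
    x0 = np.clip([z0, i0, a0, h0], lo, hi)

    def resid(p: np.ndarray) -> np.ndarray:
        return hill(concs, p[0], p[1], p[2], p[3]) - y

    def jac(p: np.ndarray) -> np.ndarray:
        zero, inf_, ac50, h = p
        f = 1.0 / (1.0 + (ac50 / concs) ** h)
        ff = f * (1.0 - f)
        span = inf_ - zero
        return np.column_stack([
            1.0 - f,
            f,
            -span * (h / ac50) * ff,
            -span * np.log(ac50 / concs) * ff,
        ])

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sol = least_squares(resid, x0, jac=jac, bounds=(lo, hi),
                                method="trf",
                                x_scale=[10.0, 10.0, max(a0, 1e-6), 1.0],
                                xtol=1e-9, ftol=1e-9, max_nfev=60)
        # status 0 = iteration budget exhausted: the best iterate is still a
        # valid (if unpolished) fit; only reject invalid solutions
        ok = sol.status >= 0 and np.all(np.isfinite(sol.x))
    except Exception:  # pragma: no cover - optimizer pathologies
        ok = False
    if not ok:
        sse0 = float(np.sum(resid(x0) ** 2))
        return HillFit(z0, i0, a0, h0, _r2(y, sse0), False, sse0)
    z, i_, a, h = (float(v) for v in sol.x)
    sse = float(2.0 * sol.cost)
    return HillFit(z, i_, a, h, _r2(y, sse), True, sse)


def classify_curve(fit: HillFit, t: Titration) -> float:
    """Assign the signed qHTS curve class to a fitted titration.

    Decision table (first match wins):

    1. |efficacy| < 25 -> 4 (inactive)
    2. significant activity (>= 25 from baseline) only at the top
       concentration -> -3
    3. r^2 >= 0.9 and both asymptotes observed within the tested range
       (fitted curve within 10% of the span of each asymptote for at least
       one dose) -> -1.1 / -1.2 by the 80% efficacy split
    4. r^2 >= 0.9 with a single (or no) observed asymptote -> -2.1 / -2.2
    5. otherwise (active but poor fit) -> 5

    Non-converged fits fall back on data-driven efficacy (difference of the
    medians of the two top-dose and two bottom-dose activities).
    """
    y = t.activities
    if fit.converged and np.isfinite(fit.efficacy):
        eff = fit.efficacy
        baseline = fit.zero_activity
    else:
        eff = float(np.median(y[-2:]) - np.median(y[:2]))
        baseline = float(np.median(y[:2]))

    if abs(eff) < INACTIVITY_BAND:
        return 4.0

    sig = np.abs(y - baseline) >= INACTIVITY_BAND
    if sig[-1] and not np.any(sig[:-1]):
        return -3.0

    if fit.converged and fit.r2 >= R2_THRESHOLD:
        pred = fit.predict(t.concs)
        span = abs(fit.efficacy)
        low_seen = np.any(np.abs(pred - fit.zero_activity) <= PLATEAU_FRACTION * span)
        high_seen = np.any(np.abs(pred - fit.inf_activity) <= PLATEAU_FRACTION * span)
        if low_seen and high_seen:
            return -1.1 if abs(eff) >= HIGH_EFFICACY else -1.2
        return -2.1 if abs(eff) >= HIGH_EFFICACY else -2.2
    return 5.0


def compute_auc(fit: HillFit, t: Titration) -> float:
    """Trapezoidal AUC of the fitted curve at the assay concentrations.

    Integration runs over the dilution-step index (unit spacing per step),
    not raw log-concentration, so curves from 7-, 8- and 11-point libraries
    share one scale: constant -100% activity over an 11-point titration
    integrates to -1000.  Non-converged fits fall back on the empirical
    points.
    """
    if t.n_points < 2:
        raise ValueError("AUC undefined for fewer than 2 dose points")
    y = fit.predict(t.concs) if fit.converged else t.activities
    return float(np.trapezoid(y))


def profile_titrations(titrations: list[Titration]) -> pd.DataFrame:
    """Fit, classify and integrate a batch of titrations.

    Returns the interchange profile table consumed by all hit calling, one
    row per compound x cell line x channel with columns: compound_id,
    cell_line, channel, zero, inf, ac50_um, hill, r2, converged,
    curve_class, auc, n_points.

    Per the class-4 convention, the AUC of a clean inactive (class 4 with
    every median activity inside the inactivity band) is set to exactly 0.
    """
    rows = []
    for t in titrations:
        fit = fit_hill(t)
        cls = classify_curve(fit, t)
        auc = compute_auc(fit, t)
        if cls == 4.0 and np.all(np.abs(t.activities) < INACTIVITY_BAND):
            auc = 0.0
        rows.append({
            "compound_id": t.compound_id,
            "cell_line": t.cell_line,
            "channel": t.channel,
            "zero": fit.zero_activity,
            "inf": fit.inf_activity,
            "ac50_um": fit.ac50,
            "hill": fit.hill_slope,
            "r2": fit.r2,
            "converged": fit.converged,
            "curve_class": cls,
            "auc": auc,
            "n_points": t.n_points,
        })
    return pd.DataFrame(rows)
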