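"""Reference-tissue kinetic modeling and occupancy calibration.

The simplified reference tissue model (SRTM) writes a target region's
time-activity curve (TAC) ``C_t(t)`` in terms of a receptor-free reference
region's curve ``C_r(t)``::

    C_t(t) = R1 * C_r(t) + (k2 - R1 * k2a) * C_r(t) (x) exp(-k2a * t)

with ``(x)`` denoting convolution, ``R1`` the relative delivery, ``k2`` the
tissue clearance rate (1/min) and ``k2a = k2 / (1 + BP_ND)``.  ``fit_srtm``
estimates (R1, k2, BP_ND) by the basis-function method: for each candidate
``k2a`` on a log-spaced grid the model is linear in (R1, k2 - R1*k2a), so a
weighted linear least-squares solve scores every grid point and a bounded
1-D refinement polishes the winner.

Occupancy is the fractional loss of binding potential under a blocking
drug, ``100 * (1 - BP_treat / BP_base)``; across regions with uniform
blockade it equals the slope of the (modified) Lassen regression of
``BP_base - BP_treat`` on ``BP_base``.  Dose- and time-dependence of
occupancy are calibrated with a one-parameter Hill model
``Occ(dose) = 100 * dose / (ED50 + dose)`` and an exponential washout
``Occ(day) = Occ_day0 * exp(-lambda * day)``.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import OptimizeWarning, curve_fit, least_squares, minimize_scalar

__all__ = [
    "TimeActivityCurve",
    "SRTMFit",
    "OccupancyEstimate",
    "HillModel",
    "DecayModel",
    "conv_trap",
    "srtm_forward",
    "fit_srtm",
    "occupancy_from_bp",
    "lassen_occupancy",
    "fit_hill",
    "fit_decay",
    "predict_occupancy",
]

#: internal uniform grid step for convolutions (min)
FINE_DT = 0.05
#: default log-spaced k2a search grid: (lo, hi) 1/min, number of points
K2A_GRID = (0.006, 0.6, 100)


@dataclass(frozen=True)
class TimeActivityCurve:
    """One region's dynamic PET radioactivity series."""

    region: str
    condition: str
    frame_start: np.ndarray  # min
    frame_end: np.ndarray  # min
    activity: np.ndarray  # kBq/mL

    def __post_init__(self) -> None:
        fs = np.asarray(self.frame_start, dtype=float)
        fe = np.asarray(self.frame_end, dtype=float)
        act = np.asarray(self.activity, dtype=float)
        object.__setattr__(self, "frame_start", fs)
        object.__setattr__(self, "frame_end", fe)
        object.__setattr__(self, "activity", act)
        if not (fs.shape == fe.shape == act.shape):
            raise ValueError("frame_start, frame_end, activity must align")
        if np.any(fe <= fs) or np.any(fs[1:] < fe[:-1] - 1e-9):
            raise ValueError("frames must be increasing and non-overlapping")
        if not np.all(np.isfinite(act)):
            raise ValueError("activity must be finite")

    @property
    def midpoints(self) -> np.ndarray:
        return 0.5 * (self.frame_start + self.frame_end)

    @property
    def durations(self) -> np.ndarray:
        return self.frame_end - self.frame_start

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "region": self.region,
                "condition": self.condition,
                "frame_start_min": self.frame_start,
                "frame_end_min": self.frame_end,
                "activity_kbq_ml": self.activity,
            }
        )

    @staticmethod
    def from_frame(df: pd.DataFrame, region: str, condition: str) -> "TimeActivityCurve":
        sel = df[(df["region"] == region) & (df["condition"] == condition)]
        sel = sel.sort_values("frame_start_min")
        if sel.empty:
            raise ValueError(f"no TAC rows for region={region!r} condition={condition!r}")
        return TimeActivityCurve(
            region=region,
            condition=condition,
            frame_start=sel["frame_start_min"].to_numpy(),
            frame_end=sel["frame_end_min"].to_numpy(),
            activity=sel["activity_kbq_ml"].to_numpy(),
        )


@dataclass
class SRTMFit:
    region: str
    r1: float
    k2: float
    bp_nd: float
    k2a: float
    rss: float
    fitted: np.ndarray
    at_grid_boundary: bool = False

    def __post_init__(self) -> None:
        if self.k2a <= 0:
            raise ValueError("k2a must be positive")


@dataclass
class OccupancyEstimate:
    occupancy_pct: float
    method: str  # "per_region_eq3" | "lassen_slope"
    regions: list[str] = field(default_factory=list)
    intercept: float | None = None
    se_pct: float | None = None
    out_of_range: bool = False


@dataclass
class HillModel:
    ed50: float
    rss: float = 0.0

    def __post_init__(self) -> None:
        if self.ed50 <= 0:
            raise ValueError("ED50 must be positive")


@dataclass
class DecayModel:
    occ_day0: float
    decay_rate: float
    rss: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.occ_day0 <= 100.0 + 1e-9:
            raise ValueError("occ_day0 must lie in [0, 100]")
        if self.decay_rate < 0:
            raise ValueError("decay rate must be non-negative")


def conv_trap(f: np.ndarray, g: np.ndarray, dt: float) -> np.ndarray:
    """Causal convolution of two sampled functions, trapezoidal rule."""
    n = len(f)
    out = np.convolve(f, g)[:n] - 0.5 * (f[0] * g + g[0] * f)
    return out * dt


# --- analytic reference-region curve used by the synthetic generator ------
# plasma input: gamma variate A * t * exp(-t / tau)
# reference impulse response: c1*exp(-t1*t) + c2*exp(-t2*t)
# their convolution has the closed form used below.
_INPUT_A = 400.0  # kBq/mL/min^2, sets the overall activity scale
_INPUT_TAU = 0.7  # min, time-to-peak of the bolus
_REF_TERMS = ((0.18, 0.30), (0.035, 0.02))  # (amplitude 1/min, rate 1/min)


def reference_tac(t: np.ndarray) -> np.ndarray:
    """Closed-form reference-region TAC at times ``t`` (min)."""
    t = np.asarray(t, dtype=float)
    b = 1.0 / _INPUT_TAU
    out = np.zeros_like(t)
    for c, theta in _REF_TERMS:
        mu = b - theta
        # int_0^t s e^{-b s} c e^{-theta (t-s)} ds
        out += c * np.exp(-theta * t) * (1.0 - np.exp(-mu * t) * (1.0 + mu * t)) / mu**2
    return _INPUT_A * out


def srtm_forward(
    t: np.ndarray,
    ref: np.ndarray,
    r1: float,
    k2: float,
    bp_nd: float,
    dt: float,
) -> np.ndarray:
    """SRTM target curve on a uniform grid ``t`` given the reference curve."""
    k2a = k2 / (1.0 + bp_nd)
    return r1 * ref + (k2 - r1 * k2a) * conv_trap(ref, np.exp(-k2a * t), dt)


def _fine_grid(t_end: float, dt: float) -> np.ndarray:
    n = int(np.ceil(t_end / dt)) + 1
    return np.arange(n) * dt


def _interp_fine(tac: TimeActivityCurve, t_fine: np.ndarray) -> np.ndarray:
    """Measured frame values linearly interpolated onto the fine grid.

    The curve is anchored at (0, 0): no activity before tracer arrival.
    """
    mids = np.concatenate(([0.0], tac.midpoints))
    vals = np.concatenate(([0.0], tac.activity))
    return np.interp(t_fine, mids, vals)


def fit_srtm(
    target: TimeActivityCurve,
    reference: TimeActivityCurve,
    k2a_grid: tuple[float, float, int] = K2A_GRID,
    dt: float = FINE_DT,
    refine: bool = True,
) -> SRTMFit:
    """Basis-function SRTM estimate of (R1, k2, BP_ND) for one region.

    Frames are weighted by duration.  If the best grid point sits on the
    grid boundary the fit is flagged (``at_grid_boundary``) and a warning
    is emitted.
    """
    if not (
        np.allclose(target.frame_start, reference.frame_start)
        and np.allclose(target.frame_end, reference.frame_end)
    ):
        raise ValueError("target and reference must share a frame schedule")

    mids = target.midpoints
    w = np.sqrt(target.durations / target.durations.sum())
    y = target.activity
    t_fine = _fine_grid(target.frame_end[-1], dt)
    ref_fine = _interp_fine(reference, t_fine)
    ref_mid = np.interp(mids, t_fine, ref_fine)

    def solve(k2a: float) -> tuple[float, np.ndarray]:
        basis = conv_trap(ref_fine, np.exp(-k2a * t_fine), dt)
        basis_mid = np.interp(mids, t_fine, basis)
        X = np.column_stack([ref_mid, basis_mid])
        theta, *_ = np.linalg.lstsq(X * w[:, None], y * w, rcond=None)
        fitted = X @ theta
        rss = float(np.sum(w**2 * (y - fitted) ** 2))
        return rss, theta

    lo, hi, n = k2a_grid
    grid = np.geomspace(lo, hi, n)
    rss_grid = np.array([solve(k)[0] for k in grid])
    j = int(np.argmin(rss_grid))
    boundary = j in (0, n - 1)
    if boundary:
        warnings.warn("best k2a at grid boundary; estimate may be unreliable", stacklevel=2)

    k2a_best = grid[j]
    if refine and not boundary:
        res = minimize_scalar(
            lambda k: solve(k)[0],
            bounds=(grid[j - 1], grid[j + 1]),
            method="bounded",
            options={"xatol": 1e-10},
        )
        k2a_best = float(res.x)

    rss, (r1, theta2) = solve(k2a_best)
    k2 = theta2 + r1 * k2a_best
    bp = k2 / k2a_best - 1.0
    basis = conv_trap(ref_fine, np.exp(-k2a_best * t_fine), dt)
    fitted = r1 * ref_mid + theta2 * np.interp(mids, t_fine, basis)
    return SRTMFit(
        region=target.region,
        r1=float(r1),
        k2=float(k2),
        bp_nd=float(bp),
        k2a=float(k2a_best),
        rss=rss,
        fitted=fitted,
        at_grid_boundary=boundary,
    )


def occupancy_from_bp(bp_baseline: float, bp_treatment: float) -> OccupancyEstimate:
    """Occupancy (%) from the fractional reduction of binding potential."""
    if bp_baseline <= 0:
        raise ValueError("baseline BP_ND must be positive")
    occ = 100.0 * (1.0 - bp_treatment / bp_baseline)
    return OccupancyEstimate(
        occupancy_pct=float(occ),
        method="per_region_eq3",
        out_of_range=not (0.0 <= occ <= 100.0),
    )


def lassen_occupancy(
    region_bps: pd.DataFrame,
    zero_intercept: bool = False,
) -> OccupancyEstimate:
    """Global occupancy as the slope of the modified Lassen regression.

    ``region_bps`` needs columns ``region, bp_baseline, bp_treatment`` with
    one row per region (>= 3 regions).  The reduction in binding
    ``bp_baseline - bp_treatment`` is regressed on ``bp_baseline``; the
    slope times 100 is the occupancy.  The intercept is free by default.
    """
    required = {"region", "bp_baseline", "bp_treatment"}
    if not required.issubset(region_bps.columns):
        raise ValueError(f"region_bps must have columns {sorted(required)}")
    if len(region_bps) < 3:
        raise ValueError("Lassen regression requires at least 3 regions")
    x = region_bps["bp_baseline"].to_numpy(dtype=float)
    y = x - region_bps["bp_treatment"].to_numpy(dtype=float)
    if np.ptp(x) < 1e-12:
        raise ValueError("degenerate input: baseline BP_ND has zero variance")
    X = x[:, None] if zero_intercept else sm.add_constant(x)
    fit = sm.OLS(y, X).fit()
    slope = fit.params[-1]
    occ = 100.0 * float(slope)
    return OccupancyEstimate(
        occupancy_pct=occ,
        method="lassen_slope",
        regions=list(region_bps["region"]),
        intercept=None if zero_intercept else float(fit.params[0]),
        se_pct=100.0 * float(fit.bse[-1]),
        out_of_range=not (0.0 <= occ <= 100.0),
    )


def hill_occupancy(dose: np.ndarray | float, ed50: float) -> np.ndarray | float:
    return 100.0 * np.asarray(dose, dtype=float) / (ed50 + np.asarray(dose, dtype=float))


def decay_occupancy(day: np.ndarray | float, occ_day0: float, decay_rate: float):
    return occ_day0 * np.exp(-decay_rate * np.asarray(day, dtype=float))


def fit_hill(doses: Sequence[float], occupancies: Sequence[float]) -> HillModel:
    """One-parameter least-squares Hill calibration (maximum fixed at 100%).

    A single (dose, occupancy) pair is inverted algebraically:
    ``ED50 = dose * (100 - occ) / occ``.
    """
    d = np.asarray(doses, dtype=float)
    o = np.asarray(occupancies, dtype=float)
    if d.size == 0 or d.size != o.size:
        raise ValueError("need matching non-empty dose and occupancy arrays")
    if np.any(d <= 0):
        raise ValueError("doses must be positive")
    if d.size == 1:
        if not 0.0 < o[0] < 100.0:
            raise ValueError("single-pair inversion needs occupancy strictly in (0, 100)")
        ed50 = float(d[0] * (100.0 - o[0]) / o[0])
        return HillModel(ed50=ed50, rss=0.0)
    res = least_squares(
        lambda p: hill_occupancy(d, p[0]) - o,
        x0=[np.median(d)],
        bounds=([1e-9], [np.inf]),
    )
    return HillModel(ed50=float(res.x[0]), rss=float(2 * res.cost))


def fit_decay(days: Sequence[float], occupancies: Sequence[float]) -> DecayModel:
    """Nonlinear least-squares exponential-washout fit in natural scale.

    A log-linear OLS on the positive observations initializes (Occ_day0,
    lambda); fitting then proceeds on the raw percentages so that noise
    truncation near zero does not bias the estimate.  Non-positive
    occupancies are dropped (with a warning) from the initializer only.
    """
    t = np.asarray(days, dtype=float)
    o = np.asarray(occupancies, dtype=float)
    if t.size < 2 or np.unique(t).size < 2:
        raise ValueError("need >= 2 points spanning >= 2 distinct days")
    pos = o > 0
    if not np.all(pos):
        warnings.warn("non-positive occupancies dropped from log-linear initializer", stacklevel=2)
    if pos.sum() >= 2 and np.ptp(t[pos]) > 0:
        b, a = np.polyfit(t[pos], np.log(o[pos]), 1)
        occ0_init = float(np.clip(np.exp(a), 1e-6, 100.0))
        lam_init = float(max(-b, 0.0))
    else:
        occ0_init, lam_init = float(np.clip(o.max(), 1e-6, 100.0)), 0.1
    if np.ptp(o) < 1e-12:  # constant series: no decay
        return DecayModel(occ_day0=float(o[0]), decay_rate=0.0, rss=0.0)
    with warnings.catch_warnings():
        # exact 2-point fits legitimately have a singular covariance
        warnings.simplefilter("ignore", category=OptimizeWarning)
        popt, _ = curve_fit(
            decay_occupancy,
            t,
            o,
            p0=[occ0_init, lam_init],
            bounds=([0.0, 0.0], [100.0, np.inf]),
            maxfev=10000,
        )
    rss = float(np.sum((decay_occupancy(t, *popt) - o) ** 2))
    return DecayModel(occ_day0=float(popt[0]), decay_rate=float(popt[1]), rss=rss)


def predict_occupancy(model: HillModel | DecayModel, at: float) -> float:
    """Closed-form occupancy (%) at a dose (Hill) or day (decay)."""
    if at < 0:
        raise ValueError("dose/day must be non-negative")
    if isinstance(model, HillModel):
        return float(hill_occupancy(at, model.ed50))
    if isinstance(model, DecayModel):
        return float(decay_occupancy(at, model.occ_day0, model.decay_rate))
    raise TypeError(f"unsupported model type {type(model)!r}")
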