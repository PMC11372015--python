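"""Irreversible two-tissue compartment model, Patlak analysis and parametric maps.

The irreversible 2TCM (dephosphorylation rate k4 fixed to 0) describes the
measured tissue concentration as

    C_T(t) = (1 - vb) * [ (K1*k2/(k2+k3)) * exp(-(k2+k3) t)
                          + K1*k3/(k2+k3) ] (x) C_p(t)  +  vb * C_b(t)

with (x) denoting convolution, C_p the plasma and C_b the whole-blood input
(not distinguished here: both default to the same image-derived input
function).  K1 is in mL/cm3/min, k2 and k3 in 1/min, vb a unitless fraction.
The net influx (macro) rate is Ki = K1*k3/(k2+k3).

Convolution is carried out on a uniform fine grid with exact integration of
the exponential kernel over each step assuming a piecewise-linear input
(realised as a first-order IIR recursion, so a model evaluation is O(n));
frame values are time-averages of the model over each frame, matching how
scanners report frames.

Time units: rate constants are per minute, but the public API accepts the
package-wide seconds-based :class:`~autoaif.frames.FrameSchedule` and
:class:`~autoaif.idif.InputFunction`; conversions are internal and explicit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, signal, stats
from sklearn.base import BaseEstimator

from .frames import DynamicImage, FrameSchedule, VoxelMask
from .idif import InputFunction

__all__ = [
    "KineticParams",
    "FitResult",
    "ParametricMap",
    "ki_macro",
    "model_2tcm_irr",
    "fit_2tcm",
    "patlak_fit",
    "parametric_maps",
    "TwoTissueIrrFit",
    "PatlakFitter",
]


@dataclass(frozen=True)
class KineticParams:
    """Rate constants of the irreversible 2TCM for one voxel or region.

    All parameters live in the fit box [0, 1] (K1 in mL/cm3/min, k2 and k3 in
    1/min, vb a fraction).  ``Ki`` is the derived macro-parameter.
    """

    K1: float
    k2: float
    k3: float
    vb: float = 0.0

    def __post_init__(self) -> None:
        for name in ("K1", "k2", "k3", "vb"):
            v = float(getattr(self, name))
            if not np.isfinite(v) or v < 0.0 or v > 1.0:
                raise ValueError(f"{name}={v!r} outside the model box [0, 1]")
            object.__setattr__(self, name, v)

    @property
    def Ki(self) -> float:
        """Net influx rate K1*k3/(k2+k3); 0 when k2+k3 == 0 (then k3 == 0)."""
        if self.k2 + self.k3 == 0.0:
            return 0.0
        return ki_macro(self.K1, self.k2, self.k3)


def ki_macro(K1: float, k2: float, k3: float) -> float:
    """Net influx rate Ki = K1*k3/(k2+k3) (mL/cm3/min)."""
    if k2 + k3 <= 0.0:
        raise ValueError("ki_macro requires k2 + k3 > 0")
    return K1 * k3 / (k2 + k3)


def _exp_conv(cp: np.ndarray, dt: float, beta: float) -> np.ndarray:
    """E(t) = int_0^t exp(-beta (t-s)) cp(s) ds for piecewise-linear cp.

    Exact per-step integration realised as a first-order IIR filter.  ``dt``
    and ``beta`` share a time unit; the result has units of cp * time.
    """
    cp = np.asarray(cp, dtype=float)
    if beta == 0.0:
        out = np.empty_like(cp)
        out[0] = 0.0
        np.cumsum((cp[1:] + cp[:-1]) * (dt / 2.0), out=out[1:])
        return out
    d = np.exp(-beta * dt)
    # int_0^dt exp(-beta (dt-u)) (c + m u) du with m the segment slope
    m = np.diff(cp) / dt
    g = (1.0 - d) / beta
    step = cp[:-1] * g + m * (dt / beta - g / beta)
    y = signal.lfilter([1.0], [1.0, -d], step)
    return np.concatenate([[0.0], y])


def _running_time_integral(cp: np.ndarray, dt: float) -> np.ndarray:
    return _exp_conv(cp, dt, 0.0)


class _ModelGrid:
    """Precomputed fine-grid input and frame-averaging machinery.

    The input function is sampled on a uniform grid (default 2 s step) from
    t = 0 to the end of the acquisition; values before the input's first
    sample are clamped to that sample after inserting a zero at t = 0 when the
    input starts after time zero (pre-arrival activity is zero).
    """

    def __init__(
        self,
        input_fn: InputFunction,
        schedule: FrameSchedule | None = None,
        t_end_s: float | None = None,
        step_s: float = 2.0,
        blood_fn: InputFunction | None = None,
    ) -> None:
        if schedule is not None:
            t_end_s = schedule.total_span
        if t_end_s is None:
            t_end_s = float(input_fn.times[-1])
        self.step_s = float(step_s)
        self.t_s = np.arange(0.0, t_end_s + self.step_s / 2.0, self.step_s)
        self.dt_min = self.step_s / 60.0
        self.cp = _sample_input(input_fn, self.t_s)
        self.cb = self.cp if blood_fn is None else _sample_input(blood_fn, self.t_s)
        self.int_cp = _running_time_integral(self.cp, self.dt_min)
        self.schedule = schedule
        if schedule is not None:
            # frame-average weights: mean of fine samples inside each frame
            idx_start = np.searchsorted(self.t_s, schedule.start - 1e-9, side="left")
            idx_end = np.searchsorted(self.t_s, schedule.end + 1e-9, side="right")
            self._frame_slices = [slice(a, max(b, a + 1)) for a, b in zip(idx_start, idx_end)]

    def frame_average(self, fine: np.ndarray) -> np.ndarray:
        return np.array([fine[s].mean() for s in self._frame_slices])

    def model(self, K1: float, k2: float, k3: float, vb: float) -> np.ndarray:
        beta = k2 + k3
        if beta > 0.0:
            conv = (K1 * k2 / beta) * _exp_conv(self.cp, self.dt_min, beta) + (
                K1 * k3 / beta
            ) * self.int_cp
        else:
            # k2 = k3 = 0: kernel degenerates to the constant K1
            conv = K1 * self.int_cp
        return (1.0 - vb) * conv + vb * self.cb


def _sample_input(input_fn: InputFunction, t_s: np.ndarray) -> np.ndarray:
    t = input_fn.times
    v = input_fn.values
    if t[0] > 0.0:
        t = np.concatenate([[0.0], t])
        v = np.concatenate([[0.0], v])
    return np.interp(t_s, t, v)


def model_2tcm_irr(
    times_min,
    params: KineticParams,
    input_fn: InputFunction,
    blood_fn: InputFunction | None = None,
    schedule: FrameSchedule | None = None,
    step_s: float = 2.0,
) -> np.ndarray:
    """Forward irreversible-2TCM tissue curve.

    Parameters
    ----------
    times_min
        Output time points in minutes (ignored when ``schedule`` is given, in
        which case frame averages over the schedule's frames are returned).
    params
        Kinetic parameters (per-minute rates).
    input_fn, blood_fn
        Plasma input and optional separate whole-blood curve (both seconds
        based); by default C_b = C_p = ``input_fn``.
    """
    if times_min is None and schedule is None:
        raise ValueError("provide output times or a schedule")
    if times_min is not None:
        times_min = np.asarray(times_min, dtype=float)
    t_end_s = (
        schedule.total_span if schedule is not None else float(np.max(times_min)) * 60.0
    )
    if input_fn.times[-1] < t_end_s - 1e-6:
        raise ValueError("input function does not cover the requested time span")
    grid = _ModelGrid(input_fn, schedule=schedule, t_end_s=t_end_s, step_s=step_s,
                      blood_fn=blood_fn)
    fine = grid.model(params.K1, params.k2, params.k3, params.vb)
    if schedule is not None:
        return grid.frame_average(fine)
    return np.interp(times_min * 60.0, grid.t_s, fine)


@dataclass(frozen=True)
class FitResult:
    """Outcome of one voxel/region fit: parameters plus convergence diagnostics."""

    params: KineticParams
    success: bool
    cost: float
    message: str = ""


def fit_2tcm(
    tac,
    input_fn: InputFunction,
    schedule: FrameSchedule,
    blood_fn: InputFunction | None = None,
    step_s: float = 2.0,
    _grid: "_ModelGrid | None" = None,
) -> FitResult:
    """Bounded nonlinear least-squares fit of the irreversible 2TCM to a TAC.

    Initial values (0.01, 0.01, 0.01, 0.01), box [0, 1]^4, unweighted
    residuals, no smoothing or outlier handling.  The bounded fit uses a
    trust-region-reflective least-squares solver (an LM-class local method
    honouring the box).  Non-convergence is reported in the returned
    :class:`FitResult` rather than raised.
    """
    tac = np.asarray(tac, dtype=float)
    if tac.shape != (schedule.n_frames,):
        raise ValueError("tac length must equal the number of frames")
    grid = _grid if _grid is not None else _ModelGrid(
        input_fn, schedule=schedule, step_s=step_s, blood_fn=blood_fn
    )

    def resid(p):
        return grid.frame_average(grid.model(*p)) - tac

    try:
        sol = optimize.least_squares(
            resid,
            x0=np.full(4, 0.01),
            bounds=(np.zeros(4), np.ones(4)),
            method="trf",
        )
        params = KineticParams(*np.clip(sol.x, 0.0, 1.0))
        return FitResult(params, bool(sol.success), float(sol.cost), sol.message)
    except Exception as exc:  # pragma: no cover - defensive
        return FitResult(KineticParams(0, 0, 0, 0), False, np.inf, str(exc))


def patlak_fit(
    tac,
    input_fn: InputFunction,
    schedule: FrameSchedule,
    t_star_min: float = 40.0,
    step_s: float = 2.0,
) -> tuple[float, float]:
    """Patlak graphical analysis: late-time slope estimates Ki.

    Ordinary linear least squares of y(t) = C_T(t)/C_p(t) against
    x(t) = int_0^t C_p / C_p(t), restricted to frames whose midpoint is at or
    after ``t_star_min`` (default 40 min, the pseudo-equilibrium window).
    Returns ``(Ki_patlak, intercept)``.
    """
    tac = np.asarray(tac, dtype=float)
    if tac.shape != (schedule.n_frames,):
        raise ValueError("tac length must equal the number of frames")
    mid_s = schedule.midtimes
    sel = mid_s >= t_star_min * 60.0
    if sel.sum() < 2:
        raise ValueError("need at least two frames past t* for the Patlak fit")
    grid = _ModelGrid(input_fn, schedule=schedule, step_s=step_s)
    cp_mid = np.interp(mid_s[sel], grid.t_s, grid.cp)
    if np.any(cp_mid <= 0):
        raise ValueError("input function must be positive on the Patlak window")
    int_mid = np.interp(mid_s[sel], grid.t_s, grid.int_cp)
    x = int_mid / cp_mid
    y = tac[sel] / cp_mid
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept)


@dataclass
class ParametricMap:
    """3D parameter grids assembled from per-voxel fits.

    Non-fitted voxels hold NaN; ``success`` flags voxels whose nonlinear fit
    converged.
    """

    maps: dict[str, np.ndarray]
    success: np.ndarray

    def __getitem__(self, key: str) -> np.ndarray:
        return self.maps[key]


def parametric_maps(
    image: DynamicImage,
    mask: VoxelMask,
    input_fn: InputFunction,
    methods: tuple[str, ...] = ("2tcm", "patlak"),
    t_star_min: float = 40.0,
    step_s: float = 2.0,
) -> ParametricMap:
    """Voxel-wise kinetic fits over a mask, assembled into parameter grids."""
    if len(mask) == 0:
        raise ValueError("mask is empty")
    shape = image.shape
    names: list[str] = []
    if "2tcm" in methods:
        names += ["K1", "k2", "k3", "vb", "Ki"]
    if "patlak" in methods:
        names += ["Ki_patlak", "patlak_intercept"]
    maps = {n: np.full(shape, np.nan) for n in names}
    success = np.zeros(shape, dtype=bool)
    grid = _ModelGrid(input_fn, schedule=image.schedule, step_s=step_s)
    for i, j, k in mask.coords:
        tac = image.values[i, j, k, :]
        ok = True
        if "2tcm" in methods:
            res = fit_2tcm(tac, input_fn, image.schedule, _grid=grid)
            p = res.params
            maps["K1"][i, j, k] = p.K1
            maps["k2"][i, j, k] = p.k2
            maps["k3"][i, j, k] = p.k3
            maps["vb"][i, j, k] = p.vb
            maps["Ki"][i, j, k] = p.Ki
            ok = ok and res.success
        if "patlak" in methods:
            try:
                slope, intercept = patlak_fit(
                    tac, input_fn, image.schedule, t_star_min=t_star_min, step_s=step_s
                )
                maps["Ki_patlak"][i, j, k] = slope
                maps["patlak_intercept"][i, j, k] = intercept
            except ValueError:
                ok = False
        success[i, j, k] = ok
    return ParametricMap(maps=maps, success=success)


# ---------------------------------------------------------------------------
# scikit-learn style estimators


class TwoTissueIrrFit(BaseEstimator):
    """Irreversible-2TCM fitter over one or many time-activity curves.

    Parameters
    ----------
    input_fn : InputFunction
        Plasma/whole-blood input driving the model.
    schedule : FrameSchedule
        Acquisition frame grid of the TACs.
    step_s : float
        Fine convolution grid step in seconds.

    Attributes
    ----------
    params_ : list[KineticParams]
        Fitted parameters, one entry per row of X.
    Ki_ : ndarray
        Derived net influx rate per row.
    success_ : ndarray of bool
        Convergence flag per row.
    """

    def __init__(self, input_fn=None, schedule=None, step_s: float = 2.0):
        self.input_fn = input_fn
        self.schedule = schedule
        self.step_s = step_s

    def fit(self, X, y=None):
        if self.input_fn is None or self.schedule is None:
            raise ValueError("input_fn and schedule are required")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.schedule.n_frames:
            raise ValueError("X columns must equal the number of frames")
        grid = _ModelGrid(self.input_fn, schedule=self.schedule, step_s=self.step_s)
        results = [
            fit_2tcm(row, self.input_fn, self.schedule, _grid=grid) for row in X
        ]
        self.results_ = results
        self.params_ = [r.params for r in results]
        self.Ki_ = np.array([p.Ki for p in self.params_])
        self.success_ = np.array([r.success for r in results])
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X=None):
        """Model curves (frame averages) for the fitted parameters."""
        if not hasattr(self, "params_"):
            raise ValueError("estimator is not fitted")
        grid = _ModelGrid(self.input_fn, schedule=self.schedule, step_s=self.step_s)
        return np.vstack(
            [grid.frame_average(grid.model(p.K1, p.k2, p.k3, p.vb)) for p in self.params_]
        )


class PatlakFitter(BaseEstimator):
    """Patlak graphical-analysis estimator over one or many TACs.

    Attributes
    ----------
    Ki_ : ndarray
        Patlak slope per row of X.
    intercept_ : ndarray
        Patlak intercept per row.
    """

    def __init__(self, input_fn=None, schedule=None, t_star_min: float = 40.0,
                 step_s: float = 2.0):
        self.input_fn = input_fn
        self.schedule = schedule
        self.t_star_min = t_star_min
        self.step_s = step_s

    def fit(self, X, y=None):
        if self.input_fn is None or self.schedule is None:
            raise ValueError("input_fn and schedule are required")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        out = [
            patlak_fit(row, self.input_fn, self.schedule,
                       t_star_min=self.t_star_min, step_s=self.step_s)
            for row in X
        ]
        self.Ki_ = np.array([o[0] for o in out])
        self.intercept_ = np.array([o[1] for o in out])
        self.n_features_in_ = X.shape[1]
        return self
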