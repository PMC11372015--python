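"""Input-function formation: cluster averages, the hybrid automatic IDIF and
the descending-aorta reference VOI.

The automatic image-derived input function (IDIF_auto) combines the initial
peak of the arterial cluster average with the post-peak portion of the venous
cluster average: arteries give the correct bolus timing and the sharper peak,
while the much thicker veins suffer far less partial-volume underestimation
of the tail.  Cluster averages are formed at the three peak-threshold levels
a1 = 0.4, 0.5, 0.6 (a2 = 0.9) and averaged across levels before combination.

All curve surgery happens on a uniform 2 s grid with linear interpolation
(monotone, no overshoot at the sharp peak); area under the curve uses the
trapezoidal rule with period boundaries inserted as grid points so period
AUCs sum exactly to the total.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from sklearn.base import BaseEstimator

from .frames import DynamicImage, FrameSchedule, TACMatrix
from .peaks import (
    cohort_peak_tail_stats,
    cwt_peak_detect,
    cwt_peak_detect_matrix,
    tail_values,
)
from .vessels import ClusterResult, ThresholdConfig, cluster_two, filter_candidates, \
    label_artery_vein

__all__ = [
    "InputFunction",
    "TimePeriods",
    "average_cluster",
    "multi_threshold_idif",
    "time_periods",
    "period_auc_errors",
    "align_peaks",
    "form_idif_auto",
    "reference_da_idif",
    "IDIFExtractor",
]

_GRID_STEP_S = 2.0
_LABELS = ("artery", "vein", "auto", "reference_da", "truth")


@dataclass(frozen=True)
class InputFunction:
    """A labelled activity curve on a time grid (seconds, kBq/mL)."""

    times: np.ndarray
    values: np.ndarray
    label: str = "auto"

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.ndim != 1 or v.shape != t.shape:
            raise ValueError("times and values must be 1D and the same length")
        if t.size < 2:
            raise ValueError("an input function needs at least two samples")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(v))):
            raise ValueError("times and values must be finite")
        if self.label not in _LABELS:
            raise ValueError(f"label must be one of {_LABELS}")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)

    def at(self, t) -> np.ndarray:
        """Linear interpolation (clamped at the ends)."""
        return np.interp(t, self.times, self.values)

    def resample(self, step: float = _GRID_STEP_S) -> "InputFunction":
        grid = np.arange(self.times[0], self.times[-1] + step / 2.0, step)
        return replace(self, times=grid, values=self.at(grid))

    def auc(self) -> float:
        """Total trapezoidal area (kBq/mL * s)."""
        return float(np.trapezoid(self.values, self.times))

    def relabel(self, label: str) -> "InputFunction":
        return replace(self, label=label)


@dataclass(frozen=True)
class TimePeriods:
    """Boundaries of the seven adjudication windows T1..T7 (seconds).

    T1 runs from 0 to 20 s past the identified peak, T2..T6 are successive
    10 min windows and T7 extends to the end of the acquisition.
    """

    boundaries: np.ndarray

    def __post_init__(self) -> None:
        b = np.asarray(self.boundaries, dtype=float)
        if b.shape != (8,) or np.any(np.diff(b) <= 0) or b[0] != 0.0:
            raise ValueError("need 8 strictly increasing boundaries starting at 0")
        object.__setattr__(self, "boundaries", b)

    @property
    def n_periods(self) -> int:
        return 7

    def window(self, p: int) -> tuple[float, float]:
        """(start, end) of period p in 1..7."""
        return float(self.boundaries[p - 1]), float(self.boundaries[p])


def average_cluster(tacs, rows, times, label: str = "artery") -> InputFunction:
    """Pointwise mean of the selected TAC rows on the frame-midtime grid."""
    if isinstance(tacs, TACMatrix):
        tacs = tacs.activities
    tacs = np.atleast_2d(np.asarray(tacs, dtype=float))
    rows = np.asarray(rows, dtype=np.intp)
    if rows.size == 0:
        raise ValueError("cannot average an empty cluster")
    return InputFunction(times=np.asarray(times, dtype=float),
                         values=tacs[rows].mean(axis=0), label=label)


def _single_level(tacs, times, peak_values, peak_times, tails, stats, cfg,
                  normalize: bool = True):
    rows = filter_candidates(tacs, peak_values, tails, stats, cfg)
    if rows.size < 2:
        raise ValueError(
            f"threshold level a1={cfg.a1} left {rows.size} candidate curve(s)"
        )
    sub = tacs.activities[rows] if isinstance(tacs, TACMatrix) else \
        np.atleast_2d(np.asarray(tacs))[rows]
    ca, cb = cluster_two(sub, normalize=normalize)
    local = label_artery_vein((ca, cb), peak_times[rows], tails[rows])
    return ClusterResult(
        artery_rows=rows[local.artery_rows],
        vein_rows=rows[local.vein_rows],
        artery_ttp=local.artery_ttp,
        vein_ttp=local.vein_ttp,
    )


def multi_threshold_idif(
    tacs,
    times,
    peak_values,
    peak_times,
    tails,
    stats,
    a1_set=(0.4, 0.5, 0.6),
    a2: float = 0.9,
    normalize: bool = True,
) -> tuple[InputFunction, InputFunction]:
    """Average the artery and vein cluster IDIFs across the a1 levels.

    For each a1 level: filter -> cluster -> label -> average; the three artery
    input functions are then averaged pointwise (likewise the veins).  Any
    level producing an empty artery or vein cluster raises an error naming the
    level.
    """
    times = np.asarray(times, dtype=float)
    artery_ifs, vein_ifs = [], []
    for a1 in a1_set:
        try:
            res = _single_level(tacs, times, peak_values, peak_times, tails,
                                stats, ThresholdConfig(a1=a1, a2=a2),
                                normalize=normalize)
        except ValueError as exc:
            raise ValueError(f"level a1={a1}: {exc}") from exc
        artery_ifs.append(average_cluster(tacs, res.artery_rows, times, "artery"))
        vein_ifs.append(average_cluster(tacs, res.vein_rows, times, "vein"))
    artery = InputFunction(times, np.mean([f.values for f in artery_ifs], axis=0),
                           "artery")
    vein = InputFunction(times, np.mean([f.values for f in vein_ifs], axis=0),
                         "vein")
    return artery, vein


def time_periods(peak_time: float, total: float) -> TimePeriods:
    """Partition [0, total] into T1..T7 around the identified peak."""
    if not peak_time + 20.0 < total:
        raise ValueError("peak_time + 20 s must precede the acquisition end")
    t1_end = peak_time + 20.0
    bounds = [0.0, t1_end]
    for _ in range(5):
        bounds.append(bounds[-1] + 600.0)
    if bounds[-1] >= total:
        raise ValueError("ten-minute windows T2..T6 exceed the acquisition span")
    bounds.append(float(total))
    return TimePeriods(np.asarray(bounds))


def _auc_on(curve: InputFunction, grid: np.ndarray, lo: float, hi: float) -> float:
    seg = grid[(grid >= lo) & (grid <= hi)]
    return float(np.trapezoid(curve.at(seg), seg))


def period_auc_errors(
    candidate: InputFunction,
    reference: InputFunction,
    periods: TimePeriods,
) -> np.ndarray:
    """Percentage AUC error of the candidate per period T1..T7.

    AUCs use the trapezoidal rule on a common 2 s grid with the period
    boundaries inserted as grid points.
    """
    b = periods.boundaries
    grid = np.union1d(np.arange(b[0], b[-1] + _GRID_STEP_S / 2.0, _GRID_STEP_S), b)
    errors = np.empty(7)
    for p in range(1, 8):
        lo, hi = periods.window(p)
        ref = _auc_on(reference, grid, lo, hi)
        if ref == 0.0:
            raise ValueError(f"reference AUC is zero on period T{p}")
        est = _auc_on(candidate, grid, lo, hi)
        errors[p - 1] = 100.0 * (est - ref) / ref
    return errors


def _detected_ttp(curve: InputFunction, step: float) -> float:
    info = cwt_peak_detect(curve.values, curve.times, grid_step_s=step)
    if not info.found:
        raise ValueError(f"no detectable peak on the {curve.label} curve")
    return info.peak_time


def align_peaks(
    artery_if: InputFunction,
    vein_if: InputFunction,
    step: float = _GRID_STEP_S,
) -> InputFunction:
    """Shift the venous curve so its peak coincides with the arterial peak.

    The venous time axis is shifted by -(vein_ttp - artery_ttp) on the 2 s
    grid; values are unchanged and any head of the shifted curve falling
    before t = 0 is discarded.
    """
    shift = _detected_ttp(vein_if, step) - _detected_ttp(artery_if, step)
    v = vein_if.resample(step)
    new_t = v.times - shift
    keep = new_t >= 0.0
    if keep.sum() < 2:
        raise ValueError("alignment shift leaves no venous samples at t >= 0")
    return InputFunction(new_t[keep], v.values[keep], vein_if.label)


def form_idif_auto(
    artery_if: InputFunction,
    vein_if: InputFunction,
    out_times=None,
    step: float = _GRID_STEP_S,
) -> InputFunction:
    """Hybrid automatic IDIF: arterial peak joined to the aligned venous tail.

    Both curves are interpolated to a uniform 2 s grid; the venous curve is
    shifted so the peaks align; arterial values are kept up to and including
    the peak and venous values after it; the two grid points (4 s) on each
    side of the junction are replaced by the mean of the two curves to smooth
    the seam; finally the curve is resampled to ``out_times`` (typically the
    frame midtimes) when given.
    """
    a = artery_if.resample(step)
    artery_ttp = _detected_ttp(artery_if, step)
    vein_ttp = _detected_ttp(vein_if, step)
    shift = vein_ttp - artery_ttp
    v_aligned = vein_if.resample(step)
    vein_on_grid = np.interp(a.times + shift, v_aligned.times, v_aligned.values)

    p = int(np.argmin(np.abs(a.times - artery_ttp)))
    values = np.concatenate([a.values[: p + 1], vein_on_grid[p + 1:]])
    for i in (p - 2, p - 1, p + 1, p + 2):
        if 0 <= i < values.size:
            values[i] = 0.5 * (a.values[i] + vein_on_grid[i])
    out = InputFunction(a.times, values, "auto")
    if out_times is not None:
        out_times = np.asarray(out_times, dtype=float)
        out = InputFunction(out_times, out.at(out_times), "auto")
    return out


def reference_da_idif(
    image: DynamicImage,
    center_mm,
    diameter_mm: float = 10.0,
    length_mm: float = 10.0,
    axis: int = 2,
) -> InputFunction:
    """Mean curve over a cylindrical blood-pool VOI (descending aorta).

    The default 10 mm diameter x 10 mm length cylinder sits well inside the
    aortic lumen, so the reference curve resists partial-volume effects at
    the image resolutions considered.  Voxel centres (index * voxel size)
    falling inside the cylinder are averaged per frame.
    """
    center = np.asarray(center_mm, dtype=float)
    vs = np.asarray(image.voxel_size)
    shape = np.asarray(image.shape)
    lo = center - diameter_mm / 2.0
    hi = center + diameter_mm / 2.0
    lo[axis] = center[axis] - length_mm / 2.0
    hi[axis] = center[axis] + length_mm / 2.0
    if np.any(lo < -vs / 2.0) or np.any(hi > (shape - 0.5) * vs):
        raise ValueError("cylinder extends outside the image grid")
    idx = np.indices(image.shape).reshape(3, -1).T * vs
    delta = idx - center
    axial_ok = np.abs(delta[:, axis]) <= length_mm / 2.0
    plane = np.delete(delta, axis, axis=1)
    radial_ok = np.einsum("ij,ij->i", plane, plane) <= (diameter_mm / 2.0) ** 2
    sel = (axial_ok & radial_ok).reshape(image.shape)
    if not sel.any():
        raise ValueError("cylinder contains no voxel centres")
    curve = image.values[sel].mean(axis=0)
    return InputFunction(image.schedule.midtimes, curve, "reference_da")


class IDIFExtractor(BaseEstimator):
    """End-to-end automatic IDIF extraction from a voxel TAC matrix.

    Runs shape identification (wavelet peak detection, tails, cohort
    statistics), peak/tail filtering and artery/vein clustering at each a1
    threshold level, multi-level cluster averaging and the arterial-peak /
    venous-tail combination.

    Parameters
    ----------
    a1_levels : tuple of float
        Peak-criterion threshold levels to average across.
    a2 : float
        Tail-criterion threshold level.
    top_n : int
        Cohort size for Mean_peak / Mean_tail.
    grid_step_s : float
        Uniform resampling step for wavelet detection and curve surgery.
    scales : (int, int)
        Inclusive integer CWT scale range.

    Attributes
    ----------
    idif_auto_ : InputFunction
        The hybrid automatic input function on the frame-midtime grid.
    idif_artery_, idif_vein_ : InputFunction
        Multi-level artery and vein cluster averages.
    levels_ : dict[float, ClusterResult]
        Per-level filtered/clustered row sets (indices into the TAC matrix).
    artery_rows_, vein_rows_ : ndarray
        Union of per-level artery (vein) rows.
    count_artery_, count_vein_ : float
        Mean per-level voxel counts (the quantity tracked across resolutions).
    stats_ : CohortStats
        Cohort Mean_peak / Mean_tail.
    """

    def __init__(
        self,
        a1_levels=(0.4, 0.5, 0.6),
        a2: float = 0.9,
        top_n: int = 10,
        grid_step_s: float = _GRID_STEP_S,
        scales: tuple[int, int] = (1, 100),
        cluster_normalize: bool = True,
    ):
        self.a1_levels = a1_levels
        self.a2 = a2
        self.top_n = top_n
        self.grid_step_s = grid_step_s
        self.scales = scales
        self.cluster_normalize = cluster_normalize

    def fit(self, X, y=None, *, schedule: FrameSchedule):
        """Extract the automatic IDIF from a TAC matrix.

        ``X`` is a :class:`~autoaif.frames.TACMatrix` or a plain (voxels x
        frames) array whose columns follow ``schedule``.
        """
        tacs = X if isinstance(X, TACMatrix) else TACMatrix(
            np.atleast_2d(np.asarray(X, dtype=float)),
            np.zeros((np.atleast_2d(np.asarray(X)).shape[0], 3), dtype=np.intp),
        )
        times = schedule.midtimes
        pv, pt, found = cwt_peak_detect_matrix(
            tacs, times, scales=self.scales, grid_step_s=self.grid_step_s
        )
        tails = tail_values(tacs, schedule)
        self.peak_values_, self.peak_times_, self.found_ = pv, pt, found
        self.tails_ = tails
        self.stats_ = cohort_peak_tail_stats(pv, tails, top_n=self.top_n)

        self.levels_ = {}
        for a1 in self.a1_levels:
            self.levels_[a1] = _single_level(
                tacs, times, pv, pt, tails, self.stats_,
                ThresholdConfig(a1=a1, a2=self.a2),
                normalize=self.cluster_normalize,
            )
        self.idif_artery_, self.idif_vein_ = multi_threshold_idif(
            tacs, times, pv, pt, tails, self.stats_,
            a1_set=self.a1_levels, a2=self.a2,
            normalize=self.cluster_normalize,
        )
        self.idif_auto_ = form_idif_auto(
            self.idif_artery_, self.idif_vein_, out_times=times,
            step=self.grid_step_s,
        )
        self.artery_rows_ = np.unique(
            np.concatenate([r.artery_rows for r in self.levels_.values()])
        )
        self.vein_rows_ = np.unique(
            np.concatenate([r.vein_rows for r in self.levels_.values()])
        )
        self.count_artery_ = float(np.mean(
            [r.artery_rows.size for r in self.levels_.values()]
        ))
        self.count_vein_ = float(np.mean(
            [r.vein_rows.size for r in self.levels_.values()]
        ))
        self.schedule_ = schedule
        self.n_features_in_ = tacs.n_frames
        return self
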