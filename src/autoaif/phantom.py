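"""Synthetic dynamic-FDG head phantom with ground truth.

The phantom emulates the structure the extraction framework assumes in a
total-body acquisition of the head: a Feng-type tri-exponential arterial
bolus, venous curves that are a delayed and dispersed copy of it, grey- and
white-matter tissue curves generated by the irreversible two-tissue
compartment model with published FDG rate constants, carotid-like arteries
and a venous-sinus tube at the skull base, a large descending-aorta
blood-pool cylinder in an inferior body slab (outside the 20 cm head
coverage), Gaussian point-spread blurring and frame-duration-dependent
Gaussian noise.

The anatomy mirrors the conditions under which voxel-wise peak/tail
filtering works on real heads: cortex occupies a superior cap and never
directly abuts the large vessels; the vessels run through low-uptake
skull-base tissue whose late activity matches the whole-blood tail; the
venous sinus is wrapped in a well-perfused dural ring whose mid-study
activity tracks blood; and extracerebral scalp/soft tissue wraps the whole
head, so no blood-dominated voxel sits next to empty background.  Activity
amplitudes are in kBq/mL with a clinically realistic whole-blood tail of
~1.3 kBq/mL — the level the fixed brain-masking threshold of one presumes.

The venous transit is a 2 s bulk delay plus a 4 s exponential dispersion;
the resulting arterial-to-venous time-to-peak difference of about 6-7 s
matches the values reported from total-body measurements.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .frames import (
    PAPER_FRAME_SPEC,
    DynamicImage,
    FrameSchedule,
    VoxelMask,
    build_frame_schedule,
)
from .idif import InputFunction
from .kinetics import KineticParams, model_2tcm_irr

__all__ = [
    "BolusParams",
    "PhantomSpec",
    "PhantomTruth",
    "bolus_aif",
    "disperse_delay",
    "frame_average",
    "build_phantom",
    "blur_psf",
]

_FINE_STEP_S = 0.5


@dataclass(frozen=True)
class BolusParams:
    """Feng-type tri-exponential bolus coefficients.

    C(t) = (A1 (t - t0) - A2 - A3) e^{l1 (t - t0)} + A2 e^{l2 (t - t0)}
           + A3 e^{l3 (t - t0)} for t >= t0, 0 before; amplitudes in kBq/mL
    (A1 per minute), rates l1..l3 in 1/min (all negative), arrival t0 in s.

    Defaults give a single bolus peak of ~26 kBq/mL at ~42 s post injection
    and a peak-to-60-min-tail ratio of ~20:1 (whole-blood tail ~1.3 kBq/mL,
    the typical clinical level; the brain-masking threshold of one image unit
    presumes this kBq/mL calibration).
    """

    A1: float = 235.0
    A2: float = 2.35
    A3: float = 4.7
    l1: float = -4.0
    l2: float = -0.01
    l3: float = -0.12
    t0: float = 25.0

    def __post_init__(self) -> None:
        if self.A1 <= 0:
            raise ValueError("A1 must be positive")
        if not (self.l1 < 0 and self.l2 < 0 and self.l3 < 0):
            raise ValueError("decay rates l1..l3 must be negative")
        t = np.arange(0.0, 3900.0 + 0.25, 0.25)
        if np.min(_feng(t, self)) < -1e-9:
            raise ValueError("bolus parameters produce negative activity")


def _feng(t: np.ndarray, p: BolusParams) -> np.ndarray:
    x = (np.asarray(t, dtype=float) - p.t0) / 60.0
    xp = np.maximum(x, 0.0)
    c = (
        (p.A1 * xp - p.A2 - p.A3) * np.exp(p.l1 * xp)
        + p.A2 * np.exp(p.l2 * xp)
        + p.A3 * np.exp(p.l3 * xp)
    )
    # strictly positive support: the value at t0 itself is identically zero
    return np.where(x > 0.0, c, 0.0)


def bolus_aif(t, aif_params: BolusParams | None = None) -> np.ndarray:
    """Arterial bolus activity (kBq/mL) at times ``t`` (seconds)."""
    return _feng(np.asarray(t, dtype=float), aif_params or BolusParams())


def disperse_delay(curve: InputFunction, delay: float, tau: float) -> InputFunction:
    """Delay a curve, then disperse it with a unit-area exponential kernel.

    ``tau = 0`` reduces to a pure shift.  The curve must be uniformly
    sampled; values before its start are treated as zero.
    """
    if delay < 0 or tau < 0:
        raise ValueError("delay and tau must be non-negative")
    t = curve.times
    dt = np.diff(t)
    if not np.allclose(dt, dt[0]):
        raise ValueError("dispersion requires a uniformly sampled curve")
    dt = float(dt[0])
    shifted = np.interp(t - delay, t, curve.values, left=0.0)
    if tau == 0.0:
        return replace(curve, values=shifted)
    k = np.exp(-np.arange(0.0, 8.0 * tau + dt, dt) / tau)
    k /= k.sum()
    dispersed = np.convolve(shifted, k)[: t.size]
    return replace(curve, values=dispersed)


def frame_average(times: np.ndarray, values: np.ndarray,
                  schedule: FrameSchedule) -> np.ndarray:
    """Mean of a finely sampled curve within each frame of a schedule."""
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    lo = np.searchsorted(times, schedule.start - 1e-9, side="left")
    hi = np.searchsorted(times, schedule.end + 1e-9, side="right")
    return np.array([values[a:max(b, a + 1)].mean() for a, b in zip(lo, hi)])


@dataclass(frozen=True)
class PhantomSpec:
    """All tunable knobs of the head phantom (lengths mm, times s).

    Geometry defaults: a 44 x 44 x 150 grid at 1.65 mm isotropic voxels; a
    head ellipsoid (semi-axes 16.5 x 16.5 x 24.75 mm) near the top of the
    FOV wrapped in a 7 mm scalp shell; a superior cortical cap (grey matter
    with an inner white-matter ellipsoid) above a skull-base zone of
    low-uptake tissue; two carotid-like arteries (radius 3.2 mm, the
    published common-carotid calibre) and one venous-sinus tube (radius
    4.4 mm) inside a perfused dural ring, all within the basal zone; and a
    descending-aorta cylinder (radius 13 mm) in a body slab that the 20 cm
    axial head crop excludes.
    """

    aif_params: BolusParams = field(default_factory=BolusParams)
    vein_delay: float = 2.0
    vein_dispersion_tau: float = 4.0
    artery_radius_mm: float = 3.2
    vein_radius_mm: float = 4.4
    da_radius_mm: float = 13.0
    gm_params: KineticParams = field(
        default_factory=lambda: KineticParams(0.173, 0.137, 0.053)
    )
    wm_params: KineticParams = field(
        default_factory=lambda: KineticParams(0.061, 0.094, 0.025)
    )
    vb_gm: float = 0.05
    vb_wm: float = 0.03
    #: skull-base ("basal") tissue kinetics: slow, largely irreversible uptake
    #: calibrated so its 55-65 min tail matches the whole-blood tail
    peri_params: KineticParams = field(
        default_factory=lambda: KineticParams(0.010, 0.020, 0.084)
    )
    vb_basal: float = 0.02
    #: dural ring around the venous sinus: highly perfused, fast-exchanging
    #: tissue whose mid-study activity tracks blood while its late tail
    #: exceeds the blood tail by ~20%
    ring_params: KineticParams = field(
        default_factory=lambda: KineticParams(0.30, 0.30, 0.0016)
    )
    vb_ring: float = 0.1
    ring_radius_mm: float = 6.4
    #: extracerebral soft tissue (scalp/skull base) wrapping the whole head;
    #: shares the basal kinetics, so its time-mean sits just below the
    #: brain-masking threshold while its tail matches whole blood
    scalp_thickness_mm: float = 7.0
    psf_fwhm_mm: float = 3.83
    noise_scale: float = 0.5
    seed: int = 0
    grid_shape: tuple[int, int, int] = (44, 44, 150)
    voxel_size_mm: float = 1.65
    head_semiaxes_mm: tuple[float, float, float] = (16.5, 16.5, 24.75)
    gm_split_dz_mm: float = 4.0
    wm_semiaxes_mm: tuple[float, float, float] = (8.0, 8.0, 8.5)
    wm_center_dz_mm: float = 12.0
    artery_offsets_mm: tuple[tuple[float, float], ...] = ((5.5, -3.3), (-5.5, -3.3))
    artery_center_dz_mm: float = -9.0
    artery_halflength_mm: float = 3.5
    vein_offset_mm: tuple[float, float] = (0.0, 4.0)
    vein_center_dz_mm: float = -8.0
    vein_halflength_mm: float = 7.0
    da_length_mm: float = 15.0
    head_top_margin_vox: int = 15

    def __post_init__(self) -> None:
        if min(self.artery_radius_mm, self.vein_radius_mm, self.da_radius_mm) <= 0:
            raise ValueError("vessel radii must be positive")
        if self.vein_delay < 0 or self.vein_dispersion_tau < 0:
            raise ValueError("vein delay and dispersion tau must be non-negative")
        for frac in (self.vb_gm, self.vb_wm, self.vb_basal, self.vb_ring):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("blood-volume fractions must lie in [0, 1]")
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be non-negative")


@dataclass(frozen=True)
class PhantomTruth:
    """Ground truth emitted alongside a simulated image."""

    true_aif: InputFunction
    true_aif_fine: InputFunction
    true_venous: InputFunction
    true_venous_fine: InputFunction
    artery_mask: VoxelMask
    vein_mask: VoxelMask
    da_mask: VoxelMask
    gm_mask: VoxelMask
    wm_mask: VoxelMask
    perivascular_mask: VoxelMask
    da_center_mm: tuple[float, float, float]
    spec: PhantomSpec


def _geometry(spec: PhantomSpec):
    """Boolean region masks of the head phantom.

    The head ellipsoid splits into a superior cortical cap (grey matter with
    an inner white-matter ellipsoid) and an inferior skull-base ("basal")
    zone of low-uptake tissue.  Two carotid-like arteries and a
    jugular/sinus-like vein run vertically through the basal zone, the vein
    inside a perfused dural ring with bloodless caps.  Keeping the vessels
    deep in the basal
    zone reproduces the real anatomy in which hot cortex never directly
    abuts the large vessels the framework relies on.
    """
    nx, ny, nz = spec.grid_shape
    vs = spec.voxel_size_mm
    X, Y, Z = np.meshgrid(
        np.arange(nx) * vs, np.arange(ny) * vs, np.arange(nz) * vs, indexing="ij"
    )
    cx, cy = (nx - 1) / 2.0 * vs, (ny - 1) / 2.0 * vs
    semi = np.asarray(spec.head_semiaxes_mm)
    cz = (nz - 1 - spec.head_top_margin_vox) * vs - semi[2]
    if cz - semi[2] < 0 or cz + semi[2] > (nz - 1) * vs:
        raise ValueError("head ellipsoid exceeds the grid")
    if semi[0] + max(abs(o[0]) for o in spec.artery_offsets_mm) > (nx - 1) / 2.0 * vs:
        raise ValueError("head geometry exceeds the grid in-plane")

    head = (
        ((X - cx) / semi[0]) ** 2
        + ((Y - cy) / semi[1]) ** 2
        + ((Z - cz) / semi[2]) ** 2
    ) <= 1.0
    outer = semi + spec.scalp_thickness_mm
    scalp = (
        (
            ((X - cx) / outer[0]) ** 2
            + ((Y - cy) / outer[1]) ** 2
            + ((Z - cz) / outer[2]) ** 2
        ) <= 1.0
    ) & ~head
    if cz + outer[2] > (nz - 1) * vs:
        raise ValueError("scalp shell exceeds the grid")
    wax = np.asarray(spec.wm_semiaxes_mm)
    wm = (
        ((X - cx) / wax[0]) ** 2
        + ((Y - cy) / wax[1]) ** 2
        + ((Z - cz - spec.wm_center_dz_mm) / wax[2]) ** 2
    ) <= 1.0
    cortical = Z > cz + spec.gm_split_dz_mm

    def ztube(offset, radius, z0, halflength):
        r2 = (X - (cx + offset[0])) ** 2 + (Y - (cy + offset[1])) ** 2
        return (r2 <= radius**2) & (np.abs(Z - (cz + z0)) <= halflength)

    artery = np.zeros_like(head)
    for off in spec.artery_offsets_mm:
        artery |= ztube(off, spec.artery_radius_mm, spec.artery_center_dz_mm,
                        spec.artery_halflength_mm)

    vein = ztube(spec.vein_offset_mm, spec.vein_radius_mm,
                 spec.vein_center_dz_mm, spec.vein_halflength_mm)
    # dura wraps the sinus radially; bloodless dural caps close its ends
    ring = ztube(spec.vein_offset_mm, spec.ring_radius_mm,
                 spec.vein_center_dz_mm, spec.vein_halflength_mm)
    cap = ztube(spec.vein_offset_mm, spec.vein_radius_mm + 1.0,
                spec.vein_center_dz_mm, spec.vein_halflength_mm + 2.0) & ~ztube(
        spec.vein_offset_mm, spec.vein_radius_mm + 1.0,
        spec.vein_center_dz_mm, spec.vein_halflength_mm)

    da_center = (cx, cy, vs + spec.da_length_mm / 2.0)
    r2 = (X - cx) ** 2 + (Y - cy) ** 2
    da = (r2 <= spec.da_radius_mm**2) & (Z >= vs) & (Z <= vs + spec.da_length_mm)
    if spec.da_radius_mm > min(cx, cy):
        raise ValueError("descending-aorta cylinder exceeds the grid")

    # overlap priority: vessels > dural cap/ring > white matter > grey/basal
    vein &= head & ~artery
    cap &= head & ~artery & ~vein
    ring &= head & ~artery & ~vein & ~cap
    wm &= head & cortical & ~artery & ~vein & ~cap & ~ring
    gm = head & cortical & ~artery & ~vein & ~cap & ~ring & ~wm
    basal = (head & ~cortical & ~artery & ~vein & ~cap & ~ring) | scalp
    return {
        "artery": artery & head,
        "vein": vein,
        "cap": cap,
        "ring": ring,
        "wm": wm,
        "gm": gm,
        "basal": basal,
        "da": da,
    }, da_center


def build_phantom(
    spec: PhantomSpec | None = None,
    schedule: FrameSchedule | None = None,
) -> tuple[DynamicImage, PhantomTruth]:
    """Simulate a dynamic head image and return it with its ground truth.

    Region curves are time-averages of the continuous curves over each frame
    (matching how scanners report frames); the image is then blurred with the
    isotropic Gaussian PSF and corrupted with zero-mean Gaussian noise whose
    variance is proportional to activity / frame duration (a standard
    surrogate for reconstructed-PET noise).  Fully reproducible for a fixed
    seed.
    """
    spec = spec or PhantomSpec()
    schedule = schedule or build_frame_schedule(PAPER_FRAME_SPEC)
    t_fine = np.arange(0.0, schedule.total_span + _FINE_STEP_S / 2.0, _FINE_STEP_S)
    aif_fine = bolus_aif(t_fine, spec.aif_params)
    aif_if = InputFunction(t_fine, aif_fine, "truth")
    venous_if = disperse_delay(aif_if, spec.vein_delay, spec.vein_dispersion_tau)

    def favg(values):
        return frame_average(t_fine, values, schedule)

    def tissue(params: KineticParams, vb: float, blood: InputFunction):
        p = KineticParams(params.K1, params.k2, params.k3, vb)
        return model_2tcm_irr(None, p, aif_if, blood_fn=blood,
                              schedule=schedule, step_s=_FINE_STEP_S)

    curves = {
        "artery": favg(aif_fine),
        "da": favg(aif_fine),
        "vein": favg(venous_if.values),
        "gm": tissue(spec.gm_params, spec.vb_gm, aif_if),
        "wm": tissue(spec.wm_params, spec.vb_wm, aif_if),
        "basal": tissue(spec.peri_params, spec.vb_basal, venous_if),
        "ring": tissue(spec.ring_params, spec.vb_ring, venous_if),
        "cap": tissue(spec.ring_params, 0.0, venous_if),
    }

    masks, da_center = _geometry(spec)
    values = np.zeros(tuple(spec.grid_shape) + (schedule.n_frames,), dtype=np.float32)
    for name, mask in masks.items():
        values[mask] = curves[name].astype(np.float32)

    vs = spec.voxel_size_mm
    if spec.psf_fwhm_mm > 0:
        sigma = spec.psf_fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / vs
        values = ndimage.gaussian_filter(values, sigma=(sigma, sigma, sigma, 0.0))

    if spec.noise_scale > 0:
        rng = np.random.default_rng(spec.seed)
        sigma = spec.noise_scale * np.sqrt(
            np.clip(values, 0.0, None) / schedule.duration.astype(np.float32)
        )
        values = values + rng.standard_normal(values.shape, dtype=np.float32) * sigma

    image = DynamicImage(values=values, voxel_size=(vs, vs, vs), schedule=schedule,
                         fwhm=spec.psf_fwhm_mm)
    mid = schedule.midtimes
    truth = PhantomTruth(
        true_aif=InputFunction(mid, curves["artery"], "truth"),
        true_aif_fine=aif_if,
        true_venous=InputFunction(mid, curves["vein"], "truth"),
        true_venous_fine=venous_if,
        artery_mask=VoxelMask.from_bool(masks["artery"]),
        vein_mask=VoxelMask.from_bool(masks["vein"]),
        da_mask=VoxelMask.from_bool(masks["da"]),
        gm_mask=VoxelMask.from_bool(masks["gm"]),
        wm_mask=VoxelMask.from_bool(masks["wm"]),
        perivascular_mask=VoxelMask.from_bool(
            masks["basal"] | masks["ring"] | masks["cap"]
        ),
        da_center_mm=tuple(float(c) for c in da_center),
        spec=spec,
    )
    return image, truth


def blur_psf(image: DynamicImage, extra_fwhm_mm: float) -> DynamicImage:
    """Apply additional isotropic Gaussian blurring to every frame.

    The image's effective resolution metadata is updated in quadrature
    (independent Gaussian blurs combine as the Euclidean norm of their
    FWHMs).  ``extra_fwhm_mm = 0`` returns an identical copy.
    """
    if extra_fwhm_mm < 0:
        raise ValueError("extra FWHM must be non-negative")
    if extra_fwhm_mm == 0:
        return DynamicImage(image.values.copy(), image.voxel_size, image.schedule,
                            fwhm=image.fwhm)
    sigmas = tuple(
        extra_fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / v
        for v in image.voxel_size
    )
    blurred = ndimage.gaussian_filter(image.values, sigma=sigmas + (0.0,))
    return DynamicImage(blurred, image.voxel_size, image.schedule,
                        fwhm=float(np.hypot(image.fwhm, extra_fwhm_mm)))
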