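"""Synthetic phantoms, surface-dose maps and gated-camera acquisitions.

Stand-ins for the three physical ingredients of the phantom study: the six
silicone skin-tone phantoms (I..VI spanning melanin index 37-120), the
treatment planning system's estimated surface dose for three whole-breast
plan archetypes (static tangents, field-in-field, VMAT), and the pulse-gated
Cherenkov camera whose per-pulse frames are summed into a cumulative image.

Dose-map geometry
-----------------
All three plans share one "breast" footprint: the union of two obliquely
oriented rectangular fields clipped to an ellipse.  Dose is a function of the
signed pixel distance ``d`` to the footprint boundary, anchored so that the
30% isodose contour coincides with the footprint boundary for every plan --
hence the >=30% footprint is identical across plans by construction.  The
plans differ in hotspot cap (tangent 110%, field-in-field 105%, VMAT 100%),
penumbra width (VMAT slightly tighter) and VMAT's 2% out-of-field bath (an
integral-dose proxy for arc delivery).

Units
-----
Dose maps are expressed directly in expected accumulated camera counts at
the reference skin tone, so Poisson shot noise is meaningful without a
separate gain parameter.  The default prescription peak is 500 accumulated
counts (photon-starved, as for a pulse-gated Cherenkov camera).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import ndimage
from scipy.special import ndtr, ndtri

from .optics import (
    EmissionModel,
    SkinToneProfile,
    cie_lightness,
    melanin_transmission_factor,
    reflectance_from_melanin_index,
)

__all__ = [
    "PLAN_TYPES",
    "CherenkovImage",
    "DeliverySpec",
    "DoseMap",
    "DoseMapParams",
    "accumulate_frames",
    "apply_rigid_transform",
    "breast_footprint",
    "default_delivery",
    "expected_accumulated_background",
    "expected_frame_means",
    "generate_dose_map",
    "make_phantom_presets",
    "noiseless",
    "perturb_setup",
    "simulate_family_images",
    "simulate_frames",
]

PLAN_TYPES = ("tangent", "field_in_field", "vmat")

# Per-plan shape parameters: hotspot cap (fraction of prescription),
# penumbra sigma in pixels, and uniform out-of-field bath fraction.
_PLAN_SHAPE = {
    "tangent": {"cap": 1.10, "penumbra_sigma_px": 2.0, "bath_fraction": 0.0},
    "field_in_field": {"cap": 1.05, "penumbra_sigma_px": 2.0, "bath_fraction": 0.0},
    "vmat": {"cap": 1.00, "penumbra_sigma_px": 1.5, "bath_fraction": 0.02},
}

# Delivery defaults: VMAT needs more monitor units for the same prescription,
# hence more accumulated frames and more leakage per frame.
_PLAN_DELIVERY = {
    "tangent": {"n_frames": 60, "mu_factor": 1.0},
    "field_in_field": {"n_frames": 80, "mu_factor": 1.0},
    "vmat": {"n_frames": 240, "mu_factor": 2.0},
}

#: Accumulated in-field prescription signal, in expected camera counts, for
#: the reference (lightest) skin tone.
DEFAULT_PRESCRIPTION_COUNTS = 500.0

_PRESET_MI = tuple(37.0 + 83.0 * i / 5.0 for i in range(6))
_PRESET_PIGMENT = (0.0, 0.005, 0.010, 0.020, 0.050, 0.075)


def make_phantom_presets(b_star: float = 17.0) -> list[SkinToneProfile]:
    """The six skin-tone phantom presets, Fitzpatrick types I..VI.

    MI runs from 37 (type I) to 120 (type VI), the study's measured
    endpoints, with the interior types evenly interpolated (the interior
    values are a modelling choice, not measurements).  Reflectance follows
    from the MI formula and L* from the CIE lightness of that reflectance.
    The type VI pigment fraction is the summed dark-tone + black pigment
    loading of the physical recipe; pigment fractions are metadata only.
    """
    presets = []
    for name, mi, pigment in zip(
        SkinToneProfile._TYPES, _PRESET_MI, _PRESET_PIGMENT
    ):
        rr = reflectance_from_melanin_index(mi)
        presets.append(
            SkinToneProfile(
                fitzpatrick_type=name,
                rr_680=rr,
                melanin_index=mi,
                l_star=cie_lightness(rr),
                b_star=b_star,
                pigment_mass_fraction=pigment,
            )
        )
    return presets


@dataclass(frozen=True)
class DoseMapParams:
    """Geometry of the synthetic breast footprint (fractions of min(shape))."""

    prescription: float = DEFAULT_PRESCRIPTION_COUNTS
    ellipse_axes_frac: tuple[float, float] = (0.36, 0.28)
    band_halfwidth_frac: float = 0.12
    band_angle_deg: float = 25.0
    hotspot_sigma_frac: float = 0.08


@dataclass
class DoseMap:
    """Planned 2-D surface-dose grid for one plan type."""

    values: np.ndarray
    spacing_mm: float
    plan_type: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("dose map must be a 2-D grid")
        if self.spacing_mm <= 0.0:
            raise ValueError("grid spacing must be > 0")
        if np.any(self.values < 0.0) or not np.any(self.values > 0.0):
            raise ValueError("dose values must be >= 0 with at least one > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def footprint(self, fraction: float = 0.30) -> np.ndarray:
        """Boolean mask of the >=fraction isodose region (of the raw max)."""
        return self.values >= fraction * self.values.max()


def breast_footprint(shape: tuple[int, int], params: DoseMapParams) -> np.ndarray:
    """Treated-area mask: union of two oblique bands clipped to an ellipse.

    The bands pass through the grid centre at +/- ``band_angle_deg`` from
    the vertical, emulating opposed tangential fields crossing the breast;
    the construction is mirror-symmetric about the vertical centre axis.
    """
    ny, nx = shape
    scale = float(min(shape))
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    y = np.arange(ny)[:, None] - cy
    x = np.arange(nx)[None, :] - cx

    ay = params.ellipse_axes_frac[0] * scale
    ax = params.ellipse_axes_frac[1] * scale
    ellipse = (y / ay) ** 2 + (x / ax) ** 2 <= 1.0

    theta = math.radians(params.band_angle_deg)
    w = params.band_halfwidth_frac * scale
    # perpendicular distance to the band axis tilted by +/- theta
    u_plus = np.abs(math.cos(theta) * x - math.sin(theta) * y)
    u_minus = np.abs(math.cos(theta) * x + math.sin(theta) * y)
    bands = (u_plus <= w) | (u_minus <= w)
    return ellipse & bands


def generate_dose_map(
    plan_type: str,
    shape: tuple[int, int] = (256, 256),
    spacing_mm: float = 2.0,
    params: DoseMapParams | None = None,
) -> DoseMap:
    """Synthetic planned surface-dose map for one plan archetype.

    Dose is ``prescription * profile(d)`` where ``d`` is the signed pixel
    distance to the shared footprint boundary and the penumbra profile is a
    Gaussian CDF anchored so the dose at ``d = 0`` equals 30% of the map
    maximum for every plan.  Tangent and field-in-field add an interior
    Gaussian hotspot clipped at 110% / 105% of prescription; VMAT adds a
    uniform 2% out-of-field bath instead.
    """
    if plan_type not in PLAN_TYPES:
        raise ValueError(f"unknown plan type {plan_type!r}; expected one of {PLAN_TYPES}")
    if min(shape) < 64:
        raise ValueError("dose-map shape must be at least 64x64")
    if params is None:
        params = DoseMapParams()

    shape_spec = _PLAN_SHAPE[plan_type]
    cap = shape_spec["cap"]
    sigma = shape_spec["penumbra_sigma_px"]
    bath = shape_spec["bath_fraction"]

    fp = breast_footprint(shape, params)
    # signed distance to the footprint boundary, in pixels (>0 inside)
    d = ndimage.distance_transform_edt(fp) - ndimage.distance_transform_edt(~fp)

    # anchor: dose at the boundary equals 30% of the plan maximum (cap)
    p0 = (0.30 * cap - bath) / (1.0 - bath)
    z0 = ndtri(p0)
    profile = ndtr(d / sigma + z0)
    dose = bath + (1.0 - bath) * profile

    if cap > 1.0:
        cy, cx = ndimage.center_of_mass(fp)
        ny, nx = shape
        hs = params.hotspot_sigma_frac * min(shape)
        r2 = (np.arange(ny)[:, None] - cy) ** 2 + (np.arange(nx)[None, :] - cx) ** 2
        bump = np.exp(-r2 / (2.0 * hs * hs))
        # overdrive the bump by 1.5x so the clip produces a flat plateau at
        # the cap (a stable hotspot maximum, robust to percentile references)
        dose = np.minimum(dose * (1.0 + 1.5 * (cap - 1.0) * bump), cap)

    return DoseMap(values=params.prescription * dose, spacing_mm=spacing_mm, plan_type=plan_type)


@dataclass(frozen=True)
class DeliverySpec:
    """Acquisition model for one delivery technique.

    ``n_frames`` gated frames accumulate the full planned dose (each frame
    carries ``dose / n_frames``); each frame also carries a spatially uniform
    background ``ambient + leakage * mu_factor`` plus Poisson shot noise and
    Gaussian read noise.  ``mu_factor`` scales the leakage term with the
    monitor units needed by the technique (VMAT > 1).  ``shot_noise=False``
    replaces Poisson sampling by the exact expectation (used for noiseless
    calibration checks).
    """

    plan_type: str
    n_frames: int
    mu_factor: float
    ambient_per_frame: float
    leakage_per_frame: float
    read_noise_sigma: float
    shot_noise: bool = True
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.mu_factor < 1.0:
            raise ValueError("mu_factor must be >= 1")
        for name in ("ambient_per_frame", "leakage_per_frame", "read_noise_sigma"):
            if getattr(self, name) < 0.0:
                raise ValueError(f"{name} must be >= 0")


def default_delivery(
    plan_type: str,
    prescription: float = DEFAULT_PRESCRIPTION_COUNTS,
    ambient_fraction: float = 0.01,
    leakage_fraction: float = 0.01,
    read_noise_fraction: float = 0.005,
    seed: int | None = None,
) -> DeliverySpec:
    """Default delivery spec for a plan type.

    Background and read-noise levels are fractions (default 1%, 1%, 0.5%)
    of the *tangent* per-frame in-field peak, so they are a fixed absolute
    camera floor shared by all techniques.
    """
    if plan_type not in PLAN_TYPES:
        raise ValueError(f"unknown plan type {plan_type!r}")
    per_frame_peak = (
        _PLAN_SHAPE["tangent"]["cap"] * prescription / _PLAN_DELIVERY["tangent"]["n_frames"]
    )
    d = _PLAN_DELIVERY[plan_type]
    return DeliverySpec(
        plan_type=plan_type,
        n_frames=d["n_frames"],
        mu_factor=d["mu_factor"],
        ambient_per_frame=ambient_fraction * per_frame_peak,
        leakage_per_frame=leakage_fraction * per_frame_peak,
        read_noise_sigma=read_noise_fraction * per_frame_peak,
        seed=seed,
    )


def noiseless(delivery: DeliverySpec, keep_background: bool = False) -> DeliverySpec:
    """Copy of ``delivery`` with all stochastic terms (and optionally the
    background) removed; used for calibration identities."""
    kwargs = {"shot_noise": False, "read_noise_sigma": 0.0}
    if not keep_background:
        kwargs.update(ambient_per_frame=0.0, leakage_per_frame=0.0)
    return replace(delivery, **kwargs)


@dataclass
class FrameStack:
    """Per-frame simulated camera signal on the dose-map grid."""

    frames: np.ndarray  # (n_frames, ny, nx)
    delivery: DeliverySpec
    seed: int | None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n_frames, ny, nx) array")
        if self.frames.shape[0] != self.delivery.n_frames:
            raise ValueError("number of frames inconsistent with the delivery spec")


@dataclass
class CherenkovImage:
    """Cumulative Cherenkov image (sum of gated frames)."""

    values: np.ndarray
    n_frames_summed: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("image must be a 2-D grid")


def expected_frame_means(
    dose: DoseMap,
    profile: SkinToneProfile,
    model: EmissionModel,
    delivery: DeliverySpec,
) -> np.ndarray:
    """Expected counts per frame: melanin-attenuated signal plus background."""
    t = melanin_transmission_factor(profile.melanin_index, model)
    signal = dose.values * (t / delivery.n_frames)
    background = delivery.ambient_per_frame + delivery.leakage_per_frame * delivery.mu_factor
    return signal + background


def expected_accumulated_background(delivery: DeliverySpec) -> float:
    """Expected accumulated out-of-field background level (counts)."""
    return delivery.n_frames * (
        delivery.ambient_per_frame + delivery.leakage_per_frame * delivery.mu_factor
    )


def simulate_frames(
    dose: DoseMap,
    profile: SkinToneProfile,
    model: EmissionModel,
    delivery: DeliverySpec,
    seed: int | None = None,
) -> FrameStack:
    """Simulate the gated frame stack for one acquisition.

    Each frame is ``Poisson(signal + background) + Normal(0, read_noise)``
    clipped at zero, with the Poisson draw first and the Gaussian second in
    a single seeded generator, so identical seeds give bitwise-identical
    stacks.  With ``shot_noise=False`` the Poisson draw is replaced by its
    expectation (read noise, if any, still applies).
    """
    if seed is None:
        seed = delivery.seed
    mean = expected_frame_means(dose, profile, model, delivery)
    shape = (delivery.n_frames,) + mean.shape
    rng = np.random.default_rng(seed)
    if delivery.shot_noise:
        frames = rng.poisson(np.broadcast_to(mean, shape)).astype(float)
    else:
        frames = np.broadcast_to(mean, shape).copy()
    if delivery.read_noise_sigma > 0.0:
        frames += rng.normal(0.0, delivery.read_noise_sigma, size=shape)
    np.clip(frames, 0.0, None, out=frames)
    return FrameStack(frames=frames, delivery=delivery, seed=seed)


def simulate_family_images(
    dose: DoseMap,
    profiles: Sequence[SkinToneProfile],
    model: EmissionModel,
    delivery: DeliverySpec,
    seed: int | None = None,
) -> dict[str, CherenkovImage]:
    """Coupled acquisitions of the same delivery for several skin tones.

    Marginally each phantom's cumulative image follows exactly the model of
    :func:`simulate_frames` (per-frame ``Poisson(signal + background)`` plus
    shared-variance Gaussian read noise, clipped at zero).  Jointly, the
    phantoms are coupled by a chained Poisson construction: per frame, the
    darkest tone's counts are drawn first and each lighter tone adds an
    independent ``Poisson(delta signal)`` increment, while the Gaussian read
    noise field is shared.  This is a common-random-numbers design: the
    shot-noise realisation is as identical as the physics allows across
    tones, so across-tone comparisons (the Fig-9-style ordering of Dice
    scores with melanin) are paired rather than swamped by independent
    noise.  Draw order per frame is fixed (darkest tone, then increments
    light-ward, then the shared read-noise field) for reproducibility.

    Returns accumulated cumulative images keyed by Fitzpatrick type.
    """
    if seed is None:
        seed = delivery.seed
    if len(profiles) == 0:
        raise ValueError("need at least one skin-tone profile")
    # darkest (lowest transmission) first; increments are then non-negative
    ordered = sorted(
        profiles,
        key=lambda p: melanin_transmission_factor(p.melanin_index, model),
    )
    trans = [melanin_transmission_factor(p.melanin_index, model) for p in ordered]
    signal_unit = dose.values / delivery.n_frames  # per-frame dose, reference tone
    background = delivery.ambient_per_frame + delivery.leakage_per_frame * delivery.mu_factor

    rng = np.random.default_rng(seed)
    acc = {p.fitzpatrick_type: np.zeros(dose.shape) for p in ordered}
    for _ in range(delivery.n_frames):
        if delivery.shot_noise:
            counts = rng.poisson(trans[0] * signal_unit + background).astype(float)
        else:
            counts = trans[0] * signal_unit + background
        frames = [counts]
        for t_prev, t_next in zip(trans, trans[1:]):
            if delivery.shot_noise:
                increment = rng.poisson((t_next - t_prev) * signal_unit)
            else:
                increment = (t_next - t_prev) * signal_unit
            frames.append(frames[-1] + increment)
        if delivery.read_noise_sigma > 0.0:
            read = rng.normal(0.0, delivery.read_noise_sigma, size=dose.shape)
        else:
            read = 0.0
        for profile, frame in zip(ordered, frames):
            acc[profile.fitzpatrick_type] += np.clip(frame + read, 0.0, None)
    return {
        p.fitzpatrick_type: CherenkovImage(
            values=acc[p.fitzpatrick_type], n_frames_summed=delivery.n_frames
        )
        for p in ordered
    }


def accumulate_frames(stack: FrameStack) -> CherenkovImage:
    """Sum the gated frames into the cumulative Cherenkov image."""
    if stack.frames.shape[0] == 0:
        raise ValueError("cannot accumulate an empty frame stack")
    return CherenkovImage(
        values=stack.frames.sum(axis=0), n_frames_summed=stack.frames.shape[0]
    )


def apply_rigid_transform(
    values: np.ndarray,
    shift_px: Sequence[float] = (0.0, 0.0),
    angle_deg: float = 0.0,
    order: int = 1,
) -> np.ndarray:
    """Rigid transform (rotation about the grid centre, then translation).

    Bilinear resampling by default with zero fill at the edges.  A pure
    integer translation of a delta image moves its argmax by exactly that
    offset (bilinear weights are then 1 and 0).
    """
    values = np.asarray(values, dtype=float)
    if angle_deg == 0.0 and tuple(shift_px) == (0.0, 0.0):
        return values.copy()
    theta = math.radians(angle_deg)
    c, s = math.cos(theta), math.sin(theta)
    rot = np.array([[c, -s], [s, c]])
    centre = (np.asarray(values.shape) - 1) / 2.0
    # inverse map: input = R (output - centre) + centre - shift
    offset = centre - rot @ centre - np.asarray(shift_px, dtype=float)
    return ndimage.affine_transform(
        values, rot, offset=offset, order=order, mode="constant", cval=0.0
    )


def perturb_setup(
    image: CherenkovImage,
    seed: int | None,
    max_shift_px: float = 2.0,
    max_rotation_deg: float = 1.0,
) -> CherenkovImage:
    """Residual setup misalignment after removing and re-positioning the phantom.

    Applies a rigid transform drawn uniformly: translation in
    [-max_shift, +max_shift] px per axis, rotation in [-max_rot, +max_rot]
    degrees, bilinear resampling with zero edge fill; seed-reproducible
    (translation drawn first, then rotation).
    """
    rng = np.random.default_rng(seed)
    shift = rng.uniform(-max_shift_px, max_shift_px, size=2)
    angle = rng.uniform(-max_rotation_deg, max_rotation_deg)
    values = apply_rigid_transform(image.values, shift_px=shift, angle_deg=angle)
    return CherenkovImage(values=values, n_frames_summed=image.n_frames_summed)
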