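"""Colorimetry and Cherenkov emission physics for skin-tone phantoms.

This module collects the small closed-form pieces of the study: the melanin
index (MI) computed from narrow-band reflectance, CIE L* lightness, the
individual typology angle (ITA), the Cherenkov threshold energy for electrons
in a refractive medium, and a single-parameter Beer--Lambert-style model of
how epidermal melanin attenuates the Cherenkov light escaping the skin.

Conventions
-----------
* Reflectance is a fraction in ``(0, 1]`` measured at 680 nm.
* MI is dimensionless, ``MI = 100 * log10(1 / R)``; higher MI = darker skin.
* The melanin transmission factor is normalised to 1 at a reference MI
  (default 37, the lightest phantom), so intensities are naturally expressed
  relative to the lightest skin tone.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "ELECTRON_REST_ENERGY_MEV",
    "EmissionModel",
    "SkinToneProfile",
    "cherenkov_threshold_energy",
    "cie_lightness",
    "depth_emission_weight",
    "ita_angle",
    "melanin_index",
    "melanin_transmission_factor",
    "reflectance_from_melanin_index",
]

ELECTRON_REST_ENERGY_MEV = 0.511

# CIE breakpoint between the cube-root and linear branches of f(Y).
_CIE_BREAK = (6.0 / 29.0) ** 3
_CIE_SLOPE = (29.0 / 6.0) ** 2 / 3.0


def melanin_index(rr):
    """Melanin index from the 680 nm reflectance fraction.

    ``MI = 100 * log10(1 / Rr)``.  Monotone decreasing in ``rr``; a perfect
    reflector (``rr == 1``) has MI 0.

    Parameters
    ----------
    rr : float or array_like
        Reflectance fraction(s) in ``(0, 1]``.

    Raises
    ------
    ValueError
        If any reflectance is outside ``(0, 1]``.
    """
    rr = np.asarray(rr, dtype=float)
    if np.any(rr <= 0.0) or np.any(rr > 1.0):
        raise ValueError("reflectance fraction out of range (0, 1]")
    out = 100.0 * np.log10(1.0 / rr)
    return float(out) if out.ndim == 0 else out


def reflectance_from_melanin_index(mi):
    """Inverse of :func:`melanin_index`: ``Rr = 10**(-MI / 100)``."""
    mi = np.asarray(mi, dtype=float)
    if np.any(mi < 0.0):
        raise ValueError("melanin index must be >= 0")
    out = 10.0 ** (-mi / 100.0)
    return float(out) if out.ndim == 0 else out


def cie_lightness(y):
    """CIE L* lightness from a luminance-reflectance fraction ``Y`` in [0, 1].

    Uses the standard two-branch CIE formula: ``L* = 116 f(Y) - 16`` with
    ``f(Y) = Y**(1/3)`` above the breakpoint ``(6/29)**3`` and the linear
    extension below it.  Gives synthetic phantoms a lightness coordinate
    comparable to a colorimeter's CIE-L reading.
    """
    y = np.asarray(y, dtype=float)
    if np.any(y < 0.0) or np.any(y > 1.0):
        raise ValueError("luminance-reflectance fraction out of range [0, 1]")
    f = np.where(y > _CIE_BREAK, np.cbrt(y), _CIE_SLOPE * y + 4.0 / 29.0)
    out = 116.0 * f - 16.0
    return float(out) if out.ndim == 0 else out


def ita_angle(l_star: float, b_star: float) -> float:
    """Individual typology angle in degrees: ``atan((L* - 50) / b*) * 180 / pi``.

    Lighter skin (L* > 50, positive b*) gives a positive angle.  The
    degenerate case ``b* == 0`` returns the limiting vertical angle:
    +90 for L* > 50, -90 for L* < 50, and 0 at L* == 50.
    """
    l_star = float(l_star)
    b_star = float(b_star)
    if not 0.0 <= l_star <= 100.0:
        raise ValueError("L* must lie in [0, 100]")
    if b_star == 0.0:
        if l_star > 50.0:
            return 90.0
        if l_star < 50.0:
            return -90.0
        return 0.0
    return math.degrees(math.atan((l_star - 50.0) / b_star))


def cherenkov_threshold_energy(n: float) -> float:
    """Kinetic threshold energy (MeV) for electron Cherenkov emission.

    An electron radiates only above the phase velocity of light in the
    medium, i.e. ``beta > 1/n``; the corresponding kinetic energy is
    ``m_e c^2 (1 / sqrt(1 - 1/n^2) - 1)``.  For skin tissue (n = 1.4) this
    evaluates to 0.219 MeV.

    Raises
    ------
    ValueError
        If ``n <= 1`` (no Cherenkov emission is possible).
    """
    n = float(n)
    if n <= 1.0:
        raise ValueError("refractive index must exceed 1 for Cherenkov emission")
    gamma = 1.0 / math.sqrt(1.0 - 1.0 / (n * n))
    return ELECTRON_REST_ENERGY_MEV * (gamma - 1.0)


@dataclass(frozen=True)
class EmissionModel:
    """Melanin / depth attenuation model for escaping Cherenkov light.

    The effective optical attenuation is taken linear in MI, so the
    surface-escaping radiant emission falls off exponentially with MI
    (diffusion-theory behaviour).  ``k_mi`` is calibrated by default so that
    the transmission ratio across the study's MI range (37 -> 120) is exactly
    a factor of 10.

    Attributes
    ----------
    mi_ref : float
        Reference melanin index at which the transmission factor is 1
        (lightest phantom).
    k_mi : float
        Exponential decay constant per MI unit (default ``ln(10)/83``).
    mu_eff_per_mm : float
        Effective attenuation coefficient for the depth weighting, per mm.
    depth_cutoff_mm : float
        Depth beyond which no Cherenkov light escapes (default 5 mm).
    """

    mi_ref: float = 37.0
    k_mi: float = math.log(10.0) / 83.0
    mu_eff_per_mm: float = 1.0
    depth_cutoff_mm: float = 5.0

    def __post_init__(self) -> None:
        if self.k_mi <= 0.0:
            raise ValueError("k_mi must be > 0")
        if self.mu_eff_per_mm <= 0.0:
            raise ValueError("mu_eff_per_mm must be > 0")
        if self.depth_cutoff_mm <= 0.0:
            raise ValueError("depth_cutoff_mm must be > 0")


def melanin_transmission_factor(mi, model: EmissionModel | None = None):
    """Fraction of Cherenkov light escaping relative to the reference tone.

    ``exp(-k_mi * (MI - mi_ref))``; equals 1 at ``mi_ref`` and, under the
    default calibration, 0.1 at MI 120 relative to MI 37.  MI values below
    the reference are allowed (they return factors > 1) but warn, since they
    fall outside the calibrated study range.
    """
    if model is None:
        model = EmissionModel()
    mi = np.asarray(mi, dtype=float)
    if np.any(mi < model.mi_ref):
        warnings.warn(
            "melanin index below the reference tone; transmission factor > 1",
            stacklevel=2,
        )
    out = np.exp(-model.k_mi * (mi - model.mi_ref))
    return float(out) if out.ndim == 0 else out


def depth_emission_weight(z_mm, model: EmissionModel | None = None):
    """Relative contribution of Cherenkov light generated at depth ``z_mm``.

    Exponential attenuation ``exp(-mu_eff * z)`` up to the escape cutoff
    (default 5 mm), zero beyond it.
    """
    if model is None:
        model = EmissionModel()
    z = np.asarray(z_mm, dtype=float)
    if np.any(z < 0.0):
        raise ValueError("depth must be non-negative")
    out = np.where(
        z <= model.depth_cutoff_mm, np.exp(-model.mu_eff_per_mm * z), 0.0
    )
    return float(out) if out.ndim == 0 else out


@dataclass
class SkinToneProfile:
    """Optical identity of one skin-tone phantom.

    ``melanin_index`` must be consistent with ``rr_680`` through the MI
    formula; construction validates this.  ``epidermis_thickness_mm`` and
    ``pigment_mass_fraction`` are carried as metadata only.
    """

    fitzpatrick_type: str
    rr_680: float
    melanin_index: float
    l_star: float
    b_star: float | None = 17.0
    epidermis_thickness_mm: float = 0.12
    pigment_mass_fraction: float | None = None

    _TYPES = ("I", "II", "III", "IV", "V", "VI")

    def __post_init__(self) -> None:
        if self.fitzpatrick_type not in self._TYPES:
            raise ValueError(f"fitzpatrick_type must be one of {self._TYPES}")
        if not 0.0 < self.rr_680 <= 1.0:
            raise ValueError("rr_680 must lie in (0, 1]")
        expected = melanin_index(self.rr_680)
        if not math.isclose(expected, self.melanin_index, abs_tol=1e-6):
            raise ValueError(
                f"melanin_index {self.melanin_index} inconsistent with "
                f"rr_680 {self.rr_680} (expected {expected:.6f})"
            )
        if not 0.0 <= self.l_star <= 100.0:
            raise ValueError("l_star must lie in [0, 100]")
        if self.epidermis_thickness_mm <= 0.0:
            raise ValueError("epidermis_thickness_mm must be > 0")

    @classmethod
    def from_reflectance(cls, fitzpatrick_type: str, rr_680: float, **kwargs):
        """Build a profile from reflectance alone; MI and L* are derived."""
        return cls(
            fitzpatrick_type=fitzpatrick_type,
            rr_680=rr_680,
            melanin_index=melanin_index(rr_680),
            l_star=cie_lightness(rr_680),
            **kwargs,
        )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SkinToneProfile":
        return cls(**d)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_json(cls, path) -> "SkinToneProfile":
        return cls.from_dict(json.loads(Path(path).read_text()))
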