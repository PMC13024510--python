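"""Interface acoustics and transducer directivity for a water-coupled ring array.

The object sits in warm water inside the transducer ring; sound enters the
tissue through the skin.  When the surface is not perpendicular to the beam,
refraction (Snell's law for longitudinal waves) and the angle-dependent
pressure transmission coefficient at the water/tissue interface redistribute
echo energy, which is what the inclination correction compensates.

Conventions
-----------
* Angles in degrees throughout the public API.
* ``transmission_coefficient`` returns the *pressure amplitude* coefficient
  T(θi) = 2 z_t cosθi / (z_t cosθi + z_i cosθt); the intensity (energy)
  convention R_I = R_p², T_I = 1 − R_I is available from
  :func:`reflection_transmission_sweep`.
* Beyond the critical angle (c_t > c_i only) :func:`snell_refraction` returns
  NaN; coefficient evaluation then uses cosθt = 0, i.e. total reflection
  (|R_p| = 1, T_I = 0).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AcousticMedium",
    "AcousticInterface",
    "WATER",
    "SOFT_TISSUE",
    "snell_refraction",
    "transmission_coefficient",
    "reflection_coefficient",
    "AngleSweep",
    "reflection_transmission_sweep",
    "DirectivityPattern",
    "element_directivity",
    "default_element_width",
]


@dataclass(frozen=True)
class AcousticMedium:
    """A fluid medium characterised by sound speed and density.

    The characteristic acoustic impedance is z = ρ·c (Rayl).
    """

    c: float          # sound speed, m/s
    density: float    # kg/m^3

    def __post_init__(self) -> None:
        if self.c <= 0 or self.density <= 0:
            raise ValueError("sound speed and density must be positive")

    @property
    def z(self) -> float:
        """Acoustic impedance ρ·c, Rayl."""
        return self.density * self.c


#: Warm water coupling medium.
WATER = AcousticMedium(c=1480.0, density=1000.0)
#: Generic soft tissue (skin / muscle bulk).
SOFT_TISSUE = AcousticMedium(c=1540.0, density=1050.0)


@dataclass(frozen=True)
class AcousticInterface:
    """A planar interface between an incident and a transmitting medium."""

    incident: AcousticMedium = WATER
    transmit: AcousticMedium = SOFT_TISSUE

    @property
    def critical_angle_deg(self) -> float | None:
        """arcsin(c_i/c_t) when c_t > c_i, else None (no total reflection)."""
        if self.transmit.c > self.incident.c:
            return math.degrees(math.asin(self.incident.c / self.transmit.c))
        return None

    def reversed(self) -> "AcousticInterface":
        return AcousticInterface(incident=self.transmit, transmit=self.incident)

    @property
    def matched(self) -> bool:
        return (
            self.incident.c == self.transmit.c
            and self.incident.z == self.transmit.z
        )


def _as_array(theta_i_deg):
    theta = np.asarray(theta_i_deg, dtype=np.float64)
    return theta, theta.ndim == 0


def snell_refraction(theta_i_deg, interface: AcousticInterface):
    """Refraction angle θt from Snell's law, degrees.

    sinθi/c_i = sinθt/c_t.  Supercritical incidence (arcsin argument > 1)
    yields NaN, a total-reflection sentinel consumed downstream by setting
    cosθt = 0.
    """
    theta, scalar = _as_array(theta_i_deg)
    arg = (interface.transmit.c / interface.incident.c) * np.sin(np.radians(theta))
    with np.errstate(invalid="ignore"):
        out = np.degrees(np.arcsin(arg))
    out = np.where(np.abs(arg) <= 1.0, out, np.nan)
    return float(out) if scalar else out


def _cosines(theta_i_deg, interface: AcousticInterface):
    theta, scalar = _as_array(theta_i_deg)
    cos_i = np.cos(np.radians(theta))
    theta_t = snell_refraction(theta, interface)
    theta_t = np.asarray(theta_t, dtype=np.float64)
    cos_t = np.where(np.isnan(theta_t), 0.0, np.cos(np.radians(np.nan_to_num(theta_t))))
    return cos_i, cos_t, scalar


def transmission_coefficient(theta_i_deg, interface: AcousticInterface):
    """Pressure amplitude transmission coefficient T(θi).

    T = 2 z_t cosθi / (z_t cosθi + z_i cosθt).  At normal incidence the
    cosines drop out and T(0) = 2 z_t / (z_t + z_i).  Supercritical angles
    are evaluated with cosθt = 0 (total internal reflection), giving T = 2.
    """
    zi, zt = interface.incident.z, interface.transmit.z
    cos_i, cos_t, scalar = _cosines(theta_i_deg, interface)
    T = 2.0 * zt * cos_i / (zt * cos_i + zi * cos_t)
    return float(T) if scalar else T


def reflection_coefficient(theta_i_deg, interface: AcousticInterface):
    """Pressure amplitude reflection coefficient R_p(θi).

    R_p = (z_t cosθi − z_i cosθt) / (z_t cosθi + z_i cosθt);
    |R_p| = 1 beyond the critical angle.
    """
    zi, zt = interface.incident.z, interface.transmit.z
    cos_i, cos_t, scalar = _cosines(theta_i_deg, interface)
    R = (zt * cos_i - zi * cos_t) / (zt * cos_i + zi * cos_t)
    return float(R) if scalar else R


@dataclass
class AngleSweep:
    """Reflection/transmission coefficients tabulated against incidence angle."""

    angles_deg: np.ndarray
    reflection: np.ndarray
    transmission: np.ndarray
    convention: str
    critical_angle_deg: float | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"angle_deg": self.angles_deg, "R": self.reflection, "T": self.transmission}
        )


def reflection_transmission_sweep(
    interface: AcousticInterface,
    convention: str = "intensity",
    n_angles: int = 181,
    max_angle_deg: float = 90.0,
) -> AngleSweep:
    """Sweep R and T over incidence angles in [0, max_angle_deg).

    ``convention="pressure"`` returns amplitude coefficients R_p, T_p;
    ``"intensity"`` returns the energy split R_I = R_p², T_I = 1 − R_I
    (complementary below the critical angle, T_I = 0 beyond it).
    """
    if n_angles < 2:
        raise ValueError("n_angles must be at least 2")
    if convention not in ("pressure", "intensity"):
        raise ValueError(f"unknown convention {convention!r}")
    angles = np.linspace(0.0, max_angle_deg, n_angles, endpoint=False)
    R_p = reflection_coefficient(angles, interface)
    if convention == "pressure":
        T = transmission_coefficient(angles, interface)
        R = R_p
    else:
        R = np.clip(R_p**2, 0.0, 1.0)
        crit = interface.critical_angle_deg
        if crit is not None:
            R = np.where(angles >= crit, 1.0, R)
        T = 1.0 - R
    return AngleSweep(
        angles_deg=angles,
        reflection=np.asarray(R),
        transmission=np.asarray(T),
        convention=convention,
        critical_angle_deg=interface.critical_angle_deg,
    )


def intensity_transmission(theta_i_deg, interface: AcousticInterface):
    """Energy transmission T_I(θi) = 1 − R_p²(θi); 0 beyond the critical angle."""
    R_p = np.asarray(reflection_coefficient(theta_i_deg, interface))
    T = 1.0 - np.clip(R_p**2, 0.0, 1.0)
    crit = interface.critical_angle_deg
    if crit is not None:
        theta = np.asarray(theta_i_deg, dtype=np.float64)
        T = np.where(theta >= crit, 0.0, T)
    if np.ndim(theta_i_deg) == 0:
        return float(T)
    return T


def default_element_width(
    inner_diameter_m: float = 0.222, n_elements: int = 2048, kerf_fraction: float = 0.1
) -> float:
    """Element width of the annular probe: circumferential pitch minus kerf, m."""
    pitch = math.pi * inner_diameter_m / n_elements
    return pitch * (1.0 - kerf_fraction)


@dataclass
class DirectivityPattern:
    """Far-field directivity of a line aperture, dB relative to on-axis."""

    frequency: float
    element_width: float
    medium_c: float
    angles_deg: np.ndarray
    level_db: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"angle_deg": self.angles_deg, "level_db": self.level_db})

    def width_deg(self, level_db: float = -6.0) -> float:
        """Full main-lobe width at the given level below the on-axis maximum."""
        half = self.angles_deg >= 0
        a, l = self.angles_deg[half], self.level_db[half]
        below = np.nonzero(l <= level_db)[0]
        if below.size == 0:
            return 2.0 * float(a[-1])
        j = below[0]
        if j == 0:
            return 0.0
        # linear interpolation of the crossing
        t = (level_db - l[j - 1]) / (l[j] - l[j - 1])
        return 2.0 * float(a[j - 1] + t * (a[j] - a[j - 1]))


def element_directivity(
    frequency: float,
    element_width: float | None = None,
    medium_c: float = WATER.c,
    angles_deg: np.ndarray | None = None,
) -> DirectivityPattern:
    """Far-field pattern of a single array element at the given frequency.

    Uses the standard line-aperture model |sinc(w·sinθ/λ)| (numpy sinc,
    i.e. sin(πx)/(πx)) normalised to 0 dB on axis; λ = c/f.  A narrow
    element (w ≪ λ) is essentially omnidirectional; a wide one concentrates
    energy straight ahead, with the first null at sinθ = λ/w.
    """
    if frequency <= 0:
        raise ValueError("frequency must be positive")
    if element_width is None:
        element_width = default_element_width()
    if element_width <= 0:
        raise ValueError("element_width must be positive")
    if angles_deg is None:
        angles_deg = np.linspace(-90.0, 90.0, 361)
    angles_deg = np.asarray(angles_deg, dtype=np.float64)
    lam = medium_c / frequency
    pattern = np.abs(np.sinc(element_width * np.sin(np.radians(angles_deg)) / lam))
    level_db = 20.0 * np.log10(np.maximum(pattern, 1e-12))
    return DirectivityPattern(
        frequency=float(frequency),
        element_width=float(element_width),
        medium_c=float(medium_c),
        angles_deg=angles_deg,
        level_db=level_db,
    )
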