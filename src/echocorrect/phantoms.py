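"""Synthetic phantoms with known ground-truth artifact fields.

Ring-array reflection tomography suffers two systematic intensity artifacts:

* *eccentricity* — a radial "centre brightening, edge darkening" caused by
  beam overlap at the ring centre and a reduced effective channel count at
  the periphery.  For multiplicative beamformers (DMAS) the output magnitude
  scales as Neff(ρ)²·A(ρ)², which amplifies the radial sensitivity
  difference; and
* *inclination* — echo loss where the object surface is tilted with respect
  to the imaging plane, so specular reflections miss the receiving elements.

This module renders calibration disks, target phantoms, stacked-cone
inclination stacks and limb-like slices under parametric versions of both
artifacts, returning the exact per-pixel fields that were applied so that the
correction stages can be validated without hardware data.

All generation is deterministic: identical (spec, seed) pairs give
bit-identical arrays.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .images import ImageSlice, ImageStack, radial_distance_map
from .physics import (
    AcousticInterface,
    intensity_transmission,
    transmission_coefficient,
)

__all__ = [
    "SensitivityModel",
    "Target",
    "LimbSpec",
    "NoiseSpec",
    "PhantomSpec",
    "GroundTruth",
    "make_calibration_phantom",
    "make_eccentricity_phantom",
    "make_inclination_stack",
    "make_limb_slice",
    "transmission_factor",
]


# ---------------------------------------------------------------------------
# radial sensitivity field models
# ---------------------------------------------------------------------------
@dataclass
class SensitivityModel:
    """Parametric radial sensitivity S(ρ), normalised to 1 at the centre.

    kinds
    -----
    ``gaussian_decay``
        S(u) = exp(ln(r_e)·u²) with u = ρ/R_edge, so S(0)=1 and
        S(R_edge) = ``edge_to_center_ratio`` (r_e).
    ``polynomial``
        S(u) = 1 + Σ_k coeffs[k]·u^(k+1); must stay positive on [0, 1].
    ``dmas_neff``
        S ∝ Neff(u)²·A(u)², the output magnitude of a
        delay-multiply-and-sum beamformer with Neff effective coherent
        channels of per-channel amplitude A, normalised at u = 0.
    """

    kind: str = "gaussian_decay"
    edge_to_center_ratio: float = 0.6
    coeffs: tuple[float, ...] = ()
    rho_grid: np.ndarray | None = None      # normalized radius grid for dmas_neff
    neff_profile: np.ndarray | None = None
    amp_profile: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("gaussian_decay", "polynomial", "dmas_neff", "identity"):
            raise ValueError(f"unknown sensitivity kind {self.kind!r}")
        if self.kind == "gaussian_decay" and not (0.0 < self.edge_to_center_ratio <= 1.0):
            raise ValueError("edge_to_center_ratio must lie in (0, 1]")
        if self.kind == "dmas_neff":
            if self.rho_grid is None or self.neff_profile is None:
                raise ValueError("dmas_neff needs rho_grid and neff_profile")
            self.rho_grid = np.asarray(self.rho_grid, dtype=np.float64)
            self.neff_profile = np.asarray(self.neff_profile, dtype=np.float64)
            if self.amp_profile is None:
                self.amp_profile = np.ones_like(self.rho_grid)
            self.amp_profile = np.asarray(self.amp_profile, dtype=np.float64)

    # constructors ----------------------------------------------------------
    @classmethod
    def identity(cls) -> "SensitivityModel":
        return cls(kind="identity")

    @classmethod
    def gaussian(cls, edge_to_center_ratio: float) -> "SensitivityModel":
        return cls(kind="gaussian_decay", edge_to_center_ratio=edge_to_center_ratio)

    @classmethod
    def polynomial(cls, coeffs: Sequence[float]) -> "SensitivityModel":
        return cls(kind="polynomial", coeffs=tuple(float(c) for c in coeffs))

    @classmethod
    def dmas(cls, rho_grid, neff_profile, amp_profile=None) -> "SensitivityModel":
        return cls(
            kind="dmas_neff",
            rho_grid=np.asarray(rho_grid, dtype=np.float64),
            neff_profile=np.asarray(neff_profile, dtype=np.float64),
            amp_profile=None if amp_profile is None else np.asarray(amp_profile, dtype=np.float64),
        )

    # evaluation ------------------------------------------------------------
    def __call__(self, rho_norm) -> np.ndarray:
        """Evaluate S at normalised radius u = ρ/R_edge (u may exceed 1)."""
        u = np.asarray(rho_norm, dtype=np.float64)
        if self.kind == "identity":
            out = np.ones_like(u)
        elif self.kind == "gaussian_decay":
            out = np.exp(np.log(self.edge_to_center_ratio) * u**2)
        elif self.kind == "polynomial":
            out = np.ones_like(u)
            for k, c in enumerate(self.coeffs, start=1):
                out = out + c * u**k
        else:  # dmas_neff
            neff = np.interp(u, self.rho_grid, self.neff_profile)
            amp = np.interp(u, self.rho_grid, self.amp_profile)
            n0 = np.interp(0.0, self.rho_grid, self.neff_profile)
            a0 = np.interp(0.0, self.rho_grid, self.amp_profile)
            out = (neff * amp) ** 2 / (n0 * a0) ** 2
        if np.any(out[np.asarray(u <= 1.0)] <= 0):
            raise ValueError("sensitivity must be strictly positive inside the edge radius")
        return out

    def field_on_grid(
        self, shape: tuple[int, int], center_xy: tuple[float, float], edge_radius_px: float
    ) -> np.ndarray:
        rho = radial_distance_map(shape, center_xy)
        return self(rho / edge_radius_px)


# ---------------------------------------------------------------------------
# phantom specifications
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class Target:
    """A circular scatterer inclusion: centre (x, y) px, radius px, reflectivity ×background."""

    center_xy: tuple[float, float]
    radius: float
    reflectivity: float = 2.0


@dataclass(frozen=True)
class LimbSpec:
    """Limb-like object: off-centre disk with a bright skin rim and interior texture."""

    radius: float
    center_offset_xy: tuple[float, float] = (0.0, 0.0)
    rim_width: float = 4.0
    rim_level: float = 2.0          # × background_level
    texture_amplitude: float = 0.05  # relative, uniform ±amplitude
    texture_seed: int = 0


@dataclass(frozen=True)
class NoiseSpec:
    kind: str = "none"  # none | rayleigh | gaussian
    sigma: float = 0.0
    seed: int = 0


@dataclass
class PhantomSpec:
    """Geometry and rendering parameters shared by all phantom kinds."""

    fov_radius_px: float = 128.0
    pixel_spacing: float = 1.0       # mm/px
    background_level: float = 1.0
    targets: tuple[Target, ...] = ()
    limb: LimbSpec | None = None
    cone_half_angle_deg: float | None = None
    cone_base_radius_px: float | None = None   # default 0.8 × fov_radius
    surface_band_px: float = 3.0
    surface_level: float = 2.0       # × background_level, on the cone surface band
    n_slices: int = 1
    slice_spacing: float = 1.0       # mm
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    grid_shape: tuple[int, int] | None = None  # default odd grid 2R+1

    def __post_init__(self) -> None:
        if self.background_level <= 0:
            raise ValueError("background_level must be positive")
        if self.cone_half_angle_deg is not None and not (
            0.0 <= self.cone_half_angle_deg < 90.0
        ):
            raise ValueError("cone_half_angle_deg must lie in [0, 90)")
        self.targets = tuple(self.targets)
        for t in self.targets:
            if np.hypot(*t.center_xy) + t.radius > self.fov_radius_px:
                raise ValueError("target extends beyond the field of view")

    @property
    def shape(self) -> tuple[int, int]:
        if self.grid_shape is not None:
            return self.grid_shape
        n = int(round(2 * self.fov_radius_px)) + 1
        return (n, n)

    @property
    def center_xy(self) -> tuple[float, float]:
        h, w = self.shape
        return ((w - 1) / 2.0, (h - 1) / 2.0)


@dataclass
class GroundTruth:
    """Exact artifact plumbing of a generated phantom.

    Before additive noise::

        generated = clean × sensitivity_field × transmission_attenuation
    """

    sensitivity_field: np.ndarray
    angle_field_true: np.ndarray
    clean_image: np.ndarray
    meta: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------
def transmission_factor(theta_deg, interface: AcousticInterface, mode: str = "pressure"):
    """Forward attenuation factor relative to normal incidence, T(θ)/T(0).

    ``mode="pressure"`` uses the pressure amplitude coefficient;
    ``"round_trip"`` uses the intensity transmission 1 − R_p² (decaying with
    angle for a water→tissue interface).  Matched media give 1 at any angle.
    """
    if mode == "pressure":
        T = np.asarray(transmission_coefficient(theta_deg, interface), dtype=np.float64)
        T0 = transmission_coefficient(0.0, interface)
    elif mode == "round_trip":
        T = np.asarray(intensity_transmission(theta_deg, interface), dtype=np.float64)
        T0 = intensity_transmission(0.0, interface)
    else:
        raise ValueError(f"unknown transmission mode {mode!r}")
    out = T / T0
    if np.ndim(theta_deg) == 0:
        return float(out)
    return out


def _sens_edge_radius(spec: PhantomSpec, edge_radius_px: float | None) -> float:
    # The sensitivity edge coincides with the effective imaging radius used
    # by the gain (0.95 × FOV), not the geometric grid edge.
    return edge_radius_px if edge_radius_px is not None else 0.95 * spec.fov_radius_px


def _apply_noise(pixels: np.ndarray, noise: NoiseSpec) -> np.ndarray:
    if noise.kind == "none" or noise.sigma == 0.0:
        return pixels
    rng = np.random.default_rng(noise.seed)
    if noise.kind == "rayleigh":
        # multiplicative speckle with unit mean
        mult = rng.rayleigh(scale=np.sqrt(2.0 / np.pi), size=pixels.shape)
        return pixels * (1.0 + noise.sigma * (mult - 1.0))
    if noise.kind == "gaussian":
        return np.maximum(pixels + rng.normal(0.0, noise.sigma, pixels.shape), 0.0)
    raise ValueError(f"unknown noise kind {noise.kind!r}")


def _fov_disk(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    rho = radial_distance_map(spec.shape, spec.center_xy)
    return rho, rho <= spec.fov_radius_px


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------
def make_calibration_phantom(
    spec: PhantomSpec,
    sens: SensitivityModel | None = None,
    sens_edge_radius: float | None = None,
) -> tuple[ImageSlice, GroundTruth]:
    """Uniform-disk calibration acquisition under a radial sensitivity field.

    The calibration frame emulates imaging a uniform scatterer through the
    same pipeline as actual imaging; it is the flat-field reference from
    which the radial gain is estimated.
    """
    if spec.targets:
        raise ValueError("calibration phantom must be uniform (no targets)")
    if spec.cone_half_angle_deg is not None:
        raise ValueError("calibration phantom must have no cone angle")
    sens = sens or SensitivityModel.identity()
    rho, disk = _fov_disk(spec)
    clean = np.where(disk, spec.background_level, 0.0)
    field_ = sens.field_on_grid(spec.shape, spec.center_xy, _sens_edge_radius(spec, sens_edge_radius))
    pixels = _apply_noise(clean * field_, spec.noise)
    img = ImageSlice(
        pixels,
        center_xy=spec.center_xy,
        pixel_spacing=spec.pixel_spacing,
        fov_mask=disk,
        meta={"phantom": "calibration"},
    )
    gt = GroundTruth(
        sensitivity_field=field_,
        angle_field_true=np.zeros(spec.shape),
        clean_image=clean,
        meta={"kind": "calibration"},
    )
    return img, gt


def make_eccentricity_phantom(
    spec: PhantomSpec,
    sens: SensitivityModel | None = None,
    sens_edge_radius: float | None = None,
) -> tuple[ImageSlice, GroundTruth]:
    """Cylindrical phantom with embedded circular targets at graded radii.

    Identical targets placed at different radii appear equally bright in the
    clean image and differ only through the sensitivity field, which is the
    signature the eccentricity correction must remove.
    """
    if not spec.targets:
        raise ValueError("eccentricity phantom needs at least one target")
    for i, a in enumerate(spec.targets):
        for b in spec.targets[i + 1 :]:
            d = np.hypot(a.center_xy[0] - b.center_xy[0], a.center_xy[1] - b.center_xy[1])
            if d < a.radius + b.radius:
                warnings.warn("overlapping targets in phantom spec", stacklevel=2)
    sens = sens or SensitivityModel.identity()
    rho, disk = _fov_disk(spec)
    clean = np.where(disk, spec.background_level, 0.0)
    cx, cy = spec.center_xy
    yy, xx = np.ogrid[: spec.shape[0], : spec.shape[1]]
    for t in spec.targets:
        tx, ty = cx + t.center_xy[0], cy + t.center_xy[1]
        m = np.hypot(xx - tx, yy - ty) <= t.radius
        clean[m] = spec.background_level * t.reflectivity
    field_ = sens.field_on_grid(spec.shape, spec.center_xy, _sens_edge_radius(spec, sens_edge_radius))
    pixels = _apply_noise(clean * field_, spec.noise)
    img = ImageSlice(
        pixels,
        center_xy=spec.center_xy,
        pixel_spacing=spec.pixel_spacing,
        fov_mask=disk,
        meta={"phantom": "eccentricity"},
    )
    gt = GroundTruth(
        sensitivity_field=field_,
        angle_field_true=np.zeros(spec.shape),
        clean_image=clean,
        meta={"kind": "eccentricity", "n_targets": len(spec.targets)},
    )
    return img, gt


def make_inclination_stack(
    spec: PhantomSpec,
    interface: AcousticInterface | None = None,
    mode: str = "pressure",
) -> tuple[ImageStack, GroundTruth]:
    """Stacked-cone inclination phantom.

    Slice 0 is the cone base (bottom); the boundary radius shrinks by
    ``slice_spacing·tan(cone_half_angle)/pixel_spacing`` pixels per slice.
    The slanted surface shows up in each slice as a thin bright annulus whose
    echo is attenuated by the interface transmission factor at the cone's
    half-angle; the flat interior is at normal incidence (no attenuation).
    """
    if spec.cone_half_angle_deg is None:
        raise ValueError("cone_half_angle_deg must be set for an inclination stack")
    if spec.n_slices < 2:
        raise ValueError("an inclination stack needs at least 2 slices")
    if spec.slice_spacing <= 0:
        raise ValueError("slice_spacing must be positive")
    interface = interface or AcousticInterface()
    angle = spec.cone_half_angle_deg
    base_r = spec.cone_base_radius_px or 0.8 * spec.fov_radius_px
    shrink = spec.slice_spacing * np.tan(np.radians(angle)) / spec.pixel_spacing
    rho, disk = _fov_disk(spec)
    att = transmission_factor(angle, interface, mode=mode)

    n = spec.n_slices
    clean = np.zeros((n,) + spec.shape)
    pixels = np.zeros_like(clean)
    angles_true = np.zeros_like(clean)
    for k in range(n):
        r_k = base_r - k * shrink
        if r_k <= spec.surface_band_px:
            raise ValueError("cone tapers below the surface band width; reduce n_slices")
        in_disk = rho <= r_k
        band = in_disk & (rho > r_k - spec.surface_band_px)
        clean[k][in_disk] = spec.background_level
        clean[k][band] = spec.background_level * spec.surface_level
        pixels[k] = clean[k].copy()
        pixels[k][band] *= att
        angles_true[k][band] = angle
        pixels[k] = _apply_noise(
            pixels[k], replace(spec.noise, seed=spec.noise.seed + k) if spec.noise.kind != "none" else spec.noise
        )
    stack = ImageStack(
        pixels,
        center_xy=spec.center_xy,
        pixel_spacing=spec.pixel_spacing,
        slice_spacing=spec.slice_spacing,
        fov_mask=disk,
        meta={"phantom": "inclination", "cone_half_angle_deg": angle, "mode": mode},
    )
    gt = GroundTruth(
        sensitivity_field=np.ones_like(clean),
        angle_field_true=angles_true,
        clean_image=clean,
        meta={"kind": "inclination", "attenuation_factor": att, "base_radius_px": base_r},
    )
    return stack, gt


def make_limb_slice(
    spec: PhantomSpec,
    sens: SensitivityModel | None = None,
    tilt_deg: float = 0.0,
    interface: AcousticInterface | None = None,
    mode: str = "pressure",
    sens_edge_radius: float | None = None,
) -> tuple[ImageSlice, GroundTruth]:
    """Limb-like slice: disk with bright skin rim and seeded interior texture.

    The slice is rendered clean, then degraded by the radial sensitivity
    field (about the *imaging* centre, not the limb centre) and by a uniform
    tilt attenuation at ``tilt_deg``, emulating a limb whose surface is
    inclined to the scanning plane.
    """
    if spec.limb is None:
        raise ValueError("spec.limb must be set for a limb slice")
    limb = spec.limb
    if not (0.0 <= limb.texture_amplitude <= 0.5):
        raise ValueError("texture_amplitude must lie in [0, 0.5]")
    off = np.hypot(*limb.center_offset_xy)
    if off + limb.radius > spec.fov_radius_px:
        raise ValueError("limb disk extends beyond the field of view")
    sens = sens or SensitivityModel.identity()
    interface = interface or AcousticInterface()
    rho, fov = _fov_disk(spec)
    cx, cy = spec.center_xy
    lx, ly = cx + limb.center_offset_xy[0], cy + limb.center_offset_xy[1]
    rho_limb = radial_distance_map(spec.shape, (lx, ly))
    disk = rho_limb <= limb.radius
    interior = rho_limb <= limb.radius - limb.rim_width
    rim = disk & ~interior

    clean = np.zeros(spec.shape)
    clean[interior] = spec.background_level
    clean[rim] = spec.background_level * limb.rim_level
    if limb.texture_amplitude > 0:
        rng = np.random.default_rng(limb.texture_seed)
        tex = 1.0 + rng.uniform(-limb.texture_amplitude, limb.texture_amplitude, spec.shape)
        clean[interior] *= tex[interior]

    field_ = sens.field_on_grid(spec.shape, spec.center_xy, _sens_edge_radius(spec, sens_edge_radius))
    att = transmission_factor(tilt_deg, interface, mode=mode) if tilt_deg else 1.0
    att_map = np.where(disk, att, 1.0)
    pixels = _apply_noise(clean * field_ * att_map, spec.noise)
    img = ImageSlice(
        pixels,
        center_xy=spec.center_xy,
        pixel_spacing=spec.pixel_spacing,
        fov_mask=fov,
        meta={"phantom": "limb", "tilt_deg": tilt_deg},
    )
    angle_true = np.where(disk, float(tilt_deg), 0.0)
    gt = GroundTruth(
        sensitivity_field=field_,
        angle_field_true=angle_true,
        clean_image=clean,
        meta={"kind": "limb", "limb_mask": disk, "attenuation_factor": att},
    )
    return img, gt
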