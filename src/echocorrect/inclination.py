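"""Incident-angle estimation and transmission-loss gain compensation.

When the imaged surface is inclined with respect to the scanning plane the
echo received by the ring drops systematically.  This module implements the
angle-based correction:

1. extract a stable foreground contour for the target slice from a maximum
   intensity projection (MIP) of the slices below it, via thresholding and
   morphological opening/closing;
2. estimate the per-pixel incident angle θi(x, y) from the radial
   displacement of the boundary across slices divided by the slice spacing
   (θi = arctan(radial shift / axial spacing)), interpolated and smoothed
   over the near-surface band;
3. map θi through Snell's law and the pressure transmission coefficient to
   a gain G(θi) = T(0)/max(T(θi), ε) clipped at G_max, or its dB form
   C(θi) = 20·log10 G(θi);
4. apply I_corr = I + κ·C(θi) in dB (equivalently I·G^κ in the linear
   domain), with the strength κ either fixed or tuned by minimising the
   overflow rate — the fraction of pixels leaving a preset display window.

Note on the gain direction: with the literal pressure coefficient a
water→tissue interface has T(θi) ≥ T(0) below the critical angle, so the
literal gain is ≤ 1.  The opt-in ``mode="round_trip"`` uses the intensity
transmission 1 − R_p², which decays with angle and therefore brightens
oblique regions.  Both modes are exact inverses of the corresponding forward
attenuation model in :mod:`echocorrect.phantoms`.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import disk

from .images import ImageSlice, ImageStack
from .physics import (
    AcousticInterface,
    intensity_transmission,
    snell_refraction,
    transmission_coefficient,
)

__all__ = [
    "InclinationConfig",
    "AngleField",
    "NoForegroundError",
    "AngleEstimationError",
    "mip_below",
    "segment_foreground",
    "incident_angle_field",
    "angle_gain",
    "apply_inclination_correction",
    "overflow_rate",
    "optimize_kappa",
    "InclinationModel",
    "InclinationResult",
]

log = logging.getLogger(__name__)

DEFAULT_KAPPA_GRID = tuple(np.round(np.arange(0.0, 1.51, 0.1), 10))


class NoForegroundError(ValueError):
    """Segmentation found no foreground; caller should fall back to adjacent slices."""


class AngleEstimationError(ValueError):
    """Too few usable boundaries to determine the incident angle."""


@dataclass
class InclinationConfig:
    """Parameters of the inclination correction.

    kappa
        Correction intensity coefficient κ ≥ 0, or ``"auto"`` to minimise
        the overflow rate on representative slices.
    epsilon
        Stabiliser flooring the transmission coefficient in the gain.
    g_max
        Ceiling on G(θi) (≥ 1).
    window_lo, window_hi
        Display-window bounds defining overflow; ``None`` means the 1st/99th
        percentile of the uncorrected slice set at optimisation time.
    seg_threshold
        Absolute segmentation threshold; ``None`` selects Otsu on the MIP
        inside the FOV.
    morph_radius
        Structuring-element radius for opening/closing, px.
    smooth_sigma
        Gaussian smoothing scale of the angle field, px.
    band_width
        Inward dilation of the surface band that receives angles, px.
    mip_depth
        Number of slices below the target used for the MIP.
    mode
        ``"pressure"`` (literal gain) or ``"round_trip"`` (intensity
        transmission).
    """

    kappa: float | str = "auto"
    epsilon: float = 1e-2
    g_max: float = 2.0
    window_lo: float | None = None
    window_hi: float | None = None
    seg_threshold: float | None = None
    morph_radius: int = 2
    smooth_sigma: float = 5.0
    band_width: int = 5
    mip_depth: int = 3
    mode: str = "pressure"
    n_angle_bins: int = 256
    kappa_grid: tuple[float, ...] = DEFAULT_KAPPA_GRID

    def __post_init__(self) -> None:
        if isinstance(self.kappa, str):
            if self.kappa != "auto":
                raise ValueError("kappa must be a number or 'auto'")
        elif self.kappa < 0:
            raise ValueError("kappa must be non-negative")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.g_max < 1:
            raise ValueError("g_max must be at least 1")
        if self.window_lo is not None and self.window_hi is not None:
            if not self.window_lo < self.window_hi:
                raise ValueError("window_lo must be below window_hi")
        if self.mode not in ("pressure", "round_trip"):
            raise ValueError(f"unknown transmission mode {self.mode!r}")


@dataclass
class AngleField:
    """Per-pixel incident angle θi (degrees, ≥ 0) with validity mask.

    Outside ``valid_mask`` no correction is applied.  ``source_slices``
    records which stack slices informed the estimate;
    ``filled_from_adjacent`` flags angular sectors whose boundary left the
    FOV and was filled by interpolation from neighbouring sectors.
    """

    theta_i: np.ndarray
    valid_mask: np.ndarray
    source_slices: tuple[int, ...] = ()
    filled_from_adjacent: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.theta_i = np.asarray(self.theta_i, dtype=np.float64)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        inside = self.theta_i[self.valid_mask]
        if inside.size and (inside.min() < 0 or inside.max() >= 90.0):
            raise ValueError("incident angles must lie in [0°, 90°) inside the mask")


# ---------------------------------------------------------------------------
# surface extraction
# ---------------------------------------------------------------------------
def mip_below(stack: ImageStack, target_index: int, depth: int = 3) -> ImageSlice:
    """Maximum intensity projection over the ``depth`` slices below the target.

    Slice 0 is the bottom of the stack, so "below" means smaller indices;
    requesting the bottom slice itself is rejected (no slices below — use
    the adjacent-slice fallback of the model instead).
    """
    if depth < 1:
        raise ValueError("depth must be at least 1")
    if target_index < 1:
        raise ValueError("target is the bottom slice: no slices below it")
    if target_index >= len(stack):
        raise IndexError("target_index out of range")
    lo = max(0, target_index - depth)
    mip = stack.pixels[lo:target_index].max(axis=0)
    return ImageSlice(
        mip,
        center_xy=stack.center_xy,
        pixel_spacing=stack.pixel_spacing,
        domain=stack.domain,
        fov_mask=stack.fov_mask.copy(),
        meta={"mip_of": list(range(lo, target_index))},
    )


def segment_foreground(mip: ImageSlice, cfg: InclinationConfig | None = None) -> np.ndarray:
    """Stable foreground mask: threshold, open/close, largest component, fill.

    The threshold is ``cfg.seg_threshold`` or Otsu's value over the FOV.
    Opening removes specks smaller than the structuring element; closing and
    hole-filling make the retained component simply connected.
    """
    cfg = cfg or InclinationConfig()
    if mip.domain != "linear":
        raise ValueError("segmentation expects a linear-domain image")
    vals = mip.pixels[mip.fov_mask]
    if vals.size == 0 or np.ptp(vals) == 0 and vals.max() <= 0:
        raise NoForegroundError("no foreground: image is empty")
    thr = cfg.seg_threshold if cfg.seg_threshold is not None else threshold_otsu(vals)
    bw = (mip.pixels > thr) & mip.fov_mask
    if cfg.morph_radius > 0:
        se = disk(cfg.morph_radius)
        bw = ndimage.binary_opening(bw, structure=se)
        bw = ndimage.binary_closing(bw, structure=se)
    if not bw.any():
        raise NoForegroundError("no foreground after threshold and morphology")
    labels, n = ndimage.label(bw)
    if n > 1:
        sizes = np.bincount(labels.ravel())
        sizes[0] = 0
        bw = labels == sizes.argmax()
    return ndimage.binary_fill_holes(bw)


def _boundary_radii(
    mask: np.ndarray, center_xy: tuple[float, float], n_bins: int
) -> np.ndarray:
    """Mean boundary radius (px) per polar-angle sector; NaN where absent."""
    boundary = mask & ~ndimage.binary_erosion(mask, structure=np.ones((3, 3)))
    ys, xs = np.nonzero(boundary)
    if ys.size == 0:
        return np.full(n_bins, np.nan)
    cx, cy = center_xy
    phi = np.arctan2(ys - cy, xs - cx)
    rho = np.hypot(xs - cx, ys - cy)
    idx = np.floor((phi + np.pi) / (2 * np.pi) * n_bins).astype(np.intp) % n_bins
    sums = np.bincount(idx, weights=rho, minlength=n_bins)
    counts = np.bincount(idx, minlength=n_bins)
    with np.errstate(invalid="ignore"):
        out = sums / counts
    out[counts == 0] = np.nan
    return out


def _interp_periodic_nan(values: np.ndarray) -> tuple[np.ndarray, bool]:
    """Fill NaN sectors by periodic linear interpolation; report whether any."""
    bad = np.isnan(values)
    if not bad.any():
        return values, False
    if bad.all():
        raise AngleEstimationError("no usable boundary sectors")
    n = len(values)
    x = np.arange(n)
    good = ~bad
    filled = values.copy()
    filled[bad] = np.interp(x[bad], x[good], values[good], period=n)
    return filled, True


def incident_angle_field(
    mask: np.ndarray,
    slice_spacing: float,
    pixel_spacing: float,
    lower_masks: Sequence[np.ndarray],
    cfg: InclinationConfig | None = None,
    center_xy: tuple[float, float] | None = None,
    fov_mask: np.ndarray | None = None,
    source_slices: tuple[int, ...] = (),
) -> AngleField:
    """Estimate the per-pixel incident angle from boundary displacement.

    ``lower_masks`` are the foreground masks of the slices below the target,
    nearest first.  For each polar sector the boundary radius is regressed
    on the axial position; the surface slope gives
    θi = arctan(|d r / d z|).  The sector angles are painted onto the
    near-surface band of the target mask (``cfg.band_width`` px inward of
    the boundary), smoothed with a normalised Gaussian of scale
    ``cfg.smooth_sigma``, and clipped to [0°, 90°).  The flat interior far
    from the surface keeps θi = 0.
    """
    cfg = cfg or InclinationConfig()
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise AngleEstimationError("empty target mask")
    if len(lower_masks) < 1:
        raise AngleEstimationError("need at least 2 usable boundaries (target + 1 below)")
    if center_xy is None:
        cy, cx = ndimage.center_of_mass(mask)
        center_xy = (cx, cy)

    n_bins = cfg.n_angle_bins
    all_masks = [mask] + [np.asarray(m, dtype=bool) for m in lower_masks]
    # target at z=0; lower slices at −spacing, −2·spacing, ...
    zs = np.array([0.0] + [-(k + 1) * slice_spacing for k in range(len(lower_masks))])
    radii = np.stack([_boundary_radii(m, center_xy, n_bins) for m in all_masks])
    radii_mm = radii * pixel_spacing

    usable = (~np.isnan(radii_mm)).sum(axis=0)
    if (usable >= 2).sum() == 0:
        raise AngleEstimationError("fewer than 2 usable boundaries in every sector")

    slopes = np.full(n_bins, np.nan)
    for b in range(n_bins):
        ok = ~np.isnan(radii_mm[:, b])
        if ok.sum() < 2:
            continue
        z, r = zs[ok], radii_mm[ok, b]
        zc = z - z.mean()
        slopes[b] = np.dot(zc, r - r.mean()) / np.dot(zc, zc)

    theta_phi = np.degrees(np.arctan(np.abs(slopes)))
    theta_phi, filled = _interp_periodic_nan(theta_phi)

    # paint sector angles on the near-surface band and smooth in 2-D
    eroded = ndimage.binary_erosion(mask, structure=disk(cfg.band_width)) if cfg.band_width > 0 else mask
    band = mask & ~eroded
    yy, xx = np.nonzero(band)
    phi = np.arctan2(yy - center_xy[1], xx - center_xy[0])
    idx = np.floor((phi + np.pi) / (2 * np.pi) * n_bins).astype(np.intp) % n_bins
    theta = np.zeros(mask.shape)
    theta[band] = theta_phi[idx]
    if cfg.smooth_sigma > 0:
        w = ndimage.gaussian_filter(band.astype(np.float64), cfg.smooth_sigma)
        num = ndimage.gaussian_filter(theta * band, cfg.smooth_sigma)
        with np.errstate(invalid="ignore", divide="ignore"):
            sm = np.where(w > 1e-12, num / w, 0.0)
        theta = np.where(band, sm, 0.0)
    theta = np.clip(theta, 0.0, np.nextafter(90.0, 0.0))

    valid = mask if fov_mask is None else (mask & fov_mask)
    theta = np.where(valid, theta, 0.0)
    frac_steep = float(np.mean(theta[band] > 60.0)) if band.any() else 0.0
    if frac_steep > 0.05:
        log.warning(
            "%.0f%% of boundary angles exceed 60°: contour extraction may fail, "
            "expect under-correction",
            100 * frac_steep,
        )
    return AngleField(
        theta_i=theta,
        valid_mask=valid,
        source_slices=source_slices,
        filled_from_adjacent=filled,
        meta={"center_xy": center_xy, "band_fraction_steep": frac_steep},
    )


# ---------------------------------------------------------------------------
# gain and application
# ---------------------------------------------------------------------------
def _trans(theta_deg, interface: AcousticInterface, mode: str):
    if mode == "pressure":
        return transmission_coefficient(theta_deg, interface)
    return intensity_transmission(theta_deg, interface)


def angle_gain(theta_i_deg, interface: AcousticInterface, cfg: InclinationConfig | None = None):
    """Gain G(θi) = T(0)/max(T(θi), ε) clipped at G_max, and C = 20·log10 G (dB)."""
    cfg = cfg or InclinationConfig()
    T = np.asarray(_trans(theta_i_deg, interface, cfg.mode), dtype=np.float64)
    T0 = _trans(0.0, interface, cfg.mode)
    G = T0 / np.maximum(T, cfg.epsilon)
    G = np.minimum(G, cfg.g_max)
    C = 20.0 * np.log10(G)
    if np.ndim(theta_i_deg) == 0:
        return float(G), float(C)
    return G, C


def apply_inclination_correction(
    image: ImageSlice,
    angles: AngleField,
    interface: AcousticInterface,
    cfg: InclinationConfig | None = None,
    kappa: float | None = None,
) -> ImageSlice:
    """Apply the angle-dependent gain with strength κ.

    dB domain: I_corr = I + κ·C(θi); linear domain: I_corr = I·G(θi)^κ —
    identical by construction.  Pixels outside ``angles.valid_mask`` pass
    through unchanged.
    """
    cfg = cfg or InclinationConfig()
    if kappa is None:
        if isinstance(cfg.kappa, str):
            raise ValueError("kappa='auto' requires optimize_kappa or an explicit value")
        kappa = float(cfg.kappa)
    if angles.theta_i.shape != image.shape:
        raise ValueError("angle field geometry does not match the image")
    G, C = angle_gain(angles.theta_i, interface, cfg)
    out = image.copy()
    v = angles.valid_mask
    if image.domain == "db":
        out.pixels[v] = out.pixels[v] + kappa * C[v]
    else:
        out.pixels[v] = out.pixels[v] * np.power(G[v], kappa)
    out.meta = {**out.meta, "inclination_corrected": True, "kappa": kappa, "mode": cfg.mode}
    return out


def overflow_rate(
    image: ImageSlice,
    angles: AngleField,
    interface: AcousticInterface,
    cfg: InclinationConfig,
    kappa: float,
    window: tuple[float, float],
) -> float:
    """Fraction of in-mask pixels outside [lo, hi] after correction with κ."""
    lo, hi = window
    corr = apply_inclination_correction(image, angles, interface, cfg, kappa=kappa)
    m = angles.valid_mask & image.fov_mask
    if not m.any():
        return 0.0
    vals = corr.pixels[m]
    return float(np.mean((vals < lo) | (vals > hi)))


def optimize_kappa(
    slices: Sequence[tuple[ImageSlice, AngleField]],
    interface: AcousticInterface,
    cfg: InclinationConfig | None = None,
    kappa_grid: Sequence[float] | None = None,
) -> float:
    """Grid-search κ minimising the mean overflow rate over representative slices.

    The overflow window defaults to the 1st–99th percentile of the
    uncorrected in-mask intensities.  Ties break towards the smaller κ
    (κ = 0 is the identity, preferred when nothing overflows anyway).
    """
    cfg = cfg or InclinationConfig()
    grid = list(kappa_grid if kappa_grid is not None else cfg.kappa_grid)
    if not grid or any(k < 0 for k in grid):
        raise ValueError("kappa_grid must be non-empty with non-negative values")
    if cfg.window_lo is None or cfg.window_hi is None:
        pool = np.concatenate(
            [img.pixels[af.valid_mask & img.fov_mask] for img, af in slices]
        )
        lo, hi = np.percentile(pool, [1.0, 99.0])
    else:
        lo, hi = cfg.window_lo, cfg.window_hi
    best_k, best_rate = None, np.inf
    for k in sorted(grid):
        rate = float(
            np.mean(
                [overflow_rate(img, af, interface, cfg, k, (lo, hi)) for img, af in slices]
            )
        )
        if rate < best_rate - 1e-15:
            best_k, best_rate = k, rate
    return float(best_k)


# ---------------------------------------------------------------------------
# estimator / results facade
# ---------------------------------------------------------------------------
class InclinationModel:
    """Inclination-correction model over an image stack.

    Segments every slice, estimates per-slice incident-angle fields from the
    boundary displacement across the slices below each target (with an
    above-slice fallback near the stack bottom), and resolves κ.  ``fit``
    returns an :class:`InclinationResult`.
    """

    def __init__(
        self,
        stack: ImageStack,
        interface: AcousticInterface | None = None,
        config: InclinationConfig | None = None,
    ) -> None:
        if len(stack) < 2:
            raise ValueError("inclination estimation needs at least 2 slices")
        self.stack = stack.to_linear() if stack.domain == "db" else stack
        self.interface = interface or AcousticInterface()
        self.config = config or InclinationConfig()

    def _segment_all(self) -> list[np.ndarray | None]:
        masks: list[np.ndarray | None] = []
        for img in self.stack:
            try:
                masks.append(segment_foreground(img, self.config))
            except NoForegroundError:
                masks.append(None)
        return masks

    def fit(
        self, target_indices: Sequence[int] | None = None, kappa: float | str | None = None
    ) -> "InclinationResult":
        cfg = self.config if kappa is None else replace(self.config, kappa=kappa)
        depth = cfg.mip_depth
        n = len(self.stack)
        if target_indices is None:
            target_indices = list(range(n))
        masks = self._segment_all()
        fields: dict[int, AngleField] = {}
        for t in target_indices:
            mask = masks[t]
            if mask is None and t >= 1:
                mask = segment_foreground(mip_below(self.stack, t, depth), cfg)
            if mask is None:
                log.warning("slice %d: no foreground, skipped", t)
                continue
            if t >= 1:
                lower_idx = [k for k in range(t - 1, max(-1, t - 1 - depth), -1) if masks[k] is not None]
            else:
                # bottom slice: fall back to the slices above, flagged
                lower_idx = [k for k in range(1, min(n, 1 + depth)) if masks[k] is not None]
            lower = [masks[k] for k in lower_idx]
            if not lower:
                log.warning("slice %d: no usable adjacent boundaries, skipped", t)
                continue
            af = incident_angle_field(
                mask,
                slice_spacing=self.stack.slice_spacing,
                pixel_spacing=self.stack.pixel_spacing,
                lower_masks=lower,
                cfg=cfg,
                fov_mask=self.stack.fov_mask,
                source_slices=tuple(lower_idx),
            )
            if t < 1:
                af.filled_from_adjacent = True
            fields[t] = af
        if not fields:
            raise AngleEstimationError("no slice yielded a usable angle field")
        if isinstance(cfg.kappa, str):  # "auto"
            pairs = [(self.stack[t], fields[t]) for t in sorted(fields)]
            kappa_star = optimize_kappa(pairs, self.interface, cfg)
        else:
            kappa_star = float(cfg.kappa)
        return InclinationResult(self, fields, kappa_star, cfg)


class InclinationResult:
    """Fitted inclination correction: angle fields, κ, and application."""

    def __init__(
        self,
        model: InclinationModel,
        angle_fields: dict[int, AngleField],
        kappa: float,
        config: InclinationConfig,
    ) -> None:
        self.model = model
        self.angle_fields = angle_fields
        self.kappa_ = kappa
        self.config = config

    def apply(self, index: int | None = None):
        """Correct one slice, or the whole stack (slices without a field pass through)."""
        stack = self.model.stack
        if index is not None:
            return apply_inclination_correction(
                stack[index], self.angle_fields[index], self.model.interface, self.config, kappa=self.kappa_
            )
        out = stack.copy()
        for t, af in self.angle_fields.items():
            corr = apply_inclination_correction(
                stack[t], af, self.model.interface, self.config, kappa=self.kappa_
            )
            out.pixels[t] = corr.pixels
        out.meta = {**out.meta, "inclination_corrected": True, "kappa": self.kappa_}
        return out

    def median_angle(self, index: int) -> float:
        af = self.angle_fields[index]
        band = af.valid_mask & (af.theta_i > 0)
        return float(np.median(af.theta_i[band])) if band.any() else 0.0

    def summary(self) -> str:
        iface = self.model.interface
        lines = [
            "Inclination correction",
            "=" * 46,
            f"slices with angle field {len(self.angle_fields):>8d} / {len(self.model.stack)}",
            f"kappa                 {self.kappa_:>10.3g}",
            f"mode                  {self.config.mode:>10s}",
            f"epsilon / G_max       {self.config.epsilon:>6.3g} / {self.config.g_max:.3g}",
            f"c_i / c_t             {iface.incident.c:>6.0f} / {iface.transmit.c:.0f} m/s",
            f"z_i / z_t             {iface.incident.z/1e6:>6.3f} / {iface.transmit.z/1e6:.3f} MRayl",
            f"critical angle        {iface.critical_angle_deg if iface.critical_angle_deg else float('nan'):>10.2f} deg",
        ]
        for t in sorted(self.angle_fields):
            af = self.angle_fields[t]
            band = af.valid_mask & (af.theta_i > 0)
            med = np.median(af.theta_i[band]) if band.any() else 0.0
            lines.append(f"  slice {t:3d}: median boundary angle {med:6.2f} deg"
                         + ("  [filled from adjacent]" if af.filled_from_adjacent else ""))
        return "\n".join(lines)
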