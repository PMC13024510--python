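"""Image containers for ring-array echo tomography.

A reconstructed reflection-mode slice lives on a regular pixel grid whose
reference point is the centre of the transducer ring (the imaging circle),
*not* the centroid of the imaged object.  All radial quantities in this
package (sensitivity profiles, gain curves, uniformity metrics) are measured
from that centre.

Intensities are carried either in the linear amplitude domain or in dB
(20·log10 of amplitude, floored at :data:`DB_FLOOR`).  Corrections operate in
the linear domain; the containers provide lossless-enough conversion both ways.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

__all__ = ["ImageSlice", "ImageStack", "DB_FLOOR", "radial_distance_map"]

#: Floor used when converting linear amplitudes to dB, in dB.
DB_FLOOR = -80.0


def radial_distance_map(shape: tuple[int, int], center_xy: tuple[float, float]) -> np.ndarray:
    """Per-pixel Euclidean distance (in pixels) from ``center_xy``.

    ``center_xy`` is ``(x, y)`` = (column, row).  The value at the centre
    pixel is 0; a pixel offset by (3, 4) pixels is at distance 5.
    """
    cx, cy = center_xy
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    return np.hypot(xx - cx, yy - cy)


def _default_center(shape: tuple[int, int]) -> tuple[float, float]:
    h, w = shape
    return ((w - 1) / 2.0, (h - 1) / 2.0)


@dataclass
class ImageSlice:
    """A single echo-intensity slice.

    Parameters
    ----------
    pixels :
        2-D intensity grid.
    center_xy :
        Imaging-circle centre in pixel coordinates ``(x, y)``.  Defaults to
        the grid centre.
    pixel_spacing :
        Physical pixel size in mm/px.
    domain :
        ``"linear"`` (amplitude) or ``"db"``.
    fov_mask :
        Boolean grid of valid pixels.  Defaults to the circle inscribed in
        the grid around ``center_xy``.
    """

    pixels: np.ndarray
    center_xy: tuple[float, float] | None = None
    pixel_spacing: float = 1.0
    domain: str = "linear"
    fov_mask: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError("ImageSlice expects a 2-D pixel array")
        if self.center_xy is None:
            self.center_xy = _default_center(self.pixels.shape)
        self.center_xy = (float(self.center_xy[0]), float(self.center_xy[1]))
        self.pixel_spacing = float(self.pixel_spacing)
        if self.domain not in ("linear", "db"):
            raise ValueError(f"unknown intensity domain {self.domain!r}")
        if self.fov_mask is None:
            self.fov_mask = self.radius_map() <= self.fov_radius
        self.fov_mask = np.asarray(self.fov_mask, dtype=bool)
        if self.fov_mask.shape != self.pixels.shape:
            raise ValueError("fov_mask shape does not match pixels")
        inside = self.pixels[self.fov_mask]
        if inside.size and not np.all(np.isfinite(inside)):
            raise ValueError("non-finite intensities inside the field of view")
        if self.domain == "linear" and inside.size and inside.min() < 0:
            raise ValueError("linear-domain intensities must be non-negative")

    # -- geometry -----------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def fov_radius(self) -> float:
        """Nominal field-of-view radius: the inscribed-circle radius, px."""
        return (min(self.pixels.shape) - 1) / 2.0

    def radius_map(self) -> np.ndarray:
        return radial_distance_map(self.pixels.shape, self.center_xy)

    def same_geometry(self, other: "ImageSlice", tol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and abs(self.center_xy[0] - other.center_xy[0]) <= tol
            and abs(self.center_xy[1] - other.center_xy[1]) <= tol
            and abs(self.pixel_spacing - other.pixel_spacing) <= tol
        )

    # -- domain conversion --------------------------------------------------
    def to_db(self, floor: float = DB_FLOOR) -> "ImageSlice":
        if self.domain == "db":
            return self.copy()
        amp = np.maximum(self.pixels, 10.0 ** (floor / 20.0))
        out = self.copy()
        out.pixels = 20.0 * np.log10(amp)
        out.domain = "db"
        return out

    def to_linear(self) -> "ImageSlice":
        if self.domain == "linear":
            return self.copy()
        out = self.copy()
        out.pixels = 10.0 ** (self.pixels / 20.0)
        out.domain = "linear"
        return out

    def copy(self) -> "ImageSlice":
        return ImageSlice(
            self.pixels.copy(),
            center_xy=self.center_xy,
            pixel_spacing=self.pixel_spacing,
            domain=self.domain,
            fov_mask=self.fov_mask.copy(),
            meta=dict(self.meta),
        )


@dataclass
class ImageStack:
    """An ordered stack of slices sharing one in-plane geometry.

    Slice index 0 is the bottom (deepest) slice; the index increases towards
    the top of the scanned volume, matching a probe that scans top-to-bottom
    and a stacked-cone phantom whose radius shrinks with height.
    """

    pixels: np.ndarray
    center_xy: tuple[float, float] | None = None
    pixel_spacing: float = 1.0
    slice_spacing: float = 1.0
    domain: str = "linear"
    fov_mask: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 3:
            raise ValueError("ImageStack expects a 3-D (n, h, w) array")
        if self.center_xy is None:
            self.center_xy = _default_center(self.pixels.shape[1:])
        self.center_xy = (float(self.center_xy[0]), float(self.center_xy[1]))
        self.pixel_spacing = float(self.pixel_spacing)
        self.slice_spacing = float(self.slice_spacing)
        if self.slice_spacing <= 0:
            raise ValueError("slice_spacing must be positive")
        if self.domain not in ("linear", "db"):
            raise ValueError(f"unknown intensity domain {self.domain!r}")
        if self.fov_mask is None:
            r = radial_distance_map(self.pixels.shape[1:], self.center_xy)
            self.fov_mask = r <= self.fov_radius
        self.fov_mask = np.asarray(self.fov_mask, dtype=bool)

    def __len__(self) -> int:
        return self.pixels.shape[0]

    def __iter__(self) -> Iterator[ImageSlice]:
        for k in range(len(self)):
            yield self[k]

    def __getitem__(self, k: int) -> ImageSlice:
        return ImageSlice(
            self.pixels[k].copy(),
            center_xy=self.center_xy,
            pixel_spacing=self.pixel_spacing,
            domain=self.domain,
            fov_mask=self.fov_mask.copy(),
            meta={**self.meta, "slice_index": k},
        )

    @property
    def fov_radius(self) -> float:
        return (min(self.pixels.shape[1:]) - 1) / 2.0

    def radius_map(self) -> np.ndarray:
        return radial_distance_map(self.pixels.shape[1:], self.center_xy)

    def to_db(self, floor: float = DB_FLOOR) -> "ImageStack":
        if self.domain == "db":
            return self.copy()
        out = self.copy()
        out.pixels = 20.0 * np.log10(np.maximum(self.pixels, 10.0 ** (floor / 20.0)))
        out.domain = "db"
        return out

    def to_linear(self) -> "ImageStack":
        if self.domain == "linear":
            return self.copy()
        out = self.copy()
        out.pixels = 10.0 ** (self.pixels / 20.0)
        out.domain = "linear"
        return out

    def copy(self) -> "ImageStack":
        return ImageStack(
            self.pixels.copy(),
            center_xy=self.center_xy,
            pixel_spacing=self.pixel_spacing,
            slice_spacing=self.slice_spacing,
            domain=self.domain,
            fov_mask=self.fov_mask.copy(),
            meta=dict(self.meta),
        )
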