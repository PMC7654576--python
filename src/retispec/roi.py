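"""Anatomical ROI placement, ROI spectra, and feature assembly.

Four rectangular regions of interest (S1, S2, I1, I2) are placed
relative to the line through the optic-disc (OD) center and the fovea,
so that sampling locations are comparable across subjects:

* the image frame is rotated so the OD->fovea direction is the +u axis
  (left eyes are mirrored first, so "superior" always means the same
  anatomical side);
* every ROI is 40 px tall and ``round(0.35 * D)`` px wide, with D the
  OD-fovea distance — widths scale with D precisely so the rectangles
  can never overlap;
* all four ROIs are horizontally centered above/below the midpoint of
  the OD-fovea segment; the near edges of S1/I1 sit 0.35*D from the
  axis and those of S2/I2 sit 0.85*D (superior ROIs above the axis,
  inferior below).

Per-ROI spectra are the means of all non-vessel pixels falling in the
rectangle.  Standardization drops the two edge bands (nearest 465 and
615 nm, the noisiest filters on a mosaic sensor) and divides the
remaining 14 values by their own mean, yielding a scale-free 14-vector;
the optional retinal-nerve-fiber-layer (RNFL) block appends the five
thickness values for the 19-feature configurations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import HyperspectralCube, VesselMask

__all__ = [
    "Landmarks",
    "ROIRect",
    "ROISet",
    "ROISpectrum",
    "FeatureVector",
    "GeometryError",
    "LandmarkError",
    "EmptyROIError",
    "StandardizationError",
    "AssemblyError",
    "ROI_IDS",
    "CONFIGS",
    "place_rois",
    "roi_pixel_mask",
    "mean_roi_spectrum",
    "standardize_spectrum",
    "assemble_features",
]

ROI_IDS = ("S1", "S2", "I1", "I2")

#: Candidate classifier input configurations, in canonical order.
CONFIGS = ("S1", "I2", "S1+RNFL", "I2+RNFL")


class GeometryError(ValueError):
    """An ROI does not fit inside the image."""


class LandmarkError(ValueError):
    """Degenerate or out-of-bounds landmarks."""


class EmptyROIError(ValueError):
    """An ROI has no usable (non-vessel) pixel."""


class StandardizationError(ValueError):
    """Spectrum cannot be standardized (non-positive values)."""


class AssemblyError(ValueError):
    """Feature vector parts inconsistent with the configuration."""


@dataclass(frozen=True)
class Landmarks:
    od_center: tuple[float, float]  # (x, y), px
    fovea: tuple[float, float]
    eye: str  # "right" | "left"

    def __post_init__(self) -> None:
        if self.eye not in ("right", "left"):
            raise LandmarkError(f"eye must be 'right' or 'left', got {self.eye!r}")
        if tuple(self.od_center) == tuple(self.fovea):
            raise LandmarkError("OD center and fovea coincide")


@dataclass(frozen=True)
class ROIRect:
    """Axis-aligned rectangle in the rotated (u, v) frame, half-open."""

    roi_id: str
    u_min: float
    v_min: float
    width: int
    height: int

    def contains(self, u: np.ndarray, v: np.ndarray) -> np.ndarray:
        # Raster rule: a pixel belongs to the ROI when the floor of its
        # transformed coordinate falls in the half-open integer range.
        iu = np.floor(u).astype(int)
        iv = np.floor(v).astype(int)
        u0 = int(np.floor(self.u_min))
        v0 = int(np.floor(self.v_min))
        return (
            (iu >= u0) & (iu < u0 + self.width) & (iv >= v0) & (iv < v0 + self.height)
        )


@dataclass(frozen=True)
class ROISet:
    """The four placed ROIs plus the image->ROI-frame transform."""

    rois: tuple[ROIRect, ...]
    od_center: tuple[float, float]  # mirrored coords if left eye
    angle: float  # radians of OD->fovea axis in mirrored frame
    mirrored: bool
    image_width: int
    distance: float

    def transform(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map image pixel coordinates (x, y) to the rotated (u, v) frame."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if self.mirrored:
            x = (self.image_width - 1) - x
        dx = x - self.od_center[0]
        dy = y - self.od_center[1]
        ca, sa = np.cos(self.angle), np.sin(self.angle)
        return ca * dx + sa * dy, -sa * dx + ca * dy

    def __getitem__(self, roi_id: str) -> ROIRect:
        for r in self.rois:
            if r.roi_id == roi_id:
                return r
        raise KeyError(roi_id)


@dataclass
class ROISpectrum:
    roi_id: str
    mean_reflectance: np.ndarray  # 16 values
    n_pixels_used: int


@dataclass
class FeatureVector:
    config_id: str
    values: np.ndarray  # 14 or 19


def place_rois(
    landmarks: Landmarks,
    image_shape: tuple[int, int],
    *,
    roi_height: int = 40,
    width_frac: float = 0.35,
    near_offset_frac: float = 0.35,
    far_offset_frac: float = 0.85,
) -> ROISet:
    """Place S1, S2, I1, I2 relative to the OD-fovea axis.

    Raises :class:`GeometryError` if any ROI corner falls outside the
    image and :class:`LandmarkError` for coincident landmarks.
    """
    h_img, w_img = image_shape[:2]
    ox, oy = landmarks.od_center
    fx, fy = landmarks.fovea
    if landmarks.eye == "left":
        ox = (w_img - 1) - ox
        fx = (w_img - 1) - fx
    d = float(np.hypot(fx - ox, fy - oy))
    if d == 0.0:
        raise LandmarkError("OD-fovea distance is zero")
    angle = float(np.arctan2(fy - oy, fx - ox))

    width = int(round(width_frac * d))
    u_mid = d / 2.0
    u_min = u_mid - width / 2.0
    near, far = near_offset_frac * d, far_offset_frac * d
    # v is positive toward the inferior retina (image-down after mirroring)
    rois = (
        ROIRect("S1", u_min, -near - roi_height, width, roi_height),
        ROIRect("S2", u_min, -far - roi_height, width, roi_height),
        ROIRect("I1", u_min, near, width, roi_height),
        ROIRect("I2", u_min, far, width, roi_height),
    )
    roi_set = ROISet(
        rois=rois,
        od_center=(ox, oy),
        angle=angle,
        mirrored=landmarks.eye == "left",
        image_width=w_img,
        distance=d,
    )

    # Every ROI corner, mapped back to image coordinates, must be in-frame.
    ca, sa = np.cos(angle), np.sin(angle)
    for roi in rois:
        for u in (roi.u_min, roi.u_min + roi.width):
            for v in (roi.v_min, roi.v_min + roi.height):
                x = ox + ca * u - sa * v
                y = oy + sa * u + ca * v
                if roi_set.mirrored:
                    x = (w_img - 1) - x
                if not (0 <= x <= w_img - 1 and 0 <= y <= h_img - 1):
                    raise GeometryError(
                        f"ROI {roi.roi_id} exits the image at ({x:.1f}, {y:.1f})"
                    )
    return roi_set


def roi_pixel_mask(
    roi_set: ROISet, roi_id: str, image_shape: tuple[int, int]
) -> np.ndarray:
    """Boolean H x W mask of pixels belonging to one ROI."""
    h, w = image_shape[:2]
    yy, xx = np.mgrid[0:h, 0:w]
    u, v = roi_set.transform(xx, yy)
    return roi_set[roi_id].contains(u, v)


def mean_roi_spectrum(
    cube: HyperspectralCube,
    roi_set: ROISet,
    roi_id: str,
    vessels: VesselMask | None = None,
) -> ROISpectrum:
    """Average the spectra of all non-vessel pixels inside one ROI."""
    h, w, _ = cube.shape
    sel = roi_pixel_mask(roi_set, roi_id, (h, w))
    if vessels is not None:
        sel &= ~vessels.mask
    n = int(sel.sum())
    if n == 0:
        raise EmptyROIError(f"ROI {roi_id} has no usable pixel")
    return ROISpectrum(
        roi_id=roi_id,
        mean_reflectance=cube.values[sel].mean(axis=0),
        n_pixels_used=n,
    )


def standardize_spectrum(
    mean_reflectance: np.ndarray, drop_bands: tuple[int, int] = (0, 15)
) -> np.ndarray:
    """16-band ROI mean spectrum -> scale-free 14-vector.

    Drops the two edge bands, then divides by the mean of the remaining
    values, so ``standardize(c * x) == standardize(x)`` for any c > 0.
    """
    s = np.asarray(mean_reflectance, dtype=float)
    if s.shape != (16,):
        raise StandardizationError(f"expected 16 bands, got shape {s.shape}")
    if np.any(s <= 0):
        raise StandardizationError("spectrum has non-positive values")
    kept = np.delete(s, list(drop_bands))
    return kept / kept.mean()


def assemble_features(
    spec14: np.ndarray,
    rnfl: np.ndarray | None,
    config_id: str,
) -> FeatureVector:
    """Concatenate the standardized spectrum with the optional RNFL block.

    Order: 14 spectral values in ascending wavelength, then
    (RNFL_AVG, SUP, NAS, INF, TEM) for the ``+RNFL`` configurations.
    """
    spec14 = np.asarray(spec14, dtype=float)
    if spec14.shape != (14,):
        raise AssemblyError(f"expected 14 spectral features, got {spec14.shape}")
    wants_rnfl = config_id.endswith("+RNFL")
    if wants_rnfl:
        if rnfl is None:
            raise AssemblyError(f"config {config_id} requires RNFL features")
        rnfl = np.asarray(rnfl, dtype=float)
        if rnfl.shape != (5,):
            raise AssemblyError(f"expected 5 RNFL features, got {rnfl.shape}")
        values = np.concatenate([spec14, rnfl])
    else:
        if rnfl is not None:
            raise AssemblyError(f"config {config_id} does not take RNFL features")
        values = spec14
    return FeatureVector(config_id=config_id, values=values)
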