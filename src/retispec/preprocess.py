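"""Raw mosaic frames -> relative-reflectance cubes -> vessel masks.

Three preprocessing stages sit between the snapshot sensor and the ROI
analysis:

1. **Demosaicing** — pure reorganisation of the raw frame: band ``b`` of
   hyperspectral pixel ``(y, x)`` is raw pixel ``(4y + r, 4x + c)`` where
   ``(r, c)`` is the filter position of ``b`` in the 4x4 block.  No
   interpolation, so :func:`demosaic` and :func:`mosaic` are exact
   inverses.
2. **Flat-field calibration** — digital numbers to relative reflectance
   via the dark level and a per-band white reference,
   ``R = (DN - dark) / (white - dark)``, clipped below at 0 because read
   noise makes small negatives inevitable.
3. **Vessel masking** — retinal blood vessels are dark, tubular
   structures in the hemoglobin absorption bands (540-580 nm); they are
   detected on an illumination-normalised hemoglobin-contrast image with
   a multiscale ridge filter, a fixed-quantile threshold and a minimum
   component size, and excluded from all spectral averaging.

The capture protocol maximises flash intensity while avoiding
saturation outside the optic nerve head; :func:`check_saturation`
enforces that rule as a QC gate.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter
import scipy.ndimage as ndi
from skimage.filters import sato

from .synthetic import CameraModel, ShapeError

__all__ = [
    "HyperspectralCube",
    "VesselMask",
    "QCReport",
    "CalibrationError",
    "demosaic",
    "mosaic",
    "to_relative_reflectance",
    "check_saturation",
    "segment_vessels",
    "write_envi_cube",
    "read_envi_cube",
]


class CalibrationError(ValueError):
    """Raised when the dark/white calibration is unusable."""


@dataclass
class HyperspectralCube:
    """An ``(H, W, 16)`` relative-reflectance cube with band centers in nm."""

    values: np.ndarray
    band_centers: np.ndarray
    subject_ref: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 3:
            raise ShapeError("cube values must be H x W x B")
        if not np.all(np.isfinite(v)):
            raise ValueError("cube contains non-finite values")
        if v.min() < 0:
            raise ValueError("relative reflectance must be non-negative")
        self.values = v
        self.band_centers = np.asarray(self.band_centers, dtype=float)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape


@dataclass
class VesselMask:
    """Boolean vessel map; ``True`` pixels are excluded from analysis."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ShapeError("vessel mask must be 2-D")


@dataclass
class QCReport:
    saturated_fraction_outside_onh: float
    usable: bool


def demosaic(raw: np.ndarray, camera: CameraModel) -> np.ndarray:
    """Reorganise a raw mosaic frame into an ``(H, W, 16)`` DN cube."""
    raw = np.asarray(raw)
    if raw.ndim != 2 or raw.shape[0] % 4 or raw.shape[1] % 4:
        raise ShapeError(f"raw frame shape {raw.shape} is not a 2-D multiple of 4")
    h, w = raw.shape[0] // 4, raw.shape[1] // 4
    cube = np.empty((h, w, 16), dtype=float)
    for b in range(16):
        r, c = camera.mosaic_offset(b)
        cube[:, :, b] = raw[r::4, c::4]
    return cube


def mosaic(cube: np.ndarray, camera: CameraModel) -> np.ndarray:
    """Inverse of :func:`demosaic`: interleave a cube back into a raw frame."""
    cube = np.asarray(cube)
    if cube.ndim != 3 or cube.shape[2] != 16:
        raise ShapeError("cube must be H x W x 16")
    h, w = cube.shape[:2]
    raw = np.empty((4 * h, 4 * w), dtype=cube.dtype)
    for b in range(16):
        r, c = camera.mosaic_offset(b)
        raw[r::4, c::4] = cube[:, :, b]
    return raw


def to_relative_reflectance(
    dn_cube: np.ndarray, camera: CameraModel, subject_ref: str = ""
) -> HyperspectralCube:
    """Flat-field DN values into relative reflectance.

    ``R = (DN - dark) / (white - dark)`` per band, clipped below at 0.
    """
    white = camera.white_reference
    if np.any(white <= camera.dark_level):
        raise CalibrationError("white reference must exceed dark level in every band")
    dn = np.asarray(dn_cube, dtype=float)
    refl = (dn - camera.dark_level) / (white - camera.dark_level)[None, None, :]
    return HyperspectralCube(
        values=np.clip(refl, 0.0, None),
        band_centers=camera.band_centers.copy(),
        subject_ref=subject_ref,
    )


def check_saturation(
    raw: np.ndarray,
    onh_center: tuple[float, float],
    onh_radius: float,
    camera: CameraModel,
    threshold: float = 0.001,
) -> QCReport:
    """Flag frames saturated outside the optic nerve head (ONH).

    ``onh_center`` is (x, y) in raw-frame coordinates; pixels within
    ``onh_radius`` of it are exempt (the bright disc is allowed to
    saturate).  The frame is usable when the saturated fraction of the
    remaining pixels is at most ``threshold``.
    """
    raw = np.asarray(raw)
    yy, xx = np.mgrid[0 : raw.shape[0], 0 : raw.shape[1]]
    outside = np.hypot(xx - onh_center[0], yy - onh_center[1]) > onh_radius
    n_outside = int(outside.sum())
    if n_outside == 0:
        frac = 0.0
    else:
        frac = float((raw[outside] >= camera.saturation_dn).sum() / n_outside)
    return QCReport(saturated_fraction_outside_onh=frac, usable=frac <= threshold)


def segment_vessels(
    cube: HyperspectralCube,
    *,
    hb_band_range: tuple[float, float] = (540.0, 580.0),
    illumination_sigma: float = 25.0,
    ridge_sigmas: tuple[float, ...] = (1.0, 1.5, 2.0, 3.0),
    response_quantile: float = 0.90,
    response_floor: float = 1e-4,
    min_component_px: int = 50,
) -> VesselMask:
    """Detect retinal blood vessels on the hemoglobin-contrast image.

    Pipeline: (1) average the bands whose centers fall in
    ``hb_band_range`` — hemoglobin absorbs strongly there, so vessels
    are dark; (2) divide by a Gaussian illumination estimate
    (``illumination_sigma`` px), which removes the slowly varying fundus
    background and makes the detector invariant to global intensity
    scaling; (3) apply a multiscale Sato ridge filter for dark tubular
    structures; (4) keep pixels above the ``response_quantile`` quantile
    of the response (and above a small absolute floor in normalised
    units, so a structure-free image yields an empty mask); (5) drop
    connected components smaller than ``min_component_px``.
    """
    bc = cube.band_centers
    sel = (bc >= hb_band_range[0]) & (bc <= hb_band_range[1])
    if not sel.any():
        raise ValueError("no bands inside the hemoglobin range")
    hb = cube.values[:, :, sel].mean(axis=2)

    illum = gaussian_filter(hb, sigma=illumination_sigma)
    illum = np.where(illum <= 0, illum.max() if illum.max() > 0 else 1.0, illum)
    norm = hb / illum  # ~1 on background, <1 on vessels; scale-free

    response = sato(norm, sigmas=ridge_sigmas, black_ridges=True, mode="reflect")
    thr = max(float(np.quantile(response, response_quantile)), response_floor)
    mask = response > thr
    # drop connected components below the minimum area
    labelled, n_comp = ndi.label(mask)
    if n_comp:
        sizes = np.bincount(labelled.ravel())
        small = np.flatnonzero(sizes < min_component_px)
        mask &= ~np.isin(labelled, small[small > 0])
    return VesselMask(mask=mask)


# ---------------------------------------------------------------------------
# ENVI-style cube I/O (header text file + band-sequential binary)
# ---------------------------------------------------------------------------

_ENVI_DTYPES = {4: np.float32, 5: np.float64, 12: np.uint16}
_ENVI_CODES = {np.dtype(np.float32): 4, np.dtype(np.float64): 5, np.dtype(np.uint16): 12}


def write_envi_cube(path, cube: HyperspectralCube, dtype=np.float32) -> None:
    """Write ``path``.hdr / ``path``.img as an ENVI BSQ cube with wavelengths."""
    path = Path(path)
    h, w, nb = cube.shape
    dtype = np.dtype(dtype)
    wavelengths = ", ".join(f"{v:.1f}" for v in cube.band_centers)
    hdr = (
        "ENVI\n"
        f"description = {{retispec cube {cube.subject_ref}}}\n"
        f"samples = {w}\nlines = {h}\nbands = {nb}\n"
        "header offset = 0\nfile type = ENVI Standard\n"
        f"data type = {_ENVI_CODES[dtype]}\ninterleave = bsq\nbyte order = 0\n"
        "wavelength units = nm\n"
        f"wavelength = {{{wavelengths}}}\n"
    )
    path.with_suffix(".hdr").write_text(hdr)
    bsq = np.ascontiguousarray(np.moveaxis(cube.values, 2, 0)).astype(dtype)
    bsq.tofile(path.with_suffix(".img"))


def read_envi_cube(path) -> HyperspectralCube:
    """Read a cube written by :func:`write_envi_cube`."""
    path = Path(path)
    text = path.with_suffix(".hdr").read_text()

    def _key(name, cast=int):
        m = re.search(rf"^{name}\s*=\s*(\S+)", text, flags=re.M)
        if m is None:
            raise ValueError(f"missing ENVI header key: {name}")
        return cast(m.group(1))

    h, w, nb = _key("lines"), _key("samples"), _key("bands")
    dtype = _ENVI_DTYPES[_key("data type")]
    if _key("interleave", str).lower() != "bsq":
        raise ValueError("only BSQ interleave is supported")
    m = re.search(r"wavelength\s*=\s*\{([^}]*)\}", text)
    bands = np.array([float(v) for v in m.group(1).split(",")]) if m else np.arange(nb)
    m = re.search(r"description\s*=\s*\{retispec cube\s*([^}]*)\}", text)
    ref = m.group(1).strip() if m else ""
    bsq = np.fromfile(path.with_suffix(".img"), dtype=dtype).reshape(nb, h, w)
    return HyperspectralCube(
        values=np.moveaxis(bsq, 0, 2).astype(float), band_centers=bands, subject_ref=ref
    )
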