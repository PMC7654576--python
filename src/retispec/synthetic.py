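"""Synthetic cohorts, retinal phantoms and raw snapshot-mosaic frames.

This module generates ground-truthed stand-ins for a bimodal retinal
imaging study of Alzheimer's disease (AD) versus cognitively intact
controls:

* a *cohort* of subjects with demographics, clinical covariates and
  peripapillary retinal nerve fiber layer (RNFL) thickness values drawn
  from group-specific distributions;
* a *retinal phantom* per subject: a smooth hyperspectral reflectance
  field (16 bands, 460-620 nm) with optic-disc / fovea landmarks and a
  vessel tree with hemoglobin-like absorption. AD retinas carry a
  short-wavelength reflectance deficit following a Rayleigh-scattering
  (lambda^-4) law, scaled by a latent amyloid load;
* a *raw mosaic frame*: the 16-band cube re-imaged through a 4x4
  spectral-filter-on-CMOS snapshot sensor model (1088x2048 raw pixels
  for a 272x512x16 cube), with dark level, per-band white reference,
  read noise and saturation clipping.

Everything is deterministic given the seeds carried in the inputs, so
every downstream stage of the analysis can be scored against ground
truth.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.draw import line as draw_line
from skimage.morphology import dilation, disk

__all__ = [
    "BAND_CENTERS",
    "CameraModel",
    "CohortSpec",
    "SubjectRecord",
    "RetinalPhantom",
    "ParameterError",
    "ShapeError",
    "generate_cohort",
    "generate_phantom",
    "render_raw_mosaic",
    "cohort_to_frame",
    "DEFAULT_DEMOGRAPHICS",
    "DEFAULT_RNFL_AD",
    "DEFAULT_RNFL_CTRL",
    "RNFL_PARAMS",
]


class ParameterError(ValueError):
    """Raised for invalid generator parameters."""


class ShapeError(ValueError):
    """Raised for incompatible array dimensions."""


#: Band centers of the snapshot sensor: sixteen 10-nm bands spanning
#: 460-620 nm, i.e. centers at 465, 475, ..., 615 nm.
BAND_CENTERS: np.ndarray = 465.0 + 10.0 * np.arange(16)

#: RNFL parameters: 360-degree average plus the four OCT quadrants.
RNFL_PARAMS = ("AVG", "SUP", "INF", "TEM", "NAS")

#: Group means (mu m) for RNFL thickness, AD and control.
DEFAULT_RNFL_AD = {"AVG": 84.8, "SUP": 104.2, "INF": 104.3, "TEM": 63.3, "NAS": 66.3}
DEFAULT_RNFL_CTRL = {"AVG": 92.1, "SUP": 109.8, "INF": 115.6, "TEM": 70.4, "NAS": 72.7}
DEFAULT_RNFL_AD_SDS = {"AVG": 7.5, "SUP": 8.9, "INF": 11.1, "TEM": 8.1, "NAS": 11.7}
DEFAULT_RNFL_CTRL_SDS = {"AVG": 7.3, "SUP": 12.4, "INF": 11.4, "TEM": 6.7, "NAS": 8.6}

#: Demographic / clinical covariates per group.  Continuous variables
#: are (mean, sd); binary variables are the probability of the first
#: level.  scan_quality is a device-style OCT signal-strength index
#: (unitless); AD scans average slightly lower, reflecting the harder
#: imaging conditions in a dementia cohort.
DEFAULT_DEMOGRAPHICS = {
    "age": {"AD": (71.9, 6.6), "CTRL": (68.6, 8.4)},
    "bmi": {"AD": (24.9, 2.9), "CTRL": (26.0, 4.4)},
    "mmse": {"AD": (17.6, 5.5), "CTRL": (29.3, 0.9)},
    "bcva": {"AD": (0.14, 0.11), "CTRL": (0.06, 0.08)},
    "iop": {"AD": (14.0, 3.0), "CTRL": (15.0, 4.0)},
    "vcdr": {"AD": (0.52, 0.15), "CTRL": (0.51, 0.21)},
    "scan_quality": {"AD": (55.0, 10.0), "CTRL": (62.0, 10.0)},
    "p_male": {"AD": 7 / 17, "CTRL": 12 / 21},
    "p_right_eye": {"AD": 10 / 17, "CTRL": 10 / 22},
    "p_phakic": {"AD": 15 / 17, "CTRL": 12 / 22},
}


def _default_white_reference() -> np.ndarray:
    # Per-band white-target response: rises toward the red end, as the
    # combined source/filter/CMOS sensitivity does for this band range.
    return 38000.0 + 900.0 * np.arange(16)


@dataclass(frozen=True)
class CameraModel:
    """Model of the 4x4 mosaic snapshot sensor.

    Each 4x4 block of raw sensor pixels carries the 16 spectral filters;
    band ``b`` sits at ``(b // 4, b % 4)`` inside its block.  A raw frame
    of ``(4H, 4W)`` pixels therefore demosaics (by reorganisation, no
    interpolation) into an ``(H, W, 16)`` cube.
    """

    band_centers: np.ndarray = field(default_factory=lambda: BAND_CENTERS.copy())
    dark_level: float = 64.0
    white_reference: np.ndarray = field(default_factory=_default_white_reference)
    read_noise_sd: float = 20.0
    saturation_dn: int = 65535

    def __post_init__(self) -> None:
        bc = np.asarray(self.band_centers, dtype=float)
        if bc.shape != (16,):
            raise ParameterError("band_centers must hold 16 wavelengths")
        if not np.all(np.diff(bc) > 0):
            raise ParameterError("band_centers must be strictly increasing")
        if bc[0] < 460.0 or bc[-1] > 620.0:
            raise ParameterError("band_centers must lie within [460, 620] nm")
        wr = np.asarray(self.white_reference, dtype=float)
        if wr.shape != (16,):
            raise ParameterError("white_reference must hold 16 values")
        object.__setattr__(self, "band_centers", bc)
        object.__setattr__(self, "white_reference", wr)

    @staticmethod
    def mosaic_offset(b: int) -> tuple[int, int]:
        """(row, col) of band ``b`` inside each 4x4 super-pixel."""
        if not 0 <= b < 16:
            raise ParameterError(f"band index {b} outside 0..15")
        return b // 4, b % 4


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a simulated AD-vs-control cohort.

    ``scatter_amplitude`` scales the hypothesised amyloid-driven
    Rayleigh-scattering reflectance deficit; 0 disables the group
    difference in the spectra entirely.
    """

    n_ad: int = 17
    n_ctrl: int = 22
    seed: int = 0
    scatter_amplitude: float = 0.1
    rnfl_ad_means: dict = field(default_factory=lambda: dict(DEFAULT_RNFL_AD))
    rnfl_ctrl_means: dict = field(default_factory=lambda: dict(DEFAULT_RNFL_CTRL))
    rnfl_ad_sds: dict = field(default_factory=lambda: dict(DEFAULT_RNFL_AD_SDS))
    rnfl_ctrl_sds: dict = field(default_factory=lambda: dict(DEFAULT_RNFL_CTRL_SDS))
    demographic_params: dict = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_DEMOGRAPHICS.items()}
    )
    amyloid_sigma: float = 0.25
    pixel_noise_sd: float = 0.02

    def __post_init__(self) -> None:
        if self.n_ad < 2 or self.n_ctrl < 2:
            raise ParameterError("need at least 2 subjects per group")
        if not 0.0 <= self.scatter_amplitude <= 1.0:
            raise ParameterError("scatter_amplitude must lie in [0, 1]")
        for d in (self.rnfl_ad_sds, self.rnfl_ctrl_sds):
            if any(s < 0 for s in d.values()):
                raise ParameterError("RNFL SDs must be non-negative")
        if self.pixel_noise_sd < 0:
            raise ParameterError("pixel_noise_sd must be non-negative")


@dataclass
class SubjectRecord:
    """One simulated study participant (one study eye)."""

    subject_id: str
    group: str  # "AD" or "CTRL"
    age: float
    sex: str  # "M" or "F"
    eye: str  # "right" or "left"
    bmi: float
    mmse: int
    bcva: float  # logMAR
    iop: float  # mmHg
    phakic: bool
    vcdr: float
    rnfl_avg: float
    rnfl_sup: float
    rnfl_inf: float
    rnfl_tem: float
    rnfl_nas: float
    scan_quality: float
    amyloid_load: float  # latent; 0 for controls

    def rnfl_vector(self) -> np.ndarray:
        """RNFL features in canonical order (AVG, SUP, NAS, INF, TEM)."""
        return np.array(
            [self.rnfl_avg, self.rnfl_sup, self.rnfl_nas, self.rnfl_inf, self.rnfl_tem]
        )


@dataclass
class RetinalPhantom:
    """Ground-truth hyperspectral retina for one subject.

    ``base_reflectance`` is the noiseless-optics relative reflectance
    (vessel and AD effects applied, pixel noise included when
    configured); ``vessel_truth`` is the rasterised vessel tree.
    Landmark coordinates are (x, y) with origin at the top-left pixel.
    """

    height: int
    width: int
    od_center: tuple[float, float]
    fovea: tuple[float, float]
    vessel_truth: np.ndarray
    base_reflectance: np.ndarray
    subject_ref: str


def _draw_clipped_normal(rng, mean, sd, n, lo=-np.inf, hi=np.inf):
    return np.clip(rng.normal(mean, sd, size=n), lo, hi)


def generate_cohort(spec: CohortSpec) -> list[SubjectRecord]:
    """Draw a deterministic cohort of :class:`SubjectRecord` from ``spec``.

    Continuous covariates come from group-specific normals clipped to
    their legal ranges, binary covariates from group proportions, and
    RNFL values from the group means/SDs.  The latent amyloid load is
    log-normal for AD subjects and exactly 0 for controls.
    """
    rng = np.random.default_rng(spec.seed)
    records: list[SubjectRecord] = []
    for group, n in (("AD", spec.n_ad), ("CTRL", spec.n_ctrl)):
        dp = spec.demographic_params
        age = _draw_clipped_normal(rng, *dp["age"][group], n, 40.0, 100.0)
        bmi = _draw_clipped_normal(rng, *dp["bmi"][group], n, 12.0, 60.0)
        mmse = np.clip(np.rint(rng.normal(*dp["mmse"][group], size=n)), 0, 30)
        bcva = _draw_clipped_normal(rng, *dp["bcva"][group], n, -0.3, 3.0)
        iop = _draw_clipped_normal(rng, *dp["iop"][group], n, 5.0, 60.0)
        vcdr = _draw_clipped_normal(rng, *dp["vcdr"][group], n, 0.02, 0.98)
        quality = _draw_clipped_normal(rng, *dp["scan_quality"][group], n, 15.0, 95.0)
        male = rng.random(n) < dp["p_male"][group]
        right = rng.random(n) < dp["p_right_eye"][group]
        phakic = rng.random(n) < dp["p_phakic"][group]
        means = spec.rnfl_ad_means if group == "AD" else spec.rnfl_ctrl_means
        sds = spec.rnfl_ad_sds if group == "AD" else spec.rnfl_ctrl_sds
        rnfl = {
            p: _draw_clipped_normal(rng, means[p], sds[p], n, 1.0, 250.0)
            for p in RNFL_PARAMS
        }
        if group == "AD":
            load = rng.lognormal(0.0, spec.amyloid_sigma, size=n) if spec.amyloid_sigma > 0 else np.ones(n)
        else:
            load = np.zeros(n)
        for i in range(n):
            records.append(
                SubjectRecord(
                    subject_id=f"{group}{i + 1:03d}",
                    group=group,
                    age=float(age[i]),
                    sex="M" if male[i] else "F",
                    eye="right" if right[i] else "left",
                    bmi=float(bmi[i]),
                    mmse=int(mmse[i]),
                    bcva=float(bcva[i]),
                    iop=float(iop[i]),
                    phakic=bool(phakic[i]),
                    vcdr=float(vcdr[i]),
                    rnfl_avg=float(rnfl["AVG"][i]),
                    rnfl_sup=float(rnfl["SUP"][i]),
                    rnfl_inf=float(rnfl["INF"][i]),
                    rnfl_tem=float(rnfl["TEM"][i]),
                    rnfl_nas=float(rnfl["NAS"][i]),
                    scan_quality=float(quality[i]),
                    amyloid_load=float(load[i]),
                )
            )
    return records


def cohort_to_frame(records: list[SubjectRecord]):
    """Cohort as a pandas DataFrame (one row per subject)."""
    import pandas as pd

    return pd.DataFrame([dataclasses.asdict(r) for r in records])


# ---------------------------------------------------------------------------
# Phantom generation
# ---------------------------------------------------------------------------

def _base_spectrum(band_centers: np.ndarray) -> np.ndarray:
    # Fundus reflectance rises with wavelength over 460-620 nm (the
    # retina looks red); a smooth monotone curve is sufficient here.
    t = (band_centers - 460.0) / 160.0
    return 0.18 + 0.42 * t**1.2


def _hemoglobin_bump(band_centers: np.ndarray) -> np.ndarray:
    # Relative absorption profile for vessel pixels: a Gaussian bump
    # centred at 560 nm (oxy-hemoglobin alpha/beta band region), so the
    # dip is concentrated in the 540-580 nm bands.
    return np.exp(-0.5 * ((band_centers - 560.0) / 22.0) ** 2)


def rayleigh_attenuation(load: float, amplitude: float, band_centers: np.ndarray) -> np.ndarray:
    """Per-band attenuation factor ``1 - a * load * (460/lambda)^4``.

    Models the hypothesised effect of soluble amyloid-beta aggregates:
    extra Rayleigh scattering removes proportionally more light at short
    wavelengths, so attenuation is maximal below 550 nm and fades with
    wavelength.  Clipped below at 0.05 so reflectance stays positive.
    """
    return np.clip(1.0 - amplitude * load * (460.0 / band_centers) ** 4, 0.05, 1.0)


def _vessel_tree(rng, height, width, od_xy):
    """Rasterise an arcade-like vessel tree rooted at the optic disc."""
    scale = min(height, width) / 272.0
    mask = np.zeros((height, width), dtype=bool)
    n_vessels = 12
    diag = float(np.hypot(height, width))
    for k in range(n_vessels):
        # Quadratic Bezier from the disc out past the image border, with
        # a curved control point so major vessels arc around the macula.
        ang = rng.uniform(0.0, 2.0 * np.pi)
        bend = rng.uniform(-0.9, 0.9)
        p0 = np.array(od_xy, dtype=float)
        p1 = p0 + 0.45 * diag * np.array([np.cos(ang + bend), np.sin(ang + bend)])
        p2 = p0 + 1.1 * diag * np.array([np.cos(ang), np.sin(ang)])
        t = np.linspace(0.0, 1.0, 160)[:, None]
        pts = (1 - t) ** 2 * p0 + 2 * t * (1 - t) * p1 + t**2 * p2
        pts = np.rint(pts).astype(int)
        stroke = np.zeros_like(mask)
        for (x0, y0), (x1, y1) in zip(pts[:-1], pts[1:]):
            if (x0, y0) == (x1, y1):
                continue
            rr, cc = draw_line(y0, x0, y1, x1)
            ok = (rr >= 0) & (rr < height) & (cc >= 0) & (cc < width)
            stroke[rr[ok], cc[ok]] = True
        # first few vessels are the thick arcades, the rest thinner
        radius = max(1, int(round(scale * (4 if k < 4 else rng.integers(2, 4)))))
        mask |= dilation(stroke, disk(radius))
    return mask


def generate_phantom(
    subject: SubjectRecord,
    camera: CameraModel,
    seed: int,
    *,
    height: int = 272,
    width: int = 512,
    scatter_amplitude: float = 0.1,
    pixel_noise_sd: float = 0.02,
    vessel_dip: float = 0.4,
) -> RetinalPhantom:
    """Build the ground-truth reflectance cube for one subject.

    The phantom is generated in right-eye convention (optic disc left of
    the fovea) and mirrored horizontally for left eyes, so that ROI
    geometry downstream must handle laterality.  The macula-centred
    field of view places the fovea near the image centre with a small
    jitter, and the OD-fovea distance is drawn so that the standard ROI
    layout fits inside the frame.
    """
    rng = np.random.default_rng(seed)
    bc = camera.band_centers

    # --- landmarks (right-eye frame) ---
    d = rng.uniform(0.186, 0.200) * width
    tilt = np.deg2rad(float(np.clip(rng.normal(0.0, 1.5), -3.0, 3.0)))
    fx = width / 2.0 + float(np.clip(rng.normal(0.0, 1.5), -3.0, 3.0))
    fy = height / 2.0 + float(np.clip(rng.normal(0.0, 1.5), -3.0, 3.0))
    ox = fx - d * np.cos(tilt)
    oy = fy - d * np.sin(tilt)

    # --- spatially smooth background with a bright disc ---
    gain = 1.0 + 0.15 * gaussian_filter(rng.standard_normal((height, width)),
                                        sigma=0.09 * min(height, width))
    yy, xx = np.mgrid[0:height, 0:width]
    r_od = 0.18 * d
    od_dist = np.hypot(xx - ox, yy - oy)
    gain += 0.35 * np.exp(-0.5 * (od_dist / r_od) ** 2)  # bright optic disc
    fov_dist = np.hypot(xx - fx, yy - fy)
    gain -= 0.08 * np.exp(-0.5 * (fov_dist / (0.10 * d)) ** 2)  # foveal dip

    spectrum = _base_spectrum(bc)
    att = rayleigh_attenuation(subject.amyloid_load, scatter_amplitude, bc)
    cube = gain[:, :, None] * (spectrum * att)[None, None, :]

    # --- vessels: hemoglobin-like absorption dip at 540-580 nm ---
    vessels = _vessel_tree(rng, height, width, (ox, oy))
    dip = 1.0 - vessel_dip * _hemoglobin_bump(bc)
    cube[vessels] *= dip

    if pixel_noise_sd > 0:
        cube = cube + rng.normal(0.0, pixel_noise_sd, size=cube.shape)
    cube = np.clip(cube, 0.0, None)

    od_center, fovea = (ox, oy), (fx, fy)
    if subject.eye == "left":
        cube = cube[:, ::-1].copy()
        vessels = vessels[:, ::-1].copy()
        od_center = (width - 1.0 - ox, oy)
        fovea = (width - 1.0 - fx, fy)

    return RetinalPhantom(
        height=height,
        width=width,
        od_center=od_center,
        fovea=fovea,
        vessel_truth=vessels,
        base_reflectance=cube,
        subject_ref=subject.subject_id,
    )


def render_raw_mosaic(
    phantom: RetinalPhantom,
    camera: CameraModel,
    *,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Image the phantom through the 4x4 mosaic sensor model.

    ``raw[4y + r, 4x + c] = dark + R[y, x, b] * (white[b] - dark) + noise``
    with ``(r, c)`` the mosaic offset of band ``b``; the result is
    clipped to ``[0, saturation_dn]`` and quantised to uint16.  Pass
    ``rng=None`` for a noiseless rendering.
    """
    h, w, nb = phantom.base_reflectance.shape
    if nb != 16:
        raise ShapeError("phantom must carry 16 bands")
    raw = np.empty((4 * h, 4 * w), dtype=float)
    dark = camera.dark_level
    for b in range(16):
        r, c = camera.mosaic_offset(b)
        raw[r::4, c::4] = dark + phantom.base_reflectance[:, :, b] * (
            camera.white_reference[b] - dark
        )
    if rng is not None and camera.read_noise_sd > 0:
        raw = raw + rng.normal(0.0, camera.read_noise_sd, size=raw.shape)
    return np.clip(np.rint(raw), 0, camera.saturation_dn).astype(np.uint16)
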