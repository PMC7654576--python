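"""End-to-end study orchestration and file I/O.

Two entry points:

* :func:`run_simulate` materialises a synthetic study on disk — one
  directory per subject with the raw 16-bit mosaic TIFF, the
  ground-truth vessel mask (PNG) and a JSON sidecar with landmarks and
  seeds, plus cohort / landmark / RNFL CSV tables and a manifest whose
  hash certifies reproducibility.
* :func:`run_full` executes the whole analysis — preprocessing, vessel
  masking, ROI spectra, standardization, cohort statistics, the
  SEM-overlap ROI screen, and nested LOOCV over the surviving
  configurations — either on an in-memory simulation or on an on-disk
  study in the simulated/real data layout.

Per-subject randomness is derived from the study seed with
``numpy.random.SeedSequence`` spawning, so a study is reproducible as a
whole and per subject.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify, preprocess, roi, stats, synthetic
from .synthetic import CameraModel, CohortSpec, ParameterError

__all__ = ["PipelineConfig", "StudyReport", "run_simulate", "run_full"]

log = logging.getLogger("retispec")

LANDMARK_COLUMNS = ["subject_id", "od_x", "od_y", "fovea_x", "fovea_y", "eye"]
RNFL_COLUMNS = ["subject_id", "rnfl_avg", "rnfl_sup", "rnfl_inf", "rnfl_tem", "rnfl_nas"]


@dataclass
class PipelineConfig:
    """All tunable parameters of the study, with study defaults."""

    # cohort / simulation
    n_ad: int = 17
    n_ctrl: int = 22
    seed: int = 0
    scatter_amplitude: float = 0.1
    pixel_noise_sd: float = 0.02
    phantom_height: int = 272
    phantom_width: int = 512
    # I/O
    input_dir: str | None = None  # read an on-disk study instead of simulating
    out_dir: str | None = None
    # ROI geometry
    roi_height: int = 40
    width_frac: float = 0.35
    near_offset_frac: float = 0.35
    far_offset_frac: float = 0.85
    drop_bands: tuple[int, int] = (0, 15)
    # vessel segmentation
    vessel_quantile: float = 0.90
    vessel_min_component: int = 50
    illumination_sigma: float = 25.0
    # QC
    saturation_threshold: float = 0.001
    # screening / statistics
    sem_multiplier: float = 1.0
    strict_screening: bool = False
    # classification
    standardize_features: bool = True
    ci_method: str = "delong"
    n_boot: int = 2000

    def cohort_spec(self) -> CohortSpec:
        return CohortSpec(
            n_ad=self.n_ad,
            n_ctrl=self.n_ctrl,
            seed=self.seed,
            scatter_amplitude=self.scatter_amplitude,
            pixel_noise_sd=self.pixel_noise_sd,
        )


@dataclass
class StudyReport:
    """Bundle of everything :func:`run_full` produces."""

    outcome: str
    cohort_table: pd.DataFrame
    qc: dict
    spectral_summaries: dict
    screened_rois: list
    configs: list
    cv: classify.NestedCVResult | None
    timings: dict = field(default_factory=dict)
    versions: dict = field(default_factory=dict)


def _subject_seed(study_seed: int, index: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(entropy=study_seed, spawn_key=(index,))


def _write_png_mask(path: Path, mask: np.ndarray) -> None:
    import imageio.v3 as iio

    iio.imwrite(path, (mask.astype(np.uint8) * 255))


def _read_png_mask(path: Path) -> np.ndarray:
    import imageio.v3 as iio

    return np.asarray(iio.imread(path)) > 127


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_simulate(config: PipelineConfig, camera: CameraModel | None = None) -> dict:
    """Write a full synthetic study under ``config.out_dir``.

    Returns the manifest (also written as ``manifest.json``), whose
    ``study_hash`` digests every generated file.
    """
    if config.out_dir is None:
        raise ParameterError("run_simulate requires out_dir")
    camera = camera or CameraModel()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    import tifffile

    cohort = synthetic.generate_cohort(config.cohort_spec())
    frame = synthetic.cohort_to_frame(cohort)
    frame.to_csv(out / "cohort.csv", index=False)

    landmarks_rows, rnfl_rows, files = [], [], ["cohort.csv"]
    for i, subject in enumerate(cohort):
        ss = _subject_seed(config.seed, i)
        phantom = synthetic.generate_phantom(
            subject, camera, ss,
            height=config.phantom_height, width=config.phantom_width,
            scatter_amplitude=config.scatter_amplitude,
            pixel_noise_sd=config.pixel_noise_sd,
        )
        raw = synthetic.render_raw_mosaic(
            phantom, camera, rng=np.random.default_rng(ss.spawn(1)[0])
        )
        sdir = out / "subjects" / subject.subject_id
        sdir.mkdir(parents=True, exist_ok=True)
        tifffile.imwrite(sdir / "raw.tiff", raw)
        _write_png_mask(sdir / "vessel_truth.png", phantom.vessel_truth)
        meta = {
            "subject_id": subject.subject_id,
            "eye": subject.eye,
            "od_center": list(phantom.od_center),
            "fovea": list(phantom.fovea),
            "height": phantom.height,
            "width": phantom.width,
            "seed_spawn_key": i,
            "camera": {
                "band_centers": camera.band_centers.tolist(),
                "dark_level": camera.dark_level,
                "white_reference": camera.white_reference.tolist(),
                "saturation_dn": camera.saturation_dn,
            },
        }
        (sdir / "meta.json").write_text(json.dumps(meta, indent=1))
        rel = f"subjects/{subject.subject_id}"
        files += [f"{rel}/raw.tiff", f"{rel}/vessel_truth.png", f"{rel}/meta.json"]
        landmarks_rows.append(
            [subject.subject_id, *phantom.od_center, *phantom.fovea, subject.eye]
        )
        rnfl_rows.append(
            [subject.subject_id, subject.rnfl_avg, subject.rnfl_sup,
             subject.rnfl_inf, subject.rnfl_tem, subject.rnfl_nas]
        )

    pd.DataFrame(landmarks_rows, columns=LANDMARK_COLUMNS).to_csv(
        out / "landmarks.csv", index=False
    )
    pd.DataFrame(rnfl_rows, columns=RNFL_COLUMNS).to_csv(out / "rnfl.csv", index=False)
    files += ["landmarks.csv", "rnfl.csv"]

    digest = hashlib.sha256()
    for f in sorted(files):
        digest.update(f.encode())
        digest.update(_sha256(out / f).encode())
    manifest = {
        "seed": config.seed,
        "n_ad": config.n_ad,
        "n_ctrl": config.n_ctrl,
        "scatter_amplitude": config.scatter_amplitude,
        "files": sorted(files),
        "study_hash": digest.hexdigest(),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    log.info("simulated study with %d subjects at %s", len(cohort), out)
    return manifest


# ---------------------------------------------------------------------------
# Full analysis
# ---------------------------------------------------------------------------

def _iter_subjects(config: PipelineConfig, camera: CameraModel):
    """Yield (subject_row, raw_frame, landmarks) for simulation or disk input."""
    if config.input_dir is None:
        cohort = synthetic.generate_cohort(config.cohort_spec())
        frame = synthetic.cohort_to_frame(cohort)
        for i, subject in enumerate(cohort):
            ss = _subject_seed(config.seed, i)
            phantom = synthetic.generate_phantom(
                subject, camera, ss,
                height=config.phantom_height, width=config.phantom_width,
                scatter_amplitude=config.scatter_amplitude,
                pixel_noise_sd=config.pixel_noise_sd,
            )
            raw = synthetic.render_raw_mosaic(
                phantom, camera, rng=np.random.default_rng(ss.spawn(1)[0])
            )
            lm = roi.Landmarks(phantom.od_center, phantom.fovea, subject.eye)
            yield frame.iloc[i], raw, lm
    else:
        import tifffile

        root = Path(config.input_dir)
        frame = pd.read_csv(root / "cohort.csv")
        landmarks = pd.read_csv(root / "landmarks.csv").set_index("subject_id")
        for _, row in frame.iterrows():
            sid = row["subject_id"]
            raw = tifffile.imread(root / "subjects" / sid / "raw.tiff")
            lrow = landmarks.loc[sid]
            lm = roi.Landmarks(
                (float(lrow["od_x"]), float(lrow["od_y"])),
                (float(lrow["fovea_x"]), float(lrow["fovea_y"])),
                str(lrow["eye"]),
            )
            yield row, raw, lm


def run_full(config: PipelineConfig, camera: CameraModel | None = None) -> StudyReport:
    """Run the complete study and optionally write the report bundle."""
    camera = camera or CameraModel()
    timings: dict[str, float] = {}
    t0 = time.perf_counter()

    roi_spectra: dict[str, list[np.ndarray]] = {r: [] for r in roi.ROI_IDS}
    rnfl_vectors: list[np.ndarray] = []
    labels: list[int] = []
    subject_ids: list[str] = []
    qc: dict[str, dict] = {}

    for row, raw, lm in _iter_subjects(config, camera):
        sid = row["subject_id"]
        try:
            dn = preprocess.demosaic(raw, camera)
            cube = preprocess.to_relative_reflectance(dn, camera, subject_ref=sid)
            # ONH exclusion disc: ~6% of the image width around the OD,
            # scaled x4 into raw-frame coordinates.
            report = preprocess.check_saturation(
                raw,
                (4.0 * lm.od_center[0], 4.0 * lm.od_center[1]),
                4.0 * 0.06 * (raw.shape[1] / 4.0),
                camera,
                threshold=config.saturation_threshold,
            )
            qc[sid] = dataclasses.asdict(report)
            vessels = preprocess.segment_vessels(
                cube,
                illumination_sigma=config.illumination_sigma,
                response_quantile=config.vessel_quantile,
                min_component_px=config.vessel_min_component,
            )
            roi_set = roi.place_rois(
                lm, cube.shape[:2],
                roi_height=config.roi_height,
                width_frac=config.width_frac,
                near_offset_frac=config.near_offset_frac,
                far_offset_frac=config.far_offset_frac,
            )
            for rid in roi.ROI_IDS:
                spectrum = roi.mean_roi_spectrum(cube, roi_set, rid, vessels)
                roi_spectra[rid].append(
                    roi.standardize_spectrum(
                        spectrum.mean_reflectance, config.drop_bands
                    )
                )
        except Exception as exc:
            raise RuntimeError(f"stage failure for subject {sid}: {exc}") from exc
        rnfl_vectors.append(
            np.array([row["rnfl_avg"], row["rnfl_sup"], row["rnfl_nas"],
                      row["rnfl_inf"], row["rnfl_tem"]])
        )
        labels.append(1 if row["group"] == "AD" else 0)
        subject_ids.append(sid)
    timings["imaging"] = time.perf_counter() - t0

    y = np.array(labels)
    spectra_mats = {r: np.vstack(v) for r, v in roi_spectra.items()}
    rnfl_mat = np.vstack(rnfl_vectors)

    # cohort statistics + SEM screen
    t0 = time.perf_counter()
    if config.input_dir is None:
        cohort_frame = synthetic.cohort_to_frame(
            synthetic.generate_cohort(config.cohort_spec())
        )
    else:
        cohort_frame = pd.read_csv(Path(config.input_dir) / "cohort.csv")
    cohort_table = stats.table2_report(cohort_frame)
    summaries = {
        r: stats.group_spectral_summary(m, y, r) for r, m in spectra_mats.items()
    }
    screened = stats.sem_screen(spectra_mats, y, config.sem_multiplier)
    timings["statistics"] = time.perf_counter() - t0

    if not screened:
        log.warning("no ROI passed the SEM screen; stopping after statistics")
        report = StudyReport(
            outcome="no ROI passed SEM screen",
            cohort_table=cohort_table,
            qc=qc,
            spectral_summaries=summaries,
            screened_rois=[],
            configs=[],
            cv=None,
            timings=timings,
            versions=_versions(),
        )
        _maybe_write(report, config, spectra_mats, None)
        return report

    # candidate configurations: spectra-only and spectra + RNFL per ROI
    feature_sets: dict[str, np.ndarray] = {}
    for rid in screened:
        feature_sets[rid] = spectra_mats[rid]
        feature_sets[f"{rid}+RNFL"] = np.hstack([spectra_mats[rid], rnfl_mat])

    config_filter = None
    if config.strict_screening:
        def config_filter(train_idx, _mats=spectra_mats, _y=y):
            sel = stats.sem_screen(
                {r: m[train_idx] for r, m in _mats.items()},
                _y[train_idx],
                config.sem_multiplier,
            )
            return [k for k in feature_sets if k.split("+")[0] in sel]

    t0 = time.perf_counter()
    cv = classify.nested_loocv(
        feature_sets, y, subject_ids,
        standardize=config.standardize_features,
        ci_method=config.ci_method,
        n_boot=config.n_boot,
        config_filter=config_filter,
        rng=np.random.default_rng(config.seed),
    )
    timings["cross_validation"] = time.perf_counter() - t0
    log.info("nested LOOCV: %s", cv.summary())

    report = StudyReport(
        outcome="ok",
        cohort_table=cohort_table,
        qc=qc,
        spectral_summaries=summaries,
        screened_rois=screened,
        configs=list(feature_sets),
        cv=cv,
        timings=timings,
        versions=_versions(),
    )
    _maybe_write(report, config, spectra_mats, feature_sets)
    return report


def _versions() -> dict:
    import scipy
    import skimage

    from . import __version__

    return {
        "retispec": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "scikit-image": skimage.__version__,
    }


def _maybe_write(report: StudyReport, config: PipelineConfig, spectra_mats, feature_sets):
    if config.out_dir is None:
        return
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.cohort_table.to_csv(out / "stats.csv", index=False)
    for rid, s in report.spectral_summaries.items():
        pd.DataFrame(
            {
                "band_index": s.band_index,
                "mean_ad": s.mean_ad,
                "sem_ad": s.sem_ad,
                "mean_ctrl": s.mean_ctrl,
                "sem_ctrl": s.sem_ctrl,
            }
        ).to_csv(out / f"group_spectra_{rid}.csv", index=False)
    payload = {
        "outcome": report.outcome,
        "screened_rois": report.screened_rois,
        "configs": report.configs,
        "qc": report.qc,
        "timings": report.timings,
        "versions": report.versions,
    }
    if report.cv is not None:
        cv = report.cv
        payload["cv"] = {
            "outer_auc": cv.outer_auc,
            "ci": list(cv.ci),
            "ci_method": cv.ci_method,
            "selection_tally": cv.selection_tally,
            "per_fold_allowed": (
                [list(a) for a in cv.per_fold_allowed]
                if cv.per_fold_allowed is not None
                else None
            ),
        }
        pd.DataFrame(
            {
                "subject_id": cv.subject_ids,
                "label": cv.y,
                "probability_ad": cv.probabilities,
                "selected_config": cv.selected_configs,
            }
        ).to_csv(out / "cv_predictions.csv", index=False)
        fpr, tpr, thr = classify.roc_curve(cv.probabilities, cv.y)
        pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr}).to_csv(
            out / "roc_curve.csv", index=False
        )
    (out / "report.json").write_text(json.dumps(payload, indent=1))
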