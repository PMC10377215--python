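"""End-to-end orchestration: simulate or ingest, segment, measure, report.

``run_pipeline`` drives the whole chain behind a single validated
:class:`RunConfig` and writes the cohort report files; ``analyze_cohort``
is the in-memory core the CLI, the analysis scripts and the tests all
share.  Identical config + seed yields byte-identical outputs.
"""

from __future__ import annotations

import copy
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import synthetic
from .dicom_io import SubjectStudy, load_subject, read_metadata_table
from .devices import DeviceProfile
from .errors import PhysometryError, ValidationError
from .morphometry import SubjectMorphometry, VolumeMode, measure_subject
from .segmentation import (
    BoundingBox,
    RefineParams,
    SegmentationResult,
    ThresholdSpec,
    default_roi_box,
    load_femur_mask,
    outline_overlay,
    segment_growth_plate,
)
from .stats import (
    CorrelationResult,
    KappaResult,
    RegressionTable,
    SummaryRow,
    average_over_observers,
    cohort_summary,
    kappa_from_counts,
    ks_normality,
    mann_whitney_u,
    multiple_regression,
    pearson_r_ci,
)

logger = logging.getLogger("physometry")

__all__ = [
    "RunConfig",
    "CohortReport",
    "validate_config",
    "config_from_dict",
    "analyze_cohort",
    "run_pipeline",
    "segment_cohort_plates",
    "DEVICE_PREDICTORS",
]

_DEFAULT_CONFIG: dict = {
    "mode": "simulate",
    "simulate": {
        "n_subjects": 50,
        "age_min": 10.0,
        "age_max": 26.0,
        "noise_sd": synthetic.DEFAULT_NOISE_SD,
        "n_observers": 3,
        "perturbation": 2.0,
        "vary_slices": True,
    },
    "input": {
        "dicom_dir": None,
        "metadata_csv": None,
        "masks_manifest": None,
    },
    "segmentation": {
        "roi_window_mm": [[-5.0, 45.0], [-55.0, 55.0]],
        "threshold": {
            "mode": "auto",
            "tmin": None,
            "tmax": None,
            "otsu_fraction": 0.6,
        },
        "refine": {
            "median": False,
            "close_radius": 1,
            "min_component": 20,
            "keep_largest": False,
        },
        "visibility_min_pixels": 20,
    },
    "volume_mode": "as_printed",
    "output_dir": "physometry_out",
    "overlays": True,
    "seed": 0,
    "log_level": "INFO",
}


@dataclass
class RunConfig:
    """Validated run configuration (see the default YAML schema)."""

    raw: dict = field(default_factory=lambda: copy.deepcopy(_DEFAULT_CONFIG))

    @property
    def mode(self) -> str:
        return self.raw["mode"]

    @property
    def seed(self) -> int:
        return int(self.raw["seed"])

    @property
    def output_dir(self) -> Path:
        return Path(self.raw["output_dir"])

    def threshold_spec(self) -> ThresholdSpec | None:
        th = self.raw["segmentation"]["threshold"]
        if th["mode"] == "fixed":
            return ThresholdSpec(float(th["tmin"]), float(th["tmax"]))
        return None

    def refine_params(self) -> RefineParams:
        r = self.raw["segmentation"]["refine"]
        return RefineParams(
            median=bool(r["median"]),
            close_radius=int(r["close_radius"]),
            min_component=int(r["min_component"]),
            keep_largest=bool(r["keep_largest"]),
        )

    def roi_window(self) -> tuple[tuple[float, float], tuple[float, float]]:
        (ylo, yhi), (xlo, xhi) = self.raw["segmentation"]["roi_window_mm"]
        return ((float(ylo), float(yhi)), (float(xlo), float(xhi)))


def _merge_checked(defaults: dict, user: dict, prefix: str = "") -> dict:
    out = copy.deepcopy(defaults)
    for key, value in user.items():
        if key not in defaults:
            raise ValidationError(f"unknown config key: {prefix}{key}")
        if isinstance(defaults[key], dict) and isinstance(value, dict):
            out[key] = _merge_checked(defaults[key], value, f"{prefix}{key}.")
        else:
            out[key] = value
    return out


def config_from_dict(user: dict | None = None) -> RunConfig:
    """Build a RunConfig from a (partial) dict, filling defaults and
    rejecting unknown keys; cross-field constraints are checked here."""
    merged = _merge_checked(_DEFAULT_CONFIG, user or {})
    if merged["mode"] not in ("simulate", "dicom_dir"):
        raise ValidationError(f"mode must be 'simulate' or 'dicom_dir', got {merged['mode']!r}")
    th = merged["segmentation"]["threshold"]
    if th["mode"] not in ("auto", "fixed"):
        raise ValidationError("segmentation.threshold.mode must be 'auto' or 'fixed'")
    if th["mode"] == "fixed":
        if th["tmin"] is None or th["tmax"] is None:
            raise ValidationError("fixed threshold mode requires tmin and tmax")
        if float(th["tmin"]) > float(th["tmax"]):
            raise ValidationError("segmentation.threshold: tmin > tmax")
    if merged["mode"] == "simulate" and int(merged["simulate"]["n_subjects"]) < 2:
        raise ValidationError("simulate.n_subjects must be >= 2")
    if merged["mode"] == "dicom_dir" and not merged["input"]["dicom_dir"]:
        raise ValidationError("dicom_dir mode requires input.dicom_dir")
    if merged["volume_mode"] not in ("as_printed", "sum_of_slabs"):
        raise ValidationError("volume_mode must be 'as_printed' or 'sum_of_slabs'")
    return RunConfig(raw=merged)


def validate_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML config file."""
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    if not isinstance(user, dict):
        raise ValidationError("config file must contain a YAML mapping")
    return config_from_dict(user)


# --------------------------------------------------------------------------
# Core analysis

DEVICE_PREDICTORS = (
    "field_strength_T",
    "pixel_size_mm2",
    "image_matrix_area_mm2",
    "n_image_pixels",
    "slice_thickness_mm",
    "n_visible_slices",
    "total_width_mm",
)


@dataclass
class CohortReport:
    """All cohort-level result tables."""

    morphometry: pd.DataFrame  # one row per subject x observer
    ari_by_subject: pd.DataFrame  # subject, age, sex, mean ARI + device columns
    kappa: list[KappaResult]
    correlations: dict[str, CorrelationResult]  # "Female", "Male", "Total"
    regression: RegressionTable
    descriptives_age: list[SummaryRow]
    descriptives_device: list[SummaryRow]
    mann_whitney: dict[str, tuple[float, float]]
    normality: dict[str, tuple[float, float]]
    seed: int = 0


def segment_cohort_plates(
    studies: list[SubjectStudy], config: RunConfig
) -> tuple[list[list[np.ndarray]], list[list[BoundingBox]]]:
    """Semi-automatic plate masks (and the ROI boxes used) per subject."""
    spec = config.threshold_spec()
    refine = config.refine_params()
    otsu_fraction = float(config.raw["segmentation"]["threshold"]["otsu_fraction"])
    window = config.roi_window()
    plate_masks, boxes = [], []
    for study in studies:
        masks, subject_boxes = [], []
        for knee_slice in study.slices:
            box = default_roi_box(knee_slice, window)
            masks.append(
                segment_growth_plate(
                    knee_slice, box, spec=spec, refine=refine,
                    otsu_fraction=otsu_fraction,
                )
            )
            subject_boxes.append(box)
        plate_masks.append(masks)
        boxes.append(subject_boxes)
    return plate_masks, boxes


def _pairwise_kappas(
    observers_per_subject: list[list[SegmentationResult]],
    boxes: list[list[BoundingBox]],
) -> list[KappaResult]:
    """Pooled pixel-wise kappa per observer pair over all subjects/slices,
    scored inside the segmentation ROI."""
    observer_ids = [o.observer_id for o in observers_per_subject[0]]
    results = []
    for i in range(len(observer_ids)):
        for j in range(i + 1, len(observer_ids)):
            a = b = c = d = 0
            for observers, subject_boxes in zip(observers_per_subject, boxes):
                oi, oj = observers[i], observers[j]
                for fi, fj, box in zip(oi.femur_masks, oj.femur_masks, subject_boxes):
                    r, cslice = box.slices
                    mi = fi[r, cslice]
                    mj = fj[r, cslice]
                    a += int(np.count_nonzero(mi & mj))
                    b += int(np.count_nonzero(mi & ~mj))
                    c += int(np.count_nonzero(~mi & mj))
                    d += int(np.count_nonzero(~mi & ~mj))
            results.append(
                kappa_from_counts(a, b, c, d, pair=(observer_ids[i], observer_ids[j]))
            )
    return results


def _device_row(study: SubjectStudy, ns: int) -> dict:
    device = study.device
    if isinstance(device, DeviceProfile):
        field_strength = device.field_strength
    else:
        field_strength = study.slices[0].field_strength
    rows, cols = study.slices[0].shape
    rsp, csp = study.pixel_spacing
    return {
        "field_strength_T": field_strength if field_strength is not None else np.nan,
        "pixel_size_mm2": rsp * csp,
        "image_matrix_area_mm2": (rows * rsp) * (cols * csp),
        "n_image_pixels": rows * cols,
        "slice_thickness_mm": study.slice_thickness,
        "n_visible_slices": ns,
        "total_width_mm": study.slice_thickness * ns,
    }


def cohort_statistics(ari_df: pd.DataFrame) -> dict:
    """Tabular statistics from the per-subject table (age, sex, mean ARI
    and device columns): correlations by sex, the device-influence
    regression, descriptive rows, Mann-Whitney group tests and normality
    checks."""
    correlations: dict[str, CorrelationResult] = {}
    for label, sel in (
        ("Female", ari_df["sex"] == "F"),
        ("Male", ari_df["sex"] == "M"),
        ("Total", ari_df["sex"].notna()),
    ):
        sub = ari_df[sel]
        correlations[label] = pearson_r_ci(sub["age"], sub["mean_ARI"])

    design = ari_df[["age"]].copy()
    design["sex"] = (ari_df["sex"] == "M").astype(float)
    for col in DEVICE_PREDICTORS:
        design[col] = ari_df[col].astype(float)
    regression = multiple_regression(ari_df["mean_ARI"].to_numpy(), design)

    descr_age = [
        cohort_summary(ari_df.loc[ari_df["sex"] == "F", "age"], "Female"),
        cohort_summary(ari_df.loc[ari_df["sex"] == "M", "age"], "Male"),
        cohort_summary(ari_df["age"], "Total"),
    ]
    descr_device = [
        cohort_summary(ari_df[col], label)
        for col, label in (
            ("field_strength_T", "Magnetic field strength (T)"),
            ("pixel_size_mm2", "Pixel size (mm^2)"),
            ("n_image_pixels", "Total number of pixels on the image"),
            ("image_matrix_area_mm2", "Image matrix area (mm^2)"),
            ("slice_thickness_mm", "Slice thickness (mm)"),
            ("n_visible_slices", "Total slices of the study area"),
            ("total_width_mm", "Total width of the study area (mm)"),
        )
    ]

    age_f = ari_df.loc[ari_df["sex"] == "F", "age"].to_numpy()
    age_m = ari_df.loc[ari_df["sex"] == "M", "age"].to_numpy()
    ari_f = ari_df.loc[ari_df["sex"] == "F", "mean_ARI"].to_numpy()
    ari_m = ari_df.loc[ari_df["sex"] == "M", "mean_ARI"].to_numpy()
    mann_whitney = {
        "age_by_sex": mann_whitney_u(age_f, age_m),
        "ARI_by_sex": mann_whitney_u(ari_f, ari_m),
    }
    normality = {
        "age": ks_normality(ari_df["age"]),
        "mean_ARI": ks_normality(ari_df["mean_ARI"]),
    }
    return {
        "correlations": correlations,
        "regression": regression,
        "descriptives_age": descr_age,
        "descriptives_device": descr_device,
        "mann_whitney": mann_whitney,
        "normality": normality,
    }


def analyze_cohort(
    studies: list[SubjectStudy],
    observers_per_subject: list[list[SegmentationResult]],
    config: RunConfig | None = None,
    plate_masks: list[list[np.ndarray]] | None = None,
) -> CohortReport:
    """Measure every subject under every observer and compute the cohort
    statistics: agreement, age-ARI correlation by sex and total, the
    device-influence regression, descriptives and group tests.

    Each inner ``SegmentationResult`` carries the observer's femur masks;
    the plate masks are computed with the configured semi-automatic chain
    (or taken from ``plate_masks`` when a cached segmentation stage is
    reused), shared across observers, and overlap is resolved in favour of
    the plate.
    """
    config = config or config_from_dict()
    visibility_min = int(config.raw["segmentation"]["visibility_min_pixels"])
    volume_mode = VolumeMode(config.raw["volume_mode"])

    if plate_masks is None:
        plate_masks, boxes = segment_cohort_plates(studies, config)
    else:
        window = config.roi_window()
        boxes = [
            [default_roi_box(s, window) for s in study.slices] for study in studies
        ]

    all_morphs: list[SubjectMorphometry] = []
    for study, observers, plates in zip(studies, observers_per_subject, plate_masks):
        for obs in observers:
            seg = SegmentationResult(
                observer_id=obs.observer_id,
                femur_masks=[m.copy() for m in obs.femur_masks],
                plate_masks=[m.copy() for m in plates],
            )
            seg.enforce_disjoint()
            all_morphs.append(
                measure_subject(study, seg, visibility_min, volume_mode)
            )

    morph_df = pd.DataFrame(
        {
            "subject_id": m.subject_id,
            "observer_id": m.observer_id,
            "Ns": m.ns,
            "Ts_mm": m.ts,
            "Af_mm2": m.af,
            "Ae_mm2": m.ae,
            "ARI": m.ari,
            "Vf_mm3": m.vf,
            "Ve_mm3": m.ve,
            "VRI": m.vri,
        }
        for m in all_morphs
    )

    mean_ari = average_over_observers(all_morphs)
    ns_by_subject = {m.subject_id: m.ns for m in all_morphs}
    rows = []
    for study in studies:
        row = {
            "subject_id": study.subject_id,
            "age": study.age,
            "sex": study.sex,
            "mean_ARI": mean_ari[study.subject_id],
        }
        row.update(_device_row(study, ns_by_subject[study.subject_id]))
        rows.append(row)
    ari_df = pd.DataFrame(rows)

    kappas = _pairwise_kappas(observers_per_subject, boxes)
    tabular = cohort_statistics(ari_df)

    return CohortReport(
        morphometry=morph_df,
        ari_by_subject=ari_df,
        kappa=kappas,
        correlations=tabular["correlations"],
        regression=tabular["regression"],
        descriptives_age=tabular["descriptives_age"],
        descriptives_device=tabular["descriptives_device"],
        mann_whitney=tabular["mann_whitney"],
        normality=tabular["normality"],
        seed=config.seed,
    )


# --------------------------------------------------------------------------
# Input assembly

def _observer_seed(seed: int, subject_index: int) -> int:
    return int((seed * 1_000_003 + 7919 * subject_index + 1) % (2**31 - 1))


def simulate_inputs(
    config: RunConfig,
) -> tuple[list[SubjectStudy], list[synthetic.GroundTruth], list[list[SegmentationResult]]]:
    """Generate the synthetic cohort and its simulated observers."""
    sim = config.raw["simulate"]
    cohort = synthetic.generate_cohort(
        n_subjects=int(sim["n_subjects"]),
        age_range=(float(sim["age_min"]), float(sim["age_max"])),
        seed=config.seed,
        noise_sd=float(sim["noise_sd"]),
        vary_slices=bool(sim["vary_slices"]),
    )
    studies = [s for s, _ in cohort]
    truths = [t for _, t in cohort]
    observers = [
        synthetic.simulate_observer_masks(
            truth,
            perturbation=float(sim["perturbation"]),
            seed=_observer_seed(config.seed, i),
            n_observers=int(sim["n_observers"]),
        )
        for i, truth in enumerate(truths)
    ]
    return studies, truths, observers


def load_inputs_from_dir(
    config: RunConfig,
) -> tuple[list[SubjectStudy], list[list[SegmentationResult]]]:
    """Load DICOM subjects plus externally produced observer femur masks.

    Expects ``input.dicom_dir`` with one sub-directory per subject,
    ``input.metadata_csv`` and ``input.masks_manifest`` (JSON:
    subject_id -> observer_id -> ordered femur-mask paths).
    """
    inp = config.raw["input"]
    dicom_dir = Path(inp["dicom_dir"])
    if not inp["metadata_csv"] or not inp["masks_manifest"]:
        raise ValidationError(
            "dicom_dir mode requires input.metadata_csv and input.masks_manifest"
        )
    records = {r["subject_id"]: r for r in read_metadata_table(inp["metadata_csv"])}
    with open(inp["masks_manifest"]) as fh:
        mask_manifest = json.load(fh)

    studies, observers_per_subject = [], []
    for subject_id in sorted(records):
        study = load_subject(dicom_dir / subject_id, records[subject_id])
        observers = []
        for observer_id in sorted(mask_manifest.get(subject_id, {})):
            paths = mask_manifest[subject_id][observer_id]
            femur = [
                load_femur_mask(p, s) for p, s in zip(paths, study.slices)
            ]
            empty = [np.zeros(s.shape, dtype=bool) for s in study.slices]
            observers.append(
                SegmentationResult(
                    observer_id=observer_id, femur_masks=femur, plate_masks=empty
                )
            )
        if not observers:
            raise ValidationError(f"no observer masks for subject {subject_id}")
        studies.append(study)
        observers_per_subject.append(observers)
    return studies, observers_per_subject


# --------------------------------------------------------------------------
# Report serialisation

def _write_reports(report: CohortReport, config: RunConfig,
                   studies: list[SubjectStudy]) -> dict[str, str]:
    out = config.output_dir
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    def _save(df: pd.DataFrame, name: str) -> None:
        path = out / name
        df.to_csv(path, index=False, float_format="%.10g")
        paths[name] = str(path)

    _save(report.morphometry, "morphometry.csv")
    _save(report.ari_by_subject, "ari_by_subject.csv")
    _save(
        pd.DataFrame(
            {
                "observer_pair": f"{k.observer_pair[0]} vs {k.observer_pair[1]}",
                "kappa": k.kappa,
                "ci_low": k.ci_low,
                "ci_high": k.ci_high,
                "n_pixels": k.n,
            }
            for k in report.kappa
        ),
        "kappa.csv",
    )
    _save(
        pd.DataFrame(
            {
                "group": label,
                "N": c.n,
                "r": c.r,
                "ci_low": c.ci_low,
                "ci_high": c.ci_high,
                "p": c.p,
            }
            for label, c in report.correlations.items()
        ),
        "correlation.csv",
    )
    reg = report.regression.table.reset_index().rename(columns={"index": "predictor"})
    _save(reg, "regression.csv")
    with open(out / "regression_model.json", "w") as fh:
        json.dump(
            {
                "r_squared": report.regression.r_squared,
                "f_stat": report.regression.f_stat,
                "f_pvalue": report.regression.f_pvalue,
                "nobs": report.regression.nobs,
            },
            fh,
            indent=2,
            sort_keys=True,
        )
    paths["regression_model.json"] = str(out / "regression_model.json")

    def _summary_df(rows: list[SummaryRow]) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "label": r.label,
                "N": r.n,
                "mean": r.mean,
                "sd": r.sd,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "sem": r.sem,
                "median": r.median,
                "min": r.min,
                "max": r.max,
            }
            for r in rows
        )

    _save(_summary_df(report.descriptives_age), "descriptives_age.csv")
    _save(_summary_df(report.descriptives_device), "descriptives_device.csv")
    _save(
        pd.DataFrame(
            {"comparison": k, "U": u, "p": p}
            for k, (u, p) in report.mann_whitney.items()
        ),
        "mann_whitney.csv",
    )
    _save(
        pd.DataFrame(
            {"variable": k, "D": d, "p": p}
            for k, (d, p) in report.normality.items()
        ),
        "normality.csv",
    )

    with open(out / "run_metadata.json", "w") as fh:
        json.dump({"seed": config.seed, "config": config.raw}, fh, indent=2,
                  sort_keys=True, default=str)
    paths["run_metadata.json"] = str(out / "run_metadata.json")

    if config.raw["overlays"] and studies:
        import imageio.v3 as iio

        overlay_dir = out / "overlays"
        overlay_dir.mkdir(exist_ok=True)
        study = studies[0]
        plates, _ = segment_cohort_plates([study], config)
        mid = len(study.slices) // 2
        overlay = outline_overlay(study.slices[mid], plates[0][mid])
        path = overlay_dir / f"{study.subject_id}_slice{mid:02d}.png"
        iio.imwrite(path, overlay.astype(np.uint8))
        paths["overlay"] = str(path)
    return paths


def run_pipeline(config: RunConfig) -> dict[str, str]:
    """Run the full chain and write all report files.

    Returns a mapping of report names to file paths.  Any stage failure is
    re-raised with a stage label so the CLI can report where it happened.
    """
    logging.basicConfig(level=config.raw["log_level"])
    stage = "input"
    try:
        if config.mode == "simulate":
            studies, _truths, observers = simulate_inputs(config)
        else:
            studies, observers = load_inputs_from_dir(config)
        logger.info("loaded %d subjects", len(studies))
        stage = "analysis"
        report = analyze_cohort(studies, observers, config)
        stage = "report"
        return _write_reports(report, config, studies)
    except PhysometryError as exc:
        raise PhysometryError(f"[{stage}] {exc}") from exc
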