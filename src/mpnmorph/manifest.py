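"""Cohort manifests and the end-to-end pipeline.

A cohort manifest is a CSV with one row per patient: ``patient_id``,
``label`` (pre-PMF, PV, ET or NOS), semicolon-separated ``roi_paths``
and ``annotation_paths``, a ``pixel_size_um`` column, and an optional
``pathologist_cellularity`` column that may hold exact fractions
("0.55") or ranges ("0.4-0.6"); ranges resolve to their upper bound.

:func:`run_pipeline` composes the stages — segmentation, morphometry,
feature building, Kruskal–Wallis screening, repeated cross-validation,
NOS scoring and the evaluation report — and writes every artifact with a
provenance record (config digest, seed, package version), so re-running
with identical inputs is byte-identical for deterministic stages.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
from shapely.geometry import shape as shapely_shape

from . import __version__
from .config import PipelineConfig
from .featurebuild import cohort_table, patient_vector
from .imaging import (
    ROIImage,
    calibrate_background,
    compute_cellularity,
    detect_adipocytes,
    detect_nucleated_cells,
)
from .metrics import ks_compare
from .model import (
    CVReport,
    ClassScores,
    kruskal_wallis_select,
    predict_nos,
    repeated_cv,
    train_svm,
)
from .morphometry import filter_megakaryocytes, shape_descriptors
from .profiles import CLASS_ORDER

__all__ = [
    "CohortManifest",
    "PipelineResult",
    "load_manifest",
    "load_roi",
    "segment_roi",
    "run_pipeline",
]

logger = logging.getLogger("mpnmorph")

VALID_LABELS = set(CLASS_ORDER) | {"NOS"}
_REQUIRED_COLUMNS = ("patient_id", "label", "roi_paths")


@dataclass
class CohortManifest:
    """Validated cohort table; ``frame`` has one row per patient."""

    frame: pd.DataFrame
    base_dir: Path

    def patients(self, labels: set[str] | None = None) -> pd.DataFrame:
        if labels is None:
            return self.frame
        return self.frame[self.frame["label"].isin(labels)]


def _parse_cellularity(value) -> tuple[float | None, bool]:
    """Parse an exact value or a 'lo-hi' range (upper bound used)."""
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None, False
    s = str(value).strip()
    if not s or s.upper() == "NA":
        return None, False
    if "-" in s:
        parts = [p for p in s.split("-") if p.strip()]
        vals = [float(p) for p in parts]
        return max(vals), True
    return float(s), False


def load_manifest(path: str | Path) -> CohortManifest:
    """Load and validate a cohort manifest CSV.

    Raises specific errors for an empty file, duplicate patient ids,
    unknown labels and missing referenced files.
    """
    path = Path(path)
    frame = pd.read_csv(path)
    if frame.empty:
        raise ValueError(f"manifest {path} contains no patients")
    missing_cols = [c for c in _REQUIRED_COLUMNS if c not in frame.columns]
    if missing_cols:
        raise ValueError(f"manifest missing required column(s): {missing_cols}")
    dup = frame["patient_id"][frame["patient_id"].duplicated()].tolist()
    if dup:
        raise ValueError(f"duplicate patient_id(s): {sorted(set(map(str, dup)))}")
    bad = sorted(set(frame["label"]) - VALID_LABELS)
    if bad:
        raise ValueError(
            f"unknown label(s) {bad}; expected one of {sorted(VALID_LABELS)}"
        )
    base = path.parent
    for col in ("roi_paths", "annotation_paths"):
        if col not in frame.columns:
            continue
        for cell in frame[col].dropna():
            for p in str(cell).split(";"):
                candidate = Path(p)
                if not candidate.is_absolute():
                    candidate = base / candidate
                if not candidate.exists():
                    raise FileNotFoundError(f"manifest references missing file: {p}")
    if "pathologist_cellularity" in frame.columns:
        parsed = frame["pathologist_cellularity"].map(_parse_cellularity)
        frame = frame.assign(
            pathologist_cellularity=[v for v, _ in parsed],
            pathologist_cellularity_is_range=[r for _, r in parsed],
        )
    return CohortManifest(frame=frame, base_dir=base)


def _read_polygons(annotation_path: Path) -> dict[str, np.ndarray]:
    doc = json.loads(annotation_path.read_text())
    out = {}
    for feat in doc.get("features", []):
        name = feat.get("properties", {}).get("classification", "")
        geom = shapely_shape(feat["geometry"])
        coords = np.asarray(geom.exterior.coords, dtype=float)[:-1]
        out[name] = coords
    return out


def load_roi(
    image_path: str | Path,
    annotation_path: str | Path,
    pixel_size_um: float,
) -> ROIImage:
    """Read a TIFF/PNG image plus its GeoJSON annotations into an ROI."""
    image_path = Path(image_path)
    if image_path.suffix.lower() in (".tif", ".tiff"):
        pixels = tifffile.imread(image_path)
    else:
        pixels = iio.imread(image_path)
    polys = _read_polygons(Path(annotation_path))
    try:
        tissue = polys["Tissue Boundaries"]
        background = polys["Background"]
    except KeyError as e:
        raise ValueError(
            f"annotation {annotation_path} lacks required class {e}"
        ) from None
    return ROIImage(
        pixels=pixels,
        pixel_size_um=float(pixel_size_um),
        tissue_polygon=tissue,
        background_polygon=background,
    )


def segment_roi(roi: ROIImage, config: PipelineConfig):
    """Run background calibration + both detection steps on one ROI.

    Returns (nuclei RegionSet, adipocytes RegionSet, cellularity).
    """
    bg = calibrate_background(roi)
    adipocytes = detect_adipocytes(roi, config.detection, bg)
    nuclei = detect_nucleated_cells(roi, config.detection)
    cellularity = compute_cellularity(nuclei, adipocytes)
    return nuclei, adipocytes, cellularity


def detections_frame(nuclei, adipocytes, config: PipelineConfig) -> pd.DataFrame:
    """Per-region measurement export mirroring a detection-measurement
    CSV: one row per region with class, geometry and (for nuclei) the
    morphometric descriptors and megakaryocyte flag."""
    rows = []
    for region in nuclei:
        s = shape_descriptors(region.mask, nuclei.pixel_size_um, region.label)
        rows.append(
            {
                "id": f"nucleus-{region.label}",
                "class": "nucleus",
                "area_um2": s.area_um2,
                "perimeter_um": s.perimeter_um,
                "centroid_x": region.centroid_xy[0],
                "centroid_y": region.centroid_xy[1],
                "circularity": s.circularity,
                "eccentricity": s.eccentricity,
                "max_caliper_um": s.max_caliper_um,
                "is_megakaryocyte": bool(
                    s.eccentricity > config.features.ecc_min
                    and s.max_caliper_um > config.features.caliper_min_um
                ),
            }
        )
    for region in adipocytes:
        rows.append(
            {
                "id": f"adipocyte-{region.label}",
                "class": "adipocyte",
                "area_um2": region.area_um2,
                "perimeter_um": region.perimeter_um,
                "centroid_x": region.centroid_xy[0],
                "centroid_y": region.centroid_xy[1],
                "circularity": region.circularity,
                "eccentricity": np.nan,
                "max_caliper_um": np.nan,
                "is_megakaryocyte": False,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class PipelineResult:
    features: pd.DataFrame
    labels: pd.Series
    selection_table: pd.DataFrame
    selected_features: list[str]
    cv_report: CVReport | None
    nos_scores: list[ClassScores]
    cellularity_ks: dict | None
    out_dir: Path | None


def _featurize_cohort(manifest: CohortManifest, config: PipelineConfig):
    vectors = []
    labels = {}
    auto_cellularity = {}
    for _, row in manifest.frame.iterrows():
        pid = str(row["patient_id"])
        img_paths = str(row["roi_paths"]).split(";")
        ann_paths = str(row["annotation_paths"]).split(";")
        px = float(row["pixel_size_um"])
        roi_shapes, cellularities = [], []
        for ip, ap in zip(img_paths, ann_paths):
            ip = ip if Path(ip).is_absolute() else str(manifest.base_dir / ip)
            ap = ap if Path(ap).is_absolute() else str(manifest.base_dir / ap)
            roi = load_roi(ip, ap, px)
            nuclei, adipocytes, cellularity = segment_roi(roi, config)
            shapes = [
                shape_descriptors(r.mask, nuclei.pixel_size_um, r.label)
                for r in nuclei
            ]
            mks = filter_megakaryocytes(
                shapes, config.features.ecc_min, config.features.caliper_min_um
            )
            logger.info(
                "%s %s: %d nuclei, %d adipocytes, %d megakaryocytes, "
                "cellularity %.3f",
                pid, Path(ip).name, len(shapes), len(adipocytes), len(mks),
                cellularity,
            )
            roi_shapes.append(shapes)
            cellularities.append(cellularity)
        vec = patient_vector(pid, roi_shapes, cellularities,
                             label=str(row["label"]), config=config.features)
        vectors.append(vec)
        labels[pid] = str(row["label"])
        auto_cellularity[pid] = float(vec["cellularity"])
    features = cohort_table(vectors)
    return features, pd.Series(labels, name="label"), auto_cellularity


def run_pipeline(
    manifest: CohortManifest,
    config: PipelineConfig = PipelineConfig(),
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Execute segment → morphometry → features → train-eval →
    predict-nos → report on a cohort manifest.

    Requires at least two of the three diagnostic classes with k or more
    patients each for cross-validation; NOS patients are scored by a
    model refitted on the full labelled cohort.  Raises with the stage
    name on failure.
    """
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    features, labels, auto_cell = _featurize_cohort(manifest, config)
    labelled = labels[labels != "NOS"]
    if labelled.empty:
        raise ValueError(
            "pipeline requires labelled (non-NOS) patients to train on"
        )
    X = features.loc[labelled.index]
    y = labelled

    selection = kruskal_wallis_select(X, y, alpha=config.model.alpha)
    selected = selection.selected or list(X.columns)
    selected = [c for c in selected if X[c].std(ddof=1) > 0]
    if not selected:
        raise ValueError("feature table has no non-constant features")

    cv = repeated_cv(
        X[selected], y,
        k=config.model.k, repeats=config.model.repeats, seed=seed,
        C=config.model.C, nested_selection=config.model.nested_selection,
        alpha=config.model.alpha, gmean_sqrt=config.model.gmean_sqrt,
    )
    cv.selected_features = selected

    nos_ids = labels.index[labels == "NOS"]
    nos_scores: list[ClassScores] = []
    if len(nos_ids) > 0:
        full_model = train_svm(X[selected], y, seed=seed, C=config.model.C)
        nos_scores = predict_nos(full_model, features.loc[nos_ids, selected])

    cellularity_ks = None
    if "pathologist_cellularity" in manifest.frame.columns:
        ref = manifest.frame.set_index("patient_id")["pathologist_cellularity"]
        ref = ref.dropna()
        if len(ref) > 0:
            ids = [str(i) for i in ref.index]
            ks = ks_compare([auto_cell[i] for i in ids], ref.to_list())
            cellularity_ks = {
                "statistic": ks.statistic,
                "p_value": ks.p_value,
                "mean_abs_difference": ks.mean_abs_difference,
                "difference_histogram": ks.difference_histogram.tolist(),
            }

    if out is not None:
        feat_out = features.copy()
        feat_out.insert(0, "label", labels)
        feat_out.to_csv(out / "features.csv")
        selection.table.to_csv(out / "kruskal_wallis.csv")
        (out / "cv_report.json").write_text(cv.to_json())
        cv.predictions.to_csv(out / "cv_predictions.csv", index=False)
        if nos_scores:
            pd.DataFrame(
                [
                    {"patient_id": s.patient_id, **s.scores,
                     "predicted_label": s.predicted_label}
                    for s in nos_scores
                ]
            ).to_csv(out / "nos_predictions.csv", index=False)
        provenance = {
            "package_version": __version__,
            "config_digest": config.digest(),
            "seed": int(seed),
            "selected_features": selected,
        }
        (out / "provenance.json").write_text(json.dumps(provenance, indent=2))
        (out / "config.json").write_text(config.to_json())

    return PipelineResult(
        features=features,
        labels=labels,
        selection_table=selection.table,
        selected_features=selected,
        cv_report=cv,
        nos_scores=nos_scores,
        cellularity_ks=cellularity_ks,
        out_dir=out,
    )
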