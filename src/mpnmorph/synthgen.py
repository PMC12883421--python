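"""Seeded synthetic bone-marrow ROI and feature-cohort generators.

Rendered ROIs emulate a single-channel H&E-like intensity image: dark
nuclei and near-background adipocyte spaces on a mid-grey stroma, with a
pure-background margin strip for calibration.  Each ROI carries exact
ground-truth label masks (nuclei with per-region megakaryocyte flags,
adipocytes) so every downstream stage of the pipeline can be tested
without any external data.

Two generation routes exist:

* :func:`generate_patient_rois` renders images + masks, exercising the
  full detection/morphometry path;
* :func:`generate_feature_cohort` draws per-patient feature vectors
  directly from class-conditional Gaussians, bypassing imaging to test
  the selection/classification stage at scale.

Megakaryocyte nuclei are rendered as unions of 2–5 overlapping discs
("lobes") laid out along a jittered line, which guarantees high
eccentricity and a maximum caliper above the identification thresholds;
the generator verifies each planted nucleus against the morphometric
filter at build time.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage as ndi

from .featurebuild import feature_columns
from .morphometry import shape_descriptors
from .profiles import ClassProfile, blend_profiles, make_default_profiles

__all__ = [
    "SyntheticROI",
    "PackingError",
    "generate_patient_rois",
    "generate_feature_cohort",
    "generate_nos_patient",
    "class_feature_means",
    "write_cohort",
]

# Rendering constants (8-bit grey levels).  Nuclei are dark on a light
# background; adipocytes sit at background intensity, which is what makes
# background calibration necessary downstream.
BACKGROUND_LEVEL = 232.0
STROMA_LEVEL = 195.0
NUCLEUS_LEVEL = 70.0
MK_NUCLEUS_LEVEL = 64.0
RENDER_BLUR_UM = 0.3
PIXEL_NOISE_SD = 2.0
ADIPOCYTE_NOISE_SD = 1.5

# Geometry defaults: field of view, calibration margin, how much of the
# tissue area is occupied by countable objects, and the minimum gap kept
# between objects so that detection can resolve them.
DEFAULT_ROI_SIZE_UM = 224.0
DEFAULT_PIXEL_SIZE_UM = 0.25
MARGIN_UM = 16.0
OCCUPIED_FRACTION = 0.16
MIN_GAP_UM = 4.0

# Megakaryocyte filter thresholds used for build-time verification, with
# a safety margin over the analysis thresholds (0.8 / 20 µm).
_VERIFY_ECC = 0.82
_VERIFY_CALIPER_UM = 21.0


class PackingError(RuntimeError):
    """Raised when the requested object densities cannot be placed
    without overlap within the attempt budget."""


@dataclass
class SyntheticROI:
    """One rendered ROI with exact ground truth.

    ``nucleus_labels`` and ``adipocyte_labels`` are disjoint labelled
    masks; ``is_megakaryocyte[label - 1]`` flags each nucleus region.
    ``true_cellularity`` always equals nucleated area over nucleated +
    adipocyte area recomputed from the masks.
    """

    image: np.ndarray
    pixel_size_um: float
    nucleus_labels: np.ndarray
    is_megakaryocyte: np.ndarray
    adipocyte_labels: np.ndarray
    true_cellularity: float
    #: polygons are (N, 2) arrays of (x, y) pixel coordinates
    tissue_polygon: np.ndarray
    background_polygon: np.ndarray

    @property
    def n_nuclei(self) -> int:
        return int(self.is_megakaryocyte.size)

    def nucleus_masks(self) -> Iterator[tuple[int, np.ndarray, bool]]:
        """Yield (label, cropped mask, is_megakaryocyte) per nucleus."""
        slices = ndi.find_objects(self.nucleus_labels)
        for lab, sl in enumerate(slices, start=1):
            if sl is None:
                continue
            yield lab, self.nucleus_labels[sl] == lab, bool(
                self.is_megakaryocyte[lab - 1]
            )

    def mask_cellularity(self) -> float:
        """Cellularity recomputed from the stored masks."""
        n = int((self.nucleus_labels > 0).sum())
        a = int((self.adipocyte_labels > 0).sum())
        return n / (n + a) if (n + a) else float("nan")


def _clipped_normal(rng: np.random.Generator, mean: float, sd: float,
                    lo: float, hi: float) -> float:
    x = rng.normal(mean, sd) if sd > 0 else mean
    x = min(max(x, mean - 3.0 * sd), mean + 3.0 * sd)
    return float(min(max(x, lo), hi))


def _disc_mask(radius_px: float) -> np.ndarray:
    r = int(np.ceil(radius_px))
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    return (yy**2 + xx**2) <= radius_px**2


def _pairwise_overlap_coeff(f: float) -> float:
    """Lens area of two unit discs at centre distance f (0 <= f <= 2),
    in units of r^2."""
    if f >= 2.0:
        return 0.0
    return 2.0 * np.arccos(f / 2.0) - (f / 2.0) * np.sqrt(4.0 - f**2)


def _megakaryocyte_mask(
    area_px: float,
    n_lobes: int,
    rng: np.random.Generator,
    pixel_size_um: float,
) -> np.ndarray:
    """Build a lobulated nucleus mask of roughly ``area_px`` pixels that
    passes the eccentricity/caliper filter; verified by measurement."""
    min_caliper_px = _VERIFY_CALIPER_UM / pixel_size_um
    n = max(2, int(n_lobes))
    for _ in range(12):
        for spacing in (1.5, 1.65, 1.8, 1.95):
            ov = _pairwise_overlap_coeff(spacing)
            denom = n * np.pi - (n - 1) * ov
            r = float(np.sqrt(area_px / denom))
            span = (n - 1) * spacing * r + 2.0 * r
            if span < 1.05 * min_caliper_px:
                continue
            theta = rng.uniform(0.0, np.pi)
            d = np.array([np.cos(theta), np.sin(theta)])
            perp = np.array([-d[1], d[0]])
            centers = []
            for i in range(n):
                along = (i - (n - 1) / 2.0) * spacing * r
                jitter = rng.uniform(-0.15, 0.15) * r
                centers.append(along * d + jitter * perp)
            centers = np.asarray(centers)
            radii = r * rng.uniform(0.92, 1.08, size=n)
            pad = int(np.ceil(radii.max())) + 2
            lo = centers.min(axis=0) - pad
            hi = centers.max(axis=0) + pad
            h, w = int(np.ceil(hi[0] - lo[0])), int(np.ceil(hi[1] - lo[1]))
            mask = np.zeros((h, w), dtype=bool)
            yy, xx = np.mgrid[0:h, 0:w]
            for (cy, cx), ri in zip(centers - lo, radii):
                mask |= (yy - cy) ** 2 + (xx - cx) ** 2 <= ri**2
            shape = shape_descriptors(mask, pixel_size_um)
            if (
                shape.eccentricity > _VERIFY_ECC
                and shape.max_caliper_um > _VERIFY_CALIPER_UM
            ):
                return mask
        n = min(n + 1, 5)
        area_px *= 1.1
    raise PackingError(
        "could not construct a megakaryocyte nucleus passing the "
        "eccentricity/caliper filter for the requested area"
    )


def _verify_small_nucleus(radius_px: float, pixel_size_um: float,
                          _cache: dict = {}) -> None:
    """Assert that a small-nucleus disc of this radius FAILS the
    megakaryocyte filter (cached per integer radius)."""
    key = (int(np.ceil(radius_px)), round(pixel_size_um, 6))
    if key in _cache:
        return
    shape = shape_descriptors(_disc_mask(radius_px), pixel_size_um)
    if shape.eccentricity > 0.8 and shape.max_caliper_um > 20.0:
        raise PackingError(
            "planted small nucleus would pass the megakaryocyte filter"
        )
    _cache[key] = True


class _Packer:
    """Sequential non-overlap placement with a minimum-gap guarantee."""

    def __init__(self, tissue_lo: int, tissue_hi_r: int, tissue_hi_c: int,
                 shape: tuple[int, int], gap_px: int,
                 rng: np.random.Generator, max_attempts: int):
        self.occupancy = np.zeros(shape, dtype=bool)
        self.lo = tissue_lo
        self.hi_r = tissue_hi_r
        self.hi_c = tissue_hi_c
        self.gap = gap_px
        self.rng = rng
        self.max_attempts = max_attempts

    def place(self, mask: np.ndarray) -> tuple[int, int] | None:
        """Try to place ``mask``; returns the top-left corner or None."""
        h, w = mask.shape
        if self.hi_r - self.lo <= h or self.hi_c - self.lo <= w:
            return None
        for _ in range(self.max_attempts):
            r0 = int(self.rng.integers(self.lo, self.hi_r - h))
            c0 = int(self.rng.integers(self.lo, self.hi_c - w))
            g = self.gap
            window = self.occupancy[
                max(r0 - g, 0) : r0 + h + g, max(c0 - g, 0) : c0 + w + g
            ]
            if window.any():
                continue
            self.occupancy[r0 : r0 + h, c0 : c0 + w] |= mask
            return r0, c0
        return None


def _generate_roi(
    profile: ClassProfile,
    rng: np.random.Generator,
    roi_size_um: float,
    pixel_size_um: float,
    occupied_fraction: float,
    min_gap_um: float,
    max_attempts: int,
) -> SyntheticROI:
    px = pixel_size_um
    side = int(round(roi_size_um / px))
    margin = int(round(MARGIN_UM / px))
    gap_px = int(round(min_gap_um / px))
    tissue_lo, tissue_hi = margin, side - margin
    tissue_area_px = (tissue_hi - tissue_lo) ** 2

    cellularity = _clipped_normal(
        rng, profile.cellularity_mean, profile.cellularity_sd, 0.05, 0.95
    )
    mk_fraction = _clipped_normal(
        rng, profile.mk_fraction_mean, profile.mk_fraction_sd, 0.0, 1.0
    )

    a_total = occupied_fraction * tissue_area_px
    a_nuc_target = cellularity * a_total
    a_adi_target = (1.0 - cellularity) * a_total
    a_mk_target = mk_fraction * a_nuc_target

    packer = _Packer(tissue_lo, tissue_hi, tissue_hi, (side, side),
                     gap_px, rng, max_attempts)
    nucleus_labels = np.zeros((side, side), dtype=np.int32)
    adipocyte_labels = np.zeros((side, side), dtype=np.int32)
    mk_flags: list[bool] = []
    next_label = 1

    # --- megakaryocyte nuclei -------------------------------------------
    mk_area_mean_px = profile.mk_area_mean_um2 / px**2
    area_floor_um2 = max(120.0, profile.mk_area_mean_um2 - 3 * profile.mk_area_sd_um2)
    placed_mk = 0.0
    while a_mk_target > 0.6 * mk_area_mean_px and placed_mk < a_mk_target - 0.5 * mk_area_mean_px:
        area_um2 = _clipped_normal(
            rng, profile.mk_area_mean_um2, profile.mk_area_sd_um2,
            area_floor_um2, profile.mk_area_mean_um2 + 3 * profile.mk_area_sd_um2,
        )
        mask = _megakaryocyte_mask(area_um2 / px**2, profile.mk_lobulation, rng, px)
        pos = packer.place(mask)
        if pos is None:
            raise PackingError(
                "could not place megakaryocyte nuclei at the requested density"
            )
        r0, c0 = pos
        region = nucleus_labels[r0 : r0 + mask.shape[0], c0 : c0 + mask.shape[1]]
        region[mask] = next_label
        mk_flags.append(True)
        next_label += 1
        placed_mk += float(mask.sum())

    # --- adipocytes ------------------------------------------------------
    r_lo_um, r_hi_um = profile.adipocyte_radius_um_range
    min_adi_um = 6.0  # a trimmed final adipocyte may close the budget
    min_adi_area_px = np.pi * (min_adi_um / px) ** 2
    placed_adi = 0.0
    adi_label = 1
    while a_adi_target - placed_adi > 0.5 * min_adi_area_px:
        remaining = a_adi_target - placed_adi
        r_draw_um = rng.uniform(r_lo_um, r_hi_um)
        r_fit_um = float(np.sqrt(remaining / np.pi) * px)
        r_um = max(min_adi_um, min(r_draw_um, r_fit_um))
        mask = _disc_mask(r_um / px)
        pos = packer.place(mask)
        if pos is None:
            raise PackingError(
                "could not place adipocytes at the requested density"
            )
        r0, c0 = pos
        region = adipocyte_labels[r0 : r0 + mask.shape[0], c0 : c0 + mask.shape[1]]
        region[mask] = adi_label
        adi_label += 1
        placed_adi += float(mask.sum())

    # --- small round nuclei ----------------------------------------------
    small_area_px = profile.small_cell_area_mean_um2 / px**2
    placed_small = 0.0
    target_small = a_nuc_target - placed_mk
    while placed_small < target_small - 0.5 * small_area_px:
        remaining = target_small - placed_small
        area = _clipped_normal(
            rng, small_area_px, 0.15 * small_area_px,
            0.5 * small_area_px, 1.5 * small_area_px,
        )
        area = min(area, remaining + 0.5 * small_area_px)
        r_px = float(np.sqrt(area / np.pi))
        _verify_small_nucleus(r_px, px)
        mask = _disc_mask(r_px)
        pos = packer.place(mask)
        if pos is None:
            raise PackingError(
                "could not place small nuclei at the requested density"
            )
        r0, c0 = pos
        region = nucleus_labels[r0 : r0 + mask.shape[0], c0 : c0 + mask.shape[1]]
        region[mask] = next_label
        mk_flags.append(False)
        next_label += 1
        placed_small += float(mask.sum())

    # --- render -----------------------------------------------------------
    img = np.full((side, side), BACKGROUND_LEVEL, dtype=float)
    img[tissue_lo:tissue_hi, tissue_lo:tissue_hi] = STROMA_LEVEL
    adi = adipocyte_labels > 0
    img[adi] = BACKGROUND_LEVEL + rng.normal(0.0, ADIPOCYTE_NOISE_SD, int(adi.sum()))
    nuc = nucleus_labels > 0
    mk_mask = np.isin(nucleus_labels, np.nonzero(mk_flags)[0] + 1) if any(mk_flags) else None
    img[nuc] = NUCLEUS_LEVEL
    if mk_mask is not None:
        img[mk_mask] = MK_NUCLEUS_LEVEL
    img = ndi.gaussian_filter(img, sigma=RENDER_BLUR_UM / px)
    img = img + rng.normal(0.0, PIXEL_NOISE_SD, img.shape)
    img = np.clip(np.round(img), 0, 255).astype(np.uint8)

    n_area = int(nuc.sum())
    a_area = int(adi.sum())
    true_cellularity = n_area / (n_area + a_area) if (n_area + a_area) else 1.0

    tissue_polygon = np.array(
        [
            (tissue_lo, tissue_lo),
            (tissue_hi - 1, tissue_lo),
            (tissue_hi - 1, tissue_hi - 1),
            (tissue_lo, tissue_hi - 1),
        ],
        dtype=float,
    )
    bg_top = max(4, margin - int(np.ceil(4 * RENDER_BLUR_UM / px)) - 4)
    background_polygon = np.array(
        [(4, 4), (side - 5, 4), (side - 5, bg_top), (4, bg_top)], dtype=float
    )

    return SyntheticROI(
        image=img,
        pixel_size_um=px,
        nucleus_labels=nucleus_labels,
        is_megakaryocyte=np.asarray(mk_flags, dtype=bool),
        adipocyte_labels=adipocyte_labels,
        true_cellularity=float(true_cellularity),
        tissue_polygon=tissue_polygon,
        background_polygon=background_polygon,
    )


def generate_patient_rois(
    profile: ClassProfile,
    n_rois: int,
    seed: int,
    *,
    roi_size_um: float = DEFAULT_ROI_SIZE_UM,
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
    occupied_fraction: float = OCCUPIED_FRACTION,
    min_gap_um: float = MIN_GAP_UM,
    max_attempts: int = 400,
) -> list[SyntheticROI]:
    """Render ``n_rois`` seeded ROIs for one synthetic patient.

    Identical ``(profile, seed)`` pairs produce bit-identical output.
    Raises :class:`PackingError` when the requested densities cannot be
    placed without overlap within ``max_attempts`` tries per object.
    """
    if n_rois < 1:
        raise ValueError("n_rois must be >= 1")
    rois = []
    for i in range(n_rois):
        rng = np.random.default_rng((int(seed), i))
        rois.append(
            _generate_roi(
                profile, rng, roi_size_um, pixel_size_um,
                occupied_fraction, min_gap_um, max_attempts,
            )
        )
    return rois


def generate_nos_patient(
    profile_a: ClassProfile,
    profile_b: ClassProfile,
    mix: float,
    seed: int,
    n_rois: int = 3,
    **kwargs,
) -> list[SyntheticROI]:
    """ROIs for an MPN-NOS-like patient whose generator parameters are
    the convex combination ``(1-mix)*profile_a + mix*profile_b``.

    ``mix=0`` reproduces ``generate_patient_rois(profile_a, ...)``
    exactly, ``mix=1`` reproduces profile_b.
    """
    blended = blend_profiles(profile_a, profile_b, mix)
    return generate_patient_rois(blended, n_rois, seed, **kwargs)


# ---------------------------------------------------------------------------
# Direct feature-cohort generation (bypasses imaging)
# ---------------------------------------------------------------------------

def class_feature_means(profile: ClassProfile) -> pd.Series:
    """Analytic per-class means of the full 21-column feature vector.

    Nuclear area statistics follow the profile's megakaryocyte area
    distribution; the perimeter mean applies a lobulation-dependent shape
    factor to the equivalent-disc perimeter, and the circularity mean is
    its consequence (1/shape_factor²).  Higher-order statistics are mild
    lobulation-dependent defaults.  Density statistics follow the
    megakaryocyte area-fraction distribution, and cellularity is the
    profile's cellularity mean.
    """
    lob = profile.mk_lobulation
    area_mean = profile.mk_area_mean_um2
    sf = 1.0 + 0.15 * (lob - 1)
    perim_mean = 2.0 * np.sqrt(np.pi * area_mean) * sf
    values = {
        "area_mean": area_mean,
        "area_sd": profile.mk_area_sd_um2,
        "area_skewness": 0.2 + 0.05 * lob,
        "area_kurtosis": 0.1 + 0.05 * lob,
        "area_entropy": 1.6 + 0.08 * lob,
        "perimeter_mean": perim_mean,
        "perimeter_sd": 0.5 * perim_mean * profile.mk_area_sd_um2 / area_mean,
        "perimeter_skewness": 0.3 + 0.05 * lob,
        "perimeter_kurtosis": 0.2,
        "perimeter_entropy": 1.7 + 0.05 * lob,
        "circularity_mean": 1.0 / sf**2,
        "circularity_sd": 0.08,
        "circularity_skewness": -0.2 - 0.05 * lob,
        "circularity_kurtosis": 0.2,
        "circularity_entropy": 1.5,
        "density_mean": profile.mk_fraction_mean,
        "density_sd": profile.mk_fraction_sd,
        "density_skewness": 0.1,
        "density_kurtosis": -0.3,
        "density_entropy": 1.0,
        "cellularity": profile.cellularity_mean,
    }
    cols = feature_columns("full")
    return pd.Series([values[c] for c in cols], index=cols, dtype=float)


def generate_feature_cohort(
    profiles: Sequence[ClassProfile],
    n_per_class: int | Sequence[int],
    noise_scale: float = 1.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Draw per-patient feature vectors from class-conditional Gaussians.

    Per-column noise SDs equal ``noise_scale`` times the between-class
    spread of the analytic column means (floored at 5% of the mean column
    magnitude), so the default ``noise_scale=1`` yields roughly 1-SD
    class separation on discriminative columns.  ``noise_scale=0``
    recovers the class means exactly.

    Returns ``(X, y)``: a feature DataFrame indexed by patient id and the
    matching label Series.
    """
    profiles = list(profiles)
    if isinstance(n_per_class, (int, np.integer)):
        counts = [int(n_per_class)] * len(profiles)
    else:
        counts = [int(n) for n in n_per_class]
    if len(counts) != len(profiles):
        raise ValueError("n_per_class length must match profiles")
    if any(n < 2 for n in counts):
        raise ValueError("need at least 2 patients per class")

    means = pd.DataFrame({p.label: class_feature_means(p) for p in profiles}).T
    spread = means.std(axis=0, ddof=0)
    floor = 0.05 * means.abs().mean(axis=0) + 1e-9
    sds = noise_scale * np.maximum(spread, floor)

    rng = np.random.default_rng((int(seed), 9001))
    rows, labels, ids = [], [], []
    for p, n in zip(profiles, counts):
        mu = means.loc[p.label].to_numpy()
        for j in range(n):
            rows.append(mu + rng.normal(0.0, 1.0, mu.size) * sds.to_numpy())
            labels.append(p.label)
            ids.append(f"{p.label}-{j:03d}")
    X = pd.DataFrame(rows, index=pd.Index(ids, name="patient_id"),
                     columns=feature_columns("full"))
    y = pd.Series(labels, index=X.index, name="label")
    return X, y


# ---------------------------------------------------------------------------
# File outputs (TIFF + GeoJSON + manifest CSV)
# ---------------------------------------------------------------------------

def _polygon_geojson(tissue_xy: np.ndarray, background_xy: np.ndarray) -> dict:
    def ring(poly: np.ndarray) -> list:
        pts = [[float(x), float(y)] for x, y in poly]
        return pts + [pts[0]]

    def feat(poly: np.ndarray, name: str) -> dict:
        return {
            "type": "Feature",
            "geometry": {"type": "Polygon", "coordinates": [ring(poly)]},
            "properties": {"classification": name},
        }

    return {
        "type": "FeatureCollection",
        "features": [
            feat(tissue_xy, "Tissue Boundaries"),
            feat(background_xy, "Background"),
        ],
    }


def write_cohort(
    out_dir: str | Path,
    profiles: Sequence[ClassProfile] | None = None,
    n_per_class: Sequence[int] = (19, 30, 39),
    n_rois: int = 3,
    seed: int = 0,
    n_nos: int = 0,
    **roi_kwargs,
) -> Path:
    """Render a full cohort to disk and return the manifest CSV path.

    Writes one TIFF + one GeoJSON annotation file per ROI and a manifest
    CSV with columns patient_id, label, roi_paths, annotation_paths,
    true_cellularity (semicolon-separated path lists).  ``n_nos``
    additional patients are generated from an even blend of the first
    and last profile and labelled ``NOS``.
    """
    if profiles is None:
        profiles = make_default_profiles()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    jobs: list[tuple[ClassProfile, str]] = []
    for profile, n in zip(profiles, n_per_class):
        jobs += [(profile, profile.label)] * int(n)
    if n_nos:
        blended = blend_profiles(profiles[0], profiles[-1], 0.5)
        jobs += [(blended, "NOS")] * int(n_nos)
    rows = []
    for patient_index, (profile, label) in enumerate(jobs):
        pid = f"P{patient_index:03d}"
        rois = generate_patient_rois(
            profile, n_rois, seed=int(seed) * 100_000 + patient_index,
            **roi_kwargs,
        )
        img_paths, ann_paths, cells = [], [], []
        for k, roi in enumerate(rois):
            img_path = out / f"{pid}_roi{k}.tif"
            ann_path = out / f"{pid}_roi{k}.geojson"
            tifffile.imwrite(
                img_path, roi.image,
                resolution=(1e4 / roi.pixel_size_um, 1e4 / roi.pixel_size_um),
            )
            ann_path.write_text(
                json.dumps(
                    _polygon_geojson(roi.tissue_polygon, roi.background_polygon)
                )
            )
            img_paths.append(str(img_path.name))
            ann_paths.append(str(ann_path.name))
            cells.append(roi.true_cellularity)
        rows.append(
            {
                "patient_id": pid,
                "label": label,
                "roi_paths": ";".join(img_paths),
                "annotation_paths": ";".join(ann_paths),
                "pixel_size_um": rois[0].pixel_size_um,
                "true_cellularity": float(np.mean(cells)),
            }
        )
    manifest = out / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest
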