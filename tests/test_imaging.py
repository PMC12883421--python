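import numpy as np
import pytest
from skimage import transform

from mpnmorph.imaging import (
    DetectionParams,
    ROIImage,
    RegionSet,
    UndefinedCellularityError,
    calibrate_background,
    compute_cellularity,
    detect_adipocytes,
    detect_nucleated_cells,
)

PARAMS = DetectionParams()


def _plain_roi(pixels, pixel_size=0.25):
    h, w = pixels.shape
    tissue = np.array([(4, 40), (w - 5, 40), (w - 5, h - 5), (4, h - 5)], float)
    background = np.array([(4, 4), (w - 5, 4), (w - 5, 30), (4, 30)], float)
    return ROIImage(pixels, pixel_size, tissue, background)


# --- background calibration -------------------------------------------------

def test_uniform_background_statistics():
    roi = _plain_roi(np.full((200, 200), 240, dtype=np.uint8))
    bg = calibrate_background(roi)
    assert bg.mean == 240.0 and bg.sd == 0.0


def test_synthetic_background_close_to_generator_constant(pv_roi_image):
    bg = calibrate_background(pv_roi_image)
    assert abs(bg.mean - 232.0) < 1.0


def test_polygon_outside_grid_rejected():
    px = np.zeros((50, 50), dtype=np.uint8)
    bad = np.array([(0, 0), (80, 0), (80, 80)], float)
    with pytest.raises(ValueError, match="outside"):
        ROIImage(px, 0.25, bad, np.array([(0, 0), (5, 0), (5, 5)], float))


def test_empty_background_polygon_signals_missing_annotation():
    px = np.full((60, 60), 200, dtype=np.uint8)
    degenerate = np.array([(1, 1), (1, 1), (1, 1)], float)
    roi = ROIImage(px, 0.25,
                   np.array([(5, 5), (50, 5), (50, 50), (5, 50)], float),
                   degenerate)
    with pytest.raises(ValueError, match="background"):
        calibrate_background(roi)


# --- adipocyte detection ----------------------------------------------------

def test_no_near_background_pixels_gives_empty_set():
    roi = _plain_roi(np.full((200, 200), 195, dtype=np.uint8))
    # background strip at 232 so calibration works
    roi.pixels[:32, :] = 232
    bg = calibrate_background(roi)
    result = detect_adipocytes(roi, PARAMS, bg)
    assert len(result) == 0


def test_planted_adipocytes_recovered(pv_roi, pv_roi_image):
    bg = calibrate_background(pv_roi_image)
    result = detect_adipocytes(pv_roi_image, PARAMS, bg)
    n_true = int(pv_roi.adipocyte_labels.max())
    assert len(result) == n_true
    true_area = (pv_roi.adipocyte_labels > 0).sum() * pv_roi.pixel_size_um**2
    assert result.total_area_um2 == pytest.approx(true_area, rel=0.10)


def test_thin_low_circularity_region_filtered_out():
    """A 2-px-wide near-background bar has 4πA/P² far below 0.3 and is
    removed by the circularity gate (also after watershed splitting)."""
    px = np.full((240, 400), 195.0)
    px[:32, :] = 232.0
    px[120:122, 40:340] = 232.0  # thin bar at background intensity
    roi = _plain_roi(px.astype(np.uint8))
    bg = calibrate_background(roi)
    result = detect_adipocytes(roi, PARAMS, bg)
    assert len(result) == 0


# --- nucleated-cell detection ----------------------------------------------

def test_blank_tissue_has_no_nuclei():
    px = np.full((240, 240), 195, dtype=np.uint8)
    px[:32, :] = 232
    roi = _plain_roi(px)
    assert len(detect_nucleated_cells(roi, PARAMS)) == 0


def test_nucleus_count_close_to_planted(pv_roi, pv_roi_image):
    result = detect_nucleated_cells(pv_roi_image, PARAMS)
    n = pv_roi.n_nuclei
    assert abs(len(result) - n) <= max(1, round(0.05 * n))


def test_oversized_nucleus_excluded_or_split_below_gate():
    """A single 600 µm² round nucleus cannot survive as one region: it is
    either split into sub-gate lobes or dropped by the 400 µm² maximum."""
    px = np.full((300, 300), 195.0)
    px[:32, :] = 232.0
    yy, xx = np.mgrid[:300, :300]
    r_px = np.sqrt(600.0 / np.pi) / 0.25  # 600 µm² at 0.25 µm/px
    px[(yy - 160) ** 2 + (xx - 150) ** 2 <= r_px**2] = 70.0
    roi = _plain_roi(px.astype(np.uint8))
    result = detect_nucleated_cells(roi, PARAMS)
    for region in result:
        assert region.area_um2 <= PARAMS.cell_max_area_um2


def test_detection_deterministic(pv_roi_image):
    a = detect_nucleated_cells(pv_roi_image, PARAMS)
    b = detect_nucleated_cells(pv_roi_image, PARAMS)
    assert np.array_equal(a.labels, b.labels)


def test_missing_pixel_size_rejected(pv_roi_image):
    roi = ROIImage(
        pv_roi_image.pixels, 1.0,
        pv_roi_image.tissue_polygon, pv_roi_image.background_polygon,
    )
    roi.pixel_size_um = 0.0
    with pytest.raises(ValueError):
        detect_nucleated_cells(roi, PARAMS)


def test_scale_consistency_on_downsampled_image(pv_roi, pv_roi_image):
    """Halving the resolution (pixel size doubled) changes measured
    areas in µm² by less than 5%."""
    small = transform.rescale(
        pv_roi_image.pixels.astype(float), 0.5, anti_aliasing=True,
        preserve_range=True,
    )
    roi2 = ROIImage(
        small.astype(np.uint8), pv_roi.pixel_size_um * 2,
        pv_roi_image.tissue_polygon / 2.0,
        pv_roi_image.background_polygon / 2.0,
    )
    a = detect_nucleated_cells(pv_roi_image, PARAMS)
    b = detect_nucleated_cells(roi2, PARAMS)
    assert b.total_area_um2 == pytest.approx(a.total_area_um2, rel=0.05)


# --- cellularity -------------------------------------------------------------

def test_cellularity_formula_and_edge_cases():
    nuclei = RegionSet.from_areas([60.0])
    adip = RegionSet.from_areas([40.0])
    assert compute_cellularity(nuclei, adip) == pytest.approx(0.6)
    assert compute_cellularity(nuclei, RegionSet.from_areas([])) == 1.0
    with pytest.raises(UndefinedCellularityError):
        compute_cellularity(RegionSet.from_areas([]), RegionSet.from_areas([]))


def test_cellularity_monotone_in_composition():
    nuclei = RegionSet.from_areas([50.0, 30.0])
    adip = RegionSet.from_areas([40.0])
    base = compute_cellularity(nuclei, adip)
    more_nuc = compute_cellularity(RegionSet.from_areas([50.0, 30.0, 10.0]), adip)
    more_adi = compute_cellularity(nuclei, RegionSet.from_areas([40.0, 10.0]))
    assert more_nuc > base > more_adi
    assert 0.0 <= more_adi and more_nuc <= 1.0


def test_cellularity_recovery_on_synthetic_roi(pv_roi, pv_roi_image):
    bg = calibrate_background(pv_roi_image)
    adip = detect_adipocytes(pv_roi_image, PARAMS, bg)
    nuclei = detect_nucleated_cells(pv_roi_image, PARAMS)
    est = compute_cellularity(nuclei, adip)
    assert abs(est - pv_roi.true_cellularity) <= 0.05
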