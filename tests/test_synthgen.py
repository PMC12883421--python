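import dataclasses

import numpy as np
import pytest

from mpnmorph.featurebuild import feature_columns
from mpnmorph.model import kruskal_wallis_select
from mpnmorph.morphometry import shape_descriptors
from mpnmorph.synthgen import (
    PackingError,
    class_feature_means,
    generate_feature_cohort,
    generate_nos_patient,
    generate_patient_rois,
)

SMALL = dict(roi_size_um=160.0)  # reduced field of view for fast tests


def test_same_seed_gives_bit_identical_rois(default_profiles):
    _, pv, _ = default_profiles
    a = generate_patient_rois(pv, 2, seed=7, **SMALL)
    b = generate_patient_rois(pv, 2, seed=7, **SMALL)
    for ra, rb in zip(a, b):
        assert np.array_equal(ra.image, rb.image)
        assert np.array_equal(ra.nucleus_labels, rb.nucleus_labels)
        assert np.array_equal(ra.adipocyte_labels, rb.adipocyte_labels)
        assert ra.true_cellularity == rb.true_cellularity
    c = generate_patient_rois(pv, 1, seed=8, **SMALL)[0]
    assert not np.array_equal(a[0].image, c.image)


def test_mask_bookkeeping_and_disjointness(pv_roi):
    assert pv_roi.true_cellularity == pv_roi.mask_cellularity()
    overlap = (pv_roi.nucleus_labels > 0) & (pv_roi.adipocyte_labels > 0)
    assert not overlap.any()
    assert 0.0 <= pv_roi.true_cellularity <= 1.0


def test_planted_shapes_respect_megakaryocyte_filter(pv_roi):
    """Every planted megakaryocyte mask passes the eccentricity/caliper
    filter and every planted small nucleus fails it."""
    for _, mask, is_mk in pv_roi.nucleus_masks():
        s = shape_descriptors(mask, pv_roi.pixel_size_um)
        passes = s.eccentricity > 0.8 and s.max_caliper_um > 20.0
        assert passes == is_mk


def test_zero_megakaryocyte_fraction_plants_none(default_profiles):
    _, pv, _ = default_profiles
    prof = dataclasses.replace(pv, mk_fraction_mean=0.0, mk_fraction_sd=0.0)
    roi = generate_patient_rois(prof, 1, seed=3, **SMALL)[0]
    assert roi.is_megakaryocyte.sum() == 0
    assert roi.n_nuclei > 0


def test_monte_carlo_cellularity_mean_matches_profile(default_profiles):
    """Across many seeds the achieved mask cellularity averages to the
    class mean (clipped-Gaussian draws, adaptive area placement)."""
    _, pv, _ = default_profiles
    vals = [
        generate_patient_rois(pv, 1, seed=s, **SMALL)[0].true_cellularity
        for s in range(1, 201)
    ]
    assert abs(np.mean(vals) - pv.cellularity_mean) < 0.02


def test_impossible_density_raises_packing_error(default_profiles):
    _, pv, _ = default_profiles
    with pytest.raises(PackingError):
        generate_patient_rois(
            pv, 1, seed=1, roi_size_um=120.0,
            occupied_fraction=0.95, max_attempts=25,
        )


def test_nos_blend_endpoints_reproduce_pure_classes(default_profiles):
    pre_pmf, pv, et = default_profiles
    a = generate_nos_patient(et, pv, mix=0.0, seed=3, n_rois=1, **SMALL)[0]
    ref_a = generate_patient_rois(et, 1, seed=3, **SMALL)[0]
    assert np.array_equal(a.image, ref_a.image)
    b = generate_nos_patient(et, pv, mix=1.0, seed=3, n_rois=1, **SMALL)[0]
    ref_b = generate_patient_rois(pv, 1, seed=3, **SMALL)[0]
    assert np.array_equal(b.image, ref_b.image)


def test_feature_cohort_noise_zero_recovers_class_means(default_profiles):
    X, y = generate_feature_cohort(default_profiles, 5, noise_scale=0.0, seed=1)
    assert list(X.columns) == feature_columns("full")
    assert len(X) == 15
    for prof in default_profiles:
        block = X[y == prof.label]
        assert (block == block.iloc[0]).all().all()  # zero within-class spread
        assert np.allclose(block.iloc[0], class_feature_means(prof))


def test_feature_cohort_separated_columns_are_detectable(default_profiles):
    """Columns whose class means differ by >= 1 noise SD come out
    significant in a Kruskal-Wallis screen at n=30 per class."""
    X, y = generate_feature_cohort(default_profiles, 30, noise_scale=1.0, seed=1)
    means = {p.label: class_feature_means(p) for p in default_profiles}
    spread = np.std(
        np.vstack([means[p.label] for p in default_profiles]), axis=0, ddof=0
    )
    sel = kruskal_wallis_select(X, y, alpha=0.05)
    for col, sp in zip(X.columns, spread):
        class_means = [means[p.label][col] for p in default_profiles]
        gap = max(class_means) - min(class_means)
        if sp > 0 and gap >= sp:  # >= 1 SD separation between extremes
            assert sel.table.loc[col, "p"] < 0.05, col


def test_feature_cohort_validates_counts(default_profiles):
    with pytest.raises(ValueError):
        generate_feature_cohort(default_profiles, 1, seed=0)
    with pytest.raises(ValueError):
        generate_feature_cohort(default_profiles, (5, 5), seed=0)
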