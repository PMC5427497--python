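"""Classic feature families: hand-computed texture oracles, invariances,
and the random-forest baseline / quality-filter machinery."""

import numpy as np
import pandas as pd
import pytest

from subloc import synth
from subloc.features import (
    RFGrid,
    _haralick_stats,
    cell_features,
    extract_feature_table,
    gabor_responses,
    glcm_matrix,
    haralick_features,
    intensity_geometry_features,
    select_quality_positives,
    train_quality_filter,
    train_rf_baseline,
    zernike_moments,
)

# ---------------------------------------------------------------------------
# Haralick / GLCM
# ---------------------------------------------------------------------------


def test_glcm_contrast_hand_oracle():
    """[[0,1],[0,1]] with the horizontal offset: symmetric co-occurrences
    {(0,1),(1,0)} each of weight 0.5, so contrast = sum P(i,j)(i-j)^2 = 1."""
    img = np.array([[0.0, 1.0], [0.0, 1.0]])
    glcm = glcm_matrix(img, n_gray_levels=2)
    P = glcm[:, :, 0, 0]  # angle 0 = horizontal neighbor
    np.testing.assert_allclose(P, [[0.0, 0.5], [0.5, 0.0]])
    stats = _haralick_stats(P)
    assert stats[1] == pytest.approx(1.0)  # contrast


def test_constant_image_haralick_conventions():
    fv = haralick_features(np.full((16, 16), 7.0), n_gray_levels=8)
    by_name = dict(zip(fv.names, fv.values))
    assert by_name["har_contrast"] == 0.0
    assert by_name["har_asm"] == 1.0
    assert np.isfinite(fv.values).all()


def test_checkerboard_has_higher_contrast_than_constant():
    checker = np.indices((16, 16)).sum(axis=0) % 2 * 100.0
    c_checker = dict(zip(*[haralick_features(checker).names,
                           haralick_features(checker).values]))["har_contrast"]
    c_flat = dict(zip(*[haralick_features(np.zeros((16, 16))).names,
                        haralick_features(np.zeros((16, 16))).values]))["har_contrast"]
    assert c_checker > c_flat


def test_glcm_is_normalized_for_every_offset(rng):
    img = rng.random((32, 32)) * 1000
    glcm = glcm_matrix(img, n_gray_levels=16)
    for a in range(glcm.shape[3]):
        assert glcm[:, :, 0, a].sum() == pytest.approx(1.0)
        # symmetric matrix
        np.testing.assert_allclose(glcm[:, :, 0, a], glcm[:, :, 0, a].T)


# ---------------------------------------------------------------------------
# Zernike
# ---------------------------------------------------------------------------


def test_zernike_zero_image_gives_zero_magnitudes():
    fv = zernike_moments(np.zeros((64, 64)))
    assert np.all(fv.values == 0)


def test_zernike_rotation_invariance(rng):
    img = rng.random((64, 64)) * 500
    a = zernike_moments(img).values
    b = zernike_moments(np.rot90(img).copy()).values
    np.testing.assert_allclose(a, b, atol=1e-6)


def test_zernike_odd_moment_vanishes_for_radial_symmetry():
    yy, xx = np.mgrid[0:64, 0:64]
    disk = (np.hypot(yy - 31.5, xx - 31.5) <= 10).astype(float)
    fv = zernike_moments(disk)
    assert dict(zip(fv.names, fv.values))["z1_1"] == pytest.approx(0.0, abs=1e-9)


def test_zernike_radius_exceeding_patch_rejected():
    with pytest.raises(ValueError, match="radius"):
        zernike_moments(np.zeros((64, 64)), radius=100)


# ---------------------------------------------------------------------------
# Gabor
# ---------------------------------------------------------------------------


def test_gabor_constant_image_gives_zero_energy():
    fv = gabor_responses(np.full((64, 64), 123.0))
    assert np.all(np.abs(fv.values) < 1e-10)  # zero up to FFT rounding


def test_gabor_orientation_selectivity():
    yy, xx = np.mgrid[0:64, 0:64]
    grating = np.sin(2 * np.pi * 0.15 * xx)  # vertical stripes, horizontal frequency
    fv = gabor_responses(grating, frequencies=(0.15,), orientations=(0.0, 90.0))
    by_name = dict(zip(fv.names, fv.values))
    assert by_name["gab_f0.15_t0_energy"] > 10 * by_name["gab_f0.15_t90_energy"]


def test_gabor_energy_is_quadratic_in_intensity(rng):
    img = rng.random((64, 64))
    e1 = gabor_responses(img).values[1::2]
    e2 = gabor_responses(2 * img).values[1::2]
    np.testing.assert_allclose(e2, 4 * e1, rtol=1e-10)


def test_gabor_empty_bank_rejected():
    with pytest.raises(ValueError, match="empty"):
        gabor_responses(np.zeros((64, 64)), frequencies=())


# ---------------------------------------------------------------------------
# Intensity and geometry
# ---------------------------------------------------------------------------


def test_constant_channel_stats():
    img = np.stack([np.full((64, 64), 42.0), np.zeros((64, 64))])
    fv = intensity_geometry_features(img)
    by_name = dict(zip(fv.names, fv.values))
    assert by_name["r_int_mean"] == 42.0
    assert by_name["r_int_sd"] == 0.0
    assert by_name["r_geo_area"] == 0.0  # degenerate-mask sentinel
    assert np.isfinite(fv.values).all()


def test_disk_mask_area_close_to_analytic():
    yy, xx = np.mgrid[0:64, 0:64]
    disk = (np.hypot(yy - 31.5, xx - 31.5) <= 10).astype(float) * 100
    img = np.stack([disk, disk])
    by_name = dict(zip(*[intensity_geometry_features(img).names,
                         intensity_geometry_features(img).values]))
    assert abs(by_name["r_geo_area"] - np.pi * 100) / (np.pi * 100) < 0.05


def test_channel_swap_swaps_tagged_features(rng):
    img = rng.random((2, 64, 64)) * 900
    fv = intensity_geometry_features(img)
    swapped = intensity_geometry_features(img[::-1].copy())
    a = dict(zip(fv.names, fv.values))
    b = dict(zip(swapped.names, swapped.values))
    for name, val in a.items():
        if name.startswith("r_"):
            assert b["g_" + name[2:]] == val
        elif name.startswith("g_"):
            assert b["r_" + name[2:]] == val


# ---------------------------------------------------------------------------
# Feature table
# ---------------------------------------------------------------------------


def test_feature_vector_finite_on_default_renders():
    for label in synth.CORE_CLASSES + synth.TRANSFER_CLASSES:
        fv = cell_features(synth.render_cell(label, seed=1).pixels)
        assert np.isfinite(fv.values).all(), label
    for kind in synth.ARTIFACT_KINDS:
        fv = cell_features(synth.render_artifact(kind, seed=1).pixels)
        assert np.isfinite(fv.values).all(), kind


def test_feature_width_at_least_200():
    assert len(cell_features(np.zeros((2, 64, 64))).values) >= 200


def test_feature_table_rows_order_and_determinism(tiny_dataset, tiny_feature_table):
    cells = list(tiny_dataset.cells())[:10]
    table, rejects = extract_feature_table(cells)
    assert len(table) == 10 and not rejects
    assert list(table.columns) == list(tiny_feature_table.columns)
    # pure function of pixels: re-extraction is bit-identical
    again, _ = extract_feature_table(cells)
    pd.testing.assert_frame_equal(table, again)
    # shuffling input order permutes rows but not values
    shuffled, _ = extract_feature_table(cells[::-1])
    pd.testing.assert_frame_equal(table.iloc[::-1], shuffled)


# ---------------------------------------------------------------------------
# Random-forest baseline
# ---------------------------------------------------------------------------


def test_rf_grid_sizes():
    assert len(list(RFGrid())) == 5 * 5 * 5
    assert len(list(RFGrid.small())) == 4
    with pytest.raises(ValueError, match="non-empty"):
        RFGrid(n_trees=())


def test_rf_baseline_grid_search(tiny_dataset, tiny_feature_table):
    man = tiny_dataset.manifest.set_index("cell_id")
    fold, labels = man["fold"], man["label"]
    tr = tiny_feature_table.index[fold[tiny_feature_table.index] == "train"]
    va = tiny_feature_table.index[fold[tiny_feature_table.index] == "val"]
    grid = RFGrid(n_trees=(20, 50), features_per_split=("sqrt",), min_node_size=(1, 5))
    model = train_rf_baseline(
        tiny_feature_table.loc[tr], labels[tr], grid,
        tiny_feature_table.loc[va], labels[va], seed=0,
    )
    assert len(model.grid_results) == 4
    # chosen configuration dominates the grid on validation accuracy
    best_acc = model.grid_results["val_accuracy"].max()
    chosen_row = model.grid_results[
        (model.grid_results["n_trees"] == model.chosen["n_trees"])
        & (model.grid_results["min_node_size"] == model.chosen["min_node_size"])
    ]
    assert chosen_row["val_accuracy"].iloc[0] == best_acc


def test_rf_baseline_rejects_single_class(tiny_feature_table):
    with pytest.raises(ValueError, match="two classes"):
        train_rf_baseline(
            tiny_feature_table.iloc[:10], ["nucleus"] * 10, RFGrid.small(),
            tiny_feature_table.iloc[:5], ["nucleus"] * 5,
        )


# ---------------------------------------------------------------------------
# Quality filter
# ---------------------------------------------------------------------------


def test_quality_positive_sampling_arithmetic():
    rows = []
    for cls in synth.CORE_CLASSES:
        for i in range(120):
            rows.append(dict(cell_id=f"{cls}_{i}", label=cls))
    manifest = pd.DataFrame(rows)
    picked = select_quality_positives(manifest, per_class=100, seed=0)
    assert len(picked) == 1200
    assert (picked.groupby("label").size() == 100).all()


def test_quality_positive_both_correct_scheme():
    manifest = pd.DataFrame(
        dict(cell_id=[f"c{i}" for i in range(8)], label=["nucleus"] * 8)
    )
    a = np.array([1, 1, 1, 1, 0, 0, 1, 1], dtype=bool)
    b = np.array([1, 1, 0, 1, 1, 0, 1, 1], dtype=bool)
    picked = select_quality_positives(
        manifest, per_class=10, scheme="both_correct", correct_a=a, correct_b=b
    )
    assert set(picked["cell_id"]) == {"c0", "c1", "c3", "c6", "c7"}


@pytest.fixture(scope="module")
def quality_fixture():
    cells = [synth.render_cell(lbl, seed=s)
             for lbl in synth.CORE_CLASSES for s in range(25)]
    artifacts = [synth.render_artifact(k, seed=s)
                 for k in synth.ARTIFACT_KINDS for s in range(13)]
    cell_table, _ = extract_feature_table(cells)
    art_table, _ = extract_feature_table(artifacts)
    cell_table.index = [f"cell{i}" for i in range(len(cell_table))]
    art_table.index = [f"art{i}" for i in range(len(art_table))]
    return cell_table, art_table


def test_quality_filter_separates_cells_from_artifacts(quality_fixture):
    cell_table, art_table = quality_fixture
    qf = train_quality_filter(cell_table, art_table, cv_folds=10, seed=0)
    assert qf.cv_accuracy >= 0.9
    # applied to a clean manifest, nearly everything is kept
    kept = qf.filter(cell_table)
    assert len(kept) >= 0.9 * len(cell_table)
    # and artifacts are mostly rejected
    assert qf.predict_is_cell(art_table).mean() < 0.5


def test_quality_filter_input_validation(quality_fixture):
    cell_table, art_table = quality_fixture
    with pytest.raises(ValueError, match="non-empty"):
        train_quality_filter(cell_table.iloc[:0], art_table)
    with pytest.raises(ValueError, match="fold"):
        train_quality_filter(cell_table.iloc[:3], art_table.iloc[:3], cv_folds=10)
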