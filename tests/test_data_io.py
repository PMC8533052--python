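"""Image/mask IO round-trips, preprocessing, fold scheme, overlays, config."""

import numpy as np
import pytest
import imageio.v3 as iio

from mfnet.data_io import (DEFAULT_CONFIG, OCTSample, load_mask, load_sample,
                           load_yaml_config, make_folds, preprocess,
                           render_overlay, save_mask)


# ---------------------------------------------------------------------------
# loading and saving
# ---------------------------------------------------------------------------

def test_uint8_image_scales_to_unit_interval(tmp_path):
    arr = np.zeros((10, 12), dtype=np.uint8)
    arr[0, 0] = 255
    arr[5, 5] = 128
    iio.imwrite(tmp_path / "img.png", arr)
    s = load_sample(tmp_path / "img.png")
    assert s.image.max() == pytest.approx(1.0)
    assert s.image[5, 5] == pytest.approx(128 / 255, abs=1e-6)
    assert s.provenance == "unlabeled" and s.mask is None


def test_mask_binarisation_including_stray_values(tmp_path):
    arr = np.zeros((4, 4), dtype=np.uint8)
    arr[0] = 255
    arr[1] = 200       # stray value above the 128 threshold
    arr[2] = 127       # just below
    iio.imwrite(tmp_path / "mask.png", arr)
    m = load_mask(tmp_path / "mask.png")
    assert set(np.unique(m)) <= {0, 1}
    assert m[0].all() and m[1].all()
    assert not m[2].any() and not m[3].any()


def test_mask_roundtrip_is_bit_exact(tmp_path, rng):
    m = (rng.random((16, 16)) > 0.5).astype(np.uint8)
    save_mask(m, tmp_path / "m.png")
    np.testing.assert_array_equal(load_mask(tmp_path / "m.png"), m)


def test_rgb_input_converted_to_luminance(tmp_path):
    rgb = np.zeros((4, 4, 3), dtype=np.uint8)
    rgb[..., 0] = 255
    iio.imwrite(tmp_path / "rgb.png", rgb)
    s = load_sample(tmp_path / "rgb.png")
    assert s.image.ndim == 2
    assert s.image[0, 0] == pytest.approx(0.299, abs=1e-3)


def test_mismatched_mask_dims_raise(tmp_path):
    iio.imwrite(tmp_path / "i.png", np.zeros((8, 8), dtype=np.uint8))
    iio.imwrite(tmp_path / "m.png", np.zeros((4, 4), dtype=np.uint8))
    with pytest.raises(ValueError, match="dims"):
        load_sample(tmp_path / "i.png", tmp_path / "m.png")


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def test_preprocess_resizes_and_keeps_mask_binary(rng):
    img = rng.random((512, 496)).astype(np.float32)
    mask = (rng.random((512, 496)) > 0.8).astype(np.uint8)
    s = preprocess(OCTSample(image=img, mask=mask, id="a"), (256, 256))
    assert s.image.shape == (256, 256)
    assert s.mask.shape == (256, 256)
    assert set(np.unique(s.mask)) <= {0, 1}


def test_preprocess_is_idempotent(rng):
    s = OCTSample(image=rng.random((300, 200)).astype(np.float32),
                  mask=(rng.random((300, 200)) > 0.5).astype(np.uint8),
                  id="a")
    once = preprocess(s, (128, 128))
    twice = preprocess(once, (128, 128))
    np.testing.assert_array_equal(once.image, twice.image)
    np.testing.assert_array_equal(once.mask, twice.mask)


def test_preprocess_rejects_bad_target():
    s = OCTSample(image=np.zeros((64, 64), dtype=np.float32), mask=None, id="a")
    with pytest.raises(ValueError, match="divisible by 16"):
        preprocess(s, (100, 128))


# ---------------------------------------------------------------------------
# folds
# ---------------------------------------------------------------------------

def test_fold_sizes_match_published_split():
    ids = [f"img{i}" for i in range(1522)]
    split = make_folds(ids, k=4, seed=0)
    assert split.sizes() == (380, 380, 380, 382)


@pytest.mark.parametrize("n,k,expected", [
    (4, 4, (1, 1, 1, 1)),
    (10, 4, (2, 2, 2, 4)),
    (9, 3, (3, 3, 3)),
])
def test_fold_size_scheme(n, k, expected):
    split = make_folds([str(i) for i in range(n)], k=k, seed=1)
    assert split.sizes() == expected


def test_folds_partition_and_reproducibility():
    ids = [f"s{i}" for i in range(37)]
    a = make_folds(ids, k=4, seed=5)
    b = make_folds(ids, k=4, seed=5)
    assert a.assignments == b.assignments
    c = make_folds(ids, k=4, seed=6)
    assert c.assignments != a.assignments
    assert sorted(c.sizes()) == sorted(a.sizes())      # size multiset invariant
    for split in (a, c):
        all_ids = [i for f in range(1, 5) for i in split.fold_ids(f)]
        assert sorted(all_ids) == sorted(ids)
        assert sorted(split.train_ids(2) + split.fold_ids(2)) == sorted(ids)


def test_fold_errors():
    with pytest.raises(ValueError, match="empty"):
        make_folds([], k=4)
    with pytest.raises(ValueError, match="cannot fill"):
        make_folds(["a", "b"], k=4)


# ---------------------------------------------------------------------------
# overlays
# ---------------------------------------------------------------------------

def test_overlay_pure_cases(rng):
    img = rng.random((4, 4))
    ones = np.ones((4, 4), dtype=np.uint8)
    zeros = np.zeros((4, 4), dtype=np.uint8)
    assert (render_overlay(ones, ones, img) == (255, 255, 0)).all()
    assert (render_overlay(ones, zeros, img) == (255, 0, 0)).all()
    assert (render_overlay(zeros, ones, img) == (0, 0, 255)).all()
    gray = render_overlay(zeros, zeros, img)
    assert (gray[..., 0] == gray[..., 1]).all() and (gray[..., 1] == gray[..., 2]).all()


def test_overlay_two_by_two_worked_example():
    pred = np.array([[1, 1], [1, 0]], dtype=np.uint8)
    gt = np.array([[1, 0], [1, 1]], dtype=np.uint8)
    rgb = render_overlay(pred, gt, np.zeros((2, 2)))
    flat = rgb.reshape(-1, 3).tolist()
    assert flat.count([255, 255, 0]) == 2
    assert flat.count([255, 0, 0]) == 1
    assert flat.count([0, 0, 255]) == 1


def test_overlay_shape_mismatch():
    with pytest.raises(ValueError, match="mismatch"):
        render_overlay(np.zeros((2, 2)), np.zeros((3, 3)), np.zeros((2, 2)))


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

def test_yaml_config_defaults_and_overrides(tmp_path):
    cfg = load_yaml_config(None)
    assert cfg == DEFAULT_CONFIG
    assert cfg["optim"]["lr"] == 0.0005
    assert cfg["optim"]["weight_decay"] == 0.0001
    assert cfg["optim"]["batch_size"] == 4 and cfg["optim"]["epochs"] == 50
    assert cfg["semi"]["beta"] == 1.0 and cfg["semi"]["pseudo_threshold"] == 0.5
    path = tmp_path / "c.yaml"
    path.write_text("optim:\n  lr: 0.001\nmodel:\n  base_channels: 16\nseed: 9\n")
    cfg2 = load_yaml_config(path)
    assert cfg2["optim"]["lr"] == 0.001
    assert cfg2["optim"]["epochs"] == 50                # default preserved
    assert cfg2["model"]["base_channels"] == 16
    assert cfg2["seed"] == 9
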