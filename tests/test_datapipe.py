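"""Resizing, splitting, augmentation, balancing and leakage checks."""

import numpy as np
import pytest

from lesiontree.datapipe import (
    AugmentationConfig,
    DataError,
    ImageRecord,
    SplitSpec,
    augment_image,
    balance_classes,
    check_leakage,
    class_histogram,
    load_dataset,
    resize_image,
    save_dataset,
    split_dataset,
)


def make_record(image_id="img0", shape=(32, 32), label="a", fill=128, patient=None):
    h, w = shape
    return ImageRecord(
        image_id=image_id,
        pixels=np.full((h, w, 3), fill, dtype=np.uint8),
        label=label,
        patient_id=patient,
    )


# -- resize ----------------------------------------------------------------

@pytest.mark.parametrize("shape", [(448, 448), (224, 224), (187, 300)])
def test_resize_produces_square_rgb(shape):
    rec = make_record(shape=shape)
    out = resize_image(rec, 224)
    assert out.pixels.shape == (224, 224, 3)
    assert out.label == rec.label and out.image_id == rec.image_id


def test_resize_identity_is_pixel_exact():
    rng = np.random.default_rng(0)
    rec = ImageRecord("r", rng.integers(0, 256, (224, 224, 3), dtype=np.uint8), "a")
    out = resize_image(rec, 224)
    assert np.array_equal(out.pixels, rec.pixels)


def test_resize_matches_reference_resampler_on_nonsquare():
    """Direct bilinear policy agrees with Pillow applied independently."""
    from PIL import Image

    rng = np.random.default_rng(1)
    pixels = rng.integers(0, 256, (187, 300, 3), dtype=np.uint8)
    rec = ImageRecord("r", pixels, "a")
    out = resize_image(rec, 224)
    ref = np.asarray(
        Image.fromarray(pixels).resize((224, 224), Image.BILINEAR), dtype=np.uint8
    )
    assert np.array_equal(out.pixels, ref)


def test_non_rgb_rejected():
    with pytest.raises(DataError):
        ImageRecord("x", np.zeros((10, 10), dtype=np.uint8), "a")


# -- split -----------------------------------------------------------------

def test_split_sizes_and_determinism():
    records = [make_record(f"i{k}") for k in range(100)]
    spec = SplitSpec(0.2, seed=5)
    train, test = split_dataset(records, spec)
    assert len(train) == 80 and len(test) == 20
    train2, test2 = split_dataset(records, spec)
    assert [r.image_id for r in test] == [r.image_id for r in test2]
    # disjoint and exhaustive
    ids = {r.image_id for r in train} | {r.image_id for r in test}
    assert len(ids) == 100


def test_split_rounds_half_up():
    records = [make_record(f"i{k}") for k in range(10)]
    _, test = split_dataset(records, SplitSpec(0.25, seed=0))
    assert len(test) == 3  # 2.5 rounds up


def test_patient_grouping_keeps_patients_on_one_side():
    records = [
        make_record(f"i{p}_{j}", patient=f"p{p}") for p in range(10) for j in range(3)
    ]
    train, test = split_dataset(records, SplitSpec(0.2, seed=1, grouping="patient"))
    train_pat = {r.patient_id for r in train}
    test_pat = {r.patient_id for r in test}
    assert not train_pat & test_pat
    assert len(train) + len(test) == 30


def test_patient_grouping_requires_patient_ids():
    records = [make_record(f"i{k}") for k in range(10)]
    with pytest.raises(DataError):
        split_dataset(records, SplitSpec(0.2, seed=0, grouping="patient"))


def test_split_rejects_augmented_records():
    recs = [make_record(f"i{k}") for k in range(9)]
    bad = make_record("aug")
    bad.is_augmented = True
    with pytest.raises(DataError):
        split_dataset(recs + [bad], SplitSpec(0.2, seed=0))


# -- augmentation ----------------------------------------------------------

def test_augment_identity_draw_changes_only_flag():
    rng = np.random.default_rng(0)
    rec = make_record(shape=(64, 64), fill=90)
    cfg = AugmentationConfig(scale_min=1.0, scale_max=1.0, reflect_probability=0.0,
                             output_size=64, target_per_class=10)
    out = augment_image(rec, cfg, rng)
    assert out.is_augmented and not rec.is_augmented
    assert np.array_equal(out.pixels, rec.pixels)
    assert out.label == rec.label and out.source == rec.source


def test_augment_downscale_pads_border_with_zeros():
    """A 0.8x draw on an all-white 224 px image: ~179 px bright center
    block, zero-filled border (geometric construction)."""
    rng = np.random.default_rng(0)
    rec = make_record(shape=(224, 224), fill=255)
    cfg = AugmentationConfig(scale_min=0.8, scale_max=0.8, reflect_probability=0.0)
    out = augment_image(rec, cfg, rng)
    assert out.pixels.shape == (224, 224, 3)
    side = round(0.8 * 224)  # 179
    off = (224 - side) // 2
    assert (out.pixels[:off] == 0).all() and (out.pixels[-off:] == 0).all()
    assert (out.pixels[:, :off] == 0).all() and (out.pixels[:, -off:] == 0).all()
    center = out.pixels[off : off + side, off : off + side]
    assert (center == 255).all()


def test_augment_upscale_center_crops_to_output_size():
    rng = np.random.default_rng(3)
    rec = make_record(shape=(64, 64))
    cfg = AugmentationConfig(scale_min=1.1, scale_max=1.1, output_size=64,
                             target_per_class=10)
    out = augment_image(rec, cfg, rng)
    assert out.pixels.shape == (64, 64, 3)


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_augment_output_size_invariant(seed):
    rng = np.random.default_rng(seed)
    rec = make_record(shape=(64, 64))
    cfg = AugmentationConfig(output_size=64, target_per_class=10)
    out = augment_image(rec, cfg, rng)
    assert out.pixels.shape == (64, 64, 3)


# -- balancing -------------------------------------------------------------

def _tiny_cfg(target):
    return AugmentationConfig(output_size=32, target_per_class=target)


def test_balance_round_robin_hand_trace():
    """Counts {a:3, b:5}, target 7: a gains augments of originals
    1,2,3,1 in order; b gains 2."""
    a = [make_record(f"a{k}", label="a") for k in range(3)]
    b = [make_record(f"b{k}", label="b") for k in range(5)]
    out = balance_classes(a + b, _tiny_cfg(7), seed=0)
    assert class_histogram(out) == {"a": 7, "b": 7}
    added_a = [r for r in out if r.label == "a" and r.is_augmented]
    parents = [r.image_id.split("~")[0] for r in added_a]
    assert parents == ["a0", "a1", "a2", "a0"]
    # originals all retained
    assert {r.image_id for r in a + b} <= {r.image_id for r in out}


def test_balance_class_already_at_target_untouched():
    recs = [make_record(f"a{k}", label="a") for k in range(5)]
    out = balance_classes(recs, _tiny_cfg(5), seed=0)
    assert [r.image_id for r in out] == [r.image_id for r in recs]


def test_balance_uniform_histogram_and_determinism():
    recs = [make_record(f"{c}{k}", label=c) for c in "abc" for k in range((ord(c) - 96) * 2)]
    out1 = balance_classes(recs, _tiny_cfg(9), seed=4)
    out2 = balance_classes(recs, _tiny_cfg(9), seed=4)
    assert class_histogram(out1) == {"a": 9, "b": 9, "c": 9}
    assert [r.image_id for r in out1] == [r.image_id for r in out2]
    for r1, r2 in zip(out1, out2):
        assert np.array_equal(r1.pixels, r2.pixels)


def test_balance_never_downsamples():
    recs = [make_record(f"a{k}", label="a") for k in range(8)]
    with pytest.raises(DataError):
        balance_classes(recs, _tiny_cfg(5), seed=0)


def test_balance_preserves_label_and_source():
    recs = [make_record(f"a{k}", label="a") for k in range(2)]
    out = balance_classes(recs, _tiny_cfg(6), seed=0)
    assert all(r.label == "a" and r.source == "unknown" for r in out)


# -- leakage ---------------------------------------------------------------

def test_leakage_clean_split():
    train = [make_record(f"t{k}", fill=k) for k in range(5)]
    test = [make_record(f"s{k}", fill=100 + k) for k in range(3)]
    assert check_leakage(train, test).is_clean


def test_leakage_duplicate_id_detected():
    rec = make_record("dup")
    rep = check_leakage([rec], [rec])
    assert rep.duplicate_ids == ["dup"]


def test_leakage_content_collision_detected():
    a = make_record("a", fill=7)
    b = make_record("b", fill=7)  # distinct id, identical pixels
    rep = check_leakage([a], [b])
    assert rep.content_collisions == [("a", "b")]


def test_leakage_patient_overlap_detected():
    a = make_record("a", fill=1, patient="p1")
    b = make_record("b", fill=2, patient="p1")
    rep = check_leakage([a], [b])
    assert rep.patient_overlaps == ["p1"]


# -- disk roundtrip --------------------------------------------------------

def test_save_load_roundtrip(tmp_path):
    recs = [make_record(f"{c}{k}", label=c, fill=40 + k, patient=f"p{k}")
            for c in "ab" for k in range(2)]
    save_dataset(recs, tmp_path / "ds")
    loaded = load_dataset(tmp_path / "ds")
    assert {r.image_id for r in loaded} == {r.image_id for r in recs}
    by_id = {r.image_id: r for r in loaded}
    for r in recs:
        assert np.array_equal(by_id[r.image_id].pixels, r.pixels)
        assert by_id[r.image_id].label == r.label
        assert by_id[r.image_id].patient_id == r.patient_id
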