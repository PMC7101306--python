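"""Rendering, decoding, ablation and file round trips."""

import numpy as np
import pytest
from PIL import Image

import tdarx as T
from tdarx.records import JointFinding, iter_joint_keys
from tdarx.rules import Category


def swap_sides(record):
    swapped = record.copy()
    swapped.joints = {("left" if side == "right" else "right", site): jf
                      for (side, site), jf in record.joints.items()}
    return swapped


def test_canvas_dimensions(small_cohort):
    img = T.render_tda(small_cohort[0])
    assert (img.width, img.height) == (871, 494)
    assert img.array.shape == (494, 871, 3)
    assert img.array.dtype == np.uint8


def test_render_is_byte_stable(small_cohort):
    a = T.render_tda(small_cohort[0]).array
    b = T.render_tda(small_cohort[0]).array
    assert np.array_equal(a, b)


def test_layout_invariants(layout):
    assert layout.validate() == []
    assert len(layout.joint_ids()) == 150
    assert len(layout.clinical_ids()) == 14


def test_decode_inverts_render(small_cohort, rules, palette, layout):
    for record in small_cohort[:20]:
        img = T.render_tda(record, rules, palette, layout)
        assert T.decode_tda(img, layout, palette) == \
            T.discretize_record(record, rules)


def test_all_negative_record_renders_green_joints(small_cohort, layout):
    record = small_cohort[0].copy()
    record.joints = {k: JointFinding() for k in iter_joint_keys()}
    cats = T.decode_tda(T.render_tda(record), layout)
    assert all(cats[fid] is Category.GREEN for fid in layout.joint_ids())


def test_mirror_symmetry(small_cohort, layout):
    record = small_cohort[3]
    cats = T.decode_tda(T.render_tda(record), layout)
    cats_swapped = T.decode_tda(T.render_tda(swap_sides(record)), layout)
    for fid in layout.joint_ids():
        mirrored = fid.replace("_right_", "_LEFT_").replace(
            "_left_", "_right_").replace("_LEFT_", "_left_")
        assert cats_swapped[fid] == cats[mirrored]
    # and geometrically, left rectangles are the mirror of right ones
    for fid in layout.joint_ids():
        if "_right_" in fid:
            left = fid.replace("_right_", "_left_")
            assert layout.blocks[left] == layout.mirror_rect(layout.blocks[fid])


def test_missing_value_renders_grey_in_permissive_mode(small_cohort, layout):
    record = small_cohort[0].copy()
    record.acpa = None
    assert T.validate_record(record, allow_missing=True) == []
    cats = T.decode_tda(T.render_tda(record), layout)
    assert cats["acpa"] is Category.MISSING


def test_ablation_partitions_nonbackground(small_cohort, palette):
    record = small_cohort[0]
    full = T.render_tda(record).array
    cru = T.split_ablation(record, "cruciform_only").array
    cli = T.split_ablation(record, "clinical_only").array
    bg = np.array(palette[Category.BACKGROUND], dtype=np.uint8)
    full_mask = (full != bg).any(axis=2)
    cru_mask = (cru != bg).any(axis=2)
    cli_mask = (cli != bg).any(axis=2)
    assert not (cru_mask & cli_mask).any()
    assert np.array_equal(cru_mask | cli_mask, full_mask)


def test_ablation_decodes_only_kept_half(small_cohort, layout, palette):
    record = small_cohort[0]
    cru = T.split_ablation(record, "cruciform_only")
    joint_cats = T.decode_tda(cru, layout, palette, fields=layout.joint_ids())
    assert joint_cats == {fid: cat for fid, cat in
                          T.discretize_record(record).items()
                          if fid.startswith("J_")}
    with pytest.raises(T.UnrecognizedColourError):
        T.decode_tda(cru, layout, palette, fields=["acpa"])


def test_ablation_accepts_image_input(small_cohort):
    img = T.render_tda(small_cohort[0])
    out = T.split_ablation(img, "clinical_only")
    assert out.array.shape == img.array.shape
    assert not np.array_equal(out.array, img.array)


def test_unknown_ablation_mode_raises(small_cohort):
    with pytest.raises(ValueError, match="unknown ablation mode"):
        T.split_ablation(small_cohort[0], "left_half")


def test_all_background_image_is_unrecognized(layout, palette):
    blank = np.full((layout.height, layout.width, 3), 255, dtype=np.uint8)
    with pytest.raises(T.UnrecognizedColourError):
        T.decode_tda(blank, layout, palette)


@pytest.mark.parametrize("fmt", ["tiff", "png"])
def test_file_round_trip_is_lossless(small_cohort, tmp_path, fmt, layout):
    img = T.render_tda(small_cohort[0])
    path = tmp_path / f"img.{fmt}"
    T.write_image(img, path)
    back = T.read_image(path)
    assert np.array_equal(back, img.array)
    with Image.open(path) as pil:
        assert pil.size == (871, 494)
    assert T.decode_tda(back, layout) == T.decode_tda(img, layout)


def test_tiff_and_png_decode_identically(small_cohort, tmp_path, layout):
    img = T.render_tda(small_cohort[1])
    T.write_image(img, tmp_path / "a.tiff")
    T.write_image(img, tmp_path / "a.png")
    assert np.array_equal(T.read_image(tmp_path / "a.tiff"),
                          T.read_image(tmp_path / "a.png"))
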