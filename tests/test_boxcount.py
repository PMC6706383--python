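import numpy as np
import pytest

from forestfrag import (
    BinaryRaster,
    box_count,
    compute_ffi,
    extract_perimeter,
    make_primitive,
)

DYADIC_256 = [2, 4, 8, 16, 32, 64, 128]


def naive_box_count(grid: np.ndarray, eps: int) -> int:
    """Exhaustive per-box scan: the independent oracle."""
    h, w = grid.shape
    n = 0
    for r0 in range(0, h, eps):
        for c0 in range(0, w, eps):
            if grid[r0 : r0 + eps, c0 : c0 + eps].any():
                n += 1
    return n


def test_filled_square_dimension_exactly_two(filled_256):
    res = box_count(filled_256, DYADIC_256)
    assert res.counts == [(256 // e) ** 2 for e in DYADIC_256]
    assert res.slope == pytest.approx(2.0, abs=1e-12)
    assert res.r_squared == pytest.approx(1.0)


def test_full_width_line_dimension_exactly_one():
    line = make_primitive("h_line", (256, 256))
    res = box_count(line, DYADIC_256)
    assert res.counts == [256 // e for e in DYADIC_256]
    assert res.slope == pytest.approx(1.0, abs=1e-12)


def test_single_pixel_dimension_zero(single_pixel_64):
    res = box_count(single_pixel_64, [2, 4, 8, 16, 32])
    assert res.counts == [1] * 5
    assert res.slope == pytest.approx(0.0, abs=1e-12)


def test_counts_non_increasing_with_scale(random_masks_32):
    for mask in random_masks_32:
        res = box_count(mask, [2, 4, 8])
        assert res.counts == sorted(res.counts, reverse=True)


def test_box_count_matches_naive_oracle(random_masks_32):
    scales = [2, 3, 4, 5, 7, 8, 11, 16]
    for mask in random_masks_32:
        res = box_count(mask, scales)
        expected = [naive_box_count(mask.bool(), e) for e in scales]
        assert res.counts == expected


def test_empty_mask_rejected():
    with pytest.raises(ValueError, match="foreground"):
        box_count(BinaryRaster(np.zeros((8, 8), dtype=np.uint8)), [2, 3, 4])


def test_fewer_than_three_scales_rejected(single_pixel_64):
    with pytest.raises(ValueError, match="3 scales"):
        box_count(single_pixel_64, [2, 4])


def test_perimeter_of_single_pixel_is_itself(single_pixel_64):
    np.testing.assert_array_equal(
        extract_perimeter(single_pixel_64).mask, single_pixel_64.mask
    )


def test_perimeter_of_filled_5x5_square_is_16_pixel_frame():
    mask = make_primitive("filled_rect", (9, 9), top=2, left=2, height=5, width=5)
    perim = extract_perimeter(mask)
    assert int(perim.mask.sum()) == 16
    # interior 3x3 removed
    assert perim.mask[4, 4] == 0


def test_perimeter_of_one_pixel_line_is_the_line():
    line = make_primitive("h_line", (16, 16))
    np.testing.assert_array_equal(extract_perimeter(line).mask, line.mask)


def test_image_edge_counts_as_boundary():
    mask = make_primitive("filled_rect", (8, 8))  # touches all image edges
    perim = extract_perimeter(mask)
    assert perim.mask[0, 0] == 1 and perim.mask[3, 3] == 0


def test_ffi_single_pixel_is_zero(single_pixel_64):
    res = compute_ffi(single_pixel_64, [2, 4, 8, 16, 32])
    assert res.ffi == 0.0
    assert res.d_area == res.d_perimeter == pytest.approx(0.0, abs=1e-12)


def test_ffi_filled_square_matches_frame_oracle(filled_256):
    res = compute_ffi(filled_256)
    scales = res.area_fit.scales
    frame_counts = [naive_box_count(extract_perimeter(filled_256).bool(), e) for e in scales]
    assert res.perimeter_fit.counts == frame_counts
    # closed-form frame: every border box occupied, 4*(256/e - 1) of them
    assert frame_counts == [4 * (256 // e - 1) for e in scales]
    assert res.d_area == pytest.approx(2.0, abs=1e-12)
    assert 0.9 <= res.ffi <= 1.05


def test_fragmenting_fixed_area_lowers_ffi():
    """One compact 12x12 square vs nine well-separated 4x4 squares of the
    same 144-pixel total area: fragmentation must lower FFI."""
    compact = make_primitive("filled_rect", (64, 64), top=0, left=0, height=12, width=12)
    scattered = make_primitive("scattered_squares", (64, 64), k=9, side=4, gap=16)
    assert int(compact.mask.sum()) == int(scattered.mask.sum()) == 144
    scales = [2, 4, 8, 16]
    assert compute_ffi(scattered, scales).ffi < compute_ffi(compact, scales).ffi


def test_translation_changes_counts_by_at_most_boundary_boxes():
    mask = make_primitive("filled_rect", (64, 64), top=10, left=10, height=20, width=20)
    shifted = make_primitive("filled_rect", (64, 64), top=11, left=10, height=20, width=20)
    for eps in (2, 4, 8):
        n0 = box_count(mask, [2, 4, 8]).counts
        n1 = box_count(shifted, [2, 4, 8]).counts
    for a, b, eps in zip(n0, n1, (2, 4, 8)):
        boundary_boxes = naive_box_count(extract_perimeter(mask).bool(), eps)
        assert abs(a - b) <= boundary_boxes


def test_determinism(random_masks_32):
    mask = random_masks_32[1]
    a = box_count(mask, [2, 4, 8, 16])
    b = box_count(mask, [2, 4, 8, 16])
    assert a.counts == b.counts and a.slope == b.slope
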