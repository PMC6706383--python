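from collections import deque

import numpy as np
import pytest

from forestfrag import (
    BinaryRaster,
    connected_mass,
    lcfd_at_pixel,
    lcfd_map,
    make_primitive,
)

SCALES_3_33 = list(range(3, 35, 2))


def bfs_connected_mass(grid: np.ndarray, seed, eps: int) -> int:
    """Independent oracle: breadth-first search restricted to the window."""
    r, c = seed
    h = eps // 2
    r0, r1 = max(0, r - h), min(grid.shape[0], r + h + 1)
    c0, c1 = max(0, c - h), min(grid.shape[1], c + h + 1)
    seen = {(r, c)}
    queue = deque([(r, c)])
    while queue:
        rr, cc = queue.popleft()
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                nr, nc = rr + dr, cc + dc
                if (
                    r0 <= nr < r1
                    and c0 <= nc < c1
                    and grid[nr, nc]
                    and (nr, nc) not in seen
                ):
                    seen.add((nr, nc))
                    queue.append((nr, nc))
    return len(seen)


def test_isolated_pixel_mass_is_one(single_pixel_64):
    assert connected_mass(single_pixel_64, (32, 32), 5) == 1
    assert connected_mass(single_pixel_64, (32, 32), 33) == 1


def test_line_center_mass_equals_window_side(h_line_101):
    assert connected_mass(h_line_101, (50, 50), 5) == 5
    assert connected_mass(h_line_101, (50, 50), 21) == 21


def test_filled_region_mass_is_window_area(filled_101):
    assert connected_mass(filled_101, (50, 50), 5) == 25


def test_window_clipped_at_border(filled_101):
    # corner pixel of a filled image: only the inside quadrant counts
    assert connected_mass(filled_101, (0, 0), 5) == 9


def test_background_seed_rejected(single_pixel_64):
    with pytest.raises(ValueError, match="background"):
        connected_mass(single_pixel_64, (0, 0), 5)


def test_disconnected_pixels_in_window_not_counted():
    grid = np.zeros((9, 9), dtype=np.uint8)
    grid[4, 4] = 1
    grid[4, 6] = 1  # inside the 5x5 window but separated by a gap
    assert connected_mass(BinaryRaster(grid), (4, 4), 5) == 1


def test_connected_mass_matches_bfs_oracle(random_masks_32):
    for mask in random_masks_32:
        grid = mask.bool()
        rows, cols = np.nonzero(grid)
        for r, c in list(zip(rows.tolist(), cols.tolist()))[::17]:
            for eps in (3, 5, 9, 15, 31):
                assert connected_mass(mask, (r, c), eps) == bfs_connected_mass(
                    grid, (r, c), eps
                )


def test_line_center_slope_exactly_one(h_line_101):
    assert lcfd_at_pixel(h_line_101, (50, 50), SCALES_3_33) == pytest.approx(1.0, abs=1e-12)


def test_filled_interior_slope_exactly_two(filled_101):
    assert lcfd_at_pixel(filled_101, (50, 50), SCALES_3_33) == pytest.approx(2.0, abs=1e-12)


def test_isolated_pixel_slope_zero(single_pixel_64):
    assert lcfd_at_pixel(single_pixel_64, (32, 32), [3, 5, 7, 9]) == pytest.approx(
        0.0, abs=1e-12
    )


def test_scale_contract():
    line = make_primitive("h_line", (21, 21))
    with pytest.raises(ValueError, match="odd"):
        lcfd_at_pixel(line, (10, 10), [3, 4, 5])
    with pytest.raises(ValueError, match="3 window"):
        lcfd_at_pixel(line, (10, 10), [3, 5])


def test_map_mean_on_line_is_one_with_exclude():
    line = make_primitive("h_line", (31, 31))
    res = lcfd_map(line, scales=[3, 5, 7, 9], border_policy="exclude")
    assert res.mean == pytest.approx(1.0, abs=1e-12)
    assert res.n_pixels == 31 - 2 * 4          # columns with unclipped 9-windows


def test_map_mean_on_filled_is_two_with_exclude():
    full = make_primitive("filled_rect", (31, 31))
    res = lcfd_map(full, scales=[3, 5, 7, 9], border_policy="exclude")
    assert res.mean == pytest.approx(2.0, abs=1e-12)


def test_map_background_stays_zero_and_values_bounded():
    line = make_primitive("h_line", (31, 31))
    res = lcfd_map(line, scales=[3, 5, 7], border_policy="clip")
    assert np.all(res.map.values[line.bool() == 0] == 0)
    fg_vals = res.map.values[line.bool()]
    assert np.all(fg_vals >= -0.1) and np.all(fg_vals <= 2.1)


def test_checkerboard_mean_regression():
    """Frozen from the first run validated against the BFS oracle."""
    board = make_primitive("checkerboard", (33, 33))
    res = lcfd_map(board, scales=[3, 5, 7, 9], border_policy="exclude")
    assert res.mean == pytest.approx(1.91415351626041, rel=1e-12)


def test_map_rotation_equivariance(random_masks_32):
    mask = random_masks_32[2]
    res = lcfd_map(mask, scales=[3, 5, 7], border_policy="clip")
    rotated = BinaryRaster(np.rot90(mask.mask).copy())
    res_rot = lcfd_map(rotated, scales=[3, 5, 7], border_policy="clip")
    np.testing.assert_allclose(res_rot.map.values, np.rot90(res.map.values), atol=1e-12)


def test_map_determinism(random_masks_32):
    mask = random_masks_32[0]
    a = lcfd_map(mask, scales=[3, 5, 7])
    b = lcfd_map(mask, scales=[3, 5, 7])
    np.testing.assert_array_equal(a.map.values, b.map.values)
    assert a.mean == b.mean


def test_empty_mask_rejected():
    with pytest.raises(ValueError, match="foreground"):
        lcfd_map(BinaryRaster(np.zeros((8, 8), dtype=np.uint8)), scales=[3, 5, 7])
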