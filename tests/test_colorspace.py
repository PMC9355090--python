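"""HSV conversion against an independent reference, and mask algebra."""

import colorsys

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from seedlingscreen.colorspace import (
    ColorRange,
    get_color_range,
    in_range,
    load_color_table,
    rgb_to_hsv,
    union_masks,
)

CORNERS = [
    (0, 0, 0),
    (255, 0, 0),
    (0, 255, 0),
    (0, 0, 255),
    (255, 255, 0),
    (255, 0, 255),
    (0, 255, 255),
    (255, 255, 255),
]


def _reference_hsv(r: int, g: int, b: int) -> tuple[float, float, float]:
    """Half-range HSV via the standard library (independent oracle)."""
    h, s, v = colorsys.rgb_to_hsv(r / 255.0, g / 255.0, b / 255.0)
    return h * 360.0 / 2.0, s * 255.0, v * 255.0


@pytest.mark.parametrize(
    "pixel,expected",
    [
        ((255, 0, 0), (0, 255, 255)),
        ((0, 255, 0), (60, 255, 255)),
        ((128, 128, 128), (0, 0, 128)),
    ],
)
def test_known_pixels(pixel, expected):
    out = rgb_to_hsv(np.array([[pixel]], dtype=np.uint8))[0, 0]
    assert tuple(int(c) for c in out) == expected


def test_matches_reference_on_cube_corners_and_random_pixels(rng):
    pixels = np.array(CORNERS + [tuple(p) for p in rng.integers(0, 256, size=(1000, 3))], dtype=np.uint8)
    got = rgb_to_hsv(pixels[None, :, :])[0].astype(float)
    for (r, g, b), (h, s, v) in zip(pixels, got):
        rh, rs, rv = _reference_hsv(int(r), int(g), int(b))
        assert abs(h - rh) <= 1.0, (r, g, b)
        assert abs(s - rs) <= 1.0, (r, g, b)
        assert abs(v - rv) <= 1.0, (r, g, b)


def test_achromatic_pixels_have_zero_saturation(rng):
    levels = rng.integers(0, 256, size=32)
    img = np.stack([levels] * 3, axis=-1).astype(np.uint8)[None]
    hsv = rgb_to_hsv(img)
    assert (hsv[..., 1] == 0).all()
    # black additionally has V = 0
    black = rgb_to_hsv(np.zeros((1, 1, 3), dtype=np.uint8))[0, 0]
    assert black[1] == 0 and black[2] == 0


def test_empty_image_rejected():
    with pytest.raises(ValueError):
        rgb_to_hsv(np.zeros((0, 3, 3), dtype=np.uint8))
    with pytest.raises(ValueError):
        rgb_to_hsv(np.zeros((4, 4), dtype=np.uint8))


@pytest.mark.parametrize(
    "pixel,color,expected",
    [
        ((0, 0, 0), "black", 255),
        ((60, 255, 255), "green", 255),
        ((0, 0, 255), "green", 0),  # white: saturation below s_min
        ((5, 200, 200), "red", 255),  # low hue interval
        ((170, 200, 200), "red", 255),  # wrapped hue interval
        ((85, 200, 200), "red", 0),
        ((85, 200, 200), "cyan", 255),
    ],
)
def test_in_range_pixels(pixel, color, expected):
    hsv = np.array([[pixel]], dtype=np.uint8)
    assert in_range(hsv, get_color_range(color))[0, 0] == expected


def test_in_range_binary_and_inversion(rng):
    hsv = rng.integers(0, 256, size=(20, 20, 3)).astype(np.uint8)
    hsv[..., 0] = np.minimum(hsv[..., 0], 180)
    crange = get_color_range("green")
    mask = in_range(hsv, crange)
    assert set(np.unique(mask)) <= {0, 255}
    # inverting the channel test inverts the mask
    h, s, v = hsv[..., 0], hsv[..., 1], hsv[..., 2]
    inside = (
        (h >= 35) & (h <= 77) & (s >= 43) & (s <= 255) & (v >= 46) & (v <= 255)
    )
    assert ((mask == 255) == inside).all()
    assert ((mask == 0) == ~inside).all()


def test_color_table_contents():
    table = load_color_table()
    assert table["black"].v_max == 46
    assert table["red"].hue_ranges == ((0, 10), (156, 180))
    assert table["ash"] is table["gray"]
    assert table["young"] is table["cyan"]
    with pytest.raises(ValueError):
        ColorRange.from_bounds("bad", 10, 5, 0, 255, 0, 255)


@given(st.integers(0, 2**30))
def test_union_mask_algebra(seed):
    r = np.random.default_rng(seed)
    masks = [(r.random((6, 7)) < 0.4).astype(np.uint8) * 255 for _ in range(3)]
    a, b, c = masks
    zeros = np.zeros_like(a)
    np.testing.assert_array_equal(union_masks([a, zeros]), a)  # identity
    np.testing.assert_array_equal(union_masks([a, a]), a)  # idempotent
    np.testing.assert_array_equal(union_masks([a, b]), union_masks([b, a]))  # commutative
    np.testing.assert_array_equal(  # associative
        union_masks([union_masks([a, b]), c]), union_masks([a, union_masks([b, c])])
    )


def test_union_disjoint_single_pixels():
    a = np.zeros((3, 3), dtype=np.uint8)
    b = np.zeros((3, 3), dtype=np.uint8)
    a[0, 0] = 255
    b[2, 2] = 255
    out = union_masks([a, b])
    assert out[0, 0] == 255 and out[2, 2] == 255 and out.sum() == 510


def test_union_shape_mismatch():
    with pytest.raises(ValueError):
        union_masks([np.zeros((2, 2), np.uint8), np.zeros((3, 3), np.uint8)])
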