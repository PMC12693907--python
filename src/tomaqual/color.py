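"""Fruit color pipeline: gray-world white balance, CIELAB a* extraction,
surface color-ratio measurement and five-level maturity grading.

The a* channel (red–green opponent axis) is computed from sRGB via the
standard inverse companding, the D65 RGB→XYZ matrix and the CIE cube-root
compression; with the matrix's own row sums as the reference white the gray
axis maps exactly to a* = 0.  Surface fractions classify masked pixels by
HSV hue into horticultural red/yellow/green bands; maturity levels 1–5
follow the red-coverage grading used for greenhouse tomato (GH/T 1193-2021
style five-grade system).
"""

from __future__ import annotations

import csv
import json
import os
from dataclasses import dataclass, field

import numpy as np
import shapely
from PIL import Image
from shapely.geometry import Polygon
from skimage.color import rgb2hsv

__all__ = [
    "LabConstants",
    "WhiteBalanceGains",
    "ColorObservation",
    "gray_world_balance",
    "rgb_to_a",
    "a_star_channel",
    "color_ratios",
    "grade_maturity",
    "read_polygon_mask",
    "read_image",
    "write_image",
    "append_observation_csv",
]

#: Hue bands (degrees) for surface color classification; low-saturation
#: pixels are left unclassified ("other") and redistributed proportionally.
RED_HUE = ((0.0, 25.0), (330.0, 360.0))
YELLOW_HUE = (25.0, 70.0)
GREEN_HUE = (70.0, 170.0)
MIN_SATURATION = 0.15


@dataclass
class LabConstants:
    """sRGB→CIELAB constants (D65/2° reference white)."""

    srgb_threshold: float = 0.04045
    srgb_divisor: float = 12.92
    matrix: np.ndarray = field(
        default_factory=lambda: np.array(
            [
                [0.412453, 0.357580, 0.180423],
                [0.212671, 0.715160, 0.072169],
                [0.019334, 0.119193, 0.950227],
            ]
        )
    )
    delta: float = 6.0 / 29.0

    def __post_init__(self):
        if abs(self.matrix[1].sum() - 1.0) > 1e-5:
            raise ValueError("Y row of the RGB→XYZ matrix must sum to 1")

    @property
    def white_point(self) -> np.ndarray:
        # Row sums = XYZ of sRGB white; using them keeps the gray axis at a*=0.
        return self.matrix.sum(axis=1)


@dataclass
class WhiteBalanceGains:
    a_gray: float
    a_r: float
    a_g: float
    a_b: float

    @property
    def s_r(self) -> float:
        return self.a_gray / self.a_r

    @property
    def s_g(self) -> float:
        return self.a_gray / self.a_g

    @property
    def s_b(self) -> float:
        return self.a_gray / self.a_b

    @property
    def gains(self) -> tuple[float, float, float]:
        return (self.s_r, self.s_g, self.s_b)


@dataclass
class ColorObservation:
    a_mean: float
    a_norm: float
    red_fraction: float
    yellow_fraction: float
    green_fraction: float
    maturity_level: int

    def __post_init__(self):
        if not 0.0 <= self.a_norm <= 1.0:
            raise ValueError("a_norm must lie in [0, 1]")


def _check_image(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3 or image.size == 0:
        raise ValueError("image must be a non-empty H×W×3 array")
    return image


def gray_world_balance(image: np.ndarray) -> tuple[np.ndarray, WhiteBalanceGains]:
    """White-balance under the gray-world assumption.

    Channel gains s_c = a_gray / a_c with a_gray the mean of the three
    channel means; the scaled image is rounded half-to-even and clipped to
    the 8-bit range.  Pre-clipping, the balanced channel means are equal by
    construction.
    """
    image = _check_image(image)
    means = image.reshape(-1, 3).mean(axis=0).astype(float)
    if np.any(means == 0):
        raise ValueError("gray-world balance undefined: a channel mean is zero")
    gains = WhiteBalanceGains(float(means.mean()), *means)
    balanced = image.astype(float) * np.array(gains.gains)
    out = np.clip(np.round(balanced), 0, 255).astype(np.uint8)
    return out, gains


def a_star_channel(image: np.ndarray, constants: LabConstants | None = None) -> np.ndarray:
    """Per-pixel CIELAB a* = 500·(f(X/Xn) − f(Y/Yn)) from an 8-bit sRGB image."""
    constants = constants or LabConstants()
    rgb = _check_image(image).astype(float) / 255.0
    thr, div = constants.srgb_threshold, constants.srgb_divisor
    linear = np.where(rgb <= thr, rgb / div, ((rgb + 0.055) / 1.055) ** 2.4)
    xyz = linear @ constants.matrix.T
    t = xyz / constants.white_point
    d = constants.delta
    f = np.where(t > d**3, np.cbrt(t), t / (3 * d * d) + 4.0 / 29.0)
    return 500.0 * (f[..., 0] - f[..., 1])


def rgb_to_a(
    image: np.ndarray, mask: np.ndarray, constants: LabConstants | None = None
) -> tuple[float, float]:
    """Mean fruit a* over the mask and its [0,1] normalization (a+128)/255."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask selects no pixels")
    a = a_star_channel(image, constants)
    a_mean = float(a[mask].mean())
    return a_mean, (a_mean + 128.0) / 255.0


def color_ratios(
    image: np.ndarray,
    mask: np.ndarray,
    min_saturation: float = MIN_SATURATION,
) -> tuple[float, float, float]:
    """Red/yellow/green surface fractions of the masked fruit pixels.

    Each pixel falls in exactly one of {red, yellow, green, other} by HSV
    hue; "other" (including low-saturation pixels) is redistributed
    proportionally so the three fractions sum to 1.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask selects no pixels")
    hsv = rgb2hsv(_check_image(image).astype(float) / 255.0)
    hue = hsv[..., 0][mask] * 360.0
    sat = hsv[..., 1][mask]
    chromatic = sat >= min_saturation
    red = chromatic & (
        ((hue >= RED_HUE[0][0]) & (hue < RED_HUE[0][1]))
        | ((hue >= RED_HUE[1][0]) & (hue < RED_HUE[1][1]))
    )
    yellow = chromatic & (hue >= YELLOW_HUE[0]) & (hue < YELLOW_HUE[1])
    green = chromatic & (hue >= GREEN_HUE[0]) & (hue < GREEN_HUE[1])
    counts = np.array([red.sum(), yellow.sum(), green.sum()], dtype=float)
    classified = counts.sum()
    if classified == 0:
        raise ValueError("no pixel falls in the red/yellow/green hue bands")
    fractions = counts / classified  # proportional redistribution of "other"
    return tuple(float(f) for f in fractions)


def grade_maturity(red_fraction: float, yellow_fraction: float = 0.0) -> int:
    """Five-level maturity from red surface coverage.

    Level 1: essentially no red or yellow (green/white-green surface);
    2: red < 10%; 3: 10–40%; 4: 40–70%; 5: ≥ 70%.  Bins are half-open and
    contiguous so every observation receives a grade.
    """
    if not (0.0 <= red_fraction <= 1.0 and 0.0 <= yellow_fraction <= 1.0):
        raise ValueError("fractions must lie in [0, 1]")
    if red_fraction + yellow_fraction < 0.01:
        return 1
    if red_fraction < 0.10:
        return 2
    if red_fraction < 0.40:
        return 3
    if red_fraction < 0.70:
        return 4
    return 5


def observe(image: np.ndarray, mask: np.ndarray) -> ColorObservation:
    """Full per-fruit color observation from a (white-balanced) image + mask."""
    a_mean, a_norm = rgb_to_a(image, mask)
    r, y, g = color_ratios(image, mask)
    return ColorObservation(a_mean, a_norm, r, y, g, grade_maturity(r, y))


# -- masks and IO ----------------------------------------------------------


def _rasterize(polygons: list[Polygon], shape: tuple[int, int]) -> np.ndarray:
    ys, xs = np.mgrid[0 : shape[0], 0 : shape[1]]
    points = shapely.points(xs.ravel(), ys.ravel())
    mask = np.zeros(shape[0] * shape[1], dtype=bool)
    for poly in polygons:
        mask |= shapely.covers(poly, points)  # boundary-inclusive
    return mask.reshape(shape)


def read_polygon_mask(path, image_shape: tuple[int, int] | None = None):
    """Rasterize a LabelMe-style polygon annotation into a boolean mask.

    Returns (mask, polygons) where polygons is the list of vertex arrays.
    Multiple shapes are unioned.  Zero-area polygons are rejected.
    """
    with open(path) as fh:
        doc = json.load(fh)
    shapes = doc.get("shapes", [])
    if not shapes:
        raise ValueError(f"{path}: no polygon shapes")
    if image_shape is None:
        image_shape = (int(doc["imageHeight"]), int(doc["imageWidth"]))
    polygons, vertices = [], []
    for shape in shapes:
        pts = np.asarray(shape["points"], dtype=float)
        if len(pts) < 3:
            raise ValueError(f"{path}: polygon needs at least 3 vertices")
        poly = Polygon(pts)
        if poly.area == 0:
            raise ValueError(f"{path}: zero-area polygon")
        polygons.append(poly)
        vertices.append(pts)
    mask = _rasterize(polygons, image_shape)
    if not mask.any():
        raise ValueError(f"{path}: mask contains no pixels")
    return mask, vertices


def read_image(path) -> np.ndarray:
    return np.asarray(Image.open(path).convert("RGB"))


def write_image(image: np.ndarray, path) -> None:
    Image.fromarray(np.asarray(image, dtype=np.uint8)).save(path)


_CSV_HEADER = [
    "image",
    "a_mean",
    "a_norm",
    "red_fraction",
    "yellow_fraction",
    "green_fraction",
    "maturity_level",
]


def append_observation_csv(path, image_name: str, obs: ColorObservation) -> None:
    """Append one per-image observation row, writing the header on first use."""
    new = not os.path.exists(path)
    with open(path, "a", newline="") as fh:
        writer = csv.writer(fh)
        if new:
            writer.writerow(_CSV_HEADER)
        writer.writerow(
            [
                image_name,
                f"{obs.a_mean:.6f}",
                f"{obs.a_norm:.6f}",
                f"{obs.red_fraction:.6f}",
                f"{obs.yellow_fraction:.6f}",
                f"{obs.green_fraction:.6f}",
                obs.maturity_level,
            ]
        )
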