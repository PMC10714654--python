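"""Synthetic ultrasound-like phantom images with known ground truth.

Real obstetric scans of the fetal skull and abdomen show a bright elliptical
rim (the skull / abdominal wall cross-section) on a darker background, and
the ossified femoral shaft appears as a bright elongated bar.  The phantom
generator renders exactly those primitives — a hard-edged elliptical ring or
a rotated rectangle — and optionally corrupts them with multiplicative
speckle, the first-order surrogate for ultrasound interference noise:

    noisy = clip(clean * (1 + sigma * G), 0, 1),   G ~ N(0, 1) i.i.d.

Every phantom carries its exact geometry, so head circumference (HC),
biparietal diameter (BPD), abdominal circumference (AC) and femur length
(FL) have analytic ground truths against which the measurement pipeline can
be scored.  Rendering is deterministic: the same spec and seed reproduce the
image bit for bit.

Coordinate convention (used throughout the package): origin at the top-left,
x = column, y = row, angles in degrees counter-clockwise from the +x axis.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.special import ellipe

from .preprocess import Image2D

__all__ = ["PhantomTruth", "generate_phantom", "clean_version"]

KINDS = ("head", "abdomen", "femur")


@dataclass(frozen=True)
class PhantomTruth:
    """Ground-truth geometry and noise parameters of one phantom.

    Ellipse kinds (head, abdomen): ``semi_major_px``/``semi_minor_px`` are
    the OUTER boundary semi-axes and ``rim_thickness_px`` the wall thickness;
    the rim is the region between the outer ellipse (a, b) and the inner
    ellipse (a - t, b - t).  Femur kind: a bar of ``bar_length_px`` x
    ``bar_width_px`` rotated by ``bar_angle_deg``.
    """

    kind: str
    center: tuple[float, float] = (256.0, 256.0)  # (x, y) pixels
    semi_major_px: float | None = None
    semi_minor_px: float | None = None
    rim_thickness_px: float | None = None
    bar_length_px: float | None = None
    bar_width_px: float | None = None
    bar_angle_deg: float = 0.0
    speckle_sigma: float = 0.0
    background_level: float = 0.1
    foreground_level: float = 0.9
    seed: int = 0
    mm_per_pixel: float = 0.2
    canvas: tuple[int, int] = (512, 512)  # (height, width)

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}, got {self.kind!r}")
        if self.speckle_sigma < 0:
            raise ValueError("speckle_sigma must be >= 0")
        if not (0 <= self.background_level <= 1 and 0 <= self.foreground_level <= 1):
            raise ValueError("intensity levels must lie in [0, 1]")
        if self.mm_per_pixel <= 0:
            raise ValueError("mm_per_pixel must be positive")
        if self.kind in ("head", "abdomen"):
            a, b, t = self.semi_major_px, self.semi_minor_px, self.rim_thickness_px
            if a is None or b is None or t is None:
                raise ValueError(f"{self.kind} phantom needs semi axes and rim thickness")
            if not (a >= b > 0):
                raise ValueError("require semi_major_px >= semi_minor_px > 0")
            if not (0 < t < b):
                raise ValueError("require 0 < rim_thickness_px < semi_minor_px")
        else:
            if self.bar_length_px is None or self.bar_width_px is None:
                raise ValueError("femur phantom needs bar_length_px and bar_width_px")
            if self.bar_length_px <= 0 or self.bar_width_px <= 0:
                raise ValueError("bar dimensions must be positive")

    # ---- analytic ground truths, in millimetres -------------------------

    def true_perimeter_px(self) -> float:
        """Exact outer-ellipse perimeter via the complete elliptic integral."""
        a, b = self.semi_major_px, self.semi_minor_px
        if a is None:
            raise ValueError("perimeter is defined only for ellipse phantoms")
        m = 1.0 - (b / a) ** 2
        return float(4.0 * a * ellipe(m))

    def true_hc_mm(self) -> float:
        return self.true_perimeter_px() * self.mm_per_pixel

    true_ac_mm = true_hc_mm

    def true_bpd_outer_mm(self) -> float:
        """Outer-to-outer biparietal diameter (full minor diameter)."""
        return 2.0 * self.semi_minor_px * self.mm_per_pixel

    def true_bpd_outer_to_inner_mm(self) -> float:
        """Outer edge of near wall to inner edge of far wall."""
        return (2.0 * self.semi_minor_px - self.rim_thickness_px) * self.mm_per_pixel

    def true_fl_mm(self) -> float:
        if self.bar_length_px is None:
            raise ValueError("FL truth is defined only for femur phantoms")
        return self.bar_length_px * self.mm_per_pixel

    # ---- (de)serialization ---------------------------------------------

    def to_json(self, path: "str | Path | None" = None) -> str:
        payload = json.dumps(dataclasses.asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_json(cls, text_or_path: "str | Path") -> "PhantomTruth":
        p = Path(str(text_or_path))
        text = p.read_text() if p.exists() else str(text_or_path)
        d = json.loads(text)
        d["center"] = tuple(d["center"])
        d["canvas"] = tuple(d["canvas"])
        return cls(**d)


def clean_version(truth: PhantomTruth) -> PhantomTruth:
    """Same geometry and seed, zero speckle — the noise-free reference."""
    return dataclasses.replace(truth, speckle_sigma=0.0)


def _render_clean(truth: PhantomTruth) -> np.ndarray:
    h, w = truth.canvas
    cx, cy = truth.center
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    dx, dy = xx - cx, yy - cy
    img = np.full((h, w), truth.background_level)

    if truth.kind in ("head", "abdomen"):
        a, b, t = truth.semi_major_px, truth.semi_minor_px, truth.rim_thickness_px
        if cx - a < 1 or cx + a > w - 2 or cy - b < 1 or cy + b > h - 2:
            raise ValueError("ellipse exceeds canvas")
        outer = (dx / a) ** 2 + (dy / b) ** 2 <= 1.0
        inner = (dx / (a - t)) ** 2 + (dy / (b - t)) ** 2 <= 1.0
        img[outer & ~inner] = truth.foreground_level
    else:
        L, W = truth.bar_length_px, truth.bar_width_px
        ang = np.deg2rad(truth.bar_angle_deg)
        # y grows downward, so a CCW angle in the (x, up) frame maps to -ang here
        u = dx * np.cos(ang) - dy * np.sin(ang)
        v = dx * np.sin(ang) + dy * np.cos(ang)
        half_diag = np.hypot(L / 2, W / 2)
        if (
            cx - half_diag < 1
            or cx + half_diag > w - 2
            or cy - half_diag < 1
            or cy + half_diag > h - 2
        ):
            raise ValueError("bar exceeds canvas")
        img[(np.abs(u) <= L / 2) & (np.abs(v) <= W / 2)] = truth.foreground_level
    return img


def generate_phantom(truth: PhantomTruth) -> tuple[Image2D, PhantomTruth]:
    """Render the phantom described by ``truth``.

    Returns the (possibly speckled) image plus the truth record unchanged.
    The speckle field is drawn from ``numpy.random.default_rng(truth.seed)``,
    so (spec, seed) fully determines the output; regenerate with
    :func:`clean_version` to obtain the matching noise-free reference.
    """
    img = _render_clean(truth)
    if truth.speckle_sigma > 0:
        rng = np.random.default_rng(truth.seed)
        g = rng.standard_normal(img.shape)
        img = np.clip(img * (1.0 + truth.speckle_sigma * g), 0.0, 1.0)
    return Image2D(img, truth.mm_per_pixel), truth
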