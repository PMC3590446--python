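"""Analytic deformable nodule templates.

A nodule template is a central-symmetric Gaussian-like gray-level
profile ``q(r) = q_max * exp(-(r/rho)^2)`` truncated at radius ``R``
where it reaches the boundary gray level ``q_min``.  Four shapes are
supported:

* ``circle`` — a single 2D disk (small nodules visible in one slice),
* ``semicircle`` — a half disk (nodules attached to the lung wall),
* ``sphere`` — a 3-layer stack approximating a large solid nodule that
  spans adjacent slices; the outer layers follow the same profile
  evaluated with an inter-slice offset ``v``,
* ``hollow_sphere`` — a sphere with the central part of each layer
  removed (cavity nodules).

The decay parameter ``rho`` is never free: it is pinned to
``rho = R * (ln q_max - ln q_min)^(-1/2)`` so that ``q(R) = q_min``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

SHAPES = ("circle", "semicircle", "sphere", "hollow_sphere")
SHAPES_3D = ("sphere", "hollow_sphere")


def estimate_rho(R: float, q_max: float, q_min: float) -> float:
    """Decay parameter of the Gaussian profile, in pixels.

    Solves ``q_max * exp(-(R/rho)^2) = q_min`` for ``rho``:
    ``rho = R * (ln q_max - ln q_min)^(-1/2)``.
    """
    if R <= 0:
        raise ValueError(f"template radius must be positive, got {R}")
    if not (0 < q_min < q_max):
        raise ValueError(f"need 0 < q_min < q_max, got q_min={q_min}, q_max={q_max}")
    return float(R) * (math.log(q_max) - math.log(q_min)) ** -0.5


@dataclass(frozen=True)
class TemplateSpec:
    """Parametric description of one deformable template.

    Parameters
    ----------
    shape : one of ``circle``, ``semicircle``, ``sphere``, ``hollow_sphere``.
    R : template radius in pixels (in-plane).
    q_max, q_min : peak (center) and boundary gray levels.
    v : inter-slice offset in pixels; only meaningful for 3D shapes.
    angle : orientation in degrees of the semicircle's flat-edge outward
        normal, measured counterclockwise from the +x axis.
    hollow_fraction : fraction of ``R`` removed from the center of a
        hollow sphere's support.
    """

    shape: str
    R: float
    q_max: float = 255.0
    q_min: float = 61.0
    v: float = 7.0
    angle: float | None = None
    hollow_fraction: float = 0.75

    def __post_init__(self) -> None:
        if self.shape not in SHAPES:
            raise ValueError(f"unknown template shape {self.shape!r}")
        if self.R <= 0:
            raise ValueError("R must be positive")
        if not (0 < self.q_min < self.q_max):
            raise ValueError("need 0 < q_min < q_max")
        if self.shape in SHAPES_3D and self.R <= self.v:
            raise ValueError(
                f"3D template needs R > v for real outer-layer radius (R={self.R}, v={self.v})"
            )
        if self.shape == "hollow_sphere" and not (0 < self.hollow_fraction < 1):
            raise ValueError("hollow_fraction must lie in (0, 1)")
        if self.shape == "semicircle" and self.angle is None:
            object.__setattr__(self, "angle", 0.0)

    @property
    def rho(self) -> float:
        return estimate_rho(self.R, self.q_max, self.q_min)

    @property
    def layer_radius(self) -> float:
        """In-plane radius of the upper/lower layer of a 3D template."""
        if self.shape not in SHAPES_3D:
            raise ValueError("layer_radius only defined for 3D shapes")
        return math.sqrt(self.R**2 - self.v**2)


@dataclass(frozen=True)
class TemplateImage:
    """Rendered gray-level stencil of a template.

    ``values`` holds the profile gray levels, ``support`` is the boolean
    mask of pixels that belong to the template (matching is restricted
    to it), ``center`` is the index of the template center within the
    stencil.  2D stencils have shape (side, side); 3D stencils
    (side, side, 3) with axis order (x, y, z).
    """

    values: np.ndarray
    support: np.ndarray
    center: tuple[int, ...]

    @property
    def is_3d(self) -> bool:
        return self.values.ndim == 3


def radial_profile(spec: TemplateSpec, r) -> float | np.ndarray:
    """Gray level of the template at in-plane radius ``r`` (central layer)."""
    r = np.asarray(r, dtype=float)
    if np.any(r < 0) or np.any(r > spec.R):
        raise ValueError(f"r must lie in [0, R={spec.R}]")
    out = spec.q_max * np.exp(-((r / spec.rho) ** 2))
    return float(out) if out.ndim == 0 else out


def offset_profile(spec: TemplateSpec, r, v) -> float | np.ndarray:
    """Gray level at in-plane radius ``r`` on a layer offset by ``v`` pixels.

    ``q_v(r) = q_max * exp(-(r^2 + v^2) / rho^2)``; reduces to
    :func:`radial_profile` at ``v = 0``.
    """
    r = np.asarray(r, dtype=float)
    v = np.asarray(v, dtype=float)
    if np.any(r < 0) or np.any(v < 0):
        raise ValueError("r and v must be non-negative")
    out = spec.q_max * np.exp(-(r**2 + v**2) / spec.rho**2)
    return float(out) if out.ndim == 0 else out


def gray_level_density(spec: TemplateSpec, q) -> float | np.ndarray:
    """Gray-level distribution profile over the 2D Gaussian template.

    ``psi(q | q_min, q_max) = 2 pi R sqrt((ln q_max - ln q)/(ln q_max - ln q_min))``,
    defined for ``q_min <= q <= q_max``; vanishes at ``q_max`` and equals
    ``2 pi R`` at ``q_min``.  The profile is unnormalized; normalize
    numerically when comparing against an empirical histogram.
    """
    q = np.asarray(q, dtype=float)
    if np.any(q < spec.q_min) or np.any(q > spec.q_max):
        raise ValueError(f"q must lie in [q_min={spec.q_min}, q_max={spec.q_max}]")
    ratio = (np.log(spec.q_max) - np.log(q)) / (np.log(spec.q_max) - np.log(spec.q_min))
    out = 2.0 * math.pi * spec.R * np.sqrt(ratio)
    return float(out) if out.ndim == 0 else out


def _layer_grid(R: float):
    c = math.ceil(R)
    side = 2 * c + 1
    dx, dy = np.mgrid[-c : c + 1, -c : c + 1].astype(float)
    return c, side, dx, dy, np.hypot(dx, dy)


@lru_cache(maxsize=512)
def build_template(spec: TemplateSpec) -> TemplateImage:
    """Rasterize a template spec to a gray-level stencil.

    A pixel belongs to the support when its center lies within the
    shape's geometry (Euclidean distance, no anti-aliasing).  Stencils
    are odd-sided so the template center is a single pixel; results are
    deterministic and cached per spec.
    """
    c, side, dx, dy, r = _layer_grid(spec.R)

    if spec.shape in ("circle", "semicircle"):
        support = r <= spec.R
        if spec.shape == "semicircle":
            theta = math.radians(spec.angle)
            # tolerance keeps the flat-edge line intact despite trig rounding
            support &= dx * math.cos(theta) + dy * math.sin(theta) >= -1e-9
        values = np.zeros((side, side))
        values[support] = spec.q_max * np.exp(-((r[support] / spec.rho) ** 2))
        return TemplateImage(values=values, support=support, center=(c, c))

    # 3-layer 3D shapes: central layer at z-offset 0, outer layers at +-v
    r_layer = spec.layer_radius
    values = np.zeros((side, side, 3))
    support = np.zeros((side, side, 3), dtype=bool)
    for k, (rad, voff) in enumerate([(r_layer, spec.v), (spec.R, 0.0), (r_layer, spec.v)]):
        sup = r <= rad
        if spec.shape == "hollow_sphere":
            sup &= r >= spec.hollow_fraction * spec.R
        layer = np.zeros((side, side))
        layer[sup] = spec.q_max * np.exp(-((r[sup] ** 2 + voff**2) / spec.rho**2))
        values[:, :, k] = layer
        support[:, :, k] = sup
    return TemplateImage(values=values, support=support, center=(c, c, 1))
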