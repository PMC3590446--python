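"""Synthetic CT-like phantoms with planted nodules and vessel distractors.

The phantom plants nodules of all four template classes using the same
analytic profiles the matcher probes with, so planted and probed
appearance agree exactly before noise.  Vessel distractors are vertical
tubes whose in-plane cross-sections are small Gaussian-profile disks —
deliberately confusable with circular nodule templates.  Gray levels
default to the template calibration q_max = 255, q_min = 61 over a dark
background of 20, with additive Gaussian noise.  Everything is a pure
function of config + seed, and ground truth is returned alongside.

A companion generator draws labeled (U, q_ave, q_10) feature vectors
for the three training classes (FPN / lung TPN / wall TPN) used by the
false-positive classifier; its class-conditional statistics mirror the
feature statistics that rendered template candidates actually exhibit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .classifier import CLASS_FPN, CLASS_TPN_LUNG, CLASS_TPN_WALL, TrainingSet
from .templates import SHAPES, TemplateSpec, build_template, estimate_rho
from .volume import CandidateRecord, Volume


@dataclass(frozen=True)
class PlantedNodule:
    shape: str
    center: tuple[int, int, int]
    R: float
    angle: float | None = None


@dataclass
class GroundTruth:
    nodules: list  # list[CandidateRecord] with similarity = 1.0 placeholders

    def __len__(self) -> int:
        return len(self.nodules)


def default_nodule_layout(dims: tuple[int, int, int] = (128, 128, 9)) -> list[PlantedNodule]:
    """Ten non-overlapping nodules covering all four shapes, R in [5, 25].

    Laid out on a grid sized for 128 x 128 x 9; positions scale with the
    requested dims.
    """
    nx, ny, nz = dims
    sx, sy = nx / 128.0, ny / 128.0
    zc = nz // 2
    raw = [
        ("sphere", (21, 21, zc), 14, None),
        ("circle", (64, 21, max(1, zc - 1)), 5, None),
        ("sphere", (107, 21, zc), 18, None),
        ("circle", (21, 64, min(nz - 2, zc + 1)), 8, None),
        ("hollow_sphere", (64, 64, zc), 20, None),
        ("semicircle", (107, 64, max(1, zc - 1)), 10, 0.0),
        ("hollow_sphere", (21, 107, zc), 12, None),
        ("semicircle", (64, 107, min(nz - 2, zc + 2)), 7, 90.0),
        ("sphere", (107, 107, zc), 9, None),
        ("circle", (42, 86, max(0, zc - 2)), 11, None),
    ]
    return [
        PlantedNodule(shape, (int(round(x * sx)), int(round(y * sy)), z), R, ang)
        for shape, (x, y, z), R, ang in raw
    ]


@dataclass
class PhantomConfig:
    """Study conditions for one synthetic volume."""

    dims: tuple[int, int, int] = (128, 128, 9)
    background_gray: float = 20.0
    noise_sigma: float = 5.0
    nodules: list = field(default_factory=default_nodule_layout)
    n_vessels: int = 3
    vessel_radius_range: tuple[float, float] = (2.0, 4.0)
    q_max: float = 255.0
    q_min: float = 61.0
    v: float = 7.0
    hollow_fraction: float = 0.75
    seed: int = 0

    def __post_init__(self) -> None:
        for nod in self.nodules:
            if nod.shape not in SHAPES:
                raise ValueError(f"unknown nodule shape {nod.shape!r}")
            if not (5.0 <= nod.R <= 30.0):
                raise ValueError(f"nodule radius {nod.R} outside [5, 30] pixels")


def _nodule_spec(nod: PlantedNodule, cfg: PhantomConfig) -> TemplateSpec:
    return TemplateSpec(shape=nod.shape, R=float(nod.R), q_max=cfg.q_max,
                        q_min=cfg.q_min, v=cfg.v, angle=nod.angle,
                        hollow_fraction=cfg.hollow_fraction)


def _support_coords(nod: PlantedNodule, cfg: PhantomConfig):
    img = build_template(_nodule_spec(nod, cfg))
    offsets = np.argwhere(img.support) - np.array(img.center)
    if offsets.shape[1] == 2:
        offsets = np.hstack([offsets, np.zeros((len(offsets), 1), dtype=int)])
    vals = img.values[img.support]
    return offsets + np.asarray(nod.center), vals


def make_phantom(config: PhantomConfig) -> tuple[Volume, Volume, GroundTruth]:
    """Render (volume, mask, ground truth) for one phantom configuration.

    Nodules are rendered with the template module's stencils; vessels as
    vertical tubes with a Gaussian radial profile spanning the template
    gray range.  The mask marks every voxel whose noiseless foreground
    exceeds the background gray.  Planted nodules must not overlap.
    """
    dims = tuple(int(d) for d in config.dims)
    rng = np.random.default_rng(config.seed)
    clean = np.full(dims, float(config.background_gray))

    claimed = np.zeros(dims, dtype=bool)
    truth = []
    for nod in config.nodules:
        coords, vals = _support_coords(nod, config)
        if coords.min() < 0 or np.any(coords >= np.array(dims)):
            raise ValueError(f"nodule {nod} does not fit inside dims {dims}")
        ix, iy, iz = coords[:, 0], coords[:, 1], coords[:, 2]
        if claimed[ix, iy, iz].any():
            raise ValueError(f"nodule {nod} overlaps a previously planted nodule")
        claimed[ix, iy, iz] = True
        clean[ix, iy, iz] = np.maximum(clean[ix, iy, iz], vals)
        truth.append(CandidateRecord(center=nod.center, shape=nod.shape,
                                     R=float(nod.R), angle=nod.angle, similarity=1.0))

    # vertical vessel tubes, kept clear of every nodule in-plane
    centers_xy = np.array([[n.center[0], n.center[1]] for n in config.nodules], dtype=float)
    radii = np.array([n.R for n in config.nodules], dtype=float)
    xs, ys = np.mgrid[0 : dims[0], 0 : dims[1]].astype(float)
    for _ in range(config.n_vessels):
        rv = float(rng.uniform(*config.vessel_radius_range))
        for _attempt in range(200):
            vx = float(rng.uniform(rv + 1, dims[0] - rv - 2))
            vy = float(rng.uniform(rv + 1, dims[1] - rv - 2))
            if len(centers_xy) == 0:
                break
            gap = np.hypot(centers_xy[:, 0] - vx, centers_xy[:, 1] - vy) - radii - rv
            if gap.min() > 2.0:
                break
        else:
            continue  # no room for this vessel; skip it
        rho_v = estimate_rho(rv, config.q_max, config.q_min)
        r2 = (xs - vx) ** 2 + (ys - vy) ** 2
        disk = r2 <= rv**2
        profile = config.q_max * np.exp(-r2 / rho_v**2)
        for z in range(dims[2]):
            sl = clean[:, :, z]
            sl[disk] = np.maximum(sl[disk], profile[disk])

    mask = (clean > config.background_gray).astype(float)
    noisy = clean + rng.normal(0.0, config.noise_sigma, size=dims) if config.noise_sigma > 0 else clean
    vol = Volume(data=noisy, spacing=(0.4, 0.4, 2.5))
    return vol, Volume(data=mask, spacing=vol.spacing), GroundTruth(nodules=truth)


# ---------------------------------------------------------------------------
# synthetic feature training/test sets
# ---------------------------------------------------------------------------

# Class-conditional feature generators (mean, sd) for (U, q_ave, q_10).
# True nodules are near-round (low U) with gray statistics matching the
# analytic template profile (mean gray ~ (q_max - q_min)/ln(q_max/q_min)
# ~ 120-136 depending on shape, 10%-tile near q_min); false positives —
# vessel fragments and partial structures — pick up background voxels,
# pulling both gray features down, and have elongated borders (high U).
DEFAULT_FEATURE_CLASSES = {
    CLASS_TPN_LUNG: {"U": (2.0, 1.0), "q_ave": (120.0, 20.0), "q_10": (68.0, 8.0)},
    CLASS_TPN_WALL: {"U": (3.0, 1.2), "q_ave": (125.0, 18.0), "q_10": (70.0, 8.0)},
    CLASS_FPN: {"U": (10.0, 2.5), "q_ave": (75.0, 12.0), "q_10": (28.0, 8.0)},
}


def make_feature_training_set(n_per_class: int = 20, seed: int = 0,
                              class_params: dict | None = None) -> TrainingSet:
    """Draw a labeled 3-class feature set (default 20 per class).

    U is truncated at zero; the draw is a pure function of the seed.
    """
    if n_per_class < 2:
        raise ValueError("need at least 2 samples per class")
    params = class_params or DEFAULT_FEATURE_CLASSES
    rng = np.random.default_rng(seed)
    rows, labels = [], []
    for label in sorted(params):
        spec = params[label]
        u = np.abs(rng.normal(*spec["U"], size=n_per_class))
        q_ave = rng.normal(*spec["q_ave"], size=n_per_class)
        q_10 = rng.normal(*spec["q_10"], size=n_per_class)
        rows.append(np.column_stack([u, q_ave, q_10]))
        labels += [label] * n_per_class
    return TrainingSet(samples=np.vstack(rows), labels=np.asarray(labels, dtype=object))
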