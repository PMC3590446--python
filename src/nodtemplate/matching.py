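"""GA-driven deformable template matching.

Position, radius and (for semicircles) orientation of a template are
encoded in a fixed-width bit-string chromosome: 9 + 9 + 5 bits for the
(x, y, z) voxel position and 5 bits for the radius — 28 bits total —
plus a 4-bit orientation gene for semicircular templates.  Fitness is
the normalized cross-correlation (NCC) between the rendered template
and the congruent subvolume cut at the decoded position, restricted to
the template's support.  Each generation applies tournament selection,
single-point crossover (rate 0.75), per-bit mutation (rate 0.05) and a
repair step that snaps off-space locations to the nearest voxel of the
restricted search space.  Every individual ever evaluated above the
similarity threshold (0.8 by default) is harvested as a candidate.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from functools import lru_cache

import numpy as np

from .candidate_space import SearchSpace
from .templates import SHAPES, TemplateImage, TemplateSpec, build_template
from .volume import CandidateRecord, Volume

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# chromosome codec
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChromosomeLayout:
    """Bit widths of the chromosome fields, in order (x, y, z, R[, angle])."""

    x_bits: int = 9
    y_bits: int = 9
    z_bits: int = 5
    r_bits: int = 5
    angle_bits: int = 0  # 4 for semicircular templates

    @property
    def n_bits(self) -> int:
        return self.x_bits + self.y_bits + self.z_bits + self.r_bits + self.angle_bits

    @property
    def field_slices(self) -> dict[str, slice]:
        edges = np.cumsum([0, self.x_bits, self.y_bits, self.z_bits, self.r_bits, self.angle_bits])
        names = ["x", "y", "z", "r", "angle"]
        return {n: slice(int(a), int(b)) for n, a, b in zip(names, edges[:-1], edges[1:])}

    def for_volume(self, dims: tuple[int, int, int]) -> "ChromosomeLayout":
        """Fit position fields to the volume's lattice.

        A field too narrow for its axis is widened so every voxel is
        addressable; a field much wider than the axis is narrowed so the
        decode space is not dominated by out-of-volume positions (which
        would all collapse onto boundary voxels at the repair step).
        """
        widths = {}
        for name, dim, default in zip(("x_bits", "y_bits", "z_bits"), dims,
                                      (self.x_bits, self.y_bits, self.z_bits)):
            widths[name] = max(1, math.ceil(math.log2(dim))) if dim > 1 else 1
            if widths[name] != default:
                log.info("adapting %s from %d to %d bits for volume dim %d",
                         name, default, widths[name], dim)
        return replace(self, **widths)


@dataclass(frozen=True)
class Chromosome:
    bits: tuple[int, ...]
    layout: ChromosomeLayout

    def __post_init__(self) -> None:
        if len(self.bits) != self.layout.n_bits:
            raise ValueError(
                f"chromosome has {len(self.bits)} bits, layout expects {self.layout.n_bits}"
            )


def _int_to_bits(value: int, width: int) -> list[int]:
    if not 0 <= value < 2**width:
        raise ValueError(f"value {value} does not fit in {width} bits")
    return [(value >> (width - 1 - i)) & 1 for i in range(width)]


def _bits_to_int(bits) -> int:
    out = 0
    for b in bits:
        out = (out << 1) | int(b)
    return out


def encode(center: tuple[int, int, int], R: float, angle: float | None,
           layout: ChromosomeLayout, radius_range: tuple[int, int] = (5, 30)) -> Chromosome:
    """Pack (position, radius, orientation) into a big-endian bit string.

    The radius gene stores ``R - R_min``; the angle gene quantizes
    degrees to ``360 / 2**angle_bits`` steps.
    """
    r_min, r_max = radius_range
    if not (r_min <= R <= r_max):
        raise ValueError(f"radius {R} outside configured range {radius_range}")
    bits: list[int] = []
    for value, width in zip(center, (layout.x_bits, layout.y_bits, layout.z_bits)):
        bits += _int_to_bits(int(value), width)
    bits += _int_to_bits(int(round(R)) - r_min, layout.r_bits)
    if layout.angle_bits:
        step = 360.0 / 2**layout.angle_bits
        gene = int(round((angle or 0.0) / step)) % 2**layout.angle_bits
        bits += _int_to_bits(gene, layout.angle_bits)
    return Chromosome(bits=tuple(bits), layout=layout)


def decode(chrom: Chromosome, radius_range: tuple[int, int] = (5, 30)
           ) -> tuple[tuple[int, int, int], int, float | None]:
    """Unpack a chromosome into ((x, y, z), R, angle)."""
    sl = chrom.layout.field_slices
    bits = chrom.bits
    center = tuple(_bits_to_int(bits[sl[n]]) for n in ("x", "y", "z"))
    r_min, r_max = radius_range
    R = min(r_min + _bits_to_int(bits[sl["r"]]), r_max)
    angle = None
    if chrom.layout.angle_bits:
        angle = _bits_to_int(bits[sl["angle"]]) * 360.0 / 2**chrom.layout.angle_bits
    return center, R, angle


# ---------------------------------------------------------------------------
# normalized cross-correlation
# ---------------------------------------------------------------------------

def similarity(a: np.ndarray, b, support: np.ndarray | None = None) -> float:
    """Normalized cross-correlation between a window and a template.

    Sums run over the template's support pixels only.  The score lies in
    [-1, 1] and is invariant to adding a constant to, or positively
    rescaling, either input.  Zero variance over the support in either
    input makes the score undefined; ``-inf`` is returned as the
    non-candidate sentinel.
    """
    if isinstance(b, TemplateImage):
        if support is None:
            support = b.support
        b = b.values
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"window shape {a.shape} does not match template shape {b.shape}")
    if support is None:
        support = np.ones(a.shape, dtype=bool)
    av = a[support]
    bv = b[support]
    if av.size < 2:
        raise ValueError("similarity needs at least 2 support pixels")
    ad = av - av.mean()
    bd = bv - bv.mean()
    denom = math.sqrt(float(ad @ ad) * float(bd @ bd))
    if denom == 0.0:
        return float("-inf")
    return float(np.clip((ad @ bd) / denom, -1.0, 1.0))


class _TemplateKernel:
    """Precomputed support offsets and mean-free values for fast batch NCC."""

    def __init__(self, spec: TemplateSpec):
        img = build_template(spec)
        self.spec = spec
        offsets = np.argwhere(img.support)
        center = np.array(img.center)
        offsets = offsets - center
        if img.values.ndim == 2:  # 2D stencil lives in a single slice
            offsets = np.hstack([offsets, np.zeros((len(offsets), 1), dtype=int)])
        self.offsets = offsets
        tvals = img.values[img.support].astype(float)
        self.tdev = tvals - tvals.mean()
        self.tnorm = math.sqrt(float(self.tdev @ self.tdev))
        self.lo = offsets.min(axis=0)
        self.hi = offsets.max(axis=0)


@lru_cache(maxsize=2048)
def _kernel(spec: TemplateSpec) -> _TemplateKernel:
    return _TemplateKernel(spec)


def evaluate_centers(volume: Volume, spec: TemplateSpec, centers: np.ndarray,
                     chunk_elems: int = 4_000_000) -> np.ndarray:
    """NCC score of one template at many centers (vectorized, chunked).

    Centers whose template window leaves the volume, or whose window has
    zero variance over the support, score ``-inf``.
    """
    centers = np.atleast_2d(np.asarray(centers, dtype=int))
    scores = np.full(len(centers), -np.inf)
    try:
        k = _kernel(spec)
    except ValueError:  # impossible geometry for this decoded radius
        return scores
    if k.tnorm == 0.0:
        return scores
    data = volume.data
    dims = np.array(data.shape)
    valid = np.all(centers + k.lo >= 0, axis=1) & np.all(centers + k.hi < dims, axis=1)
    idx = np.flatnonzero(valid)
    if idx.size == 0:
        return scores
    m = len(k.tdev)
    chunk = max(1, chunk_elems // m)
    for start in range(0, idx.size, chunk):
        sel = idx[start : start + chunk]
        c = centers[sel]
        w = data[
            c[:, 0, None] + k.offsets[None, :, 0],
            c[:, 1, None] + k.offsets[None, :, 1],
            c[:, 2, None] + k.offsets[None, :, 2],
        ]
        wd = w - w.mean(axis=1, keepdims=True)
        denom = np.sqrt(np.einsum("ij,ij->i", wd, wd)) * k.tnorm
        num = wd @ k.tdev
        with np.errstate(divide="ignore", invalid="ignore"):
            s = np.where(denom > 0, num / denom, -np.inf)
        finite = np.isfinite(s)
        s[finite] = np.clip(s[finite], -1.0, 1.0)
        scores[sel] = s
    return scores


def fitness(volume: Volume, chrom: Chromosome, spec_base: TemplateSpec,
            radius_range: tuple[int, int] = (5, 30)) -> float:
    """NCC fitness of one chromosome: build the decoded template, cut the
    congruent subvolume at the decoded center and correlate."""
    center, R, angle = decode(chrom, radius_range)
    try:
        spec = replace(spec_base, R=float(R),
                       angle=angle if spec_base.shape == "semicircle" else spec_base.angle)
    except ValueError:
        return float("-inf")
    return float(evaluate_centers(volume, spec, np.array([center]))[0])


# ---------------------------------------------------------------------------
# GA machinery
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GAConfig:
    """Parameters of the genetic template search."""

    population_size: int = 100
    generations: int = 50
    crossover_rate: float = 0.75
    mutation_rate: float = 0.05
    similarity_threshold: float = 0.8
    immigrant_fraction: float = 0.1
    niche_penalty: float = 0.5
    local_search_elite: int = 3
    seed: int = 0
    radius_range: tuple[int, int] = (5, 30)
    q_max: float = 255.0
    q_min: float = 61.0
    v: float = 7.0
    hollow_fraction: float = 0.75
    layout: ChromosomeLayout = ChromosomeLayout()

    def __post_init__(self) -> None:
        for name in ("crossover_rate", "mutation_rate"):
            rate = getattr(self, name)
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {rate}")
        if not -1.0 < self.similarity_threshold <= 1.0:
            raise ValueError("similarity_threshold must lie in (-1, 1]")
        if self.radius_range[0] >= self.radius_range[1]:
            raise ValueError("radius_range must satisfy R_min < R_max")

    def base_spec(self, shape: str) -> TemplateSpec:
        return TemplateSpec(shape=shape, R=float(self.radius_range[1]),
                            q_max=self.q_max, q_min=self.q_min, v=self.v,
                            hollow_fraction=self.hollow_fraction,
                            angle=0.0 if shape == "semicircle" else None)


def _space_voxels(search_space) -> np.ndarray:
    if isinstance(search_space, SearchSpace):
        return search_space.voxels
    vox = np.asarray(sorted(tuple(v) for v in search_space), dtype=int)
    if vox.ndim != 2 or vox.shape[1] != 3:
        raise ValueError("search space must be a set of (x, y, z) voxels")
    return vox


def repair(chrom: Chromosome, search_space, radius_range: tuple[int, int] = (5, 30)) -> Chromosome:
    """Snap an off-space location to the Euclidean-nearest search-space voxel.

    Ties break lexicographically by (x, y, z); radius and angle genes are
    untouched; an already-valid chromosome is returned unchanged.
    """
    vox = _space_voxels(search_space)
    if len(vox) == 0:
        raise ValueError("search space is empty")
    center, R, angle = decode(chrom, radius_range)
    d2 = np.sum((vox - np.asarray(center)) ** 2, axis=1)
    if d2.min() == 0:
        return chrom
    nearest = vox[int(np.argmin(d2))]  # first minimum = lexicographic winner
    return encode(tuple(int(c) for c in nearest), R, angle, chrom.layout, radius_range)


def _decode_population(pop: np.ndarray, layout: ChromosomeLayout,
                       radius_range: tuple[int, int]):
    sl = layout.field_slices
    def field(name):
        s = sl[name]
        width = s.stop - s.start
        if width == 0:
            return np.zeros(len(pop), dtype=int)
        weights = 2 ** np.arange(width - 1, -1, -1)
        return pop[:, s] @ weights
    centers = np.stack([field("x"), field("y"), field("z")], axis=1)
    radii = np.minimum(radius_range[0] + field("r"), radius_range[1])
    if layout.angle_bits:
        angles = field("angle") * 360.0 / 2**layout.angle_bits
    else:
        angles = np.full(len(pop), np.nan)
    return centers, radii, angles


def _encode_positions(pop: np.ndarray, centers: np.ndarray, layout: ChromosomeLayout) -> None:
    sl = layout.field_slices
    for name, col in zip(("x", "y", "z"), range(3)):
        s = sl[name]
        width = s.stop - s.start
        vals = centers[:, col]
        for i in range(width):
            pop[:, s.start + i] = (vals >> (width - 1 - i)) & 1


def _evaluate_population(volume: Volume, spec_base: TemplateSpec, centers, radii, angles,
                         radius_range) -> np.ndarray:
    fit = np.full(len(centers), -np.inf)
    keys = radii.astype(float) * 1000.0 + np.nan_to_num(angles, nan=-1.0)
    for key in np.unique(keys):
        sel = np.flatnonzero(keys == key)
        R = float(radii[sel[0]])
        ang = angles[sel[0]]
        try:
            spec = replace(spec_base, R=R,
                           angle=float(ang) if spec_base.shape == "semicircle" else spec_base.angle)
        except ValueError:
            continue
        fit[sel] = evaluate_centers(volume, spec, centers[sel])
    return fit


_NB_OFFSETS = np.stack(np.meshgrid([-1, 0, 1], [-1, 0, 1], [-1, 0, 1],
                                   indexing="ij"), axis=-1).reshape(-1, 3)


def _neighborhood_best(volume: Volume, spec_base: TemplateSpec, shape: str,
                       center, R: int, angle, best_fit: float, config: GAConfig,
                       in_space: np.ndarray, ang_step: float | None,
                       note=None):
    """Best (center, R, angle) in the 1-voxel / +-2-radius / +-1-angle-step
    neighborhood, restricted to the search space; ``note`` (if given) is
    called for every above-threshold evaluation.  Returns the improved
    state tuple plus score, or None when the input is already locally best."""
    dims_arr = np.array(volume.shape)
    r_min, r_max = config.radius_range
    nb = np.asarray(center)[None, :] + _NB_OFFSETS
    nb = nb[np.all(nb >= 0, axis=1) & np.all(nb < dims_arr, axis=1)]
    nb = nb[in_space[nb[:, 0], nb[:, 1], nb[:, 2]]]
    if len(nb) == 0:
        return None
    if shape == "semicircle" and ang_step:
        neighbor_angles = [((angle or 0.0) + d * ang_step) % 360.0 for d in (-1, 0, 1)]
    else:
        neighbor_angles = [None]
    best = None
    for R2 in range(max(r_min, int(R) - 2), min(r_max, int(R) + 2) + 1):
        for ang in neighbor_angles:
            try:
                spec = replace(spec_base, R=float(R2),
                               angle=ang if shape == "semicircle" else spec_base.angle)
            except ValueError:
                continue
            sc = evaluate_centers(volume, spec, nb)
            if note is not None:
                for j in np.flatnonzero(sc > config.similarity_threshold):
                    note(int(nb[j, 0]), int(nb[j, 1]), int(nb[j, 2]), R2, ang, float(sc[j]))
            j = int(np.argmax(sc))
            if sc[j] > best_fit:
                best_fit = float(sc[j])
                best = (tuple(int(v) for v in nb[j]), R2, ang, best_fit)
    return best


def polish_candidates(volume: Volume, records: list[CandidateRecord], search_space,
                      config: GAConfig, max_steps: int = 10) -> list[CandidateRecord]:
    """Deterministic hill-climb refinement of matched candidates.

    Each candidate is moved to the best neighboring (position, radius,
    orientation) until locally optimal, staying on the search space;
    this snaps near-misses onto the exact template parameters so the
    downstream features see a support that fits the object."""
    vox = _space_voxels(search_space)
    in_space = np.zeros(volume.shape, dtype=bool)
    in_space[vox[:, 0], vox[:, 1], vox[:, 2]] = True
    ang_step = 360.0 / 2 ** (config.layout.angle_bits or 4)
    out = []
    for rec in records:
        spec_base = config.base_spec(rec.shape)
        state = (rec.center, int(rec.R), rec.angle, rec.similarity)
        for _ in range(max_steps):
            imp = _neighborhood_best(volume, spec_base, rec.shape, state[0], state[1],
                                     state[2], state[3], config, in_space, ang_step)
            if imp is None:
                break
            state = imp
        out.append(CandidateRecord(center=state[0], shape=rec.shape, R=float(state[1]),
                                   angle=state[2] if rec.shape == "semicircle" else None,
                                   similarity=float(state[3])))
    return out


def non_maximum_suppression(records: list[CandidateRecord]) -> list[CandidateRecord]:
    """Greedy dedup: walk candidates by descending similarity and suppress
    any whose center lies within max(R_i, R_j) voxels of an accepted one."""
    ordered = sorted(records, key=lambda r: (-r.similarity, r.center))
    kept: list[CandidateRecord] = []
    for rec in ordered:
        c = np.asarray(rec.center, dtype=float)
        ok = True
        for acc in kept:
            if np.linalg.norm(c - np.asarray(acc.center, dtype=float)) <= max(rec.R, acc.R):
                ok = False
                break
        if ok:
            kept.append(rec)
    return kept


def _harvest_records(harvest: dict, shape: str) -> list[CandidateRecord]:
    records = [
        CandidateRecord(center=(x, y, z), shape=shape, R=float(R),
                        angle=None if ang is None else float(ang), similarity=float(s))
        for (x, y, z, R, ang), s in harvest.items()
    ]
    records.sort(key=lambda r: (-r.similarity, r.center, r.R))
    return records


def ga_search(volume: Volume, search_space, shape: str, config: GAConfig,
              dedup: bool = True) -> list[CandidateRecord]:
    """Genetic template search for one template shape.

    The initial population draws locations uniformly from the search
    space and radius/orientation genes uniformly from their ranges.
    Every individual ever evaluated with NCC above the similarity
    threshold is harvested; the harvest is deduplicated by non-maximum
    suppression unless ``dedup=False``.  Deterministic per config seed.
    """
    if shape not in SHAPES:
        raise ValueError(f"unknown template shape {shape!r}")
    if config.population_size < 2:
        raise ValueError("population_size must be >= 2")
    vox = _space_voxels(search_space)
    if len(vox) == 0:
        raise ValueError("search space is empty")
    rng = np.random.default_rng(config.seed)
    layout = config.layout.for_volume(volume.shape)
    if shape == "semicircle" and layout.angle_bits == 0:
        layout = replace(layout, angle_bits=4)
    if shape != "semicircle":
        layout = replace(layout, angle_bits=0)
    nbits = layout.n_bits
    P = config.population_size
    spec_base = config.base_spec(shape)

    mask_shape = volume.shape
    in_space = np.zeros(mask_shape, dtype=bool)
    in_space[vox[:, 0], vox[:, 1], vox[:, 2]] = True

    def fresh(n: int) -> np.ndarray:
        block = rng.integers(0, 2, size=(n, nbits), dtype=np.int64)
        _encode_positions(block, vox[rng.integers(0, len(vox), size=n)], layout)
        return block

    pop = fresh(P)
    harvest: dict[tuple, float] = {}
    # tabu niche centers: representatives of harvested peaks; selection
    # fitness is derated near them so the search moves on to other modes
    tabu_centers: list[np.ndarray] = []
    tabu_radii: list[float] = []

    def note(x: int, y: int, z: int, R: int, ang, score: float) -> None:
        key = (x, y, z, R, ang)
        if score > harvest.get(key, -np.inf):
            harvest[key] = score
        c = np.array((x, y, z), dtype=float)
        if all(np.linalg.norm(c - tc) > tr for tc, tr in zip(tabu_centers, tabu_radii)):
            tabu_centers.append(c)
            tabu_radii.append(float(max(3, R)))

    ang_step = 360.0 / 2**layout.angle_bits if layout.angle_bits else None

    for gen in range(config.generations):
        centers, radii, angles = _decode_population(pop, layout, config.radius_range)
        fit = _evaluate_population(volume, spec_base, centers, radii, angles,
                                   config.radius_range)
        for i in np.flatnonzero(fit > config.similarity_threshold):
            x, y, z = (int(c) for c in centers[i])
            if not in_space[x, y, z]:
                continue
            ang = None if shape != "semicircle" else float(angles[i])
            note(x, y, z, int(radii[i]), ang, float(fit[i]))
        # niche derating: penalize fitness near already-harvested peaks
        sel_fit = fit.copy()
        if tabu_centers and config.niche_penalty > 0:
            tc = np.asarray(tabu_centers)
            tr = np.asarray(tabu_radii)
            d = np.linalg.norm(centers[:, None, :] - tc[None, :, :], axis=2)
            near = (d <= tr[None, :]).any(axis=1)
            sel_fit[near & np.isfinite(sel_fit)] -= config.niche_penalty
        # memetic step: hill-climb the best few distinct positions,
        # ranked by derated fitness so new modes get refined first
        if config.local_search_elite > 0:
            seen = set()
            for i in np.argsort(sel_fit)[::-1]:
                if not np.isfinite(fit[i]) or fit[i] <= 0 or len(seen) >= config.local_search_elite:
                    break
                pos = tuple(int(v) for v in centers[i])
                if pos in seen:
                    continue
                seen.add(pos)
                a0 = None if shape != "semicircle" else float(angles[i])
                improved = _neighborhood_best(volume, spec_base, shape,
                                              centers[i], int(radii[i]), a0,
                                              float(fit[i]), config, in_space,
                                              ang_step, note=note)
                if improved is not None:
                    (cx, cy, cz), R2, ang, new_fit = improved
                    chrom = encode((cx, cy, cz), R2, ang, layout, config.radius_range)
                    pop[i] = np.asarray(chrom.bits, dtype=np.int64)
                    centers[i] = (cx, cy, cz)
                    fit[i] = new_fit
        if gen % 10 == 0 or gen == config.generations - 1:
            log.info("%s gen %d: best fitness %.3f, harvested %d",
                     shape, gen, float(np.max(fit)), len(harvest))
        if gen == config.generations - 1:
            break

        # tournament selection (size 2) on the niche-derated fitness
        contenders = rng.integers(0, P, size=(2, P))
        winners = np.where(sel_fit[contenders[0]] >= sel_fit[contenders[1]],
                           contenders[0], contenders[1])
        nxt = pop[winners].copy()
        # single-point crossover over consecutive pairs
        for i in range(0, P - 1, 2):
            if rng.random() < config.crossover_rate:
                pt = int(rng.integers(1, nbits))
                tail = nxt[i, pt:].copy()
                nxt[i, pt:] = nxt[i + 1, pt:]
                nxt[i + 1, pt:] = tail
        # per-bit mutation
        flips = rng.random((P, nbits)) < config.mutation_rate
        nxt[flips] ^= 1
        # random immigrants keep exploring other modes
        n_imm = int(round(config.immigrant_fraction * P))
        if n_imm:
            nxt[rng.choice(P, size=n_imm, replace=False)] = fresh(n_imm)
        # repair locations back onto the search space
        centers, _, _ = _decode_population(nxt, layout, config.radius_range)
        inside = (np.all(centers < np.array(mask_shape), axis=1)
                  & in_space[np.minimum(centers[:, 0], mask_shape[0] - 1),
                             np.minimum(centers[:, 1], mask_shape[1] - 1),
                             np.minimum(centers[:, 2], mask_shape[2] - 1)])
        bad = np.flatnonzero(~inside)
        if bad.size:
            d2 = ((vox[None, :, :] - centers[bad][:, None, :]) ** 2).sum(axis=2)
            centers[bad] = vox[np.argmin(d2, axis=1)]
            _encode_positions(nxt, centers, layout)
        pop = nxt

    records = _harvest_records(harvest, shape)
    if not dedup:
        return records
    kept = non_maximum_suppression(records)
    kept = polish_candidates(volume, kept, search_space, config)
    kept = non_maximum_suppression(kept)
    kept.sort(key=lambda r: (-r.similarity, r.center, r.R))
    return kept


def exhaustive_match(volume: Volume, search_space, shape: str,
                     radius_set=None, config: GAConfig | None = None,
                     angles=None, dedup: bool = False) -> list[CandidateRecord]:
    """Brute-force matching at every (location, radius[, angle]) combination.

    The definitive above-threshold candidate set, used as the oracle
    against which the GA's recall is measured on small problems.
    """
    if shape not in SHAPES:
        raise ValueError(f"unknown template shape {shape!r}")
    config = config or GAConfig()
    vox = _space_voxels(search_space)
    if len(vox) == 0:
        raise ValueError("search space is empty")
    r_min, r_max = config.radius_range
    if radius_set is None:
        radius_set = range(int(r_min), int(r_max) + 1)
    if angles is None:
        if shape == "semicircle":
            nang = 2 ** (config.layout.angle_bits or 4)
            angles = [k * 360.0 / nang for k in range(nang)]
        else:
            angles = [None]
    spec_base = config.base_spec(shape)
    harvest: dict[tuple, float] = {}
    for R in radius_set:
        for ang in angles:
            try:
                spec = replace(spec_base, R=float(R),
                               angle=ang if shape == "semicircle" else spec_base.angle)
            except ValueError:
                continue
            scores = evaluate_centers(volume, spec, vox)
            for i in np.flatnonzero(scores > config.similarity_threshold):
                key = (int(vox[i, 0]), int(vox[i, 1]), int(vox[i, 2]), int(R), ang)
                harvest[key] = float(scores[i])
    records = _harvest_records(harvest, shape)
    return non_maximum_suppression(records) if dedup else records
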