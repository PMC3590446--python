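"""False-positive reduction: nodule features and the LCG Bayes classifier.

Each candidate is summarized by three features: (i) radial
nonuniformity ``U`` — the spread ``max - min`` of the center-to-border
distances ``d(theta)`` of the segmented object, sampled at 8 directions;
(ii) the mean gray level ``q_ave`` over the nodular template support;
and (iii) the 10%-tile gray level ``q_10`` of the support's gray-level
distribution.  True and false positives are separated by a naive Bayes
rule with equiprobable priors, treating the features as independent;
each class-conditional feature density is a linear combination of
Gaussians (LCG) with positive and negative components fitted by an
EM-style procedure.  All three features classify nodules inside the
lung; wall-attached (semicircular) nodules use only the two gray-level
features.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates
from scipy.optimize import lsq_linear
from scipy.special import logsumexp
from scipy.stats import norm

from .templates import TemplateSpec, build_template
from .volume import CandidateRecord, Volume

FEATURE_NAMES = ("U", "q_ave", "q_10")
CLASS_FPN = "FPN"
CLASS_TPN_LUNG = "TPN_lung"
CLASS_TPN_WALL = "TPN_wall"
DENSITY_FLOOR = 1e-12


@dataclass(frozen=True)
class NoduleFeatures:
    U: float
    q_ave: float
    q_10: float

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.U, self.q_ave, self.q_10)


# ---------------------------------------------------------------------------
# geometric feature: radial nonuniformity
# ---------------------------------------------------------------------------

def radial_distances(mask: np.ndarray, center: tuple[float, float],
                     n_dirs: int = 8, step: float = 0.25) -> list[float]:
    """Center-to-border distances d(theta) at ``n_dirs`` equally spaced angles.

    Rays are cast from ``center`` over the 2D binary mask with bilinear
    lookup at ``step``-pixel increments; each ray stops at the first
    background crossing (interpolated value < 0.5) after the center and
    reports the distance of the last foreground sample.
    """
    mask = np.asarray(mask, dtype=float)
    if mask.ndim != 2:
        raise ValueError("radial_distances expects a 2D mask slice")
    cx, cy = float(center[0]), float(center[1])
    if map_coordinates(mask, [[cx], [cy]], order=1, cval=0.0)[0] < 0.5:
        raise ValueError(f"center {center} lies on background")
    max_t = math.hypot(*mask.shape)
    ts = np.arange(step, max_t, step)
    distances = []
    for k in range(n_dirs):
        theta = 2.0 * math.pi * k / n_dirs
        xs = cx + ts * math.cos(theta)
        ys = cy + ts * math.sin(theta)
        vals = map_coordinates(mask, [xs, ys], order=1, cval=0.0)
        below = np.flatnonzero(vals < 0.5)
        d = float(ts[below[0] - 1]) if below.size and below[0] > 0 else (
            0.0 if below.size else float(ts[-1]))
        distances.append(d)
    return distances


def radial_nonuniformity(distances) -> float:
    """U = max over directions minus min over directions of d(theta)."""
    distances = np.asarray(distances, dtype=float)
    if distances.size < 2:
        raise ValueError("need at least 2 radial distances")
    return float(distances.max() - distances.min())


def gray_features(volume: Volume, candidate: CandidateRecord,
                  q_max: float = 255.0, q_min: float = 61.0, v: float = 7.0,
                  hollow_fraction: float = 0.75) -> tuple[float, float]:
    """(q_ave, q_10) over the candidate's template support.

    ``q_10`` follows the lower-interpolation convention: the empirical
    10th percentile, i.e. the largest observed value with at least 10%
    of support voxels strictly below it rounds down to a data point.
    """
    spec = TemplateSpec(shape=candidate.shape, R=float(candidate.R), q_max=q_max,
                        q_min=q_min, v=v, angle=candidate.angle,
                        hollow_fraction=hollow_fraction)
    img = build_template(spec)
    offsets = np.argwhere(img.support) - np.array(img.center)
    if offsets.shape[1] == 2:
        offsets = np.hstack([offsets, np.zeros((len(offsets), 1), dtype=int)])
    coords = offsets + np.asarray(candidate.center)
    if coords.min() < 0 or np.any(coords >= np.array(volume.shape)):
        raise ValueError(f"candidate template support at {candidate.center} leaves the volume")
    vals = volume.data[coords[:, 0], coords[:, 1], coords[:, 2]]
    return float(vals.mean()), float(np.percentile(vals, 10.0, method="lower"))


def extract_features(volume: Volume, mask: np.ndarray, candidate: CandidateRecord,
                     n_dirs: int = 8, **gray_kwargs) -> NoduleFeatures:
    """All three features of one candidate; ``mask`` is the candidate-space
    boolean lattice, sliced at the candidate's center slice for d(theta)."""
    x, y, z = candidate.center
    dists = radial_distances(mask[:, :, z], (x, y), n_dirs=n_dirs)
    q_ave, q_10 = gray_features(volume, candidate, **gray_kwargs)
    return NoduleFeatures(U=radial_nonuniformity(dists), q_ave=q_ave, q_10=q_10)


# ---------------------------------------------------------------------------
# LCG density estimation
# ---------------------------------------------------------------------------

@dataclass
class LCGDensity:
    """Linear combination of Gaussians with positive and negative weights.

    The first ``n_pos`` components carry non-negative weights, the
    remaining ``n_neg`` non-positive ones; weights sum to 1 so the
    model integrates to 1 over the real line.  ``eval_range`` is the
    observed feature range padded by three standard deviations.
    """

    weights: np.ndarray
    means: np.ndarray
    sigmas: np.ndarray
    n_pos: int
    n_neg: int
    eval_range: tuple[float, float]
    positive_phase_loglik: list = field(default_factory=list, repr=False)

    def pdf(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        out = np.zeros_like(x, dtype=float)
        for w, m, s in zip(self.weights, self.means, self.sigmas):
            out += w * norm.pdf(x, m, s)
        return out

    def to_dict(self) -> dict:
        return {
            "weights": list(map(float, self.weights)),
            "means": list(map(float, self.means)),
            "sigmas": list(map(float, self.sigmas)),
            "n_pos": self.n_pos,
            "n_neg": self.n_neg,
            "eval_range": list(self.eval_range),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LCGDensity":
        return cls(weights=np.asarray(d["weights"], dtype=float),
                   means=np.asarray(d["means"], dtype=float),
                   sigmas=np.asarray(d["sigmas"], dtype=float),
                   n_pos=int(d["n_pos"]), n_neg=int(d["n_neg"]),
                   eval_range=tuple(d["eval_range"]))


def _em_positive(x: np.ndarray, k: int, rng: np.random.Generator,
                 max_iter: int, tol: float):
    """Standard 1D Gaussian-mixture EM; returns (weights, means, sigmas, loglik trace)."""
    n = len(x)
    qs = (np.arange(k) + 0.5) / k
    means = np.quantile(x, qs).astype(float)
    means += rng.normal(0.0, 1e-9, size=k)  # break exact ties deterministically per seed
    overall_var = float(x.var())
    var_floor = max(overall_var * 1e-6, 1e-12)
    sigmas = np.full(k, math.sqrt(max(overall_var, var_floor)))
    w = np.full(k, 1.0 / k)
    trace = []
    prev = -np.inf
    for _ in range(max_iter):
        logp = np.log(np.maximum(w, 1e-300))[:, None] + norm.logpdf(x[None, :], means[:, None], sigmas[:, None])
        lse = logsumexp(logp, axis=0)
        ll = float(lse.sum())
        trace.append(ll)
        r = np.exp(logp - lse[None, :])
        nk = r.sum(axis=1)
        nk = np.maximum(nk, 1e-12)
        w = nk / n
        means = (r @ x) / nk
        var = np.einsum("kn,kn->k", r, (x[None, :] - means[:, None]) ** 2) / nk
        sigmas = np.sqrt(np.maximum(var, var_floor))
        if np.isfinite(prev) and abs(ll - prev) < tol * max(1.0, abs(ll)):
            break
        prev = ll
    return w, means, sigmas, trace


def fit_lcg(samples, n_pos: int = 2, n_neg: int = 1, seed: int = 0,
            max_iter: int = 500, tol: float = 1e-6) -> LCGDensity:
    """Fit an LCG density to 1D samples.

    The positive components are fitted first by standard EM (monotone
    log-likelihood).  Negative components are then placed greedily on
    the regions where the positive model overshoots the empirical
    histogram, and all weights are jointly refined by sign-constrained
    least squares against the histogram.  The result is renormalized to
    unit weight sum and repaired (negative weights shrunk) until the
    density is non-negative over the padded observed range.
    """
    x = np.asarray(samples, dtype=float).ravel()
    if x.size < 2 * (n_pos + n_neg):
        raise ValueError(f"need at least {2 * (n_pos + n_neg)} samples, got {x.size}")
    if np.ptp(x) == 0:
        raise ValueError("degenerate samples: all values identical")
    if n_pos < 1:
        raise ValueError("need at least one positive component")
    rng = np.random.default_rng(seed)

    w, means, sigmas, trace = _em_positive(x, n_pos, rng, max_iter, tol)
    weights = list(w)
    means = list(means)
    sigmas = list(sigmas)

    if n_neg > 0:
        nbins = min(64, max(10, x.size // 4))
        hist, edges = np.histogram(x, bins=nbins, density=True)
        centers = 0.5 * (edges[:-1] + edges[1:])
        binw = edges[1] - edges[0]
        for _ in range(n_neg):
            model = np.zeros_like(centers)
            for wk, mk, sk in zip(weights, means, sigmas):
                model += wk * norm.pdf(centers, mk, sk)
            over = np.clip(model - hist, 0.0, None)
            mass = float(over.sum() * binw)
            if mass > 1e-10:
                mu = float((over * centers).sum() / over.sum())
                var = float((over * (centers - mu) ** 2).sum() / over.sum())
                sg = math.sqrt(max(var, (0.5 * binw) ** 2))
                wneg = min(mass, 0.2)
            else:  # nothing to subtract; keep a vanishing component
                mu, sg, wneg = float(np.mean(x)), float(np.std(x)), 1e-8
            weights.append(-wneg)
            means.append(mu)
            sigmas.append(sg)
        # joint refinement of weights, means/sigmas fixed
        A = np.column_stack([norm.pdf(centers, mk, sk) for mk, sk in zip(means, sigmas)])
        lb = np.array([0.0] * n_pos + [-np.inf] * n_neg)
        ub = np.array([np.inf] * n_pos + [0.0] * n_neg)
        try:
            res = lsq_linear(A, hist, bounds=(lb, ub))
            refined = res.x
            if refined[:n_pos].sum() > 0.1:
                weights = list(refined)
        except Exception:
            pass

    weights = np.asarray(weights, dtype=float)
    means = np.asarray(means, dtype=float)
    sigmas = np.asarray(sigmas, dtype=float)
    total = weights.sum()
    if total <= 0:
        raise ValueError("LCG fit collapsed: non-positive total weight")
    weights = weights / total

    pad = 3.0 * float(sigmas.max())
    eval_range = (float(x.min() - pad), float(x.max() + pad))
    grid = np.linspace(*eval_range, 2001)
    model = LCGDensity(weights=weights, means=means, sigmas=sigmas, n_pos=n_pos,
                       n_neg=n_neg, eval_range=eval_range,
                       positive_phase_loglik=trace)
    for _ in range(100):
        if model.pdf(grid).min() >= -1e-6:
            break
        neg = model.weights < 0
        model.weights[neg] *= 0.7
        model.weights /= model.weights.sum()
    return model


# ---------------------------------------------------------------------------
# training set, full model, Bayes rule
# ---------------------------------------------------------------------------

@dataclass
class TrainingSet:
    """Labeled (U, q_ave, q_10) feature vectors.

    Labels are ``FPN``, ``TPN_lung`` or ``TPN_wall``; at least 2 samples
    per present class are required for training.
    """

    samples: np.ndarray       # (n, 3) feature matrix, columns (U, q_ave, q_10)
    labels: np.ndarray        # (n,) strings

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        if self.samples.ndim != 2 or self.samples.shape[1] != 3:
            raise ValueError("samples must be an (n, 3) matrix of (U, q_ave, q_10)")
        if len(self.labels) != len(self.samples):
            raise ValueError("labels and samples length mismatch")

    def for_class(self, label: str) -> np.ndarray:
        return self.samples[self.labels == label]

    @property
    def class_sizes(self) -> dict[str, int]:
        labels, counts = np.unique(self.labels.astype(str), return_counts=True)
        return {str(lab): int(c) for lab, c in zip(labels, counts)}


_CLASS_FEATURES = {
    CLASS_FPN: FEATURE_NAMES,
    CLASS_TPN_LUNG: FEATURE_NAMES,
    CLASS_TPN_WALL: ("q_ave", "q_10"),  # U is not informative at the lung wall
}


@dataclass
class NoduleBayesModel:
    """Per-class, per-feature LCG densities for the naive Bayes rule."""

    densities: dict  # class label -> {feature name -> LCGDensity}

    def density(self, label: str, feature: str) -> LCGDensity:
        return self.densities[label][feature]

    def to_json(self, path) -> None:
        payload = {
            cls: {feat: d.to_dict() for feat, d in feats.items()}
            for cls, feats in self.densities.items()
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "NoduleBayesModel":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(densities={
            c: {f: LCGDensity.from_dict(d) for f, d in feats.items()}
            for c, feats in payload.items()
        })


def train_classifier(training: TrainingSet, n_pos: int = 2, n_neg: int = 1,
                     seed: int = 0) -> NoduleBayesModel:
    """Fit one LCG density per (class, feature), features independently.

    Priors are fixed equal and never estimated.  The wall-TPN class is
    fitted on the two gray-level features only.
    """
    sizes = training.class_sizes
    for label, count in sizes.items():
        if count < 2:
            raise ValueError(f"class {label} has {count} training samples; need >= 2")
    densities: dict = {}
    for ci, label in enumerate(sorted(sizes)):
        feats = _CLASS_FEATURES.get(label, FEATURE_NAMES)
        sub = training.for_class(label)
        densities[label] = {}
        for fi, feat in enumerate(feats):
            col = sub[:, FEATURE_NAMES.index(feat)]
            densities[label][feat] = fit_lcg(col, n_pos=n_pos, n_neg=n_neg,
                                             seed=seed + 101 * ci + 7 * fi)
    return NoduleBayesModel(densities=densities)


def classify(features, model: NoduleBayesModel, wall_nodule: bool = False
             ) -> tuple[str, float]:
    """Naive-Bayes TPN/FPN decision with equiprobable priors.

    Returns ``(label, posterior)`` where ``posterior`` is the TPN
    probability.  Lung nodules use all three features against the
    lung-TPN densities; wall nodules use only (q_ave, q_10) against the
    wall-TPN densities.  Density values are clamped below at 1e-12; an
    exact posterior of 0.5 resolves conservatively to FPN.
    """
    if isinstance(features, NoduleFeatures):
        features = features.as_tuple()
    fdict = dict(zip(FEATURE_NAMES, (float(v) for v in features)))
    tpn_class = CLASS_TPN_WALL if wall_nodule else CLASS_TPN_LUNG
    used = _CLASS_FEATURES[tpn_class]
    if tpn_class not in model.densities:
        raise ValueError(f"model was not trained with a {tpn_class} class")
    log_t = 0.0
    log_f = 0.0
    for feat in used:
        v = fdict[feat]
        log_t += math.log(max(float(model.density(tpn_class, feat).pdf(v)), DENSITY_FLOOR))
        log_f += math.log(max(float(model.density(CLASS_FPN, feat).pdf(v)), DENSITY_FLOOR))
    # posterior with equal priors
    m = max(log_t, log_f)
    st, sf = math.exp(log_t - m), math.exp(log_f - m)
    posterior = st / (st + sf)
    label = "TPN" if posterior > 0.5 else "FPN"
    return label, posterior
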