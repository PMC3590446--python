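"""End-to-end detection pipeline.

volume -> restricted search space -> per-shape GA template matching ->
global non-maximum suppression -> feature extraction -> Bayes
classification -> detection report (scored against ground truth when
supplied).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, replace

import numpy as np

from .candidate_space import space_from_mask, space_from_threshold
from .classifier import NoduleBayesModel, extract_features, train_classifier, classify
from .matching import GAConfig, ga_search, non_maximum_suppression
from .phantom import GroundTruth, make_feature_training_set
from .templates import SHAPES
from .volume import CandidateRecord, Volume, write_candidates

log = logging.getLogger(__name__)


@dataclass
class DetectionReport:
    """Summary of one pipeline run."""

    per_shape: dict                 # shape -> {"before": int, "after": int}
    n_before: int
    n_after: int
    seed: int
    config: dict
    tp: int | None = None
    fp: int | None = None
    fn: int | None = None
    matches: list | None = None     # (truth index, candidate index, distance)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)


def match_radius(R: float) -> float:
    """Center-distance radius for matching a detection to a truth nodule."""
    return max(3.0, R / 2.0)


def score_against_truth(accepted: list[CandidateRecord], truth: GroundTruth
                        ) -> tuple[int, int, int, list]:
    """Greedy one-to-one matching of accepted candidates to truth nodules."""
    used = set()
    matches = []
    for ti, nod in enumerate(truth.nodules):
        tc = np.asarray(nod.center, dtype=float)
        best, best_d = None, np.inf
        for ci, cand in enumerate(accepted):
            if ci in used:
                continue
            d = float(np.linalg.norm(tc - np.asarray(cand.center, dtype=float)))
            if d <= match_radius(nod.R) and d < best_d:
                best, best_d = ci, d
        if best is not None:
            used.add(best)
            matches.append((ti, best, best_d))
    tp = len(matches)
    fn = len(truth.nodules) - tp
    fp = len(accepted) - len(used)
    return tp, fp, fn, matches


def run_pipeline(volume: Volume, mask: Volume | None = None, q_low: float | None = None,
                 ga_config: GAConfig = GAConfig(), shapes=SHAPES,
                 model: NoduleBayesModel | None = None, training=None,
                 truth: GroundTruth | None = None, min_component: int = 1,
                 out_csv=None) -> tuple[DetectionReport, list[CandidateRecord]]:
    """Run detection end to end; deterministic per ``ga_config.seed``.

    The search space comes from ``mask`` when given, else from a gray
    threshold ``q_low``.  One GA run per template shape (seeds offset per
    shape so the runs are decorrelated but reproducible); candidates are
    merged across shapes by non-maximum suppression, featurized and
    classified; semicircular candidates take the wall-nodule path.  When
    ground truth is supplied the accepted detections are scored with a
    center-distance gate of max(3, R/2) voxels.
    """
    if mask is not None:
        space = space_from_mask(mask, min_component=min_component)
    elif q_low is not None:
        space = space_from_threshold(volume, q_low, min_component=min_component)
    else:
        raise ValueError("pipeline needs either a candidate mask or a threshold q_low")
    if len(space) == 0:
        raise ValueError("candidate search space is empty")
    log.info("search space: %d voxels (%s)", len(space), space.source)

    raw: list[CandidateRecord] = []
    per_shape: dict = {}
    for si, shape in enumerate(shapes):
        cfg = replace(ga_config, seed=ga_config.seed + 1000 * si)
        try:
            found = ga_search(volume, space, shape, cfg, dedup=True)
        except ValueError as exc:
            raise RuntimeError(f"matching stage failed for shape {shape}: {exc}") from exc
        per_shape[shape] = {"before": len(found), "after": 0}
        raw.extend(found)
        log.info("shape %s: %d candidates", shape, len(found))
    merged = non_maximum_suppression(raw)

    if model is None:
        if training is None:
            training = make_feature_training_set(n_per_class=20, seed=ga_config.seed)
        model = train_classifier(training, seed=ga_config.seed)

    labeled: list[CandidateRecord] = []
    for cand in merged:
        try:
            feats = extract_features(volume, space.mask, cand,
                                     q_max=ga_config.q_max, q_min=ga_config.q_min,
                                     v=ga_config.v,
                                     hollow_fraction=ga_config.hollow_fraction)
        except ValueError as exc:
            raise RuntimeError(f"feature stage failed for candidate {cand.center}: {exc}") from exc
        label, _post = classify(feats, model, wall_nodule=(cand.shape == "semicircle"))
        cand.features = feats.as_tuple()
        cand.label = label
        labeled.append(cand)
        if label == "TPN":
            per_shape[cand.shape]["after"] += 1
    accepted = [c for c in labeled if c.label == "TPN"]

    report = DetectionReport(
        per_shape=per_shape,
        n_before=len(merged),
        n_after=len(accepted),
        seed=ga_config.seed,
        config={k: (list(v) if isinstance(v, tuple) else v)
                for k, v in dataclasses.asdict(ga_config).items()
                if not isinstance(v, dict)},
    )
    if truth is not None:
        report.tp, report.fp, report.fn, report.matches = score_against_truth(accepted, truth)
    if out_csv is not None:
        write_candidates(labeled, out_csv)
    return report, labeled
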