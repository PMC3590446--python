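"""Restricted search space of candidate voxels.

Template matching never scans the full volume: it is restricted to the
voxels of segmented vessels, bronchi and abnormalities.  That
segmentation is delivered either as an externally produced binary mask
or, for phantoms and quick experiments, as a simple gray-level
threshold stand-in.  Connected components smaller than
``min_component`` voxels (26-connectivity) are discarded as noise.

Cavity (hollow-sphere) nodules segment as annuli whose geometric
centers are background; per-slice hole filling (on by default) returns
those interiors to the search space so a cavity template can be
centered on them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume import Volume

_CONN26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class SearchSpace:
    """Set of candidate voxels, as a sorted (N, 3) index array plus a boolean lattice."""

    voxels: np.ndarray        # (N, 3) int, lexicographically sorted by (x, y, z)
    mask: np.ndarray          # boolean array congruent with the volume
    source: str               # "mask_file" or "threshold_standin"

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=int)
        if self.voxels.ndim != 2 or self.voxels.shape[1] != 3:
            raise ValueError("voxels must be an (N, 3) index array")

    def __len__(self) -> int:
        return len(self.voxels)

    def contains(self, x: int, y: int, z: int) -> bool:
        return bool(self.mask[x, y, z])


def _as_bool(mask) -> np.ndarray:
    data = mask.data if isinstance(mask, Volume) else np.asarray(mask)
    return data > 0.5


def _component_filter(binary: np.ndarray, min_component: int, fill_holes: bool) -> np.ndarray:
    if fill_holes:
        binary = binary.copy()
        for z in range(binary.shape[2]):
            binary[:, :, z] = ndimage.binary_fill_holes(binary[:, :, z])
    if min_component > 1:
        labels, n = ndimage.label(binary, structure=_CONN26)
        if n:
            sizes = np.bincount(labels.ravel())
            keep = sizes >= min_component
            keep[0] = False
            binary = keep[labels]
        else:
            binary = np.zeros_like(binary)
    return binary


def _build(binary: np.ndarray, source: str) -> SearchSpace:
    voxels = np.argwhere(binary)  # argwhere is already lexicographic in (x, y, z)
    return SearchSpace(voxels=voxels, mask=binary, source=source)


def space_from_mask(mask, min_component: int = 1, fill_holes: bool = True) -> SearchSpace:
    """Search space from a binary candidate-tissue mask.

    Keeps voxels of 26-connected components with at least
    ``min_component`` voxels; cavity interiors are restored by per-slice
    hole filling unless ``fill_holes=False``.
    """
    binary = _component_filter(_as_bool(mask), min_component, fill_holes)
    return _build(binary, "mask_file")


def space_from_threshold(volume: Volume, q_low: float, min_component: int = 1,
                         fill_holes: bool = True) -> SearchSpace:
    """Threshold stand-in for the tissue segmentation: voxels with gray >= q_low."""
    binary = _component_filter(volume.data >= q_low, min_component, fill_holes)
    return _build(binary, "threshold_standin")
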