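"""Volume and candidate-list I/O.

Coordinate convention used throughout the package: 0-based voxel
indices, axis order (x, y, z) with z the slice axis, so ``data[x, y, z]``
addresses one voxel.  Gray levels are stored as floating point even for
8-bit sources, nominal range 0-255.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

CANDIDATE_COLUMNS = ["x", "y", "z", "shape", "R", "angle", "similarity", "U", "q_ave", "q_10", "label"]


@dataclass
class Volume:
    """A 3D gray-level image with voxel spacing metadata."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError(f"volume must be 3D with all dims >= 1, got shape {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume gray levels must be finite")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive values, got {self.spacing}")
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class CandidateRecord:
    """A matched template location.

    ``center`` is a 0-based (x, y, z) voxel index; ``R`` the matched
    radius in pixels; ``angle`` (degrees) is present for semicircular
    templates only.  ``features`` holds (U, q_ave, q_10) once extracted
    and ``label`` the classifier's TPN/FPN verdict.
    """

    center: tuple[int, int, int]
    shape: str
    R: float
    similarity: float
    angle: float | None = None
    features: tuple[float, float, float] | None = None
    label: str | None = None

    def __post_init__(self) -> None:
        self.center = tuple(int(c) for c in self.center)
        if any(c < 0 for c in self.center):
            raise ValueError(f"candidate center must be non-negative voxel indices, got {self.center}")


def rescale_gray(volume: Volume, lo: float = 0.0, hi: float = 255.0) -> Volume:
    """Linearly rescale gray levels to [lo, hi]; constant volumes map to lo."""
    d = volume.data
    dmin, dmax = d.min(), d.max()
    if dmax == dmin:
        data = np.full_like(d, lo)
    else:
        data = lo + (d - dmin) * (hi - lo) / (dmax - dmin)
    return Volume(data=data, spacing=volume.spacing, origin=volume.origin)


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".yaml")


def _infer_format(path: Path) -> str:
    name = path.name.lower()
    if name.endswith(".nii") or name.endswith(".nii.gz"):
        return "nifti"
    return "raw"


def read_volume(path, format: str | None = None, rescale: bool = False) -> Volume:
    """Read a volume from NIfTI (.nii/.nii.gz) or raw binary + YAML sidecar.

    With ``rescale=True`` gray levels are mapped linearly onto [0, 255].
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"volume file not found: {path}")
    fmt = format or _infer_format(path)
    if fmt == "nifti":
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj).astype(float)
        if data.ndim != 3:
            raise ValueError(f"expected a 3D NIfTI image, got {data.ndim}D in {path}")
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        origin = tuple(float(t) for t in img.affine[:3, 3])
        vol = Volume(data=data, spacing=spacing, origin=origin)
    elif fmt == "raw":
        meta_path = _sidecar_path(path)
        if not meta_path.exists():
            raise IOError(f"raw volume requires sidecar metadata file {meta_path}")
        with open(meta_path) as fh:
            meta = yaml.safe_load(fh)
        dims = tuple(int(d) for d in meta["dims"])
        dtype = np.dtype(meta.get("dtype", "float64"))
        data = np.fromfile(path, dtype=dtype)
        if data.size != math.prod(dims):
            raise ValueError(
                f"raw file {path} holds {data.size} values but metadata dims {dims} "
                f"imply {math.prod(dims)}"
            )
        vol = Volume(
            data=data.reshape(dims),
            spacing=tuple(meta.get("spacing", (1.0, 1.0, 1.0))),
            origin=tuple(meta.get("origin", (0.0, 0.0, 0.0))),
        )
    else:
        raise ValueError(f"unknown volume format {fmt!r}")
    return rescale_gray(vol) if rescale else vol


def write_volume(volume: Volume, path, format: str | None = None) -> None:
    """Write a volume as NIfTI or raw binary + YAML sidecar."""
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "nifti":
        affine = np.diag(list(volume.spacing) + [1.0])
        affine[:3, 3] = volume.origin
        nib.save(nib.Nifti1Image(volume.data, affine), str(path))
    elif fmt == "raw":
        volume.data.astype("float64").tofile(path)
        with open(_sidecar_path(path), "w") as fh:
            yaml.safe_dump(
                {
                    "dims": list(volume.data.shape),
                    "dtype": "float64",
                    "spacing": list(volume.spacing),
                    "origin": list(volume.origin),
                },
                fh,
            )
    else:
        raise ValueError(f"unknown volume format {fmt!r}")


def write_candidates(records: list[CandidateRecord], path) -> None:
    """Serialize candidate records to CSV (one row per candidate)."""
    rows = []
    for rec in records:
        U, q_ave, q_10 = rec.features if rec.features is not None else (None, None, None)
        rows.append(
            {
                "x": rec.center[0],
                "y": rec.center[1],
                "z": rec.center[2],
                "shape": rec.shape,
                "R": rec.R,
                "angle": rec.angle,
                "similarity": rec.similarity,
                "U": U,
                "q_ave": q_ave,
                "q_10": q_10,
                "label": rec.label,
            }
        )
    df = pd.DataFrame(rows, columns=CANDIDATE_COLUMNS)
    df.to_csv(path, index=False)


def read_candidates(path) -> list[CandidateRecord]:
    """Read candidate records back from CSV, validating 0-based integer coordinates."""
    path = Path(path)
    if not path.exists():
        raise IOError(f"candidate file not found: {path}")
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed candidate CSV {path}: {exc}") from exc
    missing = [c for c in CANDIDATE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"candidate CSV {path} missing columns {missing}")
    records = []
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        for axis in ("x", "y", "z"):
            val = row[axis]
            if pd.isna(val) or float(val) != int(val) or int(val) < 0:
                raise ValueError(
                    f"candidate CSV {path} line {line}: {axis}={val!r} is not a 0-based integer"
                )
        feats = None
        if not (pd.isna(row["U"]) and pd.isna(row["q_ave"]) and pd.isna(row["q_10"])):
            feats = (float(row["U"]), float(row["q_ave"]), float(row["q_10"]))
        records.append(
            CandidateRecord(
                center=(int(row["x"]), int(row["y"]), int(row["z"])),
                shape=str(row["shape"]),
                R=float(row["R"]),
                angle=None if pd.isna(row["angle"]) else float(row["angle"]),
                similarity=float(row["similarity"]),
                features=feats,
                label=None if pd.isna(row["label"]) else str(row["label"]),
            )
        )
    return records
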