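"""Volume, phenotype and network-matrix I/O.

Scalar and label volumes are NIfTI-1 (via nibabel); phenotype tables and
network matrices are plain TSV. Region order is ascending numeric label
everywhere downstream, fixed at extraction time.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import nibabel as nib
import numpy as np
import pandas as pd

from .synthetic import BACKGROUND

__all__ = [
    "VoxelImage",
    "LabelImage",
    "RegionalSampleSet",
    "load_scalar_volume",
    "load_label_volume",
    "extract_region_samples",
    "read_phenotype_table",
    "write_network",
    "read_network",
]

#: cerebellar Vermis labels in the 116-region SRI24 parcellation, excluded
#: from network construction for their low gray-matter signal
VERMIS_LABELS = frozenset(range(108, 116))


@dataclass
class VoxelImage:
    """A 3D scalar volume (e.g. a gray-matter volume map) with its affine."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"scalar volume must be 3D, got {self.data.ndim}D")


@dataclass
class LabelImage:
    """A 3D integer parcellation volume; one sentinel value is background."""

    data: np.ndarray
    affine: np.ndarray
    background: int = BACKGROUND

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"label volume must be 3D, got {self.data.ndim}D")
        if not np.issubdtype(self.data.dtype, np.integer):
            rounded = np.rint(self.data)
            if not np.allclose(self.data, rounded):
                raise ValueError("label volume has non-integer values")
            self.data = rounded.astype(np.int64)

    @property
    def labels(self) -> list[int]:
        vals = np.unique(self.data)
        return [int(v) for v in vals if v != self.background]


@dataclass
class RegionalSampleSet:
    """Per-subject mapping from retained region label to voxel value samples."""

    subject_id: str
    samples: dict[int, np.ndarray]
    retained_labels: list[int]

    def __post_init__(self) -> None:
        self.retained_labels = sorted(int(l) for l in self.retained_labels)
        if set(self.samples) != set(self.retained_labels):
            raise ValueError("samples keys must equal retained_labels")
        self.samples = {l: np.asarray(self.samples[l], dtype=np.float64)
                        for l in self.retained_labels}

    def __len__(self) -> int:
        return len(self.retained_labels)


def load_scalar_volume(path: str | Path, strict: bool = True) -> VoxelImage:
    """Load a 3D NIfTI scalar volume.

    In strict mode non-finite voxels raise; otherwise they are zeroed.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume: {path}")
    img = nib.load(path)
    data = np.asarray(img.get_fdata(), dtype=np.float64)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D volume, got {data.ndim}D")
    bad = ~np.isfinite(data)
    if bad.any():
        if strict:
            raise ValueError(
                f"{path}: {int(bad.sum())} non-finite voxels (strict mode)")
        data = np.where(bad, 0.0, data)
    return VoxelImage(data=data, affine=np.asarray(img.affine))


def load_label_volume(path: str | Path, background: int = BACKGROUND) -> LabelImage:
    """Load a 3D NIfTI label/atlas volume."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such atlas: {path}")
    img = nib.load(path)
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D atlas, got {data.ndim}D")
    return LabelImage(data=data, affine=np.asarray(img.affine),
                      background=background)


def extract_region_samples(
    volume: VoxelImage,
    atlas: LabelImage,
    excluded_labels: Iterable[int] = VERMIS_LABELS,
    min_voxels: int = 10,
    subject_id: str = "subject",
) -> RegionalSampleSet:
    """Collect the scalar volume's voxel values per retained atlas region.

    Every atlas label that is neither background nor excluded is retained;
    a retained region smaller than ``min_voxels`` voxels is an error (too few
    values for a density estimate). Zeros inside a region are data and kept;
    only non-finite values are invalid (rejected upstream at load time).
    """
    if volume.data.shape != atlas.data.shape:
        raise ValueError(
            f"volume shape {volume.data.shape} != atlas shape {atlas.data.shape}")
    excluded = set(int(l) for l in excluded_labels)
    samples: dict[int, np.ndarray] = {}
    for label in atlas.labels:
        if label in excluded:
            continue
        vals = volume.data[atlas.data == label]
        if len(vals) < min_voxels:
            raise ValueError(
                f"region {label} has only {len(vals)} voxels (< {min_voxels})")
        samples[label] = vals
    if not samples:
        raise ValueError("no regions retained after exclusions")
    return RegionalSampleSet(subject_id=subject_id, samples=samples,
                             retained_labels=sorted(samples))


_GROUP_MAP = {"asd": 1, "nc": 0, "case": 1, "control": 0}


def read_phenotype_table(path: str | Path) -> list[tuple[str, int]]:
    """Read a TSV of (subject_id, group); ASD maps to 1, NC to 0."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"subject_id", "group"}
    if not required <= set(df.columns):
        raise ValueError(f"phenotype table needs columns {sorted(required)}")
    records: list[tuple[str, int]] = []
    seen: set[str] = set()
    for _, row in df.iterrows():
        sid = str(row["subject_id"])
        if sid in seen:
            raise ValueError(f"duplicate subject_id: {sid}")
        seen.add(sid)
        group = str(row["group"]).strip().lower()
        if group not in _GROUP_MAP:
            raise ValueError(f"unknown group value {row['group']!r} for {sid}")
        records.append((sid, _GROUP_MAP[group]))
    return records


def write_network(matrix: np.ndarray, labels: list[int], path: str | Path) -> None:
    """Write a square region-by-region matrix as TSV with label headers."""
    matrix = np.asarray(matrix, dtype=np.float64)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValueError(f"matrix must be square, got shape {matrix.shape}")
    if len(labels) != matrix.shape[0]:
        raise ValueError("labels length must equal the matrix side")
    with open(path, "w") as fh:
        fh.write("region\t" + "\t".join(str(l) for l in labels) + "\n")
        for label, row in zip(labels, matrix):
            fh.write(str(label) + "\t"
                     + "\t".join(format(v, ".17g") for v in row) + "\n")


def read_network(path: str | Path) -> tuple[np.ndarray, list[int]]:
    """Read a network TSV; rows/columns are restored to ascending label order."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    labels = [int(l) for l in df.index]
    col_labels = [int(c) for c in df.columns]
    if sorted(labels) != sorted(col_labels):
        raise ValueError("row and column labels disagree")
    order = np.argsort(labels)
    matrix = df.to_numpy(dtype=np.float64)
    # canonicalize to ascending labels on both axes
    col_order = np.argsort(col_labels)
    matrix = matrix[np.ix_(order, col_order)]
    return matrix, sorted(labels)


def sampleset_from_cohort_subject(
    subject: tuple[str, str, Mapping[int, np.ndarray]],
) -> RegionalSampleSet:
    """Adapt one synthetic-cohort subject to a RegionalSampleSet."""
    sid, _group, samples = subject
    return RegionalSampleSet(subject_id=sid, samples=dict(samples),
                             retained_labels=sorted(samples))
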