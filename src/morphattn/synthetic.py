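"""Synthetic atlases and case/control cohorts with known effect regions.

Real studies of morphological covariance networks start from gray-matter (GM)
volume maps registered to a labelled atlas. For testing the full pipeline
without scan data, this module emulates the two ingredients the network
construction actually consumes: an integer label volume whose labels occupy
contiguous blobs, and per-region samples of GM-like voxel values. Cases and
controls share region-specific base distributions; a chosen subset of regions
carries a distributional shift (location and/or spread) in cases, so the
ground truth that a classifier and biomarker mapper should recover is known
exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

BACKGROUND = -1

__all__ = [
    "BACKGROUND",
    "EffectSpec",
    "SyntheticCohort",
    "generate_atlas_volume",
    "simulate_regional_samples",
    "simulate_cohort",
    "write_cohort",
]


@dataclass(frozen=True)
class EffectSpec:
    """Ground-truth group effect injected into case subjects.

    mean_shift is additive on the regional value scale; spread_scale
    multiplies the regional standard deviation. (0, 1) is the null effect.
    """

    effect_regions: frozenset[int]
    mean_shift: float = 0.0
    spread_scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "effect_regions",
                           frozenset(int(r) for r in self.effect_regions))
        if self.spread_scale <= 0:
            raise ValueError("spread_scale must be positive")


@dataclass
class SyntheticCohort:
    """A simulated case/control cohort with per-region voxel value samples."""

    subjects: list[tuple[str, str, dict[int, np.ndarray]]]
    ground_truth: EffectSpec
    atlas_labels: list[int]
    # per-subject per-region (mean, sd) actually used; lets volume export draw
    # distribution-faithful values for blobs of any voxel count
    region_params: dict[str, dict[int, tuple[float, float]]] = field(default_factory=dict)
    seed: int = 0

    @property
    def labels(self) -> np.ndarray:
        """Binary diagnosis vector, case = 1."""
        return np.array([1 if g == "case" else 0 for _, g, _ in self.subjects])

    @property
    def subject_ids(self) -> list[str]:
        return [sid for sid, _, _ in self.subjects]


def _interior_mask(shape: tuple[int, int, int]) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    mask[1:-1, 1:-1, 1:-1] = True
    return mask


def generate_atlas_volume(
    n_regions: int,
    grid_shape: tuple[int, int, int],
    seed: int,
    min_region_voxels: int = 50,
) -> np.ndarray:
    """Partition a 3D grid into contiguous labelled regions.

    The interior of the grid (one-voxel background shell, labelled
    ``BACKGROUND``) is split into ``n_regions`` Voronoi cells of seeded
    centroids, balanced by a few Lloyd iterations; Voronoi cells are convex
    and therefore contiguous. Raises if the grid cannot host ``n_regions``
    blobs of at least ``min_region_voxels`` voxels.
    """
    if n_regions < 1:
        raise ValueError("n_regions must be positive")
    grid_shape = tuple(int(g) for g in grid_shape)
    if len(grid_shape) != 3 or any(g < 3 for g in grid_shape):
        raise ValueError(f"grid_shape must be 3 positive dims >= 3, got {grid_shape}")
    interior = _interior_mask(grid_shape)
    n_vox = int(interior.sum())
    if n_vox < min_region_voxels * n_regions:
        raise ValueError(
            f"grid {grid_shape} has {n_vox} interior voxels; "
            f"{min_region_voxels * n_regions} needed for {n_regions} regions"
        )
    coords = np.argwhere(interior).astype(np.float64)
    rng = np.random.default_rng(seed)

    for _attempt in range(20):
        centers = coords[rng.choice(len(coords), size=n_regions, replace=False)]
        for _ in range(10):  # Lloyd balancing
            _, assign = cKDTree(centers).query(coords)
            for k in range(n_regions):
                sel = coords[assign == k]
                if len(sel):
                    centers[k] = sel.mean(axis=0)
        _, assign = cKDTree(centers).query(coords)
        counts = np.bincount(assign, minlength=n_regions)
        if counts.min() >= min_region_voxels:
            break
    else:
        raise ValueError(
            f"could not place {n_regions} regions of >= {min_region_voxels} "
            f"voxels on grid {grid_shape}"
        )

    volume = np.full(grid_shape, BACKGROUND, dtype=np.int32)
    idx = coords.astype(int)
    volume[idx[:, 0], idx[:, 1], idx[:, 2]] = assign
    return volume


def simulate_regional_samples(
    base_mean: float,
    base_sd: float,
    n_voxels: int,
    effect: tuple[float, float] | None = None,
    seed: int = 0,
    mixture: tuple[float, float] | None = None,
) -> np.ndarray:
    """Draw voxel values for one region of one subject.

    Default model is Gaussian with mean ``base_mean (+ shift)`` and sd
    ``base_sd (* scale)``; ``mixture=(weight, offset)`` replaces it by a
    two-component mixture in which a ``weight`` fraction of voxels is offset
    by ``offset``. Values are clipped at zero (GM quantities are
    non-negative). The same seed with the null effect (0, 1) reproduces the
    no-effect samples exactly.
    """
    if base_sd <= 0:
        raise ValueError("base_sd must be positive")
    if n_voxels < 10:
        raise ValueError("n_voxels must be >= 10")
    shift, scale = (0.0, 1.0) if effect is None else effect
    if scale <= 0:
        raise ValueError("spread scale must be positive")
    rng = np.random.default_rng(seed)
    z = rng.standard_normal(n_voxels)
    values = (base_mean + shift) + (base_sd * scale) * z
    if mixture is not None:
        weight, offset = mixture
        comp = rng.random(n_voxels) < weight
        values = values + comp * offset
    return np.maximum(values, 0.0)


def simulate_cohort(
    n_case: int,
    n_control: int,
    n_regions: int,
    effect: EffectSpec,
    voxels_per_region: int = 200,
    seed: int = 0,
    base_mean_range: tuple[float, float] = (0.4, 0.8),
    base_sd: float = 0.1,
    subject_jitter: float = 0.05,
) -> SyntheticCohort:
    """Simulate a case/control cohort of regional GM value samples.

    Each region gets a base mean drawn once from ``base_mean_range`` (shared
    by all subjects) and sd ``base_sd``; each subject perturbs every regional
    mean by N(0, subject_jitter * base_sd) so within-group networks differ.
    Cases additionally receive ``effect`` in ``effect.effect_regions``.
    """
    if n_case < 1 or n_control < 1:
        raise ValueError("both groups must be non-empty")
    if not set(effect.effect_regions) <= set(range(n_regions)):
        raise ValueError("effect_regions must be a subset of the atlas labels")

    root = np.random.SeedSequence(seed)
    region_ss, subject_ss = root.spawn(2)
    rng = np.random.default_rng(region_ss)
    base_means = rng.uniform(*base_mean_range, size=n_regions)

    groups = ["case"] * n_case + ["control"] * n_control
    ids = [f"case{i:03d}" for i in range(n_case)] + \
          [f"ctrl{i:03d}" for i in range(n_control)]

    subjects: list[tuple[str, str, dict[int, np.ndarray]]] = []
    region_params: dict[str, dict[int, tuple[float, float]]] = {}
    for child, sid, group in zip(subject_ss.spawn(len(ids)), ids, groups):
        srng = np.random.default_rng(child)
        jitter = srng.normal(0.0, subject_jitter * base_sd, size=n_regions)
        samples: dict[int, np.ndarray] = {}
        params: dict[int, tuple[float, float]] = {}
        for r in range(n_regions):
            mean = base_means[r] + jitter[r]
            sd = base_sd
            if group == "case" and r in effect.effect_regions:
                mean += effect.mean_shift
                sd *= effect.spread_scale
            z = srng.standard_normal(voxels_per_region)
            samples[r] = np.maximum(mean + sd * z, 0.0)
            params[r] = (float(mean), float(sd))
        subjects.append((sid, group, samples))
        region_params[sid] = params

    return SyntheticCohort(
        subjects=subjects,
        ground_truth=effect,
        atlas_labels=list(range(n_regions)),
        region_params=region_params,
        seed=seed,
    )


def write_cohort(
    cohort: SyntheticCohort,
    out_dir: str | Path,
    grid_shape: tuple[int, int, int] = (24, 24, 24),
    atlas_seed: int | None = None,
) -> dict[str, Path]:
    """Export a cohort as NIfTI volumes plus a TSV phenotype table.

    Writes ``atlas.nii.gz``, one scalar volume per subject (each region blob
    filled with values drawn from that subject's regional distribution),
    ``phenotype.tsv`` and a JSON sidecar with the ground-truth effect.
    Returns the paths written.
    """
    import nibabel as nib
    import pandas as pd

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    n_regions = len(cohort.atlas_labels)
    atlas_seed = cohort.seed if atlas_seed is None else atlas_seed
    atlas = generate_atlas_volume(n_regions, grid_shape, atlas_seed)

    paths: dict[str, Path] = {}
    affine = np.eye(4)
    atlas_path = out_dir / "atlas.nii.gz"
    nib.save(nib.Nifti1Image(atlas.astype(np.int16), affine), atlas_path)
    paths["atlas"] = atlas_path

    fill_root = np.random.SeedSequence([cohort.seed & 0x7FFFFFFF, 0xF111])
    for child, (sid, _group, _samples) in zip(
            fill_root.spawn(len(cohort.subjects)), cohort.subjects):
        frng = np.random.default_rng(child)
        vol = np.zeros(atlas.shape, dtype=np.float64)
        for r in cohort.atlas_labels:
            mask = atlas == r
            mean, sd = cohort.region_params[sid][r]
            vol[mask] = np.maximum(
                frng.normal(mean, sd, size=int(mask.sum())), 0.0)
        p = out_dir / f"{sid}.nii.gz"
        nib.save(nib.Nifti1Image(vol, affine), p)
        paths[sid] = p

    pheno = pd.DataFrame({
        "subject_id": cohort.subject_ids,
        "group": ["ASD" if g == "case" else "NC" for _, g, _ in cohort.subjects],
    })
    pheno_path = out_dir / "phenotype.tsv"
    pheno.to_csv(pheno_path, sep="\t", index=False)
    paths["phenotype"] = pheno_path

    truth = {
        "effect_regions": sorted(cohort.ground_truth.effect_regions),
        "mean_shift": cohort.ground_truth.mean_shift,
        "spread_scale": cohort.ground_truth.spread_scale,
        "seed": cohort.seed,
    }
    truth_path = out_dir / "ground_truth.json"
    truth_path.write_text(json.dumps(truth, indent=2))
    paths["ground_truth"] = truth_path
    return paths
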