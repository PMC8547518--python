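"""Biomarker identification from self-attention coefficient maps.

The attention coefficient alpha_pq is the weight with which region q's value
vector contributes to region p's output, so large coefficients point at
regions driving the classification. Per subject, the per-layer coefficient
maps are averaged into one fused heat map; fused maps can then be averaged
over a group of subjects (e.g. all true negatives). Entries above
mean + 3 SD of the fused map are the selected contributions: their column
indices q are the contributing (source) regions, their row indices p the
aggregating regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .model import AttentionRecord
from .synthetic import EffectSpec

__all__ = [
    "HeatMap",
    "BiomarkerReport",
    "fuse_layer_maps",
    "group_mean_map",
    "threshold_entries",
    "biomarker_recovery_score",
]


@dataclass
class HeatMap:
    """A non-negative M x M attention map with provenance."""

    values: np.ndarray
    region_labels: list[int]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        M = len(self.region_labels)
        if self.values.shape != (M, M):
            raise ValueError(f"heat map shape {self.values.shape} != ({M}, {M})")
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValueError("heat map must be finite and non-negative")


@dataclass
class BiomarkerReport:
    """Supra-threshold attention entries and the regions they implicate."""

    threshold: float
    supra_entries: list[tuple[int, int, float]]   # (p, q, alpha_pq), alpha desc
    source_regions: list[int]                     # unique q labels
    aggregator_regions: list[int]                 # unique p labels
    region_names: dict[int, str] = field(default_factory=dict)
    heat_map: HeatMap | None = None


def fuse_layer_maps(record: AttentionRecord,
                    region_labels: Sequence[int]) -> HeatMap:
    """Entrywise mean of a subject's per-layer attention maps."""
    if not record.alpha:
        raise ValueError("attention record has no coefficient maps")
    fused = np.mean(np.stack(record.alpha), axis=0)
    return HeatMap(values=fused, region_labels=list(region_labels),
                   provenance={"layers": len(record.alpha)})


def group_mean_map(
    maps: Sequence[HeatMap],
    outcomes: Sequence[str] | None = None,
    subject_filter: str = "all",
    subject_ids: Sequence[str] | None = None,
) -> HeatMap:
    """Entrywise mean of fused maps over a filtered group of subjects.

    ``outcomes`` gives each subject's classification outcome
    ("TP"/"TN"/"FP"/"FN"); filters: true_negative, true_positive,
    all_correct, all.
    """
    keep_by_filter = {
        "all": lambda o: True,
        "true_negative": lambda o: o == "TN",
        "true_positive": lambda o: o == "TP",
        "all_correct": lambda o: o in ("TP", "TN"),
    }
    if subject_filter not in keep_by_filter:
        raise ValueError(f"unknown subject_filter {subject_filter!r}")
    if subject_filter != "all" and outcomes is None:
        raise ValueError("classification outcomes required for this filter")
    keep = keep_by_filter[subject_filter]
    if outcomes is None:
        selected = list(range(len(maps)))
    else:
        selected = [i for i, o in enumerate(outcomes) if keep(o)]
    if not selected:
        raise ValueError(f"filter {subject_filter!r} selected no subjects")
    mean = np.mean(np.stack([maps[i].values for i in selected]), axis=0)
    ids = ([subject_ids[i] for i in selected] if subject_ids is not None
           else selected)
    return HeatMap(values=mean, region_labels=list(maps[0].region_labels),
                   provenance={"filter": subject_filter, "subjects": ids})


def threshold_entries(
    heat_map: HeatMap,
    region_names: Mapping[int, str] | None = None,
    include_diagonal: bool = True,
) -> BiomarkerReport:
    """Select entries above mean + 3 SD of the fused map.

    The statistics use all M^2 entries (population SD); a constant map yields
    an empty report rather than an error. Supra-threshold entries are sorted
    by coefficient, descending.
    """
    values = heat_map.values
    if include_diagonal:
        flat = values.ravel()
    else:
        mask = ~np.eye(values.shape[0], dtype=bool)
        flat = values[mask]
    threshold = float(flat.mean() + 3.0 * flat.std(ddof=0))
    labels = heat_map.region_labels
    entries: list[tuple[int, int, float]] = []
    for p in range(values.shape[0]):
        for q in range(values.shape[1]):
            if not include_diagonal and p == q:
                continue
            if values[p, q] > threshold:
                entries.append((labels[p], labels[q], float(values[p, q])))
    entries.sort(key=lambda e: -e[2])
    sources = sorted({q for _, q, _ in entries})
    aggregators = sorted({p for p, _, _ in entries})
    names = {}
    if region_names is not None:
        names = {r: region_names[r] for r in set(sources) | set(aggregators)
                 if r in region_names}
    return BiomarkerReport(
        threshold=threshold, supra_entries=entries,
        source_regions=sources, aggregator_regions=aggregators,
        region_names=names, heat_map=heat_map,
    )


def biomarker_recovery_score(report: BiomarkerReport, truth: EffectSpec,
                             k: int) -> float:
    """Fraction of ground-truth effect regions among the top-k source regions.

    Regions are ranked by their maximal column coefficient in the fused map
    (their strongest contribution to any region's output); supra-threshold
    source regions therefore rank first by construction.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if not truth.effect_regions:
        raise ValueError("ground truth names no effect regions")
    if report.heat_map is None:
        raise ValueError("report carries no heat map to rank regions from")
    values = report.heat_map.values
    labels = report.heat_map.region_labels
    column_score = values.max(axis=0)
    order = np.argsort(-column_score, kind="stable")
    top_k = {labels[i] for i in order[:k]}
    hits = len(set(truth.effect_regions) & top_k)
    return hits / len(truth.effect_regions)
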