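"""End-to-end orchestration: cohort -> networks -> classifier -> biomarkers.

A single PipelineConfig drives the run; the resolved config, a manifest with
checksums of every artifact, metrics, biomarker report and (optionally) the
permutation test are written under the output directory. One global seed
fans out to per-stage seeds by hashing the stage name, so stages are
individually reproducible without seed collisions.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import evaluate, explain, io, model as model_mod, network, synthetic

logger = logging.getLogger("morphattn")

__all__ = ["PipelineConfig", "SyntheticSpec", "run_pipeline", "derive_seed"]


def derive_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") & 0x7FFFFFFF


@dataclass
class SyntheticSpec:
    """Synthetic-cohort request used when no volume inputs are given."""

    n_case: int = 20
    n_control: int = 20
    n_regions: int = 20
    effect_regions: list[int] = field(default_factory=list)
    mean_shift: float = 0.0
    spread_scale: float = 1.0
    voxels_per_region: int = 200


@dataclass
class PipelineConfig:
    out_dir: str = "morphattn_run"
    input_dir: str | None = None
    atlas: str | None = None
    phenotype: str | None = None
    synthetic: SyntheticSpec | None = None
    n_points: int = 128
    excluded_labels: list[int] = field(default_factory=list)
    min_voxels: int = 10
    model: model_mod.ModelConfig = field(default_factory=model_mod.ModelConfig)
    k_folds: int = 5
    run_permtest: bool = False
    n_perm: int = 99
    flip_fraction: float = 0.2
    fast_permtest: bool = True
    explain_filter: str = "all_correct"
    seed: int = 0

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "PipelineConfig":
        """Build a config, rejecting unknown keys at every level."""
        raw = dict(raw)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "synthetic" in raw and raw["synthetic"] is not None:
            syn = dict(raw["synthetic"])
            syn_known = {f.name for f in dataclasses.fields(SyntheticSpec)}
            bad = set(syn) - syn_known
            if bad:
                raise ValueError(f"unknown synthetic config keys: {sorted(bad)}")
            raw["synthetic"] = SyntheticSpec(**syn)
        if "model" in raw and isinstance(raw["model"], dict):
            mdl = dict(raw["model"])
            mdl_known = {f.name for f in dataclasses.fields(model_mod.ModelConfig)}
            bad = set(mdl) - mdl_known
            if bad:
                raise ValueError(f"unknown model config keys: {sorted(bad)}")
            raw["model"] = model_mod.ModelConfig(**mdl)
        return cls(**raw)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_samplesets(config: PipelineConfig):
    """Return (samplesets, labels, subject_ids, ground_truth or None)."""
    if config.synthetic is not None:
        spec = config.synthetic
        effect = synthetic.EffectSpec(
            effect_regions=frozenset(spec.effect_regions),
            mean_shift=spec.mean_shift,
            spread_scale=spec.spread_scale,
            seed=derive_seed(config.seed, "cohort"),
        )
        cohort = synthetic.simulate_cohort(
            spec.n_case, spec.n_control, spec.n_regions, effect,
            voxels_per_region=spec.voxels_per_region,
            seed=derive_seed(config.seed, "cohort"),
        )
        samplesets = [io.sampleset_from_cohort_subject(s) for s in cohort.subjects]
        return samplesets, cohort.labels, cohort.subject_ids, cohort.ground_truth
    if not (config.input_dir and config.atlas and config.phenotype):
        raise ValueError("either synthetic or input_dir+atlas+phenotype required")
    atlas = io.load_label_volume(config.atlas)
    records = io.read_phenotype_table(config.phenotype)
    samplesets, labels, ids = [], [], []
    for sid, label in records:
        vol_path = Path(config.input_dir) / f"{sid}.nii.gz"
        if not vol_path.exists():
            vol_path = Path(config.input_dir) / f"{sid}.nii"
        volume = io.load_scalar_volume(vol_path)
        samplesets.append(io.extract_region_samples(
            volume, atlas, excluded_labels=config.excluded_labels,
            min_voxels=config.min_voxels, subject_id=sid))
        labels.append(label)
        ids.append(sid)
    return samplesets, np.asarray(labels), ids, None


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Execute all stages; returns the manifest written to the output dir."""
    out = Path(config.out_dir)
    (out / "networks").mkdir(parents=True, exist_ok=True)
    (out / "model").mkdir(exist_ok=True)
    artifacts: list[Path] = []

    logger.info("stage=extract seed=%d", derive_seed(config.seed, "cohort"))
    samplesets, labels, ids, truth = _load_samplesets(config)

    logger.info("stage=networks n_subjects=%d n_points=%d",
                len(samplesets), config.n_points)
    networks = [network.build_network(s, n_points=config.n_points)
                for s in samplesets]
    for net in networks:
        p = out / "networks" / f"{net.subject_id}.tsv"
        io.write_network(net.X, net.region_labels, p)
        artifacts.append(p)

    cv_seed = derive_seed(config.seed, "cv")
    logger.info("stage=cv k=%d seed=%d", config.k_folds, cv_seed)
    cv = evaluate.stratified_cross_validate(
        networks, labels, config.model, k_folds=config.k_folds, seed=cv_seed)
    metrics_path = out / "metrics.json"
    metrics_path.write_text(json.dumps({
        "mean": cv.mean_metrics,
        "auc": cv.auc,
        "folds": [m.as_dict() for m in cv.fold_metrics],
    }, indent=2))
    artifacts.append(metrics_path)

    train_seed = derive_seed(config.seed, "final-train")
    logger.info("stage=final-train seed=%d", train_seed)
    final_cfg = model_mod.ModelConfig(**{**config.model.__dict__, "seed": train_seed})
    final_model = model_mod.train_model(networks, labels, final_cfg)
    model_path = out / "model" / "model.json"
    model_mod.save_model(final_model, model_path)
    artifacts.append(model_path)

    logger.info("stage=explain filter=%s", config.explain_filter)
    records = [model_mod.model_forward(net, final_model) for net in networks]
    fused = [explain.fuse_layer_maps(r, networks[0].region_labels)
             for r in records]
    outcome_code = {(1, 1): "TP", (1, 0): "FN", (0, 0): "TN", (0, 1): "FP"}
    outcomes = [outcome_code[(int(y), int(r.probability >= 0.5))]
                for y, r in zip(labels, records)]
    group = explain.group_mean_map(fused, outcomes=outcomes,
                                   subject_filter=config.explain_filter,
                                   subject_ids=ids)
    report = explain.threshold_entries(group)
    biomarker_payload = {
        "threshold": report.threshold,
        "supra_entries": report.supra_entries,
        "source_regions": report.source_regions,
        "aggregator_regions": report.aggregator_regions,
    }
    if truth is not None and truth.effect_regions:
        biomarker_payload["recovery_top8"] = explain.biomarker_recovery_score(
            report, truth, k=8)
        biomarker_payload["ground_truth_regions"] = sorted(truth.effect_regions)
    biomarker_path = out / "biomarkers.json"
    biomarker_path.write_text(json.dumps(biomarker_payload, indent=2))
    artifacts.append(biomarker_path)

    if config.run_permtest:
        perm_seed = derive_seed(config.seed, "permtest")
        logger.info("stage=permtest n_perm=%d seed=%d", config.n_perm, perm_seed)
        perm = evaluate.permutation_test(
            networks, labels, config.model, n_perm=config.n_perm,
            flip_fraction=config.flip_fraction, seed=perm_seed,
            k_folds=config.k_folds, fast=config.fast_permtest)
        perm_path = out / "permtest.json"
        perm_path.write_text(json.dumps({
            "observed_accuracy": perm.observed_accuracy,
            "p_value": perm.p_value,
            "n_perm": perm.n_perm,
            "flip_fraction": perm.flip_fraction,
            "null_accuracies": perm.null_accuracies.tolist(),
        }, indent=2))
        artifacts.append(perm_path)

    resolved_path = out / "resolved_config.yaml"
    resolved_path.write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))
    artifacts.append(resolved_path)

    manifest = {
        "artifacts": {str(p.relative_to(out)): _sha256(p) for p in artifacts},
        "n_subjects": len(ids),
        "n_regions": networks[0].M,
        "seed": config.seed,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
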