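"""End-to-end orchestration of the two-arm analysis.

Stages: simulate -> preprocess -> (optional t-map QC) -> extract ->
select -> train radiomics arm + train CNN arm on a shared held-out test
set -> paired score comparison.  Every stage writes its artifact under the
output directory and the run ends with a JSON manifest of file hashes and
derived seeds, so a rerun with the same configuration is verifiable
bit-for-bit.

All voxel coordinates in outputs are 0-based; volumes are NIfTI-1,
tables CSV, configuration YAML.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classify, select, stats_compare, tmap
from .grids import VolumeGrid, save_mask, save_volume
from .prep import PrepConfig
from .radiomics import ExtractionConfig, extract_cohort
from .synthcohort import (
    EllipsoidSpec,
    GeneratorConfig,
    SubjectRecord,
    make_records,
    pattern_mask,
    simulate_cohort,
)

__all__ = ["RunConfig", "run_all", "tmap_qc", "write_cohort", "load_run_config"]

log = logging.getLogger("petrad")


@dataclass
class RunConfig:
    """Everything one full run needs; round-trips through YAML."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    prep: PrepConfig = field(default_factory=PrepConfig)
    extraction: ExtractionConfig = field(default_factory=ExtractionConfig)
    selection_fraction: float = 0.10
    r_threshold: float = 0.30
    nn: classify.NNConfig = field(default_factory=classify.NNConfig)
    cnn: classify.CNNConfig = field(default_factory=classify.CNNConfig)
    n_test_per_class: int = 10
    shared_test: bool = True
    run_tmap_qc: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        # one global seed drives every stage through named substreams
        self.generator.seed = self.seed
        self.nn.seed = self.seed
        self.cnn.seed = self.seed

    def to_yaml(self, path) -> None:
        def enc(obj):
            if dataclasses.is_dataclass(obj):
                return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, dict):
                return {k: enc(v) for k, v in obj.items()}
            if isinstance(obj, tuple):
                return list(obj)
            return obj

        Path(path).write_text(yaml.safe_dump(enc(self), sort_keys=False))


def load_run_config(path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text())
    gen = dict(raw.pop("generator", {}))
    if "pattern_masks" in gen:
        gen["pattern_masks"] = {
            k: EllipsoidSpec(tuple(v["center_frac"]), tuple(v["semiaxes_frac"]))
            for k, v in gen["pattern_masks"].items()
        }
    for key in ("grid_shape", "voxel_size_mm", "age_mean_sd_controls", "age_mean_sd_patients"):
        if key in gen:
            gen[key] = tuple(gen[key])
    cfg = RunConfig(
        generator=GeneratorConfig(**gen),
        prep=PrepConfig(**raw.pop("prep", {})),
        extraction=ExtractionConfig(**raw.pop("extraction", {})),
        nn=classify.NNConfig(**_tupled(raw.pop("nn", {}), "hidden_sizes")),
        cnn=classify.CNNConfig(**_tupled(raw.pop("cnn", {}), "channels", "input_shape")),
        **raw,
    )
    return cfg


def _tupled(d: dict, *keys: str) -> dict:
    for k in keys:
        if k in d:
            d[k] = tuple(d[k])
    return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_cohort(records: list[SubjectRecord], volumes: list[VolumeGrid],
                 mask: np.ndarray, outdir: Path) -> list[Path]:
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for rec, vol in zip(records, volumes):
        p = outdir / f"{rec.subject_id}.nii.gz"
        save_volume(vol, p)
        paths.append(p)
    save_mask(mask, volumes[0].voxel_size_mm, outdir / "brain_mask.nii.gz")
    table = pd.DataFrame(
        [(r.subject_id, r.group, r.subtype, r.age) for r in records],
        columns=["subject_id", "group", "subtype", "age"],
    )
    table.to_csv(outdir / "participants.csv", index=False)
    return paths + [outdir / "brain_mask.nii.gz", outdir / "participants.csv"]


def tmap_qc(
    records: list[SubjectRecord],
    volumes: list[VolumeGrid],
    mask: np.ndarray,
    config: GeneratorConfig,
    p_threshold: float = 0.01,
    min_extent: int = 100,
) -> pd.DataFrame:
    """Automated surrogate for visual t-map review: for each patient,
    compare against all controls and check whether at least one
    supra-extent hypometabolic cluster overlaps the patient's own subtype
    pattern region.  Returns a per-patient table with a summary attribute
    ``detection_fraction``."""
    controls = [v for r, v in zip(records, volumes) if r.group == "control"]
    control_ages = [r.age for r in records if r.group == "control"]
    rows = []
    for rec, vol in zip(records, volumes):
        if rec.group == "control":
            continue
        ages = np.r_[rec.age, control_ages]
        tm = tmap.voxelwise_glm_t(vol, controls, ages, mask)
        report = tmap.extract_clusters(tm, mask, p_threshold, min_extent, direction="hypo")
        region = pattern_mask(rec.subtype, config, brain=mask)
        hit = False
        if report.clusters:
            with np.errstate(invalid="ignore"):
                supra = mask & (tm.p_values < p_threshold) & (tm.t_values < 0)
            from scipy import ndimage as ndi

            labels, _ = ndi.label(supra, structure=ndi.generate_binary_structure(3, 2))
            for cl in report.clusters:
                lab = labels[cl.peak_coordinate]
                if (region & (labels == lab)).any():
                    hit = True
                    break
        rows.append({
            "subject_id": rec.subject_id,
            "subtype": rec.subtype,
            "n_clusters": len(report.clusters),
            "largest_cluster": report.clusters[0].voxel_count if report.clusters else 0,
            "pattern_hit": hit,
        })
    out = pd.DataFrame(rows)
    out.attrs["detection_fraction"] = float(out["pattern_hit"].mean()) if len(out) else float("nan")
    return out


def run_all(config: RunConfig, outdir) -> dict:
    """Execute the full two-arm analysis and return the run manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")
    artifacts: list[Path] = [outdir / "config.yaml"]

    log.info("stage simulate: %d + %d subjects on grid %s",
             config.generator.n_controls,
             sum(config.generator.n_patients_by_subtype.values()),
             config.generator.grid_shape)
    if sum(config.generator.n_patients_by_subtype.values()) == 0:
        raise ValueError("cohort has no patients; cannot train a two-class model")
    records, volumes, mask = simulate_cohort(config.generator)
    artifacts += write_cohort(records, volumes, mask, outdir / "cohort")
    # generated volumes are already smoothed and global-mean scaled by the
    # simulator (whose parameters mirror PrepConfig); re-preprocessing here
    # would double-smooth.

    groups = [r.group for r in records]
    y = classify.encode_labels(groups)
    ids = [r.subject_id for r in records]

    if config.run_tmap_qc:
        log.info("stage tmap-qc")
        qc = tmap_qc(records, volumes, mask, config.generator)
        qc.to_csv(outdir / "tmap_qc.csv", index=False)
        artifacts.append(outdir / "tmap_qc.csv")

    log.info("stage extract: 215 features per subject")
    features = extract_cohort(volumes, mask, config.extraction, subject_ids=ids)
    features.to_csv(outdir / "features.csv")
    artifacts.append(outdir / "features.csv")

    test_idx = classify.shared_test_split(y, config.n_test_per_class, config.seed)
    dev_idx = np.setdiff1d(np.arange(len(y)), test_idx)

    log.info("stage select: MRMR + correlation pruning (training subjects only)")
    # drop template-constant features (zero variance) before MRMR
    sel_result = select.select_features(
        features.iloc[dev_idx], y[dev_idx],
        fraction=config.selection_fraction, r_threshold=config.r_threshold,
    )
    kept = sel_result.kept_after_prune
    pd.Series(sel_result.ranked_features[: sel_result.k_selected], name="feature").to_csv(
        outdir / "selected_features.csv", index=False
    )
    sel_result.correlation_matrix.to_csv(outdir / "correlation_certificate.csv")
    artifacts += [outdir / "selected_features.csv", outdir / "correlation_certificate.csv"]
    log.info("kept %d features after pruning: %s", len(kept), kept)

    log.info("stage train radiomics arm")
    nn_splits = classify.make_splits(
        y, classify.SplitSpec(fractions=(0.8, 0.1, 0.1), seed=config.seed),
        test_indices=test_idx,
    )
    _, nn_scores, nn_metrics = classify.train_feature_nn(
        features[kept], y, nn_splits, config.nn
    )
    nn_scores.to_csv(outdir / "scores_radiomics.csv", index=False)
    artifacts.append(outdir / "scores_radiomics.csv")

    log.info("stage train CNN arm (input %s)", config.cnn.input_shape)
    cnn_splits = classify.make_splits(
        y, classify.SplitSpec(fractions=(0.8, 0.1, 0.1), seed=config.seed),
        test_indices=test_idx,
    )
    _, cnn_scores, cnn_metrics = classify.train_cnn_3d(
        volumes, y, cnn_splits, config.cnn, subject_ids=ids
    )
    cnn_scores.to_csv(outdir / "scores_cnn.csv", index=False)
    artifacts.append(outdir / "scores_cnn.csv")

    log.info("stage compare")
    comparison = stats_compare.compare_models(nn_scores, cnn_scores)
    comparison.to_frame().to_csv(outdir / "comparison.csv", index=False)
    artifacts.append(outdir / "comparison.csv")

    manifest = {
        "seed": config.seed,
        "n_subjects": len(records),
        "n_features": int(features.shape[1]),
        "kept_features": kept,
        "metrics": {"radiomics_nn": nn_metrics, "cnn_3d": cnn_metrics},
        "comparison": {
            g: {"p": c.p, "verdict": c.verdict, "mean_difference": c.mean_difference}
            for g, c in comparison.groups.items()
        },
        "artifacts": {str(p.relative_to(outdir)): _sha256(p) for p in artifacts},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
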