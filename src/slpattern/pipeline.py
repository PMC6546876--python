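"""End-to-end orchestration: cohort -> searchlight -> cluster inference ->
permutation validation -> post-hoc statistics -> clinical table -> report.

A single global seed deterministically derives per-stage seeds through
``numpy.random.SeedSequence.spawn`` (order: cohort, cluster permutations,
Monte-Carlo extent simulation), so identical configs produce identical
reports and stages can be re-run independently.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .clinical_table import table1
from .cluster_inference import (
    ClusterSet,
    InferenceConfig,
    accuracy_to_pmap,
    label_clusters,
    run_cluster_permutations,
)
from .posthoc_stats import (
    ExtentThreshold,
    GlmDesign,
    apply_correction,
    glm_tmap,
    mc_extent_threshold,
    spearman_cluster_dvas,
)
from .searchlight_mvpa import SvmConfig, searchlight_map
from .synthetic_cohort import (
    Blob,
    Cohort,
    CohortSpec,
    EffectSpec,
    delta_vas,
    generate_cohort,
    read_cohort,
)
from .volume_geometry import VolumeGrid, write_volume

logger = logging.getLogger("slpattern")

__all__ = ["PipelineConfig", "run_pipeline", "load_config", "encode_covariates"]


@dataclass
class PipelineConfig:
    """Everything one pipeline run needs; exactly one input source."""

    # input: either a synthetic spec or paths
    synthetic: CohortSpec = None
    volumes_path: str = None
    mask_path: str = None
    subjects_path: str = None
    # stages
    radius_mm: float = 5.0
    svm: SvmConfig = field(default_factory=SvmConfig)
    inference: InferenceConfig = field(default_factory=InferenceConfig)
    extent: ExtentThreshold = field(default_factory=ExtentThreshold)
    regress_covariates: list = field(default_factory=list)  # pre-classification
    posthoc_covariates: list = field(default_factory=lambda: ["age", "gender"])
    spearman_group: str = "MSP"
    run_posthoc: bool = True
    out_dir: str = "."
    seed: int = 0

    def __post_init__(self):
        has_synth = self.synthetic is not None
        has_paths = self.volumes_path is not None
        if has_synth == has_paths:
            raise ValueError("config must give exactly one input source "
                             "(synthetic spec or volume/subject paths)")


def encode_covariates(table: pd.DataFrame, names) -> np.ndarray:
    """Numeric covariate matrix from subject-table columns (gender -> 0/1)."""
    cols = []
    for name in names:
        if name == "gender":
            cols.append((table["gender"].to_numpy() == "M").astype(float))
        else:
            cols.append(table[name].to_numpy(dtype=float))
    return np.column_stack(cols) if cols else None


def _cluster_record(cluster, grid: VolumeGrid):
    peak_mm = grid.voxel_to_world([cluster.peak])[0]
    return {
        "label": int(cluster.label),
        "size": int(cluster.size),
        "peak_voxel": [int(v) for v in cluster.peak],
        "peak_mm": [float(v) for v in peak_mm],
        "peak_p": float(cluster.peak_p),
        "peak_accuracy": float(cluster.peak_accuracy),
        "permutation_p": None if cluster.perm_p is None else float(cluster.perm_p),
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages and write artifacts under ``config.out_dir``.

    Returns the report dict (also written as report.json).
    """
    os.makedirs(config.out_dir, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    seed_cohort, seed_perm, seed_mc = (int(s.generate_state(1)[0]) for s in ss.spawn(3))

    # --- stage 1: cohort -------------------------------------------------
    if config.synthetic is not None:
        spec = replace(config.synthetic, seed=seed_cohort)
        logger.info("generating synthetic cohort (n=%d+%d, seed=%d)",
                    spec.n1, spec.n2, seed_cohort)
        cohort = generate_cohort(spec)
    else:
        logger.info("loading cohort from %s", config.volumes_path)
        cohort = read_cohort(config.volumes_path, config.subjects_path,
                             config.mask_path)
    grid = cohort.grid
    labels = cohort.labels()
    n = cohort.n_subjects

    # --- stage 2: searchlight -------------------------------------------
    covariates = None
    if config.regress_covariates:
        covariates = encode_covariates(cohort.table, config.regress_covariates)
        logger.info("regressing out covariates before classification: %s",
                    config.regress_covariates)
    logger.info("searchlight over %d mask voxels (radius %.1f mm)",
                grid.n_mask_voxels, config.radius_mm)
    acc = searchlight_map(cohort.volumes, labels, grid, config.radius_mm,
                          config.svm, covariates=covariates)
    write_volume(acc.accuracy, grid, os.path.join(config.out_dir, "accuracy.nii.gz"))

    # --- stage 3: binomial p-map & clusters ------------------------------
    pmap = accuracy_to_pmap(acc, strict=config.inference.strict_tail)
    write_volume(pmap.p, grid, os.path.join(config.out_dir, "pmap.nii.gz"))
    clusters = label_clusters(pmap, config.inference, accuracy=acc)
    logger.info("found %d clusters (p<%g, >=%d voxels, %d-connectivity)",
                len(clusters), config.inference.voxel_alpha,
                config.inference.min_size, config.inference.connectivity)

    # --- stage 4: permutation validation ---------------------------------
    perm_cfg = replace(config.inference, seed=seed_perm)
    run_cluster_permutations(cohort.volumes, labels, clusters,
                             svm_config=config.svm, cfg=perm_cfg)
    write_volume(clusters.labels.astype(float), grid,
                 os.path.join(config.out_dir, "clusters.nii.gz"))
    cluster_records = [_cluster_record(c, grid) for c in clusters.clusters]
    with open(os.path.join(config.out_dir, "clusters.json"), "w") as fh:
        json.dump(cluster_records, fh, indent=2)

    # --- stage 5: post-hoc -----------------------------------------------
    posthoc = None
    if config.run_posthoc and len(clusters):
        cov = encode_covariates(cohort.table, config.posthoc_covariates)
        design = GlmDesign(group=labels, covariates=cov,
                           covariate_names=list(config.posthoc_covariates))
        tmap, df = glm_tmap(cohort.volumes, design, restrict_to=clusters)
        write_volume(tmap, grid, os.path.join(config.out_dir, "tmap.nii.gz"))
        extent = replace(config.extent, seed=seed_mc)
        min_size = mc_extent_threshold(grid, extent)
        extent = replace(extent, min_cluster_size=min_size)
        logger.info("Monte-Carlo extent threshold: %d voxels "
                    "(voxel p<%g, alpha=%g, fwhm=%g mm)", min_size,
                    extent.voxel_p, extent.alpha, extent.fwhm_mm)
        corrected = apply_correction(tmap, df, grid, extent)

        dvas = np.array([
            delta_vas(r.pre_vas, r.post_vas) for r in cohort.table.itertuples()
        ])
        in_group = cohort.table["group"].to_numpy() == config.spearman_group
        spearman = []
        for cluster in clusters.clusters:
            m = cluster.members
            mean_gm = cohort.volumes[:, m[:, 0], m[:, 1], m[:, 2]].mean(axis=1)
            try:
                rho, p = spearman_cluster_dvas(mean_gm[in_group], dvas[in_group])
            except ValueError:
                rho, p = float("nan"), float("nan")
            spearman.append({"cluster": int(cluster.label),
                             "rho": rho, "p": p,
                             "group": config.spearman_group})
        posthoc = {
            "df": int(df),
            "min_cluster_size": int(min_size),
            "surviving": {
                direction: [
                    {**_cluster_record(c, grid), "peak_t": float(c.peak_accuracy),
                     "direction": ("group1<group2" if direction == "negative"
                                   else "group1>group2")}
                    for c in cset.clusters
                ]
                for direction, cset in corrected.items()
            },
            "spearman": spearman,
        }
        with open(os.path.join(config.out_dir, "posthoc.json"), "w") as fh:
            json.dump(posthoc, fh, indent=2)

    # --- stage 6: clinical table -----------------------------------------
    clin = table1(cohort.table)
    clin.to_csv(os.path.join(config.out_dir, "table1.csv"), index=False)

    import slpattern

    report = {
        "n_subjects": int(n),
        "group_sizes": {str(g): int((cohort.table["group"] == g).sum())
                        for g in pd.unique(cohort.table["group"])},
        "radius_mm": float(config.radius_mm),
        "mask_voxels": int(grid.n_mask_voxels),
        "mask_mean_accuracy": float(np.nanmean(acc.accuracy)),
        "clusters": cluster_records,
        "posthoc": posthoc,
        "clinical_table": clin.to_dict(orient="records"),
        "provenance": {
            "seed": int(config.seed),
            "stage_seeds": {"cohort": seed_cohort, "permutation": seed_perm,
                            "monte_carlo": seed_mc},
            "version": slpattern.__version__,
            "config": _config_echo(config),
        },
    }
    with open(os.path.join(config.out_dir, "report.json"), "w") as fh:
        json.dump(report, fh, indent=2)
    return report


def _config_echo(config: PipelineConfig) -> dict:
    def clean(obj):
        if isinstance(obj, dict):
            return {k: clean(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [clean(v) for v in obj]
        if isinstance(obj, np.ndarray):
            return f"<array shape={obj.shape}>"
        if isinstance(obj, (np.integer, np.floating)):
            return obj.item()
        return obj

    d = asdict(config)
    if d.get("synthetic") is not None:
        d["synthetic"].pop("grid", None)
        grid = config.synthetic.grid
        d["synthetic"]["grid"] = {"shape": list(grid.shape),
                                  "voxel_size": list(grid.voxel_size)}
    return clean(d)


def _build_grid(section: dict) -> VolumeGrid:
    shape = section["shape"]
    voxel_size = section.get("voxel_size", 1.5)
    grid = VolumeGrid(shape, voxel_size)
    if "mask_margin" in section:
        m = int(section["mask_margin"])
        mask = np.zeros(grid.shape, dtype=bool)
        mask[m:-m or None, m:-m or None, m:-m or None] = True
        grid = grid.with_mask(mask)
    return grid


def load_config(path) -> PipelineConfig:
    """Build a PipelineConfig from a YAML file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)

    kwargs = {}
    if "synthetic" in raw:
        from .synthetic_cohort import MRP_MOMENTS, MSP_MOMENTS, GroupMoments

        s = dict(raw["synthetic"])
        grid = _build_grid(s.pop("grid"))
        blobs = [Blob(tuple(b["center"]), float(b["radius_mm"]), float(b["d"]))
                 for b in s.pop("blobs", [])]
        for key, default in (("group1_moments", MRP_MOMENTS),
                             ("group2_moments", MSP_MOMENTS)):
            if key in s:
                merged = {**asdict(default), **s[key]}
                merged = {k: tuple(v) if isinstance(v, list) else v
                          for k, v in merged.items()}
                s[key] = GroupMoments(**merged)
        kwargs["synthetic"] = CohortSpec(grid=grid, effect=EffectSpec(blobs), **s)
    if "input" in raw:
        kwargs["volumes_path"] = raw["input"]["volumes"]
        kwargs["mask_path"] = raw["input"].get("mask")
        kwargs["subjects_path"] = raw["input"]["subjects"]
    if "svm" in raw:
        kwargs["svm"] = SvmConfig(**raw["svm"])
    if "inference" in raw:
        kwargs["inference"] = InferenceConfig(**raw["inference"])
    if "extent" in raw:
        kwargs["extent"] = ExtentThreshold(**raw["extent"])
    for key in ("radius_mm", "regress_covariates", "posthoc_covariates",
                "spearman_group", "run_posthoc", "out_dir", "seed"):
        if key in raw:
            kwargs[key] = raw[key]
    return PipelineConfig(**kwargs)
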