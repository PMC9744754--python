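"""Stage orchestration: simulate → template → aggregate → cluster → evaluate → render.

Each stage reads only the previous stages' on-disk artifacts and writes
its own directory under ``config.out_dir`` together with a manifest
(parameters, seeds, config hash), so reruns with an identical config
reproduce identical label outputs and no stage mutates upstream artifacts.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .atlas import build_reference_atlas
from .clustering import cluster_regionwise, cluster_slicewise, sweep_cluster_counts
from .config import PipelineConfig
from .evaluation import (
    ari,
    contiguous_truth,
    match_and_color,
    overlap_matrix,
    render_hemisection,
)
from .io import (
    load_labels,
    load_parcellation,
    load_soft_atlas,
    load_stack,
    read_manifest,
    save_labels,
    save_parcellation,
    save_soft_atlas,
    save_stack,
    write_manifest,
)
from .signatures import default_signatures
from .synthetic import Cohort, SubjectSample, generate_cohort
from .registration import DisplacementField
from .template import aggregate_all_regions, build_template_stacks

STAGES = ("simulate", "template", "aggregate", "cluster", "evaluate", "render", "all")


class MissingUpstreamError(RuntimeError):
    """An earlier stage's artifacts are absent."""

    def __init__(self, needed: str, for_stage: str):
        super().__init__(
            f"stage {for_stage!r} needs artifacts from stage {needed!r}; "
            f"run `tractcluster {needed}` first"
        )


def _require(path: Path, needed: str, for_stage: str) -> Path:
    if not path.exists():
        raise MissingUpstreamError(needed, for_stage)
    return path


def _base_manifest(config: PipelineConfig) -> dict:
    return {"config_hash": config.config_hash(), "config": config.to_dict()}


# ---------------------------------------------------------------------------

def stage_simulate(config: PipelineConfig) -> Path:
    out = Path(config.out_dir) / "simulate"
    spec = config.atlas_spec()
    scheme = config.scheme()
    cohort = generate_cohort(
        spec,
        default_signatures(),
        n_subjects=config.n_subjects,
        scheme=scheme,
        seed=config.master_seed,
        noise_scale=config.noise_scale,
        deform_amplitude=config.deform_amplitude,
    )
    atlas_dir = Path(config.out_dir) / "atlas"
    for level in scheme.levels:
        atlas, _ = build_reference_atlas(spec, level, scheme)
        save_labels(atlas, atlas_dir / f"{level}_labels.nii")
    for (subject, level), sample in cohort.samples.items():
        sdir = out / f"sub-{subject:02d}" / level
        save_stack(sample.stack, sdir)
        save_labels(sample.truth, sdir / "truth.nii")
    write_manifest(out, _base_manifest(config) | cohort.manifest)
    return out


def _load_cohort(config: PipelineConfig) -> Cohort:
    out = Path(config.out_dir) / "simulate"
    manifest = read_manifest(_require(out, "simulate", "template"))
    scheme = config.scheme()
    samples = {}
    for subject in range(config.n_subjects):
        for level in scheme.levels:
            sdir = out / f"sub-{subject:02d}" / level
            stack = load_stack(sdir)
            truth = load_labels(sdir / "truth.nii")
            samples[(subject, level)] = SubjectSample(
                subject_id=subject,
                level=level,
                stack=stack,
                truth=truth,
                deformation=DisplacementField.identity(stack.shape),
                seed=manifest["sample_seeds"].get(f"{subject}:{level}", 0),
            )
    return Cohort(samples=samples, scheme=scheme, manifest=manifest)


def stage_template(config: PipelineConfig) -> Path:
    cohort = _load_cohort(config)
    out = Path(config.out_dir) / "template"
    templates = build_template_stacks(cohort, config.registration)
    for level, stack in templates.items():
        save_stack(stack, out / level)
    write_manifest(out, _base_manifest(config) | {"levels": cohort.scheme.levels})
    return out


def _load_templates(config: PipelineConfig, for_stage: str) -> dict:
    tdir = _require(Path(config.out_dir) / "template", "template", for_stage)
    return {lv: load_stack(tdir / lv) for lv in config.scheme().levels}


def stage_aggregate(config: PipelineConfig) -> Path:
    scheme = config.scheme()
    templates = _load_templates(config, "aggregate")
    adir = _require(Path(config.out_dir) / "atlas", "simulate", "aggregate")
    atlases = {lv: load_labels(adir / f"{lv}_labels.nii") for lv in scheme.levels}
    out = Path(config.out_dir) / "aggregate"
    regions = aggregate_all_regions(templates, atlases, scheme, config.registration)
    for region, (stack, soft) in regions.items():
        save_stack(stack, out / region)
        save_soft_atlas(soft, out / f"{region}_soft.nii")
    write_manifest(out, _base_manifest(config) | {"regions": scheme.regions})
    return out


def stage_cluster(config: PipelineConfig) -> Path:
    out = Path(config.out_dir) / "cluster"
    scheme = config.scheme()
    if config.mode == "slice":
        templates = _load_templates(config, "cluster")
        if config.sweep:
            lo, hi = config.sweep
            results = {}
            for level, stack in templates.items():
                for k, parc in sweep_cluster_counts(
                    stack, range(lo, hi + 1), config.connectivity, config.metrics
                ).items():
                    results[f"slice/{level}_k{k:02d}"] = parc
        else:
            parcs = cluster_slicewise(
                templates, config.n_clusters, config.connectivity, config.metrics
            )
            results = {f"slice/{lv}": p for lv, p in parcs.items()}
    else:
        agg = _require(Path(config.out_dir) / "aggregate", "aggregate", "cluster")
        stacks = {r: load_stack(agg / r) for r in scheme.regions}
        if config.sweep:
            lo, hi = config.sweep
            results = {}
            for region, stack in stacks.items():
                for k, parc in sweep_cluster_counts(
                    stack, range(lo, hi + 1), config.connectivity, config.metrics
                ).items():
                    results[f"region/{region}_k{k:02d}"] = parc
        else:
            parcs = cluster_regionwise(
                stacks, config.n_clusters, config.connectivity, config.metrics
            )
            results = {f"region/{r}": p for r, p in parcs.items()}
    for name, parc in results.items():
        path = out / f"{name}_parc.nii"
        path.parent.mkdir(parents=True, exist_ok=True)
        save_parcellation(parc, path)
    existing: list[str] = []
    if (out / "manifest.json").exists():
        existing = read_manifest(out).get("outputs", [])
    outputs = sorted(set(existing) | set(results))
    write_manifest(out, _base_manifest(config) | {"outputs": outputs})
    return out


def _cluster_outputs(config: PipelineConfig, for_stage: str):
    cdir = _require(Path(config.out_dir) / "cluster", "cluster", for_stage)
    names = read_manifest(cdir)["outputs"]
    return {name: load_parcellation(cdir / f"{name}_parc.nii") for name in names}


def _reference_for(config: PipelineConfig, name: str):
    """Reference labels for a cluster output: level atlas or region soft atlas."""
    kind, _, rest = name.partition("/")
    key = rest.split("_k")[0]
    if kind == "slice":
        adir = _require(Path(config.out_dir) / "atlas", "simulate", "evaluate")
        return load_labels(adir / f"{key}_labels.nii")
    agg = _require(Path(config.out_dir) / "aggregate", "aggregate", "evaluate")
    return load_soft_atlas(agg / f"{key}_soft.nii")


def stage_evaluate(config: PipelineConfig) -> Path:
    out = Path(config.out_dir) / "evaluate"
    out.mkdir(parents=True, exist_ok=True)
    scores: dict[str, dict] = {}
    for name, parc in _cluster_outputs(config, "evaluate").items():
        ref = _reference_for(config, name)
        om = overlap_matrix(parc, ref)
        colors = match_and_color(om)
        entry = {
            "n_clusters": parc.n_clusters,
            "overlap": om.matrix.tolist(),
            "cluster_ids": list(om.cluster_ids),
            "tract_ids": list(om.tract_ids),
            "matched_tract": {str(k): v for k, v in colors.matched_tract.items()},
            "intensity": {str(k): v for k, v in colors.intensities.items()},
        }
        if hasattr(ref, "labels"):  # discrete reference: ARI is defined
            entry["ari_vs_tracts"] = ari(parc, ref)
            entry["ari_vs_contiguous_regions"] = ari(
                parc, contiguous_truth(ref, config.connectivity)
            )
        scores[name] = entry
    (out / "scores.json").write_text(json.dumps(scores, indent=2, sort_keys=True))
    write_manifest(out, _base_manifest(config) | {"n_scored": len(scores)})
    return out


def stage_render(config: PipelineConfig) -> Path:
    out = Path(config.out_dir) / "render"
    out.mkdir(parents=True, exist_ok=True)
    count = 0
    for name, parc in _cluster_outputs(config, "render").items():
        ref = _reference_for(config, name)
        if not hasattr(ref, "labels"):
            # soft reference: render against its argmax labelling
            pv = ref.partial_volumes
            lab = np.where(
                pv.max(axis=0) > 0.5,
                np.asarray(ref.tract_ids, dtype=np.int32)[np.argmax(pv, axis=0)],
                0,
            )
            from .images import LabelAtlas

            ref = LabelAtlas(labels=lab.astype(np.int32), names=dict(ref.names))
        om = overlap_matrix(parc, ref)
        colors = match_and_color(om)
        png = out / (name.replace("/", "_") + ".png")
        render_hemisection(parc, ref, colors, png)
        count += 1
    write_manifest(out, _base_manifest(config) | {"n_rendered": count})
    return out


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "template": stage_template,
    "aggregate": stage_aggregate,
    "cluster": stage_cluster,
    "evaluate": stage_evaluate,
    "render": stage_render,
}


def run(config: PipelineConfig, stage: str) -> list[Path]:
    """Run one pipeline stage (or ``all``) and return the output paths."""
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}; choose from {STAGES}")
    if stage == "all":
        order = ["simulate", "template"]
        if config.mode == "region":
            order.append("aggregate")
        order += ["cluster", "evaluate"]
        if config.render:
            order.append("render")
        return [_STAGE_FUNCS[s](config) for s in order]
    return [_STAGE_FUNCS[stage](config)]


def run_both_modes(config: PipelineConfig) -> list[Path]:
    """Full study: slice-wise and region-wise clustering from one simulation."""
    import dataclasses

    paths = [stage_simulate(config), stage_template(config), stage_aggregate(config)]
    for mode in ("slice", "region"):
        cfg = dataclasses.replace(config, mode=mode)
        paths.append(stage_cluster(cfg))
        paths.append(stage_evaluate(cfg))
        if config.render:
            paths.append(stage_render(cfg))
    return paths
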