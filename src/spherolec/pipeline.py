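"""End-to-end orchestration: acquire → preprocess → segment → quantify → stats.

A run is described by one structured config (YAML or dict) with exactly
one input mode:

* ``simulate``: generate a phantom timecourse per replicate with a
  mandatory seed (plus the phantom parameters);
* ``load``: read existing stacks from disk, one record per
  (condition, day, replicate) with TNBC and LEC file paths.

Outputs are written under ``output_dir``: the stacks and truth tables
(simulate mode), per-stack masks, the long-format volume table and
overlap table as CSV, a statistics report, QC orthogonal projections,
and a ``manifest.json`` echoing every parameter actually used. Identical
config + seed yields byte-identical CSV outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ConfigurationError, PipelineStageError, SpherolecError, UndefinedStatisticError
from .image_io import ImageStack, read_stack, write_stack
from .phantoms import PhantomConfig, generate_timecourse
from .preprocess import PreprocessParams
from .quantify import DecompParams, OverlapParams, quantify_experiment
from .segment import SegmentParams
from .stats import box_whisker_summary, one_way_anova, tukey_hsd, validate_volume_table

__all__ = ["PipelineConfig", "run_pipeline"]

logger = logging.getLogger(__name__)

CSV_FLOAT_FORMAT = "%.6f"


@dataclass
class PipelineConfig:
    """Validated configuration of one pipeline run."""

    mode: str  # "simulate" | "load"
    output_dir: str
    phantom: PhantomConfig | None = None
    n_replicates: int = 3
    condition: str = "coculture"
    load_records: list[dict] = field(default_factory=list)
    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    segment: dict[str, SegmentParams] = field(default_factory=dict)
    overlap: OverlapParams = field(default_factory=OverlapParams)
    decomp: DecompParams = field(default_factory=DecompParams)
    stats_group: str = "day"
    stats_compartments: tuple[str, ...] = ("tnbc_total", "tnbc_core", "tnbc_outgrowth", "lec_total")
    alpha: float = 0.05
    seed: int | None = None
    log_level: str = "INFO"
    write_qc: bool = False

    def __post_init__(self):
        if self.mode not in ("simulate", "load"):
            raise ConfigurationError(f"mode must be 'simulate' or 'load', got '{self.mode}'")
        if self.mode == "simulate":
            if self.seed is None:
                raise ConfigurationError("simulate mode requires an explicit seed")
            if self.phantom is None:
                self.phantom = PhantomConfig(seed=self.seed)
        else:
            if not self.load_records:
                raise ConfigurationError("load mode requires at least one input record")
        for chan in ("TNBC", "LEC"):
            self.segment.setdefault(chan, SegmentParams())

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        has_sim = "simulate" in raw
        has_load = "load" in raw
        if has_sim == has_load:
            raise ConfigurationError(
                "config must contain exactly one input mode section: 'simulate' or 'load'"
            )
        seed = raw.get("seed")
        kwargs: dict = {
            "mode": "simulate" if has_sim else "load",
            "output_dir": raw.get("output_dir", "spherolec_out"),
            "seed": seed,
            "alpha": raw.get("alpha", 0.05),
            "stats_group": raw.get("stats_group", "day"),
            "log_level": raw.get("log_level", "INFO"),
            "write_qc": raw.get("write_qc", False),
        }
        if has_sim:
            sim = dict(raw["simulate"] or {})
            kwargs["n_replicates"] = sim.pop("n_replicates", 3)
            kwargs["condition"] = sim.pop("condition", "coculture")
            for tup in ("grid_shape", "voxel_size", "psf_sigma", "timepoints", "growth_ref_days"):
                if tup in sim:
                    sim[tup] = tuple(sim[tup])
            if seed is not None:
                sim.setdefault("seed", seed)
            kwargs["phantom"] = PhantomConfig(**sim)
        else:
            kwargs["load_records"] = list(raw["load"])
        if "preprocess" in raw:
            kwargs["preprocess"] = PreprocessParams(**{
                k: tuple(v) if k == "rescale_percentiles" else v
                for k, v in raw["preprocess"].items()
            })
        if "segment" in raw:
            seg = raw["segment"]
            if any(chan in seg for chan in ("TNBC", "LEC")):
                kwargs["segment"] = {c: SegmentParams(**p) for c, p in seg.items()}
            else:
                kwargs["segment"] = {c: SegmentParams(**seg) for c in ("TNBC", "LEC")}
        if "overlap" in raw:
            kwargs["overlap"] = OverlapParams(**raw["overlap"])
        if "decomp" in raw:
            kwargs["decomp"] = DecompParams(**raw["decomp"])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _params_echo(config: PipelineConfig) -> dict:
    def enc(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, dict):
            return {k: enc(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [enc(v) for v in obj]
        if isinstance(obj, np.generic):
            return obj.item()
        return obj

    return enc(dataclasses.asdict(config))


def _simulate_stage(config: PipelineConfig, outdir: str):
    """Generate phantom timecourses per replicate; write stacks and truth."""
    entries = []
    truth_rows = []
    base_seed = int(config.seed)
    rep_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in
                 np.random.SeedSequence(base_seed).spawn(config.n_replicates)]
    stack_dir = os.path.join(outdir, "stacks")
    os.makedirs(stack_dir, exist_ok=True)
    for rep, rep_seed in enumerate(rep_seeds, start=1):
        cfg = dataclasses.replace(config.phantom, seed=rep_seed)
        for day, stacks, truth in generate_timecourse(cfg):
            key = (config.condition, day, rep)
            for chan, stack in stacks.items():
                stack.meta.update(condition=config.condition, day=day, replicate=rep)
                path = os.path.join(stack_dir, f"{config.condition}_d{day:g}_r{rep}_{chan}.ome.tif")
                write_stack(stack, path)
            import tifffile

            stem = os.path.join(stack_dir, f"{config.condition}_d{day:g}_r{rep}")
            tifffile.imwrite(f"{stem}_truth_tnbc_labels.tif",
                             truth.tnbc_labels.astype(np.uint16))
            tifffile.imwrite(f"{stem}_truth_lec_mask.tif",
                             truth.lec_truth_mask.voxels.astype(np.uint8))
            entries.append((key, stacks))
            truth_rows.append({
                "condition": config.condition, "day": day, "replicate": rep,
                "lec_volume": truth.lec_total_volume,
                "tnbc_volume": truth.tnbc_total_volume,
                "tnbc_core_volume": sum(s.core_volume for s in truth.per_spheroid),
                "tnbc_outgrowth_volume": sum(s.outgrowth_volume for s in truth.per_spheroid),
                "true_degree_object": truth.true_degree_object,
                "true_degree_voxel": truth.true_degree_voxel,
            })
    truth_df = pd.DataFrame(truth_rows).sort_values(
        ["condition", "day", "replicate"], kind="mergesort").reset_index(drop=True)
    truth_path = os.path.join(outdir, "truth.csv")
    truth_df.to_csv(truth_path, index=False, float_format=CSV_FLOAT_FORMAT)
    return entries, {"truth_table": truth_path, "stack_dir": stack_dir}


def _load_stage(config: PipelineConfig):
    entries = []
    for rec in config.load_records:
        key = (rec["condition"], rec["day"], rec["replicate"])
        stacks = {
            "TNBC": read_stack(rec["tnbc_path"], channel="TNBC",
                               voxel_size_override=rec.get("voxel_size")),
            "LEC": read_stack(rec["lec_path"], channel="LEC",
                              voxel_size_override=rec.get("voxel_size")),
        }
        entries.append((key, stacks))
    return entries, {}


def _stats_stage(config: PipelineConfig, volumes: pd.DataFrame, overlaps: pd.DataFrame,
                 outdir: str) -> dict:
    lines = [f"spherolec {__version__} statistics report", ""]
    stats_rows = []
    group = config.stats_group
    for comp in config.stats_compartments:
        sub = volumes[volumes["compartment"] == comp]
        if sub.empty:
            continue
        lines.append(f"== compartment: {comp} (grouped by {group}) ==")
        summary = box_whisker_summary(sub, group=group)
        lines.append(summary.to_string(index=False))
        try:
            anova = one_way_anova(sub, group=group)
            lines.append(
                f"one-way ANOVA: F({anova.df_between}, {anova.df_within}) = "
                f"{anova.f_stat:.4f}, p = {anova.p_value:.4g}"
            )
            stats_rows.append({"compartment": comp, "test": "anova", "group_a": "", "group_b": "",
                               "statistic": anova.f_stat, "p": anova.p_value, "significant": anova.p_value <= config.alpha})
            tukey = tukey_hsd(sub, group=group, alpha=config.alpha)
            for c in tukey.comparisons:
                lines.append(
                    f"  Tukey {c.group_a} vs {c.group_b}: diff = {c.mean_diff:.2f}, "
                    f"p_adj = {c.p_adj:.4g}{' *' if c.significant else ''}"
                )
                stats_rows.append({"compartment": comp, "test": "tukey",
                                   "group_a": c.group_a, "group_b": c.group_b,
                                   "statistic": c.mean_diff, "p": c.p_adj,
                                   "significant": c.significant})
        except (ConfigurationError, UndefinedStatisticError) as exc:
            lines.append(f"group comparison skipped: {exc}")
        lines.append("")

    lines.append("== degree of overlap by day (mean over replicates) ==")
    by_day = overlaps.groupby("day", sort=True)["degree"].mean()
    for day, val in by_day.items():
        lines.append(f"  day {day:g}: degree = {val:.4f}")

    report_path = os.path.join(outdir, "report.txt")
    with open(report_path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    stats_path = os.path.join(outdir, "stats.csv")
    pd.DataFrame(stats_rows, columns=["compartment", "test", "group_a", "group_b",
                                      "statistic", "p", "significant"]).to_csv(
        stats_path, index=False, float_format=CSV_FLOAT_FORMAT)
    return {"report": report_path, "stats_table": stats_path}


def _qc_stage(entries, outdir: str) -> dict:
    """Maximum-intensity orthogonal projections per stack, for eyeballing."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    qc_dir = os.path.join(outdir, "qc")
    os.makedirs(qc_dir, exist_ok=True)
    for (condition, day, rep), stacks in entries:
        fig, axes = plt.subplots(2, 3, figsize=(9, 6))
        for row, (chan, stack) in enumerate(sorted(stacks.items())):
            for col, axis in enumerate(range(3)):
                axes[row, col].imshow(np.max(stack.intensities, axis=axis), cmap="magma")
                axes[row, col].set_title(f"{chan} proj axis {axis}", fontsize=8)
                axes[row, col].axis("off")
        fig.suptitle(f"{condition} day {day} rep {rep}")
        fig.savefig(os.path.join(qc_dir, f"{condition}_d{day:g}_r{rep}.png"), dpi=80)
        plt.close(fig)
    return {"qc_dir": qc_dir}


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; return (and write) the run manifest.

    The manifest echoes every parameter actually used, the package
    version, and the path of every output, making the run reproducible
    from the manifest alone. Any stage error aborts the run with the
    stage name; stages completed so far are listed in the raised error's
    manifest context.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    outdir = config.output_dir
    os.makedirs(outdir, exist_ok=True)
    manifest: dict = {
        "software": {"name": "spherolec", "version": __version__},
        "parameters": _params_echo(config),
        "outputs": {},
        "stages_completed": [],
        "partial": False,
    }

    def run_stage(name, fn, *args):
        try:
            result = fn(*args)
        except SpherolecError as exc:
            manifest["partial"] = True
            manifest["failed_stage"] = name
            _write_manifest(manifest, outdir)
            raise PipelineStageError(name, str(exc)) from exc
        manifest["stages_completed"].append(name)
        return result

    if config.mode == "simulate":
        entries, outputs = run_stage("simulate", _simulate_stage, config, outdir)
    else:
        entries, outputs = run_stage("load", _load_stage, config)
    manifest["outputs"].update(outputs)

    mask_dir = os.path.join(outdir, "masks")
    os.makedirs(mask_dir, exist_ok=True)
    object_rows: list[dict] = []

    def mask_sink(key, channel, mask, labels):
        import tifffile

        condition, day, rep = key
        stem = f"{condition}_d{day:g}_r{rep}_{channel}"
        tifffile.imwrite(os.path.join(mask_dir, f"{stem}_mask.tif"),
                         mask.voxels.astype(np.uint8))
        if labels is not None:
            tifffile.imwrite(os.path.join(mask_dir, f"{stem}_labels.tif"),
                             labels.labels.astype(np.uint16))
            for rec in labels.objects:
                object_rows.append({
                    "condition": condition, "day": day, "replicate": rep,
                    "label": rec.label, "voxel_count": rec.voxel_count,
                    "volume": rec.volume,
                    "centroid_z": rec.centroid[0], "centroid_y": rec.centroid[1],
                    "centroid_x": rec.centroid[2],
                })

    volumes, overlaps = run_stage(
        "quantify",
        lambda: quantify_experiment(
            entries,
            preprocess_params=config.preprocess,
            segment_params=config.segment,
            overlap_params=config.overlap,
            decomp_params=config.decomp,
            mask_sink=mask_sink,
        ),
    )
    objects_path = os.path.join(outdir, "objects.csv")
    pd.DataFrame(object_rows, columns=["condition", "day", "replicate", "label",
                                       "voxel_count", "volume", "centroid_z",
                                       "centroid_y", "centroid_x"]).to_csv(
        objects_path, index=False, float_format=CSV_FLOAT_FORMAT)
    manifest["outputs"].update(mask_dir=mask_dir, object_table=objects_path)
    validate_volume_table(volumes)
    vol_path = os.path.join(outdir, "volumes.csv")
    ov_path = os.path.join(outdir, "overlap.csv")
    volumes.to_csv(vol_path, index=False, float_format=CSV_FLOAT_FORMAT)
    overlaps.to_csv(ov_path, index=False, float_format=CSV_FLOAT_FORMAT)
    manifest["outputs"].update(volume_table=vol_path, overlap_table=ov_path)

    manifest["outputs"].update(run_stage("stats", _stats_stage, config, volumes, overlaps, outdir))
    if config.write_qc:
        manifest["outputs"].update(run_stage("qc", _qc_stage, entries, outdir))

    _write_manifest(manifest, outdir)
    return manifest


def _write_manifest(manifest: dict, outdir: str) -> None:
    path = os.path.join(outdir, "manifest.json")
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    manifest["outputs"]["manifest"] = path
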