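"""End-to-end orchestration: simulate → segment → measure → summarize → compare.

Each stage reads the previous stage's on-disk outputs, so the chained
subcommands of the CLI and one monolithic :func:`run_pipeline` call
produce byte-identical tables.  A run directory looks like::

    out/
      manifest.json           # config actually used, versions, timings
      stacks/<sample>.tif     # simulated stacks (+ .json sidecars)
      ground_truth/<sample>.csv
      labels/<sample>.tif     # integer label volumes
      segmentation/<sample>.json  # tissue volume, filter counts
      records/<sample>.csv    # per-object morphometry
      summaries.csv           # one row per sample
      ratios.csv              # ipsi/contra pairs
      volume_histogram.csv
      shape_scatter.csv
      comparisons.json
      figures/*.png

Because many acquisition-side parameters have no published values, the
manifest records every default actually used and is the provenance
record of a run.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import io as cmio
from . import segmentation as seg
from . import morphometry as morph
from . import stats as cmstats
from .synthetic import CohortDesign, GroupEffect, SceneSpec, generate_cohort

logger = logging.getLogger("clearmorph")

__all__ = ["PipelineConfig", "run_pipeline", "STAGES"]

STAGES = ("simulate", "segment", "measure", "summarize", "compare")


@dataclass
class PipelineConfig:
    """Fully serializable description of one pipeline run."""

    out_dir: str = "runs/demo"
    seed: int = 0
    n_samples_per_group: int = 2
    tissues: tuple[str, ...] = ("DRG",)
    scene: SceneSpec = field(default_factory=SceneSpec)
    effects: dict[tuple[str, str, str, str], GroupEffect] = field(default_factory=dict)
    segmentation: seg.SegmentationParams = field(default_factory=seg.SegmentationParams)
    histogram_bins: int = 20
    alpha: float = 0.05
    phenotype_margin: float = 0.05

    def design(self) -> CohortDesign:
        return CohortDesign(base_spec=self.scene, tissues=tuple(self.tissues), effects=self.effects)

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "out_dir": self.out_dir,
            "seed": self.seed,
            "n_samples_per_group": self.n_samples_per_group,
            "tissues": list(self.tissues),
            "scene": self.scene.to_dict(),
            "effects": {
                "/".join(k): dataclasses.asdict(v) for k, v in self.effects.items()
            },
            "segmentation": dataclasses.asdict(self.segmentation),
            "histogram_bins": self.histogram_bins,
            "alpha": self.alpha,
            "phenotype_margin": self.phenotype_margin,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        scene_d = dict(d.get("scene", {}))
        for key in ("stack_shape", "voxel_size", "tissue_envelope"):
            if scene_d.get(key) is not None:
                scene_d[key] = tuple(scene_d[key])
        if scene_d.get("cell_axes") is not None:
            scene_d["cell_axes"] = [tuple(t) for t in scene_d["cell_axes"]]
        effects = {}
        for key, eff in (d.get("effects") or {}).items():
            parts = tuple(key.split("/"))
            effects[parts] = GroupEffect(**eff)
        return cls(
            out_dir=d.get("out_dir", "runs/demo"),
            seed=int(d.get("seed", 0)),
            n_samples_per_group=int(d.get("n_samples_per_group", 2)),
            tissues=tuple(d.get("tissues", ("DRG",))),
            scene=SceneSpec(**scene_d),
            effects=effects,
            segmentation=seg.SegmentationParams(**d.get("segmentation", {})),
            histogram_bins=int(d.get("histogram_bins", 20)),
            alpha=float(d.get("alpha", 0.05)),
            phenotype_margin=float(d.get("phenotype_margin", 0.05)),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"config file not found: {path}")
        return cls.from_dict(yaml.safe_load(path.read_text()) or {})

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


# ---------------------------------------------------------------------------
# stages


def _out(cfg: PipelineConfig) -> Path:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    return out


def _sample_ids(out: Path) -> list[str]:
    stacks = sorted((out / "stacks").glob("*.tif"))
    if not stacks:
        raise FileNotFoundError(f"no stacks under {out / 'stacks'}; run the simulate stage first")
    return [p.stem for p in stacks]


def stage_simulate(cfg: PipelineConfig) -> None:
    out = _out(cfg)
    (out / "stacks").mkdir(exist_ok=True)
    (out / "ground_truth").mkdir(exist_ok=True)
    n = 0
    for sample in generate_cohort(cfg.design(), cfg.n_samples_per_group, cfg.seed):
        sid = sample.metadata.sample_id
        cmio.write_stack(sample.stack, out / "stacks" / f"{sid}.tif")
        sample.truth.to_frame().to_csv(out / "ground_truth" / f"{sid}.csv", index=False)
        scene = {
            "spec": sample.spec.to_dict(),
            "tissue_volume_um3": sample.truth.tissue_volume_um3,
            "tissue_voxels": sample.truth.tissue_voxels,
        }
        (out / "ground_truth" / f"{sid}.scene.json").write_text(json.dumps(scene, indent=1))
        n += 1
    logger.info("simulate: wrote %d stacks to %s", n, out / "stacks")


def stage_segment(cfg: PipelineConfig) -> None:
    out = _out(cfg)
    (out / "labels").mkdir(exist_ok=True)
    (out / "segmentation").mkdir(exist_ok=True)
    errors: list[tuple[str, Exception]] = []
    for sid in _sample_ids(out):
        try:
            stack = cmio.read_stack(out / "stacks" / f"{sid}.tif")
            sub = seg.subtract_background(stack, cfg.segmentation.background_sigma)
            lv = seg.segment_cells(sub, cfg.segmentation)
            lv, removed_small, removed_large = seg.filter_by_voxels(
                lv, cfg.segmentation.min_voxels, cfg.segmentation.max_voxels
            )
            tvol = seg.tissue_volume(stack, cfg.segmentation.tissue_threshold)
            tifffile.imwrite(out / "labels" / f"{sid}.tif", lv.labels.astype(np.int32))
            info = {
                "sample_id": sid,
                "n_objects": lv.n_objects,
                "removed_small": removed_small,
                "removed_large": removed_large,
                "tissue_volume_um3": tvol,
                "voxel_size_um": list(stack.voxel_size),
                "metadata": stack.metadata.to_dict() if stack.metadata else None,
            }
            (out / "segmentation" / f"{sid}.json").write_text(json.dumps(info, indent=1))
        except Exception as exc:  # keep independent samples going
            logger.error("segment: sample %s failed: %s", sid, exc)
            errors.append((sid, exc))
    if errors:
        raise RuntimeError(f"segment stage failed for {[s for s, _ in errors]}") from errors[0][1]
    logger.info("segment: done")


def stage_measure(cfg: PipelineConfig) -> None:
    out = _out(cfg)
    (out / "records").mkdir(exist_ok=True)
    errors: list[tuple[str, Exception]] = []
    for sid in _sample_ids(out):
        try:
            info = json.loads((out / "segmentation" / f"{sid}.json").read_text())
            labels = tifffile.imread(out / "labels" / f"{sid}.tif")
            lv = seg.LabeledVolume.from_labels(labels, tuple(info["voxel_size_um"]))
            records = morph.measure_all(lv, phenotype_margin=cfg.phenotype_margin)
            cmio.write_records(records, out / "records" / f"{sid}.csv")
        except FileNotFoundError as exc:
            raise FileNotFoundError(
                f"measure: missing segmentation output for {sid}: {exc}"
            ) from exc
        except Exception as exc:
            logger.error("measure: sample %s failed: %s", sid, exc)
            errors.append((sid, exc))
    if errors:
        raise RuntimeError(f"measure stage failed for {[s for s, _ in errors]}") from errors[0][1]
    logger.info("measure: done")


def _load_sample(out: Path, sid: str) -> tuple[pd.DataFrame, dict]:
    records = cmio.read_records(out / "records" / f"{sid}.csv")
    info = json.loads((out / "segmentation" / f"{sid}.json").read_text())
    return records, info


def stage_summarize(cfg: PipelineConfig) -> None:
    out = _out(cfg)
    summaries: list[cmstats.SampleSummary] = []
    per_group_records: dict[str, list[pd.DataFrame]] = {}
    for sid in _sample_ids(out):
        records, info = _load_sample(out, sid)
        md = cmio.SampleMetadata.from_dict(info["metadata"])
        s = cmstats.summarize_sample(
            records, info["tissue_volume_um3"], md, histogram_bins=cfg.histogram_bins
        )
        summaries.append(s)
        gname = f"{md.sex}:{md.condition}:{md.side}:{md.tissue}"
        per_group_records.setdefault(gname, []).append(records)

    sdf = pd.DataFrame([s.to_dict() for s in summaries])
    sdf.to_csv(out / "summaries.csv", index=False, float_format="%.17g")

    # paired ipsi/contra ratios
    by_key: dict[tuple[str, str], dict[str, cmstats.SampleSummary]] = {}
    for s in summaries:
        by_key.setdefault((s.metadata.animal_id, s.metadata.tissue), {})[s.metadata.side] = s
    rows = []
    for (animal, tissue), sides in sorted(by_key.items()):
        if set(sides) == {"ipsilateral", "contralateral"}:
            r = cmstats.ipsi_contra_ratio(sides["ipsilateral"], sides["contralateral"])
            ipsi_md = sides["ipsilateral"].metadata
            rows.append(
                {
                    "animal_id": animal,
                    "tissue": tissue,
                    "sex": ipsi_md.sex,
                    "condition": ipsi_md.condition,
                    "count_ratio": r.count_ratio,
                    "mean_volume_ratio": r.mean_volume_ratio,
                    "flags": ";".join(r.flags),
                }
            )
    pd.DataFrame(
        rows,
        columns=["animal_id", "tissue", "sex", "condition", "count_ratio",
                 "mean_volume_ratio", "flags"],
    ).to_csv(out / "ratios.csv", index=False, float_format="%.17g")

    groups = {k: pd.concat(v, ignore_index=True) for k, v in sorted(per_group_records.items())}
    cmstats.volume_frequency_distribution(groups, bins=cfg.histogram_bins).to_csv(
        out / "volume_histogram.csv", index=False, float_format="%.17g"
    )
    cmstats.shape_scatter_table(groups).to_csv(
        out / "shape_scatter.csv", index=False, float_format="%.17g"
    )
    _figures(out)
    logger.info("summarize: %d samples", len(summaries))


def _figures(out: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    figdir = out / "figures"
    figdir.mkdir(exist_ok=True)

    scatter = pd.read_csv(out / "shape_scatter.csv")
    if len(scatter):
        fig, ax = plt.subplots(figsize=(5, 5))
        for name, g in scatter.groupby("group"):
            ax.scatter(g["e_prolate"], g["e_oblate"], s=12, alpha=0.6, label=name)
        ax.set_xlabel("prolate ellipticity (elongation)")
        ax.set_ylabel("oblate ellipticity (flattening)")
        ax.set_xlim(0, 1)
        ax.set_ylim(0, 1)
        ax.plot([0, 1], [0, 1], lw=0.5, color="gray")
        ax.legend(fontsize=6)
        fig.tight_layout()
        fig.savefig(figdir / "shape_scatter.png", dpi=150)
        plt.close(fig)

    hist = pd.read_csv(out / "volume_histogram.csv")
    if len(hist):
        fig, ax = plt.subplots(figsize=(6, 4))
        for name, g in hist.groupby("group"):
            centers = (g["bin_left_um3"] + g["bin_right_um3"]) / 2
            ax.plot(centers, g["frequency"], marker="o", ms=3, label=name)
        ax.set_xlabel("cell volume (µm³)")
        ax.set_ylabel("relative frequency")
        ax.legend(fontsize=6)
        fig.tight_layout()
        fig.savefig(figdir / "volume_histogram.png", dpi=150)
        plt.close(fig)


def _comparison_dict(c: cmstats.GroupComparison) -> dict:
    return {
        "factors": list(c.factors),
        "test": c.test,
        "term": c.term,
        "statistic": c.statistic,
        "p_value": c.p_value,
        "alpha": c.alpha,
        "significant": c.significant,
        "contrasts": [
            {
                "groups": list(k.groups),
                "statistic": k.statistic,
                "p_raw": k.p_raw,
                "p_adj": k.p_adj,
                "significant": k.significant,
            }
            for k in c.contrasts
        ],
    }


def stage_compare(cfg: PipelineConfig) -> None:
    """Group comparisons per tissue.

    Within the injured condition: two-way ANOVA (sex × side) on cell
    count with all-pairwise Bonferroni contrasts — the recruitment
    question.  Across conditions: Welch t-test on per-sample mean oblate
    ellipticity — the morphology-shift question.
    """
    out = _out(cfg)
    sdf = pd.read_csv(out / "summaries.csv")
    if sdf.empty or sdf["tissue"].nunique() == 0:
        raise cmstats.InsufficientDataError("no summaries to compare")
    payload = []
    for tissue, tdf in sdf.groupby("tissue"):
        sni = tdf[tdf["condition"] == "SNI"]
        if len(sni) and sni.groupby(["sex", "side"]).size().min() >= 2:
            for comp in cmstats.compare_groups(
                sni, value="n_cells", factors=["sex", "side"], alpha=cfg.alpha
            ):
                d = _comparison_dict(comp)
                d.update(tissue=tissue, value="n_cells", subset="SNI")
                payload.append(d)
        if tdf["condition"].nunique() == 2 and tdf.groupby("condition").size().min() >= 2:
            for comp in cmstats.compare_groups(
                tdf, value="mean_e_oblate", factors=["condition"], alpha=cfg.alpha
            ):
                d = _comparison_dict(comp)
                d.update(tissue=tissue, value="mean_e_oblate", subset="all")
                payload.append(d)
    if not payload:
        raise cmstats.InsufficientDataError(
            "no comparison had ≥ 2 observations per design cell"
        )
    (out / "comparisons.json").write_text(json.dumps(payload, indent=1))
    logger.info("compare: wrote %d comparisons", len(payload))


def run_pipeline(cfg: PipelineConfig, skip_simulate: bool = False) -> Path:
    """Run all stages in order; returns the output directory.

    Deterministic given (config, seed): CSV/JSON outputs of two runs with
    the same config are identical.  The manifest archives the config
    actually used plus versions and stage timings.
    """
    out = _out(cfg)
    timings: dict[str, float] = {}
    stages = [
        ("simulate", stage_simulate),
        ("segment", stage_segment),
        ("measure", stage_measure),
        ("summarize", stage_summarize),
        ("compare", stage_compare),
    ]
    for name, fn in stages:
        if name == "simulate" and skip_simulate:
            continue
        t0 = time.perf_counter()
        fn(cfg)
        timings[name] = round(time.perf_counter() - t0, 3)
    import clearmorph

    manifest = {
        "config": cfg.to_dict(),
        "versions": {
            "clearmorph": clearmorph.__version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "timings_s": timings,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out
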