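"""End-to-end orchestration: image -> morphometry -> cohort statistics.

``run_image`` takes one vessel image through segmentation, skeleton graph
extraction, generation assignment and morphometry, writing every
intermediate with a provenance hash.  ``run_study`` does this for a whole
cohort (synthetic, or a user manifest of image files), assembles the tidy
cohort table, runs the statistics ladder and renders summary figures.

Everything is deterministic given the config and seed.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import generations as gens
from . import groupstats, morphometry, segmentation, synthgen, vesselgraph
from .io import config_hash, write_csv, write_image, write_mask

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_image", "run_study", "demo_cohort_spec"]


@dataclass
class RunConfig:
    """All tunable stage parameters in one serializable object."""

    mode: str = "tree"                  # tree | network
    binarize_method: str = "otsu"       # otsu | fixed
    threshold: float | None = None
    min_object_px: int = 20
    roi_mode: str = "hull"              # hull | frame | file
    roi_dilation: str | int = "auto"    # "auto" = 95th-percentile vessel radius
    prune_min_len: float = 5.0
    prune_radius_factor: float = 1.5
    continuation_ratio: float = 0.8
    halving_base: float = 2.0
    weighted_tv: bool = True
    alpha: float = 0.05
    dunn_correction: str = "holm"
    seed: int = 0
    out_dir: str | None = None

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_toml(self, path: str | Path) -> None:
        lines = ["[vesquant]"]
        for k, v in self.to_dict().items():
            if v is None:
                continue
            if isinstance(v, bool):
                lines.append(f"{k} = {'true' if v else 'false'}")
            elif isinstance(v, (int, float)):
                lines.append(f"{k} = {v}")
            else:
                lines.append(f'{k} = "{v}"')
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        import tomllib
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        return cls.from_dict(data.get("vesquant", data))


def _roi_dilation_px(config: RunConfig, graph: vesselgraph.VesselGraph) -> int:
    if config.roi_dilation != "auto":
        return int(config.roi_dilation)
    radii = np.concatenate([e.radius_profile for e in graph.edges.values()]) \
        if graph.edges else np.array([0.0])
    return int(np.ceil(np.percentile(radii, 95)))


def run_image(config: RunConfig, image: np.ndarray | str | Path,
              eye_id: str = "eye", roi_mask: np.ndarray | None = None
              ) -> tuple[morphometry.MorphometryRecord, dict]:
    """Process one vessel image end to end.

    Returns the per-eye morphometry record and a dict of intermediate
    artifacts (masks, skeleton map, graph, generation map).  When
    ``config.out_dir`` is set, all intermediates are written there with the
    config hash in each CSV header.
    """
    if isinstance(image, (str, Path)):
        from .io import read_image
        image = read_image(image)

    chash = config_hash(config)
    try:
        mask = segmentation.binarize(image, config.binarize_method,
                                     config.threshold, config.min_object_px)
    except Exception as exc:
        raise RuntimeError(f"[segmentation] {eye_id}: {exc}") from exc

    try:
        skel = vesselgraph.skeletonize_map(mask)
        graph = vesselgraph.build_graph(skel)
        graph = vesselgraph.prune_spurs(graph, config.prune_radius_factor,
                                        config.prune_min_len)
    except Exception as exc:
        raise RuntimeError(f"[vesselgraph] {eye_id}: {exc}") from exc

    roi = segmentation.detect_roi(mask, config.roi_mode,
                                  _roi_dilation_px(config, graph),
                                  roi_file_mask=roi_mask)

    try:
        if config.mode == "network":
            gm = gens.assign_generations_network(graph, config.halving_base)
        else:
            gm = gens.assign_generations_tree(graph, config.continuation_ratio)
        grouping = gens.group_generations(gm)
    except Exception as exc:
        raise RuntimeError(f"[generations] {eye_id}: {exc}") from exc

    record = morphometry.measure_eye(mask, roi, graph, gm, eye_id,
                                     config.weighted_tv)

    artifacts = {"mask": mask, "roi": roi, "skeleton": skel, "graph": graph,
                 "generation_map": gm, "grouping": grouping}

    if config.out_dir:
        out = Path(config.out_dir) / eye_id
        out.mkdir(parents=True, exist_ok=True)
        write_mask(out / "vessel_mask.png", mask)
        write_mask(out / "roi.png", roi)
        write_image(out / "skeleton.tif",
                    skel.skeleton.astype(np.uint8) * 255)
        write_image(out / "local_diameter.tif",
                    skel.local_diameter().astype(np.float32))
        write_csv(out / "nodes.csv", graph.nodes_frame(), chash)
        write_csv(out / "edges.csv", graph.edges_frame(), chash)
        gen_frame = pd.DataFrame(
            [{"edge_id": eid, "generation": g,
              "group": grouping.group[eid]}
             for eid, g in sorted(gm.generation.items())])
        write_csv(out / "generations.csv", gen_frame, chash)
        write_image(out / "generation_overlay.png",
                    gens.generation_overlay(mask.shape, graph, gm))
    return record, artifacts


def demo_cohort_spec(n_eyes: int = 4, seed: int = 0) -> synthgen.CohortSpec:
    """Small bundled demo study: three groups mirroring a control /
    diabetic-without-retinopathy / diabetic-with-retinopathy design, with a
    tortuosity effect confined to the retinopathy arm."""
    template = synthgen.TreeSpec(n_generations=5, canvas=(640, 640))
    return synthgen.CohortSpec(
        groups=(
            synthgen.GroupSpec("control", n_eyes),
            synthgen.GroupSpec("DM_noDR", n_eyes, tortuosity_multiplier=1.0),
            synthgen.GroupSpec("DM_DR", n_eyes, tortuosity_multiplier=1.5),
        ),
        template=template,
        seed=seed,
    )


def run_study(config: RunConfig,
              cohort: synthgen.CohortSpec | pd.DataFrame,
              make_figures: bool = True
              ) -> tuple[pd.DataFrame, list[groupstats.StatsReport], pd.DataFrame]:
    """Run a whole study and return (cohort table, reports, summary frame).

    ``cohort`` is either a synthetic :class:`~vesquant.synthgen.CohortSpec`
    or a manifest DataFrame with columns
    ``image_path, eye_id, subject_id, group`` (optional ``mode``,
    ``vessel_type``).  Groups with fewer than 3 eyes are excluded from the
    statistics with a warning (their rows stay in the table).
    """
    chash = config_hash(config)
    rows = []
    if isinstance(cohort, synthgen.CohortSpec):
        eyes, _truth = synthgen.generate_cohort(cohort, render=True)
        items = [(e["eye_id"], e["eye_id"], e["group"], e["image"]) for e in eyes]
    else:
        required = {"image_path", "eye_id", "subject_id", "group"}
        missing = required - set(cohort.columns)
        if missing:
            raise ValueError(f"manifest missing columns: {sorted(missing)}")
        items = [(r.eye_id, r.subject_id, r.group, r.image_path)
                 for r in cohort.itertuples()]
    n_groups = len({g for _, _, g, _ in items})
    if n_groups < 2:
        raise ValueError("study needs >= 2 resolvable groups")

    for eye_id, subject_id, group, image in items:
        record, _ = run_image(config, image, eye_id=eye_id)
        for row in record.to_tidy_rows():
            row.update({"subject_id": subject_id, "group": group})
            rows.append(row)
    table = pd.DataFrame(rows)[
        ["eye_id", "subject_id", "group", "metric", "scope", "value"]]

    reports, summary = groupstats.run_cohort_analysis(
        table, alpha=config.alpha, dunn_correction=config.dunn_correction)

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_csv(out / "cohort_table.csv", table, chash)
        write_csv(out / "stats_summary.csv", summary, chash)
        (out / "stats_report.md").write_text(
            groupstats.report_markdown(reports))
        config.to_toml(out / "config.toml")
        if make_figures:
            _summary_figures(table, out)
    return table, reports, summary


def _summary_figures(table: pd.DataFrame, out: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    for metric in sorted(table.metric.unique()):
        sub = table[table.metric == metric].dropna(subset=["value"])
        scopes = [s for s in ("total", "large", "medium", "micro")
                  if s in set(sub.scope)]
        if not scopes:
            continue
        fig, axes = plt.subplots(1, len(scopes),
                                 figsize=(3.2 * len(scopes), 3.2),
                                 squeeze=False)
        for ax, scope in zip(axes[0], scopes):
            chunk = sub[sub.scope == scope]
            groups = sorted(chunk.group.unique())
            data = [chunk[chunk.group == g].value.to_numpy() for g in groups]
            ax.boxplot(data, tick_labels=groups)
            ax.set_title(f"{metric} ({scope})", fontsize=9)
            ax.tick_params(axis="x", labelrotation=45, labelsize=7)
        fig.tight_layout()
        fig.savefig(out / f"summary_{metric}.png", dpi=110)
        plt.close(fig)
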