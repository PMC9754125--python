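"""End-to-end orchestration: stacks in, per-embryo measures and cohort
statistics out, with full provenance.

``run_pipeline`` applies the morphometry stage (and optionally the cell
catalog and intensity quantifications) to every embryo, classifies each as
gastrulating or not, and compares condition pairs with Fisher's exact test
on the positive/negative counts and the Mann-Whitney U test on the d/D
values.  Per-embryo failures are recorded and do not abort the run.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, asdict
from itertools import combinations

import numpy as np
import pandas as pd

from . import __version__
from .catalog import (
    ProjectionConfig, SkeletonConfig, build_catalog, dilated_skeleton,
    foreground_mask, otsu_threshold, project_stack, segment_cells,
    skeletonize_junctions,
)
from .io import ImageStack
from .morphometry import (
    MorphometryConfig, measure_invagination, midplane_section, percent_deformation,
    elliptic_ratio, segment_embryo,
)
from .quant import gradient_ratio, tissue_intensity
from .stats import CohortCounts, fisher_exact, mann_whitney

log = logging.getLogger("gastrulaquant")

__all__ = ["PipelineConfig", "RunReport", "run_pipeline"]


@dataclass(frozen=True)
class PipelineConfig:
    morphometry: MorphometryConfig = field(default_factory=MorphometryConfig)
    projection: ProjectionConfig = field(default_factory=ProjectionConfig)
    skeleton: SkeletonConfig = field(default_factory=SkeletonConfig)
    junction_channel: str = "junction"
    signal_channel: str = "signal"
    make_catalog: bool = False
    quantify: bool = False
    seed: int = 0


@dataclass
class RunReport:
    morphometry: pd.DataFrame
    tests: list[dict]
    catalog_summaries: list[dict]
    quantifications: list[dict]
    failures: list[dict]
    config: dict
    version: str
    input_hashes: dict[str, str]

    def to_json(self, path) -> None:
        payload = {
            "version": self.version,
            "config": self.config,
            "morphometry": self.morphometry.to_dict(orient="records"),
            "tests": self.tests,
            "catalog_summaries": self.catalog_summaries,
            "quantifications": self.quantifications,
            "failures": self.failures,
            "input_hashes": self.input_hashes,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, default=_jsonable)

    def morphometry_csv(self, path) -> None:
        self.morphometry.to_csv(path, index=False)


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj):
        return asdict(obj)
    return str(obj)


def _measure_embryo(embryo_id: str, stack: ImageStack, config: PipelineConfig) -> dict:
    section = midplane_section(stack, channel=config.junction_channel)
    shape = segment_embryo(section, stack.pixel_size_um, config.morphometry)
    inv = measure_invagination(shape, config.morphometry)
    return {
        "embryo_id": embryo_id,
        "L_um": shape.L_um,
        "W_um": shape.W_um,
        "ratio": elliptic_ratio(shape),
        "deformation_percent": percent_deformation(shape),
        "D_um": shape.D_um,
        "d_um": inv.d_um,
        "d_over_D": inv.d_over_D,
        "gastrulating": inv.gastrulating,
    }


def run_pipeline(inputs: list[tuple[str, str, ImageStack]],
                 config: PipelineConfig | None = None) -> RunReport:
    """Run morphometry (and optional catalog / quantification) over embryos
    and compare conditions.

    ``inputs`` is a list of (embryo_id, condition, stack).  Deterministic for
    a given config and inputs.
    """
    config = config or PipelineConfig()
    rows: list[dict] = []
    failures: list[dict] = []
    catalog_summaries: list[dict] = []
    quantifications: list[dict] = []
    hashes: dict[str, str] = {}

    for embryo_id, condition, stack in inputs:
        hashes[embryo_id] = stack.content_hash()
        try:
            row = _measure_embryo(embryo_id, stack, config)
            row["condition"] = condition
            rows.append(row)
        except Exception as exc:  # recorded, run continues
            log.warning("embryo %s failed: %s", embryo_id, exc)
            failures.append({"embryo_id": embryo_id, "stage": "morphometry", "error": str(exc)})
            continue
        if config.make_catalog:
            try:
                projected = project_stack(stack, config.projection, config.junction_channel)
                junction = projected[config.junction_channel]
                mask = foreground_mask(junction)
                skel = skeletonize_junctions(junction, mask, config.skeleton)
                labels = segment_cells(skel, mask, junction, config.skeleton)
                cat = build_catalog(
                    labels, projected, mask, dilated_skeleton(skel, config.skeleton),
                    pixel_size_um=stack.pixel_size_um,
                )
                interior = cat.interior()
                catalog_summaries.append({
                    "embryo_id": embryo_id,
                    "n_cells": len(cat),
                    "n_interior": len(interior),
                    "mean_area_um2": float(np.mean([r.apical_area_um2 for r in interior]))
                    if interior else float("nan"),
                })
            except Exception as exc:
                failures.append({"embryo_id": embryo_id, "stage": "catalog", "error": str(exc)})
        if config.quantify:
            try:
                sig = stack.channel(config.signal_channel)
                mask3d = sig > otsu_threshold(sig)
                grad = gradient_ratio(stack, mask3d, channel=config.signal_channel)
                section = midplane_section(stack, channel=config.junction_channel)
                shape = segment_embryo(section, stack.pixel_size_um, config.morphometry)
                tis = tissue_intensity(stack, shape.mask, channel=config.signal_channel)
                quantifications.append({
                    "embryo_id": embryo_id,
                    "gradient_percent": grad.gradient_ratio_percent,
                    "tissue_intensity": tis.total_intensity_per_pixel,
                })
            except Exception as exc:
                failures.append({"embryo_id": embryo_id, "stage": "quantify", "error": str(exc)})

    df = pd.DataFrame(rows)
    tests: list[dict] = []
    if not df.empty:
        for ca, cb in combinations(sorted(df["condition"].unique()), 2):
            a = df[df["condition"] == ca]
            b = df[df["condition"] == cb]
            counts = CohortCounts(
                int(a["gastrulating"].sum()), int((~a["gastrulating"]).sum()),
                int(b["gastrulating"].sum()), int((~b["gastrulating"]).sum()),
            )
            fr = fisher_exact(counts)
            mw = mann_whitney(a["d_over_D"].to_numpy(), b["d_over_D"].to_numpy())
            tests.append({
                "conditions": (ca, cb),
                "fisher_p": fr.p_value,
                "fisher_table": counts.as_array().tolist(),
                "mannwhitney_p": mw.p_value,
                "mannwhitney_U": mw.statistic,
                "n_per_group": mw.n_per_group,
            })
    return RunReport(
        morphometry=df,
        tests=tests,
        catalog_summaries=catalog_summaries,
        quantifications=quantifications,
        failures=failures,
        config=asdict(config),
        version=__version__,
        input_hashes=hashes,
    )
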