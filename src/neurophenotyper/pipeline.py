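"""End-to-end orchestration: simulate -> quantify -> compare.

A run renders (or loads) a cohort of replicate experiments, quantifies
each replicate's scenes/recordings back into summary phenotypes, and
compares patient groups against control with Dunnett's test. The
statistical n is taken at the replicate-experiment level. All thresholds
default to the study's printed values (nucleus area > 50 µm², 50% region
expansion, active electrodes > 5 spikes/min, 6.0 x SD detection after a
200-3000 Hz Butterworth bandpass, fold-change cut 2.0).
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

from . import calcium as ca
from . import mea as mea_mod
from .imaging import (
    classify_marker,
    colocalize,
    detect_puncta,
    expand_regions,
    measure_dendrites,
    neuron_mask_from_channel,
    segment_nuclei,
)
from .stats import dunnett_test
from .synth.cohort import CohortDesign, CohortReplicate, GroupEffects, GroupSpec, generate_cohort

__version__ = "0.1.0"
log = logging.getLogger("neurophenotyper")


@dataclass
class GroupConfig:
    name: str
    n_lines: int = 1
    n_replicates: int = 6
    dendrite_length_factor: float = 1.0
    puncta_count_factor: float = 1.0
    spike_rate_factor: float = 1.0


@dataclass
class RunConfig:
    """Everything a pipeline run depends on; round-trips through YAML."""

    seed: int = 0
    out_dir: str = "run_out"
    groups: list[GroupConfig] = field(
        default_factory=lambda: [
            GroupConfig("control"),
            GroupConfig("BP", dendrite_length_factor=0.7, puncta_count_factor=0.6),
            GroupConfig("SCZ", dendrite_length_factor=0.7, puncta_count_factor=0.6),
        ]
    )
    # printed analysis parameters
    min_area_um2: float = 50.0
    expansion: float = 0.5
    active_rate_per_min: float = 5.0
    threshold_sd: float = 6.0
    band_low_hz: float = 200.0
    band_high_hz: float = 3000.0
    fc_threshold: float = 2.0
    # package design parameters
    coloc_max_distance_um: float = 0.5
    alpha: float = 0.05
    include_mea: bool = False
    include_calcium: bool = False
    mea_duration_s: float = 60.0

    def to_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        data = yaml.safe_load(text)
        groups = [GroupConfig(**g) for g in data.pop("groups", [])]
        cfg = cls(**data)
        if groups:
            cfg.groups = groups
        return cfg

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]

    def cohort_design(self) -> CohortDesign:
        return CohortDesign(
            groups=[
                GroupSpec(
                    g.name,
                    n_lines=g.n_lines,
                    n_replicates=g.n_replicates,
                    effects=GroupEffects(
                        dendrite_length_factor=g.dendrite_length_factor,
                        puncta_count_factor=g.puncta_count_factor,
                        spike_rate_factor=g.spike_rate_factor,
                    ),
                )
                for g in self.groups
            ],
            seed=self.seed,
        )


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineReport:
    measurements: pd.DataFrame           # per replicate: measure, group, line, replicate, value
    comparisons: pd.DataFrame            # measurement, test, comparison, statistic, p, significant
    per_object: pd.DataFrame             # per-nucleus rows behind the dendrite counts
    manifest: dict

    def significant_measures(self) -> dict[str, bool]:
        out = {}
        for m, sub in self.comparisons.groupby("measurement"):
            out[m] = bool(sub["significant"].any())
        return out


def quantify_replicate(rep: CohortReplicate, config: RunConfig) -> tuple[dict[str, float], pd.DataFrame]:
    """Measure one replicate's scenes and recordings into summary values."""
    values: dict[str, float] = {}
    objects = []

    # dendrites: nuclei -> expanded regions -> MAP2 calls -> skeleton per cell
    scene = rep.dendrite_scene
    seg = segment_nuclei(
        scene.channel("hoechst"), scene.pixel_size_um, min_area_um2=config.min_area_um2
    )
    regions = expand_regions(seg, expansion=config.expansion)
    map2 = classify_marker(regions, scene.channel("map2"), mode="intensity", channel_name="map2")
    dend = measure_dendrites(
        scene.channel("map2"), scene.pixel_size_um, n_map2_cells=map2.n_positive
    )
    if dend.per_cell_um is not None:
        values["dendrite_length"] = dend.per_cell_um
    for r in seg.records:
        objects.append(
            {
                "group": rep.group, "line": rep.line, "replicate": rep.replicate,
                "object": f"nucleus_{r.id}", "area_um2": r.area_um2,
                "accepted": r.accepted,
                "map2_positive": bool(map2.positive.get(r.id, False)),
            }
        )

    # synapses: puncta on the βIII-tubulin mask, pre/post colocalization
    sscene = rep.synapse_scene
    px = sscene.pixel_size_um
    mask = neuron_mask_from_channel(sscene.channel("btub"), pixel_size_um=px, dilate_um=1.0)
    pre = detect_puncta(sscene.channel("synapsin"), mask, px, channel_name="synapsin")
    post = detect_puncta(sscene.channel("homer"), mask, px, channel_name="homer")
    coloc = colocalize(pre, post, max_distance_um=config.coloc_max_distance_um)
    values["pre_puncta"] = float(pre.count)
    values["post_puncta"] = float(post.count)
    values["coloc_puncta"] = float(coloc.n_coloc)

    if rep.mea is not None:
        filtered = mea_mod.bandpass(rep.mea, config.band_low_hz, config.band_high_hz)
        spikes = mea_mod.detect_spikes(filtered, threshold_sd=config.threshold_sd)
        summary = mea_mod.summarize_activity(spikes)
        rate = summary["mean_rate_active_per_s"].mean()
        if np.isfinite(rate):
            values["spike_rate"] = float(rate)

    if rep.calcium is not None:
        events = ca.analyze_traces(rep.calcium)
        summ = events.dfmax_summary()
        if np.isfinite(summ["mean_roi_max"]):
            values["dfmax"] = summ["mean_roi_max"]
        values["ca_event_rate"] = float(
            np.nanmean([r.frequency_hz for r in events.rois if not r.excluded])
        )

    return values, pd.DataFrame(objects)


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> PipelineReport:
    """Execute simulate -> quantify -> compare and write the report bundle."""
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    design = config.cohort_design()
    try:
        replicates = generate_cohort(
            design,
            include_mea=config.include_mea,
            include_calcium=config.include_calcium,
            mea_duration_s=config.mea_duration_s,
            calcium_n_frames=1000 if config.include_calcium else 0,
        )
    except Exception as e:  # noqa: BLE001
        raise StageError("simulate", e) from e
    log.info("simulated %d replicates", len(replicates))

    rows, obj_frames = [], []
    try:
        for rep in replicates:
            values, objects = quantify_replicate(rep, config)
            obj_frames.append(objects)
            for measure, value in values.items():
                rows.append(
                    {
                        "measure": measure, "group": rep.group, "line": rep.line,
                        "replicate": rep.replicate, "value": value,
                    }
                )
    except Exception as e:  # noqa: BLE001
        raise StageError("quantify", e) from e
    measurements = pd.DataFrame(rows)
    per_object = pd.concat(obj_frames, ignore_index=True)

    group_names = [g.name for g in config.groups]
    comp_rows = []
    try:
        for measure, sub in measurements.groupby("measure"):
            samples, labels = [], []
            for g in group_names:
                vals = sub.loc[sub["group"] == g, "value"].to_numpy()
                if len(vals) >= 2:
                    samples.append(vals)
                    labels.append(g)
            if len(samples) < 2:
                continue
            try:
                res = dunnett_test(
                    samples, control_index=0, alpha=config.alpha, labels=labels
                )
            except ValueError as e:  # degenerate measure, e.g. zero variance
                log.warning("measure %s skipped: %s", measure, e)
                continue
            for c in res.comparisons:
                comp_rows.append(
                    {
                        "measurement": measure, "test": "dunnett",
                        "comparison": c.label, "statistic": c.statistic,
                        "p_adjusted": c.p_adjusted, "significant": c.significant,
                    }
                )
    except Exception as e:  # noqa: BLE001
        raise StageError("stats", e) from e
    comparisons = pd.DataFrame(comp_rows)

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "n_replicates": len(replicates),
        "measures": sorted(measurements["measure"].unique()),
    }
    fmt = dict(index=False, float_format="%.10g")
    measurements.to_csv(out / "measurements.csv", **fmt)
    comparisons.to_csv(out / "comparisons.csv", **fmt)
    per_object.to_csv(out / "per_object.csv", **fmt)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    (out / "config.yaml").write_text(config.to_yaml())
    return PipelineReport(
        measurements=measurements, comparisons=comparisons,
        per_object=per_object, manifest=manifest,
    )
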