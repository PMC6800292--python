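"""Control-vs-patient cohort simulation.

A cohort is a set of donor lines per group (control, BP, SCZ, ...), each
contributing independent replicate "experiments". Patient groups differ
from control only through multiplicative effect factors on the generated
phenotypes — e.g. dendrite_length_factor 0.7 shrinks every patient fiber's
target length to 70% of the control baseline, and puncta_count_factor 0.6
thins the synaptic spot counts.

Two fidelity levels are provided:

* :func:`generate_cohort` renders full microscopy scenes (and optionally
  MEA recordings / calcium traces) per replicate; downstream quantification
  then measures them back.
* :func:`simulate_measurement_cohort` draws replicate-level summary
  measurements directly (lognormal between-experiment variation of a given
  CV around the scaled baselines), which is what large power simulations
  over thousands of cohorts use.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calcium_gen import CalciumGroundTruth, CalciumTraceSet, generate_calcium_traces
from .electro import MEAGroundTruth, MEARecording, generate_mea_recording
from .scenes import (
    FiberParams,
    ImageScene,
    MarkerParams,
    PunctaParams,
    SceneGroundTruth,
    SceneParams,
    generate_image_scene,
)


@dataclass
class GroupEffects:
    """Multiplicative effects of a group relative to control (all 1.0)."""

    dendrite_length_factor: float = 1.0
    puncta_count_factor: float = 1.0
    spike_rate_factor: float = 1.0
    positivity_fractions: dict[str, float] = field(default_factory=dict)

    def validate(self):
        for f in (self.dendrite_length_factor, self.puncta_count_factor, self.spike_rate_factor):
            if f <= 0:
                raise ValueError("effect factors must be positive")


@dataclass
class GroupSpec:
    name: str
    n_lines: int = 1
    n_replicates: int = 3
    effects: GroupEffects = field(default_factory=GroupEffects)


@dataclass
class CohortDesign:
    """Layout and effect structure of a simulated case-control study."""

    groups: list[GroupSpec]
    seed: int = 0

    def validate(self):
        if not self.groups:
            raise ValueError("need at least one group")
        for g in self.groups:
            g.effects.validate()
        ctrl = self.groups[0].effects
        if not (
            ctrl.dendrite_length_factor == ctrl.puncta_count_factor
            == ctrl.spike_rate_factor == 1.0
        ):
            raise ValueError("first (control) group must have unit effect factors")

    @classmethod
    def default(cls, seed: int = 0) -> "CohortDesign":
        return cls(
            groups=[
                GroupSpec("control", n_lines=2, n_replicates=6),
                GroupSpec(
                    "BP", n_lines=2, n_replicates=6,
                    effects=GroupEffects(dendrite_length_factor=0.7, puncta_count_factor=0.6),
                ),
                GroupSpec(
                    "SCZ", n_lines=1, n_replicates=6,
                    effects=GroupEffects(dendrite_length_factor=0.7, puncta_count_factor=0.6),
                ),
            ],
            seed=seed,
        )


@dataclass
class CohortReplicate:
    group: str
    line: str
    replicate: int
    dendrite_scene: ImageScene | None = None
    dendrite_truth: SceneGroundTruth | None = None
    synapse_scene: ImageScene | None = None
    synapse_truth: SceneGroundTruth | None = None
    mea: MEARecording | None = None
    mea_truth: MEAGroundTruth | None = None
    calcium: CalciumTraceSet | None = None
    calcium_truth: CalciumGroundTruth | None = None


def default_dendrite_scene() -> SceneParams:
    """20x-style field: nuclei plus MAP2-stained dendritic fibers."""
    return SceneParams(
        shape=(512, 512),
        pixel_size_um=0.65,
        n_nuclei=12,
        fibers=[FiberParams(channel="map2", n_fibers=6, length_um=(90.0, 150.0))],
        markers={"map2": MarkerParams(positive_fraction=1.0, mode="intensity", intensity=70.0)},
    )


def default_synapse_scene() -> SceneParams:
    """60x-style field: βIII-tubulin fibers carrying pre/post puncta."""
    return SceneParams(
        shape=(512, 512),
        pixel_size_um=0.22,
        n_nuclei=4,
        fibers=[FiberParams(channel="btub", n_fibers=4, length_um=(60.0, 90.0), width_um=1.2)],
        puncta=PunctaParams(n_pre=50, n_post=50, coloc_fraction=0.4),
    )


def _scaled_scene_params(base: SceneParams, eff: GroupEffects, which: str) -> SceneParams:
    p = copy.deepcopy(base)
    if which == "dendrite":
        for fp in p.fibers:
            fp.length_um = (
                fp.length_um[0] * eff.dendrite_length_factor,
                fp.length_um[1] * eff.dendrite_length_factor,
            )
        for ch, frac in eff.positivity_fractions.items():
            if ch in p.markers:
                p.markers[ch].positive_fraction = frac
    elif which == "synapse" and p.puncta is not None:
        f = eff.puncta_count_factor
        n_pre = max(0, int(round(p.puncta.n_pre * f)))
        n_post = max(0, int(round(p.puncta.n_post * f)))
        p.puncta.n_pre, p.puncta.n_post = n_pre, n_post
    return p


def generate_cohort(
    design: CohortDesign,
    dendrite_scene: SceneParams | None = None,
    synapse_scene: SceneParams | None = None,
    include_mea: bool = False,
    include_calcium: bool = False,
    mea_baseline_rate_per_min: float = 20.0,
    mea_electrodes_per_replicate: int = 8,
    mea_duration_s: float = 60.0,
    calcium_n_rois: int = 8,
    calcium_n_frames: int = 3500,
    between_replicate_cv: float = 0.15,
) -> list[CohortReplicate]:
    """Render the full synthetic raw data for every replicate of a cohort.

    Independent replicate experiments differ by a lognormal factor of CV
    ``between_replicate_cv`` applied to the dendrite-length baseline and to
    the puncta counts, emulating between-experiment biological variation.
    Seeds for individual replicates are derived deterministically from
    ``design.seed`` via numpy's seed-sequence spawning, so the whole cohort
    is reproducible from a single integer.
    """
    design.validate()
    dendrite_scene = dendrite_scene or default_dendrite_scene()
    synapse_scene = synapse_scene or default_synapse_scene()
    sigma = math.sqrt(math.log(1 + between_replicate_cv**2))
    root = np.random.SeedSequence(design.seed)
    replicates: list[CohortReplicate] = []
    n_total = sum(g.n_lines * g.n_replicates for g in design.groups)
    children = root.spawn(n_total)
    idx = 0
    for g in design.groups:
        dparams0 = _scaled_scene_params(dendrite_scene, g.effects, "dendrite")
        sparams0 = _scaled_scene_params(synapse_scene, g.effects, "synapse")
        for line_i in range(g.n_lines):
            line = f"{g.name}-{line_i + 1}"
            for rep in range(g.n_replicates):
                sub = children[idx].generate_state(4)
                rep_rng = np.random.default_rng(children[idx])
                idx += 1
                dparams = copy.deepcopy(dparams0)
                sparams = copy.deepcopy(sparams0)
                if sigma > 0:
                    fd = rep_rng.lognormal(-0.5 * sigma**2, sigma)
                    fp = rep_rng.lognormal(-0.5 * sigma**2, sigma)
                    for fib in dparams.fibers:
                        fib.length_um = (fib.length_um[0] * fd, fib.length_um[1] * fd)
                    if sparams.puncta is not None:
                        sparams.puncta.n_pre = max(0, int(round(sparams.puncta.n_pre * fp)))
                        sparams.puncta.n_post = max(0, int(round(sparams.puncta.n_post * fp)))
                r = CohortReplicate(group=g.name, line=line, replicate=rep)
                r.dendrite_scene, r.dendrite_truth = generate_image_scene(
                    dparams, seed=int(sub[0] % (2**31))
                )
                r.synapse_scene, r.synapse_truth = generate_image_scene(
                    sparams, seed=int(sub[1] % (2**31))
                )
                if include_mea:
                    rates = np.full(
                        mea_electrodes_per_replicate,
                        mea_baseline_rate_per_min * g.effects.spike_rate_factor,
                    )
                    r.mea, r.mea_truth = generate_mea_recording(
                        rates,
                        duration_s=mea_duration_s,
                        seed=int(sub[2] % (2**31)),
                        electrodes_per_well=mea_electrodes_per_replicate,
                    )
                if include_calcium:
                    r.calcium, r.calcium_truth = generate_calcium_traces(
                        n_rois=calcium_n_rois,
                        n_frames=calcium_n_frames,
                        seed=int(sub[3] % (2**31)),
                    )
                replicates.append(r)
    return replicates


def simulate_measurement_cohort(
    design: CohortDesign,
    baselines: dict[str, float] | None = None,
    cv: float = 0.15,
    seed: int | None = None,
) -> pd.DataFrame:
    """Replicate-level summary measurements for one cohort.

    Each replicate experiment's value is baseline x group factor x
    lognormal(CV) noise; the lognormal sigma is chosen so the multiplicative
    coefficient of variation equals ``cv``. Returns a tidy frame with
    columns (measure, group, line, replicate, value).
    """
    design.validate()
    baselines = baselines or {"dendrite_length": 100.0, "coloc_puncta": 20.0}
    rng = np.random.default_rng(design.seed if seed is None else seed)
    sigma = math.sqrt(math.log(1 + cv**2))
    factor_of = {
        "dendrite_length": lambda e: e.dendrite_length_factor,
        "coloc_puncta": lambda e: e.puncta_count_factor,
        "spike_rate": lambda e: e.spike_rate_factor,
    }
    rows = []
    for g in design.groups:
        for line_i in range(g.n_lines):
            line = f"{g.name}-{line_i + 1}"
            for rep in range(g.n_replicates):
                for measure, base in baselines.items():
                    f = factor_of.get(measure, lambda e: 1.0)(g.effects)
                    val = base * f * rng.lognormal(-0.5 * sigma**2, sigma)
                    rows.append(
                        {
                            "measure": measure,
                            "group": g.name,
                            "line": line,
                            "replicate": rep,
                            "value": val,
                        }
                    )
    return pd.DataFrame(rows)
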