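"""Microelectrode-array spike analysis.

Raw extracellular traces sampled at 12.5 kHz are bandpass filtered
(200-3000 Hz Butterworth, zero phase), spikes are detected where the
filtered voltage crosses 6.0 x the baseline noise SD, and activity is
summarized per well over *active* electrodes — those firing strictly more
than 5 spikes/min, the conventional cut that separates electrodes in
contact with neurons from silent ones. Drug responses are expressed as the
per-well ratio of total spike counts after vs before treatment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .synth.electro import MEARecording

ACTIVE_RATE_PER_MIN = 5.0
DEFAULT_THRESHOLD_SD = 6.0
DEFAULT_BAND_HZ = (200.0, 3000.0)


@dataclass
class SpikeTrain:
    electrode_id: str
    well: str
    times_s: np.ndarray
    duration_s: float
    noise_sd: float

    @property
    def count(self) -> int:
        return len(self.times_s)

    @property
    def rate_per_min(self) -> float:
        return self.count / self.duration_s * 60.0

    @property
    def rate_per_s(self) -> float:
        return self.count / self.duration_s

    @property
    def active(self) -> bool:
        # strict inequality: an electrode at exactly 5 spikes/min is inactive
        return self.rate_per_min > ACTIVE_RATE_PER_MIN


@dataclass
class SpikeTrainSet:
    trains: list[SpikeTrain] = field(default_factory=list)

    @property
    def wells(self) -> list[str]:
        seen: dict[str, None] = {}
        for t in self.trains:
            seen.setdefault(t.well, None)
        return list(seen)

    def by_well(self) -> dict[str, list[SpikeTrain]]:
        out: dict[str, list[SpikeTrain]] = {}
        for t in self.trains:
            out.setdefault(t.well, []).append(t)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "electrode": [t.electrode_id for t in self.trains],
                "well": [t.well for t in self.trains],
                "n_spikes": [t.count for t in self.trains],
                "rate_per_min": [t.rate_per_min for t in self.trains],
                "rate_per_s": [t.rate_per_s for t in self.trains],
                "active": [t.active for t in self.trains],
            }
        )


def bandpass(
    recording: MEARecording,
    low_hz: float = DEFAULT_BAND_HZ[0],
    high_hz: float = DEFAULT_BAND_HZ[1],
    order: int = 3,
) -> MEARecording:
    """Zero-phase Butterworth bandpass applied per electrode."""
    nyq = recording.sampling_rate_hz / 2.0
    if not 0 < low_hz < high_hz < nyq:
        raise ValueError(f"band ({low_hz}, {high_hz}) Hz outside (0, {nyq}) Hz")
    sos = signal.butter(
        order, [low_hz, high_hz], btype="bandpass", fs=recording.sampling_rate_hz,
        output="sos",
    )
    filtered = np.empty_like(recording.voltage, dtype=np.float32)
    for i in range(recording.n_electrodes):
        filtered[i] = signal.sosfiltfilt(sos, recording.voltage[i].astype(float))
    return MEARecording(
        voltage=filtered,
        sampling_rate_hz=recording.sampling_rate_hz,
        electrode_ids=list(recording.electrode_ids),
        well_map=dict(recording.well_map),
    )


def robust_noise_sd(trace: np.ndarray) -> float:
    """Baseline noise SD via the median-absolute estimator median(|x|)/0.6745.

    Robust to the spikes themselves, which a raw SD would inflate.
    """
    return float(np.median(np.abs(trace)) / 0.6745)


def detect_spikes(
    filtered: MEARecording,
    threshold_sd: float = DEFAULT_THRESHOLD_SD,
    refractory_ms: float = 1.0,
    polarity: str = "both",
) -> SpikeTrainSet:
    """Threshold-crossing spike detection on a filtered recording.

    Per electrode the noise SD is estimated robustly and events are placed
    at the extremum sample of each supra-threshold excursion; excursions
    closer than ``refractory_ms`` are merged so one waveform yields one
    spike. ``polarity`` is ``"both"`` (default), ``"positive"`` or
    ``"negative"``.
    """
    fs = filtered.sampling_rate_hz
    refractory = int(round(refractory_ms / 1000.0 * fs))
    trains = []
    for i, eid in enumerate(filtered.electrode_ids):
        x = filtered.voltage[i].astype(float)
        sd = robust_noise_sd(x)
        if sd <= 0:
            warnings.warn(f"electrode {eid}: zero-variance trace, no spikes")
            times = np.zeros(0)
        else:
            thr = threshold_sd * sd
            if polarity == "both":
                score = np.abs(x)
            elif polarity == "positive":
                score = x
            elif polarity == "negative":
                score = -x
            else:
                raise ValueError(f"unknown polarity {polarity!r}")
            above = np.flatnonzero(score > thr)
            if above.size == 0:
                times = np.zeros(0)
            else:
                # split supra-threshold samples into events at refractory gaps
                breaks = np.flatnonzero(np.diff(above) > refractory)
                starts = np.r_[0, breaks + 1]
                ends = np.r_[breaks, above.size - 1]
                peaks = [
                    above[s : e + 1][np.argmax(score[above[s : e + 1]])]
                    for s, e in zip(starts, ends)
                ]
                times = np.asarray(peaks, dtype=float) / fs
        trains.append(
            SpikeTrain(
                electrode_id=eid,
                well=filtered.well_map.get(eid, "W0"),
                times_s=times,
                duration_s=filtered.duration_s,
                noise_sd=sd,
            )
        )
    return SpikeTrainSet(trains=trains)


def spike_trains_from_times(
    times_by_electrode: dict[str, np.ndarray],
    duration_s: float,
    well_map: dict[str, str] | None = None,
) -> SpikeTrainSet:
    """Build a SpikeTrainSet from pre-detected spike-time lists."""
    well_map = well_map or {}
    trains = [
        SpikeTrain(
            electrode_id=eid,
            well=well_map.get(eid, "W0"),
            times_s=np.asarray(t, dtype=float),
            duration_s=duration_s,
            noise_sd=float("nan"),
        )
        for eid, t in times_by_electrode.items()
    ]
    return SpikeTrainSet(trains=trains)


def plot_raster(spikes: SpikeTrainSet, path) -> None:
    """Write a basic spike raster (one row per electrode) to an image file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 0.25 * max(len(spikes.trains), 4) + 1))
    for i, t in enumerate(spikes.trains):
        ax.vlines(t.times_s, i + 0.6, i + 1.4, color="k", lw=0.5)
    ax.set_yticks(range(1, len(spikes.trains) + 1))
    ax.set_yticklabels([t.electrode_id for t in spikes.trains], fontsize=6)
    ax.set_xlabel("time (s)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def summarize_activity(spikes: SpikeTrainSet) -> pd.DataFrame:
    """Per-well activity: active-electrode count and mean rate (spikes/s).

    The well mean is taken over active electrodes only; wells with no
    active electrode are flagged and carry a NaN mean rate.
    """
    rows = []
    for well, trains in spikes.by_well().items():
        active = [t for t in trains if t.active]
        rows.append(
            {
                "well": well,
                "n_electrodes": len(trains),
                "n_active": len(active),
                "total_spikes": int(sum(t.count for t in trains)),
                "mean_rate_active_per_s": (
                    float(np.mean([t.rate_per_s for t in active])) if active else np.nan
                ),
                "has_activity": bool(active),
            }
        )
    return pd.DataFrame(rows)


def drug_response(pre: SpikeTrainSet, post: SpikeTrainSet) -> pd.DataFrame:
    """Per-well ratio of total spikes after vs before a treatment."""
    pre_wells = pre.by_well()
    post_wells = post.by_well()
    if set(pre_wells) != set(post_wells):
        raise ValueError("pre and post recordings cover different wells")
    rows = []
    for well in pre_wells:
        n_pre = sum(t.count for t in pre_wells[well])
        n_post = sum(t.count for t in post_wells[well])
        if n_pre == 0:
            warnings.warn(f"well {well}: zero pre-treatment spikes, excluded")
            continue
        rows.append(
            {"well": well, "spikes_pre": n_pre, "spikes_post": n_post,
             "ratio": n_post / n_pre}
        )
    return pd.DataFrame(rows)
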