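"""Synthetic calcium-imaging ROI traces.

Each ROI trace is built as

    F(t) = F0 * (1 - drift(t)) + F0 * sum_j a_j * k(t - t_j) + noise,

where ``drift`` reaches ``bleach_endpoint_drop`` at the last frame (linear
by default, exponential as a robustness option), ``k`` is a fast-rise /
exponential-decay transient kernel peak-normalized to 1, and the event
amplitudes ``a_j`` are expressed directly in ΔF/F units. Event times are
homogeneous Poisson. Defaults mirror a 3500-frame stream acquisition at
31.5 ms/frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DEFAULT_N_FRAMES = 3500
DEFAULT_FRAME_INTERVAL_S = 0.0315


@dataclass
class CalciumTraceSet:
    """Raw fluorescence per ROI (frames x ROIs)."""

    raw: np.ndarray
    frame_interval_s: float = DEFAULT_FRAME_INTERVAL_S
    roi_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.raw = np.atleast_2d(np.asarray(self.raw, dtype=float))
        if self.raw.shape[0] < self.raw.shape[1] and self.raw.ndim == 2 and not self.roi_ids:
            pass  # caller is trusted on orientation: frames x ROIs
        if not self.roi_ids:
            self.roi_ids = [f"ROI{i}" for i in range(self.raw.shape[1])]

    @property
    def n_frames(self) -> int:
        return self.raw.shape[0]

    @property
    def n_rois(self) -> int:
        return self.raw.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_frames * self.frame_interval_s


@dataclass
class CalciumGroundTruth:
    event_times: list[np.ndarray]        # per ROI, seconds
    event_amplitudes: list[np.ndarray]   # per ROI, ΔF/F units
    bleach_endpoint_drop: float
    f0_level: float
    n_frames: int
    frame_interval_s: float


def transient_kernel(n_frames: int, rise_frames: int = 3, decay_frames: float = 15.0) -> np.ndarray:
    """Fast-rise, exponential-decay calcium transient, peak = 1."""
    t = np.arange(n_frames, dtype=float)
    k = (1 - np.exp(-t / max(rise_frames, 1e-9))) * np.exp(-t / decay_frames)
    return k / k.max()


def generate_calcium_traces(
    n_rois: int = 30,
    event_rate_per_min: float = 2.0,
    amplitude_range: tuple[float, float] = (0.4, 1.2),
    bleach_endpoint_drop: float = 0.2,
    f0_level: float = 1000.0,
    noise_sd_dff: float = 0.02,
    n_frames: int = DEFAULT_N_FRAMES,
    frame_interval_s: float = DEFAULT_FRAME_INTERVAL_S,
    bleach_shape: str = "linear",
    seed: int = 0,
    event_times: list | None = None,
    event_amplitudes: list | None = None,
) -> tuple[CalciumTraceSet, CalciumGroundTruth]:
    """Simulate ROI traces with known transient times and amplitudes.

    ``noise_sd_dff`` is the additive noise SD expressed in ΔF/F units
    (i.e. noise SD = ``noise_sd_dff * f0_level`` in raw counts). Explicit
    ``event_times``/``event_amplitudes`` (per ROI) override the Poisson
    draw, which is convenient for closed-form checks.
    """
    if not 0 <= bleach_endpoint_drop < 1:
        raise ValueError("bleach_endpoint_drop must be in [0, 1)")
    if n_frames < 2:
        raise ValueError("need at least 2 frames")

    rng = np.random.default_rng(seed)
    duration_s = n_frames * frame_interval_s
    tfrac = np.arange(n_frames) / (n_frames - 1)
    if bleach_shape == "linear":
        drift = bleach_endpoint_drop * tfrac
    elif bleach_shape == "exponential":
        if bleach_endpoint_drop == 0:
            drift = np.zeros(n_frames)
        else:
            tau = -1.0 / np.log(1 - bleach_endpoint_drop)
            drift = 1 - np.exp(-tfrac / tau)
    else:
        raise ValueError(f"unknown bleach_shape {bleach_shape!r}")

    kernel = transient_kernel(n_frames)
    k_len = len(kernel)

    raw = np.empty((n_frames, n_rois))
    times_out, amps_out = [], []
    for r in range(n_rois):
        if event_times is not None:
            t_ev = np.asarray(event_times[r], dtype=float)
            a_ev = np.asarray(event_amplitudes[r], dtype=float)
        else:
            n_ev = rng.poisson(event_rate_per_min / 60.0 * duration_s)
            t_ev = np.sort(rng.uniform(0, duration_s * 0.95, size=n_ev))
            a_ev = rng.uniform(*amplitude_range, size=n_ev)
        sig = np.zeros(n_frames)
        for t, a in zip(t_ev, a_ev):
            k0 = int(round(t / frame_interval_s))
            span = min(k_len, n_frames - k0)
            if span > 0:
                sig[k0 : k0 + span] += a * kernel[:span]
        trace = f0_level * (1.0 - drift + sig)
        if noise_sd_dff > 0:
            noise = rng.normal(0.0, noise_sd_dff * f0_level, size=n_frames)
            noise[0] = 0.0  # keep F0 exact so amplitude recovery is scorable
            trace = trace + noise
        raw[:, r] = trace
        times_out.append(t_ev)
        amps_out.append(a_ev)

    traces = CalciumTraceSet(raw=raw, frame_interval_s=frame_interval_s)
    gt = CalciumGroundTruth(
        event_times=times_out,
        event_amplitudes=amps_out,
        bleach_endpoint_drop=bleach_endpoint_drop,
        f0_level=f0_level,
        n_frames=n_frames,
        frame_interval_s=frame_interval_s,
    )
    return traces, gt
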