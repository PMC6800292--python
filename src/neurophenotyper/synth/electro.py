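"""Synthetic microelectrode-array recordings.

Each electrode carries Gaussian instrument noise of known SD with biphasic
extracellular spike waveforms inserted at Poisson event times. The biphasic
template (a Gaussian first derivative, ~1.3 ms wide) concentrates its energy
near 500 Hz, inside the 200-3000 Hz analysis band, so inserted spikes
survive bandpass filtering nearly intact and detection can be scored
against the recorded ground-truth times.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DEFAULT_SAMPLING_RATE_HZ = 12_500.0


@dataclass
class MEARecording:
    """Raw voltage matrix (electrodes x samples, µV) at a fixed rate."""

    voltage: np.ndarray
    sampling_rate_hz: float = DEFAULT_SAMPLING_RATE_HZ
    electrode_ids: list[str] = field(default_factory=list)
    well_map: dict[str, str] = field(default_factory=dict)   # electrode -> well

    def __post_init__(self):
        self.voltage = np.atleast_2d(np.asarray(self.voltage))
        if not self.electrode_ids:
            self.electrode_ids = [f"E{i}" for i in range(self.voltage.shape[0])]
        if not self.well_map:
            # default plate layout: 16 electrodes per well
            self.well_map = {
                e: f"W{i // 16}" for i, e in enumerate(self.electrode_ids)
            }

    @property
    def n_electrodes(self) -> int:
        return self.voltage.shape[0]

    @property
    def duration_s(self) -> float:
        return self.voltage.shape[1] / self.sampling_rate_hz


@dataclass
class MEAGroundTruth:
    spike_times: list[np.ndarray]        # per electrode, seconds
    spike_amplitude_sd: float            # template peak in multiples of noise SD
    noise_sd_uv: float
    rates_per_min: np.ndarray
    duration_s: float
    sampling_rate_hz: float


def biphasic_template(sampling_rate_hz: float, width_ms: float = 1.3) -> np.ndarray:
    """Biphasic spike waveform, peak-normalized to -1 at its largest lobe."""
    sigma = width_ms / 4.0 / 1000.0
    half = int(round(2 * width_ms / 1000.0 * sampling_rate_hz / 2))
    t = (np.arange(-half, half + 1)) / sampling_rate_hz
    w = -t * np.exp(-(t**2) / (2 * sigma**2))      # derivative-of-Gaussian
    return w / np.abs(w).max()


def generate_mea_recording(
    rates_per_min,
    amplitude_sd_multiple: float = 10.0,
    noise_sd_uv: float = 3.0,
    duration_s: float = 300.0,
    sampling_rate_hz: float = DEFAULT_SAMPLING_RATE_HZ,
    seed: int = 0,
    electrodes_per_well: int = 16,
) -> tuple[MEARecording, MEAGroundTruth]:
    """Simulate one plate's raw traces with known spike times.

    Parameters
    ----------
    rates_per_min
        Mean firing rate per electrode (spikes/min); event times are
        homogeneous Poisson over the recording.
    amplitude_sd_multiple
        Spike template peak amplitude as a multiple of the noise SD.
    """
    rates = np.atleast_1d(np.asarray(rates_per_min, dtype=float))
    if np.any(rates < 0):
        raise ValueError("rates must be non-negative")
    if amplitude_sd_multiple <= 0:
        raise ValueError("amplitude_sd_multiple must be positive")
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")

    rng = np.random.default_rng(seed)
    n_samples = int(round(duration_s * sampling_rate_hz))
    template = biphasic_template(sampling_rate_hz) * amplitude_sd_multiple * noise_sd_uv
    half = len(template) // 2

    voltage = np.empty((len(rates), n_samples), dtype=np.float32)
    all_times: list[np.ndarray] = []
    for i, rate in enumerate(rates):
        trace = rng.normal(0.0, noise_sd_uv, size=n_samples)
        n_events = rng.poisson(rate / 60.0 * duration_s)
        # keep templates fully inside the trace so every spike is scorable
        lo, hi = half / sampling_rate_hz, duration_s - half / sampling_rate_hz
        times = np.sort(rng.uniform(lo, hi, size=n_events))
        for t in times:
            k = int(round(t * sampling_rate_hz))
            trace[k - half : k + half + 1] += template
        voltage[i] = trace
        all_times.append(times)

    ids = [f"E{i}" for i in range(len(rates))]
    wells = {e: f"W{i // electrodes_per_well}" for i, e in enumerate(ids)}
    rec = MEARecording(
        voltage=voltage,
        sampling_rate_hz=sampling_rate_hz,
        electrode_ids=ids,
        well_map=wells,
    )
    gt = MEAGroundTruth(
        spike_times=all_times,
        spike_amplitude_sd=amplitude_sd_multiple,
        noise_sd_uv=noise_sd_uv,
        rates_per_min=rates,
        duration_s=duration_s,
        sampling_rate_hz=sampling_rate_hz,
    )
    return rec, gt
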