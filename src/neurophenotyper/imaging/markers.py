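"""Marker positivity calls on expanded cell regions.

Two modes match how high-content software scores markers: diffuse markers
(βIII-tubulin, MAP2, GABA ...) by mean region intensity against a threshold,
and granular markers by requiring at least one detected punctum of the
marker inside the expanded region. Positivity ratios such as
βIII-tubulin⁺/Hoechst⁺ or MAP2⁺/βIII-tubulin⁺ are derived from the flags.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from .nuclei import CellRegionSet
from .puncta import detect_puncta


@dataclass
class MarkerCallResult:
    channel: str
    mode: str
    threshold: float | None
    positive: dict[int, bool]            # nucleus id -> call
    fraction: float | None               # positives / cells; None if no cells

    @property
    def n_positive(self) -> int:
        return sum(self.positive.values())


def classify_marker(
    regions: CellRegionSet,
    marker_channel: np.ndarray,
    mode: str = "intensity",
    channel_name: str = "marker",
    intensity_threshold: float | None = None,
    pixel_size_um: float | None = None,
) -> MarkerCallResult:
    """Call each cell positive or negative for one marker channel.

    In ``intensity`` mode the threshold is data-derived by default
    (background-referenced, see :func:`_intensity_threshold`) or can be
    fixed explicitly. In ``granule`` mode a cell is positive iff at least
    one detected punctum of the marker lies inside its expanded region.
    """
    img = np.asarray(marker_channel, dtype=float)
    ids = regions.nucleus_ids
    if not ids:
        warnings.warn("no accepted cells: marker fraction undefined")
        return MarkerCallResult(channel_name, mode, None, {}, None)

    if mode == "intensity":
        means = ndi.labeled_comprehension(
            img, regions.labels, ids, np.mean, float, np.nan
        )
        regions.mean_intensity[channel_name] = dict(zip(ids, map(float, means)))
        thr = intensity_threshold
        if thr is None:
            thr = _intensity_threshold(img, means)
        positive = {i: bool(m > thr) for i, m in zip(ids, means)}
    elif mode == "granule":
        px = pixel_size_um or regions.pixel_size_um
        puncta = detect_puncta(img, neuron_mask=None, pixel_size_um=px)
        counts = {i: 0 for i in ids}
        for p in puncta.records:
            lab = regions.labels[int(round(p.centroid[0])), int(round(p.centroid[1]))]
            if lab in counts:
                counts[lab] += 1
        regions.granule_count[channel_name] = counts
        positive = {i: counts[i] >= 1 for i in ids}
        thr = None
    else:
        raise ValueError(f"unknown mode {mode!r}")

    regions.positivity[channel_name] = positive
    frac = sum(positive.values()) / len(ids)
    return MarkerCallResult(channel_name, mode, thr, positive, frac)


def _intensity_threshold(img: np.ndarray, region_means: np.ndarray) -> float:
    """Background-referenced positive/negative cut for region mean intensities.

    The image median estimates the background (background dominates the
    area). Regions are positive above background + 25% of the dynamic range
    up to the brightest region; this stays correct whether none, some, or
    all cells express the marker, unlike a bimodality-based split. A channel
    with no contrast at all (a truly flat image) is called by signal
    presence: positive iff the level exceeds zero.
    """
    bg = float(np.median(img))
    lo, hi = float(np.min(region_means)), float(np.max(region_means))
    if hi - lo <= 1e-9 * max(abs(hi), 1.0) and abs(hi - bg) <= 1e-9 * max(abs(hi), 1.0):
        return 0.0                        # flat channel: positive iff level > 0
    if hi > 2 * bg + 1e-9:
        return bg + 0.25 * (hi - bg)
    return hi + 1.0                       # nothing above background


def positivity_ratio(
    numerator: MarkerCallResult, denominator: MarkerCallResult | None = None
) -> float | None:
    """Ratio of positive cells, e.g. MAP2⁺/βIII-tubulin⁺.

    With no denominator the ratio is over all cells (i.e. per Hoechst⁺
    nucleus). Returns None when the denominator set is empty.
    """
    if numerator.fraction is None:
        return None
    if denominator is None:
        return numerator.fraction
    denom_ids = [i for i, v in denominator.positive.items() if v]
    if not denom_ids:
        return None
    num = sum(1 for i in denom_ids if numerator.positive.get(i, False))
    return num / len(denom_ids)
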