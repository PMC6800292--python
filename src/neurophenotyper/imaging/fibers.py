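"""Neurite / dendrite morphometry from fiber-marker channels.

The field convention quantified here: binarize the stained channel,
skeletonize, and report the total skeleton length per field (a), the
number of disjoint fiber components (b), and the mean fiber length a/b.
Dendrite length is the same skeleton measure on the MAP2 channel,
normalized per MAP2⁺ cell.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.morphology import skeletonize


@dataclass
class FiberMetrics:
    total_length_um: float               # a
    fiber_count: int                     # b
    mean_length_um: float | None         # a / b, None when b == 0


@dataclass
class DendriteMetrics:
    total_length_um: float
    n_cells: int
    per_cell_um: float | None


def skeleton_length_um(skeleton: np.ndarray, pixel_size_um: float) -> float:
    """Path length of a skeleton: 8-connected chain with √2 diagonal steps.

    Diagonal links that short-cut an existing orthogonal corner are not
    double-counted.
    """
    sk = np.asarray(skeleton, dtype=bool)
    n_orth = int((sk[:, :-1] & sk[:, 1:]).sum() + (sk[:-1, :] & sk[1:, :]).sum())
    # diagonal down-right: skip when either orthogonal mediator pixel exists
    dr = sk[:-1, :-1] & sk[1:, 1:]
    dr &= ~(sk[1:, :-1] | sk[:-1, 1:])
    dl = sk[:-1, 1:] & sk[1:, :-1]
    dl &= ~(sk[:-1, :-1] | sk[1:, 1:])
    n_diag = int(dr.sum() + dl.sum())
    return (n_orth + math.sqrt(2) * n_diag) * pixel_size_um


def measure_fibers(
    fiber_channel: np.ndarray,
    pixel_size_um: float,
    threshold: float | None = None,
    min_component_um: float = 10.0,
    exclude_mask: np.ndarray | None = None,
) -> FiberMetrics:
    """Total fiber length (a), fiber count (b) and mean length a/b.

    The channel is binarized (Otsu by default), skeletonized, and the
    skeleton measured as an 8-connected weighted chain; b counts its
    connected components. Components shorter than ``min_component_um`` are
    discarded — they are speckle or the stubby medial axes of cell bodies,
    not fibers. ``exclude_mask`` removes pixels (e.g. soma regions) before
    skeletonization.
    """
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be positive")
    img = np.asarray(fiber_channel, dtype=float)
    if threshold is None:
        finite = img[np.isfinite(img)]
        if finite.size == 0 or finite.max() - finite.min() < 1e-12:
            return FiberMetrics(0.0, 0, None)
        threshold = threshold_otsu(img)
    binary = img > threshold
    if exclude_mask is not None:
        binary &= ~np.asarray(exclude_mask, dtype=bool)
    if not binary.any():
        return FiberMetrics(0.0, 0, None)
    sk = skeletonize(binary)
    if not sk.any():
        return FiberMetrics(0.0, 0, None)
    labels = cc_label(sk, connectivity=2)
    total = 0.0
    n_comp = 0
    for lab in range(1, labels.max() + 1):
        comp_len = skeleton_length_um(labels == lab, pixel_size_um)
        if comp_len >= min_component_um:
            total += comp_len
            n_comp += 1
    mean = total / n_comp if n_comp else None
    return FiberMetrics(total_length_um=total, fiber_count=n_comp, mean_length_um=mean)


def measure_dendrites(
    map2_channel: np.ndarray,
    pixel_size_um: float,
    n_map2_cells: int,
    threshold: float | None = None,
    exclude_mask: np.ndarray | None = None,
) -> DendriteMetrics:
    """Dendrite (MAP2 skeleton) length per MAP2⁺ cell for one field.

    ``n_map2_cells`` is the MAP2⁺ cell count from the marker-positivity
    step; the per-field skeleton total is also returned so either
    normalization can be reported. ``exclude_mask`` (typically the expanded
    cell regions) restricts the skeleton to neurites outside the somata.
    """
    metrics = measure_fibers(
        map2_channel, pixel_size_um, threshold=threshold, exclude_mask=exclude_mask
    )
    if n_map2_cells <= 0:
        warnings.warn("no MAP2-positive cells: per-cell dendrite length undefined")
        return DendriteMetrics(metrics.total_length_um, 0, None)
    return DendriteMetrics(
        total_length_um=metrics.total_length_um,
        n_cells=n_map2_cells,
        per_cell_um=metrics.total_length_um / n_map2_cells,
    )
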