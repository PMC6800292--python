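"""Synthetic high-content microscopy scenes with exact ground truth.

The generator renders the kinds of fields an automated imager collects from
iPSC-derived neuronal cultures: a Hoechst nuclear channel (including small
debris nuclei and bright pyknotic nuclei), diffuse cytoplasmic marker
channels (βIII-tubulin, MAP2, ...), curvilinear fiber channels of known
total arc length, and punctate synaptic channels with a controllable
fraction of pre/post colocalized pairs.

Shapes are kept analytically tractable on purpose: nuclei are ellipses
(area = π·a·b), fibers are smooth random-walk polylines (length = sum of
segment lengths), puncta are Gaussian spots. Every rendered object is
recorded in a :class:`SceneGroundTruth` so downstream measurements can be
scored by parameter recovery.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi


class PlacementError(RuntimeError):
    """Requested object density too high to place without overlap."""


# ---------------------------------------------------------------------------
# containers


@dataclass
class ImageScene:
    """A multi-channel field of view with physical pixel calibration."""

    channels: dict[str, np.ndarray]
    pixel_size_um: float

    @property
    def shape(self) -> tuple[int, int]:
        ch = next(iter(self.channels.values()))
        return ch.shape

    def channel(self, name: str) -> np.ndarray:
        return self.channels[name]


@dataclass
class NucleusTruth:
    id: int
    center: tuple[float, float]          # (row, col) px
    axes_um: tuple[float, float]         # semi-axes
    angle: float                         # radians
    area_um2: float                      # π·a·b, exact
    intensity: float
    intensity_class: str                 # "normal" | "small" | "pyknotic"


@dataclass
class FiberTruth:
    id: int
    channel: str
    vertices: np.ndarray                 # (n, 2) float px, polyline
    arc_length_um: float                 # exact polyline length


@dataclass
class PunctumTruth:
    id: int
    channel: str
    center: tuple[float, float]          # (row, col) px
    sigma_um: float
    amplitude: float


@dataclass
class SceneGroundTruth:
    pixel_size_um: float
    nucleus_records: list[NucleusTruth] = field(default_factory=list)
    cell_marker_labels: dict[str, dict[int, bool]] = field(default_factory=dict)
    fiber_arcs: list[FiberTruth] = field(default_factory=list)
    puncta_lists: dict[str, list[PunctumTruth]] = field(default_factory=dict)
    colocalized_pairs: list[tuple[int, int]] = field(default_factory=list)
    coloc_distance_um: float = 0.5

    # -- convenience accessors used throughout the tests ------------------
    def n_accepted_nuclei(self, min_area_um2: float = 50.0) -> int:
        return sum(
            1
            for n in self.nucleus_records
            if n.area_um2 > min_area_um2 and n.intensity_class != "pyknotic"
        )

    def total_fiber_length_um(self, channel: str | None = None) -> float:
        return float(
            sum(
                f.arc_length_um
                for f in self.fiber_arcs
                if channel is None or f.channel == channel
            )
        )

    def fiber_count(self, channel: str | None = None) -> int:
        return sum(
            1 for f in self.fiber_arcs if channel is None or f.channel == channel
        )

    def to_json(self) -> str:
        def enc(obj):
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            if dataclasses.is_dataclass(obj):
                return dataclasses.asdict(obj)
            raise TypeError(type(obj))

        return json.dumps(dataclasses.asdict(self), default=enc)


# ---------------------------------------------------------------------------
# parameters


@dataclass
class FiberParams:
    """One population of curvilinear fibers rendered into ``channel``."""

    channel: str = "btub"
    n_fibers: int = 8
    length_um: tuple[float, float] = (80.0, 160.0)   # uniform range per fiber
    width_um: float = 1.8
    intensity: float = 140.0
    step_um: float = 2.0
    turn_sd_rad: float = 0.12


@dataclass
class MarkerParams:
    """Diffuse or granular per-cell marker expression."""

    positive_fraction: float = 0.6
    mode: str = "intensity"              # "intensity" | "granule"
    intensity: float = 120.0
    n_granules: tuple[int, int] = (2, 4)
    granule_sigma_um: float = 0.4
    granule_amplitude: float = 180.0


@dataclass
class PunctaParams:
    """Pre/post synaptic spot channels with a set colocalized fraction."""

    pre_channel: str = "synapsin"
    post_channel: str = "homer"
    n_pre: int = 50
    n_post: int = 50
    coloc_fraction: float = 0.4
    sigma_um: float = 0.25
    amplitude: float = 90.0
    coloc_offset_um: float = 0.2         # pre/post centre offset for true pairs
    exclusion_um: float = 1.4            # same-channel minimum spacing
    mask_channel: str | None = "btub"    # place puncta on this channel's structures
    mask_dilation_um: float = 0.8


@dataclass
class SceneParams:
    """Full description of one synthetic field."""

    shape: tuple[int, int] = (512, 512)
    pixel_size_um: float = 0.65
    background: float = 10.0
    noise_sd: float = 2.0

    n_nuclei: int = 20                   # normal, countable nuclei
    n_small_nuclei: int = 0              # below the 50 µm² area gate
    n_pyknotic_nuclei: int = 0           # condensed, bright (dying cells)
    nucleus_area_um2: tuple[float, float] = (80.0, 150.0)
    small_area_um2: tuple[float, float] = (15.0, 42.0)
    pyknotic_area_um2: tuple[float, float] = (55.0, 80.0)
    nucleus_intensity: tuple[float, float] = (130.0, 180.0)
    pyknotic_intensity: tuple[float, float] = (420.0, 500.0)
    nucleus_aspect: tuple[float, float] = (1.0, 1.5)

    fibers: list[FiberParams] = field(default_factory=list)
    markers: dict[str, MarkerParams] = field(default_factory=dict)
    puncta: PunctaParams | None = None
    max_place_tries: int = 2000


# ---------------------------------------------------------------------------
# rendering primitives


def _render_ellipse(img, center, axes_px, angle, value):
    cy, cx = center
    a, b = axes_px
    r = int(math.ceil(max(a, b))) + 2
    y0, y1 = max(0, int(cy) - r), min(img.shape[0], int(cy) + r + 1)
    x0, x1 = max(0, int(cx) - r), min(img.shape[1], int(cx) + r + 1)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dy, dx = yy - cy, xx - cx
    ca, sa = math.cos(angle), math.sin(angle)
    u = dy * ca + dx * sa
    v = -dy * sa + dx * ca
    inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    region = img[y0:y1, x0:x1]
    region[inside] = np.maximum(region[inside], value)


def _render_gaussian_spot(img, center, sigma_px, amplitude):
    cy, cx = center
    r = int(math.ceil(4 * sigma_px)) + 1
    y0, y1 = max(0, int(cy) - r), min(img.shape[0], int(cy) + r + 1)
    x0, x1 = max(0, int(cx) - r), min(img.shape[1], int(cx) + r + 1)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    g = amplitude * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma_px**2))
    img[y0:y1, x0:x1] = np.maximum(img[y0:y1, x0:x1], g)


def _polyline_mask(shape, vertices, half_width_px):
    """Boolean mask of a polyline dilated to the given half-width."""
    mask = np.zeros(shape, dtype=bool)
    for (y0, x0), (y1, x1) in zip(vertices[:-1], vertices[1:]):
        seg = math.hypot(y1 - y0, x1 - x0)
        n = max(2, int(seg / 0.4) + 1)   # sub-pixel sampling along the segment
        ys = np.clip(np.round(np.linspace(y0, y1, n)).astype(int), 0, shape[0] - 1)
        xs = np.clip(np.round(np.linspace(x0, x1, n)).astype(int), 0, shape[1] - 1)
        mask[ys, xs] = True
    if half_width_px >= 1:
        r = int(round(half_width_px))
        yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
        mask = ndi.binary_dilation(mask, structure=yy**2 + xx**2 <= r**2)
    return mask


def _random_walk_polyline(rng, start, heading, total_len_px, step_px, turn_sd,
                          bounds):
    """Smooth random walk clipped to a rectangular cell by steering inward."""
    ylo, yhi, xlo, xhi = bounds
    pts = [np.asarray(start, dtype=float)]
    remaining = total_len_px
    h = heading
    while remaining > 1e-9:
        step = min(step_px, remaining)
        h += rng.normal(0.0, turn_sd)
        nxt = pts[-1] + step * np.array([math.sin(h), math.cos(h)])
        tries = 0
        while not (ylo <= nxt[0] <= yhi and xlo <= nxt[1] <= xhi):
            # steer toward the cell centre when the walk hits the wall
            centre = np.array([(ylo + yhi) / 2, (xlo + xhi) / 2])
            to_c = centre - pts[-1]
            h = math.atan2(to_c[0], to_c[1]) + rng.normal(0.0, 0.3)
            nxt = pts[-1] + step * np.array([math.sin(h), math.cos(h)])
            tries += 1
            if tries > 50:  # pragma: no cover - degenerate tiny cells
                raise PlacementError("fiber cannot fit in its allotted cell")
        pts.append(nxt)
        remaining -= step
    return np.asarray(pts)


# ---------------------------------------------------------------------------
# placement helpers


def _place_centers(rng, shape, n, min_sep_px, margin_px, max_tries,
                   existing=None):
    centers = [] if existing is None else list(existing)
    placed = []
    tries = 0
    while len(placed) < n:
        if tries > max_tries:
            raise PlacementError(
                f"could not place {n} objects with separation {min_sep_px:.1f}px"
            )
        c = np.array(
            [
                rng.uniform(margin_px, shape[0] - margin_px),
                rng.uniform(margin_px, shape[1] - margin_px),
            ]
        )
        if all(np.hypot(*(c - p)) >= min_sep_px for p in centers):
            centers.append(c)
            placed.append(c)
        tries += 1
    return placed


# ---------------------------------------------------------------------------
# main generator


def generate_image_scene(params: SceneParams, seed: int) -> tuple[ImageScene, SceneGroundTruth]:
    """Render one synthetic multi-channel field and its full ground truth.

    Deterministic for a fixed ``(params, seed)`` pair. Raises
    :class:`PlacementError` when the requested object counts cannot be
    placed without overlap at the configured separations.
    """
    if params.pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be positive")
    for cnt in (params.n_nuclei, params.n_small_nuclei, params.n_pyknotic_nuclei):
        if cnt < 0:
            raise ValueError("object counts must be non-negative")

    rng = np.random.default_rng(seed)
    px = params.pixel_size_um
    shape = tuple(params.shape)
    gt = SceneGroundTruth(pixel_size_um=px)
    channels: dict[str, np.ndarray] = {"hoechst": np.zeros(shape, dtype=np.float64)}

    # ----- nuclei ---------------------------------------------------------
    specs = (
        [("normal", params.nucleus_area_um2, params.nucleus_intensity)] * params.n_nuclei
        + [("small", params.small_area_um2, params.nucleus_intensity)] * params.n_small_nuclei
        + [("pyknotic", params.pyknotic_area_um2, params.pyknotic_intensity)] * params.n_pyknotic_nuclei
    )
    max_r_px = math.sqrt(max(params.nucleus_area_um2[1], 1.0) / math.pi) / px
    min_sep = 2.6 * max_r_px + 3
    centers = _place_centers(
        rng, shape, len(specs), min_sep, max_r_px * 1.6 + 2, params.max_place_tries
    )
    hoechst = channels["hoechst"]
    for i, ((cls, arange, irange), c) in enumerate(zip(specs, centers)):
        area = rng.uniform(*arange)
        aspect = rng.uniform(*params.nucleus_aspect)
        b_um = math.sqrt(area / (math.pi * aspect))
        a_um = aspect * b_um
        angle = rng.uniform(0, math.pi)
        inten = rng.uniform(*irange)
        _render_ellipse(hoechst, c, (a_um / px, b_um / px), angle, inten)
        gt.nucleus_records.append(
            NucleusTruth(
                id=i,
                center=(float(c[0]), float(c[1])),
                axes_um=(a_um, b_um),
                angle=angle,
                area_um2=math.pi * a_um * b_um,
                intensity=inten,
                intensity_class=cls,
            )
        )

    # ----- diffuse / granular cell markers --------------------------------
    countable = [n for n in gt.nucleus_records if n.intensity_class == "normal"]
    for ch_name, mp in params.markers.items():
        img = channels.setdefault(ch_name, np.zeros(shape, dtype=np.float64))
        n_pos = int(round(mp.positive_fraction * len(countable)))
        order = rng.permutation(len(countable))
        labels: dict[int, bool] = {n.id: False for n in countable}
        for k in order[:n_pos]:
            nuc = countable[k]
            labels[nuc.id] = True
            if mp.mode == "intensity":
                # soma: marker halo slightly beyond the nucleus, but inside
                # the 50%-expanded region (1.22x linear) so that region
                # means pick it up while soma exclusion removes it fully
                _render_ellipse(
                    img,
                    nuc.center,
                    (1.15 * nuc.axes_um[0] / px, 1.15 * nuc.axes_um[1] / px),
                    nuc.angle,
                    mp.intensity,
                )
            else:
                n_gr = rng.integers(mp.n_granules[0], mp.n_granules[1] + 1)
                r_px = 0.8 * nuc.axes_um[1] / px
                for _ in range(n_gr):
                    off = rng.uniform(-r_px, r_px, size=2)
                    _render_gaussian_spot(
                        img,
                        (nuc.center[0] + off[0], nuc.center[1] + off[1]),
                        mp.granule_sigma_um / px,
                        mp.granule_amplitude,
                    )
        gt.cell_marker_labels[ch_name] = labels

    # ----- fibers ---------------------------------------------------------
    fid = 0
    for fp in params.fibers:
        img = channels.setdefault(fp.channel, np.zeros(shape, dtype=np.float64))
        cells = _fiber_grid_cells(shape, fp.n_fibers, margin_px=int(fp.width_um / px) + 3)
        if len(cells) < fp.n_fibers:
            raise PlacementError("image too small for the requested fiber count")
        for ci in range(fp.n_fibers):
            ylo, yhi, xlo, xhi = cells[ci]
            length_um = rng.uniform(*fp.length_um)
            start = (rng.uniform(ylo, yhi), rng.uniform(xlo, xhi))
            verts = _random_walk_polyline(
                rng,
                start,
                rng.uniform(0, 2 * math.pi),
                length_um / px,
                fp.step_um / px,
                fp.turn_sd_rad,
                (ylo, yhi, xlo, xhi),
            )
            mask = _polyline_mask(shape, verts, 0.5 * fp.width_um / px)
            img[mask] = np.maximum(img[mask], fp.intensity)
            seg = np.diff(verts, axis=0)
            arc_px = float(np.hypot(seg[:, 0], seg[:, 1]).sum())
            gt.fiber_arcs.append(
                FiberTruth(
                    id=fid, channel=fp.channel, vertices=verts,
                    arc_length_um=arc_px * px,
                )
            )
            fid += 1

    # ----- synaptic puncta -------------------------------------------------
    if params.puncta is not None:
        _add_puncta(rng, params, channels, gt)

    # ----- background + noise ----------------------------------------------
    for name, img in channels.items():
        img += params.background
        if params.noise_sd > 0:
            img += rng.normal(0.0, params.noise_sd, size=shape)
        np.clip(img, 0, None, out=img)
        channels[name] = img.astype(np.float32)

    return ImageScene(channels=channels, pixel_size_um=px), gt


def _fiber_grid_cells(shape, n_fibers, margin_px):
    """Disjoint rectangular cells, one per fiber, so components never merge."""
    if n_fibers == 0:
        return []
    ncol = int(math.ceil(math.sqrt(n_fibers)))
    nrow = int(math.ceil(n_fibers / ncol))
    cells = []
    ch, cw = shape[0] / nrow, shape[1] / ncol
    for r in range(nrow):
        for c in range(ncol):
            ylo, yhi = r * ch + margin_px, (r + 1) * ch - margin_px
            xlo, xhi = c * cw + margin_px, (c + 1) * cw - margin_px
            if yhi - ylo < 4 or xhi - xlo < 4:
                continue
            cells.append((ylo, yhi, xlo, xhi))
    return cells


def _add_puncta(rng, params: SceneParams, channels, gt: SceneGroundTruth):
    pp = params.puncta
    px = params.pixel_size_um
    shape = tuple(params.shape)
    pre_img = channels.setdefault(pp.pre_channel, np.zeros(shape, dtype=np.float64))
    post_img = channels.setdefault(pp.post_channel, np.zeros(shape, dtype=np.float64))

    n_coloc = int(round(pp.coloc_fraction * pp.n_pre))
    if n_coloc > pp.n_post:
        raise ValueError("coloc_fraction requires more post puncta than available")
    excl_px = pp.exclusion_um / px
    margin = 4 * pp.sigma_um / px + 2

    # puncta live on the neuron (βIII-tubulin⁺) structures when present
    allowed = None
    if pp.mask_channel is not None and pp.mask_channel in channels:
        base = channels[pp.mask_channel] > 0
        if base.any():
            r = max(1, int(round(pp.mask_dilation_um / px)))
            yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
            base = ndi.binary_dilation(base, structure=yy**2 + xx**2 <= r**2)
            base[: int(margin), :] = base[-int(margin) :, :] = False
            base[:, : int(margin)] = base[:, -int(margin) :] = False
            allowed = np.argwhere(base).astype(float)

    def draw_point():
        if allowed is not None:
            return allowed[rng.integers(len(allowed))] + rng.uniform(-0.5, 0.5, 2)
        return np.array(
            [rng.uniform(margin, shape[0] - margin), rng.uniform(margin, shape[1] - margin)]
        )

    def place(n, keep_away, min_sep, label):
        placed = []
        tries = 0
        while len(placed) < n:
            if tries > params.max_place_tries * 10:
                raise PlacementError(f"could not place {label}")
            c = draw_point()
            if all(np.hypot(*(c - p)) >= min_sep for p in placed) and all(
                np.hypot(*(c - p)) >= keep_away[1] for p in keep_away[0]
            ):
                placed.append(c)
            tries += 1
        return placed

    # pre puncta, mutually resolvable
    pre_centers = place(pp.n_pre, ([], 0.0), excl_px, "pre puncta")
    # non-colocalized post puncta stay well clear of every pre punctum
    far_post = place(
        pp.n_post - n_coloc,
        (pre_centers, 2.5 * gt.coloc_distance_um / px),
        excl_px,
        "non-colocalized post puncta",
    )

    sig_px = pp.sigma_um / px
    pre_list, post_list = [], []
    for i, c in enumerate(pre_centers):
        _render_gaussian_spot(pre_img, c, sig_px, pp.amplitude)
        pre_list.append(
            PunctumTruth(i, pp.pre_channel, (float(c[0]), float(c[1])), pp.sigma_um, pp.amplitude)
        )
    pid = 0
    for i in range(n_coloc):  # post partner within the colocalization distance
        ang = rng.uniform(0, 2 * math.pi)
        off = pp.coloc_offset_um / px
        c = pre_centers[i] + off * np.array([math.sin(ang), math.cos(ang)])
        _render_gaussian_spot(post_img, c, sig_px, pp.amplitude)
        post_list.append(
            PunctumTruth(pid, pp.post_channel, (float(c[0]), float(c[1])), pp.sigma_um, pp.amplitude)
        )
        gt.colocalized_pairs.append((i, pid))
        pid += 1
    for c in far_post:
        _render_gaussian_spot(post_img, c, sig_px, pp.amplitude)
        post_list.append(
            PunctumTruth(pid, pp.post_channel, (float(c[0]), float(c[1])), pp.sigma_um, pp.amplitude)
        )
        pid += 1

    gt.puncta_lists[pp.pre_channel] = pre_list
    gt.puncta_lists[pp.post_channel] = post_list


# ---------------------------------------------------------------------------
# embryoid bodies


@dataclass
class EBTruth:
    area_um2: float
    perimeter_um: float
    form_factor: float


def generate_eb_mask(
    area_um2: float,
    elongation: float = 1.0,
    pixel_size_um: float = 3.25,
    shape: tuple[int, int] = (512, 512),
    seed: int = 0,
) -> tuple[np.ndarray, EBTruth]:
    """Elliptical embryoid-body mask with closed-form area and form factor.

    ``elongation`` is the semi-axis ratio a/b; 1 gives a circle (form
    factor 1). The perimeter uses Ramanujan's approximation, accurate to
    well below rasterization error for modest elongations.
    """
    if area_um2 <= 0 or elongation < 1:
        raise ValueError("need area > 0 and elongation >= 1")
    rng = np.random.default_rng(seed)
    b = math.sqrt(area_um2 / (math.pi * elongation))
    a = elongation * b
    h = ((a - b) / (a + b)) ** 2
    perim = math.pi * (a + b) * (1 + 3 * h / (10 + math.sqrt(4 - 3 * h)))
    ff = 4 * math.pi * area_um2 / perim**2
    mask = np.zeros(shape, dtype=bool)
    centre = (shape[0] / 2 + rng.uniform(-5, 5), shape[1] / 2 + rng.uniform(-5, 5))
    img = np.zeros(shape, dtype=np.float64)
    _render_ellipse(
        img, centre, (a / pixel_size_um, b / pixel_size_um), rng.uniform(0, math.pi), 1.0
    )
    mask = img > 0
    return mask, EBTruth(area_um2=area_um2, perimeter_um=perim, form_factor=ff)
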