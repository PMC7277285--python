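"""Synthetic bednet-room scenes with known ground truth.

The simulator emulates the photometric structure of the two recording rigs so
the segmentation/tracking pipeline can be benchmarked without real footage:

* **rrs** — retro-reflective screen illumination: near-uniform bright
  background with gentle horizontal banding from the adhesive tape strips the
  screen is assembled from.
* **backlit** — collimated transmission illumination through a pair of
  Fresnel lenses: a centre hot-spot with intensity falling below half at the
  image corners, plus concentric sinusoidal ring modulation from the lens
  structure.

Mosquitoes fly as correlated random walks and are rendered as soft-edged dark
ellipses whose depth below the local background is drawn from a
region-dependent contrast table (background 3–5, front-of-net 2–3,
behind-net 1–2 greyscales at nominal illumination) and scaled by the local
illumination relative to the image centre — in the dim corners of a backlit
scene a mosquito image is proportionally fainter, which is the physical
mechanism behind the two rigs' different detection rates.  Temporal camera
noise is Gaussian per pixel per frame, with standard deviation a fixed
fraction (default 1.84%) of the local mean intensity, applied before 8-bit
quantisation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.draw import polygon2mask

logger = logging.getLogger(__name__)

TRUTH_REGIONS = ("background", "front_net", "behind_net", "occluded")


def _polygon_area(poly: list[tuple[float, float]]) -> float:
    xy = np.asarray(poly, dtype=float)
    x, y = xy[:, 0], xy[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, 1)) - np.dot(y, np.roll(x, 1)))


def _polygon_mask(poly: list[tuple[float, float]], shape: tuple[int, int]) -> np.ndarray:
    # polygon2mask expects (row, col) vertex order
    rc = np.asarray([(y, x) for x, y in poly], dtype=float)
    return polygon2mask(shape, rc)


@dataclass
class IlluminationField:
    """Mean background illumination of one recording mode.

    ``corner_falloff_fraction`` is the corner/centre intensity ratio of the
    radial profile (1.0 = perfectly flat).  Ring modulation (backlit) and
    horizontal banding (rrs) are multiplicative sinusoids; band period
    defaults to 100 px ≈ 50 mm tape width at 0.5 mm/px.

    ``net_contrast_factor`` scales the image contrast of mosquitoes seen
    through bednet mesh, capturing how the illumination geometry interacts
    with fibre occlusion: a diffuse reflected cone partially bypasses the
    mesh (≈1 for a retro-reflective screen), whereas fully collimated
    backlighting is blocked outright, further suppressing the already weak
    across-net mosquito images.
    """

    mode: str = "rrs"
    base_level: float = 200.0
    corner_falloff_fraction: float = 0.95
    hot_spot_width_frac: float = 0.5
    ring_modulation_amplitude: float = 0.0
    ring_period_px: float = 64.0
    band_period_px: float = 100.0
    band_amplitude: float = 6.0
    net_contrast_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.mode not in ("rrs", "backlit"):
            raise ValueError(f"unknown illumination mode {self.mode!r}")
        if not 0.0 < self.base_level <= 255.0:
            raise ValueError("base_level must lie in (0, 255]")
        if not 0.0 < self.corner_falloff_fraction <= 1.0:
            raise ValueError("corner_falloff_fraction must lie in (0, 1]")


@dataclass
class SceneGeometry:
    """Pixel-space layout of the scene.

    ``n_passes`` is how many times the imaging light crosses the bednet
    (1 for transmission/backlit, 2 for the retro-reflected path), each pass
    attenuating by ``bednet_attenuation_per_pass``.
    """

    image_size: tuple[int, int] = (256, 256)  # (H, W)
    bednet_polygon: list[tuple[float, float]] = field(default_factory=list)
    bednet_attenuation_per_pass: float = 0.45
    n_passes: int = 2
    occluder_polygons: list[list[tuple[float, float]]] = field(default_factory=list)
    px_scale_mm: float = 0.5

    def __post_init__(self) -> None:
        self.image_size = tuple(int(v) for v in self.image_size)
        h, w = self.image_size
        if h < 8 or w < 8:
            raise ValueError("image_size too small")
        if not 0.0 < self.bednet_attenuation_per_pass <= 1.0:
            raise ValueError("bednet_attenuation_per_pass must lie in (0, 1]")
        self.bednet_polygon = [tuple(map(float, p)) for p in self.bednet_polygon]
        self.occluder_polygons = [
            [tuple(map(float, p)) for p in poly] for poly in self.occluder_polygons
        ]
        for poly in [self.bednet_polygon, *self.occluder_polygons]:
            if not poly:
                continue
            if _polygon_area(poly) <= 0.0:
                raise ValueError("degenerate (zero-area) polygon in geometry")
            xy = np.asarray(poly)
            if (xy[:, 0] < 0).any() or (xy[:, 0] > w).any() \
                    or (xy[:, 1] < 0).any() or (xy[:, 1] > h).any():
                raise ValueError("polygon vertices outside image bounds")

    @property
    def net_attenuation(self) -> float:
        return self.bednet_attenuation_per_pass ** self.n_passes

    def net_mask(self) -> np.ndarray:
        if not self.bednet_polygon:
            return np.zeros(self.image_size, bool)
        return _polygon_mask(self.bednet_polygon, self.image_size)

    def occluder_mask(self) -> np.ndarray:
        m = np.zeros(self.image_size, bool)
        for poly in self.occluder_polygons:
            m |= _polygon_mask(poly, self.image_size)
        return m


@dataclass
class NoiseModel:
    """Temporal camera noise: per-pixel sd = ``relative_sd`` × local mean."""

    relative_sd: float = 0.0184
    distribution: str = "gaussian"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.relative_sd < 0:
            raise ValueError("relative_sd must be >= 0")
        if self.distribution != "gaussian":
            raise ValueError("only gaussian noise is modelled")


@dataclass
class ScheduleEntry:
    """Scripted passage: confine one mosquito to the bednet region for a frame
    window, on a given side of the net ('front' or 'behind') — the simulated
    analogue of an aspirator release at a known location."""

    mosquito_id: int
    frame_start: int
    frame_end: int
    layer: str = "behind"

    def __post_init__(self) -> None:
        if self.layer not in ("front", "behind"):
            raise ValueError("layer must be 'front' or 'behind'")
        if self.frame_end < self.frame_start:
            raise ValueError("frame_end must be >= frame_start")


@dataclass
class FlightModel:
    """Correlated-random-walk flight and body-rendering parameters.

    Headings receive Gaussian perturbations of ``turn_sd_rad`` per frame and
    per-frame speed is jittered ±20% around ``speed_mean_mm_s``; paths reflect
    off the image borders.  The rendered image footprint
    (``blob_length_px`` × ``blob_width_px``, default 20 × 14 px ≈ 10 × 7 mm at
    0.5 mm/px) represents body plus beating wings plus motion blur and
    double-pass defocus/diffraction, matching the broad intensity wells a
    real mosquito image produces rather than its bare 2.5–3.5 mm body.  Mosquitoes without a schedule entry fly freely and are
    assigned alternately to the front/behind layer for frames spent inside
    the net region.

    When ``home_range_px`` is set, each mosquito is tethered to its own
    release point: its heading is steered homeward whenever it strays farther
    than the range.  Release points may be pinned explicitly
    (``release_points``, cycled over mosquitoes — the analogue of scripted
    releases at predetermined locations) or are sampled with a minimum
    mutual separation.  A desk-scale benchmark packs mosquitoes orders of magnitude
    more densely (in image area per mosquito image) than a room-scale
    recording; tethering keeps the areal density of flight activity — and
    hence the rate of mosquito-image overlap — representative while every
    mosquito still crosses between regions that its range straddles.
    """

    n_mosquitoes: int = 10
    speed_mean_mm_s: float = 300.0
    speed_jitter: float = 0.2
    turn_sd_rad: float = 0.12
    frame_rate_hz: float = 50.0
    region_schedule: list[ScheduleEntry] | None = None
    home_range_px: float | None = None
    release_points: list[tuple[float, float]] | None = None
    blob_length_px: float = 20.0
    blob_width_px: float = 14.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_mosquitoes < 0:
            raise ValueError("n_mosquitoes must be >= 0")
        if self.speed_mean_mm_s < 0 or self.frame_rate_hz <= 0:
            raise ValueError("speeds and frame rate must be non-negative/positive")


@dataclass
class ContrastTable:
    """Region-dependent mosquito/background contrast ranges (greyscales).

    The values are peak image depths at nominal (centre) illumination:
    background ≥ front-of-net ≥ behind-net, reflecting one and two extra
    passes of bednet mesh between mosquito and camera.
    """

    background: tuple[float, float] = (3.0, 5.0)
    front_of_net: tuple[float, float] = (2.0, 3.0)
    behind_net: tuple[float, float] = (1.0, 2.0)

    def __post_init__(self) -> None:
        for name in ("background", "front_of_net", "behind_net"):
            setattr(self, name, tuple(float(v) for v in getattr(self, name)))
            lo, hi = getattr(self, name)
            if lo <= 0 or hi < lo:
                raise ValueError(f"invalid contrast range for {name}")
        if not self.background[0] >= self.front_of_net[0] >= self.behind_net[0]:
            raise ValueError("contrast minima must be ordered background >= front >= behind")

    def range_for(self, region: str) -> tuple[float, float]:
        return {
            "background": self.background,
            "front_net": self.front_of_net,
            "behind_net": self.behind_net,
        }[region]


@dataclass
class SceneTruth:
    """Ground truth emitted by the simulator.

    ``table`` has one row per mosquito per frame while on screen, with columns
    ``frame, id, x_px, y_px, heading_rad, region``.
    """

    table: pd.DataFrame
    geometry: SceneGeometry
    flight: FlightModel

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


@dataclass
class SceneConfig:
    """Everything needed to simulate one recording."""

    n_frames: int = 500
    illumination: IlluminationField = field(default_factory=IlluminationField)
    geometry: SceneGeometry = field(default_factory=SceneGeometry)
    flight: FlightModel = field(default_factory=FlightModel)
    contrast: ContrastTable = field(default_factory=ContrastTable)
    noise: NoiseModel = field(default_factory=NoiseModel)

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")


def illumination_profile(field_: IlluminationField, shape: tuple[int, int]) -> np.ndarray:
    """Noise-free illumination field (no scene objects), in greyscales.

    Radial falloff to ``corner_falloff_fraction`` at the corners, multiplied
    by the mode's sinusoidal artefact (concentric rings for backlit,
    horizontal banding for rrs).  The rrs profile is a gentle quadratic; the
    backlit profile is a Gaussian centre hot-spot of width
    ``hot_spot_width_frac`` (fraction of the centre-to-corner distance),
    rescaled so the corner/centre ratio still equals the falloff fraction.
    """
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    r2 = ((xx - cx) ** 2 + (yy - cy) ** 2) / (cx**2 + cy**2)
    f = field_.corner_falloff_fraction
    if field_.mode == "backlit":
        e = np.exp(-r2 / (2.0 * field_.hot_spot_width_frac**2))
        e_corner = np.exp(-1.0 / (2.0 * field_.hot_spot_width_frac**2))
        g = (f - e_corner) / (1.0 - e_corner)
        img = field_.base_level * (g + (1.0 - g) * e)
    else:
        img = field_.base_level * (1.0 - (1.0 - f) * r2)
    if field_.mode == "backlit" and field_.ring_modulation_amplitude > 0:
        rel = field_.ring_modulation_amplitude / field_.base_level
        img *= 1.0 + rel * np.cos(2.0 * np.pi * np.sqrt(r2 * (cx**2 + cy**2)) / field_.ring_period_px)
    elif field_.mode == "rrs" and field_.band_amplitude > 0:
        rel = field_.band_amplitude / field_.base_level
        img *= 1.0 + rel * np.sin(2.0 * np.pi * yy / field_.band_period_px)
    return np.clip(img, 0.0, 255.0)


def render_illumination(field_: IlluminationField, geometry: SceneGeometry) -> np.ndarray:
    """Deterministic mean-background image: illumination with scene objects.

    The bednet region is attenuated by ``attenuation_per_pass ** n_passes``;
    occluders transmit almost nothing (2%).
    """
    img = illumination_profile(field_, geometry.image_size)
    img[geometry.net_mask()] *= geometry.net_attenuation
    img[geometry.occluder_mask()] *= 0.02
    return img


def _reflect(v: float, lo: float, hi: float) -> float:
    # reflect a scalar into [lo, hi]
    span = hi - lo
    if span <= 0:
        return lo
    t = (v - lo) % (2 * span)
    return lo + (span - abs(t - span))


def simulate_flights(
    model: FlightModel, geometry: SceneGeometry, n_frames: int
) -> SceneTruth:
    """Generate ground-truth flight paths with per-frame region labels.

    Each mosquito follows a correlated random walk (heading perturbed by
    ``turn_sd_rad`` per frame, speed jittered ±``speed_jitter``), reflecting
    off the image borders.  The 2-D region label is geometric: inside the
    bednet polygon the mosquito is 'front_net' or 'behind_net' according to
    its depth layer, inside an occluder it is 'occluded', else 'background'.
    Scripted :class:`ScheduleEntry` windows confine a mosquito to the net
    region on a given layer (relocating it to the region centre at the window
    start if necessary).  Fully reproducible from ``model.seed``.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    rng = np.random.default_rng(model.seed)
    h, w = geometry.image_size
    margin = max(model.blob_length_px, model.blob_width_px) / 2.0 + 1.0
    lo_x, hi_x = margin, w - 1 - margin
    lo_y, hi_y = margin, h - 1 - margin

    net_mask = geometry.net_mask()
    occ_mask = geometry.occluder_mask()
    if geometry.bednet_polygon:
        poly = np.asarray(geometry.bednet_polygon)
        net_cx, net_cy = poly[:, 0].mean(), poly[:, 1].mean()
    else:
        net_cx = net_cy = None

    schedule: dict[int, list[ScheduleEntry]] = {}
    for entry in model.region_schedule or []:
        schedule.setdefault(entry.mosquito_id, []).append(entry)

    step_px = model.speed_mean_mm_s / model.frame_rate_hz / geometry.px_scale_mm

    def inside_net(x: float, y: float) -> bool:
        return bool(net_mask[int(np.clip(round(y), 0, h - 1)), int(np.clip(round(x), 0, w - 1))])

    def inside_occ(x: float, y: float) -> bool:
        return bool(occ_mask[int(np.clip(round(y), 0, h - 1)), int(np.clip(round(x), 0, w - 1))])

    # release points; mutually separated when home ranges are in force
    starts: list[tuple[float, float]] = []
    if model.release_points:
        pts = [tuple(map(float, p)) for p in model.release_points]
        starts = [pts[i % len(pts)] for i in range(model.n_mosquitoes)]
    else:
        min_sep = 1.6 * model.home_range_px if model.home_range_px else 0.0
        for _ in range(model.n_mosquitoes):
            for _attempt in range(200):
                sx, sy = rng.uniform(lo_x, hi_x), rng.uniform(lo_y, hi_y)
                if all(np.hypot(sx - px, sy - py) >= min_sep for px, py in starts):
                    break
            starts.append((sx, sy))

    rows: list[tuple] = []
    for mid in range(model.n_mosquitoes):
        x, y = starts[mid]
        home_x, home_y = x, y
        heading = rng.uniform(0.0, 2.0 * np.pi)
        body_heading = heading  # orientation of the rendered image: last motion direction
        default_layer = "front" if mid % 2 == 0 else "behind"
        entries = schedule.get(mid, [])
        for t in range(n_frames):
            active = next(
                (e for e in entries if e.frame_start <= t <= e.frame_end), None
            )
            if active is not None and t == active.frame_start and not inside_net(x, y):
                # scripted release at the net region centre
                x, y = float(net_cx), float(net_cy)
            if (
                model.home_range_px
                and np.hypot(x - home_x, y - home_y) > model.home_range_px
            ):
                heading = np.arctan2(home_y - y, home_x - x)
            heading += rng.normal(0.0, model.turn_sd_rad)
            speed = step_px * (1.0 + rng.uniform(-model.speed_jitter, model.speed_jitter))
            nx = x + speed * np.cos(heading)
            ny = y + speed * np.sin(heading)
            if nx < lo_x or nx > hi_x:
                heading = np.pi - heading
                nx = _reflect(nx, lo_x, hi_x)
            if ny < lo_y or ny > hi_y:
                heading = -heading
                ny = _reflect(ny, lo_y, hi_y)
            if active is not None and t > active.frame_start and not inside_net(nx, ny):
                heading += np.pi  # bounce back into the net region
                nx, ny = x, y
            if np.hypot(nx - x, ny - y) > 1e-9:
                body_heading = float(np.arctan2(ny - y, nx - x))
            x, y = nx, ny
            layer = active.layer if active is not None else default_layer
            if inside_occ(x, y):
                region = "occluded"
            elif inside_net(x, y):
                region = f"{layer}_net"
            else:
                region = "background"
            rows.append((t, mid, x, y, body_heading % (2.0 * np.pi), region))

    table = pd.DataFrame(
        rows, columns=["frame", "id", "x_px", "y_px", "heading_rad", "region"]
    )
    return SceneTruth(table=table, geometry=geometry, flight=model)


def _blob_profile(
    shape: tuple[int, int],
    x: float,
    y: float,
    heading: float,
    length_px: float,
    width_px: float,
    edge_frac: float = 0.2,
) -> tuple[slice, slice, np.ndarray]:
    """Unit-peak soft-edged ellipse footprint, rotated along the heading.

    Returns the bounding slices and the profile patch (flat core, linear ramp
    to zero over the outer ``edge_frac`` of the elliptical radius).
    """
    a, b = length_px / 2.0, width_px / 2.0
    r = int(np.ceil(max(a, b))) + 1
    h, w = shape
    x0, x1 = int(np.floor(x)) - r, int(np.floor(x)) + r + 1
    y0, y1 = int(np.floor(y)) - r, int(np.floor(y)) + r + 1
    x0c, x1c = max(x0, 0), min(x1, w)
    y0c, y1c = max(y0, 0), min(y1, h)
    if x0c >= x1c or y0c >= y1c:
        return slice(0, 0), slice(0, 0), np.zeros((0, 0))
    xs = np.arange(x0c, x1c) - x
    ys = np.arange(y0c, y1c) - y
    dx, dy = np.meshgrid(xs, ys)
    c, s = np.cos(heading), np.sin(heading)
    u = (c * dx + s * dy) / a
    v = (-s * dx + c * dy) / b
    rho = np.sqrt(u**2 + v**2)
    prof = np.clip((1.0 - rho) / edge_frac, 0.0, 1.0)
    return slice(y0c, y1c), slice(x0c, x1c), prof


def render_video(
    truth: SceneTruth,
    field_: IlluminationField,
    geometry: SceneGeometry,
    contrast: ContrastTable,
    noise: NoiseModel,
    n_frames: int | None = None,
) -> np.ndarray:
    """Render an 8-bit greyscale frame stack from ground truth.

    Each mosquito is drawn as a dark soft-edged ellipse aligned with its
    heading.  Its peak depth below the local background is drawn per frame
    from the contrast range of its region label and scaled by the local
    illumination relative to the nominal base level; occluded mosquitoes are
    not drawn.  Gaussian temporal noise (sd = ``relative_sd`` × local mean) is
    added last, then the frames are clipped to [0, 255] and quantised to
    8 bits.  Bit-identical for fixed seeds.
    """
    h, w = geometry.image_size
    background = render_illumination(field_, geometry)
    rel_illum = illumination_profile(field_, geometry.image_size) / field_.base_level

    master = np.random.default_rng(noise.seed)
    contrast_rng, noise_rng = master.spawn(2)

    if n_frames is None:
        n_frames = int(truth.table["frame"].max()) + 1 if len(truth.table) else 0
    by_frame = dict(tuple(truth.table.groupby("frame"))) if len(truth.table) else {}
    frames = np.empty((n_frames, h, w), dtype=np.uint8)
    n_clipped = 0
    for t in range(n_frames):
        img = background.copy()
        group = by_frame.get(t)
        if group is not None:
            for row in group.itertuples(index=False):
                if row.region == "occluded":
                    continue
                lo, hi = contrast.range_for(row.region)
                depth = contrast_rng.uniform(lo, hi)
                iy = int(np.clip(round(row.y_px), 0, h - 1))
                ix = int(np.clip(round(row.x_px), 0, w - 1))
                depth *= rel_illum[iy, ix]
                if row.region != "background":
                    depth *= field_.net_contrast_factor
                sy, sx, prof = _blob_profile(
                    (h, w), row.x_px, row.y_px, row.heading_rad,
                    truth.flight.blob_length_px, truth.flight.blob_width_px,
                )
                if prof.size:
                    patch = img[sy, sx] - depth * prof
                    n_clipped += int((patch < 0).sum())
                    img[sy, sx] = np.maximum(patch, 0.0)
        if noise.relative_sd > 0:
            img = img + noise_rng.standard_normal((h, w)) * (noise.relative_sd * img)
        frames[t] = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    if n_clipped:
        logger.info("render_video: %d blob pixels clipped at 0 greyscales", n_clipped)
    return frames


def simulate_scene(cfg: SceneConfig) -> tuple[np.ndarray, SceneTruth]:
    """Convenience wrapper: simulate flights and render the frame stack."""
    truth = simulate_flights(cfg.flight, cfg.geometry, cfg.n_frames)
    frames = render_video(
        truth, cfg.illumination, cfg.geometry, cfg.contrast, cfg.noise,
        n_frames=cfg.n_frames,
    )
    return frames, truth
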