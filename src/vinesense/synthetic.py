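"""Synthetic vineyards with known ground truth.

Every downstream stage (ground filtering, DVM, calibration, indices,
signatures, correlation) is testable without field data by simulating the
surveyed system: a sloped vineyard block with parallel vine rows, per-plant
canopy heights tied to vigour classes via the trellis wires, root-pest
infestation spreading preferentially along rows, distinct
healthy/infested/soil reflectance endmembers on a 274-band VNIR grid,
panel-granularity expert scores, and soil-conductivity (EM38) readings drawn
independently of everything else.

Spectral structure of the default endmembers: green reflectance peak near
550 nm, chlorophyll absorption well near 670 nm, red edge between 690 and
740 nm, NIR plateau.  Infested vines show higher visible reflectance, a
shallower chlorophyll well and a lower NIR plateau than healthy vines; the
soil background rises monotonically across the VNIR.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator

from .containers import (
    CANOPY,
    GROUND,
    ElevationGrid,
    GeoTransform,
    PlantRecord,
    PointCloud,
    SpectralCube,
    SpectralSignature,
)
from .errors import ValidationError
from .vigour import VigourThresholds, assign_vigour_class

__all__ = [
    "VineyardConfig",
    "GroundTruth",
    "default_wavelength_grid",
    "healthy_endmember",
    "infested_endmember",
    "soil_spectrum",
    "default_illumination",
    "generate_terrain",
    "generate_layout",
    "generate_point_cloud",
    "generate_reflectance_cube",
    "generate_radiance_scene",
    "generate_expert_vigour",
    "generate_em38",
    "expected_vigour_height_correlation",
    "generate_vineyard",
]

log = logging.getLogger(__name__)

# Sub-stream tags so each generator is independently reproducible from one seed.
_STREAMS = {
    "terrain": 11,
    "layout": 23,
    "points": 37,
    "cube": 41,
    "radiance": 53,
    "expert": 67,
    "em38": 79,
}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), _STREAMS[stream]])


def default_wavelength_grid(n_bands: int = 274) -> np.ndarray:
    """274 bands spanning 400-1000 nm (~2.2 nm sampling interval)."""
    return np.linspace(400.0, 1000.0, n_bands)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _gauss(w, centre, width):
    return np.exp(-0.5 * ((w - centre) / width) ** 2)


def _vegetation_curve(w, *, vis_base, green_peak, well_depth, nir_plateau):
    """Smooth leaf-like reflectance: green peak, 670 nm well, red edge, NIR."""
    vis = vis_base + green_peak * _gauss(w, 550.0, 40.0) - well_depth * _gauss(w, 670.0, 28.0)
    edge = _sigmoid((w - 715.0) / 12.0)
    return vis * (1.0 - edge) + nir_plateau * edge


def healthy_endmember(wavelengths=None) -> SpectralSignature:
    """Healthy vine canopy: deep chlorophyll well, high NIR plateau."""
    w = default_wavelength_grid() if wavelengths is None else np.asarray(wavelengths)
    mean = _vegetation_curve(w, vis_base=0.055, green_peak=0.07, well_depth=0.035,
                             nir_plateau=0.50)
    return SpectralSignature(w, mean, np.zeros_like(w), 1, "healthy")


def infested_endmember(wavelengths=None) -> SpectralSignature:
    """Infested canopy: brighter visible, shallower well, depressed NIR."""
    w = default_wavelength_grid() if wavelengths is None else np.asarray(wavelengths)
    mean = _vegetation_curve(w, vis_base=0.10, green_peak=0.06, well_depth=0.012,
                             nir_plateau=0.38)
    return SpectralSignature(w, mean, np.zeros_like(w), 1, "infested")


def soil_spectrum(wavelengths=None) -> SpectralSignature:
    """Inter-row bare soil: monotonically rising across the VNIR."""
    w = default_wavelength_grid() if wavelengths is None else np.asarray(wavelengths)
    mean = 0.08 + 0.25 * (w - w.min()) / (w.max() - w.min())
    return SpectralSignature(w, mean, np.zeros_like(w), 1, "soil")


def default_illumination(wavelengths=None, peak: float = 1000.0) -> np.ndarray:
    """Per-band downwelling radiance scale (sensor units), smooth and positive."""
    w = default_wavelength_grid() if wavelengths is None else np.asarray(wavelengths)
    return peak * (0.55 + 0.45 * _gauss(w, 560.0, 220.0))


@dataclass
class VineyardConfig:
    """All knobs of the simulated block; defaults emulate the surveyed system.

    Rows run east-west (along x); vines are ``vine_spacing`` apart within a
    row and rows ``row_spacing`` apart.  Panels group ``panel_size`` adjacent
    vines — the granularity of expert scoring.  Per-class canopy heights are
    anchored to the trellis wires at 1.2/1.55/1.75 m; class 1 means a dead
    plant with no canopy.
    """

    seed: int = 0
    n_rows: int = 6
    vines_per_row: int = 30
    row_spacing: float = 3.0
    vine_spacing: float = 1.5
    panel_size: int = 5
    terrain_relief: float = 5.0
    terrain_slope: float = 1.0  # relative weight of the planar trend
    undulation_fraction: float = 0.2  # share of the relief in the undulation
    terrain_cell: float = 0.25
    margin: float = 2.0
    canopy_height_by_class: dict = field(
        default_factory=lambda: {2: 0.9, 3: 1.4, 4: 1.65, 5: 1.9}
    )
    height_jitter: float = 0.06
    infestation_rate: float = 0.15
    n_foci: int = 2
    along_row_spread_prob: float = 0.5
    between_row_spread_prob: float = 0.1
    canopy_width: float = 0.6
    canopy_length: float = 1.2
    ground_point_density: float = 60.0  # points per m^2
    canopy_point_density: float = 250.0
    canopy_top_fraction: float = 0.4
    canopy_base_fraction: float = 0.75  # crown bottom as a fraction of height
    point_noise_sd: float = 0.02  # m, vertical
    cube_cell: float = 0.15
    n_bands: int = 274
    noise_sd: float = 0.01  # reflectance units
    illumination_peak: float = 1000.0
    white_patch_noise_sd: float = 0.0
    em38_mean: float = 50.0  # mS/m
    em38_sd: float = 10.0
    healthy_fracs: tuple = (0.35, 0.65)  # P(class 4), P(class 5) for healthy vines
    infested_fracs: tuple = (0.5, 0.5)  # P(class 2), P(class 3) for infested vines
    thresholds: VigourThresholds = field(default_factory=VigourThresholds)

    def __post_init__(self) -> None:
        for p in (self.infestation_rate, self.along_row_spread_prob,
                  self.between_row_spread_prob):
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"probability {p} outside [0, 1]")
        heights = [self.canopy_height_by_class[c]
                   for c in sorted(self.canopy_height_by_class)]
        if any(h <= 0 for h in heights) or any(
            b <= a for a, b in zip(heights, heights[1:])
        ):
            raise ValidationError("canopy heights must be positive and increase with class")
        if not 0 <= self.terrain_relief <= 24.0 + 1e-9:
            raise ValidationError("terrain_relief outside the 0-24 m scenario range")

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(x_min, x_max, y_min, y_max) of the block including margins."""
        return (
            -self.margin,
            (self.vines_per_row - 1) * self.vine_spacing + self.margin,
            -self.margin,
            (self.n_rows - 1) * self.row_spacing + self.margin,
        )

    @property
    def wavelengths(self) -> np.ndarray:
        return default_wavelength_grid(self.n_bands)


@dataclass
class GroundTruth:
    """Everything the generators know that the pipeline must recover."""

    plants: list
    height: np.ndarray  # true canopy height per plant, m (0 for dead)
    vigour_class: np.ndarray  # Table-style class 1-5 from the wire rule
    infested: np.ndarray  # bool per plant
    point_labels: np.ndarray | None = None
    dtm: ElevationGrid | None = None
    wavelengths: np.ndarray | None = None


# ---------------------------------------------------------------------------
# terrain


def _terrain_field(config: VineyardConfig, x, y):
    """Unscaled smooth elevation: planar trend + low-frequency undulation.

    The planar trend carries most of the relief (hillside geometry); the
    undulation share is ``undulation_fraction`` of the range, keeping local
    slopes realistic even when the full relief is compressed into one block.
    """
    x0, x1, y0, y1 = config.extent
    lx, ly = max(x1 - x0, 1e-9), max(y1 - y0, 1e-9)
    u = (np.asarray(x) - x0) / lx
    v = (np.asarray(y) - y0) / ly
    plane = config.terrain_slope * (0.8 * u + 0.6 * v) / 1.4
    und = (
        0.5 * np.sin(2.3 * np.pi * u + 0.7)
        + 0.4 * np.cos(1.7 * np.pi * v - 0.4)
        + 0.2 * np.sin(3.1 * np.pi * (u + v))
    ) / 2.2
    f = config.undulation_fraction
    return (1.0 - f) * plane + f * und


def generate_terrain(config: VineyardConfig) -> ElevationGrid:
    """Smooth terrain whose elevation range equals ``terrain_relief``.

    The raw field (plane + sinusoidal undulation) is rescaled so that
    max − min matches the configured relief exactly; relief 0 gives a flat
    grid.  Deterministic in the config alone.
    """
    x0, x1, y0, y1 = config.extent
    cell = config.terrain_cell
    xs = np.arange(x0, x1 + cell, cell)
    ys = np.arange(y1, y0 - cell, -cell)
    raw = _terrain_field(config, xs[None, :], ys[:, None])
    span = raw.max() - raw.min()
    if config.terrain_relief == 0 or span == 0:
        values = np.zeros_like(raw)
    else:
        values = (raw - raw.min()) * (config.terrain_relief / span)
    return ElevationGrid(values, GeoTransform(x0, y1, cell), role="DTM")


def _terrain_sampler(terrain: ElevationGrid):
    t = terrain.transform
    nrows, ncols = terrain.shape
    xs = t.origin_x + (np.arange(ncols) + 0.5) * t.cell
    ys = t.origin_y - (np.arange(nrows) + 0.5) * t.cell  # decreasing
    interp = RegularGridInterpolator(
        (ys[::-1], xs), terrain.values[::-1, :], bounds_error=False, fill_value=None
    )

    def sample(x, y):
        return interp(np.column_stack([np.ravel(y), np.ravel(x)])).reshape(np.shape(x))

    return sample


# ---------------------------------------------------------------------------
# plant layout, infestation, classes, heights


def _spread_infestation(config: VineyardConfig, rng) -> np.ndarray:
    """Seeded-focus contagion on the row lattice.

    ``n_foci`` initial infested vines; each spreading round infects along-row
    neighbours with ``along_row_spread_prob`` and the facing vines in
    adjacent rows with ``between_row_spread_prob``, until the target
    ``infestation_rate`` is reached (or the block saturates).
    """
    n_rows, n_vines = config.n_rows, config.vines_per_row
    n = n_rows * n_vines
    infested = np.zeros((n_rows, n_vines), dtype=bool)
    if config.infestation_rate <= 0 or n == 0:
        return infested.ravel()
    target = max(1, int(round(config.infestation_rate * n)))
    foci = rng.choice(n, size=min(config.n_foci, n), replace=False)
    infested.ravel()[foci] = True
    for _ in range(10 * (n_rows + n_vines)):
        if infested.sum() >= target:
            break
        current = np.argwhere(infested)
        new = np.zeros_like(infested)
        for r, c in current:
            for dc in (-1, 1):  # along the row
                if 0 <= c + dc < n_vines and rng.random() < config.along_row_spread_prob:
                    new[r, c + dc] = True
            for dr in (-1, 1):  # facing vine in the adjacent row
                if 0 <= r + dr < n_rows and rng.random() < config.between_row_spread_prob:
                    new[r + dr, c] = True
        if not new.any():
            continue
        infested |= new
    return infested.ravel()


def generate_layout(config: VineyardConfig) -> GroundTruth:
    """Trunk grid, infestation pattern, true heights and vigour classes.

    Healthy vines draw classes 4-5, infested vines 2-3 (per
    ``healthy_fracs``/``infested_fracs``); true height is the class's anchor
    height ± ``height_jitter``, which keeps it inside the class's wire band
    so the class always equals the wire rule applied to the height.
    """
    rng = _rng(config.seed, "layout")
    infested = _spread_infestation(config, rng)
    n = config.n_rows * config.vines_per_row

    classes = np.empty(n, dtype=int)
    healthy_p = np.asarray(config.healthy_fracs) / np.sum(config.healthy_fracs)
    infested_p = np.asarray(config.infested_fracs) / np.sum(config.infested_fracs)
    for i in range(n):
        if infested[i]:
            classes[i] = rng.choice([2, 3], p=infested_p)
        else:
            classes[i] = rng.choice([4, 5], p=healthy_p)

    anchors = np.array([config.canopy_height_by_class.get(c, 0.0) for c in classes])
    heights = np.where(
        classes > 1,
        anchors + rng.uniform(-config.height_jitter, config.height_jitter, size=n),
        0.0,
    )
    rule_classes = assign_vigour_class(heights, config.thresholds)
    if not np.array_equal(rule_classes[classes > 1], classes[classes > 1]):
        raise ValidationError(
            "height jitter pushed a plant across a wire boundary; "
            "reduce height_jitter or move the class anchors"
        )

    plants = []
    k = 0
    for r in range(config.n_rows):
        for c in range(config.vines_per_row):
            plants.append(
                PlantRecord(
                    tree_number=k + 1,
                    x=c * config.vine_spacing,
                    y=r * config.row_spacing,
                    block=1,
                    row=r + 1,
                    panel=c // config.panel_size + 1,
                    variety="Chardonnay",
                )
            )
            k += 1
    return GroundTruth(
        plants=plants,
        height=heights,
        vigour_class=rule_classes,
        infested=infested,
        wavelengths=config.wavelengths,
    )


# ---------------------------------------------------------------------------
# point cloud


def generate_point_cloud(config: VineyardConfig,
                         terrain: ElevationGrid,
                         truth: GroundTruth | None = None
                         ) -> tuple[PointCloud, GroundTruth]:
    """Unlabelled photogrammetric-style cloud plus its true labels.

    Ground points are uniform over the block on the terrain surface ± noise,
    omitted beneath living canopies (occlusion).  Each living vine gets a
    slab of canopy points over its footprint: a ``canopy_top_fraction`` share
    on the crown top at the true height ± noise, the rest filling the
    photogrammetrically visible crown between ``canopy_base_fraction`` of
    the height and the top (image matching rarely reconstructs the shaded
    canopy interior or the trunk).
    """
    truth = truth if truth is not None else generate_layout(config)
    rng = _rng(config.seed, "points")
    sample_z = _terrain_sampler(terrain)
    x0, x1, y0, y1 = config.extent
    area = (x1 - x0) * (y1 - y0)

    n_ground = int(round(config.ground_point_density * area))
    gx = rng.uniform(x0, x1, n_ground)
    gy = rng.uniform(y0, y1, n_ground)

    # occlusion: no ground returns under a living canopy footprint
    live = [(p.x, p.y) for p, h in zip(truth.plants, truth.height) if h > 0]
    shadow = np.zeros(n_ground, dtype=bool)
    hl, hw = config.canopy_length / 2, config.canopy_width / 2
    for px, py in live:
        shadow |= (np.abs(gx - px) < hl) & (np.abs(gy - py) < hw)
    gx, gy = gx[~shadow], gy[~shadow]
    gz = sample_z(gx, gy) + rng.normal(0.0, config.point_noise_sd, gx.size)
    parts = [np.column_stack([gx, gy, gz])]
    labels = [np.full(gx.size, GROUND, dtype=np.uint8)]

    footprint_area = config.canopy_length * config.canopy_width
    n_canopy = max(4, int(round(config.canopy_point_density * footprint_area)))
    for plant, height in zip(truth.plants, truth.height):
        if height <= 0:
            continue
        cx = rng.uniform(plant.x - hl, plant.x + hl, n_canopy)
        cy = rng.uniform(plant.y - hw, plant.y + hw, n_canopy)
        base = sample_z(cx, cy)
        n_top = int(round(config.canopy_top_fraction * n_canopy))
        cz = np.empty(n_canopy)
        cz[:n_top] = base[:n_top] + height + rng.normal(
            0.0, config.point_noise_sd, n_top
        )
        cz[n_top:] = base[n_top:] + rng.uniform(
            config.canopy_base_fraction * height, height, n_canopy - n_top
        )
        parts.append(np.column_stack([cx, cy, cz]))
        labels.append(np.full(n_canopy, CANOPY, dtype=np.uint8))

    xyz = np.concatenate(parts) if parts else np.empty((0, 3))
    true_labels = np.concatenate(labels) if labels else np.empty(0, dtype=np.uint8)
    truth = replace(truth, point_labels=true_labels, dtm=terrain)
    return PointCloud(xyz), truth


# ---------------------------------------------------------------------------
# reflectance / radiance imagery


def generate_reflectance_cube(config: VineyardConfig,
                              truth: GroundTruth | None = None
                              ) -> tuple[SpectralCube, GroundTruth]:
    """Reflectance cube: canopy pixels from each plant's endmember + noise,
    inter-row pixels from the soil spectrum + noise."""
    truth = truth if truth is not None else generate_layout(config)
    rng = _rng(config.seed, "cube")
    w = config.wavelengths
    healthy = healthy_endmember(w).mean
    infested = infested_endmember(w).mean
    soil = soil_spectrum(w).mean
    for sig_name, sig in (("healthy", healthy), ("infested", infested)):
        if sig.shape != w.shape:
            raise ValidationError(f"{sig_name} endmember grid mismatch")

    x0, x1, y0, y1 = config.extent
    cell = config.cube_cell
    transform = GeoTransform(x0, y1, cell)
    ncols = int(np.ceil((x1 - x0) / cell))
    nrows = int(np.ceil((y1 - y0) / cell))
    cx, cy = transform.center_grids((nrows, ncols))

    values = np.tile(soil, (nrows, ncols, 1))
    hl, hw = config.canopy_length / 2, config.canopy_width / 2
    for plant, height, inf in zip(truth.plants, truth.height, truth.infested):
        if height <= 0:
            continue
        mask = (np.abs(cx - plant.x) <= hl) & (np.abs(cy - plant.y) <= hw)
        values[mask] = infested if inf else healthy
    if config.noise_sd > 0:
        values = values + rng.normal(0.0, config.noise_sd, values.shape)
        np.clip(values, 0.0, None, out=values)

    cube = SpectralCube(values, w, transform, kind="reflectance")
    return cube, replace(truth, wavelengths=w)


def generate_radiance_scene(cube: SpectralCube, config: VineyardConfig,
                            illumination: np.ndarray | None = None
                            ) -> tuple[SpectralCube, np.ndarray]:
    """At-sensor radiance plus a white-reference patch.

    Radiance is reflectance × per-band illumination; the returned white
    patch is the illumination spectrum under the same model (± configured
    noise), so calibration against its mean inverts the scene exactly in the
    noiseless case.
    """
    rng = _rng(config.seed, "radiance")
    illum = (default_illumination(cube.wavelengths, config.illumination_peak)
             if illumination is None else np.asarray(illumination, dtype=float))
    if illum.shape != cube.wavelengths.shape:
        raise ValidationError("illumination grid mismatch")
    radiance = cube.copy_with(values=cube.values * illum, kind="radiance")
    patch = np.tile(illum, (8, 8, 1))
    if config.white_patch_noise_sd > 0:
        patch = patch * (1.0 + rng.normal(0.0, config.white_patch_noise_sd, patch.shape))
    return radiance, patch


# ---------------------------------------------------------------------------
# ground observations


def _panel_modal_class(classes: np.ndarray) -> int:
    """Modal class of a panel's plants; ties break toward the lower class."""
    vals, counts = np.unique(classes, return_counts=True)
    return int(vals[np.argmax(counts)])


def generate_expert_vigour(truth: GroundTruth, config: VineyardConfig,
                           error_rate: float = 0.1) -> pd.DataFrame:
    """Panel-granularity expert score table (block, row, panel, vigour).

    Each panel receives the modal true class of its plants, perturbed by one
    class with probability ``error_rate``.  At the class range limits the
    perturbation direction points inward, so a perturbed panel never retains
    its modal class.
    """
    rng = _rng(config.seed, "expert")
    frame = pd.DataFrame(
        {
            "row": [p.row for p in truth.plants],
            "panel": [p.panel for p in truth.plants],
            "true_class": truth.vigour_class,
        }
    )
    records = []
    for (row, panel), grp in frame.groupby(["row", "panel"], sort=True):
        cls = _panel_modal_class(grp["true_class"].to_numpy())
        if rng.random() < error_rate:
            if cls <= 1:
                cls += 1
            elif cls >= 5:
                cls -= 1
            else:
                cls += int(rng.choice([-1, 1]))
        records.append({"block": 1, "row": row, "panel": panel, "vigour": cls})
    return pd.DataFrame(records)


def generate_em38(plants, config: VineyardConfig) -> np.ndarray:
    """Per-plant soil conductivity, drawn independently of every truth field."""
    rng = _rng(config.seed, "em38")
    return rng.normal(config.em38_mean, config.em38_sd, len(plants))


def expected_vigour_height_correlation(config: VineyardConfig,
                                       error_rate: float = 0.1,
                                       n_reps: int = 200) -> tuple[float, float]:
    """Monte-Carlo expectation and SD of Pearson(expert class, true height).

    Replays only the stochastic class/height/expert chain (no rasters) over
    ``n_reps`` independent seeds at the configured block size, giving the
    sampling distribution against which a pipeline-measured correlation can
    be judged.
    """
    rs = []
    for rep in range(n_reps):
        cfg = replace(config, seed=(config.seed + 1009 * (rep + 1)) % 2**31)
        truth = generate_layout(cfg)
        expert_tbl = generate_expert_vigour(truth, cfg, error_rate)
        key = {(r, p): v for r, p, v in
               zip(expert_tbl["row"], expert_tbl["panel"], expert_tbl["vigour"])}
        expert = np.array([key[(p.row, p.panel)] for p in truth.plants], dtype=float)
        h = truth.height
        if np.std(expert) == 0 or np.std(h) == 0:
            continue
        rs.append(np.corrcoef(expert, h)[0, 1])
    rs = np.asarray(rs)
    return float(rs.mean()), float(rs.std(ddof=1))


# ---------------------------------------------------------------------------
# one-call fixture


def generate_vineyard(config: VineyardConfig) -> dict:
    """Full fixture set for a pipeline run; deterministic in ``config.seed``."""
    terrain = generate_terrain(config)
    truth = generate_layout(config)
    cloud, truth = generate_point_cloud(config, terrain, truth)
    cube, truth = generate_reflectance_cube(config, truth)
    radiance, white_patch = generate_radiance_scene(cube, config)
    expert = generate_expert_vigour(truth, config)
    em38 = generate_em38(truth.plants, config)
    return {
        "config": config,
        "terrain": terrain,
        "truth": truth,
        "cloud": cloud,
        "reflectance": cube,
        "radiance": radiance,
        "white_patch": white_patch,
        "expert": expert,
        "em38": em38,
    }
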