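"""Ground-truth-annotated synthetic data for the cohesion assay.

Two generators live here:

* :func:`simulate_image_set` renders multi-channel confocal-like fields of
  blood-derived cells — round DAPI nuclei (lymphocyte-like, mean nuclear
  diameter below 10 μm, optionally mixed with larger monocyte-like nuclei),
  a mitotic subpopulation rendered as small condensed high-intensity blobs,
  and per cell one or two diffraction-limited centrosomal dots whose pair
  distance follows a truncated normal (truncated at 0 by resampling). Dots are
  isotropic Gaussians (PSF σ default 0.15 μm); noise is Poisson shot noise
  plus additive Gaussian read noise. In dual-marker mode a γ-tubulin channel
  carries dots co-located with the pericentrin dots, plus optional
  single-marker decoys to exercise colocalization gating.

* :func:`simulate_cohort_scores` draws per-subject percent-splitting tables
  for the six study groups (control, R1441G-PD, R1441G-NMC, G2019S-PD,
  G2019S-NMC, iPD) under vehicle and MLi2 conditions, with binomial
  resampling at a finite cells-per-sample count so sampling error matches an
  n-cell assay.

Identical config + seed yields bit-identical output.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import scipy.ndimage as ndi

from .errors import ConfigurationError
from .imaging import DAPI, GTUB, PCNT, ImageStack, write_stack

GROUPS = ("control", "R1441G_PD", "R1441G_NMC",
          "G2019S_PD", "G2019S_NMC", "iPD")
CONDITIONS = ("vehicle", "MLi2")


# ---------------------------------------------------------------------------
# image simulation
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class CellClassParams:
    """Nuclear diameter distribution of one blood-cell class."""

    name: str
    diameter_mean_um: float
    diameter_sd_um: float


LYMPHOCYTE = CellClassParams("lymphocyte", 8.0, 0.8)
MONOCYTE = CellClassParams("monocyte", 12.0, 1.2)


@dataclasses.dataclass
class ImageSimConfig:
    """Rendering and population parameters for synthetic fields."""

    pixel_size_um: float = 0.1
    field_shape_px: tuple[int, int] = (1040, 1040)
    n_z: int = 3
    z_step_um: float = 0.5
    n_cells: int = 100
    two_dot_fraction: float = 0.6
    distance_mean_um: float = 1.2
    distance_sd_um: float = 0.15
    mitotic_fraction: float = 0.03
    cell_class_mix: tuple[float, float] = (1.0, 0.0)  # (lymphocyte, monocyte)
    dual_marker: bool = False
    decoy_rate: float = 0.1  # decoy single-marker dots per cell per channel
    psf_sigma_um: float = 0.15
    dot_intensity: float = 3000.0
    nuclear_intensity: float = 800.0
    mitotic_intensity_factor: float = 4.0
    background_level: float = 100.0
    noise_sd: float = 10.0
    shot_noise: bool = True
    split_threshold_um: float = 1.3
    min_spacing_factor: float = 2.0  # × max nuclear diameter
    seed: int = 0

    def validate(self) -> None:
        if self.pixel_size_um <= 0:
            raise ConfigurationError("pixel_size_um must be > 0")
        if any(s <= 0 for s in self.field_shape_px) or self.n_z < 1:
            raise ConfigurationError("field dimensions must be positive")
        if self.n_cells < 0:
            raise ConfigurationError("n_cells must be >= 0")
        for name in ("two_dot_fraction", "mitotic_fraction", "decoy_rate"):
            v = getattr(self, name)
            if not 0 <= v <= (1 if name != "decoy_rate" else 10):
                raise ConfigurationError(f"{name}={v} out of range")
        if self.distance_mean_um < 0 or self.distance_sd_um < 0:
            raise ConfigurationError("distance parameters must be >= 0")
        mix = np.asarray(self.cell_class_mix, dtype=float)
        if mix.min() < 0 or not math.isclose(mix.sum(), 1.0, rel_tol=1e-9):
            raise ConfigurationError("cell_class_mix must be >= 0 and sum to 1")

    @property
    def classes(self) -> tuple[CellClassParams, CellClassParams]:
        return (LYMPHOCYTE, MONOCYTE)

    @property
    def max_nuclear_diameter_um(self) -> float:
        active = [c for c, w in zip(self.classes, self.cell_class_mix) if w > 0]
        return max(c.diameter_mean_um + 3 * c.diameter_sd_um for c in active)

    @property
    def min_spacing_um(self) -> float:
        return self.min_spacing_factor * self.max_nuclear_diameter_um


@dataclasses.dataclass
class GroundTruth:
    """Per-cell ground truth emitted alongside synthetic fields.

    ``cells`` has one row per cell: field, cell_id, cell_class, nucleus center
    (x_um, y_um), diameter_um, mitotic, n_dots, dot coordinates
    (d1x_um..d2y_um; NaN where absent), distance_um and the split label at
    ``threshold_um``. ``decoys`` lists single-marker decoy dots (dual-marker
    mode only).
    """

    cells: pd.DataFrame
    decoys: pd.DataFrame
    threshold_um: float
    config: ImageSimConfig

    def split_labels(self, threshold_um: Optional[float] = None) -> pd.Series:
        """Re-threshold true pair distances (two-dot cells only)."""
        thr = self.threshold_um if threshold_um is None else threshold_um
        return (self.cells["distance_um"] > thr) & (self.cells["n_dots"] == 2)


def draw_pair_distances(n: int, mean_um: float, sd_um: float,
                        rng: np.random.Generator) -> np.ndarray:
    """Truncated-normal (at 0) pair distances, truncation by resampling."""
    if sd_um == 0:
        return np.full(n, float(mean_um))
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.normal(mean_um, sd_um, size=max(n - filled, 16))
        good = draw[draw > 0]
        take = min(len(good), n - filled)
        out[filled:filled + take] = good[:take]
        filled += take
    return out


def _grid_positions(config: ImageSimConfig, rng: np.random.Generator,
                    n: int) -> tuple[np.ndarray, int]:
    """Jittered-grid centers (μm) guaranteeing the minimum spacing.

    Returns positions for min(n, capacity) cells and the per-field capacity.
    """
    h_um = config.field_shape_px[0] * config.pixel_size_um
    w_um = config.field_shape_px[1] * config.pixel_size_um
    jitter = 0.2 * config.min_spacing_um
    pitch = config.min_spacing_um + jitter
    margin = 0.7 * config.max_nuclear_diameter_um
    nx = int((w_um - 2 * margin - jitter) // pitch) + 1
    ny = int((h_um - 2 * margin - jitter) // pitch) + 1
    if nx < 1 or ny < 1:
        raise ConfigurationError(
            "field too small for one cell at the configured spacing")
    capacity = nx * ny
    k = min(n, capacity)
    sites = [(ix, iy) for iy in range(ny) for ix in range(nx)][:k]
    pos = np.array([
        (margin + ix * pitch + rng.uniform(0, jitter),
         margin + iy * pitch + rng.uniform(0, jitter))
        for ix, iy in sites
    ]).reshape(-1, 2)
    return pos, capacity


def _add_gaussian_dot(img: np.ndarray, x_um: float, y_um: float,
                      amplitude: float, sigma_px: float,
                      pixel_size_um: float) -> None:
    """Accumulate an isotropic Gaussian sampled at pixel centers."""
    cx = x_um / pixel_size_um
    cy = y_um / pixel_size_um
    r = int(math.ceil(5 * sigma_px))
    r0, r1 = max(int(cy) - r, 0), min(int(cy) + r + 1, img.shape[0])
    c0, c1 = max(int(cx) - r, 0), min(int(cx) + r + 1, img.shape[1])
    if r0 >= r1 or c0 >= c1:
        return
    ys = np.arange(r0, r1, dtype=float)[:, None]
    xs = np.arange(c0, c1, dtype=float)[None, :]
    img[r0:r1, c0:c1] += amplitude * np.exp(
        -((xs - cx) ** 2 + (ys - cy) ** 2) / (2 * sigma_px ** 2))


def _render_nucleus(img: np.ndarray, x_um: float, y_um: float,
                    diameter_um: float, intensity: float, mitotic: bool,
                    mitotic_factor: float, angle: float, axis_ratio: float,
                    pixel_size_um: float) -> None:
    """Filled ellipse (interphase) or condensed small blob pair (mitotic)."""
    px = pixel_size_um
    if mitotic:
        # condensed chromatin: two bright overlapping small disks
        r_um = 0.22 * diameter_um
        off = 0.12 * diameter_um
        for sign in (-1, 1):
            _render_disk(img, x_um + sign * off * math.cos(angle),
                         y_um + sign * off * math.sin(angle),
                         r_um, intensity * mitotic_factor, px)
        return
    # equivalent diameter preserved: sqrt(a*b) = diameter/2
    a = (diameter_um / 2) / math.sqrt(axis_ratio)
    b = (diameter_um / 2) * math.sqrt(axis_ratio)
    cx, cy = x_um / px, y_um / px
    r = int(math.ceil(max(a, b) / px)) + 2
    r0, r1 = max(int(cy) - r, 0), min(int(cy) + r + 1, img.shape[0])
    c0, c1 = max(int(cx) - r, 0), min(int(cx) + r + 1, img.shape[1])
    ys = (np.arange(r0, r1, dtype=float)[:, None] - cy) * px
    xs = (np.arange(c0, c1, dtype=float)[None, :] - cx) * px
    u = xs * math.cos(angle) + ys * math.sin(angle)
    v = -xs * math.sin(angle) + ys * math.cos(angle)
    inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    img[r0:r1, c0:c1][inside] += intensity


def _render_disk(img: np.ndarray, x_um: float, y_um: float, r_um: float,
                 intensity: float, pixel_size_um: float) -> None:
    px = pixel_size_um
    cx, cy = x_um / px, y_um / px
    r = int(math.ceil(r_um / px)) + 2
    r0, r1 = max(int(cy) - r, 0), min(int(cy) + r + 1, img.shape[0])
    c0, c1 = max(int(cx) - r, 0), min(int(cx) + r + 1, img.shape[1])
    ys = (np.arange(r0, r1, dtype=float)[:, None] - cy) * px
    xs = (np.arange(c0, c1, dtype=float)[None, :] - cx) * px
    inside = xs ** 2 + ys ** 2 <= r_um ** 2
    img[r0:r1, c0:c1][inside] += intensity


def simulate_ground_truth(config: ImageSimConfig,
                          rng: Optional[np.random.Generator] = None
                          ) -> GroundTruth:
    """Draw the cell population (positions, classes, dots) without rendering.

    The same sampler backs :func:`simulate_image_set`, so distributional
    tests can run on large populations without paying rendering cost.
    """
    config.validate()
    rng = rng if rng is not None else np.random.default_rng(config.seed)

    rows = []
    decoy_rows = []
    remaining = config.n_cells
    field = 0
    while remaining > 0:
        pos, _cap = _grid_positions(config, rng, remaining)
        for cx, cy in pos:
            cell_id = config.n_cells - remaining
            cls_idx = int(rng.random() >= config.cell_class_mix[0])
            cls = config.classes[cls_idx]
            diameter = float(np.clip(
                rng.normal(cls.diameter_mean_um, cls.diameter_sd_um),
                cls.diameter_mean_um - 3 * cls.diameter_sd_um,
                cls.diameter_mean_um + 3 * cls.diameter_sd_um))
            mitotic = bool(rng.random() < config.mitotic_fraction)
            two_dots = bool(rng.random() < config.two_dot_fraction)
            # dot pair centered near the nuclear centroid
            ox, oy = rng.normal(0, 0.1 * diameter, size=2)
            if two_dots:
                dist = float(draw_pair_distances(
                    1, config.distance_mean_um, config.distance_sd_um, rng)[0])
                theta = rng.uniform(0, 2 * math.pi)
                dx, dy = (dist / 2 * math.cos(theta), dist / 2 * math.sin(theta))
                dots = [(cx + ox - dx, cy + oy - dy), (cx + ox + dx, cy + oy + dy)]
            else:
                dist = math.nan
                dots = [(cx + ox, cy + oy)]
            if config.dual_marker:
                for channel in (PCNT, GTUB):
                    n_decoy = rng.poisson(config.decoy_rate)
                    for _ in range(n_decoy):
                        ang = rng.uniform(0, 2 * math.pi)
                        rad = rng.uniform(1.2, 2.5)
                        decoy_rows.append({
                            "field": field, "cell_id": cell_id,
                            "channel": channel,
                            "x_um": cx + rad * math.cos(ang),
                            "y_um": cy + rad * math.sin(ang),
                        })
            rows.append({
                "field": field, "cell_id": cell_id, "cell_class": cls.name,
                "x_um": float(cx), "y_um": float(cy),
                "diameter_um": diameter, "mitotic": mitotic,
                "n_dots": 2 if two_dots else 1,
                "d1x_um": dots[0][0], "d1y_um": dots[0][1],
                "d2x_um": dots[1][0] if two_dots else math.nan,
                "d2y_um": dots[1][1] if two_dots else math.nan,
                "distance_um": dist,
            })
            remaining -= 1
        field += 1

    columns = ["field", "cell_id", "cell_class", "x_um", "y_um",
               "diameter_um", "mitotic", "n_dots", "d1x_um", "d1y_um",
               "d2x_um", "d2y_um", "distance_um"]
    cells = pd.DataFrame(rows, columns=columns)
    cells["split"] = (cells["distance_um"] > config.split_threshold_um
                      ).fillna(False) & (cells["n_dots"] == 2)
    decoys = pd.DataFrame(
        decoy_rows, columns=["field", "cell_id", "channel", "x_um", "y_um"])
    return GroundTruth(cells=cells, decoys=decoys,
                       threshold_um=config.split_threshold_um, config=config)


def _render_field(config: ImageSimConfig, cells: pd.DataFrame,
                  decoys: pd.DataFrame, rng: np.random.Generator
                  ) -> ImageStack:
    h, w = config.field_shape_px
    px = config.pixel_size_um
    sigma_px = config.psf_sigma_um / px

    dapi = np.zeros((h, w), dtype=float)
    pcnt = np.zeros((h, w), dtype=float)
    gtub = np.zeros((h, w), dtype=float) if config.dual_marker else None

    for row in cells.itertuples():
        angle = rng.uniform(0, math.pi)
        axis_ratio = rng.uniform(0.85, 1.0)
        _render_nucleus(dapi, row.x_um, row.y_um, row.diameter_um,
                        config.nuclear_intensity, bool(row.mitotic),
                        config.mitotic_intensity_factor, angle, axis_ratio, px)
        dots = [(row.d1x_um, row.d1y_um)]
        if row.n_dots == 2:
            dots.append((row.d2x_um, row.d2y_um))
        for dx, dy in dots:
            _add_gaussian_dot(pcnt, dx, dy, config.dot_intensity, sigma_px, px)
            if gtub is not None:
                jx, jy = rng.normal(0, 0.02, size=2)  # marker jitter, μm
                _add_gaussian_dot(gtub, dx + jx, dy + jy,
                                  config.dot_intensity, sigma_px, px)
    if gtub is not None:
        for d in decoys.itertuples():
            target = pcnt if d.channel == PCNT else gtub
            _add_gaussian_dot(target, d.x_um, d.y_um,
                              config.dot_intensity, sigma_px, px)

    # PSF blur for the nuclear stain (dots are rendered as the PSF already)
    dapi = ndi.gaussian_filter(dapi, sigma_px)

    channels: dict[str, np.ndarray] = {}
    planes = {DAPI: dapi, PCNT: pcnt}
    if gtub is not None:
        planes[GTUB] = gtub
    for name, clean in planes.items():
        signal = clean + config.background_level
        stack = np.empty((config.n_z, h, w), dtype=np.float32)
        for z in range(config.n_z):
            plane = rng.poisson(signal).astype(np.float64) \
                if config.shot_noise else signal.copy()
            if config.noise_sd > 0:
                plane = plane + rng.normal(0, config.noise_sd, size=(h, w))
            stack[z] = np.clip(plane, 0, None)
        channels[name] = stack
    return ImageStack(channels=channels, pixel_size_um=px,
                      z_step_um=config.z_step_um, source=None)


def simulate_image_set(config: ImageSimConfig
                       ) -> tuple[list[ImageStack], GroundTruth]:
    """Render a set of synthetic fields plus their ground truth.

    Cells are spread over as many fields as the minimum-spacing placement
    requires. ``n_cells=0`` yields an empty ground truth and a single
    background-only field.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    gt = simulate_ground_truth(config, rng)

    stacks: list[ImageStack] = []
    n_fields = int(gt.cells["field"].max()) + 1 if len(gt.cells) else 1
    for field in range(n_fields):
        cells = gt.cells[gt.cells["field"] == field]
        decoys = gt.decoys[gt.decoys["field"] == field] if len(gt.decoys) \
            else gt.decoys
        stacks.append(_render_field(config, cells, decoys, rng))
    return stacks, gt


def write_image_set(stacks: list[ImageStack], gt: GroundTruth, outdir) -> None:
    """Write OME-TIFF fields, the ground-truth CSV and a config echo."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for i, stack in enumerate(stacks):
        write_stack(stack, outdir / f"field_{i:03d}.ome.tif")
    gt.cells.to_csv(outdir / "ground_truth_cells.csv", index=False)
    gt.decoys.to_csv(outdir / "ground_truth_decoys.csv", index=False)
    cfg = dataclasses.asdict(gt.config)
    cfg["field_shape_px"] = list(cfg["field_shape_px"])
    cfg["cell_class_mix"] = list(cfg["cell_class_mix"])
    (outdir / "config.json").write_text(json.dumps(cfg, indent=2))


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class GroupSimParams:
    """Percent-splitting distribution of one study group."""

    n_subjects: int
    split_mean_pct: float
    split_sd_pct: float
    mli2_split_mean_pct: float
    mli2_split_sd_pct: float

    def validate(self, name: str) -> None:
        if self.n_subjects < 0:
            raise ConfigurationError(f"{name}: n_subjects must be >= 0")
        for f in ("split_sd_pct", "mli2_split_sd_pct"):
            if getattr(self, f) < 0:
                raise ConfigurationError(f"{name}: {f} must be >= 0")


@dataclasses.dataclass
class CohortSimConfig:
    """Cohort-table simulation: per-group score distributions + assay size."""

    groups: dict[str, GroupSimParams]
    cells_per_sample: Optional[int] = 175  # None = infinite-cell limit
    seed: int = 0

    def validate(self) -> None:
        for name, g in self.groups.items():
            g.validate(name)
        if self.cells_per_sample is not None and self.cells_per_sample < 1:
            raise ConfigurationError("cells_per_sample must be >= 1 or None")


def default_cohort_config(seed: int = 0,
                          cells_per_sample: Optional[int] = 175
                          ) -> CohortSimConfig:
    """Study-sized cohort: 10/12/9/7/6/4 subjects per group.

    Vehicle means put controls in the ~10% splitting regime and mutation
    carriers well above the 20% deficit line; MLi2 returns every group to the
    control regime.
    """
    groups = {
        "control":    GroupSimParams(10, 10.0, 3.0, 8.0, 3.0),
        "R1441G_PD":  GroupSimParams(12, 40.0, 6.0, 9.0, 3.0),
        "R1441G_NMC": GroupSimParams(9, 30.0, 8.0, 9.0, 3.0),
        "G2019S_PD":  GroupSimParams(7, 40.0, 6.0, 9.0, 3.0),
        "G2019S_NMC": GroupSimParams(6, 28.0, 8.0, 9.0, 3.0),
        "iPD":        GroupSimParams(4, 35.0, 10.0, 10.0, 4.0),
    }
    return CohortSimConfig(groups=groups, cells_per_sample=cells_per_sample,
                           seed=seed)


def _truncated_pct(mean: float, sd: float, rng: np.random.Generator) -> float:
    """One draw from Normal(mean, sd) truncated to [0, 100] by resampling."""
    if sd == 0:
        return float(np.clip(mean, 0, 100))
    for _ in range(10000):
        v = rng.normal(mean, sd)
        if 0 <= v <= 100:
            return float(v)
    raise ConfigurationError(
        f"truncated normal ({mean}, {sd}) has negligible mass in [0, 100]")


def simulate_cohort_scores(config: CohortSimConfig) -> pd.DataFrame:
    """One row per subject × condition with simulated percent splitting.

    The subject's latent percent splitting is drawn from the group's
    condition-specific truncated normal; the observed value is binomially
    resampled at ``cells_per_sample`` two-dot cells (or reported exactly when
    ``cells_per_sample`` is None).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    rows = []
    for group, params in config.groups.items():
        for i in range(params.n_subjects):
            subject = f"{group}_{i:03d}"
            for condition in CONDITIONS:
                if condition == "vehicle":
                    mean, sd = params.split_mean_pct, params.split_sd_pct
                else:
                    mean, sd = (params.mli2_split_mean_pct,
                                params.mli2_split_sd_pct)
                latent = _truncated_pct(mean, sd, rng)
                if config.cells_per_sample is None:
                    observed = latent
                    n_cells = math.inf
                else:
                    n_cells = config.cells_per_sample
                    observed = 100.0 * rng.binomial(n_cells, latent / 100.0) \
                        / n_cells
                rows.append({
                    "subject_id": subject, "group": group,
                    "condition": condition, "pct_split": observed,
                    "latent_pct_split": latent, "n_cells": n_cells,
                })
    return pd.DataFrame(rows, columns=[
        "subject_id", "group", "condition", "pct_split",
        "latent_pct_split", "n_cells"])
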