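"""From multi-channel z-stacks to per-cell assemblies of nuclei and centrosomal spots.

The stage mirrors how the cohesion assay is read out at the microscope:
maximum-intensity projection of a confocal z-stack, DAPI-based nucleus
segmentation with mitotic exclusion, diffraction-limited spot detection on the
centrosomal marker channels (pericentrin, optionally γ-tubulin), dual-marker
colocalization gating, and assignment of centrosomal structures to cells.
All physical quantities are expressed in μm; pixel indices are 0-based and a
pixel's physical coordinate is the position of its center
(``x_um = column_index * pixel_size_um``).
"""

from __future__ import annotations

import dataclasses
import logging
import math
from typing import Optional, Sequence

import numpy as np
import scipy.ndimage as ndi
from scipy.spatial import cKDTree
import tifffile
from skimage.filters import threshold_otsu
from skimage.measure import label as sk_label, regionprops

from .errors import CalibrationError, InputError

logger = logging.getLogger(__name__)

DAPI = "DAPI"
PCNT = "PCNT"
GTUB = "GTUB"
KNOWN_CHANNELS = (DAPI, PCNT, GTUB)


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class ImageStack:
    """Multi-channel confocal z-stack with physical calibration.

    channels maps channel name -> (z, y, x) intensity array. DAPI and PCNT are
    required for the assay; GTUB is present only in dual-marker acquisitions.
    """

    channels: dict[str, np.ndarray]
    pixel_size_um: float
    z_step_um: float = 0.5
    source: Optional[str] = None

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise CalibrationError("pixel_size_um must be positive")
        shapes = {name: ch.shape for name, ch in self.channels.items()}
        if not shapes:
            raise InputError("stack has no channels")
        first = next(iter(shapes.values()))
        if len(first) != 3:
            raise InputError("channels must be 3-D (z, y, x) arrays")
        if any(s != first for s in shapes.values()):
            raise InputError(f"channel shapes differ: {shapes}")
        for required in (DAPI, PCNT):
            if required not in self.channels:
                raise InputError(f"required channel {required!r} missing")

    @property
    def shape(self) -> tuple[int, int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def n_z(self) -> int:
        return self.shape[0]


@dataclasses.dataclass
class NucleusRegion:
    """One segmented nucleus on the DAPI projection."""

    label: int
    slice_yx: tuple[slice, slice]
    mask: np.ndarray  # boolean, within slice_yx
    centroid_um: tuple[float, float]  # (x, y)
    equivalent_diameter_um: float
    area_um2: float
    solidity: float
    mean_dapi: float
    touches_border: bool
    mitotic: bool


@dataclasses.dataclass
class Spot:
    """A detected diffraction-limited spot with subpixel centroid."""

    channel: str
    x_um: float
    y_um: float
    peak_intensity: float
    quality: float
    nucleus_label: Optional[int] = None

    @property
    def xy(self) -> tuple[float, float]:
        return (self.x_um, self.y_um)


@dataclasses.dataclass
class CentrosomalStructure:
    """A centrosome/centriole candidate built from one or two marker spots."""

    x_um: float
    y_um: float
    pcnt_index: Optional[int]
    gtub_index: Optional[int]
    dual_positive: bool
    quality: float = 0.0

    @property
    def xy(self) -> tuple[float, float]:
        return (self.x_um, self.y_um)


@dataclasses.dataclass
class CellAssembly:
    """A nucleus plus the centrosomal structures assigned to it."""

    nucleus: NucleusRegion
    structures: list[CentrosomalStructure]
    assignment_distances_um: list[float] = dataclasses.field(default_factory=list)


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

def write_stack(stack: ImageStack, path) -> None:
    """Write an ImageStack as OME-TIFF with channel names and pixel size."""
    names = list(stack.channels)
    data = np.stack([stack.channels[n] for n in names], axis=0)  # (c, z, y, x)
    tifffile.imwrite(
        path,
        data.astype(np.float32),
        ome=True,
        metadata={
            "axes": "CZYX",
            "Channel": {"Name": names},
            "PhysicalSizeX": stack.pixel_size_um,
            "PhysicalSizeXUnit": "µm",
            "PhysicalSizeY": stack.pixel_size_um,
            "PhysicalSizeYUnit": "µm",
            "PhysicalSizeZ": stack.z_step_um,
            "PhysicalSizeZUnit": "µm",
        },
    )


def _ome_channel_names(tif: tifffile.TiffFile) -> list[str] | None:
    if tif.ome_metadata is None:
        return None
    meta = tifffile.xml2dict(tif.ome_metadata)
    try:
        channels = meta["OME"]["Image"]["Pixels"]["Channel"]
    except (KeyError, TypeError):
        return None
    if isinstance(channels, dict):
        channels = [channels]
    names = [c.get("Name") for c in channels]
    if any(n is None for n in names):
        return None
    return [str(n) for n in names]


def _ome_pixel_size(tif: tifffile.TiffFile) -> tuple[float | None, float | None]:
    if tif.ome_metadata is None:
        return None, None
    meta = tifffile.xml2dict(tif.ome_metadata)
    try:
        pixels = meta["OME"]["Image"]["Pixels"]
    except (KeyError, TypeError):
        return None, None
    return pixels.get("PhysicalSizeX"), pixels.get("PhysicalSizeZ")


def load_stack(
    path,
    channel_map: Optional[dict[str, int]] = None,
    pixel_size_um: Optional[float] = None,
    z_step_um: Optional[float] = None,
) -> ImageStack:
    """Load a TIFF/OME-TIFF stack and map its channels to assay names.

    Channel identity is taken from ``channel_map`` (name -> channel index,
    case-insensitive names) when given, otherwise from OME channel names.
    An explicit ``pixel_size_um`` overrides any metadata calibration.
    """
    with tifffile.TiffFile(str(path)) as tif:
        series = tif.series[0]
        data = series.asarray()
        axes = series.axes
        meta_px, meta_z = _ome_pixel_size(tif)
        ome_names = _ome_channel_names(tif)

    # normalize axis order to (C, Z, Y, X); unknown axes (I/Q/S) are taken
    # as channel first, then z, matching a (c, z, y, x) page layout
    axes = axes.upper()
    unknown_targets = [a for a in "CZ" if a not in axes]
    resolved = []
    for a in axes:
        if a in "CZYX":
            resolved.append(a)
        elif unknown_targets:
            resolved.append(unknown_targets.pop(0))
        else:
            raise InputError(f"cannot interpret TIFF axes {axes!r}")
    axes = "".join(resolved)
    if "C" not in axes:
        data = data[np.newaxis]
        axes = "C" + axes
    if "Z" not in axes:
        data = np.expand_dims(data, axis=axes.index("C") + 1)
        axes = axes.replace("C", "CZ", 1)
    order = [axes.index(a) for a in "CZYX"]
    data = np.transpose(data, order)

    n_channels = data.shape[0]
    mapping: dict[str, int] = {}
    if channel_map:
        for name, idx in channel_map.items():
            name = name.upper()
            if not 0 <= idx < n_channels:
                raise InputError(f"channel index {idx} out of range for {name}")
            mapping[name] = idx
    elif ome_names:
        for idx, name in enumerate(ome_names):
            mapping[name.upper()] = idx
    else:
        raise InputError(
            "no channel_map given and no OME channel names in metadata"
        )

    for required in (DAPI, PCNT):
        if required not in mapping:
            raise InputError(
                f"required channel {required!r} not found "
                f"(available: {sorted(mapping)})"
            )

    if pixel_size_um is not None:
        if meta_px is not None and not math.isclose(float(meta_px), pixel_size_um):
            logger.warning(
                "pixel size override %.4g μm supersedes metadata %.4g μm for %s",
                pixel_size_um, float(meta_px), path,
            )
        px = pixel_size_um
    elif meta_px is not None:
        px = float(meta_px)
    else:
        raise CalibrationError(
            f"no pixel size in metadata of {path} and no override given"
        )

    if z_step_um is not None:
        dz = z_step_um
    elif meta_z is not None:
        dz = float(meta_z)
    else:
        dz = 0.5

    channels = {
        name: np.asarray(data[idx]) for name, idx in mapping.items()
        if name in KNOWN_CHANNELS
    }
    return ImageStack(channels=channels, pixel_size_um=px, z_step_um=dz,
                      source=str(path))


# ---------------------------------------------------------------------------
# projection
# ---------------------------------------------------------------------------

def max_project(stack: ImageStack) -> dict[str, np.ndarray]:
    """Maximum-intensity projection over z for every channel."""
    if stack.n_z < 1:
        raise InputError("stack has no z planes")
    return {name: ch.max(axis=0) for name, ch in stack.channels.items()}


# ---------------------------------------------------------------------------
# nucleus segmentation
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class SegmentationParams:
    """Parameters of DAPI nucleus segmentation and mitotic flagging.

    The mitotic heuristic flags condensed chromatin: a region whose mean DAPI
    intensity exceeds ``mitotic_intensity_factor`` times the median nucleus
    intensity of the field AND that is either non-convex
    (solidity < ``mitotic_solidity_max``) or small
    (area < ``mitotic_area_fraction`` of the median nucleus area).
    """

    blur_sigma_um: float = 0.3
    min_diameter_um: float = 3.0
    mitotic_intensity_factor: float = 2.5
    mitotic_solidity_max: float = 0.9
    mitotic_area_fraction: float = 0.5


def segment_nuclei(
    dapi: np.ndarray,
    pixel_size_um: float,
    params: Optional[SegmentationParams] = None,
) -> list[NucleusRegion]:
    """Segment nuclei on a DAPI projection by Otsu thresholding.

    Returns disjoint labeled regions with morphology in μm. A blank image
    yields an empty list. Touching nuclei are not split (the simulator places
    cells with a guaranteed minimum spacing; see the methods note).
    """
    params = params or SegmentationParams()
    img = np.asarray(dapi, dtype=float)
    if img.ndim != 2:
        raise InputError("segment_nuclei expects a 2-D projection")
    if img.max() <= img.min():
        return []

    smoothed = ndi.gaussian_filter(img, params.blur_sigma_um / pixel_size_um)
    thr = threshold_otsu(smoothed)
    fg = ndi.binary_fill_holes(smoothed > thr)
    labels = sk_label(fg)

    min_area_px = math.pi * (params.min_diameter_um / 2 / pixel_size_um) ** 2
    h, w = img.shape
    props = [p for p in regionprops(labels, intensity_image=img)
             if p.area >= min_area_px]
    if not props:
        return []

    med_intensity = float(np.median([p.intensity_mean for p in props]))
    med_area = float(np.median([p.area for p in props]))

    regions: list[NucleusRegion] = []
    for p in props:
        minr, minc, maxr, maxc = p.bbox
        touches = minr == 0 or minc == 0 or maxr == h or maxc == w
        cy, cx = p.centroid
        mitotic = (
            p.intensity_mean > params.mitotic_intensity_factor * med_intensity
            and (p.solidity < params.mitotic_solidity_max
                 or p.area < params.mitotic_area_fraction * med_area)
        )
        regions.append(NucleusRegion(
            label=int(p.label),
            slice_yx=(slice(minr, maxr), slice(minc, maxc)),
            mask=p.image.copy(),
            centroid_um=(cx * pixel_size_um, cy * pixel_size_um),
            equivalent_diameter_um=p.equivalent_diameter_area * pixel_size_um,
            area_um2=p.area * pixel_size_um ** 2,
            solidity=float(p.solidity),
            mean_dapi=float(p.intensity_mean),
            touches_border=bool(touches),
            mitotic=bool(mitotic),
        ))
    regions.sort(key=lambda r: r.label)
    return regions


# ---------------------------------------------------------------------------
# spot detection
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class SpotDetectionParams:
    """Band-pass spot detector settings.

    The detector applies a scale-normalized Laplacian-of-Gaussian at
    ``sigma_um`` (the expected dot width), extracts local maxima separated by
    at least ``min_separation_px`` pixels, and keeps maxima whose response
    exceeds max(``threshold_abs``, ``threshold_rel`` × strongest response,
    ``noise_k`` × robust noise level of the response image). Centroids are
    refined to subpixel precision by background-subtracted center of mass in a
    window of ``refine_radius_px``.
    """

    sigma_um: float = 0.15
    threshold_abs: float = 0.0
    threshold_rel: float = 0.3
    noise_k: float = 6.0
    min_separation_px: int = 3
    refine_radius_px: int = 4


def _refine_centroid(img: np.ndarray, row: int, col: int, radius: int
                     ) -> tuple[float, float]:
    """Background-subtracted center of mass around an integer peak."""
    h, w = img.shape
    r0, r1 = max(row - radius, 0), min(row + radius + 1, h)
    c0, c1 = max(col - radius, 0), min(col + radius + 1, w)
    window = img[r0:r1, c0:c1].astype(float)
    weights = np.clip(window - window.min(), 0, None)
    total = weights.sum()
    if total <= 0:
        return float(row), float(col)
    rows = np.arange(r0, r1, dtype=float)[:, None]
    cols = np.arange(c0, c1, dtype=float)[None, :]
    return float((weights * rows).sum() / total), float((weights * cols).sum() / total)


def detect_spots(
    image: np.ndarray,
    pixel_size_um: float,
    channel: str = PCNT,
    params: Optional[SpotDetectionParams] = None,
) -> list[Spot]:
    """Detect diffraction-limited spots on a 2-D marker projection.

    Returns spots sorted by descending quality (LoG response at the peak).
    An empty or blank image yields an empty list.
    """
    params = params or SpotDetectionParams()
    img = np.asarray(image, dtype=float)
    if img.ndim != 2 or img.size == 0:
        return []

    sigma_px = params.sigma_um / pixel_size_um
    response = -ndi.gaussian_laplace(img, sigma_px) * sigma_px ** 2

    mad = float(np.median(np.abs(response - np.median(response)))) * 1.4826
    thr = max(params.threshold_abs,
              params.threshold_rel * float(response.max()),
              params.noise_k * mad)
    if thr <= 0:
        return []

    size = 2 * params.min_separation_px + 1
    is_peak = (response == ndi.maximum_filter(response, size=size)) & (response > thr)
    rows, cols = np.nonzero(is_peak)

    spots: list[Spot] = []
    for row, col in zip(rows, cols):
        ry, rx = _refine_centroid(img, int(row), int(col), params.refine_radius_px)
        spots.append(Spot(
            channel=channel,
            x_um=rx * pixel_size_um,
            y_um=ry * pixel_size_um,
            peak_intensity=float(img[row, col]),
            quality=float(response[row, col]),
        ))
    spots.sort(key=lambda s: -s.quality)
    return spots


# ---------------------------------------------------------------------------
# marker pairing (colocalization gating)
# ---------------------------------------------------------------------------

def pair_markers(
    spots_pcnt: Sequence[Spot],
    spots_gtub: Sequence[Spot],
    radius_um: float = 0.5,
) -> list[CentrosomalStructure]:
    """Mutual-nearest-neighbor pairing of pericentrin and γ-tubulin spots.

    A centrosome is called dual-positive when a PCNT spot and a GTUB spot are
    mutual nearest neighbors within ``radius_um``; its centroid is the
    midpoint of the two spots. Unpaired spots of either channel become
    structures with ``dual_positive=False`` (excluded downstream in
    dual-marker scoring). The result is symmetric in channel order.
    """
    if radius_um <= 0:
        raise InputError("radius_um must be positive")
    p_xy = np.array([s.xy for s in spots_pcnt], dtype=float).reshape(-1, 2)
    g_xy = np.array([s.xy for s in spots_gtub], dtype=float).reshape(-1, 2)

    paired_p: set[int] = set()
    paired_g: set[int] = set()
    structures: list[CentrosomalStructure] = []

    if len(p_xy) and len(g_xy):
        d = np.linalg.norm(p_xy[:, None, :] - g_xy[None, :, :], axis=2)
        nn_of_p = d.argmin(axis=1)
        nn_of_g = d.argmin(axis=0)
        for i, j in enumerate(nn_of_p):
            if nn_of_g[j] == i and d[i, j] <= radius_um:
                mx = (p_xy[i, 0] + g_xy[j, 0]) / 2
                my = (p_xy[i, 1] + g_xy[j, 1]) / 2
                structures.append(CentrosomalStructure(
                    x_um=float(mx), y_um=float(my),
                    pcnt_index=i, gtub_index=int(j), dual_positive=True,
                    quality=(spots_pcnt[i].quality + spots_gtub[j].quality) / 2,
                ))
                paired_p.add(i)
                paired_g.add(int(j))

    for i, s in enumerate(spots_pcnt):
        if i not in paired_p:
            structures.append(CentrosomalStructure(
                x_um=s.x_um, y_um=s.y_um, pcnt_index=i, gtub_index=None,
                dual_positive=False, quality=s.quality))
    for j, s in enumerate(spots_gtub):
        if j not in paired_g:
            structures.append(CentrosomalStructure(
                x_um=s.x_um, y_um=s.y_um, pcnt_index=None, gtub_index=j,
                dual_positive=False, quality=s.quality))
    return structures


def pcnt_structures(spots_pcnt: Sequence[Spot]) -> list[CentrosomalStructure]:
    """Single-marker mode: every pericentrin spot is a scorable structure."""
    return [
        CentrosomalStructure(x_um=s.x_um, y_um=s.y_um, pcnt_index=i,
                             gtub_index=None, dual_positive=False,
                             quality=s.quality)
        for i, s in enumerate(spots_pcnt)
    ]


# ---------------------------------------------------------------------------
# cell assembly
# ---------------------------------------------------------------------------

def assemble_cells(
    nuclei: Sequence[NucleusRegion],
    structures: Sequence[CentrosomalStructure],
    pixel_size_um: float,
    max_distance_um: float = 5.0,
) -> tuple[list[CellAssembly], int]:
    """Assign each centrosomal structure to its nearest nucleus.

    The distance from a structure to a nucleus is zero if the structure lies
    inside the nucleus mask, otherwise the distance to the nearest boundary
    pixel. Structures farther than ``max_distance_um`` from every nucleus are
    dropped; the count of dropped structures is returned. Exact distance ties
    go to the lower nucleus label (logged).
    """
    assemblies = [CellAssembly(nucleus=n, structures=[]) for n in nuclei]
    if not nuclei:
        return assemblies, len(structures)
    by_label = {n.label: i for i, n in enumerate(nuclei)}

    # per-nucleus boundary KD-trees in μm, ordered by label
    trees: list[tuple[int, cKDTree, NucleusRegion]] = []
    for n in sorted(nuclei, key=lambda n: n.label):
        interior = ndi.binary_erosion(n.mask)
        boundary = n.mask & ~interior
        ys, xs = np.nonzero(boundary)
        coords = np.column_stack([
            (xs + n.slice_yx[1].start) * pixel_size_um,
            (ys + n.slice_yx[0].start) * pixel_size_um,
        ])
        trees.append((n.label, cKDTree(coords), n))

    dropped = 0
    for s in structures:
        best_label, best_dist = None, np.inf
        for lab, tree, n in trees:
            # inside test on the pixel grid
            row = int(round(s.y_um / pixel_size_um)) - n.slice_yx[0].start
            col = int(round(s.x_um / pixel_size_um)) - n.slice_yx[1].start
            if (0 <= row < n.mask.shape[0] and 0 <= col < n.mask.shape[1]
                    and n.mask[row, col]):
                dist = 0.0
            else:
                dist, _ = tree.query([s.x_um, s.y_um])
                dist = float(dist)
            if dist < best_dist:
                best_label, best_dist = lab, dist
            elif dist == best_dist and best_label is not None and lab > best_label:
                logger.debug("structure at (%.2f, %.2f) equidistant to nuclei "
                             "%d and %d; keeping %d",
                             s.x_um, s.y_um, best_label, lab, best_label)
        if best_label is None or best_dist > max_distance_um:
            dropped += 1
            continue
        idx = by_label[best_label]
        assemblies[idx].structures.append(s)
        assemblies[idx].assignment_distances_um.append(best_dist)
    return assemblies, dropped
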