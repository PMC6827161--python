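"""Synthetic fluorescence-microscopy data with exported ground truth.

Generates the three kinds of input the analysis pipeline consumes:

* 3-D z-stacks of Life-Act-like labeled cells embedded in a gel —
  ellipsoidal cell bodies with thin capsule-shaped filopodia attached at
  controlled surface positions, angles and lengths, plus sub-10-µm
  vesicle-like fragments (oncosomes), background and noise;
* 2-D persistent-random-walk migration tracks with controlled speed and
  directional persistence;
* two-channel (green tumor / red T cell) co-culture images containing
  rosette-like clusters and dispersed single cells.

Every generated object is recorded in a ground-truth structure using
voxel/pixel-counted sizes, so downstream measurements can be validated
exactly.  All randomness flows through a single integer seed; a fixed spec
plus seed yields bit-identical output.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .segmentation import VolumeImage, projection_perimeter


class GeometryError(ValueError):
    """An object in a synthetic spec does not fit inside the image."""


class ParameterError(ValueError):
    """A synthetic spec parameter is out of its valid range."""


# --------------------------------------------------------------------------
# 3-D stack specs
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class FilopodiumSpec:
    """One protrusion attached to a cell body.

    ``base_direction`` is the unit vector (z, y, x) from the cell center to
    the attachment point on the body surface.  ``deviation_angle`` is the
    angle in degrees between the protrusion axis and the outward radial
    direction at the base (0 = perfectly radial, 90 = tangential);
    ``azimuth`` orients that deviation around the radial axis.  ``length``
    is measured from the body surface to the tip, in µm.
    """

    base_direction: tuple[float, float, float]
    deviation_angle: float = 0.0
    length: float = 4.0
    radius: float = 0.4
    azimuth: float = 0.0

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ParameterError(f"filopodium length must be > 0, got {self.length}")
        if not 0.0 <= self.deviation_angle <= 90.0:
            raise ParameterError(
                f"deviation_angle must be in [0, 90] degrees, got {self.deviation_angle}"
            )
        if self.radius <= 0:
            raise ParameterError(f"filopodium radius must be > 0, got {self.radius}")
        norm = float(np.linalg.norm(self.base_direction))
        if not np.isclose(norm, 1.0, atol=1e-6):
            raise ParameterError("base_direction must be a unit vector")


@dataclass(frozen=True)
class SyntheticCellSpec:
    """An ellipsoidal cell body with attached filopodia, in physical µm."""

    center: tuple[float, float, float]
    body_radii: tuple[float, float, float] = (7.0, 7.0, 7.0)
    intensity: float = 100.0
    filopodia: tuple[FilopodiumSpec, ...] = ()

    def __post_init__(self) -> None:
        if any(r <= 0 for r in self.body_radii):
            raise ParameterError(f"body_radii must be > 0, got {self.body_radii}")

    @property
    def max_extent(self) -> float:
        """Largest distance from center to any rendered voxel, µm."""
        ext = max(self.body_radii)
        for f in self.filopodia:
            ext = max(ext, self._surface_distance(f.base_direction) + f.length + f.radius)
        return ext

    def _surface_distance(self, direction: Sequence[float]) -> float:
        u = np.asarray(direction, dtype=float)
        r = np.asarray(self.body_radii, dtype=float)
        return 1.0 / float(np.sqrt(np.sum((u / r) ** 2)))


@dataclass(frozen=True)
class FragmentSpec:
    """A sub-10-µm spherical vesicle-like fragment (oncosome)."""

    center: tuple[float, float, float]
    diameter: float = 5.0
    intensity: float = 80.0

    def __post_init__(self) -> None:
        if not 0 < self.diameter < 10:
            raise ParameterError(
                f"fragment diameter must be in (0, 10) µm, got {self.diameter}"
            )


@dataclass(frozen=True)
class SyntheticStackSpec:
    """A full synthetic z-stack: geometry, illumination and noise model.

    ``shape`` is in voxels (z, y, x); ``voxel_size`` in µm (dz, dy, dx),
    defaulting to a 0.3 µm z-interval with 0.25 µm lateral sampling typical
    of a 63x spinning-disc acquisition.
    """

    shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float] = (0.3, 0.25, 0.25)
    cells: tuple[SyntheticCellSpec, ...] = ()
    fragments: tuple[FragmentSpec, ...] = ()
    background_level: float = 5.0
    gaussian_sd: float = 0.0
    poisson_scaling: float = 0.0
    blur_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.shape):
            raise ParameterError(f"shape must be positive, got {self.shape}")
        if any(v <= 0 for v in self.voxel_size):
            raise ParameterError(f"voxel_size must be positive, got {self.voxel_size}")

    @property
    def physical_extent(self) -> np.ndarray:
        return (np.asarray(self.shape) - 1) * np.asarray(self.voxel_size)


@dataclass
class CellTruth:
    """Ground truth for one rendered cell (voxel-counted where applicable)."""

    cell_index: int
    centroid: tuple[float, float, float]
    volume_um3: float
    equivalent_diameter_um: float
    perimeter_um: float
    filopodia_count: int
    filopodia_lengths_um: list[float]
    filopodia_angles_deg: list[float]
    filopodia_bases: list[tuple[float, float, float]]
    filopodia_tips: list[tuple[float, float, float]]


@dataclass
class StackGroundTruth:
    cells: list[CellTruth]
    fragment_diameters_um: list[float]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.cells:
            rows.append(
                {
                    "cell_index": c.cell_index,
                    "centroid_z_um": c.centroid[0],
                    "centroid_y_um": c.centroid[1],
                    "centroid_x_um": c.centroid[2],
                    "volume_um3": c.volume_um3,
                    "equivalent_diameter_um": c.equivalent_diameter_um,
                    "perimeter_um": c.perimeter_um,
                    "filopodia_count": c.filopodia_count,
                }
            )
        return pd.DataFrame(rows)


def _perpendicular_frame(u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two unit vectors orthogonal to u, chosen deterministically."""
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, u)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(u, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(u, e1)
    return e1, e2


def filopodium_geometry(
    cell: SyntheticCellSpec, filo: FilopodiumSpec
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Physical base point, unit axis direction, and tip point of a filopodium."""
    u = np.asarray(filo.base_direction, dtype=float)
    u = u / np.linalg.norm(u)
    base = np.asarray(cell.center) + cell._surface_distance(u) * u
    e1, e2 = _perpendicular_frame(u)
    theta = np.deg2rad(filo.deviation_angle)
    phi = np.deg2rad(filo.azimuth)
    direction = np.cos(theta) * u + np.sin(theta) * (np.cos(phi) * e1 + np.sin(phi) * e2)
    direction /= np.linalg.norm(direction)
    tip = base + filo.length * direction
    return base, direction, tip


def _physical_axes(shape: Sequence[int], voxel_size: Sequence[float]):
    return [np.arange(n) * v for n, v in zip(shape, voxel_size)]


def _crop_slices(
    lo: np.ndarray, hi: np.ndarray, shape: Sequence[int], voxel_size: Sequence[float]
) -> tuple[slice, ...]:
    idx_lo = np.maximum(np.floor(lo / np.asarray(voxel_size)).astype(int) - 1, 0)
    idx_hi = np.minimum(
        np.ceil(hi / np.asarray(voxel_size)).astype(int) + 2, np.asarray(shape)
    )
    return tuple(slice(int(a), int(b)) for a, b in zip(idx_lo, idx_hi))


def _ellipsoid_mask_into(
    mask: np.ndarray,
    center: Sequence[float],
    radii: Sequence[float],
    voxel_size: Sequence[float],
) -> None:
    c = np.asarray(center, dtype=float)
    r = np.asarray(radii, dtype=float)
    sl = _crop_slices(c - r, c + r, mask.shape, voxel_size)
    axes = _physical_axes(mask.shape, voxel_size)
    zz = (axes[0][sl[0]] - c[0]) / r[0]
    yy = (axes[1][sl[1]] - c[1]) / r[1]
    xx = (axes[2][sl[2]] - c[2]) / r[2]
    quad = (
        zz[:, None, None] ** 2 + yy[None, :, None] ** 2 + xx[None, None, :] ** 2
    )
    mask[sl] |= quad <= 1.0


def _capsule_mask_into(
    mask: np.ndarray,
    p0: np.ndarray,
    p1: np.ndarray,
    radius: float,
    voxel_size: Sequence[float],
) -> None:
    """Voxels within `radius` of the segment p0-p1 (a cylinder with caps)."""
    lo = np.minimum(p0, p1) - radius
    hi = np.maximum(p0, p1) + radius
    sl = _crop_slices(lo, hi, mask.shape, voxel_size)
    axes = _physical_axes(mask.shape, voxel_size)
    zz, yy, xx = np.meshgrid(
        axes[0][sl[0]], axes[1][sl[1]], axes[2][sl[2]], indexing="ij"
    )
    pts = np.stack([zz, yy, xx], axis=-1)
    d = p1 - p0
    seg_len2 = float(np.dot(d, d))
    if seg_len2 == 0:
        dist2 = np.sum((pts - p0) ** 2, axis=-1)
    else:
        t = np.clip(np.einsum("...k,k->...", pts - p0, d) / seg_len2, 0.0, 1.0)
        proj = p0 + t[..., None] * d
        dist2 = np.sum((pts - proj) ** 2, axis=-1)
    mask[sl] |= dist2 <= radius**2


def _validate_geometry(spec: SyntheticStackSpec) -> None:
    extent = spec.physical_extent
    for i, cell in enumerate(spec.cells):
        c = np.asarray(cell.center)
        m = cell.max_extent
        if np.any(c - m < 0) or np.any(c + m > extent):
            raise GeometryError(
                f"cell {i} (center {cell.center}, extent {m:.2f} µm) does not fit "
                f"inside the stack of physical size {tuple(np.round(extent, 2))} µm"
            )
    for i, frag in enumerate(spec.fragments):
        c = np.asarray(frag.center)
        r = frag.diameter / 2
        if np.any(c - r < 0) or np.any(c + r > extent):
            raise GeometryError(
                f"fragment {i} (center {frag.center}, diameter {frag.diameter} µm) "
                f"does not fit inside the stack"
            )


def generate_stack(spec: SyntheticStackSpec) -> tuple[VolumeImage, StackGroundTruth]:
    """Render a synthetic z-stack and its ground truth.

    Rendering is performed in physical coordinates and sampled on the
    (possibly anisotropic) voxel grid.  Cell bodies and fragments are
    painted at their specified intensities over a constant background;
    optional Poisson shot noise and Gaussian read noise are then applied
    using the spec's seed.

    Returns the image and a :class:`StackGroundTruth` whose per-cell volume,
    equivalent diameter and mid-body projection perimeter are measured on
    the rendered body-only voxel mask (so they are exact voxel-counted
    references), while filopodium lengths/angles are the constructed
    physical values.
    """
    _validate_geometry(spec)
    vs = spec.voxel_size
    image = np.full(spec.shape, float(spec.background_level), dtype=np.float64)
    voxel_volume = float(np.prod(vs))

    cell_truths: list[CellTruth] = []
    for i, cell in enumerate(spec.cells):
        body = np.zeros(spec.shape, dtype=bool)
        _ellipsoid_mask_into(body, cell.center, cell.body_radii, vs)
        lengths, angles, bases, tips = [], [], [], []
        full = body.copy()
        for filo in cell.filopodia:
            base, direction, tip = filopodium_geometry(cell, filo)
            # start slightly inside the body so the capsule attaches
            p0 = base - min(0.5, filo.length * 0.1) * direction
            _capsule_mask_into(full, p0, tip, filo.radius, vs)
            lengths.append(filo.length)
            angles.append(filo.deviation_angle)
            bases.append(tuple(base))
            tips.append(tuple(tip))
        image[full] = np.maximum(image[full], cell.intensity)

        n_vox = int(body.sum())
        volume = n_vox * voxel_volume
        eq_diam = float((6.0 * volume / np.pi) ** (1.0 / 3.0))
        perim = projection_perimeter(body, vs)
        com = np.array(np.nonzero(body), dtype=float).mean(axis=1) * np.asarray(vs)
        cell_truths.append(
            CellTruth(
                cell_index=i,
                centroid=tuple(com),
                volume_um3=volume,
                equivalent_diameter_um=eq_diam,
                perimeter_um=perim,
                filopodia_count=len(cell.filopodia),
                filopodia_lengths_um=lengths,
                filopodia_angles_deg=angles,
                filopodia_bases=bases,
                filopodia_tips=tips,
            )
        )

    frag_diams = []
    for frag in spec.fragments:
        m = np.zeros(spec.shape, dtype=bool)
        r = frag.diameter / 2.0
        _ellipsoid_mask_into(m, frag.center, (r, r, r), vs)
        image[m] = np.maximum(image[m], frag.intensity)
        frag_diams.append(frag.diameter)

    if spec.blur_sigma > 0:
        from scipy.ndimage import gaussian_filter

        image = gaussian_filter(image, sigma=[spec.blur_sigma / v for v in vs])

    rng = np.random.default_rng(spec.seed)
    if spec.poisson_scaling > 0:
        image = rng.poisson(np.maximum(image, 0) * spec.poisson_scaling) / spec.poisson_scaling
    if spec.gaussian_sd > 0:
        image = image + rng.normal(0.0, spec.gaussian_sd, size=image.shape)

    return VolumeImage(image, vs), StackGroundTruth(cell_truths, frag_diams)


# --------------------------------------------------------------------------
# Migration tracks (persistent random walk)
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticTrackSpec:
    """Persistent-random-walk track ensemble.

    ``persistence`` is the directional correlation between consecutive
    steps: 1 gives straight-line tracks, 0 uncorrelated step directions.
    Step headings evolve by wrapped-Gaussian turning with circular sd
    chosen so E[cos(turn)] equals the persistence.  Step length is fixed at
    ``mean_speed * dt`` so the empirical mean speed is controlled exactly.
    """

    n_tracks: int = 50
    n_frames: int = 97
    dt: float = 15.0
    mean_speed: float = 3.0
    persistence: float = 0.5
    arena_size: float = 500.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ParameterError(f"dt must be > 0, got {self.dt}")
        if self.n_frames < 2:
            raise ParameterError(f"n_frames must be >= 2, got {self.n_frames}")
        if not 0.0 <= self.persistence <= 1.0:
            raise ParameterError(f"persistence must be in [0, 1], got {self.persistence}")
        if self.mean_speed < 0:
            raise ParameterError(f"mean_speed must be >= 0, got {self.mean_speed}")


def generate_tracks(spec: SyntheticTrackSpec) -> pd.DataFrame:
    """Simulate persistent-random-walk tracks.

    Returns a table with columns ``track_id, frame, t_min, x_um, y_um``
    matching the dialect written by manual-tracking exports.
    """
    rng = np.random.default_rng(spec.seed)
    step = spec.mean_speed * spec.dt
    n_steps = spec.n_frames - 1
    if spec.persistence >= 1.0:
        turn_sd = 0.0
    elif spec.persistence <= 0.0:
        turn_sd = None  # uniform redraw every step
    else:
        turn_sd = float(np.sqrt(-2.0 * np.log(spec.persistence)))

    frames = np.arange(spec.n_frames)
    records = []
    for tid in range(spec.n_tracks):
        start = rng.uniform(0, spec.arena_size, size=2)
        heading = rng.uniform(0, 2 * np.pi)
        xs = np.empty(spec.n_frames)
        ys = np.empty(spec.n_frames)
        xs[0], ys[0] = start
        if turn_sd is None:
            headings = rng.uniform(0, 2 * np.pi, size=n_steps)
        elif turn_sd == 0.0:
            headings = np.full(n_steps, heading)
        else:
            turns = rng.normal(0.0, turn_sd, size=n_steps)
            headings = heading + np.cumsum(turns)
        xs[1:] = xs[0] + np.cumsum(step * np.cos(headings))
        ys[1:] = ys[0] + np.cumsum(step * np.sin(headings))
        records.append(
            pd.DataFrame(
                {
                    "track_id": tid,
                    "frame": frames,
                    "t_min": frames * spec.dt,
                    "x_um": xs,
                    "y_um": ys,
                }
            )
        )
    return pd.concat(records, ignore_index=True)


# --------------------------------------------------------------------------
# Two-channel co-culture cluster images
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ClusterSpec:
    """One rosette-like aggregate: tumor disks ringed by T-cell disks."""

    center: tuple[float, float]
    tumor_members: int = 1
    tcell_members: int = 10


@dataclass(frozen=True)
class ClusterImageParams:
    pixel_size: float = 0.5
    tumor_radius: float = 7.5
    tcell_radius: float = 3.5
    tumor_intensity: float = 120.0
    tcell_intensity: float = 110.0
    background_level: float = 4.0
    gaussian_sd: float = 0.0
    dispersion_min_gap: float = 8.0
    max_attempts: int = 2000


@dataclass
class ClusterGroundTruth:
    cluster_areas_um2: list[float]
    n_dispersed_tumor: int
    n_dispersed_tcell: int


def _disk_mask_into(mask, center, radius, pixel_size) -> None:
    c = np.asarray(center, dtype=float)
    lo = np.maximum(np.floor((c - radius) / pixel_size).astype(int) - 1, 0)
    hi = np.minimum(np.ceil((c + radius) / pixel_size).astype(int) + 2, mask.shape)
    ys = np.arange(lo[0], hi[0]) * pixel_size
    xs = np.arange(lo[1], hi[1]) * pixel_size
    dist2 = (ys[:, None] - c[0]) ** 2 + (xs[None, :] - c[1]) ** 2
    mask[lo[0] : hi[0], lo[1] : hi[1]] |= dist2 <= radius**2


def generate_cluster_image(
    n_tumor: int,
    n_tcell: int,
    cluster_spec: Sequence[ClusterSpec],
    image_size: tuple[int, int],
    seed: int = 0,
    params: ClusterImageParams = ClusterImageParams(),
):
    """Render a two-channel co-culture image.

    ``n_tumor`` / ``n_tcell`` dispersed single cells are scattered by
    rejection sampling at pairwise gaps above ``dispersion_min_gap`` from
    every other object so they never form incidental clusters; the listed
    ``cluster_spec`` aggregates are rendered as a central tumor core ringed
    by touching T-cell disks.  Returns ``(green, red, pixel_size, truth)``
    where truth records each cluster's union pixel area.

    Raises :class:`GeometryError` when an object does not fit or dispersed
    placement fails after ``max_attempts`` rejections.
    """
    rng = np.random.default_rng(seed)
    px = params.pixel_size
    shape = tuple(image_size)
    green_mask = np.zeros(shape, dtype=bool)
    red_mask = np.zeros(shape, dtype=bool)
    extent = (np.asarray(shape) - 1) * px

    placed: list[tuple[np.ndarray, float]] = []  # (center, radius) in µm

    truth_areas: list[float] = []
    for ci, cl in enumerate(cluster_spec):
        c = np.asarray(cl.center, dtype=float)
        ring_r = params.tumor_radius + params.tcell_radius
        outer = ring_r + params.tcell_radius
        if np.any(c - outer < 0) or np.any(c + outer > extent):
            raise GeometryError(f"cluster {ci} at {cl.center} does not fit in the image")
        g = np.zeros(shape, dtype=bool)
        r = np.zeros(shape, dtype=bool)
        # tumor core: first disk centered, extras packed around it
        for k in range(cl.tumor_members):
            if k == 0:
                tc = c
            else:
                ang = 2 * np.pi * (k - 1) / max(cl.tumor_members - 1, 1)
                tc = c + params.tumor_radius * np.array([np.cos(ang), np.sin(ang)])
            _disk_mask_into(g, tc, params.tumor_radius, px)
        for k in range(cl.tcell_members):
            ang = 2 * np.pi * k / cl.tcell_members
            tc = c + ring_r * np.array([np.cos(ang), np.sin(ang)])
            _disk_mask_into(r, tc, params.tcell_radius, px)
        green_mask |= g
        red_mask |= r
        truth_areas.append(float((g | r).sum()) * px * px)
        placed.append((c, outer))

    def _place_single(radius: float) -> np.ndarray:
        for _ in range(params.max_attempts):
            c = rng.uniform(radius, extent - radius)
            ok = all(
                np.linalg.norm(c - pc) > pr + radius + params.dispersion_min_gap
                for pc, pr in placed
            )
            if ok:
                placed.append((c, radius))
                return c
        raise GeometryError(
            f"could not place a dispersed cell after {params.max_attempts} attempts"
        )

    for _ in range(n_tumor):
        _disk_mask_into(green_mask, _place_single(params.tumor_radius), params.tumor_radius, px)
    for _ in range(n_tcell):
        _disk_mask_into(red_mask, _place_single(params.tcell_radius), params.tcell_radius, px)

    green = np.full(shape, params.background_level, dtype=np.float64)
    red = np.full(shape, params.background_level, dtype=np.float64)
    green[green_mask] = params.tumor_intensity
    red[red_mask] = params.tcell_intensity
    if params.gaussian_sd > 0:
        green = green + rng.normal(0, params.gaussian_sd, shape)
        red = red + rng.normal(0, params.gaussian_sd, shape)

    truth = ClusterGroundTruth(truth_areas, n_tumor, n_tcell)
    return green, red, px, truth


# --------------------------------------------------------------------------
# On-disk formats
# --------------------------------------------------------------------------

def write_ground_truth(truth: StackGroundTruth, csv_path: str | Path) -> None:
    """Ground truth as a per-cell CSV plus a JSON sidecar with full detail."""
    csv_path = Path(csv_path)
    truth.to_frame().to_csv(csv_path, index=False)
    sidecar = csv_path.with_suffix(".json")
    payload = {
        "cells": [dataclasses.asdict(c) for c in truth.cells],
        "fragment_diameters_um": truth.fragment_diameters_um,
    }
    sidecar.write_text(json.dumps(payload, indent=2))


def read_ground_truth(csv_path: str | Path) -> StackGroundTruth:
    sidecar = Path(csv_path).with_suffix(".json")
    payload = json.loads(sidecar.read_text())
    cells = [
        CellTruth(
            cell_index=c["cell_index"],
            centroid=tuple(c["centroid"]),
            volume_um3=c["volume_um3"],
            equivalent_diameter_um=c["equivalent_diameter_um"],
            perimeter_um=c["perimeter_um"],
            filopodia_count=c["filopodia_count"],
            filopodia_lengths_um=list(c["filopodia_lengths_um"]),
            filopodia_angles_deg=list(c["filopodia_angles_deg"]),
            filopodia_bases=[tuple(b) for b in c["filopodia_bases"]],
            filopodia_tips=[tuple(t) for t in c["filopodia_tips"]],
        )
        for c in payload["cells"]
    ]
    return StackGroundTruth(cells, list(payload["fragment_diameters_um"]))
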