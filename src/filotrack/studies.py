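"""Parameter-recovery studies: synthetic conditions run through the full
pipeline.

These helpers build condition-level synthetic experiments — populations of
cells with controlled filopodia statistics, track ensembles with controlled
speed/persistence, cluster images with known areas — run the corresponding
analysis stages, and return measured-vs-generating summaries.  They back
the package's validation suite and the reproduction script.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import clusters as cl
from . import filopodia as fp
from . import motility as mot
from . import segmentation as seg
from . import synthetic as syn

STUDY_VOXEL_SIZE = (0.3, 0.25, 0.25)


def random_filopodia_specs(
    rng: np.random.Generator,
    n: int,
    angle_mean: float,
    angle_sd: float,
    length_mean: float,
    length_sd: float,
    min_separation_deg: float = 25.0,
) -> tuple[syn.FilopodiumSpec, ...]:
    """Filopodium specs with base directions kept apart by rejection
    sampling so neighbouring protrusions stay resolvable."""
    dirs: list[np.ndarray] = []
    attempts = 0
    while len(dirs) < n and attempts < 500:
        d = rng.normal(size=3)
        d /= np.linalg.norm(d)
        if all(
            np.degrees(np.arccos(np.clip(d @ e, -1, 1))) > min_separation_deg
            for e in dirs
        ):
            dirs.append(d)
        attempts += 1
    specs = []
    for d in dirs:
        angle = float(np.clip(rng.normal(angle_mean, angle_sd), 0.0, 85.0))
        length = float(np.clip(rng.normal(length_mean, length_sd), 2.0, None))
        specs.append(
            syn.FilopodiumSpec(
                base_direction=tuple(d),
                deviation_angle=angle,
                length=length,
                azimuth=float(rng.uniform(0, 360)),
            )
        )
    return tuple(specs)


@dataclass
class FilopodiaCellResult:
    true_count: int
    detected_count: int
    true_angles: list[float]
    detected_angles: list[float]
    true_lengths: list[float]
    detected_lengths: list[float]
    count_per_perimeter: float


def analyze_single_cell_stack(
    spec: syn.SyntheticStackSpec,
    fragment_threshold: float = 10.0,
) -> tuple[list[seg.CellBody], list[fp.Filopodium], np.ndarray, seg.VolumeImage]:
    """Run segmentation + filopodia extraction on one synthetic stack."""
    image, _ = syn.generate_stack(spec)
    labels = seg.segment_cells(image)
    labels = seg.split_touching(labels, image)
    cells = seg.measure_cells(labels, image.voxel_size)
    kept, _ = seg.filter_fragments(cells, fragment_threshold)
    enhanced = fp.dog_enhance(image)
    skeleton = fp.extract_filaments(enhanced, labels > 0)
    body_labels = np.zeros_like(labels, dtype=np.int32)
    for c in kept:
        body_labels[seg.main_body_mask(labels == c.label, image.voxel_size)] = c.label
    filopodia = fp.identify_filopodia(skeleton, kept, body_labels)
    return kept, filopodia, labels, image


def single_cell_spec(
    filopodia: tuple[syn.FilopodiumSpec, ...],
    body_radius: float = 6.0,
    intensity: float = 100.0,
    gaussian_sd: float = 2.0,
    seed: int = 0,
    voxel_size=STUDY_VOXEL_SIZE,
) -> syn.SyntheticStackSpec:
    """A compact stack holding one cell, sized to its protrusion envelope."""
    max_len = max((f.length for f in filopodia), default=0.0)
    half = body_radius + max_len + 2.0
    center = (half, half, half)
    vs = np.asarray(voxel_size)
    shape = tuple(int(np.ceil(2 * half / v)) + 2 for v in vs)
    cell = syn.SyntheticCellSpec(
        center=center,
        body_radii=(body_radius,) * 3,
        intensity=intensity,
        filopodia=filopodia,
    )
    return syn.SyntheticStackSpec(
        shape=shape,
        voxel_size=tuple(voxel_size),
        cells=(cell,),
        background_level=5.0,
        gaussian_sd=gaussian_sd,
        seed=seed,
    )


def filopodia_condition_study(
    angle_median: float,
    count_mean: float,
    length_median: float,
    n_cells: int,
    seed: int,
    angle_sd: float = 8.0,
    length_sd: float = 0.5,
    gaussian_sd: float = 2.0,
) -> pd.DataFrame:
    """Simulate one condition of single-cell stacks and measure filopodia.

    Per cell: filopodium count ~ Poisson(count_mean) (at least 1), angles
    ~ Normal(angle_median, angle_sd) clipped to [0, 85] deg, lengths
    ~ Normal(length_median, length_sd) clipped at 2 µm.  Returns a tidy
    per-cell frame with generating and measured summaries.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_cells):
        n_filo = max(int(rng.poisson(count_mean)), 1)
        specs = random_filopodia_specs(
            rng, n_filo, angle_median, angle_sd, length_median, length_sd
        )
        body_radius = float(rng.uniform(5.2, 6.2))
        stack = single_cell_spec(
            specs,
            body_radius=body_radius,
            gaussian_sd=gaussian_sd,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        kept, filopodia, _, _ = analyze_single_cell_stack(stack)
        metrics = fp.summarize_filopodia(filopodia, kept)
        m = metrics[0] if metrics else None
        rows.append(
            {
                "cell": i,
                "true_count": len(specs),
                "detected_count": len(filopodia),
                "true_mean_angle": float(np.mean([s.deviation_angle for s in specs])),
                "detected_mean_angle": m.mean_radial_angle if m else float("nan"),
                "true_mean_length": float(np.mean([s.length for s in specs])),
                "detected_mean_length": m.mean_length if m else float("nan"),
                "count_per_perimeter": m.count_per_perimeter if m else float("nan"),
            }
        )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# segmentation conservation study
# --------------------------------------------------------------------------

def random_multicell_spec(seed: int, voxel_size=STUDY_VOXEL_SIZE) -> syn.SyntheticStackSpec:
    """A small stack with 2 well-separated cells and 1-2 fragments."""
    rng = np.random.default_rng(seed)
    extent = np.array([22.0, 46.0, 46.0])
    vs = np.asarray(voxel_size)
    shape = tuple(int(np.ceil(e / v)) + 2 for e, v in zip(extent, vs))
    centers = [np.array([11.0, 12.5, 12.5]), np.array([11.0, 33.0, 33.0])]
    cells = []
    for c in centers:
        radii = rng.uniform(5.2, 6.6, size=3)
        jitter = rng.uniform(-1.5, 1.5, size=3)
        cells.append(
            syn.SyntheticCellSpec(center=tuple(c + jitter), body_radii=tuple(radii))
        )
    frag_centers = [np.array([5.0, 33.0, 11.0]), np.array([17.0, 11.0, 35.0])]
    fragments = [
        syn.FragmentSpec(center=tuple(fc), diameter=float(rng.uniform(3.0, 7.0)))
        for fc in frag_centers[: int(rng.integers(1, 3))]
    ]
    return syn.SyntheticStackSpec(
        shape=shape,
        voxel_size=tuple(voxel_size),
        cells=tuple(cells),
        fragments=tuple(fragments),
        background_level=5.0,
        gaussian_sd=2.0,
        seed=seed,
    )


# --------------------------------------------------------------------------
# track speed / persistence study
# --------------------------------------------------------------------------

def track_recovery_study(
    speeds: dict[str, float],
    persistence: float,
    n_tracks: int,
    n_frames: int,
    dt: float,
    seed: int,
) -> pd.DataFrame:
    """Generate one track ensemble per condition and summarize it."""
    by_condition = {}
    for i, (cond, speed) in enumerate(sorted(speeds.items())):
        spec = syn.SyntheticTrackSpec(
            n_tracks=n_tracks,
            n_frames=n_frames,
            dt=dt,
            mean_speed=speed,
            persistence=persistence,
            seed=seed + i,
        )
        table = syn.generate_tracks(spec)
        by_condition[cond] = mot.tracks_from_table(table, condition=cond)
    summary = mot.summarize_condition(by_condition)
    summary["true_speed"] = [speeds[c] for c in summary.condition]
    return summary


# --------------------------------------------------------------------------
# cluster study
# --------------------------------------------------------------------------

def cluster_recovery_study(
    n_images: int,
    clusters_per_image: int,
    tcells_per_cluster: int,
    seed: int,
    image_size: tuple[int, int] = (400, 400),
    params: syn.ClusterImageParams = syn.ClusterImageParams(),
) -> tuple[list[cl.ClusterSet], list[float]]:
    """Render cluster images on a grid layout and detect clusters in them."""
    rng = np.random.default_rng(seed)
    detected, true_areas = [], []
    extent = (np.asarray(image_size) - 1) * params.pixel_size
    for i in range(n_images):
        specs = []
        margin = params.tumor_radius + 2 * params.tcell_radius + 2
        slots = np.linspace(margin, extent[0] - margin, max(clusters_per_image, 2))
        for k in range(clusters_per_image):
            cx = float(slots[k]) + float(rng.uniform(-2, 2))
            cy = float(rng.uniform(margin, extent[1] - margin))
            specs.append(syn.ClusterSpec((cx, cy), 1, tcells_per_cluster))
        green, red, px, truth = syn.generate_cluster_image(
            n_tumor=2,
            n_tcell=4,
            cluster_spec=specs,
            image_size=image_size,
            seed=int(rng.integers(0, 2**31 - 1)),
            params=params,
        )
        image = cl.TwoChannelImage(green, red, px)
        detected.append(cl.detect_clusters(image))
        true_areas.extend(truth.cluster_areas_um2)
    return detected, true_areas
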