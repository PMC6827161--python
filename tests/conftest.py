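import numpy as np
import pytest

import filotrack as ft


@pytest.fixture(scope="session")
def sphere_stack():
    """Noise-free stack with one 6-µm-radius spherical cell, no filopodia."""
    cell = ft.SyntheticCellSpec(center=(10.0, 10.0, 10.0), body_radii=(6.0, 6.0, 6.0))
    spec = ft.SyntheticStackSpec(
        shape=(68, 81, 81),
        voxel_size=(0.3, 0.25, 0.25),
        cells=(cell,),
        background_level=0.0,
        seed=0,
    )
    image, truth = ft.generate_stack(spec)
    return spec, image, truth


@pytest.fixture(scope="session")
def filopodia_cell_stack():
    """One noisy cell with 5 well-separated filopodia of known geometry."""
    rng = np.random.default_rng(3)
    dirs = []
    while len(dirs) < 5:
        d = rng.normal(size=3)
        d /= np.linalg.norm(d)
        if all(np.degrees(np.arccos(np.clip(d @ e, -1, 1))) > 40 for e in dirs):
            dirs.append(d)
    filos = tuple(
        ft.FilopodiumSpec(
            base_direction=tuple(d),
            deviation_angle=25.0,
            length=5.0,
            azimuth=float(rng.uniform(0, 360)),
        )
        for d in dirs
    )
    cell = ft.SyntheticCellSpec(center=(13.0, 13.0, 13.0), body_radii=(6.0, 6.0, 6.0), filopodia=filos)
    spec = ft.SyntheticStackSpec(
        shape=(88, 105, 105),
        voxel_size=(0.3, 0.25, 0.25),
        cells=(cell,),
        background_level=5.0,
        gaussian_sd=2.0,
        seed=3,
    )
    image, truth = ft.generate_stack(spec)
    return spec, image, truth


def analyze_stack(image, fragment_threshold=10.0):
    """Full segmentation + filopodia pass; shared by several test modules."""
    from filotrack.segmentation import main_body_mask

    labels = ft.segment_cells(image)
    labels = ft.split_touching(labels, image)
    cells = ft.measure_cells(labels, image.voxel_size)
    kept, excluded = ft.filter_fragments(cells, fragment_threshold)
    enhanced = ft.dog_enhance(image)
    skeleton = ft.extract_filaments(enhanced, labels > 0)
    body_labels = np.zeros_like(labels)
    for c in kept:
        body_labels[main_body_mask(labels == c.label, image.voxel_size)] = c.label
    filopodia = ft.identify_filopodia(skeleton, kept, body_labels)
    return labels, cells, kept, excluded, filopodia
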