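"""Segmentation: two-stage thresholding, watershed conservation, physical
measurements, fragment filtering and the Gaussian size fit."""

import numpy as np
import pytest
from scipy import ndimage

import filotrack as ft
from filotrack.segmentation import CellBody, InsufficientDataError


def exhaustive_otsu(values: np.ndarray, nbins: int = 256) -> float:
    """Independent Otsu oracle: brute-force search over histogram bin
    edges minimizing intra-class variance."""
    counts, edges = np.histogram(values, bins=nbins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    best_t, best_var = centers[0], np.inf
    for k in range(1, nbins):
        w0, w1 = counts[:k].sum(), counts[k:].sum()
        if w0 == 0 or w1 == 0:
            continue
        m0 = (counts[:k] * centers[:k]).sum() / w0
        m1 = (counts[k:] * centers[k:]).sum() / w1
        v0 = (counts[:k] * (centers[:k] - m0) ** 2).sum() / w0
        v1 = (counts[k:] * (centers[k:] - m1) ** 2).sum() / w1
        intra = (w0 * v0 + w1 * v1) / (w0 + w1)
        if intra < best_var:
            best_var, best_t = intra, centers[k - 1]
    return float(best_t)


def make_cell(label=1, diam=12.0, axes=(12.0, 12.0, 12.0), perim=40.0):
    vol = np.pi / 6.0 * diam**3
    return CellBody(
        label=label, centroid=(0, 0, 0), volume=vol, equivalent_diameter=diam,
        main_body_perimeter=perim, principal_axis_lengths=axes,
    )


class TestSegmentCells:
    def test_single_sphere_noise_free(self, sphere_stack):
        spec, image, truth = sphere_stack
        labels = ft.segment_cells(image)
        assert labels.max() == 1
        vol = labels.astype(bool).sum() * image.voxel_volume
        shell = 4.0 * np.pi * 6.0**2 * max(spec.voxel_size)
        assert abs(vol - truth.cells[0].volume_um3) < shell

    def test_constant_image_yields_no_labels(self):
        img = ft.VolumeImage(np.zeros((10, 10, 10)), (0.3, 0.25, 0.25))
        assert ft.segment_cells(img).max() == 0

    def test_two_intensity_cells_match_exhaustive_otsu_oracle(self):
        cells = (
            ft.SyntheticCellSpec(center=(9.0, 10.0, 10.0), body_radii=(5.0, 5.0, 5.0), intensity=100.0),
            ft.SyntheticCellSpec(center=(9.0, 10.0, 28.0), body_radii=(5.0, 5.0, 5.0), intensity=40.0),
        )
        spec = ft.SyntheticStackSpec(
            shape=(62, 62, 154), voxel_size=(0.3, 0.25, 0.25), cells=cells,
            background_level=5.0, gaussian_sd=2.0, seed=1,
        )
        image, _ = ft.generate_stack(spec)
        labels = ft.segment_cells(image)
        assert labels.max() == 2

        # per-object oracle: exhaustive Otsu inside each detected bounding box
        for sl in ndimage.find_objects(labels):
            m = 4
            sl = tuple(
                slice(max(s.start - m, 0), min(s.stop + m, dim))
                for s, dim in zip(sl, image.shape)
            )
            crop = image.intensities[sl]
            oracle_mask = crop > exhaustive_otsu(crop)
            ours = labels[sl] > 0
            inter = (oracle_mask & ours).sum()
            union = (oracle_mask | ours).sum()
            assert inter / union > 0.98

    def test_mask_nesting_in_global_candidates(self, filopodia_cell_stack):
        _, image, _ = filopodia_cell_stack
        from skimage.filters import threshold_otsu

        labels = ft.segment_cells(image)
        candidates = image.intensities > threshold_otsu(image.intensities)
        assert not np.any((labels > 0) & ~candidates)


class TestSplitTouching:
    def test_isolated_sphere_idempotent(self, sphere_stack):
        _, image, _ = sphere_stack
        labels = ft.segment_cells(image)
        out = ft.split_touching(labels, image)
        assert np.array_equal(out > 0, labels > 0)
        assert out.max() == labels.max()

    def test_two_overlapping_spheres_split(self):
        cells = (
            ft.SyntheticCellSpec(center=(10.0, 12.0, 12.0), body_radii=(7.0, 7.0, 7.0)),
            ft.SyntheticCellSpec(center=(10.0, 12.0, 24.0), body_radii=(7.0, 7.0, 7.0)),
        )
        spec = ft.SyntheticStackSpec(
            shape=(68, 80, 130), voxel_size=(0.3, 0.25, 0.25), cells=cells,
            background_level=0.0, seed=0,
        )
        image, _ = ft.generate_stack(spec)
        labels = ft.segment_cells(image)
        assert labels.max() == 1  # merged by the 2 µm overlap
        out = ft.split_touching(labels, image)
        assert out.max() == 2
        assert np.array_equal(out > 0, labels > 0)  # voxel-union conserved
        sphere_vol = 4.0 / 3.0 * np.pi * 7.0**3
        for lab in (1, 2):
            vol = (out == lab).sum() * image.voxel_volume
            assert abs(vol - sphere_vol) / sphere_vol < 0.10

    def test_three_cell_chain_centroids(self):
        centers = [(10.0, 12.0, 12.0), (10.0, 12.0, 23.0), (10.0, 12.0, 34.0)]
        cells = tuple(
            ft.SyntheticCellSpec(center=c, body_radii=(6.0, 6.0, 6.0)) for c in centers
        )
        spec = ft.SyntheticStackSpec(
            shape=(68, 80, 186), voxel_size=(0.3, 0.25, 0.25), cells=cells,
            background_level=0.0, seed=5,
        )
        image, truth = ft.generate_stack(spec)
        labels = ft.split_touching(ft.segment_cells(image), image)
        assert labels.max() == 3
        measured = ft.measure_cells(labels, image.voxel_size)
        got = sorted([np.asarray(c.centroid) for c in measured], key=lambda v: v[2])
        want = sorted([np.asarray(t.centroid) for t in truth.cells], key=lambda v: v[2])
        for g, w in zip(got, want):
            assert np.linalg.norm(g - w) < 1.0


class TestMeasureCells:
    def test_sphere_diameter_and_perimeter(self, sphere_stack):
        spec, image, _ = sphere_stack
        labels = ft.segment_cells(image)
        (cell,) = ft.measure_cells(labels, image.voxel_size)
        assert cell.equivalent_diameter == pytest.approx(12.0, abs=0.5)
        assert cell.main_body_perimeter == pytest.approx(2 * np.pi * 6.0, rel=0.05)
        assert cell.polarity_class == "unpolarized"

    def test_volume_is_exact_voxel_count(self, sphere_stack):
        _, image, _ = sphere_stack
        labels = ft.segment_cells(image)
        (cell,) = ft.measure_cells(labels, image.voxel_size)
        assert cell.volume == (labels == 1).sum() * image.voxel_volume  # exact

    def test_ellipsoid_axis_ratio(self):
        c = ft.SyntheticCellSpec(center=(14.0, 12.0, 12.0), body_radii=(10.0, 4.0, 4.0))
        spec = ft.SyntheticStackSpec(
            shape=(96, 100, 100), voxel_size=(0.3, 0.25, 0.25), cells=(c,),
            background_level=0.0, seed=0,
        )
        image, _ = ft.generate_stack(spec)
        (cell,) = ft.measure_cells(ft.segment_cells(image), image.voxel_size)
        major, _, minor = cell.principal_axis_lengths
        assert major / minor == pytest.approx(2.5, rel=0.05)
        assert major == pytest.approx(20.0, rel=0.05)


class TestFragmentFilter:
    def test_boundary_convention(self):
        cells = [make_cell(label=i + 1, diam=d) for i, d in enumerate([5.0, 9.9, 10.0, 12.0])]
        kept, excluded = ft.filter_fragments(cells, threshold=10.0)
        assert sorted(c.equivalent_diameter for c in kept) == [10.0, 12.0]
        assert sorted(c.equivalent_diameter for c in excluded) == [5.0, 9.9]
        assert all(c.is_fragment for c in excluded)
        assert len(kept) + len(excluded) == len(cells)

    def test_empty_input(self):
        assert ft.filter_fragments([]) == ([], [])

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            ft.filter_fragments([], threshold=-1.0)

    def test_generator_stack_counts(self):
        cells = (
            ft.SyntheticCellSpec(center=(10.0, 12.0, 12.0), body_radii=(6.0, 6.0, 6.0)),
            ft.SyntheticCellSpec(center=(10.0, 12.0, 35.0), body_radii=(6.0, 6.0, 6.0)),
        )
        fragments = (
            ft.FragmentSpec(center=(6.0, 30.0, 12.0), diameter=4.0),
            ft.FragmentSpec(center=(14.0, 30.0, 30.0), diameter=6.0),
        )
        spec = ft.SyntheticStackSpec(
            shape=(68, 150, 180), voxel_size=(0.3, 0.25, 0.25), cells=cells,
            fragments=fragments, background_level=5.0, gaussian_sd=2.0, seed=8,
        )
        image, _ = ft.generate_stack(spec)
        labels = ft.split_touching(ft.segment_cells(image), image)
        measured = ft.measure_cells(labels, image.voxel_size)
        kept, excluded = ft.filter_fragments(measured)
        assert len(kept) == 2
        assert len(excluded) == 2


class TestSizeFit:
    def test_three_point_hand_computation(self):
        cells = [make_cell(label=i + 1, diam=d) for i, d in enumerate([12.0, 14.0, 16.0])]
        fit = ft.fit_size_distribution(cells)
        assert fit.mean == pytest.approx(14.0)
        assert fit.sd == pytest.approx(np.sqrt(8.0 / 3.0), abs=1e-6)
        assert fit.n_cells == 3

    def test_insufficient_data(self):
        with pytest.raises(InsufficientDataError):
            ft.fit_size_distribution([make_cell(diam=12.0)])

    def test_parameter_recovery_and_width_ordering(self):
        rng = np.random.default_rng(2)
        diams = rng.normal(15.0, 3.0, size=500).clip(10.1)
        cells = [make_cell(label=i + 1, diam=float(d)) for i, d in enumerate(diams)]
        fit = ft.fit_size_distribution(cells)
        assert fit.mean == pytest.approx(15.0, abs=0.3)
        assert fit.sd == pytest.approx(3.0, abs=0.3)

        narrow = [make_cell(label=i + 1, diam=float(d)) for i, d in enumerate(rng.normal(15, 2, 200))]
        wide = [make_cell(label=i + 1, diam=float(d)) for i, d in enumerate(rng.normal(15, 4, 200))]
        assert ft.fit_size_distribution(narrow).sd < ft.fit_size_distribution(wide).sd


class TestPolarity:
    def test_sphere_unpolarized(self):
        assert ft.classify_polarity(make_cell(axes=(12.0, 12.0, 12.0))) == "unpolarized"

    def test_elongated_polarized_threshold_monotone(self):
        cell = make_cell(axes=(20.0, 8.0, 8.0))
        assert ft.classify_polarity(cell, elongation_threshold=1.5) == "polarized"
        assert ft.classify_polarity(cell, elongation_threshold=3.0) == "unpolarized"

    def test_degenerate_axis_warns_unpolarized(self):
        cell = make_cell(axes=(12.0, 6.0, 0.0))
        with pytest.warns(UserWarning):
            assert ft.classify_polarity(cell) == "unpolarized"
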