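"""Filopodia pipeline: DoG filter properties, skeleton geometry, branch
classification, radial angles and summaries."""

import numpy as np
import pytest
from scipy import ndimage

import filotrack as ft
from filotrack.filopodia import FilamentParams, FilopodiaMetrics, filament_mask
from filotrack.synthetic import _capsule_mask_into
from tests.conftest import analyze_stack


def tube_image(p0, p1, radius=0.4, voxel_size=(0.3, 0.25, 0.25), shape=(60, 80, 80)):
    """Capsule whose total end-to-end extent is |p1 - p0| (caps included)."""
    p0, p1 = np.asarray(p0, float), np.asarray(p1, float)
    d = (p1 - p0) / np.linalg.norm(p1 - p0)
    mask = np.zeros(shape, dtype=bool)
    _capsule_mask_into(mask, p0 + radius * d, p1 - radius * d, radius, voxel_size)
    img = np.where(mask, 100.0, 0.0)
    return ft.VolumeImage(img, voxel_size)


def corrected_tube_length(image):
    """Skeleton geodesic of a bare tube, extended to the rendered tube ends
    by ray-marching along the local axis from each endpoint."""
    enhanced = ft.dog_enhance(image)
    graph = ft.extract_filaments(enhanced)
    branches = graph.branches()
    assert len(branches) == 1
    path = branches[0]
    mask = image.intensities > 50.0  # the rendered tube itself
    vs = np.asarray(image.voxel_size)

    def overhang(end, inner):
        d = graph.physical(end) - graph.physical(inner)
        d /= np.linalg.norm(d)
        s = 0.0
        while True:
            p = graph.physical(end) + (s + 0.05) * d
            idx = np.round(p / vs).astype(int)
            if np.any(idx < 0) or np.any(idx >= mask.shape) or not mask[tuple(idx)]:
                return s
            s += 0.05

    k = min(5, len(path) - 1)
    return (
        graph.path_length(path, smooth=3)
        + overhang(path[0], path[k])
        + overhang(path[-1], path[-1 - k])
    )


class TestDog:
    def test_constant_image_maps_to_zero(self):
        img = ft.VolumeImage(np.full((20, 20, 20), 7.0), (0.3, 0.25, 0.25))
        out = ft.dog_enhance(img)
        assert np.allclose(out.intensities, 0.0, atol=1e-9)

    def test_impulse_response_matches_analytic_kernel(self):
        vs = (0.3, 0.25, 0.25)
        data = np.zeros((41, 41, 41))
        data[20, 20, 20] = 1.0
        out = ft.dog_enhance(ft.VolumeImage(data, vs), 0.4, 1.0).intensities

        zz, yy, xx = np.meshgrid(
            (np.arange(41) - 20) * vs[0],
            (np.arange(41) - 20) * vs[1],
            (np.arange(41) - 20) * vs[2],
            indexing="ij",
        )
        def gauss(s):
            # separable kernel on the voxel grid, normalized per axis
            k = np.exp(-(zz**2 + yy**2 + xx**2) / (2 * s**2))
            return k / (2 * np.pi * s**2) ** 1.5 * np.prod(vs)

        analytic = gauss(0.4) - gauss(1.0)
        assert np.abs(out - analytic).max() < 5e-3 * np.abs(analytic).max() + 1e-4

    def test_linearity(self):
        rng = np.random.default_rng(0)
        vs = (0.3, 0.25, 0.25)
        a = rng.normal(size=(16, 16, 16))
        b = rng.normal(size=(16, 16, 16))
        lhs = ft.dog_enhance(ft.VolumeImage(2 * a + 3 * b, vs)).intensities
        rhs = (
            2 * ft.dog_enhance(ft.VolumeImage(a, vs)).intensities
            + 3 * ft.dog_enhance(ft.VolumeImage(b, vs)).intensities
        )
        assert np.allclose(lhs, rhs, atol=1e-10)

    def test_invalid_sigmas_rejected(self):
        img = ft.VolumeImage(np.zeros((5, 5, 5)), (0.3, 0.25, 0.25))
        with pytest.raises(ValueError):
            ft.dog_enhance(img, 1.0, 0.5)


class TestExtractFilaments:
    def test_empty_stack_gives_empty_graph(self):
        img = ft.VolumeImage(np.zeros((20, 20, 20)), (0.3, 0.25, 0.25))
        graph = ft.extract_filaments(ft.dog_enhance(img))
        assert graph.n_voxels == 0
        assert graph.branches() == []

    def test_axis_aligned_tube_length(self):
        img = tube_image((7.5, 10.0, 5.0), (7.5, 10.0, 13.0))  # 8 µm along x
        assert corrected_tube_length(img) == pytest.approx(8.0, rel=0.05)

    def test_diagonal_tube_length_uses_physical_steps(self):
        L = 8.0 / np.sqrt(2)
        img = tube_image((7.5, 5.0, 5.0), (7.5, 5.0 + L, 5.0 + L))  # 45 deg in-plane
        assert corrected_tube_length(img) == pytest.approx(8.0, rel=0.05)

    def test_oblique_tube_length(self):
        img = tube_image((4.0, 5.0, 5.0), (9.0, 9.0, 11.0))
        analytic = np.linalg.norm([5.0, 4.0, 6.0])
        assert corrected_tube_length(img) == pytest.approx(analytic, rel=0.05)


class TestRadialAngle:
    def test_radial_construction_is_zero(self):
        assert ft.radial_angle((0, 0, 1), base=(0, 0, 5), cell_centroid=(0, 0, 0)) == pytest.approx(0.0)

    def test_tangential_construction_is_ninety(self):
        assert ft.radial_angle((0, 1, 0), base=(0, 0, 5), cell_centroid=(0, 0, 0)) == pytest.approx(90.0)

    def test_zero_direction_rejected(self):
        with pytest.raises(ValueError):
            ft.radial_angle((0, 0, 0), base=(0, 0, 5), cell_centroid=(0, 0, 0))

    def test_angle_always_acute(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            d = rng.normal(size=3)
            b = rng.normal(size=3) * 5
            c = rng.normal(size=3)
            if np.allclose(d, 0) or np.allclose(b, c):
                continue
            a = ft.radial_angle(d, b, c)
            assert 0.0 <= a <= 90.0


class TestIdentifyFilopodia:
    def test_count_recovery_five_filopodia(self, filopodia_cell_stack):
        _, image, truth = filopodia_cell_stack
        _, _, kept, _, filopodia = analyze_stack(image)
        assert len(kept) == 1
        assert len(filopodia) == truth.cells[0].filopodia_count == 5

    def test_lengths_and_angles_recovered(self, filopodia_cell_stack):
        _, image, truth = filopodia_cell_stack
        _, _, _, _, filopodia = analyze_stack(image)
        lengths = np.sort([f.geodesic_length for f in filopodia])
        angles = np.array([f.radial_angle for f in filopodia])
        true_lengths = np.sort(truth.cells[0].filopodia_lengths_um)
        voxel_diag = np.linalg.norm(image.voxel_size)
        assert np.mean(np.abs(lengths - true_lengths)) <= max(0.1 * true_lengths.mean(), voxel_diag)
        assert np.abs(angles - 25.0).mean() < 3.0

    def test_geodesic_at_least_euclidean(self, filopodia_cell_stack):
        _, image, _ = filopodia_cell_stack
        _, _, _, _, filopodia = analyze_stack(image)
        for f in filopodia:
            chord = np.linalg.norm(np.asarray(f.tip) - np.asarray(f.base))
            assert f.geodesic_length >= chord - 1e-9

    def test_interior_branches_discarded(self, sphere_stack):
        _, image, _ = sphere_stack
        _, _, _, _, filopodia = analyze_stack(image)
        assert filopodia == []

    def test_two_cells_assignment(self):
        rng = np.random.default_rng(6)

        def filos(n):
            out = []
            while len(out) < n:
                d = rng.normal(size=3)
                d /= np.linalg.norm(d)
                if all(np.degrees(np.arccos(np.clip(d @ np.asarray(e.base_direction), -1, 1))) > 45 for e in out):
                    out.append(ft.FilopodiumSpec(base_direction=tuple(d), deviation_angle=20.0, length=4.0))
            return tuple(out)

        cells = (
            ft.SyntheticCellSpec(center=(12.0, 12.5, 12.5), body_radii=(5.5, 5.5, 5.5), filopodia=filos(2)),
            ft.SyntheticCellSpec(center=(12.0, 12.5, 37.0), body_radii=(5.5, 5.5, 5.5), filopodia=filos(3)),
        )
        spec = ft.SyntheticStackSpec(
            shape=(82, 102, 200), voxel_size=(0.3, 0.25, 0.25), cells=cells,
            background_level=5.0, gaussian_sd=2.0, seed=6,
        )
        image, _ = ft.generate_stack(spec)
        _, _, kept, _, filopodia = analyze_stack(image)
        assert len(kept) == 2
        by_cell = {}
        for f in filopodia:
            by_cell[f.cell_label] = by_cell.get(f.cell_label, 0) + 1
        label_by_x = sorted(kept, key=lambda c: c.centroid[2])
        assert by_cell[label_by_x[0].label] == 2
        assert by_cell[label_by_x[1].label] == 3

    def test_threshold_monotonicity(self, filopodia_cell_stack):
        _, image, _ = filopodia_cell_stack
        from filotrack.segmentation import main_body_mask

        labels = ft.segment_cells(image)
        cells = ft.measure_cells(labels, image.voxel_size)
        kept, _ = ft.filter_fragments(cells)
        body_labels = np.zeros_like(labels)
        for c in kept:
            body_labels[main_body_mask(labels == c.label, image.voxel_size)] = c.label
        enhanced = ft.dog_enhance(image)
        counts = []
        for scale in (0.5, 1.0, 2.0, 4.0):
            graph = ft.extract_filaments(
                enhanced, params=FilamentParams(threshold_scale=scale)
            )
            counts.append(len(ft.identify_filopodia(graph, kept, body_labels)))
        assert counts == sorted(counts, reverse=True)

    def test_rotation_invariance_quarter_turn(self, filopodia_cell_stack):
        _, image, _ = filopodia_cell_stack
        rotated = ft.VolumeImage(np.rot90(image.intensities, axes=(1, 2)).copy(), image.voxel_size)
        _, _, _, _, f0 = analyze_stack(image)
        _, _, _, _, f1 = analyze_stack(rotated)
        a0 = np.sort([f.radial_angle for f in f0])
        a1 = np.sort([f.radial_angle for f in f1])
        assert len(a0) == len(a1)
        assert np.abs(a0 - a1).max() < 3.0


class TestSummaries:
    def test_per_cell_arithmetic(self):
        from tests.test_segmentation import make_cell

        cell = make_cell(label=1, perim=50.0)
        filopodia = [
            ft.Filopodium(cell_label=1, base=(0, 0, 6), tip=(0, 0, 10), geodesic_length=4.0,
                          direction=(0, 0, 1), radial_angle=10.0),
            ft.Filopodium(cell_label=1, base=(0, 6, 0), tip=(0, 12, 0), geodesic_length=6.0,
                          direction=(0, 1, 0), radial_angle=20.0),
        ]
        (m,) = ft.summarize_filopodia(filopodia, [cell])
        assert m.count == 2
        assert m.count_per_perimeter == pytest.approx(0.04)
        assert m.mean_length == pytest.approx(5.0)
        assert m.mean_radial_angle == pytest.approx(15.0)

    def test_zero_count_flags(self):
        from tests.test_segmentation import make_cell

        (m,) = ft.summarize_filopodia([], [make_cell(perim=50.0)])
        assert m.count == 0
        assert m.count_per_perimeter == 0.0
        assert np.isnan(m.mean_length) and np.isnan(m.mean_radial_angle)

    def test_condition_table_all_zero_condition(self):
        metrics = [
            FilopodiaMetrics(cell_label=i, count=0, count_per_perimeter=0.0,
                             mean_length=float("nan"), mean_radial_angle=float("nan"))
            for i in range(4)
        ]
        table = ft.condition_table({"quiet": metrics})
        row = table.iloc[0]
        assert row.median_count_per_perimeter == 0.0
        assert np.isnan(row.median_angle_deg)
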