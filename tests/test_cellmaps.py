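import numpy as np
import pytest

from sptconfine.cellmaps import (NORM_LENGTH, NORM_WIDTH, confined_free_maps,
                                 normalize_coordinates, normalize_dataset,
                                 one_dim_probability, randomize_poles,
                                 speed_map, split_by_cell_size, spot_heatmap)
from sptconfine.confinement import ConfinementConfig
from sptconfine.core import CellGeometry, TrackDataset
from sptconfine.simulate import (ConfinedZoneConfig, LifetimeModel,
                                 SimulationConfig, simulate_confined_mixture)

from .conftest import TAU, make_track


def cell(length=2.0, width=1.0, origin=(5.0, 5.0), axis=(1.0, 0.0)):
    return CellGeometry("c0", length, width, origin, axis)


class TestNormalization:
    def test_centroid_maps_to_center(self):
        t = make_track([[5.0, 5.0], [5.0, 5.0]], cell_id="c0")
        n = normalize_coordinates(t, cell())
        np.testing.assert_allclose(n.xy, [[1.5, 0.5], [1.5, 0.5]])

    def test_pole_maps_to_extreme(self):
        t = make_track([[4.0, 5.0], [6.0, 5.0]], cell_id="c0")
        n = normalize_coordinates(t, cell())
        assert n.xy[0, 0] == pytest.approx(0.0)
        assert n.xy[1, 0] == pytest.approx(NORM_LENGTH)

    def test_linear_scaling_off_pole(self):
        # 4 um cell, point 1 um from the pole: quarter length -> u = 0.75
        t = make_track([[-1.0, 0.0], [0.0, 0.0]], cell_id="c0")
        n = normalize_coordinates(t, cell(length=4.0, origin=(0.0, 0.0)))
        assert n.xy[0, 0] == pytest.approx(0.75)

    def test_rotated_cell_axis(self):
        t = make_track([[0.0, 1.0], [0.0, -1.0]], cell_id="c0")
        n = normalize_coordinates(t, cell(length=4.0, origin=(0, 0), axis=(0, 1)))
        assert n.xy[0, 0] == pytest.approx(2.25)
        assert n.xy[1, 0] == pytest.approx(0.75)

    def test_outside_points_clip_with_warning(self):
        t = make_track([[10.0, 5.0], [5.0, 5.0]], cell_id="c0")
        with pytest.warns(UserWarning, match="clipped"):
            n = normalize_coordinates(t, cell())
        assert n.xy[:, 0].max() <= NORM_LENGTH


class TestSpotMap:
    def test_counts_conserved_and_single_bin(self, meta):
        t = make_track([[1.0, 0.5]] * 3 + [[1.0, 0.5]], cell_id="c0")
        ds = TrackDataset([t], meta)
        hm = spot_heatmap(ds)
        assert hm.total == 4
        assert (hm.values > 0).sum() == 1

    def test_union_additivity(self, rng, meta):
        def ds(n, seed):
            r = np.random.default_rng(seed)
            tracks = [make_track(np.column_stack([r.uniform(0, 3, 5),
                                                  r.uniform(0, 1, 5)]),
                                 track_id=f"t{seed}{i}") for i in range(n)]
            return TrackDataset(tracks, meta)
        a, b = ds(10, 1), ds(12, 2)
        union = TrackDataset(a.trajectories + b.trajectories, meta)
        np.testing.assert_array_equal(
            spot_heatmap(union).values,
            spot_heatmap(a).values + spot_heatmap(b).values)

    def test_mirror_symmetry(self, meta):
        r = np.random.default_rng(3)
        xy = np.column_stack([r.uniform(0, 3, 40), r.uniform(0, 1, 40)])
        t1 = make_track(xy)
        t2 = make_track(np.column_stack([NORM_LENGTH - xy[:, 0],
                                         NORM_WIDTH - xy[:, 1]]))
        h1 = spot_heatmap(TrackDataset([t1], meta))
        h2 = spot_heatmap(TrackDataset([t2], meta))
        np.testing.assert_array_equal(h1.values, h2.values[::-1, ::-1])


class TestSpeedMap:
    def test_constant_step_closed_form(self, meta):
        # all steps 0.2 um long: every occupied bin reads d^2/(4 tau)
        xy = np.column_stack([0.5 + np.arange(6) * 0.2, np.full(6, 0.5)])
        ds = TrackDataset([make_track(xy)], meta)
        hm = speed_map(ds, bin_area=0.1)
        vals = hm.values[~np.isnan(hm.values)]
        np.testing.assert_allclose(vals, 0.2**2 / (4 * TAU), rtol=1e-12)

    def test_zero_steps_give_zero(self, meta):
        ds = TrackDataset([make_track([[1.0, 0.5]] * 4)], meta)
        hm = speed_map(ds)
        vals = hm.values[~np.isnan(hm.values)]
        np.testing.assert_array_equal(vals, 0.0)

    def test_grid_bins_have_requested_area(self, meta):
        ds = TrackDataset([make_track([[1.0, 0.5], [1.1, 0.5]])], meta)
        hm = speed_map(ds, bin_area=0.1)
        assert hm.bin_area == pytest.approx(0.1)

    def test_order_invariance(self, meta):
        r = np.random.default_rng(4)
        tracks = [make_track(np.column_stack([r.uniform(0, 3, 6),
                                              r.uniform(0, 1, 6)]),
                             track_id=f"t{i}") for i in range(8)]
        h1 = speed_map(TrackDataset(tracks, meta))
        h2 = speed_map(TrackDataset(tracks[::-1], meta))
        np.testing.assert_allclose(h1.values, h2.values, equal_nan=True)


class TestSizeClasses:
    def make_ds(self, lengths, meta):
        cells = {f"c{i}": CellGeometry(f"c{i}", L, 1.0) for i, L in enumerate(lengths)}
        tracks = [make_track(np.zeros((3, 2)), track_id=f"t{i}", cell_id=f"c{i}")
                  for i in range(len(lengths))]
        return TrackDataset(tracks, meta, cells)

    def test_one_cell_per_class(self, meta):
        classes, per = split_by_cell_size(self.make_ds([2.0, 3.0, 4.0], meta))
        assert classes.trajectory_counts == {"small": 1, "medium": 1, "large": 1}

    def test_degenerate_lengths_single_class(self, meta):
        with pytest.warns(UserWarning, match="single size class"):
            classes, per = split_by_cell_size(self.make_ds([3.0, 3.0, 3.0], meta))
        assert classes.degenerate

    def test_tercile_counts(self, meta):
        lengths = list(np.linspace(2.0, 4.0, 30))
        classes, per = split_by_cell_size(self.make_ds(lengths, meta))
        for n in classes.trajectory_counts.values():
            assert abs(n - 10) <= 1


@pytest.fixture(scope="module")
def trap_dataset():
    cfg = SimulationConfig(n_tracks=250, seed=20,
                           lifetime=LifetimeModel("geometric", 12, 60))
    zones = ConfinedZoneConfig(depth=0.5, D_inside=0.008,
                               p_escape=0.02, p_trap=0.7)
    return simulate_confined_mixture(cfg, zones)


class TestConfinedFreeMaps:

    def test_partition_conservation(self, trap_dataset):
        cfg = ConfinementConfig(radius=0.13, min_steps=5)
        conf, free = confined_free_maps(trap_dataset, cfg)
        total = sum(len(t) for t in trap_dataset)
        assert conf.total + free.total == total

    def test_only_free_tracks_empty_confined_map(self, meta):
        tracks = [make_track(np.column_stack([np.arange(8) * 0.4,
                                              np.full(8, 0.5)]),
                             track_id=f"t{i}") for i in range(5)]
        cfg = ConfinementConfig(radius=0.05, min_steps=5)
        conf, free = confined_free_maps(TrackDataset(tracks, meta), cfg)
        assert conf.total == 0
        assert free.total == sum(len(t) for t in tracks)

    def test_polar_traps_enrich_confined_map(self, trap_dataset):
        cfg = ConfinementConfig(radius=0.13, min_steps=5)
        conf, free = confined_free_maps(trap_dataset, cfg)
        u_mid = 0.5 * (conf.u_edges[:-1] + conf.u_edges[1:])
        polar = (u_mid < 0.5) | (u_mid > 2.5)
        conf_polar = conf.values[:, polar].sum() / max(conf.total, 1)
        free_polar = free.values[:, polar].sum() / max(free.total, 1)
        assert conf_polar > 1 / 3 > free_polar


class TestOneDimProfile:
    def test_integrates_to_one(self, meta):
        r = np.random.default_rng(5)
        tracks = [make_track(np.column_stack([r.uniform(0, 3, 10),
                                              r.uniform(0, 1, 10)]),
                             track_id=f"t{i}") for i in range(20)]
        u, dens = one_dim_probability(TrackDataset(tracks, meta))
        width = u[1] - u[0]
        assert np.sum(dens) * width == pytest.approx(1.0)

    def test_polar_data_is_bimodal(self, meta):
        xy = np.array([[0.05, 0.5], [2.95, 0.5]] * 20)
        u, dens = one_dim_probability(TrackDataset([make_track(xy)], meta))
        assert dens[0] > 0 and dens[-1] > 0
        assert np.all(dens[10:20] == 0)


def test_normalize_dataset_and_pole_randomization(meta):
    cells = {"c0": CellGeometry("c0", 2.0, 1.0, (0, 0), (1, 0)),
             "c1": CellGeometry("c1", 3.0, 1.0, (10, 10), (0, 1))}
    tracks = [make_track([[0.5, 0.0], [0.6, 0.1]], track_id="a", cell_id="c0"),
              make_track([[10.0, 11.0], [10.1, 11.2]], track_id="b", cell_id="c1")]
    ds = normalize_dataset(TrackDataset(tracks, meta, cells))
    for t in ds:
        assert np.all((t.xy[:, 0] >= 0) & (t.xy[:, 0] <= NORM_LENGTH))
        assert np.all((t.xy[:, 1] >= 0) & (t.xy[:, 1] <= NORM_WIDTH))
    flipped = randomize_poles(ds, seed=0)
    assert len(flipped) == len(ds)
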