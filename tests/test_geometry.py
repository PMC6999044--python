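"""Nerve-net geometry: intersections, delays, statistics, cuts."""

import numpy as np
import pytest
from scipy import stats

import moonjelly as mj
from moonjelly.errors import UndefinedStatisticError
from moonjelly.geometry import find_synapses


class TestSegmentIntersections:
    def test_perpendicular_crossing_yields_one_synapse(self, two_neuron_net):
        net = two_neuron_net
        assert net.n_synapses == 1
        np.testing.assert_allclose(net.syn_xy[0], [0.1, 0.0], atol=1e-12)
        assert net.syn_delay[0] == pytest.approx(0.9)

    def test_parallel_segments_yield_no_synapse(self):
        net = mj.NerveNet.from_segments([[0, 0], [0, 0.1]], [0.0, 0.0], 0.5)
        assert net.n_synapses == 0

    def test_coincident_somata_give_minimum_delay(self):
        net = mj.NerveNet.from_segments([[0, 0], [0, 0]], [0.0, np.pi / 2],
                                        0.5)
        assert net.syn_delay[0] == pytest.approx(0.5)

    def test_far_end_contact_gives_maximum_delay(self):
        # intersection at a segment endpoint of both neurons: 0.25 cm each
        net = mj.NerveNet.from_segments([[0, 0], [0.25, 0.25]],
                                        [0.0, np.pi / 2], 0.5)
        assert net.n_synapses == 1
        assert net.syn_delay[0] == pytest.approx(1.5)

    def test_spatial_hash_matches_brute_force(self):
        net = mj.build_mnn(500, seed=7)
        ref = find_synapses(net.e0, net.e1, net.soma, brute_force=True)
        np.testing.assert_array_equal(ref["syn_i"], net.syn_i)
        np.testing.assert_array_equal(ref["syn_j"], net.syn_j)
        np.testing.assert_allclose(ref["syn_delay"], net.syn_delay)


class TestOrientationSampling:
    def test_uniform_at_the_offset_distance(self):
        rng = np.random.default_rng(0)
        phi = mj.sample_orientation(np.full(10_000, 0.5), 0.0, rng)
        u = (np.mod(phi, 2 * np.pi)) / (2 * np.pi)
        assert stats.kstest(u, "uniform").pvalue > 0.01

    def test_concentration_grows_with_distance(self):
        from scipy.optimize import brentq
        from scipy.special import i0, i1

        rng = np.random.default_rng(1)
        phi = mj.sample_orientation(np.full(100_000, 2.0), 0.0, rng)
        # circular mean ~ 0 and moment-estimated kappa ~ 8*(2-0.5) = 12
        z = np.exp(1j * phi)
        assert abs(np.angle(z.mean())) < 0.05
        rbar = abs(z.mean())
        kappa = brentq(lambda k: i1(k) / i0(k) - rbar, 1e-6, 100.0)
        assert kappa == pytest.approx(12.0, rel=0.12)

    def test_density_normalizes_to_one(self):
        from scipy.integrate import quad

        total, _ = quad(lambda x: mj.von_mises_density(x, 1.0, 0.3),
                        -np.pi, np.pi)
        assert total == pytest.approx(1.0, rel=1e-8)


class TestBuilders:
    def test_soma_positions_uniform_on_annulus(self):
        net = mj.build_mnn(10_008, seed=3, orientation="uniform")
        r = np.linalg.norm(net.soma[8:], axis=1)  # exclude fixed pacemakers
        th = np.mod(np.arctan2(net.soma[8:, 1], net.soma[8:, 0]), 2 * np.pi)
        # uniform on the annulus area <=> r^2 uniform on [r_in^2, r_out^2]
        u = (r**2 - 0.25) / (4.0 - 0.25)
        assert stats.kstest(u, "uniform").pvalue > 0.01
        assert stats.kstest(th / (2 * np.pi), "uniform").pvalue > 0.01

    def test_pacemakers_regular_on_outer_edge(self, small_mnn):
        pm = small_mnn.soma[small_mnn.pacemakers]
        np.testing.assert_allclose(np.linalg.norm(pm, axis=1), 2.0)
        ang = np.arctan2(pm[:, 1], pm[:, 0])
        np.testing.assert_allclose(np.diff(np.unwrap(ang)), np.pi / 4,
                                   atol=1e-12)

    def test_mnn_delays_within_printed_range(self):
        net = mj.build_mnn(2000, seed=0)
        assert net.syn_delay.min() >= 0.5
        assert net.syn_delay.max() <= 1.5

    def test_dnn_delays_within_short_neurite_range(self):
        net = mj.build_dnn(2000, seed=0)
        assert net.syn_delay.min() >= 0.5
        assert net.syn_delay.max() <= 0.9

    def test_synapse_delay_symmetric_per_pair(self):
        net = mj.build_mnn(300, seed=2)
        # one synapse per unordered pair, so delays are pairwise constants
        pairs = set(zip(net.syn_i.tolist(), net.syn_j.tolist()))
        assert len(pairs) == net.n_synapses
        assert np.all(net.syn_i < net.syn_j)

    def test_dnn_extends_quarter_cm_beyond_mnn(self):
        net = mj.build_dnn(3000, seed=1)
        r = np.linalg.norm(net.soma, axis=1)
        assert r.max() <= 2.25 + 1e-12
        assert r.max() > 2.0  # uses the margin band

    def test_dnn_orientation_uniform_by_default(self):
        net = mj.build_dnn(10_008, seed=4)
        phi = np.mod(net.angle[8:], 2 * np.pi)
        counts, _ = np.histogram(phi, bins=20, range=(0, 2 * np.pi))
        assert stats.chisquare(counts).pvalue > 0.01

    def test_von_mises_nets_sparser_than_uniform(self):
        vm, un = [], []
        for seed in range(10):
            vm.append(mj.build_mnn(2000, orientation="von_mises",
                                   seed=seed).n_synapses)
            un.append(mj.build_mnn(2000, orientation="uniform",
                                   seed=seed).n_synapses)
        assert np.mean(vm) < np.mean(un)

    def test_too_few_neurons_rejected(self):
        with pytest.raises(ValueError):
            mj.build_mnn(1)

    def test_smaller_bell_scales_radii(self):
        net = mj.build_mnn(500, diameter=3.0, seed=0)
        r = np.linalg.norm(net.soma[8:], axis=1)
        assert r.max() <= 1.5 + 1e-12
        assert r.min() >= 0.375 - 1e-12


class TestStatistics:
    def test_mean_synapses_per_neuron_small_cases(self):
        net = mj.NerveNet.from_segments([[0, 0], [0, 0.1]], [0.0, 0.0], 0.5)
        assert mj.mean_synapses_per_neuron(net) == 0.0
        # triangle of three mutually crossing segments
        tri = mj.NerveNet.from_segments(
            [[0, 0], [0.2, 0], [0.1, 0.15]],
            [np.pi / 3, 2 * np.pi / 3, 0.0], 0.5)
        assert tri.n_synapses == 3
        assert mj.mean_synapses_per_neuron(tri) == 2.0

    def test_intersynaptic_distance_on_constructed_fixture(self):
        # neuron 0 horizontal, crossed at 1, 2, 3 mm from its left end
        soma = [[0.25, 0.0], [0.1, 0.0], [0.2, 0.0], [0.3, 0.0]]
        angle = [0.0, np.pi / 2, np.pi / 2, np.pi / 2]
        net = mj.NerveNet.from_segments(soma, angle, [0.5, 0.1, 0.1, 0.1])
        assert net.n_synapses == 3
        assert mj.mean_intersynaptic_distance(net) == pytest.approx(1000.0)
        assert mj.mean_intersynaptic_distance(
            net, per_neuron=True) == pytest.approx(1000.0)

    def test_undefined_without_two_synapses_on_a_neuron(self):
        net = mj.NerveNet.from_segments([[0, 0], [0, 0.1]], [0.0, 0.0], 0.5)
        with pytest.raises(UndefinedStatisticError):
            mj.mean_intersynaptic_distance(net)


class TestCuts:
    def test_cut_missing_everything_is_identity(self, small_mnn):
        cut = mj.apply_cut(small_mnn, [mj.CutLine((10, 10), (11, 11))])
        np.testing.assert_array_equal(cut.e0, small_mnn.e0)
        np.testing.assert_array_equal(cut.e1, small_mnn.e1)
        assert cut.n_synapses == small_mnn.n_synapses

    def test_cut_removes_distal_part_and_its_synapses(self):
        # horizontal neuron crossed by two verticals at +/- 1.5 mm
        soma = [[0.0, 0.0], [0.15, 0.0], [-0.15, 0.0]]
        angle = [0.0, np.pi / 2, np.pi / 2]
        net = mj.NerveNet.from_segments(soma, angle, [0.5, 0.1, 0.1])
        assert net.n_synapses == 2
        # cut just right of the soma: right half of neuron 0 dies
        cut_net = mj.apply_cut(net, [mj.CutLine((0.01, -1), (0.01, 1))])
        assert cut_net.n_synapses == 1
        assert cut_net.syn_xy[0, 0] == pytest.approx(-0.15)
        np.testing.assert_allclose(cut_net.e1[0], [0.01, 0.0], atol=1e-12)
        # delays of surviving synapses unchanged
        assert cut_net.syn_delay[0] == net.syn_delay[net.syn_xy[:, 0] < 0][0]

    def test_octagon_with_gap_keeps_center_reachable(self):
        from moonjelly.wave import reachable_component

        net = mj.build_mnn(2000, seed=0)
        cut_net = mj.apply_cut(net, mj.octagon_cuts())
        reach = reachable_component(cut_net, [cut_net.pacemakers[0]])
        r = np.linalg.norm(cut_net.soma[reach], axis=1)
        assert (r < 0.8).sum() > 50  # wave path into the central disc exists
        assert reach.size > 0.9 * net.n_neurons

    def test_validation_of_cut_lines(self):
        with pytest.raises(ValueError):
            mj.CutLine((0, 0), (0, 0))
        with pytest.raises(ValueError):
            mj.CutLine((np.nan, 0), (1, 1))

    def test_cut_csv_round_trip(self, tmp_path):
        cuts = mj.radial_cuts()
        mj.save_cuts(tmp_path / "cuts.csv", cuts)
        back = mj.geometry.read_cuts(tmp_path / "cuts.csv")
        assert len(back) == len(cuts)
        np.testing.assert_allclose(back[3].p0, cuts[3].p0)


def test_net_serialization_round_trips(tmp_path, small_mnn):
    small_mnn.save_hdf5(tmp_path / "net.h5")
    back = mj.NerveNet.load_hdf5(tmp_path / "net.h5")
    np.testing.assert_array_equal(back.soma, small_mnn.soma)
    np.testing.assert_array_equal(back.syn_delay, small_mnn.syn_delay)
    assert back.kind == small_mnn.kind
    small_mnn.save_csv(tmp_path / "net")
    import pandas as pd

    ndf = pd.read_csv(tmp_path / "net.neurons.csv")
    assert ndf.is_pacemaker.sum() == 8
    assert len(ndf) == small_mnn.n_neurons
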