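"""RDF estimator, Boltzmann inversion, PMF features, concentration accounting."""

import numpy as np
import pytest

from nanocolloid import (
    Box,
    Environment,
    ParticleConfiguration,
    PMFCurve,
    RDFCurve,
    compute_rdf,
    number_concentration,
    pmf_features,
    rdf_to_pmf,
)

SIGMA = 7.0


def brute_force_counts(positions, box, edges):
    """All-pairs double loop with explicit half-open binning (test oracle)."""
    n = len(positions)
    counts = np.zeros(len(edges) - 1, dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            delta = positions[i] - positions[j]
            for k in range(3):
                if box.periodic[k]:
                    delta[k] -= box.lengths[k] * round(delta[k] / box.lengths[k])
            d = float(np.sqrt(np.sum(delta * delta)))
            for b in range(len(edges) - 1):
                if edges[b] <= d < edges[b + 1]:
                    counts[b] += 1
                    break
    return counts


class TestComputeRDF:
    def test_complete_spatial_randomness_gives_unity(self, rng):
        # 1e4 uniform points: g = 1 within 3 Poisson SE in >= 99% of bins
        L = 200.0
        pts = rng.uniform(0, L, size=(10_000, 3))
        config = ParticleConfiguration(positions=pts, box=Box.cube(L))
        rdf = compute_rdf(config, bin_width=2.0, r_max=90.0)
        expected = np.where(rdf.g > 0, rdf.pair_counts / np.where(rdf.g > 0, rdf.g, 1), 0)
        se = 3.0 / np.sqrt(np.maximum(expected, 1.0))
        ok = np.abs(rdf.g - 1.0) <= se
        assert ok.mean() >= 0.99

    def test_single_pair_lands_in_its_bin(self):
        d = 13.7
        pts = np.array([[50.0, 50.0, 50.0], [50.0 + d, 50.0, 50.0]])
        config = ParticleConfiguration(positions=pts, box=Box.cube(200.0))
        rdf = compute_rdf(config, bin_width=1.0, r_max=50.0)
        hit = np.nonzero(rdf.pair_counts)[0]
        assert len(hit) == 1
        assert rdf.bin_edges[hit[0]] <= d < rdf.bin_edges[hit[0] + 1]

    def test_hard_core_region_is_empty(self, hard_sphere_frames):
        frames, _, cfg = hard_sphere_frames
        rdf = compute_rdf(frames[0], bin_width=SIGMA / 20,
                          r_max=min(cfg.box.lengths) / 2 * 0.99)
        below = rdf.bin_edges[1:] <= SIGMA
        assert np.all(rdf.g[below] == 0.0)

    def test_long_range_normalization(self, hard_sphere_frames):
        frames, _, cfg = hard_sphere_frames
        rdf = compute_rdf(frames[-1], bin_width=SIGMA / 20,
                          r_max=min(cfg.box.lengths) / 2 * 0.99)
        r = rdf.bin_centers
        tail = rdf.g[r > 0.8 * r.max()]
        assert 0.95 <= tail.mean() <= 1.05

    @pytest.mark.parametrize("box", [
        Box.cube(60.0),
        Box.slab(60.0, 60.0, 35.0),
        Box((50.0, 60.0, 40.0), (False, False, False)),
    ], ids=["periodic", "slab", "walls"])
    def test_estimator_matches_brute_force_counts(self, box, rng):
        pts = rng.uniform(0, 1, size=(120, 3)) * np.asarray(box.lengths)
        config = ParticleConfiguration(positions=pts, box=box)
        rdf = compute_rdf(config, bin_width=1.5, r_max=20.0)
        oracle = brute_force_counts(pts.copy(), box, rdf.bin_edges)
        np.testing.assert_array_equal(rdf.pair_counts, oracle)

    def test_slab_edge_correction_recovers_unity(self, rng):
        # uniform points in a thin slab: analytic wall correction must give g = 1
        box = Box.slab(150.0, 150.0, 40.0)
        pts = rng.uniform(0, 1, size=(6000, 3)) * np.asarray(box.lengths)
        config = ParticleConfiguration(positions=pts, box=box)
        rdf = compute_rdf(config, bin_width=2.0, r_max=50.0)
        expected = rdf.pair_counts / np.where(rdf.g > 0, rdf.g, 1)
        se = 3.0 / np.sqrt(np.maximum(expected, 1.0))
        assert (np.abs(rdf.g - 1.0) <= se).mean() >= 0.98

    def test_r_max_beyond_half_box_rejected(self):
        config = ParticleConfiguration(
            positions=np.array([[1.0, 1, 1], [5.0, 5, 5]]), box=Box.cube(50.0))
        with pytest.raises(ValueError, match="half"):
            compute_rdf(config, bin_width=1.0, r_max=30.0)

    def test_fewer_than_two_particles_rejected(self):
        config = ParticleConfiguration(positions=np.array([[1.0, 1, 1]]),
                                       box=Box.cube(50.0))
        with pytest.raises(ValueError):
            compute_rdf(config, bin_width=1.0, r_max=20.0)


class TestBoltzmannInversion:
    def make_rdf(self, g):
        g = np.asarray(g, dtype=float)
        edges = np.arange(len(g) + 1, dtype=float)
        counts = np.round(g * 100).astype(int)
        return RDFCurve(bin_edges=edges, g=g, pair_counts=counts,
                        n_particles=10, number_concentration=1e22)

    def test_reference_values(self):
        pmf = rdf_to_pmf(self.make_rdf([1.0, np.exp(-2.0), 0.0]))
        assert pmf.W[0] == 0.0
        assert pmf.W[1] == pytest.approx(2.0, abs=1e-15)
        assert np.isinf(pmf.W[2])

    def test_round_trip_identity_on_support(self, rng):
        g = np.concatenate([[0.0, 0.0], rng.uniform(0.01, 3.0, 40)])
        rdf = self.make_rdf(g)
        pmf = rdf_to_pmf(rdf, Environment())
        back = pmf.g()
        np.testing.assert_array_equal(back[g > 0], np.exp(-(-np.log(g[g > 0]))))
        np.testing.assert_allclose(back[g > 0], g[g > 0], rtol=1e-15)
        assert np.all(back[g == 0] == 0.0)


class TestPMFFeatures:
    def constructed(self):
        # well -3 kT at 7 nm, barrier +1 kT at 20 nm, shallow dip at 35 nm
        r = np.arange(0.5, 60, 0.5)
        W = (-3.0 * np.exp(-((r - 7) / 2.5) ** 2)
             + 1.0 * np.exp(-((r - 20) / 4.0) ** 2)
             - 0.2 * np.exp(-((r - 35) / 4.0) ** 2))
        W[r < 6.0] = np.inf
        return PMFCurve(bin_centers=r, W=W, temperature_K=293.15)

    def test_constructed_well_barrier_geometry(self):
        f = pmf_features(self.constructed(), smoothing_window=3)
        assert f.has_well
        assert f.well_position == pytest.approx(7.0, abs=1.0)
        assert f.well_depth == pytest.approx(-3.0, abs=0.15)
        assert f.barrier_position == pytest.approx(20.0, abs=1.0)
        assert f.barrier_height == pytest.approx(1.0, abs=0.1)
        assert f.barrier_minus_well == pytest.approx(4.0, abs=0.25)
        assert f.secondary_minimum_position == pytest.approx(35.0, abs=1.5)

    def test_monotone_repulsive_profile_has_no_well(self):
        r = np.arange(0.5, 40, 0.5)
        W = 5.0 * np.exp(-r / 5.0)
        W[r < 6.0] = np.inf
        f = pmf_features(PMFCurve(bin_centers=r, W=W, temperature_K=293.15))
        assert not f.has_well
        assert f.well_position is None

    def test_constant_shift_moves_heights_not_positions(self):
        base = pmf_features(self.constructed())
        shifted_curve = self.constructed()
        shifted = pmf_features(PMFCurve(bin_centers=shifted_curve.bin_centers,
                                        W=shifted_curve.W + 2.5,
                                        temperature_K=293.15))
        assert shifted.well_position == base.well_position
        assert shifted.barrier_position == base.barrier_position
        assert shifted.well_depth == pytest.approx(base.well_depth + 2.5, abs=1e-9)
        assert shifted.barrier_height == pytest.approx(base.barrier_height + 2.5, abs=1e-9)
        assert shifted.barrier_minus_well == pytest.approx(base.barrier_minus_well, abs=1e-9)


class TestNumberConcentration:
    def test_reference_value(self):
        pts = np.zeros((1350, 3))
        config = ParticleConfiguration(positions=pts, box=Box.cube(300.0))
        assert number_concentration(config) == pytest.approx(5.0e22, rel=1e-12)

    def test_empty_configuration(self):
        config = ParticleConfiguration(positions=np.empty((0, 3)), box=Box.cube(100.0))
        assert number_concentration(config) == 0.0

    def test_scales_inversely_with_volume(self):
        pts = np.zeros((10, 3))
        c1 = number_concentration(ParticleConfiguration(pts, Box.cube(100.0)))
        c2 = number_concentration(ParticleConfiguration(pts, Box.cube(200.0)))
        assert c1 == pytest.approx(8.0 * c2, rel=1e-12)
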