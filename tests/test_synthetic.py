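import numpy as np
import pandas as pd
import pytest

from depthzone import SimulationConfig, generate_community, generate_effort, recovery_score
from depthzone.cluster_zone import DepthZoneAssignment
from depthzone.errors import ConfigurationError, ContractError
from depthzone.synthetic_reef import SpeciesNiche


class TestConfig:
    def test_invalid_depth_range_rejected(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(depth_range=(40, 600)).validate()
        with pytest.raises(ConfigurationError):
            SimulationConfig(depth_range=(45, 300)).validate()

    def test_zone_spans_are_bin_aligned_and_cover_range(self):
        cfg = SimulationConfig()
        spans = cfg.zone_spans()
        assert spans[0][0] == 40 and spans[-1][1] == 290
        assert all(lo % 10 == 0 and hi % 10 == 0 for lo, hi in spans)


class TestEffort:
    def test_zero_dispersion_gives_constant_hours(self):
        eff = generate_effort(SimulationConfig(effort_dispersion=0.0, seed=4))
        assert (eff["hours"] == 2.0).all()

    def test_determinism(self):
        cfg = SimulationConfig(seed=9)
        pd.testing.assert_frame_equal(generate_effort(cfg), generate_effort(cfg))

    def test_sample_mean_matches_configured_mean(self):
        cfg = SimulationConfig(
            n_sites=8, depth_range=(0, 500), effort_dispersion=0.5,
            effort_mean_hours=2.0, seed=2,
        )
        eff = generate_effort(cfg)
        assert len(eff) >= 400
        assert eff["hours"].mean() == pytest.approx(2.0, rel=0.10)


class TestCommunity:
    def test_zero_intensity_yields_empty_table(self):
        cfg = SimulationConfig(base_intensity_mean=0.0, seed=1)
        data = generate_community(cfg)
        assert data.observations.empty

    def test_determinism_bit_for_bit(self):
        cfg = SimulationConfig(seed=21)
        a, b = generate_community(cfg), generate_community(cfg)
        pd.testing.assert_frame_equal(a.observations, b.observations)
        pd.testing.assert_frame_equal(a.effort, b.effort)
        assert a.truth.species_zone == b.truth.species_zone

    def test_niche_unimodal_in_depth(self):
        niche = SpeciesNiche(
            species_id="s", genus="g", family="f", family_pool="reef",
            depth_center=100.0, depth_sd=10.0, core_halfwidth=20.0,
            site_multipliers={"A": 1.0}, base_intensity=5.0,
        )
        depths = np.linspace(0, 300, 301)
        vals = niche.intensity(depths)
        peak = np.argmax(vals)
        assert np.all(np.diff(vals[: peak + 1]) >= 0)
        assert np.all(np.diff(vals[peak:]) <= 0)
        assert niche.intensity(100) > niche.intensity(150)

    def test_poisson_noise_variance_to_mean_near_one(self):
        # replicate one fixed cell across many seeds through the full pathway
        counts = []
        cfg0 = SimulationConfig(
            n_sites=1, depth_range=(40, 60), n_zones=2, species_per_zone=1,
            n_congener_genera=0, effort_dispersion=0.0, n_dives_per_site=1,
            base_intensity_sigma=0.0, site_multiplier_sigma=0.0,
        )
        for seed in range(400):
            cfg = SimulationConfig(**{**cfg0.__dict__, "seed": seed})
            data = generate_community(cfg)
            target = next(s for s, z in data.truth.species_zone.items() if z == 0)
            obs = data.observations
            sel = obs[(obs["depth_m"] < 50) & (obs["species"] == target)]
            counts.append(sel["count"].sum())
        counts = np.array(counts, dtype=float)
        assert counts.mean() > 1
        assert counts.var() / counts.mean() == pytest.approx(1.0, abs=0.3)

    def test_deep_sea_pool_below_300(self):
        cfg = SimulationConfig(
            depth_range=(40, 480), n_zones=6, zone_edges=[110, 170, 240, 300, 380],
            seed=3,
        )
        data = generate_community(cfg)
        deep = data.deep_sea_species
        assert deep
        centers = {n.species_id: n.depth_center for n in data.niches}
        assert all(centers[sp] >= 300 for sp in deep)

    def test_congener_sets_span_consecutive_zones(self):
        data = generate_community(SimulationConfig(seed=5))
        for cs in data.truth.congener_sets:
            zones = [data.truth.species_zone[sp] for sp in cs["species"]]
            assert zones == list(range(zones[0], zones[0] + len(zones)))
            assert len(cs["species"]) >= 2


class TestRecoveryScore:
    def _assignment(self, mapping):
        return DepthZoneAssignment(site="s", mapping=mapping,
                                   zone_order=sorted(set(mapping.values())))

    def _truth(self, boundaries, rng=(40, 120)):
        from depthzone.synthetic_reef import PlantedTruth

        return PlantedTruth(zone_boundaries=boundaries, species_zone={},
                            congener_sets=[], depth_range=rng, bin_width=10)

    def test_perfect_assignment_scores_one(self):
        truth = self._truth([80])
        mapping = {b: ("u" if b < 80 else "v") for b in range(40, 120, 10)}
        assert recovery_score(self._assignment(mapping), truth) == 1.0

    def test_single_zone_against_two_equal_zones_scores_half(self):
        truth = self._truth([80])
        mapping = {b: "only" for b in range(40, 120, 10)}
        assert recovery_score(self._assignment(mapping), truth) == 0.5

    def test_bin_mismatch_rejected(self):
        truth = self._truth([80])
        mapping = {b: "u" for b in range(40, 110, 10)}
        with pytest.raises(ContractError):
            recovery_score(self._assignment(mapping), truth)

    def test_random_assignment_near_one_over_k(self):
        rng = np.random.default_rng(0)
        truth = self._truth([160, 280], rng=(40, 400))
        bins = list(range(40, 400, 10))
        scores = []
        for _ in range(200):
            mapping = {b: f"z{rng.integers(3)}" for b in bins}
            scores.append(recovery_score(self._assignment(mapping), truth))
        # expectation ~ 1/k (slightly above, by optimal label matching)
        assert 1 / 3 - 0.03 < np.mean(scores) < 1 / 3 + 0.12
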