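import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.distance import pdist, squareform

from depthzone import beta_partition, bray_curtis, distance_matrix, sqrt_transform
from depthzone.dissim import summarize_beta, zone_beta_table
from depthzone.cluster_zone import DepthZoneAssignment
from depthzone.errors import ValidationError

from conftest import make_matrix


class TestSqrtTransform:
    def test_cell_wise_square_root(self):
        m = make_matrix([[4, 9, 0]])
        t = sqrt_transform(m)
        assert t.data.iloc[0].tolist() == [2, 3, 0]
        assert t.transforms == ["sqrt"]

    def test_double_transform_refused_then_forced(self):
        t = sqrt_transform(make_matrix([[16.0]]))
        with pytest.raises(ValidationError):
            sqrt_transform(t)
        assert sqrt_transform(t, force=True).data.iloc[0, 0] == pytest.approx(2.0)

    def test_monotone(self):
        m = make_matrix([[1, 4, 9, 16]])
        t = sqrt_transform(m).data.iloc[0].to_numpy()
        assert np.all(np.diff(t) > 0)


class TestBrayCurtis:
    def test_identical_vectors_zero(self):
        assert bray_curtis([1, 2, 3], [1, 2, 3]) == 0

    def test_disjoint_supports_one(self):
        assert bray_curtis([1, 0, 2], [0, 3, 0]) == 1

    def test_direct_formula_value(self):
        assert bray_curtis([1, 0, 3], [1, 2, 0]) == pytest.approx(5 / 7, abs=1e-12)

    def test_both_zero_rejected(self):
        with pytest.raises(ValidationError):
            bray_curtis([0, 0], [0, 0])

    @given(
        st.lists(st.floats(0, 100), min_size=3, max_size=8),
        st.lists(st.floats(0, 100), min_size=3, max_size=8),
        st.floats(0.01, 50),
    )
    @settings(max_examples=60, deadline=None)
    def test_scale_invariance_and_range(self, u, v, k):
        n = min(len(u), len(v))
        u, v = np.array(u[:n]) + 0.1, np.array(v[:n]) + 0.1
        bc = bray_curtis(u, v)
        assert 0 <= bc <= 1
        assert bray_curtis(k * u, k * v) == pytest.approx(bc, abs=1e-9)

    def test_matches_scipy_on_random_matrices(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(0.1, 20, size=(7, 12))
        m = make_matrix(x)
        ours = distance_matrix(m, metric="braycurtis")
        ref = squareform(pdist(x, metric="braycurtis"))
        assert np.allclose(np.asarray(ours.data), ref, atol=1e-12)


class TestDistanceMatrix:
    def test_identical_rows_give_zero_offdiagonal(self):
        m = make_matrix([[1, 2], [1, 2]])
        assert np.allclose(np.asarray(distance_matrix(m).data), 0)

    def test_pairwise_matches_double_loop_oracle(self):
        rng = np.random.default_rng(8)
        x = rng.poisson(4, size=(6, 9)).astype(float) + 0.5
        m = make_matrix(x)
        dm = np.asarray(distance_matrix(m).data)
        for i in range(6):
            for j in range(6):
                expected = 0.0 if i == j else bray_curtis(x[i], x[j])
                assert dm[i, j] == pytest.approx(expected, abs=1e-12)

    def test_euclidean_on_univariate_is_absolute_difference(self):
        y = np.array([[1.0], [4.0], [6.0]])
        dm = np.asarray(distance_matrix(make_matrix(y), metric="euclidean").data)
        assert np.allclose(dm, np.abs(y - y.T))

    def test_all_zero_row_names_sample(self):
        m = make_matrix([[1, 2], [0, 0]], bins=[40, 50])
        with pytest.raises(ValidationError, match="A:50"):
            distance_matrix(m)


class TestBetaPartition:
    def test_identical_sets_all_zero(self):
        p = beta_partition({"x", "y"}, {"x", "y"})
        assert (p.beta_sor, p.beta_sim, p.beta_nes) == (0, 0, 0)

    def test_disjoint_sets_pure_turnover(self):
        p = beta_partition({"x"}, {"y", "z"})
        assert p.beta_sor == 1 and p.beta_sim == 1 and p.beta_nes == 0

    def test_direct_formula_values(self):
        p = beta_partition({"a", "s"}, {"a", "t"})
        assert (p.a, p.b, p.c) == (1, 1, 1)
        assert p.beta_sor == pytest.approx(0.5)
        assert p.beta_sim == pytest.approx(0.5)
        assert p.beta_nes == pytest.approx(0.0)

    def test_strict_nesting_is_pure_nestedness(self):
        p = beta_partition({"a", "b", "c"}, {"a", "b"})
        assert p.beta_sim == 0 and p.beta_nes == pytest.approx(p.beta_sor)

    def test_both_empty_rejected(self):
        with pytest.raises(ValidationError):
            beta_partition(set(), set())

    @given(
        st.sets(st.integers(0, 25), min_size=1, max_size=20),
        st.sets(st.integers(0, 25), min_size=1, max_size=20),
    )
    @settings(max_examples=100, deadline=None)
    def test_invariants_hold_for_random_sets(self, s1, s2):
        p = beta_partition(s1, s2)
        assert 0 <= p.beta_sim <= p.beta_sor <= 1
        assert 0 <= p.beta_nes <= p.beta_sor
        assert p.beta_sor == pytest.approx((p.b + p.c) / (2 * p.a + p.b + p.c))


class TestZoneBetaTable:
    def _assignment(self, site):
        mapping = {40: "upper", 50: "upper", 60: "lower", 70: "lower"}
        return DepthZoneAssignment(site=site, mapping=mapping, zone_order=["upper", "lower"])

    def test_two_identical_sites_have_zero_se(self):
        x = [[5, 0, 1], [4, 0, 2], [0, 3, 1], [0, 2, 2]]
        mats = {s: make_matrix(x, bins=[40, 50, 60, 70], site=s) for s in ("A", "B")}
        assigns = {s: self._assignment(s) for s in ("A", "B")}
        table = zone_beta_table(mats, assigns)
        summary = summarize_beta(table)
        assert summary["beta_sor_se"].iloc[0] == pytest.approx(0.0)

    def test_single_site_reports_no_se(self):
        mats = {"A": make_matrix([[5, 0], [0, 3], [0, 2], [1, 1]], bins=[40, 50, 60, 70])}
        table = zone_beta_table(mats, {"A": self._assignment("A")})
        summary = summarize_beta(table)
        assert np.isnan(summary["beta_sor_se"].iloc[0])

    def test_planted_half_turnover_recovered(self):
        # two zones sharing as many generalists as they hold exclusive species
        # -> a = b = c on average -> beta_sor ~ 0.5
        from depthzone import SimulationConfig, generate_community
        from depthzone.obsdata import build_abundance_matrix

        vals = []
        for seed in range(3):
            cfg = SimulationConfig(
                n_sites=1, n_zones=2, depth_range=(40, 160), species_per_zone=15,
                n_generalist_species=15, n_congener_genera=0, seed=seed,
            )
            data = generate_community(cfg)
            m = build_abundance_matrix(data.observations, site="site_1",
                                       depth_window=(40, 160), effort=data.effort)
            asg = DepthZoneAssignment(
                site="site_1",
                mapping={b: ("z1" if b < 100 else "z2") for b in range(40, 160, 10)},
                zone_order=["z1", "z2"],
            )
            table = zone_beta_table({"site_1": m}, {"site_1": asg})
            vals.append(table["beta_sor"].iloc[0])
        assert np.mean(vals) == pytest.approx(0.5, abs=0.1)
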