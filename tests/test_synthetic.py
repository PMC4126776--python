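"""Generator invariants: response model, random fields, cores."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import cdist

import wacalib as w
from wacalib.synthetic import (
    DEFAULT_TP_FIELD,
    correlogram,
    expected_proportions,
    pairwise_distances,
    random_coords,
    simulate_grf,
)


@pytest.fixture()
def small_pool():
    table = pd.DataFrame(
        {
            "true_optimum": [0.2, 0.5, 0.8],
            "true_tolerance": [0.1, 0.2, 0.15],
            "max_abundance": [10.0, 5.0, 20.0],
        },
        index=pd.Index(["t1", "t2", "t3"], name="taxon"),
    )
    return w.SpeciesPool(table)


class TestSpeciesPool:
    def test_expected_abundance_formula(self, small_pool):
        x = np.array([0.3, 0.6])
        mu = small_pool.expected_abundance(x)
        for i, xi in enumerate(x):
            for j, taxon in enumerate(small_pool.taxa):
                row = small_pool.table.loc[taxon]
                expected = row.max_abundance * np.exp(
                    -((xi - row.true_optimum) ** 2) / (2 * row.true_tolerance**2)
                )
                assert mu[i, j] == pytest.approx(expected, abs=1e-14)

    def test_peak_abundance_at_optimum(self, small_pool):
        mu = small_pool.expected_abundance([0.5])
        assert mu[0, 1] == pytest.approx(5.0)

    def test_validation(self):
        bad = pd.DataFrame(
            {"true_optimum": [0.0, 1.0], "true_tolerance": [0.1, 0.0],
             "max_abundance": [1.0, 1.0]}
        )
        with pytest.raises(ValueError, match="tolerances"):
            w.SpeciesPool(bad)
        with pytest.raises(ValueError, match="at least 2"):
            w.SpeciesPool(bad.iloc[:1])

    def test_expected_proportions_rows_sum_to_one(self, small_pool):
        props = expected_proportions(small_pool, np.linspace(0, 1, 7))
        assert np.allclose(props.sum(axis=1), 1.0, atol=1e-12)


class TestFields:
    def test_correlogram_limits(self):
        assert correlogram(0.0, "exponential", 100.0) == pytest.approx(1.0)
        assert correlogram(0.0, "gaussian", 100.0) == pytest.approx(1.0)
        assert correlogram(0.0, "spherical", 100.0) == pytest.approx(1.0)
        # spherical reaches exactly zero at the range
        assert correlogram(150.0, "spherical", 100.0) == pytest.approx(0.0)
        assert correlogram(100.0, "exponential", 100.0) == pytest.approx(
            np.exp(-1.0)
        )

    def test_planar_distances_match_cdist(self):
        coords = random_coords(20, seed=3)
        d = pairwise_distances(coords)
        expected = cdist(coords[["x", "y"]], coords[["x", "y"]])
        assert np.allclose(d, expected, atol=1e-9)

    def test_haversine_one_degree_latitude(self):
        coords = pd.DataFrame({"lon": [0.0, 0.0], "lat": [0.0, 1.0]})
        d = pairwise_distances(coords)
        # one degree of latitude on a 6371 km sphere
        assert d[0, 1] == pytest.approx(6371.0 * np.pi / 180.0, rel=1e-6)

    def test_grf_deterministic_and_standardized(self):
        coords = random_coords(200, seed=1)
        d = pairwise_distances(coords)
        spec = w.FieldSpec(mean=0.0, nugget=0.1, sill=0.9, range_=200.0)
        z1 = simulate_grf(d, spec, np.random.default_rng(7))
        z2 = simulate_grf(d, spec, np.random.default_rng(7))
        assert np.array_equal(z1, z2)
        # standardized field: sample variance near 1 (spatial correlation
        # widens the tolerance)
        assert 0.2 < z1.var() < 3.0

    def test_grf_zero_variance_gives_zero_field(self):
        d = pairwise_distances(random_coords(5, seed=0))
        spec = w.FieldSpec(mean=1.0, nugget=0.0, sill=0.0)
        assert np.array_equal(simulate_grf(d, spec, np.random.default_rng(0)),
                              np.zeros(5))

    def test_field_spec_validation(self):
        with pytest.raises(ValueError):
            w.FieldSpec(mean=0.0, nugget=-0.1)
        with pytest.raises(ValueError):
            w.FieldSpec(mean=0.0, range_=0.0)
        with pytest.raises(ValueError):
            w.FieldSpec(mean=0.0, family="cubic")

    def test_spatial_autocorrelation_present(self):
        """Near pairs of a long-range field are more similar than far pairs."""
        coords = random_coords(250, seed=2)
        d = pairwise_distances(coords)
        spec = w.FieldSpec(mean=0.0, nugget=0.0, sill=1.0, range_=400.0)
        z = simulate_grf(d, spec, np.random.default_rng(4))
        iu = np.triu_indices(len(z), k=1)
        sq = (z[iu[0]] - z[iu[1]]) ** 2
        near = sq[d[iu] < 100].mean()
        far = sq[d[iu] > 700].mean()
        assert near < far


class TestSimulateEnvironment:
    def test_log_transform_stored_in_original_units(self):
        coords = random_coords(50, seed=9)
        env = w.simulate_environment(
            coords, {"TP": DEFAULT_TP_FIELD}, seed=9, transforms={"TP": "log"}
        )
        assert (env.data["TP"] > 0).all()
        back = env.transformed_variable("TP")
        assert np.allclose(10.0**back, env.data["TP"], rtol=1e-12)

    def test_cross_variable_correlation_induced(self):
        coords = random_coords(300, seed=5)
        spec = w.FieldSpec(mean=0.0, nugget=0.2, sill=0.8, range_=100.0)
        corr = pd.DataFrame(
            [[1.0, 0.9], [0.9, 1.0]], index=["A", "B"], columns=["A", "B"]
        )
        env = w.simulate_environment(
            coords, {"A": spec, "B": spec}, correlation=corr, seed=5
        )
        r = np.corrcoef(env.data["A"], env.data["B"])[0, 1]
        assert r > 0.7

    def test_non_psd_correlation_rejected(self):
        coords = random_coords(10, seed=0)
        spec = w.FieldSpec(mean=0.0)
        bad = np.array([[1.0, 2.0], [2.0, 1.0]])
        with pytest.raises(ValueError, match="positive semi-definite"):
            w.simulate_environment(coords, {"A": spec, "B": spec}, correlation=bad)

    def test_coincident_sites_rejected(self):
        coords = pd.DataFrame({"x": [0.0, 0.0], "y": [0.0, 0.0]})
        with pytest.raises(ValueError, match="distinct"):
            w.simulate_environment(coords, {"A": w.FieldSpec(mean=0.0)})


class TestSimulateAssemblages:
    def test_multinomial_rows_sum_to_count_total(self, small_pool):
        coords = random_coords(40, seed=8)
        env = w.simulate_environment(
            coords, {"TP": w.FieldSpec(mean=0.5, nugget=0.0, sill=0.04)},
            seed=8,
        )
        ab = w.simulate_assemblages(small_pool, env, "TP", count_total=400, seed=8)
        assert ab.basis == "density"
        assert (ab.row_sums() == 400).all()

    def test_seed_determinism(self, small_pool):
        coords = random_coords(20, seed=8)
        env = w.simulate_environment(
            coords, {"TP": w.FieldSpec(mean=0.5, nugget=0.0, sill=0.04)},
            seed=8,
        )
        a = w.simulate_assemblages(small_pool, env, "TP", seed=42)
        b = w.simulate_assemblages(small_pool, env, "TP", seed=42)
        pd.testing.assert_frame_equal(a.data, b.data)

    def test_unknown_variable_and_noise_rejected(self, small_pool):
        coords = random_coords(10, seed=8)
        env = w.simulate_environment(
            coords, {"TP": w.FieldSpec(mean=0.5, nugget=0.0, sill=0.04)},
            seed=8,
        )
        with pytest.raises(ValueError, match="gradient variable"):
            w.simulate_assemblages(small_pool, env, "chloride")
        with pytest.raises(ValueError, match="noise"):
            w.simulate_assemblages(small_pool, env, "TP", noise="uniform")


class TestCores:
    def test_enrichment_scenario_shape(self):
        scenario = w.enrichment_core_scenario()
        assert scenario.n_intervals == 26
        traj = scenario.tp_trajectory
        assert traj[0] == pytest.approx(0.45)
        assert traj.max() == pytest.approx(0.85, abs=0.02)
        # full recovery by the core top
        assert traj[-1] == pytest.approx(0.45)
        # the peak sits mid-20th-century
        peak_year = scenario.dates[np.argmax(traj)]
        assert 1930 <= peak_year <= 1960

    def test_simulate_core_rows_sum_to_one(self, small_pool):
        scenario = w.CoreScenario(
            dates=np.array([1900.0, 1950.0, 2000.0]),
            tp_trajectory=np.array([0.4, 0.7, 0.5]),
            count_total=200,
        )
        core = w.simulate_core(small_pool, scenario, seed=3)
        assert np.allclose(core.abundances.sum(axis=1), 1.0, atol=1e-12)
        assert core.true_gradient.tolist() == [0.4, 0.7, 0.5]
        assert core.n_intervals == 3

    def test_core_scenario_validation(self):
        with pytest.raises(ValueError, match="monotone"):
            w.CoreScenario(
                dates=np.array([1900.0, 2000.0, 1950.0]),
                tp_trajectory=np.zeros(3),
            )
        with pytest.raises(ValueError, match="lengths"):
            w.CoreScenario(dates=np.array([1900.0]), tp_trajectory=np.zeros(2))


def test_benchmark_training_set_structure():
    pool, env, abundance = w.benchmark_training_set(n_sites=40, n_taxa=15, seed=2)
    assert env.transform_of("TP") == "log"
    assert env.coords is not None and {"x", "y"} <= set(env.coords.columns)
    assert len(abundance.samples) == 40
    assert (abundance.row_sums() == 400).all()
    # taxa absent everywhere may be dropped, never added
    assert set(abundance.taxa) <= set(pool.taxa)
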