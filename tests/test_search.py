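"""Evolutionary search: decoding, the three optimizers, pipeline fitness."""

import math

import numpy as np
import pytest

from cdbn_lesion.search import (
    FitnessBudget,
    Individual,
    SearchSpace,
    bumda_moments,
    decode,
    make_pipeline_fitness,
    pipeline_fitness,
    run_bumda,
    run_rcga,
    run_umda,
    umda_moments,
)
from cdbn_lesion.synth import GeneratorConfig, PatchDataset, generate_dataset

BEST_VECTOR = np.array(
    [197.8324, 0.4148, 14.6398, 0.4470, 0.9831, 71.3538,
     0.4227, 0.9839, 3.0260e-6, 4.1494e-6, 3.4456e-7]
)


class TestSpaceAndDecode:
    def test_space_has_eleven_bounded_dimensions(self):
        space = SearchSpace()
        assert space.dim == 11
        assert np.all(space.lower < space.upper)
        np.testing.assert_allclose(space.lower[:2], [100.0, 0.0])
        np.testing.assert_allclose(space.upper[1], math.pi)
        np.testing.assert_allclose(space.upper[3], 2 * math.pi)
        np.testing.assert_allclose(space.lower[8:], 1e-9)
        np.testing.assert_allclose(space.upper[8:], 1e-5)

    def test_published_best_vector_decodes_in_range(self):
        out = decode(BEST_VECTOR)
        assert not out["repaired"]
        g = out["gabor"]
        assert g.sigma == pytest.approx(197.8324)
        assert g.kernel_side == 71
        assert out["p1"] == pytest.approx(0.4227)
        assert out["p2"] == pytest.approx(0.9839)
        assert out["alphas"] == pytest.approx((3.0260e-6, 4.1494e-6, 3.4456e-7))

    def test_lower_bound_vector_decodes_exactly(self):
        space = SearchSpace()
        out = decode(space.lower.copy())
        assert out["gabor"].sigma == 100.0
        assert out["p1"] == 0.0
        assert out["alphas"][0] == 1e-9

    def test_out_of_bounds_vector_repaired_by_clipping(self):
        v = BEST_VECTOR.copy()
        v[0] = 250.0
        out = decode(v)
        assert out["repaired"]
        assert out["gabor"].sigma == 200.0


def sphere(space):
    def f(vec):
        z = space.normalize(vec)
        return -float(((z - 0.5) ** 2).sum())

    return f


ALGOS = {"rcga": run_rcga, "bumda": run_bumda, "umda": run_umda}


class TestOptimizers:
    @pytest.mark.parametrize("name", list(ALGOS))
    def test_same_seed_gives_identical_log(self, name):
        space = SearchSpace()
        f = sphere(space)
        a = ALGOS[name](space, f, pop_size=8, generations=6, seed=4)
        b = ALGOS[name](space, f, pop_size=8, generations=6, seed=4)
        assert a.elite_trace == b.elite_trace
        for ra, rb in zip(a.records, b.records):
            np.testing.assert_array_equal(np.array(ra["vectors"]), np.array(rb["vectors"]))

    @pytest.mark.parametrize("name", list(ALGOS))
    def test_elite_fitness_is_monotone_and_vectors_in_bounds(self, name):
        space = SearchSpace()
        f = sphere(space)
        log = ALGOS[name](space, f, pop_size=10, generations=15, seed=2)
        trace = log.elite_trace
        assert all(b >= a for a, b in zip(trace, trace[1:]))
        for rec in log.records:
            for vec in rec["vectors"]:
                assert np.all(vec >= space.lower - 1e-12)
                assert np.all(vec <= space.upper + 1e-12)

    def test_identical_population_without_mutation_keeps_elite(self):
        space = SearchSpace()
        f = sphere(space)
        init = np.tile(BEST_VECTOR, (6, 1))
        log = run_rcga(
            space, f, pop_size=6, generations=5, seed=0,
            mutation_prob=0.0, initial_population=init,
        )
        # SBX of identical parents reproduces them; no operator introduces change
        assert len(set(log.elite_trace)) == 1
        np.testing.assert_allclose(log.best[0], BEST_VECTOR)

    def test_failing_fitness_scores_zero_and_is_flagged(self):
        space = SearchSpace()

        def bad(vec):
            raise RuntimeError("boom")

        # 4 initial + 3 offspring evaluations (the elite is carried over)
        log = run_umda(space, bad, pop_size=4, generations=2, seed=0)
        assert log.failed_evaluations == 7
        assert all(f == 0.0 for rec in log.records for f in rec["fitness_values"])

    def test_log_dataframe_schema(self):
        space = SearchSpace()
        log = run_rcga(space, sphere(space), pop_size=4, generations=3, seed=1)
        df = log.to_dataframe()
        assert {"generation", "individual_id", "fitness", "elite_flag", "sigma", "alpha3"} <= set(
            df.columns
        )
        assert len(df) == 12
        assert df.groupby("generation")["elite_flag"].any().all()


class TestMomentFits:
    def test_constant_fitness_reduces_bumda_mean_to_arithmetic_mean(self, rng):
        sel = rng.random((7, 5))
        mean, _ = bumda_moments(sel, np.full(7, 0.42))
        np.testing.assert_allclose(mean, sel.mean(axis=0), atol=1e-12)

    def test_bumda_variance_shrinks_against_unweighted_fit(self, rng):
        sel = rng.random((8, 4))
        fits = np.full(8, 1.0)
        _, var_b = bumda_moments(sel, fits)
        _, var_u = umda_moments(sel)
        # equal weights: Boltzmann variance = n/(1+n) times the plain variance
        np.testing.assert_allclose(var_b, var_u * 8 / 9, atol=1e-12)

    def test_umda_top_half_selection_size(self):
        space = SearchSpace()
        seen = []

        def f(vec):
            seen.append(vec)
            return float(vec[0])

        run_umda(space, f, pop_size=10, generations=2, seed=0)
        # generation 1 samples pop_size - 1 = 9 new individuals
        assert len(seen) == 19


@pytest.fixture(scope="module")
def mini_dataset():
    return generate_dataset(GeneratorConfig.separable(), (15, 15, 15), master_seed=9)


class TestPipelineFitness:
    def test_missing_class_rejected(self, mini_dataset):
        broken = PatchDataset(
            patches=mini_dataset.patches[:30].copy(),
            labels=mini_dataset.labels[:30],
        )
        space = SearchSpace()
        mid = (space.lower + space.upper) / 2
        with pytest.raises(ValueError):
            pipeline_fitness(mid, broken, FitnessBudget(epochs=1))

    def test_fitness_is_deterministic(self, mini_dataset):
        space = SearchSpace()
        mid = (space.lower + space.upper) / 2
        budget = FitnessBudget(epochs=1, max_patches=45, seed=0)
        f1 = pipeline_fitness(mid, mini_dataset, budget)
        f2 = pipeline_fitness(mid, mini_dataset, budget)
        assert f1 == f2
        assert 0.0 <= f1 <= 1.0

    def test_individual_wrapper_accepted(self, mini_dataset):
        space = SearchSpace()
        ind = Individual(vector=(space.lower + space.upper) / 2)
        budget = FitnessBudget(epochs=1, max_patches=45, seed=0)
        fn = make_pipeline_fitness(mini_dataset, budget)
        assert fn(ind.vector) == pipeline_fitness(ind, mini_dataset, budget)
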