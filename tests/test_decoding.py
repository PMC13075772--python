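import numpy as np
import pytest

from audthal import decoding
from audthal.decoding import (ECOCLinearSVM, Pseudopopulation, PopulationResponses,
                              build_pseudopopulations, cross_condition_decode,
                              decode_frequency)
from audthal.stimuli import NBN, PT

N_FREQ, N_SPL, N_TRIALS = 11, 4, 6


def _tensor_from_rates(rates, rng, n_pool=30):
    """Poisson count tensor (n_pool, N_FREQ, N_SPL, N_TRIALS) from per-unit
    per-frequency mean rates."""
    lam = np.broadcast_to(rates[:, :, None, None],
                          (n_pool, N_FREQ, N_SPL, N_TRIALS))
    return rng.poisson(lam).astype(float)


def _separable_tensor(rng, n_pool=33, gain=40.0):
    """Units with disjoint frequency preferences and near-noiseless rates."""
    rates = np.full((n_pool, N_FREQ), 0.05)
    for u in range(n_pool):
        rates[u, u % N_FREQ] = gain
    return _tensor_from_rates(rates, rng, n_pool)


class TestBuildPseudopopulations:
    def test_default_count_and_size(self, grid):
        rng = np.random.default_rng(0)
        pool = np.arange(30)
        t = _separable_tensor(rng)
        pops = build_pseudopopulations({PT: t[:30]}, {PT: pool}, size=50,
                                       n_pops=10, seed=1)
        assert len(pops) == 10
        assert all(len(p.unit_ids) == 50 for p in pops)

    def test_same_seed_identical_draws(self, grid):
        rng = np.random.default_rng(0)
        pool = np.arange(30)
        t = _separable_tensor(rng)[:30]
        a = build_pseudopopulations({PT: t}, {PT: pool}, size=20, n_pops=3, seed=9)
        b = build_pseudopopulations({PT: t}, {PT: pool}, size=20, n_pops=3, seed=9)
        for pa, pb in zip(a, b):
            assert np.array_equal(pa.unit_ids, pb.unit_ids)

    def test_small_pool_sampled_with_replacement(self):
        rng = np.random.default_rng(0)
        t = _separable_tensor(rng, n_pool=5)
        pops = build_pseudopopulations({PT: t}, {PT: np.arange(5)}, size=50,
                                       n_pops=1, seed=2)
        assert len(pops[0].unit_ids) == 50
        assert len(np.unique(pops[0].unit_ids)) <= 5

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError):
            build_pseudopopulations({PT: np.zeros((0, 11, 8, 15))},
                                    {PT: np.array([])}, size=10, n_pops=1)


class TestDecodeFrequency:
    def test_separable_population_decodes_nearly_perfectly(self):
        rng = np.random.default_rng(3)
        t = _separable_tensor(rng)
        pops = build_pseudopopulations({PT: t}, {PT: np.arange(t.shape[0])},
                                       size=33, n_pops=1, seed=4)
        res = decode_frequency(pops[0], PT, seed=5, tuning_budget=4)
        assert res.accuracy >= 0.95

    def test_shuffled_labels_fall_to_chance(self):
        rng = np.random.default_rng(6)
        t = _separable_tensor(rng)
        pops = build_pseudopopulations({PT: t}, {PT: np.arange(t.shape[0])},
                                       size=33, n_pops=1, seed=7)
        res = decode_frequency(pops[0], PT, seed=8, shuffle=True, tuning_budget=4)
        # binomial 99% CI around 1/11 for the held-out trial count
        p = 1.0 / N_FREQ
        half = 2.576 * np.sqrt(p * (1 - p) / res.n_test)
        assert abs(res.accuracy - p) < max(half, 0.06)

    def test_identical_classes_confuse_each_other_only(self):
        rng = np.random.default_rng(9)
        rates = np.full((30, N_FREQ), 0.05)
        for u in range(30):
            rates[u, u % N_FREQ] = 40.0
        rates[:, 3] = rates[:, 4]          # classes 3 and 4 made identical
        t = _tensor_from_rates(rates, rng)
        pops = build_pseudopopulations({PT: t}, {PT: np.arange(30)}, size=30,
                                       n_pops=1, seed=10)
        res = decode_frequency(pops[0], PT, seed=11, tuning_budget=4)
        acc = res.per_frequency
        confused = (acc.get(3, 1.0) + acc.get(4, 1.0)) / 2
        others = acc.drop([3, 4], errors="ignore").mean()
        assert confused < 0.8
        assert others > 0.9

    def test_accuracy_invariant_to_unit_order_and_common_scaling(self):
        rng = np.random.default_rng(12)
        t = _separable_tensor(rng)
        pool = np.arange(t.shape[0])
        pops = build_pseudopopulations({PT: t}, {PT: pool}, size=25, n_pops=1,
                                       seed=13)
        pop = pops[0]
        base = decode_frequency(pop, PT, seed=14, tuning_budget=3)
        perm = np.random.default_rng(15).permutation(pop.kind_data[PT].X.shape[1])
        pop_perm = Pseudopopulation(
            population_id=0, unit_rows=pop.unit_rows, unit_ids=pop.unit_ids,
            kind_data={PT: PopulationResponses(
                X=pop.kind_data[PT].X[:, perm],
                y_freq=pop.kind_data[PT].y_freq, y_amp=pop.kind_data[PT].y_amp)})
        res_perm = decode_frequency(pop_perm, PT, seed=14, tuning_budget=3)
        assert res_perm.accuracy == pytest.approx(base.accuracy, abs=0.02)
        pop_scaled = Pseudopopulation(
            population_id=0, unit_rows=pop.unit_rows, unit_ids=pop.unit_ids,
            kind_data={PT: PopulationResponses(
                X=3.0 * pop.kind_data[PT].X,
                y_freq=pop.kind_data[PT].y_freq, y_amp=pop.kind_data[PT].y_amp)})
        res_scaled = decode_frequency(pop_scaled, PT, seed=14, tuning_budget=3)
        assert res_scaled.accuracy == pytest.approx(base.accuracy, abs=0.03)


class TestCrossCondition:
    def test_identical_kinds_generalize_fully(self):
        rng = np.random.default_rng(16)
        rates = np.full((30, N_FREQ), 0.05)
        for u in range(30):
            rates[u, u % N_FREQ] = 30.0
        t1 = _tensor_from_rates(rates, rng)
        t2 = _tensor_from_rates(rates, rng)
        pool = np.arange(30)
        pops = build_pseudopopulations({PT: t1, NBN: t2}, {PT: pool, NBN: pool},
                                       size=30, n_pops=1, seed=17)
        res = cross_condition_decode(pops[0], PT, NBN, seed=18, tuning_budget=4)
        assert res.within_cv_accuracy > 0.9
        assert res.accuracy > 0.85

    def test_independent_tuning_breaks_generalization(self):
        rng = np.random.default_rng(19)
        rates_pt = np.full((30, N_FREQ), 0.05)
        rates_nbn = np.full((30, N_FREQ), 0.05)
        perm = rng.permutation(N_FREQ)
        for u in range(30):
            rates_pt[u, u % N_FREQ] = 30.0
            rates_nbn[u, perm[u % N_FREQ]] = 30.0   # unrelated preferred bands
        t_pt = _tensor_from_rates(rates_pt, rng)
        t_nbn = _tensor_from_rates(rates_nbn, rng)
        pool = np.arange(30)
        pops = build_pseudopopulations({PT: t_pt, NBN: t_nbn},
                                       {PT: pool, NBN: pool},
                                       size=30, n_pops=1, seed=20)
        res = cross_condition_decode(pops[0], PT, NBN, seed=21, tuning_budget=4)
        assert res.within_cv_accuracy > 0.9
        assert res.accuracy < 0.4

    def test_mismatched_grids_rejected(self):
        rng = np.random.default_rng(22)
        t1 = _separable_tensor(rng)
        t2 = _separable_tensor(rng)[:, :, :2, :]
        pool = np.arange(30)
        pops = build_pseudopopulations({PT: t1[:30], NBN: t2[:30]},
                                       {PT: pool, NBN: pool}, size=10, n_pops=1,
                                       seed=23)
        with pytest.raises(ValueError):
            cross_condition_decode(pops[0], PT, NBN, seed=24)


class TestECOC:
    def test_matches_sklearn_ovo_on_well_separated_data(self):
        """On cleanly separable data the hinge-loss-weighted decoding agrees
        with scikit-learn's one-vs-one voting aggregation."""
        from sklearn.multiclass import OneVsOneClassifier
        from sklearn.svm import LinearSVC

        rng = np.random.default_rng(25)
        centers = rng.normal(0, 5, (5, 8))
        X = np.vstack([c + rng.normal(0, 0.3, (20, 8)) for c in centers])
        y = np.repeat(np.arange(5), 20)
        ours = ECOCLinearSVM(C=1.0).fit(X, y)
        ref = OneVsOneClassifier(LinearSVC(C=1.0, max_iter=3000)).fit(X, y)
        agree = np.mean(ours.predict(X) == ref.predict(X))
        assert agree > 0.98
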