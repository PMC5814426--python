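"""Training loop, subject aggregation, and the Monte-Carlo null."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import eegsex as e
from eegsex.model import ArchSpec, ConvSpec, DenseSpec, PoolSpec
from eegsex.preprocess import EpochSet
from eegsex.train import TrainConfig


class TestSplitCohort:
    def test_sizes(self):
        cohort = list(range(1308))
        tr, te = e.split_cohort(cohort, 1000)
        assert len(tr) == 1000 and len(te) == 308

    def test_disjoint(self):
        cohort = [f"S{i}" for i in range(50)]
        tr, te = e.split_cohort(cohort, 30, seed=4)
        assert set(tr) & set(te) == set()
        assert sorted(tr + te) == sorted(cohort)

    def test_full_split_rejected(self):
        with pytest.raises(e.DataError):
            e.split_cohort(list(range(10)), 10)


class _StubNet:
    """Returns a fixed male probability for every epoch."""

    input_shape = (4, 8)

    def __init__(self, p_male):
        self.p_male = np.atleast_1d(p_male)
        self._i = 0

    def predict_proba(self, x):
        p = np.full(len(x), float(self.p_male[self._i % len(self.p_male)]))
        self._i += 1
        return np.column_stack([1 - p, p])


def _epochset(sid, sex, n=4, seed=0):
    rng = np.random.default_rng(seed)
    return EpochSet(subject_id=sid, sex=sex,
                    epochs=rng.normal(size=(n, 8, 4)).astype(np.float32),
                    fs=4.0, channel_names=("a", "b", "c", "d"))


class TestPredictSubjects:
    def test_mean_probability_male(self):
        table = e.predict_subjects(_StubNet(0.6), [_epochset("A", 1)])
        assert table["mean_male_probability"].iloc[0] == pytest.approx(0.6)
        assert table["predicted_sex"].iloc[0] == 1

    def test_exact_half_is_female(self):
        table = e.predict_subjects(_StubNet(0.5), [_epochset("A", 0)])
        assert table["predicted_sex"].iloc[0] == 0

    def test_epoch_order_invariant(self, tiny_net):
        rng = np.random.default_rng(3)
        es = EpochSet(subject_id="A", sex=1,
                      epochs=rng.normal(size=(6, 32, 8)).astype(np.float32),
                      fs=16.0, channel_names=tuple("abcdefgh"))
        perm = EpochSet(subject_id="A", sex=1,
                        epochs=es.epochs[::-1].copy(), fs=es.fs,
                        channel_names=es.channel_names)
        a = e.predict_subjects(tiny_net, [es])
        b = e.predict_subjects(tiny_net, [perm])
        assert a["mean_male_probability"].iloc[0] == pytest.approx(
            b["mean_male_probability"].iloc[0], abs=1e-6)

    def test_empty_epochs_rejected(self, tiny_net):
        es = _epochset("A", 1)
        es.epochs = es.epochs[:1]
        es.epochs = np.empty((0, 8, 4), dtype=np.float32)
        with pytest.raises(e.DataError):
            e.predict_subjects(tiny_net, [es])


class TestSubjectAccuracy:
    @pytest.mark.parametrize("correct,total,expected", [
        (308, 308, 100.0), (250, 308, 81.2), (0, 10, 0.0)])
    def test_percentages(self, correct, total, expected):
        table = pd.DataFrame({
            "true_sex": [1] * total,
            "predicted_sex": [1] * correct + [0] * (total - correct)})
        assert e.subject_accuracy(table) == pytest.approx(expected, abs=0.05)

    def test_empty_rejected(self):
        with pytest.raises(e.DataError):
            e.subject_accuracy(pd.DataFrame(columns=["true_sex",
                                                     "predicted_sex"]))


def _toy_separable(n_per_class=40, n_ch=4, n_t=16, seed=0):
    """Two classes with distinct constant spatial patterns plus noise."""
    rng = np.random.default_rng(seed)
    pattern = rng.normal(size=(n_ch,))
    X, y = [], []
    for sex in (0, 1):
        base = pattern * (1.0 if sex else -1.0)
        eps = rng.normal(scale=0.1, size=(n_per_class, n_t, n_ch))
        X.append(base[None, None, :] + eps)
        y += [sex] * n_per_class
    return np.concatenate(X).astype(np.float32), np.array(y)


TOY_SPEC = ArchSpec(input_shape=(4, 16), layers=(
    ConvSpec(4, 3, 3), PoolSpec(2, 2), ConvSpec(4, 1, 3), DenseSpec(2)))


class TestTrain:
    def test_separable_reaches_perfect_accuracy(self):
        X, y = _toy_separable()
        net = e.build_network(TOY_SPEC, seed=1)
        res = e.train(net, X, y, TrainConfig(batch_size=16, max_runs=60,
                                             seed=0))
        assert res.stop_reason == "train_acc_100"
        assert res.history["train_acc"].iloc[-1] == 1.0

    def test_single_run_budget(self):
        X, y = _toy_separable(n_per_class=8)
        net = e.build_network(TOY_SPEC, seed=1)
        res = e.train(net, X, y, TrainConfig(batch_size=8, max_runs=1))
        assert len(res.history) == 1
        assert res.stop_reason == "max_runs"

    def test_plateau_stop(self):
        X, y = _toy_separable(n_per_class=8)
        net = e.build_network(TOY_SPEC, seed=1)
        # learning rate 0 cannot improve the loss -> plateau rule fires
        res = e.train(net, X, y, TrainConfig(learning_rate=0.0, batch_size=8,
                                             max_runs=50, plateau_patience=3,
                                             shuffle=False))
        assert res.stop_reason == "loss_plateau"
        assert len(res.history) <= 10

    def test_shape_mismatch_rejected(self):
        X, y = _toy_separable(n_per_class=4)
        net = e.build_network(TOY_SPEC, seed=1)
        with pytest.raises(e.DataError):
            e.train(net, X, y[:-2])

    def test_deterministic_given_seed(self):
        X, y = _toy_separable(n_per_class=8)
        cfg = TrainConfig(batch_size=8, max_runs=2, seed=9)
        r1 = e.train(e.build_network(TOY_SPEC, seed=2), X, y, cfg)
        r2 = e.train(e.build_network(TOY_SPEC, seed=2), X, y, cfg)
        pd.testing.assert_frame_equal(r1.history, r2.history)


class TestNullSimulation:
    def test_expected_single_sim_accuracy(self):
        """Mean simulated accuracy matches q*m + (1-q)(1-m) ~ 0.5006."""
        res = e.simulate_null_threshold(308, 0.49, 0.47, n_sims=20_000,
                                        seed=0)
        expected = 0.49 * 0.47 + 0.51 * 0.53
        assert expected == pytest.approx(0.5006, abs=1e-4)
        assert res.accuracies.mean() == pytest.approx(expected, abs=0.002)

    def test_threshold_shrinks_with_cohort_size(self):
        small = e.simulate_null_threshold(308, 0.49, 0.47, 20_000, seed=1)
        large = e.simulate_null_threshold(10_000, 0.49, 0.47, 20_000, seed=1)
        assert large.threshold_percent < small.threshold_percent

    def test_matches_binomial_distribution(self):
        """Goodness of fit of simulated correct-counts to Binomial(n, p)."""
        n, n_sims = 308, 10_000
        res = e.simulate_null_threshold(n, 0.49, 0.47, n_sims, seed=2)
        counts = np.round(res.accuracies * n).astype(int)
        p = 0.49 * 0.47 + 0.51 * 0.53
        lo, hi = 130, 180
        edges = np.arange(lo, hi + 1)
        observed = np.array([(counts == k).sum() for k in edges], dtype=float)
        observed = np.concatenate([[np.sum(counts < lo)], observed,
                                   [np.sum(counts > hi)]])
        pmf = stats.binom.pmf(edges, n, p)
        expected = np.concatenate([[stats.binom.cdf(lo - 1, n, p)], pmf,
                                   [stats.binom.sf(hi, n, p)]]) * n_sims
        keep = expected >= 5
        chi2 = ((observed[keep] - expected[keep]) ** 2
                / expected[keep]).sum()
        pval = stats.chi2.sf(chi2, keep.sum() - 1)
        assert pval > 0.001

    def test_zero_sims_rejected(self):
        with pytest.raises(e.ConfigurationError):
            e.simulate_null_threshold(308, 0.49, 0.47, n_sims=0)

    def test_reproducible(self):
        a = e.simulate_null_threshold(100, 0.5, 0.47, 5_000, seed=3)
        b = e.simulate_null_threshold(100, 0.5, 0.47, 5_000, seed=3)
        assert a.threshold_percent == b.threshold_percent
        assert np.array_equal(a.accuracies, b.accuracies)
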