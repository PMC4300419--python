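import numpy as np
import pandas as pd
import pytest

from biosol.dataset import CompoundRecord, SolubilityDataset
from biosol.latent import NipalsPLS
from biosol.protocol import (ProtocolError, VipGreedyPLS, augment_experimental,
                             build_summary, greedy_backward_selection,
                             relocate_outliers, sorted_thirds_split,
                             truncate_top_vip)
from biosol.synthetic import SyntheticSpec, generate_latent_dataset, plant_outlier


def tiny_dataset(values, medium="logs_fassif"):
    recs = []
    for i, v in enumerate(values):
        kwargs = {medium: v}
        recs.append(CompoundRecord(name=f"c{i:02d}", mw=300, logd65=2.0,
                                   psa=50.0, rotb=1, **kwargs))
    return SolubilityDataset(recs)


class TestSplit:
    def test_every_third_of_nine(self):
        # sorted most-soluble-first; 1-based positions 3, 6, 9 go to test
        ds = tiny_dataset([-2.0, -2.5, -3.0, -3.5, -4.0, -4.5, -5.0, -5.5, -6.0])
        split = sorted_thirds_split(ds, "fassif")
        assert sorted(split.test) == ["c02", "c05", "c08"]
        assert len(split.train) == 6

    def test_missing_response_is_loud(self, toy_ds):
        with pytest.raises(ProtocolError, match="gamma"):
            sorted_thirds_split(toy_ds, "phb")

    def test_deterministic_under_ties(self):
        ds = tiny_dataset([-3.0, -3.0, -3.0, -3.0, -3.0, -3.0])
        a = sorted_thirds_split(ds, "fassif")
        b = sorted_thirds_split(ds, "fassif")
        assert a.train == b.train and a.test == b.test


class TestRelocation:
    @staticmethod
    def _split_and_matrix(seed=0, n=40, p=12):
        X, _, truth = generate_latent_dataset(
            SyntheticSpec(n=n, p=p, k=2, n_informative=6, noise_sd=0.2, seed=seed))
        names = list(X.index)
        from biosol.protocol import SplitResult
        split = SplitResult(train=names[: 2 * n // 3], test=names[2 * n // 3:])
        return split, X, truth

    def test_clean_data_unchanged(self):
        split, X, _ = self._split_and_matrix(seed=1)
        out = relocate_outliers(split, X, alpha=0.001)  # generous limit
        assert out.train == split.train and not out.relocations

    def test_planted_outlier_moved_and_logged(self):
        split, X, truth = self._split_and_matrix(seed=2)
        victim = split.train[4]
        X = plant_outlier(X, victim, magnitude=10.0, truth=truth)
        out = relocate_outliers(split, X)
        assert victim in out.test
        assert any(name == victim for name, _ in out.relocations)

    def test_test_compounds_never_touched(self):
        split, X, truth = self._split_and_matrix(seed=3)
        in_test = split.test[0]
        X = plant_outlier(X, in_test, magnitude=10.0, truth=truth)
        out = relocate_outliers(split, X)
        assert in_test in out.test
        assert set(out.train) <= set(split.train)


class TestTruncation:
    def test_small_matrix_identity(self, rng):
        from conftest import random_regression
        X, y = random_regression(rng, n=30, p=8)
        assert truncate_top_vip(X, y, keep=100) == list(X.columns)

    def test_planted_support_survives(self):
        X, y, truth = generate_latent_dataset(
            SyntheticSpec(n=80, p=300, k=2, n_informative=5, noise_sd=0.3, seed=6))
        kept = set(truncate_top_vip(X, y, keep=100))
        assert set(truth.informative) <= kept

    def test_invariant_to_column_order(self):
        X, y, _ = generate_latent_dataset(
            SyntheticSpec(n=50, p=40, k=2, n_informative=5, noise_sd=0.3, seed=7))
        shuffled = X[list(X.columns[::-1])]
        assert set(truncate_top_vip(X, y, keep=20)) == set(
            truncate_top_vip(shuffled, y, keep=20))


class TestGreedySelection:
    def test_noise_removed_signal_kept(self):
        rng = np.random.default_rng(12)
        X = pd.DataFrame({
            "signal": rng.standard_normal(60),
            "noise": rng.standard_normal(60),
        })
        y = pd.Series(X["signal"] * 2 + rng.standard_normal(60) * 0.2)
        trace = greedy_backward_selection(X, y, max_components=1)
        assert trace.final_descriptors == ["signal"]

    def test_sole_descriptor_never_removed(self):
        rng = np.random.default_rng(13)
        X = pd.DataFrame({"a": rng.standard_normal(40),
                          "b": rng.standard_normal(40)})
        y = pd.Series(rng.standard_normal(40))
        trace = greedy_backward_selection(X, y, max_components=1)
        assert len(trace.final_descriptors) >= 1

    def test_accepted_q2_never_degrades(self):
        X, y, _ = generate_latent_dataset(
            SyntheticSpec(n=60, p=25, k=2, n_informative=5, noise_sd=0.3, seed=9))
        trace = greedy_backward_selection(X, y)
        for step in trace.accepted_steps:
            assert step.q2_after >= step.q2_before - 1e-6


class TestAugmentation:
    @staticmethod
    def _training_data(seed=21, n=60, p=10):
        X, y, _ = generate_latent_dataset(
            SyntheticSpec(n=n, p=p, k=2, n_informative=5, noise_sd=0.4, seed=seed))
        return X, y

    @staticmethod
    def _dataset_with_phb(X, phb):
        phb = [None if v is None else float(v) for v in list(phb)]
        recs = []
        for i, name in enumerate(X.index):
            recs.append(CompoundRecord(
                name=name, mw=300, logd65=2.0, psa=50.0, rotb=1,
                logs_fassif=-4.0,
                logs_phb=None if phb[i] is None else float(phb[i])))
        return SolubilityDataset(recs)

    def test_response_leak_detected(self):
        X, y = self._training_data()
        phb = np.clip(-4 + (y - y.mean()) / y.std(), -9, -0.01)
        ds = self._dataset_with_phb(X, phb)
        # replace the stored column with the response itself scaled: near-collinear
        res = augment_experimental(X, ds, y, ["phb_solubility"])
        assert res.leak_flag
        assert res.q2_augmented > 0.99

    def test_pure_noise_rejected(self):
        X, y = self._training_data(seed=22)
        rng = np.random.default_rng(5)
        phb = np.clip(rng.normal(-4, 1, len(y)), -9, -0.01)
        ds = self._dataset_with_phb(X, phb)
        res = augment_experimental(X, ds, y, ["phb_solubility"])
        assert not res.retained

    def test_correlated_column_retained(self):
        X, y = self._training_data(seed=23)
        rng = np.random.default_rng(6)
        z = (y - y.mean()) / y.std()
        noisy = 0.8 * z + np.sqrt(1 - 0.64) * rng.standard_normal(len(y))
        phb = np.clip(-4 + noisy, -9, -0.01)
        ds = self._dataset_with_phb(X, phb)
        res = augment_experimental(X, ds, y, ["phb_solubility"])
        assert res.retained
        assert res.q2_augmented > res.q2_base

    def test_missing_rows_excluded_not_imputed(self):
        X, y = self._training_data(seed=24)
        rng = np.random.default_rng(24)
        phb = [float(np.clip(rng.normal(-4, 1), -9, -0.01)) if i % 2 == 0 else None
               for i in range(len(y))]
        ds = self._dataset_with_phb(X, phb)
        res = augment_experimental(X, ds, y, ["phb_solubility"])
        assert len(res.rows) == sum(v is not None for v in phb)

    def test_entirely_missing_column_is_error(self):
        X, y = self._training_data(seed=25)
        ds = self._dataset_with_phb(X, [None] * len(y))
        with pytest.raises(ProtocolError):
            augment_experimental(X, ds, y, ["phb_solubility"])


class TestSummary:
    def test_rmse_matches_loop_oracle(self, rng):
        from conftest import random_regression
        from biosol.protocol import SplitResult
        X, y = random_regression(rng, n=30, p=5)
        m = NipalsPLS(n_components=2).fit(X, y)
        y_te = rng.standard_normal(8)
        pred = y_te + rng.standard_normal(8) * 0.5
        split = SplitResult(train=[f"t{i}" for i in range(30)],
                            test=[f"e{i}" for i in range(8)])
        s = build_summary(m, split, y_te, pred)
        acc = 0.0
        for o, p_ in zip(y_te, pred):
            acc += (o - p_) ** 2
        assert s.rmse_te == pytest.approx(np.sqrt(acc / 8), abs=1e-12)

    def test_perfect_predictor_zero_rmse(self, rng):
        from conftest import random_regression
        from biosol.protocol import SplitResult
        X, y = random_regression(rng, n=30, p=5)
        m = NipalsPLS(n_components=2).fit(X, y)
        split = SplitResult(train=list(map(str, range(30))), test=["a", "b"])
        s = build_summary(m, split, [1.0, 2.0], [1.0, 2.0])
        assert s.rmse_te == 0.0


class TestEndToEnd:
    def test_protocol_is_deterministic(self):
        X, y, _ = generate_latent_dataset(
            SyntheticSpec(n=60, p=80, k=2, n_informative=5, noise_sd=0.3, seed=17))
        a = VipGreedyPLS(keep=40).fit(X, y)
        b = VipGreedyPLS(keep=40).fit(X, y)
        assert a.selected_ == b.selected_
        assert a.q2_ == b.q2_
        assert np.array_equal(a.model_.coef_, b.model_.coef_)
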