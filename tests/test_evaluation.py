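import numpy as np
import pytest
from scipy import stats

from wborda import (
    MTSDataset,
    MTSItem,
    SearchConfig,
    SyntheticSpec,
    cross_validate,
    generate_labeled_mts,
    one_nn_classify,
    scan_components,
    wilcoxon_signed_rank,
)

from .conftest import make_item


class TestOneNN:
    def test_exact_copy_decides_the_label(self, tiny_dataset):
        query = make_item(tiny_dataset.get("a").values.copy(), "query")
        assert one_nn_classify(query, tiny_dataset) == "s"

    def test_single_item_training_set(self, rng):
        training = MTSDataset(
            [MTSItem("only", rng.normal(size=(10, 2)), label="z")]
        )
        query = make_item(rng.normal(size=(10, 2)), "q")
        assert one_nn_classify(query, training) == "z"

    def test_unlabeled_training_rejected(self, rng):
        training = MTSDataset([MTSItem("u", rng.normal(size=(10, 2)))])
        with pytest.raises(ValueError, match="unlabeled"):
            one_nn_classify(make_item(rng.normal(size=(10, 2))), training)

    def test_well_separated_classes_always_correct(self):
        dataset = generate_labeled_mts(
            SyntheticSpec(2, 5, 30, 4, 2, separation=8.0, noise_sd=0.05, seed=3)
        )
        for item in dataset:
            rest = MTSDataset([it for it in dataset if it.id != item.id])
            assert one_nn_classify(item, rest) == item.label


class TestCrossValidate:
    def test_duplicated_items_classify_perfectly(self, rng):
        base = {lab: rng.normal(size=(12, 3)) for lab in "xyz"}
        items = [
            MTSItem(f"{lab}{i}", base[lab] + 0.0, label=lab)
            for lab in "xyz"
            for i in range(4)
        ]
        with pytest.warns(RuntimeWarning, match="reducing folds"):
            report = cross_validate(MTSDataset(items), folds=10, repeats=2, seed=0)
        assert report.mean_error == 0.0

    def test_randomly_shuffled_labels_give_chance_error(self):
        # fixed geometry, labels re-dealt at random: any label-blind
        # classifier must sit at 50% on average over shuffles
        base = generate_labeled_mts(
            SyntheticSpec(2, 100, 24, 4, 2, separation=0.0, noise_sd=0.1, seed=7)
        )
        labels = [item.label for item in base]
        errors = []
        for shuffle_seed in range(5):
            rng = np.random.default_rng(shuffle_seed)
            shuffled = list(rng.permutation(labels))
            relabeled = MTSDataset(
                [
                    MTSItem(item.id, item.values, label=lab)
                    for item, lab in zip(base, shuffled)
                ]
            )
            report = cross_validate(relabeled, folds=10, repeats=1, seed=7)
            errors.append(report.mean_error)
        assert np.mean(errors) == pytest.approx(50.0, abs=5.0)

    def test_fixed_seed_reproduces_report(self):
        dataset = generate_labeled_mts(
            SyntheticSpec(2, 10, 20, 3, 2, separation=2.0, noise_sd=0.1, seed=5)
        )
        a = cross_validate(dataset, folds=5, repeats=2, seed=11)
        b = cross_validate(dataset, folds=5, repeats=2, seed=11)
        np.testing.assert_array_equal(a.fold_errors, b.fold_errors)
        assert a.mean_error == b.mean_error

    def test_mean_is_average_of_repeat_means(self):
        dataset = generate_labeled_mts(
            SyntheticSpec(2, 10, 20, 3, 2, separation=2.0, noise_sd=0.1, seed=5)
        )
        report = cross_validate(dataset, folds=5, repeats=2, seed=1)
        assert report.mean_error == pytest.approx(report.repeat_means.mean())
        assert ((report.fold_errors >= 0) & (report.fold_errors <= 100)).all()


class TestScanComponents:
    @pytest.fixture
    def dataset(self):
        return generate_labeled_mts(
            SyntheticSpec(2, 6, 20, 5, 2, separation=5.0, noise_sd=0.3, seed=2)
        )

    def test_stops_at_first_local_minimum(self, dataset):
        profile = {2: 12.0, 3: 9.0, 4: 9.0, 5: 11.0}
        best_p, best_err, table = scan_components(
            dataset, evaluator=lambda p: profile[p]
        )
        assert (best_p, best_err) == (3, 9.0)
        assert list(table) == [2, 3, 4, 5]

    def test_monotone_profile_scans_to_n(self, dataset):
        profile = {2: 12.0, 3: 10.0, 4: 8.0, 5: 6.0}
        best_p, best_err, table = scan_components(
            dataset, evaluator=lambda p: profile[p]
        )
        assert best_p == 5
        assert len(table) == 4

    def test_counts_below_variance_threshold_not_evaluated(self, dataset):
        from wborda import choose_num_components, fit_pca

        p_min = choose_num_components(
            [fit_pca(item).eigenvalues for item in dataset], 0.9
        )
        _, _, table = scan_components(dataset, evaluator=lambda p: float(p))
        assert min(table) == p_min


class TestWilcoxon:
    def test_five_positive_shifts_closed_form(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        res = wilcoxon_signed_rank(x, x + 1.0)
        assert res.w_plus == 15.0
        assert res.z == pytest.approx(2.0226, abs=1e-3)
        assert res.p_value == pytest.approx(0.0431, abs=5e-4)
        assert res.n_nonzero == 5

    def test_single_nonzero_pair(self):
        res = wilcoxon_signed_rank([1.0, 2.0], [1.0, 3.0])
        assert res.z == pytest.approx(1.0)
        assert res.p_value == pytest.approx(0.317, abs=1e-3)
        assert res.n_nonzero == 1

    def test_two_sided_p_is_symmetric(self, rng):
        x = rng.normal(size=8)
        y = rng.normal(size=8)
        assert wilcoxon_signed_rank(x, y).p_value == pytest.approx(
            wilcoxon_signed_rank(y, x).p_value
        )

    def test_all_zero_differences_undefined(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank([1.0, 2.0], [1.0, 2.0])

    def test_agrees_with_scipy_normal_approximation(self, rng):
        for _ in range(5):
            x = rng.normal(size=10)
            y = x + rng.normal(0.3, 1.0, size=10)
            res = wilcoxon_signed_rank(x, y)
            ref = stats.wilcoxon(y, x, correction=False, method="approx")
            assert res.p_value == pytest.approx(ref.pvalue, abs=1e-10)
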