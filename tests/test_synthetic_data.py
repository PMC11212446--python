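import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from noisytab.synthetic_data import (
    CohortSpec,
    LabeledTable,
    NoiseSpec,
    bayes_discriminant,
    generate_cohort,
    inject_label_noise,
    read_csv,
    split_cohort,
    write_csv,
)

from .oracles import pairwise_auroc


class TestGenerateCohort:
    def test_exact_positive_count(self):
        table = generate_cohort(CohortSpec(n_samples=1000, n_features=5, prevalence=0.05))
        assert table.labels.sum() == 50
        assert table.noise_flags.sum() == 0

    def test_no_missing_when_rate_zero(self):
        table = generate_cohort(
            CohortSpec(n_samples=200, n_features=4, missing_rate=0.0)
        )
        assert not np.isnan(table.features).any()

    def test_missing_rate_approximate(self):
        table = generate_cohort(
            CohortSpec(n_samples=5000, n_features=10, missing_rate=0.2, seed=1)
        )
        observed = np.isnan(table.features).mean()
        assert abs(observed - 0.2) < 0.01

    def test_reproducible_for_fixed_seed(self):
        spec = CohortSpec(n_samples=300, n_features=6, seed=11)
        a, b = generate_cohort(spec), generate_cohort(spec)
        np.testing.assert_array_equal(a.labels, b.labels)
        np.testing.assert_array_equal(a.features, b.features)

    def test_zero_separation_is_chance_level(self):
        """With no class shift the Bayes discriminant scores at chance AUROC."""
        spec = CohortSpec(
            n_samples=10_000, n_features=10, separation=0.0, missing_rate=0.0, seed=5
        )
        table = generate_cohort(spec)
        scores = bayes_discriminant(spec)(table.features)
        assert abs(pairwise_auroc(table.labels, scores) - 0.5) < 0.03

    def test_positive_class_shifted_by_separation(self):
        spec = CohortSpec(
            n_samples=20_000, n_features=5, prevalence=0.3, separation=1.5,
            missing_rate=0.0, seed=2,
        )
        table = generate_cohort(spec)
        shift = table.features[table.labels == 1].mean(axis=0) - table.features[
            table.labels == 0
        ].mean(axis=0)
        np.testing.assert_allclose(shift, 1.5, atol=0.1)

    @pytest.mark.parametrize(
        "kwargs, field",
        [
            ({"prevalence": 1.5}, "prevalence"),
            ({"prevalence": 0.0}, "prevalence"),
            ({"correlation": 1.0}, "correlation"),
            ({"missing_rate": -0.1}, "missing_rate"),
            ({"separation": -1.0}, "separation"),
            ({"n_features": 0}, "n_features"),
        ],
    )
    def test_invalid_spec_names_field(self, kwargs, field):
        base = dict(n_samples=100, n_features=4)
        base.update(kwargs)
        with pytest.raises(ValueError, match=field):
            CohortSpec(**base)


class TestInjectLabelNoise:
    @pytest.fixture()
    def table_10k(self):
        labels = np.array([1] * 1000 + [0] * 9000)
        features = np.zeros((10_000, 2))
        return LabeledTable(features=features, labels=labels)

    def test_exact_flip_counts(self, table_10k):
        noisy = inject_label_noise(table_10k, NoiseSpec(fn_rate=0.10, fp_rate=0.005, seed=0))
        case_flips = ((noisy.clean_labels == 1) & (noisy.labels == 0)).sum()
        control_flips = ((noisy.clean_labels == 0) & (noisy.labels == 1)).sum()
        assert case_flips == 100
        assert control_flips == 45
        assert noisy.noise_flags.sum() == 145

    def test_zero_rates_leave_labels_clean(self, table_10k):
        noisy = inject_label_noise(table_10k, NoiseSpec(fn_rate=0.0, fp_rate=0.0))
        np.testing.assert_array_equal(noisy.labels, noisy.clean_labels)

    def test_full_fn_rate_flips_every_positive(self, table_10k):
        noisy = inject_label_noise(table_10k, NoiseSpec(fn_rate=1.0, fp_rate=0.0))
        assert noisy.labels[noisy.clean_labels == 1].sum() == 0

    def test_idempotent_under_fixed_seed(self, table_10k):
        spec = NoiseSpec(fn_rate=0.3, fp_rate=0.01, seed=9)
        once = inject_label_noise(table_10k, spec)
        twice = inject_label_noise(once, spec)
        np.testing.assert_array_equal(once.labels, twice.labels)
        np.testing.assert_array_equal(once.noise_flags, twice.noise_flags)

    def test_features_and_clean_labels_untouched(self, table_10k):
        noisy = inject_label_noise(table_10k, NoiseSpec(fn_rate=0.5, fp_rate=0.1))
        np.testing.assert_array_equal(noisy.features, table_10k.features)
        np.testing.assert_array_equal(noisy.clean_labels, table_10k.clean_labels)

    def test_rejects_non_binary_labels(self):
        table = LabeledTable(features=np.zeros((3, 1)), labels=np.array([0, 1, 1]))
        table.labels = np.array([0, 1, 2])
        table.clean_labels = np.array([0, 1, 2])
        with pytest.raises(ValueError, match="binary"):
            inject_label_noise(table, NoiseSpec(fn_rate=0.1))

    @given(
        fn=st.floats(0.0, 1.0),
        fp=st.floats(0.0, 1.0),
        seed=st.integers(0, 2**20),
    )
    def test_flip_counts_follow_round_rule(self, fn, fp, seed):
        labels = np.array([1] * 37 + [0] * 163)
        table = LabeledTable(features=np.zeros((200, 1)), labels=labels)
        noisy = inject_label_noise(table, NoiseSpec(fn_rate=fn, fp_rate=fp, seed=seed))
        assert ((noisy.clean_labels == 1) & (noisy.labels == 0)).sum() == int(np.rint(fn * 37))
        assert ((noisy.clean_labels == 0) & (noisy.labels == 1)).sum() == int(np.rint(fp * 163))
        np.testing.assert_array_equal(
            noisy.noise_flags, (noisy.labels != noisy.clean_labels).astype(int)
        )


class TestSplitCohort:
    def test_sizes_and_disjoint_cover(self, small_cohort):
        train, val, test = split_cohort(small_cohort, (0.6, 0.2, 0.2), seed=0)
        assert (len(train), len(val), len(test)) == (720, 240, 240)

    def test_same_seed_identical_partition(self, small_cohort):
        a = split_cohort(small_cohort, seed=4)
        b = split_cohort(small_cohort, seed=4)
        for ta, tb in zip(a, b):
            np.testing.assert_array_equal(ta.labels, tb.labels)

    @pytest.mark.parametrize("seed", [0, 1, 17])
    def test_partition_covers_all_rows(self, seed):
        # tag each row by a unique feature value to track the partition
        n = 101
        table = LabeledTable(
            features=np.arange(n, dtype=float).reshape(-1, 1),
            labels=np.zeros(n, dtype=int),
        )
        parts = split_cohort(table, (0.6, 0.2, 0.2), seed=seed)
        ids = np.concatenate([p.features[:, 0] for p in parts])
        assert sorted(ids) == list(range(n))

    def test_fractions_must_sum_to_one(self, small_cohort):
        with pytest.raises(ValueError, match="sum to 1"):
            split_cohort(small_cohort, (0.5, 0.2, 0.2))

    def test_remainder_goes_to_train(self):
        table = LabeledTable(features=np.zeros((7, 1)), labels=np.zeros(7, dtype=int))
        train, val, test = split_cohort(table, (1 / 3, 1 / 3, 1 / 3), seed=0)
        # round(7/3) = 2 for val and test; train absorbs the remainder (3)
        assert (len(train), len(val), len(test)) == (3, 2, 2)


class TestCsvRoundTrip:
    def test_round_trip_preserves_everything(self, tmp_path):
        spec = CohortSpec(n_samples=150, n_features=4, missing_rate=0.3, seed=3)
        table = inject_label_noise(generate_cohort(spec), NoiseSpec(fn_rate=0.4, seed=1))
        path = tmp_path / "cohort.csv"
        write_csv(table, path)
        back = read_csv(path)
        np.testing.assert_allclose(back.features, table.features, equal_nan=True)
        np.testing.assert_array_equal(back.labels, table.labels)
        np.testing.assert_array_equal(back.clean_labels, table.clean_labels)
        np.testing.assert_array_equal(back.noise_flags, table.noise_flags)

    def test_missing_values_written_as_empty_fields(self, tmp_path):
        table = LabeledTable(
            features=np.array([[1.0, np.nan], [3.0, 4.0]]), labels=np.array([0, 1])
        )
        path = tmp_path / "t.csv"
        write_csv(table, path)
        lines = path.read_text().strip().splitlines()
        assert lines[1].startswith("1.0,,")

    def test_requires_label_column(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("a,b\n1,2\n")
        with pytest.raises(ValueError, match="label"):
            read_csv(path)
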