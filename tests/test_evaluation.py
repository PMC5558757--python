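import numpy as np
import pytest

from polyasig.evaluation import (
    EvalReport,
    error_rate,
    false_negative_rate,
    false_positive_rate,
    make_cv_splits,
    pool_weak_training,
    run_experiment,
    weighted_average,
)
from polyasig.features import FittedFeatureExtractor, fit_normalization
from polyasig.ga import GAConfig
from polyasig.omnitree import TreeConfig
from polyasig.seqio import PASSequence, VariantDataset
from polyasig.synthetic import default_profiles, generate_dataset

FAST_TREE = TreeConfig(
    max_depth=1, min_node_size=10,
    grids={"univariate_tree": {"confidence": [0.25]},
           "neural_net": {"hidden_units": [5]},
           "random_forest": {"n_trees": [10], "max_features": ["sqrt"]},
           "multinomial_logistic": {"ridge": [1e-2]}},
    mlp_max_iter=30,
)
FAST_GA = GAConfig(population_size=4, generations=1, seed=0)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def test_error_rate_perfect():
    assert error_rate(10, 10, 0, 0) == 0.0


def test_error_rate_inverted():
    assert error_rate(0, 0, 10, 10) == 1.0


def test_error_rate_hand_arithmetic():
    assert error_rate(8, 6, 4, 2) == pytest.approx(0.30, abs=1e-12)


def test_error_rate_zero_total():
    with pytest.raises(ValueError):
        error_rate(0, 0, 0, 0)


def test_rates():
    assert false_positive_rate(tn=6, fp=4) == pytest.approx(0.4)
    assert false_negative_rate(tp=8, fn=2) == pytest.approx(0.2)


def test_report_accuracy_complement():
    report = EvalReport()
    report.add(np.array([1, 1, 0, 0, 1]), np.array([1, 0, 0, 1, 1]))
    assert report.error_rate + report.accuracy == 1.0
    assert report.total == 5


def test_weighted_average_equal_sizes_is_mean():
    assert weighted_average([1.0, 3.0], [5, 5]) == 2.0


def test_weighted_average_identity():
    assert weighted_average([7.5], [123]) == 7.5


def test_weighted_average_bounds(rng):
    values = rng.random(10)
    sizes = rng.integers(1, 100, size=10)
    wa = weighted_average(values, sizes)
    assert values.min() <= wa <= values.max()


def test_weighted_average_errors():
    with pytest.raises(ValueError):
        weighted_average([1.0], [1, 2])
    with pytest.raises(ValueError):
        weighted_average([1.0], [0])


# ---------------------------------------------------------------------------
# CV splits
# ---------------------------------------------------------------------------

def test_cv_split_sizes():
    labels = np.array([0, 1] * 50)
    split = make_cv_splits(labels, k=5, val_frac=0.15, seed=0)
    for fold in split.folds:
        assert len(fold.test_ids) == 20
        assert len(fold.validation_ids) == 12  # floor(0.15 * 80)
        assert len(fold.train_ids) == 68


def test_cv_split_partition_and_disjointness():
    labels = np.array([0, 1] * 50)
    split = make_cv_splits(labels, k=5, seed=1)
    all_test = np.concatenate([f.test_ids for f in split.folds])
    assert sorted(all_test.tolist()) == list(range(100))
    for f in split.folds:
        sets = [set(f.train_ids), set(f.validation_ids), set(f.test_ids)]
        assert not (sets[0] & sets[1]) and not (sets[0] & sets[2]) and not (sets[1] & sets[2])
        assert sets[0] | sets[1] | sets[2] == set(range(100))


def test_cv_split_stratified():
    labels = np.array([0] * 60 + [1] * 40)
    split = make_cv_splits(labels, k=5, seed=0)
    for f in split.folds:
        test_labels = labels[f.test_ids]
        assert (test_labels == 0).sum() == 12
        assert (test_labels == 1).sum() == 8


def test_cv_split_determinism():
    labels = np.array([0, 1] * 30)
    a = make_cv_splits(labels, seed=5)
    b = make_cv_splits(labels, seed=5)
    for fa, fb in zip(a.folds, b.folds):
        np.testing.assert_array_equal(fa.train_ids, fb.train_ids)
        np.testing.assert_array_equal(fa.validation_ids, fb.validation_ids)


def test_cv_split_small_class_error():
    with pytest.raises(ValueError, match="fewer than"):
        make_cv_splits(np.array([0] * 20 + [1] * 3), k=5)


# ---------------------------------------------------------------------------
# Weak pooling
# ---------------------------------------------------------------------------

def _toy_dataset(variant, n_true, n_pseudo, seed):
    return generate_dataset(
        default_profiles("weak" if variant != "AATAAA" else "strong", 0.5,
                         variant=variant),
        n_true, n_pseudo, seed=seed,
    )


def test_pool_weak_toy_arithmetic():
    # target has 10 records (8 train / 2 test, no validation); the nine other
    # weak variants contribute 5 records each -> pooled training size 53
    from polyasig.seqio import WEAK_VARIANTS

    datasets = {}
    target = WEAK_VARIANTS[0]
    datasets[target] = _toy_dataset(target, 5, 5, seed=1)
    for i, v in enumerate(WEAK_VARIANTS[1:]):
        ds = _toy_dataset(v, 3, 2, seed=2 + i)
        datasets[v] = ds
    split = make_cv_splits(datasets[target].labels(), k=5, val_frac=0.0, seed=0)
    pooled = pool_weak_training(target, 0, datasets, split)
    assert len(pooled.train_records) == 8 + 9 * 5
    assert len(pooled.test_records) == 2
    assert all(r.variant == target for r in pooled.test_records)
    assert all(r.variant == target for r in pooled.validation_records)


def test_pool_weak_rejects_strong_target():
    datasets = {"AATAAA": _toy_dataset("AATAAA", 5, 5, seed=0)}
    split = make_cv_splits(datasets["AATAAA"].labels(), k=5, val_frac=0.0, seed=0)
    with pytest.raises(ValueError, match="weak"):
        pool_weak_training("AATAAA", 0, datasets, split)


def test_pool_weak_excludes_target_test_records():
    from polyasig.seqio import WEAK_VARIANTS

    target = WEAK_VARIANTS[2]
    datasets = {v: _toy_dataset(v, 6, 6, seed=i) for i, v in enumerate(WEAK_VARIANTS)}
    split = make_cv_splits(datasets[target].labels(), k=3, val_frac=0.2, seed=7)
    pooled = pool_weak_training(target, 1, datasets, split)
    test_seqs = {r.seq for r in pooled.test_records}
    assert not test_seqs & {r.seq for r in pooled.train_records}
    assert not test_seqs & {r.seq for r in pooled.validation_records}


# ---------------------------------------------------------------------------
# Leakage guard
# ---------------------------------------------------------------------------

def test_fitted_components_independent_of_test_fold(strong_dataset):
    records = list(strong_dataset.records)
    labels = strong_dataset.labels()
    split = make_cv_splits(labels, k=5, seed=0)
    fold = split.folds[0]
    train_seqs = [records[i].seq for i in fold.train_ids]
    y_train = labels[fold.train_ids]

    def fold_checksums():
        extractor = FittedFeatureExtractor.fit(train_seqs, y_train)
        X = extractor.extract_batch(train_seqs)
        norm = fit_normalization(X)
        return extractor.checksum(), norm.to_dict()

    before = fold_checksums()
    # mutate a test-fold record: fitted components must not change
    victim = int(fold.test_ids[0])
    seq = records[victim].seq
    mutated = ("T" if seq[0] != "T" else "G") + seq[1:]
    records[victim] = PASSequence(seq=mutated, variant=records[victim].variant,
                                  label=records[victim].label, source="synthetic")
    after = fold_checksums()
    assert before == after
    # sensitivity control: mutating a training record does change the checksum
    train_seqs[0] = ("T" if train_seqs[0][0] != "T" else "G") + train_seqs[0][1:]
    assert fold_checksums()[0] != before[0]


# ---------------------------------------------------------------------------
# Full experiment
# ---------------------------------------------------------------------------

def _separable_dataset(n_per_class=40):
    # degenerate, perfectly separable flanks
    true = [PASSequence(seq="A" * 100 + "AATAAA" + "A" * 100, variant="AATAAA",
                        label="true_pas", source="synthetic")
            for _ in range(n_per_class)]
    pseudo = [PASSequence(seq="T" * 100 + "AATAAA" + "T" * 100, variant="AATAAA",
                          label="pseudo_pas", source="synthetic")
              for _ in range(n_per_class)]
    return VariantDataset(variant="AATAAA", records=true + pseudo)


def test_experiment_perfect_signal_zero_error():
    datasets = {"AATAAA": _separable_dataset()}
    with pytest.warns(UserWarning, match="constant"):
        result = run_experiment(datasets, ga_config=FAST_GA, tree_config=FAST_TREE,
                                seed=0)
    assert result.per_variant["AATAAA"].error_rate == 0.0
    assert result.weighted_error_rate == 0.0


def test_experiment_determinism():
    ds = generate_dataset(default_profiles("strong", 1.0), 40, 40, seed=10)
    datasets = {"AATAAA": ds}
    r1 = run_experiment(datasets, ga_config=FAST_GA, tree_config=FAST_TREE, seed=3)
    r2 = run_experiment(datasets, ga_config=FAST_GA, tree_config=FAST_TREE, seed=3)
    a, b = r1.per_variant["AATAAA"], r2.per_variant["AATAAA"]
    assert (a.TP, a.TN, a.FP, a.FN) == (b.TP, b.TN, b.FP, b.FN)


def test_experiment_null_data_near_chance():
    ds = generate_dataset(default_profiles("strong", 0.0), 100, 100, seed=6)
    result = run_experiment({"AATAAA": ds}, ga_config=FAST_GA,
                            tree_config=FAST_TREE, seed=1)
    assert 0.35 <= result.per_variant["AATAAA"].error_rate <= 0.65


def test_experiment_report_tsv(tmp_path):
    ds = generate_dataset(default_profiles("strong", 1.0), 40, 40, seed=11)
    result = run_experiment({"AATAAA": ds}, ga_config=FAST_GA,
                            tree_config=FAST_TREE, seed=2)
    out = tmp_path / "report.tsv"
    result.to_tsv(out)
    lines = out.read_text().strip().splitlines()
    assert lines[0].startswith("variant\tsize")
    assert lines[-1].startswith("weighted_average")


def test_experiment_rejects_unknown_protocol():
    with pytest.raises(ValueError, match="protocol"):
        run_experiment({}, protocol="bogus")
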