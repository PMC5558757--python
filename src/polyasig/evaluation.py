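"""Training/evaluation protocol: stratified 5-fold CV with a 15% validation
holdout, training-only fitting of feature components and normalization,
PAS-weak pooling, and error metrics."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold, train_test_split

from .features import (
    FittedFeatureExtractor,
    apply_normalization,
    fit_normalization,
)
from .ga import GAConfig, decode, evolve
from .omnitree import TreeConfig, derive_seed, fit_tree, predict_tree
from .seqio import VariantDataset, classify_variant


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def error_rate(tp: int, tn: int, fp: int, fn: int) -> float:
    """1 - (TP + TN) / (TP + TN + FP + FN)."""
    total = tp + tn + fp + fn
    if total <= 0:
        raise ValueError("no predictions to score")
    return 1.0 - (tp + tn) / total


def false_positive_rate(tn: int, fp: int) -> float:
    return fp / (fp + tn) if (fp + tn) > 0 else 0.0


def false_negative_rate(tp: int, fn: int) -> float:
    return fn / (fn + tp) if (fn + tp) > 0 else 0.0


def weighted_average(values, sizes) -> float:
    """Size-weighted mean: sum(size_i * value_i) / sum(size_i)."""
    values = np.asarray(values, dtype=float)
    sizes = np.asarray(sizes, dtype=float)
    if values.shape != sizes.shape:
        raise ValueError("values and sizes must be aligned")
    if np.any(sizes <= 0):
        raise ValueError("sizes must be positive")
    return float((values * sizes).sum() / sizes.sum())


@dataclass
class EvalReport:
    TP: int = 0
    TN: int = 0
    FP: int = 0
    FN: int = 0

    def add(self, y_true: np.ndarray, y_pred: np.ndarray) -> None:
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        self.TP += int(((y_pred == 1) & (y_true == 1)).sum())
        self.TN += int(((y_pred == 0) & (y_true == 0)).sum())
        self.FP += int(((y_pred == 1) & (y_true == 0)).sum())
        self.FN += int(((y_pred == 0) & (y_true == 1)).sum())

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN

    @property
    def error_rate(self) -> float:
        return error_rate(self.TP, self.TN, self.FP, self.FN)

    @property
    def accuracy(self) -> float:
        return (self.TP + self.TN) / self.total

    @property
    def fpr(self) -> float:
        return false_positive_rate(self.TN, self.FP)

    @property
    def fnr(self) -> float:
        return false_negative_rate(self.TP, self.FN)


# ---------------------------------------------------------------------------
# Cross-validation splits
# ---------------------------------------------------------------------------

@dataclass
class FoldSplit:
    train_ids: np.ndarray
    validation_ids: np.ndarray
    test_ids: np.ndarray


@dataclass
class CVSplit:
    k: int
    val_frac: float
    seed: int
    folds: list[FoldSplit] = field(default_factory=list)


def make_cv_splits(labels, k: int = 5, val_frac: float = 0.15,
                   seed: int = 0) -> CVSplit:
    """Stratified k-fold split with a stratified validation holdout per fold.

    The validation set holds floor(val_frac * n_train) records drawn from the
    fold's training portion; the test fold is used only for final scoring.
    """
    labels = np.asarray(labels)
    for cls in np.unique(labels):
        if (labels == cls).sum() < k:
            raise ValueError(f"class {cls} has fewer than k={k} records")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = []
    for fold_idx, (train_idx, test_idx) in enumerate(skf.split(np.zeros(len(labels)), labels)):
        n_val = int(np.floor(val_frac * len(train_idx)))
        if n_val > 0:
            # holdouts smaller than the number of classes cannot be stratified
            stratify = labels[train_idx] if n_val >= len(np.unique(labels)) else None
            train_ids, val_ids = train_test_split(
                train_idx, test_size=n_val, stratify=stratify,
                random_state=derive_seed(seed, fold_idx) % (2 ** 32),
            )
        else:
            train_ids, val_ids = train_idx, np.array([], dtype=int)
        folds.append(FoldSplit(
            train_ids=np.sort(train_ids),
            validation_ids=np.sort(val_ids),
            test_ids=np.sort(test_idx),
        ))
    return CVSplit(k=k, val_frac=val_frac, seed=seed, folds=folds)


@dataclass
class PooledFold:
    """One fold of the weak-variant pooling protocol.

    ``train_records`` = the target variant's training portion for the fold
    plus every record of the other nine weak variants; validation and test
    records come exclusively from the target variant.
    """

    target_variant: str
    train_records: list
    validation_records: list
    test_records: list


def pool_weak_training(
    target_variant: str,
    fold: int,
    datasets: dict[str, VariantDataset],
    split: CVSplit,
) -> PooledFold:
    """Build the pooled training set for a weak variant (Fig.-7 style protocol)."""
    if classify_variant(target_variant) != "weak":
        raise ValueError(
            f"pooling is defined only for weak variants, got {target_variant!r}"
        )
    target = datasets[target_variant]
    fs = split.folds[fold]
    train = [target.records[i] for i in fs.train_ids]
    for variant, ds in sorted(datasets.items()):
        if variant == target_variant or classify_variant(variant) != "weak":
            continue
        train.extend(ds.records)
    return PooledFold(
        target_variant=target_variant,
        train_records=train,
        validation_records=[target.records[i] for i in fs.validation_ids],
        test_records=[target.records[i] for i in fs.test_ids],
    )


# ---------------------------------------------------------------------------
# Full experiment
# ---------------------------------------------------------------------------

def _labels(records) -> np.ndarray:
    return np.array([int(r.label == "true_pas") for r in records])


def _fit_and_score_fold(
    train_records, val_records, test_records,
    ga_config: GAConfig, tree_config: TreeConfig, fold_seed: int,
):
    """Fit every training-dependent component on the fold's training data only,
    run the GA on train/validation, and score the refit best tree on test."""
    train_seqs = [r.seq for r in train_records]
    y_train = _labels(train_records)
    extractor = FittedFeatureExtractor.fit(train_seqs, y_train)
    X_train = extractor.extract_batch(train_seqs)
    norm = fit_normalization(X_train)
    X_train = apply_normalization(X_train, norm)
    X_val = apply_normalization(
        extractor.extract_batch([r.seq for r in val_records]), norm
    )
    y_val = _labels(val_records)
    X_test = apply_normalization(
        extractor.extract_batch([r.seq for r in test_records]), norm
    )
    y_test = _labels(test_records)

    fold_ga = GAConfig(**{**ga_config.__dict__, "seed": fold_seed})
    best_genome, history = evolve(
        (X_train, y_train), (X_val, y_val), fold_ga, tree_config
    )
    tree = fit_tree(
        X_train, y_train, decode(best_genome, tree_config),
        seed=derive_seed(fold_seed, best_genome.tobytes()), config=tree_config,
    )
    y_pred = predict_tree(tree, X_test)
    return y_test, y_pred, history


@dataclass
class ExperimentResult:
    per_variant: dict[str, EvalReport]
    sizes: dict[str, int]

    @property
    def weighted_error_rate(self) -> float:
        variants = sorted(self.per_variant)
        return weighted_average(
            [self.per_variant[v].error_rate for v in variants],
            [self.sizes[v] for v in variants],
        )

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("variant\tsize\terror_rate_pct\tfpr_pct\tfnr_pct\n")
            for v in sorted(self.per_variant):
                r = self.per_variant[v]
                fh.write(f"{v}\t{self.sizes[v]}\t{100 * r.error_rate:.2f}"
                         f"\t{100 * r.fpr:.2f}\t{100 * r.fnr:.2f}\n")
            fh.write(f"weighted_average\t{sum(self.sizes.values())}"
                     f"\t{100 * self.weighted_error_rate:.2f}\t\t\n")


def desk_scale_configs(seed: int = 0) -> tuple[GAConfig, TreeConfig]:
    """Reduced GA/tree configuration sized for minutes-scale synthetic runs.

    Single-node trees with trimmed hyperparameter grids and a small GA budget;
    the full defaults (GAConfig()/TreeConfig()) remain available for real
    benchmark-scale experiments.
    """
    tree_config = TreeConfig(
        max_depth=1,
        min_node_size=30,
        grids={
            "univariate_tree": {"confidence": [0.1, 0.25, 0.5]},
            "neural_net": {"hidden_units": [5, 10]},
            "random_forest": {"n_trees": [25, 50], "max_features": ["sqrt", "log2", "all"]},
            "multinomial_logistic": {"ridge": [1e-4, 1e-2, 1.0]},
        },
        mlp_max_iter=100,
    )
    ga_config = GAConfig(population_size=6, generations=3, seed=seed)
    return ga_config, tree_config


def synthetic_cv_error(
    signal_strength: float,
    n_per_class: int = 400,
    seed: int = 0,
    kind: str = "strong",
    ga_config: GAConfig | None = None,
    tree_config: TreeConfig | None = None,
    k: int = 5,
) -> float:
    """End-to-end k-fold CV error of the full pipeline on generated data."""
    from .synthetic import default_profiles, generate_dataset

    if ga_config is None or tree_config is None:
        default_ga, default_tree = desk_scale_configs(seed)
        ga_config = ga_config or default_ga
        tree_config = tree_config or default_tree
    dataset = generate_dataset(
        default_profiles(kind, signal_strength), n_per_class, n_per_class,
        seed=derive_seed(seed, "data", signal_strength) % (2 ** 32),
    )
    result = run_experiment(
        {dataset.variant: dataset}, protocol="per-variant",
        ga_config=ga_config, tree_config=tree_config, k=k, seed=seed,
    )
    return result.weighted_error_rate


def run_experiment(
    datasets: dict[str, VariantDataset],
    protocol: str = "per-variant",
    ga_config: GAConfig | None = None,
    tree_config: TreeConfig | None = None,
    k: int = 5,
    val_frac: float = 0.15,
    seed: int = 0,
) -> ExperimentResult:
    """Run the full protocol and pool confusion counts over folds per variant.

    ``protocol``: "per-variant" trains on each variant's own training portion;
    "weak-pooled" additionally pools all records of the other nine weak
    variants into the training set of each weak target variant.
    """
    if protocol not in ("per-variant", "weak-pooled"):
        raise ValueError(f"unknown protocol {protocol!r}")
    ga_config = ga_config or GAConfig()
    tree_config = tree_config or TreeConfig()
    per_variant: dict[str, EvalReport] = {}
    sizes: dict[str, int] = {}
    splits = {
        variant: make_cv_splits(_labels(ds.records), k=k, val_frac=val_frac,
                                seed=derive_seed(seed, variant) % (2 ** 32))
        for variant, ds in datasets.items()
    }
    for variant in sorted(datasets):
        ds = datasets[variant]
        report = EvalReport()
        split = splits[variant]
        for fold in range(k):
            if protocol == "weak-pooled" and classify_variant(variant) == "weak":
                pooled = pool_weak_training(variant, fold, datasets, split)
                train_records = pooled.train_records
                val_records = pooled.validation_records
                test_records = pooled.test_records
            else:
                fs = split.folds[fold]
                train_records = [ds.records[i] for i in fs.train_ids]
                val_records = [ds.records[i] for i in fs.validation_ids]
                test_records = [ds.records[i] for i in fs.test_ids]
            y_test, y_pred, _ = _fit_and_score_fold(
                train_records, val_records, test_records,
                ga_config, tree_config,
                fold_seed=derive_seed(seed, variant, fold) % (2 ** 32),
            )
            report.add(y_test, y_pred)
        per_variant[variant] = report
        sizes[variant] = len(ds.records)
    return ExperimentResult(per_variant=per_variant, sizes=sizes)
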