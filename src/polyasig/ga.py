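"""Genetic algorithm over tree structure, node families and hyperparameters.

The genome is a flat integer vector with 4 genes per internal tree slot:
[prune bit, family index, hyperparameter gene 1, hyperparameter gene 2].
Hyperparameter genes index into the active family's discrete grids; genes a
family does not use are carried along (and canonicalized to 0 by ``encode``).
Fitness of a genome is the validation error rate of the tree it decodes to,
fitted on the training split with a seed derived from (run seed, genome), so
parallel and serial evaluation orders give identical results.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from joblib import Parallel, delayed

from .omnitree import (
    FAMILIES,
    FAMILY_GENES,
    NodeClassifierSpec,
    TreeConfig,
    derive_seed,
    fit_tree,
    predict_tree,
)

GENES_PER_SLOT = 4


@dataclass
class GAConfig:
    population_size: int = 40
    generations: int = 25
    tournament_size: int = 3
    crossover_prob: float = 0.9
    mutation_prob_per_gene: float = 0.03
    elitism_count: int = 1
    seed: int = 0
    n_workers: int = 1

    def __post_init__(self):
        if not (self.population_size >= self.elitism_count >= 0):
            raise ValueError("population_size >= elitism_count >= 0 required")
        for p in (self.crossover_prob, self.mutation_prob_per_gene):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")


def gene_cardinalities(tree_config: TreeConfig) -> np.ndarray:
    """Number of admissible values for each gene position."""
    h1 = max(
        (len(tree_config.grids[f][g]) for f, (g, _) in FAMILY_GENES.items() if g),
        default=1,
    )
    h2 = max(
        (len(tree_config.grids[f][g]) for f, (_, g) in FAMILY_GENES.items() if g),
        default=1,
    )
    per_slot = [2, len(FAMILIES), h1, h2]
    return np.array(per_slot * tree_config.n_internal_slots, dtype=np.int64)


def decode(genome: np.ndarray, tree_config: TreeConfig) -> dict[int, tuple[bool, NodeClassifierSpec | None]]:
    """Genome -> {heap slot index: (pruned, node classifier spec)}."""
    genome = np.asarray(genome, dtype=np.int64)
    n_slots = tree_config.n_internal_slots
    if len(genome) != n_slots * GENES_PER_SLOT:
        raise ValueError(
            f"genome length {len(genome)} != {n_slots * GENES_PER_SLOT}"
        )
    spec: dict[int, tuple[bool, NodeClassifierSpec | None]] = {}
    for slot in range(n_slots):
        prune, fam_idx, h1, h2 = genome[slot * GENES_PER_SLOT:(slot + 1) * GENES_PER_SLOT]
        idx = slot + 1  # heap index
        if prune:
            spec[idx] = (True, None)
            continue
        family = FAMILIES[fam_idx % len(FAMILIES)]
        grids = tree_config.grids[family]
        hp = {}
        for gene_value, grid_name in zip((h1, h2), FAMILY_GENES[family]):
            if grid_name is not None:
                grid = grids[grid_name]
                hp[grid_name] = grid[gene_value % len(grid)]
        spec[idx] = (False, NodeClassifierSpec(family=family, hyperparams=hp))
    return spec


def encode(spec: dict[int, tuple[bool, NodeClassifierSpec | None]],
           tree_config: TreeConfig) -> np.ndarray:
    """Inverse of :func:`decode`; unused genes canonicalize to 0."""
    genome = np.zeros(tree_config.n_internal_slots * GENES_PER_SLOT, dtype=np.int64)
    for slot in range(tree_config.n_internal_slots):
        idx = slot + 1
        pruned, node_spec = spec.get(idx, (True, None))
        base = slot * GENES_PER_SLOT
        if pruned or node_spec is None:
            genome[base] = 1
            continue
        genome[base + 1] = FAMILIES.index(node_spec.family)
        grids = tree_config.grids[node_spec.family]
        for offset, grid_name in zip((2, 3), FAMILY_GENES[node_spec.family]):
            if grid_name is not None:
                genome[base + offset] = grids[grid_name].index(
                    node_spec.hyperparams[grid_name]
                )
    return genome


def n_pruned(genome: np.ndarray) -> int:
    return int(np.asarray(genome)[::GENES_PER_SLOT].sum())


def _evaluate(genome: np.ndarray, X_train, y_train, X_val, y_val,
              seed: int, tree_config: TreeConfig) -> float:
    fit_seed = derive_seed(seed, np.asarray(genome, dtype=np.int64).tobytes())
    tree = fit_tree(X_train, y_train, decode(genome, tree_config),
                    seed=fit_seed, config=tree_config)
    pred = predict_tree(tree, X_val)
    return float((pred != np.asarray(y_val)).mean())


@dataclass
class FitnessHistory:
    generations: list[dict] = field(default_factory=list)

    def record(self, gen: int, fitnesses: np.ndarray, best_ever: float) -> None:
        self.generations.append({
            "generation": gen,
            "best": float(fitnesses.min()),
            "mean": float(fitnesses.mean()),
            "median": float(np.median(fitnesses)),
            "worst": float(fitnesses.max()),
            "best_ever": best_ever,
        })

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("generation\tbest\tmean\tmedian\tworst\tbest_ever\n")
            for row in self.generations:
                fh.write(
                    "{generation}\t{best}\t{mean}\t{median}\t{worst}\t{best_ever}\n"
                    .format(**row)
                )


def evolve(
    train: tuple[np.ndarray, np.ndarray],
    validation: tuple[np.ndarray, np.ndarray],
    config: GAConfig,
    tree_config: TreeConfig | None = None,
) -> tuple[np.ndarray, FitnessHistory]:
    """Run the GA; returns (best-ever genome, per-generation fitness history).

    Selection is tournament, crossover is uniform, mutation redraws each gene
    uniformly from its range.  Fitness ties prefer more pruned genomes, then
    the earlier evaluation index.  With elitism >= 1 the best-ever fitness is
    non-increasing across generations.
    """
    tree_config = tree_config or TreeConfig()
    X_train, y_train = (np.asarray(a) for a in train)
    X_val, y_val = (np.asarray(a) for a in validation)
    if len(X_val) == 0:
        raise ValueError("empty validation set")
    cards = gene_cardinalities(tree_config)
    rng = np.random.default_rng(config.seed)

    def random_genome() -> np.ndarray:
        return rng.integers(0, cards, dtype=np.int64)

    def evaluate_population(pop: list[np.ndarray]) -> np.ndarray:
        if config.n_workers > 1:
            results = Parallel(n_jobs=config.n_workers, backend="threading")(
                delayed(_evaluate)(g, X_train, y_train, X_val, y_val,
                                   config.seed, tree_config)
                for g in pop
            )
            fits = np.asarray(results, dtype=float)
        else:
            fits = np.array([
                _evaluate(g, X_train, y_train, X_val, y_val, config.seed, tree_config)
                for g in pop
            ])
        if not np.all(np.isfinite(fits)):
            raise ValueError("non-finite fitness encountered")
        return fits

    def sort_key(i: int, fits: np.ndarray, pop: list[np.ndarray]):
        return (fits[i], -n_pruned(pop[i]), i)

    population = [random_genome() for _ in range(config.population_size)]
    fitnesses = evaluate_population(population)
    order = sorted(range(len(population)), key=lambda i: sort_key(i, fitnesses, population))
    best_genome = population[order[0]].copy()
    best_fitness = float(fitnesses[order[0]])
    best_pruned = n_pruned(best_genome)
    history = FitnessHistory()
    history.record(0, fitnesses, best_fitness)

    for gen in range(1, config.generations + 1):
        elites = [population[i].copy() for i in order[:config.elitism_count]]
        offspring: list[np.ndarray] = []
        while len(elites) + len(offspring) < config.population_size:
            parents = []
            for _ in range(2):
                contenders = rng.integers(0, len(population), size=config.tournament_size)
                winner = min(contenders, key=lambda i: sort_key(i, fitnesses, population))
                parents.append(population[winner])
            c1, c2 = parents[0].copy(), parents[1].copy()
            if rng.random() < config.crossover_prob:
                swap = rng.random(len(c1)) < 0.5
                c1[swap], c2[swap] = parents[1][swap], parents[0][swap]
            for child in (c1, c2):
                mutate = rng.random(len(child)) < config.mutation_prob_per_gene
                if mutate.any():
                    child[mutate] = rng.integers(0, cards[mutate])
                if len(elites) + len(offspring) < config.population_size:
                    offspring.append(child)
        population = elites + offspring
        fitnesses = evaluate_population(population)
        order = sorted(range(len(population)), key=lambda i: sort_key(i, fitnesses, population))
        gen_best = order[0]
        cand_fit = float(fitnesses[gen_best])
        cand_pruned = n_pruned(population[gen_best])
        if (cand_fit, -cand_pruned) < (best_fitness, -best_pruned):
            best_genome = population[gen_best].copy()
            best_fitness = cand_fit
            best_pruned = cand_pruned
        history.record(gen, fitnesses, best_fitness)

    return best_genome, history
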