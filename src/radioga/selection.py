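"""Feature conditioning and genetic-algorithm feature selection.

The selector evolves fixed-size chromosomes (sets of feature indices)
toward high cross-validated classification accuracy, collects many
independently evolved solutions, and ranks features by how often they
appear across solutions (gene-rank stability). A greedy forward pass over
the stable ranking then builds a compact representative model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier

from .io import ValidationError
from .tables import FeatureTable


def drop_zero_variance(table: FeatureTable) -> FeatureTable:
    """Remove exactly the columns whose sample variance is zero."""
    if table.n_samples == 0 or table.n_features == 0:
        raise ValidationError("empty table")
    var = table.values.var(axis=0)
    keep = np.flatnonzero(var > 0)
    if keep.size == 0:
        raise ValidationError("all columns have zero variance")
    return table.subset(keep)


def whiten(table: FeatureTable) -> FeatureTable:
    """Standardize every column to mean 0 and sample (n-1) sd 1."""
    sd = table.values.std(axis=0, ddof=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        names = [table.feature_names[i] for i in bad[:5]]
        raise ValidationError(
            f"zero-variance columns {names} cannot be whitened; "
            "run drop_zero_variance first"
        )
    values = (table.values - table.values.mean(axis=0)) / sd
    return FeatureTable(values, list(table.feature_names), table.labels.copy())


@dataclass
class Chromosome:
    """A fixed-size set of feature indices with its fitness."""

    genes: tuple[int, ...]
    fitness: float = float("nan")

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError("duplicate genes in chromosome")


@dataclass(frozen=True)
class GAConfig:
    """Genetic-algorithm settings.

    An evolution run stops when the best fitness reaches ``fitness_goal``
    or after ``max_generations`` generations. ``n_solutions`` independent
    runs (seeds derived from the master seed) feed the stability ranking.
    """

    chromosome_size: int = 5
    population_size: int = 50
    max_generations: int = 300
    fitness_goal: float = 0.90
    mutation_rate: float = 0.05
    n_solutions: int = 100
    inner_cv_folds: int = 3
    classifier: str = "knn"  # knn | logistic | random_forest
    seed: int = 0

    def __post_init__(self) -> None:
        if min(
            self.chromosome_size,
            self.population_size,
            self.max_generations,
            self.n_solutions,
            self.inner_cv_folds,
        ) <= 0:
            raise ValidationError("GA sizes must be positive")
        if not 0 < self.fitness_goal <= 1 and self.fitness_goal <= 1:
            raise ValidationError("fitness_goal must be in (0, 1]")


@dataclass
class GAResult:
    """Bookkeeping of many independent evolution runs."""

    solutions: list[Chromosome]
    feature_names: list[str]

    @property
    def gene_frequency(self) -> np.ndarray:
        """Per-feature count of appearances across final solutions."""
        freq = np.zeros(len(self.feature_names), dtype=int)
        for c in self.solutions:
            for g in c.genes:
                freq[g] += 1
        return freq

    @property
    def rank_trajectory(self) -> list[list[int]]:
        """Per-solution gene lists in within-chromosome order."""
        return [list(c.genes) for c in self.solutions]

    def to_dict(self) -> dict:
        return {
            "feature_names": self.feature_names,
            "solutions": [
                {"genes": list(c.genes), "fitness": c.fitness} for c in self.solutions
            ],
            "gene_frequency": self.gene_frequency.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GAResult":
        return cls(
            solutions=[Chromosome(tuple(s["genes"]), s["fitness"]) for s in d["solutions"]],
            feature_names=list(d["feature_names"]),
        )


def _make_classifier(name: str, seed: int):
    if name == "knn":
        return KNeighborsClassifier(n_neighbors=3)
    if name == "logistic":
        from sklearn.linear_model import LogisticRegression

        return LogisticRegression(max_iter=200)
    if name == "random_forest":
        from sklearn.ensemble import RandomForestClassifier

        return RandomForestClassifier(n_estimators=50, random_state=seed)
    raise ValidationError(f"unknown inner classifier {name!r}")


def _knn3_predict(X_train: np.ndarray, y_train: np.ndarray, X_test: np.ndarray) -> np.ndarray:
    """3-nearest-neighbor majority vote (vectorized; binary labels)."""
    from scipy.spatial.distance import cdist

    d = cdist(X_test, X_train)
    k = min(3, X_train.shape[0])
    nearest = np.argpartition(d, k - 1, axis=1)[:, :k]
    return (y_train[nearest].sum(axis=1) * 2 > k).astype(int)


def fitness(
    genes,
    table: FeatureTable,
    inner_cv_folds: int = 3,
    seed: int = 0,
    classifier: str = "knn",
    _folds=None,
) -> float:
    """Stratified inner-CV accuracy of a chromosome's feature subset.

    Whitening statistics are fit on each training partition only, so no
    test-fold information leaks into the inner classifier. The default
    3-NN scorer is a vectorized in-package routine (it agrees with
    scikit-learn's classifier; see the test suite).
    """
    y = table.labels
    if len(np.unique(y)) < 2:
        raise ValidationError("both classes must be present")
    X = table.values[:, list(genes)]
    if _folds is None:
        skf = StratifiedKFold(n_splits=inner_cv_folds, shuffle=True, random_state=seed)
        _folds = list(skf.split(X, y))
    correct = 0
    for tr, te in _folds:
        mu = X[tr].mean(axis=0)
        sd = X[tr].std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        Xtr = (X[tr] - mu) / sd
        Xte = (X[te] - mu) / sd
        if classifier == "knn":
            pred = _knn3_predict(Xtr, y[tr], Xte)
        else:
            clf = _make_classifier(classifier, seed)
            clf.fit(Xtr, y[tr])
            pred = clf.predict(Xte)
        correct += int((pred == y[te]).sum())
    return correct / len(y)


class _FitnessCache:
    """Memoizes fitness per gene set; GA populations repeat chromosomes."""

    def __init__(self, table: FeatureTable, config: GAConfig, seed: int):
        self.table = table
        self.config = config
        self.seed = seed
        skf = StratifiedKFold(
            n_splits=config.inner_cv_folds, shuffle=True, random_state=seed
        )
        self._folds = list(skf.split(table.values, table.labels))
        self._cache: dict[frozenset, float] = {}

    def __call__(self, genes) -> float:
        key = frozenset(genes)
        if key not in self._cache:
            self._cache[key] = fitness(
                genes,
                self.table,
                self.config.inner_cv_folds,
                self.seed,
                self.config.classifier,
                _folds=self._folds,
            )
        return self._cache[key]


def _random_chromosome(rng: np.random.Generator, n_features: int, size: int) -> tuple:
    return tuple(rng.choice(n_features, size=size, replace=False).tolist())


def _mutate(genes: tuple, rng: np.random.Generator, n_features: int, rate: float) -> tuple:
    out = list(genes)
    for i in range(len(out)):
        if rng.random() < rate:
            pool = np.setdiff1d(np.arange(n_features), out)
            out[i] = int(rng.choice(pool))
    return tuple(out)


def _crossover(a: tuple, b: tuple, rng: np.random.Generator, n_features: int) -> tuple:
    """Single-point crossover with duplicate repair."""
    size = len(a)
    point = int(rng.integers(1, size)) if size > 1 else 0
    child = list(a[:point]) + list(b[point:])
    seen = set()
    for i, g in enumerate(child):
        if g in seen:
            pool = np.setdiff1d(np.arange(n_features), list(seen | set(child)))
            child[i] = int(rng.choice(pool))
        seen.add(child[i])
    return tuple(child)


def evolve(
    table: FeatureTable,
    config: GAConfig,
    seed: int | None = None,
    return_history: bool = False,
):
    """One evolution run: tournament selection (size 2), elitism of 1,
    single-point crossover with duplicate repair, per-gene mutation.

    Stops as soon as the best fitness reaches ``fitness_goal``, else after
    ``max_generations``; reproducible given the seed. With
    ``return_history`` the per-generation best fitness trace is returned
    alongside the chromosome.
    """
    if table.n_features < config.chromosome_size:
        raise ValidationError("fewer features than chromosome size")
    if len(np.unique(table.labels)) < 2:
        raise ValidationError("both classes must be present")
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    evaluate = _FitnessCache(table, config, seed)
    n_feat = table.n_features
    pop = [
        _random_chromosome(rng, n_feat, config.chromosome_size)
        for _ in range(config.population_size)
    ]
    fits = [evaluate(c) for c in pop]
    best_i = int(np.argmax(fits))
    best = Chromosome(pop[best_i], fits[best_i])
    history = [best.fitness]
    for _ in range(config.max_generations):
        if best.fitness >= config.fitness_goal:
            break
        new_pop = [best.genes]  # elitism of 1
        while len(new_pop) < config.population_size:
            parents = []
            for _ in range(2):
                i, j = rng.integers(0, config.population_size, size=2)
                parents.append(pop[i] if fits[i] >= fits[j] else pop[j])
            child = _crossover(parents[0], parents[1], rng, n_feat)
            child = _mutate(child, rng, n_feat, config.mutation_rate)
            new_pop.append(child)
        pop = new_pop
        fits = [evaluate(c) for c in pop]
        gen_best = int(np.argmax(fits))
        if fits[gen_best] >= best.fitness:
            best = Chromosome(pop[gen_best], fits[gen_best])
        history.append(best.fitness)
    if return_history:
        return best, history
    return best


def collect_solutions(table: FeatureTable, config: GAConfig) -> GAResult:
    """Run ``n_solutions`` independent evolutions; seeds derive from the
    master seed so the whole result is reproducible."""
    ss = np.random.SeedSequence(config.seed)
    child_seeds = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(config.n_solutions)]
    solutions = [evolve(table, config, seed=s) for s in child_seeds]
    return GAResult(solutions=solutions, feature_names=list(table.feature_names))


def stable_genes(result: GAResult, k: int) -> list[str]:
    """Top-k feature names by appearance frequency across solutions.

    Ties break by mean within-chromosome rank (earlier positions first),
    then by name.
    """
    if k > len(result.feature_names):
        raise ValidationError("k exceeds the number of features")
    freq = result.gene_frequency
    rank_sum = np.zeros(len(result.feature_names))
    for c in result.solutions:
        for pos, g in enumerate(c.genes):
            rank_sum[g] += pos
    order = sorted(
        range(len(result.feature_names)),
        key=lambda i: (
            -freq[i],
            rank_sum[i] / freq[i] if freq[i] else np.inf,
            result.feature_names[i],
        ),
    )
    return [result.feature_names[i] for i in order[:k]]


def forward_select(
    table: FeatureTable,
    ranked_genes: list[str],
    inner_cv_folds: int = 3,
    seed: int = 0,
    classifier: str = "knn",
) -> list[str]:
    """Greedy forward pass over a ranked gene list.

    The first gene is always kept; each later gene is kept iff it strictly
    improves the inner-CV accuracy of the growing model. One full pass.
    """
    if not ranked_genes:
        raise ValidationError("ranked_genes is empty")
    kept = [ranked_genes[0]]
    idx = [table.feature_names.index(g) for g in kept]
    best = fitness(idx, table, inner_cv_folds, seed, classifier)
    for gene in ranked_genes[1:]:
        trial = idx + [table.feature_names.index(gene)]
        acc = fitness(trial, table, inner_cv_folds, seed, classifier)
        if acc > best:
            best = acc
            idx = trial
            kept.append(gene)
    return kept
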