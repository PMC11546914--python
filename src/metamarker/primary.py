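"""Genetic-algorithm search for discriminative metabolite combinations.

Individual metabolites rarely separate the two patient groups, but small
combinations can.  The search evolves fixed-size subsets of metabolites with
a genetic algorithm whose fitness is the *minimum* held-out-fold accuracy of
a gradient-boosted tree classifier (XGBoost, 1000 rounds, learning rate
0.05) under stratified 5-fold cross-validation — taking the worst fold makes
the fitness pessimistic and punishes subsets that only separate part of the
cohort.  Repeating the search over many independently seeded runs and
recording how often each metabolite appears in the per-run best combination
("inclusion frequency") ranks metabolites by the stability of their
contribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import xgboost as xgb
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import KFold, StratifiedKFold

from .io_prep import MetabolomicMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FitnessConfig:
    """Cross-validated booster settings behind the GA fitness."""

    n_folds: int = 5
    booster_rounds: int = 1000
    booster_learning_rate: float = 0.05
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")


@dataclass
class GAConfig:
    """Genetic-algorithm operator settings.

    One independent GA pass is run per subset size and per run; each pass
    keeps its best combination.  ``stagnation_patience`` stops a pass early
    once the best fitness has not improved for that many generations.
    """

    subset_sizes: tuple[int, ...] = (3, 4)
    population_size: int = 50
    generations: int = 100
    mutation_rate: float = 0.1
    crossover_rate: float = 0.9
    tournament_size: int = 3
    elitism: int = 1
    stagnation_patience: int | None = 10
    n_runs: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if any(k < 1 for k in self.subset_sizes):
            raise ValueError("subset sizes must be >= 1")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")


@dataclass(frozen=True)
class MarkerCombination:
    metabolite_ids: frozenset[str]
    fitness: float


@dataclass
class PrimarySearchResult:
    """Aggregated GA output.

    ``retained`` lists the best combination of every (run, subset size) pass;
    ``combinations`` is the deduplicated list (max fitness per member set);
    ``inclusion_frequency`` is the fraction of retained combinations
    containing each metabolite that appears at least once.
    """

    combinations: list[MarkerCombination]
    retained: list[MarkerCombination] = field(repr=False, default_factory=list)
    inclusion_frequency: dict[str, float] = field(default_factory=dict)

    @property
    def union_size(self) -> int:
        return len(set().union(*(c.metabolite_ids for c in self.combinations)))


class FitnessEvaluator:
    """Caches fold assignment and per-subset fitness for one GA run.

    Sharing folds across every subset evaluated within a run removes fold
    noise from fitness comparisons inside that run.
    """

    def __init__(self, m: MetabolomicMatrix, cfg: FitnessConfig):
        if np.isnan(m.values).any():
            raise ValueError("fitness requires an imputed matrix")
        counts = (int(m.case_mask.sum()), int(m.control_mask.sum()))
        if min(counts) < cfg.n_folds:
            raise ValueError(
                f"both group sizes {counts} must be >= n_folds={cfg.n_folds}"
            )
        self.cfg = cfg
        self.X = m.values
        self.y = m.case_mask.astype(int)
        self.metabolite_ids = list(m.metabolite_ids)
        splitter = (
            StratifiedKFold(cfg.n_folds, shuffle=True, random_state=cfg.seed)
            if cfg.stratified
            else KFold(cfg.n_folds, shuffle=True, random_state=cfg.seed)
        )
        self.folds = list(splitter.split(self.X, self.y))
        self._params = {
            "objective": "binary:logistic",
            "eta": cfg.booster_learning_rate,
            "tree_method": "exact",
            "nthread": 1,
            "seed": cfg.seed,
            "verbosity": 0,
        }
        self._cache: dict[frozenset[int], tuple[float, np.ndarray]] = {}

    def _evaluate(self, subset: frozenset[int]) -> tuple[float, np.ndarray]:
        cached = self._cache.get(subset)
        if cached is not None:
            return cached
        cols = sorted(subset)
        Xs = self.X[:, cols]
        accs = []
        oof = np.empty(len(self.y))
        for train, test in self.folds:
            dtrain = xgb.DMatrix(Xs[train], label=self.y[train])
            bst = xgb.train(self._params, dtrain, num_boost_round=self.cfg.booster_rounds)
            prob = bst.predict(xgb.DMatrix(Xs[test]))
            oof[test] = prob
            accs.append(float(np.mean((prob > 0.5).astype(int) == self.y[test])))
        result = (min(accs), oof)
        self._cache[subset] = result
        return result

    def fitness(self, subset: frozenset[int]) -> float:
        if not subset:
            raise ValueError("subset must be nonempty")
        return self._evaluate(frozenset(subset))[0]

    def oof_scores(self, subset: frozenset[int]) -> np.ndarray:
        """Pooled out-of-fold case probabilities for a subset."""
        return self._evaluate(frozenset(subset))[1]

    def indices(self, metabolite_ids) -> frozenset[int]:
        return frozenset(self.metabolite_ids.index(i) for i in metabolite_ids)


def fitness(m: MetabolomicMatrix, subset, cfg: FitnessConfig | None = None) -> float:
    """Minimum held-out-fold accuracy of the booster on the subset's columns."""
    cfg = cfg or FitnessConfig()
    ev = FitnessEvaluator(m, cfg)
    return ev.fitness(ev.indices(subset))


def evaluate_auc(m: MetabolomicMatrix, subset, cfg: FitnessConfig | None = None) -> float:
    """AUC of pooled out-of-fold case probabilities against the true labels."""
    cfg = cfg or FitnessConfig()
    ev = FitnessEvaluator(m, cfg)
    return float(roc_auc_score(ev.y, ev.oof_scores(ev.indices(subset))))


def _tournament(rng, pop, fits, size):
    picks = rng.integers(0, len(pop), size=size)
    return pop[max(picks, key=lambda i: fits[i])]


def _evolve(ev, k: int, ga: GAConfig, rng, n_feat: int) -> tuple[frozenset[int], float]:
    if k > n_feat:
        raise ValueError(f"subset size {k} exceeds {n_feat} metabolites")
    pop = [frozenset(rng.choice(n_feat, size=k, replace=False)) for _ in range(ga.population_size)]
    fits = [ev.fitness(ind) for ind in pop]
    best_idx = int(np.argmax(fits))
    best, best_fit = pop[best_idx], fits[best_idx]
    stagnant = 0
    for _ in range(ga.generations):
        order = np.argsort(fits)[::-1]
        new_pop = [pop[i] for i in order[: ga.elitism]]
        while len(new_pop) < ga.population_size:
            p1 = _tournament(rng, pop, fits, ga.tournament_size)
            p2 = _tournament(rng, pop, fits, ga.tournament_size)
            if rng.random() < ga.crossover_rate:
                # uniform crossover for set-valued chromosomes: each child gene
                # drawn without replacement from the union of parent genes, so
                # genes the parents carry at different positions can co-occur
                pool = sorted(set(p1) | set(p2))
                child = list(rng.choice(pool, size=k, replace=False))
            else:
                child = list(p1)
            for i in range(k):
                if rng.random() < ga.mutation_rate:
                    g = int(rng.integers(n_feat))
                    while g in child:
                        g = int(rng.integers(n_feat))
                    child[i] = g
            new_pop.append(frozenset(child))
        pop = new_pop
        fits = [ev.fitness(ind) for ind in pop]
        gen_best = int(np.argmax(fits))
        if fits[gen_best] > best_fit:
            best, best_fit = pop[gen_best], fits[gen_best]
            stagnant = 0
        else:
            stagnant += 1
            if ga.stagnation_patience is not None and stagnant >= ga.stagnation_patience:
                break
    return best, best_fit


def ga_search(
    m: MetabolomicMatrix,
    ga: GAConfig | None = None,
    fit: FitnessConfig | None = None,
    evaluator_factory=None,
) -> PrimarySearchResult:
    """Run the multi-start GA and aggregate inclusion frequencies.

    Each of ``ga.n_runs`` runs draws its own fold assignment and GA
    randomness from a seed derived from ``ga.seed``, evolves one population
    per subset size, and retains the best combination of each pass.
    ``evaluator_factory(matrix, fitness_config)`` may swap in a different
    fitness backend; the default is the cross-validated booster.
    """
    ga = ga or GAConfig()
    fit = fit or FitnessConfig()
    if max(ga.subset_sizes) > m.n_metabolites:
        raise ValueError("largest subset size exceeds the number of metabolites")
    if evaluator_factory is None:
        evaluator_factory = FitnessEvaluator
    ids = list(m.metabolite_ids)
    retained: list[MarkerCombination] = []
    children = np.random.SeedSequence(ga.seed).spawn(ga.n_runs)
    for run, ss in enumerate(children):
        fold_seed = int(ss.generate_state(1)[0] % (2**31))
        ev = evaluator_factory(m, replace(fit, seed=fold_seed))
        rng = np.random.default_rng(ss)
        for k in ga.subset_sizes:
            best, best_fit = _evolve(ev, k, ga, rng, m.n_metabolites)
            retained.append(
                MarkerCombination(frozenset(ids[i] for i in best), best_fit)
            )
        logger.debug("run %d: best fitness %s", run, retained[-1].fitness)
    dedup: dict[frozenset[str], float] = {}
    for comb in retained:
        prev = dedup.get(comb.metabolite_ids)
        if prev is None or comb.fitness > prev:
            dedup[comb.metabolite_ids] = comb.fitness
    combinations = sorted(
        (MarkerCombination(k, v) for k, v in dedup.items()),
        key=lambda c: -c.fitness,
    )
    freq = {
        mid: sum(mid in c.metabolite_ids for c in retained) / len(retained)
        for mid in ids
        if any(mid in c.metabolite_ids for c in retained)
    }
    return PrimarySearchResult(
        combinations=combinations, retained=retained, inclusion_frequency=freq
    )
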