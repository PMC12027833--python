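"""Evolutionary optimization of the 11 pipeline hyperparameters.

Three population methods maximize the pipeline's macro F1 over the
11-dimensional box of Gabor and network hyperparameters:

* RCGA — real-coded genetic algorithm with binary tournament selection,
  simulated binary crossover (eta_c = 15), polynomial mutation
  (eta_m = 20, per-gene probability 1/11) and elitism of 1;
* BUMDA — Boltzmann univariate marginal distribution algorithm: truncation
  at the population median, per-variable normal model with
  Boltzmann-weighted mean and variance (weight g_i = f_i - f_worst_sel + 1,
  variance denominator 1 + sum g), elitism of 1;
* UMDA — univariate marginal distribution algorithm: top-50% truncation,
  unweighted per-variable normal fit, elitism of 1.

All three operate internally in coordinates normalized to [0, 1] (the raw
parameter ranges span nine orders of magnitude because of the learning
rates), repair out-of-bounds proposals by clipping, log every generation's
fitness values and elite, and are fully reproducible from one seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cdbn import CDBNConfig, ConfigError, DEFAULT_LAYER_SPECS, extract_features_batch, train_layerwise
from .classify import evaluate, stratified_split, train_classifier
from .gabor import GABOR_BOUNDS, GaborParams, apply_gabor
from .synth import PatchDataset

__all__ = [
    "SearchSpace",
    "Individual",
    "GenerationLog",
    "FitnessBudget",
    "decode",
    "run_rcga",
    "run_bumda",
    "run_umda",
    "umda_moments",
    "bumda_moments",
    "pipeline_fitness",
    "make_pipeline_fitness",
]

PARAM_NAMES: tuple[str, ...] = (
    "sigma", "theta", "lam", "psi", "gamma", "k",
    "p1", "p2", "alpha1", "alpha2", "alpha3",
)

_DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    **GABOR_BOUNDS,
    "p1": (0.0, 1.0),
    "p2": (0.0, 1.0),
    "alpha1": (1e-9, 1e-5),
    "alpha2": (1e-9, 1e-5),
    "alpha3": (1e-9, 1e-5),
}


@dataclass(frozen=True)
class SearchSpace:
    """Ordered, bounded 11-dimensional real search space."""

    names: tuple[str, ...] = PARAM_NAMES
    lower: np.ndarray = field(default_factory=lambda: np.array([_DEFAULT_BOUNDS[n][0] for n in PARAM_NAMES]))
    upper: np.ndarray = field(default_factory=lambda: np.array([_DEFAULT_BOUNDS[n][1] for n in PARAM_NAMES]))

    def __post_init__(self) -> None:
        if len(self.names) != len(self.lower) or len(self.names) != len(self.upper):
            raise ValueError("names and bounds must have the same length")
        if not np.all(self.lower < self.upper):
            raise ValueError("every lower bound must be strictly below its upper bound")

    @property
    def dim(self) -> int:
        return len(self.names)

    def clip(self, vector: np.ndarray) -> tuple[np.ndarray, bool]:
        """Clip into bounds; second value reports whether repair occurred."""
        clipped = np.clip(vector, self.lower, self.upper)
        return clipped, bool(np.any(clipped != vector))

    def normalize(self, vector: np.ndarray) -> np.ndarray:
        return (vector - self.lower) / (self.upper - self.lower)

    def denormalize(self, z: np.ndarray) -> np.ndarray:
        return self.lower + z * (self.upper - self.lower)


@dataclass
class Individual:
    """A candidate hyperparameter vector with its evaluated fitness."""

    vector: np.ndarray
    fitness: float | None = None
    generation: int = 0

    def __post_init__(self) -> None:
        self.vector = np.asarray(self.vector, dtype=np.float64)


@dataclass
class GenerationLog:
    """Per-generation record shared by all three algorithms."""

    algorithm: str
    records: list[dict] = field(default_factory=list)
    repair_events: int = 0
    failed_evaluations: int = 0

    def append(self, generation: int, population: list[Individual], elite: Individual) -> None:
        self.records.append(
            {
                "generation": generation,
                "fitness_values": [float(ind.fitness) for ind in population],
                "vectors": [ind.vector.copy() for ind in population],
                "elite_vector": elite.vector.copy(),
                "elite_fitness": float(elite.fitness),
            }
        )

    @property
    def elite_trace(self) -> list[float]:
        return [rec["elite_fitness"] for rec in self.records]

    @property
    def best(self) -> tuple[np.ndarray, float]:
        final = self.records[-1]
        return final["elite_vector"], final["elite_fitness"]

    def to_dataframe(self, names: tuple[str, ...] = PARAM_NAMES) -> pd.DataFrame:
        """Long-format log: one row per individual per generation."""
        rows = []
        for rec in self.records:
            elite = rec["elite_vector"]
            for i, (vec, fit) in enumerate(zip(rec["vectors"], rec["fitness_values"])):
                row = {"generation": rec["generation"], "individual_id": i}
                row.update({n: v for n, v in zip(names, vec)})
                row["fitness"] = fit
                row["elite_flag"] = bool(np.array_equal(vec, elite) and fit == rec["elite_fitness"])
                rows.append(row)
        return pd.DataFrame(rows)


def decode(ind: Individual | np.ndarray, space: SearchSpace | None = None) -> dict:
    """Map a repaired 11-vector onto the named pipeline hyperparameters.

    Returns a dict with a :class:`GaborParams` under ``"gabor"`` plus the
    network fragments ``p1``, ``p2`` and ``alphas``. Out-of-bounds vectors
    are repaired by clipping and the repair is reported under
    ``"repaired"``.
    """
    space = space or SearchSpace()
    vector = np.asarray(ind.vector if isinstance(ind, Individual) else ind, dtype=np.float64)
    if vector.shape != (space.dim,):
        raise ValueError(f"expected vector of length {space.dim}, got shape {vector.shape}")
    vector, repaired = space.clip(vector)
    named = dict(zip(space.names, vector))
    return {
        "gabor": GaborParams(
            sigma=named["sigma"], theta=named["theta"], lam=named["lam"],
            psi=named["psi"], gamma=named["gamma"], k=named["k"],
        ),
        "p1": float(named["p1"]),
        "p2": float(named["p2"]),
        "alphas": (float(named["alpha1"]), float(named["alpha2"]), float(named["alpha3"])),
        "repaired": repaired,
    }


# ---------------------------------------------------------------------------
# shared machinery
# ---------------------------------------------------------------------------


def _evaluate(pop_z: np.ndarray, fitness_fn, space: SearchSpace, generation: int, log: GenerationLog) -> list[Individual]:
    out = []
    for z in pop_z:
        vec = space.denormalize(z)
        try:
            fit = float(fitness_fn(vec))
        except Exception:
            fit = 0.0
            log.failed_evaluations += 1
        out.append(Individual(vector=vec, fitness=fit, generation=generation))
    return out


def _clip01(z: np.ndarray, log: GenerationLog) -> np.ndarray:
    clipped = np.clip(z, 0.0, 1.0)
    log.repair_events += int(np.any(clipped != z))
    return clipped


def _check_args(pop_size: int, generations: int) -> None:
    if pop_size < 2:
        raise ValueError("pop_size must be >= 2")
    if generations < 1:
        raise ValueError("generations must be >= 1")


# ---------------------------------------------------------------------------
# RCGA
# ---------------------------------------------------------------------------


def _sbx(p1: np.ndarray, p2: np.ndarray, rng: np.random.Generator, eta: float = 15.0) -> tuple[np.ndarray, np.ndarray]:
    """Simulated binary crossover on normalized genes.

    Genes whose parents (nearly) coincide are copied through unchanged, the
    canonical guard that keeps identical parents exactly invariant.
    """
    u = rng.random(p1.shape)
    beta = np.where(u <= 0.5, (2.0 * u) ** (1.0 / (eta + 1.0)), (0.5 / (1.0 - u)) ** (1.0 / (eta + 1.0)))
    c1 = 0.5 * ((1.0 + beta) * p1 + (1.0 - beta) * p2)
    c2 = 0.5 * ((1.0 - beta) * p1 + (1.0 + beta) * p2)
    same = np.abs(p1 - p2) < 1e-14
    c1 = np.where(same, p1, c1)
    c2 = np.where(same, p2, c2)
    swap = rng.random(p1.shape) < 0.5
    return np.where(swap, c2, c1), np.where(swap, c1, c2)


def _poly_mutate(z: np.ndarray, rng: np.random.Generator, eta: float = 20.0, p_gene: float | None = None) -> np.ndarray:
    """Polynomial mutation on normalized genes (range 1)."""
    if p_gene is None:
        p_gene = 1.0 / z.shape[0]
    u = rng.random(z.shape)
    delta = np.where(u < 0.5, (2.0 * u) ** (1.0 / (eta + 1.0)) - 1.0, 1.0 - (2.0 * (1.0 - u)) ** (1.0 / (eta + 1.0)))
    mask = rng.random(z.shape) < p_gene
    return z + np.where(mask, delta, 0.0)


def _tournament(pop: list[Individual], rng: np.random.Generator) -> Individual:
    a, b = rng.integers(0, len(pop), size=2)
    return pop[a] if pop[a].fitness >= pop[b].fitness else pop[b]


def run_rcga(
    space: SearchSpace,
    fitness_fn,
    pop_size: int = 10,
    generations: int = 20,
    seed: int = 0,
    *,
    mutation_prob: float | None = None,
    eta_c: float = 15.0,
    eta_m: float = 20.0,
    initial_population: np.ndarray | None = None,
) -> GenerationLog:
    """Real-coded GA: tournament + SBX + polynomial mutation + elitism of 1.

    ``initial_population`` (raw-unit vectors, shape (pop_size, dim))
    replaces the uniform random initialization when given.
    """
    _check_args(pop_size, generations)
    rng = np.random.default_rng(seed)
    log = GenerationLog(algorithm="rcga")
    if initial_population is not None:
        init = np.asarray(initial_population, dtype=np.float64)
        if init.shape != (pop_size, space.dim):
            raise ValueError(f"initial population must be ({pop_size}, {space.dim})")
        pop_z = np.stack([space.normalize(v) for v in init])
    else:
        pop_z = rng.random((pop_size, space.dim))
    pop = _evaluate(pop_z, fitness_fn, space, 0, log)
    elite = max(pop, key=lambda ind: ind.fitness)
    log.append(0, pop, elite)
    for gen in range(1, generations):
        offspring_z = []
        while len(offspring_z) < pop_size - 1:
            pa = space.normalize(_tournament(pop, rng).vector)
            pb = space.normalize(_tournament(pop, rng).vector)
            c1, c2 = _sbx(pa, pb, rng, eta=eta_c)
            for c in (c1, c2):
                c = _poly_mutate(c, rng, eta=eta_m, p_gene=mutation_prob)
                offspring_z.append(_clip01(c, log))
        offspring = _evaluate(np.asarray(offspring_z[: pop_size - 1]), fitness_fn, space, gen, log)
        pop = [elite] + offspring
        elite = max(pop, key=lambda ind: ind.fitness)
        log.append(gen, pop, elite)
    return log


# ---------------------------------------------------------------------------
# Estimation-of-distribution algorithms
# ---------------------------------------------------------------------------


def umda_moments(selected: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-variable mean and variance of the selected individuals."""
    selected = np.asarray(selected, dtype=np.float64)
    return selected.mean(axis=0), selected.var(axis=0)


def bumda_moments(selected: np.ndarray, fitnesses: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Boltzmann-weighted mean and variance of the selected individuals.

    Weights are g_i = f_i - min(f_selected) + 1, so on a constant fitness
    landscape every weight is 1 and the mean reduces to the arithmetic
    mean. The variance denominator is 1 + sum(g), which shrinks the model
    as selection pressure grows.
    """
    selected = np.asarray(selected, dtype=np.float64)
    fitnesses = np.asarray(fitnesses, dtype=np.float64)
    g = fitnesses - fitnesses.min() + 1.0
    gsum = g.sum()
    mean = (g[:, None] * selected).sum(axis=0) / gsum
    var = (g[:, None] * (selected - mean) ** 2).sum(axis=0) / (1.0 + gsum)
    return mean, var


def _edagen(
    algorithm: str,
    space: SearchSpace,
    fitness_fn,
    pop_size: int,
    generations: int,
    seed: int,
    var_floor: float = 1e-12,
) -> GenerationLog:
    _check_args(pop_size, generations)
    rng = np.random.default_rng(seed)
    log = GenerationLog(algorithm=algorithm)
    pop_z = rng.random((pop_size, space.dim))
    pop = _evaluate(pop_z, fitness_fn, space, 0, log)
    elite = max(pop, key=lambda ind: ind.fitness)
    log.append(0, pop, elite)
    for gen in range(1, generations):
        fits = np.array([ind.fitness for ind in pop])
        zs = np.stack([space.normalize(ind.vector) for ind in pop])
        if algorithm == "umda":
            order = np.argsort(-fits, kind="stable")
            mean, var = umda_moments(zs[order[: max(pop_size // 2, 2)]])
        else:  # bumda: truncation at the population median
            mask = fits >= np.median(fits)
            mean, var = bumda_moments(zs[mask], fits[mask])
        var = np.maximum(var, var_floor)
        samples = rng.normal(mean, np.sqrt(var), size=(pop_size - 1, space.dim))
        samples = _clip01(samples, log)
        offspring = _evaluate(samples, fitness_fn, space, gen, log)
        pop = [elite] + offspring
        elite = max(pop, key=lambda ind: ind.fitness)
        log.append(gen, pop, elite)
    return log


def run_bumda(space: SearchSpace, fitness_fn, pop_size: int = 10, generations: int = 20, seed: int = 0) -> GenerationLog:
    """Boltzmann UMDA: median truncation, fitness-weighted normal model."""
    return _edagen("bumda", space, fitness_fn, pop_size, generations, seed)


def run_umda(space: SearchSpace, fitness_fn, pop_size: int = 10, generations: int = 20, seed: int = 0) -> GenerationLog:
    """UMDA: top-50% truncation, unweighted per-variable normal fit."""
    return _edagen("umda", space, fitness_fn, pop_size, generations, seed)


# ---------------------------------------------------------------------------
# Pipeline fitness
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FitnessBudget:
    """Reduced training budget for one fitness evaluation.

    Full-budget search (hundreds of complete CDBN trainings) is available
    by raising these numbers; the defaults keep one evaluation tractable on
    a single CPU.
    """

    epochs: int = 5
    max_patches: int = 600
    batch_size: int = 32
    cd_steps: int = 1
    n_trees: int = 100
    test_fraction: float = 0.2
    seed: int = 0


def pipeline_fitness(
    ind: Individual | np.ndarray,
    dataset: PatchDataset,
    budget: FitnessBudget = FitnessBudget(),
    space: SearchSpace | None = None,
) -> float:
    """Macro F1 of the full pipeline under a decoded hyperparameter vector.

    Decode -> Gabor filtering -> layer-wise CDBN training at the budget ->
    256-d features -> boosted trees on a stratified train split -> macro F1
    on the held-out split. Deterministic given (vector, dataset, budget).
    An infeasible decoded architecture scores 0.
    """
    counts = dataset.class_counts()
    if any(v == 0 for v in counts.values()):
        raise ValueError(f"dataset must contain all classes, got counts {counts}")
    params = decode(ind, space)
    ds = dataset.subsample(budget.max_patches, seed=budget.seed)

    filtered = np.stack(
        [apply_gabor(p, params["gabor"], source_id=str(i)).data for i, p in enumerate(ds.patches)]
    )
    try:
        config = CDBNConfig(
            layers=DEFAULT_LAYER_SPECS,
            learning_rates=params["alphas"],
            pool_thresholds=(params["p1"], params["p2"]),
            epochs=budget.epochs,
            batch_size=budget.batch_size,
            cd_steps=budget.cd_steps,
            seed=budget.seed,
        )
        model = train_layerwise(filtered, config)
    except ConfigError:
        return 0.0
    features = extract_features_batch(model, filtered)
    train, test = stratified_split(features, ds.labels, budget.test_fraction, seed=budget.seed)
    clf = train_classifier(train, n_trees=budget.n_trees, seed=budget.seed)
    return evaluate(clf, test).macro_f1


def make_pipeline_fitness(dataset: PatchDataset, budget: FitnessBudget = FitnessBudget(), space: SearchSpace | None = None):
    """Bind dataset and budget into a ``fitness_fn(vector) -> float``."""

    def fitness_fn(vector: np.ndarray) -> float:
        return pipeline_fitness(vector, dataset, budget, space)

    return fitness_fn
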