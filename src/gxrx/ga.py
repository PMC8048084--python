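"""Genetic-algorithm search for fixed-size predictive gene sets.

A candidate solution ("chromosome") is a set of exactly d distinct gene
indices.  Fitness is the leave-one-out kNN squared-error loss on the
training samples, minimized by a single-population generational GA with
tournament selection, uniform set-exchange crossover (repaired to keep
|genes| = d), per-gene replacement mutation, and elitism.  The search
stops at ``max_generations`` or after ``stall_generations`` without
improvement of the best loss.

Default k = 3 neighbors and d = 30 genes; both were near-optimal on a
(k, d) grid of k in {1,3,5,7} x d in {10,20,30,40} for this class of
problem and remain configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .knn import loo_predictions, squared_error_loss

__all__ = ["Chromosome", "GAConfig", "GARunResult", "init_population", "evaluate", "evolve"]


@dataclass(frozen=True)
class Chromosome:
    """An unordered set of exactly d distinct gene indices (stored sorted)."""

    genes: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", tuple(sorted(int(g) for g in self.genes)))
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("chromosome contains repeated gene indices")
        if len(self.genes) == 0:
            raise ValueError("chromosome must contain at least one gene")
        if min(self.genes) < 0:
            raise ValueError("negative gene index")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class GAConfig:
    """GA hyperparameters.  All configurable; defaults keep many Monte-Carlo
    repeats desk-feasible while preserving the algorithm's structure."""

    d: int = 30
    k: int = 3
    population_size: int = 300
    max_generations: int = 200
    mutation_rate: float | None = None  # default 1/d, set in __post_init__
    tournament_size: int = 3
    elite_count: int = 1
    stall_generations: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mutation_rate is None:
            self.mutation_rate = 1.0 / self.d
        if not (0 < self.elite_count < self.population_size):
            raise ValueError("require 0 < elite_count < population_size")
        if not (0 < self.mutation_rate < 1):
            raise ValueError("require 0 < mutation_rate < 1")
        if self.d < 1:
            raise ValueError("require d >= 1")


@dataclass
class GARunResult:
    """Outcome of one GA run: best gene set, its loss, and the loss trace."""

    best_chromosome: Chromosome
    best_loss: float
    loss_trace: list[float] = field(default_factory=list)
    generations_run: int = 0
    seed: int = 0


def init_population(cfg: GAConfig, G: int, rng: np.random.Generator) -> list[Chromosome]:
    """population_size uniform random d-subsets of [0, G) without replacement."""
    if G < cfg.d:
        raise ValueError(f"gene universe G={G} smaller than chromosome size d={cfg.d}")
    return [Chromosome(tuple(rng.choice(G, size=cfg.d, replace=False))) for _ in range(cfg.population_size)]


def evaluate(c: Chromosome, X_train: np.ndarray, y_train: np.ndarray, k: int) -> float:
    """Leave-one-out kNN squared-error loss of a gene set on the training data."""
    if max(c.genes) >= X_train.shape[0]:
        raise IndexError("chromosome gene index out of range for training matrix")
    sub = X_train[list(c.genes), :]
    return squared_error_loss(y_train, loo_predictions(sub, y_train, k))


def _crossover(a: Chromosome, b: Chromosome, d: int, rng: np.random.Generator) -> tuple[int, ...]:
    """Uniform set exchange: shared genes kept, the rest drawn from either parent,
    repaired to size d from the parents' unused gene pool."""
    sa, sb = set(a.genes), set(b.genes)
    shared = sorted(sa & sb)
    sym = sorted(sa ^ sb)
    take = [g for g in sym if rng.random() < 0.5]
    child = shared + take
    if len(child) > d:
        drop = rng.choice(len(take), size=len(child) - d, replace=False)
        kept = [g for i, g in enumerate(take) if i not in set(drop.tolist())]
        child = shared + kept
    elif len(child) < d:
        unused = [g for g in sym if g not in set(take)]
        add = rng.choice(len(unused), size=d - len(child), replace=False)
        child = child + [unused[i] for i in add]
    return tuple(child)


def _mutate(genes: tuple[int, ...], G: int, rate: float, rng: np.random.Generator) -> Chromosome:
    """Per-gene replacement with a uniformly chosen gene not already in the set."""
    current = set(genes)
    out = list(genes)
    for i in range(len(out)):
        if rng.random() < rate:
            g = int(rng.integers(G))
            while g in current:
                g = int(rng.integers(G))
            current.discard(out[i])
            current.add(g)
            out[i] = g
    return Chromosome(tuple(out))


def evolve(cfg: GAConfig, X_train: np.ndarray, y_train: np.ndarray,
           rng: np.random.Generator | None = None) -> GARunResult:
    """Run the GA and return the best gene set found.

    The loss trace is non-increasing because the elite survive unchanged.
    Identical (config, data, seed) always yields an identical result.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    G, n = X_train.shape
    if n < cfg.k + 1:
        raise ValueError(f"need at least k+1={cfg.k + 1} training samples, got {n}")
    X_train = np.ascontiguousarray(X_train, dtype=float)
    y_train = np.asarray(y_train, dtype=float)

    cache: dict[tuple[int, ...], float] = {}

    def cached_eval(c: Chromosome) -> float:
        loss = cache.get(c.genes)
        if loss is None:
            loss = evaluate(c, X_train, y_train, cfg.k)
            cache[c.genes] = loss
        return loss

    population = init_population(cfg, G, rng)
    losses = np.array([cached_eval(c) for c in population])

    trace: list[float] = []
    best_loss = np.inf
    best_chrom = population[int(np.argmin(losses))]
    stall = 0
    gen = 0
    for gen in range(1, cfg.max_generations + 1):
        order = np.argsort(losses, kind="stable")
        gen_best = float(losses[order[0]])
        if gen_best < best_loss:
            best_loss = gen_best
            best_chrom = population[int(order[0])]
            stall = 0
        else:
            stall += 1
        trace.append(best_loss)
        if stall >= cfg.stall_generations:
            break

        elites = [population[int(i)] for i in order[: cfg.elite_count]]
        elite_losses = losses[order[: cfg.elite_count]]
        children: list[Chromosome] = []
        while len(children) < cfg.population_size - cfg.elite_count:
            pa = _tournament(population, losses, cfg.tournament_size, rng)
            pb = _tournament(population, losses, cfg.tournament_size, rng)
            child = _crossover(pa, pb, cfg.d, rng)
            children.append(_mutate(child, G, cfg.mutation_rate, rng))
        child_losses = np.array([cached_eval(c) for c in children])
        population = elites + children
        losses = np.concatenate([elite_losses, child_losses])

    return GARunResult(
        best_chromosome=best_chrom,
        best_loss=float(best_loss),
        loss_trace=trace,
        generations_run=gen,
        seed=cfg.seed,
    )


def _tournament(population: list[Chromosome], losses: np.ndarray, size: int,
                rng: np.random.Generator) -> Chromosome:
    idx = rng.integers(len(population), size=size)
    return population[int(idx[np.argmin(losses[idx])])]
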