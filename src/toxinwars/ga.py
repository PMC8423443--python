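"""Genetic algorithm for coevolving sensing strategies.

A constant-size population of sensing strategies competes in round-robin
tournaments: every strategy meets every strategy (including a clone of
itself), and its fitness is its summed final biomass across those
competitions. Each generation keeps the four fittest strategies unchanged
(elitism), draws 36 parents with probability proportional to fitness and
perturbs exactly one of their parameters with small Gaussian noise, and
adds 10 fresh random immigrants. Run either within a single regulation
mode or with all three modes competing ("mixed" tournaments); mixed runs
start with a burn-in phase in which the whole population is replaced by
immigrants each generation, so that type frequencies begin neutral.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .dynamics import simulate_batch
from .params import EcologicalParams
from .strategies import (SENSING_MODES, THRESHOLD_RANGES_GA, Strategy, pack)

logger = logging.getLogger(__name__)

_PARAM_NAMES = ("f_initial", "f_induced", "threshold")


@dataclass(frozen=True)
class GAConfig:
    """Hyperparameters of the strategy-evolution tournament."""

    modes: tuple = ("toxin_sensing",)
    population_size: int = 60
    elite_count: int = 4
    mutant_count: int = 36
    immigrant_count: int = 10
    mutation_sd: float = 0.001
    generations: int = 100
    burn_in_generations: int = 0
    constraints: dict = field(default_factory=lambda: dict(THRESHOLD_RANGES_GA))
    f_range: tuple = (0.0, 1.0)
    seed: int = 0
    top_k: int = 4          # strategies averaged for the reported optimum
    initial_population: Optional[tuple] = None

    def __post_init__(self) -> None:
        if isinstance(self.modes, str):
            object.__setattr__(self, "modes", (self.modes,))
        for m in self.modes:
            if m not in SENSING_MODES:
                raise ValueError(f"unknown sensing mode {m!r}")
        counts = (self.elite_count, self.mutant_count, self.immigrant_count)
        if any(c < 0 for c in counts):
            raise ValueError("all counts must be >= 0")
        if sum(counts) != self.population_size:
            raise ValueError(
                "elite_count + mutant_count + immigrant_count must equal "
                f"population_size ({sum(counts)} != {self.population_size})")
        if self.mutation_sd <= 0:
            raise ValueError("mutation_sd must be > 0")
        if self.generations <= 0 or self.burn_in_generations < 0:
            raise ValueError("invalid generation counts")

    @property
    def mixed(self) -> bool:
        return len(self.modes) > 1


def _param_bounds(config: GAConfig, mode: str, name: str) -> tuple:
    if name == "threshold":
        return config.constraints[mode]
    return config.f_range


def random_strategy(mode_or_modes, constraints: dict,
                    rng: np.random.Generator,
                    f_range: tuple = (0.0, 1.0)) -> Strategy:
    """Draw a uniform random sensing strategy within the constraint box.

    When several modes are given, the sensing type is drawn uniformly
    first.
    """
    if isinstance(mode_or_modes, str):
        mode = mode_or_modes
    else:
        mode = mode_or_modes[rng.integers(len(mode_or_modes))]
    lo, hi = constraints[mode]
    return Strategy(mode=mode,
                    f_initial=float(rng.uniform(*f_range)),
                    f_induced=float(rng.uniform(*f_range)),
                    threshold=float(rng.uniform(lo, hi)))


def _immigrants(n: int, config: GAConfig,
                rng: np.random.Generator) -> list:
    return [random_strategy(config.modes, config.constraints, rng,
                            config.f_range) for _ in range(n)]


def evaluate_population(population: Sequence[Strategy],
                        params: EcologicalParams) -> np.ndarray:
    """Round-robin fitness: summed final biomass across all n encounters.

    Every unordered pair (including self-pairings) is simulated once; in
    the i-vs-j competition strain i contributes its own final biomass to
    fitness_i and strain j to fitness_j. The self-pairing i-vs-i is a
    competition between two strains with identical strategies and
    contributes i's final biomass once.
    """
    n = len(population)
    ii, jj = np.triu_indices(n)
    res = simulate_batch(pack([population[i] for i in ii]),
                         pack([population[j] for j in jj]), params)
    fitness = np.zeros(n)
    np.add.at(fitness, ii, res.biomass_A)
    off = ii != jj
    np.add.at(fitness, jj[off], res.biomass_B[off])
    return fitness


def _mutate(parent: Strategy, config: GAConfig, rng: np.random.Generator,
            max_attempts: int = 1000) -> Strategy:
    name = _PARAM_NAMES[rng.integers(3)]
    lo, hi = _param_bounds(config, parent.mode, name)
    value = getattr(parent, name)
    for _ in range(max_attempts):
        candidate = value + rng.normal(0.0, config.mutation_sd)
        if lo <= candidate <= hi:
            break
    else:
        logger.warning("mutation redraw limit reached; clipping %s", name)
        candidate = float(np.clip(value + rng.normal(0.0, config.mutation_sd),
                                  lo, hi))
    fields = parent.to_dict()
    fields[name] = float(candidate)
    return Strategy.from_dict(fields)


def next_generation(population: Sequence[Strategy], fitness: np.ndarray,
                    config: GAConfig, rng_selection: np.random.Generator,
                    rng_mutation: np.random.Generator,
                    rng_immigration: np.random.Generator) -> list:
    """One generation update: elitism + proportional selection + immigrants.

    The elite are byte-identical copies of the top strategies (ties broken
    by population index); selected parents have exactly one uniformly
    chosen parameter perturbed by N(0, mutation_sd), redrawing the
    perturbation until it satisfies the constraints.
    """
    fitness = np.asarray(fitness, dtype=float)
    if len(fitness) != len(population):
        raise ValueError("fitness vector length must match population")
    if np.any(fitness < 0):
        raise ValueError("fitness must be non-negative")
    elite_idx = np.argsort(-fitness, kind="stable")[:config.elite_count]
    elite = [population[i] for i in elite_idx]

    total = fitness.sum()
    if total > 0:
        probs = fitness / total
    else:
        logger.warning("all-zero fitness: falling back to uniform selection")
        probs = np.full(len(population), 1.0 / len(population))
    parents = rng_selection.choice(len(population), size=config.mutant_count,
                                   replace=True, p=probs)
    mutants = [_mutate(population[i], config, rng_mutation) for i in parents]
    immigrants = _immigrants(config.immigrant_count, config, rng_immigration)
    return elite + mutants + immigrants


@dataclass
class GAHistory:
    """Per-generation records of one tournament run."""

    config: GAConfig
    populations: list = field(default_factory=list)      # list[list[Strategy]]
    fitness: list = field(default_factory=list)          # list[np.ndarray]
    top_means: list = field(default_factory=list)        # list[dict]
    type_fractions: list = field(default_factory=list)   # list[dict]
    type_mean_fitness: list = field(default_factory=list)

    @property
    def n_generations(self) -> int:
        return len(self.populations)

    def final_top_mean(self) -> dict:
        """Mean parameters of the fittest strategies at the last generation."""
        return self.top_means[-1]

    def top_mean_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.top_means)

    def type_fraction_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.type_fractions)

    def to_frame(self) -> pd.DataFrame:
        """Long-format per-generation population table."""
        rows = []
        for g, (pop, fit) in enumerate(zip(self.populations, self.fitness)):
            for sid, (s, w) in enumerate(zip(pop, fit)):
                rows.append({"generation": g, "strategy_id": sid,
                             "mode": s.mode, "f_initial": s.f_initial,
                             "f_induced": s.f_induced,
                             "threshold": s.threshold, "fitness": w})
        return pd.DataFrame(rows)


def _top_mean(population, fitness, k) -> dict:
    idx = np.argsort(-np.asarray(fitness), kind="stable")[:k]
    out = {"f_initial": float(np.mean([population[i].f_initial for i in idx])),
           "f_induced": float(np.mean([population[i].f_induced for i in idx])),
           "threshold": float(np.mean([population[i].threshold for i in idx])),
           "fitness": float(np.mean([fitness[i] for i in idx]))}
    modes = [population[i].mode for i in idx]
    out["top_mode"] = max(set(modes), key=modes.count)
    return out


def run_ga(config: GAConfig,
           params: EcologicalParams = EcologicalParams()) -> GAHistory:
    """Run the full tournament and record every generation.

    Randomness is split into independent sub-streams (initialisation,
    selection, mutation, immigration) derived from ``config.seed``, so a
    change in one stage's draw count does not perturb the others.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_init, rng_sel, rng_mut, rng_imm = [
        np.random.default_rng(s) for s in ss.spawn(4)]

    if config.initial_population is not None:
        population = list(config.initial_population)
        if len(population) != config.population_size:
            raise ValueError("initial population size mismatch")
    else:
        population = _immigrants(config.population_size, config, rng_init)

    history = GAHistory(config=config)
    for gen in range(config.generations):
        fitness = evaluate_population(population, params)
        history.populations.append(list(population))
        history.fitness.append(fitness)
        history.top_means.append(_top_mean(population, fitness, config.top_k))
        fracs, mean_fit = {}, {}
        for mode in config.modes:
            sel = [i for i, s in enumerate(population) if s.mode == mode]
            fracs[mode] = len(sel) / len(population)
            mean_fit[mode] = float(fitness[sel].mean()) if sel else float("nan")
        history.type_fractions.append(fracs)
        history.type_mean_fitness.append(mean_fit)

        if gen + 1 < config.generations:
            if gen + 1 <= config.burn_in_generations:
                # burn-in: no selection, whole population replaced by migrants
                population = _immigrants(config.population_size, config,
                                         rng_imm)
            else:
                population = next_generation(population, fitness, config,
                                             rng_sel, rng_mut, rng_imm)
    return history
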