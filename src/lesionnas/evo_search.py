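"""Evolutionary subnet search over the one-shot supernet.

After supernet training, subnets are ranked by inference with the shared
weights rather than retrained.  The search keeps a population of S subnet
codes: generation 0 is sampled uniformly (valid codes only), each round
evaluates the population on validation data (AP50 as fitness), keeps the
k fittest as an unmodified elite, and refills the population with
children produced by uniform crossover of two random elites followed by
per-edge mutation with probability p.  Defaults follow the study
configuration S=50, k=10, p=0.1; the number of rounds n is a free knob
(default 20).  Elitism makes the best-so-far fitness non-decreasing, and
every draw flows from one seeded generator so runs are reproducible.

Mutation resamples each edge independently with probability p over all
six kinds (the resample may repeat the old kind); the alternative reading
— exactly one random edge flipped per child — is available via
``single_edge=True``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .fpn_paths import PathKind
from .supernet import SubnetCode, SupernetDAG, sample_subnet

__all__ = [
    "Candidate",
    "SearchConfig",
    "evaluate_candidate",
    "crossover",
    "mutate",
    "evolve",
]


@dataclass
class Candidate:
    code: SubnetCode
    fitness: float

    def __post_init__(self):
        if not np.isnan(self.fitness) and not 0.0 <= self.fitness <= 1.0:
            raise ValueError(f"fitness out of [0, 1]: {self.fitness}")


@dataclass(frozen=True)
class SearchConfig:
    population: int = 50  # S
    elite: int = 10  # k
    mutation_p: float = 0.1  # p
    rounds: int = 20  # n
    seed: int = 0
    single_edge_mutation: bool = False

    def __post_init__(self):
        if not 1 <= self.elite <= self.population:
            raise ValueError("need 1 <= elite <= population")
        if not 0.0 <= self.mutation_p <= 1.0:
            raise ValueError("mutation probability outside [0, 1]")
        if self.rounds < 0:
            raise ValueError("rounds must be >= 0")


def evaluate_candidate(dag: SupernetDAG, detector, code: SubnetCode, val_set) -> float:
    """Fitness of one subnet: AP50 of the detector on the validation set.

    Deterministic given the shared weights and the data.  An undefined AP
    (no ground truths) is an error: the validation set must contain
    lesions.
    """
    if not val_set:
        raise ValueError("empty validation set")
    ap = detector.evaluate(val_set, code=code)
    if np.isnan(ap):
        raise ValueError("validation set has no ground-truth boxes")
    return float(ap)


def _redraw_valid(make, fallback: SubnetCode, retries: int = 25) -> SubnetCode:
    for _ in range(retries):
        code = make()
        if code.is_valid():
            return code
    return fallback


def crossover(a: SubnetCode, b: SubnetCode, rng: np.random.Generator) -> SubnetCode:
    """Uniform crossover: each edge's kind from either parent with prob 1/2."""
    if a.edges != b.edges:
        raise ValueError("parents are defined on different edge sets")
    ka, kb = a.kinds(), b.kinds()

    def make():
        picks = rng.random(len(a.edges)) < 0.5
        return SubnetCode.from_dict(
            a.edges,
            {e: (ka[e] if take_a else kb[e]) for e, take_a in zip(a.edges, picks)},
        )

    return _redraw_valid(make, fallback=a)


def mutate(
    code: SubnetCode,
    p: float,
    rng: np.random.Generator,
    single_edge: bool = False,
) -> SubnetCode:
    """Resample each edge uniformly over all six kinds with probability p.

    With ``single_edge=True`` exactly one uniformly chosen edge is
    resampled instead (and p is ignored).  Children that lose every
    non-null route from input to output are re-drawn.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"mutation probability outside [0, 1]: {p}")
    kinds = list(PathKind)
    edges = code.edges
    current = code.kinds()

    def make():
        if single_edge:
            edge = edges[rng.integers(len(edges))]
            out = dict(current)
            out[edge] = kinds[rng.integers(len(kinds))]
            return SubnetCode.from_dict(edges, out)
        flips = rng.random(len(edges)) < p
        out = {
            e: (kinds[rng.integers(len(kinds))] if flip else current[e])
            for e, flip in zip(edges, flips)
        }
        return SubnetCode.from_dict(edges, out)

    return _redraw_valid(make, fallback=code)


def evolve(
    dag: SupernetDAG,
    cfg: SearchConfig,
    fitness=None,
    detector=None,
    val_set=None,
    log_path=None,
):
    """Run the search; returns (best Candidate, per-generation history).

    ``fitness`` is a callable code -> [0, 1]; when omitted it is AP50 of
    ``detector`` with that code on ``val_set``.  Fitness values are cached
    per code (the evaluation is deterministic), so the best candidate ever
    seen is never lost.  ``history`` has rounds+1 entries, one per
    generation, each recording the generation's best and the running best.
    """
    if fitness is None:
        if detector is None or val_set is None:
            raise ValueError("need either a fitness callable or detector+val_set")

        def fitness(code):
            return evaluate_candidate(dag, detector, code, val_set)

    rng = np.random.default_rng(cfg.seed)
    cache: dict = {}

    def evaluated(code: SubnetCode) -> Candidate:
        key = code.assignment
        if key not in cache:
            cache[key] = float(fitness(code))
        return Candidate(code=code, fitness=cache[key])

    population = [
        evaluated(sample_subnet(dag, rng)) for _ in range(cfg.population)
    ]
    best = max(population, key=lambda c: c.fitness)
    history = []
    log_lines = []

    def record(generation: int):
        nonlocal best
        gen_best = max(population, key=lambda c: c.fitness)
        if gen_best.fitness > best.fitness:
            best = gen_best
        history.append(
            {
                "generation": generation,
                "generation_best": gen_best.fitness,
                "best_so_far": best.fitness,
                "best_code": best.code.to_json(),
            }
        )
        for cand in population:
            log_lines.append(
                json.dumps(
                    {
                        "generation": generation,
                        "code": json.loads(cand.code.to_json()),
                        "fitness": cand.fitness,
                    }
                )
            )

    record(0)
    for generation in range(1, cfg.rounds + 1):
        population.sort(key=lambda c: c.fitness, reverse=True)
        elite = population[: cfg.elite]
        children = []
        while len(children) < cfg.population - cfg.elite:
            pa = elite[rng.integers(len(elite))].code
            pb = elite[rng.integers(len(elite))].code
            child = mutate(
                crossover(pa, pb, rng),
                cfg.mutation_p,
                rng,
                single_edge=cfg.single_edge_mutation,
            )
            children.append(evaluated(child))
        population = list(elite) + children
        record(generation)
    if log_path is not None:
        with open(log_path, "w") as fh:
            fh.write("\n".join(log_lines) + "\n")
    return best, history
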