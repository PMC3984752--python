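"""Genetic-algorithm mining of fuzzy association rules.

One chromosome encodes one rule antecedent (Michigan-style); the consequent
class is fixed per run and not evolved.  The GA maximises the composite
fitness (Support + Confidence) / 2 with binary-tournament selection,
one-point crossover, independent bit-flip mutation, elitism, and generational
replacement, stopping after a fixed number of generations.  Mining runs once
per risk class; the distinct valid rules of the final population are
de-duplicated, pruned of redundant (more-specific, equal-support) variants,
ranked, and the best few returned per class.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass

import numpy as np

from .data import Dataset, RiskLabel, RISK_LEVELS, class_counts
from .partition import FuzzyPartition
from .rules import (
    REDUNDANCY_TOL,
    Chromosome,
    FeatureMatrices,
    FuzzyRule,
    InvalidRuleError,
    RuleSpace,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GAConfig:
    """Genetic-algorithm settings.

    Defaults follow the reference configuration for cohort-scale mining:
    population 100, 1000 generations, crossover rate 1.0, mutation rate 0.2.
    ``mutation_rate`` is the per-offspring probability of a mutation event
    (one uniformly selected bit inverted);
    ``elite_count`` individuals are copied unchanged each generation, which
    makes the best fitness non-decreasing; ``rules_per_class`` caps the rule
    base section returned per risk class.  ``min_support`` is the usual
    association-rule floor: candidates covering less than that fraction of
    the cohort are never admitted to the rule base, which keeps out
    overfitted rules that cover one or two (often noise-labelled) cases yet
    score perfect confidence.
    """

    population_size: int = 100
    generations: int = 1000
    crossover_rate: float = 1.0
    mutation_rate: float = 0.2
    elite_count: int = 2
    seed: int = 0
    rules_per_class: int = 2
    min_support: float = 0.02
    apc_denominator: str = "antecedent"

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if not 0 <= self.elite_count < self.population_size:
            raise ValueError("elite_count must be in [0, population_size)")
        for name in ("crossover_rate", "mutation_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.generations < 1 or self.rules_per_class < 1:
            raise ValueError("generations and rules_per_class must be positive")


@dataclass
class Population:
    """A generation of chromosomes with their cached fitness values."""

    members: list[Chromosome]
    fitness: list[float]
    generation: int = 0


# ---------------------------------------------------------------------------
# The three genetic operators, on single chromosomes (reference semantics;
# the miner applies the same logic vectorised over whole populations).

def select(pop: Population, rng: np.random.Generator) -> Chromosome:
    """Binary tournament: draw two members uniformly, keep the fitter.

    A tie goes to the first member drawn.
    """
    if not pop.members:
        raise ValueError("empty population")
    n = len(pop.members)
    a, b = int(rng.integers(n)), int(rng.integers(n))
    return pop.members[a] if pop.fitness[a] >= pop.fitness[b] else pop.members[b]


def crossover(
    p1: Chromosome, p2: Chromosome, rate: float, rng: np.random.Generator
) -> tuple[Chromosome, Chromosome]:
    """One-point crossover with probability ``rate``; else copy the parents."""
    if len(p1) != len(p2):
        raise ValueError("parents have different bit lengths")
    if rng.random() >= rate or len(p1) < 2:
        return Chromosome(p1.bits, p1.cls), Chromosome(p2.bits, p2.cls)
    cut = int(rng.integers(1, len(p1)))
    c1 = p1.bits[:cut] + p2.bits[cut:]
    c2 = p2.bits[:cut] + p1.bits[cut:]
    return Chromosome(c1, p1.cls), Chromosome(c2, p2.cls)


def mutate(c: Chromosome, rate: float, rng: np.random.Generator) -> Chromosome:
    """With probability ``rate``, flip one uniformly selected bit.

    A mutation event inverts a single randomly selected element of the
    chromosome (1 becomes 0 and vice versa); most offspring pass through
    unchanged.  Per-bit independent flipping at the same nominal rate was
    tried and rejected: at rate 0.2 it randomises ~each fifth of a long
    chromosome every generation, which prevents rules from ever shedding
    irrelevant features and stalls the search far below the optimum.
    """
    if rng.random() >= rate or len(c.bits) == 0:
        return Chromosome(c.bits, c.cls)
    pos = int(rng.integers(len(c.bits)))
    bits = tuple(b ^ 1 if i == pos else b for i, b in enumerate(c.bits))
    return Chromosome(bits, c.cls)


# ---------------------------------------------------------------------------
# Vectorised evolutionary loop.

def _segment_weights(space: RuleSpace) -> np.ndarray:
    """(n_bits, n_features) matrix turning bit rows into per-feature mask ids."""
    W = np.zeros((space.n_bits, len(space.features)), dtype=np.int64)
    offset = 0
    for f, name in enumerate(space.features):
        k = space.segment_length(name)
        W[offset: offset + k, f] = 1 << np.arange(k)
        offset += k
    return W


#: Probability that a feature's whole segment starts all-zero (irrelevant).
INIT_FEATURE_OFF = 0.75


def _sparse_bits(
    pop_size: int, space: RuleSpace, rng: np.random.Generator
) -> np.ndarray:
    """Bernoulli(0.5) bits, then whole segments zeroed with prob 0.5.

    Purely random bits make nearly every feature relevant (an all-zero or
    all-one segment is rare), and once the population converges to long
    rules, single-bit mutation cannot cross the fitness valley between a
    one-bit mask and an irrelevant segment.  Seeding the population with
    switched-off features lets crossover explore feature subsets and is what
    produces the short, readable rules this kind of system reports.
    """
    bits = (rng.random((pop_size, space.n_bits)) < 0.5).astype(np.int64)
    offset = 0
    for name in space.features:
        k = space.segment_length(name)
        drop = rng.random(pop_size) < INIT_FEATURE_OFF
        bits[drop, offset: offset + k] = 0
        offset += k
    return bits


def _init_population(
    pop_size: int, space: RuleSpace, matrices: FeatureMatrices,
    rng: np.random.Generator, W: np.ndarray, max_tries: int = 100,
) -> np.ndarray:
    """Sparse random population; resample all-irrelevant rows up to max_tries."""
    bits = _sparse_bits(pop_size, space, rng)
    rel = np.column_stack(
        [matrices.REL[f][(bits @ W)[:, f]] for f in range(W.shape[1])]
    )
    for _ in range(max_tries):
        bad = ~rel.any(axis=1)
        if not bad.any():
            break
        bits[bad] = _sparse_bits(int(bad.sum()), space, rng)
        ids = bits[bad] @ W
        rel[bad] = np.column_stack(
            [matrices.REL[f][ids[:, f]] for f in range(W.shape[1])]
        )
    return bits


def _evolve(
    matrices: FeatureMatrices,
    space: RuleSpace,
    cls: RiskLabel,
    cfg: GAConfig,
    rng: np.random.Generator,
) -> dict[bytes, tuple[float, float, float]]:
    """Run the GA; returns the archive of every distinct chromosome seen.

    The archive maps chromosome bits to (support, confidence, fitness); it
    is what rule selection draws from, so good rules discovered in early
    generations survive even if the converging population later drops them.
    """
    W = _segment_weights(space)
    L = space.n_bits
    pop = cfg.population_size
    bits = _init_population(pop, space, matrices, rng, W)
    sup, conf, fit = matrices.population_stats(bits @ W, cls)
    archive: dict[bytes, tuple[float, float, float]] = {}

    def record() -> None:
        for i in range(bits.shape[0]):
            if fit[i] > 0.0:
                key = bits[i].astype(np.uint8).tobytes()
                if key not in archive:
                    archive[key] = (float(sup[i]), float(conf[i]), float(fit[i]))

    record()
    n_children = pop - cfg.elite_count
    n_pairs = (n_children + 1) // 2
    for gen in range(cfg.generations):
        order = np.argsort(-fit, kind="stable")
        elites = bits[order[: cfg.elite_count]]
        # binary tournaments, two parents per pair
        draws = rng.integers(pop, size=(n_pairs, 2, 2))
        winners = np.where(
            fit[draws[:, :, 0]] >= fit[draws[:, :, 1]],
            draws[:, :, 0],
            draws[:, :, 1],
        )
        A, B = bits[winners[:, 0]], bits[winners[:, 1]]
        # one-point crossover per pair
        do_cx = rng.random(n_pairs) < cfg.crossover_rate
        cuts = rng.integers(1, L, size=n_pairs)
        head = np.arange(L)[None, :] < cuts[:, None]
        keep = ~do_cx[:, None] | head
        c1 = np.where(keep, A, B)
        c2 = np.where(keep, B, A)
        children = np.concatenate([c1, c2])[:n_children]
        # single-bit mutation events at the configured rate
        do_mut = rng.random(n_children) < cfg.mutation_rate
        pos = rng.integers(L, size=n_children)
        idx = np.where(do_mut)[0]
        children[idx, pos[idx]] ^= 1
        bits = np.concatenate([elites, children])
        sup, conf, fit = matrices.population_stats(bits @ W, cls)
        record()
        if (gen + 1) % 100 == 0:
            logger.info(
                "class %s gen %d: best fitness %.4f, mean %.4f",
                cls.level, gen + 1, fit.max(), fit.mean(),
            )
    return archive


def _mask_subset(m1: tuple, m2: tuple) -> bool:
    return not any(a and not b for a, b in zip(m1, m2))


def _prune_redundant(
    ranked: list[tuple[FuzzyRule, tuple]], space: RuleSpace,
    tol: float = REDUNDANCY_TOL,
) -> list[FuzzyRule]:
    """Greedy pruning down the ranking: drop a candidate when it is related
    to an already-kept rule by the redundancy test in either direction."""
    kept: list[FuzzyRule] = []
    for rule, _ in ranked:
        redundant = False
        for other in kept:
            if rule.consequent is not other.consequent:
                continue
            if abs(rule.stats["support"] - other.stats["support"]) > tol:
                continue
            forward = all(
                _mask_subset(
                    (rule.selection(n).mask if rule.selection(n)
                     else (1,) * space.segment_length(n)),
                    (other.selection(n).mask if other.selection(n)
                     else (1,) * space.segment_length(n)),
                )
                for n in space.features
            )
            backward = all(
                _mask_subset(
                    (other.selection(n).mask if other.selection(n)
                     else (1,) * space.segment_length(n)),
                    (rule.selection(n).mask if rule.selection(n)
                     else (1,) * space.segment_length(n)),
                )
                for n in space.features
            )
            if forward or backward:
                redundant = True
                break
        if not redundant:
            kept.append(rule)
    return kept


def mine_class(
    d: Dataset,
    partitions: dict[str, FuzzyPartition],
    cls: RiskLabel,
    cfg: GAConfig,
    space: RuleSpace | None = None,
    matrices: FeatureMatrices | None = None,
) -> list[FuzzyRule]:
    """Evolve rules for one risk class and return the best distinct ones.

    The per-class random stream is seeded from ``cfg.seed`` plus the class
    rank, so the three class runs are independent and reproducible.  The
    distinct valid rules of the final population are ranked by fitness
    (ties: higher confidence, fewer antecedent features, then bit-string
    order), pruned of redundant variants, and the top ``rules_per_class``
    returned with their stats cached.
    """
    counts = class_counts(d)
    if counts[cls] == 0:
        raise ValueError(f"no case of class {cls.level} in the dataset")
    if space is None:
        space = RuleSpace(d.schema, partitions)
    if matrices is None:
        matrices = FeatureMatrices(space, d, denominator=cfg.apc_denominator)
    rng = np.random.default_rng(cfg.seed + cls.rank)
    logger.info("mining %s: seed %d", cls.level, cfg.seed + cls.rank)
    archive = _evolve(matrices, space, cls, cfg, rng)

    # Rank the archive and decode only the head; canonical de-duplication
    # can only shrink it, so a few hundred entries is ample headroom.
    head = sorted(
        archive.items(), key=lambda kv: (-kv[1][2], -kv[1][1], kv[0])
    )[: max(200, 20 * cfg.rules_per_class)]
    candidates: dict[tuple, tuple[FuzzyRule, tuple]] = {}
    for key_bytes, (sup, conf, fit) in head:
        if sup <= 0.0 or sup < cfg.min_support:
            continue
        chrom = Chromosome(tuple(int(b) for b in key_bytes), cls)
        try:
            rule = space.decode(chrom)
        except InvalidRuleError:
            continue
        rule.stats = {
            "support": sup,
            "confidence": conf,
            "fitness": fit,
            "dataset_key": id(d),
        }
        rank_key = (-fit, -conf, rule.n_features, chrom.bits)
        key = rule.key()
        if key not in candidates or rank_key < candidates[key][1]:
            candidates[key] = (rule, rank_key)
    ranked = sorted(candidates.values(), key=lambda rc: rc[1])
    pruned = _prune_redundant(ranked, space)
    return pruned[: cfg.rules_per_class]


def mine_all(
    d: Dataset,
    partitions: dict[str, FuzzyPartition],
    cfg: GAConfig,
    fallback: RiskLabel | str = RiskLabel.MEDIUM,
):
    """Mine every risk class present in the cohort into one rule base.

    Classes absent from the data are skipped with a logged warning.
    ``fallback`` is the class predicted when no rule fires; pass the string
    ``"majority"`` to use the majority training class instead of the default
    medium-risk.
    """
    from .classify import RuleBase

    space = RuleSpace(d.schema, partitions)
    matrices = FeatureMatrices(space, d, denominator=cfg.apc_denominator)
    counts = class_counts(d)
    rules: list[FuzzyRule] = []
    for cls in RISK_LEVELS:
        if counts[cls] == 0:
            logger.warning("class %s absent from dataset; skipped", cls.level)
            continue
        rules.extend(
            mine_class(d, partitions, cls, cfg, space=space, matrices=matrices)
        )
    if fallback == "majority":
        fallback = max(RISK_LEVELS, key=lambda c: (counts[c], c.rank))
    return RuleBase(
        rules,
        partitions,
        provenance={"config": asdict(cfg), "seed": cfg.seed},
        fallback=fallback,
    )
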