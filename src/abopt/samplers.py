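"""Optimization strategies over a fitness landscape.

Three landscape samplers — hill climb (greedy local search over a 1000-mutant
neighborhood with random restarts), a genetic algorithm with Wright-Fisher
selection p(x) ~ exp(f(x)/beta) and single-point crossover, and single-site
Gibbs sampling with conditionals ~ exp(gamma * f(x)) — plus the two directed-
evolution baselines (random k-mutant libraries and a position-specific score
matrix fitted to better-than-candidate training sequences).

Every sampler emits a :class:`SamplerTrace` recording each evaluated sequence
with the fitness the landscape reported at visit time; libraries are built
downstream by rank-ordering trace sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import AffinityDataset, DatasetError
from .fitness import FitnessFunction
from .seq import DesignSpace, SequenceVariant, mutate_string


class SamplerError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Configs


@dataclass
class HCConfig:
    """Hill climb: neighborhood of all k=1 mutants plus random k=2 fill."""

    neighborhood_size: int = 1000
    restarts: int = 100
    init_expected_k: float = 2.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.neighborhood_size < 1 or self.restarts < 1:
            raise SamplerError("neighborhood_size and restarts must be >= 1")


@dataclass
class GAConfig:
    """Genetic algorithm with Wright-Fisher selection at temperature beta.

    beta defaults follow the published settings: 0.2 for ensemble-based and
    0.5 for GP-based fitness functions.  child_expected_k = 0 disables the
    per-child mutation step.
    """

    beta: float = 0.2
    population_size: int = 100
    child_expected_k: float = 1.0
    restarts: int = 100
    max_generations: int = 100
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.beta <= 0:
            raise SamplerError("beta must be positive")
        if self.population_size < 2:
            raise SamplerError("population_size must be >= 2")
        if self.child_expected_k < 0:
            raise SamplerError("child_expected_k must be >= 0")


@dataclass
class GibbsConfig:
    """Single-site Gibbs sampling; traces pool over the listed gamma values."""

    gammas: tuple[float, ...] = (18.0,)
    iterations: int = 30_000
    runs_per_gamma: int = 1
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if any(g <= 0 for g in self.gammas) or not self.gammas:
            raise SamplerError("every gamma must be positive")
        if self.iterations < 1 or self.runs_per_gamma < 1:
            raise SamplerError("iterations and runs_per_gamma must be >= 1")


@dataclass
class PSSMModel:
    """Per-position residue probabilities over the designable positions."""

    space: DesignSpace
    matrix: pd.DataFrame  # index = designable position, columns = alphabet
    pseudocount: float

    def __post_init__(self) -> None:
        rows = self.matrix.to_numpy()
        if not np.allclose(rows.sum(axis=1), 1.0, atol=1e-9):
            raise SamplerError("PSSM rows must sum to 1")
        if (rows <= 0).any():
            raise SamplerError("PSSM entries must be strictly positive")

    def to_tsv(self, path) -> None:
        out = self.matrix.copy()
        out.index = [p + 1 for p in out.index]  # 1-based positions in reports
        out.to_csv(path, sep="\t", index_label="position")


@dataclass
class SamplerTrace:
    """Scored record of every sequence a sampler evaluated.

    records columns: sequence, fitness, run, step, accepted (whether the
    sequence is part of the sampler's accepted state path, e.g. a hill-climb
    iterate or a Gibbs sample, as opposed to an evaluated-only candidate).
    """

    sampler: str
    records: pd.DataFrame
    config: dict = field(default_factory=dict)
    seed: int = 0

    def terminal_sequences(self) -> pd.DataFrame:
        acc = self.records[self.records["accepted"]]
        idx = acc.groupby("run")["step"].idxmax()
        return acc.loc[idx]

    def to_tsv(self, path) -> None:
        self.records.assign(sampler=self.sampler).to_csv(path, sep="\t", index=False)


def _trace(sampler: str, rows: list, config: dict, seed: int) -> SamplerTrace:
    df = pd.DataFrame(rows, columns=["sequence", "fitness", "run", "step", "accepted"])
    return SamplerTrace(sampler, df, config, seed)


# ---------------------------------------------------------------------------
# Seeds


def select_seeds(data: AffinityDataset, n: int = 10) -> list[SequenceVariant]:
    """The n strongest binders (lowest averaged measurement) in the data.

    Ties at the cut are broken lexicographically by sequence.
    """
    avg = data.averaged()
    usable = [(a, s) for a, s in zip(avg, data.sequences) if not np.isnan(a)]
    if len(usable) < n:
        raise DatasetError(f"only {len(usable)} usable records, need {n}")
    usable.sort(key=lambda t: (t[0], t[1]))
    return [SequenceVariant(data.space, s) for _, s in usable[:n]]


# ---------------------------------------------------------------------------
# Hill climb


def _k2_fill(
    s: str, space: DesignSpace, existing: set[str], n: int, rng: np.random.Generator
) -> list[str]:
    """Distinct random k=2 mutants of s not already in ``existing``."""
    designable = space.designable_positions
    out: list[str] = []
    attempts, cap = 0, 60 * n + 200
    while len(out) < n and attempts < cap:
        attempts += 1
        i, j = rng.choice(len(designable), size=2, replace=False)
        p1, p2 = designable[int(i)], designable[int(j)]
        chars = list(s)
        for p in (p1, p2):
            choices = [a for a in space.alphabet if a != chars[p]]
            chars[p] = choices[int(rng.integers(len(choices)))]
        cand = "".join(chars)
        if cand not in existing:
            existing.add(cand)
            out.append(cand)
    return out


def _as_seed_list(seed) -> list[SequenceVariant]:
    return list(seed) if isinstance(seed, (list, tuple)) else [seed]


def hill_climb(
    land: FitnessFunction,
    seed: SequenceVariant | list[SequenceVariant],
    cfg: HCConfig | None = None,
    rng: np.random.Generator | None = None,
) -> SamplerTrace:
    """Greedy ascent with random restarts.

    Each restart starts from a random mutant of a (randomly chosen) seed
    (expected k = init_expected_k) and repeatedly moves to the best sequence
    in a neighborhood of all k=1 mutants plus distinct random k=2 mutants
    filling up to neighborhood_size, stopping when no neighbor strictly
    improves.
    """
    cfg = cfg or HCConfig()
    if rng is None:
        rng = np.random.default_rng(cfg.rng_seed)
    seeds = _as_seed_list(seed)
    space = seeds[0].space
    alphabet = space.alphabet
    designable = space.designable_positions
    rows: list = []
    for run in range(cfg.restarts):
        seed_r = seeds[int(rng.integers(len(seeds)))]
        current = mutate_string(seed_r.residues, space, cfg.init_expected_k, rng)
        f_cur = float(land.batch_fitness([current])[0])
        step = 0
        rows.append((current, f_cur, run, step, True))
        while True:
            neigh: list[str] = []
            seen = {current}
            for p in designable:
                for a in alphabet:
                    if a != current[p]:
                        cand = current[:p] + a + current[p + 1 :]
                        neigh.append(cand)
                        seen.add(cand)
            if len(neigh) < cfg.neighborhood_size:
                neigh += _k2_fill(
                    current, space, seen, cfg.neighborhood_size - len(neigh), rng
                )
            else:
                neigh = neigh[: cfg.neighborhood_size]
            fvals = land.batch_fitness(neigh)
            step += 1
            rows.extend(
                (s, float(f), run, step, False) for s, f in zip(neigh, fvals)
            )
            best = int(np.argmax(fvals))
            if fvals[best] > f_cur:
                current, f_cur = neigh[best], float(fvals[best])
                rows.append((current, f_cur, run, step, True))
            else:
                break
    return _trace("hill_climb", rows, vars(cfg).copy(), cfg.rng_seed)


# ---------------------------------------------------------------------------
# Genetic algorithm


def wright_fisher_probs(fitnesses, beta: float) -> np.ndarray:
    """Selection probabilities p(x) ~ exp(f(x)/beta), numerically stable."""
    f = np.asarray(list(fitnesses), dtype=float)
    if f.size == 0:
        raise SamplerError("empty fitness list")
    if not np.isfinite(f).all():
        raise SamplerError("non-finite fitness values")
    if beta <= 0:
        raise SamplerError("beta must be positive")
    z = f / beta
    z -= z.max()
    w = np.exp(z)
    return w / w.sum()


def single_point_crossover(
    p1: SequenceVariant | str,
    p2: SequenceVariant | str,
    rng: np.random.Generator,
    space: DesignSpace | None = None,
) -> SequenceVariant | str:
    """Child = p1[:c] + p2[c:] with crossover point c uniform in [1, L-1]."""
    s1 = p1.residues if isinstance(p1, SequenceVariant) else p1
    s2 = p2.residues if isinstance(p2, SequenceVariant) else p2
    if len(s1) != len(s2):
        raise SamplerError("parents must share a design space")
    if len(s1) < 2:
        raise SamplerError("crossover needs length >= 2")
    c = int(rng.integers(1, len(s1)))
    child = s1[:c] + s2[c:]
    if isinstance(p1, SequenceVariant):
        return SequenceVariant(p1.space, child)
    return child


def genetic_algorithm(
    land: FitnessFunction,
    seed: SequenceVariant | list[SequenceVariant],
    cfg: GAConfig | None = None,
    rng: np.random.Generator | None = None,
) -> SamplerTrace:
    """Wright-Fisher GA; terminates when a generation yields nothing unseen."""
    cfg = cfg or GAConfig()
    if rng is None:
        rng = np.random.default_rng(cfg.rng_seed)
    seeds = _as_seed_list(seed)
    space = seeds[0].space
    rows: list = []
    for run in range(cfg.restarts):
        seed_r = seeds[int(rng.integers(len(seeds)))]
        pop = [
            mutate_string(seed_r.residues, space, cfg.child_expected_k, rng)
            if cfg.child_expected_k > 0
            else seed_r.residues
            for _ in range(cfg.population_size)
        ]
        fvals = land.batch_fitness(pop)
        seen = set(pop)
        rows.extend((s, float(f), run, 0, True) for s, f in zip(pop, fvals))
        for gen in range(1, cfg.max_generations + 1):
            probs = wright_fisher_probs(fvals, cfg.beta)
            parents = rng.choice(len(pop), size=(cfg.population_size, 2), p=probs)
            children = []
            for i1, i2 in parents:
                child = single_point_crossover(pop[int(i1)], pop[int(i2)], rng)
                if cfg.child_expected_k > 0:
                    child = mutate_string(child, space, cfg.child_expected_k, rng)
                children.append(child)
            fvals = land.batch_fitness(children)
            rows.extend((s, float(f), run, gen, True) for s, f in zip(children, fvals))
            new = [c for c in children if c not in seen]
            seen.update(children)
            pop = children
            if not new:
                break
    return _trace("genetic_algorithm", rows, vars(cfg).copy(), cfg.rng_seed)


# ---------------------------------------------------------------------------
# Gibbs sampling


def gibbs_conditional(
    land: FitnessFunction, v: SequenceVariant | str, position: int, gamma: float,
    space: DesignSpace | None = None,
) -> np.ndarray:
    """Full conditional over the alphabet at one site: softmax of gamma*f."""
    if isinstance(v, SequenceVariant):
        space = v.space
        s = v.residues
    else:
        if space is None:
            raise SamplerError("space required for string input")
        s = v
    if position not in space.designable_positions:
        raise SamplerError(f"position {position} is not designable")
    cands = [s[:position] + a + s[position + 1 :] for a in space.alphabet]
    f = land.batch_fitness(cands)
    z = gamma * np.asarray(f, dtype=float)
    z -= z.max()
    w = np.exp(z)
    return w / w.sum()


def gibbs_sample(
    land: FitnessFunction,
    init: SequenceVariant,
    cfg: GibbsConfig | None = None,
    rng: np.random.Generator | None = None,
) -> SamplerTrace:
    """Random-scan single-site Gibbs updates; every iterate is recorded.

    Runs once per (gamma, run) pair and pools all traces; the run index
    increments across the gamma list and each run's gamma is recorded in the
    trace config.
    """
    cfg = cfg or GibbsConfig()
    if rng is None:
        rng = np.random.default_rng(cfg.rng_seed)
    space = init.space
    alphabet = space.alphabet
    designable = space.designable_positions
    rows: list = []
    run = 0
    run_gammas: dict[int, float] = {}
    for gamma in cfg.gammas:
        for _ in range(cfg.runs_per_gamma):
            s = init.residues
            for it in range(cfg.iterations):
                p = designable[int(rng.integers(len(designable)))]
                cands = [s[:p] + a + s[p + 1 :] for a in alphabet]
                f = np.asarray(land.batch_fitness(cands), dtype=float)
                z = gamma * f
                z -= z.max()
                w = np.exp(z)
                probs = w / w.sum()
                choice = int(rng.choice(len(alphabet), p=probs))
                s = cands[choice]
                rows.append((s, float(f[choice]), run, it, True))
            run_gammas[run] = gamma
            run += 1
    config = vars(cfg).copy()
    config["run_gammas"] = run_gammas
    return _trace("gibbs", rows, config, cfg.rng_seed)


# ---------------------------------------------------------------------------
# Directed-evolution baselines


def fit_pssm(
    data: AffinityDataset,
    threshold: float,
    pseudocount: float = 0.1,
) -> PSSMModel:
    """Fit per-position residue probabilities from better-or-equal binders.

    Qualifying sequences are those with averaged measurement <= threshold
    (as good or better than the candidate).  matrix[p][a] =
    (count(p, a) + pseudocount) / (n + pseudocount * |alphabet|).
    """
    if pseudocount <= 0:
        raise SamplerError("pseudocount must be positive")
    avg = data.averaged()
    qualifying = [
        s for s, a in zip(data.sequences, avg) if not np.isnan(a) and a <= threshold
    ]
    if not qualifying:
        raise SamplerError("no sequences as good or better than the threshold")
    space = data.space
    alphabet = space.alphabet
    aindex = {a: i for i, a in enumerate(alphabet)}
    counts = np.zeros((len(space.designable_positions), len(alphabet)))
    for s in qualifying:
        for i, p in enumerate(space.designable_positions):
            counts[i, aindex[s[p]]] += 1
    probs = (counts + pseudocount) / (len(qualifying) + pseudocount * len(alphabet))
    matrix = pd.DataFrame(
        probs, index=list(space.designable_positions), columns=list(alphabet)
    )
    return PSSMModel(space, matrix, pseudocount)


def sample_pssm(
    model: PSSMModel, n: int, rng: np.random.Generator | None = None
) -> list[SequenceVariant]:
    """Draw n designs, each position independently from its PSSM row."""
    if rng is None:
        rng = np.random.default_rng(0)
    space = model.space
    probs = model.matrix.to_numpy()
    letters = np.array(list(space.alphabet))
    draws = np.stack(
        [rng.choice(len(letters), size=n, p=probs[i]) for i in range(probs.shape[0])],
        axis=1,
    )
    out = []
    for row in draws:
        chars = list(space.template)
        for i, p in enumerate(space.designable_positions):
            chars[p] = letters[row[i]]
        out.append(SequenceVariant(space, "".join(chars)))
    return out


def random_mutant_library(
    seeds: list[SequenceVariant],
    expected_k: float = 2.0,
    n: int = 1000,
    rng: np.random.Generator | None = None,
) -> list[SequenceVariant]:
    """n unique random mutants of uniformly chosen seeds (expected k subs)."""
    if not seeds:
        raise SamplerError("need at least one seed")
    if rng is None:
        rng = np.random.default_rng(0)
    space = seeds[0].space
    out: list[SequenceVariant] = []
    seen: set[str] = set()
    stale = 0
    while len(out) < n:
        if stale > 10_000:  # no new unique mutant in a long while: exhausted
            raise SamplerError(f"could not generate {n} unique mutants")
        seed = seeds[int(rng.integers(len(seeds)))]
        s = mutate_string(seed.residues, space, expected_k, rng)
        if s not in seen:
            seen.add(s)
            out.append(SequenceVariant(space, s))
            stale = 0
        else:
            stale += 1
    return out
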