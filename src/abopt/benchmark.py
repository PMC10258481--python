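"""Desk-scale end-to-end benchmark on the synthetic landscape.

Runs the whole design loop against the built-in ground-truth oracle: simulate
a mutagenesis screen, train the surrogate models, build the posterior-
probability fitness landscape, sample libraries with every strategy plus the
PSSM baseline, and score each library's ground-truth percent of success and
diversity.  This is the in-miniature version of the head-to-head study
design: ~2,000 training mutants at k in {1,2,3}, triplicate measurements
with detection-limit censoring, and top-500 libraries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import AffinityDataset
from .evaluate import DesignLibrary, diversity, rank_select_top_n
from .fitness import FitnessLandscape, estimated_percent_success, threshold_from_candidate
from .landscape import (
    LandscapeConfig,
    generate_training_data,
    ground_truth_percent_success,
    random_landscape,
)
from .models import train_ensemble, train_gp
from .samplers import (
    GAConfig,
    GibbsConfig,
    HCConfig,
    fit_pssm,
    gibbs_sample,
    genetic_algorithm,
    hill_climb,
    sample_pssm,
    select_seeds,
)
from .seq import DesignSpace

# Generic VH-like framework used as the benchmark template; the three
# designable spans play the role of CDR loops (30 designable positions).
_TEMPLATE = "EVQLVESGGGLVQPGGSLRLSCAASGFTFSSYAMSWVRQAPGKGL"
_SPANS = ((8, 18), (22, 32), (34, 44))


def default_design_space(chain_id: str = "heavy") -> DesignSpace:
    positions = tuple(p for a, b in _SPANS for p in range(a, b))
    return DesignSpace(chain_id, _TEMPLATE, positions)


# Desk-scale sampler budgets (full-scale defaults live on the config classes).
_EN_HC = dict(neighborhood_size=400, restarts=20, init_expected_k=2.0)
_EN_GA = dict(beta=0.2, population_size=50, child_expected_k=1.0, restarts=10, max_generations=30)
_EN_GIBBS = dict(gammas=(18.0,), iterations=2000)
_GP_HC = dict(neighborhood_size=300, restarts=8, init_expected_k=2.0)
_GP_GA = dict(beta=0.5, population_size=40, child_expected_k=1.0, restarts=6, max_generations=20)
_GP_GIBBS = dict(gammas=(10.0,), iterations=800)


@dataclass
class LibraryReport:
    name: str
    library: DesignLibrary
    gt_percent_success: float
    est_percent_success: float
    d_avg: float
    d_pw: float


@dataclass
class BenchmarkResult:
    seed: int
    sigma: float
    landscape: LandscapeConfig
    train: AffinityDataset
    reports: dict[str, LibraryReport] = field(default_factory=dict)

    def gt(self, name: str) -> float:
        return self.reports[name].gt_percent_success

    def est(self, name: str) -> float:
        return self.reports[name].est_percent_success


def _report(
    name: str,
    library: DesignLibrary,
    cfg: LandscapeConfig,
    sigma: float,
    land: FitnessLandscape | None,
) -> LibraryReport:
    seqs = library.sequences
    gt = ground_truth_percent_success(cfg, seqs, sigma)
    if land is None:
        est = float("nan")
    else:
        est = estimated_percent_success(land, seqs)
    d_avg, d_pw = diversity(seqs, cfg.space.template)
    return LibraryReport(name, library, gt, est, d_avg, d_pw)


def run_benchmark(
    seed: int,
    n_train: int = 2000,
    top_n: int = 500,
    include_gp: bool = False,
    n_epistatic: int = 10,
) -> BenchmarkResult:
    """One full design-and-score cycle on a seeded synthetic landscape.

    Always builds the three ensemble-driven libraries (En-HC, En-GA,
    En-Gibbs) and the PSSM baseline; with ``include_gp`` also the three
    GP-driven libraries.  Library names follow the published convention.
    """
    space = default_design_space()
    cfg = random_landscape(space, rng_seed=seed, n_epistatic=n_epistatic)
    rng = np.random.default_rng(seed)
    train = generate_training_data(cfg, n=n_train, k_values=(1, 2, 3), rng=rng, include_template=True)
    sigma = threshold_from_candidate(train, space.template)
    seeds10 = select_seeds(train, 10)
    top_seed = seeds10[0]

    result = BenchmarkResult(seed=seed, sigma=sigma, landscape=cfg, train=train)

    ensemble = train_ensemble(train, seed=seed)
    en_land = FitnessLandscape(ensemble, sigma)
    runs = {
        "En-HC": hill_climb(en_land, seeds10, HCConfig(rng_seed=seed, **_EN_HC)),
        "En-GA": genetic_algorithm(en_land, seeds10, GAConfig(rng_seed=seed, **_EN_GA)),
        "En-Gibbs": gibbs_sample(en_land, top_seed, GibbsConfig(rng_seed=seed, **_EN_GIBBS)),
    }
    lands = {name: en_land for name in runs}

    if include_gp:
        gp = train_gp(train, seed=seed, max_train=800)
        gp_land = FitnessLandscape(gp, sigma)
        runs["GP-HC"] = hill_climb(gp_land, seeds10, HCConfig(rng_seed=seed, **_GP_HC))
        runs["GP-GA"] = genetic_algorithm(gp_land, seeds10, GAConfig(rng_seed=seed, **_GP_GA))
        runs["GP-Gibbs"] = gibbs_sample(gp_land, top_seed, GibbsConfig(rng_seed=seed, **_GP_GIBBS))
        lands.update({n: gp_land for n in ("GP-HC", "GP-GA", "GP-Gibbs")})

    for name, trace in runs.items():
        library = rank_select_top_n(trace, n=top_n, name=name, land=lands[name])
        result.reports[name] = _report(name, library, cfg, sigma, lands[name])

    # PSSM baseline: raw unique draws, no fitness ranking (the directed-
    # evolution comparator library is sent to validation as sampled)
    pssm = fit_pssm(train, sigma)
    pssm_rng = np.random.default_rng(seed + 1)
    unique: dict[str, None] = {}
    while len(unique) < top_n:
        for v in sample_pssm(pssm, 2 * top_n, pssm_rng):
            unique.setdefault(v.residues, None)
            if len(unique) >= top_n:
                break
    import pandas as pd

    pssm_seqs = list(unique)
    pssm_fit = en_land.batch_fitness(pssm_seqs)
    table = pd.DataFrame(
        {"rank": np.arange(1, top_n + 1), "sequence": pssm_seqs, "fitness": pssm_fit}
    )
    pssm_lib = DesignLibrary("PSSM", table, {"samplers": ["pssm"], "seeds": [seed + 1]})
    result.reports["PSSM"] = _report("PSSM", pssm_lib, cfg, sigma, en_land)
    return result
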