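"""Hill climb, GA, Gibbs, PSSM and random-mutant baselines."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from abopt import (
    AffinityDataset,
    DesignSpace,
    GAConfig,
    GibbsConfig,
    HCConfig,
    OracleFitness,
    PSSMModel,
    fit_pssm,
    generate_training_data,
    genetic_algorithm,
    gibbs_conditional,
    gibbs_sample,
    hamming_distance,
    hill_climb,
    random_landscape,
    random_mutant_library,
    sample_pssm,
    select_seeds,
    single_point_crossover,
    true_affinity,
    wright_fisher_probs,
)
from abopt.samplers import SamplerError


@pytest.fixture
def wide_space():
    return DesignSpace("wide", "A" * 30, tuple(range(30)))


def _dataset(space, rows):
    return AffinityDataset(space, [r[0] for r in rows], np.array([r[1] for r in rows]))


# ---------------------------------------------------------------- seeds


def test_select_seeds_orders_by_affinity_then_sequence(space_small):
    data = _dataset(
        space_small,
        [
            (space_small.template, [3.0, 3.0]),
            ("ACAEFGHIKL", [1.0, 1.0]),
            ("ACCEFGHIKL", [2.0, 2.0]),
            ("ACEEFGHIKL", [2.0, 2.0]),  # tie with previous record
        ],
    )
    seeds = select_seeds(data, 1)
    assert seeds[0].residues == "ACAEFGHIKL"
    top3 = select_seeds(data, 3)
    assert [s.residues for s in top3] == ["ACAEFGHIKL", "ACCEFGHIKL", "ACEEFGHIKL"]
    with pytest.raises(Exception):
        select_seeds(data, 10)


# ---------------------------------------------------------------- softmaxes


def test_wright_fisher_uniform_for_equal_fitness():
    np.testing.assert_allclose(wright_fisher_probs([0.4] * 5, 0.2), np.full(5, 0.2))


def test_wright_fisher_two_point_example():
    p = wright_fisher_probs([0.0, 1.0], 1.0)
    np.testing.assert_allclose(p, [1 / (1 + np.e), np.e / (1 + np.e)])


def test_wright_fisher_large_beta_limit():
    p = wright_fisher_probs(np.linspace(0, 1, 10), 1000.0)
    assert np.abs(p - 0.1).max() < 0.01


@given(
    f=st.lists(st.floats(-5, 5), min_size=2, max_size=12),
    beta=st.floats(0.05, 5.0),
)
@settings(deadline=None, max_examples=50)
def test_wright_fisher_softmax_exactness(f, beta):
    """log p_i - log p_j equals (f_i - f_j)/beta to 1e-12."""
    p = wright_fisher_probs(f, beta)
    assert p.sum() == pytest.approx(1.0, abs=1e-12)
    logp = np.log(p)
    f = np.asarray(f)
    diff = logp[:, None] - logp[None, :] - (f[:, None] - f[None, :]) / beta
    assert np.abs(diff).max() < 1e-12


def test_wright_fisher_errors():
    with pytest.raises(SamplerError):
        wright_fisher_probs([], 1.0)
    with pytest.raises(SamplerError):
        wright_fisher_probs([np.inf], 1.0)


# ---------------------------------------------------------------- crossover


def test_crossover_identical_parents(rng):
    child = single_point_crossover("ACDEF", "ACDEF", rng)
    assert child == "ACDEF"


def test_crossover_structure_over_seeds():
    p1, p2 = "AAAA", "CCCC"
    seen = set()
    for seed in range(50):
        child = single_point_crossover(p1, p2, np.random.default_rng(seed))
        cs = [c for c in range(1, 4) if child == p1[:c] + p2[c:]]
        assert cs, f"child {child} is not a single-point crossover"
        seen.add(child)
    assert "AACC" in seen  # crossover point 2 occurs
    with pytest.raises(SamplerError):
        single_point_crossover("A", "C", np.random.default_rng(0))


# ---------------------------------------------------------------- hill climb


def _distance_oracle(target):
    L = len(target)
    return OracleFitness(lambda s: -hamming_distance(s, target) / L)


def test_hill_climb_reaches_unique_optimum(space4):
    """On f = -hamming(x, target)/L every restart ends at the target."""
    target = "CDEC"
    land = _distance_oracle(target)
    cfg = HCConfig(neighborhood_size=12, restarts=10, init_expected_k=2.0, rng_seed=0)
    trace = hill_climb(land, space4.template_variant, cfg)
    terminals = trace.terminal_sequences()
    assert len(terminals) == 10
    assert set(terminals["sequence"]) == {target}


def test_hill_climb_terminals_are_local_optima(wide_space, rng):
    cfg_land = random_landscape(wide_space, rng_seed=0)
    land = OracleFitness(lambda s: -true_affinity(cfg_land, s))
    cfg = HCConfig(neighborhood_size=600, restarts=3, rng_seed=1)
    trace = hill_climb(land, wide_space.template_variant, cfg)
    recs = trace.records
    for _, t in trace.terminal_sequences().iterrows():
        evaluated = recs[(recs["run"] == t["run"]) & (recs["step"] > t["step"])]
        assert (evaluated["fitness"] <= t["fitness"]).all()


def test_hill_climb_neighborhood_composition(wide_space):
    """k=1 block of 570 plus random k=2 fill up to the requested 1000."""
    land = OracleFitness(lambda s: 0.0)  # flat: terminates after one sweep
    cfg = HCConfig(neighborhood_size=1000, restarts=1, rng_seed=2)
    trace = hill_climb(land, wide_space.template_variant, cfg)
    first = trace.records
    start = first[first["accepted"]].iloc[0]["sequence"]
    evaluated = first[~first["accepted"]]
    assert len(evaluated) == 1000
    d = evaluated["sequence"].map(lambda s: hamming_distance(s, start))
    assert (d == 1).sum() == 30 * 19 == 570
    assert (d == 2).sum() == 430
    assert evaluated["sequence"].is_unique


def test_hill_climb_deterministic(space4):
    land = _distance_oracle("CDEC")
    cfg = HCConfig(neighborhood_size=12, restarts=3, rng_seed=9)
    t1 = hill_climb(land, space4.template_variant, cfg)
    t2 = hill_climb(land, space4.template_variant, cfg)
    assert t1.records.equals(t2.records)


# ---------------------------------------------------------------- GA


def test_ga_terminates_without_mutation_on_identical_population(space4):
    land = OracleFitness(lambda s: 0.0)
    cfg = GAConfig(
        beta=0.2, population_size=4, child_expected_k=0.0, restarts=1, rng_seed=0
    )
    trace = genetic_algorithm(land, space4.template_variant, cfg)
    assert trace.records["step"].max() == 1  # one generation, then converged
    assert set(trace.records["sequence"]) == {space4.template}


def test_ga_deterministic(space4):
    land = _distance_oracle("CDEC")
    cfg = GAConfig(population_size=6, restarts=2, max_generations=5, rng_seed=4)
    t1 = genetic_algorithm(land, space4.template_variant, cfg)
    t2 = genetic_algorithm(land, space4.template_variant, cfg)
    assert t1.records.equals(t2.records)


def test_ga_beats_random_mutant_search(wide_space):
    """Equal-budget head-to-head on the additive landscape, 10 seeded runs."""
    wins = 0
    for seed in range(10):
        cfg_land = random_landscape(wide_space, rng_seed=seed, n_epistatic=0)
        land = OracleFitness(lambda s: -true_affinity(cfg_land, s))
        ga_cfg = GAConfig(
            beta=0.2, population_size=30, restarts=1, max_generations=20, rng_seed=seed
        )
        trace = genetic_algorithm(land, wide_space.template_variant, ga_cfg)
        budget = len(trace.records)
        best_ga = min(true_affinity(cfg_land, s) for s in trace.records["sequence"])
        rng = np.random.default_rng(seed + 1000)
        data = generate_training_data(
            cfg_land, n=budget, k_values=(1, 2, 3), rng=rng
        )
        best_rand = min(true_affinity(cfg_land, s) for s in data.sequences)
        wins += best_ga < best_rand
    assert wins >= 9


# ---------------------------------------------------------------- Gibbs


def test_gibbs_conditional_uniform_at_gamma_zero(space4):
    land = OracleFitness(lambda s: hash(s) % 7)
    p = gibbs_conditional(land, space4.template_variant, 0, gamma=0.0)
    np.testing.assert_allclose(p, np.full(4, 0.25))


def test_gibbs_conditional_two_letter_example():
    space = DesignSpace("bin", "AA", (0, 1), alphabet="AC")
    land = OracleFitness(lambda s: 1.0 if s[0] == "C" else 0.0)
    p = gibbs_conditional(land, space.template_variant, 0, gamma=1.0)
    np.testing.assert_allclose(p, [1 / (1 + np.e), np.e / (1 + np.e)])


def test_gibbs_conditional_shift_invariance_and_exactness(space4):
    base = {a: f for a, f in zip("ACDE", [0.1, 0.9, 0.4, 0.7])}
    for shift in (0.0, 5.0, -3.0):
        land = OracleFitness(lambda s, sh=shift: base[s[1]] + sh)
        p = gibbs_conditional(land, space4.template_variant, 1, gamma=2.0)
        if shift == 0.0:
            p0 = p
        np.testing.assert_allclose(p, p0, atol=1e-12)
    logp = np.log(p0)
    f = np.array([base[a] for a in "ACDE"])
    diff = logp[:, None] - logp[None, :] - 2.0 * (f[:, None] - f[None, :])
    assert np.abs(diff).max() < 1e-12


def test_gibbs_conditional_rejects_non_designable(space_small):
    land = OracleFitness(lambda s: 0.0)
    with pytest.raises(SamplerError):
        gibbs_conditional(land, space_small.template_variant, 0, gamma=1.0)


def test_gibbs_defaults_and_determinism(space4):
    assert GibbsConfig().iterations == 30_000
    land = _distance_oracle("CDEC")
    cfg = GibbsConfig(gammas=(2.0,), iterations=50, rng_seed=3)
    t1 = gibbs_sample(land, space4.template_variant, cfg)
    t2 = gibbs_sample(land, space4.template_variant, cfg)
    assert t1.records.equals(t2.records)
    assert len(t1.records) == 50


def test_gibbs_pools_runs_across_gammas(space4):
    land = _distance_oracle("CDEC")
    cfg = GibbsConfig(gammas=(1.0, 5.0), iterations=20, runs_per_gamma=2, rng_seed=0)
    trace = gibbs_sample(land, space4.template_variant, cfg)
    assert sorted(trace.records["run"].unique()) == [0, 1, 2, 3]
    assert trace.config["run_gammas"] == {0: 1.0, 1: 1.0, 2: 5.0, 3: 5.0}


def test_samplers_never_touch_non_designable_positions(space_small):
    land = OracleFitness(lambda s: -hamming_distance(s, "ACAEFCHAKL") / 10)
    v = space_small.template_variant
    traces = [
        hill_climb(land, v, HCConfig(neighborhood_size=60, restarts=2, rng_seed=0)),
        genetic_algorithm(land, v, GAConfig(population_size=5, restarts=1, max_generations=4, rng_seed=0)),
        gibbs_sample(land, v, GibbsConfig(gammas=(3.0,), iterations=40, rng_seed=0)),
    ]
    frozen = [i for i in range(10) if i not in space_small.designable_positions]
    for trace in traces:
        for s in trace.records["sequence"]:
            assert all(s[i] == space_small.template[i] for i in frozen)


# ---------------------------------------------------------------- PSSM


def test_fit_pssm_single_sequence_hand_computation(space_small):
    """(count + pc) / (n + pc*20) with one qualifying sequence and pc = 0.1."""
    data = _dataset(
        space_small,
        [(space_small.template, [1.0, 1.0]), ("ACAEFCHAKL", [5.0, 5.0])],
    )
    model = fit_pssm(data, threshold=2.0, pseudocount=0.1)
    row = model.matrix.loc[2]
    assert row["D"] == pytest.approx(1.1 / 3.0)  # template residue observed once
    assert row["A"] == pytest.approx(0.1 / 3.0)
    np.testing.assert_allclose(model.matrix.sum(axis=1), 1.0, atol=1e-9)


def test_fit_pssm_threshold_is_inclusive(space_small):
    data = _dataset(space_small, [(space_small.template, [2.0, 2.0])])
    model = fit_pssm(data, threshold=2.0, pseudocount=0.1)  # "as good or better"
    assert model.matrix.loc[2, "D"] == pytest.approx(1.1 / 3.0)
    with pytest.raises(SamplerError):
        fit_pssm(data, threshold=1.0, pseudocount=0.1)


def test_sample_pssm_degenerate_matrix_returns_template(space_small):
    data = _dataset(space_small, [(space_small.template, [1.0, 1.0])])
    model = fit_pssm(data, threshold=2.0, pseudocount=1e-9)
    samples = sample_pssm(model, 500, np.random.default_rng(0))
    assert {v.residues for v in samples} == {space_small.template}


def test_sample_pssm_frequencies_match_matrix(space_small, rng):
    cfg_land = random_landscape(space_small, rng_seed=0)
    data = generate_training_data(cfg_land, n=50, k_values=(1, 2), rng=rng)
    model = fit_pssm(data, threshold=np.inf, pseudocount=0.1)
    n = 20_000
    samples = sample_pssm(model, n, np.random.default_rng(1))
    for i, p in enumerate(space_small.designable_positions):
        for a in space_small.alphabet:
            prob = model.matrix.loc[p, a]
            count = sum(v.residues[p] == a for v in samples)
            sd = np.sqrt(n * prob * (1 - prob))
            assert abs(count - n * prob) < 3 * sd + 3


def test_sample_pssm_deterministic(space_small):
    data = _dataset(space_small, [(space_small.template, [1.0, 1.0])])
    model = fit_pssm(data, threshold=2.0)
    a = [v.residues for v in sample_pssm(model, 50, np.random.default_rng(5))]
    b = [v.residues for v in sample_pssm(model, 50, np.random.default_rng(5))]
    assert a == b


# ---------------------------------------------------------------- random library


def test_random_mutant_library_unique_and_constrained(space_small, rng):
    seeds = [space_small.template_variant, space_small.variant("ACAEFGHIKL")]
    lib = random_mutant_library(seeds, expected_k=2.0, n=100, rng=rng)
    assert len({v.residues for v in lib}) == 100
    frozen = [i for i in range(10) if i not in space_small.designable_positions]
    for v in lib:
        assert all(v.residues[i] == space_small.template[i] for i in frozen)
    with pytest.raises(SamplerError):
        random_mutant_library([], n=10, rng=rng)


def test_random_mutant_library_capacity_error(space_small, rng):
    with pytest.raises(SamplerError):
        # 3 designable positions cannot yield 10^5 unique mutants
        random_mutant_library([space_small.template_variant], 2.0, 100_000, rng)
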