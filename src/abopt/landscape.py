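"""Synthetic ground-truth affinity landscape and assay simulator.

Stands in for a high-throughput binding assay: a deterministic additive +
pairwise-epistatic log-affinity oracle over a design space, plus a training
data generator that emulates a mutagenesis screen — random k in {1,2,3} CDR
mutants of the candidate, replicate noisy measurements, and limit-of-
detection censoring (values beyond the limit recorded as missing).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import AffinityDataset
from .seq import DesignSpace, SequenceVariant, mutate_string


class LandscapeError(ValueError):
    pass


@dataclass
class LandscapeConfig:
    """Ground-truth landscape: baseline + additive effects + epistatic pairs.

    Log-scale convention throughout: lower value = stronger binding, so a
    negative effect is a beneficial mutation.

    additive_effects maps (position, residue) -> effect; template residues
    carry zero effect by construction.  epistatic_terms are
    ((pos1, res1), (pos2, res2), effect) triples active only when both
    substitutions are present.
    """

    space: DesignSpace
    baseline: float = 3.0
    additive_effects: dict[tuple[int, str], float] = field(default_factory=dict)
    epistatic_terms: list[tuple[tuple[int, str], tuple[int, str], float]] = field(
        default_factory=list
    )
    noise_sd: float = 0.3
    detection_limit: float | None = None
    replicates: int = 3
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise LandscapeError("replicates must be >= 1")
        if self.noise_sd < 0:
            raise LandscapeError("noise_sd must be non-negative")
        if self.detection_limit is None:
            self.detection_limit = self.baseline + 2.0
        designable = set(self.space.designable_positions)
        for (p, r) in self.additive_effects:
            if p not in designable:
                raise LandscapeError(f"effect at non-designable position {p}")
            if self.space.template[p] == r and self.additive_effects[(p, r)] != 0.0:
                raise LandscapeError(f"template residue at {p} must have zero effect")


def save_landscape(cfg: LandscapeConfig, path) -> None:
    """Serialize a landscape (minus the design space) to YAML."""
    import yaml

    payload = {
        "chain_id": cfg.space.chain_id,
        "template": cfg.space.template,
        "designable_positions": list(cfg.space.designable_positions),
        "alphabet": cfg.space.alphabet,
        "baseline": cfg.baseline,
        "additive_effects": [[p, r, e] for (p, r), e in cfg.additive_effects.items()],
        "epistatic_terms": [
            [p1, r1, p2, r2, e] for (p1, r1), (p2, r2), e in cfg.epistatic_terms
        ],
        "noise_sd": cfg.noise_sd,
        "detection_limit": cfg.detection_limit,
        "replicates": cfg.replicates,
        "rng_seed": cfg.rng_seed,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh)


def load_landscape(path) -> LandscapeConfig:
    import yaml

    with open(path) as fh:
        payload = yaml.safe_load(fh)
    space = DesignSpace(
        payload["chain_id"],
        payload["template"],
        tuple(payload["designable_positions"]),
        payload["alphabet"],
    )
    return LandscapeConfig(
        space=space,
        baseline=payload["baseline"],
        additive_effects={(p, r): e for p, r, e in payload["additive_effects"]},
        epistatic_terms=[
            ((p1, r1), (p2, r2), e) for p1, r1, p2, r2, e in payload["epistatic_terms"]
        ],
        noise_sd=payload["noise_sd"],
        detection_limit=payload["detection_limit"],
        replicates=payload["replicates"],
        rng_seed=payload["rng_seed"],
    )


def random_landscape(
    space: DesignSpace,
    rng_seed: int = 0,
    baseline: float = 3.0,
    additive_sd: float = 1.0,
    n_epistatic: int = 10,
    epistatic_sd: float = 0.5,
    noise_sd: float = 0.3,
    replicates: int = 3,
    detection_limit: float | None = None,
) -> LandscapeConfig:
    """Default rugged-but-learnable landscape.

    Per-(position, residue) additive effects ~ N(0, additive_sd) for every
    non-template residue at every designable position, plus ``n_epistatic``
    random pairwise terms ~ N(0, epistatic_sd).
    """
    rng = np.random.default_rng(rng_seed)
    additive: dict[tuple[int, str], float] = {}
    for p in space.designable_positions:
        for a in space.alphabet:
            if a != space.template[p]:
                additive[(p, a)] = float(rng.normal(0.0, additive_sd))
    epistatic = []
    positions = space.designable_positions
    for _ in range(n_epistatic):
        if len(positions) < 2:
            break
        p1, p2 = rng.choice(len(positions), size=2, replace=False)
        p1, p2 = positions[int(p1)], positions[int(p2)]
        a1 = _random_non_template(space, p1, rng)
        a2 = _random_non_template(space, p2, rng)
        epistatic.append(((p1, a1), (p2, a2), float(rng.normal(0.0, epistatic_sd))))
    return LandscapeConfig(
        space=space,
        baseline=baseline,
        additive_effects=additive,
        epistatic_terms=epistatic,
        noise_sd=noise_sd,
        replicates=replicates,
        detection_limit=detection_limit,
        rng_seed=rng_seed,
    )


def _random_non_template(space: DesignSpace, p: int, rng: np.random.Generator) -> str:
    choices = [a for a in space.alphabet if a != space.template[p]]
    return choices[int(rng.integers(len(choices)))]


def true_affinity(cfg: LandscapeConfig, v: SequenceVariant | str) -> float:
    """Deterministic ground-truth log-affinity of a variant."""
    s = v.residues if isinstance(v, SequenceVariant) else v
    total = cfg.baseline
    template = cfg.space.template
    for p in cfg.space.designable_positions:
        if s[p] != template[p]:
            total += cfg.additive_effects.get((p, s[p]), 0.0)
    for (p1, r1), (p2, r2), eff in cfg.epistatic_terms:
        if s[p1] == r1 and s[p2] == r2:
            total += eff
    return float(total)


def generate_training_data(
    cfg: LandscapeConfig,
    n: int,
    k_values: tuple[int, ...] = (1, 2, 3),
    rng: np.random.Generator | None = None,
    include_template: bool = False,
) -> AffinityDataset:
    """Simulate a mutagenesis screen of ``n`` unique random mutants.

    Each variant's mutational distance to the template is drawn uniformly
    from ``k_values`` (the exact distance, not an expectation).  Replicate
    measurements are true_affinity + N(0, noise_sd) noise, then any value
    above the detection limit is recorded as missing.

    ``include_template`` appends the unmutated candidate itself as a record,
    as a screen of the candidate's own assay replicates.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.rng_seed)
    space = cfg.space
    designable = space.designable_positions
    for k in k_values:
        if not 1 <= k <= len(designable):
            raise LandscapeError(f"k={k} outside [1, {len(designable)}]")
    seqs: list[str] = []
    seen: set[str] = set()
    if include_template:
        seqs.append(space.template)
        seen.add(space.template)
    attempts, cap = 0, 200 * (n + 1) + 1000
    while len(seqs) < n + int(include_template):
        attempts += 1
        if attempts > cap:
            raise LandscapeError(
                f"could not generate {n} unique variants at distances {k_values}"
            )
        k = int(rng.choice(k_values))
        positions = rng.choice(len(designable), size=k, replace=False)
        chars = list(space.template)
        for idx in positions:
            p = designable[int(idx)]
            chars[p] = _random_non_template(space, p, rng)
        s = "".join(chars)
        if s not in seen:
            seen.add(s)
            seqs.append(s)
    truth = np.array([true_affinity(cfg, s) for s in seqs])
    meas = truth[:, None] + rng.normal(0.0, cfg.noise_sd, size=(len(seqs), cfg.replicates))
    if cfg.noise_sd == 0:
        meas = np.repeat(truth[:, None], cfg.replicates, axis=1)
    meas[meas > cfg.detection_limit] = np.nan
    return AffinityDataset(space, seqs, meas)


def ground_truth_percent_success(
    cfg: LandscapeConfig,
    library: list[SequenceVariant] | list[str],
    threshold: float,
) -> float:
    """Fraction of the library with true affinity strictly below threshold."""
    if not library:
        raise LandscapeError("percent success undefined for an empty library")
    if not np.isfinite(threshold):
        raise LandscapeError("threshold must be finite")
    hits = sum(true_affinity(cfg, v) < threshold for v in library)
    return hits / len(library)
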