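"""Bayesian acquisition layer: posterior probability of beating a threshold.

The fitness of a sequence x is f(x) = p(aff(x) < sigma | x): the posterior
probability that its (log-scale, lower-is-stronger) affinity beats the
threshold sigma.  Under the Gaussian predictive assumption this is
Phi((sigma - mu) / s) for a model prediction (mu, s).  Averaging f over a
library gives the in-silico estimate of the library's percent of success.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Protocol, runtime_checkable

import numpy as np
from scipy.special import ndtr

from .data import AffinityDataset
from .seq import SequenceVariant


class FitnessError(ValueError):
    pass


@runtime_checkable
class FitnessFunction(Protocol):
    """Anything mapping a batch of sequences to fitness values in [0, 1]."""

    def batch_fitness(self, seqs) -> np.ndarray: ...


def threshold_from_candidate(
    data: AffinityDataset, candidate: SequenceVariant | str
) -> float:
    """sigma = the candidate's averaged assayed value in the training data."""
    try:
        return data.average_for(candidate)
    except Exception as exc:
        raise FitnessError(
            "candidate absent from dataset or fully missing; supply sigma explicitly"
        ) from exc


@dataclass
class FitnessLandscape:
    """A fitted surrogate model plus the success threshold sigma.

    Model predictions are memoized per sequence (the model is deterministic),
    so re-scoring sequences a sampler already visited is free.
    """

    model: object  # EnsembleModel | GPModel (anything with predict_batch)
    sigma: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.sigma):
            raise FitnessError("threshold sigma must be finite")
        self._cache: dict[str, tuple[float, float]] = {}

    def clear_cache(self) -> None:
        self._cache.clear()

    def _predict_cached(self, seqs: list[str]) -> tuple[np.ndarray, np.ndarray]:
        keys = [s.residues if isinstance(s, SequenceVariant) else s for s in seqs]
        missing = list(dict.fromkeys(k for k in keys if k not in self._cache))
        if missing:
            mu_new, s_new = self.model.predict_batch(missing)
            for k, m, sd in zip(missing, mu_new, s_new):
                self._cache[k] = (float(m), float(sd))
        pairs = np.array([self._cache[k] for k in keys])
        return pairs[:, 0], pairs[:, 1]

    def batch_fitness(self, seqs, sigma: float | None = None) -> np.ndarray:
        seqs = list(seqs)
        if not seqs:
            return np.empty(0)
        sigma = self.sigma if sigma is None else sigma
        mu, s = self._predict_cached(seqs)
        if not (np.isfinite(mu).all() and np.isfinite(s).all()):
            bad = [str(q) for q, m, sd in zip(seqs, mu, s) if not (np.isfinite(m) and np.isfinite(sd))]
            raise FitnessError(f"non-finite prediction for variant(s) {bad[:3]}")
        out = np.empty(len(seqs))
        pos = s > 0
        out[pos] = ndtr((sigma - mu[pos]) / s[pos])
        # degenerate s = 0: deterministic prediction, step rule
        zero = ~pos
        out[zero] = np.where(mu[zero] < sigma, 1.0, np.where(mu[zero] > sigma, 0.0, 0.5))
        return out

    def batch_margin(self, seqs, sigma: float | None = None) -> np.ndarray:
        """Gaussian margin z = (sigma - mu) / s; fitness = Phi(z).

        Strictly monotone in fitness but free of the floating-point
        saturation of the CDF (Phi rounds to 1.0 beyond z ~ 8), so it is the
        preferred rank-ordering score for library selection.
        """
        seqs = list(seqs)
        if not seqs:
            return np.empty(0)
        sigma = self.sigma if sigma is None else sigma
        mu, s = self._predict_cached(seqs)
        with np.errstate(divide="ignore"):
            z = np.where(s > 0, (sigma - mu) / np.maximum(s, 1e-300), np.inf)
        z = np.where((s <= 0) & (mu > sigma), -np.inf, z)
        z = np.where((s <= 0) & (mu == sigma), 0.0, z)
        return z


def fitness(land: FitnessLandscape, v: SequenceVariant | str) -> float:
    """Posterior success probability of a single variant."""
    return float(land.batch_fitness([v])[0])


def batch_fitness(land: FitnessLandscape, variants) -> np.ndarray:
    return land.batch_fitness(variants)


def estimated_percent_success(
    land: FitnessLandscape, library, sigma: float | None = None
) -> float:
    """Mean fitness over a library: the in-silico percent-of-success forecast.

    ``sigma`` overrides the landscape threshold, supporting analyses that
    sweep the strong-binder definition.
    """
    library = list(library)
    if not library:
        raise FitnessError("estimated percent success undefined for empty library")
    return float(land.batch_fitness(library, sigma=sigma).mean())


@dataclass
class OracleFitness:
    """Fitness computed from a ground-truth callable; used for benchmarking.

    ``fn`` maps a sequence string to a real score (already a fitness, not an
    affinity); no model is involved.
    """

    fn: object

    def batch_fitness(self, seqs) -> np.ndarray:
        vals = [
            self.fn(s.residues if isinstance(s, SequenceVariant) else s) for s in seqs
        ]
        return np.asarray(vals, dtype=float)
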