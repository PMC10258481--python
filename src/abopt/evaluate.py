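"""Library construction and the evaluation battery.

Turns sampler traces into ranked design libraries and computes the library
metrics: percent of success under the replicate-count inclusion rule,
diversity (mean distance to the candidate and mean pairwise distance), fold
improvement of best binders, estimated-vs-measured library rankings, and a
2-D neighbor embedding of one-hot encoded sequences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist
from sklearn.manifold import TSNE

from .encoders import OneHotEncoder, code_matrix
from .samplers import SamplerTrace
from .seq import DesignSpace, SequenceVariant, hamming_distance


class EvalError(ValueError):
    pass


@dataclass
class DesignLibrary:
    """Unique ranked variants with fitness scores and provenance."""

    name: str
    table: pd.DataFrame  # columns: rank, sequence, fitness
    provenance: dict = field(default_factory=dict)

    @property
    def sequences(self) -> list[str]:
        return self.table["sequence"].tolist()

    def __len__(self) -> int:
        return len(self.table)

    def to_tsv(self, path, candidate: str | None = None) -> None:
        out = self.table.copy()
        out.insert(1, "id", [f"d{r}" for r in out["rank"]])
        if candidate is not None:
            out["mutations_from_candidate"] = [
                hamming_distance(s, candidate) for s in out["sequence"]
            ]
        out.to_csv(path, sep="\t", index=False)


def rank_select_top_n(
    traces: list[SamplerTrace] | SamplerTrace,
    n: int = 6000,
    name: str = "library",
    land=None,
) -> DesignLibrary:
    """Deduplicate trace sequences, rank by fitness (desc), keep the top n.

    Ties in fitness break lexicographically by sequence; the recorded
    fitness of the first occurrence is kept (identical by determinism).
    When a fitness landscape is supplied, ranking uses its Gaussian margin
    z = (sigma - mu)/s instead of the recorded probability — identical
    ordering mathematically, but immune to the CDF saturating to exactly
    1.0 in floating point (which would make ties at the top arbitrary).
    """
    if isinstance(traces, SamplerTrace):
        traces = [traces]
    pooled = pd.concat([t.records[["sequence", "fitness"]] for t in traces])
    dedup = pooled.drop_duplicates(subset="sequence", keep="first").copy()
    if land is not None and hasattr(land, "batch_margin"):
        dedup["_score"] = land.batch_margin(dedup["sequence"].tolist())
    else:
        dedup["_score"] = dedup["fitness"]
    ranked = (
        dedup.sort_values(["_score", "sequence"], ascending=[False, True], kind="mergesort")
        .drop(columns="_score")
        .reset_index(drop=True)
    )
    if len(ranked) < n:
        warnings.warn(f"only {len(ranked)} unique sequences available, requested {n}")
    top = ranked.head(n).copy()
    top.insert(0, "rank", np.arange(1, len(top) + 1))
    provenance = {
        "samplers": [t.sampler for t in traces],
        "seeds": [t.seed for t in traces],
        "configs": [
            {k: v for k, v in t.config.items() if isinstance(v, (int, float, str, tuple, list))}
            for t in traces
        ],
    }
    return DesignLibrary(name, top, provenance)


@dataclass
class MeasuredLibrary:
    """Variants with replicate validation measurements (NaN = missing).

    The published validation protocol used 6 replicate slots with a
    >=3-of-6 inclusion rule; both are configurable to match the assay.
    """

    sequences: list[str]
    measurements: np.ndarray  # (n, n_slots); all-NaN row = unmeasured
    n_slots: int = 6

    def __post_init__(self) -> None:
        self.measurements = np.asarray(self.measurements, dtype=float)
        if self.measurements.shape != (len(self.sequences), self.n_slots):
            raise EvalError("measurements must be (n_sequences, n_slots)")


def percent_success(
    lib: MeasuredLibrary, success_threshold: float, min_replicates: int = 3
) -> float:
    """Fraction of the library measurably better than the threshold.

    A variant succeeds iff it has >= min_replicates non-missing replicates
    AND its replicate mean is strictly below the threshold; everything else
    (unmeasured or under-replicated) counts as a failure in the denominator.
    """
    if len(lib.sequences) == 0:
        raise EvalError("empty library")
    counts = (~np.isnan(lib.measurements)).sum(axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        means = np.nanmean(lib.measurements, axis=1)
    ok = (counts >= min_replicates) & (means < success_threshold)
    return float(ok.sum() / len(lib.sequences))


def assign_worst_to_unsuccessful(
    lib: MeasuredLibrary, worst_value: float, min_replicates: int = 3
) -> pd.DataFrame:
    """Per-variant affinity table with unsuccessful designs set to worst_value.

    Published conventions: 5.48 for heavy-chain and 5.53 for light-chain
    variant libraries (the largest assay value observed per chain).
    """
    counts = (~np.isnan(lib.measurements)).sum(axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        means = np.nanmean(lib.measurements, axis=1)
    qualifying = counts >= min_replicates
    observed = means[qualifying & ~np.isnan(means)]
    if observed.size and worst_value < observed.max():
        warnings.warn("worst_value is below an observed mean; proceeding anyway")
    vals = np.where(qualifying, means, worst_value)
    vals = np.where(np.isnan(vals), worst_value, vals)
    return pd.DataFrame({"sequence": lib.sequences, "affinity": vals})


def diversity(
    sequences: list[str] | DesignLibrary,
    candidate: SequenceVariant | str,
    max_exact: int = 2000,
    pair_budget: int = 200_000,
    rng_seed: int = 0,
) -> tuple[float, float]:
    """(d_avg, d_pw): mean distance to the candidate, mean pairwise distance.

    d_pw is exact (all unordered pairs) up to ``max_exact`` sequences and a
    seeded uniform subsample of ``pair_budget`` pairs above that.
    """
    if isinstance(sequences, DesignLibrary):
        sequences = sequences.sequences
    if not sequences:
        raise EvalError("empty library")
    cand = candidate.residues if isinstance(candidate, SequenceVariant) else candidate
    codes = code_matrix(list(sequences))
    cand_codes = code_matrix([cand])[0]
    d_avg = float((codes != cand_codes).sum(axis=1).mean())
    n = len(sequences)
    if n < 2:
        warnings.warn("singleton library: d_pw defined as 0")
        return d_avg, 0.0
    L = codes.shape[1]
    if n <= max_exact:
        d_pw = float(pdist(codes, metric="hamming").mean() * L)
    else:
        rng = np.random.default_rng(rng_seed)
        i = rng.integers(n, size=pair_budget)
        j = rng.integers(n - 1, size=pair_budget)
        j = np.where(j >= i, j + 1, j)  # uniform over off-diagonal pairs
        d_pw = float((codes[i] != codes[j]).sum(axis=1).mean())
    return d_avg, d_pw


def fold_improvement(best_baseline_affinity: float, best_library_affinity: float) -> float:
    """baseline / library on a linear scale (e.g. pM); > 1 = stronger binding."""
    if best_baseline_affinity <= 0 or best_library_affinity <= 0:
        raise EvalError("affinities must be positive (linear scale)")
    return best_baseline_affinity / best_library_affinity


def rank_libraries(estimated: dict[str, float]) -> list[str]:
    """Library names ordered by descending estimated percent of success."""
    if len(estimated) < 2:
        raise EvalError("need at least 2 libraries to rank")
    return sorted(estimated, key=lambda k: (-estimated[k], k))


def rank_agreement(estimated: dict[str, float], actual: dict[str, float]) -> float:
    """Spearman rank correlation between estimated and actual success values."""
    if set(estimated) != set(actual):
        raise EvalError("library name sets differ")
    names = sorted(estimated)
    return float(
        stats.spearmanr([estimated[k] for k in names], [actual[k] for k in names]).statistic
    )


def onehot_encode(v: SequenceVariant | str, space: DesignSpace | None = None) -> np.ndarray:
    """Flat one-hot vector of length L x 20 with exactly L ones.

    For two sequences the L1 distance between their one-hot vectors equals
    2 x the Hamming distance (each differing site contributes two mismatched
    indicator blocks).
    """
    if isinstance(v, SequenceVariant):
        space = v.space
    if space is None:
        space = DesignSpace("adhoc", v if isinstance(v, str) else v.residues, ())
    return OneHotEncoder().encode(space, v)


def embed_2d(
    vectors: np.ndarray,
    perplexity: float = 500.0,
    learning_rate: float = 200.0,
    rng_seed: int = 0,
) -> np.ndarray:
    """t-SNE embedding with the L1 metric and PCA initialization."""
    vectors = np.asarray(vectors, dtype=float)
    if vectors.shape[0] < 2:
        raise EvalError("embedding needs at least 2 sequences")
    if perplexity >= vectors.shape[0]:
        raise EvalError("perplexity must be below the number of sequences")
    tsne = TSNE(
        n_components=2,
        metric="l1",
        init="pca",
        perplexity=perplexity,
        learning_rate=learning_rate,
        random_state=rng_seed,
    )
    return tsne.fit_transform(vectors)
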