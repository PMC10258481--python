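"""Uncertainty-aware sequence-to-affinity surrogate models.

Two model families, both reporting a predictive mean and standard deviation
per sequence:

* an ensemble of independent regressors spanning every combination of
  sequence encoder x regression loss {MSE, MAE} x missing-value policy
  {drop, median-impute} (with four encoders this is the classic 16-member
  layout; with the three shipped encoders it is 12);
* a Gaussian process on PCA-reduced encoder vectors.

The ensemble's predictive sd is the population (divide-by-n) standard
deviation over member outputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.exceptions import ConvergenceWarning
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, ConstantKernel, WhiteKernel
from sklearn.linear_model import Ridge, SGDRegressor

from .data import AffinityDataset, DatasetError
from .encoders import SequenceEncoder, default_encoders
from .seq import DesignSpace, SequenceVariant, hamming_distance

MISSING_POLICIES = ("drop_assay", "median_impute")
LOSSES = ("mse", "mae")


class ModelError(RuntimeError):
    pass


def preprocess(data: AffinityDataset, policy: str) -> pd.DataFrame:
    """Reduce replicate measurements to one target value per sequence.

    drop_assay: missing replicates are dropped before averaging; records
    whose replicates are all missing are excluded entirely.

    median_impute: each missing replicate is replaced by the median of all
    non-missing assay values in the dataset, then replicates are averaged.
    """
    if policy not in MISSING_POLICIES:
        raise ValueError(f"unknown missing-value policy {policy!r}")
    if len(data) == 0:
        raise DatasetError("empty dataset")
    meas = data.measurements
    if policy == "drop_assay":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            y = np.nanmean(meas, axis=1)
        keep = ~np.isnan(y)
        if not keep.any():
            raise DatasetError("all measurements missing under drop_assay")
        return pd.DataFrame(
            {"sequence": [s for s, k in zip(data.sequences, keep) if k], "y": y[keep]}
        )
    median = float(np.nanmedian(meas))
    filled = np.where(np.isnan(meas), median, meas)
    return pd.DataFrame({"sequence": list(data.sequences), "y": filled.mean(axis=1)})


def split(
    data: AffinityDataset,
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    rng: np.random.Generator | int = 0,
) -> tuple[AffinityDataset, AffinityDataset, AffinityDataset]:
    """Seeded train/validation/test partition, disjoint by sequence."""
    if len(data) < 3:
        raise DatasetError("need at least 3 records to split")
    fractions = tuple(float(f) for f in fractions)
    if any(f <= 0 for f in fractions) or abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must be positive and sum to 1")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    n = len(data)
    perm = rng.permutation(n)
    sizes = [int(np.floor(n * f)) for f in fractions]
    remainders = [n * f - s for f, s in zip(fractions, sizes)]
    for _ in range(n - sum(sizes)):
        i = int(np.argmax(remainders))
        sizes[i] += 1
        remainders[i] = -1
    bounds = np.cumsum([0] + sizes)
    return tuple(
        data.subset(perm[bounds[i] : bounds[i + 1]]) for i in range(3)
    )  # type: ignore[return-value]


@dataclass(frozen=True)
class AffinityPrediction:
    """Predictive mean and standard deviation of a log-affinity."""

    mean: float
    sd: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.mean) and np.isfinite(self.sd) and self.sd >= 0):
            raise ModelError(f"invalid prediction mean={self.mean} sd={self.sd}")


@dataclass
class EnsembleMember:
    encoder: SequenceEncoder
    loss: str
    policy: str
    estimator: object

    @property
    def name(self) -> str:
        return f"{self.encoder.name}/{self.loss}/{self.policy}"


@dataclass
class EnsembleModel:
    """Fitted member regressors, one per (encoder, loss, policy) cell."""

    space: DesignSpace
    members: list[EnsembleMember]

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ModelError("ensemble requires at least 2 members")

    def predict_batch(self, seqs) -> tuple[np.ndarray, np.ndarray]:
        seqs = list(seqs)
        if not seqs:
            return np.empty(0), np.empty(0)
        preds = np.empty((len(self.members), len(seqs)))
        cache: dict[str, np.ndarray] = {}
        for i, m in enumerate(self.members):
            key = m.encoder.name
            if key not in cache:
                cache[key] = m.encoder.encode_batch(self.space, seqs)
            preds[i] = m.estimator.predict(cache[key])
        return preds.mean(axis=0), preds.std(axis=0)  # population sd

    def predict(self, v: SequenceVariant | str) -> AffinityPrediction:
        mu, sd = self.predict_batch([v])
        return AffinityPrediction(float(mu[0]), float(sd[0]))


def _make_estimator(loss: str, seed: int):
    if loss == "mse":
        return Ridge(alpha=1.0, solver="lsqr", random_state=seed)
    # linear model under the exact L1 (MAE) objective
    return SGDRegressor(
        loss="epsilon_insensitive",
        epsilon=0.0,
        penalty="l2",
        alpha=1e-5,
        max_iter=300,
        tol=1e-5,
        random_state=seed,
    )


def train_ensemble(
    data: AffinityDataset,
    encoders: list[SequenceEncoder] | None = None,
    seed: int = 0,
) -> EnsembleModel:
    """Fit one regressor per (encoder, loss, missing-value policy) cell."""
    if encoders is None:
        encoders = default_encoders()
    if len(data) < 20:
        raise DatasetError("need at least 20 training records")
    tables = {policy: preprocess(data, policy) for policy in MISSING_POLICIES}
    members: list[EnsembleMember] = []
    i = 0
    for enc in encoders:
        enc_cache: dict[str, np.ndarray] = {}
        for policy in MISSING_POLICIES:
            table = tables[policy]
            if policy not in enc_cache:
                enc_cache[policy] = enc.encode_batch(data.space, table["sequence"].tolist())
            X, y = enc_cache[policy], table["y"].to_numpy()
            if np.std(y) == 0:
                warnings.warn("degenerate (zero-variance) training targets")
            for loss in LOSSES:
                est = _make_estimator(loss, seed + i)
                with warnings.catch_warnings():
                    # the SGD members run a fixed epoch budget by design
                    warnings.simplefilter("ignore", ConvergenceWarning)
                    est.fit(X, y)
                members.append(EnsembleMember(enc, loss, policy, est))
                i += 1
    return EnsembleModel(data.space, members)


@dataclass
class GPModel:
    """Gaussian process on PCA-reduced concatenated residue encodings.

    Predictions describe the latent affinity function: the fitted
    observation-noise variance (WhiteKernel) is subtracted from the
    predictive variance, so sd reflects model uncertainty about the
    underlying binding value rather than assay noise.
    """

    space: DesignSpace
    encoder: SequenceEncoder
    pca: PCA
    gpr: GaussianProcessRegressor

    def predict_batch(self, seqs) -> tuple[np.ndarray, np.ndarray]:
        seqs = list(seqs)
        if not seqs:
            return np.empty(0), np.empty(0)
        X = self.pca.transform(self.encoder.encode_batch(self.space, seqs))
        mu, sd = self.gpr.predict(X, return_std=True)
        noise = 0.0
        kernel = self.gpr.kernel_
        if hasattr(kernel, "k2") and hasattr(kernel.k2, "noise_level"):
            noise = kernel.k2.noise_level * self.gpr._y_train_std**2
        return mu, np.sqrt(np.maximum(sd**2 - noise, 1e-12))

    def predict(self, v: SequenceVariant | str) -> AffinityPrediction:
        mu, sd = self.predict_batch([v])
        return AffinityPrediction(float(mu[0]), float(sd[0]))


def train_gp(
    data: AffinityDataset,
    encoder: SequenceEncoder | None = None,
    pca_dim: int = 512,
    seed: int = 0,
    max_train: int | None = None,
) -> GPModel:
    """Fit the PCA + RBF-kernel GP model (median-impute preprocessing).

    pca_dim is capped at min(n_train, feature dim); the published recipe
    used 1024 components on transformer embeddings; the desk default is 512
    (one-hot indicator features spread signal nearly isotropically, so a
    small component count discards most of the mutation directions).
    max_train optionally subsamples the training set (GP fitting is cubic).
    """
    if pca_dim < 1:
        raise ValueError("pca_dim must be >= 1")
    if encoder is None:
        from .encoders import OneHotEncoder

        encoder = OneHotEncoder()
    table = preprocess(data, "median_impute")
    if max_train is not None and len(table) > max_train:
        rng = np.random.default_rng(seed)
        table = table.iloc[rng.choice(len(table), size=max_train, replace=False)]
    X = encoder.encode_batch(data.space, table["sequence"].tolist())
    y = table["y"].to_numpy()
    d = min(pca_dim, X.shape[0], X.shape[1])
    pca = PCA(n_components=d, random_state=seed)
    Xr = pca.fit_transform(X)
    kernel = ConstantKernel(1.0) * RBF(length_scale=np.sqrt(Xr.shape[1])) + WhiteKernel(
        noise_level=0.1
    )
    gpr = GaussianProcessRegressor(
        kernel=kernel, normalize_y=True, random_state=seed, n_restarts_optimizer=0
    )
    gpr.fit(Xr, y)
    return GPModel(data.space, encoder, pca, gpr)


def predict(model, v: SequenceVariant | str) -> AffinityPrediction:
    return model.predict(v)


@dataclass
class ModelEvalReport:
    """Hold-out regression report: Spearman, overall MAE, MAE by distance."""

    spearman: float
    mae_overall: float
    mae_by_distance: pd.DataFrame  # columns: distance, mae, sem, n

    def to_json_dict(self) -> dict:
        return {
            "spearman": self.spearman,
            "mae_overall": self.mae_overall,
            "mae_by_distance": self.mae_by_distance.to_dict(orient="records"),
        }


def evaluate(
    model, test: AffinityDataset, reference: SequenceVariant | str
) -> ModelEvalReport:
    """Spearman and distance-binned MAE of predictions vs averaged targets."""
    y = test.averaged()
    keep = ~np.isnan(y)
    if not keep.any():
        raise DatasetError("no evaluable records (all targets missing)")
    seqs = [s for s, k in zip(test.sequences, keep) if k]
    y = y[keep]
    mu, _ = model.predict_batch(seqs)
    rho = float(stats.spearmanr(mu, y).statistic)
    err = np.abs(mu - y)
    ref = reference.residues if isinstance(reference, SequenceVariant) else reference
    dist = np.array([hamming_distance(s, ref) for s in seqs])
    rows = []
    for d in sorted(set(dist.tolist())):
        e = err[dist == d]
        rows.append(
            {
                "distance": d,
                "mae": float(e.mean()),
                "sem": float(e.std(ddof=1) / np.sqrt(len(e))) if len(e) > 1 else 0.0,
                "n": int(len(e)),
            }
        )
    return ModelEvalReport(rho, float(err.mean()), pd.DataFrame(rows))


def save_model(model, path: str | Path, config: dict | None = None) -> None:
    """Serialize a fitted model with its config/seed metadata."""
    joblib.dump({"format_version": 1, "model": model, "config": config or {}}, path)


def load_model(path: str | Path):
    payload = joblib.load(path)
    return payload["model"]
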