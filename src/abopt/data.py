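"""The replicate affinity-assay table shared by the simulator and the models.

Measurements are log-scale binding values (lower = stronger binding).  A
missing replicate means the assay fell beyond the limit of detection and the
variant is, for that replicate, a poor binder.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .seq import DesignSpace, SequenceVariant


class DatasetError(ValueError):
    pass


@dataclass
class AffinityDataset:
    """Unique sequences with replicate log-affinity measurements.

    ``measurements`` is an (n_records, n_replicates) float array with NaN
    marking censored (missing) assays.  Records are keyed by sequence.
    """

    space: DesignSpace
    sequences: list[str]
    measurements: np.ndarray
    ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.measurements = np.asarray(self.measurements, dtype=float)
        if self.measurements.ndim != 2 or self.measurements.shape[0] != len(self.sequences):
            raise DatasetError("measurements must be (n_records, n_replicates)")
        if len(set(self.sequences)) != len(self.sequences):
            raise DatasetError("duplicate sequences in dataset")
        if self.ids is None:
            self.ids = [f"v{i}" for i in range(len(self.sequences))]

    def __len__(self) -> int:
        return len(self.sequences)

    @property
    def n_replicates(self) -> int:
        return self.measurements.shape[1]

    def averaged(self) -> np.ndarray:
        """Per-record mean over non-missing replicates (NaN if all missing)."""
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(self.measurements, axis=1)

    def variants(self) -> list[SequenceVariant]:
        return [SequenceVariant(self.space, s) for s in self.sequences]

    def average_for(self, sequence: str | SequenceVariant) -> float:
        s = sequence.residues if isinstance(sequence, SequenceVariant) else sequence
        try:
            i = self.sequences.index(s)
        except ValueError:
            raise DatasetError("sequence not present in dataset") from None
        avg = self.averaged()[i]
        if np.isnan(avg):
            raise DatasetError("sequence has no non-missing measurement")
        return float(avg)

    def subset(self, indices: np.ndarray | list[int]) -> "AffinityDataset":
        idx = list(indices)
        return AffinityDataset(
            self.space,
            [self.sequences[i] for i in idx],
            self.measurements[idx],
            ids=[self.ids[i] for i in idx],
        )

    # -- TSV dialect: id, sequence, rep1..repN with empty cells for missing --

    def to_frame(self) -> pd.DataFrame:
        cols = {f"rep{j + 1}": self.measurements[:, j] for j in range(self.n_replicates)}
        return pd.DataFrame({"id": self.ids, "sequence": self.sequences, **cols})

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, space: DesignSpace) -> "AffinityDataset":
        rep_cols = [c for c in df.columns if c.startswith("rep")]
        if not rep_cols:
            raise DatasetError("no replicate columns (rep1..repN) found")
        return cls(
            space,
            df["sequence"].tolist(),
            df[rep_cols].to_numpy(dtype=float),
            ids=df["id"].astype(str).tolist() if "id" in df.columns else None,
        )

    @classmethod
    def from_tsv(cls, path: str | Path, space: DesignSpace) -> "AffinityDataset":
        return cls.from_frame(pd.read_csv(path, sep="\t"), space)
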