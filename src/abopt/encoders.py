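"""Exchangeable fixed-dimension sequence encoders for the affinity models.

Three lightweight encoders ship by default — one-hot, hashed 3-mer
composition, and per-residue physico-chemical descriptors.  A learned
(e.g. transformer-embedding) encoder can be plugged in by subclassing
:class:`SequenceEncoder`; the model layer treats all encoders uniformly.
"""

from __future__ import annotations

import numpy as np

from .seq import AMINO_ACIDS, DesignSpace, SequenceVariant

# index of each canonical residue, used to vectorize string -> code conversion
_CODE = np.full(128, -1, dtype=np.int64)
for _i, _a in enumerate(AMINO_ACIDS):
    _CODE[ord(_a)] = _i

# per-residue physico-chemical descriptors (literature scales):
# Kyte-Doolittle hydropathy, net charge at neutral pH, van der Waals volume
# (A^3), Grantham polarity, aromaticity flag, Hopp-Woods hydrophilicity,
# Bhaskaran-Ponnuswamy flexibility, Zimmerman bulkiness, molar refractivity,
# free amino-acid isoelectric point, Chou-Fasman helix and sheet propensity
_PHYSCHEM = {
    "A": (1.8, 0.0, 88.6, 8.1, 0.0, -0.5, 0.357, 11.50, 4.34, 6.00, 1.42, 0.83),
    "C": (2.5, 0.0, 108.5, 5.5, 0.0, -1.0, 0.346, 13.46, 35.77, 5.07, 0.70, 1.19),
    "D": (-3.5, -1.0, 111.1, 13.0, 0.0, 3.0, 0.511, 11.68, 12.00, 2.77, 1.01, 0.54),
    "E": (-3.5, -1.0, 138.4, 12.3, 0.0, 3.0, 0.497, 13.57, 17.26, 3.22, 1.51, 0.37),
    "F": (2.8, 0.0, 189.9, 5.2, 1.0, -2.5, 0.314, 19.80, 29.40, 5.48, 1.13, 1.38),
    "G": (-0.4, 0.0, 60.1, 9.0, 0.0, 0.0, 0.544, 3.40, 0.00, 5.97, 0.57, 0.75),
    "H": (-3.2, 0.1, 153.2, 10.4, 1.0, -0.5, 0.323, 13.69, 21.81, 7.59, 1.00, 0.87),
    "I": (4.5, 0.0, 166.7, 5.2, 0.0, -1.8, 0.462, 21.40, 19.06, 6.02, 1.08, 1.60),
    "K": (-3.9, 1.0, 168.6, 11.3, 0.0, 3.0, 0.466, 15.71, 21.29, 9.74, 1.16, 0.74),
    "L": (3.8, 0.0, 166.7, 4.9, 0.0, -1.8, 0.365, 21.40, 18.78, 5.98, 1.21, 1.30),
    "M": (1.9, 0.0, 162.9, 5.7, 0.0, -1.3, 0.295, 16.25, 21.64, 5.74, 1.45, 1.05),
    "N": (-3.5, 0.0, 114.1, 11.6, 0.0, 0.2, 0.463, 12.82, 13.28, 5.41, 0.67, 0.89),
    "P": (-1.6, 0.0, 112.7, 8.0, 0.0, 0.0, 0.509, 17.43, 10.93, 6.30, 0.57, 0.55),
    "Q": (-3.5, 0.0, 143.8, 10.5, 0.0, 0.2, 0.493, 14.45, 17.56, 5.65, 1.11, 1.10),
    "R": (-4.5, 1.0, 173.4, 10.5, 0.0, 3.0, 0.529, 14.28, 26.66, 10.76, 0.98, 0.93),
    "S": (-0.8, 0.0, 89.0, 9.2, 0.0, 0.3, 0.507, 9.47, 6.35, 5.68, 0.77, 0.75),
    "T": (-0.7, 0.0, 116.1, 8.6, 0.0, -0.4, 0.444, 15.77, 11.01, 5.60, 0.83, 1.19),
    "V": (4.2, 0.0, 140.0, 5.9, 0.0, -1.5, 0.386, 21.57, 13.92, 5.96, 1.06, 1.70),
    "W": (-0.9, 0.0, 227.8, 5.4, 1.0, -3.4, 0.305, 21.67, 42.53, 5.89, 1.08, 1.37),
    "Y": (-1.3, 0.0, 193.6, 6.2, 1.0, -2.3, 0.420, 18.03, 31.53, 5.66, 0.69, 1.47),
}
_PHYSCHEM_MAT = np.array([_PHYSCHEM[a] for a in AMINO_ACIDS])
# standardize descriptor columns so no single scale dominates linear fits
_PHYSCHEM_MAT = (_PHYSCHEM_MAT - _PHYSCHEM_MAT.mean(axis=0)) / _PHYSCHEM_MAT.std(axis=0)


def code_matrix(seqs: list[str]) -> np.ndarray:
    """(n, L) int codes (index into the canonical alphabet) for equal-length seqs."""
    if not seqs:
        return np.empty((0, 0), dtype=np.int64)
    arr = np.frombuffer("".join(seqs).encode("ascii"), dtype=np.uint8)
    codes = _CODE[arr].reshape(len(seqs), len(seqs[0]))
    if (codes < 0).any():
        raise ValueError("sequence contains non-canonical residues")
    return codes


def _as_strings(seqs) -> list[str]:
    return [s.residues if isinstance(s, SequenceVariant) else s for s in seqs]


class SequenceEncoder:
    """Deterministic map from sequences of a design space to fixed vectors."""

    name: str = "base"

    def dim(self, space: DesignSpace) -> int:
        raise NotImplementedError

    def encode_batch(self, space: DesignSpace, seqs) -> np.ndarray:
        raise NotImplementedError

    def encode(self, space: DesignSpace, seq) -> np.ndarray:
        return self.encode_batch(space, [seq])[0]


class OneHotEncoder(SequenceEncoder):
    """Full-length one-hot: dimension L x 20, exactly L ones per sequence."""

    name = "onehot"

    def dim(self, space: DesignSpace) -> int:
        return space.length * len(AMINO_ACIDS)

    def encode_batch(self, space: DesignSpace, seqs) -> np.ndarray:
        seqs = _as_strings(seqs)
        n, L, A = len(seqs), space.length, len(AMINO_ACIDS)
        if n == 0:
            return np.empty((0, L * A))
        codes = code_matrix(seqs)
        out = np.zeros((n, L * A))
        cols = np.arange(L) * A + codes
        out[np.arange(n)[:, None], cols] = 1.0
        return out


class KmerEncoder(SequenceEncoder):
    """Hashed k-mer (default k=3) composition counts in a fixed dimension."""

    name = "kmer3"

    def __init__(self, k: int = 3, n_features: int = 2048):
        self.k = k
        self.n_features = n_features
        self.name = f"kmer{k}"

    def dim(self, space: DesignSpace) -> int:
        return self.n_features

    def encode_batch(self, space: DesignSpace, seqs) -> np.ndarray:
        seqs = _as_strings(seqs)
        n = len(seqs)
        if n == 0:
            return np.empty((0, self.n_features))
        codes = code_matrix(seqs)
        L = codes.shape[1]
        A = len(AMINO_ACIDS)
        kmer_ids = np.zeros((n, L - self.k + 1), dtype=np.int64)
        for j in range(self.k):
            kmer_ids = kmer_ids * A + codes[:, j : L - self.k + 1 + j]
        # fixed multiplicative hash into the feature range (deterministic)
        buckets = (kmer_ids * np.int64(2654435761)) % self.n_features
        out = np.zeros((n, self.n_features))
        np.add.at(out, (np.repeat(np.arange(n), buckets.shape[1]), buckets.ravel()), 1.0)
        return out


class PhyschemEncoder(SequenceEncoder):
    """Per-residue physico-chemical descriptors, concatenated along the chain."""

    name = "physchem"

    def dim(self, space: DesignSpace) -> int:
        return space.length * _PHYSCHEM_MAT.shape[1]

    def encode_batch(self, space: DesignSpace, seqs) -> np.ndarray:
        seqs = _as_strings(seqs)
        if not seqs:
            return np.empty((0, self.dim(space)))
        codes = code_matrix(seqs)
        return _PHYSCHEM_MAT[codes].reshape(len(seqs), -1)


def default_encoders() -> list[SequenceEncoder]:
    return [OneHotEncoder(), KmerEncoder(), PhyschemEncoder()]
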