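"""Sequence representation, mutation operators and standard-format I/O.

Sequences live in a :class:`DesignSpace`: a fixed variable-domain template
(e.g. an scFv heavy- or light-chain) together with the set of positions that
are allowed to vary (the CDR positions).  All positions are 0-based
internally; user-facing reports convert to 1-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: The 20 canonical amino acids, alphabetically ordered by one-letter code.
AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"


class SequenceError(ValueError):
    """Raised for malformed sequences, spaces or records."""


@dataclass(frozen=True)
class DesignSpace:
    """A template sequence plus the designable (CDR) positions.

    Parameters
    ----------
    chain_id:
        Free-text label for the chain ("heavy", "light", ...).
    template:
        Full-length amino-acid sequence of the candidate chain.
    designable_positions:
        0-based indices at which variants may differ from the template.
    alphabet:
        Ordered residue alphabet; defaults to the 20 canonical amino acids.
        Smaller alphabets (subsets of the canonical 20) are permitted for
        reduced/toy design problems.
    """

    chain_id: str
    template: str
    designable_positions: tuple[int, ...]
    alphabet: str = AMINO_ACIDS

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "designable_positions", tuple(sorted(set(self.designable_positions)))
        )
        if len(set(self.alphabet)) != len(self.alphabet) or not self.alphabet:
            raise SequenceError("alphabet letters must be distinct and non-empty")
        bad = set(self.alphabet) - set(AMINO_ACIDS)
        if bad:
            raise SequenceError(f"non-canonical letters in alphabet: {sorted(bad)}")
        bad = set(self.template) - set(self.alphabet)
        if bad:
            raise SequenceError(f"template contains letters outside alphabet: {sorted(bad)}")
        for p in self.designable_positions:
            if not 0 <= p < len(self.template):
                raise SequenceError(f"designable position {p} outside template of length {len(self.template)}")

    @property
    def length(self) -> int:
        return len(self.template)

    def variant(self, residues: str) -> "SequenceVariant":
        """Construct a validated variant of this space."""
        v = SequenceVariant(self, residues)
        v.validate()
        return v

    @property
    def template_variant(self) -> "SequenceVariant":
        return SequenceVariant(self, self.template)


@dataclass(frozen=True)
class SequenceVariant:
    """An amino-acid sequence constrained to a design space.

    Use :meth:`DesignSpace.variant` to construct with validation; the bare
    constructor skips checks (internal fast path for samplers).
    """

    space: DesignSpace
    residues: str

    def validate(self) -> None:
        if len(self.residues) != self.space.length:
            raise SequenceError(
                f"variant length {len(self.residues)} != template length {self.space.length}"
            )
        designable = set(self.space.designable_positions)
        for i, (a, b) in enumerate(zip(self.residues, self.space.template)):
            if a != b and i not in designable:
                raise SequenceError(f"variant differs from template at non-designable position {i}")
            if a not in self.space.alphabet:
                raise SequenceError(f"letter {a!r} at position {i} outside alphabet")

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.residues


@dataclass(frozen=True)
class MutationConfig:
    """How many substitutions a random mutant carries.

    The substitution count m is drawn from Poisson(expected_k) truncated to
    [1, n_designable], so every mutant differs from its seed.
    """

    expected_k: float
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not self.expected_k > 0:
            raise ValueError("expected_k must be positive")


def hamming_distance(a: SequenceVariant | str, b: SequenceVariant | str) -> int:
    """Number of positions at which two equal-length sequences differ."""
    sa = a.residues if isinstance(a, SequenceVariant) else a
    sb = b.residues if isinstance(b, SequenceVariant) else b
    if len(sa) != len(sb):
        raise SequenceError(f"length mismatch: {len(sa)} vs {len(sb)}")
    return sum(x != y for x, y in zip(sa, sb))


def k1_neighbors(v: SequenceVariant) -> list[SequenceVariant]:
    """All variants at Hamming distance exactly 1 from ``v``.

    Ordered position-major, then by alphabet order; the current residue at
    each position is skipped, so the result has n_designable * (|alphabet|-1)
    members and no duplicates.
    """
    out: list[SequenceVariant] = []
    s = v.residues
    for p in v.space.designable_positions:
        cur = s[p]
        for a in v.space.alphabet:
            if a != cur:
                out.append(SequenceVariant(v.space, s[:p] + a + s[p + 1 :]))
    return out


from functools import lru_cache


@lru_cache(maxsize=256)
def _truncated_poisson_pmf(lam: float, upper: int) -> np.ndarray:
    """pmf of Poisson(lam) restricted to {1, ..., upper}, renormalized."""
    ks = np.arange(1, upper + 1)
    # log pmf avoids overflow for large lam
    logp = ks * np.log(lam) - lam - np.array([np.sum(np.log(np.arange(1, k + 1))) for k in ks])
    p = np.exp(logp - logp.max())
    return p / p.sum()


def truncated_poisson_mean(lam: float, upper: int) -> float:
    """Analytic mean of the truncated substitution-count distribution."""
    p = _truncated_poisson_pmf(lam, upper)
    return float(np.arange(1, upper + 1) @ p)


def mutate_string(
    s: str, space: DesignSpace, expected_k: float, rng: np.random.Generator
) -> str:
    """String-level random mutant (fast path used by the samplers)."""
    designable = space.designable_positions
    if not designable:
        raise SequenceError("design space has no designable positions")
    if expected_k == 0:
        return s
    if expected_k > len(designable):
        raise ValueError("expected_k exceeds the number of designable positions")
    pmf = _truncated_poisson_pmf(expected_k, len(designable))
    m = int(rng.choice(np.arange(1, len(designable) + 1), p=pmf))
    positions = rng.choice(len(designable), size=m, replace=False)
    chars = list(s)
    for idx in positions:
        p = designable[int(idx)]
        choices = [a for a in space.alphabet if a != chars[p]]
        chars[p] = choices[int(rng.integers(len(choices)))]
    return "".join(chars)


def random_mutant(
    v: SequenceVariant,
    cfg: MutationConfig | float,
    rng: np.random.Generator | None = None,
) -> SequenceVariant:
    """A random mutant of ``v`` with on average ``expected_k`` substitutions.

    Substituted positions are drawn uniformly without replacement among the
    designable positions; each substituted residue is drawn uniformly from
    the letters different from the current one.
    """
    if isinstance(cfg, MutationConfig):
        expected_k = cfg.expected_k
        if rng is None:
            rng = np.random.default_rng(cfg.rng_seed)
    else:
        expected_k = float(cfg)
        if rng is None:
            raise ValueError("rng required when cfg is a bare expected_k")
    return SequenceVariant(v.space, mutate_string(v.residues, v.space, expected_k, rng))


# ---------------------------------------------------------------------------
# File formats


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read (id, sequence) records; validates residues are amino acids."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        bad = set(seq) - set(AMINO_ACIDS)
        if bad:
            raise SequenceError(
                f"record {rec.id!r} contains non-amino-acid characters: {sorted(bad)}"
            )
        records.append((rec.id, seq))
    return records


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path, width: int = 60) -> None:
    recs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(recs)


def read_sequence_table(path: str | Path) -> pd.DataFrame:
    """Read the TSV sequence-table dialect: columns id, sequence, extras."""
    df = pd.read_csv(path, sep="\t", dtype={"id": str, "sequence": str})
    for col in ("id", "sequence"):
        if col not in df.columns:
            raise SequenceError(f"sequence table missing required column {col!r}")
    return df


def write_sequence_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)
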