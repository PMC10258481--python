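"""Developability descriptors: isoelectric point and GRAVY hydrophobicity.

Each designed chain is concatenated with its fixed partner chain (heavy
first) before computing descriptors, so scores describe the full scFv.  The
isoelectric point uses the Henderson-Hasselbalch per-group model with a
Bjellqvist-style pK table; cysteines are treated as free (no disulfide
correction).  Hydrophobicity is the Kyte-Doolittle grand average (GRAVY).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .seq import AMINO_ACIDS, SequenceVariant


class BiophysError(ValueError):
    pass


@dataclass(frozen=True)
class PKTable:
    """pK values for the termini and ionizable side chains.

    positive groups gain a proton below their pK (N-terminus, H, K, R);
    negative groups lose one above it (C-terminus, D, E, C, Y).
    """

    positive: dict = field(
        default_factory=lambda: {"Nterm": 7.5, "H": 5.98, "K": 10.0, "R": 12.0}
    )
    negative: dict = field(
        default_factory=lambda: {"Cterm": 3.55, "D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0}
    )

    def __post_init__(self) -> None:
        for pk in list(self.positive.values()) + list(self.negative.values()):
            if not 0 < pk < 14:
                raise BiophysError(f"pK value {pk} outside (0, 14)")


#: Kyte-Doolittle hydropathy index.
KYTE_DOOLITTLE: dict[str, float] = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}


def concat_with_partner(
    design: SequenceVariant | str, partner: str, design_is_heavy: bool
) -> str:
    """Full scFv sequence: heavy chain first, then light chain."""
    if not partner:
        raise BiophysError("partner chain must be non-empty")
    d = design.residues if isinstance(design, SequenceVariant) else design
    return d + partner if design_is_heavy else partner + d


def net_charge(seq: str, pH: float, pk: PKTable | None = None) -> float:
    """Sum of fractional group charges at the given pH.

    Positive groups contribute 1/(1+10^(pH-pK)); negative groups contribute
    -1/(1+10^(pK-pH)).  Strictly decreasing in pH.
    """
    if not seq:
        raise BiophysError("empty sequence")
    pk = pk or PKTable()
    charge = 1.0 / (1.0 + 10 ** (pH - pk.positive["Nterm"]))
    charge -= 1.0 / (1.0 + 10 ** (pk.negative["Cterm"] - pH))
    for a in seq:
        if a in pk.positive:
            charge += 1.0 / (1.0 + 10 ** (pH - pk.positive[a]))
        elif a in pk.negative:
            charge -= 1.0 / (1.0 + 10 ** (pk.negative[a] - pH))
    return charge


def isoelectric_point(
    seq: str, pk: PKTable | None = None, tol: float = 1e-4
) -> float:
    """pH at which the net charge crosses zero, by bisection on [0, 14]."""
    pk = pk or PKTable()
    lo, hi = 0.0, 14.0
    c_lo = net_charge(seq, lo, pk)
    c_hi = net_charge(seq, hi, pk)
    if c_lo < 0 or c_hi > 0:
        raise BiophysError("charge curve does not bracket zero on [0, 14]")
    # bisect to interval convergence; the charge curve can be nearly flat
    # around the root, so a |charge| stop alone would be too loose in pH
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if net_charge(seq, mid, pk) > 0:
            lo = mid
        else:
            hi = mid
    mid = 0.5 * (lo + hi)
    if abs(net_charge(seq, mid, pk)) > tol:
        raise BiophysError("bisection failed to reduce net charge below tolerance")
    return mid


def gravy(seq: str, scale: dict[str, float] | None = None) -> float:
    """Grand average of hydropathy: mean per-residue scale value."""
    if not seq:
        raise BiophysError("empty sequence")
    scale = scale or KYTE_DOOLITTLE
    total = 0.0
    for i, a in enumerate(seq):
        if a not in scale:
            raise BiophysError(f"residue {a!r} at position {i + 1} not in hydropathy scale")
        total += scale[a]
    return total / len(seq)
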