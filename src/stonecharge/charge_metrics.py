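"""Fixed-charge composition metrics and isoelectric-point support.

The central quantities of the analysis are computed here. At normal urine
pH (6-7) the side chains of aspartate (D), glutamate (E), lysine (K) and
arginine (R) carry essentially full unit charges, so a protein's fixed-charge
content is summarised by four residue counts:

* ``total_charge``  = D + E + K + R        (every charged residue counts +1)
* ``net_charge``    = (K + R) - (D + E)    (signed)

and their length-normalised percentages (``value / length * 100``), which
make proteins of very different molecular weight comparable.

Histidine is deliberately absent from the fixed-charge metric: its side
chain (pKa ~6.5) is only fractionally protonated at urine pH. It does
participate, together with cysteine, tyrosine and the chain termini, in the
pH-dependent Henderson-Hasselbalch charge model used for isoelectric-point
classification (``charge_at_pH`` / ``isoelectric_point``).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

from scipy.optimize import bisect

__all__ = [
    "ResidueCounts",
    "ChargeProfile",
    "PKaSet",
    "PKA_TABLES",
    "IonizableGroups",
    "PIClass",
    "count_residues",
    "charge_profile",
    "charge_at_pH",
    "isoelectric_point",
    "classify_pI",
]

#: Residue alphabet accepted throughout the package: the 20 standard amino
#: acids plus ambiguity/rare codes B, Z, X, U, O. Ambiguity codes count
#: toward sequence length but never toward charge.
VALID_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY" "BZXUO")

PI_TOLERANCE = 1e-3  # pH units, bisection stopping tolerance


@dataclass(frozen=True)
class ResidueCounts:
    """Counts of the four fixed-charge residues plus total length."""

    n_D: int
    n_E: int
    n_K: int
    n_R: int
    length: int

    def __post_init__(self) -> None:
        for field in ("n_D", "n_E", "n_K", "n_R", "length"):
            if getattr(self, field) < 0:
                raise ValueError(f"{field} must be >= 0")
        if self.n_D + self.n_E + self.n_K + self.n_R > self.length:
            raise ValueError("charged residue counts exceed sequence length")


@dataclass(frozen=True)
class ChargeProfile:
    """Total/net charge numbers and length-normalised percentages.

    Carries its source :class:`ResidueCounts` so every reported number is
    traceable back to the residue tallies it came from.
    """

    total_charge: int
    net_charge: int
    total_charge_pct: float
    net_charge_pct: float
    counts: ResidueCounts


class PIClass(Enum):
    """Isoelectric-point category; pI < 5 and pI > 9 are the extremes."""

    EXTREME_ANIONIC = "extreme_anionic"
    INTERMEDIATE = "intermediate"
    EXTREME_CATIONIC = "extreme_cationic"


@dataclass(frozen=True)
class PKaSet:
    """Side-chain and terminal pKa values, in pH units."""

    D: float
    E: float
    C: float
    Y: float
    H: float
    K: float
    R: float
    n_term: float
    c_term: float

    def __post_init__(self) -> None:
        for field in ("D", "E", "C", "Y", "H", "K", "R", "n_term", "c_term"):
            v = getattr(self, field)
            if not 0.0 < v < 14.0:
                raise ValueError(f"pKa {field}={v} outside (0, 14)")


#: Named pKa tables selectable through configuration. "emboss" follows the
#: values published with the EMBOSS iep program.
PKA_TABLES: dict[str, PKaSet] = {
    "emboss": PKaSet(
        D=3.9, E=4.1, C=8.5, Y=10.1, H=6.5, K=10.8, R=12.5,
        n_term=8.6, c_term=3.6,
    ),
}

DEFAULT_PKA_SET = PKA_TABLES["emboss"]


@dataclass(frozen=True)
class IonizableGroups:
    """Per-protein counts of every ionizable group in the pH model."""

    n_D: int = 0
    n_E: int = 0
    n_C: int = 0
    n_Y: int = 0
    n_H: int = 0
    n_K: int = 0
    n_R: int = 0
    n_term: int = 0  # free alpha-amino groups (1 for an intact chain)
    c_term: int = 0  # free alpha-carboxyl groups

    @classmethod
    def from_sequence(cls, sequence: str, include_termini: bool = True) -> "IonizableGroups":
        seq = sequence.upper()
        return cls(
            n_D=seq.count("D"),
            n_E=seq.count("E"),
            n_C=seq.count("C"),
            n_Y=seq.count("Y"),
            n_H=seq.count("H"),
            n_K=seq.count("K"),
            n_R=seq.count("R"),
            n_term=1 if include_termini else 0,
            c_term=1 if include_termini else 0,
        )

    @property
    def n_ionizable(self) -> int:
        return (self.n_D + self.n_E + self.n_C + self.n_Y + self.n_H
                + self.n_K + self.n_R + self.n_term + self.c_term)


def count_residues(sequence: str) -> ResidueCounts:
    """Count D, E, K, R residues in a cleaned, uppercase sequence.

    Length includes every residue, nonstandard codes included; only the
    four fixed-charge letters contribute to the charge counts.
    """
    if not sequence:
        raise ValueError("empty sequence: cannot count residues")
    return ResidueCounts(
        n_D=sequence.count("D"),
        n_E=sequence.count("E"),
        n_K=sequence.count("K"),
        n_R=sequence.count("R"),
        length=len(sequence),
    )


def charge_profile(counts: ResidueCounts | str) -> ChargeProfile:
    """Derive total/net charge and percentages from residue counts.

    A raw sequence string is accepted as a convenience and counted first.
    Percentages are kept at full floating precision; rounding to the one
    decimal used in reports happens only at write-out.
    """
    if isinstance(counts, str):
        counts = count_residues(counts)
    if counts.length == 0:
        raise ValueError("zero-length protein: percentages undefined")
    total = counts.n_D + counts.n_E + counts.n_K + counts.n_R
    net = (counts.n_K + counts.n_R) - (counts.n_D + counts.n_E)
    return ChargeProfile(
        total_charge=total,
        net_charge=net,
        total_charge_pct=total / counts.length * 100.0,
        net_charge_pct=net / counts.length * 100.0,
        counts=counts,
    )


def charge_at_pH(groups: IonizableGroups, pH, pkas: PKaSet = DEFAULT_PKA_SET):
    """Henderson-Hasselbalch net charge of a composition at a given pH.

    Basic groups (K, R, H, N-terminus) contribute ``n / (1 + 10^(pH-pKa))``;
    acidic groups (D, E, C, Y, C-terminus) contribute ``-n / (1 + 10^(pKa-pH))``.
    The result is strictly decreasing in pH. ``pH`` may be a scalar or a
    NumPy array (values must lie in [0, 14]).
    """
    import numpy as np

    p = np.asarray(pH, dtype=float)
    if np.any(p < 0.0) or np.any(p > 14.0):
        raise ValueError("pH outside [0, 14]")

    basic = (
        (groups.n_K, pkas.K),
        (groups.n_R, pkas.R),
        (groups.n_H, pkas.H),
        (groups.n_term, pkas.n_term),
    )
    acidic = (
        (groups.n_D, pkas.D),
        (groups.n_E, pkas.E),
        (groups.n_C, pkas.C),
        (groups.n_Y, pkas.Y),
        (groups.c_term, pkas.c_term),
    )
    charge = np.zeros_like(p)
    for n, pka in basic:
        if n:
            charge = charge + n / (1.0 + 10.0 ** (p - pka))
    for n, pka in acidic:
        if n:
            charge = charge - n / (1.0 + 10.0 ** (pka - p))
    return float(charge) if np.isscalar(pH) or np.ndim(pH) == 0 else charge


def isoelectric_point(groups: IonizableGroups, pkas: PKaSet = DEFAULT_PKA_SET) -> float:
    """pH at which the modeled net charge crosses zero, by bisection.

    Deterministic root of :func:`charge_at_pH` on [0, 14] to 0.001 pH.
    Compositions whose charge never changes sign inside the interval
    (only-acidic or only-basic groups) pin to the corresponding boundary.
    """
    if groups.n_ionizable == 0:
        raise ValueError("pI undefined: no ionizable groups")
    f = lambda p: charge_at_pH(groups, p, pkas)
    lo, hi = f(0.0), f(14.0)
    if lo <= 0.0:  # negative across the whole range: acid-only composition
        return 0.0
    if hi >= 0.0:  # positive across the whole range: base-only composition
        return 14.0
    return float(bisect(f, 0.0, 14.0, xtol=PI_TOLERANCE))


def classify_pI(pi_value: float) -> PIClass:
    """Classify a pI into the extreme-anionic / intermediate / extreme-cationic bands.

    Thresholds are strict: exactly 5 or 9 is intermediate.
    """
    if not 0.0 <= pi_value <= 14.0:
        raise ValueError("pI outside [0, 14]")
    if pi_value < 5.0:
        return PIClass.EXTREME_ANIONIC
    if pi_value > 9.0:
        return PIClass.EXTREME_CATIONIC
    return PIClass.INTERMEDIATE
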