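"""Net charge, isoelectric point and amino-acid class composition.

Net charge follows the Henderson–Hasselbalch closed form: at pH ``p`` a
basic group of dissociation constant ``pKa`` contributes
``1 / (1 + 10^(p - pKa))`` positive charge and an acidic group
``-1 / (1 + 10^(pKa - p))``.  Termini are included.  For disulfide-bonded
toxins, Cys residues are engaged in S-S bridges and are excluded from
both the charge and the composition calculations (``exclude_cys``).

The default pKa set is the EMBOSS scale (N-term 8.6, C-term 3.6, K 10.8,
R 12.5, H 6.5, D 3.9, E 4.1, C 8.5, Y 10.1); a Lehninger-style scale is
selectable by name.  The charge curve is strictly decreasing in pH, so
the isoelectric point — the root of the net charge — is unique whenever
both a basic and an acidic group are present.

Composition classes (a residue may belong to several):

tiny {A,C,G,S,T} · small {A,C,D,G,N,P,S,T,V} · aliphatic {A,I,L,V} ·
aromatic {F,H,W,Y} · hydrophobic {A,C,F,G,I,L,M,P,V,W,Y} · hydrophilic
{D,E,H,K,N,Q,R,S,T} · charged {D,E,H,K,R} · cationic {H,K,R} · anionic
{D,E}.  Hydrophobic and hydrophilic partition the alphabet, so their
counts sum to the considered length; charged = cationic + anionic +
histidine is an exact identity of these alphabets.
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "ChargeModel",
    "PKA_SCALES",
    "CompositionReport",
    "AA_CLASSES",
    "net_charge",
    "charge_curve",
    "isoelectric_point",
    "aa_composition",
]

PKA_SCALES: dict[str, dict[str, float]] = {
    # EMBOSS iep values
    "default": {
        "Nterm": 8.6, "Cterm": 3.6,
        "K": 10.8, "R": 12.5, "H": 6.5,
        "D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1,
    },
    # Lehninger textbook values
    "lehninger": {
        "Nterm": 9.69, "Cterm": 2.34,
        "K": 10.5, "R": 12.4, "H": 6.0,
        "D": 3.65, "E": 4.25, "C": 8.3, "Y": 10.07,
    },
}

BASIC_RESIDUES = "KRH"
ACIDIC_RESIDUES = "DECY"  # C and Y deprotonate at high pH


@dataclass
class ChargeModel:
    """Ionizable-group pKa table plus inclusion flags."""

    pka: dict[str, float] = field(
        default_factory=lambda: dict(PKA_SCALES["default"])
    )
    exclude_cys: bool = True
    include_nterm: bool = True
    include_cterm: bool = True

    def __post_init__(self) -> None:
        for key, value in self.pka.items():
            if not 0 < value < 14:
                raise ValueError(f"pKa for {key} out of (0, 14): {value}")

    @classmethod
    def from_scale(cls, name: str, exclude_cys: bool = True) -> "ChargeModel":
        return cls(pka=dict(PKA_SCALES[name]), exclude_cys=exclude_cys)


def _effective_sequence(sequence: str, model: ChargeModel) -> str:
    seq = sequence.replace("C", "") if model.exclude_cys else sequence
    if not seq:
        raise ValueError("sequence empty after Cys exclusion")
    return seq


def net_charge(
    sequence: str, pH: float, model: ChargeModel | None = None
) -> float:
    """Henderson–Hasselbalch net charge of ``sequence`` at ``pH``."""
    model = model or ChargeModel()
    seq = _effective_sequence(sequence, model)
    pka = model.pka
    basics = [pka[r] for r in seq if r in BASIC_RESIDUES]
    if model.include_nterm:
        basics.append(pka["Nterm"])
    acidics = [
        pka[r] for r in seq if r in ACIDIC_RESIDUES and r in pka
    ]
    if model.include_cterm:
        acidics.append(pka["Cterm"])
    pos = sum(1.0 / (1.0 + 10.0 ** (pH - p)) for p in basics)
    neg = sum(1.0 / (1.0 + 10.0 ** (p - pH)) for p in acidics)
    return pos - neg


def charge_curve(
    sequence: str,
    pH_min: float = 0.0,
    pH_max: float = 14.0,
    step: float = 0.5,
    model: ChargeModel | None = None,
) -> list[tuple[float, float]]:
    """Net charge sampled on a pH grid (inclusive of both ends).

    The default grid, 0..14 in 0.5 steps, has 29 points.  The series is
    non-increasing because every Henderson–Hasselbalch term is.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    n = int(np.floor((pH_max - pH_min) / step)) + 1
    grid = [pH_min + i * step for i in range(n)]
    return [(p, net_charge(sequence, p, model)) for p in grid]


def isoelectric_point(
    sequence: str, model: ChargeModel | None = None
) -> float | None:
    """pH at which the net charge vanishes, to 2 decimals.

    Returns ``None`` ("undefined") when the charge does not change sign
    over pH 0..14, i.e. the molecule lacks a basic or an acidic group
    under the model.
    """
    model = model or ChargeModel()
    lo, hi = 1e-9, 14.0 - 1e-9
    f_lo = net_charge(sequence, lo, model)
    f_hi = net_charge(sequence, hi, model)
    if f_lo <= 0 or f_hi >= 0:
        return None
    root = brentq(lambda p: net_charge(sequence, p, model), lo, hi, xtol=1e-8)
    if abs(net_charge(sequence, root, model)) >= 1e-4:
        return None
    return round(float(root), 2)


AA_CLASSES: dict[str, frozenset[str]] = {
    "tiny": frozenset("ACGST"),
    "small": frozenset("ACDGNPSTV"),
    "aliphatic": frozenset("AILV"),
    "aromatic": frozenset("FHWY"),
    "hydrophobic": frozenset("ACFGILMPVWY"),
    "hydrophilic": frozenset("DEHKNQRST"),
    "charged": frozenset("DEHKR"),
    "cationic": frozenset("HKR"),
    "anionic": frozenset("DE"),
}


def _round_half_up(value: float, decimals: int = 1) -> float:
    quantum = decimal.Decimal(1).scaleb(-decimals)
    return float(
        decimal.Decimal(repr(value)).quantize(
            quantum, rounding=decimal.ROUND_HALF_UP
        )
    )


@dataclass
class CompositionReport:
    """Counts and percentages per residue class."""

    considered_length: int
    counts: dict[str, int]
    percentages: dict[str, float]  # half-up, 1 decimal


def aa_composition(sequence: str, exclude_cys: bool = True) -> CompositionReport:
    """Class composition of ``sequence`` after optional Cys exclusion.

    Percentages are ``100 * count / considered_length`` rounded half-up
    to one decimal.
    """
    if not sequence:
        raise ValueError("sequence must be non-empty")
    seq = sequence.replace("C", "") if exclude_cys else sequence
    if not seq:
        raise ValueError("sequence empty after Cys exclusion")
    n = len(seq)
    counts = {
        cls: sum(1 for r in seq if r in alphabet)
        for cls, alphabet in AA_CLASSES.items()
    }
    percentages = {cls: _round_half_up(100.0 * c / n) for cls, c in counts.items()}
    return CompositionReport(n, counts, percentages)
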