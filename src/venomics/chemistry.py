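"""Exact peptide mass and m/z arithmetic.

Monoisotopic masses are the basis of high-resolution precursor matching:
an intact peptide of neutral monoisotopic mass ``M`` observed at charge
``z`` appears at ``m/z = (M + z * m_proton) / z``.  Two chemical details
matter for venom peptides and are handled here explicitly:

* **Disulfide bonds.**  Each formed S-S bridge removes two hydrogen atoms
  from the reduced chain, i.e. −2 × 1.0078250319 Da per bond.  Only the
  *count* of bonds affects the mass; the pairing topology does not and is
  not modelled.
* **Post-translational modifications.**  A small catalog covers the
  modifications relevant to alkylated digests and native mature toxins:
  Cys carbamidomethylation (fixed, digest context only), Met oxidation,
  Asn/Gln deamidation, N-terminal acetylation, and C-terminal amidation.
  Amidation is annotation-driven: it is applied only when a record is
  explicitly annotated, never inferred from the sequence.

C-terminal amidation in secreted peptides is produced by peptidylglycine
alpha-amidating monooxygenase acting on a glycine-extended precursor: the
terminal Gly is consumed and the preceding residue ends in ``-NH2``.  When
an amidation annotation is applied to a sequence that still carries the
glycine donor, :func:`apply_record_modifications` removes the Gly before
applying the −0.984016 Da amide delta.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "WATER_MONO",
    "PROTON_MASS",
    "HYDROGEN_MASS",
    "MONOISOTOPIC",
    "AVERAGE",
    "Modification",
    "MODIFICATION_CATALOG",
    "ToxinRecord",
    "monoisotopic_mass",
    "mz_from_mass",
    "mass_from_mz",
    "apply_record_modifications",
]

#: Monoisotopic mass of H2O (Da); added once per peptide chain.
WATER_MONO = 18.010565
#: Monoisotopic mass of a proton (Da); one per positive charge.
PROTON_MASS = 1.00727646
#: Monoisotopic mass of a hydrogen atom (Da); two lost per disulfide bond.
HYDROGEN_MASS = 1.0078250319

#: Mass removed by one disulfide bond (two hydrogen atoms).
DISULFIDE_DELTA = 2.0 * HYDROGEN_MASS

#: Standard monoisotopic residue (amino-acid minus water) masses, Da.
MONOISOTOPIC: dict[str, float] = {
    "G": 57.021464,
    "A": 71.037114,
    "S": 87.032028,
    "P": 97.052764,
    "V": 99.068414,
    "T": 101.047678,
    "C": 103.009185,
    "L": 113.084064,
    "I": 113.084064,
    "N": 114.042927,
    "D": 115.026943,
    "Q": 128.058578,
    "K": 128.094963,
    "E": 129.042593,
    "M": 131.040485,
    "H": 137.058912,
    "F": 147.068414,
    "R": 156.101111,
    "Y": 163.063329,
    "W": 186.079313,
}

#: Standard average residue masses, Da.  Stored for completeness; the
#: pipeline core operates on monoisotopic masses only.
AVERAGE: dict[str, float] = {
    "G": 57.0519,
    "A": 71.0788,
    "S": 87.0782,
    "P": 97.1167,
    "V": 99.1326,
    "T": 101.1051,
    "C": 103.1388,
    "L": 113.1594,
    "I": 113.1594,
    "N": 114.1038,
    "D": 115.0886,
    "Q": 128.1307,
    "K": 128.1741,
    "E": 129.1155,
    "M": 131.1926,
    "H": 137.1411,
    "F": 147.1766,
    "R": 156.1875,
    "Y": 163.1760,
    "W": 186.2132,
}

STANDARD_RESIDUES = frozenset(MONOISOTOPIC)


@dataclass(frozen=True)
class Modification:
    """A mass modification: ``target`` is a residue code or terminus marker."""

    name: str
    target: str  # residue one-letter code, "N-term" or "C-term"
    delta: float  # signed Da
    mode: str  # "fixed" | "variable" | "annotation"

    def __post_init__(self) -> None:
        if self.target not in ("N-term", "C-term") and not all(
            part in STANDARD_RESIDUES for part in self.target.split("/")
        ):
            raise ValueError(f"invalid modification target {self.target!r}")
        if not (self.delta == self.delta and abs(self.delta) < 1e6):
            raise ValueError("modification delta must be finite")


#: The study's modification set.  Carbamidomethylation applies only to
#: reduced/alkylated digest aliquots, never to native mature masses.
MODIFICATION_CATALOG: dict[str, Modification] = {
    "carbamidomethyl": Modification("carbamidomethyl", "C", 57.021464, "fixed"),
    "oxidation": Modification("oxidation", "M", 15.994915, "variable"),
    "deamidation": Modification("deamidation", "N/Q", 0.984016, "variable"),
    "acetylation": Modification("acetylation", "N-term", 42.010565, "variable"),
    "amidation": Modification("amidation", "C-term", -0.984016, "annotation"),
}


def _validate_sequence(sequence: str) -> None:
    if not sequence:
        raise ValueError("sequence must be non-empty")
    for i, ch in enumerate(sequence):
        if ch not in STANDARD_RESIDUES:
            raise ValueError(
                f"unknown residue {ch!r} at position {i + 1} in sequence"
            )


def monoisotopic_mass(
    sequence: str,
    ss_bonds: int = 0,
    modifications: list[Modification] | None = None,
) -> float:
    """Neutral monoisotopic mass (Da) of a peptide.

    Parameters
    ----------
    sequence
        Residue string over the 20 standard one-letter codes.
    ss_bonds
        Number of formed disulfide bonds; each subtracts two hydrogen
        atoms.  Must satisfy ``2 * ss_bonds <= count of Cys``.
    modifications
        Applied :class:`Modification` instances (or catalog names); their
        deltas are summed onto the chain mass.
    """
    _validate_sequence(sequence)
    if ss_bonds < 0:
        raise ValueError("ss_bonds must be non-negative")
    n_cys = sequence.count("C")
    if 2 * ss_bonds > n_cys:
        raise ValueError(
            f"{ss_bonds} disulfide bonds require {2 * ss_bonds} Cys, "
            f"sequence has {n_cys}"
        )
    mass = sum(MONOISOTOPIC[ch] for ch in sequence) + WATER_MONO
    mass -= ss_bonds * DISULFIDE_DELTA
    for mod in modifications or []:
        if isinstance(mod, str):
            mod = MODIFICATION_CATALOG[mod]
        mass += mod.delta
    return mass


def mz_from_mass(neutral_mass: float, charge: int) -> float:
    """m/z of ``neutral_mass`` carrying ``charge`` protons."""
    if charge < 1:
        raise ValueError(f"charge must be >= 1, got {charge}")
    return (neutral_mass + charge * PROTON_MASS) / charge


def mass_from_mz(mz: float, charge: int) -> float:
    """Neutral mass recovered from an observed (m/z, charge) pair."""
    if charge < 1:
        raise ValueError(f"charge must be >= 1, got {charge}")
    if mz <= PROTON_MASS:
        raise ValueError(f"m/z {mz} is not above the proton mass")
    return charge * (mz - PROTON_MASS)


@dataclass
class ToxinRecord:
    """A mature toxin with the annotations the pipeline consumes.

    ``modifications`` holds catalog names applied to the mature form
    (e.g. ``["acetylation"]``).  ``ss_bonds`` is a count only; pairing is
    not modelled.
    """

    id: str
    mature_sequence: str
    ss_bonds: int = 0
    modifications: list[str] = field(default_factory=list)
    predicted_mature_start: int | None = None
    log_intensity: float | None = None
    rank: int | None = None

    def __post_init__(self) -> None:
        _validate_sequence(self.mature_sequence)
        if 2 * self.ss_bonds > self.mature_sequence.count("C"):
            raise ValueError(
                f"{self.id}: ss_bonds exceed Cys pairing capacity"
            )
        for name in self.modifications:
            if name not in MODIFICATION_CATALOG:
                raise ValueError(f"{self.id}: unknown modification {name!r}")

    @property
    def mass_form_sequence(self) -> str:
        """Sequence of the species whose mass is observed.

        Amidated peptides annotated on their glycine-extended form lose
        the C-terminal Gly donor.
        """
        seq = self.mature_sequence
        if "amidation" in self.modifications and seq.endswith("G"):
            seq = seq[:-1]
        return seq

    def theoretical_mass(self) -> float:
        """Neutral monoisotopic mass of the mature (modified) form."""
        return apply_record_modifications(
            self.mature_sequence, self.ss_bonds, self.modifications
        )


def apply_record_modifications(
    sequence: str, ss_bonds: int, modification_names: list[str]
) -> float:
    """Mass of a mature form given catalog modification names.

    Handles glycine-donor loss for amidation annotations (see module
    docstring); all other modifications contribute their delta directly.
    """
    mods = [MODIFICATION_CATALOG[name] for name in modification_names]
    if any(m.name == "amidation" for m in mods) and sequence.endswith("G"):
        sequence = sequence[:-1]
    return monoisotopic_mass(sequence, ss_bonds, mods)
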