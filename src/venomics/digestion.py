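"""In silico proteolysis with the five-enzyme digestion scheme.

The venom peptide fraction is split into aliquots and each aliquot is
digested with a different protease — trypsin, chymotrypsin, Glu-C, Asp-N
and thermolysin — so that every mature toxin is covered by overlapping
fragments with distinct termini.  Identification-search settings are
mirrored here: up to two missed cleavages and up to one nonspecific
(semi-specific) terminus per peptide.

Cleavage specificities are data, not code: each enzyme is an
:class:`EnzymeRule` naming the cleavage side, target residues, and
residues on the far side of the bond that block cleavage.  Defaults:

========= ======================= ==================
enzyme    rule                    blocked by
========= ======================= ==================
trypsin       after K/R           P following
chymotrypsin  after F/W/Y/L       P following
glu-c         after E and D       —
asp-n         before D            —
thermolysin   before I/L/V/A/M/F  —
========= ======================= ==================

Glu-C cleaves after both Glu and Asp in phosphate buffer (the buffer used
for the Glu-C aliquot); ``enzyme_catalog(glu_c_mode="e_only")`` restricts
it to Glu.  Proline blocking for trypsin/chymotrypsin, and the absence of
blocking for thermolysin, are conventional assumptions — the digestion
protocol names the enzymes but not their formal specificities.

Internal cleavage coordinates are inter-residue positions 0..L; reported
peptide coordinates are 1-based inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .chemistry import monoisotopic_mass

__all__ = [
    "EnzymeRule",
    "DigestPeptide",
    "enzyme_catalog",
    "cleavage_sites",
    "digest",
]

CLEAVE_C = "cleave-C-terminal-of-target"
CLEAVE_N = "cleave-N-terminal-of-target"


@dataclass(frozen=True)
class EnzymeRule:
    """A protease's cleavage specificity."""

    name: str
    side: str  # CLEAVE_C or CLEAVE_N
    targets: frozenset[str]
    blocked_by_next: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.side not in (CLEAVE_C, CLEAVE_N):
            raise ValueError(f"invalid cleavage side {self.side!r}")
        if not self.targets:
            raise ValueError(f"{self.name}: targets must be non-empty")


@dataclass(frozen=True)
class DigestPeptide:
    """A digest product located in its parent (1-based inclusive)."""

    sequence: str
    start: int
    end: int
    missed_cleavages: int
    nonspecific_termini: int
    enzyme: str


def enzyme_catalog(glu_c_mode: str = "phosphate") -> dict[str, EnzymeRule]:
    """The five digestion enzymes with their default specificities.

    ``glu_c_mode``: ``"phosphate"`` (default; cleaves after E and D, the
    broadened specificity in phosphate buffer) or ``"e_only"``.
    """
    if glu_c_mode == "phosphate":
        glu_c_targets = frozenset("ED")
    elif glu_c_mode == "e_only":
        glu_c_targets = frozenset("E")
    else:
        raise ValueError(f"unknown glu_c_mode {glu_c_mode!r}")
    rules = [
        EnzymeRule("trypsin", CLEAVE_C, frozenset("KR"), frozenset("P")),
        EnzymeRule("chymotrypsin", CLEAVE_C, frozenset("FWYL"), frozenset("P")),
        EnzymeRule("glu-c", CLEAVE_C, glu_c_targets),
        EnzymeRule("asp-n", CLEAVE_N, frozenset("D")),
        EnzymeRule("thermolysin", CLEAVE_N, frozenset("ILVAMF")),
    ]
    return {rule.name: rule for rule in rules}


def cleavage_sites(sequence: str, rule: EnzymeRule) -> list[int]:
    """Inter-residue cleavage positions, strictly inside the chain.

    Position ``i`` (1 <= i <= L-1) denotes the bond between residues
    ``i`` and ``i+1`` (1-based).  Termini (0 and L) are implicit and
    never returned.
    """
    if not sequence:
        raise ValueError("sequence must be non-empty")
    sites = []
    for i in range(1, len(sequence)):
        if rule.side == CLEAVE_C:
            target, far = sequence[i - 1], sequence[i]
        else:
            target, far = sequence[i], sequence[i - 1]
        if target in rule.targets and far not in rule.blocked_by_next:
            sites.append(i)
    return sites


def digest(
    sequence: str,
    rule: EnzymeRule,
    max_missed: int = 0,
    max_nonspecific: int = 0,
    min_length: int = 1,
    max_length: int | None = None,
    min_mass: float | None = None,
    max_mass: float | None = None,
) -> set[DigestPeptide]:
    """Enumerate digest products of ``sequence`` under ``rule``.

    Fully specific peptides span at most ``max_missed`` internal cleavage
    sites; with ``max_nonspecific=1`` the expansion additionally yields
    every truncation of a fully specific peptide at exactly one terminus
    (the semi-specific peptides of the identification search).  Length
    and mass windows prune the reported set.
    """
    if not sequence:
        raise ValueError("sequence must be non-empty")
    if max_missed < 0:
        raise ValueError("max_missed must be non-negative")
    if max_nonspecific not in (0, 1):
        raise ValueError("max_nonspecific must be 0 or 1")

    sites = cleavage_sites(sequence, rule)
    boundaries = [0, *sites, len(sequence)]
    site_set = set(sites)

    spans: dict[tuple[int, int], tuple[int, int]] = {}  # (start0,end0)->(missed,semi)

    def add(start0: int, end0: int, semi: int) -> None:
        missed = sum(1 for s in site_set if start0 < s < end0)
        if missed > max_missed:
            return
        key = (start0, end0)
        prev = spans.get(key)
        if prev is None or semi < prev[1]:  # prefer the fully specific reading
            spans[key] = (missed, semi)

    # fully specific: every pair of boundaries spanning <= max_missed sites
    for i in range(len(boundaries) - 1):
        for j in range(i + 1, min(i + max_missed + 2, len(boundaries))):
            start0, end0 = boundaries[i], boundaries[j]
            add(start0, end0, 0)
            if max_nonspecific == 1:
                # truncate exactly one terminus of this specific peptide
                for s in range(start0 + 1, end0):
                    add(start0, s, 0 if s in site_set else 1)
                    add(s, end0, 0 if s in site_set else 1)

    out: set[DigestPeptide] = set()
    for (start0, end0), (missed, semi) in spans.items():
        pep = sequence[start0:end0]
        if len(pep) < min_length:
            continue
        if max_length is not None and len(pep) > max_length:
            continue
        if min_mass is not None or max_mass is not None:
            m = monoisotopic_mass(pep)
            if min_mass is not None and m < min_mass:
                continue
            if max_mass is not None and m > max_mass:
                continue
        out.add(
            DigestPeptide(
                sequence=pep,
                start=start0 + 1,
                end=end0,
                missed_cleavages=missed,
                nonspecific_termini=semi,
                enzyme=rule.name,
            )
        )
    return out
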