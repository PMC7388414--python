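"""Coverage assembly and mature-boundary determination.

Identified digest peptides are mapped back onto their parent (precursor
or mature) sequences.  Three questions are answered per toxin:

* **Coverage** — per-residue depth and, per start position, which
  distinct enzymes produced a peptide beginning there.
* **Mature N-terminus** — the maturation boundary is called where
  peptides from at least ``min_enzymes`` distinct digestion channels
  begin at the same residue.  Independent enzymes sharing an N-terminal
  boundary is strong evidence of a biological (not proteolytic) terminus.
  The native (undigested) aliquot counts as its own channel.
* **Full sequencing** — a mature span counts as fully sequenced only if
  consecutive covering fragments *overlap* by at least one residue.
  Merely abutting fragments cannot exclude an insertion at the junction,
  so they do not qualify.

Coordinates in evidence and reports are 1-based inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "PeptideEvidence",
    "CoverageMap",
    "MaturationComparison",
    "build_coverage",
    "consensus_n_terminus",
    "is_fully_sequenced",
    "compare_maturation",
]

UNDETERMINED = "undetermined"


@dataclass(frozen=True)
class PeptideEvidence:
    """One identified peptide located on its parent sequence."""

    parent_id: str
    start: int
    end: int
    enzyme: str
    spectra_count: int = 1

    def __post_init__(self) -> None:
        if self.start < 1 or self.start > self.end:
            raise ValueError(
                f"{self.parent_id}: invalid span {self.start}-{self.end}"
            )


@dataclass
class CoverageMap:
    """Per-residue coverage of one parent by identified peptides."""

    parent_id: str
    depth: list[int]
    boundary_support: dict[int, set[str]]
    intervals: list[tuple[int, int]] = field(default_factory=list)


def build_coverage(
    evidence: list[PeptideEvidence], parent_sequence: str
) -> CoverageMap:
    """Exact per-residue depth and per-start enzyme support.

    Duplicate evidence rows each contribute to depth; boundary support
    collects *distinct* enzymes per start position.
    """
    length = len(parent_sequence)
    depth = [0] * length
    support: dict[int, set[str]] = {}
    intervals: list[tuple[int, int]] = []
    parent_id = evidence[0].parent_id if evidence else ""
    for ev in evidence:
        if ev.end > length:
            raise ValueError(
                f"evidence {ev.parent_id} {ev.start}-{ev.end} exceeds parent "
                f"length {length}"
            )
        for i in range(ev.start - 1, ev.end):
            depth[i] += 1
        support.setdefault(ev.start, set()).add(ev.enzyme)
        intervals.append((ev.start, ev.end))
    return CoverageMap(parent_id, depth, support, intervals)


def consensus_n_terminus(
    coverage: CoverageMap, min_enzymes: int = 2
) -> int | str:
    """Smallest start supported by >= ``min_enzymes`` distinct enzymes.

    Returns :data:`UNDETERMINED` when no position qualifies.
    """
    candidates = [
        pos
        for pos, enzymes in coverage.boundary_support.items()
        if len(enzymes) >= min_enzymes
    ]
    return min(candidates) if candidates else UNDETERMINED


def is_fully_sequenced(
    coverage: CoverageMap, mature_span: tuple[int, int]
) -> tuple[bool, int | None]:
    """Whether ``mature_span`` is covered by an overlapping fragment chain.

    Returns ``(True, None)`` when every residue of the span is covered
    and consecutive fragments overlap by >= 1 residue.  Otherwise returns
    ``(False, pos)`` where ``pos`` is the first uncovered (gap) or
    unlinked (abutting-only join) position.
    """
    span_start, span_end = mature_span
    if span_start < 1 or span_end > len(coverage.depth) or span_start > span_end:
        raise ValueError(f"mature span {mature_span} outside parent")
    relevant = sorted(
        (s, e) for (s, e) in coverage.intervals if e >= span_start and s <= span_end
    )
    reach = span_start - 1  # rightmost residue connected so far
    for s, e in relevant:
        if s > reach + 1:
            # uncovered gap, or abutting join (s == reach+1 handled below)
            return False, reach + 1
        if s == reach + 1 and reach >= span_start:
            # fragment abuts the chain without overlapping it
            return False, s
        reach = max(reach, e)
        if reach >= span_end:
            return True, None
    return False, reach + 1


@dataclass(frozen=True)
class MaturationComparison:
    """Observed vs predicted mature start of one toxin."""

    toxin_id: str
    predicted_start: int
    observed_start: int
    delta_residues: int
    extension_sequence: str


def compare_maturation(
    predicted_start: int,
    observed_start: int,
    parent_sequence: str,
    toxin_id: str = "",
) -> MaturationComparison:
    """Signed offset between predicted and observed mature starts.

    ``delta_residues = predicted_start - observed_start``; a positive
    delta means the observed mature form is N-terminally *longer* than
    predicted, and ``extension_sequence`` holds those extra residues.
    """
    length = len(parent_sequence)
    for name, pos in (("predicted", predicted_start), ("observed", observed_start)):
        if pos < 1 or pos > length:
            raise ValueError(f"{name} start {pos} outside parent (1..{length})")
    delta = predicted_start - observed_start
    extension = (
        parent_sequence[observed_start - 1 : predicted_start - 1]
        if delta > 0
        else ""
    )
    return MaturationComparison(
        toxin_id, predicted_start, observed_start, delta, extension
    )
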