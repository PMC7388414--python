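"""Native precursor-ion filtering, clustering and mature-toxin validation.

The native (undigested) venom aliquot yields a precursor-ion map: one
(m/z, charge, intensity, RT) feature per detected species.  Validation of
a candidate mature toxin asks whether its theoretical charge ladder —
m/z values at charges +2..+9 by default — matches an observed neutral
mass within a ppm tolerance, *and* whether the consensus sequence is
supported by MS/MS evidence from the digest channels.

Processing steps:

1. :func:`filter_ions` drops features below the intensity threshold
   (default 5.0e5; a feature at exactly the threshold is kept — the
   exclusion rule is strictly-below).
2. :func:`cluster_ions` decharges known-charge features and merges
   redundant observations of the same neutral mass (including different
   charge states) by single-linkage clustering at the ppm tolerance.
   Merging, rather than discarding, redundant ions keeps all signal;
   ``drop_redundant=True`` reproduces the discard convention instead.
3. :func:`match_toxins` compares each toxin's theoretical mass against
   cluster masses; ppm error is computed relative to the theoretical
   mass.  Unknown-charge ions never contribute; charge states outside
   the ladder range (e.g. +1) cannot trigger validation on their own.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .chemistry import PROTON_MASS, mass_from_mz, mz_from_mass
from .chemistry import ToxinRecord

__all__ = [
    "PrecursorIon",
    "IonCluster",
    "ValidationReport",
    "filter_ions",
    "cluster_ions",
    "theoretical_ladder",
    "match_toxins",
    "ppm_error",
]


@dataclass(frozen=True)
class PrecursorIon:
    """One observed precursor feature; ``charge=0`` means unassigned."""

    mz: float
    charge: int
    intensity: float
    rt: float = 0.0
    run_id: str = ""

    def __post_init__(self) -> None:
        if self.charge < 0:
            raise ValueError("charge must be >= 0 (0 = unknown)")
        if self.charge >= 1 and self.mz <= PROTON_MASS:
            raise ValueError(f"m/z {self.mz} not above proton mass")

    @property
    def neutral_mass(self) -> float | None:
        if self.charge < 1:
            return None
        return mass_from_mz(self.mz, self.charge)


@dataclass
class IonCluster:
    """Deisotoped/decharged neutral-mass cluster of redundant ions."""

    neutral_mass: float | None
    members: list[PrecursorIon]
    total_intensity: float
    clustered: bool = True  # False for unknown-charge pass-through singletons

    @property
    def charges(self) -> set[int]:
        return {ion.charge for ion in self.members}


def filter_ions(
    ions: Sequence[PrecursorIon], min_intensity: float = 5.0e5
) -> list[PrecursorIon]:
    """Keep ions with intensity >= ``min_intensity``, preserving order."""
    for i, ion in enumerate(ions):
        if ion.intensity < 0:
            raise ValueError(f"negative intensity in ion row {i}")
    return [ion for ion in ions if ion.intensity >= min_intensity]


def ppm_error(observed: float, theoretical: float) -> float:
    """Signed relative mass error in parts per million."""
    return (observed - theoretical) / theoretical * 1e6


def cluster_ions(
    ions: Sequence[PrecursorIon],
    ppm_tol: float = 10.0,
    drop_redundant: bool = False,
) -> list[IonCluster]:
    """Single-linkage clustering of decharged ions on neutral mass.

    Adjacent masses are linked when they differ by at most ``ppm_tol``
    relative to the lighter mass; linkage is transitive, so a toxin's
    charge states merge into one cluster.  Every input ion appears in
    exactly one cluster.  Unknown-charge ions pass through as singleton
    clusters flagged ``clustered=False`` with no neutral mass.

    With ``drop_redundant=True``, only the most intense member of each
    cluster is retained (the discard convention for redundant m/z
    values); by default members are merged and intensity is summed.
    """
    known = [ion for ion in ions if ion.charge >= 1]
    unknown = [ion for ion in ions if ion.charge < 1]

    clusters: list[IonCluster] = []
    if known:
        known.sort(key=lambda ion: ion.neutral_mass)
        group: list[PrecursorIon] = [known[0]]
        for ion in known[1:]:
            prev_mass = group[-1].neutral_mass
            if ion.neutral_mass - prev_mass <= ppm_tol * 1e-6 * prev_mass:
                group.append(ion)
            else:
                clusters.append(_make_cluster(group, drop_redundant))
                group = [ion]
        clusters.append(_make_cluster(group, drop_redundant))
    for ion in unknown:
        clusters.append(
            IonCluster(None, [ion], ion.intensity, clustered=False)
        )
    return clusters


def _make_cluster(group: list[PrecursorIon], drop_redundant: bool) -> IonCluster:
    if drop_redundant and len(group) > 1:
        best = max(group, key=lambda ion: ion.intensity)
        return IonCluster(best.neutral_mass, [best], best.intensity)
    total = sum(ion.intensity for ion in group)
    if total > 0:
        mass = sum(ion.neutral_mass * ion.intensity for ion in group) / total
    else:
        mass = sum(ion.neutral_mass for ion in group) / len(group)
    return IonCluster(mass, list(group), total)


def theoretical_ladder(
    neutral_mass: float, z_min: int = 2, z_max: int = 9
) -> list[tuple[int, float]]:
    """Theoretical (charge, m/z) pairs for ``z_min``..``z_max``."""
    if z_min < 1 or z_max < z_min:
        raise ValueError(f"invalid charge range {z_min}..{z_max}")
    return [(z, mz_from_mass(neutral_mass, z)) for z in range(z_min, z_max + 1)]


@dataclass
class ValidationReport:
    """Outcome of mass-based validation for one candidate toxin."""

    toxin_id: str
    theoretical_mass: float
    matched_charges: set[int]
    best_ppm_error: float | None
    validated: bool
    msms_supported: bool


def match_toxins(
    toxins: Iterable[ToxinRecord],
    clusters: Sequence[IonCluster],
    ppm_tol: float = 10.0,
    z_min: int = 2,
    z_max: int = 9,
    require_msms: bool = True,
    msms_supported: Mapping[str, bool] | None = None,
) -> list[ValidationReport]:
    """Validate candidate toxins against observed ion clusters.

    A toxin matches a cluster when the absolute ppm error between its
    theoretical neutral mass and the cluster neutral mass is within
    ``ppm_tol`` *and* the cluster contains at least one member in the
    ladder charge range.  ``validated`` additionally requires MS/MS
    support of the consensus sequence (``msms_supported``; toxins absent
    from the mapping count as supported) unless ``require_msms=False``.
    Every toxin yields exactly one report.
    """
    reports = []
    for toxin in toxins:
        theo = toxin.theoretical_mass()
        matched: set[int] = set()
        best: float | None = None
        for cluster in clusters:
            if cluster.neutral_mass is None:
                continue
            err = ppm_error(cluster.neutral_mass, theo)
            if abs(err) > ppm_tol:
                continue
            in_range = {z for z in cluster.charges if z_min <= z <= z_max}
            if not in_range:
                continue
            matched |= in_range
            if best is None or abs(err) < abs(best):
                best = err
        supported = True
        if msms_supported is not None:
            supported = bool(msms_supported.get(toxin.id, True))
        validated = bool(matched) and (supported or not require_msms)
        reports.append(
            ValidationReport(
                toxin_id=toxin.id,
                theoretical_mass=theo,
                matched_charges=matched,
                best_ppm_error=best,
                validated=validated,
                msms_supported=supported,
            )
        )
    return reports
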