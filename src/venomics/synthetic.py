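"""Seeded generator of synthetic toxin precursors, digests and ion maps.

The generator emulates the statistical structure the pipeline assumes,
so every stage is testable without instrument data:

* **Precursor architecture** — each toxin is a signal peptide (~20
  hydrophobic residues), a propeptide ending in an ``...R`` processing
  motif, and a mature region.  Cysteine-rich peptides (CRPs) carry an
  even number of Cys (6–10, forming 3–5 disulfide bonds) and fall in
  the 3–9 kDa window typical of tarantula CRPs; short peptides stay
  below 1.5 kDa.  Mature composition is drawn from a venom-like residue
  distribution with elevated K/R so CRPs tend to be cationic.
* **Digest evidence** — each mature sequence is digested in silico with
  all five enzymes (missed <= 2, semi-specific expansion optional) and
  individual peptides are dropped i.i.d. with ``dropout_prob``,
  emulating incomplete identification.
* **Ion maps** — per toxin, a few charge states (weighted over 2..9)
  are observed with ppm-scale m/z jitter and log-normal intensities
  (some below the 5e5 filter threshold, exercising the filter), plus
  decoy ions constrained to lie at least ``decoy_min_offset_ppm`` from
  every true mass so they are unambiguous negatives.

All randomness flows from one integer seed through
``numpy.random.default_rng``, so runs are reproducible across platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .assembly import PeptideEvidence
from .chemistry import monoisotopic_mass, mz_from_mass
from .digestion import digest, enzyme_catalog
from .validation import PrecursorIon

__all__ = [
    "SyntheticConfig",
    "SyntheticToxin",
    "generate_toxins",
    "simulate_evidence",
    "simulate_ion_map",
]

# Venom-like mature-region residue frequencies: elevated K/R (cationic
# CRPs) and G/S/E; qualitative, not fitted to any dataset.
_RESIDUES = list("ACDEFGHIKLMNPQRSTVWY")
_WEIGHTS = np.array(
    [
        0.06,  # A
        0.00,  # C (placed explicitly)
        0.05,  # D
        0.08,  # E
        0.04,  # F
        0.08,  # G
        0.02,  # H
        0.05,  # I
        0.12,  # K
        0.07,  # L
        0.02,  # M
        0.04,  # N
        0.05,  # P
        0.03,  # Q
        0.09,  # R
        0.07,  # S
        0.05,  # T
        0.05,  # V
        0.02,  # W
        0.01,  # Y
    ]
)
_WEIGHTS = _WEIGHTS / _WEIGHTS.sum()

_HYDROPHOBIC = list("AVLIFMW")


@dataclass
class SyntheticConfig:
    """Study-condition parameters of the generator."""

    seed: int = 0
    n_crp: int = 10
    n_short: int = 7
    cys_count_range: tuple[int, int] = (6, 10)  # even counts inclusive
    crp_length_range: tuple[int, int] = (30, 65)
    short_length_range: tuple[int, int] = (5, 12)
    dropout_prob: float = 0.15
    intensity_meanlog: float = 15.4  # ln scale; median ~ 4.9e6
    intensity_sdlog: float = 1.2
    mz_jitter_ppm: float = 3.0
    charge_range: tuple[int, int] = (2, 9)
    charge_weights: tuple[float, ...] = (0.05, 0.15, 0.25, 0.25, 0.15, 0.08, 0.05, 0.02)
    ions_per_toxin: int = 3
    n_decoy_ions: int = 200
    decoy_min_offset_ppm: float = 50.0
    max_missed: int = 2
    max_nonspecific: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.dropout_prob <= 1.0:
            raise ValueError("dropout_prob must be in [0, 1]")
        lo, hi = self.cys_count_range
        if lo % 2 or hi % 2 or lo > hi or lo < 2:
            raise ValueError("cys_count_range must be even and ordered")
        z_lo, z_hi = self.charge_range
        if len(self.charge_weights) != z_hi - z_lo + 1:
            raise ValueError("charge_weights length must match charge_range")


@dataclass
class SyntheticToxin:
    """Ground truth for one generated toxin."""

    id: str
    precursor: str
    signal_end: int  # last residue of signal peptide (1-based)
    propeptide_end: int  # last residue of propeptide; mature starts next
    mature: str
    ss_bonds: int
    true_mass: float
    is_crp: bool

    @property
    def mature_start(self) -> int:
        return self.propeptide_end + 1


def _sample_mature(
    rng: np.random.Generator, length: int, n_cys: int
) -> str:
    body = rng.choice(_RESIDUES, size=length, p=_WEIGHTS)
    if n_cys:
        positions = rng.choice(length, size=n_cys, replace=False)
        body[positions] = "C"
    return "".join(body)


def _sample_propeptide(rng: np.random.Generator) -> str:
    # acidic-leaning propeptide ending in an R-terminated processing motif
    length = int(rng.integers(8, 16))
    body = "".join(rng.choice(list("EDSAGNQT"), size=length))
    return body + "R"


def _sample_signal(rng: np.random.Generator) -> str:
    length = int(rng.integers(16, 24))
    core = "".join(rng.choice(_HYDROPHOBIC, size=length - 2))
    return "M" + core + "A"


def generate_toxins(config: SyntheticConfig) -> list[SyntheticToxin]:
    """Generate CRP and short-peptide ground truths; reproducible by seed."""
    rng = np.random.default_rng(config.seed)
    toxins: list[SyntheticToxin] = []
    for kind, count in (("crp", config.n_crp), ("short", config.n_short)):
        for i in range(count):
            for _ in range(200):  # resample until the mass window is met
                if kind == "crp":
                    lo, hi = config.crp_length_range
                    length = int(rng.integers(lo, hi + 1))
                    c_lo, c_hi = config.cys_count_range
                    n_cys = int(rng.choice(np.arange(c_lo, c_hi + 1, 2)))
                    mature = _sample_mature(rng, length, n_cys)
                    ss = n_cys // 2
                    mass = monoisotopic_mass(mature, ss)
                    if 3000.0 <= mass <= 9000.0:
                        break
                else:
                    lo, hi = config.short_length_range
                    length = int(rng.integers(lo, hi + 1))
                    mature = _sample_mature(rng, length, 0)
                    ss = 0
                    mass = monoisotopic_mass(mature)
                    if mass < 1500.0:
                        break
            else:
                raise RuntimeError("mass window infeasible for config")
            signal = _sample_signal(rng)
            pro = _sample_propeptide(rng)
            toxins.append(
                SyntheticToxin(
                    id=f"{kind}_{i:03d}",
                    precursor=signal + pro + mature,
                    signal_end=len(signal),
                    propeptide_end=len(signal) + len(pro),
                    mature=mature,
                    ss_bonds=ss,
                    true_mass=mass,
                    is_crp=(kind == "crp"),
                )
            )
    return toxins


def simulate_evidence(
    toxins: list[SyntheticToxin], config: SyntheticConfig
) -> list[PeptideEvidence]:
    """Digest every mature sequence with all five enzymes, with dropout.

    Evidence coordinates are on the *precursor*, so boundary consensus
    over the simulated table recovers the planted mature start.
    """
    rng = np.random.default_rng(config.seed + 1)
    catalog = enzyme_catalog()
    evidence: list[PeptideEvidence] = []
    for toxin in toxins:
        offset = toxin.propeptide_end  # mature position 1 -> precursor offset+1
        for rule in catalog.values():
            peptides = digest(
                toxin.mature,
                rule,
                max_missed=config.max_missed,
                max_nonspecific=config.max_nonspecific,
            )
            for pep in sorted(peptides, key=lambda p: (p.start, p.end)):
                if rng.random() < config.dropout_prob:
                    continue
                evidence.append(
                    PeptideEvidence(
                        parent_id=toxin.id,
                        start=offset + pep.start,
                        end=offset + pep.end,
                        enzyme=rule.name,
                        spectra_count=int(rng.integers(1, 6)),
                    )
                )
    return evidence


def simulate_ion_map(
    toxins: list[SyntheticToxin], config: SyntheticConfig
) -> list[PrecursorIon]:
    """Precursor-ion features for every toxin plus decoy ions."""
    rng = np.random.default_rng(config.seed + 2)
    z_lo, z_hi = config.charge_range
    charges = np.arange(z_lo, z_hi + 1)
    weights = np.asarray(config.charge_weights, dtype=float)
    weights = weights / weights.sum()
    ions: list[PrecursorIon] = []
    true_masses = np.array([t.true_mass for t in toxins])
    for toxin in toxins:
        observed = rng.choice(charges, size=config.ions_per_toxin, p=weights)
        for z in observed:
            mz = mz_from_mass(toxin.true_mass, int(z))
            jitter = rng.uniform(-config.mz_jitter_ppm, config.mz_jitter_ppm)
            mz *= 1.0 + jitter * 1e-6
            intensity = float(
                np.exp(rng.normal(config.intensity_meanlog, config.intensity_sdlog))
            )
            ions.append(
                PrecursorIon(
                    mz=mz,
                    charge=int(z),
                    intensity=intensity,
                    rt=float(rng.uniform(5.0, 70.0)),
                    run_id="sim",
                )
            )
    # decoys: masses kept >= decoy_min_offset_ppm away from every truth
    n = 0
    while n < config.n_decoy_ions:
        mass = float(rng.uniform(500.0, 9000.0))
        if len(true_masses) and np.min(
            np.abs(mass - true_masses) / true_masses
        ) * 1e6 < config.decoy_min_offset_ppm:
            continue
        z = int(rng.choice(charges, p=weights))
        ions.append(
            PrecursorIon(
                mz=mz_from_mass(mass, z),
                charge=z,
                intensity=float(
                    np.exp(rng.normal(config.intensity_meanlog, config.intensity_sdlog))
                ),
                rt=float(rng.uniform(5.0, 70.0)),
                run_id="sim",
            )
        )
        n += 1
    return ions
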