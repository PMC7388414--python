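"""File formats, configuration and the umbrella pipeline runner.

All tabular interchange is TSV (UTF-8, header row, ``#`` comments);
sequences travel as FASTA.  The pipeline defaults equal the published
identification settings: 10 ppm precursor tolerance, charge ladder
+2..+9, intensity threshold 5.0e5, at most two missed cleavages and one
nonspecific terminus, consensus over >= 2 enzymes.

:func:`run_pipeline` chains the stages —
filter → cluster → coverage → consensus → validate → physchem → quant →
screen — skipping stages whose inputs are absent, and writes one TSV per
stage plus a manifest (config echo + hash, package version, row counts).
Outputs are deterministic: identical config and inputs give byte-identical
files.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO

from . import __version__
from .assembly import (
    PeptideEvidence,
    build_coverage,
    compare_maturation,
    consensus_n_terminus,
    is_fully_sequenced,
)
from .chemistry import ToxinRecord
from .physchem import ChargeModel, aa_composition, isoelectric_point, net_charge
from .quantification import quantify
from .screening import screen_table
from .validation import PrecursorIon, cluster_ions, filter_ions, match_toxins

__all__ = [
    "PipelineConfig",
    "read_fasta",
    "read_table",
    "write_table",
    "read_ions",
    "read_evidence",
    "run_pipeline",
]


@dataclass
class PipelineConfig:
    """Pipeline settings; defaults are the published search settings."""

    tolerance_ppm: float = 10.0
    z_min: int = 2
    z_max: int = 9
    min_intensity: float = 5.0e5
    max_missed: int = 2
    max_nonspecific: int = 1
    min_enzymes: int = 2
    pka_scale: str = "default"
    exclude_cys: bool = True
    physiological_ph: float = 7.4
    amp_threshold: float = 0.8
    acp_threshold: float = 0.5
    min_peptides: int = 3
    min_replicates: int = 2
    drop_redundant: bool = False
    require_msms: bool = True
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls().to_dict())
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def read_fasta(path: str | Path) -> dict[str, str]:
    """Order-preserving FASTA reader.

    Sequences are upper-cased with ``*`` and whitespace stripped;
    duplicate ids are an error.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.strip():
                if not line.startswith(">"):
                    raise ValueError(
                        f"{path}: malformed FASTA, line {lineno} does not "
                        "start a record"
                    )
                break
    records: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in records:
            raise ValueError(f"{path}: duplicate FASTA id {record.id!r}")
        seq = str(record.seq).upper().replace("*", "").replace(" ", "")
        records[record.id] = seq
    return records


def read_table(path: str | Path, schema: dict[str, type]) -> pd.DataFrame:
    """Typed TSV reader; blanks parse as missing.

    ``schema`` maps required column names to ``str``, ``int`` or
    ``float``.  A missing column or a non-numeric cell in a numeric
    column is an error naming the column (and row).
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in schema if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    for col, typ in schema.items():
        if typ is str:
            df[col] = df[col].fillna("")
            continue
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[converted.isna() & df[col].notna()]
        if len(bad):
            raise ValueError(
                f"{path}: non-numeric value in column {col!r}, "
                f"row {int(bad[0]) + 2}"  # +2: header + 1-based
            )
        df[col] = converted if typ is float else converted.astype("Int64")
    return df


def write_table(df: pd.DataFrame, path: str | Path, config_hash: str | None = None) -> None:
    """Write a TSV, optionally stamped with the run's config hash."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if config_hash:
            fh.write(f"# config_hash: {config_hash}\n")
        df.to_csv(fh, sep="\t", index=False)


ION_SCHEMA = {"run_id": str, "mz": float, "charge": int, "intensity": float, "rt": float}
EVIDENCE_SCHEMA = {
    "parent_id": str,
    "start": int,
    "end": int,
    "enzyme": str,
    "spectra_count": int,
}


def read_ions(path: str | Path) -> list[PrecursorIon]:
    df = read_table(path, ION_SCHEMA)
    return [
        PrecursorIon(
            mz=float(r.mz),
            charge=int(r.charge),
            intensity=float(r.intensity),
            rt=float(r.rt),
            run_id=str(r.run_id),
        )
        for r in df.itertuples()
    ]


def read_evidence(path: str | Path) -> list[PeptideEvidence]:
    df = read_table(path, EVIDENCE_SCHEMA)
    return [
        PeptideEvidence(
            parent_id=str(r.parent_id),
            start=int(r.start),
            end=int(r.end),
            enzyme=str(r.enzyme),
            spectra_count=int(r.spectra_count),
        )
        for r in df.itertuples()
    ]


@dataclass
class PipelineInputs:
    """In-memory inputs for :func:`run_pipeline`; optional ones may be None."""

    toxins: list[ToxinRecord]
    ions: list[PrecursorIon]
    evidence: list[PeptideEvidence] | None = None
    parents: dict[str, str] | None = None  # parent_id -> sequence
    mature_spans: dict[str, tuple[int, int]] | None = None
    predicted_starts: dict[str, int] | None = None
    quant: pd.DataFrame | None = None
    scores: pd.DataFrame | None = None


def run_pipeline(
    config: PipelineConfig,
    inputs: PipelineInputs,
    outdir: str | Path | None = None,
) -> dict:
    """Execute the full downstream pipeline.

    Returns a dict of stage DataFrames plus a ``manifest``; when
    ``outdir`` is given, each table is also written as TSV.
    """
    results: dict[str, object] = {}
    counts: dict[str, int] = {}

    # --- ion filtering and clustering -------------------------------
    kept = filter_ions(inputs.ions, config.min_intensity)
    clusters = cluster_ions(
        kept, config.tolerance_ppm, drop_redundant=config.drop_redundant
    )
    counts["ions_in"] = len(inputs.ions)
    counts["ions_kept"] = len(kept)
    counts["clusters"] = len(clusters)
    results["clusters"] = pd.DataFrame(
        [
            {
                "neutral_mass": c.neutral_mass,
                "n_members": len(c.members),
                "charges": ",".join(map(str, sorted(c.charges))),
                "total_intensity": c.total_intensity,
                "clustered": c.clustered,
            }
            for c in clusters
        ]
    )

    # --- coverage, consensus, MS/MS support -------------------------
    msms: dict[str, bool] | None = None
    if inputs.evidence is not None:
        parents = inputs.parents or {
            t.id: t.mature_sequence for t in inputs.toxins
        }
        by_parent: dict[str, list[PeptideEvidence]] = {}
        for ev in inputs.evidence:
            by_parent.setdefault(ev.parent_id, []).append(ev)
        msms = {}
        cov_rows, mat_rows = [], []
        for toxin in inputs.toxins:
            seq = parents.get(toxin.id)
            if seq is None:
                msms[toxin.id] = False
                continue
            cov = build_coverage(by_parent.get(toxin.id, []), seq)
            span = (
                inputs.mature_spans.get(toxin.id)
                if inputs.mature_spans
                else None
            ) or (1, len(seq))
            full, gap = is_fully_sequenced(cov, span)
            msms[toxin.id] = full
            observed = consensus_n_terminus(cov, config.min_enzymes)
            cov_rows.append(
                {
                    "toxin_id": toxin.id,
                    "covered_residues": sum(1 for d in cov.depth if d > 0),
                    "parent_length": len(seq),
                    "fully_sequenced": full,
                    "first_gap": gap if gap is not None else "",
                    "consensus_start": observed,
                }
            )
            if (
                inputs.predicted_starts
                and toxin.id in inputs.predicted_starts
                and isinstance(observed, int)
            ):
                cmp_res = compare_maturation(
                    inputs.predicted_starts[toxin.id], observed, seq, toxin.id
                )
                mat_rows.append(
                    {
                        "toxin_id": toxin.id,
                        "predicted_start": cmp_res.predicted_start,
                        "observed_start": cmp_res.observed_start,
                        "delta_residues": cmp_res.delta_residues,
                        "extension_sequence": cmp_res.extension_sequence,
                    }
                )
        results["coverage"] = pd.DataFrame(cov_rows)
        results["maturation"] = pd.DataFrame(mat_rows)
        counts["evidence_rows"] = len(inputs.evidence)

    # --- mass-based validation --------------------------------------
    reports = match_toxins(
        inputs.toxins,
        clusters,
        ppm_tol=config.tolerance_ppm,
        z_min=config.z_min,
        z_max=config.z_max,
        require_msms=config.require_msms,
        msms_supported=msms,
    )
    results["validation"] = pd.DataFrame(
        [
            {
                "toxin_id": r.toxin_id,
                "theoretical_mass": round(r.theoretical_mass, 4),
                "matched_charges": ",".join(map(str, sorted(r.matched_charges))),
                "best_ppm": round(r.best_ppm_error, 3)
                if r.best_ppm_error is not None
                else "",
                "msms_supported": r.msms_supported,
                "validated": r.validated,
            }
            for r in reports
        ]
    )
    counts["validated"] = int(sum(r.validated for r in reports))

    # --- physicochemical profiling ----------------------------------
    model = ChargeModel.from_scale(config.pka_scale, config.exclude_cys)
    phys_rows = []
    for toxin in inputs.toxins:
        seq = toxin.mass_form_sequence
        comp = aa_composition(seq, config.exclude_cys)
        phys_rows.append(
            {
                "toxin_id": toxin.id,
                "net_charge_physiological": round(
                    net_charge(seq, config.physiological_ph, model), 2
                ),
                "isoelectric_point": isoelectric_point(seq, model),
                "hydrophobic_percent": comp.percentages["hydrophobic"],
                "cationic_percent": comp.percentages["cationic"],
            }
        )
    results["physchem"] = pd.DataFrame(phys_rows)

    # --- quantification and screening -------------------------------
    if inputs.quant is not None:
        results["quant"] = quantify(
            inputs.quant, config.min_peptides, config.min_replicates
        )
        counts["proteins_quantified"] = int(results["quant"]["retained"].sum())
    if inputs.scores is not None:
        results["screening"] = screen_table(
            inputs.scores, config.amp_threshold, config.acp_threshold
        )

    manifest = {
        "package_version": __version__,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "row_counts": counts,
    }
    results["manifest"] = manifest

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, obj in results.items():
            if isinstance(obj, pd.DataFrame):
                write_table(obj, outdir / f"{name}.tsv", manifest["config_hash"])
        with open(outdir / "manifest.yaml", "w") as fh:
            yaml.safe_dump(manifest, fh, sort_keys=True)
    return results
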