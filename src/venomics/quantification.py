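"""Hi3 label-free protein quantification.

The Hi3 estimator scores a protein's abundance as the mean signal
intensity of its three most intense (tryptic) peptides; with fewer than
three peptides, all are averaged.  Identification filters mirror the
study design: a protein is retained only if identified with at least
three distinct peptides and detected in at least two replicates.
Relative abundance normalises mean Hi3 values over the retained set to
100%.

Missing is not zero: the per-protein mean is taken over the replicates
in which the protein was detected, not over all replicates.
Filter-failing proteins are reported with a ``retained=False`` flag
rather than silently dropped; they are excluded from the percentage
denominator.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import pandas as pd

__all__ = ["hi3", "apply_filters", "relative_abundance", "quantify"]

INPUT_COLUMNS = ["protein_id", "replicate_id", "peptide_sequence", "intensity"]


def hi3(peptide_intensities: Sequence[float]) -> float:
    """Mean of the three largest intensities (all, if fewer than three)."""
    if len(peptide_intensities) == 0:
        raise ValueError("hi3 requires at least one peptide intensity")
    top = sorted(peptide_intensities, reverse=True)[:3]
    return sum(top) / len(top)


def apply_filters(
    inputs: pd.DataFrame, min_peptides: int = 3, min_replicates: int = 2
) -> set[str]:
    """Protein ids passing the identification filters.

    ``inputs`` is long-form with columns ``protein_id, replicate_id,
    peptide_sequence, intensity``.  Peptides are counted as distinct
    sequences across replicates; detection means >= 1 peptide row in a
    replicate.
    """
    _check_columns(inputs)
    grouped = inputs.groupby("protein_id")
    retained = set()
    for protein, rows in grouped:
        if rows["peptide_sequence"].nunique() < min_peptides:
            continue
        if rows["replicate_id"].nunique() < min_replicates:
            continue
        retained.add(protein)
    return retained


def relative_abundance(abundances: Mapping[str, float]) -> dict[str, float]:
    """Percent share of each protein: ``100 * value / sum``.

    Values must be non-negative with at least one positive entry.
    Shares are returned unrounded; format to one decimal for reports.
    """
    for protein, value in abundances.items():
        if value < 0:
            raise ValueError(f"negative abundance for {protein}")
    total = sum(abundances.values())
    if total <= 0:
        raise ValueError("all abundances are zero")
    return {protein: 100.0 * value / total for protein, value in abundances.items()}


def quantify(
    inputs: pd.DataFrame, min_peptides: int = 3, min_replicates: int = 2
) -> pd.DataFrame:
    """Full Hi3 quantification report.

    Returns one row per protein: distinct peptide count, replicates
    detected, per-replicate Hi3 mean (over detected replicates only),
    retention flag, and percent share among retained proteins
    (``NaN`` for filtered-out proteins).
    """
    _check_columns(inputs)
    retained = apply_filters(inputs, min_peptides, min_replicates)
    rows = []
    for protein, sub in inputs.groupby("protein_id"):
        per_rep = [
            hi3(rep_rows["intensity"].tolist())
            for _, rep_rows in sub.groupby("replicate_id")
        ]
        rows.append(
            {
                "protein_id": protein,
                "peptide_count": sub["peptide_sequence"].nunique(),
                "replicates_detected": sub["replicate_id"].nunique(),
                "mean_hi3": sum(per_rep) / len(per_rep),
                "retained": protein in retained,
            }
        )
    report = pd.DataFrame(rows)
    shares = relative_abundance(
        {
            r["protein_id"]: r["mean_hi3"]
            for r in rows
            if r["retained"]
        }
    ) if retained else {}
    report["relative_percent"] = report["protein_id"].map(shares)
    return report.sort_values(
        "mean_hi3", ascending=False, ignore_index=True
    )


def _check_columns(inputs: pd.DataFrame) -> None:
    missing = [c for c in INPUT_COLUMNS if c not in inputs.columns]
    if missing:
        raise ValueError(f"quant input missing columns: {missing}")
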