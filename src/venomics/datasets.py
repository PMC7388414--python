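"""Packaged reference tables for the *Acanthoscurria rondoniae* venom study.

Four small TSVs ship with the package so the worked examples and the
acceptance checks run without downloads:

* ``reference_toxins`` — the 18 validated mature toxins (sequence,
  disulfide count, printed monoisotopic mass, intensity rank, PTM
  annotations).
* ``reference_quant`` — the 33-protein Hi3 quantification table
  (normalized intensities and printed percent shares).
* ``reference_screening`` — predictor scores for the validated toxins
  and the positive-control peptides.
* ``reference_composition`` — printed amino-acid class composition of
  the six predicted anticancer peptides.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .chemistry import ToxinRecord

__all__ = [
    "load_reference_toxins",
    "load_reference_toxin_table",
    "load_reference_quant",
    "load_reference_screening",
    "load_reference_composition",
]


def _read(name: str) -> pd.DataFrame:
    ref = resources.files("venomics.data") / name
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", comment="#")


def load_reference_toxin_table() -> pd.DataFrame:
    """The validated-toxin table as a DataFrame."""
    df = _read("reference_toxins.tsv")
    df["modifications"] = df["modifications"].fillna("")
    df["family"] = df["family"].fillna("")
    return df


def load_reference_toxins() -> list[ToxinRecord]:
    """The 18 validated mature toxins as :class:`ToxinRecord` objects."""
    records = []
    for row in load_reference_toxin_table().itertuples():
        mods = [m for m in str(row.modifications).split(",") if m]
        records.append(
            ToxinRecord(
                id=str(row.toxin_id),
                mature_sequence=str(row.sequence),
                ss_bonds=int(row.ss_bonds),
                modifications=mods,
                log_intensity=float(row.log_intensity),
                rank=int(row.rank),
            )
        )
    return records


def load_reference_quant() -> pd.DataFrame:
    """The 33-protein quantification table (NI values and printed shares)."""
    return _read("reference_quant.tsv")


def load_reference_screening() -> pd.DataFrame:
    """Predictor scores for validated toxins plus positive controls."""
    return _read("reference_screening.tsv")


def load_reference_composition() -> pd.DataFrame:
    """Printed class composition of the six predicted anticancer peptides."""
    return _read("reference_composition.tsv")
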