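"""Bioactivity screening decision rules.

Predictor scores are *inputs*: antimicrobial scores (antibacterial,
antiviral, antifungal, each 0..1) come from a sequence-based AMP
predictor, and two anticancer scores (random-forest and SVM) from an
ACP predictor.  This module only applies the decision rules:

* an antimicrobial activity is **significant** when its score is
  strictly greater than 0.8;
* a peptide is labelled **ACP** only on consensus — both anticancer
  scores strictly greater than 0.5; with either score missing the
  peptide is **not-evaluated**.

Both thresholds are strict inequalities and configurable.
"""

from __future__ import annotations

from typing import Mapping

import pandas as pd

__all__ = ["amp_significance", "acp_consensus", "screen_table"]

AMP_ACTIVITIES = ["antibacterial", "antiviral", "antifungal"]

ACP = "ACP"
NON_ACP = "Non-ACP"
NOT_EVALUATED = "not-evaluated"


def _check_score(value: float, label: str) -> None:
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{label} score {value} outside [0, 1]")


def amp_significance(
    scores: Mapping[str, float], threshold: float = 0.8
) -> dict[str, bool]:
    """Per-activity significance flags (strict ``> threshold``)."""
    flags = {}
    for activity, value in scores.items():
        _check_score(value, activity)
        flags[activity] = value > threshold
    return flags


def acp_consensus(
    rf_score: float | None, svm_score: float | None, threshold: float = 0.5
) -> str:
    """Consensus anticancer label from the two predictor scores."""
    if rf_score is None or svm_score is None:
        return NOT_EVALUATED
    _check_score(rf_score, "rf_acp")
    _check_score(svm_score, "svm_acp")
    return ACP if (rf_score > threshold and svm_score > threshold) else NON_ACP


def screen_table(
    scores: pd.DataFrame,
    amp_threshold: float = 0.8,
    acp_threshold: float = 0.5,
) -> pd.DataFrame:
    """Apply both rules to a score table.

    ``scores`` columns: ``peptide_id``, the three AMP activities and
    ``rf_acp``/``svm_acp`` (blank/NaN = missing).  Returns one verdict
    row per peptide with boolean significance flags and the ACP label.
    """
    rows = []
    for _, r in scores.iterrows():
        amp_scores = {
            a: float(r[a])
            for a in AMP_ACTIVITIES
            if a in scores.columns and pd.notna(r[a])
        }
        flags = amp_significance(amp_scores, amp_threshold)
        rf = float(r["rf_acp"]) if "rf_acp" in scores.columns and pd.notna(r["rf_acp"]) else None
        svm = float(r["svm_acp"]) if "svm_acp" in scores.columns and pd.notna(r["svm_acp"]) else None
        rows.append(
            {
                "peptide_id": r["peptide_id"],
                **{f"{a}_significant": flags.get(a, False) for a in AMP_ACTIVITIES},
                "acp_label": acp_consensus(rf, svm, acp_threshold),
            }
        )
    return pd.DataFrame(rows)
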