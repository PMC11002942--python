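"""SILAC ratio arithmetic for heavy:light proteome quantification.

Covers the label-incorporation check, the arginine-to-proline interconversion
correction ``r_c = r_o / (1 - p)^n`` (with ``p`` the interconversion rate and
``n`` the peptide's proline count), protein-level ratios as the median of
corrected peptide ratios, and log2 fold-change selection.  The default
interconversion rate is 0.077 (7.7%).  No replicate-based hypothesis testing
is offered at this level: proteins are flagged by |log2 fold-change| > 1,
never assigned p-values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_INTERCONVERSION_RATE",
    "ProteinQuant",
    "incorporation_rate",
    "correct_ratio",
    "protein_ratio",
    "quantify_experiment",
]

DEFAULT_INTERCONVERSION_RATE = 0.077


def incorporation_rate(mean_ratio: float) -> float:
    """Mean isotopic incorporation in percent: (1 - 1/(mean + 1)) x 100."""
    if mean_ratio < 0:
        raise ValueError("mean heavy:light ratio must be >= 0")
    return (1.0 - 1.0 / (mean_ratio + 1.0)) * 100.0


def correct_ratio(
    r_observed: float,
    p: float = DEFAULT_INTERCONVERSION_RATE,
    n_prolines: int = 0,
) -> float:
    """Arg→Pro-corrected peptide ratio: r_c = r_o / (1 - p)^n."""
    if r_observed <= 0:
        raise ValueError("observed ratio must be positive")
    if not (0.0 <= p < 1.0):
        raise ValueError("interconversion rate must lie in [0, 1)")
    if n_prolines < 0 or int(n_prolines) != n_prolines:
        raise ValueError("proline count must be a non-negative integer")
    return r_observed / (1.0 - p) ** int(n_prolines)


@dataclass(frozen=True)
class ProteinQuant:
    """Protein-level SILAC quantification record."""

    protein: str
    median_ratio: float
    log2_fold_change: float
    n_peptides: int
    selected: bool


def protein_ratio(
    corrected_ratios: Sequence[float],
    protein: str = "",
    log2_threshold: float = 1.0,
) -> ProteinQuant:
    """Median of corrected peptide ratios with log2 fold-change selection.

    Selection uses the strict rule |log2 fold-change| > threshold.
    """
    ratios = np.asarray(list(corrected_ratios), float)
    if ratios.size == 0:
        raise ValueError("no peptide ratios for protein")
    if (ratios <= 0).any():
        raise ValueError("peptide ratios must be positive")
    median = float(np.median(ratios))
    log2fc = float(np.log2(median))
    return ProteinQuant(
        protein=protein,
        median_ratio=median,
        log2_fold_change=log2fc,
        n_peptides=int(ratios.size),
        selected=abs(log2fc) > log2_threshold,
    )


_REQUIRED_COLUMNS = ("protein", "peptide", "ratio", "prolines", "unique")


def quantify_experiment(
    peptides: pd.DataFrame,
    p: float = DEFAULT_INTERCONVERSION_RATE,
    log2_threshold: float = 1.0,
    min_unique_peptides: int = 2,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Peptide table in, protein quantification table and summary counts out.

    ``peptides`` columns: ``protein``, ``peptide`` (sequence or id),
    ``ratio`` (observed heavy:light, > 0), ``prolines`` (count), ``unique``
    (boolean).  Proteins with fewer than ``min_unique_peptides`` unique
    peptides are excluded from the identified set; the rest have all their
    quantified peptide ratios corrected, medianed and flagged.

    Malformed rows (non-positive ratio, negative or fractional proline count,
    missing values) are rejected with their row labels listed.
    """
    missing = [c for c in _REQUIRED_COLUMNS if c not in peptides.columns]
    if missing:
        raise ValueError(f"peptide table lacks required columns: {missing}")
    if peptides.empty:
        empty = pd.DataFrame(
            columns=["protein", "median_ratio", "log2_fold_change", "n_peptides", "selected"]
        )
        return empty, {"proteins_identified": 0, "proteins_quantified": 0, "proteins_selected": 0}

    bad_rows = []
    for label, row in peptides.iterrows():
        ratio, prolines = row["ratio"], row["prolines"]
        if pd.isna(ratio) or ratio <= 0:
            bad_rows.append(label)
        elif pd.isna(prolines) or prolines < 0 or float(prolines) != int(prolines):
            bad_rows.append(label)
    if bad_rows:
        raise ValueError(f"malformed peptide rows: {bad_rows}")

    unique_counts = (
        peptides[peptides["unique"].astype(bool)]
        .groupby("protein")["peptide"]
        .nunique()
    )
    identified = set(unique_counts[unique_counts >= min_unique_peptides].index)

    records = []
    for protein, group in peptides.groupby("protein"):
        if protein not in identified:
            continue
        corrected = [
            correct_ratio(float(r), p, int(n))
            for r, n in zip(group["ratio"], group["prolines"])
        ]
        quant = protein_ratio(corrected, protein=str(protein), log2_threshold=log2_threshold)
        records.append(
            {
                "protein": quant.protein,
                "median_ratio": quant.median_ratio,
                "log2_fold_change": quant.log2_fold_change,
                "n_peptides": quant.n_peptides,
                "selected": quant.selected,
            }
        )
    table = pd.DataFrame.from_records(
        records,
        columns=["protein", "median_ratio", "log2_fold_change", "n_peptides", "selected"],
    ).sort_values("protein").reset_index(drop=True)
    summary = {
        "proteins_identified": len(identified),
        "proteins_quantified": int(len(table)),
        "proteins_selected": int(table["selected"].sum()) if len(table) else 0,
    }
    return table, summary
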