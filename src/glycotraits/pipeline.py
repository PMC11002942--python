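"""End-to-end cohort pipeline: simulate, process, derive traits, compare.

Binds the stages together for the common two-group experiment: simulate (or
accept) a cohort of spectra, process each spectrum into an annotated peak
table, aggregate derived traits per spectrum, optionally screen spectra in
PCA/Hotelling score space, average technical replicates within biological
replicates, and compare the groups trait by trait.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .processing import QCThresholds, process_spectrum
from .simulate import (
    DEFAULT_CALIBRANTS,
    Cohort,
    GroundTruthProfile,
    SimulationDesign,
    make_profile,
    simulate_cohort,
)
from .stats import OutlierScreen, average_replicates, compare_groups, pca_hotelling_screen
from .traits import DEFAULT_RULES, TraitRules, aggregate_traits

__all__ = ["CohortResult", "run_cohort", "signal_matrix"]


@dataclass
class CohortResult:
    """Everything the two-group pipeline produces."""

    peak_tables: dict[tuple[str, int, int], pd.DataFrame]
    spectrum_traits: pd.DataFrame  # one row per spectrum (group/bio/tech + traits)
    biological_traits: pd.DataFrame  # technical replicates averaged
    comparison: pd.DataFrame  # per-trait t-test table
    screens: dict[str, OutlierScreen] = field(default_factory=dict)
    excluded_spectra: tuple[tuple[str, int, int], ...] = ()
    groups: tuple[str, str] = ("", "")


def signal_matrix(
    peak_tables: Mapping[tuple[str, int, int], pd.DataFrame]
) -> pd.DataFrame:
    """Samples x signals matrix of kept percentages, keyed by best candidate.

    Signals absent from a spectrum are recorded as 0 for score-space
    screening purposes.
    """
    rows = {}
    for key, table in peak_tables.items():
        kept = table[table["kept"]]
        rows[key] = kept.set_index("best_candidate")["percent"]
    matrix = pd.DataFrame(rows).T.fillna(0.0)
    matrix.index = pd.MultiIndex.from_tuples(matrix.index, names=["group", "bio", "tech"])
    return matrix


def run_cohort(
    profile_a: "GroundTruthProfile | str" = "ntc_like",
    profile_b: "GroundTruthProfile | str" = "knockdown_like",
    design: SimulationDesign | None = None,
    master_seed: int = 0,
    rules: TraitRules = DEFAULT_RULES,
    calibrants: Sequence[str] | None = DEFAULT_CALIBRANTS,
    qc: QCThresholds | None = None,
    tol_ppm: float = 20.0,
    screen: bool = True,
    cohort: Cohort | None = None,
    **process_kwargs,
) -> CohortResult:
    """Run the full two-group pipeline on a simulated (or given) cohort."""
    if cohort is None:
        if isinstance(profile_a, str):
            profile_a = make_profile(profile_a)
        if isinstance(profile_b, str):
            profile_b = make_profile(profile_b)
        design = design or SimulationDesign()
        cohort = simulate_cohort(profile_a, profile_b, design, master_seed=master_seed)

    peak_tables: dict[tuple[str, int, int], pd.DataFrame] = {}
    for idx, row in cohort.manifest.iterrows():
        table, _ = process_spectrum(
            cohort.spectra[idx],
            calibrants=calibrants,
            qc=qc,
            tol_ppm=tol_ppm,
            **process_kwargs,
        )
        peak_tables[(row["group"], int(row["bio"]), int(row["tech"]))] = table

    groups = tuple(dict.fromkeys(cohort.manifest["group"]))

    screens: dict[str, OutlierScreen] = {}
    excluded: list[tuple[str, int, int]] = []
    if screen:
        matrix = signal_matrix(peak_tables)
        for group in groups:
            sub = matrix.loc[[group]]
            result = pca_hotelling_screen(sub)
            screens[group] = result
            excluded.extend(result.excluded)

    trait_rows = []
    for key, table in peak_tables.items():
        if key in excluded:
            continue
        series = aggregate_traits(table, rules)
        trait_rows.append(
            {"group": key[0], "bio": key[1], "tech": key[2], **series.to_dict()}
        )
    spectrum_traits = pd.DataFrame(trait_rows)

    biological = average_replicates(spectrum_traits)
    ref = biological[biological["group"] == groups[0]].drop(columns=["group", "bio"])
    test = biological[biological["group"] == groups[1]].drop(columns=["group", "bio"])
    comparison = compare_groups(
        ref, test, reference_label=str(groups[0]), test_label=str(groups[1])
    )

    return CohortResult(
        peak_tables=peak_tables,
        spectrum_traits=spectrum_traits,
        biological_traits=biological,
        comparison=comparison,
        screens=screens,
        excluded_spectra=tuple(excluded),
        groups=(str(groups[0]), str(groups[1])),
    )
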