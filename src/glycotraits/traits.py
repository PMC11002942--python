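"""Derived-trait calculus: classify compositions, aggregate trait percentages.

Each candidate composition is classified by type (paucimannosidic,
high-mannose, hybrid, complex), glycidic motif (mono-/multifucosylation,
linkage-specific sialylation, a sialyl-Lewis-x proxy), the Hex/HexNAc count
ratio and antennarity.  Normalized peak percentages are then summed per trait
group; a peak whose candidate set spans several groups contributes its full
percentage to each, which is why trait-group totals may exceed 100% in the
presence of non-univocal assignments.

The classification thresholds live in :class:`TraitRules` and can be loaded
from a YAML file, so alternative rule sets are testable without code changes.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml

from .chem import GlycanComposition

__all__ = [
    "TraitRules",
    "TraitFlags",
    "DEFAULT_RULES",
    "TRAIT_COLUMNS",
    "classify_composition",
    "antennarity_labels",
    "aggregate_traits",
    "trait_table",
]

_ANT_NAMES = {1: "mono", 2: "di", 3: "tri", 4: "tetra"}

#: Table rows of the derived-trait calculus, in reporting order.
TRAIT_COLUMNS = (
    "type_paucimannosidic",
    "type_high_mannose",
    "type_complex",
    "type_hybrid",
    "type_unclassified",
    "fuc_mono",
    "fuc_multi",
    "fuc_total",
    "sial_a23",
    "sial_a26",
    "sial_mixed",
    "sial_total",
    "slex",
    "hn_h_gt_n",
    "hn_h_eq_n",
    "hn_h_lt_n",
    "ant_mono",
    "ant_di",
    "ant_di_tri",
    "ant_tri",
    "ant_tri_tetra",
    "ant_tetra",
    "ant_tetra_poly",
    "ant_poly",
)

_ANT_PAIR_ROWS = {
    frozenset({"di", "tri"}): "ant_di_tri",
    frozenset({"tri", "tetra"}): "ant_tri_tetra",
    frozenset({"tetra", "poly"}): "ant_tetra_poly",
}
_ANT_SINGLETON_ROWS = {
    "mono": "ant_mono",
    "di": "ant_di",
    "tri": "ant_tri",
    "tetra": "ant_tetra",
    "poly": "ant_poly",
}


@dataclass(frozen=True)
class TraitRules:
    """Configurable thresholds of the trait classification.

    Defaults encode standard N-glycan conventions: paucimannosidic structures
    keep the chitobiose core (2 HexNAc) with at most 3 hexoses and no sialic
    acid; high-mannose glycans carry 5-9 mannoses and nothing else; a third
    HexNAc with 5+ hexoses reads as hybrid, otherwise complex; polyantennarity
    (LacNAc repeats) requires Hex > 7 and HexNAc > 6.
    """

    pauci_max_hex: int = 3
    high_mannose_hex: tuple[int, int] = (5, 9)
    hybrid_min_hex: int = 5
    complex_min_hexnac: int = 4
    multi_fuc_min: int = 2
    poly_hex_gt: int = 7
    poly_hexnac_gt: int = 6
    max_antennae: int = 4
    lacnac_lower_min_antennae: int = 3

    def to_yaml(self, path: "str | Path") -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: "str | Path") -> "TraitRules":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if "high_mannose_hex" in data:
            data["high_mannose_hex"] = tuple(data["high_mannose_hex"])
        return cls(**data)


DEFAULT_RULES = TraitRules()


@dataclass(frozen=True)
class TraitFlags:
    """Classification of one composition under one rule set."""

    type_class: str
    fucosylation: str  # none / mono / multi
    a23: bool
    a26: bool
    mixed_sialylation: bool
    slex_candidate: bool
    hn_class: str  # H>N / H=N / H<N
    antennarity: frozenset[str]


def _type_class(c: GlycanComposition, rules: TraitRules) -> str:
    if c.hexnac == 2 and c.hex <= rules.pauci_max_hex and c.sialic == 0:
        return "paucimannosidic"
    lo, hi = rules.high_mannose_hex
    if c.hexnac == 2 and lo <= c.hex <= hi and c.fuc == 0 and c.sialic == 0:
        return "high_mannose"
    if c.hexnac == 3:
        return "hybrid" if c.hex >= rules.hybrid_min_hex else "complex"
    if c.hexnac >= rules.complex_min_hexnac:
        return "complex"
    return "unclassified"


def antennarity_labels(
    c: GlycanComposition, rules: TraitRules = DEFAULT_RULES
) -> frozenset[str]:
    """Consistent antenna-count labels of one composition.

    The base antenna count is ``hexnac - 2`` (capped at 4).  A composition
    satisfying the polyantennarity condition (Hex > 7 and HexNAc > 6) is read
    as tetra-antennary or LacNAc-extended ("poly").  Otherwise a composition
    with enough hexoses to be the (A-1)-antennary glycan plus one LacNAc
    repeat additionally receives the adjacent-lower label (di-/tri-,
    tri-/tetra- ambiguity); this is only applied from 3 antennas up, matching
    the intermediate groups reported in practice.
    """
    if c.hexnac < 3:
        return frozenset()
    a = min(c.hexnac - 2, rules.max_antennae)
    if c.hex > rules.poly_hex_gt and c.hexnac > rules.poly_hexnac_gt:
        return frozenset({"tetra", "poly"})
    labels = {_ANT_NAMES[a]}
    if a >= rules.lacnac_lower_min_antennae and c.hex >= a + 2:
        labels.add(_ANT_NAMES[a - 1])
    return frozenset(labels)


def classify_composition(
    composition: "GlycanComposition | str", rules: TraitRules = DEFAULT_RULES
) -> TraitFlags:
    """Deterministic trait flags of one composition (a pure function)."""
    c = (
        composition
        if isinstance(composition, GlycanComposition)
        else GlycanComposition.from_string(composition)
    )
    if c.fuc == 0:
        fucosylation = "none"
    elif c.fuc < rules.multi_fuc_min:
        fucosylation = "mono"
    else:
        fucosylation = "multi"
    a23 = c.lneuac >= 1
    a26 = c.eneuac >= 1
    if c.hex > c.hexnac:
        hn = "H>N"
    elif c.hex == c.hexnac:
        hn = "H=N"
    else:
        hn = "H<N"
    return TraitFlags(
        type_class=_type_class(c, rules),
        fucosylation=fucosylation,
        a23=a23,
        a26=a26,
        mixed_sialylation=a23 and a26,
        slex_candidate=c.fuc >= 1 and a23,
        hn_class=hn,
        antennarity=antennarity_labels(c, rules),
    )


def _peak_trait_groups(
    candidates: Iterable[GlycanComposition], rules: TraitRules
) -> set[str]:
    """Trait columns one peak contributes to, from its candidate set."""
    groups: set[str] = set()
    ant_union: set[str] = set()
    for comp in candidates:
        flags = classify_composition(comp, rules)
        groups.add(f"type_{flags.type_class}")
        if flags.fucosylation == "mono":
            groups.add("fuc_mono")
        elif flags.fucosylation == "multi":
            groups.add("fuc_multi")
        if flags.fucosylation != "none":
            groups.add("fuc_total")
        if flags.a23:
            groups.add("sial_a23")
        if flags.a26:
            groups.add("sial_a26")
        if flags.mixed_sialylation:
            groups.add("sial_mixed")
        if flags.a23 or flags.a26:
            groups.add("sial_total")
        if flags.slex_candidate:
            groups.add("slex")
        groups.add(
            {"H>N": "hn_h_gt_n", "H=N": "hn_h_eq_n", "H<N": "hn_h_lt_n"}[flags.hn_class]
        )
        ant_union |= flags.antennarity
    if ant_union:
        key = frozenset(ant_union)
        if len(key) == 1:
            groups.add(_ANT_SINGLETON_ROWS[next(iter(key))])
        elif key in _ANT_PAIR_ROWS:
            groups.add(_ANT_PAIR_ROWS[key])
        else:
            # wider ambiguity: report every adjacent pair contained in the
            # union, falling back to singleton rows when none applies
            pairs = [row for pair, row in _ANT_PAIR_ROWS.items() if pair <= key]
            if pairs:
                groups.update(pairs)
            else:
                groups.update(_ANT_SINGLETON_ROWS[label] for label in key)
    return groups


def _peak_candidates(row: pd.Series) -> list[GlycanComposition]:
    if "candidate_comps" in row.index and isinstance(row["candidate_comps"], (list, tuple, set)):
        return [
            c if isinstance(c, GlycanComposition) else GlycanComposition.from_string(c)
            for c in row["candidate_comps"]
        ]
    text = row.get("candidates", "")
    if not isinstance(text, str) or not text:
        return []
    return [GlycanComposition.from_string(part) for part in text.split(";") if part]


def aggregate_traits(
    peaks: pd.DataFrame,
    rules: TraitRules = DEFAULT_RULES,
    tol: float = 1e-6,
) -> pd.Series:
    """Sum normalized peak percentages into every trait group.

    ``peaks`` must carry ``percent`` (summing to 100 over kept peaks) and the
    candidate compositions (either a ``candidates`` column of semicolon-joined
    composition strings or a ``candidate_comps`` list column).  A peak with
    candidates in several groups contributes fully to each group.
    """
    if "kept" in peaks.columns:
        peaks = peaks[peaks["kept"]]
    peaks = peaks[peaks["percent"].notna()]
    total = peaks["percent"].sum()
    if peaks.empty or abs(total - 100.0) > max(tol, 1e-6):
        raise ValueError(
            f"peak percentages must sum to 100 (got {total!r}); normalize first"
        )
    values = dict.fromkeys(TRAIT_COLUMNS, 0.0)
    for _, row in peaks.iterrows():
        candidates = _peak_candidates(row)
        if not candidates:
            values["type_unclassified"] += float(row["percent"])
            continue
        for column in _peak_trait_groups(candidates, rules):
            values[column] += float(row["percent"])
    return pd.Series(values, index=list(TRAIT_COLUMNS), dtype=float)


def trait_table(
    peaks_by_sample: Mapping[object, pd.DataFrame],
    rules: TraitRules = DEFAULT_RULES,
) -> pd.DataFrame:
    """Per-sample trait percentages, one row per sample."""
    rows = {key: aggregate_traits(table, rules) for key, table in peaks_by_sample.items()}
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "sample"
    return out
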