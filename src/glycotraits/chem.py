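"""Exact-mass arithmetic for ethyl-esterified, sodiated N-glycans.

Sialic-acid linkage is encoded chemically: ethyl esterification converts
alpha(2,6)-linked NeuAc into an ethyl ester (residue ``ENeuAc``, NeuAc + C2H4)
while alpha(2,3)-linked NeuAc lactonizes (residue ``LNeuAc``, NeuAc - H2O), so
the two linkages become mass-distinguishable in MALDI-TOF spectra.  All ions
are treated as singly sodiated ([M+Na]+) species with a free reducing end.

The module provides:

* :class:`GlycanComposition` -- immutable residue-count record with the
  canonical ``H{h}N{n}F{f}E{e}L{l}`` text form,
* monoisotopic residue masses derived from elemental formulas,
* theoretical m/z and signed ppm errors,
* combinatorial composition enumeration within a ppm tolerance
  (Glyco-Peakfinder style, with an optional biosynthetic plausibility filter),
* aggregated isotopologue patterns for isotopic-envelope quality scoring,
* neutral-loss interpretation for MS/MS fragment deltas.
"""

from __future__ import annotations

import functools
import itertools
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from pyteomics import mass as _pmass

__all__ = [
    "ELECTRON_MASS",
    "WATER_MASS",
    "SODIUM_CATION_MASS",
    "ISOTOPE_SPACING",
    "WORKING_WINDOW",
    "RESIDUE_FORMULAS",
    "GlycanComposition",
    "CompositionBounds",
    "residue_mass",
    "residue_formula_string",
    "theoretical_mz",
    "ppm_error",
    "enumerate_compositions",
    "rank_candidates",
    "best_candidate",
    "isotope_pattern",
    "interpret_losses",
    "biosynthetically_plausible",
    "in_working_window",
    "write_residue_table",
]

ELECTRON_MASS = 5.48579909065e-4

#: monoisotopic mass of H2O (added once per glycan: free reducing end)
WATER_MASS = _pmass.calculate_mass(formula="H2O")

#: [M+Na]+ cation mass: Na atom minus one electron
SODIUM_CATION_MASS = _pmass.nist_mass["Na"][23][0] - ELECTRON_MASS

#: spacing between adjacent isotopologue peaks (13C - 12C), Da
ISOTOPE_SPACING = _pmass.nist_mass["C"][13][0] - _pmass.nist_mass["C"][12][0]

#: MALDI-TOF acquisition window used throughout (m/z)
WORKING_WINDOW = (1000.0, 5000.0)

#: elemental formulas of dehydrated (residue) monosaccharide units
RESIDUE_FORMULAS: dict[str, dict[str, int]] = {
    "Hex": {"C": 6, "H": 10, "O": 5},
    "HexNAc": {"C": 8, "H": 13, "N": 1, "O": 5},
    "Fuc": {"C": 6, "H": 10, "O": 4},
    # NeuAc residue + C2H4 (ethyl ester): alpha(2,6)-linked sialic acid
    "ENeuAc": {"C": 13, "H": 21, "N": 1, "O": 8},
    # NeuAc residue - H2O (lactone): alpha(2,3)-linked sialic acid
    "LNeuAc": {"C": 11, "H": 15, "N": 1, "O": 7},
}

RESIDUE_ORDER = ("Hex", "HexNAc", "Fuc", "ENeuAc", "LNeuAc")


def residue_formula_string(residue: str) -> str:
    """Hill-ish formula string for one residue class (e.g. ``C6H10O5``)."""
    formula = _formula_or_raise(residue)
    return "".join(
        f"{el}{n}" for el, n in formula.items() if n
    )


def _formula_or_raise(residue: str) -> dict[str, int]:
    try:
        return RESIDUE_FORMULAS[residue]
    except KeyError:
        raise ValueError(
            f"unknown residue class {residue!r}; expected one of {sorted(RESIDUE_FORMULAS)}"
        ) from None


@functools.lru_cache(maxsize=None)
def residue_mass(residue: str) -> float:
    """Monoisotopic mass (Da) of a dehydrated residue, from its formula."""
    return _pmass.calculate_mass(formula=residue_formula_string(residue))


_COMPOSITION_RE = re.compile(
    r"^H(?P<hex>\d+)N(?P<hexnac>\d+)(?:F(?P<fuc>\d+))?"
    r"(?:E(?P<eneuac>\d+))?(?:L(?P<lneuac>\d+))?$"
)


@dataclass(frozen=True, order=True)
class GlycanComposition:
    """Counts of monosaccharide residue classes; the unit of assignment.

    Fields follow the H/N/F/E/L shorthand: hexose, N-acetylhexosamine,
    deoxyhexose (fucose), ethyl-esterified NeuAc (alpha-2,6) and lactonized
    NeuAc (alpha-2,3).
    """

    hex: int = 0
    hexnac: int = 0
    fuc: int = 0
    eneuac: int = 0
    lneuac: int = 0

    def __post_init__(self) -> None:
        for name in ("hex", "hexnac", "fuc", "eneuac", "lneuac"):
            value = getattr(self, name)
            if not isinstance(value, (int, np.integer)) or isinstance(value, bool):
                raise TypeError(f"{name} count must be an integer, got {value!r}")
            if value < 0:
                raise ValueError(f"{name} count must be >= 0, got {value}")
        if self.total_residues < 1:
            raise ValueError("empty composition (all residue counts zero)")

    @property
    def total_residues(self) -> int:
        return self.hex + self.hexnac + self.fuc + self.eneuac + self.lneuac

    @property
    def sialic(self) -> int:
        """Total sialic-acid residue count (both linkages)."""
        return self.eneuac + self.lneuac

    def counts(self) -> dict[str, int]:
        return {
            "Hex": self.hex,
            "HexNAc": self.hexnac,
            "Fuc": self.fuc,
            "ENeuAc": self.eneuac,
            "LNeuAc": self.lneuac,
        }

    def formula(self, sodiated: bool = False) -> dict[str, int]:
        """Elemental formula of the neutral glycan (residues + one water)."""
        formula: dict[str, int] = {"C": 0, "H": 2, "N": 0, "O": 1}
        for residue, count in self.counts().items():
            for el, n in RESIDUE_FORMULAS[residue].items():
                formula[el] = formula.get(el, 0) + n * count
        if sodiated:
            formula["Na"] = formula.get("Na", 0) + 1
        return {el: n for el, n in formula.items() if n}

    def __str__(self) -> str:
        text = f"H{self.hex}N{self.hexnac}"
        if self.fuc:
            text += f"F{self.fuc}"
        if self.eneuac:
            text += f"E{self.eneuac}"
        if self.lneuac:
            text += f"L{self.lneuac}"
        return text

    @classmethod
    def from_string(cls, text: str) -> "GlycanComposition":
        match = _COMPOSITION_RE.match(text.strip())
        if match is None:
            raise ValueError(f"cannot parse glycan composition {text!r}")
        groups = {k: int(v) if v is not None else 0 for k, v in match.groupdict().items()}
        return cls(**groups)


def _as_composition(value: "GlycanComposition | str") -> GlycanComposition:
    if isinstance(value, GlycanComposition):
        return value
    return GlycanComposition.from_string(value)


def theoretical_mz(composition: "GlycanComposition | str") -> float:
    """m/z of the singly sodiated ion: sum of residue masses + H2O + Na+."""
    composition = _as_composition(composition)
    return (
        sum(count * residue_mass(res) for res, count in composition.counts().items())
        + WATER_MASS
        + SODIUM_CATION_MASS
    )


def ppm_error(observed_mz: float, theoretical: float) -> float:
    """Signed relative mass error, (observed - theoretical)/theoretical * 1e6."""
    if observed_mz <= 0 or theoretical <= 0:
        raise ValueError("m/z values must be positive")
    return (observed_mz - theoretical) / theoretical * 1e6


def in_working_window(mz: float) -> bool:
    return WORKING_WINDOW[0] <= mz <= WORKING_WINDOW[1]


@dataclass(frozen=True)
class CompositionBounds:
    """Inclusive per-residue count ranges for composition enumeration."""

    hex: tuple[int, int] = (0, 12)
    hexnac: tuple[int, int] = (2, 10)
    fuc: tuple[int, int] = (0, 5)
    eneuac: tuple[int, int] = (0, 4)
    lneuac: tuple[int, int] = (0, 4)

    def __post_init__(self) -> None:
        for name in ("hex", "hexnac", "fuc", "eneuac", "lneuac"):
            lo, hi = getattr(self, name)
            if lo < 0 or hi < lo:
                raise ValueError(f"invalid bounds for {name}: ({lo}, {hi})")

    def ranges(self) -> tuple[range, ...]:
        return tuple(
            range(lo, hi + 1)
            for lo, hi in (self.hex, self.hexnac, self.fuc, self.eneuac, self.lneuac)
        )


DEFAULT_BOUNDS = CompositionBounds()


def biosynthetically_plausible(composition: GlycanComposition) -> bool:
    """N-glycan plausibility: chitobiose core, antenna-capped sialylation.

    Requires hexnac >= 2 (two core GlcNAc), total sialic acids no more than
    the antenna capacity (hexnac - 2), and fucose count no more than hexnac.
    """
    c = composition
    return (
        c.hexnac >= 2
        and c.sialic <= max(c.hexnac - 2, 0)
        and c.fuc <= c.hexnac
    )


@functools.lru_cache(maxsize=8)
def _composition_table(
    bounds: CompositionBounds, biosynthetic_filter: bool
) -> tuple[np.ndarray, tuple[GlycanComposition, ...]]:
    """All in-bounds compositions with their sodiated m/z, sorted by m/z."""
    comps: list[GlycanComposition] = []
    for h, n, f, e, l in itertools.product(*bounds.ranges()):
        if h + n + f + e + l < 1:
            continue
        comp = GlycanComposition(h, n, f, e, l)
        if biosynthetic_filter and not biosynthetically_plausible(comp):
            continue
        comps.append(comp)
    masses = np.array([theoretical_mz(c) for c in comps])
    order = np.argsort(masses, kind="stable")
    return masses[order], tuple(comps[i] for i in order)


def enumerate_compositions(
    mz: float,
    tol_ppm: float = 20.0,
    bounds: CompositionBounds | None = None,
    biosynthetic_filter: bool = True,
) -> set[GlycanComposition]:
    """All compositions within ``tol_ppm`` of ``mz`` under the given bounds.

    Returns an (order-independent) set; an empty set is a valid result.
    """
    if mz <= 0:
        raise ValueError("mz must be positive")
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    bounds = bounds or DEFAULT_BOUNDS
    masses, comps = _composition_table(bounds, biosynthetic_filter)
    lo = mz * (1.0 - tol_ppm * 1e-6)
    hi = mz * (1.0 + tol_ppm * 1e-6)
    i, j = np.searchsorted(masses, (lo, hi))
    return set(comps[i:j])


def rank_candidates(
    observed_mz: float, candidates: Iterable[GlycanComposition]
) -> list[GlycanComposition]:
    """Candidates sorted by |ppm error|, then by fewest residues.

    The first element is the single "most probable" assignment reported for a
    peak; the full list is retained for the multi-assignment trait calculus.
    """
    return sorted(
        candidates,
        key=lambda c: (abs(ppm_error(observed_mz, theoretical_mz(c))), c.total_residues, str(c)),
    )


def best_candidate(
    observed_mz: float, candidates: Iterable[GlycanComposition]
) -> GlycanComposition | None:
    ranked = rank_candidates(observed_mz, candidates)
    return ranked[0] if ranked else None


@functools.lru_cache(maxsize=None)
def _element_abundances(symbol: str) -> tuple[float, ...]:
    """Isotope abundances of one element indexed by nucleon-number offset."""
    entries = sorted(
        (number, data[1])
        for number, data in _pmass.nist_mass[symbol].items()
        if number != 0 and data[1] > 0
    )
    if not entries:  # monoisotopic-only entries store abundance 0; treat as pure
        return (1.0,)
    base = entries[0][0]
    vec = [0.0] * (entries[-1][0] - base + 1)
    for number, abundance in entries:
        vec[number - base] = abundance
    return tuple(vec)


def _convolve_power(dist: np.ndarray, n: int, keep: int) -> np.ndarray:
    """dist convolved with itself n times, truncated to ``keep`` terms."""
    result = np.array([1.0])
    base = dist[:keep].copy()
    while n > 0:
        if n & 1:
            result = np.convolve(result, base)[:keep]
        n >>= 1
        if n:
            base = np.convolve(base, base)[:keep]
    return result


@functools.lru_cache(maxsize=4096)
def _isotope_pattern_cached(
    composition: GlycanComposition, n_peaks: int
) -> tuple[float, ...]:
    formula = composition.formula(sodiated=True)
    dist = np.array([1.0])
    for element, count in formula.items():
        elem = np.asarray(_element_abundances(element))
        dist = np.convolve(dist, _convolve_power(elem, count, n_peaks))[:n_peaks]
    if len(dist) < n_peaks:
        dist = np.pad(dist, (0, n_peaks - len(dist)))
    dist = dist / dist.sum()
    return tuple(dist)


def isotope_pattern(
    composition: "GlycanComposition | str", n_peaks: int = 4
) -> np.ndarray:
    """Relative abundances of the first ``n_peaks`` isotopologues.

    Aggregated (nucleon-count) isotopologue distribution of the full sodiated
    elemental formula, computed by per-element polynomial convolution and
    normalized to sum to 1.
    """
    if n_peaks < 2:
        raise ValueError("n_peaks must be >= 2")
    composition = _as_composition(composition)
    return np.asarray(_isotope_pattern_cached(composition, int(n_peaks)))


def interpret_losses(
    precursor_mz: float,
    fragment_mzs: Sequence[float],
    tol_da: float = 0.1,
) -> list[tuple[float, str]]:
    """Match precursor-fragment mass deltas against residue masses.

    Returns one ``(fragment_mz, residue_class)`` tuple per match; a fragment
    whose delta matches several residue classes is reported once per class.
    """
    if tol_da <= 0:
        raise ValueError("tol_da must be positive")
    matches: list[tuple[float, str]] = []
    for fragment in fragment_mzs:
        delta = precursor_mz - fragment
        for residue in RESIDUE_ORDER:
            if abs(delta - residue_mass(residue)) <= tol_da:
                matches.append((fragment, residue))
    return matches


def write_residue_table(path: "str | Path") -> None:
    """Export the residue mass table as tab-delimited text."""
    lines = ["residue\tformula\tmonoisotopic_mass"]
    for residue in RESIDUE_ORDER:
        lines.append(
            f"{residue}\t{residue_formula_string(residue)}\t{residue_mass(residue):.6f}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
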