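"""Peak integration, internal recalibration, QC filtering and normalization.

The processing chain mirrors the standard reflectron MALDI-TOF glycomics
workflow: detect isotopic-envelope apexes, refine apex m/z by parabolic
interpolation, recalibrate internally against glycans of known unique
composition, integrate background-subtracted areas over the first
isotopologues, propose candidate compositions by accurate mass, score the
observed envelope against the theoretical isotopologue pattern, and keep only
signals passing all three quality gates: isotopic-fit score >= 0.95, S/N > 2
and a mass-shift window of +/-20 ppm.  Kept areas are expressed as
percentages of the summed kept signal (TIC normalization).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal as _signal

from .chem import (
    DEFAULT_BOUNDS,
    ISOTOPE_SPACING,
    CompositionBounds,
    GlycanComposition,
    enumerate_compositions,
    isotope_pattern,
    ppm_error,
    rank_candidates,
    theoretical_mz,
)

__all__ = [
    "QCThresholds",
    "CalibrationModel",
    "integrate_peak",
    "detect_apexes",
    "recalibrate",
    "isotopic_fit_score",
    "qc_filter",
    "normalize_tic",
    "process_spectrum",
    "process_cohort",
    "PEAK_COLUMNS",
]

PEAK_COLUMNS = (
    "mz_observed",
    "mz_corrected",
    "area",
    "percent",
    "sn",
    "isotopic_score",
    "ppm",
    "best_candidate",
    "candidates",
    "n_candidates",
    "kept",
    "reasons",
)

_MAD_TO_SIGMA = 1.4826


@dataclass(frozen=True)
class QCThresholds:
    """Signal-quality gates: score >= 0.95, S/N > 2, |ppm| <= 20 by default."""

    min_isotopic_score: float = 0.95
    min_sn: float = 2.0
    max_abs_ppm: float = 20.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.min_isotopic_score <= 1.0):
            raise ValueError("min_isotopic_score must lie in [0, 1]")
        if self.min_sn <= 0 or self.max_abs_ppm <= 0:
            raise ValueError("min_sn and max_abs_ppm must be positive")


def _spectrum_arrays(spectrum) -> tuple[np.ndarray, np.ndarray]:
    if hasattr(spectrum, "mz") and hasattr(spectrum, "intensity"):
        return np.asarray(spectrum.mz, float), np.asarray(spectrum.intensity, float)
    mz, intensity = spectrum
    return np.asarray(mz, float), np.asarray(intensity, float)


def _local_background(
    mz: np.ndarray,
    intensity: np.ndarray,
    centers: Sequence[float],
    exclude_halfwidth: float = 0.35,
    annulus: float = 7.0,
) -> tuple[float, float]:
    """Robust (median, sigma) of the background around a peak chain.

    Points within ``annulus`` Da of the chain but farther than
    ``exclude_halfwidth`` from every chain window center are used; the noise
    sigma is the scaled median absolute deviation.
    """
    lo = min(centers) - annulus
    hi = max(centers) + annulus
    i0, i1 = np.searchsorted(mz, (lo, hi))
    seg_mz = mz[i0:i1]
    seg_y = intensity[i0:i1]
    mask = np.ones(seg_mz.size, dtype=bool)
    for c in centers:
        mask &= np.abs(seg_mz - c) > exclude_halfwidth
    background = seg_y[mask]
    if background.size < 10:
        return 0.0, 0.0
    baseline = float(np.median(background))
    noise = _MAD_TO_SIGMA * float(np.median(np.abs(background - baseline)))
    return baseline, noise


def integrate_peak(
    spectrum, window: tuple[float, float]
) -> tuple[float, float]:
    """Background-subtracted AUC and S/N of one peak window.

    The baseline is the local median (and the noise the scaled MAD) of points
    near the window but outside it; the area is the trapezoidal integral of
    the intensity above the baseline, clipped at zero, and the S/N is the
    apex height above baseline divided by the noise estimate.
    """
    mz, intensity = _spectrum_arrays(spectrum)
    lo, hi = window
    if hi <= lo:
        raise ValueError("empty integration window")
    i0, i1 = np.searchsorted(mz, (lo, hi))
    if i1 - i0 < 2:
        raise ValueError("integration window contains no spectrum points")
    center = 0.5 * (lo + hi)
    baseline, noise = _local_background(
        mz, intensity, [center], exclude_halfwidth=0.5 * (hi - lo)
    )
    above = np.clip(intensity[i0:i1] - baseline, 0.0, None)
    area = float(np.trapezoid(above, mz[i0:i1]))
    apex = float(intensity[i0:i1].max() - baseline)
    if noise <= 0:
        sn = float("inf") if apex > 0 else 0.0
    else:
        sn = apex / noise
    return area, sn


def _refine_apex(mz: np.ndarray, intensity: np.ndarray, index: int) -> float:
    """Sub-grid apex m/z by 3-point parabolic interpolation."""
    if index <= 0 or index >= mz.size - 1:
        return float(mz[index])
    y0, y1, y2 = intensity[index - 1 : index + 2]
    denom = y0 - 2.0 * y1 + y2
    if denom >= 0:
        return float(mz[index])
    shift = 0.5 * (y0 - y2) / denom
    shift = float(np.clip(shift, -1.0, 1.0))
    return float(mz[index] + shift * (mz[index + 1] - mz[index]))


def detect_apexes(
    spectrum, min_height: float | None = None
) -> pd.DataFrame:
    """Local-maximum apexes above a robust global threshold.

    Returns a frame with columns ``mz`` (parabolically refined), ``height``
    and ``index``.
    """
    mz, intensity = _spectrum_arrays(spectrum)
    if min_height is None:
        med = float(np.median(intensity))
        mad = _MAD_TO_SIGMA * float(np.median(np.abs(intensity - med)))
        floor = 1e-3 * (float(intensity.max()) - med)
        min_height = med + max(5.0 * mad, floor, 1e-12)
    idx, _ = _signal.find_peaks(intensity, height=min_height)
    return pd.DataFrame(
        {
            "mz": [_refine_apex(mz, intensity, i) for i in idx],
            "height": intensity[idx],
            "index": idx,
        }
    )


@dataclass(frozen=True)
class CalibrationModel:
    """Fitted mass-drift model: constant ppm offset or linear in m/z."""

    kind: str
    coef: tuple[float, ...]
    calibrants: tuple[str, ...]
    residual_ppm: Mapping[str, float] = field(default_factory=dict)

    def ppm_at(self, mz: "float | np.ndarray") -> "float | np.ndarray":
        if self.kind == "constant":
            return np.broadcast_to(self.coef[0], np.shape(mz)).astype(float) if np.ndim(mz) else float(self.coef[0])
        slope, intercept = self.coef
        return slope * np.asarray(mz, float) + intercept

    def apply(self, mz: "float | np.ndarray") -> "float | np.ndarray":
        """Corrected m/z: observed / (1 + drift_ppm * 1e-6)."""
        return np.asarray(mz, float) / (1.0 + self.ppm_at(mz) * 1e-6) if np.ndim(mz) else float(mz) / (1.0 + self.ppm_at(mz) * 1e-6)

    def invert(self, mz: "float | np.ndarray") -> "float | np.ndarray":
        return np.asarray(mz, float) * (1.0 + self.ppm_at(mz) * 1e-6)


def recalibrate(
    observed_mz: Iterable[float],
    calibrants: Sequence["GlycanComposition | str"],
    pre_tol_ppm: float = 50.0,
    model: str = "constant",
) -> CalibrationModel:
    """Fit an internal mass-drift model against univocal calibrant glycans.

    Each calibrant's theoretical sodiated m/z is matched to the nearest
    observed peak within ``pre_tol_ppm``; at least 3 matches are required.
    The drift model minimizes squared ppm residuals.
    """
    observed = np.sort(np.asarray(list(observed_mz), float))
    if model not in ("constant", "linear"):
        raise ValueError(f"unknown drift model {model!r}")
    matched: list[tuple[str, float, float]] = []
    for calibrant in calibrants:
        comp = (
            calibrant
            if isinstance(calibrant, GlycanComposition)
            else GlycanComposition.from_string(str(calibrant))
        )
        theo = theoretical_mz(comp)
        if observed.size == 0:
            continue
        j = int(np.clip(np.searchsorted(observed, theo), 1, observed.size - 1))
        best = min(observed[j - 1 : j + 1], key=lambda m: abs(m - theo), default=None)
        if best is None:
            continue
        err = ppm_error(float(best), theo)
        if abs(err) <= pre_tol_ppm:
            matched.append((str(comp), float(best), err))
    if len(matched) < 3:
        raise ValueError(
            f"only {len(matched)} of {len(calibrants)} calibrants matched within "
            f"{pre_tol_ppm} ppm; at least 3 are required for recalibration"
        )
    mzs = np.array([m for _, m, _ in matched])
    errs = np.array([e for _, _, e in matched])
    if model == "constant":
        coef: tuple[float, ...] = (float(errs.mean()),)
    else:
        slope, intercept = np.polyfit(mzs, errs, 1)
        coef = (float(slope), float(intercept))
    fitted = CalibrationModel(model, coef, tuple(name for name, _, _ in matched))
    residuals = {
        name: ppm_error(float(fitted.apply(m)), theoretical_mz(name))
        for name, m, _ in matched
    }
    return CalibrationModel(model, coef, fitted.calibrants, residuals)


def isotopic_fit_score(
    observed_envelope: Sequence[float],
    composition: "GlycanComposition | str",
) -> float:
    """Cosine similarity between observed and theoretical envelope fractions.

    Both envelopes are normalized to sum 1 over the same number of
    isotopologues; the score lies in [0, 1] with 1 for identical shapes.
    """
    observed = np.asarray(observed_envelope, float)
    if observed.size < 2:
        raise ValueError("need at least 2 isotopologue areas")
    if observed.sum() <= 0:
        raise ValueError("observed envelope is all zero")
    observed = np.clip(observed, 0.0, None)
    observed = observed / observed.sum()
    theoretical = isotope_pattern(composition, n_peaks=observed.size)
    denom = np.linalg.norm(observed) * np.linalg.norm(theoretical)
    if denom == 0:
        return 0.0
    return float(np.clip(np.dot(observed, theoretical) / denom, 0.0, 1.0))


def qc_filter(
    peaks: pd.DataFrame, thresholds: QCThresholds | None = None
) -> pd.DataFrame:
    """Partition annotated peaks into kept/rejected with per-peak reasons.

    A peak is kept iff isotopic score >= threshold AND S/N strictly greater
    than the S/N threshold AND |ppm| within the shift window; every failed
    criterion is listed in ``reasons``.
    """
    thresholds = thresholds or QCThresholds()
    out = peaks.copy()
    reasons: list[str] = []
    kept: list[bool] = []
    for _, row in out.iterrows():
        failed: list[str] = []
        if pd.isna(row.get("best_candidate")) or row.get("best_candidate") in ("", None):
            failed.append("no_candidate")
        score = row.get("isotopic_score")
        if pd.isna(score) or score < thresholds.min_isotopic_score:
            failed.append("isotopic_score")
        sn = row.get("sn")
        if pd.isna(sn) or not sn > thresholds.min_sn:
            failed.append("sn")
        ppm = row.get("ppm")
        if pd.isna(ppm) or abs(ppm) > thresholds.max_abs_ppm:
            failed.append("ppm")
        reasons.append(",".join(failed))
        kept.append(not failed)
    out["kept"] = kept
    out["reasons"] = reasons
    return out


def normalize_tic(areas: Sequence[float]) -> np.ndarray:
    """Relative quantification: (area / sum of areas) x 100 per peak."""
    areas = np.asarray(areas, float)
    if areas.size == 0:
        raise ValueError("no kept peaks to normalize")
    if (areas < 0).any():
        raise ValueError("areas must be >= 0")
    total = areas.sum()
    if total <= 0:
        raise ValueError("total kept area is zero")
    return areas / total * 100.0


def _chain_heads(
    apex_mz: np.ndarray,
    apex_height: np.ndarray,
    tol: float = 0.08,
    min_pred_ratio: float = 0.3,
) -> np.ndarray:
    """Apexes that are not the +1 isotopologue of a lower-mass apex.

    A predecessor one isotope spacing below only claims an apex when its
    height is a plausible within-envelope fraction of it (adjacent
    isotopologue ratios never drop below ~0.3 going backwards for glycans in
    the working window); this keeps a species from being swallowed by the
    faint envelope tail of a near-coincident lighter species.
    """
    heads = []
    for m, h in zip(apex_mz, apex_height):
        predecessors = np.abs(apex_mz - (m - ISOTOPE_SPACING)) <= tol
        if not (predecessors & (apex_height >= min_pred_ratio * h)).any():
            heads.append(m)
    return np.asarray(heads)


def process_spectrum(
    spectrum,
    calibrants: Sequence["GlycanComposition | str"] | None = None,
    qc: QCThresholds | None = None,
    tol_ppm: float = 20.0,
    bounds: CompositionBounds | None = None,
    biosynthetic_filter: bool = True,
    n_isotopologues: int = 4,
    window_halfwidth: float = 0.15,
    pre_tol_ppm: float = 50.0,
    drift_model: str = "constant",
) -> tuple[pd.DataFrame, CalibrationModel | None]:
    """Full per-spectrum chain: pick, recalibrate, integrate, assign, QC.

    Returns the annotated peak table (one row per monoisotopic signal, columns
    :data:`PEAK_COLUMNS`) and the fitted calibration model (``None`` when no
    calibrants are supplied).
    """
    mz, intensity = _spectrum_arrays(spectrum)
    qc = qc or QCThresholds()
    bounds = bounds or DEFAULT_BOUNDS

    apexes = detect_apexes((mz, intensity))
    if apexes.empty:
        return pd.DataFrame(columns=list(PEAK_COLUMNS)), None

    model: CalibrationModel | None = None
    if calibrants:
        model = recalibrate(
            apexes["mz"].to_numpy(), calibrants, pre_tol_ppm=pre_tol_ppm, model=drift_model
        )

    heads = _chain_heads(apexes["mz"].to_numpy(), apexes["height"].to_numpy())
    records: list[dict] = []
    pattern_sums: dict[GlycanComposition, float] = {}
    for head in heads:
        centers = [head + k * ISOTOPE_SPACING for k in range(n_isotopologues)]
        baseline, noise = _local_background(mz, intensity, centers)
        envelope = np.zeros(n_isotopologues)
        for k, center in enumerate(centers):
            i0, i1 = np.searchsorted(
                mz, (center - window_halfwidth, center + window_halfwidth)
            )
            if i1 - i0 < 2:
                continue
            above = np.clip(intensity[i0:i1] - baseline, 0.0, None)
            envelope[k] = np.trapezoid(above, mz[i0:i1])
        i0, i1 = np.searchsorted(
            mz, (head - window_halfwidth, head + window_halfwidth)
        )
        apex_height = float(intensity[i0:i1].max() - baseline) if i1 > i0 else 0.0
        if noise <= 0:
            sn = float("inf") if apex_height > 0 else 0.0
        else:
            sn = apex_height / noise

        corrected = float(model.apply(head)) if model is not None else float(head)
        candidates = enumerate_compositions(
            corrected, tol_ppm=tol_ppm, bounds=bounds,
            biosynthetic_filter=biosynthetic_filter,
        )
        ranked = rank_candidates(corrected, candidates)
        best = ranked[0] if ranked else None
        if best is not None:
            ppm = ppm_error(corrected, theoretical_mz(best))
            score = (
                isotopic_fit_score(envelope, best) if envelope.sum() > 0 else float("nan")
            )
            # scale the integrated (truncated) envelope up to the full
            # isotopologue distribution so areas estimate total species signal
            if best not in pattern_sums:
                pattern_sums[best] = float(
                    isotope_pattern(best, n_peaks=max(n_isotopologues, 8))[
                        :n_isotopologues
                    ].sum()
                )
            area = float(envelope.sum() / pattern_sums[best])
        else:
            ppm = float("nan")
            score = float("nan")
            area = float(envelope.sum())
        records.append(
            {
                "mz_observed": float(head),
                "mz_corrected": corrected,
                "area": area,
                "sn": float(sn),
                "isotopic_score": score,
                "ppm": ppm,
                "best_candidate": str(best) if best is not None else "",
                "candidates": ";".join(str(c) for c in ranked),
                "n_candidates": len(ranked),
            }
        )

    table = qc_filter(pd.DataFrame(records), qc)
    table["percent"] = np.nan
    if table["kept"].any():
        kept_areas = table.loc[table["kept"], "area"].to_numpy()
        table.loc[table["kept"], "percent"] = normalize_tic(kept_areas)
    return table[list(PEAK_COLUMNS)], model


def process_cohort(
    cohort,
    calibrants: Sequence["GlycanComposition | str"] | None = None,
    **kwargs,
) -> dict[tuple[str, int, int], pd.DataFrame]:
    """Process every spectrum of a simulated cohort; keys are (group, bio, tech)."""
    tables: dict[tuple[str, int, int], pd.DataFrame] = {}
    for idx, row in cohort.manifest.iterrows():
        table, _ = process_spectrum(cohort.spectra[idx], calibrants=calibrants, **kwargs)
        tables[(row["group"], int(row["bio"]), int(row["tech"]))] = table
    return tables
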