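"""Replicate handling, PCA/Hotelling outlier screening and group comparisons.

The statistical unit is the biological replicate (protein extract): technical
replicates are averaged first, and two-group trait differences are tested per
trait with a two-sided Student's t-test (pooled variance by default, Welch on
request).  Outlier screening follows chemometric practice: samples are scored
in the space of the first two principal components of the normalized signal
matrix and excluded when their Hotelling T-squared exceeds the F-distribution
based 95% ellipse.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _stats
from sklearn.decomposition import PCA

__all__ = [
    "OutlierScreen",
    "average_replicates",
    "pca_hotelling_screen",
    "compare_groups",
    "significance_flag",
    "plot_scores",
]


def significance_flag(p: float) -> str:
    """Per-trait significance convention: ** for p<=0.01, * for p<=0.05."""
    if np.isnan(p):
        return "ns"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return "ns"


def average_replicates(
    traits: pd.DataFrame,
    group_col: str = "group",
    bio_col: str = "bio",
    tech_col: str = "tech",
    expected_bio: Mapping[str, Sequence[int]] | None = None,
) -> pd.DataFrame:
    """Mean of technical replicates within each biological replicate.

    ``traits`` holds one row per spectrum with ``group``/``bio``/``tech``
    label columns plus trait columns.  When ``expected_bio`` maps group
    labels to expected biological-replicate ids, a biological replicate with
    no surviving spectra raises an error naming it.
    """
    value_cols = [
        c for c in traits.columns if c not in (group_col, bio_col, tech_col)
    ]
    out = (
        traits.groupby([group_col, bio_col], sort=True)[value_cols]
        .mean()
        .reset_index()
    )
    if expected_bio is not None:
        present = {
            (row[group_col], row[bio_col]) for _, row in out.iterrows()
        }
        missing = [
            (group, bio)
            for group, bios in expected_bio.items()
            for bio in bios
            if (group, bio) not in present
        ]
        if missing:
            raise ValueError(
                f"biological replicates with no surviving technical spectra: {missing}"
            )
    return out


@dataclass(frozen=True)
class OutlierScreen:
    """PCA score-space screen with a Hotelling T-squared 95% boundary."""

    scores: pd.DataFrame  # columns PC1, PC2
    explained_variance_ratio: tuple[float, float]
    t2: pd.Series
    t2_critical: float
    excluded: tuple[object, ...]
    ellipse: tuple[float, float] = field(default=(0.0, 0.0))  # semi-axes


def pca_hotelling_screen(
    matrix: pd.DataFrame,
    alpha: float = 0.05,
    n_components: int = 2,
) -> OutlierScreen:
    """Screen samples in PCA score space against the Hotelling T^2 ellipse.

    ``matrix`` is samples x signals (e.g. normalized percentages per glycan).
    Data are mean-centered; T^2 is computed on the first two component scores
    and compared to the F-based critical value
    ``p (n-1)(n+1) / (n (n-p)) * F_{1-alpha}(p, n-p)``.
    """
    if not isinstance(matrix, pd.DataFrame):
        matrix = pd.DataFrame(np.asarray(matrix, float))
    n, m = matrix.shape
    if n < 3:
        raise ValueError("need at least 3 samples for outlier screening")
    if m < 2:
        raise ValueError("need at least 2 signals for outlier screening")
    p = min(n_components, m, n - 1)
    pca = PCA(n_components=p)
    scores = pca.fit_transform(matrix.to_numpy(float))
    # per-component score variance; guard components with ~zero variance
    variances = scores.var(axis=0, ddof=1)
    variances = np.where(variances > 1e-30, variances, np.inf)
    t2 = pd.Series((scores**2 / variances).sum(axis=1), index=matrix.index)
    f_crit = _stats.f.ppf(1.0 - alpha, p, n - p)
    t2_crit = p * (n - 1) * (n + 1) / (n * (n - p)) * f_crit
    excluded = tuple(t2.index[t2 > t2_crit])
    with np.errstate(invalid="ignore"):
        semi_axes = tuple(
            float(np.sqrt(t2_crit * v)) if np.isfinite(v) else 0.0
            for v in variances[:2]
        )
    score_df = pd.DataFrame(
        scores[:, :2],
        index=matrix.index,
        columns=["PC1", "PC2"] if p >= 2 else ["PC1"],
    )
    evr = tuple(float(x) for x in pca.explained_variance_ratio_[:2])
    if len(evr) < 2:
        evr = (evr[0], 0.0)
    return OutlierScreen(score_df, evr, t2, float(t2_crit), excluded, semi_axes)


def compare_groups(
    reference: pd.DataFrame,
    test: pd.DataFrame,
    traits: Sequence[str] | None = None,
    equal_var: bool = True,
    reference_label: str = "reference",
    test_label: str = "test",
) -> pd.DataFrame:
    """Two-sample two-sided Student's t-test per trait group.

    ``reference`` and ``test`` hold one row per biological replicate and one
    column per trait.  Zero variance in both groups with equal means yields
    p = 1 (not significant) rather than an error.
    """
    if traits is None:
        traits = [c for c in reference.columns if c in test.columns
                  and pd.api.types.is_numeric_dtype(reference[c])]
    if len(reference) < 2 or len(test) < 2:
        raise ValueError("need at least 2 biological replicates per group")
    rows = []
    for trait in traits:
        a = reference[trait].to_numpy(float)
        b = test[trait].to_numpy(float)
        if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
            t, p = (0.0, 1.0) if a.mean() == b.mean() else (np.inf, 0.0)
        else:
            t, p = _stats.ttest_ind(b, a, equal_var=equal_var)
        rows.append(
            {
                "trait": trait,
                f"{reference_label}_mean": a.mean(),
                f"{reference_label}_sd": a.std(ddof=1),
                f"{test_label}_mean": b.mean(),
                f"{test_label}_sd": b.std(ddof=1),
                "difference": b.mean() - a.mean(),
                "t": float(t),
                "p": float(p),
                "flag": significance_flag(float(p)),
            }
        )
    return pd.DataFrame(rows).set_index("trait")


def plot_scores(screen: OutlierScreen, path: "str | None" = None):
    """Score plot with the Hotelling 95% ellipse; returns the figure."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(screen.scores["PC1"], screen.scores.get("PC2", 0.0), s=30)
    for label in screen.excluded:
        row = screen.scores.loc[label]
        ax.annotate(str(label), (row["PC1"], row.get("PC2", 0.0)), color="red")
    a, b = screen.ellipse
    if a > 0 and b > 0:
        theta = np.linspace(0, 2 * np.pi, 200)
        ax.plot(a * np.cos(theta), b * np.sin(theta), "k--", lw=1)
    ax.set_xlabel(f"PC1 ({screen.explained_variance_ratio[0]:.0%})")
    ax.set_ylabel(f"PC2 ({screen.explained_variance_ratio[1]:.0%})")
    ax.axhline(0, color="0.8", lw=0.5)
    ax.axvline(0, color="0.8", lw=0.5)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
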