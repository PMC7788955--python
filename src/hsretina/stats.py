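"""Group statistics: t-tests on mouse scores, band-wise CIs, field heatmaps.

The genotype comparison is the unpaired two-tailed Student t-test on
per-mouse hyperspectral scores, with the pooled-variance form (degrees of
freedom n1 + n2 - 2) as default and Welch's unequal-variance form behind a
flag.  Band summaries collapse each mouse to its mean spectrum first —
mice, not pixels, are the independent replicates — and report per-band
group means with t-based 95% confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import CohortManifest, eccentricity_of
from .scoring import ScoreSet, SpectrumMatrix

__all__ = [
    "GroupComparison",
    "HeatmapTable",
    "ttest_mouse_scores",
    "band_summary",
    "heatmap_table",
]


@dataclass
class GroupComparison:
    """Two-sample comparison of mouse scores between genotype groups."""

    t_statistic: float
    degrees_of_freedom: float
    p_value: float
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    n_a: int
    n_b: int
    variant: str = "student"
    degenerate: bool = False

    def to_dict(self) -> dict:
        return asdict(self)


def ttest_mouse_scores(scores_a, scores_b, welch: bool = False
                       ) -> GroupComparison:
    """Unpaired two-tailed t-test on two groups of per-mouse scores.

    Student's pooled-variance form is the default (df = n1 + n2 - 2, the
    structure behind printed statistics like t14 for 8 vs 8 mice); Welch's
    form with Satterthwaite df is selected by ``welch=True``.  Degenerate
    zero-variance inputs are reported explicitly rather than as NaN:
    identical constant groups give t = 0, p = 1; zero pooled variance with
    unequal means gives a signed infinite t with p = 0 and the degenerate
    flag set.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError(
            f"each group needs >= 2 mice, got {a.size} and {b.size}"
        )
    n1, n2 = a.size, b.size
    m1, m2 = a.mean(), b.mean()
    v1, v2 = a.var(ddof=1), b.var(ddof=1)
    variant = "welch" if welch else "student"
    if welch:
        se_sq = v1 / n1 + v2 / n2
        if se_sq == 0.0:
            return _degenerate_comparison(m1, m2, v1, v2, n1, n2,
                                          float(n1 + n2 - 2), variant)
        df = se_sq ** 2 / ((v1 / n1) ** 2 / (n1 - 1)
                           + (v2 / n2) ** 2 / (n2 - 1))
        t = (m1 - m2) / np.sqrt(se_sq)
    else:
        df = float(n1 + n2 - 2)
        pooled = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
        if pooled == 0.0:
            return _degenerate_comparison(m1, m2, v1, v2, n1, n2, df, variant)
        t = (m1 - m2) / np.sqrt(pooled * (1.0 / n1 + 1.0 / n2))
    p = float(2.0 * sps.t.sf(abs(t), df))
    return GroupComparison(float(t), float(df), p, float(m1), float(m2),
                           float(np.sqrt(v1)), float(np.sqrt(v2)),
                           n1, n2, variant)


def _degenerate_comparison(m1, m2, v1, v2, n1, n2, df, variant):
    if m1 == m2:
        t, p = 0.0, 1.0
    else:
        t, p = float(np.sign(m1 - m2)) * np.inf, 0.0
    return GroupComparison(t, float(df), p, float(m1), float(m2),
                           float(np.sqrt(v1)), float(np.sqrt(v2)),
                           int(n1), int(n2), variant, degenerate=True)


def band_summary(matrix: SpectrumMatrix, level: str = "mouse",
                 ci: float = 0.95) -> pd.DataFrame:
    """Per-band group means with t-based confidence intervals.

    At ``level="mouse"`` (default) each mouse is first collapsed to its mean
    spectrum so every mouse counts once regardless of how many pixels it
    contributed; this requires >= 2 mice per class for the CI.  At
    ``level="pixel"`` rows are treated as replicates directly — useful for
    visual parity with pixel-population plots, not for inference.

    Returns a frame with one row per band: nm, per-class mean and CI bounds,
    mean difference, and a flag marking bands where the two CIs are disjoint.
    """
    if level not in ("mouse", "pixel"):
        raise ValueError(f"unknown level {level!r}")
    if not (0.0 < ci < 1.0):
        raise ValueError("ci must be in (0, 1)")
    groups: dict[str, np.ndarray] = {}
    for cls in ("AD", "CO"):
        rows = matrix.labels == cls
        if level == "mouse":
            mice = list(dict.fromkeys(matrix.mouse_ids[rows]))
            if len(mice) < 2:
                raise ValueError(
                    f"band_summary at mouse level needs >= 2 {cls} mice"
                )
            groups[cls] = np.vstack([
                matrix.X[rows & (matrix.mouse_ids == m)].mean(axis=0)
                for m in mice
            ])
        else:
            if rows.sum() < 2:
                raise ValueError(f"need >= 2 {cls} pixels at pixel level")
            groups[cls] = matrix.X[rows]
    out = {"nm": matrix.grid.as_array()}
    for cls, X in groups.items():
        n = X.shape[0]
        mean = X.mean(axis=0)
        sd = X.std(axis=0, ddof=1)
        tcrit = sps.t.ppf(0.5 + ci / 2.0, n - 1)
        half = tcrit * sd / np.sqrt(n)
        out[f"mean_{cls}"] = mean
        out[f"ci_lo_{cls}"] = mean - half
        out[f"ci_hi_{cls}"] = mean + half
    df = pd.DataFrame(out)
    df["diff"] = df["mean_AD"] - df["mean_CO"]
    df["ci_disjoint"] = (df["ci_lo_AD"] > df["ci_hi_CO"]) | \
                        (df["ci_lo_CO"] > df["ci_hi_AD"])
    return df


@dataclass
class HeatmapTable:
    """Per-mouse 8-field score grid plus eccentricity marginals."""

    table: pd.DataFrame          # index mouse_id, columns field 1..8 (NaN = absent)
    classes: pd.Series           # mouse_id -> class_label
    marginals: pd.DataFrame      # per mouse: central/peripheral means
    class_marginals: pd.DataFrame  # per class: central/peripheral means


def heatmap_table(score_set: ScoreSet,
                  manifest: CohortManifest | None = None) -> HeatmapTable:
    """Arrange field scores as a mouse x field grid with regional marginals.

    Fields a mouse was never imaged at (or whose pixels were all masked)
    stay absent (NaN) — never imputed as zero.  Marginal means split each
    mouse's fields into central (odd) and peripheral (even) locations.
    """
    fs = score_set.field_scores
    if fs.empty:
        raise ValueError("score set has no field scores")
    grid = fs.pivot(index="mouse_id", columns="field_id", values="field_score")
    grid = grid.reindex(columns=range(1, 9))
    if manifest is not None:
        grid = grid.reindex(index=manifest.mouse_ids)
        classes = pd.Series({m: manifest.class_of(m) for m in grid.index},
                            name="class_label")
    else:
        classes = fs.drop_duplicates("mouse_id").set_index("mouse_id")[
            "class_label"].reindex(grid.index)
    central_cols = [f for f in range(1, 9) if eccentricity_of(f) == "central"]
    periph_cols = [f for f in range(1, 9) if eccentricity_of(f) == "peripheral"]
    marginals = pd.DataFrame({
        "central_mean": grid[central_cols].mean(axis=1),
        "peripheral_mean": grid[periph_cols].mean(axis=1),
        "class_label": classes,
    })
    class_marginals = marginals.groupby("class_label")[
        ["central_mean", "peripheral_mean"]].mean()
    return HeatmapTable(grid, classes, marginals, class_marginals)
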