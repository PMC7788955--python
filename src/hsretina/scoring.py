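"""Between-class contrast spectrum and hyperspectral amyloid scores.

Retained pixel spectra from the whole cohort are stacked into one matrix
with a genotype label per row.  The contrast spectrum ``d`` is the per-band
mean difference between the amyloid (AD) and control (CO) pixel populations;
a pixel's hyperspectral score is the dot product of its normalized spectrum
with ``d``, and a mouse's score is the unweighted mean over all retained
pixels of all its imaged fields.

The core is the scikit-learn style :class:`ContrastScorer` estimator
(``fit`` learns ``d`` from labelled spectra, ``decision_function`` scores
spectra); the module-level functions are thin wrappers that speak the
pipeline's domain types.

Scoring is in-sample by default — the contrast is fitted on the same pixels
it scores, which is the procedure the group comparisons are built on, but is
optimistically biased as a group-separation estimate.  A leave-one-mouse-out
mode refits the contrast without the scored mouse for bias-aware use.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_array, check_is_fitted

from .io import CLASS_LABELS, CohortManifest, WavelengthGrid, eccentricity_of
from .preprocess import NormalizedCube

__all__ = [
    "SpectrumMatrix",
    "ContrastSpectrum",
    "ScoreSet",
    "ContrastScorer",
    "stack_spectra",
    "contrast_spectrum",
    "score_pixels",
    "aggregate_scores",
    "fit_and_score",
]


@dataclass
class SpectrumMatrix:
    """Stacked retained pixel spectra with per-row cohort annotations."""

    X: np.ndarray
    labels: np.ndarray
    mouse_ids: np.ndarray
    field_ids: np.ndarray
    grid: WavelengthGrid

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        self.mouse_ids = np.asarray(self.mouse_ids, dtype=object)
        self.field_ids = np.asarray(self.field_ids, dtype=int)
        n, b = self.X.shape
        if b != self.grid.band_count:
            raise ValueError("matrix width does not match wavelength grid")
        for name, arr in (("labels", self.labels),
                          ("mouse_ids", self.mouse_ids),
                          ("field_ids", self.field_ids)):
            if len(arr) != n:
                raise ValueError(f"{name} length {len(arr)} != {n} rows")
        unknown = set(self.labels) - set(CLASS_LABELS)
        if unknown:
            raise ValueError(f"unknown class labels {sorted(unknown)}")

    @property
    def n_pixels(self) -> int:
        return self.X.shape[0]

    def classes_present(self) -> set:
        return set(self.labels)

    def subset(self, rows: np.ndarray) -> "SpectrumMatrix":
        return SpectrumMatrix(self.X[rows], self.labels[rows],
                              self.mouse_ids[rows], self.field_ids[rows],
                              self.grid)


@dataclass
class ContrastSpectrum:
    """Per-band AD minus CO mean spectrum: the scoring direction."""

    d: np.ndarray
    grid: WavelengthGrid
    n_ad: int
    n_co: int

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=float)
        if self.d.shape != (self.grid.band_count,):
            raise ValueError("contrast length does not match wavelength grid")
        if not np.all(np.isfinite(self.d)):
            raise ValueError("contrast spectrum contains non-finite values")

    def norm_sq(self) -> float:
        return float(self.d @ self.d)


@dataclass
class ScoreSet:
    """Hyperspectral scores at pixel, field and mouse granularity."""

    pixel_scores: np.ndarray
    field_scores: pd.DataFrame
    mouse_scores: pd.DataFrame
    contrast: ContrastSpectrum
    mode: str = "in_sample"


class ContrastScorer(BaseEstimator):
    """Mean-difference spectral scorer (fit the contrast, score by dot product).

    Parameters
    ----------
    positive_class, negative_class : str
        Row labels whose per-band means are differenced
        (``positive - negative``); defaults ``"AD"`` and ``"CO"``.
    balance_mice : bool
        If True, each class mean is the mean of per-mouse mean spectra
        instead of pooling all pixels equally; requires ``mouse_ids`` at fit
        time.  Off by default: every retained pixel weighs equally.

    Attributes
    ----------
    contrast_ : ndarray of shape (n_bands,)
        Fitted per-band mean difference.
    n_positive_, n_negative_ : int
        Row counts (pixels) behind each class mean.
    """

    def __init__(self, positive_class: str = "AD",
                 negative_class: str = "CO", balance_mice: bool = False):
        self.positive_class = positive_class
        self.negative_class = negative_class
        self.balance_mice = balance_mice

    def fit(self, X, y, mouse_ids=None):
        X = check_array(X, dtype=float)
        y = np.asarray(y, dtype=object)
        if len(y) != X.shape[0]:
            raise ValueError("y length does not match X rows")
        for cls in (self.positive_class, self.negative_class):
            if not np.any(y == cls):
                raise ValueError(f"class {cls!r} has no rows in the matrix")
        pos, neg = (y == self.positive_class), (y == self.negative_class)
        if self.balance_mice:
            if mouse_ids is None:
                raise ValueError("balance_mice=True requires mouse_ids")
            mouse_ids = np.asarray(mouse_ids, dtype=object)
            mean_pos = self._balanced_mean(X[pos], mouse_ids[pos])
            mean_neg = self._balanced_mean(X[neg], mouse_ids[neg])
        else:
            mean_pos = X[pos].mean(axis=0)
            mean_neg = X[neg].mean(axis=0)
        self.contrast_ = mean_pos - mean_neg
        self.n_positive_ = int(pos.sum())
        self.n_negative_ = int(neg.sum())
        self.n_features_in_ = X.shape[1]
        return self

    @staticmethod
    def _balanced_mean(X: np.ndarray, mouse_ids: np.ndarray) -> np.ndarray:
        per_mouse = [X[mouse_ids == m].mean(axis=0)
                     for m in dict.fromkeys(mouse_ids)]
        return np.mean(per_mouse, axis=0)

    def decision_function(self, X) -> np.ndarray:
        check_is_fitted(self, "contrast_")
        X = check_array(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} bands, scorer was fitted on "
                f"{self.n_features_in_}"
            )
        return X @ self.contrast_

    # transform alias lets the scorer sit at the end of a sklearn Pipeline
    def transform(self, X) -> np.ndarray:
        return self.decision_function(X)[:, None]

    def fit_transform(self, X, y, **fit_params):
        return self.fit(X, y, **fit_params).transform(X)


# ---------------------------------------------------------------------------
# domain-typed wrappers
# ---------------------------------------------------------------------------

def stack_spectra(cubes: list, manifest: CohortManifest | None = None
                  ) -> SpectrumMatrix:
    """Stack retained pixel spectra of all cubes into one labelled matrix.

    Rows follow cube order (manifest order when a manifest is given), then
    row-major pixel order within each cube, so the stacking is deterministic.
    """
    if not cubes:
        raise ValueError("no cubes to stack")
    ordered = list(cubes)
    if manifest is not None:
        by_key = {(c.meta.mouse_id, c.meta.field_id): c for c in cubes}
        ordered = []
        for row in manifest.rows():
            key = (row.mouse_id, row.field_id)
            if key in by_key:
                ordered.append(by_key[key])
    grid = ordered[0].grid
    blocks, labels, mice, fields = [], [], [], []
    for nc in ordered:
        if not isinstance(nc, NormalizedCube):
            raise TypeError("stack_spectra expects NormalizedCube inputs")
        if nc.grid.nm != grid.nm:
            raise ValueError(
                "cubes carry different wavelength grids; a cohort must share one"
            )
        if nc.meta is None:
            raise ValueError("cube without provenance cannot be stacked")
        spectra = nc.retained_spectra()
        if spectra.shape[0] == 0:
            continue
        blocks.append(spectra)
        labels.append(np.full(spectra.shape[0], nc.meta.class_label, object))
        mice.append(np.full(spectra.shape[0], nc.meta.mouse_id, object))
        fields.append(np.full(spectra.shape[0], nc.meta.field_id, int))
    if not blocks:
        raise ValueError("no retained pixels anywhere in the cohort")
    return SpectrumMatrix(np.vstack(blocks), np.concatenate(labels),
                          np.concatenate(mice), np.concatenate(fields), grid)


def contrast_spectrum(matrix: SpectrumMatrix,
                      balance_mice: bool = False) -> ContrastSpectrum:
    """Per-band mean AD spectrum minus mean CO spectrum."""
    scorer = ContrastScorer(balance_mice=balance_mice)
    scorer.fit(matrix.X, matrix.labels, mouse_ids=matrix.mouse_ids)
    return ContrastSpectrum(scorer.contrast_, matrix.grid,
                            n_ad=scorer.n_positive_, n_co=scorer.n_negative_)


def score_pixels(matrix: SpectrumMatrix,
                 contrast: ContrastSpectrum) -> np.ndarray:
    """Dot product of every row spectrum with the contrast spectrum."""
    if contrast.grid.nm != matrix.grid.nm:
        raise ValueError("contrast and matrix wavelength grids differ")
    return matrix.X @ contrast.d


def aggregate_scores(pixel_scores: np.ndarray, matrix: SpectrumMatrix,
                     contrast: ContrastSpectrum,
                     mode: str = "in_sample") -> ScoreSet:
    """Collapse pixel scores to per-field and per-mouse means.

    The mouse score is the unweighted mean over all of the mouse's retained
    pixels pooled across fields — not the mean of field means; the latter is
    reported alongside for comparison.
    """
    pixel_scores = np.asarray(pixel_scores, dtype=float)
    if pixel_scores.shape != (matrix.n_pixels,):
        raise ValueError("pixel_scores length does not match matrix rows")
    if pixel_scores.size == 0:
        raise ValueError("no pixel scores to aggregate")
    df = pd.DataFrame({
        "mouse_id": matrix.mouse_ids.astype(str),
        "class_label": matrix.labels.astype(str),
        "field_id": matrix.field_ids,
        "score": pixel_scores,
    })
    field_scores = (
        df.groupby(["mouse_id", "class_label", "field_id"], sort=False)
        .agg(n_pixels=("score", "size"), field_score=("score", "mean"))
        .reset_index()
    )
    field_scores["eccentricity"] = field_scores["field_id"].map(eccentricity_of)
    mouse_scores = (
        df.groupby(["mouse_id", "class_label"], sort=False)
        .agg(n_pixels=("score", "size"), mouse_score=("score", "mean"))
        .reset_index()
    )
    mean_of_fields = (
        field_scores.groupby("mouse_id", sort=False)["field_score"]
        .mean().rename("mean_of_field_means")
    )
    mouse_scores = mouse_scores.merge(mean_of_fields, on="mouse_id")
    return ScoreSet(pixel_scores, field_scores, mouse_scores, contrast, mode)


def fit_and_score(matrix: SpectrumMatrix, mode: str = "in_sample",
                  balance_mice: bool = False) -> ScoreSet:
    """Fit the contrast and score the cohort.

    ``in_sample`` follows the reference procedure: one contrast from all
    pixels, scores for those same pixels.  ``leave_one_mouse_out`` rescoring
    refits the contrast without the scored mouse (needs >= 2 mice per class)
    and removes the in-sample optimism.
    """
    if mode not in ("in_sample", "leave_one_mouse_out"):
        raise ValueError(f"unknown scoring mode {mode!r}")
    full_contrast = contrast_spectrum(matrix, balance_mice=balance_mice)
    if mode == "in_sample":
        scores = score_pixels(matrix, full_contrast)
        return aggregate_scores(scores, matrix, full_contrast, mode)
    # LOMO: every held-out fit must keep both classes populated
    for cls in CLASS_LABELS:
        mice = set(matrix.mouse_ids[matrix.labels == cls])
        if len(mice) < 2:
            raise ValueError(
                f"leave-one-mouse-out needs >= 2 mice in class {cls}, "
                f"found {len(mice)}"
            )
    scores = np.empty(matrix.n_pixels)
    for mouse in dict.fromkeys(matrix.mouse_ids):
        held = matrix.mouse_ids == mouse
        rest = matrix.subset(~held)
        c = contrast_spectrum(rest, balance_mice=balance_mice)
        scores[held] = matrix.X[held] @ c.d
    return aggregate_scores(scores, matrix, full_contrast,
                            "leave_one_mouse_out")
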