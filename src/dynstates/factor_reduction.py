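"""Varimax-rotated PCA for superordinate traits and diffusion patterns.

Two uses share one engine: reducing the five NEO-FFI dimension totals
to a single superordinate *emotional instability* score (high
Neuroticism, moderate Openness, low Extraversion / Agreeableness /
Conscientiousness), and extracting the leading pattern of white-matter
microstructure from subjects x ROI diffusion tables.

The engine z-scores columns, performs PCA by singular value
decomposition, optionally varimax-rotates a retained subset of the
unit-norm component coefficient vectors (Kaiser row-normalised by
default), and computes regression scores in the rotated basis.  The
varimax step itself is delegated to
``statsmodels.multivariate.factor_rotation``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.multivariate.factor_rotation import rotate_factors

from .synthetic_cohort import JHU_ROI_NAMES, NEO_DIMENSIONS

__all__ = [
    "FactorResult",
    "standardize_and_pca",
    "varimax_rotate",
    "varimax_criterion",
    "superordinate_scores",
    "dti_pc1",
]


@dataclass
class FactorResult:
    """PCA / rotated-PCA decomposition of a standardised table."""

    columns: list[str]
    mean: np.ndarray
    sd: np.ndarray
    eigenvalues: np.ndarray  # all correlation-matrix eigenvalues
    loadings_unrotated: np.ndarray  # (p, m) unit-norm coefficient vectors
    loadings: np.ndarray  # (p, m) after rotation (== unrotated if none)
    rotation: np.ndarray  # (m, m) orthogonal
    variance_explained: np.ndarray  # fraction per retained component
    scores: np.ndarray  # (n, m) subject scores
    rotated: bool = False

    @property
    def n_retained(self) -> int:
        return self.loadings.shape[1]


def _standardize(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    x = table.to_numpy(dtype=float)
    if x.shape[0] < 2:
        raise ValueError("need at least 2 rows")
    if np.isnan(x).any():
        raise ValueError("table contains missing values")
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    dead = np.nonzero(sd == 0)[0]
    if dead.size:
        names = [table.columns[i] for i in dead]
        raise ValueError(f"zero-variance column(s): {names}")
    return (x - mean) / sd, mean, sd


def standardize_and_pca(
    table: pd.DataFrame, n_retain: int | None = None
) -> FactorResult:
    """Column z-scoring followed by SVD-based PCA.

    ``n_retain`` selects how many components are kept for scores and
    (later) rotation; by default the Kaiser criterion retains the
    components whose correlation-matrix eigenvalue exceeds 1 (always at
    least one).
    """
    z, mean, sd = _standardize(table)
    n, p = z.shape
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    eigenvalues = s**2 / (n - 1)
    if n_retain is None:
        m = max(int(np.sum(eigenvalues > 1.0)), 1)
    else:
        if not 1 <= n_retain <= len(eigenvalues):
            raise ValueError(f"n_retain must be in 1..{len(eigenvalues)}")
        m = n_retain
    loadings = vt.T[:, :m]
    return FactorResult(
        columns=list(table.columns),
        mean=mean,
        sd=sd,
        eigenvalues=eigenvalues,
        loadings_unrotated=loadings,
        loadings=loadings.copy(),
        rotation=np.eye(m),
        variance_explained=eigenvalues[:m] / p,
        scores=z @ loadings,
        rotated=False,
    )


def varimax_criterion(loadings: np.ndarray) -> float:
    """Raw varimax objective: summed column variance of squared loadings."""
    sq = np.asarray(loadings, dtype=float) ** 2
    return float(np.sum(sq.var(axis=0)))


def varimax_rotate(
    result: FactorResult, kaiser_normalize: bool = True
) -> FactorResult:
    """Varimax-rotate the retained loadings of a PCA result.

    Rows are Kaiser-normalised (divided by the square root of their
    communality) before rotation by default, matching the common
    factor-rotation convention.  Scores are recomputed as regression
    scores in the rotated basis, and rotated components are reordered
    by descending explained variance so "component 1" is always the
    highest-variance rotated pattern.
    """
    m = result.n_retained
    a = result.loadings_unrotated
    if m == 1:
        return result
    if kaiser_normalize:
        h = np.sqrt((a**2).sum(axis=1))
        h = np.where(h > 0, h, 1.0)
        l_rot, rotation = rotate_factors(a / h[:, None], "varimax")
        l_rot = l_rot * h[:, None]
    else:
        l_rot, rotation = rotate_factors(a, "varimax")
    # Regression scores: Z approx S L', so S = Z L (L'L)^{-1}.
    z = (
        result.scores @ result.loadings_unrotated.T
    )  # standardised data restricted to the retained subspace
    scores = z @ l_rot @ np.linalg.inv(l_rot.T @ l_rot)
    p = a.shape[0]
    var = scores.var(axis=0, ddof=1) / p
    order = np.argsort(-var)
    return FactorResult(
        columns=result.columns,
        mean=result.mean,
        sd=result.sd,
        eigenvalues=result.eigenvalues,
        loadings_unrotated=result.loadings_unrotated,
        loadings=l_rot[:, order],
        rotation=rotation[:, order],
        variance_explained=var[order],
        scores=scores[:, order],
        rotated=True,
    )


def _orient(result: FactorResult, component: int, sign: float) -> None:
    """Flip one rotated component in place so its key loading has ``sign``."""
    if sign < 0:
        result.loadings[:, component] *= -1
        result.rotation[:, component] *= -1
        result.scores[:, component] *= -1


def superordinate_scores(
    bigfive: pd.DataFrame,
    n_retain: int | None = None,
    kaiser_normalize: bool = True,
) -> tuple[pd.Series, pd.Series]:
    """Emotional-instability scores from a Big Five table.

    The five dimension totals are z-scored and decomposed by PCA with
    varimax rotation; the component with the largest absolute
    Neuroticism loading is selected (robust to rotation reordering) and
    oriented so that the Neuroticism loading is positive, making higher
    scores mean higher emotional instability.

    Returns the per-subject scores and the component's loadings on the
    five dimensions.
    """
    cols = {c.lower(): c for c in bigfive.columns}
    missing = [d for d in NEO_DIMENSIONS if d not in cols]
    if missing:
        raise ValueError(f"missing Big Five column(s): {missing}")
    table = bigfive[[cols[d] for d in NEO_DIMENSIONS]]
    result = varimax_rotate(
        standardize_and_pca(table, n_retain=n_retain),
        kaiser_normalize=kaiser_normalize,
    )
    neuro_row = 0  # NEO_DIMENSIONS orders neuroticism first
    comp = int(np.argmax(np.abs(result.loadings[neuro_row])))
    _orient(result, comp, result.loadings[neuro_row, comp])
    scores = pd.Series(
        result.scores[:, comp], index=bigfive.index, name="emotional_instability"
    )
    loadings = pd.Series(
        result.loadings[:, comp], index=list(NEO_DIMENSIONS), name="loading"
    )
    return scores, loadings


def dti_pc1(
    roi_table: pd.DataFrame,
    n_retain: int | None = None,
    kaiser_normalize: bool = True,
) -> tuple[pd.Series, pd.Series]:
    """Leading rotated component of a subjects x ROI diffusion table.

    The table must hold exactly the 46 skeleton-ROI columns.  After
    z-scoring, PCA and varimax rotation, the highest-variance rotated
    component is oriented so that its mean ROI coefficient is positive
    (lower white-matter values then map to lower subject scores).

    Returns per-subject scores and the per-ROI coefficient map.
    """
    n_rois = len(JHU_ROI_NAMES)
    numeric = roi_table.select_dtypes(include=[np.number])
    if numeric.shape[1] != n_rois:
        raise ValueError(
            f"expected {n_rois} ROI columns, got {numeric.shape[1]}"
        )
    result = varimax_rotate(
        standardize_and_pca(numeric, n_retain=n_retain),
        kaiser_normalize=kaiser_normalize,
    )
    comp = 0  # components are ordered by descending explained variance
    _orient(result, comp, float(result.loadings[:, comp].mean()))
    scores = pd.Series(
        result.scores[:, comp], index=roi_table.index, name="dti_pc1"
    )
    coefficients = pd.Series(
        result.loadings[:, comp], index=list(numeric.columns), name="coefficient"
    )
    return scores, coefficients
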