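"""PCA decomposition and the per-day boxplot outlier screen.

Outliers are flagged per (sample_type, day) group on the first three
principal-component scores: an observation is an outlier when its score
lies further than ``k`` interquartile ranges from the group *median*
(the convention used in the source workflow).  The standard Tukey
variant, with fences measured from the quartiles, is available via
``convention="tukey"``; the two genuinely differ.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .spectra import SpectraTable

__all__ = ["PCAModel", "fit_pca", "boxplot_outliers", "remove_outliers"]

log = logging.getLogger(__name__)


@dataclass
class PCAModel:
    column_means: np.ndarray
    loadings: np.ndarray                    # (n_components, n_wavelengths)
    scores: np.ndarray                      # (n_rows, n_components)
    explained_variance_fraction: np.ndarray

    def transform(self, values: np.ndarray) -> np.ndarray:
        return (values - self.column_means) @ self.loadings.T


def fit_pca(table: SpectraTable | np.ndarray, n_components: int) -> PCAModel:
    """Centered PCA with a fixed sign convention.

    Each loading vector is flipped so that its largest-magnitude element
    is positive; scores are flipped accordingly, so reconstruction is
    unaffected.
    """
    values = table.values if isinstance(table, SpectraTable) else np.asarray(table, float)
    n, p = values.shape
    if n < 2:
        raise ValueError("PCA needs at least 2 rows")
    if n_components > min(n - 1, p):
        raise ValueError(f"n_components must be <= min(n_rows - 1, n_wavelengths) "
                         f"= {min(n - 1, p)}")
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(values)
    loadings = pca.components_.copy()
    flip = np.sign(loadings[np.arange(n_components),
                            np.abs(loadings).argmax(axis=1)])
    loadings *= flip[:, None]
    scores = scores * flip[None, :]
    return PCAModel(pca.mean_, loadings, scores,
                    pca.explained_variance_ratio_.copy())


def _quartiles(x: np.ndarray) -> tuple[float, float, float]:
    q1, med, q3 = np.percentile(x, [25, 50, 75])  # linear interpolation
    return q1, med, q3


def boxplot_outliers(scores: np.ndarray, groups, components: tuple[int, ...] = (1, 2, 3),
                     whisker_k: float = 1.5, convention: str = "median",
                     min_group: int = 4) -> np.ndarray:
    """Boxplot-rule outlier mask, per group and per listed component.

    Parameters
    ----------
    scores : (n_rows, >= max(components)) PC score matrix.
    groups : per-row group keys (sequence of hashables, or a DataFrame
        whose rows are used as keys).
    components : 1-based PC indices screened; the final mask is the union.
    convention : ``median`` fences the interval
        [median - k*IQR, median + k*IQR]; ``tukey`` uses
        [Q1 - k*IQR, Q3 + k*IQR].
    """
    scores = np.asarray(scores, float)
    if isinstance(groups, pd.DataFrame):
        keys = [tuple(r) for r in groups.itertuples(index=False)]
    else:
        keys = list(groups)
    if len(keys) != scores.shape[0]:
        raise ValueError("groups must align with score rows")
    if convention not in ("median", "tukey"):
        raise ValueError("convention must be 'median' or 'tukey'")
    if max(components) > scores.shape[1]:
        raise ValueError("requested component beyond fitted scores")
    mask = np.zeros(scores.shape[0], dtype=bool)
    order: dict = {}
    for i, k in enumerate(keys):
        order.setdefault(k, []).append(i)
    for key, idx in order.items():
        idx = np.array(idx)
        if idx.size < min_group:
            warnings.warn(f"group {key!r} has fewer than {min_group} rows; skipped",
                          stacklevel=2)
            continue
        for comp in components:
            x = scores[idx, comp - 1]
            q1, med, q3 = _quartiles(x)
            iqr = q3 - q1
            if convention == "median":
                lo, hi = med - whisker_k * iqr, med + whisker_k * iqr
            else:
                lo, hi = q1 - whisker_k * iqr, q3 + whisker_k * iqr
            mask[idx] |= (x < lo) | (x > hi)
    return mask


def remove_outliers(table: SpectraTable, mask: np.ndarray) -> SpectraTable:
    """Drop masked rows, logging the removal fraction."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape[0] != table.n_rows:
        raise ValueError("mask must align with table rows")
    if mask.all():
        raise ValueError("outlier mask removes every row")
    frac = mask.mean()
    log.info("removed %d of %d rows (%.1f%%) as outliers",
             mask.sum(), mask.size, 100 * frac)
    return table.select_rows(~mask, tag=f"outliers_removed[{frac:.3f}]")
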