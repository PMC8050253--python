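"""Autoscaling, PCA of peak areas, and signal-expression correlation.

The peak-area matrix (genes x samples) is autoscaled per gene — mean 0,
unit standard deviation (ddof=1) across samples — and decomposed by PCA
with samples as observations and genes as variables, so sample scores
separate tissues and gene loadings identify the drivers. Pearson
correlations relate log10 promoter signal to log10 RPKM, within a tissue
and as a between-tissue relative difference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import warn

__all__ = [
    "PCAResult",
    "CorrelationReport",
    "autoscale",
    "pca",
    "correlate_log",
    "relative_difference_correlation",
]


@dataclass
class PCAResult:
    scores: pd.DataFrame  # samples x components
    loadings: pd.DataFrame  # genes x components
    variance_fraction: np.ndarray

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


@dataclass
class CorrelationReport:
    r: float
    n: int
    p: float
    dropped: list[str]


def autoscale(areas: pd.DataFrame) -> pd.DataFrame:
    """Standardize each gene (row) across samples: mean 0, sd 1 (ddof=1).

    Rows with zero variance carry no comparative information and are
    dropped with a warning. A consequence of this convention is that for
    any grouping of the samples, the group-size-weighted mean of the
    per-group means of a scaled row is exactly 0.
    """
    if areas.shape[1] < 2:
        raise ValueError("autoscaling needs at least 2 samples")
    sd = areas.std(axis=1, ddof=1)
    constant = sd == 0
    if constant.any():
        warn(
            f"{int(constant.sum())} zero-variance genes dropped before "
            f"autoscaling: {list(areas.index[constant])[:5]}"
        )
    kept = areas.loc[~constant]
    return kept.sub(kept.mean(axis=1), axis=0).div(sd[~constant], axis=0)


def pca(scaled: pd.DataFrame) -> PCAResult:
    """PCA with samples as observations and genes as variables.

    ``scaled`` is genes x samples (as returned by :func:`autoscale`);
    observations are its columns. Computed by SVD of the column-centered
    observation matrix. Sign convention: each component's loading vector
    is oriented so its largest-magnitude entry is positive.
    """
    X = scaled.T.to_numpy(dtype=float)  # samples x genes
    if X.shape[0] < 2:
        raise ValueError("PCA needs at least 2 observations")
    Xc = X - X.mean(axis=0)
    if not np.any(Xc):
        raise ValueError("degenerate matrix: no variance to decompose")
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    # orient each component so its largest-|.| loading is positive
    flip = np.sign(Vt[np.arange(Vt.shape[0]), np.argmax(np.abs(Vt), axis=1)])
    flip[flip == 0] = 1.0
    Vt = Vt * flip[:, None]
    U = U * flip[None, :]
    scores = U * s
    var = s**2
    comp_names = [f"PC{i + 1}" for i in range(len(s))]
    return PCAResult(
        scores=pd.DataFrame(scores, index=scaled.columns, columns=comp_names),
        loadings=pd.DataFrame(Vt.T, index=scaled.index, columns=comp_names),
        variance_fraction=var / var.sum(),
    )


def _log_pearson(
    x: pd.Series, y: pd.Series, min_n: int = 3
) -> CorrelationReport:
    common = x.index.intersection(y.index)
    x, y = x.loc[common], y.loc[common]
    usable = (x > 0) & (y > 0)
    dropped = sorted(common[~usable])
    if dropped:
        warn(
            f"{len(dropped)} genes with a zero value dropped (log10 "
            f"undefined): {dropped[:5]}"
        )
    n = int(usable.sum())
    if n < min_n:
        raise ValueError(f"only {n} usable gene pairs; need >= {min_n}")
    r, p = stats.pearsonr(np.log10(x[usable]), np.log10(y[usable]))
    return CorrelationReport(r=float(r), n=n, p=float(p), dropped=dropped)


def correlate_log(areas: pd.Series, expr: pd.Series) -> CorrelationReport:
    """Pearson r of (log10 peak area, log10 RPKM) over shared genes.

    Genes with zero area or zero expression cannot be log-transformed;
    they are omitted and listed in ``dropped``.
    """
    return _log_pearson(areas, expr)


def relative_difference_correlation(
    areas_t1: pd.Series,
    areas_t2: pd.Series,
    expr_t1: pd.Series,
    expr_t2: pd.Series,
) -> CorrelationReport:
    """Pearson r of between-tissue log-ratios of area vs expression.

    Correlates log10(area_t1/area_t2) with log10(expr_t1/expr_t2) over
    the shared gene panel; genes with any zero value are dropped.
    """
    genes = (
        areas_t1.index.intersection(areas_t2.index)
        .intersection(expr_t1.index)
        .intersection(expr_t2.index)
    )
    a1, a2 = areas_t1.loc[genes], areas_t2.loc[genes]
    e1, e2 = expr_t1.loc[genes], expr_t2.loc[genes]
    usable = (a1 > 0) & (a2 > 0) & (e1 > 0) & (e2 > 0)
    dropped = sorted(genes[~usable])
    if dropped:
        warn(f"{len(dropped)} genes with a zero value dropped: {dropped[:5]}")
    n = int(usable.sum())
    if n < 3:
        raise ValueError(f"only {n} usable gene pairs; need >= 3")
    r, p = stats.pearsonr(
        np.log10(a1[usable] / a2[usable]), np.log10(e1[usable] / e2[usable])
    )
    return CorrelationReport(r=float(r), n=n, p=float(p), dropped=dropped)
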