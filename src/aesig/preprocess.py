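"""Expression normalization and lymphocyte-correlated gene-panel screening."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass
class GeneSelection:
    """The two screened panels: top-positive (gh) and top-negative (gl) genes.

    Both panels are ordered by descending absolute correlation with the
    lymphocyte infiltration score and are disjoint by construction.
    """

    gh_genes: list[str]
    gl_genes: list[str]
    correlations: pd.Series
    k: int

    def __post_init__(self) -> None:
        if set(self.gh_genes) & set(self.gl_genes):
            raise ValueError("gh and gl panels overlap")
        if len(self.gh_genes) != self.k or len(self.gl_genes) != self.k:
            raise ValueError("panel sizes do not match k")


def log_zscore(
    expr: ExpressionMatrix,
    pseudo: float = 1.0,
    return_dropped: bool = False,
):
    """log2-transform (raw input only) and standardize each gene across samples.

    The log step is ``log2(value + pseudo)`` and is skipped when the input is
    already on a log scale (``space="log"``) or standardized. Standardization
    subtracts the per-gene mean and divides by the per-gene sample standard
    deviation (ddof=1). Zero-variance genes are removed and reported.
    """
    if pseudo <= 0:
        raise ValueError("pseudo-count must be positive")
    if expr.n_samples < 2:
        raise ValueError("need at least 2 samples to standardize")
    v = expr.values
    if expr.space == "raw":
        if (v < 0).any():
            raise ValueError("raw expression must be non-negative")
        v = np.log2(v + pseudo)

    sd = v.std(axis=1, ddof=1)
    keep = sd > 0
    dropped = [g for g, k in zip(expr.gene_ids, keep) if not k]
    if dropped:
        logger.info("dropping %d constant genes: %s%s", len(dropped),
                    ", ".join(dropped[:5]), "..." if len(dropped) > 5 else "")
    v = v[keep]
    mu = v.mean(axis=1, keepdims=True)
    z = (v - mu) / sd[keep][:, None]
    out = ExpressionMatrix(
        [g for g, k in zip(expr.gene_ids, keep) if k],
        list(expr.sample_ids),
        z,
        space="zscore",
    )
    if return_dropped:
        return out, dropped
    return out


def correlate_with_lymphocyte(
    expr: ExpressionMatrix,
    scores: pd.Series,
    method: str = "spearman",
) -> pd.Series:
    """Correlate every gene with the per-sample lymphocyte infiltration score.

    Samples without a (finite) score are excluded pairwise. Returns one rho
    per gene, indexed by gene id; genes that are constant over the scored
    samples get NaN.
    """
    if method not in ("spearman", "pearson"):
        raise ValueError(f"unknown correlation method {method!r}")
    scores = pd.Series(scores).dropna()
    shared = [s for s in expr.sample_ids if s in scores.index]
    if len(shared) < 3:
        raise ValueError(
            f"only {len(shared)} samples shared between expression and "
            "lymphocyte scores; need >= 3"
        )
    pos = {s: i for i, s in enumerate(expr.sample_ids)}
    x = expr.values[:, [pos[s] for s in shared]]
    y = scores.loc[shared].to_numpy(dtype=float)
    if method == "spearman":
        x = stats.rankdata(x, axis=1)
        y = stats.rankdata(y)
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    denom = np.sqrt((xc**2).sum(axis=1) * (yc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.where(denom > 0, (xc @ yc) / denom, np.nan)
    return pd.Series(rho, index=expr.gene_ids, name="rho")


def select_signature_genes(correlations: pd.Series, k: int) -> GeneSelection:
    """Pick the k most positively and k most negatively correlated genes.

    Ties at the panel boundary break by gene-symbol lexicographic order so
    panels are reproducible across platforms. Each panel is returned in
    descending |rho| order.
    """
    if k < 1:
        raise ValueError("k must be positive")
    corr = correlations.dropna()
    if len(corr) < 2 * k:
        raise ValueError(
            f"only {len(corr)} genes with finite correlations; need >= {2 * k} "
            f"-- use a smaller k"
        )
    by_pos = sorted(corr.items(), key=lambda gv: (-gv[1], gv[0]))
    by_neg = sorted(corr.items(), key=lambda gv: (gv[1], gv[0]))
    gh = [g for g, _ in by_pos[:k]]
    gl = [g for g, _ in by_neg[:k]]
    return GeneSelection(gh_genes=gh, gl_genes=gl, correlations=corr, k=k)


def align_genes(
    expr: ExpressionMatrix,
    panel: list[str],
    min_overlap: float = 0.5,
    warn_overlap: float = 0.8,
) -> np.ndarray:
    """Reorder a z-scored cohort to a trained gene panel.

    Returns a (len(panel), n_samples) matrix with rows in panel order.
    Panel genes absent from the cohort are filled with 0 — the cohort mean
    in z-score space. Overlap below ``min_overlap`` is a hard error; between
    ``min_overlap`` and ``warn_overlap`` a warning is logged.
    """
    pos = {g: i for i, g in enumerate(expr.gene_ids)}
    present = [g for g in panel if g in pos]
    overlap = len(present) / len(panel)
    if overlap < min_overlap:
        raise ValueError(
            f"panel overlap {overlap:.0%} below minimum {min_overlap:.0%}"
        )
    if overlap < warn_overlap:
        logger.warning("panel overlap only %.0f%%; scores may be unreliable",
                       100 * overlap)
    else:
        logger.info("panel overlap %.0f%%", 100 * overlap)
    out = np.zeros((len(panel), expr.n_samples))
    for i, g in enumerate(panel):
        if g in pos:
            out[i] = expr.values[pos[g]]
    return out
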