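"""Tumor-genomic covariates: CNV burden, mutation burden, cytolytic index,
and generic score-feature correlations."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix

logger = logging.getLogger(__name__)

GENOME_SIZE = 3.1e9

# Variant classifications counted as non-silent for mutation burden.
NONSILENT_CLASSES = frozenset(
    {
        "Missense_Mutation",
        "Nonsense_Mutation",
        "Nonstop_Mutation",
        "Splice_Site",
        "Frame_Shift_Ins",
        "Frame_Shift_Del",
        "In_Frame_Ins",
        "In_Frame_Del",
        "Translation_Start_Site",
    }
)
SILENT_CLASSES = frozenset(
    {"Silent", "Intron", "3'UTR", "5'UTR", "3'Flank", "5'Flank", "IGR", "RNA"}
)

MIN_COPY = 0.5  # zero-copy segments are clamped here before the log


def cnv_burden(
    fragments: list[tuple[float, float]],
    genome_size: float = GENOME_SIZE,
) -> float:
    """Genome-normalized copy-number aberration burden.

    ``fragments`` is a list of (copy_number, fragment_length) pairs covering
    the aberrant part of the genome; diploid regions may simply be omitted
    (they contribute zero). Returns sum_j |log2(c_j / 2)| * f_j / N, which
    is 0 for a fully diploid profile.
    """
    if genome_size <= 0:
        raise ValueError("genome size must be positive")
    if not fragments:
        logger.info("empty fragment list; CNV burden is 0")
        return 0.0
    total = 0.0
    for c, f in fragments:
        if f <= 0:
            raise ValueError(f"fragment length must be positive, got {f}")
        if not np.isfinite(c):
            raise ValueError("copy number must be finite")
        if c <= 0:
            logger.warning("clamping copy number %g to %g before log", c, MIN_COPY)
            c = MIN_COPY
        total += abs(np.log2(c / 2.0)) * f
    return total / genome_size


def cnv_burden_per_sample(
    profiles: dict[str, list[tuple[float, float]]],
    genome_size: float = GENOME_SIZE,
) -> pd.Series:
    return pd.Series(
        {s: cnv_burden(frags, genome_size) for s, frags in profiles.items()},
        name="cnv_burden",
    )


def tmb(
    mutations: pd.DataFrame,
    samples: list[str] | None = None,
    nonsilent: frozenset = NONSILENT_CLASSES,
) -> pd.Series:
    """Non-silent mutation count per sample from a MAF-like table.

    Records with a classification outside both the non-silent and the known
    silent sets are excluded with a warning. Samples listed in ``samples``
    but absent from the table get a count of 0.
    """
    cls = mutations["variant_classification"]
    unknown = set(cls.unique()) - set(nonsilent) - set(SILENT_CLASSES)
    if unknown:
        logger.warning("excluding unknown variant classifications: %s",
                       sorted(unknown))
    counted = mutations[cls.isin(nonsilent)]
    counts = counted.groupby("sample").size()
    if samples is not None:
        counts = counts.reindex(list(samples), fill_value=0)
    return counts.rename("tmb").astype(int)


def cyt_index(expr: ExpressionMatrix) -> pd.Series:
    """Cytolytic activity: geometric mean of GZMA and PRF1 (+1 offset)."""
    for gene in ("GZMA", "PRF1"):
        if gene not in expr.gene_ids:
            raise ValueError(f"gene {gene} missing from expression matrix")
    pos = {g: i for i, g in enumerate(expr.gene_ids)}
    gzma = expr.values[pos["GZMA"]]
    prf1 = expr.values[pos["PRF1"]]
    return pd.Series(
        np.sqrt((gzma + 1.0) * (prf1 + 1.0)), index=expr.sample_ids, name="cyt"
    )


def correlate_scores(
    scores,
    feature,
    method: str = "spearman",
) -> tuple[float, float]:
    """(rho, two-sided p) between a signature score and a per-sample feature.

    Accepts aligned arrays or pandas Series (joined on index); pairs with a
    missing value in either vector are dropped.
    """
    if isinstance(scores, pd.Series) and isinstance(feature, pd.Series):
        joined = pd.concat([scores, feature], axis=1, join="inner")
        x = joined.iloc[:, 0].to_numpy(dtype=float)
        y = joined.iloc[:, 1].to_numpy(dtype=float)
    else:
        x = np.asarray(scores, dtype=float)
        y = np.asarray(feature, dtype=float)
        if x.shape != y.shape:
            raise ValueError("scores and feature have different lengths")
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    if len(x) < 3:
        raise ValueError("need at least 3 paired samples")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector; correlation undefined")
    if method == "spearman":
        rho, p = stats.spearmanr(x, y)
    elif method == "pearson":
        rho, p = stats.pearsonr(x, y)
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    return float(rho), float(p)
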