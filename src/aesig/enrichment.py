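"""Pre-ranked gene-set enrichment on attribution weights.

Implements the weighted Kolmogorov-Smirnov-like running-sum statistic with a
gene-label permutation null. The running sum walks the ranked list,
incrementing by |w|^p (normalized over in-set genes) at set members and
decrementing by 1/(N - N_set) elsewhere; the enrichment score is the
extremum of the running sum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import GeneSetCollection

logger = logging.getLogger(__name__)


@dataclass
class EnrichmentTable:
    table: pd.DataFrame  # per set: es, nes, pval, fdr, size, leading_edge

    def __len__(self) -> int:
        return len(self.table)


def _running_sum(weights: np.ndarray, inset: np.ndarray, p: float) -> np.ndarray:
    n = len(weights)
    nh = int(inset.sum())
    if nh == 0:
        raise ValueError("gene set has no overlap with the ranked list")
    steps = np.empty(n)
    if n > nh:
        steps.fill(-1.0 / (n - nh))
    else:
        steps.fill(0.0)  # set covers the whole list: no decrements
    w = np.abs(weights[inset]) ** p
    norm = w.sum()
    if norm == 0:
        steps[inset] = 1.0 / nh  # all in-set weights zero: unweighted steps
    else:
        steps[inset] = w / norm
    return np.cumsum(steps)


def enrichment_score(
    ranked_genes: list[str],
    weights: np.ndarray,
    gene_set: list[str],
    p: float = 1.0,
) -> tuple[float, np.ndarray]:
    """ES and running-sum vector for one gene set on a ranked list.

    ``ranked_genes``/``weights`` must already be sorted (descending).
    Returns the signed extremum of the running sum and the full vector.
    """
    weights = np.asarray(weights, dtype=float)
    if len(ranked_genes) != len(weights):
        raise ValueError("ranked_genes and weights differ in length")
    members = set(gene_set)
    inset = np.fromiter((g in members for g in ranked_genes), bool, len(ranked_genes))
    run = _running_sum(weights, inset, p)
    es = float(run[np.argmax(np.abs(run))])
    return es, run


def _null_es(
    weights: np.ndarray, set_size: int, p: float, n_perm: int, rng
) -> np.ndarray:
    """Null ES from random gene-label assignments of the same set size."""
    n = len(weights)
    out = np.empty(n_perm)
    inset = np.zeros(n, dtype=bool)
    for i in range(n_perm):
        idx = rng.choice(n, size=set_size, replace=False)
        inset[:] = False
        inset[idx] = True
        run = _running_sum(weights, inset, p)
        out[i] = run[np.argmax(np.abs(run))]
    return out


def preranked_gsea(
    ranked: pd.Series,
    collection: GeneSetCollection,
    n_perm: int = 1000,
    seed: int = 0,
    min_size: int = 2,
    max_size: int = 500,
    p: float = 1.0,
) -> EnrichmentTable:
    """Permutation GSEA of a pre-ranked weight profile.

    ``ranked`` maps gene -> weight, sorted descending. For each set the
    nominal p is the fraction of same-sign null ES at least as extreme
    (with +1 smoothing), and NES divides ES by the mean |null ES| of the
    same sign. FDR is Benjamini-Hochberg over the reported sets.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    genes = list(ranked.index)
    weights = ranked.to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    universe = set(genes)

    rows = []
    for name, members in collection.items():
        overlap = [g for g in members if g in universe]
        size = len(overlap)
        if size == 0:
            logger.warning("gene set %s has no overlap with ranking; skipped", name)
            continue
        if not (min_size <= size <= max_size):
            continue
        es, run = enrichment_score(genes, weights, overlap, p=p)
        null = _null_es(weights, size, p, n_perm, rng)
        same_sign = null[np.sign(null) == np.sign(es)] if es != 0 else null
        n_same = len(same_sign)
        pval = (1.0 + float((np.abs(same_sign) >= abs(es)).sum())) / (1.0 + n_same)
        mean_same = float(np.abs(same_sign).mean()) if n_same else np.nan
        nes = es / mean_same if (n_same and mean_same > 0) else np.nan

        members_set = set(overlap)
        inset = np.fromiter((g in members_set for g in genes), bool, len(genes))
        peak = int(np.argmax(np.abs(run)))
        if es >= 0:
            leading = [g for i, g in enumerate(genes) if inset[i] and i <= peak]
        else:
            leading = [g for i, g in enumerate(genes) if inset[i] and i >= peak]
        rows.append(
            {
                "set": name,
                "es": es,
                "nes": nes,
                "pval": pval,
                "size": size,
                "n_perm": n_perm,
                "leading_edge": ",".join(leading),
            }
        )

    if not rows:
        logger.warning("no gene set within size bounds [%d, %d]", min_size, max_size)
        return EnrichmentTable(
            pd.DataFrame(
                columns=["set", "es", "nes", "pval", "fdr", "size", "n_perm",
                         "leading_edge"]
            )
        )
    table = pd.DataFrame(rows).set_index("set")
    table["fdr"] = _benjamini_hochberg(table["pval"].to_numpy())
    table = table[["es", "nes", "pval", "fdr", "size", "n_perm", "leading_edge"]]
    return EnrichmentTable(table.sort_values("pval"))


def _benjamini_hochberg(pvals: np.ndarray) -> np.ndarray:
    m = len(pvals)
    order = np.argsort(pvals)
    ranked = pvals[order] * m / (np.arange(m) + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def set_activity(expr_z, collection: GeneSetCollection) -> pd.DataFrame:
    """Mean z-score of each set's member genes per sample.

    Exploratory substitute for per-sample pathway-activity scoring; not a
    GSVA implementation.
    """
    pos = {g: i for i, g in enumerate(expr_z.gene_ids)}
    rows = {}
    for name, members in collection.items():
        idx = [pos[g] for g in members if g in pos]
        if not idx:
            continue
        rows[name] = expr_z.values[idx].mean(axis=0)
    return pd.DataFrame(rows, index=expr_z.sample_ids).T
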