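"""Prognostic bottleneck-node selection and gene attribution.

A trained autoencoder yields one score per bottleneck node per sample. The
node whose median-dichotomized score is most strongly associated with
survival (smallest Wald p from a univariate proportional-hazards fit)
becomes the compartment's signature node. Node scores are attributed back
to input genes by summing, over all encoder paths, the products of the
layer weights connecting the gene to the node — equivalently a column of
the product of the encoder weight matrices. Activations and biases are
excluded from the attribution by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .autoencoder import AutoencoderModel
from .io import CohortClinical
from .survival import cox_fit, dichotomize, km_logrank

logger = logging.getLogger(__name__)

COMPARTMENTS = ("TE", "TI")


@dataclass
class NodeScoreMatrix:
    """Per-sample bottleneck activations for one compartment."""

    sample_ids: list[str]
    node_scores: np.ndarray  # (n_samples, K)
    compartment: str

    def __post_init__(self) -> None:
        self.node_scores = np.asarray(self.node_scores, dtype=float)
        if self.compartment not in COMPARTMENTS:
            raise ValueError(f"compartment must be one of {COMPARTMENTS}")
        if self.node_scores.ndim != 2 or self.node_scores.shape[0] != len(
            self.sample_ids
        ):
            raise ValueError("node_scores must be (n_samples, K)")
        if not np.all(np.isfinite(self.node_scores)):
            raise ValueError("node scores must be finite")

    @property
    def n_nodes(self) -> int:
        return self.node_scores.shape[1]


@dataclass
class SignatureDefinition:
    """Selected node for one compartment, with per-node selection statistics.

    ``node_index`` is 0-based. ``orientation`` is +1 or -1 and is chosen so
    that a higher oriented TE score associates with lower hazard and a
    higher oriented TI score with higher hazard.
    """

    compartment: str
    node_index: int
    selection_stats: pd.DataFrame  # columns: node, hr, p, logrank_p
    orientation: int = 1
    gene_weights: pd.Series | None = None


def select_prognostic_node(
    F: NodeScoreMatrix,
    clinical: CohortClinical,
    method: str = "cox",
) -> SignatureDefinition:
    """Pick the bottleneck node most associated with survival.

    Each node's scores are dichotomized at the median and a univariate
    proportional-hazards model is fit on the binary group; the node with the
    smallest Wald p wins (ties break toward the smaller index). ``method=
    "logrank"`` ranks nodes by the log-rank p instead. Constant nodes are
    skipped.
    """
    if method not in ("cox", "logrank"):
        raise ValueError(f"unknown selection method {method!r}")
    clin = clinical.table
    shared = [s for s in F.sample_ids if s in clin.index]
    surv = clin.loc[shared, ["time", "event"]].dropna()
    if len(surv) < 20:
        raise ValueError(f"only {len(surv)} samples with survival data; need >= 20")
    if surv["event"].sum() < 1:
        raise ValueError("no events in the cohort; cannot select a node")
    pos = {s: i for i, s in enumerate(F.sample_ids)}
    scores = F.node_scores[[pos[s] for s in surv.index]]

    rows = []
    for k in range(F.n_nodes):
        s = scores[:, k]
        if np.ptp(s) == 0:
            rows.append({"node": k, "hr": np.nan, "p": np.nan, "logrank_p": np.nan})
            continue
        try:
            groups = dichotomize(s)
        except ValueError:
            rows.append({"node": k, "hr": np.nan, "p": np.nan, "logrank_p": np.nan})
            continue
        high = (groups == "high").astype(float)
        df = pd.DataFrame(
            {
                "time": surv["time"].to_numpy(),
                "event": surv["event"].to_numpy(),
                "high": high,
            }
        )
        try:
            res = cox_fit(df, covariates=["high"])
            hr = float(res.summary.loc["high", "hr"])
            p = float(res.summary.loc["high", "p"])
        except Exception as exc:  # degenerate split; exclude node
            logger.debug("node %d Cox fit failed: %s", k, exc)
            rows.append({"node": k, "hr": np.nan, "p": np.nan, "logrank_p": np.nan})
            continue
        lr = km_logrank(groups, df).logrank_p
        rows.append({"node": k, "hr": hr, "p": p, "logrank_p": lr})

    stats = pd.DataFrame(rows)
    key = "p" if method == "cox" else "logrank_p"
    if stats[key].isna().all():
        raise ValueError("no node produced a valid survival fit (all constant?)")
    compartment = F.compartment
    # candidates by ascending p, ties toward the smaller node index; a node
    # whose *oriented* score cannot be median-split (mass at the maximum
    # after a sign flip) is unusable downstream, so fall through to the next
    candidates = stats.dropna(subset=[key]).sort_values([key, "node"])
    for _, row in candidates.iterrows():
        hr = row["hr"]
        flip = (compartment == "TE" and hr > 1) or (compartment == "TI" and hr < 1)
        orient = -1 if flip else 1
        try:
            dichotomize(orient * scores[:, int(row["node"])])
        except ValueError:
            logger.info(
                "node %d skipped: oriented score not dichotomizable", int(row["node"])
            )
            continue
        return SignatureDefinition(
            compartment=compartment,
            node_index=int(row["node"]),
            selection_stats=stats,
            orientation=orient,
        )
    raise ValueError("no node yields a dichotomizable oriented score")


def gene_weights(model: AutoencoderModel, node_index: int) -> np.ndarray:
    """Path-sum attribution of one bottleneck node to every input gene.

    GW(i) = sum over all hidden-unit paths (j, k, ...) of the product of
    encoder weights from gene i to ``node_index`` — the ``node_index``
    column of the product of the encoder weight matrices.
    """
    K = model.bottleneck
    if not 0 <= node_index < K:
        raise ValueError(f"node_index {node_index} out of range [0, {K})")
    prod = model.enc_W[0]
    for W in model.enc_W[1:]:
        prod = prod @ W
    return np.asarray(prod[:, node_index], dtype=float)


def attribute_signature(
    model: AutoencoderModel, panel: list[str], signature: SignatureDefinition
) -> pd.Series:
    """Gene weights for the oriented signature node, indexed by panel gene."""
    gw = gene_weights(model, signature.node_index) * signature.orientation
    return pd.Series(gw, index=list(panel), name="gw")


def rank_genes_for_gsea(weights: pd.Series) -> pd.Series:
    """Stable descending sort of attribution weights; ties break by symbol."""
    w = pd.Series(weights)
    if not np.all(np.isfinite(w.to_numpy(dtype=float))):
        raise ValueError("attribution weights must be finite")
    order = sorted(w.items(), key=lambda gv: (-gv[1], gv[0]))
    return pd.Series(
        [v for _, v in order], index=[g for g, _ in order], name=w.name or "weight"
    )
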