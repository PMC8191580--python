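"""End-to-end orchestration: decompose a training cohort into TE/TI
signature models and score new cohorts with a saved bundle."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from . import preprocess
from .autoencoder import (
    AutoencoderModel,
    TrainingConfig,
    encode,
    init_model,
    reconstruction_r2,
    train,
)
from .io import CohortClinical, ExpressionMatrix
from .preprocess import GeneSelection
from .signature import (
    NodeScoreMatrix,
    SignatureDefinition,
    attribute_signature,
    select_prognostic_node,
)

logger = logging.getLogger(__name__)


@dataclass
class TrainedSignature:
    """One compartment's trained model, gene panel and selected node."""

    compartment: str
    model: AutoencoderModel
    panel: list[str]
    node_index: int
    orientation: int
    gene_weights: pd.Series
    selection_stats: pd.DataFrame
    reconstruction_r2: float | None = None


@dataclass
class ModelBundle:
    """TE and/or TI trained signatures plus the run configuration."""

    signatures: dict[str, TrainedSignature]
    config: dict = field(default_factory=dict)
    seed: int | None = None

    def __getitem__(self, compartment: str) -> TrainedSignature:
        return self.signatures[compartment]


def _train_compartment(
    compartment: str,
    panel: list[str],
    expr_z: ExpressionMatrix,
    clinical: CohortClinical,
    config: TrainingConfig,
) -> TrainedSignature:
    sub = preprocess.align_genes(expr_z, panel, min_overlap=0.999)
    X = sub.T  # samples x genes
    model = init_model(
        d_in=len(panel),
        hidden_sizes=config.resolve_hidden(len(panel)),
        seed=config.seed,
        linear_bottleneck=config.linear_bottleneck,
        dtype=config.dtype,
    )
    train(model, X, config)
    r2 = reconstruction_r2(model, X)
    logger.info("%s model trained: reconstruction R^2 = %.3f", compartment, r2)
    F = NodeScoreMatrix(
        sample_ids=list(expr_z.sample_ids),
        node_scores=encode(model, X),
        compartment=compartment,
    )
    sig = select_prognostic_node(F, clinical)
    gw = attribute_signature(model, panel, sig)
    logger.info(
        "%s signature: node %d (orientation %+d)",
        compartment, sig.node_index, sig.orientation,
    )
    return TrainedSignature(
        compartment=compartment,
        model=model,
        panel=list(panel),
        node_index=sig.node_index,
        orientation=sig.orientation,
        gene_weights=gw,
        selection_stats=sig.selection_stats,
        reconstruction_r2=r2,
    )


def decompose(
    expr: ExpressionMatrix,
    lymphocyte: pd.Series,
    clinical: CohortClinical,
    k: int = 1000,
    cor_method: str = "spearman",
    config: TrainingConfig | None = None,
    pseudo: float = 1.0,
    compartments: tuple[str, ...] = ("TE", "TI"),
) -> tuple[ModelBundle, GeneSelection]:
    """Train the full decomposition on one cohort.

    Normalizes the cohort, screens the top-k positively (GH') and negatively
    (GL') lymphocyte-correlated panels, trains one autoencoder per requested
    compartment (TE on GH', TI on GL'), selects each compartment's
    prognostic node and computes gene attributions.
    """
    if config is None:
        config = TrainingConfig()
    expr_z = preprocess.log_zscore(expr, pseudo=pseudo)
    rho = preprocess.correlate_with_lymphocyte(expr_z, lymphocyte, method=cor_method)
    selection = preprocess.select_signature_genes(rho, k)
    panels = {"TE": selection.gh_genes, "TI": selection.gl_genes}
    signatures = {
        comp: _train_compartment(comp, panels[comp], expr_z, clinical, config)
        for comp in compartments
    }
    bundle = ModelBundle(
        signatures=signatures,
        config={
            "k": k,
            "cor_method": cor_method,
            "pseudo": pseudo,
            "lambda_reg": config.lambda_reg,
            "learning_rate": config.learning_rate,
            "momentum": config.momentum,
            "epochs": config.epochs,
            "batch_size": config.batch_size,
            "bottleneck": config.bottleneck,
            "linear_bottleneck": config.linear_bottleneck,
        },
        seed=config.seed,
    )
    return bundle, selection


def score_cohort(
    bundle: ModelBundle,
    expr: ExpressionMatrix,
    pseudo: float = 1.0,
    min_overlap: float = 0.5,
) -> pd.DataFrame:
    """Apply a trained bundle to a new cohort; no re-training occurs.

    The cohort is z-scored within itself, aligned to each compartment's gene
    panel (missing panel genes filled with the z-score mean, 0), encoded,
    and the signature node's oriented score extracted. Returns a data frame
    indexed by sample id with one ``<compartment>_score`` column per
    trained compartment.
    """
    expr_z = (
        expr
        if expr.space == "zscore"
        else preprocess.log_zscore(expr, pseudo=pseudo)
    )
    out = {}
    for comp, sig in bundle.signatures.items():
        sub = preprocess.align_genes(expr_z, sig.panel, min_overlap=min_overlap)
        F = encode(sig.model, sub.T)
        out[f"{comp.lower()}_score"] = sig.orientation * F[:, sig.node_index]
    return pd.DataFrame(out, index=pd.Index(expr_z.sample_ids, name="sample_id"))


def signature_definition(bundle: ModelBundle, compartment: str) -> SignatureDefinition:
    """View a bundle's compartment as a :class:`SignatureDefinition`."""
    sig = bundle[compartment]
    return SignatureDefinition(
        compartment=compartment,
        node_index=sig.node_index,
        selection_stats=sig.selection_stats,
        orientation=sig.orientation,
        gene_weights=sig.gene_weights,
    )
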