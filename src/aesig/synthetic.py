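"""Synthetic cohorts with planted immune and tumor-intrinsic latent factors.

Every downstream stage — panel screening, autoencoder training, node
selection, scoring, survival and response evaluation, enrichment — can be
exercised end to end on these cohorts, with the planted ground truth
retained for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import CohortClinical, ExpressionMatrix, GeneSetCollection


@dataclass
class SimulationConfig:
    n_samples: int = 200
    n_genes: int = 1000
    n_immune_genes: int = 300
    n_intrinsic_genes: int = 300
    immune_loading: float = 1.0
    intrinsic_loading: float = 1.0
    noise_sd: float = 0.5
    factor_corr: float = 0.0  # correlation planted between the two factors
    lymph_levels: int = 4
    surv_beta_te: float = -0.7  # log-HR per SD of the immune factor
    surv_beta_ti: float = 0.7
    censor_rate: float = 0.2
    baseline_hazard: float = 0.02
    age_beta: float = 0.01  # per year, centered at 60
    sex_beta: float = 0.1
    stage_beta: float = 0.2
    response_beta: float = 1.5
    mutation_log_mean: float = 4.0
    mutation_beta: float = 0.5
    weibull_shape: float = 1.0  # 1.0 = exponential survival
    expression_shift: float = 8.0  # keeps the raw scale positive
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_immune_genes + self.n_intrinsic_genes > self.n_genes:
            raise ValueError("gene blocks exceed n_genes")
        if not 0 <= self.censor_rate < 1:
            raise ValueError("censor_rate must be in [0, 1)")
        if not -1 < self.factor_corr < 1:
            raise ValueError("factor_corr must be in (-1, 1)")


@dataclass
class SyntheticCohort:
    expression: ExpressionMatrix  # raw scale
    lymphocyte: pd.Series
    clinical: CohortClinical
    mutation_counts: pd.Series
    cnv_profiles: dict[str, list[tuple[float, float]]]
    response: pd.Series
    z_immune: pd.Series  # ground truth
    z_intrinsic: pd.Series
    immune_genes: list[str]
    intrinsic_genes: list[str]
    config: SimulationConfig = field(repr=False, default=None)


def generate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Draw a full cohort from the planted generative model.

    Expression: gene g in the immune (resp. intrinsic) block follows
    loading * z + N(0, noise_sd) on the log2 scale, shifted and
    exponentiated to a positive raw scale; background genes are pure noise.
    Survival is exponential (Weibull if ``weibull_shape != 1``) with
    log-hazard linear in the two factors and the clinical covariates;
    censoring is independent. Fully reproducible from ``config.seed``.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_samples
    samples = [f"S{i:04d}" for i in range(n)]
    genes = [f"G{i:05d}" for i in range(cfg.n_genes)]
    immune_genes = genes[: cfg.n_immune_genes]
    intrinsic_genes = genes[cfg.n_immune_genes : cfg.n_immune_genes + cfg.n_intrinsic_genes]

    z_imm = rng.standard_normal(n)
    z_raw = rng.standard_normal(n)
    z_int = cfg.factor_corr * z_imm + np.sqrt(1 - cfg.factor_corr**2) * z_raw

    log_expr = rng.normal(0.0, cfg.noise_sd, size=(cfg.n_genes, n))
    log_expr[: cfg.n_immune_genes] += cfg.immune_loading * z_imm
    sl = slice(cfg.n_immune_genes, cfg.n_immune_genes + cfg.n_intrinsic_genes)
    log_expr[sl] += cfg.intrinsic_loading * z_int
    raw = np.exp2(log_expr + cfg.expression_shift)
    expression = ExpressionMatrix(genes, samples, raw, space="raw")

    # ordinal lymphocyte score: quantile bins of the immune factor
    qs = np.quantile(z_imm, np.linspace(0, 1, cfg.lymph_levels + 1)[1:-1])
    lymph = pd.Series(np.digitize(z_imm, qs) + 1, index=samples, name="lymph")

    age = rng.normal(60, 10, size=n)
    sex = rng.integers(0, 2, size=n)
    stage = rng.integers(1, 5, size=n)
    log_hr = (
        cfg.surv_beta_te * z_imm
        + cfg.surv_beta_ti * z_int
        + cfg.age_beta * (age - 60)
        + cfg.sex_beta * sex
        + cfg.stage_beta * (stage - 2.5)
    )
    hazard = cfg.baseline_hazard * np.exp(log_hr)
    u = rng.uniform(size=n)
    time = (-np.log(u) / hazard) ** (1.0 / cfg.weibull_shape)
    event = np.ones(n, dtype=int)
    if cfg.censor_rate > 0:
        cens_rate = cfg.baseline_hazard * cfg.censor_rate / (1 - cfg.censor_rate)
        cens_time = rng.exponential(1.0 / cens_rate, size=n)
        censored = cens_time < time
        time = np.where(censored, cens_time, time)
        event = np.where(censored, 0, 1)

    resp_prob = 1.0 / (1.0 + np.exp(-cfg.response_beta * z_imm))
    response = pd.Series(
        np.where(rng.uniform(size=n) < resp_prob, "R", "NR"), index=samples,
        name="response",
    )

    clinical = CohortClinical(
        pd.DataFrame(
            {
                "time": time,
                "event": event,
                "age": age,
                "sex": np.where(sex == 1, "M", "F"),
                "stage": stage,
                "breslow": np.round(rng.lognormal(0.5, 0.5, size=n), 2),
                "response": response.to_numpy(),
            },
            index=pd.Index(samples, name="sample_id"),
        )
    )

    mut = rng.poisson(np.exp(cfg.mutation_log_mean + cfg.mutation_beta * z_int))
    mutation_counts = pd.Series(mut, index=samples, name="tmb")

    # CNV: aberrant genome fraction grows as the immune factor falls, so the
    # burden is negatively correlated with z_imm.
    profiles: dict[str, list[tuple[float, float]]] = {}
    for i, s in enumerate(samples):
        n_frag = 1 + rng.poisson(3)
        scale = np.exp(-0.6 * z_imm[i])
        frags = []
        for _ in range(n_frag):
            copy = float(rng.choice([0.0, 1.0, 3.0, 4.0]))
            size = float(rng.uniform(1e6, 5e7) * scale)
            frags.append((copy, size))
        profiles[s] = frags

    return SyntheticCohort(
        expression=expression,
        lymphocyte=lymph,
        clinical=clinical,
        mutation_counts=mutation_counts,
        cnv_profiles=profiles,
        response=response,
        z_immune=pd.Series(z_imm, index=samples, name="z_immune"),
        z_intrinsic=pd.Series(z_int, index=samples, name="z_intrinsic"),
        immune_genes=immune_genes,
        intrinsic_genes=intrinsic_genes,
        config=replace(cfg),
    )


def generate_gene_sets(
    cohort: SyntheticCohort, n_decoys: int = 10, seed: int = 0
) -> GeneSetCollection:
    """Planted TRUE_IMMUNE / TRUE_INTRINSIC sets plus size-matched decoys."""
    rng = np.random.default_rng(seed)
    genes = cohort.expression.gene_ids
    sets = {
        "TRUE_IMMUNE": list(cohort.immune_genes),
        "TRUE_INTRINSIC": list(cohort.intrinsic_genes),
    }
    size = len(cohort.immune_genes)
    for d in range(n_decoys):
        pick = rng.choice(len(genes), size=min(size, len(genes)), replace=False)
        sets[f"DECOY_{d:02d}"] = [genes[i] for i in sorted(pick)]
    return GeneSetCollection(sets)
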