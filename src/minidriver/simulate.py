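"""Synthetic cohorts with the statistical structure the pipeline assumes.

Three linked generators emulate the pipeline's real inputs:

* **Expression** — block-correlated latent-factor matrices.  Gene g in
  module j is ``x = a_j * f_j + noise_sd * eps`` with factor and noise
  standard normal, so the within-module Pearson correlation is exactly
  ``a^2 / (a^2 + noise_sd^2)`` (0.9 at the default a=3, noise_sd=1).  The
  tumour condition attenuates every loading by ``1 - modularity_degradation``,
  the minimal mechanism that weakens community structure in one condition.
  Values are made non-negative by a monotone transform: by default the
  standardized latent value is exponentiated at scale 0.5 (lognormal), with
  a pure shift (which preserves Pearson correlations exactly) available.

* **Mutations** — each gene is mutated in each patient independently at a
  background rate; a planted E+ subgroup uses ``rate * boost`` (capped at 1)
  for genes of one designated module.

* **Survival** — exponential proportional-hazards event times with
  log-hazard contributions from the true E label and a sampled N stage,
  plus independent exponential censoring tuned to a target censoring
  fraction via the cohort-average hazard.

Every generator is bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .community import Partition
from .expression import ExpressionMatrix
from .mutations import PatientMutationProfile

logger = logging.getLogger(__name__)

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "generate_expression",
    "generate_mutations",
    "generate_survival",
    "generate_cohort",
    "profiles_to_maf",
]

# fixed per-generator stream offsets so the three generators draw from
# independent streams under one seed
_STREAM_EXPRESSION = 11
_STREAM_MUTATIONS = 12
_STREAM_SURVIVAL = 13


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic cohort.

    Defaults: 10 planted modules of 150 genes (loading a=3, unit noise, so
    within-module rho = 0.9) in a 3000-gene pool, 60 samples per condition,
    tumour loadings halved; 500 patients mutated at background rate 0.02
    with an 8-fold boost in the planted module for the 30% E+ subgroup;
    exponential survival with hazard ratio 2 for E+ and 1.5 per N-stage
    level, ~30% censoring before the administrative horizon.
    """

    n_genes: int = 3000
    n_samples: int = 60
    module_spec: list[tuple[int, float]] = field(
        default_factory=lambda: [(150, 3.0)] * 10
    )
    noise_sd: float = 1.0
    modularity_degradation: float = 0.5
    positivity: str = "exp"          # "exp" | "shift"
    exp_scale: float = 0.5

    n_patients: int = 500
    background_mutation_rate: float = 0.02
    enriched_module: int = 1
    enrichment_boost: float = 8.0
    e_positive_fraction: float = 0.30

    baseline_hazard: float = 2.4e-4          # per day
    log_hr_e: float = math.log(2.0)
    log_hr_n_stage: float = math.log(1.5)    # per N level
    n_stage_probs: tuple[float, ...] = (0.66, 0.18, 0.14, 0.02)
    censoring_rate: float = 0.30

    seed: int = 0

    def __post_init__(self) -> None:
        if sum(size for size, _ in self.module_spec) > self.n_genes:
            raise ValueError("module sizes exceed n_genes")
        if not 0.0 <= self.modularity_degradation <= 1.0:
            raise ValueError("modularity_degradation must be in [0, 1]")
        if not 0.0 < self.background_mutation_rate < 1.0:
            raise ValueError("background_mutation_rate must be in (0, 1)")
        if self.enrichment_boost < 1.0:
            raise ValueError("enrichment_boost must be >= 1")
        if not 0.0 <= self.e_positive_fraction <= 1.0:
            raise ValueError("e_positive_fraction must be in [0, 1]")
        if not 0.0 <= self.censoring_rate < 1.0:
            raise ValueError("censoring_rate must be in [0, 1)")
        if self.positivity not in ("exp", "shift"):
            raise ValueError("positivity must be 'exp' or 'shift'")
        if not math.isclose(sum(self.n_stage_probs), 1.0, abs_tol=1e-9):
            raise ValueError("n_stage_probs must sum to 1")


@dataclass
class SyntheticTruth:
    """Ground truth of one generated cohort."""

    partition: Partition
    e_positive: set[str]
    log_hr_e: float
    log_hr_n_stage: float
    config: SyntheticConfig


def _gene_names(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(1, n + 1)]


def _patient_names(n: int) -> list[str]:
    return [f"P{i:04d}" for i in range(1, n + 1)]


def _rng(seed: int | None, cfg: SyntheticConfig, stream: int) -> np.random.Generator:
    base = cfg.seed if seed is None else seed
    return np.random.default_rng([int(base) % (2**31), stream])


def true_partition(cfg: SyntheticConfig) -> Partition:
    """Planted module membership (module ids 1..k, in module_spec order)."""
    genes = _gene_names(cfg.n_genes)
    assignment: dict[str, int] = {}
    start = 0
    for module_id, (size, _) in enumerate(cfg.module_spec, start=1):
        for g in genes[start:start + size]:
            assignment[g] = module_id
        start += size
    return Partition(assignment)


def generate_expression(
    cfg: SyntheticConfig, condition: str, seed: int | None = None
) -> tuple[ExpressionMatrix, Partition]:
    """Latent-factor block expression matrix for one condition.

    The ``tumour`` condition multiplies every module loading by
    ``1 - modularity_degradation``; any other label uses the loadings
    as-is.  Returns the matrix and the planted partition (assigned genes
    only; trailing genes are pure noise).
    """
    rng = _rng(seed, cfg, _STREAM_EXPRESSION + (1 if condition == "tumour" else 0))
    attenuation = (
        1.0 - cfg.modularity_degradation if condition == "tumour" else 1.0
    )
    genes = _gene_names(cfg.n_genes)
    n_s = cfg.n_samples
    latent = np.empty((cfg.n_genes, n_s))
    theo_sd = np.empty(cfg.n_genes)
    start = 0
    for size, loading in cfg.module_spec:
        a = loading * attenuation
        factor = rng.standard_normal(n_s)
        eps = rng.standard_normal((size, n_s))
        latent[start:start + size] = a * factor + cfg.noise_sd * eps
        theo_sd[start:start + size] = math.sqrt(a * a + cfg.noise_sd**2)
        start += size
    n_noise = cfg.n_genes - start
    if n_noise:
        latent[start:] = cfg.noise_sd * rng.standard_normal((n_noise, n_s))
        theo_sd[start:] = cfg.noise_sd

    if cfg.positivity == "exp":
        values = np.exp(cfg.exp_scale * latent / theo_sd[:, None])
    else:  # shift: a single global offset, linear so correlations are exact
        values = latent - latent.min()
    prefix = condition[:1].upper() if condition else "S"
    samples = [f"{prefix}S{i:03d}" for i in range(1, n_s + 1)]
    condition_map = pd.Series(condition, index=samples, name="condition")
    matrix = ExpressionMatrix(
        pd.DataFrame(values, index=genes, columns=samples), condition_map
    )
    return matrix, true_partition(cfg)


def generate_mutations(
    cfg: SyntheticConfig, partition: Partition, seed: int | None = None
) -> tuple[dict[str, PatientMutationProfile], dict[str, bool]]:
    """Per-patient mutated-gene sets with a planted E+ subgroup.

    Every gene (assigned or noise) mutates at the background rate; for E+
    patients, genes of ``cfg.enriched_module`` mutate at
    ``rate * enrichment_boost`` (capped at 1, with a log message).
    """
    if cfg.enriched_module not in partition.module_sizes:
        raise ValueError(
            f"enriched module {cfg.enriched_module} not in partition"
        )
    rng = _rng(seed, cfg, _STREAM_MUTATIONS)
    genes = _gene_names(cfg.n_genes)
    gene_index = {g: i for i, g in enumerate(genes)}
    patients = _patient_names(cfg.n_patients)

    n_pos = int(round(cfg.e_positive_fraction * cfg.n_patients))
    pos_idx = set(rng.permutation(cfg.n_patients)[:n_pos].tolist())
    e_labels = {p: (i in pos_idx) for i, p in enumerate(patients)}

    base_rate = np.full(cfg.n_genes, cfg.background_mutation_rate)
    boosted = base_rate.copy()
    boosted_value = cfg.background_mutation_rate * cfg.enrichment_boost
    if boosted_value > 1.0:
        logger.warning("boosted mutation rate %.3f capped at 1", boosted_value)
        boosted_value = 1.0
    for g in partition.members(cfg.enriched_module):
        boosted[gene_index[g]] = boosted_value

    u = rng.random((cfg.n_patients, cfg.n_genes))
    profiles: dict[str, PatientMutationProfile] = {}
    for i, patient in enumerate(patients):
        rate = boosted if e_labels[patient] else base_rate
        hit = np.nonzero(u[i] < rate)[0]
        if hit.size == 0:
            logger.info("patient %s drew no mutations; omitted", patient)
            continue
        profiles[patient] = PatientMutationProfile(
            patient, frozenset(genes[j] for j in hit)
        )
    return profiles, e_labels


def generate_survival(
    cfg: SyntheticConfig, e_labels: dict[str, bool], seed: int | None = None
) -> pd.DataFrame:
    """Clinical records with exponential proportional-hazards event times.

    Hazard: ``h0 * exp(log_hr_e * E + log_hr_n_stage * N_level)`` with the
    N level sampled from ``n_stage_probs``.  Censoring is an independent
    exponential whose rate is tuned so the expected censored fraction
    (before any administrative horizon) matches ``censoring_rate``, using
    the cohort-average hazard.  Vital and tumour status are set so the
    survival-table builder reconstructs the intended event indicator.
    """
    rng = _rng(seed, cfg, _STREAM_SURVIVAL)
    patients = sorted(e_labels)
    n = len(patients)
    if n == 0:
        raise ValueError("no patients supplied")
    n_levels = rng.choice(len(cfg.n_stage_probs), size=n, p=cfg.n_stage_probs)
    e_vec = np.array([e_labels[p] for p in patients], dtype=float)
    hazard = cfg.baseline_hazard * np.exp(
        cfg.log_hr_e * e_vec + cfg.log_hr_n_stage * n_levels
    )
    event_time = rng.exponential(1.0 / hazard)
    if cfg.censoring_rate > 0:
        cens_rate = float(hazard.mean()) * cfg.censoring_rate / (
            1.0 - cfg.censoring_rate
        )
        censor_time = rng.exponential(1.0 / cens_rate, size=n)
    else:
        censor_time = np.full(n, np.inf)
    observed = np.minimum(event_time, censor_time)
    is_event = event_time <= censor_time
    days = np.maximum(1, np.ceil(observed)).astype(int)

    smoking = rng.choice(["Smoker", "Never"], size=n, p=[0.8, 0.2])
    margin = rng.choice(["R0", "R1", "RX", "Unknown"], size=n,
                        p=[0.70, 0.10, 0.10, 0.10])
    return pd.DataFrame({
        "patient": patients,
        "vital_status": np.where(is_event, "dead", "alive"),
        "tumour_status": np.where(is_event, "with tumour", "tumour free"),
        "days_to_death": np.where(is_event, days, np.nan),
        "days_to_last_followup": np.where(is_event, np.nan, days),
        "n_stage": [f"N{v}" for v in n_levels],
        "smoking": smoking,
        "margin_status": margin,
    })


def generate_cohort(cfg: SyntheticConfig, seed: int | None = None) -> dict:
    """Generate the full linked cohort (expression, mutations, clinical).

    Returns a dict with keys ``expression_normal``, ``expression_tumour``,
    ``profiles``, ``e_labels``, ``clinical`` and ``truth``.
    """
    normal, partition = generate_expression(cfg, "normal", seed=seed)
    tumour, _ = generate_expression(cfg, "tumour", seed=seed)
    profiles, e_labels = generate_mutations(cfg, partition, seed=seed)
    clinical = generate_survival(cfg, e_labels, seed=seed)
    truth = SyntheticTruth(
        partition=partition,
        e_positive={p for p, pos in e_labels.items() if pos},
        log_hr_e=cfg.log_hr_e,
        log_hr_n_stage=cfg.log_hr_n_stage,
        config=cfg,
    )
    return {
        "expression_normal": normal,
        "expression_tumour": tumour,
        "profiles": profiles,
        "e_labels": e_labels,
        "clinical": clinical,
        "truth": truth,
    }


def profiles_to_maf(
    profiles: dict[str, PatientMutationProfile]
) -> pd.DataFrame:
    """Render profiles as a minimal MAF-like table (one SNV row per gene)."""
    rows = []
    for patient in sorted(profiles):
        for gene in sorted(profiles[patient].mutated_genes):
            pos = (sum(ord(c) for c in gene) % 500) + 1
            rows.append((gene, patient, "Missense_Mutation", "SNP",
                         f"p.A{pos}V"))
    return pd.DataFrame(
        rows,
        columns=["Hugo_Symbol", "Tumor_Sample_Barcode",
                 "Variant_Classification", "Variant_Type", "Protein_Change"],
    )
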