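"""Per-patient module overrepresentation (the mini-driver statistic).

For one patient, each network module is tested for a disproportionate share
of that patient's mutated genes.  With N network genes, K of them in the
module, and n of the patient's mutated genes present in the network, the
observed in-module count k is compared to a Hypergeometric(N, K, n) null:
the one-tailed Fisher exact p-value is the upper tail P(X >= k).  P-values
are BH-adjusted within the patient's screen and a module is called enriched
at q < alpha (strict).  The background is always the whole network.

The same hypergeometric machinery drives local gene-set (GMT) enrichment
used to annotate modules functionally.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .community import Partition
from .mutations import PatientMutationProfile

logger = logging.getLogger(__name__)

__all__ = [
    "ModuleEnrichmentResult",
    "fisher_upper_tail",
    "module_overrepresentation",
    "cohort_overrepresentation",
    "bh_adjust",
    "e_status",
    "cohort_enrichment_summary",
    "union_enrichment_fraction",
    "read_gmt",
    "geneset_enrichment",
]


@dataclass
class ModuleEnrichmentResult:
    """One patient-module overrepresentation test."""

    patient: str
    module: int
    k: int          # patient's mutated genes inside the module
    K: int          # module size
    n: int          # patient's mutated genes inside the network
    N: int          # network gene count (background)
    p_value: float
    q_value: float = float("nan")
    enriched: bool = False
    testable: bool = True


def fisher_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """One-tailed Fisher exact p: P(X >= k), X ~ Hypergeometric(N, K, n)."""
    return float(min(1.0, hypergeom.sf(k - 1, N, K, n)))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    q_(i) = min_{j >= i} min(1, p_(j) * m / j) over the ascending order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    # q >= p holds mathematically; guard against 1-ulp rounding in p*m/m
    return np.maximum(q, p)


def module_overrepresentation(
    profile: PatientMutationProfile,
    partition: Partition,
    alpha: float = 0.05,
    min_module_size: int = 5,
) -> list[ModuleEnrichmentResult]:
    """Test every (sufficiently large) module of one patient's profile.

    Mutated genes are first intersected with the network gene set; BH
    adjustment is applied across the modules tested for this patient.  A
    patient with no mutated gene in the network is untestable: every module
    reports p = q = 1, enriched = False, ``testable = False``.
    """
    if len(partition) == 0:
        raise ValueError("partition is empty")
    network_genes = set(partition.assignment)
    big_n = len(network_genes)
    in_network = profile.mutated_genes & network_genes
    n = len(in_network)
    sizes = partition.module_sizes
    tested_modules = [
        mod for mod in sorted(sizes) if sizes[mod] >= min_module_size
    ]
    results: list[ModuleEnrichmentResult] = []
    if n == 0:
        for mod in tested_modules:
            results.append(
                ModuleEnrichmentResult(
                    patient=profile.patient, module=mod, k=0, K=sizes[mod],
                    n=0, N=big_n, p_value=1.0, q_value=1.0,
                    enriched=False, testable=False,
                )
            )
        return results

    module_of = partition.assignment
    k_counts = {mod: 0 for mod in tested_modules}
    for gene in in_network:
        mod = module_of[gene]
        if mod in k_counts:
            k_counts[mod] += 1
    p_values = []
    for mod in tested_modules:
        k, big_k = k_counts[mod], sizes[mod]
        p_values.append(fisher_upper_tail(k, big_n, big_k, n))
    q_values = bh_adjust(p_values)
    for mod, p, q in zip(tested_modules, p_values, q_values):
        results.append(
            ModuleEnrichmentResult(
                patient=profile.patient, module=mod, k=k_counts[mod],
                K=sizes[mod], n=n, N=big_n, p_value=p, q_value=float(q),
                enriched=bool(q < alpha),
            )
        )
    return results


def cohort_overrepresentation(
    profiles: dict[str, PatientMutationProfile],
    partition: Partition,
    alpha: float = 0.05,
    min_module_size: int = 5,
    family: str = "patient",
) -> pd.DataFrame:
    """Long-format patient x module enrichment table for a whole cohort.

    ``family`` chooses the BH adjustment family: ``"patient"`` (default;
    each patient's modules form one screen) or ``"global"`` (one family
    across all patient-module tests).
    """
    if family not in ("patient", "global"):
        raise ValueError(f"family must be 'patient' or 'global', got {family!r}")
    rows = []
    for patient in sorted(profiles):
        for r in module_overrepresentation(
            profiles[patient], partition, alpha=alpha,
            min_module_size=min_module_size,
        ):
            rows.append(vars(r).copy())
    df = pd.DataFrame(rows)
    if family == "global" and not df.empty:
        testable = df["testable"].to_numpy()
        q = np.ones(len(df))
        if testable.any():
            q[testable] = bh_adjust(df.loc[testable, "p_value"].to_numpy())
        df["q_value"] = q
        df["enriched"] = (df["q_value"] < alpha) & testable
    return df


def e_status(
    results: pd.DataFrame, module: int, alpha: float = 0.05
) -> pd.Series:
    """Per-patient enrichment status for one designated module.

    True iff that patient's q-value for the module is strictly below
    ``alpha``; untestable patients are False.
    """
    sub = results[results["module"] == module]
    if sub.empty:
        raise ValueError(f"module {module} absent from results")
    status = (sub["q_value"] < alpha) & sub["testable"]
    return pd.Series(status.to_numpy(), index=sub["patient"].to_numpy(),
                     name=f"E_module_{module}")


def cohort_enrichment_summary(results: pd.DataFrame) -> pd.DataFrame:
    """Fraction of patients enriched, per module."""
    if results.empty or results["patient"].nunique() == 0:
        raise ValueError("no patients in results")
    n_patients = results["patient"].nunique()
    grouped = results.groupby("module")
    out = pd.DataFrame({
        "module": sorted(results["module"].unique()),
    })
    out["module_size"] = grouped["K"].first().reindex(out["module"]).to_numpy()
    out["fraction_enriched"] = (
        grouped["enriched"].sum().reindex(out["module"]) / n_patients
    ).to_numpy()
    out["n_patients"] = n_patients
    return out.sort_values("fraction_enriched", ascending=False,
                           ignore_index=True)


def union_enrichment_fraction(results: pd.DataFrame, modules) -> float:
    """Fraction of patients enriched in at least one of the given modules."""
    sub = results[results["module"].isin(list(modules))]
    n_patients = results["patient"].nunique()
    enriched_patients = sub.loc[sub["enriched"], "patient"].nunique()
    return enriched_patients / n_patients


def read_gmt(path) -> dict[str, set[str]]:
    """Read a Broad-format GMT file into ``{set name: genes}``.

    Each line is ``name<TAB>description<TAB>gene...``; duplicate genes
    within a line are stored once.
    """
    collection: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line has < 3 fields")
            name = fields[0]
            if name in collection:
                raise ValueError(f"{path}:{lineno}: duplicate gene-set name {name!r}")
            genes = {g.strip() for g in fields[2:] if g.strip()}
            collection[name] = genes
    if not collection:
        raise ValueError(f"{path}: empty GMT file")
    return collection


def geneset_enrichment(
    module_genes: set[str],
    background: set[str],
    collection: dict[str, set[str]],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric gene-set enrichment of one module against the network.

    Gene sets are intersected with the background (the whole network)
    before testing; sets disjoint from the background are skipped.
    """
    if not background:
        raise ValueError("background is empty")
    module_genes = set(module_genes)
    if not module_genes <= set(background):
        raise ValueError("module genes must be a subset of the background")
    big_n = len(background)
    n = len(module_genes)
    rows = []
    for name in sorted(collection):
        geneset = collection[name] & set(background)
        if not geneset:
            logger.info("gene set %r disjoint from background; skipped", name)
            continue
        k = len(geneset & module_genes)
        p = fisher_upper_tail(k, big_n, len(geneset), n)
        rows.append((name, k, len(geneset), p))
    df = pd.DataFrame(rows, columns=["geneset", "overlap", "set_size", "p_value"])
    if df.empty:
        return df.assign(q_value=[], significant=[])
    df["q_value"] = bh_adjust(df["p_value"].to_numpy())
    df["significant"] = df["q_value"] < alpha
    return df.sort_values("p_value", ignore_index=True)
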