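"""MAF-like somatic mutation tables and per-patient mutated-gene sets.

Non-synonymous status is decided by a closed whitelist of
Variant_Classification values; anything not listed (Silent, RNA, UTRs,
introns, ...) is excluded.  No significance-based driver filtering is
applied anywhere: weak-effect mutations are exactly the ones of interest.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "NONSYNONYMOUS_CLASSIFICATIONS",
    "PatientMutationProfile",
    "read_maf",
    "classify_nonsynonymous",
    "patient_gene_sets",
    "gene_mutation_frequency",
    "residue_mutation_frequency",
]

#: Closed whitelist of non-silent Variant_Classification values.
NONSYNONYMOUS_CLASSIFICATIONS = frozenset(
    {
        "Missense_Mutation",
        "Nonsense_Mutation",
        "Frame_Shift_Del",
        "Frame_Shift_Ins",
        "In_Frame_Ins",
        "In_Frame_Del",
        "Missense",
        "Splice_Site",
        "Translation_Start_Site",
        "Nonstop_Mutation",
    }
)

#: Accepted protein-change column names (HGVSp_Short-style dialects).
PROTEIN_CHANGE_COLUMNS = (
    "Protein_Change",
    "HGVSp_Short",
    "HGVSp",
    "amino_acid_change",
    "Amino_Acid_Change",
)

# one-letter ref, residue position, one-letter alt (or stop), optional p. prefix
_PROTEIN_CHANGE_RE = re.compile(r"^(?:p\.)?([A-Z])(\d+)([A-Z*])")


@dataclass(frozen=True)
class PatientMutationProfile:
    """One patient's set of genes carrying non-synonymous somatic mutations."""

    patient: str
    mutated_genes: frozenset[str]

    @property
    def mutational_load(self) -> int:
        return len(self.mutated_genes)


def read_maf(path, *, sep: str = "\t") -> pd.DataFrame:
    """Read a MAF-like TSV, tolerant of extra columns and ``#`` comment lines."""
    df = pd.read_csv(path, sep=sep, comment="#", dtype=str, low_memory=False)
    required = {"Hugo_Symbol", "Tumor_Sample_Barcode", "Variant_Classification"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required MAF columns {sorted(missing)}")
    return df


def classify_nonsynonymous(variant_classification: str) -> bool:
    """True iff the (trimmed) classification is in the non-silent whitelist."""
    return str(variant_classification).strip() in NONSYNONYMOUS_CLASSIFICATIONS


def _patient_ids(table: pd.DataFrame, barcode_length: int | None) -> pd.Series:
    ids = table["Tumor_Sample_Barcode"].astype(str).str.strip()
    if barcode_length is not None:
        ids = ids.str[:barcode_length]
    return ids


def patient_gene_sets(
    table: pd.DataFrame,
    exclude_patients: set[str] = frozenset(),
    *,
    barcode_length: int | None = None,
) -> dict[str, PatientMutationProfile]:
    """Per-patient set of genes with >= 1 non-synonymous mutation.

    Duplicate hits to one gene collapse to a single set member; patients
    whose filtered set is empty are omitted.  ``barcode_length`` optionally
    truncates sample barcodes to a patient-level prefix (TCGA convention);
    the default uses the field verbatim.
    """
    if table.empty:
        raise ValueError("mutation table is empty")
    keep = table["Variant_Classification"].astype(str).str.strip().isin(
        NONSYNONYMOUS_CLASSIFICATIONS
    )
    sub = table.loc[keep].copy()
    sub["_patient"] = _patient_ids(sub, barcode_length)
    sub = sub[~sub["_patient"].isin(set(exclude_patients))]
    profiles: dict[str, PatientMutationProfile] = {}
    for patient, group in sub.groupby("_patient", sort=True):
        genes = frozenset(group["Hugo_Symbol"].astype(str).str.strip())
        genes = frozenset(g for g in genes if g)
        if genes:
            profiles[patient] = PatientMutationProfile(patient, genes)
    return profiles


def gene_mutation_frequency(
    profiles: dict[str, PatientMutationProfile]
) -> pd.DataFrame:
    """Per-gene patient count and fraction of profiled patients."""
    if not profiles:
        raise ValueError("no mutation profiles supplied")
    counts: dict[str, int] = {}
    for profile in profiles.values():
        for gene in profile.mutated_genes:
            counts[gene] = counts.get(gene, 0) + 1
    n = len(profiles)
    df = pd.DataFrame(
        {"gene": list(counts), "count": list(counts.values())}
    )
    df["fraction"] = df["count"] / n
    return df.sort_values(
        ["count", "gene"], ascending=[False, True], ignore_index=True
    )


def residue_mutation_frequency(
    table: pd.DataFrame, *, barcode_length: int | None = None
) -> pd.DataFrame:
    """Per-residue mutation counts from single-nucleotide variants only.

    Counts distinct patients per (gene, residue position), pooling different
    substitutions at the same position (e.g. KRAS G12C and G12D both count
    towards KRAS residue 12).  Rows that are not SNVs, are not
    non-synonymous, or lack a parseable protein change are skipped.
    """
    if "Variant_Type" not in table.columns:
        raise ValueError("mutation table lacks a Variant_Type column")
    protein_col = next(
        (c for c in PROTEIN_CHANGE_COLUMNS if c in table.columns), None
    )
    if protein_col is None:
        raise ValueError(
            f"no protein-change column found (looked for {PROTEIN_CHANGE_COLUMNS})"
        )
    snv = table[
        (table["Variant_Type"].astype(str).str.strip() == "SNP")
        & table["Variant_Classification"].astype(str).str.strip().isin(
            NONSYNONYMOUS_CLASSIFICATIONS
        )
    ].copy()
    snv["_patient"] = _patient_ids(snv, barcode_length)

    seen: set[tuple[str, int, str]] = set()
    counts: dict[tuple[str, int], int] = {}
    n_unparseable = 0
    for gene, patient, change in zip(
        snv["Hugo_Symbol"].astype(str).str.strip(),
        snv["_patient"],
        snv[protein_col].astype(str).str.strip(),
    ):
        match = _PROTEIN_CHANGE_RE.match(change)
        if match is None:
            n_unparseable += 1
            continue
        pos = int(match.group(2))
        key = (gene, pos, patient)
        if key in seen:
            continue
        seen.add(key)
        counts[(gene, pos)] = counts.get((gene, pos), 0) + 1
    if n_unparseable:
        logger.info("skipped %d SNV rows with unparseable protein change",
                    n_unparseable)
    df = pd.DataFrame(
        [(g, p, c) for (g, p), c in counts.items()],
        columns=["gene", "position", "count"],
    )
    return df.sort_values(
        ["count", "gene", "position"], ascending=[False, True, True],
        ignore_index=True,
    )
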