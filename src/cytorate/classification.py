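"""Cytonuclear functional classification of nuclear genes.

Genes are partitioned into tiers of increasing intimacy with the organelle
genomes: organelle-targeted, organelle-interacting, and members of enzyme
complexes with organelle-encoded subunits (MTEC/PTEC for mitochondria and
plastids respectively).  Classification propagates a curated reference
annotation through orthogroups: sharing an orthogroup with an interacting
reference gene confers the interacting tier, otherwise de novo targeting
predictor votes combined with the orthogroup's reference targeting majority
decide mere targeting.  Genes targeted to neither organelle are 'NOT'.
Dual-targeted genes belong to both organelle partitions.
"""

from __future__ import annotations

import logging
from typing import Iterable

import pandas as pd

from .quintet_inference import Quintet

logger = logging.getLogger("cytorate")

#: boolean tier columns of a classification table, in nesting order
TIER_COLUMNS = (
    "mito_targeted",
    "plastid_targeted",
    "mito_interacting",
    "plastid_interacting",
    "mtec",
    "ptec",
)

#: overlapping analysis partitions derived from the tier flags
PARTITIONS = {
    "NOT": lambda r: not (r["mito_targeted"] or r["plastid_targeted"]),
    "mito_targeted": lambda r: r["mito_targeted"],
    "plastid_targeted": lambda r: r["plastid_targeted"],
    "mito_targeted_noninteracting": lambda r: r["mito_targeted"] and not r["mito_interacting"],
    "plastid_targeted_noninteracting": lambda r: r["plastid_targeted"] and not r["plastid_interacting"],
    "mito_interacting": lambda r: r["mito_interacting"],
    "plastid_interacting": lambda r: r["plastid_interacting"],
    "mtec": lambda r: r["mtec"],
    "ptec": lambda r: r["ptec"],
}


def _empty_row(gene_id: str, warning: bool) -> dict:
    row = {"gene_id": gene_id, "category": "none", "warning": warning}
    row.update({c: False for c in TIER_COLUMNS})
    return row


def classify_genes(
    orthogroups: pd.DataFrame,
    reference_annotation: pd.DataFrame,
    predictor_votes: pd.DataFrame,
) -> pd.DataFrame:
    """Classify every focal gene into cytonuclear tiers.

    orthogroups: columns (orthogroup_id, gene_id, species); reference genes
    are the rows whose gene_id appears in reference_annotation.
    reference_annotation: gene_id plus boolean tier columns and a fine
    'category' label.  predictor_votes: gene_id, mito_votes, plastid_votes
    (counts of de novo targeting predictors, 0-4).

    Rules: a gene sharing an orthogroup with an interacting reference gene
    inherits that gene's interaction chain(s).  Otherwise it is
    organelle-targeted iff at least one predictor votes for that organelle
    and at least half of the reference genes in the orthogroup are
    organelle-targeted (dual-targeted reference genes counted once).
    Everything else — including genes absent from all inputs, which are
    flagged — is NOT.
    """
    ref = reference_annotation.set_index("gene_id")
    votes = predictor_votes.set_index("gene_id")

    gene_to_ogs: dict[str, list[str]] = {}
    og_members: dict[str, list[str]] = {}
    for row in orthogroups.itertuples(index=False):
        og_members.setdefault(row.orthogroup_id, []).append(row.gene_id)
        gene_to_ogs.setdefault(row.gene_id, []).append(row.orthogroup_id)

    focal_genes = sorted(
        set(votes.index) | {g for g in gene_to_ogs if g not in ref.index}
    )

    rows = []
    for gene in focal_genes:
        ogs = gene_to_ogs.get(gene, [])
        ref_ids = sorted(
            {m for og in ogs for m in og_members[og] if m in ref.index}
        )
        if not ref_ids:
            row = _empty_row(gene, warning=True)
            rows.append(row)
            continue
        refs = ref.loc[ref_ids]
        row = _empty_row(gene, warning=False)

        interacting = refs[
            refs[["mito_interacting", "plastid_interacting"]].any(axis=1)
        ]
        if len(interacting):
            row["mito_interacting"] = bool(interacting["mito_interacting"].any())
            row["plastid_interacting"] = bool(interacting["plastid_interacting"].any())
            row["mtec"] = bool(interacting["mtec"].any())
            row["ptec"] = bool(interacting["ptec"].any())
            row["mito_targeted"] = row["mito_interacting"]
            row["plastid_targeted"] = row["plastid_interacting"]
            cats = sorted(set(interacting["category"]) - {"none"})
            row["category"] = ";".join(cats) if cats else "none"
        else:
            targeted_frac = (
                refs[["mito_targeted", "plastid_targeted"]].any(axis=1).mean()
            )
            if targeted_frac >= 0.5 and gene in votes.index:
                v = votes.loc[gene]
                row["mito_targeted"] = bool(v["mito_votes"] >= 1)
                row["plastid_targeted"] = bool(v["plastid_votes"] >= 1)
        rows.append(row)

    out = pd.DataFrame(rows, columns=["gene_id", *TIER_COLUMNS, "category", "warning"])
    _check_nesting(out)
    return out


def _check_nesting(table: pd.DataFrame) -> None:
    """Enzyme-complex implies interacting implies targeted, per organelle."""
    bad = (
        (table["mtec"] & ~table["mito_interacting"])
        | (table["mito_interacting"] & ~table["mito_targeted"])
        | (table["ptec"] & ~table["plastid_interacting"])
        | (table["plastid_interacting"] & ~table["plastid_targeted"])
    )
    if bad.any():
        raise AssertionError("tier nesting violated in classification output")


def propagate_to_quintets(
    quintets: Iterable[Quintet],
    classification: pd.DataFrame,
    reference_species_role: str = "diploid_maternal",
) -> pd.DataFrame:
    """Label each quintet with its reference-species member's classification.

    The reference role is the maternal diploid by default; datasets whose
    maternal diploid lacks a usable annotation (e.g. transcriptome-only)
    may use the paternal diploid instead.  Quintets whose reference member
    is unclassified are labeled NOT and flagged.
    """
    if reference_species_role not in ("diploid_maternal", "diploid_paternal"):
        raise ValueError("reference_species_role must be a diploid role")
    cls = classification.set_index("gene_id")
    rows = []
    n_warn = 0
    for q in quintets:
        member = q.members[reference_species_role]
        if member in cls.index:
            src = cls.loc[member]
            row = {"gene_id": q.gene_id, "reference_member": member,
                   "category": src["category"], "warning": bool(src["warning"])}
            row.update({c: bool(src[c]) for c in TIER_COLUMNS})
        else:
            row = _empty_row(q.gene_id, warning=True)
            row["gene_id"] = q.gene_id
            row["reference_member"] = member
            n_warn += 1
        rows.append(row)
    if n_warn:
        logger.warning("%d quintets had unclassified reference members", n_warn)
    return pd.DataFrame(
        rows, columns=["gene_id", "reference_member", *TIER_COLUMNS, "category", "warning"]
    )


def partition_members(table: pd.DataFrame, partition: str) -> list[str]:
    """gene_ids belonging to one analysis partition (partitions overlap)."""
    pred = PARTITIONS[partition]
    return [r["gene_id"] for _, r in table.iterrows() if pred(r)]
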