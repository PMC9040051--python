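"""Single-copy orthologous quintet inference from gene trees and synteny.

A quintet is an orthologous group with exactly one sequence from the
outgroup, one from each diploid relative, and one from each polyploid
subgenome.  Gene trees are first cleaned (low-support splits collapsed),
species-complete subtrees are pruned out, lineage-specific duplicates
trimmed to the longest sequence, and the resulting phylogenetic quintets
merged with an independent synteny-derived set.  Quintets whose topology
conflicts with the species tree (a signature of homoeologous exchange or
gene conversion) are excluded, as are quintets whose tree-wide synonymous
divergence exceeds a per-dataset cutoff (poor alignments).
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping, NamedTuple

import numpy as np
import pandas as pd

from .codon_ml import BranchRates
from .io_formats import (
    QUINTET_ROLES,
    GeneTree,
    Role,
    SpeciesMap,
    log_stage,
    resolve_roles,
)

CONCORDANT = "concordant"
DISCORDANT = "discordant"
UNRESOLVED = "unresolved"


@dataclasses.dataclass(frozen=True)
class Quintet:
    """Five member sequence ids, one per quintet role."""

    gene_id: str
    members: Mapping[str, str]
    source: str = "phylogenetic"  # phylogenetic | syntenic | both

    def __post_init__(self):
        if set(self.members) != set(QUINTET_ROLES):
            raise ValueError(
                f"quintet {self.gene_id!r} must have exactly one member per role"
            )
        if len(set(self.members.values())) != 5:
            raise ValueError(f"quintet {self.gene_id!r} has repeated members")

    @property
    def member_set(self) -> frozenset[str]:
        return frozenset(self.members.values())


# ---------------------------------------------------------------------------
# tree cleaning


def collapse_low_support(tree: GeneTree, threshold: int = 50) -> GeneTree:
    """Collapse internal splits with bootstrap support <= threshold.

    Splits without a recorded support value are kept (only measured low
    support is evidence against a split).  Idempotent; tip set unchanged.
    """
    out = tree.clone()
    to_collapse = []
    for node in out.tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        if node.label is None or not str(node.label).strip():
            continue
        if int(float(node.label)) <= threshold:
            to_collapse.append(node)
    for node in to_collapse:
        node.edge.collapse()
    return GeneTree(out.tree)


# ---------------------------------------------------------------------------
# species-complete subtree extraction


def extract_species_complete_subtrees(
    tree: GeneTree, species_map: SpeciesMap
) -> list[GeneTree]:
    """All monophyletic, minimally inclusive, species-complete subtrees.

    A clade qualifies when it contains at least one tip from each of the
    four species and no descendant clade also qualifies; qualifying clades
    are therefore disjoint in tips.  The root clade itself may qualify.
    """
    roles = resolve_roles(tree, species_map)
    all_roles = set(Role.ALL)

    selected_tip_sets: list[list[str]] = []

    def visit(node) -> tuple[set[str], bool]:
        """Returns (roles below node, any qualifying clade below node)."""
        if node.is_leaf():
            return {roles[node.taxon.label].role}, False
        seen: set[str] = set()
        any_below = False
        for child in node.child_nodes():
            child_roles, child_has = visit(child)
            seen |= child_roles
            any_below = any_below or child_has
        if not any_below and seen >= all_roles:
            selected_tip_sets.append([l.taxon.label for l in node.leaf_iter()])
            return seen, True
        return seen, any_below

    visit(tree.tree.seed_node)

    out = []
    for tips in selected_tip_sets:
        sub = tree.clone()
        sub.tree.retain_taxa_with_labels(tips)
        out.append(GeneTree(sub.tree))
    return out


# ---------------------------------------------------------------------------
# duplicate trimming


def _lineage_unit(label: "RoleLabelLike") -> tuple[str, str | None]:
    if label.role == Role.POLYPLOID:
        return (label.role, label.subgenome)
    return (label.role, None)


def trim_lineage_duplicates(
    subtree: GeneTree,
    lengths: Mapping[str, int],
    seed: int = 0,
    species_map: SpeciesMap | None = None,
) -> GeneTree:
    """Reduce each maximal single-lineage clade to one representative tip.

    Within every maximal clade whose tips all come from one species (one
    subgenome, for the polyploid), only the longest sequence is kept; exact
    length ties are broken by a seeded uniform draw so reruns are
    reproducible.
    """
    if species_map is None:
        raise ValueError("species_map is required")
    roles = resolve_roles(subtree, species_map)
    rng = np.random.default_rng(seed)

    keep: list[str] = []

    def unit_of(node):
        tips = [l.taxon.label for l in node.leaf_iter()]
        units = {_lineage_unit(roles[t]) for t in tips}
        return (units.pop(), tips) if len(units) == 1 else (None, tips)

    def visit(node):
        unit, tips = unit_of(node)
        if unit is not None:
            if len(tips) == 1:
                keep.append(tips[0])
            else:
                lens = np.array([lengths.get(t, 0) for t in tips])
                best = np.flatnonzero(lens == lens.max())
                choice = best[0] if len(best) == 1 else rng.choice(best)
                keep.append(tips[int(choice)])
            return
        for child in node.child_nodes():
            visit(child)

    visit(subtree.tree.seed_node)
    out = subtree.clone()
    out.tree.retain_taxa_with_labels(keep)
    return GeneTree(out.tree)


# ---------------------------------------------------------------------------
# quintet assembly and merging


def quintet_from_tree(
    tree: GeneTree, species_map: SpeciesMap, gene_id: str, source: str = "phylogenetic"
) -> Quintet | None:
    """A Quintet if the tree has exactly one tip per quintet role, else None."""
    try:
        roles = resolve_roles(tree, species_map)
        members = {}
        for tip, label in roles.items():
            members[label.quintet_role] = tip
    except (KeyError, ValueError):
        return None
    if len(roles) != 5 or set(members) != set(QUINTET_ROLES):
        return None
    return Quintet(gene_id=gene_id, members=members, source=source)


def infer_phylogenetic_quintets(
    trees: Iterable[GeneTree],
    species_map: SpeciesMap,
    lengths: Mapping[str, int],
    support_threshold: int = 50,
    seed: int = 0,
) -> list[Quintet]:
    """Full gene-tree pipeline: collapse, extract, trim, assemble quintets."""
    quintets = []
    n_trees = 0
    for i, tree in enumerate(trees):
        n_trees += 1
        collapsed = collapse_low_support(tree, support_threshold)
        for j, sub in enumerate(
            extract_species_complete_subtrees(collapsed, species_map)
        ):
            trimmed = trim_lineage_duplicates(
                sub, lengths, seed=seed + 7919 * i + j, species_map=species_map
            )
            q = quintet_from_tree(
                trimmed, species_map, gene_id=f"pt{i + 1:05d}.{j}", source="phylogenetic"
            )
            if q is not None:
                quintets.append(q)
    log_stage("phylogenetic quintets", n_trees, len(quintets))
    return quintets


class MergedQuintets(NamedTuple):
    union: list[Quintet]
    intersection: list[Quintet]
    conflicts: list[Quintet]


def merge_quintet_sets(
    phylo: Iterable[Quintet], syntenic: Iterable[Quintet]
) -> MergedQuintets:
    """Reconcile phylogenetic and syntenic quintets.

    Intersection: identical five-member sets found by both methods.  Union:
    the intersection plus quintets from either method sharing no member
    with any quintet of the other method.  Quintets that overlap with but
    are not identical to a quintet of the other method are conflicts and
    appear in neither output.
    """
    phylo, syntenic = list(phylo), list(syntenic)
    for group, name in ((phylo, "phylogenetic"), (syntenic, "syntenic")):
        ids = [q.gene_id for q in group]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate gene_id in {name} quintets")

    def member_index(quintets):
        idx: dict[str, list[Quintet]] = {}
        for q in quintets:
            for m in q.member_set:
                idx.setdefault(m, []).append(q)
        return idx

    idx_p, idx_s = member_index(phylo), member_index(syntenic)

    def classify(quintets, other_index):
        identical, clean, conflict = [], [], []
        for q in quintets:
            partners = {id(p): p for m in q.member_set for p in other_index.get(m, [])}
            if not partners:
                clean.append(q)
            elif all(p.member_set == q.member_set for p in partners.values()):
                identical.append(q)
            else:
                conflict.append(q)
        return identical, clean, conflict

    ident_p, clean_p, confl_p = classify(phylo, idx_s)
    ident_s, clean_s, confl_s = classify(syntenic, idx_p)

    intersection = [
        dataclasses.replace(q, source="both") for q in ident_p
    ]
    union = intersection + clean_p + clean_s
    conflicts = confl_p + confl_s
    log_stage("quintet merge", len(phylo) + len(syntenic), len(union))
    return MergedQuintets(union=union, intersection=intersection, conflicts=conflicts)


# ---------------------------------------------------------------------------
# topology concordance


def check_topology_concordance(tree: GeneTree, species_map: SpeciesMap) -> str:
    """Classify a 5-tip quintet tree against the species topology.

    Rooted on the outgroup, the species history predicts the two cherries
    (polyploid_paternal, diploid_paternal) and (polyploid_maternal,
    diploid_maternal).  Concordant: both cherries present as resolved
    splits.  Discordant: any resolved ingroup clade conflicts with them.
    Unresolved: polytomies prevent both verdicts.
    """
    roles = resolve_roles(tree, species_map)
    if len(roles) != 5:
        raise ValueError(f"expected 5 tips, found {len(roles)}")
    by_role = {}
    for tip, label in roles.items():
        by_role[label.quintet_role] = tip
    if set(by_role) != set(QUINTET_ROLES):
        raise ValueError("tips do not cover the five quintet roles")

    rooted = tree.clone()
    out_leaf = next(
        l for l in rooted.tree.leaf_node_iter()
        if l.taxon.label == by_role["outgroup"]
    )
    rooted.tree.reroot_at_edge(out_leaf.edge, update_bipartitions=False)

    tip_role = {tip: role for role, tip in by_role.items()}
    cherries = (
        frozenset({"polyploid_paternal", "diploid_paternal"}),
        frozenset({"polyploid_maternal", "diploid_maternal"}),
    )
    ingroup = frozenset(set(QUINTET_ROLES) - {"outgroup"})

    seen = set()
    conflicting = False
    for node in rooted.tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        clade = frozenset(tip_role[l.taxon.label] for l in node.leaf_iter())
        if clade == ingroup or "outgroup" in clade:
            continue
        if clade in cherries:
            seen.add(clade)
        elif len(clade) >= 2:
            conflicting = True
    if conflicting:
        return DISCORDANT
    if len(seen) == 2:
        return CONCORDANT
    return UNRESOLVED


# ---------------------------------------------------------------------------
# dS quality filter


def filter_by_tree_ds(quintet_rates: BranchRates, cutoff: float) -> bool:
    """Keep (True) iff the tree-wide synonymous branch length is <= cutoff.

    The cutoff is a per-dataset maximum, read inclusively: a quintet exactly
    at the cutoff is kept.
    """
    return quintet_rates.tree_ds <= cutoff


# ---------------------------------------------------------------------------
# tabular interfaces


def quintets_to_table(quintets: Iterable[Quintet]) -> pd.DataFrame:
    rows = []
    for q in quintets:
        row = {"gene_id": q.gene_id, "source": q.source}
        row.update(q.members)
        rows.append(row)
    return pd.DataFrame(rows, columns=["gene_id", "source", *QUINTET_ROLES])


def quintets_from_table(table: pd.DataFrame, source: str | None = None) -> list[Quintet]:
    out = []
    for _, row in table.iterrows():
        out.append(
            Quintet(
                gene_id=str(row["gene_id"]),
                members={r: str(row[r]) for r in QUINTET_ROLES},
                source=source or str(row.get("source", "syntenic")),
            )
        )
    return out
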