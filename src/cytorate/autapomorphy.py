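"""Radical and conservative autapomorphies on polyploid terminal branches.

An autapomorphy here is a derived amino acid change on a focal terminal
branch at a site that is otherwise conserved across the quintet: the focal
tip differs from its reconstructed parent, the other four tips share one
amino acid, and the parent state equals that shared residue (so the change
is derived, not ancestral).  Changes are scored radical or conservative by
a symmetric 20x20 amino acid exchange matrix thresholded at a configurable
score; subgenome bias per category is tested against the non-organelle
background with Fisher's exact test.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .codon_ml import TIP_PARENT, AncestralStates
from .genetics import AMINO_ACIDS
from .io_formats import CodonAlignment

RADICAL = "radical"
CONSERVATIVE = "conservative"


# ---------------------------------------------------------------------------
# exchange matrices


@dataclasses.dataclass
class ExchangeMatrix:
    """Symmetric amino acid pair scores in [0, 1]; higher = more radical."""

    scores: np.ndarray
    name: str = "custom"

    def __post_init__(self):
        s = np.asarray(self.scores, float)
        if s.shape != (20, 20):
            raise ValueError("exchange matrix must be 20x20")
        if not np.allclose(s, s.T, atol=1e-12):
            raise ValueError("exchange matrix must be symmetric")
        off = s[~np.eye(20, dtype=bool)]
        if off.min() < 0 or off.max() > 1:
            raise ValueError("exchange scores must lie in [0, 1]")
        self.scores = s

    def score(self, from_aa: str, to_aa: str) -> float:
        i = AMINO_ACIDS.find(from_aa.upper())
        j = AMINO_ACIDS.find(to_aa.upper())
        if i < 0 or j < 0:
            raise ValueError(f"nonstandard residue in pair ({from_aa}, {to_aa})")
        return float(self.scores[i, j])

    @classmethod
    def from_table(cls, path, name: str | None = None) -> "ExchangeMatrix":
        """Load a 20x20 tab-separated table with amino acid header row/column."""
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.str.upper()
        df.columns = df.columns.str.upper()
        order = list(AMINO_ACIDS)
        missing = set(order) - set(df.index) | set(order) - set(df.columns)
        if missing:
            raise ValueError(f"exchange table lacks amino acids: {sorted(missing)}")
        return cls(df.loc[order, order].to_numpy(float),
                   name=name or Path(path).stem)

    def to_table(self, path) -> None:
        df = pd.DataFrame(self.scores, index=list(AMINO_ACIDS), columns=list(AMINO_ACIDS))
        df.to_csv(path, sep="\t")


# physicochemical classes: charge, polarity, and aromatic/aliphatic character
_AA_CLASS = {
    "D": "negative", "E": "negative",
    "K": "positive", "R": "positive", "H": "positive",
    "N": "polar", "Q": "polar", "S": "polar", "T": "polar", "Y": "polar",
    "C": "special", "G": "special", "P": "special",
    "A": "nonpolar", "V": "nonpolar", "L": "nonpolar", "I": "nonpolar",
    "M": "nonpolar", "F": "nonpolar", "W": "nonpolar",
}


def default_exchange_matrix() -> ExchangeMatrix:
    """Synthetic class-based exchange matrix (for tests and examples).

    A stand-in for curated radical/conservative indices: replacements
    crossing physicochemical classes (charge sign, polarity, special
    residues) score 1.0, within-class replacements 0.0.  Real analyses
    should load a curated matrix with from_table.
    """
    s = np.zeros((20, 20))
    for i, a in enumerate(AMINO_ACIDS):
        for j, b in enumerate(AMINO_ACIDS):
            if i != j and _AA_CLASS[a] != _AA_CLASS[b]:
                s[i, j] = 1.0
    return ExchangeMatrix(s, name="synthetic-class-based")


def classify_radical(
    from_aa: str, to_aa: str, matrix: ExchangeMatrix, threshold: float = 0.5
) -> str:
    """'radical' iff the exchange score strictly exceeds the threshold."""
    return RADICAL if matrix.score(from_aa, to_aa) > threshold else CONSERVATIVE


# ---------------------------------------------------------------------------
# autapomorphy detection


@dataclasses.dataclass
class AutapomorphyCounts:
    """Derived changes at conserved sites on one terminal branch."""

    gene_id: str
    branch: str
    total: int
    radical: int
    changes: list[tuple[int, str, str]] = dataclasses.field(default_factory=list)

    def __post_init__(self):
        if self.radical > self.total:
            raise ValueError("radical count cannot exceed total")

    @property
    def conservative(self) -> int:
        return self.total - self.radical


def find_autapomorphies(
    alignment: CodonAlignment,
    ancestral: AncestralStates,
    branch: str,
    role_map: Mapping[str, str],
    matrix: ExchangeMatrix | None = None,
    threshold: float = 0.5,
    gene_id: str = "gene",
) -> AutapomorphyCounts:
    """Count derived amino acid changes at quintet-conserved sites.

    A site counts when (a) the focal tip's amino acid differs from its
    reconstructed parent's, (b) the other four tips share one amino acid,
    (c) the parent state equals that shared residue, and (d) the site has
    no gaps or ambiguity in any sequence.
    """
    if branch not in TIP_PARENT:
        raise ValueError(f"{branch!r} is not a terminal branch")
    matrix = matrix or default_exchange_matrix()
    parent_node = TIP_PARENT[branch]
    aa = dict(zip(alignment.ids, alignment.amino_acids()))
    focal = aa[role_map[branch]]
    others = [aa[role_map[r]] for r in role_map if r != branch]
    parent = ancestral.amino_acids(parent_node)

    total = radical = 0
    changes = []
    for site in range(len(focal)):
        col = [focal[site]] + [o[site] for o in others]
        if any(c == "X" or c == "*" for c in col):
            continue
        shared = {o[site] for o in others}
        if len(shared) != 1:
            continue
        (conserved,) = shared
        if focal[site] == conserved:
            continue
        if parent[site] != conserved:
            continue  # change is not derived on the focal branch
        total += 1
        kind = classify_radical(parent[site], focal[site], matrix, threshold)
        if kind == RADICAL:
            radical += 1
        changes.append((site, parent[site], focal[site]))
    return AutapomorphyCounts(
        gene_id=gene_id, branch=branch, total=total, radical=radical, changes=changes
    )


# ---------------------------------------------------------------------------
# subgenome bias test


@dataclasses.dataclass
class FisherResult:
    odds_ratio: float
    p: float
    table: tuple[tuple[int, int], tuple[int, int]]

    @property
    def defined(self) -> bool:
        return np.isfinite(self.p)


def bias_fisher_test(
    category_counts: tuple[int, int], not_counts: tuple[int, int]
) -> FisherResult:
    """Fisher's exact test of subgenome bias in a category vs background.

    Rows are (paternal, maternal) autapomorphy counts for the category and
    for the NOT background.  Two-sided p from the conditional hypergeometric
    distribution; a zero margin makes the test undefined.
    """
    table = (tuple(int(x) for x in category_counts),
             tuple(int(x) for x in not_counts))
    arr = np.array(table)
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        return FisherResult(float("nan"), float("nan"), table)
    res = stats.fisher_exact(arr, alternative="two-sided")
    return FisherResult(float(res.statistic), float(res.pvalue), table)


def aggregate_counts(counts: list[AutapomorphyCounts], radical_only: bool = False
                     ) -> tuple[int, int]:
    """(paternal, maternal) totals over per-gene per-branch counts."""
    pat = sum((c.radical if radical_only else c.total) for c in counts
              if c.branch == "polyploid_paternal")
    mat = sum((c.radical if radical_only else c.total) for c in counts
              if c.branch == "polyploid_maternal")
    return pat, mat
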