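"""Generators for every input the pipeline consumes.

Quintet alignments are evolved under the same MG94xHKY codon process the ML
engine fits (branch-specific omega, shared kappa, F3x4-style frequencies),
so parameter recovery is well-posed.  Gene-tree sets, classification tables
and gene-content tables are generated with the statistical structure the
downstream stages assume: topological discordance mimicking homoeologous
exchange, lineage-specific paralogs, low bootstrap support, interaction
tiers with dual targeting, and subgenome-biased homoeolog loss.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, NamedTuple

import numpy as np
import pandas as pd

from .codon_ml import QUINTET_BRANCHES, BranchRate, BranchRates
from .genetics import SENSE_CODONS, UNIFORM_POSITIONS, CodonModel
from .io_formats import CodonAlignment, GeneTree, IdRule, SpeciesMap

#: species map used for all synthetic data; polyploid ids encode the
#: subgenome in a chromosome letter (M = maternal, P = paternal)
DEFAULT_SPECIES_MAP = SpeciesMap(
    roles={
        "outgroup": "Outg",
        "diploid_maternal": "Dmat",
        "diploid_paternal": "Dpat",
        "polyploid": "Poly",
    },
    id_rule=IdRule(
        pattern=r"^(?P<tag>[^_]+)_(?P<chrom>[A-Za-z])?",
        subgenome_by_chrom={"M": "maternal", "P": "paternal"},
    ),
)

_TIP_IDS = {
    "polyploid_paternal": "Poly_P{g}",
    "diploid_paternal": "Dpat_{g}",
    "polyploid_maternal": "Poly_M{g}",
    "diploid_maternal": "Dmat_{g}",
    "outgroup": "Outg_{g}",
}


def tip_ids(gene: str = "g1") -> dict[str, str]:
    """Sequence ids of one synthetic quintet, keyed by quintet role."""
    return {role: tpl.format(g=gene) for role, tpl in _TIP_IDS.items()}


# ---------------------------------------------------------------------------
# codon alignments


@dataclasses.dataclass
class QuintetSimParams:
    """Parameters of one simulated quintet gene.

    branch_lengths are expected codon substitutions per codon site per
    branch; omega_by_branch gives the branch-specific dN/dS.  Defaults
    reflect moderately diverged angiosperm quintets: tree-wide synonymous
    divergence well below saturation and genome-wide omega near 0.2.
    """

    branch_lengths: Mapping[str, float] | float = 0.2
    kappa: float = 2.0
    omega_by_branch: Mapping[str, float] | float = 0.2
    pos_freqs: np.ndarray = dataclasses.field(
        default_factory=lambda: UNIFORM_POSITIONS.copy()
    )
    n_codons: int = 500
    seed: int = 1
    gene_id: str = "g1"

    def lengths(self) -> np.ndarray:
        if isinstance(self.branch_lengths, Mapping):
            arr = np.array([self.branch_lengths[b] for b in QUINTET_BRANCHES], float)
        else:
            arr = np.full(7, float(self.branch_lengths))
        if np.any(arr < 0):
            raise ValueError("branch lengths must be non-negative")
        return arr

    def omegas(self) -> np.ndarray:
        if isinstance(self.omega_by_branch, Mapping):
            arr = np.array([self.omega_by_branch[b] for b in QUINTET_BRANCHES], float)
        else:
            arr = np.full(7, float(self.omega_by_branch))
        if np.any(arr < 0):
            raise ValueError("omega must be non-negative")
        return arr


def simulate_quintet_alignment(
    params: QuintetSimParams,
) -> tuple[CodonAlignment, GeneTree, BranchRates]:
    """Evolve one quintet alignment; returns alignment, tree, true rates.

    The root codon is drawn from the stationary distribution and each branch
    applies the matrix exponential of its scaled generator.  True per-branch
    (dN, dS, omega) are the analytic values implied by the generator, in the
    same convention the ML fit reports.
    """
    if params.n_codons <= 0:
        raise ValueError("n_codons must be positive")
    rng = np.random.default_rng(params.seed)
    model = CodonModel(params.kappa, params.pos_freqs)
    t = params.lengths()
    w = params.omegas()
    n = params.n_codons

    def evolve(parent_states: np.ndarray, k: int) -> np.ndarray:
        p = model.transition_matrix(w[k], t[k])
        u = rng.random(n)
        cdf = np.cumsum(p, axis=1)
        return np.array(
            [np.searchsorted(cdf[s], x) for s, x in zip(parent_states, u)]
        )

    root = rng.choice(len(model.pi), size=n, p=model.pi)
    n_pat = evolve(root, 5)
    n_mat = evolve(root, 6)
    tips = {
        "polyploid_paternal": evolve(n_pat, 0),
        "diploid_paternal": evolve(n_pat, 1),
        "polyploid_maternal": evolve(n_mat, 2),
        "diploid_maternal": evolve(n_mat, 3),
        "outgroup": evolve(root, 4),
    }

    ids = tip_ids(params.gene_id)
    order = list(_TIP_IDS)  # engine tip order
    seqs = [
        "".join(SENSE_CODONS[s] for s in tips[role]) for role in order
    ]
    aln = CodonAlignment([ids[r] for r in order], seqs)

    newick = "((({pp}:{t0},{dp}:{t1}){s}:{t5},({pm}:{t2},{dm}:{t3}){s}:{t6}){s},{o}:{t4});".format(
        pp=ids["polyploid_paternal"], dp=ids["diploid_paternal"],
        pm=ids["polyploid_maternal"], dm=ids["diploid_maternal"],
        o=ids["outgroup"], s=100,
        t0=t[0], t1=t[1], t2=t[2], t3=t[3], t4=t[4], t5=t[5], t6=t[6],
    )
    tree = GeneTree.from_newick(newick)

    branches = {}
    for k, label in enumerate(QUINTET_BRANCHES):
        dn, ds = model.branch_dn_ds(w[k], t[k])
        omega = w[k] if t[k] > 0 else float("nan")
        branches[label] = BranchRate(float(t[k]), dn, ds, float(omega))
    truth = BranchRates(branches=branches, kappa=params.kappa, lnl=float("nan"))
    return aln, tree, truth


def simulate_quintet_genes(
    n_genes: int,
    n_codons: int,
    seed: int,
    *,
    branch_lengths=0.2,
    kappa: float = 2.0,
    omega_by_branch=0.2,
    prefix: str = "g",
) -> list[tuple[str, CodonAlignment, BranchRates]]:
    """Simulate a set of quintet genes sharing one parameter regime."""
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_genes):
        gid = f"{prefix}{i + 1:04d}"
        params = QuintetSimParams(
            branch_lengths=branch_lengths,
            kappa=kappa,
            omega_by_branch=omega_by_branch,
            n_codons=n_codons,
            seed=int(rng.integers(1, 2**31 - 1)),
            gene_id=gid,
        )
        aln, _, truth = simulate_quintet_alignment(params)
        out.append((gid, aln, truth))
    return out


# ---------------------------------------------------------------------------
# gene-tree sets


def simulate_gene_tree_set(
    n_genes: int,
    discordance_rate: float = 0.0,
    duplication_rate: float = 0.0,
    low_support_rate: float = 0.0,
    seed: int = 1,
) -> tuple[list[GeneTree], pd.DataFrame]:
    """Gene trees exercising quintet inference, plus a truth manifest.

    Each gene is the species topology; with probability ``discordance_rate``
    one diploid tip is swapped with the opposite-subgenome polyploid tip
    (mimicking homoeologous exchange); with probability ``duplication_rate``
    a random lineage gains a paralog tip; with probability
    ``low_support_rate`` one internal split receives bootstrap support <= 50.
    """
    for name, r in (
        ("discordance_rate", discordance_rate),
        ("duplication_rate", duplication_rate),
        ("low_support_rate", low_support_rate),
    ):
        if not 0.0 <= r <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    trees, rows = [], []
    for i in range(n_genes):
        gid = f"g{i + 1:04d}"
        ids = tip_ids(gid)
        leaves = dict(ids)
        discordant = rng.random() < discordance_rate
        if discordant:
            if rng.random() < 0.5:
                leaves["diploid_paternal"], leaves["polyploid_maternal"] = (
                    leaves["polyploid_maternal"], leaves["diploid_paternal"],
                )
            else:
                leaves["diploid_maternal"], leaves["polyploid_paternal"] = (
                    leaves["polyploid_paternal"], leaves["diploid_maternal"],
                )
        duplicated = rng.random() < duplication_rate
        dup_role = None
        if duplicated:
            dup_role = str(rng.choice(list(leaves)))
            orig = leaves[dup_role]
            leaves[dup_role] = f"({orig},{orig}d)95"
        low = rng.random() < low_support_rate
        s1, s2 = (int(x) for x in rng.integers(80, 101, size=2))
        if low:
            which = rng.random() < 0.5
            if which:
                s1 = int(rng.integers(0, 51))
            else:
                s2 = int(rng.integers(0, 51))
        newick = "((({pp},{dp}){s1},({pm},{dm}){s2}){s3},{o});".format(
            pp=leaves["polyploid_paternal"], dp=leaves["diploid_paternal"],
            pm=leaves["polyploid_maternal"], dm=leaves["diploid_maternal"],
            o=leaves["outgroup"], s1=s1, s2=s2, s3=100,
        )
        trees.append(GeneTree.from_newick(newick))
        rows.append(
            {
                "gene_id": gid,
                "discordant": discordant,
                "duplicated": duplicated,
                "dup_role": dup_role,
                "low_support": low,
            }
        )
    return trees, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# gene content


@dataclasses.dataclass
class ContentSimParams:
    """Subgenome-biased homoeolog loss for a set of gene categories.

    loss_prob maps category -> (paternal, maternal) per-gene probability of
    losing that homoeolog.  Each ancestral gene loses each homoeolog
    independently; the diploid models keep every gene.
    """

    n_genes: int = 1000
    loss_prob: Mapping[str, tuple[float, float]] = dataclasses.field(
        default_factory=lambda: {"NOT": (0.2, 0.2)}
    )
    seed: int = 1

    def __post_init__(self):
        for cat, (lp, lm) in self.loss_prob.items():
            if not (0.0 <= lp <= 1.0 and 0.0 <= lm <= 1.0):
                raise ValueError(f"loss probabilities for {cat!r} must lie in [0, 1]")


def simulate_gene_content(params: ContentSimParams) -> pd.DataFrame:
    """Per-category subgenome gene counts under independent homoeolog loss."""
    rng = np.random.default_rng(params.seed)
    rows = []
    for cat, (lp, lm) in params.loss_prob.items():
        keep_p = rng.random(params.n_genes) >= lp
        keep_m = rng.random(params.n_genes) >= lm
        both = int(np.sum(keep_p & keep_m))
        single = int(np.sum(keep_p ^ keep_m))
        rows.append(
            {
                "category": cat,
                "n_pat": int(keep_p.sum()),
                "n_mat": int(keep_m.sum()),
                "n_both": both,
                "n_dip_pat": params.n_genes,
                "n_dip_mat": params.n_genes,
                "n_retained_duplicate": both,
                "n_single": single,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# classification tables


class ClassificationTables(NamedTuple):
    reference_annotation: pd.DataFrame
    predictor_votes: pd.DataFrame
    orthogroups: pd.DataFrame
    truth: pd.DataFrame


#: recognized tier labels; 'NOT' marks genes targeted to neither organelle
TIERS = (
    "NOT",
    "mito_targeted",
    "plastid_targeted",
    "mito_interacting",
    "plastid_interacting",
    "mtec",
    "ptec",
)

_FINE_CATEGORY = {
    "mito_interacting": "PPR",
    "plastid_interacting": "plastid tRNA base modification",
    "mtec": "OXPHOS complex I",
    "ptec": "chlororibosome",
}


def simulate_classification_tables(
    n_genes: int,
    tier_proportions: Mapping[str, float],
    dual_target_rate: float = 0.0,
    predictor_error_rate: float = 0.0,
    seed: int = 1,
) -> ClassificationTables:
    """Jointly consistent annotation, vote and orthogroup tables.

    Every focal gene shares an orthogroup with one reference-species gene
    whose annotation matches the focal gene's true tier; with zero predictor
    error the classification rule recovers every true tier exactly.
    """
    props = {t: tier_proportions.get(t, 0.0) for t in TIERS}
    total = sum(props.values())
    if not np.isclose(total, 1.0, atol=1e-9):
        raise ValueError("tier proportions must sum to 1")
    rng = np.random.default_rng(seed)
    tiers = rng.choice(list(props), size=n_genes, p=list(props.values()))

    ref_rows, vote_rows, og_rows, truth_rows = [], [], [], []
    for i, tier in enumerate(tiers):
        gene = f"Gene{i + 1:05d}"
        ref = f"Ref{i + 1:05d}"
        og = f"OG{i + 1:05d}"
        dual = tier != "NOT" and rng.random() < dual_target_rate

        mito = tier in ("mito_targeted", "mito_interacting", "mtec")
        plastid = tier in ("plastid_targeted", "plastid_interacting", "ptec")
        if dual:
            mito = plastid = True
        interacting = tier in ("mito_interacting", "plastid_interacting", "mtec", "ptec")
        complex_tier = tier in ("mtec", "ptec")
        ref_rows.append(
            {
                "gene_id": ref,
                "mito_targeted": mito,
                "plastid_targeted": plastid,
                "mito_interacting": interacting and mito,
                "plastid_interacting": interacting and plastid,
                "mtec": complex_tier and mito,
                "ptec": complex_tier and plastid,
                "category": _FINE_CATEGORY.get(tier, "none"),
            }
        )
        mito_votes = plastid_votes = 0
        if mito:
            mito_votes = int(rng.integers(1, 5))
        if plastid:
            plastid_votes = int(rng.integers(1, 5))
        if rng.random() < predictor_error_rate:
            # a predictor failure wipes the de novo votes for this gene
            mito_votes = plastid_votes = 0
        vote_rows.append(
            {"gene_id": gene, "mito_votes": mito_votes, "plastid_votes": plastid_votes}
        )
        og_rows.append({"orthogroup_id": og, "gene_id": gene, "species": "focal"})
        og_rows.append({"orthogroup_id": og, "gene_id": ref, "species": "reference"})
        truth_rows.append(
            {
                "gene_id": gene,
                "tier": tier,
                "dual_targeted": dual,
                "mito_targeted": mito,
                "plastid_targeted": plastid,
                "mito_interacting": interacting and mito,
                "plastid_interacting": interacting and plastid,
                "mtec": complex_tier and mito,
                "ptec": complex_tier and plastid,
            }
        )
    return ClassificationTables(
        pd.DataFrame(ref_rows),
        pd.DataFrame(vote_rows),
        pd.DataFrame(og_rows),
        pd.DataFrame(truth_rows),
    )
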