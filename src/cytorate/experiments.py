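"""Simulation studies validating the rate-test pipeline end to end.

These experiments exercise the whole stack — codon simulation, branch-model
fitting, block bootstrap, background normalization — under known truth:
parameter recovery on single quintets, type-I error of the normalized
omega_PAT/omega_MAT test under an equal-rates null, and power against a
paternally accelerated organelle category.  Problem sizes default to
desk-scale settings (see docs/methods.md); all results are reproducible
from the seed.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .codon_ml import QUINTET_BRANCHES, fit_branch_model
from .quintet_inference import Quintet
from .rate_tests import (
    Concatenation,
    concatenate_quintets,
    gene_bootstrap_omega_ratio,
    normalize_ratio,
)
from .synthetic_data import simulate_quintet_genes

_ROLE_ORDER = (
    "polyploid_paternal",
    "diploid_paternal",
    "polyploid_maternal",
    "diploid_maternal",
    "outgroup",
)


def simulated_concatenation(
    n_genes: int,
    n_codons: int,
    seed: int,
    *,
    omega_by_branch=0.2,
    branch_lengths=0.2,
    kappa: float = 2.0,
    prefix: str = "g",
) -> Concatenation:
    """A category concatenation of freshly simulated quintet genes."""
    genes = simulate_quintet_genes(
        n_genes, n_codons, seed, branch_lengths=branch_lengths,
        kappa=kappa, omega_by_branch=omega_by_branch, prefix=prefix,
    )
    quintets, alignments = [], {}
    for gid, aln, _ in genes:
        members = dict(zip(_ROLE_ORDER, aln.ids))
        quintets.append(Quintet(gene_id=gid, members=members))
        alignments[gid] = aln
    return concatenate_quintets(quintets, alignments)


def _point_ratio(concat: Concatenation, seed: int) -> float:
    fit = fit_branch_model(None, None, engine=concat.engine(), seed=seed)
    num, den = fit.omega_pat, fit.omega_mat
    if not (np.isfinite(num) and np.isfinite(den)) or den <= 0:
        return float("nan")
    return num / den


def _normalized_test(cat_concat, bg_concat, b, seed):
    """Category vs background normalized ratio with paired bootstrap."""
    res = gene_bootstrap_omega_ratio(
        cat_concat, b=b, optimizer_replicates=1, seed=seed,
        category="organelle", method="profile",
    )
    bg = gene_bootstrap_omega_ratio(
        bg_concat, b=b, optimizer_replicates=1, seed=seed + 1,
        category="NOT", method="profile",
    )
    return normalize_ratio(res, bg, paired=True)


@dataclasses.dataclass
class CalibrationResult:
    n_datasets: int
    rejections: int
    p_values: list[float]

    @property
    def rejection_rate(self) -> float:
        return self.rejections / self.n_datasets


def null_calibration_experiment(
    n_datasets: int = 80,
    n_cat_genes: int = 50,
    n_not_genes: int = 50,
    n_codons: int = 40,
    b: int = 100,
    seed: int = 1,
    omega: float = 0.3,
    alpha: float = 0.05,
) -> CalibrationResult:
    """Type-I error of the normalized ratio test under equal subgenome omega.

    Every gene (category and background) evolves with the same omega on all
    branches; the experiment records how often the normalized
    omega_PAT/omega_MAT bootstrap test rejects at the given alpha.  The
    normalization is paired (category replicate / background replicate) so
    the background's own uncertainty is part of the null distribution.
    """
    rng = np.random.default_rng(seed)
    rejections = 0
    p_values = []
    for d in range(n_datasets):
        s = int(rng.integers(1, 2**31 - 1))
        cat = simulated_concatenation(
            n_cat_genes, n_codons, s, omega_by_branch=omega, prefix="c"
        )
        bg = simulated_concatenation(
            n_not_genes, n_codons, s + 1, omega_by_branch=omega, prefix="n"
        )
        norm = _normalized_test(cat, bg, b, seed=s + 2)
        p_values.append(norm.p_two_tailed)
        if norm.p_two_tailed < alpha:
            rejections += 1
    return CalibrationResult(n_datasets, rejections, p_values)


@dataclasses.dataclass
class PowerResult:
    n_datasets: int
    detections: int  # normalized ratio > 1 and p < alpha
    ratios: list[float]
    p_values: list[float]

    @property
    def detection_rate(self) -> float:
        return self.detections / self.n_datasets


def directional_power_experiment(
    n_datasets: int = 25,
    n_cat_genes: int = 50,
    n_not_genes: int = 50,
    n_codons: int = 40,
    b: int = 100,
    seed: int = 1,
    omega_pat: float = 0.6,
    omega_mat: float = 0.2,
    background_omega: float = 0.2,
    alpha: float = 0.05,
) -> PowerResult:
    """Power to detect a paternally accelerated organelle category.

    Category genes evolve with omega_pat on the polyploid paternal branch
    and omega_mat elsewhere; background genes are unbiased.  Detection
    requires normalized ratio > 1 with bootstrap p < alpha.
    """
    cat_omegas = {br: omega_mat for br in QUINTET_BRANCHES}
    cat_omegas["polyploid_paternal"] = omega_pat
    rng = np.random.default_rng(seed)
    detections = 0
    ratios, p_values = [], []
    for d in range(n_datasets):
        s = int(rng.integers(1, 2**31 - 1))
        cat = simulated_concatenation(
            n_cat_genes, n_codons, s, omega_by_branch=cat_omegas, prefix="c"
        )
        bg = simulated_concatenation(
            n_not_genes, n_codons, s + 1, omega_by_branch=background_omega, prefix="n"
        )
        norm = _normalized_test(cat, bg, b, seed=s + 2)
        ratios.append(norm.ratio)
        p_values.append(norm.p_two_tailed)
        if norm.ratio > 1.0 and norm.p_two_tailed < alpha:
            detections += 1
    return PowerResult(n_datasets, detections, ratios, p_values)


def parameter_recovery_experiment(
    n_genes: int = 40,
    n_codons: int = 1000,
    seed: int = 1,
    omega: float = 0.2,
    branch_length: float = 0.2,
    kappa: float = 2.0,
) -> pd.DataFrame:
    """Fit simulated quintets and tabulate fitted vs true parameters."""
    genes = simulate_quintet_genes(
        n_genes, n_codons, seed, branch_lengths=branch_length,
        kappa=kappa, omega_by_branch=omega,
    )
    rows = []
    for gid, aln, truth in genes:
        members = dict(zip(_ROLE_ORDER, aln.ids))
        fit = fit_branch_model(aln, members, seed=seed)
        row = {"gene_id": gid, "kappa": fit.kappa, "lnl": fit.lnl}
        for br in QUINTET_BRANCHES:
            row[f"omega_{br}"] = fit.branches[br].omega
            row[f"t_{br}"] = fit.branches[br].t
        rows.append(row)
    return pd.DataFrame(rows)
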