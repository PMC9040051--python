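"""Paternal-versus-maternal evolutionary rate statistics.

The central quantity is the ratio of the polyploid terminal-branch omega
values, omega_PAT / omega_MAT, estimated from concatenated alignments of a
functional gene category and normalized by the same ratio in genes targeted
to neither organelle (NOT).  Uncertainty comes from resampling whole gene
blocks (or codon columns, for small categories) with replacement and
refitting the branch model; two-tailed p-values are read directly from the
bootstrap distribution.  Gene-level direction is summarized by exact
binomial sign tests on which subgenome has the higher omega (or dN).
"""

from __future__ import annotations

import dataclasses
import logging
import math
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .classification import PARTITIONS
from .codon_ml import (
    QUINTET_BRANCHES,
    BranchRate,
    BranchRates,
    CodonModelSpec,
    QuintetEngine,
    fit_branch_model,
    quintet_states,
)
from .genetics import positions_from_states
from .io_formats import CodonAlignment
from .quintet_inference import Quintet

logger = logging.getLogger("cytorate")


# ---------------------------------------------------------------------------
# concatenation with gene-block bookkeeping


@dataclasses.dataclass
class Concatenation:
    """Role-ordered codon states for a category concatenation.

    states is (5, n_codons) in engine tip order; spans[i] = (start, stop)
    codon offsets of gene_ids[i], recorded for the block bootstrap.
    """

    gene_ids: list[str]
    states: np.ndarray
    spans: list[tuple[int, int]]

    def __post_init__(self):
        self._engine = None
        self._gene_pattern_counts = None

    @property
    def n_codons(self) -> int:
        return self.states.shape[1]

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def boundaries(self) -> list[int]:
        return [stop for _, stop in self.spans[:-1]]

    def engine(self) -> QuintetEngine:
        if self._engine is None:
            self._engine = QuintetEngine(self.states, positions_from_states(self.states))
        return self._engine

    def gene_pattern_counts(self) -> np.ndarray:
        """(n_genes, n_patterns) pattern-count matrix for block resampling."""
        if self._gene_pattern_counts is None:
            eng = self.engine()
            npat = eng.patterns.shape[1]
            counts = np.zeros((self.n_genes, npat))
            for i, (start, stop) in enumerate(self.spans):
                counts[i] = np.bincount(
                    eng.site_to_pattern[start:stop], minlength=npat
                )
            self._gene_pattern_counts = counts
        return self._gene_pattern_counts


def concatenate_quintets(
    quintets: Sequence[Quintet],
    alignments: Mapping[str, CodonAlignment],
) -> Concatenation:
    """Concatenate quintet alignments in stable gene_id order."""
    ordered = sorted(quintets, key=lambda q: q.gene_id)
    blocks, spans, ids = [], [], []
    offset = 0
    for q in ordered:
        if q.gene_id not in alignments:
            raise KeyError(f"no alignment for quintet {q.gene_id!r}")
        aln = alignments[q.gene_id]
        try:
            st = quintet_states(aln, q.members)
        except ValueError as exc:
            raise ValueError(f"gene {q.gene_id!r}: {exc}") from exc
        blocks.append(st)
        spans.append((offset, offset + st.shape[1]))
        offset += st.shape[1]
        ids.append(q.gene_id)
    if not blocks:
        raise ValueError("no quintets to concatenate")
    return Concatenation(ids, np.concatenate(blocks, axis=1), spans)


def concatenate_by_category(
    quintets: Sequence[Quintet],
    alignments: Mapping[str, CodonAlignment],
    classification,
) -> dict[str, Concatenation]:
    """One concatenation per analysis partition with at least one gene."""
    cls = classification.set_index("gene_id")
    out = {}
    for partition, pred in PARTITIONS.items():
        members = [
            q for q in quintets
            if q.gene_id in cls.index and pred(cls.loc[q.gene_id])
        ]
        if members:
            out[partition] = concatenate_quintets(members, alignments)
    return out


# ---------------------------------------------------------------------------
# result containers


@dataclasses.dataclass
class OmegaRatioResult:
    """omega_PAT / omega_MAT for one category, with bootstrap uncertainty."""

    category: str
    omega_pat: float
    omega_mat: float
    ratio: float
    bootstrap_ratios: np.ndarray
    ci95: tuple[float, float]
    p_two_tailed: float
    n_excluded: int = 0
    normalized_by: float | None = None
    point_fit: BranchRates | None = None
    replicate_fits: list[BranchRates] | None = None

    @property
    def significant(self) -> bool:
        return self.p_two_tailed < 0.05


@dataclasses.dataclass
class SignTestResult:
    n_pat_higher: int
    n_mat_higher: int
    n_ties: int
    p_pat: float
    p_mat: float
    p_binomial: float  # nan when no informative genes

    @property
    def defined(self) -> bool:
        return np.isfinite(self.p_binomial)


# ---------------------------------------------------------------------------
# helpers


def _lower_median(values: Sequence[float]) -> float:
    vals = sorted(v for v in values if np.isfinite(v))
    if not vals:
        return float("nan")
    return vals[(len(vals) - 1) // 2]


def median_branch_rates(runs: Sequence[BranchRates]) -> BranchRates:
    """Per-branch lower-medians across replicate optimizer runs."""
    if len(runs) == 1:
        return runs[0]
    branches = {}
    for b in QUINTET_BRANCHES:
        branches[b] = BranchRate(
            t=_lower_median([r.branches[b].t for r in runs]),
            dn=_lower_median([r.branches[b].dn for r in runs]),
            ds=_lower_median([r.branches[b].ds for r in runs]),
            omega=_lower_median([r.branches[b].omega for r in runs]),
        )
    return BranchRates(
        branches=branches,
        kappa=_lower_median([r.kappa for r in runs]),
        lnl=max(r.lnl for r in runs),
    )


def _fit_replicated(
    engine: QuintetEngine,
    n_runs: int,
    seed: int,
    *,
    warm_start: BranchRates | None = None,
    fix_kappa: bool = False,
    max_rounds: int = 4,
    branch_maxiter: int = 60,
) -> BranchRates:
    runs = [
        fit_branch_model(
            None, None, CodonModelSpec(), n_starts=1 if r == 0 else 2,
            seed=seed + r, engine=engine, warm_start=warm_start,
            warm_jitter=0.0 if r == 0 else 0.15,
            fix_kappa=fix_kappa, max_rounds=max_rounds,
            branch_maxiter=branch_maxiter,
        )
        for r in range(n_runs)
    ]
    return median_branch_rates(runs)


def two_tailed_p(distribution: np.ndarray, reference: float) -> float:
    """Two-tailed bootstrap p of a reference value against a distribution.

    p = 2 * min(frac <= reference, frac >= reference), capped at 1 and
    floored at 2/B (the resolution of a B-replicate bootstrap).
    """
    dist = np.asarray(distribution, float)
    dist = dist[np.isfinite(dist)]
    if dist.size == 0:
        raise ValueError("empty bootstrap distribution")
    if dist.size < 20:
        raise ValueError("need at least 20 bootstrap replicates")
    lo = np.mean(dist <= reference)
    hi = np.mean(dist >= reference)
    p = 2.0 * min(lo, hi)
    return float(min(1.0, max(p, 2.0 / dist.size)))


def _ratio(fit: BranchRates) -> float:
    num, den = fit.omega_pat, fit.omega_mat
    if not (np.isfinite(num) and np.isfinite(den)) or den <= 0:
        return float("nan")
    return num / den


def _bootstrap_result(
    category: str,
    point: BranchRates,
    replicate_fits: list[BranchRates],
) -> OmegaRatioResult:
    ratios = np.array([_ratio(f) for f in replicate_fits])
    ok = np.isfinite(ratios)
    n_excluded = int((~ok).sum())
    if n_excluded:
        logger.info("%s: %d bootstrap replicates with undefined omega excluded",
                    category, n_excluded)
    dist = ratios[ok]
    ci = (float(np.percentile(dist, 2.5)), float(np.percentile(dist, 97.5)))
    p = two_tailed_p(dist, 1.0)
    return OmegaRatioResult(
        category=category,
        omega_pat=point.omega_pat,
        omega_mat=point.omega_mat,
        ratio=_ratio(point),
        bootstrap_ratios=dist,
        ci95=ci,
        p_two_tailed=p,
        n_excluded=n_excluded,
        point_fit=point,
        replicate_fits=replicate_fits,
    )


# ---------------------------------------------------------------------------
# bootstrap machinery

#: terminal branches whose omega is re-estimated per bootstrap replicate in
#: the profile method (engine index, branch label)
_PROFILE_BRANCHES = (
    (0, "polyploid_paternal"),
    (1, "diploid_paternal"),
    (2, "polyploid_maternal"),
    (3, "diploid_maternal"),
)


def _profile_bootstrap_fits(
    concat: Concatenation,
    weight_sampler,
    b: int,
    point: BranchRates,
    n_w: int = 33,
    n_t: int = 17,
    w_span: float = 1.6,
    t_span: float = 1.0,
) -> list[BranchRates]:
    """Grid-profiled replicate refits of the terminal-branch omegas.

    Per-pattern site likelihoods do not depend on the bootstrap weights, so
    each terminal branch's conditional log-likelihood (other branches held
    at the point estimate, kappa fixed) is precomputed once on a log-spaced
    (omega, t) grid; every replicate then reduces to weighted sums over the
    grid plus a parabolic refinement of log-omega around the grid maximum.
    This approximates one warm coordinate update per branch, which matches
    full refits closely while being orders of magnitude faster.
    """
    engine = concat.engine()
    model = engine.model(point.kappa)
    t0 = np.array([max(point.branches[br].t, 1e-6) for br in QUINTET_BRANCHES])
    w0 = np.array(
        [np.nan_to_num(point.branches[br].omega, nan=0.4) for br in QUINTET_BRANCHES]
    )
    w0 = np.clip(w0, 1e-4, 50.0)

    grids = []
    for k, br in _PROFILE_BRANCHES:
        site = engine.branch_site_fn(k, model, t0, w0)
        lw = np.log(w0[k]) + np.linspace(-w_span, w_span, n_w)
        lt = np.log(t0[k]) + np.linspace(-t_span, t_span, n_t)
        logs = np.empty((n_w * n_t, engine.patterns.shape[1]))
        for i in range(n_w):
            for j in range(n_t):
                logs[i * n_t + j] = np.log(
                    np.clip(site(math.exp(lt[j]), math.exp(lw[i])), 1e-300, None)
                )
        grids.append((br, lw, lt, logs))

    dw = (2.0 * w_span) / (n_w - 1)
    fits = []
    for rep in range(b):
        wts = weight_sampler(rep)
        branches = dict(point.branches)
        for (k, br), (_, lw, lt, logs) in zip(_PROFILE_BRANCHES, grids):
            scores = (logs @ wts).reshape(n_w, n_t)
            i, j = np.unravel_index(np.argmax(scores), scores.shape)
            lw_hat = lw[i]
            if 0 < i < n_w - 1:
                s_m, s_0, s_p = scores[i - 1, j], scores[i, j], scores[i + 1, j]
                denom = s_m - 2.0 * s_0 + s_p
                if denom < -1e-12:
                    lw_hat += dw * min(0.5, max(-0.5, 0.5 * (s_m - s_p) / denom))
            omega = math.exp(lw_hat)
            tt = math.exp(lt[j])
            dn, ds = model.branch_dn_ds(omega, tt)
            branches[br] = BranchRate(tt, dn, ds, omega)
        fits.append(BranchRates(branches=branches, kappa=point.kappa, lnl=float("nan")))
    return fits


def _bootstrap_engine_fits(
    concat: Concatenation,
    weight_sampler,
    b: int,
    optimizer_replicates: int,
    seed: int,
    point: BranchRates,
) -> list[BranchRates]:
    engine = concat.engine()
    base_weights = engine.weights.copy()
    fits = []
    try:
        for rep in range(b):
            engine.weights = weight_sampler(rep)
            fits.append(
                _fit_replicated(
                    engine, optimizer_replicates, seed=seed + 1000 + rep * 17,
                    warm_start=point, fix_kappa=True, max_rounds=1,
                    branch_maxiter=20,
                )
            )
    finally:
        engine.weights = base_weights
    return fits


def gene_bootstrap_omega_ratio(
    concat: Concatenation,
    b: int = 1000,
    optimizer_replicates: int = 5,
    seed: int = 1,
    category: str = "category",
    method: str = "refit",
) -> OmegaRatioResult:
    """Block bootstrap of omega_PAT/omega_MAT over whole gene blocks.

    Genes are resampled with replacement; each replicate alignment is refit
    starting from the point estimate, either by full warm optimizer runs
    (method='refit': optimizer_replicates runs, per-branch lower-medians)
    or by precomputed conditional-likelihood grids (method='profile', far
    cheaper, used by the large simulation studies).  Replicates with
    undefined omega (synonymous branch length numerically zero) are
    excluded and counted.
    """
    if concat.n_genes < 2:
        raise ValueError("gene-block bootstrap needs at least 2 gene blocks")
    engine = concat.engine()
    point = _fit_replicated(engine, optimizer_replicates, seed=seed)
    counts = concat.gene_pattern_counts()
    rng = np.random.default_rng(seed)
    draws = rng.integers(0, concat.n_genes, size=(b, concat.n_genes))

    def sampler(rep):
        return counts[draws[rep]].sum(axis=0)

    fits = _replicate_fits(concat, sampler, b, optimizer_replicates, seed, point, method)
    return _bootstrap_result(category, point, fits)


def codon_bootstrap(
    concat: Concatenation,
    b: int = 1000,
    optimizer_replicates: int = 5,
    seed: int = 1,
    category: str = "category",
    method: str = "refit",
) -> OmegaRatioResult:
    """Codon-column bootstrap, for categories too small for gene blocks."""
    if concat.n_codons < 30:
        raise ValueError("codon bootstrap needs at least 30 codons")
    engine = concat.engine()
    point = _fit_replicated(engine, optimizer_replicates, seed=seed)
    npat = engine.patterns.shape[1]
    rng = np.random.default_rng(seed)

    def sampler(rep):
        sites = rng.integers(0, concat.n_codons, size=concat.n_codons)
        return np.bincount(
            engine.site_to_pattern[sites], minlength=npat
        ).astype(float)

    fits = _replicate_fits(concat, sampler, b, optimizer_replicates, seed, point, method)
    return _bootstrap_result(category, point, fits)


def _replicate_fits(concat, sampler, b, optimizer_replicates, seed, point, method):
    if method == "refit":
        return _bootstrap_engine_fits(
            concat, sampler, b, optimizer_replicates, seed, point
        )
    if method == "profile":
        return _profile_bootstrap_fits(concat, sampler, b, point)
    raise ValueError("method must be 'refit' or 'profile'")


def normalize_ratio(
    category_result: OmegaRatioResult,
    not_result: "OmegaRatioResult | float",
    paired: bool = False,
) -> OmegaRatioResult:
    """Normalize a category's ratio by the NOT background ratio.

    With paired=False every bootstrap replicate is divided by the NOT point
    estimate (an OmegaRatioResult or a bare ratio) — appropriate when the
    background is large enough that its own uncertainty is negligible.
    With paired=True each category replicate is divided by a NOT bootstrap
    replicate, propagating the background's uncertainty into the normalized
    distribution; this keeps the two-tailed test calibrated when the
    background is itself small.  The point ratio is always normalized by
    the NOT point estimate.
    """
    ref = not_result if isinstance(not_result, float) else not_result.ratio
    if not np.isfinite(ref) or ref <= 0:
        raise ValueError("NOT reference ratio is undefined")
    if paired:
        if isinstance(not_result, float):
            raise ValueError("paired normalization needs the NOT bootstrap result")
        n = min(len(category_result.bootstrap_ratios),
                len(not_result.bootstrap_ratios))
        if n < 20:
            raise ValueError("paired normalization needs >= 20 replicates per side")
        dist = (category_result.bootstrap_ratios[:n]
                / not_result.bootstrap_ratios[:n])
    else:
        dist = category_result.bootstrap_ratios / ref
    ci = (float(np.percentile(dist, 2.5)), float(np.percentile(dist, 97.5)))
    return OmegaRatioResult(
        category=category_result.category,
        omega_pat=category_result.omega_pat,
        omega_mat=category_result.omega_mat,
        ratio=category_result.ratio / ref,
        bootstrap_ratios=dist,
        ci95=ci,
        p_two_tailed=two_tailed_p(dist, 1.0),
        n_excluded=category_result.n_excluded,
        normalized_by=ref,
        point_fit=category_result.point_fit,
        replicate_fits=category_result.replicate_fits,
    )


# ---------------------------------------------------------------------------
# gene-level sign tests


def gene_level_sign_test(
    per_gene_rates: Iterable[BranchRates], comparison: str = "omega"
) -> SignTestResult:
    """Exact binomial test of which subgenome is faster, gene by gene.

    comparison 'omega' compares the polyploid terminal-branch omega values,
    'dN' the nonsynonymous branch lengths.  Ties and genes with undefined
    values are excluded from the binomial count but reported.
    """
    if comparison not in ("omega", "dN"):
        raise ValueError("comparison must be 'omega' or 'dN'")
    n_pat = n_mat = n_tie = 0
    for rates in per_gene_rates:
        bp = rates.branches["polyploid_paternal"]
        bm = rates.branches["polyploid_maternal"]
        a, b_ = (bp.omega, bm.omega) if comparison == "omega" else (bp.dn, bm.dn)
        if not (np.isfinite(a) and np.isfinite(b_)):
            n_tie += 1
        elif a > b_:
            n_pat += 1
        elif b_ > a:
            n_mat += 1
        else:
            n_tie += 1
    total = n_pat + n_mat + n_tie
    n = n_pat + n_mat
    if n == 0:
        return SignTestResult(n_pat, n_mat, n_tie, 0.0, 0.0, float("nan"))
    p_binom = stats.binomtest(n_pat, n, 0.5).pvalue
    return SignTestResult(
        n_pat_higher=n_pat,
        n_mat_higher=n_mat,
        n_ties=n_tie,
        p_pat=n_pat / total,
        p_mat=n_mat / total,
        p_binomial=float(p_binom),
    )


# ---------------------------------------------------------------------------
# divergence binning


def divergence_binning(dn_by_gene: Mapping[str, float]) -> dict[str, str]:
    """Split genes into equally sized low/high diploid-divergence bins.

    Genes at or below the median dN go to 'low'; above to 'high'.  With an
    odd count the median gene lands in 'low'.
    """
    if len(dn_by_gene) < 2:
        raise ValueError("need at least 2 genes to bin")
    values = np.array(list(dn_by_gene.values()), float)
    med = float(np.median(values))
    bins = {g: ("low" if v <= med else "high") for g, v in dn_by_gene.items()}
    if all(b == "low" for b in bins.values()):
        logger.warning("divergence_binning: all dN equal; 'high' bin is empty")
    return bins


# ---------------------------------------------------------------------------
# polyploid vs diploid contrasts


@dataclasses.dataclass
class SubgenomeDiploidRatio:
    subgenome: str
    ratio: float  # polyploid branch omega / sister diploid branch omega
    ci95: tuple[float, float]
    significant: bool  # CI excludes 1.0
    n_excluded: int
    flags: tuple[str, ...] = ()


_PAIRING = {
    "paternal": ("polyploid_paternal", "diploid_paternal"),
    "maternal": ("polyploid_maternal", "diploid_maternal"),
}


def polyploid_vs_diploid_ratio(
    point: BranchRates, replicate_fits: Sequence[BranchRates]
) -> dict[str, SubgenomeDiploidRatio]:
    """Per-subgenome omega ratio of the polyploid branch to its sister diploid.

    The ratio is computed for every bootstrap replicate; significance means
    the 95% percentile interval excludes 1.0.
    """
    out = {}
    for sub, (poly_b, dip_b) in _PAIRING.items():
        def branch_ratio(fit):
            num = fit.branches[poly_b].omega
            den = fit.branches[dip_b].omega
            if not (np.isfinite(num) and np.isfinite(den)) or den <= 0:
                return float("nan")
            return num / den

        ratios = np.array([branch_ratio(f) for f in replicate_fits])
        ok = np.isfinite(ratios)
        point_ratio = branch_ratio(point)
        flags = () if np.isfinite(point_ratio) else ("undefined",)
        if ok.sum() >= 20 and np.isfinite(point_ratio):
            ci = (float(np.percentile(ratios[ok], 2.5)),
                  float(np.percentile(ratios[ok], 97.5)))
            sig = not (ci[0] <= 1.0 <= ci[1])
        else:
            ci, sig = (float("nan"), float("nan")), False
            flags = flags + ("insufficient_replicates",)
        out[sub] = SubgenomeDiploidRatio(
            subgenome=sub, ratio=point_ratio, ci95=ci,
            significant=sig, n_excluded=int((~ok).sum()), flags=flags,
        )
    return out
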