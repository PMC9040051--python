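"""Branch-model codon maximum likelihood on the fixed quintet topology.

The quintet tree is (((poly_pat, dip_pat), (poly_mat, dip_mat)), outgroup).
Every branch carries its own omega (a free-ratio branch model) on the
61-state MG94xHKY chain with F3x4 frequencies.  The likelihood is computed
by Felsenstein pruning over compressed site patterns; because the topology
is fixed and small, per-branch conditional likelihoods reduce to cheap
vector contractions, which the coordinate-wise optimizer exploits.
"""

from __future__ import annotations

import dataclasses
import itertools
import math
from typing import Mapping

import numpy as np
from scipy.optimize import minimize_scalar

from .genetics import (
    CODON_AA,
    MISSING,
    N_CODONS,
    SENSE_CODONS,
    STOP_CODONS,
    CodonModel,
    codon_freqs_from_positions,
)
from .io_formats import QUINTET_ROLES, CodonAlignment, GeneTree, SpeciesMap, resolve_roles

#: branch labels in engine order: five terminal branches then the two
#: internal branches subtending the paternal and maternal cherries
QUINTET_BRANCHES = (
    "polyploid_paternal",
    "diploid_paternal",
    "polyploid_maternal",
    "diploid_maternal",
    "outgroup",
    "ancestral_paternal",
    "ancestral_maternal",
)

_TIPS = QUINTET_BRANCHES[:5]
_T_MIN, _T_MAX = 1e-9, 30.0
_W_MIN, _W_MAX = 1e-4, 50.0
_T_ZERO = 1e-7  # below this a branch is reported as length zero
OMEGA_CAP = 50.0


class OptimizationError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# result containers


@dataclasses.dataclass
class BranchRate:
    t: float
    dn: float
    ds: float
    omega: float  # nan when dS is (numerically) zero
    flags: tuple[str, ...] = ()


@dataclasses.dataclass
class BranchRates:
    """Per-branch rates plus tree-wide totals from one codon ML fit."""

    branches: dict[str, BranchRate]
    kappa: float
    lnl: float

    @property
    def tree_dn(self) -> float:
        return sum(b.dn for b in self.branches.values())

    @property
    def tree_ds(self) -> float:
        return sum(b.ds for b in self.branches.values())

    @property
    def omega_pat(self) -> float:
        return self.branches["polyploid_paternal"].omega

    @property
    def omega_mat(self) -> float:
        return self.branches["polyploid_maternal"].omega

    def omega_vector(self) -> np.ndarray:
        return np.array([self.branches[b].omega for b in QUINTET_BRANCHES])


@dataclasses.dataclass
class CodonModelSpec:
    """Model settings for a branch-model fit.

    omega_assignment maps branch label -> omega parameter index; the default
    (None) is the free-ratio model with one omega per branch.  codon_freqs,
    when given, are F3x4 frequencies; otherwise they are estimated from the
    alignment.
    """

    kappa: float = 2.0
    omega_init: float = 0.4
    omega_assignment: Mapping[str, int] | None = None
    pos_freqs: np.ndarray | None = None

    def __post_init__(self):
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")


@dataclasses.dataclass
class AncestralStates:
    """Maximum-posterior codon states at the three internal nodes.

    states[node, site] is a 61-state codon index; posterior[node, site] its
    marginal posterior probability.  Node order: root, ancestral_paternal,
    ancestral_maternal.
    """

    nodes: tuple[str, ...]
    states: np.ndarray
    posterior: np.ndarray

    def codon(self, node: str, site: int) -> str:
        return SENSE_CODONS[self.states[self.nodes.index(node), site]]

    def amino_acids(self, node: str) -> str:
        row = self.states[self.nodes.index(node)]
        return "".join(CODON_AA[s] for s in row)


#: parent node of each terminal branch, for ancestral-state lookups
TIP_PARENT = {
    "polyploid_paternal": "ancestral_paternal",
    "diploid_paternal": "ancestral_paternal",
    "polyploid_maternal": "ancestral_maternal",
    "diploid_maternal": "ancestral_maternal",
    "outgroup": "root",
}


# ---------------------------------------------------------------------------
# frequencies


def compute_f3x4(alignment: CodonAlignment) -> np.ndarray:
    """F3x4 sense-codon frequencies from position-specific nucleotide counts."""
    return codon_freqs_from_positions(f3x4_positions(alignment))


def f3x4_positions(alignment: CodonAlignment) -> np.ndarray:
    """3x4 observed nucleotide frequencies by codon position."""
    counts = np.zeros((3, 4))
    nt_index = {"A": 0, "C": 1, "G": 2, "T": 3}
    total_codons = 0
    for seq in alignment.seqs:
        for k in range(0, len(seq), 3):
            codon = seq[k : k + 3]
            if any(c not in nt_index for c in codon):
                continue
            total_codons += 1
            for p, c in enumerate(codon):
                counts[p, nt_index[c]] += 1
    if total_codons == 0:
        raise ValueError("alignment has no ungapped codons")
    return counts / counts.sum(axis=1, keepdims=True)


def _floored_positions(pos_freqs: np.ndarray, floor: float = 1e-4) -> np.ndarray:
    """Keep stationary frequencies strictly positive for the likelihood."""
    pos = np.maximum(np.asarray(pos_freqs, float), floor)
    return pos / pos.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# likelihood engine


class QuintetEngine:
    """Pruning likelihood for one quintet alignment on the fixed topology."""

    def __init__(self, states: np.ndarray, pos_freqs: np.ndarray, weights=None):
        states = np.asarray(states)
        if states.ndim != 2 or states.shape[0] != 5:
            raise ValueError("states must be (5, n_codons)")
        patterns, inverse, counts = np.unique(
            states, axis=1, return_inverse=True, return_counts=True
        )
        self.patterns = patterns  # (5, npat)
        self.site_to_pattern = inverse
        self.weights = counts.astype(float) if weights is None else np.asarray(weights, float)
        self.n_sites = states.shape[1]
        self.pos_freqs = _floored_positions(pos_freqs)
        # MISSING -> extra ones-column index 61
        self.obs = [np.where(patterns[k] == MISSING, N_CODONS, patterns[k]) for k in range(5)]
        self._model_cache: dict[float, CodonModel] = {}

    def model(self, kappa: float) -> CodonModel:
        model = self._model_cache.get(kappa)
        if model is None:
            if len(self._model_cache) > 64:
                self._model_cache.clear()
            model = CodonModel(kappa, self.pos_freqs)
            self._model_cache[kappa] = model
        return model

    @staticmethod
    def _tipmat(p: np.ndarray, obs: np.ndarray) -> np.ndarray:
        ext = np.hstack([p, np.ones((N_CODONS, 1))])
        return ext[:, obs]

    def _parts(self, model: CodonModel, t: np.ndarray, w: np.ndarray):
        p = [model.transition_matrix(w[k], t[k]) for k in range(7)]
        tm = [self._tipmat(p[k], self.obs[k]) for k in range(5)]
        a = tm[0] * tm[1]
        b = tm[2] * tm[3]
        x = p[5] @ a
        y = p[6] @ b
        return p, tm, a, b, x, y

    def loglik(self, kappa: float, t: np.ndarray, w: np.ndarray, model=None) -> float:
        model = model or self.model(kappa)
        _, tm, _, _, x, y = self._parts(model, t, w)
        site = model.pi @ (x * y * tm[4])
        return float(self.weights @ np.log(np.clip(site, 1e-300, None)))

    def _site_posteriors(self, model: CodonModel, t, w):
        """Joint per-pattern marginals at root, n_pat, n_mat (61, npat) each."""
        p, tm, a, b, x, y = self._parts(model, t, w)
        pi = model.pi[:, None]
        root = pi * tm[4] * x * y
        up1 = p[5].T @ (pi * tm[4] * y)  # message into n_pat excluding its subtree
        up2 = p[6].T @ (pi * tm[4] * x)
        n_pat = up1 * a
        n_mat = up2 * b
        return root, n_pat, n_mat

    # -- conditional objectives for coordinate-wise optimization ------------

    def branch_site_fn(self, k: int, model: CodonModel, t, w):
        """site(tt, ww) -> per-pattern likelihood for branch k's candidates.

        All other branches are held at the supplied parameters.  The
        returned vectors do not depend on the pattern weights, which is
        what makes grid-profiled bootstrap replicates cheap.
        """
        p, tm, a, b, x, y = self._parts(model, t, w)
        pi = model.pi

        if k in (0, 1):
            g = p[5].T @ (pi[:, None] * tm[4] * y)
            h = g * tm[1 - k]
            obs = self.obs[k]

            def site(tt, ww):
                pm = model.transition_matrix(ww, tt)
                return np.einsum("jp,jp->p", h, self._tipmat(pm, obs))

        elif k in (2, 3):
            g = p[6].T @ (pi[:, None] * tm[4] * x)
            h = g * tm[5 - k]
            obs = self.obs[k]

            def site(tt, ww):
                pm = model.transition_matrix(ww, tt)
                return np.einsum("jp,jp->p", h, self._tipmat(pm, obs))

        elif k == 4:
            r = pi[:, None] * x * y
            obs = self.obs[4]

            def site(tt, ww):
                pm = model.transition_matrix(ww, tt)
                return np.einsum("ip,ip->p", r, self._tipmat(pm, obs))

        elif k == 5:
            u = pi[:, None] * tm[4] * y

            def site(tt, ww):
                pm = model.transition_matrix(ww, tt)
                return np.einsum("ip,ip->p", u, pm @ a)

        else:
            u = pi[:, None] * tm[4] * x

            def site(tt, ww):
                pm = model.transition_matrix(ww, tt)
                return np.einsum("ip,ip->p", u, pm @ b)

        return site

    def _branch_objective(self, k: int, model: CodonModel, t, w):
        site = self.branch_site_fn(k, model, t, w)
        logw = self.weights

        def obj(tt, ww):
            return float(logw @ np.log(np.clip(site(tt, ww), 1e-300, None)))

        return obj

    def _optimize_branch(self, k, model, t, w, maxiter):
        """Alternating 1-D line searches in log t and log omega.

        Splitting the 2-D problem keeps the branch-length phase on a single
        cached eigendecomposition (only omega changes require a new one),
        which dominates the cost of candidate evaluations.
        """
        obj = self._branch_objective(k, model, t, w)
        cycles = max(1, maxiter // 24)
        it_per_phase = max(8, min(maxiter, 24) // 2)
        cur = -obj(t[k], w[k])
        for _ in range(cycles):
            res_t = minimize_scalar(
                lambda lt: -obj(math.exp(lt), w[k]),
                bounds=(math.log(_T_MIN), math.log(_T_MAX)),
                method="bounded",
                options={"xatol": 2e-3, "maxiter": it_per_phase},
            )
            if res_t.fun <= cur:
                t[k] = math.exp(res_t.x)
                cur = res_t.fun
            res_w = minimize_scalar(
                lambda lw: -obj(t[k], math.exp(lw)),
                bounds=(math.log(_W_MIN), math.log(_W_MAX)),
                method="bounded",
                options={"xatol": 2e-3, "maxiter": it_per_phase},
            )
            if res_w.fun <= cur:
                w[k] = math.exp(res_w.x)
                cur = res_w.fun

    def optimize(self, kappa, t, w, *, fix_kappa=False, max_rounds=4,
                 branch_maxiter=60, tol=1e-4):
        """Coordinate-wise maximization; returns (lnl, kappa, t, w)."""
        t = np.asarray(t, float).copy()
        w = np.asarray(w, float).copy()
        model = self.model(kappa)
        prev = self.loglik(kappa, t, w, model)
        if not np.isfinite(prev):
            raise OptimizationError("non-finite initial likelihood")
        for _ in range(max_rounds):
            for k in range(7):
                self._optimize_branch(k, model, t, w, branch_maxiter)
            if not fix_kappa:
                res = minimize_scalar(
                    lambda lk: -self.loglik(math.exp(lk), t, w),
                    bounds=(math.log(0.2), math.log(20.0)),
                    method="bounded",
                    options={"xatol": 5e-3, "maxiter": 25},
                )
                if -res.fun >= prev - 1e-9:
                    kappa = math.exp(res.x)
                    model = self.model(kappa)
            cur = self.loglik(kappa, t, w, model)
            if not np.isfinite(cur):
                raise OptimizationError("non-finite likelihood during optimization")
            if cur - prev < tol:
                prev = max(cur, prev)
                break
            prev = cur
        return prev, kappa, t, w


# ---------------------------------------------------------------------------
# public fitting interface


def _role_map_from_tree(tree, alignment, species_map):
    if isinstance(tree, Mapping):
        return dict(tree)
    if isinstance(tree, GeneTree):
        if species_map is None:
            raise ValueError("species_map required when tree is a GeneTree")
        labels = resolve_roles(tree, species_map)
        return {lbl.quintet_role: tip for tip, lbl in labels.items()}
    if tree is None:
        if species_map is None:
            raise ValueError("provide a role map, or a species_map to resolve ids")
        labels = resolve_roles(alignment, species_map)
        return {lbl.quintet_role: sid for sid, lbl in labels.items()}
    raise TypeError("tree must be a role mapping or a GeneTree")


def quintet_states(alignment: CodonAlignment, role_map: Mapping[str, str]) -> np.ndarray:
    """(5, n_codons) codon-state matrix in engine tip order."""
    missing = set(QUINTET_ROLES) - set(role_map)
    if missing:
        raise ValueError(f"role map lacks quintet roles: {sorted(missing)}")
    sub = alignment.select([role_map[r] for r in _TIPS])
    return sub.codon_states()


def _initial_lengths(states: np.ndarray) -> np.ndarray:
    """Rough starting branch lengths from per-tip codon mismatch fractions."""
    t0 = np.full(7, 0.05)
    ref = states[4]  # outgroup as crude reference
    for k in range(4):
        ok = (states[k] != MISSING) & (ref != MISSING)
        if ok.sum() >= 10:
            t0[k] = max(0.02, 0.75 * float(np.mean(states[k][ok] != ref[ok])))
    ok = (states[4] != MISSING) & (states[0] != MISSING)
    if ok.sum() >= 10:
        t0[4] = max(0.02, 0.75 * float(np.mean(states[4][ok] != states[0][ok])))
    return t0


def fit_branch_model(
    alignment: CodonAlignment,
    tree,
    spec: CodonModelSpec | None = None,
    n_starts: int = 1,
    seed: int = 0,
    *,
    species_map: SpeciesMap | None = None,
    warm_start: BranchRates | None = None,
    warm_jitter: float = 0.0,
    fix_kappa: bool = False,
    max_rounds: int = 4,
    branch_maxiter: int = 60,
    engine: QuintetEngine | None = None,
) -> BranchRates:
    """Free-ratio branch-model ML fit on the fixed quintet topology.

    Multiple optimizer starts (the first at kappa=2, omega=0.4; the rest
    with seeded lognormal jitter) guard against local optima; ties within
    1e-6 log-likelihood are broken in favour of the earliest start.  A
    ``warm_start`` BranchRates skips the jittered starts and refines from
    the given parameters, which is how the bootstrap machinery keeps
    replicate fits cheap.
    """
    spec = spec or CodonModelSpec()
    if spec.omega_assignment is not None:
        indices = [spec.omega_assignment[b] for b in QUINTET_BRANCHES]
        if len(set(indices)) != len(QUINTET_BRANCHES):
            raise NotImplementedError(
                "only the free-ratio assignment (one omega per branch) is supported"
            )
    if engine is None:
        role_map = _role_map_from_tree(tree, alignment, species_map)
        states = quintet_states(alignment, role_map)
        pos = spec.pos_freqs if spec.pos_freqs is not None else f3x4_positions(alignment)
        engine = QuintetEngine(states, pos)
        t_init = _initial_lengths(states)
    else:
        t_init = _initial_lengths(engine.patterns) if warm_start is None else None

    rng = np.random.default_rng(seed)
    best = None
    if warm_start is not None:
        t_w = np.array([warm_start.branches[b].t for b in QUINTET_BRANCHES])
        w_w = np.array(
            [np.nan_to_num(warm_start.branches[b].omega, nan=spec.omega_init)
             for b in QUINTET_BRANCHES]
        )
        if warm_jitter > 0:
            t_w = t_w * rng.lognormal(0.0, warm_jitter, size=7)
            w_w = w_w * rng.lognormal(0.0, warm_jitter, size=7)
        starts = [(warm_start.kappa, t_w, w_w)]
    else:
        starts = []
        for s in range(n_starts):
            if s == 0:
                starts.append((spec.kappa, t_init.copy(), np.full(7, spec.omega_init)))
            else:
                jit_t = t_init * rng.lognormal(0.0, 0.4, size=7)
                jit_w = spec.omega_init * rng.lognormal(0.0, 0.5, size=7)
                starts.append((spec.kappa * rng.lognormal(0.0, 0.3), jit_t, jit_w))

    for kappa0, t0, w0 in starts:
        w0 = np.clip(w0, _W_MIN, _W_MAX)
        t0 = np.clip(t0, _T_MIN, _T_MAX)
        lnl, kappa, t, w = engine.optimize(
            kappa0, t0, w0, fix_kappa=fix_kappa, max_rounds=max_rounds,
            branch_maxiter=branch_maxiter,
        )
        if best is None or lnl > best[0] + 1e-6:
            best = (lnl, kappa, t, w)

    lnl, kappa, t, w = best
    model = engine.model(kappa)
    branches = {}
    for k, label in enumerate(QUINTET_BRANCHES):
        flags = []
        tk, wk = float(t[k]), float(w[k])
        if tk < _T_ZERO:
            branches[label] = BranchRate(0.0, 0.0, 0.0, float("nan"), ("undefined",))
            continue
        if wk >= OMEGA_CAP:
            wk = OMEGA_CAP
            flags.append("at_cap")
        dn, ds = model.branch_dn_ds(wk, tk)
        omega = dn / ds if ds > 1e-8 else float("nan")
        if not np.isfinite(omega):
            flags.append("undefined")
        branches[label] = BranchRate(tk, dn, ds, omega, tuple(flags))
    return BranchRates(branches=branches, kappa=float(kappa), lnl=float(lnl))


# ---------------------------------------------------------------------------
# ancestral reconstruction


def reconstruct_ancestral(
    alignment: CodonAlignment,
    tree,
    fitted: BranchRates,
    *,
    species_map: SpeciesMap | None = None,
) -> AncestralStates:
    """Marginal (empirical Bayes) codon reconstruction at internal nodes.

    Posteriors are computed under the fitted model; at each node and site
    the maximum-posterior codon is reported, ties broken toward the
    lexicographically smallest codon.
    """
    role_map = _role_map_from_tree(tree, alignment, species_map)
    states = quintet_states(alignment, role_map)
    engine = QuintetEngine(states, f3x4_positions(alignment))
    model = engine.model(fitted.kappa)
    t = np.array([max(fitted.branches[b].t, _T_MIN) for b in QUINTET_BRANCHES])
    w = np.array([np.nan_to_num(fitted.branches[b].omega, nan=1.0) for b in QUINTET_BRANCHES])
    w = np.clip(w, _W_MIN, _W_MAX)
    mats = engine._site_posteriors(model, t, w)
    nodes = ("root", "ancestral_paternal", "ancestral_maternal")
    n_sites = engine.n_sites
    st = np.empty((3, n_sites), dtype=np.int64)
    post = np.empty((3, n_sites))
    for i, m in enumerate(mats):
        m = m / np.clip(m.sum(axis=0, keepdims=True), 1e-300, None)
        # argmax returns the first (lexicographically smallest) codon on ties
        pat_state = np.argmax(m, axis=0)
        pat_post = m[pat_state, np.arange(m.shape[1])]
        st[i] = pat_state[engine.site_to_pattern]
        post[i] = pat_post[engine.site_to_pattern]
    return AncestralStates(nodes=nodes, states=st, posterior=post)


# ---------------------------------------------------------------------------
# NG86-style counting oracle


@dataclasses.dataclass
class PairwiseRates:
    dn: float
    ds: float
    n_sites: float
    s_sites: float
    flags: tuple[str, ...] = ()


def _codon_path_counts(c1: str, c2: str) -> tuple[float, float]:
    """Average syn/nonsyn difference counts over all mutational paths."""
    diffs = [p for p in range(3) if c1[p] != c2[p]]
    paths = []
    for order in itertools.permutations(diffs):
        cur = c1
        syn = non = 0
        ok = True
        for p in order:
            nxt = cur[:p] + c2[p] + cur[p + 1 :]
            if nxt in STOP_CODONS:
                ok = False
                break
            from .genetics import STANDARD_CODE
            if STANDARD_CODE[cur] == STANDARD_CODE[nxt]:
                syn += 1
            else:
                non += 1
            cur = nxt
        if ok:
            paths.append((syn, non))
    if not paths:  # all paths pass through stops; fall back to ignoring them
        return 0.0, float(len(diffs))
    syn = sum(p[0] for p in paths) / len(paths)
    non = sum(p[1] for p in paths) / len(paths)
    return syn, non


def _codon_sites(codon: str) -> tuple[float, float]:
    """Fractional (syn, nonsyn) site counts of one sense codon."""
    from .genetics import STANDARD_CODE

    syn = 0.0
    for p in range(3):
        for nt in "ACGT":
            if nt == codon[p]:
                continue
            alt = codon[:p] + nt + codon[p + 1 :]
            if alt in STOP_CODONS:
                continue
            if STANDARD_CODE[alt] == STANDARD_CODE[codon]:
                syn += 1.0 / 3.0
    return syn, 3.0 - syn


def count_pairwise_dnds(seq_a: str, seq_b: str) -> PairwiseRates:
    """NG86-style pairwise dN/dS with Jukes-Cantor correction.

    Codons containing gaps or ambiguity in either sequence are skipped.
    When the JC correction saturates (p >= 3/4) the corresponding rate is
    reported as inf with a 'saturated' flag.
    """
    if len(seq_a) != len(seq_b) or len(seq_a) % 3 != 0:
        raise ValueError("sequences must be equal-length and in frame")
    seq_a, seq_b = seq_a.upper(), seq_b.upper()
    s_sites = n_sites = s_diff = n_diff = 0.0
    for k in range(0, len(seq_a), 3):
        c1, c2 = seq_a[k : k + 3], seq_b[k : k + 3]
        from .genetics import STANDARD_CODE
        if c1 not in STANDARD_CODE or c2 not in STANDARD_CODE:
            continue
        if c1 in STOP_CODONS or c2 in STOP_CODONS:
            continue
        s1, n1 = _codon_sites(c1)
        s2, n2 = _codon_sites(c2)
        s_sites += (s1 + s2) / 2.0
        n_sites += (n1 + n2) / 2.0
        if c1 != c2:
            sd, nd = _codon_path_counts(c1, c2)
            s_diff += sd
            n_diff += nd
    if s_sites == 0 or n_sites == 0:
        raise ValueError("no comparable codons")
    flags = []

    def jc(p):
        if p >= 0.75:
            flags.append("saturated")
            return float("inf")
        return -0.75 * math.log(1.0 - 4.0 * p / 3.0)

    ds = jc(s_diff / s_sites)
    dn = jc(n_diff / n_sites)
    return PairwiseRates(dn=dn, ds=ds, n_sites=n_sites, s_sites=s_sites, flags=tuple(flags))
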