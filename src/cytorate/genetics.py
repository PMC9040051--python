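"""Codon-level substitution machinery shared by the simulator and the ML engine.

The substitution process is MG94-style: a 61-state continuous-time Markov
chain over sense codons in which only single-nucleotide changes have nonzero
rate.  A change is weighted by ``kappa`` when it is a transition, by a
branch-specific ``omega`` when it is nonsynonymous, and by the stationary
frequency of the target nucleotide at the changed codon position.  With
product-form codon frequencies (the F3x4 construction) the chain is
time-reversible, which we exploit for fast matrix exponentials via a
symmetric eigendecomposition.
"""

from __future__ import annotations

import numpy as np

NUCLEOTIDES = "ACGT"
NT_INDEX = {n: i for i, n in enumerate(NUCLEOTIDES)}

STANDARD_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

STOP_CODONS = frozenset(c for c, a in STANDARD_CODE.items() if a == "*")

#: the 61 sense codons in lexicographic (ACGT) order; this ordering is the
#: state-space convention used throughout the package
SENSE_CODONS = tuple(sorted(c for c in STANDARD_CODE if c not in STOP_CODONS))
CODON_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}
N_CODONS = len(SENSE_CODONS)  # 61

CODON_AA = "".join(STANDARD_CODE[c] for c in SENSE_CODONS)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: sentinel state for a codon containing a gap, N, or other ambiguity
MISSING = -1


def translate_codon(codon: str) -> str:
    """Translate one codon; returns 'X' for codons with gaps or ambiguity."""
    aa = STANDARD_CODE.get(codon.upper())
    return aa if aa is not None else "X"


def codon_state(codon: str) -> int:
    """Map a codon string to its 61-state index, or MISSING if not a sense codon."""
    return CODON_INDEX.get(codon.upper(), MISSING)


def _is_transition(a: str, b: str) -> bool:
    return {a, b} in ({"A", "G"}, {"C", "T"})


def _build_pair_tables():
    """Enumerate ordered sense-codon pairs differing at exactly one position."""
    src, dst, pos, tgt, ts, syn = [], [], [], [], [], []
    for i, ci in enumerate(SENSE_CODONS):
        for j, cj in enumerate(SENSE_CODONS):
            if i == j:
                continue
            diffs = [p for p in range(3) if ci[p] != cj[p]]
            if len(diffs) != 1:
                continue
            p = diffs[0]
            src.append(i)
            dst.append(j)
            pos.append(p)
            tgt.append(NT_INDEX[cj[p]])
            ts.append(_is_transition(ci[p], cj[p]))
            syn.append(CODON_AA[i] == CODON_AA[j])
    return (
        np.array(src), np.array(dst), np.array(pos),
        np.array(tgt), np.array(ts, bool), np.array(syn, bool),
    )


PAIR_SRC, PAIR_DST, PAIR_POS, PAIR_TGT, PAIR_TS, PAIR_SYN = _build_pair_tables()


def codon_freqs_from_positions(pos_freqs: np.ndarray) -> np.ndarray:
    """Product-form (F3x4) sense-codon frequencies from 3x4 position nt freqs."""
    pos_freqs = np.asarray(pos_freqs, float)
    if pos_freqs.shape != (3, 4):
        raise ValueError("pos_freqs must be 3x4 (position x ACGT)")
    pi = np.empty(N_CODONS)
    for i, codon in enumerate(SENSE_CODONS):
        pi[i] = np.prod([pos_freqs[p, NT_INDEX[codon[p]]] for p in range(3)])
    return pi / pi.sum()


def positions_from_codon_freqs(codon_freqs: np.ndarray) -> np.ndarray:
    """Marginal per-position nucleotide frequencies of a codon distribution."""
    codon_freqs = np.asarray(codon_freqs, float)
    pos = np.zeros((3, 4))
    for i, codon in enumerate(SENSE_CODONS):
        for p in range(3):
            pos[p, NT_INDEX[codon[p]]] += codon_freqs[i]
    return pos / pos.sum(axis=1, keepdims=True)


UNIFORM_POSITIONS = np.full((3, 4), 0.25)

#: nucleotide index at each position of each sense codon, shape (61, 3)
STATE_NT = np.array(
    [[NT_INDEX[c[p]] for p in range(3)] for c in SENSE_CODONS]
)


def positions_from_states(states: np.ndarray) -> np.ndarray:
    """3x4 position-specific nt frequencies from a codon-state matrix."""
    flat = states[states != MISSING]
    if flat.size == 0:
        raise ValueError("no ungapped codons")
    pos = np.zeros((3, 4))
    for p in range(3):
        pos[p] = np.bincount(STATE_NT[flat, p], minlength=4)
    return pos / pos.sum(axis=1, keepdims=True)


class CodonModel:
    """MG94xHKY codon model for a fixed kappa and position frequencies.

    Branch-specific quantities (rate matrix, transition matrices, dN/dS
    decompositions) are produced on demand for a given omega.  Rate matrices
    are scaled so that branch length is the expected number of codon
    substitutions per codon site.
    """

    def __init__(self, kappa: float, pos_freqs: np.ndarray = UNIFORM_POSITIONS):
        if kappa <= 0:
            raise ValueError("kappa must be positive")
        self.kappa = float(kappa)
        self.pos_freqs = np.asarray(pos_freqs, float)
        self.pi = codon_freqs_from_positions(self.pos_freqs)

        # symmetric unscaled flow matrices: flow[i, j] = pi_i * q_ij
        w = np.where(PAIR_TS, self.kappa, 1.0) * self.pos_freqs[PAIR_POS, PAIR_TGT]
        flow = self.pi[PAIR_SRC] * w
        fs = np.zeros((N_CODONS, N_CODONS))
        fn = np.zeros((N_CODONS, N_CODONS))
        fs[PAIR_SRC[PAIR_SYN], PAIR_DST[PAIR_SYN]] = flow[PAIR_SYN]
        fn[PAIR_SRC[~PAIR_SYN], PAIR_DST[~PAIR_SYN]] = flow[~PAIR_SYN]
        self._flow_syn = fs
        self._flow_nonsyn = fn
        self._total_syn = fs.sum()
        self._total_nonsyn = fn.sum()
        # mutational-opportunity site fractions (omega = 1 flows)
        tot = self._total_syn + self._total_nonsyn
        self.f_syn = self._total_syn / tot
        self.f_nonsyn = self._total_nonsyn / tot
        self._sqrt_pi = np.sqrt(self.pi)
        self._eig_cache: dict[float, tuple[np.ndarray, np.ndarray]] = {}

    def flow_proportions(self, omega: float) -> tuple[float, float]:
        """(rho_syn, rho_nonsyn): proportions of substitution flow by class."""
        tot = self._total_syn + omega * self._total_nonsyn
        return self._total_syn / tot, omega * self._total_nonsyn / tot

    def rate_matrix(self, omega: float) -> np.ndarray:
        """Scaled generator Q for a branch with the given omega."""
        if omega < 0:
            raise ValueError("omega must be non-negative")
        flow = self._flow_syn + omega * self._flow_nonsyn
        flow = flow / flow.sum()
        q = flow / self.pi[:, None]
        np.fill_diagonal(q, -q.sum(axis=1))
        return q

    @staticmethod
    def _quantize(omega: float) -> float:
        """Round omega to 4 significant digits for eigendecomposition reuse."""
        if omega <= 0:
            return 0.0
        return float(f"{omega:.4g}")

    def _eig(self, omega: float):
        omega = self._quantize(omega)
        cached = self._eig_cache.get(omega)
        if cached is not None:
            return cached
        flow = self._flow_syn + omega * self._flow_nonsyn
        flow = flow / flow.sum()
        sym = flow / np.outer(self._sqrt_pi, self._sqrt_pi)
        diag = -(flow.sum(axis=1) / self.pi)
        sym[np.diag_indices_from(sym)] = diag
        lam, u = np.linalg.eigh(sym)
        if len(self._eig_cache) > 4096:
            self._eig_cache.clear()
        self._eig_cache[omega] = (lam, u)
        return lam, u

    def transition_matrix(self, omega: float, t: float) -> np.ndarray:
        """P(t) = expm(Q t) via the symmetric eigendecomposition."""
        if t < 0:
            raise ValueError("branch length must be non-negative")
        lam, u = self._eig(omega)
        inner = (u * np.exp(lam * t)) @ u.T
        p = (inner / self._sqrt_pi[:, None]) * self._sqrt_pi[None, :]
        np.clip(p, 0.0, None, out=p)
        p /= p.sum(axis=1, keepdims=True)
        return p

    def branch_dn_ds(self, omega: float, t: float) -> tuple[float, float]:
        """Per-branch (dN, dS) in the codeml convention.

        dN = t * rho_N / (3 f_N) and dS = t * rho_S / (3 f_S), where rho are
        the proportions of substitution flow through each class under the
        branch omega, and f the mutational-opportunity site fractions
        (omega = 1 flows).  The ratio dN/dS equals omega exactly.
        """
        rho_s, rho_n = self.flow_proportions(omega)
        dn = t * rho_n / (3.0 * self.f_nonsyn)
        ds = t * rho_s / (3.0 * self.f_syn)
        return dn, ds
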