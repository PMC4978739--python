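"""Codon-level machinery: genetic code tables, NG86 site/difference counting,
and the GY94-style 61-state codon model with F3x4 equilibrium frequencies.

Shared by the Ks estimators (:mod:`nlr_evolkit.ks_dating`) and the sequence
evolver (:mod:`nlr_evolkit.synthetic_data`).
"""

from __future__ import annotations

from functools import lru_cache
from itertools import product

import numpy as np

NUCS = "TCAG"

#: Standard genetic code, codon -> amino acid ('*' = stop).
CODON_TABLE: dict[str, str] = {}
_AA_ORDER = (
    "FFLLSSSSYY**CC*W"
    "LLLLPPPPHHQQRRRR"
    "IIIMTTTTNNKKSSRR"
    "VVVVAAAADDEEGGGG"
)
for _i, (_n1, _n2, _n3) in enumerate(product(NUCS, NUCS, NUCS)):
    CODON_TABLE[_n1 + _n2 + _n3] = _AA_ORDER[_i]

SENSE_CODONS: tuple[str, ...] = tuple(c for c in CODON_TABLE if CODON_TABLE[c] != "*")
CODON_INDEX: dict[str, int] = {c: i for i, c in enumerate(SENSE_CODONS)}
N_SENSE = len(SENSE_CODONS)  # 61

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


def is_transition(a: str, b: str) -> bool:
    return (a, b) in _TRANSITIONS


def translate_codon(codon: str) -> str:
    return CODON_TABLE.get(codon, "X")


@lru_cache(maxsize=None)
def single_step_neighbors(codon: str) -> tuple[tuple[int, str, bool, bool], ...]:
    """All sense codons one nucleotide change away.

    Returns tuples ``(position, new_codon, is_transition, is_synonymous)``.
    """
    out = []
    aa = CODON_TABLE[codon]
    for pos in range(3):
        for nt in NUCS:
            if nt == codon[pos]:
                continue
            new = codon[:pos] + nt + codon[pos + 1:]
            if CODON_TABLE[new] == "*":
                continue
            out.append((pos, new, is_transition(codon[pos], nt), CODON_TABLE[new] == aa))
    return tuple(out)


# ---------------------------------------------------------------------------
# NG86 site and difference counting
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def ng86_sites(codon: str) -> tuple[float, float]:
    """Synonymous and nonsynonymous site counts for one codon.

    Each of the three positions contributes the fraction of its possible
    single-nucleotide changes (to sense codons) that are synonymous; changes
    to stop codons are excluded from the denominator.
    """
    aa = CODON_TABLE[codon]
    s = 0.0
    for pos in range(3):
        syn = 0
        valid = 0
        for nt in NUCS:
            if nt == codon[pos]:
                continue
            new = codon[:pos] + nt + codon[pos + 1:]
            if CODON_TABLE[new] == "*":
                continue
            valid += 1
            if CODON_TABLE[new] == aa:
                syn += 1
        if valid:
            s += syn / valid
    return s, 3.0 - s


@lru_cache(maxsize=None)
def ng86_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Synonymous and nonsynonymous difference counts between two codons,
    averaged over all shortest mutational pathways through sense codons.

    Pathways passing through a stop codon are excluded; if every pathway is
    blocked, blocked steps are counted from the direct position-by-position
    comparison (vanishingly rare for real pairs).
    """
    diff_pos = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_pos:
        return 0.0, 0.0

    from itertools import permutations

    path_counts: list[tuple[float, float]] = []
    for order in permutations(diff_pos):
        cur = codon_a
        sd = nd = 0.0
        ok = True
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1:]
            if CODON_TABLE[nxt] == "*":
                ok = False
                break
            if CODON_TABLE[nxt] == CODON_TABLE[cur]:
                sd += 1.0
            else:
                nd += 1.0
            cur = nxt
        if ok:
            path_counts.append((sd, nd))
    if not path_counts:
        # all pathways stop-blocked: count each differing position directly
        sd = nd = 0.0
        for pos in diff_pos:
            nxt = codon_a[:pos] + codon_b[pos] + codon_a[pos + 1:]
            if CODON_TABLE.get(nxt) == CODON_TABLE[codon_a]:
                sd += 1.0
            else:
                nd += 1.0
        return sd, nd
    arr = np.array(path_counts)
    return float(arr[:, 0].mean()), float(arr[:, 1].mean())


# ---------------------------------------------------------------------------
# F3x4 frequencies and the GY94 rate matrix
# ---------------------------------------------------------------------------

def f3x4_frequencies(codon_seqs: list[str]) -> np.ndarray:
    """Equilibrium codon frequencies from observed nucleotide frequencies at
    each codon position (the F3x4 parameterization), renormalized over the
    61 sense codons.

    A small pseudocount keeps unseen nucleotides at nonzero frequency so the
    rate matrix stays irreducible.
    """
    counts = np.full((3, 4), 0.1)
    nuc_idx = {n: i for i, n in enumerate(NUCS)}
    for seq in codon_seqs:
        for i in range(0, len(seq) - len(seq) % 3, 3):
            codon = seq[i:i + 3]
            for pos, nt in enumerate(codon):
                j = nuc_idx.get(nt)
                if j is not None:
                    counts[pos, j] += 1.0
    pos_freq = counts / counts.sum(axis=1, keepdims=True)
    pi = np.empty(N_SENSE)
    for k, codon in enumerate(SENSE_CODONS):
        pi[k] = (
            pos_freq[0, nuc_idx[codon[0]]]
            * pos_freq[1, nuc_idx[codon[1]]]
            * pos_freq[2, nuc_idx[codon[2]]]
        )
    return pi / pi.sum()


def gy94_rate_matrix(kappa: float, omega: float, pi: np.ndarray) -> tuple[np.ndarray, float]:
    """GY94-style instantaneous rate matrix over the 61 sense codons.

    Off-diagonal rates are nonzero only between codons one nucleotide apart:
    ``q_ij = pi_j * kappa^[transition] * omega^[nonsynonymous]``.  The matrix
    is scaled so the expected number of substitutions per codon per unit time
    is 1.

    Returns ``(Q, rho_s)`` where ``rho_s`` is the proportion of that unit
    substitution flux that is synonymous.
    """
    Q = np.zeros((N_SENSE, N_SENSE))
    syn_mask = np.zeros((N_SENSE, N_SENSE), dtype=bool)
    for i, codon in enumerate(SENSE_CODONS):
        for _pos, new, ts, syn in single_step_neighbors(codon):
            j = CODON_INDEX[new]
            rate = pi[j]
            if ts:
                rate *= kappa
            if not syn:
                rate *= omega
            Q[i, j] = rate
            syn_mask[i, j] = syn
    np.fill_diagonal(Q, -Q.sum(axis=1))
    flux = pi[:, None] * Q
    total = -np.sum(pi * np.diag(Q))
    Q /= total
    rho_s = float(np.sum(flux[syn_mask]) / total)
    return Q, rho_s


def synonymous_site_fraction(kappa: float, pi: np.ndarray) -> float:
    """Fraction of mutational opportunity that is synonymous: the synonymous
    flux proportion of the same model with ``omega = 1`` (the standard codon-
    model definition of synonymous sites)."""
    _, rho_s1 = gy94_rate_matrix(kappa, 1.0, pi)
    return rho_s1


class CodonModel:
    """A fitted-parameter view of the GY94/F3x4 model supporting transition
    probabilities via the symmetrized eigendecomposition (the model is time
    reversible)."""

    def __init__(self, kappa: float, omega: float, pi: np.ndarray):
        self.kappa = kappa
        self.omega = omega
        self.pi = pi
        self.Q, self.rho_s = gy94_rate_matrix(kappa, omega, pi)
        sqrt_pi = np.sqrt(pi)
        B = (sqrt_pi[:, None] * self.Q) / sqrt_pi[None, :]
        B = (B + B.T) / 2.0  # symmetrize against rounding noise
        self._eigvals, self._eigvecs = np.linalg.eigh(B)
        self._left = self._eigvecs / sqrt_pi[:, None]
        self._right = self._eigvecs * sqrt_pi[:, None]

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = exp(Qt), clipped to nonnegative."""
        P = (self._left * np.exp(self._eigvals * t)) @ self._right.T
        np.clip(P, 1e-300, None, out=P)
        return P

    def ks_ka_decomposition(self, t: float) -> tuple[float, float]:
        """(Ks, Ka) for branch length ``t`` (expected substitutions/codon):
        Ks = t * rho_s / (3 * f_s) with f_s the synonymous site fraction at
        omega = 1, and symmetrically for Ka."""
        f_s = synonymous_site_fraction(self.kappa, self.pi)
        ks = t * self.rho_s / (3.0 * f_s)
        ka = t * (1.0 - self.rho_s) / (3.0 * (1.0 - f_s))
        return ks, ka


def codons_of(seq: str) -> list[str]:
    """Split an in-frame nucleotide sequence into codons (truncating any
    trailing partial codon)."""
    return [seq[i:i + 3] for i in range(0, len(seq) - len(seq) % 3, 3)]
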