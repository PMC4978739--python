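"""Duplication dating by synonymous substitution rates (Ks).

Pipeline: protein-guided codon alignment of a paralog pair -> Ks under
either Nei--Gojobori counting (NG86, the engineering oracle) or maximum
likelihood under a GY94-style codon model with F3x4 equilibrium frequencies
(the primary estimator) -> single-linkage grouping of pairs into gene
families -> UPGMA dendrogram per family whose n-1 join heights are the
deduplicated duplication-age sample -> chi-square test for post-speciation
duplication excess per subgroup.

Pairs with Ks > 2 are treated as saturated and discarded from dating.  The
Ks->time conversion is calibrated so Ks = 0.3 corresponds to 19.1 Mya (the
pepper vs tomato/potato speciation).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from ._codon import (
    CodonModel,
    f3x4_frequencies,
    ng86_differences,
    ng86_sites,
    translate_codon,
)
from .core_io import CdsRecord, ProteinRecord, RunConfig
from .classify import local_align

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CodonAlignment:
    """Gapless, N-free, stop-free paired codon columns for one paralog pair."""

    id_a: str
    id_b: str
    codons_a: tuple[str, ...]
    codons_b: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.codons_a) != len(self.codons_b):
            raise ValueError("unequal codon column counts")

    @property
    def n_codons(self) -> int:
        return len(self.codons_a)


@dataclass(frozen=True)
class KsEstimate:
    id_a: str
    id_b: str
    ks: float
    ka: float
    method: str                      # "NG86" or "ML-F3x4"
    kappa: float | None = None
    omega: float | None = None
    t: float | None = None
    saturated: bool = False
    flags: tuple[str, ...] = ()


class CodonAlignmentError(ValueError):
    pass


def codon_align_from_protein(prot_a: ProteinRecord, prot_b: ProteinRecord,
                             cds_a: CdsRecord, cds_b: CdsRecord) -> CodonAlignment:
    """Protein-guided codon alignment of a paralog pair.

    The proteins are aligned locally (Smith--Waterman); each aligned residue
    pair maps to its codon pair in the CDS.  Gap columns, any column whose
    codon contains N, and stop codons are dropped.
    """
    for prot, cds in ((prot_a, cds_a), (prot_b, cds_b)):
        n_codons = len(cds.sequence) // 3
        trans = cds.translate()
        if len(trans) != len(prot.sequence) and n_codons != len(prot.sequence):
            raise CodonAlignmentError(
                f"CDS of {prot.id!r} ({n_codons} codons) does not match its "
                f"protein ({len(prot.sequence)} aa)"
            )
    aln = local_align(prot_a, prot_b)
    if not aln.aligned_a:
        return CodonAlignment(prot_a.id, prot_b.id, (), ())
    ca, cb = [], []
    ia, ib = aln.start_a, aln.start_b
    for ra, rb in zip(aln.aligned_a, aln.aligned_b):
        if ra != "-" and rb != "-":
            codon_a = cds_a.sequence[3 * ia: 3 * ia + 3]
            codon_b = cds_b.sequence[3 * ib: 3 * ib + 3]
            if ("N" not in codon_a and "N" not in codon_b
                    and translate_codon(codon_a) != "*"
                    and translate_codon(codon_b) != "*"):
                ca.append(codon_a)
                cb.append(codon_b)
        if ra != "-":
            ia += 1
        if rb != "-":
            ib += 1
    return CodonAlignment(prot_a.id, prot_b.id, tuple(ca), tuple(cb))


# ---------------------------------------------------------------------------
# NG86
# ---------------------------------------------------------------------------

def ks_ng86(aln: CodonAlignment, ks_max: float = 2.0) -> KsEstimate:
    """Nei--Gojobori (1986) Ks/Ka with Jukes--Cantor correction.

    Synonymous site counts are averaged over the two sequences; multi-hit
    codons average the difference counts over all sense-codon pathways.
    ``pS > 3/4`` (outside the JC domain) marks the pair saturated.
    """
    if aln.n_codons < 1:
        raise ValueError("empty codon alignment")
    S = N = Sd = Nd = 0.0
    for codon_a, codon_b in zip(aln.codons_a, aln.codons_b):
        sa, na = ng86_sites(codon_a)
        sb, nb = ng86_sites(codon_b)
        S += (sa + sb) / 2.0
        N += (na + nb) / 2.0
        sd, nd = ng86_differences(codon_a, codon_b)
        Sd += sd
        Nd += nd
    flags: list[str] = []
    if S <= 0:
        return KsEstimate(aln.id_a, aln.id_b, math.nan, math.nan, "NG86",
                          saturated=False, flags=("no-synonymous-sites",))
    pS, pN = Sd / S, Nd / max(N, 1e-12)

    def jc(p: float) -> float:
        if p >= 0.75:
            return math.inf
        return -0.75 * math.log(1.0 - (4.0 / 3.0) * p)

    ks, ka = jc(pS), jc(pN)
    saturated = not math.isfinite(ks) or ks > ks_max
    return KsEstimate(aln.id_a, aln.id_b, ks, ka, "NG86",
                      saturated=saturated, flags=tuple(flags))


# ---------------------------------------------------------------------------
# ML under GY94 / F3x4
# ---------------------------------------------------------------------------

MIN_CODONS_FOR_ML = 20


def _pair_counts(aln: CodonAlignment) -> np.ndarray:
    from ._codon import CODON_INDEX, N_SENSE

    C = np.zeros((N_SENSE, N_SENSE))
    for a, b in zip(aln.codons_a, aln.codons_b):
        ia, ib = CODON_INDEX.get(a), CODON_INDEX.get(b)
        if ia is not None and ib is not None:
            C[ia, ib] += 1.0
    return C


def ks_ml_f3x4(aln: CodonAlignment, ks_max: float = 2.0) -> KsEstimate:
    """Pairwise maximum-likelihood Ks under the GY94-style codon model with
    F3x4 equilibrium frequencies.

    The likelihood of the observed codon-pair columns is maximized over
    (t, kappa, omega) by bounded quasi-Newton optimization in log space;
    Ks/Ka follow the standard codon-model bookkeeping (synonymous share of
    the substitution flux over the synonymous share of sites).  Alignments
    under 20 codons fall back to NG86 with a flag, as does optimizer failure.
    """
    if aln.n_codons < MIN_CODONS_FOR_ML:
        est = ks_ng86(aln, ks_max)
        return KsEstimate(est.id_a, est.id_b, est.ks, est.ka, "NG86",
                          saturated=est.saturated,
                          flags=est.flags + ("too-short-for-ML",))
    pi = f3x4_frequencies([''.join(aln.codons_a), ''.join(aln.codons_b)])
    C = _pair_counts(aln)
    if C.sum() == 0:
        raise ValueError("no unambiguous sense-codon columns")
    if np.array_equal(aln.codons_a, aln.codons_b):
        return KsEstimate(aln.id_a, aln.id_b, 0.0, 0.0, "ML-F3x4",
                          kappa=None, omega=None, t=0.0)

    rows, cols = np.nonzero(C)
    weights = C[rows, cols]

    def neg_loglik(x: np.ndarray) -> float:
        t, kappa, omega = np.exp(x)
        model = CodonModel(kappa, omega, pi)
        P = model.transition_matrix(t)
        ll = np.sum(weights * (np.log(pi[rows]) + np.log(P[rows, cols])))
        return -ll

    ng = ks_ng86(aln, ks_max=np.inf)
    t0 = max(min((ng.ks if math.isfinite(ng.ks) else 1.0) + ng.ka, 5.0), 0.01)
    best = None
    for x0 in ([np.log(t0), np.log(2.0), np.log(0.3)],
               [np.log(0.5), np.log(1.0), np.log(1.0)]):
        res = optimize.minimize(
            neg_loglik, np.array(x0), method="L-BFGS-B",
            bounds=[(np.log(1e-5), np.log(50.0)),
                    (np.log(0.05), np.log(50.0)),
                    (np.log(1e-4), np.log(20.0))],
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        est = ks_ng86(aln, ks_max)
        return KsEstimate(est.id_a, est.id_b, est.ks, est.ka, "NG86",
                          saturated=est.saturated,
                          flags=est.flags + ("ML-non-convergence",))
    t, kappa, omega = np.exp(best.x)
    model = CodonModel(kappa, omega, pi)
    ks, ka = model.ks_ka_decomposition(t)
    flags = () if best.success else ("optimizer-warning",)
    return KsEstimate(aln.id_a, aln.id_b, float(ks), float(ka), "ML-F3x4",
                      kappa=float(kappa), omega=float(omega), t=float(t),
                      saturated=bool(ks > ks_max), flags=flags)


# ---------------------------------------------------------------------------
# Family deduplication
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FamilyDendrogram:
    """One gene family (single-linkage component of unsaturated Ks pairs)
    with its UPGMA join heights — the n-1 deduplicated duplication ages."""

    members: tuple[str, ...]
    heights: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.heights) != len(self.members) - 1:
            raise ValueError("a family of n members must carry n-1 heights")
        if any(b < a - 1e-12 for a, b in zip(self.heights, self.heights[1:])):
            raise ValueError("join heights must be non-decreasing")


def dedup_family_ks(pair_ks: dict[tuple[str, str], float],
                    config: RunConfig | None = None) -> list[FamilyDendrogram]:
    """Deduplicate pairwise Ks into per-family duplication-age estimates.

    Saturated pairs (Ks > ``config.ks_max``) are discarded first.  Families
    are the single-linkage connected components over the remaining pairs;
    within each family a UPGMA (average-linkage) dendrogram on the Ks matrix
    is built and its n-1 join heights reported, eliminating the redundancy of
    the n(n-1)/2 pairwise values.  Missing or discarded within-family pairs
    enter the matrix at the saturation cap.
    """
    from scipy.cluster.hierarchy import linkage
    from scipy.spatial.distance import squareform

    config = config or RunConfig()
    kept = {
        tuple(sorted(pair)): ks for pair, ks in pair_ks.items()
        if math.isfinite(ks) and 0.0 <= ks <= config.ks_max
    }
    if not kept:
        return []
    import networkx as nx

    g = nx.Graph()
    g.add_edges_from(kept)
    families: list[FamilyDendrogram] = []
    for comp in sorted(nx.connected_components(g), key=lambda c: (-len(c), min(c))):
        members = sorted(comp)
        n = len(members)
        if n < 2:
            continue
        idx = {m: i for i, m in enumerate(members)}
        D = np.full((n, n), config.ks_max)
        np.fill_diagonal(D, 0.0)
        for (a, b), ks in kept.items():
            if a in idx and b in idx:
                D[idx[a], idx[b]] = D[idx[b], idx[a]] = ks
        Z = linkage(squareform(D, checks=False), method="average")
        heights = tuple(float(h) for h in Z[:, 2])
        families.append(FamilyDendrogram(members=tuple(members), heights=heights))
    return families


# ---------------------------------------------------------------------------
# Post-speciation enrichment test
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PostSpeciationResult:
    chi2: float
    dof: int
    p: float
    direction: str                    # "enriched" or "depleted" post-speciation
    table: tuple[tuple[int, int], tuple[int, int]]
    fisher_p: float | None = None     # reported when any expected cell < 1
    warning: str | None = None


def post_speciation_test(heights_subgroup: list[float],
                         heights_rest: list[float],
                         config: RunConfig | None = None) -> PostSpeciationResult:
    """Chi-square test for duplication excess after speciation.

    2x2 contingency: (subgroup vs all-other) x (Ks < speciation threshold vs
    Ks >= threshold), Pearson chi-square without continuity correction.  When
    any expected count falls below 1 a Fisher exact p-value is reported
    alongside, with a warning.
    """
    config = config or RunConfig()
    if not heights_subgroup or not heights_rest:
        raise ValueError("both height samples must be non-empty")
    thr = config.speciation_ks
    a = sum(1 for h in heights_subgroup if h < thr)
    b = len(heights_subgroup) - a
    c = sum(1 for h in heights_rest if h < thr)
    d = len(heights_rest) - c
    table = np.array([[a, b], [c, d]], dtype=float)
    row = table.sum(axis=1, keepdims=True)
    col = table.sum(axis=0, keepdims=True)
    expected = row @ col / table.sum()
    if np.any(expected == 0):
        chi2, p = 0.0, 1.0
    else:
        chi2, p, _, _ = stats.chi2_contingency(table, correction=False)[:4]
    frac_sub = a / len(heights_subgroup)
    frac_rest = c / len(heights_rest)
    direction = "enriched" if frac_sub >= frac_rest else "depleted"
    fisher_p = None
    warning = None
    if np.any(expected < 1.0):
        warning = "expected cell count < 1; chi-square approximation unreliable"
        logger.warning(warning)
        fisher_p = float(stats.fisher_exact([[a, b], [c, d]])[1])
    return PostSpeciationResult(
        chi2=float(chi2), dof=1, p=float(p), direction=direction,
        table=((a, b), (c, d)), fisher_p=fisher_p, warning=warning,
    )


def post_speciation_tests_by_subgroup(
        heights_by_subgroup: dict[str, list[float]],
        config: RunConfig | None = None) -> dict[str, dict]:
    """Run the post-speciation test for every subgroup against the pooled
    rest, with Benjamini--Hochberg adjusted p-values alongside the raw ones
    (the multiple-testing handling across subgroups is a package choice)."""
    config = config or RunConfig()
    results: dict[str, PostSpeciationResult] = {}
    for sg, heights in heights_by_subgroup.items():
        rest = [h for other, hs in heights_by_subgroup.items() if other != sg
                for h in hs]
        if heights and rest:
            results[sg] = post_speciation_test(heights, rest, config)
    if not results:
        return {}
    names = sorted(results)
    pvals = np.array([results[n].p for n in names])
    order = np.argsort(pvals)
    m = len(pvals)
    adj = np.empty(m)
    running = 1.0
    for rank_from_end, i in enumerate(order[::-1]):
        k = m - rank_from_end
        running = min(running, pvals[i] * m / k)
        adj[i] = running
    out = {}
    for i, n in enumerate(names):
        r = results[n]
        out[n] = {
            "chi2": r.chi2, "dof": r.dof, "p": r.p, "p_bh": float(adj[i]),
            "direction": r.direction, "table": r.table, "fisher_p": r.fisher_p,
        }
    return out


# ---------------------------------------------------------------------------
# Ks -> time and histograms
# ---------------------------------------------------------------------------

def ks_to_time(ks: float, config: RunConfig | None = None) -> float:
    """Convert Ks to million years via T = Ks / (2r), with the substitution
    rate r anchored so the speciation Ks maps to the speciation time."""
    if ks < 0:
        raise ValueError("ks must be nonnegative")
    config = config or RunConfig()
    return ks / (2.0 * config.ks_rate_per_year) / 1e6


def ks_histogram(heights: list[float], bin_width: float = 0.025,
                 ks_max: float = 2.0) -> dict:
    """Fixed-width Ks histogram with peak calling.

    Peaks are local maxima of the 3-bin moving average of the counts (edges
    padded with zeros); returned as bin-center positions.
    """
    heights = [h for h in heights if 0.0 <= h <= ks_max]
    n_bins = int(math.ceil(ks_max / bin_width))
    edges = np.arange(0, n_bins + 1) * bin_width
    if not heights:
        return {"edges": edges, "counts": np.zeros(n_bins, dtype=int),
                "peaks": []}
    counts, _ = np.histogram(heights, bins=edges)
    padded = np.concatenate([[0.0], counts.astype(float), [0.0]])
    smooth = np.convolve(padded, np.ones(3) / 3.0, mode="valid")
    peaks = []
    for i in range(len(smooth)):
        left = smooth[i - 1] if i > 0 else 0.0
        right = smooth[i + 1] if i < len(smooth) - 1 else 0.0
        if smooth[i] > 0 and smooth[i] > left and smooth[i] >= right:
            peaks.append(float((edges[i] + edges[i + 1]) / 2.0))
    return {"edges": edges, "counts": counts, "peaks": peaks}
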