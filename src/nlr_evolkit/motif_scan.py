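"""Motif/domain detection and NLR architecture typing.

NB-ARC motifs (four major: P-loop, kinase-2, GLPL, MHDV; four minor:
RNBS-A/B/C/D), the TIR core, LRR units and the Solanaceae Domain are
detected with position-specific scoring matrices (PSSMs) built from shipped
seed alignments; score cutoffs are calibrated on a shuffled-sequence null
(99th percentile of the per-protein maximum).  Coiled-coils are scored with
a Lupas-style heptad sliding-window scan.

Each NB-encoding gene is then assigned one of eight architecture types —
TNL, CNL, NL_tir, NL_cc, TN, CN, N_tir, N_cc — from the presence of the
TIR/CC/LRR signals, and flagged *full-type* when its NB span reaches 160 aa
with at least three major and three minor motifs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from functools import lru_cache
from importlib import resources
from pathlib import Path

import numpy as np

from .core_io import ProteinRecord, RunConfig

logger = logging.getLogger(__name__)

AA20 = "ACDEFGHIKLMNPQRSTVWY"
_AA_IDX = {a: i for i, a in enumerate(AA20)}

MAJOR_MOTIFS = ("P-loop", "kinase-2", "GLPL", "MHDV")
MINOR_MOTIFS = ("RNBS-A", "RNBS-B", "RNBS-C", "RNBS-D")
#: canonical N-to-C order of the NB-ARC motifs
NB_MOTIF_ORDER = ("P-loop", "RNBS-A", "kinase-2", "RNBS-B", "RNBS-C",
                  "GLPL", "RNBS-D", "MHDV")

TYPE_LABELS = ("TNL", "CNL", "NL_tir", "NL_cc", "TN", "CN", "N_tir", "N_cc")


# ---------------------------------------------------------------------------
# PSSM models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MotifModel:
    name: str
    class_tag: str                    # major | minor | tir | lrr | sd
    pssm: np.ndarray                  # width x 20 log-odds (bits)
    score_cutoff: float

    def __post_init__(self) -> None:
        if self.pssm.ndim != 2 or self.pssm.shape[1] != 20 or self.pssm.shape[0] < 1:
            raise ValueError(f"model {self.name}: pssm must be width x 20, width >= 1")
        if not np.all(np.isfinite(self.pssm)):
            raise ValueError(f"model {self.name}: non-finite pssm entries")

    @property
    def width(self) -> int:
        return int(self.pssm.shape[0])

    @property
    def consensus(self) -> str:
        return "".join(AA20[int(i)] for i in np.argmax(self.pssm, axis=1))


@dataclass(frozen=True)
class MotifHit:
    motif_name: str
    start: int                        # 1-based inclusive aa positions
    end: int
    score: float

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError("hit positions must satisfy 1 <= start <= end")


def _encode(seq: str) -> np.ndarray:
    return np.array([_AA_IDX.get(c, -1) for c in seq.upper()], dtype=np.int64)


def _window_scores(enc: np.ndarray, pssm: np.ndarray) -> np.ndarray:
    """Score of every window of width ``pssm.shape[0]``; unknown residues (X)
    contribute 0."""
    w = pssm.shape[0]
    n = len(enc) - w + 1
    if n <= 0:
        return np.empty(0)
    padded = np.vstack([pssm.T, np.zeros((1, w))])  # row 20 for unknowns
    scores = np.zeros(n)
    for k in range(w):
        col = enc[k:k + n].copy()
        col[col < 0] = 20
        scores += padded[col, k]
    return scores


def calibrate_cutoff(pssm: np.ndarray, seed: int = 0, n_seqs: int = 500,
                     seq_len: int = 300, quantile: float = 0.99) -> float:
    """Null-calibrated score cutoff: the ``quantile`` of the per-sequence
    maximum window score over random (uniform-composition) proteins.

    With the default 99th percentile, at most ~1% of shuffled proteins of
    this length produce any hit at all.
    """
    rng = np.random.default_rng(seed)
    maxima = np.empty(n_seqs)
    for i in range(n_seqs):
        enc = rng.integers(0, 20, size=seq_len)
        scores = _window_scores(enc, pssm)
        maxima[i] = scores.max() if scores.size else -np.inf
    return float(np.quantile(maxima, quantile))


def build_profile_from_alignment(seqs: list[str], name: str, class_tag: str,
                                 pseudocount: float = 0.5,
                                 calibration_seed: int = 0) -> MotifModel:
    """Build a log-odds PSSM (uniform background, additive pseudocounts)
    from >= 2 aligned seed sequences of equal length.

    All-gap columns are dropped; columns that are mostly gaps (> 50%) are
    dropped as uninformative.  The score cutoff comes from the shuffled-
    sequence null at the 99th percentile (:func:`calibrate_cutoff`).
    """
    if len(seqs) < 2:
        raise ValueError("need at least 2 aligned seed sequences")
    L = len(seqs[0])
    if any(len(s) != L for s in seqs):
        raise ValueError("ragged alignment")
    cols = []
    for c in range(L):
        column = [s[c].upper() for s in seqs]
        gap_frac = sum(1 for ch in column if ch in "-.") / len(column)
        if gap_frac > 0.5:
            continue
        counts = np.full(20, pseudocount)
        n_eff = 0
        for ch in column:
            i = _AA_IDX.get(ch)
            if i is not None:
                counts[i] += 1.0
                n_eff += 1
        if n_eff == 0:
            continue
        freqs = counts / counts.sum()
        cols.append(np.log2(freqs / (1.0 / 20.0)))
    if not cols:
        raise ValueError(f"model {name}: no usable alignment columns")
    pssm = np.vstack(cols)
    cutoff = calibrate_cutoff(pssm, seed=calibration_seed)
    return MotifModel(name=name, class_tag=class_tag, pssm=pssm, score_cutoff=cutoff)


_SEED_FILES = {
    "P-loop": ("p_loop.txt", "major"),
    "RNBS-A": ("rnbs_a.txt", "minor"),
    "kinase-2": ("kinase_2.txt", "major"),
    "RNBS-B": ("rnbs_b.txt", "minor"),
    "RNBS-C": ("rnbs_c.txt", "minor"),
    "GLPL": ("glpl.txt", "major"),
    "RNBS-D": ("rnbs_d.txt", "minor"),
    "MHDV": ("mhdv.txt", "major"),
    "TIR-core": ("tir_core.txt", "tir"),
    "LRR-unit": ("lrr_unit.txt", "lrr"),
    "SD-core": ("sd_core.txt", "sd"),
}


def read_seed_alignment(path: str | Path) -> list[str]:
    """Aligned seed sequences from a seed-alignment text file (``#`` lines
    are comments)."""
    return [l.strip() for l in Path(path).read_text().splitlines()
            if l.strip() and not l.startswith("#")]


@lru_cache(maxsize=1)
def default_motif_models() -> dict[str, MotifModel]:
    """The shipped motif models (seed alignments under ``data/motif_seeds``),
    built and null-calibrated once per process."""
    models: dict[str, MotifModel] = {}
    base = resources.files("nlr_evolkit").joinpath("data/motif_seeds")
    for name, (fname, tag) in _SEED_FILES.items():
        seqs = [l.strip() for l in base.joinpath(fname).read_text().splitlines()
                if l.strip() and not l.startswith("#")]
        models[name] = build_profile_from_alignment(seqs, name, tag)
    return models


def scan_profile(protein: ProteinRecord | str, model: MotifModel) -> list[MotifHit]:
    """All non-overlapping windows scoring at or above the model cutoff,
    chosen greedily best-first, returned sorted by position.  A protein
    shorter than the model width yields no hits."""
    seq = protein.sequence if isinstance(protein, ProteinRecord) else protein
    enc = _encode(seq)
    scores = _window_scores(enc, model.pssm)
    if scores.size == 0:
        return []
    candidates = [
        (float(scores[i]), i) for i in np.nonzero(scores >= model.score_cutoff)[0]
    ]
    candidates.sort(key=lambda t: (-t[0], t[1]))
    taken: list[tuple[int, int]] = []
    hits: list[MotifHit] = []
    w = model.width
    for score, i in candidates:
        if any(i < e and i + w > s for s, e in taken):
            continue
        taken.append((i, i + w))
        hits.append(MotifHit(model.name, start=i + 1, end=i + w, score=score))
    hits.sort(key=lambda h: h.start)
    return hits


# ---------------------------------------------------------------------------
# Coiled-coil (Lupas-style)
# ---------------------------------------------------------------------------

# Heptad-position propensities (positions a..g).  Hydrophobics favored at the
# buried a/d positions, charged/polar at the surface positions, proline
# strongly disfavored throughout — an in-package table calibrated together
# with the two-Gaussian transform below (see docs/methods.md).
_CC_AD = {"L": 3.0, "I": 2.4, "M": 2.2, "V": 2.0, "A": 1.6, "F": 1.4,
          "Y": 0.8, "W": 0.7, "T": 0.5, "S": 0.4, "N": 0.4, "Q": 0.5,
          "E": 0.4, "K": 0.4, "R": 0.4, "D": 0.3, "H": 0.5, "C": 0.6,
          "G": 0.2, "P": 0.05}
_CC_OTHER = {"E": 1.6, "K": 1.5, "Q": 1.4, "R": 1.3, "A": 1.3, "L": 1.1,
             "D": 1.0, "N": 1.0, "S": 0.9, "T": 0.8, "M": 0.9, "H": 0.9,
             "I": 0.7, "V": 0.6, "F": 0.6, "Y": 0.7, "W": 0.5, "C": 0.5,
             "G": 0.5, "P": 0.1}
_AD_WEIGHT = 2.5  # extra geometric weight on the buried positions

_CC_TABLE = np.zeros((7, 21))
for _p in range(7):
    src = _CC_AD if _p in (0, 3) else _CC_OTHER
    for _a, _v in src.items():
        _CC_TABLE[_p, _AA_IDX[_a]] = _v
_CC_TABLE[:, 20] = 0.5  # unknown residue
_CC_LOG = np.log(np.clip(_CC_TABLE, 1e-9, None))


def _cc_window_scores(enc: np.ndarray, window: int) -> np.ndarray:
    """Best-frame weighted geometric-mean propensity for every window."""
    n = len(enc) - window + 1
    if n <= 0:
        return np.empty(0)
    col = enc.copy()
    col[col < 0] = 20
    best = np.full(n, -np.inf)
    for frame in range(7):
        wlog = np.zeros(n)
        wsum = 0.0
        for k in range(window):
            pos = (k + frame) % 7
            w = _AD_WEIGHT if pos in (0, 3) else 1.0
            wlog += w * _CC_LOG[pos, col[k:k + n]]
            wsum += w
        best = np.maximum(best, wlog / wsum)
    return np.exp(best)


@lru_cache(maxsize=3)
def _cc_gaussians(window: int) -> tuple[float, float, float, float]:
    """(mean, sd) of window scores under the globular (uniform-composition)
    and coil (propensity-sampled heptad) models; fixed-seed calibration."""
    rng = np.random.default_rng(2024)
    n = 3000
    glob_scores = np.empty(n)
    for i in range(n):
        enc = rng.integers(0, 20, size=window)
        glob_scores[i] = _cc_window_scores(enc, window)[0]
    coil_scores = np.empty(n)
    probs = _CC_TABLE[:, :20] / _CC_TABLE[:, :20].sum(axis=1, keepdims=True)
    for i in range(n):
        enc = np.array([rng.choice(20, p=probs[(k + (i % 7)) % 7])
                        for k in range(window)])
        coil_scores[i] = _cc_window_scores(enc, window)[0]
    return (float(glob_scores.mean()), float(glob_scores.std()),
            float(coil_scores.mean()), float(coil_scores.std()))


_CC_PRIOR_ODDS = 30.0  # prior weight of the globular class


def detect_coiled_coil(protein: ProteinRecord | str, window: int = 28,
                       threshold: float = 0.9) -> tuple[float, np.ndarray, bool]:
    """Lupas-style coiled-coil scan.

    For every window of ``window`` residues and each of the 7 heptad frames,
    the weighted geometric mean of per-position propensities is computed
    (buried a/d positions up-weighted); the best window score is turned into
    a coiled-coil probability by a two-Gaussian (coil vs globular)
    likelihood ratio with a 1:30 prior.  Returns ``(max_probability,
    per-residue scores, cc_present)``; proteins shorter than the window give
    ``(0.0, [], False)``.
    """
    if window not in (14, 21, 28):
        raise ValueError("window must be one of 14, 21, 28")
    seq = protein.sequence if isinstance(protein, ProteinRecord) else protein
    enc = _encode(seq)
    scores = _cc_window_scores(enc, window)
    if scores.size == 0:
        return 0.0, np.empty(0), False
    mg, sg, mc, sc = _cc_gaussians(window)

    def prob(x: np.ndarray) -> np.ndarray:
        gcc = np.exp(-0.5 * ((x - mc) / sc) ** 2) / sc
        gg = np.exp(-0.5 * ((x - mg) / sg) ** 2) / sg
        return gcc / (gcc + _CC_PRIOR_ODDS * gg)

    win_prob = prob(scores)
    per_residue = np.zeros(len(enc))
    for i, p in enumerate(win_prob):
        sl = per_residue[i:i + window]
        np.maximum(sl, p, out=sl)
    max_p = float(win_prob.max())
    return max_p, per_residue, bool(max_p >= threshold)


# ---------------------------------------------------------------------------
# LRR
# ---------------------------------------------------------------------------

LRR_MIN_UNITS = 3
LRR_WINDOW_AA = 200


def detect_lrr(protein: ProteinRecord | str,
               lrr_model: MotifModel | None = None) -> tuple[bool, list[MotifHit]]:
    """Scan for LxxLxLxx repeat units; LRR present iff at least 3 units fall
    within a 200-aa window."""
    model = lrr_model or default_motif_models()["LRR-unit"]
    hits = scan_profile(protein, model)
    present = False
    for i in range(len(hits)):
        k = i
        while k < len(hits) and hits[k].end - hits[i].start + 1 <= LRR_WINDOW_AA:
            k += 1
        if k - i >= LRR_MIN_UNITS:
            present = True
            break
    return present, hits


# ---------------------------------------------------------------------------
# NB domain extraction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NbDomainCall:
    nb_present: bool
    nb_span: tuple[int, int] | None   # 1-based inclusive aa interval
    major_count: int
    minor_count: int
    chain: tuple[MotifHit, ...] = ()
    secondary: tuple[MotifHit, ...] = ()  # consistent leftover chain (tandem NB)

    @property
    def span_length(self) -> int:
        return 0 if self.nb_span is None else self.nb_span[1] - self.nb_span[0] + 1


_MOTIF_RANK = {name: i for i, name in enumerate(NB_MOTIF_ORDER)}


def _best_chain(hits: list[MotifHit]) -> list[MotifHit]:
    """Highest-scoring subset of hits with strictly increasing canonical motif
    rank and position (weighted longest-increasing-subsequence DP)."""
    hits = sorted(hits, key=lambda h: (h.start, _MOTIF_RANK[h.motif_name]))
    n = len(hits)
    best_score = [h.score for h in hits]
    parent = [-1] * n
    for i in range(n):
        for j in range(i):
            if (hits[j].end < hits[i].start
                    and _MOTIF_RANK[hits[j].motif_name] < _MOTIF_RANK[hits[i].motif_name]
                    and best_score[j] + hits[i].score > best_score[i]):
                best_score[i] = best_score[j] + hits[i].score
                parent[i] = j
    if n == 0:
        return []
    i = int(np.argmax(best_score))
    chain = []
    while i >= 0:
        chain.append(hits[i])
        i = parent[i]
    return list(reversed(chain))


def extract_nb_domain(protein: ProteinRecord | str,
                      hits: list[MotifHit]) -> NbDomainCall:
    """Resolve NB-ARC motif hits into one consistent motif chain.

    The canonical chain (P-loop .. MHDV in order) is the highest-scoring
    position- and rank-consistent subset of hits; out-of-order hits are
    thereby dropped.  A second consistent chain among the leftovers is
    reported as a secondary (tandem) NB.  ``nb_present`` requires at least
    one major motif in the chain.
    """
    nb_hits = [h for h in hits if h.motif_name in _MOTIF_RANK]
    chain = _best_chain(nb_hits)
    chain_set = {(h.motif_name, h.start) for h in chain}
    leftovers = [h for h in nb_hits if (h.motif_name, h.start) not in chain_set]
    secondary = _best_chain(leftovers)
    majors = {h.motif_name for h in chain if h.motif_name in MAJOR_MOTIFS}
    minors = {h.motif_name for h in chain if h.motif_name in MINOR_MOTIFS}
    if not majors:
        return NbDomainCall(False, None, 0, len(minors), tuple(chain),
                            tuple(secondary))
    span = (min(h.start for h in chain), max(h.end for h in chain))
    return NbDomainCall(True, span, len(majors), len(minors), tuple(chain),
                        tuple(secondary))


# ---------------------------------------------------------------------------
# Architecture typing
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ArchitectureCall:
    gene_id: str
    nb_present: bool
    nb_span: tuple[int, int] | None
    major_count: int
    minor_count: int
    lrr_present: bool
    tir_present: bool
    cc_present: bool
    nb_lineage: str                   # tir | cc | unassigned
    type_label: str
    full_type: bool
    cc_probability: float = 0.0
    sd_present: bool = False

    @property
    def span_length(self) -> int:
        return 0 if self.nb_span is None else self.nb_span[1] - self.nb_span[0] + 1


def _type_label(tir: bool, cc: bool, lrr: bool, lineage: str) -> str:
    # total, deterministic decision table; TIR wins when both N-terminal
    # signals fire
    if tir:
        return "TNL" if lrr else "TN"
    if cc:
        return "CNL" if lrr else "CN"
    suffix = lineage if lineage in ("tir", "cc") else "unassigned"
    return f"NL_{suffix}" if lrr else f"N_{suffix}"


def is_full_type(call: ArchitectureCall | NbDomainCall,
                 config: RunConfig | None = None) -> bool:
    """Full-type (intact) NLR: NB span >= 160 aa, >= 3 of the 4 major motifs
    and >= 3 of the 4 RNBS minor motifs."""
    config = config or RunConfig()
    return (call.span_length >= config.nb_min_len
            and call.major_count >= config.major_min
            and call.minor_count >= config.minor_min)


def classify_architecture(gene_id: str, nb: NbDomainCall, tir_present: bool,
                          cc_present: bool, lrr_present: bool,
                          nb_lineage: str = "unassigned",
                          config: RunConfig | None = None,
                          cc_probability: float = 0.0,
                          sd_present: bool = False) -> ArchitectureCall:
    """Assign the architecture type from the decision table.

    Precondition: ``nb.nb_present`` (non-NB genes are not NLR-family and are
    excluded upstream).  When both TIR and CC fire, TIR wins (domain identity
    over heptad propensity) and the event is logged.  Genes without TIR/CC
    whose lineage is still unassigned are flagged for classification-stage
    backfill.
    """
    if not nb.nb_present:
        raise ValueError(f"{gene_id}: classify_architecture requires an NB domain")
    if tir_present and cc_present:
        logger.info("%s: both TIR and CC detected; TIR takes precedence", gene_id)
        cc_effective = False
    else:
        cc_effective = cc_present
    label = _type_label(tir_present, cc_effective, lrr_present, nb_lineage)
    lineage = "tir" if tir_present else ("cc" if cc_effective else nb_lineage)
    call = ArchitectureCall(
        gene_id=gene_id, nb_present=True, nb_span=nb.nb_span,
        major_count=nb.major_count, minor_count=nb.minor_count,
        lrr_present=lrr_present, tir_present=tir_present,
        cc_present=cc_present, nb_lineage=lineage,
        type_label=label, full_type=False, cc_probability=cc_probability,
        sd_present=sd_present,
    )
    return replace(call, full_type=is_full_type(call, config))


def relabel_with_lineage(call: ArchitectureCall, lineage: str) -> ArchitectureCall:
    """Re-apply the decision table after lineage backfill (e.g. a CN-typed
    gene placed in a TIR-lineage subgroup becomes TN)."""
    if lineage not in ("tir", "cc"):
        return call
    if call.tir_present or call.cc_present:
        # N-terminal evidence present: lineage follows it unless the subgroup
        # contradicts it, in which case the subgroup (clade membership) wins
        tir = lineage == "tir" and (call.tir_present or not call.cc_present)
        cc = lineage == "cc" and (call.cc_present or not call.tir_present)
        if call.tir_present and lineage == "cc":
            tir, cc = False, True
        if call.cc_present and lineage == "tir":
            tir, cc = True, False
    else:
        tir = cc = False
    label = _type_label(tir, cc, call.lrr_present, lineage)
    return replace(call, nb_lineage=lineage, type_label=label)


# ---------------------------------------------------------------------------
# SD domain
# ---------------------------------------------------------------------------

def scan_sd_domain(protein: ProteinRecord | str, sd_model: MotifModel | None,
                   nb_start: int) -> tuple[bool, MotifHit | None]:
    """Solanaceae-Domain scan restricted to the extended N-terminus.

    SD present iff a hit at or above the model cutoff lies entirely upstream
    of the CC/NB start (1-based ``nb_start``).  Requires an NB domain.
    """
    if nb_start < 1:
        raise ValueError("scan_sd_domain requires the NB/CC start position")
    model = sd_model or default_motif_models()["SD-core"]
    hits = scan_profile(protein, model)
    for h in hits:
        if h.end < nb_start:
            return True, h
    return False, None


# ---------------------------------------------------------------------------
# Whole-protein annotation
# ---------------------------------------------------------------------------

def annotate_protein(protein: ProteinRecord,
                     models: dict[str, MotifModel] | None = None,
                     config: RunConfig | None = None) -> ArchitectureCall | None:
    """Run the full per-protein annotation: NB motif chain, N-terminal TIR /
    coiled-coil (scanned upstream of the NB start), LRR units, SD.

    Returns None when no NB domain is found (the gene is not NLR-family).
    """
    config = config or RunConfig()
    models = models or default_motif_models()
    nb_hits: list[MotifHit] = []
    for name in NB_MOTIF_ORDER:
        nb_hits.extend(scan_profile(protein, models[name]))
    nb = extract_nb_domain(protein, nb_hits)
    if not nb.nb_present:
        return None
    nb_start = nb.nb_span[0]
    upstream = protein.sequence[: nb_start - 1]
    tir_present = bool(scan_profile(upstream, models["TIR-core"])) if upstream else False
    cc_prob, _, cc_present = (
        detect_coiled_coil(upstream, threshold=config.coils_threshold)
        if upstream else (0.0, np.empty(0), False)
    )
    lrr_present, _ = detect_lrr(protein, models["LRR-unit"])
    sd_present, _ = scan_sd_domain(protein, models["SD-core"], nb_start) \
        if upstream else (False, None)
    return classify_architecture(
        protein.id, nb, tir_present, cc_present, lrr_present,
        config=config, cc_probability=cc_prob, sd_present=sd_present,
    )
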