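"""Truth-labeled synthetic inputs for every pipeline stage.

The generator emulates the statistical structure the analysis assumes:

* proteins assembled from region templates — optional Solanaceae Domain,
  TIR or coiled-coil N-terminus, an NB block carrying the eight NB-ARC
  motifs in canonical order with subgroup-specific spacers, an LRR block of
  tandem units — with per-residue substitution noise and recorded truth
  spans;
* chromosome layouts with planted tandem NLR clusters separated by
  motif-free filler genes;
* gene families whose CDS diverge by synonymous-only evolution at
  controlled Ks depths (so protein-level truth is exact while duplication
  ages are planted);
* a GY94 codon-model evolver (Gillespie simulation) for estimator
  validation.

Everything is deterministic under ``(spec, seed)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from ._codon import (
    CODON_TABLE,
    CodonModel,
    SENSE_CODONS,
    CODON_INDEX,
    codons_of,
    f3x4_frequencies,
    synonymous_site_fraction,
)
from .core_io import CdsRecord, GeneLocus, ProteinRecord
from .motif_scan import (
    MotifModel,
    NB_MOTIF_ORDER,
    default_motif_models,
    detect_coiled_coil,
    scan_profile,
)

logger = logging.getLogger(__name__)

AA20 = "ACDEFGHIKLMNPQRSTVWY"

# region geometry (aa)
_SPACER_LEN = 30
_LINKER1_LEN = 25
_LINKER2_LEN = 20
_TAIL_LEN = 30
_LRR_UNITS = 5
_LRR_X_LEN = 8
CC_BLOCK = "LAELEQK" * 5
_TIR_FLANK_5 = "SSSRE"
_TIR_FLANK_3 = "EGFTGNLYKALSD"
_SD_FLANK_5 = "AE"
_SD_FLANK_3 = "QTRS"

_CODONS_BY_AA: dict[str, list[str]] = {}
for _c, _aa in CODON_TABLE.items():
    if _aa != "*":
        _CODONS_BY_AA.setdefault(_aa, []).append(_c)
for _aa in _CODONS_BY_AA:
    _CODONS_BY_AA[_aa].sort()


def _random_aa(rng: np.random.Generator, n: int) -> str:
    return "".join(AA20[i] for i in rng.integers(0, 20, size=n))


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            choices = AA20.replace(out[i], "")
            out[i] = choices[rng.integers(0, len(choices))]
    return "".join(out)


# ---------------------------------------------------------------------------
# Subgroup cores
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SubgroupCore:
    """Region templates for one subgroup: motif boxes lightly diverged from
    consensus, spacers/linkers fully subgroup-specific, so within-subgroup
    identity is high (~90%+ before noise) and between-subgroup identity is
    confined to the conserved boxes (~35-40% overall)."""

    name: str
    lineage: str                       # "tir" | "cc"
    has_sd: bool
    motif_boxes: dict[str, str]        # NB motif name -> box sequence
    spacers: tuple[str, ...]           # 7 inter-motif spacers
    linker1: str
    linker2: str
    tail: str
    tir_block: str
    cc_block: str
    sd_block: str
    lrr_units: tuple[str, ...]


_BOX_MUTATION_RATE = 0.15
_CC_SURFACE_CHOICES = "EKQRASND"


def _mutate_cc(block: str, rng: np.random.Generator, rate: float = 0.3) -> str:
    # only surface (non-a/d) heptad positions vary, drawn from polar/charged
    # residues, so the coiled-coil signal itself is preserved
    out = list(block)
    for i in range(len(out)):
        if i % 7 in (0, 3):
            continue
        if rng.random() < rate:
            out[i] = _CC_SURFACE_CHOICES[rng.integers(0, len(_CC_SURFACE_CHOICES))]
    return "".join(out)


def make_subgroup_core(name: str, lineage: str, rng: np.random.Generator,
                       has_sd: bool = False,
                       models: dict[str, MotifModel] | None = None,
                       max_tries: int = 50) -> SubgroupCore:
    """Derive a subgroup's region templates from the shared consensus
    templates.  Motif boxes are re-validated against their PSSM cutoffs (and
    the CC block against the coiled-coil threshold) so a noise-free protein
    built from the core is always fully detectable."""
    models = models or default_motif_models()
    consensus = {nm: models[nm].consensus for nm in NB_MOTIF_ORDER}
    for _ in range(max_tries):
        boxes = {}
        ok = True
        for nm in NB_MOTIF_ORDER:
            box = _mutate(consensus[nm], _BOX_MUTATION_RATE, rng)
            hits = scan_profile(box, models[nm])
            if not hits:
                ok = False
                break
            boxes[nm] = box
        if not ok:
            continue
        tir_core = _mutate(models["TIR-core"].consensus, _BOX_MUTATION_RATE, rng)
        if not scan_profile(_TIR_FLANK_5 + tir_core + _TIR_FLANK_3,
                            models["TIR-core"]):
            continue
        cc = _mutate_cc(CC_BLOCK, rng)
        if not detect_coiled_coil(cc)[2]:
            continue
        sd_core = _mutate(models["SD-core"].consensus, _BOX_MUTATION_RATE, rng)
        if has_sd and not scan_profile(_SD_FLANK_5 + sd_core + _SD_FLANK_3,
                                       models["SD-core"]):
            continue
        lrr_cons = models["LRR-unit"].consensus
        units = []
        for _u in range(_LRR_UNITS):
            unit = _mutate(lrr_cons, 0.05, rng) + _random_aa(rng, _LRR_X_LEN)
            units.append(unit)
        if sum(1 for u in units if scan_profile(u, models["LRR-unit"])) < 4:
            continue
        return SubgroupCore(
            name=name, lineage=lineage, has_sd=has_sd,
            motif_boxes=boxes,
            spacers=tuple(_random_aa(rng, _SPACER_LEN) for _ in range(7)),
            linker1=_random_aa(rng, _LINKER1_LEN),
            linker2=_random_aa(rng, _LINKER2_LEN),
            tail=_random_aa(rng, _TAIL_LEN),
            tir_block=_TIR_FLANK_5 + tir_core + _TIR_FLANK_3,
            cc_block=cc,
            sd_block=_SD_FLANK_5 + sd_core + _SD_FLANK_3,
            lrr_units=tuple(units),
        )
    raise RuntimeError(f"could not build a detectable core for subgroup {name}")


# ---------------------------------------------------------------------------
# Protein assembly
# ---------------------------------------------------------------------------

@dataclass
class ProteinTruth:
    gene_id: str
    type_label: str
    subgroup: str
    motif_spans: dict[str, tuple[int, int]]  # 1-based inclusive aa spans
    nb_span: tuple[int, int] | None = None
    has_sd: bool = False


_TYPE_HAS = {
    # type_label -> (tir, cc, lrr)
    "TNL": (True, False, True), "CNL": (False, True, True),
    "NL_tir": (False, False, True), "NL_cc": (False, False, True),
    "TN": (True, False, False), "CN": (False, True, False),
    "N_tir": (False, False, False), "N_cc": (False, False, False),
}


def make_nlr_protein(gene_id: str, type_label: str, core: SubgroupCore,
                     noise: float, rng: np.random.Generator
                     ) -> tuple[ProteinRecord, ProteinTruth]:
    """Assemble one NLR protein of the given architecture type from the
    subgroup core, apply per-residue substitution noise, and record the
    planted feature spans."""
    if type_label not in _TYPE_HAS:
        raise ValueError(f"unknown type label {type_label!r}")
    tir, cc, lrr = _TYPE_HAS[type_label]
    parts: list[tuple[str, str]] = []  # (feature name or '', sequence)
    if core.has_sd and cc:
        parts.append(("SD", core.sd_block))
    if tir:
        parts.append(("TIR", core.tir_block))
    if cc:
        parts.append(("CC", core.cc_block))
    parts.append(("", core.linker1))
    for k, nm in enumerate(NB_MOTIF_ORDER):
        parts.append((nm, core.motif_boxes[nm]))
        if k < 7:
            parts.append(("", core.spacers[k]))
    parts.append(("", core.linker2))
    if lrr:
        for u, unit in enumerate(core.lrr_units):
            parts.append((f"LRR{u + 1}", unit))
    parts.append(("", core.tail))

    seq_parts: list[str] = []
    spans: dict[str, tuple[int, int]] = {}
    pos = 0
    for name, part in parts:
        if name:
            spans[name] = (pos + 1, pos + len(part))
        seq_parts.append(part)
        pos += len(part)
    sequence = _mutate("".join(seq_parts), noise, rng)
    nb_span = (spans["P-loop"][0], spans["MHDV"][1])
    truth = ProteinTruth(
        gene_id=gene_id, type_label=type_label, subgroup=core.name,
        motif_spans=spans, nb_span=nb_span, has_sd=core.has_sd and cc,
    )
    return ProteinRecord(id=gene_id, sequence=sequence), truth


def make_filler_protein(gene_id: str, rng: np.random.Generator,
                        models: dict[str, MotifModel] | None = None,
                        length_range: tuple[int, int] = (150, 300),
                        max_tries: int = 100) -> ProteinRecord:
    """A random ORF guaranteed motif-free by rejection sampling against every
    motif model and the coiled-coil detector."""
    models = models or default_motif_models()
    for _ in range(max_tries):
        n = int(rng.integers(*length_range))
        seq = "M" + _random_aa(rng, n - 1)
        if any(scan_profile(seq, m) for m in models.values()):
            continue
        if detect_coiled_coil(seq)[2]:
            continue
        return ProteinRecord(id=gene_id, sequence=seq)
    raise RuntimeError("could not sample a motif-free filler protein")


def reverse_translate(protein: ProteinRecord, rng: np.random.Generator) -> CdsRecord:
    """Random synonymous codon choice per residue, plus a stop codon."""
    codons = []
    for aa in protein.sequence:
        opts = _CODONS_BY_AA.get(aa) or _CODONS_BY_AA["A"]  # X -> alanine codon
        codons.append(opts[rng.integers(0, len(opts))])
    return CdsRecord(id=protein.id, sequence="".join(codons) + "TAA")


# ---------------------------------------------------------------------------
# Codon evolution (GY94 Gillespie)
# ---------------------------------------------------------------------------

def _evolve_codons(codons: list[str], ks_amount: float, model: CodonModel,
                   f_s: float, rng: np.random.Generator
                   ) -> tuple[list[str], int, int]:
    """Evolve codons for a branch accumulating ``ks_amount`` synonymous
    substitutions per synonymous site; returns (codons, n_syn, n_nonsyn)."""
    if ks_amount <= 0:
        return list(codons), 0, 0
    t = ks_amount * 3.0 * f_s / model.rho_s  # codon-substitution time units
    Q = model.Q
    out = list(codons)
    n_syn = n_nonsyn = 0
    for i, codon in enumerate(out):
        x = CODON_INDEX.get(codon)
        if x is None:
            continue
        remaining = t
        while True:
            rate = -Q[x, x]
            if rate <= 0:
                break
            wait = rng.exponential(1.0 / rate)
            if wait > remaining:
                break
            remaining -= wait
            probs = Q[x].copy()
            probs[x] = 0.0
            probs /= probs.sum()
            y = int(rng.choice(len(probs), p=probs))
            if CODON_TABLE[SENSE_CODONS[y]] == CODON_TABLE[SENSE_CODONS[x]]:
                n_syn += 1
            else:
                n_nonsyn += 1
            x = y
        out[i] = SENSE_CODONS[x]
    return out, n_syn, n_nonsyn


def evolve_codon_pair(ancestor_codons: list[str], target_ks: float,
                      kappa: float, omega: float, rng: np.random.Generator
                      ) -> tuple[list[str], list[str], dict]:
    """Evolve two descendants from an ancestor so their expected synonymous
    divergence is ``target_ks`` (each branch carries half), by Gillespie
    simulation under the GY94 rate matrix with F3x4 frequencies taken from
    the ancestor."""
    pi = f3x4_frequencies(["".join(ancestor_codons)])
    model = CodonModel(kappa, omega, pi)
    f_s = synonymous_site_fraction(kappa, pi)
    a, sa, na = _evolve_codons(ancestor_codons, target_ks / 2.0, model, f_s, rng)
    b, sb, nb = _evolve_codons(ancestor_codons, target_ks / 2.0, model, f_s, rng)
    n_codons = len(ancestor_codons)
    realized = {
        "n_syn": sa + sb, "n_nonsyn": na + nb,
        "realized_ks": (sa + sb) / (3.0 * f_s * n_codons) if n_codons else 0.0,
        "synonymous_site_fraction": f_s,
    }
    return a, b, realized


def random_ancestor_codons(n_codons: int, rng: np.random.Generator) -> list[str]:
    return [SENSE_CODONS[i] for i in rng.integers(0, len(SENSE_CODONS), size=n_codons)]


def simulate_gene_family(n: int, duplication_depths_ks: list[float],
                         kappa: float, omega: float,
                         rng: np.random.Generator,
                         ancestor_codons: list[str] | None = None,
                         n_codons: int = 300,
                         id_prefix: str = "fam"
                         ) -> tuple[list[CdsRecord], dict]:
    """Simulate a family of ``n`` genes produced by ``n-1`` duplications at
    the given pairwise-Ks depths (sorted ascending).

    The duplication tree has random topology with planted event times; every
    lineage evolves under the GY94 model between events.  Returns the CDS
    set and a truth dict with the planted heights and the pairwise
    divergence-depth matrix.
    """
    depths = list(duplication_depths_ks)
    if len(depths) != n - 1:
        raise ValueError("need exactly n-1 duplication depths")
    if depths != sorted(depths):
        raise ValueError("duplication depths must be sorted ascending")
    if ancestor_codons is None:
        ancestor_codons = random_ancestor_codons(n_codons, rng)
    pi = f3x4_frequencies(["".join(ancestor_codons)])
    model = CodonModel(kappa, omega, pi)
    f_s = synonymous_site_fraction(kappa, pi)

    events = sorted(depths, reverse=True)  # oldest first
    lineages: list[list[str]] = [list(ancestor_codons)]
    div: dict[tuple[int, int], float] = {}
    prev_time = events[0]
    for k, ev in enumerate(events):
        if k > 0:
            delta = prev_time - ev
            for li in range(len(lineages)):
                lineages[li], _, _ = _evolve_codons(
                    lineages[li], delta / 2.0, model, f_s, rng)
            prev_time = ev
        src = int(rng.integers(0, len(lineages)))
        new = len(lineages)
        lineages.append(list(lineages[src]))
        for other in range(new):
            if other == src:
                div[(src, new)] = ev
            else:
                key = (min(other, src), max(other, src))
                div[(min(other, new), max(other, new))] = div[key]
    for li in range(len(lineages)):
        lineages[li], _, _ = _evolve_codons(
            lineages[li], prev_time / 2.0, model, f_s, rng)

    cds = [CdsRecord(id=f"{id_prefix}_{i + 1}",
                     sequence="".join(lineages[i]) + "TAA")
           for i in range(n)]
    truth = {
        "heights": sorted(depths),
        "pairwise_depth": {
            (f"{id_prefix}_{a + 1}", f"{id_prefix}_{b + 1}"): d
            for (a, b), d in div.items()
        },
    }
    return cds, truth


# ---------------------------------------------------------------------------
# Genome assembly
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SubgroupSpec:
    name: str
    lineage: str                      # "tir" | "cc"
    type_label: str                   # one of the eight architecture types
    counts: dict                      # species -> gene count
    has_sd: bool = False


@dataclass(frozen=True)
class ClusterSpec:
    species: str
    chromosome: int                   # 1-based
    subgroup: str
    n_genes: int
    gap_bp: int = 20_000              # between consecutive cluster members
    n_intervening: int = 0            # filler genes between consecutive members


@dataclass(frozen=True)
class GenomeSpec:
    species: tuple[str, ...] = ("pepper", "tomato", "potato")
    n_chromosomes: int = 3
    subgroups: tuple[SubgroupSpec, ...] = ()
    clusters: tuple[ClusterSpec, ...] = ()
    noise: float = 0.0                # per-residue substitution probability
    n_filler_per_chromosome: int = 4
    isolated_gap_bp: int = 300_000    # keeps unclustered NLRs unchained
    family_ks_depths: tuple[float, ...] = ()   # planted per-family depths
    kappa: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        for cs in self.clusters:
            if cs.gap_bp <= 0:
                raise ValueError("cluster gaps must be positive")
        for sg in self.subgroups:
            if any(v < 0 for v in sg.counts.values()):
                raise ValueError("gene counts must be nonnegative")


@dataclass
class SyntheticGenome:
    proteins: dict                    # species -> list[ProteinRecord]
    cds: dict                         # species -> list[CdsRecord]
    loci: dict                        # species -> list[GeneLocus]
    truth_proteins: dict              # gene_id -> ProteinTruth
    truth_clusters: dict              # species -> list[tuple of gene_ids]
    truth_families: dict              # (species, subgroup) -> dict(members, depths)
    cores: dict                       # subgroup name -> SubgroupCore


def make_annotated_genome(spec: GenomeSpec) -> SyntheticGenome:
    """Emit protein+CDS FASTA-ready records, GFF-ready loci and the full
    truth table for a genome spec.

    NLR genes of one (species, subgroup) form one family: their CDS descend
    from a common reverse-translated ancestor by synonymous-only evolution
    at the planted Ks depths, then codons at noise-substituted residues are
    repainted — protein truth stays exact while duplication ages are
    controlled.  Cluster plans place members with the given gaps and filler
    counts; remaining NLRs are isolated beyond the cluster rule's reach.
    """
    rng = np.random.default_rng(spec.seed)
    models = default_motif_models()
    cores = {
        sg.name: make_subgroup_core(sg.name, sg.lineage,
                                    np.random.default_rng([spec.seed, 77, k]),
                                    has_sd=sg.has_sd, models=models)
        for k, sg in enumerate(spec.subgroups)
    }

    proteins: dict[str, list[ProteinRecord]] = {s: [] for s in spec.species}
    cds: dict[str, list[CdsRecord]] = {s: [] for s in spec.species}
    loci: dict[str, list[GeneLocus]] = {s: [] for s in spec.species}
    truth_proteins: dict[str, ProteinTruth] = {}
    truth_clusters: dict[str, list[tuple[str, ...]]] = {s: [] for s in spec.species}
    truth_families: dict[tuple[str, str], dict] = {}

    # build genes per species x subgroup
    genes_by_key: dict[tuple[str, str], list[ProteinRecord]] = {}
    for sgk, sg in enumerate(spec.subgroups):
        core = cores[sg.name]
        for sp in spec.species:
            count = int(sg.counts.get(sp, 0))
            if count == 0:
                continue
            key = (sp, sg.name)
            members: list[ProteinRecord] = []
            grng = np.random.default_rng([spec.seed, 101, sgk,
                                          list(spec.species).index(sp)])
            for i in range(count):
                gid = f"{sp}_{sg.name}_{i + 1}"
                prot, truth = make_nlr_protein(gid, sg.type_label, core,
                                               spec.noise, grng)
                members.append(prot)
                truth_proteins[gid] = truth
            genes_by_key[key] = members
            # family CDS: synonymous-only evolution at planted depths
            frng = np.random.default_rng([spec.seed, 202, sgk,
                                          list(spec.species).index(sp)])
            ancestor_prot, _ = make_nlr_protein("anc", sg.type_label, core,
                                                0.0, np.random.default_rng(0))
            anc_cds = reverse_translate(ancestor_prot, frng)
            anc_codons = codons_of(anc_cds.sequence)[:-1]  # drop stop
            n = len(members)
            if n >= 2:
                if spec.family_ks_depths and len(spec.family_ks_depths) >= n - 1:
                    depths = sorted(spec.family_ks_depths[: n - 1])
                else:
                    depths = sorted(frng.uniform(0.05, 0.25, size=n - 1).tolist())
                fam_cds, _ = simulate_gene_family(
                    n, depths, spec.kappa, 0.0, frng,
                    ancestor_codons=anc_codons, id_prefix="tmp")
                truth_families[key] = {
                    "members": [m.id for m in members], "depths": depths,
                }
            else:
                fam_cds = [CdsRecord(id="tmp_1", sequence="".join(anc_codons) + "TAA")]
            # repaint codons where the noisy protein differs from the ancestor
            for member, fam in zip(members, fam_cds):
                fam_codons = codons_of(fam.sequence)[:-1]
                out = []
                for aa, codon in zip(member.sequence, fam_codons):
                    if CODON_TABLE.get(codon) == aa:
                        out.append(codon)
                    else:
                        opts = _CODONS_BY_AA.get(aa, _CODONS_BY_AA["A"])
                        out.append(opts[frng.integers(0, len(opts))])
                cds[sp].append(CdsRecord(id=member.id,
                                         sequence="".join(out) + "TAA"))
            proteins[sp].extend(members)

    # physical layout
    for sp in spec.species:
        placed: set[str] = set()
        queue_by_subgroup: dict[str, list[ProteinRecord]] = {
            sg.name: list(genes_by_key.get((sp, sg.name), []))
            for sg in spec.subgroups
        }
        next_pos = {c: 50_000 for c in range(1, spec.n_chromosomes + 1)}
        filler_k = 0
        lrng = np.random.default_rng([spec.seed, 303, list(spec.species).index(sp)])

        def place_gene(rec: ProteinRecord | None, chrom: int, gap: int,
                       is_nlr: bool) -> GeneLocus:
            nonlocal filler_k
            start = next_pos[chrom] + gap
            if rec is None:
                filler_k += 1
                gid = f"{sp}_filler_{filler_k}"
                prot = make_filler_protein(gid, lrng, models)
                proteins[sp].append(prot)
                cds[sp].append(reverse_translate(prot, lrng))
                length = len(prot.sequence) * 3 + 3
            else:
                gid = rec.id
                length = len(rec.sequence) * 3 + 3
            loc = GeneLocus(gene_id=gid, chromosome=f"chr{chrom}",
                            start=start, end=start + length - 1,
                            strand="+" if lrng.random() < 0.5 else "-",
                            is_nlr=is_nlr)
            loci[sp].append(loc)
            next_pos[chrom] = loc.end
            return loc

        for cs in spec.clusters:
            if cs.species != sp:
                continue
            if cs.chromosome > spec.n_chromosomes:
                raise ValueError("cluster plan names a chromosome beyond the genome")
            pool = queue_by_subgroup.get(cs.subgroup, [])
            if len(pool) < cs.n_genes:
                raise ValueError(
                    f"cluster plan for {sp}/{cs.subgroup} wants {cs.n_genes} genes "
                    f"but only {len(pool)} remain"
                )
            member_ids = []
            for k in range(cs.n_genes):
                rec = pool.pop(0)
                gap = spec.isolated_gap_bp if k == 0 else cs.gap_bp
                if k > 0:
                    for _ in range(cs.n_intervening):
                        place_gene(None, cs.chromosome, max(
                            cs.gap_bp // (cs.n_intervening + 1), 500), False)
                place_gene(rec, cs.chromosome, gap if k > 0 else gap, True)
                member_ids.append(rec.id)
                placed.add(rec.id)
            truth_clusters[sp].append(tuple(member_ids))

        # isolated leftovers round-robin across chromosomes
        chrom_cycle = 0
        for sg in spec.subgroups:
            for rec in queue_by_subgroup.get(sg.name, []):
                chrom = (chrom_cycle % spec.n_chromosomes) + 1
                chrom_cycle += 1
                place_gene(rec, chrom, spec.isolated_gap_bp, True)
                placed.add(rec.id)
        # background fillers
        for chrom in range(1, spec.n_chromosomes + 1):
            for _ in range(spec.n_filler_per_chromosome):
                place_gene(None, chrom, 40_000, False)
        loci[sp].sort(key=lambda l: (l.chromosome, l.start))

    return SyntheticGenome(
        proteins=proteins, cds=cds, loci=loci,
        truth_proteins=truth_proteins, truth_clusters=truth_clusters,
        truth_families=truth_families, cores=cores,
    )


def default_genome_spec(seed: int = 0, noise: float = 0.0) -> GenomeSpec:
    """The study-condition genome: three species, five subgroups (one TIR
    lineage, four CC lineages, one carrying the Solanaceae Domain), with
    tandem clusters planted in the pepper-like species."""
    subgroups = (
        SubgroupSpec("TNL-A", "tir", "TNL",
                     {"pepper": 4, "tomato": 4, "potato": 4}),
        SubgroupSpec("CNL-A", "cc", "CNL",
                     {"pepper": 6, "tomato": 4, "potato": 4}, has_sd=True),
        SubgroupSpec("CNL-B", "cc", "CNL",
                     {"pepper": 6, "tomato": 3, "potato": 3}),
        SubgroupSpec("CNL-C", "cc", "CN",
                     {"pepper": 4, "tomato": 3, "potato": 3}),
        SubgroupSpec("CNL-D", "cc", "NL_cc",
                     {"pepper": 4, "tomato": 3, "potato": 3}),
    )
    clusters = (
        ClusterSpec("pepper", 1, "CNL-A", 4, gap_bp=20_000, n_intervening=0),
        ClusterSpec("pepper", 2, "CNL-B", 4, gap_bp=50_000, n_intervening=2),
        ClusterSpec("pepper", 3, "TNL-A", 3, gap_bp=30_000, n_intervening=1),
    )
    return GenomeSpec(subgroups=subgroups, clusters=clusters,
                      noise=noise, seed=seed)
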