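"""Physical clustering of NLR loci on chromosomes.

Two adjacent NLRs belong to the same physical cluster when they are less
than 200 kb apart (end of the upstream gene to start of the downstream one)
and have fewer than 8 annotated non-NLR genes between them.  Clusters are
maximal chains of length >= 2.  Strand is ignored; nested or overlapping
genes count once.
"""

from __future__ import annotations

from dataclasses import dataclass

from .core_io import GeneLocus, RunConfig, loci_by_chromosome


@dataclass(frozen=True)
class PhysicalCluster:
    chromosome: str
    members: tuple[str, ...]          # gene ids ordered by start
    start: int
    end: int
    homogeneous: bool = False
    dominant_subgroup: str | None = None

    @property
    def span(self) -> int:
        return self.end - self.start + 1

    def __len__(self) -> int:
        return len(self.members)


def _chainable(a: GeneLocus, b: GeneLocus, intervening: int, config: RunConfig) -> bool:
    gap = b.start - a.end
    return gap < config.cluster_max_gap and intervening < config.cluster_max_intervening


def call_physical_clusters(loci: list[GeneLocus], nlr_ids: set[str],
                           config: RunConfig | None = None) -> list[PhysicalCluster]:
    """Call maximal physical clusters of NLR loci.

    ``nlr_ids`` flags which gene ids are NLRs; all other loci only matter for
    the intervening-gene count.  Genes without a locus simply do not appear
    here (they are 'unanchored' and handled by the tallies).
    """
    config = config or RunConfig()
    clusters: list[PhysicalCluster] = []
    for chrom, chrom_loci in sorted(loci_by_chromosome(loci).items()):
        nlrs = [l for l in chrom_loci if l.gene_id in nlr_ids or l.is_nlr]
        if len(nlrs) < 2:
            continue
        # count non-NLR genes strictly between consecutive NLR pairs
        nlr_set = {l.gene_id for l in nlrs}
        chain: list[GeneLocus] = [nlrs[0]]
        for prev, cur in zip(nlrs, nlrs[1:]):
            intervening = sum(
                1 for l in chrom_loci
                if l.gene_id not in nlr_set and l.start > prev.end and l.end < cur.start
            )
            if _chainable(prev, cur, intervening, config):
                chain.append(cur)
            else:
                if len(chain) >= 2:
                    clusters.append(_finish(chrom, chain))
                chain = [cur]
        if len(chain) >= 2:
            clusters.append(_finish(chrom, chain))
    return clusters


def _finish(chrom: str, chain: list[GeneLocus]) -> PhysicalCluster:
    return PhysicalCluster(
        chromosome=chrom,
        members=tuple(l.gene_id for l in chain),
        start=chain[0].start,
        end=max(l.end for l in chain),
    )


def cluster_composition(clusters: list[PhysicalCluster],
                        subgroup_of: dict[str, str],
                        mapped_nlr_ids: set[str]) -> tuple[list[PhysicalCluster], dict]:
    """Annotate clusters with subgroup composition and summarize the genome.

    A cluster is *homogeneous* when all members share one subgroup (members
    without an assignment count under ``none-grouping``).  The summary
    reports cluster counts, clustered-gene counts, the clustered fraction of
    mapped NLRs, and the per-subgroup clustered fraction.
    """
    from .classify import NONE_GROUP

    annotated: list[PhysicalCluster] = []
    for cl in clusters:
        subs = [subgroup_of.get(g, NONE_GROUP) for g in cl.members]
        uniq: dict[str, int] = {}
        for s in subs:
            uniq[s] = uniq.get(s, 0) + 1
        dominant = max(sorted(uniq), key=lambda s: uniq[s])
        annotated.append(
            PhysicalCluster(
                chromosome=cl.chromosome, members=cl.members,
                start=cl.start, end=cl.end,
                homogeneous=len(uniq) == 1, dominant_subgroup=dominant,
            )
        )

    clustered_genes = {g for cl in clusters for g in cl.members}
    per_subgroup: dict[str, dict[str, float]] = {}
    for g in mapped_nlr_ids:
        sg = subgroup_of.get(g, NONE_GROUP)
        rec = per_subgroup.setdefault(sg, {"mapped": 0, "clustered": 0})
        rec["mapped"] += 1
        if g in clustered_genes:
            rec["clustered"] += 1
    for rec in per_subgroup.values():
        rec["clustered_fraction"] = (
            rec["clustered"] / rec["mapped"] if rec["mapped"] else 0.0
        )

    summary = {
        "n_clusters": len(clusters),
        "n_homogeneous": sum(1 for cl in annotated if cl.homogeneous),
        "genes_in_clusters": len(clustered_genes),
        "clustered_fraction": (
            len(clustered_genes & mapped_nlr_ids) / len(mapped_nlr_ids)
            if mapped_nlr_ids else 0.0
        ),
        "per_subgroup": per_subgroup,
    }
    return annotated, summary


def chromosome_tally(loci: list[GeneLocus], type_of: dict[str, str],
                     subgroup_of: dict[str, str] | None = None) -> dict:
    """Per-chromosome counts of NLRs by architecture type (and optionally by
    subgroup), plus mapped/unmapped totals.

    ``type_of`` covers every NLR gene; genes present there but absent from
    ``loci`` are counted as unmapped.
    """
    located = {l.gene_id: l for l in loci}
    by_chrom_type: dict[str, dict[str, int]] = {}
    by_chrom_subgroup: dict[str, dict[str, int]] = {}
    mapped = 0
    for gene, tlabel in type_of.items():
        loc = located.get(gene)
        if loc is None:
            continue
        mapped += 1
        row = by_chrom_type.setdefault(loc.chromosome, {})
        row[tlabel] = row.get(tlabel, 0) + 1
        if subgroup_of is not None:
            srow = by_chrom_subgroup.setdefault(loc.chromosome, {})
            sg = subgroup_of.get(gene, "none-grouping")
            srow[sg] = srow.get(sg, 0) + 1
    # zero rows for chromosomes with genes but no NLRs
    for l in loci:
        by_chrom_type.setdefault(l.chromosome, {})
        if subgroup_of is not None:
            by_chrom_subgroup.setdefault(l.chromosome, {})
    total = len(type_of)
    return {
        "by_chromosome_type": by_chrom_type,
        "by_chromosome_subgroup": by_chrom_subgroup if subgroup_of is not None else None,
        "total": total,
        "mapped": mapped,
        "unmapped": total - mapped,
        "mapped_percentage": round(100.0 * mapped / total, 1) if total else None,
    }


def clusters_to_bed(clusters: list[PhysicalCluster]) -> str:
    """BED (0-based half-open) text for the called clusters."""
    lines = []
    for k, cl in enumerate(clusters, 1):
        lines.append(
            f"{cl.chromosome}\t{cl.start - 1}\t{cl.end}\tcluster_{k}\t{len(cl)}\t."
        )
    return "\n".join(lines) + ("\n" if lines else "")
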