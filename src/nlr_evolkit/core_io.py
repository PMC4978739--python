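"""Domain types, standard-format readers/writers and run configuration.

Every downstream stage of the pipeline consumes only the types defined here
(:class:`ProteinRecord`, :class:`CdsRecord`, :class:`GeneLocus`,
:class:`RunConfig`); no stage re-reads files from disk.

Coordinates follow GFF3 conventions internally: 1-based, inclusive on both
ends.  Exports to BED convert to 0-based half-open.
"""

from __future__ import annotations

import logging
import tomllib
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX*")
NT_ALPHABET = set("ACGTN")


class ParseError(ValueError):
    """Raised for malformed FASTA/GFF input, naming the offending record."""


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence from an annotated gene set (20 letters + X)."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ParseError("protein record with empty id")
        if not self.sequence:
            raise ParseError(f"protein record {self.id!r} has an empty sequence")
        bad = set(self.sequence.upper()) - AA_ALPHABET
        if bad:
            raise ParseError(
                f"protein record {self.id!r} contains non-amino-acid characters: "
                f"{sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class CdsRecord:
    """A coding sequence paired (by id) with a :class:`ProteinRecord`."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ParseError("CDS record with empty id")
        if not self.sequence:
            raise ParseError(f"CDS record {self.id!r} has an empty sequence")
        bad = set(self.sequence.upper()) - NT_ALPHABET
        if bad:
            raise ParseError(
                f"CDS record {self.id!r} contains non-nucleotide characters: "
                f"{sorted(bad)}"
            )
        if len(self.sequence) % 3 != 0:
            raise ParseError(f"CDS record {self.id!r} length not divisible by 3")

    def __len__(self) -> int:
        return len(self.sequence)

    def translate(self) -> str:
        """Standard-code translation with a trailing stop removed."""
        aa = str(Seq(self.sequence).translate())
        return aa[:-1] if aa.endswith("*") else aa


@dataclass(frozen=True)
class GeneLocus:
    """A gene's physical position: chromosome, 1-based inclusive span, strand."""

    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str = "+"
    is_nlr: bool = False

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ParseError(
                f"gene {self.gene_id!r}: start {self.start} > end {self.end}"
            )
        if self.start < 1:
            raise ParseError(f"gene {self.gene_id!r}: start {self.start} < 1")
        if self.strand not in {"+", "-", "."}:
            raise ParseError(f"gene {self.gene_id!r}: bad strand {self.strand!r}")

    def to_bed_interval(self) -> tuple[str, int, int]:
        """(chrom, start, end) as 0-based half-open for BED export."""
        return (self.chromosome, self.start - 1, self.end)


#: Constants of the analysis, with defaults set to the values the method
#: prescribes (coiled-coil probability cutoff, full-type motif minima,
#: physical-cluster gap rules, MCL inflation, bootstrap depth, Ks filters and
#: the Ks↔time calibration point).
@dataclass(frozen=True)
class RunConfig:
    coils_threshold: float = 0.9        # coiled-coil present iff P >= this
    nb_min_len: int = 160               # aa; minimum intact NB-domain span
    major_min: int = 3                  # of P-loop/kinase-2/GLPL/MHDV
    minor_min: int = 3                  # of RNBS-A/B/C/D
    cluster_max_gap: int = 200_000      # bp; adjacent NLRs must be < this apart
    cluster_max_intervening: int = 8    # fewer than this many genes between
    mcl_inflation: float = 1.5
    sim_evalue_like_cutoff: float = 0.20  # normalized SW score cutoff (stands in for 1e-10)
    min_match_frac: float = 0.5
    bootstrap_reps: int = 500
    collapse_support: float = 0.5       # collapse branches below this support
    subgroup_support: float = 0.7       # seed subgroup clades need > this
    ks_max: float = 2.0                 # Ks above this is saturation; discarded
    speciation_ks: float = 0.3          # pepper vs tomato/potato divergence
    speciation_mya: float = 19.1        # million years for speciation_ks
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for f in fields(self):
            if f.name == "rng_seed":
                continue
            v = getattr(self, f.name)
            if v <= 0:
                raise ValueError(f"config field {f.name} must be positive, got {v}")
        if not self.speciation_ks < self.ks_max:
            raise ValueError("speciation_ks must be below ks_max")

    @property
    def ks_rate_per_year(self) -> float:
        """Synonymous substitution rate r such that Ks/(2r) maps speciation_ks
        to speciation_mya."""
        return self.speciation_ks / (2.0 * self.speciation_mya * 1e6)


def read_fasta(path: str | Path, kind: str = "protein") -> list[ProteinRecord] | list[CdsRecord]:
    """Read a FASTA file into protein or CDS records, preserving file order.

    Parameters
    ----------
    path : file path
    kind : ``"protein"`` or ``"cds"``

    Raises
    ------
    ParseError
        On duplicate ids, empty sequences, or alphabet violations — the
        message names the offending record.
    """
    cls = {"protein": ProteinRecord, "cds": CdsRecord}.get(kind)
    if cls is None:
        raise ValueError(f"kind must be 'protein' or 'cds', got {kind!r}")
    records: list = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ParseError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(cls(id=rec.id, sequence=str(rec.seq).upper()))
    return records


def write_fasta(records: Iterable[ProteinRecord | CdsRecord], path: str | Path,
                width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i:i + width] + "\n")


def _gff_attributes(text: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for part in text.strip().split(";"):
        part = part.strip()
        if not part or "=" not in part:
            continue
        k, v = part.split("=", 1)
        out[k] = v
    return out


def read_gene_loci(path: str | Path) -> list[GeneLocus]:
    """Read ``gene`` features from a GFF3 file as :class:`GeneLocus` records.

    Non-gene features are ignored; a file with no gene features returns an
    empty list with a logged warning.  Coordinates are kept 1-based inclusive
    as in GFF3.
    """
    loci: list[GeneLocus] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ParseError(f"{path}:{lineno}: expected 9 GFF columns, got {len(cols)}")
            chrom, _source, ftype, start, end, _score, strand, _phase, attrs = cols
            if ftype != "gene":
                continue
            attributes = _gff_attributes(attrs)
            gene_id = attributes.get("ID")
            if gene_id is None:
                raise ParseError(f"{path}:{lineno}: gene feature without an ID attribute")
            loci.append(
                GeneLocus(
                    gene_id=gene_id,
                    chromosome=chrom,
                    start=int(start),
                    end=int(end),
                    strand=strand if strand in {"+", "-"} else ".",
                    is_nlr=attributes.get("is_nlr", "").lower() in {"1", "true", "yes"},
                )
            )
    if not loci:
        logger.warning("no gene features found in %s", path)
    return loci


def write_gene_loci(loci: Iterable[GeneLocus], path: str | Path,
                    source: str = "nlr-evolkit") -> None:
    """Write loci back out as minimal GFF3 gene lines (round-trip partner of
    :func:`read_gene_loci`)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for loc in loci:
            attrs = f"ID={loc.gene_id}"
            if loc.is_nlr:
                attrs += ";is_nlr=1"
            fh.write(
                f"{loc.chromosome}\t{source}\tgene\t{loc.start}\t{loc.end}\t.\t"
                f"{loc.strand}\t.\t{attrs}\n"
            )


def loci_by_chromosome(loci: Sequence[GeneLocus]) -> dict[str, list[GeneLocus]]:
    """Group loci per chromosome, sorted by start coordinate."""
    out: dict[str, list[GeneLocus]] = {}
    for loc in loci:
        out.setdefault(loc.chromosome, []).append(loc)
    for chrom in out:
        out[chrom].sort(key=lambda l: (l.start, l.end, l.gene_id))
    return out


def pair_protein_cds(proteins: Sequence[ProteinRecord],
                     cds: Sequence[CdsRecord]) -> list[tuple[ProteinRecord, CdsRecord]]:
    """Pair proteins with CDS by identical id.

    Translation mismatches (beyond X/N ambiguity) are logged as warnings, not
    errors: real annotation sets contain edge cases.  Proteins without a CDS
    are silently omitted from the pairing (callers that require CDS raise
    their own stage errors).
    """
    cds_by_id = {c.id: c for c in cds}
    pairs: list[tuple[ProteinRecord, CdsRecord]] = []
    for prot in proteins:
        c = cds_by_id.get(prot.id)
        if c is None:
            continue
        trans = c.translate()
        if len(trans) != len(prot.sequence):
            logger.warning("CDS/protein length mismatch for %s", prot.id)
        else:
            mism = sum(
                1 for a, b in zip(trans, prot.sequence)
                if a != b and a != "X" and b != "X"
            )
            if mism:
                logger.warning(
                    "CDS translation of %s differs from protein at %d sites", prot.id, mism
                )
        pairs.append((prot, c))
    return pairs


_CONFIG_FIELDS = {f.name for f in fields(RunConfig)}


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Load a :class:`RunConfig`, optionally from a TOML file plus keyword
    overrides.  Unknown keys raise an error listing the valid ones; applied
    overrides are logged."""
    values: dict = {}
    if path is not None:
        with open(path, "rb") as fh:
            values.update(tomllib.load(fh))
    values.update(overrides)
    unknown = set(values) - _CONFIG_FIELDS
    if unknown:
        raise ValueError(
            f"unknown config keys {sorted(unknown)}; valid keys: {sorted(_CONFIG_FIELDS)}"
        )
    cfg = RunConfig(**values)
    for k, v in values.items():
        default = getattr(RunConfig(), k)
        if v != default:
            logger.info("config override: %s = %r (default %r)", k, v, default)
    return cfg
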