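"""Reading and writing the standard annotation formats.

Coordinate conventions: everything in memory is 0-based half-open on the
forward strand; GFF3 on disk is 1-based inclusive.  Segments are stored in
ascending coordinate order for both strands; strand is applied only when a
spliced CDS sequence is extracted.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

VALID_ALPHABET = frozenset("ACGTN")

DOMAIN_VOCABULARY = frozenset(
    {"CC", "TIR", "NBS", "LRR", "STK", "TM", "MLO", "OTHER"}
)
HIT_DATABASES = frozenset(
    {
        "refseq_plant",
        "mrna",
        "archaea",
        "bacteria",
        "eukaryote",
        "viridiplantae",
        "fungi",
        "metazoa",
    }
)
TAXONOMY_TAGS = frozenset({"plant_nuclear", "bacterial", "plastid", "none"})


@dataclass(frozen=True)
class GenomeSequence:
    """One genomic scaffold: an identifier plus an A/C/G/T/N string."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if len(self.seq) < 1:
            raise ValueError(f"scaffold {self.id!r}: empty sequence")
        bad = set(self.seq) - VALID_ALPHABET
        if bad:
            offset = next(
                i for i, c in enumerate(self.seq) if c in bad
            )
            raise ValueError(
                f"scaffold {self.id!r}: illegal character "
                f"{self.seq[offset]!r} at position {offset}"
            )


@dataclass(frozen=True)
class GeneModel:
    """One predicted gene: ordered CDS segments on a scaffold strand.

    ``segments`` are 0-based half-open forward-strand intervals, sorted
    ascending and pairwise non-overlapping regardless of strand.
    ``origin`` (optional) records provenance to a simulated true locus and
    does not take part in equality.
    """

    id: str
    source: str
    scaffold: str
    strand: str
    segments: tuple[tuple[int, int], ...]
    origin: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"model {self.id!r}: unknown strand {self.strand!r}")
        segs = tuple((int(s), int(e)) for s, e in self.segments)
        if not segs:
            raise ValueError(f"model {self.id!r}: no CDS segments")
        for s, e in segs:
            if e <= s:
                raise ValueError(
                    f"model {self.id!r}: segment [{s},{e}) has end <= start"
                )
        for (_, e0), (s1, _) in zip(segs, segs[1:]):
            if s1 < e0:
                raise ValueError(f"model {self.id!r}: overlapping CDS segments")
        object.__setattr__(self, "segments", segs)

    @property
    def span(self) -> tuple[int, int]:
        """Genomic extent [min start, max end)."""
        return self.segments[0][0], self.segments[-1][1]

    @property
    def span_length(self) -> int:
        s, e = self.span
        return e - s

    @property
    def exon_count(self) -> int:
        return len(self.segments)

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.segments)


@dataclass(frozen=True)
class HomologyHit:
    """One homology-evidence row (tabular BLAST-style)."""

    query: str
    subject: str
    description: str
    database: str
    e_value: float
    bit_score: float
    pct_identity: float
    query_cov: float
    subject_cov: float

    def __post_init__(self) -> None:
        if self.database not in HIT_DATABASES:
            raise ValueError(f"unknown hit database tag {self.database!r}")
        if self.e_value < 0:
            raise ValueError(f"hit {self.query}->{self.subject}: negative E-value")
        for name in ("pct_identity", "query_cov", "subject_cov"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ValueError(
                    f"hit {self.query}->{self.subject}: {name}={v} out of [0,100]"
                )


@dataclass(frozen=True)
class DomainHit:
    gene: str
    domain: str

    def __post_init__(self) -> None:
        if self.domain not in DOMAIN_VOCABULARY:
            raise ValueError(f"unknown domain label {self.domain!r}")


@dataclass(frozen=True)
class TMRecord:
    gene: str
    tm_helices: int

    def __post_init__(self) -> None:
        if self.tm_helices < 0:
            raise ValueError(f"gene {self.gene!r}: negative TM helix count")


@dataclass(frozen=True)
class ScaffoldTaxonomy:
    """Best-hit taxonomy of a scaffold plus three support flags.

    The flags record support from a sister genome, from transcriptome data,
    and from a newer assembly build, in that order.
    """

    scaffold: str
    best_hit: str
    support: tuple[bool, bool, bool]

    def __post_init__(self) -> None:
        if self.best_hit not in TAXONOMY_TAGS:
            raise ValueError(f"unknown taxonomy tag {self.best_hit!r}")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | os.PathLike) -> list[GenomeSequence]:
    """Read a genome FASTA into validated scaffold records.

    Lower-case bases are folded to upper case; any character outside
    {A,C,G,T,N} raises a ``ValueError`` naming the record and offset.
    """
    records = [
        GenomeSequence(rec.id, str(rec.seq).upper())
        for rec in SeqIO.parse(os.fspath(path), "fasta")
    ]
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def write_fasta(genome: Sequence[GenomeSequence], path: str | os.PathLike,
                width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in genome:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3


def read_gff3(path: str | os.PathLike, source_label: str | None = None
              ) -> list[GeneModel]:
    """Read gene models from GFF3 (gene/mRNA/CDS rows).

    One :class:`GeneModel` is produced per mRNA carrying at least one CDS
    child.  Coordinates convert from 1-based inclusive to 0-based half-open.
    ``source_label`` overrides the GFF3 source column as the model's
    prediction-set label.
    """
    try:
        db = gffutils.create_db(
            os.fspath(path),
            dbfn=":memory:",
            keep_order=True,
            merge_strategy="create_unique",
        )
    except gffutils.exceptions.EmptyInputError:
        return []  # header-only file: a valid, empty model set
    for cds in db.features_of_type("CDS"):
        if "Parent" not in cds.attributes:
            raise ValueError(f"{path}: CDS at {cds.seqid}:{cds.start} has no Parent")

    models: list[GeneModel] = []
    for mrna in db.features_of_type("mRNA"):
        segments = []
        strand = mrna.strand
        for cds in db.children(mrna, featuretype="CDS", order_by="start"):
            if cds.end < cds.start:
                raise ValueError(
                    f"{path}: CDS {cds.seqid}:{cds.start}-{cds.end} has end < start"
                )
            if cds.strand not in ("+", "-"):
                raise ValueError(
                    f"{path}: CDS of {mrna.id} has unknown strand {cds.strand!r}"
                )
            segments.append((cds.start - 1, cds.end))
        if not segments:
            continue
        if strand not in ("+", "-"):
            raise ValueError(f"{path}: mRNA {mrna.id} has unknown strand {strand!r}")
        models.append(
            GeneModel(
                id=mrna.id,
                source=source_label if source_label is not None else mrna.source,
                scaffold=mrna.seqid,
                strand=strand,
                segments=tuple(sorted(segments)),
            )
        )
    return models


def _cds_phases(model: GeneModel) -> list[int]:
    # phase accumulates in translation order: ascending on +, descending on -
    order = (
        range(len(model.segments))
        if model.strand == "+"
        else range(len(model.segments) - 1, -1, -1)
    )
    phases = [0] * len(model.segments)
    acc = 0
    for i in order:
        phases[i] = (3 - acc % 3) % 3
        acc += model.segments[i][1] - model.segments[i][0]
    return phases


def write_gff3(
    models: Iterable[GeneModel],
    path: str | os.PathLike,
    locus_of: Mapping[str, str] | None = None,
    representatives: frozenset | set | None = None,
) -> None:
    """Write gene models as GFF3 gene/mRNA/CDS rows (1-based inclusive).

    ``locus_of`` maps model id -> locus id (emitted as a ``locus_id``
    attribute); ``representatives`` is the set of model ids flagged
    ``representative=true``.  Output is deterministic for a given input.
    """
    locus_of = locus_of or {}
    representatives = representatives or set()
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            start1, end1 = m.span[0] + 1, m.span[1]
            attrs = [f"ID={m.id}"]
            if m.id in locus_of:
                attrs.append(f"locus_id={locus_of[m.id]}")
            if m.id in representatives:
                attrs.append("representative=true")
            fh.write(
                f"{m.scaffold}\t{m.source}\tgene\t{start1}\t{end1}\t.\t"
                f"{m.strand}\t.\tID={m.id}.gene\n"
            )
            fh.write(
                f"{m.scaffold}\t{m.source}\tmRNA\t{start1}\t{end1}\t.\t"
                f"{m.strand}\t.\t{';'.join(attrs)};Parent={m.id}.gene\n"
            )
            for (s, e), phase in zip(m.segments, _cds_phases(m)):
                fh.write(
                    f"{m.scaffold}\t{m.source}\tCDS\t{s + 1}\t{e}\t.\t"
                    f"{m.strand}\t{phase}\tParent={m.id}\n"
                )


# ---------------------------------------------------------------------------
# CDS extraction


def extract_cds(genome: Mapping[str, GenomeSequence] | Sequence[GenomeSequence],
                model: GeneModel) -> str:
    """Spliced CDS of ``model``: segments concatenated in ascending order,
    reverse-complemented for the minus strand."""
    if not isinstance(genome, Mapping):
        genome = {g.id: g for g in genome}
    if model.scaffold not in genome:
        raise KeyError(f"model {model.id!r}: scaffold {model.scaffold!r} not in genome")
    seq = genome[model.scaffold].seq
    for s, e in model.segments:
        if s < 0 or e > len(seq):
            raise ValueError(
                f"model {model.id!r}: segment [{s},{e}) outside scaffold "
                f"{model.scaffold!r} of length {len(seq)}"
            )
    cds = "".join(seq[s:e] for s, e in model.segments)
    if model.strand == "-":
        cds = str(Seq(cds).reverse_complement())
    return cds


# ---------------------------------------------------------------------------
# Evidence tables

HITS_COLUMNS = [
    "query", "subject", "description", "database",
    "e_value", "bit_score", "pct_identity", "query_cov", "subject_cov",
]
DOMAINS_COLUMNS = ["gene", "domain"]
TM_COLUMNS = ["gene", "tm_helices"]
TAXONOMY_COLUMNS = [
    "scaffold", "best_hit",
    "support_sister_genome", "support_transcriptome", "support_newer_build",
]

_BOOL_MAP = {"true": True, "false": False, "1": True, "0": False,
             "t": True, "f": False}


def _read_tsv(path: str | os.PathLike, columns: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    return df


def read_hits_table(path: str | os.PathLike) -> list[HomologyHit]:
    df = _read_tsv(path, HITS_COLUMNS)
    hits: list[HomologyHit] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            numeric = {
                name: float(getattr(row, name))
                for name in ("e_value", "bit_score", "pct_identity",
                             "query_cov", "subject_cov")
            }
        except ValueError as exc:
            # a non-numeric numeric field is a file-format error, not a bad row
            raise ValueError(f"{path}: row {i}: {exc}") from exc
        try:
            hits.append(
                HomologyHit(
                    query=row.query,
                    subject=row.subject,
                    description=row.description,
                    database=row.database,
                    **numeric,
                )
            )
        except ValueError as exc:
            logger.warning("%s: row %d rejected: %s", path, i, exc)
    return hits


def read_domains_table(path: str | os.PathLike) -> list[DomainHit]:
    df = _read_tsv(path, DOMAINS_COLUMNS)
    out: list[DomainHit] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        label = row.domain
        if label not in DOMAIN_VOCABULARY:
            logger.warning(
                "%s: row %d: unknown domain label %r mapped to OTHER", path, i, label
            )
            label = "OTHER"
        out.append(DomainHit(gene=row.gene, domain=label))
    return out


def read_tm_table(path: str | os.PathLike) -> list[TMRecord]:
    df = _read_tsv(path, TM_COLUMNS)
    out: list[TMRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            out.append(TMRecord(gene=row.gene, tm_helices=int(row.tm_helices)))
        except ValueError as exc:
            raise ValueError(f"{path}: row {i}: bad TM helix count") from exc
    return out


def read_taxonomy_table(path: str | os.PathLike) -> list[ScaffoldTaxonomy]:
    df = _read_tsv(path, TAXONOMY_COLUMNS)
    out: list[ScaffoldTaxonomy] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            support = tuple(
                _BOOL_MAP[str(v).strip().lower()]
                for v in (
                    row.support_sister_genome,
                    row.support_transcriptome,
                    row.support_newer_build,
                )
            )
        except KeyError as exc:
            raise ValueError(f"{path}: row {i}: bad boolean flag") from exc
        out.append(
            ScaffoldTaxonomy(scaffold=row.scaffold, best_hit=row.best_hit,
                             support=support)
        )
    return out


def read_evidence_tables(
    hits_path: str | os.PathLike,
    domains_path: str | os.PathLike,
    tm_path: str | os.PathLike,
    taxonomy_path: str | os.PathLike,
) -> tuple[list[HomologyHit], list[DomainHit], list[TMRecord], list[ScaffoldTaxonomy]]:
    """Read all four evidence TSVs (see README for the column dialects)."""
    return (
        read_hits_table(hits_path),
        read_domains_table(domains_path),
        read_tm_table(tm_path),
        read_taxonomy_table(taxonomy_path),
    )
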