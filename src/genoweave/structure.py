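"""Exon statistics, intronless-gene detection and taxonomic sharing.

An intronless gene (IG) is a mono-exonic model whose CDS is a complete open
reading frame: it starts with ATG, ends with a stop codon, is a multiple of
three long and contains no internal in-frame stop.  IG are then classified
by which domains of life (archaea, bacteria, eukaryotes) and which
eukaryotic groups (green plants, fungi, animals) carry a homolog at a BLAST
E-value cutoff, reproducing the Venn-style sharing categories used in
comparative analyses of intronless gene content.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

from .io import GeneModel, GenomeSequence, HomologyHit, extract_cds

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
KINGDOM_TAGS = frozenset({"archaea", "bacteria", "eukaryote"})
EUKARYOTE_GROUP_TAGS = frozenset({"viridiplantae", "fungi", "metazoa"})


@dataclass(frozen=True)
class StructureSummary:
    exon_count_histogram: dict[int, int]
    mean_exons: float
    mean_cds_length: float
    fraction_intronless: float


@dataclass(frozen=True)
class SharingRecord:
    gene: str
    kingdoms_hit: frozenset[str]
    eukaryote_groups_hit: frozenset[str]
    category: str


def exon_stats(models: Sequence[GeneModel]) -> StructureSummary:
    """Exon-count histogram, mean exon count/CDS length, mono-exonic fraction."""
    if not models:
        raise ValueError("no models")
    hist = Counter(m.exon_count for m in models)
    n = len(models)
    return StructureSummary(
        exon_count_histogram=dict(sorted(hist.items())),
        mean_exons=sum(m.exon_count for m in models) / n,
        mean_cds_length=sum(m.cds_length for m in models) / n,
        fraction_intronless=hist.get(1, 0) / n,
    )


def is_full_orf(cds: str) -> bool:
    """Start codon, terminal stop, frame-complete, no internal in-frame stop."""
    if len(cds) < 6 or len(cds) % 3:
        return False
    if not cds.startswith("ATG") or cds[-3:] not in STOP_CODONS:
        return False
    return all(
        cds[i : i + 3] not in STOP_CODONS for i in range(3, len(cds) - 3, 3)
    )


def find_intronless(
    models: Sequence[GeneModel],
    genome: Mapping[str, GenomeSequence] | Sequence[GenomeSequence],
) -> list[str]:
    """Ids of mono-exonic models whose CDS is a full-length ORF."""
    if not isinstance(genome, Mapping):
        genome = {g.id: g for g in genome}
    return [
        m.id
        for m in models
        if m.exon_count == 1 and is_full_orf(extract_cds(genome, m))
    ]


def _category(kingdoms: frozenset[str], groups: frozenset[str]) -> str:
    if not kingdoms:
        return "ORFan"
    if kingdoms == KINGDOM_TAGS:
        return "all-three-domains"
    if kingdoms == {"eukaryote", "bacteria"}:
        return "eukaryote-bacteria"
    if kingdoms == {"eukaryote", "archaea"}:
        return "eukaryote-archaea"
    if kingdoms == {"eukaryote"}:
        if groups == EUKARYOTE_GROUP_TAGS:
            return "eukaryote-all-groups"
        if groups == {"viridiplantae"}:
            return "viridiplantae-only"
        if not groups:
            return "eukaryote-other"
        return "eukaryote-" + "-".join(sorted(groups))
    # prokaryote-only combinations (possible on synthetic input)
    return "-".join(sorted(kingdoms)) + "-only"


def classify_kingdom_sharing(
    ig_ids: Sequence[str],
    hits: Sequence[HomologyHit],
    e_cutoff: float = 1e-5,
) -> list[SharingRecord]:
    """Assign each intronless gene a taxonomic-sharing category.

    A kingdom or eukaryotic group counts as hit when at least one homology
    hit in its database is at or below ``e_cutoff``; group hits imply a hit
    in the eukaryote domain.  Genes with no qualifying hit are ORFans.  The
    categories partition the input set.
    """
    kingdoms: dict[str, set[str]] = {g: set() for g in ig_ids}
    groups: dict[str, set[str]] = {g: set() for g in ig_ids}
    for h in hits:
        if h.query not in kingdoms or h.e_value > e_cutoff:
            continue
        if h.database in KINGDOM_TAGS:
            kingdoms[h.query].add(h.database)
        elif h.database in EUKARYOTE_GROUP_TAGS:
            kingdoms[h.query].add("eukaryote")
            groups[h.query].add(h.database)
    return [
        SharingRecord(
            gene=g,
            kingdoms_hit=frozenset(kingdoms[g]),
            eukaryote_groups_hit=frozenset(groups[g]),
            category=_category(frozenset(kingdoms[g]), frozenset(groups[g])),
        )
        for g in ig_ids
    ]


def ortholog_intronless_fraction(
    ig_ids: Sequence[str],
    ortholog_table: Mapping[str, Sequence[tuple[str, str, int]]],
    denominator: str = "with-orthologs",
) -> tuple[float | None, dict[str, bool]]:
    """Fraction of IG whose orthologs are themselves intronless.

    ``ortholog_table`` maps gene id -> [(species, ortholog id, exon_count)].
    A gene is flagged when at least one ortholog is mono-exonic.  The
    denominator is IG with at least one ortholog (default) or all IG
    (``denominator='all'``).  Returns (fraction or None when undefined,
    per-gene flags for genes with orthologs).
    """
    if denominator not in ("with-orthologs", "all"):
        raise ValueError("denominator must be 'with-orthologs' or 'all'")
    flags: dict[str, bool] = {}
    for g in ig_ids:
        orthos = ortholog_table.get(g, ())
        if orthos:
            flags[g] = any(exons == 1 for _, _, exons in orthos)
    denom = len(flags) if denominator == "with-orthologs" else len(ig_ids)
    if denom == 0:
        return None, flags
    return sum(flags.values()) / denom, flags
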