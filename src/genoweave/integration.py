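"""Merging gene-prediction sets into consensus loci.

Two (or more) prediction sets are combined by single-linkage clustering of
same-strand gene models: two models overlap when the shared genomic extent
exceeds a threshold fraction of the shorter model's extent, and a locus is
a connected component of that overlap graph.  The threshold is chosen by
sweeping 60-95% in 5% steps and locating the knee where the ratio of
single-model to multi-model loci starts climbing fastest.  Evidence filters
(RefSeq + transcriptome support), representative selection by lowest
E-value, and contaminant-scaffold removal complete the workflow.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from .io import GeneModel, HomologyHit, ScaffoldTaxonomy

DEFAULT_THRESHOLDS = tuple(round(0.60 + 0.05 * i, 2) for i in range(8))
BLACKLIST_WORDS = ("predicted", "putative", "hypothetical", "unnamed",
                   "uncharacterized")
REPRESENTATIVE_EVALUE_CUTOFF = 1e-10


@dataclass
class Locus:
    """A single-linkage cluster of gene models on one scaffold and strand."""

    id: str
    scaffold: str
    strand: str
    members: list[str]
    representative: str | None = None
    annotation: tuple[str, str, float] | None = None  # (subject, description, E)
    span: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("a locus needs at least one member")
        if self.representative is not None and self.representative not in self.members:
            raise ValueError(
                f"locus {self.id}: representative {self.representative!r} "
                "is not a member"
            )


@dataclass(frozen=True)
class SweepRow:
    threshold: float
    n_loci: int
    n_single_model_loci: int
    n_multi_model_loci: int
    single_to_multi_ratio: float | None  # None when no multi-model locus exists


def overlap_fraction(a: GeneModel, b: GeneModel, mode: str = "span") -> float:
    """Shared extent as a fraction of the shorter model's extent.

    Models on different scaffolds or strands never overlap.  The default
    ``span`` mode compares genomic extents (introns included); ``exon``
    mode compares summed exon intersection against the shorter CDS.
    """
    if mode not in ("span", "exon"):
        raise ValueError("mode must be 'span' or 'exon'")
    if a.scaffold != b.scaffold or a.strand != b.strand:
        return 0.0
    if mode == "span":
        (s1, e1), (s2, e2) = a.span, b.span
        shared = min(e1, e2) - max(s1, s2)
        shorter = min(e1 - s1, e2 - s2)
    else:
        shared = sum(
            max(0, min(e1, e2) - max(s1, s2))
            for s1, e1 in a.segments
            for s2, e2 in b.segments
        )
        shorter = min(a.cds_length, b.cds_length)
    if shorter <= 0:
        raise ValueError("zero-length gene span")
    return max(0, shared) / shorter


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def cluster_loci(
    models: Sequence[GeneModel],
    threshold: float,
    min_orf_nt: int = 300,
    overlap_mode: str = "span",
) -> list[Locus]:
    """Partition models into single-linkage loci at an overlap threshold.

    Models with a CDS shorter than ``min_orf_nt`` are excluded first.  The
    remaining models, per scaffold and strand, form the connected components
    of the graph with an edge wherever ``overlap_fraction >= threshold``.
    Locus ids are deterministic in (scaffold, strand, leftmost start).
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0,1]")
    kept = [m for m in models if m.cds_length >= min_orf_nt]
    groups: dict[tuple[str, str], list[GeneModel]] = {}
    for m in kept:
        groups.setdefault((m.scaffold, m.strand), []).append(m)

    loci: list[Locus] = []
    for (scaffold, strand), group in groups.items():
        group = sorted(group, key=lambda m: (m.span, m.id))
        uf = _UnionFind(len(group))
        # sweep: only span-overlapping pairs can clear any positive threshold
        active: list[int] = []
        for j, m in enumerate(group):
            start = m.span[0]
            active = [i for i in active if group[i].span[1] > start]
            for i in active:
                if overlap_fraction(group[i], m, mode=overlap_mode) >= threshold:
                    uf.union(i, j)
            active.append(j)
        comps: dict[int, list[GeneModel]] = {}
        for j, m in enumerate(group):
            comps.setdefault(uf.find(j), []).append(m)
        for members in comps.values():
            leftmost = min(m.span[0] for m in members)
            rightmost = max(m.span[1] for m in members)
            strand_tag = "p" if strand == "+" else "m"
            loci.append(
                Locus(
                    id=f"locus-{scaffold}-{strand_tag}-{leftmost}",
                    scaffold=scaffold,
                    strand=strand,
                    members=sorted(m.id for m in members),
                    span=(leftmost, rightmost),
                )
            )
    loci.sort(key=lambda loc: (loc.scaffold, loc.strand, loc.span[0], loc.id))
    return loci


def sweep_and_select(
    models: Sequence[GeneModel],
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    min_orf_nt: int = 300,
    overlap_mode: str = "span",
) -> tuple[list[SweepRow], float | None]:
    """Cluster at each threshold and pick the knee of the single:multi ratio.

    The selected threshold is the one just before the largest forward
    difference of the single-to-multi-model locus ratio (ties toward the
    smaller threshold).  Differences are taken only between consecutive
    finite ratios; if no positive finite difference exists the selection is
    undefined and ``None`` is returned.
    """
    thresholds = list(thresholds)
    if len(thresholds) < 3 or any(
        b <= a for a, b in zip(thresholds, thresholds[1:])
    ):
        raise ValueError("need at least 3 strictly increasing thresholds")
    rows: list[SweepRow] = []
    for t in thresholds:
        loci = cluster_loci(models, t, min_orf_nt=min_orf_nt,
                            overlap_mode=overlap_mode)
        n_single = sum(1 for loc in loci if len(loc.members) == 1)
        n_multi = len(loci) - n_single
        ratio = n_single / n_multi if n_multi > 0 else None
        rows.append(SweepRow(threshold=t, n_loci=len(loci),
                             n_single_model_loci=n_single,
                             n_multi_model_loci=n_multi,
                             single_to_multi_ratio=ratio))
    best_i, best_diff = None, 0.0
    for i in range(len(rows) - 1):
        r0, r1 = rows[i].single_to_multi_ratio, rows[i + 1].single_to_multi_ratio
        if r0 is None or r1 is None:
            continue
        diff = r1 - r0
        if diff > best_diff and not math.isclose(diff, best_diff):
            best_i, best_diff = i, diff
    selected = thresholds[best_i] if best_i is not None else None
    return rows, selected


def evidence_filter(
    models: Sequence[GeneModel],
    hits: Sequence[HomologyHit],
    require: str = "both",
) -> list[GeneModel]:
    """Keep models with homology support.

    RefSeq support means one hit with identity >= 50, bit score >= 100 and
    both coverages >= 80; transcriptome support means one mRNA hit with
    identity strictly above 90.  ``require='both'`` (default) demands the
    intersection; ``'either'`` the union.
    """
    if require not in ("both", "either"):
        raise ValueError("require must be 'both' or 'either'")
    refseq_ok: set[str] = set()
    mrna_ok: set[str] = set()
    for h in hits:
        if (h.database == "refseq_plant" and h.pct_identity >= 50
                and h.bit_score >= 100 and h.query_cov >= 80
                and h.subject_cov >= 80):
            refseq_ok.add(h.query)
        elif h.database == "mrna" and h.pct_identity > 90:
            mrna_ok.add(h.query)
    if require == "both":
        passing = refseq_ok & mrna_ok
    else:
        passing = refseq_ok | mrna_ok
    return [m for m in models if m.id in passing]


def _description_blacklisted(description: str) -> bool:
    low = description.lower()
    return any(w in low for w in BLACKLIST_WORDS)


def select_representative(
    locus: Locus, hits: Sequence[HomologyHit]
) -> Locus | None:
    """Pick the locus member whose best RefSeq hit has the lowest E-value.

    Hits above E-value 1e-10 or with an uninformative description word
    ("predicted", "putative", "hypothetical", "unnamed", "uncharacterized")
    are removed first; a locus left with no usable hit is discarded (returns
    ``None``).  Ties break by higher bit score, then lexicographic model id.
    """
    members = set(locus.members)
    usable = [
        h for h in hits
        if h.database == "refseq_plant"
        and h.query in members
        and h.e_value <= REPRESENTATIVE_EVALUE_CUTOFF
        and not _description_blacklisted(h.description)
    ]
    if not usable:
        return None
    best_by_member: dict[str, HomologyHit] = {}
    for h in usable:
        cur = best_by_member.get(h.query)
        if cur is None or (h.e_value, -h.bit_score) < (cur.e_value, -cur.bit_score):
            best_by_member[h.query] = h
    rep = min(
        best_by_member,
        key=lambda g: (best_by_member[g].e_value, -best_by_member[g].bit_score, g),
    )
    h = best_by_member[rep]
    return replace(locus, representative=rep,
                   annotation=(h.subject, h.description, h.e_value))


def filter_contaminant_scaffolds(
    loci: Sequence[Locus], taxonomy: Sequence[ScaffoldTaxonomy]
) -> list[Locus]:
    """Drop loci on contaminant scaffolds.

    A scaffold is contaminant when its best hit is bacterial or plastid AND
    none of the three support levels (sister genome, transcriptome, newer
    build) vouches for it.  Scaffolds absent from the table count as plant
    nuclear.
    """
    tax = {t.scaffold: t for t in taxonomy}
    out = []
    for locus in loci:
        t = tax.get(locus.scaffold)
        if (t is not None and t.best_hit in ("bacterial", "plastid")
                and not any(t.support)):
            continue
        out.append(locus)
    return out


@dataclass
class IntegrationResult:
    loci: list[Locus]
    sweep: list[SweepRow]
    threshold: float
    models: dict[str, GeneModel] = field(default_factory=dict)

    @property
    def representatives(self) -> list[str]:
        return [loc.representative for loc in self.loci
                if loc.representative is not None]


def integrate(
    prediction_sets: Iterable[Sequence[GeneModel]],
    hits: Sequence[HomologyHit],
    taxonomy: Sequence[ScaffoldTaxonomy] = (),
    threshold: float | str = "auto",
    min_orf_nt: int = 300,
    require_evidence: str = "both",
    overlap_mode: str = "span",
) -> IntegrationResult:
    """Full integration workflow over two or more prediction sets.

    Order of operations: evidence filter -> single-linkage clustering (at a
    fixed or knee-selected threshold) -> representative selection (loci with
    no qualifying RefSeq hit are discarded) -> contaminant-scaffold removal.
    """
    models: list[GeneModel] = [m for ms in prediction_sets for m in ms]
    supported = evidence_filter(models, hits, require=require_evidence)
    sweep, selected = sweep_and_select(supported, min_orf_nt=min_orf_nt,
                                       overlap_mode=overlap_mode)
    if threshold == "auto":
        # no detectable knee: fall back to the conventional 85% default
        threshold = selected if selected is not None else 0.85
    loci = cluster_loci(supported, float(threshold), min_orf_nt=min_orf_nt,
                        overlap_mode=overlap_mode)
    kept: list[Locus] = []
    for locus in loci:
        annotated = select_representative(locus, hits)
        if annotated is not None:
            kept.append(annotated)
    kept = filter_contaminant_scaffolds(kept, taxonomy)
    return IntegrationResult(
        loci=kept, sweep=sweep, threshold=float(threshold),
        models={m.id: m for m in supported},
    )
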