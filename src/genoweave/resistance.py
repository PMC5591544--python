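"""Domain-rule classification of candidate resistance (R) genes.

Plant R genes fall into domain-defined classes: CNL (coiled-coil + NBS +
LRR), TNL (TIR + NBS + LRR, absent from monocots), receptor-like kinases
and proteins (RLK: TM + LRR + STK; RLP: TM + LRR without the kinase),
Mlo-like (MLO domain with six or seven transmembrane helices) and plain
kinases (STK only).  A gene must carry ALL the domains of a class to be
assigned to it.  CNL genes additionally form physical clusters: maximal
runs where adjacent CNL genes lie under 200 kb apart with at most eight
non-NBS-LRR genes between them.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

from .io import DomainHit, GeneModel, TMRecord

R_CLASSES = ("CNL", "TNL", "Kinase", "RLP", "RLK", "Mlo-like")
CLUSTER_MAX_DISTANCE_NT = 200_000
CLUSTER_MAX_INTERVENING = 8


@dataclass(frozen=True)
class RGeneRecord:
    gene: str
    domains: frozenset[str]
    tm_helices: int
    r_class: str
    position: tuple[str, tuple[int, int]] | None = None  # (chromosome, span)


@dataclass(frozen=True)
class CnlCluster:
    id: str
    chromosome: str
    member_cnl_genes: tuple[str, ...]
    intervening_non_nbslrr: tuple[int, ...]  # one count per adjacent pair


def _assign_class(domains: frozenset[str], tm_helices: int) -> str:
    # priority resolves multi-rule matches; TIR discriminates TNL from CNL
    if {"TIR", "NBS", "LRR"} <= domains:
        return "TNL"
    if {"CC", "NBS", "LRR"} <= domains:
        return "CNL"
    if {"TM", "LRR", "STK"} <= domains:
        return "RLK"
    if {"TM", "LRR"} <= domains and "STK" not in domains:
        return "RLP"
    if "MLO" in domains and tm_helices in (6, 7):
        return "Mlo-like"
    if "STK" in domains and not domains & {"TM", "LRR", "NBS"}:
        return "Kinase"
    return "unclassified"


def classify_r_genes(
    domain_hits: Sequence[DomainHit],
    tm_records: Sequence[TMRecord],
    models: Mapping[str, GeneModel] | Sequence[GeneModel] | None = None,
) -> list[RGeneRecord]:
    """Classify genes into the six R-gene classes from their domain sets.

    Genes appearing in either evidence table are classified; a gene absent
    from the TM table counts as having zero transmembrane helices.  When
    ``models`` is given, genomic positions are attached for cluster
    detection.  The classifier is a pure function of (domains, tm_helices).
    """
    if models is not None and not isinstance(models, Mapping):
        models = {m.id: m for m in models}
    domains: dict[str, set[str]] = {}
    for d in domain_hits:
        domains.setdefault(d.gene, set()).add(d.domain)
    tm = {t.gene: t.tm_helices for t in tm_records}
    genes = sorted(set(domains) | set(tm))
    records = []
    for g in genes:
        doms = frozenset(domains.get(g, set()))
        helices = tm.get(g, 0)
        pos = None
        if models is not None and g in models:
            m = models[g]
            pos = (m.scaffold, m.span)
        records.append(
            RGeneRecord(gene=g, domains=doms, tm_helices=helices,
                        r_class=_assign_class(doms, helices), position=pos)
        )
    return records


def _is_nbs_lrr(domains: frozenset[str]) -> bool:
    return bool(domains & {"NBS", "LRR"})


def find_cnl_clusters(
    records: Sequence[RGeneRecord],
    all_genes: Sequence[tuple[str, str, int, frozenset[str]]] | None = None,
    max_distance_nt: int = CLUSTER_MAX_DISTANCE_NT,
    max_intervening: int = CLUSTER_MAX_INTERVENING,
    distance_mode: str = "start-start",
) -> list[CnlCluster]:
    """Maximal runs of physically clustered CNL genes.

    Adjacent CNL genes chain when they are under ``max_distance_nt`` apart
    (gene-start to gene-start by default; ``distance_mode='end-start'``
    measures from the upstream gene's end) with at most ``max_intervening``
    non-NBS-LRR genes between them; genes carrying NBS or LRR do not count
    against that budget.  ``all_genes`` lists every positioned gene as
    (gene id, chromosome, start, domain set); when omitted it is derived
    from the records themselves.  Singleton runs are not clusters.
    """
    if distance_mode not in ("start-start", "end-start"):
        raise ValueError("distance_mode must be 'start-start' or 'end-start'")
    positioned = [r for r in records if r.position is not None]
    if all_genes is None:
        all_genes = [
            (r.gene, r.position[0], r.position[1][0], r.domains)
            for r in positioned
        ]
    by_chrom: dict[str, list[tuple[str, int, frozenset[str]]]] = {}
    for gene, chrom, start, doms in all_genes:
        by_chrom.setdefault(chrom, []).append((gene, start, doms))
    cnl = {r.gene: r for r in positioned if r.r_class == "CNL"}
    span_end = {r.gene: r.position[1][1] for r in positioned}

    clusters: list[CnlCluster] = []
    n_clusters = 0
    for chrom in sorted(by_chrom):
        genes = sorted(by_chrom[chrom], key=lambda g: (g[1], g[0]))
        cnl_idx = [i for i, (gid, _, _) in enumerate(genes) if gid in cnl]
        run: list[int] = []
        counts: list[int] = []

        def flush() -> None:
            nonlocal n_clusters
            if len(run) >= 2:
                n_clusters += 1
                clusters.append(
                    CnlCluster(
                        id=f"cnl-cluster-{n_clusters:03d}",
                        chromosome=chrom,
                        member_cnl_genes=tuple(genes[i][0] for i in run),
                        intervening_non_nbslrr=tuple(counts),
                    )
                )
            run.clear()
            counts.clear()

        for i in cnl_idx:
            if run:
                prev = run[-1]
                if distance_mode == "start-start":
                    dist = genes[i][1] - genes[prev][1]
                else:
                    dist = genes[i][1] - span_end[genes[prev][0]]
                between = sum(
                    1
                    for j in range(prev + 1, i)
                    if not _is_nbs_lrr(genes[j][2])
                )
                if dist < max_distance_nt and between <= max_intervening:
                    run.append(i)
                    counts.append(between)
                    continue
                flush()
            run.append(i)
        flush()
    return clusters


def summarize_classes(
    records: Sequence[RGeneRecord],
    total_genes: int | None = None,
    clusters: Sequence[CnlCluster] = (),
):
    """Class-count table plus per-chromosome distribution.

    Returns a pandas DataFrame with one row per class (count and fraction of
    the total gene set) and a dict chromosome -> class -> count.  When
    clusters are supplied the clustered fraction of CNL genes is included.
    """
    import pandas as pd

    counts = Counter(r.r_class for r in records if r.r_class != "unclassified")
    total = total_genes if total_genes is not None else len(records)
    rows = [
        {"r_class": cls, "count": counts.get(cls, 0),
         "fraction": counts.get(cls, 0) / total if total else 0.0}
        for cls in R_CLASSES
    ]
    table = pd.DataFrame(rows)
    by_chrom: dict[str, dict[str, int]] = {}
    for r in records:
        if r.r_class == "unclassified" or r.position is None:
            continue
        by_chrom.setdefault(r.position[0], {}).setdefault(r.r_class, 0)
        by_chrom[r.position[0]][r.r_class] += 1
    n_cnl = counts.get("CNL", 0)
    clustered = {g for c in clusters for g in c.member_cnl_genes}
    table.attrs["clustered_cnl_fraction"] = (
        len(clustered) / n_cnl if n_cnl else 0.0
    )
    return table, by_chrom
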