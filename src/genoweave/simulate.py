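"""Synthetic genomes with planted gene models and mock evidence tables.

The generator emulates, at desk scale, the inputs of a two-pipeline genome
annotation project: a scaffolded genome, two independently predicted gene
sets that disagree at gene boundaries, homology-evidence tables, protein
domain calls and transmembrane-helix counts.  Every quantity downstream
stages estimate (locus count, GC3 and its per-codon gradient, intronless
status, resistance-gene class) is planted with known ground truth.

Determinism: every generator draws from a named sub-stream of the single
config seed, so adding a generator never shifts existing streams.
"""

from __future__ import annotations

import json
import os
import zlib
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .io import (
    DomainHit,
    GeneModel,
    GenomeSequence,
    HomologyHit,
    ScaffoldTaxonomy,
    TMRecord,
    write_fasta,
    write_gff3,
)

STOP_CODONS = ("TAA", "TAG", "TGA")

# domain architecture planted for each resistance-gene class
R_CLASS_DOMAINS: dict[str, frozenset[str]] = {
    "CNL": frozenset({"CC", "NBS", "LRR"}),
    "TNL": frozenset({"TIR", "NBS", "LRR"}),
    "Kinase": frozenset({"STK"}),
    "RLP": frozenset({"TM", "LRR"}),
    "RLK": frozenset({"TM", "LRR", "STK"}),
    "Mlo-like": frozenset({"MLO"}),
}

_BLACKLIST_DESCRIPTIONS = (
    "hypothetical protein",
    "predicted protein",
    "putative uncharacterized protein",
    "unnamed protein product",
    "uncharacterized protein",
)
_CLEAN_DESCRIPTIONS = (
    "serine/threonine-protein kinase TOR",
    "translation activator GCN1",
    "acyl-ACP thioesterase",
    "stearoyl-ACP desaturase",
    "MADS-box transcription factor",
    "leucine-rich repeat receptor kinase",
    "cytochrome P450 monooxygenase",
    "ABC transporter family protein",
)


@dataclass(frozen=True)
class GC3Profile:
    """Per-gene third-position composition target.

    ``mean``/``sd`` describe the per-gene GC3 target distribution (clipped to
    [0,1]); ``slope`` is a linear per-codon gradient added around the gene's
    midpoint, so the gene-wide mean stays at the target.
    """

    mean: float = 0.53
    sd: float = 0.13
    slope: float = 0.0


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    n_scaffolds: int = 10
    scaffold_length: int = 60_000
    background_gc: float = 0.37
    n_loci: int = 100
    exon_count_distribution: tuple[tuple[int, float], ...] = (
        (1, 0.14), (2, 0.16), (3, 0.14), (4, 0.12), (5, 0.11),
        (6, 0.09), (7, 0.08), (8, 0.07), (9, 0.05), (10, 0.04),
    )
    intron_length_range: tuple[int, int] = (50, 400)
    cds_length_range: tuple[int, int] = (300, 2166)
    gc3_profile: GC3Profile = field(default_factory=GC3Profile)
    jitter_sd: float = 10.0
    split_rate: float = 0.02
    drop_rate: float = 0.15
    spurious_rate: float = 0.0
    # evidence-table knobs
    refseq_pass_rate: float = 1.0
    mrna_pass_rate: float = 1.0
    blacklist_rate: float = 0.0
    evalue_decades: tuple[float, float] = (-50.0, -11.0)
    kingdom_mix: tuple[tuple[tuple[str, ...], float], ...] = (
        (("archaea", "bacteria", "eukaryote", "viridiplantae"), 0.15),
        (("bacteria", "eukaryote", "viridiplantae"), 0.20),
        (("archaea", "eukaryote", "viridiplantae"), 0.01),
        (("eukaryote", "viridiplantae", "fungi", "metazoa"), 0.36),
        (("viridiplantae",), 0.23),
        ((), 0.05),
    )
    r_class_proportions: tuple[tuple[str, float], ...] = ()
    contaminant_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.n_scaffolds < 1 or self.scaffold_length < 1 or self.n_loci < 0:
            raise ValueError("counts must be positive")
        if not 0.0 <= self.background_gc <= 1.0:
            raise ValueError("background_gc must be in [0,1]")
        psum = sum(p for _, p in self.exon_count_distribution)
        if abs(psum - 1.0) > 1e-9:
            raise ValueError("exon_count_distribution probabilities must sum to 1")
        if any(k < 1 or p < 0 for k, p in self.exon_count_distribution):
            raise ValueError("exon_count_distribution entries must be valid")
        for name in ("intron_length_range", "cds_length_range"):
            lo, hi = getattr(self, name)
            if lo > hi or lo < 1:
                raise ValueError(f"{name} must be a non-empty positive range")
        for name in ("jitter_sd",):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("split_rate", "drop_rate", "spurious_rate",
                     "refseq_pass_rate", "mrna_pass_rate", "blacklist_rate",
                     "contaminant_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1]")
        ksum = sum(p for _, p in self.kingdom_mix)
        if abs(ksum - 1.0) > 1e-9:
            raise ValueError("kingdom_mix probabilities must sum to 1")
        rsum = sum(p for _, p in self.r_class_proportions)
        if rsum > 1.0 + 1e-9:
            raise ValueError("r_class_proportions must sum to at most 1")
        for name, _ in self.r_class_proportions:
            if name not in R_CLASS_DOMAINS:
                raise ValueError(f"unknown resistance class {name!r}")


@dataclass
class SyntheticTruth:
    """Ground truth for one simulated dataset."""

    true_models: list[GeneModel]
    true_locus_assignment: dict[str, str]
    planted_gc3: dict[str, float]
    planted_r_class: dict[str, str] = field(default_factory=dict)
    planted_slope: float = 0.0


def _rng(config: SimulationConfig, stream: str) -> np.random.Generator:
    """Named sub-stream of the config seed (stable under new generators)."""
    key = zlib.crc32(stream.encode())
    return np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(key,)))


# ---------------------------------------------------------------------------


def generate_genome(config: SimulationConfig) -> list[GenomeSequence]:
    """I.i.d. background sequence at the configured GC content."""
    rng = _rng(config, "genome")
    gc = config.background_gc
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    bases = np.array(list("ACGT"))
    out = []
    for i in range(config.n_scaffolds):
        draw = rng.choice(4, size=config.scaffold_length, p=probs)
        out.append(GenomeSequence(f"scf{i + 1:04d}", "".join(bases[draw])))
    return out


def _sample_cds(rng: np.random.Generator, n_codons: int, target: float,
                slope: float) -> str:
    """A valid ORF of ``n_codons`` codons whose third-position GC follows the
    planted linear profile: ATG, body, one stop, no internal in-frame stop."""
    if n_codons < 2:
        raise ValueError("an ORF needs at least start and stop codons")
    mid = (n_codons + 1) / 2.0
    codons = ["ATG"]
    for k in range(2, n_codons):  # codon indices 2..n-1 (1-based)
        p = float(np.clip(target + slope * (k - mid), 0.0, 1.0))
        if rng.random() < p:
            third = "G" if rng.random() < 0.5 else "C"
        else:
            third = "A" if rng.random() < 0.5 else "T"
        while True:
            first_two = "".join(
                "ACGT"[i] for i in rng.integers(0, 4, size=2)
            )
            if first_two + third not in STOP_CODONS:
                break
        codons.append(first_two + third)
    codons.append(STOP_CODONS[rng.integers(0, 3)])
    return "".join(codons)


def _revcomp(s: str) -> str:
    return s.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def plant_gene_models(
    config: SimulationConfig, genome: Sequence[GenomeSequence]
) -> tuple[list[GenomeSequence], SyntheticTruth]:
    """Write non-overlapping gene loci into the genome; return truth records.

    Each planted gene is a complete ORF whose extracted CDS obeys the planted
    GC3 target and per-codon gradient.  Planted genes never overlap; overlap
    structure between prediction sets comes only from perturbation.
    """
    rng = _rng(config, "genes")
    prof = config.gc3_profile
    ks = np.array([k for k, _ in config.exon_count_distribution])
    ps = np.array([p for _, p in config.exon_count_distribution])

    buffers = {g.id: bytearray(g.seq, "ascii") for g in genome}
    scaffold_ids = [g.id for g in genome]
    cursor = {sid: 0 for sid in scaffold_ids}

    truth = SyntheticTruth(
        true_models=[], true_locus_assignment={}, planted_gc3={},
        planted_slope=prof.slope,
    )

    for i in range(config.n_loci):
        k = int(rng.choice(ks, p=ps))
        lo, hi = config.cds_length_range
        L = int(rng.integers(lo, hi + 1)) // 3 * 3
        L = max(L, max(6, 3 * k))  # room for start+stop and one nt per exon
        n_codons = L // 3
        target = float(np.clip(rng.normal(prof.mean, prof.sd), 0.0, 1.0)) \
            if prof.sd > 0 else float(np.clip(prof.mean, 0.0, 1.0))
        cds = _sample_cds(rng, n_codons, target, prof.slope)
        strand = "+" if rng.random() < 0.5 else "-"

        # split CDS into k exon chunks (each >= 3 nt where possible)
        if k == 1:
            chunk_lens = [L]
        else:
            cuts = sorted(rng.choice(np.arange(1, n_codons), size=k - 1,
                                     replace=False))
            bounds = [0, *cuts, n_codons]
            chunk_lens = [3 * (b - a) for a, b in zip(bounds, bounds[1:])]
        introns = [int(rng.integers(*config.intron_length_range))
                   for _ in range(k - 1)]
        span_len = L + sum(introns)

        # place on the first scaffold with room, with an intergenic gap
        placed = False
        for sid in scaffold_ids:
            gap = int(rng.integers(200, 1000))
            start = cursor[sid] + gap
            if start + span_len <= config.scaffold_length:
                cursor[sid] = start + span_len
                placed = True
                break
        if not placed:
            raise ValueError(
                "insufficient scaffold space for all loci; increase "
                "scaffold_length or n_scaffolds"
            )

        segments = []
        pos = start
        for j, clen in enumerate(chunk_lens):
            segments.append((pos, pos + clen))
            pos += clen + (introns[j] if j < k - 1 else 0)

        # forward-strand text of the segments: the ascending concatenation
        # must extract (after strand handling) to the designed CDS
        text = cds if strand == "+" else _revcomp(cds)
        buf = buffers[sid]
        off = 0
        for s, e in segments:
            buf[s:e] = text[off : off + (e - s)].encode("ascii")
            off += e - s

        gid = f"g{i + 1:05d}"
        model = GeneModel(id=gid, source="truth", scaffold=sid, strand=strand,
                          segments=tuple(segments), origin=f"L{i + 1:05d}")
        truth.true_models.append(model)
        truth.true_locus_assignment[gid] = f"L{i + 1:05d}"
        truth.planted_gc3[gid] = target

    new_genome = [GenomeSequence(sid, buffers[sid].decode("ascii"))
                  for sid in scaffold_ids]
    return new_genome, truth


# ---------------------------------------------------------------------------


def _perturb_model(model: GeneModel, rng: np.random.Generator,
                   config: SimulationConfig, new_id: str, source: str
                   ) -> GeneModel:
    segs = [list(s) for s in model.segments]
    if config.jitter_sd > 0:
        ds = int(round(rng.normal(0.0, config.jitter_sd)))
        de = int(round(rng.normal(0.0, config.jitter_sd)))
        segs[0][0] = max(0, min(segs[0][0] + ds, segs[0][1] - 3))
        last = segs[-1]
        last[1] = min(config.scaffold_length, max(last[1] + de, last[0] + 3))
        if len(segs) > 1:
            segs[0][0] = min(segs[0][0], segs[0][1] - 1)
    return GeneModel(id=new_id, source=source, scaffold=model.scaffold,
                     strand=model.strand,
                     segments=tuple(tuple(s) for s in segs),
                     origin=model.origin)


def emulate_pipelines(
    truth: SyntheticTruth, config: SimulationConfig
) -> tuple[list[GeneModel], list[GeneModel]]:
    """Two perturbed copies of the true model set, one per mock pipeline.

    Each copy independently drops models (``drop_rate``), jitters gene
    boundaries (``jitter_sd``) and splits models in two (``split_rate``).
    Provenance to the true locus is kept on each model's ``origin``.
    """
    out: list[list[GeneModel]] = []
    for label in ("pipelineA", "pipelineB"):
        rng = _rng(config, f"pipeline/{label}")
        models: list[GeneModel] = []
        for m in truth.true_models:
            if rng.random() < config.drop_rate:
                continue
            base_id = f"{label[-1]}_{m.id}"
            if rng.random() < config.split_rate:
                models.extend(_split_model(m, rng, base_id, label, config))
            else:
                models.append(_perturb_model(m, rng, config, base_id, label))
        if config.spurious_rate > 0:
            n_spur = rng.binomial(len(truth.true_models), config.spurious_rate)
            for j in range(n_spur):
                length = int(rng.integers(300, 901)) // 3 * 3
                start = int(rng.integers(0, config.scaffold_length - length))
                sid = f"scf{int(rng.integers(1, config.n_scaffolds + 1)):04d}"
                models.append(
                    GeneModel(id=f"{label[-1]}_spur{j + 1:04d}", source=label,
                              scaffold=sid,
                              strand="+" if rng.random() < 0.5 else "-",
                              segments=((start, start + length),),
                              origin="spurious")
                )
        out.append(models)
    return out[0], out[1]


def _split_model(m: GeneModel, rng: np.random.Generator, base_id: str,
                 source: str, config: SimulationConfig) -> list[GeneModel]:
    if m.exon_count >= 2:
        j = int(rng.integers(1, m.exon_count))
        parts = (m.segments[:j], m.segments[j:])
    else:
        s, e = m.segments[0]
        cut = int(rng.integers(s + 3, e - 3)) if e - s > 6 else (s + e) // 2
        parts = (((s, cut),), ((cut, e),))
    return [
        _perturb_model(
            GeneModel(id=m.id, source=m.source, scaffold=m.scaffold,
                      strand=m.strand, segments=part, origin=m.origin),
            rng, config, f"{base_id}.{i + 1}", source)
        for i, part in enumerate(parts)
    ]


# ---------------------------------------------------------------------------


def _log_uniform_evalue(rng: np.random.Generator,
                        decades: tuple[float, float]) -> float:
    return float(10.0 ** rng.uniform(*decades))


def synthesize_hits(models: Sequence[GeneModel],
                    config: SimulationConfig) -> list[HomologyHit]:
    """Mock homology evidence for ``models``.

    With the default pass-all configuration every model receives a RefSeq
    hit passing all four thresholds plus a transcriptome hit above 90%
    identity; ``blacklist_rate`` controls how often the RefSeq description
    carries an uninformative word that disqualifies it for representative
    selection; ``kingdom_mix`` controls taxonomic-sharing hits.
    """
    rng = _rng(config, "hits")
    hits: list[HomologyHit] = []
    tags = [t for t, _ in config.kingdom_mix]
    kprobs = np.array([p for _, p in config.kingdom_mix])
    for m in models:
        if rng.random() < config.blacklist_rate:
            desc = _BLACKLIST_DESCRIPTIONS[rng.integers(0, len(_BLACKLIST_DESCRIPTIONS))]
        else:
            desc = _CLEAN_DESCRIPTIONS[rng.integers(0, len(_CLEAN_DESCRIPTIONS))]
        if rng.random() < config.refseq_pass_rate:
            hits.append(HomologyHit(
                query=m.id, subject=f"XP_{rng.integers(10**6, 10**7)}",
                description=desc, database="refseq_plant",
                e_value=_log_uniform_evalue(rng, config.evalue_decades),
                bit_score=float(rng.uniform(120, 500)),
                pct_identity=float(rng.uniform(55, 95)),
                query_cov=float(rng.uniform(80, 100)),
                subject_cov=float(rng.uniform(80, 100))))
        else:
            # fail exactly one of the four conjuncts, chosen at random
            fail = rng.integers(0, 4)
            hits.append(HomologyHit(
                query=m.id, subject=f"XP_{rng.integers(10**6, 10**7)}",
                description=desc, database="refseq_plant",
                e_value=_log_uniform_evalue(rng, config.evalue_decades),
                bit_score=float(rng.uniform(20, 99)) if fail == 1
                else float(rng.uniform(120, 500)),
                pct_identity=float(rng.uniform(20, 49)) if fail == 0
                else float(rng.uniform(55, 95)),
                query_cov=float(rng.uniform(10, 79)) if fail == 2
                else float(rng.uniform(80, 100)),
                subject_cov=float(rng.uniform(10, 79)) if fail == 3
                else float(rng.uniform(80, 100))))
        ident = (rng.uniform(91, 100) if rng.random() < config.mrna_pass_rate
                 else rng.uniform(70, 90))
        hits.append(HomologyHit(
            query=m.id, subject=f"mRNA_{rng.integers(10**5, 10**6)}",
            description="transcript assembly", database="mrna",
            e_value=_log_uniform_evalue(rng, config.evalue_decades),
            bit_score=float(rng.uniform(120, 500)),
            pct_identity=float(ident),
            query_cov=float(rng.uniform(80, 100)),
            subject_cov=float(rng.uniform(80, 100))))
        category = tags[rng.choice(len(tags), p=kprobs)]
        for tag in category:
            hits.append(HomologyHit(
                query=m.id, subject=f"{tag}_{rng.integers(10**4, 10**5)}",
                description=f"{tag} homolog", database=tag,
                e_value=_log_uniform_evalue(rng, (-40.0, -6.0)),
                bit_score=float(rng.uniform(60, 400)),
                pct_identity=float(rng.uniform(30, 90)),
                query_cov=float(rng.uniform(40, 100)),
                subject_cov=float(rng.uniform(40, 100))))
    return hits


def synthesize_domains(
    models: Sequence[GeneModel],
    config: SimulationConfig,
    counts: dict[str, int] | None = None,
) -> tuple[list[DomainHit], list[TMRecord], dict[str, str]]:
    """Plant resistance-class domain architectures on a subset of models.

    ``counts`` (class -> number of genes) overrides the proportional config;
    each selected gene gets exactly the domain set of its class, Mlo-like
    genes get 6 or 7 transmembrane helices, and every other model gets at
    most an OTHER domain.  Returns the hits, TM records, and the planted
    class per gene id.
    """
    rng = _rng(config, "domains")
    if counts is None:
        counts = {name: int(round(p * len(models)))
                  for name, p in config.r_class_proportions}
    total = sum(counts.values())
    if total > len(models):
        raise ValueError(
            f"cannot plant {total} resistance genes among {len(models)} models"
        )
    order = rng.permutation(len(models))
    planted: dict[str, str] = {}
    domain_hits: list[DomainHit] = []
    tm_records: list[TMRecord] = []
    idx = 0
    for cls, n in sorted(counts.items()):
        for _ in range(n):
            gene = models[order[idx]].id
            idx += 1
            planted[gene] = cls
            for dom in sorted(R_CLASS_DOMAINS[cls]):
                domain_hits.append(DomainHit(gene=gene, domain=dom))
            if cls == "Mlo-like":
                tm_records.append(TMRecord(gene=gene,
                                           tm_helices=int(rng.choice([6, 7]))))
            elif "TM" in R_CLASS_DOMAINS[cls]:
                tm_records.append(TMRecord(gene=gene, tm_helices=1))
    for j in order[idx:]:
        if rng.random() < 0.5:
            domain_hits.append(DomainHit(gene=models[j].id, domain="OTHER"))
    return domain_hits, tm_records, planted


def synthesize_taxonomy(config: SimulationConfig) -> list[ScaffoldTaxonomy]:
    """Scaffold taxonomy table; ``contaminant_rate`` of scaffolds are marked
    bacterial/plastid with no support at any of the three levels."""
    rng = _rng(config, "taxonomy")
    out = []
    for i in range(config.n_scaffolds):
        sid = f"scf{i + 1:04d}"
        if rng.random() < config.contaminant_rate:
            best = "bacterial" if rng.random() < 0.5 else "plastid"
            out.append(ScaffoldTaxonomy(sid, best, (False, False, False)))
        else:
            out.append(ScaffoldTaxonomy(sid, "plant_nuclear", (True, True, True)))
    return out


# ---------------------------------------------------------------------------


def write_dataset(config: SimulationConfig, outdir: str | os.PathLike) -> SyntheticTruth:
    """Generate a full synthetic dataset and write it to ``outdir``.

    Files: genome.fasta, truth.gff3, pipelineA.gff3, pipelineB.gff3,
    hits.tsv, domains.tsv, tm.tsv, taxonomy.tsv, truth.json.
    """
    os.makedirs(outdir, exist_ok=True)
    genome = generate_genome(config)
    genome, truth = plant_gene_models(config, genome)
    models_a, models_b = emulate_pipelines(truth, config)
    hits = synthesize_hits(models_a + models_b, config)
    domain_hits, tm_records, planted_r = synthesize_domains(
        truth.true_models, config)
    truth.planted_r_class = planted_r
    taxonomy = synthesize_taxonomy(config)

    outdir = os.fspath(outdir)
    write_fasta(genome, os.path.join(outdir, "genome.fasta"))
    write_gff3(truth.true_models, os.path.join(outdir, "truth.gff3"))
    write_gff3(models_a, os.path.join(outdir, "pipelineA.gff3"))
    write_gff3(models_b, os.path.join(outdir, "pipelineB.gff3"))

    with open(os.path.join(outdir, "hits.tsv"), "w") as fh:
        fh.write("query\tsubject\tdescription\tdatabase\te_value\tbit_score\t"
                 "pct_identity\tquery_cov\tsubject_cov\n")
        for h in hits:
            fh.write(f"{h.query}\t{h.subject}\t{h.description}\t{h.database}\t"
                     f"{h.e_value:.6g}\t{h.bit_score:.2f}\t{h.pct_identity:.2f}\t"
                     f"{h.query_cov:.2f}\t{h.subject_cov:.2f}\n")
    with open(os.path.join(outdir, "domains.tsv"), "w") as fh:
        fh.write("gene\tdomain\n")
        for d in domain_hits:
            fh.write(f"{d.gene}\t{d.domain}\n")
    with open(os.path.join(outdir, "tm.tsv"), "w") as fh:
        fh.write("gene\ttm_helices\n")
        for t in tm_records:
            fh.write(f"{t.gene}\t{t.tm_helices}\n")
    with open(os.path.join(outdir, "taxonomy.tsv"), "w") as fh:
        fh.write("scaffold\tbest_hit\tsupport_sister_genome\t"
                 "support_transcriptome\tsupport_newer_build\n")
        for t in taxonomy:
            s = "\t".join(str(v).lower() for v in t.support)
            fh.write(f"{t.scaffold}\t{t.best_hit}\t{s}\n")
    with open(os.path.join(outdir, "truth.json"), "w") as fh:
        json.dump(
            {
                "true_locus_assignment": truth.true_locus_assignment,
                "planted_gc3": truth.planted_gc3,
                "planted_r_class": truth.planted_r_class,
                "planted_slope": truth.planted_slope,
                "config": _config_dict(config),
            },
            fh, indent=2)
    return truth


def _config_dict(config: SimulationConfig) -> dict:
    d = asdict(config)
    return d
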