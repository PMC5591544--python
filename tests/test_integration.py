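"""Single-linkage locus clustering, threshold sweep and evidence filters."""

import itertools

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from genoweave import (
    HomologyHit,
    Locus,
    ScaffoldTaxonomy,
    cluster_loci,
    evidence_filter,
    filter_contaminant_scaffolds,
    overlap_fraction,
    select_representative,
    sweep_and_select,
)
from genoweave.integration import DEFAULT_THRESHOLDS

from conftest import make_model, span_model


def refseq_hit(query, e_value=1e-50, bit_score=200.0, identity=60.0,
               qcov=90.0, scov=90.0, description="kinase", subject="XP_1"):
    return HomologyHit(query=query, subject=subject, description=description,
                       database="refseq_plant", e_value=e_value,
                       bit_score=bit_score, pct_identity=identity,
                       query_cov=qcov, subject_cov=scov)


def mrna_hit(query, identity=95.0):
    return HomologyHit(query=query, subject="mRNA_1", description="transcript",
                       database="mrna", e_value=1e-30, bit_score=200.0,
                       pct_identity=identity, query_cov=90.0, subject_cov=90.0)


class TestOverlapFraction:
    def test_partial_overlap_is_fraction_of_shorter(self):
        a = span_model("a", 100, 400)
        b = span_model("b", 250, 550)
        assert overlap_fraction(a, b) == pytest.approx(150 / 300)

    def test_identical_spans(self):
        a = span_model("a", 0, 100)
        b = span_model("b", 0, 100)
        assert overlap_fraction(a, b) == 1.0

    def test_disjoint_spans(self):
        assert overlap_fraction(span_model("a", 0, 100),
                                span_model("b", 200, 300)) == 0.0

    def test_different_strand_or_scaffold_is_zero(self):
        a = span_model("a", 0, 100)
        assert overlap_fraction(a, span_model("b", 0, 100, strand="-")) == 0.0
        assert overlap_fraction(a, span_model("b", 0, 100, scaffold="s2")) == 0.0

    def test_span_includes_introns(self):
        # b sits inside a's intron-containing span: span overlap is complete
        # even though the exons barely touch
        a = make_model("a", segments=((0, 100), (200, 300)))
        b = span_model("b", 100, 250)
        assert overlap_fraction(a, b) == 1.0

    def test_exon_mode_compares_summed_exon_overlap(self):
        a = make_model("a", segments=((0, 100), (200, 300)))
        b = span_model("b", 100, 250)
        # only [200,250) intersects a's exons; shorter CDS is b's 150 nt
        assert overlap_fraction(a, b, mode="exon") == pytest.approx(50 / 150)
        assert overlap_fraction(a, a, mode="exon") == 1.0

    def test_exon_mode_clusters_more_strictly(self):
        a = make_model("a", segments=((0, 100), (200, 300)))
        b = span_model("b", 100, 250)
        assert len(cluster_loci([a, b], 0.9, min_orf_nt=0)) == 1
        assert len(cluster_loci([a, b], 0.9, min_orf_nt=0,
                                overlap_mode="exon")) == 2


def chain_models():
    # A-B and B-C overlap 0.9; A-C only 0.8
    return [span_model("A", 0, 1000), span_model("B", 100, 1100),
            span_model("C", 200, 1200)]


class TestClusterLoci:
    def test_chain_merges_at_low_threshold(self):
        (locus,) = cluster_loci(chain_models(), 0.85)
        assert locus.members == ["A", "B", "C"]

    def test_chain_splits_at_high_threshold(self):
        loci = cluster_loci(chain_models(), 0.95)
        assert sorted(len(l.members) for l in loci) == [1, 1, 1]

    def test_min_orf_boundary(self):
        models = [span_model("short", 0, 299), span_model("ok", 1000, 1300)]
        loci = cluster_loci(models, 0.85)
        assert [l.members for l in loci] == [["ok"]]

    def test_strands_never_merge(self):
        models = [span_model("f", 0, 1000), span_model("r", 0, 1000, strand="-")]
        assert len(cluster_loci(models, 0.6)) == 2

    def test_deterministic_ids(self):
        loci = cluster_loci(chain_models(), 0.85)
        assert loci[0].id == "locus-s1-p-0"

    def test_conservation(self):
        models = chain_models() + [span_model("D", 5000, 5600)]
        loci = cluster_loci(models, 0.85)
        seen = [m for l in loci for m in l.members]
        assert sorted(seen) == ["A", "B", "C", "D"]


def _random_instance(rng, n_max=50, scaffolds=("s1", "s2")):
    n = int(rng.integers(2, n_max + 1))
    models = []
    for i in range(n):
        start = int(rng.integers(0, 5000))
        length = int(rng.integers(300, 2000))
        models.append(span_model(
            f"m{i}", start, start + length,
            scaffold=scaffolds[int(rng.integers(0, len(scaffolds)))],
            strand="+-"[int(rng.integers(0, 2))]))
    return models


def _oracle_partition(models, threshold):
    """Brute force: all-pairs overlap matrix + graph connected components."""
    g = nx.Graph()
    g.add_nodes_from(m.id for m in models)
    for a, b in itertools.combinations(models, 2):
        if overlap_fraction(a, b) >= threshold:
            g.add_edge(a.id, b.id)
    return {frozenset(c) for c in nx.connected_components(g)}


def test_cluster_matches_brute_force_oracle(rng):
    """Sweep-based union-find equals all-pairs connected components."""
    for _ in range(200):
        models = _random_instance(rng)
        t = float(rng.choice([0.6, 0.75, 0.85, 0.95]))
        got = {frozenset(l.members) for l in cluster_loci(models, t, min_orf_nt=0)}
        assert got == _oracle_partition(models, t)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_locus_count_monotone_in_threshold(seed):
    """Raising the threshold never merges loci."""
    models = _random_instance(np.random.default_rng(seed), n_max=30)
    counts = [len(cluster_loci(models, t, min_orf_nt=0))
              for t in DEFAULT_THRESHOLDS]
    assert counts == sorted(counts)


def knee_fixture(rng, n_pairs=40):
    """Pairs of models whose overlaps all lie strictly inside (0.85, 0.95)."""
    models = []
    for i in range(n_pairs):
        base = 10_000 * i
        d = int(rng.integers(16, 45))  # overlap (300-d)/300 in (0.85, 0.95)
        models.append(span_model(f"a{i}", base, base + 300))
        models.append(span_model(f"b{i}", base + d, base + 300 + d))
    return models


class TestSweepAndSelect:
    def test_knee_selects_085(self, rng):
        rows, selected = sweep_and_select(knee_fixture(rng))
        assert selected == 0.85

    def test_identical_sets_have_undefined_selection(self):
        models = [span_model("a", 0, 1000), span_model("b", 0, 1000)]
        rows, selected = sweep_and_select(models)
        assert selected is None
        assert len({r.n_loci for r in rows}) == 1

    def test_rows_are_consistent(self, rng):
        rows, _ = sweep_and_select(knee_fixture(rng))
        for r in rows:
            assert r.n_single_model_loci + r.n_multi_model_loci == r.n_loci
            if r.n_multi_model_loci:
                assert r.single_to_multi_ratio == pytest.approx(
                    r.n_single_model_loci / r.n_multi_model_loci)
            else:
                assert r.single_to_multi_ratio is None

    def test_requires_three_increasing_thresholds(self):
        with pytest.raises(ValueError):
            sweep_and_select([], thresholds=[0.9, 0.8, 0.7])


class TestEvidenceFilter:
    M = [span_model("g1", 0, 1000)]

    def test_both_evidence_classes_pass(self):
        hits = [refseq_hit("g1", identity=60, bit_score=150, qcov=85, scov=90),
                mrna_hit("g1", identity=95)]
        assert [m.id for m in evidence_filter(self.M, hits)] == ["g1"]

    def test_failing_one_refseq_conjunct_drops(self):
        hits = [refseq_hit("g1", identity=40), mrna_hit("g1")]
        assert evidence_filter(self.M, hits) == []

    def test_mrna_identity_exactly_90_drops(self):
        hits = [refseq_hit("g1"), mrna_hit("g1", identity=90.0)]
        assert evidence_filter(self.M, hits) == []

    def test_missing_mrna_evidence_drops(self):
        assert evidence_filter(self.M, [refseq_hit("g1")]) == []

    def test_either_mode_takes_union(self):
        hits = [refseq_hit("g1")]
        assert [m.id for m in evidence_filter(self.M, hits, require="either")] \
            == ["g1"]


def _locus(members):
    return Locus(id="L1", scaffold="s1", strand="+", members=list(members))


class TestSelectRepresentative:
    def test_lowest_evalue_wins(self):
        hits = [refseq_hit("a", e_value=1e-50), refseq_hit("b", e_value=1e-20)]
        locus = select_representative(_locus(["a", "b"]), hits)
        assert locus.representative == "a"
        assert locus.annotation[2] == 1e-50

    def test_blacklisted_description_discards_locus(self):
        hits = [refseq_hit("a", description="hypothetical protein X")]
        assert select_representative(_locus(["a"]), hits) is None

    def test_evalue_above_cutoff_discards_locus(self):
        hits = [refseq_hit("a", e_value=1e-9), refseq_hit("b", e_value=1e-9)]
        assert select_representative(_locus(["a", "b"]), hits) is None

    def test_evalue_tie_breaks_by_bit_score_then_id(self):
        hits = [refseq_hit("b", e_value=1e-30, bit_score=300),
                refseq_hit("a", e_value=1e-30, bit_score=200)]
        assert select_representative(_locus(["a", "b"]), hits).representative == "b"
        hits = [refseq_hit("b", e_value=1e-30), refseq_hit("a", e_value=1e-30)]
        assert select_representative(_locus(["a", "b"]), hits).representative == "a"

    def test_only_refseq_hits_count(self):
        assert select_representative(_locus(["a"]), [mrna_hit("a")]) is None


class TestContaminantFilter:
    def _loci(self):
        return [Locus(id="L1", scaffold="scf1", strand="+", members=["a"]),
                Locus(id="L2", scaffold="scf2", strand="+", members=["b"])]

    def test_unsupported_bacterial_scaffold_removed(self):
        tax = [ScaffoldTaxonomy("scf1", "bacterial", (False, False, False))]
        kept = filter_contaminant_scaffolds(self._loci(), tax)
        assert [l.id for l in kept] == ["L2"]

    def test_any_support_level_rescues(self):
        tax = [ScaffoldTaxonomy("scf1", "bacterial", (False, True, False))]
        assert len(filter_contaminant_scaffolds(self._loci(), tax)) == 2

    def test_plant_nuclear_kept_regardless(self):
        tax = [ScaffoldTaxonomy("scf1", "plant_nuclear", (False, False, False))]
        assert len(filter_contaminant_scaffolds(self._loci(), tax)) == 2

    def test_plastid_unsupported_removed(self):
        tax = [ScaffoldTaxonomy("scf2", "plastid", (False, False, False))]
        kept = filter_contaminant_scaffolds(self._loci(), tax)
        assert [l.id for l in kept] == ["L1"]
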