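"""Contig triage cascade: decoy, coverage, linkage, clustering, ledger."""

import numpy as np
import pytest

from acrsift import (
    ContigRecord,
    HomologyHit,
    classify_phage_associated,
    cluster_redundant,
    coverage_filter,
    detect_cross_contamination,
    filter_homologs,
    remove_vector_contigs,
    run_filter_pipeline,
)
from acrsift.contig_filtering import pairwise_match
from acrsift.escape_genotyping import LinkageVerdict
from acrsift.synthetic_library import reverse_complement
from conftest import random_dna

DECOY = random_dna(2500, seed=77)


def _mutate(seq, n_subs, seed=0):
    rng = np.random.default_rng(seed)
    s = list(seq)
    for i in rng.choice(len(s), size=n_subs, replace=False):
        s[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[s[i]]
    return "".join(s)


class TestPairwiseMatch:
    def test_exact_substring_full_identity(self):
        ident, span = pairwise_match(DECOY[200:1200], DECOY)
        assert ident == 1.0 and span == 1000

    def test_substitution_identity_matches_construction(self):
        """Identity agrees with the direct position-wise count on a pair
        built by known substitutions."""
        q = _mutate(DECOY[:1000], 10, seed=1)
        direct = sum(a == b for a, b in zip(q, DECOY[:1000])) / 1000
        ident, span = pairwise_match(q, DECOY)
        assert span == 1000
        assert ident == pytest.approx(direct)

    def test_reverse_strand_detected(self):
        ident, span = pairwise_match(reverse_complement(DECOY[300:900]),
                                     DECOY)
        assert ident == 1.0 and span == 600

    def test_unrelated_sequences_do_not_match(self):
        other = random_dna(1000, seed=99)
        ident, span = pairwise_match(other, DECOY)
        assert span < 100


class TestRemoveVectorContigs:
    def test_exact_substring_removed(self):
        c = ContigRecord("c", DECOY[100:1300], "L1")
        kept, removed = remove_vector_contigs([c], {"pCas9": DECOY})
        assert kept == [] and "c" in removed
        assert "pCas9" in removed["c"]

    def test_diverged_contig_kept(self):
        c = ContigRecord("c", _mutate(DECOY[100:1300], 120, seed=2), "L1")
        kept, removed = remove_vector_contigs([c], {"pCas9": DECOY})
        assert kept == [c] and removed == {}

    def test_near_identical_full_length_removed(self):
        seq = _mutate(DECOY[100:1300], 6, seed=3)  # 99.5% identity
        kept, removed = remove_vector_contigs(
            [ContigRecord("c", seq, "L1")], {"pCas9": DECOY})
        assert "c" in removed

    def test_half_vector_chimera_removed(self):
        """A contig whose vector-derived half covers >= 50% of its length."""
        seq = DECOY[100:900] + random_dna(700, seed=4)
        kept, removed = remove_vector_contigs(
            [ContigRecord("c", seq, "L1")], {"pCas9": DECOY})
        assert "c" in removed

    def test_requires_decoys(self):
        with pytest.raises(ValueError):
            remove_vector_contigs([], {})


class TestCoverageFilter:
    @pytest.mark.parametrize("rpbm,removed", [
        (1.67, True),   # the vector-contig coverage maximum, below cutoff
        (2.0, False),   # boundary: "less than two" is strict
        (0.0, True),
        (3.5, False),
    ])
    def test_strict_threshold(self, rpbm, removed):
        c = ContigRecord("c", "ACGT" * 100, "L1", rpbm=rpbm)
        kept, dropped = coverage_filter([c], rpbm_min=2.0)
        assert ("c" in dropped) is removed

    def test_missing_rpbm_is_an_error(self):
        with pytest.raises(ValueError, match="c1"):
            coverage_filter([ContigRecord("c1", "ACGT" * 100, "L1")])


class TestClusterRedundant:
    def test_contained_contig_clusters_under_longer(self):
        a = ContigRecord("a", DECOY[:2000], "L1", rpbm=5.0)
        b = ContigRecord("b", DECOY[500:1500], "L1", rpbm=3.0)
        reps, removed = cluster_redundant([a, b])
        assert [r.contig_id for r in reps] == ["a"]
        assert "b" in removed

    def test_below_identity_both_kept(self):
        a = ContigRecord("a", DECOY[:1500], "L1")
        b = ContigRecord("b", _mutate(DECOY[:1500], 150, seed=5), "L1")
        reps, removed = cluster_redundant([a, b])
        assert len(reps) == 2 and removed == {}

    def test_prefix_with_substitutions_clusters(self):
        """A 1 kb copy of a 3 kb contig's start at 99% identity joins its
        cluster; the longer contig represents it."""
        big = random_dna(3000, seed=6)
        small = _mutate(big[:1000], 10, seed=7)
        a = ContigRecord("a", big, "L1")
        b = ContigRecord("b", small, "L1")
        reps, removed = cluster_redundant([a, b])
        assert [r.contig_id for r in reps] == ["a"]
        assert "b" in removed and "a" in removed["b"]

    def test_idempotent_on_representatives(self):
        contigs = [ContigRecord("a", DECOY[:2000], "L1"),
                   ContigRecord("b", DECOY[500:1500], "L1"),
                   ContigRecord("c", random_dna(1200, seed=8), "L1")]
        reps, _ = cluster_redundant(contigs)
        again, removed = cluster_redundant(reps)
        assert [r.contig_id for r in again] == [r.contig_id for r in reps]
        assert removed == {}


class TestCrossContamination:
    def test_higher_coverage_copy_in_other_library_removes_rep(self):
        seq = random_dna(1500, seed=9)
        rep = ContigRecord("rep", seq, "L1", rpbm=3.0)
        donor = ContigRecord("donor", seq, "L2", rpbm=30.0)
        kept, removed = detect_cross_contamination([rep], [rep, donor])
        assert kept == [] and "rep" in removed
        assert "L2" in removed["rep"]

    def test_unique_representative_kept(self):
        rep = ContigRecord("rep", random_dna(1500, seed=10), "L1", rpbm=3.0)
        other = ContigRecord("x", random_dna(1500, seed=11), "L2", rpbm=30.0)
        kept, removed = detect_cross_contamination([rep], [rep, other])
        assert kept == [rep] and removed == {}

    def test_presumed_source_is_kept(self):
        """When the representative itself has the higher coverage it is the
        presumed contamination source and stays."""
        seq = random_dna(1500, seed=12)
        rep = ContigRecord("rep", seq, "L1", rpbm=30.0)
        copy = ContigRecord("copy", seq, "L2", rpbm=3.0)
        kept, removed = detect_cross_contamination([rep], [rep, copy])
        assert kept == [rep] and removed == {}


class TestHomologyHits:
    def _hit(self, **kw):
        base = dict(query_id="orf1", subject_id="s", percent_identity=50.0,
                    alignment_length=150, query_length=182, rank=1,
                    subject_is_phage=False, contig_id="c1")
        base.update(kw)
        return HomologyHit(**base)

    def test_top_five_phage_hit_classifies_contig(self):
        hits = [self._hit(rank=3, subject_is_phage=True)]
        assert classify_phage_associated("c1", hits) is True

    def test_rank_beyond_cutoff_ignored(self):
        hits = [self._hit(rank=6, subject_is_phage=True)]
        assert classify_phage_associated("c1", hits) is False

    def test_no_hits_not_phage(self):
        assert classify_phage_associated("c1", []) is False

    @pytest.mark.parametrize("identity,aln_len,kept", [
        (40.0, 140, True),    # 76.9% of a 182 aa query
        (34.9, 182, False),   # identity boundary
        (90.0, 91, False),    # 50% coverage fails
        (35.0, 137, True),    # both exactly at threshold (137/182 = 75.3%)
    ])
    def test_homolog_thresholds(self, identity, aln_len, kept):
        hits = [self._hit(percent_identity=identity,
                          alignment_length=aln_len)]
        out = filter_homologs(hits)
        assert (len(out) == 1) is kept


def _planted_contigs():
    """20 contigs with known violations: 2 vector, 3 low-coverage,
    2 escape-linked, 4 redundant, 1 cross-contaminant -> 8 survivors."""
    contigs = []
    clean = [random_dna(1500 + 37 * i, seed=100 + i) for i in range(8)]
    for i, seq in enumerate(clean):
        contigs.append(ContigRecord(f"c{i + 1:02d}", seq, "L1", rpbm=5.0))
    contigs.append(ContigRecord("c09", DECOY[100:1400], "L1", rpbm=5.0))
    contigs.append(ContigRecord("c10", _mutate(DECOY[500:2100], 3, seed=13),
                                "L1", rpbm=5.0))
    for i in (11, 12, 13):
        contigs.append(ContigRecord(f"c{i}", random_dna(1400, seed=200 + i),
                                    "L1", rpbm=1.0))
    for i, (nl, nv) in ((14, (12, 2)), (15, (5, 1))):
        c = ContigRecord(f"c{i}", random_dna(1400, seed=300 + i), "L1",
                         rpbm=5.0)
        c.linkage["A"] = LinkageVerdict(c.contig_id, "A", nl, nv,
                                       "eliminate", "variant-supported")
        contigs.append(c)
    for j, i in enumerate((16, 17, 18, 19)):
        parent = clean[j]
        contigs.append(ContigRecord(f"c{i}",
                                    _mutate(parent[:1200], 5, seed=400 + i),
                                    "L1", rpbm=3.0))
    contigs.append(ContigRecord("c20", clean[4], "L2", rpbm=2.5))
    return contigs


class TestFilterPipeline:
    def test_planted_violations_are_each_caught(self):
        contigs = _planted_contigs()
        final, ledger = run_filter_pipeline(contigs, {"pCas9": DECOY})
        assert sorted(c.contig_id for c in final) == \
            [f"c{i:02d}" for i in range(1, 9)]
        by_stage = {s.name: s for s in ledger.stages}
        assert set(by_stage["remove_vector_contigs"].removed) == {"c09", "c10"}
        assert set(by_stage["coverage_filter"].removed) == {"c11", "c12",
                                                            "c13"}
        assert set(by_stage["escape_linked_filter"].removed) == {"c14", "c15"}
        assert set(by_stage["cluster_redundant"].removed) == {"c16", "c17",
                                                              "c18", "c19"}
        assert set(by_stage["detect_cross_contamination"].removed) == {"c20"}
        assert ledger.conserved()

    def test_ledger_counts_chain(self):
        final, ledger = run_filter_pipeline(_planted_contigs(),
                                            {"pCas9": DECOY})
        for prev, nxt in zip(ledger.stages, ledger.stages[1:]):
            assert prev.output_count == nxt.input_count
            assert prev.input_count - len(prev.removed) == prev.output_count

    def test_empty_input(self):
        final, ledger = run_filter_pipeline([], {"pCas9": DECOY})
        assert final == []
        assert all(s.input_count == s.output_count == 0
                   for s in ledger.stages)

    def test_all_clean_input_passes_unchanged(self):
        contigs = [ContigRecord(f"c{i}", random_dna(1500, seed=500 + i),
                                f"L{i % 2}", rpbm=4.0) for i in range(5)]
        final, ledger = run_filter_pipeline(contigs, {"pCas9": DECOY})
        assert sorted(c.contig_id for c in final) == \
            sorted(c.contig_id for c in contigs)

    def test_output_invariant_under_input_permutation(self):
        base = _planted_contigs()
        final_a, _ = run_filter_pipeline(base, {"pCas9": DECOY})
        rng = np.random.default_rng(3)
        shuffled = _planted_contigs()
        rng.shuffle(shuffled)
        final_b, _ = run_filter_pipeline(shuffled, {"pCas9": DECOY})
        assert [c.contig_id for c in final_a] == \
            [c.contig_id for c in final_b]

    def test_whitelist_shields_escape_linked_contig(self):
        contigs = _planted_contigs()
        final, ledger = run_filter_pipeline(contigs, {"pCas9": DECOY},
                                            whitelist=("c14",))
        ids = [c.contig_id for c in final]
        assert "c14" in ids and "c15" not in ids

    def test_phage_annotation_does_not_remove(self):
        contigs = [ContigRecord("c1", random_dna(1500, seed=600), "L1",
                                rpbm=4.0)]
        hits = [HomologyHit("orf1", "phage_prot", 60.0, 100, 120, rank=1,
                            subject_is_phage=True, contig_id="c1")]
        final, _ = run_filter_pipeline(contigs, {"pCas9": DECOY}, hits=hits)
        assert len(final) == 1
        assert any(stage == "phage_associated"
                   for stage, _ in final[0].flags)
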