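"""Screening rules: forward thresholds, reciprocal best hit, domains, loci."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from olfrep.screen import (
    CandidateGene,
    DomainAnnotation,
    HitRecord,
    ScreenThresholds,
    _union_coverage,
    apply_domain_filter,
    filter_forward_hits,
    join_split_loci,
    reciprocal_confirm,
    reconcile_candidates,
)

THR = ScreenThresholds()


def hit(q="q1", s="s1", evalue=1e-20, alen=300, **kw):
    return HitRecord(query_id=q, subject_id=s, evalue=evalue, align_len=alen, **kw)


class TestForwardFilter:
    @pytest.mark.parametrize(
        "mode,evalue,alen,passes",
        [
            ("proteome", 1e-4, 260, True),
            ("proteome", 1e-3, 300, False),  # E-value cutoff is strict
            ("proteome", 1e-4, 249, False),  # length floor is inclusive at 250
            ("proteome", 1e-4, 250, True),
            ("genome", 1e-4, 300, False),  # genome mode tightens E to 1e-10
            ("genome", 1e-11, 300, True),
            ("genome", 1e-10, 300, False),
        ],
    )
    def test_threshold_boundaries(self, mode, evalue, alen, passes):
        got = filter_forward_hits([hit(evalue=evalue, alen=alen)], THR, mode)
        assert (got == {"q1"}) is passes

    def test_sequence_fails_when_every_hit_fails(self):
        hits = [hit(evalue=1e-2, alen=400), hit(evalue=1e-5, alen=249)]
        assert filter_forward_hits(hits, THR, "proteome") == set()

    def test_any_passing_hit_rescues_sequence(self):
        hits = [hit(evalue=1e-2, alen=400), hit(evalue=1e-5, alen=260)]
        assert filter_forward_hits(hits, THR, "proteome") == {"q1"}

    def test_idempotent_and_order_independent_with_witness(self):
        hits = [
            hit(q=f"q{i}", evalue=e, alen=a)
            for i, (e, a) in enumerate(
                [(1e-9, 300), (1e-2, 300), (1e-9, 100), (5e-4, 250), (0.0, 251)]
            )
        ]
        fwd = filter_forward_hits(hits, THR, "proteome")
        assert fwd == filter_forward_hits(list(reversed(hits)), THR, "proteome")
        # every survivor has a witnessing hit satisfying both rules
        for q in fwd:
            assert any(
                h.query_id == q and h.evalue < THR.max_evalue_proteome
                and h.align_len >= THR.min_alen
                for h in hits
            )

    def test_invalid_records_rejected(self):
        with pytest.raises(ValueError):
            HitRecord(query_id="q", subject_id="s", evalue=-1.0, align_len=300)
        with pytest.raises(ValueError):
            HitRecord(query_id="q", subject_id="s", evalue=1e-5, align_len=0)


class TestReciprocalConfirm:
    def test_best_hit_in_family_confirms(self):
        rev = [hit(q="c1", s="OR_hs_1", evalue=1e-50)]
        assert reciprocal_confirm(["c1"], rev, {"OR_hs_1"}) == {"c1"}

    def test_best_hit_outside_family_rejects_even_with_second_best_inside(self):
        rev = [
            hit(q="c1", s="HTR4_hs", evalue=1e-60, bitscore=500),
            hit(q="c1", s="OR_hs_1", evalue=1e-40, bitscore=300),
        ]
        assert reciprocal_confirm(["c1"], rev, {"OR_hs_1"}) == set()

    def test_tie_broken_by_bitscore(self):
        rev = [
            hit(q="c1", s="in_family", evalue=1e-50, bitscore=310),
            hit(q="c1", s="outside", evalue=1e-50, bitscore=290),
        ]
        assert reciprocal_confirm(["c1"], rev, {"in_family"}) == {"c1"}

    def test_no_passing_reverse_hit_rejects(self):
        rev = [hit(q="c1", s="OR_hs_1", evalue=0.5)]
        assert reciprocal_confirm(["c1"], rev, {"OR_hs_1"}) == set()

    def test_empty_family_set_is_config_error(self):
        with pytest.raises(ValueError):
            reciprocal_confirm(["c1"], [], set())


class TestDomainFilter:
    def dom(self, seq, name="TM7_3", s=30, e=250):
        return DomainAnnotation(seq_id=seq, domain_name=name, env_start=s, env_end=e)

    @pytest.mark.parametrize(
        "envs,kept",
        [
            ([(30, 250)], True),   # coverage 221
            ([(100, 250)], False),  # coverage 151
            ([(1, 120), (100, 220)], True),  # union 220
            ([(1, 100), (150, 240)], False),  # union 191
        ],
    )
    def test_v2r_coverage_union(self, envs, kept):
        doms = [self.dom("c1", s=s, e=e) for s, e in envs]
        got = apply_domain_filter(["c1"], doms, "V2R", THR)
        assert (got == {"c1"}) is kept

    def test_or_any_7tm_domain(self):
        assert apply_domain_filter(["c1"], [self.dom("c1", name="7tm_1", s=1, e=50)],
                                   "OR") == {"c1"}
        assert apply_domain_filter(["c1"], [self.dom("c1", name="Pkinase")],
                                   "OR") == set()

    def test_unknown_family_errors(self):
        with pytest.raises(ValueError):
            apply_domain_filter(["c1"], [], "GPCRX")

    @given(st.lists(st.tuples(st.integers(1, 300), st.integers(0, 100)),
                    min_size=1, max_size=8))
    @settings(max_examples=50, deadline=None)
    def test_union_coverage_matches_set_cardinality(self, spans):
        envs = [(s, s + w) for s, w in spans]
        expected = len(set().union(*(range(s, e + 1) for s, e in envs)))
        assert _union_coverage(envs) == expected


class TestJoinSplitLoci:
    def ghit(self, q, scaf="s1", start=0, end=100, strand="+"):
        return HitRecord(query_id=q, subject_id=scaf, evalue=1e-20, align_len=100,
                         subject_scaffold=scaf, subject_start=start,
                         subject_end=end, subject_strand=strand)

    def test_gap_below_100kb_merges(self):
        loci = join_split_loci(
            [self.ghit("a", start=0, end=1000), self.ghit("b", start=51_000, end=52_000)]
        )
        assert len(loci) == 1 and set(loci[0].member_hits) == {"a", "b"}

    def test_gap_above_100kb_splits(self):
        loci = join_split_loci(
            [self.ghit("a", start=0, end=1000), self.ghit("b", start=151_000, end=152_000)]
        )
        assert len(loci) == 2

    def test_opposite_strands_never_merge(self):
        loci = join_split_loci(
            [self.ghit("a", start=0, end=1000),
             self.ghit("b", start=500, end=1500, strand="-")]
        )
        assert len(loci) == 2

    def test_flank_applied_and_clipped(self):
        loci = join_split_loci([self.ghit("a", start=100, end=1000)],
                               scaffold_lengths={"s1": 1500})
        assert loci[0].start == 0  # 100 - 900 clipped at 0
        assert loci[0].end == 1500  # 1000 + 900 clipped at scaffold length

    def test_loci_pairwise_non_mergeable_and_members_conserved(self):
        import numpy as np

        rng = np.random.default_rng(5)
        hits = [
            self.ghit(f"h{i}", scaf=f"s{rng.integers(3)}",
                      start=(p := int(rng.integers(1_000, 2_000_000))), end=p + 500,
                      strand="+-"[rng.integers(2)])
            for i in range(40)
        ]
        loci = join_split_loci(hits)
        assert sum(len(l.member_hits) for l in loci) == len(hits)
        thr = ScreenThresholds()
        for i, a in enumerate(loci):
            for b in loci[i + 1:]:
                if a.scaffold == b.scaffold and a.strand == b.strand:
                    # gap between flank-stripped loci stays >= max_join_gap
                    gap = max(a.start, b.start) - min(a.end, b.end) + 2 * thr.flank
                    assert gap >= thr.max_join_gap

    def test_missing_scaffold_errors(self):
        bad = HitRecord(query_id="a", subject_id="s", evalue=1e-20, align_len=100)
        with pytest.raises(ValueError):
            join_split_loci([bad])


class TestReconcile:
    def gene(self, gid, scaf="s1", start=0, end=1000, strand="+", source="gene_model"):
        return CandidateGene(gene_id=gid, family="OR", source=source, scaffold=scaf,
                             start=start, end=end, strand=strand)

    def test_overlap_same_strand_matches(self):
        out = reconcile_candidates(
            [self.gene("m1", start=0, end=1000)],
            [self.gene("g1", start=900, end=2000, source="genome_predicted")],
        )
        assert [(c.gene_id, c.flag) for c in out] == [("m1", "matched")]

    def test_constructed_fixture_counts(self):
        # 5 model genes, 4 genome loci of which 3 overlap -> 6 genes
        models = [self.gene(f"m{i}", start=i * 10_000, end=i * 10_000 + 1000)
                  for i in range(5)]
        genome = [
            self.gene("g1", start=500, end=1500, source="genome_predicted"),
            self.gene("g2", start=10_500, end=11_500, source="genome_predicted"),
            self.gene("g3", start=20_500, end=21_500, source="genome_predicted"),
            self.gene("g4", scaf="s9", start=0, end=1000, source="genome_predicted"),
        ]
        out = reconcile_candidates(models, genome)
        flags = sorted(c.flag for c in out)
        assert len(out) == 6
        assert flags == ["genome_only", "matched", "matched", "matched",
                         "model_only", "model_only"]

    def test_opposite_strand_overlap_is_not_a_match(self):
        out = reconcile_candidates(
            [self.gene("m1")],
            [self.gene("g1", strand="-", source="genome_predicted")],
        )
        assert sorted(c.flag for c in out) == ["genome_only", "model_only"]

    def test_peptide_identity_fallback(self):
        pep = {"m1": "M" + "A" * 199, "g1": "M" + "A" * 198 + "V"}
        model = CandidateGene(gene_id="m1", family="OR", source="gene_model",
                              scaffold="", start=0, end=1, strand="+")
        out = reconcile_candidates(
            [model], [self.gene("g1", source="genome_predicted")], peptides=pep
        )
        assert [c.flag for c in out] == ["matched"]  # 199/200 = 99.5%

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError):
            reconcile_candidates([self.gene("x")],
                                 [self.gene("x", source="genome_predicted")])

    def test_output_size_invariant(self):
        models = [self.gene(f"m{i}", start=i * 5000, end=i * 5000 + 1000)
                  for i in range(4)]
        genome = [self.gene(f"g{i}", start=i * 7000 + 200, end=i * 7000 + 1200,
                            source="genome_predicted") for i in range(3)]
        out = reconcile_candidates(models, genome)
        n_genome_only = sum(1 for c in out if c.flag == "genome_only")
        assert len(out) == len(models) + n_genome_only
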