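import pytest

from bovimito import (AnnotatedGenome, MultiAlignment, Region, RootedTree,
                      annotate_effect, call_events, classify_sharing,
                      find_islands, map_to_branches, merge_micro_events)
from bovimito.simulate import SimulationConfig, simulate
from bovimito.likelihood import SubstitutionModel
from bovimito.variants import NON_FOCAL, VariantEvent


def sub(pos, carriers, ref="A", alt="G"):
    return VariantEvent(ref_start=pos, ref_end=pos, kind="substitution",
                        ref_allele=ref, alt_allele=alt,
                        carriers=frozenset(carriers))


TRIO_TREE = RootedTree.from_newick(
    "(BRS:1,(wisent:1,(bison:1,yak:1):1):1);")


class TestCallEvents:
    def test_identical_sequences_no_events(self):
        aln = MultiAlignment(["r", "a", "b"], ["ACGT"] * 3, "r")
        assert call_events(aln, "r") == []

    def test_single_substitution(self):
        aln = MultiAlignment(["r", "a", "b", "c"],
                             ["ACGT", "ACAT", "ACGT", "ACGT"], "r")
        evs = call_events(aln, "r")
        assert len(evs) == 1
        ev = evs[0]
        assert (ev.ref_start, ev.ref_allele, ev.alt_allele) == (3, "G", "A")
        assert ev.carriers == frozenset({"a"})

    def test_multiallelic_column_one_event_per_allele(self):
        aln = MultiAlignment(["r", "a", "b"], ["AAAA", "ACAA", "AGAA"], "r")
        evs = call_events(aln, "r")
        assert {(e.alt_allele, tuple(e.carriers)) for e in evs} == \
            {("C", ("a",)), ("G", ("b",))}

    def test_ambiguity_compatible_with_root_not_a_carrier(self):
        # R = A/G is compatible with root A; Y = C/T is not
        aln = MultiAlignment(["r", "a", "b"], ["AAAA", "RAAA", "YAAA"], "r")
        evs = call_events(aln, "r")
        assert len(evs) == 1 and evs[0].carriers == frozenset({"b"})
        assert evs[0].alt_allele == "Y"

    def test_indel_runs_become_single_events(self):
        aln = MultiAlignment(
            ["r", "a", "b"],
            ["ACGTACGT", "AC--ACGT", "ACGTACGT"], "r")
        evs = call_events(aln, "r")
        assert len(evs) == 1
        ev = evs[0]
        assert ev.kind == "deletion" and (ev.ref_start, ev.ref_end) == (3, 4)
        assert ev.ref_allele == "GT"

    def test_insertion_keyed_to_preceding_position(self):
        aln = MultiAlignment(["r", "a"], ["AC--GT", "ACTTGT"], "r")
        evs = call_events(aln, "r")
        assert len(evs) == 1
        ev = evs[0]
        assert ev.kind == "insertion" and ev.ref_start == 2
        assert ev.alt_allele == "TT"

    def test_shared_indels_share_one_event(self):
        aln = MultiAlignment(["r", "a", "b"],
                             ["ACGTA", "AC-TA", "AC-TA"], "r")
        evs = call_events(aln, "r")
        assert len(evs) == 1 and evs[0].carriers == frozenset({"a", "b"})

    def test_root_all_gaps_errors(self):
        aln = MultiAlignment(["r", "a"], ["----", "ACGT"], "r")
        with pytest.raises(ValueError):
            call_events(aln, "r")

    def test_simulator_truth_carriers_recovered(self):
        tree = RootedTree.from_newick("(r:0.0,(a:0.004,b:0.003):0.002);")
        cfg = SimulationConfig(tree=tree, model=SubstitutionModel.jc(),
                               genome_length=10000, indel_rate=0.05,
                               seed=23, reference="r")
        _, aln, truth = simulate(cfg)
        evs = call_events(aln, "r")
        got = {}
        for e in evs:
            got[e.carriers] = got.get(e.carriers, 0) + 1
        assert got == truth.pattern_counts


class TestMergeMicroEvents:
    def test_distant_events_untouched(self):
        evs = [sub(10, {"w"}), sub(100, {"w"}), sub(200, {"w"})]
        assert merge_micro_events(evs, max_gap=2, min_components=3) == evs

    def test_worked_example_contiguous_block(self):
        """Eight contiguous same-carrier differences merge into one event."""
        evs = [sub(p, {"wisent"}) for p in range(1472, 1480)]
        out = merge_micro_events(evs)
        assert len(out) == 1
        m = out[0]
        assert m.kind == "micro_reorganization"
        assert (m.ref_start, m.ref_end, m.component_count) == (1472, 1479, 8)
        assert m.carriers == frozenset({"wisent"})

    def test_merging_requires_identical_carrier_sets(self):
        evs = [sub(10, {"a"}), sub(11, {"a"}), sub(12, {"a"}),
               sub(13, {"a", "b"})]
        out = merge_micro_events(evs)
        kinds = sorted((e.kind, e.ref_start) for e in out)
        assert kinds == [("micro_reorganization", 10), ("substitution", 13)]

    def test_min_components_threshold(self):
        evs = [sub(10, {"a"}), sub(11, {"a"})]
        assert merge_micro_events(evs, min_components=3) == evs

    def test_idempotent_and_span_preserving(self):
        evs = [sub(p, {"a"}) for p in (5, 6, 7, 30, 31, 32, 90)]
        once = merge_micro_events(evs)
        twice = merge_micro_events(once)
        assert once == twice
        assert min(e.ref_start for e in once) == 5
        assert max(e.ref_end for e in once) == 90

    def test_empty_input(self):
        assert merge_micro_events([]) == []


class TestClassifyAndMap:
    FOCAL = ["wisent", "bison", "yak"]

    def test_patterns(self):
        evs = [sub(1, {"wisent"}), sub(2, {"bison", "yak"}),
               sub(3, {"wisent", "bison", "yak"}), sub(4, {"zebu"})]
        pats = classify_sharing(evs, self.FOCAL, "BRS")
        assert {k if isinstance(k, str) else "+".join(sorted(k)): len(v)
                for k, v in pats.items()} == {
            "wisent": 1, "bison+yak": 1, "bison+wisent+yak": 1,
            NON_FOCAL: 1}

    def test_empty_focal_errors(self):
        with pytest.raises(ValueError):
            classify_sharing([sub(1, {"x"})], ["BRS"], "BRS")

    def test_clade_patterns_map_to_subtending_branch(self):
        evs = [sub(1, {"wisent"}), sub(2, {"bison", "yak"}),
               sub(3, {"bison", "yak"})]
        pats = classify_sharing(evs, self.FOCAL, "BRS")
        counts = map_to_branches(pats, TRIO_TREE)
        assert counts.branch_counts["wisent"] == ("unique", 1)
        assert counts.branch_counts["bison+yak"] == ("shared", 2)
        assert counts.unresolved_patterns == []

    def test_non_clade_pattern_is_unresolved(self):
        pats = classify_sharing([sub(1, {"wisent", "yak"})],
                                self.FOCAL, "BRS")
        counts = map_to_branches(pats, TRIO_TREE)
        assert counts.branch_counts == {}
        assert counts.unresolved_patterns == [(frozenset({"wisent", "yak"}), 1)]

    def test_totals_conserved(self):
        evs = [sub(i, c) for i, c in enumerate(
            [{"wisent"}, {"bison"}, {"yak"}, {"bison", "yak"},
             {"wisent", "yak"}, {"zebu"},
             {"wisent", "bison", "yak"}], start=1)]
        pats = classify_sharing(evs, self.FOCAL, "BRS")
        assert sum(len(v) for v in pats.values()) == len(evs)
        counts = map_to_branches(pats, TRIO_TREE)
        assert counts.total == len(evs)

    def test_missing_taxon_errors(self):
        pats = classify_sharing([sub(1, {"aurochs"})], ["aurochs"], "BRS")
        with pytest.raises(KeyError):
            map_to_branches(pats, TRIO_TREE)


class TestIslands:
    def test_sparse_events_no_islands(self):
        evs = [sub(p, {"a"}) for p in (10, 200, 400)]
        assert find_islands(evs, max_island_gap=60, min_events=2) == []

    def test_packed_window_single_island(self):
        """20 events within a 223-bp window form one island, as in the
        16S rRNA cluster of the two-wisent comparison."""
        positions = [1471 + round(i * 222 / 19) for i in range(20)]
        evs = [sub(p, {"w2"}) for p in positions[:16]] + [
            VariantEvent(ref_start=p, ref_end=p, kind="deletion",
                         ref_allele="A", alt_allele="",
                         carriers=frozenset({"w2"}))
            for p in positions[16:]]
        islands = find_islands(evs)
        assert len(islands) == 1
        isl = islands[0]
        assert (isl.start, isl.end) == (1471, 1693)
        assert isl.n_events == 20
        assert isl.n_substitutions == 16 and isl.n_indels == 4

    def test_two_planted_clusters(self):
        evs = [sub(p, {"a"}) for p in range(100, 110)] + \
              [sub(p, {"a"}) for p in range(5000, 5010)]
        islands = find_islands(evs)
        assert [(i.start, i.end) for i in islands] == \
            [(100, 109), (5000, 5009)]

    def test_island_reports_overlapping_regions(self):
        g = AnnotatedGenome(id="g", sequence="A" * 2000,
                            regions=[Region("16S", 1400, 1800, "rRNA")])
        evs = [sub(p, {"a"}) for p in range(1471, 1480)]
        islands = find_islands(evs, genome=g)
        assert islands[0].regions == ("16S",)


class TestAnnotateEffect:
    @pytest.fixture
    def genome(self):
        # gene: ATG CTA CTG CCC TAA  (M L L P *)
        seq = "TTTT" + "ATGCTACTGCCCTAA" + "GGGG" + "A" * 20
        return AnnotatedGenome(
            id="g", sequence=seq,
            regions=[Region("nd0", 5, 19, "protein_coding"),
                     Region("rrn", 24, 33, "rRNA")])

    def test_fourfold_site_synonymous(self, genome):
        # CTA -> CTG (Leu -> Leu), third codon position 10
        ev = sub(10, {"x"}, ref="A", alt="G")
        out = annotate_effect(ev, genome)
        assert out.effect == "synonymous"
        assert out.aa_change == "L2L"

    def test_nonsynonymous(self, genome):
        # CTA -> CCA at position 9 (Leu -> Pro)
        ev = sub(9, {"x"}, ref="T", alt="C")
        out = annotate_effect(ev, genome)
        assert out.effect == "nonsynonymous" and out.aa_change == "L2P"

    def test_one_bp_insertion_is_frameshift(self, genome):
        ev = VariantEvent(ref_start=9, ref_end=9, kind="insertion",
                          ref_allele="", alt_allele="T",
                          carriers=frozenset({"x"}))
        out = annotate_effect(ev, genome)
        assert out.effect == "frameshift"
        assert out.aa_change  # novel residue stretch reported

    def test_third_position_window_all_synonymous(self, genome):
        # every third position of the L/P codons tolerates transitions
        evs = [sub(10, {"x"}, "A", "G"), sub(13, {"x"}, "G", "A"),
               sub(16, {"x"}, "C", "T")]
        effects = {annotate_effect(e, genome).effect for e in evs}
        assert effects == {"synonymous"}

    def test_rna_gene_and_intergenic(self, genome):
        assert annotate_effect(sub(25, {"x"}), genome).effect == "rna_gene"
        assert annotate_effect(sub(2, {"x"}), genome).effect == "intergenic"

    def test_out_of_bounds_errors(self, genome):
        with pytest.raises(ValueError):
            annotate_effect(sub(9999, {"x"}), genome)

    def test_minus_strand_translation(self):
        # reverse strand gene: genome holds revcomp of ATGAAATAA
        seq = "TT" + "TTATTTCAT" + "TT"
        g = AnnotatedGenome(id="g", sequence=seq,
                            regions=[Region("nd6", 3, 11, "protein_coding",
                                            strand="-")])
        # the Lys codon AAA occupies genome positions 8..6 on the minus
        # strand; its wobble base maps to + strand position 6 (a T)
        ev = sub(6, {"x"}, ref="T", alt="C")  # AAA -> AAG (Lys -> Lys)
        out = annotate_effect(ev, g)
        assert out.effect == "synonymous"
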