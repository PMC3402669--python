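import numpy as np
import pytest

from bovimito import banded_pairwise_align, chain_anchors, project_msa
from bovimito.align import DEFAULT_SCORES, alignment_score, gotoh_align
from bovimito.genome import GAP, MultiAlignment

from conftest import random_dna


def scalar_gotoh(a: str, b: str) -> float:
    """Slow reference affine-gap aligner, scores only (independent oracle)."""
    match, mismatch = DEFAULT_SCORES["match"], DEFAULT_SCORES["mismatch"]
    go, ge = DEFAULT_SCORES["gap_open"], DEFAULT_SCORES["gap_extend"]
    NEG = float("-inf")
    n, m = len(a), len(b)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = go + ge * i
    for j in range(1, m + 1):
        Y[0][j] = go + ge * j
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            M[i][j] = s + max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
            X[i][j] = max(M[i - 1][j] + go + ge, Y[i - 1][j] + go + ge,
                          X[i - 1][j] + ge)
            Y[i][j] = max(M[i][j - 1] + go + ge, X[i][j - 1] + go + ge,
                          Y[i][j - 1] + ge)
    return max(M[n][m], X[n][m], Y[n][m])


class TestChainAnchors:
    def test_identical_sequences_nearly_fully_covered(self):
        rng = np.random.default_rng(0)
        seq = random_dna(rng, 1000)
        chain = chain_anchors(seq, seq, k=12)
        assert chain.matched_length >= 1000 - 2 * 11

    def test_single_deletion_gives_two_blocks_with_offset(self):
        rng = np.random.default_rng(1)
        ref = random_dna(rng, 1000)
        query = ref[:400] + ref[405:]
        chain = chain_anchors(ref, query, k=12)
        assert len(chain.anchors) == 2
        a, b = chain.anchors
        assert a.ref_start - a.query_start == 0
        assert b.ref_start - b.query_start == 5

    def test_unrelated_sequences_empty_chain(self):
        # expected unique shared 16-mers between random 1 kb sequences < 1
        empty = 0
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            if not chain_anchors(random_dna(rng, 1000),
                                 random_dna(rng, 1000), k=16).anchors:
                empty += 1
        assert empty >= 9

    def test_k_and_emptiness_validation(self):
        with pytest.raises(ValueError):
            chain_anchors("ACGTACGTACGT", "", k=12)
        with pytest.raises(ValueError):
            chain_anchors("ACGTACGT", "ACGTACGT", k=4)


class TestGotoh:
    def test_identical(self):
        s, ga, gb = gotoh_align("ACGTACGT", "ACGTACGT")
        assert s == 8.0 and ga == gb == "ACGTACGT"

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_scalar_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = random_dna(rng, int(rng.integers(20, 120)))
        b = random_dna(rng, int(rng.integers(20, 120)))
        s, ga, gb = gotoh_align(a, b)
        assert s == pytest.approx(scalar_gotoh(a, b))
        # traceback consistent with the reported score
        pw = MultiAlignment(["a", "b"], [ga, gb], "a")
        assert alignment_score(pw) == pytest.approx(s)
        assert ga.replace(GAP, "") == a and gb.replace(GAP, "") == b


class TestBandedAlignment:
    def test_identical_gapless(self):
        rng = np.random.default_rng(3)
        seq = random_dna(rng, 2000)
        pw = banded_pairwise_align(seq, seq)
        assert GAP not in pw.rows[0] and GAP not in pw.rows[1]
        assert alignment_score(pw) == len(seq) * DEFAULT_SCORES["match"]

    def test_score_equals_full_dp_with_planted_variants(self):
        rng = np.random.default_rng(4)
        ref = random_dna(rng, 2000)
        q = list(ref)
        for p in rng.integers(0, 2000, 3):
            q[p] = "ACGT"[int(rng.integers(0, 4))]
        q = "".join(q[:1000]) + "TTAC" + "".join(q[1000:])  # 4-bp insertion
        pw = banded_pairwise_align(ref, q)
        s_full, _, _ = gotoh_align(ref, q)
        assert alignment_score(pw) == pytest.approx(s_full)
        assert pw.degapped("query") == q

    def test_tandem_rearrangement_appears_as_mismatch_block(self):
        rng = np.random.default_rng(5)
        ref = random_dna(rng, 1500)
        block = ref[700:708]
        repl = "".join("ACGT"[(("ACGT".index(c)) + 2) % 4] for c in block)
        q = ref[:700] + repl + ref[708:]
        pw = banded_pairwise_align(ref, q)
        ra, rb = pw.rows
        assert GAP not in ra and GAP not in rb
        assert ra[700:708] != rb[700:708]
        assert sum(x != y for x, y in zip(ra, rb)) == 8


class TestProjectMSA:
    def test_single_pairwise_identity(self):
        pw = MultiAlignment(["r", "q"], ["AC-GT", "ACCGT"], "r")
        out = project_msa("r", [pw])
        assert out.rows == pw.rows and out.taxa == pw.taxa

    def test_insertions_at_distinct_positions_stack(self):
        pw1 = MultiAlignment(["r", "q1"], ["AC-GT", "ACAGT"], "r")
        pw2 = MultiAlignment(["r", "q2"], ["ACGT-", "ACGTC"], "r")
        out = project_msa("r", [pw1, pw2])
        assert out.length == 4 + 1 + 1
        assert out.degapped("q1") == "ACAGT"
        assert out.degapped("q2") == "ACGTC"

    def test_order_invariance(self):
        rng = np.random.default_rng(6)
        ref = random_dna(rng, 800)
        alns = []
        for i in range(3):
            q = list(ref)
            for p in rng.integers(0, 800, 10):
                q[p] = "ACGT"[int(rng.integers(0, 4))]
            rows = banded_pairwise_align(ref, "".join(q)).rows
            alns.append(MultiAlignment(["ref", f"q{i}"], rows, "ref"))
        out1 = project_msa("ref", alns)
        out2 = project_msa("ref", alns[::-1])
        assert out1.rows == out2.rows and out1.taxa == out2.taxa

    def test_duplicate_taxon_errors(self):
        pw = MultiAlignment(["r", "q"], ["ACGT", "ACGT"], "r")
        with pytest.raises(ValueError):
            project_msa("r", [pw, pw])

    def test_projected_p_distances_match_pairwise(self, preset_run):
        from bovimito import align_genomes, p_distance
        from bovimito.align import banded_pairwise_align

        _, genomes, _, _ = preset_run
        msa = align_genomes(genomes, "BRS")
        ref = next(g for g in genomes if g.id == "BRS")
        for g in genomes:
            if g.id == "BRS":
                continue
            pw = banded_pairwise_align(ref, g)
            d_direct = p_distance(pw, "BRS", g.id).p_distance
            d_msa = p_distance(msa, "BRS", g.id).p_distance
            assert abs(d_direct - d_msa) < 0.001
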