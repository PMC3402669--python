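"""Anchored pairwise and reference-projected multiple alignment.

Complete mitogenomes within a tribe differ by a few percent, so alignment
reduces to chaining unique exact k-mer matches and solving the short gaps
between them exactly.  The chain is found by maximum-weight collinear
chaining over unique shared k-mers; inter-anchor segments are aligned with
full affine-gap (Gotoh) dynamic programming, so whenever the optimal global
path passes through the anchors the anchored score equals the unconstrained
optimum.  Multiple sequences are aligned pairwise against one reference and
projected into a single reference-coordinate MSA.

Affine gap convention: a gap of length L costs ``gap_open + L * gap_extend``
(both negative).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .genome import GAP, AnnotatedGenome, MultiAlignment

log = logging.getLogger(__name__)

DEFAULT_SCORES = {"match": 1.0, "mismatch": -2.0,
                  "gap_open": -5.0, "gap_extend": -1.0}
NEG = -1e30


@dataclass(frozen=True)
class Anchor:
    ref_start: int    # 1-based
    query_start: int  # 1-based
    length: int

    @property
    def ref_end(self) -> int:
        return self.ref_start + self.length - 1

    @property
    def query_end(self) -> int:
        return self.query_start + self.length - 1


@dataclass
class AnchorChain:
    anchors: list[Anchor] = field(default_factory=list)

    def __post_init__(self) -> None:
        prev = None
        for a in self.anchors:
            if prev is not None and (a.ref_start <= prev.ref_end
                                     or a.query_start <= prev.query_end):
                raise ValueError("anchors overlap or are out of order")
            prev = a

    def __len__(self) -> int:
        return len(self.anchors)

    @property
    def matched_length(self) -> int:
        return sum(a.length for a in self.anchors)


def _unique_kmer_positions(seq: str, k: int) -> dict[str, int]:
    seen: dict[str, int] = {}
    dup: set[str] = set()
    for i in range(len(seq) - k + 1):
        kmer = seq[i:i + k]
        if kmer in seen:
            dup.add(kmer)
        else:
            seen[kmer] = i
    for kmer in dup:
        del seen[kmer]
    return seen


def chain_anchors(ref: str, query: str, k: int = 12) -> AnchorChain:
    """Maximal-scoring collinear chain of unique shared k-mer matches.

    Consecutive matches on the same diagonal are merged into blocks before
    chaining, then blocks are chained by dynamic programming maximising the
    total matched length.  An empty chain signals sequences too divergent
    for anchored alignment.
    """
    if not ref or not query:
        raise ValueError("sequences must be non-empty")
    if k < 8:
        raise ValueError("seed length k must be >= 8")
    ref_pos = _unique_kmer_positions(ref, k)
    query_pos = _unique_kmer_positions(query, k)
    matches = sorted((ref_pos[m], query_pos[m])
                     for m in ref_pos.keys() & query_pos.keys())
    if not matches:
        return AnchorChain([])

    # merge same-diagonal consecutive k-mers into maximal blocks
    blocks: list[list[int]] = []  # [ref0, query0, length], 0-based
    for r, q in matches:
        if blocks and r == blocks[-1][0] + blocks[-1][2] - k + 1 \
                and q == blocks[-1][1] + blocks[-1][2] - k + 1:
            blocks[-1][2] += 1
        else:
            blocks.append([r, q, k])

    # O(m^2) chaining on blocks; m is small for near-identical genomes
    m = len(blocks)
    score = [b[2] for b in blocks]
    back = [-1] * m
    for j in range(m):
        rj, qj, lj = blocks[j]
        for i in range(j):
            ri, qi, li = blocks[i]
            if ri + li <= rj and qi + li <= qj and score[i] + lj > score[j]:
                score[j] = score[i] + lj
                back[j] = i
    best = int(np.argmax(score))
    chain_blocks = []
    while best != -1:
        chain_blocks.append(blocks[best])
        best = back[best]
    chain_blocks.reverse()
    return AnchorChain([Anchor(r + 1, q + 1, l) for r, q, l in chain_blocks])


# ---------------------------------------------------------------------------
# full affine-gap (Gotoh) global alignment, row-vectorised

def gotoh_align(a: str, b: str, scores: dict | None = None
                ) -> tuple[float, str, str]:
    """Optimal global alignment of ``a`` and ``b`` under affine gap costs.

    Returns (score, gapped_a, gapped_b).  Tie-breaking prefers diagonal over
    up (gap in ``b``) over left (gap in ``a``) for reproducibility.
    """
    sc = dict(DEFAULT_SCORES, **(scores or {}))
    match, mismatch = sc["match"], sc["mismatch"]
    go, ge = sc["gap_open"], sc["gap_extend"]
    n, m = len(a), len(b)
    if n == 0 or m == 0:
        gap_cost = go + ge * max(n, m) if (n or m) else 0.0
        return gap_cost, a + GAP * m, GAP * n + b
    av = np.frombuffer(a.encode(), dtype=np.uint8)
    bv = np.frombuffer(b.encode(), dtype=np.uint8)
    sub = np.where(av[:, None] == bv[None, :], match, mismatch)

    M = np.full((n + 1, m + 1), NEG)
    Ix = np.full((n + 1, m + 1), NEG)  # gap in b (consumes a)
    Iy = np.full((n + 1, m + 1), NEG)  # gap in a (consumes b)
    M[0, 0] = 0.0
    Ix[1:, 0] = go + ge * np.arange(1, n + 1)
    Iy[0, 1:] = go + ge * np.arange(1, m + 1)
    js = np.arange(m + 1)
    for i in range(1, n + 1):
        M[i, 1:] = sub[i - 1] + np.maximum.reduce(
            [M[i - 1, :-1], Ix[i - 1, :-1], Iy[i - 1, :-1]])
        Ix[i, 1:] = np.maximum(
            np.maximum(M[i - 1, 1:], Iy[i - 1, 1:]) + go + ge,
            Ix[i - 1, 1:] + ge)
        # horizontal pass: Iy[i,j] = max_{k<j} best[i,k] + go + ge*(j-k)
        best = np.maximum(M[i], Ix[i])
        run = np.maximum.accumulate(best[:-1] - ge * js[:-1])
        Iy[i, 1:] = run + go + ge * js[1:]

    score = max(M[n, m], Ix[n, m], Iy[n, m])

    # traceback
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = n, m
    eps = 1e-9
    state = max(((M[n, m], 0), (Ix[n, m], 1), (Iy[n, m], 2)),
                key=lambda t: (t[0], -t[1]))[1]
    while i > 0 or j > 0:
        if state == 0:
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            prev = M[i, j] - sub[i - 1, j - 1]
            i, j = i - 1, j - 1
            if abs(M[i, j] - prev) < eps:
                state = 0
            elif abs(Ix[i, j] - prev) < eps:
                state = 1
            else:
                state = 2
        elif state == 1:
            out_a.append(a[i - 1])
            out_b.append(GAP)
            cur = Ix[i, j]
            i -= 1
            if abs(M[i, j] + go + ge - cur) < eps:
                state = 0
            elif abs(Ix[i, j] + ge - cur) < eps:
                state = 1
            else:
                state = 2
        else:
            out_a.append(GAP)
            out_b.append(b[j - 1])
            cur = Iy[i, j]
            j -= 1
            if abs(M[i, j] + go + ge - cur) < eps:
                state = 0
            elif abs(Ix[i, j] + go + ge - cur) < eps:
                state = 1
            else:
                state = 2
        if i == 0 and j == 0:
            break
    return float(score), "".join(reversed(out_a)), "".join(reversed(out_b))


# ---------------------------------------------------------------------------
# anchored alignment

def _ids(x, default: str) -> tuple[str, str]:
    if isinstance(x, AnnotatedGenome):
        return x.id, x.sequence
    return default, x


ANCHOR_TRIM = 8  # bp shaved off each anchor end so the DP can move freely


def banded_pairwise_align(ref, query, chain: AnchorChain | None = None,
                          band: int = 50, scores: dict | None = None,
                          k: int = 12) -> MultiAlignment:
    """Globally align two near-identical sequences through an anchor chain.

    Anchors (trimmed by a few bp at each end) are kept as exact ungapped
    blocks; the segments between them are solved by full affine-gap dynamic
    programming, which is exact because inter-anchor segments are short.
    When the length difference of a segment pair exceeds ``band`` the band
    is considered blown and the (already exact) full-matrix solve is logged
    as a widening; with no usable anchors the whole pair is solved by the
    full matrix.
    """
    sc = dict(DEFAULT_SCORES, **(scores or {}))
    ref_id, ref_seq = _ids(ref, "ref")
    query_id, query_seq = _ids(query, "query")
    if chain is None:
        chain = chain_anchors(ref_seq, query_seq, k=k)

    trimmed: list[Anchor] = []
    for a in chain.anchors:
        if a.length - 2 * ANCHOR_TRIM >= 8:
            trimmed.append(Anchor(a.ref_start + ANCHOR_TRIM,
                                  a.query_start + ANCHOR_TRIM,
                                  a.length - 2 * ANCHOR_TRIM))
    if not trimmed:
        log.warning("no usable anchors between %s and %s; "
                    "widening to the full matrix", ref_id, query_id)
        _, ga, gb = gotoh_align(ref_seq, query_seq, sc)
        return MultiAlignment([ref_id, query_id], [ga, gb], ref_id)

    rows_a: list[str] = []
    rows_b: list[str] = []
    r_prev = q_prev = 0  # 0-based exclusive end of the previous block
    for a in trimmed + [None]:  # type: ignore[list-item]
        if a is None:
            rseg = ref_seq[r_prev:]
            qseg = query_seq[q_prev:]
        else:
            rseg = ref_seq[r_prev:a.ref_start - 1]
            qseg = query_seq[q_prev:a.query_start - 1]
        if abs(len(rseg) - len(qseg)) > band:
            log.warning("inter-anchor gap (%d vs %d bp) exceeds band %d "
                        "between %s and %s; widening",
                        len(rseg), len(qseg), band, ref_id, query_id)
        if rseg or qseg:
            _, ga, gb = gotoh_align(rseg, qseg, sc)
            rows_a.append(ga)
            rows_b.append(gb)
        if a is not None:
            block = ref_seq[a.ref_start - 1:a.ref_end]
            rows_a.append(block)
            rows_b.append(query_seq[a.query_start - 1:a.query_end])
            r_prev, q_prev = a.ref_end, a.query_end
    return MultiAlignment([ref_id, query_id],
                          ["".join(rows_a), "".join(rows_b)], ref_id)


def alignment_score(aln: MultiAlignment, scores: dict | None = None) -> float:
    """Affine-gap score of a pairwise alignment (for oracle comparisons)."""
    sc = dict(DEFAULT_SCORES, **(scores or {}))
    a, b = aln.rows
    total = 0.0
    in_gap_a = in_gap_b = False
    for x, y in zip(a, b):
        if x == GAP:
            total += sc["gap_extend"] + (0 if in_gap_a else sc["gap_open"])
            in_gap_a, in_gap_b = True, False
        elif y == GAP:
            total += sc["gap_extend"] + (0 if in_gap_b else sc["gap_open"])
            in_gap_b, in_gap_a = True, False
        else:
            total += sc["match"] if x == y else sc["mismatch"]
            in_gap_a = in_gap_b = False
    return total


# ---------------------------------------------------------------------------
# reference projection

def project_msa(ref_id: str, pairwise: list[MultiAlignment]) -> MultiAlignment:
    """Merge pairwise alignments sharing one reference into a single MSA.

    One column per reference base plus the union of insertion columns keyed
    by (reference position, offset); insertions at the same reference
    position in different taxa are left-aligned and stacked, not re-aligned.
    The result is independent of the order of the pairwise alignments.
    """
    ref_seq: str | None = None
    per_query: dict[str, tuple[dict[int, str], dict[int, str]]] = {}
    for pw in pairwise:
        if pw.ref_id != ref_id or len(pw.taxa) != 2:
            raise ValueError("each input must be a pairwise alignment "
                             f"with reference {ref_id!r}")
        q_id = next(t for t in pw.taxa if t != ref_id)
        if q_id in per_query:
            raise ValueError(f"duplicate taxon id {q_id!r}")
        rrow, qrow = pw.row(ref_id), pw.row(q_id)
        seq = rrow.replace(GAP, "")
        if ref_seq is None:
            ref_seq = seq
        elif seq != ref_seq:
            raise ValueError("pairwise alignments disagree on the reference")
        at_pos: dict[int, str] = {}
        ins_at: dict[int, str] = {}
        p = 0
        for rc, qc in zip(rrow, qrow):
            if rc == GAP:
                if qc != GAP:
                    ins_at[p] = ins_at.get(p, "") + qc
            else:
                p += 1
                at_pos[p] = qc
        per_query[q_id] = (at_pos, ins_at)
    if ref_seq is None:
        raise ValueError("no pairwise alignments supplied")

    n = len(ref_seq)
    ins_len = {p: max(len(per_query[q][1].get(p, "")) for q in per_query)
               for p in range(n + 1)}
    taxa = [ref_id] + sorted(per_query)
    rows: list[list[str]] = [[] for _ in taxa]
    colmap: list[int | None] = []

    def emit_insertions(p: int) -> None:
        width = ins_len[p]
        if not width:
            return
        colmap.extend([None] * width)
        rows[0].append(GAP * width)
        for qi, q in enumerate(taxa[1:], start=1):
            ins = per_query[q][1].get(p, "")
            rows[qi].append(ins + GAP * (width - len(ins)))

    emit_insertions(0)
    for p in range(1, n + 1):
        colmap.append(p)
        rows[0].append(ref_seq[p - 1])
        for qi, q in enumerate(taxa[1:], start=1):
            rows[qi].append(per_query[q][0][p])
        emit_insertions(p)
    return MultiAlignment(taxa, ["".join(r) for r in rows], ref_id, colmap)


def align_genomes(genomes: list[AnnotatedGenome], ref_id: str,
                  k: int = 12, band: int = 50,
                  scores: dict | None = None) -> MultiAlignment:
    """Align every genome against ``ref_id`` and project into one MSA."""
    by_id = {g.id: g for g in genomes}
    if ref_id not in by_id:
        raise KeyError(f"reference {ref_id!r} not among genomes")
    ref = by_id[ref_id]
    pairwise = [banded_pairwise_align(ref, g, band=band, scores=scores, k=k)
                for g in genomes if g.id != ref_id]
    if not pairwise:
        return MultiAlignment([ref_id], [ref.sequence], ref_id)
    return project_msa(ref_id, pairwise)
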