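"""Variant cataloguing against a designated root reference.

Mutations are read off a multiple alignment by comparison with a root
sequence (in the wisent study, the Bos taurus reference V00654 serves as an
artificial root), then clustered micro-reorganizations are merged, events
are classified by which focal taxa share the derived state, mapped onto
branches of a fixed rooted topology under a single-origin (Fitch-style)
assumption, grouped into difference islands for two-genome comparisons, and
annotated for their coding effect under the vertebrate mitochondrial code.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from Bio.Data import CodonTable

from .genome import GAP, IUPAC, AnnotatedGenome, MultiAlignment, Region
from .trees import RootedTree

MITO_TABLE = CodonTable.unambiguous_dna_by_id[2]  # vertebrate mitochondrial

EVENT_KINDS = ("substitution", "insertion", "deletion", "micro_reorganization")
EFFECTS = ("synonymous", "nonsynonymous", "frameshift", "rna_gene",
           "intergenic", "not_annotated")


@dataclass
class VariantEvent:
    """One substitution, indel or merged micro-reorganization.

    Coordinates are 1-based in the root reference frame; an insertion is
    keyed to the preceding root position with ``ref_allele == ''``.
    """

    ref_start: int
    ref_end: int
    kind: str
    ref_allele: str
    alt_allele: str
    carriers: frozenset[str]
    component_count: int = 1
    effect: str | None = None
    aa_change: str | None = None
    region: str | None = None
    components: list["VariantEvent"] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.ref_start > self.ref_end:
            raise ValueError("ref_start > ref_end")
        if not self.carriers:
            raise ValueError("carriers must be non-empty")
        if self.component_count < 1:
            raise ValueError("component_count must be >= 1")

    @property
    def is_indel(self) -> bool:
        return self.kind in ("insertion", "deletion")

    @property
    def length_change(self) -> int:
        if self.kind == "micro_reorganization":
            return sum(c.length_change for c in self.components)
        return len(self.alt_allele) - len(self.ref_allele)

    def sort_key(self) -> tuple:
        return (self.ref_start, self.ref_end, self.kind, self.alt_allele)


def _compatible(a: str, b: str) -> bool:
    return bool(IUPAC.get(a, set()) & IUPAC.get(b, set()))


def left_normalize_deletion(root_seq: str, start: int, end: int
                            ) -> tuple[int, int, str]:
    """Shift a deletion to its leftmost equivalent placement.

    In homopolymer or tandem context a deleted block can be placed at
    several coordinates; rotating it left until the preceding base differs
    from the block's last base gives aligner-independent coordinates.
    """
    block = root_seq[start - 1:end]
    while start > 1 and root_seq[start - 2] == block[-1]:
        block = root_seq[start - 2] + block[:-1]
        start -= 1
        end -= 1
    return start, end, block


def left_normalize_insertion(root_seq: str, anchor: int, alt: str
                             ) -> tuple[int, str]:
    """Shift an insertion (after ``anchor``) to its leftmost placement."""
    while anchor >= 1 and root_seq[anchor - 1] == alt[-1]:
        alt = root_seq[anchor - 1] + alt[:-1]
        anchor -= 1
    return anchor, alt


# ---------------------------------------------------------------------------
# event calling

def call_events(aln: MultiAlignment, root_id: str) -> list[VariantEvent]:
    """Identify substitution and indel events relative to the root taxon.

    Substitutions: one event per distinct alternate allele per column where
    at least one taxon carries a base incompatible with the root base (IUPAC
    codes compatible with the root are not counted as carriers).  Maximal
    runs of gap columns in a taxon become single deletion events; columns
    where the root is gapped become insertions keyed to the preceding root
    position.  Identical indels in several taxa share one event.
    """
    if root_id not in aln.taxa:
        raise KeyError(f"root {root_id!r} not in alignment")
    root_row = aln.row(root_id)
    if set(root_row) == {GAP}:
        raise ValueError("root row is all gaps")
    others = [t for t in aln.taxa if t != root_id]

    # root coordinate of each column; for root-gap columns, the preceding one
    root_pos: list[int] = []
    p = 0
    for ch in root_row:
        if ch != GAP:
            p += 1
        root_pos.append(p)

    events: list[VariantEvent] = []

    # substitutions, column-wise
    for j, rc in enumerate(root_row):
        if rc == GAP:
            continue
        by_alt: dict[str, set[str]] = {}
        for t in others:
            tc = aln.row(t)[j]
            if tc == GAP or _compatible(tc, rc):
                continue
            by_alt.setdefault(tc, set()).add(t)
        for alt in sorted(by_alt):
            events.append(VariantEvent(
                ref_start=root_pos[j], ref_end=root_pos[j],
                kind="substitution", ref_allele=rc, alt_allele=alt,
                carriers=frozenset(by_alt[alt])))

    # indels, per-taxon run detection; both-gap columns are transparent
    root_seq = root_row.replace(GAP, "")
    deletions: dict[tuple[int, int, str], set[str]] = {}
    insertions: dict[tuple[int, str], set[str]] = {}
    for t in others:
        row = aln.row(t)
        del_run: list[int] = []
        ins_anchor: int | None = None
        ins_buf: list[str] = []

        def flush_del() -> None:
            if del_run:
                key = left_normalize_deletion(root_seq, del_run[0], del_run[-1])
                deletions.setdefault(key, set()).add(t)
                del_run.clear()

        def flush_ins() -> None:
            nonlocal ins_anchor
            if ins_buf:
                key = left_normalize_insertion(root_seq, ins_anchor or 0,
                                               "".join(ins_buf))
                insertions.setdefault(key, set()).add(t)
                ins_buf.clear()
            ins_anchor = None

        for j, (rc, tc) in enumerate(zip(root_row, row)):
            if rc == GAP and tc == GAP:
                continue
            if rc == GAP:                      # insertion column
                flush_del()
                if ins_buf and ins_anchor != root_pos[j]:
                    flush_ins()
                ins_anchor = root_pos[j]
                ins_buf.append(tc)
            elif tc == GAP:                    # deletion column
                flush_ins()
                if del_run and root_pos[j] != del_run[-1] + 1:
                    flush_del()
                del_run.append(root_pos[j])
            else:
                flush_del()
                flush_ins()
        flush_del()
        flush_ins()

    for (start, end, ref), taxa in deletions.items():
        events.append(VariantEvent(
            ref_start=start, ref_end=end, kind="deletion",
            ref_allele=ref, alt_allele="", carriers=frozenset(taxa)))
    for (anchor, alt), taxa in insertions.items():
        pos = max(anchor, 1)
        events.append(VariantEvent(
            ref_start=pos, ref_end=pos, kind="insertion",
            ref_allele="", alt_allele=alt, carriers=frozenset(taxa)))

    events.sort(key=VariantEvent.sort_key)
    return events


# ---------------------------------------------------------------------------
# micro-reorganization merging

def merge_micro_events(events: Sequence[VariantEvent], max_gap: int = 2,
                       min_components: int = 3) -> list[VariantEvent]:
    """Collapse clustered same-carrier differences into single events.

    A run of adjacent differences with an identical carrier set most likely
    records one mutational event that an aligner rendered as a range of
    substitutions (the wisent 1472-1479 block is the worked example).
    Maximal groups of at least ``min_components`` events whose consecutive
    reference gaps are <= ``max_gap`` are replaced by one
    ``micro_reorganization`` event spanning the group.  Idempotent: merged
    events never participate in further merging.
    """
    by_carriers: dict[frozenset[str], list[VariantEvent]] = {}
    passthrough: list[VariantEvent] = []
    for ev in events:
        if ev.kind == "micro_reorganization":
            passthrough.append(ev)
        else:
            by_carriers.setdefault(ev.carriers, []).append(ev)

    out: list[VariantEvent] = list(passthrough)
    for carriers, group in by_carriers.items():
        group.sort(key=VariantEvent.sort_key)
        cluster: list[VariantEvent] = []

        def flush() -> None:
            if len(cluster) >= min_components:
                out.append(VariantEvent(
                    ref_start=cluster[0].ref_start,
                    ref_end=max(e.ref_end for e in cluster),
                    kind="micro_reorganization",
                    ref_allele="", alt_allele="",
                    carriers=carriers,
                    component_count=sum(e.component_count for e in cluster),
                    components=list(cluster)))
            else:
                out.extend(cluster)
            cluster.clear()

        for ev in group:
            if cluster and ev.ref_start - max(e.ref_end for e in cluster) > max_gap:
                flush()
            cluster.append(ev)
        flush()
    out.sort(key=VariantEvent.sort_key)
    return out


# ---------------------------------------------------------------------------
# sharing patterns and branch mapping

NON_FOCAL = "non-focal"


def classify_sharing(events: Iterable[VariantEvent],
                     focal_taxa: Sequence[str],
                     root_id: str) -> dict[frozenset[str] | str, list[VariantEvent]]:
    """Bin events by which focal taxa share the derived (non-root) state."""
    focal = [t for t in focal_taxa if t != root_id]
    if not focal:
        raise ValueError("focal taxon set is empty")
    focal_set = frozenset(focal)
    out: dict[frozenset[str] | str, list[VariantEvent]] = {}
    for ev in events:
        pattern = ev.carriers & focal_set
        key: frozenset[str] | str = pattern if pattern else NON_FOCAL
        out.setdefault(key, []).append(ev)
    return out


@dataclass
class BranchMutationCounts:
    """Per-branch mutation tallies from parsimony pattern mapping."""

    branch_counts: dict[str, tuple[str, int]] = field(default_factory=dict)
    unresolved_patterns: list[tuple[frozenset[str], int]] = field(default_factory=list)
    non_focal: int = 0

    @property
    def total(self) -> int:
        return (sum(c for _, c in self.branch_counts.values())
                + sum(c for _, c in self.unresolved_patterns)
                + self.non_focal)


def map_to_branches(patterns: Mapping[frozenset[str] | str, list[VariantEvent]],
                    tree: RootedTree) -> BranchMutationCounts:
    """Assign each sharing pattern to the branch where it arose once.

    A pattern that forms a clade maps to the branch above the most recent
    common ancestor of exactly that taxon set; patterns that are not clades
    on the given topology (homoplasy or introgression signal) are reported
    as unresolved rather than forced onto a branch.
    """
    tree_leaves = tree.clade_leaves(tree.root)
    out = BranchMutationCounts()
    for key, evs in patterns.items():
        if key == NON_FOCAL:
            out.non_focal += len(evs)
            continue
        pattern = frozenset(key)  # type: ignore[arg-type]
        missing = pattern - tree_leaves
        if missing:
            raise KeyError(f"pattern taxa not in tree: {sorted(missing)}")
        node = tree.mrca(pattern)
        if tree.clade_leaves(node) == pattern:
            bid = tree.branch_id(node)
            label = "unique" if len(pattern) == 1 else "shared"
            prev = out.branch_counts.get(bid, (label, 0))
            out.branch_counts[bid] = (label, prev[1] + len(evs))
        else:
            out.unresolved_patterns.append((pattern, len(evs)))
    return out


# ---------------------------------------------------------------------------
# difference islands (two-genome comparison)

@dataclass(frozen=True)
class Island:
    start: int
    end: int
    n_events: int
    n_substitutions: int
    n_indels: int
    regions: tuple[str, ...] = ()


def find_islands(events: Sequence[VariantEvent], max_island_gap: int = 60,
                 min_events: int = 4,
                 genome: AnnotatedGenome | None = None) -> list[Island]:
    """Locate clusters ("islands") of differences along the reference.

    Maximal runs of at least ``min_events`` events whose consecutive
    reference gaps are <= ``max_island_gap``; each island reports its
    substitution/indel breakdown and overlapping annotated regions.
    """
    evs = sorted(events, key=VariantEvent.sort_key)
    islands: list[Island] = []
    cluster: list[VariantEvent] = []

    def flush() -> None:
        if len(cluster) >= min_events:
            start = cluster[0].ref_start
            end = max(e.ref_end for e in cluster)
            n_sub = sum(e.component_count for e in cluster if not e.is_indel)
            n_ind = sum(1 for e in cluster if e.is_indel)
            names: tuple[str, ...] = ()
            if genome is not None:
                names = tuple(r.name for r in genome.regions
                              if r.overlaps(start, end))
            islands.append(Island(start, end, len(cluster), n_sub, n_ind, names))
        cluster.clear()

    for ev in evs:
        if cluster and ev.ref_start - max(e.ref_end for e in cluster) > max_island_gap:
            flush()
        cluster.append(ev)
    flush()
    return islands


# ---------------------------------------------------------------------------
# coding effect annotation

def _gene_sequence(genome: AnnotatedGenome, r: Region) -> str:
    seq = genome.sequence[r.start - 1:r.end]
    if r.strand == "-":
        seq = _revcomp(seq)
    return seq[r.frame_offset:]


_COMP = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def _revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


def _translate(codon: str) -> str:
    if len(codon) != 3 or any(c not in "ACGT" for c in codon):
        return "X"
    if codon in MITO_TABLE.stop_codons:
        return "*"
    return MITO_TABLE.forward_table[codon]


def _gene_offset(r: Region, pos: int) -> int:
    """Offset of reference position ``pos`` within the reading frame."""
    if r.strand == "+":
        return pos - r.start - r.frame_offset
    return r.end - pos - r.frame_offset


def annotate_effect(event: VariantEvent,
                    genome: AnnotatedGenome) -> VariantEvent:
    """Classify an event's coding consequence on the reference genome.

    Substitutions inside protein-coding genes are translated under the
    vertebrate mitochondrial code (translation table 2); indels whose length
    is not a multiple of three are frameshifts, reported with the novel
    residue stretch up to the next stop; events in structural RNA genes are
    ``rna_gene``; outside all annotation, ``intergenic``.
    """
    if event.ref_end > len(genome) or event.ref_start < 1:
        raise ValueError(
            f"event {event.ref_start}..{event.ref_end} outside genome "
            f"{genome.id!r} (length {len(genome)})")
    if not genome.regions:
        return replace(event, effect="not_annotated")
    here = genome.regions_at(event.ref_start)
    coding = [r for r in here if r.kind == "protein_coding"]
    rnas = [r for r in here if r.kind in ("rRNA", "tRNA")]
    if coding:
        r = coding[0]
        return _annotate_coding(event, genome, r)
    if rnas:
        return replace(event, effect="rna_gene", region=rnas[0].name)
    if here:
        return replace(event, effect="not_annotated", region=here[0].name)
    return replace(event, effect="intergenic")


def _annotate_coding(event: VariantEvent, genome: AnnotatedGenome,
                     r: Region) -> VariantEvent:
    gene = _gene_sequence(genome, r)
    if event.kind == "substitution":
        off = _gene_offset(r, event.ref_start)
        if off < 0 or off >= len(gene):
            return replace(event, effect="not_annotated", region=r.name)
        ci = off // 3
        codon = gene[ci * 3:ci * 3 + 3]
        if len(codon) < 3:
            return replace(event, effect="not_annotated", region=r.name)
        alt = event.alt_allele if r.strand == "+" else _revcomp(event.alt_allele)
        mutated = codon[:off % 3] + alt + codon[off % 3 + 1:]
        aa_ref, aa_alt = _translate(codon), _translate(mutated)
        effect = "synonymous" if aa_ref == aa_alt else "nonsynonymous"
        return replace(event, effect=effect, region=r.name,
                       aa_change=f"{aa_ref}{ci + 1}{aa_alt}")
    # indels and micro-reorganizations
    if event.length_change % 3 != 0:
        stretch = _frameshift_stretch(event, genome, r)
        return replace(event, effect="frameshift", region=r.name,
                       aa_change=stretch)
    if event.kind == "micro_reorganization":
        return replace(event, effect="nonsynonymous", region=r.name)
    return replace(event, effect="nonsynonymous", region=r.name)


def _frameshift_stretch(event: VariantEvent, genome: AnnotatedGenome,
                        r: Region, limit: int = 60) -> str:
    """Novel residue run read through the shifted frame, up to a stop."""
    gene = _gene_sequence(genome, r)
    off = max(_gene_offset(r, event.ref_start), 0)
    if event.kind == "insertion":
        ins = (event.alt_allele if r.strand == "+"
               else _revcomp(event.alt_allele))
        mutated = gene[:off + 1] + ins + gene[off + 1:]
    elif event.kind == "deletion":
        n = len(event.ref_allele)
        mutated = gene[:off] + gene[off + n:]
    else:
        mutated = gene
    start = (off // 3) * 3
    residues = []
    for i in range(start, min(len(mutated) - 2, start + 3 * limit), 3):
        aa = _translate(mutated[i:i + 3])
        if aa == "*":
            break
        residues.append(aa)
    return "".join(residues)


def annotate_events(events: Iterable[VariantEvent],
                    genome: AnnotatedGenome) -> list[VariantEvent]:
    return [annotate_effect(e, genome) for e in events]


# ---------------------------------------------------------------------------
# tabular output

TSV_COLUMNS = ["ref_start", "ref_end", "kind", "ref_allele", "alt_allele",
               "carriers", "component_count", "effect", "aa_change", "region"]


def write_event_table(events: Iterable[VariantEvent], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(TSV_COLUMNS)
        for e in events:
            w.writerow([e.ref_start, e.ref_end, e.kind, e.ref_allele,
                        e.alt_allele, ",".join(sorted(e.carriers)),
                        e.component_count, e.effect or "", e.aa_change or "",
                        e.region or ""])


def write_branch_counts(counts: BranchMutationCounts, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["branch", "label", "count"])
        for bid in sorted(counts.branch_counts):
            label, c = counts.branch_counts[bid]
            w.writerow([bid, label, c])
        for pattern, c in counts.unresolved_patterns:
            w.writerow(["+".join(sorted(pattern)), "unresolved", c])
        if counts.non_focal:
            w.writerow(["(none)", "non-focal", counts.non_focal])
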