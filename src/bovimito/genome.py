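"""Mitogenome records, region maps and gapped alignments.

A mitochondrial genome is held as a linear uppercase DNA string in record
orientation together with a region map (protein-coding genes, rRNAs, tRNAs,
the non-coding control region / D-loop) in 1-based inclusive coordinates, as
annotated in the source GenBank record.  A D-loop spanning the replication
origin must be annotated as two regions, matching GenBank flat-file
convention.  IUPAC ambiguity codes are retained verbatim; resolving them is
the business of downstream operations, never of I/O.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

REGION_KINDS = ("protein_coding", "rRNA", "tRNA", "d_loop", "other")

#: IUPAC nucleotide codes -> set of compatible unambiguous bases.
IUPAC = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
    "R": {"A", "G"}, "Y": {"C", "T"}, "S": {"C", "G"}, "W": {"A", "T"},
    "K": {"G", "T"}, "M": {"A", "C"},
    "B": {"C", "G", "T"}, "D": {"A", "G", "T"}, "H": {"A", "C", "T"},
    "V": {"A", "C", "G"}, "N": {"A", "C", "G", "T"},
}

GAP = "-"


class GenomeParseError(ValueError):
    """Raised when a sequence record cannot be parsed or is empty."""


@dataclass(frozen=True)
class Region:
    """One annotated span, 1-based inclusive."""

    name: str
    start: int
    end: int
    kind: str = "other"
    strand: str = "+"
    frame_offset: int = 0

    def __post_init__(self) -> None:
        if self.kind not in REGION_KINDS:
            raise ValueError(f"unknown region kind {self.kind!r}")
        if not (1 <= self.start <= self.end):
            raise ValueError(f"bad region span {self.start}..{self.end}")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end

    def overlaps(self, start: int, end: int) -> bool:
        return self.start <= end and start <= self.end


@dataclass
class AnnotatedGenome:
    """A mitogenome sequence plus its region map."""

    id: str
    sequence: str
    regions: list[Region] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise GenomeParseError(f"genome {self.id!r} has an empty sequence")
        self.sequence = self.sequence.upper().replace("U", "T")
        bad = set(self.sequence) - set(IUPAC)
        if bad:
            raise GenomeParseError(
                f"genome {self.id!r} contains non-IUPAC characters {sorted(bad)}")
        n = len(self.sequence)
        for r in self.regions:
            if r.end > n:
                raise ValueError(
                    f"region {r.name!r} ({r.start}..{r.end}) exceeds sequence "
                    f"length {n} of {self.id!r}")
        dloops = [r for r in self.regions if r.kind == "d_loop"]
        for d in dloops:
            for r in self.regions:
                if r.kind == "protein_coding" and r.overlaps(d.start, d.end):
                    raise ValueError(
                        f"d_loop {d.name!r} overlaps protein_coding {r.name!r}")

    def __len__(self) -> int:
        return len(self.sequence)

    def regions_of_kind(self, kind: str) -> list[Region]:
        return [r for r in self.regions if r.kind == kind]

    def regions_at(self, pos: int) -> list[Region]:
        return [r for r in self.regions if r.contains(pos)]


@dataclass
class MultiAlignment:
    """Equal-length gapped rows with a column -> reference coordinate map.

    ``colmap[j]`` is the 1-based position in the *reference* (``ref_id``)
    sequence that column ``j`` aligns to, or ``None`` for columns where the
    reference carries a gap (insertions relative to the reference).
    """

    taxa: list[str]
    rows: list[str]
    ref_id: str
    colmap: list[int | None] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.rows):
            raise ValueError("taxa and rows differ in length")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("duplicate taxon ids in alignment")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError(f"rows have unequal lengths {sorted(lengths)}")
        if self.ref_id not in self.taxa:
            raise ValueError(f"reference {self.ref_id!r} not among taxa")
        if not self.colmap:
            self.colmap = self._build_colmap()
        if len(self.colmap) != self.length:
            raise ValueError("colmap length does not match alignment length")

    def _build_colmap(self) -> list[int | None]:
        ref_row = self.row(self.ref_id)
        out: list[int | None] = []
        pos = 0
        for ch in ref_row:
            if ch == GAP:
                out.append(None)
            else:
                pos += 1
                out.append(pos)
        return out

    @property
    def length(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, taxon: str) -> str:
        return self.rows[self.taxa.index(taxon)]

    def degapped(self, taxon: str) -> str:
        return self.row(taxon).replace(GAP, "")

    def column(self, j: int) -> list[str]:
        return [r[j] for r in self.rows]

    def subset_columns(self, keep: Sequence[int]) -> "MultiAlignment":
        rows = ["".join(r[j] for j in keep) for r in self.rows]
        colmap = [self.colmap[j] for j in keep]
        return MultiAlignment(list(self.taxa), rows, self.ref_id, colmap)


# ---------------------------------------------------------------------------
# readers / writers

_GENBANK_KIND = {
    "CDS": "protein_coding",
    "rRNA": "rRNA",
    "tRNA": "tRNA",
    "D-loop": "d_loop",
}


def _regions_from_record(rec: SeqRecord) -> list[Region]:
    regions: list[Region] = []
    for feat in rec.features:
        kind = _GENBANK_KIND.get(feat.type)
        if kind is None:
            if feat.type == "misc_feature":
                notes = " ".join(feat.qualifiers.get("note", [])).lower()
                if "d-loop" in notes or "control region" in notes:
                    kind = "d_loop"
                else:
                    continue
            else:
                continue
        name = (feat.qualifiers.get("gene") or feat.qualifiers.get("product")
                or feat.qualifiers.get("note") or [feat.type])[0]
        # compound locations (e.g. origin-spanning D-loop) yield one region
        # per part, matching the two-region convention for circular features
        for part in feat.location.parts:
            strand = "-" if part.strand == -1 else "+"
            frame = int(feat.qualifiers.get("codon_start", ["1"])[0]) - 1
            regions.append(Region(
                name=name,
                start=int(part.start) + 1,  # biopython is 0-based half-open
                end=int(part.end),
                kind=kind,
                strand=strand,
                frame_offset=frame,
            ))
    regions.sort(key=lambda r: (r.start, r.end))
    return regions


def read_genome(path: str | Path, fmt: str = "genbank",
                region_table: str | Path | None = None) -> AnnotatedGenome:
    """Read one mitogenome record from a GenBank flat file or FASTA.

    FASTA records carry no annotation; an optional sidecar region TSV
    (columns name/start/end/kind/strand[/frame_offset]) supplies it.
    """
    path = Path(path)
    if fmt not in ("genbank", "fasta"):
        raise ValueError(f"unsupported format {fmt!r}")
    try:
        rec = next(SeqIO.parse(str(path), fmt))
    except StopIteration:
        raise GenomeParseError(f"no records in {path}") from None
    except ValueError as exc:
        raise GenomeParseError(f"malformed {fmt} record in {path}: {exc}") from exc
    seq = str(rec.seq)
    if not seq:
        raise GenomeParseError(f"record {rec.id!r} in {path} has empty sequence")
    if fmt == "genbank":
        regions = _regions_from_record(rec)
    else:
        regions = read_region_table(region_table) if region_table else []
    return AnnotatedGenome(id=rec.id, sequence=seq, regions=regions)


def write_fasta(genomes: Iterable[AnnotatedGenome], path: str | Path,
                width: int = 70) -> None:
    with open(path, "w") as fh:
        for g in genomes:
            fh.write(f">{g.id}\n")
            for i in range(0, len(g.sequence), width):
                fh.write(g.sequence[i:i + width] + "\n")


def write_genbank(genome: AnnotatedGenome, path: str | Path) -> None:
    """Write a minimal GenBank flat file preserving the region map."""
    rec = SeqRecord(Seq(genome.sequence), id=genome.id, name=genome.id[:16],
                    description="", annotations={"molecule_type": "DNA"})
    inv_kind = {v: k for k, v in _GENBANK_KIND.items()}
    for r in genome.regions:
        ftype = inv_kind.get(r.kind, "misc_feature")
        loc = FeatureLocation(r.start - 1, r.end, strand=-1 if r.strand == "-" else 1)
        quals: dict[str, list[str]] = {"gene": [r.name]}
        if r.kind == "protein_coding":
            quals["codon_start"] = [str(r.frame_offset + 1)]
        if ftype == "misc_feature" and r.kind == "d_loop":
            quals["note"] = ["control region; D-loop"]
        rec.features.append(SeqFeature(loc, type=ftype, qualifiers=quals))
    SeqIO.write([rec], str(path), "genbank")


def read_region_table(path: str | Path) -> list[Region]:
    """Read a region TSV with header name/start/end/kind/strand[/frame_offset]."""
    regions = []
    with open(path) as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            regions.append(Region(
                name=row["name"], start=int(row["start"]), end=int(row["end"]),
                kind=row.get("kind", "other"), strand=row.get("strand", "+"),
                frame_offset=int(row.get("frame_offset", 0) or 0)))
    return regions


def write_region_table(regions: Iterable[Region], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["name", "start", "end", "kind", "strand", "frame_offset"])
        for r in regions:
            w.writerow([r.name, r.start, r.end, r.kind, r.strand, r.frame_offset])


def read_alignment(path: str | Path, ref_id: str | None = None) -> MultiAlignment:
    """Read an aligned multi-FASTA; the first record is the reference unless
    ``ref_id`` says otherwise."""
    taxa, rows = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        taxa.append(rec.id)
        rows.append(str(rec.seq).upper().replace("U", "T"))
    if not taxa:
        raise GenomeParseError(f"no aligned records in {path}")
    return MultiAlignment(taxa, rows, ref_id or taxa[0])


def write_alignment(aln: MultiAlignment, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for taxon, row in zip(aln.taxa, aln.rows):
            fh.write(f">{taxon}\n")
            for i in range(0, len(row), width):
                fh.write(row[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# D-loop exclusion

def extract_coding_alignment(
    aln: MultiAlignment,
    genomes: Mapping[str, AnnotatedGenome],
) -> MultiAlignment:
    """Restrict an alignment to columns outside the reference's D-loop.

    The control region evolves far faster than the rest of the molecule and
    is dropped before any distance or likelihood computation.  Exclusion is
    defined in the *reference* coordinate frame: a column is removed when its
    reference coordinate falls inside any ``d_loop`` region of the reference
    genome; insertion columns (no reference coordinate) are removed when
    anchored inside the D-loop.  Idempotent.
    """
    missing = [t for t in aln.taxa if t not in genomes]
    if missing:
        raise ValueError(
            "D-loop exclusion requested but taxa lack annotation: "
            + ", ".join(missing))
    ref_genome = genomes[aln.ref_id]
    dloops = ref_genome.regions_of_kind("d_loop")
    if not dloops:
        return aln

    def excluded(pos: int | None, anchor: int) -> bool:
        p = pos if pos is not None else anchor
        return p > 0 and any(d.contains(p) for d in dloops)

    keep = []
    anchor = 0  # last defined reference coordinate
    for j, pos in enumerate(aln.colmap):
        if pos is not None:
            anchor = pos
        if not excluded(pos, anchor):
            keep.append(j)
    return aln.subset_columns(keep)
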