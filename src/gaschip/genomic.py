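"""Core genomic data model and format I/O.

All in-memory coordinates are 0-based, half-open.  Conversion to and from
other conventions (GFF3 is 1-based, fully closed) happens only at the format
boundary, never inside the analysis code.

The three central containers are :class:`GenomeSequence` (chromosome name ->
uppercase DNA string), :class:`GeneModel` (a stranded gene with ordered exons,
from which introns and their transcription-direction ordinals are derived) and
:class:`ClonedSite` (a mapped ChIP fragment interval, optionally carrying its
plus-strand sequence).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

DNA_ALPHABET = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string over {A,C,G,T,N}; N maps to N.

    The operation is an involution: ``reverse_complement(reverse_complement(s))
    == s`` for any valid input.
    """
    bad = set(seq) - DNA_ALPHABET
    if bad:
        raise ValueError(f"non-DNA characters in sequence: {sorted(bad)}")
    return seq.translate(_COMPLEMENT)[::-1]


class GenomeSequence:
    """Uppercase DNA sequences keyed by unique chromosome name."""

    def __init__(self, sequences: dict[str, str]):
        if not sequences:
            raise ValueError("genome must contain at least one sequence")
        normalized: dict[str, str] = {}
        for name, seq in sequences.items():
            if not seq:
                raise ValueError(f"chromosome {name!r} has an empty sequence")
            seq = seq.upper()
            bad = set(seq) - DNA_ALPHABET
            if bad:
                raise ValueError(
                    f"chromosome {name!r} contains non-DNA characters: {sorted(bad)}"
                )
            normalized[name] = seq
        self._sequences = normalized

    @property
    def chrom_names(self) -> list[str]:
        return list(self._sequences)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._sequences

    def __getitem__(self, chrom: str) -> str:
        return self._sequences[chrom]

    def length(self, chrom: str) -> int:
        return len(self._sequences[chrom])

    def items(self):
        return self._sequences.items()

    def __eq__(self, other) -> bool:
        return isinstance(other, GenomeSequence) and self._sequences == other._sequences

    def __repr__(self) -> str:
        return f"GenomeSequence({len(self._sequences)} chromosomes)"


@dataclass(frozen=True)
class GeneModel:
    """A stranded, multi-exon gene.

    Introns are the gaps between consecutive exons; their ordinals are
    assigned in transcription direction, so intron 1 is always the intron
    nearest the TSS (the first genomic gap on the + strand, the last on the
    - strand).
    """

    gene_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: unknown strand {self.strand!r}")
        if not (0 <= self.tx_start < self.tx_end):
            raise ValueError(f"gene {self.gene_id}: invalid span")
        exons = tuple(tuple(e) for e in self.exons)
        if not exons:
            raise ValueError(f"gene {self.gene_id}: needs at least one exon")
        object.__setattr__(self, "exons", exons)
        prev_end = None
        for s, e in exons:
            if not (self.tx_start <= s < e <= self.tx_end):
                raise ValueError(
                    f"gene {self.gene_id}: exon [{s},{e}) outside span "
                    f"[{self.tx_start},{self.tx_end})"
                )
            if prev_end is not None and s < prev_end:
                raise ValueError(f"gene {self.gene_id}: exons overlap or unsorted")
            prev_end = e

    @property
    def tss(self) -> int:
        """Transcription start site (0-based base position)."""
        return self.tx_start if self.strand == "+" else self.tx_end - 1

    @property
    def introns(self) -> list[tuple[int, int]]:
        """Genomically ordered intron intervals (gaps between exons)."""
        return [
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        ]

    def introns_with_ordinals(self) -> list[tuple[int, int, int]]:
        """(start, end, ordinal) per intron; ordinal 1 is nearest the TSS."""
        introns = self.introns
        n = len(introns)
        if self.strand == "+":
            return [(s, e, i + 1) for i, (s, e) in enumerate(introns)]
        return [(s, e, n - i) for i, (s, e) in enumerate(introns)]

    def upstream_distance(self, pos: int) -> int | None:
        """Strand-aware distance from `pos` to the TSS if `pos` lies 5' of it.

        Returns None when `pos` is at or downstream of the TSS.
        """
        d = self.tss - pos if self.strand == "+" else pos - self.tss
        return d if d > 0 else None


@dataclass(frozen=True)
class ClonedSite:
    """A mapped ChIP-cloned fragment interval, optionally with its sequence.

    Sequences are stored in plus-strand orientation; assembly is a free-text
    tag (the coordinate system is whatever the input was mapped against).
    """

    site_id: str
    chrom: str
    start: int
    end: int
    sequence: str | None = None
    assembly: str | None = None

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(
                f"site {self.site_id}: start {self.start} >= end {self.end}"
            )
        if self.sequence is not None and len(self.sequence) != self.end - self.start:
            raise ValueError(
                f"site {self.site_id}: sequence length {len(self.sequence)} != "
                f"interval length {self.end - self.start}"
            )

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> GenomeSequence:
    """Read a FASTA file into a :class:`GenomeSequence`.

    Record names are the first whitespace-delimited token of each header;
    duplicate names are an error, sequences are uppercased on load.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.strip():
                if not line.startswith(">"):
                    raise ValueError(
                        f"{path}: line {lineno}: expected FASTA header, got {line.strip()!r}"
                    )
                break
        else:
            raise ValueError(f"{path}: empty FASTA file")
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in sequences:
            raise ValueError(f"{path}: duplicate sequence name {record.id!r}")
        sequences[record.id] = str(record.seq)
    return GenomeSequence(sequences)


def write_fasta(sequences: dict[str, str] | GenomeSequence, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Gene models: GFF3 and BED12
# ---------------------------------------------------------------------------

def read_gene_models(path: str | Path, format: str = "gff3") -> list[GeneModel]:
    """Read gene models from GFF3 or BED12 into 0-based half-open coordinates."""
    if format == "gff3":
        return _read_gff3(path)
    if format == "bed12":
        return _read_bed12(path)
    raise ValueError(f"unknown gene-model format {format!r}")


def _read_gff3(path: str | Path) -> list[GeneModel]:
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    genes = []
    for gene in db.features_of_type("gene"):
        exons = sorted(
            (ex.start - 1, ex.end)  # GFF3 1-based closed -> 0-based half-open
            for ex in db.children(gene, featuretype="exon")
        )
        if not exons:
            raise ValueError(f"gene {gene.id}: no exon features in {path}")
        genes.append(
            GeneModel(
                gene_id=gene.id,
                chrom=gene.seqid,
                strand=gene.strand,
                tx_start=gene.start - 1,
                tx_end=gene.end,
                exons=tuple(exons),
            )
        )
    genes.sort(key=lambda g: (g.chrom, g.tx_start, g.gene_id))
    return genes


def _read_bed12(path: str | Path) -> list[GeneModel]:
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise ValueError(f"{path}: line {lineno}: expected 12 BED fields")
            chrom, start, end, name, _score, strand = fields[:6]
            start, end = int(start), int(end)
            n_blocks = int(fields[9])
            sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
            offsets = [int(x) for x in fields[11].rstrip(",").split(",")]
            if len(sizes) != n_blocks or len(offsets) != n_blocks:
                raise ValueError(f"{path}: line {lineno}: block count mismatch")
            exons = tuple(
                (start + off, start + off + size)
                for off, size in zip(offsets, sizes)
            )
            genes.append(
                GeneModel(
                    gene_id=name,
                    chrom=chrom,
                    strand=strand,
                    tx_start=start,
                    tx_end=end,
                    exons=exons,
                )
            )
    genes.sort(key=lambda g: (g.chrom, g.tx_start, g.gene_id))
    return genes


def write_gene_models(genes: Sequence[GeneModel], path: str | Path,
                      format: str = "gff3") -> None:
    """Write gene models as GFF3 (gene + exon features) or BED12."""
    path = Path(path)
    if format == "gff3":
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for g in genes:
                fh.write(
                    f"{g.chrom}\t.\tgene\t{g.tx_start + 1}\t{g.tx_end}\t.\t"
                    f"{g.strand}\t.\tID={g.gene_id}\n"
                )
                for i, (s, e) in enumerate(g.exons, 1):
                    fh.write(
                        f"{g.chrom}\t.\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                        f"ID={g.gene_id}.exon{i};Parent={g.gene_id}\n"
                    )
    elif format == "bed12":
        with open(path, "w") as fh:
            for g in genes:
                sizes = ",".join(str(e - s) for s, e in g.exons)
                offsets = ",".join(str(s - g.tx_start) for s, _ in g.exons)
                fh.write(
                    f"{g.chrom}\t{g.tx_start}\t{g.tx_end}\t{g.gene_id}\t0\t"
                    f"{g.strand}\t{g.tx_start}\t{g.tx_end}\t0\t"
                    f"{len(g.exons)}\t{sizes}\t{offsets}\n"
                )
    else:
        raise ValueError(f"unknown gene-model format {format!r}")


# ---------------------------------------------------------------------------
# Cloned sites: BED and the supplementary clone table
# ---------------------------------------------------------------------------

def read_sites(path: str | Path) -> list[ClonedSite]:
    """Read BED3+ intervals as cloned sites, deduplicating exact coordinates.

    Records with identical (chrom, start, end) are merged (first name kept);
    the unique-site count is logged, matching how a clone library is reported
    as "unique binding sites" after mapping.
    """
    path = Path(path)
    sites: list[ClonedSite] = []
    seen: set[tuple[str, int, int]] = set()
    n_records = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno}: expected >= 3 BED fields")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if start >= end:
                raise ValueError(
                    f"{path}: line {lineno}: start {start} >= end {end}"
                )
            n_records += 1
            key = (chrom, start, end)
            if key in seen:
                continue
            seen.add(key)
            name = fields[3] if len(fields) > 3 else f"site_{len(sites) + 1}"
            sites.append(ClonedSite(site_id=name, chrom=chrom, start=start, end=end))
    if n_records == 0:
        logger.warning("%s: empty site file, returning empty cohort", path)
    logger.info("%s: %d records, %d unique sites", path, n_records, len(sites))
    return sites


def write_sites(sites: Iterable[ClonedSite], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in sites:
            fh.write(f"{s.chrom}\t{s.start}\t{s.end}\t{s.site_id}\n")


def dedupe_sites(sites: Iterable[ClonedSite]) -> list[ClonedSite]:
    """Drop later sites with exactly duplicated (chrom, start, end)."""
    seen: set[tuple[str, int, int]] = set()
    out = []
    for s in sites:
        key = (s.chrom, s.start, s.end)
        if key in seen:
            continue
        seen.add(key)
        out.append(s)
    return out


def read_clone_table_xlsx(
    path: str | Path,
    chrom_col: str = "chrom",
    start_col: str = "start",
    end_col: str = "end",
    id_col: str | None = None,
    assembly_col: str | None = None,
    one_based: bool = False,
) -> list[ClonedSite]:
    """Read a mapped-clone table (XLSX) into deduplicated cloned sites.

    The column mapping is configurable because clone tables vary in layout;
    set ``one_based=True`` for genome-browser style coordinates (1-based,
    fully closed).  The assembly column, when present, is stored as a free
    text tag and never converted between assemblies.
    """
    import openpyxl

    wb = openpyxl.load_workbook(str(path), read_only=True, data_only=True)
    ws = wb.active
    rows = ws.iter_rows(values_only=True)
    header = [str(c).strip() if c is not None else "" for c in next(rows)]
    try:
        ichrom = header.index(chrom_col)
        istart = header.index(start_col)
        iend = header.index(end_col)
    except ValueError as exc:
        raise ValueError(f"{path}: missing expected column: {exc}") from exc
    iid = header.index(id_col) if id_col else None
    iasm = header.index(assembly_col) if assembly_col else None
    sites = []
    for i, row in enumerate(rows, 1):
        if row is None or row[ichrom] is None:
            continue
        start, end = int(row[istart]), int(row[iend])
        if one_based:
            start -= 1
        sites.append(
            ClonedSite(
                site_id=str(row[iid]) if iid is not None else f"clone_{i}",
                chrom=str(row[ichrom]),
                start=start,
                end=end,
                assembly=str(row[iasm]) if iasm is not None else None,
            )
        )
    wb.close()
    unique = dedupe_sites(sites)
    logger.info("%s: %d rows, %d unique sites", path, len(sites), len(unique))
    return unique


def extract_site_sequences(
    sites: Sequence[ClonedSite], genome: GenomeSequence
) -> list[ClonedSite]:
    """Fill each site's sequence from the genome (plus strand, [start, end))."""
    out = []
    for s in sites:
        if s.chrom not in genome:
            raise ValueError(f"site {s.site_id}: chromosome {s.chrom!r} not in genome")
        if s.end > genome.length(s.chrom):
            raise ValueError(
                f"site {s.site_id}: end {s.end} beyond chromosome "
                f"{s.chrom} length {genome.length(s.chrom)}"
            )
        out.append(replace(s, sequence=genome[s.chrom][s.start:s.end]))
    return out
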