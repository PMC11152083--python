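"""Readers and writers for the on-disk formats the scan consumes and emits.

All in-memory coordinates are 0-based, half-open.  GFF3 (1-based inclusive
on disk) is converted at the boundary; MAF minus-strand rows are normalised
to forward-strand source coordinates at parse time, so downstream windowing
never has to reason about strand.
"""

from __future__ import annotations

import logging
import os
import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
from Bio import AlignIO, SeqIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger("divscan")

# IUPAC nucleotide alphabet; everything outside it is a parse error.
# Codes other than ACGT are treated as N by the counting layer.
_VALID_NT = re.compile(r"^[ACGTUNRYSWKMBDHV]*$", re.IGNORECASE)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class SequenceRecord:
    """One scaffold: name plus nucleotide string (case preserved;
    lowercase means soft-masked)."""

    id: str
    seq: str

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class Assembly:
    """An ordered collection of scaffolds."""

    records: list[SequenceRecord]
    name: str = ""

    def __len__(self) -> int:
        return len(self.records)

    @property
    def total_length(self) -> int:
        return sum(len(r) for r in self.records)

    def chrom_sizes(self) -> dict[str, int]:
        return {r.id: len(r) for r in self.records}


@dataclass
class AssemblyStats:
    """Quast-style scaffold metrics over scaffolds longer than ``min_len_filter``."""

    total_len: int
    n_scaffolds: int
    n_ge_5kb: int
    n_ge_50kb: int
    largest: int
    n50: int
    gc_pct: float
    n_pct: float
    min_len_filter: int


@dataclass(frozen=True, order=True)
class GenomeInterval:
    """Half-open interval [start, end) on a scaffold."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GeneModel:
    """A gene interval with strand and the strand-aware 5' end.

    ``start_codon_pos`` is the gene's 5'-most base: ``interval.start`` on the
    plus strand, ``interval.end - 1`` on the minus strand.  It stands in for
    the annotated start codon in the proximity rule.
    """

    gene_id: str
    interval: GenomeInterval
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")

    @property
    def start_codon_pos(self) -> int:
        return self.interval.start if self.strand == "+" else self.interval.end - 1


@dataclass(frozen=True)
class PafRecord:
    """One pairwise alignment record (minimap2 PAF dialect, 12 mandatory columns)."""

    qname: str
    qlen: int
    qstart: int
    qend: int
    strand: str
    tname: str
    tlen: int
    tstart: int
    tend: int
    n_match: int
    block_len: int
    mapq: int

    def __post_init__(self) -> None:
        if not (0 <= self.qstart < self.qend <= self.qlen):
            raise ValueError(f"PAF query coordinates out of order: {self}")
        if not (0 <= self.tstart < self.tend <= self.tlen):
            raise ValueError(f"PAF target coordinates out of order: {self}")
        if self.n_match > self.block_len:
            raise ValueError(f"PAF n_match > block_len: {self}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"PAF strand must be + or -: {self}")


@dataclass(frozen=True)
class MafRow:
    """One species row of a MAF block, with forward-strand source coordinates.

    ``start`` is always on the forward strand of the source sequence
    (minus-strand rows are flipped with ``src_size`` at parse time); ``text``
    keeps the alignment orientation as printed, which is what column-wise
    comparison needs.
    """

    species: str
    chrom: str
    start: int
    size: int
    strand: str
    src_size: int
    text: str


@dataclass
class MafBlock:
    rows: list[MafRow]

    @property
    def width(self) -> int:
        return len(self.rows[0].text) if self.rows else 0

    def row_for(self, species: str) -> MafRow | None:
        for r in self.rows:
            if r.species == species:
                return r
        return None


class ChromosomeClassMap(dict):
    """scaffold id -> chromosome class {autosome, Z, W, exclude}."""

    CLASSES = ("autosome", "Z", "W", "exclude")

    def __setitem__(self, key: str, value: str) -> None:
        if value not in self.CLASSES:
            raise ValueError(f"unknown chromosome class {value!r} for {key}")
        super().__setitem__(key, value)

    def class_of(self, chrom: str) -> str:
        if chrom not in self:
            raise KeyError(f"scaffold {chrom} has no chromosome class")
        return self[chrom]


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | os.PathLike, name: str | None = None) -> Assembly:
    """Read a FASTA file into an :class:`Assembly`.

    Case is preserved (lowercase = soft-masked).  Duplicate record ids and
    symbols outside the IUPAC nucleotide alphabet raise ``ValueError`` (the
    error names the offending record and 0-based offset).  An empty file
    yields an empty assembly with a warning.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA record id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq)
        if not _VALID_NT.match(seq):
            bad = next(i for i, c in enumerate(seq) if not _VALID_NT.match(c))
            raise ValueError(
                f"non-nucleotide symbol {seq[bad]!r} in record {rec.id!r} "
                f"at offset {bad}"
            )
        records.append(SequenceRecord(rec.id, seq))
    if not records:
        log.warning("FASTA file %s contains no records", path)
    return Assembly(records, name=name or os.path.basename(str(path)))


def write_fasta(assembly: Assembly, path: str | os.PathLike, width: int = 80) -> None:
    with open(path, "w") as fh:
        for rec in assembly.records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# assembly statistics
# ---------------------------------------------------------------------------

def n50(lengths: Sequence[int]) -> int:
    """Largest L such that scaffolds of length >= L cover at least half the total."""
    arr = np.sort(np.asarray(lengths, dtype=np.int64))[::-1]
    if arr.size == 0:
        raise ValueError("n50 of empty length set")
    half = arr.sum() / 2.0
    idx = int(np.searchsorted(np.cumsum(arr), half))
    return int(arr[idx])


def assembly_stats(assembly: Assembly, min_len: int = 500) -> AssemblyStats:
    """Quast-style scaffold metrics over scaffolds strictly longer than ``min_len``.

    GC% uses A/C/G/T as denominator (N excluded), case-insensitive, so
    soft-masked bases count as their base.  N% is over the full filtered
    length.
    """
    if min_len < 0:
        raise ValueError("min_len must be >= 0")
    kept = [r for r in assembly.records if len(r) > min_len]
    if not kept:
        raise ValueError(f"no scaffold longer than {min_len} bp")
    lengths = [len(r) for r in kept]
    total = int(sum(lengths))
    counts = {b: 0 for b in "ACGTN"}
    for r in kept:
        up = r.seq.upper()
        for b in counts:
            counts[b] += up.count(b)
    acgt = sum(counts[b] for b in "ACGT")
    return AssemblyStats(
        total_len=total,
        n_scaffolds=len(kept),
        n_ge_5kb=sum(l >= 5_000 for l in lengths),
        n_ge_50kb=sum(l >= 50_000 for l in lengths),
        largest=int(max(lengths)),
        n50=n50(lengths),
        gc_pct=100.0 * (counts["G"] + counts["C"]) / acgt if acgt else float("nan"),
        n_pct=100.0 * counts["N"] / total,
        min_len_filter=min_len,
    )


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def read_gff_genes(path: str | os.PathLike) -> list[GeneModel]:
    """Extract features of type ``gene`` from a GFF3 file.

    Coordinates are converted from 1-based inclusive to 0-based half-open.
    A gene without a strand raises (the proximity rule needs the 5' end).
    Transcript/CDS children are ignored.
    """
    import gffutils

    with open(path) as fh:
        has_features = any(
            line.strip() and not line.startswith("#") for line in fh
        )
    if not has_features:
        return []
    db = gffutils.create_db(
        str(path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    genes: list[GeneModel] = []
    for feat in db.features_of_type("gene", order_by=("seqid", "start")):
        if feat.strand not in ("+", "-"):
            raise ValueError(
                f"gene {feat.id} on {feat.seqid} lacks a strand; "
                "the start-codon proximity rule requires one"
            )
        genes.append(
            GeneModel(
                gene_id=feat.id,
                interval=GenomeInterval(feat.seqid, feat.start - 1, feat.end),
                strand=feat.strand,
            )
        )
    return genes


def write_gff_genes(genes: Iterable[GeneModel], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                "\t".join(
                    [
                        g.interval.chrom,
                        "divscan",
                        "gene",
                        str(g.interval.start + 1),
                        str(g.interval.end),
                        ".",
                        g.strand,
                        ".",
                        f"ID={g.gene_id}",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# PAF
# ---------------------------------------------------------------------------

def read_paf(path: str | os.PathLike) -> list[PafRecord]:
    """Parse a PAF file (12 mandatory columns; optional SAM-like tags ignored).

    No installed library reads PAF, so this is a minimal hand parser.
    Malformed lines raise ``ValueError`` naming the 1-based line number.
    """
    records: list[PafRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) < 12:
                raise ValueError(
                    f"{path}: line {lineno}: expected >=12 PAF columns, "
                    f"got {len(cols)}"
                )
            try:
                rec = PafRecord(
                    qname=cols[0],
                    qlen=int(cols[1]),
                    qstart=int(cols[2]),
                    qend=int(cols[3]),
                    strand=cols[4],
                    tname=cols[5],
                    tlen=int(cols[6]),
                    tstart=int(cols[7]),
                    tend=int(cols[8]),
                    n_match=int(cols[9]),
                    block_len=int(cols[10]),
                    mapq=int(cols[11]),
                )
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from exc
            records.append(rec)
    return records


def write_paf(records: Iterable[PafRecord], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        r.qname, r.qlen, r.qstart, r.qend, r.strand,
                        r.tname, r.tlen, r.tstart, r.tend,
                        r.n_match, r.block_len, r.mapq,
                    )
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# MAF
# ---------------------------------------------------------------------------

def _split_src(src: str) -> tuple[str, str]:
    # MAF convention: src = "species.chrom"; chrom may itself contain dots.
    if "." in src:
        sp, chrom = src.split(".", 1)
        return sp, chrom
    return src, src


def read_maf(path: str | os.PathLike) -> Iterator[MafBlock]:
    """Stream MAF alignment blocks.

    Minus-strand rows are converted to forward-strand source coordinates
    (``start_fwd = src_size - start - size``); the aligned text keeps the
    printed alignment orientation.  Rows of unequal aligned width raise.
    """
    with open(path) as fh:
        for aln in AlignIO.parse(fh, "maf"):
            widths = {len(rec.seq) for rec in aln}
            if len(widths) > 1:
                raise ValueError(f"{path}: MAF block rows have unequal widths {widths}")
            rows = []
            for rec in aln:
                ann = rec.annotations
                species, chrom = _split_src(rec.id)
                start = int(ann["start"])
                size = int(ann["size"])
                src_size = int(ann["srcSize"])
                strand = "+" if ann["strand"] in (1, "+") else "-"
                if strand == "-":
                    start = src_size - start - size
                rows.append(
                    MafRow(
                        species=species,
                        chrom=chrom,
                        start=start,
                        size=size,
                        strand=strand,
                        src_size=src_size,
                        text=str(rec.seq),
                    )
                )
            yield MafBlock(rows)


def write_maf(blocks: Iterable[MafBlock], path: str | os.PathLike) -> None:
    """Write MAF blocks (forward-coordinate rows are emitted as stored)."""
    alns = []
    for block in blocks:
        recs = []
        for r in block.rows:
            start = r.start
            if r.strand == "-":
                start = r.src_size - r.start - r.size
            recs.append(
                SeqRecord(
                    Seq(r.text),
                    id=f"{r.species}.{r.chrom}",
                    annotations={
                        "start": start,
                        "size": r.size,
                        "strand": 1 if r.strand == "+" else -1,
                        "srcSize": r.src_size,
                    },
                )
            )
        alns.append(MultipleSeqAlignment(recs))
    with open(path, "w") as fh:
        AlignIO.write(alns, fh, "maf")


# ---------------------------------------------------------------------------
# intervals (BED / TSV)
# ---------------------------------------------------------------------------

def write_intervals(
    intervals: Iterable[GenomeInterval],
    path: str | os.PathLike,
    fmt: str = "BED",
    extra: pd.DataFrame | None = None,
) -> None:
    """Write intervals as BED (0-based half-open, no header) or TSV (with
    header, optional extra columns)."""
    rows = [(iv.chrom, iv.start, iv.end) for iv in intervals]
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    if fmt.upper() == "BED":
        df.to_csv(path, sep="\t", header=False, index=False)
    elif fmt.upper() == "TSV":
        if extra is not None:
            df = pd.concat([df, extra.reset_index(drop=True)], axis=1)
        df.to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown interval format {fmt!r}")


def read_intervals(path: str | os.PathLike, fmt: str = "BED") -> list[GenomeInterval]:
    if fmt.upper() == "BED":
        df = pd.read_csv(path, sep="\t", header=None, usecols=[0, 1, 2],
                         names=["chrom", "start", "end"])
    elif fmt.upper() == "TSV":
        df = pd.read_csv(path, sep="\t")
    else:
        raise ValueError(f"unknown interval format {fmt!r}")
    return [
        GenomeInterval(str(r.chrom), int(r.start), int(r.end))
        for r in df.itertuples(index=False)
    ]


def read_class_map(path: str | os.PathLike) -> ChromosomeClassMap:
    cmap = ChromosomeClassMap()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            chrom, cls = line.split("\t")[:2]
            if chrom == "chrom" and cls == "class":
                continue
            cmap[chrom] = cls
    return cmap


def write_class_map(cmap: ChromosomeClassMap, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tclass\n")
        for chrom, cls in cmap.items():
            fh.write(f"{chrom}\t{cls}\n")
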