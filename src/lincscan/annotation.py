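"""Transcript models and GTF/BED-like/FASTA readers and writers.

GTF I/O follows the Ensembl attribute dialect (``gene_id "x"; transcript_id
"y";``).  GTF coordinates are 1-based inclusive on disk and converted to the
package-internal 0-based half-open convention on read.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import intervals
from .intervals import GenomicInterval

HEADER_PREFIX = "#"

BIOTYPES = ("coding", "lincRNA_known", "candidate", "other")


@dataclass(frozen=True)
class TranscriptModel:
    """A stranded, exon-structured transcript.

    ``exons`` are sorted, non-overlapping, share one chromosome and strand.
    ``interval`` is the genomic span (min exon start to max exon end).
    """

    transcript_id: str
    gene_id: str
    exons: tuple[GenomicInterval, ...]
    biotype: str = "other"

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: transcript must have >= 1 exon")
        chroms = {e.chrom for e in self.exons}
        if len(chroms) != 1:
            raise ValueError(
                f"{self.transcript_id}: exons on multiple chromosomes {sorted(chroms)}"
            )
        strands = {e.strand for e in self.exons}
        if len(strands) != 1:
            raise ValueError(f"{self.transcript_id}: exons on mixed strands")
        prev_end = None
        for e in self.exons:
            if prev_end is not None and e.start < prev_end:
                raise ValueError(f"{self.transcript_id}: exons unsorted or overlapping")
            prev_end = e.end
        if self.biotype not in BIOTYPES:
            raise ValueError(f"{self.transcript_id}: unknown biotype {self.biotype!r}")

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(
            self.exons[0].chrom,
            self.exons[0].start,
            self.exons[-1].end,
            self.exons[0].strand,
        )

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def n_exons(self) -> int:
        return len(self.exons)


@dataclass(frozen=True)
class QTLRecord:
    """A named, unstranded genomic interval associated with a trait."""

    qtl_id: str
    interval: GenomicInterval
    trait: str
    trait_type: str
    trait_class: str

    def __post_init__(self) -> None:
        for name in ("trait", "trait_type", "trait_class"):
            if not getattr(self, name):
                raise ValueError(f"{self.qtl_id}: {name} must be non-empty")


def transcript_length(t: TranscriptModel) -> int:
    """Mature transcript length: the sum of exon lengths.

    This (not the genomic span) is the length the >200 bp lincRNA definition
    refers to; the span is available as ``len(t.interval)``.
    """
    return sum(len(e) for e in t.exons)


_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_attributes(field: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(field))


def read_gtf(path: str | Path) -> list[TranscriptModel]:
    """Read transcripts from a GTF file (exon features only).

    Transcripts are reconstructed by grouping exon rows on
    ``transcript_id``; 1-based inclusive coordinates become 0-based
    half-open.  Raises ValueError naming the offending line when a mandatory
    attribute is missing, and a structural error if one transcript's exons
    sit on mixed chromosomes or strands.
    """
    path = Path(path)
    groups: dict[str, dict] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ValueError(f"{path}:{lineno}: expected 9 tab-separated GTF fields")
            chrom, _source, feature, start, end, _score, strand, _frame, attrs = fields[:9]
            if feature != "exon":
                continue
            attr = _parse_attributes(attrs)
            for mandatory in ("gene_id", "transcript_id"):
                if mandatory not in attr:
                    raise ValueError(f"{path}:{lineno}: missing mandatory attribute {mandatory}")
            tid = attr["transcript_id"]
            exon = GenomicInterval(chrom, int(start) - 1, int(end), strand)
            if tid not in groups:
                groups[tid] = {
                    "gene_id": attr["gene_id"],
                    "biotype": attr.get("transcript_biotype", "other"),
                    "exons": [],
                }
                order.append(tid)
            groups[tid]["exons"].append(exon)
    transcripts = []
    for tid in order:
        g = groups[tid]
        exons = tuple(sorted(g["exons"], key=lambda e: e.start))
        biotype = g["biotype"] if g["biotype"] in BIOTYPES else "other"
        transcripts.append(
            TranscriptModel(transcript_id=tid, gene_id=g["gene_id"], exons=exons, biotype=biotype)
        )
    return transcripts


def write_gtf(transcripts: Iterable[TranscriptModel], path: str | Path, source: str = "lincscan") -> None:
    """Write exon rows in 1-based inclusive coordinates.

    Records are sorted by (chrom, span start, transcript_id) so output is
    stable; a ``#`` header line records the tool version.
    """
    from . import __version__

    ts = sorted(transcripts, key=lambda t: (t.chrom, t.interval.start, t.transcript_id))
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"{HEADER_PREFIX} lincscan {__version__} GTF export\n")
        for t in ts:
            for e in t.exons:
                attrs = (
                    f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}"; '
                    f'transcript_biotype "{t.biotype}";'
                )
                fh.write(
                    "\t".join(
                        [
                            e.chrom,
                            source,
                            "exon",
                            str(e.start + 1),
                            str(e.end),
                            ".",
                            e.strand,
                            ".",
                            attrs,
                        ]
                    )
                    + "\n"
                )


QTL_COLUMNS = ["chrom", "start", "end", "qtl_id", "trait", "trait_type", "trait_class"]


def read_qtl_table(path: str | Path) -> list[QTLRecord]:
    """Read a BED-like QTL TSV (0-based half-open coordinates)."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None, names=QTL_COLUMNS)
    records = []
    for row in df.itertuples(index=False):
        records.append(
            QTLRecord(
                qtl_id=str(row.qtl_id),
                interval=GenomicInterval(str(row.chrom), int(row.start), int(row.end), "."),
                trait=str(row.trait),
                trait_type=str(row.trait_type),
                trait_class=str(row.trait_class),
            )
        )
    return records


def write_qtl_table(records: Iterable[QTLRecord], path: str | Path) -> None:
    from . import __version__

    recs = sorted(records, key=lambda r: (r.interval.chrom, r.interval.start, r.qtl_id))
    with open(path, "w") as fh:
        fh.write(f"{HEADER_PREFIX} lincscan {__version__} QTL table: " + "\t".join(QTL_COLUMNS) + "\n")
        for r in recs:
            fh.write(
                "\t".join(
                    [
                        r.interval.chrom,
                        str(r.interval.start),
                        str(r.interval.end),
                        r.qtl_id,
                        r.trait,
                        r.trait_type,
                        r.trait_class,
                    ]
                )
                + "\n"
            )


def read_fasta(path: str | Path) -> dict[str, str]:
    """Sequences keyed by record id."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sorted(sequences.items())
    ]
    SeqIO.write(records, str(path), "fasta")


def spliced_sequence(t: TranscriptModel, chrom_seq: str) -> str:
    """Mature (exon-concatenated) sequence of a transcript on the + genome
    strand; reverse-complemented for minus-strand transcripts."""
    seq = "".join(chrom_seq[e.start : e.end] for e in t.exons)
    if t.strand == "-":
        seq = str(Seq(seq).reverse_complement())
    return seq


def span_map(transcripts: Sequence[TranscriptModel]) -> dict[str, GenomicInterval]:
    """transcript_id -> genomic span, a common input to the intersect engine."""
    return {t.transcript_id: t.interval for t in transcripts}
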