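"""The lincRNA identification cascade.

Six predicates classify each assembled transcript:

1. intergenic — the genomic span overlaps no reference transcript span, on
   either strand (the intergenic class of a reference comparison);
2. length > 200 bp (mature, exon-summed length; strict);
3. >= 2 exons;
4. coding score < 0 (strict) — an ORF-fraction heuristic standing in for a
   trained coding-potential classifier, with the same sign convention
   (negative = non-coding);
5. no protein/domain hit — exact peptide k-mer match of any 6-frame
   translation against a supplied protein set, a defined stand-in for
   database homology/domain search;
6. FPKM > 0.5 (strict) in at least one sample.

All predicates are evaluated for every transcript (no short-circuiting), so
each rejected candidate carries a full audit trail.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from Bio.Seq import Seq

from .annotation import TranscriptModel, span_map, transcript_length
from .expression import ExpressionMatrix
from .intervals import GenomicInterval, intersect

STOP_CODONS = {"TAA", "TAG", "TGA"}

FILTER_NAMES = (
    "intergenic",
    "length_gt_200",
    "exons_ge_2",
    "coding_score_lt_0",
    "no_domain_hit",
    "fpkm_gt_0.5_any_sample",
)


@dataclass(frozen=True)
class IdentifyConfig:
    """Thresholds of the cascade. Defaults follow the standard lincRNA
    definition (length strictly > 200 bp, >= 2 exons, coding score < 0,
    FPKM strictly > 0.5 in >= 1 sample)."""

    min_length: int = 200
    min_exons: int = 2
    coding_cutoff: float = 0.35
    peptide_k: int = 8
    min_fpkm: float = 0.5


@dataclass(frozen=True)
class FilterTrail:
    """Per-filter pass/fail record for one candidate."""

    results: Mapping[str, bool]
    coding_score: float
    max_fpkm: float

    def __post_init__(self) -> None:
        missing = set(FILTER_NAMES) - set(self.results)
        if missing:
            raise ValueError(f"trail missing filters: {sorted(missing)}")

    @property
    def all_pass(self) -> bool:
        return all(self.results[name] for name in FILTER_NAMES)

    def failed(self) -> list[str]:
        return [name for name in FILTER_NAMES if not self.results[name]]


@dataclass(frozen=True)
class LincCall:
    """One classified candidate: transcript, audit trail, status, novelty."""

    transcript: TranscriptModel
    trail: FilterTrail
    status: str  # "lincRNA" | "rejected"
    novelty: str = "n/a"  # "known" | "novel" | "n/a"

    def __post_init__(self) -> None:
        if self.status not in ("lincRNA", "rejected"):
            raise ValueError(f"bad status {self.status!r}")
        if self.novelty not in ("known", "novel", "n/a"):
            raise ValueError(f"bad novelty {self.novelty!r}")
        if self.status != "lincRNA" and self.novelty != "n/a":
            raise ValueError("novelty set on a rejected call")


def classify_intergenic(
    candidates: Sequence[TranscriptModel], reference: Sequence[TranscriptModel]
) -> dict[str, str]:
    """Per-transcript class: 'u' iff the candidate's genomic span overlaps no
    reference transcript span on either strand, else 'non_u'.

    Span (not exon) overlap is used, so intronic transcripts are non-'u';
    the comparison is strand-agnostic, the conservative reading for
    *intergenic* lincRNAs.
    """
    hits = intersect(span_map(candidates), span_map(reference), stranded=False)
    overlapping = {qid for qid, _, _ in hits}
    return {
        t.transcript_id: ("non_u" if t.transcript_id in overlapping else "u")
        for t in candidates
    }


def longest_orf(sequence: str) -> int:
    """Length in nt of the longest ORF (ATG..stop, stop included) in the 3
    forward frames.  Codons containing N (or any non-ACGT letter) break an
    open ORF and cannot start one."""
    seq = sequence.upper()
    best = 0
    for frame in range(3):
        start = None
        for i in range(frame, len(seq) - 2, 3):
            codon = seq[i : i + 3]
            if any(b not in "ACGT" for b in codon):
                start = None
                continue
            if start is None:
                if codon == "ATG":
                    start = i
            elif codon in STOP_CODONS:
                best = max(best, i + 3 - start)
                start = None
    return best


def coding_score(sequence: str, cutoff: float = 0.35) -> float:
    """ORF-fraction coding-potential score.

    score = (longest forward-frame ORF length / sequence length) - cutoff.
    A score < 0 is treated as non-coding.  The cutoff is chosen so that a
    sequence that is one full-length ORF scores clearly positive and a
    sequence with no ORF scores -cutoff.  The scorer is a plain function so
    a real CPC/CPAT score column can be substituted upstream.
    """
    if not sequence:
        raise ValueError("empty sequence")
    return longest_orf(sequence) / len(sequence) - cutoff


def _peptide_kmers(protein: str, k: int) -> set[str]:
    return {
        protein[i : i + k]
        for i in range(len(protein) - k + 1)
        if "*" not in protein[i : i + k] and "X" not in protein[i : i + k]
    }


def build_peptide_index(protein_set: Iterable[str], k: int = 8) -> set[str]:
    """All k-residue windows over a protein collection."""
    index: set[str] = set()
    for prot in protein_set:
        index |= _peptide_kmers(prot.upper(), k)
    return index


def six_frame_translations(sequence: str) -> list[str]:
    seq = Seq(sequence.upper())
    rc = seq.reverse_complement()
    frames = []
    for s in (seq, rc):
        for off in range(3):
            sub = s[off:]
            sub = sub[: len(sub) - len(sub) % 3]
            frames.append(str(sub.translate()))
    return frames


def domain_hit(
    sequence: str, protein_set: Iterable[str] | set[str], k: int = 8
) -> bool:
    """True iff any 6-frame translation of ``sequence`` contains an exact
    k-residue peptide window present in the protein set.

    Windows spanning a stop (``*``) or an ambiguous residue (``X``, from N
    bases) are excluded.  ``protein_set`` may be raw protein strings or a
    prebuilt k-mer index from :func:`build_peptide_index`.
    """
    if isinstance(protein_set, set) and all(len(p) == k for p in protein_set):
        index = protein_set
    else:
        index = build_peptide_index(protein_set, k)
    if not index:
        return False
    for frame in six_frame_translations(sequence):
        for i in range(len(frame) - k + 1):
            window = frame[i : i + k]
            if "*" in window or "X" in window:
                continue
            if window in index:
                return True
    return False


def identify_lincrnas(
    assembled: Sequence[TranscriptModel],
    reference: Sequence[TranscriptModel],
    sequences: Mapping[str, str],
    protein_set: Iterable[str],
    expr: ExpressionMatrix,
    config: IdentifyConfig = IdentifyConfig(),
) -> list[LincCall]:
    """Run the full six-predicate cascade over every assembled transcript.

    Every candidate gets a complete :class:`FilterTrail`; status is
    ``lincRNA`` iff all six predicates pass.  Raises when a transcript lacks
    a sequence or an expression row, listing the offending ids.
    """
    if expr.fpkm is None:
        raise ValueError("FPKM not computed; call lincscan.fpkm() first")
    no_seq = [t.transcript_id for t in assembled if t.transcript_id not in sequences]
    no_expr = [t.transcript_id for t in assembled if t.transcript_id not in expr.fpkm.index]
    if no_seq or no_expr:
        raise ValueError(
            f"transcripts lacking sequence: {no_seq[:10]}; lacking expression row: {no_expr[:10]}"
        )
    classes = classify_intergenic(assembled, reference)
    peptide_index = build_peptide_index(protein_set, config.peptide_k)
    calls = []
    for t in assembled:
        tid = t.transcript_id
        score = coding_score(sequences[tid], config.coding_cutoff)
        max_fpkm = float(expr.fpkm.loc[tid].max())
        results = {
            "intergenic": classes[tid] == "u",
            "length_gt_200": transcript_length(t) > config.min_length,
            "exons_ge_2": t.n_exons >= config.min_exons,
            "coding_score_lt_0": score < 0.0,
            "no_domain_hit": not domain_hit(sequences[tid], peptide_index, config.peptide_k),
            "fpkm_gt_0.5_any_sample": max_fpkm > config.min_fpkm,
        }
        trail = FilterTrail(results=results, coding_score=score, max_fpkm=max_fpkm)
        calls.append(
            LincCall(
                transcript=t,
                trail=trail,
                status="lincRNA" if trail.all_pass else "rejected",
            )
        )
    return calls


def split_known_novel(
    calls: Sequence[LincCall], known_linc_annotation: Sequence[TranscriptModel]
) -> list[LincCall]:
    """Set novelty on lincRNA calls: known iff the genomic span overlaps any
    known-lincRNA record by >= 1 bp (strand-agnostic), else novel."""
    linc_calls = [c for c in calls if c.status == "lincRNA"]
    spans = {c.transcript.transcript_id: c.transcript.interval for c in linc_calls}
    hits = intersect(spans, span_map(known_linc_annotation), stranded=False)
    known_ids = {qid for qid, _, _ in hits}
    out = []
    for c in calls:
        if c.status != "lincRNA":
            out.append(c)
        else:
            novelty = "known" if c.transcript.transcript_id in known_ids else "novel"
            out.append(LincCall(transcript=c.transcript, trail=c.trail, status=c.status, novelty=novelty))
    return out


def calls_to_frame(calls: Sequence[LincCall]):
    """Flatten calls to a table (one row per candidate, all trail columns)."""
    import pandas as pd

    rows = []
    for c in calls:
        row = {
            "transcript_id": c.transcript.transcript_id,
            "gene_id": c.transcript.gene_id,
            "chrom": c.transcript.chrom,
            "span_start": c.transcript.interval.start,
            "span_end": c.transcript.interval.end,
            "strand": c.transcript.strand,
            "length": transcript_length(c.transcript),
            "n_exons": c.transcript.n_exons,
        }
        row.update({name: c.trail.results[name] for name in FILTER_NAMES})
        row.update(
            {
                "coding_score": c.trail.coding_score,
                "max_fpkm": c.trail.max_fpkm,
                "status": c.status,
                "novelty": c.novelty,
            }
        )
        rows.append(row)
    return pd.DataFrame(rows).set_index("transcript_id")
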