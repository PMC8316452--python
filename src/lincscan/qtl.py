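"""Colocalization of DE lincRNA loci with QTL intervals and its summaries.

A lincRNA is "located in" a QTL when their genomic spans share >= 1 bp
(strand-agnostic any-overlap, the default behaviour of interval
intersection tools).  One lincRNA may hit many QTLs and vice versa; hits
are never deduplicated, only the distinct-lincRNA summaries are.
"""

from __future__ import annotations

from typing import Sequence

import pandas as pd

from .annotation import QTLRecord, TranscriptModel
from .intervals import intersect

HIT_COLUMNS = [
    "lincRNA_id",
    "qtl_id",
    "chrom",
    "overlap_bp",
    "trait",
    "trait_type",
    "trait_class",
]


def map_to_qtl(
    de_lincs: Sequence[TranscriptModel], qtls: Sequence[QTLRecord]
) -> pd.DataFrame:
    """One hit per (lincRNA, QTL) pair whose spans overlap >= 1 bp."""
    linc_spans = {t.transcript_id: t.interval for t in de_lincs}
    qtl_spans = {q.qtl_id: q.interval for q in qtls}
    qtl_by_id = {q.qtl_id: q for q in qtls}
    rows = []
    for linc_id, qtl_id, overlap_bp in intersect(linc_spans, qtl_spans, stranded=False):
        q = qtl_by_id[qtl_id]
        rows.append(
            dict(
                lincRNA_id=linc_id,
                qtl_id=qtl_id,
                chrom=q.interval.chrom,
                overlap_bp=overlap_bp,
                trait=q.trait,
                trait_type=q.trait_type,
                trait_class=q.trait_class,
            )
        )
    return pd.DataFrame(rows, columns=HIT_COLUMNS)


def summarize_qtl(
    hits: pd.DataFrame, trait_types_of_interest: Sequence[str] | None = None
) -> dict[str, pd.DataFrame]:
    """Trait-class, trait-type, and chromosome summaries of QTL hits.

    Returns a dict with:

    - ``by_class``: QTL-hit count and percentage per trait class;
    - ``by_type``: per trait type, the number of distinct DE lincRNAs with
      >= 1 hit (restricted to ``trait_types_of_interest`` when given);
    - ``by_chrom``: per chromosome, hit counts by trait type.
    """
    if hits.empty:
        return {
            "by_class": pd.DataFrame(columns=["trait_class", "n_hits", "percent"]),
            "by_type": pd.DataFrame(columns=["trait_type", "n_distinct_lincs"]),
            "by_chrom": pd.DataFrame(),
        }
    by_class = (
        hits.groupby("trait_class").size().rename("n_hits").reset_index().sort_values(
            "n_hits", ascending=False, kind="stable"
        )
    )
    by_class["percent"] = 100.0 * by_class["n_hits"] / by_class["n_hits"].sum()
    by_class = by_class.reset_index(drop=True)

    sub = hits
    if trait_types_of_interest is not None:
        sub = hits[hits["trait_type"].isin(trait_types_of_interest)]
    by_type = (
        sub.groupby("trait_type")["lincRNA_id"]
        .nunique()
        .rename("n_distinct_lincs")
        .reset_index()
        .sort_values("trait_type", kind="stable")
        .reset_index(drop=True)
    )

    by_chrom = (
        sub.groupby(["chrom", "trait_type"]).size().rename("n_hits").reset_index()
        .pivot(index="chrom", columns="trait_type", values="n_hits")
        .fillna(0)
        .astype(int)
        .sort_index()
    )
    return {"by_class": by_class, "by_type": by_type, "by_chrom": by_chrom}
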