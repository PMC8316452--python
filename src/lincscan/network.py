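"""Co-expression network export, hypergeometric enrichment, and
characterization statistics.

The network restricts target pairs to differentially expressed target
genes (DEPTGs) by default, mirroring the usual lincRNA-network analysis;
edges carry the correlation coefficient, its sign and the cis/trans mode
and are exported as SIF and GraphML for downstream visualization tools.
Enrichment is a plain hypergeometric upper-tail test against a
user-supplied term -> gene map, the local stand-in for a web-service
annotation tool; significance follows the raw-p rule (p <= alpha) with BH
adjusted values also reported.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .annotation import TranscriptModel, transcript_length
from .expression import ExpressionMatrix, bh_adjust
from .identify import LincCall

EDGE_COLUMNS = ["source", "target", "r", "sign", "mode", "target_is_de"]


def build_network(
    pairs: pd.DataFrame,
    de_gene_ids: Iterable[str],
    restrict_to_de: bool = True,
) -> pd.DataFrame:
    """Edges of the lincRNA-target co-expression network.

    ``pairs`` is a target-pair table (lincRNA_id, gene_id, mode, r, sign).
    With ``restrict_to_de`` (default) only pairs whose target gene is in
    ``de_gene_ids`` become edges.  Edges are unique per (source, target).
    """
    de_set = set(de_gene_ids)
    edges = []
    seen = set()
    for row in pairs.itertuples(index=False):
        key = (row.lincRNA_id, row.gene_id)
        target_is_de = row.gene_id in de_set
        if restrict_to_de and not target_is_de:
            continue
        if key in seen:
            raise ValueError(f"duplicate pair {key} in target table")
        seen.add(key)
        edges.append(
            dict(
                source=row.lincRNA_id,
                target=row.gene_id,
                r=float(row.r),
                sign="positive" if row.r > 0 else "negative",
                mode=row.mode,
                target_is_de=target_is_de,
            )
        )
    df = pd.DataFrame(edges, columns=EDGE_COLUMNS)
    return df.sort_values(["source", "target"], kind="stable").reset_index(drop=True)


def sign_counts(edges: pd.DataFrame) -> dict[str, int]:
    """Count of positively and negatively correlated edges."""
    return {
        "positive": int((edges["sign"] == "positive").sum()),
        "negative": int((edges["sign"] == "negative").sum()),
    }


def export_sif(edges: pd.DataFrame, path: str | Path) -> None:
    """SIF export: ``source <tab> pos|neg <tab> target`` per edge."""
    with open(path, "w") as fh:
        for row in edges.itertuples(index=False):
            interaction = "pos" if row.sign == "positive" else "neg"
            fh.write(f"{row.source}\t{interaction}\t{row.target}\n")


def read_sif(path: str | Path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            source, interaction, target = line.rstrip("\n").split("\t")
            rows.append(dict(source=source, interaction=interaction, target=target))
    return pd.DataFrame(rows, columns=["source", "interaction", "target"])


def to_graph(edges: pd.DataFrame) -> nx.Graph:
    g = nx.Graph()
    for row in edges.itertuples(index=False):
        g.add_node(row.source, kind="lincRNA")
        g.add_node(row.target, kind="gene", is_de=bool(row.target_is_de))
        g.add_edge(
            row.source,
            row.target,
            r=float(row.r),
            sign=row.sign,
            mode=row.mode,
        )
    return g


def export_graphml(edges: pd.DataFrame, path: str | Path) -> None:
    """GraphML export with r/sign/mode edge attributes."""
    nx.write_graphml(to_graph(edges), str(path))


def enrich(
    gene_set: Iterable[str],
    universe: Iterable[str],
    term_map: Mapping[str, Iterable[str]],
    alpha: float = 0.05,
    term_names: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``gene_set`` in each term.

    p is the upper-tail probability of drawing >= k term genes in
    ``n = |gene_set|`` draws without replacement from ``N = |universe|``
    containing ``K`` term genes.  BH-adjusted p-values are reported; the
    ``significant`` flag follows the raw-p rule ``p <= alpha``.  Raises if
    the gene set is not a subset of the universe, listing offenders.
    """
    genes = set(gene_set)
    uni = set(universe)
    outside = sorted(genes - uni)
    if outside:
        raise ValueError(f"gene_set not a subset of universe: {outside[:10]}")
    N = len(uni)
    n = len(genes)
    rows = []
    for term_id in sorted(term_map):
        term_genes = set(term_map[term_id]) & uni
        K = len(term_genes)
        k = len(term_genes & genes)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if K > 0 else 1.0
        rows.append(
            dict(
                term_id=term_id,
                term_name=(term_names or {}).get(term_id, term_id),
                k=k,
                K=K,
                n=n,
                N=N,
                p=min(p, 1.0),
            )
        )
    df = pd.DataFrame(rows, columns=["term_id", "term_name", "k", "K", "n", "N", "p"])
    if not df.empty:
        df["padj"] = bh_adjust(df["p"].to_numpy())
        df["significant"] = df["p"] <= alpha
    else:
        df["padj"] = []
        df["significant"] = []
    return df.sort_values(["p", "term_id"], kind="stable").reset_index(drop=True)


CHARACTERIZE_CLASSES = ("known lincRNA", "novel lincRNA", "protein-coding")


def characterize(
    calls: Sequence[LincCall],
    coding: Sequence[TranscriptModel],
    expr: ExpressionMatrix,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Length/exon/expression comparison of lincRNA classes vs coding genes.

    Returns (summary, per_transcript): the summary has one row per class
    {known lincRNA, novel lincRNA, protein-coding} with transcript count,
    mean/median transcript length, mean exon length, mean exon count and
    mean FPKM (a class with no members gets an explicit n = 0 row); the
    per-transcript table carries the underlying distributions for plotting.
    """
    if expr.fpkm is None:
        raise ValueError("FPKM not computed; call lincscan.fpkm() first")
    groups: dict[str, list[TranscriptModel]] = {c: [] for c in CHARACTERIZE_CLASSES}
    for c in calls:
        if c.status != "lincRNA":
            continue
        if c.novelty == "known":
            groups["known lincRNA"].append(c.transcript)
        elif c.novelty == "novel":
            groups["novel lincRNA"].append(c.transcript)
        else:
            raise ValueError(
                f"call {c.transcript.transcript_id} lacks a novelty label; "
                "run split_known_novel first"
            )
    groups["protein-coding"].extend(coding)

    detail_rows = []
    summary_rows = []
    for cls in CHARACTERIZE_CLASSES:
        ts = groups[cls]
        for t in ts:
            mean_fpkm = (
                float(expr.fpkm.loc[t.transcript_id].mean())
                if t.transcript_id in expr.fpkm.index
                else np.nan
            )
            detail_rows.append(
                dict(
                    transcript_id=t.transcript_id,
                    transcript_class=cls,
                    length=transcript_length(t),
                    n_exons=t.n_exons,
                    mean_exon_length=transcript_length(t) / t.n_exons,
                    mean_fpkm=mean_fpkm,
                )
            )
        if not ts:
            summary_rows.append(
                dict(
                    transcript_class=cls,
                    n=0,
                    mean_length=np.nan,
                    median_length=np.nan,
                    mean_exon_length=np.nan,
                    mean_exon_count=np.nan,
                    mean_fpkm=np.nan,
                )
            )
            continue
        sub = pd.DataFrame(detail_rows)
        sub = sub[sub["transcript_class"] == cls]
        summary_rows.append(
            dict(
                transcript_class=cls,
                n=len(ts),
                mean_length=float(sub["length"].mean()),
                median_length=float(sub["length"].median()),
                mean_exon_length=float(sub["mean_exon_length"].mean()),
                mean_exon_count=float(sub["n_exons"].mean()),
                mean_fpkm=float(sub["mean_fpkm"].mean()),
            )
        )
    summary = pd.DataFrame(summary_rows).set_index("transcript_class")
    detail = pd.DataFrame(
        detail_rows,
        columns=[
            "transcript_id",
            "transcript_class",
            "length",
            "n_exons",
            "mean_exon_length",
            "mean_fpkm",
        ],
    )
    return summary, detail
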