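"""End-to-end pipeline: simulate -> identify -> DE -> QTL -> targets -> network.

``run_pipeline`` executes every stage on a synthetic world and writes all
tables and exports into an output directory.  Every stage is seeded from
the world seed, all writers order rows deterministically and no output
embeds a timestamp, so two runs with the same configuration and seed
produce byte-identical files.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from .annotation import write_fasta, write_gtf, write_qtl_table
from .expression import de_test, de_union, fpkm
from .identify import IdentifyConfig, calls_to_frame, identify_lincrnas, split_known_novel
from .network import (
    build_network,
    characterize,
    enrich,
    export_graphml,
    export_sif,
    sign_counts,
)
from .qtl import map_to_qtl, summarize_qtl
from .simulate import (
    SyntheticWorld,
    WorldConfig,
    build_counts,
    build_qtls,
    build_term_map,
    build_world,
    feature_lengths,
)
from .targets import predict_targets

FLOAT_FORMAT = "%.6g"

DEFAULT_ANALYSIS = dict(
    linc_lfc_min=1.0,
    linc_alpha=0.05,
    gene_lfc_min=2.0,
    gene_alpha=0.05,
    cis_window=100_000,
    cis_r_min=0.8,
    cis_p_max=0.01,
    trans_r_min=0.96,
    trans_padj_max=0.05,
    n_qtls=50,
    qtl_overlap_fraction=0.6,
    enrich_alpha=0.05,
)


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FORMAT)


def run_pipeline(
    outdir: str | Path,
    world_config: WorldConfig | Mapping[str, Any] | None = None,
    seed: int | None = None,
    analysis: Mapping[str, Any] | None = None,
) -> dict[str, Any]:
    """Run the whole analysis on a synthetic world and write its outputs.

    ``world_config`` may be a :class:`WorldConfig` or a mapping of its
    fields; ``seed`` overrides the config's ``rng_seed`` when given.
    Returns a summary dict (also written as ``run_summary.json``).
    """
    if world_config is None:
        cfg = WorldConfig()
    elif isinstance(world_config, WorldConfig):
        cfg = world_config
    else:
        cfg = WorldConfig(**dict(world_config))
    if seed is not None:
        cfg = WorldConfig(**{**asdict(cfg), "rng_seed": int(seed)})
    params = {**DEFAULT_ANALYSIS, **dict(analysis or {})}

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    # --- simulate
    world = build_world(cfg)
    expr_raw, truth = build_counts(world)
    qtls = build_qtls(world, n_qtls=params["n_qtls"], overlap_fraction=params["qtl_overlap_fraction"])

    write_gtf(world.reference, outdir / "reference.gtf")
    write_gtf(world.assembled, outdir / "assembled.gtf")
    write_gtf(world.known_lincs, outdir / "known_lincs.gtf")
    write_fasta(world.sequences, outdir / "transcripts.fa")
    write_fasta({f"P{i + 1:03d}": p for i, p in enumerate(world.proteins)}, outdir / "proteins.fa")
    write_qtl_table(qtls, outdir / "qtls.tsv")
    _write_tsv(expr_raw.counts, outdir / "counts.tsv")
    truth.to_tsv(outdir / "truth_transcripts.tsv")
    _write_tsv(truth.targets, outdir / "truth_targets.tsv", index=False)

    # --- quantify + identify
    lengths = feature_lengths(world)
    expr = fpkm(expr_raw, lengths)
    calls = identify_lincrnas(
        world.assembled, world.reference, world.sequences, world.proteins, expr
    )
    calls = split_known_novel(calls, world.known_lincs)
    calls_df = calls_to_frame(calls)
    _write_tsv(calls_df, outdir / "linc_calls.tsv")
    linc_ids = sorted(calls_df.index[calls_df["status"] == "lincRNA"])

    # --- differential expression (all pairwise stage contrasts)
    stages = cfg.stage_labels
    contrasts = [
        (stages[i], stages[j])
        for i in range(len(stages))
        for j in range(i + 1, len(stages))
    ]
    coding_ids = {t.transcript_id for t in world.reference}
    de_tables = []
    de_linc_ids: set[str] = set()
    de_gene_ids: set[str] = set()
    for a, b in contrasts:
        res = de_test(expr, (a, b), lfc_min=params["linc_lfc_min"], alpha=params["linc_alpha"])
        _write_tsv(res, outdir / f"de_{a}_vs_{b}.tsv")
        de_tables.append(res)
        de_linc_ids |= {f for f in res.index[res["is_de"]] if f in linc_ids}
        gene_de = (
            (res["log2FoldChange"].abs() >= params["gene_lfc_min"])
            & (res["padj"] <= params["gene_alpha"])
        )
        de_gene_ids |= {f for f in res.index[gene_de] if f in coding_ids}
    de_linc_ids = set(sorted(de_linc_ids))
    de_gene_ids = set(sorted(de_gene_ids))

    by_id = {t.transcript_id: t for t in world.assembled + world.reference}
    de_linc_transcripts = [by_id[i] for i in sorted(de_linc_ids)]

    # --- QTL colocalization
    hits = map_to_qtl(de_linc_transcripts, qtls)
    _write_tsv(hits, outdir / "qtl_hits.tsv", index=False)
    summaries = summarize_qtl(hits, trait_types_of_interest=["Muscle", "Growth", "Fat deposition"])
    _write_tsv(summaries["by_class"], outdir / "qtl_summary_by_class.tsv", index=False)
    _write_tsv(summaries["by_type"], outdir / "qtl_summary_by_type.tsv", index=False)
    _write_tsv(summaries["by_chrom"], outdir / "qtl_summary_by_chrom.tsv")

    # --- target prediction
    pairs = predict_targets(
        de_linc_transcripts,
        world.reference,
        expr,
        mode="both",
        cis_window=params["cis_window"],
        cis_r_min=params["cis_r_min"],
        cis_p_max=params["cis_p_max"],
        trans_r_min=params["trans_r_min"],
        trans_padj_max=params["trans_padj_max"],
    )
    _write_tsv(pairs, outdir / "target_pairs.tsv", index=False)

    # --- network + enrichment + characterization
    edges = build_network(pairs, de_gene_ids)
    _write_tsv(edges, outdir / "network_edges.tsv", index=False)
    export_sif(edges, outdir / "network.sif")
    export_graphml(edges, outdir / "network.graphml")
    signs = sign_counts(edges)

    term_map = build_term_map(world)
    universe = sorted(coding_ids)
    target_genes = sorted(set(pairs["gene_id"]) & coding_ids)
    enrichment = enrich(target_genes, universe, term_map, alpha=params["enrich_alpha"])
    _write_tsv(enrichment, outdir / "enrichment.tsv", index=False)

    summary_tbl, detail = characterize(calls, world.reference, expr)
    _write_tsv(summary_tbl, outdir / "characterization_summary.tsv")
    _write_tsv(detail, outdir / "characterization_per_transcript.tsv", index=False)

    summary = {
        "seed": cfg.rng_seed,
        "n_assembled": len(world.assembled),
        "n_lincRNAs": len(linc_ids),
        "n_known": int((calls_df["novelty"] == "known").sum()),
        "n_novel": int((calls_df["novelty"] == "novel").sum()),
        "n_de_lincRNAs": len(de_linc_ids),
        "n_de_genes": len(de_gene_ids),
        "n_qtl_hits": int(len(hits)),
        "n_de_lincs_in_qtl": int(hits["lincRNA_id"].nunique()) if not hits.empty else 0,
        "n_target_pairs": int(len(pairs)),
        "n_cis_pairs": int((pairs["mode"] == "cis").sum()),
        "n_trans_pairs": int((pairs["mode"] == "trans").sum()),
        "n_network_edges": int(len(edges)),
        "n_positive_edges": signs["positive"],
        "n_negative_edges": signs["negative"],
        "n_significant_terms": int(enrichment["significant"].sum()) if len(enrichment) else 0,
    }
    with open(outdir / "run_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary
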