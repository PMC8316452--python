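"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from lincscan import (
    ExpressionMatrix,
    GenomicInterval,
    TranscriptModel,
    WorldConfig,
    build_counts,
    build_world,
    feature_lengths,
    fpkm,
)

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_transcript(
    tid: str,
    exons: list[tuple[int, int]],
    chrom: str = "chr1",
    strand: str = "+",
    gene_id: str | None = None,
    biotype: str = "other",
) -> TranscriptModel:
    return TranscriptModel(
        transcript_id=tid,
        gene_id=gene_id or f"G_{tid}",
        exons=tuple(GenomicInterval(chrom, s, e, strand) for s, e in exons),
        biotype=biotype,
    )


def make_expr(
    counts: dict[str, list[float]], samples: list[str], design: dict[str, str]
) -> ExpressionMatrix:
    df = pd.DataFrame(counts, index=samples).T
    return ExpressionMatrix(counts=df, design=pd.Series(design))


# ---------------------------------------------------------------------------
# independent oracles (deliberately written with different algorithms than
# the package implementations)


def brute_force_intersect(queries, subjects, stranded=False):
    """O(n*m) all-pairs overlap, the reference for the interval engine."""
    out = []
    for qid, q in queries.items():
        for sid, s in subjects.items():
            if q.chrom != s.chrom:
                continue
            ov = min(q.end, s.end) - max(q.start, s.start)
            if ov <= 0:
                continue
            if stranded and not (
                q.strand == "." or s.strand == "." or q.strand == s.strand
            ):
                continue
            out.append((qid, sid, ov))
    out.sort(key=lambda t: (t[0], t[1]))
    return out


def brute_force_bh(p):
    """Textbook BH step-up: padj_(i) = min_{j>=i} min(1, m*p_(j)/j)."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, m * p[idx] / rank)
        adj[idx] = running
    return adj


def brute_force_longest_orf(seq):
    """Regex-based 3-frame ORF scan (ATG..stop inclusive, N breaks codons)."""
    import re

    seq = seq.upper()
    best = 0
    for frame in range(3):
        codons = [seq[i : i + 3] for i in range(frame, len(seq) - 2, 3)]
        # positions of valid start/stop codons; invalid codons act as walls
        open_at = None
        for ci, codon in enumerate(codons):
            if not re.fullmatch("[ACGT]{3}", codon):
                open_at = None
                continue
            if open_at is None:
                if codon == "ATG":
                    open_at = ci
            elif codon in ("TAA", "TAG", "TGA"):
                best = max(best, (ci - open_at + 1) * 3)
                open_at = None
    return best


@pytest.fixture(scope="session")
def small_world():
    """A compact planted world shared by read-only tests."""
    cfg = WorldConfig(
        rng_seed=7,
        n_coding_genes=40,
        n_background_genes=120,
        n_true_lincs=12,
        n_decoys_per_mode=2,
        n_de_lincs=4,
        n_de_genes=6,
        n_cis_targets=3,
        n_trans_targets=3,
    )
    world = build_world(cfg)
    expr, truth = build_counts(world)
    expr = fpkm(expr, feature_lengths(world))
    return world, expr, truth
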