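"""Cis and trans target-gene prediction for DE lincRNAs.

Cis candidates are protein-coding genes whose genomic span lies strictly
within 100 kb of the lincRNA span (gap distance < window, strand-agnostic,
0 when the spans overlap); a candidate becomes a target when the Pearson
correlation of log2(FPKM + 1) across samples has |r| >= 0.8 and raw
p <= 0.01.  Trans candidates are all (lincRNA, gene) pairs genome-wide,
gated at |r| >= 0.96 with BH-adjusted p <= 0.05 across every tested pair.
Absolute r is used in both modes: negatively correlated targets are
biologically meaningful and are reported with sign = negative.  A pair
qualifying in both modes is reported once, as cis.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import TranscriptModel
from .expression import ExpressionMatrix, bh_adjust

PAIR_COLUMNS = [
    "lincRNA_id",
    "gene_id",
    "mode",
    "r",
    "p",
    "padj",
    "distance",
    "sign",
]


def pearson(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson r and two-sided p from the t transform.

    p comes from ``t = r * sqrt(n - 2) / sqrt(1 - r^2)`` on n - 2 df.
    Conventions: a constant vector gives (0, 1); |r| = 1 gives p = 0.
    Requires equal lengths and n >= 3.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    n = x.size
    if n < 3:
        raise ValueError(f"need n >= 3 samples, got {n}")
    sx = x.std()
    sy = y.std()
    if sx == 0 or sy == 0:
        return 0.0, 1.0
    r = float(np.clip(np.mean((x - x.mean()) * (y - y.mean())) / (sx * sy), -1.0, 1.0))
    # exactly collinear vectors can land 1 ulp inside +-1; snap so the
    # |r| = 1 -> p = 0 convention holds for y = a*x + b
    if 1.0 - abs(r) <= 4.0 * np.finfo(float).eps:
        r = math.copysign(1.0, r)
    return r, _p_from_r(np.array([r]), n)[0]


def _p_from_r(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p-values for Pearson r via the t transform (vectorized)."""
    r = np.clip(r, -1.0, 1.0)
    denom = 1.0 - r * r
    with np.errstate(divide="ignore"):
        t = np.abs(r) * math.sqrt(n - 2) / np.sqrt(np.where(denom > 0, denom, np.inf))
    p = 2.0 * stats.t.sf(t, n - 2)
    return np.where(denom <= 0, 0.0, np.clip(p, 0.0, 1.0))


def _corr_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-by-row correlation between two feature x sample arrays.

    Constant rows produce r = 0 against everything (the constant-vector
    convention)."""
    n = a.shape[1]
    az = a - a.mean(axis=1, keepdims=True)
    bz = b - b.mean(axis=1, keepdims=True)
    asd = az.std(axis=1)
    bsd = bz.std(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        az = np.where(asd[:, None] > 0, az / asd[:, None], 0.0)
        bz = np.where(bsd[:, None] > 0, bz / bsd[:, None], 0.0)
    return np.clip(az @ bz.T / n, -1.0, 1.0)


def _span_gap(a, b) -> int:
    return a.gap_to(b)


def cis_targets(
    de_lincs: Sequence[TranscriptModel],
    coding_genes: Sequence[TranscriptModel],
    expr: ExpressionMatrix,
    window: int = 100_000,
    r_min: float = 0.8,
    p_max: float = 0.01,
) -> pd.DataFrame:
    """Proximity-gated correlation targets.

    Candidate genes lie strictly within ``window`` bp of the lincRNA span
    on the same chromosome (a gene whose span starts exactly ``window`` bp
    away is excluded); kept when |r| >= r_min and raw p <= p_max.
    """
    log_fpkm = expr.log2_fpkm()
    rows = []
    for linc in de_lincs:
        lid = linc.transcript_id
        if lid not in log_fpkm.index:
            raise ValueError(f"no expression row for lincRNA {lid}")
        x = log_fpkm.loc[lid].to_numpy()
        for gene in coding_genes:
            if gene.chrom != linc.chrom:
                continue
            distance = _span_gap(linc.interval, gene.interval)
            if distance >= window:
                continue
            gid = gene.transcript_id
            if gid not in log_fpkm.index:
                raise ValueError(f"no expression row for gene {gid}")
            r, p = pearson(x, log_fpkm.loc[gid].to_numpy())
            if abs(r) >= r_min and p <= p_max:
                rows.append(
                    dict(
                        lincRNA_id=lid,
                        gene_id=gid,
                        mode="cis",
                        r=r,
                        p=p,
                        padj=np.nan,
                        distance=distance,
                        sign="positive" if r > 0 else "negative",
                    )
                )
    return pd.DataFrame(rows, columns=PAIR_COLUMNS)


def trans_targets(
    de_lincs: Sequence[TranscriptModel],
    coding_genes: Sequence[TranscriptModel],
    expr: ExpressionMatrix,
    r_min: float = 0.96,
    padj_max: float = 0.05,
) -> pd.DataFrame:
    """Genome-wide correlation targets.

    All (DE lincRNA, coding gene) pairs are tested; BH adjustment runs
    across every tested pair; kept when |r| >= r_min and padj <= padj_max.
    Cis/trans precedence is applied by :func:`predict_targets`.
    """
    if not de_lincs or not coding_genes:
        return pd.DataFrame(columns=PAIR_COLUMNS)
    log_fpkm = expr.log2_fpkm()
    linc_ids = [t.transcript_id for t in de_lincs]
    gene_ids = [t.transcript_id for t in coding_genes]
    for ids, kind in ((linc_ids, "lincRNA"), (gene_ids, "gene")):
        missing = [i for i in ids if i not in log_fpkm.index]
        if missing:
            raise ValueError(f"no expression row for {kind}s: {missing[:5]}")
    n = log_fpkm.shape[1]
    a = log_fpkm.loc[linc_ids].to_numpy()
    b = log_fpkm.loc[gene_ids].to_numpy()
    r = _corr_matrix(a, b)
    p = _p_from_r(r.ravel(), n)
    padj = bh_adjust(p).reshape(r.shape)
    p = p.reshape(r.shape)
    keep = (np.abs(r) >= r_min) & (padj <= padj_max)
    rows = []
    for i, j in zip(*np.nonzero(keep)):
        rows.append(
            dict(
                lincRNA_id=linc_ids[i],
                gene_id=gene_ids[j],
                mode="trans",
                r=float(r[i, j]),
                p=float(p[i, j]),
                padj=float(padj[i, j]),
                distance=np.nan,
                sign="positive" if r[i, j] > 0 else "negative",
            )
        )
    return pd.DataFrame(rows, columns=PAIR_COLUMNS)


def predict_targets(
    de_lincs: Sequence[TranscriptModel],
    coding_genes: Sequence[TranscriptModel],
    expr: ExpressionMatrix,
    mode: str = "both",
    cis_window: int = 100_000,
    cis_r_min: float = 0.8,
    cis_p_max: float = 0.01,
    trans_r_min: float = 0.96,
    trans_padj_max: float = 0.05,
) -> pd.DataFrame:
    """Cis and/or trans targets with cis-over-trans precedence.

    A pair passing both gates is reported once, as cis, so downstream
    network edges are unique.
    """
    if mode not in ("cis", "trans", "both"):
        raise ValueError(f"mode must be cis, trans or both, got {mode!r}")
    frames = []
    cis = pd.DataFrame(columns=PAIR_COLUMNS)
    if mode in ("cis", "both"):
        cis = cis_targets(de_lincs, coding_genes, expr, cis_window, cis_r_min, cis_p_max)
        frames.append(cis)
    if mode in ("trans", "both"):
        trans = trans_targets(de_lincs, coding_genes, expr, trans_r_min, trans_padj_max)
        if not cis.empty and not trans.empty:
            cis_keys = set(zip(cis["lincRNA_id"], cis["gene_id"]))
            trans = trans[
                [
                    (l, g) not in cis_keys
                    for l, g in zip(trans["lincRNA_id"], trans["gene_id"])
                ]
            ]
        frames.append(trans)
    frames = [f for f in frames if not f.empty]
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=PAIR_COLUMNS)
    return out.sort_values(["lincRNA_id", "gene_id"], kind="stable").reset_index(drop=True)
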