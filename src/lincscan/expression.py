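"""Expression quantification and differential expression.

FPKM follows the classic definition

    fpkm[f, s] = counts[f, s] * 1e9 / (libsize[s] * length[f])

with the library size taken as the column sum of the raw count matrix.

The stage-wise differential test is an empirical-Bayes moderated t on
log2(FPKM + 1): per-feature pooled variances are shrunk toward a lowess
mean-variance trend with the prior degrees of freedom estimated from the
spread of log-variances (the limma-trend idea).  With 3 replicates per
stage a plain per-feature t-test has ~4 degrees of freedom for its variance
estimate, which destroys power after FDR adjustment; borrowing variance
information across features restores it while keeping the null calibrated.
This is the desk-scale stand-in for a count-model package such as DESeq2,
whose dispersion estimation pools across genes for the same reason.  The
result table carries DESeq2-compatible column names (baseMean,
log2FoldChange, pvalue, padj) so externally computed results can be swapped
into the downstream stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

PSEUDOCOUNT = 1.0


@dataclass
class ExpressionMatrix:
    """Counts (features x samples), the sample->stage design, and derived FPKM.

    ``counts`` rows are transcript or gene ids, columns sample ids.  ``fpkm``
    is present only after :func:`fpkm` has been applied.
    """

    counts: pd.DataFrame
    design: pd.Series  # sample id -> stage label
    fpkm: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        c = self.counts
        if c.index.has_duplicates:
            raise ValueError("duplicate feature ids in count matrix")
        if c.columns.has_duplicates:
            raise ValueError("duplicate sample ids in count matrix")
        vals = c.to_numpy()
        if not np.all(np.isfinite(vals)) or (vals < 0).any():
            raise ValueError("counts must be finite and non-negative")
        missing = [s for s in c.columns if s not in self.design.index]
        if missing:
            raise ValueError(f"samples missing from design: {missing}")

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def features(self) -> list[str]:
        return list(self.counts.index)

    def stage_samples(self, stage: str) -> list[str]:
        return [s for s in self.counts.columns if self.design[s] == stage]

    def log2_fpkm(self, pseudocount: float = PSEUDOCOUNT) -> pd.DataFrame:
        if self.fpkm is None:
            raise ValueError("FPKM not computed; call lincscan.fpkm() first")
        return np.log2(self.fpkm + pseudocount)


def fpkm(expr: ExpressionMatrix, lengths: Mapping[str, float] | pd.Series) -> ExpressionMatrix:
    """Attach FPKM to an expression matrix.

    ``lengths`` maps every feature id to its mature length in bp (> 0).
    Raises on zero library size (an all-zero sample has no defined FPKM).
    """
    lengths = pd.Series(lengths, dtype=float)
    missing = [f for f in expr.counts.index if f not in lengths.index]
    if missing:
        raise ValueError(f"lengths missing for features: {missing[:5]}{'...' if len(missing) > 5 else ''}")
    lens = lengths.reindex(expr.counts.index)
    if (lens <= 0).any():
        bad = list(lens.index[lens <= 0][:5])
        raise ValueError(f"non-positive lengths for features: {bad}")
    libsize = expr.counts.sum(axis=0)
    if (libsize == 0).any():
        bad = list(libsize.index[libsize == 0])
        raise ValueError(f"zero library size in samples: {bad}")
    # scale before dividing so exactly-representable cases (e.g. counts and
    # library sizes that make c*1e9/(lib*L) a dyadic rational) stay exact
    fp = (expr.counts * 1e9).div(libsize, axis=1).div(lens, axis=0)
    return ExpressionMatrix(counts=expr.counts, design=expr.design, fpkm=fp)


def bh_adjust(pvalues: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _fit_f_dist(ratio: np.ndarray, df: float) -> tuple[float, float]:
    """Moments estimate of the prior df d0 and scale s0^2 for variance ratios.

    Models ``ratio ~ s0^2 * F(df, d0)``; matches mean and variance of
    log(ratio) using digamma/trigamma, the standard empirical-Bayes fit for
    variance shrinkage.  Returns (inf, s0sq) when the observed spread of
    log-variances is no larger than the chi-square sampling noise alone.
    """
    e = np.log(np.maximum(ratio, 1e-300))
    emean = float(np.mean(e))
    bias_df = special.polygamma(0, df / 2) - np.log(df / 2)
    if e.size < 2:
        return np.inf, float(np.exp(emean - bias_df))
    evar = float(np.var(e, ddof=1))
    target = evar - float(special.polygamma(1, df / 2))
    if target <= 0:
        return np.inf, float(np.exp(emean - bias_df))
    d0 = optimize.brentq(lambda x: special.polygamma(1, x / 2) - target, 1e-6, 1e7)
    bias_d0 = special.polygamma(0, d0 / 2) - np.log(d0 / 2)
    s0sq = float(np.exp(emean - bias_df + bias_d0))
    return float(d0), s0sq


def _moderated_t(
    a: np.ndarray, b: np.ndarray, trend: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Moderated two-group t statistics and two-sided p-values.

    ``a`` and ``b`` are features x replicates arrays on the log2 scale.
    Per-feature pooled variances (df = n_a + n_b - 2) are shrunk toward a
    lowess trend in mean expression; t is referenced to df + prior df.
    """
    n1, n2 = a.shape[1], b.shape[1]
    df = n1 + n2 - 2
    v = ((n1 - 1) * a.var(axis=1, ddof=1) + (n2 - 1) * b.var(axis=1, ddof=1)) / df
    amean = np.hstack([a, b]).mean(axis=1)
    if trend and v.size >= 10 and np.ptp(amean) > 0:
        smoothed = lowess(np.log(np.maximum(v, 1e-10)), amean, frac=0.5, return_sorted=False)
        prior_shape = np.exp(smoothed)
    else:
        prior_shape = np.full_like(v, max(float(np.mean(v)), 1e-12))
    d0, s0sq = _fit_f_dist(np.maximum(v, 1e-12) / prior_shape, df)
    prior_var = s0sq * prior_shape
    if np.isinf(d0):
        v_post = prior_var
        df_post = np.inf
    else:
        v_post = (d0 * prior_var + df * v) / (d0 + df)
        df_post = d0 + df
    diff = b.mean(axis=1) - a.mean(axis=1)
    se = np.sqrt(np.maximum(v_post, 0.0) * (1 / n1 + 1 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, diff / np.where(se > 0, se, 1.0), np.where(diff == 0, 0.0, np.inf * np.sign(diff)))
    if np.isinf(df_post):
        p = 2 * stats.norm.sf(np.abs(t))
    else:
        p = 2 * stats.t.sf(np.abs(t), df_post)
    p = np.where(np.isnan(p), 1.0, p)
    # features that are exactly constant and equal across both groups
    flat = (diff == 0) & (v == 0)
    p = np.where(flat, 1.0, p)
    return t, np.clip(p, 0.0, 1.0)


def de_test(
    expr: ExpressionMatrix,
    contrast: tuple[str, str],
    lfc_min: float = 1.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Differential expression between two stages.

    ``contrast = (stage_a, stage_b)``; log2FoldChange is
    ``log2((mean_fpkm_b + 1) / (mean_fpkm_a + 1))`` so it is bounded for
    zero counts.  A feature is called DE iff ``|log2FoldChange| >= lfc_min``
    and ``padj <= alpha`` with BH adjustment across all features in the
    contrast.  Requires >= 2 samples per group and a computed FPKM matrix.
    """
    stage_a, stage_b = contrast
    if expr.fpkm is None:
        raise ValueError("FPKM not computed; call lincscan.fpkm() first")
    sa = expr.stage_samples(stage_a)
    sb = expr.stage_samples(stage_b)
    if len(sa) < 2 or len(sb) < 2:
        raise ValueError(
            f"each group needs >= 2 samples (got {len(sa)} for {stage_a}, {len(sb)} for {stage_b})"
        )
    log_fpkm = expr.log2_fpkm()
    a = log_fpkm[sa].to_numpy()
    b = log_fpkm[sb].to_numpy()
    t, p = _moderated_t(a, b)
    mean_a = expr.fpkm[sa].mean(axis=1).to_numpy()
    mean_b = expr.fpkm[sb].mean(axis=1).to_numpy()
    log2fc = np.log2((mean_b + 1.0) / (mean_a + 1.0))
    padj = bh_adjust(p)
    is_de = (np.abs(log2fc) >= lfc_min) & (padj <= alpha)
    return pd.DataFrame(
        {
            "feature_id": expr.features,
            "baseMean": (mean_a + mean_b) / 2.0,
            f"mean_fpkm_{stage_a}": mean_a,
            f"mean_fpkm_{stage_b}": mean_b,
            "log2FoldChange": log2fc,
            "stat": t,
            "pvalue": p,
            "padj": padj,
            "is_de": is_de,
            "contrast": f"{stage_a}:{stage_b}",
        }
    ).set_index("feature_id")


def de_union(results: Iterable[pd.DataFrame]) -> list[str]:
    """Feature ids called DE in at least one contrast (sorted)."""
    hits: set[str] = set()
    for df in results:
        hits.update(df.index[df["is_de"]])
    return sorted(hits)


def ddct(
    ct: pd.DataFrame,
    target_gene: str,
    reference_gene: str,
    calibrator_sample: str,
) -> pd.Series:
    """Relative expression per sample by the 2^-ddCt method.

    ``ct`` is a long table with columns (sample, gene, ct).  dCt is the
    target-minus-reference Ct per sample, ddCt subtracts the calibrator
    sample's dCt, and the returned value is ``2 ** (-ddCt)`` (1.0 at the
    calibrator by construction).
    """
    required = {"sample", "gene", "ct"}
    if not required.issubset(ct.columns):
        raise ValueError(f"ct table must have columns {sorted(required)}")
    wide = ct.pivot_table(index="sample", columns="gene", values="ct")
    for gene in (target_gene, reference_gene):
        if gene not in wide.columns:
            raise KeyError(f"gene {gene!r} absent from Ct table")
    if calibrator_sample not in wide.index:
        raise KeyError(f"calibrator sample {calibrator_sample!r} absent from Ct table")
    if not np.all(np.isfinite(wide[[target_gene, reference_gene]].to_numpy())):
        raise ValueError("Ct values must be finite for target and reference genes")
    dct = wide[target_gene] - wide[reference_gene]
    dd = dct - dct.loc[calibrator_sample]
    out = 2.0 ** (-dd)
    out.name = "relative_expression"
    return out
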