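"""Synthetic transcriptome worlds with planted ground truth.

The generator emulates the design of a 3-stage x 3-replicate bulk RNA-seq
study of an annotated genome: protein-coding genes, intergenic non-coding
loci, decoy transcripts that each violate exactly one lincRNA
identification predicate, negative-binomial counts with planted stage
effects, latent-factor-induced correlations between chosen lincRNA/gene
pairs, and QTL intervals placed to overlap chosen lincRNA loci.  Every
planted property is recorded in a :class:`TruthTable` and is independently
verifiable from the emitted files alone.

Expression is specified on the FPKM scale.  A set of background coding
genes absorbs the remainder of the library mass so that the realized FPKM
of each foreground feature matches its intended value (the conservation
identity sum(FPKM * L / 1e3) = 1e6 forces the total FPKM mass to be fixed;
without a background, desk-scale worlds with a few hundred features cannot
realize small FPKM values at all).  The default target library size of
5e7 fragments per sample matches the depth of a typical mammalian bulk
RNA-seq library and puts the FPKM = 0.5 identification threshold at
tens of counts, where it is a meaningful boundary.

Latent-correlation planting: each planted (lincRNA, gene) pair shares a
per-sample standard-normal factor added on the log2-mean scale.  The
loading is chosen in closed form to compensate for negative-binomial
counting noise so the population correlation of realized log2 FPKM is
approximately the configured ``latent_r``:

    loading_m^2 = rho / (1 - rho) * sigma_m^2,
    sigma_m^2 ~= (1/mu_m + dispersion) / ln(2)^2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .annotation import QTLRecord, TranscriptModel, transcript_length
from .expression import ExpressionMatrix
from .identify import build_peptide_index, coding_score, domain_hit
from .intervals import GenomicInterval

LN2_SQ = math.log(2.0) ** 2

DECOY_MODES = (
    "overlap",
    "short",
    "mono_exonic",
    "coding_like",
    "domain_hit",
    "low_expression",
)

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

# one codon per amino acid (standard genetic code)
AA_CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT",
    "G": "GGT", "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTT",
    "M": "ATG", "N": "AAT", "P": "CCT", "Q": "CAA", "R": "CGT",
    "S": "TCT", "T": "ACT", "V": "GTT", "W": "TGG", "Y": "TAT",
}

NON_STOP_CODONS = sorted(
    {a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"} - {"TAA", "TAG", "TGA"}
)

TRAIT_STRUCTURE = {
    "Meat and Carcass": ["Muscle", "Fat deposition", "Carcass composition"],
    "Production": ["Growth", "Feed efficiency"],
    "Reproduction": ["Litter size"],
    "Health": ["Immune capacity"],
}
TRAIT_CLASS_PROBS = {
    "Meat and Carcass": 0.59,
    "Production": 0.11,
    "Reproduction": 0.15,
    "Health": 0.15,
}


class PlacementError(RuntimeError):
    """Raised when a chromosome cannot accommodate the requested loci."""


@dataclass(frozen=True)
class WorldConfig:
    """Parameters of the synthetic study.

    Defaults mirror the study design (3 stages x 3 replicates) and the
    planted-truth scenarios used throughout the test suite: 30 true
    lincRNAs, 10 decoys per failure mode, |log2FC| = 2 stage effects,
    NB dispersion 0.05, and library depth 5e7 fragments per sample.
    """

    n_chromosomes: int = 6
    chrom_length: int = 5_000_000
    n_coding_genes: int = 80
    n_background_genes: int = 300
    n_true_lincs: int = 30
    n_decoys_per_mode: int = 10
    decoy_modes: tuple[str, ...] = DECOY_MODES
    n_samples_per_stage: int = 3
    n_stages: int = 3
    nb_dispersion: float = 0.05
    de_log2fc: float = 2.0
    n_de_genes: int = 20
    n_de_lincs: int = 10
    n_known_lincs: int | None = None
    n_cis_targets: int = 8
    n_trans_targets: int = 10
    latent_r_cis: float = 0.95
    latent_r_trans: float = 0.99
    cis_plant_max_gap: int = 50_000
    trans_plant_min_gap: int = 500_000
    library_size: float = 5e7
    count_noise: bool = True
    n_proteins: int = 20
    rng_seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_chromosomes": self.n_chromosomes,
            "chrom_length": self.chrom_length,
            "n_coding_genes": self.n_coding_genes,
            "n_background_genes": self.n_background_genes,
            "n_true_lincs": self.n_true_lincs,
            "n_decoys_per_mode": self.n_decoys_per_mode,
            "n_samples_per_stage": self.n_samples_per_stage,
            "n_stages": self.n_stages,
            "n_de_genes": self.n_de_genes,
            "n_de_lincs": self.n_de_lincs,
            "n_cis_targets": self.n_cis_targets,
            "n_trans_targets": self.n_trans_targets,
        }
        for name, value in counts.items():
            if value < 0:
                raise ValueError(f"{name} must be >= 0, got {value}")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        unknown = set(self.decoy_modes) - set(DECOY_MODES)
        if unknown:
            raise ValueError(f"unknown decoy modes: {sorted(unknown)}")
        for name in ("latent_r_cis", "latent_r_trans"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0, 1], got {v}")

    @property
    def stage_labels(self) -> list[str]:
        if self.n_stages == 3:
            return ["D33", "D65", "D90"]
        return [f"D{i + 1}" for i in range(self.n_stages)]

    @property
    def sample_ids(self) -> list[str]:
        return [
            f"S{s + 1}_{r + 1}"
            for s in range(self.n_stages)
            for r in range(self.n_samples_per_stage)
        ]


@dataclass
class TruthTable:
    """Planted ground truth: per-transcript roles and planted effects,
    planted target pairs, planted QTL overlaps, and the planted log2-mean
    expression matrix (for diagnostic checks of the latent construction)."""

    transcripts: pd.DataFrame
    targets: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["linc_id", "gene_id", "mode", "latent_r"])
    )
    qtl_overlaps: dict[str, list[str]] = field(default_factory=dict)
    log2_means: pd.DataFrame | None = None

    def true_linc_ids(self) -> list[str]:
        return sorted(self.transcripts.index[self.transcripts["is_true_linc"]])

    def decoy_ids(self, mode: str | None = None) -> list[str]:
        df = self.transcripts
        sel = df["role"] == "decoy"
        if mode is not None:
            sel &= df["decoy_mode"] == mode
        return sorted(df.index[sel])

    def planted_de_ids(self, contrast: str | None = None) -> list[str]:
        col = self.transcripts["planted_de_contrasts"]
        if contrast is None:
            return sorted(self.transcripts.index[col != ""])
        return sorted(
            self.transcripts.index[col.str.split(",").apply(lambda cs: contrast in cs)]
        )

    def to_tsv(self, path: str | Path) -> None:
        self.transcripts.to_csv(path, sep="\t")


@dataclass
class SyntheticWorld:
    """The generated annotation, sequences, proteins and truth skeleton."""

    config: WorldConfig
    reference: list[TranscriptModel]
    known_lincs: list[TranscriptModel]
    assembled: list[TranscriptModel]
    sequences: dict[str, str]
    proteins: list[str]
    truth: TruthTable
    chrom_names: list[str]

    def transcript(self, tid: str) -> TranscriptModel:
        for t in self.assembled + self.reference:
            if t.transcript_id == tid:
                return t
        raise KeyError(tid)


# ---------------------------------------------------------------------------
# sequence construction


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


def _noncoding_seq(rng, length: int, peptide_index: set[str], max_tries: int = 200) -> str:
    """Random sequence with coding score < 0 and no peptide-index hit."""
    for _ in range(max_tries):
        s = _random_seq(rng, length)
        if coding_score(s) < 0 and not domain_hit(s, peptide_index):
            return s
    raise RuntimeError(f"could not draw a non-coding sequence of length {length}")


def _coding_like_seq(rng, length: int, peptide_index: set[str], max_tries: int = 200) -> str:
    """Sequence whose longest ORF covers ~90% of its length (score > 0)."""
    n_codons = max(int(0.9 * length) // 3, 10)
    for _ in range(max_tries):
        body = "".join(rng.choice(NON_STOP_CODONS, size=n_codons - 2))
        orf = "ATG" + body + "TAA"
        pad = length - len(orf)
        left = pad // 2
        s = _random_seq(rng, left) + orf + _random_seq(rng, pad - left)
        if coding_score(s) >= 0 and not domain_hit(s, peptide_index):
            return s
    raise RuntimeError("could not draw a coding-like sequence")


def _domain_hit_seq(
    rng, length: int, peptide: str, peptide_index: set[str], max_tries: int = 200
) -> str:
    """Non-coding sequence carrying an exact in-frame encoding of ``peptide``."""
    insert = "".join(AA_CODON[a] for a in peptide)
    for _ in range(max_tries):
        s = _random_seq(rng, length)
        pos = int(rng.integers(0, length - len(insert) + 1))
        s = s[:pos] + insert + s[pos + len(insert) :]
        if coding_score(s) < 0 and domain_hit(s, peptide_index):
            # must fail only the domain predicate: hit present, ORFs short
            return s
    raise RuntimeError("could not draw a domain-hit sequence")


# ---------------------------------------------------------------------------
# exon structures and placement


def _structure(rng, kind: str) -> list[tuple[int, int]]:
    """Relative exon coordinates (sorted, non-overlapping, starting at 0)."""
    if kind == "coding":
        n_exons = int(rng.integers(4, 11))
        exon_lens = rng.integers(120, 401, size=n_exons)
        introns = rng.integers(200, 3001, size=n_exons - 1)
    elif kind == "mono_exonic":
        return [(0, int(rng.integers(300, 1501)))]
    elif kind == "short":
        total = int(rng.integers(100, 201))
        first = total // 2
        intron = int(rng.integers(200, 1001))
        return [(0, first), (first + intron, first + intron + (total - first))]
    else:  # linc-like: true lincs and remaining decoy kinds
        n_exons = int(rng.integers(2, 5))
        exon_lens = rng.integers(150, 601, size=n_exons)
        introns = rng.integers(200, 2001, size=n_exons - 1)
    exons = []
    pos = 0
    for i, el in enumerate(exon_lens):
        exons.append((pos, pos + int(el)))
        pos += int(el)
        if i < len(exon_lens) - 1:
            pos += int(introns[i])
    return exons


def _place(
    chrom: str, offset: int, rel_exons: list[tuple[int, int]], strand: str
) -> tuple[GenomicInterval, ...]:
    return tuple(
        GenomicInterval(chrom, offset + s, offset + e, strand) for s, e in rel_exons
    )


# ---------------------------------------------------------------------------
# world construction


def build_world(config: WorldConfig) -> SyntheticWorld:
    """Generate annotation, sequences and the truth skeleton.

    Deterministic given ``config.rng_seed``.  Coding genes are placed
    non-overlapping; true-lincRNA loci sit strictly outside every reference
    gene span; each decoy violates exactly its planted predicate.  Raises
    :class:`PlacementError` naming the crowded chromosome when loci do not
    fit.
    """
    rng = np.random.default_rng([config.rng_seed, 0])
    chrom_names = [f"chr{i + 1}" for i in range(config.n_chromosomes)]

    # --- protein set (built first; all non-coding sequences are screened
    # against its full peptide index)
    proteins = [
        "".join(rng.choice(list(AA_ALPHABET), size=int(rng.integers(150, 401))))
        for _ in range(config.n_proteins)
    ]
    n_domain_decoys = (
        config.n_decoys_per_mode if "domain_hit" in config.decoy_modes else 0
    )
    bait_alphabet = [a for a in AA_ALPHABET if a != "M"]
    planted_peptides = []
    seen = set()
    while len(planted_peptides) < n_domain_decoys:
        pep = "".join(rng.choice(bait_alphabet, size=8))
        if pep not in seen:
            seen.add(pep)
            planted_peptides.append(pep)
    if planted_peptides:
        # one bait protein carrying every planted peptide
        proteins.append("".join(planted_peptides))
    peptide_index = build_peptide_index(proteins, k=8)

    # --- decide the loci and interleave coding/non-coding so every lincRNA
    # has a coding neighbour within cis range
    n_coding_total = config.n_coding_genes + config.n_background_genes
    noncoding_kinds: list[tuple[str, str]] = []  # (kind, decoy_mode or "")
    for i in range(config.n_true_lincs):
        noncoding_kinds.append(("linc", ""))
    for mode in config.decoy_modes:
        if mode == "overlap":
            continue  # placed afterwards, overlapping a coding gene
        for _ in range(config.n_decoys_per_mode):
            noncoding_kinds.append(("decoy", mode))

    order: list[tuple[str, str]] = []
    ci, ni = 0, 0
    while ci < n_coding_total or ni < len(noncoding_kinds):
        if ci < n_coding_total:
            order.append(("coding", ""))
            ci += 1
        if ni < len(noncoding_kinds):
            order.append(noncoding_kinds[ni])
            ni += 1

    per_chrom = math.ceil(len(order) / config.n_chromosomes) if order else 0
    reference: list[TranscriptModel] = []
    assembled: list[TranscriptModel] = []
    sequences: dict[str, str] = {}
    rows = []
    coding_counter = 0
    linc_counter = 0
    decoy_counters = {m: 0 for m in DECOY_MODES}

    for chrom_idx, chrom in enumerate(chrom_names):
        chunk = order[chrom_idx * per_chrom : (chrom_idx + 1) * per_chrom]
        cursor = int(rng.integers(5_000, 20_001))
        for kind, mode in chunk:
            strand = str(rng.choice(["+", "-"]))
            if kind == "coding":
                rel = _structure(rng, "coding")
            elif kind == "decoy":
                rel = _structure(rng, mode if mode in ("short", "mono_exonic") else "linc")
            else:
                rel = _structure(rng, "linc")
            span = rel[-1][1]
            if cursor + span > config.chrom_length:
                raise PlacementError(
                    f"chromosome {chrom} too crowded: cannot place locus of span "
                    f"{span} at {cursor} (chrom_length={config.chrom_length})"
                )
            exons = _place(chrom, cursor, rel, strand)
            if kind == "coding":
                coding_counter += 1
                is_background = coding_counter > config.n_coding_genes
                gid = f"G{coding_counter:04d}"
                t = TranscriptModel(f"{gid}.1", gid, exons, biotype="coding")
                reference.append(t)
                rows.append(
                    dict(
                        transcript_id=t.transcript_id,
                        gene_id=gid,
                        role="background" if is_background else "coding",
                        decoy_mode="",
                        is_true_linc=False,
                        novelty="",
                    )
                )
            elif kind == "linc":
                linc_counter += 1
                gid = f"LINC{linc_counter:04d}"
                t = TranscriptModel(f"{gid}.1", gid, exons, biotype="candidate")
                assembled.append(t)
                sequences[t.transcript_id] = _noncoding_seq(
                    rng, transcript_length(t), peptide_index
                )
                rows.append(
                    dict(
                        transcript_id=t.transcript_id,
                        gene_id=gid,
                        role="true_linc",
                        decoy_mode="",
                        is_true_linc=True,
                        novelty="",
                    )
                )
            else:
                decoy_counters[mode] += 1
                gid = f"DEC_{mode}{decoy_counters[mode]:03d}"
                t = TranscriptModel(f"{gid}.1", gid, exons, biotype="candidate")
                assembled.append(t)
                L = transcript_length(t)
                if mode == "coding_like":
                    seq = _coding_like_seq(rng, L, peptide_index)
                elif mode == "domain_hit":
                    pep = planted_peptides[decoy_counters[mode] - 1]
                    seq = _domain_hit_seq(rng, L, pep, peptide_index)
                else:
                    seq = _noncoding_seq(rng, L, peptide_index)
                sequences[t.transcript_id] = seq
                rows.append(
                    dict(
                        transcript_id=t.transcript_id,
                        gene_id=gid,
                        role="decoy",
                        decoy_mode=mode,
                        is_true_linc=False,
                        novelty="",
                    )
                )
            cursor += span + int(rng.integers(2_000, 30_001))

    # --- overlap decoys: one exon shares exonic bp with a reference transcript
    if "overlap" in config.decoy_modes and config.n_decoys_per_mode > 0:
        if not reference:
            raise ValueError("overlap decoys require at least one reference gene")
        gene_pool = rng.choice(len(reference), size=config.n_decoys_per_mode, replace=len(reference) < config.n_decoys_per_mode)
        for k, gi in enumerate(np.atleast_1d(gene_pool)):
            gene = reference[int(gi)]
            first_exon = gene.exons[0]
            decoy_counters["overlap"] += 1
            gid = f"DEC_overlap{decoy_counters['overlap']:03d}"
            strand = str(rng.choice(["+", "-"]))
            e1 = GenomicInterval(
                gene.chrom, first_exon.start, min(first_exon.start + 200, first_exon.end + 100), strand
            )
            intron = int(rng.integers(300, 1501))
            e2_start = e1.end + intron
            e2 = GenomicInterval(gene.chrom, e2_start, e2_start + 300, strand)
            t = TranscriptModel(f"{gid}.1", gid, (e1, e2), biotype="candidate")
            assembled.append(t)
            sequences[t.transcript_id] = _noncoding_seq(
                rng, transcript_length(t), peptide_index
            )
            rows.append(
                dict(
                    transcript_id=t.transcript_id,
                    gene_id=gid,
                    role="decoy",
                    decoy_mode="overlap",
                    is_true_linc=False,
                    novelty="",
                )
            )

    # --- known-lincRNA annotation: records coincident with the first
    # n_known true lincs (the rest are novel)
    true_lincs = [t for t in assembled if t.transcript_id.startswith("LINC")]
    n_known = (
        config.n_known_lincs
        if config.n_known_lincs is not None
        else (2 * config.n_true_lincs) // 3
    )
    n_known = min(n_known, len(true_lincs))
    known_lincs = []
    for i, t in enumerate(true_lincs[:n_known]):
        known_lincs.append(
            TranscriptModel(
                f"KNOWN{i + 1:04d}.1",
                f"KNOWN{i + 1:04d}",
                t.exons,
                biotype="lincRNA_known",
            )
        )
    truth_df = pd.DataFrame(rows).set_index("transcript_id")
    truth_df["planted_de_contrasts"] = ""
    truth_df["base_fpkm"] = np.nan
    known_ids = {t.transcript_id for t in true_lincs[:n_known]}
    truth_df.loc[truth_df["is_true_linc"], "novelty"] = [
        "known" if tid in known_ids else "novel"
        for tid in truth_df.index[truth_df["is_true_linc"]]
    ]

    # sanity: verify the planted intergenic property (no hidden state)
    ref_spans = {t.transcript_id: t.interval for t in reference}
    from .intervals import intersect as _intersect

    linc_spans = {t.transcript_id: t.interval for t in true_lincs}
    bad = {q for q, _, _ in _intersect(linc_spans, ref_spans)}
    if bad:
        raise PlacementError(f"true lincs unexpectedly overlap reference genes: {sorted(bad)}")

    return SyntheticWorld(
        config=config,
        reference=reference,
        known_lincs=known_lincs,
        assembled=assembled,
        sequences=sequences,
        proteins=proteins,
        truth=TruthTable(transcripts=truth_df),
        chrom_names=chrom_names,
    )


# ---------------------------------------------------------------------------
# counts


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """NB draw parameterized by mean and dispersion (var = mu + d * mu^2)."""
    r = 1.0 / dispersion
    p = r / (r + np.maximum(mu, 1e-12))
    return rng.negative_binomial(r, p, size=mu.shape).astype(float)


def _nb_log2_sd(mu: float, dispersion: float) -> float:
    """Approximate SD of log2 of an NB draw with mean mu."""
    return math.sqrt((1.0 / max(mu, 1.0) + dispersion) / LN2_SQ)


def build_counts(
    world: SyntheticWorld, config: WorldConfig | None = None
) -> tuple[ExpressionMatrix, TruthTable]:
    """Draw the count matrix and complete the truth table.

    Counts are negative-binomial around per-transcript expected values
    derived from base FPKM, planted stage effects (stage-mean ratio
    ``2 ** de_log2fc``) and latent pair factors.  With
    ``config.count_noise = False`` the expected counts are emitted without
    sampling (used to verify the latent construction exactly).
    Deterministic given the config seed.
    """
    config = config or world.config
    rng = np.random.default_rng([config.rng_seed, 1])
    truth = world.truth
    df = truth.transcripts
    stage_labels = config.stage_labels
    samples = config.sample_ids
    n_samples = len(samples)
    sample_stage = np.repeat(np.arange(config.n_stages), config.n_samples_per_stage)

    features = list(df.index)
    lengths = {}
    for t in world.assembled + world.reference:
        lengths[t.transcript_id] = transcript_length(t)
    L = np.array([lengths[f] for f in features], dtype=float)

    # --- base FPKM by role
    role = df["role"].to_numpy()
    base = np.empty(len(features))
    for i, r in enumerate(role):
        if r in ("coding", "background"):
            base[i] = rng.lognormal(math.log(5.0), 1.0)
        elif r == "true_linc":
            base[i] = 2.0 + rng.lognormal(math.log(1.0), 1.0)
        elif df["decoy_mode"].iloc[i] == "low_expression":
            base[i] = 0.1
        else:
            base[i] = 2.0 + rng.lognormal(math.log(1.0), 1.0)

    # --- background absorbs the remaining FPKM mass so realized FPKM ~= base
    is_bg = role == "background"
    fg_mass = float(np.sum(base[~is_bg] * L[~is_bg]))
    n_bg = int(is_bg.sum())
    if n_bg > 0:
        remaining = 1e9 - fg_mass
        if remaining <= 0:
            raise ValueError("foreground FPKM mass exceeds the library budget")
        base[is_bg] = remaining / n_bg / L[is_bg]

    # --- planted stage effects (log2 units)
    effects = np.zeros((len(features), n_samples))
    contrasts = [
        f"{stage_labels[i]}:{stage_labels[j]}"
        for i in range(config.n_stages)
        for j in range(i + 1, config.n_stages)
    ]
    de_contrast_col = pd.Series("", index=df.index, dtype=object)
    patterns = []
    if config.n_stages >= 2:
        for boundary in range(1, config.n_stages):
            vec = np.zeros(config.n_stages)
            vec[boundary:] = 1.0
            patterns.append(vec)
        if config.n_stages >= 3:
            bump = np.zeros(config.n_stages)
            bump[1:-1] = 1.0
            patterns.append(bump)

    linc_ids = [f for f, r in zip(features, role) if r == "true_linc"]
    gene_ids = [f for f, r in zip(features, role) if r == "coding"]
    de_lincs = list(rng.choice(linc_ids, size=min(config.n_de_lincs, len(linc_ids)), replace=False))
    de_genes = list(rng.choice(gene_ids, size=min(config.n_de_genes, len(gene_ids)), replace=False))
    fidx = {f: i for i, f in enumerate(features)}
    for fid in de_lincs + de_genes:
        pat = patterns[int(rng.integers(0, len(patterns)))] if patterns else np.zeros(config.n_stages)
        sign = float(rng.choice([-1.0, 1.0]))
        stage_effect = sign * config.de_log2fc * pat
        effects[fidx[fid]] += stage_effect[sample_stage]
        hit = [
            c
            for c, (i, j) in zip(
                contrasts,
                [
                    (i, j)
                    for i in range(config.n_stages)
                    for j in range(i + 1, config.n_stages)
                ],
            )
            if stage_effect[i] != stage_effect[j]
        ]
        de_contrast_col[fid] = ",".join(hit)

    # --- planted target pairs with shared latent factors
    mu_base = base * L * config.library_size / 1e9
    span = {t.transcript_id: t.interval for t in world.assembled + world.reference}
    tid_of_gene = {df["gene_id"].loc[f]: f for f in features}

    def _loading(fid: str, rho: float) -> float:
        # total non-factor variance of the member's log2 expression: NB
        # counting noise plus any planted stage effect (an independent
        # signal that would otherwise dilute the pair correlation below
        # the requested latent_r)
        sigma_sq = _nb_log2_sd(float(mu_base[fidx[fid]]), config.nb_dispersion) ** 2
        sigma_sq += float(np.var(effects[fidx[fid]]))
        if rho >= 1.0:
            return 2.0
        return math.sqrt(rho / (1.0 - rho) * sigma_sq)

    used_genes: set[str] = set()
    used_lincs: set[str] = set()
    pair_rows = []
    # lincs planted DE first, so the end-to-end pipeline predicts targets for them
    linc_order = de_lincs + [l for l in linc_ids if l not in de_lincs]
    # only foreground coding genes are eligible targets: the background
    # mass-absorbers are so highly expressed that their counts perturb the
    # per-sample library size, which would distort the planted correlation
    coding_transcripts = [
        t for t in world.reference if df["role"].get(t.transcript_id) == "coding"
    ]

    def _plant_pairs(mode: str, n_pairs: int, rho: float) -> None:
        planted = 0
        for lid in linc_order:
            if planted >= n_pairs:
                break
            if lid in used_lincs:
                continue
            liv = span[lid]
            candidates = []
            for t in coding_transcripts:
                tid = t.transcript_id
                if tid in used_genes:
                    continue
                if mode == "cis":
                    if t.chrom != liv.chrom:
                        continue
                    if liv.gap_to(t.interval) >= config.cis_plant_max_gap:
                        continue
                else:
                    if t.chrom == liv.chrom:
                        continue
                candidates.append(tid)
            if not candidates:
                continue
            gid = candidates[int(rng.integers(0, len(candidates)))]
            used_genes.add(gid)
            used_lincs.add(lid)
            f = rng.normal(0.0, 1.0, size=n_samples)
            if rho >= 1.0:
                c = 2.0
                effects[fidx[lid]] += c * f
                effects[fidx[gid]] += c * f
            else:
                effects[fidx[lid]] += _loading(lid, rho) * f
                effects[fidx[gid]] += _loading(gid, rho) * f
            pair_rows.append(dict(linc_id=lid, gene_id=gid, mode=mode, latent_r=rho))
            planted += 1
        if planted < n_pairs:
            raise ValueError(
                f"could only plant {planted}/{n_pairs} {mode} target pairs; "
                "increase n_true_lincs/n_coding_genes or relax distances"
            )

    _plant_pairs("cis", config.n_cis_targets, config.latent_r_cis)
    _plant_pairs("trans", config.n_trans_targets, config.latent_r_trans)

    # --- expected counts and NB sampling
    log2_mu = np.log2(np.maximum(mu_base, 1e-300))[:, None] + effects
    mu = np.minimum(2.0 ** log2_mu, 1e9)
    if config.count_noise:
        counts = _nb_draw(rng, mu, config.nb_dispersion)
    else:
        counts = mu
    counts_df = pd.DataFrame(counts, index=features, columns=samples)
    design = pd.Series(
        {s: stage_labels[sample_stage[i]] for i, s in enumerate(samples)}, name="stage"
    )
    expr = ExpressionMatrix(counts=counts_df, design=design)

    new_df = df.copy()
    new_df["planted_de_contrasts"] = de_contrast_col
    new_df["base_fpkm"] = base
    completed = TruthTable(
        transcripts=new_df,
        targets=pd.DataFrame(pair_rows, columns=["linc_id", "gene_id", "mode", "latent_r"]),
        qtl_overlaps=dict(truth.qtl_overlaps),
        log2_means=pd.DataFrame(log2_mu, index=features, columns=samples),
    )
    world.truth = completed
    return expr, completed


def feature_lengths(world: SyntheticWorld) -> pd.Series:
    """Mature lengths for every expression row of the world."""
    return pd.Series(
        {
            t.transcript_id: float(transcript_length(t))
            for t in world.assembled + world.reference
        }
    )


# ---------------------------------------------------------------------------
# QTLs


def build_qtls(
    world: SyntheticWorld,
    n_qtls: int = 50,
    overlap_fraction: float = 0.6,
    seed: int | None = None,
) -> list[QTLRecord]:
    """QTL intervals with trait labels; ``overlap_fraction`` of them are
    placed to intersect a randomly chosen true-lincRNA locus, the remainder
    avoid all true-linc loci.  Updates ``world.truth.qtl_overlaps``."""
    if not (0.0 <= overlap_fraction <= 1.0):
        raise ValueError(f"overlap_fraction must be in [0, 1], got {overlap_fraction}")
    config = world.config
    rng = np.random.default_rng(
        [config.rng_seed, 2] if seed is None else [int(seed), 2]
    )
    true_lincs = [t for t in world.assembled if t.transcript_id.startswith("LINC")]
    linc_spans = [t.interval for t in true_lincs]
    n_overlap = int(round(overlap_fraction * n_qtls))
    if n_overlap > 0 and not true_lincs:
        raise ValueError("cannot place overlapping QTLs: world has no true lincRNAs")

    classes = list(TRAIT_STRUCTURE)
    probs = np.array([TRAIT_CLASS_PROBS[c] for c in classes])
    probs = probs / probs.sum()

    records = []
    overlaps: dict[str, list[str]] = {t.transcript_id: [] for t in true_lincs}
    for k in range(n_qtls):
        qid = f"QTL{k + 1:05d}"
        if k < n_overlap:
            t = true_lincs[int(rng.integers(0, len(true_lincs)))]
            start = max(0, t.interval.start - int(rng.integers(0, 50_001)))
            end = min(config.chrom_length, t.interval.end + int(rng.integers(0, 50_001)))
            iv = GenomicInterval(t.chrom, start, end, ".")
        else:
            iv = None
            for _ in range(1000):
                chrom = world.chrom_names[int(rng.integers(0, len(world.chrom_names)))]
                length = int(rng.integers(10_000, 100_001))
                start = int(rng.integers(0, max(config.chrom_length - length, 1)))
                cand = GenomicInterval(chrom, start, start + length, ".")
                if all(cand.overlap_bp(sp) == 0 for sp in linc_spans):
                    iv = cand
                    break
            if iv is None:
                raise PlacementError("could not place a non-overlapping QTL in 1000 tries")
        cls = classes[int(rng.choice(len(classes), p=probs))]
        ttype = TRAIT_STRUCTURE[cls][int(rng.integers(0, len(TRAIT_STRUCTURE[cls])))]
        trait = f"{ttype} trait {int(rng.integers(1, 6))}"
        records.append(QTLRecord(qtl_id=qid, interval=iv, trait=trait, trait_type=ttype, trait_class=cls))
        for t in true_lincs:
            if iv.overlap_bp(t.interval) > 0:
                overlaps[t.transcript_id].append(qid)
    world.truth.qtl_overlaps = overlaps
    return records


def build_term_map(
    world: SyntheticWorld, n_terms: int = 15, seed: int | None = None
) -> dict[str, list[str]]:
    """A synthetic term -> gene map over the world's coding transcripts,
    for exercising the enrichment test without an external annotation."""
    config = world.config
    rng = np.random.default_rng([config.rng_seed, 3] if seed is None else [int(seed), 3])
    genes = [t.transcript_id for t in world.reference]
    terms: dict[str, list[str]] = {}
    for i in range(n_terms):
        size = int(rng.integers(5, max(6, len(genes) // 4)))
        members = rng.choice(genes, size=min(size, len(genes)), replace=False)
        terms[f"TERM{i + 1:03d}"] = sorted(members)
    return terms


# ---------------------------------------------------------------------------
# simple two-group count simulation (operating-characteristic checks)


def simulate_two_group_counts(
    n_features: int = 2000,
    n_de: int = 100,
    log2fc: float = 2.0,
    dispersion: float = 0.05,
    n_per_group: int = 3,
    base_log_mean: float = math.log(5000.0),
    base_log_sd: float = 1.0,
    seed: int = 0,
) -> tuple[ExpressionMatrix, pd.Series, list[str]]:
    """Two-condition NB counts with the first ``n_de`` features shifted by
    ``log2fc``.  Returns (expression matrix, unit lengths, planted DE ids);
    used for power/FDR/type-I calibration of the differential test."""
    rng = np.random.default_rng(seed)
    base = rng.lognormal(base_log_mean, base_log_sd, n_features)
    lfc = np.zeros(n_features)
    lfc[:n_de] = log2fc
    features = [f"F{i + 1:05d}" for i in range(n_features)]
    samples = [f"A_{r + 1}" for r in range(n_per_group)] + [
        f"B_{r + 1}" for r in range(n_per_group)
    ]
    mu = np.concatenate(
        [
            np.tile(base[:, None], (1, n_per_group)),
            np.tile((base * 2.0 ** lfc)[:, None], (1, n_per_group)),
        ],
        axis=1,
    )
    counts = _nb_draw(rng, mu, dispersion)
    design = pd.Series(
        {s: ("A" if s.startswith("A") else "B") for s in samples}, name="stage"
    )
    expr = ExpressionMatrix(pd.DataFrame(counts, index=features, columns=samples), design)
    lengths = pd.Series(1000.0, index=features)
    return expr, lengths, features[:n_de]
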