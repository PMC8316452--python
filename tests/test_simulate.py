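"""The synthetic-world generator and its planted-truth contracts."""

import math

import numpy as np
import pandas as pd
import pytest

from lincscan import (
    WorldConfig,
    build_counts,
    build_qtls,
    build_world,
    fpkm,
)
from lincscan.identify import build_peptide_index, coding_score, domain_hit
from lincscan.annotation import transcript_length
from lincscan.simulate import (
    DECOY_MODES,
    build_term_map,
    feature_lengths,
    simulate_two_group_counts,
)

SMALL = dict(
    n_coding_genes=30,
    n_background_genes=100,
    n_true_lincs=10,
    n_decoys_per_mode=2,
    n_de_lincs=3,
    n_de_genes=4,
    n_cis_targets=2,
    n_trans_targets=2,
)


class TestWorldConfig:
    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            WorldConfig(n_true_lincs=-1)

    def test_dispersion_positive(self):
        with pytest.raises(ValueError):
            WorldConfig(nb_dispersion=0.0)

    def test_unknown_decoy_mode(self):
        with pytest.raises(ValueError):
            WorldConfig(decoy_modes=("overlap", "bogus"))

    def test_latent_r_range(self):
        with pytest.raises(ValueError):
            WorldConfig(latent_r_trans=1.5)

    def test_stage_and_sample_labels(self):
        cfg = WorldConfig()
        assert cfg.stage_labels == ["D33", "D65", "D90"]
        assert len(cfg.sample_ids) == 9


class TestBuildWorldDeterminism:
    def test_same_seed_identical(self):
        cfg = WorldConfig(rng_seed=5, **SMALL)
        w1 = build_world(cfg)
        w2 = build_world(cfg)
        assert [t.transcript_id for t in w1.assembled] == [t.transcript_id for t in w2.assembled]
        assert all(
            a.exons == b.exons for a, b in zip(w1.assembled + w1.reference, w2.assembled + w2.reference)
        )
        assert w1.sequences == w2.sequences
        assert w1.proteins == w2.proteins

    def test_counts_identical(self):
        cfg = WorldConfig(rng_seed=5, **SMALL)
        e1, t1 = build_counts(build_world(cfg))
        e2, t2 = build_counts(build_world(cfg))
        pd.testing.assert_frame_equal(e1.counts, e2.counts)
        pd.testing.assert_frame_equal(t1.targets, t2.targets)

    def test_different_seed_differs(self):
        w1 = build_world(WorldConfig(rng_seed=1, **SMALL))
        w2 = build_world(WorldConfig(rng_seed=2, **SMALL))
        assert w1.sequences != w2.sequences


def test_no_true_lincs_case():
    cfg = WorldConfig(rng_seed=0, **{**SMALL, "n_true_lincs": 0, "n_de_lincs": 0,
                                     "n_cis_targets": 0, "n_trans_targets": 0})
    world = build_world(cfg)
    assert not world.truth.transcripts["is_true_linc"].any()


class TestPlantedPredicates:
    """Each planted role verified by independent per-predicate checks over
    the emitted annotation, sequences and counts."""

    @pytest.fixture(scope="class")
    @staticmethod
    def world():
        cfg = WorldConfig(rng_seed=11, **SMALL)
        w = build_world(cfg)
        expr, truth = build_counts(w)
        expr = fpkm(expr, feature_lengths(w))
        return w, expr, truth

    def _spans_overlap(self, t, reference):
        return any(
            t.chrom == r.chrom and t.interval.overlap_bp(r.interval) > 0
            for r in reference
        )

    def test_true_lincs_pass_every_predicate(self, world):
        w, expr, truth = world
        index = build_peptide_index(w.proteins, 8)
        for tid in truth.true_linc_ids():
            t = w.transcript(tid)
            assert not self._spans_overlap(t, w.reference)
            assert transcript_length(t) > 200
            assert t.n_exons >= 2
            assert coding_score(w.sequences[tid]) < 0
            assert not domain_hit(w.sequences[tid], index)
            assert float(expr.fpkm.loc[tid].max()) > 0.5

    def test_overlap_decoys_share_exonic_bp(self, world):
        w, _, truth = world
        for tid in truth.decoy_ids("overlap"):
            t = w.transcript(tid)
            shares_exon = any(
                e.overlap_bp(re_) > 0
                for r in w.reference
                if r.chrom == t.chrom
                for e in t.exons
                for re_ in r.exons
            )
            assert shares_exon

    def test_short_decoys(self, world):
        w, _, truth = world
        for tid in truth.decoy_ids("short"):
            assert transcript_length(w.transcript(tid)) <= 200

    def test_mono_exonic_decoys(self, world):
        w, _, truth = world
        for tid in truth.decoy_ids("mono_exonic"):
            assert w.transcript(tid).n_exons == 1

    def test_coding_like_decoys(self, world):
        w, _, truth = world
        for tid in truth.decoy_ids("coding_like"):
            assert coding_score(w.sequences[tid]) >= 0

    def test_domain_hit_decoys(self, world):
        w, _, truth = world
        index = build_peptide_index(w.proteins, 8)
        for tid in truth.decoy_ids("domain_hit"):
            assert domain_hit(w.sequences[tid], index)

    def test_low_expression_decoys(self, world):
        w, expr, truth = world
        for tid in truth.decoy_ids("low_expression"):
            # planted expected FPKM is <= 0.5 in every sample
            assert truth.transcripts.loc[tid, "base_fpkm"] <= 0.5
            assert float(expr.fpkm.loc[tid].max()) <= 0.5

    def test_each_decoy_fails_exactly_one_predicate(self, world):
        w, expr, truth = world
        index = build_peptide_index(w.proteins, 8)
        expected_fail = {
            "overlap": "intergenic",
            "short": "length_gt_200",
            "mono_exonic": "exons_ge_2",
            "coding_like": "coding_score_lt_0",
            "domain_hit": "no_domain_hit",
            "low_expression": "fpkm_gt_0.5_any_sample",
        }
        for mode in DECOY_MODES:
            for tid in truth.decoy_ids(mode):
                t = w.transcript(tid)
                results = {
                    "intergenic": not self._spans_overlap(t, w.reference),
                    "length_gt_200": transcript_length(t) > 200,
                    "exons_ge_2": t.n_exons >= 2,
                    "coding_score_lt_0": coding_score(w.sequences[tid]) < 0,
                    "no_domain_hit": not domain_hit(w.sequences[tid], index),
                    "fpkm_gt_0.5_any_sample": float(expr.fpkm.loc[tid].max()) > 0.5,
                }
                failed = [k for k, ok in results.items() if not ok]
                assert failed == [expected_fail[mode]], (mode, tid, failed)


class TestBuildCounts:
    def test_de_bookkeeping(self):
        cfg = WorldConfig(rng_seed=4, **{**SMALL, "n_de_lincs": 3, "n_de_genes": 4})
        world = build_world(cfg)
        _, truth = build_counts(world)
        de_ids = truth.planted_de_ids()
        assert len(de_ids) == 7
        roles = truth.transcripts.loc[de_ids, "role"]
        assert (roles == "true_linc").sum() == 3
        assert (roles == "coding").sum() == 4

    def test_zero_log2fc_mean_ratio_near_one(self):
        # with de_log2fc = 0 the realized stage-mean ratio of the planted
        # features is 1 within 5% over ~1000 replicate draws
        ratios = []
        for seed in range(12):
            cfg = WorldConfig(
                rng_seed=seed,
                de_log2fc=0.0,
                **{**SMALL, "n_de_genes": 10, "n_de_lincs": 0,
                   "n_cis_targets": 0, "n_trans_targets": 0},
            )
            world = build_world(cfg)
            expr, truth = build_counts(world)
            coding_ids = truth.transcripts.index[
                truth.transcripts["role"] == "coding"
            ]
            c = expr.counts
            stages = cfg.stage_labels
            by_stage = {
                st: [s for s in c.columns if expr.design[s] == st] for st in stages
            }
            for i in range(len(stages)):
                for j in range(i + 1, len(stages)):
                    a = c.loc[coding_ids, by_stage[stages[i]]].mean(axis=1)
                    b = c.loc[coding_ids, by_stage[stages[j]]].mean(axis=1)
                    ratios.extend(((b + 1) / (a + 1)).tolist())
        assert len(ratios) >= 1000
        assert abs(np.mean(ratios) - 1.0) < 0.05

    def test_latent_r_one_exact_without_noise(self):
        cfg = WorldConfig(
            rng_seed=2,
            count_noise=False,
            latent_r_cis=1.0,
            latent_r_trans=1.0,
            **{**SMALL, "n_de_genes": 0, "n_de_lincs": 0},
        )
        world = build_world(cfg)
        _, truth = build_counts(world)
        assert len(truth.targets) == 4
        for row in truth.targets.itertuples(index=False):
            x = truth.log2_means.loc[row.linc_id].to_numpy()
            y = truth.log2_means.loc[row.gene_id].to_numpy()
            r = np.corrcoef(x, y)[0, 1]
            assert r == pytest.approx(1.0, abs=1e-9)

    def test_planted_pairs_respect_geometry(self):
        cfg = WorldConfig(rng_seed=9, **SMALL)
        world = build_world(cfg)
        _, truth = build_counts(world)
        for row in truth.targets.itertuples(index=False):
            linc = world.transcript(row.linc_id)
            gene = world.transcript(row.gene_id)
            if row.mode == "cis":
                assert linc.chrom == gene.chrom
                assert linc.interval.gap_to(gene.interval) < cfg.cis_plant_max_gap
            else:
                assert linc.chrom != gene.chrom
            # planted targets are foreground coding genes, never background
            assert truth.transcripts.loc[row.gene_id, "role"] == "coding"

    def test_nb_variance_exceeds_mean(self):
        # distributional invariant of the NB sampler at n = 10,000 draws
        from lincscan.simulate import _nb_draw

        rng = np.random.default_rng(0)
        mu, disp = 500.0, 0.05
        draws = _nb_draw(rng, np.full((10_000, 1), mu), disp).ravel()
        expected_var = mu + disp * mu * mu
        assert draws.var() > draws.mean()
        assert abs(draws.var() / expected_var - 1.0) < 0.10
        assert abs(draws.mean() / mu - 1.0) < 0.10

    def test_fpkm_matches_intended_base(self):
        # background absorption makes realized FPKM track the planted base
        cfg = WorldConfig(rng_seed=6, **SMALL)
        world = build_world(cfg)
        expr, truth = build_counts(world)
        expr = fpkm(expr, feature_lengths(world))
        coding = truth.transcripts[truth.transcripts["role"] == "coding"]
        no_effect = coding[coding["planted_de_contrasts"] == ""]
        ids = [i for i in no_effect.index
               if i not in set(truth.targets["gene_id"])]
        realized = expr.fpkm.loc[ids].mean(axis=1)
        base = truth.transcripts.loc[ids, "base_fpkm"]
        ratio = (realized / base).to_numpy()
        assert abs(np.median(ratio) - 1.0) < 0.25


class TestBuildQtls:
    def test_overlap_fraction_zero(self):
        cfg = WorldConfig(rng_seed=3, **SMALL)
        world = build_world(cfg)
        qtls = build_qtls(world, n_qtls=20, overlap_fraction=0.0)
        lincs = [world.transcript(t) for t in world.truth.true_linc_ids()]
        for q in qtls:
            assert all(q.interval.overlap_bp(t.interval) == 0 for t in lincs)

    def test_overlap_fraction_one(self):
        cfg = WorldConfig(rng_seed=3, **SMALL)
        world = build_world(cfg)
        qtls = build_qtls(world, n_qtls=50, overlap_fraction=1.0)
        lincs = [world.transcript(t) for t in world.truth.true_linc_ids()]
        assert len(qtls) == 50
        for q in qtls:
            assert any(q.interval.overlap_bp(t.interval) > 0 for t in lincs)

    def test_determinism(self):
        cfg = WorldConfig(rng_seed=3, **SMALL)
        q1 = build_qtls(build_world(cfg), n_qtls=25, overlap_fraction=0.6)
        q2 = build_qtls(build_world(cfg), n_qtls=25, overlap_fraction=0.6)
        assert q1 == q2

    def test_bad_fraction(self):
        world = build_world(WorldConfig(rng_seed=3, **SMALL))
        with pytest.raises(ValueError):
            build_qtls(world, overlap_fraction=1.5)

    def test_truth_overlap_bookkeeping(self):
        cfg = WorldConfig(rng_seed=8, **SMALL)
        world = build_world(cfg)
        qtls = build_qtls(world, n_qtls=30, overlap_fraction=0.5)
        for tid, qids in world.truth.qtl_overlaps.items():
            t = world.transcript(tid)
            expected = sorted(
                q.qtl_id for q in qtls if q.interval.overlap_bp(t.interval) > 0
            )
            assert sorted(qids) == expected


def test_term_map_structure():
    world = build_world(WorldConfig(rng_seed=3, **SMALL))
    terms = build_term_map(world, n_terms=8)
    gene_ids = {t.transcript_id for t in world.reference}
    assert len(terms) == 8
    for members in terms.values():
        assert set(members) <= gene_ids
        assert len(members) >= 5


def test_simulate_two_group_counts_shapes():
    expr, lengths, de_ids = simulate_two_group_counts(
        n_features=100, n_de=10, seed=1
    )
    assert expr.counts.shape == (100, 6)
    assert len(de_ids) == 10
    assert (lengths == 1000.0).all()
    # planted features really are shifted
    e = fpkm(expr, lengths)
    a = e.fpkm[[c for c in e.fpkm.columns if c.startswith("A")]].mean(axis=1)
    b = e.fpkm[[c for c in e.fpkm.columns if c.startswith("B")]].mean(axis=1)
    lfc = np.log2((b + 1) / (a + 1))
    assert lfc[de_ids].mean() > 1.0
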