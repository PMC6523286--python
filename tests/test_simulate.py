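"""Seeded generators: planted structure, determinism, distributions."""

import numpy as np
import pandas as pd
import pytest

from shadowy.gwas import HOM_REF, HET, HOM_ALT, MISSING, run_sex_gwas
from shadowy.simulate import (
    EXCLUDED_TYPE,
    NULL,
    SHADOW_Y,
    X_LINKED,
    SeqSimConfig,
    SimConfig,
    TrackSimConfig,
    simulate_feature_tracks,
    simulate_genotypes,
    simulate_retrocopy_sequences,
)


class TestGenotypeSim:
    def test_shadow_markers_forced_pattern(self):
        cfg = SimConfig(n_males=25, n_females=25, n_null_markers=0,
                        n_shadow_markers=10, missing_rate=0.0, seed=3)
        gm, truth = simulate_genotypes(cfg)
        male = gm.sex_mask("male")
        female = gm.sex_mask("female")
        assert all(t == SHADOW_Y for t in truth.values())
        for j in range(gm.n_markers):
            assert (gm.calls[male, j] == HET).all()
            fem = gm.calls[female, j]
            assert len(np.unique(fem)) == 1 and fem[0] in (HOM_REF, HOM_ALT)

    def test_seeded_determinism(self):
        cfg = SimConfig(n_null_markers=500, n_shadow_markers=5,
                        n_xlinked_markers=5, n_excluded_markers=5,
                        missing_rate=0.02, seed=1)
        gm1, t1 = simulate_genotypes(cfg)
        gm2, t2 = simulate_genotypes(cfg)
        assert np.array_equal(gm1.calls, gm2.calls)
        assert t1 == t2
        pd.testing.assert_frame_equal(gm1.markers, gm2.markers)

    def test_hwe_heterozygote_frequency(self):
        # MAF pinned at 0.2: per-marker het frequency ~ Binomial(1000, 0.32)
        cfg = SimConfig(n_males=500, n_females=500, n_null_markers=2000,
                        maf_range=(0.2, 0.2), n_shadow_markers=0, seed=7)
        gm, _ = simulate_genotypes(cfg)
        het_freq = (gm.calls == HET).mean(axis=0)
        expect = 2 * 0.2 * 0.8
        se = np.sqrt(expect * (1 - expect) / 1000)
        # mean over 2000 markers: SE shrinks by sqrt(2000)
        assert abs(het_freq.mean() - expect) < 3 * se / np.sqrt(2000)
        assert (np.abs(het_freq - expect) < 5 * se).mean() > 0.99

    def test_null_markers_sex_independent(self):
        # >=1000 nulls: conservative exact P distribution, no Bonferroni hits
        cfg = SimConfig(n_null_markers=1500, n_shadow_markers=0, seed=11)
        gm, _ = simulate_genotypes(cfg)
        _, man = run_sex_gwas(gm)
        assert man["significant"].sum() == 0
        assert 0.4 <= man["p"].median() <= 1.0

    def test_class_counts_and_missingness(self):
        cfg = SimConfig(n_null_markers=400, n_shadow_markers=30,
                        n_xlinked_markers=20, n_excluded_markers=10,
                        missing_rate=0.05, seed=2)
        gm, truth = simulate_genotypes(cfg)
        counts = pd.Series(truth).value_counts()
        assert gm.n_markers == 460 == len(truth)
        assert (counts[NULL], counts[SHADOW_Y], counts[X_LINKED],
                counts[EXCLUDED_TYPE]) == (400, 30, 20, 10)
        miss = (gm.calls == MISSING).mean()
        se = np.sqrt(0.05 * 0.95 / gm.calls.size)
        assert abs(miss - 0.05) < 3 * se

    def test_xlinked_males_emitted_homozygous(self):
        cfg = SimConfig(n_null_markers=0, n_shadow_markers=0,
                        n_xlinked_markers=40, seed=5)
        gm, _ = simulate_genotypes(cfg)
        male_calls = gm.calls[gm.sex_mask("male"), :]
        assert not (male_calls == HET).any()
        assert (gm.markers["chrom"] == "X").all()

    def test_excluded_markers_mix_het_and_hom(self):
        cfg = SimConfig(n_null_markers=0, n_shadow_markers=0,
                        n_excluded_markers=15, seed=9)
        gm, _ = simulate_genotypes(cfg)
        male = gm.sex_mask("male")
        female = gm.sex_mask("female")
        for j in range(gm.n_markers):
            mc = gm.calls[male, j]
            assert (mc == HET).any() and ((mc == HOM_REF) | (mc == HOM_ALT)).any()
            assert len(np.unique(gm.calls[female, j])) == 1

    def test_shadow_without_both_sexes_rejected(self):
        with pytest.raises(ValueError, match="both sexes"):
            simulate_genotypes(SimConfig(n_females=0, n_shadow_markers=1))

    @pytest.mark.parametrize(
        "kw", [dict(n_males=-1), dict(missing_rate=1.0), dict(maf_range=(0.0, 0.2))]
    )
    def test_invalid_config_rejected(self, kw):
        with pytest.raises(ValueError):
            SimConfig(**kw)


class TestTrackSim:
    SEXES = {"m1": "male", "m2": "male", "f1": "female", "f2": "female"}

    def test_depth_expectations(self):
        cfg = TrackSimConfig(n_windows=60, exon_windows=frozenset(range(30)),
                             base_depth=30, dup_depth_factor=1.5, seed=4)
        tr = simulate_feature_tracks(cfg, self.SEXES)
        exon = tr["window_start"] <= 30 * cfg.window_size
        male = tr["sex"] == "male"
        # 60 draws per cell: SE of the mean ~ sqrt(lambda/n)
        m_exon = tr.loc[exon & male, "depth"].mean()
        f_exon = tr.loc[exon & ~male, "depth"].mean()
        assert abs(m_exon - 45) < 3 * np.sqrt(45 / 60)
        assert abs(f_exon - 30) < 3 * np.sqrt(30 / 60)

    def test_non_exon_windows_sex_balanced(self):
        cfg = TrackSimConfig(n_windows=80, exon_windows=frozenset({0}), seed=6)
        tr = simulate_feature_tracks(cfg, self.SEXES)
        null = tr["window_start"] > cfg.window_size
        male = tr["sex"] == "male"
        for col in ("depth", "het_density", "discordant_frac", "lowmapq_frac"):
            m = tr.loc[null & male, col].mean()
            f = tr.loc[null & ~male, col].mean()
            sd = tr.loc[null, col].std()
            n = null.sum() / 2
            assert abs(m - f) < 4 * sd / np.sqrt(n)

    def test_empty_exon_set_is_pure_null(self):
        cfg = TrackSimConfig(n_windows=10, exon_windows=frozenset(), seed=8)
        tr = simulate_feature_tracks(cfg, self.SEXES)
        assert len(tr) == 10 * 4

    def test_byte_identical_given_seed(self):
        cfg = TrackSimConfig(n_windows=20, exon_windows=frozenset({3}), seed=12)
        t1 = simulate_feature_tracks(cfg, self.SEXES)
        t2 = simulate_feature_tracks(cfg, self.SEXES)
        assert t1.to_csv() == t2.to_csv()

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            TrackSimConfig(n_windows=5, exon_windows=frozenset({5}))
        with pytest.raises(ValueError):
            TrackSimConfig(dup_depth_factor=1.0)


FIVE_TAXON = "(urocyon,(vulpes,(lycaon,(latrans,familiaris))));"
ROOT_BRANCH = "familiaris,latrans,lycaon,urocyon,vulpes"


class TestSequenceSim:
    def test_divergence_sets_identity(self):
        cfg = SeqSimConfig(parent_length=3000, divergence_rate=0.02,
                           branch_rate=0.0, tree=FIVE_TAXON,
                           gain_branch=ROOT_BRANCH, seed=13)
        parent, copies, truth = simulate_retrocopy_sequences(cfg)
        assert truth.gain_branches == (ROOT_BRANCH,)
        copy = copies["familiaris"]
        mismatches = sum(a != b for a, b in zip(parent, copy))
        se = np.sqrt(0.02 * 0.98 / 3000)
        assert abs(mismatches / 3000 - 0.02) < 3 * se

    def test_no_gain_no_copies(self):
        cfg = SeqSimConfig(tree=FIVE_TAXON, gain_branch=None, seed=1)
        parent, copies, truth = simulate_retrocopy_sequences(cfg)
        assert len(parent) == cfg.parent_length
        assert all(v is None for v in copies.values())
        assert truth.gain_branches == () and truth.n_events == 0

    def test_root_gain_reaches_every_tip_with_shared_sites(self):
        cfg = SeqSimConfig(parent_length=800, divergence_rate=0.03,
                           branch_rate=0.0, tree=FIVE_TAXON,
                           gain_branch=ROOT_BRANCH, seed=21)
        parent, copies, _ = simulate_retrocopy_sequences(cfg)
        seqs = list(copies.values())
        assert all(s is not None for s in seqs)
        # no further mutation below the gain: all tips carry the same copy
        assert len(set(seqs)) == 1 and seqs[0] != parent

    def test_subtree_gain_excludes_outgroups(self):
        gain = "familiaris,latrans"
        cfg = SeqSimConfig(tree=FIVE_TAXON, gain_branch=gain, seed=2)
        _, copies, _ = simulate_retrocopy_sequences(cfg)
        assert copies["familiaris"] is not None and copies["latrans"] is not None
        assert copies["vulpes"] is None and copies["urocyon"] is None

    def test_malformed_newick_rejected(self):
        with pytest.raises(ValueError, match="Newick"):
            simulate_retrocopy_sequences(
                SeqSimConfig(tree="((a,b);", gain_branch=None))

    def test_unknown_gain_branch_rejected(self):
        with pytest.raises(KeyError):
            simulate_retrocopy_sequences(
                SeqSimConfig(tree=FIVE_TAXON, gain_branch="vulpes,urocyon"))

    def test_seeded_determinism(self):
        cfg = SeqSimConfig(tree=FIVE_TAXON, gain_branch=ROOT_BRANCH,
                           indel_rate=0.005, seed=33)
        out1 = simulate_retrocopy_sequences(cfg)
        out2 = simulate_retrocopy_sequences(cfg)
        assert out1[0] == out2[0] and out1[1] == out2[1]
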