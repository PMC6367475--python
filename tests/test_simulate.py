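"""Synthetic-data generator: determinism, structure, planted ground truth."""

import numpy as np
import pandas as pd
import pytest

from mirarray.config import SimConfig
from mirarray.errors import ConfigurationError
from mirarray.simulate import (
    make_design,
    make_microarray,
    make_mirna_set,
    make_transcriptome,
    simulate_all,
    _draw_mirnas,
)
from oracles import brute_force_orfs


class TestMakeMirnaSet:
    def test_deterministic_given_seed(self):
        cfg = SimConfig(rng_seed=7, n_mirnas=1)
        assert make_mirna_set(cfg) == make_mirna_set(cfg)

    def test_names_unique(self):
        cfg = SimConfig(rng_seed=1, n_mirnas=100)
        names = [n for n, _ in make_mirna_set(cfg)]
        assert len(set(names)) == 100

    def test_degenerate_length_range(self):
        cfg = SimConfig(rng_seed=1, n_mirnas=25, mirna_len=(22, 22))
        assert all(len(s) == 22 for _, s in make_mirna_set(cfg))

    def test_rna_alphabet(self):
        cfg = SimConfig(rng_seed=2, n_mirnas=50)
        for _, seq in make_mirna_set(cfg):
            assert set(seq) <= set("ACGU")
            assert 18 <= len(seq) <= 24

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigurationError):
            make_mirna_set(SimConfig(n_mirnas=0))
        with pytest.raises(ConfigurationError):
            make_mirna_set(SimConfig(mirna_len=(24, 18)))


class TestMakeTranscriptome:
    def test_zero_plant_probability_gives_no_sites(self):
        cfg = SimConfig(rng_seed=3, n_contigs=20, n_mirnas=10, site_plant_prob=0.0)
        mirnas = make_mirna_set(cfg)
        _contigs, truth = make_transcriptome(cfg, mirnas)
        assert truth.planted_sites == []

    def test_plant_probability_one_covers_every_contig(self, small_sim):
        planted_contigs = {c for c, _m, _o in small_sim["truth"].planted_sites}
        assert planted_contigs == {c for c, _ in small_sim["contigs"]}

    def test_planted_orfs_refound_by_brute_force_at_coordinates(self, small_sim):
        """Six-frame-style every-ATG walk finds each planted ORF exactly where
        the truth table says."""
        seqs = dict(small_sim["contigs"])
        min_len = small_sim["config"].min_orf_codons
        for cid, start, end, frame in small_sim["truth"].planted_orfs:
            found = brute_force_orfs(seqs[cid], min_len)
            assert (start, end, frame, True) in found

    def test_coordinates_stay_inside_sequences(self, small_sim):
        seqs = dict(small_sim["contigs"])
        for cid, start, end, _frame in small_sim["truth"].planted_orfs:
            assert 0 <= start < end <= len(seqs[cid])
        orf_end = {c: e for c, _s, e, _f in small_sim["truth"].planted_orfs}
        for cid, _m, off in small_sim["truth"].planted_sites:
            assert orf_end[cid] + off + 7 <= len(seqs[cid])

    def test_sites_lie_downstream_of_orf_stop(self, small_sim):
        orf_end = {c: e for c, _s, e, _f in small_sim["truth"].planted_orfs}
        for cid, _m, off in small_sim["truth"].planted_sites:
            assert off >= 0 and orf_end[cid] >= 0

    def test_incompatible_orf_and_contig_lengths_rejected(self):
        with pytest.raises(ConfigurationError):
            SimConfig(contig_len=(200, 300), orf_len=(80, 100)).validate()

    def test_deterministic_sequences(self):
        cfg = SimConfig(rng_seed=8, n_contigs=5, n_mirnas=5)
        a = make_transcriptome(cfg, make_mirna_set(cfg))[0]
        b = make_transcriptome(cfg, make_mirna_set(cfg))[0]
        assert a == b


class TestMakeDesign:
    @pytest.mark.parametrize("replicates,expected", [(3, 24), (2, 16)])
    def test_sample_count(self, replicates, expected):
        design = make_design(SimConfig(replicates=replicates))
        assert len(design) == expected
        assert design["sample_id"].nunique() == expected

    def test_cohort_levels_fixed(self):
        design = make_design(SimConfig())
        assert set(design["cohort"]) == {"R+", "R-", "S+", "S-"}
        assert set(design["tissue"]) == {"cuticle", "fat_body"}

    def test_single_replicate_rejected(self):
        with pytest.raises(ConfigurationError):
            make_design(SimConfig(replicates=1))


class TestMakeMicroarray:
    def test_noiseless_null_replicates_identical(self):
        cfg = SimConfig(rng_seed=4, n_mirnas=20, noise_sd=0.0, bias_amplitude=0.0)
        rng = np.random.default_rng(4)
        mirnas = _draw_mirnas(cfg, rng)
        design = make_design(cfg)
        matrix, _ = make_microarray(cfg, mirnas, design, rng=rng, planted_de=[])
        fg = matrix.foreground
        # every column identical up to the background draw
        corrected = fg.values - matrix.background.values
        assert np.allclose(corrected, corrected[:, [0]])

    def test_planted_effect_reads_back_exactly_without_noise(self):
        planted = [("syn-mir-0003", "R- vs S- / fat_body", "up", 2.0)]
        cfg = SimConfig(rng_seed=5, n_mirnas=10, noise_sd=0.0, bias_amplitude=0.0)
        rng = np.random.default_rng(5)
        mirnas = _draw_mirnas(cfg, rng)
        design = make_design(cfg)
        matrix, _ = make_microarray(cfg, mirnas, design, rng=rng, planted_de=planted)
        signal = np.log2(matrix.foreground.values - matrix.background.values)
        cols = list(matrix.foreground.columns)
        rminus = [i for i, s in enumerate(cols) if s.startswith("R-_fat_body")]
        sminus = [i for i, s in enumerate(cols) if s.startswith("S-_fat_body")]
        rows = [i for i, p in enumerate(matrix.foreground.index)
                if p.startswith("syn-mir-0003|")]
        diff = signal[np.ix_(rows, rminus)].mean() - signal[np.ix_(rows, sminus)].mean()
        assert diff == pytest.approx(2.0, abs=1e-12)

    def test_probe_triplicate_structure(self, small_sim):
        counts = small_sim["matrix"].probe_to_mirna.value_counts()
        assert (counts == 3).all()
        assert len(counts) == small_sim["config"].n_mirnas

    def test_intensities_nonnegative(self, small_sim):
        assert (small_sim["matrix"].foreground.values >= 0).all()
        assert (small_sim["matrix"].background.values >= 0).all()

    def test_unknown_planted_mirna_rejected(self):
        cfg = SimConfig(rng_seed=6, n_mirnas=5)
        rng = np.random.default_rng(6)
        mirnas = _draw_mirnas(cfg, rng)
        with pytest.raises(ConfigurationError):
            make_microarray(cfg, mirnas, make_design(cfg), rng=rng,
                            planted_de=[("nope", "R- vs S- / cuticle", "up", 2.0)])

    def test_planted_de_mirnas_exist(self, small_sim):
        names = {n for n, _ in small_sim["mirnas"]}
        for mirna, _cmp, _d, _lfc in small_sim["truth"].planted_de:
            assert mirna in names


class TestEndToEndDeterminism:
    def test_identical_config_reproduces_everything(self):
        cfg = SimConfig(rng_seed=99, n_contigs=10, n_mirnas=15)
        m1, c1, d1, x1, t1 = simulate_all(cfg)
        m2, c2, d2, x2, t2 = simulate_all(cfg)
        assert m1 == m2 and c1 == c2
        pd.testing.assert_frame_equal(d1, d2)
        pd.testing.assert_frame_equal(x1.foreground, x2.foreground)
        pd.testing.assert_frame_equal(x1.background, x2.background)
        assert t1.planted_orfs == t2.planted_orfs
        assert t1.planted_sites == t2.planted_sites
        assert t1.planted_de == t2.planted_de
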