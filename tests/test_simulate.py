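"""Generator contracts: exact fractions, determinism, planted motifs,
and the Poisson/binomial counts model."""

import numpy as np
import pandas as pd
import pytest

from circapa.annotation import read_counts, read_three_prime_annotation
from circapa.characterize import scan_pas
from circapa.simulate import (
    CANONICAL_PAS,
    InvalidConfigError,
    SimConfig,
    VARIANT_PAS,
    frame_to_truth,
    generate_annotation,
    generate_truth,
    read_truth,
    simulate_counts,
    simulate_dataset,
    truth_to_frame,
    write_dataset,
)


class TestConfig:
    def test_designs_yield_expected_time_grids(self):
        assert len(SimConfig(design="1-cycle/3h").time_grid()) == 8
        assert len(SimConfig(design="2-cycle/4h").time_grid()) == 12
        assert len(SimConfig(design="2-cycle/6h").time_grid()) == 8
        grid = SimConfig(design="2-cycle/4h", sampling_start_ct=22.0).time_grid()
        assert grid[0] == 22.0 and grid[-1] == 66.0

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"frac_multi_pas": 1.2},
            {"frac_rhythmic": -0.1},
            {"design": "3-cycle/1h"},
            {"amplitude_range": (0.0, 0.3)},
            {"amplitude_range": (0.2, 0.7)},
            {"n_genes": 0},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(InvalidConfigError):
            SimConfig(**kwargs)


class TestAnnotation:
    def test_multi_pas_count_is_deterministic_rounding(self):
        ann = generate_annotation(SimConfig(n_genes=1000, frac_multi_pas=0.574, seed=1))
        assert len(ann.tandem_genes) == 574
        assert len(ann.single_genes) == 426

    def test_all_single_site_when_fraction_zero(self):
        ann = generate_annotation(SimConfig(n_genes=10, frac_multi_pas=0.0, seed=2))
        assert len(ann.tandem_genes) == 0
        assert len(ann.single_genes) == 10

    def test_forced_canonical_distal_motif_roundtrip(self):
        cfg = SimConfig(
            n_genes=30,
            frac_multi_pas=1.0,
            pas_canonical_prob_distal=1.0,
            pas_variant_prob_distal=0.0,
            seed=3,
        )
        ann = generate_annotation(cfg)
        for g in ann.tandem_genes:
            call = scan_pas(g.sequence_long_utr, g.long_utr_len)
            assert call.pas_class == "canonical"
            assert call.hexamer == CANONICAL_PAS

    def test_planted_hexamers_match_truth_and_background_is_clean(self):
        cfg = SimConfig(n_genes=40, frac_multi_pas=1.0, seed=4)
        ann = generate_annotation(cfg)
        genes = {g.gene_id: g for g in ann.tandem_genes}
        for rec in ann.pas_truth:
            g = genes[rec.gene_id]
            offset = g.common_len if rec.site == "proximal" else g.long_utr_len
            call = scan_pas(g.sequence_long_utr, offset)
            if rec.hexamer is None:
                assert call.pas_class == "none"
            else:
                assert call.hexamer == rec.hexamer
                assert call.offset_from_3end == rec.offset

    def test_no_pas_motif_anywhere_outside_plants(self):
        cfg = SimConfig(
            n_genes=20,
            frac_multi_pas=1.0,
            pas_canonical_prob_proximal=0.0,
            pas_variant_prob_proximal=0.0,
            pas_canonical_prob_distal=0.0,
            pas_variant_prob_distal=0.0,
            seed=5,
        )
        ann = generate_annotation(cfg)
        for g in ann.tandem_genes:
            assert CANONICAL_PAS not in g.sequence_long_utr
            assert VARIANT_PAS not in g.sequence_long_utr

    def test_deterministic_given_seed(self):
        a = generate_annotation(SimConfig(n_genes=25, seed=9))
        b = generate_annotation(SimConfig(n_genes=25, seed=9))
        assert a.tandem_genes == b.tandem_genes
        assert a.single_genes == b.single_genes
        assert a.contigs == b.contigs

    def test_segment_lengths_allow_full_scan_window(self):
        ann = generate_annotation(SimConfig(n_genes=50, seed=10))
        for g in ann.tandem_genes:
            assert g.common_len >= 46
            assert g.extension_len >= 46


class TestTruth:
    def test_no_rhythmic_genes_when_fraction_zero(self, small_config):
        ann = generate_annotation(small_config)
        truth = generate_truth(
            SimConfig(**{**small_config.__dict__, "frac_rhythmic": 0.0}), ann
        )
        assert all(r.amplitude == 0.0 for r in truth)

    def test_cosine_arithmetic(self):
        # baseline 0.5, amplitude 0.3, phase 0, period 24 -> psi(12) = 0.2
        cfg = SimConfig(n_genes=4, frac_multi_pas=1.0, frac_rhythmic=1.0, seed=0)
        t = cfg.time_grid()
        psi = 0.5 + 0.3 * np.cos(2 * np.pi * (t - 0.0) / 24.0)
        assert psi[list(t).index(12.0)] == pytest.approx(0.2)

    def test_truth_trajectories_match_cosine_form(self, small_config, small_dataset):
        annotation, truth, _ = small_dataset
        t = small_config.time_grid()
        for rec in truth:
            if not rec.is_multi_pas:
                continue
            expected = np.clip(
                rec.baseline_psi_prox
                + rec.amplitude * np.cos(2 * np.pi * (t - rec.phase_true) / 24.0),
                0.0,
                1.0,
            )
            assert np.allclose(rec.psi_prox_by_time, expected)

    def test_rhythmic_count_is_deterministic_rounding(self):
        cfg = SimConfig(n_genes=200, frac_multi_pas=1.0, frac_rhythmic=0.05, seed=6)
        ann = generate_annotation(cfg)
        truth = generate_truth(cfg, ann)
        assert sum(r.is_rhythmic for r in truth) == 10

    def test_same_seed_same_truth(self, small_config):
        ann = generate_annotation(small_config)
        assert generate_truth(small_config, ann) == generate_truth(small_config, ann)


class TestCounts:
    def test_zero_long_fraction_gives_zero_extension_reads(self):
        # theta = 0 everywhere -> no extension reads ever
        cfg = SimConfig(n_genes=10, frac_multi_pas=1.0, frac_rhythmic=0.0, seed=8)
        ann = generate_annotation(cfg)
        truth = [
            r.__class__(**{**r.__dict__, "baseline_psi_prox": 1.0,
                           "psi_prox_by_time": tuple([1.0] * len(cfg.time_grid()))})
            for r in generate_truth(cfg, ann)
        ]
        counts = simulate_counts(ann, truth, cfg)
        assert (counts.frame["c_ext"] == 0).all()

    def test_extension_fraction_expectation(self):
        # theta=1, L_c=1000, L_e=500 -> E[c_ext/n] = 1/3 (Monte Carlo, 1e5 draws)
        rng = np.random.default_rng(12)
        n = rng.poisson(100, size=100_000)
        p = 1.0 * 500 / (1000 + 1.0 * 500)
        c_ext = rng.binomial(n, p)
        ok = n > 0
        mean = (c_ext[ok] / n[ok]).mean()
        se = (c_ext[ok] / n[ok]).std() / np.sqrt(ok.sum())
        assert abs(mean - 1 / 3) < 3 * se

    def test_simulated_extension_fraction_converges(self):
        # generator-level check of the same expectation over >= 1e4 points
        cfg = SimConfig(
            n_genes=1000, frac_multi_pas=1.0, frac_rhythmic=0.0,
            reads_per_gene_mean=500, seed=13,
        )
        ann = generate_annotation(cfg)
        truth = generate_truth(cfg, ann)
        counts = simulate_counts(ann, truth, cfg)
        lengths = {g.gene_id: (g.common_len, g.extension_len) for g in ann.tandem_genes}
        theta = {r.gene_id: 1.0 - np.asarray(r.psi_prox_by_time) for r in truth}
        frame = counts.frame
        resid = []
        for gene_id, grp in frame.groupby("gene_id"):
            l_c, l_e = lengths[gene_id]
            th = theta[gene_id]
            p = th * l_e / (l_c + th * l_e)
            n = (grp["c_common"] + grp["c_ext"]).to_numpy()
            f = grp["c_ext"].to_numpy() / np.maximum(n, 1)
            resid.extend((f - p)[n > 0])
        resid = np.asarray(resid)
        assert len(resid) >= 10_000
        se = resid.std() / np.sqrt(len(resid))
        assert abs(resid.mean()) < 3 * se

    def test_same_seed_same_counts(self, small_config, small_dataset):
        annotation, truth, counts = small_dataset
        again = simulate_counts(annotation, truth, small_config)
        pd.testing.assert_frame_equal(counts.frame, again.frame)


class TestWriteDataset:
    def test_roundtrip_identity(self, small_dataset, written_dataset):
        annotation, truth, counts = small_dataset
        tandem, single = read_three_prime_annotation(
            written_dataset["gff3"], written_dataset["fasta"]
        )
        assert tuple(tandem) == tuple(sorted(annotation.tandem_genes, key=lambda g: g.gene_id))
        assert tuple(single) == tuple(sorted(annotation.single_genes, key=lambda g: g.gene_id))
        counts_back = read_counts(written_dataset["counts"])
        pd.testing.assert_frame_equal(counts.frame, counts_back.frame)
        assert read_truth(written_dataset["truth"]) == list(truth)

    def test_truth_tsv_row_count(self, small_config, written_dataset):
        frame = pd.read_csv(written_dataset["truth"], sep="\t")
        assert len(frame) == small_config.n_genes

    def test_truth_frame_roundtrip(self, small_dataset):
        _, truth, _ = small_dataset
        assert frame_to_truth(truth_to_frame(truth)) == list(truth)
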