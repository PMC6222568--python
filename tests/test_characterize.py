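"""PAS scanning, the shared-window double-count rule, combination
groups, rank-sum comparisons and the characterization report."""

import numpy as np
import pandas as pd
import pytest

from circapa.characterize import (
    apply_double_count_rule,
    classify_all_sites,
    classify_pas_combination,
    compare_groups,
    count_overlap,
    phase_histogram,
    scan_pas,
    summarize_dataset,
)
from circapa.simulate import SimConfig, generate_annotation


def _window(upstream: str, pad: str = "C") -> str:
    """Build a sequence whose scan window ends exactly at the cleavage."""
    assert len(upstream) <= 40
    return pad * (60 - len(upstream)) + upstream


class TestScanner:
    def test_planted_canonical_with_offset(self):
        # AATAAA ends 21 nt upstream of the cleavage site
        seq = _window("AATAAA" + "C" * 21)
        call = scan_pas(seq, len(seq))
        assert call.pas_class == "canonical"
        assert call.hexamer == "AATAAA"
        assert call.offset_from_3end == 21

    def test_rna_alphabet_accepted(self):
        seq = _window("AAUAAA" + "C" * 10).replace("T", "U")
        call = scan_pas(seq, len(seq))
        assert call.pas_class == "canonical"

    def test_canonical_beats_closer_variant(self):
        # variant closer to the 3' end must lose to the canonical hexamer
        seq = _window("AATAAA" + "C" * 5 + "ATTAAA" + "C" * 3)
        call = scan_pas(seq, len(seq))
        assert call.pas_class == "canonical" and call.offset_from_3end == 14

    def test_closest_occurrence_within_class_wins(self):
        seq = _window("AATAAA" + "CC" + "AATAAA" + "C" * 4)
        call = scan_pas(seq, len(seq))
        assert call.offset_from_3end == 4

    def test_variant_only_window(self):
        call = scan_pas(_window("ATTAAA" + "C" * 8), 60)
        assert call.pas_class == "variant" and call.hexamer == "ATTAAA"

    def test_empty_window(self):
        call = scan_pas("C" * 60, 60)
        assert call.pas_class == "none" and call.hexamer is None

    def test_motif_outside_window_ignored(self):
        seq = "AATAAA" + "C" * 50  # ends 50 nt upstream, outside the 40-nt window
        call = scan_pas(seq, len(seq))
        assert call.pas_class == "none"

    def test_truncated_window_flagged(self):
        call = scan_pas("CCCAATAAACC", 11)
        assert call.truncated and call.pas_class == "canonical"


class TestDoubleCount:
    def _call(self, seq, cleavage, site):
        return scan_pas(seq, cleavage, gene_id="g", site=site)

    def test_shared_motif_counted_for_both_sites(self):
        # distance 30 < 40; single AATAAA upstream of the proximal site
        # lands in both scan windows
        seq = "C" * 50 + "AATAAA" + "C" * 4 + "C" * 30
        prox_cleav, dist_cleav = 60, 90
        prox = self._call(seq, prox_cleav, "proximal")
        dist = self._call(seq, dist_cleav, "distal")
        # both independent scans resolve to the same occurrence
        assert prox.pas_class == "canonical" and dist.pas_class == "canonical"
        assert dist.offset_from_3end == prox.offset_from_3end + 30
        prox2, dist2 = apply_double_count_rule(prox, dist, 30)
        assert prox2.double_counted and dist2.double_counted
        assert dist2.pas_class == "canonical"

    def test_distant_sites_scanned_independently(self):
        seq = "C" * 50 + "AATAAA" + "C" * 4 + "C" * 100
        prox = self._call(seq, 60, "proximal")
        dist = self._call(seq, 160, "distal")
        prox2, dist2 = apply_double_count_rule(prox, dist, 100)
        assert (prox2, dist2) == (prox, dist)
        assert dist2.pas_class == "none" and not dist2.double_counted

    def test_no_motif_no_double_count(self):
        seq = "C" * 90
        prox2, dist2 = apply_double_count_rule(
            self._call(seq, 60, "proximal"), self._call(seq, 90, "distal"), 30
        )
        assert prox2.pas_class == "none" and dist2.pas_class == "none"
        assert not prox2.double_counted and not dist2.double_counted


class TestCombinations:
    @pytest.mark.parametrize(
        "prox,dist,fine,agg",
        [
            ("variant", "canonical", "variant-canonical", "noncanonical-canonical"),
            ("canonical", "canonical", "canonical-canonical", "canonical-canonical"),
            ("none", "none", "none-none", "noncanonical-noncanonical"),
        ],
    )
    def test_labels(self, prox, dist, fine, agg):
        assert classify_pas_combination(prox, dist) == (fine, agg)

    def test_unknown_class_rejected(self):
        with pytest.raises(ValueError):
            classify_pas_combination("canonical", "cryptic")

    def test_all_canonical_generator_gives_pure_table(self):
        cfg = SimConfig(
            n_genes=20, frac_multi_pas=1.0,
            pas_canonical_prob_proximal=1.0, pas_variant_prob_proximal=0.0,
            pas_canonical_prob_distal=1.0, pas_variant_prob_distal=0.0,
            seed=14,
        )
        ann = generate_annotation(cfg)
        table = classify_all_sites(ann.tandem_genes)
        assert (table["combination"] == "canonical-canonical").all()


class TestRankSum:
    def test_identical_groups_not_significant(self):
        a = np.arange(20.0)
        res = compare_groups(a, a)
        assert res.p_value > 0.9
        assert res.delta_median == 0.0

    def test_complete_separation_u_zero(self):
        # group a below group b entirely: U (wins of a) = 0
        res = compare_groups([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert res.u_statistic == 0.0

    def test_shift_alternative_recovers_sign(self):
        rng = np.random.default_rng(23)
        a = rng.normal(0.0, 1.0, 100)
        b = a + 2.0
        res = compare_groups(a, b)
        assert res.p_value < 1e-6
        assert res.delta_median < 0

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([], [1.0])


class TestSummaries:
    def test_dataset_summary_fractions(self):
        s = summarize_dataset(n_single=426, n_multi=574)
        assert s["pct_multi_pas"] == pytest.approx(57.4)
        assert s["mean_sites_per_gene"] == pytest.approx(1.574)

    def test_phase_histogram_conserves_counts(self):
        rng = np.random.default_rng(2)
        phases = rng.uniform(0, 24, 137)
        hist = phase_histogram(phases)
        assert len(hist) == 12 and sum(hist) == 137

    def test_identical_runs_overlap_fully(self):
        pairs = {("g1", "proximal", "distal"), ("g2", "proximal", "distal")}
        out = count_overlap({"run1": set(pairs), "run2": set(pairs)})
        assert out["pairwise"]["run1&run2"] == 2 and out["all"] == 2

    def test_pair_identity_requires_both_isoforms(self):
        a = {("g1", "isoA", "isoB")}
        b = {("g1", "isoA", "isoC")}  # same gene, different second isoform
        out = count_overlap({"run1": a, "run2": b})
        assert out["pairwise"]["run1&run2"] == 0


@pytest.fixture(scope="module")
def pipeline_report(tmp_path_factory):
    from circapa.pipeline import RunConfig, run_end_to_end

    cfg = RunConfig(
        sim=SimConfig(n_genes=150, frac_rhythmic=0.2, seed=19),
        out_dir=str(tmp_path_factory.mktemp("report_run")),
        n_perm=199,
        seed=19,
    )
    return run_end_to_end(cfg)


class TestReport:
    def test_combination_fractions_sum_to_one(self, pipeline_report):
        block = pipeline_report.report["pas_combinations"]["all"]
        assert sum(block["fractions"].values()) == pytest.approx(1.0)
        assert sum(block["fractions_2x2"].values()) == pytest.approx(1.0)

    def test_histogram_matches_rhythmic_count(self, pipeline_report):
        rep = pipeline_report.report
        if rep["phase_histogram_2h"] is not None:
            assert sum(rep["phase_histogram_2h"]) == rep["n_rhythmic_pairs"]

    def test_uniform_phases_fill_histogram_without_hotspot(self):
        # planted phases are uniform; no 2-h bin may exceed a 99.9%
        # binomial envelope
        from scipy import stats

        rng = np.random.default_rng(29)
        n = 600
        hist = phase_histogram(rng.uniform(0, 24, n))
        bound = stats.binom.ppf(0.999, n, 1 / 12)
        assert max(hist) <= bound

    def test_empty_rhythmic_section_marked_absent(self, tmp_path):
        from circapa.pipeline import RunConfig, run_end_to_end

        cfg = RunConfig(
            sim=SimConfig(n_genes=40, frac_rhythmic=0.0, seed=20),
            out_dir=str(tmp_path / "null_run"),
            n_perm=199,
            seed=20,
        )
        rep = run_end_to_end(cfg).report
        if rep["n_rhythmic_pairs"] == 0:
            assert rep["phase_histogram_2h"] is None
            assert rep["utr_lengths"]["rhythmic"] is None
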