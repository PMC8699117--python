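"""PWM scanning, exact score thresholds, and the resampling-null
enrichment statistic."""

import math

import numpy as np
import pytest

from spliceshift import (GenomicInterval, MotifModel, MotifEnrichmentModel,
                         ScanRegion, SplicingEvent, build_scan_regions,
                         enrichment_zscore, pwm_score_threshold,
                         sample_control_sets, scan_sequence)
from spliceshift.motifs import classify_direction, pwm_tail_distribution


def sharp_motif(consensus, p=0.997, motif_id="M1"):
    idx = {"A": 0, "C": 1, "G": 2, "U": 3}
    pwm = np.full((len(consensus), 4), (1 - p) / 3)
    for i, c in enumerate(consensus):
        pwm[i, idx[c]] = p
    return MotifModel(motif_id, motif_id, pwm)


def region(seq, direction="null", event_id="E", label="spliced_region",
           ase_type="ES"):
    return ScanRegion(event_id, ase_type, label,
                      GenomicInterval("chr1", 0, len(seq)), seq, direction)


class TestThreshold:
    def test_uninformative_motif_is_unscannable(self, caplog):
        m = MotifModel("U", "U", np.full((4, 4), 0.25))
        with caplog.at_level("WARNING"):
            thr = pwm_score_threshold(m)
        assert math.isinf(thr)
        assert m.score_threshold == math.inf
        assert scan_sequence(m, "ACGU" * 50).size == 0

    def test_tail_at_threshold_within_cutoff(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            pwm = rng.dirichlet(np.ones(4), size=6)
            m = MotifModel("M", "M", pwm)
            thr = pwm_score_threshold(m, pvalue_cutoff=0.001)
            support, pmf, tail = pwm_tail_distribution(m)
            at = tail[np.searchsorted(support, thr)]
            assert at <= 0.001
            # smallest such attainable score: the next attainable score
            # below has tail > cutoff
            below = (support < thr) & (pmf > 0)
            if below.any():
                assert tail[np.nonzero(below)[0][-1]] > 0.001

    def test_pmf_sums_to_one(self):
        m = sharp_motif("ACGUA")
        _, pmf, tail = pwm_tail_distribution(m)
        assert pmf.sum() == pytest.approx(1.0)
        assert tail[0] == pytest.approx(1.0)

    def test_invalid_cutoff_rejected(self):
        with pytest.raises(ValueError):
            pwm_score_threshold(sharp_motif("ACGU"), pvalue_cutoff=1.5)


class TestScan:
    def test_finds_planted_consensus_at_exact_offsets(self):
        m = sharp_motif("ACGUACG")
        pwm_score_threshold(m)
        seq = "U" * 30 + "ACGUACG" + "U" * 20 + "ACGUACG" + "U" * 10
        np.testing.assert_array_equal(scan_sequence(m, seq), [30, 57])

    def test_background_of_nonmatching_letters_has_no_hits(self):
        m = sharp_motif("ACGUACG")
        pwm_score_threshold(m)
        assert scan_sequence(m, "U" * 500).size == 0

    def test_unknown_letters_never_match(self):
        m = sharp_motif("ACGUACG")
        pwm_score_threshold(m)
        assert scan_sequence(m, "ACGNACG" + "U" * 10).size == 0

    def test_sequence_shorter_than_motif(self):
        m = sharp_motif("ACGUACG")
        pwm_score_threshold(m)
        assert scan_sequence(m, "ACG").size == 0

    def test_threshold_required_before_scanning(self):
        with pytest.raises(ValueError, match="threshold"):
            scan_sequence(sharp_motif("ACGU"), "ACGUACGU")

    def test_overlapping_hits_all_counted(self):
        m = sharp_motif("AAAAA")
        pwm_score_threshold(m)
        assert scan_sequence(m, "AAAAAAA").size == 3


class TestClassifyDirection:
    @pytest.mark.parametrize("dpsi,p,expected", [
        (0.2, 0.001, "up"), (-0.2, 0.001, "down"),
        (0.001, 0.8, "null"), (0.03, 0.8, None), (0.001, 0.01, None)])
    def test_rule_table(self, dpsi, p, expected):
        assert classify_direction(dpsi, p) == expected


class TestBuildScanRegions:
    def _event(self, strand, dpsi=0.2, pvalue=0.001):
        return SplicingEvent(
            "E1", "G1", "ES",
            {"alt": GenomicInterval("chrT", 10, 14, strand)},
            {"s": 1}, {"s": 1}, dpsi=dpsi, pvalue=pvalue)

    def test_plus_strand_layout(self):
        genome = {"chrT": "AAAACCCCGG" + "ACGU" + "GGUUUUAAAA"}
        regions = build_scan_regions([self._event("+")], genome, flank=4)
        by_label = {r.region_label: r for r in regions}
        assert by_label["upstream_flank"].sequence == "CCGG"
        assert by_label["spliced_region"].sequence == "ACGU"
        assert by_label["downstream_flank"].sequence == "GGUU"
        assert all(r.direction == "up" for r in regions)

    def test_minus_strand_reverse_complements_and_swaps_flanks(self):
        genome = {"chrT": "AAAACCCCGG" + "ACGU" + "GGUUUUAAAA"}
        regions = build_scan_regions([self._event("-")], genome, flank=4)
        by_label = {r.region_label: r for r in regions}
        # upstream in transcript coordinates is genomic-right on "-"
        assert by_label["upstream_flank"].sequence == "AACC"  # rc(GGUU)
        assert by_label["spliced_region"].sequence == "ACGU"  # rc(ACGU)
        assert by_label["downstream_flank"].sequence == "CCGG"  # rc(CCGG)

    def test_flank_truncated_at_bounds_with_warning(self, caplog):
        genome = {"chrT": "AAAACCCCGG" + "ACGU" + "GG"}
        with caplog.at_level("WARNING"):
            regions = build_scan_regions([self._event("+")], genome, flank=6)
        by_label = {r.region_label: r for r in regions}
        assert by_label["downstream_flank"].sequence == "GG"
        assert "truncated" in caplog.text

    def test_unclassifiable_events_dropped(self):
        genome = {"chrT": "A" * 30}
        ev = self._event("+", dpsi=0.03, pvalue=0.5)
        assert build_scan_regions([ev], genome, flank=2) == []


class TestControlSets:
    def _pool(self, n, length=50, direction="null"):
        rng = np.random.default_rng(0)
        letters = np.array(list("ACGU"))
        return [region("".join(letters[rng.integers(0, 4, size=length)]),
                       direction, event_id=f"N{i}") for i in range(n)]

    def test_cardinality_matches_target(self):
        pool = self._pool(40)
        targets = self._pool(7, direction="up")
        sets = sample_control_sets(pool, targets, n_sets=20,
                                   rng=np.random.default_rng(1))
        assert len(sets) == 20
        assert all(len(s) == 7 for s in sets)

    def test_without_replacement_within_a_set(self):
        pool = self._pool(30)
        targets = self._pool(10, direction="up")
        sets = sample_control_sets(pool, targets, n_sets=10,
                                   rng=np.random.default_rng(2))
        for s in sets:
            assert len({id(r) for r in s}) == len(s)

    def test_length_matching_with_heterogeneous_pool(self):
        pool = [region("A" * L, event_id=f"N{i}")
                for i, L in enumerate([20] * 10 + [500] * 10)]
        targets = [region("A" * 22, "up", event_id=f"T{i}")
                   for i in range(3)]
        sets = sample_control_sets(pool, targets, n_sets=10,
                                   rng=np.random.default_rng(3))
        for s in sets:
            # nearest-length sampling never reaches the 500-nt decoys
            assert all(len(r.sequence) == 20 for r in s)

    def test_small_pool_forces_replacement_with_warning(self, caplog):
        pool = self._pool(3)
        targets = self._pool(5, direction="up")
        with caplog.at_level("WARNING"):
            sets = sample_control_sets(pool, targets, n_sets=4,
                                       rng=np.random.default_rng(4))
        assert "WITH" in caplog.text
        assert all(len(s) == 5 for s in sets)

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            sample_control_sets([], self._pool(2), 5)

    def test_deterministic_under_seeded_rng(self):
        pool = self._pool(20)
        targets = self._pool(5, direction="up")
        a = sample_control_sets(pool, targets, 5,
                                np.random.default_rng(9))
        b = sample_control_sets(pool, targets, 5,
                                np.random.default_rng(9))
        assert [[r.event_id for r in s] for s in a] == \
            [[r.event_id for r in s] for s in b]


class TestEnrichmentZscore:
    def _setup(self, target_plants, control_plants):
        """Sequences of non-matching U's with exact consensus plants, so
        hit counts are known integers."""
        m = sharp_motif("ACGUACG")
        pwm_score_threshold(m)
        def seq(k):
            return ("U" * 10).join(["ACGUACG"] * k) + "U" * 20 if k else "U" * 50
        targets = [region(seq(k), "up", event_id=f"T{i}")
                   for i, k in enumerate(target_plants)]
        controls = [[region(seq(k), "null", event_id=f"C{i}_{j}")
                     for j, k in enumerate(ks)]
                    for i, ks in enumerate(control_plants)]
        return m, targets, controls

    def test_z_arithmetic_on_known_counts(self):
        m, targets, controls = self._setup(
            [3, 2], [[1, 0], [0, 0], [2, 1], [1, 1]])
        res = enrichment_zscore(m, targets, controls)
        ctrl = np.array([1.0, 0.0, 3.0, 2.0])
        assert res.observed_count == 5
        assert res.control_mean == pytest.approx(ctrl.mean())
        assert res.control_sd == pytest.approx(ctrl.std(ddof=1))
        assert res.zscore == pytest.approx(
            (5 - ctrl.mean()) / ctrl.std(ddof=1))
        assert res.enriched == (res.zscore > 1.96)

    def test_per_sequence_mode_caps_each_region_at_one(self):
        m, targets, controls = self._setup(
            [3, 2], [[1, 0], [0, 0], [2, 1], [1, 1]])
        res = enrichment_zscore(m, targets, controls, per_sequence=True)
        assert res.observed_count == 2

    def test_degenerate_null_falls_back_to_exceedance(self):
        m, targets, controls = self._setup([2], [[1], [1], [1]])
        res = enrichment_zscore(m, targets, controls)
        assert res.degenerate_null
        assert math.isnan(res.zscore)
        assert res.enriched  # 2 > every control count of 1


class TestModel:
    def test_fit_builds_one_row_per_cell_and_is_deterministic(self):
        rng = np.random.default_rng(5)
        letters = np.array(list("ACGU"))
        regions = []
        for i in range(40):
            direction = "up" if i < 5 else ("down" if i < 8 else "null")
            for label in ("upstream_flank", "spliced_region",
                          "downstream_flank"):
                seq = "".join(letters[rng.integers(0, 4, size=120)])
                regions.append(region(seq, direction, event_id=f"E{i}",
                                      label=label))
        motifs = [sharp_motif("ACGUACG", motif_id="Ma"),
                  sharp_motif("GGGCCC", motif_id="Mb")]
        res = MotifEnrichmentModel(regions, motifs, seed=3).fit()
        # (ES x 3 labels) x 2 directions x 2 motifs
        assert len(res.table) == 12
        assert set(res.table.direction) == {"up", "down"}
        res2 = MotifEnrichmentModel(regions, motifs, seed=3).fit()
        assert res.table.equals(res2.table)
        assert "RBP motif enrichment" in res.summary()
        assert res.n_enriched == res.table.enriched.sum()
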