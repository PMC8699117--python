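"""Cohort association: marker correlation, group comparisons, survival,
list and interval overlaps, DE plumbing."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from spliceshift import (CohortAssociationModel, GenomicInterval,
                         SimulationConfig, SplicingEvent, compare_groups,
                         correlate_psi_with_marker, de_plumbing,
                         hypergeometric_overlap, median_split_survival,
                         overlap_with_peaks, simulate_cohort)
from spliceshift.cohort import (_logrank_chi2, flagged_in_all_comparisons,
                                _marker_median_split)
from spliceshift.datamodel import CohortSample


def sample(sid, group, marker, psi, os_time=100.0, os_event=True):
    return CohortSample(sid, group, marker, {"E1": psi},
                        os_time=os_time, os_event=os_event,
                        dfs_time=os_time, dfs_event=os_event)


class TestCorrelation:
    def test_monotone_psi_marker_relation_passes(self):
        cohort = [sample(f"S{i}", "ERpos_tumor", float(i), 0.05 * i + 0.1)
                  for i in range(8)]
        df = correlate_psi_with_marker(cohort, ["E1"])
        assert df.iloc[0].rho == pytest.approx(1.0)
        assert bool(df.iloc[0].passed)

    def test_only_requested_group_used(self):
        erpos = [sample(f"P{i}", "ERpos_tumor", float(i), 0.1 * i + 0.1)
                 for i in range(6)]
        # anticorrelated normals must not dilute the ER+ estimate
        normals = [sample(f"N{i}", "normal", float(i), 0.9 - 0.1 * i)
                   for i in range(6)]
        df = correlate_psi_with_marker(erpos + normals, ["E1"])
        assert df.iloc[0].n == 6
        assert df.iloc[0].rho == pytest.approx(1.0)

    def test_constant_psi_skipped_with_warning(self, caplog):
        cohort = [sample(f"S{i}", "ERpos_tumor", float(i), 0.5)
                  for i in range(6)]
        with caplog.at_level("WARNING"):
            df = correlate_psi_with_marker(cohort, ["E1"])
        assert df.empty
        assert "constant" in caplog.text

    def test_signed_mode_rejects_negative_correlations(self):
        cohort = [sample(f"S{i}", "ERpos_tumor", float(i), 0.9 - 0.1 * i)
                  for i in range(8)]
        both = correlate_psi_with_marker(cohort, ["E1"])
        pos_only = correlate_psi_with_marker(cohort, ["E1"], signed=True)
        assert bool(both.iloc[0].passed)
        assert not bool(pos_only.iloc[0].passed)


class TestGroupComparisons:
    def _cohort(self):
        # ER+ PSI high (~0.8), ER- and normal low (~0.2); within ER+ the
        # marker splits cleanly with high-marker PSI higher still
        out = []
        for i in range(6):
            out.append(sample(f"P{i}", "ERpos_tumor", 10.0 + i,
                              0.7 + 0.03 * i))
        for i in range(4):
            out.append(sample(f"N{i}", "ERneg_tumor", 5.0, 0.2 + 0.01 * i))
        for i in range(4):
            out.append(sample(f"M{i}", "normal", 8.0, 0.2 + 0.01 * i))
        return out

    def test_dpsi_and_flags_per_comparison(self):
        df = compare_groups(self._cohort(), ["E1"])
        by = df.set_index("comparison")
        assert by.loc["ERpos_vs_ERneg", "dpsi"] == pytest.approx(
            np.mean([0.7 + 0.03 * i for i in range(6)]) - 0.215)
        assert bool(by.loc["ERpos_vs_ERneg", "flagged"])
        assert bool(by.loc["tumor_vs_normal", "flagged"])
        assert by.loc["high_vs_low_marker", "n_a"] == 3  # ties go low

    def test_marker_median_split_sends_ties_low(self):
        erpos = [sample(f"P{i}", "ERpos_tumor", m, 0.5)
                 for i, m in enumerate([1.0, 2.0, 2.0, 3.0])]
        high, low = _marker_median_split(erpos)
        assert {s.marker_expr for s in high} == {3.0}
        assert len(low) == 3

    def test_small_group_skips_comparison(self):
        cohort = self._cohort()
        cohort = [s for s in cohort if not s.sample_id.startswith("M")]
        df = compare_groups(cohort, ["E1"])
        assert "tumor_vs_normal" not in set(df.comparison)

    def test_flagged_in_all_comparisons(self):
        df = compare_groups(self._cohort(), ["E1"])
        assert flagged_in_all_comparisons(df) == (
            ["E1"] if df.flagged.all() else [])
        assert flagged_in_all_comparisons(pd.DataFrame()) == []


class TestSurvival:
    def _cohort(self, n=30, hr_effect=True, seed=0):
        rng = np.random.default_rng(seed)
        out = []
        for i in range(n):
            psi = 0.8 if i % 2 else 0.2
            scale = 100.0 if (psi > 0.5 and hr_effect) else 400.0
            t = float(rng.exponential(scale))
            out.append(sample(f"S{i}", "ERpos_tumor", 10.0, psi,
                              os_time=t, os_event=True))
        return out

    def test_statistic_matches_lifelines_on_censored_data(self):
        from lifelines.statistics import logrank_test
        rng = np.random.default_rng(7)
        times = rng.exponential(100, size=40)
        events = rng.random(40) < 0.7
        grp = rng.random(40) < 0.5
        ours = _logrank_chi2(times, events.astype(float), grp)
        ref = logrank_test(times[grp], times[~grp], events[grp], events[~grp])
        assert ours == pytest.approx(float(ref.test_statistic))

    def test_exact_small_sample_p_is_permutation_fraction(self):
        cohort = self._cohort(n=10)
        res = median_split_survival(cohort, "E1")
        assert res.exact
        times = np.array([s.os_time for s in cohort])
        flags = np.ones(10)
        psi = np.array([s.psi_by_event["E1"] for s in cohort])
        in_high = psi > np.median(psi)
        obs = _logrank_chi2(times, flags, in_high)
        n1 = int(in_high.sum())
        count = sum(
            1 for combo in itertools.combinations(range(10), n1)
            if _logrank_chi2(times, flags,
                             np.isin(np.arange(10), combo)) >= obs - 1e-12)
        assert res.pvalue == pytest.approx(count / math.comb(10, n1))

    def test_large_sample_detects_planted_hazard(self):
        res = median_split_survival(self._cohort(n=60), "E1")
        assert not res.exact
        assert res.pvalue < 0.01
        assert set(res.km_curves) == {"high", "low"}

    def test_errors_for_insufficient_or_constant_data(self):
        with pytest.raises(ValueError, match=">= 10"):
            median_split_survival(self._cohort(n=6), "E1")
        flat = [sample(f"S{i}", "normal", 1.0, 0.5, os_time=float(i + 1))
                for i in range(12)]
        with pytest.raises(ValueError, match="constant PSI"):
            median_split_survival(flat, "E1")
        with pytest.raises(ValueError, match="endpoint"):
            median_split_survival(self._cohort(), "E1", endpoint="PFS")


class TestHypergeometric:
    def test_hand_computed_tail(self):
        universe = [f"g{i}" for i in range(10)]
        a = universe[:4]
        b = universe[2:7]       # overlap g2, g3 -> k = 2
        k, p = hypergeometric_overlap(a, b, universe)
        assert k == 2
        expect = sum(math.comb(4, i) * math.comb(6, 5 - i)
                     for i in range(2, 5)) / math.comb(10, 5)
        assert p == pytest.approx(expect)

    def test_matches_comb_formula_on_random_instances(self):
        rng = np.random.default_rng(13)
        for _ in range(30):
            nu = int(rng.integers(4, 13))
            universe = list(range(nu))
            a = list(rng.choice(nu, size=rng.integers(1, nu + 1),
                                replace=False))
            b = list(rng.choice(nu, size=rng.integers(1, nu + 1),
                                replace=False))
            k, p = hypergeometric_overlap(a, b, universe)
            na, nb = len(a), len(b)
            expect = sum(
                math.comb(na, i) * math.comb(nu - na, nb - i)
                for i in range(k, min(na, nb) + 1)) / math.comb(nu, nb)
            assert p == pytest.approx(min(1.0, expect), rel=1e-12)

    def test_validation(self):
        with pytest.raises(ValueError, match="universe"):
            hypergeometric_overlap(["a"], ["a"], [])
        with pytest.raises(ValueError, match="subsets"):
            hypergeometric_overlap(["x"], ["a"], ["a", "b"])


class TestPeakOverlap:
    def _events(self, rng, n=30):
        out = []
        for i in range(n):
            start = int(rng.integers(0, 5000))
            alt = GenomicInterval("chr1", start + 300, start + 400)
            out.append(SplicingEvent(
                f"E{i}", f"G{i}", "ES",
                {"upstream_exon": GenomicInterval("chr1", start, start + 100),
                 "alt": alt,
                 "downstream_exon": GenomicInterval("chr1", start + 700,
                                                    start + 800)},
                {"s": 1}, {"s": 1}))
        return out

    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(21)
        events = self._events(rng)
        peaks = [GenomicInterval("chr1", int(s), int(s) + int(w))
                 for s, w in zip(rng.integers(0, 6000, 40),
                                 rng.integers(10, 300, 40))]
        got = overlap_with_peaks(events, peaks, extension=200).set_index(
            "event_id")
        for ev in events:
            ivs = list(ev.regions.values())
            span = (min(i.start for i in ivs), max(i.end for i in ivs))
            in_gene = any(p.start < span[1] and span[0] < p.end
                          for p in peaks)
            in_exon = any(
                p.start < a.end + 200 and max(0, a.start - 200) < p.end
                for a in ev.alt_regions() for p in peaks)
            assert bool(got.loc[ev.event_id, "peak_in_gene"]) == in_gene
            assert bool(got.loc[ev.event_id, "peak_in_exon_ext"]) == in_exon

    def test_assembly_mismatch_rejected(self):
        with pytest.raises(ValueError, match="assembly"):
            overlap_with_peaks([], [], events_assembly="hg19",
                               peaks_assembly="hg38")


class TestDePlumbing:
    def _counts(self):
        # the large stable gene pins the library sizes so normalization
        # does not distort the planted fold change
        return pd.DataFrame(
            {"c1": [1000, 5, 500, 100000], "c2": [1020, 6, 505, 100000],
             "s1": [2000, 5, 505, 100001], "s2": [2040, 6, 500, 100000]},
            index=["up_gene", "low_gene", "flat_gene", "house"])

    COND = {"c1": "control", "c2": "control",
            "s1": "silenced", "s2": "silenced"}

    def test_floor_filter_and_fold_change(self):
        df = de_plumbing(self._counts(), self.COND).set_index("gene_id")
        assert "low_gene" not in df.index  # below the 10-count floor
        assert df.loc["up_gene", "log2fc"] == pytest.approx(1.0, abs=0.15)
        assert bool(df.loc["up_gene", "flagged"])
        assert not bool(df.loc["flat_gene", "flagged"])

    def test_requires_two_conditions_with_replicates(self):
        with pytest.raises(ValueError):
            de_plumbing(self._counts(), {"c1": "control", "s1": "silenced"})


class TestModel:
    def test_fit_recovers_planted_cohort_structure(self):
        cfg = SimulationConfig(seed=9)
        event_ids = [f"EV{i}" for i in range(8)]
        cohort, truth = simulate_cohort(event_ids, cfg)
        model = CohortAssociationModel(cohort, event_ids)
        res = model.fit(survival_events=["EV0"], endpoints=("OS",))
        corr = res.correlations.set_index("event_id")
        planted = truth[truth.planted_rho > 0].event_id
        assert corr.loc[planted, "passed"].all()
        assert not corr.loc[~corr.index.isin(planted), "passed"].any()
        comp = res.comparisons.set_index(["event_id", "comparison"])
        for e in planted:
            # the tumor-group PSI shift is plainly visible in both
            # tumor-centred comparisons
            assert bool(comp.loc[(e, "ERpos_vs_ERneg"), "flagged"])
            assert bool(comp.loc[(e, "tumor_vs_normal"), "flagged"])
        assert set(res.all_three) <= set(planted)
        (sr,) = res.survival
        assert sr.event_id == "EV0"
        assert sr.pvalue < 0.05  # planted hazard ratio of 2 at n = 200
        assert "Cohort association" in res.summary()
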