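"""Activation calling: replicate criteria, profiles, ranking, label switching."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import latsplice as L
from latsplice.activation import ReplicatePair, median_ci_bounds, standardize_profile
from latsplice.catalog import _set_junctions


CFG = L.ActivationConfig()


def pair(case, control):
    return ReplicatePair(case=L.usage_ratio(*case), control=L.usage_ratio(*control))


def make_site(gt=120, donor=100, ext=20, residual=40, cls="LSS", score=5.0, gene="g1", strand="+"):
    site = L.CandidateSite(
        chrom="chr1", strand=strand, gt_start=gt, parent_donor=donor,
        extension_length=ext, residual_intron=residual, gene_id=gene,
        site_class=cls, score=score, has_inframe_stop=cls == "LSS",
    )
    _set_junctions(site)
    return site


def make_counts(site_reads, condition_of, totals=None):
    """site_reads: {sample: [(latent|canonical, site, n), ...]} shorthand builder."""
    out = []
    rep_index = {"case": 0, "control": 0}
    for sample, reads in site_reads.items():
        cond = condition_of[sample]
        rep_index[cond] += 1
        counts = {}
        for kind, site, n in reads:
            key = (site.chrom, *(site.latent_junction if kind == "latent" else site.canonical_junction))
            counts[key] = counts.get(key, 0) + n
        out.append(
            L.JunctionCounts(
                sample_id=sample, condition=cond, replicate=rep_index[cond],
                counts=counts,
                total_mapped_reads=(totals or {}).get(sample, 1_000_000),
            )
        )
    return out


class TestInitialCriteria:
    def test_strong_plus_weak_replicate_passes(self):
        assert L.check_initial_criteria(
            pair((6, 100), (2, 100)), pair((1, 50), (0, 50)), CFG
        )

    def test_no_replicate_reaches_four_reads(self):
        p = pair((3, 100), (1, 100))
        assert not L.check_initial_criteria(p, p, CFG)

    def test_either_replicate_may_be_primary(self):
        weak = pair((8, 100), (6, 100))   # fold 1.33: secondary only
        strong = pair((6, 100), (2, 100))  # fold 3: can be primary
        assert L.check_initial_criteria(weak, strong, CFG)
        assert L.check_initial_criteria(strong, weak, CFG)
        # two weak replicates fail: no assignment meets 4 reads + 1.5-fold
        assert not L.check_initial_criteria(weak, weak, CFG)

    def test_secondary_needs_any_increase(self):
        strong = pair((6, 100), (2, 100))
        flat = pair((5, 100), (5, 100))  # fold exactly 1: not an increase
        assert not L.check_initial_criteria(strong, flat, CFG)

    def test_undefined_usage_fails(self):
        strong = pair((6, 100), (2, 100))
        undefined = pair((6, 100), (2, 0))
        assert not L.check_initial_criteria(strong, undefined, CFG)

    def test_zero_control_usage_counts_as_any_fold(self):
        assert L.check_initial_criteria(
            pair((6, 100), (0, 100)), pair((1, 100), (0, 100)), CFG
        )


class TestStringentCriteria:
    def test_both_replicates_strong(self):
        p = pair((6, 100), (2, 100))
        assert L.check_stringent_criteria(p, p, CFG)

    def test_fold_below_threshold_fails(self):
        ok = pair((6, 100), (2, 100))
        weak = pair((7, 100), (5, 100))  # fold 1.4
        assert not L.check_stringent_criteria(ok, weak, CFG)

    @given(st.lists(st.integers(0, 40), min_size=8, max_size=8))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_stringent_implies_initial(self, reads):
        c1, k1, c2, k2, c3, k3, c4, k4 = reads
        r1 = pair((c1, k1 + 1), (c2, k2 + 1))
        r2 = pair((c3, k3 + 1), (c4, k4 + 1))
        if L.check_stringent_criteria(r1, r2, CFG):
            assert L.check_initial_criteria(r1, r2, CFG)


class TestProfileSupport:
    def prof(self, depths, norm=1.0):
        return L.CoverageProfile(site_key=("s",), sample_id="x", depths=np.array(depths, float), normalization=norm)

    def test_case_covered_control_absent(self):
        case = [self.prof([10] * 20)] * 2
        ctrl = [self.prof([0] * 20)] * 2
        assert L.check_profile_support(case, ctrl, CFG)

    def test_internal_coverage_gap_fails_presence(self):
        depths = [10] * 20
        depths[7] = 0
        case = [self.prof(depths)] * 2
        ctrl = [self.prof([0] * 20)] * 2
        assert not L.check_profile_support(case, ctrl, CFG)

    def test_identical_profiles_fail_excess(self):
        case = [self.prof([5] * 20)] * 2
        ctrl = [self.prof([5] * 20)] * 2
        assert not L.check_profile_support(case, ctrl, CFG)

    def test_normalization_matters(self):
        # raw case depth higher, but case canonical support is 10x larger
        case = [self.prof([10] * 20, norm=100.0)] * 2
        ctrl = [self.prof([5] * 20, norm=10.0)] * 2
        assert not L.check_profile_support(case, ctrl, CFG)

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError, match="length"):
            L.check_profile_support([self.prof([1, 2])], [self.prof([1, 2, 3])], CFG)


class TestCallActivated:
    conditions = {"c1": "case", "c2": "case", "k1": "control", "k2": "control"}

    def activated_counts(self, site):
        return make_counts(
            {
                "c1": [("latent", site, 12), ("canonical", site, 100)],
                "c2": [("latent", site, 9), ("canonical", site, 110)],
                "k1": [("latent", site, 2), ("canonical", site, 105)],
                "k2": [("latent", site, 1), ("canonical", site, 95)],
            },
            self.conditions,
        )

    def test_activated_site_is_called(self):
        site = make_site()
        calls = L.call_activated(L.SiteCatalog([site]), self.activated_counts(site))
        assert len(calls) == 1 and calls[0].called(CFG)
        assert calls[0].passes_stringent

    def test_equal_counts_give_no_calls(self):
        site = make_site()
        counts = make_counts(
            {s: [("latent", site, 5), ("canonical", site, 100)] for s in self.conditions},
            self.conditions,
        )
        calls = L.call_activated(L.SiteCatalog([site]), counts)
        assert not any(c.called(CFG) for c in calls)

    def test_undefined_canonical_is_excluded_with_reason(self):
        site = make_site()
        counts = make_counts(
            {
                "c1": [("latent", site, 12)],
                "c2": [("latent", site, 9), ("canonical", site, 110)],
                "k1": [("latent", site, 2), ("canonical", site, 105)],
                "k2": [("latent", site, 1), ("canonical", site, 95)],
            },
            self.conditions,
        )
        calls = L.call_activated(L.SiteCatalog([site]), counts)
        assert not calls[0].called(CFG)
        assert calls[0].exclusion_reason == "undefined_usage"

    def test_wrong_replicate_structure_raises(self):
        site = make_site()
        counts = self.activated_counts(site)[:3]
        with pytest.raises(ValueError, match="2 case"):
            L.call_activated(L.SiteCatalog([site]), counts)

    def test_calls_invariant_to_uniform_sample_scaling(self):
        site = make_site()
        counts = self.activated_counts(site)
        calls = L.call_activated(L.SiteCatalog([site]), counts)
        for jc in counts:
            if jc.sample_id == "c1":
                jc.counts = {k: v * 3 for k, v in jc.counts.items()}
                jc.total_mapped_reads *= 3
        scaled = L.call_activated(L.SiteCatalog([site]), counts)
        assert [c.called(CFG) for c in calls] == [c.called(CFG) for c in scaled]


class TestLabelSwitch:
    conditions = TestCallActivated.conditions

    def test_symmetric_counts_give_equal_calls(self):
        site = make_site()
        counts = make_counts(
            {s: [("latent", site, 8), ("canonical", site, 100)] for s in self.conditions},
            self.conditions,
        )
        fwd = L.call_activated(L.SiteCatalog([site]), counts)
        rev = L.label_switch(L.SiteCatalog([site]), counts)
        assert sum(c.called(CFG) for c in fwd) == sum(c.called(CFG) for c in rev)

    def test_switching_twice_restores_original(self):
        site = make_site()
        counts = TestCallActivated().activated_counts(site)
        fwd = L.call_activated(L.SiteCatalog([site]), counts)
        swapped = [
            L.JunctionCounts(
                c.sample_id,
                {"case": "control", "control": "case"}[c.condition],
                c.replicate, dict(c.counts), c.total_mapped_reads,
            )
            for c in counts
        ]
        back = L.label_switch(L.SiteCatalog([site]), swapped)
        assert [c.called(CFG) for c in fwd] == [c.called(CFG) for c in back]
        assert all(c.label_switched for c in back)

    def test_planted_activation_is_directional(self, sim_bundle):
        cat = sim_bundle["catalog"]
        exp = sim_bundle["experiment"]
        fwd = sum(c.called(CFG) for c in L.call_activated(cat, exp.counts, exp.profiles))
        rev = sum(c.called(CFG) for c in L.label_switch(cat, exp.counts, exp.profiles))
        assert fwd >= 4
        assert rev <= fwd / 2


class TestRanking:
    def test_rank_table_columns_and_order(self):
        s1, s2 = make_site(gt=120), make_site(gt=130, ext=30)
        conditions = TestCallActivated.conditions
        counts = make_counts(
            {
                "c1": [("latent", s1, 20), ("canonical", s1, 100), ("latent", s2, 6), ("canonical", s2, 100)],
                "c2": [("latent", s1, 18), ("canonical", s1, 100), ("latent", s2, 5), ("canonical", s2, 100)],
                "k1": [("latent", s1, 2), ("canonical", s1, 100), ("latent", s2, 1), ("canonical", s2, 100)],
                "k2": [("latent", s1, 2), ("canonical", s1, 100), ("latent", s2, 1), ("canonical", s2, 100)],
            },
            conditions,
        )
        calls = L.call_activated(L.SiteCatalog([s1, s2]), counts)
        table = L.rank_calls(calls)
        assert list(table["gt_start"]) == [120, 130]  # stronger evidence first
        assert (table["combined_p"].diff().dropna() >= 0).all()

    def test_geometric_mean_fold(self):
        site = make_site()
        counts = make_counts(
            {
                "c1": [("latent", site, 8), ("canonical", site, 100)],
                "c2": [("latent", site, 32), ("canonical", site, 100)],
                "k1": [("latent", site, 4), ("canonical", site, 100)],
                "k2": [("latent", site, 4), ("canonical", site, 100)],
            },
            TestCallActivated.conditions,
        )
        calls = L.call_activated(L.SiteCatalog([site]), counts)
        assert calls[0].folds == (2.0, 8.0)
        assert calls[0].fold_geomean == pytest.approx(4.0)

    def test_combined_p_is_fishers_method_of_replicates(self):
        site = make_site()
        calls = L.call_activated(
            L.SiteCatalog([site]), TestCallActivated().activated_counts(site)
        )
        c = calls[0]
        assert c.combined_p == pytest.approx(L.fishers_method(list(c.rep_p)))


class TestComparisonSet:
    def build(self, support1, support2):
        site = make_site()
        weak = make_site(gt=130, ext=30, score=1.0)
        counts = make_counts(
            {
                "k1": [("canonical", site, support1)],
                "k2": [("canonical", site, support2)],
            },
            {"k1": "control", "k2": "control"},
        )
        return L.SiteCatalog([site, weak]), counts

    def test_insufficient_support_in_one_control_excludes(self):
        cat, counts = self.build(10, 9)
        assert L.build_comparison_set(cat, counts) == {}

    def test_highest_scoring_lss_is_selected(self):
        cat, counts = self.build(10, 10)
        chosen = L.build_comparison_set(cat, counts)
        assert list(chosen.values())[0].score == 5.0

    def test_donor_without_lss_is_absent(self):
        site = make_site(cls="adSS_3n")
        counts = make_counts(
            {"k1": [("canonical", site, 50)], "k2": [("canonical", site, 50)]},
            {"k1": "control", "k2": "control"},
        )
        assert L.build_comparison_set(L.SiteCatalog([site]), counts) == {}


class TestCompositeProfile:
    conditions = TestCallActivated.conditions

    def build(self, fold_per_site, ext=20):
        sites, calls, profiles = [], [], {}
        counts = make_counts(
            {s: [] for s in self.conditions}, self.conditions
        )
        for i, fold in enumerate(fold_per_site):
            site = make_site(gt=1000 * (i + 1) + 20, donor=1000 * (i + 1), ext=ext)
            sites.append(site)
            calls.append(L.ActivationCall(site=site, replicates=[], passes_initial=True))
            for sample in self.conditions:
                depth = 10.0 * fold if self.conditions[sample] == "case" else 10.0
                profiles[(site.key, sample)] = L.CoverageProfile(
                    site_key=site.key, sample_id=sample,
                    depths=np.full(ext, depth), normalization=1.0,
                )
        return calls, profiles, counts

    def test_constant_fold_gives_flat_median_and_tight_band(self):
        calls, profiles, counts = self.build([2.0, 2.0, 2.0])
        comp = L.composite_profile(calls, profiles, counts)
        assert np.allclose(comp.median, 2.0)
        assert np.allclose(comp.ci_low, 2.0) and np.allclose(comp.ci_high, 2.0)

    def test_single_site_is_degenerate(self):
        calls, profiles, counts = self.build([3.0])
        comp = L.composite_profile(calls, profiles, counts)
        assert comp.degenerate
        assert np.allclose(comp.median, 3.0)

    def test_three_sites_order_statistic_band(self):
        calls, profiles, counts = self.build([1.0, 2.0, 9.0])
        comp = L.composite_profile(calls, profiles, counts)
        assert np.allclose(comp.median, 2.0)
        assert np.allclose(comp.ci_low, 1.0)
        assert np.allclose(comp.ci_high, 9.0)

    def test_standardized_profile_has_100_bins(self):
        calls, profiles, counts = self.build([2.0], ext=37)
        comp = L.composite_profile(calls, profiles, counts)
        assert comp.standardized.shape == (1, 100)

    def test_median_ci_bounds_are_valid_ranks(self):
        for n in range(1, 30):
            lo, hi = median_ci_bounds(n)
            assert 0 <= lo <= hi <= n - 1

    def test_standardize_averages_within_bins(self):
        fold = np.arange(200, dtype=float)
        out = standardize_profile(fold, n_bins=100)
        assert out[0] == pytest.approx(np.mean(fold[0:2]))
        assert len(out) == 100
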