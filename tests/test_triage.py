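"""Unexplained-variant triage: the Wilcoxon rank-sum test (exact and
approximate), project exclusion arithmetic, and the filtering cascade on the
synthetic cohort."""

import numpy as np
import pytest
from scipy.stats import mannwhitneyu

from ptriage.triage import exclude_project, wilcoxon_rank_sum
from ptriage.variants import Sample


class TestWilcoxon:
    def test_exact_small_sample_example(self):
        """Three old vs three young ages: 2 of the C(6,3)=20 rank
        assignments are as extreme, so exact two-sided p = 0.1."""
        stat, p = wilcoxon_rank_sum([80, 85, 90], [40, 45, 50])
        assert stat == 4 + 5 + 6
        assert p == pytest.approx(0.1)

    def test_identical_multisets_p_one(self):
        _, p = wilcoxon_rank_sum([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == pytest.approx(1.0)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1, 2])

    def test_midranks_for_ties(self):
        # with ties present the test falls through to the tie-corrected
        # normal approximation and still behaves symmetrically
        _, p1 = wilcoxon_rank_sum([1, 2, 2, 9, 9, 9, 10, 11, 12, 13],
                                  [2, 2, 3, 9, 9, 9, 9, 4, 5, 6])
        _, p2 = wilcoxon_rank_sum([2, 2, 3, 9, 9, 9, 9, 4, 5, 6],
                                  [1, 2, 2, 9, 9, 9, 10, 11, 12, 13])
        assert p1 == pytest.approx(p2)

    def test_agrees_with_scipy(self):
        """Independent route: scipy's Mann-Whitney U maps onto the rank-sum
        statistic by U = W - n_a(n_a+1)/2 and gives the same p-values."""
        rng = np.random.default_rng(5)
        for _ in range(20):
            a = rng.normal(size=9)
            b = rng.normal(0.5, size=12)
            w, p = wilcoxon_rank_sum(a, b, exact_max_n=0)  # force approx
            res = mannwhitneyu(a, b, alternative="two-sided", method="asymptotic",
                               use_continuity=True)
            assert res.statistic == pytest.approx(w - 9 * 10 / 2)
            assert p == pytest.approx(res.pvalue, rel=1e-6)
        # exact route against scipy's exact method
        for _ in range(10):
            a = rng.normal(size=6)
            b = rng.normal(size=7)
            _, p = wilcoxon_rank_sum(a, b)
            res = mannwhitneyu(a, b, alternative="two-sided", method="exact")
            assert p == pytest.approx(res.pvalue, rel=1e-9)

    def test_exact_vs_approx_agreement_bulk(self):
        """For n=8 vs 8 without ties the approximation agrees with the exact
        enumeration within 10% relative error throughout the non-extreme
        support (exact p >= 0.04), and is conservative further out."""
        from itertools import combinations

        data = list(range(1, 17))  # any tie-free sample reduces to its ranks
        for w_target in range(36, 69):
            ranks_a = next(
                c for c in combinations(range(1, 17), 8) if sum(c) == w_target
            )
            a = [float(r) for r in ranks_a]
            b = [float(r) for r in data if r not in ranks_a]
            _, p_exact = wilcoxon_rank_sum(a, b)
            _, p_approx = wilcoxon_rank_sum(a, b, exact_max_n=0)
            if p_exact >= 0.04:
                assert abs(p_approx - p_exact) / p_exact <= 0.10, w_target
            else:
                assert p_approx >= p_exact  # conservative in the far tail


class TestExcludeProject:
    def _samples(self, n_excluded, n_total):
        out = {}
        for i in range(n_total):
            proj = "1kg" if i < n_excluded else "pop"
            out[f"S{i}"] = Sample(f"S{i}", "nfe", proj, age=50.0)
        return out

    def test_cascade_arithmetic_matches_cohort_scale(self):
        """236 carriers of 137 variants with 41 excluded-project carriers
        arranged so 31 variants become carrier-less: 195 carriers of 106
        variants remain."""
        samples = self._samples(41, 236)
        excluded_ids = [f"S{i}" for i in range(41)]
        kept_ids = [f"S{i}" for i in range(41, 236)]
        carriers: dict[str, set] = {}
        # 31 variants carried only by excluded-project samples
        for k in range(31):
            carriers[f"v{k}"] = {excluded_ids[k]}
        # 10 variants with one excluded and one kept carrier
        for k in range(31, 41):
            carriers[f"v{k}"] = {excluded_ids[k], kept_ids[k - 31]}
        # remaining 96 variants carried by kept samples (2 each, overlapping)
        idx = 10
        for k in range(41, 137):
            carriers[f"v{k}"] = {
                kept_ids[idx % 195], kept_ids[(idx + 1) % 195]
            }
            idx += 2
        # ensure every sample is a carrier of something
        all_carr = set().union(*carriers.values())
        for sid in samples:
            if sid not in all_carr:
                carriers["v136"].add(sid)
        assert len(carriers) == 137
        assert len(set().union(*carriers.values())) == 236

        out, dropped = exclude_project(carriers, samples, "1kg")
        assert len(dropped) == 31
        assert len(out) == 106
        assert len(set().union(*out.values())) == 195

    def test_unknown_project_noop(self):
        samples = self._samples(0, 3)
        carriers = {"v": {"S0", "S1"}}
        with pytest.warns(UserWarning):
            out, dropped = exclude_project(carriers, samples, "nope")
        assert out == carriers and not dropped

    def test_all_carriers_excluded(self):
        samples = self._samples(3, 3)
        out, dropped = exclude_project({"v": {"S0", "S1", "S2"}}, samples, "1kg")
        assert out == {} and dropped == {"v"}

    def test_no_excluded_carriers_identity(self):
        samples = self._samples(1, 4)
        carriers = {"v": {"S1", "S2", "S3"}}
        out, dropped = exclude_project(carriers, samples, "1kg")
        assert out == carriers and not dropped


class TestCascadeOnCohort:
    def test_monotone_counts_and_planted_drops(self, cohort, pipeline_report):
        """Cascade counts never increase; the project-restricted plants
        vanish at the project stage and the somatic CH plants at the
        somatic stage; genuine LoF plants survive."""
        triage = pipeline_report.triage
        stages = triage["stages"]
        for a, b in zip(stages, stages[1:]):
            assert b["variants"] <= a["variants"]
            assert b["carriers"] <= a["carriers"]

        truth = cohort.truth
        project_ids = set(
            truth.loc[truth["scenario"] == "project_cluster", "variant_id"]
        )
        somatic_ids = set(
            truth.loc[truth["scenario"] == "somatic_low_ab_ch", "variant_id"]
        )
        true_lof_ids = set(
            truth.loc[truth["scenario"] == "true_lof_unexplained", "variant_id"]
        )
        reasons = triage["drop_reason"]
        for vid in project_ids:
            assert reasons.get(vid) == "excluded_project_only"
        for vid in somatic_ids:
            assert "ch_gene" in reasons.get(vid, "")
        dropped = set(reasons)
        assert dropped & true_lof_ids == set()
        assert set(triage["surviving_variants"]) >= true_lof_ids

    def test_age_skew_detected_for_ch_plants(self, pipeline_report):
        tests = pipeline_report.triage["age_tests"]
        assert "ch_gene" in tests
        assert tests["ch_gene"]["p_two_sided"] < 0.05
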