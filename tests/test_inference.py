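"""Permutation machinery, p-value conventions, and the family-wise maximum."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

import wmconn as w
from wmconn.inference import _group_means

from conftest import separable_features, toy_registry


@pytest.fixture(scope="module")
def labels_runs():
    return np.tile(np.arange(6), 4), np.repeat(np.arange(4), 6)


class TestPermuteLabels:
    def test_per_run_histogram_conserved(self, labels_runs):
        labels, runs = labels_runs
        perm = w.permute_labels_within_runs(labels, runs, 0)
        for r in range(4):
            assert sorted(perm[runs == r]) == sorted(labels[runs == r])

    def test_deterministic_given_seed(self, labels_runs):
        labels, runs = labels_runs
        p1 = w.permute_labels_within_runs(labels, runs, 42)
        p2 = w.permute_labels_within_runs(labels, runs, 42)
        assert np.array_equal(p1, p2)

    def test_within_run_arrangements_uniform(self):
        # 3-label toy block: all 3! arrangements equally likely (chi-square)
        labels = np.array([0, 1, 2])
        runs = np.zeros(3, dtype=int)
        rng = np.random.default_rng(7)
        counts = {p: 0 for p in itertools.permutations([0, 1, 2])}
        n = 10_000
        for _ in range(n):
            counts[tuple(w.permute_labels_within_runs(labels, runs, rng))] += 1
        chi2 = sum((c - n / 6) ** 2 / (n / 6) for c in counts.values())
        assert chi2 < stats.chi2.ppf(0.999, df=5)

    def test_runs_shuffled_independently(self):
        labels = np.tile(np.arange(3), 2)
        runs = np.repeat([0, 1], 3)
        rng = np.random.default_rng(1)
        same = sum(
            np.array_equal(p[:3], p[3:])
            for p in (w.permute_labels_within_runs(labels, runs, rng) for _ in range(500))
        )
        assert 30 < same < 150  # ~1/6 of 500 if independent


class TestAssignPvalue:
    def _null(self, values):
        return w.NullDistribution(max_stats=np.asarray(values, dtype=float),
                                  family=("u",), seed=0)

    def test_floor_at_one_over_nperm(self):
        null = self._null(np.linspace(0.1, 0.3, 500))
        assert w.assign_pvalue(0.99, null) == pytest.approx(1 / 500) == 0.002

    def test_median_gives_half(self):
        null = self._null(np.linspace(0, 1, 500))
        med = float(np.median(null.max_stats))
        assert w.assign_pvalue(med, null) == pytest.approx(0.5, abs=0.01)

    def test_below_all_gives_one(self):
        null = self._null(np.linspace(0.1, 0.3, 500))
        assert w.assign_pvalue(0.0, null) == 1.0

    def test_ties_count_against_observation(self):
        null = self._null([0.1, 0.2, 0.2, 0.3])
        assert w.assign_pvalue(0.2, null) == pytest.approx(3 / 4)


class TestBuildNull:
    def test_max_stats_length(self, labels_runs):
        labels, runs = labels_runs
        rng = np.random.default_rng(0)
        grams = np.stack(
            [[w.gram_matrix(rng.normal(size=(24, 10))) for _ in range(2)]]
        )
        null = w.build_null(grams, labels, runs, n_perm=50, seed=1)
        assert null.n_perm == 50
        assert np.all((null.max_stats >= 0) & (null.max_stats <= 1))

    def test_single_unit_family_max_is_identity(self, labels_runs):
        labels, runs = labels_runs
        rng = np.random.default_rng(2)
        grams = np.stack(
            [[w.gram_matrix(rng.normal(size=(24, 10))) for _ in range(3)]]
        )
        null = w.build_null(grams, labels, runs, n_perm=30, seed=3, keep_unit_nulls=True)
        assert np.array_equal(null.max_stats, null.unit_nulls[:, 0])

    def test_deterministic_given_seed(self, labels_runs):
        labels, runs = labels_runs
        rng = np.random.default_rng(4)
        grams = np.stack(
            [[w.gram_matrix(rng.normal(size=(24, 10))) for _ in range(2)]
             for _ in range(3)]
        )
        n1 = w.build_null(grams, labels, runs, n_perm=20, seed=5)
        n2 = w.build_null(grams, labels, runs, n_perm=20, seed=5)
        assert np.array_equal(n1.max_stats, n2.max_stats)

    def test_family_max_inflates_null_center(self, labels_runs):
        # max over units pushes the null above single-unit chance (1/6)
        labels, runs = labels_runs
        rng = np.random.default_rng(6)
        grams = np.stack(
            [[w.gram_matrix(rng.normal(size=(24, 10))) for _ in range(4)]
             for _ in range(10)]
        )
        null = w.build_null(grams, labels, runs, n_perm=60, seed=7, keep_unit_nulls=True)
        assert null.max_stats.mean() > 1 / 6 + 0.02
        # and stochastically dominates every single unit's own null
        for u in range(grams.shape[0]):
            assert np.all(null.max_stats >= null.unit_nulls[:, u])
        for q in (0.25, 0.5, 0.75):
            assert np.quantile(null.max_stats, q) >= np.quantile(null.unit_nulls[:, 0], q)

    def test_pvalues_invariant_to_unit_order_and_class_relabeling(self, labels_runs):
        labels, runs = labels_runs
        rng = np.random.default_rng(8)
        gram_list = [
            [w.gram_matrix(rng.normal(size=(24, 12))) for _ in range(3)]
            for _ in range(4)
        ]
        grams = np.stack(gram_list)
        obs = _group_means(grams, labels, runs)
        null = w.build_null(grams, labels, runs, n_perm=40, seed=9)
        p = [w.assign_pvalue(o, null) for o in obs]

        order = [2, 0, 3, 1]
        grams_perm = grams[order]
        obs_perm = _group_means(grams_perm, labels, runs)
        null_perm = w.build_null(grams_perm, labels, runs, n_perm=40, seed=9)
        p_perm = [w.assign_pvalue(o, null_perm) for o in obs_perm]
        assert [p[i] for i in order] == p_perm

        # monotone relabeling of classes: 0..5 -> 10,20,..,60
        relabeled = labels * 10 + 10
        obs_rel = _group_means(grams, relabeled, runs)
        null_rel = w.build_null(grams, relabeled, runs, n_perm=40, seed=9)
        p_rel = [w.assign_pvalue(o, null_rel) for o in obs_rel]
        assert p == p_rel


@pytest.fixture(scope="module")
def signal_cohort():
    reg = toy_registry(n_rois=6, n_subrois=8)
    truth = w.GroundTruth(
        signal_networks=(("R00", "R01", "R02"),), coupling_strength=0.7
    )
    return w.simulate_cohort(4, reg, w.AcqConfig(), truth, seed=31), reg


class TestFamilyAnalysis:
    def test_planted_network_detected_controls_spared(self, signal_cohort):
        cohort, reg = signal_cohort
        nets = w.enumerate_networks(reg, {2, 3})
        planted = {"R00", "R01", "R02"}
        family = [n for n in nets if set(n.names) == planted or len(set(n.names) & planted) <= 1]
        report, null = w.run_family_analysis(
            "connectivity-2500", cohort, n_perm=49, seed=5, family=family
        )
        sig = set(report[report.significant]["unit"])
        assert "R00+R01+R02" in sig
        clean = [n.label for n in family if not (set(n.label.split("+")) & planted)]
        assert not (sig & set(clean))

    def test_irrelevant_item_mode_runs_and_differs(self, signal_cohort):
        cohort, reg = signal_cohort
        nets = w.enumerate_networks(reg, {3})
        planted = next(n for n in nets if set(n.names) == {"R00", "R01", "R02"})
        rep_wm, _ = w.run_family_analysis(
            "connectivity-2500", cohort, n_perm=19, seed=6, family=[planted]
        )
        rep_irr, _ = w.run_family_analysis(
            "irrelevant-item", cohort, n_perm=19, seed=6, family=[planted]
        )
        # content is tied to the retro-cued item only: the irrelevant-item
        # labeling must not carry the planted signal
        assert rep_wm["observed"].iloc[0] > 0.5
        assert rep_irr["observed"].iloc[0] < rep_wm["observed"].iloc[0] - 0.2

    def test_within_roi_control_mode(self, signal_cohort):
        cohort, reg = signal_cohort
        report, _ = w.run_family_analysis(
            "within-roi-control", cohort, n_perm=19, seed=7,
            family=[reg["R00"], reg["R03"]],
        )
        assert set(report["unit"]) == {"R00", "R03"}

    def test_unknown_mode_rejected(self, signal_cohort):
        cohort, _ = signal_cohort
        with pytest.raises(ValueError, match="unknown mode"):
            w.run_family_analysis("searchlight", cohort)

    def test_max_units_subsamples_deterministically(self, signal_cohort):
        cohort, reg = signal_cohort
        r1, _ = w.run_family_analysis(
            "connectivity-2500", cohort, n_perm=9, seed=8, max_units=5
        )
        r2, _ = w.run_family_analysis(
            "connectivity-2500", cohort, n_perm=9, seed=8, max_units=5
        )
        assert len(r1) == 5 and list(r1["unit"]) == list(r2["unit"])


class TestActivationPath:
    def test_activation_family_on_toy_registry(self):
        # content betas carry no class signal in this generator (coupling,
        # not amplitude, codes content), so the activation path runs at chance
        reg = toy_registry(n_rois=4, n_subrois=5)
        cohort = w.simulate_cohort(3, reg, w.AcqConfig(), w.GroundTruth(), seed=41)
        report, null = w.run_family_analysis(
            "activation-86", cohort, n_perm=19, seed=9, family=list(reg.rois)
        )
        assert len(report) == 4
        assert not report["significant"].any()
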