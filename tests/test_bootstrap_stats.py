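import numpy as np
import pandas as pd
import pytest

from boldhrf.bootstrap_stats import (
    GroupResult,
    bootstrap_across,
    bootstrap_within,
    compare_params,
    resample_curves,
    undershoot_pvalue,
)
from boldhrf.epoching import EpochSet, baseline_adjust
from boldhrf.errors import GridMismatchError, InsufficientDataError
from boldhrf.synthetic_data import HrfModel, simulate_epochs

TR = 1.25


def make_subject(acq, model, noise_sd, rng, n_boot=500, subject_id="s0"):
    epochs, truth = simulate_epochs(acq, model, noise_sd, rng=rng)
    es = baseline_adjust(
        EpochSet(epochs, acq.tr_seconds, subject_id=subject_id)
    )
    return (
        bootstrap_within(es, n_boot=n_boot, seed=int(rng.integers(2**31))),
        truth,
    )


def synthetic_group(stat_samples, params=None, n_boot2=None):
    """Hand-built GroupResult for testing the inference helpers alone."""
    stat = np.asarray(stat_samples, dtype=float)
    n = stat.size if n_boot2 is None else n_boot2
    if params is None:
        params = pd.DataFrame({"ttp": stat})
    return GroupResult(
        times=np.arange(4) * TR,
        group_mean_curve=np.zeros(4),
        ci_low=np.zeros(4),
        ci_high=np.zeros(4),
        param_samples=params,
        undershoot_stat_samples=stat,
        p_undershoot=float("nan"),
        n_boot2=n,
        seed=0,
    )


class TestBootstrapWithin:
    def test_identical_epochs_are_degenerate(self, acq_uhf):
        epochs, truth = simulate_epochs(acq_uhf, HrfModel(), 0.0, rng=0)
        es = EpochSet(np.tile(truth, (10, 1)), acq_uhf.tr_seconds)
        res = bootstrap_within(es, n_boot=100, seed=1)
        assert np.allclose(res.ci_low, res.mean_curve)
        assert np.allclose(res.ci_high, res.mean_curve)
        assert res.variability == 0.0
        assert np.isinf(res.cnr)
        assert res.flags.get("degenerate")

    def test_variability_matches_analytic_sem(self, rng):
        """85 pure-noise epochs: variability ~ sigma/sqrt(85) within 20%."""
        sigma, n = 1.0, 85
        ratios = []
        for _ in range(100):
            es = EpochSet(sigma * rng.standard_normal((n, 21)), TR)
            res = bootstrap_within(es, n_boot=200, seed=int(rng.integers(2**31)))
            ratios.append(res.variability / (sigma / np.sqrt(n)))
        assert np.mean(ratios) == pytest.approx(1.0, abs=0.2)

    def test_cnr_is_peak_over_variability(self, acq_uhf, rng):
        # sigma chosen so variability ~ sigma/sqrt(85) ~ 0.2 -> CNR ~ 5
        model = HrfModel(amplitude_percent=1.0)
        res, _ = make_subject(acq_uhf, model, 0.2 * np.sqrt(85), rng)
        assert res.cnr == res.params.p_amp / res.variability  # identity
        assert res.cnr == pytest.approx(5.0, rel=0.35)

    def test_seed_reproducibility(self, acq_uhf):
        epochs, _ = simulate_epochs(acq_uhf, HrfModel(), 0.5, rng=3)
        es = EpochSet(epochs, acq_uhf.tr_seconds)
        a = bootstrap_within(es, n_boot=50, seed=42)
        b = bootstrap_within(es, n_boot=50, seed=42)
        assert np.array_equal(a.replicate_curves, b.replicate_curves)
        assert a.variability == b.variability
        assert a.param_samples.equals(b.param_samples)

    def test_adding_noise_does_not_decrease_variability(self, acq_uhf, rng):
        base_epochs, _ = simulate_epochs(acq_uhf, HrfModel(), 0.2, rng=rng)
        noisier = base_epochs + 0.6 * rng.standard_normal(base_epochs.shape)
        v0 = bootstrap_within(EpochSet(base_epochs, TR), 300, seed=7).variability
        v1 = bootstrap_within(EpochSet(noisier, TR), 300, seed=7).variability
        assert v1 > v0

    def test_too_few_epochs_rejected(self):
        with pytest.raises(InsufficientDataError):
            bootstrap_within(EpochSet(np.zeros((1, 21)), TR), 100, 0)


class TestBootstrapAcross:
    def test_one_subject_duplicated_recovers_subject_mean(self, acq_uhf, rng):
        res, _ = make_subject(acq_uhf, HrfModel(), 0.4, rng)
        g = bootstrap_across([res, res], n_boot2=500, seed=0)
        assert np.allclose(g.group_mean_curve, res.mean_curve, atol=1e-12)
        assert np.abs(
            g.param_samples["ttp"].mean() - res.param_samples["ttp"].mean()
        ) < 0.5

    def test_deterministic_subjects_give_zero_width_cis(self, acq_uhf):
        _, truth = simulate_epochs(acq_uhf, HrfModel(), 0.0, rng=0)
        subs = []
        for s in range(7):
            es = EpochSet(np.tile(truth, (10, 1)), TR, subject_id=f"s{s}")
            subs.append(bootstrap_within(es, n_boot=100, seed=s))
        g = bootstrap_across(subs, n_boot2=400, seed=1)
        assert np.allclose(g.ci_high - g.ci_low, 0.0)

    def test_group_ci_coverage_near_68_percent(self, acq_uhf):
        """7 subjects sharing one truth: group CIs cover the true curve for
        ~68% of timepoints, aggregated over outer replications."""
        root = np.random.default_rng(2024)
        model = HrfModel(amplitude_percent=1.0)
        covered, total = 0, 0
        for _ in range(25):
            subs, truth = [], None
            for s in range(7):
                res, truth = make_subject(
                    acq_uhf, model, 0.5, root, n_boot=300, subject_id=f"s{s}"
                )
                subs.append(res)
            adj = truth - 0.5 * (truth[0] + truth[-1])
            g = bootstrap_across(subs, n_boot2=500, seed=int(root.integers(2**31)))
            covered += int(np.sum((adj >= g.ci_low) & (adj <= g.ci_high)))
            total += adj.size
        assert covered / total == pytest.approx(0.68, abs=0.10)

    def test_mixed_grids_require_resample_directive(self, acq_uhf, acq_3t, rng):
        a, _ = make_subject(acq_uhf, HrfModel(), 0.4, rng, n_boot=100)
        b_epochs, _ = simulate_epochs(acq_3t, HrfModel(), 0.4, rng=rng)
        b = bootstrap_within(
            baseline_adjust(EpochSet(b_epochs, acq_3t.tr_seconds)), 100, seed=3
        )
        with pytest.raises(GridMismatchError):
            bootstrap_across([a, b], n_boot2=100, seed=0)
        g = bootstrap_across(
            [a, b], n_boot2=100, seed=0, resample_to_common_grid=True
        )
        assert g.times[1] - g.times[0] == pytest.approx(0.25)

    def test_resample_curves_reproduces_knots(self, rng):
        y = rng.standard_normal(21)
        out = resample_curves(y, TR, np.arange(21) * TR)
        assert np.allclose(out, y, atol=1e-9)


class TestUndershootTest:
    def test_all_negative_samples_floor_p(self):
        g = synthetic_group(-np.abs(np.random.default_rng(0).standard_normal(2000)) - 0.01)
        assert undershoot_pvalue(g) == pytest.approx(1 / 2000)

    def test_symmetric_samples_give_half(self):
        rng = np.random.default_rng(1)
        g = synthetic_group(rng.standard_normal(4000))
        assert undershoot_pvalue(g) == pytest.approx(0.5, abs=0.05)

    def test_cortical_like_group_detects_undershoot(self, acq_uhf):
        root = np.random.default_rng(77)
        model = HrfModel(
            amplitude_percent=1.0,
            peak_time_seconds=6.5,
            undershoot_ratio=0.3,
            undershoot_delay_seconds=9.0,
        )
        subs = [
            make_subject(acq_uhf, model, 0.77, root, subject_id=f"s{s}")[0]
            for s in range(7)
        ]
        g = bootstrap_across(subs, n_boot2=2000, seed=5)
        assert g.p_undershoot < 0.05

    def test_null_group_accepts(self, acq_uhf):
        root = np.random.default_rng(88)
        model = HrfModel(amplitude_percent=1.0, undershoot_ratio=0.0)
        subs = [
            make_subject(acq_uhf, model, 0.5, root, subject_id=f"s{s}")[0]
            for s in range(7)
        ]
        g = bootstrap_across(subs, n_boot2=2000, seed=6)
        assert g.p_undershoot > 0.05


class TestCompareParams:
    def test_identical_samples_give_p_one(self):
        s = np.random.default_rng(0).standard_normal(2000)
        p = compare_params(synthetic_group(s), synthetic_group(s), "ttp")
        assert p == pytest.approx(1.0)

    def test_separated_distributions_hit_floor(self):
        rng = np.random.default_rng(0)
        a = synthetic_group(rng.normal(10, 0.1, 2000))
        b = synthetic_group(rng.normal(0, 0.1, 2000))
        assert compare_params(a, b, "ttp") == pytest.approx(1 / 2000)

    def test_ttp_gap_power(self, acq_uhf):
        """1-s true TTP gap, ~0.3-s within-subject TTP SD, 7 vs 7 subjects:
        the two-sided bootstrap comparison rejects in >= 80% of replications
        (observed rate pinned near 100%)."""
        root = np.random.default_rng(31)
        fast = HrfModel(amplitude_percent=1.0, peak_time_seconds=5.5)
        slow = HrfModel(amplitude_percent=1.0, peak_time_seconds=6.5)
        n_rep, reject = 40, 0
        for _ in range(n_rep):
            groups = []
            for model in (fast, slow):
                subs = [
                    make_subject(acq_uhf, model, 0.35, root, n_boot=300,
                                 subject_id=f"s{s}")[0]
                    for s in range(7)
                ]
                groups.append(
                    bootstrap_across(subs, n_boot2=1000,
                                     seed=int(root.integers(2**31)))
                )
            if compare_params(groups[0], groups[1], "ttp") < 0.05:
                reject += 1
        assert reject / n_rep >= 0.80

    def test_missing_parameter_rejected(self):
        g = synthetic_group(np.zeros(10))
        with pytest.raises(Exception):
            compare_params(g, g, "nope")
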