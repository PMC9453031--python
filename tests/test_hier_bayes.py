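"""Hierarchical interaction models, HPDI, difference distributions, strata."""

import numpy as np
import pandas as pd
import pytest

from mal_profiler.errors import (
    InsufficientDataError,
    NonIdentifiableError,
    SeparationError,
    ValidationError,
)
from mal_profiler.hier_bayes import (
    HierModelSpec,
    StratumSpec,
    difference_distribution,
    fit_hier_linear,
    fit_hier_logistic,
    hpdi,
    stratify_cohort,
)
from tests.conftest import make_linear_frame, make_logistic_frame


def hpdi_brute_force(draws, mass):
    """Oracle: scan every window of ceil(mass·n) sorted draws."""
    d = np.sort(np.asarray(draws, dtype=float))
    m = int(np.ceil(mass * d.size))
    best = None
    for i in range(d.size - m + 1):
        width = d[i + m - 1] - d[i]
        if best is None or width < best[0] - 1e-15:
            best = (width, d[i], d[i + m - 1])
    return best[1], best[2]


class TestHpdi:
    def test_degenerate_distribution(self):
        assert hpdi([3.0] * 10, 0.9) == (3.0, 3.0)

    def test_uniform_grid_first_window_tie_break(self):
        assert hpdi(np.arange(1, 101), 0.90) == (1.0, 90.0)

    def test_standard_normal_interval(self):
        rng = np.random.default_rng(0)
        low, high = hpdi(rng.standard_normal(1_000_000), 0.90)
        assert low == pytest.approx(-1.6449, abs=0.01)
        assert high == pytest.approx(1.6449, abs=0.01)

    @pytest.mark.parametrize("mass", [0.5, 0.8, 0.9, 0.95])
    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_matches_brute_force_window_search(self, mass, seed):
        rng = np.random.default_rng(seed)
        draws = rng.gamma(2.0, 1.5, 500)  # skewed posterior stand-in
        assert hpdi(draws, mass) == pytest.approx(hpdi_brute_force(draws, mass))

    def test_width_monotone_in_mass_and_contains_median(self):
        rng = np.random.default_rng(7)
        draws = rng.normal(2.0, 1.0, 4000)
        widths = []
        for mass in (0.5, 0.7, 0.9, 0.99):
            low, high = hpdi(draws, mass)
            widths.append(high - low)
            assert low <= np.median(draws) <= high
        assert widths == sorted(widths)

    def test_insufficient_draws(self):
        with pytest.raises(InsufficientDataError):
            hpdi([1.0], 0.9)


class TestDifferenceDistribution:
    def test_self_difference_is_degenerate_zero(self):
        draws = np.random.default_rng(0).normal(size=1000)
        summary, substantial = difference_distribution(draws, draws)
        assert summary.mean == 0.0
        assert (summary.hpdi_low, summary.hpdi_high) == (0.0, 0.0)
        assert not substantial

    def test_constant_shift(self):
        a = np.random.default_rng(1).normal(size=1000)
        summary, substantial = difference_distribution(a, a + 0.5)
        assert summary.mean == pytest.approx(-0.5)
        assert substantial

    def test_mismatched_draw_counts_rejected(self):
        with pytest.raises(ValidationError, match="aligned"):
            difference_distribution(np.zeros(10), np.zeros(11))

    def test_independent_normals_closed_form(self):
        # difference of N(1.15, 0.08) and N(1.21, 0.08) has mean -0.06
        rng = np.random.default_rng(2)
        a = rng.normal(1.15, 0.08, 100_000)
        b = rng.normal(1.21, 0.08, 100_000)
        summary, _ = difference_distribution(a, b)
        assert summary.mean == pytest.approx(-0.06, abs=0.005)
        # sd of the difference is sqrt(2)·0.08; 90% HPDI ≈ mean ± 1.645·sd
        assert summary.hpdi_high - summary.hpdi_low == pytest.approx(
            2 * 1.645 * 0.08 * np.sqrt(2), abs=0.02
        )


class TestStratify:
    @staticmethod
    def _labelled(rows):
        return pd.DataFrame(rows)

    def test_lacunar_excluded_from_anterior_by_default(self):
        cohort = self._labelled(
            [
                {"circulation": "anterior", "lacunar": 1},
                {"circulation": "anterior", "lacunar": 0},
            ]
        )
        out = stratify_cohort(cohort, StratumSpec("anterior"))
        assert len(out) == 1
        # explicit override keeps lacunar patients
        kept = stratify_cohort(cohort, StratumSpec("anterior", exclude_lacunar=False))
        assert len(kept) == 2

    def test_both_circulation_patients_in_neither_stratum(self):
        cohort = self._labelled(
            [
                {"circulation": "both", "lacunar": 0},
                {"circulation": "anterior", "lacunar": 0},
                {"circulation": "posterior", "lacunar": 0},
            ]
        )
        assert len(stratify_cohort(cohort, StratumSpec("anterior"))) == 1
        assert len(stratify_cohort(cohort, StratumSpec("posterior"))) == 1
        assert len(stratify_cohort(cohort, StratumSpec("all"))) == 3

    def test_published_anterior_stratum_sizes(self):
        rows = (
            [{"circulation": "anterior", "lacunar": 0, "mal": True}] * 292
            + [{"circulation": "anterior", "lacunar": 0, "mal": False}] * 140
            + [{"circulation": "anterior", "lacunar": 1, "mal": False}] * 30
            + [{"circulation": "posterior", "lacunar": 0, "mal": True}] * 20
        )
        out = stratify_cohort(self._labelled(rows), StratumSpec("anterior"))
        assert out["mal"].sum() == 292
        assert (~out["mal"]).sum() == 140

    def test_unlabelled_cohort_rejected(self):
        with pytest.raises(ValidationError):
            stratify_cohort(pd.DataFrame({"mal": [True]}), StratumSpec("anterior"))


class TestLinearFit:
    def test_agrees_with_per_group_least_squares(self):
        frame = make_linear_frame(42, 500, 1.2, 1.2, 2.0)
        res = fit_hier_linear(frame, HierModelSpec(seed=3))
        assert res.diagnostics["rhat_max"] < 1.01
        x = np.log(np.clip(frame["dwi_vol_ml"], 0.01, None))
        for grp, summary in ((False, res.slope_single), (True, res.slope_multiple)):
            mask = frame["mal"] == grp
            slope = np.polyfit(x[mask], frame.loc[mask, "nihss"], 1)[0]
            sd = (summary.hpdi_high - summary.hpdi_low) / (2 * 1.645)
            assert abs(summary.mean - slope) < 2 * sd

    def test_zero_outcome_concentrates_slopes_at_zero(self):
        frame = make_linear_frame(0, 100, 0.0, 0.0, 1.0)
        frame["nihss"] = 0.0
        res = fit_hier_linear(frame, HierModelSpec(seed=1, warmup=300, draws=300))
        assert abs(res.slope_single.mean) < 0.01
        assert abs(res.slope_multiple.mean) < 0.01
        assert not res.substantial

    def test_reproducible_under_fixed_seed(self):
        frame = make_linear_frame(9, 120, 1.0, 1.0, 1.5)
        spec = HierModelSpec(seed=11, warmup=300, draws=300)
        first = fit_hier_linear(frame, spec)
        second = fit_hier_linear(frame, spec)
        assert first.slope_single == second.slope_single
        assert first.difference == second.difference

    def test_constant_predictor_rejected(self):
        frame = make_linear_frame(1, 50, 1.0, 1.0, 1.0)
        frame["dwi_vol_ml"] = 5.0
        with pytest.raises(NonIdentifiableError):
            fit_hier_linear(frame, HierModelSpec(seed=0))

    def test_small_group_refused(self):
        frame = make_linear_frame(1, 5, 1.0, 1.0, 1.0)
        with pytest.raises(InsufficientDataError, match="single"):
            fit_hier_linear(frame, HierModelSpec(seed=0))

    def test_agrees_with_ensemble_sampler_cross_check(self):
        """Independent MCMC route: emcee on the same posterior density."""
        import emcee

        frame = make_linear_frame(8, 200, 0.8, 1.1, 1.5)
        spec = HierModelSpec(seed=5)
        res = fit_hier_linear(frame, spec)

        x = np.log(np.clip(frame["dwi_vol_ml"].to_numpy(), 0.01, None))
        y = frame["nihss"].to_numpy()
        grp = frame["mal"].to_numpy(bool)
        splits = [(x[~grp], y[~grp]), (x[grp], y[grp])]

        def log_post(theta):
            a = theta[0:2]
            b = theta[2:4]
            mu_a, mu_b, lta, ltb, ls = theta[4:]
            if not (-7 < lta < 7 and -7 < ltb < 7 and -7 < ls < 7):
                return -np.inf
            ta, tb, sig = np.exp([lta, ltb, ls])
            lp = -0.5 * (mu_a / 10) ** 2 - 0.5 * (mu_b / 10) ** 2
            lp += -0.5 * (ta / 10) ** 2 + lta - 0.5 * (tb / 10) ** 2 + ltb
            lp += -0.5 * (sig / 10) ** 2 + ls
            lp += sum(-np.log(ta) - 0.5 * ((ai - mu_a) / ta) ** 2 for ai in a)
            lp += sum(-np.log(tb) - 0.5 * ((bi - mu_b) / tb) ** 2 for bi in b)
            for g, (xg, yg) in enumerate(splits):
                resid = yg - a[g] - b[g] * xg
                lp += -len(xg) * ls - 0.5 * np.sum(resid**2) / sig**2
            return lp

        rng = np.random.default_rng(1)
        p0 = np.array([2, 2, 0.8, 1.1, 2, 1, 0, 0, 0.4]) + 0.05 * rng.standard_normal((32, 9))
        sampler = emcee.EnsembleSampler(32, 9, log_post)
        sampler.random_state = np.random.RandomState(1).get_state()
        sampler.run_mcmc(p0, 4000, progress=False)
        chain = sampler.get_chain(discard=2000, flat=True)
        for j, summary in ((2, res.slope_single), (3, res.slope_multiple)):
            sd = (summary.hpdi_high - summary.hpdi_low) / (2 * 1.645)
            assert abs(summary.mean - chain[:, j].mean()) < max(0.05, sd)


class TestLogisticFit:
    def test_agrees_with_maximum_likelihood(self):
        import statsmodels.api as sm

        frame = make_logistic_frame(3, 800, 0.8, 0.8)
        res = fit_hier_logistic(
            frame, HierModelSpec(outcome_kind="logistic", outcome="mrs_gt2", seed=2)
        )
        assert res.diagnostics["rhat_max"] < 1.02
        x = np.log(np.clip(frame["dwi_vol_ml"], 0.01, None))
        for grp, summary in ((False, res.slope_single), (True, res.slope_multiple)):
            mask = (frame["mal"] == grp).to_numpy()
            X = np.column_stack([np.ones(mask.sum()), x[mask]])
            ml = sm.Logit(frame.loc[mask, "mrs_gt2"].to_numpy(), X).fit(disp=0)
            sd = (summary.hpdi_high - summary.hpdi_low) / (2 * 1.645)
            assert abs(summary.mean - ml.params[1]) < 2 * sd
        assert not res.substantial

    def test_single_class_group_raises_separation_error(self):
        frame = make_logistic_frame(0, 60, 0.5, 0.5)
        frame.loc[frame["mal"], "mrs_gt2"] = 1.0
        with pytest.raises(SeparationError, match="multiple"):
            fit_hier_logistic(
                frame, HierModelSpec(outcome_kind="logistic", outcome="mrs_gt2", seed=0)
            )

    def test_non_binary_outcome_rejected(self):
        frame = make_logistic_frame(0, 60, 0.5, 0.5)
        frame["mrs_gt2"] = frame["mrs_gt2"] * 2.0 + 0.5
        with pytest.raises(ValidationError):
            fit_hier_logistic(
                frame, HierModelSpec(outcome_kind="logistic", outcome="mrs_gt2", seed=0)
            )


class TestSpecValidation:
    def test_bad_mass(self):
        with pytest.raises(ValidationError):
            HierModelSpec(hpdi_mass=1.5)

    def test_bad_prior_scale(self):
        with pytest.raises(ValidationError):
            HierModelSpec(sigma_scale=-1.0)

    def test_kind_mismatch(self):
        with pytest.raises(ValidationError):
            fit_hier_logistic(pd.DataFrame(), HierModelSpec(outcome_kind="linear"))
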