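"""Group statistics, regressions, ratio analyses and kernel densities."""
import itertools

import numpy as np
import pytest
from scipy import stats

from helpers import letters_are_valid, make_experiment
from nutlim.core_data import Concentration, Nutrient
from nutlim.growth_rates import GrowthResponse, compute_responses
from nutlim.meta_trends import (
    compact_letter_display,
    group_stats,
    kde,
    ols_fit,
    ratio_response_analysis,
)
from nutlim.synthetic import simulate_response_groups

N, P, Fe = Nutrient.N, Nutrient.P, Nutrient.Fe


def _responses(groups):
    """groups: {n_added: [values]} -> GrowthResponse list."""
    sets = {0: frozenset(), 1: frozenset({N}), 2: frozenset({N, Fe}),
            3: frozenset({N, Fe, P})}
    out = []
    for k, vals in groups.items():
        for i, v in enumerate(vals):
            out.append(GrowthResponse(
                experiment_id=f"{k}-{i}", added=sets[k], mu_net=float(v),
                chl_T=1.0, chl_I=1.0, t=1.0,
            ))
    return out


class TestGroupStats:
    def test_identical_groups_share_letter(self):
        groups, _, p = group_stats(_responses({0: [1.0, 1.1, 0.9],
                                               1: [1.0, 1.1, 0.9]}))
        assert groups[0].letter == groups[1].letter
        assert p > 0.05

    def test_clearly_different_groups_get_different_letters(self):
        groups, f, p = group_stats(_responses({0: [0.0, 0.0, 0.0],
                                               1: [10.0, 10.1, 9.9]}))
        assert p < 0.05
        assert not (set(groups[0].letter) & set(groups[1].letter))

    def test_means_invariant_to_within_group_ordering(self):
        a = group_stats(_responses({0: [1, 2, 3], 1: [4, 5, 6]}))[0]
        b = group_stats(_responses({0: [3, 1, 2], 1: [6, 4, 5]}))[0]
        assert [g.mean for g in a] == [g.mean for g in b]

    def test_single_group_no_letters(self):
        groups, f, p = group_stats(_responses({1: [1.0, 2.0, 3.0]}))
        assert groups[0].letter == "" and np.isnan(f)

    def test_planted_means_recovered_within_standard_errors(self):
        """Synthetic survey with per-group means 0.03/0.20/0.42/0.73 and SDs
        0.25/0.36/0.47/0.54 at n = 200/group."""
        means = (0.03, 0.20, 0.42, 0.73)
        sds = (0.25, 0.36, 0.47, 0.54)
        responses = simulate_response_groups(means, sds, n_per_group=200, seed=5)
        groups, _, p = group_stats(responses)
        for g, mu, sd in zip(groups, means, sds):
            se = sd / np.sqrt(g.n)
            assert abs(g.mean - mu) < 3 * se
            assert abs(g.sd - sd) < 4 * se
        assert p < 1e-6

    def test_letters_match_all_pairs_brute_force(self):
        responses = simulate_response_groups(
            (0.0, 0.1, 0.5, 0.52), (0.1, 0.1, 0.1, 0.1), n_per_group=30, seed=9
        )
        groups, _, _ = group_stats(responses)
        keyed = {g.key: g for g in groups}
        samples = {k: [r.mu_net for r in responses if min(r.n_added, 3) == k]
                   for k in keyed}
        tuk = stats.tukey_hsd(*(samples[k] for k in sorted(samples)))
        order = sorted(samples)
        sig = [
            (order[i], order[j])
            for i, j in itertools.combinations(range(len(order)), 2)
            if tuk.pvalue[i, j] <= 0.05
        ]
        letters = {k: keyed[k].letter for k in keyed}
        assert letters_are_valid(letters, list(keyed), sig)


class TestCompactLetterDisplay:
    @pytest.mark.parametrize("n_groups", [2, 3, 4, 5])
    def test_valid_for_random_significance_structures(self, n_groups):
        rng = np.random.default_rng(n_groups)
        keys = list(range(n_groups))
        for _ in range(20):
            pairs = [
                p for p in itertools.combinations(keys, 2)
                if rng.random() < 0.4
            ]
            letters = compact_letter_display(keys, pairs)
            assert letters_are_valid(letters, keys, pairs)


class TestOlsFit:
    def test_exact_line(self):
        x = np.arange(10.0)
        fit = ols_fit(x, 2 * x + 1)
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(1.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_orthogonal_response(self):
        x = np.array([-1.0, -1.0, 1.0, 1.0])
        y = np.array([1.0, -1.0, 1.0, -1.0])
        fit = ols_fit(x, y)
        assert fit.slope == pytest.approx(0.0)
        assert fit.r_squared == pytest.approx(0.0)

    def test_five_point_hand_example(self):
        """slope = Sxy/Sxx = 1.01, intercept = 0.97, R^2 = 0.99039
        (textbook formulas evaluated by hand)."""
        fit = ols_fit([1, 2, 3, 4, 5], [2.0, 2.9, 4.2, 4.8, 6.1])
        assert fit.slope == pytest.approx(1.01)
        assert fit.intercept == pytest.approx(0.97)
        assert fit.r_squared == pytest.approx(0.990388349514563)

    def test_r_squared_equals_squared_pearson(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=80)
        y = 0.4 * x + rng.normal(size=80)
        fit = ols_fit(x, y)
        r, _ = stats.pearsonr(x, y)
        assert fit.r_squared == pytest.approx(r**2, rel=1e-12)

    def test_pairwise_deletion_of_missing(self):
        x = [1.0, 2.0, np.nan, 4.0, 5.0]
        y = [1.0, 2.0, 3.0, np.nan, 5.0]
        fit = ols_fit(x, y)
        assert fit.n == 3

    def test_zero_variance_error(self):
        with pytest.raises(ValueError, match="variance"):
            ols_fit([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            ols_fit([1.0, 2.0], [1.0, 2.0])


def _ratio_survey(slope=-0.5, n=30, seed=4):
    """Experiments spanning log10(N:Fe) with a planted linear response of
    mu_net to the ratio for N additions."""
    rng = np.random.default_rng(seed)
    exps, resp = [], []
    for i in range(n):
        log_ratio = rng.uniform(-1.0, 1.5)  # N:Fe in mol:mmol
        n_umol = 10 ** rng.uniform(-1.5, 1.0)
        fe_nmol = n_umol / (10 ** log_ratio)  # ratio = N/(Fe*1e3)
        mu_n = 1.0 + slope * log_ratio + rng.normal(0, 0.05)
        exp = make_experiment(
            {frozenset(): 0.2, frozenset({N}): 0.6},
            exp_id=f"r{i}",
            nutrients={N: Concentration(n_umol, "umol/L"),
                       Fe: Concentration(fe_nmol, "nmol/L")},
        )
        exps.append(exp)
        resp.append(GrowthResponse(
            experiment_id=f"r{i}", added=frozenset({N}), mu_net=mu_n,
            chl_T=1.0, chl_I=1.0, t=1.0,
        ))
    return exps, resp


class TestRatioResponse:
    def test_planted_negative_slope_recovered(self):
        exps, resp = _ratio_survey(slope=-0.5)
        analysis = ratio_response_analysis(resp, exps, (N, Fe))
        fit = analysis.fits[("N", "mu_net")]
        # 95% CI of the fitted slope covers the planted slope
        x = [np.log10(e.nutrients[N].molar / e.nutrients[Fe].molar / 1e3)
             for e in exps]
        res = stats.linregress(x, [r.mu_net for r in resp])
        tcrit = stats.t.ppf(0.975, len(x) - 2)
        assert fit.slope == pytest.approx(res.slope)
        assert res.slope - tcrit * res.stderr <= -0.5 <= res.slope + tcrit * res.stderr
        assert fit.slope < 0

    def test_ratio_units_and_critical_line(self):
        """N = 2.13 µmol/L with Fe = 1 nmol/L sits exactly on the critical
        N:Fe requirement ratio of 2.13 mol:mmol."""
        exps, _ = _ratio_survey()
        analysis = ratio_response_analysis([], exps, (N, Fe))
        assert analysis.ratio_units == "mol:mmol"
        assert analysis.critical == pytest.approx(16 / 7.5e-3 / 1000)
        ratio = (2.13e-6 / 1e-9) / 1000.0
        assert ratio == pytest.approx(2.13)

    def test_empty_response_set_gives_no_fits(self):
        exps, _ = _ratio_survey()
        analysis = ratio_response_analysis([], exps, (N, Fe))
        assert analysis.fits == {}

    def test_zero_denominator_excluded(self):
        exps, resp = _ratio_survey(n=5)
        exps[0].nutrients[Fe] = Concentration(0.0, "nmol/L")
        analysis = ratio_response_analysis(resp, exps, (N, Fe))
        assert analysis.excluded == 1


class TestKde:
    def test_density_integrates_to_one(self):
        rng = np.random.default_rng(2)
        grid, dens = kde(rng.normal(size=200))
        assert np.trapezoid(dens, grid) == pytest.approx(1.0, abs=1e-3)

    def test_symmetric_input_symmetric_density(self):
        grid, dens = kde(np.array([-2.0, -1.0, 0.0, 1.0, 2.0]))
        assert dens == pytest.approx(dens[::-1], rel=1e-9)

    def test_two_point_closed_form(self):
        """Two points at +-1 with unit bandwidth: an equal mixture of two
        unit-variance Gaussians."""
        grid, dens = kde([-1.0, 1.0], bandwidth=1.0)
        expected = 0.5 * (
            stats.norm.pdf(grid, -1.0) + stats.norm.pdf(grid, 1.0)
        )
        assert dens == pytest.approx(expected, abs=1e-12)

    def test_nrd0_bandwidth_matches_r_rule(self):
        values = np.array([0.1, 0.4, 0.2, 0.9, 1.3, 0.7, 0.3, 1.1])
        sd = np.std(values, ddof=1)
        iqr = np.percentile(values, 75) - np.percentile(values, 25)
        bw = 0.9 * min(sd, iqr / 1.34) * len(values) ** -0.2
        grid, dens = kde(values)
        grid2, dens2 = kde(values, bandwidth=bw)
        assert dens == pytest.approx(dens2)

    def test_single_point_rejected(self):
        with pytest.raises(ValueError):
            kde([1.0])
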