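import numpy as np
import pytest
from scipy import stats as sps
from scipy.special import expit, gammaln

import matriline as ml
from matriline.errors import CapabilityError, ConfigurationError
from matriline.model import ChainDraws, batch_means_mcse

from conftest import make_binomial_records


def flat_records(n_dams=4, male=5, female=5):
    return [
        ml.DamRecord(f"d{i}", f"m{i}", male, female) for i in range(n_dams)
    ]


def zero_state(records, tau_m=1.0, tau_e=1.0):
    return ml.ParameterState(
        mu=0.0,
        m={r.matriline_id: 0.0 for r in records},
        e={r.dam_id: 0.0 for r in records},
        tau_m=tau_m,
        tau_e=tau_e,
    )


class TestLogitSexratio:
    def test_identity_at_zero(self):
        record = ml.DamRecord("d", "m", 5, 5)
        state = ml.ParameterState(mu=0.0, m={"m": 0.0}, e={"d": 0.0})
        assert ml.logit_sexratio(state, record) == pytest.approx(0.5)

    def test_closed_form_expit(self):
        record = ml.DamRecord("d", "m", 5, 5)
        state = ml.ParameterState(mu=-0.5, m={"m": -0.3}, e={"d": 0.1})
        assert ml.logit_sexratio(state, record) == pytest.approx(
            expit(-0.7), abs=1e-12
        )

    def test_additive_confounding_leaves_pi_unchanged(self):
        record = ml.DamRecord("d", "m", 5, 5)
        base = ml.ParameterState(mu=-0.2, m={"m": 0.4}, e={"d": 0.1})
        for c in (-1.3, 0.7, 2.0):
            shifted = ml.ParameterState(
                mu=base.mu + c, m={"m": 0.4 - c}, e={"d": 0.1}
            )
            assert ml.logit_sexratio(shifted, record) == pytest.approx(
                ml.logit_sexratio(base, record), abs=1e-12
            )

    def test_missing_effect_is_state_error(self):
        record = ml.DamRecord("d", "other", 5, 5)
        state = ml.ParameterState(mu=0.0, m={"m": 0.0}, e={"d": 0.0})
        with pytest.raises(ml.model.StateConsistencyError):
            ml.logit_sexratio(state, record)


class TestLogPosterior:
    def test_flat_data_closed_form(self):
        records = flat_records(n_dams=6)
        spec = ml.MaternalModelSpec()
        state = zero_state(records)
        lp = ml.log_posterior(state, records, spec)
        data_term = 6 * (gammaln(11) - 2 * gammaln(6) + 10 * np.log(0.5))
        # independent prior computation via scipy densities
        priors = (
            6 * sps.norm.logpdf(0.0, 0.0, 1.0)  # m effects at tau_m = 1
            + 6 * sps.norm.logpdf(0.0, 0.0, 1.0)  # e effects
            + sps.norm.logpdf(0.0, 0.0, np.sqrt(1000.0))  # mu
            + 2 * sps.gamma.logpdf(1.0, 0.1, scale=10.0)  # both precisions
        )
        assert lp == pytest.approx(data_term + priors, rel=1e-12)

    def test_bernoulli_and_binomial_differ_by_log_coefficient(self):
        rng = np.random.default_rng(3)
        records = make_binomial_records(rng, n_matrilines=3, dams_per_matriline=2)
        spec = ml.MaternalModelSpec()
        state = ml.ParameterState(
            mu=-0.4,
            m={r.matriline_id: rng.normal() * 0.3 for r in records},
            e={r.dam_id: rng.normal() * 0.3 for r in records},
        )
        per_offspring = []
        for r in records:
            for sex in [1] * r.total_male + [0] * r.total_female:
                per_offspring.append(
                    ml.DamRecord(r.dam_id, r.matriline_id, sex, 1 - sex)
                )
        lp_binom = ml.log_posterior(state, records, spec)
        lp_bern = ml.log_posterior(state, per_offspring, spec)
        log_coeffs = sum(
            gammaln(r.total + 1)
            - gammaln(r.total_male + 1)
            - gammaln(r.total_female + 1)
            for r in records
        )
        assert lp_binom - lp_bern == pytest.approx(log_coeffs, rel=1e-10)

    def test_precision_prior_term_monotone_up_to_mode(self):
        records = flat_records(n_dams=4)
        spec = ml.MaternalModelSpec()
        # with all m = 0 the tau_m-dependent part is
        # (M/2 + a - 1) log(tau) - b tau, maximised at (M/2 + a - 1)/b
        mode = (4 / 2 + 0.1 - 1) / 0.1
        taus = np.linspace(0.05, mode, 12)
        lps = [
            ml.log_posterior(zero_state(records, tau_m=t), records, spec)
            for t in taus
        ]
        assert np.all(np.diff(lps) > 0)
        beyond = ml.log_posterior(
            zero_state(records, tau_m=mode * 3), records, spec
        )
        assert beyond < lps[-1]


class TestPsrf:
    def test_identical_long_chains_near_one(self):
        rng = np.random.default_rng(0)
        chain = rng.normal(size=2_000_000)
        value = ml.psrf(np.stack([chain, chain]))
        assert abs(value - 1.0) < 1e-6

    def test_disjoint_constant_chains_diverge(self):
        chains = np.stack([np.zeros(100) + 1e-9, np.ones(100)])
        chains[0, 0] = 1e-8  # avoid exactly-zero within-variance
        assert ml.psrf(chains) > 10

    def test_matches_hand_computed_formula(self):
        chains = np.array(
            [[1.0, 2.0, 3.0, 4.0, 5.0], [2.0, 3.0, 5.0, 7.0, 8.0]]
        )
        n = 5
        w = (np.var(chains[0], ddof=1) + np.var(chains[1], ddof=1)) / 2
        b_over_n = np.var([chains[0].mean(), chains[1].mean()], ddof=1)
        expected = np.sqrt(((n - 1) / n * w + b_over_n) / w)
        assert ml.psrf(chains) == pytest.approx(expected, rel=1e-12)

    def test_single_chain_rejected(self):
        with pytest.raises(CapabilityError):
            ml.psrf(np.ones((1, 10)))


def make_draws(values, names=("x",), thin=1, burn_in=0):
    values = np.asarray(values, dtype=float)
    if values.ndim == 2:
        values = values[:, :, None]
    return ChainDraws(names=list(names), values=values, thin=thin, burn_in=burn_in)


class TestSummarize:
    def test_constant_draws_degenerate_interval(self):
        draws = make_draws(np.full((2, 50), 3.25))
        summ = ml.summarize(draws, burn_in=10)
        assert summ.mean("x") == 3.25
        assert summ.ci("x") == (3.25, 3.25)

    def test_known_sequence_mean_and_quantiles(self):
        seq = np.arange(1.0, 101.0)
        draws = make_draws(np.stack([seq, seq]))
        summ = ml.summarize(draws, burn_in=0)
        assert summ.mean("x") == pytest.approx(50.5)
        lo, hi = summ.ci("x")
        # numpy's linear-interpolation quantile rule on the pooled draws
        pooled = np.concatenate([seq, seq])
        assert lo == pytest.approx(np.quantile(pooled, 0.025))
        assert hi == pytest.approx(np.quantile(pooled, 0.975))

    def test_sigma2_summarised_drawwise_not_one_over_mean(self):
        rng = np.random.default_rng(5)
        tau = rng.gamma(3.0, 1.0, size=(2, 400))
        values = np.stack([tau, 1.0 / tau], axis=2)
        draws = make_draws(values[:, :, 0])  # placeholder to reuse helper
        draws = ChainDraws(
            names=["tau_m", "sigma2_m"], values=values, thin=1, burn_in=0
        )
        summ = ml.summarize(draws, burn_in=0)
        drawwise = float(np.mean(1.0 / tau))
        jensen = 1.0 / float(np.mean(tau))
        assert summ.mean("sigma2_m") == pytest.approx(drawwise)
        assert abs(summ.mean("sigma2_m") - jensen) > 0.05  # Jensen gap is real

    def test_empty_post_burn_in_rejected(self):
        draws = make_draws(np.ones((2, 10)))
        with pytest.raises(ConfigurationError):
            ml.summarize(draws, burn_in=10)


class TestSampler:
    def test_determinism_same_seed(self, binomial_records_factory):
        rng = np.random.default_rng(8)
        records = binomial_records_factory(rng, n_matrilines=8)
        config = ml.McmcConfig(n_iterations=400, burn_in=100, seed=4)
        d1 = ml.run_chains(records, config=config)
        d2 = ml.run_chains(records, config=config)
        assert np.array_equal(d1.values, d2.values)
        d3 = ml.run_chains(records, config=ml.McmcConfig(
            n_iterations=400, burn_in=100, seed=5))
        assert not np.array_equal(d1.values, d3.values)

    def test_null_variance_recovery(self):
        rng = np.random.default_rng(12)
        males = rng.binomial(20, 0.5, size=200)
        records = [
            ml.DamRecord(f"d{i}", f"m{i}", int(k), 20 - int(k))
            for i, k in enumerate(males)
        ]
        res = ml.MaternalSexRatioModel(records).fit(
            ml.McmcConfig(n_iterations=4000, burn_in=1000, seed=2)
        )
        summ = res.summary()
        assert abs(summ.mean("mu")) < 0.1
        assert summ.mean("sigma2_m") < 0.1
        assert summ.table.loc["sigma2_m", "q97.5"] < 0.3

    def test_chains_mix_on_generative_data(self, binomial_records_factory):
        rng = np.random.default_rng(30)
        records = binomial_records_factory(rng, n_matrilines=40)
        res = ml.MaternalSexRatioModel(records).fit(
            ml.McmcConfig(n_iterations=6000, burn_in=1500, seed=9)
        )
        for name in ("mu", "sigma2_m", "sigma2_e"):
            assert res.psrf[name] < 1.1

    def test_geweke_style_stationarity(self, binomial_records_factory):
        rng = np.random.default_rng(31)
        records = binomial_records_factory(rng, n_matrilines=30)
        res = ml.MaternalSexRatioModel(records).fit(
            ml.McmcConfig(n_iterations=8000, burn_in=2000, seed=13)
        )
        for name in ("mu", "sigma2_m", "sigma2_e"):
            x = res.draws.post_burn_in(name).reshape(-1)
            head, tail = x[: x.size // 5], x[-x.size // 2:]
            se = np.hypot(batch_means_mcse(head), batch_means_mcse(tail))
            assert abs(head.mean() - tail.mean()) < 5 * se

    def test_location_sum_stable_across_prior_variance(self):
        # mu and the matriline effects are additively confounded; only the
        # priors separate them, so mu + mean(m) should not depend on how
        # vague the intercept prior is, while mu alone may drift.
        rng = np.random.default_rng(77)
        records = make_binomial_records(rng, n_matrilines=6, dams_per_matriline=2,
                                        n_offspring=25)
        sums = []
        for v0 in (100.0, 1000.0):
            spec = ml.MaternalModelSpec(prior_location_variance=v0)
            res = ml.MaternalSexRatioModel(records, spec=spec).fit(
                ml.McmcConfig(
                    n_iterations=8000, burn_in=2000, seed=3,
                    store_effect_draws=True,
                )
            )
            start = res.draws.stored_burn_in()
            mu = res.draws.values[:, start:, res.draws.names.index("mu")]
            m_bar = res.draws.m_draws[:, start:, :].mean(axis=2)
            combo = (mu + m_bar).reshape(-1)
            sums.append((combo.mean(), batch_means_mcse(combo)))
        (mean_a, se_a), (mean_b, se_b) = sums
        assert abs(mean_a - mean_b) < 4 * np.hypot(se_a, se_b)

    def test_sd_prior_parameterization_runs(self, binomial_records_factory):
        rng = np.random.default_rng(15)
        records = binomial_records_factory(rng, n_matrilines=15)
        spec = ml.MaternalModelSpec(prior_on="sd")
        res = ml.MaternalSexRatioModel(records, spec=spec).fit(
            ml.McmcConfig(n_iterations=3000, burn_in=1000, seed=6)
        )
        assert 0.0 < res.sigma2_m_mean < 5.0

    def test_sigma2_interval_coverage(self):
        # 95% equal-tailed interval for sigma2_m should cover the
        # generating value in the vast majority of replicates
        covered = 0
        n_reps = 100
        for rep in range(n_reps):
            rng = np.random.default_rng(1000 + rep)
            records = make_binomial_records(rng)
            res = ml.MaternalSexRatioModel(records).fit(
                ml.McmcConfig(n_iterations=2500, burn_in=500, seed=rep)
            )
            lo, hi = res.summary().ci("sigma2_m")
            covered += lo <= 0.64 <= hi
        assert covered >= 85
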