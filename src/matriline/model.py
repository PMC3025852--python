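"""Hierarchical logit-Bernoulli model of clutch sex ratio with a
maternally inherited variance component.

The model
---------
Let ``Y_i`` be the sex of adult offspring ``i`` (male = 1) and ``d(i)`` its
dam. Then ``Y_i ~ Bernoulli(pi_d)`` with

    logit(pi_d) = mu + x_d' beta + m_{matriline(d)} + e_d

where ``mu`` is the population average logit sex ratio, ``beta`` optional
fixed effects (infection status, treatment, ...), ``m`` a maternally
inherited effect shared by the whole matriline (a mother's effect equals
her daughters': strict maternal transmission collapses it to one value per
founding female), and ``e_d`` a dam-level residual effect. Priors:
``m ~ N(0, sigma2_m)``, ``e ~ N(0, sigma2_e)``, vague normals on ``mu`` and
``beta``, and Gamma(0.1, 0.1) on the precisions ``tau = 1/sigma2``
(optionally on the standard deviations instead).

Because each dam record enters exactly one matriline and one dam effect,
the full conditionals of all ``m`` (and of all ``e``) factorise; the
sampler therefore proposes every matriline (dam) effect simultaneously
with independent random-walk Metropolis moves and accepts element-wise,
which is what makes two chains of 12,000 iterations cheap. Precisions use
their conjugate Gamma full conditionals. Proposal scales adapt only during
burn-in (targeting ~30% acceptance) and are frozen afterwards so the
post-burn-in kernel satisfies detailed balance.

Since offspring within a dam are exchangeable, the per-offspring Bernoulli
likelihood is collapsed to a dam-level binomial; the two differ only by
the constant log binomial coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, gammaln, logit

from .errors import (
    CapabilityError,
    ConfigurationError,
    DomainError,
    StateConsistencyError,
)
from .pedigree import DamRecord

__all__ = [
    "ParameterState",
    "MaternalModelSpec",
    "McmcConfig",
    "PosteriorSummary",
    "ChainDraws",
    "MaternalSexRatioModel",
    "MaternalSexRatioResults",
    "logit_sexratio",
    "log_posterior",
    "run_chains",
    "summarize",
    "psrf",
    "batch_means_mcse",
    "encode_covariate_value",
]

_PROB_EPS = 1e-12


# --------------------------------------------------------------------------
# parameter containers


@dataclass
class ParameterState:
    """One point in parameter space.

    ``m`` maps matriline id -> maternally inherited logit effect, ``e``
    maps dam id -> residual logit effect. ``tau_m`` and ``tau_e`` are the
    precisions 1/sigma2_m and 1/sigma2_e.
    """

    mu: float
    beta: dict[str, float] = field(default_factory=dict)
    m: dict[str, float] = field(default_factory=dict)
    e: dict[str, float] = field(default_factory=dict)
    tau_m: float = 1.0
    tau_e: float = 1.0

    def __post_init__(self) -> None:
        if not self.tau_m > 0 or not self.tau_e > 0:
            raise DomainError("precisions tau_m and tau_e must be > 0")

    @property
    def sigma2_m(self) -> float:
        return 1.0 / self.tau_m

    @property
    def sigma2_e(self) -> float:
        return 1.0 / self.tau_e


@dataclass
class MaternalModelSpec:
    """Structural and prior choices for the model.

    ``prior_on`` selects where the Gamma(a, b) prior sits: on the
    precisions (default, the WinBUGS convention) or on the standard
    deviations. ``fixed_tau_m`` / ``fixed_tau_e`` pin a precision instead
    of sampling it (used when validating against the quadrature oracle).
    ``dam_effect=False`` drops the e-level entirely.
    """

    covariates: tuple[str, ...] = ()
    prior_location_variance: float = 1000.0
    prior_shape: float = 0.1
    prior_rate: float = 0.1
    prior_on: str = "precision"  # "precision" | "sd"
    dam_effect: bool = True
    fixed_tau_m: Optional[float] = None
    fixed_tau_e: Optional[float] = None

    def __post_init__(self) -> None:
        if self.prior_shape <= 0 or self.prior_rate <= 0:
            raise ConfigurationError("gamma prior shape and rate must be > 0")
        if self.prior_location_variance <= 0:
            raise ConfigurationError("prior_location_variance must be > 0")
        if self.prior_on not in ("precision", "sd"):
            raise ConfigurationError("prior_on must be 'precision' or 'sd'")
        self.covariates = tuple(self.covariates)


@dataclass
class McmcConfig:
    """Sampler settings; defaults follow the original analysis
    (2 chains, 12,000 iterations, the first 2,000 discarded)."""

    n_chains: int = 2
    n_iterations: int = 12000
    burn_in: int = 2000
    thin: int = 1
    seed: int = 0
    scale_m: float = 0.6
    scale_e: float = 0.6
    scale_mu: float = 0.15
    scale_beta: float = 0.25
    scale_log_sigma: float = 0.3
    adapt_during_burn_in: bool = True
    store_effect_draws: bool = False

    def __post_init__(self) -> None:
        if self.burn_in >= self.n_iterations:
            raise ConfigurationError("burn_in must be < n_iterations")
        if self.n_chains < 1:
            raise ConfigurationError("need at least one chain")
        if self.thin < 1:
            raise ConfigurationError("thin must be >= 1")


@dataclass
class PosteriorSummary:
    """Per-parameter posterior mean, sd, equal-tailed 95% interval and
    potential scale reduction factor, as a DataFrame in ``table``."""

    table: pd.DataFrame

    def mean(self, param: str) -> float:
        return float(self.table.loc[param, "mean"])

    def sd(self, param: str) -> float:
        return float(self.table.loc[param, "sd"])

    def ci(self, param: str) -> tuple[float, float]:
        row = self.table.loc[param]
        return float(row["q2.5"]), float(row["q97.5"])

    def __str__(self) -> str:
        return self.table.to_string(float_format=lambda v: f"{v:10.4f}")


@dataclass
class ChainDraws:
    """Raw MCMC output: ``values[chain, stored_iteration, parameter]``.

    Iteration ``k`` of the stored axis corresponds to sampler iteration
    ``k * thin``. Effect draws (one column per matriline / dam) are stored
    only when requested. ``m_mean`` / ``e_mean`` are post-burn-in posterior
    means of the effects accumulated during sampling.
    """

    names: list[str]
    values: np.ndarray
    thin: int
    burn_in: int
    m_names: list[str] = field(default_factory=list)
    e_names: list[str] = field(default_factory=list)
    m_draws: Optional[np.ndarray] = None
    e_draws: Optional[np.ndarray] = None
    m_mean: dict[str, float] = field(default_factory=dict)
    e_mean: dict[str, float] = field(default_factory=dict)
    acceptance: dict[str, float] = field(default_factory=dict)

    @property
    def n_chains(self) -> int:
        return self.values.shape[0]

    def stored_burn_in(self) -> int:
        return int(np.ceil(self.burn_in / self.thin))

    def post_burn_in(self, param: str) -> np.ndarray:
        """Post-burn-in draws of one parameter, shape (n_chains, n_kept)."""
        j = self.names.index(param)
        return self.values[:, self.stored_burn_in():, j]


# --------------------------------------------------------------------------
# covariate encoding


def encode_covariate_value(value) -> float:
    """Coerce a covariate value to a float regressor.

    Infection statuses encode as pos = 1, neg = 0; booleans and numerics
    pass through. Untested / missing values are rejected.
    """
    if isinstance(value, bool):
        return float(value)
    if isinstance(value, (int, float, np.integer, np.floating)):
        if isinstance(value, float) and np.isnan(value):
            raise DomainError("covariate value is NaN")
        return float(value)
    if isinstance(value, str):
        lowered = value.lower()
        if lowered in ("pos", "positive", "infected", "true", "yes"):
            return 1.0
        if lowered in ("neg", "negative", "uninfected", "false", "no"):
            return 0.0
        if lowered in ("na", "untested", ""):
            raise DomainError(f"covariate value {value!r} is missing/untested")
        try:
            return float(value)
        except ValueError:
            raise DomainError(f"cannot encode covariate value {value!r}") from None
    raise DomainError(f"cannot encode covariate value {value!r}")


def _record_x(record: DamRecord, covariates: Sequence[str]) -> np.ndarray:
    xs = []
    for name in covariates:
        if name not in record.covariates:
            raise StateConsistencyError(
                f"dam {record.dam_id!r} lacks covariate {name!r}"
            )
        xs.append(encode_covariate_value(record.covariates[name]))
    return np.asarray(xs, dtype=float)


# --------------------------------------------------------------------------
# pointwise operations


def logit_sexratio(
    state: ParameterState,
    record: DamRecord,
    covariates: Sequence[str] = (),
) -> float:
    """Expected proportion of sons for one dam record under ``state``.

    Returns ``expit(mu + x'beta + m[matriline] + e[dam])``, guarded away
    from exactly 0 or 1.
    """
    if record.matriline_id not in state.m:
        raise StateConsistencyError(
            f"state has no matriline effect for {record.matriline_id!r}"
        )
    eta = state.mu + state.m[record.matriline_id]
    if state.e:
        if record.dam_id not in state.e:
            raise StateConsistencyError(
                f"state has no dam effect for {record.dam_id!r}"
            )
        eta += state.e[record.dam_id]
    names = tuple(covariates) if covariates else tuple(state.beta)
    for name in names:
        if name not in state.beta:
            raise StateConsistencyError(f"state has no coefficient {name!r}")
        eta += state.beta[name] * encode_covariate_value(record.covariates[name])
    return float(np.clip(expit(eta), _PROB_EPS, 1.0 - _PROB_EPS))


def _gamma_logpdf(x: float, shape: float, rate: float) -> float:
    return float(
        shape * np.log(rate) - gammaln(shape) + (shape - 1.0) * np.log(x) - rate * x
    )


def log_posterior(
    state: ParameterState,
    records: Iterable[DamRecord],
    spec: MaternalModelSpec,
) -> float:
    """Log joint density: binomial likelihood over dam records plus all
    effect and hyper priors. Finite for any valid state."""
    lp = 0.0
    for record in records:
        if record.excluded or record.total == 0:
            continue
        pi = logit_sexratio(state, record, spec.covariates)
        k, n = record.total_male, record.total
        lp += (
            gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
            + k * np.log(pi) + (n - k) * np.log1p(-pi)
        )
    m = np.asarray(list(state.m.values()), dtype=float)
    lp += float(
        0.5 * m.size * np.log(state.tau_m / (2 * np.pi))
        - 0.5 * state.tau_m * np.sum(m**2)
    )
    if spec.dam_effect and state.e:
        e = np.asarray(list(state.e.values()), dtype=float)
        lp += float(
            0.5 * e.size * np.log(state.tau_e / (2 * np.pi))
            - 0.5 * state.tau_e * np.sum(e**2)
        )
    v0 = spec.prior_location_variance
    lp += -0.5 * np.log(2 * np.pi * v0) - 0.5 * state.mu**2 / v0
    for coef in state.beta.values():
        lp += -0.5 * np.log(2 * np.pi * v0) - 0.5 * coef**2 / v0
    a, b = spec.prior_shape, spec.prior_rate
    if spec.fixed_tau_m is None:
        if spec.prior_on == "precision":
            lp += _gamma_logpdf(state.tau_m, a, b)
        else:
            sigma = state.tau_m ** -0.5
            lp += _gamma_logpdf(sigma, a, b)
    if spec.dam_effect and spec.fixed_tau_e is None:
        if spec.prior_on == "precision":
            lp += _gamma_logpdf(state.tau_e, a, b)
        else:
            sigma = state.tau_e ** -0.5
            lp += _gamma_logpdf(sigma, a, b)
    return float(lp)


# --------------------------------------------------------------------------
# sampler


class _FitData:
    """Records flattened to aligned arrays for the vectorized sampler."""

    def __init__(self, records: Sequence[DamRecord], spec: MaternalModelSpec):
        usable = [r for r in records if not r.excluded and r.total > 0]
        if not usable:
            raise DomainError("no dam records with sexed adult offspring")
        self.records = usable
        self.mat_names = sorted({r.matriline_id for r in usable})
        self.dam_names = sorted({r.dam_id for r in usable})
        mat_index = {name: i for i, name in enumerate(self.mat_names)}
        dam_index = {name: i for i, name in enumerate(self.dam_names)}
        self.k = np.array([r.total_male for r in usable], dtype=float)
        self.n = np.array([r.total for r in usable], dtype=float)
        self.mat_idx = np.array([mat_index[r.matriline_id] for r in usable])
        self.dam_idx = np.array([dam_index[r.dam_id] for r in usable])
        if spec.covariates:
            self.X = np.vstack([_record_x(r, spec.covariates) for r in usable])
            for j, name in enumerate(spec.covariates):
                if np.ptp(self.X[:, j]) == 0:
                    raise DomainError(
                        f"covariate {name!r} is constant across records"
                    )
        else:
            self.X = np.zeros((len(usable), 0))
        self.n_mat = len(self.mat_names)
        self.n_dam = len(self.dam_names)
        self.k_total = float(self.k.sum())
        self.n_total = float(self.n.sum())


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def _run_single_chain(
    data: _FitData,
    spec: MaternalModelSpec,
    config: McmcConfig,
    rng: np.random.Generator,
    chain_index: int,
) -> dict:
    M, D = data.n_mat, data.n_dam
    p = data.X.shape[1]
    a, b = spec.prior_shape, spec.prior_rate
    v0 = spec.prior_location_variance
    use_e = spec.dam_effect

    # over-dispersed start: empirical-logit centre plus chain-specific jitter
    pooled = data.k_total / data.n_total
    mu = float(logit(np.clip(pooled, 0.02, 0.98))) + rng.normal(0.0, 0.5)
    beta = rng.normal(0.0, 0.5, p)
    m = rng.normal(0.0, 0.5, M)
    e = rng.normal(0.0, 0.5, D) if use_e else np.zeros(D)
    tau_m = spec.fixed_tau_m if spec.fixed_tau_m is not None else 1.0
    tau_e = spec.fixed_tau_e if spec.fixed_tau_e is not None else 1.0
    log_sigma_m = -0.5 * np.log(tau_m)
    log_sigma_e = -0.5 * np.log(tau_e)

    scale_m = np.full(M, config.scale_m)
    scale_e = np.full(D, config.scale_e)
    scale_mu = config.scale_mu
    scale_beta = np.full(p, config.scale_beta)
    scale_ls = config.scale_log_sigma

    eta = mu + data.X @ beta + m[data.mat_idx] + e[data.dam_idx]
    if not np.all(np.isfinite(eta)):
        raise ConfigurationError(
            "non-finite linear predictor at the initial state; "
            f"mu={mu}, chain={chain_index}"
        )

    kept = (config.n_iterations + config.thin - 1) // config.thin
    names = (
        ["mu"]
        + [f"beta[{name}]" for name in spec.covariates]
        + ["tau_m", "tau_e", "sigma2_m", "sigma2_e"]
    )
    out = np.empty((kept, len(names)))
    m_draws = np.empty((kept, M)) if config.store_effect_draws else None
    e_draws = np.empty((kept, D)) if config.store_effect_draws and use_e else None
    m_sum = np.zeros(M)
    e_sum = np.zeros(D)
    n_post = 0

    acc_m = np.zeros(M)
    acc_e = np.zeros(D)
    acc_mu = 0.0
    acc_beta = np.zeros(p)
    win_m = np.zeros(M)
    win_e = np.zeros(D)
    win_mu = 0.0
    win_beta = np.zeros(p)
    window = 50
    post_iters = 0

    sp_eta = _softplus(eta)
    for t in range(config.n_iterations):
        in_burn = t < config.burn_in

        # (1) matriline effects: independent element-wise Metropolis
        dm = rng.normal(0.0, 1.0, M) * scale_m
        eta_prop = eta + dm[data.mat_idx]
        sp_prop = _softplus(eta_prop)
        d_rec = data.k * dm[data.mat_idx] - data.n * (sp_prop - sp_eta)
        d_mat = np.bincount(data.mat_idx, weights=d_rec, minlength=M)
        d_prior = -0.5 * tau_m * ((m + dm) ** 2 - m**2)
        acc = np.log(rng.random(M)) < d_mat + d_prior
        step = np.where(acc, dm, 0.0)
        m += step
        eta += step[data.mat_idx]
        sp_eta = _softplus(eta)
        win_m += acc

        # (2) dam effects
        if use_e:
            de = rng.normal(0.0, 1.0, D) * scale_e
            eta_prop = eta + de[data.dam_idx]
            sp_prop = _softplus(eta_prop)
            d_rec = data.k * de[data.dam_idx] - data.n * (sp_prop - sp_eta)
            d_dam = np.bincount(data.dam_idx, weights=d_rec, minlength=D)
            d_prior = -0.5 * tau_e * ((e + de) ** 2 - e**2)
            acc = np.log(rng.random(D)) < d_dam + d_prior
            step = np.where(acc, de, 0.0)
            e += step
            eta += step[data.dam_idx]
            sp_eta = _softplus(eta)
            win_e += acc

        # (3) intercept and fixed effects: scalar Metropolis each
        dmu = rng.normal(0.0, scale_mu)
        sp_prop = _softplus(eta + dmu)
        delta = (
            data.k_total * dmu
            - float(np.sum(data.n * (sp_prop - sp_eta)))
            - 0.5 * ((mu + dmu) ** 2 - mu**2) / v0
        )
        if np.log(rng.random()) < delta:
            mu += dmu
            eta += dmu
            sp_eta = sp_prop
            win_mu += 1.0
        for j in range(p):
            dbj = rng.normal(0.0, scale_beta[j])
            xj = data.X[:, j]
            sp_prop = _softplus(eta + dbj * xj)
            delta = (
                dbj * float(np.sum(data.k * xj))
                - float(np.sum(data.n * (sp_prop - sp_eta)))
                - 0.5 * ((beta[j] + dbj) ** 2 - beta[j] ** 2) / v0
            )
            if np.log(rng.random()) < delta:
                beta[j] += dbj
                eta += dbj * xj
                sp_eta = sp_prop
                win_beta[j] += 1.0

        # (4) precisions
        if spec.fixed_tau_m is None:
            if spec.prior_on == "precision":
                tau_m = rng.gamma(a + 0.5 * M, 1.0 / (b + 0.5 * float(m @ m)))
            else:
                ls_prop = log_sigma_m + rng.normal(0.0, scale_ls)
                delta = _log_sigma_target(ls_prop, m, a, b) - _log_sigma_target(
                    log_sigma_m, m, a, b
                )
                if np.log(rng.random()) < delta:
                    log_sigma_m = ls_prop
                tau_m = float(np.exp(-2.0 * log_sigma_m))
        if use_e and spec.fixed_tau_e is None:
            if spec.prior_on == "precision":
                tau_e = rng.gamma(a + 0.5 * D, 1.0 / (b + 0.5 * float(e @ e)))
            else:
                ls_prop = log_sigma_e + rng.normal(0.0, scale_ls)
                delta = _log_sigma_target(ls_prop, e, a, b) - _log_sigma_target(
                    log_sigma_e, e, a, b
                )
                if np.log(rng.random()) < delta:
                    log_sigma_e = ls_prop
                tau_e = float(np.exp(-2.0 * log_sigma_e))

        # burn-in-only adaptation toward ~30% acceptance
        if in_burn and config.adapt_during_burn_in and (t + 1) % window == 0:
            rate_m = win_m / window
            scale_m = np.clip(scale_m * np.exp(0.66 * (rate_m - 0.3)), 1e-3, 10.0)
            if use_e:
                rate_e = win_e / window
                scale_e = np.clip(
                    scale_e * np.exp(0.66 * (rate_e - 0.3)), 1e-3, 10.0
                )
            scale_mu = float(
                np.clip(scale_mu * np.exp(0.66 * (win_mu / window - 0.3)), 1e-3, 10.0)
            )
            if p:
                scale_beta = np.clip(
                    scale_beta * np.exp(0.66 * (win_beta / window - 0.3)),
                    1e-3,
                    10.0,
                )
            win_m[:] = 0.0
            win_e[:] = 0.0
            win_mu = 0.0
            win_beta[:] = 0.0
        if not in_burn:
            acc_m += win_m
            acc_e += win_e
            acc_mu += win_mu
            acc_beta += win_beta
            win_m[:] = 0.0
            win_e[:] = 0.0
            win_mu = 0.0
            win_beta[:] = 0.0
            post_iters += 1
            m_sum += m
            e_sum += e
            n_post += 1

        if t % config.thin == 0:
            s = t // config.thin
            row = [mu] + list(beta) + [tau_m, tau_e, 1.0 / tau_m, 1.0 / tau_e]
            out[s] = row
            if m_draws is not None:
                m_draws[s] = m
            if e_draws is not None:
                e_draws[s] = e

    denom = max(post_iters, 1)
    acceptance = {
        "m": float(np.mean(acc_m)) / denom,
        "e": float(np.mean(acc_e)) / denom if use_e else float("nan"),
        "mu": acc_mu / denom,
    }
    if p:
        acceptance["beta"] = float(np.mean(acc_beta)) / denom
    return {
        "names": names,
        "values": out,
        "m_draws": m_draws,
        "e_draws": e_draws,
        "m_mean": m_sum / max(n_post, 1),
        "e_mean": e_sum / max(n_post, 1),
        "acceptance": acceptance,
    }


def _log_sigma_target(
    log_sigma: float, effects: np.ndarray, a: float, b: float
) -> float:
    sigma = np.exp(log_sigma)
    n = effects.size
    return float(
        -n * log_sigma
        - 0.5 * float(effects @ effects) / sigma**2
        + (a - 1.0) * log_sigma
        - b * sigma
        + log_sigma  # Jacobian of the log transform
    )


def run_chains(
    records: Sequence[DamRecord],
    spec: Optional[MaternalModelSpec] = None,
    config: Optional[McmcConfig] = None,
) -> ChainDraws:
    """Run independent MCMC chains and collect scalar parameter draws.

    Per iteration the blocks update in fixed order: matriline effects,
    dam effects, intercept + fixed effects, precisions. Chains differ only
    in their substream of the master seed and their over-dispersed starting
    values; identical data + config + seed reproduce draws exactly.
    """
    spec = spec or MaternalModelSpec()
    config = config or McmcConfig()
    data = _FitData(records, spec)
    chains = []
    for c in range(config.n_chains):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=config.seed, spawn_key=(c,))
        )
        chains.append(_run_single_chain(data, spec, config, rng, c))
    values = np.stack([ch["values"] for ch in chains])
    draws = ChainDraws(
        names=chains[0]["names"],
        values=values,
        thin=config.thin,
        burn_in=config.burn_in,
        m_names=data.mat_names,
        e_names=data.dam_names,
        m_draws=np.stack([ch["m_draws"] for ch in chains])
        if config.store_effect_draws
        else None,
        e_draws=np.stack([ch["e_draws"] for ch in chains])
        if config.store_effect_draws and spec.dam_effect
        else None,
        m_mean={
            name: float(np.mean([ch["m_mean"][i] for ch in chains]))
            for i, name in enumerate(data.mat_names)
        },
        e_mean={
            name: float(np.mean([ch["e_mean"][i] for ch in chains]))
            for i, name in enumerate(data.dam_names)
        },
        acceptance={
            key: float(np.mean([ch["acceptance"][key] for ch in chains]))
            for key in chains[0]["acceptance"]
        },
    )
    return draws


# --------------------------------------------------------------------------
# summaries and diagnostics


def psrf(chains: np.ndarray) -> float:
    """Gelman-Rubin potential scale reduction factor.

    ``chains`` has shape (n_chains, n_draws). Uses the classic formula:
    with within-chain variance W and between-chain variance B,
    ``PSRF = sqrt(((n-1)/n W + B/n) / W)``. Values near 1 indicate the
    chains have mixed.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2:
        raise CapabilityError("psrf needs >= 2 chains of equal length")
    n = chains.shape[1]
    if n < 2:
        raise CapabilityError("psrf needs >= 2 draws per chain")
    means = chains.mean(axis=1)
    w = float(np.mean(chains.var(axis=1, ddof=1)))
    b_over_n = float(np.var(means, ddof=1))
    if w == 0.0:
        return 1.0 if b_over_n == 0.0 else float("inf")
    var_hat = (n - 1) / n * w + b_over_n
    return float(np.sqrt(var_hat / w))


def summarize(draws: ChainDraws, burn_in: Optional[int] = None) -> PosteriorSummary:
    """Pool post-burn-in draws across chains into a posterior summary.

    Variance components are summarised from the draw-wise transformed
    ``sigma2 = 1/tau`` samples (never as 1/mean(tau)). Quantiles use
    numpy's default linear interpolation.
    """
    burn_in = draws.burn_in if burn_in is None else burn_in
    start = int(np.ceil(burn_in / draws.thin))
    if start >= draws.values.shape[1]:
        raise ConfigurationError("burn-in leaves no post-burn-in draws")
    rows = {}
    for j, name in enumerate(draws.names):
        per_chain = draws.values[:, start:, j]
        pooled = per_chain.reshape(-1)
        rows[name] = {
            "mean": float(np.mean(pooled)),
            "sd": float(np.std(pooled, ddof=1)) if pooled.size > 1 else 0.0,
            "q2.5": float(np.quantile(pooled, 0.025)),
            "q97.5": float(np.quantile(pooled, 0.975)),
            "psrf": psrf(per_chain) if draws.n_chains >= 2 else float("nan"),
        }
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "parameter"
    return PosteriorSummary(table=table)


def batch_means_mcse(x: np.ndarray, n_batches: int = 25) -> float:
    """Monte-Carlo standard error of a chain mean by batch means."""
    x = np.asarray(x, dtype=float).reshape(-1)
    n_batches = min(n_batches, max(2, x.size // 2))
    usable = (x.size // n_batches) * n_batches
    batches = x[:usable].reshape(n_batches, -1).mean(axis=1)
    return float(np.std(batches, ddof=1) / np.sqrt(n_batches))


# --------------------------------------------------------------------------
# model / results facade


class MaternalSexRatioModel:
    """Hierarchical logit-Bernoulli sex-ratio model over dam records.

    Parameters
    ----------
    records : sequence of DamRecord
        One pooled binomial record per dam (see ``aggregate_dams``).
        Records flagged ``excluded`` or with zero sexed adults are dropped.
    spec : MaternalModelSpec, optional
        Priors, covariates and structural switches.
    """

    def __init__(
        self,
        records: Sequence[DamRecord],
        spec: Optional[MaternalModelSpec] = None,
    ) -> None:
        self.spec = spec or MaternalModelSpec()
        self.records = [r for r in records if not r.excluded and r.total > 0]
        if not self.records:
            raise DomainError("no usable dam records")
        # fail fast on malformed covariates
        _FitData(self.records, self.spec)

    @classmethod
    def from_pedigree(
        cls,
        pedigree,
        covariates: Sequence[str] = (),
        spec: Optional[MaternalModelSpec] = None,
    ) -> "MaternalSexRatioModel":
        from .pedigree import aggregate_dams

        if spec is None:
            spec = MaternalModelSpec(covariates=tuple(covariates))
        elif covariates:
            spec = replace(spec, covariates=tuple(covariates))
        return cls(aggregate_dams(pedigree), spec=spec)

    def log_posterior(self, state: ParameterState) -> float:
        return log_posterior(state, self.records, self.spec)

    def fit(self, config: Optional[McmcConfig] = None) -> "MaternalSexRatioResults":
        config = config or McmcConfig()
        draws = run_chains(self.records, self.spec, config)
        return MaternalSexRatioResults(self, config, draws)


class MaternalSexRatioResults:
    """Fitted-model container: draws, summaries, diagnostics."""

    def __init__(
        self,
        model: MaternalSexRatioModel,
        config: McmcConfig,
        draws: ChainDraws,
    ) -> None:
        self.model = model
        self.config = config
        self.draws = draws
        self._summary: Optional[PosteriorSummary] = None

    def summary(self) -> PosteriorSummary:
        if self._summary is None:
            self._summary = summarize(self.draws, self.config.burn_in)
        return self._summary

    @property
    def psrf(self) -> dict[str, float]:
        return {
            name: float(self.summary().table.loc[name, "psrf"])
            for name in self.draws.names
        }

    @property
    def sigma2_m_mean(self) -> float:
        return self.summary().mean("sigma2_m")

    @property
    def sigma2_e_mean(self) -> float:
        return self.summary().mean("sigma2_e")

    @property
    def m_posterior_mean(self) -> dict[str, float]:
        return self.draws.m_mean

    @property
    def e_posterior_mean(self) -> dict[str, float]:
        return self.draws.e_mean

    def posterior_mean_state(self) -> ParameterState:
        """Posterior means packed into a ParameterState (point summary)."""
        summ = self.summary()
        beta = {
            name: summ.mean(f"beta[{name}]") for name in self.model.spec.covariates
        }
        return ParameterState(
            mu=summ.mean("mu"),
            beta=beta,
            m=dict(self.draws.m_mean),
            e=dict(self.draws.e_mean),
            tau_m=1.0 / summ.mean("sigma2_m"),
            tau_e=1.0 / summ.mean("sigma2_e"),
        )

    def mcse(self, param: str) -> float:
        """Monte-Carlo standard error of the posterior-mean estimate of
        ``param`` (batch means per chain, combined across chains)."""
        per_chain = self.draws.post_burn_in(param)
        ses = [batch_means_mcse(chain) for chain in per_chain]
        return float(np.sqrt(np.sum(np.square(ses))) / len(ses))

    def effect_mean_and_mcse(self, kind: str, name: str) -> tuple[float, float]:
        """Posterior mean and MC s.e. for one matriline ('m') or dam ('e')
        effect; requires ``store_effect_draws=True`` at fit time."""
        draws = self.draws.m_draws if kind == "m" else self.draws.e_draws
        names = self.draws.m_names if kind == "m" else self.draws.e_names
        if draws is None:
            raise CapabilityError(
                "effect draws were not stored; fit with store_effect_draws=True"
            )
        j = names.index(name)
        start = self.draws.stored_burn_in()
        per_chain = draws[:, start:, j]
        mean = float(per_chain.mean())
        ses = [batch_means_mcse(chain) for chain in per_chain]
        se = float(np.sqrt(np.sum(np.square(ses))) / len(ses))
        return mean, se

    def draws_long(self) -> pd.DataFrame:
        """All stored draws in long format (chain, iteration, parameter,
        value), the on-disk interchange layout."""
        frames = []
        kept = self.draws.values.shape[1]
        iters = np.arange(kept) * self.draws.thin
        for c in range(self.draws.n_chains):
            for j, name in enumerate(self.draws.names):
                frames.append(
                    pd.DataFrame(
                        {
                            "chain": c,
                            "iteration": iters,
                            "parameter": name,
                            "value": self.draws.values[c, :, j],
                        }
                    )
                )
        return pd.concat(frames, ignore_index=True)

    def plot_trace(self, params: Optional[Sequence[str]] = None, path=None):
        """Optional trace plots (matplotlib imported lazily)."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        params = list(params or ["mu", "sigma2_m", "sigma2_e"])
        fig, axes = plt.subplots(len(params), 1, figsize=(8, 2.2 * len(params)))
        if len(params) == 1:
            axes = [axes]
        kept = self.draws.values.shape[1]
        iters = np.arange(kept) * self.draws.thin
        for ax, name in zip(axes, params):
            j = self.draws.names.index(name)
            for c in range(self.draws.n_chains):
                ax.plot(iters, self.draws.values[c, :, j], lw=0.5)
            ax.set_ylabel(name)
        axes[-1].set_xlabel("iteration")
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=100)
            plt.close(fig)
        return fig
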