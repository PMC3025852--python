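"""Downstream endosymbiont statistics.

Covers the inference steps that surround the hierarchical model: the
clutch-size / sex-ratio weighted correlation, sex- and population-level
prevalence comparisons (Fisher's exact test), the expected-infected-male
accounting, the exact binomial test against that expectation, a Bayesian
group contrast of sex ratio by a binary covariate, and the brood-size
diagnostic that separates male killing (broods roughly halved) from
feminization (broods untouched).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

from .errors import ConfigurationError, DomainError, UndefinedValueError
from .model import (
    MaternalModelSpec,
    MaternalSexRatioModel,
    MaternalSexRatioResults,
    McmcConfig,
)
from .pedigree import DamRecord

__all__ = [
    "ContingencyTable2x2",
    "PrevalenceScenario",
    "GroupContrastResult",
    "MechanismDiagnostic",
    "weighted_pearson",
    "fisher_exact",
    "exact_binomial_test",
    "expected_male_infection",
    "group_sexratio_contrast",
    "clutch_size_mechanism_diagnostic",
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts with rows = sex and columns = infected / uninfected."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise DomainError("contingency counts must be >= 0")
        if self.a + self.b + self.c + self.d == 0:
            raise DomainError("contingency table is empty")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


@dataclass(frozen=True)
class PrevalenceScenario:
    """Inputs to the infected-male accounting: the fraction of females
    infected and the sex ratios their broods produce."""

    prevalence: float
    sr_infected: float
    sr_uninfected: float

    def __post_init__(self) -> None:
        for name in ("prevalence", "sr_infected", "sr_uninfected"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise DomainError(f"{name} must be in [0,1]")


def weighted_pearson(
    sizes: Sequence[float],
    ratios: Sequence[float],
    weights: Optional[Sequence[float]] = None,
) -> float:
    """Weighted Pearson correlation of clutch size and clutch sex ratio.

    Weights default to the clutch sizes, down-weighting the noisy sex-ratio
    estimates of small clutches. Weighted means/variances/covariance are
    used throughout; with equal weights this reduces to the ordinary
    Pearson correlation.
    """
    x = np.asarray(sizes, dtype=float)
    y = np.asarray(ratios, dtype=float)
    w = x.copy() if weights is None else np.asarray(weights, dtype=float)
    if x.size != y.size or x.size != w.size:
        raise DomainError("sizes, ratios and weights must have equal length")
    if x.size < 3:
        raise DomainError("need at least 3 clutches")
    if np.any(w <= 0):
        raise DomainError("weights must be > 0")
    w = w / w.sum()
    mx = float(w @ x)
    my = float(w @ y)
    cov = float(w @ ((x - mx) * (y - my)))
    vx = float(w @ (x - mx) ** 2)
    vy = float(w @ (y - my) ** 2)
    if vx == 0.0 or vy == 0.0:
        raise UndefinedValueError(
            "weighted correlation undefined: zero weighted variance"
        )
    r = cov / np.sqrt(vx * vy)
    return float(np.clip(r, -1.0, 1.0))


def fisher_exact(table: ContingencyTable2x2) -> float:
    """Two-sided Fisher exact p-value for a 2x2 table.

    Sums hypergeometric probabilities of all tables with the observed
    margins whose point probability does not exceed the observed one
    (the minimum-likelihood rule). A zero margin carries no information:
    p = 1 by convention, with a warning.
    """
    arr = table.as_array()
    if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
        warnings.warn(
            "2x2 table has a zero margin; Fisher exact p-value set to 1",
            stacklevel=2,
        )
        return 1.0
    p = float(sps.fisher_exact(arr, alternative="two-sided")[1])
    return min(p, 1.0)


def exact_binomial_test(
    k: int, n: int, p0: float, alternative: str = "two-sided"
) -> float:
    """Exact binomial tail test of ``k`` successes in ``n`` trials.

    ``alternative`` is ``"two-sided"``, ``"greater"``, ``"less"``, or
    ``"two-sided-doubled"``. Two-sided uses the minimum-likelihood rule
    (sum point probabilities <= that of ``k``); the doubled variant takes
    twice the smaller tail, capped at 1 — both conventions appear in the
    literature and can disagree near the threshold.
    """
    if not 0 <= k <= n:
        raise DomainError("need 0 <= k <= n")
    if not 0.0 <= p0 <= 1.0:
        raise DomainError("p0 must be in [0,1]")
    if alternative == "two-sided-doubled":
        lower = float(sps.binom.cdf(k, n, p0))
        upper = float(sps.binom.sf(k - 1, n, p0))
        return min(1.0, 2.0 * min(lower, upper))
    if alternative not in ("two-sided", "greater", "less"):
        raise ConfigurationError(f"unknown alternative {alternative!r}")
    return float(sps.binomtest(k, n, p0, alternative=alternative).pvalue)


def expected_male_infection(
    scenario: PrevalenceScenario,
) -> tuple[float, float, float]:
    """Expected fractions of (male & infected), (male & uninfected) and the
    implied proportion of males that are infected.

    With female infection prevalence ``p`` and brood sex ratios ``s1``
    (infected mothers) and ``s0`` (uninfected): males inherit their
    mother's infection class, so the male-and-infected fraction is
    ``p * s1``, the male-and-uninfected fraction ``(1-p) * s0``, and the
    infected share among males their ratio.
    """
    frac_inf = scenario.prevalence * scenario.sr_infected
    frac_uninf = (1.0 - scenario.prevalence) * scenario.sr_uninfected
    if frac_inf + frac_uninf == 0.0:
        raise UndefinedValueError(
            "no males produced under this scenario; proportion undefined"
        )
    return frac_inf, frac_uninf, frac_inf / (frac_inf + frac_uninf)


@dataclass
class GroupContrastResult:
    """Posterior contrast of sex ratio between two covariate groups."""

    covariate: str
    beta_mean: float
    beta_ci: tuple[float, float]
    group0_ratio: float
    group0_ci: tuple[float, float]
    group1_ratio: float
    group1_ci: tuple[float, float]
    results: MaternalSexRatioResults

    @property
    def beta_excludes_zero(self) -> bool:
        return self.beta_ci[0] > 0.0 or self.beta_ci[1] < 0.0

    def group_differs_from_half(self, group: int) -> bool:
        lo, hi = self.group0_ci if group == 0 else self.group1_ci
        return lo > 0.5 or hi < 0.5


def group_sexratio_contrast(
    records: Sequence[DamRecord],
    covariate: str,
    spec: Optional[MaternalModelSpec] = None,
    config: Optional[McmcConfig] = None,
) -> GroupContrastResult:
    """Fit the hierarchical model with one binary fixed effect and report
    the coefficient plus each group's expected sex ratio with 95% CI.

    Group ratios are computed draw-wise as ``expit(mu)`` (covariate = 0)
    and ``expit(mu + beta)`` (covariate = 1), so their intervals carry the
    full posterior uncertainty.
    """
    from scipy.special import expit

    if spec is None:
        spec = MaternalModelSpec(covariates=(covariate,))
    elif covariate not in spec.covariates:
        raise ConfigurationError(
            f"covariate {covariate!r} missing from the model spec"
        )
    model = MaternalSexRatioModel(records, spec=spec)
    res = model.fit(config or McmcConfig())
    mu = res.draws.post_burn_in("mu").reshape(-1)
    beta = res.draws.post_burn_in(f"beta[{covariate}]").reshape(-1)
    g0 = expit(mu)
    g1 = expit(mu + beta)

    def _ci(x: np.ndarray) -> tuple[float, float]:
        return float(np.quantile(x, 0.025)), float(np.quantile(x, 0.975))

    return GroupContrastResult(
        covariate=covariate,
        beta_mean=float(beta.mean()),
        beta_ci=_ci(beta),
        group0_ratio=float(g0.mean()),
        group0_ci=_ci(g0),
        group1_ratio=float(g1.mean()),
        group1_ci=_ci(g1),
        results=res,
    )


@dataclass
class MechanismDiagnostic:
    """Ratio of mean brood sizes (infected / uninfected) with a percentile
    bootstrap interval; values near 0.5 point at male killing, near 1.0 at
    feminization or no manipulation."""

    ratio: float
    ci: tuple[float, float]
    n_infected: int
    n_uninfected: int
    n_resamples: int


def clutch_size_mechanism_diagnostic(
    infected_sizes: Sequence[float],
    uninfected_sizes: Sequence[float],
    n_resamples: int = 10_000,
    seed: int = 0,
) -> MechanismDiagnostic:
    """Point estimate and clutch-level percentile bootstrap CI of the
    hatched-brood-size ratio between infected and uninfected dams."""
    inf = np.asarray(infected_sizes, dtype=float)
    uninf = np.asarray(uninfected_sizes, dtype=float)
    if inf.size < 2 or uninf.size < 2:
        raise DomainError("each infection group needs >= 2 clutches")
    if uninf.mean() == 0.0:
        raise UndefinedValueError("uninfected mean brood size is zero")
    point = float(inf.mean() / uninf.mean())
    rng = np.random.default_rng(seed)
    idx_i = rng.integers(0, inf.size, size=(n_resamples, inf.size))
    idx_u = rng.integers(0, uninf.size, size=(n_resamples, uninf.size))
    means_u = uninf[idx_u].mean(axis=1)
    means_i = inf[idx_i].mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = means_i / means_u
    ratios = ratios[np.isfinite(ratios)]
    ci = (float(np.quantile(ratios, 0.025)), float(np.quantile(ratios, 0.975)))
    return MechanismDiagnostic(
        ratio=point,
        ci=ci,
        n_infected=int(inf.size),
        n_uninfected=int(uninf.size),
        n_resamples=n_resamples,
    )
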