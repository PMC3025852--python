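"""Dense-grid quadrature oracle for small posteriors.

With the precisions fixed and at most three free location parameters
(the intercept plus matriline effects), the unnormalized posterior can be
integrated on a dense tensor grid. This is an independent check of the
MCMC sampler on tiny instances, not a fitting method.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from .errors import CapabilityError, ConfigurationError
from .model import MaternalModelSpec, _FitData, _softplus
from .pedigree import DamRecord

__all__ = ["posterior_oracle_small"]

_MAX_FREE = 3


def posterior_oracle_small(
    records: Sequence[DamRecord],
    spec: Optional[MaternalModelSpec] = None,
    tau_m: float = 1.0,
    tau_e: float = 1.0,
    free: Sequence[str] = ("mu",),
    n_points: int = 161,
    half_width_sds: float = 6.0,
) -> dict[str, float]:
    """Posterior means of free location parameters by grid integration.

    ``free`` names the parameters to integrate over: ``"mu"`` and/or
    matriline ids (their ``m`` effects). All other location effects are
    fixed at 0 and the dam level is ignored (use it with
    ``MaternalModelSpec(dam_effect=False)`` fits). Each axis spans
    ``half_width_sds`` prior standard deviations around 0 (for ``mu`` the
    prior sd is ``sqrt(prior_location_variance)``, for effects
    ``1/sqrt(tau_m)``), with ``n_points`` nodes.
    """
    spec = spec or MaternalModelSpec(dam_effect=False)
    if len(free) == 0:
        raise ConfigurationError("need at least one free parameter")
    if len(free) > _MAX_FREE:
        raise CapabilityError(
            f"oracle supports at most {_MAX_FREE} free parameters, got {len(free)}"
        )
    if half_width_sds < 6.0:
        raise ConfigurationError("grid must cover >= 6 prior standard deviations")
    data = _FitData(records, spec)
    if data.X.shape[1]:
        raise CapabilityError("oracle does not support fixed-effect covariates")

    free = list(free)
    axes = []
    for name in free:
        if name == "mu":
            sd = float(np.sqrt(spec.prior_location_variance))
        else:
            if name not in data.mat_names:
                raise ConfigurationError(f"unknown matriline {name!r}")
            sd = tau_m ** -0.5
        axes.append(np.linspace(-half_width_sds * sd, half_width_sds * sd, n_points))
    grids = np.meshgrid(*axes, indexing="ij")

    logpost = np.zeros(grids[0].shape)
    # prior terms for the free parameters
    for name, grid in zip(free, grids):
        if name == "mu":
            logpost += -0.5 * grid**2 / spec.prior_location_variance
        else:
            logpost += -0.5 * tau_m * grid**2

    mu_grid = grids[free.index("mu")] if "mu" in free else 0.0
    for i, rec in enumerate(data.records):
        mat = rec.matriline_id
        eta = mu_grid + (grids[free.index(mat)] if mat in free else 0.0)
        eta = np.asarray(eta, dtype=float)
        logpost += data.k[i] * eta - data.n[i] * _softplus(eta)

    logpost -= logpost.max()
    weights = np.exp(logpost)
    total = weights.sum()
    return {
        name: float((weights * grid).sum() / total)
        for name, grid in zip(free, grids)
    }
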