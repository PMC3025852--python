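import numpy as np
import pytest
from hypothesis import settings
from scipy.special import expit, logit

import matriline as ml

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=60)
settings.load_profile("ci")


@pytest.fixture
def tiny_pedigree():
    """Founder F1 with daughter D1, granddaughter G1 and son S1, plus an
    unrelated founder F2; two clutches for F1, one for D1."""
    individuals = [
        ml.Individual("F1", None, ml.Sex.FEMALE, "popA"),
        ml.Individual("F2", None, ml.Sex.FEMALE, "popA"),
        ml.Individual("D1", "F1", ml.Sex.FEMALE, "popA"),
        ml.Individual("G1", "D1", ml.Sex.FEMALE, "popA"),
        ml.Individual("S1", "F1", ml.Sex.MALE, "popA"),
    ]
    clutches = [
        ml.Clutch("F1", 2, 3, 6, clutch_index=1),
        ml.Clutch("F1", 1, 4, 5, clutch_index=2),
        ml.Clutch("D1", 0, 5, 8, clutch_index=1),
    ]
    return ml.Pedigree(individuals, clutches)


def make_binomial_records(
    rng,
    n_matrilines=30,
    dams_per_matriline=2,
    n_offspring=15,
    mu=float(logit(0.34)),
    sigma2_m=0.64,
    sigma2_e=0.27,
    covariate=None,
):
    """Dam records drawn straight from the generative model (no pedigree
    plumbing): the fastest route to calibrated fit experiments."""
    records = []
    for j in range(n_matrilines):
        m = rng.normal(0.0, np.sqrt(sigma2_m))
        for d in range(dams_per_matriline):
            e = rng.normal(0.0, np.sqrt(sigma2_e))
            k = int(rng.binomial(n_offspring, expit(mu + m + e)))
            cov = {} if covariate is None else dict(covariate)
            records.append(
                ml.DamRecord(
                    dam_id=f"d{j}_{d}",
                    matriline_id=f"M{j:03d}",
                    total_male=k,
                    total_female=n_offspring - k,
                    covariates=cov,
                )
            )
    return records


@pytest.fixture
def binomial_records_factory():
    return make_binomial_records
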