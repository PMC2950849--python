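import numpy as np
import pytest

from rsfbayes import (
    FitResult,
    MCMCConfig,
    ModelFormula,
    PatchCovariates,
    Standardization,
    UseRecord,
    build_design,
)


def make_records(bares, heights, ys, ids):
    """Build a UseRecord list from parallel sequences."""
    return [
        UseRecord(individual_id=i, y=int(y), covs=PatchCovariates(bare=b, height=h))
        for b, h, y, i in zip(bares, heights, ys, ids)
    ]


@pytest.fixture
def ten_record_fixture():
    """Fixed 10-record, 2-individual dataset used for hand-checked oracles."""
    bares = [0.1, 0.3, 0.5, 0.7, 0.9, 0.2, 0.4, 0.6, 0.8, 1.0]
    heights = [12.0, 8.0, 5.0, 3.0, 0.0, 10.0, 7.0, 4.0, 2.0, 0.0]
    ys = [1, 0, 1, 0, 1, 0, 1, 0, 1, 0]
    ids = ["a"] * 5 + ["b"] * 5
    return make_records(bares, heights, ys, ids)


@pytest.fixture
def ten_record_design(ten_record_fixture):
    return build_design(ten_record_fixture, ModelFormula.from_string("b+b2"))


def manual_fit_result(
    beta_draws,
    mu_draws=None,
    sigma_draws=None,
    deviance_draws=None,
    columns=("intercept",),
    individuals=("a", "b"),
    std_mean=None,
    std_sd=None,
):
    """Assemble a FitResult directly from draw arrays, for fixture-based tests."""
    beta = np.asarray(beta_draws, dtype=float)
    nd, n_ind, k = beta.shape
    mu = np.asarray(mu_draws, dtype=float) if mu_draws is not None else beta.mean(axis=1)
    sigma = (
        np.asarray(sigma_draws, dtype=float)
        if sigma_draws is not None
        else np.zeros((nd, k))
    )
    dev = (
        np.asarray(deviance_draws, dtype=float)
        if deviance_draws is not None
        else np.ones(nd)
    )
    covs = [c for c in ("b", "h") if c in columns]
    return FitResult(
        mu=mu,
        sigma=sigma,
        beta=beta,
        deviance=dev,
        n_chains=1,
        columns=tuple(columns),
        individuals=tuple(individuals),
        standardization=Standardization(
            mean=std_mean or {c: 0.0 for c in covs},
            sd=std_sd or {c: 1.0 for c in covs},
        ),
        formula=ModelFormula(tuple(c for c in columns if c != "intercept")),
    )


@pytest.fixture
def quick_config():
    """Short two-chain sampler settings for fast unit tests."""
    return MCMCConfig(chains=2, iterations=1200, burn_in=400, seed=7)
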