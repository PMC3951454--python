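import numpy as np
import pytest

from capturebayes.domain import CaptureDataset, SiteVisit
from capturebayes.model import ModelSpec
from capturebayes.synthetic import GeneratorConfig, generate_dataset


def make_visit(site="s0", forest="f0", x=0.0, y=0.0, year=2004, traps=5,
               nights=2, counts=None, covariates=None, season="breeding"):
    base_counts = {"total": 0, "males": 0, "females": 0, "f2": 0, "f2_teats": 0}
    if counts:
        base_counts.update(counts)
    # defaults vary with position so standardization is never degenerate
    base_covs = {"Condition": 7.0 + 0.0005 * x, "FloodDist": 2.0 + 0.001 * x,
                 "Logs": 60.0 + 0.01 * x, "RainPrevYr": 500.0 + 0.02 * x,
                 "Webs": np.nan}
    if covariates:
        base_covs.update(covariates)
    return SiteVisit(site_id=site, forest_id=forest, x=x, y=y, year=year,
                     traps=traps, nights=nights, counts=base_counts,
                     covariates=base_covs, season=season)


@pytest.fixture
def tiny_dataset():
    """3 visits at 2 sites, well-formed."""
    visits = [
        make_visit(site="s0", x=0.0, y=0.0, year=2004,
                   counts={"total": 2, "males": 1, "females": 1, "f2": 1},
                   covariates={"Condition": 6.5}),
        make_visit(site="s0", x=0.0, y=0.0, year=2005,
                   counts={"total": 1, "females": 1},
                   covariates={"Condition": 7.5}, season="JD"),
        make_visit(site="s1", x=1000.0, y=0.0, year=2004,
                   counts={"total": 3, "males": 2, "females": 1},
                   covariates={"Condition": 8.0}, season="postJD"),
    ]
    return CaptureDataset(visits=visits)


@pytest.fixture(scope="session")
def oracle_fixture():
    """4-visit, 2-covariate dataset without random effects, plus raw arrays."""
    raw1 = [-1.0, -0.3, 0.4, 1.0]
    raw2 = [0.5, -1.0, 1.0, -0.5]
    y = [1, 2, 3, 6]
    n = [10, 12, 8, 15]
    visits = []
    for i in range(4):
        visits.append(make_visit(
            site=f"s{i}", forest=f"f{i}", x=i * 1000.0, year=2004,
            traps=n[i], nights=1,
            counts={"total": y[i], "females": y[i]},
            covariates={"Condition": raw1[i], "FloodDist": raw2[i]}))
    return CaptureDataset(visits=visits), np.array(y), np.array(n)


#: Study-scale generator truth used for recovery experiments: two real
#: effects (stand condition, fallen timber) and five pure-noise covariates.
RECOVERY_BETA = {"Condition": 0.8, "FloodDist": 0.0, "Logs": 0.5,
                 "RainPrevYr": 0.0, "Webs": 0.0, "JD": 0.0, "PostJD": 0.0}


def recovery_config(seed: int) -> GeneratorConfig:
    return GeneratorConfig(seed=seed, beta=dict(RECOVERY_BETA))


@pytest.fixture(scope="session")
def strong_signal_fit():
    """One desk-scale fit of a strong-signal synthetic dataset (cached)."""
    from capturebayes.model import run_mcmc

    dataset, truth = generate_dataset(recovery_config(seed=101))
    spec = ModelSpec(seed=202)
    return dataset, truth, run_mcmc(dataset, spec)


@pytest.fixture(scope="session")
def small_dataset():
    """Smaller synthetic dataset for fast end-to-end paths."""
    cfg = GeneratorConfig(seed=11, n_sites=60, n_sites_2011=16,
                          beta=dict(RECOVERY_BETA))
    return generate_dataset(cfg)
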