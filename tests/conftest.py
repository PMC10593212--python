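import sys
from pathlib import Path

import numpy as np
import pytest
from hypothesis import settings

sys.path.insert(0, str(Path(__file__).parent))  # make the naive oracle importable

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

from vawrisk.electre import CriterionSpec, LimitProfiles, ModelConfig, default_config


@pytest.fixture(scope="session")
def study_config() -> ModelConfig:
    """The published configuration: 4 criteria, 5 profiles, lambda = 0.60."""
    return default_config()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


def random_instance(rng, n_criteria=4, n_profiles=5):
    """Random TRI-B instance with valid thresholds q <= p <= v."""
    q, p, v = np.sort(rng.uniform(0.0, 0.6, size=(3, n_criteria)), axis=0)
    weights = rng.uniform(0.1, 1.0, size=n_criteria)
    profiles = np.sort(rng.uniform(0.0, 1.0, size=(n_profiles, n_criteria)),
                       axis=0)
    criteria = tuple(
        CriterionSpec(code=f"C{j + 1}", weight=float(weights[j]),
                      q=float(q[j]), p=float(p[j]), v=float(v[j]))
        for j in range(n_criteria))
    boundaries = {f"C{j + 1}": tuple(float(x) for x in profiles[:, j])
                  for j in range(n_criteria)}
    config = ModelConfig(criteria=criteria,
                         profiles=LimitProfiles(boundaries=boundaries),
                         lambda_cut=float(rng.uniform(0.5, 0.95)))
    return config, profiles


@pytest.fixture
def sample_csv(tmp_path) -> Path:
    """Tiny hand-written indicator CSV (3 municipalities, 1 missing HDI)."""
    text = (
        "id,name,eq_police_station,eq_programs,eq_campaigns,eq_rights_body,"
        "eq_hr_policy,hdi,gdp_per_capita,gini,complaints\n"
        "A,Alpha,1,1,1,1,1,0.75,30000,0.52,40\n"
        "B,Beta,0,1,0,0,0,,12000,0.61,5\n"
        "C,Gamma,0,0,0,0,0,0.48,8000,0.70,\n"
    )
    path = tmp_path / "municipalities.csv"
    path.write_text(text, encoding="utf-8")
    return path
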